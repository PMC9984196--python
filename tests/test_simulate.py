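"""Generator correctness: determinism, planted truth, distributional sanity."""

import numpy as np
import pandas as pd
import pytest

import rnaloc as rl
from rnaloc import ConfigurationError


class TestEnrichmentCounts:
    def test_same_seed_bit_identical(self):
        cfg = rl.EnrichmentSimConfig(n_genes=300, seed=42)
        cm1, t1 = rl.generate_enrichment_counts(cfg)
        cm2, t2 = rl.generate_enrichment_counts(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counts_are_nonnegative_integers(self):
        cm, _ = rl.generate_enrichment_counts(rl.EnrichmentSimConfig(n_genes=200, seed=0))
        values = cm.counts.to_numpy()
        assert (values >= 0).all()
        assert np.issubdtype(values.dtype, np.integer)

    def test_truth_labels_partition_genes(self):
        cfg = rl.EnrichmentSimConfig(
            n_genes=400, enriched_fraction=0.2, depleted_fraction=0.1, seed=5
        )
        cm, truth = rl.generate_enrichment_counts(cfg)
        assert list(truth["gene_id"]) == list(cm.gene_ids)
        assert set(truth["label"]) == {"enriched", "depleted", "null"}
        assert (truth["label"] == "enriched").sum() == 80
        assert (truth["label"] == "depleted").sum() == 40
        assert np.all(truth.loc[truth.label == "null", "true_log2fc"] == 0)

    def test_null_effect_gives_zero_mean_bias(self):
        cfg = rl.EnrichmentSimConfig(
            n_genes=5000, enriched_fraction=0.0, size_factor_range=(1.0, 1.0), seed=7
        )
        cm, _ = rl.generate_enrichment_counts(cfg)
        bias = rl.compute_bias(cm, "pulldown", "input", min_count=0)
        assert abs(bias["bias"].mean()) < 0.05

    def test_poisson_limit_ratio(self):
        # near-zero dispersion, unit size factors, large means: the raw
        # count ratio per enriched gene approaches 2**effect
        cfg = rl.EnrichmentSimConfig(
            n_genes=500,
            mean_log_expression=np.log(5000.0),
            sd_log_expression=0.2,
            dispersion=1e-6,
            enriched_fraction=1.0,
            effect_log2fc=2.0,
            size_factor_range=(1.0, 1.0),
            seed=3,
        )
        cm, truth = rl.generate_enrichment_counts(cfg)
        pulled = cm.counts[cm.samples_of("pulldown")].mean(axis=1)
        inp = cm.counts[cm.samples_of("input")].mean(axis=1)
        ratio = pulled / inp
        assert np.all(np.abs(ratio / 4.0 - 1.0) < 0.05)

    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            rl.EnrichmentSimConfig(dispersion=0.0)
        with pytest.raises(ConfigurationError):
            rl.EnrichmentSimConfig(n_replicates=0)
        with pytest.raises(ConfigurationError):
            rl.EnrichmentSimConfig(enriched_fraction=0.8, depleted_fraction=0.3)


class TestSpotTable:
    def test_zero_shift_matches_control(self):
        cfg = rl.SpotSimConfig(n_cells=30, spots_per_cell=200, spot_noise_sd=0.0, seed=1)
        spots, _ = rl.generate_spot_table(cfg, [("target", 0.0)])
        mean_by = spots.groupby("target")["z_um"].mean()
        assert abs(mean_by["target"] - mean_by["Fluc"]) < 0.2

    def test_translated_uniform_mean_shift(self):
        # band inset from the slab keeps the translated law un-clipped, so
        # the mean displacement equals the planted shift exactly
        cfg = rl.SpotSimConfig(
            n_cells=30, spots_per_cell=400, spot_noise_sd=0.0, z_band=(4.0, 12.0), seed=2
        )
        spots, truth = rl.generate_spot_table(cfg, [("basal_reporter", -2.0)])
        mean_by = spots.groupby("target")["z_um"].mean()
        delta = mean_by["basal_reporter"] - mean_by["Fluc"]
        assert delta == pytest.approx(-2.0, abs=0.05)
        assert truth.set_index("target").loc["basal_reporter", "true_shift_um"] == -2.0

    def test_z_inside_slab(self):
        cfg = rl.SpotSimConfig(n_cells=4, spots_per_cell=100, spot_noise_sd=1.0, seed=3)
        spots, _ = rl.generate_spot_table(cfg, [("t", -3.0), ("u", 3.0)])
        assert spots["z_um"].between(0.0, cfg.cell_height).all()

    def test_empty_table_for_zero_cells(self):
        spots, truth = rl.generate_spot_table(
            rl.SpotSimConfig(n_cells=0, seed=0), [("t", 1.0)]
        )
        assert len(spots) == 0
        assert list(truth["target"]) == ["Fluc", "t"]

    def test_every_spot_has_cell_and_unique_id(self):
        spots, _ = rl.generate_spot_table(
            rl.SpotSimConfig(n_cells=3, spots_per_cell=50, seed=4), [("t", 1.0)]
        )
        assert spots["cell_id"].notna().all()
        assert spots["spot_id"].is_unique

    def test_overlarge_shift_rejected(self):
        cfg = rl.SpotSimConfig(seed=0)
        with pytest.raises(ConfigurationError):
            rl.generate_spot_table(cfg, [("t", -20.0)])

    def test_same_seed_identical(self):
        cfg = rl.SpotSimConfig(n_cells=3, spots_per_cell=20, seed=9)
        s1, _ = rl.generate_spot_table(cfg, [("t", -1.0)])
        s2, _ = rl.generate_spot_table(cfg, [("t", -1.0)])
        pd.testing.assert_frame_equal(s1, s2)


class TestUtrSet:
    def test_planted_motifs_recovered_exactly(self):
        cfg = rl.UtrSimConfig(n_sequences=60, seed=1)
        records, truth = rl.generate_utr_set(cfg)
        annotation = rl.annotate_genes(records)
        merged = annotation.merge(truth, left_on="gene_id", right_on="sequence_id")
        planted = merged[merged["planted_start"].notna()]
        assert (planted["has_prre"]).all()
        assert np.array_equal(
            planted["position"].to_numpy(), planted["element_start"].to_numpy()
        )
        clean = merged[merged["planted_start"].isna()]
        # background can produce rare spurious hits, but not at defaults/seed
        assert not clean["has_prre"].any()

    def test_position_one_is_top_downstream_is_prte(self):
        cfg = rl.UtrSimConfig(
            n_sequences=2,
            planted_fraction=1.0,
            planted_position_range=(1, 1),
            seed=2,
        )
        records, _ = rl.generate_utr_set(cfg)
        hits = rl.scan_prre(str(records[0].seq))
        assert hits[0].start == 1 and hits[0].motif_class == "TOP"
        cfg40 = rl.UtrSimConfig(
            n_sequences=2, planted_fraction=1.0, planted_position_range=(40, 40), seed=2
        )
        records40, truth40 = rl.generate_utr_set(cfg40)
        hits40 = rl.scan_prre(str(records40[0].seq))
        # the window holding the flank purine plus nine run pyrimidines
        # qualifies, so the element begins one base before the run
        assert hits40[0].start == 39 and hits40[0].motif_class == "PRTE"
        assert truth40.loc[0, "element_start"] == 39

    def test_zero_background_pyrimidines_no_spurious_hits(self):
        cfg = rl.UtrSimConfig(
            n_sequences=40, planted_fraction=0.0, background_pyrimidine_prob=0.0, seed=3
        )
        records, _ = rl.generate_utr_set(cfg)
        assert all(not rl.scan_prre(str(r.seq)) for r in records)

    def test_background_rarely_qualifies(self):
        # empirical check of the composition invariant: spurious-hit
        # probability below 5% at default background settings
        cfg = rl.UtrSimConfig(n_sequences=400, planted_fraction=0.0, seed=4)
        records, _ = rl.generate_utr_set(cfg)
        frac = np.mean([bool(rl.scan_prre(str(r.seq))) for r in records])
        assert frac < 0.05

    def test_motif_must_fit(self):
        with pytest.raises(ConfigurationError):
            rl.UtrSimConfig(length_range=(30, 50), planted_position_range=(25, 25))

    def test_same_seed_identical(self):
        cfg = rl.UtrSimConfig(n_sequences=10, seed=5)
        r1, t1 = rl.generate_utr_set(cfg)
        r2, t2 = rl.generate_utr_set(cfg)
        assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]
        pd.testing.assert_frame_equal(t1, t2)


class TestMultidatasetLr:
    def test_noise_free_identity_lrz(self):
        effects = np.linspace(-2, 2, 50)
        mat, _ = rl.generate_multidataset_lr(
            50, 3, gene_effects=effects,
            dataset_scales=np.ones(3), dataset_offsets=np.zeros(3),
            noise_sd=0.0, seed=0,
        )
        lrz = rl.compute_lrz(mat)
        expected = (effects - effects.mean()) / effects.std(ddof=1)
        assert np.allclose(lrz.lrz.to_numpy(), expected)

    def test_affine_distortions_cancel(self):
        effects = np.random.default_rng(1).normal(size=80)
        plain, _ = rl.generate_multidataset_lr(
            80, 4, gene_effects=effects,
            dataset_scales=np.ones(4), dataset_offsets=np.zeros(4),
            noise_sd=0.0, seed=2,
        )
        skewed, _ = rl.generate_multidataset_lr(
            80, 4, gene_effects=effects,
            dataset_scales=np.array([0.2, 1.0, 5.0, 3.3]),
            dataset_offsets=np.array([-4.0, 0.0, 7.5, 1.1]),
            noise_sd=0.0, seed=2,
        )
        dev = (rl.compute_lrz(plain).lrz - rl.compute_lrz(skewed).lrz).abs().max()
        assert dev < 1e-9

    def test_missing_mask_and_seeding(self):
        m1, _ = rl.generate_multidataset_lr(100, 5, missing_rate=0.2, seed=3)
        m2, _ = rl.generate_multidataset_lr(100, 5, missing_rate=0.2, seed=3)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.05)

    def test_nonpositive_scales_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.generate_multidataset_lr(10, 2, dataset_scales=np.array([1.0, -1.0]), seed=0)


class TestQpcrCt:
    @pytest.mark.parametrize("true_lr", [-3.0, -1.5, 0.0, 2.0, 3.0])
    def test_zero_noise_inverts_exactly(self, true_lr):
        ct = rl.generate_qpcr_ct(true_lr, noise_sd=0.0, seed=0)
        assert rl.qpcr_localization_ratio(ct) == pytest.approx(true_lr, abs=1e-12)

    def test_monte_carlo_recovery_with_noise(self):
        # at 0.1-cycle noise and 3 replicates the recovered LR stays within
        # +-0.3 of truth in at least 95% of simulations
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            ct = rl.generate_qpcr_ct(2.0, replicates=3, noise_sd=0.1, seed=i)
            hits += abs(rl.qpcr_localization_ratio(ct) - 2.0) <= 0.3
        assert hits / n_sim >= 0.95

    def test_replicates_validated(self):
        with pytest.raises(ConfigurationError):
            rl.generate_qpcr_ct(1.0, replicates=0)
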