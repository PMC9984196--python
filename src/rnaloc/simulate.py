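"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one experimental data
type and returns both the data and a truth table of the planted signal:

* negative-binomial fraction-pair count matrices with planted log2
  enrichment for designated gene sets (proximity-labeling pulldown/input,
  apical/basal, neurite/soma designs);
* 5' UTR sets with pyrimidine runs planted at recorded positions;
* per-cell 3D smFISH spot clouds with planted apicobasal shifts relative
  to a uniformly distributed control transcript;
* gene x dataset localization-ratio matrices with per-dataset affine
  distortions over a shared latent effect;
* qPCR Ct tables whose delta-delta-Ct inverts to a planted localization
  ratio.

All randomness flows from explicit ``seed`` fields; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from ._exceptions import ConfigurationError
from .containers import CountMatrix
from .io import make_record

DEFAULT_CONTROL_TARGET = "Fluc"  # untagged Firefly luciferase, the non-localized control


# ---------------------------------------------------------------------------
# fraction-pair counts


@dataclass
class EnrichmentSimConfig:
    """Conditions for a two-fraction NB count simulation.

    The variance model is Var = mu + dispersion * mu**2 (the common RNA-seq
    convention); gene base means are log-normal. ``enriched_fraction`` of
    genes carry ``effect_log2fc`` in the numerator fraction,
    ``depleted_fraction`` carry ``-effect_log2fc``, the rest are null.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    mean_log_expression: float = float(np.log(500.0))
    sd_log_expression: float = 1.0
    dispersion: float = 0.05
    enriched_fraction: float = 0.10
    depleted_fraction: float = 0.0
    effect_log2fc: float = 2.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("replicate count must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.sd_log_expression <= 0:
            raise ConfigurationError("sd_log_expression must be positive")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ConfigurationError("enriched_fraction must lie in [0, 1]")
        if not 0.0 <= self.depleted_fraction <= 1.0 - self.enriched_fraction:
            raise ConfigurationError("enriched + depleted fractions must not exceed 1")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("size_factor_range must be a positive interval")


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, Var = mu + a mu^2) via the gamma-Poisson mixture."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_enrichment_counts(
    config: EnrichmentSimConfig,
    design: tuple[str, str] = ("pulldown", "input"),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate counts for a (numerator, denominator) fraction pair.

    Returns the count matrix (2 x n_replicates samples) and a truth table
    with columns ``gene_id``, ``label`` (enriched/depleted/null) and
    ``true_log2fc``. Enriched genes have expected numerator/denominator
    ratio ``2**effect_log2fc`` after size-factor correction.
    """
    numerator, denominator = design
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(g)], name="gene_id")

    base_mean = rng.lognormal(config.mean_log_expression, config.sd_log_expression, g)
    n_enr = int(round(config.enriched_fraction * g))
    n_dep = int(round(config.depleted_fraction * g))
    effect = np.zeros(g)
    labels = np.array(["null"] * g, dtype=object)
    idx = rng.permutation(g)
    effect[idx[:n_enr]] = config.effect_log2fc
    labels[idx[:n_enr]] = "enriched"
    effect[idx[n_enr : n_enr + n_dep]] = -config.effect_log2fc
    labels[idx[n_enr : n_enr + n_dep]] = "depleted"

    n = config.n_replicates
    lo, hi = config.size_factor_range
    size_factors = rng.uniform(lo, hi, 2 * n)

    sample_ids, fractions, columns = [], [], []
    for j, (fraction, fc) in enumerate(
        [(numerator, 2.0**effect), (denominator, np.ones(g))]
    ):
        for rep in range(n):
            s = j * n + rep
            mu = base_mean * fc * size_factors[s]
            columns.append(_nb_draws(rng, mu, config.dispersion))
            sample_ids.append(f"{fraction}_rep{rep + 1}")
            fractions.append(fraction)

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    meta = pd.DataFrame(
        {
            "fraction": fractions,
            "replicate": [int(s.rsplit("rep", 1)[1]) for s in sample_ids],
            "dataset": "sim",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "label": labels, "true_log2fc": effect}
    ).reset_index(drop=True)
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# smFISH spot clouds


@dataclass
class SpotSimConfig:
    """Conditions for a per-cell 3D spot cloud simulation.

    z runs apically from the basal surface at z=0 up to ``cell_height``
    (micrometres). Spots of the control transcript are uniform over
    ``z_band`` (the full slab by default); a shifted target follows the
    same law translated by its shift, with Gaussian localization noise,
    and is kept inside the slab by reject-and-resample. Choosing a band
    inset from the slab boundaries by at least |shift| + 3*noise keeps
    the translated law un-clipped, so the planted shift equals the true
    mean displacement.
    """

    n_cells: int = 20
    spots_per_cell: int = 200
    cell_height: float = 12.6
    spot_noise_sd: float = 0.5
    z_band: tuple[float, float] | None = None
    xy_extent: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.spots_per_cell < 1:
            raise ConfigurationError("cell and spot counts must be positive")
        if self.cell_height <= 0:
            raise ConfigurationError("cell_height must be positive")
        if self.spot_noise_sd < 0:
            raise ConfigurationError("spot_noise_sd must be non-negative")
        if self.z_band is not None:
            lo, hi = self.z_band
            if not (0.0 <= lo < hi <= self.cell_height):
                raise ConfigurationError("z_band must be a sub-interval of [0, cell_height]")


def generate_spot_table(
    config: SpotSimConfig,
    targets: list[tuple[str, float]],
    control_target: str = DEFAULT_CONTROL_TARGET,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spot tables for a control plus shifted targets.

    ``targets`` is a list of (name, z shift in micrometres; negative =
    basal). A control target with shift 0 is always generated. Each target
    is expressed in its own set of ``n_cells`` cells, mirroring reporter
    experiments where control and target constructs live in different
    cells. Returns the spot table and a truth table target -> shift.
    """
    rng = np.random.default_rng(config.seed)
    h = config.cell_height
    band = config.z_band if config.z_band is not None else (0.0, h)
    all_targets = [(control_target, 0.0)] + list(targets)
    for name, shift in all_targets:
        if abs(shift) >= h:
            raise ConfigurationError(f"target {name!r}: |shift| {abs(shift)} exceeds cell height {h}")
        if abs(shift) + 3.0 * config.spot_noise_sd >= h:
            raise ConfigurationError(
                f"target {name!r}: |shift| + 3*noise must stay below cell_height"
            )

    frames = []
    for name, shift in all_targets:
        for c in range(config.n_cells):
            m = config.spots_per_cell
            z = np.empty(m)
            todo = np.arange(m)
            while todo.size:  # reject-and-resample outside the slab
                draw = (
                    rng.uniform(band[0], band[1], todo.size)
                    + shift
                    + rng.normal(0.0, config.spot_noise_sd, todo.size)
                )
                ok = (draw >= 0.0) & (draw <= h)
                z[todo[ok]] = draw[ok]
                todo = todo[~ok]
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": f"{name}_cell{c:03d}",
                        "target": name,
                        "x_um": rng.uniform(0.0, config.xy_extent, m),
                        "y_um": rng.uniform(0.0, config.xy_extent, m),
                        "z_um": z,
                    }
                )
            )
    if frames:
        spots = pd.concat(frames, ignore_index=True)
    else:
        spots = pd.DataFrame(columns=["cell_id", "target", "x_um", "y_um", "z_um"])
    spots.insert(0, "spot_id", [f"spot{i:07d}" for i in range(len(spots))])
    truth = pd.DataFrame(
        {"target": [t for t, _ in all_targets], "true_shift_um": [s for _, s in all_targets]}
    )
    return spots, truth


# ---------------------------------------------------------------------------
# 5' UTR sequence sets

_PYRIMIDINES = np.array(list("CT"))
_PURINES = np.array(list("AG"))


@dataclass
class UtrSimConfig:
    """Conditions for a synthetic 5' UTR set.

    Planted motifs are solid pyrimidine runs of ``planted_motif_length`` at
    a position drawn from ``planted_position_range`` (1-based), flanked by
    one purine window on each side so the element's boundaries are
    unambiguous. Background bases are pyrimidine with probability
    ``background_pyrimidine_prob`` (< 0.5 keeps spurious qualifying windows
    rare).
    """

    n_sequences: int = 200
    length_range: tuple[int, int] = (60, 200)
    planted_motif_length: int = 12
    planted_position_range: tuple[int, int] = (1, 40)
    planted_fraction: float = 0.5
    background_pyrimidine_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ConfigurationError("n_sequences must be non-negative")
        if self.planted_motif_length < 10:
            raise ConfigurationError("planted_motif_length must be at least 10")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigurationError("planted_fraction must lie in [0, 1]")
        if not 0.0 <= self.background_pyrimidine_prob < 0.5:
            raise ConfigurationError("background_pyrimidine_prob must lie in [0, 0.5)")
        lo, hi = self.length_range
        plo, phi = self.planted_position_range
        if lo < 1 or hi < lo or plo < 1 or phi < plo:
            raise ConfigurationError("length and position ranges must be non-empty")
        if phi + self.planted_motif_length - 1 > lo:
            raise ConfigurationError(
                "planted motif at the largest position does not fit in the shortest sequence"
            )


def _background(rng: np.random.Generator, n: int, p_pyr: float) -> np.ndarray:
    is_pyr = rng.random(n) < p_pyr
    bases = np.where(
        is_pyr,
        _PYRIMIDINES[rng.integers(0, 2, n)],
        _PURINES[rng.integers(0, 2, n)],
    )
    return bases


def generate_utr_set(config: UtrSimConfig) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate 5' UTRs, planting pyrimidine runs in a subset.

    Returns FASTA records and a truth table with columns ``sequence_id``,
    ``planted_start`` (1-based start of the pyrimidine run; NaN for
    sequences without a motif) and ``element_start`` (where the window
    rule places the merged element: one base earlier for interior runs,
    because a window holding one flank purine plus nine run pyrimidines
    still qualifies under the 9-of-10 rule).
    """
    rng = np.random.default_rng(config.seed)
    n_planted = int(round(config.planted_fraction * config.n_sequences))
    records: list[SeqRecord] = []
    rows = []
    window = 10  # insulator flank width, matching the scanner window
    for i in range(config.n_sequences):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _background(rng, length, config.background_pyrimidine_prob)
        planted = i < n_planted
        start = np.nan
        if planted:
            start = int(
                rng.integers(config.planted_position_range[0], config.planted_position_range[1] + 1)
            )
            s0 = start - 1  # 0-based
            s1 = s0 + config.planted_motif_length
            seq[s0:s1] = _PYRIMIDINES[rng.integers(0, 2, config.planted_motif_length)]
            # purine insulator flanks keep the merged element exactly at the
            # planted coordinates
            left = max(0, s0 - window)
            seq[left:s0] = _PURINES[rng.integers(0, 2, s0 - left)]
            right = min(length, s1 + window)
            seq[s1:right] = _PURINES[rng.integers(0, 2, right - s1)]
        seq_id = f"utr{i:04d}"
        records.append(make_record("".join(seq), seq_id))
        element = start if (not planted or start == 1) else start - 1
        rows.append(
            {"sequence_id": seq_id, "planted_start": start, "element_start": element}
        )
    truth = pd.DataFrame(rows, columns=["sequence_id", "planted_start", "element_start"])
    return records, truth


# ---------------------------------------------------------------------------
# multi-dataset localization-ratio matrices


def generate_multidataset_lr(
    n_genes: int,
    n_datasets: int,
    gene_effects: np.ndarray | None = None,
    dataset_scales: np.ndarray | None = None,
    dataset_offsets: np.ndarray | None = None,
    noise_sd: float = 0.3,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x dataset LR matrix with per-dataset distortions.

    Entry (g, d) = offset_d + scale_d * (effect_g + noise). Because the
    LRz statistic z-normalizes within each dataset, the affine distortions
    are removed downstream. An optional missing-at-random mask emulates
    genes absent from some experiments. Returns the matrix and the truth
    table of latent gene effects.
    """
    rng = np.random.default_rng(seed)
    if gene_effects is None:
        gene_effects = rng.normal(0.0, 1.0, n_genes)
    gene_effects = np.asarray(gene_effects, dtype=float)
    if gene_effects.shape != (n_genes,):
        raise ConfigurationError("gene_effects must have length n_genes")
    if dataset_scales is None:
        dataset_scales = rng.uniform(0.5, 2.0, n_datasets)
    dataset_scales = np.asarray(dataset_scales, dtype=float)
    if dataset_offsets is None:
        dataset_offsets = rng.normal(0.0, 1.0, n_datasets)
    dataset_offsets = np.asarray(dataset_offsets, dtype=float)
    if (dataset_scales <= 0).any():
        raise ConfigurationError("dataset scales must be positive")
    if dataset_scales.shape != (n_datasets,) or dataset_offsets.shape != (n_datasets,):
        raise ConfigurationError("dataset scales/offsets must have length n_datasets")

    noise = rng.normal(0.0, noise_sd, (n_genes, n_datasets)) if noise_sd > 0 else 0.0
    values = dataset_offsets + dataset_scales * (gene_effects[:, None] + noise)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    dataset_ids = [f"dataset{d + 1:02d}" for d in range(n_datasets)]
    mat = pd.DataFrame(values, index=gene_ids, columns=dataset_ids)
    if missing_rate > 0:
        mask = rng.random((n_genes, n_datasets)) < missing_rate
        mat = mat.mask(mask)
    truth = pd.DataFrame({"gene_id": gene_ids, "true_effect": gene_effects}).reset_index(
        drop=True
    )
    return mat, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_qpcr_ct(
    true_lr: float,
    base_ct: float = 25.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table whose delta-delta-Ct inverts to ``true_lr``.

    The reference transcript (the internal control, e.g. Renilla
    luciferase) has identical expected Ct in both fractions; the reporter's
    neurite Ct is offset so that LR = (dCt_soma - dCt_neurite) equals the
    planted value at efficiency 2. Gaussian cycle noise applies per
    replicate.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be at least 1")
    rng = np.random.default_rng(seed)
    expected = {
        ("reference", "neurite"): base_ct,
        ("reference", "soma"): base_ct,
        ("reporter", "soma"): base_ct + 2.0,
        ("reporter", "neurite"): base_ct + 2.0 - true_lr,
    }
    rows = []
    for (target, fraction), ct0 in expected.items():
        for rep in range(1, replicates + 1):
            ct = ct0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"target": target, "fraction": fraction, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)
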