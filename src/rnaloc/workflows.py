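"""End-to-end workflows tying the analysis stages together.

A :class:`RunConfig` holds input paths, thresholds and the seed; each run
writes its outputs plus a verbatim copy of the serialized config and a
structured JSON report into the output directory, so every result is
reproducible and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._exceptions import InputError
from . import io as rio
from .crosscomp import class_bias_summary, compute_lrz, correlate_compartments
from .enrichment import compute_bias
from .motifs import annotate_genes, bias_by_motif_class

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for the end-to-end workflows.

    Thresholds follow the analysis conventions: genes need 10 counts in
    some sample to enter a contrast; cytoplasmic-bias calls use FDR 0.01
    and apical-bias calls FDR 0.05; the scanner uses >= 9 pyrimidines in a
    10-nt window.
    """

    out_dir: str = "rnaloc_run"
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    utr_fasta_path: str | None = None
    lr_matrix_path: str | None = None
    gene_map_path: str | None = None
    metric: str = "CB"  # CB, AB, or LR
    min_count: int = 10
    fdr_threshold: float = 0.01
    scan_window: int = 10
    scan_min_pyrimidines: int = 9
    qc_min_spots: int = 100
    qc_max_spots: int = 1000
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    _CONTRASTS = {
        "CB": ("pulldown", "input"),
        "AB": ("apical", "basal"),
        "LR": ("neurite", "soma"),
    }

    def contrast(self) -> tuple[str, str]:
        try:
            return self._CONTRASTS[self.metric]
        except KeyError:
            raise InputError(f"unknown metric {self.metric!r}; pick one of CB, AB, LR")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise InputError(f"unsupported config schema version {version}")
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _prepare_out_dir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")  # provenance copy
    return out


def run_enrichment_workflow(config: RunConfig) -> dict:
    """Count matrix -> bias table + significance report.

    Writes ``bias_<metric>.tsv`` and ``report.json`` into the output
    directory and returns the report dict.
    """
    if not config.counts_path or not config.sample_sheet_path:
        raise InputError("enrichment workflow needs counts_path and sample_sheet_path")
    out = _prepare_out_dir(config)
    counts = rio.read_counts(config.counts_path, config.sample_sheet_path)
    numerator, denominator = config.contrast()
    bias = compute_bias(
        counts, numerator, denominator, min_count=config.min_count
    )
    rio.write_bias_table(bias, out / f"bias_{config.metric}.tsv")
    significant = bias["fdr"] < config.fdr_threshold
    report = {
        "metric": config.metric,
        "contrast": f"{numerator}/{denominator}",
        "n_genes_input": int(counts.counts.shape[0]),
        "n_genes_tested": int(len(bias)),
        "fdr_threshold": config.fdr_threshold,
        "n_significant": int(significant.sum()),
        "n_significant_up": int((significant & (bias["bias"] > 0)).sum()),
        "n_significant_down": int((significant & (bias["bias"] < 0)).sum()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("enrichment workflow: %s", report)
    return report


def run_localization_workflow(config: RunConfig) -> dict:
    """Motif annotation + bias-by-class + cross-compartment report.

    Scans the UTR FASTA, relates motif classes to the bias table computed
    from the counts, computes LRz from the LR matrix, summarizes motif
    classes on the LRz axis, and (when a gene map is given) correlates the
    two compartment axes. Writes annotation, class-summary and LRz tables
    plus ``report.json``.
    """
    if not config.utr_fasta_path:
        raise InputError("localization workflow needs utr_fasta_path")
    out = _prepare_out_dir(config)
    report: dict = {}

    utrs = rio.read_fasta(config.utr_fasta_path)
    annotation = annotate_genes(
        utrs, window=config.scan_window, min_pyrimidines=config.scan_min_pyrimidines
    )
    annotation.to_csv(out / "prre_annotation.tsv", sep="\t", index=False)
    report["n_genes_scanned"] = int(len(annotation))
    report["n_with_prre"] = int(annotation["has_prre"].sum())

    bias = None
    if config.counts_path and config.sample_sheet_path:
        counts = rio.read_counts(config.counts_path, config.sample_sheet_path)
        numerator, denominator = config.contrast()
        bias = compute_bias(counts, numerator, denominator, min_count=config.min_count)
        rio.write_bias_table(bias, out / f"bias_{config.metric}.tsv")
        by_class = bias_by_motif_class(bias, annotation)
        by_class.to_csv(out / "bias_by_motif_class.tsv", sep="\t", index=False)
        report["bias_by_class"] = {
            row["motif_class"]: {
                "n": int(row["n_class"]),
                "class_median": float(row["class_median"]),
                "background_median": float(row["background_median"]),
                "p_value": float(row["p_value"]),
            }
            for _, row in by_class.iterrows()
        }

    lrz = None
    if config.lr_matrix_path:
        lr = rio.read_lr_matrix(config.lr_matrix_path)
        lrz = compute_lrz(lr)
        lrz.frame().to_csv(out / "lrz.tsv", sep="\t", index=False, na_rep="NA")
        report["n_genes_lrz"] = int(lrz.lrz.notna().sum())
        prre_genes = set(annotation.loc[annotation["has_prre"], "gene_id"])
        lrz_values = lrz.lrz.dropna()
        if len(prre_genes & set(lrz_values.index)) >= 2:
            s = class_bias_summary(lrz_values, prre_genes)
            report["lrz_by_prre"] = {
                "class_median": s.class_median,
                "background_median": s.background_median,
                "p_value": s.p_value,
            }

    if bias is not None and lrz is not None:
        if not config.gene_map_path:
            raise InputError(
                "cross-compartment correlation requested (both bias and LR matrix "
                "given) but gene_map_path is missing; provide a two-column "
                "ortholog table mapping bias-side to LR-side gene ids"
            )
        gene_map = rio.read_gene_map(config.gene_map_path)
        corr = correlate_compartments(bias, lrz, gene_map)
        report["cross_compartment"] = {
            "spearman_rho": corr.rho,
            "p_value": corr.p_value,
            "n_genes": corr.n_genes,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("localization workflow: %s", report)
    return report
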