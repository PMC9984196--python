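"""Cross-dataset and cross-compartment localization statistics.

LRz pools neurite/soma localization ratios over many fractionation
experiments: each dataset's LR values are z-normalized within that
dataset, and a gene's LRz is the median of its z-scores across the
datasets where it was measured. Affine per-dataset distortions (library
scale, compositional offsets) cancel by construction. The module also
provides the delta-delta-Ct qPCR localization ratio and the Spearman
correlation between an apicobasal bias table and LRz through an ortholog
map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InputError
from .stats import rank_sum_test

logger = logging.getLogger(__name__)


@dataclass
class LrzTable:
    """Within-dataset z-scores and the per-gene LRz median."""

    z: pd.DataFrame  # gene x dataset z-scores (NaN where missing)
    lrz: pd.Series  # median z across datasets (NaN below min_datasets)
    n_datasets: pd.Series  # datasets contributing per gene
    min_datasets: int

    def frame(self) -> pd.DataFrame:
        """Tidy summary table (gene_id, lrz, n_datasets)."""
        return pd.DataFrame(
            {"gene_id": self.lrz.index, "lrz": self.lrz.to_numpy(), "n_datasets": self.n_datasets.to_numpy()}
        )


def compute_lrz(lr_matrix: pd.DataFrame, min_datasets: int | None = None) -> LrzTable:
    """Z-normalize an LR matrix within each dataset and take gene medians.

    Each dataset column is standardized over its non-missing genes (mean
    0, sd 1 with the n-1 denominator). A gene's LRz is the median of its
    available z-scores; genes measured in fewer than ``min_datasets``
    datasets (default: half the datasets, rounded up) get a missing LRz.
    """
    n_data = lr_matrix.shape[1]
    if min_datasets is None:
        min_datasets = math.ceil(n_data / 2)
    z = pd.DataFrame(index=lr_matrix.index, columns=lr_matrix.columns, dtype=float)
    for col in lr_matrix.columns:
        x = lr_matrix[col]
        ok = x.notna()
        if ok.sum() < 3:
            raise InputError(f"dataset {col!r} has fewer than 3 non-missing genes")
        sd = x[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise InputError(f"dataset {col!r} has zero variance; cannot z-normalize")
        z.loc[ok, col] = (x[ok] - x[ok].mean()) / sd
    n_per_gene = z.notna().sum(axis=1)
    lrz = z.median(axis=1)
    lrz[n_per_gene < min_datasets] = np.nan
    return LrzTable(z=z, lrz=lrz.rename("lrz"), n_datasets=n_per_gene.rename("n_datasets"), min_datasets=min_datasets)


def qpcr_localization_ratio(ct: pd.DataFrame, efficiency: float = 2.0) -> float:
    """Delta-delta-Ct localization ratio in log2 units.

    ``ct`` has columns target (reporter/reference), fraction
    (neurite/soma), replicate, ct. Technical replicates are averaged
    before the delta; the reference transcript (the unmodified internal
    control) cancels loading differences between fractions.

    LR = log2(efficiency) * [(Ct_ref,neurite - Ct_rep,neurite)
                             - (Ct_ref,soma - Ct_rep,soma)]
    which at the default perfect doubling efficiency is the plain
    delta-delta-Ct difference.
    """
    if efficiency <= 1.0:
        raise InputError("amplification efficiency must exceed 1")
    if (ct["ct"] <= 0).any():
        raise InputError("Ct values must be positive")
    means = ct.groupby(["target", "fraction"])["ct"].mean()
    needed = [(t, f) for t in ("reporter", "reference") for f in ("neurite", "soma")]
    missing = [cell for cell in needed if cell not in means.index]
    if missing:
        raise InputError(f"Ct table missing cells: {missing}")
    ddct = (means[("reference", "neurite")] - means[("reporter", "neurite")]) - (
        means[("reference", "soma")] - means[("reporter", "soma")]
    )
    return float(np.log2(efficiency) * ddct)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_genes: int


def correlate_compartments(
    bias: pd.DataFrame,
    lrz: LrzTable | pd.Series,
    gene_map: pd.DataFrame,
    subset: set[str] | None = None,
) -> CorrelationResult:
    """Spearman correlation between a bias table and LRz across species.

    ``gene_map`` maps bias-side gene ids (column ``source``) to LRz-side
    ids (column ``target``); many-to-many pairs are dropped with a logged
    count. ``subset`` optionally restricts to a gene set (ids of either
    side), e.g. ribosomal protein genes. Requires at least 10 mapped
    genes.
    """
    lrz_series = lrz.lrz if isinstance(lrz, LrzTable) else lrz
    counts_a = gene_map["source"].value_counts()
    counts_b = gene_map["target"].value_counts()
    unique = gene_map[
        gene_map["source"].map(counts_a).eq(1) & gene_map["target"].map(counts_b).eq(1)
    ]
    dropped = len(gene_map) - len(unique)
    if dropped:
        logger.info("correlate_compartments: dropped %d many-to-many map pairs", dropped)
    bias_values = bias.set_index("gene_id")["bias"]
    merged = pd.DataFrame(
        {
            "source": unique["source"].to_numpy(),
            "target": unique["target"].to_numpy(),
        }
    )
    merged["bias"] = merged["source"].map(bias_values)
    merged["lrz"] = merged["target"].map(lrz_series)
    if subset is not None:
        keep = merged["source"].isin(subset) | merged["target"].isin(subset)
        merged = merged[keep]
    merged = merged.dropna(subset=["bias", "lrz"])
    if len(merged) < 10:
        raise InputError(f"only {len(merged)} mapped genes with data; need at least 10")
    rho, p = stats.spearmanr(merged["bias"], merged["lrz"])
    return CorrelationResult(rho=float(rho), p_value=float(p), n_genes=len(merged))


@dataclass(frozen=True)
class ClassSummary:
    class_median: float
    background_median: float
    p_value: float
    n_class: int
    n_background: int


def class_bias_summary(values: pd.Series, gene_class: set[str]) -> ClassSummary:
    """Compare a gene class against all other genes on a per-gene metric.

    ``values`` is indexed by gene id (bias, LR, LRz, ...). Two-sided
    Wilcoxon rank-sum of class members versus the complement.
    """
    members = values.index.isin(set(gene_class))
    x = values[members].dropna()
    y = values[~members].dropna()
    if len(x) < 2:
        raise InputError(f"gene class has {len(x)} members with data; need at least 2")
    res = rank_sum_test(x.to_numpy(), y.to_numpy())
    return ClassSummary(
        class_median=float(x.median()),
        background_median=float(y.median()),
        p_value=res.p_value,
        n_class=len(x),
        n_background=len(y),
    )
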