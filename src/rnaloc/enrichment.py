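"""Fraction-enrichment bias metrics and the NB differential test.

A localization bias is the log2 ratio of a gene's normalized abundance in
one fraction over another: Cytoplasmic Bias (pulldown/input), Apical Bias
(apical/basal) and the neuronal Localization Ratio (neurite/soma) are the
same computation on different fraction pairs. Normalization is the
median-of-ratios size-factor method; significance comes from a Wald test
under the negative-binomial variance model Var = mu + alpha * mu**2 with
empirical-Bayes moderated per-gene dispersion, followed by
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._exceptions import InputError
from .containers import BIAS_COLUMNS, CountMatrix
from .stats import benjamini_hochberg, rank_sum_test

#: Pseudocount added to normalized fraction means before the log2 ratio.
#: Keeps zero-count fractions finite while leaving large counts untouched.
PSEUDOCOUNT = 0.5

#: Bounds on the per-gene NB dispersion estimate.
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over reference genes (rows
    with no zero counts) of count / per-gene geometric mean across samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    nonzero = (values > 0).all(axis=1)
    if not nonzero.any():
        raise InputError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    logs = np.log(values[nonzero])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_geomean, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=mat.columns, name="size_factor")


def _inverse_trigamma(x: float) -> float:
    """Solve psi'(y) = x by Newton iteration (x > 0)."""
    y = 0.5 + 1.0 / x
    for _ in range(80):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - step
        if abs(step) < 1e-12 * abs(y):
            break
    return float(y)


def _fit_cv2_prior(q: np.ndarray, df: int) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior to per-gene squared-CV estimates.

    Models q_g ~ q0 * chi2_df / df marginally on the log scale (the limma
    moment-matching approach): the excess of var(log q) over trigamma(df/2)
    determines the prior degrees of freedom d0; infinite d0 means the data
    are consistent with a single shared value.
    """
    lq = np.log(np.maximum(q, 1e-12))
    e_log_chi = special.digamma(df / 2.0) - np.log(df / 2.0)
    if lq.size < 2:
        return np.inf, float(np.exp(np.mean(lq) - e_log_chi))
    excess = np.var(lq, ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(excess) or excess <= 1e-10:
        return np.inf, float(np.exp(np.mean(lq) - e_log_chi))
    d0 = 2.0 * _inverse_trigamma(excess)
    q0 = float(
        np.exp(np.mean(lq) - e_log_chi + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, q0


def nb_wald_test(
    numerator: pd.DataFrame,
    denominator: pd.DataFrame,
    numerator_size_factors: pd.Series | np.ndarray,
    denominator_size_factors: pd.Series | np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene Wald test of log2 enrichment between two fraction groups.

    Counts are size-factor normalized; the per-gene squared coefficient of
    variation (Poisson part + NB dispersion) is estimated by the method of
    moments and squeezed toward a global prior fit across genes
    (empirical-Bayes, constant prior, no trend). The Wald statistic is
    bias / se with the standard error from the moderated NB variance, and
    the p-value is two-sided from a t reference with (prior + residual)
    degrees of freedom. Genes with all-zero counts get missing statistics.

    Returns a DataFrame indexed like the inputs with columns ``base_mean``,
    ``bias``, ``se``, ``wald_stat``, ``p_value``.
    """
    if not numerator.index.equals(denominator.index):
        raise InputError("numerator and denominator gene indices differ")
    n1 = numerator.shape[1]
    n2 = denominator.shape[1]
    if n1 + n2 < 2 or n1 < 1 or n2 < 1:
        raise InputError("need at least one sample per fraction and two in total")

    y1 = numerator.to_numpy(dtype=float) / np.asarray(numerator_size_factors, dtype=float)
    y2 = denominator.to_numpy(dtype=float) / np.asarray(denominator_size_factors, dtype=float)
    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    c = pseudocount
    # the log2 ratio of group means is the saturated-model MLE and is
    # exactly invariant under per-sample rescaling; the pseudocount only
    # rescues genes where one fraction is all-zero (all-zero genes get 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(
            (m1 > 0) & (m2 > 0),
            np.log2(np.where(m2 > 0, m1, 1.0) / np.where(m2 > 0, m2, 1.0)),
            np.log2((m1 + c) / (m2 + c)),
        )
    base_mean = np.concatenate([y1, y2], axis=1).mean(axis=1)

    df_resid = n1 + n2 - 2
    if df_resid >= 1:
        s1 = y1.var(axis=1, ddof=1) if n1 > 1 else np.zeros_like(m1)
        s2 = y2.var(axis=1, ddof=1) if n2 > 1 else np.zeros_like(m2)
        w = (n1 - 1) * (m1 + c) ** 2 + (n2 - 1) * (m2 + c) ** 2
        # total squared CV (= dispersion + Poisson part) and its Poisson floor
        q_hat = ((n1 - 1) * s1 + (n2 - 1) * s2) / w
        pois = ((n1 - 1) * (m1 + c) + (n2 - 1) * (m2 + c)) / w
        informative = base_mean > 0
        d0, q0 = _fit_cv2_prior(q_hat[informative], df_resid) if informative.any() else (np.inf, 0.0)
        # recenter the constant prior at each gene's own Poisson floor
        prior = q0 - np.median(pois[informative]) + pois if informative.any() else pois
        if np.isinf(d0):
            q_mod = prior
            df_t = np.inf
        else:
            q_mod = (d0 * prior + df_resid * q_hat) / (d0 + df_resid)
            df_t = d0 + df_resid
        dispersion = np.clip(q_mod - pois, MIN_DISPERSION, MAX_DISPERSION)
    else:
        # single sample per fraction: no replication, fall back to the
        # Poisson floor (documented limitation)
        pois = 0.5 * (1.0 / (m1 + c) + 1.0 / (m2 + c))
        dispersion = np.full_like(m1, MIN_DISPERSION)
        df_t = np.inf

    v1 = (m1 + c) + dispersion * (m1 + c) ** 2
    v2 = (m2 + c) + dispersion * (m2 + c) ** 2
    se = np.sqrt(v1 / (n1 * (m1 + c) ** 2) + v2 / (n2 * (m2 + c) ** 2)) / np.log(2.0)
    wald = bias / se
    if np.isinf(df_t):
        p = 2.0 * stats.norm.sf(np.abs(wald))
    else:
        p = 2.0 * stats.t.sf(np.abs(wald), df_t)

    dead = (m1 + m2) == 0  # all-zero rows: test undefined
    wald = np.where(dead, np.nan, wald)
    p = np.where(dead, np.nan, p)

    return pd.DataFrame(
        {"base_mean": base_mean, "bias": bias, "se": se, "wald_stat": wald, "p_value": p},
        index=numerator.index,
    )


def compute_bias(
    counts: CountMatrix,
    numerator_fraction: str,
    denominator_fraction: str,
    min_count: int = 10,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 bias table for a fraction contrast.

    Genes are kept only if at least one sample (of the two fractions)
    reaches ``min_count`` raw counts. Bias is the log2 ratio of mean
    normalized counts between the fractions (pseudocount-rescued when one
    fraction is all-zero), tested by :func:`nb_wald_test` and BH-adjusted.
    Returns a DataFrame
    with the fixed column order gene_id, base_mean, bias, se, wald_stat,
    p_value, fdr.
    """
    pair = counts.subset_fractions((numerator_fraction, denominator_fraction))
    num_samples = pair.samples_of(numerator_fraction)
    den_samples = pair.samples_of(denominator_fraction)
    if not num_samples or not den_samples:
        raise InputError(
            f"need samples in both fractions {numerator_fraction!r} and {denominator_fraction!r}"
        )
    keep = pair.counts.max(axis=1) >= min_count
    if not keep.any():
        raise InputError(f"no gene reaches {min_count} counts in any sample")
    filtered = pair.counts.loc[keep]

    size_factors = estimate_size_factors(filtered)
    result = nb_wald_test(
        filtered[num_samples],
        filtered[den_samples],
        size_factors[num_samples],
        size_factors[den_samples],
        pseudocount=pseudocount,
    )
    result["fdr"] = benjamini_hochberg(result["p_value"].to_numpy())
    result = result.reset_index().rename(columns={"index": "gene_id"})
    result = result.rename(columns={result.columns[0]: "gene_id"})
    return result[BIAS_COLUMNS]


@dataclass(frozen=True)
class IsoformBiasComparison:
    """Spliced vs unspliced bias distributions for a dual transcriptome."""

    spliced: pd.Series
    unspliced: pd.Series
    median_spliced: float
    median_unspliced: float
    p_value: float
    paired_delta: pd.Series  # spliced - unspliced bias per parent transcript


def compare_isoform_bias(
    bias: pd.DataFrame, isoform_of: pd.DataFrame | None = None
) -> IsoformBiasComparison:
    """Compare bias between spliced and unspliced isoform classes.

    ``bias`` is a bias table whose gene_ids end in ``::spliced`` /
    ``::unspliced`` (the dual-transcriptome convention), or ``isoform_of``
    supplies columns ``gene_id``, ``parent``, ``isoform_class`` explicitly.
    Returns per-class distributions, medians, the two-sided Wilcoxon
    rank-sum p between classes, and per-parent paired differences.
    """
    if isoform_of is None:
        ids = bias["gene_id"].astype(str)
        cls = ids.str.rsplit("::", n=1).str[-1]
        parent = ids.str.rsplit("::", n=1).str[0]
        iso = pd.DataFrame({"gene_id": ids, "parent": parent, "isoform_class": cls})
    else:
        iso = isoform_of
    merged = bias.merge(iso, on="gene_id")
    spliced = merged.loc[merged["isoform_class"] == "spliced"].set_index("parent")["bias"]
    unspliced = merged.loc[merged["isoform_class"] == "unspliced"].set_index("parent")["bias"]
    if len(spliced) < 2 or len(unspliced) < 2:
        raise InputError("both isoform classes need at least 2 members")
    res = rank_sum_test(spliced.to_numpy(), unspliced.to_numpy())
    shared = spliced.index.intersection(unspliced.index)
    return IsoformBiasComparison(
        spliced=spliced,
        unspliced=unspliced,
        median_spliced=float(spliced.median()),
        median_unspliced=float(unspliced.median()),
        p_value=res.p_value,
        paired_delta=(spliced.loc[shared] - unspliced.loc[shared]).rename("delta_bias"),
    )
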