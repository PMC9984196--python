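"""Per-cell summaries of smFISH spot positions.

Spots arrive as 3D coordinates with cell and target labels; z runs
apically from the basal surface at z=0. Monolayer analyses summarize each
cell's mean spot z, normalized by subtracting the experiment-wide median
z of a non-localized control transcript. Neuronal analyses count spots per
compartment and form per-cell neurite/soma ratios. The cell, not the
spot, is the unit of analysis for all comparisons (two-sided Wilcoxon
rank-sum).
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from ._exceptions import InputError
from .stats import RankSumResult, rank_sum_test

logger = logging.getLogger(__name__)

#: Default QC bounds: reporter expression is thresholded until cells carry
#: on the order of 100-1000 spots; endogenous targets default to no upper
#: bound.
DEFAULT_MIN_SPOTS = 100
DEFAULT_MAX_SPOTS = 1000

#: Default axial slice spacing (micrometres) when z arrives as slice indices.
DEFAULT_SLICE_SPACING = 0.2


def z_from_slices(spots: pd.DataFrame, slice_spacing: float = DEFAULT_SLICE_SPACING) -> pd.DataFrame:
    """Convert a ``z_slice`` column (stack index) into ``z_um``."""
    if "z_slice" not in spots.columns:
        raise InputError("no 'z_slice' column to convert")
    out = spots.copy()
    out["z_um"] = out["z_slice"].astype(float) * slice_spacing
    return out


def qc_filter_cells(
    spots: pd.DataFrame,
    min_spots: int = DEFAULT_MIN_SPOTS,
    max_spots: int | None = DEFAULT_MAX_SPOTS,
) -> pd.DataFrame:
    """Keep spots of (cell, target) groups with a plausible spot count.

    A group survives iff its spot count lies in [min_spots, max_spots]
    (inclusive; ``max_spots=None`` means unbounded). If an ``in_frame``
    column is present, spots of cells not fully in frame are dropped
    first.
    """
    if min_spots < 0 or (max_spots is not None and max_spots < min_spots):
        raise InputError("QC bounds must satisfy 0 <= min_spots <= max_spots")
    working = spots
    if "in_frame" in spots.columns:
        n_before = len(working)
        working = working[working["in_frame"].astype(bool)]
        logger.info("qc_filter_cells: dropped %d out-of-frame spots", n_before - len(working))
    counts = working.groupby(["cell_id", "target"])["spot_id"].transform("size")
    upper = math.inf if max_spots is None else max_spots
    kept = working[(counts >= min_spots) & (counts <= upper)]
    logger.info(
        "qc_filter_cells: kept %d/%d spots in bounds [%s, %s]",
        len(kept),
        len(spots),
        min_spots,
        max_spots,
    )
    return kept.reset_index(drop=True)


def summarize_z(spots: pd.DataFrame, control_target: str) -> pd.DataFrame:
    """Per-cell mean z, normalized to the control transcript's median.

    The reference is the median z over ALL spots of ``control_target`` in
    the experiment (control and targets are expressed in different cells,
    so a per-cell reference is not available); ``normalized_z`` is each
    cell's mean z minus that reference, in micrometres.

    Returns a DataFrame with columns cell_id, target, n_spots, mean_z,
    normalized_z (control cells included).
    """
    if control_target not in set(spots["target"]):
        raise InputError(f"control target {control_target!r} not present in spot table")
    reference = float(spots.loc[spots["target"] == control_target, "z_um"].median())
    summary = (
        spots.groupby(["cell_id", "target"], as_index=False)
        .agg(n_spots=("z_um", "size"), mean_z=("z_um", "mean"))
        .sort_values(["target", "cell_id"], ignore_index=True)
    )
    summary["normalized_z"] = summary["mean_z"] - reference
    return summary


def compare_position(
    summaries: pd.DataFrame, target_a: str, target_b: str
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum over per-cell normalized z positions."""
    a = summaries.loc[summaries["target"] == target_a, "normalized_z"].to_numpy()
    b = summaries.loc[summaries["target"] == target_b, "normalized_z"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise InputError("need at least 2 cells per group")
    return rank_sum_test(a, b)


def neurite_soma_ratio(
    spots: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RankSumResult]]:
    """Per-cell neurite/soma spot-count ratios plus pairwise comparisons.

    Requires a ``compartment`` column with values ``neurite``/``soma``.
    Cells without soma spots are excluded with a logged warning; cells
    without neurite spots keep ratio 0. Returns the per-cell table and a
    dict of two-sided rank-sum results for every pair of targets with at
    least 2 cells each.
    """
    if "compartment" not in spots.columns:
        raise InputError("spot table has no 'compartment' column")
    bad = set(spots["compartment"].dropna()) - {"neurite", "soma"}
    if bad:
        raise InputError(f"unknown compartment labels: {sorted(bad)}")
    tab = (
        spots.pivot_table(
            index=["cell_id", "target"],
            columns="compartment",
            values="spot_id",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=["neurite", "soma"], fill_value=0)
        .reset_index()
    )
    no_soma = tab["soma"] == 0
    if no_soma.any():
        logger.warning(
            "neurite_soma_ratio: excluding %d cells with zero soma spots: %s",
            int(no_soma.sum()),
            list(tab.loc[no_soma, "cell_id"]),
        )
        tab = tab[~no_soma]
    tab = tab.rename(columns={"neurite": "n_neurite", "soma": "n_soma"})
    tab["ratio"] = tab["n_neurite"] / tab["n_soma"]
    tab = tab.sort_values(["target", "cell_id"], ignore_index=True)[
        ["cell_id", "target", "n_neurite", "n_soma", "ratio"]
    ]

    comparisons: dict[tuple[str, str], RankSumResult] = {}
    targets = sorted(tab["target"].unique())
    for i, ta in enumerate(targets):
        for tb in targets[i + 1 :]:
            ra = tab.loc[tab["target"] == ta, "ratio"].to_numpy()
            rb = tab.loc[tab["target"] == tb, "ratio"].to_numpy()
            if ra.size >= 2 and rb.size >= 2:
                comparisons[(ta, tb)] = rank_sum_test(ra, rb)
    return tab, comparisons
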