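"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError

#: Fraction labels a sample may carry. Input/pulldown are the proximity
#: labeling pair, apical/basal the epithelial pair, neurite/soma the
#: neuronal fractionation pair.
FRACTIONS = frozenset({"input", "pulldown", "apical", "basal", "neurite", "soma"})

#: Fixed column order for bias tables written to disk.
BIAS_COLUMNS = ["gene_id", "base_mean", "bias", "se", "wald_stat", "p_value", "fdr"]

#: Required columns of a spot table. ``compartment`` is optional and only
#: present for neuronal geometry.
SPOT_COLUMNS = ["spot_id", "cell_id", "target", "x_um", "y_um", "z_um"]


@dataclass
class CountMatrix:
    """Gene x sample count matrix with per-sample fraction metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene ids),
        samples as columns.
    sample_meta
        DataFrame indexed by sample id with columns ``fraction``,
        ``replicate``, ``dataset``. Every column of ``counts`` must appear.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InputError("gene ids must be unique")
        if not self.counts.columns.equals(self.sample_meta.index):
            missing = set(self.counts.columns) ^ set(self.sample_meta.index)
            raise InputError(f"counts columns and sample sheet disagree: {sorted(missing)}")
        if "fraction" not in self.sample_meta.columns:
            raise InputError("sample sheet needs a 'fraction' column")
        bad = set(self.sample_meta["fraction"]) - FRACTIONS
        if bad:
            raise InputError(f"unknown fraction labels: {sorted(bad)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InputError("counts must be numeric")
        if (values < 0).any():
            raise InputError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise InputError("counts must be integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, fraction: str) -> list[str]:
        """Sample ids carrying the given fraction label, in sheet order."""
        if fraction not in FRACTIONS:
            raise InputError(f"unknown fraction label: {fraction!r}")
        mask = self.sample_meta["fraction"] == fraction
        return list(self.sample_meta.index[mask])

    def subset_fractions(self, fractions: tuple[str, ...]) -> "CountMatrix":
        """Restrict to samples whose fraction is in ``fractions``."""
        keep = [s for s in self.sample_ids if self.sample_meta.loc[s, "fraction"] in fractions]
        return CountMatrix(self.counts[keep], self.sample_meta.loc[keep])


@dataclass
class MotifHit:
    """A merged pyrimidine-rich element within one 5' UTR.

    ``start``/``end`` are 1-based inclusive positions in the UTR. An element
    beginning at position 1 is a 5' TOP motif; anything downstream is a PRTE.
    """

    sequence_id: str
    start: int
    end: int
    n_qualifying_windows: int
    motif_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(f"bad hit coordinates [{self.start}, {self.end}]")
        self.motif_class = "TOP" if self.start == 1 else "PRTE"

    @property
    def length(self) -> int:
        return self.end - self.start + 1
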