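"""Pyrimidine-rich regulatory element (PRRE) detection in 5' UTRs.

A PRRE is a stretch holding at least 9 pyrimidines (C/T/U) within a 10-nt
window. Overlapping or book-ended qualifying windows merge into one
element; its position is the merged start (1-based within the UTR). An
element at position 1 sits at the 5' cap and is a 5' TOP motif; anything
downstream is a pyrimidine-rich translational element (PRTE). The mutant
rule swaps every pyrimidine for a purine (C->A, T/U->G), which destroys
every qualifying window while preserving length and purine content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from ._exceptions import InputError
from .containers import MotifHit
from .crosscomp import class_bias_summary

#: IUPAC nucleotide codes accepted by the scanner; ambiguity codes other
#: than C/T/U count as non-pyrimidine (conservative detection).
IUPAC = set("ACGTUNRYSWKMBDHV")
PYRIMIDINES = set("CTU")

_MUTATE = str.maketrans("CTUctu", "AGGagg")

DEFAULT_WINDOW = 10
DEFAULT_MIN_PYRIMIDINES = 9


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - IUPAC
    if bad:
        raise InputError(f"non-nucleotide character {sorted(bad)[0]!r} in sequence")
    return seq


def scan_prre(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    min_pyrimidines: int = DEFAULT_MIN_PYRIMIDINES,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Find merged pyrimidine-rich elements in one sequence.

    A window of ``window`` nt qualifies iff it contains at least
    ``min_pyrimidines`` pyrimidines. Overlapping or book-ended qualifying
    windows merge into a single element spanning from the first window's
    start to the last window's end. Hits are sorted and non-overlapping;
    an element starting at position 1 is classified TOP, else PRTE.
    """
    if window < 1:
        raise InputError("window must be at least 1")
    if min_pyrimidines > window or min_pyrimidines < 1:
        raise InputError("min_pyrimidines must lie in [1, window]")
    seq = _validate(sequence)
    n = len(seq)
    if n < window:
        return []
    is_pyr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_pyr = (
        (is_pyr == ord("C")) | (is_pyr == ord("T")) | (is_pyr == ord("U"))
    ).astype(np.int32)
    window_sums = np.convolve(is_pyr, np.ones(window, dtype=np.int32), mode="valid")
    starts = np.flatnonzero(window_sums >= min_pyrimidines)  # 0-based window starts
    if starts.size == 0:
        return []
    hits: list[MotifHit] = []
    run_start = 0
    for i in range(1, starts.size + 1):
        # book-ended windows (next start == previous end + 1) still merge
        if i == starts.size or starts[i] - starts[i - 1] > window:
            group = starts[run_start:i]
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=int(group[0]) + 1,
                    end=int(group[-1]) + window,
                    n_qualifying_windows=int(group.size),
                )
            )
            run_start = i
    return hits


def mutate_prre(sequence: str) -> str:
    """Swap every pyrimidine for a purine: C->A, T/U->G; purines and
    ambiguity codes unchanged; length and case preserved."""
    _validate(sequence)
    return sequence.translate(_MUTATE)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Tabulate MotifHits (one row per merged element)."""
    return pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "start": h.start,
                "end": h.end,
                "n_qualifying_windows": h.n_qualifying_windows,
                "motif_class": h.motif_class,
            }
            for h in hits
        ],
        columns=["sequence_id", "start", "end", "n_qualifying_windows", "motif_class"],
    )


def _gene_of(record_id: str) -> tuple[str, str]:
    """Split a record id into (gene, transcript). Ids of the form
    ``GENE|TX`` map transcripts to genes; otherwise the id is both."""
    if "|" in record_id:
        gene, tx = record_id.split("|", 1)
        return gene, tx
    return record_id, record_id


def annotate_genes(
    utrs: list[SeqRecord],
    window: int = DEFAULT_WINDOW,
    min_pyrimidines: int = DEFAULT_MIN_PYRIMIDINES,
) -> pd.DataFrame:
    """Per-gene PRRE annotation over each gene's longest 5' UTR.

    Multiple UTRs per gene are allowed (record ids ``GENE|TRANSCRIPT``);
    the longest is scanned, ties broken lexicographically by transcript
    id. The reported position is the most 5' merged element's start.

    Returns a DataFrame with columns gene_id, utr_id, utr_length,
    has_prre, position, motif_class.
    """
    if not utrs:
        raise InputError("empty UTR set")
    chosen: dict[str, tuple[str, str]] = {}
    for rec in utrs:
        gene, tx = _gene_of(rec.id)
        seq = str(rec.seq)
        if gene not in chosen:
            chosen[gene] = (tx, seq)
        else:
            tx0, seq0 = chosen[gene]
            if len(seq) > len(seq0) or (len(seq) == len(seq0) and tx < tx0):
                chosen[gene] = (tx, seq)
    rows = []
    for gene in sorted(chosen):
        tx, seq = chosen[gene]
        hits = scan_prre(seq, window=window, min_pyrimidines=min_pyrimidines, sequence_id=tx)
        if hits:
            first = hits[0]  # hits are sorted; most 5' element wins
            rows.append(
                {
                    "gene_id": gene,
                    "utr_id": tx,
                    "utr_length": len(seq),
                    "has_prre": True,
                    "position": first.start,
                    "motif_class": first.motif_class,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": gene,
                    "utr_id": tx,
                    "utr_length": len(seq),
                    "has_prre": False,
                    "position": np.nan,
                    "motif_class": "",
                }
            )
    return pd.DataFrame(rows)


def bias_by_motif_class(
    bias: pd.DataFrame,
    annotation: pd.DataFrame,
    classes: tuple[str, ...] = ("TOP", "PRTE"),
) -> pd.DataFrame:
    """Summarize bias distributions by motif class, with rank-sum tests.

    For each requested class (``TOP``, ``PRTE``, or ``PRRE`` meaning any
    element), genes in the class are compared against all other genes in
    the bias table by a two-sided Wilcoxon rank-sum test. Returns one row
    per class with medians and p-values.
    """
    known = {"TOP", "PRTE", "PRRE"}
    bad = set(classes) - known
    if bad:
        raise InputError(f"unknown motif classes: {sorted(bad)}")
    values = bias.set_index("gene_id")["bias"].dropna()
    rows = []
    for cls in classes:
        if cls == "PRRE":
            members = set(annotation.loc[annotation["has_prre"], "gene_id"])
        else:
            members = set(annotation.loc[annotation["motif_class"] == cls, "gene_id"])
        summary = class_bias_summary(values, members)
        rows.append(
            {
                "motif_class": cls,
                "n_class": summary.n_class,
                "class_median": summary.class_median,
                "background_median": summary.background_median,
                "p_value": summary.p_value,
            }
        )
    return pd.DataFrame(rows)
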