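"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as a gene x sample TSV plus a sample sheet TSV (sample,
fraction, replicate, dataset). Sequences are FASTA via Biopython. Spot
tables are CSV with the schema ``spot_id,cell_id,target,x_um,y_um,z_um``
(optionally ``compartment`` and ``in_frame``). LR matrices are gene x
dataset TSVs with ``NA`` for missing. Every writer round-trips through its
reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._exceptions import InputError
from .containers import BIAS_COLUMNS, SPOT_COLUMNS, CountMatrix


def read_counts(counts_path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Load a count matrix TSV and its sample sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.empty:
        raise InputError(f"{counts_path}: empty count matrix")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    required = {"sample", "fraction", "replicate", "dataset"}
    missing = required - set(sheet.columns)
    if missing:
        raise InputError(f"{sample_sheet_path}: missing columns {sorted(missing)}")
    sheet = sheet.set_index("sample")
    try:
        sheet = sheet.loc[counts.columns]
    except KeyError as exc:
        raise InputError(f"{sample_sheet_path}: sample sheet does not cover all samples: {exc}")
    sheet.index.name = "sample"
    return CountMatrix(counts, sheet)


def write_counts(cm: CountMatrix, counts_path: str | Path, sample_sheet_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.sample_meta.rename_axis("sample").to_csv(sample_sheet_path, sep="\t")


def read_spots(path: str | Path) -> pd.DataFrame:
    """Load a spot CSV, validating the schema."""
    spots = pd.read_csv(path)
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise InputError(f"{path}: spot table missing columns {sorted(missing)}")
    if (spots["z_um"] < 0).any():
        raise InputError(f"{path}: negative z coordinates")
    return spots


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: empty FASTA")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def make_record(seq: str, seq_id: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=seq_id, description=description)


def read_lr_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x dataset LR matrix TSV; 'NA' marks missing entries."""
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if mat.empty:
        raise InputError(f"{path}: empty LR matrix")
    return mat


def write_lr_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="NA")


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Two-column ortholog/gene-mapping table (no header required)."""
    gm = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if gm.shape[1] < 2:
        raise InputError(f"{path}: gene map needs two columns")
    gm = gm.iloc[:, :2]
    gm.columns = ["source", "target"]
    return gm


def read_bias_table(path: str | Path) -> pd.DataFrame:
    bias = pd.read_csv(path, sep="\t")
    missing = set(BIAS_COLUMNS) - set(bias.columns)
    if missing:
        raise InputError(f"{path}: bias table missing columns {sorted(missing)}")
    return bias[BIAS_COLUMNS]


def write_bias_table(bias: pd.DataFrame, path: str | Path) -> None:
    bias[BIAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = {"target", "fraction", "replicate", "ct"} - set(ct.columns)
    if missing:
        raise InputError(f"{path}: Ct table missing columns {sorted(missing)}")
    return ct


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, index=False)


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: pd.DataFrame, path: str | Path) -> None:
    """Write motif hits as BED (0-based half-open, UTR-local coordinates)."""
    bed = pd.DataFrame(
        {
            "chrom": hits["sequence_id"],
            "start": hits["start"] - 1,
            "end": hits["end"],
            "name": hits["motif_class"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
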