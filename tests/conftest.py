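import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Printed wildtype/mutant PRRE pairs used for cloning the reporter
# constructs; the scanner and mutant rule must reproduce them exactly.
RPL7_WT = "CCTCTTTTTCCGGCTGGAACC"
RPL7_MUT = "AAGAGGGGGAAGGAGGGAAAA"
RPS28_WT = "ACTCCTCTCCGCCAGACCGCCGCCGCGCCGCCATC"
RPS28_MUT = "AAGAAGAGAAGAAAGAAAGAAGAAGAGAAGAAAGA"


@pytest.fixture
def toy_genome(tmp_path):
    """Toy contig with a 2-exon gene on each strand and a 1-exon gene."""
    contig = "ACGTACGTTTAATTTT"
    fasta = tmp_path / "genome.fa"
    fasta.write_text(f">chr1\n{contig}\n")
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttoy\tmRNA\t1\t12\t.\t+\t.\tID=tx_plus\n"
        "chr1\ttoy\texon\t1\t4\t.\t+\t.\tParent=tx_plus\n"
        "chr1\ttoy\texon\t9\t12\t.\t+\t.\tParent=tx_plus\n"
        "chr1\ttoy\tmRNA\t1\t12\t.\t-\t.\tID=tx_minus\n"
        "chr1\ttoy\texon\t1\t4\t.\t-\t.\tParent=tx_minus\n"
        "chr1\ttoy\texon\t9\t12\t.\t-\t.\tParent=tx_minus\n"
        "chr1\ttoy\tmRNA\t5\t8\t.\t+\t.\tID=tx_single\n"
        "chr1\ttoy\texon\t5\t8\t.\t+\t.\tParent=tx_single\n"
    )
    return fasta, gff, contig


@pytest.fixture
def small_counts():
    """4-sample pulldown/input matrix small enough to recompute by hand."""
    from rnaloc import CountMatrix

    counts = pd.DataFrame(
        {
            "pulldown_rep1": [400, 100, 50, 0, 12],
            "pulldown_rep2": [420, 90, 55, 0, 9],
            "input_rep1": [100, 100, 50, 0, 11],
            "input_rep2": [110, 95, 45, 0, 10],
        },
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "fraction": ["pulldown", "pulldown", "input", "input"],
            "replicate": [1, 2, 1, 2],
            "dataset": "toy",
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return CountMatrix(counts, meta)


def brute_force_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mean_w = nx * (len(pooled) + 1) / 2
    stats_all = [sum(comb) for comb in combinations(ranks, nx)]
    dev = abs(w_obs - mean_w)
    extreme = sum(abs(w - mean_w) >= dev - 1e-9 for w in stats_all)
    return extreme / len(stats_all)


def brute_force_scan(seq: str, window: int = 10, min_pyr: int = 9):
    """Naive enumerate-all-windows-then-merge PRRE oracle.

    Returns (start, end, n_windows) tuples with 1-based inclusive
    coordinates; independent of the production scanner's vectorized path.
    """
    seq = seq.upper()
    qualifying = []
    for i in range(len(seq) - window + 1):
        win = seq[i : i + window]
        if sum(base in "CTU" for base in win) >= min_pyr:
            qualifying.append(i)
    merged = []
    for start in qualifying:
        if merged and start - merged[-1][-1] <= window:
            merged[-1].append(start)
        else:
            merged.append([start])
    return [(g[0] + 1, g[-1] + window, len(g)) for g in merged]
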