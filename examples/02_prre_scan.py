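"""Scanning 5' UTRs for pyrimidine-rich regulatory elements (PRREs).

A PRRE is any stretch with at least 9 pyrimidines in a 10-nt window;
an element starting at UTR position 1 is a 5' TOP motif, anything
downstream a PRTE. The mutant rule swaps every pyrimidine for a purine,
which abolishes detection while preserving length.
"""

import rnaloc as rl

RPL7_UTR_PRRE = "CCTCTTTTTCCGGCTGGAACC"
RPS28_UTR_PRRE = "ACTCCTCTCCGCCAGACCGCCGCCGCGCCGCCATC"

for name, seq in [("RPL7", RPL7_UTR_PRRE), ("RPS28", RPS28_UTR_PRRE)]:
    hits = rl.scan_prre(seq)
    mutant = rl.mutate_prre(seq)
    print(f"{name} wildtype: {seq}")
    for h in hits:
        print(f"  element at {h.start}-{h.end} ({h.motif_class}, "
              f"{h.n_qualifying_windows} qualifying windows)")
    print(f"{name} mutant:   {mutant}")
    print(f"  elements in mutant: {len(rl.scan_prre(mutant))}")
# Both wildtype elements begin at position 1, i.e. directly at the 5' cap
# (TOP class); the purine-swapped mutants contain no detectable element,
# which is what makes them localization-null controls.
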