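"""Brute-force reference implementations, independent of the package.

These enumerate every position directly on plain strings (reverse
complement via Biopython, so nothing from magecs is reused) and exist only
to check the real scanner against an implementation too simple to be
wrong.
"""

from Bio.Seq import Seq

PROTO = 20


def rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


def brute_pam_sites(seq: str) -> set[tuple[int, str]]:
    """All (pam_start, strand) with NGG and a full 20-nt protospacer (linear)."""
    n = len(seq)
    out = set()
    for i in range(n - 2):
        if seq[i + 1] == "G" and seq[i + 2] == "G" and i >= PROTO:
            out.add((i, "+"))
    rcs = rc(seq)
    for j in range(n - 2):
        if rcs[j + 1] == "G" and rcs[j + 2] == "G" and j >= PROTO:
            out.add((n - j - 3, "-"))
    return out


def brute_protospacer(seq: str, pam_start: int, strand: str) -> str:
    if strand == "+":
        return seq[pam_start - PROTO : pam_start]
    return rc(seq[pam_start + 3 : pam_start + 3 + PROTO])


def brute_seed_pam_count(seq: str, seed: str) -> int:
    """Occurrences of seed + N + GG on both strands of a linear sequence."""
    def count(s: str) -> int:
        total = 0
        for i in range(len(s) - len(seed) - 2):
            if s[i : i + len(seed)] == seed and s[i + len(seed) + 1 : i + len(seed) + 3] == "GG":
                total += 1
        return total

    return count(seq) + count(rc(seq))
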