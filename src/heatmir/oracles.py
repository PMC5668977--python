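"""Independent brute-force reference implementations.

These deliberately avoid the optimised code paths they are used to check:
the exact mapper is cross-checked against a naive full-text scan, the
folding engine against exhaustive enumeration of all nested structures,
and the chi-square routine against the textbook 2x2 closed form.
"""

from __future__ import annotations

from ._util import revcomp
from .fold import MIN_LOOP, PAIR_SCORES, structure_score


def naive_scan(tag: str, chroms: dict[str, str]) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``tag`` on both strands, by sliding every
    window of every chromosome.  Returns (chrom, start0, strand) sorted."""
    hits = []
    rc = revcomp(tag)
    m = len(tag)
    for chrom in sorted(chroms):
        seq = chroms[chrom].upper()
        for i in range(0, len(seq) - m + 1):
            window = seq[i : i + m]
            if window == tag:
                hits.append((chrom, i, "+"))
            if window == rc:
                hits.append((chrom, i, "-"))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def enumerate_structures(sequence: str):
    """Yield every nested secondary structure (as a list of pairs) of the
    sequence, restricted to complementary pairs (WC or G:U) and a minimum
    hairpin loop of MIN_LOOP.  Exponential; intended for length <= ~18."""
    seq = sequence.upper().replace("T", "U")
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        return seq[i] + seq[j] in PAIR_SCORES

    def gen(i: int, j: int):
        # unique decomposition: position i is either unpaired or paired to k
        if i > j:
            yield []
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not pairable(i, k):
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    yield from gen(0, n - 1)


def best_structure_score(sequence: str) -> float:
    """Maximal built-in-model score over all nested structures, by
    exhaustive enumeration."""
    return max(
        structure_score(sequence, pairs) for pairs in enumerate_structures(sequence)
    )


def chi2_closed_form(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Pearson chi-square of the 2x2 table via N(ad-bc)^2 / product of margins."""
    a, b = count_a, total_a - count_a
    c, d = count_b, total_b - count_b
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom
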