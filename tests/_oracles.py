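"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (hard-coded
tables, exhaustive enumeration) so that agreement with the package is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

# The standard genetic code, written out by hand (not imported from any
# library the implementation uses).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def brute_force_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG..stop span by scanning every ATG/stop pair directly."""
    best = None
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if GENETIC_CODE.get(seq[j:j + 3]) == "*":
                cand = (-(j + 3 - i), i)
                if best is None or cand < best:
                    best = cand
                break
            j += 3
    if best is None:
        return None
    return best[1], -best[0]


def ng86_sites_oracle(codon: str) -> tuple[Fraction, Fraction]:
    """Synonymous/nonsynonymous site fractions by explicit enumeration of
    the nine single-base neighbours, stop neighbours excluded."""
    aa = GENETIC_CODE[codon]
    s = Fraction(0)
    for pos in range(3):
        syn, considered = 0, 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mutant] == "*":
                continue
            considered += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if considered:
            s += Fraction(syn, considered)
    return s, 3 - s


def set_partitions(items: list):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def min_legal_partition_count(labels, carriers) -> int | None:
    """Minimum group count over all partitions obeying the diploid rule
    (no group holds more than two alleles of one individual)."""
    best = None
    for part in set_partitions(list(labels)):
        legal = True
        for group in part:
            counts: dict[str, int] = {}
            for allele in group:
                for ind in carriers[allele]:
                    counts[ind] = counts.get(ind, 0) + 1
            if any(v > 2 for v in counts.values()):
                legal = False
                break
        if legal and (best is None or len(part) < best):
            best = len(part)
    return best


def best_alignment_by_enumeration(a: str, b: str, match=1.0, mismatch=-1.0,
                                  open_gap=-5.0, extend_gap=-1.0
                                  ) -> tuple[float, int]:
    """Optimal global alignment score and its gap-column count, by
    enumerating every alignment of two short strings."""

    def rec(i, j, prev):
        # prev: None | 'm' | 'ga' (gap in a) | 'gb' (gap in b)
        if i == len(a) and j == len(b):
            return 0.0, 0
        options = []
        if i < len(a) and j < len(b):
            sc = match if a[i] == b[j] else mismatch
            tail, gaps = rec(i + 1, j + 1, "m")
            options.append((sc + tail, gaps))
        if j < len(b):  # gap in a
            sc = extend_gap if prev == "ga" else open_gap
            tail, gaps = rec(i, j + 1, "ga")
            options.append((sc + tail, gaps + 1))
        if i < len(a):  # gap in b
            sc = extend_gap if prev == "gb" else open_gap
            tail, gaps = rec(i + 1, j, "gb")
            options.append((sc + tail, gaps + 1))
        return max(options)

    score, _ = rec(0, 0, None)
    # among optimal-score alignments, find the minimum gap count
    best_gaps = None

    def rec2(i, j, prev, acc_score, acc_gaps):
        nonlocal best_gaps
        if i == len(a) and j == len(b):
            if abs(acc_score - score) < 1e-9:
                if best_gaps is None or acc_gaps < best_gaps:
                    best_gaps = acc_gaps
            return
        if i < len(a) and j < len(b):
            sc = match if a[i] == b[j] else mismatch
            rec2(i + 1, j + 1, "m", acc_score + sc, acc_gaps)
        if j < len(b):
            sc = extend_gap if prev == "ga" else open_gap
            rec2(i, j + 1, "ga", acc_score + sc, acc_gaps + 1)
        if i < len(a):
            sc = extend_gap if prev == "gb" else open_gap
            rec2(i + 1, j, "gb", acc_score + sc, acc_gaps + 1)

    rec2(0, 0, None, 0.0, 0)
    return score, best_gaps
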