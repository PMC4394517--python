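"""Tandem-repeat (microsatellite) detection and per-locus intron tables.

Repeat copy-number variation in introns is what makes intron length
locus-diagnostic in multi-copy MHC genes (GT dinucleotide runs, decamer and
16-mer motifs).  Detection uses a period-u self-match scan: a position
belongs to a period-u repeat when it equals the base u positions earlier;
maximal high-purity runs become calls, and overlapping calls of different
periods are resolved by span x purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, extract_introns
from .loci import LocusGrouping
from .seqio import SequenceRecord


@dataclass(frozen=True)
class TandemRepeat:
    """One tandem-repeat call on a source sequence.

    ``unit`` is reported in its canonical (lexicographically smallest)
    rotation so that calls are invariant to the phase at which the run was
    entered; ``copy_number`` may be fractional.
    """

    unit: str
    copy_number: float
    start: int
    end: int
    purity: float

    @property
    def span(self) -> int:
        return self.end - self.start


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a power of a shorter unit."""
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def _runs_for_period(seq: str, u: int, min_purity: float
                     ) -> list[tuple[int, int, int]]:
    """Maximal match-runs for period u, merged across small impurities.

    Returns (span_start, span_end, n_matches) with the span including the
    leading unit.
    """
    n = len(seq)
    match = [seq[i] == seq[i - u] for i in range(u, n)]
    # raw runs of consecutive matches, as [start, end) over match indices
    raw = []
    i = 0
    while i < len(match):
        if match[i]:
            j = i
            while j < len(match) and match[j]:
                j += 1
            raw.append((i, j))
            i = j
        else:
            i += 1
    # merge neighbouring runs when the merged purity stays acceptable
    merged: list[tuple[int, int, int]] = []  # (start, end, matches)
    for s, e in raw:
        if merged:
            ps, pe, pm = merged[-1]
            cand_m = pm + (e - s)
            if cand_m / (e - ps) >= min_purity:
                merged[-1] = (ps, e, cand_m)
                continue
        merged.append((s, e, e - s))
    # convert match-index runs to sequence spans (include the leading unit)
    return [(s, e + u, m) for s, e, m in merged]


def find_tandem_repeats(seq: SequenceRecord | str, max_unit: int = 20,
                        min_copies: float = 2.0, min_purity: float = 0.85,
                        min_homopolymer_copies: int = 6
                        ) -> list[TandemRepeat]:
    """Detect tandem repeats with unit length up to ``max_unit``.

    Homopolymers (unit length 1) are only reported at
    ``min_homopolymer_copies`` or more copies to suppress noise.
    Overlapping calls are resolved keeping the larger purity x span, ties
    to the shorter unit then the leftmost start.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    n = len(s)
    candidates: list[TandemRepeat] = []
    for u in range(1, min(max_unit, n // 2) + 1):
        for span_s, span_e, matches in _runs_for_period(s, u, min_purity):
            span = span_e - span_s
            copies = span / u
            comparable = span - u
            purity = matches / comparable if comparable else 0.0
            floor = min_homopolymer_copies if u == 1 else min_copies
            if copies < floor or purity < min_purity:
                continue
            # read the unit from the middle of the run: merged spans may
            # start a few impure bases into the flank
            mid = span_s + u * ((span // u) // 2)
            mid = min(mid, span_e - u)
            raw_unit = s[mid:mid + u]
            if not _is_primitive(raw_unit):
                continue  # covered by the scan at the shorter period
            unit = canonical_rotation(raw_unit)
            candidates.append(TandemRepeat(unit=unit, copy_number=copies,
                                           start=span_s, end=span_e,
                                           purity=purity))
    candidates.sort(key=lambda r: (-(r.purity * r.span), len(r.unit), r.start))
    accepted: list[TandemRepeat] = []
    for cand in candidates:
        if any(cand.start < a.end and a.start < cand.end for a in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda r: r.start)
    return accepted


def repeats_to_frame(seq_id: str, repeats: Iterable[TandemRepeat]
                     ) -> pd.DataFrame:
    rows = [(seq_id, r.start, r.end, r.unit, round(r.copy_number, 2),
             round(r.purity, 3)) for r in repeats]
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "unit",
                                       "copies", "purity"])


def intron_length_table(models: Sequence[GeneModel],
                        seqs: Mapping[str, SequenceRecord],
                        grouping: LocusGrouping | None = None,
                        max_unit: int = 20, min_purity: float = 0.85
                        ) -> pd.DataFrame:
    """One row per allele x intron: length and the dominant repeat within.

    All models must share the gene architecture (equal exon counts); the
    dominant repeat is the call with the largest span, or ``none``.
    """
    if not models:
        return pd.DataFrame(columns=["allele", "group", "intron", "length",
                                     "unit", "copies"])
    exon_counts = {m.genomic_id: m.n_exons for m in models}
    distinct = set(exon_counts.values())
    if len(distinct) > 1:
        majority = max(distinct, key=lambda k: sum(
            1 for v in exon_counts.values() if v == k))
        offenders = sorted(g for g, v in exon_counts.items() if v != majority)
        raise ValueError(f"mixed exon counts; offending models: {offenders}")
    rows = []
    for model in models:
        gdna = seqs[model.genomic_id]
        group = ""
        if grouping is not None:
            gi = grouping.group_of(model.genomic_id)
            group = f"group{gi + 1}" if gi is not None else "unassigned"
        for idx, residues, length in extract_introns(model, gdna):
            calls = find_tandem_repeats(residues, max_unit=max_unit,
                                        min_purity=min_purity)
            if calls:
                dominant = max(calls, key=lambda r: r.span)
                unit, copies = dominant.unit, round(dominant.copy_number, 2)
            else:
                unit, copies = "none", 0.0
            rows.append((model.genomic_id, group, idx, length, unit, copies))
    return pd.DataFrame(rows, columns=["allele", "group", "intron", "length",
                                       "unit", "copies"])
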