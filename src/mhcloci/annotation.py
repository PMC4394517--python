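"""Exon/intron annotation of genomic alleles by spliced alignment of a cDNA.

The aligner chains exact exon matches between a cDNA and its genomic
sequence, allowing gaps (introns) only where the genomic sequence offers a
canonical GT .. AG intron.  Among all GT–AG-consistent chains covering the
cDNA it prefers the one with the fewest introns and then the leftmost
intron starts, which is well defined and deterministic.  An exhaustive
memoised search is used; at single-gene scale (a few kb) this is fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .seqio import OrfAnnotation, SequenceRecord, find_orf

MIN_INTRON = 4  # "GT" + "AG" with nothing between is the degenerate minimum


class SplicedAlignmentError(ValueError):
    """No GT–AG-consistent exon chain covers the cDNA.

    Carries the longest partial chain found, as genomic (start, end)
    intervals, to aid debugging of near-miss inputs.
    """

    def __init__(self, message: str, partial_chain: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.partial_chain = tuple(partial_chain)


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one genomic allele.

    ``exons`` are 0-based half-open genomic intervals whose concatenated
    substrings reproduce the cDNA exactly; every gap between consecutive
    exons is a GT .. AG intron.
    """

    genomic_id: str
    cdna_id: str
    exons: tuple[tuple[int, int], ...]
    cdna_len: int
    orf: OrfAnnotation | None = None
    utr5_len: int = 0
    utr3_len: int = 0
    mismatches: int = 0

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def exon_cdna_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals mapped onto cDNA coordinates."""
        out, pos = [], 0
        for s, e in self.exons:
            out.append((pos, pos + (e - s)))
            pos += e - s
        return tuple(out)

    def validate(self, cdna: SequenceRecord, gdna: SequenceRecord) -> None:
        """Check all structural invariants against the actual sequences."""
        if not self.exons:
            raise ValueError("model has no exons")
        prev_end = -1
        for s, e in self.exons:
            if not 0 <= s < e <= len(gdna.residues):
                raise ValueError(f"exon ({s},{e}) outside genomic bounds")
            if s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        spliced = "".join(gdna.residues[s:e] for s, e in self.exons)
        if self.mismatches == 0 and spliced != cdna.residues:
            raise ValueError("exon concatenation does not reproduce the cDNA")
        for s, e in self.introns:
            if gdna.residues[s:s + 2] != "GT" or gdna.residues[e - 2:e] != "AG":
                raise ValueError(f"intron ({s},{e}) is not GT..AG")


@dataclass(frozen=True)
class RegionPartition:
    """Named cDNA regions, each a tuple of disjoint 0-based half-open intervals."""

    regions: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> tuple[tuple[int, int], ...]:
        return self.regions[name]

    def names(self) -> list[str]:
        return list(self.regions)

    def length(self, name: str) -> int:
        return sum(e - s for s, e in self.regions[name])


def _common_extension(cdna: str, gdna: str, ci: int, gi: int) -> int:
    m, n = len(cdna), len(gdna)
    t = 0
    while ci + t < m and gi + t < n and cdna[ci + t] == gdna[gi + t]:
        t += 1
    return t


def spliced_align(cdna: SequenceRecord, gdna: SequenceRecord,
                  min_exon: int = 20) -> GeneModel:
    """Annotate ``gdna`` by chaining exact matches of ``cdna`` across introns.

    The first exon may start anywhere in the genomic sequence (primer
    flanks are tolerated); every intron must start with GT and end with AG
    and every exon of a multi-exon chain must span at least ``min_exon``
    bases.  Raises :class:`SplicedAlignmentError` when no chain covers the
    cDNA.
    """
    c, g = cdna.residues, gdna.residues
    m, n = len(c), len(g)
    if m < 1:
        raise SplicedAlignmentError("empty cDNA")

    ag_ends = [j for j in range(2, n) if g[j - 2:j] == "AG"]  # intron end (excl)

    best_partial: list[tuple[tuple[int, int], ...]] = [()]

    memo: dict[tuple[int, int], tuple | None] = {}

    def search(ci: int, gi: int) -> tuple | None:
        """Best chain for cdna[ci:] starting an exon at gdna[gi].

        Returns (n_introns, intron_starts, exons) or None.
        """
        key = (ci, gi)
        if key in memo:
            return memo[key]
        memo[key] = None  # guard against re-entry
        L = _common_extension(c, g, ci, gi)
        remaining = m - ci
        best: tuple | None = None
        if L >= remaining and (remaining >= min_exon or ci == 0):
            # final exon ends the chain
            best = (0, (), ((gi, gi + remaining),))
        hi = min(L, remaining - 1)  # splice point leaves cDNA residue(s)
        for t in range(min_exon, hi + 1):
            ist = gi + t  # intron start
            if g[ist:ist + 2] != "GT":
                continue
            nc = ci + t
            want = c[nc]
            # candidate intron ends: resume position j with g[j-2:j]=="AG"
            for j in ag_ends:
                if j < ist + MIN_INTRON:
                    continue
                if j + (m - nc) > n:
                    break
                if g[j] != want:
                    continue
                # cheap look-ahead before recursing
                k = min(min_exon, m - nc)
                if g[j:j + k] != c[nc:nc + k]:
                    continue
                sub = search(nc, j)
                if sub is None:
                    continue
                cand = (
                    sub[0] + 1,
                    (ist,) + sub[1],
                    ((gi, ist),) + sub[2],
                )
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None and L > 0:
            prev = best_partial[0]
            prev_len = (prev[0][1] - prev[0][0]) if prev else 0
            if L > prev_len:
                best_partial[0] = ((gi, gi + L),)
        memo[key] = best
        return best

    # candidate genomic starts: occurrences of the cDNA prefix
    probe = c[: min(min_exon, m)]
    starts = []
    pos = g.find(probe)
    while pos != -1:
        starts.append(pos)
        pos = g.find(probe, pos + 1)
    overall: tuple | None = None
    for gi0 in starts:
        res = search(0, gi0)
        if res is None:
            continue
        cand = (res[0], res[1], res[2])
        if overall is None or cand[:2] < overall[:2]:
            overall = cand
    if overall is None:
        raise SplicedAlignmentError(
            f"no GT-AG-consistent exon chain covers {cdna.seq_id} "
            f"on {gdna.seq_id}",
            partial_chain=best_partial[0],
        )
    exons = overall[2]
    orf = find_orf(cdna)
    utr5 = orf.start if orf else 0
    utr3 = (m - orf.end) if orf else 0
    model = GeneModel(
        genomic_id=gdna.seq_id, cdna_id=cdna.seq_id, exons=exons,
        cdna_len=m, orf=orf, utr5_len=utr5, utr3_len=utr3, mismatches=0,
    )
    model.validate(cdna, gdna)
    return model


def extract_introns(model: GeneModel, gdna: SequenceRecord
                    ) -> list[tuple[int, str, int]]:
    """Return ``(intron_index, residues, length)`` for each intron (1-based index)."""
    out = []
    for idx, (s, e) in enumerate(model.introns, start=1):
        res = gdna.residues[s:e]
        out.append((idx, res, e - s))
    return out


def partition_regions(model: GeneModel, scheme: str = "pbr_vs_rest"
                      ) -> RegionPartition:
    """Partition the cDNA into named regions.

    ``per_exon`` maps every exon to its cDNA interval.  ``pbr_vs_rest``
    returns the peptide binding region (PBR) — the cDNA span of exons 2 and
    3, clipped to the ORF and expanded to whole codons — against the rest
    of the ORF.
    """
    intervals = model.exon_cdna_intervals
    if scheme == "per_exon":
        return RegionPartition(
            {f"exon{i}": (iv,) for i, iv in enumerate(intervals, start=1)}
        )
    if scheme != "pbr_vs_rest":
        raise ValueError(f"unknown scheme {scheme!r}")
    if model.n_exons < 3:
        raise ValueError("pbr_vs_rest needs a model with at least 3 exons")
    if model.orf is None:
        raise ValueError("pbr_vs_rest needs an ORF annotation")
    orf = model.orf
    pbr_lo = max(intervals[1][0], orf.start)
    pbr_hi = min(intervals[2][1], orf.end)
    # snap to codon boundaries of the ORF frame: start down, end up
    pbr_lo = orf.start + ((pbr_lo - orf.start) // 3) * 3
    pbr_hi = orf.start + -((-(pbr_hi - orf.start)) // 3) * 3
    pbr_hi = min(pbr_hi, orf.end)
    if pbr_hi <= pbr_lo:
        raise ValueError("PBR interval is empty after clipping to the ORF")
    non_pbr = []
    if orf.start < pbr_lo:
        non_pbr.append((orf.start, pbr_lo))
    if pbr_hi < orf.end:
        non_pbr.append((pbr_hi, orf.end))
    return RegionPartition({
        "PBR": ((pbr_lo, pbr_hi),),
        "nonPBR": tuple(non_pbr),
    })


def gene_model_to_gff3(model: GeneModel) -> str:
    """Render the model as GFF3 (1-based inclusive) gene/exon/CDS features."""
    lines = ["##gff-version 3"]
    gid = model.genomic_id
    gene_s = model.exons[0][0] + 1
    gene_e = model.exons[-1][1]
    lines.append(
        f"{gid}\tmhcloci\tgene\t{gene_s}\t{gene_e}\t.\t+\t.\tID=gene:{gid}"
    )
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(
            f"{gid}\tmhcloci\texon\t{s + 1}\t{e}\t.\t+\t.\t"
            f"ID=exon:{gid}.{i};Parent=gene:{gid}"
        )
    if model.orf is not None:
        # map ORF cDNA interval back to genomic CDS chunks
        pos = 0
        for (s, e) in model.exons:
            ex_len = e - s
            lo = max(model.orf.start, pos)
            hi = min(model.orf.end, pos + ex_len)
            if lo < hi:
                gs = s + (lo - pos)
                ge = s + (hi - pos)
                phase = (3 - (lo - model.orf.start) % 3) % 3
                lines.append(
                    f"{gid}\tmhcloci\tCDS\t{gs + 1}\t{ge}\t.\t+\t{phase}\t"
                    f"ID=cds:{gid};Parent=gene:{gid}"
                )
            pos += ex_len
    return "\n".join(lines) + "\n"


def gene_model_to_json(model: GeneModel) -> str:
    """Serialise the model as a JSON document mirroring its fields."""
    doc = {
        "genomic_id": model.genomic_id,
        "cdna_id": model.cdna_id,
        "exons": [list(iv) for iv in model.exons],
        "introns": [list(iv) for iv in model.introns],
        "cdna_len": model.cdna_len,
        "utr5_len": model.utr5_len,
        "utr3_len": model.utr3_len,
        "mismatches": model.mismatches,
        "orf": None if model.orf is None else {
            "start": model.orf.start,
            "end": model.orf.end,
            "protein": model.orf.protein,
        },
    }
    return json.dumps(doc, indent=2)
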