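"""Multiple alignment, polymorphic sites, substitution nomenclature and the
Nei–Gojobori (NG86) codon-based test of positive selection.

The NG86 scheme partitions each codon position into synonymous and
nonsynonymous site fractions by enumerating the nine single-base
neighbours; pairwise differences in multi-hit codons are averaged over all
minimal substitution pathways that avoid stop codons.  Proportions are
Jukes–Cantor corrected and the dN-vs-dS contrast is tested with a Z score
whose standard error comes from a seeded bootstrap over codon columns, the
behaviour of the widely used codon-based Z test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import make_aligner, pairwise_align
from .annotation import RegionPartition
from .seqio import CODON_TO_AA, OrfAnnotation, SequenceRecord, translate

BASES = "ACGT"


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """A multiple alignment: equal-length gapped rows in input order."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self) -> str:
        out = []
        for sid, row in zip(self.ids, self.rows):
            out.append(f">{sid}")
            for i in range(0, len(row), 70):
                out.append(row[i:i + 70])
        return "\n".join(out) + "\n"


def _merge_into_profile(rows: list[str], consensus: str, new_seq: str,
                        aligner) -> tuple[list[str], str]:
    a_cons, a_new = pairwise_align(consensus, new_seq, aligner)
    out_rows = []
    for row in rows:
        merged, k = [], 0
        for ch in a_cons:
            if ch == "-":
                merged.append("-")
            else:
                merged.append(row[k])
                k += 1
        out_rows.append("".join(merged))
    out_rows.append(a_new)
    return out_rows, _consensus(out_rows)


def _consensus(rows: list[str]) -> str:
    cols = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            best = max(sorted(counts), key=lambda ch: counts[ch])
        else:
            best = "N"
        cols.append(best)
    return "".join(cols)


def build_msa(seqs: Sequence[SequenceRecord], match: float = 1.0,
              mismatch: float = -1.0, open_gap: float = -5.0,
              extend_gap: float = -1.0) -> Msa:
    """Align two or more sequences.

    Equal-length inputs (the common case for full-length allele sets) are
    stacked without gaps; otherwise sequences are added progressively, each
    aligned against the running consensus in input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = tuple(s.seq_id for s in seqs)
    if len({len(s.residues) for s in seqs}) == 1:
        return Msa(ids, tuple(s.residues for s in seqs))
    aligner = make_aligner(match, mismatch, open_gap, extend_gap)
    rows = [seqs[0].residues]
    consensus = seqs[0].residues
    for s in seqs[1:]:
        rows, consensus = _merge_into_profile(rows, consensus, s.residues,
                                              aligner)
    return Msa(ids, tuple(rows))


def polymorphic_sites(msa: Msa, regions: RegionPartition | None = None
                      ) -> tuple[int, dict[str, int]]:
    """Count polymorphic columns, overall and per named region.

    A column is polymorphic when it holds at least two distinct unambiguous
    bases among its non-gap residues.
    """
    poly = []
    for j in range(msa.ncol):
        bases = {row[j] for row in msa.rows} & set(BASES)
        poly.append(len(bases) >= 2)
    total = sum(poly)
    per_region: dict[str, int] = {}
    if regions is not None:
        for name in regions.names():
            count = 0
            for s, e in regions[name]:
                if s < 0 or e > msa.ncol:
                    raise ValueError(
                        f"region {name} interval ({s},{e}) outside alignment")
                count += sum(poly[s:e])
            per_region[name] = count
    return total, per_region


# ---------------------------------------------------------------------------
# substitution classification / nomenclature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionRecord:
    """One substitution between two alleles, in biological nomenclature.

    ``cdna_position`` is 1-based from the ORF start (the paper-style
    "242A>G" coordinate); the protein position counts from the initiator
    Met.
    """

    cdna_position: int
    ref_base: str
    alt_base: str
    kind: str  # "synonymous" | "nonsynonymous"
    cdna_notation: str
    protein_notation: str | None = None


def classify_substitutions(ref: SequenceRecord, alt: SequenceRecord,
                           orf: OrfAnnotation) -> list[SubstitutionRecord]:
    """Classify every substitution inside the ORF between two equal-length
    cDNAs as synonymous or nonsynonymous."""
    if len(ref.residues) != len(alt.residues):
        raise ValueError("ref and alt must have equal length")
    r, a = ref.residues, alt.residues
    out = []
    for pos in range(orf.start, orf.end):
        if r[pos] == a[pos]:
            continue
        orf_pos0 = pos - orf.start
        codon_idx = orf_pos0 // 3
        cs = orf.start + codon_idx * 3
        ref_codon = r[cs:cs + 3]
        alt_codon = a[cs:cs + 3]
        ref_aa = translate(ref_codon)
        alt_aa = translate(alt_codon)
        kind = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
        notation = f"{orf_pos0 + 1}{r[pos]}>{a[pos]}"
        prot = None
        if kind == "nonsynonymous":
            prot = f"{ref_aa}{codon_idx + 1}{alt_aa}"
        out.append(SubstitutionRecord(
            cdna_position=orf_pos0 + 1, ref_base=r[pos], alt_base=a[pos],
            kind=kind, cdna_notation=notation, protein_notation=prot,
        ))
    return out


# ---------------------------------------------------------------------------
# NG86 machinery
# ---------------------------------------------------------------------------

def _is_stop(codon: str) -> bool:
    return CODON_TO_AA.get(codon) == "*"


def _is_sense(codon: str) -> bool:
    aa = CODON_TO_AA.get(codon)
    return aa is not None and aa != "*"


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, stops: str = "exclude") -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one sense codon.

    For each position the synonymous fraction is (synonymous single-base
    changes) / (considered single-base changes); with ``stops="exclude"``
    changes creating stop codons are left out of the denominator, with
    ``stops="nonsyn"`` they count as nonsynonymous.  s is the sum of the
    three fractions and n = 3 - s.
    """
    codon = codon.upper()
    if not _is_sense(codon):
        raise ValueError(f"{codon!r} is not a sense codon")
    if stops not in ("exclude", "nonsyn"):
        raise ValueError("stops must be 'exclude' or 'nonsyn'")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if _is_stop(mutant):
                if stops == "nonsyn":
                    considered += 1
                continue
            considered += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if considered:
            s += syn / considered
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    sense codons, over all minimal substitution pathways avoiding stops."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _is_stop(nxt):
                blocked = True
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        # all pathways pass through stops (rare); fall back to counting
        # steps without the stop exclusion
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                a1, a2 = CODON_TO_AA[cur], CODON_TO_AA[nxt]
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _codon_arrays(a: str, b: str, stops: str = "exclude"
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon (Sd, Nd, S, N) contributions of one aligned sequence pair.

    Codons containing gaps, N, or stop codons in either sequence are
    dropped pairwise (all four contributions zero).
    """
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal length, multiple of 3")
    n_codons = len(a) // 3
    sd = np.zeros(n_codons)
    nd = np.zeros(n_codons)
    s_sites = np.zeros(n_codons)
    n_sites = np.zeros(n_codons)
    for k in range(n_codons):
        ca, cb = a[3 * k:3 * k + 3], b[3 * k:3 * k + 3]
        if not (_is_sense(ca) and _is_sense(cb)):
            continue
        sa, na = ng86_site_counts(ca, stops)
        sb, nb = ng86_site_counts(cb, stops)
        s_sites[k] = (sa + sb) / 2.0
        n_sites[k] = (na + nb) / 2.0
        sd[k], nd[k] = _pair_codon_diffs(ca, cb)
    return sd, nd, s_sites, n_sites


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); nan for p>=3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class Ng86Pairwise:
    """NG86 counts and distances for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons_used: int


def ng86_pairwise(a: str, b: str, stops: str = "exclude") -> Ng86Pairwise:
    """NG86 proportions and Jukes–Cantor distances for two coding sequences.

    Codons with gaps, N, or stops in either sequence are dropped pairwise.
    When a proportion reaches 3/4 the corrected distance is reported as nan
    (undefined) with the raw proportion retained.
    """
    sd, nd, s_sites, n_sites = _codon_arrays(a, b, stops)
    S, N = float(s_sites.sum()), float(n_sites.sum())
    Sd, Nd = float(sd.sum()), float(nd.sum())
    used = int(np.count_nonzero(s_sites + n_sites))
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return Ng86Pairwise(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                        dS=jukes_cantor(pS), dN=jukes_cantor(pN),
                        n_codons_used=used)


# ---------------------------------------------------------------------------
# codon-based Z test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTestResult:
    """Region-restricted dN/dS contrast with a bootstrap Z test."""

    region: str
    dN: float
    dS: float
    ratio: float
    Z: float
    p: float
    n_bootstrap: int
    seed: int
    applicable: bool = True


def _region_sequence(row: str, intervals: Iterable[tuple[int, int]]) -> str:
    return "".join(row[s:e] for s, e in intervals)


def _jc_array(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return out


def selection_test(msa: Msa, region: str | None = None,
                   partition: RegionPartition | None = None,
                   n_bootstrap: int = 1000, seed: int = 0,
                   stops: str = "exclude") -> SelectionTestResult:
    """Codon-based test of positive selection (H1: dN > dS) on one region.

    dN and dS are the means of NG86 pairwise distances over all sequence
    pairs restricted to the region; the standard error of dN - dS comes
    from ``n_bootstrap`` resamples of codon columns (seeded), and the
    one-tailed p-value from the normal tail.
    """
    if len(msa.rows) < 2:
        raise ValueError("selection test needs at least 2 sequences")
    if region is None or partition is None:
        intervals: tuple[tuple[int, int], ...] = ((0, msa.ncol),)
        region_name = region or "all"
    else:
        intervals = partition[region]
        region_name = region
    seqs = [_region_sequence(row, intervals) for row in msa.rows]
    length = len(seqs[0])
    if length % 3:
        raise ValueError("region is not codon-aligned (length % 3 != 0)")
    n_codons = length // 3
    if n_codons < 2:
        raise ValueError("region shorter than 2 codons")

    pairs = list(itertools.combinations(range(len(seqs)), 2))
    SD = np.zeros((len(pairs), n_codons))
    ND = np.zeros((len(pairs), n_codons))
    SS = np.zeros((len(pairs), n_codons))
    NN = np.zeros((len(pairs), n_codons))
    for idx, (i, j) in enumerate(pairs):
        sd, nd, ss, nn = _codon_arrays(seqs[i], seqs[j], stops)
        SD[idx], ND[idx], SS[idx], NN[idx] = sd, nd, ss, nn

    S_pair = SS.sum(axis=1)
    N_pair = NN.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = np.where(S_pair > 0, SD.sum(axis=1) / S_pair, 0.0)
        pN = np.where(N_pair > 0, ND.sum(axis=1) / N_pair, 0.0)
    dS_pair = _jc_array(pS)
    dN_pair = _jc_array(pN)
    dS = float(np.nanmean(dS_pair))
    dN = float(np.nanmean(dN_pair))

    if dN == 0.0 and dS == 0.0:
        return SelectionTestResult(region=region_name, dN=0.0, dS=0.0,
                                   ratio=math.nan, Z=math.nan, p=1.0,
                                   n_bootstrap=n_bootstrap, seed=seed,
                                   applicable=False)
    ratio = dN / dS if dS > 0 else math.inf

    rng = np.random.default_rng(seed)
    # resampling codon columns with replacement == multinomial weights
    W = rng.multinomial(n_codons, np.full(n_codons, 1.0 / n_codons),
                        size=n_bootstrap).T.astype(float)  # (C, B)
    SDb, NDb = SD @ W, ND @ W          # (P, B)
    Sb, Nb = SS @ W, NN @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        pSb = np.where(Sb > 0, SDb / Sb, 0.0)
        pNb = np.where(Nb > 0, NDb / Nb, 0.0)
    theta_b = np.nanmean(_jc_array(pNb) - _jc_array(pSb), axis=0)
    se = float(np.nanstd(theta_b, ddof=1))
    if se > 0:
        Z = (dN - dS) / se
        p = float(stats.norm.sf(Z))
    else:
        Z = math.inf if dN > dS else (-math.inf if dN < dS else 0.0)
        p = 0.0 if dN > dS else 1.0
    return SelectionTestResult(region=region_name, dN=dN, dS=dS, ratio=ratio,
                               Z=Z, p=p, n_bootstrap=n_bootstrap, seed=seed,
                               applicable=True)
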