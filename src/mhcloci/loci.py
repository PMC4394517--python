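"""Minimum locus-number inference under the diploid constraint.

A diploid individual carries at most two alleles of any one locus, so k
validated alleles in one individual imply at least ceil(k/2) loci, and no
candidate locus group may hold more than two alleles of the same
individual.  Alleles are grouped by constrained average-linkage
agglomeration (the constraint is a hard merge blocker); for small inputs
where greedy merging is provably not minimal in group count, an exact
search over legal partitions refines the result.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .align import make_aligner, pairwise_align
from .validation import Allele, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix over labelled alleles."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _as_named_seqs(items: Sequence) -> list[tuple[str, str]]:
    out = []
    for it in items:
        if isinstance(it, Allele):
            out.append((it.allele_name, it.residues))
        elif isinstance(it, tuple):
            out.append((it[0], it[1]))
        else:  # SequenceRecord-like
            out.append((it.seq_id, it.residues))
    return out


def _pair_p_distance(a: str, b: str, aligner) -> float:
    if len(a) == len(b):
        ga, gb = a, b
    else:
        ga, gb = pairwise_align(a, b, aligner)
    compared = mismatched = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatched += 1
    return mismatched / compared if compared else 0.0


def p_distance_matrix(items: Sequence, mode: str = "whole",
                      regions: Mapping[str, tuple[tuple[int, int], ...]] | None = None,
                      ) -> DistanceMatrix:
    """Pairwise p-distances (mismatches per compared column, gaps excluded).

    Equal-length pairs are compared positionally; unequal pairs are first
    globally aligned.  With ``mode="per_region"`` each sequence is first
    restricted to its entry in ``regions`` (label -> cDNA intervals), which
    supports mixing partial and whole-length alleles over their shared
    annotated span.
    """
    named = _as_named_seqs(items)
    if len(named) < 2:
        raise ValueError("need at least 2 sequences")
    if mode == "per_region":
        if regions is None:
            raise ValueError("per_region mode requires regions")
        named = [(name, "".join(seq[s:e] for s, e in regions[name]))
                 for name, seq in named]
    elif mode != "whole":
        raise ValueError(f"unknown mode {mode!r}")
    labels = tuple(name for name, _ in named)
    n = len(named)
    values = np.zeros((n, n))
    aligner = make_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_p_distance(named[i][1], named[j][1], aligner)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Negative branch lengths produced by NJ are clamped to zero (logged).
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    names = list(dm.labels)
    triangle = [[float(dm.values[i, j]) for j in range(i + 1)]
                for i in range(len(names))]
    bio_dm = _BioDM(names=names, matrix=triangle)
    tree = DistanceTreeConstructor().nj(bio_dm)
    clamped = 0
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
            clamped += 1
        if clade.name and clade.name.startswith("Inner"):
            clade.name = None
    if clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", clamped)
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def min_locus_bound(table: GenotypeTable) -> int:
    """Lower bound on locus number: ceil of the largest per-individual
    allele count over 2 (a diploid carries at most two alleles per locus)."""
    counts = table.counts()
    if not counts:
        raise ValueError("genotype table is empty")
    return math.ceil(max(counts.values()) / 2)


@dataclass(frozen=True)
class LocusGrouping:
    """Partition of alleles into candidate locus groups."""

    groups: tuple[tuple[str, ...], ...]
    unassigned: tuple[str, ...]
    min_locus_estimate: int
    per_group_individual_counts: tuple[dict[str, int], ...]
    focal_individual: str | None = None

    def group_of(self, allele: str) -> int | None:
        for i, g in enumerate(self.groups):
            if allele in g:
                return i
        return None


def _carrier_map(table: GenotypeTable, labels: Iterable[str]
                 ) -> dict[str, frozenset[str]]:
    carriers: dict[str, set[str]] = {lbl: set() for lbl in labels}
    for ind in table.individuals():
        for name in table.alleles_of(ind):
            if name in carriers:
                carriers[name].add(ind)
    return {k: frozenset(v) for k, v in carriers.items()}


def _ind_counts(cluster: Iterable[str], carriers: Mapping[str, frozenset[str]]
                ) -> dict[str, int]:
    counts: dict[str, int] = {}
    for allele in cluster:
        for ind in carriers[allele]:
            counts[ind] = counts.get(ind, 0) + 1
    return counts


def _merge_legal(c1: Sequence[str], c2: Sequence[str],
                 carriers: Mapping[str, frozenset[str]]) -> bool:
    counts = _ind_counts(list(c1) + list(c2), carriers)
    return all(v <= 2 for v in counts.values())


def _avg_linkage(c1: Sequence[str], c2: Sequence[str], dm: DistanceMatrix,
                 index: Mapping[str, int]) -> float:
    total = 0.0
    for a in c1:
        for b in c2:
            total += dm.values[index[a], index[b]]
    return total / (len(c1) * len(c2))


def _exact_min_partition(labels: list[str],
                         carriers: Mapping[str, frozenset[str]],
                         dm: DistanceMatrix, index: Mapping[str, int],
                         ) -> list[list[str]]:
    """Exhaustive search for a legal partition with the fewest groups,
    ties broken by the smallest total within-group distance."""
    n = len(labels)
    best: tuple[int, float, list[list[str]]] | None = None

    def within_cost(groups: list[list[str]]) -> float:
        cost = 0.0
        for g in groups:
            for a, b in itertools.combinations(g, 2):
                cost += dm.values[index[a], index[b]]
        return cost

    def rec(i: int, groups: list[list[str]],
            counts: list[dict[str, int]]) -> None:
        nonlocal best
        if best is not None and len(groups) > best[0]:
            return
        if i == n:
            cand = (len(groups), within_cost(groups),
                    [sorted(g) for g in groups])
            if best is None or cand[:2] < best[:2]:
                best = cand
            return
        lbl = labels[i]
        inds = carriers[lbl]
        for gi, g in enumerate(groups):
            if all(counts[gi].get(ind, 0) < 2 for ind in inds):
                g.append(lbl)
                for ind in inds:
                    counts[gi][ind] = counts[gi].get(ind, 0) + 1
                rec(i + 1, groups, counts)
                g.pop()
                for ind in inds:
                    counts[gi][ind] -= 1
        # open a new group (canonical: new groups appended in order)
        groups.append([lbl])
        counts.append({ind: 1 for ind in inds})
        rec(i + 1, groups, counts)
        groups.pop()
        counts.pop()

    rec(0, [], [])
    assert best is not None
    return best[2]


def constrained_grouping(dm: DistanceMatrix, table: GenotypeTable,
                         outlier_quantile: float = 0.90,
                         exact_limit: int = 10) -> LocusGrouping:
    """Group alleles into candidate loci under the diploid constraint.

    Alleles whose nearest neighbour lies beyond the ``outlier_quantile``
    of all pairwise distances are first set aside as ``unassigned`` —
    sequences too isolated for any grouping to be evidence of a shared
    locus.  The rest undergo average-linkage agglomeration (closest legal
    pair first, ties by smallest label pair) until no legal merge remains.
    When the greedy group count exceeds the per-individual lower bound and
    at most ``exact_limit`` alleles are in play, an exact search replaces
    the greedy partition with a provably minimal one.
    """
    labels = list(dm.labels)
    index = {lbl: i for i, lbl in enumerate(labels)}
    for lbl in labels:
        if not any(lbl in table.alleles_of(ind) for ind in table.individuals()):
            raise ValueError(f"allele {lbl} missing from the genotype table")
    carriers = _carrier_map(table, labels)

    # set aside alleles too isolated to place (no close relative at all):
    # their nearest neighbour lies beyond the chosen quantile of all
    # pairwise distances, so any group they joined would be arbitrary
    unassigned: list[str] = []
    if len(labels) >= 3:
        off_diag = dm.values[np.triu_indices(len(labels), k=1)]
        cutoff = float(np.quantile(off_diag, outlier_quantile))
        for lbl in labels:
            nn = min(dm.values[index[lbl], index[b]]
                     for b in labels if b != lbl)
            if nn > cutoff:
                unassigned.append(lbl)
    active = [lbl for lbl in labels if lbl not in unassigned]

    clusters: list[list[str]] = [[lbl] for lbl in active]
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if not _merge_legal(clusters[i], clusters[j], carriers):
                    continue
                d = _avg_linkage(clusters[i], clusters[j], dm, index)
                key = (d, min(clusters[i]), min(clusters[j]))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]

    assigned = [lbl for cl in clusters for lbl in cl]
    if assigned:
        counts_assigned = _ind_counts(assigned, carriers)
        lower = max(
            (math.ceil(v / 2) for v in counts_assigned.values()), default=1)
        if len(clusters) > lower and len(assigned) <= exact_limit:
            clusters = _exact_min_partition(sorted(assigned), carriers, dm,
                                            index)

    groups = tuple(tuple(sorted(cl)) for cl in
                   sorted(clusters, key=lambda cl: sorted(cl)))
    per_group_counts = tuple(_ind_counts(g, carriers) for g in groups)
    for counts in per_group_counts:
        assert all(v <= 2 for v in counts.values()), \
            "diploid constraint violated"

    table_counts = table.counts()
    focal = max(sorted(table_counts), key=lambda ind: table_counts[ind]) \
        if table_counts else None
    n_focal_groups = 0
    if focal is not None:
        focal_alleles = table.alleles_of(focal)
        n_focal_groups = sum(1 for g in groups if focal_alleles & set(g))
    estimate = max(n_focal_groups, min_locus_bound(table))
    return LocusGrouping(
        groups=groups, unassigned=tuple(sorted(unassigned)),
        min_locus_estimate=estimate,
        per_group_individual_counts=per_group_counts,
        focal_individual=focal,
    )


def export_nexus(named_seqs: Sequence[tuple[str, str]],
                 gamma_rates: bool = True) -> str:
    """NEXUS data block plus a MrBayes command stub (GTR, optionally +gamma)
    so the grouping's input alignment can be re-analysed externally."""
    seqs = _as_named_seqs(named_seqs)
    if not seqs:
        raise ValueError("no sequences to export")
    nchar = max(len(s) for _, s in seqs)
    lines = [
        "#NEXUS",
        "begin data;",
        f"  dimensions ntax={len(seqs)} nchar={nchar};",
        "  format datatype=dna missing=? gap=-;",
        "  matrix",
    ]
    for name, seq in seqs:
        padded = seq + "?" * (nchar - len(seq))
        lines.append(f"    {name.replace(' ', '_')}  {padded}")
    lines += [
        "  ;",
        "end;",
        "",
        "begin mrbayes;",
        "  lset nst=6" + (" rates=gamma;" if gamma_rates else ";"),
        "  mcmc ngen=1000000 samplefreq=100;",
        "  sump; sumt;",
        "end;",
    ]
    return "\n".join(lines) + "\n"
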