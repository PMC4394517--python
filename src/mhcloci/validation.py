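"""Clone-support allele validation and genotype bookkeeping.

PCR/cloning artifacts are filtered with the clone-support rule: a sequence
is accepted as a real allele only when at least ``min_support`` independent
clones of one individual carry it exactly.  Sequences seen in only one or
two clones, and any sequence containing N, are reported as discards.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .seqio import DNA_ALPHABET


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced bacterial clone, tagged with its individual of origin."""

    clone_id: str
    individual_id: str
    source: str  # "cdna" | "gdna"
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.source not in ("cdna", "gdna"):
            raise ValueError(f"{self.clone_id}: source must be cdna or gdna")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.clone_id}: non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class Allele:
    """A clone-validated allele sequence with its carriers."""

    allele_name: str
    residues: str
    support: int                       # total clone count over all carriers
    carriers: frozenset[str]
    per_individual_support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "N" in self.residues:
            raise ValueError(f"{self.allele_name}: validated allele contains N")
        if not self.carriers:
            raise ValueError(f"{self.allele_name}: no carriers")


class GenotypeTable:
    """Per-individual sets of allele names."""

    def __init__(self, genotypes: dict[str, set[str]]):
        self.genotypes = {ind: set(names) for ind, names in genotypes.items()
                          if names}

    def individuals(self) -> list[str]:
        return sorted(self.genotypes)

    def alleles_of(self, individual: str) -> set[str]:
        return set(self.genotypes.get(individual, set()))

    def allele_count(self, individual: str) -> int:
        return len(self.genotypes.get(individual, set()))

    def allele_names(self) -> list[str]:
        names = set()
        for s in self.genotypes.values():
            names |= s
        return sorted(names)

    def counts(self) -> dict[str, int]:
        return {ind: len(s) for ind, s in sorted(self.genotypes.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = [(ind, name) for ind in self.individuals()
                for name in sorted(self.genotypes[ind])]
        return pd.DataFrame(rows, columns=["individual_id", "allele_name"])


def collapse_clones(clones: Iterable[CloneRecord], min_support: int = 3,
                    name_prefix: str = "DAB",
                    ) -> tuple[list[Allele], GenotypeTable, pd.DataFrame]:
    """Collapse exact-identical clones into validated alleles.

    An allele is retained when some single individual supports it with at
    least ``min_support`` identical clones; its carriers are all individuals
    contributing at least one clone.  Returns (alleles, genotype table,
    discard report).  Allele names are assigned in descending total-support
    order, ties by sequence, numbered ``<prefix>*01`` on.
    """
    clones = list(clones)
    if not clones:
        raise ValueError("no clones supplied")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    by_seq: dict[str, Counter] = defaultdict(Counter)
    for cl in clones:
        by_seq[cl.residues][cl.individual_id] += 1

    kept: list[tuple[str, Counter]] = []
    discard_rows = []
    for seq, per_ind in by_seq.items():
        total = sum(per_ind.values())
        max_per_ind = max(per_ind.values())
        if "N" in seq:
            discard_rows.append((seq, total, max_per_ind, "contains_N"))
        elif max_per_ind >= min_support:
            kept.append((seq, per_ind))
        elif total >= min_support:
            # seen often enough overall but never >= min_support in one
            # individual; flagged distinctly, the rule discards it
            discard_rows.append(
                (seq, total, max_per_ind, "insufficient_per_individual_support")
            )
        else:
            discard_rows.append((seq, total, max_per_ind, "low_support"))

    kept.sort(key=lambda item: (-sum(item[1].values()), item[0]))
    alleles = []
    genotypes: dict[str, set[str]] = defaultdict(set)
    for i, (seq, per_ind) in enumerate(kept, start=1):
        name = f"{name_prefix}*{i:02d}"
        carriers = frozenset(per_ind)
        alleles.append(Allele(
            allele_name=name, residues=seq, support=sum(per_ind.values()),
            carriers=carriers, per_individual_support=dict(per_ind),
        ))
        for ind in carriers:
            genotypes[ind].add(name)

    discard = pd.DataFrame(
        discard_rows,
        columns=["residues", "total_clones", "max_clones_per_individual",
                 "reason"],
    ).sort_values(["total_clones", "residues"],
                  ascending=[False, True]).reset_index(drop=True)
    return alleles, GenotypeTable(genotypes), discard


def allele_sharing_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Binary individuals x alleles incidence matrix.

    Row sums equal per-individual allele counts; column sums count carriers.
    """
    individuals = table.individuals()
    names = table.allele_names()
    data = [[1 if name in table.alleles_of(ind) else 0 for name in names]
            for ind in individuals]
    return pd.DataFrame(data, index=individuals, columns=names)
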