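"""Ground-truthed simulator for multi-locus diploid MHC-like cloning data.

The generator emulates the data-generating process of a cloning study of a
multi-copy MHC class II B gene: a 6-exon/5-intron gene whose introns carry
tandem-repeat blocks with locus-specific copy numbers (so intron length is
locus-diagnostic), an allele pool per locus with elevated nonsynonymous
substitution in the peptide-binding-region exons (2-3), diploid
individuals drawing at most two alleles per carried locus, and clone
resampling at 8-20 clones per allele with independent per-base
substitution errors.  Every run emits a full truth record so each pipeline
stage can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import spliced_align
from .seqio import CODON_TO_AA, SequenceRecord, write_clone_metadata, write_fasta
from .validation import CloneRecord

BASES = "ACGT"
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")


@dataclass(frozen=True)
class IntronSpec:
    """Shape of one intron: random body plus an optional repeat block whose
    per-locus copy number is drawn from ``copy_range`` (inclusive)."""

    base_len: int
    repeat_unit: str | None = None
    copy_range: tuple[int, int] = (0, 0)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a flatfish MHC class II B cloning study: 4 loci in 8
    diploid individuals, a 794 nt cDNA (25 nt 5'UTR + 747 nt ORF + 22 nt
    3'UTR) over six exons, introns whose GT / GTCCAGTTGA / ACCTGTCTGTCTGCTC
    repeat copy numbers vary by locus, clone depth 8-20 per allele, and a
    2e-4 per-base clone error rate.
    """

    n_loci: int = 4
    n_individuals: int = 8
    alleles_per_locus: int = 4
    exon_lengths: tuple[int, ...] = (112, 270, 282, 60, 40, 30)
    utr5_len: int = 25
    utr3_len: int = 22
    intron_specs: tuple[IntronSpec, ...] = (
        IntronSpec(140),
        IntronSpec(80, "GT", (5, 30)),
        IntronSpec(90, "GTCCAGTTGA", (4, 60)),
        IntronSpec(50, "ACCTGTCTGTCTGCTC", (2, 8)),
        IntronSpec(90),
    )
    pbr_exons: tuple[int, int] = (2, 3)       # 1-based exon numbers
    locus_divergence: float = 0.03            # founder subs/base vs ancestor
    allele_mut_rate: float = 0.004            # within-locus subs/base
    pbr_multiplier: float = 3.0               # extra nonsyn rate in the PBR
    clone_depth: tuple[int, int] = (8, 20)
    clone_error_rate: float = 2e-4
    missing_locus_prob: float = 0.125
    make_cdna_clones: bool = True
    make_gdna_clones: bool = True
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_loci", "n_individuals", "alleles_per_locus",
                     "utr5_len", "utr3_len"):
            if getattr(self, name) <= 0:
                problems.append(name)
        for name in ("locus_divergence", "allele_mut_rate",
                     "clone_error_rate", "missing_locus_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(name)
        if self.pbr_multiplier < 1.0:
            problems.append("pbr_multiplier")
        if len(self.intron_specs) != len(self.exon_lengths) - 1:
            problems.append("intron_specs")
        if any(l <= 0 for l in self.exon_lengths):
            problems.append("exon_lengths")
        if not 1 <= self.clone_depth[0] <= self.clone_depth[1]:
            problems.append("clone_depth")
        orf_len = sum(self.exon_lengths) - self.utr5_len - self.utr3_len
        if orf_len < 9 or orf_len % 3:
            problems.append("exon_lengths/utr (ORF length)")
        if problems:
            raise ValueError(f"invalid SimConfig fields: {sorted(set(problems))}")

    @property
    def cdna_len(self) -> int:
        return sum(self.exon_lengths)

    @property
    def orf_interval(self) -> tuple[int, int]:
        return self.utr5_len, self.cdna_len - self.utr3_len


@dataclass
class TruthAllele:
    name: str
    locus: int
    cdna: str
    gdna: str
    exons: tuple[tuple[int, int], ...]
    repeat_copies: tuple[int, ...]


@dataclass
class SimTruth:
    """Everything needed to score pipeline output against the generator."""

    run_id: str
    config: dict
    alleles: list[TruthAllele]
    genotypes: dict[str, dict[str, list[str]]]   # individual -> locus -> names
    clone_map: dict[str, str]                    # clone_id -> allele name

    def allele_by_name(self, name: str) -> TruthAllele:
        for al in self.alleles:
            if al.name == name:
                return al
        raise KeyError(name)

    def gdna_sequences(self) -> set[str]:
        return {al.gdna for al in self.alleles}

    def cdna_sequences(self) -> set[str]:
        return {al.cdna for al in self.alleles}

    def carried_allele_names(self) -> set[str]:
        names: set[str] = set()
        for loci in self.genotypes.values():
            for allele_names in loci.values():
                names.update(allele_names)
        return names

    def to_json(self) -> str:
        doc = {
            "schema": "mhcloci-sim-truth/1",
            "run_id": self.run_id,
            "config": self.config,
            "alleles": [
                {
                    "name": al.name, "locus": al.locus, "cdna": al.cdna,
                    "gdna": al.gdna, "exons": [list(iv) for iv in al.exons],
                    "repeat_copies": list(al.repeat_copies),
                }
                for al in self.alleles
            ],
            "genotypes": self.genotypes,
            "clone_map": self.clone_map,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        doc = json.loads(text)
        alleles = [
            TruthAllele(
                name=a["name"], locus=a["locus"], cdna=a["cdna"],
                gdna=a["gdna"],
                exons=tuple(tuple(iv) for iv in a["exons"]),
                repeat_copies=tuple(a["repeat_copies"]),
            )
            for a in doc["alleles"]
        ]
        return cls(run_id=doc["run_id"], config=doc["config"],
                   alleles=alleles, genotypes=doc["genotypes"],
                   clone_map=doc["clone_map"])


@dataclass
class SimResult:
    clones: list[CloneRecord]
    truth: SimTruth
    config: SimConfig

    def clones_fasta_text(self) -> str:
        out = []
        for cl in self.clones:
            out.append(f">{cl.clone_id} individual={cl.individual_id} "
                       f"source={cl.source}")
            for i in range(0, len(cl.residues), 70):
                out.append(cl.residues[i:i + 70])
        return "\n".join(out) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "clones.fasta"
        meta = outdir / "clones.tsv"
        truth = outdir / "truth.json"
        records = [SequenceRecord(cl.clone_id, cl.residues,
                                  f"individual={cl.individual_id} "
                                  f"source={cl.source}")
                   for cl in self.clones]
        write_fasta(records, fasta)
        write_clone_metadata(
            [(cl.clone_id, cl.individual_id, cl.source)
             for cl in self.clones], meta)
        truth.write_text(self.truth.to_json())
        return {"fasta": fasta, "metadata": meta, "truth": truth}


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    n_internal = orf_len // 3 - 2
    codons = [SENSE_CODONS[i] for i in
              rng.integers(0, len(SENSE_CODONS), size=n_internal)]
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(codons) + stop


def _pbr_interval(config: SimConfig) -> tuple[int, int]:
    bounds = np.cumsum((0,) + config.exon_lengths)
    lo = int(bounds[config.pbr_exons[0] - 1])
    hi = int(bounds[config.pbr_exons[1]])
    orf_s, orf_e = config.orf_interval
    return max(lo, orf_s), min(hi, orf_e)


def _classify_change(cdna: str, pos: int, base: str, config: SimConfig
                     ) -> str:
    """Kind of substituting ``base`` at ``pos``: utr / synonymous /
    nonsynonymous / stop."""
    orf_s, orf_e = config.orf_interval
    if not orf_s <= pos < orf_e:
        return "utr"
    if pos < orf_s + 3:
        return "start"  # never mutate the initiator ATG away
    ci = (pos - orf_s) // 3
    cs = orf_s + ci * 3
    old = cdna[cs:cs + 3]
    off = pos - cs
    new = old[:off] + base + old[off + 1:]
    last_codon = ci == (orf_e - orf_s) // 3 - 1
    if CODON_TO_AA[new] == "*":
        return "syn_stop" if last_codon else "stop"
    if CODON_TO_AA[old] == "*":  # mutating the terminal stop away
        return "stop"
    return ("synonymous" if CODON_TO_AA[new] == CODON_TO_AA[old]
            else "nonsynonymous")


def _mutate_cdna(cdna: str, n_subs: int, rng: np.random.Generator,
                 config: SimConfig, region: tuple[int, int] | None = None,
                 kind: str | None = None, max_tries: int = 2000) -> str:
    """Apply ``n_subs`` substitutions, never creating or destroying a stop.

    ``kind`` restricts accepted changes ("synonymous"/"nonsynonymous");
    ``region`` restricts positions.  Changes in the UTRs count as accepted
    for unrestricted draws.
    """
    seq = list(cdna)
    lo, hi = region if region else (0, len(cdna))
    placed = tries = 0
    while placed < n_subs and tries < max_tries:
        tries += 1
        pos = int(rng.integers(lo, hi))
        base = BASES[rng.integers(0, 4)]
        if base == seq[pos]:
            continue
        change = _classify_change("".join(seq), pos, base, config)
        if change in ("stop", "start"):
            continue
        if kind is not None and change != kind:
            continue
        if kind is None and change == "syn_stop":
            continue  # keep the terminal stop codon untouched
        seq[pos] = base
        placed += 1
    return "".join(seq)


def _build_introns(config: SimConfig, rng: np.random.Generator
                   ) -> tuple[list[str], list[int]]:
    """Intron sequences for one locus plus the drawn repeat copy numbers."""
    introns, copies = [], []
    for spec in config.intron_specs:
        c = 0
        if spec.repeat_unit and spec.copy_range[1] > 0:
            c = int(rng.integers(spec.copy_range[0], spec.copy_range[1] + 1))
        body_len = max(spec.base_len - 4, 2)
        left = _random_bases(rng, body_len // 2)
        right = _random_bases(rng, body_len - body_len // 2)
        block = (spec.repeat_unit * c) if c else ""
        if block:
            # guard the block so flanks do not extend the repeat phase
            u = len(spec.repeat_unit)
            if left[-1:] == block[u - 1]:
                left = left[:-1] + ("A" if block[u - 1] != "A" else "C")
            if right[:1] == block[0]:
                right = ("A" if block[0] != "A" else "C") + right[1:]
        introns.append("GT" + left + block + right + "AG")
        copies.append(c)
    return introns, copies


def _assemble_gdna(cdna: str, exon_lengths: tuple[int, ...],
                   introns: list[str]
                   ) -> tuple[str, tuple[tuple[int, int], ...]]:
    parts, exons = [], []
    pos = cpos = 0
    for i, ex_len in enumerate(exon_lengths):
        exon = cdna[cpos:cpos + ex_len]
        exons.append((pos, pos + ex_len))
        parts.append(exon)
        pos += ex_len
        cpos += ex_len
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    return "".join(parts), tuple(exons)


def _annotates_exactly(name: str, cdna: str, gdna: str,
                       exons: tuple[tuple[int, int], ...]) -> bool:
    try:
        model = spliced_align(SequenceRecord(f"{name}_cdna", cdna),
                              SequenceRecord(f"{name}_gdna", gdna))
    except Exception:
        return False
    return model.exons == exons


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate one ground-truthed dataset; deterministic given the seed."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    orf_len = config.cdna_len - config.utr5_len - config.utr3_len
    ancestor = (_random_bases(rng, config.utr5_len)
                + _random_orf(rng, orf_len)
                + _random_bases(rng, config.utr3_len))
    pbr = _pbr_interval(config)
    pbr_len = pbr[1] - pbr[0]

    alleles: list[TruthAllele] = []
    for locus in range(1, config.n_loci + 1):
        # locus founder: diverged exons + locus-specific introns; the
        # founder must annotate unambiguously (regenerated otherwise)
        for _ in range(60):
            founder = _mutate_cdna(
                ancestor,
                int(rng.poisson(config.locus_divergence * config.cdna_len)),
                rng, config)
            # diversifying selection shapes the whole genealogy: the PBR
            # carries extra nonsynonymous divergence between loci as well
            n_extra = int(rng.poisson(config.locus_divergence
                                      * (config.pbr_multiplier - 1.0)
                                      * pbr_len))
            if n_extra:
                founder = _mutate_cdna(founder, n_extra, rng, config,
                                       region=pbr, kind="nonsynonymous")
            introns, copies = _build_introns(config, rng)
            gdna, exons = _assemble_gdna(founder, config.exon_lengths, introns)
            if _annotates_exactly(f"L{locus}F", founder, gdna, exons):
                break
        else:
            raise RuntimeError(f"locus {locus}: could not build an "
                               "unambiguously spliceable founder")
        pool_seqs: set[str] = set()
        for a in range(1, config.alleles_per_locus + 1):
            name = f"L{locus}A{a}"
            for _ in range(60):
                n_base = int(rng.poisson(
                    config.allele_mut_rate * config.cdna_len))
                n_extra = int(rng.poisson(
                    config.allele_mut_rate * (config.pbr_multiplier - 1.0)
                    * pbr_len))
                cdna = _mutate_cdna(founder, max(n_base, 1), rng, config)
                if n_extra:
                    cdna = _mutate_cdna(cdna, n_extra, rng, config,
                                        region=pbr, kind="nonsynonymous")
                if cdna in pool_seqs:
                    continue
                gdna, exons = _assemble_gdna(cdna, config.exon_lengths,
                                             introns)
                if _annotates_exactly(name, cdna, gdna, exons):
                    break
            else:
                raise RuntimeError(f"{name}: could not draw a distinct, "
                                   "spliceable allele")
            pool_seqs.add(cdna)
            alleles.append(TruthAllele(name=name, locus=locus, cdna=cdna,
                                       gdna=gdna, exons=exons,
                                       repeat_copies=tuple(copies)))

    by_locus: dict[int, list[TruthAllele]] = {}
    for al in alleles:
        by_locus.setdefault(al.locus, []).append(al)

    genotypes: dict[str, dict[str, list[str]]] = {}
    for i in range(1, config.n_individuals + 1):
        ind = f"ind{i}"
        genotypes[ind] = {}
        for locus in range(1, config.n_loci + 1):
            if rng.random() < config.missing_locus_prob:
                continue
            pool = by_locus[locus]
            picks = rng.integers(0, len(pool), size=2)
            names = sorted({pool[k].name for k in picks})
            genotypes[ind][f"locus{locus}"] = names

    by_name = {al.name: al for al in alleles}
    clones: list[CloneRecord] = []
    clone_map: dict[str, str] = {}
    counter = 0
    sources = ([s for s, on in (("cdna", config.make_cdna_clones),
                                ("gdna", config.make_gdna_clones)) if on])
    lo, hi = config.clone_depth
    for ind in sorted(genotypes, key=lambda s: int(s[3:])):
        carried = sorted({n for names in genotypes[ind].values()
                          for n in names})
        for name in carried:
            al = by_name[name]
            for source in sources:
                template = al.cdna if source == "cdna" else al.gdna
                depth = int(rng.integers(lo, hi + 1))
                for _ in range(depth):
                    counter += 1
                    seq = list(template)
                    k = rng.binomial(len(template), config.clone_error_rate)
                    if k:
                        positions = rng.choice(len(template), size=int(k),
                                               replace=False)
                        for pos in positions:
                            choices = [b for b in BASES if b != seq[pos]]
                            seq[pos] = choices[rng.integers(0, 3)]
                    clone_id = f"cl{counter:05d}"
                    clones.append(CloneRecord(clone_id, ind, source,
                                              "".join(seq)))
                    clone_map[clone_id] = name

    config_doc = dataclasses.asdict(config)
    config_doc["intron_specs"] = [dataclasses.asdict(s)
                                  for s in config.intron_specs]
    result = SimResult(clones=clones,
                       truth=SimTruth(run_id="", config=config_doc,
                                      alleles=alleles, genotypes=genotypes,
                                      clone_map=clone_map),
                       config=config)
    run_id = hashlib.sha1(
        result.clones_fasta_text().encode()).hexdigest()[:16]
    result.truth.run_id = run_id
    return result


def neutral_codon_alignment(n_seqs: int, n_codons: int, n_subs: int,
                            rng: np.random.Generator) -> list[str]:
    """Equal-length coding sequences diverged from one founder by ``n_subs``
    random substitutions each, accepted regardless of their synonymous or
    nonsynonymous effect (stop-creating changes rejected): a neutral null
    for calibrating the selection test."""
    founder = "".join(SENSE_CODONS[i] for i in
                      rng.integers(0, len(SENSE_CODONS), size=n_codons))
    seqs = []
    for _ in range(n_seqs):
        seq = list(founder)
        placed = tries = 0
        while placed < n_subs and tries < 100 * n_subs + 100:
            tries += 1
            pos = int(rng.integers(0, 3 * n_codons))
            base = BASES[rng.integers(0, 4)]
            if base == seq[pos]:
                continue
            ci = pos // 3
            codon = "".join(seq[3 * ci:3 * ci + 3])
            new = codon[:pos % 3] + base + codon[pos % 3 + 1:]
            if CODON_TO_AA[new] == "*":
                continue
            seq[pos] = base
            placed += 1
        seqs.append("".join(seq))
    return seqs


@dataclass(frozen=True)
class Scorecard:
    """Pipeline-vs-truth comparison for one simulation run."""

    allele_recovery: float        # fraction of truth alleles recovered
    locus_count_error: int        # estimate - true locus count (signed)
    exon_exactness: float         # fraction of annotated alleles exact


def truth_compare(summary: dict, truth: SimTruth) -> Scorecard:
    """Score a pipeline summary against the truth record of the same run."""
    if summary.get("run_id") != truth.run_id:
        raise ValueError(
            f"run id mismatch: summary {summary.get('run_id')!r} "
            f"vs truth {truth.run_id!r}")
    carried = truth.carried_allele_names()
    truth_gdna = {truth.allele_by_name(n).gdna for n in carried}
    recovered = set(summary.get("allele_sequences", {}).get("gdna", []))
    if truth_gdna:
        recovery = len(truth_gdna & recovered) / len(truth_gdna)
    else:
        recovery = 1.0
    n_loci = len({truth.allele_by_name(n).locus for n in carried})
    locus_error = int(summary.get("min_locus_estimate", 0)) - n_loci
    exact = total = 0
    models = summary.get("models", {})
    seq_by_name = {}
    for al in truth.alleles:
        seq_by_name[al.gdna] = al
    recovered_names = summary.get("allele_sequences", {}).get("gdna_names", {})
    for allele_name, exons in models.items():
        seq = recovered_names.get(allele_name)
        if seq is None or seq not in seq_by_name:
            continue
        total += 1
        if tuple(tuple(iv) for iv in exons) == seq_by_name[seq].exons:
            exact += 1
    exactness = exact / total if total else 0.0
    return Scorecard(allele_recovery=recovery, locus_count_error=locus_error,
                     exon_exactness=exactness)
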