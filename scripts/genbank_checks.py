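#!/usr/bin/env python
"""Checks against deposited flatfish MHC class II B GenBank records.

Requires network access (or pre-fetched FASTA files) and is therefore not
part of the offline test suite.  Usage:

    # with network access (set your e-mail for NCBI Entrez):
    python scripts/genbank_checks.py --email you@example.org --cache gb/

    # offline, with records already fetched into gb/<accession>.fasta:
    python scripts/genbank_checks.py --cache gb/

Checks performed on the real data:
  * 11 stone flounder cDNA alleles (JX645176-JX645186): 93 polymorphic
    sites; PBR dN/dS ~ 2.87 significant at 0.05, non-PBR ~ 1.16 not.
  * Japanese flounder KJ784490 (cDNA, 774 nt) vs KJ784489 (gDNA,
    2164 bp): 6 exons / 5 introns; ORF 744 nt encoding 247 aa.
  * KJ784490-KJ784493: 5 polymorphic sites.
  * Stone flounder whole-length alleles KF535998/KF536000/KF536002/
    KF536004: intron 3 lengths led by 770 bp; intron 4 up to 170 bp.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from mhcloci.annotation import extract_introns, partition_regions, spliced_align
from mhcloci.selection import build_msa, polymorphic_sites, selection_test
from mhcloci.seqio import SequenceRecord, find_orf, read_fasta, write_fasta

SF_CDNA = [f"JX6451{n}" for n in range(76, 87)]          # 11 cDNA alleles
JF_CDNA = [f"KJ7844{n}" for n in range(90, 94)]          # 4 cDNA alleles
JF_GDNA = "KJ784489"
SF_WHOLE = ["KF535998", "KF536000", "KF536002", "KF536004"]


def fetch(accession: str, cache: Path, email: str | None) -> SequenceRecord:
    path = cache / f"{accession}.fasta"
    if not path.exists():
        if email is None:
            sys.exit(f"{path} missing and no --email given for Entrez fetch")
        from Bio import Entrez, SeqIO
        Entrez.email = email
        with Entrez.efetch(db="nuccore", id=accession, rettype="fasta",
                           retmode="text") as handle:
            rec = SeqIO.read(handle, "fasta")
        cache.mkdir(parents=True, exist_ok=True)
        write_fasta([SequenceRecord(accession, str(rec.seq))], path)
    return read_fasta(path)[0]


def check(label: str, ok: bool, detail: str) -> bool:
    print(f"[{'ok' if ok else 'FAIL'}] {label}: {detail}")
    return ok


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cache", type=Path, default=Path("gb"))
    ap.add_argument("--email", default=None)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    results = []

    # Japanese flounder gene structure
    cdna = fetch(JF_CDNA[0], args.cache, args.email)
    gdna = fetch(JF_GDNA, args.cache, args.email)
    model = spliced_align(cdna, gdna)
    results.append(check("KJ784489 length", len(gdna.residues) == 2164,
                         f"{len(gdna.residues)} bp"))
    results.append(check("exon/intron count",
                         model.n_exons == 6 and len(model.introns) == 5,
                         f"{model.n_exons} exons"))
    orf = find_orf(cdna)
    results.append(check("ORF", orf.length == 744 and
                         len(orf.protein) == 247,
                         f"{orf.length} nt, {len(orf.protein)} aa"))

    # Japanese flounder cDNA polymorphism
    jf = [fetch(a, args.cache, args.email) for a in JF_CDNA]
    msa = build_msa(jf)
    total, _ = polymorphic_sites(msa)
    results.append(check("JF polymorphic sites", total == 5, f"{total}"))

    # Stone flounder cDNA selection contrast
    sf = [fetch(a, args.cache, args.email) for a in SF_CDNA]
    msa = build_msa(sf)
    part = partition_regions(model, "pbr_vs_rest")  # same architecture
    pbr = selection_test(msa, "PBR", part, seed=args.seed)
    rest = selection_test(msa, "nonPBR", part, seed=args.seed)
    total, _ = polymorphic_sites(msa)
    results.append(check("SF polymorphic sites", total == 93, f"{total}"))
    results.append(check("PBR dN/dS", abs(pbr.ratio - 2.872) <= 0.05
                         and pbr.p <= 0.05,
                         f"{pbr.ratio:.3f}, p={pbr.p:.3f}"))
    results.append(check("non-PBR dN/dS", abs(rest.ratio - 1.161) <= 0.05
                         and rest.p > 0.05,
                         f"{rest.ratio:.3f}, p={rest.p:.3f}"))

    # whole-length intron lengths
    lengths3, lengths4 = [], []
    for acc in SF_WHOLE:
        g = fetch(acc, args.cache, args.email)
        for c in sf:
            try:
                m = spliced_align(c, g)
                break
            except Exception:
                continue
        else:
            print(f"[warn] no cDNA splices onto {acc}")
            continue
        introns = extract_introns(m, g)
        lengths3.append(introns[2][2])
        lengths4.append(introns[3][2])
    results.append(check("intron 3 max", 770 in lengths3, f"{lengths3}"))
    results.append(check("intron 4 max", max(lengths4, default=0) == 170,
                         f"{lengths4}"))

    sys.exit(0 if all(results) else 1)


if __name__ == "__main__":
    main()
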