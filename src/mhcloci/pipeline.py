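"""Composite pipeline: validate -> annotate -> polymorphism/selection ->
loci -> repeats, with a single summary JSON as the headline artifact.

The summary is written only when every stage succeeds (atomicity of the
minimum-locus estimate); a stage failure raises :class:`PipelineError`
naming the stage, with earlier per-stage outputs preserved on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (GeneModel, SplicedAlignmentError, gene_model_to_json,
                         partition_regions, spliced_align)
from .loci import (constrained_grouping, export_nexus, min_locus_bound,
                   nj_tree, p_distance_matrix)
from .repeats import intron_length_table
from .selection import Msa, build_msa, polymorphic_sites, selection_test
from .seqio import (SequenceRecord, find_orf, read_clone_metadata, read_fasta,
                    write_fasta)
from .validation import CloneRecord, GenotypeTable, collapse_clones

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run; the seed feeds every
    stochastic step and is recorded in the summary."""

    min_support: int = 3
    n_bootstrap: int = 1000
    seed: int = 0
    outlier_quantile: float = 0.90
    min_exon: int = 20
    repeat_min_purity: float = 0.85
    stops: str = "exclude"
    name_prefix: str = "DAB"

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


def load_clones(fasta_path: str | Path, metadata_path: str | Path | None = None
                ) -> list[CloneRecord]:
    """Read clone sequences plus their individual/source metadata.

    Metadata comes from the sidecar TSV when given, otherwise from
    ``individual=<id> source=<cdna|gdna>`` keys in FASTA descriptions.
    """
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"no clone records in {fasta_path}")
    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        df = read_clone_metadata(metadata_path)
        meta = {row.clone_id: (row.individual_id, row.source)
                for row in df.itertuples()}
    clones = []
    for rec in records:
        if rec.seq_id in meta:
            ind, source = meta[rec.seq_id]
        else:
            ind = rec.individual
            source = "gdna"
            for token in rec.description.split():
                if token.startswith("source="):
                    source = token.split("=", 1)[1]
            if ind is None:
                raise ValueError(
                    f"clone {rec.seq_id}: no individual metadata (TSV or "
                    "individual=<id> tag)")
        clones.append(CloneRecord(rec.seq_id, ind, source, rec.residues))
    return clones


def _annotate_alleles(gdna_alleles, cdna_alleles, min_exon: int
                      ) -> dict[str, GeneModel]:
    """Annotate each genomic allele with the cDNA allele it splices to."""
    models: dict[str, GeneModel] = {}
    for g in gdna_alleles:
        gseq = SequenceRecord(g.allele_name, g.residues)
        for c in cdna_alleles:
            cseq = SequenceRecord(c.allele_name, c.residues)
            # cheap pre-filter: shared leading sequence
            k = min(20, len(c.residues))
            if g.residues[:k] != c.residues[:k]:
                continue
            try:
                models[g.allele_name] = spliced_align(cseq, gseq,
                                                      min_exon=min_exon)
                break
            except SplicedAlignmentError:
                continue
        else:
            # fall back: try every cDNA without the pre-filter
            for c in cdna_alleles:
                cseq = SequenceRecord(c.allele_name, c.residues)
                try:
                    models[g.allele_name] = spliced_align(cseq, gseq,
                                                          min_exon=min_exon)
                    break
                except SplicedAlignmentError:
                    continue
    return models


def run_pipeline(clones: list[CloneRecord], config: RunConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage on a clone set and return the summary document."""
    config = config or RunConfig()
    if not clones:
        raise PipelineError("validate", "empty clone input")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    fasta_text = []
    for cl in clones:
        fasta_text.append(f">{cl.clone_id} individual={cl.individual_id} "
                          f"source={cl.source}")
        for i in range(0, len(cl.residues), 70):
            fasta_text.append(cl.residues[i:i + 70])
    run_id = hashlib.sha1(("\n".join(fasta_text) + "\n").encode()
                          ).hexdigest()[:16]

    # --- validate ---------------------------------------------------------
    try:
        cdna_clones = [c for c in clones if c.source == "cdna"]
        gdna_clones = [c for c in clones if c.source == "gdna"]
        cdna_alleles, cdna_table, cdna_discard = ([], None, None)
        if cdna_clones:
            cdna_alleles, cdna_table, cdna_discard = collapse_clones(
                cdna_clones, config.min_support,
                name_prefix=f"{config.name_prefix}c")
        gdna_alleles, gdna_table, gdna_discard = ([], None, None)
        if gdna_clones:
            gdna_alleles, gdna_table, gdna_discard = collapse_clones(
                gdna_clones, config.min_support,
                name_prefix=f"{config.name_prefix}g")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("validate", str(exc)) from exc
    if out is not None:
        for label, alleles, table, discard in (
                ("cdna", cdna_alleles, cdna_table, cdna_discard),
                ("gdna", gdna_alleles, gdna_table, gdna_discard)):
            if table is None:
                continue
            write_fasta([SequenceRecord(a.allele_name, a.residues)
                         for a in alleles], out / f"alleles_{label}.fasta")
            table.to_frame().to_csv(out / f"genotypes_{label}.tsv",
                                    sep="\t", index=False)
            discard.to_csv(out / f"discards_{label}.tsv", sep="\t",
                           index=False)

    # --- annotate ---------------------------------------------------------
    try:
        models = _annotate_alleles(gdna_alleles, cdna_alleles,
                                   config.min_exon)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc
    if out is not None and models:
        (out / "gene_models.json").write_text(json.dumps(
            {name: json.loads(gene_model_to_json(m))
             for name, m in sorted(models.items())}, indent=2))

    # --- polymorphism / selection ----------------------------------------
    selection_results = {}
    poly_total, poly_regions = 0, {}
    try:
        # reference for region definitions: the annotated model with the
        # longest ORF (guards against rare null alleles with broken starts)
        ref_model = None
        if models:
            ref_model = max(
                (models[n] for n in sorted(models)),
                key=lambda m: m.orf.length if m.orf else 0)
        if len(cdna_alleles) >= 2:
            msa = build_msa([SequenceRecord(a.allele_name, a.residues)
                             for a in cdna_alleles])
            partition = None
            if ref_model is not None and ref_model.n_exons >= 3:
                partition = partition_regions(ref_model, "pbr_vs_rest")
            poly_total, poly_regions = polymorphic_sites(msa, partition)
            if partition is not None:
                for region in partition.names():
                    res = selection_test(
                        msa, region, partition,
                        n_bootstrap=config.n_bootstrap, seed=config.seed,
                        stops=config.stops)
                    selection_results[region] = {
                        "dN": res.dN, "dS": res.dS, "ratio": res.ratio,
                        "Z": res.Z, "p": res.p,
                        "applicable": res.applicable,
                    }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("polymorphism", str(exc)) from exc

    # --- loci -------------------------------------------------------------
    try:
        grouping = None
        newick = None
        focal_alleles = gdna_alleles if gdna_alleles else cdna_alleles
        focal_table = gdna_table if gdna_alleles else cdna_table
        dist_items: list[tuple[str, str]] = []
        if len(focal_alleles) >= 2 and focal_table is not None:
            if models and all(a.allele_name in models
                              for a in focal_alleles):
                dist_items = [
                    (a.allele_name,
                     "".join(SequenceRecord(a.allele_name, a.residues)
                             .residues[s:e]
                             for s, e in models[a.allele_name].exons))
                    for a in focal_alleles
                ]
            else:
                dist_items = [(a.allele_name, a.residues)
                              for a in focal_alleles]
            dm = p_distance_matrix(dist_items)
            grouping = constrained_grouping(
                dm, focal_table, outlier_quantile=config.outlier_quantile)
            if len(dm.labels) >= 3:
                newick = nj_tree(dm)
        bound = min_locus_bound(focal_table) if focal_table else 0
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("loci", str(exc)) from exc
    if out is not None:
        if newick:
            (out / "alleles.nwk").write_text(newick + "\n")
        if dist_items:
            (out / "alleles.nex").write_text(export_nexus(dist_items))

    # --- repeats ----------------------------------------------------------
    try:
        intron_df = pd.DataFrame()
        if models:
            seqs = {a.allele_name: SequenceRecord(a.allele_name, a.residues)
                    for a in gdna_alleles}
            intron_df = intron_length_table(
                [models[n] for n in sorted(models)], seqs, grouping,
                min_purity=config.repeat_min_purity)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("repeats", str(exc)) from exc
    if out is not None and not intron_df.empty:
        intron_df.to_csv(out / "intron_table.tsv", sep="\t", index=False)

    summary = {
        "tool": "mhcloci",
        "version": __version__,
        "run_id": run_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_clones": len(clones),
        "n_alleles": {"cdna": len(cdna_alleles), "gdna": len(gdna_alleles)},
        "allele_sequences": {
            "cdna": sorted(a.residues for a in cdna_alleles),
            "gdna": sorted(a.residues for a in gdna_alleles),
            "gdna_names": {a.allele_name: a.residues for a in gdna_alleles},
        },
        "per_individual_allele_counts":
            focal_table.counts() if focal_table else {},
        "min_locus_bound": bound,
        "min_locus_estimate":
            grouping.min_locus_estimate if grouping else bound,
        "estimate_is_lower_bound": True,
        "groups": [list(g) for g in grouping.groups] if grouping else [],
        "unassigned": list(grouping.unassigned) if grouping else [],
        "polymorphic_sites": {"total": poly_total, **poly_regions},
        "selection": selection_results,
        "models": {name: [list(iv) for iv in m.exons]
                   for name, m in sorted(models.items())},
        "intron_table": intron_df.to_dict(orient="records"),
    }
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_pipeline_files(fasta_path: str | Path,
                       metadata_path: str | Path | None = None,
                       config: RunConfig | None = None,
                       outdir: str | Path | None = None) -> dict:
    """File-based wrapper around :func:`run_pipeline`."""
    clones = load_clones(fasta_path, metadata_path)
    return run_pipeline(clones, config=config, outdir=outdir)
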