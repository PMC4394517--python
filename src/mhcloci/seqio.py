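"""Sequence records, FASTA and clone-metadata I/O, translation, ORF discovery.

All coordinates handled here are 0-based half-open; user-facing reports
elsewhere in the package convert to 1-based inclusive biological numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_INDIVIDUAL_RE = re.compile(r"\bindividual=(\S+)")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    The individual of origin, when known, is carried in the free-text
    description as an ``individual=<id>`` key (FASTA has no standard slot
    for per-clone metadata).
    """

    seq_id: str
    residues: str
    description: str = ""
    moltype: str = "dna"

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"{self.seq_id}: unknown moltype {self.moltype!r}")
        bad = set(residues) - alphabet
        if bad:
            raise ValueError(
                f"{self.seq_id}: characters {sorted(bad)} outside the "
                f"{self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def individual(self) -> str | None:
        m = _INDIVIDUAL_RE.search(self.description)
        return m.group(1) if m else None


@dataclass(frozen=True)
class OrfAnnotation:
    """An ATG-initiated, stop-terminated open reading frame on a cDNA.

    ``start``/``end`` are 0-based half-open on the cDNA; ``end`` points just
    past the stop codon.  ``protein`` excludes the stop.
    """

    start: int
    end: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file.

    Order is preserved, one record per ``>`` header.  A file whose first
    non-blank line is not a header raises :class:`FastaParseError` naming
    the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.seq_id
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def translate(dna: str, frame: int = 0) -> str:
    """Translate ``dna`` in the given frame under the standard genetic code.

    Stop codons become ``*``; codons containing ``N`` (or any non-ACGT
    character) become ``X``; a trailing partial codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    dna = dna.upper()
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def find_orf(cdna: SequenceRecord) -> OrfAnnotation | None:
    """Locate the longest complete ORF (ATG .. in-frame stop) on a cDNA.

    Ties on length are broken by the smallest start offset.  Returns ``None``
    when no ATG-initiated, stop-terminated frame exists.
    """
    if cdna.moltype != "dna":
        raise ValueError("find_orf expects a dna record")
    seq = cdna.residues
    n = len(seq)
    # earliest in-frame stop end for each frame, precomputed left to right
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if CODON_TO_AA.get(seq[i:i + 3]) == "*":
            stops_by_frame[i % 3].append(i)
    best: tuple[int, int] | None = None  # (-length, start)
    for i in range(n - 2):
        if seq[i:i + 3] != "ATG":
            continue
        frame_stops = stops_by_frame[i % 3]
        stop = next((s for s in frame_stops if s >= i + 3), None)
        if stop is None:
            continue
        length = stop + 3 - i
        key = (-length, i)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    length, start = -best[0], best[1]
    end = start + length
    protein = translate(seq[start:end - 3], 0)
    if "*" in protein:  # cannot happen: stop chosen as the first in frame
        raise AssertionError("internal stop in ORF protein")
    return OrfAnnotation(start=start, end=end, protein=protein)


def read_clone_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar clone metadata TSV.

    Expected columns: ``clone_id  individual_id  source`` where source is
    ``cdna`` or ``gdna``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone_id", "individual_id", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone metadata missing columns: {sorted(missing)}")
    bad = set(df["source"]) - {"cdna", "gdna"}
    if bad:
        raise ValueError(f"clone metadata has unknown sources: {sorted(bad)}")
    return df


def write_clone_metadata(rows: Iterable[tuple[str, str, str]],
                         path: str | Path) -> None:
    """Write ``(clone_id, individual_id, source)`` rows as the metadata TSV."""
    df = pd.DataFrame(rows, columns=["clone_id", "individual_id", "source"])
    df.to_csv(path, sep="\t", index=False)
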