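"""Pairwise global alignment shared by the MSA builder and distance code.

Scoring defaults (match +1, mismatch -1, gap open -5, gap extend -1) are
tuned for near-identical allele sets, where any sensible scheme produces
the same alignment; they are exposed for callers that need otherwise.
"""

from __future__ import annotations

from Bio import Align


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 open_gap: float = -5.0, extend_gap: float = -1.0
                 ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_align(a: str, b: str, aligner: Align.PairwiseAligner | None = None
                   ) -> tuple[str, str]:
    """Globally align two sequences; returns the gapped strings.

    The first optimal alignment reported by the aligner is used, which is
    deterministic for fixed inputs and scoring.
    """
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])
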