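"""Novel-lncRNA / TUCP identification cascade.

Candidate transcripts pass four stages, evaluated strictly in order:

1. structural filter — transcript length >= 200 nt and a determinate strand;
2. annotation filter — no exonic overlap (>= 1 base, same strand by default)
   with the reference annotation's exons;
3. expression filter — maximum FPKM across all samples >= 0.5;
4. coding-potential classification of the survivors.

Stage 4 is a self-contained ORF heuristic standing in for external
coding-potential predictors: the longest ATG-to-stop open reading frame over
the three sense frames (stop codon excluded from the length) yields

* ``noncoding``  — longest ORF < 300 nt            -> novel lncRNA
* ``coding``     — longest ORF >= 900 nt and ORF coverage >= 0.8 of the
  transcript                                       -> coding discard
* ``uncertain``  — anything in between             -> TUCP (transcript of
  uncertain coding potential)

A per-stage audit table records input and survivor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .simdata import GeneModel

__all__ = [
    "TranscriptCandidate",
    "CodingPotentialScore",
    "filter_length_strand",
    "filter_annotation_overlap",
    "filter_expression",
    "coding_potential",
    "classify_candidates",
]

MIN_TX_LENGTH = 200  # nt; "<200 bp" candidates are removed
MIN_FPKM = 0.5
ORF_NONCODING_MAX = 300  # nt, exclusive upper bound for a clear noncoding call
ORF_CODING_MIN = 900  # nt
ORF_COVERAGE_MIN = 0.8
STOP_CODONS = {"TAA", "TAG", "TGA"}
STAGES = ("length_strand", "annotation_overlap", "expression", "coding_potential")


@dataclass(frozen=True)
class CodingPotentialScore:
    longest_orf_nt: int
    orf_coverage: float
    verdict: str  # noncoding | uncertain | coding


@dataclass
class TranscriptCandidate:
    """A putative noncoding transcript moving through the cascade.

    ``stage_flags`` records a pass/fail verdict per stage, only up to the
    first failing stage; ``final_class`` is ``filtered_out`` when any of
    stages 1-3 failed, otherwise the stage-4 class.
    """

    transcript_id: str
    model: GeneModel
    max_fpkm: float | None = None
    sequence: str | None = None
    stage_flags: dict[str, bool] = field(default_factory=dict)
    final_class: str | None = None


def filter_length_strand(candidates: Sequence[TranscriptCandidate]) -> dict[str, bool]:
    """Stage 1: keep transcripts >= 200 nt with a determinate strand."""
    return {
        c.transcript_id: (
            c.model.tx_length >= MIN_TX_LENGTH and c.model.strand in ("+", "-")
        )
        for c in candidates
    }


def _exon_trees(
    reference: Iterable[GeneModel], same_strand: bool
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in reference:
        key_strand = g.strand if same_strand else "*"
        tree = trees.setdefault((g.chrom, key_strand), IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e + 1)  # closed interval -> half-open
    return trees


def filter_annotation_overlap(
    candidates: Sequence[TranscriptCandidate],
    reference: Sequence[GeneModel],
    same_strand: bool = True,
) -> dict[str, bool]:
    """Stage 2: fail on >= 1 base exonic overlap with the reference.

    Overlap is on 1-based closed intervals (a.start <= b.end and
    b.start <= a.end), same-strand by default; with ``same_strand=False``
    exons on either strand disqualify. An unknown-strand candidate is
    compared against both strands in same-strand mode.
    """
    trees = _exon_trees(reference, same_strand)

    def overlaps(c: TranscriptCandidate) -> bool:
        strands = [c.model.strand] if c.model.strand in ("+", "-") else ["+", "-"]
        keys = [(c.model.chrom, s) for s in strands] if same_strand else [
            (c.model.chrom, "*")
        ]
        for key in keys:
            tree = trees.get(key)
            if tree is None:
                continue
            for s, e in c.model.exons:
                if tree.overlap(s, e + 1):
                    return True
        return False

    return {c.transcript_id: not overlaps(c) for c in candidates}


def filter_expression(
    candidates: Sequence[TranscriptCandidate],
    fpkm: pd.DataFrame | Mapping[str, float],
    threshold: float = MIN_FPKM,
) -> dict[str, bool]:
    """Stage 3: keep transcripts whose max FPKM over all samples >= 0.5."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    result = {}
    for c in candidates:
        if isinstance(fpkm, pd.DataFrame):
            if c.transcript_id not in fpkm.index:
                raise KeyError(f"candidate {c.transcript_id} absent from FPKM table")
            value = float(fpkm.loc[c.transcript_id].max())
        else:
            if c.transcript_id not in fpkm:
                raise KeyError(f"candidate {c.transcript_id} absent from FPKM table")
            value = float(fpkm[c.transcript_id])
        c.max_fpkm = value
        result[c.transcript_id] = value >= threshold
    return result


def coding_potential(sequence: str) -> CodingPotentialScore:
    """Stage 4 scorer: longest sense-strand ATG->stop ORF over three frames.

    The ORF length excludes the stop codon and is therefore divisible by 3;
    an ORF requires an in-frame stop. The empty sequence scores noncoding
    with ORF 0; characters outside {A, C, G, T, N} are rejected.
    """
    seq = sequence.upper()
    if any(ch not in "ACGTN" for ch in seq):
        bad = sorted({ch for ch in seq if ch not in "ACGTN"})
        raise ValueError(f"invalid nucleotide character(s): {bad}")
    n = len(seq)
    longest = 0
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                longest = max(longest, i - start)
                start = None
    coverage = longest / n if n else 0.0
    if longest < ORF_NONCODING_MAX:
        verdict = "noncoding"
    elif longest >= ORF_CODING_MIN and coverage >= ORF_COVERAGE_MIN:
        verdict = "coding"
    else:
        verdict = "uncertain"
    return CodingPotentialScore(longest, coverage, verdict)


_VERDICT_CLASS = {
    "noncoding": "novel_lncRNA",
    "uncertain": "TUCP",
    "coding": "coding_discard",
}


def classify_candidates(
    candidates: Sequence[TranscriptCandidate],
    reference: Sequence[GeneModel],
    fpkm: pd.DataFrame | Mapping[str, float],
    same_strand: bool = True,
    expression_threshold: float = MIN_FPKM,
) -> tuple[list[TranscriptCandidate], pd.DataFrame]:
    """Run the full cascade and produce per-stage audit counts.

    Stages run in the fixed order 1 -> 2 -> 3 -> 4; a candidate failing stage
    k records no verdicts for later stages and is classed ``filtered_out``.
    Output is sorted by transcript_id, so it is independent of input order.
    """
    ordered = sorted(candidates, key=lambda c: c.transcript_id)
    audit_rows = []
    alive = list(ordered)

    stage_fns = [
        ("length_strand", lambda cs: filter_length_strand(cs)),
        (
            "annotation_overlap",
            lambda cs: filter_annotation_overlap(cs, reference, same_strand),
        ),
        (
            "expression",
            lambda cs: filter_expression(cs, fpkm, expression_threshold),
        ),
    ]
    for stage, fn in stage_fns:
        n_in = len(alive)
        verdicts = fn(alive) if alive else {}
        survivors = []
        for c in alive:
            ok = verdicts[c.transcript_id]
            c.stage_flags[stage] = ok
            if ok:
                survivors.append(c)
            else:
                c.final_class = "filtered_out"
        audit_rows.append({"stage": stage, "n_in": n_in, "n_out": len(survivors)})
        alive = survivors

    n_in = len(alive)
    for c in alive:
        if c.sequence is None:
            raise ValueError(
                f"candidate {c.transcript_id} reached coding-potential scoring "
                "without a sequence"
            )
        score = coding_potential(c.sequence)
        c.stage_flags["coding_potential"] = score.verdict != "coding"
        c.final_class = _VERDICT_CLASS[score.verdict]
    n_kept = sum(1 for c in alive if c.final_class != "coding_discard")
    audit_rows.append({"stage": "coding_potential", "n_in": n_in, "n_out": n_kept})
    audit = pd.DataFrame(audit_rows)
    return ordered, audit
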