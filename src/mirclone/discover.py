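"""Novel miRNA discovery from genome-matched, database-unmatched reads.

Reads that occur verbatim in the genome but match no reference database are
grouped into candidate loci by single-linkage merging of overlapping
same-strand intervals.  Each group is then classified by a fixed cascade:

1. overlaps a known precursor on the same strand, on the arm opposite the
   annotated mature miRNA -> ``opposite`` (star/passenger product; the
   precursor structure is already accepted, so it is not re-folded);
2. overlaps a known miRNA locus on the other strand and folds into a
   passing hairpin in its own strand's context -> ``antisense``
   (conservation is not required: the locus is the same chromosomal region);
3. no overlap with any known locus, passes the structural criteria and the
   stem-conservation test -> ``novel``;
4. otherwise ``rejected`` with the first failing reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin import (
    CriteriaReport,
    CriteriaThresholds,
    evaluate_criteria,
    fold,
    stem_conservation,
    window_scan,
)


@dataclass
class CandidateGroup:
    start: int
    end: int
    strand: str
    reads: list[tuple[str, str, int, int]] = field(default_factory=list)  # (read_id, seq, pos, count)

    @property
    def clone_count(self) -> int:
        return sum(c for *_, c in self.reads)

    @property
    def representative(self) -> tuple[str, int, int]:
        """(sequence, start, end) of the highest-clone-count sequence.

        Ties go to the lexicographically smallest sequence.
        """
        agg: dict[str, tuple[int, int]] = {}
        for _, seq, pos, count in self.reads:
            c, p = agg.get(seq, (0, pos))
            agg[seq] = (c + count, p)
        seq = max(sorted(agg), key=lambda s: agg[s][0])
        pos = agg[seq][1]
        return seq, pos, pos + len(seq)


@dataclass
class CandidateCall:
    group: CandidateGroup
    call_class: str  # novel / opposite / antisense / rejected
    reason: str | None = None
    criteria: CriteriaReport | None = None
    fold_score: int | None = None

    def as_row(self) -> dict:
        seq, ms, me = self.group.representative
        return dict(start=self.group.start, end=self.group.end, strand=self.group.strand,
                    clone_count=self.group.clone_count, n_reads=len(self.group.reads),
                    sequence=seq, call=self.call_class, reason=self.reason or "",
                    fold_score=self.fold_score if self.fold_score is not None else "")


def group_candidates(frame: pd.DataFrame, min_reads: int = 0) -> list[CandidateGroup]:
    """Single-linkage merge of overlapping same-strand genome-class reads.

    ``frame`` is the annotation frame restricted by this function to
    ``db_class == "genome"`` rows (exact genomic hits).  Groups are returned
    sorted by (strand, start); input row order never affects the result.
    """
    gen = frame[frame.db_class == "genome"]
    groups: list[CandidateGroup] = []
    for strand in ("+", "-"):
        sub = gen[gen.strand == strand]
        if sub.empty:
            continue
        ivs = sorted(
            (int(r.offset), int(r.offset) + len(r.seq), r.read_id, r.seq, int(r.count))
            for r in sub.itertuples()
        )
        cur: CandidateGroup | None = None
        for start, end, rid, seq, count in ivs:
            if cur is not None and start < cur.end:  # >= 1 nt overlap
                cur.end = max(cur.end, end)
                cur.reads.append((rid, seq, start, count))
            else:
                cur = CandidateGroup(start, end, strand, [(rid, seq, start, count)])
                groups.append(cur)
    groups = [g for g in groups if g.clone_count >= min_reads]
    return sorted(groups, key=lambda g: (g.strand, g.start))


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _terminal_loop_midpoint(precursor_seq: str, start: int) -> float:
    """Genomic midpoint of the precursor's terminal loop (plus strand)."""
    fr = fold(precursor_seq)
    partner = fr.partner
    paired = np.flatnonzero(partner >= 0)
    if paired.size == 0:
        return start + len(precursor_seq) / 2
    # innermost pair = the pair (i, j) with minimal j - i
    i, j = min(((int(i), int(partner[i])) for i in paired if partner[i] > i),
               key=lambda p: p[1] - p[0])
    return start + (i + j) / 2


def classify_candidate(
    group: CandidateGroup,
    known_loci: pd.DataFrame,
    genome: str,
    track: np.ndarray | None,
    thresholds: CriteriaThresholds | None = None,
    min_reads: int = 2,
    conservation_window: int = 15,
    conservation_cutoff: float = 0.8,
    fold_window: int = 110,
    context: int = 88,
    step: int = 5,
) -> CandidateCall:
    """Apply the discovery cascade to one candidate group.

    ``known_loci`` needs columns locus_id, cls, start, end, strand,
    mature_start, mature_end with classes ``known-precursor`` and
    ``known-mature``.  ``track`` may be None, which disables novel calls
    (conservation cannot be evaluated).
    """
    if group.clone_count < min_reads:
        return CandidateCall(group, "rejected", reason="low-support")
    seq, ms, me = group.representative
    if me - ms > fold_window:
        return CandidateCall(group, "rejected", reason="candidate-too-long")

    pre = known_loci[known_loci.cls == "known-precursor"]
    same = pre[(pre.strand == group.strand)]
    for r in same.itertuples():
        if _overlaps(group.start, group.end, r.start, r.end):
            mid = _terminal_loop_midpoint(genome[r.start : r.end], r.start)
            cand_mid = (ms + me) / 2
            mature_mid = (r.mature_start + r.mature_end) / 2
            if (cand_mid - mid) * (mature_mid - mid) < 0:
                return CandidateCall(group, "opposite")
            return CandidateCall(group, "rejected", reason="overlaps-known")

    mat = known_loci[known_loci.cls == "known-mature"]
    anti = mat[mat.strand != group.strand]
    antisense_hit = any(_overlaps(group.start, group.end, r.start, r.end) for r in anti.itertuples())

    any_known = any(
        _overlaps(group.start, group.end, r.start, r.end) for r in known_loci.itertuples()
    )
    if any_known and not antisense_hit:
        return CandidateCall(group, "rejected", reason="overlaps-known")

    scan = window_scan(genome, ms, me, strand=group.strand,
                       window=fold_window, context=context, step=step)
    report = evaluate_criteria(scan.fold, scan.mature_span, thresholds)

    if antisense_hit:
        if report.structure_pass:
            return CandidateCall(group, "antisense", criteria=report, fold_score=scan.fold.score)
        return CandidateCall(group, "rejected", reason=report.first_failure(),
                             criteria=report, fold_score=scan.fold.score)

    if not report.structure_pass:
        return CandidateCall(group, "rejected", reason=report.first_failure(),
                             criteria=report, fold_score=scan.fold.score)
    if track is None:
        return CandidateCall(group, "rejected", reason="no-conservation-track",
                             criteria=report, fold_score=scan.fold.score)
    conserved, best_mean, flag = stem_conservation(
        scan.fold, track, mature_span=scan.mature_span,
        window=conservation_window, cutoff=conservation_cutoff,
    )
    report.conserved = conserved
    report.best_window_mean = best_mean
    report.conservation_flag = flag
    if conserved:
        return CandidateCall(group, "novel", criteria=report, fold_score=scan.fold.score)
    return CandidateCall(group, "rejected", reason=flag or "not-conserved",
                         criteria=report, fold_score=scan.fold.score)


def discover(
    frame: pd.DataFrame,
    known_loci: pd.DataFrame,
    genome: str,
    track: np.ndarray | None,
    min_reads: int = 2,
    **kw,
) -> pd.DataFrame:
    """Group genome-class reads and classify every candidate locus."""
    groups = group_candidates(frame)
    calls = [classify_candidate(g, known_loci, genome, track, min_reads=min_reads, **kw)
             for g in groups]
    return pd.DataFrame([c.as_row() for c in calls])
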