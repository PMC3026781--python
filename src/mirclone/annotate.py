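"""Classify cloned small-RNA reads against reference databases and count clones.

Each read is searched against the reference databases in a fixed class
priority order (miRNA, piRNA, rRNA, tRNA, snRNA, snoRNA, mRNA), then
against the genome.  A database hit is valid when a best ungapped sliding
alignment exceeds 90% identity (strictly), allowing up to 3 nt of
unpenalized 5'/3' end overhang — cloning yields end variation, not indels.
Reads that match no database but occur verbatim in the genome form the
novel-candidate pool; everything else is unmatched.

Clone counts are then assembled into an expression matrix normalized per
1000 miRNA-annotated reads per sample, with optional modified/nonmodified
sub-rows supplied by the editing module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hairpin import revcomp

logger = logging.getLogger(__name__)

DB_PRIORITY = ["miRNA", "piRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "mRNA"]

_PAD = 255  # sentinel byte that matches nothing


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    seq: str  # DNA alphabet, T for U
    sample: str
    count: int = 1

    def __post_init__(self):
        if not 15 <= len(self.seq) <= 35:
            raise ValueError(f"read {self.read_id}: length {len(self.seq)} outside [15, 35]")
        if set(self.seq) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: invalid alphabet")
        if self.count < 1:
            raise ValueError(f"read {self.read_id}: multiplicity must be >= 1")


@dataclass
class AnnotationRecord:
    read_id: str
    db_class: str  # one of DB_PRIORITY, "genome", or "unmatched"
    ref_id: str | None
    identity: float
    offset: int | None  # read start on the reference (db hits) or genome (genome hits)
    end5: int  # 5' overhang beyond the reference
    end3: int  # 3' overhang beyond the reference
    strand: str = "+"


def reads_from_fasta(records: list[tuple[str, str, dict]]) -> list[ReadRecord]:
    """Expand parsed FASTA (id, seq, attrs) into ReadRecords with multiplicity."""
    out = []
    for rid, seq, attrs in records:
        out.append(ReadRecord(rid, seq, attrs.get("sample", "NA"), int(attrs.get("count", 1))))
    return out


def _to_bytes(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    a[a == ord("N")] = _PAD - 1  # N matches nothing (distinct from pad)
    return a


class ReferenceSet:
    """One database class: named reference sequences with a match routine."""

    def __init__(self, db_class: str, entries: dict[str, str]):
        self.db_class = db_class
        # deterministic entry order (by id) so file order never matters
        self.entries = dict(sorted(entries.items()))
        self._enc = {rid: _to_bytes(s) for rid, s in self.entries.items()}

    def best_match(self, seq: str, min_identity: float, max_overhang: int):
        """Best ungapped hit as (identity, ref_id, offset, end5, end3) or None.

        Identity = matches / aligned-core length over all slide offsets with
        each end overhang <= max_overhang; best identity wins, ties go to the
        lexicographically smallest reference id (first in sorted order).
        """
        q = _to_bytes(seq)
        nq = q.size
        best = None
        for rid, r in self._enc.items():
            if best is not None and best[0] == 1.0:
                break  # nothing can beat a perfect hit under sorted-id ties
            m = r.size
            if nq > m + 2 * max_overhang:
                continue
            # fast path: exact substring
            pos = self.entries[rid].find(seq)
            if pos >= 0 and "N" not in seq:
                cand = (1.0, rid, pos, 0, 0)
                if best is None or cand[0] > best[0]:
                    best = cand
                continue
            padded = np.full(m + 2 * max_overhang, _PAD, dtype=np.uint8)
            padded[max_overhang : max_overhang + m] = r
            if padded.size < nq:
                continue
            win = np.lib.stride_tricks.sliding_window_view(padded, nq)
            matches = (win == q[None, :]).sum(axis=1)
            offs = np.arange(win.shape[0]) - max_overhang  # read start on reference
            end5 = np.maximum(0, -offs)
            end3 = np.maximum(0, offs + nq - m)
            core = nq - end5 - end3
            with np.errstate(divide="ignore", invalid="ignore"):
                ident = matches / core
            valid = (end5 <= max_overhang) & (end3 <= max_overhang) & (core > 0) & (ident > min_identity)
            if valid.any():
                k = int(np.flatnonzero(valid)[np.argmax(ident[valid])])
                cand = (float(ident[k]), rid, int(offs[k]), int(end5[k]), int(end3[k]))
                if best is None or cand[0] > best[0]:
                    best = cand
        return best


class Annotator:
    """Priority-ordered classifier over reference databases plus a genome."""

    def __init__(
        self,
        dbs: dict[str, dict[str, str]],
        genome: str | None = None,
        min_identity: float = 0.90,
        max_overhang: int = 3,
    ):
        if not dbs and genome is None:
            raise ValueError("no reference databases or genome provided")
        unknown = set(dbs) - set(DB_PRIORITY)
        if unknown:
            raise ValueError(f"unknown database classes: {sorted(unknown)}")
        self.sets = {cls: ReferenceSet(cls, dbs[cls]) for cls in DB_PRIORITY if cls in dbs and dbs[cls]}
        self.genome = genome
        self.min_identity = min_identity
        self.max_overhang = max_overhang
        self._cache: dict[str, AnnotationRecord] = {}

    def classify_seq(self, seq: str) -> AnnotationRecord:
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        rec = None
        for cls, rs in self.sets.items():
            m = rs.best_match(seq, self.min_identity, self.max_overhang)
            if m is not None:
                ident, rid, off, e5, e3 = m
                rec = AnnotationRecord("", cls, rid, ident, off, e5, e3)
                break
        if rec is None and self.genome is not None and "N" not in seq:
            pos = self.genome.find(seq)
            if pos >= 0:
                rec = AnnotationRecord("", "genome", None, 1.0, pos, 0, 0, "+")
            else:
                pos = self.genome.find(revcomp(seq))
                if pos >= 0:
                    rec = AnnotationRecord("", "genome", None, 1.0, pos, 0, 0, "-")
        if rec is None:
            rec = AnnotationRecord("", "unmatched", None, 0.0, None, 0, 0)
        self._cache[seq] = rec
        return rec

    def classify_read(self, read: ReadRecord) -> AnnotationRecord:
        base = self.classify_seq(read.seq)
        return AnnotationRecord(read.read_id, base.db_class, base.ref_id, base.identity,
                                base.offset, base.end5, base.end3, base.strand)

    def classify_reads(self, reads: list[ReadRecord]) -> list[AnnotationRecord]:
        return [self.classify_read(r) for r in reads]


def annotations_to_frame(reads: list[ReadRecord], anns: list[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "sample": [r.sample for r in reads],
            "seq": [r.seq for r in reads],
            "count": [r.count for r in reads],
            "db_class": [a.db_class for a in anns],
            "ref_id": [a.ref_id for a in anns],
            "identity": [a.identity for a in anns],
            "offset": [a.offset for a in anns],
            "end5": [a.end5 for a in anns],
            "end3": [a.end3 for a in anns],
            "strand": [a.strand for a in anns],
        }
    )


def count_and_normalize(
    frame: pd.DataFrame,
    modified_read_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the (miRNA, form) x sample expression matrix and class composition.

    ``frame`` is the annotation frame from :func:`annotations_to_frame`.
    Counts are clone counts (multiplicity-weighted).  Normalization is per
    1000 miRNA-annotated reads per sample, so each sample's total-form
    column sums to exactly 1000.  ``modified_read_ids`` (from the editing
    module) splits each miRNA into nonmodified/modified/total sub-rows;
    without it the modified rows are zero.

    Returns (normalized matrix with MultiIndex rows (mirna, form),
    composition table of per-class clone-count fractions per sample).
    """
    if frame.empty:
        raise ValueError("no annotated reads")
    totals = frame.groupby("sample")["count"].sum()
    empty = [s for s, t in totals.items() if t == 0]
    if empty:
        logger.warning("samples with zero reads excluded: %s", empty)
        frame = frame[~frame["sample"].isin(empty)]

    comp = frame.pivot_table(index="db_class", columns="sample", values="count", aggfunc="sum", fill_value=0)
    comp = comp / comp.sum(axis=0)

    mir = frame[frame["db_class"] == "miRNA"].copy()
    if modified_read_ids is None:
        modified_read_ids = set()
    mir["form"] = np.where(mir["read_id"].isin(modified_read_ids), "modified", "nonmodified")
    counts = mir.pivot_table(index=["ref_id", "form"], columns="sample", values="count", aggfunc="sum", fill_value=0)
    samples = sorted(frame["sample"].unique())
    counts = counts.reindex(columns=samples, fill_value=0)

    mirnas = sorted(counts.index.get_level_values(0).unique())
    full_idx = pd.MultiIndex.from_product([mirnas, ["nonmodified", "modified"]], names=["mirna", "form"])
    counts = counts.reindex(full_idx, fill_value=0)
    tot = counts.groupby(level="mirna").sum()
    tot.index = pd.MultiIndex.from_product([tot.index, ["total"]], names=["mirna", "form"])
    raw = pd.concat([counts, tot]).sort_index()

    denom = raw.xs("total", level="form").sum(axis=0)
    norm = raw * 1000.0 / denom
    return norm, comp


def raw_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Raw miRNA clone-count matrix (mirna x sample), total form only."""
    mir = frame[frame["db_class"] == "miRNA"]
    return mir.pivot_table(index="ref_id", columns="sample", values="count", aggfunc="sum", fill_value=0)
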