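"""Per-position modification (editing) profiling of clone reads.

Reads annotated to a mature miRNA are re-aligned 5'-anchored against the
reference, positions are numbered +1 from the reference 5' end, and
single-base substitutions at positions +1..+18 are called; the 3'-variable
tail (and anything past +18) is ignored because 1-3 nt of 3'-end length
variation is a normal product of biogenesis, not modification.  A->G calls
are reported as A->I (inosine reads as guanosine), and T (U in the RNA) is
reported as U in class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROFILE_SPAN = 18  # positions +1..+18 profiled
SEED_RANGE = (2, 8)

_CLASS_ALIAS = {("A", "G"): "A→I"}


def modification_class(from_base: str, to_base: str) -> str:
    alias = _CLASS_ALIAS.get((from_base, to_base))
    if alias:
        return alias
    u = {"T": "U"}
    return f"{u.get(from_base, from_base)}→{u.get(to_base, to_base)}"


@dataclass
class ModificationCall:
    position: int  # 1-based on the reference
    from_base: str
    to_base: str

    @property
    def label(self) -> str:
        return modification_class(self.from_base, self.to_base)

    @property
    def seed(self) -> bool:
        return SEED_RANGE[0] <= self.position <= SEED_RANGE[1]


def align_to_mature(
    read_seq: str,
    ref_seq: str,
    max_offset: int = 2,
    min_identity: float = 0.90,
    max_calls: int = 2,
) -> tuple[int, list[ModificationCall]] | None:
    """Call substitutions from the best 5'-anchored ungapped alignment.

    Offsets of the read 5' end relative to the reference 5' end in
    [-max_offset, +max_offset] are tried (0 first, then by increasing
    magnitude); the offset with the most matches over the overlap wins.
    Returns (offset, calls at +1..+18 within the shared 3' extent), or
    ``None`` when no offset reaches ``min_identity`` or the read carries
    more than ``max_calls`` substitutions (probable artifact).
    """
    order = [0]
    for k in range(1, max_offset + 1):
        order += [-k, k]
    best_off, best_matches, best_ov = None, -1, 0
    for off in order:
        # read index i aligns reference index i + off
        lo = max(0, -off)
        hi = min(len(read_seq), len(ref_seq) - off)
        if hi - lo <= 0:
            continue
        matches = sum(1 for i in range(lo, hi) if read_seq[i] == ref_seq[i + off])
        if matches > best_matches:
            best_off, best_matches, best_ov = off, matches, hi - lo
    if best_off is None or best_ov == 0 or best_matches / best_ov <= min_identity:
        return None
    off = best_off
    lo = max(0, -off)
    hi = min(len(read_seq), len(ref_seq) - off)
    calls = []
    for i in range(lo, hi):
        p = i + off + 1  # 1-based reference position
        if p > PROFILE_SPAN:
            break
        if read_seq[i] != ref_seq[i + off]:
            calls.append(ModificationCall(p, ref_seq[i + off], read_seq[i]))
    if len(calls) > max_calls:
        return None
    return off, calls


@dataclass
class ModificationProfile:
    """Per-group modified-read fractions for one miRNA."""

    mirna_id: str
    sites: pd.DataFrame  # mirna, position, from, to, class, seed, group, fraction, n_edited, n_covering
    group_n: dict[str, int] = field(default_factory=dict)
    modified_read_ids: set[str] = field(default_factory=set)


def modification_profile(
    mirna_id: str,
    reads: list[tuple[str, str, str, int]],  # (read_id, seq, group, count)
    ref_seq: str,
    min_reads: int = 10,
    report_threshold: float = 0.05,
    snp_mask: set[int] | None = None,
    max_offset: int = 2,
) -> ModificationProfile:
    """Profile modification fractions per group for one miRNA.

    ``fraction`` at a (position, from->to) site is edited clones / clones
    covering that position in the group; groups with fewer than
    ``min_reads`` clones get NaN fractions.  A site is reported when some
    group reaches ``report_threshold`` and its position is not in
    ``snp_mask`` (1-based positions to exclude as known polymorphisms).
    """
    snp_mask = snp_mask or set()
    cover: dict[str, np.ndarray] = {}
    edited: dict[tuple[str, int, str, str], int] = {}
    group_n: dict[str, int] = {}
    modified_ids: set[str] = set()
    for read_id, seq, group, count in reads:
        aligned = align_to_mature(seq, ref_seq, max_offset=max_offset)
        if aligned is None:
            continue
        off, calls = aligned
        group_n[group] = group_n.get(group, 0) + count
        cov = cover.setdefault(group, np.zeros(PROFILE_SPAN, dtype=np.int64))
        # covered reference positions: max(+1, 1+off) .. min(read 3' extent, ref, +18)
        lo = max(0, off)
        hi = min(len(seq) + off, len(ref_seq), PROFILE_SPAN)
        if hi > lo:
            cov[lo:hi] += count
        if calls:
            modified_ids.add(read_id)
        for c in calls:
            key = (group, c.position, c.from_base, c.to_base)
            edited[key] = edited.get(key, 0) + count

    site_keys = sorted({(p, f, t) for (_, p, f, t) in edited})
    groups = sorted(group_n)
    rows = []
    for p, f, t in site_keys:
        fracs = {}
        for g in groups:
            cov = int(cover[g][p - 1]) if g in cover else 0
            ne = edited.get((g, p, f, t), 0)
            fracs[g] = (ne, cov)
        reportable = any(
            cov >= min_reads and cov > 0 and ne / cov >= report_threshold for ne, cov in fracs.values()
        ) and p not in snp_mask
        if not reportable:
            continue
        for g in groups:
            ne, cov = fracs[g]
            frac = ne / cov if (group_n.get(g, 0) >= min_reads and cov > 0) else np.nan
            rows.append(dict(mirna=mirna_id, position=p, from_base=f, to_base=t,
                             mod_class=modification_class(f, t),
                             seed=SEED_RANGE[0] <= p <= SEED_RANGE[1],
                             group=g, fraction=frac, n_edited=ne, n_covering=cov))
    sites = pd.DataFrame(rows, columns=["mirna", "position", "from_base", "to_base",
                                        "mod_class", "seed", "group", "fraction",
                                        "n_edited", "n_covering"])
    return ModificationProfile(mirna_id=mirna_id, sites=sites, group_n=group_n,
                               modified_read_ids=modified_ids)


def split_expression_forms(frame: pd.DataFrame, modified_read_ids: set[str]):
    """Modified / nonmodified / total expression rows per miRNA.

    Thin wrapper over the matrix builder: each miRNA contributes three row
    forms and total = nonmodified + modified per sample by construction.
    """
    from .annotate import count_and_normalize

    return count_and_normalize(frame, modified_read_ids)


def profile_all(
    frame: pd.DataFrame,
    mature_seqs: dict[str, str],
    sample_groups: dict[str, str],
    **kw,
) -> tuple[pd.DataFrame, set[str]]:
    """Run modification profiling for every annotated miRNA.

    ``frame`` is the annotation frame (miRNA-class rows are used);
    ``sample_groups`` maps sample id -> group label.  Returns the combined
    site table and the set of modified read ids (any substitution call),
    which feeds the modified/nonmodified split of the expression matrix.
    """
    mir = frame[frame.db_class == "miRNA"]
    tables = []
    modified: set[str] = set()
    for mid, sub in mir.groupby("ref_id"):
        if mid not in mature_seqs:
            continue
        reads = [(r.read_id, r.seq, sample_groups.get(r.sample, r.sample), int(r.count))
                 for r in sub.itertuples()]
        prof = modification_profile(mid, reads, mature_seqs[mid], **kw)
        modified |= prof.modified_read_ids
        if not prof.sites.empty:
            tables.append(prof.sites)
    sites = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return sites, modified
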