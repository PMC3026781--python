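"""Hairpin folding and structural evaluation of miRNA precursor candidates.

Candidate loci are folded in sliding windows over their genomic context and
the resulting secondary structure is screened with the classic precursor
criteria: a single stem-loop, a well-paired mature region, and bounded loop,
internal-loop and bulge sizes, plus a stem-conservation test against a
per-base conservation track.

The folder is a maximum-weighted nested-pairing dynamic program
(Nussinov-style) with pair weights G:C=3, A:U=2, G:U=1 and a minimum hairpin
loop of 3 nt.  It is a deliberate surrogate for a thermodynamic
nearest-neighbour folder: the downstream criteria operate on pairing
topology only, and the surrogate is exhaustively verifiable against brute
force enumeration on short sequences.  ``fold_bruteforce`` provides that
independent reference path.  A different folder can be substituted anywhere
a :class:`FoldResult` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldResult",
    "StructureElements",
    "CriteriaThresholds",
    "CriteriaReport",
    "fold",
    "fold_bruteforce",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "decompose",
    "evaluate_criteria",
    "window_scan",
    "stem_conservation",
]

MIN_HAIRPIN_LOOP = 3

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
# pair weights: G:C=3, A:U=2, G:U=1 (T stands for U throughout)
_W = np.zeros((4, 4), dtype=np.int64)
for _x, _y, _w in [("G", "C", 3), ("A", "T", 2), ("G", "T", 1)]:
    _W[_ENC[_x], _ENC[_y]] = _w
    _W[_ENC[_y], _ENC[_x]] = _w


def _encode(seq: str) -> np.ndarray:
    enc = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c not in _ENC:
            raise ValueError(f"invalid base {c!r} at position {i}")
        enc[i] = _ENC[c]
    return enc


@dataclass
class FoldResult:
    """A nested secondary structure for one window.

    ``pairs`` holds 0-based (i, j) index pairs within the window; ``score``
    is the total pair weight (acts as a negative pseudo-energy: higher is
    more stable).  ``window_start`` is the genomic start of the window on
    the plus strand; ``strand`` records which strand was folded.
    """

    seq: str
    pairs: list[tuple[int, int]]
    score: int
    window_start: int = 0
    strand: str = "+"

    @property
    def partner(self) -> np.ndarray:
        p = np.full(len(self.seq), -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(len(self.seq), self.pairs)


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def dotbracket_to_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced '(' remaining")
    return sorted(pairs)


def fold(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> FoldResult:
    """Maximum-weighted nested pairing of ``seq``.

    Dynamic program over half-open intervals; ties are broken during
    traceback by preferring to pair the leftmost position, and among its
    partners the rightmost one, giving a deterministic structure.
    """
    n = len(seq)
    if not 1 <= n <= 10000:
        raise ValueError("sequence length out of range")
    x = _encode(seq)
    # E[i, j] = best score of half-open interval [i, j)
    E = np.zeros((n + 2, n + 1), dtype=np.int64)
    W = _W[x[:, None], x[None, :]]  # pair weight for (i, k)

    for span in range(min_loop + 2, n + 1):
        i = np.arange(0, n - span + 1)
        j = i + span
        best = E[i + 1, j].copy()
        for m in range(min_loop + 1, span):
            k = i + m
            cand = W[i, k] + E[i + 1, k] + E[k + 1, j]
            np.maximum(best, cand, out=best)
        E[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        while j - i > min_loop + 1:
            target = E[i, j]
            if target == 0:
                break
            paired = False
            for k in range(j - 1, i + min_loop, -1):
                w = W[i, k]
                if w and w + E[i + 1, k] + E[k + 1, j] == target:
                    pairs.append((i, k))
                    stack.append((k + 1, j))
                    j = k
                    i = i + 1
                    paired = True
                    break
            if not paired:
                i += 1
    return FoldResult(seq=seq, pairs=sorted(pairs), score=int(E[0, n]))


def fold_bruteforce(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> int:
    """Best score by explicit enumeration of every nested pairing.

    Exponential-time reference used to validate :func:`fold`; practical
    for sequences up to ~14 nt.
    """
    x = _encode(seq)

    def best(i: int, j: int) -> int:  # half-open [i, j)
        if j - i <= min_loop + 1:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j):
            w = _W[x[i], x[k]]
            if w:
                out = max(out, w + best(i + 1, k) + best(k + 1, j))
        return out

    return best(0, len(seq))


@dataclass
class StructureElements:
    """Element decomposition of one nested structure.

    Sizes follow standard nomenclature: a terminal (hairpin) loop is the
    unpaired stretch closed by an innermost pair; an internal loop has
    unpaired nt on both sides (size = total over both sides); a bulge has
    unpaired nt on exactly one side; stems are maximal stacked-pair runs.
    """

    stems: list[list[tuple[int, int]]] = field(default_factory=list)
    terminal_loops: list[int] = field(default_factory=list)
    internal_loops: list[int] = field(default_factory=list)
    bulges: list[int] = field(default_factory=list)
    multiloops: int = 0
    span: tuple[int, int] | None = None  # outermost closed interval


def _children(pairs: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Top-level pairs strictly inside (lo, hi), in order."""
    out = []
    last_end = lo
    for i, j in pairs:
        if lo < i and j < hi and i > last_end:
            out.append((i, j))
            last_end = j
    return out


def _component_elements(pairs_sorted: list[tuple[int, int]], root: tuple[int, int]) -> StructureElements:
    el = StructureElements(span=root)
    pairset = set(pairs_sorted)

    def kids(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        last = i
        for a, b in pairs_sorted:
            if a > i and b < j and a > last:
                out.append((a, b))
                last = b
        return out

    cur_stem: list[tuple[int, int]] = []

    def walk(i: int, j: int) -> None:
        nonlocal cur_stem
        cur_stem.append((i, j))
        ch = kids(i, j)
        if not ch:
            el.terminal_loops.append(j - i - 1)
            el.stems.append(cur_stem)
            cur_stem = []
            return
        if len(ch) >= 2:
            el.multiloops += 1
            el.stems.append(cur_stem)
            cur_stem = []
            for a, b in ch:
                walk(a, b)
            return
        (a, b) = ch[0]
        left, right = a - i - 1, j - b - 1
        if left == 0 and right == 0:
            pass  # stacked pair, stem continues
        else:
            el.stems.append(cur_stem)
            cur_stem = []
            if left > 0 and right > 0:
                el.internal_loops.append(left + right)
            else:
                el.bulges.append(left + right)
        walk(a, b)

    walk(*root)
    assert root in pairset
    return el


def decompose(fold_result: FoldResult, component: tuple[int, int] | None = None) -> StructureElements:
    """Decompose the structure (or one outermost component) into elements."""
    pairs = sorted(fold_result.pairs)
    if not pairs:
        return StructureElements()
    if component is None:
        roots = _children(pairs, -1, len(fold_result.seq))
        merged = StructureElements()
        for r in roots:
            el = _component_elements(pairs, r)
            merged.stems += el.stems
            merged.terminal_loops += el.terminal_loops
            merged.internal_loops += el.internal_loops
            merged.bulges += el.bulges
            merged.multiloops += el.multiloops
        merged.span = (roots[0][0], roots[-1][1]) if roots else None
        return merged
    return _component_elements(pairs, component)


@dataclass
class CriteriaThresholds:
    """Structural acceptance bounds for a precursor hairpin.

    Defaults encode the published screen: mature portion with more than
    16 nt paired, terminal loop fewer than 20 nt, internal loops fewer
    than 10 nt, bulges fewer than 5 nt.
    """

    min_mature_paired: int = 16  # strict: paired mature nt must exceed this
    max_terminal_loop: int = 20  # strict: loop must be smaller
    max_internal_loop: int = 10
    max_bulge: int = 5


@dataclass
class CriteriaReport:
    a: bool  # single stem-loop configuration
    b: bool  # mature portion > min_mature_paired nt double-stranded
    c: bool  # terminal loop < max_terminal_loop
    d: bool  # every internal loop < max_internal_loop
    e: bool  # every bulge < max_bulge
    n_terminal_loops: int
    mature_paired_nt: int
    terminal_loop_size: int | None
    max_internal_loop: int
    max_bulge: int
    conserved: bool | None = None
    best_window_mean: float | None = None
    conservation_flag: str | None = None

    @property
    def structure_pass(self) -> bool:
        return self.a and self.b and self.c and self.d and self.e

    @property
    def full_pass(self) -> bool:
        return self.structure_pass and bool(self.conserved)

    def first_failure(self) -> str | None:
        if not self.a:
            return "no-single-stem-loop"
        if not self.b:
            return "mature-paired<=16"
        if not self.c:
            return "terminal-loop>=20"
        if not self.d:
            return "internal-loop>=10"
        if not self.e:
            return "bulge>=5"
        if self.conserved is False:
            return "not-conserved"
        return None


def _pair_tree(pairs: list[tuple[int, int]]):
    """Parent and children maps of the nesting tree over sorted pairs."""
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in pairs:  # sorted by i; push/pop by nesting
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    return parent, children


def _stems(pairs: list[tuple[int, int]]):
    """Maximal stacked-pair runs (helices), outermost pair first."""
    parent, children = _pair_tree(pairs)
    stems = []
    for p in pairs:
        q = parent[p]
        stacked = (
            q is not None
            and len(children[q]) == 1
            and p[0] == q[0] + 1
            and p[1] == q[1] - 1
        )
        if not stacked:  # p starts a new stem
            stem = [p]
            cur = p
            while len(children[cur]) == 1:
                (c,) = children[cur]
                if c[0] == cur[0] + 1 and c[1] == cur[1] - 1:
                    stem.append(c)
                    cur = c
                else:
                    break
            stems.append(stem)
    return stems, parent, children


def mature_component(
    pairs: list[tuple[int, int]],
    mature_span: tuple[int, int],
    thresholds: "CriteriaThresholds | None" = None,
) -> tuple[int, int] | None:
    """Root pair of the stem-loop housing the mature span.

    The anchor is the helix carrying most of the mature positions' pairs.
    From its outermost pair, the root extends outward through single-child
    junctions small enough to be precursor elements (internal loops below
    the internal-loop bound, bulges below the bulge bound) and stops at a
    multiloop, a larger junction, or the window exterior — so spurious
    flanking-context structure never joins the hairpin under evaluation.
    """
    th = thresholds or CriteriaThresholds()
    ms, me = mature_span
    touching = {p for p in pairs if (ms <= p[0] < me) or (ms <= p[1] < me)}
    if not touching:
        return None
    pairs = sorted(pairs)
    stems, parent, children = _stems(pairs)
    anchor = max(stems, key=lambda st: (sum(p in touching for p in st), -st[0][0]))
    if not any(p in touching for p in anchor):
        return None
    node = anchor[0]
    while parent[node] is not None and len(children[parent[node]]) == 1:
        q = parent[node]
        left = node[0] - q[0] - 1
        right = q[1] - node[1] - 1
        if left > 0 and right > 0:
            if left + right >= th.max_internal_loop:
                break
        elif left + right > 0:
            if left + right >= th.max_bulge:
                break
        node = q
    return node


def evaluate_criteria(
    fold_result: FoldResult,
    mature_span: tuple[int, int],
    thresholds: CriteriaThresholds | None = None,
) -> CriteriaReport:
    """Evaluate the structural criteria for a mature span within a window.

    ``mature_span`` is 0-based half-open within the window.  The stem-loop
    test (a) applies to the hairpin component housing the mature span (see
    :func:`mature_component`); loop/bulge bounds (c)-(e) apply within that
    component; the pairing count (b) counts mature positions paired
    anywhere in the selected fold.
    """
    th = thresholds or CriteriaThresholds()
    ms, me = mature_span
    pairs = sorted(fold_result.pairs)
    partner = fold_result.partner
    mature_paired = int((partner[ms:me] >= 0).sum())

    best_root = mature_component(pairs, mature_span, th)
    if best_root is None:
        el = StructureElements()
    else:
        el = _component_elements(pairs, best_root)

    n_tl = len(el.terminal_loops)
    tl_size = max(el.terminal_loops) if el.terminal_loops else None
    max_il = max(el.internal_loops) if el.internal_loops else 0
    max_bu = max(el.bulges) if el.bulges else 0

    a = n_tl == 1 and best_root is not None
    b = mature_paired > th.min_mature_paired
    c = tl_size is not None and tl_size < th.max_terminal_loop
    d = max_il < th.max_internal_loop
    e = max_bu < th.max_bulge
    return CriteriaReport(
        a=a, b=b, c=c, d=d, e=e,
        n_terminal_loops=n_tl,
        mature_paired_nt=mature_paired,
        terminal_loop_size=tl_size,
        max_internal_loop=max_il,
        max_bulge=max_bu,
    )


def prune_short_helices(fold_result: FoldResult, min_stack: int = 3) -> FoldResult:
    """Drop helices with fewer than ``min_stack`` stacked pairs.

    Isolated base pairs and 2-stacks are thermodynamically unstable and are
    an artifact of the maximum-pairing surrogate; discarding them before
    structural evaluation mirrors a no-lone-pair folding constraint.  The
    score is kept from the unpruned optimum (used only for window ranking).
    """
    pairs = sorted(fold_result.pairs)
    if not pairs:
        return fold_result
    stems, _, _ = _stems(pairs)
    keep = [p for st in stems if len(st) >= min_stack for p in st]
    return FoldResult(seq=fold_result.seq, pairs=sorted(keep), score=fold_result.score,
                      window_start=fold_result.window_start, strand=fold_result.strand)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class WindowScanResult:
    fold: FoldResult
    mature_span: tuple[int, int]  # within window, strand-local coordinates
    n_windows: int
    truncated_context: bool


def window_scan(
    genome: str,
    locus_start: int,
    locus_end: int,
    strand: str = "+",
    window: int = 110,
    context: int = 88,
    step: int = 5,
    min_stack: int = 3,
) -> WindowScanResult:
    """Fold sliding windows over the genomic context of a candidate locus.

    Adds ``context`` nt of flanking genome on each side, slides ``window``-nt
    windows in ``step``-nt increments keeping only windows that fully contain
    the mature locus, and returns the window whose fold scores highest
    (ties: leftmost window).  Helices shorter than ``min_stack`` are pruned
    from the winning structure before it is returned (see
    :func:`prune_short_helices`).  Minus-strand loci are folded on the
    reverse complement; window coordinates are reported on the plus strand.
    """
    if locus_end - locus_start > window:
        raise ValueError("locus longer than the fold window")
    ext_start = max(0, locus_start - context)
    ext_end = min(len(genome), locus_end + context)
    truncated = ext_start > locus_start - context or ext_end < locus_end + context

    wlen = min(window, ext_end - ext_start)
    starts = []
    s = ext_start
    while s + wlen <= ext_end:
        if s <= locus_start and s + wlen >= locus_end:
            starts.append(s)
        s += step
    if not starts:
        starts = [max(ext_start, min(locus_start, ext_end - wlen))]

    best: FoldResult | None = None
    best_span = (0, 0)
    for s in starts:
        sub = genome[s : s + wlen]
        if strand == "+":
            span = (locus_start - s, locus_end - s)
            seq = sub
        else:
            seq = revcomp(sub)
            span = (s + wlen - locus_end, s + wlen - locus_start)
        fr = fold(seq)
        fr.window_start = s
        fr.strand = strand
        if best is None or fr.score > best.score:
            best, best_span = fr, span
    best = prune_short_helices(best, min_stack=min_stack)
    return WindowScanResult(fold=best, mature_span=best_span, n_windows=len(starts), truncated_context=truncated)


def stem_conservation(
    fold_result: FoldResult,
    track: np.ndarray,
    mature_span: tuple[int, int] | None = None,
    window: int = 15,
    cutoff: float = 0.8,
) -> tuple[bool, float | None, str | None]:
    """Test stem conservation: any 15-nt run of paired positions averaging >= cutoff.

    ``track`` is the per-base conservation score for the whole genome (plus
    strand).  Paired window positions are mapped to genomic coordinates
    (strand-aware), grouped into maximal runs of consecutive genomic
    positions, and every contiguous ``window``-nt sub-window inside a run is
    averaged; the verdict is the maximum mean.  Returns
    (conserved, best_mean, flag) where flag is ``"stem-too-short"`` when no
    run reaches ``window`` nt.
    """
    partner = fold_result.partner
    if mature_span is not None:
        root = mature_component(sorted(fold_result.pairs), mature_span)
        if root is not None:
            mask = np.zeros(len(partner), dtype=bool)
            mask[root[0] : root[1] + 1] = True
            partner = np.where(mask, partner, -1)
    idx = np.flatnonzero(partner >= 0)
    if idx.size == 0:
        return False, None, "stem-too-short"
    n = len(fold_result.seq)
    if fold_result.strand == "+":
        gpos = fold_result.window_start + idx
    else:
        gpos = fold_result.window_start + (n - 1 - idx)
    gpos = np.sort(gpos)

    best_mean: float | None = None
    run_start = 0
    for i in range(1, gpos.size + 1):
        if i == gpos.size or gpos[i] != gpos[i - 1] + 1:
            run = gpos[run_start:i]
            if run.size >= window:
                vals = track[run[0] : run[-1] + 1].astype(float)
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                means = (csum[window:] - csum[:-window]) / window
                m = float(means.max())
                if best_mean is None or m > best_mean:
                    best_mean = m
            run_start = i
    if best_mean is None:
        return False, None, "stem-too-short"
    return bool(best_mean >= cutoff), best_mean, None
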