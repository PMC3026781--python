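"""Generate a self-contained toy clone-sequencing study.

The generator emulates the design of a paired tumor / adjacent-normal
small-RNA cloning experiment: a single synthetic chromosome carrying known
miRNA precursors, planted un-annotated conserved hairpins (novel), decoy
t/r/sn/sno/piRNA loci and antisense targets; per-sample read libraries with
3'-end length variation, per-position editing at configurable group rates
and uniform sequencing error; and clinical outcomes in which one planted
expression cluster carries an elevated recurrence hazard.

Everything is deterministic given the config seed; identical configs
produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .hairpin import revcomp

CHROM = "chrS"

# arm-mismatch substitution, keyed by the base being replaced: the new base
# pairs with neither the partner base (plus strand) nor its complement
# (minus strand), so planted hairpin arms are cleanly bulged on both strands
_MISMATCH = {"T": "A", "A": "C", "C": "A", "G": "C"}


@dataclass
class EditingRule:
    """One planted modification site: mirna, 1-based position, from->to, per-group rates."""

    mirna_id: str
    position: int  # 1-based from the mature 5' end
    from_base: str
    to_base: str
    rate_hcc: float
    rate_anl: float

    def rate(self, group: str) -> float:
        return self.rate_hcc if group == "HCC" else self.rate_anl


@dataclass
class SimConfig:
    seed: int = 0
    n_pairs: int = 22
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 10
    n_decoys: int = 50
    n_opposite: int = 15
    n_antisense: int = 3
    library_size: int = 2000
    genome_length: int = 100_000
    mature_length: int = 22
    loop_length: int = 9
    arm_mismatches: int = 2
    editing_spec: list[EditingRule] = field(default_factory=lambda: [
        EditingRule("mir-03", 6, "A", "G", 0.31, 0.50),
        EditingRule("mir-04", 10, "C", "A", 0.96, 1.00),
        EditingRule("mir-05", 17, "T", "A", 0.74, 0.78),
    ])
    trim3_probs: dict[int, float] = field(default_factory=lambda: {0: 0.55, 1: 0.25, 2: 0.15, 3: 0.05})
    seq_error_rate: float = 0.002
    fold_change_spec: list[tuple[str, float]] = field(default_factory=lambda: [
        ("mir-01", 1.0),   # marker miRNA, up in tumor (miR-21-like)
        ("mir-02", -2.0),  # liver-abundant miRNA, down in tumor (miR-122-like)
        ("mir-06", 1.5),
    ])
    marker_id: str = "mir-01"
    marker_base_abundance: float = 0.08
    downreg_base_abundance: float = 0.12
    highrisk_marker_boost: float = 2.5
    # extra log2 fold changes carried by high-risk tumors only: the distinct
    # expression signature that lets clustering isolate the high-risk group
    highrisk_signature: list[tuple[str, float]] = field(default_factory=lambda: [
        ("mir-07", 2.0), ("mir-08", -2.0), ("mir-09", 2.0), ("mir-10", -2.0),
        ("mir-11", 2.0), ("mir-12", -2.0), ("mir-13", 2.0), ("mir-14", -2.0),
    ])
    expr_sigma: float = 0.5  # per-sample biological variability, log2 sd
    n_highrisk: int = 5
    hazard_ratio: float = 8.0
    baseline_hazard: float = 1.0 / 50.0  # events per month
    censor_rate: float = 0.2
    # class abundance budget (fractions of each library)
    frac_mirna: float = 0.80
    frac_decoy: float = 0.14
    frac_novel: float = 0.03
    frac_opposite: float = 0.02
    frac_antisense: float = 0.01

    def validate(self) -> None:
        rates = [self.seq_error_rate, self.censor_rate] + list(self.trim3_probs.values())
        for r in self.editing_spec:
            rates += [r.rate_hcc, r.rate_anl]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if abs(sum(self.trim3_probs.values()) - 1) > 1e-9:
            raise ValueError("trim3_probs must sum to 1")
        known = {f"mir-{i + 1:02d}" for i in range(self.n_known_mirnas)}
        for r in self.editing_spec:
            if r.mirna_id not in known:
                raise ValueError(f"editing_spec references unknown miRNA {r.mirna_id}")
        if self.n_opposite > self.n_known_mirnas or self.n_antisense > self.n_known_mirnas:
            raise ValueError("opposite/antisense counts exceed known miRNAs")
        if self.n_highrisk > self.n_pairs:
            raise ValueError("n_highrisk exceeds n_pairs")


@dataclass
class SimTruth:
    genome: str
    conservation: np.ndarray
    loci: pd.DataFrame  # locus_id, cls, start, end, strand, mature_start, mature_end, seq, mature_arm
    mature_seqs: dict[str, str]        # known mature miRNAs
    precursor_seqs: dict[str, str]
    novel_mature: dict[str, str]       # planted novel hairpin mature arms
    opposite_ids: list[str]            # precursors whose other arm is expressed
    antisense_ids: list[str]           # known loci with antisense reads
    decoy_entries: dict[str, tuple[str, str]]  # decoy id -> (db class, sequence)
    abundances: pd.DataFrame | None = None     # true per-sample source fractions
    true_counts: pd.DataFrame | None = None    # realized per-source clone counts
    sample_sheet: pd.DataFrame | None = None
    highrisk_samples: list[str] = field(default_factory=list)
    survival_params: dict = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int, p=None) -> str:
    if p is None:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# mature miRNA base composition: GC-enriched so planted precursor stems are
# strongly paired and reliably dominate the fold of their genomic window
_MATURE_P = [0.10, 0.40, 0.40, 0.10]  # A, C, G, T


def _build_precursor(rng: np.random.Generator, mature: str, loop_len: int, n_mm: int, mature_arm: str) -> str:
    """Hairpin precursor: mature arm + loop + mismatched reverse complement."""
    other = list(revcomp(mature))
    if n_mm:
        # one adjacent block near the arm's 5' end: a single small internal
        # loop, leaving a long contiguous paired run on both arms (needed
        # for the 15-nt conservation window)
        for p in range(3, 3 + n_mm):
            other[p] = _MISMATCH[other[p]]
    other_arm = "".join(other)
    # poly-A terminal loop: cannot pair with the GC-rich arms, so the
    # planted stem is the unique optimum of the pairing surrogate
    loop = "A" * loop_len
    if mature_arm == "5p":
        return mature + loop + other_arm
    return other_arm + loop + mature

DECOY_CLASSES = ["tRNA", "rRNA", "snRNA", "snoRNA", "piRNA"]
_DECOY_LEN = {"tRNA": 73, "rRNA": 120, "snRNA": 100, "snoRNA": 80}


def generate_reference(config: SimConfig) -> SimTruth:
    """Build genome, reference databases, conservation track and truth loci."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mature_seqs: dict[str, str] = {}
    precursor_seqs: dict[str, str] = {}
    mature_arms: dict[str, str] = {}
    edit_pos = {r.mirna_id: r for r in config.editing_spec}
    for i in range(config.n_known_mirnas):
        mid = f"mir-{i + 1:02d}"
        mature = list(_rand_seq(rng, config.mature_length, _MATURE_P))
        if mid in edit_pos:
            mature[edit_pos[mid].position - 1] = edit_pos[mid].from_base
        mature = "".join(mature)
        arm = "5p" if rng.random() < 0.5 else "3p"
        mature_seqs[mid] = mature
        mature_arms[mid] = arm
        precursor_seqs[mid] = _build_precursor(rng, mature, config.loop_length, config.arm_mismatches, arm)

    novel_mature: dict[str, str] = {}
    novel_precursor: dict[str, str] = {}
    novel_arms: dict[str, str] = {}
    for i in range(config.n_novel_hairpins):
        nid = f"novel-{i + 1:02d}"
        mature = _rand_seq(rng, config.mature_length, _MATURE_P)
        arm = "5p" if rng.random() < 0.5 else "3p"
        novel_mature[nid] = mature
        novel_arms[nid] = arm
        novel_precursor[nid] = _build_precursor(rng, mature, config.loop_length, config.arm_mismatches, arm)

    decoy_entries: dict[str, tuple[str, str]] = {}
    for i in range(config.n_decoys):
        cls = DECOY_CLASSES[i % len(DECOY_CLASSES)]
        if cls == "piRNA":
            n = int(rng.integers(26, 32))
        else:
            n = _DECOY_LEN[cls]
        decoy_entries[f"{cls.lower()}-{i + 1:02d}"] = (cls, _rand_seq(rng, n))

    planted = (
        [(mid, "known-precursor", precursor_seqs[mid]) for mid in precursor_seqs]
        + [(nid, "novel-hairpin", novel_precursor[nid]) for nid in novel_precursor]
        + [(did, f"decoy-{cls}", seq) for did, (cls, seq) in decoy_entries.items()]
    )
    spacing = 300
    need = sum(len(s) for _, _, s in planted) + spacing * (len(planted) + 1)
    if need > config.genome_length:
        raise ValueError(
            f"infeasible config: planted loci need {need} nt but genome_length is {config.genome_length}"
        )

    genome = list(_rand_seq(rng, config.genome_length))
    slack = config.genome_length - sum(len(s) for _, _, s in planted)
    gaps = rng.dirichlet(np.ones(len(planted) + 1)) * (slack - spacing * (len(planted) + 1))
    rows = []
    pos = 0
    cons = rng.normal(0.2, 0.05, size=config.genome_length)
    for k, (lid, cls, seq) in enumerate(planted):
        pos += spacing + int(gaps[k])
        start, end = pos, pos + len(seq)
        genome[start:end] = list(seq)
        base = {"known-precursor": 0.9, "novel-hairpin": 0.95}.get(cls, 0.2)
        cons[start:end] = rng.normal(base, 0.05, size=end - start)
        if cls == "known-precursor":
            arm = mature_arms[lid]
        elif cls == "novel-hairpin":
            arm = novel_arms[lid]
        else:
            arm = ""
        if arm == "5p":
            ms, me = start, start + config.mature_length
        elif arm == "3p":
            ms, me = end - config.mature_length, end
        else:
            ms, me = start, end
        rows.append(dict(locus_id=lid, cls=cls, start=start, end=end, strand="+",
                         mature_start=ms, mature_end=me, seq=seq, mature_arm=arm))
        pos = end
    known_ids = sorted(mature_seqs)
    antisense_set = set(known_ids[config.n_opposite : config.n_opposite + config.n_antisense])

    # verify-and-redraw: every planted hairpin that downstream discovery
    # will fold (novel loci on the plus strand; antisense targets on the
    # minus strand of their mature locus) must pass the structural screen
    # and, for novel loci, the stem-conservation test, in its actual
    # genomic context.  Shift-degenerate arms (near-repeats) that confuse
    # the pairing surrogate are redrawn on the spot.
    from . import hairpin as hp

    def _locus_ok(row, strand: str, need_conservation: bool) -> bool:
        g = "".join(genome)
        scan = hp.window_scan(g, row["mature_start"], row["mature_end"], strand=strand)
        rep = hp.evaluate_criteria(scan.fold, scan.mature_span)
        if not rep.structure_pass:
            return False
        if need_conservation:
            ok, _, _ = hp.stem_conservation(scan.fold, np.clip(cons, 0, 1),
                                            mature_span=scan.mature_span)
            return ok
        return True

    for row in rows:
        lid, cls = row["locus_id"], row["cls"]
        if cls == "novel-hairpin":
            strand, need_cons = "+", True
        elif cls == "known-precursor" and lid in antisense_set:
            strand, need_cons = "-", False
        else:
            continue
        for attempt in range(40):
            if _locus_ok(row, strand, need_cons):
                break
            mature = list(_rand_seq(rng, config.mature_length, _MATURE_P))
            if lid in edit_pos:
                mature[edit_pos[lid].position - 1] = edit_pos[lid].from_base
            mature = "".join(mature)
            arm = row["mature_arm"]
            pre = _build_precursor(rng, mature, config.loop_length, config.arm_mismatches, arm)
            genome[row["start"] : row["end"]] = list(pre)
            row["seq"] = pre
            if cls == "novel-hairpin":
                novel_mature[lid] = mature
            else:
                mature_seqs[lid] = mature
                precursor_seqs[lid] = pre
        else:
            raise RuntimeError(f"could not plant a recoverable hairpin at {lid}")

    cons = np.clip(cons, 0.0, 1.0)
    genome = "".join(genome)

    loci = pd.DataFrame(rows)
    # mature sub-loci of known precursors as their own annotation rows
    mat_rows = []
    for _, r in loci[loci.cls == "known-precursor"].iterrows():
        mat_rows.append(dict(locus_id=r.locus_id + "-mature", cls="known-mature",
                             start=r.mature_start, end=r.mature_end, strand="+",
                             mature_start=r.mature_start, mature_end=r.mature_end,
                             seq=mature_seqs[r.locus_id], mature_arm=r.mature_arm))
    loci = pd.concat([loci, pd.DataFrame(mat_rows)], ignore_index=True)

    opposite_ids = known_ids[: config.n_opposite]
    antisense_ids = sorted(antisense_set)

    return SimTruth(
        genome=genome,
        conservation=cons,
        loci=loci,
        mature_seqs=mature_seqs,
        precursor_seqs=precursor_seqs,
        novel_mature=novel_mature,
        opposite_ids=opposite_ids,
        antisense_ids=antisense_ids,
        decoy_entries=decoy_entries,
    )


def write_reference(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(outdir / "genome.fa", [(CHROM, truth.genome)])
    io.write_fasta(outdir / "mature.fa", sorted(truth.mature_seqs.items()))
    io.write_fasta(outdir / "precursor.fa", sorted(truth.precursor_seqs.items()))
    for cls in DECOY_CLASSES:
        entries = sorted((did, s) for did, (c, s) in truth.decoy_entries.items() if c == cls)
        io.write_fasta(outdir / f"{cls}.fa", entries)
    io.write_track(outdir / "conservation.tsv", truth.conservation)
    bed = truth.loci.assign(chrom=CHROM, name=truth.loci.locus_id, score=0)[
        ["chrom", "start", "end", "name", "score", "strand"]
    ].assign(score=0)
    io.write_bed(outdir / "loci.bed", bed)
    extra = truth.loci[["locus_id", "cls", "start", "end", "strand", "mature_start", "mature_end", "mature_arm"]]
    io.write_tsv(outdir / "loci.tsv", extra)


def _other_arm_seq(truth: SimTruth, mid: str) -> str:
    """Sequence of the precursor arm opposite the mature miRNA."""
    pre = truth.precursor_seqs[mid]
    n = len(truth.mature_seqs[mid])
    row = truth.loci[(truth.loci.locus_id == mid)].iloc[0]
    if row.mature_arm == "5p":
        return pre[-n:]
    return pre[:n]


def _sources(truth: SimTruth, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Base (pre-fold-change) source table: id, kind, sequence drawn from, weight."""
    rows = []
    known = sorted(truth.mature_seqs)
    w = rng.lognormal(0.0, 1.0, size=len(known))
    w = w / w.sum()
    base = dict(zip(known, w * config.frac_mirna))
    # force marker and down-regulated miRNA to realistic liver-scale shares
    reserved = config.marker_base_abundance + config.downreg_base_abundance
    others = [k for k in known if k not in (config.marker_id, "mir-02")]
    rest = config.frac_mirna - reserved
    ow = np.array([base[k] for k in others])
    ow = ow / ow.sum() * rest
    base = dict(zip(others, ow))
    base[config.marker_id] = config.marker_base_abundance
    base["mir-02"] = config.downreg_base_abundance
    for mid in known:
        rows.append(dict(source_id=mid, kind="mirna", seq=truth.mature_seqs[mid], weight=base[mid]))
    for nid, seq in sorted(truth.novel_mature.items()):
        rows.append(dict(source_id=nid, kind="novel", seq=seq, weight=config.frac_novel / len(truth.novel_mature)))
    for mid in truth.opposite_ids:
        rows.append(dict(source_id=f"{mid}-opp", kind="opposite", seq=_other_arm_seq(truth, mid),
                         weight=config.frac_opposite / len(truth.opposite_ids)))
    for mid in truth.antisense_ids:
        rows.append(dict(source_id=f"{mid}-as", kind="antisense", seq=revcomp(truth.mature_seqs[mid]),
                         weight=config.frac_antisense / len(truth.antisense_ids)))
    for did, (cls, seq) in sorted(truth.decoy_entries.items()):
        wt = 0.1 if cls == "piRNA" else 1.0  # piRNA fragments rare in the 18-24 nt cut
        rows.append(dict(source_id=did, kind=f"decoy-{cls}", seq=seq, weight=wt))
    df = pd.DataFrame(rows)
    dmask = df.kind.str.startswith("decoy")
    if dmask.any():
        df.loc[dmask, "weight"] = df.loc[dmask, "weight"] / df.loc[dmask, "weight"].sum() * config.frac_decoy
    df["weight"] /= df["weight"].sum()
    return df


def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:02d}"
        rows.append(dict(sample_id=f"{pid}T", group="HCC", pair_id=pid))
        rows.append(dict(sample_id=f"{pid}N", group="ANL", pair_id=pid))
    return pd.DataFrame(rows)


def simulate_reads(truth: SimTruth, config: SimConfig):
    """Per-sample read libraries: list of (read_id, seq, attrs) + sample sheet.

    Reads are 18-24 nt after 3' trimming; editing is applied at the
    configured per-group rates before trimming; each base then suffers a
    uniform substitution error at ``seq_error_rate``.  Identical
    (sample, sequence) reads are collapsed into one record with a clone
    ``count`` attribute.
    """
    config.validate()
    rng = np.random.default_rng((config.seed + 1) % 2**31)
    sheet = make_sample_sheet(config)
    src = _sources(truth, config, rng)
    fold_changes = dict(config.fold_change_spec)
    highrisk = assign_highrisk(sheet, config)
    rules = {r.mirna_id: r for r in config.editing_spec}

    trims = np.array(sorted(config.trim3_probs))
    trim_p = np.array([config.trim3_probs[t] for t in trims])

    records = []
    abund_rows = {}
    count_rows = {}
    rid_counter = 0
    for _, samp in sheet.iterrows():
        w = src.weight.to_numpy().copy()
        if samp.group == "HCC":
            for sid, lfc in fold_changes.items():
                w[src.source_id == sid] *= 2.0 ** lfc
            if samp.sample_id in highrisk:
                w[src.source_id == config.marker_id] *= config.highrisk_marker_boost
                for sid, lfc in config.highrisk_signature:
                    w[src.source_id == sid] *= 2.0 ** lfc
        if config.expr_sigma > 0:
            w = w * 2.0 ** rng.normal(0.0, config.expr_sigma, size=w.size)
        w = w / w.sum()
        abund_rows[samp.sample_id] = w
        counts = rng.multinomial(config.library_size, w)
        count_rows[samp.sample_id] = counts
        collapsed: dict[str, int] = {}
        for (si, row), c in zip(src.iterrows(), counts):
            if c == 0:
                continue
            seq = row.seq
            kind = row.kind
            edited = np.zeros(c, dtype=bool)
            rule = rules.get(row.source_id) if kind == "mirna" else None
            if rule is not None:
                edited = rng.random(c) < rule.rate(samp.group)
            if kind.startswith("decoy"):
                lens = rng.integers(18, min(25, len(seq) + 1), size=c)
                starts = np.array([rng.integers(0, len(seq) - L + 1) for L in lens])
                base_reads = [seq[s : s + L] for s, L in zip(starts, lens)]
            else:
                tr = rng.choice(trims, size=c, p=trim_p)
                base_reads = []
                for k in range(c):
                    r = seq[: len(seq) - int(tr[k])]
                    if edited[k] and rule.position <= len(r):
                        r = r[: rule.position - 1] + rule.to_base + r[rule.position :]
                    base_reads.append(r)
            for r in base_reads:
                if config.seq_error_rate > 0:
                    nerr = rng.binomial(len(r), config.seq_error_rate)
                    if nerr:
                        rl = list(r)
                        for p in rng.choice(len(r), size=nerr, replace=False):
                            rl[p] = "ACGT"[(("ACGT".index(rl[p])) + int(rng.integers(1, 4))) % 4]
                        r = "".join(rl)
                collapsed[r] = collapsed.get(r, 0) + 1
        for seq, cnt in sorted(collapsed.items()):
            rid_counter += 1
            records.append((f"r{rid_counter:07d}", seq, dict(sample=samp.sample_id, count=cnt)))

    truth.sample_sheet = sheet
    truth.highrisk_samples = highrisk
    truth.abundances = pd.DataFrame(abund_rows, index=src.source_id)
    truth.true_counts = pd.DataFrame(count_rows, index=src.source_id)
    return records, sheet


def write_reads(records, sheet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(outdir / "reads.fa", [(rid, seq) for rid, seq, _ in records],
                   attrs=[a for _, _, a in records])
    io.write_tsv(outdir / "samples.tsv", sheet)


COVARIATES = ["capsule_invasion", "portal_invasion", "septum", "serosa", "metastasis"]


def assign_highrisk(sheet: pd.DataFrame, config: SimConfig) -> list[str]:
    """Draw the tumor samples belonging to the planted high-risk cluster.

    Uses a dedicated seed stream so the labels are identical whether or not
    reads are simulated.
    """
    rng = np.random.default_rng((config.seed + 3) % 2**31)
    hr_pairs = sorted(rng.choice(sheet.pair_id.unique(), size=config.n_highrisk, replace=False).tolist())
    return [p + "T" for p in hr_pairs]


def simulate_clinical(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Recurrence outcomes for tumor samples.

    Times are exponential with the baseline hazard multiplied by
    ``hazard_ratio`` for samples in the planted high-risk cluster.
    Censoring is independent and exponential, tuned so the expected
    censored fraction equals ``censor_rate``.  Binary pathological
    covariates are drawn independently of the cluster.
    """
    if truth.sample_sheet is None:
        raise ValueError("simulate_reads must run first (cluster labels undefined)")
    return _clinical(truth.sample_sheet, truth.highrisk_samples, config, truth)


def simulate_clinical_only(config: SimConfig) -> tuple[pd.DataFrame, list[str]]:
    """Clinical outcomes without read simulation (sheet + high-risk labels only)."""
    sheet = make_sample_sheet(config)
    highrisk = assign_highrisk(sheet, config)
    return _clinical(sheet, highrisk, config, None), highrisk


def _clinical(sheet: pd.DataFrame, highrisk: list[str], config: SimConfig,
              truth: SimTruth | None) -> pd.DataFrame:
    rng = np.random.default_rng((config.seed + 2) % 2**31)
    tumors = sheet[sheet.group == "HCC"]
    rows = []
    for _, s in tumors.iterrows():
        lam = config.baseline_hazard * (config.hazard_ratio if s.sample_id in highrisk else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if config.censor_rate > 0:
            mu = lam * config.censor_rate / (1.0 - config.censor_rate)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.inf
        time = min(t_event, t_cens)
        row = dict(sample_id=s.sample_id, time_months=round(float(time), 3),
                   event=int(t_event <= t_cens),
                   highrisk_true=int(s.sample_id in highrisk),
                   age=int(rng.integers(45, 76)))
        for cv in COVARIATES:
            row[cv] = int(rng.random() < 0.4)
        rows.append(row)
    df = pd.DataFrame(rows)
    if truth is not None:
        truth.survival_params = dict(baseline_hazard=config.baseline_hazard,
                                     hazard_ratio=config.hazard_ratio,
                                     censor_rate=config.censor_rate)
    return df


def simulate_study(config: SimConfig, outdir: str | Path | None = None):
    """Full study: reference + reads + clinical; optionally written to disk."""
    truth = generate_reference(config)
    records, sheet = simulate_reads(truth, config)
    clinical = simulate_clinical(truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        write_reference(truth, outdir)
        write_reads(records, sheet, outdir)
        io.write_tsv(outdir / "clinical.tsv", clinical)
        io.dump_yaml(outdir / "config.yaml", config_to_dict(config))
    return truth, records, clinical


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["editing_spec"] = [asdict(r) for r in config.editing_spec]
    d["fold_change_spec"] = [list(t) for t in config.fold_change_spec]
    d["highrisk_signature"] = [list(t) for t in config.highrisk_signature]
    d["trim3_probs"] = {int(k): float(v) for k, v in config.trim3_probs.items()}
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "editing_spec" in d:
        d["editing_spec"] = [EditingRule(**r) for r in d["editing_spec"]]
    if "fold_change_spec" in d:
        d["fold_change_spec"] = [tuple(t) for t in d["fold_change_spec"]]
    if "highrisk_signature" in d:
        d["highrisk_signature"] = [tuple(t) for t in d["highrisk_signature"]]
    if "trim3_probs" in d:
        d["trim3_probs"] = {int(k): float(v) for k, v in d["trim3_probs"].items()}
    return SimConfig(**d)
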