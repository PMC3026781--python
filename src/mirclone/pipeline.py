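"""Stage orchestration: simulate -> annotate -> discover -> edit -> stats -> clinical.

Each stage reads its inputs from and writes its artifacts to a run
directory, so stages are idempotent given identical inputs and config, and
any stage can be re-run in isolation.  The resolved configuration is
written beside the outputs of every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotate import Annotator, annotations_to_frame, count_and_normalize, reads_from_fasta
from .clinical import cox_fit, km_by_group, logrank, roc
from .discover import discover
from .editing import profile_all
from .hairpin import CriteriaThresholds
from .stats import cluster, paired_t, prevalence_filter, sam_test
from .synth import SimConfig, config_from_dict, config_to_dict, simulate_study

logger = logging.getLogger(__name__)

STAGES = ["simulate", "annotate", "discover", "edit", "stats", "clinical"]


@dataclass
class RunConfig:
    """Resolved pipeline parameters; defaults are the published thresholds."""

    seed: int = 0
    min_identity: float = 0.90
    max_overhang: int = 3
    fold_window: int = 110
    context: int = 88
    window_step: int = 5
    conservation_window: int = 15
    conservation_cutoff: float = 0.8
    min_mature_paired: int = 16
    max_terminal_loop: int = 20
    max_internal_loop: int = 10
    max_bulge: int = 5
    min_candidate_reads: int = 2
    editing_min_reads: int = 10
    editing_report_threshold: float = 0.05
    prevalence: float = 0.25
    marker: str = "mir-01"
    marker_threshold: float = 250.0
    n_clusters: int = 3
    sam_n_perm: int = 1000
    sim: SimConfig = field(default_factory=SimConfig)

    def thresholds(self) -> CriteriaThresholds:
        return CriteriaThresholds(self.min_mature_paired, self.max_terminal_loop,
                                  self.max_internal_loop, self.max_bulge)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = config_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = config_from_dict(d["sim"])
        return cls(**d)


class MissingArtifact(FileNotFoundError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifact(f"missing {path.name}: run the '{stage}' stage first")
    return path


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    cfg.sim.seed = cfg.seed if cfg.sim.seed == 0 else cfg.sim.seed
    simulate_study(cfg.sim, outdir)
    logger.info("simulate: wrote reference, reads and clinical tables to %s", outdir)


def stage_annotate(cfg: RunConfig, outdir: Path) -> None:
    genome = io.read_fasta(_require(outdir / "genome.fa", "simulate"))
    genome = next(iter(genome.values()))
    dbs = {"miRNA": io.read_fasta(_require(outdir / "mature.fa", "simulate"))}
    for cls in ["piRNA", "rRNA", "snRNA", "snoRNA"]:
        p = outdir / f"{cls}.fa"
        if p.exists():
            dbs[cls] = io.read_fasta(p)
    reads = reads_from_fasta(io.read_fasta_attrs(_require(outdir / "reads.fa", "simulate")))
    ann = Annotator(dbs, genome, cfg.min_identity, cfg.max_overhang)
    frame = annotations_to_frame(reads, ann.classify_reads(reads))
    io.write_tsv(outdir / "annotations.tsv", frame)
    logger.info("annotate: %d read records, %d clones", len(frame), frame["count"].sum())


def stage_discover(cfg: RunConfig, outdir: Path) -> None:
    frame = io.read_tsv(_require(outdir / "annotations.tsv", "annotate"))
    genome = next(iter(io.read_fasta(_require(outdir / "genome.fa", "simulate")).values()))
    track = io.read_track(_require(outdir / "conservation.tsv", "simulate"))
    loci = io.read_tsv(_require(outdir / "loci.tsv", "simulate"))
    known = loci[loci.cls.isin(["known-precursor", "known-mature"])]
    calls = discover(frame, known, genome, track,
                     min_reads=cfg.min_candidate_reads, thresholds=cfg.thresholds(),
                     conservation_window=cfg.conservation_window,
                     conservation_cutoff=cfg.conservation_cutoff,
                     fold_window=cfg.fold_window, context=cfg.context, step=cfg.window_step)
    io.write_tsv(outdir / "candidates.tsv", calls)
    if not calls.empty:
        novel = calls[calls.call == "novel"]
        io.write_fasta(outdir / "novel_mature.fa",
                       [(f"novel-cand-{i + 1:02d}", r.sequence) for i, r in enumerate(novel.itertuples())],
                       attrs=[dict(clone_count=r.clone_count, call=r.call) for r in novel.itertuples()])
    logger.info("discover: %d candidate groups", len(calls))


def stage_edit(cfg: RunConfig, outdir: Path) -> None:
    frame = io.read_tsv(_require(outdir / "annotations.tsv", "annotate"))
    mature = io.read_fasta(_require(outdir / "mature.fa", "simulate"))
    sheet = io.read_tsv(_require(outdir / "samples.tsv", "simulate"))
    groups = dict(zip(sheet.sample_id, sheet.group))
    sites, modified = profile_all(frame, mature, groups,
                                  min_reads=cfg.editing_min_reads,
                                  report_threshold=cfg.editing_report_threshold)
    io.write_tsv(outdir / "modification_sites.tsv", sites)
    pd.Series(sorted(modified), name="read_id").to_csv(outdir / "modified_reads.tsv",
                                                       sep="\t", index=False)
    norm, comp = count_and_normalize(frame, modified)
    io.write_tsv(outdir / "expression.tsv", norm.reset_index())
    io.write_tsv(outdir / "composition.tsv", comp.reset_index())
    logger.info("edit: %d reported sites, %d modified reads", len(sites), len(modified))


def _load_expression(outdir: Path) -> pd.DataFrame:
    df = io.read_tsv(_require(outdir / "expression.tsv", "edit"))
    return df.set_index(["mirna", "form"])


def stage_stats(cfg: RunConfig, outdir: Path) -> None:
    norm = _load_expression(outdir)
    sheet = io.read_tsv(_require(outdir / "samples.tsv", "simulate"))
    groups = dict(zip(sheet.sample_id, sheet.group))
    pairs = dict(zip(sheet.sample_id, sheet.pair_id))

    forms = norm.drop("total", level="form")
    filt = prevalence_filter(forms, cfg.prevalence)
    res = cluster(filt, groups, marker=cfg.marker, marker_threshold=cfg.marker_threshold,
                  k=cfg.n_clusters)
    io.write_tsv(outdir / "linkage.tsv", pd.DataFrame(res.linkage,
                 columns=["left", "right", "height", "size"]))
    lab = res.labels.rename("cluster").rename_axis("sample_id").reset_index()
    lab["high_risk"] = lab.sample_id.isin(res.high_risk_samples).astype(int)
    io.write_tsv(outdir / "clusters.tsv", lab)

    totals = norm.xs("total", level="form")
    filt_tot = prevalence_filter(totals, cfg.prevalence)
    sam = sam_test(filt_tot, groups, pairs, paired=True, n_perm=cfg.sam_n_perm, seed=cfg.seed)
    out = sam.table.copy()
    out.insert(0, "mirna", out.index)
    io.write_tsv(outdir / "sam.tsv", out)
    tt = paired_t(filt_tot, groups, pairs)
    tt.insert(0, "mirna", tt.index)
    io.write_tsv(outdir / "paired_t.tsv", tt)
    logger.info("stats: %d miRNAs after prevalence filter; %d SAM-significant (delta=%.3g)",
                len(filt_tot), len(sam.significant), sam.delta)


def stage_clinical(cfg: RunConfig, outdir: Path) -> None:
    norm = _load_expression(outdir)
    sheet = io.read_tsv(_require(outdir / "samples.tsv", "simulate"))
    clin = io.read_tsv(_require(outdir / "clinical.tsv", "simulate"))
    clusters = io.read_tsv(_require(outdir / "clusters.tsv", "stats"))
    groups = dict(zip(sheet.sample_id, sheet.group))

    totals = norm.xs("total", level="form")
    y = np.array([1 if groups[s] == "HCC" else 0 for s in totals.columns])
    rocs = []
    for mid, orient in [(cfg.marker, True), ("mir-02", False)]:
        if mid in totals.index:
            r = roc(totals.loc[mid].to_numpy(), y, higher_is_positive=orient)
            tab = r.table.assign(mirna=mid, auc=r.auc)
            rocs.append(tab)
    if rocs:
        io.write_tsv(outdir / "roc.tsv", pd.concat(rocs, ignore_index=True))

    clin = clin.merge(clusters, on="sample_id", how="left")
    clin["high_risk"] = clin["high_risk"].fillna(0).astype(int)
    kms = km_by_group(clin.time_months, clin.event, clin.high_risk)
    km_rows = [t.assign(group=g) for g, t in kms.items()]
    io.write_tsv(outdir / "km.tsv", pd.concat(km_rows, ignore_index=True))
    if clin.high_risk.nunique() == 2:
        lr = logrank(clin.time_months, clin.event, clin.high_risk)
        covs = [c for c in clin.columns if c not in
                ("sample_id", "time_months", "event", "cluster", "highrisk_true")]
        X = clin[covs].astype(float)
        X["age"] = (X["age"] - X["age"].mean()) / X["age"].std()
        try:
            cox = cox_fit(X, clin.time_months, clin.event)
            cox_tab = cox.summary.copy()
            cox_tab.insert(0, "covariate", cox_tab.index)
        except (RuntimeError, ValueError) as err:
            logger.warning("Cox fit failed: %s", err)
            cox_tab = pd.DataFrame()
        summary = pd.DataFrame([dict(logrank_chi2=lr.chi2, logrank_p=lr.p,
                                     n_high=int(clin.high_risk.sum()),
                                     n_low=int((1 - clin.high_risk).sum()))])
        io.write_tsv(outdir / "survival_summary.tsv", summary)
        io.write_tsv(outdir / "cox.tsv", cox_tab)
    logger.info("clinical: wrote ROC, KM and model summaries")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "discover": stage_discover,
    "edit": stage_edit,
    "stats": stage_stats,
    "clinical": stage_clinical,
}


def run_pipeline(cfg: RunConfig, outdir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the requested stages in canonical order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    io.dump_yaml(outdir / "run_config.yaml", cfg.to_dict())
    for s in STAGES:
        if s in stages:
            STAGE_FUNCS[s](cfg, outdir)
    return outdir
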