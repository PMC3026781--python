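"""Shared fixtures: the default synthetic study, annotated once per session."""

import pytest

from mirclone.annotate import Annotator, ReadRecord, annotations_to_frame, count_and_normalize
from mirclone.editing import profile_all
from mirclone.synth import SimConfig, simulate_study


def build_annotator(truth, include_decoys=True):
    dbs = {"miRNA": truth.mature_seqs}
    if include_decoys:
        for cls in ["piRNA", "rRNA", "snRNA", "snoRNA", "tRNA"]:
            entries = {did: s for did, (c, s) in truth.decoy_entries.items() if c == cls}
            if entries:
                dbs[cls] = entries
    return Annotator(dbs, truth.genome)


def annotate_records(truth, records, include_decoys=True):
    ann = build_annotator(truth, include_decoys)
    reads = [ReadRecord(rid, seq, a["sample"], int(a["count"])) for rid, seq, a in records]
    return annotations_to_frame(reads, ann.classify_reads(reads))


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, seed 1: (config, truth, read records, clinical)."""
    cfg = SimConfig(seed=1)
    truth, records, clinical = simulate_study(cfg)
    return cfg, truth, records, clinical


@pytest.fixture(scope="session")
def annotation(study):
    _, truth, records, _ = study
    return annotate_records(truth, records)


@pytest.fixture(scope="session")
def expression(study, annotation):
    _, truth, _, _ = study
    groups = dict(zip(truth.sample_sheet.sample_id, truth.sample_sheet.group))
    sites, modified = profile_all(annotation, truth.mature_seqs, groups)
    norm, comp = count_and_normalize(annotation, modified)
    return sites, modified, norm, comp


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale config for pipeline round-trip tests."""
    return SimConfig(
        seed=5, n_pairs=4, n_known_mirnas=10, n_novel_hairpins=2, n_decoys=10,
        n_opposite=3, n_antisense=1, library_size=400, genome_length=40_000,
        n_highrisk=2,
    )
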