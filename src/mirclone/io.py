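"""File-format helpers: FASTA with attribute headers, BED, TSV tracks and sheets.

Read FASTA headers carry clone multiplicity and sample of origin as
``key=value`` attributes, e.g. ``>r0001 sample=S01T count=12``.  All genomic
intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}, uppercased with U mapped to T."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def read_fasta_attrs(path: str | Path) -> list[tuple[str, str, dict[str, str]]]:
    """FASTA -> [(id, sequence, {attr: value})] preserving header attributes."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                attrs[k] = v
        out.append((rec.id, str(rec.seq).upper().replace("U", "T"), attrs))
    return out


def write_fasta(path: str | Path, records: list[tuple[str, str]] | dict[str, str], attrs: list[dict] | None = None) -> None:
    if isinstance(records, dict):
        records = list(records.items())
    with open(path, "w") as fh:
        for i, (rid, seq) in enumerate(records):
            extra = ""
            if attrs is not None:
                extra = " " + " ".join(f"{k}={v}" for k, v in attrs[i].items())
            fh.write(f">{rid}{extra}\n{seq}\n")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)


def write_track(path: str | Path, values) -> None:
    """Per-base conservation track as two-column TSV (0-based pos, score)."""
    pd.DataFrame({"pos": range(len(values)), "score": values}).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_track(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    return df["score"].to_numpy()


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
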