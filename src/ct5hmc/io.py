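"""Tabular I/O: gzip TSV matrices, BED-like annotation, YAML/JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml


def _compression(path: Path):
    # fixed mtime keeps gzip outputs byte-identical across re-runs
    if path.suffix == ".gz":
        return {"method": "gzip", "mtime": 0}
    return "infer"


def write_matrix(mat: pd.DataFrame, path: str | Path) -> Path:
    """Write a probes/genes x samples matrix as (optionally gzipped) TSV."""
    path = Path(path)
    mat.to_csv(path, sep="\t", index_label=mat.index.name or "id",
               compression=_compression(path))
    return path

def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    """BED-like TSV: chrom, start, end, probe_id, then annotation columns."""
    path = Path(path)
    lead = ["chrom", "start", "end"]
    rest = [c for c in ann.columns if c not in lead]
    out = ann[lead + rest].reset_index()
    out = out[lead + [ann.index.name or "probe_id"] + rest]
    out.to_csv(path, sep="\t", index=False)
    return path

def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    id_col = "probe_id" if "probe_id" in ann.columns else ann.columns[3]
    return ann.set_index(id_col)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, compression=_compression(path))
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, set):
            return sorted(o)
        if hasattr(o, "item"):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path
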