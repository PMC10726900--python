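"""Readers/writers for the plain-text interchange formats.

TSV matrices carry features as rows and samples as columns with a header row
of sample IDs; gene sets use GMT (``name<TAB>description<TAB>gene...``);
ground truth and manifests are JSON; run configuration is YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
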