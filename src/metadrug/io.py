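"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices are TSV with genes as rows and samples as columns;
gene sets are GMT; protein interactions are STRING-style TSV with a
``combined_score`` column on the 0-1000 scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "FormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_string_edges",
    "write_string_edges",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_json",
    "write_json",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Raises :class:`FormatError` on duplicated gene ids or non-numeric
    values, naming the offending entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated gene ids: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [gene, ...]}``.

    Each line must carry at least name, description and one member.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_string_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style edge table (protein1, protein2, combined_score).

    Scores must be integers in [0, 1000]; duplicate undirected pairs are
    collapsed keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    scores = df["combined_score"]
    bad = df[(scores < 0) | (scores > 1000)]
    if len(bad):
        raise FormatError(
            f"{path}: combined_score outside [0, 1000] at rows {bad.index.tolist()}"
        )
    # canonical undirected key, keep max score across duplicates
    lo = df[["protein1", "protein2"]].min(axis=1)
    hi = df[["protein1", "protein2"]].max(axis=1)
    out = pd.DataFrame({"protein1": lo, "protein2": hi, "combined_score": scores})
    out = out[out["protein1"] != out["protein2"]]
    out = (
        out.groupby(["protein1", "protein2"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein1", "protein2"])
        .reset_index(drop=True)
    )
    return out


def write_string_edges(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample ids: {dupes}")
    if (df["os_months"] <= 0).any():
        raise FormatError(f"{path}: nonpositive os_months present")
    if not df["os_event"].isin([0, 1]).all():
        raise FormatError(f"{path}: os_event must be 0/1")
    return df


def write_clinical_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
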