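"""Readers and writers for the on-disk dialects the pipeline exchanges.

Matrices travel as TSV with a feature-ID first column and sample columns;
mutations as a MAF-like TSV; copy-number segments as SEG; genesets as GMT;
run configuration as YAML.  Readers validate strictly and reject rather than
coerce malformed input, naming the offending file, row and field.

Coordinates are 0-based half-open internally.  SEG files on disk follow the
common 1-based inclusive convention and are converted on read/write.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrices import (
    CopyNumberMatrix,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    ClusterAssignment,
    ValidationError,
    MUTATION_COLUMNS,
    PROBE_ANNOTATION_COLUMNS,
    SEGMENT_COLUMNS,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_probe_annotation",
    "read_mutations",
    "write_mutations",
    "read_segments",
    "write_segments",
    "read_genesets",
    "write_genesets",
    "read_config",
    "write_config",
    "write_assignment",
    "write_manifest",
]

_MATRIX_KINDS = ("expression", "methylation", "copy_number")


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate sample column {sorted(dupes)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValidationError(f"{path}: duplicate feature ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique()[0]
        raise ValidationError(f"{path}: duplicate sample column {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric cell in sample column {col!r}"
                f" at feature {bad.index[0]!r}"
            )
    return df


def read_matrix(path, kind: str, annotation_path=None):
    """Read a feature x sample TSV as the requested matrix type.

    Parameters
    ----------
    kind
        One of ``expression``, ``methylation``, ``copy_number``.
    annotation_path
        Probe annotation TSV, required for methylation matrices.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {_MATRIX_KINDS}")
    df = _read_tsv_matrix(path)
    if kind == "expression":
        return ExpressionMatrix(df)
    if kind == "copy_number":
        return CopyNumberMatrix(df)
    if annotation_path is None:
        raise ValueError("methylation matrices require annotation_path")
    ann = read_probe_annotation(annotation_path)
    try:
        return MethylationMatrix(df, ann)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_matrix(matrix, path, annotation_path=None) -> None:
    """Write a matrix container back to TSV (round-trips with read_matrix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(matrix, ExpressionMatrix):
        df, label = matrix.values, "gene"
    elif isinstance(matrix, MethylationMatrix):
        df, label = matrix.betas, "probe"
        if annotation_path is not None:
            matrix.probe_annotation.rename_axis("probe").to_csv(annotation_path, sep="\t")
    elif isinstance(matrix, CopyNumberMatrix):
        df, label = matrix.values, "locus"
    else:
        raise TypeError(f"cannot write {type(matrix).__name__}")
    df.rename_axis(label).to_csv(path, sep="\t")


def read_probe_annotation(path) -> pd.DataFrame:
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"{path}: probe annotation missing columns {missing}")
    ann["promoter"] = ann["promoter"].astype(bool)
    return ann


def read_mutations(path) -> MutationTable:
    """Read a MAF-like TSV of somatic mutations."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: mutation table missing columns {missing}")
    try:
        return MutationTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_mutations(table: MutationTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.records.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive on disk -> 0-based half-open)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    rename = {df.columns[i]: c for i, c in enumerate(SEGMENT_COLUMNS) if i < len(df.columns)}
    df = df.rename(columns=rename)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: SEG file missing columns {missing}")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(
            f"{path}: segment with start >= end at row {bad.index[0]}"
        )
    return df


def write_segments(segments: pd.DataFrame, path) -> None:
    out = segments.copy()
    out["start"] = out["start"].astype(int) + 1
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_genesets(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line (name, description, members...).

    Duplicate members within a set are dropped with a warning; member order
    is preserved.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected name, description, members")
            name = parts[0].strip()
            if not name:
                raise ValidationError(f"{path}:{lineno}: blank geneset name")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate geneset name {name!r}")
            members, seen = [], set()
            for g in parts[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate member {g!r} in set {name!r}")
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    return sets


def write_genesets(sets: dict[str, list[str]], path, descriptions=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_assignment(path) -> ClusterAssignment:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "platform", "cluster", "robustness") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: assignment missing columns {missing}")
    labels = pd.Series(df["cluster"].to_numpy(), index=df["sample"])
    return ClusterAssignment(
        platform=str(df["platform"].iloc[0]),
        labels=labels,
        robustness=pd.Series(df["robustness"].to_numpy(), index=df["sample"]),
        k=int(labels.max()),
    )


def write_assignment(assignment: ClusterAssignment, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(run_dir, entries: dict, path_name: str = "manifest.json") -> Path:
    """Write the run manifest listing every produced file with provenance."""
    run_dir = Path(run_dir)
    out = run_dir / path_name
    with open(out, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
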