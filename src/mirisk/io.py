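"""Readers and writers for the on-disk formats.

Expression matrices and clinical tables travel as TSV (features in rows
for expression, one sample per row for clinical), gene sets as GMT,
validated miRNA->target pairs as two-column TSV, and fitted models as
JSON with an explicit schema version. Every reader/writer pair is an
exact round trip on valid files.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    ValidatedPair,
    CLINICAL_COLUMNS,
)
from .risk import SignatureModel

log = logging.getLogger(__name__)


def read_expression(path: str | Path, kind: str = "normalized", transpose: bool = False) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids). ``transpose=True`` accepts samples-in-rows files."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate column ids in {path}: {dups[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise FormatError(f"non-numeric expression columns: {list(non_numeric)[:5]}")
    return ExpressionMatrix(df, kind=kind)


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    df = X.values
    if X.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical TSV (sample_id, os_days, os_event,
    sample_type, stage, age, sex, batch, treatment; NA allowed)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse clinical TSV {path}: {exc}") from exc
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.loc[:, list(CLINICAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[ValidatedPair]:
    """Read validated miRNA->gene pairs (two-column TSV, header optional).
    Duplicate rows are dropped with a log entry."""
    pairs: list[ValidatedPair] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{i + 1}: expected 2 tab-separated fields")
            a, b = fields[0].strip(), fields[1].strip()
            if i == 0 and {a.lower(), b.lower()} & {"mirna_id", "mirna", "gene_id", "gene"}:
                continue  # header row
            key = (a, b)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append(ValidatedPair(a, b))
    if n_dup:
        log.info("dropped %d duplicate pair rows from %s", n_dup, path)
    return pairs


def write_pairs(pairs: list[ValidatedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.gene_id}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, member genes per line).
    Empty sets are dropped with a warning; duplicate names are an error."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_empty = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{i + 1}: GMT lines need >= 3 fields (name, description, genes)"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
            if name in sets:
                raise FormatError(f"{path}:{i + 1}: duplicate gene-set name {name!r}")
            if not genes:
                n_empty += 1
                continue
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    if n_empty:
        log.warning("dropped %d empty gene sets from %s", n_empty, path)
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def save_model(model: SignatureModel, path: str | Path) -> None:
    """Serialize a fitted model as schema-versioned JSON (full precision)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> SignatureModel:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse model JSON {path}: {exc}") from exc
    return SignatureModel.from_dict(d)


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
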