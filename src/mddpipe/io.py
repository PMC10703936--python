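"""Readers and writers for the plain-text formats used across the pipeline.

Counts and metadata travel as TSV, gene sets as GMT (name, description,
tab-separated members), ground truth and reports as JSON.  Gene and sample
identifiers are opaque strings throughout.
"""

from __future__ import annotations

import json
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (a GMT file in memory).

    Membership order within a set is preserved as given but has no
    semantic meaning; sets may overlap.
    """

    sets: "OrderedDict[str, list[str]]" = field(default_factory=OrderedDict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        genes = list(genes)
        seen: set[str] = set()
        deduped = [g for g in genes if not (g in seen or seen.add(g))]
        if len(deduped) < len(genes):
            warnings.warn(f"gene set {name!r}: duplicate members removed")
        self.sets[name] = deduped
        self.descriptions[name] = description

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        out = GeneSetCollection()
        for n in names:
            out.add(n, self.sets[n], self.descriptions.get(n, ""))
        return out

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(self, path)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix.

    First column holds gene ids, header row holds sample ids.  Validates
    uniqueness, integrality and non-negativity.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = df.index.get_loc(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, line {line}")
    values = df.to_numpy()
    if np.any(values < 0):
        raise ValueError(f"{path}: negative count")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer count")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (index: sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Empty sets are dropped with a warning; duplicate set names are an error.
    """
    coll = GeneSetCollection()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>description")
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"{path}:{lineno}: empty gene set {name!r} dropped")
                continue
            if name in coll:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            coll.add(name, genes, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
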