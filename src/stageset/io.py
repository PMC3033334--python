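"""Readers and writers for the tabular artifacts of the pipeline.

All files are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  Identifiers are opaque, case-sensitive strings — no symbol
normalisation is ever attempted (ortholog/symbol translation is an explicit
:class:`PairTable` input).  Matrices admit no missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSheet",
    "ExpressionMatrix",
    "GeneSetCollection",
    "PairTable",
    "FormatError",
    "read_sample_sheet",
    "read_expression_matrix",
    "read_gene_sets",
    "read_pair_table",
    "write_expression_matrix",
    "write_gene_sets",
    "write_results",
]


class FormatError(ValueError):
    """A file violates the expected dialect or an invariant of its type."""


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: one (condition, replicate) label per sample."""

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.conditions) != n or len(self.replicates) != n:
            raise FormatError("sample sheet columns have unequal lengths")
        if len(set(self.sample_ids)) != n:
            raise FormatError("sample_ids are not unique")
        pairs = list(zip(self.conditions, self.replicates))
        if len(set(pairs)) != n:
            raise FormatError("(condition, replicate) pairs are not unique")
        if any(r < 1 for r in self.replicates):
            raise FormatError("replicate numbers must be positive")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        """Distinct conditions in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return tuple(seen)

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]
        if not out:
            raise KeyError(f"unknown condition label: {condition!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": self.conditions,
                "replicate": self.replicates,
            }
        )


@dataclass
class ExpressionMatrix:
    """Non-negative intensities of features (genes or probes) x samples.

    ``probe_index`` is present iff the matrix is probe-level; then
    ``feature_ids`` repeats the probe-set identifier once per probe and
    every probe set must carry at least ``min_probes`` probes.
    """

    feature_ids: np.ndarray  # dtype=object, shape (n_rows,)
    values: np.ndarray  # float, shape (n_rows, n_samples)
    samples: SampleSheet
    probe_index: np.ndarray | None = None
    min_probes: int = 3

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.feature_ids.size:
            raise FormatError("values shape does not match feature_ids")
        if self.values.shape[1] != len(self.samples.sample_ids):
            raise FormatError("values shape does not match sample sheet")
        if not np.isfinite(self.values).all():
            raise FormatError("intensities must be finite")
        if (self.values < 0).any():
            r, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative intensity at feature {self.feature_ids[r]!r}, "
                f"sample {self.samples.sample_ids[c]!r}"
            )
        if self.probe_index is None:
            if len(set(self.feature_ids)) != self.feature_ids.size:
                raise FormatError("gene-level matrix has duplicate feature_ids")
        else:
            self.probe_index = np.asarray(self.probe_index, dtype=int)
            if self.probe_index.size != self.feature_ids.size:
                raise FormatError("probe_index length mismatch")
            ids, counts = np.unique(self.feature_ids.astype(str), return_counts=True)
            low = counts < self.min_probes
            if low.any():
                raise FormatError(
                    f"probe set {ids[np.argmax(low)]!r} has fewer than "
                    f"{self.min_probes} probes"
                )

    @property
    def is_probe_level(self) -> bool:
        return self.probe_index is not None

    @property
    def gene_ids(self) -> list[str]:
        """Distinct probe-set / gene identifiers in row order."""
        seen: dict[str, None] = {}
        for f in self.feature_ids:
            seen.setdefault(str(f))
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.samples.sample_ids))
        df.insert(0, "feature_id", self.feature_ids)
        if self.probe_index is not None:
            df.insert(1, "probe", self.probe_index)
        return df


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally confined to a universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(map(str, self.universe))
            for name, members in self.sets.items():
                stray = members - self.universe
                if stray:
                    raise FormatError(
                        f"set {name!r} has {len(stray)} members outside the universe"
                    )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class PairTable:
    """Ordered identifier pairs: (ligand, receptor) or (gene, ortholog)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise FormatError("pair table contains duplicate rows")
        for a, b in self.rows:
            if not a or not b:
                raise FormatError("pair table has an empty identifier")

    def mapping(self, reverse: bool = False) -> dict[str, set[str]]:
        """Many-to-many map id_a -> {id_b} (or id_b -> {id_a})."""
        out: dict[str, set[str]] = {}
        for a, b in self.rows:
            k, v = (b, a) if reverse else (a, b)
            out.setdefault(k, set()).add(v)
        return out


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet must have columns {sorted(required)}")
    return SampleSheet(
        sample_ids=tuple(df["sample_id"]),
        conditions=tuple(df["condition"]),
        replicates=tuple(int(r) for r in df["replicate"]),
    )


def read_expression_matrix(
    path: str | Path, sample_sheet_path: str | Path, min_probes: int = 3
) -> ExpressionMatrix:
    """Read a matrix TSV (feature_id [, probe], one column per sample).

    Row order is preserved.  Every sample in the sheet must appear as a
    column; extra columns are an error so silent sample loss is impossible.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2 or df.columns[0] != "feature_id":
        raise FormatError("matrix must start with a 'feature_id' column")
    probe_index = None
    data_cols = list(df.columns[1:])
    if data_cols and data_cols[0] == "probe":
        probe_index = df["probe"].to_numpy(dtype=int)
        data_cols = data_cols[1:]
    missing = [s for s in sheet.sample_ids if s not in data_cols]
    if missing:
        raise FormatError(f"matrix is missing sample column {missing[0]!r}")
    extra = [c for c in data_cols if c not in sheet.sample_ids]
    if extra:
        raise FormatError(f"matrix has column {extra[0]!r} absent from sample sheet")
    try:
        values = df[list(sheet.sample_ids)].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity: {exc}") from exc
    return ExpressionMatrix(
        feature_ids=df["feature_id"].to_numpy(dtype=object),
        values=values,
        samples=sheet,
        probe_index=probe_index,
        min_probes=min_probes,
    )


def read_gene_sets(
    path: str | Path, format: str = "list", universe: frozenset[str] | None = None
) -> GeneSetCollection:
    """Read gene sets: one per file ("list") or one per line ("gmt").

    GMT lines are ``name<TAB>description<TAB>member...``.  Duplicates within
    a set are collapsed with a logged warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty gene-set file: {path}")
    sets: dict[str, frozenset[str]] = {}
    if format == "list":
        ids = [ln.strip() for ln in lines]
        uniq = frozenset(ids)
        if len(uniq) != len(ids):
            logger.warning(
                "%s: %d duplicate IDs collapsed", path.name, len(ids) - len(uniq)
            )
        sets[path.stem] = uniq
    elif format == "gmt":
        for i, ln in enumerate(lines, start=1):
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line has fewer than 3 columns")
            name, members = parts[0], parts[2:]
            uniq = frozenset(members)
            if len(uniq) != len(members):
                logger.warning(
                    "%s: set %r: %d duplicates collapsed",
                    path.name,
                    name,
                    len(members) - len(uniq),
                )
            if name in sets:
                raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
            sets[name] = uniq
    else:
        raise ValueError(f"unknown gene-set format: {format!r}")
    return GeneSetCollection(sets=sets, universe=universe)


def read_pair_table(path: str | Path) -> PairTable:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError("pair table needs two columns")
    rows = tuple((str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False))
    return PairTable(rows=rows)


# ---------------------------------------------------------------------------
# writers


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (members sorted for determinism)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\tna\t{members}\n")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write named result tables as deterministic TSVs.

    Rows are sorted by the leading identifier columns, column order is the
    frame's own; returns a manifest frame (file, rows).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for name in sorted(tables):
        df = tables[name]
        sort_cols = [c for c in ("feature_id", "set_name", "cluster", "category") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, float_format="%.10g")
        records.append({"file": dest.name, "rows": len(df)})
    return pd.DataFrame.from_records(records, columns=["file", "rows"])
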