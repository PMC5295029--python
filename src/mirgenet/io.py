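"""Readers, writers and core containers for expression data.

The on-disk dialects are deliberately plain: tab-separated expression
matrices with one header row/column of identifiers, two-column label
files, GMT gene-set collections and two-column miRNA->gene edge lists.
Everything is parsed through :mod:`pandas`; this module only adds the
validation (duplicate identifiers, non-numeric cells, ragged rows) and
the orientation handling that the downstream statistics rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClassLabels",
    "GeneSetCollection",
    "TargetPredictionSet",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "detection_filter",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"duplicate {what} identifier(s): {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """A samples x features matrix of log2 intensities.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique identifiers for rows (samples) and columns (features).
    values
        ``(n_samples, n_features)`` float array, finite everywhere.
    detected
        Optional boolean array of the same shape carrying per-cell
        detection calls (e.g. array "is gene detected" flags).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    detected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )
        if self.detected is not None:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.values.shape:
                raise FormatError("detected flags must have the same shape as values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, detected: np.ndarray | None = None):
        return cls(
            sample_ids=list(frame.index.astype(str)),
            feature_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            detected=detected,
        )

    # -- subsetting -----------------------------------------------------
    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        """Return a copy restricted to ``feature_ids`` (given order kept)."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        cols = [index[f] for f in feature_ids]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in cols],
            values=self.values[:, cols].copy(),
            detected=None if self.detected is None else self.detected[:, cols].copy(),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        rows = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            feature_ids=list(self.feature_ids),
            values=self.values[rows, :].copy(),
            detected=None if self.detected is None else self.detected[rows, :].copy(),
        )

    def feature_vector(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


@dataclass
class ClassLabels:
    """Per-sample binary outcome labels.

    The two class names are ordered alphabetically; the first one is
    "class0" in every sign convention downstream (a positive log2 fold
    change means higher in class0).
    """

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.labels):
            raise FormatError("sample_ids and labels differ in length")
        classes = sorted(set(self.labels))
        if len(classes) != 2:
            raise FormatError(f"expected exactly two classes, found {classes}")
        self.classes: tuple[str, str] = (classes[0], classes[1])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def indicator(self) -> np.ndarray:
        """Boolean mask per class, shape (2, n_samples), class0 first."""
        arr = np.asarray(self.labels)
        return np.stack([arr == c for c in self.classes])

    def y_index(self) -> np.ndarray:
        """Integer class index per sample (0 = first class)."""
        return np.asarray([self.classes.index(l) for l in self.labels])

    def for_samples(self, sample_ids) -> "ClassLabels":
        mapping = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise KeyError(f"samples without labels: {missing}")
        return ClassLabels(list(sample_ids), [mapping[s] for s in sample_ids])

    def check_matches(self, m: ExpressionMatrix) -> None:
        if list(self.sample_ids) != list(m.sample_ids):
            raise FormatError("label sample_ids do not match the expression matrix")


@dataclass
class GeneSetCollection:
    """Named gene sets with one description per set (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class TargetPredictionSet:
    """Directed miRNA -> gene predictions from one database."""

    database_name: str
    edges: set[tuple[str, str]]

    @classmethod
    def from_pairs(cls, database_name: str, pairs) -> "TargetPredictionSet":
        edges = set()
        n = 0
        for m, g in pairs:
            edges.add((str(m), str(g)))
            n += 1
        if n != len(edges):
            warnings.warn(
                f"database {database_name!r}: {n - len(edges)} duplicate edge(s) dropped"
            )
        return cls(database_name, edges)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path,
    orientation: str = "features_in_rows",
    detected_path=None,
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Parameters
    ----------
    path
        TSV file with one header row and one leading identifier column.
    orientation
        ``"features_in_rows"`` (the common array-export layout) or
        ``"samples_in_rows"``. The returned matrix is always samples x
        features.
    detected_path
        Optional TSV of 0/1 detection flags in the same orientation and
        with identical identifiers.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_tsv_matrix(path)
    if orientation == "features_in_rows":
        frame = frame.T
    detected = None
    if detected_path is not None:
        dframe = _read_tsv_matrix(detected_path)
        if orientation == "features_in_rows":
            dframe = dframe.T
        if list(dframe.index) != list(frame.index) or list(dframe.columns) != list(
            frame.columns
        ):
            raise FormatError("detection flags do not match matrix identifiers")
        detected = dframe.to_numpy() != 0
    return ExpressionMatrix.from_frame(frame, detected=detected)


def _read_tsv_matrix(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc
    if frame.index.has_duplicates:
        dup = sorted(frame.index[frame.index.duplicated()].unique().astype(str))
        raise FormatError(f"{path}: duplicate row identifier(s): {dup}")
    if frame.columns.has_duplicates:
        dup = sorted(frame.columns[frame.columns.duplicated()].unique().astype(str))
        raise FormatError(f"{path}: duplicate column identifier(s): {dup}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} (ragged or empty cell)"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return numeric


def write_expression(
    m: ExpressionMatrix, path, orientation: str = "features_in_rows"
) -> None:
    frame = m.to_frame()
    if orientation == "features_in_rows":
        frame = frame.T
        frame.index.name = "feature_id"
    elif orientation == "samples_in_rows":
        frame.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_detection(m: ExpressionMatrix, path, orientation="features_in_rows") -> None:
    if m.detected is None:
        raise ValueError("matrix carries no detection flags")
    frame = pd.DataFrame(
        m.detected.astype(int), index=m.sample_ids, columns=m.feature_ids
    )
    if orientation == "features_in_rows":
        frame = frame.T
        frame.index.name = "feature_id"
    else:
        frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path) -> ClassLabels:
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (sample_id, label)")
    return ClassLabels(list(frame.iloc[:, 0]), list(frame.iloc[:, 1]))


def write_labels(labels: ClassLabels, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path, database_name: str | None = None) -> TargetPredictionSet:
    """Read a two-column TSV of miRNA -> gene predictions (with header)."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (mirna_id, gene_id)")
    name = database_name if database_name is not None else str(path)
    return TargetPredictionSet.from_pairs(
        name, zip(frame.iloc[:, 0], frame.iloc[:, 1])
    )


def write_edge_list(db: TargetPredictionSet, path) -> None:
    frame = pd.DataFrame(sorted(db.edges), columns=["mirna_id", "gene_id"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def detection_filter(m: ExpressionMatrix, min_fraction: float = 0.10) -> ExpressionMatrix:
    """Keep features detected in at least ``min_fraction`` of samples.

    A feature survives iff its detection count is >= ceil(min_fraction * n),
    so "at least 10%" keeps a feature detected in exactly 4 of 40 samples.
    Feature order is preserved; the operation is idempotent.
    """
    if m.detected is None:
        raise ValueError(
            "matrix has no detection flags; supply them at read time or skip "
            "the detection filter"
        )
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * m.n_samples)
    counts = m.detected.sum(axis=0)
    keep = [f for f, c in zip(m.feature_ids, counts) if c >= threshold]
    return m.subset_features(keep)
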