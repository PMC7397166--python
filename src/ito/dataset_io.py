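"""Expression-matrix I/O and the canonical in-memory dataset container.

Datasets are delimited text matrices (TSV/CSV) with a header row and a
leading identifier column, in either orientation (samples in rows is
canonical). Labels come from a column of the matrix file or from a
two-column sidecar file, and are mapped to {0, 1} with a user-supplied
positive-class token — no guessing. Missing expression values are the
tokens "", "NA", "NaN", "null" (case-insensitive) and are represented as
NaN in memory.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

ORIENTATIONS = ("samples_in_rows", "features_in_rows")

#: fixed row order of the summary TSV written by :func:`write_report`
SUMMARY_ENTITIES = (
    "lig_member_best",
    "ft_member_best",
    "lig_ensemble",
    "ft_ensemble",
    "combined",
    "final",
)


class DatasetError(ValueError):
    """Raised for malformed matrices, labels or identifiers."""


@dataclass(eq=False)
class ExpressionDataset:
    """Samples x features real matrix with binary labels.

    Parameters
    ----------
    matrix
        ``(n_samples, n_features)`` float array; NaN marks a missing value.
    labels
        Per-sample class in ``{0, 1}``, 1 being the positive class.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    """

    matrix: np.ndarray
    labels: np.ndarray
    sample_ids: list
    feature_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.matrix.ndim != 2:
            raise DatasetError("matrix must be 2-dimensional")
        n, f = self.matrix.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DatasetError("labels/sample_ids length must match matrix rows")
        if len(self.feature_ids) != f:
            raise DatasetError("feature_ids length must match matrix columns")
        if not np.isin(self.labels, (0, 1)).all():
            raise DatasetError("labels must contain only 0/1")
        if len(set(self.sample_ids)) != n:
            raise DatasetError("duplicate sample ids")
        if len(set(self.feature_ids)) != f:
            raise DatasetError("duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def feature_index(self, ids) -> np.ndarray:
        """Column positions of ``ids``; error if any is absent."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([pos[str(f)] for f in ids], dtype=int)
        except KeyError as exc:
            raise DatasetError(f"feature {exc.args[0]!r} not present in dataset") from None

    def subset_features(self, ids) -> "ExpressionDataset":
        idx = self.feature_index(ids)
        return ExpressionDataset(
            self.matrix[:, idx].copy(),
            self.labels.copy(),
            list(self.sample_ids),
            [str(f) for f in ids],
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.matrix.copy(), self.labels.copy(), list(self.sample_ids), list(self.feature_ids)
        )

    def equals(self, other: "ExpressionDataset", rtol: float = 1e-9) -> bool:
        """Content equality; matrix values NaN-aware within ``rtol``."""
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.labels, other.labels)
            and self.matrix.shape == other.matrix.shape
            and bool(
                np.all(
                    np.isclose(self.matrix, other.matrix, rtol=rtol, atol=0.0, equal_nan=True)
                )
            )
        )


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_sidecar_labels(path: Path, sep: str) -> dict:
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise DatasetError(f"label sidecar {path} must have two columns (sample_id, label)")
    return dict(zip(raw.iloc[:, 0].str.strip(), raw.iloc[:, 1].str.strip()))


def read_expression_matrix(
    path,
    orientation: str = "samples_in_rows",
    label_source: str = "label",
    positive_label: str = "1",
) -> ExpressionDataset:
    """Read a delimited expression matrix into the canonical representation.

    Parameters
    ----------
    path
        TSV (default) or CSV file, dialect sniffed from the extension.
    orientation
        ``samples_in_rows`` or ``features_in_rows`` (transposed on read).
    label_source
        Name of the label column (a label *row* in a features-in-rows
        file), or path of a headerless two-column sidecar file.
    positive_label
        Label token mapped to class 1; every other token maps to 0.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise DatasetError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas silently mangles duplicate names
        raise DatasetError("duplicate identifiers in header row")
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "features_in_rows":
        df = df.T
    if df.index.has_duplicates:
        raise DatasetError("duplicate sample ids in file")
    if df.columns.has_duplicates:
        raise DatasetError("duplicate feature ids in file")

    sidecar = Path(str(label_source))
    if sidecar.is_file():
        mapping = _read_sidecar_labels(sidecar, _sep_for(sidecar))
        raw_labels = []
        for sid in df.index:
            if str(sid) not in mapping or mapping[str(sid)] == "":
                raise DatasetError(f"missing label for sample {sid!r}")
            raw_labels.append(mapping[str(sid)])
    elif label_source in df.columns:
        raw_labels = [str(v).strip() for v in df[label_source]]
        for sid, lab in zip(df.index, raw_labels):
            if lab == "":
                raise DatasetError(f"missing label for sample {sid!r}")
        df = df.drop(columns=[label_source])
    else:
        raise DatasetError(
            f"label source {label_source!r} is neither a column of {path.name} nor a file"
        )
    labels = np.array([1 if lab == str(positive_label) else 0 for lab in raw_labels], dtype=int)

    values = df.to_numpy(dtype=str)
    stripped = np.char.strip(values.astype(str))
    missing = np.isin(np.char.lower(stripped), list(MISSING_TOKENS))
    numeric = (
        pd.to_numeric(pd.Series(stripped.ravel()), errors="coerce")
        .to_numpy(dtype=float)
        .reshape(stripped.shape)
    )
    bad = np.isnan(numeric) & ~missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DatasetError(
            f"non-numeric cell at sample {df.index[i]!r}, feature {df.columns[j]!r}: "
            f"{values[i, j]!r}"
        )
    numeric[missing] = np.nan

    if numeric.shape[0] < 2 or numeric.shape[1] < 2:
        raise DatasetError("need at least 2 samples and 2 features")
    return ExpressionDataset(numeric, labels, list(df.index), list(df.columns))


def write_expression_matrix(
    dataset: ExpressionDataset,
    path,
    orientation: str = "samples_in_rows",
    label_column: str = "label",
) -> Path:
    """Write a dataset as delimited text (inverse of :func:`read_expression_matrix`).

    Values are formatted with 10 significant digits; NaN becomes "NA". The
    labels are stored as a ``label_column`` column (samples in rows) or row
    (features in rows), so the file round-trips through the reader with
    ``positive_label="1"``.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise DatasetError(f"unknown orientation {orientation!r}")
    cells = np.where(
        np.isnan(dataset.matrix),
        "NA",
        np.char.mod("%.10g", dataset.matrix),
    )
    df = pd.DataFrame(cells, index=dataset.sample_ids, columns=dataset.feature_ids)
    df[label_column] = [str(v) for v in dataset.labels]
    if orientation == "features_in_rows":
        df = df.T
    df.to_csv(path, sep=_sep_for(path), index_label="id")
    return path


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.12g}" if isinstance(value, float) else str(value)


def write_report(report, out_dir) -> list:
    """Serialize a run report: full JSON plus summary/improvement TSVs.

    ``report`` is any object exposing ``to_dict()`` whose dictionary has
    ``soldiers``, ``summary`` (keyed by :data:`SUMMARY_ENTITIES`) and
    ``improvements`` entries. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    written = []

    jpath = out / "report.json"
    with open(jpath, "w") as fh:
        json.dump(d, fh, indent=2)
    written.append(jpath)

    spath = out / "summary.tsv"
    with open(spath, "w") as fh:
        fh.write("entity\taccuracy\tmcc\trho\tn_evaluated\n")
        for entity in SUMMARY_ENTITIES:
            row = d["summary"].get(entity)
            if row is None:
                fh.write(f"{entity}\tNA\tNA\tNA\tNA\n")
            else:
                fh.write(
                    f"{entity}\t{_fmt(row['accuracy'])}\t{_fmt(row['mcc'])}"
                    f"\t{_fmt(row['rho'])}\t{_fmt(row['n_evaluated'])}\n"
                )
    written.append(spath)

    ipath = out / "improvements.tsv"
    improvements = d.get("improvements") or {}
    with open(ipath, "w") as fh:
        cols = [e for e in SUMMARY_ENTITIES if e != "final"]
        fh.write("measure\t" + "\t".join(cols) + "\n")
        for measure in ("accuracy", "mcc", "rho"):
            row = improvements.get(measure) or {}
            fh.write(measure + "\t" + "\t".join(_fmt(row.get(c)) for c in cols) + "\n")
    written.append(ipath)
    return written
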