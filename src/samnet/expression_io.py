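"""Reading, validation and normalization of two-group expression matrices.

The central container is :class:`ExpressionMatrix`, a thin wrapper around a
features x samples :class:`pandas.DataFrame` with an explicit intensity
scale (``linear`` or ``log2``).  All downstream statistics (SAM d scores,
fold changes) expect log2 intensities; fold changes are reported on the
signed linear scale so that a 2-fold decrease prints as -2, matching the
convention of microarray DEG tables.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "none", "n/a"}

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Features x samples intensity matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    scale
        ``"linear"`` or ``"log2"``.  Statistics require log2.
    """

    values: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}; expected 'linear' or 'log2'")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        """Write as plain TSV (feature id in the first column).

        ``header_lines`` are emitted first as ``#``-prefixed comments.
        """
        path = Path(path)
        with path.open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature_id")


@dataclass
class GroupDesign:
    """Assignment of every sample to one of exactly two groups.

    ``control`` and ``experimental`` name the two levels of
    ``group_of_sample`` (the reference and the condition of interest);
    differences are always experimental minus control.
    """

    group_of_sample: Mapping[str, str]
    control: str = "control"
    experimental: str = "experimental"

    def __post_init__(self) -> None:
        levels = set(self.group_of_sample.values())
        if levels != {self.control, self.experimental}:
            raise ValueError(
                f"design must contain exactly the two groups {self.control!r} and "
                f"{self.experimental!r}; found {sorted(levels)}"
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of_sample.items() if g == group]

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(self.control)

    @property
    def experimental_samples(self) -> list[str]:
        return self.samples_in(self.experimental)

    def swapped(self) -> "GroupDesign":
        """Return the design with the two group labels exchanged."""
        flip = {self.control: self.experimental, self.experimental: self.control}
        return GroupDesign(
            {s: flip[g] for s, g in self.group_of_sample.items()},
            control=self.control,
            experimental=self.experimental,
        )


def read_design(path: str | Path, control: str = "control", experimental: str = "experimental") -> GroupDesign:
    """Read a two-column ``sample<TAB>group`` design table (header optional)."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "sample" and row[1] == "group":
                continue
            mapping[row[0]] = row[1]
    return GroupDesign(mapping, control=control, experimental=experimental)


def write_design(design: GroupDesign, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in design.group_of_sample.items():
            fh.write(f"{s}\t{g}\n")


def _series_matrix_table_lines(lines: list[str]) -> list[str]:
    """Extract the data-table block of a GEO series-matrix file.

    Lines beginning with ``!`` are metadata; when the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers
    are present only the block between them is parsed.
    """
    begin = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")]
    end = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")]
    if begin and end:
        lines = lines[begin[0] + 1 : end[0]]
    return [l for l in lines if not l.startswith("!")]


def read_expression_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    scale: str = LOG2,
) -> ExpressionMatrix:
    """Parse a TSV expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        Tab-separated file: header row of sample ids, one row per feature,
        feature id in the first column.
    dialect
        ``"plain_tsv"`` or ``"series_matrix"`` (GEO dialect: ``!`` metadata
        lines ignored, optional table begin/end markers, quoted ids).
    scale
        Scale the stored intensities are on.

    Rows containing a missing value are dropped (the count is logged).
    Duplicate ids or non-numeric cells raise ``ValueError`` naming the
    offender.
    """
    if dialect not in ("plain_tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = Path(path).read_text().splitlines()
    raw = [l for l in raw if l and not l.startswith("#")]
    if dialect == "series_matrix":
        raw = _series_matrix_table_lines(raw)
    if not raw:
        raise ValueError(f"{path}: no table content found")

    rows = list(csv.reader(raw, delimiter="\t"))
    header = [c.strip().strip('"') for c in rows[0]]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        seen: set[str] = set()
        for s in sample_ids:
            if s in seen:
                raise ValueError(f"duplicate sample id: {s!r}")
            seen.add(s)

    feature_ids: list[str] = []
    data: list[np.ndarray] = []
    n_dropped = 0
    seen_features: set[str] = set()
    for irow, row in enumerate(rows[1:], start=2):
        fid = row[0].strip().strip('"')
        if fid in seen_features:
            raise ValueError(f"duplicate feature id: {fid!r}")
        seen_features.add(fid)
        cells = [c.strip().strip('"') for c in row[1:]]
        if len(cells) != len(sample_ids):
            raise ValueError(
                f"{path}: row {irow} ({fid!r}) has {len(cells)} values for {len(sample_ids)} samples"
            )
        if any(c.lower() in _MISSING_TOKENS for c in cells):
            n_dropped += 1
            continue
        try:
            vals = np.array([float(c) for c in cells], dtype=float)
        except ValueError:
            for j, c in enumerate(cells):
                try:
                    float(c)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {c!r} at row {irow} ({fid!r}), "
                        f"column {sample_ids[j]!r}"
                    ) from None
            raise
        if not np.all(np.isfinite(vals)):
            n_dropped += 1
            continue
        feature_ids.append(fid)
        data.append(vals)

    if n_dropped:
        logger.info("%s: dropped %d feature rows with missing values", path, n_dropped)
    values = pd.DataFrame(np.vstack(data) if data else np.empty((0, len(sample_ids))),
                          index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(values, scale=scale)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares one value distribution.

    The reference distribution is the across-sample mean of the sorted
    columns; each column's value at rank r is replaced by reference[r].
    Tied values within a column receive the mean of the reference values
    over their rank span, the standard microarray convention.  Rank order
    within each column is preserved.
    """
    X = m.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("quantile normalization requires finite values")
    n, k = X.shape
    if n == 0 or k == 0:
        return ExpressionMatrix(m.values.copy(), scale=m.scale)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = ref.copy()
        # average the reference over runs of tied input values
        start = 0
        for i in range(1, n + 1):
            if i == n or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[start:i] = ref[start:i].mean()
                start = i
        out[order, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), scale=m.scale
    )


def to_log2(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Convert a linear-scale matrix to log2(value + pseudocount)."""
    if m.scale != LINEAR:
        raise ValueError("to_log2 expects a linear-scale matrix")
    X = m.values.to_numpy(dtype=float) + pseudocount
    if np.any(X <= 0):
        raise ValueError(
            "non-positive value encountered; supply a positive pseudocount"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(X), index=m.values.index, columns=m.values.columns),
        scale=LOG2,
    )


def signed_fold_change_from_diff(log2_diff: np.ndarray | float) -> np.ndarray | float:
    """Map a log2 mean difference to the signed linear fold-change scale.

    With R = 2**diff, returns R when R >= 1 and -1/R otherwise, so
    downregulation is negative and |fc| is always >= 1 (fc = 1 means no
    change; there are no values in (-1, 1)).
    """
    diff = np.asarray(log2_diff, dtype=float)
    r = np.power(2.0, diff)
    out = np.where(r >= 1.0, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def signed_fold_change(m: ExpressionMatrix, design: GroupDesign, gene: str) -> float:
    """Signed linear fold change (experimental vs control) of one gene."""
    if m.scale != LOG2:
        raise ValueError("signed_fold_change expects a log2-scale matrix")
    row = m.values.loc[gene]
    diff = row[design.experimental_samples].mean() - row[design.control_samples].mean()
    return float(signed_fold_change_from_diff(diff))
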