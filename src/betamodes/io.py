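"""Reading beta matrices, probe subsetting, and the results table.

The canonical interchange format is delimited text (comma by default,
tab accepted): first column probe IDs, header row sample IDs, one beta
value in [0, 1] per cell, empty cells or a configurable token for
missing.  A "serialized" alternative uses Parquet for large matrices.
Results are written as a flat, spreadsheet-friendly CSV with per-peak
columns padded to the widest probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .summary import ProbeResult

__all__ = [
    "BetaMatrix",
    "BetaMatrixError",
    "read_beta_matrix",
    "write_beta_matrix",
    "subset_probes",
    "write_results_csv",
    "read_results_csv",
    "results_to_frame",
]

#: Decimal places used for numeric fields in the results CSV.
CSV_PRECISION = 6


class BetaMatrixError(ValueError):
    """Malformed beta-matrix input."""


@dataclass
class BetaMatrix:
    """Probes × samples matrix of beta values with NaN for missing."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise BetaMatrixError("matrix shape does not match ID lists")
        self._check_unique(self.probe_ids, "probe")
        self._check_unique(self.sample_ids, "sample")
        self._check_range()

    @staticmethod
    def _check_unique(ids: list[str], what: str) -> None:
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise BetaMatrixError(f"duplicate {what} ID {i!r}")
            seen.add(i)

    def _check_range(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise BetaMatrixError(
                f"beta value {self.values[r, c]!r} outside [0, 1] at probe "
                f"{self.probe_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(
            probe_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_beta_matrix(
    path, format: str = "delimited", missing_token: str = "NA", sep: str | None = None
) -> BetaMatrix:
    """Read and validate a beta matrix.

    ``format="delimited"`` expects probe IDs in the first column and
    sample IDs in the header; the delimiter is sniffed from the first
    line unless ``sep`` is given.  ``format="serialized"`` reads a
    Parquet file with the probe IDs as the index.  Empty cells and
    ``missing_token`` become missing entries; any other non-numeric
    cell, out-of-range value, or duplicate ID raises
    :class:`BetaMatrixError` naming the offender.
    """
    path = Path(path)
    if format == "serialized":
        df = pd.read_parquet(path)
        return BetaMatrix.from_frame(df)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    sep = sep or _sniff_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise BetaMatrixError(f"could not parse {path}: {exc}") from exc
    probe_ids = [str(i) for i in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    cells = raw.to_numpy(dtype=object)
    missing = (cells == "") | (cells == missing_token)
    numeric = pd.to_numeric(pd.Series(cells.ravel()), errors="coerce").to_numpy()
    bad = np.isnan(numeric) & ~missing.ravel()
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        r, c = divmod(flat, len(sample_ids))
        raise BetaMatrixError(
            f"unparseable value {cells[r, c]!r} at line {r + 2}, probe "
            f"{probe_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    values = numeric.reshape(cells.shape)
    return BetaMatrix(probe_ids=probe_ids, sample_ids=sample_ids, values=values)


def write_beta_matrix(
    matrix: BetaMatrix, path, format: str = "delimited", sep: str = ","
) -> None:
    """Write a beta matrix in the same layout :func:`read_beta_matrix`
    expects (full float precision; missing entries as empty cells)."""
    df = matrix.to_frame()
    if format == "serialized":
        df.to_parquet(path)
    elif format == "delimited":
        df.to_csv(path, sep=sep, na_rep="")
    else:
        raise ValueError(f"unknown format {format!r}")


def subset_probes(matrix: BetaMatrix, probe_ids: list[str]) -> BetaMatrix:
    """Row-subset preserving the requested order.

    Unknown IDs are an error (reported by name), as is an empty request.
    """
    if not probe_ids:
        raise BetaMatrixError("empty probe subset requested")
    index = {p: i for i, p in enumerate(matrix.probe_ids)}
    unknown = [p for p in probe_ids if p not in index]
    if unknown:
        raise BetaMatrixError(f"unknown probe IDs: {', '.join(map(repr, unknown))}")
    rows = [index[p] for p in probe_ids]
    return BetaMatrix(
        probe_ids=list(probe_ids),
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[rows],
    )


# ---------------------------------------------------------------------------
# results table


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{CSV_PRECISION}f}"


def results_to_frame(results: list[ProbeResult], drop_filtered: bool = False) -> pd.DataFrame:
    """Flatten result records into the stable wide CSV schema.

    Columns: probe, n_obs, meanBeta, modality, numPeaks, then
    peakLocation_k / peakProportion_k / peakVariance_k for
    k = 1..max peaks observed (ordered by apex location, blank where a
    probe has fewer peaks), then proportionSample_2 (the size-ordered
    secondary proportion), hypoFlag, hyperFlag, passedSecondaryFilter,
    status.  Numeric fields are fixed at 6 decimal places.
    """
    if drop_filtered:
        results = [r for r in results if r.passed_secondary_filter]
    max_peaks = max((r.n_peaks for r in results), default=0)
    rows = []
    for r in results:
        row = {
            "probe": r.probe_id,
            "n_obs": r.n_obs,
            "meanBeta": _fmt(r.mean_beta),
            "modality": r.modality.label if r.modality is not None else "",
            "numPeaks": r.n_peaks,
        }
        for k in range(max_peaks):
            suffix = str(k + 1)
            has = k < r.n_peaks
            row[f"peakLocation_{suffix}"] = _fmt(r.peak_locations[k]) if has else ""
            row[f"peakProportion_{suffix}"] = _fmt(r.peak_proportions[k]) if has else ""
            row[f"peakVariance_{suffix}"] = _fmt(r.peak_variances[k]) if has else ""
        row["proportionSample_2"] = _fmt(r.proportion_sample_2)
        row["hypoFlag"] = r.hypo_flag
        row["hyperFlag"] = r.hyper_flag
        row["passedSecondaryFilter"] = r.passed_secondary_filter
        row["status"] = r.status
        rows.append(row)
    columns = ["probe", "n_obs", "meanBeta", "modality", "numPeaks"]
    for k in range(max_peaks):
        columns += [f"peakLocation_{k+1}", f"peakProportion_{k+1}", f"peakVariance_{k+1}"]
    columns += [
        "proportionSample_2",
        "hypoFlag",
        "hyperFlag",
        "passedSecondaryFilter",
        "status",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_results_csv(
    results: list[ProbeResult], path, drop_filtered: bool = False
) -> int:
    """Write the per-probe results table; returns the row count written."""
    df = results_to_frame(results, drop_filtered=drop_filtered)
    df.to_csv(path, index=False)
    return len(df)


def read_results_csv(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_csv`."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
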