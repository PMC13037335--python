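"""Subject-level functional connectivity from parcel-averaged BOLD time series.

A subject's resting-state signal is summarised as one mean time series per
atlas parcel.  Functional connectivity (FC) is the matrix of pairwise Pearson
correlations between parcel series, used raw — no Fisher-Z transform and no
nuisance regression here; inputs are assumed fully preprocessed upstream.

The canonical edge vectorization used throughout the package is the strict
upper triangle of the FC matrix, row-major, 0-based: edge k corresponds to
the k-th pair (i, j) with i < j.  Templates and scores all share this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-12


def edge_index_pairs(n_parcels: int) -> list[tuple[int, int]]:
    """Canonical (i, j) pairs for the strict upper triangle, row-major."""
    iu, ju = np.triu_indices(n_parcels, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class ParcelTimeSeries:
    """One subject's timepoints x parcels matrix of mean BOLD signal.

    Rows are timepoints (T >= 3 so correlations have positive degrees of
    freedom), columns are parcels in atlas order.
    """

    subject_id: str
    data: np.ndarray
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: time series must be 2-D (timepoints x parcels)"
            )
        t, p = self.data.shape
        if t < 3:
            raise ValidationError(f"{self.subject_id}: need >= 3 timepoints, got {t}")
        if p < 2:
            raise ValidationError(f"{self.subject_id}: need >= 2 parcels, got {p}")
        if len(self.parcel_labels) != p:
            raise ValidationError(
                f"{self.subject_id}: {len(self.parcel_labels)} labels for {p} parcels"
            )
        if len(set(self.parcel_labels)) != p:
            raise ValidationError(f"{self.subject_id}: parcel labels not unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric P x P matrix of Pearson correlations with unit diagonal."""

    subject_id: str
    values: np.ndarray
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValidationError(f"{self.subject_id}: FC matrix must be square")
        if len(self.parcel_labels) != p:
            raise ValidationError(f"{self.subject_id}: label count mismatch")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Strict-upper-triangle vectorization of an FC matrix.

    ``values[k]`` is the correlation at ``edge_index[k] = (i, j)``, i < j,
    enumerated row-major — the "connection i" indexing the scoring equation
    averages over.
    """

    subject_id: str
    values: np.ndarray
    edge_index: list[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.edge_index) != self.values.size:
            raise ValidationError(
                f"{self.subject_id}: edge index length {len(self.edge_index)} "
                f"!= values length {self.values.size}"
            )

    @property
    def n_edges(self) -> int:
        return self.values.size

    @property
    def n_parcels(self) -> int:
        # E = P(P-1)/2  =>  P = (1 + sqrt(1 + 8E)) / 2
        p = int(round((1 + np.sqrt(1 + 8 * self.n_edges)) / 2))
        if p * (p - 1) // 2 != self.n_edges:
            raise ValidationError(
                f"{self.subject_id}: edge count {self.n_edges} is not P(P-1)/2"
            )
        return p


def _degenerate_parcels(data: np.ndarray) -> np.ndarray:
    """Indices of parcels with zero variance or missing values."""
    constant = np.ptp(data, axis=0) == 0
    has_nan = np.isnan(data).any(axis=0)
    return np.where(constant | has_nan)[0]


def compute_fc(ts: ParcelTimeSeries, degenerate_policy: str = "strict") -> FCMatrix:
    """Pairwise Pearson correlation of all parcel series, used raw.

    Parameters
    ----------
    ts
        Parcel-level time series (assumed preprocessed; nothing is regressed
        out here).
    degenerate_policy
        ``"strict"``: any zero-variance (or missing-valued) parcel raises
        :class:`DegenerateInputError` naming the parcel.  ``"lenient"``: such
        a parcel's correlations are set to 0 and a warning is logged.

    Returns
    -------
    FCMatrix
        Symmetric, unit diagonal, entries clipped to [-1, 1].  No Fisher-Z
        transform is applied.
    """
    if degenerate_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")

    bad = _degenerate_parcels(ts.data)
    if bad.size and degenerate_policy == "strict":
        names = [ts.parcel_labels[i] for i in bad]
        raise DegenerateInputError(
            f"{ts.subject_id}: degenerate parcel(s) {names} "
            "(zero variance or missing values); use lenient mode to zero-fill"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts.data, rowvar=False)
    r = np.asarray(r, dtype=float)

    if bad.size:
        logger.warning(
            "%s: zero-filling correlations of %d degenerate parcel(s): %s",
            ts.subject_id,
            bad.size,
            [ts.parcel_labels[i] for i in bad],
        )
        r[bad, :] = 0.0
        r[:, bad] = 0.0

    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(subject_id=ts.subject_id, values=r, parcel_labels=list(ts.parcel_labels))


def vectorize_fc(fc: FCMatrix, tol: float = _SYMMETRY_TOL) -> EdgeVector:
    """Extract the strict upper triangle as the canonical edge vector."""
    v = fc.values
    asym = np.abs(v - v.T).max() if v.size else 0.0
    if asym > tol:
        raise ValidationError(
            f"{fc.subject_id}: FC matrix asymmetric (max |A - A.T| = {asym:.3g} > {tol:g})"
        )
    p = fc.n_parcels
    iu, ju = np.triu_indices(p, k=1)
    return EdgeVector(
        subject_id=fc.subject_id,
        values=v[iu, ju].copy(),
        edge_index=list(zip(iu.tolist(), ju.tolist())),
    )


def devectorize(edges: EdgeVector, parcel_labels: list[str] | None = None) -> FCMatrix:
    """Rebuild the symmetric matrix (unit diagonal) from an edge vector."""
    p = edges.n_parcels
    m = np.eye(p)
    iu, ju = np.triu_indices(p, k=1)
    m[iu, ju] = edges.values
    m[ju, iu] = edges.values
    if parcel_labels is None:
        parcel_labels = [f"p{i}" for i in range(p)]
    return FCMatrix(subject_id=edges.subject_id, values=m, parcel_labels=parcel_labels)


# ---------------------------------------------------------------------------
# Plain-text readers / writers
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, subject_id: str | None = None) -> ParcelTimeSeries:
    """Read a delimited time-series file (rows = timepoints, header = labels).

    Delimiter is inferred from the extension (.tsv -> tab, otherwise comma).
    The filename stem is the subject id unless one is given.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return ParcelTimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        parcel_labels=[str(c) for c in df.columns],
    )


def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(ts.data, columns=ts.parcel_labels).to_csv(path, sep=sep, index=False)


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    """Square-matrix CSV with parcel labels as header and index."""
    pd.DataFrame(fc.values, index=fc.parcel_labels, columns=fc.parcel_labels).to_csv(path)


def write_edge_table(fc: FCMatrix, path: str | Path) -> None:
    """Long-format edge TSV: parcel_i, parcel_j, r (strict upper triangle)."""
    edges = vectorize_fc(fc)
    rows = [
        (fc.parcel_labels[i], fc.parcel_labels[j], r)
        for (i, j), r in zip(edges.edge_index, edges.values)
    ]
    pd.DataFrame(rows, columns=["parcel_i", "parcel_j", "r"]).to_csv(path, sep="\t", index=False)
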