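"""Polyconnectomic scoring (PCS) against disorder-specific edge-weight templates.

A connectome-summary-statistic (CSS) template assigns each connection of an
atlas a meta-analytic effect size (Cohen's d, patients vs controls).  The PCS
of a subject is the weighted average of the template weights and the
subject's functional connectivity over the connections carrying information:

    PCS = (1/n) * sum_i  beta_i * C_i      over edges with beta_i != 0

where C_i is the subject's Pearson correlation at edge i, beta_i the template
weight, and n the number of non-zero-weight edges.  No further scaling is
applied: higher scores mean stronger alignment of the individual connectome
with the disorder-related pattern.

Template distribution format (this package's own, documented here since the
published toolbox maps are not redistributed): an edge TSV with columns
``parcel_i``, ``parcel_j``, ``weight`` plus a JSON sidecar carrying
``template_id``, ``atlas_id``, ``P``, ``parcel_labels`` (atlas order) and
``network_partition`` (parcel label -> network label).  A square-matrix CSV
form is also accepted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome_fc import EdgeVector, edge_index_pairs
from .exceptions import ContractError, UndefinedScoreError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CSSTemplate:
    """Atlas-bound edge-weight map with a parcel -> network partition."""

    template_id: str
    atlas_id: str
    weights: np.ndarray
    edge_index: list[tuple[int, int]] = field(repr=False)
    parcel_labels: list[str] = field(repr=False)
    network_partition: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        p = len(self.parcel_labels)
        e = p * (p - 1) // 2
        if self.weights.size != e:
            raise ValidationError(
                f"template {self.template_id}: {self.weights.size} weights for "
                f"{p} parcels (expected {e})"
            )
        if list(self.edge_index) != edge_index_pairs(p):
            raise ValidationError(
                f"template {self.template_id}: edge index is not the canonical "
                "strict-upper-triangle order"
            )
        if not np.any(self.weights != 0):
            raise ValidationError(f"template {self.template_id}: all weights are zero")
        missing = [lab for lab in self.parcel_labels if lab not in self.network_partition]
        if missing:
            raise ValidationError(
                f"template {self.template_id}: parcels missing from network "
                f"partition: {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)

    @property
    def n_edges(self) -> int:
        return self.weights.size

    def edge_networks(self) -> tuple[list[str], list[str]]:
        """Network labels of each edge's two endpoints, in canonical order."""
        net = [self.network_partition[lab] for lab in self.parcel_labels]
        a = [net[i] for i, _ in self.edge_index]
        b = [net[j] for _, j in self.edge_index]
        return a, b

    def weight_matrix(self) -> np.ndarray:
        """Symmetric P x P weight matrix with zero diagonal."""
        p = self.n_parcels
        m = np.zeros((p, p))
        iu, ju = np.triu_indices(p, k=1)
        m[iu, ju] = self.weights
        m[ju, iu] = self.weights
        return m


@dataclass
class PCSResult:
    subject_id: str
    template_id: str
    score: float
    n_nonzero: int


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_template(path: str | Path, format: str = "edge_tsv") -> CSSTemplate:
    """Load a CSS template from disk, aligning weights to canonical edge order.

    The JSON sidecar (same stem, ``.json`` suffix) declares the atlas:
    parcel labels in order, the network partition, and ids.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"missing template sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("template_id", "atlas_id", "parcel_labels", "network_partition"):
        if key not in meta:
            raise ValidationError(f"template sidecar {sidecar} lacks '{key}'")
    labels = [str(x) for x in meta["parcel_labels"]]
    p = len(labels)
    pos = {lab: k for k, lab in enumerate(labels)}
    weights = np.zeros(p * (p - 1) // 2)

    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"parcel_i", "parcel_j", "weight"}
        if not required.issubset(df.columns):
            raise ValidationError(f"{path}: edge TSV needs columns {sorted(required)}")
        seen: set[tuple[int, int]] = set()
        for row in df.itertuples(index=False):
            a, b = str(row.parcel_i), str(row.parcel_j)
            for lab in (a, b):
                if lab not in pos:
                    raise ValidationError(f"{path}: unknown parcel label {lab!r}")
            i, j = sorted((pos[a], pos[b]))
            if i == j:
                raise ValidationError(f"{path}: self-edge on parcel {a!r}")
            if (i, j) in seen:
                raise ValidationError(f"{path}: duplicate edge ({a!r}, {b!r})")
            seen.add((i, j))
            k = i * p - i * (i + 1) // 2 + (j - i - 1)  # triu row-major offset
            weights[k] = float(row.weight)
    elif format == "square_csv":
        df = pd.read_csv(path, index_col=0)
        cols = [str(c) for c in df.columns]
        rows = [str(r) for r in df.index]
        if cols != labels or rows != labels:
            unknown = [c for c in cols + rows if c not in pos]
            raise ValidationError(
                f"{path}: square CSV labels do not match the atlas"
                + (f" (unknown: {unknown[:5]})" if unknown else " (order mismatch)")
            )
        m = df.to_numpy(dtype=float)
        if np.abs(m - m.T).max() > 1e-12:
            raise ValidationError(f"{path}: square template matrix is not symmetric")
        iu, ju = np.triu_indices(p, k=1)
        weights = m[iu, ju]
    else:
        raise ValueError(f"unknown template format {format!r}")

    return CSSTemplate(
        template_id=str(meta["template_id"]),
        atlas_id=str(meta["atlas_id"]),
        weights=weights,
        edge_index=edge_index_pairs(p),
        parcel_labels=labels,
        network_partition={str(k): str(v) for k, v in meta["network_partition"].items()},
    )


def save_template(template: CSSTemplate, path: str | Path) -> None:
    """Write a template as edge TSV + JSON sidecar (non-zero edges only)."""
    path = Path(path)
    rows = [
        (template.parcel_labels[i], template.parcel_labels[j], w)
        for (i, j), w in zip(template.edge_index, template.weights)
        if w != 0
    ]
    pd.DataFrame(rows, columns=["parcel_i", "parcel_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "template_id": template.template_id,
        "atlas_id": template.atlas_id,
        "P": template.n_parcels,
        "parcel_labels": template.parcel_labels,
        "network_partition": template.network_partition,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def compute_pcs(
    edges: EdgeVector, template: CSSTemplate, zero_tol: float = 0.0
) -> PCSResult:
    """Weighted average of template weights and individual connectivity.

    Only edges whose template weight is non-zero (|beta| > ``zero_tol``;
    exact inequality at the default 0) enter the average — connections the
    meta-analytic map is silent about carry no information about alignment.
    """
    if edges.n_edges != template.n_edges:
        raise ContractError(
            f"{edges.subject_id} vs template {template.template_id}: "
            f"{edges.n_edges} edges vs {template.n_edges} (atlas mismatch)"
        )
    if list(edges.edge_index) != list(template.edge_index):
        raise ContractError(
            f"{edges.subject_id} vs template {template.template_id}: "
            "edge orderings differ"
        )
    mask = np.abs(template.weights) > zero_tol if zero_tol > 0 else template.weights != 0
    n = int(mask.sum())
    if n == 0:
        raise UndefinedScoreError(
            f"template {template.template_id}: no non-zero weights, score undefined"
        )
    score = float(template.weights[mask] @ edges.values[mask]) / n
    if not np.isfinite(score):
        raise UndefinedScoreError(
            f"{edges.subject_id}: non-finite score against {template.template_id}"
        )
    return PCSResult(
        subject_id=edges.subject_id,
        template_id=template.template_id,
        score=score,
        n_nonzero=n,
    )


def batch_score(
    cohort_edges: list[EdgeVector],
    templates: list[CSSTemplate],
    strict: bool = True,
) -> pd.DataFrame:
    """Score every subject against every template.

    Returns a tidy frame (subject_id, template_id, pcs, n_nonzero), one row
    per subject x template in input order.  In lenient mode a failing subject
    x template pair is logged and skipped instead of aborting the batch.
    """
    rows = []
    for edges in cohort_edges:
        for template in templates:
            try:
                res = compute_pcs(edges, template)
            except Exception:
                if strict:
                    raise
                logger.exception(
                    "skipping %s x %s", edges.subject_id, template.template_id
                )
                continue
            rows.append((res.subject_id, res.template_id, res.score, res.n_nonzero))
    return pd.DataFrame(rows, columns=["subject_id", "template_id", "pcs", "n_nonzero"])
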