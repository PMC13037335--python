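"""Contribution structure of a CSS template: top edges and network blocks.

These summaries describe the template itself — which connections drive the
score and how the weight mass distributes within and between large-scale
networks (e.g. the Yeo-7 partition).  No subject data enters this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .pcs_scoring import CSSTemplate


@dataclass
class NetworkBlockSummary:
    """K x K aggregation of template weights over a network partition.

    Diagonal blocks aggregate within-network edges, off-diagonal blocks
    between-network edges.  ``block_counts`` gives the number of edges per
    block; blocks containing no edges report aggregate 0.
    """

    network_labels: list[str]
    block_matrix: np.ndarray
    block_counts: np.ndarray
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.block_matrix, index=self.network_labels, columns=self.network_labels
        )


def top_edges(template: CSSTemplate, k: int, sign: str) -> pd.DataFrame:
    """The k strongest positive or negative template contributors.

    Positive edges sort descending by weight, negative ascending (most
    negative first); ties keep canonical edge order.  Each row carries the
    parcel labels, weight, and the networks of both endpoints.
    """
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    if k < 1:
        raise ValueError("k must be a positive integer")

    w = template.weights
    idx = np.where(w > 0)[0] if sign == "positive" else np.where(w < 0)[0]
    if k > idx.size:
        raise ValueError(
            f"requested top {k} {sign} edges but only {idx.size} available"
        )
    key = -w[idx] if sign == "positive" else w[idx]
    order = idx[np.argsort(key, kind="stable")][:k]

    net_a, net_b = template.edge_networks()
    rows = [
        (
            template.parcel_labels[template.edge_index[e][0]],
            template.parcel_labels[template.edge_index[e][1]],
            w[e],
            net_a[e],
            net_b[e],
        )
        for e in order
    ]
    return pd.DataFrame(
        rows, columns=["parcel_i", "parcel_j", "weight", "network_i", "network_j"]
    )


def network_aggregate(template: CSSTemplate, statistic: str = "mean") -> NetworkBlockSummary:
    """Aggregate template weights into within/between-network blocks.

    ``mean`` (default) is comparable across blocks of different sizes;
    ``sum`` conserves the template's total weight over the blocks.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"statistic must be 'mean' or 'sum', got {statistic!r}")

    missing = [p for p in template.parcel_labels if p not in template.network_partition]
    if missing:
        raise ValidationError(f"parcels missing from partition: {missing[:5]}")

    labels = sorted(set(template.network_partition[p] for p in template.parcel_labels))
    pos = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)

    net_a, net_b = template.edge_networks()
    ai = np.array([pos[x] for x in net_a])
    bi = np.array([pos[x] for x in net_b])
    lo, hi = np.minimum(ai, bi), np.maximum(ai, bi)

    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    np.add.at(sums, (lo, hi), template.weights)
    np.add.at(counts, (lo, hi), 1)
    # mirror the upper-triangle accumulation to keep the summary symmetric
    sums = sums + np.triu(sums, 1).T
    counts = counts + np.triu(counts, 1).T

    if statistic == "mean":
        with np.errstate(invalid="ignore"):
            block = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    else:
        block = sums
    return NetworkBlockSummary(
        network_labels=labels, block_matrix=block, block_counts=counts, statistic=statistic
    )
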