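"""Skeleton graph construction and symmetric adjacency normalization.

The classifier treats the marker cloud as a graph G=(V,E) with M nodes.
Spatial aggregation uses the self-looped, symmetrically normalized adjacency

    O-tilde = O + I,   T-tilde = diag(rowsum(O-tilde)),
    O-hat   = T-tilde^(-1/2) O-tilde T-tilde^(-1/2).

Two presets ship: the 39-marker body graph and the 46-marker body+racket
graph in which the seven racket markers form a complete subgraph (a rigid
body: all racket points move simultaneously) attached to the gripping hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .markers import EdgeList, MarkerSet, load_edge_list, load_marker_set

__all__ = [
    "SkeletonGraph",
    "normalize_adjacency",
    "build_body_graph",
    "attach_racket",
    "body_graph",
    "body_racket_graph",
]

log = logging.getLogger(__name__)


def normalize_adjacency(O: np.ndarray) -> np.ndarray:
    """Return ``T̃^(-1/2) (O+I) T̃^(-1/2)`` for a symmetric adjacency ``O``."""
    O = np.asarray(O, dtype=np.float64)
    if O.ndim != 2 or O.shape[0] != O.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {O.shape}")
    if not np.array_equal(O, O.T):
        raise ValueError("adjacency must be symmetric")
    if (O < 0).any():
        raise ValueError("adjacency must be non-negative")
    O_tilde = O + np.eye(O.shape[0])
    d = O_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * O_tilde * inv_sqrt[None, :]


@dataclass(frozen=True)
class SkeletonGraph:
    """Marker graph with raw, self-looped, and normalized adjacency."""

    node_order: tuple[str, ...]
    O: np.ndarray          # M x M binary, zero diagonal
    O_tilde: np.ndarray    # O + I
    T_tilde: np.ndarray    # diagonal degree matrix of O_tilde
    O_hat: np.ndarray      # normalized adjacency

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @classmethod
    def from_adjacency(cls, node_order, O: np.ndarray) -> "SkeletonGraph":
        O = np.asarray(O, dtype=np.float64)
        O_hat = normalize_adjacency(O)
        O_tilde = O + np.eye(O.shape[0])
        T_tilde = np.diag(O_tilde.sum(axis=1))
        return cls(tuple(node_order), O, O_tilde, T_tilde, O_hat)

    def to_csv(self, path) -> None:
        """Write the raw adjacency with label header row/column."""
        import pandas as pd

        pd.DataFrame(self.O, index=self.node_order,
                     columns=self.node_order).to_csv(path)


def build_body_graph(markers: MarkerSet, edges: EdgeList) -> SkeletonGraph:
    """Assemble a SkeletonGraph from a marker set and an edge table."""
    edges.validate(markers)
    M = markers.count
    O = np.zeros((M, M))
    for a, b in edges:
        i, j = markers.index(a), markers.index(b)
        O[i, j] = O[j, i] = 1.0
    return SkeletonGraph.from_adjacency(markers.names, O)


def attach_racket(body: SkeletonGraph, racket: MarkerSet,
                  attachment: EdgeList | None = None) -> SkeletonGraph:
    """Extend the body graph with the rigid racket cluster.

    The racket markers form a complete subgraph (constant pairwise
    distances: one rigid transform moves all of them), appended after the
    body markers.  ``attachment`` edges tie the racket to the body; the
    default connects the bottom-of-handle marker to the right wrist bar.
    """
    overlap = set(body.node_order) & set(racket.names)
    if overlap:
        raise ValueError(f"marker label collision: {sorted(overlap)}")
    if attachment is None:
        attachment = load_edge_list("racket_attachment_right")
    Mb, Mr = body.n_nodes, racket.count
    order = body.node_order + racket.names
    M = Mb + Mr
    O = np.zeros((M, M))
    O[:Mb, :Mb] = body.O
    # complete K_Mr subgraph among racket markers
    O[Mb:, Mb:] = 1.0 - np.eye(Mr)
    idx = {lbl: i for i, lbl in enumerate(order)}
    if len(attachment) == 0:
        log.warning("empty racket attachment: racket subgraph is disconnected "
                    "from the body")
    for a, b in attachment:
        for lbl in (a, b):
            if lbl not in idx:
                raise ValueError(f"attachment references unknown marker {lbl!r}")
        O[idx[a], idx[b]] = O[idx[b], idx[a]] = 1.0
    return SkeletonGraph.from_adjacency(order, O)


def body_graph() -> SkeletonGraph:
    """The shipped 39-node body graph."""
    return build_body_graph(load_marker_set("plug_in_gait_39"),
                            load_edge_list("body_edges_39"))


def body_racket_graph(side: str = "right") -> SkeletonGraph:
    """The shipped 46-node body+racket graph (grip side 'right'/'left')."""
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    return attach_racket(body_graph(), load_marker_set("racket_7"),
                         load_edge_list(f"racket_attachment_{side}"))
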