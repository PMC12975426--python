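"""Spinal label schema and the anatomical adjacency graph.

The spine is modeled as an alternating chain of vertebral bodies and
intervertebral discs (IVDs): for the default thoraco-lumbo-sacral field of
view T9..S1 that is 10 vertebrae interleaved with 9 discs, i.e. 19
foreground structures.  Each structure is a node of a graph; edges connect
physically contiguous structures (a vertebra and the disc touching it), so
the full chain is a path graph with C-1 edges.  Background is not a node --
it is handled by the CNN path of the segmentation network.

Graph convolution uses the self-loop-augmented, symmetrically degree-
normalized propagation matrix ``A_hat = D^{-1/2} (A + I) D^{-1/2}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_LEVELS",
    "StructureLabel",
    "AnatomyGraph",
    "SchemaError",
    "build_schema",
    "build_adjacency",
    "normalize_adjacency",
    "full_graph",
]

#: Cranio-caudal vertebra levels of the default field of view.
DEFAULT_LEVELS = ("T9", "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5", "S1")

VERTEBRA = "vertebra"
DISC = "disc"


class SchemaError(ValueError):
    """Raised for an invalid label schema (e.g. duplicate level names)."""


@dataclass(frozen=True)
class StructureLabel:
    """One foreground structure: a vertebra or a disc.

    ``id`` is the integer class index (1-based; 0 is background), ``position``
    the 0-based rank along the cranio-caudal chain.
    """

    id: int
    name: str
    kind: str  # "vertebra" | "disc"
    position: int


@dataclass
class AnatomyGraph:
    """Label schema plus adjacency ``A`` and propagation matrix ``A_hat``."""

    labels: tuple[StructureLabel, ...]
    A: np.ndarray
    A_hat: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def label_by_name(self, name: str) -> StructureLabel:
        for lab in self.labels:
            if lab.name == name:
                return lab
        raise KeyError(name)

    # -- provenance export -------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "labels": [
                {"id": l.id, "name": l.name, "kind": l.kind, "position": l.position}
                for l in self.labels
            ],
            "edges": [[int(i), int(j)] for i, j in zip(*np.nonzero(np.triu(self.A)))],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AnatomyGraph":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        labels = tuple(StructureLabel(**d) for d in doc["labels"])
        n = len(labels)
        A = np.zeros((n, n))
        for i, j in doc["edges"]:
            A[i, j] = A[j, i] = 1.0
        return normalize_adjacency(cls(labels=labels, A=A))


def build_schema(levels=DEFAULT_LEVELS) -> list[StructureLabel]:
    """Build the alternating vertebra/disc label chain for ``levels``.

    ``levels`` are vertebra names in cranio-caudal order; a disc label
    ``"A/B"`` is inserted between each consecutive pair.  Ids are assigned
    contiguously 1..C in chain order.
    """
    levels = list(levels)
    if not levels:
        raise SchemaError("levels must be non-empty")
    if len(set(levels)) != len(levels):
        raise SchemaError(f"duplicate level names in {levels}")
    labels: list[StructureLabel] = []
    pos = 0
    for i, name in enumerate(levels):
        if i > 0:
            labels.append(StructureLabel(id=pos + 1, name=f"{levels[i-1]}/{name}",
                                         kind=DISC, position=pos))
            pos += 1
        labels.append(StructureLabel(id=pos + 1, name=name, kind=VERTEBRA, position=pos))
        pos += 1
    return labels


def build_adjacency(schema, vertebra_links: bool = False) -> AnatomyGraph:
    """Path-graph adjacency over the chain: edges between consecutive labels.

    ``vertebra_links=True`` additionally connects each vertebra to the next
    vertebra (skipping the shared disc); the default keeps only physically
    contiguous structures.
    """
    schema = tuple(sorted(schema, key=lambda l: l.position))
    n = len(schema)
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    if vertebra_links:
        for i in range(n):
            if schema[i].kind == VERTEBRA and i + 2 < n:
                A[i, i + 2] = A[i + 2, i] = 1.0
    return AnatomyGraph(labels=schema, A=A)


def normalize_adjacency(graph: AnatomyGraph) -> AnatomyGraph:
    """Fill ``A_hat = D^{-1/2} (A + I) D^{-1/2}`` (D from A + I)."""
    A = np.asarray(graph.A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    graph.A_hat = dinv[:, None] * A_tilde * dinv[None, :]
    return graph


def full_graph(levels=DEFAULT_LEVELS) -> AnatomyGraph:
    """Schema + adjacency + normalization in one call."""
    return normalize_adjacency(build_adjacency(build_schema(levels)))
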