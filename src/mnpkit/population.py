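"""Cohort structure: UPGMA clustering of 1 - GS distances and principal
coordinates analysis (classical metric MDS) of the similarity matrix.

UPGMA repeatedly merges the closest cluster pair (ties broken by the
lexicographically smallest pair of cluster leaf labels), with the new
cluster's distance to the rest the size-weighted arithmetic mean; node
heights are half the merge distance, so the tree is ultrametric by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .genotyping import Fingerprint
from .metrics import ComparisonResult, pairwise_compare

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def validate(self) -> "DistanceMatrix":
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if np.any(self.values < 0):
            raise DataError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal must be zero")
        return self


def distance_matrix_from_comparisons(results: Sequence[ComparisonResult]
                                     ) -> DistanceMatrix:
    """D = 1 - GS over all compared accession pairs."""
    labels = sorted({r.accession_a for r in results}
                    | {r.accession_b for r in results})
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    seen = np.eye(n, dtype=bool)
    for r in results:
        i, j = index[r.accession_a], index[r.accession_b]
        values[i, j] = values[j, i] = 1.0 - r.gs
        seen[i, j] = seen[j, i] = True
    if not seen.all():
        raise DataError("comparison results do not cover all pairs")
    return DistanceMatrix(labels, values).validate()


def distance_matrix_from_fingerprints(fingerprints: dict[str, Fingerprint],
                                      denominator_mode: str = "panel"
                                      ) -> DistanceMatrix:
    return distance_matrix_from_comparisons(
        pairwise_compare(fingerprints, denominator_mode))


@dataclass
class DendrogramNode:
    """Binary ultrametric tree node; leaves carry labels at height 0."""

    height: float = 0.0
    label: Optional[str] = None
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [lab for child in self.children
                for lab in child.leaf_labels()]


def upgma(matrix: DistanceMatrix) -> DendrogramNode:
    """Unweighted pair group method with arithmetic mean.

    Merge distance for clusters A and B is the arithmetic mean of all
    leaf-pair distances; node height is half the merge distance.
    """
    matrix.validate()
    n = len(matrix.labels)
    if n < 2:
        raise DataError("UPGMA needs at least two accessions")
    nodes = {i: DendrogramNode(label=lab) for i, lab in
             enumerate(matrix.labels)}
    sizes = {i: 1 for i in range(n)}
    min_label = {i: lab for i, lab in enumerate(matrix.labels)}
    dist = {frozenset((i, j)): float(matrix.values[i, j])
            for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            (pair for pair in dist),
            key=lambda pair: (dist[pair],
                              tuple(sorted(min_label[k] for k in pair))))
        d = dist[best]
        i, j = sorted(best, key=lambda k: min_label[k])
        node = DendrogramNode(height=d / 2.0,
                              children=(nodes[i], nodes[j]))
        new = next_id
        next_id += 1
        for k in list(active - {i, j}):
            dk = (sizes[i] * dist[frozenset((i, k))]
                  + sizes[j] * dist[frozenset((j, k))]) \
                / (sizes[i] + sizes[j])
            dist[frozenset((new, k))] = dk
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active -= {i, j}
        active.add(new)
        nodes[new] = node
        sizes[new] = sizes[i] + sizes[j]
        min_label[new] = min(min_label[i], min_label[j])
    return nodes[next_id - 1]


def to_newick(tree: DendrogramNode) -> str:
    """Newick string with branch lengths = parent height - child height."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        branch = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{branch:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{branch:.10g}"

    if tree.is_leaf:
        return f"{tree.label}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def cophenetic_distances(tree: DendrogramNode) -> DistanceMatrix:
    """Pairwise cophenetic distances (2x merge height of the LCA)."""
    labels = sorted(tree.leaf_labels())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))

    def walk(node: DendrogramNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        i, j = index[a], index[b]
                        values[i, j] = values[j, i] = 2.0 * node.height
        return [lab for g in groups for lab in g]

    walk(tree)
    return DistanceMatrix(labels, values)


def pcoa(matrix: DistanceMatrix, n_axes: int = 2
         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical multidimensional scaling (principal coordinates).

    Double-centers -0.5 * D^2, eigendecomposes, and returns the top
    ``n_axes`` axes scaled by the square root of their eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are truncated with a
    warning; each axis sign is fixed so its largest-magnitude loading is
    positive. Returns (coordinates frame, explained fractions).
    """
    matrix.validate()
    n = len(matrix.labels)
    if n_axes >= n:
        raise DataError("n_axes must be smaller than the number of samples")
    d2 = matrix.values ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if np.any(eigvals < -1e-9 * max(1.0, abs(eigvals[0]))):
        logger.warning("PCoA: negative eigenvalues truncated "
                       "(non-Euclidean distances)")
    positive = np.clip(eigvals, 0.0, None)
    total = positive.sum()
    coords = np.zeros((n, n_axes))
    explained = np.zeros(n_axes)
    for axis in range(n_axes):
        if positive[axis] <= 0:
            continue
        vec = eigvecs[:, axis] * np.sqrt(positive[axis])
        if abs(vec.min()) > abs(vec.max()):
            vec = -vec
        coords[:, axis] = vec
        explained[axis] = positive[axis] / total if total > 0 else 0.0
    frame = pd.DataFrame(coords, index=matrix.labels,
                         columns=[f"axis{k + 1}" for k in range(n_axes)])
    return frame, explained


def pca_onehot(fingerprints: dict[str, Fingerprint], n_axes: int = 2
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Plain PCA on a one-hot allele-membership matrix (alternative view).

    Each (locus, allele) pair is an indicator column; rows are centered
    and decomposed by SVD.
    """
    accs = sorted(fingerprints)
    if n_axes >= len(accs):
        raise DataError("n_axes must be smaller than the number of samples")
    columns: dict[tuple[str, str], int] = {}
    for fp in fingerprints.values():
        for locus, call in fp.calls.items():
            if call.called:
                for allele in call.alleles:
                    columns.setdefault((locus, allele), len(columns))
    x = np.zeros((len(accs), len(columns)))
    for i, acc in enumerate(accs):
        for locus, call in fingerprints[acc].calls.items():
            if call.called:
                for allele in call.alleles:
                    x[i, columns[(locus, allele)]] = 1.0
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_axes] * s[:n_axes]
    for axis in range(coords.shape[1]):
        vec = coords[:, axis]
        if abs(vec.min()) > abs(vec.max()):
            coords[:, axis] = -vec
    var = s ** 2
    explained = (var[:n_axes] / var.sum()) if var.sum() > 0 else \
        np.zeros(n_axes)
    frame = pd.DataFrame(coords, index=accs,
                         columns=[f"axis{k + 1}" for k in range(n_axes)])
    return frame, explained
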