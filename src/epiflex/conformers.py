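"""Conformational cluster analysis on Cα RMSD.

Frames are compared by *pairwise fitted* Cα RMSD (each pair superposed
independently, standard cluster-analysis practice) and grouped by
average-linkage agglomeration: clusters are merged while the smallest
average between-cluster distance does not exceed a threshold epsilon
(default 3.0 Å). This is the stopping rule used by CPPTRAJ's
``cluster ... averagelinkage epsilon``; it is equivalent to cutting the
average-linkage dendrogram at height epsilon, which is how it is computed
here (scipy's hierarchy routines on the condensed distance matrix).

The representative conformation of a cluster is the arithmetic mean of its
member frames after superposition (a time-averaged conformation, no energy
minimisation). Ties for the most populated cluster break towards the lowest
cluster id; cluster ids are assigned by order of first frame occurrence so
results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .core import ConformationFrame, TrajectoryEnsemble, check_same_labels
from .errors import InsufficientDataError
from .superpose import batch_fit, pairwise_fitted_rmsd, rmsd

__all__ = [
    "DEFAULT_EPSILON",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "average_linkage_cluster",
    "most_populated_average",
    "compare_to_reference",
    "ConformationClusterer",
]

DEFAULT_EPSILON = 3.0  # Å


@dataclass
class ClusterResult:
    """Flat clustering of trajectory frames.

    ``assignments[i]`` is the cluster id of frame ``i``; ids are dense,
    start at 0 and are ordered by first occurrence. ``populations[k]`` is
    the number of member frames of cluster ``k`` (sums to the frame count).
    ``representative_average`` maps cluster id to the time-averaged member
    conformation when frames were supplied to the clustering entry point.
    """

    assignments: np.ndarray
    populations: dict[int, int]
    representative_average: dict[int, ConformationFrame] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def most_populated(self) -> int:
        """Id of the largest cluster; ties break to the lowest id."""
        best = max(self.populations.values())
        return min(k for k, v in self.populations.items() if v == best)

    def to_frame(self) -> pd.DataFrame:
        total = int(self.assignments.size)
        ids = sorted(self.populations)
        return pd.DataFrame(
            {
                "cluster": ids,
                "population": [self.populations[k] for k in ids],
                "fraction": [self.populations[k] / total for k in ids],
            }
        )


def _coords_stack(frames) -> tuple[np.ndarray, tuple | None]:
    """Normalise frames input to an (F, N, 3) array plus shared labels."""
    if isinstance(frames, TrajectoryEnsemble):
        return frames.pooled(), frames.labels
    if isinstance(frames, np.ndarray):
        if frames.ndim != 3:
            raise ValueError(f"expected (F, N, 3) coordinates, got {frames.shape}")
        return np.asarray(frames, dtype=float), None
    frames = list(frames)
    labels = None
    for fr in frames:
        if isinstance(fr, ConformationFrame):
            if labels is None:
                labels = fr.labels
            else:
                check_same_labels(labels, fr.labels, "cluster input")
    coords = np.stack(
        [fr.coords if isinstance(fr, ConformationFrame) else np.asarray(fr, float)
         for fr in frames]
    )
    return coords, labels


def pairwise_rmsd_matrix(frames) -> np.ndarray:
    """Symmetric matrix of pairwise fitted Cα RMSDs (zero diagonal), Å.

    ``frames`` may be a :class:`TrajectoryEnsemble` (replicas pooled), a
    list of identically-labelled frames, or an ``(F, N, 3)`` array.
    """
    coords, _ = _coords_stack(frames)
    if coords.shape[0] < 2:
        raise InsufficientDataError("pairwise RMSD needs at least 2 frames")
    return pairwise_fitted_rmsd(coords)


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"distance matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("distances must be non-negative")
    return m


def _dense_relabel(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids densely by order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty(raw.size, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def average_linkage_cluster(matrix, epsilon: float = DEFAULT_EPSILON) -> ClusterResult:
    """Average-linkage agglomeration with merge threshold ``epsilon``.

    Merging proceeds while the minimum average between-cluster distance does
    not exceed epsilon; equivalently the dendrogram is cut at height
    epsilon. Representative averages are not computed here (a matrix alone
    carries no coordinates); see :func:`most_populated_average` and
    :class:`ConformationClusterer`.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    m = _check_matrix(matrix)
    if m.shape[0] == 1:
        assignments = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(m, checks=False), method="average")
        raw = fcluster(z, t=epsilon, criterion="distance")
        assignments = _dense_relabel(raw)
    populations = {int(k): int(v) for k, v in zip(*np.unique(assignments, return_counts=True))}
    return ClusterResult(assignments=assignments, populations=populations)


def _cluster_average(coords: np.ndarray, labels) -> ConformationFrame:
    """Time-averaged conformation of member frames (two-pass fit, no minimisation)."""
    if coords.shape[0] == 1:
        avg = coords[0]
    else:
        step1 = batch_fit(coords, coords[0])
        avg = batch_fit(coords, step1.mean(axis=0)).mean(axis=0)
    if labels is None:
        from .core import ResidueLabel

        labels = tuple(
            ResidueLabel(chain_id="A", crystal_number=i + 1, residue_name="ALA")
            for i in range(coords.shape[1])
        )
    return ConformationFrame(labels, avg)


def most_populated_average(frames, result: ClusterResult) -> ConformationFrame:
    """Time-averaged conformation of the most populated cluster.

    Member frames are superposed (two passes, as in the ensemble fit) and
    averaged arithmetically without minimisation. Ties between equally
    populated clusters break towards the lowest cluster id.
    """
    coords, labels = _coords_stack(frames)
    if coords.shape[0] != result.assignments.size:
        raise ValueError("frame count does not match cluster assignments")
    k = result.most_populated()
    members = coords[result.assignments == k]
    return _cluster_average(members, labels)


def compare_to_reference(avg: ConformationFrame, reference: ConformationFrame) -> float:
    """Fitted Cα RMSD between a representative average and a reference.

    When the two structures differ in length (e.g. chains 16-238 vs 16-239)
    the comparison runs over the residues common to both, matched by chain,
    crystal number and insertion code; at least 3 common residues required.
    """
    key = lambda lab: (lab.chain_id, lab.crystal_number, lab.insertion_code)
    ref_index = {key(lab): i for i, lab in enumerate(reference.labels)}
    ia, ib = [], []
    for i, lab in enumerate(avg.labels):
        j = ref_index.get(key(lab))
        if j is not None:
            ia.append(i)
            ib.append(j)
    if len(ia) < 3:
        raise InsufficientDataError(
            f"only {len(ia)} residues in common; need at least 3"
        )
    return rmsd(avg.coords[ia], reference.coords[ib], fit=True)


class ConformationClusterer(BaseEstimator, ClusterMixin):
    """Average-linkage conformational clustering estimator.

    Parameters
    ----------
    epsilon : float
        Merge-stopping threshold on average between-cluster Cα RMSD, Å.
    metric : {"rmsd", "precomputed"}
        With ``"rmsd"`` (default) ``fit(X)`` expects frames (ensemble, frame
        list or ``(F, N, 3)`` array) and builds the pairwise fitted RMSD
        matrix; with ``"precomputed"`` it expects the distance matrix.
    stride : int
        Keep every ``stride``-th frame before clustering (frame input only).

    Attributes
    ----------
    labels_ : (F,) int array of cluster assignments.
    populations_ : dict cluster id -> member count.
    result_ : ClusterResult (with representative averages for frame input).
    representative_average_ : ConformationFrame of the most populated cluster
        (frame input only).
    """

    def __init__(self, epsilon: float = DEFAULT_EPSILON, metric: str = "rmsd", stride: int = 1):
        self.epsilon = epsilon
        self.metric = metric
        self.stride = stride

    def fit(self, X, y=None):
        if self.metric not in ("rmsd", "precomputed"):
            raise ValueError("metric must be 'rmsd' or 'precomputed'")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.metric == "precomputed":
            result = average_linkage_cluster(X, epsilon=self.epsilon)
            self.result_ = result
        else:
            coords, labels = _coords_stack(X)
            coords = coords[:: self.stride]
            matrix = pairwise_rmsd_matrix(coords)
            result = average_linkage_cluster(matrix, epsilon=self.epsilon)
            for k in sorted(result.populations):
                result.representative_average[k] = _cluster_average(
                    coords[result.assignments == k], labels
                )
            self.result_ = result
            self.representative_average_ = result.representative_average[
                result.most_populated()
            ]
        self.labels_ = result.assignments
        self.populations_ = result.populations
        return self
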