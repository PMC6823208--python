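"""Least-squares rigid-body superposition and the two-step ensemble fit.

The superposition is the classical unweighted Kabsch solution: for point
sets P (mobile) and Q (reference), both centred, the rotation maximising
tr(R C) with C = P^T Q is R = V diag(1, 1, d) U^T where C = U S V^T and
d = sign(det(V U^T)) excludes reflections. All Cα atoms carry equal weight.

The two-step fit mirrors the standard trajectory protocol for fluctuation
analysis: (1) superpose every frame — pooled across replicas — onto the
first frame of the first replica and average the fitted coordinates
arithmetically to obtain an average conformation; (2) superpose every
original frame onto that average. Exactly two passes, no iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ConformationFrame, TrajectoryEnsemble, check_same_labels
from .errors import DegenerateGeometryError, InsufficientDataError

__all__ = [
    "Superposition",
    "FittedEnsemble",
    "kabsch_fit",
    "rmsd",
    "two_step_fit",
    "EnsembleAligner",
]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping mobile onto reference.

    ``transform(x) = rotation @ (x - mobile_centroid) + reference_centroid``;
    equivalently ``rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class FittedEnsemble:
    """Ensemble coordinates after the two-step fit plus the fit reference."""

    ensemble: TrajectoryEnsemble
    average: ConformationFrame


def _as_coords(x) -> np.ndarray:
    if isinstance(x, ConformationFrame):
        return x.coords
    return np.asarray(x, dtype=float)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise InsufficientDataError("superposition needs at least 3 atoms")


def _check_conditioning(centered: np.ndarray) -> None:
    # Collinear (rank<2) point sets leave the rotation under-determined.
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "degenerate (collinear) geometry: superposition is not unique"
        )


def _kabsch_rotation(p_centered: np.ndarray, q_centered: np.ndarray) -> np.ndarray:
    c = p_centered.T @ q_centered
    u, _, vt = np.linalg.svd(c)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def kabsch_fit(mobile, reference) -> Superposition:
    """Optimal (reflection-free) rigid superposition of mobile onto reference.

    Parameters may be :class:`ConformationFrame` or plain ``(N, 3)`` arrays
    with equal atom counts (N >= 3, not all collinear).
    """
    p = _as_coords(mobile)
    q = _as_coords(reference)
    _check_pair(p, q)
    pc_mean, qc_mean = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - pc_mean, q - qc_mean
    _check_conditioning(pc)
    _check_conditioning(qc)
    rot = _kabsch_rotation(pc, qc)
    fitted = pc @ rot.T
    val = float(np.sqrt(np.mean(np.sum((fitted - qc) ** 2, axis=1))))
    translation = qc_mean - rot @ pc_mean
    return Superposition(rotation=rot, translation=translation, rmsd=val)


def rmsd(a, b, fit: bool = True) -> float:
    """Cα RMSD between two conformations, in Å.

    With ``fit=True`` the minimised (superposed) RMSD; with ``fit=False``
    the raw coordinate deviation. Symmetric in its arguments.
    """
    p = _as_coords(a)
    q = _as_coords(b)
    if p.shape != q.shape:
        raise ValueError(f"coordinate shapes differ: {p.shape} vs {q.shape}")
    if not fit:
        return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))
    return kabsch_fit(p, q).rmsd


def batch_fit(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose a stack of frames ``(F, N, 3)`` onto one reference ``(N, 3)``.

    Vectorised Kabsch: one stacked 3x3 SVD for all frames. Returns the
    transformed stack.
    """
    x = np.asarray(coords, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean(axis=0)
    cent = x.mean(axis=1, keepdims=True)
    xc = x - cent
    cov = np.einsum("fni,nj->fij", xc, ref_c)
    u, _, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    flip = np.ones((x.shape[0], 3))
    flip[:, 2] = np.sign(det)
    rot = np.einsum("fji,fj,fjk->fik", vt, flip, np.transpose(u, (0, 2, 1)))
    # rot[f] maps frame f onto ref; rows transform as xc @ rot.T
    return np.einsum("fni,fji->fnj", xc, rot) + ref.mean(axis=0)


def pairwise_fitted_rmsd(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of minimised RMSDs between all frame pairs.

    Uses the singular-value identity rmsd^2 = (E0 - 2 D) / N with
    D = s1 + s2 +/- s3 so no rotations are materialised.
    """
    x = np.asarray(coords, dtype=float)
    f, n, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("fni,fni->f", xc, xc)
    ii, jj = np.triu_indices(f, k=1)
    cov = np.einsum("pni,pnj->pij", xc[ii], xc[jj])
    s = np.linalg.svd(cov, compute_uv=False)
    det = np.linalg.det(cov)
    d = s[:, 0] + s[:, 1] + np.where(det < 0, -s[:, 2], s[:, 2])
    msd = np.maximum(sq[ii] + sq[jj] - 2.0 * d, 0.0) / n
    mat = np.zeros((f, f))
    mat[ii, jj] = mat[jj, ii] = np.sqrt(msd)
    return mat


def two_step_fit(ensemble: TrajectoryEnsemble) -> FittedEnsemble:
    """Two-pass superposition of an ensemble onto its average conformation.

    Pass 1 fits every frame (pooled across replicas) onto the first frame of
    the first replica and averages the fitted coordinates; pass 2 refits all
    original frames onto that average. Returns the pass-2 coordinates split
    back into replicas together with the average conformation.

    The global pose of the output is anchored to the first saved
    conformation; fluctuation statistics derived from the output are
    invariant to rigid motions of any input frame.
    """
    pooled = ensemble.pooled()
    if pooled.shape[0] < 1:
        raise InsufficientDataError("empty ensemble")
    first = ensemble.replicas[0][0]
    _check_conditioning(first - first.mean(axis=0))
    step1 = batch_fit(pooled, first)
    average = step1.mean(axis=0)
    step2 = batch_fit(pooled, average)
    out, pos = [], 0
    for rep in ensemble.replicas:
        out.append(step2[pos : pos + rep.shape[0]])
        pos += rep.shape[0]
    return FittedEnsemble(
        ensemble=ensemble.with_replicas(out),
        average=ConformationFrame(ensemble.labels, average),
    )


class EnsembleAligner(BaseEstimator, TransformerMixin):
    """Transformer wrapping the two-step ensemble fit.

    ``fit`` derives the average conformation from the training ensemble via
    the two-step protocol; ``transform`` superposes any ensemble sharing the
    same labelling onto that stored average.

    Attributes
    ----------
    average_ : ConformationFrame
        Pooled average conformation (the pass-2 fit reference).
    fitted_ensemble_ : TrajectoryEnsemble
        The training ensemble after pass 2.
    """

    def fit(self, X: TrajectoryEnsemble, y=None):
        fe = two_step_fit(X)
        self.average_ = fe.average
        self.fitted_ensemble_ = fe.ensemble
        return self

    def transform(self, X: TrajectoryEnsemble) -> TrajectoryEnsemble:
        if not hasattr(self, "average_"):
            raise RuntimeError("EnsembleAligner is not fitted")
        check_same_labels(self.average_.labels, X.labels, "transform input")
        reps = [batch_fit(rep, self.average_.coords) for rep in X.replicas]
        return X.with_replicas(reps)

    def fit_transform(self, X: TrajectoryEnsemble, y=None) -> TrajectoryEnsemble:
        return self.fit(X).fitted_ensemble_
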