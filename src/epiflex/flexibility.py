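"""Simulated Cα B-factors with replica-ensemble statistics.

The B-factor (temperature factor) of an atom measures its positional
fluctuation about its mean position. Two conventions are in use:

``peraxis`` (default)
    B = (8 pi^2 / 3) <|r - r_bar|^2>, the crystallographic per-axis
    convention used by the PTRAJ/CPPTRAJ ``atomicfluct`` command. For an
    isotropic Gaussian with per-coordinate standard deviation sigma this
    equals 8 pi^2 sigma^2.
``total``
    B = 8 pi^2 <|r - r_bar|^2>, i.e. three times the per-axis value; the
    literal reading of "8 pi^2 <u^2>" with u the 3-D displacement.

Replica aggregation: the ensemble is superposed with the pooled two-step
fit, a per-residue B is computed within each replica, and the reported
value is the mean over replicas. The standard error is the sample standard
deviation across replicas divided by sqrt(R) — the standard
replica-ensemble estimator — and the 95% confidence interval is
mean +/- z * SE with z = 1.96 (large-sample normal interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (
    ConformationFrame,
    LoopDefinition,
    ResidueLabel,
    TrajectoryEnsemble,
    residue_sort_key,
)
from .errors import InsufficientDataError, LoopResolutionError
from .superpose import two_step_fit

__all__ = [
    "EIGHT_PI_SQUARED",
    "ScalarWithError",
    "BFactorProfile",
    "atomic_fluctuation",
    "replica_profile",
    "mean_over_residues",
    "BFactorProfiler",
]

EIGHT_PI_SQUARED = 8.0 * np.pi**2

_CONVENTIONS = ("peraxis", "total")


@dataclass(frozen=True)
class ScalarWithError:
    """A value in Å² with standard error and normal 95% CI."""

    value: float
    se: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("standard error must be non-negative")

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.value - self.z * self.se, self.value + self.z * self.se)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci95
        return f"{self.value:.2f} (95% CI: {lo:.2f}-{hi:.2f})"


class BFactorProfile:
    """Per-residue B-factors aggregated over replicas.

    Attributes
    ----------
    labels : tuple of ResidueLabel
    per_replica_B : (R, N) array, Å²
    mean_B : (N,) array — mean over replicas.
    se_B : (N,) array — sample SD across replicas / sqrt(R); NaN when R = 1.
    ci95_low, ci95_high : (N,) arrays — mean +/- z * SE.
    """

    def __init__(
        self,
        labels: Sequence[ResidueLabel],
        per_replica_B: np.ndarray,
        z: float = 1.96,
        convention: str = "peraxis",
    ):
        labels = tuple(labels)
        per_replica_B = np.asarray(per_replica_B, dtype=float)
        if per_replica_B.ndim != 2 or per_replica_B.shape[1] != len(labels):
            raise ValueError("per_replica_B must be (R, N) matching labels")
        if np.any(per_replica_B < 0):
            raise ValueError("B-factors must be non-negative")
        self.labels = labels
        self.per_replica_B = per_replica_B
        self.z = float(z)
        self.convention = convention
        self.mean_B = per_replica_B.mean(axis=0)
        r = per_replica_B.shape[0]
        if r >= 2:
            self.se_B = per_replica_B.std(axis=0, ddof=1) / np.sqrt(r)
        else:
            self.se_B = np.full(len(labels), np.nan)
        self.ci95_low = self.mean_B - self.z * self.se_B
        self.ci95_high = self.mean_B + self.z * self.se_B

    @property
    def n_replicas(self) -> int:
        return self.per_replica_B.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def indices_for(self, subset) -> np.ndarray:
        """Resolve a residue selection to positional indices.

        Accepts a :class:`LoopDefinition` (crystal range, insertion codes
        honoured), an iterable of crystal identifiers (ints, "38C" strings or
        ``(number, icode)`` pairs), an iterable of bools, or positional ints.
        """
        if isinstance(subset, LoopDefinition):
            idx = [i for i, lab in enumerate(self.labels) if subset.contains(lab)]
            if not idx:
                raise LoopResolutionError(
                    f"loop {subset.name} ({subset.crystal_range_str}) matches no "
                    f"residue in the profile"
                )
            return np.asarray(idx, dtype=int)
        subset = list(subset)
        if not subset:
            raise ValueError("empty residue subset")
        if all(isinstance(s, (bool, np.bool_)) for s in subset):
            mask = np.asarray(subset, bool)
            if mask.shape != (self.n_residues,):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(mask)
        key_index = {lab.sort_key: i for i, lab in enumerate(self.labels)}
        out = []
        for item in subset:
            if isinstance(item, (int, np.integer)):
                # bare ints are positional indices
                out.append(int(item))
                continue
            if isinstance(item, ResidueLabel):
                key = item.sort_key
            elif isinstance(item, tuple):
                key = residue_sort_key(int(item[0]), item[1])
            else:
                from .core import parse_residue_id

                key = residue_sort_key(*parse_residue_id(item))
            if key not in key_index:
                raise LoopResolutionError(f"residue {key[0]} not found in profile")
            out.append(key_index[key])
        idx = np.asarray(out, dtype=int)
        if np.any((idx < 0) | (idx >= self.n_residues)):
            raise IndexError("residue index out of range")
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per residue, one column per replica."""
        data = {
            "chain": [lab.chain_id for lab in self.labels],
            "crystal_number": [lab.crystal_number for lab in self.labels],
            "insertion_code": [lab.insertion_code for lab in self.labels],
            "sequence_number": [
                lab.sequence_number if lab.sequence_number is not None else ""
                for lab in self.labels
            ],
            "resname": [lab.residue_name for lab in self.labels],
            "B_mean": self.mean_B,
            "B_se": self.se_B,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
        }
        for r in range(self.n_replicas):
            data[f"B_rep{r + 1}"] = self.per_replica_B[r]
        return pd.DataFrame(data)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, z: float = 1.96) -> "BFactorProfile":
        df = pd.read_csv(path, sep="\t", comment="#")
        rep_cols = [c for c in df.columns if c.startswith("B_rep")]
        labels = [
            ResidueLabel(
                chain_id=str(row.chain),
                crystal_number=int(row.crystal_number),
                insertion_code=(
                    str(row.insertion_code).strip()
                    if isinstance(row.insertion_code, str)
                    else ""
                ),
                sequence_number=(
                    int(row.sequence_number)
                    if str(row.sequence_number).strip() not in ("", "nan")
                    else None
                ),
                residue_name=str(row.resname),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(labels, df[rep_cols].to_numpy().T, z=z)

    def whole_molecule(self) -> ScalarWithError:
        """Average B over all residues with propagated SE."""
        return mean_over_residues(self, np.arange(self.n_residues))


def atomic_fluctuation(
    fitted_frames, average: ConformationFrame | None = None, convention: str = "peraxis"
) -> np.ndarray:
    """Per-residue B-factors from superposed frames, in Å².

    ``fitted_frames`` is an ``(F, N, 3)`` array or list of frames that have
    already been superposed (the function cannot detect unfitted input —
    documented contract). Fluctuations are taken about the per-residue mean
    position of the supplied frames; ``average`` records the fit reference
    and does not enter the formula.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    if isinstance(fitted_frames, np.ndarray):
        coords = np.asarray(fitted_frames, dtype=float)
    else:
        coords = np.stack([f.coords if isinstance(f, ConformationFrame) else f
                           for f in fitted_frames])
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise InsufficientDataError("atomic fluctuation needs at least 2 frames")
    mean_pos = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0)
    factor = EIGHT_PI_SQUARED / 3.0 if convention == "peraxis" else EIGHT_PI_SQUARED
    return factor * msf


class BFactorProfiler(BaseEstimator):
    """Estimator computing a replica-aggregated Cα B-factor profile.

    Parameters
    ----------
    convention : {"peraxis", "total"}
        B-factor convention (see module docstring).
    z : float
        Normal quantile for the confidence interval (1.96 -> 95%).
    fluctuation_reference : {"replica_mean", "pooled_mean"}
        Mean position each replica's fluctuations are taken about. The
        default uses each replica's own mean after fitting to the pooled
        average, so between-replica drift inflates the SE rather than B.
    small_sample_correction : bool
        Superposing each frame onto the average absorbs the 6 rigid-body
        components of the fluctuation (a deterministic ~2/N deflation), and
        taking fluctuations about the sample mean removes another 1/F.
        When True (default) each replica's raw mean-square fluctuation is
        rescaled by 3N/(3N-6) * F/(F-1) to undo both; False reproduces the
        uncorrected ``atomicfluct``-style estimator exactly. The correction
        is exact for homogeneous isotropic fluctuations and approximate
        otherwise; it vanishes as N and F grow.

    Attributes
    ----------
    profile_ : BFactorProfile
    average_ : ConformationFrame — pooled two-step-fit average conformation.
    mean_B_, se_B_, per_replica_B_ : arrays (views into ``profile_``).
    """

    def __init__(
        self,
        convention: str = "peraxis",
        z: float = 1.96,
        fluctuation_reference: str = "replica_mean",
        small_sample_correction: bool = True,
    ):
        self.convention = convention
        self.z = z
        self.fluctuation_reference = fluctuation_reference
        self.small_sample_correction = small_sample_correction

    def fit(self, X: TrajectoryEnsemble, y=None):
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"convention must be one of {_CONVENTIONS}")
        if self.fluctuation_reference not in ("replica_mean", "pooled_mean"):
            raise ValueError("fluctuation_reference must be replica_mean or pooled_mean")
        if min(X.frames_per_replica) < 2:
            raise InsufficientDataError(
                "insufficient frames: every replica needs >= 2 frames"
            )
        fitted = two_step_fit(X)
        pooled_mean = fitted.ensemble.pooled().mean(axis=0)
        rows = []
        factor = EIGHT_PI_SQUARED / 3.0 if self.convention == "peraxis" else EIGHT_PI_SQUARED
        n = X.n_residues
        for rep in fitted.ensemble.replicas:
            ref = rep.mean(axis=0) if self.fluctuation_reference == "replica_mean" else pooled_mean
            msf = np.mean(np.sum((rep - ref) ** 2, axis=2), axis=0)
            if self.small_sample_correction:
                f = rep.shape[0]
                msf = msf * (3.0 * n) / (3.0 * n - 6.0) * f / (f - 1.0)
            rows.append(factor * msf)
        self.per_replica_B_ = np.vstack(rows)
        self.profile_ = BFactorProfile(
            X.labels, self.per_replica_B_, z=self.z, convention=self.convention
        )
        self.average_ = fitted.average
        self.mean_B_ = self.profile_.mean_B
        self.se_B_ = self.profile_.se_B
        return self

    def fit_profile(self, X: TrajectoryEnsemble) -> BFactorProfile:
        return self.fit(X).profile_


def replica_profile(
    ensemble: TrajectoryEnsemble,
    convention: str = "peraxis",
    z: float = 1.96,
    fluctuation_reference: str = "replica_mean",
    small_sample_correction: bool = True,
) -> BFactorProfile:
    """Two-step fit + per-replica ``atomicfluct`` + replica statistics."""
    return BFactorProfiler(
        convention=convention,
        z=z,
        fluctuation_reference=fluctuation_reference,
        small_sample_correction=small_sample_correction,
    ).fit_profile(ensemble)


def mean_over_residues(profile: BFactorProfile, subset) -> ScalarWithError:
    """Average B over a residue subset with SE propagation.

    value = mean of per-residue means; SE = sqrt(sum SE_i^2) / n (standard
    propagation of independent errors through an arithmetic mean);
    CI = value +/- z * SE.
    """
    idx = profile.indices_for(subset)
    if idx.size == 0:
        raise ValueError("empty residue subset")
    value = float(profile.mean_B[idx].mean())
    se = float(np.sqrt(np.sum(profile.se_B[idx] ** 2)) / idx.size)
    return ScalarWithError(value=value, se=se, z=profile.z)
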