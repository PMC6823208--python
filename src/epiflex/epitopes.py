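"""Loop/epitope-level antigenicity scoring and variant comparison.

A surface loop is called *potentially antigenic* when its mean Cα B-factor
strictly exceeds a mobility cutoff (default 9.00 Å², a conservative
threshold ~2 Å² above typical whole-protein means of ~7 Å²). Loops whose
mean equals the cutoff exactly are classified non-antigenic (strict ``>``).

Variant comparison reports per-loop differences, flags pairs whose 95%
confidence intervals are disjoint, and records antigenicity transitions
(``gained``/``lost``/``none``). Significance is reported as CI disjointness
only — no additional hypothesis test is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import ConformationFrame, LoopDefinition, parse_residue_id
from .errors import LoopResolutionError
from .flexibility import BFactorProfile, ScalarWithError, mean_over_residues

__all__ = [
    "DEFAULT_CUTOFF",
    "LoopReport",
    "VariantComparison",
    "score_loops",
    "count_antigenic",
    "compare_variants",
    "ca_distance",
    "reports_to_frame",
    "LoopAntigenicityScorer",
]

DEFAULT_CUTOFF = 9.00  # Å²


@dataclass(frozen=True)
class LoopReport:
    """Mean B of one loop plus its antigenicity call against a cutoff."""

    loop: LoopDefinition
    mean_B: ScalarWithError
    antigenic: bool
    n_residues: int
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("loop must cover at least one residue")
        if self.antigenic != (self.mean_B.value > self.cutoff):
            raise ValueError("antigenic flag inconsistent with cutoff")


@dataclass(frozen=True)
class VariantComparison:
    """Per-loop B-factor comparison between two variants (b minus a)."""

    loop_name: str
    value_a: ScalarWithError
    value_b: ScalarWithError
    delta: float
    ci_overlap: bool
    antigenicity_change: str  # "none" | "gained" | "lost"


def score_loops(
    profile: BFactorProfile,
    loops: Sequence[LoopDefinition] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[LoopReport]:
    """Score loops for antigenic potential against a mobility cutoff.

    Every loop must be resolvable in the profile's labels (crystal
    numbering, insertion codes honoured); otherwise
    :class:`~epiflex.errors.LoopResolutionError` names the loop.
    """
    if loops is None:
        from .io import load_loop_table

        loops = load_loop_table()
    if np.isnan(cutoff):
        raise ValueError("cutoff must be a number")
    reports = []
    for loop in loops:
        idx = profile.indices_for(loop)
        mean = mean_over_residues(profile, idx)
        reports.append(
            LoopReport(
                loop=loop,
                mean_B=mean,
                antigenic=bool(mean.value > cutoff),
                n_residues=int(idx.size),
                cutoff=float(cutoff),
            )
        )
    return reports


def count_antigenic(reports: Sequence[LoopReport]) -> int:
    """Number of loops called potentially antigenic."""
    return sum(1 for r in reports if r.antigenic)


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_variants(
    reports_a: Sequence[LoopReport], reports_b: Sequence[LoopReport]
) -> list[VariantComparison]:
    """Pairwise loop comparison between two variants' reports.

    Loops are matched by name (the sets must be identical). Disjoint 95%
    CIs are flagged (``ci_overlap=False`` marks a significant difference).
    """
    by_name_a = {r.loop.name: r for r in reports_a}
    by_name_b = {r.loop.name: r for r in reports_b}
    if set(by_name_a) != set(by_name_b):
        raise ValueError(
            "loop sets differ between variants: "
            f"{sorted(set(by_name_a) ^ set(by_name_b))}"
        )
    out = []
    for name in (r.loop.name for r in reports_a):
        ra, rb = by_name_a[name], by_name_b[name]
        if ra.antigenic == rb.antigenic:
            change = "none"
        elif rb.antigenic:
            change = "gained"
        else:
            change = "lost"
        out.append(
            VariantComparison(
                loop_name=name,
                value_a=ra.mean_B,
                value_b=rb.mean_B,
                delta=float(rb.mean_B.value - ra.mean_B.value),
                ci_overlap=_intervals_overlap(ra.mean_B.ci95, rb.mean_B.ci95),
                antigenicity_change=change,
            )
        )
    return out


def _resolve_residue(frame: ConformationFrame, residue) -> int:
    if isinstance(residue, tuple):
        num, icode = int(residue[0]), str(residue[1])
    else:
        num, icode = parse_residue_id(str(residue))
    try:
        return frame.index_of(num, icode)
    except KeyError as exc:
        raise LoopResolutionError(str(exc)) from None


def ca_distance(frame: ConformationFrame, residue_a, residue_b) -> float:
    """Euclidean Cα–Cα distance (Å) between two crystal-numbered residues."""
    ia = _resolve_residue(frame, residue_a)
    ib = _resolve_residue(frame, residue_b)
    return float(np.linalg.norm(frame.coords[ia] - frame.coords[ib]))


def reports_to_frame(reports: Sequence[LoopReport]) -> pd.DataFrame:
    """Loop reports as a table (values in Å², rounded to 2 decimals)."""
    return pd.DataFrame(
        {
            "loop": [r.loop.name for r in reports],
            "epitope": [r.loop.epitope for r in reports],
            "crystal_range": [r.loop.crystal_range_str for r in reports],
            "n_residues": [r.n_residues for r in reports],
            "B_mean": [round(r.mean_B.value, 2) for r in reports],
            "B_se": [round(r.mean_B.se, 2) for r in reports],
            "ci_low": [round(r.mean_B.ci95[0], 2) for r in reports],
            "ci_high": [round(r.mean_B.ci95[1], 2) for r in reports],
            "antigenic": [r.antigenic for r in reports],
        }
    )


def comparisons_to_frame(comparisons: Sequence[VariantComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "loop": [c.loop_name for c in comparisons],
            "B_a": [round(c.value_a.value, 2) for c in comparisons],
            "B_b": [round(c.value_b.value, 2) for c in comparisons],
            "delta": [round(c.delta, 2) for c in comparisons],
            "ci_overlap": [c.ci_overlap for c in comparisons],
            "antigenicity_change": [c.antigenicity_change for c in comparisons],
        }
    )


def compare_report_tables(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Variant comparison straight from two loop-report tables.

    Tables must carry the columns written by :func:`reports_to_frame`
    (``loop``, ``B_mean``, ``ci_low``, ``ci_high``, ``antigenic``) and
    identical loop sets; b is compared against a (delta = b - a).
    """
    if set(a["loop"]) != set(b["loop"]):
        raise ValueError(
            "loop sets differ between reports: "
            f"{sorted(set(a['loop']) ^ set(b['loop']))}"
        )
    bi = b.set_index("loop")
    rows = []
    for ra in a.itertuples(index=False):
        rb = bi.loc[ra.loop]
        ant_a, ant_b = bool(ra.antigenic), bool(rb["antigenic"])
        change = "none" if ant_a == ant_b else ("gained" if ant_b else "lost")
        rows.append(
            {
                "loop": ra.loop,
                "B_a": round(float(ra.B_mean), 2),
                "B_b": round(float(rb["B_mean"]), 2),
                "delta": round(float(rb["B_mean"]) - float(ra.B_mean), 2),
                "ci_overlap": _intervals_overlap(
                    (float(ra.ci_low), float(ra.ci_high)),
                    (float(rb["ci_low"]), float(rb["ci_high"])),
                ),
                "antigenicity_change": change,
            }
        )
    return pd.DataFrame(rows)


class LoopAntigenicityScorer(BaseEstimator):
    """Estimator-style wrapper around :func:`score_loops`.

    Parameters
    ----------
    cutoff : float
        Strict antigenicity threshold on the loop-mean B, Å².
    loops : list of LoopDefinition, optional
        Defaults to the packaged PR3 loop table.

    Attributes
    ----------
    reports_ : list of LoopReport
    n_antigenic_ : int
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF, loops=None):
        self.cutoff = cutoff
        self.loops = loops

    def fit(self, X: BFactorProfile, y=None):
        self.reports_ = score_loops(X, loops=self.loops, cutoff=self.cutoff)
        self.n_antigenic_ = count_antigenic(self.reports_)
        return self

    def fit_predict(self, X: BFactorProfile, y=None) -> np.ndarray:
        """Boolean antigenicity call per loop, in table order."""
        self.fit(X)
        return np.asarray([r.antigenic for r in self.reports_], dtype=bool)
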