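"""Core containers for per-residue Cα coordinate ensembles.

Everything downstream (superposition, B-factor profiling, loop scoring,
clustering) operates on three containers defined here:

``ResidueLabel``
    Residue identity carrying *both* numbering schemes used for serine
    proteases of the chymotrypsin family: the crystal-structure numbering
    with insertion codes (e.g. 38C, 63A) and an optional sequential
    (UniProt/NCBI-style) numbering.
``ConformationFrame``
    One conformation: an ordered N x 3 matrix of Cα coordinates in Å,
    aligned to an ordered list of labels.
``TrajectoryEnsemble``
    R independent replicas of F frames each, all sharing one label list.

Residue matching across frames is positional after label verification; no
alignment heuristics are applied because trajectory frames share a topology
by construction.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import StructuralMismatchError

_ICODE_RANK = {c: i + 1 for i, c in enumerate(string.ascii_uppercase)}

_RESID_RE = re.compile(r"^(\d+)([A-Za-z]?)$")


def icode_rank(insertion_code: str) -> int:
    """Rank of an insertion code under PDB ordering ('' < 'A' < ... < 'Z')."""
    if not insertion_code:
        return 0
    return _ICODE_RANK[insertion_code.upper()]


def parse_residue_id(text: str) -> tuple[int, str]:
    """Parse a crystal residue identifier like ``"38"`` or ``"38C"``.

    Returns ``(crystal_number, insertion_code)`` where the insertion code is
    ``""`` when absent.
    """
    m = _RESID_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"cannot parse residue identifier {text!r}")
    return int(m.group(1)), m.group(2).upper()


def residue_sort_key(crystal_number: int, insertion_code: str = "") -> tuple[int, int]:
    """Total order on crystal identifiers: 38 < 38A < 38B < 38C < 39."""
    return (int(crystal_number), icode_rank(insertion_code))


@dataclass(frozen=True)
class ResidueLabel:
    """Identity of one residue in both numbering schemes.

    Parameters
    ----------
    chain_id : str
        Single-character chain identifier.
    crystal_number : int
        Crystal-structure (chymotrypsin-style) residue number, >= 1.
    insertion_code : str
        Optional insertion code, one of A-Z (empty string when absent).
    sequence_number : int or None
        Sequential numbering (e.g. the NCBI P24158.3 scheme for PR3); None
        when not assigned.
    residue_name : str
        Three-letter residue code.
    """

    chain_id: str
    crystal_number: int
    insertion_code: str = ""
    sequence_number: int | None = None
    residue_name: str = "ALA"

    def __post_init__(self) -> None:
        if len(self.chain_id) != 1:
            raise ValueError(f"chain_id must be one character, got {self.chain_id!r}")
        if self.crystal_number < 1:
            raise ValueError(f"crystal_number must be >= 1, got {self.crystal_number}")
        ic = self.insertion_code
        if ic and (len(ic) != 1 or ic.upper() not in _ICODE_RANK):
            raise ValueError(f"insertion_code must be empty or A-Z, got {ic!r}")

    @property
    def sort_key(self) -> tuple[int, int]:
        return residue_sort_key(self.crystal_number, self.insertion_code)

    @property
    def crystal_id(self) -> str:
        """Crystal identifier as printed, e.g. ``"38C"``."""
        return f"{self.crystal_number}{self.insertion_code}"

    def same_site(self, other: "ResidueLabel") -> bool:
        """True when both labels name the same crystallographic site."""
        return (
            self.chain_id == other.chain_id
            and self.crystal_number == other.crystal_number
            and self.insertion_code == other.insertion_code
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain_id}:{self.residue_name}{self.crystal_id}"


class ConformationFrame:
    """An ordered set of Cα positions (Å) aligned to residue labels."""

    def __init__(self, labels: Sequence[ResidueLabel], coords: np.ndarray):
        labels = tuple(labels)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be N x 3, got shape {coords.shape}")
        if coords.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        seen: set[tuple[str, int, str]] = set()
        for lab in labels:
            key = (lab.chain_id, lab.crystal_number, lab.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue label {lab}")
            seen.add(key)
        self.labels = labels
        self.coords = coords
        self._index: dict[tuple[int, int], int] | None = None

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def _build_index(self) -> dict[tuple[int, int], int]:
        if self._index is None:
            self._index = {lab.sort_key: i for i, lab in enumerate(self.labels)}
        return self._index

    def index_of(self, crystal_number: int, insertion_code: str = "") -> int:
        """Positional index of a residue by crystal identifier."""
        key = residue_sort_key(crystal_number, insertion_code)
        idx = self._build_index().get(key)
        if idx is None:
            raise KeyError(
                f"residue {crystal_number}{insertion_code} not present in frame"
            )
        return idx

    def with_coords(self, coords: np.ndarray) -> "ConformationFrame":
        return ConformationFrame(self.labels, coords)

    def subset(self, indices: Sequence[int]) -> "ConformationFrame":
        idx = np.asarray(indices, dtype=int)
        return ConformationFrame(
            tuple(self.labels[i] for i in idx), self.coords[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConformationFrame):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.coords, other.coords)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ConformationFrame {self.n_residues} residues>"


def check_same_labels(
    a: Sequence[ResidueLabel], b: Sequence[ResidueLabel], context: str = ""
) -> None:
    """Verify two label lists describe the same residues, else raise.

    The comparison covers chain, crystal number, insertion code and residue
    name; the error names the first differing residue.
    """
    prefix = f"{context}: " if context else ""
    if len(a) != len(b):
        raise StructuralMismatchError(
            f"{prefix}residue counts differ ({len(a)} vs {len(b)})"
        )
    for la, lb in zip(a, b):
        if not la.same_site(lb) or la.residue_name != lb.residue_name:
            raise StructuralMismatchError(
                f"{prefix}first differing residue: {la} vs {lb}"
            )


class TrajectoryEnsemble:
    """R replicas x F frames of Cα conformations sharing one label list.

    Coordinates are stored per replica as ``(F_r, N, 3)`` arrays for
    vectorised downstream work; :meth:`frames` recovers
    :class:`ConformationFrame` views.
    """

    def __init__(self, labels: Sequence[ResidueLabel], replicas: Sequence[np.ndarray]):
        if len(replicas) < 1:
            raise ValueError("ensemble needs at least one replica")
        labels = tuple(labels)
        n = len(labels)
        arrays = []
        for r, rep in enumerate(replicas):
            arr = np.asarray(rep, dtype=float)
            if arr.ndim != 3 or arr.shape[1:] != (n, 3):
                raise ValueError(
                    f"replica {r}: expected (F, {n}, 3) coordinates, got {arr.shape}"
                )
            if arr.shape[0] < 1:
                raise ValueError(f"replica {r} has no frames")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"replica {r} contains non-finite coordinates")
            arrays.append(arr)
        self.labels = labels
        self.replicas = arrays

    @classmethod
    def from_frames(
        cls, replica_frames: Sequence[Sequence[ConformationFrame]]
    ) -> "TrajectoryEnsemble":
        """Build an ensemble from lists of frames, verifying shared labels."""
        if not replica_frames or not replica_frames[0]:
            raise ValueError("need at least one frame")
        ref = replica_frames[0][0].labels
        arrays = []
        for r, frames in enumerate(replica_frames):
            for f, frame in enumerate(frames):
                check_same_labels(ref, frame.labels, f"replica {r} frame {f}")
            arrays.append(np.stack([fr.coords for fr in frames]))
        return cls(ref, arrays)

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    @property
    def frames_per_replica(self) -> list[int]:
        return [rep.shape[0] for rep in self.replicas]

    @property
    def total_frames(self) -> int:
        return sum(self.frames_per_replica)

    def pooled(self) -> np.ndarray:
        """All frames pooled across replicas, shape (sum F_r, N, 3)."""
        return np.concatenate(self.replicas, axis=0)

    def frame(self, replica: int, index: int) -> ConformationFrame:
        return ConformationFrame(self.labels, self.replicas[replica][index])

    def frames(self, replica: int | None = None) -> Iterator[ConformationFrame]:
        reps = self.replicas if replica is None else [self.replicas[replica]]
        for rep in reps:
            for coords in rep:
                yield ConformationFrame(self.labels, coords)

    def with_replicas(self, replicas: Sequence[np.ndarray]) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(self.labels, replicas)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TrajectoryEnsemble R={self.n_replicas} "
            f"F={self.frames_per_replica} N={self.n_residues}>"
        )


@dataclass(frozen=True)
class LoopDefinition:
    """A surface loop given in both numbering schemes.

    ``crystal_start``/``crystal_end`` are ``(number, insertion_code)`` pairs;
    the range is inclusive under PDB insertion-code ordering, so 36-38C
    covers 36, 37, 38, 38A, 38B and 38C. The sequential range is recorded as
    printed in the source loop table and is not required to span the same
    number of residues (crystal numbering is authoritative).
    """

    name: str
    epitope: int
    crystal_start: tuple[int, str]
    crystal_end: tuple[int, str]
    seq_start: int | None = None
    seq_end: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.epitope <= 5:
            raise ValueError(f"epitope must be 1-5, got {self.epitope}")
        if residue_sort_key(*self.crystal_start) > residue_sort_key(*self.crystal_end):
            raise ValueError(f"loop {self.name}: crystal start > end")
        if (
            self.seq_start is not None
            and self.seq_end is not None
            and self.seq_start > self.seq_end
        ):
            raise ValueError(f"loop {self.name}: sequence start > end")

    def contains(self, label: ResidueLabel) -> bool:
        lo = residue_sort_key(*self.crystal_start)
        hi = residue_sort_key(*self.crystal_end)
        return lo <= label.sort_key <= hi

    @property
    def crystal_range_str(self) -> str:
        a = f"{self.crystal_start[0]}{self.crystal_start[1]}"
        b = f"{self.crystal_end[0]}{self.crystal_end[1]}"
        return f"{a}-{b}"
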