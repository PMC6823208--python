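"""Structure and table I/O.

Reading is Cα-only: the whole analysis is Cα-based, so every other atom is
dropped at parse time. Multi-model PDB is the normative trajectory dialect
(one file per replica, frames ordered by MODEL record); binary trajectories
(DCD, AMBER NetCDF, ...) are supported behind the same contract through
mdtraj when that package is available.

Alternate locations: only altloc ``' '`` or ``'A'`` conformers are kept so
reading is deterministic. Residues lacking a Cα are skipped with a warning.
"""

from __future__ import annotations

import logging
import urllib.request
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .core import (
    ConformationFrame,
    LoopDefinition,
    ResidueLabel,
    TrajectoryEnsemble,
    check_same_labels,
    parse_residue_id,
)
from .errors import NumberingLookupError, StructureParseError

logger = logging.getLogger(__name__)

_MAX_PDB_BFACTOR = 999.99


def _frame_from_model(model, chain_id: str | None, path: str) -> ConformationFrame:
    labels: list[ResidueLabel] = []
    coords: list[np.ndarray] = []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue  # waters / ligands are never part of the Cα trace
            if "CA" not in res:
                logger.warning(
                    "%s: residue %s%s%s in chain %s lacks a CA atom; skipped",
                    path, res.get_resname(), resseq, icode.strip(), chain.id,
                )
                continue
            atom = res["CA"]
            if atom.is_disordered():
                ids = atom.disordered_get_id_list()
                sel = " " if " " in ids else ("A" if "A" in ids else sorted(ids)[0])
                atom = atom.disordered_get(sel)
            labels.append(
                ResidueLabel(
                    chain_id=chain.id if chain.id.strip() else "A",
                    crystal_number=int(resseq),
                    insertion_code=icode.strip().upper(),
                    residue_name=res.get_resname(),
                )
            )
            coords.append(np.asarray(atom.get_coord(), dtype=float))
    if not labels:
        raise StructureParseError(f"{path}: no CA atoms found")
    return ConformationFrame(labels, np.vstack(coords))


def _parse(path) -> list:
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(Path(path).stem, str(path))
    except PDBConstructionException as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureParseError(f"{path}: file contains no models")
    return models


def read_structure(path, model_index: int = 0, chain: str | None = None) -> ConformationFrame:
    """Read one model of a PDB file as a Cα :class:`ConformationFrame`.

    Parameters
    ----------
    path : path-like
        PDB file (ATOM/MODEL/ENDMDL records).
    model_index : int
        Zero-based index into the file's MODEL records.
    chain : str, optional
        Restrict to one chain; default keeps every chain in file order.
    """
    models = _parse(path)
    if not 0 <= model_index < len(models):
        raise StructureParseError(
            f"{path}: model {model_index} requested but file has {len(models)}"
        )
    return _frame_from_model(models[model_index], chain, str(path))


def read_frames(path, chain: str | None = None) -> list[ConformationFrame]:
    """Read every MODEL of a multi-model PDB, in MODEL order."""
    return [_frame_from_model(m, chain, str(path)) for m in _parse(path)]


def read_ensemble(paths: Sequence, chain: str | None = None, stride: int = 1) -> TrajectoryEnsemble:
    """Read one multi-model PDB per replica into a :class:`TrajectoryEnsemble`.

    All files must share identical residue labelling; a mismatch raises
    :class:`~epiflex.errors.StructuralMismatchError` naming the first
    differing residue.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("need at least one trajectory path")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    replica_frames = []
    for p in paths:
        frames = read_frames(p, chain)[::stride]
        replica_frames.append(frames)
    ref = replica_frames[0][0].labels
    for p, frames in zip(paths, replica_frames):
        for i, fr in enumerate(frames):
            check_same_labels(ref, fr.labels, f"{p} frame {i}")
    return TrajectoryEnsemble(
        ref, [np.stack([fr.coords for fr in frames]) for frames in replica_frames]
    )


def read_ensemble_binary(traj_paths: Sequence, topology) -> TrajectoryEnsemble:
    """Load binary trajectories (DCD/NetCDF/XTC/...) via mdtraj, Cα only.

    Optional convenience behind the same :class:`TrajectoryEnsemble`
    contract; multi-model PDB remains the normative dialect.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover
        raise ImportError("binary trajectory input requires mdtraj") from exc
    replicas, labels = [], None
    for p in traj_paths:
        traj = md.load(str(p), top=str(topology))
        idx = traj.topology.select("name CA and protein")
        if idx.size == 0:
            raise StructureParseError(f"{p}: no CA atoms in topology selection")
        sub = traj.atom_slice(idx)
        labs = tuple(
            ResidueLabel(
                chain_id=chr(ord("A") + (a.residue.chain.index % 26)),
                crystal_number=int(a.residue.resSeq),
                residue_name=a.residue.name,
            )
            for a in sub.topology.atoms
        )
        if labels is None:
            labels = labs
        else:
            check_same_labels(labels, labs, str(p))
        replicas.append(np.asarray(sub.xyz, dtype=float) * 10.0)  # nm -> Å
    return TrajectoryEnsemble(labels, replicas)


# ---------------------------------------------------------------------------
# PDB writing


def _atom_line(serial, label, xyz, bfactor, occupancy=1.0):
    icode = label.insertion_code or " "
    return (
        f"ATOM  {serial:5d}  CA  {label.residue_name:>3.3s} {label.chain_id:1.1s}"
        f"{label.crystal_number:4d}{icode:1.1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"           C"
    )


def _clamp_bfactors(values, n) -> np.ndarray:
    b = np.asarray(values, dtype=float)
    if b.shape != (n,):
        raise ValueError(f"expected {n} B-factor values, got shape {b.shape}")
    if np.any(b > _MAX_PDB_BFACTOR):
        logger.warning(
            "%d B-factor value(s) exceed %.2f and were clamped for PDB output",
            int(np.sum(b > _MAX_PDB_BFACTOR)), _MAX_PDB_BFACTOR,
        )
    return np.clip(b, None, _MAX_PDB_BFACTOR)


def write_bfactor_pdb(frame: ConformationFrame, bfactors, path) -> None:
    """Write a Cα-only PDB with per-residue values in the B-factor column.

    Values are formatted to two decimals; anything above 999.99 is clamped
    with a warning (PDB fixed-width limit).
    """
    b = _clamp_bfactors(bfactors, frame.n_residues)
    with open(path, "w") as fh:
        for i, (lab, xyz) in enumerate(zip(frame.labels, frame.coords)):
            fh.write(_atom_line(i + 1, lab, xyz, b[i]) + "\n")
        fh.write("TER\nEND\n")


def write_ensemble_pdb(frames: Iterable[ConformationFrame], path, bfactors=None) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL per frame)."""
    frames = list(frames)
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            b = (
                _clamp_bfactors(bfactors, frame.n_residues)
                if bfactors is not None
                else np.zeros(frame.n_residues)
            )
            fh.write(f"MODEL     {m:4d}\n")
            for i, (lab, xyz) in enumerate(zip(frame.labels, frame.coords)):
                fh.write(_atom_line(i + 1, lab, xyz, b[i]) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Loop tables and numbering maps


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return int(value)


def _data_path(name: str):
    return resources.files("epiflex.data").joinpath(name)


def load_loop_table(path=None) -> list[LoopDefinition]:
    """Load a loop/epitope definition table (TSV).

    Columns: ``name``, ``epitope``, ``crystal_start``, ``crystal_end``,
    ``seq_start``, ``seq_end``. With no path, the packaged table of the
    twelve PR3 surface loops is returned.
    """
    src = str(path) if path is not None else _data_path("pr3_loops.tsv")
    with (open(src) if path is not None else src.open()) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    required = {"name", "epitope", "crystal_start", "crystal_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"loop table missing columns {required - set(df.columns)}")
    loops = []
    for row in df.itertuples(index=False):
        loops.append(
            LoopDefinition(
                name=row.name,
                epitope=int(row.epitope),
                crystal_start=parse_residue_id(row.crystal_start),
                crystal_end=parse_residue_id(row.crystal_end),
                seq_start=_opt_int(getattr(row, "seq_start", None)),
                seq_end=_opt_int(getattr(row, "seq_end", None)),
            )
        )
    names = [lp.name for lp in loops]
    if len(set(names)) != len(names):
        raise ValueError("loop names must be unique")
    return loops


class NumberingMap:
    """Bijective map between crystal and sequential residue numbering.

    Covered residues map both ways and round-trip exactly; queries outside
    the table raise :class:`~epiflex.errors.NumberingLookupError`.
    """

    def __init__(self, pairs: Iterable[tuple[tuple[int, str], int]]):
        self._c2s: dict[tuple[int, str], int] = {}
        self._s2c: dict[int, tuple[int, str]] = {}
        for crystal, seq in pairs:
            crystal = (int(crystal[0]), crystal[1].upper())
            seq = int(seq)
            if crystal in self._c2s or seq in self._s2c:
                raise ValueError(f"duplicate map entry {crystal} <-> {seq}")
            self._c2s[crystal] = seq
            self._s2c[seq] = crystal

    @classmethod
    def default(cls) -> "NumberingMap":
        """The packaged PR3 crystal <-> NCBI P24158.3 map."""
        with _data_path("pr3_numbering_map.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
        return cls(
            ((int(r.crystal_number), (r.insertion_code or "").strip().upper()
              if isinstance(r.insertion_code, str) else ""), int(r.sequence_number))
            for r in df.itertuples(index=False)
        )

    def __len__(self) -> int:
        return len(self._c2s)

    def crystal_keys(self):
        return sorted(self._c2s)

    def crystal_to_sequence(self, query) -> int:
        key = _as_crystal_key(query)
        try:
            return self._c2s[key]
        except KeyError:
            raise NumberingLookupError(
                f"crystal residue {key[0]}{key[1]} is not covered by the numbering map"
            ) from None

    def sequence_to_crystal(self, seq: int) -> tuple[int, str]:
        try:
            return self._s2c[int(seq)]
        except KeyError:
            raise NumberingLookupError(
                f"sequence residue {seq} is not covered by the numbering map"
            ) from None


def _as_crystal_key(query) -> tuple[int, str]:
    if isinstance(query, ResidueLabel):
        return (query.crystal_number, query.insertion_code)
    if isinstance(query, tuple) and len(query) == 2 and isinstance(query[0], int):
        return (int(query[0]), str(query[1]).upper())
    if isinstance(query, int):
        return (query, "")
    return parse_residue_id(query)


def map_numbering(query, direction: str = "crystal_to_sequence", table: NumberingMap | None = None):
    """Translate residue identifiers (or ``(start, end)`` ranges) between schemes.

    ``direction`` is ``"crystal_to_sequence"`` or ``"sequence_to_crystal"``.
    A range maps endpoint-wise. Round trips are the identity on every
    covered residue.
    """
    table = table if table is not None else NumberingMap.default()
    if direction == "crystal_to_sequence":
        fn = table.crystal_to_sequence
    elif direction == "sequence_to_crystal":
        fn = table.sequence_to_crystal
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(query, tuple) and len(query) == 2 and not isinstance(query[0], int):
        return (fn(query[0]), fn(query[1]))
    if (
        direction == "sequence_to_crystal"
        and isinstance(query, tuple)
        and len(query) == 2
        and all(isinstance(q, int) for q in query)
    ):
        return (fn(query[0]), fn(query[1]))
    return fn(query)


def fetch_pdb(pdb_id: str, dest_dir=None, timeout: float = 15.0) -> Path:
    """Download a PDB entry from the RCSB (needs network access).

    Returns the local path; reuses an existing download when present.
    """
    pdb_id = pdb_id.lower()
    dest_dir = Path(dest_dir) if dest_dir is not None else Path.cwd()
    dest = dest_dir / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
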