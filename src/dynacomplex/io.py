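"""Tabular and trajectory I/O.

Delimited-text tables are the interchange format for everything except
trajectories, which are read through mdtraj (PDB topology; XTC/DCD or
multi-model PDB frames) into :class:`TrajectoryFrames`, the package's
in-memory container (coordinates in nm, frame interval in ps).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or cannot be coerced."""


@dataclass
class ColumnSpec:
    name: str
    dtype: type = float
    required: bool = True


def load_table(path: str | Path, schema: list[ColumnSpec] | dict[str, type]) -> pd.DataFrame:
    """Load a delimited-text table with a header row and coerce columns.

    ``schema`` declares the expected columns and their types; extra
    columns are preserved untouched as annotations. Rows where a
    required column fails to parse are dropped (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(schema, dict):
        schema = [ColumnSpec(k, v) for k, v in schema.items()]
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has a header but no data rows")
    for col in schema:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{path}: missing required column {col.name!r}")
            continue
        coerced = pd.to_numeric(df[col.name], errors="coerce") if col.dtype in (float, int) \
            else df[col.name]
        if col.required:
            bad = coerced.isna()
            if bad.any():
                logger.warning("%s: dropped %d rows with unparseable %r",
                               path, int(bad.sum()), col.name)
                df = df.loc[~bad]
                coerced = coerced.loc[~bad]
        df[col.name] = coerced.astype(col.dtype)
    return df.reset_index(drop=True)


@dataclass
class TrajectoryFrames:
    """Coordinate frames plus atom metadata.

    coords: (n_frames, n_atoms, 3) in nm; frame_interval in ps;
    atoms: DataFrame with columns name, element, resid (1-based),
    resname, chain; box: (n_frames, 3) orthorhombic box lengths in nm
    or None.
    """

    coords: np.ndarray
    frame_interval: float  # ps
    atoms: pd.DataFrame
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0 ps")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom metadata does not match coordinate array")
        if (self.atoms["resid"] < 1).any():
            raise ValueError("residue indices must be 1-based and positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def times_ns(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval * 1e-3

    def heavy_mask(self) -> np.ndarray:
        return (self.atoms["element"].str.upper() != "H").to_numpy()


_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                 "P": 30.974}


def atom_masses(atoms: pd.DataFrame) -> np.ndarray:
    return np.array([_ELEMENT_MASS.get(str(e).upper(), 12.0) for e in atoms["element"]])


def _from_mdtraj(traj) -> TrajectoryFrames:
    top = traj.topology
    atoms = pd.DataFrame({
        "name": [a.name for a in top.atoms],
        "element": [a.element.symbol if a.element is not None else "C" for a in top.atoms],
        "resid": [a.residue.resSeq for a in top.atoms],
        "resname": [a.residue.name for a in top.atoms],
        "chain": [a.residue.chain.index for a in top.atoms],
    })
    if (atoms["resid"] < 1).any():  # some formats number from 0
        atoms["resid"] = atoms["resid"] - atoms["resid"].min() + 1
    box = None
    if traj.unitcell_lengths is not None:
        box = np.asarray(traj.unitcell_lengths, dtype=float)
    dt_ps = float(traj.timestep) if traj.n_frames > 1 and traj.timestep > 0 else 1.0
    return TrajectoryFrames(np.asarray(traj.xyz, dtype=float), dt_ps, atoms, box)


def load_trajectory(coords_path: str | Path, topology_path: str | Path | None = None,
                    frame_interval: float | None = None) -> TrajectoryFrames:
    """Load a trajectory (XTC/DCD/PDB) into :class:`TrajectoryFrames`.

    ``frame_interval`` (ps) overrides whatever interval the file
    declares; formats that carry no time information default to 1 ps.
    """
    import mdtraj as md

    coords_path = Path(coords_path)
    try:
        if topology_path is None:
            traj = md.load(str(coords_path))
        else:
            traj = md.load(str(coords_path), top=str(topology_path))
    except (ValueError, IndexError) as exc:
        raise ValueError(
            f"failed to read {coords_path} "
            f"(atom-count mismatch with topology?): {exc}") from exc
    frames = _from_mdtraj(traj)
    if frame_interval is not None:
        frames.frame_interval = float(frame_interval)
    return frames


def write_trajectory(frames: TrajectoryFrames, path: str | Path) -> None:
    """Write frames as a multi-model PDB (text, mdtraj-readable)."""
    import mdtraj as md

    top = md.Topology()
    chain_objs: dict = {}
    res_objs: dict = {}
    for i, row in frames.atoms.iterrows():
        ch = row["chain"]
        if ch not in chain_objs:
            chain_objs[ch] = top.add_chain()
        key = (ch, row["resid"])
        if key not in res_objs:
            res_objs[key] = top.add_residue(row["resname"], chain_objs[ch],
                                            resSeq=int(row["resid"]))
        el = md.element.get_by_symbol(str(row["element"]))
        top.add_atom(row["name"], el, res_objs[key])
    traj = md.Trajectory(frames.coords, top,
                         time=frames.times_ns() * 1e3,
                         unitcell_lengths=frames.box,
                         unitcell_angles=None if frames.box is None
                         else np.full((frames.n_frames, 3), 90.0))
    traj.save_pdb(str(path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
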