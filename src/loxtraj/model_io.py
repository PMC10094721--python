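"""Read multi-model PDB trajectories and selection configs; write reports.

The multi-model PDB reader is built on biotite; one ``MODEL`` record becomes
one :class:`~loxtraj.core.Frame`.  Selection configs are YAML or JSON files
mapping semantic roles (substrate carbons, cofactor atoms, contact groups,
domain residue ranges) to 1-based PDB serials, converted to 0-based indices
on load and validated against the topology.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    DescriptorSeries,
    Frame,
    SelectionConfig,
    SelectionError,
    Topology,
    Trajectory,
    TrajectoryFormatError,
    carbon_number,
)

__all__ = [
    "read_multimodel_pdb",
    "iter_frames",
    "write_multimodel_pdb",
    "load_selection_config",
    "write_report",
    "read_series",
]

# Hydrogens closer than this to a carbon are taken as bonded to it when the
# config does not enumerate them (MD-derived PDBs name hydrogens inconsistently).
H_BOND_CUTOFF = 1.2


def read_multimodel_pdb(path: Union[str, Path]) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    A single-structure file yields a one-frame trajectory.  Models with
    inconsistent atom counts raise :class:`TrajectoryFormatError` naming the
    offending model.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise TrajectoryFormatError(f"{path} contains no models")

    first = pdb.get_structure(model=1)
    topology = Topology(
        atom_names=list(first.atom_name),
        residue_names=list(first.res_name),
        residue_ids=[int(r) for r in first.res_id],
        chain_ids=list(first.chain_id),
    )
    frames = [Frame(coords=np.array(first.coord, dtype=float), frame_id=0)]
    for m in range(2, n_models + 1):
        arr = pdb.get_structure(model=m)
        if arr.array_length() != topology.n_atoms:
            raise TrajectoryFormatError(
                f"model {m} has {arr.array_length()} atoms, "
                f"model 1 has {topology.n_atoms}"
            )
        frames.append(Frame(coords=np.array(arr.coord, dtype=float), frame_id=m - 1))
    return Trajectory(topology=topology, frames=frames)


def iter_frames(path: Union[str, Path]):
    """Stream (topology, frame) pairs from a multi-model PDB one at a time."""
    traj = read_multimodel_pdb(path)
    for fr in traj:
        yield traj.topology, fr


def write_multimodel_pdb(trajectory: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a multi-model PDB (fixture emission)."""
    topo = trajectory.topology
    n = topo.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = np.array(topo.atom_names)
    template.res_name = np.array(topo.residue_names)
    template.res_id = np.array(topo.residue_ids)
    template.chain_id = np.array(topo.chain_ids if topo.chain_ids else ["A"] * n)
    template.element = np.array([_guess_element(a) for a in topo.atom_names])
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.AtomArrayStack(trajectory.n_frames, n)
    for cat in ("atom_name", "res_name", "res_id", "chain_id", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.stack([fr.coords for fr in trajectory.frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in ("FE", "CL", "BR"):
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# selection config


def load_selection_config(
    path: Union[str, Path],
    topology: Topology,
    frame: Optional[Frame] = None,
) -> SelectionConfig:
    """Load and validate a YAML/JSON selection config against ``topology``.

    Atom references in the file are 1-based PDB serials.  If
    ``substrate_hydrogens`` is not enumerated and a ``frame`` is given,
    hydrogens are resolved by connectivity (< 1.2 angstrom to the parent
    carbon).
    """
    raw = yaml.safe_load(Path(path).read_text())
    return resolve_selection(raw, topology, frame=frame)


def resolve_selection(
    raw: dict, topology: Topology, frame: Optional[Frame] = None
) -> SelectionConfig:
    """Resolve an in-memory selection mapping (1-based serials) to a
    validated :class:`SelectionConfig` (0-based indices)."""
    n = topology.n_atoms

    def to_index(serial, role: str) -> int:
        idx = int(serial) - 1
        if not 0 <= idx < n:
            raise SelectionError(
                f"role {role!r}: atom serial {serial} outside topology (1..{n})"
            )
        return idx

    carbons_raw = raw.get("substrate_carbons", {})
    if not carbons_raw:
        raise SelectionError("selection config must define substrate_carbons")
    substrate_carbons = {
        name: to_index(serial, f"substrate_carbons.{name}")
        for name, serial in carbons_raw.items()
    }
    numbers = sorted(carbon_number(name) for name in substrate_carbons)
    if numbers != list(range(numbers[0], numbers[-1] + 1)):
        raise SelectionError("substrate carbons must be consecutive along the chain")

    hydrogens = {
        cname: [to_index(s, f"substrate_hydrogens.{cname}") for s in serials]
        for cname, serials in raw.get("substrate_hydrogens", {}).items()
    }
    if not hydrogens and frame is not None:
        hydrogens = resolve_hydrogens(topology, frame, substrate_carbons)

    cofactor = {
        role: to_index(s, f"cofactor.{role}") for role, s in raw.get("cofactor", {}).items()
    }
    o2 = None
    if raw.get("o2"):
        o2 = {role: to_index(s, f"o2.{role}") for role, s in raw["o2"].items()}
    contact_groups = {
        name: [to_index(s, f"contact_groups.{name}") for s in serials]
        for name, serials in raw.get("contact_groups", {}).items()
    }

    domain_ranges = {}
    res_ids = np.asarray(topology.residue_ids)
    for name, (lo, hi) in raw.get("domain_ranges", {}).items():
        members = np.nonzero((res_ids >= int(lo)) & (res_ids <= int(hi)))[0]
        if members.size == 0:
            raise SelectionError(f"domain range {name!r} ({lo}-{hi}) selects no atoms")
        domain_ranges[name] = [int(i) for i in members]

    double_bonds = []
    for pair in raw.get("double_bonds", []):
        a, b = pair
        na, nb = carbon_number(a), carbon_number(b)
        if abs(na - nb) != 1:
            raise SelectionError(f"double bond ({a}, {b}) is non-adjacent")
        for cname in (a, b):
            if cname not in substrate_carbons:
                raise SelectionError(f"double bond references unknown carbon {cname!r}")
        double_bonds.append((a, b) if na < nb else (b, a))

    return SelectionConfig(
        substrate_carbons=substrate_carbons,
        substrate_hydrogens=hydrogens,
        cofactor=cofactor,
        o2=o2,
        contact_groups=contact_groups,
        domain_ranges=domain_ranges,
        double_bonds=double_bonds,
        contacts=list(raw.get("contacts", [])),
        stereo=dict(raw.get("stereo", {})),
    )


def resolve_hydrogens(
    topology: Topology, frame: Frame, substrate_carbons: dict[str, int]
) -> dict[str, list[int]]:
    """Attach hydrogens to substrate carbons by distance (< 1.2 angstrom)."""
    h_idx = [
        i for i, name in enumerate(topology.atom_names) if name.strip().upper().startswith("H")
    ]
    if not h_idx:
        return {}
    h_coords = frame.coords[h_idx]
    out: dict[str, list[int]] = {}
    for cname, ci in substrate_carbons.items():
        d = np.linalg.norm(h_coords - frame.coords[ci], axis=1)
        attached = [h_idx[k] for k in np.nonzero(d < H_BOND_CUTOFF)[0]]
        if attached:
            out[cname] = attached
    return out


# ---------------------------------------------------------------------------
# report writing


def write_report(series_and_reports: dict, out_dir: Union[str, Path]) -> dict:
    """Write analysis outputs: CSV per DescriptorSeries, JSON per mapping.

    Returns a manifest {logical name -> file path}.  Column order and float
    formatting are deterministic; re-reading reproduces values exactly
    (floats serialized via ``repr``-roundtrip-safe formatting).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest: dict[str, str] = {}
    for name in sorted(series_and_reports):
        obj = series_and_reports[name]
        if isinstance(obj, DescriptorSeries):
            path = out_dir / f"{name}.csv"
            df = pd.DataFrame(
                {"frame_id": obj.frame_ids, "value": obj.values, "unit": obj.unit}
            )
            df.to_csv(path, index=False, float_format="%.17g")
        else:
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
        manifest[name] = str(path)
    return manifest


def read_series(path: Union[str, Path]) -> DescriptorSeries:
    """Read back a DescriptorSeries CSV written by :func:`write_report`."""
    df = pd.read_csv(path, float_precision="round_trip")
    unit = str(df["unit"].iloc[0]) if len(df) else "unitless"
    return DescriptorSeries(
        name=Path(path).stem,
        frame_ids=df["frame_id"].to_numpy(),
        values=df["value"].to_numpy(),
        unit=unit,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return None
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj
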