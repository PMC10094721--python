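"""Synthetic structures and trajectories with known ground truth.

The generator emulates the statistical structure of the MD output the
analyses were designed for, without any force field:

* a DHA-like 22-carbon chain with six methylene-interrupted double bonds
  (delta-4,7,10,13,16,19, all Z by default) built at ideal geometry
  (C=C 1.33 A, C-C 1.50 A, C-H 1.09 A, sp2 angles 120 deg, sp3 109.47 deg);
* a mock Fe(III)-OH- site whose hydroxide oxygen is placed by least squares
  at prescribed distances from the candidate bis-allylic hydrogens;
* two rod-like "domains" as anisotropic Gaussian point clouds with exact
  center separation and prescribed principal-axis angle;
* per-frame control of the inter-plane angles Pi(C10C11C12)/Pi(C12C13C14)
  and Pi(C7C8C9)/Pi(C9C10C11), scheduled conformational events, and i.i.d.
  Gaussian coordinate noise added after everything else, so the ground
  truth is always the noiseless value.

The inter-plane angle is controlled exactly: with the first span torsion
anti (180 deg), the plane angle equals 180 deg minus the torsion about the
central-to-distal bond, so a target angle theta is realized by setting that
torsion to 180 - theta.  Planarizing the span after "abstraction" then
snaps the torsion to the nearer of 0/180, which yields the E configuration
exactly when theta < 90 deg - the stereochemistry criterion under study,
true here by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .core import Frame, SelectionConfig, Topology, Trajectory
from . import model_io

__all__ = [
    "BOND_CC_DOUBLE",
    "BOND_CC_SINGLE",
    "BOND_CH",
    "DHA_DOUBLE_BONDS",
    "Fragment",
    "DomainGeometry",
    "Event",
    "SyntheticSpec",
    "SyntheticResult",
    "build_polyene_fragment",
    "abstraction_fragment",
    "place_cofactor",
    "build_two_domain_cloud",
    "o2_candidate_positions",
    "make_trajectory",
    "make_selection_raw",
    "mirror_fragment",
]

BOND_CC_DOUBLE = 1.33
BOND_CC_SINGLE = 1.50
BOND_CH = 1.09
BOND_CO_CARBOXYLATE = 1.25
BOND_O_FE = 1.90
BOND_O_H = 0.97
ANGLE_SP2 = 120.0
ANGLE_SP3 = 109.47
N_CARBONS = 22

# first carbon of each double bond in fatty-acid numbering (C1 = carboxyl)
DHA_DOUBLE_BONDS = (4, 7, 10, 13, 16, 19)

# default inter-plane angle targets: the C10C11C12/C12C13C14 pair below 90
# (the 12E-competent regime dominating the closed-conformation ensemble) and
# the C7C8C9/C9C10C11 pair above 90 (the 11Z regime)
DEFAULT_PLANE_ANGLES = {"C12": 75.0, "C9": 115.0}

# precatalytic fractions observed for the three candidate hydrogens
DEFAULT_PRECAT_FRACTIONS = {"H12": 0.74, "H9": 0.73, "H15": 0.10}

_NEAR_RANGE = (2.8, 3.6)  # angstrom, draw for precatalytic frames
_FAR_RANGE = (4.6, 5.8)  # angstrom, draw for non-precatalytic frames


def _place_atom(a, b, c, r: float, theta: float, tau: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: new atom at distance r from c,
    angle theta (deg) at c w.r.t. b, torsion tau (deg) about b-c w.r.t a."""
    theta = np.radians(theta)
    tau = np.radians(tau)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(tau), r * np.sin(theta) * np.sin(tau)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class Fragment:
    """A built structure: topology + one coordinate set + ground truth."""

    topology: Topology
    coords: np.ndarray
    info: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def frame(self, frame_id: int = 0) -> Frame:
        return Frame(coords=self.coords.copy(), frame_id=frame_id)

    def index_of(self, atom_name: str) -> int:
        return self.topology.atom_names.index(atom_name)


def _double_bond_set(bond_configs: dict[int, str]) -> set[int]:
    return set(bond_configs)


def _normalize_bond_configs(bond_configs: Optional[dict]) -> dict[int, str]:
    configs = {b: "Z" for b in DHA_DOUBLE_BONDS}
    if bond_configs:
        for key, val in bond_configs.items():
            k = int(str(key).lstrip("C").lstrip("delta"))
            if k not in configs:
                raise ValueError(f"unknown double bond starting at C{k} (expected {DHA_DOUBLE_BONDS})")
            if val not in ("Z", "E"):
                raise ValueError(f"bond config must be 'Z' or 'E', got {val!r}")
            configs[k] = val
    return configs


def build_polyene_fragment(
    bond_configs: Optional[dict] = None,
    plane_angles: Optional[dict[str, float]] = None,
    torsion_overrides: Optional[dict[int, float]] = None,
    radical_center: Optional[int] = None,
) -> Fragment:
    """Build the DHA-like hexaene chain at ideal geometry.

    ``bond_configs`` maps the first carbon of a double bond (4, 7, 10, 13,
    16, 19) to "Z" or "E".  ``plane_angles`` sets the target inter-plane
    angle of the C12 and/or C9 span (degrees in (0, 180)).
    ``torsion_overrides`` maps a single-bond first-carbon index b to the
    torsion (deg) of the dihedral C(b-1)-C(b)-C(b+1)-C(b+2).  With
    ``radical_center`` the given carbon becomes a planar sp2 radical center
    carrying a single hydrogen (post-abstraction geometry); the caller is
    responsible for snapping the span torsions (see
    :func:`abstraction_fragment`).
    """
    configs = _normalize_bond_configs(bond_configs)
    plane_angles = dict(plane_angles or {})
    dbl_first = _double_bond_set(configs)

    def is_sp2(i: int) -> bool:
        if i == radical_center:
            return True
        return i in dbl_first or (i - 1) in dbl_first or i == 1

    # torsion assigned to bond (b, b+1): dihedral C(b-1)-Cb-C(b+1)-C(b+2);
    # single bonds default to anti (the extended chain is free of nonbonded
    # clashes, unlike skew/helical defaults)
    torsions: dict[int, float] = {}
    for b in range(2, N_CARBONS - 1):
        if b in dbl_first:
            torsions[b] = 0.0 if configs[b] == "Z" else 180.0
        else:
            torsions[b] = 180.0
    # exact plane-angle control for the two bis-allylic spans
    for span_center, (psi1_bond, psi2_bond) in (("C12", (11, 12)), ("C9", (8, 9))):
        if span_center in plane_angles:
            theta = float(plane_angles[span_center])
            if not 0.0 < theta < 180.0:
                raise ValueError(f"plane angle target must be in (0, 180), got {theta}")
            torsions[psi1_bond] = 180.0
            torsions[psi2_bond] = 180.0 - theta
    if torsion_overrides:
        for b, tau in torsion_overrides.items():
            if b not in torsions:
                raise ValueError(f"no torsion attached to bond ({b}, {b + 1})")
            torsions[int(b)] = float(tau)

    def bond_length(b: int) -> float:
        return BOND_CC_DOUBLE if b in dbl_first else BOND_CC_SINGLE

    def angle_at(i: int) -> float:
        return ANGLE_SP2 if is_sp2(i) else ANGLE_SP3

    # carbons
    carbons = np.zeros((N_CARBONS, 3))
    carbons[1] = [bond_length(1), 0.0, 0.0]
    ang2 = np.radians(angle_at(2))
    carbons[2] = carbons[1] + bond_length(2) * np.array(
        [-np.cos(ang2), np.sin(ang2), 0.0]
    )
    for i in range(3, N_CARBONS):
        # placing 0-based atom i = 1-based C(i+1): bond key i, angle at C(i),
        # torsion about bond (C(i-1), C(i))
        carbons[i] = _place_atom(
            carbons[i - 3],
            carbons[i - 2],
            carbons[i - 1],
            bond_length(i),
            angle_at(i),
            torsions[i - 1],
        )

    names = [f"C{i + 1}" for i in range(N_CARBONS)]
    coords = [carbons[i] for i in range(N_CARBONS)]

    # carboxylate oxygens on C1, in the C1-C2-C3 plane
    e1 = carbons[1] - carbons[0]
    e1 = e1 / np.linalg.norm(e1)
    nrm = np.cross(e1, carbons[2] - carbons[1])
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, e1)
    for tag, s in (("O1A", 1.0), ("O1B", -1.0)):
        d = np.cos(np.radians(120.0)) * e1 + s * np.sin(np.radians(120.0)) * m
        names.append(tag)
        coords.append(carbons[0] + BOND_CO_CARBOXYLATE * d)

    # hydrogens
    hydrogens: dict[str, list[int]] = {}
    half = np.radians(ANGLE_SP3 / 2.0)
    for i in range(1, N_CARBONS):  # C1 carries no H (carboxyl)
        ci = carbons[i]
        cname = f"C{i + 1}"
        if i == N_CARBONS - 1:  # terminal methyl: three H by NeRF
            for k, tau in enumerate((60.0, 180.0, -60.0)):
                h = _place_atom(carbons[i - 2], carbons[i - 1], ci, BOND_CH, ANGLE_SP3, tau)
                names.append(f"H{i + 1}{'ABC'[k]}")
                coords.append(h)
                hydrogens.setdefault(cname, []).append(len(coords) - 1)
            continue
        b1 = carbons[i - 1] - ci
        b1 = b1 / np.linalg.norm(b1)
        b2 = carbons[i + 1] - ci
        b2 = b2 / np.linalg.norm(b2)
        bis = -(b1 + b2)
        bis = bis / np.linalg.norm(bis)
        if is_sp2(i + 1):  # 0-based carbon i is C(i+1) 1-based
            names.append(f"H{i + 1}")
            coords.append(ci + BOND_CH * bis)
            hydrogens.setdefault(cname, []).append(len(coords) - 1)
        else:
            perp = np.cross(b1, b2)
            perp = perp / np.linalg.norm(perp)
            for tag, s in (("A", 1.0), ("B", -1.0)):
                h = ci + BOND_CH * (np.cos(half) * bis + s * np.sin(half) * perp)
                names.append(f"H{i + 1}{tag}")
                coords.append(h)
                hydrogens.setdefault(cname, []).append(len(coords) - 1)

    coords = np.asarray(coords)
    n = len(names)
    topology = Topology(
        atom_names=names,
        residue_names=["DHA"] * n,
        residue_ids=[9998] * n,
        chain_ids=["S"] * n,
    )
    info = {
        "bond_configs": {f"C{b}=C{b + 1}": configs[b] for b in sorted(configs)},
        "hydrogens": hydrogens,
        "torsions": {int(k): float(v) for k, v in torsions.items()},
        "plane_angles": {k: float(v) for k, v in plane_angles.items()},
        "radical_center": radical_center,
    }
    return Fragment(topology=topology, coords=coords, info=info)


_SPANS = {12: ("C12", 12, (10, 14), (9, 15)), 9: ("C9", 9, (7, 11), (6, 12))}


def abstraction_fragment(
    theta: float,
    span_center: int = 12,
    bond_configs: Optional[dict] = None,
    plane_angles: Optional[dict[str, float]] = None,
) -> Fragment:
    """Post-abstraction planar pentadienyl geometry for one frame.

    The span torsion 180 - theta is snapped to the nearer of {0, 180}:
    theta < 90 snaps to 180 (-> E), theta >= 90 snaps to 0 (-> Z); the tie
    at exactly 90 is assigned Z.  Returns the radical fragment (one
    methylene hydrogen removed at the span center) with the resulting
    two-letter label in ``info["abstraction_label"]``.
    """
    if span_center not in _SPANS:
        raise ValueError("span_center must be 12 or 9")
    key, center, (lo, hi), flanks = _SPANS[span_center]
    psi2 = 180.0 - float(theta)
    snapped_e = abs(psi2) > 90.0
    pa = dict(plane_angles or {})
    pa.pop(key, None)
    overrides = {center - 1: 180.0, center: 180.0 if snapped_e else 0.0}
    frag = build_polyene_fragment(
        bond_configs=bond_configs,
        plane_angles=pa,
        torsion_overrides=overrides,
        radical_center=center,
    )
    first = frag.info["bond_configs"][f"C{lo}=C{lo + 1}"]
    frag.info["abstraction_label"] = first + ("E" if snapped_e else "Z")
    frag.info["abstraction_span"] = [f"C{c}" for c in range(lo, hi + 1)]
    frag.info["theta"] = float(theta)
    return frag


def mirror_fragment(fragment: Fragment) -> Fragment:
    """Reflect all coordinates through the x=0 plane (improper operation):
    Z/E labels are unchanged, every chirality/prochirality label flips."""
    coords = fragment.coords.copy()
    coords[:, 0] *= -1.0
    return Fragment(topology=fragment.topology, coords=coords, info=dict(fragment.info))


# ---------------------------------------------------------------------------
# cofactor placement


def place_cofactor(
    fragment: Fragment,
    targets: dict[int, float],
    parent_carbons: Optional[dict[int, int]] = None,
) -> tuple[Fragment, dict]:
    """Append a mock Fe(III)-OH- site with the hydroxide oxygen placed so
    each listed hydrogen sits at its target distance.

    ``targets`` maps hydrogen atom index -> target distance (angstrom).
    With a single target the placement is exact (along the C-H direction if
    ``parent_carbons`` supplies the parent, else radially from the
    centroid); with several targets the oxygen solves the least-squares
    trilateration problem and the residual is reported - infeasible target
    sets yield the closest achievable geometry rather than an error.
    """
    if not targets:
        raise ValueError("place_cofactor: at least one target required")
    for h, t in targets.items():
        if t <= 0:
            raise ValueError(f"target distance for atom {h} must be positive, got {t}")
    h_idx = sorted(targets)
    pts = fragment.coords[h_idx]
    tgt = np.array([targets[h] for h in h_idx], dtype=float)

    if len(h_idx) == 1:
        h = h_idx[0]
        if parent_carbons and h in parent_carbons:
            direction = fragment.coords[h] - fragment.coords[parent_carbons[h]]
        else:
            direction = fragment.coords[h] - fragment.coords.mean(axis=0)
        nd = np.linalg.norm(direction)
        direction = direction / nd if nd > 1e-9 else np.array([0.0, 0.0, 1.0])
        o_pos = fragment.coords[h] + tgt[0] * direction
        residual = 0.0
    else:
        def f(x):
            return np.linalg.norm(pts - x, axis=1) - tgt

        centroid = pts.mean(axis=0)
        starts = [centroid + tgt.mean() * u for u in _DEFAULT_DIRECTIONS]
        best = None
        method = "lm" if len(h_idx) >= 3 else "trf"
        for x0 in starts:
            sol = least_squares(f, x0, method=method)
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost < 1e-16:  # exact trilateration found
                break
        o_pos = best.x
        residual = float(np.sqrt(np.mean(f(o_pos) ** 2)))

    # Fe away from the substrate, hydroxide H off-axis
    away = o_pos - fragment.coords.mean(axis=0)
    away = away / max(np.linalg.norm(away), 1e-9)
    fe_pos = o_pos + BOND_O_FE * away
    perp = np.cross(away, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(away, np.array([0.0, 1.0, 0.0]))
    perp = perp / np.linalg.norm(perp)
    h_pos = o_pos + BOND_O_H * perp

    names = fragment.topology.atom_names + ["OC", "HOC", "FE"]
    res_names = fragment.topology.residue_names + ["COF"] * 3
    res_ids = fragment.topology.residue_ids + [9999] * 3
    chains = (fragment.topology.chain_ids or ["S"] * fragment.n_atoms) + ["C"] * 3
    coords = np.vstack([fragment.coords, o_pos, h_pos, fe_pos])
    topo = Topology(names, res_names, res_ids, chains)
    achieved = {h: float(np.linalg.norm(fragment.coords[h] - o_pos)) for h in h_idx}
    placement = {
        "achieved": achieved,
        "targets": {int(h): float(t) for h, t in targets.items()},
        "residual": residual,
        "o_index": len(names) - 3,
        "h_index": len(names) - 2,
        "fe_index": len(names) - 1,
    }
    info = dict(fragment.info)
    info["cofactor_placement"] = placement
    return Fragment(topology=topo, coords=coords, info=info), placement


# ---------------------------------------------------------------------------
# two-domain clouds


@dataclass
class DomainGeometry:
    """Two rod-like domains: exact center separation, prescribed angle
    between the longest principal axes.  Defaults are the closed-state
    metrics of the two-domain enzyme (42.3 angstrom, 38.2 deg)."""

    center_distance: float = 42.3
    axis_angle: float = 38.2
    points_per_domain: int = 500
    aspect_ratio: float = 10.0
    sigma_short: float = 1.0

    def __post_init__(self) -> None:
        if self.points_per_domain < 4:
            raise ValueError("points per domain must be >= 4")
        if self.aspect_ratio <= 1.0:
            raise ValueError("aspect ratio must exceed 1 (axis ambiguous otherwise)")
        if not 0.0 <= self.axis_angle <= 90.0:
            raise ValueError("axis angle must be in [0, 90] (axes are unsigned)")


def _sample_rod(rng: np.random.Generator, geom: DomainGeometry) -> np.ndarray:
    """Centered anisotropic Gaussian rod with long axis along x."""
    sig = np.array(
        [geom.aspect_ratio * geom.sigma_short, geom.sigma_short, geom.sigma_short]
    )
    pts = rng.normal(size=(geom.points_per_domain, 3)) * sig
    return pts - pts.mean(axis=0)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


def build_two_domain_cloud(
    geom: DomainGeometry,
    seed: Union[int, np.random.Generator] = 0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Fragment:
    """Two anisotropic Gaussian clouds with centers exactly
    ``center_distance`` apart and long principal axes at ``axis_angle``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float)
    cloud_a = _sample_rod(rng, geom) + origin
    cloud_b = _sample_rod(rng, geom) @ _rot_z(geom.axis_angle).T
    cloud_b = cloud_b - cloud_b.mean(axis=0) + origin + np.array(
        [geom.center_distance, 0.0, 0.0]
    )
    npts = geom.points_per_domain
    names = ["CA"] * (2 * npts)
    res_names = ["DMA"] * npts + ["DMB"] * npts
    res_ids = list(range(1, npts + 1)) + list(range(5001, 5001 + npts))
    chains = ["A"] * npts + ["B"] * npts
    coords = np.vstack([cloud_a, cloud_b])
    topo = Topology(names, res_names, res_ids, chains)
    info = {
        "center_distance": geom.center_distance,
        "axis_angle": geom.axis_angle,
        "domain_a": list(range(npts)),
        "domain_b": list(range(npts, 2 * npts)),
    }
    return Fragment(topology=topo, coords=coords, info=info)


# ---------------------------------------------------------------------------
# O2 candidate placement

_AXES = [
    np.array(v, dtype=float)
    for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
]
_BISECTORS = [
    np.array(v, dtype=float) / np.sqrt(2.0)
    for v in [(1, 1, 0), (-1, -1, 0), (1, 0, 1), (-1, 0, -1), (0, 1, 1), (0, -1, -1)]
]
_DEFAULT_DIRECTIONS = _AXES + _BISECTORS


def o2_candidate_positions(
    frame: Frame,
    center_atom: int,
    radius: float = 3.0,
    direction_set: Optional[Sequence[Sequence[float]]] = None,
) -> np.ndarray:
    """Candidate O2 positions at exactly ``radius`` from ``center_atom``
    along the configured directions.

    The default set is the six Cartesian semi-axes plus one bisector pair
    per coordinate plane (12 positions); the exact sign convention of the
    published placement is ambiguous, so the set is configurable.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dirs = _DEFAULT_DIRECTIONS if direction_set is None else [
        np.asarray(d, dtype=float) for d in direction_set
    ]
    if len(dirs) == 0:
        raise ValueError("direction set must be non-empty")
    center = frame.coords[center_atom]
    out = []
    for d in dirs:
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("zero direction vector")
        out.append(center + radius * d / norm)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Event:
    """A scheduled parameter change applied from ``frame`` onward."""

    frame: int
    parameter: str
    value: float


_EVENT_PARAMS = (
    "center_distance",
    "axis_angle",
    "plane_angle_C12",
    "plane_angle_C9",
    "cofactor_target_H9",
    "cofactor_target_H12",
    "cofactor_target_H15",
)


@dataclass
class SyntheticSpec:
    """Everything the trajectory generator needs, with study-condition
    defaults: all-Z DHA bonds, 12E-competent C12-span regime, precatalytic
    fractions 0.74/0.73/0.10 for H12/H9/H15."""

    n_frames: int = 100
    seed: int = 0
    noise_sigma: float = 0.0
    bond_configs: Optional[dict] = None
    plane_angles: dict = field(default_factory=lambda: dict(DEFAULT_PLANE_ANGLES))
    regime_fractions: Optional[dict[str, float]] = None
    precatalytic_fractions: Optional[dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRECAT_FRACTIONS)
    )
    cofactor_targets: Optional[dict[str, float]] = None
    domain_geometry: Optional[DomainGeometry] = None
    events: list[Event] = field(default_factory=list)
    emit_abstraction: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.cofactor_targets is None and not self.precatalytic_fractions:
            raise ValueError(
                "spec needs cofactor_targets or precatalytic_fractions "
                "(the generator always places the cofactor)"
            )
        for ev in self.events:
            if not 0 <= ev.frame < self.n_frames:
                raise ValueError(f"event frame {ev.frame} outside [0, {self.n_frames})")
            if ev.parameter not in _EVENT_PARAMS:
                raise ValueError(f"unknown event parameter {ev.parameter!r}")


@dataclass
class GroundTruth:
    """Noiseless per-frame values of every generator-controlled descriptor."""

    global_info: dict = field(default_factory=dict)
    frames: list[dict] = field(default_factory=list)

    def fraction(self, key: str) -> float:
        vals = [fr[key] for fr in self.frames]
        return float(np.mean([bool(v) for v in vals]))

    def series(self, key: str) -> np.ndarray:
        return np.array([fr[key] for fr in self.frames])

    def to_dict(self) -> dict:
        return {"global": self.global_info, "frames": self.frames}

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


@dataclass
class SyntheticResult:
    trajectory: Trajectory
    ground_truth: GroundTruth
    selection: SelectionConfig
    selection_raw: dict
    abstraction_trajectory: Optional[Trajectory] = None


_CANDIDATES = ("H9", "H12", "H15")


def make_trajectory(spec: SyntheticSpec) -> SyntheticResult:
    """Deterministic synthetic trajectory with frame-by-frame ground truth.

    Per frame: the chain is rebuilt with the current plane-angle targets,
    the hydroxide oxygen is placed against the current candidate-hydrogen
    distance targets (the closest hydrogen of each candidate methylene is
    constrained, iterating the least-squares placement until the closest-H
    choice is stable), domains (if any) are laid down with the current
    center distance and axis angle, events are applied, and only then is
    Gaussian noise added - ground truth records the pre-noise values.
    """
    rng = np.random.default_rng(spec.seed)
    events_by_frame: dict[int, list[Event]] = {}
    for ev in spec.events:
        events_by_frame.setdefault(ev.frame, []).append(ev)

    # mutable per-parameter state
    plane_state = dict(spec.plane_angles)
    target_state: dict[str, Optional[float]] = {c: None for c in _CANDIDATES}
    if spec.cofactor_targets:
        for cand, t in spec.cofactor_targets.items():
            target_state[cand] = float(t)
    geom = spec.domain_geometry
    center_distance = geom.center_distance if geom else None
    axis_angle = geom.axis_angle if geom else None
    frozen_targets = {c: target_state[c] is not None for c in _CANDIDATES}
    frozen_planes = {k: False for k in ("C12", "C9")}

    base_clouds = None
    if geom is not None:
        base_clouds = (_sample_rod(rng, geom), _sample_rod(rng, geom))

    frames: list[Frame] = []
    abs_frames: list[Frame] = []
    truth = GroundTruth(
        global_info={
            "seed": spec.seed,
            "noise_sigma": spec.noise_sigma,
            "n_frames": spec.n_frames,
            "plane_angles": dict(spec.plane_angles),
            "precatalytic_fractions": dict(spec.precatalytic_fractions or {}),
        }
    )
    topology = None
    abs_topology = None
    selection = None
    selection_raw = None

    for f in range(spec.n_frames):
        for ev in events_by_frame.get(f, []):
            if ev.parameter == "center_distance":
                center_distance = float(ev.value)
            elif ev.parameter == "axis_angle":
                axis_angle = float(ev.value)
            elif ev.parameter.startswith("plane_angle_"):
                key = ev.parameter.split("_")[-1]
                plane_state[key] = float(ev.value)
                frozen_planes[key] = True
            elif ev.parameter.startswith("cofactor_target_"):
                cand = ev.parameter.split("_")[-1]
                target_state[cand] = float(ev.value)
                frozen_targets[cand] = True

        # per-frame plane-angle regime draws
        for key in ("C12", "C9"):
            if (
                spec.regime_fractions
                and key in spec.regime_fractions
                and not frozen_planes[key]
            ):
                below = rng.random() < spec.regime_fractions[key]
                plane_state[key] = (
                    rng.uniform(50.0, 85.0) if below else rng.uniform(95.0, 130.0)
                )

        # per-frame candidate-distance draws
        frame_targets: dict[str, float] = {}
        for cand in _CANDIDATES:
            if frozen_targets[cand] and target_state[cand] is not None:
                frame_targets[cand] = target_state[cand]
            elif spec.precatalytic_fractions and cand in spec.precatalytic_fractions:
                near = rng.random() < spec.precatalytic_fractions[cand]
                lo, hi = _NEAR_RANGE if near else _FAR_RANGE
                frame_targets[cand] = float(rng.uniform(lo, hi))
            elif target_state[cand] is not None:
                frame_targets[cand] = target_state[cand]

        frag = build_polyene_fragment(
            bond_configs=spec.bond_configs, plane_angles=plane_state
        )
        hyds = frag.info["hydrogens"]
        # constrain the closest hydrogen of each candidate; iterate until the
        # closest-H choice under the solved placement is stable
        chosen = {cand: hyds[f"C{cand[1:]}"][0] for cand in frame_targets}
        placement = None
        with_cof = frag
        for _ in range(4):
            with_cof, placement = place_cofactor(
                frag, {chosen[cand]: frame_targets[cand] for cand in frame_targets}
            )
            o_pos = with_cof.coords[placement["o_index"]]
            new_chosen = {}
            stable = True
            for cand in frame_targets:
                hs = hyds[f"C{cand[1:]}"]
                d = [np.linalg.norm(frag.coords[h] - o_pos) for h in hs]
                pick = hs[int(np.argmin(d))]
                new_chosen[cand] = pick
                stable = stable and pick == chosen[cand]
            chosen = new_chosen
            if stable:
                break

        coords = with_cof.coords
        topo = with_cof.topology
        record: dict = {"frame_id": f}
        o_idx = placement["o_index"]
        for cand in frame_targets:
            hs = hyds[f"C{cand[1:]}"]
            dmin = float(
                min(np.linalg.norm(coords[h] - coords[o_idx]) for h in hs)
            )
            record[f"dist_{cand}"] = dmin
            record[f"precat_{cand}"] = bool(dmin < 4.0)
            record[f"target_{cand}"] = frame_targets[cand]
        record["placement_residual"] = placement["residual"]

        for key in ("C12", "C9"):
            if key in plane_state:
                theta = float(plane_state[key])
                record[f"plane_angle_{key}"] = theta
                record[f"regime_{key}"] = bool(theta < 90.0)
                lo = _SPANS[int(key[1:])][2][0]
                first = _normalize_bond_configs(spec.bond_configs)[lo]
                record[f"abstraction_label_{key}"] = first + (
                    "E" if theta < 90.0 else "Z"
                )

        if geom is not None:
            origin = np.array([60.0, 40.0, 0.0])
            cloud_a = base_clouds[0] + origin
            cloud_b = base_clouds[1] @ _rot_z(axis_angle).T
            cloud_b = cloud_b - cloud_b.mean(axis=0) + origin + np.array(
                [center_distance, 0.0, 0.0]
            )
            dom_coords = np.vstack([cloud_a, cloud_b])
            npts = geom.points_per_domain
            if topology is None:
                dom_topo = Topology(
                    ["CA"] * (2 * npts),
                    ["DMA"] * npts + ["DMB"] * npts,
                    list(range(1, npts + 1)) + list(range(5001, 5001 + npts)),
                    ["A"] * npts + ["B"] * npts,
                )
                topo = Topology(
                    topo.atom_names + dom_topo.atom_names,
                    topo.residue_names + dom_topo.residue_names,
                    topo.residue_ids + dom_topo.residue_ids,
                    (topo.chain_ids or []) + dom_topo.chain_ids,
                )
            else:
                topo = topology
            coords = np.vstack([coords, dom_coords])
            record["center_distance"] = float(center_distance)
            record["axis_angle"] = float(axis_angle)

        if topology is None:
            topology = topo
            selection_raw = make_selection_raw(with_cof, geom)
            selection = model_io.resolve_selection(
                selection_raw, topology, frame=Frame(coords=coords, frame_id=0)
            )

        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(coords=coords, frame_id=f))

        if spec.emit_abstraction:
            theta12 = record.get("plane_angle_C12", DEFAULT_PLANE_ANGLES["C12"])
            rad = abstraction_fragment(
                theta12, span_center=12, bond_configs=spec.bond_configs,
                plane_angles={k: v for k, v in plane_state.items() if k != "C12"},
            )
            record["abstraction_label_C12"] = rad.info["abstraction_label"]
            rad_coords = rad.coords
            if spec.noise_sigma > 0:
                rad_coords = rad_coords + rng.normal(0.0, spec.noise_sigma, rad_coords.shape)
            if abs_topology is None:
                abs_topology = rad.topology
            abs_frames.append(Frame(coords=rad_coords, frame_id=f))

        truth.frames.append(record)

    trajectory = Trajectory(topology=topology, frames=frames)
    abs_traj = (
        Trajectory(topology=abs_topology, frames=abs_frames) if abs_frames else None
    )
    return SyntheticResult(
        trajectory=trajectory,
        ground_truth=truth,
        selection=selection,
        selection_raw=selection_raw,
        abstraction_trajectory=abs_traj,
    )


def make_selection_raw(
    fragment: Fragment, geom: Optional[DomainGeometry] = None
) -> dict:
    """Selection-config mapping (1-based serials) for a generated system."""
    names = fragment.topology.atom_names

    def serial(name: str) -> int:
        return names.index(name) + 1

    raw: dict = {
        "substrate_carbons": {f"C{i}": serial(f"C{i}") for i in range(1, N_CARBONS + 1)},
        "substrate_hydrogens": {
            cname: [h + 1 for h in hs] for cname, hs in fragment.info["hydrogens"].items()
        },
        "contact_groups": {"carboxylate_O": [serial("O1A"), serial("O1B")]},
        "double_bonds": [[f"C{b}", f"C{b + 1}"] for b in DHA_DOUBLE_BONDS],
        "stereo": {
            "pentadienyl_spans": {
                "C10_C14": {
                    "span": ["C10", "C11", "C12", "C13", "C14"],
                    "flanks": ["C9", "C15"],
                },
                "C7_C11": {
                    "span": ["C7", "C8", "C9", "C10", "C11"],
                    "flanks": ["C6", "C12"],
                },
            },
            "prochiral_centers": {
                "C12": {"neighbor_priority": ["C13", "C11"]},
                "C9": {"neighbor_priority": ["C10", "C8"]},
                "C15": {"neighbor_priority": ["C16", "C14"]},
            },
        },
    }
    if "FE" in names:
        raw["cofactor"] = {
            "Fe": serial("FE"),
            "O_hydroxide": serial("OC"),
            "H_hydroxide": serial("HOC"),
        }
    if geom is not None:
        raw["domain_ranges"] = {
            "domain_A": [1, geom.points_per_domain],
            "domain_B": [5001, 5000 + geom.points_per_domain],
        }
    return raw
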