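"""Precatalytic-structure statistics and reaction-coordinate descriptors.

A frame is *precatalytic* for a candidate hydrogen when that hydrogen lies
strictly within 4.0 angstrom of the cofactor hydroxide oxygen - the
geometric filter used to pick snapshots worth optimizing.  The scalar
reaction coordinates of the mechanistic steps (abstraction, O2 addition,
carbon-chain rotation, retro-hydrogen transfer) are plain distance /
distance-difference / torsion descriptors; no energies are computed here.

Distance alone is explicitly not a reactivity ranking: the closer hydrogen
does not necessarily have the lower barrier, so these functions report
descriptors and leave any ranking to the energetics tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import DescriptorSeries, Frame, SelectionConfig, SelectionError, Trajectory
from .geometry import dihedral, distance, plane_angle
from .stereo import prochiral_labels

__all__ = [
    "PRECATALYTIC_THRESHOLD",
    "PLANE_ANGLE_THRESHOLD",
    "candidate_h_distances",
    "precatalytic_stats",
    "abstraction_coordinate",
    "addition_coordinate",
    "rotation_coordinate",
    "retro_coordinate",
    "plane_angle_regime",
    "PrecatalyticReport",
]

PRECATALYTIC_THRESHOLD = 4.0  # angstrom, strict "<"
PLANE_ANGLE_THRESHOLD = 90.0  # degrees, strict "<"

# chain neighbor that outranks the other at each bis-allylic methylene of
# DHA (higher-numbered neighbor carries the closer double bond toward the
# methyl end and outranks in the declared priority scheme)
_DEFAULT_CANDIDATES = ("C9", "C12", "C15")


def candidate_h_distances(
    trajectory: Trajectory,
    selection: SelectionConfig,
    candidates: Sequence[str] = _DEFAULT_CANDIDATES,
) -> dict[str, DescriptorSeries]:
    """Distances from each candidate hydrogen to the cofactor hydroxide O.

    For each candidate carbon the two methylene hydrogens are labeled
    pro-R/pro-S per frame, giving series named e.g. ``dist_H12proS_OH`` plus
    a per-carbon minimum series ``dist_H12_OH`` (the "closest hydrogen"
    series).  Raises SelectionError naming the carbon when its hydrogens are
    missing.
    """
    if "O_hydroxide" not in selection.cofactor:
        raise SelectionError("cofactor O_hydroxide not resolved in selection")
    o_idx = selection.cofactor["O_hydroxide"]
    per_label: dict[str, list[float]] = {}
    per_min: dict[str, list[float]] = {c: [] for c in candidates}
    ids = []
    for fr in trajectory:
        ids.append(fr.frame_id)
        for cname in candidates:
            num = int(cname[1:])
            hyds = selection.substrate_hydrogens.get(cname)
            if not hyds:
                raise SelectionError(f"no hydrogens resolved for candidate carbon {cname}")
            if len(hyds) == 2:
                labels = prochiral_labels(
                    fr,
                    selection.carbon(cname),
                    (selection.carbon(f"C{num + 1}"), selection.carbon(f"C{num - 1}")),
                    (hyds[0], hyds[1]),
                )
                named = {
                    f"dist_H{num}{'proR' if lab == 'pro-R' else 'proS'}_OH": h
                    for h, lab in labels.items()
                }
            else:
                named = {f"dist_H{num}_only_OH": hyds[0]}
            dmin = np.inf
            for sname, h in named.items():
                d = distance(fr, h, o_idx)
                per_label.setdefault(sname, []).append(d)
                dmin = min(dmin, d)
            per_min[cname].append(dmin)
    ids = np.array(ids)
    out = {
        name: DescriptorSeries(name=name, frame_ids=ids, values=np.array(vals), unit="angstrom")
        for name, vals in per_label.items()
    }
    for cname, vals in per_min.items():
        name = f"dist_H{cname[1:]}_OH"
        out[name] = DescriptorSeries(
            name=name, frame_ids=ids, values=np.array(vals), unit="angstrom"
        )
    return out


def precatalytic_stats(
    series: DescriptorSeries, threshold: float = PRECATALYTIC_THRESHOLD
) -> tuple[np.ndarray, float]:
    """Per-frame precatalytic flags (distance strictly below threshold) and
    their fraction."""
    if len(series) == 0:
        raise ValueError("precatalytic_stats: empty series")
    flags = series.values < threshold
    return flags, float(flags.mean())


def abstraction_coordinate(frame: Frame, cx: int, hx: int, o_cofactor: int) -> float:
    """Hydrogen-abstraction reaction coordinate d(Cx,Hx) - d(Hx,O).

    Negative in reactant-like geometries (H still bonded to carbon),
    positive once the hydrogen has transferred to the hydroxide oxygen.
    """
    return distance(frame, cx, hx) - distance(frame, hx, o_cofactor)


def addition_coordinate(frame: Frame, o_attacking: int, c14: int) -> float:
    """O2-addition coordinate: distance from the attacking oxygen to C14."""
    return distance(frame, o_attacking, c14)


def rotation_coordinate(frame: Frame, selection: SelectionConfig) -> float:
    """Carbon-chain rotation coordinate: the C13-C14-C15-C16 torsion."""
    return dihedral(
        frame,
        selection.carbon("C13"),
        selection.carbon("C14"),
        selection.carbon("C15"),
        selection.carbon("C16"),
    )


def retro_coordinate(
    frame: Frame, h_water: int, o_water: int, o_peroxyl_outer: int
) -> float:
    """Retro-hydrogen-abstraction coordinate: breaking H-OH (water ligand)
    distance minus forming H-OO(C14) distance."""
    return distance(frame, h_water, o_water) - distance(frame, h_water, o_peroxyl_outer)


def plane_angle_regime(
    trajectory: Trajectory,
    triple_a: Sequence[int],
    triple_b: Sequence[int],
    threshold: float = PLANE_ANGLE_THRESHOLD,
) -> tuple[np.ndarray, float]:
    """Per-frame flags for the plane-angle stereochemistry criterion.

    Flag = (angle between the two oriented carbon planes strictly below
    threshold).  Frames below 90 degrees for the C10C11C12/C12C13C14 pair
    are the ones prompted to give the 12E radical.
    """
    flags = np.array(
        [plane_angle(fr, triple_a, triple_b) < threshold for fr in trajectory]
    )
    if flags.size == 0:
        raise ValueError("plane_angle_regime: empty trajectory")
    return flags, float(flags.mean())


@dataclass
class PrecatalyticReport:
    """Per-candidate distance series, flags and precatalytic fractions."""

    threshold: float
    fractions: dict[str, float] = field(default_factory=dict)
    flags: dict[str, list[bool]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold_angstrom": self.threshold,
            "fractions": self.fractions,
            "flags": {k: [bool(b) for b in v] for k, v in self.flags.items()},
        }


def precatalytic_report(
    trajectory: Trajectory,
    selection: SelectionConfig,
    threshold: float = PRECATALYTIC_THRESHOLD,
    candidates: Sequence[str] = _DEFAULT_CANDIDATES,
) -> tuple[PrecatalyticReport, dict[str, DescriptorSeries]]:
    """Closest-hydrogen distances plus flags/fractions for every candidate."""
    series = candidate_h_distances(trajectory, selection, candidates=candidates)
    report = PrecatalyticReport(threshold=threshold)
    for cname in candidates:
        key = f"dist_H{cname[1:]}_OH"
        flags, frac = precatalytic_stats(series[key], threshold)
        report.fractions[f"H{cname[1:]}"] = frac
        report.flags[f"H{cname[1:]}"] = list(map(bool, flags))
    return report, series
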