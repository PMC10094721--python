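"""Stereochemical labels from 3-D coordinates.

Covers the labels a lipoxygenase peroxidation study needs:

* Z/E of a double bond from the substituent torsion (|torsion| <= 90 -> Z);
* the two-letter pentadienyl label (e.g. "ZE") of the planar five-carbon
  radical formed after hydrogen abstraction;
* pro-R / pro-S of the two hydrogens of a prochiral methylene;
* R/S at a tetrahedral center with *declared* substituent priorities
  (a general CIP engine is deliberately out of scope: for the handful of
  centers that matter here - e.g. the C14 peroxyl with O > C13 > C15 > H -
  the priorities are known and are part of the selection config);
* suprafacial/antarafacial classification of an oxygen probe relative to
  the pentadienyl plane and the cofactor side.

Sign convention for chirality: with unit vectors u1, u2, u3 from the center
to the three highest-priority substituents, t = (u1 x u2) . u3; t < 0 -> R,
t > 0 -> S.  The convention is anchored to a hand-verified worked example
kept in the test suite, so it cannot drift silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import DegenerateGeometryError, Frame, SelectionConfig
from .geometry import dihedral

__all__ = [
    "bond_config",
    "pentadienyl_label",
    "prochiral_labels",
    "center_chirality",
    "face_classification",
    "least_squares_plane",
    "StereoReport",
    "PentadienylResult",
    "FaceResult",
    "analyze_stereo",
]

_DEGENERATE_VOLUME = 1e-6  # cubic angstrom, |triple product| floor
_IN_PLANE_TOL = 1e-6  # angstrom


def bond_config(
    frame: Frame,
    bond: tuple[int, int],
    substituents: tuple[int, int],
) -> tuple[str, float]:
    """Z/E of the double bond (Ci, Cj) from the torsion Ch-Ci-Cj-Ck.

    ``substituents`` = (Ch, Ck) with Ch bonded to Ci and Ck bonded to Cj
    (the chain substituents).  |torsion| <= 90 degrees -> Z, else E; the tie
    at exactly 90 goes to Z (measure-zero boundary).
    """
    ci, cj = bond
    ch, ck = substituents
    tor = dihedral(frame, ch, ci, cj, ck)
    return ("Z" if abs(tor) <= 90.0 else "E"), tor


@dataclass
class PentadienylResult:
    label: str  # two letters, e.g. "ZE"
    torsions: tuple[float, float]  # degrees, about the two formal double bonds
    planarity: float  # angstrom, max |out-of-plane deviation| of span carbons

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "torsions_deg": list(self.torsions),
            "planarity_angstrom": self.planarity,
        }


def least_squares_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s.size < 3 or s[1] < _IN_PLANE_TOL:
        raise DegenerateGeometryError("plane atoms are collinear")
    return centroid, vt[2]


def pentadienyl_label(
    frame: Frame,
    span: Sequence[int],
    flanks: tuple[int, int],
) -> PentadienylResult:
    """Two-letter stereochemistry of a pentadienyl radical span Ca..Ca+4.

    The first letter is the Z/E of the formal double bond (Ca, Ca+1) with
    chain substituents (Ca-1, Ca+2); the second that of (Ca+2, Ca+3) with
    substituents (Ca+1, Ca+4).  For the C10-C14 span of DHA this yields the
    (10Z/10E, 12Z/12E) label of the radical that decides whether the
    maresin-competent 12E hydroperoxide can form.  A planarity score (max
    deviation of the five carbons from their least-squares plane) is
    reported alongside; the label is only chemically meaningful for a
    near-planar radical.
    """
    c = list(span)
    if len(c) != 5:
        raise ValueError("pentadienyl span must have exactly 5 carbons")
    pre, post = flanks
    first, t1 = bond_config(frame, (c[0], c[1]), (pre, c[2]))
    second, t2 = bond_config(frame, (c[2], c[3]), (c[1], c[4]))
    centroid, normal = least_squares_plane(frame.coords[c])
    dev = np.abs((frame.coords[c] - centroid) @ normal)
    return PentadienylResult(
        label=first + second, torsions=(t1, t2), planarity=float(dev.max())
    )


def center_chirality(
    frame: Frame,
    center: int,
    substituents: Sequence[int],
    validate_lowest: bool = True,
) -> str:
    """R/S at a tetrahedral center given substituents in descending CIP
    priority (s1, s2, s3, s4).

    Signed-volume rule: t = (u1 x u2) . u3 over unit vectors center->s1..s3;
    t < 0 -> R, t > 0 -> S.  The lowest-priority substituent s4 is used only
    to validate that it lies on the opposite side of the s1-s2-s3 face.
    """
    s = list(substituents)
    if len(s) != 4:
        raise ValueError("center_chirality needs exactly 4 substituents")
    ctr = frame.coords[center]
    u = []
    for i in s:
        v = frame.coords[i] - ctr
        norm = np.linalg.norm(v)
        if norm < _IN_PLANE_TOL:
            raise DegenerateGeometryError("substituent coincides with center")
        u.append(v / norm)
    t = float(np.dot(np.cross(u[0], u[1]), u[2]))
    if abs(t) < _DEGENERATE_VOLUME:
        raise DegenerateGeometryError("near-planar center: chirality undefined")
    if validate_lowest and float(np.dot(u[3], u[0] + u[1] + u[2])) > 0:
        raise DegenerateGeometryError(
            "lowest-priority substituent does not lie opposite the other three"
        )
    return "R" if t < 0 else "S"


def prochiral_labels(
    frame: Frame,
    center: int,
    neighbor_priority: tuple[int, int],
    hydrogens: tuple[int, int],
) -> dict[int, str]:
    """pro-R / pro-S of the two methylene hydrogens at ``center``.

    ``neighbor_priority`` = (C_high, C_low) declares which chain neighbor
    outranks the other (for C12 of DHA: C13 > C11).  Each hydrogen is
    assessed by promoting it above its geminal partner and applying the R/S
    signed-volume rule; the two hydrogens always receive opposite labels.
    """
    c_high, c_low = neighbor_priority
    h1, h2 = hydrogens
    out: dict[int, str] = {}
    for assessed, other in ((h1, h2), (h2, h1)):
        label = center_chirality(
            frame, center, (c_high, c_low, assessed, other), validate_lowest=False
        )
        out[assessed] = "pro-R" if label == "R" else "pro-S"
    if out[h1] == out[h2]:
        raise DegenerateGeometryError("prochirality undefined: hydrogens equivalent")
    return out


@dataclass
class FaceResult:
    label: str  # "suprafacial" | "antarafacial"
    probe_side: float  # signed distance (angstrom) of probe from the plane
    reference_side: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "probe_side": self.probe_side,
            "reference_side": self.reference_side,
        }


def face_classification(
    frame: Frame,
    plane_atoms: Sequence[int],
    probe: int,
    reference: int,
) -> FaceResult:
    """Classify on which face of the pentadienyl plane a probe atom sits
    relative to a reference atom (the cofactor hydroxide oxygen).

    Same side -> suprafacial; opposite sides -> antarafacial.  Oxygen
    addition to the radical is antarafacial in a lipoxygenase: the O2 comes
    in on the face opposite the iron cofactor.
    """
    centroid, normal = least_squares_plane(frame.coords[list(plane_atoms)])
    sp = float((frame.coords[probe] - centroid) @ normal)
    sr = float((frame.coords[reference] - centroid) @ normal)
    if abs(sp) < _IN_PLANE_TOL or abs(sr) < _IN_PLANE_TOL:
        raise DegenerateGeometryError("probe or reference lies in the plane")
    label = "suprafacial" if sp * sr > 0 else "antarafacial"
    return FaceResult(label=label, probe_side=sp, reference_side=sr)


# ---------------------------------------------------------------------------
# config-driven per-frame report


@dataclass
class StereoReport:
    """All stereo labels of one frame, serializable to JSON."""

    bond_configs: dict[str, dict] = field(default_factory=dict)
    pentadienyl: dict[str, dict] = field(default_factory=dict)
    prochiral: dict[str, str] = field(default_factory=dict)
    center_chirality: dict[str, str] = field(default_factory=dict)
    face: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "bond_configs": self.bond_configs,
            "pentadienyl": self.pentadienyl,
            "prochiral": self.prochiral,
            "center_chirality": self.center_chirality,
        }
        if self.face is not None:
            out["face"] = self.face
        return out


def analyze_stereo(frame: Frame, selection: SelectionConfig) -> StereoReport:
    """Evaluate every stereo descriptor declared in the selection config.

    Double bonds come from ``double_bonds`` (chain substituents are the
    flanking chain carbons); pentadienyl spans, prochiral centers, chirality
    centers and the face probe come from the ``stereo`` section.
    """
    from .core import carbon_number

    report = StereoReport()
    for ca, cb in selection.double_bonds:
        na = carbon_number(ca)
        pre = f"C{na - 1}"
        post = f"C{carbon_number(cb) + 1}"
        if pre not in selection.substrate_carbons or post not in selection.substrate_carbons:
            continue
        label, tor = bond_config(
            frame,
            (selection.carbon(ca), selection.carbon(cb)),
            (selection.carbon(pre), selection.carbon(post)),
        )
        report.bond_configs[f"{ca}={cb}"] = {"label": label, "torsion_deg": tor}

    stereo_cfg = selection.stereo
    for name, span_def in stereo_cfg.get("pentadienyl_spans", {}).items():
        span = [selection.carbon(c) for c in span_def["span"]]
        flanks = tuple(selection.carbon(c) for c in span_def["flanks"])
        report.pentadienyl[name] = pentadienyl_label(frame, span, flanks).to_dict()

    for cname, pdef in stereo_cfg.get("prochiral_centers", {}).items():
        center = selection.carbon(cname)
        prio = tuple(selection.carbon(c) for c in pdef["neighbor_priority"])
        hyds = selection.hydrogens_of(cname)
        if len(hyds) != 2:
            continue
        labels = prochiral_labels(frame, center, prio, (hyds[0], hyds[1]))
        for h_idx, lab in labels.items():
            report.prochiral[f"{cname}:atom{h_idx}"] = lab

    for name, cdef in stereo_cfg.get("chirality_centers", {}).items():
        center = _resolve_ref(cdef["center"], selection)
        subs = [_resolve_ref(s, selection) for s in cdef["substituents"]]
        report.center_chirality[name] = center_chirality(frame, center, subs)

    if "face" in stereo_cfg:
        fdef = stereo_cfg["face"]
        plane = [selection.carbon(c) for c in fdef["plane"]]
        res = face_classification(
            frame,
            plane,
            _resolve_ref(fdef["probe"], selection),
            _resolve_ref(fdef["reference"], selection),
        )
        report.face = res.to_dict()
    return report


def _resolve_ref(ref, selection: SelectionConfig) -> int:
    """Resolve a stereo-config atom reference: int index, 'C14' carbon name,
    'cofactor.O_hydroxide' or 'o2.O_attacking' dotted role."""
    if isinstance(ref, int):
        return ref
    if isinstance(ref, str):
        if ref.startswith("cofactor."):
            return selection.cofactor[ref.split(".", 1)[1]]
        if ref.startswith("o2."):
            if selection.o2 is None:
                raise KeyError("selection has no o2 section")
            return selection.o2[ref.split(".", 1)[1]]
        return selection.carbon(ref)
    raise TypeError(f"cannot resolve atom reference {ref!r}")
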