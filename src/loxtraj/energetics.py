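"""Ensemble statistics of per-snapshot QM/MM barriers and energy ladders.

The central quantity is the exponential (Boltzmann) average of an ensemble
of activation barriers,

    dE_av = -kB*T * ln( (1/N) * sum_i exp(-dE_i / (kB*T)) ),

which is dominated by the lowest barriers of the ensemble and satisfies
min <= dE_av <= arithmetic mean.  kB = 0.0019872 kcal/(mol K); the default
temperature is 300 K, the production temperature of the simulations the
barrier tables come from.

Energies are never computed here; the module post-processes CSV tables of
per-frame barriers/reaction energies with their stereo labels, and builds
stationary-point energy ladders from explicit (barrier, reaction energy,
offset) step inputs.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "K_B",
    "exponential_average",
    "compare_ensembles",
    "barrier_table_summary",
    "read_barrier_table",
    "load_packaged_table",
    "packaged_table_names",
    "energy_ladder",
    "LadderStep",
    "EnergyLadder",
]

K_B = 0.0019872  # kcal mol^-1 K^-1

# agreement with a table's printed average is "flagged, not asserted" beyond
# this margin (one unit in the last printed decimal place)
PRINTED_AVERAGE_TOL = 0.05


def exponential_average(
    barriers: Sequence[float], temperature: float = 300.0
) -> float:
    """Boltzmann-exponential average of an ensemble of barriers (kcal/mol)."""
    b = np.asarray(list(barriers), dtype=float)
    if b.size == 0:
        raise ValueError("exponential_average: empty barrier list")
    if not np.all(np.isfinite(b)):
        raise ValueError("exponential_average: barriers must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = K_B * temperature
    return float(-kt * (logsumexp(-b / kt) - np.log(b.size)))


def compare_ensembles(
    barriers_a: Sequence[float],
    barriers_b: Sequence[float],
    temperature: float = 300.0,
) -> float:
    """exponential_average(B) - exponential_average(A), kcal/mol."""
    return exponential_average(barriers_b, temperature) - exponential_average(
        barriers_a, temperature
    )


def read_barrier_table(path_or_buffer) -> pd.DataFrame:
    """Read a barrier table CSV with columns
    (frame_id, d_react, dE_barrier, dE_reaction, stereo).

    Leading ``# key: value`` comment lines become DataFrame ``attrs``
    metadata (used to carry a table's printed exponential average so the
    summary can cross-check it).
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        text = Path(path_or_buffer).read_text()
    meta: dict[str, str] = {}
    lines = []
    for line in text.splitlines():
        m = re.match(r"#\s*([\w.]+)\s*:\s*(.+)", line)
        if m:
            meta[m.group(1)] = m.group(2).strip()
        elif line.strip() and not line.startswith("#"):
            lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(lines)))
    if "dE_barrier" not in df.columns:
        raise ValueError("barrier table must have a dE_barrier column")
    df.attrs.update(meta)
    return df


def packaged_table_names() -> list[str]:
    """Names of the barrier tables shipped with the package."""
    pkg = resources.files("loxtraj.data")
    return sorted(p.stem for p in pkg.iterdir() if p.name.endswith(".csv"))


def load_packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged QM/MM result tables by stem name, e.g.
    ``halox12_h12pros_abstraction``."""
    res = resources.files("loxtraj.data") / f"{name}.csv"
    with res.open("r") as fh:
        return read_barrier_table(fh)


def barrier_table_summary(
    records: pd.DataFrame, temperature: float = 300.0
) -> dict:
    """Summary of one barrier ensemble: min, arithmetic mean and exponential
    average of the barriers, mean reaction energy, and stereo-label tally.

    If the table carries a ``printed_exponential_average`` metadata entry,
    the recomputed average is compared against it and a ``discrepancy`` flag
    is set when they disagree beyond the printed precision; the recomputed
    value is always the one reported.
    """
    if len(records) == 0:
        raise ValueError("barrier_table_summary: no records")
    b = records["dE_barrier"].to_numpy(dtype=float)
    out = {
        "n": int(len(records)),
        "barrier_min": float(b.min()),
        "barrier_mean": float(b.mean()),
        "barrier_exponential_average": exponential_average(b, temperature),
        "temperature_K": float(temperature),
    }
    if "dE_reaction" in records.columns and records["dE_reaction"].notna().any():
        out["reaction_energy_mean"] = float(records["dE_reaction"].mean())
    if "stereo" in records.columns:
        tally = records["stereo"].value_counts().to_dict()
        out["stereo_tally"] = {str(k): int(v) for k, v in tally.items()}
    printed = records.attrs.get("printed_exponential_average")
    if printed is not None:
        printed = float(printed)
        out["printed_exponential_average"] = printed
        out["discrepancy_vs_printed"] = bool(
            abs(out["barrier_exponential_average"] - printed) > PRINTED_AVERAGE_TOL
        )
    return out


# ---------------------------------------------------------------------------
# energy ladders


@dataclass
class LadderStep:
    """One mechanistic step: barrier and reaction energy from the step's own
    reactant, plus an optional energy offset applied *before* the step
    (e.g. the falloff on O2 approach between abstraction and addition)."""

    label: str
    barrier: float  # dE_ddag, kcal/mol
    reaction_energy: float  # dE, kcal/mol
    offset_before: float = 0.0


@dataclass
class EnergyLadder:
    """Ordered stationary points (label, energy relative to the zero)."""

    zero_label: str
    points: list[tuple[str, float]] = field(default_factory=list)

    def energies(self) -> dict[str, float]:
        return dict(self.points)

    def to_dict(self) -> dict:
        return {"zero_label": self.zero_label, "points": [[l, e] for l, e in self.points]}


def energy_ladder(steps: Sequence[LadderStep], zero_label: str = "reference") -> EnergyLadder:
    """Assemble cumulative stationary-point energies from ordered steps.

    Each TS sits at (preceding minimum + barrier); each product at
    (preceding minimum + reaction energy); an ``offset_before`` shifts the
    next reactant relative to the previous product.
    """
    ladder = EnergyLadder(zero_label=zero_label, points=[(zero_label, 0.0)])
    level = 0.0
    for step in steps:
        if step.barrier is None or step.reaction_energy is None:
            raise ValueError(f"step {step.label!r}: barrier and reaction energy required")
        if step.offset_before:
            level += step.offset_before
            ladder.points.append((f"{step.label}_reactant", level))
        ladder.points.append((f"{step.label}_TS", level + step.barrier))
        level += step.reaction_energy
        ladder.points.append((f"{step.label}_product", level))
    return ladder
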