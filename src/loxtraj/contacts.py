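"""Hydrogen-bond and pi-stacking contact distance series.

Both descriptors are operationalized as the minimum heavy-atom / hydrogen
pairwise distance between the declared groups ("closest atom" definition);
no angular hydrogen-bond criterion and no centroid variant are implemented,
so there is exactly one documented definition per series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DescriptorSeries, SelectionConfig, Trajectory
from .geometry import min_group_distance

__all__ = ["ContactDefinition", "hbond_series", "stacking_series", "contact_from_config"]


@dataclass
class ContactDefinition:
    """A named substrate-group / residue-group atom-set pair.

    For a hydrogen bond the substrate group is typically the carboxylate
    oxygen pair and the residue group the donor hydrogens (e.g. the
    guanidinium hydrogens of an arginine).  For a stacking contact the
    substrate group is the two carbons of a double bond and the residue
    group the aromatic ring heavy atoms.
    """

    name: str
    substrate_group: list[int]
    residue_group: list[int]

    def __post_init__(self) -> None:
        if not self.substrate_group or not self.residue_group:
            raise ValueError(f"contact {self.name!r}: both atom groups must be non-empty")


def _min_distance_series(
    trajectory: Trajectory, contact: ContactDefinition, unit_name: str
) -> DescriptorSeries:
    ids, vals = [], []
    for fr in trajectory:
        d, _ = min_group_distance(fr, contact.substrate_group, contact.residue_group)
        ids.append(fr.frame_id)
        vals.append(d)
    return DescriptorSeries(
        name=unit_name, frame_ids=np.array(ids), values=np.array(vals), unit="angstrom"
    )


def hbond_series(trajectory: Trajectory, contact: ContactDefinition) -> DescriptorSeries:
    """Per-frame minimum distance between substrate acceptor oxygens and the
    closest donor hydrogen of the residue group."""
    return _min_distance_series(trajectory, contact, f"hbond_{contact.name}")


def stacking_series(trajectory: Trajectory, contact: ContactDefinition) -> DescriptorSeries:
    """Per-frame minimum distance between any residue heavy atom and the
    closer of the two carbons of the tracked double bond."""
    if len(contact.substrate_group) != 2:
        raise ValueError(
            f"stacking contact {contact.name!r}: substrate group must be the "
            "two carbons of a double bond"
        )
    return _min_distance_series(trajectory, contact, f"stacking_{contact.name}")


def contact_from_config(entry: dict, selection: SelectionConfig) -> ContactDefinition:
    """Build a ContactDefinition from a selection-config ``contacts:`` entry.

    Groups are named references into ``contact_groups`` or lists of carbon
    names (e.g. the two carbons of a double bond).
    """

    def resolve(group) -> list[int]:
        if isinstance(group, str):
            if group not in selection.contact_groups:
                raise KeyError(f"unknown contact group {group!r}")
            return list(selection.contact_groups[group])
        return [selection.carbon(c) if isinstance(c, str) else int(c) for c in group]

    return ContactDefinition(
        name=entry["name"],
        substrate_group=resolve(entry["substrate_group"]),
        residue_group=resolve(entry["residue_group"]),
    )
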