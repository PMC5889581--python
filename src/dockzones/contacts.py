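"""Residue-residue contact detection for a single docking configuration.

Two residues from opposite units are *in contact* when their minimum
heavy-atom Euclidean distance lies in the closed interval [d_min, d_max]
(default 3-5 Å).  Pairs strictly closer than d_min are *collisions* and are
reported separately, never as contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .structures_io import Configuration, Residue, ResidueKey

__all__ = [
    "ContactParams",
    "ContactPair",
    "ContactZone",
    "min_residue_distance",
    "compute_contact_zone",
    "closest_pair",
]


@dataclass(frozen=True)
class ContactParams:
    """Interaction distance window in Å."""

    d_min: float = 3.0
    d_max: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min <= self.d_max):
            raise ValidationError(
                f"require 0 < d_min <= d_max, got d_min={self.d_min}, d_max={self.d_max}"
            )


@dataclass(frozen=True, order=True)
class ContactPair:
    ref_key: ResidueKey
    paired_key: ResidueKey
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("contact distance must be non-negative")

    @property
    def keys(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.ref_key, self.paired_key)


@dataclass
class ContactZone:
    """All contacts (and collisions) of one configuration."""

    config_id: str
    pairs: tuple[ContactPair, ...]
    collisions: tuple[ContactPair, ...] = ()
    params: ContactParams = field(default_factory=ContactParams)
    reference_side: str = "reference"
    # residue names for display/sorting, keyed by ResidueKey
    ref_names: dict = field(default_factory=dict)
    paired_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = tuple(sorted(self.pairs))
        self.collisions = tuple(sorted(self.collisions))
        overlap = self.pair_keys & {p.keys for p in self.collisions}
        if overlap:
            raise ValidationError(f"pairs and collisions overlap: {sorted(map(str, overlap))[:3]}")

    @property
    def pair_keys(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return {p.keys for p in self.pairs}

    @property
    def ref_residues(self) -> set[ResidueKey]:
        return {p.ref_key for p in self.pairs}

    @property
    def paired_residues(self) -> set[ResidueKey]:
        return {p.paired_key for p in self.pairs}

    def residues(self, side: str) -> set[ResidueKey]:
        if side == "reference":
            return self.ref_residues
        if side == "paired":
            return self.paired_residues
        raise ValidationError(f"side must be 'reference' or 'paired', got {side!r}")

    def names(self, side: str) -> dict:
        if side == "reference":
            return self.ref_names
        if side == "paired":
            return self.paired_names
        raise ValidationError(f"side must be 'reference' or 'paired', got {side!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def min_residue_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over heavy-atom pairs; symmetric by construction."""
    return float(cdist(res_a.heavy_coords(), res_b.heavy_coords()).min())


def _unit_heavy_arrays(unit) -> tuple[np.ndarray, np.ndarray]:
    """Stacked heavy-atom coordinates plus the residue index of each atom."""
    coords, owner = [], []
    for idx, res in enumerate(unit.residues):
        xyz = res.heavy_coords()
        coords.append(xyz)
        owner.append(np.full(len(xyz), idx))
    return np.vstack(coords), np.concatenate(owner)


def compute_contact_zone(conf: Configuration, params: ContactParams | None = None) -> ContactZone:
    """Find all cross-unit contacts and collisions of one configuration.

    Vectorized over all heavy-atom pairs; results are exactly the brute-force
    all-pairs minimum per residue pair.
    """
    params = params or ContactParams()
    ref_xyz, ref_owner = _unit_heavy_arrays(conf.reference)
    par_xyz, par_owner = _unit_heavy_arrays(conf.paired)

    dmat = cdist(ref_xyz, par_xyz)
    n_ref, n_par = len(conf.reference), len(conf.paired)
    # minimum atom-atom distance per residue pair
    res_min = np.full((n_ref, n_par), np.inf)
    np.minimum.at(res_min, (ref_owner[:, None], par_owner[None, :]), dmat)

    pairs, collisions = [], []
    ref_names, paired_names = {}, {}
    for i, j in zip(*np.nonzero(res_min <= params.d_max)):
        d = float(res_min[i, j])
        ref_res = conf.reference.residues[i]
        par_res = conf.paired.residues[j]
        pair = ContactPair(ref_res.key, par_res.key, d)
        ref_names[ref_res.key] = ref_res.name
        paired_names[par_res.key] = par_res.name
        if d < params.d_min:
            collisions.append(pair)
        else:
            pairs.append(pair)
    return ContactZone(
        conf.id, tuple(pairs), tuple(collisions), params,
        ref_names=ref_names, paired_names=paired_names,
    )


def closest_pair(zone: ContactZone) -> ContactPair | None:
    """Contact pair with minimal distance, or None for an empty zone.

    Ties are broken by (ref chain, ref number, ref insertion code, paired
    chain, paired number, paired insertion code), ascending.
    """
    if not zone.pairs:
        return None
    return min(zone.pairs, key=lambda p: (p.distance, p.ref_key, p.paired_key))
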