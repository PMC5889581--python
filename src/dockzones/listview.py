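"""Contact-zone list-view models.

One panel lists the contact residues of a chosen side on the left; the right
column repeats each partner residue once per connection, grouped under its
left entry, so connection lines drawn in listed order never cross.  Panels of
several configurations can be compared against a primary panel, whose left
ordering is imposed on all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .contacts import ContactZone
from .errors import ValidationError
from .matrix_filter import FrequencyMatrix
from .structures_io import ResidueKey

__all__ = [
    "KYTE_DOOLITTLE",
    "hydrophobicity",
    "LeftEntry",
    "RightEntry",
    "ListViewModel",
    "ComparisonModel",
    "build_listview",
    "compare_listviews",
]

# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

SORT_KEYS = ("hydrophobicity", "distance", "frequency")
MODES = ("compare", "compact")


def hydrophobicity(residue_name: str) -> float:
    """Kyte-Doolittle value; unknown residues map to 0 with a warning."""
    try:
        return KYTE_DOOLITTLE[residue_name.upper()]
    except KeyError:
        warnings.warn(f"no hydrophobicity value for residue {residue_name!r}; using 0")
        return 0.0


@dataclass(frozen=True)
class LeftEntry:
    key: ResidueKey
    name: str
    sort_value: float


@dataclass(frozen=True)
class RightEntry:
    key: ResidueKey
    name: str
    distance: float
    left_index: int


@dataclass
class ListViewModel:
    config_id: str
    side: str
    sort_key: str
    left: list[LeftEntry]
    right: list[RightEntry]

    @property
    def connections(self) -> list[tuple[int, int, float]]:
        return [(r.left_index, i, r.distance) for i, r in enumerate(self.right)]

    def to_dict(self) -> dict:
        return {
            "config_id": self.config_id,
            "side": self.side,
            "sort_key": self.sort_key,
            "left": [
                {"residue": str(e.key), "name": e.name, "sort_value": e.sort_value}
                for e in self.left
            ],
            "right": [
                {
                    "residue": str(e.key),
                    "name": e.name,
                    "distance": round(e.distance, 6),
                    "left_index": e.left_index,
                }
                for e in self.right
            ],
        }


@dataclass
class ComparisonModel:
    primary_model: ListViewModel
    compared_models: list[ListViewModel]
    matched_pairs: dict[str, set[tuple[ResidueKey, ResidueKey]]]
    missing_left_residues: dict[str, set[ResidueKey]]
    mode: str
    side: str
    sort_key: str

    def placeholders(self, config_id: str) -> set[ResidueKey]:
        """Residues rendered as white placeholders (empty in compact mode)."""
        if self.mode == "compact":
            return set()
        return self.missing_left_residues[config_id]


def _oriented_pairs(zone: ContactZone, side: str) -> dict[ResidueKey, list[tuple[ResidueKey, float]]]:
    """left key -> [(partner key, distance)] for the chosen left side."""
    grouped: dict[ResidueKey, list[tuple[ResidueKey, float]]] = {}
    for pair in zone.pairs:
        if side == "reference":
            left, right = pair.ref_key, pair.paired_key
        else:
            left, right = pair.paired_key, pair.ref_key
        grouped.setdefault(left, []).append((right, pair.distance))
    for partners in grouped.values():
        partners.sort(key=lambda t: (t[1], t[0]))
    return grouped


def _frequency_of(zone: ContactZone, matrix: FrequencyMatrix, left: ResidueKey, side: str) -> int:
    counts = []
    for pair in zone.pairs:
        if (side == "reference" and pair.ref_key == left) or (
            side == "paired" and pair.paired_key == left
        ):
            counts.append(matrix.count(pair.ref_key, pair.paired_key))
    return max(counts, default=0)


def _sort_values(
    zone: ContactZone,
    grouped: Mapping[ResidueKey, list[tuple[ResidueKey, float]]],
    sort_key: str,
    matrix: FrequencyMatrix | None,
    side: str,
) -> dict[ResidueKey, float]:
    names = zone.names(side)
    values: dict[ResidueKey, float] = {}
    for left, partners in grouped.items():
        if sort_key == "hydrophobicity":
            values[left] = hydrophobicity(names.get(left, ""))
        elif sort_key == "distance":
            values[left] = min(d for _, d in partners)
        else:  # frequency
            values[left] = float(_frequency_of(zone, matrix, left, side))
    return values


def _order_keys(values: Mapping[ResidueKey, float], sort_key: str) -> list[ResidueKey]:
    # hydrophobic-first / closest-first / most-frequent-first; ties by residue key
    if sort_key == "distance":
        return sorted(values, key=lambda k: (values[k], k))
    return sorted(values, key=lambda k: (-values[k], k))


def _assemble(
    zone: ContactZone,
    left_order: Sequence[ResidueKey],
    values: Mapping[ResidueKey, float],
    grouped: Mapping[ResidueKey, list[tuple[ResidueKey, float]]],
    sort_key: str,
    side: str,
) -> ListViewModel:
    left_names = zone.names(side)
    right_names = zone.names("paired" if side == "reference" else "reference")
    left_entries, right_entries = [], []
    for idx, key in enumerate(left_order):
        left_entries.append(LeftEntry(key, left_names.get(key, ""), float(values[key])))
        for partner, dist in grouped[key]:
            right_entries.append(RightEntry(partner, right_names.get(partner, ""), dist, idx))
    return ListViewModel(zone.config_id, side, sort_key, left_entries, right_entries)


def build_listview(
    zone: ContactZone,
    sort_key: str = "hydrophobicity",
    matrix: FrequencyMatrix | None = None,
    side: str = "reference",
) -> ListViewModel:
    """Build one list-view panel for a contact zone.

    ``sort_key`` orders the left column: hydrophobicity descending, minimum
    connection distance ascending, or maximum pair frequency descending
    (requires ``matrix``).  The right column repeats partners per connection
    in left order.
    """
    if sort_key not in SORT_KEYS:
        raise ValidationError(f"sort_key must be one of {SORT_KEYS}, got {sort_key!r}")
    if side not in ("reference", "paired"):
        raise ValidationError(f"side must be 'reference' or 'paired', got {side!r}")
    if sort_key == "frequency" and matrix is None:
        raise ValidationError("frequency sorting requires a FrequencyMatrix")
    grouped = _oriented_pairs(zone, side)
    values = _sort_values(zone, grouped, sort_key, matrix, side)
    order = _order_keys(values, sort_key)
    return _assemble(zone, order, values, grouped, sort_key, side)


def compare_listviews(
    primary_zone: ContactZone,
    compared_zones: Sequence[ContactZone],
    mode: str = "compare",
    sort_key: str = "hydrophobicity",
    matrix: FrequencyMatrix | None = None,
    side: str = "reference",
) -> ComparisonModel:
    """Juxtapose panels against the primary configuration.

    All panels reuse the primary's left ordering; residues unique to a
    compared zone are appended after, ordered by the same sort key.  Matched
    pairs and missing primary residues are recorded per panel; ``compact``
    mode suppresses placeholder rendering without changing the matches.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    for zone in compared_zones:
        if zone.reference_side != primary_zone.reference_side:
            raise ValidationError(
                f"zone {zone.config_id!r} uses a different reference-side convention"
            )

    primary_model = build_listview(primary_zone, sort_key, matrix, side)
    primary_order = [e.key for e in primary_model.left]

    compared_models = []
    matched: dict[str, set] = {}
    missing: dict[str, set] = {}
    for zone in compared_zones:
        grouped = _oriented_pairs(zone, side)
        values = _sort_values(zone, grouped, sort_key, matrix, side)
        own_order = _order_keys(values, sort_key)
        order = [k for k in primary_order if k in grouped] + [
            k for k in own_order if k not in set(primary_order)
        ]
        compared_models.append(_assemble(zone, order, values, grouped, sort_key, side))
        matched[zone.config_id] = zone.pair_keys & primary_zone.pair_keys
        missing[zone.config_id] = primary_zone.residues(side) - zone.residues(side)

    return ComparisonModel(primary_model, compared_models, matched, missing, mode, side, sort_key)
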