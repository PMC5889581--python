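"""Ensemble-wide contact frequency matrix and conjunctive pair filtering.

Rows are reference-unit residues, columns paired-unit residues; a cell counts
in how many configurations that residue pair is in contact.  Only residues
participating in at least one contact appear, and zero cells are not stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .contacts import ContactParams, ContactZone, compute_contact_zone
from .errors import ValidationError
from .structures_io import Ensemble, ResidueKey

__all__ = [
    "FrequencyMatrix",
    "PairSelection",
    "build_frequency_matrix",
    "marginal_counts",
    "filter_configurations",
]


@dataclass
class FrequencyMatrix:
    row_keys: list[ResidueKey]
    col_keys: list[ResidueKey]
    cells: dict[tuple[ResidueKey, ResidueKey], int]
    n: int
    row_names: dict[ResidueKey, str] = field(default_factory=dict)
    col_names: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows, cols = set(self.row_keys), set(self.col_keys)
        for (r, c), count in self.cells.items():
            if r not in rows or c not in cols:
                raise ValidationError(f"cell ({r}, {c}) outside declared rows/columns")
            if not 0 < count <= self.n:
                raise ValidationError(f"cell ({r}, {c}) count {count} outside (0, n={self.n}]")

    def count(self, row: ResidueKey, col: ResidueKey) -> int:
        return self.cells.get((row, col), 0)

    @property
    def max_count(self) -> int:
        return max(self.cells.values(), default=0)

    def to_dict(self) -> dict:
        def key_entry(key: ResidueKey, names: Mapping[ResidueKey, str]) -> dict:
            return {
                "chain": key.chain_id,
                "number": key.number,
                "insertion_code": key.insertion_code,
                "name": names.get(key, ""),
            }

        row_index = {k: i for i, k in enumerate(self.row_keys)}
        col_index = {k: i for i, k in enumerate(self.col_keys)}
        return {
            "n": self.n,
            "rows": [key_entry(k, self.row_names) for k in self.row_keys],
            "cols": [key_entry(k, self.col_names) for k in self.col_keys],
            "cells": [
                {"row": row_index[r], "col": col_index[c], "count": self.cells[(r, c)]}
                for r, c in sorted(self.cells)
            ],
        }


@dataclass(frozen=True)
class PairSelection:
    """Conjunction of required (reference residue, paired residue) contacts."""

    required: frozenset[tuple[ResidueKey, ResidueKey]]

    def __init__(self, required: Iterable[tuple[ResidueKey, ResidueKey]]):
        object.__setattr__(self, "required", frozenset(required))


def _zones_for(ensemble: Ensemble, params: ContactParams) -> dict[str, ContactZone]:
    return {conf.id: compute_contact_zone(conf, params) for conf in ensemble}


def build_frequency_matrix(
    ensemble: Ensemble,
    params: ContactParams | None = None,
    zones: Mapping[str, ContactZone] | None = None,
) -> FrequencyMatrix:
    """Count, per residue pair, the configurations whose zone contains it.

    ``zones`` may be supplied to reuse precomputed contact zones; otherwise
    they are computed with ``params``.
    """
    params = params or ContactParams()
    if zones is None:
        zones = _zones_for(ensemble, params)
    cells: dict[tuple[ResidueKey, ResidueKey], int] = {}
    row_names: dict[ResidueKey, str] = {}
    col_names: dict[ResidueKey, str] = {}
    for conf in ensemble:
        zone = zones[conf.id]
        for keys in zone.pair_keys:  # each configuration increments a cell at most once
            cells[keys] = cells.get(keys, 0) + 1
        for pair in zone.pairs:
            ref_res = conf.reference.get(pair.ref_key)
            par_res = conf.paired.get(pair.paired_key)
            if ref_res is not None:
                row_names[pair.ref_key] = ref_res.name
            if par_res is not None:
                col_names[pair.paired_key] = par_res.name
    row_keys = sorted({r for r, _ in cells})
    col_keys = sorted({c for _, c in cells})
    return FrequencyMatrix(row_keys, col_keys, cells, len(ensemble), row_names, col_names)


def marginal_counts(matrix: FrequencyMatrix) -> tuple[dict[ResidueKey, int], dict[ResidueKey, int]]:
    """Per-row and per-column totals (the axis 'histograms')."""
    rows = {k: 0 for k in matrix.row_keys}
    cols = {k: 0 for k in matrix.col_keys}
    for (r, c), count in matrix.cells.items():
        rows[r] += count
        cols[c] += count
    return rows, cols


def filter_configurations(
    ensemble: Ensemble,
    selection: PairSelection,
    params: ContactParams | None = None,
    zones: Mapping[str, ContactZone] | None = None,
) -> Ensemble:
    """Keep exactly the configurations whose contact zone contains every
    required pair; empty selection is the identity.  Order is preserved.
    """
    params = params or ContactParams()
    if not selection.required:
        return ensemble

    ref_keys: set[ResidueKey] = set()
    paired_keys: set[ResidueKey] = set()
    for conf in ensemble:
        ref_keys |= conf.reference.keys
        paired_keys |= conf.paired.keys
    for r, c in selection.required:
        if r not in ref_keys:
            raise ValidationError(f"selection names unknown reference residue {r}")
        if c not in paired_keys:
            raise ValidationError(f"selection names unknown paired residue {c}")

    if zones is None:
        zones = _zones_for(ensemble, params)
    kept = [
        conf for conf in ensemble if selection.required <= zones[conf.id].pair_keys
    ]
    primary_id = ensemble.primary_id if ensemble.primary_id in {c.id for c in kept} else None
    return Ensemble(kept, primary_id=primary_id)
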