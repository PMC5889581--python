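"""Structure model and PDB input/output for two-protein docking configurations.

A docking pose is modelled as a :class:`Configuration`: a *reference* protein
unit plus a *paired* protein unit, each an ordered list of residues with
atomic coordinates.  Reading is delegated to Biopython's PDB parser; writing
emits standard fixed-width ATOM records so external viewers can consume
transformed poses.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .errors import (
    ChainSelectionError,
    EmptyEnsembleError,
    ValidationError,
)

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "ProteinUnit",
    "Configuration",
    "Ensemble",
    "read_configuration",
    "read_ensemble",
    "write_configuration",
]

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue as printed in the source PDB file."""

    chain_id: str
    number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.number}{self.insertion_code}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"residue {self.key}: no atoms")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of non-hydrogen atoms, shape (k, 3)."""
        heavy = self.heavy_atoms
        if not heavy:
            raise ValidationError(f"residue {self.key}: no heavy atoms")
        return np.array([a.position for a in heavy], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinUnit:
    """One of the two interacting proteins, tagged by its role."""

    label: str  # "reference" | "paired"
    residues: list[Residue]

    def __post_init__(self) -> None:
        if self.label not in ("reference", "paired"):
            raise ValidationError(f"unit label must be 'reference' or 'paired', got {self.label!r}")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate residue keys within one protein unit")
        self._index = {r.key: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def get(self, key: ResidueKey) -> Residue | None:
        return self._index.get(key)

    @property
    def keys(self) -> set[ResidueKey]:
        return set(self._index)

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.heavy_coords() for r in self.residues])

    def transformed(self, transform) -> "ProteinUnit":
        """Copy of the unit with ``transform.apply`` mapped over all atoms."""
        residues = []
        for res in self.residues:
            atoms = [
                Atom(a.serial, a.name, a.element, transform.apply(a.position), a.occupancy, a.altloc)
                for a in res.atoms
            ]
            residues.append(Residue(res.key, res.name, atoms))
        return ProteinUnit(self.label, residues)


@dataclass
class Configuration:
    """One docking pose: a reference unit and a paired unit."""

    id: str
    reference: ProteinUnit
    paired: ProteinUnit

    def __post_init__(self) -> None:
        if len(self.reference) == 0 or len(self.paired) == 0:
            raise ValidationError(f"configuration {self.id!r}: both units must be non-empty")

    def unit(self, side: str) -> ProteinUnit:
        if side == "reference":
            return self.reference
        if side == "paired":
            return self.paired
        raise ValidationError(f"side must be 'reference' or 'paired', got {side!r}")


@dataclass
class Ensemble:
    configurations: list[Configuration]
    primary_id: str | None = None

    def __post_init__(self) -> None:
        # Loading raises EmptyEnsembleError; a filtered subset may be empty.
        ids = [c.id for c in self.configurations]
        if len(ids) != len(set(ids)):
            raise ValidationError("configuration ids must be unique")
        if self.primary_id is not None and self.primary_id not in ids:
            raise ValidationError(f"primary id {self.primary_id!r} names no member configuration")
        self._index = {c.id: c for c in self.configurations}

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def get(self, config_id: str) -> Configuration:
        try:
            return self._index[config_id]
        except KeyError:
            raise ValidationError(f"no configuration with id {config_id!r}") from None

    @property
    def primary(self) -> Configuration | None:
        return None if self.primary_id is None else self._index[self.primary_id]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.configurations]


# ---------------------------------------------------------------------------
# reading


def _select_altloc(bio_residue) -> list:
    """One atom per altloc group: highest occupancy, ties by altloc character."""
    groups: dict[str, list] = {}
    for atom in bio_residue.get_unpacked_list():
        groups.setdefault(atom.get_name(), []).append(atom)
    chosen = []
    for name in groups:
        cands = groups[name]
        best = min(cands, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
        chosen.append(best)
    return chosen


def _build_unit(bio_model, chain_ids: Iterable[str], label: str, include_het: bool) -> ProteinUnit:
    available = {c.id for c in bio_model}
    residues: list[Residue] = []
    for chain_id in sorted(chain_ids):
        if chain_id not in available:
            raise ChainSelectionError(chain_id, tuple(available))
        chain = bio_model[chain_id]
        for bio_res in chain:
            hetflag, number, icode = bio_res.get_id()
            if hetflag == "W":
                continue
            if hetflag.strip() and not include_het:
                continue
            atoms = []
            for bio_atom in _select_altloc(bio_res):
                occ = bio_atom.get_occupancy()
                occ = 1.0 if occ is None else min(max(float(occ), 0.0), 1.0)
                atoms.append(
                    Atom(
                        serial=int(bio_atom.get_serial_number() or 0),
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "").strip(),
                        # PDB files print exactly 3 decimals; Biopython hands back
                        # float32, so snapping to the millangstrom grid recovers
                        # the printed values exactly (coords < 8192 Å).
                        position=np.round(np.array(bio_atom.get_coord(), dtype=float), 3),
                        occupancy=occ,
                        altloc=(bio_atom.get_altloc() or "").strip(),
                    )
                )
            if not atoms:
                continue
            key = ResidueKey(chain_id, int(number), icode.strip())
            residues.append(Residue(key, bio_res.get_resname().strip(), atoms))
    return ProteinUnit(label, residues)


def _validate_chain_sets(ref_chains, paired_chains) -> tuple[set[str], set[str]]:
    ref = set(ref_chains)
    paired = set(paired_chains)
    if not ref or not paired:
        raise ValidationError("both chain selectors must be non-empty")
    overlap = ref & paired
    if overlap:
        raise ValidationError(
            f"reference and paired chain sets overlap: {', '.join(sorted(overlap))}"
        )
    return ref, paired


def _parse_structure(pdb_source):
    parser = PDBParser(QUIET=True)
    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        path = Path(pdb_source)
        if not path.exists():
            raise IOError(f"cannot read PDB source: {path}")
        handle: io.TextIOBase = open(path)
        name = path.stem
    else:
        handle = io.StringIO(str(pdb_source))
        name = "structure"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with handle:
            return parser.get_structure(name, handle)


def read_configuration(
    pdb_source,
    ref_chains: Iterable[str],
    paired_chains: Iterable[str],
    *,
    include_het: bool = False,
    config_id: str | None = None,
) -> Configuration:
    """Parse a single-pose PDB file (or text) into a :class:`Configuration`.

    ``ref_chains`` and ``paired_chains`` are disjoint chain-id sets selecting
    which chains form each unit.  Waters are always dropped; other HETATM
    records only kept with ``include_het``.  Hydrogens are stored but flagged,
    so distance stages can ignore them.
    """
    ref, paired = _validate_chain_sets(ref_chains, paired_chains)
    structure = _parse_structure(pdb_source)
    model = next(iter(structure))
    cid = config_id if config_id is not None else structure.id
    return Configuration(
        id=cid,
        reference=_build_unit(model, ref, "reference", include_het),
        paired=_build_unit(model, paired, "paired", include_het),
    )


def read_ensemble(
    sources: Sequence | str | Path,
    ref_chains: Iterable[str],
    paired_chains: Iterable[str],
    *,
    primary: str | Path | None = None,
    include_het: bool = False,
) -> Ensemble:
    """Load an ensemble from per-file poses or one multi-MODEL file.

    A single path yields one configuration per MODEL record (ids are the
    model serial numbers as strings); a list of paths yields one per file
    (ids are the file stems).  ``primary`` is loaded with the same chain
    selectors and marked via ``Ensemble.primary_id``.
    """
    ref, paired = _validate_chain_sets(ref_chains, paired_chains)
    configurations: list[Configuration] = []

    if isinstance(sources, (str, Path)):
        structure = _parse_structure(sources)
        for model in structure:
            configurations.append(
                Configuration(
                    id=str(model.serial_num if model.serial_num > 0 else model.id + 1),
                    reference=_build_unit(model, ref, "reference", include_het),
                    paired=_build_unit(model, paired, "paired", include_het),
                )
            )
    else:
        for src in sources:
            configurations.append(
                read_configuration(
                    src, ref, paired, include_het=include_het, config_id=Path(src).stem
                )
            )

    if not configurations:
        raise EmptyEnsembleError("no configurations resolved from the given sources")

    primary_id = None
    if primary is not None:
        primary_conf = read_configuration(
            primary, ref, paired, include_het=include_het, config_id=Path(primary).stem
        )
        if primary_conf.id in {c.id for c in configurations}:
            primary_conf.id = f"primary:{primary_conf.id}"
        configurations.insert(0, primary_conf)
        primary_id = primary_conf.id

    return Ensemble(configurations, primary_id=primary_id)


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # Standard alignment: 1-letter elements start in column 14 unless the
    # name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_record(serial: int, atom: Atom, residue: Residue, pos: np.ndarray) -> str:
    key = residue.key
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' '}{residue.name:>3s} {key.chain_id:1s}{key.number:4d}"
        f"{key.insertion_code or ' ':1s}   "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_configuration(
    conf: Configuration,
    path: str | Path,
    transforms: Mapping[str, object] | None = None,
) -> Path:
    """Write a configuration as a PDB file, optionally transforming each unit.

    ``transforms`` maps unit labels (``"reference"``/``"paired"``) to objects
    exposing ``apply(coords) -> coords`` (e.g. ``geometry_views.RigidTransform``).
    Coordinates are emitted in fixed 8.3 fields, so round-trips agree to 1e-3 Å.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for unit in (conf.reference, conf.paired):
        transform = (transforms or {}).get(unit.label)
        for residue in unit.residues:
            for atom in residue.atoms:
                serial += 1
                pos = atom.position if transform is None else transform.apply(atom.position)
                lines.append(_atom_record(serial, atom, residue, np.asarray(pos, dtype=float)))
        last = unit.residues[-1]
        serial += 1
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {last.key.chain_id:1s}"
            f"{last.key.number:4d}{last.key.insertion_code or ' ':1s}"
        )
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB to {path}: {exc}") from exc
    return path
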