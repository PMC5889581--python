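"""Synthetic two-protein docking ensembles with exactly-known planted contacts.

Chains are laid out so that geometry is trivially auditable: chain A
(reference) runs along the x axis at y=0, chain B (paired) runs parallel at a
large y offset.  A *planted* contact moves one B residue so that its lowest
atom (CB) sits exactly ``target_distance`` above the highest atom (O) of the
chosen A residue, axis-aligned in y.  Every coordinate is an exact multiple
of 0.001 Å, so fixed 8.3 PDB fields preserve planted distances bit-for-bit;
all other atom pairs of the planted residue pair are at least 1 Å farther,
and every non-planted cross-unit residue pair is kept beyond d_max + 2 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .contacts import ContactParams, compute_contact_zone
from .errors import GenerationError, ValidationError
from .structures_io import Atom, Configuration, Ensemble, ProteinUnit, Residue, ResidueKey

__all__ = [
    "PlantedPair",
    "EnsembleSpec",
    "GroundTruthRow",
    "Finding",
    "generate_ensemble",
    "build_ensemble",
    "write_manifest",
    "load_manifest",
    "verify_against_truth",
    "random_spec",
    "plant",
]

REF_CHAIN = "A"
PAIRED_CHAIN = "B"

# 5-heavy-atom rigid residue template (local coordinates, exact 0.001 multiples).
# O is the unique highest-y atom, CB the unique lowest-y atom; the runner-up
# gap of 1.0 Å in y guarantees the planted O..CB pair is the unique minimum.
_TEMPLATE = (
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.458, 0.600, 0.000)),
    ("C", "C", (2.000, 1.400, 0.000)),
    ("O", "O", (1.251, 2.400, 0.000)),
    ("CB", "C", (2.300, -1.000, 0.800)),
)
_O_LOCAL = np.array(_TEMPLATE[3][2])
_CB_LOCAL = np.array(_TEMPLATE[4][2])

_AA_NAMES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


def _is_milliangstrom(x: float) -> bool:
    return abs(x * 1000.0 - round(x * 1000.0)) < 1e-6


@dataclass(frozen=True)
class PlantedPair:
    ref_key: ResidueKey
    paired_key: ResidueKey
    target_distance: float

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValidationError("target_distance must be positive")
        if not _is_milliangstrom(self.target_distance):
            raise ValidationError(
                f"target_distance {self.target_distance} must be a multiple of 0.001 Å "
                "(PDB 8.3 coordinate fields cannot realize finer targets exactly)"
            )


def plant(ref_num: int, paired_num: int, distance: float) -> PlantedPair:
    """Shorthand for a plant between chain-A residue ``ref_num`` and chain-B ``paired_num``."""
    return PlantedPair(
        ResidueKey(REF_CHAIN, ref_num), ResidueKey(PAIRED_CHAIN, paired_num), distance
    )


@dataclass
class EnsembleSpec:
    n_configs: int
    residues_per_unit: int
    planted: Sequence[Sequence[PlantedPair]] = ()
    collision_plants: Sequence[Sequence[PlantedPair]] = ()
    seed: int = 0
    d_max: float = 5.0

    def __post_init__(self) -> None:
        if self.n_configs < 1:
            raise ValidationError("n_configs must be >= 1")
        if self.residues_per_unit < 1:
            raise ValidationError("residues_per_unit must be >= 1")
        self.planted = self._normalize(self.planted, "planted")
        self.collision_plants = self._normalize(self.collision_plants, "collision_plants")
        for per_conf in self.collision_plants:
            for p in per_conf:
                if p.target_distance >= 3.0:
                    raise ValidationError(
                        f"collision plant {p.ref_key}-{p.paired_key} must target < 3 Å"
                    )
        for conf_idx in range(self.n_configs):
            for p in self.all_plants(conf_idx):
                for key, chain in ((p.ref_key, REF_CHAIN), (p.paired_key, PAIRED_CHAIN)):
                    if key.chain_id != chain or not (1 <= key.number <= self.residues_per_unit):
                        raise ValidationError(f"plant names nonexistent residue {key}")

    def _normalize(self, plants, label) -> list[list[PlantedPair]]:
        plants = [list(per_conf) for per_conf in plants]
        if not plants:
            plants = [[] for _ in range(self.n_configs)]
        if len(plants) != self.n_configs:
            raise ValidationError(f"{label} must list plants for each of the {self.n_configs} configurations")
        return plants

    def all_plants(self, conf_idx: int) -> list[PlantedPair]:
        return list(self.planted[conf_idx]) + list(self.collision_plants[conf_idx])

    @property
    def spacing(self) -> float:
        return max(14.0, round(self.d_max, 3) + 9.0)

    @property
    def baseline_y(self) -> float:
        return round(self.d_max + 30.0, 3)


@dataclass(frozen=True)
class GroundTruthRow:
    config_id: str
    ref_key: ResidueKey
    paired_key: ResidueKey
    distance: float
    is_collision: bool


@dataclass(frozen=True)
class Finding:
    kind: str  # unexpected_contact | missing_contact | distance_mismatch |
    #            unexpected_collision | missing_collision
    config_id: str
    ref_key: ResidueKey
    paired_key: ResidueKey
    detail: str = ""


def _zigzag(index: int) -> float:
    return 0.4 * (index % 2)


def _config_id(idx: int) -> str:
    return f"conf_{idx + 1:03d}"


def _make_residue(chain: str, number: int, origin: np.ndarray, serial_start: int) -> Residue:
    atoms = []
    for offset, (name, element, local) in enumerate(_TEMPLATE):
        atoms.append(
            Atom(
                serial=serial_start + offset,
                name=name,
                element=element,
                position=np.round(origin + np.array(local), 6),
            )
        )
    name = _AA_NAMES[(number - 1) % len(_AA_NAMES)]
    return Residue(ResidueKey(chain, number), name, atoms)


def _build_configuration(spec: EnsembleSpec, conf_idx: int) -> Configuration:
    m = spec.residues_per_unit
    spacing = spec.spacing

    plants = spec.all_plants(conf_idx)
    by_paired: dict[ResidueKey, PlantedPair] = {}
    for p in plants:
        if p.paired_key in by_paired:
            q = by_paired[p.paired_key]
            raise GenerationError(
                f"configuration {conf_idx + 1}: residue {p.paired_key} is planted twice "
                f"(against {q.ref_key} at {q.target_distance} Å and {p.ref_key} at "
                f"{p.target_distance} Å) — contradictory placement"
            )
        by_paired[p.paired_key] = p

    serial = 1
    ref_residues = []
    for i in range(1, m + 1):
        # alternate z so CA atoms are never collinear (superposition needs rank >= 2)
        origin = np.array([i * spacing, 0.0, _zigzag(i)])
        ref_residues.append(_make_residue(REF_CHAIN, i, origin, serial))
        serial += len(_TEMPLATE)

    paired_residues = []
    for j in range(1, m + 1):
        key = ResidueKey(PAIRED_CHAIN, j)
        if key in by_paired:
            p = by_paired[key]
            # place CB exactly target Å above the partner residue's O atom
            o_global = (
                np.array([p.ref_key.number * spacing, 0.0, _zigzag(p.ref_key.number)])
                + _O_LOCAL
            )
            origin = o_global + np.array([0.0, p.target_distance, 0.0]) - _CB_LOCAL
        else:
            origin = np.array([j * spacing, spec.baseline_y, _zigzag(j)])
        paired_residues.append(_make_residue(PAIRED_CHAIN, j, np.round(origin, 6), serial))
        serial += len(_TEMPLATE)

    return Configuration(
        id=_config_id(conf_idx),
        reference=ProteinUnit("reference", ref_residues),
        paired=ProteinUnit("paired", paired_residues),
    )


def _check_isolation(spec: EnsembleSpec, conf: Configuration, conf_idx: int) -> None:
    """Every non-planted cross-unit pair must stay beyond d_max + 2 Å."""
    planted_keys = {(p.ref_key, p.paired_key): p for p in spec.all_plants(conf_idx)}
    from .contacts import min_residue_distance

    for ref_res in conf.reference:
        for par_res in conf.paired:
            d = min_residue_distance(ref_res, par_res)
            p = planted_keys.get((ref_res.key, par_res.key))
            if p is not None:
                if abs(d - p.target_distance) > 1e-9:
                    raise GenerationError(
                        f"{conf.id}: planted pair {ref_res.key}-{par_res.key} realized at "
                        f"{d:.9f} Å instead of {p.target_distance}"
                    )
            elif d <= spec.d_max + 2.0:
                raise GenerationError(
                    f"{conf.id}: non-planted pair {ref_res.key}-{par_res.key} at {d:.3f} Å "
                    f"violates the isolation margin (> {spec.d_max + 2.0:.3f} Å required)"
                )


def build_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, list[GroundTruthRow]]:
    """Realize the spec in memory (no files) and return ensemble + ground truth."""
    configurations, truth = [], []
    for idx in range(spec.n_configs):
        conf = _build_configuration(spec, idx)
        _check_isolation(spec, conf, idx)
        configurations.append(conf)
        for p in spec.planted[idx]:
            truth.append(GroundTruthRow(conf.id, p.ref_key, p.paired_key, p.target_distance, False))
        for p in spec.collision_plants[idx]:
            truth.append(GroundTruthRow(conf.id, p.ref_key, p.paired_key, p.target_distance, True))
    return Ensemble(configurations), truth


def write_manifest(rows: Sequence[GroundTruthRow], path: str | Path) -> Path:
    path = Path(path)
    lines = ["config_id\tref_chain\tref_resnum\tpaired_chain\tpaired_resnum\tdistance\tis_collision"]
    for r in rows:
        lines.append(
            f"{r.config_id}\t{r.ref_key.chain_id}\t{r.ref_key.number}\t"
            f"{r.paired_key.chain_id}\t{r.paired_key.number}\t{r.distance:.6f}\t"
            f"{int(r.is_collision)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_manifest(path: str | Path) -> list[GroundTruthRow]:
    rows = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        cid, rc, rn, pc, pn, dist, coll = line.split("\t")
        rows.append(
            GroundTruthRow(
                cid,
                ResidueKey(rc, int(rn)),
                ResidueKey(pc, int(pn)),
                float(dist),
                bool(int(coll)),
            )
        )
    return rows


def generate_ensemble(spec: EnsembleSpec, out_dir: str | Path) -> tuple[list[Path], list[GroundTruthRow]]:
    """Write one PDB per configuration plus a TSV ground-truth manifest.

    Identical specs produce byte-identical outputs.
    """
    from .structures_io import write_configuration

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ensemble, truth = build_ensemble(spec)
    paths = []
    for conf in ensemble:
        paths.append(write_configuration(conf, out_dir / f"{conf.id}.pdb"))
    write_manifest(truth, out_dir / "manifest.tsv")
    return paths, truth


def verify_against_truth(
    ensemble: Ensemble,
    manifest: Sequence[GroundTruthRow],
    params: ContactParams | None = None,
    tolerance: float = 1e-6,
) -> list[Finding]:
    """Cross-check computed contact zones against the generator's manifest.

    Returns an empty list iff, for every configuration, the computed contacts
    equal the manifest rows falling inside [d_min, d_max] and the computed
    collisions equal the rows flagged is_collision.
    """
    params = params or ContactParams()
    manifest_ids = {r.config_id for r in manifest}
    ensemble_ids = set(ensemble.ids)
    if not manifest_ids <= ensemble_ids:
        raise ValidationError(
            f"manifest names unknown configurations: {sorted(manifest_ids - ensemble_ids)}"
        )

    expected_contacts: dict[str, dict[tuple, float]] = {cid: {} for cid in ensemble_ids}
    expected_collisions: dict[str, dict[tuple, float]] = {cid: {} for cid in ensemble_ids}
    # classify by distance against the supplied params, not the stored flag,
    # so tightened/widened windows verify consistently
    for r in manifest:
        if r.distance < params.d_min:
            expected_collisions[r.config_id][(r.ref_key, r.paired_key)] = r.distance
        elif r.distance <= params.d_max:
            expected_contacts[r.config_id][(r.ref_key, r.paired_key)] = r.distance

    findings: list[Finding] = []
    for conf in ensemble:
        zone = compute_contact_zone(conf, params)
        exp_c = expected_contacts[conf.id]
        exp_x = expected_collisions[conf.id]
        for pair in zone.pairs:
            if pair.keys not in exp_c:
                findings.append(
                    Finding("unexpected_contact", conf.id, *pair.keys, f"{pair.distance:.6f} Å")
                )
            elif abs(pair.distance - exp_c[pair.keys]) > tolerance:
                findings.append(
                    Finding(
                        "distance_mismatch", conf.id, *pair.keys,
                        f"computed {pair.distance:.9f}, expected {exp_c[pair.keys]:.9f}",
                    )
                )
        got_c = zone.pair_keys
        for keys in exp_c:
            if keys not in got_c:
                findings.append(Finding("missing_contact", conf.id, *keys))
        got_x = {p.keys for p in zone.collisions}
        for pair in zone.collisions:
            if pair.keys not in exp_x:
                findings.append(
                    Finding("unexpected_collision", conf.id, *pair.keys, f"{pair.distance:.6f} Å")
                )
        for keys in exp_x:
            if keys not in got_x:
                findings.append(Finding("missing_collision", conf.id, *keys))
    return findings


def random_spec(
    seed: int,
    n_configs: int | None = None,
    residues_per_unit: int | None = None,
    d_max: float = 5.0,
    max_plants: int = 4,
    with_collisions: bool = True,
) -> EnsembleSpec:
    """Draw a valid randomized spec; equal seeds give equal specs."""
    rng = np.random.default_rng(seed)
    n = n_configs if n_configs is not None else int(rng.integers(1, 6))
    m = residues_per_unit if residues_per_unit is not None else int(rng.integers(3, 21))
    planted, collisions = [], []
    for _ in range(n):
        k = int(rng.integers(0, min(max_plants, m) + 1))
        paired_nums = rng.choice(np.arange(1, m + 1), size=k, replace=False)
        conf_plants, conf_colls = [], []
        for pn in paired_nums:
            rn = int(rng.integers(1, m + 1))
            if with_collisions and rng.random() < 0.25:
                dist = round(float(rng.uniform(1.5, 2.95)), 3)
                conf_colls.append(plant(rn, int(pn), dist))
            else:
                dist = round(float(rng.uniform(3.0, d_max)), 3)
                conf_plants.append(plant(rn, int(pn), dist))
        planted.append(conf_plants)
        collisions.append(conf_colls)
    return EnsembleSpec(
        n_configs=n,
        residues_per_unit=m,
        planted=planted,
        collision_plants=collisions,
        seed=seed,
        d_max=d_max,
    )
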