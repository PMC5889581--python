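import numpy as np
import pytest

from dockzones import synth_fixtures as sf
from dockzones.contacts import ContactPair, ContactParams, ContactZone
from dockzones.structures_io import Atom, Configuration, ProteinUnit, Residue, ResidueKey

AA20 = list(sf._AA_NAMES)


def make_residue(chain, number, coords, name="ALA", start_serial=1):
    atoms = [
        Atom(serial=start_serial + i, name=f"C{i}" if i else "CA", element="C", position=np.asarray(p, float))
        for i, p in enumerate(np.atleast_2d(coords))
    ]
    return Residue(ResidueKey(chain, number), name, atoms)


def make_zone(config_id, pairs, collisions=(), names=None, reference_side="reference"):
    """Build a ContactZone from (ref_num, paired_num, distance) triples."""
    def to_pair(t):
        r, p, d = t
        return ContactPair(ResidueKey("A", r), ResidueKey("B", p), float(d))

    zone_pairs = tuple(to_pair(t) for t in pairs)
    zone_colls = tuple(to_pair(t) for t in collisions)
    ref_names, paired_names = {}, {}
    for cp in zone_pairs + zone_colls:
        ref_names[cp.ref_key] = (names or {}).get(cp.ref_key, AA20[(cp.ref_key.number - 1) % 20])
        paired_names[cp.paired_key] = (names or {}).get(
            cp.paired_key, AA20[(cp.paired_key.number - 1) % 20]
        )
    return ContactZone(
        config_id, zone_pairs, zone_colls,
        reference_side=reference_side, ref_names=ref_names, paired_names=paired_names,
    )


def random_zone(rng, config_id="z", max_residues=8, reference_side="reference"):
    """Random zone over residues A:1..m x B:1..m with distinct pairs."""
    m = int(rng.integers(2, max_residues + 1))
    all_pairs = [(r, p) for r in range(1, m + 1) for p in range(1, m + 1)]
    k = int(rng.integers(0, min(len(all_pairs), 12) + 1))
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    triples = [
        (all_pairs[i][0], all_pairs[i][1], float(rng.uniform(3.0, 5.0))) for i in idx
    ]
    return make_zone(config_id, triples, reference_side=reference_side)


@pytest.fixture
def simple_spec():
    return sf.EnsembleSpec(
        n_configs=3,
        residues_per_unit=6,
        planted=[
            [sf.plant(2, 3, 4.0)],
            [sf.plant(2, 3, 4.0), sf.plant(5, 1, 3.25)],
            [],
        ],
        collision_plants=[[], [], [sf.plant(1, 2, 2.5)]],
    )


@pytest.fixture
def simple_ensemble(simple_spec):
    ensemble, truth = sf.build_ensemble(simple_spec)
    return ensemble, truth


@pytest.fixture
def aligned_spec():
    # identical plants in every configuration: reference units coincide
    return sf.EnsembleSpec(
        n_configs=5,
        residues_per_unit=8,
        planted=[[sf.plant(2, 3, 4.0), sf.plant(4, 6, 3.5)]] * 5,
    )


def brute_force_zone(conf, params=None):
    """Independent O(R^2 A^2) oracle for contact zones."""
    params = params or ContactParams()
    pairs, collisions = [], []
    for ref_res in conf.reference:
        ref_xyz = [a.position for a in ref_res.atoms if not a.is_hydrogen]
        for par_res in conf.paired:
            par_xyz = [a.position for a in par_res.atoms if not a.is_hydrogen]
            best = min(
                float(np.linalg.norm(pa - pb)) for pa in ref_xyz for pb in par_xyz
            )
            if best <= params.d_max:
                entry = (ref_res.key, par_res.key, best)
                if best < params.d_min:
                    collisions.append(entry)
                else:
                    pairs.append(entry)
    return sorted(pairs), sorted(collisions)
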