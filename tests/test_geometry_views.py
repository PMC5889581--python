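import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from dockzones import synth_fixtures as sf
from dockzones.contacts import compute_contact_zone
from dockzones.errors import (
    AlignmentError,
    DegenerateInputError,
    LayoutError,
    ValidationError,
)
from dockzones.geometry_views import (
    RigidTransform,
    align_ensemble,
    contact_zone_centroid,
    contact_zone_normal,
    exploded_layout,
    kabsch_superpose,
    open_book_transforms,
)
from dockzones.structures_io import Configuration, Ensemble


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def aligned_fixture(n=5, m=8):
    spec = sf.EnsembleSpec(n, m, planted=[[sf.plant(2, 3, 4.0), sf.plant(4, 6, 3.5)]] * n)
    ens, _ = sf.build_ensemble(spec)
    zones = {c.id: compute_contact_zone(c) for c in ens}
    return ens, zones


class TestRigidTransform:
    def test_identity(self):
        t = RigidTransform.identity()
        x = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(t.apply(x), x)

    def test_rejects_reflection(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self):
        rng = np.random.default_rng(1)
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        x = rng.normal(size=(7, 3))
        roundtrip = t.inverse().apply(t.apply(x))
        np.testing.assert_allclose(roundtrip, x, atol=1e-12)

    def test_as_matrix_homogeneous(self):
        rng = np.random.default_rng(2)
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        x = rng.normal(size=(5, 3))
        hom = np.hstack([x, np.ones((5, 1))]) @ t.as_matrix().T
        np.testing.assert_allclose(hom[:, :3], t.apply(x), atol=1e-12)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = kabsch_superpose(x, x)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, np.zeros(3), atol=1e-12)
        assert rmsd < 1e-12

    def test_recovers_planted_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        y = x @ rot.T + np.array([5.0, 0.0, 0.0])
        t, rmsd = kabsch_superpose(x, y)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, [5, 0, 0], atol=1e-9)
        assert rmsd < 1e-9

    def test_100_random_planted_transforms(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.normal(size=(int(rng.integers(4, 30)), 3))
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 10
            y = x @ rot.T + shift
            t, rmsd = kabsch_superpose(x, y)
            assert rmsd < 1e-9
            np.testing.assert_allclose(t.rotation, rot, atol=1e-8)

    def test_noisy_rmsd_matches_svd_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 3))
        y = x @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(size=(20, 3)) * 0.1
        t, rmsd = kabsch_superpose(x, y)
        # independent oracle: scipy's align_vectors on centered clouds
        rot_oracle, _ = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        residual = (x - x.mean(0)) @ rot_oracle.as_matrix().T - (y - y.mean(0))
        rmsd_oracle = np.sqrt((residual**2).sum() / len(x))
        assert rmsd == pytest.approx(rmsd_oracle, abs=1e-9)
        np.testing.assert_allclose(t.rotation, rot_oracle.as_matrix(), atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(x, x * 2.0)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=(6, 3))
            y = rng.normal(size=(6, 3))
            t, _ = kabsch_superpose(x, y)
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


class TestAlignEnsemble:
    def test_identical_references_coincide(self):
        ens, _ = aligned_fixture()
        aligned, results = align_ensemble(ens)
        anchor_ca = np.array(
            [r.atom("CA").position for r in aligned.configurations[0].reference]
        )
        for conf, res in zip(aligned, results):
            assert res.rmsd < 1e-9
            ca = np.array([r.atom("CA").position for r in conf.reference])
            np.testing.assert_allclose(ca, anchor_ca, atol=1e-9)

    def test_contact_distances_preserved(self):
        ens, zones = aligned_fixture()
        # pre-rotate each configuration rigidly so alignment has work to do
        rng = np.random.default_rng(11)
        moved = []
        for conf in ens:
            t = RigidTransform(random_rotation(rng), rng.normal(size=3) * 20)
            moved.append(
                Configuration(conf.id, conf.reference.transformed(t), conf.paired.transformed(t))
            )
        aligned, results = align_ensemble(Ensemble(moved))
        for conf in aligned:
            zone = compute_contact_zone(conf)
            orig = {p.keys: p.distance for p in zones[conf.id].pairs}
            got = {p.keys: p.distance for p in zone.pairs}
            assert set(got) == set(orig)
            for k in orig:
                assert abs(got[k] - orig[k]) < 1e-9

    def test_recovers_planted_inverse(self):
        ens, _ = aligned_fixture(n=3)
        rng = np.random.default_rng(13)
        transforms = {}
        moved = [ens.configurations[0]]
        for conf in list(ens)[1:]:
            t = RigidTransform(random_rotation(rng), rng.normal(size=3) * 10)
            transforms[conf.id] = t
            moved.append(
                Configuration(conf.id, conf.reference.transformed(t), conf.paired.transformed(t))
            )
        _, results = align_ensemble(Ensemble(moved), anchor=ens.configurations[0].id)
        for res in results[1:]:
            inv = transforms[res.config_id].inverse()
            np.testing.assert_allclose(res.transform.rotation, inv.rotation, atol=1e-9)
            np.testing.assert_allclose(res.transform.translation, inv.translation, atol=1e-8)

    def test_alignment_idempotent(self):
        ens, _ = aligned_fixture()
        aligned, _ = align_ensemble(ens)
        again, results = align_ensemble(aligned)
        for res in results:
            np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(res.transform.translation, np.zeros(3), atol=1e-8)

    def test_anchor_unmoved(self):
        ens, _ = aligned_fixture(n=3)
        aligned, results = align_ensemble(ens, anchor="conf_002")
        orig = ens.get("conf_002").reference.heavy_coords()
        new = aligned.get("conf_002").reference.heavy_coords()
        np.testing.assert_array_equal(orig, new)

    def test_no_common_ca_errors(self):
        ens, _ = aligned_fixture(n=2)
        # strip CA atoms from one configuration's reference unit
        conf = ens.configurations[1]
        from dockzones.structures_io import ProteinUnit, Residue

        bald = ProteinUnit(
            "reference",
            [
                Residue(r.key, r.name, [a for a in r.atoms if a.name != "CA"])
                for r in conf.reference
            ],
        )
        broken = Ensemble([ens.configurations[0], Configuration(conf.id, bald, conf.paired)])
        with pytest.raises(AlignmentError, match="conf_002"):
            align_ensemble(broken, anchor="conf_001")


class TestZoneGeometry:
    def test_centroid_single_residue(self):
        ens, zones = aligned_fixture(n=1)
        conf = ens.configurations[0]
        zone = zones[conf.id]
        centroid = contact_zone_centroid(conf, zone, "reference")
        cas = [conf.reference.get(k).atom("CA").position for k in sorted(zone.ref_residues)]
        np.testing.assert_allclose(centroid, np.mean(cas, axis=0), atol=1e-12)

    def test_centroid_mean_oracle(self):
        ens, zones = aligned_fixture(n=1)
        conf = ens.configurations[0]
        zone = zones[conf.id]
        for side in ("reference", "paired"):
            unit = conf.unit(side)
            pts = [unit.get(k).atom("CA").position for k in sorted(zone.residues(side))]
            np.testing.assert_allclose(
                contact_zone_centroid(conf, zone, side), np.mean(pts, axis=0), atol=1e-12
            )

    def test_empty_side_errors(self):
        ens, _ = aligned_fixture(n=1)
        conf = ens.configurations[0]
        from conftest import make_zone

        with pytest.raises(ValidationError, match="empty"):
            contact_zone_centroid(conf, make_zone(conf.id, []), "reference")

    def test_normal_of_coplanar_zone(self):
        # 3 residues in the z=0 plane, partner above at +z
        from conftest import make_residue
        from dockzones.structures_io import ProteinUnit

        ref = ProteinUnit(
            "reference",
            [
                make_residue("A", 1, [[0, 0, 0]]),
                make_residue("A", 2, [[4, 0, 0]]),
                make_residue("A", 3, [[0, 4, 0]]),
            ],
        )
        par = ProteinUnit("paired", [make_residue("B", 1, [[1, 1, 4.0]])])
        conf = Configuration("c", ref, par)
        zone = compute_contact_zone(conf)
        from conftest import make_zone

        zone3 = make_zone("c", [(1, 1, 4.0), (2, 1, 4.0), (3, 1, 4.0)])
        n = contact_zone_normal(conf, zone3, "reference")
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-9)

    def test_normal_sign_follows_partner(self):
        from conftest import make_residue, make_zone
        from dockzones.structures_io import ProteinUnit

        ref = ProteinUnit(
            "reference",
            [
                make_residue("A", 1, [[0, 0, 0]]),
                make_residue("A", 2, [[4, 0, 0]]),
                make_residue("A", 3, [[0, 4, 0]]),
            ],
        )
        par = ProteinUnit("paired", [make_residue("B", 1, [[1, 1, -4.0]])])
        conf = Configuration("c", ref, par)
        zone3 = make_zone("c", [(1, 1, 4.0), (2, 1, 4.0), (3, 1, 4.0)])
        n = contact_zone_normal(conf, zone3, "reference")
        np.testing.assert_allclose(n, [0, 0, -1], atol=1e-9)

    def test_normal_orthogonal_to_leading_directions(self):
        rng = np.random.default_rng(31)
        from conftest import make_residue, make_zone
        from dockzones.structures_io import ProteinUnit

        for _ in range(10):
            pts = rng.normal(size=(6, 3)) * [5, 3, 0.3]  # flattened cloud
            ref = ProteinUnit(
                "reference", [make_residue("A", i + 1, [p]) for i, p in enumerate(pts)]
            )
            par = ProteinUnit("paired", [make_residue("B", 1, [[0, 0, 30.0]])])
            conf = Configuration("c", ref, par)
            zone = make_zone("c", [(i + 1, 1, 4.0) for i in range(6)])
            n = contact_zone_normal(conf, zone, "reference")
            centered = pts - pts.mean(0)
            _, _, vt = np.linalg.svd(centered)
            assert abs(np.dot(n, vt[0])) < 1e-9
            assert abs(np.dot(n, vt[1])) < 1e-9


class TestExplodedLayout:
    def test_single_configuration_on_axis(self):
        ens, zones = aligned_fixture(n=1)
        plan = exploded_layout(ens, zones)
        conf = ens.configurations[0]
        cid = conf.id
        start, end = plan.tubes[cid]
        np.testing.assert_allclose(
            start, contact_zone_centroid(conf, zones[cid], "reference"), atol=1e-9
        )
        np.testing.assert_allclose(
            end,
            plan.slots[cid].apply(contact_zone_centroid(conf, zones[cid], "paired")),
            atol=1e-9,
        )

    def test_no_bounding_sphere_overlap(self):
        ens, zones = aligned_fixture(n=9)
        aligned, _ = align_ensemble(ens)
        plan = exploded_layout(aligned, zones)
        centers, radii = [], []
        for conf in aligned:
            coords = plan.slots[conf.id].apply(conf.paired.heavy_coords())
            c = coords.mean(axis=0)
            centers.append(c)
            radii.append(np.linalg.norm(coords - c, axis=1).max())
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
                assert gap > 0

    def test_translation_only(self):
        ens, zones = aligned_fixture(n=4)
        plan = exploded_layout(ens, zones)
        for conf in ens:
            t = plan.slots[conf.id]
            np.testing.assert_array_equal(t.rotation, np.eye(3))
            before = pdist(conf.paired.heavy_coords())
            after = pdist(t.apply(conf.paired.heavy_coords()))
            np.testing.assert_allclose(before, after, atol=1e-9)

    def test_min_center_distance_at_least_step(self):
        ens, zones = aligned_fixture(n=9)
        plan = exploded_layout(ens, zones)
        centers = [
            plan.slots[c.id].apply(c.paired.heavy_coords().mean(axis=0)) for c in ens
        ]
        dmin = min(
            np.linalg.norm(a - b) for i, a in enumerate(centers) for b in centers[i + 1:]
        )
        assert dmin >= plan.spacing - 1e-6

    def test_empty_zone_errors(self):
        ens, zones = aligned_fixture(n=2)
        from conftest import make_zone

        zones = dict(zones)
        zones["conf_002"] = make_zone("conf_002", [])
        with pytest.raises(LayoutError):
            exploded_layout(ens, zones)


class TestOpenBook:
    def test_normals_face_viewer(self):
        ens, zones = aligned_fixture(n=1)
        conf = ens.configurations[0]
        res = open_book_transforms(conf, zones[conf.id])
        view = np.array([0.0, 0.0, 1.0])
        assert np.dot(res.normal_ref_after, view) >= 0.999
        assert np.dot(res.normal_paired_after, view) >= 0.999

    def test_gap_between_bounding_boxes(self):
        ens, zones = aligned_fixture(n=1)
        conf = ens.configurations[0]
        res = open_book_transforms(conf, zones[conf.id], gap=12.0)
        ref = conf.reference.transformed(res.transform_ref).heavy_coords()
        par = conf.paired.transformed(res.transform_paired).heavy_coords()
        assert par[:, 0].min() - ref[:, 0].max() >= 12.0 - 1e-9

    def test_internal_distances_preserved(self):
        ens, zones = aligned_fixture(n=1)
        conf = ens.configurations[0]
        res = open_book_transforms(conf, zones[conf.id])
        for unit, t in (
            (conf.reference, res.transform_ref),
            (conf.paired, res.transform_paired),
        ):
            before = pdist(unit.heavy_coords())
            after = pdist(t.apply(unit.heavy_coords()))
            assert np.abs(before - after).max() < 1e-9

    def test_already_facing_is_near_identity_rotation(self):
        from conftest import make_residue, make_zone
        from dockzones.structures_io import ProteinUnit

        ref = ProteinUnit(
            "reference",
            [
                make_residue("A", 1, [[0, 0, 0]]),
                make_residue("A", 2, [[4, 0, 0]]),
                make_residue("A", 3, [[0, 4, 0]]),
            ],
        )
        par = ProteinUnit(
            "paired",
            [
                make_residue("B", 1, [[0, 0, 4]]),
                make_residue("B", 2, [[4, 0, 4]]),
                make_residue("B", 3, [[0, 4, 4]]),
            ],
        )
        conf = Configuration("c", ref, par)
        zone = make_zone("c", [(1, 1, 4.0), (2, 2, 4.0), (3, 3, 4.0)])
        res = open_book_transforms(conf, zone)
        # reference normal already +z
        np.testing.assert_allclose(res.transform_ref.rotation, np.eye(3), atol=1e-9)

    def test_antiparallel_normal_flipped(self):
        from conftest import make_residue, make_zone
        from dockzones.structures_io import ProteinUnit

        # paired zone normal points -z (towards reference below)
        ref = ProteinUnit(
            "reference",
            [
                make_residue("A", 1, [[0, 0, 0]]),
                make_residue("A", 2, [[4, 0, 0]]),
                make_residue("A", 3, [[0, 4, 0]]),
            ],
        )
        par = ProteinUnit(
            "paired",
            [
                make_residue("B", 1, [[0, 0, 4]]),
                make_residue("B", 2, [[4, 0, 4]]),
                make_residue("B", 3, [[0, 4, 4]]),
            ],
        )
        conf = Configuration("c", ref, par)
        zone = make_zone("c", [(1, 1, 4.0), (2, 2, 4.0), (3, 3, 4.0)])
        res = open_book_transforms(conf, zone)
        assert np.dot(res.normal_paired_before, [0, 0, 1]) == pytest.approx(-1.0)
        assert np.dot(res.normal_paired_after, [0, 0, 1]) >= 0.999

    def test_random_orientations(self):
        rng = np.random.default_rng(55)
        # three contacts on non-collinear residues so the least-squares plane
        # normal is well defined on both sides (matches the package's rule)
        spec = sf.EnsembleSpec(
            1, 8, planted=[[sf.plant(2, 3, 4.0), sf.plant(4, 6, 3.5), sf.plant(5, 1, 3.8)]]
        )
        ens, _ = sf.build_ensemble(spec)
        base = ens.configurations[0]
        zone = compute_contact_zone(base)
        view = np.array([0.0, 0.0, 1.0])
        for _ in range(10):
            t = RigidTransform(random_rotation(rng), rng.normal(size=3) * 5)
            conf = Configuration(base.id, base.reference.transformed(t), base.paired.transformed(t))
            res = open_book_transforms(conf, zone, gap=10.0)
            moved = Configuration(
                conf.id,
                conf.reference.transformed(res.transform_ref),
                conf.paired.transformed(res.transform_paired),
            )
            # recompute plane normals after the transform (sign-free check)
            for side in ("reference", "paired"):
                unit = moved.unit(side)
                pts = np.array(
                    [unit.get(k).atom("CA").position for k in sorted(zone.residues(side))]
                )
                _, _, vt = np.linalg.svd(pts - pts.mean(0))
                dot = abs(np.dot(vt[-1], view))
                assert dot >= np.cos(np.deg2rad(2.6))
            ref = moved.reference.heavy_coords()
            par = moved.paired.heavy_coords()
            assert par[:, 0].min() - ref[:, 0].max() >= 10.0 - 1e-9
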