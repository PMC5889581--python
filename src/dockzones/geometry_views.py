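"""Rigid-body machinery for the exploded and open-book layouts.

Everything here emits explicit transforms (rotation matrix + translation)
rather than rendered geometry: superposition of reference units across the
ensemble, contact-zone centroids and least-squares plane normals, a
parabolic-grid layout that provably never overlaps paired-unit bounding
spheres, and the pair of transforms that opens one configuration so both
contact surfaces face the viewer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactZone
from .errors import AlignmentError, DegenerateInputError, LayoutError, ValidationError
from .structures_io import Configuration, Ensemble, ProteinUnit, ResidueKey

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "LayoutPlan",
    "OpenBookResult",
    "kabsch_superpose",
    "align_ensemble",
    "contact_zone_centroid",
    "contact_zone_normal",
    "exploded_layout",
    "open_book_transforms",
]

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-8):
            raise ValidationError("rotation matrix must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class AlignmentResult:
    config_id: str
    transform: RigidTransform
    rmsd: float
    n_matched: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValidationError("rmsd must be non-negative")
        if self.n_matched < 3:
            raise ValidationError("alignment needs at least 3 matched atoms")


@dataclass
class LayoutPlan:
    """Exploded-view layout: translation slot per configuration plus tubes."""

    slots: dict[str, RigidTransform]  # paired-unit transforms (pure translations)
    tubes: dict[str, tuple[np.ndarray, np.ndarray]]  # (ref centroid, moved paired centroid)
    spacing: float
    focal: float
    axis: np.ndarray

    def to_dict(self) -> dict:
        return {
            "grid": {
                "spacing": self.spacing,
                "focal": self.focal,
                "axis": [round(float(x), 9) for x in self.axis],
            },
            "configurations": [
                {
                    "id": cid,
                    "paired_transform": [
                        round(float(x), 9) for x in self.slots[cid].as_matrix().ravel()
                    ],
                    "tube": [
                        [round(float(x), 6) for x in self.tubes[cid][0]],
                        [round(float(x), 6) for x in self.tubes[cid][1]],
                    ],
                }
                for cid in self.slots
            ],
        }


@dataclass
class OpenBookResult:
    config_id: str
    transform_ref: RigidTransform
    transform_paired: RigidTransform
    normal_ref_before: np.ndarray
    normal_paired_before: np.ndarray
    normal_ref_after: np.ndarray
    normal_paired_after: np.ndarray
    gap: float

    def to_dict(self) -> dict:
        def vec(v):
            return [round(float(x), 9) for x in v]

        return {
            "config_id": self.config_id,
            "reference_transform": [round(float(x), 9) for x in self.transform_ref.as_matrix().ravel()],
            "paired_transform": [round(float(x), 9) for x in self.transform_paired.as_matrix().ravel()],
            "normals_before": {"reference": vec(self.normal_ref_before), "paired": vec(self.normal_paired_before)},
            "normals_after": {"reference": vec(self.normal_ref_after), "paired": vec(self.normal_paired_after)},
            "gap": self.gap,
        }


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rotation + translation taking ``moving``
    onto ``fixed`` (SVD with determinant correction), plus the residual RMSD.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("point sets must both have shape (n, 3)")
    n = len(moving)
    if n < 3:
        raise DegenerateInputError("superposition needs at least 3 point pairs")

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # collinearity check: centered points must span at least a plane on one side
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 and np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise DegenerateInputError("point sets are collinear; rotation is underdetermined")

    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = fc - rotation @ mc
    transform = RigidTransform(rotation, translation)
    residual = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((residual**2).sum() / n))
    return transform, rmsd


def _ca_map(unit: ProteinUnit) -> dict[ResidueKey, np.ndarray]:
    out = {}
    for res in unit:
        ca = res.atom("CA")
        if ca is not None and not ca.is_hydrogen:
            out[res.key] = ca.position
    return out


def _transform_configuration(conf: Configuration, transform: RigidTransform) -> Configuration:
    return Configuration(
        conf.id,
        conf.reference.transformed(transform),
        conf.paired.transformed(transform),
    )


def align_ensemble(
    ensemble: Ensemble, anchor: str | None = None
) -> tuple[Ensemble, list[AlignmentResult]]:
    """Superpose every configuration's reference unit onto the anchor's.

    Correspondence is the intersection of reference-unit residue keys that
    carry a CA atom; each configuration is moved rigidly as a whole (both
    units).  The anchor (default: the primary, else the first configuration)
    is left unmoved.
    """
    if len(ensemble) == 0:
        raise ValidationError("cannot align an empty ensemble")
    anchor_id = anchor or ensemble.primary_id or ensemble.configurations[0].id
    anchor_conf = ensemble.get(anchor_id)
    anchor_ca = _ca_map(anchor_conf.reference)

    aligned, results = [], []
    for conf in ensemble:
        if conf.id == anchor_id:
            aligned.append(conf)
            results.append(AlignmentResult(conf.id, RigidTransform.identity(), 0.0, len(anchor_ca)))
            continue
        ca = _ca_map(conf.reference)
        common = sorted(set(ca) & set(anchor_ca))
        if len(common) < 3:
            raise AlignmentError(conf.id, f"only {len(common)} common CA atoms with anchor {anchor_id!r}")
        moving = np.array([ca[k] for k in common])
        fixed = np.array([anchor_ca[k] for k in common])
        try:
            transform, rmsd = kabsch_superpose(moving, fixed)
        except DegenerateInputError as exc:
            raise AlignmentError(conf.id, str(exc)) from exc
        aligned.append(_transform_configuration(conf, transform))
        results.append(AlignmentResult(conf.id, transform, rmsd, len(common)))
    return Ensemble(aligned, primary_id=ensemble.primary_id), results


# ---------------------------------------------------------------------------
# contact-zone geometry


def _zone_anchor_coords(conf: Configuration, zone: ContactZone, side: str) -> np.ndarray:
    """One point per contact-zone residue: its CA, or its heavy-atom centroid."""
    keys = sorted(zone.residues(side))
    if not keys:
        raise ValidationError(f"contact zone of {conf.id!r} is empty on the {side} side")
    unit = conf.unit(side)
    points = []
    for key in keys:
        res = unit.get(key)
        if res is None:
            raise ValidationError(f"zone residue {key} absent from the {side} unit of {conf.id!r}")
        ca = res.atom("CA")
        if ca is not None and not ca.is_hydrogen:
            points.append(ca.position)
        else:
            points.append(res.heavy_coords().mean(axis=0))
    return np.array(points, dtype=float)


def contact_zone_centroid(conf: Configuration, zone: ContactZone, side: str) -> np.ndarray:
    """Mean anchor position (CA, falling back to heavy centroid) of the side's
    contact-zone residues."""
    return _zone_anchor_coords(conf, zone, side).mean(axis=0)


def _other_side(side: str) -> str:
    return "paired" if side == "reference" else "reference"


def contact_zone_normal(conf: Configuration, zone: ContactZone, side: str) -> np.ndarray:
    """Unit normal of the least-squares plane through the side's zone residues,
    oriented towards the partner side's centroid.

    With fewer than 3 residues the plane is underdetermined and the unit
    vector towards the partner centroid is returned instead.
    """
    points = _zone_anchor_coords(conf, zone, side)
    partner_centroid = contact_zone_centroid(conf, zone, _other_side(side))
    centroid = points.mean(axis=0)
    towards = partner_centroid - centroid

    if len(points) < 3:
        norm = np.linalg.norm(towards)
        if norm < 1e-12:
            raise DegenerateInputError(
                f"contact zone of {conf.id!r}: coincident centroids, normal undefined"
            )
        return towards / norm

    centered = points - centroid
    if np.linalg.norm(centered) < 1e-12:
        raise DegenerateInputError(f"contact zone of {conf.id!r}: coincident points")
    # smallest principal direction of the residue cloud
    _, svals, vt = np.linalg.svd(centered, full_matrices=True)
    normal = vt[-1]
    if np.dot(normal, towards) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


# ---------------------------------------------------------------------------
# exploded view


def _bounding_sphere(unit: ProteinUnit) -> tuple[np.ndarray, float]:
    coords = unit.heavy_coords()
    center = coords.mean(axis=0)
    radius = float(np.linalg.norm(coords - center, axis=1).max())
    return center, radius


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane unit vectors (u, v) orthogonal to ``axis``."""
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def exploded_layout(
    ensemble: Ensemble,
    zones: Mapping[str, ContactZone],
    spacing_margin: float = 10.0,
    focal: float | None = None,
    order: Sequence[str] | None = None,
) -> LayoutPlan:
    """Translate each paired unit to a slot on a parabolic grid.

    The grid axis is the mean reference-side contact-zone normal; slots sit
    row-major at regular (u, v) positions with step 2*R_max + margin on the
    paraboloid w = (u^2 + v^2) / (4 f), which makes the paired-unit bounding
    spheres provably disjoint.  Paired units are translated, never rotated.
    """
    if len(ensemble) == 0:
        raise LayoutError("cannot lay out an empty ensemble")
    ids = list(order) if order is not None else ensemble.ids
    for cid in ids:
        if cid not in zones:
            raise LayoutError(f"no contact zone for configuration {cid!r}")
        if len(zones[cid]) == 0:
            raise LayoutError(f"contact zone of configuration {cid!r} is empty")

    normals, ref_centroids = [], []
    for cid in ids:
        conf = ensemble.get(cid)
        normals.append(contact_zone_normal(conf, zones[cid], "reference"))
        ref_centroids.append(contact_zone_centroid(conf, zones[cid], "reference"))
    axis = np.mean(normals, axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        axis = np.array([0.0, 0.0, 1.0])  # normals cancel; fall back to +z
    else:
        axis = axis / norm

    spheres = {cid: _bounding_sphere(ensemble.get(cid).paired) for cid in ids}
    r_max = max(r for _, r in spheres.values())
    r_ref = max(_bounding_sphere(ensemble.get(cid).reference)[1] for cid in ids)
    step = 2.0 * r_max + spacing_margin
    f = focal if focal is not None else max(2.0 * r_max, 1.0)
    if f <= 0:
        raise LayoutError("focal length must be positive")

    base = np.mean(ref_centroids, axis=0) + axis * (r_ref + r_max + spacing_margin)
    u_vec, v_vec = _orthonormal_frame(axis)
    m = math.ceil(math.sqrt(len(ids)))

    slots, tubes = {}, {}
    for idx, cid in enumerate(ids):
        col, row = idx % m, idx // m
        uu = (col - (m - 1) / 2.0) * step
        vv = (row - (m - 1) / 2.0) * step
        ww = (uu * uu + vv * vv) / (4.0 * f)
        slot_center = base + uu * u_vec + vv * v_vec + ww * axis
        center, _ = spheres[cid]
        transform = RigidTransform.from_translation(slot_center - center)
        slots[cid] = transform
        conf = ensemble.get(cid)
        paired_centroid = contact_zone_centroid(conf, zones[cid], "paired")
        tubes[cid] = (
            contact_zone_centroid(conf, zones[cid], "reference"),
            transform.apply(paired_centroid),
        )
    return LayoutPlan(slots, tubes, spacing=step, focal=f, axis=axis)


# ---------------------------------------------------------------------------
# open-book view


def _minimal_rotation(from_vec: np.ndarray, to_vec: np.ndarray, fallback_axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``from_vec`` to ``to_vec`` about
    their common perpendicular; antiparallel input rotates 180 degrees about
    ``fallback_axis`` (deterministic)."""
    c = float(np.clip(np.dot(from_vec, to_vec), -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        a = fallback_axis / np.linalg.norm(fallback_axis)
        return 2.0 * np.outer(a, a) - np.eye(3)
    axis = np.cross(from_vec, to_vec)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def open_book_transforms(
    conf: Configuration,
    zone: ContactZone,
    view_dir: Sequence[float] = (0.0, 0.0, 1.0),
    gap: float = 10.0,
) -> OpenBookResult:
    """Open one configuration like a book: rotate each unit about its zone
    centroid so its contact-zone normal points along ``view_dir``, then place
    the units side by side with at least ``gap`` Å between bounding boxes.
    """
    view = np.asarray(view_dir, dtype=float)
    norm = np.linalg.norm(view)
    if norm < 1e-12:
        raise ValidationError("view_dir must be a nonzero vector")
    view = view / norm
    sep_axis, _ = _orthonormal_frame(view)  # in-plane separation direction

    normals_before = {
        side: contact_zone_normal(conf, zone, side) for side in ("reference", "paired")
    }

    transforms: dict[str, RigidTransform] = {}
    normals_after: dict[str, np.ndarray] = {}
    extents: dict[str, tuple[float, float]] = {}
    rotated_units: dict[str, ProteinUnit] = {}
    for side, sign in (("reference", -1.0), ("paired", +1.0)):
        unit = conf.unit(side)
        centroid = contact_zone_centroid(conf, zone, side)
        rotation = _minimal_rotation(normals_before[side], view, sep_axis)
        about_centroid = RigidTransform(rotation, centroid - rotation @ centroid)
        rotated = unit.transformed(about_centroid)
        rotated_units[side] = rotated
        coords = rotated.heavy_coords()
        proj = coords @ sep_axis
        extents[side] = (float(proj.min()), float(proj.max()))
        transforms[side] = about_centroid
        normals_after[side] = rotation @ normals_before[side]

    # slide the units apart along the separation axis: reference to the left,
    # paired to the right, exactly `gap` between axis-aligned extents
    shift_ref = (-gap / 2.0) - extents["reference"][1]
    shift_par = (gap / 2.0) - extents["paired"][0]
    for side, shift in (("reference", shift_ref), ("paired", shift_par)):
        slide = RigidTransform.from_translation(shift * sep_axis)
        transforms[side] = slide.compose(transforms[side])

    return OpenBookResult(
        config_id=conf.id,
        transform_ref=transforms["reference"],
        transform_paired=transforms["paired"],
        normal_ref_before=normals_before["reference"],
        normal_paired_before=normals_before["paired"],
        normal_ref_after=normals_after["reference"],
        normal_paired_after=normals_after["paired"],
        gap=gap,
    )
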