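"""Screw-transform fitting, application and fragment replication.

A screw motion (rotation about plus translation along a single axis) is
the generator of filament helical symmetry: one protein subunit maps onto
the next by one screw step.  Fitting the screw between equivalent point
sets is done by least-squares rigid superposition followed by closed-form
decomposition of the rigid motion into its axis, rotation angle and pitch
translation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .structure import Structure


class GeometryError(ValueError):
    pass


@dataclasses.dataclass
class Axis:
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise GeometryError("axis direction must be non-zero")
            self.direction = self.direction / norm

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate of points along the axis."""
        return (np.atleast_2d(points) - self.point) @ self.direction

    def radial_vectors(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.point
        return rel - np.outer(rel @ self.direction, self.direction)

    def radii(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.radial_vectors(points), axis=1)

    def azimuths(self, points: np.ndarray) -> np.ndarray:
        """Azimuth (degrees) of each point about the axis, right-handed.

        The zero reference is an arbitrary but fixed direction orthogonal
        to the axis, so only azimuth differences are meaningful.
        """
        e1, e2 = _orthonormal_frame(self.direction)
        rad = self.radial_vectors(points)
        return np.degrees(np.arctan2(rad @ e2, rad @ e1))


def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def rotation_about_axis(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit direction."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    theta = math.radians(angle_deg)
    k = np.array([[0, -direction[2], direction[1]],
                  [direction[2], 0, -direction[0]],
                  [-direction[1], direction[0], 0]])
    return np.eye(3) + math.sin(theta) * k + (1.0 - math.cos(theta)) * (k @ k)


@dataclasses.dataclass
class ScrewTransform:
    """Rigid screw motion: rotate ``angle_per_step`` about the axis then
    translate ``translation_per_step`` along it, per integer step."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    angle_per_step: float      # degrees, right-handed about axis_dir
    translation_per_step: float  # Å

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(self.axis_dir)
        if norm == 0:
            raise GeometryError("screw axis direction must be non-zero")
        self.axis_dir = self.axis_dir / norm
        # Wrap the per-step angle into (-180, 180].
        angle = float(self.angle_per_step) % 360.0
        if angle > 180.0:
            angle -= 360.0
        self.angle_per_step = angle

    @property
    def axis(self) -> Axis:
        return Axis(self.axis_point, self.axis_dir)

    def matrix(self, n: int | float = 1) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) of n screw steps: x -> R @ (x - c) + c + n*d*u."""
        rot = rotation_about_axis(self.axis_dir, self.angle_per_step * n)
        shift = self.translation_per_step * n * self.axis_dir
        offset = self.axis_point - rot @ self.axis_point + shift
        return rot, offset

    def transform_points(self, points: np.ndarray, n: int | float = 1) -> np.ndarray:
        rot, offset = self.matrix(n)
        return np.atleast_2d(points) @ rot.T + offset

    def steps_per_turn(self) -> float:
        if self.angle_per_step == 0:
            raise GeometryError("pure translation has no angular period")
        return 360.0 / abs(self.angle_per_step)


def apply_screw(transform: ScrewTransform, structure: Structure, n: int = 1) -> Structure:
    """Rigidly move a structure by n screw steps (negative n = inverse)."""
    return structure.with_coords(transform.transform_points(structure.coords, n))


def fit_screw(coords_a: np.ndarray, coords_b: np.ndarray) -> ScrewTransform:
    """Screw motion minimising the RMSD of coords_a mapped onto coords_b.

    The rotation comes from least-squares superposition (Kabsch); the rigid
    motion is then decomposed into a rotation about a unique axis plus a
    translation along it.  An identity pair returns angle 0, translation 0.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 3:
        raise GeometryError("screw fit needs two matched sets of at least 3 points")
    if _collinear(a):
        raise GeometryError("screw fit is degenerate for collinear points")
    rot, offset = _kabsch(a, b)
    return _decompose_rigid(rot, offset, fallback_point=a.mean(axis=0))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = math.copysign(1.0, np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cb - rot @ ca


def _decompose_rigid(rot: np.ndarray, offset: np.ndarray,
                     fallback_point: np.ndarray) -> ScrewTransform:
    cos_theta = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    theta = math.acos(cos_theta)
    if theta < 1e-9:
        # Pure translation (or identity).
        norm = np.linalg.norm(offset)
        direction = offset / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        return ScrewTransform(fallback_point, direction, 0.0, norm)
    skew = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]])
    if np.linalg.norm(skew) > 1e-8:
        direction = skew / np.linalg.norm(skew)
    else:
        # theta ~ 180 deg: axis from the symmetric part.
        eigval, eigvec = np.linalg.eigh((rot + rot.T) / 2.0)
        direction = eigvec[:, np.argmax(eigval)]
        direction = direction / np.linalg.norm(direction)
    translation = float(offset @ direction)
    perp = offset - translation * direction
    # Axis point solves (I - R) c = t_perp in the plane orthogonal to the axis.
    point, *_ = np.linalg.lstsq(np.eye(3) - rot, perp, rcond=None)
    point = point - (point @ direction) * direction
    angle = math.degrees(theta)
    # Canonical orientation: positive pitch; for pure rotations, positive angle.
    if translation < -1e-12 or (abs(translation) <= 1e-12 and angle < 0):
        direction, translation, angle = -direction, -translation, -angle
    return ScrewTransform(point, direction, angle, translation)


def replicate_along_screw(fragment: Structure, transform: ScrewTransform,
                          count: int) -> Structure:
    """Concatenate ``count`` screw-related copies of a fragment.

    Copy k is the fragment advanced by k-1 screw steps; residues are
    renumbered sequentially per chain so the result reads as one
    continuous molecule.
    """
    if count < 1:
        raise ValueError("replication count must be >= 1")
    residues_per_chain = {c: len(fragment.residue_indices(c)) for c in fragment.chains()}
    atoms = []
    for k in range(count):
        copy = apply_screw(transform, fragment, k)
        for atom in copy.atoms:
            moved = atom.copy()
            moved.residue_index = atom.residue_index + k * residues_per_chain[atom.chain_id]
            atoms.append(moved)
    meta = dict(fragment.metadata)
    meta["replicated"] = {"count": count,
                          "angle_per_step": transform.angle_per_step,
                          "translation_per_step": transform.translation_per_step}
    return Structure(atoms, fragment.roles, meta)


def infer_axis(structure: Structure, period: int, chain_id: str | None = None) -> Axis:
    """Helix axis of a periodic strand from windowed screw fits.

    Residues ``i..i+w`` are fitted onto ``i+period..i+period+w`` for every
    admissible window (w = max(period, 2) residues) and the per-window axes
    are averaged with equal weight.  Bridging O3' atoms are excluded from
    the fits: they point at the following residue and so are not
    screw-periodic across region boundaries.
    """
    chain = chain_id or structure.chains()[0]
    residues = structure.residue_indices(chain)
    window = max(period, 2)
    n_fits = len(residues) - period - window + 1
    if n_fits < 1:
        raise GeometryError(
            f"need at least {period + window} residues (two periods) to infer an axis, "
            f"chain {chain!r} has {len(residues)}")
    directions, points = [], []
    for i in range(n_fits):
        sel_a = structure.select(chain_id=chain, residues=residues[i:i + window])
        sel_b = structure.select(chain_id=chain, residues=residues[i + period:i + period + window])
        keep_a = np.array([a.name != "O3'" for a in sel_a.atoms])
        keep_b = np.array([a.name != "O3'" for a in sel_b.atoms])
        screw = fit_screw(sel_a.coords[keep_a], sel_b.coords[keep_b])
        direction = screw.axis_dir
        if directions and direction @ directions[0] < 0:
            direction = -direction
        directions.append(direction)
        points.append(screw.axis_point)
    mean_dir = np.mean(directions, axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    return Axis(np.mean(points, axis=0), mean_dir)
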