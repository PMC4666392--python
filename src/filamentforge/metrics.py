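"""Structural observables of filament-bound DNA.

Per-step axial rise and twist, strand radius, P-P spacing, the extension
factor relative to B-form, the D1/theta1 base-pairing metrics with their
flip-state classification, junction angles, and triplet registration.

All metrics are defined relative to a helix :class:`~filamentforge.screw.Axis`;
when none is supplied it is inferred from the structure itself, which makes
every observable invariant under global rigid motion.
"""

from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np

from . import config as cfg
from .screw import Axis, GeometryError, infer_axis
from .structure import COMPLEMENTARY, INITIATING, Structure

UNFLIPPED = "unflipped"
FLIPPING = "flipping"
PAIRED = "paired"


class MetricError(ValueError):
    pass


class RoleError(KeyError):
    pass


@dataclasses.dataclass
class StepParams:
    step_index: int
    axial_rise: float
    twist: float
    pp_distance: float


@dataclasses.dataclass
class BasePairMetrics:
    pair_index: int
    D1: float
    theta1: float
    state: str


def _default_axis(structure: Structure, chain: str | None = None) -> Axis:
    period = int(structure.metadata.get("period", 3))
    try:
        return infer_axis(structure, period, chain_id=chain)
    except GeometryError:
        return Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))


def step_parameters(strand: Structure, axis: Axis | None = None,
                    chain_id: str | None = None) -> list[StepParams]:
    """Per-step rise (axis projection of successive-P displacement), signed
    twist about the axis, and Euclidean P-P distance."""
    chain = chain_id or strand.chains()[0]
    residues = strand.residue_indices(chain)
    if len(residues) < 2:
        raise MetricError(f"chain {chain!r} needs at least 2 residues for step parameters")
    try:
        p = strand.atom_positions(chain, "P", residues)
    except KeyError as exc:
        raise MetricError(str(exc)) from exc
    axis = axis or _default_axis(strand, chain)
    d = axis.direction
    axial = axis.axial(p)
    radial = axis.radial_vectors(p)
    steps = []
    for i in range(len(p) - 1):
        delta = p[i + 1] - p[i]
        u, v = radial[i], radial[i + 1]
        twist = math.degrees(math.atan2(float(np.cross(u, v) @ d), float(u @ v)))
        steps.append(StepParams(i + 1, float(delta @ d), twist, float(np.linalg.norm(delta))))
    return steps


def triplet_means(steps: list[StepParams]) -> dict[str, float]:
    """Mean rise/twist/P-P over whole triplets (groups of three steps,
    the third being the triplet boundary).  Falls back to all steps when
    fewer than three are available."""
    m = len(steps) // 3
    used = steps[:3 * m] if m >= 1 else steps
    return {
        "rise": float(np.mean([s.axial_rise for s in used])),
        "twist": float(np.mean([s.twist for s in used])),
        "pp": float(np.mean([s.pp_distance for s in used])),
        "n_steps": len(used),
    }


def strand_radius(strand: Structure, axis: Axis | None = None,
                  chain_id: str | None = None) -> tuple[np.ndarray, float]:
    """Perpendicular distance of each phosphate to the helix axis."""
    chain = chain_id or strand.chains()[0]
    residues = strand.residue_indices(chain)
    p = strand.atom_positions(chain, "P", residues)
    axis = axis or _default_axis(strand, chain)
    if not np.all(np.isfinite(axis.direction)):
        raise GeometryError("degenerate axis")
    radii = axis.radii(p)
    return radii, float(np.mean(radii))


def extension_factor(structure: Structure, axis: Axis | None = None,
                     chain_id: str | None = None) -> float:
    """Mean axial rise per step divided by the canonical B-form rise.

    B-form DNA returns 1.0 by definition; filament-bound DNA about 1.5.
    """
    steps = step_parameters(structure, axis, chain_id)
    return abs(triplet_means(steps)["rise"]) / cfg.B_RISE


# -- base-pairing metrics ----------------------------------------------------

@functools.lru_cache(maxsize=1)
def paired_reference() -> tuple[float, float]:
    """(D1, theta1) of a paired base pair, measured on the package's own
    B-form template rather than assumed."""
    from .builder import build_bdna
    duplex = build_bdna("TTT")
    c1_a = duplex.atom("A", 2, "C1'").position
    c1_b = duplex.atom("B", 2, "C1'").position
    d1 = float(np.linalg.norm(c1_a - c1_b))
    theta1 = _theta1(duplex, "B", 2, c1_a)
    return d1, theta1


@functools.lru_cache(maxsize=1)
def unflipped_reference() -> float:
    """D1 of an untouched site-II complementary base against its initiating
    partner, from the builder's own minimal synaptic stub."""
    from .builder import TripletPattern, build_synaptic_model
    stub = build_synaptic_model("TTT", TripletPattern(1, 0, 0))
    entry = stub.metadata["pairs"][0]
    c1_i = stub.atom("I", entry["I"], "C1'").position
    c1_c = stub.atom("C", entry["C"], "C1'").position
    return float(np.linalg.norm(c1_i - c1_c))


def _theta1(structure: Structure, comp_chain: str, comp_res: int,
            c1_init: np.ndarray) -> float:
    """C1'-C1'-N angle at the complementary C1', projected onto the plane
    normal to the local strand tangent (the base-flipping plane)."""
    residues = structure.residue_indices(comp_chain)
    pos = structure.atom_positions(comp_chain, "P", residues)
    idx = residues.index(comp_res)
    lo, hi = max(idx - 1, 0), min(idx + 1, len(residues) - 1)
    tangent = pos[hi] - pos[lo]
    norm = np.linalg.norm(tangent)
    tangent = tangent / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])

    c1_c = structure.atom(comp_chain, comp_res, "C1'").position
    resname = structure.atom(comp_chain, comp_res, "C1'").residue_name
    n_name = "N9" if resname in ("DA", "DG") else "N1"
    n_pos = structure.atom(comp_chain, comp_res, n_name).position

    v1 = c1_init - c1_c
    v2 = n_pos - c1_c
    p1 = v1 - (v1 @ tangent) * tangent
    p2 = v2 - (v2 @ tangent) * tangent
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        p1, p2 = v1, v2
    cosang = float(p1 @ p2) / (np.linalg.norm(p1) * np.linalg.norm(p2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def classify_flip(d1: float, theta1: float) -> str:
    d1_ref, theta1_ref = paired_reference()
    if abs(d1 - d1_ref) <= cfg.D1_TOLERANCE and abs(theta1 - theta1_ref) <= cfg.THETA1_TOLERANCE:
        return PAIRED
    d1_un = unflipped_reference()
    progress = (d1_un - d1) / (d1_un - d1_ref) if d1_un != d1_ref else 0.0
    return FLIPPING if progress >= cfg.FLIP_PROGRESS else UNFLIPPED


def basepair_metrics(structure: Structure, pair_index: int) -> BasePairMetrics:
    """D1 (C1'-C1' distance, complementary vs initiating), theta1 and the
    derived flip state for one base pair of an annotated model."""
    try:
        init_chain = structure.chain_role(INITIATING)
        comp_chain = structure.chain_role(COMPLEMENTARY)
    except KeyError as exc:
        raise RoleError(f"initiating/complementary roles must be annotated: {exc}") from exc
    entries = {p["index"]: p for p in structure.metadata.get("pairs", [])}
    if pair_index not in entries:
        raise MetricError(f"no pairing record for pair {pair_index}")
    entry = entries[pair_index]
    c1_i = structure.atom(init_chain, entry["I"], "C1'").position
    c1_c = structure.atom(comp_chain, entry["C"], "C1'").position
    d1 = float(np.linalg.norm(c1_i - c1_c))
    theta1 = _theta1(structure, comp_chain, entry["C"], c1_i)
    return BasePairMetrics(pair_index, d1, theta1, classify_flip(d1, theta1))


def all_basepair_metrics(structure: Structure) -> list[BasePairMetrics]:
    return [basepair_metrics(structure, p["index"])
            for p in structure.metadata.get("pairs", [])]


# -- junction angle ----------------------------------------------------------

def junction_angles(structure: Structure) -> list[float]:
    """Angle between each B-form tail axis and the filament-region axis,
    measured as deviation from collinear continuation (0 = straight)."""
    junctions = structure.metadata.get("junctions", [])
    if not junctions:
        raise MetricError("structure carries no junction tags")
    angles = []
    for j in junctions:
        point = np.asarray(j["point"], dtype=float)
        fil = structure.select(chain_id=j["fil_chain"],
                               residues=range(j["fil_residues"][0], j["fil_residues"][1] + 1))
        tail = structure.select(chain_id=j["tail_chain"],
                                residues=range(j["tail_residues"][0], j["tail_residues"][1] + 1))
        fil_axis = infer_axis(fil, int(j["fil_period"]))
        tail_axis = infer_axis(tail, int(j["tail_period"]))
        fil_away = _oriented(fil_axis.direction, fil.coords.mean(axis=0) - point)
        tail_away = _oriented(tail_axis.direction, tail.coords.mean(axis=0) - point)
        cosang = np.clip(float(fil_away @ tail_away), -1.0, 1.0)
        angles.append(180.0 - math.degrees(math.acos(cosang)))
    return angles


def junction_angle(structure: Structure) -> float:
    return float(np.mean(junction_angles(structure)))


def _oriented(direction: np.ndarray, toward: np.ndarray) -> np.ndarray:
    return direction if float(direction @ toward) >= 0 else -direction


# -- triplet registration ----------------------------------------------------

def registration_check(structure: Structure, axis: Axis | None = None
                       ) -> tuple[list[bool], dict]:
    """Per-triplet registration of corresponding bases across strands.

    A base pair is in register when its non-initiating residues fall in the
    same axial window (half a mean rise) as the initiating residue and at a
    constant azimuthal station modulo 180° (the incoming duplex sits
    diametrically opposite the initiating strand, so diametric placement is
    in-register).
    """
    try:
        init_chain = structure.chain_role(INITIATING)
    except KeyError as exc:
        raise RoleError(str(exc)) from exc
    pairs = structure.metadata.get("pairs", [])
    if not pairs:
        raise MetricError("no pairing records in metadata")
    mean_rise = float(structure.metadata.get("mean_rise", cfg.MEAN_RISE))
    other_chains = {role: chain for chain, role in structure.roles.items()
                    if role in ("complementary", "outgoing")}
    if not other_chains:
        raise RoleError("no complementary/outgoing strand to check against")
    if axis is None:
        site2 = structure.metadata.get("site2", {})
        rng = site2.get("ranges", {}).get("C")
        try:
            if rng:
                seg = structure.select(chain_id=other_chains.get("complementary", init_chain),
                                       residues=range(rng[0], rng[1] + 1))
                axis = infer_axis(seg, 3)
            else:
                axis = infer_axis(structure, 3, chain_id=init_chain)
        except GeometryError:
            axis = Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    key = {"complementary": "C", "outgoing": "O"}
    per_pair = []
    for entry in pairs:
        p_init = structure.atom(init_chain, entry["I"], "P").position
        z_i = float(axis.axial(p_init[None])[0])
        az_i = float(axis.azimuths(p_init[None])[0])
        ok = True
        detail = {"index": entry["index"]}
        for role, chain in other_chains.items():
            res_key = key[role]
            if res_key not in entry:
                continue
            p = structure.atom(chain, entry[res_key], "P").position
            dz = abs(float(axis.axial(p[None])[0]) - z_i)
            daz = float(axis.azimuths(p[None])[0]) - az_i
            daz = (daz + 90.0) % 180.0 - 90.0
            detail[role] = {"dz": dz, "dphi": daz}
            if dz > cfg.REGISTRATION_AXIAL_FRACTION * mean_rise or abs(daz) > cfg.REGISTRATION_SECTOR:
                ok = False
        per_pair.append((entry["index"], ok, detail))

    n_triplets = max(1, len(pairs) // 3)
    verdict = []
    for t in range(n_triplets):
        members = [ok for idx, ok, _ in per_pair if 3 * t + 1 <= idx <= 3 * t + 3]
        verdict.append(bool(members) and all(members))
    report = {"pairs": [d for _, _, d in per_pair],
              "pass": [ok for _, ok, _ in per_pair]}
    return verdict, report
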