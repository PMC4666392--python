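"""Builders for every DNA conformer of the strand-exchange intermediate.

The package models nucleotides at reduced resolution: a phosphate P, the
bridging O3', the sugar C1', the glycosidic nitrogen (N9 for purines, N1
for pyrimidines) and a base-centroid pseudo-atom CEN.  C1', N and CEN lie
on the pairing direction of the base, at fixed arm lengths from P, so the
C1'-C1' pairing distance of the package's own B-form template
(2*(9.4 - 4.2) = 10.4 Å) is the self-consistent "paired" reference used by
the base-flipping metrics.

Conformers provided:

* canonical B-form duplex (rise 3.38 Å, twist 36°, P radius 9.4 Å);
* triplet-patterned stretched/unwound filament strands (mean rise 5.1 Å,
  mean twist 20°, extension concentrated in the inter-triplet step);
* the three-strand synaptic model: initiating strand in site I (9 Å),
  complementary + outgoing duplex threaded through site II (12 / 15 Å)
  diametrically opposite, in triplet registration, with B-form tails
  joined through sharply kinked junctions;
* the geometric duplet-flip operator that swings the two 5'-most
  complementary bases of a triplet into the paired site-I pose.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from . import config as cfg
from .screw import Axis, GeometryError, fit_screw, infer_axis, rotation_about_axis
from .structure import (Atom, COMPLEMENTARY, INITIATING, OUTGOING, SCAFFOLD,
                        Structure)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINES = {"A", "G"}
_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_BASE1 = {v: k for k, v in _RESNAME.items()}


class SequenceError(ValueError):
    pass


class DegenerateModelError(ValueError):
    pass


class FlipStateError(ValueError):
    pass


@dataclasses.dataclass
class HelicalParams:
    """Per-strand building parameters for filament-bound DNA.

    Rise/twist are split into a within-triplet (intra) and a
    triplet-boundary (inter) value; the configured means are the
    per-base-pair-step averages (2*intra + inter)/3.
    """

    intra_rise: float = cfg.INTRA_RISE
    inter_rise: float = cfg.INTER_RISE
    intra_twist: float = cfg.INTRA_TWIST
    inter_twist: float = cfg.INTER_TWIST
    radius: float = cfg.OUT_RADIUS
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("strand radius must be positive")

    @property
    def mean_rise(self) -> float:
        return (2.0 * self.intra_rise + self.inter_rise) / 3.0

    @property
    def mean_twist(self) -> float:
        return (2.0 * self.intra_twist + self.inter_twist) / 3.0

    @classmethod
    def uniform(cls, rise: float, twist: float, radius: float,
                phase: float = 0.0) -> "HelicalParams":
        return cls(rise, rise, twist, twist, radius, phase)

    @classmethod
    def bform(cls, radius: float | None = None) -> "HelicalParams":
        return cls.uniform(cfg.B_RISE, cfg.B_TWIST, radius or cfg.B_P_RADIUS)


@dataclasses.dataclass
class TripletPattern:
    """Layout of a synaptic model: how many triplets sit in site II and how
    long the flanking B-form tails are, with the junction kink angle."""

    n_triplets_siteII: int = 2
    tail_bp_5p: int = 6
    tail_bp_3p: int = 6
    bend_angle: float = cfg.BEND_ANGLE

    def __post_init__(self) -> None:
        if self.n_triplets_siteII < 0 or self.tail_bp_5p < 0 or self.tail_bp_3p < 0:
            raise ValueError("triplet and tail counts must be non-negative")
        if not 0.0 <= self.bend_angle < 180.0:
            raise ValueError("bend angle must lie in [0, 180)")

    @property
    def total_bp(self) -> int:
        return self.tail_bp_5p + 3 * self.n_triplets_siteII + self.tail_bp_3p


# -- low-level geometry helpers ---------------------------------------------

def _cyl(radius: float, phi_deg: float, z: float) -> np.ndarray:
    phi = math.radians(phi_deg)
    return np.array([radius * math.cos(phi), radius * math.sin(phi), z])


def _radial(phi_deg: float) -> np.ndarray:
    phi = math.radians(phi_deg)
    return np.array([math.cos(phi), math.sin(phi), 0.0])


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGT")
    if bad or not sequence:
        raise SequenceError(f"sequence must be non-empty over A/C/G/T, offending: {sorted(bad)}")
    return sequence


def glyco_name(base: str) -> str:
    return "N9" if base in PURINES else "N1"


@dataclasses.dataclass
class _Pose:
    """One reduced nucleotide: backbone P plus the base pairing direction."""
    base: str
    p: np.ndarray
    b: np.ndarray  # unit vector from P towards the pairing partner


def nucleotide_atoms(pose: _Pose, chain_id: str, residue_index: int,
                     o3_position: np.ndarray) -> list[Atom]:
    resname = _RESNAME[pose.base]
    p, b = pose.p, pose.b
    return [
        Atom("P", "P", p, residue_index, resname, chain_id),
        Atom("C1'", "C", p + cfg.C1_ARM * b, residue_index, resname, chain_id),
        Atom(glyco_name(pose.base), "N", p + cfg.N_ARM * b, residue_index, resname, chain_id),
        Atom("CEN", "C", p + cfg.CEN_ARM * b, residue_index, resname, chain_id),
        Atom("O3'", "O", o3_position, residue_index, resname, chain_id),
    ]


def o3_between(p_here: np.ndarray, p_next: np.ndarray) -> np.ndarray:
    gap = p_next - p_here
    norm = np.linalg.norm(gap)
    if norm < 1e-9:
        raise GeometryError("coincident consecutive phosphates")
    return p_next - cfg.O3_P_BOND * gap / norm


def _chain_atoms(chain_id: str, poses: list[_Pose],
                 virtual_next_p: np.ndarray | None = None) -> list[Atom]:
    """Assemble a chain in 5'->3' residue order, placing each O3' on the
    bond vector into the next phosphate (extrapolated at the 3' end)."""
    atoms: list[Atom] = []
    n = len(poses)
    for i, pose in enumerate(poses):
        if i + 1 < n:
            nxt = poses[i + 1].p
        elif virtual_next_p is not None:
            nxt = virtual_next_p
        elif n >= 2:
            nxt = poses[-1].p + (poses[-1].p - poses[-2].p)
        else:
            nxt = pose.p + np.array([0.0, 0.0, cfg.B_RISE])
        atoms.extend(nucleotide_atoms(pose, chain_id, i + 1, o3_between(pose.p, nxt)))
    return atoms


def _triplet_steps(n_steps: int, intra: float, inter: float) -> np.ndarray:
    # step k sits between residues k+1 and k+2 (1-based); every third step
    # is the stretched/unwound triplet boundary.
    return np.array([inter if k % 3 == 2 else intra for k in range(n_steps)])


def _helix_arrays(n: int, params: HelicalParams) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth (deg) and height (Å) of n+1 consecutive positions (the extra
    one drives terminal O3' extrapolation)."""
    twists = _triplet_steps(n, params.intra_twist, params.inter_twist)
    rises = _triplet_steps(n, params.intra_rise, params.inter_rise)
    phi = params.phase + np.concatenate([[0.0], np.cumsum(twists)])
    z = np.concatenate([[0.0], np.cumsum(rises)])
    return phi, z


# -- reference conformers ----------------------------------------------------

def build_bdna(sequence: str) -> Structure:
    """Canonical B-form duplex with a complementary antiparallel strand.

    Chain A carries the given sequence 5'->3' along +z; chain B is its
    reverse complement.  By construction the extension factor of the result
    is exactly 1.
    """
    sequence = _validate_sequence(sequence)
    n = len(sequence)
    params = HelicalParams.bform()
    phi, z = _helix_arrays(n, params)
    r = params.radius

    poses_a = [_Pose(sequence[k], _cyl(r, phi[k], z[k]), -_radial(phi[k]))
               for k in range(n)]
    virtual_a = _cyl(r, phi[n], z[n])
    # Chain B pairs diametrically and runs antiparallel: residue j of B is
    # the partner of pair n+1-j.
    poses_b = [_Pose(COMPLEMENT[sequence[n - j]],
                     _cyl(r, phi[n - j] + 180.0, z[n - j]),
                     _radial(phi[n - j]))
               for j in range(1, n + 1)]
    virtual_b = _cyl(r, phi[0] - params.intra_twist + 180.0, z[0] - params.intra_rise)

    atoms = _chain_atoms("A", poses_a, virtual_a) + _chain_atoms("B", poses_b, virtual_b)
    pairs = [{"index": k + 1, "phi": float(phi[k]), "z": float(z[k]),
              "A": k + 1, "B": n - k} for k in range(n)]
    meta = {"kind": "bdna", "mean_rise": cfg.B_RISE, "mean_twist": cfg.B_TWIST,
            "radius": r, "pairs": pairs, "period": 1}
    return Structure(atoms, {"A": SCAFFOLD, "B": SCAFFOLD}, meta)


def build_filament_strand(sequence: str, params: HelicalParams | None = None) -> Structure:
    """Single strand threaded on the filament screw at ``params.radius``.

    With uniform B-form parameters this coincides with chain A of
    :func:`build_bdna`; with the triplet-patterned defaults the mean axial
    rise and twist over whole triplets equal the configured filament means.
    """
    sequence = _validate_sequence(sequence)
    params = params or HelicalParams()
    if len(sequence) % 3 and (params.intra_rise != params.inter_rise
                              or params.intra_twist != params.inter_twist):
        warnings.warn("sequence length is not a multiple of the 3-nt triplet repeat",
                      stacklevel=2)
    n = len(sequence)
    phi, z = _helix_arrays(n, params)
    poses = [_Pose(sequence[k], _cyl(params.radius, phi[k], z[k]), -_radial(phi[k]))
             for k in range(n)]
    virtual = _cyl(params.radius, phi[n], z[n])
    meta = {"kind": "filament_strand", "mean_rise": params.mean_rise,
            "mean_twist": params.mean_twist, "radius": params.radius, "period": 3}
    return Structure(_chain_atoms("A", poses, virtual), {"A": SCAFFOLD}, meta)


def make_scaffold_anchor_frames(n_monomers: int) -> Structure:
    """Pseudo-atom frame per protein subunit, screw-replicated.

    Three non-collinear markers per monomer let a screw fit between
    consecutive monomers recover the filament symmetry (60° and 15.3 Å per
    subunit, i.e. six subunits per turn).
    """
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    template = [
        ("CA", np.array([20.0, 0.0, 0.0])),
        ("CB", np.array([18.0, 5.0, 4.0])),
        ("CG", np.array([22.0, -3.0, 9.0])),
    ]
    atoms = []
    for m in range(n_monomers):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), cfg.MONOMER_TWIST * m)
        shift = np.array([0.0, 0.0, cfg.MONOMER_RISE * m])
        for j, (name, pos) in enumerate(template):
            atoms.append(Atom(name, "C", rot @ pos + shift, m + 1, "MON", "S"))
    meta = {"kind": "scaffold", "monomer_twist": cfg.MONOMER_TWIST,
            "monomer_rise": cfg.MONOMER_RISE}
    return Structure(atoms, {"S": SCAFFOLD}, meta)


# -- synaptic model ----------------------------------------------------------

def _site2_pair_geometry(n_pairs: int,
                         params: HelicalParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    params = params or HelicalParams()
    phi, z = _helix_arrays(n_pairs, params)
    return phi, z


def _tail_frame(phi_j: float, bend_angle: float, sense: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis direction and roll reference of a B-form tail leaving the
    filament at azimuth ``phi_j`` (already on the duplex side).  ``sense``
    is +1 for the top (5') junction, -1 for the bottom (3') one."""
    b = math.radians(bend_angle)
    radial = _radial(phi_j)
    d = math.sin(b) * radial + sense * math.cos(b) * np.array([0.0, 0.0, 1.0])
    w = radial - (radial @ d) * d
    if np.linalg.norm(w) < 1e-6:
        zhat = np.array([0.0, 0.0, 1.0])
        w = zhat - (zhat @ d) * d
    return d, w / np.linalg.norm(w)


def _tail_poses(n_pairs: int, origin: np.ndarray, axis_dir: np.ndarray,
                roll_ref: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centre, outward unit) of each local tail pair, pair 0 adjacent to
    the junction, B-form rise/twist along the local axis."""
    out = []
    for j in range(n_pairs):
        centre = origin + j * cfg.B_RISE * axis_dir
        u = rotation_about_axis(axis_dir, cfg.B_TWIST * j) @ roll_ref
        out.append((centre, u))
    return out


def build_synaptic_model(sequence: str, pattern: TripletPattern | None = None,
                         site2_params: HelicalParams | None = None) -> Structure:
    """Three-strand strand-exchange intermediate.

    The initiating strand sits in site I (P radius 9 Å); the incoming
    duplex is threaded through site II diametrically opposite, the
    complementary backbone at 12 Å and the outgoing backbone at 15 Å, all
    three strands in triplet registration on the filament screw.  B-form
    tails continue the incoming duplex through kinked junctions at
    ``pattern.bend_angle``.  ``sequence`` is the complementary strand read
    5'->3' (its 5' tail is the top one).
    """
    pattern = pattern or TripletPattern()
    n = pattern.n_triplets_siteII
    t5, t3 = pattern.tail_bp_5p, pattern.tail_bp_3p
    if n == 0:
        if t5 == 0 and t3 == 0:
            raise DegenerateModelError("no site-II triplets and no tails: nothing to build")
        raise DegenerateModelError("a synaptic model needs at least one site-II triplet")
    sequence = _validate_sequence(sequence)
    total = pattern.total_bp
    if len(sequence) < total:
        raise ValueError(f"sequence of length {len(sequence)} cannot cover "
                         f"{total} bp (tails + 3*n_triplets)")
    sequence = sequence[:total]
    n_pairs = 3 * n
    site2_params = site2_params or HelicalParams()
    phi, z = _site2_pair_geometry(n_pairs, site2_params)

    comp_poses: dict[int, _Pose] = {}
    out_poses: dict[int, _Pose] = {}
    init_poses: list[_Pose] = []
    pairs_meta = []

    def comp_res_for_pair(i: int) -> int:      # pair index 1-based, ascending z
        return t5 + (n_pairs - i + 1)

    for i in range(1, n_pairs + 1):
        k = i - 1
        cr = comp_res_for_pair(i)
        orr = t3 + i
        comp_base = sequence[cr - 1]
        r_in = _radial(phi[k])
        r_out = _radial(phi[k] + 180.0)
        init_poses.append(_Pose(COMPLEMENT[comp_base], _cyl(cfg.SITE1_RADIUS, phi[k], z[k]), -r_in))
        comp_poses[cr] = _Pose(comp_base, _cyl(cfg.COMP_RADIUS, phi[k] + 180.0, z[k]), r_out)
        out_poses[orr] = _Pose(COMPLEMENT[comp_base], _cyl(cfg.OUT_RADIUS, phi[k] + 180.0, z[k]), -r_out)
        pairs_meta.append({"index": i, "phi": float(phi[k]), "z": float(z[k]),
                           "I": i, "C": cr, "O": orr, "flipped": False})

    junctions = []
    # Top junction / 5' tail of the complementary strand.
    if t5 > 0:
        k_top = n_pairs - 1
        d_top, w_top = _tail_frame(phi[k_top] + 180.0, pattern.bend_angle, +1.0)
        a_top = (_cyl(cfg.COMP_RADIUS, phi[k_top] + 180.0, z[k_top])
                 + _cyl(cfg.OUT_RADIUS, phi[k_top] + 180.0, z[k_top])) / 2.0
        origin = a_top + cfg.JUNCTION_STEP * d_top
        local = _tail_poses(t5, origin, d_top, w_top)
        for p, (centre, u) in enumerate(local):
            cr = t5 - p
            comp_base = sequence[cr - 1]
            comp_poses[cr] = _Pose(comp_base, centre - cfg.B_P_RADIUS * u, u)
            out_poses[t3 + n_pairs + 1 + p] = _Pose(COMPLEMENT[comp_base],
                                                    centre + cfg.B_P_RADIUS * u, -u)
        junctions.append({"side": "top", "bend_angle": pattern.bend_angle,
                          "point": [float(v) for v in a_top],
                          "fil_chain": "C", "fil_residues": [t5 + 1, t5 + n_pairs],
                          "fil_period": 3,
                          "tail_chain": "C", "tail_residues": [1, t5], "tail_period": 1})
    # Bottom junction / 3' tail of the complementary strand.
    if t3 > 0:
        d_bot, w_bot = _tail_frame(phi[0] + 180.0, pattern.bend_angle, -1.0)
        a_bot = (_cyl(cfg.COMP_RADIUS, phi[0] + 180.0, z[0])
                 + _cyl(cfg.OUT_RADIUS, phi[0] + 180.0, z[0])) / 2.0
        origin = a_bot + cfg.JUNCTION_STEP * d_bot
        local = _tail_poses(t3, origin, d_bot, w_bot)
        for p, (centre, u) in enumerate(local):
            cr = t5 + n_pairs + 1 + p
            comp_base = sequence[cr - 1]
            comp_poses[cr] = _Pose(comp_base, centre - cfg.B_P_RADIUS * u, u)
            out_poses[t3 - p] = _Pose(COMPLEMENT[comp_base], centre + cfg.B_P_RADIUS * u, -u)
        junctions.append({"side": "bottom", "bend_angle": pattern.bend_angle,
                          "point": [float(v) for v in a_bot],
                          "fil_chain": "C", "fil_residues": [t5 + 1, t5 + n_pairs],
                          "fil_period": 3,
                          "tail_chain": "C",
                          "tail_residues": [t5 + n_pairs + 1, t5 + n_pairs + t3],
                          "tail_period": 1})

    comp_list = [comp_poses[r] for r in sorted(comp_poses)]
    out_list = [out_poses[r] for r in sorted(out_poses)]
    atoms = (_chain_atoms("I", init_poses,
                          _cyl(cfg.SITE1_RADIUS, phi[n_pairs], z[n_pairs]))
             + _chain_atoms("C", comp_list)
             + _chain_atoms("O", out_list))
    meta = {
        "kind": "synaptic",
        "mean_rise": site2_params.mean_rise, "mean_twist": site2_params.mean_twist,
        "pattern": dataclasses.asdict(pattern),
        "site2": {"n_triplets": n,
                  "ranges": {"I": [1, n_pairs],
                             "C": [t5 + 1, t5 + n_pairs],
                             "O": [t3 + 1, t3 + n_pairs]}},
        "pairs": pairs_meta,
        "junctions": junctions,
        "flipped_triplets": [],
    }
    structure = Structure(atoms, {"I": INITIATING, "C": COMPLEMENTARY, "O": OUTGOING}, meta)
    structure.validate()
    return structure


def make_postsynaptic_reference(length_bp: int, sequence: str | None = None) -> Structure:
    """Product heteroduplex in site I: initiating and complementary strands
    paired at the filament geometry.

    The complementary backbone radius is fixed by requiring the C1'-C1'
    pairing distance to equal the B-form template value against an
    initiating backbone at 9 Å.  This fixture calibrates the paired
    D1/theta1 thresholds.
    """
    if length_bp < 3:
        raise ValueError("postsynaptic reference needs at least 3 bp")
    comp_seq = _validate_sequence(sequence) if sequence else "T" * length_bp
    if len(comp_seq) != length_bp:
        raise ValueError("sequence length mismatch")
    n = length_bp
    phi, z = _site2_pair_geometry(n)
    init_poses, pairs_meta = [], []
    comp_poses: dict[int, _Pose] = {}
    for i in range(1, n + 1):
        k = i - 1
        cr = n - i + 1
        base = comp_seq[cr - 1]
        r_in = _radial(phi[k])
        init_poses.append(_Pose(COMPLEMENT[base], _cyl(cfg.SITE1_RADIUS, phi[k], z[k]), -r_in))
        comp_poses[cr] = _Pose(base, _cyl(cfg.COMP_PAIRED_RADIUS, phi[k] + 180.0, z[k]), r_in)
        pairs_meta.append({"index": i, "phi": float(phi[k]), "z": float(z[k]),
                           "I": i, "C": cr, "flipped": True})
    comp_list = [comp_poses[r] for r in sorted(comp_poses)]
    atoms = (_chain_atoms("I", init_poses, _cyl(cfg.SITE1_RADIUS, phi[n], z[n]))
             + _chain_atoms("C", comp_list))
    meta = {"kind": "postsynaptic", "mean_rise": cfg.MEAN_RISE,
            "mean_twist": cfg.MEAN_TWIST,
            "site2": {"n_triplets": n // 3,
                      "ranges": {"I": [1, n], "C": [1, n]}},
            "pairs": pairs_meta, "junctions": [], "flipped_triplets": [], "period": 3}
    return Structure(atoms, {"I": INITIATING, "C": COMPLEMENTARY}, meta)


# -- junction as a standalone operator --------------------------------------

def build_junction(b_segment: Structure, fil_segment: Structure,
                   bend_angle: float) -> Structure:
    """Rigidly attach a B-form duplex to the top end of a filament duplex
    so that the angle between the two helix axes equals ``bend_angle``.

    Chains of the two segments are matched in order; the attachment keeps
    the junction backbone gaps minimal under the rigid-placement freedom
    (axis alignment, roll about the new axis, translation).  Base stacking
    is interrupted at exactly the junction step, which is recorded in the
    metadata junction tag.
    """
    shared = set(b_segment.chains()) & set(fil_segment.chains())
    if shared:
        raise ValueError(f"segments share chain ids {sorted(shared)}; cannot merge")
    fil_period = int(fil_segment.metadata.get("period", 3))
    b_period = int(b_segment.metadata.get("period", 1))
    fil_chains = fil_segment.chains()
    b_chains = b_segment.chains()
    fil_axis = infer_axis(fil_segment, fil_period, chain_id=fil_chains[0])
    b_axis = infer_axis(b_segment, b_period, chain_id=b_chains[0])

    # Work at the end of the filament segment with the largest axial extent.
    fil_p = {c: fil_segment.atom_positions(c, "P") for c in fil_chains}
    axial_top = max(float(np.max(fil_axis.axial(p))) for p in fil_p.values())
    attach_fil = {}
    for c in fil_chains:
        ax = fil_axis.axial(fil_p[c])
        attach_fil[c] = fil_p[c][int(np.argmax(ax))]
    mid_fil = np.mean(list(attach_fil.values()), axis=0)
    radial_ref = mid_fil - (fil_axis.point
                            + float(fil_axis.axial(mid_fil[None])[0]) * fil_axis.direction)
    if np.linalg.norm(radial_ref) < 1e-6:
        radial_ref = np.array([1.0, 0.0, 0.0])
    radial_ref = radial_ref / np.linalg.norm(radial_ref)
    b_rad = math.radians(bend_angle)
    d = math.sin(b_rad) * radial_ref + math.cos(b_rad) * fil_axis.direction
    d = d / np.linalg.norm(d)

    # Orient the B segment: its axis (pointing from its attachment end into
    # the segment) goes onto d.
    b_p = {c: b_segment.atom_positions(c, "P") for c in b_chains}
    all_b = np.concatenate(list(b_p.values()))
    ax_all = b_axis.axial(all_b)
    b_dir = b_axis.direction if (ax_all.mean() - ax_all.min()) >= 0 else -b_axis.direction
    rot = _rotation_between(b_dir, d)
    moved = b_segment.with_coords((b_segment.coords - b_axis.point) @ rot.T)
    attach_b = {}
    for c in b_chains:
        p = moved.atom_positions(c, "P")
        ax = (p @ d)
        attach_b[c] = p[int(np.argmin(ax))]
    # Roll about d to line the attachment phosphates up with the filament
    # side, then translate onto the junction-step targets.
    targets = [attach_fil[fc] + cfg.JUNCTION_STEP * d for fc in fil_chains]
    current = [attach_b[bc] for bc in b_chains[:len(fil_chains)]]
    best = None
    for gamma in np.arange(0.0, 360.0, 0.5):
        rg = rotation_about_axis(d, gamma)
        pts = [rg @ c for c in current]
        tau = np.mean([t - p for t, p in zip(targets, pts)], axis=0)
        cost = sum(np.sum((p + tau - t) ** 2) for p, t in zip(pts, targets))
        if best is None or cost < best[0]:
            best = (cost, gamma, tau)
    _, gamma, tau = best
    rg = rotation_about_axis(d, gamma)
    placed = moved.with_coords(moved.coords @ rg.T + tau)

    atoms = [a.copy() for a in fil_segment.atoms] + [a.copy() for a in placed.atoms]
    meta = dict(fil_segment.metadata)
    junctions = list(meta.get("junctions", []))
    junctions.append({"side": "top", "bend_angle": float(bend_angle),
                      "point": [float(v) for v in mid_fil],
                      "fil_chain": fil_chains[0],
                      "fil_residues": [min(fil_segment.residue_indices(fil_chains[0])),
                                       max(fil_segment.residue_indices(fil_chains[0]))],
                      "fil_period": fil_period,
                      "tail_chain": b_chains[0],
                      "tail_residues": [min(b_segment.residue_indices(b_chains[0])),
                                        max(b_segment.residue_indices(b_chains[0]))],
                      "tail_period": b_period})
    meta["junctions"] = junctions
    roles = dict(fil_segment.roles)
    roles.update(placed.roles)
    return Structure(atoms, roles, meta)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    cross = np.cross(a, b)
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        if a @ b > 0:
            return np.eye(3)
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return rotation_about_axis(axis, 180.0)
    axis = cross / norm
    angle = math.degrees(math.atan2(norm, float(a @ b)))
    return rotation_about_axis(axis, angle)


# -- the duplet-flip operator -------------------------------------------------

def flip_duplet(structure: Structure, triplet_index: int,
                which: str = "5p-duplet") -> Structure:
    """Swing the 5'-duplet of a site-II triplet into the paired site-I pose.

    The two 5'-most complementary bases of the triplet rotate as a rigid
    stacked pair towards the initiating strand: their backbone phosphates
    move radially inward to the product-duplex radius and the bases point
    at their initiating partners, so the C1'-C1' distance to the initiating
    strand reaches the paired template value.  The triplet's 3' base and
    the outgoing strand are untouched.
    """
    if which != "5p-duplet":
        raise ValueError(f"unknown duplet selector {which!r}")
    meta = structure.metadata
    if meta.get("kind") != "synaptic" or "site2" not in meta:
        raise IndexError("duplet flips require a synaptic model with site-II metadata")
    n = meta["site2"]["n_triplets"]
    if not 1 <= triplet_index <= n:
        raise IndexError(f"triplet {triplet_index} not in site II (1..{n})")
    if triplet_index in meta.get("flipped_triplets", []):
        raise FlipStateError(f"triplet {triplet_index} is already flipped")

    out = structure.copy()
    pairs = {p["index"]: p for p in out.metadata["pairs"]}
    duplet_pairs = [3 * triplet_index, 3 * triplet_index - 1]   # comp 5'-most two
    moved_comp_res = []
    for i in duplet_pairs:
        entry = pairs[i]
        phi_k, z_k, cr = entry["phi"], entry["z"], entry["C"]
        new_p = _cyl(cfg.COMP_PAIRED_RADIUS, phi_k + 180.0, z_k)
        new_b = _radial(phi_k)    # towards the initiating backbone
        base = _BASE1[out.atom("C", cr, "P").residue_name]
        out.atom("C", cr, "P").position = new_p
        out.atom("C", cr, "C1'").position = new_p + cfg.C1_ARM * new_b
        out.atom("C", cr, glyco_name(base)).position = new_p + cfg.N_ARM * new_b
        out.atom("C", cr, "CEN").position = new_p + cfg.CEN_ARM * new_b
        entry["flipped"] = True
        moved_comp_res.append(cr)
    # Refresh the linking backbone oxygens around the moved duplet.
    comp_residues = out.residue_indices("C")
    touched = sorted({r for cr in moved_comp_res for r in (cr - 1, cr, cr + 1)
                      if r in comp_residues})
    for r in touched:
        here = out.atom("C", r, "P").position
        if r + 1 in comp_residues:
            nxt = out.atom("C", r + 1, "P").position
        else:
            prev = out.atom("C", r - 1, "P").position
            nxt = here + (here - prev)
        out.atom("C", r, "O3'").position = o3_between(here, nxt)
    out.metadata["flipped_triplets"] = sorted(meta.get("flipped_triplets", [])
                                              + [triplet_index])
    return out
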