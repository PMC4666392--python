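"""Protein stand-ins: helically replicated anchor points.

The filament protein is represented by pseudo-atom anchors rather than
full residues: the site-II basic cluster (R226/R227/R243/K245) that grips
two consecutive outgoing-strand phosphates per subunit, the C-terminal
domain lysine patch (K280/K282/K286/K302) that first tethers the incoming
B-form duplex at the groove entrance, and the L2 loop markers whose steric
bulk blocks flipping of the triplet's 3' base.  Anchor templates live in
the first-monomer frame and are replicated by the filament screw, which
keeps the set exactly screw-periodic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import config as cfg
from .screw import ScrewTransform
from .structure import Structure

SITE2_LABELS = ("R226", "R227", "R243", "K245")
CTD_LABELS = ("K280", "K282", "K286", "K302")
L2_LABELS = ("L2:198-206", "F203", "M202")
ALLOWED_LABELS = SITE2_LABELS + ("K232",) + CTD_LABELS + L2_LABELS


class TemplateError(KeyError):
    pass


@dataclasses.dataclass
class Anchor:
    label: str
    monomer_index: int
    position: np.ndarray
    kind: str   # siteII | ctd | L2

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclasses.dataclass
class AnchorSet:
    anchors: list[Anchor]
    screw: ScrewTransform

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.anchors]).reshape(len(self.anchors), 3)

    def merged_with(self, other: "AnchorSet") -> "AnchorSet":
        return AnchorSet(self.anchors + other.anchors, self.screw)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnchorSet":
        moved = [Anchor(a.label, a.monomer_index, rotation @ a.position + translation, a.kind)
                 for a in self.anchors]
        axis_point = rotation @ self.screw.axis_point + translation
        axis_dir = rotation @ self.screw.axis_dir
        screw = ScrewTransform(axis_point, axis_dir, self.screw.angle_per_step,
                               self.screw.translation_per_step)
        return AnchorSet(moved, screw)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "screw": {"axis_point": list(self.screw.axis_point),
                      "axis_dir": list(self.screw.axis_dir),
                      "angle_per_step": self.screw.angle_per_step,
                      "translation_per_step": self.screw.translation_per_step},
            "anchors": [{"label": a.label, "monomer_index": a.monomer_index,
                         "position": [float(v) for v in a.position], "kind": a.kind}
                        for a in self.anchors],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnchorSet":
        payload = json.loads(Path(path).read_text())
        screw = ScrewTransform(np.array(payload["screw"]["axis_point"]),
                               np.array(payload["screw"]["axis_dir"]),
                               payload["screw"]["angle_per_step"],
                               payload["screw"]["translation_per_step"])
        anchors = [Anchor(a["label"], a["monomer_index"], np.array(a["position"]), a["kind"])
                   for a in payload["anchors"]]
        return cls(anchors, screw)


def filament_screw() -> ScrewTransform:
    """One protein subunit per step: 60° and 15.3 Å along +z (six subunits
    per helical turn, three nucleotides bound per subunit)."""
    return ScrewTransform(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                          cfg.MONOMER_TWIST, cfg.MONOMER_RISE)


def _cyl(radius: float, phi_deg: float, z: float) -> np.ndarray:
    phi = np.radians(phi_deg)
    return np.array([radius * np.cos(phi), radius * np.sin(phi), z])


def default_site2_template() -> dict[str, np.ndarray]:
    """Basic-cluster centroids of monomer 1, in the builder frame.

    R226/R227 sit just outside the first two outgoing phosphates of the
    monomer's triplet, R243 bridges them, and the K245-equivalent grips
    the 5'-most phosphate of the complementary duplet from the side, so
    that its contact is broken when the duplet flips inward.
    """
    phi = [0.0, cfg.INTRA_TWIST, 2 * cfg.INTRA_TWIST]
    z = [0.0, cfg.INTRA_RISE, 2 * cfg.INTRA_RISE]
    r_anchor = cfg.SITE2_ANCHOR_RADIUS
    return {
        "R226": _cyl(r_anchor, 180.0 + phi[0], z[0]),
        "R227": _cyl(r_anchor, 180.0 + phi[1], z[1]),
        "R243": _cyl(r_anchor, 180.0 + (phi[0] + phi[1]) / 2, (z[0] + z[1]) / 2),
        "K245": _cyl(cfg.COMP_RADIUS, 180.0 + phi[2], z[2] - 4.8),
    }


def default_l2_template() -> dict[str, np.ndarray]:
    """Steric markers of the L2 loop at the inter-triplet gap on the
    site-I side (the bulk that keeps the triplet's 3' base in site II)."""
    phi_gap = 2 * cfg.INTRA_TWIST + cfg.INTER_TWIST / 2
    z_gap = 2 * cfg.INTRA_RISE + cfg.INTER_RISE / 2
    return {
        "L2:198-206": _cyl(10.0, phi_gap, z_gap),
        "F203": _cyl(9.0, phi_gap, z_gap - 1.0),
        "M202": _cyl(11.0, phi_gap, z_gap + 1.0),
    }


def default_ctd_template(pattern=None) -> dict[str, np.ndarray]:
    """Lysine-patch positions derived from the default model's 5' tail.

    Each anchor sits 3 Å radially outside a tail phosphate near the groove
    entrance; two labels are stationed one screw step behind the other
    two, so the replicated set contacts the duplex through two consecutive
    C-terminal domains.
    """
    from .builder import TripletPattern, build_synaptic_model
    pattern = pattern or TripletPattern()
    if pattern.tail_bp_5p < 2:
        raise TemplateError("CTD template needs a 5' tail of at least 2 bp")
    model = build_synaptic_model("T" * pattern.total_bp, pattern)
    t5, t3 = pattern.tail_bp_5p, pattern.tail_bp_3p
    n_pairs = 3 * pattern.n_triplets_siteII
    picks = {"K280": ("O", t3 + n_pairs + 1, 0), "K282": ("O", t3 + n_pairs + 2, 0),
             "K286": ("C", t5, 1), "K302": ("C", t5 - 1, 1)}
    screw = filament_screw()
    base_monomer = pattern.n_triplets_siteII + 1   # first subunit above site II
    template = {}
    for label, (chain, res, back) in picks.items():
        p = model.atom(chain, res, "P").position
        radial = np.array([p[0], p[1], 0.0])
        norm = np.linalg.norm(radial)
        radial = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        q = p + 3.0 * radial
        # station the anchor so that the replica of monomer (base_monomer+back)
        # lands on q: express q in the monomer-1 frame.
        template[label] = screw.transform_points(q, -(base_monomer + back - 1))[0]
    return template


def _generate(screw: ScrewTransform, n_monomers: int,
              template_positions: dict[str, np.ndarray],
              required: tuple[str, ...], kind: str) -> AnchorSet:
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    missing = [lbl for lbl in required if lbl not in template_positions]
    if missing:
        raise TemplateError(f"template is missing required label(s) {missing}")
    unknown = [lbl for lbl in template_positions if lbl not in ALLOWED_LABELS]
    if unknown:
        raise TemplateError(f"unknown anchor label(s) {unknown}")
    anchors = []
    for m in range(1, n_monomers + 1):
        for label, pos in template_positions.items():
            moved = screw.transform_points(np.asarray(pos, dtype=float), m - 1)[0]
            anchors.append(Anchor(label, m, moved, kind))
    return AnchorSet(anchors, screw)


def generate_siteII_anchors(screw: ScrewTransform, n_monomers: int,
                            template_positions: dict[str, np.ndarray] | None = None
                            ) -> AnchorSet:
    """One basic-residue cluster per subunit, replicated by the screw."""
    template = template_positions if template_positions is not None else default_site2_template()
    return _generate(screw, n_monomers, template, SITE2_LABELS, "siteII")


def generate_ctd_anchors(screw: ScrewTransform, n_monomers: int,
                         template_positions: dict[str, np.ndarray] | None = None
                         ) -> AnchorSet:
    """C-terminal-domain lysine patch per subunit at the groove entrance."""
    template = template_positions if template_positions is not None else default_ctd_template()
    return _generate(screw, n_monomers, template, CTD_LABELS, "ctd")


def generate_l2_anchors(screw: ScrewTransform, n_monomers: int,
                        template_positions: dict[str, np.ndarray] | None = None
                        ) -> AnchorSet:
    template = template_positions if template_positions is not None else default_l2_template()
    return _generate(screw, n_monomers, template, L2_LABELS, "L2")


@dataclasses.dataclass
class SaltBridge:
    phosphate: str      # "chain:residue"
    label: str
    monomer_index: int
    distance: float


def salt_bridge_map(structure: Structure, anchors: AnchorSet,
                    cutoff: float = cfg.SALT_BRIDGE_CUTOFF) -> list[SaltBridge]:
    """All phosphate-anchor pairs within the cutoff, sorted by distance.

    The ordering is fully deterministic (distance, then phosphate id, then
    label) and the map is invariant under a common rigid motion of the
    structure and the anchor set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not anchors.anchors:
        raise ValueError("empty anchor set")
    contacts = []
    for atom in structure.atoms:
        if atom.name != "P":
            continue
        pid = f"{atom.chain_id}:{atom.residue_index}"
        for anchor in anchors.anchors:
            d = float(np.linalg.norm(atom.position - anchor.position))
            if d <= cutoff:
                contacts.append(SaltBridge(pid, anchor.label, anchor.monomer_index, d))
    contacts.sort(key=lambda c: (c.distance, c.phosphate, c.label, c.monomer_index))
    return contacts


def occupancy_fraction(contacts: list[SaltBridge], structure: Structure) -> float:
    total = sum(1 for a in structure.atoms if a.name == "P")
    if total == 0:
        return 0.0
    return len({c.phosphate for c in contacts}) / total
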