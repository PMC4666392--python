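"""Package-wide geometric and energetic defaults.

Every default that corresponds to a published structural parameter of the
RecA filament is collected here so that builders, metrics and the relaxation
engine stay mutually consistent.  Values are in Å, degrees and
kcal·mol⁻¹·Å⁻².
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

# Canonical B-form duplex used as the reference state.
B_RISE = 3.38          # axial rise per base-pair step
B_TWIST = 36.0         # twist per base-pair step
B_P_RADIUS = 9.4       # phosphate distance from the duplex axis

# Reduced-nucleotide arm lengths, measured from P along the pairing
# direction (towards the Watson-Crick partner's backbone).
C1_ARM = 4.2           # P -> C1'
N_ARM = 5.5            # P -> glycosidic nitrogen (N9 purines / N1 pyrimidines)
CEN_ARM = 7.4          # P -> base centroid pseudo-atom
O3_P_BOND = 1.6        # O3'(i) -> P(i+1) phosphodiester linkage

# C1'-C1' distance of a paired base pair in the builder's own B-form
# template (diametric backbones): derived, not assumed.
D1_PAIRED = 2.0 * (B_P_RADIUS - C1_ARM)   # = 10.4

# Filament-bound DNA: triplet-patterned extension/unwinding.  The mean rise
# and twist are the filament values; the intra/inter split concentrates the
# extension between triplets.
MEAN_RISE = 5.1
MEAN_TWIST = 20.0
INTRA_RISE = 3.6
INTER_RISE = 8.1
INTRA_TWIST = 25.0
INTER_TWIST = 10.0

# Strand radial placement inside the filament.
SITE1_RADIUS = 9.0     # initiating strand backbone (site I)
COMP_RADIUS = 12.0     # complementary strand backbone (site II, inner)
OUT_RADIUS = 15.0      # outgoing strand backbone (site II, outer)

# Product-duplex radius of the complementary backbone after pairing in
# site I, fixed by requiring C1'-C1' = D1_PAIRED against an initiating
# backbone at SITE1_RADIUS with diametric geometry.
COMP_PAIRED_RADIUS = D1_PAIRED + 2.0 * C1_ARM - SITE1_RADIUS   # = 9.8

# Filament protein scaffold: six subunits per turn, three nucleotides each.
NT_PER_MONOMER = 3
MONOMER_TWIST = 60.0           # NT_PER_MONOMER * MEAN_TWIST
MONOMER_RISE = 15.3            # NT_PER_MONOMER * MEAN_RISE

# Junction between filament-bound DNA and the free B-form tail.
BEND_ANGLE = 90.0
JUNCTION_STEP = 3.38           # axial gap given to the first tail pair

# Anchor geometry (protein stand-ins).
SITE2_ANCHOR_RADIUS = 17.5     # basic-cluster centroids binding the outgoing backbone
CTD_ANCHOR_RADIUS = 22.0       # lysine patch at the groove entrance
SALT_BRIDGE_CUTOFF = 5.0       # centroid-to-phosphate contact distance

# Spring-network constants (energy convention E = k * (r - r0)^2).
K_ANCHOR = 0.5
K_BOND = 10.0
K_REPULSION = 1.0
K_PULL = 10.0
K_WEAK = 0.02
R_MIN = 2.5
MIN_TOL = 1e-8
MAX_ITER = 50_000

# Base-flip classification bands around the template values.
D1_TOLERANCE = 1.5
THETA1_TOLERANCE = 25.0
FLIP_PROGRESS = 0.30

# Registration windows.
REGISTRATION_AXIAL_FRACTION = 0.5   # axial window = fraction of mean rise
REGISTRATION_SECTOR = 10.0          # azimuthal half-width, degrees, modulo 180


@dataclasses.dataclass
class Config:
    """Mutable bundle of the defaults above.

    A plain key=value text file can override any field, which is how the
    command line and the pipeline expose configuration.
    """

    b_rise: float = B_RISE
    b_twist: float = B_TWIST
    b_p_radius: float = B_P_RADIUS
    intra_rise: float = INTRA_RISE
    inter_rise: float = INTER_RISE
    intra_twist: float = INTRA_TWIST
    inter_twist: float = INTER_TWIST
    site1_radius: float = SITE1_RADIUS
    comp_radius: float = COMP_RADIUS
    out_radius: float = OUT_RADIUS
    bend_angle: float = BEND_ANGLE
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF
    k_anchor: float = K_ANCHOR
    k_bond: float = K_BOND
    k_pull: float = K_PULL
    min_tol: float = MIN_TOL
    max_iter: int = MAX_ITER

    @property
    def mean_rise(self) -> float:
        return (2.0 * self.intra_rise + self.inter_rise) / 3.0

    @property
    def mean_twist(self) -> float:
        return (2.0 * self.intra_twist + self.inter_twist) / 3.0

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if not hasattr(cfg, key):
                raise KeyError(f"{path}:{lineno}: unknown configuration key {key!r}")
            field_type = type(getattr(cfg, key))
            setattr(cfg, key, field_type(float(value)) if field_type in (int, float) else value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
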