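# Methods

## Scope and representation

filamentforge models RecA-filament/DNA intermediates at a reduced,
fully parametric resolution.  Each nucleotide is five pseudo-atoms: the
phosphate P, the bridging O3′, the sugar C1′, the glycosidic nitrogen
(N9 for purines, N1 for pyrimidines) and a base-centroid marker CEN.
C1′, N and CEN lie on the base's pairing direction at fixed arm lengths
from P (4.2, 5.5 and 7.4 Å); O3′ sits 1.6 Å before the next residue's P
along the backbone.  This is the smallest atom set on which every
observable the package reports is defined — strand radii and P–P spacing
need P, the base-pairing metrics need C1′ and N9/N1, registration needs
the base stations.  Full-atom detail (sugar pucker, base planes,
protein side chains) is deliberately out of scope.

Coordinate convention: the filament helix axis is +z, the initiating
strand runs 5′→3′ toward +z, and the right-handed filament has positive
twist.  Angles are degrees, lengths Å, spring constants
kcal·mol⁻¹·Å⁻².

## Helical construction

Filament-bound DNA is built on cylindrical coordinates with a
triplet-patterned step sequence: two intra-triplet steps followed by one
inter-triplet step.  Defaults (config.py):

| parameter | intra | inter | per-step mean |
|---|---|---|---|
| rise | 3.6 Å | 8.1 Å | 5.1 Å |
| twist | 25° | 10° | 20° |

The means are the filament values; the split is constrained by them
(mean = (2·intra + inter)/3) but its exact partition is a package
default chosen so the intra-triplet steps stay near B-form and the
extension/unwinding concentrates at the triplet boundary, where the
stacking interruption (the protein's intercalating residues) lives.  Any
other split satisfying the mean invariant can be configured.
Backbone radii: initiating 9 Å, outgoing 15 Å (both characteristic
site-I/site-II values), complementary 12 Å — the complementary radius is
not an established number; it is a package default placed between the
strands it must pair with on either side of the exchange.  B-form
reference: 3.38 Å, 36°, P radius 9.4 Å; the extension factor is defined
as mean axial rise / 3.38 Å, so B-DNA is exactly 1.0 and filament DNA
5.1/3.38 ≈ 1.509.

Whole-triplet averaging: per-step means are reported over groups of
three steps (the third being the boundary step), so an 18-nt strand
closes one 360° turn at 20°/step and the configured means are recovered
exactly on noiseless builds.

### The synaptic model and its pairing geometry

The incoming duplex sits diametrically opposite the initiating strand
(azimuth +180° at each rung).  This choice resolves a genuine geometric
tension of the reduced representation: the paired C1′–C1′ distance of
the package's own B-form template is D1 = 2·(9.4 − 4.2) = 10.4 Å, a
distance comparable to the strand radii themselves, so a flipped
complementary base can only reach its initiating partner at 10.4 Å by
crossing the axis region.  With the diametric layout the product-duplex
pose is fixed by self-consistency: the complementary backbone lands at
10.4 + 2·4.2 − 9 = 9.8 Å on the far side, and the duplet flip becomes a
purely radial move (12 Å → 9.8 Å at constant azimuth and height), which
is also why registration survives the flip.  Triplet registration is
accordingly checked as: same axial window (half a mean rise) and a fixed
azimuthal station modulo 180° (half-width 10°).

The duplet-flip operator moves exactly the two 5′-most complementary
nucleotides of a triplet (plus the O3′ atoms linking them) into that
product pose; the 3′ base and the outgoing strand are untouched.  Flip
classification (metrics.py) is three-state: *paired* within ±1.5 Å of
the template D1 and ±25° of the template θ1; *flipping* once D1 has
moved ≥30% of the way from the unflipped reference (21.0 Å, measured on
the package's own minimal pre-flip model) toward the paired value;
*unflipped* otherwise.  Both references are computed from the builders
at run time, never hard-coded, so they stay consistent with any
reconfiguration of the geometry.  The "base-flipping plane" in which θ1
is measured is operationalised as the plane normal to the local
complementary-strand tangent at C1′ — the only frame available at this
resolution.

### Junctions

B-form tails continue the incoming duplex through a single-step kink:
the tail's helix axis makes the configured bend angle (default 90°) with
the filament axis, stacking is interrupted at exactly the junction step,
and the tail is translated so the attachment backbone gaps are minimal
under rigid placement.  Because the site-II duplex cross-section (3 Å
between backbones) is much narrower than a B-form duplex (18.8 Å), the
junction backbone steps of the synaptic model are necessarily long
(~8 Å, comparable to the inter-triplet step); the standalone junction
operator joining two B-form-like duplex ends achieves near-seamless
gaps.  The junction-angle metric infers each segment's axis
independently (windowed screw fits) and reports the deviation from
collinear continuation, so a straight joint reads 0° and the default
kink 90°.

## Screw engine

`fit_screw` superposes point sets by least squares (Kabsch) and
decomposes the rigid motion in closed form: rotation angle from the
trace, axis from the skew part (symmetric part at the 180° edge case),
translation as the axis component of the offset, axis point from the
perpendicular component via least squares.  The canonical orientation
takes the translation non-negative (positive angle for pure rotations);
pure translations return angle 0.  `infer_axis` averages windowed fits
of residues i..i+w onto i+period..i+period+w (w = max(period, 2), equal
weights — the simplest defensible rule).  Bridging O3′ atoms are
excluded from axis fits: each points at the *following* residue and so
is not screw-periodic across junctions or region boundaries.

## Protein stand-ins

The protein appears only as labelled anchor pseudo-atoms replicated by
the filament screw (60°, 15.3 Å per subunit): the site-II basic cluster
(R226/R227/R243 at 17.5 Å radius gripping the first two outgoing
phosphates of each triplet; the K245-equivalent stationed beside the
complementary duplet's 5′ phosphate so its contact breaks on flipping),
the C-terminal-domain lysine patch near the tail at the groove entrance
(placed 3 Å outside tail phosphates, stationed across two consecutive
subunits), and L2-loop steric markers at the inter-triplet gap.  The
template coordinates are geometric placeholders computed from the
builder's own frame to satisfy the documented contact patterns; they can
be overridden with positions measured from a user-supplied crystal
structure.  Salt bridges are centroid-to-phosphate distances under a
5 Å cutoff, reported in a deterministic order.

## Spring network and minimisation

Energy convention E = k·(r − r0)² (no ½), so published restraint
constants are usable verbatim; the default anchor constant is
0.5 kcal·mol⁻¹·Å⁻².  Terms: bonded springs along the backbone and base
arms (rest lengths = built geometry, except O3′–P linkages at the ideal
1.6 Å so gapped junctions close), phosphate anchors, and one-sided
repulsions below r_min = 2.5 Å.  Repulsion candidates exclude bonded
neighbours, base-paired residues, and pairs already in contact in the
built geometry — excluded volume exists to prevent *new* overlap during
relaxation, not to fight deliberate features of the reduced
representation.  Minimisation is scipy's L-BFGS-B with the analytic
gradient: deterministic, monotone over accepted iterates, iteration cap
50 000.  Backbone closure anchors every phosphate at its pre-closure
position (k = 0.5) and lets the junction O3′ atoms move onto the 1.6 Å
bond; the radial-pull protocol anchors selected phosphates at their
radially scaled targets (k = 10) with weak anchors (k = 0.02) elsewhere.
The pull selection the filament imposes — two of every three residues —
is period-3, which is why the strand's screw parameters survive the pull
within 1%.  "Constant helical symmetry" is thus enforced through the
periodic restraint pattern plus a post-hoc screw-fit check, not through
helicoidal internal coordinates; that substitution is a documented
approximation of this package.

## Synthetic data and what passing tests show

`synth` generates every test input: the 1–5-triplet scenario series,
i.i.d. Gaussian coordinate noise (a stand-in for thermal fluctuation;
no correlated elastic modes), and decoys that corrupt exactly one
property (wrong twist 30°/step, a one-step registration slide, a
straightened junction) for metric-specificity checks.  Generation is
bitwise deterministic given the spec and seed.  Passing tests therefore
demonstrate internal consistency — builders and metrics agree, engines
meet their contracts, parameters are recoverable under isotropic noise
of 0.3 Å — not fidelity to experimental coordinates; validation against
a crystal structure requires supplying one through `read_pdb`.

## Numerical choices and limitations

* Degenerate screw fits (collinear or <3 points) raise; near-180°
  rotations take the symmetric-part axis branch.
* θ1 comparisons are accurate to ~1e-4° at the 0°/180° endpoints (acos
  conditioning).
* Axis inference needs two helical periods; shorter segments fall back
  to the build frame where a caller does not supply an axis.
* Problem sizes throughout are desk-scale (≤ 5 triplets, ≤ 18-bp tails,
  hundreds of pseudo-atoms); all suites and the acceptance run complete
  in seconds.
* No electrostatics, solvent, force fields, thermal sampling or kinetic
  quantities anywhere: observables are purely geometric.
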