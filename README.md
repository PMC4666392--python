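# filamentforge

Geometric model construction and structural analysis of RecA
presynaptic-filament / double-stranded DNA intermediates — the species in
which a recombinase filament, wound around an initiating single strand,
interrogates an incoming duplex for sequence homology.

The package is for structural bioinformaticians and modellers who need
reproducible, parameter-explicit starting structures and observables for
this system rather than a molecular-dynamics engine: it builds the
models, relaxes them with a restrained spring network, and measures
every quantity that characterises them.

## The model

The active filament is a right-handed helix with **six protein subunits
per turn and three nucleotides bound per subunit**, generated by the screw
transform

&nbsp;&nbsp;&nbsp;&nbsp;S: rotation of 60° about the helix axis + 15.3 Å translation per subunit.

DNA bound inside the filament is extended to ≈1.5× its B-form length and
unwound, with the deformation concentrated between **triplets** — groups
of three stacked, nearly B-form base pairs, one per subunit.  The builders
parameterise each strand by a `HelicalParams` record
(intra/inter-triplet rise and twist, backbone radius, phase) whose
per-step means are the filament values *h* = 5.1 Å and *Ω* = 20°
(B-form: 3.38 Å, 36°, P radius 9.4 Å).  A full synaptic model threads

* the **initiating** strand in the primary site (site I, P radius ~9 Å),
* the **complementary** + **outgoing** duplex through the secondary site
  (site II, radii 12 Å and ~15 Å) diametrically opposite, in triplet
  registration,

and continues the incoming duplex into B-form tails through sharp ~90°
junction kinks.  The elementary homology-testing move is the **duplet
flip**: the two 5′-most complementary bases of a triplet swing as a
stacked pair toward the initiating strand until their C1′–C1′ distance to
the initiating partner reaches the paired value D1 = 10.4 Å taken from
the package's own B-form template; the triplet's 3′ base stays in
site II.  Observables: per-step axial rise and twist about the inferred
helix axis, strand radius, P–P spacing, extension factor (mean rise /
3.38 Å), base-pairing metrics D1 and θ1 with a three-state flip
classification, junction angle, triplet registration, and a
phosphate–anchor salt-bridge map against screw-replicated stand-ins for
the protein's basic residue clusters.

Refinement uses a harmonic spring network (E = k·Δr², so published
restraint constants such as k = 0.5 kcal·mol⁻¹·Å⁻² apply verbatim) with
backbone/base-arm bonds, phosphate anchors, and soft excluded-volume
terms, minimised deterministically.

## Worked example

```
$ python examples/full_pipeline.py
site-II rise        5.10 A   (filament value ~5.1)
site-II twist       20.0 deg  (filament value ~20)
outgoing radius     15.0 A   (~15)
initiating radius   9.0 A    (~9)
extension factor    1.509  (~1.5x B-form)
junction angle      90.0 deg  (~90)
salt-bridge contacts: 16 ({'siteII': 11, 'ctd': 5})
```

The run builds the default two-triplet model with 6-bp tails, generates
the anchor set, relaxes the network and reports the observables; the
numbers are the geometric signature of DNA held in the filament's
secondary site — stretched to 1.5× and unwound to 20°/step, with the
outgoing backbone pushed to 15 Å while the initiating strand sits at
9 Å, and the free B-DNA leaving through a right-angle kink.

The flip example prints the homology-sampling move directly:

```
$ python examples/flip_and_metrics.py
pair   D1 before -> after   state
  1     21.0 A  ->  21.0 A   unflipped
  2     21.0 A  ->  10.4 A   paired
  3     21.0 A  ->  10.4 A   paired
  ...
salt bridges released by the flips: [('C:10', 'K245'), ('C:7', 'K245')]
```

Each triplet exchanges its 5′ duplet (D1 drops to the paired 10.4 Å)
while the 3′ base stays put, and the flip releases the salt bridge
between the duplet's 5′ phosphate and its K245-equivalent anchor.

One `examples/*.py` script exists per capability; a thin `filamentforge`
CLI (`build`, `analyze`, `fit-screw`, `anchors`, `contacts`, `relax`,
`fixtures`, `run`) wraps the same functions for shell use.

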