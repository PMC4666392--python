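"""End-to-end orchestration: build -> anchor -> relax -> analyze -> report.

A single call reconstructs a synaptic starting structure, surrounds it
with the protein anchor stand-ins, relaxes the spring network, measures
every structural observable and returns a self-consistent report: each
reported mean is recomputable from the archived relaxed structure with
the metrics module alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import config as cfg
from . import metrics
from .anchors import (AnchorSet, TemplateError, default_ctd_template,
                      filament_screw, generate_ctd_anchors,
                      generate_siteII_anchors, occupancy_fraction,
                      salt_bridge_map)
from .builder import TripletPattern, flip_duplet
from .screw import Axis, GeometryError, infer_axis
from .springs import build_network, minimize
from .structure import Structure, write_pdb
from .synth import ScenarioSpec, make_scenario

log = logging.getLogger("filamentforge.pipeline")


@dataclasses.dataclass
class RunReport:
    scenario: dict
    means: dict
    flip_states: list
    contacts: dict
    provenance: dict
    relaxation: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def site2_axis(structure: Structure) -> Axis:
    """Helix axis of the site-II region, inferred from the strand itself
    (falls back to the build frame for models too short to fit)."""
    rng = structure.metadata["site2"]["ranges"]["O"]
    try:
        seg = structure.select(chain_id="O", residues=range(rng[0], rng[1] + 1))
        return infer_axis(seg, 3)
    except GeometryError:
        return Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))


def measure(structure: Structure) -> dict:
    """All scalar observables of a (possibly relaxed) synaptic model."""
    axis = site2_axis(structure)
    ranges = structure.metadata["site2"]["ranges"]
    means: dict = {}
    role_of = {"I": "initiating", "C": "complementary", "O": "outgoing"}
    for chain, role in role_of.items():
        if chain not in ranges:
            continue
        lo, hi = ranges[chain]
        seg = structure.select(chain_id=chain, residues=range(lo, hi + 1))
        steps = metrics.step_parameters(seg, axis)
        tm = metrics.triplet_means(steps)
        _, mean_radius = metrics.strand_radius(seg, axis)
        means[f"rise_{role}"] = abs(tm["rise"])
        means[f"twist_{role}"] = abs(tm["twist"])
        means[f"pp_{role}"] = tm["pp"]
        means[f"radius_{role}"] = mean_radius
    means["rise"] = means["rise_outgoing"]
    means["twist"] = means["twist_outgoing"]
    means["extension"] = means["rise"] / cfg.B_RISE
    try:
        means["junction_angle"] = metrics.junction_angle(structure)
    except metrics.MetricError:
        means["junction_angle"] = float("nan")
    return means


def run_scenario(spec: ScenarioSpec, config: cfg.Config | None = None,
                 outdir: str | Path | None = None,
                 flip_triplets: tuple[int, ...] = ()) -> tuple[RunReport, Structure]:
    """Execute the full pipeline for one scenario.

    Returns the report together with the relaxed structure; with
    ``outdir`` set, pre-/post-relaxation PDBs, the JSON report, a
    per-step table and the contact table are archived there.
    ``flip_triplets`` applies the duplet-flip operator to the listed
    site-II triplets after construction.
    """
    config = config or cfg.Config()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        log.info("stage %s done", name)
        return result

    structure = stage("build", make_scenario, spec)
    for t in flip_triplets:
        structure = stage(f"flip:{t}", flip_duplet, structure, t)
    if outdir is not None:
        write_pdb(structure, outdir / "model_initial.pdb")

    n_monomers = spec.n_triplets + 3
    screw = filament_screw()
    anchor_set = stage("anchors", generate_siteII_anchors, screw, n_monomers)
    if spec.tails >= 2:
        try:
            pattern = TripletPattern(spec.n_triplets, spec.tails, spec.tails)
            ctd = generate_ctd_anchors(screw, n_monomers, default_ctd_template(pattern))
            anchor_set = anchor_set.merged_with(ctd)
        except TemplateError:
            pass
    if outdir is not None:
        anchor_set.to_json(outdir / "anchors.json")

    net = stage("network", build_network, structure, anchor_set,
                config.k_anchor, config.k_bond)
    relaxed, trace = stage("relax", minimize, net, config.min_tol, config.max_iter)
    log.info("relaxation: %d trace points, E %.3g -> %.3g",
             len(trace), trace[0], trace[-1])

    means = stage("metrics", measure, relaxed)
    flips = [dataclasses.asdict(m) for m in metrics.all_basepair_metrics(relaxed)]
    contacts = stage("contacts", salt_bridge_map, relaxed, anchor_set,
                     config.salt_bridge_cutoff)
    contact_summary = {
        "n_contacts": len(contacts),
        "occupancy": occupancy_fraction(contacts, relaxed),
        "by_kind": _count_by(contacts, anchor_set),
    }
    report = RunReport(
        scenario=dataclasses.asdict(spec),
        means={k: float(v) for k, v in means.items()},
        flip_states=flips,
        contacts=contact_summary,
        provenance={"config": config.digest(), "seed": spec.seed},
        relaxation=relaxed.metadata.get("relaxation", {}),
    )
    if outdir is not None:
        write_pdb(relaxed, outdir / "model_relaxed.pdb")
        (outdir / "report.json").write_text(report.to_json())
        _write_steps_tsv(relaxed, outdir / "steps.tsv")
        _write_contacts_tsv(contacts, outdir / "contacts.tsv")
    return report, relaxed


def _count_by(contacts, anchor_set: AnchorSet) -> dict:
    kind_of = {a.label: a.kind for a in anchor_set.anchors}
    counts: dict[str, int] = {}
    for c in contacts:
        kind = kind_of.get(c.label, "?")
        counts[kind] = counts.get(kind, 0) + 1
    return counts


def _write_steps_tsv(structure: Structure, path: Path) -> None:
    axis = site2_axis(structure)
    rows = ["chain\tstep\trise\ttwist\tpp"]
    ranges = structure.metadata["site2"]["ranges"]
    for chain, (lo, hi) in ranges.items():
        seg = structure.select(chain_id=chain, residues=range(lo, hi + 1))
        for s in metrics.step_parameters(seg, axis):
            rows.append(f"{chain}\t{s.step_index}\t{s.axial_rise:.4f}"
                        f"\t{s.twist:.4f}\t{s.pp_distance:.4f}")
    path.write_text("\n".join(rows) + "\n")


def _write_contacts_tsv(contacts, path: Path) -> None:
    rows = ["phosphate\tlabel\tmonomer\tdistance"]
    rows += [f"{c.phosphate}\t{c.label}\t{c.monomer_index}\t{c.distance:.4f}"
             for c in contacts]
    path.write_text("\n".join(rows) + "\n")
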