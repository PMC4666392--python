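"""Deterministic fixture generation: scenarios, noise, decoys.

Every test input the analysis assumes is generated here: the 1-5-triplet
scenario series of starting structures, Gaussian-perturbed replicas
standing in for thermal fluctuation, and decoys that corrupt exactly one
named geometric property so the metrics' specificity can be checked.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import config as cfg
from .builder import (HelicalParams, TripletPattern, build_synaptic_model,
                      make_postsynaptic_reference)
from .structure import Structure

DECOY_MODES = ("none", "wrong_twist", "misregistered", "unkinked")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic starting structure: how many triplets are bound in
    site II, the tail length, coordinate noise, seed, and an optional
    decoy corruption."""

    n_triplets: int = 2
    tails: int = 6
    noise_sigma: float = 0.0
    seed: int = 0
    decoy_mode: str = "none"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.decoy_mode not in DECOY_MODES:
            raise ValueError(f"unknown decoy mode {self.decoy_mode!r}")


def default_sequence(length: int) -> str:
    # poly-dT complementary strand: the canonical filament substrate.
    return "T" * length


def make_scenario(spec: ScenarioSpec) -> Structure:
    """Build the starting structure a scenario describes.

    Deterministic given the spec (the seed drives the only randomness,
    the coordinate noise); decoy modes alter exactly the named property:
    ``wrong_twist`` rebuilds site II at 30°/step, ``misregistered`` slides
    the complementary strand one axial step out of register, ``unkinked``
    straightens the junctions.
    """
    if not 1 <= spec.n_triplets <= 5:
        raise ValueError("n_triplets must lie in 1..5")
    bend = 0.0 if spec.decoy_mode == "unkinked" else cfg.BEND_ANGLE
    pattern = TripletPattern(spec.n_triplets, spec.tails, spec.tails, bend)
    params = None
    if spec.decoy_mode == "wrong_twist":
        params = HelicalParams(intra_twist=30.0, inter_twist=30.0)
    structure = build_synaptic_model(default_sequence(pattern.total_bp), pattern,
                                     site2_params=params)
    if spec.decoy_mode == "misregistered":
        structure = _shift_complementary(structure)
    if spec.noise_sigma > 0:
        structure = perturb_structure(structure, spec.noise_sigma, spec.seed)
    structure.metadata["scenario"] = dataclasses.asdict(spec)
    return structure


def _shift_complementary(structure: Structure) -> Structure:
    out = structure.copy()
    rng = out.metadata["site2"]["ranges"]["C"]
    shift = np.array([0.0, 0.0, float(out.metadata["mean_rise"])])
    for atom in out.atoms:
        if atom.chain_id == "C" and rng[0] <= atom.residue_index <= rng[1]:
            atom.position = atom.position + shift
    return out


def perturb_structure(structure: Structure, sigma: float, seed: int) -> Structure:
    """Add i.i.d. Gaussian displacement per coordinate (sigma in Å)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    coords = structure.coords + rng.normal(0.0, sigma, size=(len(structure), 3))
    return structure.with_coords(coords)


def scenario_grid(tails: int = 6) -> list[ScenarioSpec]:
    """The full 1-5-triplet x decoy-mode grid of starting structures."""
    return [ScenarioSpec(n, tails, 0.0, 0, decoy)
            for n in range(1, 6) for decoy in DECOY_MODES]


__all__ = ["ScenarioSpec", "DECOY_MODES", "make_scenario", "perturb_structure",
           "make_postsynaptic_reference", "scenario_grid", "default_sequence"]
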