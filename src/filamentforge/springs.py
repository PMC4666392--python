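"""Spring-network restrained relaxation.

The network is harmonic throughout, with the convention E = k*(r - r0)^2
(no 1/2 factor), so published restraint constants in kcal·mol⁻¹·Å⁻² are
usable verbatim.  Terms:

* bonded springs along each backbone and base arm (r0 = current length at
  build time, except the O3'-P phosphodiester linkage which uses the ideal
  1.6 Å so that gapped junctions are pulled closed);
* harmonic anchors tying mapped phosphates to fixed target points
  (default k = 0.5 kcal·mol⁻¹·Å⁻², the soft restraint used to hold
  interacting phosphates during refinement);
* soft one-sided excluded-volume repulsions active below r_min.

Minimisation is deterministic (scipy L-BFGS-B with an analytic gradient);
the energy trace over accepted iterates is returned alongside the relaxed
structure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from . import config as cfg
from .screw import Axis, GeometryError, infer_axis
from .structure import Structure, concatenate


class MappingError(KeyError):
    pass


class ClosureError(RuntimeError):
    def __init__(self, message: str, junction_index: int | None = None):
        super().__init__(message)
        self.junction_index = junction_index


@dataclasses.dataclass
class SpringNetwork:
    structure: Structure
    bonds: np.ndarray        # (nb, 2) int indices
    bond_k: np.ndarray       # (nb,)
    bond_r0: np.ndarray      # (nb,)
    anchor_idx: np.ndarray   # (na,) int
    anchor_k: np.ndarray     # (na,)
    anchor_target: np.ndarray  # (na, 3)
    rep_pairs: np.ndarray    # (nr, 2) int
    rep_k: np.ndarray
    rep_rmin: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.structure)

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = coords.reshape(self.n_atoms, 3)
        energy = 0.0
        grad = np.zeros_like(x)
        if len(self.bonds):
            d = x[self.bonds[:, 0]] - x[self.bonds[:, 1]]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
            dr = r - self.bond_r0
            energy += float(np.sum(self.bond_k * dr ** 2))
            f = (2.0 * self.bond_k * dr / r)[:, None] * d
            np.add.at(grad, self.bonds[:, 0], f)
            np.add.at(grad, self.bonds[:, 1], -f)
        if len(self.anchor_idx):
            d = x[self.anchor_idx] - self.anchor_target
            energy += float(np.sum(self.anchor_k * np.sum(d ** 2, axis=1)))
            np.add.at(grad, self.anchor_idx, 2.0 * self.anchor_k[:, None] * d)
        if len(self.rep_pairs):
            d = x[self.rep_pairs[:, 0]] - x[self.rep_pairs[:, 1]]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
            overlap = np.maximum(self.rep_rmin - r, 0.0)
            energy += float(np.sum(self.rep_k * overlap ** 2))
            f = (-2.0 * self.rep_k * overlap / r)[:, None] * d
            np.add.at(grad, self.rep_pairs[:, 0], f)
            np.add.at(grad, self.rep_pairs[:, 1], -f)
        return energy, grad.ravel()

    def energy(self, coords: np.ndarray | None = None) -> float:
        x = coords if coords is not None else self.structure.coords
        return self.energy_and_gradient(np.asarray(x, dtype=float).ravel())[0]


_RESIDUE_PATH = ("P", "C1'", "N9", "N1", "CEN")


def _atom_index(structure: Structure) -> dict[tuple[str, int, str], int]:
    return {(a.chain_id, a.residue_index, a.name): i
            for i, a in enumerate(structure.atoms)}


def build_network(structure: Structure, anchors=None,
                  k_anchor: float = cfg.K_ANCHOR, k_bond: float = cfg.K_BOND,
                  k_repulsion: float = cfg.K_REPULSION, r_min: float = cfg.R_MIN,
                  cutoff: float = cfg.SALT_BRIDGE_CUTOFF,
                  extra_link_bonds: list[tuple[int, int]] | None = None) -> SpringNetwork:
    """Assemble the spring network of a structure.

    Bonded springs connect the atoms of every nucleotide (P-C1'-N-CEN arm,
    P-O3') and the O3'(i)-P(i+1) linkage along each chain; the linkage r0
    is the ideal phosphodiester length, everything else keeps its built
    geometry.  If an anchor set is given, every phosphate within ``cutoff``
    of an anchor receives a harmonic anchor at its current position.
    """
    index = _atom_index(structure)
    coords = structure.coords
    bonds, bond_k, bond_r0 = [], [], []

    def add_bond(i: int, j: int, k: float, r0: float | None = None):
        length = float(np.linalg.norm(coords[i] - coords[j]))
        bonds.append((i, j))
        bond_k.append(k)
        bond_r0.append(length if r0 is None else r0)

    for chain in structure.chains():
        residues = structure.residue_indices(chain)
        for n, res in enumerate(residues):
            names = [a.name for a in structure.atoms
                     if a.chain_id == chain and a.residue_index == res]
            path = [nm for nm in _RESIDUE_PATH if nm in names]
            for a, b in zip(path, path[1:]):
                add_bond(index[(chain, res, a)], index[(chain, res, b)], k_bond)
            if "P" in names and "O3'" in names:
                add_bond(index[(chain, res, "P")], index[(chain, res, "O3'")], k_bond)
            if n + 1 < len(residues):
                nxt = residues[n + 1]
                if "O3'" in names and (chain, nxt, "P") in index:
                    add_bond(index[(chain, res, "O3'")], index[(chain, nxt, "P")],
                             k_bond, cfg.O3_P_BOND)
    for i, j in (extra_link_bonds or []):
        add_bond(i, j, k_bond, cfg.O3_P_BOND)

    anchor_idx, anchor_k, anchor_target = [], [], []
    if anchors is not None:
        if not anchors.anchors:
            raise ValueError("empty anchor set")
        p_atoms = [(i, a) for i, a in enumerate(structure.atoms) if a.name == "P"]
        if not p_atoms:
            raise MappingError("structure has no phosphates to anchor")
        p_coords = np.array([coords[i] for i, _ in p_atoms])
        for anchor in anchors.anchors:
            dist = np.linalg.norm(p_coords - anchor.position, axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= cutoff:
                idx = p_atoms[j][0]
                if idx not in anchor_idx:
                    anchor_idx.append(idx)
                    anchor_k.append(k_anchor)
                    anchor_target.append(coords[idx].copy())

    bonded = set()
    for i, j in bonds:
        bonded.add((min(i, j), max(i, j)))
    # Residues recorded as base-paired are deliberately in contact: exclude
    # them from excluded-volume terms, like 1-2 bonded neighbours.
    paired: set[frozenset] = set()
    for entry in structure.metadata.get("pairs", []):
        members = [(c, r) for c, r in entry.items()
                   if len(c) == 1 and isinstance(r, (int, np.integer))]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                paired.add(frozenset((members[a], members[b])))
    # Candidate excluded-volume pairs: close non-bonded neighbours that are
    # NOT already in contact in the built geometry.  Contacts present at
    # build time are by-design features of the reduced representation (the
    # stretched site-II duplex threads base arms between backbones); the
    # repulsion terms exist to keep relaxation from creating new overlap.
    rep_pairs, rep_k, rep_rmin = [], [], []
    if len(structure) > 1 and k_repulsion > 0:
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(2.0 * r_min)):
            ai, aj = structure.atoms[i], structure.atoms[j]
            if ai.chain_id == aj.chain_id and abs(ai.residue_index - aj.residue_index) <= 1:
                continue
            if (i, j) in bonded:
                continue
            if frozenset(((ai.chain_id, ai.residue_index),
                          (aj.chain_id, aj.residue_index))) in paired:
                continue
            if float(np.linalg.norm(coords[i] - coords[j])) < r_min:
                continue
            rep_pairs.append((i, j))
            rep_k.append(k_repulsion)
            rep_rmin.append(r_min)

    def arr(x, dtype=float):
        return np.asarray(x, dtype=dtype) if x else np.zeros((0,), dtype=dtype)

    return SpringNetwork(
        structure,
        np.asarray(bonds, dtype=int) if bonds else np.zeros((0, 2), dtype=int),
        arr(bond_k), arr(bond_r0),
        arr(anchor_idx, int), arr(anchor_k),
        np.asarray(anchor_target, dtype=float) if anchor_target else np.zeros((0, 3)),
        np.asarray(rep_pairs, dtype=int) if rep_pairs else np.zeros((0, 2), dtype=int),
        arr(rep_k), arr(rep_rmin))


def minimize(net: SpringNetwork, tol: float = cfg.MIN_TOL,
             max_iter: int = cfg.MAX_ITER,
             start_coords: np.ndarray | None = None) -> tuple[Structure, list[float]]:
    """Deterministic restrained minimisation of the network.

    Returns the relaxed structure and the energy trace over accepted
    iterates (non-increasing).  The terminal gradient norm is checked
    against ``tol``; hitting the iteration cap is reported in the trace's
    metadata rather than raised.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    x0 = (np.asarray(start_coords, dtype=float) if start_coords is not None
          else net.structure.coords).ravel()
    e0, _ = net.energy_and_gradient(x0)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at the starting configuration")
    trace = [e0]

    def callback(xk):
        trace.append(net.energy_and_gradient(xk)[0])

    result = _scipy_minimize(net.energy_and_gradient, x0, jac=True, method="L-BFGS-B",
                             callback=callback,
                             options={"maxiter": max_iter, "gtol": tol, "ftol": 0.0})
    if result.fun <= trace[-1]:
        trace.append(float(result.fun))
    relaxed = net.structure.with_coords(result.x.reshape(-1, 3))
    relaxed.metadata.setdefault("relaxation", {})
    relaxed.metadata["relaxation"] = {
        "iterations": int(result.nit),
        "final_energy": float(result.fun),
        "gradient_norm": float(np.linalg.norm(result.jac)),
        "converged": bool(result.success or np.linalg.norm(result.jac) <= tol),
    }
    return relaxed, trace


def close_backbone(fragments: list[Structure], screw=None,
                   k_anchor: float = cfg.K_ANCHOR, k_bond: float = cfg.K_BOND,
                   gap_limit: float = 5.0) -> Structure:
    """Link screw-replicated fragments into continuous strands.

    Fragments are concatenated with sequential residue renumbering; the
    inter-fragment O3'-P linkages become springs at the ideal 1.6 Å while
    every phosphate is softly anchored at its pre-closure position, so the
    junctions close without disturbing the anchored interactions.
    """
    if not fragments:
        raise ValueError("no fragments to close")
    renumbered = []
    offsets: dict[str, int] = {}
    for frag in fragments:
        shifted = frag.copy()
        for atom in shifted.atoms:
            atom.residue_index += offsets.get(atom.chain_id, 0)
        for chain in frag.chains():
            offsets[chain] = offsets.get(chain, 0) + len(frag.residue_indices(chain))
        renumbered.append(shifted)
    merged = concatenate(renumbered, metadata=dict(fragments[0].metadata))
    index = _atom_index(merged)
    coords = merged.coords

    links = []
    boundary = {}
    for chain in merged.chains():
        residues = merged.residue_indices(chain)
        cursor = 0
        for frag in fragments[:-1]:
            cursor += len(frag.residue_indices(chain))
            boundary.setdefault(chain, []).append((residues[cursor - 1], residues[cursor]))
    junction_no = 0
    for chain, pairs in boundary.items():
        for last, first in pairs:
            junction_no += 1
            i = index.get((chain, last, "O3'"))
            j = index.get((chain, first, "P"))
            if i is None or j is None:
                raise ClosureError(f"junction {junction_no}: missing O3'/P atoms", junction_no)
            gap = float(np.linalg.norm(coords[i] - coords[j]))
            if gap > gap_limit:
                raise ClosureError(
                    f"junction {junction_no}: O3'-P gap {gap:.2f} Å exceeds the "
                    f"{gap_limit:.1f} Å closure budget", junction_no)
            links.append((i, j))

    net = build_network(merged, k_anchor=k_anchor, k_bond=k_bond,
                        extra_link_bonds=links)
    for i, a in enumerate(merged.atoms):   # anchor every phosphate where it is
        if a.name == "P":
            net.anchor_idx = np.append(net.anchor_idx, i)
            net.anchor_k = np.append(net.anchor_k, k_anchor)
            net.anchor_target = np.vstack([net.anchor_target, coords[i]])
    closed, _trace = minimize(net)
    final = closed.coords
    for n, (i, j) in enumerate(links, 1):
        bond = float(np.linalg.norm(final[i] - final[j]))
        if abs(bond - cfg.O3_P_BOND) > 0.2:
            raise ClosureError(
                f"junction {n}: closed O3'-P bond {bond:.2f} Å outside 1.6 ± 0.2 Å", n)
    return closed


def radial_pull(structure: Structure, selection, target_radius: float,
                k: float = cfg.K_PULL, axis: Axis | None = None) -> Structure:
    """Pull selected phosphates to a target radius under the helical frame.

    Each selected phosphate is pulled along its own radial direction to
    ``target_radius`` (azimuth and axial station untouched), every other
    atom is weakly anchored, and the bonded network rides along.  The
    selection pattern the filament imposes (two of every three residues)
    keeps the period-3 screw of the strand intact.
    """
    if target_radius <= 0:
        raise ValueError("target radius must be positive")
    chain = structure.chains()[0]
    if axis is None:
        try:
            axis = infer_axis(structure, int(structure.metadata.get("period", 3)),
                              chain_id=chain)
        except GeometryError:
            axis = Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    net = build_network(structure, k_bond=cfg.K_BOND)
    coords = structure.coords
    selection = set(int(s) for s in selection)
    sel_idx, sel_target = [], []
    for i, atom in enumerate(structure.atoms):
        if atom.chain_id != chain:
            continue
        if atom.name == "P" and atom.residue_index in selection:
            radial = coords[i] - (axis.point + float(axis.axial(coords[i][None])[0]) * axis.direction)
            norm = np.linalg.norm(radial)
            if norm < 1e-9:
                raise GeometryError(f"residue {atom.residue_index}: phosphate on the axis")
            sel_idx.append(i)
            sel_target.append(coords[i] + (target_radius - norm) * radial / norm)
    if not sel_idx:
        raise ValueError("selection matched no phosphates")
    weak_idx = [i for i in range(len(structure)) if i not in set(sel_idx)]
    net.anchor_idx = np.concatenate([np.asarray(sel_idx, int), np.asarray(weak_idx, int)])
    net.anchor_k = np.concatenate([np.full(len(sel_idx), k),
                                   np.full(len(weak_idx), cfg.K_WEAK)])
    net.anchor_target = np.vstack([np.asarray(sel_target),
                                   coords[np.asarray(weak_idx, int)]])
    pulled, _trace = minimize(net)
    return pulled
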