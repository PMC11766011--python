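"""Stepped S4 downshift with restrained Monte-Carlo energy minimization.

The energy is a documented coarse-grained surrogate over the CA trace plus
one charged interaction site per ionizable side chain:

* Coulomb ``332.06 * qi * qj / (eps(r) * r)`` with a distance-dependent
  dielectric ``eps(r) = r`` (configurable) over nonbonded site pairs;
* 12-6 Lennard-Jones ``4*eps*((sigma/r)^12 - (sigma/r)^6)`` over all
  nonbonded atom pairs (sigma 4.0 A, eps 0.1 kcal/mol);
* harmonic virtual bonds keeping each helix near-ideal (CA i,i+1 at 3.8 A;
  CA i,i+4 at 6.2 A; k = 10 kcal/mol/A^2) and tethering each charged site
  to its CA at the builder offset;
* flat-bottom positional restraints (free radius 4 A, k = 10) and exact
  plane constraints on selected atoms.

Nonbonded pairs are atoms on different helices/chains or >= 3 residues
apart.  The minimizer alternates seeded random moves (rigid in-plane
translation/rotation of a designated helix about its vertical axis plus
per-site jitter) with a deterministic coordinate-descent refinement, and
terminates when a fixed number of consecutive candidate minimizations
fails to improve the best energy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .structures_io import (
    RESIDUE_CHARGE,
    SITE_ATOM_NAME,
    SITE_OFFSET,
    Structure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyModel",
    "PlaneConstraint",
    "FlatBottomRestraint",
    "MCConfig",
    "TrajectoryStep",
    "Trajectory",
    "EnergySystem",
    "total_energy",
    "mc_minimize",
    "deactivate_s4",
]

KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/mol/K

AtomId = tuple[str, int, str]


@dataclass
class EnergyModel:
    """Parameters of the surrogate energy (kcal/mol, Angstrom, elementary charges)."""

    coulomb_constant: float = 332.06
    dielectric: Callable[[np.ndarray], np.ndarray] = field(default=lambda r: r)
    lj_sigma: float = 4.0
    lj_epsilon: float = 0.1
    backbone_k: float = 10.0
    charges: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_CHARGE))

    def __post_init__(self) -> None:
        for label, value in (("coulomb_constant", self.coulomb_constant),
                             ("lj_sigma", self.lj_sigma),
                             ("lj_epsilon", self.lj_epsilon),
                             ("backbone_k", self.backbone_k)):
            if value <= 0:
                raise ValueError(f"{label} must be positive, got {value}")


@dataclass
class PlaneConstraint:
    """Pin atoms to the plane z = target_z; they move freely within the plane."""

    atom_ids: tuple[AtomId, ...]
    target_z: float

    def __post_init__(self) -> None:
        self.atom_ids = tuple(self.atom_ids)


@dataclass
class FlatBottomRestraint:
    """Zero penalty within free_radius of the reference, harmonic beyond it."""

    atom_id: AtomId
    reference: np.ndarray
    free_radius: float = 4.0
    force_k: float = 10.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.free_radius < 0 or self.force_k <= 0:
            raise ValueError("free_radius must be >= 0 and force_k > 0")

    def energy(self, xyz: np.ndarray) -> float:
        d = float(np.linalg.norm(np.asarray(xyz) - self.reference))
        excess = max(0.0, d - self.free_radius)
        return self.force_k * excess * excess


@dataclass
class MCConfig:
    """Monte-Carlo minimization settings.  A fixed seed gives a bit-identical run."""

    seed: int = 0
    temperature: float = 300.0
    rigid_shift: float = 0.4       # A, sd of in-plane rigid-group translation
    rigid_rot: float = 4.0         # degrees, sd of rigid-group rotation about its axis
    site_jitter: float = 0.3       # A, max per-site random displacement
    big_rot_prob: float = 0.2      # chance of a large uniform rotation proposal
    termination_window: int = 100  # consecutive non-improving minimizations
    max_moves: int = 2000
    descent_iters: int = 20
    descent_step: float = 0.5      # A (and degrees x4 for rotation), halved on failure
    rigid_helix: str | None = None

    def __post_init__(self) -> None:
        if self.termination_window < 1:
            raise ValueError("termination_window must be >= 1")
        if self.max_moves < 1:
            raise ValueError("max_moves must be >= 1")


@dataclass
class TrajectoryStep:
    index: int
    z_offset: float
    structure: Structure
    energy_terms: dict[str, float]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("step index must be >= 0")
        if self.index == 0 and self.z_offset != 0.0:
            raise ValueError("step 0 must have zero z offset")
        if self.index > 0 and self.z_offset > 0.0:
            raise ValueError("steps after 0 cannot have positive z offset")
        if self.energy_terms.get("restraint", 0.0) < -1e-9:
            raise ValueError("restraint energy must be non-negative")


@dataclass
class Trajectory:
    steps: list[TrajectoryStep]
    provenance: dict

    def __post_init__(self) -> None:
        for i, step in enumerate(self.steps):
            if step.index != i:
                raise ValueError("trajectory step indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def structures(self) -> list[Structure]:
        return [s.structure for s in self.steps]

    @property
    def n_downshifted(self) -> int:
        """Number of recorded downshifted (z_offset < 0) minimized structures."""
        return sum(1 for s in self.steps if s.z_offset < 0)


# ---------------------------------------------------------------------------
# Energy system: precompiled pair lists for fast vectorized evaluation
# ---------------------------------------------------------------------------

class EnergySystem:
    """Pair lists and parameters compiled once per structure topology."""

    def __init__(self, structure: Structure, model: EnergyModel,
                 restraints: Sequence[FlatBottomRestraint | PlaneConstraint] = ()):
        self.structure = structure
        self.model = model
        atoms = structure.atoms
        n = len(atoms)
        helix = np.array([structure.helix_of(a.chain, a.residue_index) or f"@{a.chain}"
                          for a in atoms], dtype=object)
        resi = np.array([a.residue_index for a in atoms])
        chain = np.array([a.chain for a in atoms], dtype=object)
        is_site = np.array([a.name == SITE_ATOM_NAME.get(a.residue_name) for a in atoms])
        charge = np.zeros(n)
        for i, a in enumerate(atoms):
            if is_site[i]:
                q = model.charges.get(a.residue_name)
                if q is None:
                    logger.warning("no charge entry for residue %s; treated as neutral",
                                   a.residue_name)
                    q = 0.0
                charge[i] = q

        iu, ju = np.triu_indices(n, k=1)
        different = (chain[iu] != chain[ju]) | (helix[iu] != helix[ju])
        separated = np.abs(resi[iu] - resi[ju]) >= 3
        nonbonded = different | separated
        self.lj_i = iu[nonbonded]
        self.lj_j = ju[nonbonded]
        qq = charge[iu] * charge[ju]
        charged = nonbonded & (qq != 0.0) & is_site[iu] & is_site[ju]
        self.cou_i = iu[charged]
        self.cou_j = ju[charged]
        self.cou_qq = qq[charged]

        bonds: list[tuple[int, int, float]] = []
        ca_index: dict[tuple[str, int], int] = {}
        for i, a in enumerate(atoms):
            if a.name == "CA":
                ca_index[(a.chain, a.residue_index)] = i
        for helix_id, (ch, lo, hi) in structure.annotations.items():
            for r in range(lo, hi + 1):
                if (ch, r) in ca_index:
                    if (ch, r + 1) in ca_index and r + 1 <= hi:
                        bonds.append((ca_index[(ch, r)], ca_index[(ch, r + 1)], 3.8))
                    if (ch, r + 4) in ca_index and r + 4 <= hi:
                        bonds.append((ca_index[(ch, r)], ca_index[(ch, r + 4)], 6.2))
        for i, a in enumerate(atoms):
            if is_site[i] and (a.chain, a.residue_index) in ca_index:
                bonds.append((ca_index[(a.chain, a.residue_index)], i,
                              SITE_OFFSET[a.residue_name]))
        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_r0 = np.array([b[2] for b in bonds])

        self.flat_bottom = [r for r in restraints if isinstance(r, FlatBottomRestraint)]
        self.fb_index = np.array(
            [structure.index_of(*r.atom_id) for r in self.flat_bottom], dtype=int)
        self.fb_ref = (np.array([r.reference for r in self.flat_bottom])
                       if self.flat_bottom else np.zeros((0, 3)))
        self.fb_radius = np.array([r.free_radius for r in self.flat_bottom])
        self.fb_k = np.array([r.force_k for r in self.flat_bottom])

        self.planes = [r for r in restraints if isinstance(r, PlaneConstraint)]
        self.plane_index = [np.array([structure.index_of(*aid) for aid in p.atom_ids],
                                     dtype=int) for p in self.planes]
        self.is_site = is_site
        self._build_fused(n)

    def _build_fused(self, n: int) -> None:
        """Fused pair arrays for fast evaluation.

        Coulomb pairs are a subset of the nonbonded (LJ) pairs, so one
        distance pass serves both terms: ``pair_kq`` holds
        ``coulomb_constant * qi * qj`` aligned with the LJ pair list
        (zero for uncharged pairs).
        """
        kq_lookup = {(int(i), int(j)): self.model.coulomb_constant * qq
                     for i, j, qq in zip(self.cou_i, self.cou_j, self.cou_qq)}
        self.pair_kq = np.array([kq_lookup.get((int(i), int(j)), 0.0)
                                 for i, j in zip(self.lj_i, self.lj_j)])
        nbr: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i, j, kq in zip(self.lj_i, self.lj_j, self.pair_kq):
            nbr[int(i)].append((int(j), kq))
            nbr[int(j)].append((int(i), kq))
        self.nbr_idx = [np.array([p[0] for p in pairs], dtype=int) for pairs in nbr]
        self.nbr_kq = [np.array([p[1] for p in pairs]) for pairs in nbr]
        bond: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i, j, r0 in zip(self.bond_i, self.bond_j, self.bond_r0):
            bond[int(i)].append((int(j), r0))
            bond[int(j)].append((int(i), r0))
        self.bond_nbr = [(np.array([p[0] for p in pairs], dtype=int),
                          np.array([p[1] for p in pairs])) for pairs in bond]
        fb: dict[int, tuple[np.ndarray, float, float]] = {}
        for k, idx in enumerate(self.fb_index):
            fb[int(idx)] = (self.fb_ref[k], float(self.fb_radius[k]),
                            float(self.fb_k[k]))
        self.fb_by_atom = fb
        self._cross_cache: tuple[bytes, np.ndarray, np.ndarray, np.ndarray] | None = None

    def set_rigid_group(self, idx: np.ndarray) -> None:
        """Precompute the nonbonded pairs crossing a rigid group's boundary.

        Rigid moves change only these pair distances (bonds and restraints
        never cross the boundary by construction), enabling cheap deltas.
        """
        in_group = np.zeros(len(self.structure.atoms), dtype=bool)
        in_group[idx] = True
        cross = in_group[self.lj_i] != in_group[self.lj_j]
        self.cross_i = self.lj_i[cross]
        self.cross_j = self.lj_j[cross]
        self.cross_kq = self.pair_kq[cross]

    def cross_energy(self, coords: np.ndarray) -> float:
        """Nonbonded energy of the rigid-group boundary pairs only."""
        model = self.model
        diff = coords[self.cross_i] - coords[self.cross_j]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        sr6 = (model.lj_sigma / d) ** 6
        e = np.sum(4.0 * model.lj_epsilon * (sr6 * sr6 - sr6))
        e += np.sum(self.cross_kq / (model.dielectric(d) * d))
        return float(e)

    def atom_energy(self, coords: np.ndarray, i: int, pos: np.ndarray) -> float:
        """Energy contribution of atom ``i`` placed at ``pos`` (its pair terms only)."""
        model = self.model
        e = 0.0
        j = self.nbr_idx[i]
        if len(j):
            diff = coords[j] - pos
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            sr6 = (model.lj_sigma / d) ** 6
            e += float(np.sum(4.0 * model.lj_epsilon * (sr6 * sr6 - sr6))
                       + np.sum(self.nbr_kq[i] / (model.dielectric(d) * d)))
        j, r0 = self.bond_nbr[i]
        if len(j):
            diff = coords[j] - pos
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            e += float(np.sum(model.backbone_k * (d - r0) ** 2))
        if i in self.fb_by_atom:
            ref, radius, k = self.fb_by_atom[i]
            excess = max(0.0, float(np.linalg.norm(pos - ref)) - radius)
            e += k * excess * excess
        return e

    def project_planes(self, coords: np.ndarray) -> None:
        for plane, idx in zip(self.planes, self.plane_index):
            coords[idx, 2] = plane.target_z

    def energy_terms(self, coords: np.ndarray) -> dict[str, float]:
        model = self.model
        terms: dict[str, float] = {}
        if len(self.cou_i):
            d = np.linalg.norm(coords[self.cou_i] - coords[self.cou_j], axis=1)
            terms["coulomb"] = float(np.sum(
                model.coulomb_constant * self.cou_qq / (model.dielectric(d) * d)))
        else:
            terms["coulomb"] = 0.0
        if len(self.lj_i):
            d = np.linalg.norm(coords[self.lj_i] - coords[self.lj_j], axis=1)
            sr6 = (model.lj_sigma / d) ** 6
            terms["lj"] = float(np.sum(4.0 * model.lj_epsilon * (sr6 * sr6 - sr6)))
        else:
            terms["lj"] = 0.0
        if len(self.bond_i):
            d = np.linalg.norm(coords[self.bond_i] - coords[self.bond_j], axis=1)
            terms["backbone"] = float(np.sum(model.backbone_k * (d - self.bond_r0) ** 2))
        else:
            terms["backbone"] = 0.0
        if len(self.fb_index):
            d = np.linalg.norm(coords[self.fb_index] - self.fb_ref, axis=1)
            excess = np.maximum(0.0, d - self.fb_radius)
            terms["restraint"] = float(np.sum(self.fb_k * excess * excess))
        else:
            terms["restraint"] = 0.0
        terms["total"] = terms["coulomb"] + terms["lj"] + terms["backbone"] + terms["restraint"]
        return terms

    def energy(self, coords: np.ndarray) -> float:
        """Total energy (fused fast path; identical value to energy_terms)."""
        model = self.model
        e = 0.0
        if len(self.lj_i):
            diff = coords[self.lj_i] - coords[self.lj_j]
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            sr6 = (model.lj_sigma / d) ** 6
            e += float(np.sum(4.0 * model.lj_epsilon * (sr6 * sr6 - sr6))
                       + np.sum(self.pair_kq / (model.dielectric(d) * d)))
        if len(self.bond_i):
            diff = coords[self.bond_i] - coords[self.bond_j]
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            e += float(np.sum(model.backbone_k * (d - self.bond_r0) ** 2))
        if len(self.fb_index):
            d = np.linalg.norm(coords[self.fb_index] - self.fb_ref, axis=1)
            excess = np.maximum(0.0, d - self.fb_radius)
            e += float(np.sum(self.fb_k * excess * excess))
        return e


def total_energy(
    structure: Structure,
    model: EnergyModel | None = None,
    restraints: Sequence[FlatBottomRestraint | PlaneConstraint] = (),
) -> dict[str, float]:
    """Per-term surrogate energy breakdown (coulomb, lj, backbone, restraint, total)."""
    model = model or EnergyModel()
    system = EnergySystem(structure, model, restraints)
    terms = system.energy_terms(structure.coords)
    if not math.isfinite(terms["total"]):
        raise ArithmeticError(_diagnose_nonfinite(system, structure.coords))
    return terms


def _diagnose_nonfinite(system: EnergySystem, coords: np.ndarray) -> str:
    for i, j in zip(system.lj_i, system.lj_j):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < 1e-9 or not math.isfinite(d):
            a, b = system.structure.atoms[i], system.structure.atoms[j]
            return (f"non-finite energy: atom pair {a.key} / {b.key} at distance {d:.3g} A")
    return "non-finite energy encountered"


# ---------------------------------------------------------------------------
# Monte-Carlo minimization
# ---------------------------------------------------------------------------

def _rigid_group_indices(structure: Structure, helix: str) -> np.ndarray:
    chain, lo, hi = structure.annotations[helix]
    return np.array([i for i, a in enumerate(structure.atoms)
                     if a.chain == chain and lo <= a.residue_index <= hi], dtype=int)


def _rotate_in_plane(coords: np.ndarray, idx: np.ndarray, angle_deg: float) -> None:
    """Rotate a group about the vertical axis through its centroid (z preserved)."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    center = coords[idx, :2].mean(axis=0)
    xy = coords[idx, :2] - center
    coords[idx, 0] = c * xy[:, 0] - s * xy[:, 1] + center[0]
    coords[idx, 1] = s * xy[:, 0] + c * xy[:, 1] + center[1]


def _coordinate_descent(system: EnergySystem, coords: np.ndarray,
                        rigid_idx: np.ndarray | None,
                        site_idx: np.ndarray, config: MCConfig) -> float:
    """Greedy per-DOF line search with step halving; returns the final energy."""
    energy = system.energy(coords)
    step = config.descent_step
    axes = np.eye(3)
    if rigid_idx is not None and len(rigid_idx):
        # Deterministic coarse rotation scan: pick the best rotational basin
        # before local refinement (seed-independent handoff between contacts).
        e_cross = system.cross_energy(coords)
        best_angle, best_gain = 0.0, 0.0
        backup = coords[rigid_idx].copy()
        for angle in range(30, 360, 30):
            _rotate_in_plane(coords, rigid_idx, 30.0)
            gain = system.cross_energy(coords) - e_cross
            if gain < best_gain - 1e-12:
                best_angle, best_gain = float(angle), gain
        coords[rigid_idx] = backup
        if best_angle:
            _rotate_in_plane(coords, rigid_idx, best_angle)
            energy += best_gain
    for _ in range(config.descent_iters):
        improved = False
        if rigid_idx is not None and len(rigid_idx):
            # Rigid in-plane moves change only boundary-crossing pairs.
            e_cross = system.cross_energy(coords)
            for axis in (0, 1):
                for sign in (1.0, -1.0):
                    coords[rigid_idx, axis] += sign * step
                    trial = system.cross_energy(coords)
                    if trial < e_cross - 1e-12:
                        energy += trial - e_cross
                        e_cross = trial
                        improved = True
                    else:
                        coords[rigid_idx, axis] -= sign * step
            for sign in (1.0, -1.0):
                backup = coords[rigid_idx].copy()
                _rotate_in_plane(coords, rigid_idx, sign * step * 4.0)
                trial = system.cross_energy(coords)
                if trial < e_cross - 1e-12:
                    energy += trial - e_cross
                    e_cross = trial
                    improved = True
                else:
                    coords[rigid_idx] = backup
        for i in site_idx:
            # Single-atom moves use incremental pair energies (cheap).
            e_here = system.atom_energy(coords, i, coords[i])
            for axis in range(3):
                for sign in (1.0, -1.0):
                    trial_pos = coords[i] + sign * step * axes[axis]
                    e_trial = system.atom_energy(coords, i, trial_pos)
                    if e_trial < e_here - 1e-12:
                        energy += e_trial - e_here
                        coords[i] = trial_pos
                        e_here = e_trial
                        improved = True
        if not improved:
            step *= 0.5
            if step < 1e-3:
                break
    # Guard against accumulated float drift in the incremental updates.
    return system.energy(coords)


def mc_minimize(
    structure: Structure,
    model: EnergyModel | None = None,
    restraints: Sequence[FlatBottomRestraint | PlaneConstraint] = (),
    config: MCConfig | None = None,
) -> tuple[Structure, dict[str, float]]:
    """Monte-Carlo energy minimization under plane constraints and restraints.

    Random seeded moves (rigid in-plane shift/rotation of ``config.rigid_helix``
    if set, plus jitter of every charged site) are each refined by coordinate
    descent and accepted by a Metropolis test at ``config.temperature``.  The
    run stops after ``termination_window`` consecutive candidates fail to
    improve the best energy, or at ``max_moves``.  Returns the best structure
    and its energy terms; the returned energy never exceeds the input energy.
    """
    model = model or EnergyModel()
    config = config or MCConfig()
    system = EnergySystem(structure, model, restraints)
    coords = structure.coords
    system.project_planes(coords)

    rigid_idx = (_rigid_group_indices(structure, config.rigid_helix)
                 if config.rigid_helix else None)
    if rigid_idx is not None and len(rigid_idx):
        system.set_rigid_group(rigid_idx)
    site_idx = np.flatnonzero(system.is_site)
    rng = np.random.default_rng(config.seed)
    kt = KCAL_PER_MOL_K * max(config.temperature, 1e-9)

    current = coords.copy()
    current_e = _coordinate_descent(system, current, rigid_idx, site_idx, config)
    if not math.isfinite(current_e):
        raise ArithmeticError(_diagnose_nonfinite(system, current))
    best = current.copy()
    best_e = current_e
    input_terms = system.energy_terms(coords)
    if input_terms["total"] < best_e:  # descent should only improve, but be safe
        best, best_e = coords.copy(), input_terms["total"]

    stall = 0
    for _ in range(config.max_moves):
        candidate = current.copy()
        if rigid_idx is not None and len(rigid_idx):
            dx, dy = rng.normal(0.0, config.rigid_shift, size=2)
            candidate[rigid_idx, 0] += dx
            candidate[rigid_idx, 1] += dy
            # Move mixture: mostly small rotations, occasionally a large one
            # so contact handoffs between rotational basins stay reachable.
            if rng.random() < config.big_rot_prob:
                angle = rng.uniform(-180.0, 180.0)
            else:
                angle = rng.normal(0.0, config.rigid_rot)
            _rotate_in_plane(candidate, rigid_idx, angle)
        if len(site_idx):
            jitter = rng.normal(size=(len(site_idx), 3))
            norms = np.linalg.norm(jitter, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            radii = rng.uniform(0.0, config.site_jitter, size=(len(site_idx), 1))
            candidate[site_idx] += jitter / norms * radii
        cand_e = _coordinate_descent(system, candidate, rigid_idx, site_idx, config)
        if not math.isfinite(cand_e):
            raise ArithmeticError(_diagnose_nonfinite(system, candidate))
        if cand_e < best_e - 1e-9:
            best, best_e = candidate.copy(), cand_e
            stall = 0
        else:
            stall += 1
        delta = cand_e - current_e
        if delta <= 0 or rng.random() < math.exp(-delta / kt):
            current, current_e = candidate, cand_e
        if stall >= config.termination_window:
            break

    system.project_planes(best)
    out = structure.copy()
    out.set_coords(best)
    return out, system.energy_terms(best)


# ---------------------------------------------------------------------------
# Stepped S4 deactivation driver
# ---------------------------------------------------------------------------

def deactivate_s4(
    structure: Structure,
    s4_basic_ca: Sequence[AtomId] | None = None,
    n_steps: int = 21,
    step_size: float = 0.5,
    model: EnergyModel | None = None,
    config: MCConfig | None = None,
) -> Trajectory:
    """Drive the S4 helix down in ``n_steps`` increments of ``step_size`` A.

    The four S4 basic-residue CA atoms are plane-constrained to a cumulative
    target ``-step_size * i`` below their start at step i and the structure is
    MC-minimized at every step.  All S1-S3 CA atoms carry flat-bottom
    restraints (free radius 4 A, k 10) to their step-0 positions throughout.
    Step 0 records the minimized undisplaced state; the downshifted minimized
    states are steps 1..n_steps.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if step_size <= 0:
        raise ValueError(f"step_size must be positive, got {step_size}")
    model = model or EnergyModel()
    config = config or MCConfig()
    if config.rigid_helix is None:
        config = replace(config, rigid_helix="S4")
    s4 = config.rigid_helix
    if s4 not in structure.annotations:
        raise ValueError(f"structure lacks an annotated {s4} helix")
    if s4_basic_ca is None:
        chain, lo, hi = structure.annotations[s4]
        s4_basic_ca = [(a.chain, a.residue_index, "CA") for a in structure.atoms
                       if a.chain == chain and lo <= a.residue_index <= hi
                       and a.name == "CA" and a.residue_name in ("ARG", "LYS", "GLU")]
    s4_basic_ca = list(s4_basic_ca)
    if len(s4_basic_ca) != 4:
        raise ValueError(f"expected 4 S4 basic-residue CA atoms, got {len(s4_basic_ca)}")
    chain, lo, hi = structure.annotations[s4]
    for cid, resi, name in s4_basic_ca:
        if cid != chain or not (lo <= resi <= hi) or name != "CA":
            raise ValueError(f"atom ({cid}, {resi}, {name}) is not a CA on helix {s4}")

    work = structure.copy()
    start_z = {aid: work.atom(*aid).xyz[2] for aid in s4_basic_ca}
    # z targets of the 4 constrained CA atoms differ by their helical spacing,
    # so one PlaneConstraint per atom.
    restraints: list[FlatBottomRestraint | PlaneConstraint] = []
    for helix_id in structure.annotations:
        if helix_id == s4:
            continue
        for idx in structure.helix_atom_indices(helix_id, "CA"):
            a = structure.atoms[idx]
            restraints.append(FlatBottomRestraint(
                (a.chain, a.residue_index, a.name), a.xyz.copy()))

    s4_indices = _rigid_group_indices(work, s4)
    steps: list[TrajectoryStep] = []
    for i in range(n_steps + 1):
        if i > 0:
            coords = work.coords
            coords[s4_indices, 2] -= step_size
            work.set_coords(coords)
        planes = [PlaneConstraint((aid,), start_z[aid] - step_size * i)
                  for aid in s4_basic_ca]
        step_config = replace(config, seed=int(config.seed) + i)
        work, terms = mc_minimize(work, model, restraints + planes, step_config)
        steps.append(TrajectoryStep(index=i, z_offset=-step_size * i,
                                    structure=work.copy(), energy_terms=terms))
    provenance = {
        "model": {
            "coulomb_constant": model.coulomb_constant,
            "lj_sigma": model.lj_sigma,
            "lj_epsilon": model.lj_epsilon,
            "backbone_k": model.backbone_k,
            "charges": dict(model.charges),
        },
        "config": {k: v for k, v in vars(config).items() if not callable(v)},
        "n_steps": n_steps,
        "step_size": step_size,
        "s4_basic_ca": [list(a) for a in s4_basic_ca],
    }
    return Trajectory(steps, provenance)
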