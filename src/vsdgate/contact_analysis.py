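"""Ionizable-pair contacts, bridge-distance series, and S4 rotation direction.

Distances are measured between one representative charged atom per
ionizable residue (Arg CZ, Lys NZ, Glu CD, Asp CG) — the same convention
for full-atom and toy structures.  Rotation is the azimuth of a marker CA
about the per-step S4 principal axis, positive anticlockwise when viewed
from the extracellular (+z) side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .steered_deactivation import Trajectory
from .structures_io import RESIDUE_CHARGE, SITE_ATOM_NAME, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ChargedSite",
    "ContactRecord",
    "RotationSeries",
    "charged_sites",
    "salt_bridges",
    "bridge_distance_series",
    "s4_rotation_series",
    "pair_coulomb_energy",
]

ResidueId = tuple[str, int]


@dataclass(frozen=True)
class ChargedSite:
    """One ionizable residue's representative charged atom."""

    chain: str
    residue_index: int
    residue_name: str
    site_atom: str
    charge: float
    xyz: tuple[float, float, float]

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.residue_index)


@dataclass(frozen=True)
class ContactRecord:
    """A close ionizable pair; symmetric under swap of the two sites."""

    site_a: ChargedSite
    site_b: ChargedSite
    distance: float
    kind: str  # "salt_bridge" | "repulsive_pair"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class RotationSeries:
    """Unwrapped per-step azimuth of a marker residue about the S4 axis, degrees."""

    angles: np.ndarray
    marker: ResidueId

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if abs(self.angles[0]) > 1e-9:
            raise ValueError("rotation series must start at 0 degrees")


def charged_sites(structure: Structure) -> list[ChargedSite]:
    """One site per Arg/Lys/Glu/Asp carrying its representative atom."""
    seen: set[ResidueId] = set()
    sites: list[ChargedSite] = []
    for atom in structure.atoms:
        if atom.residue_name not in SITE_ATOM_NAME:
            continue
        rid = (atom.chain, atom.residue_index)
        if rid in seen:
            continue
        site_name = SITE_ATOM_NAME[atom.residue_name]
        try:
            site_atom = structure.atom(atom.chain, atom.residue_index, site_name)
        except KeyError:
            logger.warning("ionizable residue %s %s%d lacks site atom %s; skipped",
                           atom.residue_name, atom.chain, atom.residue_index, site_name)
            seen.add(rid)
            continue
        seen.add(rid)
        sites.append(ChargedSite(
            chain=atom.chain,
            residue_index=atom.residue_index,
            residue_name=atom.residue_name,
            site_atom=site_name,
            charge=RESIDUE_CHARGE[atom.residue_name],
            xyz=tuple(float(v) for v in site_atom.xyz),
        ))
    return sites


def salt_bridges(structure: Structure, cutoff: float = 4.5) -> list[ContactRecord]:
    """All ionizable pairs within ``cutoff``: opposite charges are salt bridges,
    like charges repulsive pairs.  Sorted by distance."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    sites = charged_sites(structure)
    records: list[ContactRecord] = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            d = float(np.linalg.norm(np.array(a.xyz) - np.array(b.xyz)))
            if d <= cutoff:
                kind = "salt_bridge" if a.charge * b.charge < 0 else "repulsive_pair"
                records.append(ContactRecord(a, b, d, kind))
    records.sort(key=lambda r: r.distance)
    return records


def _site_xyz(structure: Structure, residue: ResidueId) -> np.ndarray:
    chain, resi = residue
    res_name = next((a.residue_name for a in structure.atoms
                     if a.chain == chain and a.residue_index == resi), None)
    if res_name is None:
        raise KeyError(f"residue {residue} not found")
    if res_name not in SITE_ATOM_NAME:
        raise KeyError(f"residue {residue} ({res_name}) is not ionizable")
    return structure.atom(chain, resi, SITE_ATOM_NAME[res_name]).xyz


def bridge_distance_series(trajectory: Trajectory,
                           pair: tuple[ResidueId, ResidueId]) -> np.ndarray:
    """Charged-site distance of one residue pair at every trajectory step, A."""
    distances = []
    for step in trajectory.steps:
        try:
            a = _site_xyz(step.structure, pair[0])
            b = _site_xyz(step.structure, pair[1])
        except KeyError as exc:
            raise KeyError(f"step {step.index}: {exc}") from exc
        distances.append(float(np.linalg.norm(a - b)))
    return np.array(distances)


def pair_coulomb_energy(structure: Structure, pair: tuple[ResidueId, ResidueId],
                        coulomb_constant: float = 332.06) -> float:
    """Coulomb term of one charged-site pair with the eps(r) = r dielectric."""
    a = _site_xyz(structure, pair[0])
    b = _site_xyz(structure, pair[1])
    qa = next(RESIDUE_CHARGE[x.residue_name] for x in structure.atoms
              if (x.chain, x.residue_index) == tuple(pair[0]))
    qb = next(RESIDUE_CHARGE[x.residue_name] for x in structure.atoms
              if (x.chain, x.residue_index) == tuple(pair[1]))
    r = float(np.linalg.norm(a - b))
    return coulomb_constant * qa * qb / (r * r)


def _s4_axis(structure: Structure, helix: str = "S4") -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of the S4 CA set, oriented toward +z; returns (centroid, axis)."""
    idx = structure.helix_atom_indices(helix, "CA")
    if len(idx) < 4:
        raise ValueError(f"helix {helix} has fewer than 4 CA atoms; axis degenerate")
    coords = structure.coords[idx]
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return centroid, axis


def s4_rotation_series(trajectory: Trajectory, marker_residue: ResidueId,
                       helix: str = "S4") -> RotationSeries:
    """Azimuth of the marker CA about the per-step S4 axis, relative to step 0.

    Angles are unwrapped (no +-180 deg jumps); positive values are
    anticlockwise when viewed from the extracellular (+z) side.
    """
    chain, resi = marker_residue
    first = trajectory.steps[0].structure
    if first.helix_of(chain, resi) != helix:
        raise ValueError(f"marker residue {marker_residue} is not on helix {helix}")
    raw = []
    for step in trajectory.steps:
        structure = step.structure
        centroid, axis = _s4_axis(structure, helix)
        e1 = np.array([1.0, 0.0, 0.0])
        e1 = e1 - np.dot(e1, axis) * axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        v = structure.atom(chain, resi, "CA").xyz - centroid
        v = v - np.dot(v, axis) * axis
        raw.append(np.arctan2(np.dot(v, e2), np.dot(v, e1)))
    unwrapped = np.degrees(np.unwrap(np.array(raw)))
    return RotationSeries(unwrapped - unwrapped[0], marker_residue)
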