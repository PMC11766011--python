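"""PDB reading/writing, toy voltage-sensor construction, and Kabsch superposition.

The in-memory model is a flat, ordered atom list plus helix annotations
(helix id -> (chain, first residue, last residue)).  Only fixed-column
ATOM/HETATM/HELIX/MODEL records are interpreted; insertion codes and
alternate locations are ignored with a warning.  Multi-model files are the
trajectory interchange format and parse to a list of structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "HelixBuildSpec",
    "Superposition",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "build_toy_vsd",
    "default_toy_specs",
    "toy_vsd",
    "superpose",
    "SITE_ATOM_NAME",
    "SITE_OFFSET",
    "RESIDUE_CHARGE",
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
    "HELIX_CA_RADIUS",
]

# Ideal alpha-helix CA geometry used by the toy builder.
HELIX_RISE = 1.5          # Angstrom per residue along the axis
HELIX_TWIST_DEG = 100.0   # degrees per residue
HELIX_CA_RADIUS = 2.3     # CA distance from the helix axis, Angstrom

# One representative charged interaction site per ionizable side chain.
# Atom names follow the full-atom convention so toy and real structures
# are interrogated identically by the contact layer.
SITE_ATOM_NAME = {"ARG": "CZ", "LYS": "NZ", "GLU": "CD", "ASP": "CG"}
# Site distance from CA along the outward radial vector, Angstrom.
SITE_OFFSET = {"ARG": 4.1, "LYS": 3.9, "GLU": 3.1, "ASP": 2.5}
RESIDUE_CHARGE = {"ARG": +1.0, "LYS": +1.0, "GLU": -1.0, "ASP": -1.0}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class PDBFormatError(ValueError):
    """Raised when a fixed-column PDB record cannot be parsed."""


@dataclass
class Atom:
    """A single atom: label, residue identity, chain, and coordinates in Angstrom."""

    name: str
    residue_name: str
    residue_index: int
    chain: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"xyz must be a 3-vector, got shape {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.key}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_index, self.name)

    def copy(self) -> "Atom":
        return Atom(self.name, self.residue_name, self.residue_index, self.chain,
                    self.xyz.copy())


@dataclass
class Structure:
    """Ordered atom collection with helix annotations.

    ``annotations`` maps a helix id (e.g. ``"S4"``) to
    ``(chain, first_residue_index, last_residue_index)``.
    """

    atoms: list[Atom] = field(default_factory=list)
    annotations: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise ValueError(f"duplicate atom {atom.key}")
            seen.add(atom.key)
        for helix, (chain, lo, hi) in self.annotations.items():
            if hi - lo + 1 < 4:
                raise ValueError(f"helix {helix} spans fewer than 4 residues")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.xyz = xyz.copy()

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], dict(self.annotations))

    def index_of(self, chain: str, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.residue_index == residue_index and a.name == name:
                return i
        raise KeyError(f"atom ({chain}, {residue_index}, {name}) not found")

    def atom(self, chain: str, residue_index: int, name: str) -> Atom:
        return self.atoms[self.index_of(chain, residue_index, name)]

    def helix_of(self, chain: str, residue_index: int) -> str | None:
        for helix, (ch, lo, hi) in self.annotations.items():
            if ch == chain and lo <= residue_index <= hi:
                return helix
        return None

    def helix_atom_indices(self, helix: str, name: str | None = "CA") -> list[int]:
        """Indices of atoms on an annotated helix, optionally filtered by atom name."""
        chain, lo, hi = self.annotations[helix]
        return [i for i, a in enumerate(self.atoms)
                if a.chain == chain and lo <= a.residue_index <= hi
                and (name is None or a.name == name)]


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column dialect)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        res_index = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable ATOM record: {exc}") from exc
    if altloc or icode:
        logger.warning("line %d: altloc/insertion code ignored", lineno)
    return Atom(name, res_name, res_index, chain, np.array([x, y, z]))


def _parse_helix_line(line: str, lineno: int) -> tuple[str, tuple[str, int, int]]:
    try:
        helix_id = line[11:14].strip()
        chain = line[19:20].strip() or "A"
        lo = int(line[21:25])
        hi = int(line[33:37])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable HELIX record: {exc}") from exc
    return helix_id, (chain, lo, hi)


def read_pdb(path: str | Path) -> Structure | list[Structure]:
    """Parse a fixed-column PDB file.

    Returns a single :class:`Structure`, or a list of structures when the
    file contains MODEL records (the multi-model trajectory dialect).
    HELIX records are read into the annotation table of every model.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBFormatError(f"{path}: empty PDB file")
    annotations: dict[str, tuple[str, int, int]] = {}
    models: list[list[Atom]] = []
    current: list[Atom] = []
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif record == "HELIX":
            helix_id, span = _parse_helix_line(line, lineno)
            annotations[helix_id] = span
        elif record == "MODEL":
            saw_model = True
            if current:
                models.append(current)
                current = []
        elif record == "ENDMDL":
            models.append(current)
            current = []
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBFormatError(f"{path}: no ATOM records found")
    structures = [Structure(atoms, dict(annotations)) for atoms in models]
    if saw_model:
        return structures
    return structures[0]


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    element = atom.name[:1].strip()
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{atom.chain:1.1s}{atom.residue_index:4d}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2.2s}"
    )


def _helix_lines(structure: Structure) -> list[str]:
    lines = []
    for n, (helix_id, (chain, lo, hi)) in enumerate(sorted(structure.annotations.items()), 1):
        res_lo = next((a.residue_name for a in structure.atoms
                       if a.chain == chain and a.residue_index == lo), "ALA")
        res_hi = next((a.residue_name for a in structure.atoms
                       if a.chain == chain and a.residue_index == hi), "ALA")
        lines.append(
            f"HELIX  {n:3d} {helix_id:>3.3s} {res_lo:<3.3s} {chain:1.1s} {lo:4d}  "
            f"{res_hi:<3.3s} {chain:1.1s} {hi:4d}  1{'':30s} {hi - lo + 1:5d}"
        )
    return lines


def write_pdb(structure: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one structure, or a sequence of structures as MODEL/ENDMDL blocks."""
    path = Path(path)
    if isinstance(structure, Structure):
        if not structure.atoms:
            raise ValueError("refusing to write an empty structure")
        lines = _helix_lines(structure)
        lines += [_format_atom_line(a, i + 1) for i, a in enumerate(structure.atoms)]
        lines.append("END")
    else:
        structures = list(structure)
        if not structures or any(not s.atoms for s in structures):
            raise ValueError("refusing to write an empty structure")
        lines = _helix_lines(structures[0])
        for m, s in enumerate(structures, start=1):
            lines.append(f"MODEL     {m:4d}")
            lines += [_format_atom_line(a, i + 1) for i, a in enumerate(s.atoms)]
            lines.append("ENDMDL")
        lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Toy voltage-sensor builder
# ---------------------------------------------------------------------------

@dataclass
class HelixBuildSpec:
    """Recipe for one ideal helix of the toy voltage-sensor bundle."""

    helix_id: str
    sequence: str
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    phase: float = 0.0        # degrees, azimuth of the first CA around the axis
    chain: str = "A"
    first_residue_index: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if not math.isclose(norm, 1.0, abs_tol=1e-6):
            raise ValueError("axis_direction must be a unit vector")


def _helix_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane normal to the helix axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def build_toy_vsd(
    specs: Sequence[HelixBuildSpec],
    charged_positions: Mapping[str, Iterable[tuple[int, str]]] | None = None,
) -> Structure:
    """Build a four-helix toy voltage-sensor domain of ideal alpha-helices.

    Each helix is a CA trace (rise 1.5 A/residue, 100 deg/residue, radius
    2.3 A).  Ionizable residues additionally get a single charged pseudo-site
    placed along the outward radial vector of their CA, at the per-type
    offset in :data:`SITE_OFFSET`, named per :data:`SITE_ATOM_NAME`.

    ``charged_positions`` optionally overrides residue identities,
    mapping helix id to ``(residue_index, residue_name)`` pairs.

    The S4 helix must carry four basic residues spaced i, i+3, i+6, i+9
    (R1, R2, R3, K4 pattern: the last may be Arg or Lys).
    """
    if len(specs) != 4:
        raise ValueError(f"expected exactly 4 helix specs (S1-S4), got {len(specs)}")
    overrides = {h: dict(pairs) for h, pairs in (charged_positions or {}).items()}

    atoms: list[Atom] = []
    annotations: dict[str, tuple[str, int, int]] = {}
    for spec in specs:
        e1, e2 = _helix_frame(spec.axis_direction)
        n = len(spec.sequence)
        lo = spec.first_residue_index
        annotations[spec.helix_id] = (spec.chain, lo, lo + n - 1)
        for j, letter in enumerate(spec.sequence):
            res_index = lo + j
            res_name = ONE_TO_THREE.get(letter.upper(), "ALA")
            res_name = overrides.get(spec.helix_id, {}).get(res_index, res_name)
            angle = math.radians(spec.phase + HELIX_TWIST_DEG * j)
            radial = math.cos(angle) * e1 + math.sin(angle) * e2
            ca = (spec.axis_origin + HELIX_RISE * j * spec.axis_direction
                  + HELIX_CA_RADIUS * radial)
            atoms.append(Atom("CA", res_name, res_index, spec.chain, ca))
            if res_name in SITE_ATOM_NAME:
                site = ca + SITE_OFFSET[res_name] * radial
                atoms.append(Atom(SITE_ATOM_NAME[res_name], res_name, res_index,
                                  spec.chain, site))

    structure = Structure(atoms, annotations)
    _validate_s4_basics(structure)
    return structure


def _validate_s4_basics(structure: Structure) -> None:
    if "S4" not in structure.annotations:
        raise ValueError("toy VSD requires an annotated S4 helix")
    chain, lo, hi = structure.annotations["S4"]
    # Charge-reversal variants substitute a basic slot with Glu/Asp, so the
    # spacing pattern is checked over all charged S4 residues.
    charged = sorted(a.residue_index for a in structure.atoms
                     if a.chain == chain and lo <= a.residue_index <= hi
                     and a.name == "CA" and a.residue_name in RESIDUE_CHARGE)
    ok = any({i, i + 3, i + 6, i + 9} <= set(charged) for i in charged)
    if not ok:
        raise ValueError(
            "S4 must carry 4 charged residues at spacing i, i+3, i+6, i+9 "
            f"(R1, R2, R3, K4 slots); found charged residues at {charged}"
        )


# Default toy geometry: four vertical helices on a 12 A square, membrane
# normal = z, extracellular side = +z.  S4 starts two helical turns
# (10.5 A at 0.5 A steps x 21) above its resting depth so that the full
# downshift brings R1 level with the S2 glutamate E1.
_S4_UPSHIFT = 10.5
_HELIX_LEN = 18
_TOP_Z = 12.75  # z of the first (uppermost) residue of S1-S3


def default_toy_specs(r1_residue: str = "ARG") -> tuple[list[HelixBuildSpec], dict]:
    """Helix specs and charge map for the default WT-like toy VSD.

    ``r1_residue`` substitutes the uppermost S4 basic residue (R1), e.g.
    ``"GLU"`` builds the charge-reversal variant with identical geometry.
    """
    plain = "A" * _HELIX_LEN
    down = np.array([0.0, 0.0, -1.0])
    specs = [
        HelixBuildSpec("S1", plain, np.array([12.0, 12.0, _TOP_Z]), down,
                       phase=0.0, first_residue_index=1),
        HelixBuildSpec("S2", plain, np.array([12.0, 0.0, _TOP_Z]), down,
                       phase=-20.0, first_residue_index=21),
        HelixBuildSpec("S3", plain, np.array([0.0, 12.0, _TOP_Z]), down,
                       phase=0.0, first_residue_index=41),
        HelixBuildSpec("S4", plain, np.array([0.0, 0.0, _TOP_Z + _S4_UPSHIFT]), down,
                       phase=160.0, first_residue_index=61),
    ]
    charged = {
        # E1 near the extracellular end of S2, site facing the S4 axis.
        "S2": [(23, "GLU")],
        # R1, R2, R3, K4 at i, i+3, i+6, i+9 on S4.
        "S4": [(63, r1_residue), (66, "ARG"), (69, "ARG"), (72, "LYS")],
    }
    return specs, charged


def toy_vsd(variant: str = "WT") -> Structure:
    """Convenience builder: ``"WT"`` or the R1->Glu charge reversal ``"R1E"``."""
    if variant.upper() in ("WT", "WILDTYPE"):
        specs, charged = default_toy_specs("ARG")
    elif variant.upper() in ("R1E", "R219E"):
        specs, charged = default_toy_specs("GLU")
    else:
        raise ValueError(f"unknown toy variant {variant!r}")
    return build_toy_vsd(specs, charged)


# Identifiers of the four S4 basic-residue CA atoms in the default toy VSD.
TOY_S4_BASIC_CA = [("A", 63, "CA"), ("A", 66, "CA"), ("A", 69, "CA"), ("A", 72, "CA")]
TOY_R1 = ("A", 63)
TOY_E1 = ("A", 23)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    """Rigid transform mapping mobile onto reference: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (det < 0)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]] | None = None,
) -> Superposition:
    """Least-squares rigid superposition (Kabsch) of paired CA anchors.

    ``selection`` pairs (mobile atom id, reference atom id); when omitted,
    CA atoms are matched by (chain, residue_index).  At least three
    non-collinear pairs are required; a proper rotation is enforced.
    """
    if selection is None:
        ref_keys = {(a.chain, a.residue_index): a for a in reference.atoms if a.name == "CA"}
        pairs = [(a.xyz, ref_keys[(a.chain, a.residue_index)].xyz)
                 for a in mobile.atoms
                 if a.name == "CA" and (a.chain, a.residue_index) in ref_keys]
    else:
        pairs = [(mobile.atom(*mid).xyz, reference.atom(*rid).xyz)
                 for mid, rid in selection]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired atoms for superposition, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection for superposition")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = yc - rotation @ xc
    moved = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return Superposition(rotation, translation, rmsd)
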