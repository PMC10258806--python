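"""Trajectory/topology containers, file I/O, and periodic-geometry primitives.

Everything downstream (pair statistics, shell tracking, spectra, surface areas)
operates on the two containers defined here: :class:`Topology` carries static
atom identities and roles, :class:`Trajectory` carries frame-major Cartesian
coordinates in Å with an optional cubic periodic box.

Conventions: 0-based atom indexing, half-open ``[lo, hi)`` bins everywhere, and
the minimum-image boundary at exactly +box/2 resolves to the negative image.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import BONDI_VDW_RADII

# Canonical atom roles.
ROLES = (
    "metal",
    "ring_N",
    "ring_C_alpha",
    "ring_C_beta",
    "ring_C_meso",
    "ring_H",
    "water_O",
    "water_H",
    "other",
)

RING_HEAVY_ROLES = ("metal", "ring_N", "ring_C_alpha", "ring_C_beta", "ring_C_meso")
SOLUTE_ROLES = RING_HEAVY_ROLES + ("ring_H",)


class MalformedTrajectoryError(ValueError):
    """Raised for structurally inconsistent or unparseable trajectory files."""


class RoleAssignmentError(ValueError):
    """Raised when atom roles cannot satisfy the macrocycle invariants."""


@dataclass
class Topology:
    """Static description of the atoms in a system.

    Attributes
    ----------
    elements : list of str
        Chemical symbols, one per atom.
    names : list of str
        Atom names (PDB-style, or synthetic labels for generated systems).
    roles : list of str
        One of :data:`ROLES` per atom.
    vdw_radius : ndarray or None
        Per-atom van der Waals radii in Å (``nan`` where unknown).
    polarity : list of str or None
        ``"hydrophobic"`` / ``"hydrophilic"`` per atom, for SASA decomposition.
    torsion_quadruples : dict
        ``{"proper": [...], "improper": [...]}`` lists of 4-tuples of atom ids.
    water_parent : dict
        Maps each ``water_H`` index to its parent ``water_O`` index.
    positions : ndarray or None
        Single-frame reference coordinates in Å, when the source format has them.
    resnames, resids : optional per-atom residue metadata from PDB input.
    """

    elements: list
    names: list
    roles: list
    vdw_radius: np.ndarray | None = None
    polarity: list | None = None
    torsion_quadruples: dict = field(default_factory=lambda: {"proper": [], "improper": []})
    water_parent: dict = field(default_factory=dict)
    positions: np.ndarray | None = None
    resnames: list | None = None
    resids: list | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def indices_with_role(self, role) -> np.ndarray:
        """Atom indices whose role is ``role`` (a string or iterable of strings)."""
        if isinstance(role, str):
            role = (role,)
        wanted = set(role)
        return np.array([i for i, r in enumerate(self.roles) if r in wanted], dtype=int)

    @property
    def metal_index(self) -> int:
        idx = self.indices_with_role("metal")
        if len(idx) != 1:
            raise RoleAssignmentError(f"expected exactly 1 metal atom, found {len(idx)}")
        return int(idx[0])

    @property
    def ring_n_indices(self) -> np.ndarray:
        return self.indices_with_role("ring_N")

    def validate_macrocycle(self) -> None:
        """Enforce the metalloporphyrin invariants (1 metal, 4 ring N, H parents)."""
        n_metal = len(self.indices_with_role("metal"))
        n_ring_n = len(self.ring_n_indices)
        if n_metal != 1:
            raise RoleAssignmentError(f"macrocycle requires exactly 1 metal atom, found {n_metal}")
        if n_ring_n != 4:
            raise RoleAssignmentError(
                f"macrocycle requires exactly 4 ring_N atoms, found {n_ring_n}"
            )
        for i, r in enumerate(self.roles):
            if r == "water_H" and i not in self.water_parent:
                raise RoleAssignmentError(f"water_H atom {i} has no parent water_O")
        if self.vdw_radius is not None:
            radii = np.asarray(self.vdw_radius, dtype=float)
            bad = np.where(~np.isnan(radii) & (radii <= 0))[0]
            if bad.size:
                raise RoleAssignmentError(f"non-positive vdW radius for atom {bad[0]}")


@dataclass
class Trajectory:
    """Frame-major Cartesian trajectory.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)`` in Å; ``velocities``
    (optional) the same shape in Å/ps; ``dt`` is the time between stored frames
    in ps; ``box_length`` the cubic periodic box edge in Å, or ``None`` for a
    non-periodic system.
    """

    coordinates: np.ndarray
    dt: float
    box_length: float | None = None
    velocities: np.ndarray | None = None
    elements: list | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.box_length is not None and self.box_length <= 0:
            raise ValueError("box_length must be positive when given")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError("velocities must match coordinates in shape")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def minimum_image_displacement(a, b, box_length):
    """Displacement ``b − a`` mapped to the nearest periodic image.

    Each component of the result lies in ``[−box/2, +box/2)``; a displacement of
    exactly +box/2 resolves to −box/2 (deterministic tie-break). With
    ``box_length=None`` the plain displacement is returned. Broadcasts over
    leading dimensions.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box_length is None:
        return d
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    return d - box_length * np.floor(d / box_length + 0.5)


def minimum_image_distance(a, b, box_length):
    """Euclidean length of the minimum-image displacement (broadcasts)."""
    d = minimum_image_displacement(a, b, box_length)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coordinates(traj: Trajectory) -> Trajectory:
    """Return a copy with every coordinate wrapped into [−box/2, box/2)."""
    if traj.box_length is None:
        return replace(traj, coordinates=traj.coordinates.copy())
    wrapped = minimum_image_displacement(0.0, traj.coordinates, traj.box_length)
    return replace(traj, coordinates=wrapped)


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path, dt, box_length=None) -> Trajectory:
    """Read a multi-frame XYZ file (count line, comment, ``element x y z`` rows).

    Raises :class:`MalformedTrajectoryError` if frames disagree on the atom
    count or a coordinate fails to parse (the message carries the line number).
    """
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    frame_no = 0
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise MalformedTrajectoryError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i].strip()!r}"
            )
        if i + 1 + n_atoms >= n_lines + 1:
            raise MalformedTrajectoryError(
                f"{path}: frame {frame_no} truncated (expected {n_atoms} atom records)"
            )
        frame_elems = []
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise MalformedTrajectoryError(
                    f"{path}: line {ln + 1}: expected 'element x y z', got {lines[ln].rstrip()!r}"
                )
            frame_elems.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise MalformedTrajectoryError(
                    f"{path}: line {ln + 1}: non-numeric coordinate in {lines[ln].rstrip()!r}"
                )
        if elements is None:
            elements = frame_elems
        elif len(frame_elems) != len(elements):
            raise MalformedTrajectoryError(
                f"{path}: frame {frame_no} has {len(frame_elems)} atoms, frame 0 has {len(elements)}"
            )
        frames.append(coords)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise MalformedTrajectoryError(f"{path}: no frames found")
    return Trajectory(np.stack(frames), dt=dt, box_length=box_length, elements=elements)


def write_xyz_trajectory(path, traj: Trajectory, elements=None, comment="frame {i}") -> None:
    """Write a :class:`Trajectory` as multi-frame XYZ with 6-decimal coordinates."""
    elems = elements or traj.elements
    if elems is None:
        elems = ["X"] * traj.n_atoms
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(comment.format(i=i) + "\n")
            for e, (x, y, z) in zip(elems, traj.coordinates[i]):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PDB topologies
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {
    "CO", "FE", "MG", "ZN", "MN", "NI", "CU", "NA", "CL", "BR", "CA_ION",
}


def _element_from_name(name: str, resname: str) -> str:
    """Best-effort element from a PDB atom name when the element column is empty."""
    stripped = re.sub(r"[^A-Za-z]", "", name).upper()
    if not stripped:
        raise MalformedTrajectoryError(f"cannot infer element for atom record {name!r}")
    # Water hydrogens/oxygens first (names like OW, HW1, OH2).
    if resname.upper() in {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC"}:
        return "O" if stripped.startswith("O") else "H"
    if stripped[:2] in _TWO_LETTER_ELEMENTS and stripped[:2] != "CA_ION":
        return stripped[0] + stripped[1].lower()
    return stripped[0]


def read_pdb_topology(path) -> Topology:
    """Read a single-model PDB into a :class:`Topology` (roles all ``other``).

    Elements come from the PDB element column where present, otherwise from an
    atom-name heuristic; an unrecognizable record raises an error naming it.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise MalformedTrajectoryError(f"{path}: not a readable PDB file ({exc})") from exc
    if len(u.atoms) == 0:
        raise MalformedTrajectoryError(f"{path}: no ATOM/HETATM records")
    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resids = [int(a.resid) for a in u.atoms]
    elements = []
    for a in u.atoms:
        el = getattr(a, "element", "") or ""
        el = el.strip()
        if not el:
            el = _element_from_name(a.name, a.resname)
        elements.append(el.capitalize() if len(el) > 1 else el.upper())
    return Topology(
        elements=elements,
        names=names,
        roles=["other"] * len(names),
        positions=u.atoms.positions.astype(float).copy(),
        resnames=resnames,
        resids=resids,
    )


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

DEFAULT_ROLE_RULES = {
    "metal_elements": ["Co", "Fe", "Mg", "Zn", "Mn", "Ni", "Cu"],
    "water_resnames": ["HOH", "WAT", "SOL", "TIP", "TIP3", "SPC", "W"],
    # Radial bands (Å from metal) used to classify ring carbons when atom names
    # are uninformative; the idealized macrocycle has Cα ≈ 3.0, Cmeso ≈ 3.4,
    # Cβ ≈ 4.3 Å from the center.
    "carbon_bands": {"ring_C_alpha": (0.0, 3.25), "ring_C_meso": (3.25, 3.85),
                     "ring_C_beta": (3.85, 5.0)},
    "hydrophilic_elements": ["N", "O"],
}


def _default_polarity(role: str, element: str, rules) -> str:
    if role in ("water_O", "water_H", "metal"):
        return "hydrophilic"
    if element in rules["hydrophilic_elements"]:
        return "hydrophilic"
    return "hydrophobic"


def assign_roles(topology: Topology, rules=None, macrocycle=True) -> Topology:
    """Assign atom roles from element/residue patterns (and geometry for ring C).

    Water residues become ``water_O``/``water_H`` with parent mapping; a metal
    element becomes ``metal``; non-water N become ``ring_N``; carbons are
    classified by radial distance from the metal when positions are available;
    remaining H on the ring become ``ring_H``. With ``macrocycle=True`` the
    metalloporphyrin invariants are enforced and torsion quadruples are built.
    """
    rules = {**DEFAULT_ROLE_RULES, **(rules or {})}
    n = topology.n_atoms
    roles = ["other"] * n
    water_parent = {}
    resnames = topology.resnames or [""] * n
    resids = topology.resids or list(range(n))
    water_res = {r.upper() for r in rules["water_resnames"]}
    metal_elems = {e.capitalize() for e in rules["metal_elements"]}

    # Waters by residue name; parent O is the oxygen sharing the residue id.
    res_oxygen = {}
    for i in range(n):
        if resnames[i].upper() in water_res:
            if topology.elements[i].upper().startswith("O"):
                roles[i] = "water_O"
                res_oxygen[resids[i]] = i
    for i in range(n):
        if resnames[i].upper() in water_res and topology.elements[i].upper().startswith("H"):
            roles[i] = "water_H"
            if resids[i] in res_oxygen:
                water_parent[i] = res_oxygen[resids[i]]

    for i in range(n):
        if roles[i] != "other":
            continue
        el = topology.elements[i].capitalize()
        if el in metal_elems:
            roles[i] = "metal"
        elif el == "N":
            roles[i] = "ring_N"

    metal_idx = [i for i, r in enumerate(roles) if r == "metal"]
    pos = topology.positions
    for i in range(n):
        if roles[i] != "other":
            continue
        el = topology.elements[i].upper()
        if el.startswith("C") and len(el) == 1:
            name = topology.names[i].upper()
            if name.startswith("CA"):
                roles[i] = "ring_C_alpha"
            elif name.startswith("CB"):
                roles[i] = "ring_C_beta"
            elif name.startswith(("CM", "CH")):
                roles[i] = "ring_C_meso"
            elif pos is not None and len(metal_idx) == 1:
                r = float(np.linalg.norm(pos[i] - pos[metal_idx[0]]))
                for role, (lo, hi) in rules["carbon_bands"].items():
                    if lo <= r < hi:
                        roles[i] = role
                        break
        elif el.startswith("H"):
            roles[i] = "ring_H"

    radii = np.array(
        [BONDI_VDW_RADII.get(e.upper(), np.nan) for e in topology.elements], dtype=float
    )
    polarity = [_default_polarity(roles[i], topology.elements[i].capitalize(), rules)
                for i in range(n)]
    out = replace(
        topology,
        roles=roles,
        vdw_radius=radii,
        polarity=polarity,
        water_parent=water_parent,
    )
    if macrocycle:
        out.validate_macrocycle()
        if pos is not None:
            out.torsion_quadruples = build_macrocycle_torsions(out, pos)
    return out


def build_macrocycle_torsions(topology: Topology, positions: np.ndarray) -> dict:
    """Construct the standard torsion quadruples of a metalloporphyrin.

    Proper: the four ring nitrogens in azimuthal order (N–N–N–N). Improper: one
    metal–Cα–Cα–N quadruple per pyrrole, with the two α-carbons bonded to that
    nitrogen (within 1.6 Å).
    """
    metal = topology.metal_index
    n_ids = topology.ring_n_indices
    rel = positions[n_ids] - positions[metal]
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
    proper = [tuple(int(n_ids[k]) for k in order)]
    improper = []
    alpha = topology.indices_with_role("ring_C_alpha")
    for ni in n_ids:
        d = np.linalg.norm(positions[alpha] - positions[ni], axis=1)
        bonded = alpha[np.argsort(d)[:2]] if len(alpha) >= 2 else []
        if len(bonded) == 2 and np.sort(d)[1] < 1.6:
            improper.append((metal, int(bonded[0]), int(bonded[1]), int(ni)))
    return {"proper": proper, "improper": improper}
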