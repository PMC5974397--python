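"""Atomic structures for hard-sphere AFM simulation.

Reads PDB/mmCIF coordinates, assigns hard-sphere radii, orients ring
oligomers into the scan frame (symmetry axis along +z, grounded at z = 0)
and extracts retinal chromophores as transition dipoles.

Conventions
-----------
* Lengths are nanometres everywhere after parsing (files are in Å).
* The scan frame is right-handed with z the scan normal; the support plane
  (standing in for the membrane surface) is z = 0 and the lowest atom
  sphere is tangent to it.
* Hydrogens and waters are dropped on reading; the heavy-atom radii are
  united-atom-like values that absorb the missing hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .errors import (
    AmbiguousSideError,
    ChromophoreGeometryError,
    EmptyStructureError,
    MissingChromophoreError,
    StructureParseError,
    SymmetryError,
    UnknownElementError,
)

ANGSTROM_TO_NM = 0.1

#: United-atom-like hard-sphere radii (nm).  Heavy atoms only; values are
#: slightly inflated van der Waals radii so that the omitted hydrogens are
#: absorbed into the parent sphere.
ELEMENT_RADII_NM: dict[str, float] = {
    "C": 0.17,
    "N": 0.155,
    "O": 0.152,
    "S": 0.18,
    "P": 0.18,
}

#: Fallback radius (nm) for elements missing from :data:`ELEMENT_RADII_NM`
#: (metals, halides in ligands, ...).  Chosen equal to carbon; can be
#: disabled by passing ``default_radius=None`` to :func:`assign_radii`.
DEFAULT_RADIUS_NM = 0.17

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "LYR",  # selenomethionine; retinal-linked lysine stays polymeric
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom as a hard sphere."""

    element: str
    position: np.ndarray  # (3,) nm
    radius: float  # nm
    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str


@dataclass
class MolecularStructure:
    """A set of atoms with chain bookkeeping, stored as parallel arrays.

    ``frame_label`` records which frame the coordinates are in:
    ``raw`` (as read), or a membrane frame with the N- or C-terminal face
    pointing up (``membrane-N-up`` / ``membrane-C-up``).
    """

    positions: np.ndarray  # (n, 3) nm
    radii: np.ndarray  # (n,) nm
    elements: np.ndarray  # (n,) str
    chain_ids: np.ndarray  # (n,) str
    residue_names: np.ndarray  # (n,) str
    residue_numbers: np.ndarray  # (n,) int
    atom_names: np.ndarray  # (n,) str
    frame_label: str = "raw"
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.positions) == 0:
            raise EmptyStructureError("structure has no atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if not np.all(self.radii > 0):
            raise ValueError("all hard-sphere radii must be positive")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.positions)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                element=str(self.elements[i]),
                position=self.positions[i].copy(),
                radius=float(self.radii[i]),
                chain_id=str(self.chain_ids[i]),
                residue_name=str(self.residue_names[i]),
                residue_number=int(self.residue_numbers[i]),
                atom_name=str(self.atom_names[i]),
            )

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def chain_centroids(self) -> np.ndarray:
        """(n_chains, 3) centroid of each chain, in chain order."""
        return np.array(
            [self.positions[self.chain_mask(c)].mean(axis=0) for c in self.chains]
        )

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "MolecularStructure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return replace(self, positions=pos)


@dataclass
class ChromophoreSet:
    """Point transition dipoles, one per protomer carrying a chromophore.

    ``directions`` are unit vectors from the Schiff-base end (C15) to the
    beta-ionone end (C5) of the retinal polyene, so the vector tip is the
    "head" in the head-to-tail vocabulary of retinal packing.
    """

    positions: np.ndarray  # (n, 3) nm, dipole origins
    directions: np.ndarray  # (n, 3) unit vectors
    site_wavelengths: np.ndarray  # (n,) nm
    dipole_strengths: np.ndarray  # (n,) reduced units
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.site_wavelengths = np.atleast_1d(
            np.asarray(self.site_wavelengths, dtype=float)
        )
        self.dipole_strengths = np.atleast_1d(
            np.asarray(self.dipole_strengths, dtype=float)
        )
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("dipole directions must be unit vectors")
        if np.any(self.site_wavelengths <= 300) or np.any(self.site_wavelengths >= 750):
            raise ValueError("site wavelengths must lie in (300, 750) nm")
        if not self.labels:
            self.labels = [f"chromophore_{i}" for i in range(len(self.positions))]

    def __len__(self) -> int:
        return len(self.positions)

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "ChromophoreSet":
        pos, dirs = self.positions, self.directions
        if rotation is not None:
            rot = np.asarray(rotation, dtype=float)
            pos = pos @ rot.T
            dirs = dirs @ rot.T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return ChromophoreSet(
            pos, dirs, self.site_wavelengths.copy(), self.dipole_strengths.copy(),
            list(self.labels),
        )

    def mirrored(self, plane_normal: Sequence[float] = (1.0, 0.0, 0.0)) -> "ChromophoreSet":
        """Reflect positions and dipole directions through a plane at the origin.

        Used to flip the handedness of a chromophore arrangement (a pure
        chirality inversion).
        """
        n = np.asarray(plane_normal, dtype=float)
        n = n / np.linalg.norm(n)
        refl = np.eye(3) - 2.0 * np.outer(n, n)
        return self.transformed(rotation=refl)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(
    path: str, format: str = "auto", radii_from_bfactor: bool = False
) -> MolecularStructure:
    """Read a PDB or mmCIF file into a :class:`MolecularStructure`.

    Only the first model is used.  Waters and hydrogens are excluded.
    Coordinates are converted from Å to nm and every atom gets the
    element-table hard-sphere radius (see :func:`assign_radii` to change
    the radius set afterwards).  ``radii_from_bfactor`` instead takes each
    radius from the B-factor column (in Å) — the convention used by the
    pseudo-atom fixtures of :mod:`oligoscope.synthetic`.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no models")

    model = st[0]
    elements, positions, chain_ids, bfactors = [], [], [], []
    residue_names, residue_numbers, atom_names = [], [], []
    for chain in model:
        for residue in chain:
            if residue.name.strip().upper() in _WATER_NAMES or residue.is_water():
                continue
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                elements.append(atom.element.name.upper())
                positions.append(
                    (atom.pos.x * ANGSTROM_TO_NM,
                     atom.pos.y * ANGSTROM_TO_NM,
                     atom.pos.z * ANGSTROM_TO_NM)
                )
                chain_ids.append(chain.name)
                residue_names.append(residue.name.strip().upper())
                residue_numbers.append(residue.seqid.num)
                atom_names.append(atom.name.strip())
                bfactors.append(atom.b_iso)
    if not positions:
        raise EmptyStructureError(
            f"{path}: no atoms left after excluding waters and hydrogens"
        )

    if radii_from_bfactor:
        radii = np.asarray(bfactors, dtype=float) * ANGSTROM_TO_NM
        if np.any(radii <= 0):
            raise StructureParseError(
                f"{path}: radii_from_bfactor requires positive B-factors"
            )
    else:
        radii = np.ones(len(positions))  # placeholder, replaced below

    struct = MolecularStructure(
        positions=np.array(positions, dtype=float),
        radii=radii,
        elements=np.array(elements, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        residue_names=np.array(residue_names, dtype=object),
        residue_numbers=np.array(residue_numbers, dtype=int),
        atom_names=np.array(atom_names, dtype=object),
        frame_label="raw",
        source=str(path),
    )
    return struct if radii_from_bfactor else assign_radii(struct, "table")


# ---------------------------------------------------------------------------
# radii
# ---------------------------------------------------------------------------

def assign_radii(
    structure: MolecularStructure,
    radius_set: str = "table",
    default_radius: float | None = DEFAULT_RADIUS_NM,
) -> MolecularStructure:
    """Assign hard-sphere radii from a radius set.

    Parameters
    ----------
    radius_set:
        ``"table"`` for the per-element united-atom-like table, or
        ``"uniform:<value_nm>"`` (e.g. ``"uniform:0.15"``) for one radius
        for every atom.
    default_radius:
        Radius for elements absent from the table; pass ``None`` to make
        unknown elements an error.
    """
    if radius_set.startswith("uniform"):
        try:
            value = float(radius_set.split(":", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"uniform radius set must look like 'uniform:0.15', got {radius_set!r}"
            ) from exc
        if value <= 0:
            raise ValueError("uniform radius must be positive")
        radii = np.full(len(structure), value)
    elif radius_set == "table":
        radii = np.empty(len(structure))
        for i, elem in enumerate(structure.elements):
            r = ELEMENT_RADII_NM.get(str(elem))
            if r is None:
                if default_radius is None:
                    raise UnknownElementError(
                        f"no tabulated radius for element {elem!r} and defaults disabled"
                    )
                r = default_radius
            radii[i] = r
    else:
        raise ValueError(f"unknown radius set {radius_set!r}")
    return replace(structure, radii=radii)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector ``a`` onto unit vector ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _symmetry_axis(centroids: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through the chain centroids.

    For a ring oligomer the chain centroids lie on a circle; the plane
    normal of that circle is the n-fold symmetry axis.  This is the
    eigenvector of the centroid covariance with the smallest eigenvalue.
    """
    centered = centroids - centroids.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, 0]
    # deterministic sign: positive z component, then positive x
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis


def _terminal_mean_z(
    structure: MolecularStructure, terminus: str, window: int
) -> float:
    """Mean z of the first (N) or last (C) ``window`` residues of each chain."""
    zs = []
    for c in structure.chains:
        mask = structure.chain_mask(c)
        # prefer amino-acid residues so ligands (retinal, lipids) at high
        # residue numbers do not masquerade as the C-terminus
        aa = mask & np.isin(structure.residue_names.astype(str), list(_AMINO_ACIDS))
        if np.any(aa):
            mask = aa
        resnums = structure.residue_numbers[mask]
        z = structure.positions[mask][:, 2]
        order = np.unique(resnums)
        # never let the two windows overlap on short (pseudo-atom) chains
        w = min(window, max(1, len(order) // 2))
        picked = order[:w] if terminus == "N" else order[-w:]
        sel = np.isin(resnums, picked)
        zs.append(float(z[sel].mean()))
    return float(np.mean(zs))


def orient_oligomer(
    structure: MolecularStructure,
    side: str = "N",
    terminal_window: int = 5,
) -> MolecularStructure:
    """Rotate a ring oligomer into the scan frame.

    The n-fold symmetry axis (plane normal of the chain-centroid ring) is
    aligned with +z; ``side`` ("N" or "C") selects which terminus faces the
    tip, decided from the mean z of the first/last ``terminal_window``
    residues per chain; the structure is recentred laterally on the ring
    centroid and grounded so the lowest sphere is tangent to z = 0.
    """
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    if structure.n_chains < 2:
        raise SymmetryError(
            f"ring orientation needs >= 2 chains, found {structure.n_chains}"
        )
    centroids = structure.chain_centroids()
    axis = _symmetry_axis(centroids)
    rot = _rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    out = structure.transformed(rotation=rot)

    n_z = _terminal_mean_z(out, "N", terminal_window)
    c_z = _terminal_mean_z(out, "C", terminal_window)
    if abs(n_z - c_z) < 1e-9:
        raise AmbiguousSideError(
            "N- and C-terminal mean z are identical; cannot assign the face"
        )
    up_is_n = n_z > c_z
    want_n = side == "N"
    if up_is_n != want_n:
        flip = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
        out = out.transformed(rotation=flip)

    centroid_xy = out.chain_centroids().mean(axis=0)
    ground = np.min(out.positions[:, 2] - out.radii)
    out = out.transformed(
        translation=np.array([-centroid_xy[0], -centroid_xy[1], -ground])
    )
    out.frame_label = f"membrane-{side}-up"
    return out


# ---------------------------------------------------------------------------
# chromophores
# ---------------------------------------------------------------------------

#: Polyene-chain atom names used for the dipole origin (mean position).
POLYENE_ATOMS = tuple(f"C{i}" for i in range(5, 16))


def extract_retinal_chromophores(
    structure: MolecularStructure,
    site_wavelength: float = 524.0,
    dipole_strength: float = 0.03,
    residue_names: Sequence[str] = ("RET", "LYR"),
) -> ChromophoreSet:
    """Extract one transition dipole per retinal residue.

    The dipole origin is the polyene-chain midpoint (mean of atoms C5..C15
    that are present); the direction is the unit vector from the
    Schiff-base end atom (C15, the "tail") to the beta-ionone end atom
    (C5, the "head").  ``site_wavelength`` (lambda_max of the uncoupled
    chromophore, nm) and ``dipole_strength`` (reduced units) are copied to
    every entry.
    """
    names = {n.upper() for n in residue_names}
    is_ret = np.isin(structure.residue_names.astype(str), list(names))
    if not np.any(is_ret):
        raise MissingChromophoreError(
            f"no residue named one of {sorted(names)} in structure"
        )
    positions, directions, labels = [], [], []
    # one retinal per (chain, residue number)
    keys = sorted(
        {(str(c), int(r))
         for c, r in zip(structure.chain_ids[is_ret], structure.residue_numbers[is_ret])}
    )
    for chain_id, resnum in keys:
        mask = (
            is_ret
            & (structure.chain_ids == chain_id)
            & (structure.residue_numbers == resnum)
        )
        atom_names = structure.atom_names[mask].astype(str)
        pos = structure.positions[mask]
        by_name = {n: p for n, p in zip(atom_names, pos)}
        if "C5" not in by_name or "C15" not in by_name:
            raise ChromophoreGeometryError(
                f"retinal in chain {chain_id} lacks C5 or C15"
            )
        chain_sel = [by_name[n] for n in POLYENE_ATOMS if n in by_name]
        origin = np.mean(chain_sel, axis=0)
        vec = by_name["C5"] - by_name["C15"]
        directions.append(vec / np.linalg.norm(vec))
        positions.append(origin)
        labels.append(f"{chain_id}:{resnum}")
    n = len(positions)
    return ChromophoreSet(
        positions=np.array(positions),
        directions=np.array(directions),
        site_wavelengths=np.full(n, float(site_wavelength)),
        dipole_strengths=np.full(n, float(dipole_strength)),
        labels=labels,
    )
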