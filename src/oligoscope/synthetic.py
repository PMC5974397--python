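"""Ground-truth synthetic ring oligomers and AFM-like noise.

Emulates the desk-scale geometry of microbial-rhodopsin rings: n-fold
rings (n = 3, 5, 6) of cylinder-like protomers with ring diameters in the
2.8-4.9 nm range, an optional central protrusion (His-tag mimic) or
guaranteed-open pore, per-protomer retinal-like transition dipoles with a
controllable head-to-tail (tangentially circulating) or tail-to-tail
(radially pointing) azimuth pattern, and pixel/scan-line measurement
noise.  Every artifact is emitted together with its exact ground truth so
recovery tests never re-derive it from the rendered fixture.

Protomers are vertical stacks of overlapping spheres — O(10) spheres per
protomer — so the brute-force dilation oracle stays fast; an all-atom
path exists via real PDB input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .afm import HeightMap
from .errors import PackingError
from .structures import ChromophoreSet, MolecularStructure

_CLS_BY_ORDER = {3: "trimer", 4: "tetramer", 5: "pentamer", 6: "hexamer"}


@dataclass(frozen=True)
class SyntheticOligomerSpec:
    """Geometry of one synthetic ring oligomer.

    ``ring_radius`` is the protomer-centre circle radius, so the
    ground-truth peak-circle diameter is ``2 * ring_radius``.
    ``dipole_polar`` is the dipole tilt above the membrane plane in
    degrees; ``dipole_azimuth_mode`` selects the in-plane pattern:
    ``head_to_tail`` circulates the heads tangentially around the ring
    (the trimer-like packing), ``tail_to_tail`` points every head radially
    outward (the pentamer-like packing).  The seed fixes the random
    azimuthal phase of the ring.
    """

    n: int = 5
    ring_radius: float = 2.15
    protomer_height: float = 3.5
    protomer_radius: float | None = None  # None -> 0.95 * ring_radius * sin(pi/n)
    central_feature: str = "none"  # "none" | "pore" | "protrusion:<height_nm>"
    dipole_polar: float = 20.0
    dipole_azimuth_mode: str = "head_to_tail"
    site_wavelength: float = 524.0
    dipole_strength: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.dipole_azimuth_mode not in ("head_to_tail", "tail_to_tail"):
            raise ValueError("dipole_azimuth_mode must be head_to_tail or tail_to_tail")
        feat = self.central_feature.split(":", 1)[0]
        if feat not in ("none", "pore", "protrusion"):
            raise ValueError(f"unknown central_feature {self.central_feature!r}")

    @property
    def effective_protomer_radius(self) -> float:
        if self.protomer_radius is not None:
            return self.protomer_radius
        # near-tangent packing of n circles on the ring, capped at a
        # seven-transmembrane-bundle radius
        return min(0.95 * self.ring_radius * math.sin(math.pi / self.n), 1.25)

    @property
    def outer_radius(self) -> float:
        return self.ring_radius + self.effective_protomer_radius

    @property
    def protrusion_height(self) -> float:
        if self.central_feature.startswith("protrusion"):
            _, _, arg = self.central_feature.partition(":")
            return float(arg) if arg else 0.8
        return 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """AFM-like measurement noise: pixel Gaussian + per-scanline offsets."""

    sigma: float = 0.05
    line_offset_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.line_offset_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class RingGroundTruth:
    """Exact generator-side answers for one ring."""

    n: int
    cls: str
    center: np.ndarray  # (2,) nm
    diameter: float  # peak-circle diameter, nm
    peak_positions: np.ndarray  # (n, 2) nm, protomer apices
    phase: float  # azimuth of protomer 0, rad
    dipole_azimuth_mode: str
    dipole_positions: np.ndarray  # (n, 3) nm
    dipole_directions: np.ndarray  # (n, 3) unit
    central_feature: str = "none"


_PROTRUSION_SPHERE_R = 0.35

#: Azimuthal cant (degrees, clockwise) of the tail-to-tail dipoles off the
#: radial direction.  Exactly radial dipoles would be mirror-symmetric and
#: give a vanishing couplet; the cant is the minimal chirality that makes
#: the pentamer-like packing optically active.
_TAIL_TO_TAIL_CANT_DEG = 30.0


def make_ring_oligomer(
    spec: SyntheticOligomerSpec,
) -> tuple[MolecularStructure, ChromophoreSet, RingGroundTruth]:
    """Build a pseudo-atomic ring oligomer with exact ground truth.

    Each protomer is a vertical stack of overlapping spheres (a
    transmembrane-cylinder stand-in) on a circle of ``ring_radius``; a
    central sphere stack mimics the pooled His-tag protrusion, or the
    centre is left guaranteed-empty for a pore.  One dipole per protomer
    sits at mid-height with the requested tilt and azimuth pattern.
    Identical specs produce identical output (the only randomness, the
    ring phase, is drawn from the spec seed).
    """
    r_prot = spec.effective_protomer_radius
    if spec.protomer_height < 2 * r_prot:
        raise ValueError("protomer_height must be at least 2x the protomer radius")
    gap = spec.ring_radius - r_prot  # clear radius at the ring centre
    feat = spec.central_feature.split(":", 1)[0]
    if feat in ("pore", "protrusion") and gap < _PROTRUSION_SPHERE_R:
        raise ValueError(
            f"protomers (inner clearance {gap:.2f} nm) overlap the central "
            f"feature; increase ring_radius or shrink protomer_radius"
        )
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0.0, 2.0 * math.pi / spec.n))
    angles = phase + 2.0 * math.pi * np.arange(spec.n) / spec.n

    positions, radii, chain_ids, resnums = [], [], [], []
    # sphere centres span [r, height - r] exactly, so the stack bottom sits
    # on the plane and the stack top reaches protomer_height
    n_spheres = max(
        2, int(np.ceil((spec.protomer_height - 2 * r_prot) / (0.5 * r_prot))) + 1
    )
    z_centers = np.linspace(r_prot, spec.protomer_height - r_prot, n_spheres)
    for i, a in enumerate(angles):
        cx, cy = spec.ring_radius * math.cos(a), spec.ring_radius * math.sin(a)
        for k, z in enumerate(z_centers):
            positions.append((cx, cy, float(z)))
            radii.append(r_prot)
            chain_ids.append(chr(ord("A") + i))
            resnums.append(k + 1)
    if feat == "protrusion":
        # the His-tag mimic is a bump seated on the C-terminal (top) face:
        # flipped to the N-side view it hangs below the ring and the tip
        # sees an open pore instead
        top = spec.protomer_height + spec.protrusion_height
        base = max(spec.protomer_height - _PROTRUSION_SPHERE_R, _PROTRUSION_SPHERE_R)
        n_spheres = max(2, int(np.ceil((top - _PROTRUSION_SPHERE_R - base)
                                       / _PROTRUSION_SPHERE_R)) + 1)
        for k, z in enumerate(np.linspace(base, top - _PROTRUSION_SPHERE_R, n_spheres)):
            positions.append((0.0, 0.0, float(z)))
            radii.append(_PROTRUSION_SPHERE_R)
            chain_ids.append("z")
            resnums.append(k + 1)
    n_atoms = len(positions)
    structure = MolecularStructure(
        positions=np.array(positions),
        radii=np.array(radii),
        elements=np.array(["C"] * n_atoms, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        residue_names=np.array(["CYL"] * n_atoms, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        atom_names=np.array(["SPH"] * n_atoms, dtype=object),
        frame_label="membrane-C-up",
        source=f"synthetic:C{spec.n}",
    )

    tilt = math.radians(spec.dipole_polar)
    cant = math.radians(_TAIL_TO_TAIL_CANT_DEG)
    dip_pos, dip_dir = [], []
    for a in angles:
        radial = np.array([math.cos(a), math.sin(a), 0.0])
        tangent = np.array([-math.sin(a), math.cos(a), 0.0])
        dip_pos.append(spec.ring_radius * radial + [0.0, 0.0, spec.protomer_height / 2.0])
        if spec.dipole_azimuth_mode == "head_to_tail":
            # heads circulate clockwise (viewed from +z): each head points
            # at the tail of its neighbour
            inplane = -tangent
        else:
            # heads point outward, canted clockwise off pure radial; an
            # exactly radial arrangement is achiral and carries no couplet
            inplane = math.cos(cant) * radial - math.sin(cant) * tangent
        dip_dir.append(math.cos(tilt) * inplane + math.sin(tilt) * np.array([0, 0, 1.0]))
    chromophores = ChromophoreSet(
        positions=np.array(dip_pos),
        directions=np.array(dip_dir),
        site_wavelengths=np.full(spec.n, spec.site_wavelength),
        dipole_strengths=np.full(spec.n, spec.dipole_strength),
        labels=[f"{chr(ord('A') + i)}:RET" for i in range(spec.n)],
    )
    peaks = spec.ring_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    truth = RingGroundTruth(
        n=spec.n,
        cls=_CLS_BY_ORDER.get(spec.n, "other"),
        center=np.zeros(2),
        diameter=2.0 * spec.ring_radius,
        peak_positions=peaks,
        phase=phase,
        dipole_azimuth_mode=spec.dipole_azimuth_mode,
        dipole_positions=np.array(dip_pos),
        dipole_directions=np.array(dip_dir),
        central_feature=spec.central_feature,
    )
    return structure, chromophores, truth


@dataclass
class PlacedRing:
    structure: MolecularStructure
    chromophores: ChromophoreSet
    truth: RingGroundTruth
    spec: SyntheticOligomerSpec


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_patch_scene(
    specs: list[SyntheticOligomerSpec],
    patch_diameter: float,
    min_gap: float = 0.5,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[PlacedRing]:
    """Place rings at random positions/orientations in a circular patch.

    Centres are rejection-sampled inside the patch so that every pairwise
    centre distance is at least the sum of the rings' outer radii plus
    ``min_gap``.  Each ring gets its own RNG stream derived from
    ``(seed, index)``, so scenes are reproducible item by item.  If a ring
    cannot be placed within ``max_tries`` draws, a :class:`PackingError`
    reports how many rings were placed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), len(specs)]))
    placed: list[PlacedRing] = []
    centers: list[np.ndarray] = []
    outer: list[float] = []
    patch_r = patch_diameter / 2.0
    for i, spec in enumerate(specs):
        sub_seed = int(
            np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31)
        )
        s = replace(spec, seed=sub_seed)
        structure, chromophores, truth = make_ring_oligomer(s)
        r_out = s.outer_radius
        if r_out > patch_r:
            raise PackingError(
                f"ring {i} (outer radius {r_out:.2f} nm) exceeds the patch",
                achieved=len(placed),
            )
        ok = False
        for _ in range(max_tries):
            rho = patch_r - r_out
            c = rng.uniform(-rho, rho, size=2)
            if np.hypot(*c) > rho:
                continue
            if all(
                np.linalg.norm(c - cj) >= r_out + oj + min_gap
                for cj, oj in zip(centers, outer)
            ):
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place ring {i} of {len(specs)} after {max_tries} tries",
                achieved=len(placed),
            )
        angle = float(rng.uniform(0.0, 2.0 * math.pi))
        rot = _rot_z(angle)
        shift3 = np.array([c[0], c[1], 0.0])
        structure = structure.transformed(rotation=rot, translation=shift3)
        chromophores = chromophores.transformed(rotation=rot, translation=shift3)
        truth = replace(
            truth,
            center=np.asarray(c, dtype=float),
            peak_positions=truth.peak_positions @ rot[:2, :2].T + c,
            phase=truth.phase + angle,
            dipole_positions=truth.dipole_positions @ rot.T + shift3,
            dipole_directions=truth.dipole_directions @ rot.T,
        )
        placed.append(PlacedRing(structure, chromophores, truth, s))
        centers.append(np.asarray(c, dtype=float))
        outer.append(r_out)
    return placed


def merge_structures(structures: list[MolecularStructure]) -> MolecularStructure:
    """Concatenate structures into one scene (chain ids get a ring prefix)."""
    if not structures:
        raise ValueError("nothing to merge")
    parts = {
        "positions": [], "radii": [], "elements": [], "chain_ids": [],
        "residue_names": [], "residue_numbers": [], "atom_names": [],
    }
    for i, st in enumerate(structures):
        parts["positions"].append(st.positions)
        parts["radii"].append(st.radii)
        parts["elements"].append(st.elements)
        parts["chain_ids"].append(
            np.array([f"r{i}{c}" for c in st.chain_ids], dtype=object)
        )
        parts["residue_names"].append(st.residue_names)
        parts["residue_numbers"].append(st.residue_numbers)
        parts["atom_names"].append(st.atom_names)
    return MolecularStructure(
        positions=np.concatenate(parts["positions"]),
        radii=np.concatenate(parts["radii"]),
        elements=np.concatenate(parts["elements"]),
        chain_ids=np.concatenate(parts["chain_ids"]),
        residue_names=np.concatenate(parts["residue_names"]),
        residue_numbers=np.concatenate(parts["residue_numbers"]),
        atom_names=np.concatenate(parts["atom_names"]),
        frame_label=structures[0].frame_label,
        source="synthetic:scene",
    )


def corrupt_heightmap(hm: HeightMap, noise: NoiseSpec) -> HeightMap:
    """Add seeded pixel noise and per-scanline offsets.

    Negative pixels are allowed — noise can undercut the support plane,
    as in real topographs.
    """
    rng = np.random.default_rng(noise.seed)
    h = hm.heights.copy()
    if noise.sigma > 0:
        h += rng.normal(0.0, noise.sigma, size=h.shape)
    if noise.line_offset_sigma > 0:
        h += rng.normal(0.0, noise.line_offset_sigma, size=(h.shape[0], 1))
    return HeightMap(grid=hm.grid, heights=h, provenance="synthetic")


def write_ring_fixture(
    spec: SyntheticOligomerSpec, out_dir: str
) -> tuple[str, str]:
    """Write a ring as a pseudo-atom PDB plus a JSON ground-truth sidecar.

    PDB has no radius field, so each pseudo-sphere's hard-sphere radius is
    stored in the B-factor column in Å (read back with
    ``read_structure(..., radii_from_bfactor=True)``).  Each protomer also
    carries a two-atom pseudo-retinal (RET residue with C15 and C5 0.98 nm
    apart along the dipole) so chromophore extraction round-trips.
    """
    import json
    from pathlib import Path

    structure, chromophores, truth = make_ring_oligomer(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / f"ring_C{spec.n}_seed{spec.seed}.pdb"
    with open(pdb_path, "w") as fh:
        fh.write("REMARK synthetic pseudo-atom ring oligomer (oligoscope)\n")
        serial = 1

        def atom_line(name, res, chain, resnum, pos_nm, radius_nm):
            nonlocal serial
            x, y, z = (np.asarray(pos_nm) / 0.1)  # nm -> Angstrom
            fh.write(
                f"ATOM  {serial:5d}  {name:<3s} {res:<3s} {chain:1s}{resnum:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00{radius_nm * 10.0:6.2f}"
                f"           C\n"
            )
            serial += 1

        for a in structure.atoms:
            atom_line(a.atom_name, a.residue_name, a.chain_id[:1],
                      a.residue_number, a.position, a.radius)
        for i in range(len(chromophores)):
            p, d = chromophores.positions[i], chromophores.directions[i]
            chain = chr(ord("A") + i)
            atom_line("C15", "RET", chain, 900, p - 0.49 * d, 0.17)
            atom_line("C5", "RET", chain, 900, p + 0.49 * d, 0.17)
        fh.write("END\n")
    truth_path = out / f"ring_C{spec.n}_seed{spec.seed}.truth.json"
    payload = {
        "n": truth.n,
        "cls": truth.cls,
        "center_nm": truth.center.tolist(),
        "diameter_nm": truth.diameter,
        "peak_positions_nm": truth.peak_positions.tolist(),
        "phase_rad": truth.phase,
        "dipole_azimuth_mode": truth.dipole_azimuth_mode,
        "central_feature": truth.central_feature,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return str(pdb_path), str(truth_path)
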