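"""Slow reference implementations used to validate the fast paths.

These deliberately avoid the closed-form contact branches of
:mod:`oligoscope.afm`.  The reference topograph treats the tip-sample
touching condition as a 1D optimisation: the tip apex must clear the
sample surface everywhere, so the apex height at pixel ``p`` is

    h(p) = max over surface points q of  S(q) - s(|q - p|)

with ``S`` the top surface of the union of atom spheres and ``s`` the tip
profile.  For a single sphere the optimum lies on the line through the
pixel and the atom axis, leaving a bounded scalar maximisation that
:func:`scipy.optimize.minimize_scalar` solves to machine accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .afm import HeightMap, ScanGrid, TipModel, tip_profile
from .structures import MolecularStructure


def _sphere_contact_height(
    dist: float, z_a: float, r_a: float, tip: TipModel
) -> float:
    """max_u [ z_a + sqrt(r_a^2 - u^2) - s(|dist - u|) ] over u in [-r_a, r_a]."""

    def neg_g(u: float) -> float:
        return -(z_a + np.sqrt(max(r_a * r_a - u * u, 0.0))
                 - tip_profile(tip, abs(dist - u)))

    res = minimize_scalar(
        neg_g, bounds=(-r_a + 1e-12, r_a - 1e-12), method="bounded",
        options={"xatol": 1e-12},
    )
    best = -res.fun
    # the bounded optimiser can miss a boundary/kink optimum by a hair;
    # polish with a fine local scan around the reported optimum
    u0 = float(res.x)
    for span in (1e-6, 1e-9):
        us = np.clip(np.linspace(u0 - span, u0 + span, 21), -r_a, r_a)
        vals = [-neg_g(float(u)) for u in us]
        i = int(np.argmax(vals))
        u0, best = float(us[i]), max(best, float(vals[i]))
    return float(best)


def reference_topograph(
    structure: MolecularStructure, tip: TipModel, grid: ScanGrid
) -> HeightMap:
    """Per-pixel exhaustive contact scan over all atoms (slow oracle)."""
    pos, radii = structure.positions, structure.radii
    heights = np.zeros((grid.ny, grid.nx))
    xs, ys = grid.x, grid.y
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            h = 0.0
            for (xa, ya, za), ra in zip(pos, radii):
                if za + ra <= 0.0:
                    continue
                dist = float(np.hypot(x - xa, y - ya))
                # cheap upper bound: the sphere top minus the tip height at
                # the closest possible lateral offset
                bound = za + ra - tip_profile(tip, max(dist - ra, 0.0))
                if bound <= h:
                    continue
                h = max(h, _sphere_contact_height(dist, za, ra, tip))
            heights[iy, ix] = h
    return HeightMap(grid=grid, heights=heights, provenance="simulated")


def random_scene(
    rng: np.random.Generator,
    n_atoms: int = 20,
    box: float = 3.0,
    z_max: float = 2.0,
    r_range: tuple[float, float] = (0.1, 0.3),
) -> MolecularStructure:
    """Random atom cloud above the support plane for oracle comparisons."""
    n = int(n_atoms)
    radii = rng.uniform(*r_range, size=n)
    xy = rng.uniform(0.0, box, size=(n, 2))
    z = rng.uniform(radii, z_max)  # sphere centres at least one radius up
    return MolecularStructure(
        positions=np.column_stack([xy, z]),
        radii=radii,
        elements=np.array(["C"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        residue_names=np.array(["SPH"] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        atom_names=np.array(["X"] * n, dtype=object),
        frame_label="membrane-N-up",
        source="synthetic:random-scene",
    )
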