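"""Hard-sphere AFM topograph simulation.

The probe is a cone (half angle ``alpha`` from the axis) blended with a
spherical apex of radius ``R``; the sample is a union of hard spheres
standing on the support plane z = 0.  The simulated topograph records, for
each lateral pixel, the lowest apex height at which the rigid tip touches
the sample — exactly the grayscale dilation of the union-of-spheres top
surface by the reflected tip.  A Fourier low-pass filter with a cut-off
wavelength (default 2 nm) emulates the finite lateral resolution of the
instrument.

Contact geometry for one atom (sphere radius ``r`` centred at height
``z_a``, lateral distance ``d`` from the pixel):

* apex-sphere contact, valid for ``d <= (R + r) cos(alpha)``::

      h = z_a - R + sqrt((R + r)^2 - d^2)

* cone-flank contact, valid beyond the blend circle::

      h = z_a - R(1 - sin(alpha)) + (r + R(1 - sin(alpha)) - d cos(alpha) ... )

  i.e. ``h = z_a + (r - (d - R cos a) cos a) / sin a - R (1 - sin a)``,
  the signed-distance condition of the flank plane; the two branches agree
  at the blend circle.

The map height is the maximum over atoms and branches, clipped at the
support plane.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import EmptyStructureError, FilterError
from .structures import MolecularStructure


@dataclass(frozen=True)
class TipModel:
    """Blended sphere/cone probe: cone half angle (degrees) + apex radius (nm)."""

    half_angle: float = 5.0
    end_radius: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle < 90.0:
            raise ValueError("half_angle must be in (0, 90) degrees")
        if self.end_radius <= 0:
            raise ValueError("end_radius must be positive")


@dataclass(frozen=True)
class ScanGrid:
    """Regular lateral grid: x = origin[0] + ix * pixel_size, same for y."""

    pixel_size: float = 0.1
    nx: int = 64
    ny: int = 64
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.pixel_size * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.pixel_size * np.arange(self.ny)

    @classmethod
    def centered(cls, pixel_size: float, nx: int, ny: int,
                 center: tuple[float, float] = (0.0, 0.0)) -> "ScanGrid":
        """Grid whose pixel lattice is centred on ``center``."""
        ox = center[0] - pixel_size * (nx - 1) / 2.0
        oy = center[1] - pixel_size * (ny - 1) / 2.0
        return cls(pixel_size=pixel_size, nx=nx, ny=ny, origin=(ox, oy))


@dataclass
class HeightMap:
    """Topograph on a :class:`ScanGrid`; ``heights[iy, ix]`` in nm."""

    grid: ScanGrid
    heights: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"heights shape {self.heights.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    def to_tsv(self, path: str) -> None:
        """Write as a TSV matrix with a 3-line header."""
        g = self.grid
        header = (
            f"# pixel_size_nm {g.pixel_size!r}\n"
            f"# nx {g.nx} ny {g.ny} origin {g.origin[0]!r} {g.origin[1]!r}\n"
            f"# provenance {self.provenance}\n"
        )
        buf = io.StringIO()
        np.savetxt(buf, self.heights, fmt="%.9g", delimiter="\t")
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path: str) -> "HeightMap":
        with open(path) as fh:
            l1 = fh.readline().split()
            l2 = fh.readline().split()
            l3 = fh.readline().split()
            heights = np.loadtxt(fh, delimiter="\t", ndmin=2)
        pixel = float(l1[2])
        nx, ny = int(l2[2]), int(l2[4])
        origin = (float(l2[6]), float(l2[7]))
        provenance = l3[2] if len(l3) > 2 else "loaded"
        grid = ScanGrid(pixel_size=pixel, nx=nx, ny=ny, origin=origin)
        return cls(grid=grid, heights=heights, provenance=provenance)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter: cut-off wavelength (nm) and kernel shape.

    ``kernel`` is ``"gaussian"`` (attenuation 1/2 at the cut-off),
    ``"ideal"`` (brick wall) or ``"butterworth:<order>"``.
    """

    cutoff_wavelength: float = 2.0
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.cutoff_wavelength <= 0:
            raise ValueError("cutoff_wavelength must be positive")
        name = self.kernel.split(":", 1)[0]
        if name not in ("gaussian", "ideal", "butterworth"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


# ---------------------------------------------------------------------------
# tip profile
# ---------------------------------------------------------------------------

def tip_profile(tip: TipModel, lateral_offset) -> np.ndarray | float:
    """Height of the tip surface above its apex at a lateral offset (nm).

    Spherical cap ``R - sqrt(R^2 - x^2)`` out to the blend circle
    ``x = R cos(alpha)``, then the tangent cone
    ``R (1 - sin(alpha)) + (x - R cos(alpha)) cot(alpha)``; the blend is
    continuous and once-differentiable.
    """
    x = np.asarray(lateral_offset, dtype=float)
    if np.any(x < 0):
        raise ValueError("lateral_offset must be non-negative")
    R = tip.end_radius
    alpha = np.deg2rad(tip.half_angle)
    xb = R * np.cos(alpha)
    sphere = R - np.sqrt(np.maximum(R * R - np.minimum(x, xb) ** 2, 0.0))
    cone = R * (1.0 - np.sin(alpha)) + (x - xb) / np.tan(alpha)
    out = np.where(x <= xb, sphere, cone)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# topograph simulation
# ---------------------------------------------------------------------------

def _atom_contact_heights(
    d: np.ndarray, z_a: float, r_a: float, R: float, alpha: float
) -> np.ndarray:
    """Apex height at which the tip touches one atom sphere, vs lateral d."""
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    reach = (R + r_a) * cos_a  # blend circle of the dilated sphere
    h = np.full(d.shape, -np.inf)
    near = d <= reach
    h[near] = z_a - R + np.sqrt((R + r_a) ** 2 - d[near] ** 2)
    far = ~near
    # flank tangency: signed distance of the sphere centre to the cone flank
    h[far] = (
        z_a
        + (r_a - (d[far] - R * cos_a) * cos_a) / sin_a
        - R * (1.0 - sin_a)
    )
    return h


def simulate_topograph(
    structure: MolecularStructure, tip: TipModel, grid: ScanGrid
) -> HeightMap:
    """Simulate the contact topograph of an oriented structure.

    The structure must be in a membrane frame (symmetry axis along z,
    grounded at z = 0).  Heights are clipped at the support plane.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot scan an empty structure")
    pos, radii = structure.positions, structure.radii
    extent = max(
        pos[:, 0].max() - pos[:, 0].min(), pos[:, 1].max() - pos[:, 1].min()
    )
    if grid.pixel_size >= extent and extent > 0:
        warnings.warn(
            "pixel size exceeds the lateral extent of the structure; "
            "the topograph is degenerate",
            stacklevel=2,
        )
    R = tip.end_radius
    alpha = np.deg2rad(tip.half_angle)
    tan_a = np.tan(alpha)
    x, y = grid.x, grid.y
    px = grid.pixel_size
    heights = np.zeros((grid.ny, grid.nx))
    for i in range(len(pos)):
        xa, ya, za = pos[i]
        ra = radii[i]
        if za + ra <= 0:
            continue
        # lateral reach: where the cone-flank contact height crosses zero
        d_max = (za + (ra + R * (1.0 - np.sin(alpha))) / np.sin(alpha)) * tan_a
        d_max = max(d_max, (R + ra))  # at least the dilated-sphere radius
        ix0 = np.searchsorted(x, xa - d_max)
        ix1 = np.searchsorted(x, xa + d_max, side="right")
        iy0 = np.searchsorted(y, ya - d_max)
        iy1 = np.searchsorted(y, ya + d_max, side="right")
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        dx = x[ix0:ix1] - xa
        dy = y[iy0:iy1] - ya
        d = np.hypot(dx[None, :], dy[:, None])
        h = _atom_contact_heights(d, za, ra, R, alpha)
        block = heights[iy0:iy1, ix0:ix1]
        np.maximum(block, h, out=block)
    np.maximum(heights, 0.0, out=heights)
    # guard: an isolated sub-pixel feature may be missed entirely at very
    # coarse sampling; that is inherent to sampling, not an error
    _ = px
    return HeightMap(grid=grid, heights=heights, provenance="simulated")


# ---------------------------------------------------------------------------
# low-pass filter
# ---------------------------------------------------------------------------

def _kernel_response(f: np.ndarray, spec: FilterSpec) -> np.ndarray:
    fc = 1.0 / spec.cutoff_wavelength
    name, _, arg = spec.kernel.partition(":")
    if name == "gaussian":
        return np.exp(-np.log(2.0) * (f / fc) ** 2)
    if name == "ideal":
        return (f <= fc + 1e-12).astype(float)
    order = int(arg) if arg else 2
    return 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * order))


def lowpass_filter(hm: HeightMap, spec: FilterSpec, pad: str = "mirror") -> HeightMap:
    """Attenuate spatial wavelengths below the cut-off in the Fourier domain.

    ``pad="mirror"`` (default) reflects the map by one cut-off wavelength on
    each side before the transform to suppress wrap-around; ``pad="none"``
    uses the plain periodic transform (exact for periodic content).  The
    mean height (DC component) is preserved exactly.
    """
    g = hm.grid
    if spec.cutoff_wavelength < 2.0 * g.pixel_size:
        raise FilterError(
            f"cutoff {spec.cutoff_wavelength} nm is below the Nyquist wavelength "
            f"{2.0 * g.pixel_size} nm"
        )
    if pad not in ("mirror", "none"):
        raise ValueError("pad must be 'mirror' or 'none'")
    h = hm.heights
    if pad == "mirror":
        w = int(np.ceil(spec.cutoff_wavelength / g.pixel_size))
        w = min(w, h.shape[0] - 1, h.shape[1] - 1)
        work = np.pad(h, w, mode="reflect")
    else:
        w = 0
        work = h
    fy = np.fft.fftfreq(work.shape[0], d=g.pixel_size)
    fx = np.fft.rfftfreq(work.shape[1], d=g.pixel_size)
    f = np.hypot(fy[:, None], fx[None, :])
    H = _kernel_response(f, spec)
    out = np.fft.irfft2(np.fft.rfft2(work) * H, s=work.shape)
    if w:
        out = out[w:-w, w:-w]
    out = out + (h.mean() - out.mean())  # exact DC preservation after cropping
    return HeightMap(grid=g, heights=out, provenance="filtered")


def shift_heightmap(hm: HeightMap, dx_pixels: int, dy_pixels: int) -> HeightMap:
    """Integer-pixel roll of the map (used by equivariance tests)."""
    return replace(hm, heights=np.roll(hm.heights, (dy_pixels, dx_pixels), (0, 1)))
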