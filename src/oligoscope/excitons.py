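"""Exciton-coupled circular dichroism from chromophore geometry.

A ring oligomer carries one retinal transition dipole per protomer.  The
degenerate point-dipole exciton model couples them:

* site energies ``E_i = 1 / lambda_i`` (reduced wavenumbers, nm^-1), equal
  within an oligomer;
* couplings ``V_ij = mu_i mu_j kappa_ij / d_ij^3`` with the orientation
  factor ``kappa_ij = u_i.u_j - 3 (u_i.R_ij)(u_j.R_ij)`` (unit vectors
  ``u``, unit separation ``R_ij``, distance ``d_ij`` in nm).

Diagonalising the Hamiltonian gives exciton states ``k`` with energies
``E_k`` (band positions ``lambda_k = 1/E_k``) and rotational strengths

    R_k = -(pi / lambda_bar) * sum_{i<j} c_ik c_jk  R_ij . (mu_i x mu_j)

which sum to zero over the manifold (degenerate-exciton sum rule).  The
CD spectrum is a sum of unit-area Gaussians weighted by ``R_k`` plus a
single intrinsic band at lambda_max — the monomer CD that survives
without coupling.  Only signs, orderings and peak positions are
meaningful: units are reduced (no absolute Delta-epsilon scale).

A couplet that is positive on the blue side and negative on the red side
of lambda_max is a *normal* couplet (the trimer signature for microbial
rhodopsins); the reverse is an *inverted* couplet (the pentamer
signature).  A weak inverted couplet under a dominant positive intrinsic
band does not cross zero — it shifts the single apparent peak to the red
of lambda_max, which is how pentamer formation shows up when the couplet
lobes are unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ExcitonError
from .structures import ChromophoreSet

#: Minimum inter-chromophore distance (nm) for the point-dipole picture.
POINT_DIPOLE_GUARD_NM = 0.3


@dataclass
class ExcitonSystem:
    chromophores: ChromophoreSet
    coupling_matrix: np.ndarray  # (N, N), reduced energy units (nm^-1)
    state_energies: np.ndarray | None = None  # (N,) nm^-1
    state_coefficients: np.ndarray | None = None  # (N, N), columns = states
    rotational_strengths: np.ndarray | None = None  # (N,), reduced units
    warnings: list[str] = field(default_factory=list)

    @property
    def solved(self) -> bool:
        return self.state_energies is not None

    @property
    def state_wavelengths(self) -> np.ndarray:
        """Band positions lambda_k = 1/E_k (nm)."""
        if not self.solved:
            raise ExcitonError("system not solved yet")
        return 1.0 / self.state_energies


@dataclass
class CDSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    delta_eps: np.ndarray  # reduced CD units
    lambda_max_abs: float  # nm, uncoupled absorption maximum
    bandwidth: float  # nm FWHM used in synthesis
    apparent_peak: float = 0.0  # nm, argmax of delta_eps

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class CoupletClass:
    label: str  # normal_couplet | inverted_couplet | single_peak_redshifted
    #           | single_peak_at_max | null
    blue_lobe_sign: str  # "+", "-", "0"
    red_lobe_sign: str


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

def build_exciton_system(chromophores: ChromophoreSet) -> ExcitonSystem:
    """Point-dipole coupling Hamiltonian for a chromophore set."""
    n = len(chromophores)
    if n < 2:
        raise ExcitonError("exciton coupling needs >= 2 chromophores")
    pos = chromophores.positions
    dirs = chromophores.directions
    strengths = chromophores.dipole_strengths
    V = np.zeros((n, n))
    V[np.diag_indices(n)] = 1.0 / chromophores.site_wavelengths
    warn: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            rij = pos[j] - pos[i]
            d = float(np.linalg.norm(rij))
            if d < 1e-9:
                raise ExcitonError(f"chromophores {i} and {j} coincide")
            if d < POINT_DIPOLE_GUARD_NM:
                warn.append(
                    f"chromophores {i},{j} are {d:.3f} nm apart; point-dipole "
                    f"coupling is unreliable below {POINT_DIPOLE_GUARD_NM} nm"
                )
            u = rij / d
            kappa = float(
                dirs[i] @ dirs[j] - 3.0 * (dirs[i] @ u) * (dirs[j] @ u)
            )
            V[i, j] = V[j, i] = strengths[i] * strengths[j] * kappa / d**3
    return ExcitonSystem(chromophores=chromophores, coupling_matrix=V, warnings=warn)


def solve_exciton(system: ExcitonSystem) -> ExcitonSystem:
    """Diagonalise the Hamiltonian and compute rotational strengths."""
    V = system.coupling_matrix
    if not np.allclose(V, V.T, atol=1e-12):
        raise ExcitonError("coupling matrix is not symmetric")
    energies, coef = np.linalg.eigh(V)
    ch = system.chromophores
    mu = ch.directions * ch.dipole_strengths[:, None]
    lam_bar = float(ch.site_wavelengths.mean())
    n = len(ch)
    # pairwise chirality terms R_ij . (mu_i x mu_j)
    cross = np.cross(mu[:, None, :], mu[None, :, :])  # (n, n, 3)
    sep = ch.positions[None, :, :] - ch.positions[:, None, :]  # R_ij = r_j - r_i
    chir = np.einsum("ijk,ijk->ij", sep, cross)  # symmetric under i<->j
    iu, ju = np.triu_indices(n, k=1)
    R = np.empty(n)
    for k in range(n):
        c = coef[:, k]
        R[k] = -(np.pi / lam_bar) * float(np.sum(c[iu] * c[ju] * chir[iu, ju]))
    total = float(R.sum())
    if abs(total) > 1e-9:
        raise ExcitonError(f"sum rule violated: sum R_k = {total:g}")
    system.state_energies = energies
    system.state_coefficients = coef
    system.rotational_strengths = R
    return system


# ---------------------------------------------------------------------------
# spectrum synthesis & classification
# ---------------------------------------------------------------------------

def _gaussian(lam: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2) / (
        sigma * np.sqrt(2.0 * np.pi)
    )


def synthesize_cd_spectrum(
    system: ExcitonSystem,
    bandwidth: float = 40.0,
    intrinsic_amplitude: float = 0.0,
    grid: np.ndarray | tuple[float, float, float] = (380.0, 700.0, 0.5),
) -> CDSpectrum:
    """Sum of exciton couplet bands plus the intrinsic monomer band.

    ``bandwidth`` is the Gaussian full width at half maximum (nm);
    ``grid`` is either an explicit wavelength array or (start, stop, step).
    """
    if not system.solved:
        raise ExcitonError("solve the exciton system before synthesis")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if isinstance(grid, tuple):
        lam = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    else:
        lam = np.asarray(grid, dtype=float)
    lam_k = system.state_wavelengths
    if np.all((lam_k < lam[0]) | (lam_k > lam[-1])):
        raise ExcitonError(
            f"no exciton band ({lam_k.min():.0f}-{lam_k.max():.0f} nm) falls "
            f"inside the grid ({lam[0]:.0f}-{lam[-1]:.0f} nm)"
        )
    lam_max_abs = float(system.chromophores.site_wavelengths.mean())
    de = np.zeros_like(lam)
    for Rk, lk in zip(system.rotational_strengths, lam_k):
        de += Rk * _gaussian(lam, lk, bandwidth)
    de += intrinsic_amplitude * _gaussian(lam, lam_max_abs, bandwidth)
    spec = CDSpectrum(
        wavelengths=lam, delta_eps=de, lambda_max_abs=lam_max_abs,
        bandwidth=bandwidth,
    )
    spec.apparent_peak = float(lam[np.argmax(de)])
    return spec


def classify_couplet(
    spectrum: CDSpectrum, zero_tolerance: float = 1e-9
) -> CoupletClass:
    """Label the spectrum as a couplet or a single band.

    A couplet has a positive and a negative extremum, both above
    ``zero_tolerance`` in magnitude; its lobes are named by wavelength
    order (the extremum at shorter wavelength is the blue lobe).  A
    positive blue lobe with a negative red lobe is a *normal* couplet,
    the reverse an *inverted* couplet.  Note the lobes are ordered
    relative to each other, not to the monomer lambda_max: exciton bands
    of a coupled ring can sit entirely to one side of the uncoupled
    absorption maximum.

    A single-signed spectrum is a single peak, ``redshifted`` when its
    extremum lies more than bandwidth/4 to the red of lambda_max, else
    ``at_max``.  An everywhere-small spectrum is ``null``.
    """
    lam, de = spectrum.wavelengths, spectrum.delta_eps
    lmax = spectrum.lambda_max_abs
    i_max, i_min = int(np.argmax(de)), int(np.argmin(de))
    vmax, vmin = float(de[i_max]), float(de[i_min])
    has_pos = vmax > zero_tolerance
    has_neg = -vmin > zero_tolerance

    if has_pos and has_neg:
        lam_pos, lam_neg = float(lam[i_max]), float(lam[i_min])
        if lam_pos < lam_neg:
            return CoupletClass("normal_couplet", "+", "-")
        return CoupletClass("inverted_couplet", "-", "+")
    if not has_pos and not has_neg:
        return CoupletClass("null", "0", "0")
    sign = "+" if has_pos else "-"
    peak_lam = float(lam[i_max if has_pos else i_min])
    if peak_lam > lmax + spectrum.bandwidth / 4.0:
        return CoupletClass("single_peak_redshifted", "0", sign)
    return CoupletClass("single_peak_at_max", sign, sign)


def predict_cd(
    chromophores: ChromophoreSet,
    bandwidth: float = 40.0,
    intrinsic_amplitude: float = 0.0,
    grid: np.ndarray | tuple[float, float, float] = (380.0, 700.0, 0.5),
    zero_tolerance: float | None = None,
) -> tuple[ExcitonSystem, CDSpectrum, CoupletClass]:
    """Geometry -> Hamiltonian -> spectrum -> couplet label, in one call.

    ``zero_tolerance`` defaults to 1e-6 of the spectrum's absolute maximum
    (scale-free, since units are reduced).
    """
    system = solve_exciton(build_exciton_system(chromophores))
    spec = synthesize_cd_spectrum(
        system, bandwidth=bandwidth, intrinsic_amplitude=intrinsic_amplitude,
        grid=grid,
    )
    tol = zero_tolerance
    if tol is None:
        scale = float(np.max(np.abs(spec.delta_eps)))
        tol = 1e-6 * scale if scale > 0 else 1e-12
    return system, spec, classify_couplet(spec, zero_tolerance=tol)
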