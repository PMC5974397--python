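"""Ring-oligomer analysis of height maps.

Detects subunit peaks, estimates the rotational symmetry order, fits the
ring geometry (two diameter conventions), scores the central
protrusion/pore, classifies the oligomer, and aggregates per-patch
statistics.

Diameter conventions
--------------------
Experimental reports mix two measures, so both are computed:

* ``diameter`` — the *peak-circle* diameter: diameter of the least-squares
  circle through the subunit peak maxima.
* ``outer_diameter`` — where the azimuthally averaged radial height
  profile falls to half the ring-crest height above background, beyond
  the crest.

The *central feature* is the height at the ring centre minus the mean
height on the peak circle: positive marks a protrusion (e.g. pooled
C-terminal His-tags), negative a pore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .afm import FilterSpec, HeightMap, lowpass_filter
from .errors import AnalysisError, DegenerateFitError

__all__ = [
    "SubunitPeak",
    "SymmetryResult",
    "RingMeasurement",
    "OligomerCall",
    "PatchSummary",
    "detect_subunit_peaks",
    "estimate_symmetry_order",
    "fit_ring",
    "classify_oligomer",
    "aggregate_patch_calls",
    "analyze_heightmap",
]


@dataclass(frozen=True)
class SubunitPeak:
    """One detected subunit apex (sub-pixel position, nm)."""

    position: np.ndarray  # (2,) nm
    height: float  # nm
    prominence: float  # nm


@dataclass
class SymmetryResult:
    """Rotational-autocorrelation scores C(n) and the winning order."""

    order: int
    scores: dict[int, float]
    margin: float  # C(best) - C(second best)
    low_confidence: bool = False

    @property
    def confidence(self) -> float:
        """Heuristic [0, 1] confidence from the winner's margin.

        A margin of 0.2 correlation units or more counts as fully
        confident; degenerate (rotationally uniform) maps get 0.
        """
        if self.low_confidence:
            return 0.0
        return float(np.clip(self.margin / 0.2, 0.0, 1.0))


@dataclass
class RingMeasurement:
    center: np.ndarray  # (2,) nm
    n_subunits: int
    symmetry_order: int
    diameter: float  # nm, peak-circle convention
    outer_diameter: float  # nm, half-height convention (nan if no crossing)
    central_feature: float  # nm; >0 protrusion, <0 pore


@dataclass
class OligomerCall:
    cls: str  # trimer | tetramer | pentamer | hexamer | other
    face: str  # C-side | N-side | unknown
    confidence: float
    measurement: RingMeasurement
    patch_id: str = ""


@dataclass
class PatchSummary:
    n_patches: int
    counts_per_patch: list[int]
    mean: float
    sd: float
    class_fractions: dict[str, float]
    single_patch: bool = False


# ---------------------------------------------------------------------------
# peak detection (topographic prominence via persistence)
# ---------------------------------------------------------------------------

def _persistence_peaks(h: np.ndarray) -> list[tuple[int, int, float, float]]:
    """All local maxima of a 2D array with their topographic prominence.

    Classic sub-level persistence with 8-connectivity: pixels are swept
    from high to low; a new component is born at each local maximum and
    dies (merges into a higher component) at its key saddle.  Prominence
    = birth height - saddle height; the global maximum gets
    max - min of the map.  Ties are broken by row-major scan order.

    Returns (row, col, height, prominence) per peak.
    """
    ny, nx = h.shape
    flat = h.ravel()
    # stable sort: equal heights processed in scan order
    order = np.argsort(-flat, kind="stable")
    rank = np.empty(flat.size, dtype=np.int64)  # processing rank per pixel
    rank[order] = np.arange(flat.size)
    parent = np.full(flat.size, -1, dtype=np.int64)  # union-find
    comp_peak: dict[int, int] = {}  # root -> flat index of birth peak
    peaks: dict[int, float] = {}  # birth peak -> prominence (filled at death)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = int(root), int(parent[i])
        return int(root)

    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for idx in order:
        idx = int(idx)
        r, c = divmod(idx, nx)
        roots = set()
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx:
                j = rr * nx + cc
                if parent[j] != -1:
                    roots.add(find(j))
        parent[idx] = idx
        if not roots:
            comp_peak[idx] = idx  # birth of a new peak
            continue
        # merge into the component whose birth peak is highest (earliest rank)
        best = min(roots, key=lambda rt: rank[comp_peak[rt]])
        parent[idx] = best
        for rt in roots:
            if rt == best:
                continue
            dead_peak = comp_peak.pop(rt)
            peaks[dead_peak] = float(flat[dead_peak] - flat[idx])
            parent[rt] = best

    for pk in comp_peak.values():  # survivors, incl. the global maximum
        peaks[pk] = float(flat[pk] - flat.min())
    out = []
    for pk, prom in peaks.items():
        r, c = divmod(pk, nx)
        out.append((r, c, float(flat[pk]), prom))
    return out


def _refine_subpixel(h: np.ndarray, r: int, c: int) -> tuple[float, float, float]:
    """Quadratic 3x3 refinement; returns (dr, dc, refined height)."""
    ny, nx = h.shape
    if not (1 <= r < ny - 1 and 1 <= c < nx - 1):
        return 0.0, 0.0, float(h[r, c])
    patch = h[r - 1 : r + 2, c - 1 : c + 2]
    yy, xx = np.mgrid[-1:2, -1:2]
    A = np.column_stack(
        [np.ones(9), xx.ravel(), yy.ravel(),
         xx.ravel() ** 2, xx.ravel() * yy.ravel(), yy.ravel() ** 2]
    )
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    a0, b, c1, d, e, f = coef
    hess = np.array([[2 * d, e], [e, 2 * f]])
    if np.linalg.det(hess) <= 0 or hess[0, 0] >= 0:
        return 0.0, 0.0, float(h[r, c])
    dx, dy = np.linalg.solve(hess, [-b, -c1])
    dx = float(np.clip(dx, -0.5, 0.5))
    dy = float(np.clip(dy, -0.5, 0.5))
    hval = float(
        a0 + b * dx + c1 * dy + d * dx * dx + e * dx * dy + f * dy * dy
    )
    return dy, dx, hval


def detect_subunit_peaks(
    hm: HeightMap,
    min_prominence: float = 0.05,
    min_separation: float = 0.8,
    presmooth: FilterSpec | None = None,
) -> list[SubunitPeak]:
    """Find subunit apices: prominent, well-separated local maxima.

    ``presmooth`` applies the stated low-pass filter before detection so
    that noisy (experimental-style) and already-filtered simulated maps
    are treated identically.  Peaks are refined to sub-pixel positions by
    a quadratic fit on the 3x3 neighbourhood.  A flat map yields no peaks.
    """
    g = hm.grid
    if min_separation < g.pixel_size:
        raise AnalysisError("min_separation must be at least one pixel")
    work = lowpass_filter(hm, presmooth).heights if presmooth else hm.heights
    if np.ptp(work) < 1e-12:
        return []
    candidates = [
        (r, c, h, p) for r, c, h, p in _persistence_peaks(work) if p >= min_prominence
    ]
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept: list[SubunitPeak] = []
    for r, c, h, p in candidates:
        dy, dx, hval = _refine_subpixel(work, r, c)
        pos = np.array(
            [g.origin[0] + (c + dx) * g.pixel_size,
             g.origin[1] + (r + dy) * g.pixel_size]
        )
        if all(np.linalg.norm(pos - k.position) >= min_separation for k in kept):
            kept.append(SubunitPeak(position=pos, height=hval, prominence=p))
    return kept


# ---------------------------------------------------------------------------
# symmetry order
# ---------------------------------------------------------------------------

#: Angular samples per turn; divisible by every candidate order in 2..8.
_N_THETA = 840


def _polar_samples(
    hm: HeightMap, center: np.ndarray, radii: np.ndarray, n_theta: int = _N_THETA
) -> np.ndarray:
    """(n_r, n_theta) bilinear samples of the map on a polar grid."""
    g = hm.grid
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    xs = center[0] + radii[:, None] * np.cos(theta)[None, :]
    ys = center[1] + radii[:, None] * np.sin(theta)[None, :]
    cols = (xs - g.origin[0]) / g.pixel_size
    rows = (ys - g.origin[1]) / g.pixel_size
    return ndimage.map_coordinates(
        hm.heights, [rows, cols], order=1, mode="nearest"
    )


def estimate_symmetry_order(
    hm: HeightMap,
    center,
    orders=(3, 4, 5, 6),
    annulus: tuple[float, float] | None = None,
) -> SymmetryResult:
    """Rotational-autocorrelation symmetry order on an annulus.

    For each candidate order ``n`` the score is the Pearson correlation
    between the polar-resampled annulus and its copy rotated by 2*pi/n;
    the winner is the argmax.  A rotationally uniform map (all scores
    equal within 1e-6) is flagged low-confidence.
    """
    center = np.asarray(center, dtype=float)
    g = hm.grid
    orders = sorted(set(int(n) for n in orders))
    if not orders or min(orders) < 2 or max(orders) > 8:
        raise AnalysisError("orders must be a subset of {2..8}")
    edge = min(
        center[0] - g.x[0], g.x[-1] - center[0],
        center[1] - g.y[0], g.y[-1] - center[1],
    )
    if edge <= 0:
        raise AnalysisError("center lies outside the map")
    if annulus is None:
        r_out = 0.95 * edge
        r_in = 0.15 * r_out
    else:
        r_in, r_out = annulus
        if r_out > edge:
            raise AnalysisError("annulus leaves the map")
    n_r = max(8, int(np.ceil((r_out - r_in) / g.pixel_size)))
    radii = np.linspace(r_in, r_out, n_r)
    P = _polar_samples(hm, center, radii)
    Pc = P - P.mean()
    denom = float(np.sqrt((Pc * Pc).sum()))
    scores: dict[int, float] = {}
    for n in orders:
        Q = np.roll(P, _N_THETA // n, axis=1)
        Qc = Q - Q.mean()
        if denom < 1e-15:
            scores[n] = 1.0
        else:
            scores[n] = float((Pc * Qc).sum() / denom**2)
    vals = sorted(scores.values(), reverse=True)
    spread = vals[0] - vals[-1]
    best = max(orders, key=lambda n: scores[n])
    # a Cn map also correlates under rotations by its divisors (C3 of a
    # hexamer); promote to the finest order whose score ties the winner
    for m in sorted(orders, reverse=True):
        if m > best and m % best == 0 and scores[m] >= scores[best] - 0.05:
            best = m
            break
    rivals = [scores[n] for n in orders if n != best and best % n != 0]
    margin = scores[best] - max(rivals) if rivals else 1.0
    # degenerate (rotationally uniform) maps: all scores equal up to the
    # bilinear-resampling ripple of the polar transform
    return SymmetryResult(
        order=best,
        scores=scores,
        margin=float(margin),
        low_confidence=bool(spread < 1e-4),
    )


# ---------------------------------------------------------------------------
# ring geometry
# ---------------------------------------------------------------------------

def _circle_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle through 2D points."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x * x + y * y
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise DegenerateFitError("peaks are collinear; no circle is defined")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(c + cx * cx + cy * cy))
    return np.array([cx, cy]), r


def fit_ring(
    peaks: list[SubunitPeak],
    hm: HeightMap,
    symmetry: SymmetryResult | None = None,
) -> RingMeasurement:
    """Fit ring geometry from subunit peaks and the height map.

    ``symmetry`` (if given) supplies the symmetry order; otherwise the
    number of peaks is used.
    """
    if len(peaks) < 3:
        raise AnalysisError(f"ring fit needs >= 3 peaks, got {len(peaks)}")
    pts = np.array([p.position for p in peaks])
    center, r_peak = _circle_fit(pts)
    g = hm.grid
    edge = min(
        center[0] - g.x[0], g.x[-1] - center[0],
        center[1] - g.y[0], g.y[-1] - center[1],
    )
    if edge <= 0:
        raise AnalysisError("fitted ring centre lies outside the map")
    r_max = 0.98 * edge
    radii = np.arange(0.0, r_max, g.pixel_size / 2.0)
    polar = _polar_samples(hm, center, radii)
    profile = polar.mean(axis=1)

    # crest of the azimuthally averaged profile near the fitted ring radius
    window = (radii >= 0.6 * r_peak) & (radii <= min(1.6 * r_peak, r_max))
    if not np.any(window):
        window = radii > 0
    i_crest = np.argmax(np.where(window, profile, -np.inf))
    crest_r, crest_h = radii[i_crest], profile[i_crest]
    tail = profile[radii >= 0.9 * r_max]
    background = float(np.median(tail)) if tail.size else 0.0
    half = background + 0.5 * (crest_h - background)
    outer = np.nan
    if crest_h - background > 1e-12:
        for j in range(i_crest, len(radii) - 1):
            if profile[j] >= half > profile[j + 1]:
                frac = (profile[j] - half) / (profile[j] - profile[j + 1])
                outer = 2.0 * (radii[j] + frac * (radii[j + 1] - radii[j]))
                break

    center_h = float(_polar_samples(hm, center, np.array([0.0]), 4).mean())
    ring_h = float(_polar_samples(hm, center, np.array([r_peak])).mean())
    return RingMeasurement(
        center=center,
        n_subunits=len(peaks),
        symmetry_order=symmetry.order if symmetry else len(peaks),
        diameter=2.0 * r_peak,
        outer_diameter=float(outer),
        central_feature=center_h - ring_h,
    )


# ---------------------------------------------------------------------------
# classification & aggregation
# ---------------------------------------------------------------------------

_CLS_BY_ORDER = {3: "trimer", 4: "tetramer", 5: "pentamer", 6: "hexamer"}


def classify_oligomer(
    m: RingMeasurement,
    protrusion_threshold: float = 0.2,
    symmetry: SymmetryResult | None = None,
    patch_id: str = "",
) -> OligomerCall:
    """Class from the symmetry order; face from the central feature.

    A central feature above +threshold marks the C-side (His-tag
    protrusion), below -threshold the N-side (open pore); otherwise the
    face is unknown.  Deterministic given (measurement, threshold).
    """
    cls = _CLS_BY_ORDER.get(m.symmetry_order, "other")
    if m.central_feature > protrusion_threshold:
        face = "C-side"
    elif m.central_feature < -protrusion_threshold:
        face = "N-side"
    else:
        face = "unknown"
    confidence = symmetry.confidence if symmetry is not None else 1.0
    return OligomerCall(
        cls=cls, face=face, confidence=confidence, measurement=m, patch_id=patch_id
    )


def aggregate_patch_calls(calls: list[OligomerCall]) -> PatchSummary:
    """Per-patch oligomer counts (mean, sample s.d.) and class fractions.

    The s.d. uses the n-1 denominator; a single patch reports s.d. 0 and
    is flagged.
    """
    if not calls:
        raise AnalysisError("no oligomer calls to aggregate")
    df = pd.DataFrame(
        {"patch_id": [c.patch_id for c in calls], "cls": [c.cls for c in calls]}
    )
    counts = df.groupby("patch_id").size().sort_index()
    single = len(counts) == 1
    sd = 0.0 if single else float(counts.std(ddof=1))
    fractions = (df["cls"].value_counts() / len(df)).to_dict()
    return PatchSummary(
        n_patches=len(counts),
        counts_per_patch=[int(v) for v in counts],
        mean=float(counts.mean()),
        sd=sd,
        class_fractions={str(k): float(v) for k, v in fractions.items()},
        single_patch=single,
    )


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def analyze_heightmap(
    hm: HeightMap,
    min_prominence: float = 0.05,
    min_separation: float = 0.8,
    orders=(3, 4, 5, 6),
    protrusion_threshold: float = 0.2,
    presmooth: FilterSpec | None = None,
    patch_id: str = "",
) -> OligomerCall:
    """Peaks -> symmetry -> ring fit -> classification, in one call."""
    peaks = detect_subunit_peaks(
        hm, min_prominence=min_prominence, min_separation=min_separation,
        presmooth=presmooth,
    )
    if len(peaks) >= 4:
        # a central protrusion (His-tag mimic) shows up as one extra peak
        # at the ring centre; drop peaks much closer to the peak centroid
        # than the ring radius before fitting the circle
        pts = np.array([p.position for p in peaks])
        centroid = pts.mean(axis=0)
        radii = np.linalg.norm(pts - centroid, axis=1)
        keep = radii >= 0.5 * np.median(radii)
        if keep.sum() >= 3:
            peaks = [p for p, k in zip(peaks, keep) if k]
    if len(peaks) < 3:
        raise AnalysisError(
            f"only {len(peaks)} subunit peaks found; cannot fit a ring"
        )
    pts = np.array([p.position for p in peaks])
    center, _ = _circle_fit(pts)
    sym = estimate_symmetry_order(hm, center, orders=orders)
    m = fit_ring(peaks, hm, symmetry=sym)
    return classify_oligomer(
        m, protrusion_threshold=protrusion_threshold, symmetry=sym,
        patch_id=patch_id,
    )
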