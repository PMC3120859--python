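"""Depth-normalized nucleus segmentation.

Stages, applied to each time point's (deconvolved) stack:

1. ``tissue_hull`` — the 3D convex hull of supra-threshold voxels
   approximates the root boundary.
2. ``optical_depths`` — for any point, the tissue path lengths to the hull
   along the collection axis (+z, toward the objective) and the sheet axis
   (-x, toward the laser).
3. ``fit_attenuation`` / ``normalize_intensity`` — the log of local
   maximum intensity is fit by least squares to a second-order polynomial
   in the two optical depths and used to flatten the depth-dependent
   intensity decay.
4. ``segment`` — connected components (26-connectivity) above an
   increasing series of global thresholds are classified as nuclei by
   morphological criteria; voxels of accepted nuclei are masked out before
   the next, higher threshold is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import peak_local_max

from .types import ImageStack, NucleusRecord

__all__ = [
    "AttenuationModel",
    "SegmentationCriteria",
    "tissue_hull",
    "optical_depths",
    "attenuation_samples",
    "fit_attenuation",
    "normalize_intensity",
    "segment",
    "segment_stack",
    "refine_centroid",
    "default_threshold_series",
    "typical_peak_intensity",
]

#: optical axes along which depth is accumulated: emission travels toward
#: the objective (+z), illumination arrives from the laser side (-x)
COLLECTION_DIR = np.array([0.0, 0.0, 1.0])
SHEET_DIR = np.array([-1.0, 0.0, 0.0])


@dataclass
class AttenuationModel:
    """log(max intensity) ~ quadratic polynomial in the two optical depths.

    ``coefficients`` are ordered for the design (1, d1, d2, d1^2, d2^2,
    d1*d2) with d1 the collection-axis depth and d2 the sheet-axis depth,
    both in µm.
    """

    coefficients: np.ndarray
    hull_threshold: float = 0.0
    residual: float = 0.0

    def predict_log(self, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
        d1 = np.asarray(d1, dtype=float)
        d2 = np.asarray(d2, dtype=float)
        X = np.stack(
            [np.ones_like(d1), d1, d2, d1**2, d2**2, d1 * d2], axis=-1
        )
        return X @ self.coefficients


@dataclass
class SegmentationCriteria:
    """Acceptance ranges for candidate blobs plus the threshold series.

    Defaults are calibrated on the package's synthetic fixtures (nuclei of
    ~2 µm intrinsic SD imaged at 2 x 2 x 2.5 µm voxels).  All (min, max)
    ranges are inclusive; ``threshold_series`` must be strictly increasing
    and is interpreted in normalized intensity units.  If it is empty, a
    geometric series is built per stack by ``default_threshold_series``.
    """

    voxel_count: tuple[float, float] = (4, 400)
    mean_intensity: tuple[float, float] = (0.0, np.inf)
    lateral_size: tuple[float, float] = (3.0, 9.0)
    lateral_eccentricity: tuple[float, float] = (0.0, 0.88)
    axial_size: tuple[float, float] = (2.0, 8.5)
    threshold_series: tuple[float, ...] = ()
    single_axial_maximum: bool = True
    peak_prominence_fraction: float = 0.10
    #: after the threshold sweep, accept leftover bright blobs under
    #: relaxed shape maxima.  Unresolved pairs of neighbouring nuclei then
    #: still yield one (oversized) record instead of a detection gap —
    #: exactly the artifact class the division classifier must see.
    fallback_relaxed: bool = True

    def __post_init__(self) -> None:
        for name in (
            "voxel_count",
            "mean_intensity",
            "lateral_size",
            "lateral_eccentricity",
            "axial_size",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has min > max")
        ts = np.asarray(self.threshold_series, dtype=float)
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("threshold_series must be strictly increasing")

    @classmethod
    def deconvolved(cls) -> "SegmentationCriteria":
        """Ranges calibrated for deconvolved stacks at 1.5 x 1.5 x 2 µm
        voxels, tight enough that an unresolved pair of freshly separated
        daughter nuclei (a dumbbell ~5 µm across) fails the maxima and is
        split at a higher threshold instead of absorbed."""
        return cls(
            voxel_count=(3, 120),
            lateral_size=(1.5, 5.8),
            lateral_eccentricity=(0.0, 0.90),
            axial_size=(1.2, 4.2),
            peak_prominence_fraction=0.06,
        )


def default_threshold_series(
    anchor_peak: float,
    n_levels: int = 24,
    lo_frac: float = 0.18,
    hi_frac: float = 6.0,
) -> np.ndarray:
    """Geometric threshold series anchored on the typical nucleus peak.

    ``anchor_peak`` should be a robust central peak intensity (e.g. the
    median of local maxima), not the stack maximum: transient bright
    nuclei — the marker intensifies several-fold just before division —
    would otherwise push every threshold above the dim blobs that matter
    most (freshly separated daughters).  The top of the series must still
    exceed those bright peaks, or a pre-division nucleus stays oversized
    at every level and drops out entirely."""
    return anchor_peak * np.geomspace(lo_frac, hi_frac, n_levels)


def typical_peak_intensity(
    stack: ImageStack, min_distance_vox: int = 2
) -> float:
    """Median local-maximum intensity — the threshold-series anchor."""
    data = stack.voxels
    lo = float(np.percentile(data, 50))
    hi = float(np.percentile(data, 99.9))
    floor = lo + 0.2 * (hi - lo)  # robust to mostly-background scenes
    peaks = peak_local_max(
        data, min_distance=min_distance_vox, threshold_abs=floor,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return float(data.max())
    return float(np.median(data[peaks[:, 0], peaks[:, 1], peaks[:, 2]]))


def tissue_hull(stack: ImageStack, threshold: float) -> ConvexHull:
    """Convex hull (in physical µm) of all voxels above ``threshold``."""
    zz, yy, xx = np.nonzero(stack.voxels > threshold)
    if len(zz) < 4:
        raise ValueError("fewer than 4 voxels above the hull threshold")
    dx, dy, dz = stack.voxel_sizes
    ox, oy, oz = stack.origin
    pts = np.column_stack([ox + xx * dx, oy + yy * dy, oz + zz * dz])
    try:
        return ConvexHull(pts)
    except QhullError as exc:  # coplanar / degenerate point set
        raise ValueError(f"degenerate point set for convex hull: {exc}") from exc


def _ray_depth(hull: ConvexHull, points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Distance from each interior point to the hull surface along
    ``direction``; 0 for points outside the hull."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    normals = hull.equations[:, :3]  # outward: n.x + b <= 0 inside
    offsets = hull.equations[:, 3]
    signed = points @ normals.T + offsets  # (N, F), <= 0 inside
    inside = np.all(signed <= 1e-9, axis=1)
    du = normals @ direction  # (F,)
    exit_facets = du > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -signed[:, exit_facets] / du[exit_facets]
    depth = np.min(np.where(s >= -1e-9, s, np.inf), axis=1)
    depth = np.where(np.isfinite(depth), np.clip(depth, 0.0, None), 0.0)
    return np.where(inside, depth, 0.0)


def optical_depths(
    hull: ConvexHull, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tissue depths (µm) along the collection (+z) and sheet (-x) axes."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d_col = _ray_depth(hull, pts, COLLECTION_DIR)
    d_sheet = _ray_depth(hull, pts, SHEET_DIR)
    if np.asarray(points).ndim == 1:
        return float(d_col[0]), float(d_sheet[0])
    return d_col, d_sheet


def attenuation_samples(
    stack: ImageStack,
    hull: ConvexHull,
    min_distance_um: float = 6.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Local-maximum intensities with their optical depths, as rows
    ``(max_intensity, d_collection, d_sheet)`` — the fit samples."""
    data = stack.voxels
    if threshold is None:
        threshold = float(np.percentile(data, 50) + 0.15 * np.ptp(data))
    dx, dy, dz = stack.voxel_sizes
    min_dist = max(1, int(round(min_distance_um / min(dx, dy, dz))))
    peaks = peak_local_max(
        data, min_distance=min_dist, threshold_abs=threshold, exclude_border=False
    )
    if len(peaks) == 0:
        return np.zeros((0, 3))
    pos = stack.index_to_physical(peaks)
    d1, d2 = optical_depths(hull, pos)
    vals = data[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
    keep = (d1 > 0) | (d2 > 0)  # interior maxima only
    return np.column_stack([vals, d1, d2])[keep]


def fit_attenuation(samples: np.ndarray, hull_threshold: float = 0.0) -> AttenuationModel:
    """Least-squares quadratic fit of log max intensity on the two depths."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 6:
        raise ValueError("need at least 6 samples to fit the attenuation model")
    intensity, d1, d2 = samples[:, 0], samples[:, 1], samples[:, 2]
    X = np.column_stack([np.ones_like(d1), d1, d2, d1**2, d2**2, d1 * d2])
    y = np.log(np.clip(intensity, 1e-12, None))
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 6:
        raise ValueError("rank-deficient design: samples do not span both depth axes")
    residual = float(res[0] / len(y)) if res.size else 0.0
    return AttenuationModel(
        coefficients=coef, hull_threshold=hull_threshold, residual=residual
    )


def _axis_envelopes(hull: ConvexHull, axis: int, u: np.ndarray, v: np.ndarray):
    """Upper and lower hull envelopes along ``axis`` over a (u, v) grid of
    the two remaining physical axes.  Exploits convexity: along any line
    the in-hull set is the interval [lower, upper]."""
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    others = [i for i in range(3) if i != axis]
    U, V = np.meshgrid(u, v, indexing="ij")
    na = normals[:, axis]
    rhs = -(
        offsets[None, None, :]
        + U[..., None] * normals[None, None, :, others[0]]
        + V[..., None] * normals[None, None, :, others[1]]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = rhs / na[None, None, :]
    upper = np.min(
        np.where(na[None, None, :] > 1e-12, bound, np.inf), axis=-1
    )
    lower = np.max(
        np.where(na[None, None, :] < -1e-12, bound, -np.inf), axis=-1
    )
    return lower, upper


def _depth_maps(stack: ImageStack, hull: ConvexHull):
    """Per-voxel optical depths (collection +z, sheet -x) for the whole
    stack, via hull envelopes per column; 0 outside the hull."""
    xs, ys, zs = stack.voxel_centers()
    # collection axis: depth = z_upper(x, y) - z inside the hull
    zlo, zup = _axis_envelopes(hull, 2, xs, ys)  # (nx, ny)
    Z = zs[:, None, None]
    inside_z = (Z >= zlo.T[None]) & (Z <= zup.T[None])  # (nz, ny, nx)
    d_col = np.where(inside_z, zup.T[None] - Z, 0.0)
    # sheet axis: light enters from -x, depth = x - x_lower(y, z)
    xlo, xup = _axis_envelopes(hull, 0, ys, zs)  # (ny, nz)
    X = xs[None, None, :]
    inside_x = (X >= xlo.T[:, :, None]) & (X <= xup.T[:, :, None])
    d_sheet = np.where(inside_x, X - xlo.T[:, :, None], 0.0)
    return np.clip(d_col, 0.0, None), np.clip(d_sheet, 0.0, None)


def normalize_intensity(
    stack: ImageStack,
    model: AttenuationModel,
    hull: ConvexHull,
    min_factor: float = 0.05,
) -> ImageStack:
    """Divide out the depth-predicted attenuation, relative to zero depth.

    The correction factor ``exp(pred(d1, d2) - pred(0, 0))`` is clipped to
    ``[min_factor, 1]`` so that noise in deep voxels is not amplified
    without bound and surface voxels are never dimmed.
    """
    d1, d2 = _depth_maps(stack, hull)
    log_rel = model.predict_log(d1.ravel(), d2.ravel()) - model.predict_log(0.0, 0.0)
    factor = np.exp(log_rel).reshape(stack.voxels.shape)
    factor = np.clip(factor, min_factor, 1.0)
    return ImageStack(
        voxels=stack.voxels / factor,
        voxel_sizes=stack.voxel_sizes,
        time=stack.time,
        origin=stack.origin,
    )


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _component_record(
    comp_idx: tuple[np.ndarray, np.ndarray, np.ndarray],
    intensities: np.ndarray,
    stack: ImageStack,
    criteria: SegmentationCriteria,
    next_id: int,
) -> NucleusRecord | None:
    """Measure one connected component and classify it against the
    criteria; returns a record if every criterion passes."""
    n_vox = len(intensities)
    lo, hi = criteria.voxel_count
    if not (lo <= n_vox <= hi):
        return None
    mean_i = float(intensities.mean())
    max_i = float(intensities.max())
    lo, hi = criteria.mean_intensity
    if not (lo <= mean_i <= hi):
        return None
    zz, yy, xx = comp_idx
    dx, dy, dz = stack.voxel_sizes
    ox, oy, oz = stack.origin
    px = ox + xx * dx
    py = oy + yy * dy
    pz = oz + zz * dz
    w = intensities / intensities.sum()
    cx, cy, cz = (px * w).sum(), (py * w).sum(), (pz * w).sum()
    # second moments; half-voxel variance floor for single-voxel extents
    var_floor = np.array([dx, dy, dz]) ** 2 / 12.0
    vxx = ((px - cx) ** 2 * w).sum() + var_floor[0]
    vyy = ((py - cy) ** 2 * w).sum() + var_floor[1]
    vzz = ((pz - cz) ** 2 * w).sum() + var_floor[2]
    vxy = ((px - cx) * (py - cy) * w).sum()
    lateral_size = 2.0 * np.sqrt(vxx + vyy)
    axial_size = 2.0 * np.sqrt(vzz)
    lo, hi = criteria.lateral_size
    if not (lo <= lateral_size <= hi):
        return None
    lo, hi = criteria.axial_size
    if not (lo <= axial_size <= hi):
        return None
    cov = np.array([[vxx, vxy], [vxy, vyy]])
    evals = np.linalg.eigvalsh(cov)
    ecc = float(np.sqrt(1.0 - evals[0] / evals[1])) if evals[1] > 0 else 0.0
    lo, hi = criteria.lateral_eccentricity
    if not (lo <= ecc <= hi):
        return None
    if criteria.single_axial_maximum:
        z0 = zz.min()
        profile = np.zeros(zz.max() - z0 + 1)
        np.maximum.at(profile, zz - z0, intensities)
        if len(profile) >= 3:
            sm = np.convolve(profile, np.ones(3) / 3.0, mode="same")
        else:
            sm = profile
        peaks, _ = find_peaks(
            np.concatenate([[0.0], sm, [0.0]]),
            prominence=criteria.peak_prominence_fraction * sm.max(),
        )
        if len(peaks) > 1:
            return None
    return NucleusRecord(
        id=next_id,
        time=stack.time,
        centroid=np.array([cx, cy, cz]),
        max_intensity=max_i,
        mean_intensity=mean_i,
        voxel_count=int(n_vox),
        lateral_size=float(lateral_size),
        lateral_eccentricity=ecc,
        axial_size=float(axial_size),
    )


def segment(
    stack: ImageStack,
    criteria: SegmentationCriteria | None = None,
    start_id: int = 0,
) -> list[NucleusRecord]:
    """Extract nuclei with an increasing series of global thresholds.

    At each threshold, 26-connected components of not-yet-claimed voxels
    are measured; components passing every criterion (including, when
    enabled, a single axial intensity maximum) become records and their
    voxels are removed from consideration at all higher thresholds.
    """
    criteria = criteria or SegmentationCriteria()
    data = stack.voxels
    if data.size == 0 or data.max() <= 0:
        return []
    thresholds = np.asarray(criteria.threshold_series, dtype=float)
    if thresholds.size == 0:
        thresholds = default_threshold_series(typical_peak_intensity(stack))
    available = np.ones(data.shape, dtype=bool)
    records: list[NucleusRecord] = []
    next_id = start_id

    def sweep(
        thr: float, crit: SegmentationCriteria, require_peaks=None
    ) -> None:
        nonlocal next_id
        mask = available & (data >= thr)
        labels, n_comp = ndimage.label(mask, structure=_STRUCT26)
        if n_comp == 0:
            return
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            sub = labels[sl] == lab
            zz, yy, xx = np.nonzero(sub)
            zz = zz + sl[0].start
            yy = yy + sl[1].start
            xx = xx + sl[2].start
            if require_peaks is not None and not require_peaks[zz, yy, xx].any():
                continue
            rec = _component_record(
                (zz, yy, xx), data[zz, yy, xx], stack, crit, next_id
            )
            if rec is not None:
                records.append(rec)
                next_id += 1
                available[zz, yy, xx] = False

    for thr in thresholds:
        sweep(thr, criteria)
    if criteria.fallback_relaxed:
        relaxed = SegmentationCriteria(
            voxel_count=(criteria.voxel_count[0], 4 * criteria.voxel_count[1]),
            mean_intensity=criteria.mean_intensity,
            lateral_size=(criteria.lateral_size[0], 2.5 * criteria.lateral_size[1]),
            lateral_eccentricity=(0.0, 0.98),
            axial_size=(criteria.axial_size[0], 2.5 * criteria.axial_size[1]),
            single_axial_maximum=False,
            fallback_relaxed=False,
        )
        # only blobs still holding an unclaimed intensity peak qualify:
        # the sub-threshold skirts of already-accepted nuclei do not
        peaks = peak_local_max(
            data, min_distance=2, threshold_abs=float(thresholds[0]),
            exclude_border=False,
        )
        peak_mask = np.zeros(data.shape, dtype=bool)
        peak_mask[peaks[:, 0], peaks[:, 1], peaks[:, 2]] = True
        peak_mask &= available
        sweep(float(thresholds[0]), relaxed, require_peaks=peak_mask)
    return records


def refine_centroid(
    stack: ImageStack,
    p0: np.ndarray,
    radius: float = 2.8,
    iterations: int = 2,
) -> np.ndarray:
    """Iterated centre-of-mass refinement in a symmetric spherical window.

    Thresholded connected components lose their flank voxels wherever a
    neighbour's skirt raises the local saddle, which skews the support
    asymmetrically; re-centring with a symmetric window and
    background-relative weights removes that truncation bias.
    """
    xs, ys, zs = stack.voxel_centers()
    data = stack.voxels
    p = np.asarray(p0, dtype=float).copy()
    for _ in range(iterations):
        ix = np.searchsorted(xs, [p[0] - radius, p[0] + radius])
        iy = np.searchsorted(ys, [p[1] - radius, p[1] + radius])
        iz = np.searchsorted(zs, [p[2] - radius, p[2] + radius])
        sub = data[iz[0] : iz[1], iy[0] : iy[1], ix[0] : ix[1]]
        if sub.size == 0:
            return p
        Z, Y, X = np.meshgrid(
            zs[iz[0] : iz[1]], ys[iy[0] : iy[1]], xs[ix[0] : ix[1]], indexing="ij"
        )
        inside = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 <= radius**2
        w = np.clip(sub - np.percentile(sub, 20), 0.0, None) * inside
        total = w.sum()
        if total <= 0:
            return p
        p = np.array([(X * w).sum(), (Y * w).sum(), (Z * w).sum()]) / total
    return p


def segment_stack(
    stack: ImageStack,
    criteria: SegmentationCriteria | None = None,
    hull_threshold: float | None = None,
    start_id: int = 0,
    refine_centroids: bool = True,
) -> tuple[list[NucleusRecord], AttenuationModel]:
    """Full per-stack segmentation: hull, attenuation fit, depth
    normalization, then thresholded extraction.

    ``hull_threshold`` defaults to a robust level separating tissue signal
    from background.  Returns the accepted records together with the
    fitted attenuation model.
    """
    data = stack.voxels
    if hull_threshold is None:
        hull_threshold = float(
            np.percentile(data, 55) + 0.05 * np.ptp(data)
        )
    hull = tissue_hull(stack, hull_threshold)
    try:
        model = fit_attenuation(
            attenuation_samples(stack, hull), hull_threshold=hull_threshold
        )
        normalized = normalize_intensity(stack, model, hull)
    except ValueError:
        # too few/degenerate fit samples (sparse scenes): skip correction
        model = AttenuationModel(
            coefficients=np.zeros(6), hull_threshold=hull_threshold
        )
        normalized = stack
    records = segment(normalized, criteria, start_id=start_id)
    if refine_centroids:
        for rec in records:
            rec.centroid = refine_centroid(normalized, rec.centroid)
    return records, model
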