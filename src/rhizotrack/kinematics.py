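"""Collective-motion analysis of tracked nuclei in the root frame.

Velocities are finite differences of root-frame trajectories, expressed
in cylindrical components (v_m, v_rho, rho*v_theta, all µm/min) and
attributed to the step's spatial midpoint.  Fields are binned medians
with quartiles (bins with too few samples are masked), the longitudinal
expansion is the least-squares slope of v_m against m over a fixed
region (default 80–300 µm from the tip), rigid rotation and shear are
assessed by the spatial mean of rho*v_theta and by regression slopes with
confidence intervals, and individual trajectories can be split into low-
and high-frequency components around a cutoff (default 0.23 hr^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import TrajectorySet
from .types import NucleusRecord

__all__ = [
    "VelocityField",
    "ExpansionFit",
    "compute_velocities",
    "bin_field",
    "profile_1d",
    "fit_expansion",
    "rotation_and_shear",
    "frequency_split",
    "radius_contraction",
]

FREQUENCY_CUTOFF_HR = 0.23  # boundary between directed motion and jitter
FIT_RANGE_UM = (80.0, 300.0)


@dataclass
class VelocityField:
    """Median/quartile velocity components over an (m, rho) grid."""

    m_edges: np.ndarray
    rho_edges: np.ndarray
    median: dict  # component -> (nm, nrho) array
    q25: dict
    q75: dict
    counts: np.ndarray
    min_count: int

    @property
    def mask(self) -> np.ndarray:
        """True where the bin holds at least ``min_count`` samples."""
        return self.counts >= self.min_count


def compute_velocities(
    trajectories: TrajectorySet,
    records: list[NucleusRecord],
    cyl: np.ndarray,
    time_window: tuple[float, float] | None = None,
    exclude_records: set[int] | None = None,
    lag: int = 1,
) -> pd.DataFrame:
    """Velocity samples in cylindrical components over ``lag`` frames.

    ``cyl`` holds the root-frame coordinates (m, rho, theta) per record,
    aligned with ``records``.  Steps touching ``exclude_records``
    (typically division parents/daughters) are dropped; theta differences
    are wrapped so a step across ±pi does not produce a 2*pi jump.
    Nuclear jitter is a bounded fluctuation about the advected cell
    position, so a longer lag suppresses its contribution roughly as
    1/lag while persistent drift is untouched — use ``lag`` > 1 when
    fitting weak velocity gradients, or ``lag = -1`` for one sample per
    trajectory (its endpoint displacement over its full span, the
    highest-precision estimate a trajectory can give).  Columns: t_mid,
    m_mid, rho_mid, v_m, v_rho, rho_v_theta, trajectory.
    """
    if lag < 1 and lag != -1:
        raise ValueError("lag must be >= 1, or -1 for whole trajectories")
    excl = exclude_records or set()
    rows = []
    for tr in trajectories.trajectories:
        idxs = tr.record_indices
        if lag == -1:
            # one endpoint sample per trajectory; division-touched
            # trajectories are skipped outright
            if len(idxs) <= 15 or any(k in excl for k in idxs):
                continue
            pairs = [(idxs[0], idxs[-1])]
        else:
            pairs = [
                (a, b)
                for a, b in zip(idxs[:-lag], idxs[lag:])
                if a not in excl and b not in excl
            ]
        for a, b in pairs:
            dt = records[b].time - records[a].time
            if dt <= 0:
                continue
            t_mid = 0.5 * (records[a].time + records[b].time)
            if time_window is not None and not (
                time_window[0] <= t_mid < time_window[1]
            ):
                continue
            m_a, rho_a, th_a = cyl[a]
            m_b, rho_b, th_b = cyl[b]
            dth = np.arctan2(np.sin(th_b - th_a), np.cos(th_b - th_a))
            rho_mid = 0.5 * (rho_a + rho_b)
            rows.append(
                (
                    t_mid,
                    0.5 * (m_a + m_b),
                    rho_mid,
                    (m_b - m_a) / dt,
                    (rho_b - rho_a) / dt,
                    rho_mid * dth / dt,
                    tr.id,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["t_mid", "m_mid", "rho_mid", "v_m", "v_rho", "rho_v_theta", "trajectory"],
    )


_COMPONENTS = ("v_m", "v_rho", "rho_v_theta")


def bin_field(
    samples: pd.DataFrame,
    bin_width: float = 5.0,
    min_count: int = 36,
    rho_bin_width: float | None = None,
) -> VelocityField:
    """Median and quartiles of each velocity component per (m, rho) bin.

    Bins holding fewer than ``min_count`` samples are masked.  By default
    a single rho bin is used (pure m profile); pass ``rho_bin_width`` for
    a 2D field.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    m = samples["m_mid"].to_numpy()
    rho = samples["rho_mid"].to_numpy()
    if len(m) == 0:
        raise ValueError("no velocity samples to bin")
    lo_edge = np.floor(m.min() / bin_width) * bin_width
    m_edges = np.arange(lo_edge, m.max() + bin_width, bin_width)
    if len(m_edges) < 2:
        m_edges = np.array([lo_edge, lo_edge + bin_width])
    if rho_bin_width:
        rho_edges = np.arange(0.0, rho.max() + rho_bin_width, rho_bin_width)
    else:
        rho_edges = np.array([0.0, max(rho.max(), 1e-9) + 1e-9])
    im = np.clip(np.digitize(m, m_edges) - 1, 0, len(m_edges) - 2)
    ir = np.clip(np.digitize(rho, rho_edges) - 1, 0, len(rho_edges) - 2)
    shape = (len(m_edges) - 1, len(rho_edges) - 1)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, (im, ir), 1)
    median = {c: np.full(shape, np.nan) for c in _COMPONENTS}
    q25 = {c: np.full(shape, np.nan) for c in _COMPONENTS}
    q75 = {c: np.full(shape, np.nan) for c in _COMPONENTS}
    flat = im * shape[1] + ir
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    boundaries = np.searchsorted(sorted_flat, np.arange(shape[0] * shape[1] + 1))
    for comp in _COMPONENTS:
        vals = samples[comp].to_numpy()[order]
        for cell in range(shape[0] * shape[1]):
            lo, hi = boundaries[cell], boundaries[cell + 1]
            if hi > lo:
                v = vals[lo:hi]
                qs = np.percentile(v, [25, 50, 75])
                i, r = divmod(cell, shape[1])
                q25[comp][i, r] = qs[0]
                median[comp][i, r] = qs[1]
                q75[comp][i, r] = qs[2]
    return VelocityField(
        m_edges=m_edges,
        rho_edges=rho_edges,
        median=median,
        q25=q25,
        q75=q75,
        counts=counts,
        min_count=min_count,
    )


def profile_1d(field: VelocityField, component: str = "v_m"):
    """Masked 1D profile (bin centres, median, q25, q75) along m."""
    centers = 0.5 * (field.m_edges[:-1] + field.m_edges[1:])
    med = field.median[component][:, 0]
    keep = field.mask[:, 0]
    return (
        centers[keep],
        med[keep],
        field.q25[component][:, 0][keep],
        field.q75[component][:, 0][keep],
    )


@dataclass
class ExpansionFit:
    """Linear fit of v_m against m: slope in (µm/min)/µm."""

    slope: float
    intercept: float
    fit_range: tuple[float, float]
    residual: float
    stderr: float
    n_samples: int


def fit_expansion(
    samples: pd.DataFrame,
    fit_range: tuple[float, float] = FIT_RANGE_UM,
    min_samples: int = 10,
) -> ExpansionFit:
    """Least-squares line of v_m on m over ``fit_range``."""
    m = samples["m_mid"].to_numpy()
    v = samples["v_m"].to_numpy()
    keep = (m >= fit_range[0]) & (m <= fit_range[1]) & np.isfinite(v)
    if keep.sum() < min_samples:
        raise ValueError(
            f"only {int(keep.sum())} samples in {fit_range}; need {min_samples}"
        )
    res = stats.linregress(m[keep], v[keep])
    pred = res.intercept + res.slope * m[keep]
    return ExpansionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=fit_range,
        residual=float(np.mean((v[keep] - pred) ** 2)),
        stderr=float(res.stderr),
        n_samples=int(keep.sum()),
    )


def _slope_ci(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.slope - 1.96 * res.stderr), float(
        res.slope + 1.96 * res.stderr
    )


def rotation_and_shear(samples: pd.DataFrame) -> dict:
    """Rigid-rotation estimate and twist/shear regressions.

    Returns the spatial mean of rho*v_theta with its 95% interval (rigid
    rotation), the slope of v_theta on m (twist), the slopes of v_m and
    v_theta on rho (shear), and the mean radial velocity, each with a
    confidence interval.
    """
    rvt = samples["rho_v_theta"].to_numpy()
    vr = samples["v_rho"].to_numpy()
    vm = samples["v_m"].to_numpy()
    m = samples["m_mid"].to_numpy()
    rho = samples["rho_mid"].to_numpy()
    ok = rho > 1e-9
    v_theta = np.where(ok, rvt / np.where(ok, rho, 1.0), np.nan)

    def mean_ci(x):
        x = x[np.isfinite(x)]
        se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        return float(x.mean()), float(x.mean() - 1.96 * se), float(x.mean() + 1.96 * se)

    fin = np.isfinite(v_theta)
    out = {
        "mean_rho_v_theta": mean_ci(rvt),
        "mean_v_rho": mean_ci(vr),
        "twist_slope_vtheta_on_m": _slope_ci(m[fin], v_theta[fin]),
        "shear_slope_vm_on_rho": _slope_ci(rho, vm),
        "shear_slope_vtheta_on_rho": _slope_ci(rho[fin], v_theta[fin]),
        "n_samples": int(len(samples)),
    }
    return out


def frequency_split(
    times: np.ndarray,
    values: np.ndarray,
    cutoff_hr: float = FREQUENCY_CUTOFF_HR,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a uniformly sampled trajectory at a frequency cutoff.

    ``times`` are minutes, ``values`` is (n,) or (n, d).  The discrete
    Fourier components strictly below ``cutoff_hr`` (including the mean)
    form the low-frequency part; the rest the high-frequency part.  The
    two parts sum to the input to numerical precision.
    """
    times = np.asarray(times, dtype=float)
    vals = np.asarray(values, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 samples for the frequency split")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trajectory must be uniformly sampled (interpolate gaps)")
    freqs_hr = np.fft.rfftfreq(len(times), d=dt[0] / 60.0)  # cycles per hour
    squeeze = vals.ndim == 1
    arr = vals[:, None] if squeeze else vals
    low = np.empty_like(arr)
    high = np.empty_like(arr)
    keep_low = freqs_hr < cutoff_hr
    for k in range(arr.shape[1]):
        spec = np.fft.rfft(arr[:, k])
        low[:, k] = np.fft.irfft(np.where(keep_low, spec, 0), n=len(times))
        high[:, k] = np.fft.irfft(np.where(keep_low, 0, spec), n=len(times))
    if squeeze:
        return low[:, 0], high[:, 0]
    return low, high


def interpolate_gaps(times: np.ndarray, values: np.ndarray, step: float):
    """Resample a gapped trajectory onto a uniform grid (linear), for the
    Fourier split; returns (grid_times, values, was_interpolated_mask)."""
    times = np.asarray(times, dtype=float)
    grid = np.arange(times[0], times[-1] + step / 2, step)
    vals = np.asarray(values, dtype=float)
    arr = vals[:, None] if vals.ndim == 1 else vals
    out = np.column_stack([np.interp(grid, times, arr[:, k]) for k in range(arr.shape[1])])
    observed = np.isclose(grid[:, None], times[None, :], atol=step / 4).any(axis=1)
    if vals.ndim == 1:
        out = out[:, 0]
    return grid, out, ~observed


def mean_step_displacement(
    trajectories: TrajectorySet,
    records: list[NucleusRecord],
    cyl: np.ndarray,
    drift_slope: float = 0.0,
    drift_onset_m: float = 90.0,
    drift_rho_v_theta: float = 0.0,
    exclude_records: set[int] | None = None,
    lateral_size_max: float | None = None,
    step_max: float = 5.0,
    time_step: float = 10.0,
) -> tuple[float, int]:
    """Mean per-step displacement magnitude with the collective drift
    removed — the erratic (jitter) component of nuclear motion.

    Steps are kept only between consecutive frames, away from excluded
    records (divisions), with both endpoint blobs compact
    (``lateral_size`` below a cut that defaults to the record population's
    median + 2.5 robust SD; unresolved neighbouring nuclei masquerade as
    one oversized blob whose centroid jumps) and with a magnitude below
    ``step_max`` (the largest physically observed displacement per
    interval).  The longitudinal stretch
    ``drift_slope * max(0, m - drift_onset_m)`` and the rigid rotation
    ``drift_rho_v_theta`` are subtracted before taking magnitudes.
    Returns (mean, n_steps).
    """
    excl = exclude_records or set()
    if lateral_size_max is None:
        # self-calibrated compactness cut: unresolved neighbouring pairs
        # masquerade as oversized blobs in the upper tail
        lat = np.array([r.lateral_size for r in records])
        mad = np.median(np.abs(lat - np.median(lat)))
        lateral_size_max = float(np.median(lat) + 2.5 * 1.4826 * mad)
    residuals: list[np.ndarray] = []
    start_times: list[float] = []
    for tr in trajectories.trajectories:
        idxs = tr.record_indices
        for a, b in zip(idxs[:-1], idxs[1:]):
            if a in excl or b in excl:
                continue
            ra, rb = records[a], records[b]
            if not np.isclose(rb.time - ra.time, time_step):
                continue
            if (
                ra.lateral_size > lateral_size_max
                or rb.lateral_size > lateral_size_max
            ):
                continue
            m_a, rho_a, th_a = cyl[a]
            m_b, rho_b, th_b = cyl[b]
            m_mid = 0.5 * (m_a + m_b)
            rho_mid = 0.5 * (rho_a + rho_b)
            dth = np.arctan2(np.sin(th_b - th_a), np.cos(th_b - th_a))
            dm = (m_b - m_a) - drift_slope * max(0.0, m_mid - drift_onset_m) * time_step
            dtan = rho_mid * dth - drift_rho_v_theta * time_step
            drho = rho_b - rho_a
            residuals.append(np.array([dm, dtan, drho]))
            start_times.append(ra.time)
    if not residuals:
        return np.nan, 0
    res = np.asarray(residuals)
    start_times = np.asarray(start_times)
    # residual common mode per frame pair (alignment noise is collective
    # drift too) is removed before taking magnitudes
    for t in np.unique(start_times):
        sel = start_times == t
        if sel.sum() >= 20:
            res[sel] -= np.median(res[sel], axis=0)
    mags = np.linalg.norm(res, axis=1)
    mags = mags[mags <= step_max]
    if not len(mags):
        return np.nan, 0
    return float(np.mean(mags)), int(len(mags))


def radius_contraction(
    cyl: np.ndarray,
    records: list[NucleusRecord],
    rho_threshold: float = 55.0,
) -> pd.DataFrame:
    """Count of nuclei with rho above a threshold per time point — the
    diagnostic used to justify splitting early and late windows."""
    times = np.array([r.time for r in records])
    rho = cyl[:, 1]
    out = []
    for t in np.unique(times):
        sel = times == t
        out.append((t, int(np.sum(rho[sel] > rho_threshold))))
    return pd.DataFrame(out, columns=["time", "n_outer"])
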