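"""Rigid 3D alignment across time and the root frame of reference.

Image-based registration follows the Lucas–Kanade idea: iterated
Gauss–Newton minimization of the summed squared intensity difference over
the six rigid parameters (axis-angle rotation + translation), run on a
coarse-to-fine pyramid so the small-motion assumption holds at each level.
It mirrors the microscope's tip-tracking loop, where the computed
translations reposition the stage while rotations are only estimated.

Point-cloud refinement aligns segmented centroids of adjacent time points
by alternating nearest-neighbour correspondence with the closed-form
least-squares rigid motion (Kabsch), iterated to a fixed point — the same
mean-squared-displacement objective, minimized exactly per iteration.

The root frame is the cylindrical system (m, rho, theta) anchored at the
tip: m is the distance from the tip along the root's principal axis, rho
the distance from the axis, and theta the azimuth measured from the
objective (collection) axis, with theta = pi/2 toward the laser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .types import ImageStack, NucleusRecord

__all__ = [
    "RigidMotion",
    "RootFrame",
    "register_rigid_images",
    "track_tip",
    "refine_alignment",
    "estimate_root_frame",
    "to_root_frame",
    "cylindrical_to_cartesian",
]


@dataclass
class RigidMotion:
    """Rigid map ``x -> R x + t`` taking moving-frame points into the
    reference frame; ``residual`` is the final mean squared mismatch."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidMotion") -> "RigidMotion":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidMotion(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def angle(self) -> float:
        """Rotation angle in radians."""
        return float(
            np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())
        )


def _sample(stack_voxels: np.ndarray, coords_zyx: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        stack_voxels, coords_zyx.T, order=1, mode="constant", cval=np.nan
    )


def _lk_level(
    ref: np.ndarray,
    mov: np.ndarray,
    spacing_xyz: np.ndarray,
    R0: np.ndarray,
    t0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gauss–Newton rigid registration at one pyramid level.

    Estimates the warp ``W(x) = R x + t`` (about the stack centre, in
    physical µm) such that ``mov(W(x)) ~= ref(x)``.  Each iteration
    resamples the moving image, takes the gradient of the resampled image
    in reference space, and right-composes the solved increment.  Voxels
    within two voxels of an out-of-bounds sample are excluded: gradient
    cliffs at the data edge otherwise dominate the normal equations.
    """
    nz, ny, nx = ref.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    center = 0.5 * np.array([nx - 1, ny - 1, nz - 1]) * spacing_xyz
    pts = (
        np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) * spacing_xyz
        - center
    )
    ref_flat = ref.ravel()
    border = 3
    in_core = (
        (zz.ravel() >= border)
        & (zz.ravel() < nz - border)
        & (yy.ravel() >= border)
        & (yy.ravel() < ny - border)
        & (xx.ravel() >= border)
        & (xx.ravel() < nx - border)
    )

    def resample(R: np.ndarray, t: np.ndarray):
        idx = (pts @ R.T + t + center) / spacing_xyz  # (x, y, z) voxel idx
        w = _sample(mov, idx[:, ::-1]).reshape(ref.shape)
        bad = ~np.isfinite(w)
        valid = ~ndimage.binary_dilation(bad, iterations=2).ravel() & in_core
        w_filled = np.nan_to_num(w, nan=0.0)
        if valid.sum() < 50:
            return w_filled, valid, np.inf
        r = w_filled.ravel()[valid] - ref_flat[valid]
        return w_filled, valid, float(np.mean(r**2))

    R, t = R0.copy(), t0.copy()
    w_filled, valid, cost = resample(R, t)
    for _ in range(max_iter):
        if not np.isfinite(cost):
            break
        wgz, wgy, wgx = np.gradient(w_filled, *spacing_xyz[::-1])
        g = np.column_stack([wgx.ravel(), wgy.ravel(), wgz.ravel()])[valid]
        x = pts[valid]
        r = w_filled.ravel()[valid] - ref_flat[valid]
        # right-composed increment: W_new(x) = W((I + [d]x) x + dt)
        J = np.empty((int(valid.sum()), 6))
        J[:, 0] = g[:, 1] * (-x[:, 2]) + g[:, 2] * x[:, 1]
        J[:, 1] = g[:, 0] * x[:, 2] + g[:, 2] * (-x[:, 0])
        J[:, 2] = g[:, 0] * (-x[:, 1]) + g[:, 1] * x[:, 0]
        J[:, 3:6] = g
        try:
            dp = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        # backtracking: halve the step until the cost decreases
        improved = False
        for _ in range(8):
            dR = Rotation.from_rotvec(dp[:3]).as_matrix()
            R_new = R @ dR
            t_new = R @ dp[3:6] + t
            w_new, valid_new, cost_new = resample(R_new, t_new)
            if cost_new < cost:
                improved = True
                break
            dp = dp / 2.0
        if not improved:
            break
        converged = cost - cost_new < tol * max(cost, 1e-12)
        R, t, w_filled, valid, cost = R_new, t_new, w_new, valid_new, cost_new
        if converged:
            break
    return R, t, cost


def register_rigid_images(
    reference: ImageStack,
    moving: ImageStack,
    init: RigidMotion | None = None,
    n_levels: int = 3,
    max_iter: int = 40,
    tol: float = 1e-7,
) -> RigidMotion:
    """Rigid motion mapping ``moving`` into ``reference``.

    Iterated Gauss–Newton descent on the summed squared voxel difference,
    coarse-to-fine over ``n_levels`` pyramid levels.  Both stacks must
    share the same voxel grid; the returned rotation is taken about the
    stack centre.  Raises if the final residual exceeds the initial one
    (divergence).
    """
    if init is None:
        R_w, t_w = np.eye(3), np.zeros(3)
    else:
        # init maps moving -> reference; the internal warp is its inverse
        R_w = init.rotation.T
        t_w = -init.rotation.T @ init.translation
    spacing = np.asarray(reference.voxel_sizes, dtype=float)
    ref0 = reference.voxels.astype(float)
    mov0 = moving.voxels.astype(float)
    initial_cost = float(np.mean((mov0 - ref0) ** 2))
    cost = initial_cost
    for level in range(n_levels - 1, -1, -1):
        f = 2**level
        if f > 1:
            ref_l = ndimage.zoom(ref0, 1.0 / f, order=1)
            mov_l = ndimage.zoom(mov0, 1.0 / f, order=1)
            sp = spacing * np.array(mov0.shape[::-1]) / np.array(mov_l.shape[::-1])
        else:
            ref_l, mov_l, sp = ref0, mov0, spacing
        R_w, t_w, cost = _lk_level(ref_l, mov_l, sp, R_w, t_w, max_iter, tol)
    if cost > initial_cost * 1.001 and initial_cost > 0:
        raise RuntimeError(
            f"registration diverged: residual {cost:.3g} exceeds initial "
            f"{initial_cost:.3g}"
        )
    # the warp satisfies mov(W(x)) = ref(x) with W about the stack centre;
    # the physical motion taking moving-frame points to the reference
    # frame is its inverse
    motion = RigidMotion(R_w.T, -R_w.T @ t_w, residual=cost)
    return motion


def track_tip(
    stacks: list[ImageStack], point_of_interest: np.ndarray | None = None
) -> list[RigidMotion]:
    """Per-step stage corrections keeping a point of interest fixed.

    Each consecutive pair is registered; the translation components are
    the corrections a stage would apply (rotations are estimated and
    reported but, as on the instrument, not applied).  Entry ``k`` maps
    frame ``k+1`` onto frame ``k``.
    """
    corrections = []
    for ref, mov in zip(stacks[:-1], stacks[1:]):
        motion = register_rigid_images(ref, mov)
        corrections.append(motion)
    return corrections


def refine_alignment(
    points_t: np.ndarray,
    points_t1: np.ndarray,
    init: RigidMotion | None = None,
    max_iter: int = 60,
    tol: float = 1e-8,
    allow_rotation: bool = True,
) -> RigidMotion:
    """Rigid motion aligning the point cloud at t+1 onto the one at t.

    Alternates nearest-neighbour correspondence with the least-squares
    rigid update (Kabsch) until the mean squared nearest-neighbour
    distance stops decreasing.  With ``allow_rotation=False`` only the
    translation is updated (stage-like correction).
    """
    a = np.atleast_2d(np.asarray(points_t, dtype=float))
    b = np.atleast_2d(np.asarray(points_t1, dtype=float))
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 points per time point")
    motion = init or RigidMotion.identity()
    tree = cKDTree(a)
    moved = motion.apply(b)
    prev = np.inf
    for _ in range(max_iter):
        d, j = tree.query(moved)
        msd = float(np.mean(d**2))
        if prev - msd < tol * max(prev, 1e-12):
            break
        prev = msd
        # trim unreliable correspondences (merged/missing detections)
        keep = d <= max(2.0 * np.median(d), 1.0)
        if keep.sum() < 10:
            keep = np.ones(len(d), dtype=bool)
        target = a[j[keep]]
        src = moved[keep]
        mu_b, mu_t = src.mean(axis=0), target.mean(axis=0)
        if allow_rotation:
            H = (src - mu_b).T @ (target - mu_t)
            U, _, Vt = np.linalg.svd(H)
            D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
            R_step = Vt.T @ D @ U.T
        else:
            R_step = np.eye(3)
        t_step = mu_t - R_step @ mu_b
        step = RigidMotion(R_step, t_step)
        motion = step.compose(motion)
        moved = motion.apply(b)
    d, _ = tree.query(moved)
    motion.residual = float(np.mean(d**2))
    return motion


@dataclass
class RootFrame:
    """Tip-anchored cylindrical frame, per time point.

    ``tip_origin[k]`` is the lab-frame origin of the axis at frame k;
    ``axis_direction[k]`` the unit vector of increasing m;
    ``theta_reference[k]`` the unit vector of theta = 0 (toward the
    objective).  theta = pi/2 points toward the laser (-x side).
    """

    tip_origin: np.ndarray  # (T, 3)
    axis_direction: np.ndarray  # (T, 3)
    theta_reference: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        self.tip_origin = np.atleast_2d(np.asarray(self.tip_origin, float))
        self.axis_direction = np.atleast_2d(np.asarray(self.axis_direction, float))
        self.theta_reference = np.atleast_2d(np.asarray(self.theta_reference, float))
        for k in range(len(self.axis_direction)):
            a = self.axis_direction[k]
            r = self.theta_reference[k]
            if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-6):
                raise ValueError("axis_direction must be unit length")
            if abs(a @ r) > 1e-6 or not np.isclose(np.linalg.norm(r), 1.0, atol=1e-6):
                raise ValueError("theta_reference must be unit and orthogonal to axis")

    @classmethod
    def static(
        cls,
        tip: np.ndarray,
        axis: np.ndarray = (0.0, 1.0, 0.0),
        n_frames: int = 1,
    ) -> "RootFrame":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        ref = _objective_reference(axis)
        return cls(
            np.tile(np.asarray(tip, float), (n_frames, 1)),
            np.tile(axis, (n_frames, 1)),
            np.tile(ref, (n_frames, 1)),
        )


def _objective_reference(axis: np.ndarray) -> np.ndarray:
    """Unit vector toward the objective (+z) orthogonalized to the axis."""
    zhat = np.array([0.0, 0.0, 1.0])
    ref = zhat - (zhat @ axis) * axis
    n = np.linalg.norm(ref)
    if n < 1e-9:  # axis parallel to the objective: fall back to +y
        ref = np.array([0.0, 1.0, 0.0]) - (axis[1]) * axis
        n = np.linalg.norm(ref)
    return ref / n


def estimate_root_frame(
    records_per_frame: list[list[NucleusRecord]],
    smooth_window: int = 5,
    tip_offset: float = 10.0,
    tip_percentile: float = 1.0,
) -> RootFrame:
    """Estimate the tip-anchored frame from segmented centroids.

    The axis is the principal component of each frame's centroid cloud
    (oriented tip-to-base, i.e. toward +y), the tip origin sits
    ``tip_offset`` µm distal of the most tip-ward centroids, and both are
    smoothed with a centred moving average over ``smooth_window`` frames.
    """
    axes, tips = [], []
    for recs in records_per_frame:
        pts = np.array([r.centroid for r in recs])
        if len(pts) < 3:
            raise ValueError("need at least 3 records per frame")
        c = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - c, full_matrices=False)
        axis = Vt[0]
        if axis[1] < 0:
            axis = -axis
        proj = (pts - c) @ axis
        tip_m = np.percentile(proj, tip_percentile)
        tips.append(c + (tip_m - tip_offset) * axis)
        axes.append(axis)
    axes = np.asarray(axes)
    tips = np.asarray(tips)
    if smooth_window > 1 and len(axes) > 1:
        k = min(smooth_window, len(axes))
        kern = np.ones(k) / k
        pad = k // 2
        axes = np.stack(
            [
                np.convolve(np.pad(axes[:, i], pad, mode="edge"), kern, "valid")
                for i in range(3)
            ],
            axis=1,
        )[: len(tips)]
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        tips = np.stack(
            [
                np.convolve(np.pad(tips[:, i], pad, mode="edge"), kern, "valid")
                for i in range(3)
            ],
            axis=1,
        )[: len(tips)]
    refs = np.array([_objective_reference(a) for a in axes])
    return RootFrame(tips, axes, refs)


def to_root_frame(
    points: np.ndarray, frame: RootFrame, t_index: int = 0
) -> np.ndarray:
    """Cylindrical coordinates (m, rho, theta) of lab-frame points.

    theta = 0 toward the objective, pi/2 toward the laser, in (-pi, pi];
    on-axis points report theta = 0 by convention.
    """
    if not (0 <= t_index < len(frame.tip_origin)):
        raise IndexError(f"frame index {t_index} outside root-frame coverage")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    axis = frame.axis_direction[t_index]
    e0 = frame.theta_reference[t_index]
    e1 = np.cross(e0, axis)  # toward the laser (-x when axis = +y, e0 = +z)
    d = pts - frame.tip_origin[t_index]
    m = d @ axis
    radial = d - np.outer(m, axis)
    rho = np.linalg.norm(radial, axis=1)
    theta = np.arctan2(radial @ e1, radial @ e0)
    theta[theta == -np.pi] = np.pi  # contract: theta in (-pi, pi]
    theta[rho < 1e-12] = 0.0
    out = np.column_stack([m, rho, theta])
    return out if np.asarray(points).ndim > 1 else out[0]


def cylindrical_to_cartesian(
    cyl: np.ndarray, frame: RootFrame, t_index: int = 0
) -> np.ndarray:
    """Inverse of :func:`to_root_frame`."""
    cyl = np.atleast_2d(np.asarray(cyl, dtype=float))
    axis = frame.axis_direction[t_index]
    e0 = frame.theta_reference[t_index]
    e1 = np.cross(e0, axis)
    m, rho, theta = cyl[:, 0], cyl[:, 1], cyl[:, 2]
    pts = (
        frame.tip_origin[t_index]
        + np.outer(m, axis)
        + np.outer(rho * np.cos(theta), e0)
        + np.outer(rho * np.sin(theta), e1)
    )
    return pts if np.asarray(cyl).ndim > 1 else pts[0]
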