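"""Dense and sparse 3D Lucas-Kanade optical flow.

Motion of water-proton signal between consecutive fast-fMRI volumes (100 ms
apart) is estimated voxel-wise from the brightness-constancy constraint

    Ix*u + Iy*v + Iz*w = -It,

solved per voxel by Gaussian-weighted least squares over a local window.
A coarse-to-fine multi-resolution pyramid extends the solver's range to
displacements of several voxels per frame (cardiac pulsations), while the
slow bands are solved at the base resolution.  The resulting field
V = vs_x*i + vs_y*j + vs_z*k decomposes into a speed map v_s = |V| and a
unit direction map v_hat = V / |V|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spectral import VolumeSeries

__all__ = [
    "FlowParams",
    "VelocityField",
    "BAND_PYRAMID_DEPTH",
    "lucas_kanade_3d",
    "pyramidal_flow",
    "sparse_extremum_flow",
    "to_physical_velocity",
    "decompose_velocity",
]

#: Pyramid depth (levels above the base resolution) per pulsation band:
#: cardiac displacements reach several voxels per frame and need the
#: deepest pyramid; vasomotor motion is sub-voxel and is solved directly.
BAND_PYRAMID_DEPTH = {"cardiac": 3, "respiratory": 1, "vasomotor": 0}

_MIN_LEVEL_VOXELS = 8


@dataclass(frozen=True)
class FlowParams:
    """Lucas-Kanade solver parameters.

    ``window_radius`` r gives a (2r+1)^3 window with Gaussian weights of
    scale ``weight_sigma`` (default r / 1.5).  Voxels whose structure
    tensor has smallest eigenvalue below ``conditioning_threshold`` times
    its trace are flagged invalid (aperture problem / flat signal).
    """

    window_radius: int = 2
    pyramid_depth: int = 0
    band_name: str = ""
    weight_sigma: float | None = None
    conditioning_threshold: float = 1e-4
    n_iter: int = 1
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.pyramid_depth < 0:
            raise ValueError("pyramid_depth must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def sigma(self) -> float:
        return self.weight_sigma if self.weight_sigma is not None else self.window_radius / 1.5


@dataclass
class VelocityField:
    """Per-frame, per-voxel velocity 3-vectors.

    ``components`` has shape ``(n_frames, nx, ny, nz, 3)`` ordered
    (x, y, z) in voxel space; ``valid_mask`` flags voxels where the solve
    was well conditioned.  ``units`` is ``"voxel/frame"`` or ``"cm/s"``.
    """

    components: np.ndarray
    valid_mask: np.ndarray
    units: str = "voxel/frame"
    band_name: str = ""

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.components.ndim != 5 or self.components.shape[-1] != 3:
            raise ValueError("components must have shape (t, x, y, z, 3)")
        if self.valid_mask.shape != self.components.shape[:-1]:
            raise ValueError("valid_mask shape must match components[:-1]")

    @property
    def n_frames(self) -> int:
        return self.components.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.components, axis=-1)


def _gauss_kernel(radius: int, sigma: float) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _window_sum(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = vol
    for ax in range(3):
        out = ndimage.correlate1d(out, kernel, axis=ax, mode="reflect")
    return out


def _smallest_eigval_sym3(
    axx: np.ndarray, axy: np.ndarray, axz: np.ndarray,
    ayy: np.ndarray, ayz: np.ndarray, azz: np.ndarray,
) -> np.ndarray:
    """Smallest eigenvalue of symmetric 3x3 matrices, vectorized.

    Closed-form trigonometric solution for symmetric 3x3 eigenvalues;
    avoids per-voxel LAPACK calls on whole volumes.
    """
    q = (axx + ayy + azz) / 3.0
    bxx, byy, bzz = axx - q, ayy - q, azz - q
    p2 = (bxx**2 + byy**2 + bzz**2 + 2.0 * (axy**2 + axz**2 + ayz**2)) / 6.0
    p = np.sqrt(p2)
    # det(B) for symmetric B with diagonal bxx,byy,bzz and off-diag axy,axz,ayz
    detb = (
        bxx * (byy * bzz - ayz**2)
        - axy * (axy * bzz - ayz * axz)
        + axz * (axy * ayz - byy * axz)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = detb / (2.0 * p**3)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    # smallest eigenvalue: q + 2 p cos(phi + 2*pi/3)
    lam_min = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    return np.where(p > 0, lam_min, q)


def _lk_solve(
    prev: np.ndarray,
    nxt: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-level LK normal-equations solve; returns (flow, valid)."""
    avg = 0.5 * (prev + nxt)
    gx, gy, gz = np.gradient(avg, axis=(0, 1, 2))
    gt = nxt - prev

    kernel = _gauss_kernel(params.window_radius, params.sigma)
    sxx = _window_sum(gx * gx, kernel)
    sxy = _window_sum(gx * gy, kernel)
    sxz = _window_sum(gx * gz, kernel)
    syy = _window_sum(gy * gy, kernel)
    syz = _window_sum(gy * gz, kernel)
    szz = _window_sum(gz * gz, kernel)
    bx = -_window_sum(gx * gt, kernel)
    by = -_window_sum(gy * gt, kernel)
    bz = -_window_sum(gz * gt, kernel)

    trace = sxx + syy + szz
    lam_min = _smallest_eigval_sym3(sxx, sxy, sxz, syy, syz, szz)
    valid = lam_min > params.conditioning_threshold * np.maximum(trace, 1e-300)
    # signal floor: numerically flat regions pass the relative eigenvalue
    # test on round-off noise; require a minimal fraction of the strongest
    # local gradient energy in the volume
    valid &= trace > 1e-9 * trace.max()

    flow = np.zeros(prev.shape + (3,), dtype=np.float64)
    if valid.any():
        # optional Tikhonov damping: directions the local structure tensor
        # does not constrain (aperture problem) are shrunk toward zero
        # instead of amplifying the unconstrained component
        ridge = params.ridge * trace[valid]
        a = np.empty((int(valid.sum()), 3, 3))
        a[:, 0, 0] = sxx[valid]
        a[:, 0, 1] = a[:, 1, 0] = sxy[valid]
        a[:, 0, 2] = a[:, 2, 0] = sxz[valid]
        a[:, 1, 1] = syy[valid]
        a[:, 1, 2] = a[:, 2, 1] = syz[valid]
        a[:, 2, 2] = szz[valid]
        if params.ridge > 0:
            a[:, 0, 0] += ridge
            a[:, 1, 1] += ridge
            a[:, 2, 2] += ridge
        b = np.stack([bx[valid], by[valid], bz[valid]], axis=-1)
        flow[valid] = np.linalg.solve(a, b[..., None])[..., 0]
    return flow, valid


def lucas_kanade_3d(
    prev: np.ndarray, nxt: np.ndarray, params: FlowParams | None = None
) -> VelocityField:
    """Single-level dense 3D Lucas-Kanade flow between two volumes.

    Spatial gradients are central differences of the frame average,
    the temporal gradient is the two-frame forward difference, and
    volumes are reflect-padded so output shape matches input.  Returns a
    one-frame :class:`VelocityField` in voxels/frame.
    """
    params = params or FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    nxt = np.asarray(nxt, dtype=np.float64)
    if prev.shape != nxt.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {nxt.shape}")
    if prev.ndim != 3:
        raise ValueError("volumes must be 3D")
    flow, valid = _lk_solve(prev, nxt, params)
    return VelocityField(flow[None], valid[None], "voxel/frame", params.band_name)


def _downsample(vol: np.ndarray) -> np.ndarray:
    """Halve each axis with Gaussian anti-aliasing."""
    sm = ndimage.gaussian_filter(vol, sigma=1.0, mode="reflect")
    return sm[::2, ::2, ::2]


def _upsample_flow(flow: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Upscale a flow field to ``target_shape`` and double its values."""
    out = np.empty(target_shape + (3,), dtype=np.float64)
    zoom = [t / s for t, s in zip(target_shape, flow.shape[:3])]
    for c in range(3):
        out[..., c] = ndimage.zoom(flow[..., c], zoom, order=1, mode="nearest")
    return 2.0 * out


def _warp(vol: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Inverse-warp ``vol`` by ``flow``: result(x) = vol(x + flow(x))."""
    idx = np.indices(vol.shape, dtype=np.float64)
    coords = idx + np.moveaxis(flow, -1, 0)
    return ndimage.map_coordinates(vol, coords, order=1, mode="reflect")


def _flow_pair(
    prev: np.ndarray, nxt: np.ndarray, params: FlowParams
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-to-fine LK between one volume pair."""
    depth = params.pyramid_depth
    pyr_prev, pyr_nxt = [prev], [nxt]
    for _ in range(depth):
        if min(pyr_prev[-1].shape) // 2 < _MIN_LEVEL_VOXELS:
            raise ValueError(
                f"volume {prev.shape} too small for pyramid depth {depth} "
                f"(every level needs >= {_MIN_LEVEL_VOXELS} voxels per axis)"
            )
        pyr_prev.append(_downsample(pyr_prev[-1]))
        pyr_nxt.append(_downsample(pyr_nxt[-1]))

    flow = None
    valid = None
    for lvl in range(depth, -1, -1):
        p, n = pyr_prev[lvl], pyr_nxt[lvl]
        if flow is not None:
            flow = _upsample_flow(flow, p.shape)
        # warp-and-refine iterations per level; with n_iter=1 and no
        # initial flow this is the plain normal-equations solve
        for it in range(params.n_iter):
            if flow is None:
                flow, valid = _lk_solve(p, n, params)
            else:
                warped = _warp(n, flow)
                resid, valid = _lk_solve(p, warped, params)
                # the LK linearization is only trustworthy within the
                # window; clamp runaway residuals at ill-posed voxels
                rnorm = np.linalg.norm(resid, axis=-1, keepdims=True)
                cap = float(params.window_radius)
                resid = np.where(rnorm > cap, resid * (cap / np.maximum(rnorm, 1e-30)), resid)
                flow = flow + resid
    flow = np.where(valid[..., None], flow, 0.0)  # rejected voxels: zero velocity
    return flow, valid


def pyramidal_flow(series: VolumeSeries, params: FlowParams) -> VelocityField:
    """Dense multi-resolution LK flow over a whole series.

    Flow is estimated at the coarsest pyramid level, upscaled (values
    doubled), used to warp the next-finer level, and refined, down to the
    base resolution.  Depth 0 reduces exactly to :func:`lucas_kanade_3d`.
    One field is produced per consecutive frame pair (``n_frames - 1``).
    """
    data = np.asarray(series.data, dtype=np.float64)
    if data.shape[0] < 2:
        raise ValueError("series needs at least two frames")
    n_pairs = data.shape[0] - 1
    comps = np.zeros((n_pairs,) + series.grid_shape + (3,), dtype=np.float32)
    valid = np.zeros((n_pairs,) + series.grid_shape, dtype=bool)
    for t in range(n_pairs):
        f, v = _flow_pair(data[t], data[t + 1], params)
        comps[t] = f
        valid[t] = v
    return VelocityField(comps, valid, "voxel/frame", params.band_name)


def _refine_extremum(vol: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """Sub-voxel extremum position by per-axis parabolic interpolation."""
    pos = np.array(idx, dtype=np.float64)
    for ax in range(3):
        i = idx[ax]
        if 0 < i < vol.shape[ax] - 1:
            sl = list(idx)
            sl[ax] = slice(i - 1, i + 2)
            a, b, c = vol[tuple(sl)]
            denom = a - 2 * b + c
            if abs(denom) > 1e-12:
                # sub-voxel offset of a sampled extremum is at most half a
                # voxel; clip degenerate parabolas
                pos[ax] += np.clip(0.5 * (a - c) / denom, -0.5, 0.5)
    return pos


def sparse_extremum_flow(
    series: VolumeSeries,
    feature: str = "min",
    params: FlowParams | None = None,
    roi: np.ndarray | None = None,
    prominence_sd: float = 2.0,
    search_radius: int = 3,
) -> VelocityField:
    """Sparse flow tracking a single moving intensity extremum.

    Follows the location of the global minimum (e.g. the pulse-induced
    signal nadir) or maximum frame by frame, with sub-voxel parabolic
    refinement; the velocity is the displacement of that feature between
    consecutive frames, defined only at the tracked location.  After the
    first frame the search is confined to ``search_radius`` voxels around
    the previous position (feature continuity), so the tracker follows
    one feature instead of hopping between look-alikes.  Raises if the
    extremum never stands out from the frame by ``prominence_sd``
    standard deviations.
    """
    params = params or FlowParams()
    if feature not in ("min", "max"):
        raise ValueError("feature must be 'min' or 'max'")
    data = np.asarray(series.data, dtype=np.float64)
    if data.shape[0] < 2:
        raise ValueError("series needs at least two frames")
    mask = np.ones(series.grid_shape, bool) if roi is None else np.asarray(roi, bool)

    positions = []
    prominent = False
    prev_idx = None
    for t in range(data.shape[0]):
        frame = data[t]
        search = mask
        if prev_idx is not None:
            box = np.zeros_like(mask)
            sl = tuple(
                slice(max(0, i - search_radius), i + search_radius + 1)
                for i in prev_idx
            )
            box[sl] = True
            search = mask & box
            if not search.any():
                search = mask
        vals = np.where(search, frame, np.inf if feature == "min" else -np.inf)
        flat = int(np.argmin(vals) if feature == "min" else np.argmax(vals))
        idx = np.unravel_index(flat, frame.shape)
        prev_idx = idx
        sd = frame[mask].std()
        if sd > 0 and abs(frame[idx] - frame[mask].mean()) >= prominence_sd * sd:
            prominent = True
        positions.append(_refine_extremum(frame, idx))
    if not prominent:
        raise ValueError(
            f"no {feature} feature exceeding {prominence_sd} SD prominence; "
            "nothing to track"
        )

    n_pairs = data.shape[0] - 1
    comps = np.zeros((n_pairs,) + series.grid_shape + (3,), dtype=np.float32)
    valid = np.zeros((n_pairs,) + series.grid_shape, dtype=bool)
    for t in range(n_pairs):
        disp = positions[t + 1] - positions[t]
        vox = tuple(
            int(np.clip(round(p), 0, s - 1))
            for p, s in zip(positions[t], series.grid_shape)
        )
        comps[(t,) + vox] = disp
        valid[(t,) + vox] = True
    return VelocityField(comps, valid, "voxel/frame", params.band_name)


def to_physical_velocity(
    field: VelocityField, voxel_size_mm: float, fs: float
) -> VelocityField:
    """Convert voxels/frame to cm/s: scale by (voxel_size_mm / 10) * fs."""
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if field.units == "cm/s":
        raise ValueError("field is already in cm/s")
    scale = (voxel_size_mm / 10.0) * fs
    return VelocityField(
        field.components * scale, field.valid_mask.copy(), "cm/s", field.band_name
    )


def decompose_velocity(
    field: VelocityField, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Split a velocity field into speed v_s and unit direction v_hat.

    Returns ``(speed, direction)`` where ``speed = |V| >= 0`` and
    ``direction = V / |V|`` (NaN where ``speed <= eps`` or the solve was
    invalid; the direction of a vanishing vector is undefined).
    ``speed[..., None] * direction`` reconstructs the field where defined.
    """
    speed = np.linalg.norm(field.components, axis=-1)
    defined = (speed > eps) & field.valid_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        direction = field.components / speed[..., None]
    direction = np.where(defined[..., None], direction, np.nan)
    return speed, direction
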