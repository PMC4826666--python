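"""Coarse-to-fine 2D cross-correlation displacement estimation on RF data.

Three iterations: a large-kernel coarse pass finds integer-sample offsets
over a sparse grid; a small-kernel pass refines on the fine grid using the
coarse map as search-window offset; the final pass locally aligns the
post-deformation frame by the current estimate (bilinear re-sampling) and
adds parabolic subsample interpolation of the correlation peak.  A 5 x 5
median filter cleans each iteration's map.  Correlation is zero-mean
normalized cross-correlation (robust to amplitude drift).

The default schedule uses template/search kernels of 3850 x 715 µm over
7700 x 935 µm (axial x lateral, 50% / 92% overlap) for the coarse pass and
60 x 715 µm over 120 x 935 µm (75% / 92%) for both fine passes, giving a
final displacement grid of 15 µm axially and 55 µm laterally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.ndimage import median_filter
from skimage.feature import match_template

from plaquemech.errors import TrackingError
from plaquemech.ultrasound import RFFrame

__all__ = ["KernelStage", "KernelSchedule", "DisplacementMap",
           "default_schedule", "ncc_surface", "parabolic_subsample",
           "median_filter_displacements", "estimate_displacement",
           "accumulate_displacement",
           "write_displacement_map", "read_displacement_map"]


@dataclass(frozen=True)
class KernelStage:
    """One iteration: template/search kernel sizes (axial, lateral) in µm,
    overlap fractions per axis, and refinement flags."""

    template_um: tuple
    search_um: tuple
    overlap: tuple
    local_align: bool = False
    subsample: bool = False

    def __post_init__(self):
        if (self.search_um[0] < self.template_um[0]
                or self.search_um[1] < self.template_um[1]):
            raise ValueError("search kernel must be at least template size per axis")
        if not all(0.0 <= o < 1.0 for o in self.overlap):
            raise ValueError("overlaps must lie in [0, 1)")

    def grid_step_um(self):
        """Template-grid step per axis: template size x (1 - overlap)."""
        return (self.template_um[0] * (1.0 - self.overlap[0]),
                self.template_um[1] * (1.0 - self.overlap[1]))


@dataclass(frozen=True)
class KernelSchedule:
    stages: tuple

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("schedule needs at least one stage")

    def final_grid_step_um(self):
        return self.stages[-1].grid_step_um()


def default_schedule() -> KernelSchedule:
    """The three-iteration schedule with the standard printed kernel sizes.

    The final stage's axial grid step is 60 µm x (1 - 0.75) = 15 µm.
    """
    s1 = KernelStage((3850.0, 715.0), (7700.0, 935.0), (0.50, 0.92))
    s2 = KernelStage((60.0, 715.0), (120.0, 935.0), (0.75, 0.92))
    s3 = KernelStage((60.0, 715.0), (120.0, 935.0), (0.75, 0.92),
                     local_align=True, subsample=True)
    return KernelSchedule((s1, s2, s3))


def _to_even_samples(size_um: float, step_um: float, minimum: int = 8) -> int:
    """Physical size -> integer sample count: floor to even, at least 8."""
    n = int(np.floor(size_um / step_um))
    n -= n % 2
    return max(n, minimum)


@dataclass
class _StageGeom:
    """Stage kernel geometry in integer samples/lines."""

    ta: int
    tl: int
    ma: int
    ml: int
    step_ax: int
    step_lat: int


def _stage_geometry(stage: KernelStage, axial_step_um: float,
                    pitch_um: float) -> _StageGeom:
    ta = _to_even_samples(stage.template_um[0], axial_step_um)
    tl = _to_even_samples(stage.template_um[1], pitch_um)
    sa = _to_even_samples(stage.search_um[0], axial_step_um)
    sl = _to_even_samples(stage.search_um[1], pitch_um)
    step_ax = max(1, int(round(ta * (1.0 - stage.overlap[0]))))
    step_lat = max(1, int(round(tl * (1.0 - stage.overlap[1]))))
    return _StageGeom(ta, tl, (sa - ta) // 2, (sl - tl) // 2, step_ax, step_lat)


@dataclass
class DisplacementMap:
    """Estimated displacements on a regular grid.

    axial_um / lateral_um: (rows, cols) arrays; NaN marks nodes where no
    valid correlation was possible.  Grid steps in µm, origin (mm) is the
    center of the first template.
    """

    axial_um: np.ndarray
    lateral_um: np.ndarray
    grid_axial_step_um: float
    grid_lateral_step_um: float
    origin_mm: tuple

    def __post_init__(self):
        self.axial_um = np.asarray(self.axial_um, float)
        self.lateral_um = np.asarray(self.lateral_um, float)
        if self.axial_um.shape != self.lateral_um.shape:
            raise ValueError("axial and lateral maps must share shape")

    @property
    def shape(self):
        return self.axial_um.shape

    def node_positions_mm(self):
        """(y (rows,), x (cols,)) grid-node coordinates in mm."""
        ny, nx = self.shape
        y = self.origin_mm[1] + np.arange(ny) * self.grid_axial_step_um * 1e-3
        x = self.origin_mm[0] + np.arange(nx) * self.grid_lateral_step_um * 1e-3
        return y, x


def ncc_surface(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Zero-mean normalized cross-correlation at every integer lag.

    ``search`` must be strictly larger than ``template`` in at least one
    axis; returns an array of shape (search - template + 1) with values in
    [-1, 1].  Raises :class:`TrackingError` for a zero-variance template.
    """
    template = np.asarray(template, float)
    search = np.asarray(search, float)
    if search.shape[0] < template.shape[0] or search.shape[1] < template.shape[1]:
        raise TrackingError("search must contain the template")
    if search.shape == template.shape:
        raise TrackingError("search must be strictly larger in at least one axis")
    if np.ptp(template) == 0:
        raise TrackingError("zero-variance template (flat signal region)")
    surf = match_template(search, template)
    return np.clip(surf, -1.0, 1.0)


def parabolic_subsample(c_minus: float, c_peak: float, c_plus: float) -> float:
    """Subsample peak offset from three correlation samples.

    delta = (c- - c+) / (2 (c- - 2 c0 + c+)), clipped to [-0.5, 0.5].
    A flat (degenerate) triple returns 0 with a warning.
    """
    if c_peak < max(c_minus, c_plus):
        raise ValueError("center sample must be the peak")
    denom = c_minus - 2.0 * c_peak + c_plus
    if denom == 0.0:
        warnings.warn("flat correlation triple; subsample offset set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.clip((c_minus - c_plus) / (2.0 * denom), -0.5, 0.5))


def median_filter_displacements(dmap: DisplacementMap,
                                size: int = 5) -> DisplacementMap:
    """Componentwise median filter (reflect padding at the edges)."""
    if min(dmap.shape) < size:
        raise TrackingError(f"map smaller than the {size}x{size} median kernel")
    return DisplacementMap(
        median_filter(dmap.axial_um, size=size, mode="reflect"),
        median_filter(dmap.lateral_um, size=size, mode="reflect"),
        dmap.grid_axial_step_um, dmap.grid_lateral_step_um, dmap.origin_mm)


def _median_clean(arr, size=5):
    """NaN-aware median filter (reflect padding), tolerating small maps.

    Nodes that are NaN stay NaN; valid nodes take the median of the valid
    values in their window.
    """
    # an axis shorter than the window is left unfiltered: on a coarse map
    # with very few rows the window would mix physically distant regions
    ra = size // 2 if arr.shape[0] >= size else 0
    rl = size // 2 if arr.shape[1] >= size else 0
    padded = np.pad(arr, ((ra, ra), (rl, rl)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * ra + 1, 2 * rl + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(win, axis=(-2, -1))
    out[~np.isfinite(arr)] = np.nan
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _match_stage(pre, post, i0s, j0s, off_ax, off_lat, ta, tl, ma, ml,
                 lag_ax, lag_lat, trip_ax, trip_lat, valid, tstd):
    ns, nl = pre.shape
    nn = i0s.shape[0]
    ncorr = (2 * ma + 1) * (2 * ml + 1)
    surf = np.empty((2 * ma + 1, 2 * ml + 1))
    for n in range(nn):
        i0, j0 = i0s[n], j0s[n]
        tm = 0.0
        for p in range(ta):
            for q in range(tl):
                tm += pre[i0 + p, j0 + q]
        tm /= ta * tl
        tss = 0.0
        for p in range(ta):
            for q in range(tl):
                d = pre[i0 + p, j0 + q] - tm
                tss += d * d
        tstd[n] = np.sqrt(tss / (ta * tl))
        if tss <= 0.0:
            valid[n] = False
            continue
        best = -2.0
        bda, bdl = 0, 0
        for da in range(-ma, ma + 1):
            ii = i0 + off_ax[n] + da
            for dl in range(-ml, ml + 1):
                jj = j0 + off_lat[n] + dl
                if ii < 0 or ii + ta > ns or jj < 0 or jj + tl > nl:
                    surf[da + ma, dl + ml] = -2.0
                    continue
                sm = 0.0
                ss = 0.0
                sc = 0.0
                for p in range(ta):
                    for q in range(tl):
                        v = post[ii + p, jj + q]
                        sm += v
                        ss += v * v
                        sc += pre[i0 + p, j0 + q] * v
                cov = sc - tm * sm
                var = ss - sm * sm / (ta * tl)
                c = cov / np.sqrt(tss * var) if var > 0.0 else -2.0
                surf[da + ma, dl + ml] = c
                if c > best or (c == best and da * da + dl * dl < bda * bda + bdl * bdl):
                    best = c
                    bda, bdl = da, dl
        if best <= -2.0:
            valid[n] = False
            continue
        valid[n] = True
        lag_ax[n] = bda
        lag_lat[n] = bdl
        for k in range(3):
            trip_ax[n, k] = best
            trip_lat[n, k] = best
        if bda > -ma and bda < ma:
            trip_ax[n, 0] = surf[bda + ma - 1, bdl + ml]
            trip_ax[n, 2] = surf[bda + ma + 1, bdl + ml]
        if bdl > -ml and bdl < ml:
            trip_lat[n, 0] = surf[bda + ma, bdl + ml - 1]
            trip_lat[n, 2] = surf[bda + ma, bdl + ml + 1]


@njit(cache=True, inline="always")
def _bilinear(img, y, x):
    ns, nl = img.shape
    iy = int(np.floor(y))
    ix = int(np.floor(x))
    if iy < 0 or ix < 0 or iy + 1 >= ns or ix + 1 >= nl:
        return np.nan
    fy = y - iy
    fx = x - ix
    return ((1 - fy) * (1 - fx) * img[iy, ix] + (1 - fy) * fx * img[iy, ix + 1]
            + fy * (1 - fx) * img[iy + 1, ix] + fy * fx * img[iy + 1, ix + 1])


@njit(cache=True)
def _aligned_stage(pre, post, i0s, j0s, est_ax, est_lat, ta, tl, ma, ml,
                   lag_ax, lag_lat, trip_ax, trip_lat, valid, tstd):
    """Block matching against a locally aligned (bilinear re-sampled) post
    frame; estimates are float sample offsets."""
    ns, nl = pre.shape
    nn = i0s.shape[0]
    patch = np.empty((ta + 2 * ma, tl + 2 * ml))
    surf = np.empty((2 * ma + 1, 2 * ml + 1))
    for n in range(nn):
        i0, j0 = i0s[n], j0s[n]
        ok = True
        for p in range(ta + 2 * ma):
            for q in range(tl + 2 * ml):
                v = _bilinear(post, i0 - ma + p + est_ax[n], j0 - ml + q + est_lat[n])
                if np.isnan(v):
                    ok = False
                patch[p, q] = v
        if not ok:
            valid[n] = False
            continue
        tm = 0.0
        for p in range(ta):
            for q in range(tl):
                tm += pre[i0 + p, j0 + q]
        tm /= ta * tl
        tss = 0.0
        for p in range(ta):
            for q in range(tl):
                d = pre[i0 + p, j0 + q] - tm
                tss += d * d
        tstd[n] = np.sqrt(tss / (ta * tl))
        if tss <= 0.0:
            valid[n] = False
            continue
        best = -2.0
        bda, bdl = 0, 0
        for da in range(-ma, ma + 1):
            for dl in range(-ml, ml + 1):
                sm = 0.0
                ss = 0.0
                sc = 0.0
                for p in range(ta):
                    for q in range(tl):
                        v = patch[ma + da + p, ml + dl + q]
                        sm += v
                        ss += v * v
                        sc += pre[i0 + p, j0 + q] * v
                cov = sc - tm * sm
                var = ss - sm * sm / (ta * tl)
                c = cov / np.sqrt(tss * var) if var > 0.0 else -2.0
                surf[da + ma, dl + ml] = c
                if c > best or (c == best and da * da + dl * dl < bda * bda + bdl * bdl):
                    best = c
                    bda, bdl = da, dl
        if best <= -2.0:
            valid[n] = False
            continue
        valid[n] = True
        lag_ax[n] = bda
        lag_lat[n] = bdl
        for k in range(3):
            trip_ax[n, k] = best
            trip_lat[n, k] = best
        if -ma < bda < ma:
            trip_ax[n, 0] = surf[bda + ma - 1, bdl + ml]
            trip_ax[n, 2] = surf[bda + ma + 1, bdl + ml]
        if -ml < bdl < ml:
            trip_lat[n, 0] = surf[bda + ma, bdl + ml - 1]
            trip_lat[n, 2] = surf[bda + ma, bdl + ml + 1]


def _fft_match(pre, post, i_flat, j_flat, off_ax, off_lat, ta, tl, ma, ml,
               lag_ax, lag_lat, trip_ax, trip_lat, valid, tstd):
    """FFT-based NCC stage for large kernels (per-node match_template)."""
    ns, nl = pre.shape
    for n in range(len(i_flat)):
        i0, j0 = int(i_flat[n]), int(j_flat[n])
        T = pre[i0:i0 + ta, j0:j0 + tl]
        tstd[n] = T.std()
        if np.ptp(T) == 0:
            valid[n] = False
            continue
        ii0 = i0 + int(off_ax[n]) - ma
        jj0 = j0 + int(off_lat[n]) - ml
        ci0, cj0 = max(ii0, 0), max(jj0, 0)
        ci1 = min(ii0 + ta + 2 * ma, ns)
        cj1 = min(jj0 + tl + 2 * ml, nl)
        S = post[ci0:ci1, cj0:cj1]
        if S.shape[0] < ta or S.shape[1] < tl:
            valid[n] = False
            continue
        if S.shape == T.shape:
            valid[n] = False
            continue
        surf = match_template(S, T)
        m = surf.max()
        cand = np.argwhere(surf >= m - 1e-12)
        lags_a = ci0 + cand[:, 0] - i0 - off_ax[n]
        lags_l = cj0 + cand[:, 1] - j0 - off_lat[n]
        pick = int(np.argmin(lags_a ** 2 + lags_l ** 2))
        pr, pc = cand[pick]
        valid[n] = True
        lag_ax[n] = lags_a[pick]
        lag_lat[n] = lags_l[pick]
        trip_ax[n, :] = m
        trip_lat[n, :] = m
        if 0 < pr < surf.shape[0] - 1:
            trip_ax[n, 0] = surf[pr - 1, pc]
            trip_ax[n, 2] = surf[pr + 1, pc]
        if 0 < pc < surf.shape[1] - 1:
            trip_lat[n, 0] = surf[pr, pc - 1]
            trip_lat[n, 2] = surf[pr, pc + 1]


def _parabolic_vec(trip):
    """Vectorized 3-point parabolic refinement; degenerate triples -> 0."""
    denom = trip[:, 0] - 2.0 * trip[:, 1] + trip[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (trip[:, 0] - trip[:, 2]) / (2.0 * denom)
    delta[~np.isfinite(delta)] = 0.0
    return np.clip(delta, -0.5, 0.5)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def _node_grid(n_total, t_size, step, lo=0, hi=None):
    """Template start indices with given step, clipped to the frame."""
    hi = n_total - t_size if hi is None else min(hi, n_total - t_size)
    if hi < lo:
        raise TrackingError("frame too small for the kernel schedule")
    return np.arange(lo, hi + 1, step, dtype=np.int64)


def _fill_nearest(arr):
    """Replace NaNs with the nearest finite value (all-NaN -> zeros)."""
    from scipy.ndimage import distance_transform_edt
    mask = ~np.isfinite(arr)
    if not mask.any():
        return arr
    if mask.all():
        return np.zeros_like(arr)
    idx = distance_transform_edt(mask, return_distances=False,
                                 return_indices=True)
    return arr[tuple(idx)]


def _interp_to(src_rows, src_cols, src, dst_rows, dst_cols):
    """Bilinear interpolation of a coarse map onto a finer node grid, with
    edge clamping; NaNs are filled from the nearest valid node first."""
    a = _fill_nearest(src)
    r = np.clip(np.interp(dst_rows, src_rows, np.arange(len(src_rows)))
                if len(src_rows) > 1 else np.zeros(len(dst_rows)), 0, len(src_rows) - 1)
    c = np.clip(np.interp(dst_cols, src_cols, np.arange(len(src_cols)))
                if len(src_cols) > 1 else np.zeros(len(dst_cols)), 0, len(src_cols) - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, len(src_rows) - 1)
    c1 = np.minimum(c0 + 1, len(src_cols) - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    return ((1 - fr) * (1 - fc) * a[np.ix_(r0, c0)] + (1 - fr) * fc * a[np.ix_(r0, c1)]
            + fr * (1 - fc) * a[np.ix_(r1, c0)] + fr * fc * a[np.ix_(r1, c1)])


def estimate_displacement(rf_pre: RFFrame, rf_post: RFFrame,
                          schedule: KernelSchedule | None = None,
                          roi_mm: tuple | None = None,
                          align_margin: int = 2,
                          align_passes: int = 2,
                          min_correlation: float = 0.15,
                          signal_gate: float = 0.1,
                          prior: DisplacementMap | None = None) -> DisplacementMap:
    """Estimate the displacement field between two RF frames (µm).

    ``roi_mm`` = (x_min, x_max, y_min, y_max) restricts template centers to
    a region of interest (windows may still read RF outside it).  The final
    local-alignment pass searches ±``align_margin`` integer lags around the
    aligned position before parabolic refinement; after alignment the
    residual is subsample, so a small margin suffices.  The alignment is
    applied ``align_passes`` times: re-aligning at the fractional estimate
    drives the residual lag toward zero, where the parabolic interpolator
    is unbiased (a single pass leaves the known parabola-on-carrier bias
    of a few hundredths of a sample).

    Anechoic regions (lumen, bath) carry no trackable speckle: a node is
    kept only if its template RF standard deviation exceeds ``signal_gate``
    times the strong-signal level (95th percentile over the grid) and its
    correlation peak reaches ``min_correlation``; gated nodes are NaN and
    are excluded from the search-offset propagation between iterations.

    ``prior`` supplies an expected displacement map (µm, e.g. the previous
    increment of a quasi-static sequence): the fine pass then evaluates
    both the coarse-pass offsets and the prior's offsets and keeps the
    better correlation peak per node.  This protects regions where the
    coarse templates are dominated by anechoic content and their peak can
    lose to noise.

    Raises :class:`TrackingError` on mismatched frames or all-zero input.
    """
    if rf_pre.samples.shape != rf_post.samples.shape:
        raise TrackingError("frames must share shape")
    if (rf_pre.axial_step_um != rf_post.axial_step_um
            or rf_pre.line_pitch_um != rf_post.line_pitch_um):
        raise TrackingError("frames must share transducer metadata")
    if np.ptp(rf_pre.samples) == 0 or np.ptp(rf_post.samples) == 0:
        raise TrackingError("all-zero RF frame")
    schedule = schedule or default_schedule()
    pre = np.ascontiguousarray(rf_pre.samples, float)
    post = np.ascontiguousarray(rf_post.samples, float)
    dy = rf_pre.axial_step_um
    dx = rf_pre.line_pitch_um
    ns, nl = pre.shape

    est_ax = est_lat = None
    rows_prev = cols_prev = None
    geom = None
    for k, stage in enumerate(schedule.stages):
        geom = _stage_geometry(stage, dy, dx)
        lo_ax, hi_ax = 0, None
        lo_lat, hi_lat = 0, None
        if roi_mm is not None:
            x_lo = (roi_mm[0] - rf_pre.x0_mm) * 1e3 / dx
            x_hi = (roi_mm[1] - rf_pre.x0_mm) * 1e3 / dx
            y_lo = roi_mm[2] * 1e3 / dy
            y_hi = roi_mm[3] * 1e3 / dy
            lo_ax = max(0, int(y_lo - geom.ta / 2))
            hi_ax = int(y_hi - geom.ta / 2)
            lo_lat = max(0, int(x_lo - geom.tl / 2))
            hi_lat = int(x_hi - geom.tl / 2)
        i0s = _node_grid(ns, geom.ta, geom.step_ax, lo_ax, hi_ax)
        j0s = _node_grid(nl, geom.tl, geom.step_lat, lo_lat, hi_lat)
        rows_mm = (i0s + (geom.ta - 1) / 2.0) * dy * 1e-3
        cols_mm = rf_pre.x0_mm + (j0s + (geom.tl - 1) / 2.0) * dx * 1e-3
        II, JJ = np.meshgrid(i0s, j0s, indexing="ij")
        nn = II.size
        i_flat = II.ravel()
        j_flat = JJ.ravel()

        if est_ax is None:
            off_ax = np.zeros(nn, np.int64)
            off_lat = np.zeros(nn, np.int64)
            prev_ax = np.zeros((len(i0s), len(j0s)))
            prev_lat = np.zeros((len(i0s), len(j0s)))
        else:
            prev_ax = _interp_to(rows_prev, cols_prev, est_ax, rows_mm, cols_mm)
            prev_lat = _interp_to(rows_prev, cols_prev, est_lat, rows_mm, cols_mm)
            off_ax = np.rint(prev_ax).astype(np.int64).ravel()
            off_lat = np.rint(prev_lat).astype(np.int64).ravel()
            prev_ax = _fill_nearest(prev_ax)
            prev_lat = _fill_nearest(prev_lat)

        lag_ax = np.zeros(nn, np.int64)
        lag_lat = np.zeros(nn, np.int64)
        trip_ax = np.zeros((nn, 3))
        trip_lat = np.zeros((nn, 3))
        valid = np.zeros(nn, np.bool_)
        tstd = np.zeros(nn)

        if not stage.local_align:
            cost = ((2 * geom.ma + 1) * (2 * geom.ml + 1)
                    * geom.ta * geom.tl)
            matcher = _fft_match if cost > 5e6 else _match_stage
            matcher(pre, post, i_flat, j_flat, off_ax, off_lat,
                    geom.ta, geom.tl, geom.ma, geom.ml,
                    lag_ax, lag_lat, trip_ax, trip_lat, valid, tstd)
            if prior is not None and est_ax is not None:
                # second hypothesis: offsets from the prior map
                py, px = prior.node_positions_mm()
                pr_ax = _interp_to(py, px, prior.axial_um / dy,
                                   rows_mm, cols_mm)
                pr_lat = _interp_to(py, px, prior.lateral_um / dx,
                                    rows_mm, cols_mm)
                off2_ax = np.rint(pr_ax).astype(np.int64).ravel()
                off2_lat = np.rint(pr_lat).astype(np.int64).ravel()
                lag2_ax = np.zeros(nn, np.int64)
                lag2_lat = np.zeros(nn, np.int64)
                trip2_ax = np.zeros((nn, 3))
                trip2_lat = np.zeros((nn, 3))
                valid2 = np.zeros(nn, np.bool_)
                tstd2 = np.zeros(nn)
                matcher(pre, post, i_flat, j_flat, off2_ax, off2_lat,
                        geom.ta, geom.tl, geom.ma, geom.ml,
                        lag2_ax, lag2_lat, trip2_ax, trip2_lat, valid2,
                        tstd2)
                take2 = (valid2 & ~valid) | (valid2 & valid
                                             & (trip2_ax[:, 1] > trip_ax[:, 1]))
                off_ax = np.where(take2, off2_ax, off_ax)
                off_lat = np.where(take2, off2_lat, off_lat)
                lag_ax = np.where(take2, lag2_ax, lag_ax)
                lag_lat = np.where(take2, lag2_lat, lag_lat)
                trip_ax = np.where(take2[:, None], trip2_ax, trip_ax)
                trip_lat = np.where(take2[:, None], trip2_lat, trip_lat)
                valid = valid | valid2
            new_ax = (off_ax + lag_ax).astype(float)
            new_lat = (off_lat + lag_lat).astype(float)
            if stage.subsample:
                new_ax += _parabolic_vec(trip_ax)
                new_lat += _parabolic_vec(trip_lat)
        else:
            ma3 = min(geom.ma, align_margin)
            ml3 = min(geom.ml, align_margin)
            e_ax = prev_ax.ravel().copy()
            e_lat = prev_lat.ravel().copy()
            _aligned_stage(pre, post, i_flat, j_flat, e_ax, e_lat,
                           geom.ta, geom.tl, ma3, ml3,
                           lag_ax, lag_lat, trip_ax, trip_lat, valid, tstd)
            d_ax = lag_ax + (_parabolic_vec(trip_ax) if stage.subsample else 0.0)
            d_lat = lag_lat + (_parabolic_vec(trip_lat) if stage.subsample else 0.0)
            new_ax = e_ax + d_ax
            new_lat = e_lat + d_lat
            # re-align nodes with a substantial fractional residual: the
            # parabolic interpolator is unbiased near zero lag, so a second
            # pass at the fractional estimate removes the carrier bias;
            # near-integer residuals skip it (re-sampling noise would
            # dominate)
            for _ in range(max(1, align_passes) - 1):
                sel = valid & ((np.abs(d_ax - np.rint(d_ax)) > 0.05)
                               | (np.abs(d_lat - np.rint(d_lat)) > 0.05)
                               | (lag_ax != 0) | (lag_lat != 0))
                if not sel.any():
                    break
                idx = np.nonzero(sel)[0]
                n_s = len(idx)
                l_ax = np.zeros(n_s, np.int64)
                l_lat = np.zeros(n_s, np.int64)
                t_ax = np.zeros((n_s, 3))
                t_lat = np.zeros((n_s, 3))
                v_s = np.zeros(n_s, np.bool_)
                ts_s = np.zeros(n_s)
                _aligned_stage(pre, post, i_flat[idx], j_flat[idx],
                               np.ascontiguousarray(new_ax[idx]),
                               np.ascontiguousarray(new_lat[idx]),
                               geom.ta, geom.tl, ma3, ml3,
                               l_ax, l_lat, t_ax, t_lat, v_s, ts_s)
                d2_ax = l_ax + (_parabolic_vec(t_ax) if stage.subsample else 0.0)
                d2_lat = l_lat + (_parabolic_vec(t_lat) if stage.subsample else 0.0)
                upd = idx[v_s]
                new_ax[upd] = new_ax[idx][v_s] + d2_ax[v_s]
                new_lat[upd] = new_lat[idx][v_s] + d2_lat[v_s]
                d_ax = np.zeros_like(d_ax)
                d_lat = np.zeros_like(d_lat)
                d_ax[idx] = d2_ax
                d_lat[idx] = d2_lat
                lag_ax = np.zeros_like(lag_ax)
                lag_lat = np.zeros_like(lag_lat)
                lag_ax[idx] = l_ax
                lag_lat[idx] = l_lat
        # anechoic templates carry only noise, with std far below speckle;
        # gate against a fraction of the strong-signal level so homogeneous
        # all-tissue fields are untouched
        strong = np.percentile(tstd, 95)
        valid &= tstd > signal_gate * strong
        valid &= trip_ax[:, 1] >= min_correlation
        new_ax[~valid] = np.nan
        new_lat[~valid] = np.nan
        est_ax = _median_clean(new_ax.reshape(len(i0s), len(j0s)))
        est_lat = _median_clean(new_lat.reshape(len(i0s), len(j0s)))
        rows_prev, cols_prev = rows_mm, cols_mm

    origin = (float(cols_prev[0]), float(rows_prev[0]))
    return DisplacementMap(est_ax * dy, est_lat * dx,
                           geom.step_ax * dy, geom.step_lat * dx, origin)


def accumulate_displacement(maps: list, return_partials: bool = False):
    """Accumulate a sequence of incremental displacement maps.

    Quasi-static inflation is tracked frame-to-frame (small interframe
    motion keeps each pair within the fine-pass search range); the total
    displacement of the material point starting at each node of the first
    map's grid is obtained by following its trajectory through the
    incremental (Eulerian) maps.  Nodes whose trajectory leaves the valid
    region become NaN.

    With ``return_partials`` the cumulative map after every increment is
    returned as a list (material displacement up to each acquired frame).
    """
    from scipy.interpolate import RegularGridInterpolator
    if len(maps) == 0:
        raise ValueError("no maps to accumulate")
    base = maps[0]
    y0, x0 = base.node_positions_mm()
    X, Y = np.meshgrid(x0, y0)
    pos_x, pos_y = X.copy(), Y.copy()
    tot_ax = np.zeros_like(X)
    tot_lat = np.zeros_like(X)
    partials = []
    for m in maps:
        y, x = m.node_positions_mm()
        pts = np.column_stack([pos_y.ravel(), pos_x.ravel()])
        if len(y) > 1 and len(x) > 1:
            fa = RegularGridInterpolator((y, x), m.axial_um,
                                         bounds_error=False, fill_value=np.nan)
            fl = RegularGridInterpolator((y, x), m.lateral_um,
                                         bounds_error=False, fill_value=np.nan)
            ax = fa(pts).reshape(X.shape)
            lat = fl(pts).reshape(X.shape)
        else:
            ax = np.broadcast_to(m.axial_um, X.shape).copy()
            lat = np.broadcast_to(m.lateral_um, X.shape).copy()
        tot_ax = tot_ax + ax
        tot_lat = tot_lat + lat
        pos_y = pos_y + ax * 1e-3
        pos_x = pos_x + lat * 1e-3
        if return_partials:
            partials.append(DisplacementMap(tot_ax.copy(), tot_lat.copy(),
                                            base.grid_axial_step_um,
                                            base.grid_lateral_step_um,
                                            base.origin_mm))
    total = DisplacementMap(tot_ax, tot_lat, base.grid_axial_step_um,
                            base.grid_lateral_step_um, base.origin_mm)
    return partials if return_partials else total


def write_displacement_map(dmap: DisplacementMap, path_prefix) -> None:
    """Flat CSV (x_mm, y_mm, axial_um, lateral_um) plus JSON header."""
    prefix = Path(path_prefix)
    y, x = dmap.node_positions_mm()
    X, Y = np.meshgrid(x, y)
    data = np.column_stack([X.ravel(), Y.ravel(),
                            dmap.axial_um.ravel(), dmap.lateral_um.ravel()])
    np.savetxt(prefix.with_suffix(".csv"), data, delimiter=",",
               header="x_mm,y_mm,axial_um,lateral_um", comments="")
    meta = {"grid_axial_step_um": dmap.grid_axial_step_um,
            "grid_lateral_step_um": dmap.grid_lateral_step_um,
            "origin_mm": list(dmap.origin_mm), "shape": list(dmap.shape)}
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_displacement_map(path_prefix) -> DisplacementMap:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1)
    shape = tuple(meta["shape"])
    return DisplacementMap(data[:, 2].reshape(shape), data[:, 3].reshape(shape),
                           meta["grid_axial_step_um"], meta["grid_lateral_step_um"],
                           tuple(meta["origin_mm"]))
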