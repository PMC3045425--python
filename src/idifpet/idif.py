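"""The seven carotid image-derived input-function (IDIF) extraction methods.

Blood-based methods (need arterial samples for scaling/calibration):

* ``chen_idif``     — carotid/background linear model, recovery and spill-in
  coefficients calibrated against four blood samples.
* ``mourik_idif``   — four hottest pixels per plane, tri-exponential fit,
  scaled with three late blood samples.
* ``naganawa_idif`` — independent component analysis of the smoothed dynamic
  image, blood component scaled with the same three-sample rule.

Blood-free methods:

* ``su_idif``       — Chen's model with the frame-wise hottest carotid voxel
  standing in for sampled blood.
* ``parker_idif``   — Chen's model fed with the mean of the hottest 5% of
  carotid voxels, spill-corrected late in the scan.
* ``backes_idif``   — vessel-fraction/transport model inverted as a Volterra
  equation.
* ``croteau_idif``  — four hottest pixels on three planes, divided by a
  simulated, diameter-dependent recovery coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from .io import (
    BloodSeries,
    DynamicImage,
    InputFunction,
    ValidationError,
    interpolate_curve,
)
from .synthetic import PhantomSpec

__all__ = [
    "CarotidROISet",
    "ChenFit",
    "ParkerFit",
    "BackesParams",
    "RecoveryTable",
    "TriexpFit",
    "DetectionError",
    "CalibrationError",
    "ExtractionError",
    "auto_carotid_rois",
    "hottest_pixels_curve",
    "fit_triexponential",
    "chen_idif",
    "mourik_idif",
    "naganawa_idif",
    "su_idif",
    "parker_idif",
    "backes_idif",
    "croteau_idif",
    "build_recovery_table",
    "calibrate_parameter_grid",
    "square_rois_from_carotids",
    "CHEN_CALIBRATION_TIMES",
    "MOURIK_SCALING_TIMES",
    "SU_DEFAULT_TRUNCATION",
    "SU_TRUNCATION_GRID",
    "BACKES_GRID",
    "BACKES_DEFAULTS",
]


class DetectionError(RuntimeError):
    """No carotid-like structure could be found."""


class CalibrationError(RuntimeError):
    """The least-squares calibration is singular or failed."""


class ExtractionError(RuntimeError):
    """A method could not produce an input curve."""


CHEN_CALIBRATION_TIMES = {
    "rolipram_like": (6.0, 20.0, 60.0, 90.0),
    "pbr28_like": (4.0, 20.0, 60.0, 90.0),
}
MOURIK_SCALING_TIMES = (20.0, 60.0, 90.0)
SU_DEFAULT_TRUNCATION = {"rolipram_like": 20.0, "pbr28_like": 40.0}
SU_TRUNCATION_GRID = tuple(float(t) for t in range(10, 91, 10))
# a_v x k grid as printed; ties resolve to the earlier entry
BACKES_GRID = tuple(
    (a_v, k) for a_v in (0.3, 0.4, 0.5) for k in (5e-1, 5e-2, 5e-3, 5e-4)
)
BACKES_DEFAULTS = {"rolipram_like": (0.4, 5e-4), "pbr28_like": (0.5, 5e-2)}


@dataclass
class CarotidROISet:
    """Carotid voxels plus a nearby (but not adjacent) background shell."""

    carotid_mask: np.ndarray
    background_mask: np.ndarray
    plane_ids: np.ndarray

    def __post_init__(self):
        self.carotid_mask = np.asarray(self.carotid_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if not self.carotid_mask.any():
            raise ValidationError("carotid mask is empty")
        if np.any(self.carotid_mask & self.background_mask):
            raise ValidationError("carotid and background masks overlap")
        self.plane_ids = np.asarray(self.plane_ids, dtype=int)


@dataclass(frozen=True)
class ChenFit:
    """Recovery coefficient and spill-in fraction of the carotid linear model."""

    RC: float
    SP: float
    calibration_times: tuple

    def __post_init__(self):
        if self.RC <= 0:
            raise CalibrationError("recovery coefficient must be positive")
        if self.SP < 0:
            raise CalibrationError("spill-in fraction must be non-negative")


@dataclass
class ParkerFit:
    """Per-frame hottest-5% curve with its late-frame spill correction."""

    imax_curve: np.ndarray
    imean_curve: np.ndarray
    tmean_curve: np.ndarray
    corrected_frames: np.ndarray


@dataclass(frozen=True)
class BackesParams:
    """Fractional vessel volume a_v and vessel-to-tissue transport constant k."""

    a_v: float
    k: float

    def __post_init__(self):
        if not 0 < self.a_v <= 1:
            raise ValidationError("a_v must lie in (0, 1]")
        if self.k < 0:
            raise ValidationError("k must be non-negative")


@dataclass
class RecoveryTable:
    """Recovery coefficient versus cylinder diameter (mm)."""

    diameters: np.ndarray
    rc: np.ndarray

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        if np.any(self.rc <= 0) or np.any(self.rc > 1.0 + 1e-9):
            raise ValidationError("recovery coefficients must lie in (0, 1]")
        if np.any(np.diff(self.rc) < -1e-9):
            raise ValidationError("recovery coefficients must be non-decreasing")

    def __call__(self, diameter: float) -> float:
        if diameter < self.diameters[0] or diameter > self.diameters[-1]:
            raise ValidationError(
                f"diameter {diameter} mm outside table range "
                f"[{self.diameters[0]}, {self.diameters[-1]}]"
            )
        return float(np.interp(diameter, self.diameters, self.rc))


# ---------------------------------------------------------------------------
# ROI definition


def _early_sum(image: DynamicImage, window=(0.0, 2.0)) -> np.ndarray:
    """Duration-weighted sum of the frames inside the early window."""
    sched = image.schedule
    sel = (sched.start_times < window[1] - 1e-9) & (sched.end_times > window[0] + 1e-9)
    if not sel.any():
        raise ValidationError("no frames inside the early window")
    w = sched.durations[sel]
    return np.tensordot(image.voxels[..., sel], w, axes=([3], [0]))


def auto_carotid_rois(
    image: DynamicImage,
    early_window_min=(0.0, 2.0),
    threshold_fraction: float = 0.5,
    min_cluster_voxels: int = 4,
    max_clusters: int = 8,
) -> CarotidROISet:
    """Automated carotid/background ROI definition on the early summed frames.

    Within the lower third of the axial field of view, voxels above
    ``threshold_fraction`` of the slab maximum are clustered; the largest
    clusters form the carotid mask.  The background is a shell 2-4 voxels
    away from the carotid mask, leaving a one-voxel gap.
    """
    summed = _early_sum(image, early_window_min)
    nz = summed.shape[2]
    slab = np.zeros_like(summed, dtype=bool)
    slab[..., : max(nz // 3, 1)] = True
    slab_vals = summed[slab]
    peak = slab_vals.max()
    if peak <= 0:
        raise DetectionError("no early activity in the lower axial slab")
    hot = (summed >= threshold_fraction * peak) & slab
    lab, n = ndimage.label(hot)
    if n == 0:
        raise DetectionError("no suprathreshold carotid cluster")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:max_clusters] + 1
    keep = [k for k in keep if sizes[k - 1] >= min_cluster_voxels]
    if not keep:
        raise DetectionError("all carotid clusters below the minimum size")
    carotid = np.isin(lab, keep)
    dist = ndimage.distance_transform_edt(~carotid)
    background = (dist >= 2.0) & (dist <= 4.0) & slab
    planes = np.unique(np.nonzero(carotid)[2])
    return CarotidROISet(carotid, background, planes)


def hottest_pixels_curve(
    image: DynamicImage, mask: np.ndarray, n_per_plane: int = 4,
    early_window_min=(0.0, 2.0),
) -> np.ndarray:
    """Mean TAC of the ``n`` hottest early-frame voxels of each carotid plane.

    The hottest-pixel cluster is fixed on the early summed image and reused
    for every frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty carotid mask")
    summed = _early_sum(image, early_window_min)
    sel = np.zeros_like(mask)
    for plane in np.unique(np.nonzero(mask)[2]):
        pmask = mask[..., plane]
        idx = np.argwhere(pmask)
        vals = summed[pmask, plane]
        if idx.shape[0] < n_per_plane:
            warnings.warn(f"plane {plane} has fewer than {n_per_plane} carotid voxels")
            chosen = idx
        else:
            order = np.argsort(vals)[::-1][:n_per_plane]
            chosen = idx[order]
        sel[chosen[:, 0], chosen[:, 1], plane] = True
    return image.roi_tac(sel)


# ---------------------------------------------------------------------------
# Tri-exponential tail fit


@dataclass
class TriexpFit:
    """Piecewise input-curve model: sampled rise to the peak, tri-exp tail."""

    rise_times: np.ndarray = field(repr=False)
    rise_values: np.ndarray = field(repr=False)
    t_peak: float = 0.0
    amplitudes: np.ndarray = None
    rates: np.ndarray = None
    rmse: float = np.nan

    def tail(self, t) -> np.ndarray:
        dt = np.asarray(t, dtype=float) - self.t_peak
        return np.sum(
            self.amplitudes[:, None] * np.exp(-self.rates[:, None] * dt[None, :]),
            axis=0,
        )

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        early = t < self.t_peak
        if early.any():
            out[early] = interpolate_curve(self.rise_times, self.rise_values, t[early])
        out[~early] = self.tail(t[~early])
        return out


def _triexp_nnls(dt: np.ndarray, values: np.ndarray, rates: np.ndarray, w: np.ndarray):
    basis = np.exp(-np.outer(dt, rates))
    amps, _ = optimize.nnls(basis * w[:, None], values * w)
    resid = (basis @ amps - values) * w
    return amps, resid


def fit_triexponential(times, values) -> TriexpFit:
    """Fit the tail (from the peak on) with three decaying exponentials.

    The rise is kept as the sampled curve (linear from (0,0) to the peak);
    the tail is fitted by variable projection: non-negative amplitudes from
    NNLS inside a multi-start optimisation of the log decay rates.  Residuals
    are weighted approximately relatively (1/value, floored at 2% of the
    peak), since a blood tail spans two orders of magnitude and an unweighted
    fit would ignore its late, low-amplitude part.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 8:
        raise ValidationError("need at least 8 samples for a tri-exponential fit")
    ipeak = int(np.argmax(v))
    t_peak = t[ipeak]
    dt = t[ipeak:] - t_peak
    tail = v[ipeak:]
    if dt.size < 4:
        raise ExtractionError("no discernible tail after the peak")
    scale = max(tail.max(), 1e-12)
    w = scale / np.maximum(np.abs(tail), 0.02 * scale)

    def cost(log_rates):
        rates = np.exp(log_rates)
        _, resid = _triexp_nnls(dt, tail / scale, rates, w)
        return resid

    starts = [
        np.log([2.0, 0.2, 0.02]),
        np.log([1.0, 0.1, 0.01]),
        np.log([4.0, 0.4, 0.04]),
        np.log([0.5, 0.08, 0.008]),
    ]
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                cost, x0, bounds=(np.log(1e-5), np.log(50.0)), xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ExtractionError("tri-exponential fit did not converge")
    rates = np.exp(best.x)
    amps, resid = _triexp_nnls(dt, tail / scale, rates, w)
    amps = amps * scale
    # merge numerically coincident rates so nested models report zero amplitudes
    order = np.argsort(rates)[::-1]
    rates, amps = rates[order], amps[order]
    merged_r, merged_a = [], []
    for r, a in zip(rates, amps):
        if merged_r and abs(r - merged_r[-1]) <= 1e-3 * merged_r[-1]:
            merged_a[-1] += a
        else:
            merged_r.append(r)
            merged_a.append(a)
    while len(merged_r) < 3:
        merged_r.append(merged_r[-1] * 0.5)
        merged_a.append(0.0)
    rmse = float(np.sqrt(np.mean((resid / w * scale) ** 2)))
    return TriexpFit(
        rise_times=t[: ipeak + 1],
        rise_values=v[: ipeak + 1],
        t_peak=float(t_peak),
        amplitudes=np.asarray(merged_a),
        rates=np.asarray(merged_r),
        rmse=rmse,
    )


# ---------------------------------------------------------------------------
# Eq.-1 style least squares shared by Chen / Su / Parker


def _fit_rc_sp(c_carotid, c_blood, c_surround, label) -> tuple[float, float]:
    c_carotid = np.asarray(c_carotid, dtype=float)
    c_blood = np.asarray(c_blood, dtype=float)
    c_surround = np.asarray(c_surround, dtype=float)
    if np.linalg.norm(c_surround) <= 1e-12 * np.linalg.norm(c_blood):
        # cold surround: no spill-in term to estimate
        rc = float(c_blood @ c_carotid / (c_blood @ c_blood))
        sp = 0.0
    else:
        design = np.column_stack([c_blood, c_surround])
        if np.linalg.matrix_rank(design, tol=1e-10 * np.abs(design).max()) < 2:
            raise CalibrationError(f"singular carotid calibration design ({label})")
        coef, *_ = np.linalg.lstsq(design, c_carotid, rcond=None)
        rc, sp = float(coef[0]), float(coef[1])
    if rc <= 0:
        raise CalibrationError(f"non-positive recovery coefficient ({label})")
    return rc, max(sp, 0.0)


def _recover(c_carotid, c_surround, rc, sp) -> np.ndarray:
    return np.maximum((c_carotid - sp * c_surround) / rc, 0.0)


def chen_idif(
    image: DynamicImage,
    rois: CarotidROISet,
    blood_series: BloodSeries,
    mode: str = "rolipram_like",
) -> tuple[InputFunction, ChenFit]:
    """Blood-calibrated carotid model: C_carotid = RC*C_wb + SP*C_surround.

    RC and SP are estimated by unweighted linear least squares at the four
    calibration times (6/20/60/90 min in the low-metabolite mode, 4/20/60/90
    min in the high-metabolite mode); the whole-blood curve is then recovered
    on the frame grid as (C_carotid - SP*C_surround)/RC.

    The calibration times coincide with arterial sampling times, so blood
    needs no interpolation; the image TACs are evaluated at those times with
    a shape-preserving (monotone cubic) interpolant of the frame curve, which
    avoids the convexity bias a linear interpolant picks up on the steep
    early descent.
    """
    from scipy.interpolate import PchipInterpolator

    times = np.asarray(CHEN_CALIBRATION_TIMES[mode], dtype=float)
    mid = image.schedule.midpoints
    c_car = image.roi_tac(rois.carotid_mask)
    c_sur = image.roi_tac(rois.background_mask)
    car_at = PchipInterpolator(mid, c_car)(times)
    sur_at = PchipInterpolator(mid, c_sur)(times)
    wb_at = blood_series.whole_blood_at(times)
    rc, sp = _fit_rc_sp(car_at, wb_at, sur_at, "chen")
    recovered = _recover(c_car, c_sur, rc, sp)
    fit = ChenFit(rc, sp, tuple(times))
    return InputFunction(mid, recovered, provenance="chen"), fit


def mourik_idif(
    image: DynamicImage, rois: CarotidROISet, blood_series: BloodSeries,
    scaling_times=MOURIK_SCALING_TIMES,
) -> InputFunction:
    """Four hottest pixels per plane, tri-exponential fit, three-sample scaling."""
    mid = image.schedule.midpoints
    curve = hottest_pixels_curve(image, rois.carotid_mask, n_per_plane=4)
    fit = fit_triexponential(mid, curve)
    st = np.asarray(scaling_times, dtype=float)
    fitted_at = fit(st)
    if np.any(fitted_at <= 0):
        raise ExtractionError("fitted image curve non-positive at a scaling time")
    scale = float(np.mean(blood_series.whole_blood_at(st) / fitted_at))
    return InputFunction(mid, np.maximum(scale * fit(mid), 0.0), provenance="mourik")


def naganawa_idif(
    image: DynamicImage,
    blood_series: BloodSeries,
    n_components: int = 3,
    seed: int = 0,
    smoothing_fwhm_mm: float = 6.0,
    top_fraction: float = 0.002,
) -> InputFunction:
    """ICA-based extraction: blood component by earliest, most skewed peak.

    Frames are smoothed with a 6 mm FWHM Gaussian, the head region is
    cropped, and FastICA is run on the frame-by-voxel matrix.  The blood
    component's spatial map defines a data-driven ROI whose mean TAC is
    tri-exponentially fitted and scaled with the three-sample rule.
    """
    from sklearn.decomposition import FastICA

    sched = image.schedule
    mid = sched.midpoints
    sigma_vox = smoothing_fwhm_mm / 2.3548 / image.voxel_size
    smooth = np.empty_like(image.voxels)
    for f in range(sched.n_frames):
        smooth[..., f] = ndimage.gaussian_filter(image.voxels[..., f], sigma_vox)
    total = np.tensordot(smooth, sched.durations, axes=([3], [0]))
    head = total > 0.02 * total.max()
    data = smooth[head, :]  # voxels x frames
    ica = FastICA(
        n_components=n_components, random_state=seed, whiten="unit-variance",
        max_iter=2000, tol=1e-6,
    )
    sources = ica.fit_transform(data.T)  # frames x comp (temporal courses)
    maps = ica.mixing_  # voxels x comp (spatial maps)

    best_j, best_key = None, None
    for j in range(sources.shape[1]):
        s = sources[:, j].copy()
        if abs(s.min()) > abs(s.max()):
            s = -s
        peak_t = mid[int(np.argmax(s))]
        if peak_t > 5.0:
            continue
        key = (stats.skew(s), -peak_t)
        if best_key is None or key > best_key:
            best_key, best_j = key, j
    if best_j is None:
        raise ExtractionError("no independent component peaks within 5 minutes")
    s = sources[:, best_j]
    m = maps[:, best_j]
    if abs(s.min()) > abs(s.max()):
        m = -m
    k = max(int(round(top_fraction * m.size)), 8)
    roi_flat = np.argsort(m)[::-1][:k]
    curve = data[roi_flat, :].mean(axis=0)
    fit = fit_triexponential(mid, curve)
    st = np.asarray(MOURIK_SCALING_TIMES, dtype=float)
    fitted_at = fit(st)
    if np.any(fitted_at <= 0):
        raise ExtractionError("ICA component non-positive at a scaling time")
    scale = float(np.mean(blood_series.whole_blood_at(st) / fitted_at))
    return InputFunction(mid, np.maximum(scale * fit(mid), 0.0), provenance="naganawa")


def su_idif(
    image: DynamicImage,
    rois: CarotidROISet,
    truncation_min: float | None = None,
    mode: str = "rolipram_like",
) -> tuple[InputFunction, ChenFit]:
    """Chen's model with the frame-wise hottest carotid voxel as pseudo-blood.

    RC/SP are fitted over all frames whose midpoint falls before the
    truncation time (20 min low-metabolite, 40 min high-metabolite default).
    """
    if truncation_min is None:
        truncation_min = SU_DEFAULT_TRUNCATION[mode]
    sched = image.schedule
    mid = sched.midpoints
    if truncation_min > sched.scan_end:
        raise ValidationError("truncation beyond the scan span")
    c_car = image.roi_tac(rois.carotid_mask)
    c_sur = image.roi_tac(rois.background_mask)
    hottest = image.voxels[rois.carotid_mask, :].max(axis=0)
    use = mid <= truncation_min
    if use.sum() < 3:
        raise CalibrationError("fewer than 3 frames before the truncation time")
    rc, sp = _fit_rc_sp(c_car[use], hottest[use], c_sur[use], "su")
    recovered = _recover(c_car, c_sur, rc, sp)
    fit = ChenFit(rc, sp, tuple(mid[use]))
    return InputFunction(mid, recovered, provenance="su"), fit


def parker_idif(
    image: DynamicImage,
    rois: CarotidROISet,
    truncation_min: float | None = None,
    mode: str = "rolipram_like",
    hottest_fraction: float = 0.05,
) -> tuple[InputFunction, ParkerFit, ChenFit]:
    """Chen's model driven by the mean of the hottest 5% of carotid voxels.

    Frames where the background mean exceeds the carotid mean have I_max
    corrected to I_max * I_mean / T_mean before the least-squares step.
    """
    if truncation_min is None:
        truncation_min = SU_DEFAULT_TRUNCATION[mode]
    sched = image.schedule
    mid = sched.midpoints
    car_vals = image.voxels[rois.carotid_mask, :]
    n_hot = max(int(np.ceil(hottest_fraction * car_vals.shape[0])), 1)
    imax = np.sort(car_vals, axis=0)[-n_hot:, :].mean(axis=0)
    imean = car_vals.mean(axis=0)
    tmean = image.roi_tac(rois.background_mask)
    correct = tmean > imean
    imax_corr = np.where(correct & (tmean > 0), imax * imean / np.where(tmean > 0, tmean, 1.0), imax)
    use = mid <= truncation_min
    if use.sum() < 3:
        raise CalibrationError("fewer than 3 frames before the truncation time")
    rc, sp = _fit_rc_sp(imean[use], imax_corr[use], tmean[use], "parker")
    recovered = _recover(imean, tmean, rc, sp)
    pfit = ParkerFit(imax_corr, imean, tmean, np.nonzero(correct)[0])
    cfit = ChenFit(rc, sp, tuple(mid[use]))
    return InputFunction(mid, recovered, provenance="parker"), pfit, cfit


def backes_idif(
    image: DynamicImage,
    square_rois: np.ndarray,
    params: BackesParams,
) -> InputFunction:
    """Vessel-fraction model: C_carotid = a_v C_wb + (1-a_v) k int_0^t C_wb.

    The whole-blood curve is recovered by forward substitution of the
    trapezoid-discretized Volterra equation.
    """
    mid = image.schedule.midpoints
    c_car = image.roi_tac(square_rois)
    return InputFunction(
        mid, _backes_invert(mid, c_car, params), provenance="backes"
    )


def _backes_invert(t: np.ndarray, c_car: np.ndarray, params: BackesParams) -> np.ndarray:
    a_v, k = params.a_v, params.k
    beta = (1.0 - a_v) * k
    wb = np.zeros_like(c_car)
    # virtual sample at t=0 where both curves vanish
    t_full = np.concatenate([[0.0], t]) if t[0] > 0 else t
    c_full = np.concatenate([[0.0], c_car]) if t[0] > 0 else c_car
    wb_full = np.zeros_like(c_full)
    integral = 0.0
    for n in range(1, t_full.size):
        h = t_full[n] - t_full[n - 1]
        rhs = c_full[n] - beta * (integral + wb_full[n - 1] * h / 2.0)
        wb_full[n] = rhs / (a_v + beta * h / 2.0)
        integral += (wb_full[n - 1] + wb_full[n]) * h / 2.0
    wb = wb_full[1:] if t[0] > 0 else wb_full
    return np.maximum(wb, 0.0)


def backes_forward(t: np.ndarray, wb: np.ndarray, params: BackesParams) -> np.ndarray:
    """Forward model of the vessel-fraction equation (used for calibration checks)."""
    t = np.asarray(t, dtype=float)
    wb = np.asarray(wb, dtype=float)
    t_full = np.concatenate([[0.0], t]) if t[0] > 0 else t
    wb_full = np.concatenate([[0.0], wb]) if t[0] > 0 else wb
    integral = np.concatenate(
        [[0.0], np.cumsum(np.diff(t_full) * (wb_full[1:] + wb_full[:-1]) / 2.0)]
    )
    out = params.a_v * wb_full + (1.0 - params.a_v) * params.k * integral
    return out[1:] if t[0] > 0 else out


def square_rois_from_carotids(
    rois: CarotidROISet, half_width: int = 2, n_slices: int = 4
) -> np.ndarray:
    """Square ROIs centered on each carotid over ``n_slices`` axial slices."""
    lab, n = ndimage.label(rois.carotid_mask)
    if n == 0:
        raise ValidationError("no carotid component to center squares on")
    out = np.zeros_like(rois.carotid_mask)
    shape = out.shape
    for comp in range(1, n + 1):
        idx = np.argwhere(lab == comp)
        cx, cy = int(round(idx[:, 0].mean())), int(round(idx[:, 1].mean()))
        zs = np.unique(idx[:, 2])
        zmid = zs[len(zs) // 2]
        z0 = int(max(zmid - n_slices // 2, 0))
        for dz in range(n_slices):
            zz = min(z0 + dz, shape[2] - 1)
            out[max(cx - half_width, 0): cx + half_width + 1,
                max(cy - half_width, 0): cy + half_width + 1, zz] = True
    return out


def croteau_idif(
    image: DynamicImage,
    rois: CarotidROISet,
    carotid_diameter_mm: float,
    recovery_table: RecoveryTable,
    n_planes: int = 3,
) -> InputFunction:
    """Recovery-coefficient method: hottest pixels on three adjacent planes.

    The four hottest pixels of the early summed image on the three hottest
    adjacent carotid planes are averaged, tri-exponentially fitted and
    divided by the diameter's recovery coefficient (partial-volume
    correction only; no spill-in correction).
    """
    rc = recovery_table(carotid_diameter_mm)
    mid = image.schedule.midpoints
    summed = _early_sum(image)
    planes = rois.plane_ids
    if planes.size < n_planes:
        chosen = planes
    else:
        strength = []
        for p0 in range(planes.size - n_planes + 1):
            window = planes[p0: p0 + n_planes]
            if window[-1] - window[0] != n_planes - 1:
                strength.append(-np.inf)
                continue
            s = sum(summed[rois.carotid_mask[..., p], p].max() for p in window)
            strength.append(s)
        if np.all(np.isneginf(strength)):
            chosen = planes[:n_planes]
        else:
            best = int(np.argmax(strength))
            chosen = planes[best: best + n_planes]
    plane_mask = np.zeros_like(rois.carotid_mask)
    plane_mask[..., chosen] = rois.carotid_mask[..., chosen]
    curve = hottest_pixels_curve(image, plane_mask, n_per_plane=4)
    fit = fit_triexponential(mid, curve)
    return InputFunction(mid, np.maximum(fit(mid), 0.0) / rc, provenance="croteau")


# ---------------------------------------------------------------------------
# Recovery-coefficient table and AUC-ratio grid calibration


def _kernel_2d(spec: PhantomSpec, half: int) -> np.ndarray:
    g = np.arange(-half, half + 1) * spec.voxel_size
    xx, yy = np.meshgrid(g, g, indexing="ij")
    r2 = xx**2 + yy**2

    def gauss(sig):
        k = np.exp(-r2 / (2.0 * sig**2))
        return k / k.sum()

    s1, s2, rho = spec.psf["sigma1"], spec.psf["sigma2"], spec.psf["rho"]
    k = (1.0 - rho) * gauss(s1) + rho * gauss(s2)
    return k / k.sum()


def cylinder_cross_section(
    diameter_mm: float, voxel_size: float, n_vox: int, center_offset=(0.0, 0.0),
    supersample: int = 8,
) -> np.ndarray:
    """Fractional-occupancy raster of a disk (long-cylinder cross-section)."""
    r = diameter_mm / 2.0
    sub = (np.arange(n_vox * supersample) + 0.5) / supersample
    cx = n_vox / 2.0 + center_offset[0]
    cy = n_vox / 2.0 + center_offset[1]
    xx, yy = np.meshgrid((sub - cx) * voxel_size, (sub - cy) * voxel_size, indexing="ij")
    inside = (xx**2 + yy**2 <= r**2).astype(float)
    return inside.reshape(n_vox, supersample, n_vox, supersample).mean(axis=(1, 3))


DEFAULT_RC_OFFSETS = ((0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5))


def build_recovery_table(
    spec: PhantomSpec,
    diameters=None,
    n_per_plane: int = 4,
    offsets=DEFAULT_RC_OFFSETS,
) -> RecoveryTable:
    """Simulated recovery coefficients for uniform cylinders of 3-8 mm.

    Each diameter's cross-section (fractional voxel occupancy, averaged over
    the sub-voxel centre ``offsets``) is convolved with the in-plane
    resolution kernel; the recovery coefficient is the mean of the ``n``
    hottest pixels over the true cylinder value.  The axial direction drops
    out for a long cylinder imaged with a stationary isotropic kernel.
    """
    from scipy.signal import fftconvolve

    if spec.psf is None:
        raise ValidationError("recovery table requires a PSF specification")
    if diameters is None:
        diameters = np.round(np.arange(3.0, 8.0 + 1e-9, 0.1), 1)
    diameters = np.asarray(diameters, dtype=float)
    half = int(np.ceil(4.0 * spec.psf["sigma2"] / spec.voxel_size))
    kern = _kernel_2d(spec, half)
    n_vox = int(np.ceil((diameters.max() + 8.0 * spec.psf["sigma2"]) / spec.voxel_size)) + 4
    rc = np.empty_like(diameters)
    for i, d in enumerate(diameters):
        vals = []
        for off in offsets:
            img = fftconvolve(
                cylinder_cross_section(d, spec.voxel_size, n_vox, off), kern, mode="same"
            )
            vals.append(np.sort(img, axis=None)[-n_per_plane:].mean())
        rc[i] = np.mean(vals)
    rc = np.minimum.accumulate(rc[::-1])[::-1]  # clip sub-1e-4 voxelization ripple
    return RecoveryTable(diameters, np.clip(rc, 1e-6, 1.0))


def calibrate_parameter_grid(
    candidates,
    runner,
    reference_input: InputFunction,
    t_end: float = 90.0,
):
    """Pick the candidate whose image/arterial AUC ratio is closest to 1.

    ``runner(candidate)`` must return an InputFunction; candidates that raise
    are skipped.  Ties resolve to the smaller candidate index.
    """
    from .merit import auc_ratio

    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no candidates to calibrate over")
    best_i, best_err = None, None
    for i, cand in enumerate(candidates):
        try:
            idif = runner(cand)
            ratio = auc_ratio(
                (idif.times, idif.whole_blood),
                (reference_input.times, reference_input.whole_blood),
                t_end,
            )
        except Exception:
            continue
        err = abs(ratio - 1.0)
        if best_err is None or err < best_err - 1e-15:
            best_i, best_err = i, err
    if best_i is None:
        raise CalibrationError("every candidate failed")
    return candidates[best_i]
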