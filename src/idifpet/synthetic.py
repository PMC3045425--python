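"""Synthetic study generator: arterial input functions, tissue kinetics, a digital
head phantom, and simulated dynamic scans.

This module stands in for all raw data.  It emulates:

* whole-blood curves peaking ~90 s after injection (Feng-type tri-exponential
  bolus model),
* a low-metabolite tracer mode (``rolipram_like``; parent/whole-blood ratio
  ~0.99 at 60 min, ~0.80 at 90 min) and a high-metabolite mode
  (``pbr28_like``; ~0.96 at 4 min, ~0.07 at 90 min),
* brain-region time-activity curves generated by two-tissue-compartment
  kinetics,
* a procedural head phantom with two pairs of internal carotids (8 mm and
  5 mm diameter) imaged through a two-Gaussian point-spread function with
  frame-dependent noise.

The scanner's list-mode reconstruction is modelled in image space: each frame
is the label-wise linear combination of the region kinetics, convolved with
the resolution kernel and degraded with count-statistics-like noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .io import (
    BloodSeries,
    DynamicImage,
    FrameSchedule,
    InputFunction,
    LabelMap,
    ValidationError,
    interpolate_curve,
)
from .kinetics import KineticParams, two_tissue_solution

__all__ = [
    "TracerTemplate",
    "PhantomSpec",
    "feng_whole_blood",
    "parent_fraction_curve",
    "make_input_function",
    "tissue_tac_from_rates",
    "build_head_phantom",
    "psf_kernel",
    "simulate_dynamic_scan",
    "sample_arterial_blood",
    "default_sampling_times",
    "make_label_tacs",
    "simulate_study",
    "SimulatedStudy",
]

GREY_MATTER_REGIONS = (
    "frontal_gm",
    "temporal_gm",
    "parietal_gm",
    "occipital_gm",
    "basal_ganglia",
    "cerebellum",
)

CAROTID_REGIONS = ("carotid_8mm", "carotid_5mm")


@dataclass
class TracerTemplate:
    """Generative parameters for one tracer mode.

    ``feng`` holds the tri-exponential bolus model: amplitudes ``A1`` (kBq/mL
    per min), ``A2``, ``A3`` (kBq/mL), rates ``lam1 > lam2 > lam3`` (1/min)
    and the appearance delay ``tau`` (min).  ``metabolite`` holds anchor
    points ``(t_min, parent/whole-blood ratio)`` and the Hill slope of the
    parent-fraction decline.  ``regions`` maps region names to 2TCM rates.
    """

    name: str
    feng: dict
    metabolite: dict
    plasma_over_wholeblood: float
    regions: dict[str, KineticParams]

    def __post_init__(self):
        f = self.feng
        rates = [f["lam1"], f["lam2"], f["lam3"]]
        if any(r <= 0 for r in rates):
            raise ValidationError("Feng rates must be positive")
        if len({round(r, 12) for r in rates}) != 3:
            raise ValidationError("Feng rates must be distinct")
        anchors = self.metabolite["anchors"]
        ratios = [r for _, r in anchors]
        if any(not (0 <= r <= 1.5) for r in ratios):
            raise ValidationError("anchor ratios must lie in [0, 1.5]")
        if ratios and ratios[0] < ratios[-1]:
            raise ValidationError("anchor ratios must be non-increasing")

    @classmethod
    def rolipram_like(cls) -> "TracerTemplate":
        """Low-metabolite mode: parent remains ~80% of blood activity at 90 min."""
        return cls(
            name="rolipram_like",
            feng={"A1": 200.0, "A2": 4.0, "A3": 1.8,
                  "lam1": 2.0, "lam2": 0.12, "lam3": 0.02, "tau": 1.0},
            metabolite={"anchors": [(60.0, 0.99), (90.0, 0.80)], "hill_slope": 8.0},
            plasma_over_wholeblood=1.05,
            regions={
                "frontal_gm": KineticParams(0.12, 0.18, 0.060, 0.030),
                "temporal_gm": KineticParams(0.11, 0.17, 0.060, 0.030),
                "parietal_gm": KineticParams(0.12, 0.19, 0.055, 0.030),
                "occipital_gm": KineticParams(0.13, 0.20, 0.050, 0.028),
                "basal_ganglia": KineticParams(0.11, 0.18, 0.070, 0.032),
                "cerebellum": KineticParams(0.12, 0.19, 0.050, 0.030),
                "white_matter": KineticParams(0.06, 0.15, 0.040, 0.030),
                # peripheral tissues retain tracer: at late times the
                # surround outshines the carotid blood pool
                "scalp": KineticParams(0.05, 0.12, 0.010, 0.010),
                "soft_tissue": KineticParams(0.06, 0.08, 0.020, 0.010),
            },
        )

    @classmethod
    def pbr28_like(cls) -> "TracerTemplate":
        """High-metabolite mode: parent falls to ~7% of blood activity at 90 min."""
        return cls(
            name="pbr28_like",
            feng={"A1": 200.0, "A2": 4.0, "A3": 1.8,
                  "lam1": 2.0, "lam2": 0.12, "lam3": 0.02, "tau": 1.0},
            # slope anchored so radiometabolites dominate from ~9 min on
            metabolite={"anchors": [(4.0, 0.96), (90.0, 0.07)], "hill_slope": 4.0},
            plasma_over_wholeblood=1.05,
            regions={
                "frontal_gm": KineticParams(0.15, 0.120, 0.050, 0.035),
                "temporal_gm": KineticParams(0.14, 0.115, 0.050, 0.035),
                "parietal_gm": KineticParams(0.15, 0.125, 0.045, 0.035),
                "occipital_gm": KineticParams(0.16, 0.130, 0.040, 0.030),
                "basal_ganglia": KineticParams(0.14, 0.120, 0.055, 0.035),
                "cerebellum": KineticParams(0.15, 0.130, 0.040, 0.033),
                "white_matter": KineticParams(0.08, 0.110, 0.040, 0.035),
                # translocator-protein-like peripheral binding in the neck
                "scalp": KineticParams(0.06, 0.10, 0.020, 0.012),
                "soft_tissue": KineticParams(0.08, 0.10, 0.030, 0.012),
            },
        )

    @classmethod
    def by_name(cls, name: str) -> "TracerTemplate":
        try:
            return {"rolipram_like": cls.rolipram_like, "pbr28_like": cls.pbr28_like}[name]()
        except KeyError:
            raise ValidationError(f"unknown tracer template {name!r}") from None


@dataclass
class PhantomSpec:
    """Geometry, resolution and noise parameters of the digital phantom."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 2.0  # mm, isotropic
    carotid_diameters: tuple[float, float] = (8.0, 5.0)
    psf: dict | None = field(
        default_factory=lambda: {"sigma1": 0.9, "sigma2": 2.5, "rho": 0.07}
    )
    noise_alpha: float = 0.1
    isotope_half_life: float = 20.364  # min, carbon-11
    frame_averaging: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.psf is not None:
            if self.psf["sigma1"] <= 0 or self.psf["sigma2"] <= 0:
                raise ValidationError("PSF sigmas must be positive")
            if self.psf["sigma1"] >= self.psf["sigma2"]:
                raise ValidationError("sigma1 must be smaller than sigma2")
            if not 0 <= self.psf["rho"] <= 1:
                raise ValidationError("rho must lie in [0, 1]")
        if self.noise_alpha < 0:
            raise ValidationError("noise_alpha must be non-negative")
        if any(d <= 0 for d in self.carotid_diameters):
            raise ValidationError("carotid diameters must be positive")


# ---------------------------------------------------------------------------
# Input-function generation


def feng_whole_blood(template: TracerTemplate, time_grid) -> np.ndarray:
    """Tri-exponential bolus model of the whole-blood curve (kBq/mL).

    Zero up to the appearance delay tau, then
    ``A1 (t-tau) e^{-lam1 (t-tau)}`` plus two slower washout exponentials;
    the defaults put the peak at ~1.5 min (90 s) post injection.
    """
    t = np.asarray(time_grid, dtype=float)
    f = template.feng
    a1, a2, a3 = f["A1"], f["A2"], f["A3"]
    l1, l2, l3 = f["lam1"], f["lam2"], f["lam3"]
    tp = t - f["tau"]
    tp = np.where(tp > 0, tp, 0.0)
    out = (
        a1 * tp * np.exp(-l1 * tp)
        + a2 * (np.exp(-l2 * tp) - np.exp(-l1 * tp))
        + a3 * (np.exp(-l3 * tp) - np.exp(-l1 * tp))
    )
    out[t <= f["tau"]] = 0.0
    return np.maximum(out, 0.0)


def _hill_ratio(t, t50, f_drop, h):
    t = np.asarray(t, dtype=float)
    th = np.where(t > 0, t, 0.0) ** h
    return 1.0 - f_drop * th / (th + t50**h)


def parent_fraction_curve(template: TracerTemplate, time_grid) -> np.ndarray:
    """Monotone non-increasing Hill-type parent/whole-blood ratio with r(0) = 1.

    ``r(t) = 1 - f * t^h / (t^h + t50^h)`` with the Hill slope ``h`` taken
    from the template and ``(t50, f)`` fitted through the metabolite anchors.
    """
    t = np.asarray(time_grid, dtype=float)
    anchors = template.metabolite["anchors"]
    h = float(template.metabolite["hill_slope"])
    at = np.array([a for a, _ in anchors], dtype=float)
    ar = np.array([r for _, r in anchors], dtype=float)
    if np.any(np.diff(at) <= 0):
        raise ValidationError("anchor times must be strictly increasing")
    if np.any(np.diff(ar) > 1e-12):
        raise ValidationError("anchor ratios must be non-increasing")
    if np.allclose(ar, 1.0):
        return np.ones_like(t)

    def resid(p):
        log_t50, logit_f = p
        f_drop = 1.0 / (1.0 + np.exp(-logit_f))
        return _hill_ratio(at, np.exp(log_t50), f_drop, h) - ar

    sol = optimize.least_squares(resid, [np.log(at.mean()), 0.0], xtol=1e-14, ftol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 0.02:
        raise ValidationError("metabolite anchors are not representable by a Hill curve")
    t50 = np.exp(sol.x[0])
    f_drop = 1.0 / (1.0 + np.exp(-sol.x[1]))
    return np.clip(_hill_ratio(t, t50, f_drop, h), 0.0, 1.0)


def make_input_function(
    template: TracerTemplate, time_grid=None
) -> InputFunction:
    """Arterial truth: Feng whole blood with parent plasma = whole blood * r(t)."""
    if time_grid is None:
        time_grid = np.arange(0.0, 90.0 + 1e-9, 0.01)
    t = np.asarray(time_grid, dtype=float)
    wb = feng_whole_blood(template, t)
    r = parent_fraction_curve(template, t)
    return InputFunction(t, wb, wb * r, provenance="arterial")


def tissue_tac_from_rates(
    params: KineticParams, input_function: InputFunction, time_grid
) -> np.ndarray:
    """2TCM tissue curve C1+C2 driven by the parent-plasma input (vB = 0)."""
    cp_v = (
        input_function.parent_plasma
        if input_function.parent_plasma is not None
        else input_function.whole_blood
    )
    return two_tissue_solution(params, np.asarray(time_grid, float),
                               input_function.times, cp_v)


# ---------------------------------------------------------------------------
# Phantom geometry


def build_head_phantom(spec: PhantomSpec) -> LabelMap:
    """Procedural head label map.

    A brain ellipsoid is split into four cortical sectors, a white-matter
    core, basal ganglia and cerebellum; a skull/scalp double shell surrounds
    it, a soft-tissue neck block sits below, and two pairs of vertical
    carotid cylinders (8 mm and 5 mm diameter by default) run up through the
    neck into the skull base near the temporal sectors.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    x, y, z = np.meshgrid(
        (np.arange(nx) + 0.5) * vs,
        (np.arange(ny) + 0.5) * vs,
        (np.arange(nz) + 0.5) * vs,
        indexing="ij",
    )
    cx, cy = nx * vs / 2.0, ny * vs / 2.0
    extent_z = nz * vs
    bz = 0.635 * extent_z  # brain centre height
    ax_, ay_, az_ = 0.32 * nx * vs, 0.40 * ny * vs, 0.28 * nz * vs

    def ellipsoid(scale):
        return ((x - cx) / (ax_ * scale)) ** 2 + ((y - cy) / (ay_ * scale)) ** 2 + (
            (z - bz) / (az_ * scale)
        ) ** 2 <= 1.0

    brain = ellipsoid(1.0)
    skull = ellipsoid(1.10) & ~ellipsoid(1.04)
    scalp = ellipsoid(1.17) & ~ellipsoid(1.10)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    ids = {
        "scalp": 1, "skull": 2, "soft_tissue": 3, "white_matter": 4,
        "frontal_gm": 5, "temporal_gm": 6, "parietal_gm": 7, "occipital_gm": 8,
        "basal_ganglia": 9, "cerebellum": 10, "carotid_8mm": 11, "carotid_5mm": 12,
    }

    # neck / facial soft tissue below the brain
    neck = (z < bz - 0.6 * az_) & (np.hypot(x - cx, y - cy) <= 0.58 * cx)
    labels[neck] = ids["soft_tissue"]
    labels[skull] = ids["skull"]
    labels[scalp] = ids["scalp"]

    dx, dy = x - cx, y - cy
    white = ellipsoid(0.72)
    grey = brain & ~white
    sector = np.where(
        z > bz + 0.55 * az_, ids["parietal_gm"],
        np.where(dy > 0.28 * ay_, ids["frontal_gm"],
                 np.where(dy < -0.28 * ay_, ids["occipital_gm"], ids["temporal_gm"])),
    )
    labels[grey] = sector[grey]
    labels[white] = ids["white_matter"]

    bg = (dx / (0.22 * ax_)) ** 2 + ((y - cy - 0.05 * ay_) / (0.28 * ay_)) ** 2 + (
        (z - bz + 0.1 * az_) / (0.25 * az_)
    ) ** 2 <= 1.0
    labels[bg] = ids["basal_ganglia"]

    cb = (dx / (0.45 * ax_)) ** 2 + ((y - cy + 0.55 * ay_) / (0.30 * ay_)) ** 2 + (
        (z - (bz - 0.75 * az_)) / (0.35 * az_)
    ) ** 2 <= 1.0
    labels[cb] = ids["cerebellum"]

    # carotid cylinders: vertical, entering below the brain near the temporal lobes
    z_top = bz - 0.55 * az_ + 10.0 * vs
    z_bot = 2.0 * vs
    placements = [
        (ids["carotid_8mm"], spec.carotid_diameters[0], (cx - 0.27 * nx * vs, cy - 0.06 * ny * vs)),
        (ids["carotid_8mm"], spec.carotid_diameters[0], (cx + 0.27 * nx * vs, cy - 0.06 * ny * vs)),
        (ids["carotid_5mm"], spec.carotid_diameters[1], (cx - 0.36 * nx * vs, cy + 0.08 * ny * vs)),
        (ids["carotid_5mm"], spec.carotid_diameters[1], (cx + 0.36 * nx * vs, cy + 0.08 * ny * vs)),
    ]
    for lab, diam, (px, py) in placements:
        r = diam / 2.0
        if r < vs / 2 or px - r < 0 or px + r > nx * vs or py - r < 0 or py + r > ny * vs:
            raise ValidationError("carotid does not fit in the phantom grid")
        cyl = (np.hypot(x - px, y - py) <= r) & (z >= z_bot) & (z <= z_top)
        labels[cyl] = lab

    names = {v: k for k, v in ids.items()}
    return LabelMap(labels, names, np.full(3, vs))


# ---------------------------------------------------------------------------
# PSF and scan simulation


def psf_kernel(spec: PhantomSpec, kernel_grid=None) -> np.ndarray:
    """Two-Gaussian resolution kernel (1-rho)G(sigma1) + rho G(sigma2), sum 1.

    Discretized at the voxel spacing with half-width >= 4 sigma2.
    """
    if spec.psf is None:
        k = np.zeros((1, 1, 1))
        k[0, 0, 0] = 1.0
        return k
    s1, s2, rho = spec.psf["sigma1"], spec.psf["sigma2"], spec.psf["rho"]
    vs = spec.voxel_size
    if kernel_grid is None:
        half = int(np.ceil(4.0 * s2 / vs))
        kernel_grid = np.arange(-half, half + 1) * vs
    g = np.asarray(kernel_grid, dtype=float)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    r2 = xx**2 + yy**2 + zz**2

    def gauss(sig):
        k = np.exp(-r2 / (2.0 * sig**2))
        return k / k.sum()

    kernel = (1.0 - rho) * gauss(s1) + rho * gauss(s2)
    return kernel / kernel.sum()


def _frame_values(times, values, schedule: FrameSchedule, averaging: bool) -> np.ndarray:
    """Sample a continuous curve per frame: midpoint value or in-frame mean."""
    if not averaging:
        return interpolate_curve(times, values, schedule.midpoints)
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.start_times, schedule.durations)):
        sub = np.linspace(s, s + d, 21)
        out[i] = np.trapezoid(interpolate_curve(times, values, sub), sub) / d
    return out


def make_label_tacs(
    template: TracerTemplate,
    time_grid=None,
    input_function: InputFunction | None = None,
) -> tuple[InputFunction, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Continuous TACs for every phantom label; carotid labels carry whole blood."""
    if time_grid is None:
        time_grid = np.arange(0.0, 90.0 + 1e-9, 0.01)
    t = np.asarray(time_grid, dtype=float)
    arterial = input_function if input_function is not None else make_input_function(template, t)
    tacs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, params in template.regions.items():
        tacs[name] = (t, tissue_tac_from_rates(params, arterial, t))
    for name in CAROTID_REGIONS:
        tacs[name] = (arterial.times, arterial.whole_blood)
    tacs["skull"] = (t, np.zeros_like(t))
    return arterial, tacs


def simulate_dynamic_scan(
    label_map: LabelMap,
    label_tacs: dict[str, tuple[np.ndarray, np.ndarray]],
    spec: PhantomSpec,
    schedule: FrameSchedule,
) -> DynamicImage:
    """Simulate a dynamic scan from a label phantom.

    Per frame, every voxel takes its label's TAC value at the frame midpoint
    (punctual detection) or the TAC's in-frame mean (``frame_averaging``);
    the frame is convolved with the resolution kernel (zero padding) and
    zero-mean Gaussian noise with variance
    ``alpha * max(v, 0) / (decay_factor(t_mid) * duration)`` is added.
    """
    missing = [label_map.names[i] for i in np.unique(label_map.labels) if i != 0
               and label_map.names[i] not in label_tacs]
    if missing:
        raise ValidationError(f"labels without TACs: {missing}")
    kernel = psf_kernel(spec)
    rng = np.random.default_rng(spec.seed)
    nframes = schedule.n_frames
    vol = np.zeros(label_map.labels.shape + (nframes,), dtype=float)

    frame_vals = {
        name: _frame_values(t, v, schedule, spec.frame_averaging)
        for name, (t, v) in label_tacs.items()
    }
    label_ids = [i for i in np.unique(label_map.labels) if i != 0]
    masks = {i: label_map.labels == i for i in label_ids}

    mid = schedule.midpoints
    decay = 2.0 ** (-mid / spec.isotope_half_life)
    for f in range(nframes):
        frame = np.zeros(label_map.labels.shape, dtype=float)
        for i in label_ids:
            frame[masks[i]] = frame_vals[label_map.names[i]][f]
        if kernel.size > 1:
            frame = signal.fftconvolve(frame, kernel, mode="same")
        if spec.noise_alpha > 0:
            var = spec.noise_alpha * np.maximum(frame, 0.0) / (decay[f] * schedule.durations[f])
            frame = frame + rng.standard_normal(frame.shape) * np.sqrt(var)
        vol[..., f] = frame
    return DynamicImage(vol, np.full(3, spec.voxel_size), schedule)


# ---------------------------------------------------------------------------
# Arterial sampling


def default_sampling_times() -> np.ndarray:
    """Clinical arterial schedule: every 15 s to 150 s, then sparse to 90 min."""
    return np.concatenate(
        [np.arange(0.25, 2.51, 0.25),
         [3, 4, 6, 8, 10, 15, 20, 30, 40, 50, 60, 75, 90]]
    )


def sample_arterial_blood(
    input_function: InputFunction,
    sampling_times=None,
    noise_cv: float = 0.0,
    seed: int = 0,
    plasma_over_wholeblood: float = 1.05,
) -> BloodSeries:
    """Draw discrete arterial samples from a continuous input function.

    Optional multiplicative Gaussian noise of coefficient of variation
    ``noise_cv`` is applied to the activity channels (seed-deterministic).
    """
    times = np.asarray(
        default_sampling_times() if sampling_times is None else sampling_times, float
    )
    wb = input_function.whole_blood_at(times)
    plasma = wb * plasma_over_wholeblood
    if input_function.parent_plasma is not None:
        parent = input_function.parent_plasma_at(times)
    else:
        parent = plasma.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        wb = np.maximum(wb * (1.0 + noise_cv * rng.standard_normal(wb.size)), 0.0)
        plasma = np.maximum(plasma * (1.0 + noise_cv * rng.standard_normal(wb.size)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pf = np.where(plasma > 0, parent / plasma, 0.0)
    return BloodSeries(times, wb, plasma, np.clip(pf, 0.0, 1.0))


# ---------------------------------------------------------------------------
# One-call study assembly (used by the merit layer, the CLI and the tests)


@dataclass
class SimulatedStudy:
    """Everything a method comparison needs from one simulated scan."""

    template: TracerTemplate
    spec: PhantomSpec
    schedule: FrameSchedule
    phantom: LabelMap
    image: DynamicImage
    arterial: InputFunction                 # continuous truth, parent included
    blood: BloodSeries                      # discrete noiseless/noisy samples
    parent_ratio: tuple[np.ndarray, np.ndarray]
    region_tacs: dict[str, np.ndarray]      # measured ROI means on the frame grid

    @property
    def grey_regions(self) -> tuple[str, ...]:
        return GREY_MATTER_REGIONS


def simulate_study(
    template: TracerTemplate,
    spec: PhantomSpec | None = None,
    schedule: FrameSchedule | None = None,
    blood_noise_cv: float = 0.0,
) -> SimulatedStudy:
    """Build phantom, TACs and a simulated scan for one tracer mode."""
    spec = spec if spec is not None else PhantomSpec()
    schedule = schedule if schedule is not None else FrameSchedule.clinical_default()
    phantom = build_head_phantom(spec)
    arterial, tacs = make_label_tacs(template)
    image = simulate_dynamic_scan(phantom, tacs, spec, schedule)
    blood = sample_arterial_blood(
        arterial, noise_cv=blood_noise_cv, seed=spec.seed + 104729,
        plasma_over_wholeblood=template.plasma_over_wholeblood,
    )
    t_r = np.asarray(arterial.times)
    ratio = parent_fraction_curve(template, t_r)
    region_tacs = {
        name: image.roi_tac(phantom.mask(name)) for name in GREY_MATTER_REGIONS
    }
    region_tacs["white_matter"] = image.roi_tac(phantom.mask("white_matter"))
    brain = np.zeros(phantom.labels.shape, dtype=bool)
    for name in (*GREY_MATTER_REGIONS, "white_matter"):
        brain |= phantom.mask(name)
    region_tacs["whole_brain"] = image.roi_tac(brain)
    return SimulatedStudy(
        template, spec, schedule, phantom, image, arterial, blood,
        (t_r, ratio), region_tacs,
    )
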