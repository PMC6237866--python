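"""Synthetic acquisition and cohort generator.

Everything the real study measured is emulated here so that every downstream
stage (input-function fitting, Logan quantification, regional statistics,
voxel-wise mapping) can be exercised end-to-end without any acquired data:

* a metabolite-corrected arterial input function of the linear-rise /
  tri-exponential family (the same family the analysis fits);
* a Hill-type parent-fraction curve (total plasma = parent / parent fraction);
* two-tissue-compartment tissue curves, solved in closed form;
* 4-D phantom images whose voxels follow atlas-structured kinetics;
* trait-score cohorts with configurable BPnd-trait association strength.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DynamicImage,
    FrameSchedule,
    SubjectRecord,
    TimeActivityCurve,
    TCI_TRAITS,
    VoiAtlas,
)
from .errors import ConfigurationError, ContractError, CoverageError

# ---------------------------------------------------------------------------
# Input function and metabolite models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AifParams:
    """Linear rise to a peak, then tri-exponential decay.

    Models the metabolite-corrected (parent) plasma concentration. The peak
    value is the sum of the amplitudes, so the curve is continuous at
    ``peak_time``.
    """

    peak_time: float = 1.5                      # min
    amplitudes: tuple = (20.0, 8.0, 3.0)        # kBq/mL
    decay_rates: tuple = (4.0, 0.5, 0.02)       # 1/min

    def __post_init__(self):
        if self.peak_time <= 0:
            raise ContractError("peak_time must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ContractError("amplitudes must be non-negative")
        if any(l <= 0 for l in self.decay_rates):
            raise ContractError("decay rates must be positive")
        if len(set(self.decay_rates)) != len(self.decay_rates):
            raise ContractError("decay rates must be distinct")

    @property
    def peak_value(self) -> float:
        return float(sum(self.amplitudes))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rise = self.peak_value * np.clip(t / self.peak_time, 0.0, None)
        u = t - self.peak_time
        decay = sum(a * np.exp(-l * np.clip(u, 0.0, None))
                    for a, l in zip(self.amplitudes, self.decay_rates))
        out = np.where(t <= self.peak_time, rise, decay)
        return np.where(t < 0, 0.0, out)

    def cum_integral(self, t) -> np.ndarray:
        """Exact running integral of the curve from 0 to t (kBq/mL * min)."""
        t = np.asarray(t, dtype=float)
        m = self.peak_value / self.peak_time
        ramp = 0.5 * m * np.clip(t, 0.0, self.peak_time) ** 2
        u = np.clip(t - self.peak_time, 0.0, None)
        tail = sum(a / l * (1.0 - np.exp(-l * u))
                   for a, l in zip(self.amplitudes, self.decay_rates))
        return ramp + tail


@dataclass(frozen=True)
class HillParams:
    """Hill-type parent fraction f(t) = 1 - a * t^b / (t^b + c).

    f(0)=1, monotone non-increasing, asymptote 1-a. Default parameters are
    calibrated so that roughly half the tracer is unmetabolized at 60 min
    post injection.
    """

    a: float = 0.55
    b: float = 1.0
    c: float = 6.6   # min^b

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ContractError("a must lie in [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise ContractError("b and c must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ContractError("parent fraction undefined for t < 0")
        tb = np.power(t, self.b)
        return 1.0 - self.a * tb / (tb + self.c)


def parent_fraction(params: HillParams, t):
    """Fraction of plasma activity attributable to unmetabolized tracer."""
    return params(t)


def simulate_aif(params: AifParams, times) -> TimeActivityCurve:
    """Sample the parent-plasma input model at the given times (minutes)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (len(times) > 1 and not np.all(np.diff(times) > 0)):
        raise ContractError("times must be 1-D strictly increasing")
    return TimeActivityCurve(times, params(times), label="plasma_parent", model=params)


# ---------------------------------------------------------------------------
# Two-tissue compartment model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TcmParams:
    """Rate constants of the two-tissue compartment model.

    K1 [mL/cm3/min] plasma->free, k2 [1/min] free->plasma, k3/k4 [1/min]
    free<->bound exchange. A reference region has k3 = 0.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0 or not 0 <= self.vB < 1:
            raise ContractError("rate constants must be non-negative, 0 <= vB < 1")
        if self.k3 > 0 and self.k4 <= 0:
            raise ContractError("k4 must be positive when k3 > 0")

    @property
    def vt(self) -> float:
        """Total distribution volume (K1/k2)(1 + k3/k4)."""
        bp = self.k3 / self.k4 if self.k3 > 0 else 0.0
        return self.K1 / self.k2 * (1.0 + bp)

    @property
    def bpnd(self) -> float:
        return self.k3 / self.k4 if self.k3 > 0 else 0.0

    def impulse_response(self):
        """Macro-rates (theta) and weights (phi) of IRF = K1 sum phi_i exp(-theta_i t)."""
        b = self.k2 + self.k3 + self.k4
        disc = np.sqrt(max(b * b - 4.0 * self.k2 * self.k4, 0.0))
        th1, th2 = 0.5 * (b - disc), 0.5 * (b + disc)
        if th2 - th1 < 1e-12:        # repeated macro-rate; perturb for stability
            th2 = th1 + 1e-9
        phi1 = (self.k3 + self.k4 - th1) / (th2 - th1)
        return (th1, th2), (phi1, 1.0 - phi1)


def _conv_ramp_exp(t, slope, theta):
    """∫0^t (slope*s) e^{-theta (t-s)} ds, stable as theta -> 0."""
    t = np.asarray(t, dtype=float)
    if theta < 1e-8:
        return 0.5 * slope * t * t
    return slope * (t / theta - (1.0 - np.exp(-theta * t)) / theta ** 2)


def _conv_exp_exp(u, lam, theta):
    """∫0^u e^{-lam s} e^{-theta (u-s)} ds."""
    u = np.asarray(u, dtype=float)
    if abs(theta - lam) < 1e-10:
        return u * np.exp(-theta * u)
    return (np.exp(-lam * u) - np.exp(-theta * u)) / (theta - lam)


def _conv_aif_exp(aif: AifParams, t, theta):
    """Exact convolution of the input model with e^{-theta t}, evaluated at t.

    Split at the peak: the ramp's contribution for t > tp is its value at tp
    carried forward under the exponential kernel; the tri-exponential tail
    contributes pairwise exp*exp convolutions.
    """
    t = np.asarray(t, dtype=float)
    tp = aif.peak_time
    m = aif.peak_value / tp
    u = np.clip(t - tp, 0.0, None)
    ramp_at_t = _conv_ramp_exp(np.clip(t, 0.0, tp), m, theta)
    ramp_at_tp = _conv_ramp_exp(np.asarray(tp), m, theta)
    carried = ramp_at_tp * (np.exp(-theta * u) if theta >= 1e-8 else 1.0)
    ramp_part = np.where(t <= tp, ramp_at_t, carried)
    tail = sum(a * _conv_exp_exp(u, lam, theta)
               for a, lam in zip(aif.amplitudes, aif.decay_rates))
    return ramp_part + np.where(t > tp, tail, 0.0)


def tissue_curve(tcm: TcmParams, aif: AifParams, t) -> np.ndarray:
    """Instantaneous tissue concentration of the 2TCM, in closed form."""
    (th1, th2), (ph1, ph2) = tcm.impulse_response()
    ct = tcm.K1 * (ph1 * _conv_aif_exp(aif, t, th1) + ph2 * _conv_aif_exp(aif, t, th2))
    if tcm.vB > 0:
        ct = (1.0 - tcm.vB) * ct + tcm.vB * aif(t)
    return ct


def conv_exp_sampled(times, cp, theta):
    """Convolution of a sampled curve (piecewise linear) with e^{-theta t}.

    Exact for piecewise-linear cp; used when the input exists only as samples.
    """
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    out = np.zeros_like(cp)
    for n in range(len(times) - 1):
        dt = times[n + 1] - times[n]
        a, b = cp[n], (cp[n + 1] - cp[n]) / dt
        if theta < 1e-8:
            inc = (a + 0.5 * b * dt) * dt
            out[n + 1] = out[n] + inc
        else:
            E = np.exp(-theta * dt)
            inc = (a + b * dt) * (1.0 - E) / theta - b * (1.0 - E * (1.0 + theta * dt)) / theta ** 2
            out[n + 1] = out[n] * E + inc
    return out


def _frame_grid(schedule: FrameSchedule, n_sub: int = 16):
    """(F, n_sub+1) matrix of times subdividing each frame."""
    w = np.linspace(0.0, 1.0, n_sub + 1)
    return schedule.frame_start[:, None] + schedule.durations[:, None] * w[None, :]


def simulate_2tcm(tcm: TcmParams, aif, schedule: FrameSchedule,
                  n_sub: int = 16, label: str = "tissue") -> TimeActivityCurve:
    """Frame-averaged tissue curve for the given kinetics and input.

    ``aif`` may be an :class:`AifParams` (or a TAC carrying one as ``model``),
    in which case the solution is fully analytic, or a plain sampled TAC, in
    which case an exact piecewise-linear convolution is used.
    """
    model = aif if isinstance(aif, AifParams) else getattr(aif, "model", None)
    grid = _frame_grid(schedule, n_sub)
    if model is not None:
        ct = tissue_curve(tcm, model, grid)
    else:
        if not isinstance(aif, TimeActivityCurve):
            raise ContractError("aif must be AifParams or TimeActivityCurve")
        if aif.times[-1] < schedule.frame_end[-1] - 1e-9:
            raise CoverageError("input function does not cover the frame schedule")
        flat = np.unique(np.concatenate([[0.0], aif.times, grid.ravel()]))
        cp = np.interp(flat, np.concatenate([[0.0], aif.times]),
                       np.concatenate([[0.0], aif.activity]))
        (th1, th2), (ph1, ph2) = tcm.impulse_response()
        conv = tcm.K1 * (ph1 * conv_exp_sampled(flat, cp, th1)
                         + ph2 * conv_exp_sampled(flat, cp, th2))
        if tcm.vB > 0:
            conv = (1.0 - tcm.vB) * conv + tcm.vB * cp
        ct = np.interp(grid, flat, conv)
    avg = np.trapezoid(ct, grid, axis=1) / schedule.durations
    return TimeActivityCurve(schedule.midpoints, avg, label=label)


def add_tac_noise(tac: TimeActivityCurve, schedule: FrameSchedule,
                  noise_fraction: float, seed) -> TimeActivityCurve:
    """Frame-duration-weighted Gaussian noise.

    Variance is proportional to activity / frame duration (the standard
    dynamic-PET surrogate for count statistics), scaled so the relative
    standard deviation at the last frame equals ``noise_fraction``.
    """
    if noise_fraction < 0:
        raise ContractError("noise_fraction must be >= 0")
    if noise_fraction == 0:
        return replace(tac)
    rng = np.random.default_rng(seed)
    a = np.clip(tac.activity, 0.0, None)
    d = schedule.durations
    ref = a[-1] / d[-1] if a[-1] > 0 else max(a.max() / d[-1], 1e-12)
    sd = noise_fraction * max(a[-1], 1e-12) * np.sqrt((a / d) / ref)
    noisy = np.clip(tac.activity + rng.normal(0.0, 1.0, size=a.shape) * sd, 0.0, None)
    return TimeActivityCurve(tac.times, noisy, label=tac.label)


# ---------------------------------------------------------------------------
# Atlas and phantoms
# ---------------------------------------------------------------------------


def make_synthetic_atlas(shape=(24, 28, 24), voxel_mm: float = 2.0) -> VoiAtlas:
    """Box-parcel atlas on an MNI-like centred grid.

    Parcels are axis-aligned blocks: crude geometry, but each named region of
    the study is present with enough voxels for stable regional means.
    """
    labels = np.zeros(shape, dtype=np.int32)
    boxes = {
        "cerebellum":    (slice(8, 16), slice(3, 8),  slice(2, 6)),
        "medulla":       (slice(10, 14), slice(8, 12), slice(2, 5)),
        "thalamus_AM":   (slice(8, 16), slice(15, 18), slice(13, 15)),
        "thalamus_AL":   (slice(8, 16), slice(15, 18), slice(11, 13)),
        "thalamus_CM":   (slice(8, 16), slice(13, 15), slice(13, 15)),
        "thalamus_CL":   (slice(8, 16), slice(13, 15), slice(11, 13)),
        "thalamus_P":    (slice(8, 16), slice(11, 13), slice(11, 15)),
        "amygdala_L":    (slice(4, 8),  slice(16, 20), slice(7, 10)),
        "amygdala_R":    (slice(16, 20), slice(16, 20), slice(7, 10)),
        "hypothalamus_L": (slice(9, 12), slice(17, 20), slice(9, 11)),
        "hypothalamus_R": (slice(12, 15), slice(17, 20), slice(9, 11)),
        "SON":           (slice(13, 15), slice(18, 20), slice(9, 11)),
        "cortex":        (slice(6, 18), slice(8, 22), slice(18, 21)),
    }
    name_map = {}
    for i, (name, box) in enumerate(boxes.items(), start=1):
        labels[box] = i
        name_map[i] = name
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) / 2.0)
    return VoiAtlas(labels, affine, name_map)


def tcm_for_bpnd(bpnd: float, K1: float = 0.30, k2: float = 0.25,
                 k4: float = 0.15) -> TcmParams:
    """Kinetic parameters whose reference-normalized truth equals ``bpnd``.

    With K1/k2 shared with the reference region, DVR = 1 + k3/k4, so setting
    k3 = bpnd * k4 makes the configured truth exact by construction. The
    default rates equilibrate well within the 60-min acquisition, so the
    terminal Logan segment is linear on the scan's own support.
    """
    if bpnd < 0:
        raise ContractError("bpnd must be >= 0")
    if bpnd == 0:
        return TcmParams(K1=K1, k2=k2, k3=0.0, k4=0.0)
    return TcmParams(K1=K1, k2=k2, k3=bpnd * k4, k4=k4)


def build_phantom(atlas: VoiAtlas, regional_params: Mapping[str, TcmParams],
                  aif, schedule: FrameSchedule, noise_fraction: float,
                  seed) -> DynamicImage:
    """4-D phantom: every voxel follows its region's 2TCM curve plus noise."""
    missing = [r for r in atlas.name_map.values() if r not in regional_params]
    if missing:
        raise ConfigurationError(f"no kinetic parameters for regions: {missing}")
    cer = regional_params.get("cerebellum")
    if cer is not None and cer.k3 != 0:
        raise ConfigurationError("reference region (cerebellum) must have k3 = 0")
    rng = np.random.default_rng(seed)
    vox = np.zeros(atlas.labels.shape + (schedule.n_frames,), dtype=float)
    for lab, name in atlas.name_map.items():
        tac = simulate_2tcm(regional_params[name], aif, schedule, label=name)
        mask = atlas.labels == lab
        n_vox = int(mask.sum())
        block = np.empty((n_vox, schedule.n_frames))
        for j in range(n_vox):
            block[j] = add_tac_noise(tac, schedule, noise_fraction,
                                     rng.integers(0, 2 ** 31)).activity
        vox[mask] = block
    return DynamicImage(vox, atlas.affine.copy(), schedule)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitLink:
    """A configured linear association between a trait score and a region."""

    trait: str            # "baq_total" or a TCI trait name
    region: str           # atlas label, or a prefix like "thalamus"
    direction: str        # "positive" | "negative"
    target_r2: float
    sex: str = "all"      # "F" | "M" | "all"

    def __post_init__(self):
        if not 0.0 <= self.target_r2 < 1.0:
            raise ConfigurationError("target_r2 must lie in [0, 1)")
        if self.direction not in ("positive", "negative"):
            raise ConfigurationError("direction must be positive|negative")


def default_region_means() -> dict[str, tuple[float, float]]:
    """Per-region (female, male) BPnd means.

    Ordering thalamus > medulla ~ amygdala ~ hypothalamus > cortex >
    cerebellum = 0, with a male > female shift everywhere except the right
    hypothalamus, where the tendency reverses.
    """
    return {
        "cerebellum": (0.0, 0.0),
        "thalamus_AM": (1.40, 1.50),
        "thalamus_AL": (1.35, 1.45),
        "thalamus_CM": (1.30, 1.40),
        "thalamus_CL": (1.25, 1.35),
        "thalamus_P": (1.50, 1.60),
        "amygdala_L": (0.90, 1.00),
        "amygdala_R": (0.90, 1.00),
        "hypothalamus_L": (0.85, 1.05),
        "hypothalamus_R": (1.00, 0.95),
        "SON": (1.00, 1.10),
        "medulla": (1.00, 1.10),
        "cortex": (0.30, 0.35),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to regenerate a synthetic cohort deterministically."""

    n_female: int = 10
    n_male: int = 11
    region_bpnd_means: Mapping[str, tuple] = field(default_factory=default_region_means)
    between_subject_sd: float = 0.15
    trait_links: tuple = (
        TraitLink("baq_total", "amygdala_L", "positive", 0.83, sex="F"),
        TraitLink("cooperativeness", "thalamus", "negative", 0.71, sex="all"),
    )
    noise_fraction: float = 0.02
    bpnd_voxel_sd: float = 0.10
    trait_mean: float = 50.0
    trait_sd: float = 10.0
    seed: int = 0


@dataclass
class CohortData:
    records: list
    truth: "object"                      # DataFrame: subject, sex, region, bpnd_truth
    bpnd_images: dict | None = None      # subject id -> 3-D array
    dynamic_images: dict | None = None   # subject id -> DynamicImage


def _resolve_region_truth(truths: Mapping[str, float], region: str) -> float:
    """A region name may be one label or a prefix covering several labels."""
    if region in truths:
        return truths[region]
    hits = [v for k, v in truths.items() if k.startswith(region)]
    if not hits:
        raise ConfigurationError(f"region {region!r} not resolvable in atlas")
    return float(np.mean(hits))


def _matched_labels(region_names: Sequence[str], region: str) -> list[str]:
    if region in region_names:
        return [region]
    hits = [r for r in region_names if r.startswith(region)]
    if not hits:
        raise ConfigurationError(f"region {region!r} not resolvable in atlas")
    return hits


def _predictor_moments(spec: "CohortSpec", region_names, link: TraitLink):
    """Population mean and SD of the link's predictor over the linked subjects.

    The predictor is the mean truth over the matched labels; its variance
    combines the within-sex subject variance (shrunk by label averaging) and,
    for pooled links, the between-sex mean shift.
    """
    labels = _matched_labels(region_names, link.region)
    mu_f = float(np.mean([spec.region_bpnd_means[r][0] for r in labels]))
    mu_m = float(np.mean([spec.region_bpnd_means[r][1] for r in labels]))
    var_within = spec.between_subject_sd ** 2 / len(labels)
    if link.sex == "F":
        return mu_f, np.sqrt(var_within)
    if link.sex == "M":
        return mu_m, np.sqrt(var_within)
    n = spec.n_female + spec.n_male
    p_f = spec.n_female / n
    mu = p_f * mu_f + (1 - p_f) * mu_m
    var = var_within + p_f * (mu_f - mu) ** 2 + (1 - p_f) * (mu_m - mu) ** 2
    return mu, np.sqrt(var)


def generate_cohort(spec: CohortSpec, atlas: VoiAtlas, image_mode: str = "bpnd",
                    aif: AifParams | None = None,
                    schedule: FrameSchedule | None = None) -> CohortData:
    """Draw a cohort of subjects with atlas-structured BPnd and linked traits.

    Each subject's regional BPnd truth is Gaussian around the per-sex mean;
    each linked trait is beta * BPnd + noise with the noise variance set so
    the population R^2 equals the link's target. ``image_mode``:

    * ``"bpnd"``    — parametric BPnd images directly (truth + voxel noise);
    * ``"dynamic"`` — full 4-D phantoms (requires ``aif`` and ``schedule``);
    * ``"none"``    — records and truths only.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    region_names = list(atlas.name_map.values())
    for r in region_names:
        if r not in spec.region_bpnd_means:
            raise ConfigurationError(f"no BPnd mean configured for region {r!r}")

    sexes = ["F"] * spec.n_female + ["M"] * spec.n_male
    ids = [f"sub-{i + 1:03d}" for i in range(len(sexes))]
    truths: dict[str, dict[str, float]] = {}
    rows = []
    for sid, sex in zip(ids, sexes):
        t = {}
        for r in region_names:
            mu = spec.region_bpnd_means[r][0 if sex == "F" else 1]
            t[r] = 0.0 if r == "cerebellum" else max(
                float(rng.normal(mu, spec.between_subject_sd)), 0.01)
        truths[sid] = t
        rows.extend({"subject": sid, "sex": sex, "region": r, "bpnd_truth": v}
                    for r, v in t.items())
    truth_df = pd.DataFrame(rows)

    # trait scores: linked traits regress on the subject's regional truth
    all_traits = ("baq_total",) + TCI_TRAITS
    links_by_trait = {}
    for link in spec.trait_links:
        links_by_trait.setdefault(link.trait, link)   # first link wins per trait
    scores = {sid: {} for sid in ids}
    for trait in all_traits:
        link = links_by_trait.get(trait)
        for sid, sex in zip(ids, sexes):
            if link is not None and link.sex in ("all", sex):
                x = _resolve_region_truth(truths[sid], link.region)
                mu_x, sd_x = _predictor_moments(spec, region_names, link)
                sgn = 1.0 if link.direction == "positive" else -1.0
                beta = sgn * spec.trait_sd * np.sqrt(link.target_r2) / sd_x
                eps_sd = spec.trait_sd * np.sqrt(1.0 - link.target_r2)
                val = spec.trait_mean + beta * (x - mu_x) + rng.normal(0.0, eps_sd)
            else:
                val = spec.trait_mean + rng.normal(0.0, spec.trait_sd)
            scores[sid][trait] = float(val)

    records = []
    for sid, sex in zip(ids, sexes):
        age_mu, age_sd = (34.7, 6.4) if sex == "F" else (31.7, 8.1)
        records.append(SubjectRecord(
            id=sid, sex=sex, age=float(np.clip(rng.normal(age_mu, age_sd), 20, 60)),
            baq_total=scores[sid]["baq_total"],
            tci={t: scores[sid][t] for t in TCI_TRAITS},
            arterial_sampled=False))

    bpnd_images = dynamic_images = None
    if image_mode == "bpnd":
        bpnd_images = {}
        for sid in ids:
            img = np.zeros(atlas.labels.shape, dtype=float)
            for lab, name in atlas.name_map.items():
                m = atlas.labels == lab
                img[m] = truths[sid][name] + rng.normal(
                    0.0, spec.bpnd_voxel_sd, size=int(m.sum()))
            bpnd_images[sid] = img
    elif image_mode == "dynamic":
        if aif is None or schedule is None:
            raise ConfigurationError("dynamic image mode needs aif and schedule")
        dynamic_images = {}
        for sid in ids:
            params = {r: tcm_for_bpnd(truths[sid][r]) for r in region_names}
            dynamic_images[sid] = build_phantom(
                atlas, params, aif, schedule, spec.noise_fraction,
                seed=rng.integers(0, 2 ** 31))
    elif image_mode != "none":
        raise ConfigurationError(f"unknown image_mode {image_mode!r}")

    return CohortData(records, truth_df, bpnd_images, dynamic_images)


# ---------------------------------------------------------------------------
# Arterial subject (blood + tissue) generation
# ---------------------------------------------------------------------------


@dataclass
class ArterialSubject:
    """One subject with blood sampling: what the arterial Logan route needs."""

    id: str
    plasma_samples: TimeActivityCurve        # total plasma (parent + metabolites)
    parent_fraction_samples: tuple           # (times, fractions)
    regional_tacs: dict                      # region -> frame-averaged TAC
    aif_truth: AifParams
    hill_truth: HillParams
    tcm_truth: dict


def simulate_arterial_subject(regional_params: Mapping[str, TcmParams],
                              aif: AifParams, hill: HillParams,
                              schedule: FrameSchedule, sample_times,
                              parent_times, noise_fraction: float,
                              seed, subject_id: str = "art-001") -> ArterialSubject:
    """Blood samples plus regional tissue curves for one arterial subject.

    Total plasma = parent curve / parent fraction (the tissue is driven by the
    parent only, matching the metabolite-correction step of the analysis).
    Blood sample noise is proportional (3 percent of each value at
    ``noise_fraction`` 0.03); tissue noise follows the frame-weighted model.
    """
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    total = aif(sample_times) / np.clip(hill(sample_times), 1e-6, None)
    total = total * (1.0 + rng.normal(0.0, noise_fraction, size=total.shape))
    plasma = TimeActivityCurve(sample_times, np.clip(total, 0.0, None),
                               label="plasma_total")
    pf_t = np.asarray(parent_times, dtype=float)
    pf = np.clip(hill(pf_t) + rng.normal(0.0, noise_fraction / 3.0, size=pf_t.shape),
                 0.0, 1.0)
    tacs = {}
    for name, p in regional_params.items():
        clean = simulate_2tcm(p, aif, schedule, label=name)
        tacs[name] = add_tac_noise(clean, schedule, noise_fraction,
                                   rng.integers(0, 2 ** 31))
    return ArterialSubject(subject_id, plasma, (pf_t, pf), tacs, aif, hill,
                           dict(regional_params))
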