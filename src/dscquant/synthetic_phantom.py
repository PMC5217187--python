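"""Seeded 4D DSC phantoms with full ground truth.

The phantom emulates a standard glioma perfusion acquisition: 40 dynamic
frames at 2.2 s spacing, TE = 60 ms, a few T1-saturated leading frames, a
pre-bolus baseline, and a gamma-variate first-pass bolus arriving about 25 s
after the start of acquisition, followed by a smaller, broader recirculation
bump.  Three tissue classes (white matter, gray matter, tumor) carry distinct
blood volumes (default CBV multipliers 1 : 2 : 3); tumor voxels optionally
leak contrast according to the same linear reference-curve model the
correction stage fits, so coefficient recovery can be tested exactly.

The signal model inverts the concentration equation exactly,

    S(t) = S_base * exp(-TE * dR2*(t)) + Gaussian noise,

so on noiseless phantoms the signal -> concentration stage is exactly
invertible.  The leakage term uses the discrete trapezoidal running integral
of the sampled reference curve (the same quadrature the correction uses), so
noiseless K1/K2 recovery is exact rather than merely close.

Geometry is deliberately simple — a gray-matter band around a white-matter
core with an embedded tumor sphere on a 32 x 32 x 8 grid — small enough for
seconds-scale tests, structured enough for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import gamma as gamma_fn

from .errors import SpecError
from .io_volumes import DscSeries, ProbabilityMap

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "gamma_variate",
    "generate_phantom",
    "generate_t1_post",
    "generate_rater_table",
    "CLASS_BACKGROUND",
    "CLASS_WM",
    "CLASS_GM",
    "CLASS_TUMOR",
]

CLASS_BACKGROUND = 0
CLASS_WM = 1
CLASS_GM = 2
CLASS_TUMOR = 3


@dataclass
class PhantomSpec:
    """Acquisition and tissue parameters of the synthetic phantom.

    Defaults follow a typical 1.5/3 T DSC protocol: 40 frames, ~2 s apart,
    TE 60 ms, bolus appearing in the brain ~25 s after acquisition start,
    with the first 3 frames distorted by saturation.
    """

    shape: tuple[int, int, int] = (8, 32, 32)  # (z, y, x)
    n_frames: int = 40
    frame_spacing: float = 2.2  # seconds
    te: float = 60.0  # milliseconds
    n_saturation: int = 3
    saturation_factors: tuple[float, ...] = (1.5, 1.2, 1.05)
    bolus_arrival: float = 25.0  # seconds from acquisition start
    gamma_alpha: float = 3.0  # gamma-variate shape
    gamma_beta: float = 1.5  # gamma-variate time scale, seconds
    recirc_delay: float = 12.0  # seconds after first-pass onset
    recirc_fraction: float = 0.25  # recirculation amplitude fraction
    recirc_beta: float = 3.0  # broader second pass
    wm_peak_dr2s: float = 0.010  # peak WM dR2*, 1/ms
    cbv_multipliers: dict[int, float] = field(
        default_factory=lambda: {CLASS_WM: 1.0, CLASS_GM: 2.0, CLASS_TUMOR: 3.0}
    )
    baseline_si: dict[int, float] = field(
        default_factory=lambda: {
            CLASS_BACKGROUND: 50.0,
            CLASS_WM: 400.0,
            CLASS_GM: 500.0,
            CLASS_TUMOR: 450.0,
        }
    )
    tumor_k2: float = 0.02  # leakage rate, 1/s; 0 disables leakage
    tumor_k1: float | None = None  # if set, tumor curve = k1*ref - k2*cum(ref)
    noise_sd: float = 5.0  # additive Gaussian signal noise
    tumor_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bolus_arrival >= self.n_frames * self.frame_spacing:
            raise SpecError("bolus arrival beyond the series duration")
        if self.frame_spacing <= 0 or self.te <= 0:
            raise SpecError("frame spacing and TE must be positive")
        if self.gamma_alpha <= 0 or self.gamma_beta <= 0 or self.recirc_beta <= 0:
            raise SpecError("gamma-variate parameters must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be >= 0")


@dataclass
class PhantomTruth:
    """Everything the generator knows that the pipeline must recover."""

    class_labels: np.ndarray  # (z, y, x) int
    brain_mask: np.ndarray  # (z, y, x) bool
    true_cbv: np.ndarray  # (z, y, x): first-pass area of the noiseless curve
    entrance: int  # post-discard frame indices
    trough: int
    exit: int
    n_saturation: int
    true_k1: np.ndarray  # relative to the non-enhancing reference curve
    true_k2: np.ndarray  # 1/s
    wm_probability: ProbabilityMap
    reference_curve: np.ndarray  # noiseless non-enhancing mean, post-discard
    cumulative_reference: np.ndarray  # its trapezoidal running integral
    noiseless_signal: np.ndarray  # (t, z, y, x), all frames incl. saturation
    unit_curve: np.ndarray  # post-discard noiseless WM dR2*(t) (multiplier 1)


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate bolus shape with unit time-integral, zero before ``t0``."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    norm = beta ** (alpha + 1) * gamma_fn(alpha + 1)
    out[pos] = dt[pos] ** alpha * np.exp(-dt[pos] / beta) / norm
    return out


def _class_geometry(spec: PhantomSpec) -> np.ndarray:
    """Concentric blocks: GM band around a WM core with a tumor sphere."""
    nz, ny, nx = spec.shape
    labels = np.full(spec.shape, CLASS_BACKGROUND, dtype=np.int32)
    margin, band = 2, 2
    brain = np.zeros(spec.shape, dtype=bool)
    brain[:, margin : ny - margin, margin : nx - margin] = True
    inner = np.zeros(spec.shape, dtype=bool)
    inner[:, margin + band : ny - margin - band, margin + band : nx - margin - band] = True
    labels[brain & ~inner] = CLASS_GM
    labels[inner] = CLASS_WM
    zc, yc, xc = (nz - 1) / 2.0, (ny - 1) / 2.0, 3 * nx / 4.0
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    sphere = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= spec.tumor_radius**2
    labels[sphere & inner] = CLASS_TUMOR
    return labels


def _unit_concentration(spec: PhantomSpec, times: np.ndarray) -> np.ndarray:
    """Noiseless WM (multiplier 1) dR2* curve: first pass + recirculation."""
    fp_peak = (
        spec.gamma_alpha**spec.gamma_alpha
        * np.exp(-spec.gamma_alpha)
        / (spec.gamma_beta * gamma_fn(spec.gamma_alpha + 1))
    )
    cbv_wm = spec.wm_peak_dr2s / fp_peak  # first-pass area giving the target peak
    fp = gamma_variate(times, spec.bolus_arrival, spec.gamma_alpha, spec.gamma_beta)
    rc = gamma_variate(
        times,
        spec.bolus_arrival + spec.recirc_delay,
        spec.gamma_alpha,
        spec.recirc_beta,
    )
    return cbv_wm * (fp + spec.recirc_fraction * rc), cbv_wm


def _landmarks(unit_pd: np.ndarray) -> tuple[int, int, int]:
    """True entrance/trough/exit frames from the noiseless post-discard curve."""
    trough = int(np.argmax(unit_pd))  # concentration peak = signal trough
    entrance = int(np.flatnonzero(unit_pd[: trough + 1] <= 0)[-1])
    # exit: concentration local minimum between first pass and recirculation
    seg = unit_pd[trough + 1 :]
    rel_min = 1 + np.flatnonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))
    if rel_min.size:
        exit_ = trough + 1 + int(rel_min[0])
    else:  # no recirculation: take effective first-pass end (<2% of peak)
        below = np.flatnonzero(seg <= 0.02 * unit_pd[trough])
        exit_ = trough + 1 + (int(below[0]) if below.size else seg.size - 1)
    return entrance, trough, exit_


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[DscSeries, PhantomTruth]:
    """Generate a seeded DSC phantom and its ground truth.

    The per-voxel noiseless concentration is the class multiplier times the
    unit curve; tumor voxels additionally subtract ``k2`` times the running
    trapezoidal integral of the non-enhancing reference curve (T1-dominant
    leakage).  Ground-truth K1 is expressed relative to that reference curve,
    which is what the correction stage estimates.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _class_geometry(spec)
    brain = labels != CLASS_BACKGROUND
    times = np.arange(spec.n_frames) * spec.frame_spacing
    unit, cbv_wm = _unit_concentration(spec, times)

    mult = np.zeros(spec.shape)
    for cls, m in spec.cbv_multipliers.items():
        mult[labels == cls] = m

    # Non-enhancing reference = mean noiseless curve over WM + GM voxels.
    nonenh = (labels == CLASS_WM) | (labels == CLASS_GM)
    mean_mult = float(mult[nonenh].mean())
    reference = mean_mult * unit

    nd = spec.n_saturation
    unit_pd = unit[nd:]
    ref_pd = reference[nd:]
    cum_ref_pd = cumulative_trapezoid(ref_pd, dx=spec.frame_spacing, initial=0.0)
    cum_full = np.zeros_like(times)
    cum_full[nd:] = cum_ref_pd  # leakage accrues on the analysed axis

    conc = mult[None] * unit[:, None, None, None]
    tumor = labels == CLASS_TUMOR
    k1_true = np.where(brain, mult / mean_mult, np.nan)
    k2_true = np.where(brain, 0.0, np.nan)
    if tumor.any() and (spec.tumor_k2 != 0 or spec.tumor_k1 is not None):
        if spec.tumor_k1 is not None:
            conc[:, tumor] = (
                spec.tumor_k1 * reference[:, None]
                - spec.tumor_k2 * cum_full[:, None]
            )
            k1_true[tumor] = spec.tumor_k1
        else:
            conc[:, tumor] = conc[:, tumor] - spec.tumor_k2 * cum_full[:, None]
        k2_true[tumor] = spec.tumor_k2

    s_base = np.zeros(spec.shape)
    for cls, si in spec.baseline_si.items():
        s_base[labels == cls] = si
    signal = s_base[None] * np.exp(-spec.te * conc)
    sat = np.ones(spec.n_frames)
    sat[: len(spec.saturation_factors)] = spec.saturation_factors
    signal = signal * sat[:, None, None, None]
    noiseless = signal.copy()
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    signal = np.maximum(signal, 0.0)

    entrance, trough, exit_ = _landmarks(unit_pd)
    true_cbv = np.where(brain, mult * cbv_wm, np.nan)
    wm_prob = np.full(spec.shape, 0.02)
    wm_prob[labels == CLASS_GM] = 0.30
    wm_prob[labels == CLASS_WM] = 0.98

    series = DscSeries(
        signal=signal,
        frame_spacing=spec.frame_spacing,
        te=spec.te,
        brain_mask=brain,
    )
    truth = PhantomTruth(
        class_labels=labels,
        brain_mask=brain,
        true_cbv=true_cbv,
        entrance=entrance,
        trough=trough,
        exit=exit_,
        n_saturation=nd,
        true_k1=k1_true,
        true_k2=k2_true,
        wm_probability=ProbabilityMap(prob=wm_prob),
        reference_curve=ref_pd,
        cumulative_reference=cum_ref_pd,
        noiseless_signal=noiseless,
        unit_curve=unit_pd,
    )
    return series, truth


def generate_t1_post(
    truth: PhantomTruth, noise_sd: float = 10.0, seed: int = 0
) -> np.ndarray:
    """Synthetic post-contrast T1w volume: enhancing tumor on a dim brain."""
    rng = np.random.default_rng(seed)
    intensity = {CLASS_BACKGROUND: 40.0, CLASS_WM: 300.0, CLASS_GM: 350.0,
                 CLASS_TUMOR: 700.0}
    vol = np.zeros(truth.class_labels.shape)
    for cls, v in intensity.items():
        vol[truth.class_labels == cls] = v
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return vol


def generate_rater_table(
    n_subjects: int,
    sigma_b: float,
    sigma_w: float,
    k: int = 2,
    seed: int = 0,
    mu: float = 2.0,
) -> np.ndarray:
    """n x k ratings under the one-way random-effects model.

    value_ij = mu + b_i + e_ij with b_i ~ N(0, sigma_b^2) shared across
    raters and e_ij ~ N(0, sigma_w^2), so the population ICC is
    sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    if n_subjects < 2:
        raise SpecError("need at least 2 subjects")
    if sigma_b < 0 or sigma_w < 0:
        raise SpecError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, size=n_subjects)
    e = rng.normal(0.0, sigma_w, size=(n_subjects, k))
    return mu + b[:, None] + e
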