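"""Synthetic 12-lead ECG / phenotype / genotype generator with known truth.

The beat model is a deterministic sum of Gaussian wave components (P, Q, R,
S, T) on a time grid.  Wave centers and widths are derived from the PR
interval, QRS duration and QT interval; each wave is projected onto the six
limb leads through the cosine of the angle between its frontal-plane axis
and the lead direction, and onto the precordial leads through a fixed gain
vector.  Within the fixed median-beat window the beat is replicated at the
RR period, so that at faster heart rates the neighbouring beat's P wave and
QRS enter the window — the mechanism by which fixed-window median beats
carry rate information.

Phenotypes (continuous, binary, survival) are generated from stated linear,
logistic and exponential proportional-hazards models on the generative
parameters plus age and sex; every coefficient is recorded as ground truth.
Genotypes are Hardy-Weinberg binomial dosages with optional planted
additive effects on generative parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ECGRecord,
    GenerativeParams,
    LEAD_NAMES,
    LIMB_LEAD_ANGLES,
    MedianBeat,
    PRECORDIAL_GAINS,
    WAVE_NAMES,
)

# Wave geometry constants (seconds); widths of the QRS sub-waves scale with
# the QRS duration, P and T widths are fixed.
P_SIGMA_S = 0.020
T_SIGMA_S = 0.050
_QRS_SIGMA_FRAC = {"Q": 0.08, "R": 0.13, "S": 0.08}
_QRS_CENTER_FRAC = {"Q": 0.15, "R": 0.50, "S": 0.85}
_WAVE_AXIS_FIELD = {"P": "p_axis", "Q": "r_axis", "R": "r_axis",
                    "S": "r_axis", "T": "t_axis"}

#: Default fraction of the median-beat window preceding the R peak.
R_PEAK_FRACTION = 0.25


def _lead_projection(axis_deg: float) -> np.ndarray:
    """Per-lead scale factor for a wave with the given frontal-plane axis."""
    proj = np.empty(len(LEAD_NAMES))
    for i, lead in enumerate(LEAD_NAMES):
        if lead in LIMB_LEAD_ANGLES:
            proj[i] = math.cos(math.radians(axis_deg - LIMB_LEAD_ANGLES[lead]))
        else:
            proj[i] = PRECORDIAL_GAINS[lead]
    return proj


def _wave_schedule(params: GenerativeParams, r_time: float) -> list[tuple[str, float, float]]:
    """(wave, center_s, sigma_s) for one beat whose R peak sits at r_time."""
    qrs_s = params.qrs_duration / 1000.0
    qrs_onset = r_time - qrs_s / 2.0
    sched = []
    p_center = qrs_onset - params.pr_interval / 1000.0 + 2.0 * P_SIGMA_S
    sched.append(("P", p_center, P_SIGMA_S))
    for w in ("Q", "R", "S"):
        sched.append((w, qrs_onset + _QRS_CENTER_FRAC[w] * qrs_s,
                      _QRS_SIGMA_FRAC[w] * qrs_s))
    t_center = qrs_onset + params.qt_interval / 1000.0 - 2.0 * T_SIGMA_S
    sched.append(("T", t_center, T_SIGMA_S))
    return sched


def _beat_waveform(params: GenerativeParams, t: np.ndarray, r_time: float) -> np.ndarray:
    """12 x len(t) contribution of a single beat with R peak at r_time (s)."""
    out = np.zeros((len(LEAD_NAMES), t.size))
    for wave, center, sigma in _wave_schedule(params, r_time):
        amp = float(params.wave_amplitudes[wave])
        if amp == 0.0:
            continue
        shape = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        proj = _lead_projection(getattr(params, _WAVE_AXIS_FIELD[wave]))
        out += amp * np.outer(proj, shape)
    return out


def simulate_median_beat(
    params: GenerativeParams,
    length_ms: float = 1200.0,
    sampling_rate: float = 500.0,
    r_peak_index: int | None = None,
    rng: np.random.Generator | None = None,
) -> MedianBeat:
    """Render one median beat from generative parameters.

    The central beat's R peak is placed at ``r_peak_index`` (default 25% of
    the window) and the beat is replicated at multiples of the RR interval
    so neighbouring-beat waves appear inside the window exactly as they
    would in a fixed-window median beat of a periodic rhythm.  Deterministic
    unless an ``rng`` is supplied and ``params.noise_sd > 0``.
    """
    n = int(round(length_ms / 1000.0 * sampling_rate))
    if r_peak_index is None:
        r_peak_index = int(round(R_PEAK_FRACTION * n))
    if not 0 <= r_peak_index < n:
        raise ValueError("r_peak_index outside beat window")
    t = np.arange(n) / sampling_rate
    r_time = r_peak_index / sampling_rate
    length_s = length_ms / 1000.0

    sched = _wave_schedule(params, r_time)
    p_start = sched[0][1] - 2.0 * sched[0][2]
    t_end = sched[-1][1] + 2.0 * sched[-1][2]
    if p_start < 0 or t_end > length_s:
        raise ValueError(
            "P-to-T extent does not fit the beat window: "
            f"P onset {p_start * 1000:.0f} ms, T offset {t_end * 1000:.0f} ms, "
            f"window {length_ms:.0f} ms"
        )

    rr = 60.0 / params.ventricular_rate
    # replicate beats covering the window with a half-second margin
    k_lo = int(math.floor((-0.5 - r_time) / rr))
    k_hi = int(math.ceil((length_s + 0.5 - r_time) / rr))
    samples = np.zeros((len(LEAD_NAMES), n))
    for k in range(k_lo, k_hi + 1):
        samples += _beat_waveform(params, t, r_time + k * rr)

    if rng is not None and params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, samples.shape)
    return MedianBeat(samples, sampling_rate, r_peak_index)


def simulate_rhythm_strip(
    params: GenerativeParams,
    duration: float = 10.0,
    rr_jitter_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 500.0,
) -> ECGRecord:
    """Render a multi-beat rhythm strip with baseline drift and white noise.

    R peaks form a train at mean RR = 60/rate starting at RR/2, with
    Gaussian jitter added to each RR step.  A linear baseline
    (slope * t + offset) and white noise of sd ``params.noise_sd`` are added
    to every lead.  Reproducible: a pure function of (inputs, seed).
    """
    rr = 60.0 / params.ventricular_rate
    n_beats = int(math.floor(duration / rr + 0.5))
    if n_beats < 2:
        raise ValueError(
            f"rate {params.ventricular_rate} yields {n_beats} beat(s) in "
            f"{duration} s; need at least 2"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    r_times = [0.5 * rr]
    while True:
        nxt = r_times[-1] + rr + (rng.normal(0.0, rr_jitter_sd) if rr_jitter_sd > 0 else 0.0)
        if nxt >= duration:
            break
        r_times.append(nxt)

    samples = np.zeros((len(LEAD_NAMES), n))
    for rt in r_times:
        samples += _beat_waveform(params, t, rt)
    samples += params.baseline_slope * t + params.baseline_offset
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, samples.shape)

    peaks = np.array([int(round(rt * sampling_rate)) for rt in r_times])
    peaks = peaks[peaks < n]
    return ECGRecord(samples, sampling_rate, duration, true_r_peaks=peaks)


# ---------------------------------------------------------------------------
# Population sampling


@dataclass
class ParamDistributions:
    """Truncated-normal marginals (and optional correlation) for the seven
    traditional generative parameters, plus wave-amplitude marginals.

    ``marginals`` maps parameter name to (mean, sd, low, high).  ``corr`` is
    an optional correlation matrix across the seven parameters in
    ``PARAM_ORDER``; identity (independent variation) by default.
    """

    PARAM_ORDER = ("ventricular_rate", "pr_interval", "qrs_duration",
                   "qt_interval", "p_axis", "r_axis", "t_axis")

    marginals: dict = field(default_factory=lambda: {
        "ventricular_rate": (62.0, 10.0, 45.0, 100.0),
        "pr_interval": (162.0, 22.0, 100.0, 240.0),
        "qrs_duration": (92.0, 10.0, 65.0, 130.0),
        "qt_interval": (410.0, 28.0, 320.0, 500.0),
        "p_axis": (48.0, 20.0, -30.0, 110.0),
        "r_axis": (25.0, 30.0, -60.0, 110.0),
        "t_axis": (40.0, 22.0, -30.0, 110.0),
    })
    amplitude_marginals: dict = field(default_factory=lambda: {
        "P": (0.15, 0.03), "Q": (-0.10, 0.025), "R": (1.00, 0.15),
        "S": (-0.25, 0.06), "T": (0.35, 0.07),
    })
    corr: np.ndarray | None = None
    noise_sd: float = 0.01
    age_mean: float = 64.6
    age_sd: float = 7.73
    age_bounds: tuple = (40.0, 80.0)
    female_fraction: float = 0.516

    def __post_init__(self) -> None:
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            k = len(self.PARAM_ORDER)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ValueError("corr must be a symmetric 7x7 matrix")
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError as exc:
                raise ValueError("corr must be positive definite") from exc
            self.corr = c


@dataclass
class OutcomeSpec:
    """One phenotype generated from generative parameters, age and sex.

    Predictors are centered at ``centers`` before the coefficients apply, so
    intercepts are interpretable at the reference subject.  ``kind`` is
    'continuous' (Gaussian noise ``noise_sd``), 'binary' (logistic), or
    'survival' (exponential proportional hazards; ``intercept`` is the log
    baseline hazard per year, censoring administrative at a per-subject
    follow-up drawn uniformly from ``follow_up_range`` years).
    """

    name: str
    kind: str
    intercept: float
    coeffs: dict
    noise_sd: float = 0.0
    centers: dict = field(default_factory=dict)
    follow_up_range: tuple = (2.0, 5.5)


def default_outcome_model() -> list[OutcomeSpec]:
    centers = {"age": 64.6, "sex": 0.5, "ventricular_rate": 62.0,
               "pr_interval": 162.0, "qrs_duration": 92.0, "qt_interval": 410.0}
    return [
        OutcomeSpec("lv_mass", "continuous", 88.0,
                    {"qrs_duration": 0.45, "age": 0.4, "sex": 14.0,
                     "ventricular_rate": -0.12}, noise_sd=9.0, centers=centers),
        OutcomeSpec("stroke_volume", "continuous", 76.0,
                    {"qt_interval": 0.07, "ventricular_rate": -0.3,
                     "sex": 12.0, "age": -0.2}, noise_sd=8.0, centers=centers),
        OutcomeSpec("hypertension", "binary", -1.0,
                    {"age": 0.05, "sex": 0.3, "ventricular_rate": 0.015},
                    centers=centers),
        OutcomeSpec("conduction_disease", "binary", -2.6,
                    {"qrs_duration": 0.05, "age": 0.03}, centers=centers),
        OutcomeSpec("survival", "survival", math.log(0.012),
                    {"age": 0.06, "sex": 0.4, "ventricular_rate": 0.012},
                    centers=centers),
    ]


@dataclass
class PhenotypeTable:
    """Per-subject phenotypes plus the ground-truth model that made them."""

    data: pd.DataFrame
    truth: dict

    def __getitem__(self, col):
        return self.data[col]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _sample_truncnorm(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    bad = (x < low) | (x > high)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x < low) | (x > high)
    return x


def sample_population(
    n: int,
    param_distributions: ParamDistributions | None = None,
    outcome_model: list[OutcomeSpec] | None = None,
    seed: int = 0,
) -> tuple[list[GenerativeParams], PhenotypeTable]:
    """Draw a cohort of generative parameters and model-generated phenotypes.

    Returns the per-subject generative parameters and a PhenotypeTable whose
    ``truth`` dict records every coefficient used, keyed by outcome name.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = param_distributions or ParamDistributions()
    outcomes = outcome_model if outcome_model is not None else default_outcome_model()
    rng = np.random.default_rng(seed)

    order = ParamDistributions.PARAM_ORDER
    k = len(order)
    if dist.corr is None:
        z = rng.standard_normal((n, k))
    else:
        z = rng.multivariate_normal(np.zeros(k), dist.corr, size=n,
                                    method="cholesky")
    cols = {}
    for j, name in enumerate(order):
        mean, sd, low, high = dist.marginals[name]
        x = mean + sd * z[:, j]
        bad = (x < low) | (x > high)
        # redraw out-of-bounds values marginally (correlation structure is
        # preserved for the overwhelming in-bounds majority)
        if np.any(bad):
            x[bad] = _sample_truncnorm(rng, mean, sd, low, high, int(bad.sum()))
        cols[name] = x
    amps = {w: rng.normal(m, s, n) for w, (m, s) in dist.amplitude_marginals.items()}

    age = _sample_truncnorm(rng, dist.age_mean, dist.age_sd, *dist.age_bounds, n)
    sex = (rng.random(n) >= dist.female_fraction).astype(int)  # 1 = male

    params_list = []
    for i in range(n):
        params_list.append(GenerativeParams(
            ventricular_rate=cols["ventricular_rate"][i],
            pr_interval=cols["pr_interval"][i],
            qrs_duration=cols["qrs_duration"][i],
            qt_interval=max(cols["qt_interval"][i], cols["qrs_duration"][i] + 60.0),
            p_axis=cols["p_axis"][i], r_axis=cols["r_axis"][i],
            t_axis=cols["t_axis"][i],
            wave_amplitudes={w: float(amps[w][i]) for w in WAVE_NAMES},
            noise_sd=dist.noise_sd,
        ))

    predictors = dict(cols)
    predictors["age"] = age
    predictors["sex"] = sex.astype(float)

    table = {"id": [f"S{i:06d}" for i in range(n)], "age": age, "sex": sex}
    truth = {}
    for spec in outcomes:
        lp = np.full(n, float(spec.intercept))
        for pname, coef in spec.coeffs.items():
            lp += coef * (predictors[pname] - spec.centers.get(pname, 0.0))
        truth[spec.name] = {"kind": spec.kind, "intercept": spec.intercept,
                            "coeffs": dict(spec.coeffs),
                            "centers": dict(spec.centers)}
        if spec.kind == "continuous":
            table[spec.name] = lp + (rng.normal(0.0, spec.noise_sd, n)
                                     if spec.noise_sd > 0 else 0.0)
            truth[spec.name]["noise_sd"] = spec.noise_sd
        elif spec.kind == "binary":
            p = 1.0 / (1.0 + np.exp(-lp))
            table[spec.name] = (rng.random(n) < p).astype(int)
        elif spec.kind == "survival":
            hazard = np.exp(lp)  # events per year
            event_time = rng.exponential(1.0 / hazard)
            follow_up = rng.uniform(*spec.follow_up_range, n)
            observed = np.minimum(event_time, follow_up)
            table["survival_time"] = observed
            table["event"] = (event_time <= follow_up).astype(int)
        else:
            raise ValueError(f"unknown outcome kind {spec.kind!r}")

    return params_list, PhenotypeTable(pd.DataFrame(table), truth)


def four_parameter_cohort() -> ParamDistributions:
    """Recovery-study conditions: ventricular rate, PR, QRS and QT vary
    independently across their default marginals while axes and wave
    amplitudes are clamped at the cohort means, so the four interval/rate
    parameters are the only generative degrees of freedom."""
    dist = ParamDistributions()
    for ax in ("p_axis", "r_axis", "t_axis"):
        mean = dist.marginals[ax][0]
        dist.marginals[ax] = (mean, 0.0, mean - 1.0, mean + 1.0)
    dist.amplitude_marginals = {
        w: (m, 0.0) for w, (m, _) in dist.amplitude_marginals.items()}
    return dist


def params_to_frame(params_list: list[GenerativeParams]) -> pd.DataFrame:
    """Tabulate per-subject generative (traditional ECG) parameters."""
    return pd.DataFrame([p.as_dict() for p in params_list])


def cohort_median_beats(
    params_list: list[GenerativeParams],
    length_ms: float = 1200.0,
    sampling_rate: float = 500.0,
    seed: int | None = None,
) -> list[MedianBeat]:
    """Median beats for a cohort; measurement noise added when seeded."""
    rng = np.random.default_rng(seed) if seed is not None else None
    return [simulate_median_beat(p, length_ms, sampling_rate, rng=rng)
            for p in params_list]


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2) with per-variant allele frequencies and the
    planted additive effects on generative parameters (per effect allele)."""

    dosages: np.ndarray           # n_subjects x m_variants
    mafs: np.ndarray              # (m,)
    true_effects: dict            # variant_id -> {param_name: per-allele shift}
    variant_ids: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        m = self.dosages.shape[1]
        if self.mafs.shape != (m,) or len(self.variant_ids) != m:
            raise ValueError("inconsistent variant dimensions")
        if m and (np.any(self.mafs <= 0) or np.any(self.mafs > 0.5)):
            raise ValueError("mafs must lie in (0, 0.5]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, columns=self.variant_ids).to_csv(
            path, sep="\t", index=False)


def simulate_genotypes(
    n: int,
    m: int,
    mafs,
    effect_spec: dict | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Hardy-Weinberg binomial(2, maf) dosages with planted effects.

    ``effect_spec`` maps variant index (or id) to a dict of per-allele
    additive shifts on generative parameters; it is recorded as truth and
    applied to a cohort with :func:`apply_genotype_effects`.
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if mafs.size == 1 and m != 1:
        mafs = np.full(m, float(mafs[0]))
    if mafs.shape != (m,):
        raise ValueError(f"need {m} mafs, got {mafs.shape}")
    if m and (np.any(mafs <= 0) or np.any(mafs > 0.5)):
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = (rng.binomial(2, mafs, size=(n, m)) if m
               else np.zeros((n, 0), dtype=int))
    variant_ids = [f"var{j:05d}" for j in range(m)]
    true_effects = {}
    for key, eff in (effect_spec or {}).items():
        vid = variant_ids[key] if isinstance(key, (int, np.integer)) else key
        if vid not in variant_ids:
            raise KeyError(f"unknown variant {key!r}")
        true_effects[vid] = dict(eff)
    return GenotypeMatrix(dosages, mafs, true_effects, variant_ids)


def apply_genotype_effects(
    params_list: list[GenerativeParams],
    genotypes: GenotypeMatrix,
) -> list[GenerativeParams]:
    """Additively shift generative parameters by dosage x per-allele effect."""
    if len(params_list) != genotypes.n_subjects:
        raise ValueError("cohort size mismatch")
    if not genotypes.true_effects:
        return list(params_list)
    col = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    out = []
    for i, p in enumerate(params_list):
        shifts: dict = {}
        for vid, eff in genotypes.true_effects.items():
            d = genotypes.dosages[i, col[vid]]
            if d == 0:
                continue
            for pname, delta in eff.items():
                shifts[pname] = shifts.get(pname, 0.0) + d * delta
        if shifts:
            changes = {k: getattr(p, k) + v for k, v in shifts.items()
                       if k != "wave_amplitudes"}
            p = p.replace(**changes)
        out.append(p)
    return out
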