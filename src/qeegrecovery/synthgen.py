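"""Synthetic post-resuscitation EEG cohort generator.

Emulates two-channel rat EEG during the first four hours after restoration of
spontaneous circulation (ROSC), for a two-arm study (hydrogen-treated ``H2``
vs. control ``Ctrl``).  Each animal passes through the canonical recovery
sequence

    isoelectric  ->  burst suppression  ->  continuous background

with a *planted* (known) onset time of burst (OTOB), time to normal trace
(TTNT), instantaneous burst-occupancy trajectory, and outcome variables
(96-h survival, survival time, neurological deficit score, serum S100B).
Because the ground truth is planted, every downstream detector and statistic
can be verified against it.

Amplitude regimes are constructed to respect the annotation thresholds used
by the analysis (isoelectric envelope < 5 uV, burst envelope > 10 uV in both
channels, suppression envelope < 10 uV, continuous floor > 5 uV), with margin,
so that threshold-based classification is well posed by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import optimize, signal
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "QuartileDistribution",
    "GroupParams",
    "AmplitudeParams",
    "GeneratorConfig",
    "AnimalProfile",
    "Recording",
    "generate_cohort",
    "generate_recording",
    "generate_baseline",
    "iter_recording_chunks",
    "cohort_to_frame",
]


class ConfigurationError(ValueError):
    """Raised when generator parameters violate their invariants."""


# ---------------------------------------------------------------------------
# Quartile-matched sampling distribution
# ---------------------------------------------------------------------------

_Z75 = norm.ppf(0.75)  # 0.6744897...


@dataclass(frozen=True)
class QuartileDistribution:
    """Continuous distribution fitted to a (Q1, median, Q3) triple.

    A shifted log-normal matches right-skewed triples (Q3 - med > med - Q1)
    exactly at all three quartiles.  Left-skewed triples use the reflected
    shifted log-normal; symmetric ones a normal with sd = IQR / 1.349.
    """

    kind: str          # "lognormal" | "reflected" | "normal"
    shift: float       # location shift (or reflection point for "reflected")
    mu: float          # log-scale mean (or mean for "normal")
    sigma: float       # log-scale sd   (or sd for "normal")

    @classmethod
    def fit(cls, q1: float, median: float, q3: float) -> "QuartileDistribution":
        if not (0 < q1 <= median <= q3):
            raise ConfigurationError(
                f"quartiles must satisfy 0 < Q1 <= median <= Q3, got "
                f"({q1}, {median}, {q3})"
            )
        a = q3 - median
        b = median - q1
        if a <= 0 or b <= 0 or abs(a - b) < 1e-9 * max(a, b, 1.0):
            iqr = q3 - q1
            sd = iqr / (2 * _Z75) if iqr > 0 else 0.0
            return cls("normal", 0.0, median, sd)
        if a > b:  # right skew: X = shift + exp(mu + sigma Z)
            sigma = math.log(a / b) / _Z75
            scale = a / (math.exp(_Z75 * sigma) - 1.0)
            return cls("lognormal", median - scale, math.log(scale), sigma)
        # left skew: X = shift - exp(mu + sigma Z); quartiles reflect
        sigma = math.log(b / a) / _Z75
        scale = b / (math.exp(_Z75 * sigma) - 1.0)
        return cls("reflected", median + scale, math.log(scale), sigma)

    def ppf(self, u):
        """Quantile function, vectorised over ``u`` in (0, 1)."""
        u = np.asarray(u, dtype=float)
        z = norm.ppf(u)
        if self.kind == "normal":
            return self.mu + self.sigma * z
        if self.kind == "lognormal":
            return self.shift + np.exp(self.mu + self.sigma * z)
        # reflected: quantile u of X maps to quantile 1-u of the mirrored LN
        return self.shift - np.exp(self.mu - self.sigma * z)

    @property
    def median(self) -> float:
        if self.kind == "normal":
            return self.mu
        if self.kind == "lognormal":
            return self.shift + math.exp(self.mu)
        return self.shift - math.exp(self.mu)


def stratified_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted stratified draws: one uniform per stratum [i/n, (i+1)/n)."""
    return (np.arange(n) + rng.uniform(size=n)) / n


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Per-arm calibration of recovery dynamics and outcomes.

    Onset times are given as (Q1, median, Q3) in minutes post-ROSC;
    ``twa_bsr_mean``/``sd`` calibrate the Normal distribution of the planted
    time-weighted-average burst-suppression ratio; the pooled survival-time
    quartiles (hours, survivors censored at 96 h) calibrate death times.
    """

    otob_quartiles_min: tuple[float, float, float]
    ttnt_quartiles_min: tuple[float, float, float]
    twa_bsr_mean: float
    twa_bsr_sd: float
    survival_prob: float
    survival_time_quartiles_h: tuple[float, float, float]

    def validate(self) -> None:
        QuartileDistribution.fit(*self.otob_quartiles_min)
        QuartileDistribution.fit(*self.ttnt_quartiles_min)
        if not self.otob_quartiles_min[2] < self.ttnt_quartiles_min[0]:
            raise ConfigurationError(
                "OTOB quartiles must lie below TTNT quartiles"
            )
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ConfigurationError("survival_prob must be in [0, 1]")
        if not 0 < self.twa_bsr_mean < 1:
            raise ConfigurationError("twa_bsr_mean must be in (0, 1)")
        q1, q2, q3 = self.survival_time_quartiles_h
        if not 0 < q1 <= q2 <= q3:
            raise ConfigurationError("survival-time quartiles out of order")


@dataclass(frozen=True)
class AmplitudeParams:
    """Amplitude regimes (uV) for the three EEG phases.

    The classification thresholds are 5 uV (isoelectric / continuous floor)
    and 10 uV (burst); defaults keep each regime clear of its threshold:
    isoelectric and suppression noise envelopes sit near 3-4 uV, burst
    envelopes at 12-22 uV, and the continuous background alternates between
    an 8-9.5 uV floor and 12-22 uV runs.
    """

    iso_sd: float = 1.0
    suppression_sd: float = 1.2
    burst_amp_range: tuple[float, float] = (12.0, 22.0)
    continuous_env_range: tuple[float, float] = (7.5, 25.0)

    def validate(self) -> None:
        if self.burst_amp_range[0] <= 10.0:
            raise ConfigurationError("burst amplitudes must exceed 10 uV")
        if 4.0 * self.suppression_sd >= 10.0:
            raise ConfigurationError(
                "suppression_sd too large: suppression envelope must stay "
                "below 10 uV"
            )
        if 4.0 * self.iso_sd >= 5.0:
            raise ConfigurationError(
                "iso_sd too large: isoelectric envelope must stay below 5 uV"
            )
        lo, hi = self.continuous_env_range
        if not (5.0 < lo < 10.0 < hi):
            raise ConfigurationError(
                "continuous_env_range must straddle the 10 uV threshold with "
                "a floor above 5 uV"
            )

    @property
    def continuous_low_range(self) -> tuple[float, float]:
        lo = self.continuous_env_range[0]
        return (max(8.0, lo), 9.5)

    @property
    def continuous_high_range(self) -> tuple[float, float]:
        hi = self.continuous_env_range[1]
        return (12.0, max(13.0, min(hi, 22.0)))


def _default_groups() -> Mapping[str, GroupParams]:
    return {
        "H2": GroupParams(
            otob_quartiles_min=(20.00, 21.85, 23.38),
            ttnt_quartiles_min=(161.63, 169.83, 208.55),
            twa_bsr_mean=0.66,
            twa_bsr_sd=0.09,
            survival_prob=0.90,
            survival_time_quartiles_h=(96.00, 96.00, 96.00),
        ),
        "Ctrl": GroupParams(
            otob_quartiles_min=(22.48, 25.70, 30.05),
            ttnt_quartiles_min=(186.29, 208.39, 248.80),
            twa_bsr_mean=0.52,
            twa_bsr_sd=0.17,
            survival_prob=0.40,
            survival_time_quartiles_h=(22.85, 44.00, 96.00),
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort-generator configuration.

    ``duration_min`` is the monitored post-ROSC window (the TTNT censoring
    horizon); the synthesized signal carries one extra tail minute so the
    final scheduled analysis segment [240, 241] min is covered.
    """

    n_per_group: int = 20
    fs: float = 1000.0
    duration_min: float = 240.0
    groups: Mapping[str, GroupParams] = field(default_factory=_default_groups)
    amplitude: AmplitudeParams = field(default_factory=AmplitudeParams)
    line_noise_freq: float = 50.0
    line_noise_amp: float = 2.0
    artifact_rate_per_h: float = 1.0
    artifact_amp: float = 2000.0
    # burst-occupancy trajectory shape
    ramp_min: float = 45.0            # minutes from OTOB to plateau
    onset_floor_occupancy: float = 0.10
    bs_occupancy_cap: float = 0.79    # burst<=3 s with suppression>=0.8 s
    cont_occupancy_cap: float = 0.95
    min_burst_s: float = 0.6
    max_burst_s: float = 3.0
    min_suppression_s: float = 0.8
    # bursts/high runs are rendered longer at each edge so the *envelope*
    # stays above threshold for the nominal duration (the carrier needs a
    # fraction of a cycle to build peak-to-peak amplitude; short events
    # lose proportionally more, hence the extra length-dependent term in
    # the schedule builder)
    burst_edge_comp_s: float = 0.075
    censor_h: float = 96.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_min <= 0:
            raise ConfigurationError("duration_min must be positive")
        if self.fs <= 2.0 * self.line_noise_freq:
            raise ConfigurationError(
                f"fs={self.fs} cannot represent {self.line_noise_freq} Hz "
                "line interference (Nyquist)"
            )
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        for gp in self.groups.values():
            gp.validate()
        self.amplitude.validate()
        if not 0 < self.onset_floor_occupancy < self.bs_occupancy_cap:
            raise ConfigurationError("occupancy floor/cap out of order")
        if not self.bs_occupancy_cap <= self.cont_occupancy_cap < 1.0:
            raise ConfigurationError("occupancy caps out of order")


# ---------------------------------------------------------------------------
# Profiles and recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalProfile:
    """Planted ground truth for one animal.

    ``planted_ttnt_min`` may exceed the monitored duration, in which case the
    animal never reaches the continuous pattern within the recording
    (right-censored TTNT), matching the minority of animals that remain in
    burst suppression at 4 h.
    """

    animal_id: str
    group: str
    planted_otob_min: float
    planted_ttnt_min: float
    plateau_occupancy: float
    twa_bsr_target: float
    survived_96h: bool
    survival_time_h: float
    nds_24: float
    nds_48: float
    nds_72: float
    nds_96: float
    s100b_bl: float
    s100b_120: float
    s100b_240: float
    stream_seed: int
    # trajectory shape parameters copied from the generating config
    ramp_min: float = 45.0
    onset_floor_occupancy: float = 0.10
    bs_occupancy_cap: float = 0.79
    cont_occupancy_cap: float = 0.95

    def __post_init__(self):
        if not self.planted_otob_min < self.planted_ttnt_min:
            raise ConfigurationError("planted OTOB must precede planted TTNT")
        for v in (self.nds_24, self.nds_48, self.nds_72, self.nds_96):
            if not 0 <= v <= 500:
                raise ConfigurationError("NDS out of [0, 500]")

    def bsr_trajectory(self, t_min):
        """Instantaneous burst occupancy (fraction of time above 10 uV)
        at ``t_min`` minutes post-ROSC."""
        return _occupancy(
            np.asarray(t_min, dtype=float),
            self.planted_otob_min,
            self.planted_ttnt_min,
            self.plateau_occupancy,
            self.ramp_min,
            self.onset_floor_occupancy,
            self.bs_occupancy_cap,
            self.cont_occupancy_cap,
        )

    def wpe_complexity_trajectory(self, t_min):
        """Planted signal-complexity index in [0, 1]; scales the bandwidth
        of the synthesized activity (higher = broader band = higher WPE)."""
        occ = self.bsr_trajectory(t_min)
        return np.clip(0.2 + 0.6 * occ / self.cont_occupancy_cap, 0.0, 1.0)


@dataclass
class Recording:
    """Two-channel EEG trace in uV with a ROSC-relative clock."""

    data: np.ndarray          # shape (2, n_samples)
    fs: float
    animal_id: str
    t0_post_rosc_min: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise ValueError("Recording data must have shape (2, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_samples / self.fs / 60.0


def _occupancy(t, otob, ttnt, plateau, ramp, floor, bs_cap, cont_cap):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    post = t >= otob
    g = np.clip((t - otob) / max(ramp, 1e-9), 0.0, 1.0)
    raw = np.maximum(floor, plateau * g)
    in_bs = post & (t < ttnt)
    out[in_bs] = np.minimum(raw[in_bs], bs_cap)
    in_cont = t >= ttnt
    out[in_cont] = min(max(plateau, floor), cont_cap)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Post-ROSC analysis schedule in minutes (5 min, then every 30 min).
DEFAULT_SCHEDULE_MIN = (5.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)


def planted_twa(
    profile_or_kwargs,
    schedule_min: Sequence[float] = DEFAULT_SCHEDULE_MIN,
    segment_len_min: float = 1.0,
) -> float:
    """Trapezoidal time-weighted average of the planted occupancy trajectory,
    evaluated exactly as the measurement pipeline does: per-segment means over
    each one-minute window, trapezoid over the schedule."""
    traj = (
        profile_or_kwargs.bsr_trajectory
        if isinstance(profile_or_kwargs, AnimalProfile)
        else profile_or_kwargs
    )
    sched = np.asarray(schedule_min, dtype=float)
    sub = np.linspace(0.0, segment_len_min, 13)
    seg_means = np.array(
        [np.trapezoid(traj(t + sub), sub) / segment_len_min for t in sched]
    )
    return float(np.trapezoid(seg_means, sched) / (sched[-1] - sched[0]))


def _solve_plateau(target_twa, otob, ttnt, config: GeneratorConfig) -> float:
    """Plateau occupancy whose planted TWA equals ``target_twa`` (clamped to
    the achievable range under the occupancy caps)."""

    def twa_of(p):
        def traj(t):
            return _occupancy(
                t, otob, ttnt, p, config.ramp_min,
                config.onset_floor_occupancy, config.bs_occupancy_cap,
                config.cont_occupancy_cap,
            )
        return planted_twa(traj)

    lo, hi = 1e-3, 1.5
    f_lo, f_hi = twa_of(lo) - target_twa, twa_of(hi) - target_twa
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return float(optimize.brentq(
        lambda p: twa_of(p) - target_twa, lo, hi, xtol=1e-4))


def _fit_death_lognormal(
    pooled_q: tuple[float, float, float], n: int, n_deaths: int,
    censor_h: float,
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal death-time distribution chosen so that
    stratified death draws reproduce the configured survival-time quartiles
    under the product-limit (Kaplan-Meier) quantile convention: the cohort's
    KM median/quartiles then match the configured values.  Quartiles in the
    censored region (value at the censoring horizon) carry no information.
    """
    constraints = []
    for q, v in ((0.25, pooled_q[0]), (0.5, pooled_q[1]), (0.75, pooled_q[2])):
        # product-limit convention: the q-quantile of survival is the k-th
        # death with k = ceil(q n) (first time S drops to 1 - q or below)
        k = math.ceil(q * n)
        if 1 <= k <= n_deaths and v < censor_h - 1e-9:
            u = (k - 0.5) / n_deaths      # matching stratified-draw quantile
            constraints.append((norm.ppf(u), math.log(v)))
    if len(constraints) >= 2:
        (z1, l1), (z2, l2) = constraints[0], constraints[-1]
        if z2 - z1 > 1e-9 and l2 > l1:
            sigma = (l2 - l1) / (z2 - z1)
            return l1 - sigma * z1, sigma
    # unidentifiable (e.g. nearly all survivors): generic post-arrest spread
    return math.log(25.0), 0.6


def _ranks(x: np.ndarray) -> np.ndarray:
    return np.argsort(np.argsort(x, kind="stable"), kind="stable")


def generate_cohort(config: GeneratorConfig) -> list[AnimalProfile]:
    """Draw one cohort of planted animal profiles, fully reproducible from
    ``config.seed``.

    Planted OTOB/TTNT come from quartile-fitted distributions via stratified
    inverse-CDF sampling, rank-coupled through a latent per-animal severity so
    that slow burst onset, slow normalisation, low burst occupancy, death,
    high NDS and high S100B co-occur, as in the physiology being emulated.
    """
    config.validate()
    if config.n_per_group <= 0:
        return []
    n = config.n_per_group
    profiles: list[AnimalProfile] = []
    master = np.random.SeedSequence(config.seed)
    group_seqs = master.spawn(len(config.groups))

    for (gname, gp), gseq in zip(config.groups.items(), group_seqs):
        rng = np.random.Generator(np.random.PCG64(gseq))
        otob_dist = QuartileDistribution.fit(*gp.otob_quartiles_min)
        ttnt_dist = QuartileDistribution.fit(*gp.ttnt_quartiles_min)

        severity = rng.standard_normal(n)
        u_otob = stratified_uniform(n, rng)[
            _ranks(severity + 0.5 * rng.standard_normal(n))]
        u_ttnt = stratified_uniform(n, rng)[
            _ranks(severity + 0.5 * rng.standard_normal(n))]
        u_twa = stratified_uniform(n, rng)[
            _ranks(-(severity + 0.6 * rng.standard_normal(n)))]

        otob = np.asarray(otob_dist.ppf(u_otob))
        ttnt = np.asarray(ttnt_dist.ppf(u_ttnt))
        ttnt = np.maximum(ttnt, otob + 5.0)
        twa_target = gp.twa_bsr_mean + gp.twa_bsr_sd * norm.ppf(u_twa)
        twa_target = np.clip(twa_target, 0.02, 0.98)

        # survival: fixed calibrated death count, worst recoverers die
        n_deaths = n - int(round(n * gp.survival_prob))
        death_rank_score = severity + 0.7 * rng.standard_normal(n)
        dying = np.zeros(n, dtype=bool)
        if n_deaths > 0:
            dying[np.argsort(death_rank_score)[::-1][:n_deaths]] = True
        survival_time = np.full(n, config.censor_h)
        if n_deaths > 0:
            mu_d, sigma_d = _fit_death_lognormal(
                gp.survival_time_quartiles_h, n, n_deaths, config.censor_h)
            u_death = stratified_uniform(n_deaths, rng)
            death_times = np.exp(mu_d + sigma_d * norm.ppf(u_death))
            death_times = np.clip(death_times, 1.0, config.censor_h - 0.5)
            # earliest deaths go to the worst-ranked animals
            dying_idx = np.where(dying)[0]
            order = np.argsort(death_rank_score[dying_idx])[::-1]
            survival_time[dying_idx[order]] = np.sort(death_times)

        # outcome scores, rank-linked to severity
        nds_base = np.clip(
            140.0 + 110.0 * (severity + 0.4 * rng.standard_normal(n)),
            0.0, 470.0)
        decay = {24: 1.0, 48: 0.75, 72: 0.55, 96: 0.40}
        nds = {}
        for tp, d in decay.items():
            val = np.clip(nds_base * d * (1 + 0.05 * rng.standard_normal(n)),
                          0.0, 500.0)
            val[~dying & (val > 470)] = 470.0
            val[dying & (survival_time <= tp)] = 500.0
            nds[tp] = val
        s100b_bl = np.clip(60.0 + 8.0 * rng.standard_normal(n), 10.0, None)
        s100b_120 = np.clip(
            120.0 + 90.0 * (severity + 0.3 * rng.standard_normal(n)),
            20.0, None)
        s100b_240 = np.clip(
            180.0 + 130.0 * (severity + 0.3 * rng.standard_normal(n)),
            20.0, None)

        stream_seeds = rng.integers(0, 2**31 - 1, size=n)

        for i in range(n):
            plateau = _solve_plateau(
                float(twa_target[i]), float(otob[i]), float(ttnt[i]), config)
            profiles.append(AnimalProfile(
                animal_id=f"{gname}-{i + 1:02d}",
                group=gname,
                planted_otob_min=float(otob[i]),
                planted_ttnt_min=float(ttnt[i]),
                plateau_occupancy=plateau,
                twa_bsr_target=float(twa_target[i]),
                survived_96h=bool(not dying[i]),
                survival_time_h=float(survival_time[i]),
                nds_24=float(nds[24][i]),
                nds_48=float(nds[48][i]),
                nds_72=float(nds[72][i]),
                nds_96=float(nds[96][i]),
                s100b_bl=float(s100b_bl[i]),
                s100b_120=float(s100b_120[i]),
                s100b_240=float(s100b_240[i]),
                stream_seed=int(stream_seeds[i]),
                ramp_min=config.ramp_min,
                onset_floor_occupancy=config.onset_floor_occupancy,
                bs_occupancy_cap=config.bs_occupancy_cap,
                cont_occupancy_cap=config.cont_occupancy_cap,
            ))
    return profiles


def cohort_to_frame(profiles: Sequence[AnimalProfile]):
    """Ground-truth table (one row per animal) as a pandas DataFrame."""
    import pandas as pd

    cols = [
        "animal_id", "group", "planted_otob_min", "planted_ttnt_min",
        "plateau_occupancy", "twa_bsr_target", "survived_96h",
        "survival_time_h", "nds_24", "nds_48", "nds_72", "nds_96",
        "s100b_bl", "s100b_120", "s100b_240", "stream_seed",
    ]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in profiles])


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

# event kinds: "std" events scale band-limited noise to a target standard
# deviation (isoelectric background, suppression); "p2p" events scale to a
# target max-absolute amplitude with cosine edge tapers (bursts, continuous
# high/low runs); "artifact" adds a high-amplitude transient on top.


@dataclass(frozen=True)
class _Event:
    start_s: float
    dur_s: float
    kind: str
    amp: float
    f_lo: float
    f_hi: float
    seed_l: int
    seed_r: int


@lru_cache(maxsize=256)
def _band_sos(f_lo: float, f_hi: float, fs: float):
    f_hi = min(f_hi, 0.45 * fs)
    f_lo = min(f_lo, 0.5 * f_hi)
    return signal.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs,
                         output="sos")


def _build_schedule(profile: AnimalProfile, config: GeneratorConfig,
                    total_s: float) -> list[_Event]:
    rng = np.random.default_rng([profile.stream_seed, 0])
    amp = config.amplitude
    events: list[_Event] = []

    def seeds():
        s = rng.integers(0, 2**31 - 1, size=2)
        return int(s[0]), int(s[1])

    def add(start, dur, kind, a, f_lo, f_hi):
        if kind == "p2p_floor":  # envelope edge compensation (see config)
            e = config.burst_edge_comp_s + 0.0625 * math.exp(
                -max(0.0, dur - 0.6) / 0.6)
            start, dur = max(0.0, start - e), dur + 2.0 * e
        sl, sr = seeds()
        events.append(_Event(start, dur, kind, a,
                             f_lo, float(round(f_hi)), sl, sr))

    otob_s = profile.planted_otob_min * 60.0
    ttnt_s = profile.planted_ttnt_min * 60.0

    t = 0.0
    while t < min(otob_s, total_s):
        dur = min(10.0, min(otob_s, total_s) - t)
        add(t, dur, "std", amp.iso_sd, 0.5, 3.0)
        t += dur

    # burst-suppression phase: cycle length L is drawn so that burst = occ*L
    # and suppression = (1-occ)*L satisfy the duration constraints exactly,
    # making per-cycle occupancy equal the trajectory by construction.
    t = otob_s
    while t < min(ttnt_s, total_s):
        occ = float(profile.bsr_trajectory(t / 60.0))
        c = float(profile.wpe_complexity_trajectory(t / 60.0))
        occ = min(max(occ, 0.02), config.bs_occupancy_cap)
        l_lo = max(config.min_suppression_s / (1.0 - occ),
                   config.min_burst_s / occ)
        l_hi = max(l_lo, min(config.max_burst_s / occ, 2.5 * l_lo))
        cyc = rng.uniform(l_lo, l_hi)
        b, supp = occ * cyc, (1.0 - occ) * cyc
        b_amp = rng.uniform(*amp.burst_amp_range)
        end = min(ttnt_s, total_s)
        add(t, min(b, end - t), "p2p_floor", b_amp, 8.0,
            8.0 + 4.0 + 30.0 * c)
        t += b
        if t < end:
            add(t, min(supp, end - t), "std", amp.suppression_sd, 0.5, 4.0)
            t += supp

    # continuous phase: same exact-occupancy construction with a >5 uV floor
    t = ttnt_s
    while t < total_s:
        occ = float(profile.bsr_trajectory(t / 60.0 + 1e-9))
        c = float(profile.wpe_complexity_trajectory(t / 60.0 + 1e-9))
        occ = min(max(occ, 0.05), config.cont_occupancy_cap)
        l_lo = max(0.8 / (1.0 - occ), 1.0 / occ)
        cyc = rng.uniform(l_lo, min(max(1.8 * l_lo, 2.5), 24.0 + l_lo))
        high, low = occ * cyc, (1.0 - occ) * cyc
        h_amp = rng.uniform(*amp.continuous_high_range)
        l_amp = rng.uniform(*amp.continuous_low_range)
        add(t, min(high, total_s - t), "p2p_floor", h_amp, 8.0,
            8.0 + 4.0 + 30.0 * c)
        t += high
        if t < total_s:
            add(t, min(low, total_s - t), "p2p_ceil", l_amp, 10.0, 30.0)
            t += low

    n_art = rng.poisson(config.artifact_rate_per_h * total_s / 3600.0)
    for _ in range(n_art):
        t0 = rng.uniform(0.0, total_s - 0.5)
        add(t0, 0.3, "artifact", config.artifact_amp, 1.0, 40.0)

    return events


def _rolling_half_p2p(x: np.ndarray, fs: float) -> np.ndarray:
    """Half peak-to-peak over 0.5-s windows (the analysis envelope)."""
    from numpy.lib.stride_tricks import sliding_window_view

    w = max(2, int(round(0.5 * fs)))
    if x.size <= w:
        return np.array([0.5 * np.ptp(x)])
    view = sliding_window_view(x, w)
    return 0.5 * (view.max(axis=1) - view.min(axis=1))


def _render_event(ev: _Event, fs: float, channel: int) -> np.ndarray:
    """Band-limited noise scaled to the event's amplitude semantics.

    ``std`` events (isoelectric background, suppression) scale to a target
    standard deviation.  ``p2p_floor`` events (bursts, continuous high runs)
    scale so the *minimum* rolling 0.5-s half peak-to-peak equals ``amp`` --
    every analysis-envelope sample inside the event then clears the burst
    threshold.  ``p2p_ceil`` events (continuous low runs) scale so the
    *maximum* equals ``amp``, keeping the whole event inside the 5-10 uV
    corridor.  ``artifact`` events scale to peak absolute amplitude.
    """
    n = max(4, int(round(ev.dur_s * fs)))
    pad = int(round(0.3 * fs))  # causal-filter warm-up, discarded
    rng = np.random.default_rng(ev.seed_l if channel == 0 else ev.seed_r)
    x = rng.standard_normal(n + pad)
    x = signal.sosfilt(_band_sos(ev.f_lo, ev.f_hi, fs), x)[pad:]
    if ev.kind == "std":
        sd = x.std()
        x *= ev.amp / sd if sd > 0 else 0.0
        return x
    if ev.kind == "artifact":
        m = np.max(np.abs(x))
        x *= ev.amp / m if m > 0 else 0.0
    elif ev.kind == "p2p_ceil":
        # flatten the amplitude modulation: divide by the local envelope so
        # every 0.5-s window sits at ``amp`` -- the continuous-background
        # floor then never dips below the 5 uV quiet threshold
        env = _rolling_half_p2p(x, fs)
        if env.size > 1 and env.max() > 0:
            w = max(2, int(round(0.5 * fs)))
            centers = np.arange(env.size) + 0.5 * w
            local = np.interp(np.arange(x.size), centers, env)
            local = np.maximum(local, 0.3 * np.median(env))
            x = x / local * ev.amp
        elif env.max() > 0:
            x *= ev.amp / env.max()
    else:
        env = _rolling_half_p2p(x, fs)
        ref = env.min()
        x *= ev.amp / ref if ref > 0 else 0.0
    if ev.kind == "p2p_floor":
        # bursts begin and end abruptly; no taper, so the envelope clears
        # the threshold for (nearly) the whole nominal duration
        return x
    n_taper = min(n // 4, max(2, int(round(0.04 * fs))))
    w = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
    x[:n_taper] *= w
    x[-n_taper:] *= w[::-1]
    return x


def _synthesize_span(events: Sequence[_Event], fs: float, i0: int, i1: int,
                     line_amp: float, line_freq: float,
                     phases: tuple[float, float]) -> np.ndarray:
    out = np.zeros((2, i1 - i0))
    for ev in events:
        e0 = int(round(ev.start_s * fs))
        e1 = e0 + max(4, int(round(ev.dur_s * fs)))
        if e1 <= i0 or e0 >= i1:
            continue
        for ch in range(2):
            x = _render_event(ev, fs, ch)
            s0 = max(e0, i0)
            s1 = min(e1, i1)
            out[ch, s0 - i0:s1 - i0] += x[s0 - e0:s1 - e0]
    if line_amp > 0:
        t = np.arange(i0, i1) / fs
        for ch in range(2):
            out[ch] += line_amp * np.sin(
                2 * np.pi * line_freq * t + phases[ch])
    return out


def _line_phases(profile: AnimalProfile) -> tuple[float, float]:
    rng = np.random.default_rng([profile.stream_seed, 1])
    return tuple(rng.uniform(0, 2 * np.pi, size=2))


def iter_recording_chunks(
    profile: AnimalProfile, config: GeneratorConfig,
    chunk_s: float = 600.0,
) -> Iterator[np.ndarray]:
    """Yield the recording in consecutive ``(2, n)`` chunks.

    Chunking is purely a memory device: samples are identical regardless of
    ``chunk_s`` because every event carries its own seed.
    """
    config.validate()
    total_s = (config.duration_min + 1.0) * 60.0
    n_total = int(round(total_s * config.fs))
    events = _build_schedule(profile, config, total_s)
    phases = _line_phases(profile)
    step = max(1, int(round(chunk_s * config.fs)))
    for i0 in range(0, n_total, step):
        i1 = min(n_total, i0 + step)
        yield _synthesize_span(events, config.fs, i0, i1,
                               config.line_noise_amp, config.line_noise_freq,
                               phases)


def generate_recording(profile: AnimalProfile,
                       config: GeneratorConfig) -> Recording:
    """Synthesize the full two-channel post-ROSC recording for one animal."""
    data = np.concatenate(list(iter_recording_chunks(profile, config)), axis=1)
    return Recording(data=data, fs=config.fs, animal_id=profile.animal_id)


def generate_baseline(profile: AnimalProfile, config: GeneratorConfig,
                      duration_s: float = 62.0) -> Recording:
    """Pre-arrest baseline minute: continuous-pattern EEG at high occupancy."""
    config.validate()
    rng = np.random.default_rng([profile.stream_seed, 2])
    amp = config.amplitude
    events: list[_Event] = []
    t = 0.0
    while t < duration_s:
        low = rng.uniform(0.8, 1.4)
        high = rng.uniform(4.0, 10.0)
        sl, sr = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
        events.append(_Event(t, min(high, duration_s - t), "p2p_floor",
                             rng.uniform(*amp.continuous_high_range),
                             8.0, 35.0, sl, sr))
        t += high
        if t < duration_s:
            sl, sr = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
            events.append(_Event(t, min(low, duration_s - t), "p2p_ceil",
                                 rng.uniform(*amp.continuous_low_range),
                                 10.0, 30.0, sl, sr))
            t += low
    n = int(round(duration_s * config.fs))
    data = _synthesize_span(events, config.fs, 0, n,
                            config.line_noise_amp, config.line_noise_freq,
                            _line_phases(profile))
    return Recording(data=data, fs=config.fs, animal_id=profile.animal_id,
                     t0_post_rosc_min=-duration_s / 60.0)
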