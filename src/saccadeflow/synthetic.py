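"""Synthetic sessions with the statistical structure the analysis assumes.

The generator emulates head-fixed and freely-moving mouse recordings:

* eye traces with sigmoidal saccade displacement profiles at the observed
  rates (~3.1/min head-fixed, ~44.2/min freely moving), amplitudes
  (nasal ~12.2 deg, temporal ~8.2 deg head-fixed; ~19 deg freely moving)
  and 10-90% rise times (~22 ms head-fixed), plus Gaussian tracking
  jitter;
* per-unit spike trains from an inhomogeneous Poisson process whose rate
  combines a *non-visual* saccade-locked kernel (begins before saccade
  onset; the non-preferred direction is suppressed below baseline) and a
  *visual* stimulus-locked kernel (strictly causal, no suppression), with
  independent preferred directions for the two components;
* a grating condition in which the saccade response equals a shared gain
  ``g`` times the sum of the visual and non-visual components — the
  generative rule that the integration model is meant to recover.

Every random draw descends from the single config seed through named
substreams, so a fixed seed reproduces sessions bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .eye_geometry import EyeTrace
from . import pseudosaccades as ps

__all__ = [
    "SimConfig",
    "SyntheticSession",
    "make_ground_truth",
    "make_eye_trace",
    "nonvisual_rate_kernel",
    "visual_rate_kernel",
    "condition_rate",
    "simulate_spikes",
    "simulate_condition",
    "generate_session",
    "make_response_table",
    "saccade_displacement_profile",
    "CONDITIONS",
]

CONDITIONS = ("grey_screen", "pseudo", "grating", "pulvinar_silenced", "blinded")

# fraction of the 0-100% smoothstep duration spanned by the 10-90% rise
_SMOOTHSTEP_10_90 = 0.60836


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Defaults reproduce the head-fixed recording configuration; use
    :meth:`freely_moving` for the arena configuration.  Rates and
    amplitudes follow the descriptive statistics of the emulated
    recordings; kernel time constants are only weakly constrained by the
    average response histograms and are exposed as parameters.
    """

    session_length_s: float = 600.0
    condition: str = "head_fixed"
    frame_rate: float = 200.0
    saccade_rate_per_min: float = 3.1
    p_nasal: float = 1.9 / 3.1            # nasal fraction of saccades
    amplitude_mean_nasal: float = 12.2    # deg
    amplitude_mean_temporal: float = 8.2  # deg
    amplitude_cv: float = 0.30            # per-saccade lognormal spread
    amplitude_min: float = 3.0            # deg, truncation floor
    rise_time_mean_ms: float = 22.0       # 10-90% rise
    rise_time_sd_ms: float = 3.0
    quiet_min_s: float = 0.6              # enforced inter-saccade stillness
    noise_sd: float = 0.05                # deg, per-frame tracking jitter
    # unit population
    n_units: int = 64
    baseline_rate_range: tuple[float, float] = (0.5, 8.0)    # Hz
    nonvisual_gain_range: tuple[float, float] = (25.0, 80.0)  # Hz peak
    visual_gain_range: tuple[float, float] = (5.0, 25.0)      # Hz peak
    suppression_fraction: float = 0.5     # suppression_amp / nonvisual_amp
    # kernel shape
    pre_onset_lead_ms: float = 100.0      # non-visual kernel starts this early
    nonvisual_peak_ms: float = 50.0       # after saccade onset
    nonvisual_decay_ms: float = 120.0     # slow decay: response outlasts saccade
    visual_latency_ms: float = 40.0
    visual_rise_ms: float = 20.0
    visual_decay_ms: float = 40.0         # transient response to the brief shift
    visual_dir_mod: float = 0.2           # population-mean pref/non-pref contrast
    excitability_sd: float = 0.4          # lognormal sigma of shared per-unit scale
    nonvisual_trial_gain_sd: float = 0.6  # lognormal sigma of per-saccade motor gain
    # integration
    integration_gain: float = 0.62
    response_noise_sd: float = 0.05       # Gaussian noise on grating counts, spikes
    seed: int = 0

    @classmethod
    def freely_moving(cls, **overrides) -> "SimConfig":
        base = dict(
            condition="freely_moving",
            frame_rate=90.0,
            saccade_rate_per_min=44.2,
            amplitude_mean_nasal=19.0,
            amplitude_mean_temporal=19.0,
            rise_time_mean_ms=26.8,
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if self.session_length_s <= 0 or self.frame_rate <= 0:
            raise ValueError("session length and frame rate must be positive")
        if self.saccade_rate_per_min <= 0:
            raise ValueError("saccade rate must be positive")
        if self.integration_gain <= 0:
            raise ValueError("integration gain must be positive")
        if self.condition not in ("head_fixed", "freely_moving"):
            raise ValueError(f"unknown condition {self.condition!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticSession:
    """Everything the analysis chain consumes, plus the generating truth."""

    config: SimConfig
    ground_truth: pd.DataFrame
    trace: EyeTrace
    saccades: pd.DataFrame
    pseudos: pd.DataFrame
    spikes: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    @property
    def integration_gain(self) -> float:
        return self.config.integration_gain


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Fork the master seed into named substreams."""
    names = ["trace", "units", "pseudo", "spikes", "noise"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# ground truth

def make_ground_truth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-unit tuning parameters.

    Visual and non-visual preferred directions are drawn independently
    (uniform on the circle), so their population correlation vanishes as
    the population grows — the structural property the analysis tests.
    Response *magnitudes*, in contrast, share a per-unit excitability
    scale (many neurons respond to both inputs, with overall
    responsiveness varying far more across units than between inputs).
    """
    if rng is None:
        rng = _streams(config.seed)["units"]
    n = config.n_units
    lo_b, hi_b = config.baseline_rate_range
    lo_nv, hi_nv = config.nonvisual_gain_range
    lo_v, hi_v = config.visual_gain_range
    excitability = rng.lognormal(0.0, config.excitability_sd, size=n)
    nonvisual_amp = rng.uniform(lo_nv, hi_nv, size=n) * excitability
    # visual direction tuning is sparse (most units barely discriminate
    # shift direction) and concentrated in the strongly responsive units:
    # a Gaussian copula couples the Beta-distributed contrast to amplitude
    from scipy import stats as _st

    z_amp = rng.normal(size=n)
    z_mix = 0.7 * z_amp + np.sqrt(1.0 - 0.7**2) * rng.normal(size=n)
    mean_m = config.visual_dir_mod
    beta_b = 0.8 * (1.0 - mean_m) / mean_m
    visual_amp = (lo_v + (hi_v - lo_v) * _st.norm.cdf(z_amp)) * excitability
    visual_dir_mod = _st.beta.ppf(_st.norm.cdf(z_mix), 0.8, beta_b)
    gt = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "pref_dir_nonvisual": rng.uniform(0.0, 360.0, size=n),
            "pref_dir_visual": rng.uniform(0.0, 360.0, size=n),
            "nonvisual_amp": nonvisual_amp,
            "visual_amp": visual_amp,
            "visual_dir_mod": visual_dir_mod,
            "suppression_amp": config.suppression_fraction * nonvisual_amp,
            "baseline": rng.uniform(lo_b, hi_b, size=n),
            "depth_um": rng.uniform(100.0, 900.0, size=n),
            "trough_to_peak_ms": np.where(
                rng.random(n) < 0.8,
                rng.uniform(0.55, 1.0, size=n),
                rng.uniform(0.2, 0.45, size=n),
            ),
        }
    )
    return gt


# ---------------------------------------------------------------------------
# eye trace

def saccade_displacement_profile(
    t_s: np.ndarray, onset_s: float, amplitude: float, rise_time_10_90_ms: float
) -> np.ndarray:
    """Smoothstep displacement profile with compact support.

    The 0-100% duration is chosen so the 10-90% rise of the smoothstep
    ``u^2 (3 - 2u)`` equals ``rise_time_10_90_ms``.
    """
    T = rise_time_10_90_ms / 1000.0 / _SMOOTHSTEP_10_90
    u = np.clip((np.asarray(t_s) - onset_s) / T, 0.0, 1.0)
    return amplitude * u * u * (3.0 - 2.0 * u)


def _draw_amplitude(rng, mean: float, cv: float, floor: float) -> float:
    """Lognormal amplitude with the given mean/CV, truncated below ``floor``."""
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(1000):
        a = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if a >= floor:
            return a
    raise RuntimeError(
        f"amplitude floor {floor} incompatible with lognormal(mean={mean}, cv={cv})"
    )


def make_eye_trace(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[EyeTrace, pd.DataFrame]:
    """Generate an eye trace plus the true saccade-event table.

    Saccade onsets follow a renewal process: a quiet period of at least
    ``quiet_min_s`` followed by an exponential gap, giving the configured
    long-run rate.  Head-fixed sessions move only in azimuth (nasal
    positive); freely-moving sessions move in 2-D with directions biased
    towards the horizontal axis.
    """
    if rng is None:
        rng = _streams(config.seed)["trace"]
    rate_s = config.saccade_rate_per_min / 60.0
    mean_gap = 1.0 / rate_s
    if mean_gap <= config.quiet_min_s:
        raise ValueError(
            f"saccade rate {config.saccade_rate_per_min}/min incompatible with "
            f"quiet period {config.quiet_min_s}s"
        )
    margin = config.quiet_min_s + 0.3
    if config.session_length_s < 2 * margin + 0.2:
        raise ValueError(
            f"session of {config.session_length_s}s too short to place a saccade "
            f"with {config.quiet_min_s}s quiet periods"
        )

    n = int(round(config.session_length_s * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    az = np.zeros(n)
    el = np.zeros(n)
    free = config.condition == "freely_moving"

    events = []
    pos_az = 0.0
    clock = margin + rng.exponential(mean_gap - config.quiet_min_s)
    while clock < config.session_length_s - margin:
        rise = max(10.0, rng.normal(config.rise_time_mean_ms, config.rise_time_sd_ms))
        if free:
            # horizontal bias: nasal/temporal sectors over-represented
            sector = rng.choice(8, p=_HORIZONTAL_BIASED_P)
            direction = (sector * 45.0 + rng.uniform(-22.5, 22.5)) % 360.0
            amp = _draw_amplitude(
                rng, config.amplitude_mean_nasal, config.amplitude_cv, config.amplitude_min
            )
        else:
            nasal = rng.random() < config.p_nasal
            # keep the eye within a plausible oculomotor range
            if abs(pos_az) > 20.0:
                nasal = pos_az < 0
            mean = config.amplitude_mean_nasal if nasal else config.amplitude_mean_temporal
            amp = _draw_amplitude(rng, mean, config.amplitude_cv, config.amplitude_min)
            direction = 0.0 if nasal else 180.0
        d_az = amp * np.cos(np.radians(direction))
        d_el = amp * np.sin(np.radians(direction)) if free else 0.0
        prof = saccade_displacement_profile(t, clock, 1.0, rise)
        az += d_az * prof
        el += d_el * prof
        pos_az += d_az
        T100 = rise / 1000.0 / _SMOOTHSTEP_10_90
        events.append(
            {
                "onset_t": clock,
                "offset_t": clock + T100,
                "amplitude": amp,
                "direction_deg": direction,
                "direction_label": "nasal" if (direction <= 90 or direction > 270) else "temporal",
                "rise_time_10_90_ms": rise,
            }
        )
        clock += T100 + config.quiet_min_s + rng.exponential(mean_gap - config.quiet_min_s)

    if not events:
        raise ValueError("session too short: no saccade could be placed")
    if config.noise_sd > 0:
        az = az + rng.normal(0.0, config.noise_sd, size=n)
        el = el + rng.normal(0.0, config.noise_sd, size=n)
    trace = EyeTrace(
        t=t,
        azimuth=az,
        elevation=el,
        pupil_diameter=np.full(n, 1.0),
        frame_rate=config.frame_rate,
        condition=config.condition,
    )
    return trace, pd.DataFrame(events)


# saccade directions are biased along the horizontal (naso-temporal) axis
_HORIZONTAL_BIASED_P = np.array([0.25, 0.07, 0.11, 0.07, 0.25, 0.07, 0.11, 0.07])
_HORIZONTAL_BIASED_P = _HORIZONTAL_BIASED_P / _HORIZONTAL_BIASED_P.sum()


# ---------------------------------------------------------------------------
# rate kernels

def _rise_decay_shape(t_ms: np.ndarray, start_ms: float, peak_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak kernel: smoothstep rise on [start, peak], exp decay after."""
    t_ms = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t_ms)
    rising = (t_ms >= start_ms) & (t_ms <= peak_ms)
    u = (t_ms[rising] - start_ms) / (peak_ms - start_ms)
    out[rising] = u * u * (3.0 - 2.0 * u)
    after = t_ms > peak_ms
    out[after] = np.exp(-(t_ms[after] - peak_ms) / decay_ms)
    return out


def nonvisual_rate_kernel(
    unit: pd.Series, saccade_dir_deg: float, config: SimConfig
):
    """Non-visual (saccade-locked) rate modulation, Hz vs time from onset (ms).

    The modulation begins ``pre_onset_lead_ms`` before onset, peaks shortly
    after, and decays over ~100-200 ms.  Directional tuning is cosine:
    ``+nonvisual_amp`` at the preferred direction, ``-suppression_amp`` at
    the opposite one (a dip below baseline).  The returned callable is a
    modulation; the caller adds the baseline and clips negative rates at 0.
    """
    theta = np.radians(saccade_dir_deg - unit["pref_dir_nonvisual"])
    A, S = unit["nonvisual_amp"], unit["suppression_amp"]
    amp = (A - S) / 2.0 + (A + S) / 2.0 * np.cos(theta)

    def kernel(t_ms):
        return amp * _rise_decay_shape(
            np.asarray(t_ms, dtype=float),
            -config.pre_onset_lead_ms,
            config.nonvisual_peak_ms,
            config.nonvisual_decay_ms,
        )

    return kernel


def visual_rate_kernel(
    unit: pd.Series, stim_dir, amplitude_deg: float, config: SimConfig
):
    """Visual (stimulus-locked) rate modulation, Hz vs time from onset (ms).

    Strictly causal: exactly zero before ``visual_latency_ms``.  Both
    directions elicit non-negative modulation (no suppression), larger for
    the visually preferred direction; the response grows monotonically but
    saturates with shift amplitude (half-saturation 5 deg, normalised to 1
    at 10 deg), as displacement responses do.
    """
    if amplitude_deg < 0:
        raise ValueError("amplitude must be non-negative")
    stim_deg = {"nasal": 0.0, "temporal": 180.0}.get(stim_dir, stim_dir)
    theta = np.radians(float(stim_deg) - unit["pref_dir_visual"])
    m = float(unit.get("visual_dir_mod", config.visual_dir_mod))
    amp = unit["visual_amp"] * (1.0 + m * np.cos(theta)) / (1.0 + m)
    amp *= 1.5 * amplitude_deg / (amplitude_deg + 5.0)

    def kernel(t_ms):
        return amp * _rise_decay_shape(
            np.asarray(t_ms, dtype=float),
            config.visual_latency_ms,
            config.visual_latency_ms + config.visual_rise_ms,
            config.visual_decay_ms,
        )

    return kernel


def condition_rate(
    unit: pd.Series,
    events: pd.DataFrame,
    condition: str,
    config: SimConfig,
    t_grid_s: np.ndarray,
    event_gains: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) on ``t_grid_s`` for one unit.

    Which kernels contribute depends on the condition:

    * ``grey_screen`` / ``blinded``: non-visual kernel only (no patterned
      retinal input, or retina silenced);
    * ``pseudo``: visual kernel only (stimulus shift without a saccade);
    * ``grating``: ``g * (visual + nonvisual)`` per saccade — the linear
      integration rule;
    * ``pulvinar_silenced``: visual kernel only during real saccades on the
      grating (non-visual source silenced).

    ``event_gains`` scales the non-visual kernel per event (saccade-to-
    saccade motor variability; the visual kernel is stimulus-locked and
    not scaled).  Negative rates are clipped at zero (the suppression
    kernel may exceed a low baseline).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if event_gains is None:
        event_gains = np.ones(len(events))
    rate = np.full(len(t_grid_s), float(unit["baseline"]))
    dt_ms = (t_grid_s[1] - t_grid_s[0]) * 1000.0 if len(t_grid_s) > 1 else 1.0
    window_ms = config.pre_onset_lead_ms + config.nonvisual_peak_ms + 8 * max(
        config.nonvisual_decay_ms, config.visual_decay_ms
    )
    for k, (_, ev) in enumerate(events.iterrows()):
        onset = float(ev["onset_t"])
        direction = ev.get("direction_deg", 0.0 if ev["direction_label"] == "nasal" else 180.0)
        amplitude = float(ev["amplitude"])
        i0 = np.searchsorted(t_grid_s, onset - (config.pre_onset_lead_ms + 2 * dt_ms) / 1000.0)
        i1 = np.searchsorted(t_grid_s, onset + window_ms / 1000.0)
        trel_ms = (t_grid_s[i0:i1] - onset) * 1000.0
        mod = np.zeros_like(trel_ms)
        if condition in ("grey_screen", "blinded"):
            mod = event_gains[k] * nonvisual_rate_kernel(unit, direction, config)(trel_ms)
        elif condition == "pseudo":
            mod = visual_rate_kernel(unit, direction, amplitude, config)(trel_ms)
        elif condition == "grating":
            mod = config.integration_gain * (
                visual_rate_kernel(unit, direction, amplitude, config)(trel_ms)
                + event_gains[k] * nonvisual_rate_kernel(unit, direction, config)(trel_ms)
            )
        elif condition == "pulvinar_silenced":
            mod = visual_rate_kernel(unit, direction, amplitude, config)(trel_ms)
        rate[i0:i1] += mod
    return np.clip(rate, 0.0, None)


# ---------------------------------------------------------------------------
# spiking

def simulate_spikes(
    rate_hz: np.ndarray,
    dt_s: float,
    rng: np.random.Generator,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Draw an inhomogeneous Poisson spike train from a sampled rate.

    Counts are Poisson per grid bin with mean ``rate * dt``; spike times
    are placed uniformly within their bin.  Adequate when ``dt`` is small
    relative to the kernel time constants (default grid: 1 ms).
    """
    lam = np.clip(np.asarray(rate_hz, dtype=float), 0.0, None) * dt_s
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    idx = np.repeat(np.arange(len(lam)), counts)
    times = t0_s + (idx + rng.random(total)) * dt_s
    return np.sort(times)


def simulate_condition(
    ground_truth: pd.DataFrame,
    events: pd.DataFrame,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator,
    duration_s: float | None = None,
    dt_s: float = 0.001,
) -> dict[int, np.ndarray]:
    """Spike trains for every unit under one stimulus/silencing condition."""
    if duration_s is None:
        duration_s = config.session_length_s
    t_grid = np.arange(0.0, duration_s, dt_s)
    sd = config.nonvisual_trial_gain_sd
    if sd > 0 and condition in ("grey_screen", "blinded", "grating"):
        # per-saccade motor gain, mean 1, shared across the population
        event_gains = rng.lognormal(-(sd**2) / 2.0, sd, size=len(events))
    else:
        event_gains = None
    out = {}
    for _, unit in ground_truth.iterrows():
        rate = condition_rate(unit, events, condition, config, t_grid, event_gains)
        out[int(unit["unit_id"])] = simulate_spikes(rate, dt_s, rng)
    return out


# ---------------------------------------------------------------------------
# full session

def generate_session(
    config: SimConfig,
    conditions: tuple[str, ...] = ("grey_screen", "pseudo", "grating"),
) -> SyntheticSession:
    """Generate a full synthetic session.

    The eye trace and true saccades are shared across conditions (in the
    emulated experiment the condition blocks are recorded back to back;
    reusing the saccade times keeps event counts matched across blocks
    while spike draws stay independent).  Pseudo-saccades are scheduled
    from the session's own saccade sample and cleaned of events near real
    saccades.
    """
    streams = _streams(config.seed)
    gt = make_ground_truth(config, streams["units"])
    trace, saccades = make_eye_trace(config, streams["trace"])
    pseudos = ps.schedule(
        saccades, config.session_length_s, seed=streams["pseudo"]
    )
    pseudos = ps.exclude_near_saccades(pseudos, saccades)
    pseudos["direction_deg"] = np.where(
        pseudos["direction_label"] == "nasal", 0.0, 180.0
    )
    spikes = {}
    for cond in conditions:
        ev = pseudos if cond == "pseudo" else saccades
        spikes[cond] = simulate_condition(gt, ev, cond, config, streams["spikes"])
    return SyntheticSession(
        config=config,
        ground_truth=gt,
        trace=trace,
        saccades=saccades,
        pseudos=pseudos,
        spikes=spikes,
    )


# ---------------------------------------------------------------------------
# response tables for the integration model

def _window_integral_ms(kernel, lo_ms: float = 0.0, hi_ms: float = 100.0) -> float:
    """Expected extra spike count of a modulation kernel over a window."""
    grid = np.arange(lo_ms, hi_ms, 0.5)
    return float(np.sum(kernel(grid)) * 0.5 / 1000.0)


def make_response_table(
    ground_truth: pd.DataFrame,
    config: SimConfig,
    n_events_per_direction: int = 60,
    noise: str = "poisson",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-neuron mean evoked counts for the integration-model analysis.

    For each neuron the visual component is the mean baseline-subtracted
    spike count in the 100-ms response window over pseudo-saccade events
    and the non-visual component the same over grey-screen saccades; with
    ``noise="poisson"`` these are measured from Poisson per-event counts,
    with ``noise="none"`` they are the analytic kernel expectations.  The
    grating response follows the generative rule

        y = g * (visual + nonvisual) + eps,  eps ~ N(0, response_noise_sd),

    applied to the component responses themselves, so the shared gain is
    recoverable up to the Gaussian response noise and, in the noiseless
    case, the linear relation is exact.
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    if rng is None:
        rng = _streams(config.seed)["noise"]
    window_s = 0.100
    amp_n = config.amplitude_mean_nasal
    amp_t = config.amplitude_mean_temporal
    rows = []
    for _, unit in ground_truth.iterrows():
        base_count = unit["baseline"] * window_s
        per_dir = {}
        for direction, amp in (("nasal", amp_n), ("temporal", amp_t)):
            v = _window_integral_ms(visual_rate_kernel(unit, direction, amp, config))
            nv = _window_integral_ms(
                nonvisual_rate_kernel(unit, 0.0 if direction == "nasal" else 180.0, config)
            )
            per_dir[direction] = (v, nv)

        def evoked(component_means: list[float]) -> float:
            # mean over events (split across the two directions) of
            # baseline-subtracted window counts
            if noise == "none":
                return float(np.mean(component_means))
            means = np.repeat(component_means, n_events_per_direction)
            lam = np.clip(means + base_count, 0.0, None)
            return float(rng.poisson(lam).mean() - base_count)

        x_visual = evoked([per_dir["nasal"][0], per_dir["temporal"][0]])
        x_nonvisual = evoked([per_dir["nasal"][1], per_dir["temporal"][1]])
        y = config.integration_gain * (x_visual + x_nonvisual)
        if noise == "poisson" and config.response_noise_sd > 0:
            y += float(rng.normal(0.0, config.response_noise_sd))
        rows.append(
            {
                "unit_id": int(unit["unit_id"]),
                "y_grating": y,
                "x_visual": x_visual,
                "x_nonvisual": x_nonvisual,
                "baseline_hz": float(unit["baseline"]),
            }
        )
    return pd.DataFrame(rows)
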