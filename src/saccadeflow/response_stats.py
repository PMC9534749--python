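"""Per-unit response quantification and statistics.

Implements the quantities used to characterise saccade responses:

* spike counts in event-aligned windows (response [0, 100) ms, baseline
  [-300, -200) ms relative to onset);
* peri-event time histograms (PETHs) with baseline normalisation;
* naso-temporal (NT) discriminability — the area under the ROC curve
  between the nasal and temporal spike-count distributions rescaled to
  [-1, 1] (a signed Gini coefficient, ``2*AROC - 1``; positive = nasal
  preference);
* responsiveness criteria for head-fixed (rank-sum, FDR 10%) and
  freely-moving (Kruskal-Wallis + Tukey HSD + 50%-change) recordings;
* inclusion filters (putative eye-position units), circular statistics
  (Rao's spacing test), spike-width classing, and layer assignment from
  the spontaneous-rate depth profile.

All response windows are half-open ``[a, b)`` so no spike is counted
twice at a boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UnitRecording",
    "DiscriminabilityResult",
    "windowed_counts",
    "peth",
    "normalize_and_average_peths",
    "binwise_direction_test",
    "responsiveness_head_fixed",
    "responsiveness_freely_moving",
    "nt_discriminability",
    "discriminability_table",
    "preferred_direction_and_discriminability_free",
    "direction_selectivity_index",
    "exclude_eye_position_units",
    "rao_spacing_test",
    "classify_spike_width",
    "assign_layers",
    "antidromic_id",
    "bh_qvalues",
]

RESPONSE_WINDOW_MS = (0.0, 100.0)
BASELINE_WINDOW_MS = (-300.0, -200.0)


@dataclass
class UnitRecording:
    """Spike times and identity metadata for one isolated unit."""

    spike_times: np.ndarray
    unit_id: int = 0
    depth_um: float = np.nan
    trough_to_peak_ms: float = np.nan
    layer: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))

    @property
    def cls(self) -> str:
        return classify_spike_width(self.trough_to_peak_ms)


@dataclass
class DiscriminabilityResult:
    """Signed NT discriminability for one unit."""

    gini: float
    p_value: float
    n_nasal: int
    n_temporal: int
    q_value: float = np.nan
    significant: bool = False


def _count_in_windows(
    spikes: np.ndarray, onsets: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    lo = onsets + window_ms[0] / 1000.0
    hi = onsets + window_ms[1] / 1000.0
    return np.searchsorted(spikes, hi, side="left") - np.searchsorted(
        spikes, lo, side="left"
    )


def windowed_counts(
    spikes: np.ndarray,
    onsets: np.ndarray,
    response_ms: tuple[float, float] = RESPONSE_WINDOW_MS,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    recording_span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Raw per-event (response, baseline) spike counts, half-open windows.

    Events whose windows fall outside ``recording_span`` are dropped (the
    returned frame keeps the original event index).
    """
    spikes = np.asarray(spikes, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    keep = np.ones(len(onsets), dtype=bool)
    if recording_span is not None:
        lo_edge = onsets + min(response_ms[0], baseline_ms[0]) / 1000.0
        hi_edge = onsets + max(response_ms[1], baseline_ms[1]) / 1000.0
        keep = (lo_edge >= recording_span[0]) & (hi_edge <= recording_span[1])
    out = pd.DataFrame(
        {
            "response": _count_in_windows(spikes, onsets[keep], response_ms),
            "baseline": _count_in_windows(spikes, onsets[keep], baseline_ms),
        },
        index=np.flatnonzero(keep),
    )
    return out


def peth(
    spikes: np.ndarray,
    onsets: np.ndarray,
    bin_ms: float = 20.0,
    range_ms: tuple[float, float] = (-500.0, 500.0),
) -> pd.DataFrame:
    """Peri-event time histogram: mean rate (Hz) per bin, s.e.m. across events."""
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("need at least one event")
    edges = np.arange(range_ms[0], range_ms[1] + bin_ms / 2, bin_ms)
    n_bins = len(edges) - 1
    counts = np.empty((len(onsets), n_bins))
    spikes = np.asarray(spikes, dtype=float)
    for i, onset in enumerate(onsets):
        rel = (spikes - onset) * 1000.0
        counts[i], _ = np.histogram(rel, bins=edges)
    rate = counts / (bin_ms / 1000.0)
    sem = rate.std(axis=0, ddof=1) / np.sqrt(len(onsets)) if len(onsets) > 1 else np.zeros(n_bins)
    return pd.DataFrame(
        {
            "bin_left_ms": edges[:-1],
            "bin_right_ms": edges[1:],
            "mean_rate_hz": rate.mean(axis=0),
            "sem_hz": sem,
            "n_events": len(onsets),
        }
    )


def normalize_and_average_peths(
    peths: list[pd.DataFrame],
    baselines_hz: np.ndarray,
    min_baseline_hz: float = 0.5,
    mode: str = "subtract",
) -> pd.DataFrame:
    """Baseline-normalised population average PETH.

    Units with baseline below ``min_baseline_hz`` are excluded — from this
    visualisation average only; statistics elsewhere always use all units.
    ``mode`` is ``"subtract"`` (rate minus baseline) or ``"divide"``
    (rate over baseline).
    """
    baselines = np.asarray(baselines_hz, dtype=float)
    if len(peths) != len(baselines):
        raise ValueError("one baseline per PETH required")
    keep = baselines >= min_baseline_hz
    if not keep.any():
        raise ValueError(
            f"all units fall below the {min_baseline_hz} Hz baseline floor"
        )
    stack = []
    for p, b, k in zip(peths, baselines, keep):
        if not k:
            continue
        if mode == "subtract":
            stack.append(p["mean_rate_hz"].to_numpy() - b)
        elif mode == "divide":
            stack.append(p["mean_rate_hz"].to_numpy() / b)
        else:
            raise ValueError("mode must be 'subtract' or 'divide'")
    arr = np.vstack(stack)
    template = peths[int(np.flatnonzero(keep)[0])]
    return pd.DataFrame(
        {
            "bin_left_ms": template["bin_left_ms"],
            "bin_right_ms": template["bin_right_ms"],
            "mean": arr.mean(axis=0),
            "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            if arr.shape[0] > 1
            else 0.0,
            "n_units": arr.shape[0],
        }
    )


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pvals)
    q = np.full_like(pvals, np.nan)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return q


def binwise_direction_test(
    pref_rates: np.ndarray,
    nonpref_rates: np.ndarray,
    alpha: float = 0.10,
    min_units: int = 6,
) -> pd.DataFrame:
    """Per-bin one-tailed paired signed-rank test, BH-corrected across bins.

    ``pref_rates``/``nonpref_rates`` are (units x bins) matrices of
    per-unit PETH rates for the preferred and non-preferred directions.
    Tests the alternative pref > non-pref in each bin; significance at FDR
    ``alpha`` across bins.
    """
    pref = np.atleast_2d(np.asarray(pref_rates, dtype=float))
    nonp = np.atleast_2d(np.asarray(nonpref_rates, dtype=float))
    if pref.shape != nonp.shape:
        raise ValueError("matrices must have equal shape")
    n_units, n_bins = pref.shape
    pvals = np.full(n_bins, np.nan)
    testable = n_units >= min_units
    if testable:
        for b in range(n_bins):
            diff = pref[:, b] - nonp[:, b]
            if np.allclose(diff, 0.0):
                pvals[b] = 1.0
            else:
                pvals[b] = stats.wilcoxon(
                    pref[:, b], nonp[:, b], alternative="greater",
                    zero_method="wilcox",
                ).pvalue
    q = bh_qvalues(pvals)
    return pd.DataFrame(
        {
            "p_value": pvals,
            "q_value": q,
            "significant": (q <= alpha) & np.isfinite(q),
            "testable": testable,
        }
    )


def responsiveness_head_fixed(
    counts: dict[int, dict[str, pd.DataFrame]],
    alpha: float = 0.10,
    min_events_per_direction: int = 15,
) -> pd.DataFrame:
    """Head-fixed responsiveness with FDR control across all comparisons.

    ``counts[unit]["nasal"|"temporal"]`` are windowed-count frames with
    ``response`` and ``baseline`` columns.  A unit is responsive when at
    least one of three rank-sum comparisons survives BH at ``alpha``:
    response vs baseline for each direction, and nasal vs temporal
    response.  Directions with fewer than ``min_events_per_direction``
    events make the dataset ineligible (the animal-inclusion rule).
    """
    records = []  # (unit, criterion, p)
    for unit, per_dir in counts.items():
        nas = per_dir.get("nasal")
        tem = per_dir.get("temporal")
        for label, frame in (("nasal", nas), ("temporal", tem)):
            if frame is None or len(frame) == 0:
                warnings.warn(f"unit {unit}: no {label} events, criterion skipped", stacklevel=2)
                continue
            if len(frame) < min_events_per_direction:
                raise ValueError(
                    f"unit {unit}: only {len(frame)} {label} events; "
                    f"dataset fails the >= {min_events_per_direction} rule"
                )
            p = _ranksum(frame["response"], frame["baseline"])
            records.append((unit, f"resp_vs_base_{label}", p))
        if nas is not None and tem is not None and len(nas) and len(tem):
            p = _ranksum(nas["response"], tem["response"])
            records.append((unit, "nasal_vs_temporal", p))
    if not records:
        return pd.DataFrame(columns=["unit_id", "responsive"])
    df = pd.DataFrame(records, columns=["unit_id", "criterion", "p_value"])
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] <= alpha
    out = (
        df.groupby("unit_id")["significant"]
        .any()
        .rename("responsive")
        .reset_index()
    )
    return out.merge(
        df.pivot(index="unit_id", columns="criterion", values="p_value"),
        on="unit_id",
    )


def _ranksum(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(a.mean(), b.mean()):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def responsiveness_freely_moving(
    response_by_dir: dict[int, pd.DataFrame],
    baseline_by_dir: dict[int, pd.DataFrame] | None = None,
    alpha: float = 0.05,
    change_fraction: float = 0.5,
    min_events: int = 3,
) -> bool:
    """Freely-moving responsiveness for one unit (8 direction sectors).

    ``response_by_dir[sector]`` / ``baseline_by_dir[sector]`` hold
    per-event counts.  If ``baseline_by_dir`` is None, the frames in
    ``response_by_dir`` must have ``response`` and ``baseline`` columns.

    The unit is responsive iff (1) a Kruskal-Wallis test over the 16
    categories (8 responses + 8 baselines) rejects at ``alpha``; (2) at
    least one direction's mean response is ``change_fraction`` above or
    below its mean baseline (with a zero baseline, "above" requires a
    positive response); and (3) Tukey's HSD over the 16 categories finds a
    significant baseline-vs-response contrast for some direction or a
    response-vs-response contrast for some pair.
    """
    resp, base = {}, {}
    for sector, frame in response_by_dir.items():
        if isinstance(frame, pd.DataFrame):
            resp[sector] = frame["response"].to_numpy(dtype=float)
            if baseline_by_dir is None:
                base[sector] = frame["baseline"].to_numpy(dtype=float)
        else:
            resp[sector] = np.asarray(frame, dtype=float)
    if baseline_by_dir is not None:
        for sector, frame in baseline_by_dir.items():
            base[sector] = np.asarray(
                frame["baseline"] if isinstance(frame, pd.DataFrame) else frame,
                dtype=float,
            )
    sectors = sorted(set(resp) & set(base))
    groups, names = [], []
    for s in sectors:
        if len(resp[s]) < min_events:
            continue
        groups += [resp[s], base[s]]
        names += [("resp", s), ("base", s)]
    if len(groups) < 4:
        return False
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return False  # no variability at all (e.g. all-zero unit)
    kw_p = stats.kruskal(*groups).pvalue
    if kw_p > alpha:
        return False
    # 50%-change rule
    changed = False
    for s in sectors:
        if len(resp[s]) < min_events:
            continue
        mb = base[s].mean()
        mr = resp[s].mean()
        if mb == 0:
            if mr > 0:
                changed = True
        elif abs(mr - mb) >= change_fraction * mb:
            changed = True
    if not changed:
        return False
    # Tukey HSD contrasts over the 16 categories
    hsd = stats.tukey_hsd(*groups)
    p_matrix = hsd.pvalue
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            same_dir_contrast = ni[0] != nj[0] and ni[1] == nj[1]
            resp_resp_contrast = ni[0] == "resp" and nj[0] == "resp"
            if (same_dir_contrast or resp_resp_contrast) and p_matrix[i, j] <= alpha:
                return True
    return False


def nt_discriminability(
    counts_nasal: np.ndarray, counts_temporal: np.ndarray
) -> DiscriminabilityResult:
    """Signed NT discriminability: ``2*AROC - 1`` with ties counted 1/2.

    AROC is the probability that a randomly drawn nasal-event count
    exceeds a randomly drawn temporal-event count (ties counted half),
    so positive values indicate nasal preference.  The p-value is a
    two-sided rank-sum test between the two count series.
    """
    nas = np.asarray(counts_nasal, dtype=float)
    tem = np.asarray(counts_temporal, dtype=float)
    if len(nas) == 0 or len(tem) == 0:
        raise ValueError("both direction samples must be non-empty")
    res = stats.mannwhitneyu(nas, tem, alternative="two-sided")
    aroc = res.statistic / (len(nas) * len(tem))  # U counts ties as 1/2
    if np.allclose(nas.std(), 0) and np.allclose(tem.std(), 0) and nas.mean() == tem.mean():
        p = 1.0
    else:
        p = float(res.pvalue)
    return DiscriminabilityResult(
        gini=float(2.0 * aroc - 1.0),
        p_value=p,
        n_nasal=len(nas),
        n_temporal=len(tem),
    )


def discriminability_table(
    per_unit: dict[int, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.10,
) -> pd.DataFrame:
    """NT discriminability for a population, FDR-controlled across units."""
    rows = []
    for unit, (nas, tem) in per_unit.items():
        r = nt_discriminability(nas, tem)
        rows.append(
            {
                "unit_id": unit,
                "gini": r.gini,
                "p_value": r.p_value,
                "n_nasal": r.n_nasal,
                "n_temporal": r.n_temporal,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] <= alpha
    return df


def preferred_direction_and_discriminability_free(
    counts_by_sector: dict[int, np.ndarray],
) -> dict:
    """Preferred sector (argmax mean count) and |Gini| vs the opposite sector.

    Ties in the argmax go to the lower sector index.  Requires the
    preferred and opposite sectors to be populated.
    """
    sectors = sorted(counts_by_sector)
    means = np.array([np.mean(counts_by_sector[s]) for s in sectors])
    pref = sectors[int(np.argmax(means))]  # argmax takes the first (lower) tie
    opposite = (pref + len(sectors) // 2) % len(sectors)
    if opposite not in counts_by_sector or len(counts_by_sector[opposite]) == 0:
        raise ValueError(f"opposite sector {opposite} is empty")
    r = nt_discriminability(counts_by_sector[pref], counts_by_sector[opposite])
    return {
        "pref_sector": pref,
        "pref_dir_deg": pref * (360.0 / len(sectors)),
        "abs_gini": abs(r.gini),
        "p_value": r.p_value,
    }


def direction_selectivity_index(r_pref: float, r_nonpref: float) -> float:
    """DSI = (R_pref - R_nonpref) / (R_pref + R_nonpref)."""
    total = r_pref + r_nonpref
    if total <= 0:
        raise ValueError("DSI undefined: R_pref + R_nonpref must be positive")
    return float((r_pref - r_nonpref) / total)


def exclude_eye_position_units(
    baseline_counts: dict[int, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag putative eye-position units.

    Pre-saccade eye position correlates with upcoming saccade direction,
    so a unit whose *pre-onset baseline* differs between upcoming nasal
    and temporal saccades codes position, not saccade direction, and is
    dropped.  ``baseline_counts[unit] = (pre_nasal, pre_temporal)`` are
    baseline window counts split by the direction of the upcoming saccade.
    """
    rows = []
    for unit, (pre_nas, pre_tem) in baseline_counts.items():
        p = _ranksum(pre_nas, pre_tem)
        rows.append({"unit_id": unit, "p_value": p, "keep": p > alpha})
    return pd.DataFrame(rows)


def rao_spacing_test(
    angles_deg: np.ndarray,
    n_resamples: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Rao's spacing test of circular uniformity.

    ``U = 1/2 * sum |spacing_i - 360/n|``; the p-value is estimated from
    seeded uniform resamples (the null distribution has no convenient
    closed form).
    """
    angles = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    n = len(angles)
    if n < 4:
        raise ValueError("need at least 4 angles")

    def u_stat(a: np.ndarray) -> float:
        a = np.sort(a)
        spacings = np.diff(np.concatenate([a, [a[0] + 360.0]]))
        return 0.5 * float(np.sum(np.abs(spacings - 360.0 / len(a))))

    u_obs = u_stat(angles)
    rng = np.random.default_rng(seed)
    null = np.array(
        [u_stat(rng.uniform(0.0, 360.0, size=n)) for _ in range(n_resamples)]
    )
    p = (1.0 + np.sum(null >= u_obs)) / (n_resamples + 1.0)
    return u_obs, float(p)


def classify_spike_width(trough_to_peak_ms: float, threshold_ms: float = 0.5) -> str:
    """Regular-spiking iff trough-to-peak is strictly above the threshold."""
    if trough_to_peak_ms <= 0 or not np.isfinite(trough_to_peak_ms):
        raise ValueError("trough-to-peak width must be positive")
    return "RS" if trough_to_peak_ms > threshold_ms else "FS"


def assign_layers(
    channel_depth_um: np.ndarray,
    spontaneous_rate_hz: np.ndarray,
    border_offset_um: float = 125.0,
    l5_extent_um: float = 200.0,
    l4_extent_um: float = 150.0,
) -> pd.DataFrame:
    """Assign cortical layers from the spontaneous-rate depth profile.

    The L4/L5 border sits ``border_offset_um`` above the channel with
    maximum spontaneous rate; channels within ``l5_extent_um`` below the
    border are L5 and within ``l4_extent_um`` above are L4.  Channels
    above the L4 band are labelled L2/3 and below the L5 band L6.  A flat
    or multi-peaked rate profile leaves the border ambiguous: all channels
    are flagged.
    """
    depth = np.asarray(channel_depth_um, dtype=float)
    rate = np.asarray(spontaneous_rate_hz, dtype=float)
    if len(depth) != len(rate):
        raise ValueError("one rate per channel required")
    ambiguous = False
    if np.allclose(rate, rate[0]):
        ambiguous = True
        border = np.nan
    else:
        peaks = np.flatnonzero(rate == rate.max())
        if len(peaks) > 1:
            ambiguous = True
        border = depth[peaks[0]] - border_offset_um
    layers = []
    for d in depth:
        if ambiguous:
            layers.append("unknown")
        elif d < border - l4_extent_um:
            layers.append("L2/3")
        elif d < border:
            layers.append("L4")
        elif d <= border + l5_extent_um:
            layers.append("L5")
        else:
            layers.append("L6")
    return pd.DataFrame(
        {
            "depth_um": depth,
            "layer": layers,
            "border_um": border,
            "ambiguous": ambiguous,
        }
    )


def antidromic_id(
    spike_times: np.ndarray,
    pulse_times: np.ndarray,
    window_ms: float = 5.0,
    min_probability: float = 0.2,
    max_jitter_ms: float = 0.5,
) -> dict:
    """Antidromic identification from optogenetic terminal stimulation.

    A projection is confirmed when the probability of at least one spike
    within ``window_ms`` of pulse onset exceeds ``min_probability`` and
    the s.d. of the first-spike latency is below ``max_jitter_ms``.
    """
    pulses = np.asarray(pulse_times, dtype=float)
    if len(pulses) == 0:
        raise ValueError("at least one light pulse required")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    latencies = []
    for p in pulses:
        i = np.searchsorted(spikes, p, side="left")
        if i < len(spikes) and (spikes[i] - p) * 1000.0 < window_ms:
            latencies.append((spikes[i] - p) * 1000.0)
    prob = len(latencies) / len(pulses)
    jitter = float(np.std(latencies, ddof=1)) if len(latencies) > 1 else np.inf
    return {
        "identified": prob > min_probability and jitter < max_jitter_ms,
        "response_probability": prob,
        "latency_jitter_ms": jitter,
        "mean_latency_ms": float(np.mean(latencies)) if latencies else np.nan,
        "n_pulses": len(pulses),
    }
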