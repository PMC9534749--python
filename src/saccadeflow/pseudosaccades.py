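"""Pseudo-saccade scheduling, exclusion and amplitude matching.

A pseudo-saccade is an experimenter-imposed rapid horizontal shift of a
displayed grating that mimics the retinal image shift of a real saccade.
By convention the labels are inverted: a *nasal* pseudo-saccade is a
temporal-direction grating shift, because that is the retinal consequence
of a real nasal saccade.

The schedule draws shift amplitudes and directions i.i.d. from an observed
real-saccade sample, at exponential intervals (mean 1.5 s).  Events within
500 ms of a real saccade are discarded.  For analysis, each real saccade is
then matched to the k = 2 same-direction pseudo-saccades with the closest
amplitudes, so visual-only and saccade responses can be compared on
amplitude-matched event sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["schedule", "exclude_near_saccades", "match_to_saccades"]

SHIFT_DURATION_MS = 25.0  # grating shift spans 7 frames at 240 Hz


def schedule(
    real_saccades: pd.DataFrame,
    session_length_s: float,
    mean_interval_s: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a pseudo-saccade schedule from a real-saccade sample.

    Parameters
    ----------
    real_saccades : DataFrame
        Must have ``amplitude`` and ``direction_label`` columns; the
        empirical (amplitude, direction) pairs are resampled jointly.
    session_length_s : float
        Stimulus session duration.
    mean_interval_s : float
        Mean of the exponential inter-event interval.
    seed : int or Generator
        Randomness source.

    Returns
    -------
    DataFrame with ``onset_t``, ``amplitude``, ``direction_label``,
    ``shift_duration_ms``.
    """
    if len(real_saccades) == 0:
        raise ValueError("real-saccade sample must be non-empty")
    rng = np.random.default_rng(seed)
    # generous over-draw of exponential gaps, then truncate to the session
    n_guess = max(16, int(3 * session_length_s / mean_interval_s))
    gaps = rng.exponential(mean_interval_s, size=n_guess)
    onsets = np.cumsum(gaps)
    while onsets[-1] < session_length_s:
        more = rng.exponential(mean_interval_s, size=n_guess)
        onsets = np.concatenate([onsets, onsets[-1] + np.cumsum(more)])
    onsets = onsets[onsets < session_length_s]
    idx = rng.integers(0, len(real_saccades), size=len(onsets))
    amp = real_saccades["amplitude"].to_numpy(dtype=float)[idx]
    lab = real_saccades["direction_label"].to_numpy()[idx]
    return pd.DataFrame(
        {
            "onset_t": onsets,
            "amplitude": amp,
            "direction_label": lab,
            "shift_duration_ms": SHIFT_DURATION_MS,
        }
    )


def exclude_near_saccades(
    pseudos: pd.DataFrame,
    saccades: pd.DataFrame,
    window_s: float = 0.5,
) -> pd.DataFrame:
    """Drop pseudo-saccades within ``window_s`` of any real saccade onset."""
    if pseudos.empty or saccades.empty:
        return pseudos.reset_index(drop=True)
    p = pseudos["onset_t"].to_numpy(dtype=float)
    s = np.sort(saccades["onset_t"].to_numpy(dtype=float))
    j = np.searchsorted(s, p)
    d_right = np.where(j < len(s), s[np.minimum(j, len(s) - 1)] - p, np.inf)
    d_left = np.where(j > 0, p - s[np.maximum(j - 1, 0)], np.inf)
    nearest = np.minimum(np.abs(d_left), np.abs(d_right))
    return pseudos.loc[nearest > window_s].reset_index(drop=True)


def match_to_saccades(
    pseudos: pd.DataFrame,
    saccades: pd.DataFrame,
    k: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Assign to each real saccade the k closest-amplitude pseudo-saccades.

    Matching is restricted to pseudo-saccades with the same direction
    label.  Candidates are ranked by absolute amplitude difference (ties
    broken by earliest onset); assignment is without replacement while the
    pool allows, then with replacement (rows flagged ``with_replacement``).
    Saccades with an empty same-direction pool are left unmatched and
    flagged in the summary.

    Returns
    -------
    matched : DataFrame
        One row per (saccade, pseudo) pair: ``saccade_id``, ``pseudo_id``,
        pseudo onset/amplitude, ``delta_amplitude`` (pseudo - real,
        signed), ``with_replacement``.
    summary : dict
        ``mean_delta``, ``sd_delta`` of signed amplitude differences,
        ``n_matched``, ``n_unmatched_saccades``.
    """
    saccades = saccades.reset_index(drop=True)
    pseudos = pseudos.reset_index(drop=True)
    rows = []
    n_unmatched = 0
    for label in ("nasal", "temporal"):
        sac_idx = saccades.index[saccades["direction_label"] == label]
        pool_idx = pseudos.index[pseudos["direction_label"] == label].to_numpy()
        if len(sac_idx) == 0:
            continue
        if len(pool_idx) == 0:
            n_unmatched += len(sac_idx)
            continue
        pool_amp = pseudos.loc[pool_idx, "amplitude"].to_numpy(dtype=float)
        pool_onset = pseudos.loc[pool_idx, "onset_t"].to_numpy(dtype=float)
        available = np.ones(len(pool_idx), dtype=bool)
        for sid in sac_idx:
            target = float(saccades.at[sid, "amplitude"])
            order = np.lexsort((pool_onset, np.abs(pool_amp - target)))
            picked = 0
            # first pass without replacement
            for j in order:
                if picked == k:
                    break
                if available[j]:
                    available[j] = False
                    rows.append(_match_row(sid, pseudos, pool_idx[j], target, False))
                    picked += 1
            # pool exhausted: fall back to sampling with replacement
            for j in order:
                if picked == k:
                    break
                rows.append(_match_row(sid, pseudos, pool_idx[j], target, True))
                picked += 1
    matched = pd.DataFrame(
        rows,
        columns=[
            "saccade_id",
            "pseudo_id",
            "onset_t",
            "amplitude",
            "direction_label",
            "delta_amplitude",
            "with_replacement",
        ],
    )
    deltas = matched["delta_amplitude"].to_numpy(dtype=float)
    summary = {
        "mean_delta": float(np.mean(deltas)) if len(deltas) else np.nan,
        "sd_delta": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else np.nan,
        "n_matched": int(len(matched)),
        "n_unmatched_saccades": int(n_unmatched),
    }
    return matched, summary


def _match_row(sid, pseudos, pid, target, with_replacement) -> dict:
    return {
        "saccade_id": int(sid),
        "pseudo_id": int(pid),
        "onset_t": float(pseudos.at[pid, "onset_t"]),
        "amplitude": float(pseudos.at[pid, "amplitude"]),
        "direction_label": pseudos.at[pid, "direction_label"],
        "delta_amplitude": float(pseudos.at[pid, "amplitude"]) - target,
        "with_replacement": bool(with_replacement),
    }
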