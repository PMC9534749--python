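"""Rectified no-intercept linear integration of visual and non-visual inputs.

The saccade-on-grating response of each neuron (baseline-subtracted spike
count in the 100-ms window after onset) is predicted from its
pseudo-saccade response (visual input), its grey-screen saccade response
(non-visual input), or their sum, through a single shared gain fitted by
least squares without an intercept:

    y_i = g * x_i + eps_i ,    g = sum(x y) / sum(x^2).

Predictions are made under five-fold cross-validation and rectified so a
predicted suppression never drives the implied firing rate below zero:
``pred >= -baseline_count``.  Model quality is the explained variance
ESS/TSS with ESS = TSS - RSS computed on the pooled held-out predictions
(this cross-validated convention can fall below zero for uninformative
predictors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntegrationFit",
    "fit",
    "explained_variance",
    "compare_predictor_sets",
    "layerwise_contributions",
]

RESPONSE_WINDOW_S = 0.100


@dataclass
class IntegrationFit:
    """Shared-gain fit for one predictor set."""

    predictor_set: str
    gain: float
    explained_variance: float
    predictions: np.ndarray = field(repr=False)
    fold_assignments: np.ndarray = field(repr=False)
    per_fold_gain: np.ndarray = field(repr=False)


def _shared_gain(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise ValueError("predictor is all zero; gain is undefined")
    return float(np.sum(x * y) / denom)


def fit(
    y: np.ndarray,
    x: np.ndarray,
    baseline_hz: np.ndarray | None = None,
    predictor_set: str = "sum",
    n_folds: int = 5,
    rectify: bool = True,
    seed: int = 0,
) -> IntegrationFit:
    """Fit the shared gain with cross-validated, rectified predictions.

    Parameters
    ----------
    y, x : arrays, one entry per neuron
        Baseline-subtracted evoked counts in the 100-ms response window.
    baseline_hz : array or None
        Per-neuron baseline rates; needed for rectification (the
        prediction may not take the implied rate below 0 Hz).  With
        ``None`` and ``rectify=True`` a zero baseline is assumed.
    n_folds : int
        Cross-validation folds; ``n_folds=1`` fits and predicts on the
        full sample (no held-out predictions), in which case the gain is
        exactly the closed form sum(xy)/sum(x^2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D and equal length")
    n = len(y)
    if n_folds > 1 and n < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} neurons for {n_folds}-fold fitting")
    if baseline_hz is None:
        base_counts = np.zeros(n)
    else:
        base_counts = np.asarray(baseline_hz, dtype=float) * RESPONSE_WINDOW_S

    rng = np.random.default_rng(seed)
    if n_folds <= 1:
        folds = np.zeros(n, dtype=int)
        gains = np.array([_shared_gain(x, y)])
        preds = gains[0] * x
    else:
        folds = rng.permutation(np.arange(n) % n_folds)
        gains = np.empty(n_folds)
        preds = np.empty(n)
        for k in range(n_folds):
            held = folds == k
            gains[k] = _shared_gain(x[~held], y[~held])
            preds[held] = gains[k] * x[held]
    if rectify:
        preds = np.maximum(preds, -base_counts)
    ev = explained_variance(preds, y)
    return IntegrationFit(
        predictor_set=predictor_set,
        gain=_shared_gain(x, y),
        explained_variance=ev,
        predictions=preds,
        fold_assignments=folds,
        per_fold_gain=gains,
    )


def explained_variance(predictions: np.ndarray, observations: np.ndarray) -> float:
    """ESS/TSS with ESS = TSS - RSS, on (cross-validated) predictions."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must have equal length")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observations have zero variance; EV undefined")
    rss = float(np.sum((obs - pred) ** 2))
    return (tss - rss) / tss


def compare_predictor_sets(
    y: np.ndarray,
    x_visual: np.ndarray,
    x_nonvisual: np.ndarray,
    baseline_hz: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, IntegrationFit]:
    """Shared-gain fits for visual-only, non-visual-only and summed input."""
    xv = np.asarray(x_visual, dtype=float)
    xnv = np.asarray(x_nonvisual, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {}
    for name, x in (("visual", xv), ("nonvisual", xnv), ("sum", xv + xnv)):
        try:
            out[name] = fit(
                y, x, baseline_hz=baseline_hz, predictor_set=name,
                n_folds=n_folds, seed=seed,
            )
        except ValueError:
            # degenerate (all-zero) component: report an undefined fit
            # rather than aborting the comparison
            out[name] = IntegrationFit(
                predictor_set=name,
                gain=np.nan,
                explained_variance=np.nan,
                predictions=np.full_like(y, np.nan),
                fold_assignments=np.zeros(len(y), dtype=int),
                per_fold_gain=np.array([np.nan]),
            )
    return out


def layerwise_contributions(
    table: pd.DataFrame,
    min_units: int = 5,
) -> pd.DataFrame:
    """Relative visual vs non-visual weight per cortical layer.

    Fits, per layer, the two-predictor no-intercept regression
    ``y ~ b_v * x_visual + b_nv * x_nonvisual`` on standardised predictors
    and reports the weight ratio ``b_nv / (|b_v| + |b_nv|)``.  Layers with
    fewer than ``min_units`` units are reported but skipped (NaN).
    """
    required = {"y_grating", "x_visual", "x_nonvisual", "layer"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for layer, grp in table.groupby("layer", sort=True):
        row = {"layer": layer, "n_units": len(grp)}
        if len(grp) < min_units:
            row.update(b_visual=np.nan, b_nonvisual=np.nan, nonvisual_share=np.nan, skipped=True)
        else:
            xv = grp["x_visual"].to_numpy(dtype=float)
            xnv = grp["x_nonvisual"].to_numpy(dtype=float)
            y = grp["y_grating"].to_numpy(dtype=float)
            sv = xv.std() or 1.0
            snv = xnv.std() or 1.0
            design = np.column_stack([xv / sv, xnv / snv])
            (bv, bnv), *_ = np.linalg.lstsq(design, y, rcond=None)
            denom = abs(bv) + abs(bnv)
            row.update(
                b_visual=float(bv),
                b_nonvisual=float(bnv),
                nonvisual_share=float(abs(bnv) / denom) if denom > 0 else np.nan,
                skipped=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
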