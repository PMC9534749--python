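"""Cross-condition population decoding of saccade direction.

A quadratic-discriminant classifier is trained on single-trial population
responses to pseudo-saccades (per-unit spike counts in the 20-ms bin at
+60 ms from onset) and tested either on held-out pseudo-saccades (10-fold
cross-validation) or on responses to real saccades.  Its cross-condition
accuracy measures how similar the population representations of external
and self-generated image motion are: a strong uncorrelated non-visual
component drives it towards chance, and silencing that component restores
transfer.

The discriminant is preceded by per-unit standardisation and PCA, with
the number of components capped at 20% of the training-event count to
avoid overfitting; all standardisation and projection parameters derive
from training folds only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PopulationResponse",
    "build_population_response",
    "make_balanced_training_set",
    "train",
    "evaluate_cross_condition",
    "cv_accuracy",
    "accuracy_vs_population_size",
    "permutation_feature_importance",
    "exclude_top_contributors",
]

RESPONSE_BIN_MS = (60.0, 80.0)
MIN_MEAN_RATE_HZ = 0.5
COMPONENT_CAP = 0.2


class PopulationResponse:
    """Events x units spike-count matrix with direction labels."""

    def __init__(
        self,
        counts: np.ndarray,
        labels: np.ndarray,
        unit_ids: np.ndarray,
        amplitudes: np.ndarray | None = None,
    ) -> None:
        self.counts = np.asarray(counts, dtype=float)
        self.labels = np.asarray(labels)
        self.unit_ids = np.asarray(unit_ids)
        self.amplitudes = (
            np.asarray(amplitudes, dtype=float)
            if amplitudes is not None
            else np.full(len(self.labels), np.nan)
        )
        if self.counts.shape != (len(self.labels), len(self.unit_ids)):
            raise ValueError("counts must be (n_events, n_units)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def subset_events(self, idx: np.ndarray) -> "PopulationResponse":
        return PopulationResponse(
            self.counts[idx], self.labels[idx], self.unit_ids, self.amplitudes[idx]
        )

    def subset_units(self, unit_idx: np.ndarray) -> "PopulationResponse":
        return PopulationResponse(
            self.counts[:, unit_idx],
            self.labels,
            self.unit_ids[unit_idx],
            self.amplitudes,
        )


def build_population_response(
    spikes: dict[int, np.ndarray],
    events: pd.DataFrame,
    session_length_s: float,
    bin_ms: tuple[float, float] = RESPONSE_BIN_MS,
    min_rate_hz: float = MIN_MEAN_RATE_HZ,
) -> PopulationResponse:
    """Assemble the events x units count matrix for decoding.

    One count per event per unit from the ``[60, 80)`` ms bin after onset
    (the bin grid is anchored at event onset).  Units whose session-wide
    mean rate is at or below ``min_rate_hz`` are excluded.
    """
    onsets = events["onset_t"].to_numpy(dtype=float)
    labels = events["direction_label"].to_numpy()
    eligible, columns = [], []
    for unit_id in sorted(spikes):
        st = np.asarray(spikes[unit_id], dtype=float)
        if len(st) / session_length_s <= min_rate_hz:
            continue
        lo = onsets + bin_ms[0] / 1000.0
        hi = onsets + bin_ms[1] / 1000.0
        counts = np.searchsorted(st, hi, side="left") - np.searchsorted(st, lo, side="left")
        eligible.append(unit_id)
        columns.append(counts)
    if not eligible:
        raise ValueError(f"no unit exceeds the {min_rate_hz} Hz rate floor")
    return PopulationResponse(
        counts=np.column_stack(columns),
        labels=labels,
        unit_ids=np.array(eligible),
        amplitudes=events["amplitude"].to_numpy(dtype=float)
        if "amplitude" in events
        else None,
    )


def make_balanced_training_set(
    pop: PopulationResponse,
    n_subsets: int = 10,
    seed: int = 0,
    max_amp_diff_deg: float = 1.0,
    min_pairs: int = 10,
) -> list[PopulationResponse]:
    """Label- and amplitude-balanced training subsets.

    Greedy nearest-amplitude pairing without replacement matches each
    event of the minority label with the closest-amplitude event of the
    majority label; pairs whose amplitude difference exceeds
    ``max_amp_diff_deg`` are then dropped (keeping counts balanced), so
    the selected subsets have both matched event numbers and matched
    amplitude distributions even when the two directions draw from
    different amplitude ranges.  ``n_subsets`` independent subsets
    (randomised pairing order) are returned for averaging.
    """
    labs = np.unique(pop.labels)
    if len(labs) < 2:
        raise ValueError("both direction labels must be present")
    idx_a = np.flatnonzero(pop.labels == labs[0])
    idx_b = np.flatnonzero(pop.labels == labs[1])
    if len(idx_a) > len(idx_b):
        idx_a, idx_b = idx_b, idx_a  # a = minority
    rng = np.random.default_rng(seed)
    no_amplitudes = not np.isfinite(pop.amplitudes).all()
    subsets = []
    for _ in range(n_subsets):
        order = rng.permutation(idx_a)
        available = dict.fromkeys(idx_b)
        pairs = []
        for i in order:
            amp_i = pop.amplitudes[i]
            pool = np.fromiter(available.keys(), dtype=int)
            j = pool[np.argmin(np.abs(pop.amplitudes[pool] - amp_i))]
            del available[j]
            pairs.append((i, j, abs(pop.amplitudes[j] - amp_i)))
        if not no_amplitudes:
            good = [(i, j, d) for i, j, d in pairs if d <= max_amp_diff_deg]
            if len(good) < min_pairs:  # fall back to the best-matched pairs
                good = sorted(pairs, key=lambda p: p[2])[: max(min_pairs, len(pairs) // 2)]
            pairs = good
        chosen = np.sort(np.array([k for i, j, _ in pairs for k in (i, j)]))
        subsets.append(pop.subset_events(chosen))
    return subsets


def train(training: PopulationResponse, reg_param: float = 1e-3) -> Pipeline:
    """Fit the decoding pipeline on a training population response."""
    labs, counts = np.unique(training.labels, return_counts=True)
    if len(labs) < 2 or counts.min() < 10:
        raise ValueError("need >= 10 training events per label")
    n_components = max(1, int(COMPONENT_CAP * len(training)))
    n_components = min(n_components, training.counts.shape[1])
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=n_components)),
            ("qda", QuadraticDiscriminantAnalysis(reg_param=reg_param)),
        ]
    )
    pipe.fit(training.counts, training.labels)
    return pipe


def evaluate_cross_condition(
    model: Pipeline, test: PopulationResponse, balanced: bool = False
) -> float:
    """Accuracy of a fitted pipeline on a fully held-out condition.

    With ``balanced=True`` the per-class accuracies are averaged, so a
    label-biased classifier scores 0.5 on an unbalanced test set (real
    saccades are predominantly nasal; the emulated analysis evaluates on
    direction-matched test pools).
    """
    expected = model.named_steps["scale"].n_features_in_
    if test.counts.shape[1] != expected:
        raise ValueError(
            f"test set has {test.counts.shape[1]} units, model expects {expected}"
        )
    pred = model.predict(test.counts)
    if not balanced:
        return float(np.mean(pred == test.labels))
    per_class = [
        np.mean(pred[test.labels == lab] == lab) for lab in np.unique(test.labels)
    ]
    return float(np.mean(per_class))


def cv_accuracy(
    pop: PopulationResponse,
    n_folds: int = 10,
    reg_param: float = 1e-3,
    seed: int = 0,
) -> float:
    """Within-condition accuracy via stratified 10-fold cross-validation."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(pop.counts, pop.labels):
        model = train(pop.subset_events(tr), reg_param=reg_param)
        pred = model.predict(pop.counts[te])
        correct += int(np.sum(pred == pop.labels[te]))
    return correct / len(pop)


def accuracy_vs_population_size(
    training_sets: list[PopulationResponse],
    test: PopulationResponse,
    sizes: tuple[int, ...] = (5, 10, 15, 20, 30, 40, 50, 100, 175, 250),
    n_resamples: int = 50,
    seed: int = 0,
    reg_param: float = 1e-3,
    balanced: bool = False,
) -> pd.DataFrame:
    """Decoding accuracy as a function of the number of units included.

    For each size, units are sampled without replacement ``n_resamples``
    times per training set; every (training set, resample) run trains on
    the pseudo-saccade subset and tests on the held-out condition, and the
    runs are averaged.  Averaging over random unit subsets also averages
    over the chance alignment between the classifier and patterns that are
    uninformative about the trained labels.  Sizes above the unit pool are
    skipped.
    """
    n_units = training_sets[0].counts.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n_units:
            continue
        accs = []
        for tr_set in training_sets:
            for _ in range(n_resamples):
                unit_idx = (
                    rng.choice(n_units, size=size, replace=False)
                    if size < n_units
                    else np.arange(n_units)
                )
                model = train(tr_set.subset_units(unit_idx), reg_param=reg_param)
                accs.append(
                    evaluate_cross_condition(
                        model, test.subset_units(unit_idx), balanced=balanced
                    )
                )
        rows.append(
            {
                "n_units": size,
                "accuracy": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else np.nan,
                "n_runs": len(accs),
            }
        )
    return pd.DataFrame(rows)


def permutation_feature_importance(
    pop: PopulationResponse,
    n_folds: int = 10,
    seed: int = 0,
    reg_param: float = 1e-3,
) -> pd.DataFrame:
    """Per-unit permutation feature importance under cross-validation.

    Importance of a unit is the increase in 10-fold cross-validated
    misclassification rate when that unit's column is permuted across
    events (breaking its relation to direction while preserving its
    marginal distribution).
    """
    rng = np.random.default_rng(seed)
    baseline_err = 1.0 - cv_accuracy(pop, n_folds=n_folds, reg_param=reg_param, seed=seed)
    n_units = pop.counts.shape[1]
    rows = []
    for u in range(n_units):
        shuffled = pop.counts.copy()
        shuffled[:, u] = rng.permutation(shuffled[:, u])
        perm_pop = PopulationResponse(shuffled, pop.labels, pop.unit_ids, pop.amplitudes)
        err = 1.0 - cv_accuracy(perm_pop, n_folds=n_folds, reg_param=reg_param, seed=seed)
        rows.append(
            {
                "unit_id": pop.unit_ids[u],
                "importance": err - baseline_err,
            }
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out


def exclude_top_contributors(
    pop: PopulationResponse,
    importance: pd.DataFrame,
    top_fraction: float = 0.2,
    n_folds: int = 10,
    seed: int = 0,
    reg_param: float = 1e-3,
) -> dict:
    """Accuracy with the top-importance units permuted simultaneously."""
    n_top = max(1, int(round(top_fraction * len(importance))))
    top_units = importance.nsmallest(len(importance), "rank").head(n_top)["unit_id"].to_numpy()
    rng = np.random.default_rng(seed)
    shuffled = pop.counts.copy()
    for u in top_units:
        col = int(np.flatnonzero(pop.unit_ids == u)[0])
        shuffled[:, col] = rng.permutation(shuffled[:, col])
    perm_pop = PopulationResponse(shuffled, pop.labels, pop.unit_ids, pop.amplitudes)
    return {
        "top_units": top_units,
        "accuracy_all_permuted": cv_accuracy(
            perm_pop, n_folds=n_folds, reg_param=reg_param, seed=seed
        ),
        "accuracy_baseline": cv_accuracy(
            pop, n_folds=n_folds, reg_param=reg_param, seed=seed
        ),
    }
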