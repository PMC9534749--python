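"""Session containers, disk round-tripping and pipeline orchestration.

A session bundle lives in one directory of plain-text files:

```
session/
  metadata.json        condition, frame_rate, session_length_s, seed, ...
  trace.csv            t_s, azimuth_deg, elevation_deg, pupil_mm
  saccades.csv         onset_t, offset_t, amplitude, direction_deg, ...
  pseudosaccades.csv   onset_t, amplitude, direction_label, ...
  spikes.csv           condition, unit_id, t_s (long format)
  ground_truth.json    generator truth, when the session is synthetic
```

Unknown extra columns are preserved (with a warning) so bundles written
by newer versions still round-trip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, detection, integration, pseudosaccades as ps, response_stats, synthetic
from .eye_geometry import EyeTrace

__all__ = ["SessionBundle", "read_session", "write_session", "run_pipeline"]

logger = logging.getLogger("saccadeflow")

_REQUIRED = {
    "metadata": "metadata.json",
    "trace": "trace.csv",
    "saccades": "saccades.csv",
}


@dataclass
class SessionBundle:
    """Everything recorded (or generated) in one session."""

    metadata: dict
    trace: EyeTrace
    saccades: pd.DataFrame
    pseudos: pd.DataFrame = field(default_factory=pd.DataFrame)
    spikes: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    ground_truth: pd.DataFrame | None = None

    def validate(self) -> None:
        span = (float(self.trace.t[0]), float(self.trace.t[-1]))
        for name, events in (("saccades", self.saccades), ("pseudosaccades", self.pseudos)):
            if events.empty:
                continue
            onsets = events["onset_t"].to_numpy(dtype=float)
            if onsets.min() < span[0] or onsets.max() > span[1]:
                raise ValueError(f"{name}: event onset outside the trace time span {span}")
        for cond, units in self.spikes.items():
            if len(set(units)) != len(units):
                raise ValueError(f"duplicate unit ids in condition {cond!r}")


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    (path / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2))
    bundle.trace.to_frame().to_csv(path / "trace.csv", index=False)
    bundle.saccades.to_csv(path / "saccades.csv", index=False)
    bundle.pseudos.to_csv(path / "pseudosaccades.csv", index=False)
    rows = []
    for cond, units in bundle.spikes.items():
        for uid, st in units.items():
            rows.append(
                pd.DataFrame({"condition": cond, "unit_id": uid, "t_s": np.asarray(st)})
            )
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["condition", "unit_id", "t_s"])
    )
    spikes.to_csv(path / "spikes.csv", index=False)
    if bundle.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            bundle.ground_truth.to_json(orient="records", double_precision=15)
        )
    return path


def read_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    for key, fname in _REQUIRED.items():
        if not (path / fname).exists():
            raise FileNotFoundError(f"session at {path} is missing required file {fname!r}")
    metadata = json.loads((path / "metadata.json").read_text())
    for key in ("condition", "frame_rate"):
        if key not in metadata:
            raise ValueError(f"metadata.json is missing required field {key!r}")
    trace_df = pd.read_csv(path / "trace.csv")
    known = {"t_s", "azimuth_deg", "elevation_deg", "pupil_mm"}
    extra = set(trace_df.columns) - known
    if extra:
        warnings.warn(f"trace.csv has unknown columns {sorted(extra)}; preserved", stacklevel=2)
    trace = EyeTrace.from_frame(
        trace_df, frame_rate=metadata["frame_rate"], condition=metadata["condition"]
    )
    saccades = pd.read_csv(path / "saccades.csv")
    pseudo_file = path / "pseudosaccades.csv"
    pseudos = pd.read_csv(pseudo_file) if pseudo_file.exists() else pd.DataFrame()
    spikes: dict[str, dict[int, np.ndarray]] = {}
    spikes_file = path / "spikes.csv"
    if spikes_file.exists():
        long = pd.read_csv(spikes_file)
        for (cond, uid), grp in long.groupby(["condition", "unit_id"]):
            spikes.setdefault(str(cond), {})[int(uid)] = grp["t_s"].to_numpy(dtype=float)
    gt_file = path / "ground_truth.json"
    ground_truth = pd.read_json(gt_file) if gt_file.exists() else None
    bundle = SessionBundle(
        metadata=metadata,
        trace=trace,
        saccades=saccades,
        pseudos=pseudos,
        spikes=spikes,
        ground_truth=ground_truth,
    )
    bundle.validate()
    return bundle


def bundle_from_synthetic(session: synthetic.SyntheticSession) -> SessionBundle:
    meta = session.config.to_dict()
    meta["provenance"] = "synthetic"
    return SessionBundle(
        metadata=meta,
        trace=session.trace,
        saccades=session.saccades,
        pseudos=session.pseudos,
        spikes=session.spikes,
        ground_truth=session.ground_truth,
    )


def run_pipeline(config: synthetic.SimConfig, out_dir: str | Path) -> dict:
    """Run the full chain on a synthetic session and write results.

    simulate -> detect -> isolate -> match pseudo-saccades -> per-unit
    discriminability (grey-screen and pseudo conditions) -> cross-
    condition decoding (control vs pulvinar-silenced) -> integration-model
    fits.  Deterministic for a fixed config seed; every stage logs its
    parameters and counts and failures halt the pipeline with the stage
    name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        session = synthetic.generate_session(
            config,
            conditions=("grey_screen", "pseudo", "grating", "pulvinar_silenced"),
        )
        write_session(bundle_from_synthetic(session), out / "session")
        logger.info(
            "simulate: %d saccades, %d pseudo-saccades, %d units",
            len(session.saccades), len(session.pseudos), config.n_units,
        )

        stage = "detect"
        if config.condition == "head_fixed":
            detected = detection.detect_head_fixed(session.trace)
        else:
            detected = detection.detect_freely_moving(session.trace)
        detected = detection.isolation_filter(detected, session.trace)
        detected.to_csv(out / "detected_saccades.csv", index=False)
        logger.info("detect: %d events after isolation filtering", len(detected))
        results["n_detected"] = int(len(detected))

        stage = "match"
        matched, match_summary = ps.match_to_saccades(session.pseudos, session.saccades)
        matched.to_csv(out / "matched_pseudosaccades.csv", index=False)
        logger.info("match: %s", match_summary)
        results["match_summary"] = match_summary

        stage = "stats"
        onsets = {
            lab: session.saccades.loc[
                session.saccades["direction_label"] == lab, "onset_t"
            ].to_numpy()
            for lab in ("nasal", "temporal")
        }
        per_unit = {}
        for uid, st in session.spikes["grey_screen"].items():
            per_unit[uid] = (
                response_stats.windowed_counts(st, onsets["nasal"])["response"].to_numpy(),
                response_stats.windowed_counts(st, onsets["temporal"])["response"].to_numpy(),
            )
        stats_grey = response_stats.discriminability_table(per_unit)
        stats_grey.to_csv(out / "discriminability_grey_screen.csv", index=False)
        results["n_discriminating_grey"] = int(stats_grey["significant"].sum())
        logger.info("stats: %d/%d units discriminate on grey screen",
                    results["n_discriminating_grey"], len(stats_grey))

        stage = "decode"
        span = float(config.session_length_s)
        pop_pseudo = decoding.build_population_response(
            session.spikes["pseudo"], session.pseudos, span
        )
        training_sets = decoding.make_balanced_training_set(
            pop_pseudo, n_subsets=3, seed=config.seed
        )
        accs = {}
        for cond in ("grating", "pulvinar_silenced"):
            pop = decoding.build_population_response(
                session.spikes[cond], session.saccades, span
            )
            common = np.intersect1d(pop.unit_ids, pop_pseudo.unit_ids)
            tr = training_sets[0].subset_units(
                np.flatnonzero(np.isin(training_sets[0].unit_ids, common))
            )
            te = pop.subset_units(np.flatnonzero(np.isin(pop.unit_ids, common)))
            m = decoding.train(tr)
            accs[cond] = decoding.evaluate_cross_condition(m, te)
        results["decoding_accuracy"] = accs
        logger.info("decode: cross-condition accuracy %s", accs)

        stage = "integrate"
        table = synthetic.make_response_table(session.ground_truth, config)
        fits = integration.compare_predictor_sets(
            table["y_grating"], table["x_visual"], table["x_nonvisual"],
            baseline_hz=table["baseline_hz"], seed=config.seed,
        )
        results["integration"] = {
            name: {"gain": f.gain, "explained_variance": f.explained_variance}
            for name, f in fits.items()
        }
        logger.info("integrate: %s", results["integration"])
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
    except Exception as exc:  # halt with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
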