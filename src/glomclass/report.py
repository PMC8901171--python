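"""Cohort summaries, report arithmetic and pipeline orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .classify import LABELS, ResponseClassifier
from .recording import ParameterError, read_recording
from .spikes import detect_spikes

logger = logging.getLogger(__name__)


def percent(n: int, total: int) -> int:
    """Integer percentage, rounded half up: round(100 n / total)."""
    if total <= 0:
        raise ParameterError("total must be > 0")
    if not 0 <= n <= total:
        raise ParameterError("n must satisfy 0 <= n <= total")
    return int(math.floor(100.0 * n / total + 0.5))


def format_mean_sd(mean: float, sd: float, digits: int = 1) -> str:
    """'mean +/- SD' formatting used in cohort text summaries."""
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"


@dataclasses.dataclass
class CohortSummary:
    counts: dict
    total: int
    percentages: dict
    confusion: pd.DataFrame | None = None
    accuracy: float | None = None

    def summary(self) -> str:
        lines = [f"Cohort summary ({self.total} cells)", "=" * 40]
        for label, c in self.counts.items():
            lines.append(f"{label:32s} {c:5d}  ({self.percentages[label]}%)")
        if self.accuracy is not None:
            lines.append(f"accuracy vs ground truth: {self.accuracy:.3f}")
        return "\n".join(lines)


def summarize_cohort(results, truth: pd.DataFrame | None = None
                     ) -> CohortSummary:
    """Label counts and percentages; confusion matrix when truth is given.

    ``results`` is a list of ClassificationResult (or anything with
    ``label`` and ``cell_id``); ``truth`` needs cell_id and label columns.
    """
    if not results:
        raise ParameterError("empty result list")
    for r in results:
        if r.label not in LABELS:
            raise ParameterError(f"label {r.label!r} outside taxonomy")
    pred = pd.DataFrame({"cell_id": [r.cell_id for r in results],
                         "predicted": [r.label for r in results]})
    counts = pred["predicted"].value_counts().to_dict()
    total = len(pred)
    percentages = {lab: percent(c, total) for lab, c in counts.items()}
    confusion = accuracy = None
    if truth is not None:
        merged = pred.merge(truth[["cell_id", "label"]], on="cell_id")
        confusion = pd.crosstab(merged["label"], merged["predicted"])
        accuracy = float((merged["label"] == merged["predicted"]).mean())
    return CohortSummary(counts=counts, total=total, percentages=percentages,
                         confusion=confusion, accuracy=accuracy)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _digest(obj) -> str:
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, params) -> None:
    header = f"# glomclass stage={stage} params={_digest(params)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_config(config):
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir, seed: int | None = None) -> Path:
    """Simulate (optionally) -> detect -> classify -> summarize.

    ``config`` is a dict or YAML path.  Keys:

    - ``simulate``: {cohort: [{label, n_cells, overrides...}], n_episodes,
      episode_duration, stim_time, write_recordings}
    - ``input_dir``: directory of recordings (alternative to simulate)
    - ``classify``: parameter overrides for the classifier
    - ``seed``: int, mandatory when simulating (CLI --seed overrides)

    Every stage writes its artifact plus ``run.json`` logging parameters,
    seed and stage digests.  Deterministic stages are bit-reproducible.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed") if seed is None else seed
    log: dict = {"seed": seed, "stages": {}}

    truth = None
    recordings = {}
    spikes_by_cell = {}
    stim_times = None
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        if seed is None:
            raise ParameterError("a seed is mandatory when simulating")
        kw = {k: sim[k] for k in ("n_episodes", "episode_duration",
                                  "stim_time") if k in sim}
        spec = []
        for entry in sim["cohort"]:
            entry = dict(entry)
            label = entry.pop("label")
            n_cells = int(entry.pop("n_cells"))
            base = synth.preset_config(label, **kw)
            c = dataclasses.replace(base, **entry) if entry else base
            spec.append((label, c, n_cells))
        render = bool(sim.get("write_recordings", False))
        truth = synth.simulate_cohort(spec, out_dir / "cohort", seed=seed,
                                      render=render)
        spikes_by_cell = truth.attrs["spikes"]
        stim_times = [kw.get("stim_time", 1.5)]
        ep_dur = kw.get("episode_duration", 4.0)
        log["stages"]["simulate"] = {"n_cells": len(truth),
                                     "render": render,
                                     "params": _digest(sim)}
    elif "input_dir" in cfg:
        in_dir = Path(cfg["input_dir"])
        for meta in sorted(in_dir.glob("*.meta.json")):
            rec = read_recording(meta)
            recordings[rec.cell_id] = rec
        if not recordings:
            raise ParameterError(f"no recordings found in {in_dir}")
        log["stages"]["load"] = {"n_cells": len(recordings)}
    else:
        raise ParameterError("config must name 'simulate' or 'input_dir'")

    cls_params = dict(cfg.get("classify", {}))
    rows = []
    results = []
    from .spikes import SpikeTrainSet

    if recordings:
        items = [(cid, None, rec) for cid, rec in recordings.items()]
    else:
        items = [(cid, SpikeTrainSet(trains=tr, episode_duration=ep_dur,
                                     cell_id=cid), None)
                 for cid, tr in spikes_by_cell.items()]
    spike_rows = []
    for cell_id, spk, rec in items:
        try:
            if rec is not None:
                spk = detect_spikes(rec)
                spk.cell_id = cell_id
                st = rec.stim_times
            else:
                st = stim_times
            for ep, train in enumerate(spk.trains):
                for t in train:
                    spike_rows.append({"cell_id": cell_id, "episode": ep,
                                       "t_s": round(float(t), 6)})
            res = ResponseClassifier(recording=rec, spikes=spk,
                                     stim_times=st, **cls_params).fit()
        except Exception as exc:
            raise RuntimeError(
                f"classification stage failed for cell {cell_id}: {exc}"
            ) from exc
        res.cell_id = cell_id
        results.append(res)
        rows.append({
            "cell_id": cell_id, "label": res.label,
            "p_inhib": res.inhibition.p_value, "p_slow": res.slow.p_value,
            "p_fast": res.fast.p_value,
            "inhib_window_ms": (abs(res.inhibition.window[0]) * 1e3
                                if res.inhibition.window else np.nan),
            "inhib_duration_ms": (res.inhibition_duration_s * 1e3
                                  if res.inhibition_duration_s is not None
                                  else np.nan),
            "latency_ms": (res.mean_latency_s * 1e3
                           if res.mean_latency_s is not None else np.nan),
            "latency_class": res.latency_class,
            "polarity": res.polarity,
        })
    _write_csv(pd.DataFrame(spike_rows), out_dir / "spikes.csv",
               "detect-spikes", cls_params)
    table = pd.DataFrame(rows)
    _write_csv(table, out_dir / "classification.csv", "classify", cls_params)
    summary = summarize_cohort(results, truth=truth)
    log["stages"]["classify"] = {"n_cells": len(rows),
                                 "params": _digest(cls_params)}
    log["summary"] = {"counts": summary.counts,
                      "percentages": summary.percentages,
                      "accuracy": summary.accuracy}
    if summary.confusion is not None:
        summary.confusion.to_csv(out_dir / "confusion.csv")
    with open(out_dir / "run.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d cells -> %s", len(rows), out_dir)
    return out_dir
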