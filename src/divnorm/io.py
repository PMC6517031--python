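"""Interchange formats: manifest JSON, trial/feature CSV tables, trace stores.

CSV floats are written with a fixed repr ('%.10g') so that regenerating an
experiment from the same seed reproduces the files byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from . import signal as sig
from .datatypes import Condition

__all__ = [
    "FLOAT_FORMAT",
    "write_manifest",
    "read_manifest",
    "trial_table",
    "write_trial_table",
    "write_traces_h5",
    "write_traces_csv",
    "build_feature_table",
    "write_csv",
]

FLOAT_FORMAT = "%.10g"


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def trial_table(trials) -> pd.DataFrame:
    rows = [{
        "cell_id": t.cell_id,
        "pattern_id": t.pattern.pattern_id,
        "n_squares": t.pattern.n_squares,
        "squares": ";".join(str(s) for s in t.pattern.squares),
        "condition": t.condition.value,
        "repeat": t.repeat_index,
        "stim_onset_ms": t.trace.stim_onset_ms,
        "units": t.trace.units,
    } for t in trials]
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_trial_table(trials, path) -> None:
    write_csv(trial_table(trials), path)


def _trial_key(t) -> str:
    return f"{t.cell_id}/{t.pattern.pattern_id}/{t.condition.value}/r{t.repeat_index}"


def write_traces_h5(trials, path) -> None:
    """One dataset per trial; dt and units stored as attributes."""
    with h5py.File(path, "w") as f:
        for t in trials:
            ds = f.create_dataset(_trial_key(t), data=t.trace.samples)
            ds.attrs["dt_ms"] = t.trace.dt_ms
            ds.attrs["units"] = t.trace.units
            ds.attrs["stim_onset_ms"] = t.trace.stim_onset_ms


def write_traces_csv(trials, path) -> None:
    """Plain-text fallback: wide CSV, one column per trial."""
    cols = {_trial_key(t).replace("/", "|"): t.trace.samples for t in trials}
    df = pd.DataFrame(cols)
    df.insert(0, "time_ms", trials[0].trace.time_ms())
    write_csv(df, path)


def build_feature_table(trials, preprocess: bool = True,
                        filter_cutoff_hz: float = 2000.0) -> pd.DataFrame:
    """Per-trial QC flags and response features as a tidy table."""
    rows = []
    for t in trials:
        trace = sig.preprocess(t.trace, filter_cutoff_hz) if preprocess else t.trace
        verdict = sig.flag_trial(t.trace if t.trace.units == "mV" else trace)
        feats = sig.extract_features(trace, sign=sig.condition_sign(t.condition))
        rows.append({
            "cell_id": t.cell_id,
            "pattern_id": t.pattern.pattern_id,
            "n_squares": t.pattern.n_squares,
            "squares": ";".join(str(s) for s in t.pattern.squares),
            "condition": t.condition.value,
            "repeat": t.repeat_index,
            "peak_amp": feats.peak_amp,
            "peak_time": feats.peak_time_ms,
            "auc": feats.auc,
            "mean_v": feats.mean_v,
            "auc_to_peak": feats.auc_to_peak,
            "onset_time_ms": feats.onset_time_ms,
            "flagged": not verdict.passed,
            "flags": ";".join(sorted(fl.value for fl in verdict.trial_flags)),
        })
    return pd.DataFrame(rows)


REQUIRED_TRIAL_COLUMNS = ["cell_id", "pattern_id", "n_squares", "condition",
                          "repeat", "stim_onset_ms"]
REQUIRED_FEATURE_COLUMNS = ["cell_id", "pattern_id", "n_squares", "condition",
                            "repeat", "peak_amp", "auc", "flagged"]


def validate_tables(paths) -> dict:
    """Schema check for interchange CSVs: columns, unit tags, key uniqueness."""
    verdict = {"passed": True, "violations": []}

    def fail(path, msg):
        verdict["passed"] = False
        verdict["violations"].append(f"{path}: {msg}")

    for path in paths:
        path = Path(path)
        if not path.exists():
            fail(path, "file does not exist")
            continue
        df = pd.read_csv(path)
        required = (REQUIRED_FEATURE_COLUMNS if "peak_amp" in df.columns
                    else REQUIRED_TRIAL_COLUMNS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            fail(path, f"missing columns {missing}")
            continue
        key = ["cell_id", "pattern_id", "condition", "repeat"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = df[dup].iloc[0]
            fail(path, "duplicate trial key "
                 f"({row['cell_id']}, {row['pattern_id']}, "
                 f"{row['condition']}, {row['repeat']})")
        if "units" in df.columns:
            for cond, units in zip(df["condition"], df["units"]):
                expected = Condition(cond).units
                if units != expected:
                    fail(path, f"condition {cond} requires {expected} traces, "
                         f"found {units}")
                    break
    return verdict
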