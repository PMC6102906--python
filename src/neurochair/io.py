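"""File formats: columnar signal containers (CSV), stimulus event tables
(TSV), model JSON, JSONL session logs and metrics CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .p300_decoder import SWLDAModel
from .session import SessionMetrics
from .synth_signals import EEGRecord, StimEvent, StimulusSchedule


def write_signal_csv(record: EEGRecord, path) -> None:
    df = pd.DataFrame(record.samples.T, columns=list(record.channel_names))
    df.insert(0, "time_s", record.times)
    df.to_csv(path, index=False, float_format="%.6f")


def read_signal_csv(path) -> EEGRecord:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    times = df.pop("time_s").to_numpy()
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.median(np.diff(times)))
    return EEGRecord(round(fs, 6), tuple(df.columns), df.to_numpy().T,
                     start_time=float(times[0]))


def write_events_tsv(schedules, attended_indices, path) -> None:
    """Stimulus event table: one row per intensification."""
    rows = []
    for sched, att in zip(schedules, attended_indices):
        for ev in sched.events:
            rows.append({
                "onset_s": ev.onset,
                "stimulus_index": ev.stimulus_index,
                "sequence_index": ev.sequence_index,
                "trial_id": sched.trial_id,
                "attended": int(ev.stimulus_index == att),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> tuple[list[StimulusSchedule], list[int]]:
    df = pd.read_csv(path, sep="\t")
    schedules, attended = [], []
    for trial_id, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("onset_s")
        events = tuple(StimEvent(float(r.onset_s), int(r.stimulus_index),
                                 int(r.sequence_index))
                       for r in grp.itertuples())
        onsets = np.array([e.onset for e in events])
        soa = float(np.median(np.diff(onsets))) if len(onsets) > 1 else 0.2
        att_rows = grp[grp.attended == 1]
        schedules.append(StimulusSchedule(
            trial_id=int(trial_id), events=events,
            n_sequences=int(grp.sequence_index.max()) + 1,
            t_intensify=0.6 * soa, t_interval=0.4 * soa,
            active_set=frozenset(int(i) for i in grp.stimulus_index.unique()),
        ))
        attended.append(int(att_rows.stimulus_index.iloc[0]) if len(att_rows)
                        else -1)
    return schedules, attended


def save_model(model: SWLDAModel, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> SWLDAModel:
    return SWLDAModel.from_json(Path(path).read_text())


def write_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def metrics_to_frame(metrics_list) -> pd.DataFrame:
    rows = [{"TrP3": m.trp3, "TiP3": m.tip3, "VT": m.vt, "FV": m.fv,
             "SR": m.sr, "EP": m.ep, "NV": m.nv} for m in metrics_list]
    return pd.DataFrame(rows)


def write_metrics_csv(metrics_list, path, aggregate: bool = True) -> pd.DataFrame:
    """Per-session metric rows plus mean/std aggregate rows."""
    df = metrics_to_frame(metrics_list)
    df.insert(0, "session", np.arange(1, len(df) + 1))
    out = df
    if aggregate and len(df):
        stats = df.drop(columns="session").agg(["mean", "std"])
        stats.insert(0, "session", stats.index)
        out = pd.concat([df, stats], ignore_index=True)
    out.to_csv(path, index=False)
    return out
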