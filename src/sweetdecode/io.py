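"""Session directory format: trials.csv, spikes.csv, licks.csv, meta.json.

Timestamps are written with microsecond (1e-6 s) resolution, so a
write/read cycle reproduces them bit-exactly at that resolution.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EPOCHS, FormatError, LickTrain, Session, SpikeTrain, Trial, ValidationError

_TRIAL_COLUMNS = [
    "trial_id", "cue_kind", "concentration_wt_pct", "intensity_label", "choice",
    "correct", "rewarded", "t_cue", "t_response_onset", "t_second_lateral_lick",
    "t_return_onset", "return_side", "high_port",
]
_EPOCH_COLUMNS = [f"{name.lower()}_{edge}" for name in EPOCHS for edge in ("t0", "t1")]


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory of CSV tables plus meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trials:
        row = {c: getattr(t, c) for c in _TRIAL_COLUMNS}
        for name in EPOCHS:
            a, b = t.epochs[name]
            row[f"{name.lower()}_t0"] = a
            row[f"{name.lower()}_t1"] = b
        rows.append(row)
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS + _EPOCH_COLUMNS).to_csv(
        path / "trials.csv", index=False, float_format="%.6f")

    spike_rows = [
        {"neuron_id": s.neuron_id, "channel": s.channel, "timestamp_s": ts}
        for s in session.spikes for ts in s.timestamps
    ]
    pd.DataFrame(spike_rows, columns=["neuron_id", "channel", "timestamp_s"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.6f")

    lick_rows = [
        {"spout": l.spout, "timestamp_s": ts} for l in session.licks for ts in l.timestamps
    ]
    pd.DataFrame(lick_rows, columns=["spout", "timestamp_s"]).to_csv(
        path / "licks.csv", index=False, float_format="%.6f")

    meta = {"session_id": session.session_id, "region_label": session.region_label}
    meta.update(session.meta)
    # neurons with zero spikes would otherwise vanish from spikes.csv
    meta["neuron_order"] = [s.neuron_id for s in session.spikes]
    meta["neuron_channels"] = {s.neuron_id: int(s.channel) for s in session.spikes}
    (path / "meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a session directory")
    for fname in ("trials.csv", "spikes.csv", "licks.csv", "meta.json"):
        if not (path / fname).exists():
            raise FormatError(f"missing {fname} in {path}")

    meta = json.loads((path / "meta.json").read_text())
    trials_df = pd.read_csv(path / "trials.csv")
    missing = set(_TRIAL_COLUMNS + _EPOCH_COLUMNS) - set(trials_df.columns)
    if missing:
        raise FormatError(f"trials.csv missing columns: {sorted(missing)}")

    trials = []
    bad = []
    for _, row in trials_df.iterrows():
        try:
            trials.append(Trial(
                trial_id=int(row.trial_id),
                cue_kind=str(row.cue_kind),
                concentration_wt_pct=float(row.concentration_wt_pct),
                intensity_label=str(row.intensity_label),
                choice=str(row.choice),
                correct=bool(row.correct),
                rewarded=bool(row.rewarded),
                t_cue=float(row.t_cue),
                t_response_onset=float(row.t_response_onset),
                t_second_lateral_lick=float(row.t_second_lateral_lick),
                t_return_onset=float(row.t_return_onset),
                epochs={name: (float(row[f"{name.lower()}_t0"]), float(row[f"{name.lower()}_t1"]))
                        for name in EPOCHS},
                return_side=str(row.return_side),
                high_port=str(row.high_port),
            ))
        except ValidationError:
            bad.append(int(row.trial_id))
    if bad:
        raise ValidationError(f"invalid trials in trials.csv: {bad}")

    spikes_df = pd.read_csv(path / "spikes.csv")
    if not {"neuron_id", "timestamp_s"} <= set(spikes_df.columns):
        raise FormatError("spikes.csv must have neuron_id and timestamp_s columns")
    channels = {str(k): int(v) for k, v in meta.pop("neuron_channels", {}).items()}
    order = [str(n) for n in meta.pop("neuron_order", [])]
    grouped = {str(nid): g["timestamp_s"].to_numpy()
               for nid, g in spikes_df.groupby("neuron_id", sort=False)}
    if not order:
        order = list(grouped)
    spikes = [SpikeTrain(nid, grouped.get(nid, np.empty(0)), channels.get(nid, 0))
              for nid in order]

    licks_df = pd.read_csv(path / "licks.csv")
    licks = [LickTrain(str(spout), g["timestamp_s"].to_numpy())
             for spout, g in licks_df.groupby("spout", sort=False)]

    session_id = str(meta.pop("session_id", path.name))
    region = str(meta.pop("region_label", "synthetic"))
    return Session(session_id, trials, spikes, licks, region_label=region, meta=meta)
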