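"""End-to-end orchestration: staging → N2 extraction → detection →
postprocessing → characteristics → (optional) cohort comparison.

Three analysis modes mirror common practice:

* ``expert`` — sleep stages are supplied per subject (hypnogram files);
  spindle detection is restricted to the annotated N2 sleep.
* ``auto`` — stages are predicted by a stage predictor (the trainable
  spectral baseline, fitted on the subjects that carry hypnograms), then
  detection is restricted to the predicted N2 sleep.
* ``unstaged`` — detection runs over the whole recording with no stage
  restriction.  This reproduces the known failure mode of stage-unaware
  detection (spindles reported in Wake/REM) and is therefore disabled unless
  explicitly requested.

Every run writes a resolved-config file alongside its outputs; re-running
from that file reproduces the results (single-threaded determinism).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import evaluation as evl
from .errors import ParameterError
from .io import (
    EventList,
    Hypnogram,
    Recording,
    read_events,
    read_hypnogram,
    read_recording,
    write_events,
    write_hypnogram,
)
from .preprocessing import extract_n2_blocks
from .staging import baseline_predictor_train, stage_recording
from .unet import SpindleUNet, detect_spindles, load_checkpoint

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "spindlekit_out",
    "checkpoint": None,
    "staging": {"mode": "expert"},  # expert | auto | unstaged
    "allow_unstaged": False,
    "detection": {"min_iou": 0.2},
    "channels": None,  # None = all channels in each recording
    "subjects": [],    # [{id, edf, hypnogram?, group?}]
}


def merge_config(*layers: Mapping) -> dict:
    """Deep-merge config layers, later layers winning (defaults < file < flags)."""
    out: dict = {}
    for layer in layers:
        for k, v in (layer or {}).items():
            if isinstance(v, Mapping) and isinstance(out.get(k), dict):
                out[k] = merge_config(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    return data


def analyze_recording(
    recording: Recording,
    model: SpindleUNet,
    hypnogram: Hypnogram | None = None,
    predictor: Callable[[np.ndarray], np.ndarray] | None = None,
    channels: Sequence[str] | None = None,
    allow_unstaged: bool = False,
) -> dict:
    """Run the spindle-analysis chain for one recording.

    Returns a dict with the hypnogram used (or ``None`` in unstaged mode),
    per-channel postprocessed events, the channel-union event list, the
    per-spindle characteristics table and the subject-level summary table.
    """
    channels = list(channels) if channels else list(recording.channels)
    if hypnogram is None and predictor is not None:
        hypnogram, _ = stage_recording(recording, predictor)
    if hypnogram is None:
        if not allow_unstaged:
            raise ParameterError(
                "no hypnogram and no predictor: pass allow_unstaged=True to "
                "run stage-unaware detection (spindles may then be reported "
                "in Wake/REM)"
            )
        n_ep = max(1, recording.n_epochs)
        hypnogram_for_blocks = Hypnogram(["N2"] * n_ep)
    else:
        hypnogram_for_blocks = hypnogram

    per_channel: dict[str, EventList] = {}
    for ch in channels:
        signal, fs = recording.channel(ch)
        blocks = extract_n2_blocks(signal, fs, hypnogram_for_blocks, channel=ch)
        raw = detect_spindles(model, blocks)
        per_channel[ch] = ev.postprocess_events(raw)
    merged = ev.union_merge_channels(per_channel)
    all_events = EventList(
        [e for lst in per_channel.values() for e in lst]
    ).sorted()
    records = ev.characterize(all_events, recording)
    summary = ev.summarize_characteristics(records, hypnogram_for_blocks) \
        if len(records) else pd.DataFrame(
            columns=["subject", "channel", "speed_class", "metric", "value"])
    return {
        "hypnogram": hypnogram,
        "per_channel_events": per_channel,
        "merged_events": merged,
        "records": records,
        "summary": summary,
    }


def run_pipeline(config: Mapping) -> Path:
    """Execute the configured analysis for all subjects; returns the out dir.

    Emits per-subject hypnograms (auto mode), event CSVs and characteristics,
    a pooled summary table and, when subjects carry two distinct ``group``
    labels, a cohort-comparison table in the shape of the study's
    characteristics tables.
    """
    cfg = merge_config(DEFAULT_CONFIG, config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg))
    if not cfg["subjects"]:
        raise ParameterError("config lists no subjects")
    if cfg["checkpoint"] is None:
        raise ParameterError("config field 'checkpoint' is required "
                             "(path to a trained spindle model)")
    model = load_checkpoint(cfg["checkpoint"])

    mode = cfg["staging"]["mode"]
    subjects = cfg["subjects"]
    recordings: dict[str, Recording] = {}
    hypnograms: dict[str, Hypnogram | None] = {}
    for s in subjects:
        recordings[s["id"]] = read_recording(s["edf"])
        hypnograms[s["id"]] = (
            read_hypnogram(s["hypnogram"]) if s.get("hypnogram") else None
        )

    predictor = None
    if mode == "auto":
        labeled = [s["id"] for s in subjects if hypnograms[s["id"]] is not None]
        if len(labeled) < 2:
            raise ParameterError(
                "auto staging needs >= 2 subjects with hypnograms to fit the "
                "baseline predictor"
            )
        predictor = baseline_predictor_train(
            [recordings[i] for i in labeled],
            [hypnograms[i] for i in labeled],
            seed=cfg["seed"],
        )

    summaries = []
    for s in subjects:
        sid = s["id"]
        hyp = hypnograms[sid] if mode == "expert" else None
        result = analyze_recording(
            recordings[sid], model,
            hypnogram=hyp,
            predictor=predictor if mode == "auto" else None,
            channels=cfg["channels"],
            allow_unstaged=(mode == "unstaged" and cfg["allow_unstaged"]),
        )
        if mode == "auto" and result["hypnogram"] is not None:
            write_hypnogram(result["hypnogram"], out_dir / f"{sid}_stages.csv")
        write_events(result["merged_events"], out_dir / f"{sid}_events.csv")
        result["records"].to_csv(out_dir / f"{sid}_spindles.csv", index=False)
        summary = result["summary"].copy()
        summary["subject"] = sid
        summary["group"] = s.get("group", "")
        summaries.append(summary)
    pooled = pd.concat(summaries, ignore_index=True)
    pooled.to_csv(out_dir / "summary.csv", index=False)

    groups = sorted({g for g in pooled["group"] if g})
    group_sizes = {g: pooled.loc[pooled["group"] == g, "subject"].nunique()
                   for g in groups}
    if len(groups) == 2 and all(n >= 2 for n in group_sizes.values()):
        ga = pooled[pooled["group"] == groups[0]]
        gb = pooled[pooled["group"] == groups[1]]
        # fold speed class into the metric name so each cell is one test
        def fold(df):
            df = df.copy()
            df["metric"] = df["speed_class"] + "_" + df["metric"]
            return df[["subject", "channel", "metric", "value"]]
        table = evl.compare_cohorts(fold(ga), fold(gb))
        table.to_csv(out_dir / "cohort_comparison.csv", index=False)
    return out_dir
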