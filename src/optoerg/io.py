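"""Sweep CSV reading/writing and YAML config loading.

Sweep files are UTF-8, LF-terminated CSVs with '.' decimals: a few ``#``
header lines carrying acquisition metadata, then long-format columns
``sweep_id,time_ms,voltage_uV``::

    # sample_rate_hz=2000
    # pre_stimulus_ms=20
    # channel=ERG
    # stimulus={"flash_energy": 100.0, "background_luminance": 30.0, ...}
    # trial_onset_times_s=0,0.987,1.974
    sweep_id,time_ms,voltage_uV
    0,-20.0,1.234
    ...
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .photometry import StimulusSpec
from .preprocessing import Channel, SweepSet


def _stimulus_to_json(stim: StimulusSpec) -> str:
    d = asdict(stim)
    d["adaptation"] = stim.adaptation.value
    return json.dumps(d, sort_keys=True)


def write_sweepset_csv(sweepset: SweepSet, path: str | Path) -> Path:
    """Write one recording to the sweep CSV dialect."""
    path = Path(path)
    t_ms = (
        np.arange(sweepset.sweeps.shape[1]) / sweepset.sample_rate * 1000.0
        - sweepset.pre_stimulus_ms
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sample_rate_hz={sweepset.sample_rate:g}\n")
        fh.write(f"# pre_stimulus_ms={sweepset.pre_stimulus_ms:g}\n")
        fh.write(f"# channel={sweepset.channel.value}\n")
        fh.write(f"# stimulus={_stimulus_to_json(sweepset.stimulus)}\n")
        if sweepset.trial_onset_times_s:
            onsets = ",".join(f"{o:.6g}" for o in sweepset.trial_onset_times_s)
            fh.write(f"# trial_onset_times_s={onsets}\n")
        fh.write("sweep_id,time_ms,voltage_uV\n")
        for k, sweep in enumerate(sweepset.sweeps):
            for t, v in zip(t_ms, sweep):
                fh.write(f"{k},{t:.6g},{v:.9g}\n")
    return path


def read_sweepset_csv(path: str | Path) -> SweepSet:
    """Read a sweep CSV back into a :class:`SweepSet`."""
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
    required = {"sample_rate_hz", "pre_stimulus_ms", "channel", "stimulus"}
    missing = required - header.keys()
    if missing:
        raise DomainError(f"{path}: missing header keys {sorted(missing)}")

    body = pd.read_csv(path, skiprows=n_header)
    expected_cols = ["sweep_id", "time_ms", "voltage_uV"]
    if list(body.columns) != expected_cols:
        raise DomainError(f"{path}: expected columns {expected_cols}")

    stim_dict = json.loads(header["stimulus"])
    stimulus = StimulusSpec(**stim_dict)
    sweep_ids = sorted(body["sweep_id"].unique())
    sweeps = np.stack(
        [body.loc[body["sweep_id"] == sid, "voltage_uV"].to_numpy() for sid in sweep_ids]
    )
    onsets: tuple[float, ...] = ()
    if "trial_onset_times_s" in header and header["trial_onset_times_s"]:
        onsets = tuple(float(x) for x in header["trial_onset_times_s"].split(","))
    return SweepSet(
        sweeps=sweeps,
        stimulus=stimulus,
        channel=Channel(header["channel"]),
        sample_rate=float(header["sample_rate_hz"]),
        pre_stimulus_ms=float(header["pre_stimulus_ms"]),
        trial_onset_times_s=onsets,
    )


def load_config_dict(path: str | Path) -> dict:
    """Load a YAML pipeline config into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise DomainError(f"{path}: config must be a mapping")
    return data
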