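"""Time-aligned multimodal recording session container and HDF5 layout.

Layout on disk::

    /raw/<channel>          1-D float datasets, each with an ``fs`` attribute
    /events/{onset_s,type,duration_s,side}
    /vessels/frames         optional (n, h, w) stack with fs / pixel size attrs
    root attrs              JSON-encoded session metadata

Channel naming: reflectance_{530,480,630}_{L,R}, fluorescence_{L,R},
lfp_cortexL, lfp_cortexR, lfp_hipp, emg, whisker, force.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import ParameterError

EVENT_COLUMNS = ["onset_s", "type", "duration_s", "side"]


@dataclass
class RecordingSession:
    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    meta: dict = field(default_factory=dict)
    vessel_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in self.channels:
            if name not in self.rates:
                raise ParameterError(f"channel {name!r} has no sampling rate")
            self.channels[name] = np.asarray(self.channels[name], dtype=float)

    def fs(self, name: str) -> float:
        return self.rates[name]

    def duration_s(self) -> float:
        name = next(iter(self.channels))
        return self.channels[name].size / self.rates[name]

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            raw = fh.create_group("raw")
            for name, data in self.channels.items():
                ds = raw.create_dataset(name, data=data)
                ds.attrs["fs"] = self.rates[name]
            ev = fh.create_group("events")
            ev.create_dataset("onset_s", data=np.asarray(self.events["onset_s"], dtype=float))
            ev.create_dataset("duration_s", data=np.asarray(self.events["duration_s"], dtype=float))
            str_dt = h5py.string_dtype()
            ev.create_dataset("type", data=np.asarray(self.events["type"], dtype=object), dtype=str_dt)
            ev.create_dataset("side", data=np.asarray(self.events["side"], dtype=object), dtype=str_dt)
            if self.vessel_frames is not None:
                vg = fh.create_group("vessels")
                vg.create_dataset("frames", data=self.vessel_frames)
            fh.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "RecordingSession":
        with h5py.File(path, "r") as fh:
            channels, rates = {}, {}
            for name, ds in fh["raw"].items():
                channels[name] = ds[()]
                rates[name] = float(ds.attrs["fs"])
            ev = fh["events"]
            events = pd.DataFrame(
                {
                    "onset_s": ev["onset_s"][()],
                    "type": [s.decode() if isinstance(s, bytes) else s for s in ev["type"][()]],
                    "duration_s": ev["duration_s"][()],
                    "side": [s.decode() if isinstance(s, bytes) else s for s in ev["side"][()]],
                }
            )
            vessel_frames = fh["vessels/frames"][()] if "vessels" in fh else None
            meta = json.loads(fh.attrs.get("meta", "{}"))
        return cls(channels=channels, rates=rates, events=events, meta=meta, vessel_frames=vessel_frames)

    def events_to_csv(self, path) -> None:
        self.events[EVENT_COLUMNS].to_csv(path, index=False)

    def stim_onsets(self, types=("stim_contra", "stim_ipsi")) -> np.ndarray:
        sel = self.events["type"].isin(types)
        return np.asarray(self.events.loc[sel, "onset_s"], dtype=float)


def write_group(path, group: str, arrays: dict[str, np.ndarray], attrs: dict | None = None) -> None:
    """Write derived arrays (e.g. /hemo, /arousal, /spectral) into a session file."""
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for name, data in arrays.items():
            g.create_dataset(name, data=np.asarray(data))
        for key, val in (attrs or {}).items():
            g.attrs[key] = val


def read_group(path, group: str) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as fh:
        return {name: ds[()] for name, ds in fh[group].items()}
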