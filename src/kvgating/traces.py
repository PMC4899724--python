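"""Time-series containers for voltage-clamp recordings.

Two trace types cover the experiments analysed here: :class:`CurrentTrace`
for seconds-long ionic-current sweeps (C-type inactivation protocols) and
:class:`GatingTrace` for millisecond-resolved gating-current sweeps recorded
with conduction blocked.  Both serialize as a two-column CSV plus a JSON
sidecar holding the protocol metadata, so that files remain inspectable with
any spreadsheet tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CurrentTrace", "GatingTrace"]


def _validate_time_current(time: np.ndarray, current: np.ndarray, min_len: int) -> None:
    if time.ndim != 1 or current.ndim != 1:
        raise ValueError("time and current must be one-dimensional arrays")
    if len(time) != len(current):
        raise ValueError(
            f"time ({len(time)}) and current ({len(current)}) differ in length"
        )
    if len(time) < min_len:
        raise ValueError(f"trace needs at least {min_len} samples, got {len(time)}")
    if not np.all(np.isfinite(time)) or not np.all(np.isfinite(current)):
        raise ValueError("trace contains non-finite samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class CurrentTrace:
    """A single ionic-current sweep at one step voltage.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing.
    current : ndarray
        Membrane current in microamperes, same length as ``time``.
    step_voltage : float
        Test-pulse voltage in mV.
    holding_voltage : float
        Pre-pulse holding voltage in mV.
    label : str
        Free-text condition tag (mutant name, drug, pH ...).
    """

    time: np.ndarray
    current: np.ndarray
    step_voltage: float
    holding_voltage: float = -80.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        _validate_time_current(self.time, self.current, min_len=10)
        if not np.isfinite(self.step_voltage):
            raise ValueError("step_voltage must be finite")

    def __len__(self) -> int:
        return len(self.time)

    def scaled(self, factor: float) -> "CurrentTrace":
        """Return a copy with the current multiplied by ``factor``."""
        return replace(self, current=self.current * factor)

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,current_uA`` CSV plus a ``.json`` metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"time_s": self.time, "current_uA": self.current}).to_csv(
            path, index=False
        )
        sidecar = {
            "step_voltage_mV": self.step_voltage,
            "holding_voltage_mV": self.holding_voltage,
            "label": self.label,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrentTrace":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            time=df["time_s"].to_numpy(),
            current=df["current_uA"].to_numpy(),
            step_voltage=meta["step_voltage_mV"],
            holding_voltage=meta.get("holding_voltage_mV", -80.0),
            label=meta.get("label", ""),
        )


@dataclass(frozen=True)
class GatingTrace:
    """A gating-current sweep; time in ms with 0 at pulse onset.

    Samples with negative times are pre-pulse baseline, samples beyond
    ``pulse_duration`` belong to the OFF (tail) phase at the holding voltage.
    """

    time: np.ndarray
    current: np.ndarray
    step_voltage: float
    holding_voltage: float
    pulse_duration: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        _validate_time_current(self.time, self.current, min_len=10)
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.time[-1] < self.pulse_duration:
            raise ValueError("trace must cover the full ON pulse")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def on_mask(self) -> np.ndarray:
        return (self.time >= 0) & (self.time <= self.pulse_duration)

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.time < 0

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"time_ms": self.time, "current_uA": self.current}).to_csv(
            path, index=False
        )
        sidecar = {
            "step_voltage_mV": self.step_voltage,
            "holding_voltage_mV": self.holding_voltage,
            "pulse_duration_ms": self.pulse_duration,
            "label": self.label,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "GatingTrace":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            time=df["time_ms"].to_numpy(),
            current=df["current_uA"].to_numpy(),
            step_voltage=meta["step_voltage_mV"],
            holding_voltage=meta["holding_voltage_mV"],
            pulse_duration=meta["pulse_duration_ms"],
            label=meta.get("label", ""),
        )
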