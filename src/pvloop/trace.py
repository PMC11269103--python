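"""Waveform trace container.

A :class:`WaveformTrace` is a thin wrapper over a pandas DataFrame with the
canonical column schema used throughout the package and written to CSV:

    time_s, p_lv_mmHg, v_lv_ml, q_mls, phase, preload_level_mmHg

``phase`` holds the integer codes 1-4 of :class:`pvloop.phases.Phase`;
``q_mls`` is the piston flow in cm^3/s, positive out of the ventricle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRACE_COLUMNS = ("time_s", "p_lv_mmHg", "v_lv_ml", "q_mls", "phase", "preload_level_mmHg")

VALID_PHASES = frozenset({1, 2, 3, 4})


@dataclass
class WaveformTrace:
    """Sampled pressure/volume/flow time series with phase labels."""

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(TRACE_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace is missing columns: {missing}")
        self.data = self.data.loc[:, list(TRACE_COLUMNS)].reset_index(drop=True)
        if len(self.data):
            self.data["phase"] = self.data["phase"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def pressure(self) -> np.ndarray:
        return self.data["p_lv_mmHg"].to_numpy()

    @property
    def volume(self) -> np.ndarray:
        return self.data["v_lv_ml"].to_numpy()

    @property
    def flow(self) -> np.ndarray:
        return self.data["q_mls"].to_numpy()

    @property
    def phase(self) -> np.ndarray:
        return self.data["phase"].to_numpy()

    @property
    def preload_level(self) -> np.ndarray:
        return self.data["preload_level_mmHg"].to_numpy()

    def levels(self) -> list[float]:
        """Distinct preload levels in order of first appearance."""
        seen: list[float] = []
        for v in self.data["preload_level_mmHg"]:
            if not seen or v != seen[-1]:
                if v not in seen:
                    seen.append(float(v))
        return seen

    def split_by_level(self) -> "list[WaveformTrace]":
        """One sub-trace per preload level, in protocol order."""
        return [
            WaveformTrace(self.data[self.data["preload_level_mmHg"] == lv])
            for lv in self.levels()
        ]

    def equals(self, other: "WaveformTrace") -> bool:
        return self.data.equals(other.data)


def trace_from_arrays(
    time_s: Sequence[float],
    p_lv_mmhg: Sequence[float],
    v_lv_ml: Sequence[float],
    q_mls: Sequence[float],
    phase: Sequence[int],
    preload_level_mmhg: Sequence[float],
) -> WaveformTrace:
    """Assemble a trace from parallel arrays."""
    return WaveformTrace(
        pd.DataFrame(
            {
                "time_s": np.asarray(time_s, dtype=float),
                "p_lv_mmHg": np.asarray(p_lv_mmhg, dtype=float),
                "v_lv_ml": np.asarray(v_lv_ml, dtype=float),
                "q_mls": np.asarray(q_mls, dtype=float),
                "phase": np.asarray(phase, dtype=np.int64),
                "preload_level_mmHg": np.asarray(preload_level_mmhg, dtype=float),
            }
        )
    )


def concat_traces(traces: Iterable[WaveformTrace]) -> WaveformTrace:
    """Concatenate traces in order (e.g. per-level traces of one ramp)."""
    frames = [t.data for t in traces if len(t)]
    if not frames:
        return WaveformTrace()
    return WaveformTrace(pd.concat(frames, ignore_index=True))
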