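"""Spike-train container shared by every stage of the pipeline.

A :class:`SpikeDataset` holds per-neuron event times (seconds) over a known
recording duration, together with an optional condition tag (e.g. one of the
pharmacological conditions ``CBX``/``CON``/``PIX``).  Event times are kept
sorted and strictly inside ``[0, duration]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeDataset"]


@dataclass
class SpikeDataset:
    """Per-neuron spike times with duration and labels.

    Parameters
    ----------
    trains : dict[int, np.ndarray]
        Mapping neuron id -> sorted array of spike times in seconds.
    duration : float
        Recording length in seconds.
    condition : str, optional
        Condition tag carried through analysis tables.
    meta : dict
        Free-form provenance (seed, generator parameters, ...).
    """

    trains: dict[int, np.ndarray]
    duration: float
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean: dict[int, np.ndarray] = {}
        for nid, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(
                    f"neuron {nid}: spike times outside [0, {self.duration}]"
                )
            clean[int(nid)] = np.sort(t)
        self.trains = clean

    # -- basic accessors -------------------------------------------------
    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    def __getitem__(self, neuron_id: int) -> np.ndarray:
        return self.trains[neuron_id]

    def rates(self) -> dict[int, float]:
        """Mean firing rate (spikes/s) per neuron."""
        return {i: len(t) / self.duration for i, t in self.trains.items()}

    def mean_rate(self) -> float:
        """Population mean firing rate in spikes/s."""
        return float(np.mean([len(t) for t in self.trains.values()])) / self.duration

    # -- slicing ---------------------------------------------------------
    def window(self, start: float, stop: float, rezero: bool = True) -> "SpikeDataset":
        """Return the sub-dataset of spikes in ``[start, stop)``."""
        if not 0 <= start < stop <= self.duration + 1e-9:
            raise ValueError(f"bad window [{start}, {stop}) for duration {self.duration}")
        out = {}
        for nid, t in self.trains.items():
            sel = t[(t >= start) & (t < stop)]
            out[nid] = sel - start if rezero else sel
        return SpikeDataset(out, stop - start, condition=self.condition, meta=dict(self.meta))

    def subset(self, neuron_ids) -> "SpikeDataset":
        out = {int(i): self.trains[int(i)] for i in neuron_ids}
        return SpikeDataset(out, self.duration, condition=self.condition, meta=dict(self.meta))

    # -- tabular form ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Two-column table (neuron_id, spike_time_s), sorted by id then time."""
        ids, times = [], []
        for nid in self.neuron_ids:
            t = self.trains[nid]
            ids.extend([nid] * len(t))
            times.extend(t.tolist())
        return pd.DataFrame({"neuron_id": ids, "spike_time_s": times})
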