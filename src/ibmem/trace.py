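"""Uniformly-sampled scalar time series (receptor displacement/separation)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """times [s] (uniform), values [nm], free-form metadata."""

    times: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=0):
                raise ValueError("trace sampling must be uniform")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("trace contains non-finite entries")

    @property
    def dt(self) -> float:
        """Sampling interval [s]."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.times)
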