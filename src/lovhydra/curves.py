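"""Lightweight containers for 1-D experimental series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

import numpy as np
import pandas as pd


@dataclass
class RecoveryCurve:
    """Amplitude versus time (or versus recovery delay).

    Used for inversion-recovery series (``time_unit="ms"``), photocycle
    absorbance traces (``"s"``) and water-population kinetics (``"min"``).
    ``meta`` carries generator ground truth or fit provenance.
    """

    time: np.ndarray
    amplitude: np.ndarray
    time_unit: str = "ms"
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.shape != self.amplitude.shape or self.time.ndim != 1:
            raise ValueError("time and amplitude must be matching 1-D arrays")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"time_{self.time_unit}": self.time,
                             "amplitude": self.amplitude})
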