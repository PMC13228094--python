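"""Vertex-wise time-series container with frame censoring."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VertexTimeSeries:
    """A vertices x frames signal matrix with a per-frame censor mask.

    ``censor_mask`` is True for retained frames (the convention used by
    motion censoring: frames flagged for excessive framewise displacement are
    False and excluded from all correlation and regression fits).
    ``tr`` is the frame duration in seconds (default 0.8 s).
    """

    data: np.ndarray
    censor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    tr: float = 0.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be vertices x frames")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.data.shape[1], dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (self.data.shape[1],):
            raise ValueError("censor_mask length must equal the frame count")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.censor_mask.sum())

    def retained(self) -> np.ndarray:
        """Signal restricted to retained frames (vertices x retained)."""
        return self.data[:, self.censor_mask]
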