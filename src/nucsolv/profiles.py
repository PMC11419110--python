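"""The ScatteringProfile container: (q, I, σ) triplets plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatteringProfile"]


@dataclass
class ScatteringProfile:
    """A reduced 1-D scattering profile.

    q      scattering vector, Å⁻¹, strictly increasing, non-negative
    I      intensity, arbitrary units (negatives allowed: background
           subtraction legitimately produces them)
    sigma  1-σ uncertainty of I, same units; None when the source had none
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.size < 3:
            raise ValueError("profile needs at least 3 points")
        if self.I.shape != self.q.shape:
            raise ValueError("q and I must have equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q in length")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return self.q.size

    def require_sigma(self) -> np.ndarray:
        if self.sigma is None:
            raise ValueError(
                "this operation needs uncertainties but the profile has none"
            )
        return self.sigma

    def trim(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringProfile":
        keep = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringProfile(
            q=self.q[keep],
            I=self.I[keep],
            sigma=None if self.sigma is None else self.sigma[keep],
            metadata=dict(self.metadata),
        )
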