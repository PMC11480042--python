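"""Shared predictive-output container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PredictiveDistribution:
    """Per-example class probabilities, plus latent Gaussian moments where the
    model provides them (the GP does; the baselines leave them ``None``)."""

    probs: np.ndarray  # n x C rows on the simplex
    latent_means: np.ndarray | None = None
    latent_variances: np.ndarray | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be an n x C matrix")
        rows = self.probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9) or np.any(self.probs < -1e-12):
            raise ValueError("probability rows must lie on the simplex within 1e-9")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def num_classes(self) -> int:
        return self.probs.shape[1]
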