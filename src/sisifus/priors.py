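"""Shared container for high-resolution lifetime priors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


@dataclass
class PriorImage:
    """High-resolution lifetime estimate (ns) with a per-pixel validity mask.

    Invalid pixels contribute nothing to the inverse-retrieval fidelity
    terms (their mask entry multiplies the corresponding residual).
    """

    values: np.ndarray
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("prior must be 2-D")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("validity mask must match prior shape")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "PriorImage":
        """An all-invalid prior: its fidelity term drops out of the solver."""
        return cls(values=np.zeros(shape), valid=np.zeros(shape, dtype=bool))
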