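"""Frame-rate reduction (FRR).

Dose scales with the number of frames acquired, so dropping frames from an
already-acquired series simulates a lower-dose acquisition.  The three
experimental levels keep every 2nd, 3rd, or 4th frame (nominal 50%, 66%,
and 75% reductions), always retaining frame 0 so the pre-arrival baseline
is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FrameStack
from .model import TimeGrid

__all__ = ["FrrScheme", "FrameRateReducer", "reduce", "retained_fraction"]


@dataclass(frozen=True)
class FrrScheme:
    """A frame-rate-reduction level and its keep stride.

    ``FRR50`` keeps every 2nd frame, ``FRR66`` every 3rd, ``FRR75`` every
    4th, always starting at frame 0.
    """

    level: str

    _STRIDES = {"FRR50": 2, "FRR66": 3, "FRR75": 4}

    def __post_init__(self) -> None:
        if self.level not in self._STRIDES:
            raise ValueError(
                f"level must be one of {sorted(self._STRIDES)}, got {self.level!r}"
            )

    @property
    def keep_stride(self) -> int:
        return self._STRIDES[self.level]

    @property
    def nominal_reduction(self) -> float:
        """Nominal fraction of frames dropped (0.5, 2/3, 0.75)."""
        return 1.0 - 1.0 / self.keep_stride

    @classmethod
    def from_percent(cls, percent: int | str) -> "FrrScheme":
        """Build a scheme from the CLI-facing percentage label (50, 66, 75)."""
        label = str(percent)
        if label not in {"50", "66", "75"}:
            raise ValueError(f"unsupported FRR level {percent!r}; expected 50, 66 or 75")
        return cls(f"FRR{label}")


class FrameRateReducer(BaseEstimator, TransformerMixin):
    """Stateless transformer that drops frames at a fixed stride.

    Parameters
    ----------
    level : {"FRR50", "FRR66", "FRR75"} or {50, 66, 75}
        Reduction level; keeps every 2nd / 3rd / 4th frame respectively.

    Attributes
    ----------
    retained_indices_ : ndarray of int
        Original-stack frame indices kept by the last :meth:`transform`.
    original_grid_ : TimeGrid
        Grid of the last input stack.
    """

    def __init__(self, level="FRR50"):
        self.level = level

    def _scheme(self) -> FrrScheme:
        if isinstance(self.level, FrrScheme):
            return self.level
        if isinstance(self.level, str) and self.level.startswith("FRR"):
            return FrrScheme(self.level)
        return FrrScheme.from_percent(self.level)

    def fit(self, X: FrameStack, y=None) -> "FrameRateReducer":
        self._scheme()  # validate the level eagerly
        return self

    def transform(self, X: FrameStack) -> FrameStack:
        scheme = self._scheme()
        stride = scheme.keep_stride
        indices = np.arange(0, X.n_frames, stride)
        grid = TimeGrid(len(indices), X.grid.frame_rate / stride, X.grid.origin)
        self.retained_indices_ = indices
        self.original_grid_ = X.grid
        return FrameStack(
            X.voxels[indices].copy(), grid, X.polarity,
            f"{X.source_id}|{scheme.level}",
        )


def reduce(stack: FrameStack, scheme: FrrScheme) -> tuple[FrameStack, np.ndarray]:
    """Drop frames from ``stack`` per ``scheme``; the input is unmodified.

    Returns
    -------
    reduced : FrameStack
        Retained frames in order, with frame rate divided by the stride.
    retained_indices : ndarray of int
        ``{0, s, 2s, ...}`` for stride ``s``.
    """
    reducer = FrameRateReducer(level=scheme)
    reduced = reducer.fit(stack).transform(stack)
    return reduced, reducer.retained_indices_


def retained_fraction(scheme: FrrScheme, n_frames: int) -> float:
    """Achieved retained fraction ``|kept| / n_frames`` for a finite series."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    kept = len(range(0, n_frames, scheme.keep_stride))
    return kept / n_frames
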