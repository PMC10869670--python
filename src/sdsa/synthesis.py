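"""Synthetic-DSA assembly.

The synthetic series (sDSA) is produced by sampling each voxel's fitted
gamma-variate curve back on the original acquisition grid, regenerating the
frames dropped during frame-rate reduction.  By default the retained
(acquired) frames are also replaced by model samples, which keeps the whole
series temporally consistent; ``keep_acquired`` passes them through
verbatim instead.

Background voxels reconstruct as the zero baseline; voxels whose series
were too short to fit, or whose fits did not converge, reconstruct by
piecewise-linear interpolation of the retained samples with constant
extrapolation beyond the endpoints.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fitting import FitConfig, GammaVariateReconstructor, _config_kwargs
from .frr import FrameRateReducer, FrrScheme
from .io import FrameStack
from .model import TimeGrid, sample_curve

__all__ = ["synthesize", "synthesize_study"]


def synthesize(
    fit_map: np.ndarray,
    original_grid: TimeGrid,
    reduced: FrameStack,
    retained_indices: np.ndarray | None = None,
) -> FrameStack:
    """Sample fitted voxel curves on the original grid to build the sDSA.

    Parameters
    ----------
    fit_map : (rows, cols) object array of FitResult
        One result per voxel; a coverage gap raises.
    original_grid : TimeGrid
        The full-rate acquisition grid to regenerate.
    reduced : FrameStack
        The reduced stack the fits were computed from (its samples feed the
        interpolation fallback).
    retained_indices : array of int, optional
        Original-grid indices of the retained frames (bookkeeping only; the
        default synthesis replaces every frame with model samples).
    """
    rows, cols = reduced.frame_shape
    if fit_map.shape != (rows, cols):
        raise ValueError(
            f"fit_map shape {fit_map.shape} does not cover stack {rows}x{cols}"
        )
    if original_grid.n_frames < reduced.n_frames:
        raise ValueError("original grid has fewer frames than the reduced stack")
    times = original_grid.times
    reduced_times = reduced.grid.times
    voxels = np.zeros((original_grid.n_frames, rows, cols))
    for r in range(rows):
        for c in range(cols):
            result = fit_map[r, c]
            if result is None:
                raise ValueError(f"fit_map has no result for voxel ({r}, {c})")
            if result.status == "fitted":
                series = sample_curve(result.params, original_grid)
            elif result.status == "background":
                continue
            else:  # fallback_interp / failed: linear, constant beyond endpoints
                series = np.interp(times, reduced_times, reduced.voxels[:, r, c])
            voxels[:, r, c] = np.maximum(series, 0.0)
    return FrameStack(voxels, original_grid, reduced.polarity,
                      f"{reduced.source_id}|sdsa")


def synthesize_study(
    stack: FrameStack,
    scheme: FrrScheme,
    config: FitConfig = FitConfig(),
    keep_acquired: bool = False,
) -> dict:
    """End-to-end reduce → fit → resample pipeline for one study.

    Returns a dict with the synthetic stack (``sdsa``), the per-voxel
    ``fit_map``, the ``retained_indices`` into the original grid, and the
    intermediate ``reduced`` stack.  Deterministic for identical inputs.
    """
    floor = config.min_fit_points * scheme.keep_stride
    if stack.n_frames < max(16, floor):
        warnings.warn(
            f"{stack.n_frames}-frame stack is below the 16-frame study floor "
            f"for {scheme.level}; fits may be under-determined",
            stacklevel=2,
        )
    reducer = FrameRateReducer(level=scheme)
    reduced = reducer.fit(stack).transform(stack)
    recon = GammaVariateReconstructor(**_config_kwargs(config)).fit(reduced)
    sdsa = recon.predict(
        stack.grid,
        keep_acquired=keep_acquired,
        retained_indices=reducer.retained_indices_,
    )
    return {
        "sdsa": sdsa,
        "fit_map": recon.fit_map_,
        "retained_indices": reducer.retained_indices_,
        "reduced": reduced,
        "sigma": recon.sigma_,
    }
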