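"""Fidelity evaluation of synthetic angiograms.

The per-voxel, per-frame figure of merit is the relative signal-intensity
error

    R(t) = |SI_o(t) - SI_s(t)| / SI_o(t)

between the original (``o``) and synthetic (``s``) series, defined only
where the original intensity exceeds a small guard ``epsilon`` (the metric
is singular at zero signal, so near-zero voxels are masked rather than
divided).  Per voxel the error is time-averaged over its defined frames;
study-level summaries are the mean and standard deviation over valid
voxels, reported in percent.

Heatmaps follow the green-to-red display convention: green at or below 3%
error, red at or above 15%, masked voxels neutral gray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, Normalize

from .fitting import status_census
from .io import FrameStack

__all__ = ["ErrorMap", "voxel_error", "error_map", "render_heatmap",
           "study_report", "default_epsilon"]

#: Fraction of the stack's dynamic range below which the relative-error
#: denominator is considered noise-dominated regardless of the noise level.
EPSILON_REL_FLOOR = 0.01

#: Display convention: green at <= 3% error, red at >= 15% (values clipped).
HEATMAP_GREEN_BELOW = 0.03
HEATMAP_RED_ABOVE = 0.15
_NEUTRAL_GRAY = (0.6, 0.6, 0.6, 1.0)

_CMAP = LinearSegmentedColormap.from_list(
    "sdsa_error", [(0.0, 0.65, 0.0), (1.0, 0.85, 0.0), (0.8, 0.0, 0.0)]
)


@dataclass
class ErrorMap:
    """Per-voxel time-averaged relative error with a validity mask."""

    per_voxel_error: np.ndarray
    valid_mask: np.ndarray

    @property
    def summary(self) -> dict:
        """Mean/sd (fractions) over valid voxels, plus counts."""
        valid = self.per_voxel_error[self.valid_mask]
        n = int(valid.size)
        return {
            "mean": float(valid.mean()) if n else float("nan"),
            "sd": float(valid.std(ddof=1)) if n > 1 else float("nan"),
            "n_valid": n,
            "n_masked": int(self.valid_mask.size - n),
        }


def default_epsilon(original: FrameStack) -> float:
    """Default denominator guard for the relative-error metric.

    ``max(3 * sigma, 0.01 * max intensity)``: the background threshold when
    noise dominates, floored at 1% of the study's dynamic range — a ratio
    against an intensity below that floor is meaningless even in a
    noise-free series (the denominator vanishes just after contrast
    arrival).
    """
    from .fitting import estimate_noise

    sigma = estimate_noise(original) if original.n_frames >= 2 else 0.0
    return max(3.0 * sigma, EPSILON_REL_FLOOR * float(original.voxels.max()))


def voxel_error(si_original: float, si_synthetic: float, epsilon: float) -> float:
    """Relative intensity error at one voxel and frame.

    Returns ``nan`` (masked) when the original intensity does not exceed
    ``epsilon``, where the ratio is undefined or noise-dominated.
    """
    if not (np.isfinite(si_original) and np.isfinite(si_synthetic)):
        raise ValueError("intensities must be finite")
    if si_original <= epsilon:
        return float("nan")
    return abs(si_original - si_synthetic) / si_original


def error_map(original: FrameStack, sdsa: FrameStack, epsilon: float) -> ErrorMap:
    """Time-averaged relative error per voxel between two aligned stacks.

    A voxel is valid if the metric is defined on at least one frame; its
    value is the arithmetic mean over the defined frames.
    """
    if original.voxels.shape != sdsa.voxels.shape:
        raise ValueError(
            f"shape mismatch: {original.voxels.shape} vs {sdsa.voxels.shape}"
        )
    o = original.voxels
    s = sdsa.voxels
    defined = o > epsilon
    with np.errstate(invalid="ignore", divide="ignore"):
        err = np.where(defined, np.abs(o - s) / np.where(defined, o, 1.0), np.nan)
    n_defined = defined.sum(axis=0)
    valid = n_defined > 0
    with np.errstate(invalid="ignore"):
        mean_err = np.nansum(err, axis=0) / np.where(valid, n_defined, 1)
    mean_err = np.where(valid, mean_err, np.nan)
    return ErrorMap(per_voxel_error=mean_err, valid_mask=valid)


def render_heatmap(emap: ErrorMap, path) -> None:
    """Write a PNG error heatmap using the green (<=3%) to red (>=15%) scale."""
    norm = Normalize(vmin=HEATMAP_GREEN_BELOW, vmax=HEATMAP_RED_ABOVE, clip=True)
    values = np.where(emap.valid_mask, emap.per_voxel_error, HEATMAP_GREEN_BELOW)
    rgba = _CMAP(norm(values))
    rgba[~emap.valid_mask] = _NEUTRAL_GRAY
    plt.imsave(path, rgba)


def study_report(
    original: FrameStack,
    sdsa_by_scheme: dict,
    epsilon: float,
    fit_maps: dict | None = None,
) -> pd.DataFrame:
    """Per-scheme fidelity summary table.

    Parameters
    ----------
    original : FrameStack
        Ground-truth full-rate stack.
    sdsa_by_scheme : dict of level -> FrameStack
        Synthetic stacks aligned frame-for-frame with ``original``.
    epsilon : float
        Denominator guard for the error metric.
    fit_maps : dict of level -> FitResult map, optional
        When given, the per-scheme fit-status census is appended.

    Returns
    -------
    pandas.DataFrame
        One row per scheme: mean/sd error in percent, valid-voxel count,
        and the fit-status census.
    """
    rows = []
    for level, sdsa in sdsa_by_scheme.items():
        emap = error_map(original, sdsa, epsilon)
        summary = emap.summary
        row = {
            "scheme": level,
            "mean_error_pct": 100.0 * summary["mean"],
            "sd_error_pct": 100.0 * summary["sd"],
            "n_valid_voxels": summary["n_valid"],
        }
        if fit_maps is not None and level in fit_maps:
            row.update(
                {f"n_{k}": v for k, v in status_census(fit_maps[level]).items()}
            )
        rows.append(row)
    return pd.DataFrame(rows)
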