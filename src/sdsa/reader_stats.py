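"""Reader-study statistics.

Diagnostic quality of synthetic angiograms is graded against the original
study on a four-item rubric — arterial phase, capillary phase, venous
phase, and overall image quality, each 1–5 — whose sum gives a composite
score in [4, 20].  This module implements the composite scoring, Kendall's
coefficient of concordance W (mid-rank tie correction, chi-square p-value),
the coefficient of variation, the per-reader/per-reduction-level summary
table, and the two-sample sample-size calculation used to power such a
study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReaderScore",
    "composite_score",
    "kendalls_w",
    "coefficient_of_variation",
    "sample_size_two_means",
    "score_table_summary",
    "read_scores_csv",
]

_SUBSCALES = ("arterial", "capillary", "venous", "overall_quality")


@dataclass(frozen=True)
class ReaderScore:
    """One rater's rubric sub-scores for one study at one reduction level."""

    reader_id: str
    study_id: str
    frr_level: str
    arterial: int
    capillary: int
    venous: int
    overall_quality: int

    def __post_init__(self) -> None:
        for name in _SUBSCALES:
            value = getattr(self, name)
            if value not in {1, 2, 3, 4, 5}:
                raise ValueError(f"{name} sub-score must be in 1..5, got {value}")

    @property
    def composite(self) -> int:
        """Sum of the four sub-scores; ranges from 4 to 20."""
        return sum(getattr(self, name) for name in _SUBSCALES)


def composite_score(score: ReaderScore) -> int:
    """Composite rubric score (sum of the four 1–5 items), in [4, 20]."""
    return score.composite


def kendalls_w(ratings: np.ndarray) -> dict:
    """Kendall's coefficient of concordance for an m-raters x n-subjects matrix.

    Uses mid-ranks within each rater (ordinal rubric scores are heavily
    tied) and the standard tie correction:

        W = 12 S / (m^2 (n^3 - n) - m T),

    with S the sum of squared deviations of subject rank sums and
    T = sum over raters of sum(t^3 - t) over tie groups.  The p-value is
    from the chi-square approximation chi2 = m (n - 1) W on n - 1 degrees
    of freedom.

    Raises if every rater scores all subjects identically (W undefined).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D (raters x subjects) matrix")
    m, n = ratings.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 subjects")

    ranks = np.apply_along_axis(stats.rankdata, 1, ratings)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())

    tie_term = 0.0
    for row in ratings:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())

    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise ValueError("W undefined: all raters gave constant ratings")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return {"W": float(w), "p": p, "chi2": float(chi2), "df": n - 1}


def coefficient_of_variation(values) -> float:
    """Coefficient of variation: 100 * sample standard deviation / mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return float(100.0 * sd / mean)


def _power_two_sample(n: int, effect: float, pooled_sd: float, alpha: float) -> float:
    """Power of a two-sided two-sample t-test with n per group (noncentral t)."""
    df = 2 * n - 2
    nc = effect / pooled_sd * np.sqrt(n / 2.0)
    crit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def sample_size_two_means(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.75,
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    Pooled-variance formulation: effect ``|mean1 - mean2|``, pooled sd
    ``sqrt((sd1^2 + sd2^2) / 2)``, power from the noncentral t distribution
    at ``df = 2n - 2``.  Returns n per group, floored at 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    effect = abs(mean1 - mean2)
    if effect == 0:
        raise ValueError("zero effect size: no finite sample size reaches power")
    pooled_sd = float(np.sqrt((sd1**2 + sd2**2) / 2.0))
    for n in range(2, n_max + 1):
        if _power_two_sample(n, effect, pooled_sd, alpha) >= power:
            return n
    raise ValueError(f"required n exceeds {n_max}")


def read_scores_csv(path) -> list[ReaderScore]:
    """Load reader scores from CSV (reader_id, study_id, frr, four items)."""
    df = pd.read_csv(path)
    frr_col = "frr_level" if "frr_level" in df.columns else "frr"
    return [
        ReaderScore(
            reader_id=str(row["reader_id"]),
            study_id=str(row["study_id"]),
            frr_level=str(row[frr_col]),
            arterial=int(row["arterial"]),
            capillary=int(row["capillary"]),
            venous=int(row["venous"]),
            overall_quality=int(row["overall_quality"]),
        )
        for _, row in df.iterrows()
    ]


def score_table_summary(scores) -> pd.DataFrame:
    """Composite-score summary by reduction level and reader.

    For each (frr_level, reader) group and each per-level total: n, mean,
    sample sd, range, and the 95% t confidence interval
    ``mean ± t(0.975, n-1) * sd / sqrt(n)``.  Groups of size 1 leave sd and
    the CI blank.
    """
    if not scores:
        raise ValueError("no scores given")
    df = pd.DataFrame(
        {
            "frr_level": s.frr_level,
            "reader_id": s.reader_id,
            "composite": s.composite,
        }
        for s in scores
    )

    def _summarize(group: pd.Series) -> dict:
        n = int(group.size)
        mean = float(group.mean())
        if n > 1:
            sd = float(group.std(ddof=1))
            half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
            ci_low, ci_high = mean - half, mean + half
        else:
            sd = ci_low = ci_high = float("nan")
        return {
            "n": n,
            "mean": mean,
            "sd": sd,
            "min": float(group.min()),
            "max": float(group.max()),
            "ci95_low": ci_low,
            "ci95_high": ci_high,
        }

    rows = []
    for (level, reader), group in sorted(
        df.groupby(["frr_level", "reader_id"])["composite"]
    ):
        rows.append({"frr_level": level, "reader_id": reader, **_summarize(group)})
    for level, group in sorted(df.groupby("frr_level")["composite"]):
        rows.append({"frr_level": level, "reader_id": "all", **_summarize(group)})
    return pd.DataFrame(rows)
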