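"""Cohort validation statistics: means ± SD, Student-t confidence
intervals and the vaginal-opening vs first-ovulation correlation.

Cohorts in this setting are small (tens of animals), so confidence
intervals use the Student t distribution with ``df = n − 1`` rather than
normal quantiles.  The VO–FO association is summarized by the squared
Pearson correlation (coefficient of determination R²) with the two-sided
p-value from the standard t transform of r.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import estimate_first_ovulation_age
from .types import PubScoreResult, ScoreStatus

logger = logging.getLogger(__name__)


def t_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided t confidence interval ``mean ± t_{df=n−1} · sd/√n``."""
    if n < 2:
        raise ValueError(f"confidence interval needs n >= 2, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    half = stats.t.ppf((1 + level) / 2, df=n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


@dataclass
class CohortSummary:
    """Cohort-level summary: VO age, estimated FO age, elapsed VO→FO time
    (all mean ± SD with t confidence intervals) and the VO–FO R²."""

    n: int
    n_excluded: int
    proportion_ovulating: float
    ci_level: float
    vo_mean: float
    vo_sd: float
    vo_ci: tuple[float, float]
    fo_mean: float
    fo_sd: float
    fo_ci: tuple[float, float]
    elapsed_mean: float
    elapsed_sd: float
    elapsed_ci: tuple[float, float]
    r2: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        """One-row table in the conventional layout (values to full precision)."""
        return pd.DataFrame(
            [
                {
                    "n": self.n,
                    "n_excluded": self.n_excluded,
                    "proportion_ovulating": self.proportion_ovulating,
                    "ci_level": self.ci_level,
                    "vo_mean": self.vo_mean,
                    "vo_sd": self.vo_sd,
                    "vo_ci_lo": self.vo_ci[0],
                    "vo_ci_hi": self.vo_ci[1],
                    "fo_mean": self.fo_mean,
                    "fo_sd": self.fo_sd,
                    "fo_ci_lo": self.fo_ci[0],
                    "fo_ci_hi": self.fo_ci[1],
                    "elapsed_mean": self.elapsed_mean,
                    "elapsed_sd": self.elapsed_sd,
                    "elapsed_ci_lo": self.elapsed_ci[0],
                    "elapsed_ci_hi": self.elapsed_ci[1],
                    "r2": self.r2,
                    "p_value": self.p_value,
                }
            ]
        )

    def to_text(self) -> str:
        """Human-readable summary rounded to one decimal, as usually printed."""
        pct = int(round(self.ci_level * 100))

        def row(label, m, s, ci):
            return f"{label}: {m:.1f} ± {s:.1f}  {pct}% CI ({ci[0]:.1f}–{ci[1]:.1f})"

        lines = [
            f"n = {self.n} ovulating ({self.n_excluded} excluded; "
            f"{100 * self.proportion_ovulating:.0f}% ovulating)",
            row("VO age (PND)", self.vo_mean, self.vo_sd, self.vo_ci),
            row("FO age (PND)", self.fo_mean, self.fo_sd, self.fo_ci),
            row("Time elapsed VO→FO (days)", self.elapsed_mean, self.elapsed_sd, self.elapsed_ci),
            f"R² (VO vs FO) = {self.r2:.2f} (p = {self.p_value:.3g})",
        ]
        return "\n".join(lines)


def summarize_cohort(
    records: Iterable[tuple[int, PubScoreResult, int]],
    level: float = 0.95,
) -> CohortSummary:
    """Summarize a scored cohort.

    ``records`` holds ``(vo_age_pnd, result, sacrifice_age_pnd)`` per
    animal.  Non-ovulating (prepubertal), censored and inconsistent
    animals are excluded from the FO statistics (with a logged count) but
    enter the ovulating proportion.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    vo_ages: list[float] = []
    fo_ages: list[float] = []
    n_excluded = 0
    for vo_age, result, sacrifice_age in records:
        if result.status is not ScoreStatus.OVULATING or vo_age is None:
            n_excluded += 1
            continue
        fo = result.estimated_fo_age_pnd
        if fo is None:  # defensive; PubScoreResult guarantees presence
            fo = estimate_first_ovulation_age(sacrifice_age, result.score)
        vo_ages.append(float(vo_age))
        fo_ages.append(float(fo))
    if n_excluded:
        logger.warning(
            "excluded %d of %d animals from FO statistics (non-ovulating, censored "
            "or inconsistent)",
            n_excluded,
            len(records),
        )
    n = len(vo_ages)
    if n < 3:
        raise ValueError(f"need at least 3 ovulating animals with a VO age, got {n}")
    vo = np.asarray(vo_ages)
    fo = np.asarray(fo_ages)
    elapsed = fo - vo

    def block(x: np.ndarray) -> tuple[float, float, tuple[float, float]]:
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        return m, s, t_confidence_interval(m, s, n, level)

    vo_mean, vo_sd, vo_ci = block(vo)
    fo_mean, fo_sd, fo_ci = block(fo)
    el_mean, el_sd, el_ci = block(elapsed)
    r2, p = pearson_r2(vo, fo)
    return CohortSummary(
        n=n,
        n_excluded=n_excluded,
        proportion_ovulating=sum(
            1 for _, r, _ in records if r.status in (ScoreStatus.OVULATING, ScoreStatus.CENSORED)
        )
        / len(records),
        ci_level=level,
        vo_mean=vo_mean,
        vo_sd=vo_sd,
        vo_ci=vo_ci,
        fo_mean=fo_mean,
        fo_sd=fo_sd,
        fo_ci=fo_ci,
        elapsed_mean=el_mean,
        elapsed_sd=el_sd,
        elapsed_ci=el_ci,
        r2=r2,
        p_value=p,
    )


def plot_vo_fo(
    vo_ages: Sequence[float], fo_ages: Sequence[float], path: str
) -> None:
    """Scatterplot of VO age against estimated FO age (written to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(vo_ages, fo_ages, s=18, alpha=0.7, edgecolor="none")
    lo = min(min(vo_ages), min(fo_ages)) - 1
    hi = max(max(vo_ages), max(fo_ages)) + 1
    ax.plot([lo, hi], [lo, hi], ls="--", lw=0.8, color="grey", label="FO = VO")
    ax.set_xlabel("Age at vaginal opening (PND)")
    ax.set_ylabel("Estimated age at first ovulation (PND)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
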