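"""Fixed- and random-effects meta-analysis of 2x2 case-control tables.

Pools odds ratios for a binary outcome (e.g. disease prevalence) across
studies comparing an exposed group with a control group.  Fixed-effect
pooling is Mantel-Haenszel (Robins-Breslow-Greenland variance) or
inverse-variance; random-effects pooling is DerSimonian-Laird with the
moment estimator of the between-study variance tau^2.  Heterogeneity is
summarized by Cochran's Q and I^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("crosstrait.meta")

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class TwoByTwoStudy:
    """Events/totals in an exposed and a control arm of one study."""

    label: str
    events_exposed: int
    n_exposed: int
    events_control: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_exposed <= 0 or self.n_control <= 0:
            raise ValueError(f"{self.label}: arm sizes must be positive")
        if not (0 <= self.events_exposed <= self.n_exposed):
            raise ValueError(f"{self.label}: exposed events out of range")
        if not (0 <= self.events_control <= self.n_control):
            raise ValueError(f"{self.label}: control events out of range")

    def cells(self, *, corrected: bool = False) -> tuple[float, float, float, float]:
        """(a, b, c, d) = (events_exp, nonevents_exp, events_ctl, nonevents_ctl).

        With ``corrected=True``, 0.5 is added to all four cells whenever
        any cell is zero (Haldane-Anscombe correction).
        """
        a = float(self.events_exposed)
        b = float(self.n_exposed - self.events_exposed)
        c = float(self.events_control)
        d = float(self.n_control - self.events_control)
        if corrected and min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return a, b, c, d

    @property
    def is_double_zero(self) -> bool:
        """No events in both arms, or all events in both arms: no OR information."""
        a, b, c, d = self.cells()
        return (a == 0 and c == 0) or (b == 0 and d == 0)


@dataclass
class MetaResult:
    model: str  # fixed-MH, fixed-IV, random-DL
    pooled_or: float
    ci_low: float
    ci_high: float
    weights_pct: np.ndarray
    tau2: float
    q: float
    q_df: int
    q_p: float
    i2: float
    flag: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_or <= self.ci_high):
            raise ValueError("CI must bracket the pooled OR")


def read_studies(path: str | Path) -> list[TwoByTwoStudy]:
    """Read a tab-separated study file: label, events and n per arm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return [
        TwoByTwoStudy(
            label=str(r["label"]),
            events_exposed=int(r["events_exposed"]),
            n_exposed=int(r["n_exposed"]),
            events_control=int(r["events_control"]),
            n_control=int(r["n_control"]),
        )
        for _, r in df.iterrows()
    ]


def study_effect(study: TwoByTwoStudy) -> tuple[float, float]:
    """Per-study log odds ratio and its standard error.

    If any cell is zero, 0.5 is added to all four cells before both the
    estimate and the variance (logged).
    """
    if study.is_double_zero:
        raise ValueError(f"{study.label}: double-zero study carries no OR information")
    a, b, c, d = study.cells(corrected=True)
    if min(*study.cells()) == 0:
        logger.info("%s: zero cell, 0.5 added to all cells", study.label)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(log_or), float(se)


def _includable(studies: list[TwoByTwoStudy]) -> list[TwoByTwoStudy]:
    kept = []
    for s in studies:
        if s.is_double_zero:
            logger.warning("%s excluded: double-zero study", s.label)
        else:
            kept.append(s)
    if not kept:
        raise ValueError("no includable studies")
    return kept


def heterogeneity(studies: list[TwoByTwoStudy]) -> tuple[float, int, float, float]:
    """Cochran's Q, its df = k-1, the chi-squared p, and I^2.

    I^2 = max(0, (Q - df) / Q): the share of total variability in the
    per-study effects attributable to between-study heterogeneity.
    """
    studies = _includable(studies)
    k = len(studies)
    if k < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    y, se = _effects(studies)
    w = 1.0 / se**2
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, q_p, i2


def _effects(studies: list[TwoByTwoStudy]) -> tuple[np.ndarray, np.ndarray]:
    eff = [study_effect(s) for s in studies]
    return np.array([e[0] for e in eff]), np.array([e[1] for e in eff])


def pool_fixed(studies: list[TwoByTwoStudy], method: str = "MH") -> MetaResult:
    """Fixed-effect pooled odds ratio.

    ``method="MH"``: Mantel-Haenszel on uncorrected cells (studies with
    a zero cell enter through 0.5-corrected terms), with the
    Robins-Breslow-Greenland variance for the CI.  ``method="IV"``:
    inverse-variance weighted mean of per-study log ORs.
    """
    studies = _includable(studies)
    y, se = _effects(studies)
    w_iv = 1.0 / se**2
    q, q_df, q_p, i2 = (0.0, 0, 1.0, 0.0) if len(studies) < 2 else heterogeneity(studies)

    if method == "IV":
        pooled = float(np.sum(w_iv * y) / np.sum(w_iv))
        se_pooled = float(1.0 / np.sqrt(np.sum(w_iv)))
        weights = 100.0 * w_iv / np.sum(w_iv)
        label = "fixed-IV"
    elif method == "MH":
        cells = []
        for s in studies:
            a, b, c, d = s.cells()
            if min(a, b, c, d) == 0:
                a, b, c, d = s.cells(corrected=True)
            cells.append((a, b, c, d))
        a = np.array([x[0] for x in cells])
        b = np.array([x[1] for x in cells])
        c = np.array([x[2] for x in cells])
        d = np.array([x[3] for x in cells])
        n = a + b + c + d
        r = a * d / n
        s_ = b * c / n
        pooled = float(np.log(np.sum(r) / np.sum(s_)))
        # Robins-Breslow-Greenland variance of log(OR_MH)
        p_ = (a + d) / n
        q_ = (b + c) / n
        rs, ss = np.sum(r), np.sum(s_)
        var = (
            np.sum(p_ * r) / (2 * rs**2)
            + np.sum(p_ * s_ + q_ * r) / (2 * rs * ss)
            + np.sum(q_ * s_) / (2 * ss**2)
        )
        se_pooled = float(np.sqrt(var))
        weights = 100.0 * s_ / ss  # conventional MH weights b*c/n
        label = "fixed-MH"
    else:
        raise ValueError(f"unknown fixed-effect method {method!r}")

    return MetaResult(
        model=label,
        pooled_or=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - _Z95 * se_pooled)),
        ci_high=float(np.exp(pooled + _Z95 * se_pooled)),
        weights_pct=np.asarray(weights),
        tau2=0.0,
        q=q, q_df=q_df, q_p=q_p, i2=i2,
    )


def pool_random(studies: list[TwoByTwoStudy]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) from the IV
    weights; random weights are 1/(se^2 + tau^2).  With a single study
    the fixed-IV result is returned, flagged.
    """
    studies = _includable(studies)
    if len(studies) == 1:
        res = pool_fixed(studies, method="IV")
        res.model = "random-DL"
        res.flag = "single-study: equals fixed-effect result"
        return res
    y, se = _effects(studies)
    w = 1.0 / se**2
    q, q_df, q_p, i2 = heterogeneity(studies)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - q_df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    return MetaResult(
        model="random-DL",
        pooled_or=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - _Z95 * se_pooled)),
        ci_high=float(np.exp(pooled + _Z95 * se_pooled)),
        weights_pct=100.0 * w_star / np.sum(w_star),
        tau2=float(tau2),
        q=q, q_df=q_df, q_p=q_p, i2=i2,
    )


def forest_data(studies: list[TwoByTwoStudy]) -> pd.DataFrame:
    """Forest-plot table: per-study ORs/CIs, fixed and random weights, pooled rows."""
    studies = _includable(studies)
    fixed = pool_fixed(studies, method="MH")
    random_ = pool_random(studies)
    iv = pool_fixed(studies, method="IV")
    rows = []
    for i, s in enumerate(studies):
        log_or, se = study_effect(s)
        rows.append(
            {
                "label": s.label,
                "events_exposed": s.events_exposed,
                "n_exposed": s.n_exposed,
                "events_control": s.events_control,
                "n_control": s.n_control,
                "or": float(np.exp(log_or)),
                "ci_low": float(np.exp(log_or - _Z95 * se)),
                "ci_high": float(np.exp(log_or + _Z95 * se)),
                "weight_fixed_pct": float(iv.weights_pct[i]),
                "weight_random_pct": float(random_.weights_pct[i]),
            }
        )
    for res in (fixed, random_):
        rows.append(
            {
                "label": f"pooled ({res.model})",
                "events_exposed": sum(s.events_exposed for s in studies),
                "n_exposed": sum(s.n_exposed for s in studies),
                "events_control": sum(s.events_control for s in studies),
                "n_control": sum(s.n_control for s in studies),
                "or": res.pooled_or,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "weight_fixed_pct": 100.0 if res.model.startswith("fixed") else float("nan"),
                "weight_random_pct": 100.0 if res.model.startswith("random") else float("nan"),
            }
        )
    return pd.DataFrame(rows)
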