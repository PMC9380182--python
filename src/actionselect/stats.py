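"""The study's statistical layer.

Within-subject (repeated-measures) ANOVA with one or two crossed factors and
effect-specific error terms (each effect tested against its interaction with
subjects), the Wilcoxon signed-rank test (exact by full sign enumeration up
to n = 12, normal approximation with tie correction beyond), Pearson
correlation, two-sample t tests, and the outlier sensitivity rule (flag
subjects more than 2.5 SD above the group mean and rerun the analysis
without them).  Alpha is .05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Input carries no information for the requested test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_two_sided) or 0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p value outside [0, 1]")


@dataclass
class RmAnovaResult:
    """Effects table of a within-subject ANOVA.

    ``table`` columns: effect, ss, df, ms, error_ss, error_df, error_ms, F, p
    (plus gg_epsilon / p_gg when the Greenhouse-Geisser correction is on).
    """

    table: pd.DataFrame
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def F(self, name: str) -> float:
        return float(self.effect(name)["F"])


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level scores."""
    k = scores.shape[1]
    if k < 2:
        return 1.0
    cov = np.cov(scores, rowvar=False)
    centered = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    tr = np.trace(centered)
    denom = (k - 1) * np.sum(centered**2)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), tr**2 / denom)))


def anova_rm(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    factors: Sequence[str] = ("condition", "day"),
    gg_correction: bool = False,
) -> RmAnovaResult:
    """Classical balanced within-subject ANOVA (one or two factors).

    Requires a complete design: every subject observed once in every factor
    cell.  Subjects are a random blocking factor; each effect's F uses its
    own effect-by-subject interaction as the error term (the highest-order
    interaction with subjects is the residual for the two-factor
    interaction).  Optional Greenhouse-Geisser sphericity correction adjusts
    the degrees of freedom of effects with more than one numerator df.
    """
    factors = list(factors)
    if len(factors) not in (1, 2):
        raise ValueError("anova_rm supports one or two within-subject factors")
    cols = [subject, *factors, dv]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = table[cols].copy()
    if data[dv].isna().any():
        bad = data.loc[data[dv].isna(), [subject, *factors]]
        raise ValueError(f"missing dv values for cells:\n{bad.to_string(index=False)}")
    pivot = data.pivot_table(index=subject, columns=factors, values=dv, aggfunc="mean")
    levels = [sorted(data[f].unique()) for f in factors]
    full_cols = (
        levels[0] if len(factors) == 1 else pd.MultiIndex.from_product(levels)
    )
    pivot = pivot.reindex(columns=full_cols)
    if pivot.isna().any().any():
        holes = [
            (subj, col)
            for subj, row in pivot.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError(f"incomplete design; missing subject/cell pairs: {holes[:10]}")
    s = pivot.shape[0]
    if s < 3:
        raise ValueError("need at least 3 subjects")
    if len(factors) == 1:
        a = len(levels[0])
        y = pivot.to_numpy().reshape(s, a)
        grand = y.mean()
        m_a = y.mean(axis=0)
        m_s = y.mean(axis=1)
        ss_a = s * np.sum((m_a - grand) ** 2)
        ss_as = np.sum((y - m_a[None, :] - m_s[:, None] + grand) ** 2)
        rows = [
            _effect_row(factors[0], ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        ]
        gg_scores = {factors[0]: y}
    else:
        a, b = len(levels[0]), len(levels[1])
        y = pivot.to_numpy().reshape(s, a, b)
        grand = y.mean()
        m_a = y.mean(axis=(0, 2))
        m_b = y.mean(axis=(0, 1))
        m_ab = y.mean(axis=0)
        m_s = y.mean(axis=(1, 2))
        m_sa = y.mean(axis=2)
        m_sb = y.mean(axis=1)
        ss_a = s * b * np.sum((m_a - grand) ** 2)
        ss_b = s * a * np.sum((m_b - grand) ** 2)
        ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
        ss_sa = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2)
        ss_sb = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2)
        ss_tot = np.sum((y - grand) ** 2)
        ss_s = a * b * np.sum((m_s - grand) ** 2)
        ss_res = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
        ss_res = max(0.0, ss_res)
        inter = f"{factors[0]}:{factors[1]}"
        rows = [
            _effect_row(factors[0], ss_a, a - 1, ss_sa, (a - 1) * (s - 1)),
            _effect_row(factors[1], ss_b, b - 1, ss_sb, (b - 1) * (s - 1)),
            _effect_row(inter, ss_ab, (a - 1) * (b - 1), ss_res, (a - 1) * (b - 1) * (s - 1)),
        ]
        gg_scores = {
            factors[0]: y.mean(axis=2),
            factors[1]: y.mean(axis=1),
            inter: y.reshape(s, a * b),
        }
    result = pd.DataFrame(rows)
    if gg_correction:
        eps, p_gg = [], []
        for _, row in result.iterrows():
            scores = gg_scores[row["effect"]]
            e = _gg_epsilon(scores)
            eps.append(e)
            p_gg.append(
                float(sps.f.sf(row["F"], e * row["df"], e * row["error_df"]))
                if row["df"] > 0
                else np.nan
            )
        result["gg_epsilon"] = eps
        result["p_gg"] = p_gg
    return RmAnovaResult(table=result, n_subjects=s)


def _effect_row(name: str, ss: float, df: int, error_ss: float, error_df: int) -> dict:
    ms = ss / df if df else np.nan
    error_ms = error_ss / error_df if error_df else np.nan
    if error_ms > 0:
        F = ms / error_ms
        p = float(sps.f.sf(F, df, error_df))
    else:
        # zero error variance: an exactly null effect is F = 0, otherwise infinite
        F = 0.0 if ss <= 1e-12 else np.inf
        p = 1.0 if ss <= 1e-12 else 0.0
    return {
        "effect": name,
        "ss": float(ss),
        "df": int(df),
        "ms": float(ms),
        "error_ss": float(error_ss),
        "error_df": int(error_df),
        "error_ms": float(error_ms),
        "F": float(F),
        "p": p,
    }


EXACT_WILCOXON_MAX_N = 12


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  ``exact`` enumerates all 2^n sign
    assignments of the ranked absolute differences (ties get average ranks);
    ``approx`` uses the normal approximation with tie-corrected variance and
    a 0.5 continuity correction.  ``auto`` picks exact for n <= 12.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if mode == "auto":
        mode = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "exact":
        masks = np.arange(2**n, dtype=np.int64)
        bits = (masks[:, None] >> np.arange(n)) & 1
        sums = bits @ ranks
        p_le = np.mean(sums <= w_plus + 1e-12)
        p_ge = np.mean(sums >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w_plus, p_two_sided=float(p), n=n, method="wilcoxon-exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance after tie correction")
    dev = w_plus - mean
    dev = np.sign(dev) * max(0.0, abs(dev) - 0.5)
    z = dev / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p_two_sided=min(1.0, p), n=n, method="wilcoxon-approx")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance input")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n=x.size,
        method="pearson",
    )


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> TestResult:
    """Two-sided independent-samples t test (Welch by default, or pooled)."""
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, a.size + b.size, f"t-{variant}")
        raise DegenerateDataError("zero within-group variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n=a.size + b.size,
        method=f"t-{variant}",
    )


@dataclass
class OutlierReport:
    flagged: list
    original: object
    reanalysis: object
    bound: float


def outlier_sensitivity(
    values_by_subject: Mapping | pd.Series,
    analysis: Callable[[Sequence], object],
    rule_sd: float = 2.5,
    two_sided: bool = False,
) -> OutlierReport:
    """Flag subjects beyond ``mean + rule_sd * SD`` (one-sided high by
    default) and rerun ``analysis`` on the retained subject ids.

    ``analysis`` receives a list of subject ids and returns any result
    object; it is called once with all subjects and once with the flagged
    ones removed (the second call is skipped and the original result reused
    when nothing is flagged).
    """
    series = pd.Series(dict(values_by_subject) if not isinstance(values_by_subject, pd.Series) else values_by_subject)
    if series.size < 3:
        raise ValueError("need at least 3 subjects")
    mean, sd = float(series.mean()), float(series.std(ddof=1))
    upper = mean + rule_sd * sd
    mask = series > upper
    if two_sided:
        mask |= series < mean - rule_sd * sd
    flagged = list(series.index[mask])
    original = analysis(list(series.index))
    reanalysis = (
        original if not flagged else analysis([s for s in series.index if s not in flagged])
    )
    return OutlierReport(flagged=flagged, original=original, reanalysis=reanalysis, bound=upper)
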