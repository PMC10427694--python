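"""Rank-based factorial statistics for the two-modality, seven-distance design.

The centerpiece is the Scheirer–Ray–Hare (SRH) test, the multi-factor
extension of the Kruskal–Wallis test: all responses are rank-transformed
jointly (average ranks on ties), a two-way sum-of-squares decomposition is
computed on the ranks, and each term's statistic is

    H_term = SS_term / MS_total,     MS_total = SS_total / (N - 1),

referred to a chi-square distribution at the term's degrees of freedom.
Computing ``SS_total`` from the tie-averaged ranks themselves is exactly
the classical tie correction: with one factor collapsed the statistic
reduces to the tie-corrected Kruskal–Wallis H.

Around it sit the rest of the study's battery: the two-stage procedure
(drop the interaction if it is not significant, otherwise split into
per-modality Kruskal–Wallis tests over distance), Brown–Forsythe spread
tests, two-sided variance-ratio F tests, and ordinary least-squares
scaling regressions of a metric on movement distance.

Factorial samples are tidy DataFrames with columns ``response``,
``modality`` and ``distance`` (see :func:`factorial_samples`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TermResult",
    "SRHResult",
    "TestResult",
    "RegressionFit",
    "TwoStageResult",
    "DesignError",
    "factorial_samples",
    "srh_test",
    "two_stage_analysis",
    "kruskal_wallis",
    "brown_forsythe",
    "variance_f_test",
    "scaling_regression",
]


class DesignError(ValueError):
    """The data cannot support the requested factorial design."""


@dataclass(frozen=True)
class TermResult:
    H: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SRHResult:
    """Per-term SRH outputs plus design bookkeeping."""

    terms: dict[str, TermResult]
    N: int
    tie_correction_applied: bool
    degenerate: bool = False

    def __getitem__(self, term: str) -> TermResult:
        return self.terms[term]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[int, ...]
    p_value: float
    method: str


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class TwoStageResult:
    """One response variable's staged analysis."""

    response: str
    stage1: SRHResult
    interaction_significant: bool
    branch: str  # "srh_no_interaction" | "per_modality_kw"
    stage2_srh: SRHResult | None = None
    stage2_kw: dict[str, TestResult] = field(default_factory=dict)


def factorial_samples(
    metrics: pd.DataFrame, response: str
) -> pd.DataFrame:
    """Tidy (response, modality, distance) table from a per-trial metrics table.

    Keeps completed trials with a finite value of ``response``.
    """
    df = metrics.loc[metrics["completed"].astype(bool), ["modality", "target_distance", response]]
    df = df.rename(columns={"target_distance": "distance", response: "response"})
    return df.dropna(subset=["response"]).reset_index(drop=True)


def _sequential_ss(ranks: np.ndarray, designs: list[np.ndarray]) -> list[float]:
    """Type-I sums of squares: RSS reductions as design columns accumulate."""
    n = ranks.size
    rss = [float(np.sum((ranks - ranks.mean()) ** 2))]
    X = np.ones((n, 1))
    for block in designs:
        X = np.hstack([X, block])
        fitted = X @ np.linalg.lstsq(X, ranks, rcond=None)[0]
        rss.append(float(np.sum((ranks - fitted) ** 2)))
    return [rss[i] - rss[i + 1] for i in range(len(designs))]


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    cols = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.empty((labels.size, 0))
    return cols, levels


def srh_test(
    samples: pd.DataFrame,
    include_interaction: bool = True,
    factors: tuple[str, str] = ("modality", "distance"),
) -> SRHResult:
    """Scheirer–Ray–Hare rank test on a two-factor table.

    Sums of squares are sequential (Type I) in the order ``factors`` then
    interaction; in a balanced design this coincides with the marginal
    decomposition.  If every response is tied the design is degenerate:
    all H are 0 with p = 1 and the result is flagged.
    """
    a_name, b_name = factors
    y = samples["response"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    A = samples[a_name].to_numpy()
    B = samples[b_name].to_numpy()
    Xa, a_levels = _dummies(A)
    Xb, b_levels = _dummies(B)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DesignError("each factor needs at least 2 observed levels")
    N = y.size
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b

    ranks = sps.rankdata(y)
    ties = np.unique(y).size < N
    ss_total = float(np.sum((ranks - ranks.mean()) ** 2))
    term_dfs = {a_name: df_a, b_name: df_b}
    if include_interaction:
        term_dfs["interaction"] = df_ab
    if ss_total == 0.0:
        terms = {t: TermResult(0.0, d, 1.0) for t, d in term_dfs.items()}
        return SRHResult(terms, N, tie_correction_applied=True, degenerate=True)

    designs = [Xa, Xb]
    if include_interaction:
        Xab = np.column_stack([Xa[:, i] * Xb[:, j] for i in range(df_a) for j in range(df_b)])
        designs.append(Xab)
    ss_terms = _sequential_ss(ranks, designs)

    ms_total = ss_total / (N - 1)
    terms = {}
    for (name, df_t), ss in zip(term_dfs.items(), ss_terms):
        H = ss / ms_total
        terms[name] = TermResult(float(H), df_t, float(sps.chi2.sf(H, df_t)))
    return SRHResult(terms, N, tie_correction_applied=ties)


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H with tie correction, chi-square p at k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DesignError("Kruskal–Wallis needs >= 2 nonempty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, (len(groups) - 1,), 1.0, "KW")
    H, p = sps.kruskal(*arrays)
    return TestResult(float(H), (len(groups) - 1,), float(p), "KW")


def brown_forsythe(groups: list[np.ndarray]) -> TestResult:
    """Brown–Forsythe spread test: ANOVA F on |x - group median|."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DesignError("Brown–Forsythe needs >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    stat, p = sps.levene(*arrays, center="median")
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return TestResult(float(stat), (k - 1, n - k), float(p), "Brown-Forsythe")


def variance_f_test(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sided variance-ratio test, F = s_a^2 / s_b^2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DesignError("variance F test needs >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0.0:
        raise ValueError("zero variance in the denominator group")
    F = va / vb
    dfn, dfd = a.size - 1, b.size - 1
    cdf = sps.f.cdf(F, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return TestResult(float(F), (dfn, dfd), float(min(p, 1.0)), "variance-F")


def scaling_regression(distances: np.ndarray, values: np.ndarray) -> RegressionFit:
    """OLS of a metric on movement distance (% workspace width)."""
    x = np.asarray(distances, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise DesignError("regression needs >= 2 distinct distances")
    if np.ptp(y) == 0.0:  # constant response: flat fit, no variance explained
        return RegressionFit(0.0, float(y[0]), 0.0)
    res = sps.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def two_stage_analysis(
    samples_by_response: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, TwoStageResult]:
    """The study's two-stage procedure, per response variable.

    Stage 1 is an SRH test with the modality x distance interaction.  If
    the interaction is not significant at ``alpha``, stage 2 re-runs the
    SRH test without it; if it is significant, stage 2 fixes modality and
    runs one Kruskal–Wallis test over distance per modality subset.
    """
    report: dict[str, TwoStageResult] = {}
    for name, samples in samples_by_response.items():
        stage1 = srh_test(samples, include_interaction=True)
        sig = stage1["interaction"].p_value < alpha
        if not sig:
            report[name] = TwoStageResult(
                response=name,
                stage1=stage1,
                interaction_significant=False,
                branch="srh_no_interaction",
                stage2_srh=srh_test(samples, include_interaction=False),
            )
        else:
            kw = {}
            for modality, sub in samples.groupby("modality", sort=True):
                groups = [g["response"].to_numpy() for _, g in sub.groupby("distance", sort=True)]
                kw[str(modality)] = kruskal_wallis(groups)
            report[name] = TwoStageResult(
                response=name,
                stage1=stage1,
                interaction_significant=True,
                branch="per_modality_kw",
                stage2_kw=kw,
            )
    return report
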