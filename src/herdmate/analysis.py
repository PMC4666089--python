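"""Expected allele-frequency trajectories, slope regressions, and
inbreeding-vs-recessive-load diagnostics.

The expected trajectory of a lethal recessive uses the recursion

    p_t = (p²_{t−1} + p_{t−1}q_{t−1}) / (2p²_{t−1} + p_{t−1}q_{t−1}),
    q_t = p_{t−1}q_{t−1} / (2p²_{t−1} + p_{t−1}q_{t−1}),

iterated exactly as written. Note that away from q = ½ this pair does not
renormalize (p_t + q_t ≠ 1) and it differs from the textbook
post-selection recursion q′ = q/(1+q); the textbook form is available as
:func:`expected_frequency_lethal_textbook` and is never substituted
silently. Neutral loci follow Hardy–Weinberg proportions, whose printed
recursion is algebraically the identity — expected frequencies are constant.

Observed and expected frequencies are regressed on the year index
(y_t = b₀ + b₁·g_t + e_t, ordinary least squares) and slopes compared with a
Welch two-sample t test (unequal variances, Satterthwaite degrees of
freedom) with a Bonferroni correction across the comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .mating import MatingPlan

__all__ = [
    "FrequencySeries",
    "SlopeComparison",
    "LoadDiagnostics",
    "expected_frequency_lethal",
    "expected_frequency_lethal_textbook",
    "expected_frequency_neutral",
    "frequency_slope",
    "compare_slopes",
    "prob_any_affected",
    "recessive_load_diagnostics",
]


@dataclass(frozen=True)
class FrequencySeries:
    """Minor-allele frequency per year, t = 0…T."""

    locus: str
    values: np.ndarray
    kind: str = "observed"  # or "expected"
    replicate: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SlopeComparison:
    """Welch t test between two samples of regression slopes."""

    mean_a: float
    mean_b: float
    t: float
    df: float
    p_raw: float
    p_bonferroni: float
    n_comparisons: int


def expected_frequency_lethal(q0: float, years: int) -> FrequencySeries:
    """Expected minor-allele trajectory for a lethal recessive.

    Iterates the printed recursion from (p₀, q₀) = (1 − q₀, q₀). The
    degenerate q₀ = 1 starting point (no major allele) zeroes the
    denominator; the series is returned as NaN after year 0 with a warning.
    """
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 must be in [0, 1]")
    if years < 1:
        raise ValueError("years must be >= 1")
    q = np.empty(years + 1)
    q[0] = q0
    p, qq = 1.0 - q0, q0
    for t in range(1, years + 1):
        denom = 2.0 * p * p + p * qq
        if denom == 0.0:
            if q0 == 1.0:
                warnings.warn(
                    "q0 = 1: the lethal recursion divides by zero; series is NaN",
                    RuntimeWarning,
                    stacklevel=2,
                )
                q[t:] = np.nan
            else:
                q[t:] = 0.0  # allele lost
            break
        p, qq = (p * p + p * qq) / denom, (p * qq) / denom
        q[t] = qq
    return FrequencySeries("expected_lethal", q, kind="expected")


def expected_frequency_lethal_textbook(q0: float, years: int) -> FrequencySeries:
    """Classic selection against a recessive lethal: q′ = q/(1 + q).

    Provided for comparison with :func:`expected_frequency_lethal`; the two
    agree at q = ½ and diverge elsewhere.
    """
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 must be in [0, 1]")
    q = np.empty(years + 1)
    q[0] = q0
    for t in range(1, years + 1):
        q[t] = q[t - 1] / (1.0 + q[t - 1])
    return FrequencySeries("expected_lethal_textbook", q, kind="expected")


def expected_frequency_neutral(q0: float, years: int) -> FrequencySeries:
    """Hardy–Weinberg expectation for a neutral locus: constant frequency.

    The printed recursion q_t = q² + pq is the identity, so the series is
    flat at q₀.
    """
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 must be in [0, 1]")
    return FrequencySeries("expected_neutral", np.full(years + 1, q0), kind="expected")


def frequency_slope(series: FrequencySeries | np.ndarray) -> tuple[float, float, float]:
    """OLS of frequency on year index; returns (b0, b1, residual SE)."""
    y = series.values if isinstance(series, FrequencySeries) else np.asarray(series, float)
    if len(y) < 3:
        raise ValueError("series must have at least 3 points")
    g = np.arange(len(y), dtype=float)
    model = sm.OLS(y, sm.add_constant(g)).fit()
    resid_se = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    return float(model.params[0]), float(model.params[1]), resid_se


def compare_slopes(
    slopes_a: np.ndarray, slopes_b: np.ndarray, n_comparisons: int = 1
) -> SlopeComparison:
    """Welch two-sample t test on slope samples, Bonferroni-adjusted.

    Two samples with zero variance and equal means give t = 0, p = 1 by
    convention.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 slopes")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0.0 else 0.0
        df = float(na + nb - 2)
    else:
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=float(df),
        p_raw=float(p),
        p_bonferroni=float(min(1.0, n_comparisons * p)),
        n_comparisons=n_comparisons,
    )


def prob_any_affected(sum_paa: np.ndarray, per_locus_paa: np.ndarray | None = None) -> np.ndarray:
    """1 − Π_r (1 − P(aa)_r): chance of at least one affected condition.

    The load diagnostics below use the plain sum Σ P(aa) as the affected
    probability; this complement form is the alternative for callers who
    want a true probability when several P(aa) terms are large. If only the
    sum is available it is clipped to [0, 1].
    """
    if per_locus_paa is not None:
        return 1.0 - np.prod(1.0 - per_locus_paa, axis=-1)
    return np.clip(np.asarray(sum_paa, dtype=float), 0.0, 1.0)


@dataclass
class LoadDiagnostics:
    """Correlation and regressions of recessive load on inbreeding."""

    correlation: float | None  # Pearson r of F_ij with ΣP(aa), all pairs
    n_pairs: int
    slope_made: float | None
    intercept_made: float | None
    n_made: int
    slope_not_made: float | None
    intercept_not_made: float | None
    n_not_made: int


def _regress(f: np.ndarray, load: np.ndarray) -> tuple[float | None, float | None]:
    if len(f) < 3 or np.ptp(f) == 0.0:
        return None, None
    model = sm.OLS(load, sm.add_constant(f)).fit()
    return float(model.params[1]), float(model.params[0])


def recessive_load_diagnostics(plan: MatingPlan) -> LoadDiagnostics:
    """Relate prospective-calf inbreeding to expected recessive load.

    Over every evaluated pair in the plan: the Pearson correlation of F_ij
    with ΣP(aa), and separate OLS regressions of ΣP(aa) on F_ij for the
    matings made versus those evaluated but not made. Strata with fewer than
    3 pairs, or degenerate (zero-variance) inputs, are reported as ``None``
    with a warning.
    """
    if plan.pair_f is None or plan.pair_sum_paa is None or plan.pair_made is None:
        raise ValueError(
            "plan does not retain evaluated pairs; run a portfolio scheme "
            "(pryce / modified_pryce)"
        )
    f = np.asarray(plan.pair_f, dtype=float)
    load = np.asarray(plan.pair_sum_paa, dtype=float)
    made = np.asarray(plan.pair_made, dtype=bool)

    if np.ptp(f) == 0.0 or np.ptp(load) == 0.0:
        warnings.warn(
            "correlation undefined: zero variance in F_ij or ΣP(aa)",
            RuntimeWarning,
            stacklevel=2,
        )
        corr = None
    else:
        corr = float(np.corrcoef(f, load)[0, 1])

    slope_m, int_m = _regress(f[made], load[made])
    slope_n, int_n = _regress(f[~made], load[~made])
    if slope_m is None and made.sum() < 3:
        warnings.warn("fewer than 3 made pairs; regression omitted", RuntimeWarning, stacklevel=2)
    if slope_n is None and (~made).sum() < 3:
        warnings.warn("fewer than 3 unmade pairs; regression omitted", RuntimeWarning, stacklevel=2)
    return LoadDiagnostics(
        correlation=corr,
        n_pairs=len(f),
        slope_made=slope_m,
        intercept_made=int_m,
        n_made=int(made.sum()),
        slope_not_made=slope_n,
        intercept_not_made=int_n,
        n_not_made=int((~made).sum()),
    )
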