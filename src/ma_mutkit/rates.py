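"""Mutation rates, spectrum statistics and treatment comparisons.

Rates are per diploid site per generation: a per-line SNM rate is
n / (C_i * g_i) with C_i callable sites and g_i generations; the pooled
rate is sum(n_i) / sum(C_i * g_i), identically the callable-generation-
weighted mean of per-line rates. LOH rates are reported as events per
generation, affected bp per generation, and affected bp per callable bp
per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ma_mutkit.spectrum import SPECTRUM_CLASSES


@dataclass
class RateEstimate:
    line_id: str
    treatment: str
    n_mutations: int
    callable_bp: float
    generations: float
    rate: float


@dataclass
class PooledRate:
    rate: float
    se: float
    ci_low: float
    ci_high: float
    n_total: int
    denominator: float      # sum of C_i * g_i


def per_line_snm_rate(n: int, callable_bp: float, generations: float) -> float:
    """rate = n / (C * g); C and g must be positive."""
    if callable_bp <= 0 or generations <= 0:
        raise ValueError("callable_bp and generations must be positive")
    return n / (callable_bp * generations)


def pooled_snm_rate(ns: np.ndarray, cs: np.ndarray, gs: np.ndarray
                    ) -> PooledRate:
    """Pooled rate sum(n) / sum(C*g) with a between-line normal-theory CI.

    The SE is that of the callable-generation-weighted mean of per-line
    rates; 95% CI via the normal approximation.
    """
    ns = np.asarray(ns, float)
    cs = np.asarray(cs, float)
    gs = np.asarray(gs, float)
    if np.any(cs <= 0) or np.any(gs <= 0):
        raise ValueError("callable sites and generations must be positive")
    w = cs * gs
    denom = float(w.sum())
    rate = float(ns.sum() / denom)
    per_line = ns / w
    wn = w / denom
    # variance of the weighted mean from between-line dispersion
    k = len(ns)
    if k > 1:
        var = float(np.sum(wn ** 2 * (per_line - rate) ** 2) * k / (k - 1))
        se = math.sqrt(var)
    else:
        se = float("nan")
    z = 1.959963984540054
    return PooledRate(rate, se, rate - z * se, rate + z * se,
                      int(ns.sum()), denom)


def weighted_mean_identity(ns, cs, gs) -> tuple[float, float]:
    """(pooled rate, weighted mean of per-line rates) — equal by identity."""
    ns = np.asarray(ns, float)
    w = np.asarray(cs, float) * np.asarray(gs, float)
    pooled = ns.sum() / w.sum()
    weighted = float(np.sum(w * (ns / w)) / w.sum())
    return float(pooled), weighted


@dataclass
class LOHRates:
    events_per_gen: float
    bp_per_gen: float
    per_bp_per_gen: float


def loh_rates(n_events: int, total_avg_bp: float, callable_bp: float,
              generations: float) -> LOHRates:
    """Per-line LOH rates: events/gen, affected bp/gen, per bp per gen."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    per_bp = (total_avg_bp / (callable_bp * generations)
              if callable_bp > 0 else float("nan"))
    return LOHRates(n_events / generations, total_avg_bp / generations, per_bp)


def pooled_loh_event_rate(n_events: int, total_line_generations: float
                          ) -> float:
    return n_events / total_line_generations


# ---------------------------------------------------------------------------
# spectrum


@dataclass
class SpectrumCounts:
    counts: np.ndarray          # length 6, order of SPECTRUM_CLASSES
    at_fraction: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (6,):
            raise ValueError("exactly 6 substitution classes expected")
        if not (0.0 < self.at_fraction < 1.0):
            raise ValueError("AT fraction must lie in (0, 1)")


def spectrum_counts_from_calls(calls, at_fraction: float) -> SpectrumCounts:
    counts = np.zeros(6)
    for c in calls:
        if getattr(c, "mclass", "SNM") == "SNM" and c.class6 is not None:
            counts[c.class6] += 1
    return SpectrumCounts(counts, at_fraction)


def spectrum_test(sc: SpectrumCounts) -> tuple[float, int, float]:
    """Equal-frequency test corrected for AT:GC composition.

    Expected counts: each A:T-origin class N * AT/3, each G:C-origin class
    N * GC/3. Pearson chi-squared with df = 5.
    """
    n = sc.counts.sum()
    if n <= 0:
        raise ValueError("no SNMs to test")
    at, gc = sc.at_fraction, 1.0 - sc.at_fraction
    expected = np.array([at, at, at, gc, gc, gc]) / 3.0 * n
    if np.any(expected <= 0):
        raise ValueError("zero expected count in a spectrum cell")
    chi2 = float(np.sum((sc.counts - expected) ** 2 / expected))
    df = 5
    return chi2, df, float(stats.chi2.sf(chi2, df))


def spectrum_homogeneity(counts_by_treatment: dict[str, np.ndarray]
                         ) -> tuple[float, int, float]:
    """Contingency chi-squared across treatments; df = 5 * (T - 1)."""
    rows = []
    for trt, c in counts_by_treatment.items():
        c = np.asarray(c, float)
        if c.sum() == 0:
            import warnings
            warnings.warn(f"treatment {trt!r} has no SNMs; dropped",
                          stacklevel=2)
            continue
        rows.append(c)
    if len(rows) < 2:
        raise ValueError("need >= 2 non-empty treatments")
    tab = np.vstack(rows)
    # classes absent from every treatment carry no information; drop them
    tab = tab[:, tab.sum(axis=0) > 0]
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def mnm_fraction(n_snms_in_mnms: int, n_snms_total: int) -> float:
    """Percent of all SNMs inside MNM groups."""
    if n_snms_total == 0:
        raise ValueError("undefined: zero SNMs")
    return 100.0 * n_snms_in_mnms / n_snms_total


# ---------------------------------------------------------------------------
# treatment comparisons


@dataclass
class GroupTest:
    test: str               # "anova" | "kruskal"
    statistic: float
    df: tuple[float, float] | float
    p: float


def treatment_rate_tests(values_by_treatment: dict[str, np.ndarray],
                         test: str = "auto",
                         normality_alpha: float = 0.05) -> GroupTest:
    """One-way ANOVA or Kruskal-Wallis across treatments.

    test="auto" gates on a Shapiro-Wilk test of the pooled residuals: ANOVA
    where normality is not rejected at ``normality_alpha``, Kruskal-Wallis
    otherwise.
    """
    groups = [np.asarray(v, float) for v in values_by_treatment.values()]
    if len(groups) < 2:
        raise ValueError("need >= 2 treatments")
    if test == "auto":
        resid = np.concatenate([g - g.mean() for g in groups])
        use_anova = True
        if len(resid) >= 3 and np.ptp(resid) > 0:
            use_anova = stats.shapiro(resid).pvalue >= normality_alpha
        test = "anova" if use_anova else "kruskal"
    if test == "anova":
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA requires >= 2 observations per group")
        f, p = stats.f_oneway(*groups)
        df = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
        return GroupTest("anova", float(f), df, float(p))
    if test == "kruskal":
        h, p = stats.kruskal(*groups)
        return GroupTest("kruskal", float(h), float(len(groups) - 1), float(p))
    raise ValueError(f"unknown test: {test}")


def chance_same_chromosome(k_events: int, n_chromosomes: int) -> float:
    """P(k independent events land on one same chromosome) = (1/n)^(k-1)."""
    if k_events < 1 or n_chromosomes < 1:
        raise ValueError("k_events and n_chromosomes must be >= 1")
    return (1.0 / n_chromosomes) ** (k_events - 1)


def expected_het_hom_snms(mu: float, het_frac: float,
                          total_callable_line_generations: float,
                          allele_factor: float = 1.0 / 3.0) -> float:
    """Expected het-to-hom SNM count: mu * het_frac * sum(C*g) * factor.

    ``allele_factor`` is the fraction of substitutions at a het site that
    convert it to homozygosity (default 1/3: one of the three possible
    derived alleles matches the other ancestral allele).
    """
    if min(mu, het_frac, total_callable_line_generations, allele_factor) < 0:
        raise ValueError("all inputs must be >= 0")
    return mu * het_frac * total_callable_line_generations * allele_factor


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f: float
    df: tuple[int, int]
    p: float


def rate_vs_generations(rates: np.ndarray, generations: np.ndarray
                        ) -> RegressionResult:
    """OLS of per-line rate on generations with an F test of the slope."""
    y = np.asarray(rates, float)
    x = np.asarray(generations, float)
    if y.size < 3:
        raise ValueError("need >= 3 lines")
    if np.ptp(x) == 0:
        raise ValueError("generations are constant; slope undefined")
    res = stats.linregress(x, y)
    f = res.rvalue ** 2 / (1 - res.rvalue ** 2) * (y.size - 2) \
        if abs(res.rvalue) < 1 else float("inf")
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(f),
                            (1, y.size - 2), float(res.pvalue))


__all__ = [
    "SPECTRUM_CLASSES", "RateEstimate", "PooledRate", "LOHRates",
    "SpectrumCounts", "GroupTest", "RegressionResult",
    "per_line_snm_rate", "pooled_snm_rate", "weighted_mean_identity",
    "loh_rates", "pooled_loh_event_rate", "spectrum_counts_from_calls",
    "spectrum_test", "spectrum_homogeneity", "mnm_fraction",
    "treatment_rate_tests", "chance_same_chromosome",
    "expected_het_hom_snms", "rate_vs_generations",
]
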