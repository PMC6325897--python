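"""Life tables, intrinsic rate of increase, and mutational parameters.

Implements partial life-table construction from subline records, the
Euler-Lotka root for the intrinsic rate of increase r (with a stochastic
age-structured projection as an independent cross-check), anchored weighted
least-squares mutational bias (dM), variance-component based CV_m / dCV_m,
mutational heritability V_M/V_E, and broad-sense heritability H2, plus the
treatment-interaction, line-divergence and Bartlett tests.

Ages are in the time units of the input records; r is per unit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class LifeHistoryRecord:
    """One subline's trait observations."""

    line_id: str
    subline_id: str
    treatment: str
    generations: float
    body_size: float | None
    clutch_ages: list[float] = field(default_factory=list)
    clutch_sizes: list[float] = field(default_factory=list)
    longevity: float | None = None
    survived_to_assay: bool = True

    def __post_init__(self) -> None:
        if len(self.clutch_ages) != len(self.clutch_sizes):
            raise ValueError("clutch_ages and clutch_sizes must align")
        if len(self.clutch_ages) > 1 and any(
                b <= a for a, b in zip(self.clutch_ages, self.clutch_ages[1:])):
            raise ValueError("clutch_ages must be strictly increasing")
        if any(c < 0 for c in self.clutch_sizes):
            raise ValueError("clutch sizes must be >= 0")
        if self.body_size is not None and self.body_size <= 0:
            raise ValueError("body_size must be positive")


@dataclass
class LifeTable:
    """Age-specific survivorship l_x and fecundity m_x (partial table)."""

    ages: np.ndarray          # increasing age classes
    survivorship: np.ndarray  # l_x in [0, 1], nonincreasing, l at age 0 is 1
    fecundity: np.ndarray     # m_x >= 0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survivorship = np.asarray(self.survivorship, dtype=float)
        self.fecundity = np.asarray(self.fecundity, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.survivorship < 0) or np.any(self.survivorship > 1):
            raise ValueError("l_x must lie in [0, 1]")
        if np.any(np.diff(self.survivorship) > 1e-12):
            raise ValueError("l_x must be nonincreasing")
        if np.any(self.fecundity < 0):
            raise ValueError("m_x must be >= 0")

    @property
    def net_reproduction(self) -> float:
        return float(np.sum(self.survivorship * self.fecundity))


def build_life_table(records: list[LifeHistoryRecord]) -> LifeTable:
    """Partial life table for one line from its subline records.

    l_x is the fraction of sublines surviving to age x (death time =
    longevity); m_x is the mean clutch size released at age x among sublines
    alive at x. The table is truncated at the last observed clutch age.
    """
    if not records:
        raise ValueError("no records")
    ages = sorted({a for r in records for a in r.clutch_ages})
    if not ages:
        raise ValueError("no clutch data in records")
    l_x, m_x = [], []
    for x in ages:
        alive = [r for r in records
                 if r.longevity is None or r.longevity >= x]
        l = len(alive) / len(records)
        if alive:
            per = []
            for r in alive:
                tot = sum(c for a, c in zip(r.clutch_ages, r.clutch_sizes)
                          if abs(a - x) < 1e-9)
                per.append(tot)
            m = float(np.mean(per))
        else:
            m = 0.0
        l_x.append(l)
        m_x.append(m)
    return LifeTable(np.array(ages), np.array(l_x), np.array(m_x))


def euler_lotka_residual(r: float, table: LifeTable) -> float:
    return float(np.sum(np.exp(-r * table.ages) * table.survivorship
                        * table.fecundity) - 1.0)


def solve_r(table: LifeTable, method: str = "euler-lotka",
            rng: np.random.Generator | None = None,
            n_individuals: int = 20_000) -> float:
    """Intrinsic rate of increase for a life table.

    ``euler-lotka``: unique root of sum_x e^(-r x) l_x m_x = 1 by bracketed
    root-finding (|residual| < 1e-10). ``projection``: stochastic
    age-structured projection whose log growth rate converges to the same
    root.
    """
    R0 = table.net_reproduction
    if R0 <= 0:
        raise ValueError("no net reproduction: sum l_x m_x <= 0")
    if method == "projection":
        return _project_r(table, rng, n_individuals)
    if method != "euler-lotka":
        raise ValueError(f"unknown method: {method}")
    lo, hi = -50.0, 50.0
    flo, fhi = euler_lotka_residual(lo, table), euler_lotka_residual(hi, table)
    for _ in range(20):
        if flo > 0 > fhi:
            break
        lo *= 2.0
        hi *= 2.0
        flo, fhi = euler_lotka_residual(lo, table), euler_lotka_residual(hi, table)
    else:
        raise ValueError("could not bracket the Euler-Lotka root "
                         f"(R0={R0:.4g}, residuals {flo:.4g}/{fhi:.4g})")
    r = optimize.brentq(euler_lotka_residual, lo, hi, args=(table,),
                        xtol=1e-12, rtol=8.9e-16, maxiter=200)
    assert abs(euler_lotka_residual(r, table)) < 1e-10
    return float(r)


def _project_r(table: LifeTable, rng: np.random.Generator | None,
               n_individuals: int) -> float:
    """Stochastic age-structured projection on a uniform time grid.

    Table ages must lie on a common grid (multiples of the smallest age
    spacing). Each step, individuals survive to the next age class with the
    conditional probability implied by l_x (binomial draw) and survivors at
    a clutch age produce Poisson(m_x) newborns. The population is
    renormalized each step; r is the mean per-unit-time log growth after a
    burn-in long enough for the age structure to settle.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ages = table.ages
    dt = float(np.min(np.concatenate(([ages[0]], np.diff(ages)))))
    n_steps = int(round(ages[-1] / dt))
    if not np.allclose(np.round(ages / dt) * dt, ages, atol=1e-9):
        raise ValueError("ages must lie on a uniform grid for projection")
    # l(t) as a right-continuous step function from the partial table
    l_step = np.ones(n_steps + 1)
    m_step = np.zeros(n_steps + 1)
    for x, l, m in zip(ages, table.survivorship, table.fecundity):
        s = int(round(x / dt))
        l_step[s:] = l
        m_step[s] = m
    counts = np.zeros(n_steps + 1)
    counts[0] = n_individuals
    burn, measure = 3 * n_steps, 40
    logsum, tsum = 0.0, 0.0
    for step in range(burn + measure):
        before = counts.sum()
        new = np.zeros_like(counts)
        surv = counts[:-1] * 0.0
        p = np.where(l_step[:-1] > 0, l_step[1:] / l_step[:-1], 0.0)
        surv = rng.binomial(counts[:-1].astype(np.int64),
                            np.clip(p, 0.0, 1.0))
        new[1:] = surv
        births = rng.poisson(np.sum(new * m_step))
        new[0] += births
        after = new.sum()
        if after <= 0:
            raise ValueError("population went extinct during projection")
        if step >= burn:
            logsum += math.log(after / before)
            tsum += dt
        # renormalize to keep the population near its nominal size
        if after > 4 * n_individuals:
            keep = n_individuals / after
            new = rng.binomial(new.astype(np.int64), keep).astype(float)
            if new.sum() <= 0:
                new[0] = n_individuals
        counts = new
    return logsum / tsum


def fecundity_for_r(r: float, ages: list[float]) -> float:
    """Equal clutch size m over ``ages`` whose Euler-Lotka root is ``r``."""
    denom = sum(math.exp(-r * x) for x in ages)
    return 1.0 / denom


# ---------------------------------------------------------------------------
# mutational parameters


@dataclass
class DeltaMResult:
    slope: float
    delta_m_pct: float      # % of anchor mean per generation
    se_pct: float
    t: float
    p: float
    df: int
    anchor_mean: float


def delta_m(line_values: np.ndarray, line_sds: np.ndarray,
            generations: np.ndarray, anchor_mean: float,
            anchor_sd: float) -> DeltaMResult:
    """Mutational bias by anchored weighted least squares.

    Regresses (value - anchor_mean) on generations with zero intercept so
    the fit passes exactly through (0, anchor_mean); weights are 1/SD.
    Zero/missing SDs are replaced by the median SD (warning-free fallback
    for single-surviving-subline lines). The anchor enters as a
    pseudo-observation at g = 0 weighted 1/anchor_sd; with zero intercept it
    constrains the line but contributes nothing to the slope sums.
    """
    y = np.asarray(line_values, float)
    g = np.asarray(generations, float)
    sd = np.asarray(line_sds, float).copy()
    if y.size < 2:
        raise ValueError("need >= 2 lines")
    bad = ~np.isfinite(sd) | (sd <= 0)
    if bad.all():
        sd[:] = 1.0
    elif bad.any():
        sd[bad] = np.median(sd[~bad])
    w = 1.0 / sd
    yc = y - anchor_mean
    sxx = float(np.sum(w * g * g))
    slope = float(np.sum(w * g * yc) / sxx)
    resid = yc - slope * g
    df = y.size - 1
    sigma2 = float(np.sum(w * resid ** 2) / df)
    se = math.sqrt(sigma2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), df)
    scale = 100.0 / anchor_mean
    return DeltaMResult(slope, slope * scale, se * scale, t, p, df,
                        anchor_mean)


@dataclass
class VarianceComponents:
    ms_among: float
    ms_within: float
    v_line: float           # among-line component, truncated at 0
    n0: float               # unbalanced-design coefficient
    grand_mean: float
    df_among: int
    df_within: int
    f: float
    p: float


def variance_components(values_by_line: dict[str, np.ndarray]
                        ) -> VarianceComponents:
    """One-way ANOVA variance partition among/within lines."""
    groups = [np.asarray(v, float) for v in values_by_line.values()
              if len(v) > 0]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 lines")
    ns = np.array([len(g) for g in groups], float)
    N = ns.sum()
    grand = float(np.concatenate(groups).mean())
    ss_among = float(sum(n * (g.mean() - grand) ** 2
                         for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_a, df_w = k - 1, int(N) - k
    if df_w <= 0:
        raise ValueError("need within-line replication (>= 2 sublines somewhere)")
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (N - float(np.sum(ns ** 2)) / N) / (k - 1)
    v_line = max((ms_a - ms_w) / n0, 0.0)
    f = ms_a / ms_w if ms_w > 0 else np.inf
    p = float(stats.f.sf(f, df_a, df_w)) if np.isfinite(f) else 0.0
    return VarianceComponents(ms_a, ms_w, v_line, n0, grand, df_a, df_w, f, p)


def cv_m(values_by_line: dict[str, np.ndarray], mean_generations: float
         ) -> tuple[float, float, VarianceComponents]:
    """CV_m (%) and per-generation dCV_m from among-line variance.

    CV_m = 100 * sqrt(V_L) / grand mean, with V_L the among-line variance
    component (truncated at zero); dCV_m = CV_m / mean generations.
    """
    vc = variance_components(values_by_line)
    cv = 100.0 * math.sqrt(vc.v_line) / abs(vc.grand_mean)
    dcv = cv / mean_generations if mean_generations > 0 else float("nan")
    return cv, dcv, vc


def vm_ve(values_by_line: dict[str, np.ndarray], t_generations: float,
          divisor: float = 2.0) -> tuple[float, VarianceComponents]:
    """Mutational heritability V_M/V_E with V_M = V_L/(divisor * t)."""
    vc = variance_components(values_by_line)
    if vc.ms_within <= 0:
        raise ValueError("V_E is zero; V_M/V_E undefined")
    v_m = vc.v_line / (divisor * t_generations)
    return v_m / vc.ms_within, vc


def broad_sense_h2(values_by_line: dict[str, np.ndarray]) -> float:
    """H2 = V_L / (V_L + V_within), clipped to [0, 1]."""
    vc = variance_components(values_by_line)
    tot = vc.v_line + vc.ms_within
    if tot <= 0:
        return 0.0
    return float(min(max(vc.v_line / tot, 0.0), 1.0))


def treatment_interaction_test(line_values: np.ndarray, line_sds: np.ndarray,
                               generations: np.ndarray, treatments: np.ndarray,
                               anchor_mean: float) -> tuple[float, float]:
    """Treatment x generation interaction under the anchored WLS model.

    Nested-model F comparison: common anchored slope vs one anchored slope
    per treatment. Returns (F, p).
    """
    y = np.asarray(line_values, float) - anchor_mean
    g = np.asarray(generations, float)
    trts = np.asarray(treatments)
    sd = np.asarray(line_sds, float).copy()
    labels = sorted(set(trts.tolist()))
    if len(labels) < 2:
        raise ValueError("need >= 2 treatments")
    for lab in labels:
        if np.sum(trts == lab) < 2:
            raise ValueError(f"treatment {lab!r} has < 2 lines")
    bad = ~np.isfinite(sd) | (sd <= 0)
    if bad.all():
        sd[:] = 1.0
    elif bad.any():
        sd[bad] = np.median(sd[~bad])
    w = 1.0 / sd

    def rss(mask: np.ndarray) -> float:
        sxx = np.sum(w[mask] * g[mask] ** 2)
        b = np.sum(w[mask] * g[mask] * y[mask]) / sxx
        return float(np.sum(w[mask] * (y[mask] - b * g[mask]) ** 2))

    rss_full = sum(rss(trts == lab) for lab in labels)
    sxx = np.sum(w * g ** 2)
    b = np.sum(w * g * y) / sxx
    rss_red = float(np.sum(w * (y - b * g) ** 2))
    df1 = len(labels) - 1
    df2 = y.size - len(labels)
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


@dataclass
class DivergenceTests:
    anova_f: dict[str, float]
    anova_p: dict[str, float]
    tukey_flagged: dict[str, list[str]]
    bartlett_k2: float
    bartlett_p: float


def divergence_and_variance_tests(values_by_line: dict[str, np.ndarray],
                                  treatment_of_line: dict[str, str],
                                  tukey_alpha: float = 0.05
                                  ) -> DivergenceTests:
    """Per-treatment line-effect ANOVA + Tukey HSD; Bartlett across treatments.

    The Bartlett test compares variances of line means between treatments.
    Tukey flags lines involved in significant pairwise contrasts.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    by_trt: dict[str, dict[str, np.ndarray]] = {}
    for line, vals in values_by_line.items():
        by_trt.setdefault(treatment_of_line[line], {})[line] = np.asarray(
            vals, float)
    anova_f, anova_p, flagged = {}, {}, {}
    for trt, lines in by_trt.items():
        groups = [v for v in lines.values() if len(v) > 0]
        if len(groups) < 2:
            continue
        f, p = stats.f_oneway(*groups)
        anova_f[trt], anova_p[trt] = float(f), float(p)
        vals = np.concatenate(groups)
        labs = np.concatenate([[lid] * len(v) for lid, v in lines.items()])
        if len(set(labs)) >= 2 and len(vals) > len(set(labs)):
            res = pairwise_tukeyhsd(vals, labs, alpha=tukey_alpha)
            hits: list[str] = []
            for (g1, g2), rej in zip(
                    zip(res.groupsunique[res._multicomp.pairindices[0]],
                        res.groupsunique[res._multicomp.pairindices[1]]),
                    res.reject):
                if rej:
                    hits.extend([str(g1), str(g2)])
            flagged[trt] = sorted(set(hits))
        else:
            flagged[trt] = []
    means_by_trt = [np.array([v.mean() for v in lines.values()])
                    for lines in by_trt.values() if len(lines) >= 2]
    if len(means_by_trt) >= 2:
        k2, p = stats.bartlett(*means_by_trt)
    else:
        k2, p = float("nan"), float("nan")
    return DivergenceTests(anova_f, anova_p, flagged, float(k2), float(p))


# ---------------------------------------------------------------------------
# record-level convenience


def subline_r(records: list[LifeHistoryRecord],
              method: str = "euler-lotka") -> dict[str, float]:
    """Per-subline r, excluding sublines that died before the assay."""
    out = {}
    for rec in records:
        if not rec.survived_to_assay or not rec.clutch_ages:
            continue
        table = build_life_table([rec])
        out[rec.subline_id] = solve_r(table, method=method)
    return out


def group_by_line(records: list[LifeHistoryRecord], trait: str,
                  method: str = "euler-lotka") -> dict[str, np.ndarray]:
    """Subline trait values grouped by line. trait: 'r' or 'body_size'."""
    out: dict[str, list[float]] = {}
    if trait == "r":
        rs = subline_r(records, method=method)
        for rec in records:
            if rec.subline_id in rs:
                out.setdefault(rec.line_id, []).append(rs[rec.subline_id])
    elif trait == "body_size":
        for rec in records:
            if rec.survived_to_assay and rec.body_size is not None:
                out.setdefault(rec.line_id, []).append(rec.body_size)
    else:
        raise ValueError(f"unknown trait: {trait}")
    return {k: np.array(v) for k, v in out.items()}
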