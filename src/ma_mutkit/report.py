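"""End-to-end report assembly: rates, spectrum, LOH and life-history blocks."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

import ma_mutkit
from ma_mutkit.config import RunConfig
from ma_mutkit.lifehist import (
    broad_sense_h2,
    cv_m,
    delta_m,
    group_by_line,
    vm_ve,
)
from ma_mutkit.rates import (
    loh_rates,
    mnm_fraction,
    pooled_snm_rate,
    spectrum_homogeneity,
    spectrum_test,
    treatment_rate_tests,
    SpectrumCounts,
)
from ma_mutkit.tables import LineMeta


def genomic_block(calls, loh_events, masks, metas: list[LineMeta],
                  at_fraction: float, cfg: RunConfig) -> dict[str, Any]:
    """Per-treatment rates + spectrum + LOH summaries from pipeline outputs."""
    meta_by_line = {m.line_id: m for m in metas}
    snms = [c for c in calls if c.mclass == "SNM"]
    per_line = []
    for m in metas:
        n = sum(c.line_id == m.line_id for c in snms)
        c_bp = masks[m.line_id].snm_bp
        rate = n / (c_bp * m.generations) if c_bp > 0 else float("nan")
        evs = [e for e in loh_events if e.line_id == m.line_id]
        lr = loh_rates(len(evs), sum(e.avg_size for e in evs),
                       masks[m.line_id].loh_bp, m.generations)
        per_line.append({
            "line_id": m.line_id, "treatment": m.treatment,
            "generations": m.generations, "n_snm": n, "callable_bp": c_bp,
            "loh_callable_bp": masks[m.line_id].loh_bp,
            "snm_rate": rate, "n_loh": len(evs),
            "loh_events_per_gen": lr.events_per_gen,
            "loh_bp_per_gen": lr.bp_per_gen,
            "loh_per_bp_per_gen": lr.per_bp_per_gen})
    ns = np.array([r["n_snm"] for r in per_line], float)
    cs = np.array([max(r["callable_bp"], 1) for r in per_line], float)
    gs = np.array([r["generations"] for r in per_line], float)
    pooled = pooled_snm_rate(ns, cs, gs)

    counts = np.zeros(6)
    by_trt: dict[str, np.ndarray] = {}
    for c in snms:
        if c.class6 is None:
            continue
        counts[c.class6] += 1
        trt = meta_by_line[c.line_id].treatment
        by_trt.setdefault(trt, np.zeros(6))[c.class6] += 1
    out: dict[str, Any] = {
        "per_line": per_line,
        "pooled_snm_rate": {"rate": pooled.rate, "se": pooled.se,
                            "ci": [pooled.ci_low, pooled.ci_high],
                            "n": pooled.n_total},
        "n_snm_total": len(snms),
        "n_indel_total": sum(c.mclass == "INDEL" for c in calls),
        "n_loh_total": len(loh_events),
        "spectrum_counts": counts.tolist(),
    }
    in_mnm = sum(1 for c in snms if c.mnm_group)
    if snms:
        out["mnm_fraction_pct"] = mnm_fraction(in_mnm, len(snms))
        out["n_mnm_groups"] = len({c.mnm_group for c in snms if c.mnm_group})
    if counts.sum() > 0:
        chi2, df, p = spectrum_test(SpectrumCounts(counts, at_fraction))
        out["spectrum_test"] = {"chi2": chi2, "df": df, "p": p}
    if len([t for t, c in by_trt.items() if c.sum() > 0]) >= 2:
        chi2, df, p = spectrum_homogeneity(by_trt)
        out["spectrum_homogeneity"] = {"chi2": chi2, "df": df, "p": p}
    rates_by_trt: dict[str, list[float]] = {}
    for r in per_line:
        rates_by_trt.setdefault(r["treatment"], []).append(r["snm_rate"])
    if len(rates_by_trt) >= 2 and all(len(v) >= 2
                                      for v in rates_by_trt.values()):
        gt = treatment_rate_tests(
            {k: np.array(v) for k, v in rates_by_trt.items()},
            test=cfg.rate_test, normality_alpha=cfg.normality_alpha)
        out["snm_rate_treatment_test"] = {
            "test": gt.test, "statistic": gt.statistic,
            "df": gt.df, "p": gt.p}
    return out


def life_history_block(records, anchor_records, cfg: RunConfig,
                       trait: str = "r") -> dict[str, Any]:
    """Table-1 style mutational parameters for one trait."""
    by_line = group_by_line(records, trait, method=cfg.r_method)
    anchor_by_line = group_by_line(anchor_records, trait, method=cfg.r_method)
    if not by_line or not anchor_by_line:
        return {"absent": True}
    meta: dict[str, tuple[str, float]] = {}
    for r in records:
        meta[r.line_id] = (r.treatment, r.generations)
    anchor_vals = np.concatenate(list(anchor_by_line.values()))
    anchor_mean = float(anchor_vals.mean())
    anchor_sd = float(anchor_vals.std(ddof=1)) if anchor_vals.size > 1 else 1.0

    lines = sorted(by_line)
    vals = np.array([by_line[lid].mean() for lid in lines])
    sds = np.array([by_line[lid].std(ddof=1) if len(by_line[lid]) > 1
                    else np.nan for lid in lines])
    gens = np.array([meta[lid][1] for lid in lines])
    dm = delta_m(vals, sds, gens, anchor_mean, anchor_sd)
    mean_gen = float(gens.mean())
    cv, dcv, vc = cv_m(by_line, mean_gen)
    ratio, _ = vm_ve(by_line, mean_gen, divisor=cfg.vm_divisor)
    h2 = broad_sense_h2(by_line)
    return {
        "trait": trait,
        "anchor_mean": anchor_mean, "anchor_sd": anchor_sd,
        "delta_m_pct_per_gen": dm.delta_m_pct, "delta_m_se": dm.se_pct,
        "delta_m_t": dm.t, "delta_m_p": dm.p,
        "cv_m_pct": cv, "dcv_m_pct_per_gen": dcv,
        "vm_over_ve": ratio, "broad_sense_h2": h2,
        "n_lines": len(lines),
    }


def write_report(report: dict[str, Any], out_dir: str | Path,
                 cfg: RunConfig) -> Path:
    """Write JSON report + human-readable summary; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = dict(report)
    report["software_version"] = ma_mutkit.__version__
    report["config_hash"] = cfg.config_hash()
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1, default=_jsonable))
    lines = [f"ma-mutkit {ma_mutkit.__version__} report "
             f"(config {report['config_hash']})", ""]
    gen = report.get("genomic")
    if gen:
        pr = gen["pooled_snm_rate"]
        lines.append(f"SNMs: {gen['n_snm_total']} "
                     f"(pooled rate {pr['rate']:.3g} /bp/gen, "
                     f"SE {pr['se']:.2g})")
        lines.append(f"INDELs: {gen['n_indel_total']}  "
                     f"LOH events: {gen['n_loh_total']}")
        if "mnm_fraction_pct" in gen:
            lines.append(f"MNM fraction: {gen['mnm_fraction_pct']:.1f}%")
    else:
        lines.append("genomic block: absent")
    for trait in ("life_history_r", "life_history_body_size"):
        blk = report.get(trait)
        if blk and not blk.get("absent"):
            lines.append(
                f"{trait}: dM {blk['delta_m_pct_per_gen']:.4g} %/gen "
                f"(p={blk['delta_m_p']:.3g}), CV_m {blk['cv_m_pct']:.3g}%, "
                f"V_M/V_E {blk['vm_over_ve']:.3g}, H2 "
                f"{blk['broad_sense_h2']:.2f}")
        else:
            lines.append(f"{trait}: absent")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
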