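"""De novo SNM / MNM / small-INDEL identification from multi-line tables.

The MA design is its own control: the ancestral genotype at a site is the
consensus of all non-focal lines, and a candidate mutation is a site where
exactly one line departs from an otherwise uniform genotype pattern. Sites
with two or more divergent lines are ancestral polymorphism or artifact and
are excluded. Candidates are then confirmed by exact binomial consistency
tests: the focal line's allele counts must fit its called genotype, and
every other line's alternate-allele count must be explainable as sequencing
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ma_mutkit.config import RunConfig
from ma_mutkit.spectrum import collapse_type
from ma_mutkit.tables import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    CallableMask,
    SiteCallTable,
    intervals_from_bool,
)


@dataclass
class MutationCall:
    line_id: str
    scaffold: str
    pos: int                      # 0-based
    ref: str
    alt: str
    mclass: str                   # "SNM" | "INDEL"
    zygosity: str                 # "het" | "hom"
    ancestral_gt: int             # consensus genotype code
    class6: int | None = None     # collapsed substitution class for SNMs
    mnm_group: str | None = None
    p_focal: float = float("nan")
    p_others_min: float = float("nan")
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# callable mask


def depth_mins(depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site smallest and second-smallest depth across lines."""
    p = np.partition(depth, 1, axis=1)
    return p[:, 0], p[:, 1]


def snm_callable_sites(table: SiteCallTable, focal_idx: int,
                       cfg: RunConfig,
                       depth: np.ndarray | None = None,
                       mins: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> np.ndarray:
    """Boolean per-site SNM-callability for one line.

    A site is callable iff the focal line has >= min_depth quality-passing
    reads and every other line has >= min_other_depth. ``depth``/``mins``
    may be precomputed once when iterating over many focal lines.
    """
    d = table.depth() if depth is None else depth
    m1, m2 = depth_mins(d) if mins is None else mins
    dj = d[:, focal_idx]
    others_min = np.where(dj == m1, m2, m1)
    return (dj >= cfg.min_depth) & (others_min >= cfg.min_other_depth)


def snm_callable_mask(table: SiteCallTable, focal_line: str,
                      cfg: RunConfig | None = None,
                      depth: np.ndarray | None = None,
                      mins: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> CallableMask:
    """SNM-callable intervals (0-based half-open) for ``focal_line``."""
    cfg = cfg or RunConfig()
    j = table.line_index(focal_line)
    flags = snm_callable_sites(table, j, cfg, depth, mins)
    mask = CallableMask(focal_line)
    for s, name in enumerate(table.scaffolds):
        sel = table.scaffold_idx == s
        # sites absent from the table are not callable
        b = np.zeros(table.scaffold_lengths[s], dtype=bool)
        b[table.pos[sel]] = flags[sel]
        mask.snm[name] = intervals_from_bool(b)
    return mask


# ---------------------------------------------------------------------------
# candidate detection


def detect_candidates(table: SiteCallTable) -> list[tuple[int, int]]:
    """Sites where exactly one line departs from the shared consensus.

    Returns (site_index, focal_line_index) pairs. Requires >= 3 lines.
    Sites with any missing genotype or with >= 2 divergent lines are not
    candidates.
    """
    n = table.n_lines
    if n < 3:
        raise ValueError("candidate detection requires >= 3 lines")
    gt = table.gt
    c0 = (gt == GT_HOM_REF).sum(axis=1)
    c1 = (gt == GT_HET).sum(axis=1)
    c2 = (gt == GT_HOM_ALT).sum(axis=1)
    counts = np.stack([c0, c1, c2], axis=1)
    no_missing = (c0 + c1 + c2) == n
    top = counts.max(axis=1)
    rows = np.flatnonzero(no_missing & (top == n - 1))
    out: list[tuple[int, int]] = []
    for i in rows:
        consensus = int(np.argmax(counts[i]))
        focal = int(np.flatnonzero(gt[i] != consensus)[0])
        out.append((int(i), focal))
    return out


def consensus_gt(table: SiteCallTable, site: int, focal_idx: int) -> int:
    """Majority genotype among non-focal lines (the inferred ancestor)."""
    g = np.delete(table.gt[site], focal_idx)
    g = g[g != GT_MISSING]
    if g.size == 0:
        return GT_MISSING
    vals, cnt = np.unique(g, return_counts=True)
    return int(vals[np.argmax(cnt)])


# ---------------------------------------------------------------------------
# binomial consistency


@dataclass
class ConsistencyResult:
    ok: bool
    p_focal: float
    p_others_min: float
    flags: list[str]


def focal_genotype_pvalue(ref: int, alt: int, gt_code: int, eps: float) -> float:
    """Exact binomial p-value for the focal line's genotype consistency.

    het: two-sided test of alt vs depth at p = 0.5. hom-alt: one-sided lower
    tail vs 1 - eps (too few alt reads rejects). hom-ref: symmetric, on ref.
    """
    depth = ref + alt
    if depth == 0:
        return float("nan")
    if gt_code == GT_HET:
        return float(stats.binomtest(alt, depth, 0.5).pvalue)
    if gt_code == GT_HOM_ALT:
        return float(stats.binom.cdf(alt, depth, 1.0 - eps))
    if gt_code == GT_HOM_REF:
        return float(stats.binom.cdf(ref, depth, 1.0 - eps))
    return float("nan")


def other_line_error_pvalue(alt: int, depth: int, eps: float) -> float:
    """Upper-tail exact binomial p for an other line's alt count vs error."""
    if depth == 0:
        return 1.0
    return float(stats.binom.sf(alt - 1, depth, eps))


def binomial_consistency(table: SiteCallTable, site: int, focal_idx: int,
                         cfg: RunConfig) -> ConsistencyResult:
    """PASS iff the focal counts fit the called genotype and every other
    line's alternate count is consistent with sequencing error (all exact
    binomial tests at level ``cfg.alpha`` with error rate ``cfg.eps``)."""
    flags: list[str] = []
    ref = int(table.ref_count[site, focal_idx])
    alt = int(table.alt_count[site, focal_idx])
    if ref + alt == 0:
        return ConsistencyResult(False, float("nan"), float("nan"),
                                 ["zero_focal_depth"])
    gt_code = int(table.gt[site, focal_idx])
    p_focal = focal_genotype_pvalue(ref, alt, gt_code, cfg.eps)
    ok = bool(p_focal >= cfg.alpha)
    if not ok:
        flags.append("focal_inconsistent")

    # Other lines: their divergent-allele support must look like error.
    # The tested allele is the focal line's divergent allele; at hom-alt
    # consensus sites that allele is REF, otherwise ALT.
    cons = consensus_gt(table, site, focal_idx)
    p_min = 1.0
    for j in range(table.n_lines):
        if j == focal_idx:
            continue
        d = int(table.ref_count[site, j] + table.alt_count[site, j])
        if cons == GT_HOM_ALT:
            a = int(table.ref_count[site, j])
        elif cons == GT_HOM_REF:
            a = int(table.alt_count[site, j])
        else:
            continue  # het consensus: both alleles expected in others
        p = other_line_error_pvalue(a, d, cfg.eps)
        p_min = min(p_min, p)
    if p_min < cfg.alpha:
        ok = False
        flags.append("other_line_signal")
    return ConsistencyResult(ok, p_focal, p_min, flags)


# ---------------------------------------------------------------------------
# assembling calls


def _zygosity(gt_code: int) -> str:
    return "het" if gt_code == GT_HET else "hom"


def call_mutations(table: SiteCallTable, cfg: RunConfig | None = None
                   ) -> tuple[list[MutationCall], list[MutationCall]]:
    """Full candidate -> filter -> classify chain.

    Returns (calls, het_hom_routed): confirmed SNM/INDEL calls, and
    candidate het-to-hom transitions removed from the SNM set and routed to
    LOH-event detection.
    """
    cfg = cfg or RunConfig()
    d = table.depth()
    calls: list[MutationCall] = []
    routed: list[MutationCall] = []
    for site, focal in detect_candidates(table):
        # callable-site rule for the focal line at this site
        others_d = np.delete(d[site], focal)
        if d[site, focal] < cfg.min_depth or \
                others_d.min() < cfg.min_other_depth:
            continue
        res = binomial_consistency(table, site, focal, cfg)
        if not res.ok:
            continue
        cons = consensus_gt(table, site, focal)
        focal_gt = int(table.gt[site, focal])
        ref_str, alt_str = table.alleles(site)
        scaffold = table.scaffolds[int(table.scaffold_idx[site])]
        is_indel = site in table.indel_alleles
        call = MutationCall(
            line_id=table.line_ids[focal], scaffold=scaffold,
            pos=int(table.pos[site]), ref=ref_str, alt=alt_str,
            mclass="INDEL" if is_indel else "SNM",
            zygosity=_zygosity(focal_gt), ancestral_gt=cons,
            p_focal=res.p_focal, p_others_min=res.p_others_min)
        if is_indel:
            if abs(len(ref_str) - len(alt_str)) >= cfg.max_indel_len:
                call.flags.append("indel_ge_50bp")
                continue
            calls.append(call)
            continue
        # het ancestor collapsing to hom: not an SNM, belongs to LOH
        if cons == GT_HET and focal_gt in (GT_HOM_REF, GT_HOM_ALT):
            call.flags.append("het_hom")
            routed.append(call)
            continue
        # a het-consensus candidate whose focal line is itself het is not
        # representable in a biallelic table, so the remaining candidates
        # have a homozygous consensus
        anc_code = int(table.ref_code[site]) if cons == GT_HOM_REF \
            else int(table.alt_code[site])
        der_code = int(table.alt_code[site]) if cons == GT_HOM_REF \
            else int(table.ref_code[site])
        if anc_code >= 0 and der_code >= 0 and anc_code != der_code:
            call.class6 = collapse_type(anc_code, der_code)
        calls.append(call)
    group_mnms([c for c in calls if c.mclass == "SNM"], cfg.mnm_window)
    return calls, routed


def exclude_het_hom_snms(calls: list[MutationCall]
                         ) -> tuple[list[MutationCall], list[MutationCall]]:
    """Split het->hom single-site transitions out of an SNM call list."""
    kept, routed = [], []
    for c in calls:
        if c.ancestral_gt == GT_HET and c.zygosity == "hom":
            routed.append(c)
        else:
            kept.append(c)
    return kept, routed


def group_mnms(snms: list[MutationCall], window_bp: int = 50) -> int:
    """Annotate maximal same-line clusters spanning <= window_bp bases.

    Cluster span is (max pos - min pos + 1) <= window_bp, i.e. all members
    fit within ``window_bp`` consecutive bases. Returns the group count.
    Groups of size 1 stay unannotated.
    """
    snms_sorted = sorted(snms, key=lambda c: (c.line_id, c.scaffold, c.pos))
    n_groups = 0
    cluster: list[MutationCall] = []

    def close() -> None:
        nonlocal n_groups
        if len(cluster) >= 2:
            n_groups += 1
            gid = f"{cluster[0].line_id}:mnm{n_groups}"
            for c in cluster:
                c.mnm_group = gid

    for c in snms_sorted:
        if cluster and c.line_id == cluster[0].line_id \
                and c.scaffold == cluster[0].scaffold \
                and c.pos - cluster[0].pos <= window_bp - 1:
            cluster.append(c)
        else:
            close()
            cluster = [c]
    close()
    return n_groups


def detect_indels(table: SiteCallTable, cfg: RunConfig | None = None
                  ) -> list[MutationCall]:
    """INDEL calls only (same filtering chain as SNMs, < 50 bp enforced)."""
    calls, _ = call_mutations(table, cfg)
    return [c for c in calls if c.mclass == "INDEL"]


def per_line_summary(calls: list[MutationCall],
                     masks: dict[str, CallableMask]) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for lid, mask in masks.items():
        mine = [c for c in calls if c.line_id == lid]
        snms = [c for c in mine if c.mclass == "SNM"]
        out[lid] = {
            "n_snm": len(snms),
            "n_indel": sum(c.mclass == "INDEL" for c in mine),
            "n_mnm_groups": len({c.mnm_group for c in snms if c.mnm_group}),
            "callable_bp": mask.snm_bp,
        }
    return out
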