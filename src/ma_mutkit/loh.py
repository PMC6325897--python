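"""Loss-of-heterozygosity event assembly, sizing, merging, classification.

A Het-Hom site is ancestrally heterozygous (all non-focal lines het) but
homozygous in the focal line. Events are maximal runs of >= 2 Het-Hom sites
covering >= 200 bp with no interior focal-het evidence. Minimum size is the
Het-Hom run span; maximum size is bounded by the nearest unaffected focal
het sites (or scaffold edges); reported size is their average. Whole-
scaffold homozygous runs on scaffolds mapped to one chromosome merge into a
single event sized by the summed minimum spans. Mechanism is classified
from standardized relative coverage: >= 0.75 is gene-conversion-like,
below is hemizygous deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ma_mutkit.config import RunConfig
from ma_mutkit.tables import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    CallableMask,
    SiteCallTable,
    intervals_from_bool,
)

logger = logging.getLogger(__name__)


@dataclass
class HetHomSite:
    line_id: str
    scaffold: str
    pos: int                 # 0-based
    retained_is_alt: bool    # focal homozygous for the site's ALT allele


@dataclass
class LOHEvent:
    line_id: str
    scaffolds: list[str]
    first: int               # first Het-Hom position (0-based, primary scaffold)
    last: int                # last Het-Hom position
    n_het_hom_sites: int
    min_span: int
    max_span: int | None     # None for multi-scaffold events
    avg_size: float
    mechanism: str | None = None
    std_rel_cov: float | None = None
    multi_scaffold: bool = False
    whole_scaffold: bool = False
    event_id: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def scaffold(self) -> str:
        return self.scaffolds[0]


# ---------------------------------------------------------------------------
# callable mask


def merge_runs(flags: np.ndarray, max_gap: int, min_span: int) -> np.ndarray:
    """Merge qualifying-site runs tolerating internal gaps <= max_gap bp,
    then drop merged runs shorter than min_span. Returns half-open
    intervals; merged spans include their internal gap bases."""
    iv = intervals_from_bool(flags)
    if iv.size == 0:
        return iv
    merged = [iv[0].tolist()]
    for a, b in iv[1:]:
        if a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = np.array([m for m in merged if m[1] - m[0] >= min_span],
                   dtype=np.int64)
    return out.reshape(-1, 2)


def loh_callable_mask(table: SiteCallTable, focal_line: str,
                      cfg: RunConfig | None = None,
                      snm_flags: np.ndarray | None = None) -> CallableMask:
    """LOH-callable intervals: SNM-callable runs >= min_span bp tolerating
    gaps <= max_gap (gaps accommodate small ancestor/reference INDELs)."""
    from ma_mutkit.calling import snm_callable_sites

    cfg = cfg or RunConfig()
    j = table.line_index(focal_line)
    flags = snm_callable_sites(table, j, cfg) if snm_flags is None else snm_flags
    mask = CallableMask(focal_line)
    for s, name in enumerate(table.scaffolds):
        sel = table.scaffold_idx == s
        b = np.zeros(table.scaffold_lengths[s], dtype=bool)
        b[table.pos[sel]] = flags[sel]
        mask.loh[name] = merge_runs(b, cfg.max_gap, cfg.min_span)
    return mask


# ---------------------------------------------------------------------------
# Het-Hom sites


def _ancestral_het_rows(table: SiteCallTable, focal_idx: int,
                        het: np.ndarray | None = None,
                        het_rowsum: np.ndarray | None = None) -> np.ndarray:
    """Rows where every non-focal line is called heterozygous."""
    if het is None:
        het = table.gt == GT_HET
    if het_rowsum is None:
        het_rowsum = het.sum(axis=1)
    n_het_others = het_rowsum - het[:, focal_idx]
    return n_het_others == (table.n_lines - 1)


def find_het_hom_sites(table: SiteCallTable, focal_line: str,
                       cfg: RunConfig | None = None,
                       het: np.ndarray | None = None,
                       het_rowsum: np.ndarray | None = None
                       ) -> tuple[list[HetHomSite], np.ndarray]:
    """Het-Hom sites for one line, plus the focal-het site index array.

    The focal line must be called homozygous with its minor-allele count
    consistent with sequencing error (one-sided exact binomial vs eps,
    p >= alpha). Returns (het_hom_sites, focal_het_rows) where the second
    element indexes sites that remain heterozygous in the focal line (the
    run breakers / event bounds).
    """
    cfg = cfg or RunConfig()
    j = table.line_index(focal_line)
    anc_het = _ancestral_het_rows(table, j, het, het_rowsum)
    focal_gt = table.gt[:, j]
    hom_rows = np.flatnonzero(anc_het & ((focal_gt == GT_HOM_REF)
                                         | (focal_gt == GT_HOM_ALT)))
    het_rows = np.flatnonzero(anc_het & (focal_gt == GT_HET))
    sites: list[HetHomSite] = []
    for i in hom_rows:
        ref = int(table.ref_count[i, j])
        alt = int(table.alt_count[i, j])
        minor = min(ref, alt)
        d = ref + alt
        if d == 0:
            continue
        # minor reads must be explainable as error
        if stats.binom.sf(minor - 1, d, cfg.eps) < cfg.alpha:
            continue
        sites.append(HetHomSite(focal_line, table.scaffolds[
            int(table.scaffold_idx[i])], int(table.pos[i]),
            retained_is_alt=focal_gt[i] == GT_HOM_ALT))
    return sites, het_rows


# ---------------------------------------------------------------------------
# event assembly


def assemble_events(het_hom_sites: list[HetHomSite],
                    het_positions: dict[str, np.ndarray],
                    scaffold_lengths: dict[str, int],
                    line_id: str,
                    min_sites: int = 2, min_span: int = 200) -> list[LOHEvent]:
    """Assemble per-scaffold Het-Hom runs into events.

    ``het_positions`` maps scaffold -> sorted positions where the focal line
    is still heterozygous; any such position interior to a run breaks it.
    Runs failing ``min_sites`` or ``min_span`` (first-to-last inclusive
    span) are dropped. Size bounds are attached via :func:`size_bounds`.
    """
    by_scaffold: dict[str, list[HetHomSite]] = {}
    for s in het_hom_sites:
        by_scaffold.setdefault(s.scaffold, []).append(s)
    events: list[LOHEvent] = []
    for scaffold, sites in by_scaffold.items():
        sites.sort(key=lambda s: s.pos)
        hets = np.asarray(het_positions.get(scaffold, np.empty(0)), dtype=np.int64)
        L = scaffold_lengths[scaffold]
        run: list[HetHomSite] = []

        def close(run: list[HetHomSite]) -> None:
            if len(run) < min_sites:
                return
            first, last = run[0].pos, run[-1].pos
            span = last - first + 1
            if span < min_span:
                return
            mn, mx, avg = size_bounds(first, last, hets, L)
            whole = hets.size == 0 and first == min(s.pos for s in sites) \
                and last == max(s.pos for s in sites)
            events.append(LOHEvent(line_id, [scaffold], first, last,
                                   len(run), mn, mx, avg,
                                   whole_scaffold=whole))

        for s in sites:
            if run:
                # a focal-het site strictly between breaks the run
                n_interior = int(np.searchsorted(hets, s.pos)
                                 - np.searchsorted(hets, run[-1].pos, "right"))
                if n_interior > 0:
                    close(run)
                    run = []
            run.append(s)
        close(run)
    for k, ev in enumerate(sorted(events, key=lambda e: (e.scaffold, e.first))):
        ev.event_id = f"{line_id}:loh{k + 1}"
    return events


def size_bounds(first: int, last: int, het_positions: np.ndarray,
                scaffold_length: int) -> tuple[int, int, float]:
    """(min_span, max_span, avg_size) for a Het-Hom run.

    min = last - first + 1. max = the largest stretch that could be
    homozygous without touching the flanking unaffected het sites
    (exclusive of those sites); where no flanking het exists the bound
    extends to the scaffold edge. avg = (min + max) / 2.
    """
    hets = np.asarray(het_positions, dtype=np.int64)
    i = np.searchsorted(hets, first)
    prev_het = int(hets[i - 1]) if i > 0 else -1
    k = np.searchsorted(hets, last, side="right")
    next_het = int(hets[k]) if k < hets.size else scaffold_length
    mn = last - first + 1
    mx = next_het - prev_het - 1
    return mn, mx, (mn + mx) / 2.0


def merge_multiscaffold(events: list[LOHEvent],
                        chrom_map: dict[str, int]) -> list[LOHEvent]:
    """Merge same-line whole-scaffold events sharing a chromosome.

    Merged events use the minimum size estimate: avg_size = sum of member
    min_spans (relative scaffold order/orientation unknown). Events on
    scaffolds absent from the map are left unmerged with a warning. Events
    are never merged across lines.
    """
    out: list[LOHEvent] = []
    groups: dict[tuple[str, int], list[LOHEvent]] = {}
    for ev in events:
        if not ev.whole_scaffold:
            out.append(ev)
            continue
        chrom = chrom_map.get(ev.scaffold)
        if chrom is None:
            logger.warning("scaffold %s missing from chromosome map; "
                           "event %s left unmerged", ev.scaffold, ev.event_id)
            ev.flags.append("unmapped_scaffold")
            out.append(ev)
            continue
        groups.setdefault((ev.line_id, chrom), []).append(ev)
    for (line_id, chrom), members in groups.items():
        if len(members) == 1:
            out.append(members[0])
            continue
        members.sort(key=lambda e: -(e.last - e.first))
        total_min = sum(m.min_span for m in members)
        merged = LOHEvent(
            line_id=line_id,
            scaffolds=[m.scaffold for m in members],
            first=members[0].first, last=members[0].last,
            n_het_hom_sites=sum(m.n_het_hom_sites for m in members),
            min_span=total_min, max_span=None, avg_size=float(total_min),
            multi_scaffold=True, whole_scaffold=True,
            event_id=members[0].event_id + "+merged")
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# mechanism classification


def classify_event(event: LOHEvent, table: SiteCallTable,
                   cfg: RunConfig | None = None,
                   depth: np.ndarray | None = None) -> LOHEvent:
    """Attach standardized relative coverage and mechanism to an event.

    std_rel_cov = (focal event depth / all-lines event depth), corrected by
    (focal genome-wide depth / all-lines genome-wide depth). Multi-scaffold
    events are classified over their largest member scaffold. Zero
    all-lines event depth marks the event unclassifiable.
    """
    cfg = cfg or RunConfig()
    j = table.line_index(event.line_id)
    s_idx = table.scaffolds.index(event.scaffolds[0])
    d = table.depth() if depth is None else depth
    sel = (table.scaffold_idx == s_idx) & (table.pos >= event.first) \
        & (table.pos <= event.last)
    ev_focal = float(d[sel, j].mean()) if sel.any() else 0.0
    ev_all = float(d[sel].mean()) if sel.any() else 0.0
    if ev_all <= 0:
        event.flags.append("unclassifiable_zero_depth")
        return event
    gw_focal = float(d[:, j].mean())
    gw_all = float(d.mean())
    event.std_rel_cov = (ev_focal / ev_all) / (gw_focal / gw_all)
    event.mechanism = ("gene_conversion"
                       if event.std_rel_cov >= cfg.cov_ratio_threshold
                       else "hemizygous_deletion")
    return event


# ---------------------------------------------------------------------------
# per-line / all-lines drivers


def call_loh_for_line(table: SiteCallTable, focal_line: str,
                      cfg: RunConfig | None = None,
                      het: np.ndarray | None = None,
                      het_rowsum: np.ndarray | None = None) -> list[LOHEvent]:
    cfg = cfg or RunConfig()
    sites, het_rows = find_het_hom_sites(table, focal_line, cfg, het,
                                         het_rowsum)
    het_positions: dict[str, np.ndarray] = {}
    for s, name in enumerate(table.scaffolds):
        sel = table.scaffold_idx[het_rows] == s
        het_positions[name] = table.pos[het_rows[sel]]
    lengths = dict(zip(table.scaffolds, table.scaffold_lengths))
    return assemble_events(sites, het_positions, lengths, focal_line,
                           cfg.min_sites, cfg.min_span)


def call_loh(table: SiteCallTable, chrom_map: dict[str, int] | None = None,
             cfg: RunConfig | None = None) -> list[LOHEvent]:
    """Het-Hom detection, assembly, multi-scaffold merging and mechanism
    classification for every line in the table."""
    cfg = cfg or RunConfig()
    het = table.gt == GT_HET
    het_rowsum = het.sum(axis=1)
    depth = table.depth()
    events: list[LOHEvent] = []
    for lid in table.line_ids:
        evs = call_loh_for_line(table, lid, cfg, het, het_rowsum)
        if chrom_map is not None:
            evs = merge_multiscaffold(evs, chrom_map)
        for ev in evs:
            classify_event(ev, table, cfg, depth)
        events.extend(evs)
    for ev in events:
        assert ev.n_het_hom_sites >= cfg.min_sites
        assert ev.min_span >= cfg.min_span
    return events


def total_loh_bp(events: list[LOHEvent]) -> float:
    """The 'bp affected by LOH' numerator: sum of event avg sizes."""
    return float(sum(ev.avg_size for ev in events))
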