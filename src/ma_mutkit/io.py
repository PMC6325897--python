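"""Readers and writers for the pipeline's tabular formats.

TSVs are tab-delimited UTF-8 with a header line. Site tables store 1-based
positions (VCF-style); BED output is 0-based half-open. Every writer's
output round-trips through its paired reader.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ma_mutkit.lifehist import LifeHistoryRecord
from ma_mutkit.loh import LOHEvent
from ma_mutkit.tables import (
    BASE_INDEX,
    GT_CODES,
    GT_STRINGS,
    LineMeta,
    SiteCallTable,
)


def _opener(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# site-call tables


def write_site_table(table: SiteCallTable, path: str | Path) -> None:
    """TSV: scaffold, pos (1-based), ref, alt, then per line
    <line>.ref_count, <line>.alt_count, <line>.gt."""
    with _opener(path, "w") as fh:
        header = ["scaffold", "pos", "ref", "alt"]
        for lid in table.line_ids:
            header += [f"{lid}.ref_count", f"{lid}.alt_count", f"{lid}.gt"]
        fh.write("## scaffold_lengths=" + ",".join(
            f"{s}:{L}" for s, L in zip(table.scaffolds,
                                       table.scaffold_lengths)) + "\n")
        fh.write("\t".join(header) + "\n")
        for i in range(table.n_sites):
            ref, alt = table.alleles(i)
            row = [table.scaffolds[int(table.scaffold_idx[i])],
                   str(int(table.pos[i]) + 1), ref, alt]
            for j in range(table.n_lines):
                row += [str(int(table.ref_count[i, j])),
                        str(int(table.alt_count[i, j])),
                        GT_STRINGS[int(table.gt[i, j])]]
            fh.write("\t".join(row) + "\n")


def read_site_table(path: str | Path) -> SiteCallTable:
    with _opener(path, "r") as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("## scaffold_lengths="):
            raise ValueError("missing scaffold_lengths header")
        pairs = meta_line.split("=", 1)[1].split(",")
        scaffolds = [p.split(":")[0] for p in pairs]
        lengths = [int(p.split(":")[1]) for p in pairs]
        header = fh.readline().rstrip("\n").split("\t")
        line_ids = [c[:-len(".ref_count")] for c in header[4:]
                    if c.endswith(".ref_count")]
        n = len(line_ids)
        scaf_idx, pos, ref_c, alt_c = [], [], [], []
        rc, ac, gt = [], [], []
        indel_alleles: dict[int, tuple[str, str]] = {}
        s_index = {s: i for i, s in enumerate(scaffolds)}
        i = 0
        for line in fh:
            f = line.rstrip("\n").split("\t")
            scaf_idx.append(s_index[f[0]])
            pos.append(int(f[1]) - 1)
            ref, alt = f[2], f[3]
            if len(ref) > 1 or len(alt) > 1:
                indel_alleles[i] = (ref, alt)
                ref_c.append(BASE_INDEX[ref[0]])
                alt_c.append(BASE_INDEX[ref[0]])
            else:
                ref_c.append(BASE_INDEX[ref])
                alt_c.append(-1 if alt == "." else BASE_INDEX[alt])
            vals = f[4:]
            rc.append([int(vals[3 * j]) for j in range(n)])
            ac.append([int(vals[3 * j + 1]) for j in range(n)])
            gt.append([GT_CODES[vals[3 * j + 2]] for j in range(n)])
            i += 1
    return SiteCallTable(
        scaffolds=scaffolds, scaffold_lengths=lengths, line_ids=line_ids,
        scaffold_idx=np.array(scaf_idx, np.int32),
        pos=np.array(pos, np.int64),
        ref_code=np.array(ref_c, np.int8),
        alt_code=np.array(alt_c, np.int8),
        ref_count=np.array(rc, np.int32).reshape(-1, n),
        alt_count=np.array(ac, np.int32).reshape(-1, n),
        gt=np.array(gt, np.int8).reshape(-1, n),
        indel_alleles=indel_alleles)


def write_vcf(table: SiteCallTable, path: str | Path,
              variant_only: bool = True) -> None:
    """Minimal multi-sample VCF 4.2 export with GT:AD:DP."""
    with _opener(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for s, L in zip(table.scaffolds, table.scaffold_lengths):
            fh.write(f"##contig=<ID={s},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.line_ids) + "\n")
        for i in range(table.n_sites):
            ref, alt = table.alleles(i)
            if variant_only and alt == ".":
                continue
            row = [table.scaffolds[int(table.scaffold_idx[i])],
                   str(int(table.pos[i]) + 1), ".", ref, alt, ".", "PASS",
                   ".", "GT:AD:DP"]
            for j in range(table.n_lines):
                r, a = int(table.ref_count[i, j]), int(table.alt_count[i, j])
                row.append(f"{GT_STRINGS[int(table.gt[i, j])]}:{r},{a}:{r + a}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# metadata, truth, calls


def write_line_metadata(metas: list[LineMeta], path: str | Path) -> None:
    pd.DataFrame([{"line_id": m.line_id, "treatment": m.treatment,
                   "generations": m.generations} for m in metas]
                 ).to_csv(path, sep="\t", index=False)


def read_line_metadata(path: str | Path) -> list[LineMeta]:
    df = pd.read_csv(path, sep="\t")
    return [LineMeta(str(r.line_id), str(r.treatment), float(r.generations))
            for r in df.itertuples()]


def write_truth(truths, path: str | Path) -> None:
    payload = {t.line_id: {
        "snms": [dataclasses.asdict(m) for m in t.snms],
        "indels": [dataclasses.asdict(m) for m in t.indels],
        "loh": [dataclasses.asdict(m) for m in t.loh],
    } for t in truths}
    Path(path).write_text(json.dumps(payload, indent=1))


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "line_id": c.line_id, "scaffold": c.scaffold, "pos": c.pos + 1,
            "ref": c.ref, "alt": c.alt, "class": c.mclass,
            "zygosity": c.zygosity, "class6": c.class6,
            "mnm_group": c.mnm_group or ".",
            "p_focal": c.p_focal, "p_others_min": c.p_others_min,
            "flags": ";".join(c.flags) or "."})
    cols = ["line_id", "scaffold", "pos", "ref", "alt", "class", "zygosity",
            "class6", "mnm_group", "p_focal", "p_others_min", "flags"]
    return pd.DataFrame(rows, columns=cols)


def write_calls(calls, path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def loh_to_frame(events: list[LOHEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id, "line_id": ev.line_id,
            "scaffolds": ",".join(ev.scaffolds),
            "first": ev.first + 1, "last": ev.last + 1,
            "n_sites": ev.n_het_hom_sites, "min_span": ev.min_span,
            "max_span": ev.max_span if ev.max_span is not None else ".",
            "avg_size": ev.avg_size, "mechanism": ev.mechanism or ".",
            "std_rel_cov": (ev.std_rel_cov
                            if ev.std_rel_cov is not None else float("nan")),
            "multi_scaffold": ev.multi_scaffold,
            "flags": ";".join(ev.flags) or "."})
    return pd.DataFrame(rows)


def write_loh_tsv(events: list[LOHEvent], path: str | Path) -> None:
    loh_to_frame(events).to_csv(path, sep="\t", index=False)


def write_loh_bed(events: list[LOHEvent], path: str | Path) -> None:
    """BED (0-based half-open): the avg-size span anchored at the min-span
    midpoint, clipped at zero; name = line:event id, score = site count."""
    with _opener(path, "w") as fh:
        for ev in events:
            mid = (ev.first + ev.last) / 2.0
            half = ev.avg_size / 2.0
            start = max(0, int(round(mid - half)))
            end = int(round(mid + half))
            score = min(1000, ev.n_het_hom_sites)
            fh.write(f"{ev.scaffold}\t{start}\t{end}\t{ev.event_id}\t"
                     f"{score}\n")


# ---------------------------------------------------------------------------
# life history


_LH_COLS = ["line_id", "subline_id", "treatment", "generations", "body_size",
            "clutch_ages", "clutch_sizes", "longevity", "survived_to_assay"]


def write_life_history(records: list[LifeHistoryRecord],
                       path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "line_id": r.line_id, "subline_id": r.subline_id,
            "treatment": r.treatment, "generations": r.generations,
            "body_size": "" if r.body_size is None else r.body_size,
            "clutch_ages": ";".join(repr(a) for a in r.clutch_ages),
            "clutch_sizes": ";".join(repr(c) for c in r.clutch_sizes),
            "longevity": "" if r.longevity is None else r.longevity,
            "survived_to_assay": int(r.survived_to_assay)})
    pd.DataFrame(rows, columns=_LH_COLS).to_csv(path, index=False)


def read_life_history(path: str | Path) -> list[LifeHistoryRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for r in df.itertuples():
        ages = [float(x) for x in str(r.clutch_ages).split(";") if x]
        sizes = [float(x) for x in str(r.clutch_sizes).split(";") if x]
        out.append(LifeHistoryRecord(
            str(r.line_id), str(r.subline_id), str(r.treatment),
            float(r.generations),
            None if r.body_size == "" else float(r.body_size),
            ages, sizes,
            None if r.longevity == "" else float(r.longevity),
            bool(int(r.survived_to_assay))))
    return out


def write_chrom_map(chrom_map: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(chrom_map.items()),
                 columns=["scaffold", "chromosome"]
                 ).to_csv(path, sep="\t", index=False)


def read_chrom_map(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.scaffold): int(r.chromosome) for r in df.itertuples()}
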