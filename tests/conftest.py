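from __future__ import annotations

import numpy as np
import pytest

from ma_mutkit.tables import BASE_INDEX, GT_CODES, SiteCallTable


def build_table(sites, line_ids, scaffolds=None, scaffold_lengths=None
                ) -> SiteCallTable:
    """Construct a SiteCallTable from explicit per-site specs.

    ``sites`` is a list of dicts with keys: scaffold (name), pos (0-based),
    ref, alt ('.' or base or an (ref_str, alt_str) tuple for INDELs), and
    lines: list of (ref_count, alt_count, gt_string) per line.
    """
    if scaffolds is None:
        scaffolds = sorted({s["scaffold"] for s in sites})
    if scaffold_lengths is None:
        scaffold_lengths = [max((s["pos"] for s in sites
                                 if s["scaffold"] == name), default=0) + 1000
                            for name in scaffolds]
    s_index = {name: i for i, name in enumerate(scaffolds)}
    n = len(line_ids)
    sites = sorted(sites, key=lambda s: (s_index[s["scaffold"]], s["pos"]))
    scaf_idx, pos, ref_c, alt_c = [], [], [], []
    rc, ac, gt = [], [], []
    indel_alleles = {}
    for i, s in enumerate(sites):
        scaf_idx.append(s_index[s["scaffold"]])
        pos.append(s["pos"])
        alt = s.get("alt", ".")
        if isinstance(alt, tuple):
            indel_alleles[i] = alt
            ref_c.append(BASE_INDEX[alt[0][0]])
            alt_c.append(BASE_INDEX[alt[0][0]])
        else:
            ref_c.append(BASE_INDEX[s.get("ref", "A")])
            alt_c.append(-1 if alt == "." else BASE_INDEX[alt])
        assert len(s["lines"]) == n
        rc.append([x[0] for x in s["lines"]])
        ac.append([x[1] for x in s["lines"]])
        gt.append([GT_CODES[x[2]] for x in s["lines"]])
    return SiteCallTable(
        scaffolds=list(scaffolds),
        scaffold_lengths=[int(x) for x in scaffold_lengths],
        line_ids=list(line_ids),
        scaffold_idx=np.array(scaf_idx, np.int32),
        pos=np.array(pos, np.int64),
        ref_code=np.array(ref_c, np.int8),
        alt_code=np.array(alt_c, np.int8),
        ref_count=np.array(rc, np.int32).reshape(-1, n),
        alt_count=np.array(ac, np.int32).reshape(-1, n),
        gt=np.array(gt, np.int8).reshape(-1, n),
        indel_alleles=indel_alleles)


def uniform_site(scaffold, pos, n_lines, rc=6, ac=0, gt="0/0", ref="A",
                 alt="."):
    return {"scaffold": scaffold, "pos": pos, "ref": ref, "alt": alt,
            "lines": [(rc, ac, gt)] * n_lines}


@pytest.fixture
def table_builder():
    return build_table
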