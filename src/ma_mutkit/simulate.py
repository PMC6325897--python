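"""Synthetic MA-experiment generator with recoverable ground truth.

Generates a diploid ancestor (Bernoulli heterozygosity), plants per-line
SNMs / small INDELs / LOH events forward in time, emulates post-alignment
allele read counts (Poisson depth, binomial allele sampling, per-read
miscalls), and produces line-level life-history records with configured
mutational bias and among-line mutational variance.

The genotype column of the emitted :class:`SiteCallTable` emulates the
output of a quality-aware upstream genotype caller: it reflects the true
diploid state (missing where depth is zero), while the read counts carry
sequencing noise. Downstream binomial filters test count/genotype
consistency, mirroring a call-then-filter pipeline.

Simulation starts at allele counts — no read-level FASTQ, no alignment,
and no CNV/large-duplication model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ma_mutkit.config import ConfigError, SimConfig
from ma_mutkit.lifehist import LifeHistoryRecord, fecundity_for_r
from ma_mutkit.spectrum import DERIVED_BASE, classes_for_base
from ma_mutkit.tables import (
    BASES,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    LineMeta,
    SiteCallTable,
)

# ---------------------------------------------------------------------------
# domain types


@dataclass
class AncestralGenome:
    """Diploid ancestor: reference haplotype plus heterozygous positions.

    Every site has two allele slots: haplotype 1 equals ``ref`` everywhere;
    haplotype 2 differs only at ``het_pos`` where it carries ``het_alt``.
    """

    scaffolds: list[str]
    lengths: list[int]
    ref: list[np.ndarray]          # per-scaffold int8 base codes
    het_pos: list[np.ndarray]      # per-scaffold sorted int64 positions
    het_alt: list[np.ndarray]      # per-scaffold int8 codes of haplotype 2
    chrom_map: dict[str, int]      # scaffold -> chromosome (1-based)

    @property
    def length(self) -> int:
        return int(sum(self.lengths))

    def n_het_sites(self) -> int:
        return int(sum(p.size for p in self.het_pos))


@dataclass
class PlantedSNM:
    scaffold: int
    pos: int
    anc_code: int
    derived_code: int
    class6: int
    zygosity: str = "het"


@dataclass
class PlantedIndel:
    scaffold: int
    pos: int
    length: int
    kind: str                      # "ins" | "del"


@dataclass
class PlantedLOH:
    scaffold: int
    start: int                     # 0-based half-open span
    end: int
    mechanism: str                 # "gene_conversion" | "hemizygous_deletion"
    retained_hap: int              # 1 or 2
    n_het_sites: int


@dataclass
class TruthSet:
    """Ground-truth mutations planted in one line."""

    line_id: str
    snms: list[PlantedSNM] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)
    loh: list[PlantedLOH] = field(default_factory=list)

    def mnm_groups(self, window: int = 50) -> list[list[int]]:
        """Indices of planted SNMs clustered within a ``window``-bp stretch."""
        order = sorted(range(len(self.snms)),
                       key=lambda i: (self.snms[i].scaffold, self.snms[i].pos))
        groups: list[list[int]] = []
        cur: list[int] = []
        for i in order:
            s = self.snms[i]
            if cur and s.scaffold == self.snms[cur[0]].scaffold \
                    and s.pos - self.snms[cur[0]].pos <= window - 1:
                cur.append(i)
            else:
                if len(cur) >= 2:
                    groups.append(cur)
                cur = [i]
        if len(cur) >= 2:
            groups.append(cur)
        return groups


# ---------------------------------------------------------------------------
# generation


def generate_ancestor(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> AncestralGenome:
    """Draw a diploid ancestor with Bernoulli(ancestral_het) het sites.

    Base composition follows ``cfg.at_content`` (A and T equiprobable, C and
    G equiprobable). Deterministic given the generator state.
    """
    if any(int(L) <= 0 for L in cfg.scaffold_lengths):
        raise ConfigError("scaffold lengths must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    at = cfg.at_content
    base_p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    scaffolds = [f"scaffold_{i}" for i in range(cfg.n_scaffolds)]
    ref, het_pos, het_alt = [], [], []
    for L in cfg.scaffold_lengths:
        L = int(L)
        r = rng.choice(4, size=L, p=base_p).astype(np.int8)
        hp = np.flatnonzero(rng.random(L) < cfg.ancestral_het).astype(np.int64)
        # haplotype-2 allele differs from ref: shift by 1..3 mod 4
        shift = rng.integers(1, 4, size=hp.size)
        ha = ((r[hp].astype(np.int64) + shift) % 4).astype(np.int8)
        ref.append(r)
        het_pos.append(hp)
        het_alt.append(ha)
    chrom_map = {s: (i % cfg.n_chromosomes) + 1 for i, s in enumerate(scaffolds)}
    return AncestralGenome(scaffolds, [int(L) for L in cfg.scaffold_lengths],
                           ref, het_pos, het_alt, chrom_map)


def make_line_metas(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> list[LineMeta]:
    """Per-line metadata with generations ~ Normal(mean, SD) truncated at 1."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    metas = []
    for trt in cfg.treatments:
        mean, sd = cfg.generations[trt]
        n = cfg.n_lines_per_treatment[trt]
        g = np.maximum(1.0, rng.normal(mean, sd, size=n))
        for j in range(n):
            metas.append(LineMeta(f"{trt}-{j + 1:02d}", trt, float(g[j])))
    return metas


def simulate_line_mutations(genome: AncestralGenome, meta: LineMeta,
                            cfg: SimConfig,
                            rng: np.random.Generator | None = None) -> TruthSet:
    """Plant one line's mutations forward over ``meta.generations``.

    SNM count ~ Poisson(mu_snm * L * g), per diploid site per generation;
    INDELs ~ Poisson(mu_indel * L * g); LOH events ~ Poisson(loh_rate * g)
    with log-uniform sizes clipped to the scaffold and mechanism drawn
    Bernoulli(p_conversion). LOH spans are placed so they cover at least two
    ancestrally heterozygous sites (otherwise invisible and unrecoverable).
    """
    if meta.generations <= 0:
        raise ConfigError("generations must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mult = cfg.treatments[meta.treatment]
    L, g = genome.length, meta.generations
    truth = TruthSet(meta.line_id)

    lengths = np.asarray(genome.lengths, dtype=np.float64)
    scaf_p = lengths / lengths.sum()

    # SNMs: planted at ancestrally homozygous sites (99.3% of the genome);
    # the derived allele realizes one of the 6 collapsed classes.
    w = np.asarray(cfg.spectrum_weights, dtype=np.float64)
    n_snm = rng.poisson(cfg.mu_snm * mult * L * g)
    for _ in range(int(n_snm)):
        for _try in range(100):
            s = int(rng.choice(len(lengths), p=scaf_p))
            pos = int(rng.integers(0, genome.lengths[s]))
            if pos not in genome.het_pos[s]:  # arrays are small-ish; see below
                break
        anc = int(genome.ref[s][pos])
        cls = classes_for_base(anc)
        pw = w[cls]
        cls_pick = int(rng.choice(cls, p=pw / pw.sum())) if pw.sum() > 0 \
            else int(rng.choice(cls))
        truth.snms.append(PlantedSNM(s, pos, anc, DERIVED_BASE[(anc, cls_pick)],
                                     cls_pick))

    n_ind = rng.poisson(cfg.mu_indel * mult * L * g)
    for _ in range(int(n_ind)):
        s = int(rng.choice(len(lengths), p=scaf_p))
        pos = int(rng.integers(0, max(1, genome.lengths[s] - 12)))
        truth.indels.append(PlantedIndel(s, pos, int(rng.integers(1, 11)),
                                         "del" if rng.random() < 0.5 else "ins"))

    lo, hi = cfg.loh_size_dist
    n_loh = rng.poisson(cfg.loh_rate * mult * g)
    for _ in range(int(n_loh)):
        placed = None
        for _try in range(100):
            s = int(rng.choice(len(lengths), p=scaf_p))
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            size = max(1, min(size, genome.lengths[s]))
            start = int(rng.integers(0, genome.lengths[s] - size + 1))
            end = start + size
            hp = genome.het_pos[s]
            k = int(np.searchsorted(hp, end) - np.searchsorted(hp, start))
            if k >= 2:
                placed = (s, start, end, k)
                break
        if placed is None:
            continue
        s, start, end, k = placed
        mech = "gene_conversion" if rng.random() < cfg.p_conversion \
            else "hemizygous_deletion"
        truth.loh.append(PlantedLOH(s, start, end, mech,
                                    1 if rng.random() < 0.5 else 2, k))
    return truth


def _fast_poisson(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Poisson sampling via inverse-CDF table lookup (fast for huge draws)."""
    if lam <= 0:
        return np.zeros(size, dtype=np.int16)
    k_max = int(lam + 12.0 * np.sqrt(lam) + 25)
    ks = np.arange(k_max + 1)
    logpmf = -lam + ks * np.log(lam) - np.cumsum(
        np.concatenate(([0.0], np.log(np.maximum(ks[1:], 1)))))
    cdf = np.cumsum(np.exp(logpmf))
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="right").astype(np.int16)


def _het_lookup(genome: AncestralGenome) -> list[np.ndarray]:
    """Per-scaffold boolean vectors flagging ancestrally het positions."""
    out = []
    for L, hp in zip(genome.lengths, genome.het_pos):
        b = np.zeros(L, dtype=bool)
        b[hp] = True
        out.append(b)
    return out


def simulate_site_calls(genome: AncestralGenome, truths: list[TruthSet],
                        metas: list[LineMeta], cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> SiteCallTable:
    """Emulate post-alignment per-site, per-line allele counts.

    Depth ~ Poisson(mean_coverage); halved over hemizygous-deletion spans.
    Heterozygous cells draw alt reads Binomial(depth, 0.5); homozygous cells
    accumulate miscalls toward the site's alternate base at rate
    seq_error / 3. Genotype calls reflect the true state, missing at zero
    depth.
    """
    if len(truths) != len(metas):
        raise ValueError("one TruthSet per line required")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = len(metas)
    e3 = cfg.seq_error / 3.0

    truth_by_line = {t.line_id: t for t in truths}
    line_order = [m.line_id for m in metas]

    parts: dict[str, list[np.ndarray]] = {k: [] for k in
                                          ("scaf", "pos", "ref", "alt",
                                           "rc", "ac", "gt")}
    indel_alleles: dict[int, tuple[str, str]] = {}
    site_offset = 0

    for s, L in enumerate(genome.lengths):
        refc = genome.ref[s]
        hp = genome.het_pos[s]
        ha = genome.het_alt[s]

        alt_code = np.full(L, -1, dtype=np.int8)
        alt_code[hp] = ha

        # chunked draws into an int16 buffer: large one-shot allocations are
        # page-fault bound in constrained containers
        depth = np.empty((L, n), np.int16)
        B = 131_072
        for i0 in range(0, L, B):
            depth[i0:i0 + B] = rng.poisson(cfg.mean_coverage,
                                           size=(min(B, L - i0), n))
        het = np.zeros((L, n), dtype=bool)
        het[hp, :] = True
        homalt = np.zeros((L, n), dtype=bool)

        for j, lid in enumerate(line_order):
            truth = truth_by_line[lid]
            for ev in truth.loh:
                if ev.scaffold != s:
                    continue
                sl = slice(ev.start, ev.end)
                if ev.mechanism == "hemizygous_deletion":
                    depth[sl, j] = _fast_poisson(rng, cfg.mean_coverage / 2.0,
                                                 ev.end - ev.start)
                span_het = hp[(hp >= ev.start) & (hp < ev.end)]
                het[span_het, j] = False
                if ev.retained_hap == 2:
                    homalt[span_het, j] = True
            for m in truth.snms:
                if m.scaffold != s:
                    continue
                if alt_code[m.pos] >= 0 and alt_code[m.pos] != m.derived_code:
                    continue  # collision with an existing alternate allele
                alt_code[m.pos] = m.derived_code
                het[m.pos, j] = True
            for ind in truth.indels:
                if ind.scaffold != s:
                    continue
                het[ind.pos, j] = True
                ref_b = str(BASES[refc[ind.pos]])
                if ind.kind == "del":
                    tail = "".join(BASES[refc[ind.pos + 1:
                                               ind.pos + 1 + ind.length]])
                    r_str, a_str = ref_b + tail, ref_b
                else:
                    ins = "".join(BASES[rng.integers(0, 4, size=ind.length)])
                    r_str, a_str = ref_b, ref_b + ins
                indel_alleles[site_offset + ind.pos] = (r_str, a_str)
                if alt_code[ind.pos] < 0:
                    alt_code[ind.pos] = refc[ind.pos]  # placeholder code

        alt = np.empty((L, n), np.int16)
        for i0 in range(0, L, B):
            alt[i0:i0 + B] = rng.binomial(
                depth[i0:i0 + B].astype(np.int64), e3)
        nh = int(het.sum())
        if nh:
            alt[het] = rng.binomial(depth[het].astype(np.int64), 0.5)
        na = int(homalt.sum())
        if na:
            dh = depth[homalt].astype(np.int64)
            alt[homalt] = (dh - rng.binomial(dh, e3)).astype(np.int16)

        gt = np.zeros((L, n), dtype=np.int8)
        gt[het] = GT_HET
        gt[homalt] = GT_HOM_ALT
        gt[depth == 0] = GT_MISSING

        parts["scaf"].append(np.full(L, s, dtype=np.int32))
        parts["pos"].append(np.arange(L, dtype=np.int64))
        parts["ref"].append(refc)
        parts["alt"].append(alt_code)
        parts["rc"].append(depth - alt)
        parts["ac"].append(alt)
        parts["gt"].append(gt)
        site_offset += L

    return SiteCallTable(
        scaffolds=list(genome.scaffolds),
        scaffold_lengths=list(genome.lengths),
        line_ids=line_order,
        scaffold_idx=np.concatenate(parts["scaf"]),
        pos=np.concatenate(parts["pos"]),
        ref_code=np.concatenate(parts["ref"]),
        alt_code=np.concatenate(parts["alt"]),
        ref_count=np.concatenate(parts["rc"]),
        alt_count=np.concatenate(parts["ac"]),
        gt=np.concatenate(parts["gt"]),
        indel_alleles=indel_alleles,
    )


# ---------------------------------------------------------------------------
# life history


def simulate_life_history(metas: list[LineMeta], cfg: SimConfig,
                          rng: np.random.Generator | None = None,
                          ) -> list[LifeHistoryRecord]:
    """Generate per-subline life-history records with known parameters.

    Line effect b_i ~ Normal(g_i * delta_true * trait_anchor, g_i * vm_true)
    on the intrinsic-rate scale; subline r = anchor + b_i + Normal(0,
    ve_true). The clutch schedule (four clutches at ages 1..4 time units,
    equal expected sizes) is solved so the subline's Euler-Lotka root equals
    its drawn r. Body size follows the same line/subline model with its own
    anchor and variances.
    """
    if cfg.n_sublines < 2:
        raise ConfigError("n_sublines must be >= 2 for variance estimation")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ages = [1.0, 2.0, 3.0, 4.0]
    records: list[LifeHistoryRecord] = []
    for meta in metas:
        g = meta.generations
        b_r = rng.normal(g * cfg.delta_true * cfg.trait_anchor,
                         np.sqrt(max(g * cfg.vm_true, 0.0)))
        b_s = rng.normal(g * cfg.body_delta * cfg.body_anchor,
                         np.sqrt(max(g * cfg.body_vm, 0.0)))
        for k in range(cfg.n_sublines):
            sid = f"{meta.line_id}.s{k + 1}"
            if rng.random() < cfg.p_subline_death:
                records.append(LifeHistoryRecord(
                    meta.line_id, sid, meta.treatment, g, body_size=None,
                    clutch_ages=[], clutch_sizes=[],
                    longevity=float(rng.uniform(0.1, 1.0)),
                    survived_to_assay=False))
                continue
            r_s = cfg.trait_anchor + b_r + rng.normal(0, np.sqrt(cfg.ve_true))
            r_s = max(r_s, 0.01)
            m = fecundity_for_r(r_s, ages)
            size = max(cfg.body_anchor + b_s
                       + rng.normal(0, np.sqrt(cfg.body_ve)), 0.01)
            records.append(LifeHistoryRecord(
                meta.line_id, sid, meta.treatment, g, body_size=float(size),
                clutch_ages=list(ages), clutch_sizes=[m] * len(ages),
                longevity=float(ages[-1] + rng.exponential(2.0)),
                survived_to_assay=True))
    return records


def make_anchor_metas(cfg: SimConfig, n_lines: int = 10) -> list[LineMeta]:
    """Non-MA anchor population lines (generation 0, no mutational effects)."""
    return [LineMeta(f"nonMA-{j + 1:02d}", "nonMA", 0.0) for j in range(n_lines)]


def simulate_anchor_life_history(cfg: SimConfig, n_lines: int = 10,
                                 rng: np.random.Generator | None = None,
                                 ) -> list[LifeHistoryRecord]:
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    metas = make_anchor_metas(cfg, n_lines)
    zero = SimConfig(**{**_as_dict(cfg), "delta_true": 0.0, "vm_true": 0.0,
                        "body_delta": 0.0, "body_vm": 0.0})
    for m in metas:
        m.generations = 1e-9  # effectively generation zero; must be > 0
    return simulate_life_history(metas, zero, rng)


def _as_dict(cfg: SimConfig) -> dict:
    import dataclasses
    return dataclasses.asdict(cfg)


# ---------------------------------------------------------------------------
# one-call experiment


@dataclass
class Experiment:
    cfg: SimConfig
    genome: AncestralGenome
    metas: list[LineMeta]
    truths: list[TruthSet]
    table: SiteCallTable
    life_history: list[LifeHistoryRecord]
    anchor_records: list[LifeHistoryRecord]


def simulate_experiment(cfg: SimConfig) -> Experiment:
    """Run every generator stage from the single configured seed."""
    rng = np.random.default_rng(cfg.seed)
    genome = generate_ancestor(cfg, rng)
    metas = make_line_metas(cfg, rng)
    truths = [simulate_line_mutations(genome, m, cfg, rng) for m in metas]
    table = simulate_site_calls(genome, truths, metas, cfg, rng)
    life = simulate_life_history(metas, cfg, rng)
    anchor = simulate_anchor_life_history(cfg, 10, rng)
    return Experiment(cfg, genome, metas, truths, table, life, anchor)
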