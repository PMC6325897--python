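"""Core data containers: site-call tables, callable masks, line metadata.

Coordinates are 0-based half-open internally; 1-based in VCF-style output
and 0-based half-open in BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Base codes
BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Genotype codes
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_STRINGS = {GT_MISSING: "./.", GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1"}
GT_CODES = {v: k for k, v in GT_STRINGS.items()}


@dataclass
class LineMeta:
    line_id: str
    treatment: str
    generations: float


@dataclass
class SiteCallTable:
    """Per-site, per-line allele read counts and genotype calls.

    ``ref_count``/``alt_count`` hold quality-passing reads (mapping quality
    > 20, base quality > 10 upstream). ``gt`` holds coded genotype calls.
    Sites span one or more scaffolds; ``scaffold_idx``/``pos`` are parallel
    per-site arrays sorted by (scaffold, position).
    """

    scaffolds: list[str]
    scaffold_lengths: list[int]
    line_ids: list[str]
    scaffold_idx: np.ndarray        # (n_sites,) int32
    pos: np.ndarray                 # (n_sites,) int64, 0-based
    ref_code: np.ndarray            # (n_sites,) int8, 0..3
    alt_code: np.ndarray            # (n_sites,) int8, -1 if no alt allele
    ref_count: np.ndarray           # (n_sites, n_lines) int32
    alt_count: np.ndarray           # (n_sites, n_lines) int32
    gt: np.ndarray                  # (n_sites, n_lines) int8
    # sparse INDEL allele strings keyed by site index: (ref_str, alt_str)
    indel_alleles: dict[int, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise KeyError(f"unknown line id: {line_id}") from None

    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def alleles(self, i: int) -> tuple[str, str]:
        """REF/ALT strings for site ``i`` ('.' when no alternate allele)."""
        if i in self.indel_alleles:
            return self.indel_alleles[i]
        ref = str(BASES[self.ref_code[i]])
        alt = "." if self.alt_code[i] < 0 else str(BASES[self.alt_code[i]])
        return ref, alt

    def validate(self) -> None:
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("read counts must be nonnegative")
        for s in range(len(self.scaffolds)):
            p = self.pos[self.scaffold_idx == s]
            if p.size and np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing per scaffold")
        d = self.depth()
        if np.any((self.gt != GT_MISSING) & (d == 0)):
            raise ValueError("genotype call at zero depth")


def intervals_from_bool(flags: np.ndarray) -> np.ndarray:
    """Collapse a boolean site vector into (k, 2) half-open intervals."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False]))))
    return edges.reshape(-1, 2).astype(np.int64)


def total_bp(intervals: np.ndarray) -> int:
    if intervals.size == 0:
        return 0
    return int(np.sum(intervals[:, 1] - intervals[:, 0]))


@dataclass
class CallableMask:
    """Per-line callable intervals (0-based half-open), one set per scaffold.

    ``snm`` holds SNM/INDEL-callable intervals; ``loh`` holds LOH-callable
    intervals (>= min_span runs tolerating small gaps). Interval arrays are
    sorted and non-overlapping by construction.
    """

    line_id: str
    snm: dict[str, np.ndarray] = field(default_factory=dict)
    loh: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def snm_bp(self) -> int:
        return sum(total_bp(v) for v in self.snm.values())

    @property
    def loh_bp(self) -> int:
        return sum(total_bp(v) for v in self.loh.values())

    def snm_contains(self, scaffold: str, pos: int) -> bool:
        return _contains(self.snm.get(scaffold), pos)

    def loh_contains(self, scaffold: str, pos: int) -> bool:
        return _contains(self.loh.get(scaffold), pos)


def _contains(iv: np.ndarray | None, pos: int) -> bool:
    if iv is None or iv.size == 0:
        return False
    j = np.searchsorted(iv[:, 0], pos, side="right") - 1
    return j >= 0 and pos < iv[j, 1]
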