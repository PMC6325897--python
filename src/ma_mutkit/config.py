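"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value or file is invalid."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of a synthetic MA experiment.

    Rates are per diploid site per generation (a site is counted once, not
    per haploid copy). Probabilities must lie in [0, 1]; rates must be >= 0.
    """

    n_scaffolds: int = 4
    scaffold_lengths: list[int] = field(default_factory=lambda: [250_000] * 4)
    ancestral_het: float = 0.007
    at_content: float = 0.5818
    n_chromosomes: int = 12
    n_lines_per_treatment: dict[str, int] = field(
        default_factory=lambda: {"Control": 28, "Ni": 9, "Cu": 9, "NiCu": 9}
    )
    treatments: dict[str, float] = field(
        default_factory=lambda: {"Control": 1.0, "Ni": 1.0, "Cu": 1.0, "NiCu": 1.0}
    )
    generations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Control": (82.3, 4.7),
            "Ni": (120.5, 10.4),
            "Cu": (120.5, 10.4),
            "NiCu": (120.5, 10.4),
        }
    )
    mu_snm: float = 1.61e-9
    spectrum_weights: list[float] = field(default_factory=lambda: [1.0] * 6)
    mu_indel: float = 4.0e-11
    loh_rate: float = 0.012
    loh_size_dist: tuple[float, float] = (200.0, 100_000.0)
    p_conversion: float = 0.7
    mean_coverage: float = 12.4
    seq_error: float = 0.005
    trait_anchor: float = 1.30
    delta_true: float = -0.0001
    vm_true: float = 1.0e-6
    ve_true: float = 2.0e-3
    body_anchor: float = 2.46
    body_delta: float = 0.0
    body_vm: float = 1.0e-6
    body_ve: float = 4.0e-3
    n_sublines: int = 5
    p_subline_death: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check(self.n_scaffolds >= 1, "n_scaffolds must be >= 1")
        _check(len(self.scaffold_lengths) == self.n_scaffolds,
               "scaffold_lengths must have n_scaffolds entries")
        _check(all(int(L) > 0 for L in self.scaffold_lengths),
               "scaffold lengths must be positive")
        for name, p in [("ancestral_het", self.ancestral_het),
                        ("at_content", self.at_content),
                        ("p_conversion", self.p_conversion),
                        ("seq_error", self.seq_error),
                        ("p_subline_death", self.p_subline_death)]:
            _check(0.0 <= p <= 1.0, f"{name} must be a probability in [0, 1]")
        for name, r in [("mu_snm", self.mu_snm), ("mu_indel", self.mu_indel),
                        ("loh_rate", self.loh_rate),
                        ("mean_coverage", self.mean_coverage),
                        ("vm_true", self.vm_true), ("ve_true", self.ve_true)]:
            _check(r >= 0.0, f"{name} must be >= 0")
        _check(len(self.spectrum_weights) == 6,
               "spectrum_weights must have exactly 6 entries")
        _check(all(w >= 0 for w in self.spectrum_weights)
               and sum(self.spectrum_weights) > 0,
               "spectrum_weights must be nonnegative and not all zero")
        lo, hi = self.loh_size_dist
        _check(lo >= 1.0 and hi >= lo, "loh_size_dist must satisfy 1 <= lo <= hi")
        _check(set(self.treatments) == set(self.n_lines_per_treatment)
               == set(self.generations),
               "treatments / n_lines_per_treatment / generations keys must match")
        _check(all(n >= 1 for n in self.n_lines_per_treatment.values()),
               "each treatment needs >= 1 line")
        _check(all(m > 0 for m, _ in self.generations.values()),
               "mean generations must be positive")
        _check(self.n_sublines >= 2, "n_sublines must be >= 2")
        _check(1 <= self.n_chromosomes, "n_chromosomes must be >= 1")

    @property
    def genome_length(self) -> int:
        return int(sum(self.scaffold_lengths))


# Pipeline thresholds. Defaults follow the published filtering rules:
# >= 6 reads in the focal line, >= 1 read in every other line, LOH-callable
# runs >= 200 bp with internal gaps <= 6 bp, coverage-ratio threshold 0.75
# for gene-conversion vs hemizygous-deletion, 50 bp MNM window.
@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    eps: float = 0.01
    min_depth: int = 6
    min_other_depth: int = 1
    min_span: int = 200
    max_gap: int = 6
    min_sites: int = 2
    cov_ratio_threshold: float = 0.75
    mnm_window: int = 50
    max_indel_len: int = 50
    rate_test: str = "auto"        # "auto" | "anova" | "kruskal"
    normality_alpha: float = 0.05
    vm_divisor: float = 2.0        # V_M = V_L / (vm_divisor * t)
    r_method: str = "euler-lotka"  # "euler-lotka" | "projection"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check(0.0 < self.alpha < 1.0, "alpha must be in (0, 1)")
        _check(0.0 < self.eps < 0.5, "eps must be in (0, 0.5)")
        _check(self.min_depth >= 1, "min_depth must be >= 1")
        _check(self.min_other_depth >= 0, "min_other_depth must be >= 0")
        _check(self.min_span >= 1, "min_span must be >= 1")
        _check(self.max_gap >= 0, "max_gap must be >= 0")
        _check(self.min_sites >= 1, "min_sites must be >= 1")
        _check(self.cov_ratio_threshold > 0, "cov_ratio_threshold must be > 0")
        _check(self.mnm_window >= 2, "mnm_window must be >= 2")
        _check(self.rate_test in ("auto", "anova", "kruskal"),
               "rate_test must be auto|anova|kruskal")
        _check(self.r_method in ("euler-lotka", "projection"),
               "r_method must be euler-lotka|projection")
        _check(self.vm_divisor > 0, "vm_divisor must be > 0")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_TUPLE_FIELDS = {"loh_size_dist"}


def _coerce(cls: type, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        if k == "generations" and isinstance(v, dict):
            v = {t: tuple(g) for t, g in v.items()}
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str) -> tuple[SimConfig, RunConfig]:
    """Load a YAML config with optional ``simulate:`` and ``run:`` sections.

    An empty file yields all defaults. Unknown keys raise :class:`ConfigError`
    naming the offending keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"simulate", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    sim = _coerce(SimConfig, raw.get("simulate") or {})
    run = _coerce(RunConfig, raw.get("run") or {})
    return sim, run
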