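"""Synthetic herd generator calibrated to the published farm roster and
breed-level trait distributions.

The generator emulates the structure of the study population: 17 commercial
organic / low-input farms in England and Wales, 1,070 cows, four sampling
dates (autumn 2011; spring, summer and autumn 2012), eight analyzable breed
groups, and per-group trait distributions given as mean +- SD. Continuous
traits are modelled as zero-truncated normals (moment-matched where the
mean/SD pair is attainable under truncation), somatic cell count as a
moment-matched lognormal (heavily right-skewed in real herds), and treatment
counts as a moment-matched negative binomial (variance far exceeding the
mean) with a Poisson fallback. The omega-6/omega-3 ratio is always computed
from the sampled omega-6 and omega-3 percentages, never drawn independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .herd_model import (
    DATE_CODES,
    CowRecord,
    FarmInfo,
    FattyAcidProfile,
    HerdDataset,
    HerdError,
)

__all__ = [
    "TraitDistribution",
    "GeneratorConfig",
    "ConfigError",
    "ANALYSIS_GROUPS",
    "GROUP_SIZES",
    "GROUP_MEDIAN_SCC",
    "SIM_TRAITS",
    "GROUP_REQUIREMENTS",
    "default_config",
    "generate_herd",
    "inject_rare_combinations",
    "simulate_group_records",
]


class ConfigError(HerdError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# Printed study constants
# --------------------------------------------------------------------------

#: Farm roster: id, management, cows included, calving pattern, breeds present.
FARM_ROSTER_TABLE: tuple[tuple[int, str, int, str, tuple[str, ...]], ...] = (
    (1, "organic", 40, "spring", ("AYR", "JE", "HF", "NZF", "SR", "SH")),
    (2, "organic", 42, "year-round", ("HF", "JE", "SR")),
    (3, "low_input", 55, "spring", ("BS", "JE", "HF", "SR")),
    (4, "low_input", 52, "spring", ("NZF", "JE", "HF")),
    (5, "organic", 49, "year-round", ("HF", "SR", "SH", "MRI")),
    (6, "low_input", 28, "spring", ("HF", "JE", "SR")),
    (7, "organic", 61, "autumn-late", ("AYR", "HF", "SH", "SR")),
    (8, "low_input", 113, "year-round", ("BF", "HF", "SR", "SH", "MRI")),
    (9, "low_input", 60, "autumn-early", ("BF", "JE", "HF", "NZF", "SH")),
    (10, "organic", 55, "autumn-early", ("BF", "BS", "HF", "MO", "SR")),
    (11, "low_input", 66, "spring", ("JE", "NZF", "BF", "HF")),
    (12, "low_input", 27, "spring", ("BF", "SR", "JE")),
    (13, "low_input", 84, "year-round", ("AYR", "BF", "HF", "SR", "MO", "NZF")),
    (14, "low_input", 76, "spring", ("BF", "JE", "NZF", "SR", "HF", "MRI")),
    (15, "organic", 93, "autumn", ("AYR", "HF", "MO", "SR", "JE")),
    (16, "low_input", 97, "spring", ("AYR", "JE", "HF", "NZF")),
    (17, "organic", 72, "autumn", ("AYR", "HF", "SH", "XX")),
)

#: The eight breed groups that survive inclusion filtering in the study.
ANALYSIS_GROUPS: tuple[str, ...] = (
    "AYRX", "HF", "HFJE", "HFSR", "JEX", "NZFX", "SH", "SRX",
)

#: Record counts per group (used as default allocation weights).
GROUP_SIZES: dict[str, int] = {
    "AYRX": 100, "HF": 325, "HFJE": 184, "HFSR": 274,
    "JEX": 121, "NZFX": 90, "SH": 80, "SRX": 140,
}

#: Published median SCC per group (x10^3 cells/ml), for plausibility checks.
GROUP_MEDIAN_SCC: dict[str, float] = {
    "AYRX": 78.5, "HF": 78.0, "HFJE": 70.0, "HFSR": 73.0,
    "JEX": 84.0, "NZFX": 56.5, "SH": 89.0, "SRX": 73.0,
}

#: Traits sampled by the generator, in draw order. n6_n3_ratio is derived.
SIM_TRAITS: tuple[str, ...] = (
    "days_in_milk", "concentrate_kg_day", "forage_kg_day",
    "yield_l_day", "solids_kg_day", "scc_kcells_ml", "treatments_n",
    "c12_pct", "c14_pct", "c16_pct", "n6_pct",
    "oa_pct", "cla9_pct", "epa_dpa_dha_pct", "n3_pct",
)

# mean, sd per group, per trait (trait order = _TRAIT_ROWS order below).
_TRAIT_ROWS: tuple[str, ...] = (
    "days_in_milk", "concentrate_kg_day", "forage_kg_day",
    "yield_l_day", "solids_kg_day", "scc_kcells_ml", "treatments_n",
    "c12_pct", "c14_pct", "c16_pct", "n6_pct", "n6_n3_ratio",
    "oa_pct", "cla9_pct", "epa_dpa_dha_pct", "n3_pct",
)
_GROUP_TRAIT_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    #         dim         conc         forage       yield        solids        scc           treat         c12          c14          c16          n6           n6/n3        oa           cla9          epa           n3
    "AYRX": ((154, 94.25), (3.0, 1.54), (3.7, 4.91), (20.2, 7.33), (1.7, 0.799), (243, 454.2), (0.41, 0.818), (3.2, 0.797), (10.9, 1.82), (29.6, 4.79), (1.6, 0.300), (1.0, 0.309), (20.3, 3.87), (0.99, 0.418), (0.23, 0.074), (1.7, 0.460)),
    "HF":   ((182, 96.89), (3.3, 2.15), (6.1, 5.25), (21.2, 8.67), (1.6, 0.618), (234, 584.5), (0.34, 0.713), (3.3, 0.807), (11.4, 1.53), (32.5, 4.92), (1.7, 0.532), (1.4, 0.655), (18.8, 3.87), (0.88, 0.507), (0.20, 0.073), (1.4, 0.513)),
    "HFJE": ((157, 102.23), (3.6, 1.68), (6.5, 5.65), (21.8, 8.89), (1.8, 0.704), (248, 782.1), (0.35, 0.670), (4.0, 0.918), (12.2, 1.69), (32.9, 6.23), (1.6, 0.419), (1.4, 0.441), (16.6, 4.02), (0.67, 0.451), (0.19, 0.056), (1.3, 0.450)),
    "HFSR": ((161, 94.26), (4.5, 2.45), (5.6, 5.48), (21.9, 9.50), (1.7, 0.627), (293, 885.4), (0.24, 0.549), (3.6, 1.003), (11.8, 1.56), (31.4, 3.99), (1.6, 0.462), (1.3, 0.485), (19.5, 4.01), (0.79, 0.416), (0.19, 0.046), (1.3, 0.295)),
    "JEX":  ((134, 85.21), (3.1, 2.49), (3.1, 3.80), (17.9, 7.47), (1.7, 0.652), (247, 664.1), (0.12, 0.369), (3.9, 0.832), (11.6, 1.45), (31.4, 6.32), (1.4, 0.434), (1.1, 0.526), (17.8, 4.45), (0.93, 0.491), (0.23, 0.070), (1.4, 0.412)),
    "NZFX": ((138, 96.88), (3.5, 3.00), (1.7, 2.94), (20.1, 7.08), (1.7, 0.555), (232, 944.9), (0.08, 0.343), (3.4, 0.822), (10.7, 1.74), (29.6, 5.10), (1.6, 0.437), (1.3, 0.765), (20.2, 4.22), (1.03, 0.454), (0.22, 0.085), (1.5, 0.504)),
    "SH":   ((153, 106.91), (3.3, 1.49), (8.2, 4.78), (17.8, 8.81), (1.5, 0.763), (261, 688.2), (0.09, 0.284), (3.7, 0.844), (11.6, 1.49), (29.9, 3.93), (2.1, 0.454), (1.9, 0.887), (20.2, 3.46), (0.74, 0.602), (0.20, 0.083), (1.4, 0.650)),
    "SRX":  ((151, 93.30), (3.1, 2.55), (3.2, 4.09), (19.7, 7.68), (1.6, 0.516), (170, 400.8), (0.18, 0.527), (3.8, 0.771), (11.9, 1.40), (31.3, 5.68), (1.4, 0.444), (1.1, 0.514), (18.6, 4.20), (0.91, 0.417), (0.21, 0.056), (1.4, 0.295)),
}

#: Which roster breed tokens each analysis group requires on a farm.
GROUP_REQUIREMENTS: dict[str, tuple[str, ...]] = {
    "AYRX": ("AYR",), "HF": ("HF",), "HFJE": ("HF", "JE"),
    "HFSR": ("HF", "SR"), "JEX": ("JE",), "NZFX": ("NZF",),
    "SH": ("SH",), "SRX": ("SR",),
}

#: Per-date probability that a record is incomplete (no production/health/FA
#: block), calibrated so expected complete cohorts match the reported
#: 299 / 757 / 772 / 613 records on D1-D4 out of 1,070 cows.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "D1": 1 - 299 / 1070, "D2": 1 - 757 / 1070,
    "D3": 1 - 772 / 1070, "D4": 1 - 613 / 1070,
}


# --------------------------------------------------------------------------
# Trait distributions
# --------------------------------------------------------------------------

@dataclass
class TraitDistribution:
    """A univariate trait distribution parameterized by mean and SD.

    Families:

    ``truncated_normal``
        Normal truncated below at ``lower_bound``. The underlying (mu, sigma)
        are solved so the *truncated* distribution has the requested mean and
        SD; when that is unattainable (a left-truncated normal cannot exceed
        a coefficient of variation of 1) the parent normal N(mean, sd) is
        truncated as-is and ``realized_moments`` reports the shifted moments.
    ``lognormal_moment_matched``
        sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    ``negbinom_moment_matched``
        r = mean^2/(sd^2 - mean), p = mean/sd^2; Poisson fallback when
        sd^2 <= mean.
    ``poisson``
        Poisson(mean); sd is ignored.
    """

    family: str
    mean: float
    sd: float
    lower_bound: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sd <= 0 and self.family != "poisson":
            raise ConfigError(f"sd must be > 0, got {self.sd}")
        if self.family not in ("truncated_normal", "lognormal_moment_matched",
                               "negbinom_moment_matched", "poisson"):
            raise ConfigError(f"unknown distribution family {self.family!r}")

    # -- truncated normal ---------------------------------------------------
    def _truncnorm_params(self) -> tuple[float, float, bool]:
        """(mu, sigma, matched) of the parent normal."""
        if "tn" in self._cache:
            return self._cache["tn"]
        lb, m, s = self.lower_bound, self.mean, self.sd
        matched = False
        mu, sigma = m, s
        # CV of a left-truncated normal is bounded by 1 (exponential limit)
        if s / max(m - lb, 1e-12) < 0.95:
            def resid(p):
                mu_, logsig = p
                sig = math.exp(logsig)
                a = (lb - mu_) / sig
                tm, tv = stats.truncnorm.stats(a, np.inf, loc=mu_, scale=sig,
                                               moments="mv")
                return [float(tm) - m, math.sqrt(float(tv)) - s]
            sol = optimize.root(resid, [m, math.log(s)], method="hybr")
            if sol.success and max(abs(r) for r in sol.fun) < 1e-6 * max(1.0, s):
                mu, sigma = float(sol.x[0]), math.exp(float(sol.x[1]))
                matched = True
        self._cache["tn"] = (mu, sigma, matched)
        return self._cache["tn"]

    def _lognorm_params(self) -> tuple[float, float]:
        cv2 = (self.sd / self.mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.mean) - sigma2 / 2
        return mu, math.sqrt(sigma2)

    def _negbinom_params(self) -> Optional[tuple[float, float]]:
        v = self.sd ** 2
        if v <= self.mean:
            return None  # Poisson fallback
        r = self.mean ** 2 / (v - self.mean)
        p = self.mean / v
        return r, p

    def realized_moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the distribution actually sampled."""
        if self.family == "truncated_normal":
            mu, sigma, matched = self._truncnorm_params()
            if matched:
                return self.mean, self.sd
            a = (self.lower_bound - mu) / sigma
            tm, tv = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                           moments="mv")
            return float(tm), math.sqrt(float(tv))
        if self.family == "negbinom_moment_matched":
            if self._negbinom_params() is None:
                return self.mean, math.sqrt(self.mean)
            return self.mean, self.sd
        if self.family == "poisson":
            return self.mean, math.sqrt(self.mean)
        return self.mean, self.sd

    def median(self) -> float:
        """Analytic median (notably exp(mu) for the lognormal family)."""
        return float(self.ppf(np.array([0.5]))[0])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "truncated_normal":
            mu, sigma, _ = self._truncnorm_params()
            a = (self.lower_bound - mu) / sigma
            u = rng.random(n)
            lo = stats.norm.cdf(a)
            return stats.norm.ppf(lo + u * (1 - lo)) * sigma + mu
        if self.family == "lognormal_moment_matched":
            mu, sig = self._lognorm_params()
            return rng.lognormal(mu, sig, n)
        if self.family == "negbinom_moment_matched":
            params = self._negbinom_params()
            if params is None:
                return rng.poisson(self.mean, n).astype(float)
            r, p = params
            return rng.negative_binomial(r, p, n).astype(float)
        return rng.poisson(self.mean, n).astype(float)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Quantile function (used by the Gaussian-copula hook)."""
        q = np.asarray(q, dtype=float)
        if self.family == "truncated_normal":
            mu, sigma, _ = self._truncnorm_params()
            a = (self.lower_bound - mu) / sigma
            return stats.truncnorm.ppf(q, a, np.inf, loc=mu, scale=sigma)
        if self.family == "lognormal_moment_matched":
            mu, sig = self._lognorm_params()
            return stats.lognorm.ppf(q, sig, scale=math.exp(mu))
        if self.family == "negbinom_moment_matched":
            params = self._negbinom_params()
            if params is None:
                return stats.poisson.ppf(q, self.mean)
            r, p = params
            return stats.nbinom.ppf(q, r, p)
        return stats.poisson.ppf(q, self.mean)

    def to_dict(self) -> dict:
        return {"family": self.family, "mean": self.mean, "sd": self.sd,
                "lower_bound": self.lower_bound}

    @classmethod
    def from_dict(cls, d: dict) -> "TraitDistribution":
        return cls(family=d["family"], mean=float(d["mean"]), sd=float(d["sd"]),
                   lower_bound=float(d.get("lower_bound", 0.0)))


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------

@dataclass
class CorrelationSpec:
    """Optional trait-by-trait correlation applied through a Gaussian copula."""

    traits: tuple[str, ...]
    matrix: np.ndarray

    def validate(self) -> None:
        r = np.asarray(self.matrix, dtype=float)
        k = len(self.traits)
        if r.shape != (k, k):
            raise ConfigError("correlation matrix shape does not match traits")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ConfigError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ConfigError("correlation matrix must be positive semi-definite")


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a herd: roster, trait table, variance
    components, missingness, and the seed."""

    farm_roster: list[FarmInfo]
    breed_trait_table: dict[str, dict[str, TraitDistribution]]
    group_weights: dict[str, float]
    variance_components: dict[str, tuple[float, float]]  # trait -> (farm_sd, season_sd)
    missingness: dict[str, float]
    generation_mix: tuple[float, float, float] = (0.20, 0.40, 0.40)  # purebred, F1, F2plus
    correlation_spec: Optional[CorrelationSpec] = None
    seed: int = 1

    def validate(self) -> None:
        if not self.farm_roster:
            raise ConfigError("farm roster is empty")
        for farm in self.farm_roster:
            if farm.n_cows < 1:
                raise ConfigError(f"farm {farm.farm_id} has n_cows < 1")
        if abs(sum(self.generation_mix) - 1.0) > 1e-9:
            raise ConfigError("generation_mix must sum to 1")
        for d in DATE_CODES:
            p = self.missingness.get(d, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"missingness[{d}] must be in [0, 1]")
        if self.correlation_spec is not None:
            self.correlation_spec.validate()

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "seed": self.seed,
            "generation_mix": list(self.generation_mix),
            "missingness": dict(self.missingness),
            "farm_roster": [
                {"farm_id": f.farm_id, "management": f.management,
                 "n_cows": f.n_cows, "calving_pattern": f.calving_pattern,
                 "breeds": list(f.breeds)} for f in self.farm_roster],
            "group_weights": dict(self.group_weights),
            "variance_components": {t: list(v) for t, v in self.variance_components.items()},
            "breed_trait_table": {
                g: {t: dist.to_dict() for t, dist in traits.items()}
                for g, traits in self.breed_trait_table.items()},
        }
        if self.correlation_spec is not None:
            d["correlation"] = {
                "traits": list(self.correlation_spec.traits),
                "matrix": np.asarray(self.correlation_spec.matrix).tolist()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        corr = None
        if "correlation" in d:
            corr = CorrelationSpec(
                traits=tuple(d["correlation"]["traits"]),
                matrix=np.asarray(d["correlation"]["matrix"], dtype=float))
        cfg = cls(
            farm_roster=[FarmInfo(farm_id=int(f["farm_id"]),
                                  management=f["management"],
                                  n_cows=int(f["n_cows"]),
                                  calving_pattern=f["calving_pattern"],
                                  breeds=tuple(f["breeds"]))
                         for f in d["farm_roster"]],
            breed_trait_table={
                g: {t: TraitDistribution.from_dict(td) for t, td in traits.items()}
                for g, traits in d["breed_trait_table"].items()},
            group_weights={g: float(w) for g, w in d["group_weights"].items()},
            variance_components={t: (float(v[0]), float(v[1]))
                                 for t, v in d["variance_components"].items()},
            missingness={k: float(v) for k, v in d["missingness"].items()},
            generation_mix=tuple(float(x) for x in d.get("generation_mix", (0.2, 0.4, 0.4))),
            correlation_spec=corr,
            seed=int(d.get("seed", 1)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _family_for(trait: str) -> str:
    if trait == "scc_kcells_ml":
        return "lognormal_moment_matched"
    if trait == "treatments_n":
        return "negbinom_moment_matched"
    return "truncated_normal"


def default_config(seed: int = 1) -> GeneratorConfig:
    """The study-calibrated default configuration.

    Farm roster and cow counts reproduce the printed 17-farm table (1,070
    cows in total); trait distributions carry the printed per-group mean/SD
    pairs; the generation mix is 20% purebred / 40% F1 / 40% F2+. Default
    farm-intercept and season-shift SDs are set to 30% and 15% of the
    across-group mean trait SD for continuous traits (zero for SCC and
    treatment counts, whose skewed families absorb herd-level spread), and
    traits are independent unless a correlation spec is supplied.
    """
    roster = [FarmInfo(*row) for row in FARM_ROSTER_TABLE]
    table: dict[str, dict[str, TraitDistribution]] = {}
    for group, cells in _GROUP_TRAIT_TABLE.items():
        table[group] = {
            trait: TraitDistribution(_family_for(trait), mean, sd)
            for trait, (mean, sd) in zip(_TRAIT_ROWS, cells)
        }
    vc: dict[str, tuple[float, float]] = {}
    for i, trait in enumerate(_TRAIT_ROWS):
        if trait in ("scc_kcells_ml", "treatments_n", "n6_n3_ratio"):
            vc[trait] = (0.0, 0.0)
        else:
            mean_sd = float(np.mean([cells[i][1] for cells in _GROUP_TRAIT_TABLE.values()]))
            vc[trait] = (0.30 * mean_sd, 0.15 * mean_sd)
    cfg = GeneratorConfig(
        farm_roster=roster,
        breed_trait_table=table,
        group_weights={g: float(n) for g, n in GROUP_SIZES.items()},
        variance_components=vc,
        missingness=dict(DEFAULT_MISSINGNESS),
        seed=seed,
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Herd generation
# --------------------------------------------------------------------------

def _largest_remainder(total: int, weights: list[float]) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ConfigError("allocation weights must be positive")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    for idx in order[:rem]:
        counts[idx] += 1
    return counts.tolist()


def _eligible_groups(farm: FarmInfo, groups: list[str]) -> list[str]:
    present = set(farm.breeds)
    return [g for g in groups if set(GROUP_REQUIREMENTS.get(g, (g,))) <= present]


def _draw_traits(group_dists: dict[str, TraitDistribution], rng: np.random.Generator,
                 n: int, corr: Optional[CorrelationSpec]) -> dict[str, np.ndarray]:
    """Sample all SIM_TRAITS for n records, independently or via copula."""
    out: dict[str, np.ndarray] = {}
    copula_traits: tuple[str, ...] = ()
    if corr is not None:
        copula_traits = tuple(t for t in corr.traits if t in group_dists)
        k = len(copula_traits)
        idx = [corr.traits.index(t) for t in copula_traits]
        r = np.asarray(corr.matrix, dtype=float)[np.ix_(idx, idx)]
        z = rng.multivariate_normal(np.zeros(k), r, size=n, method="cholesky")
        u = stats.norm.cdf(z)
        # keep quantiles strictly inside (0, 1)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        for j, t in enumerate(copula_traits):
            out[t] = np.asarray(group_dists[t].ppf(u[:, j]), dtype=float)
    for t in SIM_TRAITS:
        if t in out:
            continue
        out[t] = group_dists[t].sample(rng, n)
    return out


def generate_herd(config: GeneratorConfig) -> HerdDataset:
    """Simulate a herd dataset under ``config``.

    Cows are allocated to farms per the roster and to breed groups
    proportionally to ``group_weights`` among the groups each farm's breed
    list supports (largest-remainder rounding). Each cow contributes up to
    four date records; continuous traits receive an additive farm random
    intercept and a season (date) shift, then are clipped at the trait's
    lower bound. Records drawn as missing keep background fields but carry
    no production/health/FA block. Identical seeds give identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = sorted(config.breed_trait_table)
    for g in groups:
        missing = [t for t in SIM_TRAITS if t not in config.breed_trait_table[g]]
        if missing:
            raise ConfigError(f"group {g} lacks trait distribution(s): {missing}")

    # cow roster: (cow_id, farm, group, generation)
    cows: list[tuple[str, FarmInfo, str]] = []
    for farm in config.farm_roster:
        eligible = _eligible_groups(farm, groups)
        if not eligible:
            raise ConfigError(
                f"farm {farm.farm_id} breed list {farm.breeds} supports no "
                f"group in the trait table")
        weights = [config.group_weights.get(g, 0.0) for g in eligible]
        counts = _largest_remainder(farm.n_cows, weights)
        i = 0
        for g, c in zip(eligible, counts):
            for _ in range(c):
                i += 1
                cows.append((f"F{farm.farm_id:02d}C{i:03d}", farm, g))
    generations = rng.choice(
        ["purebred", "F1", "F2plus"], size=len(cows), p=list(config.generation_mix))

    # farm intercepts and season shifts per trait (continuous shifts only)
    farm_eff: dict[tuple[int, str], float] = {}
    for farm in config.farm_roster:
        for t in SIM_TRAITS:
            sd = config.variance_components.get(t, (0.0, 0.0))[0]
            farm_eff[(farm.farm_id, t)] = rng.normal(0.0, sd) if sd > 0 else 0.0
    season_eff: dict[tuple[str, str], float] = {}
    for d in DATE_CODES:
        for t in SIM_TRAITS:
            sd = config.variance_components.get(t, (0.0, 0.0))[1]
            season_eff[(d, t)] = rng.normal(0.0, sd) if sd > 0 else 0.0

    cow_idx_by_group: dict[str, list[int]] = {}
    for i, (_, _, g) in enumerate(cows):
        cow_idx_by_group.setdefault(g, []).append(i)

    records: list[CowRecord] = [None] * (len(cows) * len(DATE_CODES))  # type: ignore
    for d_i, date in enumerate(DATE_CODES):
        p_miss = config.missingness.get(date, 0.0)
        for g in groups:
            idxs = cow_idx_by_group.get(g, [])
            if not idxs:
                continue
            n = len(idxs)
            draws = _draw_traits(config.breed_trait_table[g], rng, n, config.correlation_spec)
            miss = rng.random(n) < p_miss
            for j, ci in enumerate(idxs):
                cow_id, farm, _ = cows[ci]
                vals = {}
                for t in SIM_TRAITS:
                    v = draws[t][j] + farm_eff[(farm.farm_id, t)] + season_eff[(date, t)]
                    lb = config.breed_trait_table[g][t].lower_bound
                    vals[t] = max(v, lb)
                ratio = vals["n6_pct"] / vals["n3_pct"] if vals["n3_pct"] > 0 else 0.0
                incomplete = bool(miss[j])
                fa = None if incomplete else FattyAcidProfile(
                    oa_pct=vals["oa_pct"], cla9_pct=vals["cla9_pct"],
                    n3_pct=vals["n3_pct"],
                    epa_dpa_dha_pct=min(vals["epa_dpa_dha_pct"], vals["n3_pct"]),
                    c12_pct=vals["c12_pct"], c14_pct=vals["c14_pct"],
                    c16_pct=vals["c16_pct"], n6_pct=vals["n6_pct"],
                    n6_n3_ratio=ratio)
                rec = CowRecord(
                    cow_id=cow_id, farm_id=farm.farm_id,
                    management=farm.management, date_code=date,
                    breed_code=g, generation=str(generations[ci]),
                    days_in_milk=float(round(vals["days_in_milk"])),
                    concentrate_kg_day=vals["concentrate_kg_day"],
                    forage_kg_day=vals["forage_kg_day"],
                    yield_l_day=None if incomplete else max(vals["yield_l_day"], vals["solids_kg_day"]),
                    solids_kg_day=None if incomplete else vals["solids_kg_day"],
                    scc_kcells_ml=None if incomplete else vals["scc_kcells_ml"],
                    treatments_n=None if incomplete else int(vals["treatments_n"]),
                    fa=fa)
                records[ci * len(DATE_CODES) + d_i] = rec
    farm_table = {f.farm_id: f for f in config.farm_roster}
    ds = HerdDataset(records=list(records), farm_table=farm_table)
    return ds


def inject_rare_combinations(
    dataset: HerdDataset,
    spec: list[tuple[str, int, int]],
    donor_group: str = "HF",
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
) -> HerdDataset:
    """Append sub-threshold rare breed-combination cows to a herd.

    ``spec`` lists (breed label, farm_id, n cows); traits are drawn from the
    ``donor_group`` distributions of ``config`` (default study config) so the
    inclusion filter can be exercised against realistic records. Returns a
    new dataset; the input is unchanged.
    """
    cfg = config if config is not None else default_config()
    if donor_group not in cfg.breed_trait_table:
        raise ConfigError(f"donor group {donor_group!r} not in trait table")
    rng = np.random.default_rng(seed)
    new_records = list(dataset.records)
    dists = cfg.breed_trait_table[donor_group]
    for label, farm_id, n in spec:
        if n <= 0:
            raise ValueError(f"n must be > 0 for injected group {label!r}")
        if farm_id not in dataset.farm_table:
            raise HerdError(f"farm {farm_id} not present in dataset")
        farm = dataset.farm_table[farm_id]
        for k in range(n):
            cow_id = f"F{farm_id:02d}R{label}{k:02d}"
            for date in DATE_CODES:
                draws = {t: float(dists[t].sample(rng, 1)[0]) for t in SIM_TRAITS}
                ratio = draws["n6_pct"] / draws["n3_pct"] if draws["n3_pct"] > 0 else 0.0
                fa = FattyAcidProfile(
                    oa_pct=draws["oa_pct"], cla9_pct=draws["cla9_pct"],
                    n3_pct=draws["n3_pct"],
                    epa_dpa_dha_pct=min(draws["epa_dpa_dha_pct"], draws["n3_pct"]),
                    c12_pct=draws["c12_pct"], c14_pct=draws["c14_pct"],
                    c16_pct=draws["c16_pct"], n6_pct=draws["n6_pct"],
                    n6_n3_ratio=ratio)
                new_records.append(CowRecord(
                    cow_id=cow_id, farm_id=farm_id, management=farm.management,
                    date_code=date, breed_code=label,
                    days_in_milk=float(round(draws["days_in_milk"])),
                    concentrate_kg_day=draws["concentrate_kg_day"],
                    forage_kg_day=draws["forage_kg_day"],
                    yield_l_day=max(draws["yield_l_day"], draws["solids_kg_day"]),
                    solids_kg_day=draws["solids_kg_day"],
                    scc_kcells_ml=draws["scc_kcells_ml"],
                    treatments_n=int(draws["treatments_n"]), fa=fa))
    return HerdDataset(records=new_records, farm_table=dict(dataset.farm_table))


def simulate_group_records(
    config: GeneratorConfig,
    rng: np.random.Generator,
    group_sizes: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Draw complete LI-P records group-by-group with no farm/season effects.

    This is the sampling scheme behind the rank-recovery experiments: each
    breed group contributes its published record count, drawn straight from
    its trait distributions. Returns a long DataFrame with one row per record
    carrying breed_code, cow_id/date keys, and all 13 LI-P variables.
    """
    sizes = group_sizes if group_sizes is not None else {
        g: int(round(config.group_weights[g])) for g in sorted(config.breed_trait_table)}
    frames = []
    for g in sorted(sizes):
        n = sizes[g]
        draws = _draw_traits(config.breed_trait_table[g], rng, n, config.correlation_spec)
        df = pd.DataFrame({t: draws[t] for t in SIM_TRAITS})
        with np.errstate(divide="ignore"):
            df["n6_n3_ratio"] = np.where(df["n3_pct"] > 0,
                                         df["n6_pct"] / df["n3_pct"], 0.0)
        df["epa_dpa_dha_pct"] = np.minimum(df["epa_dpa_dha_pct"], df["n3_pct"])
        df["breed_code"] = g
        df["cow_id"] = [f"{g}{i:04d}" for i in range(n)]
        df["date_code"] = "D2"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
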