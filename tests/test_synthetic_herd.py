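"""Synthetic herd generator: roster calibration, distribution families,
determinism and rare-combination injection."""

import math

import numpy as np
import pytest
from scipy import stats

from liprod.herd_model import DATE_CODES, apply_inclusion_criteria, write_herd_csv
from liprod.synthetic_herd import (
    ANALYSIS_GROUPS,
    ConfigError,
    CorrelationSpec,
    GeneratorConfig,
    TraitDistribution,
    default_config,
    generate_herd,
    inject_rare_combinations,
    simulate_group_records,
)


# -- default configuration --------------------------------------------------

def test_default_roster_matches_printed_table(study_config):
    roster = {f.farm_id: f for f in study_config.farm_roster}
    assert len(roster) == 17
    farm1 = roster[1]
    assert (farm1.management, farm1.n_cows, farm1.calving_pattern) == ("organic", 40, "spring")
    assert sum(f.n_cows for f in study_config.farm_roster) == 1070
    assert sum(1 for f in study_config.farm_roster if f.management == "organic") == 7


def test_default_trait_table_calibration(study_config):
    y = study_config.breed_trait_table["NZFX"]["yield_l_day"]
    assert (y.mean, y.sd) == (20.1, 7.08)
    assert study_config.breed_trait_table["NZFX"]["scc_kcells_ml"].family == "lognormal_moment_matched"
    assert study_config.breed_trait_table["AYRX"]["treatments_n"].family == "negbinom_moment_matched"
    assert set(study_config.breed_trait_table) == set(ANALYSIS_GROUPS)
    assert study_config.generation_mix == (0.20, 0.40, 0.40)


def test_config_yaml_round_trip(tmp_path, study_config):
    path = tmp_path / "cfg.yaml"
    study_config.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.to_dict() == study_config.to_dict()


# -- trait distributions ----------------------------------------------------

def test_truncated_normal_moment_matching():
    rng = np.random.default_rng(0)
    dist = TraitDistribution("truncated_normal", 20.1, 7.08)
    x = dist.sample(rng, 100_000)
    assert x.min() >= 0
    se = 7.08 / math.sqrt(100_000)
    assert abs(x.mean() - 20.1) < 3 * se
    assert abs(x.std(ddof=1) - 7.08) < 0.1
    assert dist.realized_moments() == (20.1, 7.08)


def test_truncated_normal_high_cv_fallback_reports_realized_moments():
    # CV > 1 is unattainable for a left-truncated normal; the parent normal
    # is truncated as-is and realized moments are shifted upward.
    dist = TraitDistribution("truncated_normal", 1.7, 2.94)
    m, s = dist.realized_moments()
    assert m > 1.7 and s < 2.94
    x = dist.sample(np.random.default_rng(1), 100_000)
    assert abs(x.mean() - m) < 3 * s / math.sqrt(100_000) + 0.02
    assert x.min() >= 0


def test_lognormal_moment_matched_median():
    # mu = ln(mean) - sigma^2/2 with sigma^2 = ln(1 + CV^2)
    dist = TraitDistribution("lognormal_moment_matched", 232.0, 944.9)
    assert dist.median() == pytest.approx(55.3, abs=0.1)
    x = dist.sample(np.random.default_rng(2), 200_000)
    assert abs(x.mean() - 232.0) < 3 * 944.9 / math.sqrt(200_000)


def test_negbinom_moment_matched_and_poisson_fallback():
    rng = np.random.default_rng(3)
    nb = TraitDistribution("negbinom_moment_matched", 0.41, 0.818)
    x = nb.sample(rng, 200_000)
    assert abs(x.mean() - 0.41) < 3 * 0.818 / math.sqrt(200_000)
    assert abs(x.std(ddof=1) - 0.818) < 0.02
    under = TraitDistribution("negbinom_moment_matched", 2.0, 1.0)  # sd^2 < mean
    assert under.realized_moments() == (2.0, math.sqrt(2.0))


@pytest.mark.parametrize("group", ["NZFX", "SH"])
def test_moment_recovery_all_traits(study_config, group):
    """Simulated mean and SD converge to the distribution's realized moments."""
    rng = np.random.default_rng(11)
    n = 20_000
    for trait, dist in study_config.breed_trait_table[group].items():
        if trait == "n6_n3_ratio":
            continue  # derived, never sampled
        m, s = dist.realized_moments()
        x = dist.sample(rng, n)
        se_mean = s / math.sqrt(n)
        assert abs(x.mean() - m) < 4 * se_mean, trait
        # SD tolerance via the large-sample SE of the sample SD, inflated by
        # excess kurtosis for the skewed families
        kappa = float(stats.kurtosis(x, fisher=True))
        se_sd = s * math.sqrt((2 + max(kappa, 0.0)) / (4 * n)) * 2
        assert abs(x.std(ddof=1) - s) < 6 * se_sd + 0.01 * s, trait


def test_scc_draws_positive_and_right_skewed(study_config):
    dist = study_config.breed_trait_table["HF"]["scc_kcells_ml"]
    x = dist.sample(np.random.default_rng(4), 50_000)
    assert (x > 0).all()
    assert stats.skew(x) > 1.0


# -- herd generation --------------------------------------------------------

def test_default_herd_structure(default_herd):
    assert len(default_herd.farm_table) == 17
    assert len({r.cow_id for r in default_herd.records}) == 1070
    assert len(default_herd) == 1070 * 4
    assert {r.breed_code for r in default_herd.records} == set(ANALYSIS_GROUPS)
    default_herd.validate()


def test_same_seed_gives_identical_csv_bytes(tmp_path, study_config):
    paths = []
    for i in (1, 2):
        ds = generate_herd(default_config(seed=7))
        p = tmp_path / f"h{i}.csv"
        write_herd_csv(ds, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_ratio_consistency_is_exact(default_herd):
    for rec in default_herd.records:
        if rec.fa is not None:
            assert rec.fa.n6_n3_ratio == rec.fa.n6_pct / rec.fa.n3_pct


def test_missingness_drives_per_date_cohorts(default_herd):
    from liprod.herd_model import filter_complete_records
    expected = {"D1": 299, "D2": 757, "D3": 772, "D4": 613}
    for date, n_exp in expected.items():
        n = len(filter_complete_records(default_herd, date))
        # binomial noise around the calibrated completeness probability
        p = n_exp / 1070
        assert abs(n - n_exp) < 4 * math.sqrt(1070 * p * (1 - p))


def test_farm_intercept_induces_positive_icc(study_config):
    """Components-of-variance estimate of the farm ICC is positive when the
    farm-intercept SD is positive."""
    ds = generate_herd(default_config(seed=5))
    rows = [(r.farm_id, r.yield_l_day) for r in ds.records
            if r.breed_code == "HF" and r.yield_l_day is not None]
    farms = sorted({f for f, _ in rows})
    groups = [[y for f, y in rows if f == fid] for fid in farms]
    grand = np.mean([y for _, y in rows])
    k = len(groups)
    n_i = np.array([len(g) for g in groups])
    msb = sum(n * (np.mean(g) - grand) ** 2 for n, g in zip(n_i, groups)) / (k - 1)
    msw = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / (sum(n_i) - k)
    n0 = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (k - 1)
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    assert icc > 0.02


def test_copula_correlation_is_recovered(study_config):
    traits = ("n3_pct", "epa_dpa_dha_pct")
    spec = CorrelationSpec(traits=traits, matrix=np.array([[1.0, 0.7], [0.7, 1.0]]))
    cfg = default_config(seed=9)
    cfg.correlation_spec = spec
    df = simulate_group_records(cfg, np.random.default_rng(9),
                                group_sizes={"NZFX": 5000})
    r = np.corrcoef(df["n3_pct"], df["epa_dpa_dha_pct"])[0, 1]
    assert 0.55 < r < 0.8


def test_invalid_correlation_matrix_rejected():
    with pytest.raises(ConfigError):
        CorrelationSpec(traits=("a", "b"),
                        matrix=np.array([[1.0, 0.5], [0.4, 1.0]])).validate()


def test_farm_with_unsupported_breeds_is_config_error(study_config):
    cfg = default_config(seed=1)
    cfg.farm_roster[0].breeds = ("MO", "BS")  # no analysis group available
    with pytest.raises(ConfigError):
        generate_herd(cfg)


def test_missing_trait_distribution_is_config_error():
    cfg = default_config(seed=1)
    del cfg.breed_trait_table["HF"]["yield_l_day"]
    with pytest.raises(ConfigError):
        generate_herd(cfg)


# -- rare-combination injection ---------------------------------------------

def test_inject_empty_spec_is_identity(default_herd):
    out = inject_rare_combinations(default_herd, [])
    assert len(out) == len(default_herd)


def test_injected_singleton_fails_inclusion(default_herd):
    out = inject_rare_combinations(default_herd, [("BFMO", 10, 1)], seed=3)
    assert len(out) == len(default_herd) + 4
    retained, _ = apply_inclusion_criteria(out)
    assert "BFMO" not in retained
    assert retained == set(ANALYSIS_GROUPS)


def test_injected_group_meeting_thresholds_passes_inclusion(default_herd):
    spec = [("BFMO", 1, 2), ("BFMO", 2, 2), ("BFMO", 3, 2)]  # 6 cows, 3 farms
    out = inject_rare_combinations(default_herd, spec, seed=3)
    retained, _ = apply_inclusion_criteria(out)
    assert "BFMO" in retained


def test_inject_rejects_nonpositive_n(default_herd):
    with pytest.raises(ValueError):
        inject_rare_combinations(default_herd, [("BFMO", 1, 0)])
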