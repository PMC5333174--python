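import numpy as np
import pytest

import qphylo as q
from qphylo.filtering import MISSING, MalformedInputError, windowed_entropy

from conftest import make_noiseless_dataset


# --------------------------------------------------------------------------- #
# dimeric entropy


def test_entropy_of_homopolymer_is_zero():
    assert q.dimeric_entropy("AAAAAAAA") == 0.0


def test_entropy_of_ac_repeat_matches_closed_form():
    # 16 bp of (AC)8: dimers AC x8, CA x7 out of 15
    p = np.array([8 / 15, 7 / 15])
    expected = float(-(p * np.log2(p)).sum() / 4)
    assert q.dimeric_entropy("AC" * 8) == pytest.approx(expected)
    assert expected == pytest.approx(0.249, abs=5e-4)


def test_entropy_of_random_windows_is_high():
    rng = np.random.default_rng(0)
    for _ in range(100):
        window = "".join(rng.choice(list("ACGT"), size=1000))
        assert q.dimeric_entropy(window) > 0.9


def test_entropy_bounds_and_short_window_error():
    rng = np.random.default_rng(1)
    for length in (2, 3, 5, 17, 64):
        for _ in range(20):
            w = "".join(rng.choice(list("ACGTN"), size=length))
            assert 0.0 <= q.dimeric_entropy(w) <= 1.0
    with pytest.raises(ValueError):
        q.dimeric_entropy("A")


def test_windowed_entropy_agrees_with_scalar_function():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    window = 30
    vector = windowed_entropy(seq, window)
    half = window // 2
    for pos in (0, 10, 150, 299):
        a = max(pos - half, 0)
        b = min(pos - half + window, len(seq))
        assert vector[pos] == pytest.approx(q.dimeric_entropy(seq[a:b]))


# --------------------------------------------------------------------------- #
# STR masking


def test_str_tract_interior_is_masked():
    ref = q.simulate_reference(5000, [(2000, "AC", 20)], seed=7)
    intervals = q.mask_str_regions(ref, q.FilterConfig())
    assert intervals, "tract not detected"
    tract_core = set(range(2010, 2030))
    masked = {p for s, e in intervals for p in range(s, e)}
    assert tract_core <= masked


def test_homopolymer_run_is_masked():
    seq = "ACGT" * 100 + "A" * 40 + "GTCA" * 100
    intervals = q.mask_str_regions(seq, q.FilterConfig())
    masked = {p for s, e in intervals for p in range(s, e)}
    assert set(range(410, 430)) <= masked


def test_random_background_mostly_unmasked():
    cfg = q.FilterConfig()
    frac_masked = []
    for seed in range(100):
        ref = q.simulate_reference(2000, seed=seed)
        masked = sum(e - s for s, e in q.mask_str_regions(ref, cfg))
        frac_masked.append(masked / 2000)
    assert np.mean(frac_masked) < 0.01


def test_masking_deterministic():
    ref = q.simulate_reference(3000, [(1000, "AT", 15)], seed=3)
    cfg = q.FilterConfig()
    assert q.mask_str_regions(ref, cfg) == q.mask_str_regions(ref, cfg)


# --------------------------------------------------------------------------- #
# per-sample-site calling (rules pinned to the published thresholds)


def obs_rows(*rows):
    return [(base, count, bq, mq) for base, count, bq, mq in rows]


def test_depth_below_two_is_missing_under_relaxed_rules():
    cfg = q.FilterConfig.relaxed()
    assert q.call_sample_site(obs_rows(("G", 1, 30, 50)), cfg) == MISSING
    assert q.call_sample_site(obs_rows(("G", 2, 30, 50)), cfg) == "G"


def test_minor_allele_boundary_ten_percent_kept_above_excluded():
    cfg = q.FilterConfig.relaxed()
    assert q.call_sample_site(
        obs_rows(("G", 9, 30, 50), ("T", 1, 30, 50)), cfg
    ) == "G"  # minor = 10% exactly: retained
    assert q.call_sample_site(
        obs_rows(("G", 8, 30, 50), ("T", 2, 30, 50)), cfg
    ) == MISSING  # minor = 20%: excluded


def test_stringent_preset_depth_ten_single_allele():
    cfg = q.FilterConfig.stringent()
    assert cfg.min_depth == 10 and cfg.max_minor_fraction == 0.0
    assert q.call_sample_site(obs_rows(("G", 12, 30, 50)), cfg) == "G"
    assert q.call_sample_site(obs_rows(("G", 9, 30, 50)), cfg) == MISSING
    assert q.call_sample_site(
        obs_rows(("G", 30, 30, 50), ("T", 1, 30, 50)), cfg
    ) == MISSING


def test_quality_gates_discard_failing_read_sets():
    cfg = q.FilterConfig.relaxed()
    # base quality 14 < 15: the G reads are discarded entirely
    assert q.call_sample_site(obs_rows(("G", 10, 14, 50)), cfg) == MISSING
    # mapping quality 9 < 10 likewise
    assert q.call_sample_site(obs_rows(("G", 10, 30, 9)), cfg) == MISSING
    assert q.call_sample_site(obs_rows(("G", 10, 15, 10)), cfg) == "G"


def test_conflicting_indel_flags_raise():
    with pytest.raises(MalformedInputError):
        q.call_sample_site(
            [("G", 5, 30, 50, False), ("T", 5, 30, 50, True)], q.FilterConfig()
        )


# --------------------------------------------------------------------------- #
# matrix construction


def _manual_observation_set(n_samples, calls_by_pos, region=1000):
    """Build an ObservationSet where calls_by_pos maps pos -> list of
    (sample_index, base) clean deep observations."""
    import pandas as pd

    from qphylo.simulate import ObservationSet

    samples = [f"s{i:02d}" for i in range(n_samples)]
    rows = []
    for pos, calls in calls_by_pos.items():
        for idx, base in calls:
            rows.append((samples[idx], pos, base, 10, 30.0, 50.0, False))
    table = pd.DataFrame(
        rows,
        columns=["sample", "pos", "base", "count", "base_quality",
                 "mapping_quality", "is_indel"],
    )
    coverage = {s: ((0, region),) for s in samples}
    return ObservationSet(table=table, coverage=coverage, samples=samples)


def test_call_rate_boundary_kept_at_0604_dropped_at_0583():
    """48 samples: a position callable in 29 (rate 0.604) survives the 60%
    rule; callable in 28 (0.583) does not."""
    n = 48
    calls29 = [(i, "G" if i else "T") for i in range(29)]
    calls28 = [(i, "G" if i else "T") for i in range(28)]
    obs = _manual_observation_set(n, {100: calls29, 200: calls28})
    matrix = q.build_matrix(obs, None, q.FilterConfig())
    assert list(matrix.positions) == [100]


def test_whitelisted_branch_naming_snp_exempt_from_call_rate():
    n = 48
    calls = [(i, "G" if i else "T") for i in range(24)]  # rate 0.5
    obs = _manual_observation_set(n, {100: calls})
    assert q.build_matrix(obs, None, q.FilterConfig()).is_empty()
    kept = q.build_matrix(obs, None, q.FilterConfig(whitelist=frozenset([100])))
    assert list(kept.positions) == [100]


def test_invariant_positions_dropped():
    obs = _manual_observation_set(4, {10: [(i, "G") for i in range(4)],
                                      20: [(0, "T")] + [(i, "G") for i in range(1, 4)]})
    matrix = q.build_matrix(obs, None, q.FilterConfig(min_call_rate=0.5))
    assert list(matrix.positions) == [20]


def test_indel_positions_excluded():
    import pandas as pd

    from qphylo.simulate import ObservationSet

    samples = ["a", "b"]
    rows = [
        ("a", 5, "G", 10, 30.0, 50.0, True),
        ("b", 5, "T", 10, 30.0, 50.0, True),
        ("a", 9, "G", 10, 30.0, 50.0, False),
        ("b", 9, "T", 10, 30.0, 50.0, False),
    ]
    table = pd.DataFrame(rows, columns=["sample", "pos", "base", "count",
                                        "base_quality", "mapping_quality", "is_indel"])
    obs = ObservationSet(table=table, coverage={s: ((0, 100),) for s in samples},
                         samples=samples)
    matrix = q.build_matrix(obs, None, q.FilterConfig())
    assert list(matrix.positions) == [9]


def test_noiseless_retained_sites_equal_true_mutation_sites(noiseless8):
    cfg, truth, ref, obs, matrix = noiseless8
    # the random background can contain by-chance low-entropy windows, which
    # the STR mask removes; recovery is exact outside the mask
    masked = q.mask_str_regions(ref, q.FilterConfig())
    true_sites = sorted(
        p
        for n in truth.postorder()
        for p in n.mutations
        if not any(s <= p < e for s, e in masked)
    )
    assert list(matrix.positions) == true_sites
    # and every retained column is variable with call rate 1
    assert (matrix.call_rate() == 1.0).all()


def test_empty_result_reports_diagnostics_not_exception():
    obs = _manual_observation_set(4, {})
    matrix = q.build_matrix(obs, None, q.FilterConfig())
    assert matrix.is_empty()
    assert matrix.diagnostics["n_candidates"] == 0


def test_tightening_thresholds_never_adds_positions():
    """Monotonicity: raising any single threshold can only shrink the
    retained position set (checked over seeded noisy datasets)."""
    base = q.FilterConfig()
    tighter = [
        base.with_(min_depth=5),
        base.with_(max_minor_fraction=0.02),
        base.with_(min_call_rate=0.8),
        base.with_(entropy_min=0.6),
        base.with_(min_base_quality=25.0),
        base.with_(min_mapping_quality=30.0),
    ]
    for seed in range(6):
        cfg = q.SimulationConfig(
            n_tips=10, tmrca_years=15_100, region_length=60_000,
            mutation_rate=2e-7, base_error_rate=0.03, seed=seed,
            platform_profiles=(
                q.PlatformProfile(name="p", intervals=((0, 60_000),),
                                  depth_mean=8.0, depth_dispersion=2.0),
            ),
        )
        truth = q.drop_mutations(q.simulate_genealogy(cfg, mode="yule"), cfg)
        ref = q.simulate_reference(cfg.region_length, [(30_000, "AC", 20)], seed=seed)
        obs = q.simulate_observations(truth, ref, cfg)
        loose_set = set(q.build_matrix(obs, ref, base).positions)
        for tcfg in tighter:
            tight_set = set(q.build_matrix(obs, ref, tcfg).positions)
            assert tight_set <= loose_set


def test_vectorised_calling_matches_scalar_reference():
    """The matrix builder's vectorised calling agrees with call_sample_site
    applied per sample-site group, on a noisy simulated table."""
    from qphylo.filtering import _call_all

    cfg = q.SimulationConfig(
        n_tips=6, tmrca_years=15_100, region_length=40_000,
        mutation_rate=2e-7, base_error_rate=0.05, seed=13,
        platform_profiles=(
            q.PlatformProfile(name="p", intervals=((0, 40_000),),
                              depth_mean=6.0, depth_dispersion=2.0),
        ),
    )
    truth = q.drop_mutations(q.simulate_genealogy(cfg, mode="yule"), cfg)
    ref = q.simulate_reference(cfg.region_length, seed=13)
    obs = q.simulate_observations(truth, ref, cfg)
    fcfg = q.FilterConfig(min_base_quality=28.0)  # gate actually bites
    candidates = np.array(sorted(obs.table["pos"].unique()))
    vector = _call_all(obs.table, obs.samples, candidates, fcfg)
    cand_index = {int(p): j for j, p in enumerate(candidates)}
    for (sample, pos), grp in obs.table.groupby(["sample", "pos"]):
        i = obs.samples.index(sample)
        assert vector[i, cand_index[int(pos)]] == q.call_sample_site(grp, fcfg)


def test_sweep_reports_rf_zero_on_clean_data(noiseless8):
    cfg, truth, ref, obs, matrix = noiseless8
    grid = [q.FilterConfig.relaxed(), q.FilterConfig.stringent()]
    report = q.sweep_configs(obs, ref, grid, seed=0,
                             search_kwargs={"n_restarts": 3})
    assert (report["mean_rf"].fillna(0) == 0).all()
    assert not report["flagged"].any()
    # relaxed resolves at least as many positions as stringent
    relaxed_n = report.loc[report.preset == "relaxed", "n_positions"].iloc[0]
    stringent_n = report.loc[report.preset == "stringent", "n_positions"].iloc[0]
    assert relaxed_n >= stringent_n
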