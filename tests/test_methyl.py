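"""Smoothing, dispersion, DMC/DMR calling, and region means."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from regmeth.core import (
    CpGSite,
    GenomicInterval,
    MethylationExperiment,
    MethylationSample,
    RegionSet,
)
from regmeth.methyl import (
    DMCConfig,
    DMRConfig,
    TARGETED,
    WGBS,
    call_dmc,
    call_dmr,
    compare_region_means,
    estimate_dispersion,
    per_sample_dmc_counts,
    region_mean_methylation,
    smooth_methylation,
)
from regmeth.simulate import SimConfig, simulate_genome, simulate_methylation


def _sample(counts, sid="s", group="g"):
    return MethylationSample(sid, group, {CpGSite(c, p): mn for (c, p), mn in counts.items()})


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_preserves_constant_fraction():
    s = _sample({("chr1", p): (5, 10) for p in range(0, 2000, 37)})
    sm = smooth_methylation(s, 300)
    assert all(f == pytest.approx(0.5) for f, _n in sm.values())


def test_smoothing_hand_example():
    s = _sample({("chr1", 100): (5, 10), ("chr1", 200): (10, 10), ("chr1", 400): (0, 10)})
    sm = smooth_methylation(s, 300)
    frac, depth = sm[CpGSite("chr1", 200)]
    assert frac == pytest.approx(15 / 20) and depth == 20
    assert sm[CpGSite("chr1", 400)] == (pytest.approx(0.0), 10)


def test_smoothing_identity_when_window_below_spacing():
    s = _sample({("chr1", p): (p % 7, 10) for p in range(0, 5000, 400)})
    sm = smooth_methylation(s, 300)
    for site, (m, n) in s.counts.items():
        assert sm[site] == (pytest.approx(m / n), n)


def test_smoothing_matches_windowed_sum_oracle(rng):
    pos = np.unique(rng.integers(0, 3000, size=150))
    counts = {("chrZ", int(p)): (int(rng.integers(0, 11)), 10) for p in pos}
    s = _sample(counts)
    window = 250
    sm = smooth_methylation(s, window)
    for p in pos:
        msum = sum(m for (c, q), (m, n) in counts.items() if abs(q - p) <= window / 2)
        nsum = sum(n for (c, q), (m, n) in counts.items() if abs(q - p) <= window / 2)
        frac, depth = sm[CpGSite("chrZ", int(p))]
        assert depth == nsum and frac == pytest.approx(msum / nsum)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_floor_when_replicates_identical():
    meth = np.full((5, 20), 50)
    tot = np.full((5, 20), 100)
    phi = estimate_dispersion(meth, tot)
    assert np.all(phi < 0.01)


def test_dispersion_recovery_from_simulated_beta_binomial(rng):
    true_phi, depth, reps, sites = 0.05, 50, 20, 1000
    a = 0.5 * (1 - true_phi) / true_phi
    b = 0.5 * (1 - true_phi) / true_phi
    p = rng.beta(a, b, size=(sites, reps))
    tot = np.full((sites, reps), depth)
    meth = rng.binomial(depth, p)
    phi = estimate_dispersion(meth, tot)
    assert 0.03 <= np.median(phi) <= 0.08


# ---------------------------------------------------------------------------
# DMC calling


def _two_group_experiment(counts_a, counts_b, n_a=2, n_b=2):
    samples = [
        _sample(counts_a, f"a{i}", "A") for i in range(n_a)
    ] + [_sample(counts_b, f"b{i}", "B") for i in range(n_b)]
    return MethylationExperiment(samples, {})


def test_dmc_identical_groups_yield_no_calls():
    counts = {("chr1", p): (int(p % 11), 20) for p in range(0, 3000, 50)}
    exp = _two_group_experiment(counts, counts)
    recs = call_dmc(exp, "A", "B", TARGETED)
    assert recs and all(r.diff == pytest.approx(0.0) and not r.significant for r in recs)


def test_dmc_extreme_site_is_hyper_significant():
    # group A pooled 300/300 vs group B pooled 0/300 at an isolated site
    a = {("chr1", 1000): (150, 150)}
    b = {("chr1", 1000): (0, 150)}
    exp = _two_group_experiment(a, b)
    (rec,) = call_dmc(exp, "A", "B", TARGETED)
    assert rec.diff == pytest.approx(1.0)
    assert rec.direction == "hyper" and rec.significant
    # direct evaluation of the posterior-probability formula
    assert rec.postprob == pytest.approx(norm.cdf((abs(rec.diff) - 0.2) / rec.se))
    assert rec.postprob > 0.99999


def test_dmc_direction_antisymmetric_under_group_swap(null_dataset):
    _cfg, _genome, _truth, experiment = null_dataset
    ab = call_dmc(experiment, "carrier", "control", TARGETED)
    ba = call_dmc(experiment, "control", "carrier", TARGETED)
    assert len(ab) == len(ba)
    for r1, r2 in zip(ab, ba):
        assert r1.site == r2.site
        assert r1.diff == pytest.approx(-r2.diff)
        assert r1.se == pytest.approx(r2.se)


def test_dmc_depth_filter_applies_per_group():
    a = {("chr1", 100): (3, 5), ("chr1", 900): (3, 6)}
    b = {("chr1", 100): (3, 6), ("chr1", 900): (3, 6)}
    exp = _two_group_experiment(a, b, n_a=1, n_b=1)
    recs = call_dmc(exp, "A", "B", TARGETED)
    assert [r.site.pos for r in recs] == [900]  # site 100 has depth 5 < 6 in group A


def test_dmc_excludes_sex_chromosomes():
    a = {("chrX", 100): (10, 10), ("chr1", 100): (10, 10)}
    b = {("chrX", 100): (0, 10), ("chr1", 100): (0, 10)}
    exp = _two_group_experiment(a, b)
    recs = call_dmc(exp, "A", "B", TARGETED)
    assert {r.site.chrom for r in recs} == {"chr1"}


def test_dmc_unknown_group_errors(null_dataset):
    _cfg, _genome, _truth, experiment = null_dataset
    with pytest.raises(ValueError, match="no samples"):
        call_dmc(experiment, "carrier", "nonexistent", TARGETED)


def test_dmc_planted_recovery_sensitivity_and_false_positives():
    cfg = SimConfig(
        n_chroms=2, chrom_length=200_000, cpg_density=50.0,
        baseline_mu=(("enhancer", 0.5), ("heterochromatin", 0.5), ("background", 0.5)),
        dispersion=0.005, affected_scope="run", n_affected_sites=200, effect_size=0.3,
        hyper_fraction=1.0, n_carriers=5, n_controls=5, depth_mean=30.0, seed=11,
    )
    _genome, truth = simulate_genome(cfg)
    exp = simulate_methylation(truth, cfg)
    recs = call_dmc(exp, "carrier", "control", TARGETED)
    affected = set(truth.affected_sites)
    called = {r.site for r in recs if r.significant}
    tp = len(called & affected)
    fp = len(called - affected)
    assert tp / len(affected) >= 0.9
    assert fp <= 5


# ---------------------------------------------------------------------------
# DMR merging


def _dmc(pos, diff, p, chrom="chr1"):
    from regmeth.methyl import DMCRecord

    return DMCRecord(CpGSite(chrom, pos), 0.5 + diff / 2, 0.5 - diff / 2, diff, 0.01,
                     diff / 0.01, p, 0.5, p < 0.01)


def test_dmr_requires_three_cpgs():
    dmcs = [_dmc(100, 0.3, 1e-5), _dmc(160, 0.3, 1e-5)]
    assert call_dmr(dmcs, DMRConfig()) == []


def test_dmr_four_hyper_cpgs_merge():
    dmcs = [_dmc(p, 0.3, 1e-5) for p in (100, 140, 180, 220)]
    (dmr,) = call_dmr(dmcs, DMRConfig())
    assert dmr.interval == GenomicInterval("chr1", 100, 221)
    assert dmr.n_cpg == 4 and dmr.direction == "hyper"


def test_dmr_min_length_filter():
    dmcs = [_dmc(p, 0.3, 1e-5) for p in (100, 115, 130)]  # span 31 < 50
    assert call_dmr(dmcs, DMRConfig()) == []


def test_dmr_nonsignificant_cpg_breaks_run():
    dmcs = [_dmc(100, 0.3, 1e-5), _dmc(140, 0.3, 1e-5), _dmc(180, 0.3, 0.5),
            _dmc(220, 0.3, 1e-5)]
    assert call_dmr(dmcs, DMRConfig()) == []


def test_dmr_direction_change_breaks_run():
    dmcs = [_dmc(100, 0.3, 1e-5), _dmc(140, -0.3, 1e-5), _dmc(180, 0.3, 1e-5),
            _dmc(220, 0.3, 1e-5)]
    assert call_dmr(dmcs, DMRConfig()) == []


def test_dmr_max_gap_breaks_run():
    dmcs = [_dmc(p, 0.3, 1e-5) for p in (100, 140, 180, 500, 540, 580)]
    out = call_dmr(dmcs, DMRConfig(min_length=50, max_gap=100))
    assert [d.interval for d in out] == [
        GenomicInterval("chr1", 100, 181),
        GenomicInterval("chr1", 500, 581),
    ]


def test_dmr_invariant_under_input_permutation(rng):
    dmcs = [_dmc(int(p), 0.3, float(rng.choice([1e-5, 0.5]))) for p in
            sorted(rng.choice(5000, size=60, replace=False))]
    ref = call_dmr(dmcs, DMRConfig())
    perm = list(dmcs)
    rng.shuffle(perm)
    assert call_dmr(perm, DMRConfig()) == ref


# ---------------------------------------------------------------------------
# per-sample counts and region means


def test_per_sample_counts_scaling_arithmetic():
    # 2,000 tested sites, planted extremes at 4 -> rates scale by 1e6 / n_tested
    baseline_counts = {("chr1", p): (10, 20) for p in range(0, 100_000, 50)}
    query_counts = dict(baseline_counts)
    hyper_pos = [200_000 + i for i in (0, 400, 800)]  # isolated, far from baseline noise
    for p in hyper_pos:
        for c in (baseline_counts, query_counts):
            c[("chr1", p)] = (0, 200)
        query_counts[("chr1", p)] = (200, 200)
    baseline = [_sample(baseline_counts, f"b{i}", "baseline") for i in range(5)]
    query = _sample(query_counts, "q", "query")
    hyper, hypo, n_tested = per_sample_dmc_counts(query, baseline, TARGETED)
    assert n_tested == len(query_counts)
    assert hyper == pytest.approx(1e6 * len(hyper_pos) / n_tested)
    assert hypo == 0.0


def test_per_sample_counts_null_near_zero(null_dataset):
    cfg, _genome, _truth, experiment = null_dataset
    controls = experiment.group_samples("control")
    hyper, hypo, n = per_sample_dmc_counts(controls[5], controls[:5], TARGETED)
    assert n > 0
    assert hyper <= 1e6 * 5 / n and hypo <= 1e6 * 5 / n  # at most a handful of calls


def test_region_mean_methylation_examples():
    s = _sample({("chr1", 10): (5, 10), ("chr1", 20): (10, 20), ("chr1", 40): (3, 4),
                 ("chr1", 100): (1, 2)})
    regions = RegionSet("r", [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 90, 120)])
    per_region, set_mean = region_mean_methylation(s, regions, min_depth=6)
    assert per_region[GenomicInterval("chr1", 0, 50)] == pytest.approx(0.5)
    assert GenomicInterval("chr1", 90, 120) not in per_region  # depth 2 < 6
    assert set_mean == pytest.approx(0.5)
    per_region1, _ = region_mean_methylation(s, regions, min_depth=1)
    assert per_region1[GenomicInterval("chr1", 90, 120)] == pytest.approx(0.5)
    per_single, _ = region_mean_methylation(
        _sample({("chr1", 10): (3, 4)}), RegionSet("r", [GenomicInterval("chr1", 0, 50)]), 1
    )
    assert per_single[GenomicInterval("chr1", 0, 50)] == pytest.approx(0.75)


def test_region_mean_all_below_depth_is_missing():
    s = _sample({("chr1", 10): (1, 3)})
    regions = RegionSet("r", [GenomicInterval("chr1", 0, 50)])
    per_region, set_mean = region_mean_methylation(s, regions, min_depth=6)
    assert per_region == {} and set_mean is None


def test_compare_region_means_null_and_planted(null_dataset):
    cfg, _genome, truth, experiment = null_dataset
    df = compare_region_means(experiment, {ct: rs for ct, rs in truth.celltype_peaks.items()},
                              "carrier", "control", min_depth=6)
    assert set(df["cell_type"]) == set(truth.celltype_peaks)
    assert (df["qvalue"] > 0.05).all()  # no effect planted
    # planted shift at one cell type's regions
    cfg2 = dataclasses.replace(cfg, affected_scope="peaks", effect_size=0.15,
                               hyper_fraction=1.0, seed=7)
    _g2, truth2 = simulate_genome(cfg2)
    exp2 = simulate_methylation(truth2, cfg2)
    df2 = compare_region_means(exp2, dict(truth2.celltype_peaks), "carrier", "control", 6)
    df2 = df2.set_index("cell_type")
    assert df2.loc["celltype1", "qvalue"] <= 0.05
    assert (df2.drop(index="celltype1")["qvalue"] > 0.05).all()
    assert df2.loc["celltype1", "delta"] == pytest.approx(0.15, abs=0.05)
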