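"""Motif-repositioning permutation test: statistic, shuffle, p-values."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare

from regmeth.core import GenomicInterval, MotifMatch, RegionSet
from regmeth.permtest import (
    PermConfig,
    observed_statistic,
    permutation_test,
    region_delta,
    run_all,
    shuffle_matches,
)
from regmeth.simulate import SimConfig, simulate_genome, simulate_methylation


def _match(chrom, start, width=10, motif="m", strand="+"):
    return MotifMatch(motif, GenomicInterval(chrom, start, start + width), strand, 1.0)


# ---------------------------------------------------------------------------
# region delta


def test_region_delta_zero_when_groups_identical(null_dataset):
    _cfg, _genome, truth, experiment = null_dataset
    regions = truth.all_peaks()
    carriers = experiment.group_samples("carrier")
    deltas = region_delta(regions, carriers, carriers, min_depth=6)
    assert deltas and all(v == pytest.approx(0.0) for v in deltas.values())


def test_region_delta_matches_loop_oracle(null_dataset):
    _cfg, _genome, truth, experiment = null_dataset
    regions = truth.celltype_peaks["celltype1"]
    carriers = experiment.group_samples("carrier")
    controls = experiment.group_samples("control")
    deltas = region_delta(regions, carriers, controls, min_depth=6)
    for iv in list(deltas)[:25]:
        def group_mean(samples):
            per = []
            for s in samples:
                fr = [
                    m / n
                    for site, (m, n) in s.counts.items()
                    if site.chrom == iv.chrom and iv.start <= site.pos < iv.end and n >= 6
                ]
                if fr:
                    per.append(sum(fr) / len(fr))
            return sum(per) / len(per)

        assert deltas[iv] == pytest.approx(group_mean(carriers) - group_mean(controls),
                                           abs=1e-12)


# ---------------------------------------------------------------------------
# observed statistic


def test_observed_statistic_region_level_mean():
    r1 = GenomicInterval("chr1", 0, 100)
    r2 = GenomicInterval("chr1", 200, 300)
    r3 = GenomicInterval("chr1", 400, 500)
    regions = RegionSet("r", [r1, r2, r3])
    deltas = {r1: 0.2, r2: 0.4, r3: -5.0}
    matches = [_match("chr1", 10), _match("chr1", 20), _match("chr1", 210)]
    # two matches in r1 count once; r3 bears no match
    assert observed_statistic(deltas, matches, regions) == pytest.approx(0.3)


def test_observed_statistic_undefined_without_bearing_region():
    regions = RegionSet("r", [GenomicInterval("chr1", 0, 100)])
    with pytest.raises(ValueError, match="no motif-bearing"):
        observed_statistic({GenomicInterval("chr1", 0, 100): 0.1},
                           [_match("chr2", 5)], regions)


# ---------------------------------------------------------------------------
# shuffle


def test_shuffle_forced_placement_is_identity(rng):
    regions = RegionSet("r", [GenomicInterval("chr1", 50, 60)])
    m = _match("chr1", 50, width=10)
    (out,) = shuffle_matches([m], regions, rng)
    assert out.interval == m.interval and out.motif_id == m.motif_id


def test_shuffle_start_positions_uniform(rng):
    L, w = 40, 10
    regions = RegionSet("r", [GenomicInterval("chr1", 100, 100 + L)])
    m = _match("chr1", 100, width=w)
    n_starts = L - w + 1
    counts = np.zeros(n_starts, dtype=int)
    for _ in range(10_000):
        (out,) = shuffle_matches([m], regions, rng)
        counts[out.interval.start - 100] += 1
    stat, p = chisquare(counts)
    assert p > 0.001


def test_shuffle_region_choice_weighted_by_valid_starts(rng):
    # region of 20 valid starts vs region of 10: expect 2:1 placement ratio
    r1 = GenomicInterval("chr1", 0, 29)
    r2 = GenomicInterval("chr1", 100, 119)
    regions = RegionSet("r", [r1, r2])
    m = _match("chr1", 0, width=10)
    in_r1 = sum(
        shuffle_matches([m], regions, rng)[0].interval.start < 50 for _ in range(6000)
    )
    assert 0.6 < in_r1 / 6000 < 0.73  # 2/3 within binomial tolerance


def test_shuffle_conserves_counts_and_widths(rng):
    regions = RegionSet("r", [GenomicInterval("chr1", i * 100, i * 100 + 60) for i in range(5)])
    matches = [_match("chr1", 10, width=w, motif=f"m{w}") for w in (6, 8, 10, 12)] * 3
    out = shuffle_matches(matches, regions, rng)
    assert len(out) == len(matches)
    assert [m.motif_id for m in out] == [m.motif_id for m in matches]
    assert [m.interval.length for m in out] == [m.interval.length for m in matches]
    assert all(regions.contains_interval(m.interval) for m in out)


def test_shuffle_width_too_large_errors(rng):
    regions = RegionSet("r", [GenomicInterval("chr1", 0, 5)])
    with pytest.raises(ValueError, match="width"):
        shuffle_matches([_match("chr1", 0, width=10)], regions, rng)


# ---------------------------------------------------------------------------
# permutation p-values


def _toy_setup(deltas_values):
    regions = RegionSet("r", [GenomicInterval("chr1", i * 100, i * 100 + 50)
                              for i in range(len(deltas_values))])
    deltas = {iv: v for iv, v in zip(regions.intervals, deltas_values)}
    return regions, deltas


def test_p_boundaries():
    regions, deltas = _toy_setup([10.0] + [0.0] * 9)
    matches = [_match("chr1", 5)]  # sits in the extreme region
    res = permutation_test(deltas, matches, regions, PermConfig(n_perm=500, seed=0))
    assert res.t_obs == pytest.approx(10.0)
    assert res.p_one_sided == 0.0
    assert res.p_add_one >= 1 / 501
    low = permutation_test(deltas, [_match("chr1", 105)], regions,
                           PermConfig(n_perm=500, seed=0))
    # t_obs = 0 while most null draws hit the extreme region sometimes;
    # opposite boundary: statistic smaller than every strictly-greater draw
    assert low.p_one_sided <= 1.0


def test_saturated_single_region_point_mass_null():
    # with one region every shuffle lands in it: the null is a point mass
    # at t_obs and the strict-inequality convention gives p = 0
    regions, deltas = _toy_setup([0.4])
    res = permutation_test(deltas, [_match("chr1", 5)], regions,
                           PermConfig(n_perm=200, seed=1))
    assert res.t_obs == pytest.approx(0.4)
    assert np.allclose(res.null, res.t_obs)
    assert res.p_one_sided == 0.0


def test_all_regions_bearing_t_obs_is_global_mean():
    regions, deltas = _toy_setup([0.1, 0.3, 0.5])
    matches = [_match("chr1", s) for s in (5, 105, 205)]  # every region bearing
    res = permutation_test(deltas, matches, regions, PermConfig(n_perm=200, seed=1))
    assert res.t_obs == pytest.approx(np.mean([0.1, 0.3, 0.5]))
    # independent repositioning can leave a region empty, so the null is
    # not a point mass, but no draw can exceed the maximum delta
    assert res.null.max() <= max(deltas.values()) + 1e-12


def test_empirical_p_invariant_under_monotone_transform():
    regions, deltas = _toy_setup([0.5, 0.1, -0.2, 0.05, 0.3])
    matches = [_match("chr1", 5), _match("chr1", 405)]
    r1 = permutation_test(deltas, matches, regions, PermConfig(n_perm=300, seed=2))
    deltas_t = {iv: np.exp(3 * v) for iv, v in deltas.items()}  # strictly monotone
    r2 = permutation_test(deltas_t, matches, regions, PermConfig(n_perm=300, seed=2))
    assert r1.p_one_sided == r2.p_one_sided


def test_tail_probabilities_sum_to_about_one():
    regions, deltas = _toy_setup(list(np.linspace(-0.3, 0.4, 8)))
    matches = [_match("chr1", 5), _match("chr1", 205), _match("chr1", 505)]
    res = permutation_test(deltas, matches, regions, PermConfig(n_perm=400, seed=3))
    total = res.p_one_sided + (res.null < res.t_obs).mean()
    assert 1 - (res.null == res.t_obs).mean() - 1e-9 <= total <= 1 + 1 / 400


def test_run_all_deterministic_and_order_invariant(null_dataset):
    _cfg, _genome, truth, experiment = null_dataset
    carriers = experiment.group_samples("carrier")
    controls = experiment.group_samples("control")
    matches = {}
    for p in truth.motif_placements:
        matches.setdefault(p.motif_id, []).append(p)
    regions = {ct: rs for ct, rs in truth.celltype_peaks.items()}
    cfg = PermConfig(n_perm=50, seed=9)
    _r1, t1 = run_all(matches, regions, carriers, controls, cfg)
    reordered = dict(reversed(list(matches.items())))
    _r2, t2 = run_all(reordered, regions, carriers, controls, cfg)
    t1s = t1.sort_values(["motif", "cell_type"]).reset_index(drop=True)
    t2s = t2.sort_values(["motif", "cell_type"]).reset_index(drop=True)
    assert t1s.equals(t2s)


def test_doubling_n_perm_leaves_t_obs_unchanged(null_dataset):
    _cfg, _genome, truth, experiment = null_dataset
    carriers = experiment.group_samples("carrier")
    controls = experiment.group_samples("control")
    regions = truth.celltype_peaks["celltype1"]
    deltas = region_delta(regions, carriers, controls, 6)
    contained = [m for m in truth.motif_placements if regions.contains_interval(m.interval)]
    r1 = permutation_test(deltas, contained, regions, PermConfig(n_perm=50, seed=4))
    r2 = permutation_test(deltas, contained, regions, PermConfig(n_perm=100, seed=4))
    assert r1.t_obs == r2.t_obs


def test_null_rate_never_anticonservative_for_structured_placements():
    """With no planted effect but structured observed placements (one motif
    per peak, without replacement) the test may only err on the
    conservative side: the null repositions with replacement, spreading
    over fewer distinct regions, so its spread dominates that of the
    observed statistic. The type-I rate must not exceed the upper 99%
    binomial bound for a nominal 0.05 test."""
    cfg = SimConfig(affected_scope="none", seed=5)
    _genome, truth = simulate_genome(cfg)
    regions = truth.all_peaks()
    matches = truth.motif_placements
    n_rep = 200
    rejections = 0
    for rep in range(n_rep):
        c = dataclasses.replace(cfg, seed=20_000 + rep)
        exp = simulate_methylation(truth, c)
        carriers = [s for s in exp.samples if s.group == "carrier"]
        controls = [s for s in exp.samples if s.group == "control"]
        deltas = region_delta(regions, carriers, controls, min_depth=6)
        res = permutation_test(deltas, matches, regions, PermConfig(n_perm=200, seed=rep))
        rejections += res.p_one_sided < 0.05
    assert rejections / n_rep <= 0.09
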