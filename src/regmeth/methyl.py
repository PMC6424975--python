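"""Beta-binomial differential methylation: DMCs, DMRs, and region means.

The caller follows the smoothed Wald-test construction used for bisulfite
count data: per CpG, group methylation levels are estimated from pooled
counts smoothed over a basepair window, the between-replicate
overdispersion phi enters the variance as Var(mu_g) = phi*mu(1-mu)/N_g
with N_g the smoothed effective depth, and a site is called differentially
methylated when |mu_a - mu_b| exceeds a practical threshold delta with
posterior probability Phi((|diff| - delta)/se) above a cutoff. Two presets
mirror common deep-targeted and whole-genome settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import CpGSite, GenomicInterval, MethylationExperiment, MethylationSample, RegionSet
from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "DMCConfig",
    "DMCRecord",
    "DMRConfig",
    "DMRRecord",
    "TARGETED",
    "WGBS",
    "smooth_methylation",
    "estimate_dispersion",
    "call_dmc",
    "call_dmr",
    "per_sample_dmc_counts",
    "region_mean_methylation",
    "compare_region_means",
]

PHI_FLOOR = 1e-4
PHI_CAP = 0.5
_SEX_CHROMS = frozenset({"chrX", "chrY", "chrM", "X", "Y", "M", "MT"})


@dataclass(frozen=True)
class DMCConfig:
    min_depth: int = 6
    smooth_window: int = 300
    delta: float = 0.2
    pp_threshold: float = 0.99999
    autosomes_only: bool = True
    exclude_chroms: frozenset = _SEX_CHROMS

    def __post_init__(self):
        if self.min_depth < 1 or self.smooth_window <= 0:
            raise ValueError("min_depth >= 1 and smooth_window > 0 required")
        if not (0 <= self.delta < 1 and 0 < self.pp_threshold < 1):
            raise ValueError("delta in [0,1) and pp_threshold in (0,1) required")


#: deep targeted bisulfite preset: depth >= 6, 300 bp smoothing,
#: |diff| > 0.2 at posterior probability > 0.99999
TARGETED = DMCConfig(min_depth=6, smooth_window=300, delta=0.2, pp_threshold=0.99999)
#: whole-genome preset: depth >= 2, |diff| > 0.1 at posterior probability > 0.99
WGBS = DMCConfig(min_depth=2, smooth_window=300, delta=0.1, pp_threshold=0.99)


@dataclass
class DMCRecord:
    site: CpGSite
    mu_a: float
    mu_b: float
    diff: float
    se: float
    wald: float
    pvalue: float
    postprob: float
    significant: bool

    @property
    def direction(self) -> str:
        return "hyper" if self.diff > 0 else "hypo"


@dataclass(frozen=True)
class DMRConfig:
    min_cpg: int = 3
    min_length: int = 50
    p_threshold: float = 0.01
    max_gap: int = 100

    def __post_init__(self):
        if self.min_cpg < 1 or self.min_length < 1:
            raise ValueError("min_cpg >= 1 and min_length >= 1 required")


@dataclass
class DMRRecord:
    interval: GenomicInterval
    n_cpg: int
    mean_diff: float
    direction: str
    min_p: float
    median_p: float


# ---------------------------------------------------------------------------
# array plumbing


def _chrom_arrays(
    samples: Sequence[MethylationSample], chroms: Optional[Iterable[str]] = None
) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Union of sites per chromosome -> (positions, meth, total) matrices.

    ``meth`` and ``total`` have shape (n_sites, n_samples); absent sites
    carry zero depth.
    """
    site_union: Dict[str, set] = {}
    for s in samples:
        for site in s.counts:
            site_union.setdefault(site.chrom, set()).add(site.pos)
    if chroms is not None:
        keep = set(chroms)
        site_union = {c: p for c, p in site_union.items() if c in keep}
    out = {}
    for chrom, posset in sorted(site_union.items()):
        pos = np.fromiter(sorted(posset), dtype=np.int64)
        idx = {p: i for i, p in enumerate(pos)}
        meth = np.zeros((pos.size, len(samples)), dtype=np.int64)
        tot = np.zeros_like(meth)
        for j, s in enumerate(samples):
            for site, (m, n) in s.counts.items():
                if site.chrom == chrom:
                    i = idx[site.pos]
                    meth[i, j] = m
                    tot[i, j] = n
        out[chrom] = (pos, meth, tot)
    return out


def _window_pool(pos: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Sum ``values`` over sites within +/- window/2 of each site (inclusive)."""
    half = window / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    csum = np.concatenate([[0], np.cumsum(values)])
    return csum[hi] - csum[lo]


def smooth_methylation(
    sample: MethylationSample, window: int
) -> Dict[CpGSite, Tuple[float, int]]:
    """Window-smoothed methylation: site -> (pooled fraction, pooled depth).

    Counts from all CpGs of the same chromosome within +/- window/2 of a
    site are pooled; sites whose pooled depth is zero are omitted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    out: Dict[CpGSite, Tuple[float, int]] = {}
    for chrom, (pos, meth, tot) in _chrom_arrays([sample]).items():
        pm = _window_pool(pos, meth[:, 0], window)
        pt = _window_pool(pos, tot[:, 0], window)
        for p, m, n in zip(pos, pm, pt):
            if n > 0:
                out[CpGSite(chrom, int(p))] = (m / n, int(n))
    return out


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(meth: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Per-site beta-binomial dispersion phi from replicate fractions.

    Method of moments: across replicates the variance of the observed
    fractions is mu(1-mu) * (phi + (1-phi)/n) at depth n, so
    phi = (s2/(mu(1-mu)) - E[1/n]) / (1 - E[1/n]). Raw estimates are
    shrunk toward the chromosome-wide median with weight 1/(1+k) for k
    informative replicates, floored at 1e-4 and capped at 0.5. Sites with
    fewer than two informative replicates return NaN (the caller supplies
    a fallback).
    """
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # <2 informative replicates
        frac = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
        k = (tot > 0).sum(axis=1).astype(float)
        mu = meth.sum(axis=1) / np.maximum(tot.sum(axis=1), 1)
        mu = np.clip(mu, 1e-6, 1 - 1e-6)
        s2 = np.nanvar(frac, axis=1, ddof=1)
        invn = np.where(tot > 0, 1.0 / np.maximum(tot, 1), np.nan)
        invn_mean = np.nanmean(invn, axis=1)
        phi_raw = (s2 / (mu * (1 - mu)) - invn_mean) / (1 - invn_mean)
    phi_raw = np.where(k >= 2, phi_raw, np.nan)
    phi_raw = np.clip(phi_raw, PHI_FLOOR, PHI_CAP)
    valid = np.isfinite(phi_raw)
    center = np.median(phi_raw[valid]) if valid.any() else PHI_FLOOR
    w = 1.0 / (1.0 + k)
    phi = w * center + (1.0 - w) * phi_raw
    return np.clip(phi, PHI_FLOOR, PHI_CAP)


# ---------------------------------------------------------------------------
# DMC calling


def call_dmc(
    experiment: MethylationExperiment,
    group_a: str,
    group_b: str,
    config: DMCConfig = TARGETED,
    dispersion_from: Optional[str] = None,
) -> List[DMCRecord]:
    """Call differentially methylated cytosines between two groups.

    A site is tested only where the unsmoothed pooled depth reaches
    ``config.min_depth`` in *both* groups. Group levels mu come from
    window-smoothed pooled counts; diff = mu_a - mu_b is positive for
    hypermethylation in group A. ``dispersion_from`` names a group whose
    phi is used for both sides (the natural choice in 1-vs-baseline
    comparisons where the single sample cannot inform phi).
    """
    samples_a = experiment.group_samples(group_a)
    samples_b = experiment.group_samples(group_b)
    chroms = None
    if config.autosomes_only:
        all_chroms = {s.chrom for smp in samples_a + samples_b for s in smp.counts}
        chroms = sorted(all_chroms - set(config.exclude_chroms))
    arrays = _chrom_arrays(list(samples_a) + list(samples_b), chroms)
    na = len(samples_a)
    records: List[DMCRecord] = []
    for chrom in sorted(arrays):
        pos, meth, tot = arrays[chrom]
        ma, ta = meth[:, :na], tot[:, :na]
        mb, tb = meth[:, na:], tot[:, na:]
        depth_a = ta.sum(axis=1)
        depth_b = tb.sum(axis=1)
        tested = (depth_a >= config.min_depth) & (depth_b >= config.min_depth)
        if not tested.any():
            continue
        # smoothed pooled group counts
        sm_a = _window_pool(pos, ma.sum(axis=1), config.smooth_window)
        st_a = _window_pool(pos, ta.sum(axis=1), config.smooth_window)
        sm_b = _window_pool(pos, mb.sum(axis=1), config.smooth_window)
        st_b = _window_pool(pos, tb.sum(axis=1), config.smooth_window)
        mu_a = sm_a / np.maximum(st_a, 1)
        mu_b = sm_b / np.maximum(st_b, 1)
        phi_a = estimate_dispersion(ma, ta)
        phi_b = estimate_dispersion(mb, tb)
        if dispersion_from == group_a:
            phi_b = phi_a
        elif dispersion_from == group_b:
            phi_a = phi_b
        else:
            # one-sided fallback where a group lacks replicates
            phi_a = np.where(np.isfinite(phi_a), phi_a, phi_b)
            phi_b = np.where(np.isfinite(phi_b), phi_b, phi_a)
        phi_a = np.where(np.isfinite(phi_a), phi_a, PHI_FLOOR)
        phi_b = np.where(np.isfinite(phi_b), phi_b, PHI_FLOOR)
        mca = np.clip(mu_a, 1e-4, 1 - 1e-4)
        mcb = np.clip(mu_b, 1e-4, 1 - 1e-4)
        # pooled beta-binomial variance. Each sample's count at one site has
        # Var = mu(1-mu) * n (1 + (n-1) phi); beta draws are independent
        # across sites and samples, so the variance of the smoothed pooled
        # count is the window sum over sites of the per-sample sum of these
        # terms, and Var(mu_g) divides by the squared pooled depth N_g.
        odisp_a = _window_pool(pos, (ta * (1 + np.maximum(ta - 1, 0) * phi_a[:, None])).sum(axis=1),
                               config.smooth_window)
        odisp_b = _window_pool(pos, (tb * (1 + np.maximum(tb - 1, 0) * phi_b[:, None])).sum(axis=1),
                               config.smooth_window)
        var = (mca * (1 - mca) * odisp_a / np.maximum(st_a, 1) ** 2
               + mcb * (1 - mcb) * odisp_b / np.maximum(st_b, 1) ** 2)
        se = np.sqrt(var)
        diff = mu_a - mu_b
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(se > 0, diff / se, 0.0)
        pval = 2.0 * norm.sf(np.abs(wald))
        postprob = np.where(se > 0, norm.cdf((np.abs(diff) - config.delta) / se), 0.0)
        signif = (np.abs(diff) > config.delta) & (postprob > config.pp_threshold)
        for i in np.flatnonzero(tested):
            records.append(
                DMCRecord(
                    site=CpGSite(chrom, int(pos[i])),
                    mu_a=float(mu_a[i]),
                    mu_b=float(mu_b[i]),
                    diff=float(diff[i]),
                    se=float(se[i]),
                    wald=float(wald[i]),
                    pvalue=float(pval[i]),
                    postprob=float(postprob[i]),
                    significant=bool(signif[i]),
                )
            )
    if not records:
        warnings.warn("call_dmc: zero tested sites")
    return records


def call_dmr(dmcs: Sequence[DMCRecord], config: DMRConfig = DMRConfig()) -> List[DMRRecord]:
    """Merge runs of significant same-direction CpGs into regions.

    A run extends over consecutive tested CpGs with pvalue < p_threshold
    and a common direction, with at most ``max_gap`` bp between
    neighbours; any non-qualifying CpG terminates the run. Runs with at
    least ``min_cpg`` sites spanning at least ``min_length`` bp (first to
    last cytosine, half-open) are emitted.
    """
    dmcs = sorted(dmcs, key=lambda r: (r.site.chrom, r.site.pos))
    out: List[DMRRecord] = []
    run: List[DMCRecord] = []

    def flush():
        if len(run) >= config.min_cpg:
            start, end = run[0].site.pos, run[-1].site.pos + 1
            if end - start >= config.min_length:
                ps = [r.pvalue for r in run]
                out.append(
                    DMRRecord(
                        interval=GenomicInterval(run[0].site.chrom, start, end),
                        n_cpg=len(run),
                        mean_diff=float(np.mean([r.diff for r in run])),
                        direction=run[0].direction,
                        min_p=min(ps),
                        median_p=float(np.median(ps)),
                    )
                )
        run.clear()

    for rec in dmcs:
        qualifies = rec.pvalue < config.p_threshold
        if not qualifies:
            flush()
            continue
        if run and (
            rec.site.chrom != run[-1].site.chrom
            or rec.direction != run[-1].direction
            or rec.site.pos - run[-1].site.pos > config.max_gap
        ):
            flush()
        run.append(rec)
    flush()
    return out


def per_sample_dmc_counts(
    sample: MethylationSample,
    baseline: Sequence[MethylationSample],
    config: DMCConfig = TARGETED,
) -> Tuple[float, float, int]:
    """Hyper/hypo DMC counts of one sample against a baseline panel.

    Each sample is compared alone against the pooled baseline controls;
    the common dispersion is estimated from the baseline group. Counts are
    scaled to 'per million tested CpGs': 1e6 * n_signif / n_tested.
    """
    exp = MethylationExperiment(
        samples=[replace_group(sample, "query")] + [replace_group(b, "baseline") for b in baseline],
        design={},
    )
    dmcs = call_dmc(exp, "query", "baseline", config, dispersion_from="baseline")
    n_tested = len(dmcs)
    if n_tested == 0:
        raise ValueError("per_sample_dmc_counts: zero tested sites")
    hyper = sum(1 for r in dmcs if r.significant and r.diff > 0)
    hypo = sum(1 for r in dmcs if r.significant and r.diff < 0)
    scale = 1e6 / n_tested
    return hyper * scale, hypo * scale, n_tested


def replace_group(sample: MethylationSample, group: str) -> MethylationSample:
    return MethylationSample(sample_id=sample.sample_id, group=group, counts=sample.counts)


# ---------------------------------------------------------------------------
# region averages


def region_mean_methylation(
    sample: MethylationSample, regions: RegionSet, min_depth: int = 6
) -> Tuple[Dict[GenomicInterval, float], Optional[float]]:
    """Average methylation over a region set, depth-filtered.

    Per region: the unweighted mean of per-CpG methylation fractions over
    CpGs inside the region with depth >= min_depth; regions with no
    qualifying CpG are absent from the result. The set-level value is the
    unweighted mean over all qualifying CpGs falling in any region (each
    CpG counted once), or None when no CpG qualifies.
    """
    per_region: Dict[GenomicInterval, float] = {}
    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for site, (m, n) in sample.counts.items():
        if n >= min_depth:
            by_chrom.setdefault(site.chrom, []).append((site.pos, m / n))
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        pos = np.fromiter((p for p, _ in entries), dtype=np.int64, count=len(entries))
        frac = np.fromiter((f for _, f in entries), dtype=float, count=len(entries))
        arrays[chrom] = (pos, frac, np.concatenate([[0.0], np.cumsum(frac)]))
    member_sum = 0.0
    member_n = 0
    ivs_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in regions.intervals:
        ivs_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in ivs_by_chrom.items():
        if chrom not in arrays:
            continue
        pos, frac, csum = arrays[chrom]
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        for iv, l, h in zip(ivs, lo, hi):
            if h > l:
                per_region[iv] = float((csum[h] - csum[l]) / (h - l))
        # set-level membership (each CpG once): merge overlapping intervals
        order = np.argsort(starts)
        mstart, mend = [], []
        for s, e in zip(starts[order], ends[order]):
            if mend and s <= mend[-1]:
                mend[-1] = max(mend[-1], e)
            else:
                mstart.append(s)
                mend.append(e)
        mstart_a, mend_a = np.array(mstart), np.array(mend)
        idx = np.searchsorted(mstart_a, pos, side="right") - 1
        inside = (idx >= 0) & (pos < mend_a[np.maximum(idx, 0)])
        member_sum += float(frac[inside].sum())
        member_n += int(inside.sum())
    set_mean = member_sum / member_n if member_n else None
    return per_region, set_mean


def compare_region_means(
    experiment: MethylationExperiment,
    regionsets_by_celltype: Mapping[str, RegionSet],
    carriers: str,
    controls: str,
    min_depth: int = 6,
) -> pd.DataFrame:
    """Per cell type: carrier-vs-control difference of set-level means.

    For each cell type's region set, each sample contributes one set-level
    mean methylation; the two groups of per-sample means are compared with
    a two-sided Wilcoxon rank-sum test and BH-corrected across cell types.
    """
    carrier_samples = experiment.group_samples(carriers)
    control_samples = experiment.group_samples(controls)
    if len(carrier_samples) < 2 or len(control_samples) < 2:
        raise ValueError("compare_region_means: need >= 2 samples per group")
    rows = []
    for ct in sorted(regionsets_by_celltype):
        regions = regionsets_by_celltype[ct]
        xs = [region_mean_methylation(s, regions, min_depth)[1] for s in carrier_samples]
        ys = [region_mean_methylation(s, regions, min_depth)[1] for s in control_samples]
        xs = [v for v in xs if v is not None]
        ys = [v for v in ys if v is not None]
        if not xs or not ys:
            warnings.warn(f"cell type {ct}: all set-level means missing; excluded")
            continue
        delta = float(np.mean(xs) - np.mean(ys))
        _stat, p = wilcoxon_rank_sum(xs, ys, alternative="two_sided")
        rows.append({"cell_type": ct, "delta": delta, "pvalue": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    return df
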