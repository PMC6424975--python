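"""Synthetic genomes, methylation counts, ATAC counts, and planted truth.

The generator emulates the input structure of a blood-methylation study:
chromosomes carrying disjoint region classes (enhancer-like open-chromatin
peaks, a heterochromatin-like block, background), per-cell-type peak sets
with one "specific" cell type each, transcription-factor consensus
sequences embedded inside a configurable fraction of peaks, beta-binomial
methylation counts with group effects planted at known CpGs, and
negative-binomial ATAC fragment counts elevated in each peak's specific
cell type. Every piece of planted signal is recorded in a truth object so
downstream callers can be scored for recovery.

All randomness flows from ``numpy.random.default_rng`` seeded via
``SeedSequence(seed, stream)``; identical configs give byte-identical
outputs on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .atac import ATACExperiment
from .core import (
    CpGSite,
    GenomicInterval,
    MethylationExperiment,
    MethylationSample,
    MotifMatch,
    PFM,
    RegionSet,
)
from .motif import reverse_complement

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "default_motifs",
    "simulate_genome",
    "simulate_methylation",
    "simulate_atac_counts",
]


def default_motifs() -> List[PFM]:
    """Built-in PFMs with sharply peaked columns (consensus-dominated).

    Shapes are loosely modeled on ETS-, RUNT- and GATA-family binding
    sites of hematopoietic master regulators; counts of 85 vs 5 make the
    consensus overwhelmingly the best-scoring word.
    """

    def pfm(motif_id: str, consensus: str) -> PFM:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = []
        for ch in consensus:
            col = [5.0, 5.0, 5.0, 5.0]
            col[idx[ch]] = 85.0
            counts.append(col)
        return PFM(motif_id=motif_id, counts=counts)

    return [
        pfm("ETS_like", "AGAGGAAGTG"),
        pfm("RUNT_like", "TGTGGTTTCC"),
        pfm("GATA_like", "AGATAAGAGA"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 5 carriers vs 10 controls, 2,000 CpGs across
    200 open-chromatin peaks of 4 cell types, depth ~30x, beta-binomial
    dispersion 0.05, planted shifts of 0.3 of which 97.6% are positive."""

    n_chroms: int = 2
    chrom_length: int = 100_000
    cpg_density: float = 10.0  # CpGs per kb
    cpg_jitter: float = 1.0  # fraction of the inter-CpG slot used for placement jitter
    n_celltypes: int = 4
    peaks_per_celltype: int = 50
    peak_width: int = 300
    enhancer_fraction: float = 0.5  # fraction of peaks carrying a planted motif
    motif_set: Tuple[PFM, ...] = field(default_factory=lambda: tuple(default_motifs()))
    n_carriers: int = 5
    n_controls: int = 10
    depth_mean: float = 30.0
    dispersion: float = 0.05  # beta-binomial phi
    baseline_mu: Tuple[Tuple[str, float], ...] = (
        ("enhancer", 0.2),
        ("heterochromatin", 0.8),
        ("background", 0.5),
    )
    effect_size: float = 0.3  # methylation-fraction shift at affected CpGs
    hyper_fraction: float = 0.976  # share of planted effects that are positive
    n_affected_sites: Optional[int] = None  # None = every CpG in scope
    affected_scope: str = "motif_peaks"  # motif_peaks | peaks | all | run | none
    sign_per_region: bool = False  # one effect sign per peak instead of per site
    affected_celltype: Optional[str] = None  # None = first cell type
    atac_mean_base: float = 50.0
    atac_fold: float = 10.0
    atac_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.n_celltypes,
               self.peaks_per_celltype, self.peak_width, self.n_carriers,
               self.n_controls) < 1:
            raise ValueError("all counts must be positive")
        for _cls, mu in self.baseline_mu:
            if not (0 < mu < 1):
                raise ValueError("baseline_mu values must lie in (0, 1)")
        if not (0 <= self.hyper_fraction <= 1):
            raise ValueError("hyper_fraction in [0, 1] required")
        if not (0 < self.dispersion < 1):
            raise ValueError("dispersion phi in (0, 1) required")
        if self.affected_scope not in ("motif_peaks", "peaks", "all", "run", "none"):
            raise ValueError("unknown affected_scope")

    @property
    def baseline_mu_map(self) -> Dict[str, float]:
        return dict(self.baseline_mu)

    @property
    def celltypes(self) -> List[str]:
        return [f"celltype{i + 1}" for i in range(self.n_celltypes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    cpg_sites: List[CpGSite]
    cpg_class: Dict[CpGSite, str]
    affected_sites: Dict[CpGSite, float]  # site -> signed effect
    motif_placements: List[MotifMatch]
    celltype_peaks: Dict[str, RegionSet]
    region_classes: Dict[str, RegionSet]

    def all_peaks(self) -> RegionSet:
        ivs = [iv for rs in self.celltype_peaks.values() for iv in rs.intervals]
        return RegionSet(name="open_chromatin_all", intervals=ivs)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(stream)))


def simulate_genome(config: SimConfig) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Build sequences, region annotation, motif placements, and truth.

    Chromosome layout: the first 70% hosts equally spaced open-chromatin
    peaks (round-robin across cell types) separated by background, the
    last 25% is a heterochromatin-like block. Motif consensus sequences
    are embedded on a random strand at a random offset inside the
    configured fraction of each cell type's peaks; CpG dinucleotides are
    written at the configured density, avoiding motif footprints.
    """
    rng = _rng(config.seed, 0)
    celltypes = config.celltypes
    n_peaks_total = config.n_celltypes * config.peaks_per_celltype
    peaks_per_chrom = -(-n_peaks_total // config.n_chroms)  # ceil
    peak_zone_end = int(config.chrom_length * 0.70)
    het_start = int(config.chrom_length * 0.75)
    slot = peak_zone_end // max(peaks_per_chrom, 1)
    if slot < config.peak_width + 10:
        raise ValueError(
            f"requested {n_peaks_total} peaks of width {config.peak_width} exceed "
            f"chromosome capacity ({peaks_per_chrom} slots of {slot} bp)"
        )

    genome: Dict[str, str] = {}
    seqs: Dict[str, np.ndarray] = {}
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in range(config.n_chroms):
        seqs[f"chr{c + 1}"] = base_arr[rng.integers(0, 4, size=config.chrom_length)].copy()

    celltype_peaks: Dict[str, List[GenomicInterval]] = {ct: [] for ct in celltypes}
    peak_list: List[Tuple[GenomicInterval, str]] = []
    for k in range(n_peaks_total):
        chrom = f"chr{(k % config.n_chroms) + 1}"
        slot_idx = k // config.n_chroms
        offset = (slot - config.peak_width) // 2
        start = slot_idx * slot + offset
        iv = GenomicInterval(chrom, start, start + config.peak_width)
        ct = celltypes[k % config.n_celltypes]
        celltype_peaks[ct].append(iv)
        peak_list.append((iv, ct))

    # motif placements: consensus embedded inside a fraction of each type's peaks
    placements: List[MotifMatch] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {chrom: [] for chrom in seqs}
    motifs = list(config.motif_set)
    for ct in celltypes:
        ivs = celltype_peaks[ct]
        n_bearing = int(round(config.enhancer_fraction * len(ivs)))
        chosen = rng.choice(len(ivs), size=n_bearing, replace=False) if n_bearing else []
        for j, pk_idx in enumerate(sorted(chosen)):
            iv = ivs[pk_idx]
            pfm = motifs[j % len(motifs)] if motifs else None
            if pfm is None:
                continue
            w = pfm.width
            if iv.length < w:
                raise ValueError("peak narrower than motif width")
            start = iv.start + int(rng.integers(0, iv.length - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cons = pfm.consensus()
            planted = cons if strand == "+" else reverse_complement(cons)
            seqs[iv.chrom][start : start + w] = np.frombuffer(planted.encode(), dtype=np.uint8)
            placements.append(
                MotifMatch(pfm.motif_id, GenomicInterval(iv.chrom, start, start + w), strand, 0.0)
            )
            occupied[iv.chrom].append((start, start + w))

    # CpG sites at the configured density, avoiding motif footprints
    n_cpg_per_chrom = int(round(config.chrom_length / 1000.0 * config.cpg_density))
    cpg_sites: List[CpGSite] = []
    cpg_class: Dict[CpGSite, str] = {}
    region_classes: Dict[str, List[GenomicInterval]] = {
        "enhancer": [],
        "heterochromatin": [],
        "background": [],
    }
    for chrom, arr in seqs.items():
        region_classes["heterochromatin"].append(
            GenomicInterval(chrom, het_start, config.chrom_length)
        )
        region_classes["background"].append(GenomicInterval(chrom, peak_zone_end, het_start))
        forbidden = sorted(occupied[chrom])

        def in_motif(p: int) -> bool:
            for s, e in forbidden:
                if s - 1 <= p < e:
                    return True
            return False

        spacing = config.chrom_length / max(n_cpg_per_chrom, 1)
        taken = set()
        for i in range(n_cpg_per_chrom):
            base = int(i * spacing)
            jitter_span = max(int((spacing - 2) * config.cpg_jitter), 1)
            pos = base + int(rng.integers(0, jitter_span))
            pos = min(pos, config.chrom_length - 2)
            # adjacent CpGs would overwrite each other's G; keep 1 bp apart
            while in_motif(pos) or pos in taken or pos + 1 in taken or pos - 1 in taken:
                pos += 1
                if pos >= config.chrom_length - 1:
                    pos = 0
            taken.add(pos)
            arr[pos] = ord("C")
            arr[pos + 1] = ord("G")
            cpg_sites.append(CpGSite(chrom, pos))
    region_classes["enhancer"] = [iv for iv, _ct in peak_list]

    class_sets = {
        name: RegionSet(name=name, intervals=ivs) for name, ivs in region_classes.items()
    }
    for site in cpg_sites:
        if class_sets["enhancer"].contains_point(site.chrom, site.pos):
            cpg_class[site] = "enhancer"
        elif class_sets["heterochromatin"].contains_point(site.chrom, site.pos):
            cpg_class[site] = "heterochromatin"
        else:
            cpg_class[site] = "background"

    genome = {chrom: arr.tobytes().decode("ascii") for chrom, arr in seqs.items()}
    truth = SyntheticTruth(
        cpg_sites=sorted(cpg_sites),
        cpg_class=cpg_class,
        affected_sites={},
        motif_placements=placements,
        celltype_peaks={
            ct: RegionSet(name=f"open_chromatin_{ct}", intervals=ivs,
                          metadata={"cell_type": ct})
            for ct, ivs in celltype_peaks.items()
        },
        region_classes=class_sets,
    )
    truth.affected_sites = _plant_effects(truth, config)
    return genome, truth


def _plant_effects(truth: SyntheticTruth, config: SimConfig) -> Dict[CpGSite, float]:
    """Choose affected CpGs within the configured scope and sign them."""
    if config.affected_scope == "none" or config.effect_size == 0:
        return {}
    ct = config.affected_celltype or config.celltypes[0]
    if config.affected_scope == "run":
        # one contiguous block of CpGs (region-localized effect) anchored at
        # the first site, so only the trailing edge borders unaffected CpGs
        n = config.n_affected_sites or len(truth.cpg_sites)
        pool = list(truth.cpg_sites)[:n]
        rng = _rng(config.seed, 2)
        signs = np.where(rng.random(len(pool)) < config.hyper_fraction, 1.0, -1.0)
        return {site: float(s) * config.effect_size for site, s in zip(pool, signs)}
    if config.affected_scope == "all":
        pool = list(truth.cpg_sites)
    else:
        peaks = truth.celltype_peaks[ct]
        if config.affected_scope == "motif_peaks":
            bearing = [
                iv
                for iv in peaks.intervals
                if any(
                    p.interval.chrom == iv.chrom
                    and iv.start <= p.interval.start
                    and p.interval.end <= iv.end
                    for p in truth.motif_placements
                )
            ]
            peaks = RegionSet(name="bearing", intervals=bearing)
        pool = [s for s in truth.cpg_sites if peaks.contains_point(s.chrom, s.pos)]
    rng = _rng(config.seed, 2)
    if config.n_affected_sites is not None and config.n_affected_sites < len(pool):
        idx = rng.choice(len(pool), size=config.n_affected_sites, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    if config.sign_per_region and config.affected_scope in ("motif_peaks", "peaks"):
        # coherent direction per peak, emulating region-level gain or loss
        peak_sign = {
            iv: 1.0 if rng.random() < config.hyper_fraction else -1.0
            for iv in peaks.intervals
        }
        out: Dict[CpGSite, float] = {}
        for site in pool:
            for iv in peaks.intervals:
                if iv.chrom == site.chrom and iv.start <= site.pos < iv.end:
                    out[site] = peak_sign[iv] * config.effect_size
                    break
        return out
    signs = np.where(rng.random(len(pool)) < config.hyper_fraction, 1.0, -1.0)
    return {site: float(s) * config.effect_size for site, s in zip(pool, signs)}


def simulate_methylation(truth: SyntheticTruth, config: SimConfig) -> MethylationExperiment:
    """Beta-binomial methylation counts for carriers and controls.

    Per sample and CpG: depth n ~ Poisson(depth_mean); the methylation
    fraction p is Beta-distributed with mean mu (the site's region-class
    baseline, shifted by the signed planted effect for carriers, clamped
    to [0.01, 0.99]) and dispersion phi via alpha = mu(1-phi)/phi,
    beta = (1-mu)(1-phi)/phi; n_meth ~ Binomial(n, p).
    """
    sites = truth.cpg_sites
    mu0 = np.array([config.baseline_mu_map[truth.cpg_class[s]] for s in sites])
    effect = np.array([truth.affected_sites.get(s, 0.0) for s in sites])
    phi = config.dispersion
    samples: List[MethylationSample] = []
    design: Dict[str, str] = {}
    labels = [("carrier", f"carrier{i + 1}") for i in range(config.n_carriers)] + [
        ("control", f"control{i + 1}") for i in range(config.n_controls)
    ]
    for j, (group, sid) in enumerate(labels):
        rng = _rng(config.seed, 1, j)
        mu = np.clip(mu0 + (effect if group == "carrier" else 0.0), 0.01, 0.99)
        n = rng.poisson(config.depth_mean, size=len(sites))
        alpha = mu * (1 - phi) / phi
        beta = (1 - mu) * (1 - phi) / phi
        p = rng.beta(alpha, beta)
        m = rng.binomial(n, p)
        counts = {site: (int(mi), int(ni)) for site, mi, ni in zip(sites, m, n)}
        samples.append(MethylationSample(sample_id=sid, group=group, counts=counts))
        design[sid] = group
    return MethylationExperiment(samples=samples, design=design)


def simulate_atac_counts(
    truth: SyntheticTruth, config: SimConfig, samples_per_celltype: int = 5
) -> ATACExperiment:
    """Negative-binomial fragment counts across all peaks and cell types.

    A peak's counts have mean ``atac_mean_base`` everywhere except in
    samples of the peak's specific cell type, where the mean is multiplied
    by ``atac_fold``.
    """
    if samples_per_celltype < 2:
        raise ValueError("need >= 2 samples per cell type")
    celltypes = list(truth.celltype_peaks)
    peaks: List[GenomicInterval] = []
    peak_ct: List[str] = []
    for ct in celltypes:
        for iv in truth.celltype_peaks[ct].intervals:
            peaks.append(iv)
            peak_ct.append(ct)
    sample_ids: List[str] = []
    sample_cts: List[str] = []
    for ct in celltypes:
        for i in range(samples_per_celltype):
            sample_ids.append(f"{ct}_s{i + 1}")
            sample_cts.append(ct)
    disp = config.atac_dispersion
    size = 1.0 / disp  # NB shape: variance = m + disp*m^2
    counts = np.zeros((len(peaks), len(sample_ids)), dtype=np.int64)
    peak_ct_arr = np.asarray(peak_ct)
    for j, ct in enumerate(sample_cts):
        rng = _rng(config.seed, 3, j)
        mean = np.where(peak_ct_arr == ct, config.atac_mean_base * config.atac_fold,
                        config.atac_mean_base)
        pnb = size / (size + mean)
        counts[:, j] = rng.negative_binomial(size, pnb)
    return ATACExperiment(peaks=peaks, sample_ids=sample_ids, cell_types=sample_cts,
                          counts=counts)
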