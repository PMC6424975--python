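"""End-to-end orchestration on synthetic data with planted truth.

``run_pipeline`` chains the stages in analysis order — simulate, DMC/DMR
calling, chromatin enrichment, ATAC cell-type specificity, motif scanning,
the motif-repositioning permutation test, region-mean comparison — and
writes per-stage TSV outputs plus a machine-readable ``summary.json``.
Everything is deterministic given the config seed; stage seeds are derived
from the root seed and the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List

import pandas as pd

from .atac import cell_type_specific_regions
from .enrichment import enrich_across_tracks, enrichment_table
from .methyl import (
    DMCConfig,
    DMRConfig,
    TARGETED,
    call_dmc,
    call_dmr,
    compare_region_means,
    per_sample_dmc_counts,
)
from .motif import ScanConfig, pfm_to_pwm, scan_genome
from .permtest import PermConfig, run_all
from .simulate import SimConfig, simulate_atac_counts, simulate_genome, simulate_methylation

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

REPORT_SCHEMA = {
    "sample_counts": ["sample", "group", "hyper_per_million", "hypo_per_million", "n_tested"],
    "enrichment": ["query", "track", "a", "b", "c", "d", "odds_ratio", "pvalue", "qvalue"],
    "region_means": ["cell_type", "delta", "pvalue", "qvalue"],
    "permtest": [
        "motif", "cell_type", "t_obs", "p_one_sided", "p_two_sided", "p_add_one",
        "qvalue", "n_perm", "n_bearing_regions",
    ],
}


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    dmc: DMCConfig = TARGETED
    dmr: DMRConfig = field(default_factory=DMRConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    fdr: float = 0.05
    atac_samples_per_celltype: int = 5


def dmc_table(dmcs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "mu_a": r.mu_a,
                "mu_b": r.mu_b,
                "diff": r.diff,
                "se": r.se,
                "pvalue": r.pvalue,
                "postprob": r.postprob,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in dmcs
        ]
    )


def dmr_bed(dmrs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "name": r.direction,
                "score": r.n_cpg,
                "strand": ".",
                "mean_diff": r.mean_diff,
            }
            for r in dmrs
        ]
    )


def run_pipeline(config: PipelineConfig, outdir: str) -> Dict:
    """Run the full synthetic replica of the analysis; return the summary."""
    os.makedirs(outdir, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=_stage_seed(config.sim.seed, "simulate"))
    genome, truth = simulate_genome(sim)
    experiment = simulate_methylation(truth, sim)
    atac = simulate_atac_counts(truth, sim, config.atac_samples_per_celltype)

    log: List[str] = [f"seed_root={config.sim.seed}", f"seed_simulate={sim.seed}"]

    # --- differential methylation ---------------------------------------
    dmcs = call_dmc(experiment, "carrier", "control", config.dmc)
    dmrs = call_dmr([r for r in dmcs], config.dmr)
    dmc_df = dmc_table(dmcs)
    dmc_df.to_csv(os.path.join(outdir, "dmc.tsv"), sep="\t", index=False)
    dmr_bed(dmrs).to_csv(os.path.join(outdir, "dmr.tsv"), sep="\t", index=False)

    # --- per-sample counts against a 5-control baseline ------------------
    controls = experiment.group_samples("control")
    baseline = controls[:5]
    rows = []
    for s in experiment.samples:
        if s in baseline:
            continue
        hyper, hypo, n_tested = per_sample_dmc_counts(s, baseline, config.dmc)
        rows.append(
            {
                "sample": s.sample_id,
                "group": experiment.design[s.sample_id],
                "hyper_per_million": hyper,
                "hypo_per_million": hypo,
                "n_tested": n_tested,
            }
        )
    counts_df = pd.DataFrame(rows)
    counts_df.to_csv(os.path.join(outdir, "sample_counts.tsv"), sep="\t", index=False)

    # --- chromatin enrichment of hyper/hypo DMCs -------------------------
    universe = {r.site for r in dmcs}
    tracks = [truth.region_classes[name] for name in sorted(truth.region_classes)]
    enr_frames = []
    for direction in ("hyper", "hypo"):
        query = {r.site for r in dmcs if r.significant and r.direction == direction}
        if query:
            recs = enrich_across_tracks(query, tracks, universe)
            df = enrichment_table(recs)
            df.insert(0, "query", direction)
            enr_frames.append(df)
    enr_df = (
        pd.concat(enr_frames, ignore_index=True)
        if enr_frames
        else pd.DataFrame(columns=REPORT_SCHEMA["enrichment"])
    )
    enr_df.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)

    # --- ATAC specificity -------------------------------------------------
    celltype_regions, atac_stats = cell_type_specific_regions(atac, fdr=config.fdr)
    atac_stats.to_csv(os.path.join(outdir, "specificity.tsv"), sep="\t", index=False)

    # --- motif scanning ---------------------------------------------------
    matches_by_motif = {}
    for pfm in sim.motif_set:
        pwm = pfm_to_pwm(pfm, config.scan.background, config.scan.pseudocount)
        matches_by_motif[pfm.motif_id] = scan_genome(genome, pwm, config.scan)

    # --- permutation test -------------------------------------------------
    carriers = experiment.group_samples("carrier")
    perm = dataclasses.replace(config.perm, seed=_stage_seed(config.sim.seed, "permtest"))
    log.append(f"seed_permtest={perm.seed}")
    _results, perm_df = run_all(
        matches_by_motif, celltype_regions, carriers, controls,
        perm, min_depth=config.dmc.min_depth,
    )
    perm_df.to_csv(os.path.join(outdir, "permtest.tsv"), sep="\t", index=False)

    # --- region-mean comparison ------------------------------------------
    means_df = compare_region_means(
        experiment, celltype_regions, "carrier", "control", config.dmc.min_depth
    )
    means_df.to_csv(os.path.join(outdir, "region_means.tsv"), sep="\t", index=False)

    n_sig = int(dmc_df["significant"].sum()) if not dmc_df.empty else 0
    n_hyper_dmr = sum(1 for r in dmrs if r.direction == "hyper")
    ranked = perm_df.dropna(subset=["qvalue"]).sort_values(
        ["qvalue", "p_one_sided", "motif", "cell_type"]
    )
    top = (
        {"motif": str(ranked.iloc[0]["motif"]), "cell_type": str(ranked.iloc[0]["cell_type"]),
         "qvalue": float(ranked.iloc[0]["qvalue"])}
        if not ranked.empty
        else None
    )
    summary = {
        "seed": config.sim.seed,
        "n_cpg": len(truth.cpg_sites),
        "n_tested": len(dmcs),
        "n_significant_dmc": n_sig,
        "n_dmr": len(dmrs),
        "n_hyper_dmr": n_hyper_dmr,
        "hyper_dmr_fraction": (n_hyper_dmr / len(dmrs)) if dmrs else None,
        "n_specific_peaks": int(atac_stats["specific"].sum()),
        "n_motif_matches": {k: len(v) for k, v in sorted(matches_by_motif.items())},
        "top_permutation_result": top,
        "planted": {
            "affected_celltype": sim.affected_celltype or sim.celltypes[0],
            "n_affected_sites": len(truth.affected_sites),
            "motifs": sorted({p.motif_id for p in truth.motif_placements}),
        },
        "log": log,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def make_report(summary: Dict, outdir: str) -> List[str]:
    """Render human-readable tables from stage outputs next to the summary.

    Returns the list of report lines written to ``report.txt``. Works from
    the stage TSVs in ``outdir``; an empty DMC stage is reported as zero
    DMCs rather than failing. Column sets are validated against the frozen
    schema.
    """
    lines: List[str] = ["# pipeline report", ""]
    for stage, cols in REPORT_SCHEMA.items():
        path = os.path.join(outdir, f"{stage}.tsv")
        lines.append(f"## {stage}")
        if not os.path.exists(path):
            lines.append("(stage not run)")
            lines.append("")
            continue
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            lines.append("(no rows)")
        else:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"stage {stage}: missing columns {missing}")
            lines.extend(df[cols].to_string(index=False).splitlines())
        lines.append("")
    lines.append(f"significant DMCs: {summary.get('n_significant_dmc', 0)}")
    lines.append(f"DMRs: {summary.get('n_dmr', 0)}")
    top = summary.get("top_permutation_result")
    if top:
        lines.append(
            f"top permutation result: {top['motif']} in {top['cell_type']} "
            f"(q = {top['qvalue']:.4g})"
        )
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return lines
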