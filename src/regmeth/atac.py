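"""Cell-type-specific open chromatin from a peaks x samples count matrix.

Fragment counts per peak are library-size normalized to CPM, and each
(peak, cell type) pair is tested with a one-sided Wilcoxon rank-sum test
of the type's samples against all other samples. BH correction is pooled
across every peak x type hypothesis; a peak is assigned to every cell
type reaching the FDR cutoff, so assignment is not exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, RegionSet
from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = ["ATACExperiment", "normalize_cpm", "cell_type_specific_regions"]


@dataclass
class ATACExperiment:
    peaks: List[GenomicInterval]
    sample_ids: List[str]
    cell_types: List[str]  # parallel to sample_ids
    counts: np.ndarray  # peaks x samples, non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_peaks, n_samples)")
        if len(self.cell_types) != len(self.sample_ids):
            raise ValueError("one cell type per sample required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.cell_types)) < 2:
            raise ValueError("need >= 2 cell types")

    @property
    def celltype_order(self) -> List[str]:
        seen: List[str] = []
        for ct in self.cell_types:
            if ct not in seen:
                seen.append(ct)
        return seen


def normalize_cpm(experiment: ATACExperiment) -> np.ndarray:
    """Counts-per-million per sample column."""
    totals = experiment.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero total count for sample(s): {[experiment.sample_ids[i] for i in zero]}"
        )
    return experiment.counts * (1e6 / totals)


def cell_type_specific_regions(
    experiment: ATACExperiment, fdr: float = 0.05
) -> Tuple[Dict[str, RegionSet], pd.DataFrame]:
    """Call peaks specifically open in each cell type.

    Returns ({cell_type: RegionSet of specific peaks}, stats table with one
    row per peak x type). Requires >= 2 samples in the focal type and in
    its complement.
    """
    cpm = normalize_cpm(experiment)
    ct_arr = np.asarray(experiment.cell_types)
    rows = []
    for ct in experiment.celltype_order:
        mask = ct_arr == ct
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cell type {ct}: need >= 2 samples in type and complement")
        for i, peak in enumerate(experiment.peaks):
            _stat, p = wilcoxon_rank_sum(cpm[i, mask], cpm[i, ~mask], alternative="greater")
            rows.append(
                {
                    "peak_index": i,
                    "chrom": peak.chrom,
                    "start": peak.start,
                    "end": peak.end,
                    "cell_type": ct,
                    "mean_cpm_type": float(cpm[i, mask].mean()),
                    "mean_cpm_rest": float(cpm[i, ~mask].mean()),
                    "pvalue": p,
                }
            )
    table = pd.DataFrame(rows)
    table["qvalue"] = bh_fdr(table["pvalue"].to_numpy())
    table["specific"] = table["qvalue"] <= fdr
    region_sets: Dict[str, RegionSet] = {}
    for ct in experiment.celltype_order:
        sel = table[(table["cell_type"] == ct) & table["specific"]]
        ivs = [experiment.peaks[i] for i in sel["peak_index"]]
        region_sets[ct] = RegionSet(name=f"open_chromatin_{ct}", intervals=ivs,
                                    metadata={"cell_type": ct})
    return region_sets, table
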