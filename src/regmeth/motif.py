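"""PWM construction, exact p-value thresholding, and sequence scanning.

Scores are log2 odds against an i.i.d. background (uniform by default).
The p-value -> score threshold is computed exactly (up to a discretization
bin) by dynamic programming over the distribution of the score of a
random background word: per-column score distributions are discretized on
a common grid and convolved across the motif width. Scanning scores every
window on both strands and reports windows meeting both the p-value
threshold and an absolute score cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .core import BASES, GenomicInterval, MotifMatch, PFM, PWM

__all__ = [
    "ScanConfig",
    "pfm_to_pwm",
    "score_threshold_from_pvalue",
    "scan_sequence",
    "reverse_complement",
]

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanConfig:
    pvalue_cutoff: float = 1e-4
    score_cutoff: float = 5.0  # log2-odds units
    pseudocount: float = 0.8
    background: Tuple[float, float, float, float] = UNIFORM_BG
    discretization_bins: int = 10_000

    def __post_init__(self):
        if not (0 < self.pvalue_cutoff < 1):
            raise ValueError("pvalue_cutoff in (0, 1) required")
        if self.discretization_bins < 1000:
            raise ValueError("discretization_bins >= 1000 required")


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = UNIFORM_BG,
    pseudocount: float = 0.8,
) -> PWM:
    """Log2-odds PWM with background-proportional pseudocounts.

    logodds[i, b] = log2((counts[i,b] + pc*bg[b]) / (total_i + pc)) - log2(bg[b])
    """
    bg = tuple(float(b) for b in background)
    if any(b <= 0 for b in bg):
        raise ValueError("background probabilities must be strictly positive")
    logodds: List[List[float]] = []
    for i, col in enumerate(pfm.counts):
        total = sum(col)
        if total + pseudocount <= 0:
            raise ValueError(f"PFM {pfm.motif_id}: zero column total with zero pseudocount")
        row = []
        for b in range(4):
            num = col[b] + pseudocount * bg[b]
            if num <= 0:
                raise ValueError(
                    f"PFM {pfm.motif_id}: zero probability at position {i}, base {BASES[b]}"
                )
            row.append(math.log2(num / (total + pseudocount)) - math.log2(bg[b]))
        logodds.append(row)
    return PWM(motif_id=pfm.motif_id, logodds=logodds, background=bg, pseudocount=pseudocount)


def score_threshold_from_pvalue(
    pwm: PWM,
    background: Optional[Sequence[float]] = None,
    pvalue_cutoff: float = 1e-4,
    bins: int = 10_000,
) -> Tuple[float, bool]:
    """Smallest score t with P(score(W) >= t) <= cutoff for background words W.

    Returns (threshold, reachable). When even the maximum score carries
    tail mass above the cutoff the threshold is the maximum score and
    ``reachable`` is False.
    """
    bg = np.asarray(background if background is not None else pwm.background, dtype=float)
    lom = np.asarray(pwm.logodds, dtype=float)
    width = lom.shape[0]
    lo, hi = pwm.min_score(), pwm.max_score()
    span = hi - lo
    if span <= 0:
        # degenerate flat PWM: every word has the same score
        return hi, pvalue_cutoff >= 1.0
    # internal grid is `width` times finer than the nominal bin so that the
    # accumulated per-column rounding error stays below half a nominal bin
    eps = span / (bins * width)
    # integer offsets per column relative to the column minimum
    col_min = lom.min(axis=1)
    q = np.rint((lom - col_min[:, None]) / eps).astype(np.int64)
    # distribution over the integer score sum
    dist = np.zeros(1, dtype=float)
    dist[0] = 1.0
    for i in range(width):
        col = np.zeros(int(q[i].max()) + 1, dtype=float)
        for b in range(4):
            col[q[i, b]] += bg[b]
        dist = fftconvolve(dist, col)
    dist = np.clip(dist, 0.0, None)  # FFT round-off can go slightly negative
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(sum >= k)
    base = float(col_min.sum())
    ok = np.flatnonzero(tail <= pvalue_cutoff)
    if ok.size == 0:
        return hi, False
    return base + float(ok[0]) * eps, True


def _score_windows(seq_idx: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of all windows; windows containing N (index 4) score -inf."""
    width = lom.shape[0]
    n = seq_idx.size - width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for i in range(width):
        idx = seq_idx[i : i + n]
        valid = idx < 4
        bad |= ~valid
        scores += np.where(valid, lom[i, np.minimum(idx, 3)], 0.0)
    scores[bad] = -np.inf
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    config: ScanConfig = ScanConfig(),
    chrom: str = "seq",
    threshold: Optional[float] = None,
) -> List[MotifMatch]:
    """Scan both strands of ``seq`` for PWM matches.

    The effective threshold is max(p-value threshold, score_cutoff) unless
    given explicitly. Minus-strand matches (reverse-complement PWM on the
    + sequence) are reported in + strand window coordinates. Windows
    containing N are skipped.
    """
    width = pwm.width
    if len(seq) < width:
        return []
    if threshold is None:
        t_p, _reachable = score_threshold_from_pvalue(
            pwm, config.background, config.pvalue_cutoff, config.discretization_bins
        )
        threshold = max(t_p, config.score_cutoff)
    idx = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    seq_idx = lut[idx]
    lom = np.asarray(pwm.logodds, dtype=float)
    rc_lom = np.asarray(pwm.reverse_complement().logodds, dtype=float)
    matches: List[MotifMatch] = []
    fwd = _score_windows(seq_idx, lom)
    rev = _score_windows(seq_idx, rc_lom)
    for pos in np.flatnonzero(fwd >= threshold):
        matches.append(
            MotifMatch(pwm.motif_id, GenomicInterval(chrom, int(pos), int(pos) + width), "+",
                       float(fwd[pos]))
        )
    for pos in np.flatnonzero(rev >= threshold):
        matches.append(
            MotifMatch(pwm.motif_id, GenomicInterval(chrom, int(pos), int(pos) + width), "-",
                       float(rev[pos]))
        )
    matches.sort(key=lambda m: (m.interval.start, m.strand))
    return matches


def scan_genome(
    genome: Dict[str, str], pwm: PWM, config: ScanConfig = ScanConfig()
) -> List[MotifMatch]:
    """Scan every sequence of a genome; threshold computed once per PWM."""
    t_p, _ = score_threshold_from_pvalue(
        pwm, config.background, config.pvalue_cutoff, config.discretization_bins
    )
    threshold = max(t_p, config.score_cutoff)
    out: List[MotifMatch] = []
    for chrom, seq in genome.items():
        out.extend(scan_sequence(seq, pwm, config, chrom=chrom, threshold=threshold))
    return out
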