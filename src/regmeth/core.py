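"""Domain types and interval algebra shared across the pipeline.

All coordinates are 0-based half-open throughout the package; 1-based
inputs (Bismark coverage) are converted at the I/O boundary. A CpG site is
identified by the + strand position of its cytosine.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Tuple

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "CpGSite",
    "MethylationSample",
    "MethylationExperiment",
    "PFM",
    "PWM",
    "MotifMatch",
    "contained_matches",
]


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # type: ignore[override]
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "GenomicInterval":
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        return self


class CpGSite(NamedTuple):
    """A CpG dinucleotide, addressed by the + strand cytosine position."""

    chrom: str
    pos: int


@dataclass
class RegionSet:
    """A named collection of genomic intervals (chromatin track, peak set, ...).

    Intervals are kept sorted by (chrom, start); internal overlaps are
    permitted and never merged, matching how downloaded annotation tracks
    are consumed as-is.
    """

    name: str
    intervals: List[GenomicInterval]
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iv in self.intervals:
            iv.validate()
        self.intervals = sorted(self.intervals)
        self._index: Optional[Dict[str, Tuple[List[int], List[int], List[int]]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    # -- interval queries -------------------------------------------------
    def _build_index(self) -> Dict[str, Tuple[List[int], List[int], List[int]]]:
        """Per-chromosome (starts, ends, prefix-max-ends), starts ascending.

        The prefix maximum of ends over intervals with start <= x answers
        containment queries in O(log n): the interval attaining the prefix
        max itself starts at or before x.
        """
        if self._index is None:
            idx: Dict[str, Tuple[List[int], List[int], List[int]]] = {}
            by_chrom: Dict[str, List[GenomicInterval]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, ivs in by_chrom.items():
                starts = [iv.start for iv in ivs]
                ends = [iv.end for iv in ivs]
                pmax: List[int] = []
                cur = -1
                for e in ends:
                    cur = max(cur, e)
                    pmax.append(cur)
                idx[chrom] = (starts, ends, pmax)
            self._index = idx
        return self._index

    def contains_interval(self, iv: GenomicInterval) -> bool:
        """True iff some region fully contains ``iv`` (same chromosome)."""
        index = self._build_index()
        entry = index.get(iv.chrom)
        if entry is None:
            return False
        starts, _ends, pmax = entry
        k = bisect.bisect_right(starts, iv.start)
        return k > 0 and pmax[k - 1] >= iv.end

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` lies inside some region (half-open semantics)."""
        index = self._build_index()
        entry = index.get(chrom)
        if entry is None:
            return False
        starts, _ends, pmax = entry
        k = bisect.bisect_right(starts, pos)
        return k > 0 and pmax[k - 1] > pos

    def invalidate_index(self) -> None:
        self._index = None


@dataclass
class MethylationSample:
    """Per-CpG (methylated, total) read counts for one sample."""

    sample_id: str
    group: str
    counts: Dict[CpGSite, Tuple[int, int]]

    def __post_init__(self) -> None:
        for site, (m, n) in self.counts.items():
            if not (0 <= m <= n):
                raise ValueError(
                    f"sample {self.sample_id}, site {site.chrom}:{site.pos}: "
                    f"require 0 <= n_meth <= n_total, got ({m}, {n})"
                )

    def sites(self) -> Iterable[CpGSite]:
        return self.counts.keys()


@dataclass
class MethylationExperiment:
    """A set of methylation samples together with the group design."""

    samples: List[MethylationSample]
    design: Dict[str, str]

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        for sid in self.design:
            if sid not in ids:
                raise ValueError(f"design references unknown sample {sid!r}")
        for s in self.samples:
            self.design.setdefault(s.sample_id, s.group)

    def group_samples(self, group: str) -> List[MethylationSample]:
        out = [s for s in self.samples if self.design.get(s.sample_id) == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out

    @property
    def groups(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            g = self.design[s.sample_id]
            if g not in seen:
                seen.append(g)
        return seen


BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PFM:
    """Position frequency matrix: per-position observed base counts (A,C,G,T)."""

    motif_id: str
    counts: List[List[float]]  # width x 4

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError(f"PFM {self.motif_id}: width must be >= 1")
        for i, col in enumerate(self.counts):
            if len(col) != 4:
                raise ValueError(f"PFM {self.motif_id}: position {i} lacks 4 base counts")
            if any(c < 0 for c in col):
                raise ValueError(f"PFM {self.motif_id}: negative count at position {i}")
            if sum(col) <= 0:
                raise ValueError(f"PFM {self.motif_id}: position {i} has zero total")

    @property
    def width(self) -> int:
        return len(self.counts)

    def consensus(self) -> str:
        """Column-wise argmax sequence (ties broken by A<C<G<T order)."""
        return "".join(BASES[max(range(4), key=lambda b: col[b])] for col in self.counts)


@dataclass
class PWM:
    """Log-odds position weight matrix over background base frequencies."""

    motif_id: str
    logodds: List[List[float]]  # width x 4, log2 units
    background: Tuple[float, float, float, float]
    pseudocount: float

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")
        for col in self.logodds:
            for v in col:
                if not (v == v and abs(v) != float("inf")):
                    raise ValueError(f"PWM {self.motif_id}: non-finite score")

    @property
    def width(self) -> int:
        return len(self.logodds)

    def max_score(self) -> float:
        return sum(max(col) for col in self.logodds)

    def min_score(self) -> float:
        return sum(min(col) for col in self.logodds)

    def reverse_complement(self) -> "PWM":
        # reverse position order, swap A<->T and C<->G within each column
        rc = [[col[3], col[2], col[1], col[0]] for col in reversed(self.logodds)]
        return PWM(self.motif_id, rc, self.background, self.pseudocount)


class MotifMatch(NamedTuple):
    """A PWM hit; the interval always spans exactly the motif width."""

    motif_id: str
    interval: GenomicInterval
    strand: str  # '+' or '-'
    score: float


def contained_matches(matches: Iterable[MotifMatch], regions: RegionSet) -> List[MotifMatch]:
    """Matches fully contained in some region (full overlap), order preserved."""
    return [m for m in matches if regions.contains_interval(m.interval)]
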