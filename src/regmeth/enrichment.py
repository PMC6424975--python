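"""Region-set overlap enrichment of CpG sets against labeled tracks.

For a query set of CpGs (e.g. hypermethylated sites) and a tested-CpG
universe, each track yields a 2x2 table of point-in-interval memberships
and a one-sided Fisher's exact p-value (hypergeometric upper tail), the
construction used by locus-overlap enrichment tools. The background set is
always the full universe of tested CpGs, never the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

import pandas as pd
from scipy.stats import hypergeom

from .core import CpGSite, RegionSet
from .stats import bh_fdr

__all__ = ["EnrichmentRecord", "enrichment_test", "enrich_across_tracks"]


@dataclass
class EnrichmentRecord:
    track: str
    a: int  # query CpGs in track
    b: int  # query CpGs outside track
    c: int  # non-query universe CpGs in track
    d: int  # remainder
    odds_ratio: float
    pvalue: float
    qvalue: float = float("nan")


def enrichment_test(
    query_sites: Set[CpGSite], track: RegionSet, universe: Set[CpGSite]
) -> EnrichmentRecord:
    """One-sided (enrichment) Fisher's exact test of query vs universe.

    Membership is point-in-interval; a CpG inside several overlapping
    intervals of the track counts once. The odds ratio is (a*d)/(b*c) with
    the Haldane-Anscombe +0.5 applied to every cell iff any cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query_sites <= universe:
        raise ValueError("query sites must be a subset of the universe")
    in_track = {s for s in universe if track.contains_point(s.chrom, s.pos)}
    a = len(query_sites & in_track)
    b = len(query_sites) - a
    c = len(in_track) - a
    d = len(universe) - a - b - c
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    else:
        oa, ob, oc, od = (a, b, c, d)
    odds_ratio = (oa * od) / (ob * oc)
    # P(X >= a) for X ~ Hypergeom(N=|universe|, K=|track cap universe|, n=|query|)
    p = float(hypergeom.sf(a - 1, len(universe), a + c, a + b))
    return EnrichmentRecord(track=track.name, a=a, b=b, c=c, d=d, odds_ratio=odds_ratio, pvalue=p)


def enrich_across_tracks(
    query_sites: Set[CpGSite], tracks: Sequence[RegionSet], universe: Set[CpGSite]
) -> List[EnrichmentRecord]:
    """Enrichment of one query set against many tracks, BH across tracks.

    Returns records sorted by descending odds ratio.
    """
    if not tracks:
        raise ValueError("need at least one track")
    records = [enrichment_test(query_sites, t, universe) for t in tracks]
    qs = bh_fdr([r.pvalue for r in records])
    for r, q in zip(records, qs):
        r.qvalue = float(q)
    records.sort(key=lambda r: -r.odds_ratio)
    return records


def enrichment_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track": r.track,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
            }
            for r in records
        ]
    )
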