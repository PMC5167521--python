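"""Population-level refinement of insertion calls.

Insertion breakpoints discovered per sample are merged across the
population; every sample is then re-interrogated at every merged site
with a relaxed evidence threshold (a single TE-linked split read), so a
site confidently discovered in one accession rescues borderline support
in another.  A site with no read coverage in a sample is genotyped NA
rather than 0.  Absence calls are not refined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DiscoverParams, RefineParams
from .discover import (
    Evidence,
    LibraryStats,
    TEIndex,
    TEInsertionCall,
    estimate_library_stats,
    extract_evidence,
)
from .io import GenomeLayout, TEAnnotation


@dataclass(frozen=True)
class MergedInsertionSite:
    site_id: str
    chrom: str
    start: int
    end: int
    te_ids: tuple[str, ...]
    carriers: tuple[str, ...]


def merge_insertions(
    call_sets: Mapping[str, Sequence[TEInsertionCall]],
    merge_distance: int = 100,
) -> list[MergedInsertionSite]:
    """Collapse per-sample insertion calls into population sites.

    Calls within ``merge_distance`` bp sharing at least one candidate TE
    collapse into one site; the consensus interval is the intersection of
    the member intervals when nonempty, else their union.
    """
    entries = []
    for sample, calls in call_sets.items():
        for call in calls:
            entries.append((call.chrom, call.start, call.end, set(call.te_ids), sample))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    sites: list[MergedInsertionSite] = []
    group: list[tuple] = []

    def _flush() -> None:
        if not group:
            return
        starts = [g[1] for g in group]
        ends = [g[2] for g in group]
        lo, hi = max(starts), min(ends)
        if lo > hi:  # no common intersection -> union
            lo, hi = min(starts), max(ends)
        tes: set[str] = set()
        for g in group:
            tes |= g[3]
        carriers = tuple(sorted({g[4] for g in group}))
        sites.append(
            MergedInsertionSite(
                site_id=f"site_{len(sites) + 1:05d}",
                chrom=group[0][0],
                start=lo,
                end=hi,
                te_ids=tuple(sorted(tes)),
                carriers=carriers,
            )
        )
        group.clear()

    group_end = -1
    group_tes: set = set()
    for entry in entries:
        chrom, start, end, tes, _ = entry
        if (
            group
            and chrom == group[0][0]
            and start - group_end <= merge_distance
            and tes & group_tes
        ):
            group.append(entry)
            group_end = max(group_end, end)
            group_tes |= tes
        else:
            _flush()
            group.append(entry)
            group_end = end
            group_tes = set(tes)
    _flush()
    # renumber in sorted order for stable site ids
    sites.sort(key=lambda s: (s.chrom, s.start))
    return [
        MergedInsertionSite(f"site_{i + 1:05d}", s.chrom, s.start, s.end, s.te_ids, s.carriers)
        for i, s in enumerate(sites)
    ]


def refine_sample(
    evidence: Evidence,
    sites: Sequence[MergedInsertionSite],
    annotation: Sequence[TEAnnotation],
    stats: LibraryStats,
    sample: str,
    refine_params: RefineParams | None = None,
    discover_params: DiscoverParams | None = None,
) -> pd.Series:
    """Genotype one sample at every merged site: 1 / 0 / NA.

    Carriers (samples whose own discovery produced the site) keep 1.
    For non-carriers: any zero-coverage base within the site extended by
    one read length gives NA; otherwise one or more split reads linking
    the site to its TE give 1, and uninterrupted concordant coverage
    with no TE-linked evidence gives 0.
    """
    refine_params = refine_params or RefineParams()
    discover_params = discover_params or DiscoverParams()
    index = TEIndex(annotation)
    rl = stats.read_length

    # TE-linked split anchors, as in discovery but kept at 1-read evidence
    anchors: list[tuple[str, int, int, frozenset]] = []
    for split in evidence.splits:
        te_1 = index.covering_frac_of_read(split.seg1, discover_params.te_overlap_frac)
        te_2 = index.covering_frac_of_read(split.seg2, discover_params.te_overlap_frac)
        if bool(te_1) == bool(te_2):
            continue
        seg, tes = (split.seg2, te_1) if te_1 else (split.seg1, te_2)
        anchors.append((seg.chrom, seg.start, seg.end, frozenset(t.te_id for t in tes)))

    out = {}
    for site in sites:
        if sample in site.carriers:
            out[site.site_id] = 1.0
            continue
        depth = evidence.depth.get(site.chrom)
        if depth is None:
            out[site.site_id] = np.nan
            continue
        lo = max(0, site.start - rl)
        hi = min(len(depth), site.end + rl)
        window = depth[lo:hi]
        if window.size == 0 or window.min() == 0:
            out[site.site_id] = np.nan
            continue
        n_link = sum(
            1
            for chrom, s, e, tes in anchors
            if chrom == site.chrom and s < hi and e > lo and tes & set(site.te_ids)
        )
        out[site.site_id] = 1.0 if n_link >= refine_params.min_split_reads else 0.0
    series = pd.Series(out, name=sample)
    return series.reindex([s.site_id for s in sites])


def refine_sample_from_file(
    path: str | Path,
    sites: Sequence[MergedInsertionSite],
    annotation: Sequence[TEAnnotation],
    layout: GenomeLayout,
    sample: str,
    refine_params: RefineParams | None = None,
    discover_params: DiscoverParams | None = None,
) -> pd.Series:
    stats = estimate_library_stats(path, layout, discover_params)
    evidence = extract_evidence(path, stats, layout, discover_params)
    return refine_sample(
        evidence, sites, annotation, stats, sample, refine_params, discover_params
    )


def build_population_matrix(
    refined: Mapping[str, pd.Series],
    discover_counts: Mapping[str, int],
    sites: Sequence[MergedInsertionSite],
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the sites x samples genotype matrix and per-sample
    refinement gains (calls added by refinement / discovery calls)."""
    site_ids = [s.site_id for s in sites]
    columns = {}
    for sample, series in refined.items():
        if list(series.index) != site_ids:
            raise ValueError(f"sample {sample!r} genotyped over a different site list")
        columns[sample] = series
    matrix = pd.DataFrame(columns)
    carrier_lookup = {s.site_id: set(s.carriers) for s in sites}
    gains = {}
    for sample in matrix.columns:
        added = sum(
            1
            for site_id in site_ids
            if matrix.at[site_id, sample] == 1.0
            and sample not in carrier_lookup[site_id]
        )
        denom = discover_counts.get(sample, 0)
        gains[sample] = added / denom if denom else np.nan
    return matrix, pd.Series(gains, name="refinement_gain")
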