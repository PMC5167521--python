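"""TE presence/absence discovery from split and discordant alignments.

The caller estimates the library insert model from proper pairs, extracts
discordant pairs (mates mapping beyond four standard deviations of the
insert mean, or to different chromosomes) and split reads (segments at
least 5 kb apart, MAPQ >= 5), links evidence reads to annotated TEs at
80% overlap, and then:

* calls a TE *insertion* where clustered evidence reads anchor a
  breakpoint whose mates all point into the same TE, with a read-count
  threshold scaled to sequencing depth (coverage/10, floor 2, doubled in
  the absence of facing read pairs);
* calls a TE *absence* where split/discordant reads span at least 80% of
  an annotated TE and internal sequencing depth collapses below 10% of
  the 2 kb flanks (or, at depth ratios below 1, twice the spanning-read
  threshold is demanded).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .config import DiscoverParams
from .io import GenomeLayout, TEAnnotation, VariantRecord, open_alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class DiscoverError(RuntimeError):
    pass


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size model and genome-wide mean coverage for one sample."""

    insert_mean: float
    insert_sd: float
    mean_coverage: float
    read_length: int

    def __post_init__(self) -> None:
        if self.insert_mean <= 0 or self.mean_coverage <= 0 or self.read_length <= 0:
            raise ValueError("library statistics must be positive")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")

    def discordance_cutoff(self, params: DiscoverParams) -> float:
        return self.insert_mean + params.sd_multiplier * self.insert_sd


@dataclass(frozen=True)
class Mate:
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class DiscordantPair:
    name: str
    a: Mate  # sorted: a <= b by (chrom, start)
    b: Mate


@dataclass(frozen=True)
class SplitRead:
    name: str
    seg1: Mate           # the primary (soft-clipped) alignment
    seg2: Mate           # the remote segment from the SA tag
    mapq: int
    junction1: int       # seg1 edge adjacent to seg2 in the query
    junction2: int


@dataclass
class Evidence:
    discordant: list[DiscordantPair]
    splits: list[SplitRead]
    depth: dict[str, np.ndarray]


@dataclass(frozen=True)
class TEInsertionCall:
    chrom: str
    start: int
    end: int
    te_ids: tuple[str, ...]        # ranked by supporting-read count
    families: tuple[str, ...]
    n_split: int
    n_discordant: int
    has_facing_pairs: bool
    read_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class TEAbsenceCall:
    chrom: str
    start: int                     # spanned interval
    end: int
    te_ids: tuple[str, ...]
    n_spanning: int
    internal_coverage: float
    flanking_coverage: float
    read_names: tuple[str, ...] = ()


def insertion_read_threshold(
    mean_coverage: float, params: DiscoverParams | None = None
) -> int:
    """Minimum supporting reads: coverage/10 when coverage exceeds 10,
    otherwise (and never below) 2."""
    if mean_coverage <= 0:
        raise ValueError("coverage must be > 0")
    return (params or DiscoverParams()).threshold(mean_coverage)


# ---------------------------------------------------------------------------
# Library statistics
# ---------------------------------------------------------------------------


def estimate_library_stats(
    path: str | Path,
    layout: GenomeLayout,
    params: DiscoverParams | None = None,
) -> LibraryStats:
    """Estimate insert mean/SD (from proper-pair template lengths, top and
    bottom 1% trimmed) and mean coverage (aligned bases over the unmasked
    genome length)."""
    params = params or DiscoverParams()
    tlens: list[int] = []
    aligned = 0
    read_length = 0
    with open_alignments(path) as afile:
        for rec in afile:
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            if rec.reference_name in layout.masked:
                continue
            aligned += rec.reference_length or 0
            if rec.is_supplementary:
                continue
            if rec.query_length:
                read_length = max(read_length, rec.query_length)
            if rec.is_proper_pair and rec.template_length > 0:
                tlens.append(rec.template_length)
    if len(tlens) < params.min_proper_pairs:
        raise DiscoverError(
            f"only {len(tlens)} proper pairs found; "
            f"need >= {params.min_proper_pairs} to model the insert size"
        )
    arr = np.sort(np.asarray(tlens, dtype=float))
    k = int(len(arr) * params.trim_frac)
    if len(arr) - 2 * k >= 2:
        arr = arr[k : len(arr) - k]
    coverage = aligned / layout.unmasked_length
    return LibraryStats(
        insert_mean=float(arr.mean()),
        insert_sd=float(arr.std()),
        mean_coverage=float(coverage),
        read_length=int(read_length),
    )


def trimmed_moments(values: Iterable[float], trim_frac: float = 0.01) -> tuple[float, float]:
    """Mean/SD after trimming the top and bottom ``trim_frac`` — the same
    statistic :func:`estimate_library_stats` reports."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    k = int(len(arr) * trim_frac)
    if len(arr) - 2 * k >= 2:
        arr = arr[k : len(arr) - k]
    return float(arr.mean()), float(arr.std())


# ---------------------------------------------------------------------------
# Evidence extraction
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str) -> tuple[int, int, int]:
    """(reference_length, leading_clip, trailing_clip) of a CIGAR string."""
    ops = _CIGAR_RE.findall(cigar)
    ref_len = sum(int(n) for n, op in ops if op in "MDN=X")
    lead = int(ops[0][0]) if ops and ops[0][1] in "SH" else 0
    trail = int(ops[-1][0]) if ops and ops[-1][1] in "SH" else 0
    return ref_len, lead, trail


def _segment_distance(a: Mate, b: Mate) -> float:
    if a.chrom != b.chrom:
        return float("inf")
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0.0


def extract_evidence(
    path: str | Path,
    stats: LibraryStats,
    layout: GenomeLayout,
    params: DiscoverParams | None = None,
) -> Evidence:
    """One pass over the alignments collecting discordant pairs, filtered
    split reads and the per-base depth of every unmasked chromosome."""
    params = params or DiscoverParams()
    cutoff = stats.discordance_cutoff(params)
    pending: dict[str, Mate] = {}
    discordant: list[DiscordantPair] = []
    splits: list[SplitRead] = []
    starts: dict[str, list[int]] = {c: [] for c in layout.chroms}
    ends: dict[str, list[int]] = {c: [] for c in layout.chroms}

    with open_alignments(path) as afile:
        for rec in afile:
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            chrom = rec.reference_name
            if chrom in layout.masked:
                continue
            if chrom in starts:
                starts[chrom].append(rec.reference_start)
                ends[chrom].append(rec.reference_end)
            if rec.is_supplementary:
                continue

            strand = "-" if rec.is_reverse else "+"
            mate = Mate(chrom, rec.reference_start, rec.reference_end, strand)

            # split reads via the SA tag on the primary record
            if rec.has_tag("SA") and rec.mapping_quality >= params.min_mapq:
                sa = rec.get_tag("SA").split(";")[0].split(",")
                o_chrom, o_pos, o_strand, o_cigar = sa[0], int(sa[1]) - 1, sa[2], sa[3]
                o_ref_len, o_lead, o_trail = _parse_cigar(o_cigar)
                seg2 = Mate(o_chrom, o_pos, o_pos + o_ref_len, o_strand)
                if seg2.chrom not in layout.masked:
                    dist = _segment_distance(mate, seg2)
                    if dist >= params.min_split_distance:
                        _, lead, trail = _parse_cigar(rec.cigarstring)
                        j1 = mate.start if lead > trail else mate.end
                        j2 = seg2.start if o_lead > o_trail else seg2.end
                        splits.append(
                            SplitRead(
                                f"{rec.query_name}/{1 if rec.is_read1 else 2}",
                                mate, seg2, rec.mapping_quality, j1, j2,
                            )
                        )

            # discordant pairs: pair up the two primaries by name
            if rec.is_paired and not rec.mate_is_unmapped:
                mate_chrom = rec.next_reference_name
                if mate_chrom in layout.masked:
                    continue
                is_disc = (mate_chrom != chrom) or abs(rec.template_length) > cutoff
                if not is_disc:
                    continue
                other = pending.pop(rec.query_name, None)
                if other is None:
                    pending[rec.query_name] = mate
                else:
                    a, b = sorted([other, mate], key=lambda m: (m.chrom, m.start))
                    discordant.append(DiscordantPair(rec.query_name, a, b))

    depth = {}
    for chrom in layout.chroms:
        L = layout.chrom_lengths[chrom]
        diff = np.zeros(L + 1, dtype=np.int32)
        if starts[chrom]:
            np.add.at(diff, np.asarray(starts[chrom]), 1)
            np.add.at(diff, np.minimum(np.asarray(ends[chrom]), L), -1)
        depth[chrom] = np.cumsum(diff[:-1], dtype=np.int32)
    return Evidence(discordant, splits, depth)


# ---------------------------------------------------------------------------
# TE interval index
# ---------------------------------------------------------------------------


class TEIndex:
    """Interval lookup of annotated TEs, by chromosome."""

    def __init__(self, annotation: Sequence[TEAnnotation]):
        self.by_id = {t.te_id: t for t in annotation}
        self._trees: dict[str, IntervalTree] = {}
        for te in annotation:
            self._trees.setdefault(te.chrom, IntervalTree()).addi(
                te.start, te.end, te
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[TEAnnotation]:
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def covering_frac_of_read(
        self, mate: Mate, frac: float
    ) -> list[TEAnnotation]:
        """TEs overlapping at least ``frac`` of the mate's mapped span."""
        span = mate.end - mate.start
        out = []
        for te in self.overlapping(mate.chrom, mate.start, mate.end):
            ovl = min(mate.end, te.end) - max(mate.start, te.start)
            if ovl >= frac * span:
                out.append(te)
        return out


# ---------------------------------------------------------------------------
# Insertion calling
# ---------------------------------------------------------------------------


@dataclass
class _Anchor:
    chrom: str
    start: int
    end: int
    strand: str
    te_ids: frozenset
    kind: str            # 'disc' | 'split'
    name: str
    junction: int | None = None


def _build_anchors(
    evidence: Evidence, index: TEIndex, params: DiscoverParams
) -> list[_Anchor]:
    anchors = []
    for pair in evidence.discordant:
        te_a = index.covering_frac_of_read(pair.a, params.te_overlap_frac)
        te_b = index.covering_frac_of_read(pair.b, params.te_overlap_frac)
        if bool(te_a) == bool(te_b):
            continue  # need exactly one TE-side mate to anchor the other
        anchor_mate, tes = (pair.b, te_a) if te_a else (pair.a, te_b)
        anchors.append(
            _Anchor(
                anchor_mate.chrom, anchor_mate.start, anchor_mate.end,
                anchor_mate.strand, frozenset(t.te_id for t in tes),
                "disc", pair.name,
            )
        )
    for split in evidence.splits:
        te_1 = index.covering_frac_of_read(split.seg1, params.te_overlap_frac)
        te_2 = index.covering_frac_of_read(split.seg2, params.te_overlap_frac)
        if bool(te_1) == bool(te_2):
            continue
        seg, junction, tes = (
            (split.seg2, split.junction2, te_1) if te_1
            else (split.seg1, split.junction1, te_2)
        )
        anchors.append(
            _Anchor(
                seg.chrom, seg.start, seg.end, seg.strand,
                frozenset(t.te_id for t in tes), "split", split.name,
                junction=junction,
            )
        )
    anchors.sort(key=lambda a: (a.chrom, a.start, a.end))
    return anchors


def call_insertions(
    evidence: Evidence,
    annotation: Sequence[TEAnnotation],
    stats: LibraryStats,
    params: DiscoverParams | None = None,
) -> list[TEInsertionCall]:
    """Cluster TE-linked evidence anchors into insertion calls.

    Anchors (the non-TE-side mappings) within one insert-model span of
    each other and sharing a candidate TE form a site.  A site is called
    when its split+discordant support reaches the coverage-scaled
    threshold — doubled when no facing discordant pairs bracket the
    breakpoint.  The breakpoint is the innermost interval between facing
    inner edges, narrowed to the junction when a split read crosses it.
    """
    params = params or DiscoverParams()
    index = TEIndex(annotation)
    anchors = _build_anchors(evidence, index, params)
    merge = params.merge_distance
    if merge is None:
        merge = int(stats.discordance_cutoff(params))
    threshold = params.threshold(stats.mean_coverage)

    calls: list[TEInsertionCall] = []
    cluster: list[_Anchor] = []

    def _flush() -> None:
        if not cluster:
            return
        fwd = [a for a in cluster if a.kind == "disc" and a.strand == "+"]
        rev = [a for a in cluster if a.kind == "disc" and a.strand == "-"]
        facing = any(
            f.te_ids & r.te_ids
            and f.start <= r.start
            and f.end <= r.start + stats.read_length
            for f in fwd
            for r in rev
        )
        required = threshold if facing else 2 * threshold
        n_split = sum(a.kind == "split" for a in cluster)
        n_disc = len(cluster) - n_split
        if n_split + n_disc < required:
            cluster.clear()
            return
        junctions = [a.junction for a in cluster if a.junction is not None]
        if junctions:
            lo, hi = min(junctions), max(junctions)
        elif fwd and rev:
            lo = max(a.end for a in fwd)
            hi = min(a.start for a in rev)
        else:
            lo = min(a.start for a in cluster)
            hi = max(a.end for a in cluster)
        if hi < lo:
            lo = hi = (lo + hi) // 2
        cap = int(stats.discordance_cutoff(params))
        if hi - lo > cap:
            mid = (lo + hi) // 2
            lo, hi = mid - cap // 2, mid + cap // 2
        counts: dict[str, int] = {}
        for a in cluster:
            for te in a.te_ids:
                counts[te] = counts.get(te, 0) + 1
        ranked = sorted(counts, key=lambda t: (-counts[t], t))
        calls.append(
            TEInsertionCall(
                chrom=cluster[0].chrom,
                start=lo,
                end=hi,
                te_ids=tuple(ranked),
                families=tuple(index.by_id[t].family for t in ranked),
                n_split=n_split,
                n_discordant=n_disc,
                has_facing_pairs=facing,
                read_names=tuple(a.name for a in cluster),
            )
        )
        cluster.clear()

    cluster_end = -1
    cluster_tes: set = set()
    for anchor in anchors:
        if (
            cluster
            and anchor.chrom == cluster[0].chrom
            and anchor.start - cluster_end <= merge
            and anchor.te_ids & cluster_tes
        ):
            cluster.append(anchor)
            cluster_end = max(cluster_end, anchor.end)
            cluster_tes |= anchor.te_ids
        else:
            _flush()
            cluster.append(anchor)
            cluster_end = anchor.end
            cluster_tes = set(anchor.te_ids)
    _flush()
    for call in calls:  # invariant: support never below the applied threshold
        applied = threshold if call.has_facing_pairs else 2 * threshold
        assert call.n_split + call.n_discordant >= applied
    return calls


# ---------------------------------------------------------------------------
# Absence calling
# ---------------------------------------------------------------------------


def _spanning_intervals(
    evidence: Evidence, params: DiscoverParams
) -> list[tuple[str, int, int, str]]:
    """(chrom, gap_start, gap_end, read_name) intervals spanned by split or
    facing discordant reads, capped at ``max_span``."""
    spans = []
    for split in evidence.splits:
        if split.seg1.chrom != split.seg2.chrom:
            continue
        left, right = sorted([split.seg1, split.seg2], key=lambda m: m.start)
        if left.end < right.start and right.start - left.end <= params.max_span:
            spans.append((left.chrom, left.end, right.start, split.name))
    for pair in evidence.discordant:
        if pair.a.chrom != pair.b.chrom:
            continue
        if pair.a.strand != "+" or pair.b.strand != "-":
            continue
        if pair.a.end < pair.b.start and pair.b.start - pair.a.end <= params.max_span:
            spans.append((pair.a.chrom, pair.a.end, pair.b.start, pair.name))
    return spans


def call_absences(
    evidence: Evidence,
    annotation: Sequence[TEAnnotation],
    stats: LibraryStats,
    layout: GenomeLayout,
    params: DiscoverParams | None = None,
) -> list[TEAbsenceCall]:
    """Call reference TEs absent from the sample.

    A TE is absent when split/discordant reads span >= 80% of its length,
    its internal depth is below 10% of the 2 kb flanking depth (TE bases
    excluded from flanks), and the spanning-read count reaches the
    coverage threshold — doubled when the depth ratio is merely < 1.
    """
    params = params or DiscoverParams()
    index = TEIndex(annotation)
    threshold = params.threshold(stats.mean_coverage)

    te_mask: dict[str, np.ndarray] = {}
    for chrom in layout.chroms:
        te_mask[chrom] = np.zeros(layout.chrom_lengths[chrom], dtype=bool)
    for te in annotation:
        if te.chrom in te_mask:
            te_mask[te.chrom][te.start : te.end] = True

    support: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, gs, ge, name in _spanning_intervals(evidence, params):
        for te in index.overlapping(chrom, gs, ge):
            ovl = min(ge, te.end) - max(gs, te.start)
            if ovl >= params.span_frac * te.length:
                support.setdefault(te.te_id, []).append((gs, ge, name))

    calls: list[TEAbsenceCall] = []
    for te_id, items in support.items():
        te = index.by_id[te_id]
        if te.chrom not in evidence.depth:
            continue
        depth = evidence.depth[te.chrom]
        L = len(depth)
        internal = float(depth[te.start : te.end].mean())
        fl = np.r_[
            np.arange(max(0, te.start - params.flank_bp), te.start),
            np.arange(te.end, min(L, te.end + params.flank_bp)),
        ]
        fl = fl[~te_mask[te.chrom][fl]]
        if fl.size == 0:
            continue
        flank = float(depth[fl].mean())
        if flank <= 0:
            continue
        ratio = internal / flank
        n_spanning = len(items)
        if ratio < params.depth_ratio:
            required = threshold
        elif ratio < 1.0:
            required = 2 * threshold
        else:
            continue
        if n_spanning < required:
            continue
        start = min(gs for gs, _, _ in items)
        end = max(ge for _, ge, _ in items)
        calls.append(
            TEAbsenceCall(
                chrom=te.chrom,
                start=start,
                end=end,
                te_ids=(te_id,),
                n_spanning=n_spanning,
                internal_coverage=internal,
                flanking_coverage=flank,
                read_names=tuple(name for _, _, name in items),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start))
    for call in calls:  # invariant: depth-ratio rule honoured on every call
        assert call.internal_coverage < call.flanking_coverage
    return calls


# ---------------------------------------------------------------------------
# Uniform variant records
# ---------------------------------------------------------------------------


def recategorize_by_reference(
    insertions: Sequence[TEInsertionCall],
    absences: Sequence[TEAbsenceCall],
    accession: str = ".",
    sample_is_reference_accession: bool = False,
) -> list[VariantRecord]:
    """Express calls uniformly relative to the reference annotation.

    Presence calls keep their breakpoint interval; absence calls keep the
    reference TE locus (an absence in a non-reference accession is a TE
    present in the reference genome and missing from the sample; the
    population-frequency reinterpretation happens downstream).
    """
    out: list[VariantRecord] = []
    for call in insertions:
        out.append(
            VariantRecord(
                variant_id=f"ins_{call.chrom}_{call.start}_{call.te_ids[0]}",
                chrom=call.chrom,
                start=call.start,
                end=call.end,
                variant_type="presence",
                te_ids=call.te_ids,
                accession=accession,
                n_split=call.n_split,
                n_discordant=call.n_discordant,
                evidence_read_names=call.read_names,
            )
        )
    for call in absences:
        out.append(
            VariantRecord(
                variant_id=f"abs_{call.te_ids[0]}",
                chrom=call.chrom,
                start=call.start,
                end=call.end,
                variant_type="absence",
                te_ids=call.te_ids,
                accession=accession,
                n_split=0,
                n_discordant=call.n_spanning,
                evidence_read_names=call.read_names,
            )
        )
    return out


@dataclass
class DiscoverResult:
    stats: LibraryStats
    insertions: list[TEInsertionCall]
    absences: list[TEAbsenceCall]
    records: list[VariantRecord]


def discover_sample(
    path: str | Path,
    annotation: Sequence[TEAnnotation],
    layout: GenomeLayout,
    params: DiscoverParams | None = None,
    accession: str = ".",
) -> DiscoverResult:
    """Run the full discovery pipeline on one sample's alignments."""
    params = params or DiscoverParams()
    stats = estimate_library_stats(path, layout, params)
    evidence = extract_evidence(path, stats, layout, params)
    ins = call_insertions(evidence, annotation, stats, params)
    abse = call_absences(evidence, annotation, stats, layout, params)
    records = recategorize_by_reference(ins, abse, accession)
    return DiscoverResult(stats, ins, abse, records)
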