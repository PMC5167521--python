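"""Population summaries of the TE genotype matrix.

Presence/absence calls are arbitrary comparisons to the reference
accession; under the expectation that the minor allele is the derived
allele, each variant is re-expressed as a true TE *insertion* or
*deletion* in the population: a TE absent from >= 80% of accessions is
an insertion private to the reference lineage, a TE present in >= 80% is
a deletion in the reference, and variants with minor allele frequency
above 20% cannot be polarised (class NA).  Rare variants are those below
3% MAF carried by fewer than 7 accessions.  Positional enrichment of
variants in candidate regions is tested by resampling random windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeLayout


def compute_maf(row: pd.Series | np.ndarray) -> tuple[float, float]:
    """(presence frequency, minor allele frequency) over non-NA calls."""
    arr = np.asarray(row, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("all-NA genotype row: MAF undefined")
    f = float(arr.mean())
    return f, min(f, 1.0 - f)


def classify_variant(variant_type: str, presence_freq: float, maf: float) -> str:
    """'insertion' | 'deletion' | 'NA' from the polarisation rules."""
    if maf > 0.20:
        return "NA"
    if variant_type == "absence":
        absence_freq = presence_freq  # the variant allele IS the absence
        return "insertion" if absence_freq >= 0.80 else "deletion"
    if variant_type == "presence":
        return "deletion" if presence_freq >= 0.80 else "insertion"
    raise ValueError(f"unknown variant_type {variant_type!r}")


def classify_matrix(
    matrix: pd.DataFrame, variant_types: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-variant frequency, MAF and insertion/deletion/NA class.

    ``variant_types`` maps variant_id -> 'presence' | 'absence' (the
    original call relative to the reference accession).
    """
    rows = []
    for vid, row in matrix.iterrows():
        f, maf = compute_maf(row)
        vtype = variant_types[vid]
        arr = row.to_numpy(dtype=float)
        arr = arr[~np.isnan(arr)]
        carriers = int(arr.sum())
        minor_carriers = carriers if f <= 0.5 else int(arr.size - carriers)
        rows.append(
            (vid, vtype, f, maf, carriers, minor_carriers,
             classify_variant(vtype, f, maf))
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "variant_type", "presence_freq", "maf",
                 "carriers", "minor_carriers", "class"],
    ).set_index("variant_id")


def classification_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts by (original call, class) — the shape of the published
    classification table."""
    return (
        classified.groupby(["variant_type", "class"])
        .size()
        .rename("count")
        .reset_index()
    )


def partition_rare_common(
    classified: pd.DataFrame,
    maf_threshold: float = 0.03,
    carrier_threshold: int = 7,
) -> pd.Series:
    """'rare' where MAF < 3% AND minor-allele carriers < 7, else 'common'."""
    rare = (classified["maf"] < maf_threshold) & (
        classified["minor_carriers"] < carrier_threshold
    )
    return pd.Series(np.where(rare, "rare", "common"), index=classified.index,
                     name="rarity")


def sharing_spectrum(matrix: pd.DataFrame) -> pd.Series:
    """Histogram of carrier counts per variant (over non-NA calls)."""
    if matrix.empty:
        return pd.Series(dtype=int)
    carriers = matrix.sum(axis=1, skipna=True).astype(int)
    return carriers.value_counts().sort_index()


@dataclass(frozen=True)
class EnrichmentResult:
    region_id: str
    observed: int
    null_mean: float
    ci_low: float
    ci_high: float
    p_value: float


def window_enrichment(
    variant_positions: pd.DataFrame,
    regions: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 300_000,
    n_resamples: int = 10_000,
    seed: int = 1,
) -> list[EnrichmentResult]:
    """Resampling test for variant enrichment in candidate regions.

    Counts variants (by midpoint) in each region, then in ``n_resamples``
    windows of ``window_bp`` placed uniformly on the unmasked genome;
    the empirical p is (1 + #{null >= observed}) / (n_resamples + 1).
    ``variant_positions`` needs chrom/start/end columns; ``regions``
    needs region_id/chrom/start/end.
    """
    chroms = [c for c in layout.chroms if layout.chrom_lengths[c] >= window_bp]
    if not chroms:
        raise ValueError("window_bp exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    mids: dict[str, np.ndarray] = {}
    for chrom, sub in variant_positions.groupby("chrom"):
        mids[chrom] = np.sort(
            ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        )

    def _count(chrom: str, start: int, end: int) -> int:
        pos = mids.get(chrom)
        if pos is None:
            return 0
        return int(
            np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left")
        )

    weights = np.array(
        [layout.chrom_lengths[c] - window_bp + 1 for c in chroms], dtype=float
    )
    weights /= weights.sum()
    chrom_draw = rng.choice(len(chroms), size=n_resamples, p=weights)
    null = np.empty(n_resamples, dtype=int)
    for i, ci in enumerate(chrom_draw):
        chrom = chroms[ci]
        start = int(rng.integers(0, layout.chrom_lengths[chrom] - window_bp + 1))
        null[i] = _count(chrom, start, start + window_bp)

    out = []
    for row in regions.itertuples(index=False):
        obs = _count(row.chrom, int(row.start), int(row.end))
        p = (1 + int((null >= obs).sum())) / (n_resamples + 1)
        out.append(
            EnrichmentResult(
                region_id=str(row.region_id),
                observed=obs,
                null_mean=float(null.mean()),
                ci_low=float(np.percentile(null, 2.5)),
                ci_high=float(np.percentile(null, 97.5)),
                p_value=p,
            )
        )
    return out


def feature_overlap(
    variant_positions: pd.DataFrame,
    feature_sets: Mapping[str, pd.DataFrame],
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Fraction of features in each set intersected (>= 1 bp, half-open)
    by at least one variant, optionally split by a variant grouping
    (class or rarity).  Feature frames need chrom/start/end columns.
    """
    group_values = ["all"]
    if groups is not None:
        group_values += sorted(set(groups.dropna()))

    def _hit_fraction(features: pd.DataFrame, variants: pd.DataFrame) -> float:
        if len(features) == 0:
            return np.nan
        hits = 0
        by_chrom = {}
        for chrom, sub in variants.groupby("chrom"):
            order = np.argsort(sub["start"].to_numpy())
            starts = sub["start"].to_numpy()[order]
            ends = sub["end"].to_numpy()[order]
            by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
        for row in features.itertuples(index=False):
            entry = by_chrom.get(row.chrom)
            if entry is None:
                continue
            starts, cummax_end = entry
            idx = np.searchsorted(starts, row.end, "left")
            if idx > 0 and cummax_end[idx - 1] > row.start:
                hits += 1
        return hits / len(features)

    rows = []
    for gname in group_values:
        if gname == "all":
            variants = variant_positions
        else:
            variants = variant_positions.loc[groups[groups == gname].index]
        for fname, feats in feature_sets.items():
            rows.append((fname, gname, _hit_fraction(feats, variants)))
    return pd.DataFrame(rows, columns=["feature_set", "group", "fraction_with_variant"])
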