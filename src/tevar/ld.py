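"""Rank-based linkage of TE variants to flanking SNPs.

For each common TE variant, the 300 nearest SNPs on each side (MAF > 3%)
form a local panel.  Pairwise genotype r^2 (squared Pearson correlation
over complete cases) is computed for the TE against every flanking SNP
and for every SNP against every other.  Each marker's r^2 vector is
sorted in decreasing order; at each rank the median over the SNPs' own
sorted vectors gives the local background, and the number of rank
positions where the TE exceeds that median (0-600) classifies the
variant: fewer than 200 wins is low LD (the TE is untagged by SNPs),
200-400 mid, more than 400 high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise complete-case squared Pearson correlation of the rows of
    ``X`` (markers x samples, NaN = missing).  Pairs with fewer than two
    complete cases or zero variance are NaN."""
    X = np.asarray(X, dtype=float)
    M = (~np.isnan(X)).astype(float)
    Z = np.nan_to_num(X)
    Z2 = Z * Z
    n = M @ M.T
    s_xy = Z @ M.T          # sum of x over the pair's complete cases
    s2_xy = Z2 @ M.T
    cross = Z @ Z.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = cross - s_xy * s_xy.T / n
        var_x = s2_xy - s_xy**2 / n
        var_y = var_x.T
        r2 = cov**2 / (var_x * var_y)
        r2[(var_x <= 0) | (var_y <= 0) | (n < 2)] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


def genotype_r2(a, b) -> float:
    """r^2 between two genotype vectors over complete cases; NaN when
    fewer than two complete cases or either vector is constant."""
    out = pairwise_r2(np.vstack([np.asarray(a, float), np.asarray(b, float)]))
    return float(out[0, 1])


@dataclass(frozen=True)
class LDProfile:
    variant_id: str
    n_snps: int
    n_ranks: int               # rank positions actually compared
    te_rank_wins: int
    category: str              # low | mid | high
    te_sorted_r2: np.ndarray
    median_sorted_r2: np.ndarray


def classify_ld(te_rank_wins: int, n_ranks: int = 600) -> str:
    """<200 wins -> low, 200-400 -> mid, >400 -> high (thresholds prorated
    when fewer than 600 rank positions are available)."""
    if not 0 <= te_rank_wins <= n_ranks:
        raise ValueError("wins outside the available rank range")
    scale = n_ranks / 600
    if te_rank_wins < 200 * scale:
        return "low"
    if te_rank_wins > 400 * scale:
        return "high"
    return "mid"


def rank_profile(
    te: pd.Series | np.ndarray,
    snps: pd.DataFrame | np.ndarray,
    variant_id: str = "te",
) -> LDProfile:
    """Rank-comparison LD profile of one TE variant against a SNP block.

    ``snps`` is markers x accessions, aligned to ``te``'s accessions.
    The TE's sorted r^2 vector is compared rank-by-rank with the median
    of the SNPs' own sorted SNP-SNP vectors.
    """
    snp_arr = np.asarray(snps, dtype=float)
    te_arr = np.asarray(te, dtype=float)
    m = len(snp_arr)
    if m < 2:
        raise ValueError("need at least two flanking SNPs")
    X = np.vstack([snp_arr, te_arr])
    R = pairwise_r2(X)

    def _sorted_vec(i: int, js: np.ndarray) -> np.ndarray:
        vals = R[i, js]
        vals = vals[~np.isnan(vals)]
        return np.sort(vals)[::-1]

    snp_sorted = [
        _sorted_vec(i, np.array([j for j in range(m) if j != i])) for i in range(m)
    ]
    te_sorted = _sorted_vec(m, np.arange(m))

    max_rank = len(te_sorted)
    medians = np.full(max_rank, np.nan)
    for k in range(max_rank):
        at_k = [v[k] for v in snp_sorted if len(v) > k]
        if at_k:
            medians[k] = np.median(at_k)
    valid = ~np.isnan(medians)
    wins = int((te_sorted[valid] > medians[valid]).sum())
    n_ranks = int(valid.sum())
    return LDProfile(
        variant_id=variant_id,
        n_snps=m,
        n_ranks=n_ranks,
        te_rank_wins=wins,
        category=classify_ld(wins, n_ranks),
        te_sorted_r2=te_sorted,
        median_sorted_r2=medians,
    )


def _maf(arr: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        f = np.nanmean(arr, axis=1)
    return np.minimum(f, 1 - f)


def ld_classify_population(
    te_matrix: pd.DataFrame,
    te_positions: pd.DataFrame,
    snp_matrix: pd.DataFrame,
    snp_positions: pd.DataFrame,
    n_flank: int = 300,
    maf_min: float = 0.03,
) -> pd.DataFrame:
    """LD category for every common TE variant.

    Both matrices are markers x accessions over the same accession list
    (pre-pruned of clonal accessions).  SNPs and TEs below ``maf_min``
    MAF are dropped; the nearest ``n_flank`` SNPs on each side of the TE
    midpoint (same chromosome) form the panel.  Position frames need
    chrom plus start/end (TEs) or pos (SNPs).
    """
    snp_ok = _maf(snp_matrix.to_numpy(dtype=float)) > maf_min
    snps = snp_matrix.loc[snp_ok]
    spos = snp_positions.loc[snps.index]
    te_ok = _maf(te_matrix.to_numpy(dtype=float)) > maf_min
    tes = te_matrix.loc[te_ok]

    rows = []
    for chrom, chrom_spos in spos.groupby("chrom"):
        order = np.argsort(chrom_spos["pos"].to_numpy())
        ids = chrom_spos.index.to_numpy()[order]
        pos = chrom_spos["pos"].to_numpy()[order]
        chrom_tes = te_positions.loc[
            te_positions.index.isin(tes.index) & (te_positions["chrom"] == chrom)
        ]
        for vid, trow in chrom_tes.iterrows():
            mid = (int(trow.start) + int(trow.end)) // 2
            i = int(np.searchsorted(pos, mid))
            sel = ids[max(0, i - n_flank) : i + n_flank]
            if len(sel) < 2:
                continue
            profile = rank_profile(tes.loc[vid], snps.loc[sel], variant_id=vid)
            rows.append(
                (vid, profile.n_snps, profile.n_ranks, profile.te_rank_wins,
                 profile.category)
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "n_snps", "n_ranks", "te_rank_wins", "category"]
    ).set_index("variant_id")
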