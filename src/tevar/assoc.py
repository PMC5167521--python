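"""Association of TE genotypes with expression and DNA methylation.

Differential expression uses a two-sided Mann-Whitney U test between
carrier and non-carrier accessions for each gene-variant pair (exact
null enumeration for small groups, tie-corrected normal approximation
otherwise), with Storey q-value control and a two-fold change gate.
Rare variants, untestable individually, are aggregated in a burden test:
carriers' normalised phenotype ranks are pooled and a quadratic is
fitted to their histogram — enrichment in the population extremes shows
up as positive curvature.  Methylation analyses correlate DMR levels
with the nearest variant's genotype, compare correlation distributions
with the two-sample KS statistic, profile weighted methylation in 200 bp
bins flanking variants, and run a genome-wide permutation scan in which
a variant-DMR pair is significant only when its |r| exceeds all label
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .io import GenomeLayout


# ---------------------------------------------------------------------------
# Masked (complete-case) Pearson correlation
# ---------------------------------------------------------------------------


def masked_pearson(A: np.ndarray, B: np.ndarray, min_n: int = 3) -> np.ndarray:
    """Pearson r between every row of A and every row of B over their
    pairwise complete cases.  NaN where fewer than ``min_n`` complete
    cases or a constant vector."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ma = (~np.isnan(A)).astype(float)
    Mb = (~np.isnan(B)).astype(float)
    Za, Zb = np.nan_to_num(A), np.nan_to_num(B)
    n = Ma @ Mb.T
    sx = Za @ Mb.T
    sy = Ma @ Zb.T
    sxx = (Za * Za) @ Mb.T
    syy = Ma @ (Zb * Zb).T
    sxy = Za @ Zb.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    r[(n < min_n) | (vx <= 0) | (vy <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def pearson_complete(x, y, min_n: int = 3) -> tuple[float, int]:
    """(r, n complete cases) for two vectors; NaN under ``min_n`` cases
    or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < min_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan"), n
    return float(np.corrcoef(x[ok], y[ok])[0, 1]), n


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def mannwhitney_de(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    pairs: pd.DataFrame,
    min_carriers: int = 7,
    epsilon: float = 0.01,
    exclude_genes: Sequence[str] = (),
    fold_gate: float = 2.0,
    q_gate: float = 0.01,
) -> pd.DataFrame:
    """Mann-Whitney differential expression for gene-variant pairs.

    ``pairs`` columns: gene_id, variant_id and (optionally) context.
    Groups with fewer than ``min_carriers`` accessions on either side
    are skipped; TE gene models are excluded via ``exclude_genes``.
    Exact enumeration is used when both groups have at most 8 members
    and no ties, the tie-corrected normal approximation otherwise.
    Fold change is (mean+eps)/(mean+eps) carrier over non-carrier; a
    pair is differentially expressed at |log2 FC| > 1 and q < 0.01.
    """
    excluded = set(exclude_genes)
    shared = expression.columns.intersection(genotypes.columns)
    rows = []
    has_context = "context" in pairs.columns
    for pair in pairs.itertuples(index=False):
        gene, variant = pair.gene_id, pair.variant_id
        if gene in excluded or gene not in expression.index:
            continue
        if variant not in genotypes.index:
            continue
        e = expression.loc[gene, shared].to_numpy(dtype=float)
        g = genotypes.loc[variant, shared].to_numpy(dtype=float)
        ok = ~np.isnan(e) & ~np.isnan(g)
        x = e[ok & (g == 1)]
        y = e[ok & (g == 0)]
        if len(x) < min_carriers or len(y) < min_carriers:
            continue
        pooled = np.concatenate([x, y])
        exact = (
            len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
        )
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        fold = (x.mean() + epsilon) / (y.mean() + epsilon)
        log2_fold = float(np.log2(fold)) if fold > 0 else np.nan
        rows.append(
            (
                gene, variant,
                getattr(pair, "context", ".") if has_context else ".",
                len(x), len(y), float(res.statistic), float(res.pvalue),
                fold, log2_fold,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "variant_id", "context", "n_carrier", "n_noncarrier",
                 "U", "p", "fold_change", "log2_fold_change"],
    )
    if len(out):
        out["q"] = qvalue_estimate(out["p"].to_numpy())
        out["is_DE"] = (out["log2_fold_change"].abs() > np.log2(fold_gate)) & (
            out["q"] < q_gate
        )
    else:
        out["q"] = pd.Series(dtype=float)
        out["is_DE"] = pd.Series(dtype=bool)
    return out


def qvalue_estimate(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    smooth_df: int = 4,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with pi0 smoothed over lambda in {0, 0.05, ..., 0.6}.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fitted with a
    ``smooth_df``-coefficient least-squares polynomial and evaluated at
    the largest lambda, clipped to (0, 1].  q_(i) = pi0 * min_{j>=i}
    p_(j) m / j, monotone nondecreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.0, 0.6001, 0.05)
        pi0_hat = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        if len(lambdas) >= smooth_df:
            coef = np.polyfit(lambdas, pi0_hat, deg=smooth_df - 1)
            pi0 = float(np.polyval(coef, lambdas.max()))
        else:
            pi0 = float(pi0_hat[-1])
        pi0 = min(pi0, 1.0)
        if pi0 <= 0:
            pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * p_sorted * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Rare-variant burden
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurdenResult:
    bin_edges: np.ndarray
    counts: np.ndarray
    coefficients: tuple[float, float, float]   # intercept, linear, quadratic
    r_squared: float
    p_value: float
    n_observations: int

    @property
    def curvature(self) -> float:
        return self.coefficients[2]


def burden_test(
    phenotypes: pd.DataFrame,
    rare_genotypes: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
    n_bins: int = 20,
) -> BurdenResult:
    """Rare-variant burden in the phenotype extremes.

    For every phenotype with mapped rare variants, accessions are ranked
    by value (average ranks for ties, normalised to [0, 1]) and the
    carriers' normalised ranks pooled across phenotypes.  The pooled
    ranks are binned and a quadratic fitted to the counts; U-shaped
    enrichment gives positive curvature and a high R^2.
    """
    pooled: list[float] = []
    for pheno_id, variant_ids in mapping.items():
        if pheno_id not in phenotypes.index:
            continue
        values = phenotypes.loc[pheno_id].dropna()
        if len(values) < 2:
            continue
        ranks = sps.rankdata(values.to_numpy())
        norm = (ranks - 1) / (len(values) - 1)
        norm = pd.Series(norm, index=values.index)
        for vid in variant_ids:
            if vid not in rare_genotypes.index:
                continue
            g = rare_genotypes.loc[vid, values.index]
            pooled.extend(norm[g == 1.0].tolist())
    if not pooled:
        raise ValueError("no rare-variant carrier observations to pool")
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    X = sm.add_constant(np.column_stack([centers, centers**2]))
    fit = sm.OLS(counts, X).fit()
    return BurdenResult(
        bin_edges=edges,
        counts=counts,
        coefficients=tuple(float(c) for c in fit.params),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        n_observations=len(pooled),
    )


# ---------------------------------------------------------------------------
# DMR / TE correlation
# ---------------------------------------------------------------------------


def dmr_te_correlation(
    dmr_matrix: pd.DataFrame,
    genotypes: pd.DataFrame,
    dmr_positions: pd.DataFrame,
    variant_positions: pd.DataFrame,
    te_dmr_max_dist: int = 1000,
) -> pd.DataFrame:
    """Pearson r between each DMR's methylation level and the genotype of
    its nearest TE variant; DMRs within 1 kb of the variant are grouped
    as TE-DMRs, the rest as non-TE-DMRs.  Position frames need
    chrom/start/end indexed by id."""
    shared = dmr_matrix.columns.intersection(genotypes.columns)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in variant_positions.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy())
        by_chrom[chrom] = (
            sub.index.to_numpy()[order],
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
        )
    rows = []
    for dmr_id, drow in dmr_positions.iterrows():
        if dmr_id not in dmr_matrix.index:
            continue
        entry = by_chrom.get(drow["chrom"])
        if entry is None:
            continue
        ids, starts, ends = entry
        dist = np.maximum(
            np.maximum(starts - int(drow["end"]), int(drow["start"]) - ends), 0
        )
        j = int(np.argmin(dist))
        vid = ids[j]
        r, n = pearson_complete(
            dmr_matrix.loc[dmr_id, shared], genotypes.loc[vid, shared]
        )
        rows.append(
            (
                dmr_id, vid, int(dist[j]), r, n,
                "TE-DMR" if dist[j] <= te_dmr_max_dist else "non-TE-DMR",
            )
        )
    return pd.DataFrame(
        rows, columns=["dmr_id", "variant_id", "distance", "r", "n", "group"]
    ).set_index("dmr_id")


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Flanking methylation profiles
# ---------------------------------------------------------------------------


def flanking_methylation_profile(
    variant_positions: pd.DataFrame,
    genotypes: pd.DataFrame,
    methylomes: Mapping[str, Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]],
    layout: GenomeLayout,
    bin_bp: int = 200,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Weighted methylation level in bins flanking variant breakpoints.

    ``methylomes[accession][context][chrom]`` is a (methylated_calls,
    total_calls) pair of per-base arrays.  Levels are averaged (weighted:
    sum of methylated over sum of total calls) per 200 bp bin within
    +/-2 kb of each variant's breakpoint, separately for carrier and
    non-carrier accessions and for pericentromeric (<3 Mb from the
    centromere) versus arm variants.  Bases inside the variant's own TE
    interval are excluded; bins with no covered cytosines are NaN.
    """
    n_bins = 2 * flank_bp // bin_bp
    acc_m: dict[tuple, np.ndarray] = {}
    acc_t: dict[tuple, np.ndarray] = {}
    contexts = sorted({ctx for acc in methylomes.values() for ctx in acc})

    for vid, vrow in variant_positions.iterrows():
        if vid not in genotypes.index:
            continue
        chrom = vrow["chrom"]
        bp = int(vrow["start"])
        strata = "pericentromeric" if layout.is_pericentromeric(chrom, bp) else "arm"
        lo = bp - flank_bp
        g = genotypes.loc[vid]
        for acc, contexts_map in methylomes.items():
            gt = g.get(acc, np.nan)
            if np.isnan(gt):
                continue
            group = "carrier" if gt == 1.0 else "noncarrier"
            key = None
            for ctx in contexts:
                if ctx not in contexts_map or chrom not in contexts_map[ctx]:
                    continue
                m_arr, t_arr = contexts_map[ctx][chrom]
                L = len(t_arr)
                key = (ctx, group, strata)
                if key not in acc_m:
                    acc_m[key] = np.zeros(n_bins)
                    acc_t[key] = np.zeros(n_bins)
                for b in range(n_bins):
                    s = lo + b * bin_bp
                    e = s + bin_bp
                    s_c, e_c = max(0, s), min(L, e)
                    if s_c >= e_c:
                        continue
                    idx = np.arange(s_c, e_c)
                    keep = (idx < int(vrow["start"])) | (idx >= int(vrow["end"]))
                    idx = idx[keep]
                    acc_m[key][b] += m_arr[idx].sum()
                    acc_t[key][b] += t_arr[idx].sum()

    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    data = {}
    for key in sorted(acc_m):
        with np.errstate(divide="ignore", invalid="ignore"):
            level = np.where(acc_t[key] > 0, acc_m[key] / acc_t[key], np.nan)
        data["|".join(key)] = level
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset_bp"))


# ---------------------------------------------------------------------------
# Genome-wide permutation scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    observed_r: pd.DataFrame      # variants x DMRs (signed)
    exceedance: pd.DataFrame      # #{perm: |r_perm| >= |r_obs|}
    significant: pd.DataFrame     # exceedance == 0
    n_perm: int

    @property
    def p_floor(self) -> float:
        """Minimum achievable permutation p: 1 / (n_perm + 1)."""
        return 1.0 / (self.n_perm + 1)

    def per_variant_counts(self) -> pd.Series:
        """Genome-wide significant-pair count per variant."""
        return self.significant.sum(axis=1)

    def to_pairs(
        self,
        variant_positions: pd.DataFrame | None = None,
        dmr_positions: pd.DataFrame | None = None,
        cis_bp: int = 1000,
    ) -> pd.DataFrame:
        rows = []
        for vid in self.observed_r.index:
            for did in self.observed_r.columns:
                r = self.observed_r.at[vid, did]
                if np.isnan(r):
                    continue
                exceed = int(self.exceedance.at[vid, did])
                rec = {
                    "variant_id": vid,
                    "dmr_id": did,
                    "r": r,
                    "exceedance": exceed,
                    "p": (exceed + 1) / (self.n_perm + 1),
                    "significant": exceed == 0,
                }
                if variant_positions is not None and dmr_positions is not None:
                    v = variant_positions.loc[vid]
                    d = dmr_positions.loc[did]
                    if v["chrom"] != d["chrom"]:
                        dist = np.inf
                    else:
                        dist = max(
                            v["start"] - d["end"], d["start"] - v["end"], 0
                        )
                    rec["distance"] = dist
                    rec["cis"] = dist <= cis_bp
                rows.append(rec)
        return pd.DataFrame(rows)


def permutation_scan(
    genotypes: pd.DataFrame,
    dmr_matrix: pd.DataFrame,
    n_perm: int = 500,
    seed: int = 1,
    coverage_filter: float = 0.15,
    maf_min: float = 0.03,
) -> ScanResult:
    """Genome-wide TE-variant / DMR association by label permutation.

    DMRs missing in more than ``coverage_filter`` of accessions are
    dropped; only common variants (MAF > ``maf_min``) are tested.  The
    observed |r| of every pair is compared against ``n_perm`` whole-
    accession-label permutations of the DMR matrix; a pair is significant
    only when its observed |r| exceeds every permuted value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    shared = genotypes.columns.intersection(dmr_matrix.columns)
    G = genotypes[shared]
    D = dmr_matrix[shared]
    D = D.loc[D.isna().mean(axis=1) <= coverage_filter]
    g_arr = G.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g_arr, axis=1)
    maf = np.minimum(freq, 1 - freq)
    G = G.loc[maf > maf_min]
    if G.empty or D.empty:
        raise ValueError("nothing to test after the coverage and MAF filters")

    g_arr = G.to_numpy(dtype=float)
    d_arr = D.to_numpy(dtype=float)
    obs = np.abs(masked_pearson(g_arr, d_arr))
    exceed = np.zeros_like(obs, dtype=int)
    rng = np.random.default_rng(seed)
    n_acc = d_arr.shape[1]
    for _ in range(n_perm):
        idx = rng.permutation(n_acc)
        perm = np.abs(masked_pearson(g_arr, d_arr[:, idx]))
        exceed += np.where(np.isnan(perm), 0, (perm >= obs).astype(int))
    exceed[np.isnan(obs)] = n_perm  # untestable pairs can never be significant
    signed = masked_pearson(g_arr, d_arr)
    return ScanResult(
        observed_r=pd.DataFrame(signed, index=G.index, columns=D.index),
        exceedance=pd.DataFrame(exceed, index=G.index, columns=D.index),
        significant=pd.DataFrame(exceed == 0, index=G.index, columns=D.index),
        n_perm=n_perm,
    )
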