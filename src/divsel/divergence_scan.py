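"""Per-SNP divergence scans and allele-frequency-change analyses.

The workhorse is the allelic chi-square test: a 1-df Pearson test on the
2x2 table of allele counts in two groups (two lines, or one line at two
generations).  When both groups are fixed for alternative alleles the
statistic equals the table's total allele count — 80 for 20 vs 20 birds and
118 for 49 vs 10 — which sets the natural ceiling of a scan.  No continuity
correction is applied.

Also here: Fisher's exact alternative, sliding-window smoothing for plots,
the 5-SNP-block / 95th-percentile / Poisson-window test for regions with
elevated allele-frequency change between generations, and observed
heterozygosity accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_model import (
    GenotypePanel,
    GroupAlleleCounts,
    MarkerMap,
    allele_frequencies,
    group_allele_counts,
)


def allelic_chi2(counts: GroupAlleleCounts) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 allele table.

    Returns ``(nan, nan)`` when a column margin is zero (SNP monomorphic in
    both groups pooled), where the statistic is undefined.
    """
    a, b = counts.n_allele1_g1, counts.n_allele2_g1
    c, d = counts.n_allele1_g2, counts.n_allele2_g2
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = counts.total
    if r1 == 0 or r2 == 0:
        raise ValueError("both group totals must be positive")
    if c1 == 0 or c2 == 0:
        return float("nan"), float("nan")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_exact(counts: GroupAlleleCounts) -> float:
    """Two-sided Fisher exact p-value on the 2x2 allele table."""
    c1 = counts.n_allele1_g1 + counts.n_allele1_g2
    c2 = counts.n_allele2_g1 + counts.n_allele2_g2
    if counts.n_allele1_g1 + counts.n_allele2_g1 == 0 or counts.n_allele1_g2 + counts.n_allele2_g2 == 0:
        raise ValueError("both group totals must be positive")
    if c1 == 0 or c2 == 0:
        return float("nan")
    return float(stats.fisher_exact(counts.as_table(), alternative="two-sided")[1])


@dataclass
class ScanResult:
    """Per-SNP chi-square scan with Bonferroni-corrected significance flags."""

    table: pd.DataFrame  # snp_id, chi2, p, [fisher_p], sig flags
    n_tested: int        # Bonferroni m: SNPs with a defined statistic
    alphas: tuple[float, ...]


def scan(
    panel: GenotypePanel,
    group1: tuple[str | None, int | None],
    group2: tuple[str | None, int | None],
    alphas: tuple[float, ...] = (0.05, 0.001),
    include_fisher: bool = False,
) -> ScanResult:
    """Allelic chi-square scan between two disjoint sample groups.

    Bonferroni correction uses m = the number of SNPs with a defined
    statistic in *this* comparison; a flag column ``sig_<alpha>`` marks SNPs
    with p < alpha/m.
    """
    counts = group_allele_counts(panel, group1, group2)
    chi2 = np.full(panel.n_snps, np.nan)
    pval = np.full(panel.n_snps, np.nan)
    for j, c in enumerate(counts):
        chi2[j], pval[j] = allelic_chi2(c)
    table = pd.DataFrame({"snp_id": panel.snp_ids, "chi2": chi2, "p": pval})
    if include_fisher:
        table["fisher_p"] = [fisher_exact(c) for c in counts]
    m = int(np.sum(~np.isnan(pval)))
    for alpha in alphas:
        table[f"sig_{alpha:g}"] = pval < (alpha / m if m else np.nan)
    return ScanResult(table=table, n_tested=m, alphas=tuple(alphas))


def max_chi2(n_samples_g1: int, n_samples_g2: int) -> float:
    """Ceiling of the allelic chi-square: total allele count at full divergence."""
    return float(2 * (n_samples_g1 + n_samples_g2))


def sliding_window_mean(
    values: np.ndarray,
    chromosomes: np.ndarray,
    window: int = 20,
    normalize_by: float | None = None,
) -> np.ndarray:
    """Centered moving average within each chromosome (for scan plots).

    Flanking windows shrink to the available markers.  ``normalize_by``
    rescales the output (e.g. by the group-size-dependent maximum chi-square,
    80 or 118) so scans at different sample sizes share one axis.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    grouped = s.groupby(pd.Series(np.asarray(chromosomes, dtype=object)), sort=False)
    out = grouped.transform(
        lambda x: x.rolling(window, center=True, min_periods=1).mean()
    ).to_numpy()
    if normalize_by is not None:
        out = out / normalize_by
    return out


def poisson_window_threshold(p_threshold: float = 1e-5, mean: float = 1.0) -> int:
    """Smallest k with P(Poisson(mean) >= k) <= p_threshold.

    Under the null that 5% of blocks are outliers independently, the outlier
    count in a 20-block window is Poisson with mean 1; k*(1e-5) = 9.
    """
    k = 0
    while stats.poisson.sf(k - 1, mean) > p_threshold:
        k += 1
    return k


@dataclass
class BlockScan:
    """Blockwise allele-frequency-change scan between two generations.

    ``blocks`` holds per 5-SNP block the mean |Δp| and an outlier flag
    (above the genome-wide 95th percentile); ``windows`` holds sliding
    20-block outlier counts with significance at the Poisson threshold
    ``k_star``.
    """

    blocks: pd.DataFrame
    windows: pd.DataFrame
    percentile_value: float
    k_star: int


def block_change_scan(
    panel: GenotypePanel,
    marker_map: MarkerMap,
    line: str,
    gen1: int,
    gen2: int,
    block_size: int = 5,
    percentile: float = 95.0,
    window_blocks: int = 20,
    p_threshold: float = 1e-5,
) -> BlockScan:
    """Scan one line for regions of elevated allele-frequency change.

    |Δp| per SNP between the two generations is averaged over non-overlapping
    blocks of ``block_size`` consecutive SNPs within a chromosome (trailing
    partial blocks dropped).  Blocks above the genome-wide ``percentile`` of
    block means are outliers; a sliding window of ``window_blocks`` blocks is
    significant when its outlier count reaches the Poisson(1) threshold k*.
    """
    f1 = allele_frequencies(panel, line=line, generation=gen1)
    f2 = allele_frequencies(panel, line=line, generation=gen2)
    dp = np.abs(f2 - f1)

    rows = []
    for chrom in dict.fromkeys(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == chrom)
        if idx.size < block_size:
            warnings.warn(
                f"chromosome {chrom} has fewer than {block_size} SNPs; skipped"
            )
            continue
        n_blocks = idx.size // block_size
        for b in range(n_blocks):
            members = idx[b * block_size: (b + 1) * block_size]
            rows.append(
                {
                    "chromosome": chrom,
                    "block": b,
                    "start_bp": int(marker_map.position_bp[members[0]]),
                    "end_bp": int(marker_map.position_bp[members[-1]]),
                    "mean_abs_dp": float(np.nanmean(dp[members])),
                }
            )
    blocks = pd.DataFrame(rows)
    threshold = float(np.percentile(blocks["mean_abs_dp"].dropna(), percentile))
    blocks["outlier"] = blocks["mean_abs_dp"] > threshold  # ties are non-outliers

    k_star = poisson_window_threshold(p_threshold)
    win_rows = []
    for chrom, grp in blocks.groupby("chromosome", sort=False):
        flags = grp["outlier"].to_numpy()
        if flags.size < window_blocks:
            counts = np.array([int(flags.sum())])
            starts = [0]
        else:
            counts = np.convolve(flags.astype(int), np.ones(window_blocks, dtype=int), "valid")
            starts = range(len(counts))
        for st, cnt in zip(starts, counts):
            sub = grp.iloc[st: st + window_blocks]
            win_rows.append(
                {
                    "chromosome": chrom,
                    "window_start_block": int(st),
                    "start_bp": int(sub["start_bp"].iloc[0]),
                    "end_bp": int(sub["end_bp"].iloc[-1]),
                    "n_outliers": int(cnt),
                    "significant": bool(cnt >= k_star),
                }
            )
    windows = pd.DataFrame(win_rows)
    return BlockScan(blocks=blocks, windows=windows, percentile_value=threshold, k_star=k_star)


@dataclass
class HetDecline:
    """Observed-heterozygosity change in one line between two generations."""

    line: str
    gen1: int
    gen2: int
    mean_ho: dict[int, float]       # mean H_o per generation
    decrease: np.ndarray            # per-locus H_o(gen1) - H_o(gen2)


def observed_heterozygosity(
    panel: GenotypePanel, line: str | None = None, generation: int | None = None
) -> np.ndarray:
    """Per-SNP fraction of heterozygous calls among non-missing calls."""
    mask = panel.group_mask(line, generation)
    if not mask.any():
        raise ValueError("empty sample group")
    g = panel.genotypes[mask]
    called = (g != -1).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = het / called
    return np.where(called > 0, ho, np.nan)


def heterozygosity_decline(
    panel: GenotypePanel, line: str, gen1: int, gen2: int
) -> HetDecline:
    """Per-locus H_o decrease in one line between two sampled generations."""
    h1 = observed_heterozygosity(panel, line, gen1)
    h2 = observed_heterozygosity(panel, line, gen2)
    return HetDecline(
        line=line,
        gen1=gen1,
        gen2=gen2,
        mean_ho={gen1: float(np.nanmean(h1)), gen2: float(np.nanmean(h2))},
        decrease=h1 - h2,
    )


def compare_heterozygosity_decline(a: HetDecline, b: HetDecline) -> tuple[float, float]:
    """Two-sample two-sided t-test on per-locus H_o decreases of two lines.

    Returns (t, p); p is NaN when either line's decreases are degenerate
    (zero variance).
    """
    x = a.decrease[~np.isnan(a.decrease)]
    y = b.decrease[~np.isnan(b.decrease)]
    if np.var(x) == 0 and np.var(y) == 0:
        return (0.0, float("nan")) if np.mean(x) == np.mean(y) else (float("inf"), float("nan"))
    t, p = stats.ttest_ind(x, y)
    return float(t), float(p)
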