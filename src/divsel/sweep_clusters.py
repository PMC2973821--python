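"""Clusters of alternatively fixed SNPs and haplotype-persistence arithmetic.

A candidate sweep is a maximal run of SNPs fixed for different alleles in
the two lines with at most ``max_gap_bp`` (default 1 Mb) between successive
members; runs shorter than ``min_snps`` (2 for a liberal scan, 5 for a
conservative one) are discarded.  Physical lengths convert to map lengths
through per-chromosome cM/Mb ratios, map length to recombination fraction
through Haldane's function, and the probability that a region of that size
sweeps to fixation unrecombined in g generations is
((1-r) + r(p^2+q^2))^(2Ng) for starting haplotype frequencies p and q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import MarkerMap


@dataclass
class SweepCluster:
    """A contiguous run of alternatively fixed SNPs."""

    chromosome: str
    first_bp: int
    last_bp: int
    n_snps: int
    length_mb: float
    length_cm: float | None = None        # None when the chromosome lacks a cM/Mb ratio
    qtl_overlaps: list[str] | None = None

    @property
    def length_bp(self) -> int:
        return self.last_bp - self.first_bp


def cluster_fixed_snps(
    diff_flags: np.ndarray,
    marker_map: MarkerMap,
    max_gap_bp: int = 1_000_000,
    min_snps: int = 2,
) -> tuple[list[SweepCluster], dict[str, float]]:
    """Group DIFF-fixed SNPs into sweep clusters.

    Parameters
    ----------
    diff_flags
        Boolean per-SNP array aligned to ``marker_map``: True where the SNP
        is fixed for alternative alleles in the two lines.
    max_gap_bp
        Maximum distance between successive member SNPs.
    min_snps
        Minimum cluster size; smaller runs are dropped.

    Returns the clusters plus a summary: number of clusters, percentage of
    DIFF SNPs inside clusters, and percentage of the marker-spanned genome
    covered by clusters.
    """
    diff_flags = np.asarray(diff_flags, dtype=bool)
    if diff_flags.shape[0] != len(marker_map):
        raise ValueError("diff_flags must align with the marker map")

    clusters: list[SweepCluster] = []
    genome_span = 0
    for chrom in dict.fromkeys(marker_map.chromosome):
        on = marker_map.chromosome == chrom
        pos_all = marker_map.position_bp[on]
        genome_span += int(pos_all.max() - pos_all.min()) if pos_all.size > 1 else 0
        pos = pos_all[diff_flags[on]]
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        for run in np.split(pos, breaks + 1):
            if run.size < min_snps:
                continue
            first, last = int(run[0]), int(run[-1])
            length_mb = (last - first) / 1e6
            ratio = marker_map.cm_per_mb.get(str(chrom))
            clusters.append(
                SweepCluster(
                    chromosome=str(chrom),
                    first_bp=first,
                    last_bp=last,
                    n_snps=int(run.size),
                    length_mb=length_mb,
                    length_cm=None if ratio is None else length_mb * ratio,
                )
            )

    n_diff = int(diff_flags.sum())
    in_clusters = sum(c.n_snps for c in clusters)
    covered = sum(c.length_bp for c in clusters)
    summary = {
        "n_clusters": float(len(clusters)),
        "pct_diff_snps_in_clusters": 100.0 * in_clusters / n_diff if n_diff else float("nan"),
        "pct_genome_in_clusters": 100.0 * covered / genome_span if genome_span else float("nan"),
    }
    return clusters, summary


def clusters_to_frame(clusters: list[SweepCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in clusters],
            "first_bp": [c.first_bp for c in clusters],
            "last_bp": [c.last_bp for c in clusters],
            "n_snps": [c.n_snps for c in clusters],
            "length_mb": [c.length_mb for c in clusters],
            "length_cm": [c.length_cm for c in clusters],
            "qtl_overlaps": [
                ",".join(c.qtl_overlaps) if c.qtl_overlaps else "" for c in clusters
            ],
        }
    )


def cm_length(cluster: SweepCluster, marker_map: MarkerMap) -> float | None:
    """Map length of a cluster from its chromosome's cM/Mb ratio.

    Returns None (blank) for chromosomes without a ratio, e.g. Z.
    """
    ratio = marker_map.cm_per_mb.get(cluster.chromosome)
    return None if ratio is None else cluster.length_mb * ratio


def annotate_qtl_overlaps(
    clusters: list[SweepCluster], intervals_bed: str
) -> list[SweepCluster]:
    """Label clusters overlapping intervals from a BED file (any bp shared).

    BED is 0-based half-open; converted to 1-based inclusive internally.
    Interval names come from the BED name column (4th), else coordinates.
    """
    bed = pd.read_csv(
        intervals_bed, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "name"][: 4],
        dtype={"chromosome": str},
    )
    if "name" not in bed or bed["name"].isna().all():
        bed["name"] = bed["chromosome"] + ":" + bed["start"].astype(str) + "-" + bed["end"].astype(str)
    for c in clusters:
        hits = bed[
            (bed["chromosome"] == c.chromosome)
            & (bed["start"] + 1 <= c.last_bp)
            & (bed["end"] >= c.first_bp)
        ]
        c.qtl_overlaps = list(hits["name"].astype(str))
    return clusters


def haldane_r(d_cm: float) -> float:
    """Haldane map function: r = (1 - exp(-2d))/2 with d in centimorgans."""
    if d_cm < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


@dataclass(frozen=True)
class PersistenceQuery:
    """Inputs for the unrecombined-haplotype persistence probability."""

    r: float
    p: float
    N: float
    g: float
    q: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")
        q = 1.0 - self.p if self.q is None else self.q
        if self.p < 0 or q < 0 or abs(self.p + q - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies p, q must be >= 0 with p+q=1")
        if self.N <= 0 or self.g < 0:
            raise ValueError("require N > 0 and g >= 0")


def persistence_probability(query: PersistenceQuery) -> float:
    """Probability a region persists unrecombined through a sweep.

    Each of the 2Ng meioses during g generations in a population of size N
    either has no crossover in the region (prob 1-r) or crosses over between
    two copies of the same haplotype (prob r(p^2+q^2)):

        P = ((1-r) + r(p^2 + q^2))^(2Ng)
    """
    q = 1.0 - query.p if query.q is None else query.q
    per_meiosis = (1.0 - query.r) + query.r * (query.p ** 2 + q ** 2)
    return float(per_meiosis ** (2.0 * query.N * query.g))


def region_persistence(
    d_cm: float, p: float, n_e: float = 36.21, generations: float = 3
) -> float:
    """Persistence probability for a region of ``d_cm`` centimorgans.

    Convenience wrapper: Haldane conversion then the closed form.  The
    default N is the through-generation-50 harmonic-mean effective size.
    """
    return persistence_probability(
        PersistenceQuery(r=haldane_r(d_cm), p=p, N=n_e, g=generations)
    )
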