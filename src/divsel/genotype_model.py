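"""Core genotype containers and PED/MAP-style I/O.

A :class:`GenotypePanel` holds a samples x SNPs allele-dosage matrix for two
divergently selected lines sampled at one or more generations.  A
:class:`MarkerMap` holds per-SNP genomic coordinates plus per-chromosome
cM/Mb ratios used to convert physical cluster lengths to map lengths.

Dosage is the count of the *reference* allele declared per SNP in the map
sidecar, so "fixed for different alleles" is well defined across files.
Missing genotypes are coded ``-1`` and are excluded per SNP from allele
frequency denominators.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

LINE_HIGH = "HIGH"
LINE_LOW = "LOW"


class FixationClass(Enum):
    """Joint fixation status of one SNP in the two lines."""

    DIFF = "DIFF"          # fixed for alternative alleles
    SAME = "SAME"          # fixed for the same allele in both lines
    H_NOT_L = "H_NOT_L"    # fixed in the high line, segregating in the low
    L_NOT_H = "L_NOT_H"    # fixed in the low line, segregating in the high
    BOTH_SEG = "BOTH_SEG"  # segregating in both lines
    UNKNOWN = "UNKNOWN"    # frequency undefined in at least one line


class PanelFormatError(ValueError):
    """Raised when genotype/map files are malformed or inconsistent."""


@dataclass
class MarkerMap:
    """Per-SNP chromosome and position plus per-chromosome cM/Mb ratios.

    Parameters
    ----------
    snp_id, chromosome, position_bp
        Aligned per-SNP arrays; positions are 1-based and must be strictly
        increasing within a chromosome.
    cm_per_mb
        Mapping from chromosome label to its cM/Mb ratio.  A chromosome may
        be absent (e.g. Z), in which case map lengths are left blank.
    ref_allele
        Per-SNP reference allele letter against which dosage is counted.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    cm_per_mb: dict[str, float] = field(default_factory=dict)
    ref_allele: np.ndarray | None = None
    alt_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if self.ref_allele is None:
            self.ref_allele = np.full(len(self.snp_id), "A", dtype=object)
        if self.alt_allele is None:
            self.alt_allele = np.full(len(self.snp_id), "G", dtype=object)
        self.validate()

    def __len__(self) -> int:
        return len(self.snp_id)

    def validate(self) -> None:
        n = len(self.snp_id)
        if not (len(self.chromosome) == len(self.position_bp) == n):
            raise PanelFormatError("marker map columns have unequal lengths")
        if np.any(self.position_bp < 1):
            raise PanelFormatError("positions must be 1-based (>= 1)")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise PanelFormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        for chrom, ratio in self.cm_per_mb.items():
            if ratio < 0:
                raise PanelFormatError(f"negative cM/Mb ratio for {chrom}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "ref_allele": self.ref_allele,
                "alt_allele": self.alt_allele,
            }
        )


@dataclass
class GenotypePanel:
    """Samples x SNPs diploid dosage matrix with line/generation labels.

    ``genotypes[i, j]`` is the number of reference-allele copies carried by
    sample ``i`` at SNP ``j`` (0, 1 or 2), or :data:`MISSING`.
    """

    sample_ids: list[str]
    line: np.ndarray
    generation: np.ndarray
    genotypes: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.line = np.asarray(self.line, dtype=object)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_samples, self.n_snps):
            raise PanelFormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{self.n_samples} samples x {self.n_snps} SNPs"
            )
        if len(self.line) != self.n_samples or len(self.generation) != self.n_samples:
            raise PanelFormatError("line/generation labels must cover every sample")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"invalid dosage {self.genotypes[i, j]} for sample "
                f"{self.sample_ids[i]} at SNP {self.snp_ids[j]}"
            )
        for sid, ln in zip(self.sample_ids, self.line):
            if ln not in (LINE_HIGH, LINE_LOW):
                raise PanelFormatError(f"sample {sid} has unknown line label {ln!r}")

    def group_mask(self, line: str | None = None, generation: int | None = None) -> np.ndarray:
        """Boolean sample mask for a line and/or generation selector."""
        mask = np.ones(self.n_samples, dtype=bool)
        if line is not None:
            mask &= self.line == line
        if generation is not None:
            mask &= self.generation == int(generation)
        return mask

    def subset(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            line=self.line[mask],
            generation=self.generation[mask],
            genotypes=self.genotypes[mask],
            snp_ids=list(self.snp_ids),
        )


@dataclass(frozen=True)
class GroupAlleleCounts:
    """2x2 allele-count table for one SNP in two sample groups."""

    n_allele1_g1: int
    n_allele2_g1: int
    n_allele1_g2: int
    n_allele2_g2: int

    def __post_init__(self) -> None:
        for v in (self.n_allele1_g1, self.n_allele2_g1, self.n_allele1_g2, self.n_allele2_g2):
            if v < 0:
                raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_allele1_g1 + self.n_allele2_g1 + self.n_allele1_g2 + self.n_allele2_g2

    def as_table(self) -> np.ndarray:
        return np.array(
            [
                [self.n_allele1_g1, self.n_allele2_g1],
                [self.n_allele1_g2, self.n_allele2_g2],
            ],
            dtype=np.int64,
        )


def concat_panels(panels: Sequence[GenotypePanel]) -> GenotypePanel:
    """Stack panels sample-wise (e.g. the two sampled generations)."""
    if not panels:
        raise ValueError("no panels to concatenate")
    snp_ids = panels[0].snp_ids
    for p in panels[1:]:
        if p.snp_ids != snp_ids:
            raise PanelFormatError("panels must share the same SNP set and order")
    return GenotypePanel(
        sample_ids=[s for p in panels for s in p.sample_ids],
        line=np.concatenate([p.line for p in panels]),
        generation=np.concatenate([p.generation for p in panels]),
        genotypes=np.vstack([p.genotypes for p in panels]),
        snp_ids=list(snp_ids),
    )


# ---------------------------------------------------------------------------
# Allele frequencies and fixation classes
# ---------------------------------------------------------------------------

def allele_frequencies(
    panel: GenotypePanel,
    line: str | None = None,
    generation: int | None = None,
) -> np.ndarray:
    """Per-SNP reference-allele frequency within one sample group.

    Missing genotypes are dropped from the denominator per SNP; SNPs with no
    non-missing call in the group get ``nan``.
    """
    mask = panel.group_mask(line, generation)
    if not mask.any():
        raise ValueError(
            f"empty sample group for line={line!r}, generation={generation!r}"
        )
    g = panel.genotypes[mask].astype(np.float64)
    g[g == MISSING] = np.nan
    n_called = np.sum(~np.isnan(g), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(g, axis=0) / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    return freq


def group_allele_counts(
    panel: GenotypePanel,
    group1: tuple[str | None, int | None],
    group2: tuple[str | None, int | None],
) -> list[GroupAlleleCounts]:
    """Build per-SNP 2x2 allele-count tables for two disjoint sample groups."""
    m1 = panel.group_mask(*group1)
    m2 = panel.group_mask(*group2)
    if not m1.any() or not m2.any():
        raise ValueError("both sample groups must be non-empty")
    if (m1 & m2).any():
        raise ValueError("sample groups overlap")

    out = []
    for m in (m1, m2):
        g = panel.genotypes[m]
        called = g != MISSING
        n1 = np.where(called, g, 0).sum(axis=0)
        n_tot = 2 * called.sum(axis=0)
        out.append((n1, n_tot - n1))
    (a1, b1), (a2, b2) = out
    return [
        GroupAlleleCounts(int(a1[j]), int(b1[j]), int(a2[j]), int(b2[j]))
        for j in range(panel.n_snps)
    ]


def classify_fixation(freq_high: np.ndarray, freq_low: np.ndarray) -> np.ndarray:
    """Classify each SNP by joint fixation status of the two lines.

    Returns an object array of :class:`FixationClass` values.  A frequency of
    exactly 0 or 1 counts as fixed; ``nan`` in either line yields ``UNKNOWN``.
    """
    fh = np.asarray(freq_high, dtype=np.float64)
    fl = np.asarray(freq_low, dtype=np.float64)
    if fh.shape != fl.shape:
        raise ValueError("frequency arrays must be aligned")

    out = np.empty(fh.shape, dtype=object)
    out[:] = FixationClass.BOTH_SEG
    with np.errstate(invalid="ignore"):
        h_fixed = (fh == 0.0) | (fh == 1.0)
        l_fixed = (fl == 0.0) | (fl == 1.0)
        diff = h_fixed & l_fixed & (fh != fl)
        same = h_fixed & l_fixed & (fh == fl)
    out[h_fixed & ~l_fixed] = FixationClass.H_NOT_L
    out[l_fixed & ~h_fixed] = FixationClass.L_NOT_H
    out[diff] = FixationClass.DIFF
    out[same] = FixationClass.SAME
    out[np.isnan(fh) | np.isnan(fl)] = FixationClass.UNKNOWN
    return out


def fixation_counts(classes: np.ndarray) -> dict[FixationClass, int]:
    """Tally SNPs per fixation class (UNKNOWN reported but not classifiable)."""
    return {c: int(np.sum(classes == c)) for c in FixationClass}


# ---------------------------------------------------------------------------
# PED/MAP I/O with TSV sidecars
# ---------------------------------------------------------------------------
#
# Files share a common stem:  <stem>.ped, <stem>.map, <stem>.samples.tsv
# (sample_id, line, generation), <stem>.chroms.tsv (chromosome, cm_per_mb),
# <stem>.alleles.tsv (snp_id, ref_allele, alt_allele).  The PED holds one row
# per sample with two allele columns per SNP ("0 0" = missing); the MAP holds
# chromosome, snp_id, cM (written 0) and bp.

def _stem(map_path: str) -> str:
    stem, ext = os.path.splitext(map_path)
    return stem if ext == ".map" else map_path


def read_panel(genotype_path: str, map_path: str) -> tuple[GenotypePanel, MarkerMap]:
    """Read a PED/MAP pair plus its TSV sidecars into panel + map."""
    stem = _stem(map_path)
    for path in (genotype_path, map_path):
        if not os.path.exists(path):
            raise FileNotFoundError(path)

    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
        dtype={"chromosome": str, "snp_id": str},
    )
    alleles = pd.read_csv(stem + ".alleles.tsv", sep="\t", dtype=str)
    alleles = alleles.set_index("snp_id").reindex(map_df["snp_id"])
    if alleles["ref_allele"].isna().any():
        missing = map_df["snp_id"][alleles["ref_allele"].isna().values].iloc[0]
        raise PanelFormatError(f"no reference allele declared for SNP {missing}")
    chroms = pd.read_csv(stem + ".chroms.tsv", sep="\t", dtype={"chromosome": str})
    samples = pd.read_csv(stem + ".samples.tsv", sep="\t", dtype={"sample_id": str})
    if samples["line"].isna().any():
        sid = samples.loc[samples["line"].isna(), "sample_id"].iloc[0]
        raise PanelFormatError(f"sample {sid} is missing a line label")

    marker_map = MarkerMap(
        snp_id=map_df["snp_id"].to_numpy(),
        chromosome=map_df["chromosome"].to_numpy(),
        position_bp=map_df["position_bp"].to_numpy(),
        cm_per_mb=dict(zip(chroms["chromosome"], chroms["cm_per_mb"].astype(float))),
        ref_allele=alleles["ref_allele"].to_numpy(),
        alt_allele=alleles["alt_allele"].to_numpy(),
    )

    n_snps = len(marker_map)
    ref = marker_map.ref_allele
    alt = marker_map.alt_allele
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(genotype_path) as fh:
        for line_no, raw in enumerate(fh, 1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PanelFormatError(
                    f"PED line {line_no}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            sid = fields[1]
            sample_ids.append(sid)
            a = np.array(fields[6::2], dtype=object)
            b = np.array(fields[7::2], dtype=object)
            dose = np.full(n_snps, MISSING, dtype=np.int8)
            miss = (a == "0") | (b == "0")
            known = ((a == ref) | (a == alt)) & ((b == ref) | (b == alt))
            bad = ~miss & ~known
            if bad.any():
                j = int(np.argmax(bad))
                raise PanelFormatError(
                    f"sample {sid}: unknown allele code "
                    f"{a[j]!r}/{b[j]!r} at SNP {marker_map.snp_id[j]}"
                )
            ok = ~miss
            dose[ok] = (a[ok] == ref[ok]).astype(np.int8) + (b[ok] == ref[ok]).astype(np.int8)
            rows.append(dose)

    samples = samples.set_index("sample_id").reindex(sample_ids)
    if samples["line"].isna().any():
        sid = [s for s in sample_ids if s not in samples.index or pd.isna(samples.loc[s, "line"])][0]
        raise PanelFormatError(f"sample {sid} is missing a line label")

    panel = GenotypePanel(
        sample_ids=sample_ids,
        line=samples["line"].to_numpy(),
        generation=samples["generation"].astype(int).to_numpy(),
        genotypes=np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8),
        snp_ids=list(marker_map.snp_id),
    )
    if panel.n_snps != len(marker_map):
        raise PanelFormatError("panel and map disagree on SNP count")
    return panel, marker_map


def write_panel(panel: GenotypePanel, marker_map: MarkerMap, prefix: str) -> dict[str, str]:
    """Write panel + map as PED/MAP with TSV sidecars; returns written paths."""
    if panel.n_snps != len(marker_map):
        raise PanelFormatError("panel and map disagree on SNP count")
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)

    paths = {
        "ped": prefix + ".ped",
        "map": prefix + ".map",
        "samples": prefix + ".samples.tsv",
        "chroms": prefix + ".chroms.tsv",
        "alleles": prefix + ".alleles.tsv",
    }

    with open(paths["map"], "w") as fh:
        for snp, chrom, pos in zip(marker_map.snp_id, marker_map.chromosome, marker_map.position_bp):
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")

    ref = marker_map.ref_allele
    alt = marker_map.alt_allele
    with open(paths["ped"], "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            dose = panel.genotypes[i]
            pair = np.empty((panel.n_snps, 2), dtype=object)
            pair[dose == 2] = np.stack([ref, ref], axis=1)[dose == 2]
            pair[dose == 1] = np.stack([ref, alt], axis=1)[dose == 1]
            pair[dose == 0] = np.stack([alt, alt], axis=1)[dose == 0]
            pair[dose == MISSING] = ("0", "0")
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + list(pair.ravel())) + "\n")

    pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "line": panel.line,
            "generation": panel.generation,
        }
    ).to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame(
        sorted(marker_map.cm_per_mb.items()), columns=["chromosome", "cm_per_mb"]
    ).to_csv(paths["chroms"], sep="\t", index=False)
    pd.DataFrame(
        {
            "snp_id": marker_map.snp_id,
            "ref_allele": marker_map.ref_allele,
            "alt_allele": marker_map.alt_allele,
        }
    ).to_csv(paths["alleles"], sep="\t", index=False)
    return paths
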