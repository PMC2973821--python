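"""Synthetic two-line, two-timepoint SNP panels with drift and planted sweeps.

The generator emulates a divergent single-trait selection experiment
genotyped on a dense SNP chip: markers at roughly one per 15 kb across a few
macro- and micro-chromosomes, founder allele frequencies on multiples of 1/7
(the base population is a cross of seven inbred lines), per-line genetic
drift, and planted selective sweeps that leave clusters of SNPs fixed for
alternative alleles in the two lines.

Linkage is emulated cheaply: SNPs are grouped into 30-60 kb blocks (the LD
scale reported for such populations) that share one drift trajectory, with
small per-SNP jitter.  This reproduces clustered fixation without a
genome-scale recombination engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_model import (
    LINE_HIGH,
    LINE_LOW,
    MISSING,
    GenotypePanel,
    MarkerMap,
)

LINES = (LINE_HIGH, LINE_LOW)


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep.

    SNPs within ``half_width_bp`` of ``center_bp`` are driven to fixation for
    the reference allele in ``line_favoured`` and for the alternative allele
    in the other line by ``fixation_generation``, except for SNPs that
    "escape" (probability rising linearly with distance from the center, to
    ``edge_escape_prob`` at the boundary) and keep drifting — the soft edge
    of a sweep from standing variation.
    """

    chromosome: str
    center_bp: int
    half_width_bp: int
    line_favoured: str = LINE_HIGH
    fixation_generation: int = 40
    edge_escape_prob: float = 0.5
    onset_generation: int | None = None  # default: 15 generations before fixation

    def __post_init__(self) -> None:
        if self.half_width_bp <= 0:
            raise ValueError("half_width_bp must be positive")
        if self.onset_generation is not None and not (
            0 <= self.onset_generation < self.fixation_generation
        ):
            raise ValueError("onset_generation must lie in [0, fixation_generation)")
        if self.line_favoured not in LINES:
            raise ValueError(f"line_favoured must be one of {LINES}")
        if not 0.0 <= self.edge_escape_prob <= 1.0:
            raise ValueError("edge_escape_prob must be in [0, 1]")


def default_sample_sizes() -> dict[tuple[str, int], int]:
    """Chip sample sizes: 20/20 birds at generation 40, 49 high / 10 low at 50."""
    return {
        (LINE_HIGH, 40): 20,
        (LINE_LOW, 40): 20,
        (LINE_HIGH, 50): 49,
        (LINE_LOW, 50): 10,
    }


def default_chromosomes(n_snps: int, bp_per_snp: int) -> dict[str, int]:
    """Five chromosomes (3 macro, 2 micro) splitting ``n_snps`` markers."""
    total = n_snps * bp_per_snp
    fractions = {"1": 0.35, "2": 0.25, "3": 0.18, "24": 0.13, "27": 0.09}
    return {c: max(int(total * f), 10 * bp_per_snp) for c, f in fractions.items()}


@dataclass
class SynthConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the experiment the generator emulates: ~1 marker/15 kb,
    effective size 35 per line, founder frequencies uniform on
    {1/7, ..., 6/7}, sampling at generations 40 and 50 with 20/20 and 49/10
    birds, 30-60 kb LD blocks.  ``n_snps=5000`` on five chromosomes is the
    test scale; pass ``n_snps=57636`` with more chromosomes for a full-chip
    emulation.
    """

    n_snps: int = 5000
    bp_per_snp: int = 15_000
    chromosome_lengths: dict[str, int] | None = None
    cm_per_mb: dict[str, float] | None = None
    effective_size: int = 35
    census_size: int = 288
    sample_sizes: dict[tuple[str, int], int] = field(default_factory=default_sample_sizes)
    sweeps: list[SweepSpec] = field(default_factory=list)
    base_freq_choices: tuple[float, ...] = tuple(k / 7 for k in range(1, 7))
    ld_block_kb: tuple[float, float] = (30.0, 60.0)
    snp_jitter_sd: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_lengths is None:
            self.chromosome_lengths = default_chromosomes(self.n_snps, self.bp_per_snp)
        if self.cm_per_mb is None:
            # macro chromosomes recombine at ~3 cM/Mb, micro at ~10
            self.cm_per_mb = {
                c: (3.0 if length > 8_000_000 else 10.0)
                for c, length in self.chromosome_lengths.items()
            }
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")
        if self.effective_size < 1:
            raise ValueError("effective_size must be >= 1")
        self._check_sweeps()

    @property
    def sampled_generations(self) -> list[int]:
        return sorted({g for (_, g) in self.sample_sizes})

    def _check_sweeps(self) -> None:
        by_chrom: dict[str, list[SweepSpec]] = {}
        last_gen = max(self.sampled_generations)
        for sw in self.sweeps:
            if sw.chromosome not in self.chromosome_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chromosome}")
            if sw.fixation_generation > last_gen:
                raise ValueError(
                    "sweep fixation_generation exceeds the latest sampled generation"
                )
            by_chrom.setdefault(sw.chromosome, []).append(sw)
        for chrom, sweeps in by_chrom.items():
            spans = sorted(
                (s.center_bp - s.half_width_bp, s.center_bp + s.half_width_bp)
                for s in sweeps
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise ValueError(f"overlapping sweeps on chromosome {chrom}")


@dataclass
class SynthDataset:
    """Panels per sampled generation, the marker map, and ground truth."""

    panels: dict[int, GenotypePanel]
    marker_map: MarkerMap
    truth: pd.DataFrame


def _build_map(config: SynthConfig, rng: np.random.Generator) -> MarkerMap:
    lengths = config.chromosome_lengths
    total = sum(lengths.values())
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    remaining = config.n_snps
    items = list(lengths.items())
    for k, (chrom, length) in enumerate(items):
        n = remaining if k == len(items) - 1 else max(2, round(config.n_snps * length / total))
        n = min(n, remaining)
        remaining -= n
        # near-regular spacing with jitter, then de-duplicated and sorted
        base = np.linspace(1, length, n, dtype=np.int64)
        jitter = rng.integers(-config.bp_per_snp // 3, config.bp_per_snp // 3 + 1, size=n)
        pos = np.sort(np.clip(base + jitter, 1, length))
        pos = pos + np.arange(n)  # break ties, keep strictly increasing
        chroms.append(np.full(n, chrom, dtype=object))
        positions.append(pos)
    chromosome = np.concatenate(chroms)
    position_bp = np.concatenate(positions)
    snp_id = np.array(
        [f"snp_{c}_{p}" for c, p in zip(chromosome, position_bp)], dtype=object
    )
    return MarkerMap(
        snp_id=snp_id,
        chromosome=chromosome,
        position_bp=position_bp,
        cm_per_mb=dict(config.cm_per_mb),
    )


def _assign_blocks(marker_map: MarkerMap, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Group consecutive SNPs into shared-drift blocks of 30-60 kb."""
    lo, hi = (kb * 1000 for kb in config.ld_block_kb)
    block = np.empty(len(marker_map), dtype=np.int64)
    bid = -1
    for chrom in dict.fromkeys(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == chrom)
        pos = marker_map.position_bp[idx]
        start = -np.inf
        size = 0.0
        for i, p in zip(idx, pos):
            if p - start > size:
                bid += 1
                start = p
                size = rng.uniform(lo, hi)
            block[i] = bid
    return block


def _drift_trajectories(
    p0: np.ndarray, n_gen: int, n_e: int, rng: np.random.Generator
) -> np.ndarray:
    """Wright-Fisher binomial drift of block frequencies; shape (n_gen+1, n_blocks)."""
    two_ne = 2 * n_e
    traj = np.empty((n_gen + 1, p0.size))
    traj[0] = p0
    p = p0.copy()
    for g in range(1, n_gen + 1):
        p = rng.binomial(two_ne, p) / two_ne
        traj[g] = p
    return traj


def _sample_genotypes(
    freqs: np.ndarray, n_samples: int, census: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw diploid dosages for ``n_samples`` birds without replacement.

    The line's gamete pool is 2*census gametes with round(2*census*p) copies
    of the reference allele; 2*n_samples gametes are drawn hypergeometrically
    and paired at random into genotypes.
    """
    pool = 2 * census
    draw = 2 * n_samples
    if draw > pool:
        raise ValueError("cannot sample more gametes than the census provides")
    k_ref = np.rint(pool * freqs).astype(np.int64)
    n_ref = rng.hypergeometric(k_ref, pool - k_ref, draw)
    # pair the drawn gametes at random: hets follow from a second hypergeometric
    geno = np.empty((n_samples, freqs.size), dtype=np.int8)
    for j in range(freqs.size):
        gametes = np.zeros(draw, dtype=np.int8)
        gametes[: n_ref[j]] = 1
        rng.shuffle(gametes)
        geno[:, j] = gametes[0::2] + gametes[1::2]
    return geno


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate panels at each sampled generation plus map and ground truth.

    Non-sweep SNPs drift independently per line (block-shared binomial
    trajectories from a common founder frequency); sweep SNPs ramp linearly
    to opposite fixation in the two lines by their sweep's
    ``fixation_generation``.  Identical configs produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _build_map(config, rng)
    block = _assign_blocks(marker_map, config, rng)
    n_blocks = int(block.max()) + 1
    n_snps = len(marker_map)
    n_gen = max(config.sampled_generations)

    base_block = rng.choice(config.base_freq_choices, size=n_blocks)
    base = base_block[block]

    # sweep membership and escapes
    sweep_id = np.full(n_snps, -1, dtype=np.int64)
    escaped = np.zeros(n_snps, dtype=bool)
    for si, sw in enumerate(config.sweeps):
        on_chrom = marker_map.chromosome == sw.chromosome
        dist = np.abs(marker_map.position_bp - sw.center_bp)
        inside = on_chrom & (dist <= sw.half_width_bp)
        p_escape = sw.edge_escape_prob * dist / sw.half_width_bp
        esc = inside & (rng.random(n_snps) < p_escape)
        sweep_id[inside] = si
        escaped[inside] = esc[inside]
    swept = (sweep_id >= 0) & ~escaped

    freqs: dict[tuple[str, int], np.ndarray] = {}
    gens = config.sampled_generations
    for line in LINES:
        traj_block = _drift_trajectories(base_block, n_gen, config.effective_size, rng)
        traj = traj_block[:, block]
        jitter = rng.normal(0.0, config.snp_jitter_sd, size=traj.shape)
        interior = (traj > 0.0) & (traj < 1.0)
        traj = np.clip(np.where(interior, traj + jitter, traj), 0.0, 1.0)
        for si, sw in enumerate(config.sweeps):
            members = swept & (sweep_id == si)
            if not members.any():
                continue
            target = 1.0 if line == sw.line_favoured else 0.0
            g_fix = sw.fixation_generation
            # a sweep rises over ~15 generations, matching the fixation times
            # the forward simulator gives for s in the 0.2-0.9 range
            onset = max(0, g_fix - 15) if sw.onset_generation is None else sw.onset_generation
            ramp = np.clip((np.arange(n_gen + 1) - onset) / (g_fix - onset), 0.0, 1.0)[:, None]
            p0 = base[members][None, :]
            traj[:, members] = p0 + (target - p0) * ramp
        for g in gens:
            freqs[(line, g)] = traj[g].copy()

    # sampled panels
    panels: dict[int, GenotypePanel] = {}
    for g in gens:
        ids, lines, genos = [], [], []
        for line in LINES:
            n = config.sample_sizes.get((line, g), 0)
            if n == 0:
                continue
            geno = _sample_genotypes(freqs[(line, g)], n, config.census_size, rng)
            if config.missing_rate > 0:
                miss = rng.random(geno.shape) < config.missing_rate
                geno[miss] = MISSING
            ids += [f"{line[0]}{g}_{k:03d}" for k in range(n)]
            lines += [line] * n
            genos.append(geno)
        panels[g] = GenotypePanel(
            sample_ids=ids,
            line=np.array(lines, dtype=object),
            generation=np.full(len(ids), g),
            genotypes=np.vstack(genos),
            snp_ids=list(marker_map.snp_id),
        )

    truth = pd.DataFrame(
        {
            "snp_id": marker_map.snp_id,
            "chromosome": marker_map.chromosome,
            "position_bp": marker_map.position_bp,
            "block": block,
            "base_freq": base,
            "sweep_id": sweep_id,
            "escaped": escaped,
            "in_sweep_core": swept,
        }
    )
    for line in LINES:
        for g in gens:
            truth[f"p_{line}_{g}"] = freqs[(line, g)]
    return SynthDataset(panels=panels, marker_map=marker_map, truth=truth)
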