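"""Individual-based two-locus forward simulation of one selected line.

The breeding scheme mirrors a pedigreed single-trait selection experiment:
each generation 12 sires and 48 dams are chosen from a census of 288 birds
(48 dams x 6 offspring), dams are split 4 per sire, and every dam produces
six offspring.  Selection acts on locus A with viability-style fitnesses
1, 1-hs, 1-s for genotypes AA, Aa, aa and a sex-specific selection
coefficient (selection intensities differ between males and females).
Locus B is neutral and linked to A at recombination fraction r.

Founders are drawn from a four-digit haplotype code xyzw giving sevenths of
haplotypes AB, Ab, aB, ab — the base population being a cross of seven
inbred lines, founder frequencies are multiples of 1/7.

Parents are picked by fitness-weighted sampling without replacement within
each sex, which honours both the fitness model and the fixed parent counts.
All populations carry a leading replicate axis so a thousand replicates
step in lockstep through vectorised numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BreedingScheme:
    """Constant-size breeding design: census = n_dams * offspring_per_dam."""

    n_sires: int = 12
    n_dams: int = 48
    dams_per_sire: int = 4
    offspring_per_dam: int = 6

    def __post_init__(self) -> None:
        if self.n_dams != self.n_sires * self.dams_per_sire:
            raise ValueError("n_dams must equal n_sires * dams_per_sire")
        if min(self.n_sires, self.n_dams, self.dams_per_sire, self.offspring_per_dam) < 1:
            raise ValueError("scheme counts must be positive")

    @property
    def census(self) -> int:
        return self.n_dams * self.offspring_per_dam


@dataclass(frozen=True)
class SelectionParams:
    """Sex-specific selection on locus A: fitnesses 1, 1-hs, 1-s."""

    s_male: float = 0.0
    s_female: float = 0.0
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.s_male < 0 or self.s_female < 0:
            raise ValueError("selection coefficients must be >= 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must be in [0, 1]")
        for s in (self.s_male, self.s_female):
            if min(1.0, 1.0 - self.h * s, 1.0 - s) < 0:
                raise ValueError("fitnesses 1, 1-hs, 1-s must all be >= 0")

    def fitness(self, n_A: np.ndarray, male: np.ndarray) -> np.ndarray:
        """Fitness from the locus-A genotype (n_A = copies of allele A)."""
        s = np.where(male, self.s_male, self.s_female)
        w = np.ones_like(s, dtype=np.float64)
        w = np.where(n_A == 1, 1.0 - self.h * s, w)
        w = np.where(n_A == 0, 1.0 - s, w)
        return w

    @property
    def neutral(self) -> bool:
        return self.s_male == 0.0 and self.s_female == 0.0


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Founder haplotype proportions as a four-digit code xyzw (sevenths).

    x, y, z, w are the sevenths of haplotypes AB, Ab, aB and ab; they must
    sum to 7.  Code "4003" means 4/7 AB and 3/7 ab.
    """

    code: str

    def __post_init__(self) -> None:
        if len(self.code) != 4 or not self.code.isdigit():
            raise ValueError(f"haplotype code must be four digits, got {self.code!r}")
        if sum(int(c) for c in self.code) != 7:
            raise ValueError(f"haplotype code digits must sum to 7, got {self.code!r}")

    @property
    def proportions(self) -> np.ndarray:
        """Probabilities of haplotypes (AB, Ab, aB, ab)."""
        return np.array([int(c) for c in self.code], dtype=np.float64) / 7.0


@dataclass
class Population:
    """Diploid two-locus individuals with sex, batched over replicates.

    ``hapA1/hapB1`` and ``hapA2/hapB2`` are the two haplotypes (1 = allele
    A or B, 0 = a or b), each of shape (n_reps, census); ``male`` likewise.
    """

    hapA1: np.ndarray
    hapB1: np.ndarray
    hapA2: np.ndarray
    hapB2: np.ndarray
    male: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.hapA1.shape[0]

    @property
    def size(self) -> int:
        return self.hapA1.shape[1]

    def freq_A(self) -> np.ndarray:
        """Per-replicate frequency of allele A."""
        return (self.hapA1 + self.hapA2).mean(axis=1) / 2.0

    def freq_B(self) -> np.ndarray:
        return (self.hapB1 + self.hapB2).mean(axis=1) / 2.0

    def fixed_at(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """(is_fixed, fixed_allele) per replicate at locus 'A' or 'B'."""
        h1 = self.hapA1 if locus == "A" else self.hapB1
        h2 = self.hapA2 if locus == "A" else self.hapB2
        total = h1.sum(axis=1) + h2.sum(axis=1)
        n = 2 * self.size
        fixed = (total == 0) | (total == n)
        allele = (total == n).astype(np.int8)
        return fixed, allele

    def gamete_counts(self) -> np.ndarray:
        """Per-replicate counts of gametes (AB, Ab, aB, ab) in the population."""
        out = np.empty((self.n_reps, 4), dtype=np.int64)
        for k, (a, b) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)]):
            out[:, k] = ((self.hapA1 == a) & (self.hapB1 == b)).sum(axis=1) + (
                (self.hapA2 == a) & (self.hapB2 == b)
            ).sum(axis=1)
        return out


class ParentShortageError(RuntimeError):
    """Not enough selectable parents of one sex."""


def init_population(
    freqs: HaplotypeFreqs,
    scheme: BreedingScheme,
    seed: int | np.random.Generator,
    n_reps: int = 1,
) -> Population:
    """Found a population: 2*census haplotypes i.i.d. from the code, sexes fair."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = freqs.proportions
    shape = (n_reps, scheme.census)
    # haplotype index 0..3 -> (A allele, B allele)
    a_of = np.array([1, 1, 0, 0], dtype=np.int8)
    b_of = np.array([1, 0, 1, 0], dtype=np.int8)
    h1 = rng.choice(4, size=shape, p=p)
    h2 = rng.choice(4, size=shape, p=p)
    pop = Population(
        hapA1=a_of[h1], hapB1=b_of[h1], hapA2=a_of[h2], hapB2=b_of[h2],
        male=_draw_sexes(rng, shape, scheme),
    )
    return pop


def _draw_sexes(
    rng: np.random.Generator, shape: tuple[int, int], scheme: BreedingScheme
) -> np.ndarray:
    """Bernoulli(1/2) sexes, redrawing any replicate short of either sex."""
    male = rng.random(shape) < 0.5
    for _ in range(1000):
        n_male = male.sum(axis=1)
        bad = (n_male < scheme.n_sires) | (shape[1] - n_male < scheme.n_dams)
        if not bad.any():
            return male
        male[bad] = rng.random((int(bad.sum()), shape[1])) < 0.5
    raise ParentShortageError("could not draw sexes satisfying the scheme")


def _select_parents(
    rng: np.random.Generator,
    weights: np.ndarray,
    eligible: np.ndarray,
    k: int,
    sex_name: str,
) -> np.ndarray:
    """Fitness-weighted sampling without replacement: k columns per replicate.

    Uses exponential race keys (key = Exp(1)/w), whose ascending order is
    exactly successive weighted draws without replacement.
    """
    n_ok = (eligible & (weights > 0)).sum(axis=1)
    if (n_ok < k).any():
        raise ParentShortageError(
            f"replicate has fewer than {k} selectable {sex_name}s"
        )
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=weights.shape) / np.where(eligible, weights, 0.0)
    keys[~eligible | (weights <= 0)] = np.inf
    return np.argsort(keys, axis=1, kind="stable")[:, :k]


def step_generation(
    pop: Population,
    scheme: BreedingScheme,
    sel: SelectionParams,
    r: float,
    rng: np.random.Generator,
) -> Population:
    """Advance one generation of selection, mating and recombination.

    Sires and dams are drawn within sex by fitness-weighted sampling without
    replacement, dams are partitioned uniformly at random among sires
    (dams_per_sire each), every dam bears offspring_per_dam offspring, and
    each gamete recombines between the parent's haplotypes with probability r.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    n_A = pop.hapA1 + pop.hapA2
    w = sel.fitness(n_A, pop.male)

    sires = _select_parents(rng, w, pop.male, scheme.n_sires, "male")
    dams = _select_parents(rng, w, ~pop.male, scheme.n_dams, "female")

    # partition dams among sires: random order, consecutive groups of dams_per_sire
    perm = rng.permuted(
        np.broadcast_to(np.arange(scheme.n_dams), dams.shape).copy(), axis=1
    )
    dams_shuffled = np.take_along_axis(dams, perm, axis=1)
    sire_of_dam = np.repeat(sires, scheme.dams_per_sire, axis=1)

    mother = np.repeat(dams_shuffled, scheme.offspring_per_dam, axis=1)
    father = np.repeat(sire_of_dam, scheme.offspring_per_dam, axis=1)

    kid_shape = mother.shape  # (n_reps, census)
    h1A, h1B = _gametes(rng, pop, mother, r, kid_shape)
    h2A, h2B = _gametes(rng, pop, father, r, kid_shape)
    return Population(
        hapA1=h1A, hapB1=h1B, hapA2=h2A, hapB2=h2B,
        male=_draw_sexes(rng, kid_shape, scheme),
    )


def _gametes(
    rng: np.random.Generator,
    pop: Population,
    parent: np.ndarray,
    r: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per offspring from the given parents.

    The A allele comes from a uniformly chosen parental haplotype; the B
    allele comes from the same haplotype, or from the other one with
    probability r (a crossover between the loci).
    """
    pick2 = rng.random(shape) < 0.5  # which haplotype carries the A allele
    cross = rng.random(shape) < r
    a1 = np.take_along_axis(pop.hapA1, parent, axis=1)
    a2 = np.take_along_axis(pop.hapA2, parent, axis=1)
    b1 = np.take_along_axis(pop.hapB1, parent, axis=1)
    b2 = np.take_along_axis(pop.hapB2, parent, axis=1)
    gA = np.where(pick2, a2, a1)
    b_same = np.where(pick2, b2, b1)
    b_other = np.where(pick2, b1, b2)
    gB = np.where(cross, b_other, b_same)
    return gA, gB


@dataclass
class SimOutcome:
    """Per-replicate fixation records and run-level summaries.

    ``replicates`` has one row per replicate with the first generation at
    which each locus became monomorphic (NaN if never within max_gen) and
    the fixed allele (1 = A/B, 0 = a/b).  ``prop_fixed_A_by_gen[g]`` is the
    proportion of replicates fixed at locus A by generation g (index 0 =
    founders).
    """

    replicates: pd.DataFrame
    prop_fixed_A_by_gen: np.ndarray
    max_gen: int

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    @property
    def prop_fixed_A(self) -> float:
        """Proportion of replicates fixed at locus A by max_gen."""
        return float(self.prop_fixed_A_by_gen[self.max_gen])

    @property
    def first_fixation_gen(self) -> float:
        """Earliest fixation generation at locus A across replicates (NaN if none)."""
        col = self.replicates["fix_gen_A"]
        return float(col.min()) if col.notna().any() else float("nan")

    def fixation_quantile_gen(self, prop: float = 0.10) -> float:
        """First generation by which >= ``prop`` of replicates are fixed at A."""
        hit = np.flatnonzero(self.prop_fixed_A_by_gen >= prop)
        return float(hit[0]) if hit.size else float("nan")

    def summary(self) -> pd.DataFrame:
        """One-row summary matching the fixation-time table layout."""
        fixed = self.replicates["fix_gen_A"].notna()
        sel_fixed = self.replicates.loc[fixed, "allele_A"] == 1
        return pd.DataFrame(
            {
                "n_replicates": [self.n_reps],
                "first_fixation_gen": [self.first_fixation_gen],
                "gen_10pct_fixed": [self.fixation_quantile_gen(0.10)],
                "prop_fixed": [self.prop_fixed_A],
                "prop_fixed_for_A_given_fixed": [
                    float(sel_fixed.mean()) if fixed.any() else float("nan")
                ],
            }
        )


def run_replicates(
    freqs: HaplotypeFreqs,
    scheme: BreedingScheme,
    sel: SelectionParams,
    r: float,
    n_reps: int,
    max_gen: int,
    seed: int | np.random.Generator,
) -> SimOutcome:
    """Run ``n_reps`` replicate lines for ``max_gen`` generations.

    Fixation means every individual in the replicate is homozygous for the
    same allele.  All replicates share one seeded generator, stepped in
    lockstep, so a fixed seed reproduces the run exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = init_population(freqs, scheme, rng, n_reps=n_reps)

    fix_gen = {loc: np.full(n_reps, np.nan) for loc in "AB"}
    allele = {loc: np.full(n_reps, -1, dtype=np.int8) for loc in "AB"}
    prop_by_gen = np.zeros(max_gen + 1)

    def record(g: int) -> None:
        for loc in "AB":
            fixed, al = pop.fixed_at(loc)
            new = fixed & np.isnan(fix_gen[loc])
            fix_gen[loc][new] = g
            allele[loc][new] = al[new]
        prop_by_gen[g] = np.mean(~np.isnan(fix_gen["A"]))

    record(0)
    for g in range(1, max_gen + 1):
        pop = step_generation(pop, scheme, sel, r, rng)
        record(g)

    replicates = pd.DataFrame(
        {
            "replicate": np.arange(n_reps),
            "fix_gen_A": fix_gen["A"],
            "allele_A": allele["A"],
            "fix_gen_B": fix_gen["B"],
            "allele_B": allele["B"],
        }
    )
    return SimOutcome(replicates=replicates, prop_fixed_A_by_gen=prop_by_gen, max_gen=max_gen)


def neutral_fixation_probabilities(
    freqs: HaplotypeFreqs,
    scheme: BreedingScheme,
    n_reps: int,
    max_gen: int,
    seed: int | np.random.Generator,
    r: float = 0.5,
) -> dict[str, float]:
    """Monte-Carlo fixation probabilities at locus A under pure drift (s=0).

    Returns P(fix A), P(fix a) within ``max_gen`` generations in one line,
    with binomial standard errors.
    """
    out = run_replicates(
        freqs, scheme, SelectionParams(0.0, 0.0), r, n_reps, max_gen, seed
    )
    fixed = out.replicates["fix_gen_A"].notna().to_numpy()
    is_A = fixed & (out.replicates["allele_A"].to_numpy() == 1)
    is_a = fixed & (out.replicates["allele_A"].to_numpy() == 0)
    p_A = float(is_A.mean())
    p_a = float(is_a.mean())
    return {
        "p_fix_A": p_A,
        "p_fix_a": p_a,
        "se_A": float(np.sqrt(p_A * (1 - p_A) / n_reps)),
        "se_a": float(np.sqrt(p_a * (1 - p_a) / n_reps)),
    }
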