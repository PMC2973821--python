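"""Quantitative-genetic estimators for a divergent selection experiment.

Covers the arithmetic that connects the selection experiment's design to
population-genetic expectations: selection intensity from the proportion
selected, per-QTL selection coefficients s = i*2a/sigma, effective
population size from parent counts and its harmonic mean across epochs, the
Otto-Jones projection of the total number of trait loci from detected QTL
effects, and the attribution of alternative-allele fixations to selection
versus drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def selection_intensity(p_selected: float) -> float:
    """Selection intensity i for truncation selection of a proportion p.

    i = phi(z)/p where z is the standard-normal truncation point with upper
    tail p.  Computed analytically from the normal density (tabulated values
    in the classical texts agree to <0.01).
    """
    if not 0.0 < p_selected < 1.0:
        raise ValueError("proportion selected must be in (0, 1)")
    z = stats.norm.isf(p_selected)
    return float(stats.norm.pdf(z) / p_selected)


@dataclass(frozen=True)
class QTLEffect:
    """A detected QTL: additive effect a (trait units), phenotypic SD sigma,
    and sex-specific selection intensities (SD units)."""

    name: str
    a: float
    sigma: float
    i_male: float
    i_female: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("phenotypic SD must be positive")
        if self.i_male < 0 or self.i_female < 0:
            raise ValueError("selection intensities must be >= 0")


def selection_coefficient(qtl: QTLEffect, sex: str, s_max: float = 1.0) -> float:
    """Selection coefficient s = i * 2a / sigma for one sex ('M' or 'F').

    Values above ``s_max`` are capped with a warning (fitness 1-s may not
    drop below 0).
    """
    i = {"M": qtl.i_male, "F": qtl.i_female}.get(sex.upper())
    if i is None:
        raise ValueError("sex must be 'M' or 'F'")
    s = i * 2.0 * qtl.a / qtl.sigma
    if s > s_max:
        warnings.warn(
            f"selection coefficient {s:.3f} for {qtl.name} exceeds {s_max}; capped"
        )
        s = s_max
    return float(s)


def ne_from_parents(n_males: float, n_females: float) -> float:
    """Effective size with unequal sex numbers: Ne = 4*Nm*Nf/(Nm+Nf)."""
    if n_males <= 0 or n_females <= 0:
        raise ValueError("parent counts must be positive")
    return 4.0 * n_males * n_females / (n_males + n_females)


@dataclass(frozen=True)
class NeSegments:
    """Epochs of (n_generations, Ne) plus the numerator for the harmonic mean.

    ``total_generations`` is an explicit input rather than the sum of the
    segment lengths, so published epoch tables can be reproduced as printed.
    """

    segments: tuple[tuple[int, float], ...]
    total_generations: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("at least one segment required")
        for n_g, ne in self.segments:
            if n_g < 1:
                raise ValueError("segment lengths must be >= 1 generation")
            if ne <= 0:
                raise ValueError("segment Ne must be positive")


def harmonic_ne(segments: NeSegments) -> float:
    """Harmonic-mean effective size across epochs:
    total_generations / sum(n_g / Ne_g)."""
    denom = sum(n_g / ne for n_g, ne in segments.segments)
    return float(segments.total_generations / denom)


@dataclass(frozen=True)
class OttoJonesInput:
    """Inputs to the Otto-Jones loci-number projection.

    D: half the phenotypic difference between the parental lines;
    M: mean additive effect of the detected loci; a_min: smallest detected
    additive effect; n_d: number of detected loci.
    """

    D: float
    M: float
    a_min: float
    n_d: int

    def __post_init__(self) -> None:
        if self.n_d < 2:
            raise ValueError("need at least 2 detected loci")
        if self.M <= 0:
            raise ValueError("mean detected effect M must be positive")


@dataclass(frozen=True)
class OttoJonesResult:
    threshold_T: float
    n_loci_raw: float
    n_loci: int


def otto_jones(inp: OttoJonesInput) -> OttoJonesResult:
    """Estimate the total number of loci behind a selected trait.

    Detection threshold T ~= (a_min*n_d - M)/(n_d - 1); loci number
    n = D/(M - T).  ``n_loci`` rounds half away from zero; the raw value is
    retained.  Raises when M <= T (estimator undefined — the detected
    effects leave no room for undetected loci).
    """
    T = (inp.a_min * inp.n_d - inp.M) / (inp.n_d - 1)
    if inp.M <= T:
        raise ValueError(f"estimator undefined: M={inp.M} <= T={T}")
    n_raw = inp.D / (inp.M - T)
    n = int(np.floor(n_raw + 0.5))  # round half away from zero (n_raw > 0)
    return OttoJonesResult(threshold_T=float(T), n_loci_raw=float(n_raw), n_loci=n)


@dataclass(frozen=True)
class DriftAttribution:
    p_diff_drift: float
    expected_drift_fixations: float
    fraction_selection: float


def drift_attribution(
    n_snps: int, p_fix_A: float, p_fix_a: float, observed_diff: int
) -> DriftAttribution:
    """Fraction of alternative-allele fixations attributable to selection.

    Under independent drift in the two lines, a SNP fixes for different
    alleles with probability 2*P_fix(A)*P_fix(a); comparing the expected
    count over ``n_snps`` with the observed count gives the excess
    attributed to selection.
    """
    for p in (p_fix_A, p_fix_a):
        if not 0.0 <= p <= 1.0:
            raise ValueError("fixation probabilities must be in [0, 1]")
    if observed_diff > n_snps:
        raise ValueError("observed_diff cannot exceed n_snps")
    if observed_diff == 0:
        raise ValueError("no observed fixations: attribution undefined")
    p_diff = 2.0 * p_fix_A * p_fix_a
    expected = n_snps * p_diff
    fraction = max(0.0, (observed_diff - expected) / observed_diff)
    return DriftAttribution(
        p_diff_drift=float(p_diff),
        expected_drift_fixations=float(expected),
        fraction_selection=float(fraction),
    )


def uniform_start_expectation(
    per_pair_probs: dict[tuple[int, int], tuple[float, float]],
) -> tuple[float, float]:
    """Expected same-/different-allele fixation fractions under uniform starts.

    ``per_pair_probs`` maps unordered founder-frequency pairs in sevenths —
    (3,4), (2,5), (1,6) — to (P_same, P_diff) from drift simulations.  With
    founder frequencies uniform on multiples of 1/7 the six configurations
    are equally likely and each unordered pair occurs twice, so the
    expectation is the unweighted mean of the three pair values.
    """
    required = {frozenset(p) for p in [(3, 4), (2, 5), (1, 6)]}
    given = {frozenset(k) for k in per_pair_probs}
    if given != required:
        raise ValueError(
            "need probabilities for exactly the pairs (3,4), (2,5), (1,6) in sevenths"
        )
    same = float(np.mean([v[0] for v in per_pair_probs.values()]))
    diff = float(np.mean([v[1] for v in per_pair_probs.values()]))
    return same, diff
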