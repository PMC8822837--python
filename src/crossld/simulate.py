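"""Multinomial simulation of crossbred two-locus data.

A scenario fixes per-line allele frequencies, within-line r^2 and phase,
and a crossbred sample size.  Sampling draws the 4x4 table of ordered
(line-A haplotype, line-B haplotype) counts directly from a 16-category
multinomial with cell probabilities hA_i * hB_j — distributionally
identical to drawing n haplotypes per line and pairing them at random,
but much faster.  The explicit pairing sampler is kept as a slow
reference for equivalence testing.

Seeding: a master seed plus the scenario's position in the grid determine
a per-scenario seed through ``numpy.random.SeedSequence``, so any scenario
can be re-run in isolation and full runs are bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import LDValue, LineHapFreqs, crossbred_true_ld, hap_freqs_from_params
from .estimators import PairCounts, batch_genotype_ld, batch_haplotype_ld

__all__ = [
    "CrossScenario",
    "ReplicateResult",
    "ScenarioRun",
    "GridConfig",
    "DEFAULT_FREQ_LEVELS",
    "DEFAULT_R2_LEVELS",
    "DEFAULT_SAMPLE_SIZES",
    "scenario_seed",
    "build_scenario_grid",
    "sample_crossbred",
    "sample_crossbred_explicit",
    "run_scenario",
]

#: Default grid axes: unordered line-frequency pairs from these levels
#: (equal at both loci within a line), crossed with the r^2 levels and
#: sample sizes — 15 * 4 * 3 = 180 scenarios.
DEFAULT_FREQ_LEVELS = (0.05, 0.15, 0.25, 0.35, 0.45)
DEFAULT_R2_LEVELS = (0.2, 0.4, 0.6, 0.8)
DEFAULT_SAMPLE_SIZES = (900, 1800, 2700)


@dataclass(frozen=True)
class CrossScenario:
    """One simulation scenario for an F1 cross of lines A and B."""

    pM_A: float
    pN_A: float
    pM_B: float
    pN_B: float
    r2_A: float
    r2_B: float
    n: int
    n_reps: int = 1000
    seed: int = 0
    phase_A: int = 1
    phase_B: int = 1

    def __post_init__(self) -> None:
        for name in ("pM_A", "pN_A", "pM_B", "pN_B"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        # fail fast on infeasible (frequency, r2) combinations
        self.line_freqs()

    def line_freqs(self) -> tuple[LineHapFreqs, LineHapFreqs]:
        """Haplotype frequencies implied by each line's parameters."""
        hA = hap_freqs_from_params(self.pM_A, self.pN_A, self.r2_A, self.phase_A)
        hB = hap_freqs_from_params(self.pM_B, self.pN_B, self.r2_B, self.phase_B)
        return hA, hB

    def true_ld(self) -> LDValue:
        """The benchmark: true crossbred LD from the scenario parameters."""
        return crossbred_true_ld(*self.line_freqs())

    def pair_probs(self) -> np.ndarray:
        """4x4 cell probabilities hA_i * hB_j of the ordered haplotype pairs."""
        hA, hB = self.line_freqs()
        return np.outer(hA.as_array(), hB.as_array())


@dataclass(frozen=True)
class ReplicateResult:
    """Both estimates for one simulated replicate."""

    replicate_index: int
    r2_hap: LDValue
    r2_geno: LDValue

    @property
    def defined_both(self) -> bool:
        return self.r2_hap.defined and self.r2_geno.defined


@dataclass(frozen=True)
class ScenarioRun:
    """A scenario together with its benchmark value and replicate results."""

    scenario: CrossScenario
    true_ld: LDValue
    replicates: tuple[ReplicateResult, ...]

    @property
    def n_undefined(self) -> int:
        return sum(not r.defined_both for r in self.replicates)


@dataclass(frozen=True)
class GridConfig:
    """Axes of a scenario grid; defaults reproduce the 180-scenario design."""

    freq_levels: Sequence[float] = DEFAULT_FREQ_LEVELS
    r2_levels: Sequence[float] = DEFAULT_R2_LEVELS
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    n_reps: int = 1000
    master_seed: int = 0
    phase_A: int = 1
    phase_B: int = 1


def scenario_seed(master_seed: int, index: int) -> int:
    """Deterministic per-scenario seed from a master seed and grid position."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def build_scenario_grid(config: GridConfig) -> list[CrossScenario]:
    """Expand a grid config into scenarios.

    Frequency pairs are unordered combinations (with repetition) of the
    levels, assigned to lines A and B; within a line the two loci share the
    frequency, and both lines share the r^2 level.  Infeasible
    (frequency, r^2) combinations raise at build time.
    """
    freq_pairs = list(itertools.combinations_with_replacement(config.freq_levels, 2))
    scenarios = []
    index = 0
    for n in config.sample_sizes:
        for r2 in config.r2_levels:
            for pA, pB in freq_pairs:
                scenarios.append(
                    CrossScenario(
                        pM_A=pA, pN_A=pA, pM_B=pB, pN_B=pB,
                        r2_A=r2, r2_B=r2,
                        phase_A=config.phase_A, phase_B=config.phase_B,
                        n=n, n_reps=config.n_reps,
                        seed=scenario_seed(config.master_seed, index),
                    )
                )
                index += 1
    return scenarios


def sample_crossbred(scn: CrossScenario, rng: np.random.Generator) -> PairCounts:
    """Draw one crossbred sample as a multinomial over the 16 pair categories."""
    counts = rng.multinomial(scn.n, scn.pair_probs().ravel()).reshape(4, 4)
    return PairCounts(counts)


def sample_crossbred_explicit(scn: CrossScenario, rng: np.random.Generator) -> PairCounts:
    """Reference sampler: draw n haplotypes per line, pair them at random.

    Distributionally identical to :func:`sample_crossbred`; kept only to
    validate that shortcut and for demonstration.  O(n) python-level work.
    """
    hA, hB = scn.line_freqs()
    a = rng.choice(4, size=scn.n, p=hA.as_array())
    b = rng.choice(4, size=scn.n, p=hB.as_array())
    b = rng.permutation(b)  # random pairing of the two gamete pools
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return PairCounts(counts)


def run_scenario(scn: CrossScenario) -> ScenarioRun:
    """Run all replicates of a scenario and collect both estimates.

    Replicates where either estimator is undefined (a monomorphic sample
    margin) keep their flagged result; summarization excludes them.  All
    replicates are drawn in one vectorized multinomial call from the
    scenario's own seed.
    """
    rng = np.random.default_rng(scn.seed)
    true_ld = scn.true_ld()
    counts = rng.multinomial(scn.n, scn.pair_probs().ravel(), size=scn.n_reps)
    counts = counts.reshape(scn.n_reps, 4, 4)
    hap = batch_haplotype_ld(counts)
    geno = batch_genotype_ld(counts)
    reps = tuple(
        ReplicateResult(
            replicate_index=i,
            r2_hap=LDValue(hap.r2[i], hap.D[i], hap.Dprime[i], bool(hap.defined[i])),
            r2_geno=LDValue(geno.r2[i], geno.D[i], geno.Dprime[i], bool(geno.defined[i])),
        )
        for i in range(scn.n_reps)
    )
    return ScenarioRun(scenario=scn, true_ld=true_ld, replicates=reps)
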