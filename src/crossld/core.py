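"""Closed-form two-locus linkage disequilibrium for a two-line cross.

Population-level quantities for an F1 produced by random mating between two
parental lines (A and B) at two biallelic loci (M and N):

* crossbred allele frequencies and (negative) inbreeding coefficients,
* haplotype-frequency construction from (allele frequency, r^2, phase),
* true crossbred LD computed two ways — from the per-line haplotype
  covariances, and from unphased genotype-dosage moments — which agree
  exactly under random mating between the lines.

Haplotypes at (M, N) are indexed 00, 01, 10, 11, where the first digit is
the allele at M and the second the allele at N; "allele 1" is the counted
allele throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlleleFreqPair",
    "LineHapFreqs",
    "LDValue",
    "DosageMoments",
    "MonomorphicLocusError",
    "InfeasibleLDError",
    "crossbred_allele_freq",
    "inbreeding_coefficient",
    "inbreeding_coefficient_printed",
    "d_bounds",
    "hap_freqs_from_params",
    "line_ld",
    "crossbred_true_ld",
    "crossbred_genotype_freqs",
    "dosage_moments",
    "crossbred_r2_from_moments",
    "lewontin_dprime",
    "HAP_LABELS",
    "HAP_DOSE_M",
    "HAP_DOSE_N",
]

#: Haplotype labels in index order.
HAP_LABELS = ("00", "01", "10", "11")
#: Allele carried at locus M by haplotype index 0..3.
HAP_DOSE_M = np.array([0, 0, 1, 1])
#: Allele carried at locus N by haplotype index 0..3.
HAP_DOSE_N = np.array([0, 1, 0, 1])

_SUM_TOL = 1e-12
_BOUND_TOL = 1e-9


class MonomorphicLocusError(ValueError):
    """A quantity is undefined because a locus has no variation."""


class InfeasibleLDError(ValueError):
    """Requested LD level is incompatible with the allele frequencies."""

    def __init__(self, message: str, max_r2: float):
        super().__init__(message)
        self.max_r2 = max_r2


def _check_prob(value: float, name: str) -> None:
    if not (-_BOUND_TOL <= value <= 1.0 + _BOUND_TOL):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class AlleleFreqPair:
    """Frequencies of allele 1 at one locus in parental lines A and B."""

    pA: float
    pB: float

    def __post_init__(self) -> None:
        _check_prob(self.pA, "pA")
        _check_prob(self.pB, "pB")


@dataclass(frozen=True)
class LineHapFreqs:
    """The four haplotype frequencies of one parental line at loci (M, N).

    ``f10 + f11`` is the frequency of allele 1 at M, ``f01 + f11`` at N.
    """

    f00: float
    f01: float
    f10: float
    f11: float

    def __post_init__(self) -> None:
        vals = {}
        for name in ("f00", "f01", "f10", "f11"):
            v = getattr(self, name)
            _check_prob(v, name)
            # tolerate float dust from frequency arithmetic, store clamped
            vals[name] = min(1.0, max(0.0, float(v)))
        total = sum(vals.values())
        if abs(total - 1.0) > max(_SUM_TOL, 4 * _BOUND_TOL):
            raise ValueError(f"haplotype frequencies must sum to 1, got {total!r}")
        for name, v in vals.items():
            object.__setattr__(self, name, v)

    @property
    def pM(self) -> float:
        """Frequency of allele 1 at locus M."""
        return self.f10 + self.f11

    @property
    def pN(self) -> float:
        """Frequency of allele 1 at locus N."""
        return self.f01 + self.f11

    def as_array(self) -> np.ndarray:
        return np.array([self.f00, self.f01, self.f10, self.f11])


@dataclass(frozen=True)
class LDValue:
    """A bundle of LD measures; ``defined`` is False at monomorphic loci."""

    r2: float
    D: float
    Dprime: float
    defined: bool = True

    @staticmethod
    def undefined() -> "LDValue":
        return LDValue(r2=math.nan, D=math.nan, Dprime=math.nan, defined=False)


@dataclass(frozen=True)
class DosageMoments:
    """First and second moments of crossbred genotype dosages at M and N."""

    E_Mg: float
    E_Ng: float
    E_Mg2: float
    E_Ng2: float
    E_MgNg: float

    @property
    def var_M(self) -> float:
        return self.E_Mg2 - self.E_Mg**2

    @property
    def var_N(self) -> float:
        return self.E_Ng2 - self.E_Ng**2

    @property
    def cov(self) -> float:
        return self.E_MgNg - self.E_Mg * self.E_Ng


def crossbred_allele_freq(freqs: AlleleFreqPair) -> float:
    """Expected frequency of allele 1 in the F1: the mean of the line frequencies."""
    return (freqs.pA + freqs.pB) / 2.0


def inbreeding_coefficient(freqs: AlleleFreqPair) -> float:
    """Crossbred inbreeding coefficient f at one locus.

    Solves ``pA*pB = p^2 + p(1-p) f`` with ``p = (pA+pB)/2``, i.e.::

        f = -(pA - pB)^2 / ((pA + pB) (2 - pA - pB))

    Always <= 0 (heterozygote excess); 0 iff the lines have equal
    frequencies.  Raises :class:`MonomorphicLocusError` when the crossbred
    locus is monomorphic (pA = pB in {0, 1}).
    """
    p = crossbred_allele_freq(freqs)
    denom = p * (1.0 - p)
    if denom <= 0.0:
        raise MonomorphicLocusError(
            "inbreeding coefficient undefined at a monomorphic crossbred locus"
        )
    return (freqs.pA * freqs.pB - p * p) / denom


def inbreeding_coefficient_printed(freqs: AlleleFreqPair) -> float:
    """Variant of :func:`inbreeding_coefficient` with denominator
    ``(pA + pB)(2 - pA + pB)``.

    Kept separately for reproducing published example values computed with
    this denominator; :func:`inbreeding_coefficient` is the
    derivation-consistent form (the two differ by the sign of pB in the
    second factor).
    """
    denom = (freqs.pA + freqs.pB) * (2.0 - freqs.pA + freqs.pB)
    if denom == 0.0:
        raise MonomorphicLocusError("zero denominator in printed-form inbreeding coefficient")
    return -((freqs.pA - freqs.pB) ** 2) / denom


def d_bounds(pM: float, pN: float) -> tuple[float, float]:
    """Feasible range (Dmin, Dmax) of the gametic covariance D.

    Standard feasibility bounds given allele frequencies: all four haplotype
    frequencies must stay non-negative.
    """
    _check_prob(pM, "pM")
    _check_prob(pN, "pN")
    if pM in (0.0, 1.0) or pN in (0.0, 1.0):
        raise MonomorphicLocusError("D bounds undefined at a monomorphic locus")
    qM, qN = 1.0 - pM, 1.0 - pN
    dmin = -min(pM * pN, qM * qN)
    dmax = min(pM * qN, qM * pN)
    return dmin, dmax


def _normalize_phase(phase) -> int:
    if phase in (1, +1, "+", "coupling"):
        return 1
    if phase in (-1, "-", "repulsion"):
        return -1
    raise ValueError(f"phase must be +1/-1 (or '+'/'-'), got {phase!r}")


def hap_freqs_from_params(pM: float, pN: float, r2: float, phase=1) -> LineHapFreqs:
    """Build haplotype frequencies from allele frequencies, r^2 and phase sign.

    D = phase * sqrt(r2 * pM(1-pM) pN(1-pN)); the result round-trips through
    :func:`line_ld` to the input r2.  Raises :class:`InfeasibleLDError`
    (carrying the admissible maximum r2) when D falls outside the feasible
    range for these frequencies.
    """
    sign = _normalize_phase(phase)
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2!r}")
    dmin, dmax = d_bounds(pM, pN)
    qM, qN = 1.0 - pM, 1.0 - pN
    varprod = pM * qM * pN * qN
    D = sign * math.sqrt(r2 * varprod)
    limit = dmax if sign > 0 else -dmin
    if abs(D) > limit + _SUM_TOL:
        max_r2 = limit**2 / varprod
        raise InfeasibleLDError(
            f"r2={r2} with phase {sign:+d} is infeasible for pM={pM}, pN={pN}; "
            f"maximum attainable r2 is {max_r2:.6g}",
            max_r2=max_r2,
        )
    return LineHapFreqs(
        f00=qM * qN + D,
        f01=qM * pN - D,
        f10=pM * qN - D,
        f11=pM * pN + D,
    )


def lewontin_dprime(D: float, pM: float, pN: float) -> float:
    """D normalized by its frequency-constrained extreme (D/Dmax for D >= 0,
    D/|Dmin| otherwise)."""
    if D == 0.0:
        return 0.0
    dmin, dmax = d_bounds(pM, pN)
    return D / dmax if D > 0 else D / abs(dmin)


def line_ld(h: LineHapFreqs) -> LDValue:
    """Within-line LD: D = f11 - pM*pN, r^2 = D^2 / (pM qM pN qN), Lewontin D'."""
    pM, pN = h.pM, h.pN
    D = h.f11 - pM * pN
    varprod = pM * (1.0 - pM) * pN * (1.0 - pN)
    if varprod <= 0.0:
        return LDValue.undefined()
    return LDValue(r2=D * D / varprod, D=D, Dprime=lewontin_dprime(D, pM, pN))


def crossbred_true_ld(hA: LineHapFreqs, hB: LineHapFreqs) -> LDValue:
    """True crossbred r^2 via the haplotype route.

    The numerator is the square of the average of the two per-line gametic
    covariances; the denominator is the product, over loci, of the average
    per-line binomial variances p(1-p).  (The factors of 2 cancel, so sums
    are used directly.)  D is the average covariance; D' uses the crossbred
    mean allele frequencies.
    """
    D_A = hA.f11 - hA.pM * hA.pN
    D_B = hB.f11 - hB.pM * hB.pN
    varM = hA.pM * (1.0 - hA.pM) + hB.pM * (1.0 - hB.pM)
    varN = hA.pN * (1.0 - hA.pN) + hB.pN * (1.0 - hB.pN)
    denom = varM * varN
    if denom <= 0.0:
        return LDValue.undefined()
    D_cross = (D_A + D_B) / 2.0
    r2 = (D_A + D_B) ** 2 / denom
    pM = (hA.pM + hB.pM) / 2.0
    pN = (hA.pN + hB.pN) / 2.0
    return LDValue(r2=r2, D=D_cross, Dprime=lewontin_dprime(D_cross, pM, pN))


def crossbred_genotype_freqs(hA: LineHapFreqs, hB: LineHapFreqs) -> np.ndarray:
    """4x4 joint distribution of (line-A haplotype, line-B haplotype) pairs.

    Under random mating between the lines the cell (i, j) probability is the
    product of the two marginal haplotype frequencies; rows marginalize to
    ``hA`` and columns to ``hB``.
    """
    return np.outer(hA.as_array(), hB.as_array())


def dosage_moments(hA: LineHapFreqs, hB: LineHapFreqs) -> DosageMoments:
    """Expected crossbred dosage moments in closed form.

    With per-line allele-1 frequencies pM = f10+f11 and pN = f01+f11:

    * E(Mg)    = pM_A + pM_B
    * E(Mg^2)  = pM_A + pM_B + 2 pM_A pM_B          (and likewise at N)
    * E(Mg Ng) = f11_B (1 + pM_A) + f11_A (1 + pM_B)
                 + f01_B pM_A + f01_A pM_B
    """
    tA, tB = hA.pM, hB.pM  # allele-1 frequency at M per line
    sA, sB = hA.pN, hB.pN  # allele-1 frequency at N per line
    return DosageMoments(
        E_Mg=tA + tB,
        E_Ng=sA + sB,
        E_Mg2=tA + tB + 2.0 * tA * tB,
        E_Ng2=sA + sB + 2.0 * sA * sB,
        E_MgNg=(
            hB.f11 * (1.0 + tA)
            + hA.f11 * (1.0 + tB)
            + hB.f01 * tA
            + hA.f01 * tB
        ),
    )


def crossbred_r2_from_moments(m: DosageMoments) -> LDValue:
    """Crossbred LD via the genotype-dosage route: r^2 = cov^2/(varM varN).

    Identical to :func:`crossbred_true_ld` for moments derived from any
    valid pair of line haplotype frequencies.  D is reported on the gametic
    scale (half the dosage covariance); D' uses allele frequencies E(g)/2.
    """
    varM, varN = m.var_M, m.var_N
    if varM <= 0.0 or varN <= 0.0:
        return LDValue.undefined()
    cov = m.cov
    r2 = cov * cov / (varM * varN)
    D = cov / 2.0
    return LDValue(r2=r2, D=D, Dprime=lewontin_dprime(D, m.E_Mg / 2.0, m.E_Ng / 2.0))
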