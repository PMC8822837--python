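"""Sample-based LD estimators for a crossbred dataset.

Two routes:

* haplotype route — plug the per-line sample haplotype frequencies into the
  crossbred formula (per-line plug-in; a pooled variant is available but
  estimates a different target when line frequencies differ);
* genotype route — squared Pearson correlation between unphased genotype
  dosages at the two loci.

The sufficient statistic for both is a 4x4 table of (line-A haplotype,
line-B haplotype) counts; collapsing it to a 3x3 dosage table merges the
coupling (00/11) and repulsion (01/10) double heterozygotes, which is the
only information the genotype route loses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import (
    HAP_DOSE_M,
    HAP_DOSE_N,
    LDValue,
    LineHapFreqs,
    crossbred_true_ld,
    lewontin_dprime,
    line_ld,
)

__all__ = [
    "PairCounts",
    "DosageSample",
    "EmptySampleError",
    "pair_counts_to_dosage",
    "estimate_ld_haplotype",
    "estimate_ld_genotype",
    "BatchLD",
    "batch_haplotype_ld",
    "batch_genotype_ld",
]

# Dosage contributed at (M, N) by each ordered (hapA, hapB) cell, flattened
# row-major over the 4x4 table.
_CELL_DOSE_M = (HAP_DOSE_M[:, None] + HAP_DOSE_M[None, :]).ravel()
_CELL_DOSE_N = (HAP_DOSE_N[:, None] + HAP_DOSE_N[None, :]).ravel()


class EmptySampleError(ValueError):
    """Estimation was attempted on an empty sample."""


@dataclass(frozen=True)
class PairCounts:
    """4x4 counts of ordered (line-A haplotype, line-B haplotype) pairs.

    Rows index the line-A haplotype (00, 01, 10, 11), columns the line-B
    haplotype; row margins are the line-A haplotype counts, column margins
    the line-B counts.  One count per crossbred individual.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (4, 4):
            raise ValueError(f"counts must be 4x4, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("counts must be integers")
            arr = rounded.astype(np.int64)
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def line_a_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def line_b_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def line_freqs(self, line: str) -> LineHapFreqs:
        """Sample haplotype frequencies for one parental line ('A' or 'B')."""
        if self.n == 0:
            raise EmptySampleError("no individuals in sample")
        margin = {"A": self.line_a_counts, "B": self.line_b_counts}[line]
        f = margin / self.n
        return LineHapFreqs(*f)


@dataclass(frozen=True)
class DosageSample:
    """3x3 counts of unphased genotype-dosage pairs (dosage at M, dosage at N)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, pairs) -> "DosageSample":
        """Build from an iterable of per-individual (dosage_M, dosage_N) pairs."""
        counts = np.zeros((3, 3), dtype=np.int64)
        for m, g in pairs:
            m, g = int(m), int(g)
            if not (0 <= m <= 2 and 0 <= g <= 2):
                raise ValueError(f"dosages must be in {{0,1,2}}, got ({m}, {g})")
            counts[m, g] += 1
        return cls(counts)


def pair_counts_to_dosage(pc: PairCounts) -> DosageSample:
    """Collapse ordered haplotype-pair counts to unphased dosage counts.

    The (1, 1) dosage cell pools the coupling (00/11) and repulsion (01/10)
    double-heterozygote configurations — the phase information lost by the
    genotype route.
    """
    dosage = np.zeros((3, 3), dtype=np.int64)
    flat = pc.counts.ravel()
    np.add.at(dosage, (_CELL_DOSE_M, _CELL_DOSE_N), flat)
    return DosageSample(dosage)


def estimate_ld_haplotype(pc: PairCounts, pooled: bool = False) -> LDValue:
    """Haplotype-route estimate of crossbred LD.

    Default: per-line plug-in — sample haplotype frequencies of each line
    are inserted into the crossbred haplotype formula, so counts exactly
    proportional to the population cell probabilities recover the true
    value.  With ``pooled=True`` the 2n haplotypes of both lines are pooled
    before computing within-"population" LD; this adds a between-line
    covariance term and targets the pooled-gamete LD instead.
    """
    if pc.n == 0:
        raise EmptySampleError("no individuals in sample")
    if pooled:
        f = (pc.line_a_counts + pc.line_b_counts) / (2 * pc.n)
        return line_ld(LineHapFreqs(*f))
    return crossbred_true_ld(pc.line_freqs("A"), pc.line_freqs("B"))


def estimate_ld_genotype(ds: DosageSample) -> LDValue:
    """Genotype-route estimate: squared sample Pearson correlation of dosages.

    Moments use the divide-by-n convention (r^2 is invariant to n vs n-1).
    D is the dosage covariance on the gametic scale (cov/2); D' uses the
    sample allele frequencies mean(dosage)/2.
    """
    n = ds.n
    if n == 0:
        raise EmptySampleError("no individuals in sample")
    dm = np.arange(3, dtype=float)
    w = ds.counts / n
    pm_marg = w.sum(axis=1)
    pn_marg = w.sum(axis=0)
    E_m = pm_marg @ dm
    E_n = pn_marg @ dm
    var_m = pm_marg @ dm**2 - E_m**2
    var_n = pn_marg @ dm**2 - E_n**2
    if var_m <= 0.0 or var_n <= 0.0:
        return LDValue.undefined()
    cov = np.einsum("ij,i,j->", w, dm, dm) - E_m * E_n
    D = cov / 2.0
    return LDValue(
        r2=cov * cov / (var_m * var_n),
        D=D,
        Dprime=lewontin_dprime(D, E_m / 2.0, E_n / 2.0),
    )


class BatchLD(NamedTuple):
    """Vectorized LD estimates over a stack of replicate count tables."""

    r2: np.ndarray
    D: np.ndarray
    Dprime: np.ndarray
    defined: np.ndarray


def _batch_dprime(D: np.ndarray, pM: np.ndarray, pN: np.ndarray) -> np.ndarray:
    qM, qN = 1.0 - pM, 1.0 - pN
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax = np.minimum(pM * qN, qM * pN)
        dmin = np.minimum(pM * pN, qM * qN)
        out = np.where(D >= 0, D / dmax, D / dmin)
    return np.where(D == 0.0, 0.0, out)


def batch_haplotype_ld(counts: np.ndarray) -> BatchLD:
    """Per-line plug-in estimates for a stack of 4x4 count tables.

    ``counts`` has shape (k, 4, 4); matches :func:`estimate_ld_haplotype`
    applied row-wise, but vectorized for simulation use.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(1, 2))
    hA = counts.sum(axis=2) / n[:, None]
    hB = counts.sum(axis=1) / n[:, None]
    pM_A = hA @ HAP_DOSE_M
    pN_A = hA @ HAP_DOSE_N
    pM_B = hB @ HAP_DOSE_M
    pN_B = hB @ HAP_DOSE_N
    D_A = hA[:, 3] - pM_A * pN_A
    D_B = hB[:, 3] - pM_B * pN_B
    varM = pM_A * (1 - pM_A) + pM_B * (1 - pM_B)
    varN = pN_A * (1 - pN_A) + pN_B * (1 - pN_B)
    denom = varM * varN
    defined = denom > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(defined, (D_A + D_B) ** 2 / denom, np.nan)
    D = (D_A + D_B) / 2.0
    Dp = _batch_dprime(D, (pM_A + pM_B) / 2.0, (pN_A + pN_B) / 2.0)
    return BatchLD(r2=r2, D=np.where(defined, D, np.nan),
                   Dprime=np.where(defined, Dp, np.nan), defined=defined)


def batch_genotype_ld(counts: np.ndarray) -> BatchLD:
    """Dosage-correlation estimates for a stack of 4x4 count tables.

    Equivalent to ``estimate_ld_genotype(pair_counts_to_dosage(...))`` per
    table; the dosage collapse happens implicitly through the per-cell
    dosage vectors.
    """
    counts = np.asarray(counts, dtype=float)
    flat = counts.reshape(counts.shape[0], 16)
    n = flat.sum(axis=1)
    w = flat / n[:, None]
    E_m = w @ _CELL_DOSE_M
    E_n = w @ _CELL_DOSE_N
    var_m = w @ _CELL_DOSE_M**2 - E_m**2
    var_n = w @ _CELL_DOSE_N**2 - E_n**2
    cov = w @ (_CELL_DOSE_M * _CELL_DOSE_N) - E_m * E_n
    defined = (var_m > 0.0) & (var_n > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(defined, cov**2 / (var_m * var_n), np.nan)
    D = cov / 2.0
    Dp = _batch_dprime(D, E_m / 2.0, E_n / 2.0)
    return BatchLD(r2=r2, D=np.where(defined, D, np.nan),
                   Dprime=np.where(defined, Dp, np.nan), defined=defined)
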