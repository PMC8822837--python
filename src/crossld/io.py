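"""File readers/writers and run configuration.

Formats:

* haplotype TSV — columns ``individual_id, line, allele_M, allele_N``;
  exactly two rows per individual, one for each parental line;
* genotype TSV — columns ``individual_id, dosage_M, dosage_N`` with
  dosages in {0, 1, 2};
* two-site VCF — phased GT plus a line map yields haplotype pair counts,
  unphased GT yields dosages only;
* fixture writer — emits all of the above for one sampled replicate of a
  scenario, plus a truth JSON with the scenario parameters and true LD.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import HAP_DOSE_M, HAP_DOSE_N
from .estimators import DosageSample, PairCounts
from .simulate import (
    DEFAULT_FREQ_LEVELS,
    DEFAULT_R2_LEVELS,
    DEFAULT_SAMPLE_SIZES,
    CrossScenario,
    GridConfig,
    sample_crossbred,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "read_haplotype_table",
    "read_genotype_table",
    "read_line_map",
    "read_vcf_pair",
    "write_fixture",
]

log = logging.getLogger("crossld")

_HAP_INDEX = {"00": 0, "01": 1, "10": 2, "11": 3}


class ParseError(ValueError):
    """Malformed input file; message includes the offending line number."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a simulation run (YAML or JSON).

    Unknown keys are rejected so silent typos cannot change a run.
    """

    freq_levels: Sequence[float] = DEFAULT_FREQ_LEVELS
    r2_levels: Sequence[float] = DEFAULT_R2_LEVELS
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    n_reps: int = 1000
    seed: int = 0
    phase_A: int = 1
    phase_B: int = 1
    keep_replicates: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_levels", tuple(float(x) for x in self.freq_levels))
        object.__setattr__(self, "r2_levels", tuple(float(x) for x in self.r2_levels))
        object.__setattr__(self, "sample_sizes", tuple(int(x) for x in self.sample_sizes))
        if not self.freq_levels or not self.r2_levels or not self.sample_sizes:
            raise ValueError("freq_levels, r2_levels and sample_sizes must be non-empty")
        for p in self.freq_levels:
            if not 0.0 < p < 1.0:
                raise ValueError(f"frequency level {p} outside (0, 1)")
        for r2 in self.r2_levels:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 level {r2} outside [0, 1]")
        for n in self.sample_sizes:
            if n < 2:
                raise ValueError(f"sample size {n} must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {
            "freq_levels": list(self.freq_levels),
            "r2_levels": list(self.r2_levels),
            "sample_sizes": list(self.sample_sizes),
            "n_reps": self.n_reps,
            "seed": self.seed,
            "phase_A": self.phase_A,
            "phase_B": self.phase_B,
            "keep_replicates": self.keep_replicates,
        }

    def grid_config(self) -> GridConfig:
        return GridConfig(
            freq_levels=self.freq_levels,
            r2_levels=self.r2_levels,
            sample_sizes=self.sample_sizes,
            n_reps=self.n_reps,
            master_seed=self.seed,
            phase_A=self.phase_A,
            phase_B=self.phase_B,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_mapping(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TSV readers

def _read_tsv_rows(path, required_cols):
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise ParseError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in required_cols if c not in header]
        if missing:
            raise ParseError(f"{path}:1: missing required columns {missing}")
        idx = {c: header.index(c) for c in required_cols}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            yield lineno, {c: fields[idx[c]] for c in required_cols}


def read_haplotype_table(path) -> PairCounts:
    """Read a phased haplotype TSV into pair counts.

    Each individual must contribute exactly one line-A and one line-B row;
    alleles must be 0/1.  Errors name the offending line.
    """
    per_ind: dict[str, dict[str, int]] = {}
    for lineno, row in _read_tsv_rows(path, ("individual_id", "line", "allele_M", "allele_N")):
        line = row["line"]
        if line not in ("A", "B"):
            raise ParseError(f"{path}:{lineno}: line must be 'A' or 'B', got {line!r}")
        alleles = row["allele_M"] + row["allele_N"]
        if alleles not in _HAP_INDEX:
            raise ParseError(
                f"{path}:{lineno}: alleles must be 0/1, got "
                f"({row['allele_M']!r}, {row['allele_N']!r})"
            )
        ind = per_ind.setdefault(row["individual_id"], {})
        if line in ind:
            raise ParseError(
                f"{path}:{lineno}: duplicate line-{line} haplotype for "
                f"individual {row['individual_id']!r}"
            )
        ind[line] = _HAP_INDEX[alleles]
    counts = np.zeros((4, 4), dtype=np.int64)
    for ind_id, haps in per_ind.items():
        if set(haps) != {"A", "B"}:
            raise ParseError(
                f"{path}: individual {ind_id!r} is missing its "
                f"line-{({'A', 'B'} - set(haps)).pop()} haplotype"
            )
        counts[haps["A"], haps["B"]] += 1
    return PairCounts(counts)


def read_genotype_table(path) -> DosageSample:
    """Read an unphased genotype-dosage TSV (dosages 0/1/2, one row per individual)."""
    counts = np.zeros((3, 3), dtype=np.int64)
    seen = set()
    for lineno, row in _read_tsv_rows(path, ("individual_id", "dosage_M", "dosage_N")):
        if row["individual_id"] in seen:
            raise ParseError(f"{path}:{lineno}: duplicate individual {row['individual_id']!r}")
        seen.add(row["individual_id"])
        try:
            m, n = int(row["dosage_M"]), int(row["dosage_N"])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: dosages must be integers") from None
        if not (0 <= m <= 2 and 0 <= n <= 2):
            raise ParseError(f"{path}:{lineno}: dosages must be in {{0,1,2}}, got ({m}, {n})")
        counts[m, n] += 1
    return DosageSample(counts)


def read_line_map(path) -> dict[str, tuple[str, str]]:
    """Read a line map: for each individual, the parental line of GT haplotypes 1 and 2."""
    mapping: dict[str, tuple[str, str]] = {}
    for lineno, row in _read_tsv_rows(path, ("individual_id", "hap1_line", "hap2_line")):
        h1, h2 = row["hap1_line"], row["hap2_line"]
        if {h1, h2} != {"A", "B"}:
            raise ParseError(
                f"{path}:{lineno}: each individual needs one 'A' and one 'B' haplotype, "
                f"got ({h1!r}, {h2!r})"
            )
        if row["individual_id"] in mapping:
            raise ParseError(f"{path}:{lineno}: duplicate individual {row['individual_id']!r}")
        mapping[row["individual_id"]] = (h1, h2)
    return mapping


# ---------------------------------------------------------------------------
# VCF

def _parse_locus(spec: str) -> tuple[str, int]:
    chrom, _, pos = spec.rpartition(":")
    if not chrom:
        raise ValueError(f"locus must be 'chrom:pos', got {spec!r}")
    return chrom, int(pos)


def _fetch_site(vcf_path: str, chrom: str, pos: int):
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    found = None
    for variant in vcf:
        if variant.CHROM == chrom and variant.POS == pos:
            found = variant
            break
    if found is None:
        raise ValueError(f"site {chrom}:{pos} not found in {vcf_path}")
    if len(found.ALT) != 1:
        raise ValueError(f"site {chrom}:{pos} is not biallelic (ALT={found.ALT})")
    gts = []
    for sample, gt in zip(samples, found.genotypes):
        a, b, phased = int(gt[0]), int(gt[1]), bool(gt[2])
        if a < 0 or b < 0:
            raise ValueError(f"missing GT for sample {sample!r} at {chrom}:{pos}")
        if a > 1 or b > 1:
            raise ValueError(f"non-biallelic allele index for {sample!r} at {chrom}:{pos}")
        gts.append((a, b, phased))
    return samples, gts


def read_vcf_pair(path, locus_m: str, locus_n: str, line_map=None):
    """Read two biallelic sites from a VCF.

    Fully phased GTs plus a line map (individual -> parental line of each
    haplotype) give a :class:`PairCounts`; unphased or mixed-phase data give
    a :class:`DosageSample` (with a warning when phase is mixed).  Phased
    data without a line map is an error: the parental origin of each
    haplotype cannot be inferred from the VCF alone.
    """
    if isinstance(line_map, (str, Path)):
        line_map = read_line_map(line_map)
    samples_m, gt_m = _fetch_site(path, *_parse_locus(locus_m))
    samples_n, gt_n = _fetch_site(path, *_parse_locus(locus_n))
    if samples_m != samples_n:
        raise ValueError("inconsistent sample ordering between sites")
    phased_flags = [pm and pn for (_, _, pm), (_, _, pn) in zip(gt_m, gt_n)]
    if all(phased_flags):
        if line_map is None:
            raise ValueError(
                "phased VCF requires a line map giving the parental line of each haplotype"
            )
        counts = np.zeros((4, 4), dtype=np.int64)
        for sample, (am1, am2, _), (an1, an2, _) in zip(samples_m, gt_m, gt_n):
            if sample not in line_map:
                raise ValueError(f"sample {sample!r} missing from line map")
            haps = {
                line_map[sample][0]: 2 * am1 + an1,
                line_map[sample][1]: 2 * am2 + an2,
            }
            counts[haps["A"], haps["B"]] += 1
        return PairCounts(counts)
    if any(phased_flags):
        warnings.warn(
            "mixed phased/unphased genotypes; falling back to dosages", stacklevel=2
        )
    return DosageSample.from_pairs(
        (am1 + am2, an1 + an2)
        for (am1, am2, _), (an1, an2, _) in zip(gt_m, gt_n)
    )


# ---------------------------------------------------------------------------
# fixture writer

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_fixture(
    scn: CrossScenario,
    outdir,
    prefix: str = "fixture",
    chrom: str = "1",
    pos_m: int = 1000,
    pos_n: int = 2000,
) -> dict[str, Path]:
    """Write one sampled replicate of a scenario as test/demo files.

    Emits ``<prefix>.haplotypes.tsv``, ``<prefix>.genotypes.tsv``,
    ``<prefix>.vcf`` (phased), ``<prefix>.linemap.tsv`` and
    ``<prefix>.truth.json``; byte-identical on re-run for a fixed scenario
    seed.  Returns a dict of the written paths.
    """
    from .estimators import pair_counts_to_dosage  # local to avoid cycle noise

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scn.seed)
    pc = sample_crossbred(scn, rng)

    # expand counts into per-individual records (deterministic order)
    individuals = []
    for i in range(4):
        for j in range(4):
            individuals.extend([(i, j)] * pc.counts[i, j])

    paths = {}
    hap_path = outdir / f"{prefix}.haplotypes.tsv"
    with hap_path.open("w") as fh:
        fh.write("individual_id\tline\tallele_M\tallele_N\n")
        for k, (i, j) in enumerate(individuals):
            ind = f"ind{k:05d}"
            fh.write(f"{ind}\tA\t{HAP_DOSE_M[i]}\t{HAP_DOSE_N[i]}\n")
            fh.write(f"{ind}\tB\t{HAP_DOSE_M[j]}\t{HAP_DOSE_N[j]}\n")
    paths["haplotypes"] = hap_path

    geno_path = outdir / f"{prefix}.genotypes.tsv"
    with geno_path.open("w") as fh:
        fh.write("individual_id\tdosage_M\tdosage_N\n")
        for k, (i, j) in enumerate(individuals):
            fh.write(
                f"ind{k:05d}\t{HAP_DOSE_M[i] + HAP_DOSE_M[j]}"
                f"\t{HAP_DOSE_N[i] + HAP_DOSE_N[j]}\n"
            )
    paths["genotypes"] = geno_path

    vcf_path = outdir / f"{prefix}.vcf"
    names = [f"ind{k:05d}" for k in range(len(individuals))]
    with vcf_path.open("w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=max(pos_m, pos_n) + 1000))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        # haplotype 1 in the GT is the line-A gamete, haplotype 2 line-B
        gts_m = "\t".join(f"{HAP_DOSE_M[i]}|{HAP_DOSE_M[j]}" for i, j in individuals)
        gts_n = "\t".join(f"{HAP_DOSE_N[i]}|{HAP_DOSE_N[j]}" for i, j in individuals)
        fh.write(f"{chrom}\t{pos_m}\tlocus_M\tA\tC\t.\tPASS\t.\tGT\t{gts_m}\n")
        fh.write(f"{chrom}\t{pos_n}\tlocus_N\tG\tT\t.\tPASS\t.\tGT\t{gts_n}\n")
    paths["vcf"] = vcf_path

    linemap_path = outdir / f"{prefix}.linemap.tsv"
    with linemap_path.open("w") as fh:
        fh.write("individual_id\thap1_line\thap2_line\n")
        for name in names:
            fh.write(f"{name}\tA\tB\n")
    paths["linemap"] = linemap_path

    truth = {
        "scenario": {
            "pM_A": scn.pM_A, "pN_A": scn.pN_A,
            "pM_B": scn.pM_B, "pN_B": scn.pN_B,
            "r2_A": scn.r2_A, "r2_B": scn.r2_B,
            "phase_A": scn.phase_A, "phase_B": scn.phase_B,
            "n": scn.n, "seed": scn.seed,
        },
        "true_r2": scn.true_ld().r2,
        "true_D": scn.true_ld().D,
        "true_Dprime": scn.true_ld().Dprime,
        "sampled_dosage_counts": pair_counts_to_dosage(pc).counts.tolist(),
    }
    truth_path = outdir / f"{prefix}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths
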