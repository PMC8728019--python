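"""Synthetic haplotype-block genotype panels with known ground truth.

The generator emulates the block structure that LD-based tag-SNP design
exploits: each chromosome is a sequence of haplotype blocks, each block a
small number of founder haplotypes in perfect internal LD (no intra-block
recombination), with blocks independent of one another. Every sample draws
two founder haplotypes per block (diploid), so with two founders per block
every polymorphic intra-block SNP pair has r² = 1 in the absence of noise.

Noise layers, applied after the clean matrix is built:

* random missingness at ``missing_rate``,
* heterozygote-call errors at ``het_error_rate`` — a random homozygote is
  flipped to dosage 1, mimicking the error mode typical of exome-capture
  heterozygous calls,
* optional per-allele mutation at ``mutation_rate``, which decorrelates
  intra-block LD.

Probe annotations (design score, alignment hit counts, underlying
polymorphism, Type-I allele pairs) are drawn independently of the
genotypes at configurable per-filter failure rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from tagarray.genodata import MISSING, GenotypeMatrix, SNPRecord, annotate_from_calls

#: default per-filter probe failure probabilities
PROBE_FAIL_DEFAULTS: dict[str, float] = {
    "type_I": 0.08,
    "low_score": 0.15,
    "multi_hit": 0.10,
    "other_genome_hit": 0.05,
    "underlying_poly": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Panel-simulation parameters.

    ``maf_spectrum`` is the Dirichlet concentration over founder-haplotype
    frequencies within a block: values < 1 skew frequencies toward the
    extremes, giving the U-shaped folded MAF spectrum typical of diverse
    resequencing panels; 1.0 gives a flat spectrum. ``founder_haplotypes``
    and the other range fields are inclusive (lo, hi) ranges sampled per
    block.
    """

    n_samples: int = 200
    n_chromosomes: int = 5
    blocks_per_chromosome: int = 10
    snps_per_block: tuple[int, int] = (5, 40)
    founder_haplotypes: tuple[int, int] = (2, 2)
    block_span_bp: tuple[int, int] = (50_000, 400_000)
    inter_block_gap_bp: int = 100_000
    maf_spectrum: float = 0.5
    missing_rate: float = 0.05
    het_error_rate: float = 0.0
    mutation_rate: float = 0.0
    probe_fail_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(PROBE_FAIL_DEFAULTS)
    )
    species: str = "wheat"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_error_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("snps_per_block", "founder_haplotypes", "block_span_bp"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range ({lo}, {hi}) invalid")
        if self.founder_haplotypes[0] < 2:
            raise ValueError("need >= 2 founder haplotypes per block")
        for k, v in self.probe_fail_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probe_fail_rates[{k}]={v} outside [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    block_of_snp: dict[str, str]
    founder_patterns: dict[str, np.ndarray]      # block id -> (n_founders, n_snps)
    founder_assignment: dict[str, np.ndarray]    # block id -> (n_samples, 2)
    clean_calls: np.ndarray                      # error-free dosage matrix


def _draw_probe(rng: np.random.Generator, rates: Mapping[str, float]):
    """Probe metadata for one SNP; failure modes drawn independently."""
    if rng.random() < rates.get("type_I", 0.0):
        ref, alt = ("A", "T") if rng.random() < 0.5 else ("C", "G")
    else:
        ref, alt = rng.choice(["A", "C", "G", "T"]), None
        others = {"A": "G", "C": "T", "G": "A", "T": "C"}
        alt = others[ref]
    if rng.random() < rates.get("low_score", 0.0):
        score = float(rng.uniform(0.0, 0.6))
    else:
        score = float(rng.uniform(0.6, 1.0))
    if rng.random() < rates.get("multi_hit", 0.0):
        hits_target = int(rng.integers(2, 5))    # 2-4: some rescue-able, some not
    else:
        hits_target = 1
    hits_other = 1 if rng.random() < rates.get("other_genome_hit", 0.0) else 0
    underlying = bool(rng.random() < rates.get("underlying_poly", 0.0))
    return ref, alt, round(score, 3), hits_target, hits_other, underlying


def simulate_panel(
    config: SimConfig | None = None,
) -> tuple[GenotypeMatrix, list[SNPRecord], SimTruth]:
    """Simulate a haplotype-block panel with probe annotations and truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    snp_ids: list[str] = []
    records: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    truth = SimTruth({}, {}, {}, np.empty(0))

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = 1
        for b in range(config.blocks_per_chromosome):
            block_id = f"{chrom}_b{b:02d}"
            k_snps = int(rng.integers(config.snps_per_block[0],
                                      config.snps_per_block[1] + 1))
            n_founders = int(rng.integers(config.founder_haplotypes[0],
                                          config.founder_haplotypes[1] + 1))
            span = int(rng.integers(config.block_span_bp[0],
                                    config.block_span_bp[1] + 1))

            # founder haplotypes: binary allele patterns, each SNP polymorphic
            # across founders (so block frequency drives SNP MAF)
            patterns = np.zeros((n_founders, k_snps), dtype=np.int8)
            for j in range(k_snps):
                while True:
                    col = rng.integers(0, 2, size=n_founders)
                    if 0 < col.sum() < n_founders:
                        break
                patterns[:, j] = col

            # founder frequencies from a symmetric Dirichlet: small
            # concentration -> U-shaped folded MAF spectrum
            freqs = rng.dirichlet(np.full(n_founders, config.maf_spectrum))
            assignment = rng.choice(n_founders, size=(config.n_samples, 2), p=freqs)

            haps = patterns[assignment]              # (n_samples, 2, k_snps)
            if config.mutation_rate > 0:
                flips = rng.random(haps.shape) < config.mutation_rate
                haps = np.where(flips, 1 - haps, haps)
            block_calls = haps.sum(axis=1).astype(np.int8)

            positions = np.sort(rng.choice(np.arange(span), size=k_snps,
                                           replace=False)) + cursor
            cursor += span + config.inter_block_gap_bp

            for j in range(k_snps):
                snp_id = f"{block_id}_s{j:03d}"
                ref, alt, score, h_t, h_o, upoly = _draw_probe(
                    rng, config.probe_fail_rates
                )
                snp_ids.append(snp_id)
                records.append(
                    SNPRecord(
                        snp_id=snp_id, chromosome=chrom, position=int(positions[j]),
                        ref_allele=ref, alt_allele=alt, design_score=score,
                        hits_target_genome=h_t, hits_other_genome=h_o,
                        underlying_polymorphism=upoly, species=config.species,
                    )
                )
                truth.block_of_snp[snp_id] = block_id
                columns.append(block_calls[:, j])
            truth.founder_patterns[block_id] = patterns
            truth.founder_assignment[block_id] = assignment

    calls = np.stack(columns, axis=1)
    truth.clean_calls = calls.copy()

    # noise layers: het errors on homozygotes, then missingness
    if config.het_error_rate > 0:
        hom = calls != 1
        flip = hom & (rng.random(calls.shape) < config.het_error_rate)
        calls = np.where(flip, 1, calls).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)

    panel = GenotypeMatrix(sample_ids, snp_ids, calls)
    return panel, annotate_from_calls(panel, records), truth


# ---------------------------------------------------------------------------
# Deterministic toy instances for documentation and tests
# ---------------------------------------------------------------------------

TOY_NAMES = ("three_snp_chain", "all_singletons", "two_blocks")


def make_toy_instance(name: str) -> tuple[GenotypeMatrix, list[SNPRecord]]:
    """Hand-sized deterministic instances.

    * ``three_snp_chain`` — 40 samples, 3 SNPs A/B/C close together where
      r²(A,B) and r²(A,C) exceed 0.9 but r²(B,C) does not, so at q = 0.9
      the tag sets are T(A) = {A,B,C}, T(B) = {A,B}, T(C) = {A,C}.
    * ``all_singletons`` — 3 mutually uncorrelated SNPs: every tag set is a
      singleton and selection at any m >= 2 is empty.
    * ``two_blocks`` — two disjoint 3-SNP blocks in perfect internal LD.
    """
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy instance {name!r}; choose from {TOY_NAMES}")

    def rec(snp_id, pos, chrom="chr1"):
        return SNPRecord(snp_id=snp_id, chromosome=chrom, position=pos,
                         ref_allele="A", alt_allele="G", design_score=0.9,
                         hits_target_genome=1, hits_other_genome=0,
                         underlying_polymorphism=False)

    if name == "three_snp_chain":
        n = 40
        base = np.array([0] * 20 + [2] * 20, dtype=np.int8)
        a = base.copy()
        b = base.copy()
        b[0] = 2          # one mismatch with A -> r² ~ 0.9025
        c = base.copy()
        c[n - 1] = 0      # one mismatch with A, two with B -> r²(B,C) ~ 0.81
        calls = np.stack([a, b, c], axis=1)
        samples = [f"S{i:03d}" for i in range(n)]
        panel = GenotypeMatrix(samples, ["A", "B", "C"], calls)
        records = [rec("A", 1_000), rec("B", 2_000), rec("C", 3_000)]
    elif name == "all_singletons":
        n = 16
        rng = np.random.default_rng(7)
        cols = []
        while len(cols) < 3:
            col = rng.integers(0, 3, size=n).astype(np.int8)
            if np.unique(col).size > 1:
                if all(abs(np.corrcoef(col, c)[0, 1]) < 0.5 for c in cols):
                    cols.append(col)
        calls = np.stack(cols, axis=1)
        samples = [f"S{i:03d}" for i in range(n)]
        panel = GenotypeMatrix(samples, ["X", "Y", "Z"], calls)
        records = [rec("X", 1_000), rec("Y", 2_000), rec("Z", 3_000)]
    else:  # two_blocks
        n = 24
        blk1 = np.array(([0] * 12 + [2] * 12), dtype=np.int8)
        blk2 = np.array(([0, 2] * 12), dtype=np.int8)
        calls = np.stack([blk1, blk1, blk1, blk2, blk2, blk2], axis=1)
        samples = [f"S{i:03d}" for i in range(n)]
        ids = ["P1", "P2", "P3", "Q1", "Q2", "Q3"]
        panel = GenotypeMatrix(samples, ids, calls)
        records = [rec("P1", 1_000), rec("P2", 2_000), rec("P3", 3_000),
                   rec("Q1", 2_001_000, "chr2"), rec("Q2", 2_002_000, "chr2"),
                   rec("Q3", 2_003_000, "chr2")]
    return panel, annotate_from_calls(panel, records)
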