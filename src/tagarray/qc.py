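"""Panel QC, probe-design filtering (strict and relaxed), singleton detection.

The filtered subset F of designable SNPs is the intersection of

* panel QC: MAF and call-rate strictly above their thresholds, and
* probe designability: a one-probe (Infinium Type II) allele pair, no known
  polymorphism under the probe, an adequate vendor design score, and a
  unique alignment to the target genome with no alignment to the other
  genome (the strict rule; the relaxed rule allows up to three target-genome
  alignments, rescuing tag sets otherwise untaggable).

Singletons — SNPs with no partner at r² ≥ 0.9 within 1 Mb up/downstream —
can only be tagged directly and are excluded from tagging candidacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from tagarray.genodata import GenotypeMatrix, SNPRecord

#: unordered allele pairs needing two probes on an Infinium array (Type I)
TYPE_I_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for panel QC and probe filtering.

    MAF and call-rate use strict ``>`` comparisons; the design score uses
    ``>=``. Wheat defaults shown; barley panels conventionally use
    ``maf_min=0.05`` (smaller reference population).
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.6
    design_score_min: float = 0.6
    strict_max_target_hits: int = 1
    relaxed_max_target_hits: int = 3
    max_other_genome_hits: int = 0
    exclude_type_I: bool = True
    singleton_radius_bp: int = 1_000_000
    singleton_r2: float = 0.9

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "design_score_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.relaxed_max_target_hits < self.strict_max_target_hits:
            raise ValueError("relaxed hit bound must be >= strict hit bound")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "FilterConfig":
        if species == "barley":
            overrides.setdefault("maf_min", 0.05)
        return cls(**overrides)


@dataclass
class FilterVerdict:
    """Per-SNP filter outcome. ``passes_strict`` implies ``passes_relaxed``."""

    snp_id: str
    passes_qc: bool = True
    passes_strict: bool = True
    passes_relaxed: bool = True
    reasons: list[str] = field(default_factory=list)

    @property
    def designable_strict(self) -> bool:
        return self.passes_qc and self.passes_strict

    @property
    def designable_relaxed(self) -> bool:
        return self.passes_qc and self.passes_relaxed


def qc_filter(
    records: Sequence[SNPRecord], config: FilterConfig | None = None
) -> dict[str, FilterVerdict]:
    """Panel-level QC: keep SNPs with maf > maf_min and call_rate > call_rate_min.

    Both comparisons are strict, so a SNP at exactly the threshold fails.
    """
    config = config or FilterConfig()
    out: dict[str, FilterVerdict] = {}
    for rec in records:
        verdict = FilterVerdict(rec.snp_id)
        if not rec.maf > config.maf_min:
            verdict.reasons.append("low_maf")
        if not rec.call_rate > config.call_rate_min:
            verdict.reasons.append("low_call_rate")
        verdict.passes_qc = not verdict.reasons
        out[rec.snp_id] = verdict
    return out


def probe_filter(
    record: SNPRecord, config: FilterConfig | None = None
) -> FilterVerdict:
    """Probe-design filter for one SNP: strict and relaxed verdicts.

    Strict pass requires a non-Type-I allele pair, no underlying
    polymorphism, design score >= threshold, exactly one target-genome hit
    and zero other-genome hits. Relaxed pass is identical except up to
    ``relaxed_max_target_hits`` target-genome alignments are allowed.
    """
    config = config or FilterConfig()
    verdict = FilterVerdict(record.snp_id)
    if not record.has_probe_data:
        verdict.reasons.append("no_probe_data")
        verdict.passes_strict = verdict.passes_relaxed = False
        return verdict

    reasons_common: list[str] = []
    pair = frozenset((record.ref_allele.upper(), record.alt_allele.upper()))
    if config.exclude_type_I and pair in TYPE_I_PAIRS:
        reasons_common.append("type_I")
    if record.underlying_polymorphism:
        reasons_common.append("underlying_polymorphism")
    if record.design_score < config.design_score_min:
        reasons_common.append("low_design_score")
    if record.hits_other_genome > config.max_other_genome_hits:
        reasons_common.append("other_genome_hit")
    if record.hits_target_genome < 1:
        reasons_common.append("no_target_hit")

    verdict.reasons.extend(reasons_common)
    verdict.passes_relaxed = (
        not reasons_common
        and record.hits_target_genome <= config.relaxed_max_target_hits
    )
    if not verdict.passes_relaxed and record.hits_target_genome is not None:
        if record.hits_target_genome > config.relaxed_max_target_hits:
            verdict.reasons.append("multi_target_hit")
    verdict.passes_strict = (
        verdict.passes_relaxed
        and record.hits_target_genome <= config.strict_max_target_hits
    )
    if verdict.passes_relaxed and not verdict.passes_strict:
        verdict.reasons.append("multi_target_hit_strict_only")
    return verdict


def filter_panel(
    records: Sequence[SNPRecord], config: FilterConfig | None = None
) -> dict[str, FilterVerdict]:
    """Combined QC + probe verdict per SNP (the membership test for F)."""
    config = config or FilterConfig()
    qc = qc_filter(records, config)
    out: dict[str, FilterVerdict] = {}
    for rec in records:
        probe = probe_filter(rec, config)
        verdict = FilterVerdict(
            rec.snp_id,
            passes_qc=qc[rec.snp_id].passes_qc,
            passes_strict=qc[rec.snp_id].passes_qc and probe.passes_strict,
            passes_relaxed=qc[rec.snp_id].passes_qc and probe.passes_relaxed,
            reasons=qc[rec.snp_id].reasons + probe.reasons,
        )
        out[rec.snp_id] = verdict
    return out


def detect_singletons(
    ld, records: Sequence[SNPRecord], config: FilterConfig | None = None
) -> set[str]:
    """SNPs with no partner at r² >= 0.9 within 1 Mb up/downstream.

    ``ld`` is a :class:`tagarray.ldtag.LDTable` computed at (at least) the
    singleton radius. Singletons can only be tagged directly, so they are
    dropped from tagging candidacy.
    """
    config = config or FilterConfig()
    pos = {r.snp_id: (r.chromosome, r.position) for r in records}
    non_singletons: set[str] = set()
    radius = config.singleton_radius_bp
    for snp_a, snp_b, r2 in ld.iter_pairs():
        if r2 < config.singleton_r2:
            continue
        chrom_a, pos_a = pos[snp_a]
        chrom_b, pos_b = pos[snp_b]
        if chrom_a == chrom_b and abs(pos_a - pos_b) <= radius:
            non_singletons.add(snp_a)
            non_singletons.add(snp_b)
    return {r.snp_id for r in records} - non_singletons
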