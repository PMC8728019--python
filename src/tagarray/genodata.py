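"""Core data model and I/O: genotype panels, SNP/probe annotations, manifests.

Genotypes are stored as diploid ALT-allele dosages in an ``int8`` matrix of
shape (n_samples, n_snps); missing calls are encoded as ``MISSING`` (-1).
Coordinates are 1-based throughout, as in VCF, and all window arithmetic
uses inclusive bounds.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing diploid call
MISSING: int = -1


class IntegrityError(ValueError):
    """Raised when a data structure violates its own invariants."""


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP identity, coordinates, allele pair, QC stats, probe metadata.

    ``design_score`` is an array-vendor probe designability score in [0, 1]
    (e.g. the Illumina Design Tool score). ``hits_target_genome`` /
    ``hits_other_genome`` count probe alignments against the target species'
    genome and the other species' genome respectively (the array supports
    dual hybridization, so cross-species probe specificity matters).
    ``underlying_polymorphism`` flags known variation under the 50-mer
    probe sequence, which shifts genotype-cluster positions.
    """

    snp_id: str
    chromosome: str
    position: int
    ref_allele: str = "N"
    alt_allele: str = "N"
    maf: float = float("nan")
    call_rate: float = float("nan")
    design_score: float | None = None
    hits_target_genome: int | None = None
    hits_other_genome: int | None = None
    underlying_polymorphism: bool | None = None
    species: str = "wheat"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise IntegrityError(f"{self.snp_id}: position must be >= 1")
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise IntegrityError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.ref_allele != "N" and self.ref_allele == self.alt_allele:
            raise IntegrityError(f"{self.snp_id}: ref and alt alleles identical")
        if self.design_score is not None and not 0.0 <= self.design_score <= 1.0:
            raise IntegrityError(
                f"{self.snp_id}: design_score {self.design_score} outside [0, 1]"
            )

    @property
    def has_probe_data(self) -> bool:
        return (
            self.design_score is not None
            and self.hits_target_genome is not None
            and self.hits_other_genome is not None
            and self.underlying_polymorphism is not None
        )


@dataclass
class GenotypeMatrix:
    """A samples × SNPs panel of diploid ALT-allele dosages.

    ``calls[i, j]`` is the number of ALT alleles carried by sample ``i`` at
    SNP ``j`` (0, 1, 2), or ``MISSING``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise IntegrityError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise IntegrityError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise IntegrityError("duplicate SNP ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise IntegrityError("calls contain values outside {0,1,2,missing}")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def dosages(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP as float with NaN for missing."""
        col = self.calls[:, self.snp_index(snp_id)].astype(float)
        col[col == MISSING] = np.nan
        return col

    def as_float(self) -> np.ndarray:
        """Whole matrix as float with NaN for missing calls."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.snp_ids), self.calls[idx, :])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(list(self.sample_ids), list(snp_ids), self.calls[:, idx])

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over called alleles."""
        called = self.calls != MISSING
        alt = np.where(called, self.calls, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)


@dataclass
class SubgroupSpec:
    """Assignment of panel samples to population subgroups."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.assignment.values())) < 2:
            raise IntegrityError("SubgroupSpec needs >= 2 distinct subgroup labels")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, label in self.assignment.items():
            out.setdefault(label, []).append(sample)
        return out

    def validate_against(self, panel: GenotypeMatrix) -> None:
        missing = set(self.assignment) - set(panel.sample_ids)
        if missing:
            raise IntegrityError(
                f"subgroup assignment names {len(missing)} samples absent from panel"
            )


def annotate_from_calls(panel: GenotypeMatrix, records: list[SNPRecord]) -> list[SNPRecord]:
    """Return records with maf and call_rate recomputed from the panel."""
    mafs = panel.maf()
    rates = panel.call_rate()
    out = []
    for rec in records:
        j = panel.snp_index(rec.snp_id)
        out.append(replace(rec, maf=float(mafs[j]), call_rate=float(rates[j])))
    return out


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, species: str = "wheat") -> tuple[GenotypeMatrix, list[SNPRecord]]:
    """Read a diploid VCF into a panel and per-SNP records.

    Only biallelic SNP records with diploid GT fields are kept; everything
    else is skipped with a logged count. Dosage is the ALT-allele count;
    ``./.`` becomes missing. ``maf`` and ``call_rate`` are computed from the
    resulting calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    records: list[SNPRecord] = []
    n_skipped = 0
    seen: set[str] = set()
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        ok = True
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                ok = False
                break
            a, b = alleles
            if a < 0 or b < 0:
                continue
            col[i] = a + b
        if not ok:
            n_skipped += 1
            continue
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        if snp_id in seen:
            n_skipped += 1
            continue
        seen.add(snp_id)
        columns.append(col)
        records.append(
            SNPRecord(
                snp_id=snp_id,
                chromosome=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                species=species,
            )
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-diploid records", n_skipped)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    panel = GenotypeMatrix(samples, [r.snp_id for r in records], calls)
    return panel, annotate_from_calls(panel, records)


# ---------------------------------------------------------------------------
# Dosage-matrix text format (SNPs x samples, {0,1,2,NA})
# ---------------------------------------------------------------------------

_MATRIX_META = ["snp_id", "chromosome", "position", "ref_allele", "alt_allele"]


def write_matrix(
    panel: GenotypeMatrix, records: Sequence[SNPRecord], path: str | Path
) -> None:
    """Write the plain tab-delimited dosage matrix (SNPs × samples)."""
    by_id = {r.snp_id: r for r in records}
    with open(path, "w") as fh:
        fh.write("\t".join(_MATRIX_META + list(panel.sample_ids)) + "\n")
        for j, snp_id in enumerate(panel.snp_ids):
            rec = by_id[snp_id]
            row = [snp_id, rec.chromosome, str(rec.position), rec.ref_allele, rec.alt_allele]
            col = panel.calls[:, j]
            row.extend("NA" if c == MISSING else str(int(c)) for c in col)
            fh.write("\t".join(row) + "\n")


def read_matrix(
    path: str | Path, species: str = "wheat"
) -> tuple[GenotypeMatrix, list[SNPRecord]]:
    """Read the plain dosage-matrix format written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing_cols = [c for c in _MATRIX_META if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dosage matrix lacks columns: {missing_cols}")
    sample_ids = [c for c in df.columns if c not in _MATRIX_META]
    calls = (
        df[sample_ids]
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
        .T
    )
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    records = [
        SNPRecord(
            snp_id=str(row.snp_id),
            chromosome=str(row.chromosome),
            position=int(row.position),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
            species=species,
        )
        for row in df.itertuples()
    ]
    panel = GenotypeMatrix(sample_ids, [r.snp_id for r in records], calls)
    return panel, annotate_from_calls(panel, records)


# ---------------------------------------------------------------------------
# Probe annotation table
# ---------------------------------------------------------------------------

_PROBE_REQUIRED = {
    "snp_id",
    "design_score",
    "hits_target_genome",
    "hits_other_genome",
    "underlying_polymorphism",
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_probe_table(
    path: str | Path, records: Sequence[SNPRecord]
) -> list[SNPRecord]:
    """Merge a probe-annotation table (CSV or TSV) onto panel records by snp_id.

    Rows naming SNPs absent from the panel are logged and ignored; panel
    SNPs absent from the table keep ``None`` probe fields (and later fail
    probe filters with reason ``no_probe_data``).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not _PROBE_REQUIRED.issubset(reader.fieldnames):
            missing = _PROBE_REQUIRED - set(reader.fieldnames or [])
            raise ValueError(f"probe table missing mandatory columns: {sorted(missing)}")
        rows = {row["snp_id"]: row for row in reader}

    by_id = {r.snp_id: r for r in records}
    unmatched = set(rows) - set(by_id)
    if unmatched:
        logger.warning(
            "read_probe_table: %d rows name SNPs absent from the panel", len(unmatched)
        )
    out: list[SNPRecord] = []
    for rec in records:
        row = rows.get(rec.snp_id)
        if row is None:
            out.append(rec)
            continue
        out.append(
            replace(
                rec,
                design_score=float(row["design_score"]),
                hits_target_genome=int(row["hits_target_genome"]),
                hits_other_genome=int(row["hits_other_genome"]),
                underlying_polymorphism=_parse_bool(row["underlying_polymorphism"]),
                ref_allele=row.get("ref_allele", rec.ref_allele),
                alt_allele=row.get("alt_allele", rec.alt_allele),
            )
        )
    return out


def write_probe_table(records: Sequence[SNPRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["snp_id", "ref_allele", "alt_allele", "design_score",
             "hits_target_genome", "hits_other_genome", "underlying_polymorphism"]
        )
        for rec in records:
            if not rec.has_probe_data:
                continue
            writer.writerow(
                [rec.snp_id, rec.ref_allele, rec.alt_allele, rec.design_score,
                 rec.hits_target_genome, rec.hits_other_genome,
                 str(rec.underlying_polymorphism).lower()]
            )


# ---------------------------------------------------------------------------
# Manifest output
# ---------------------------------------------------------------------------

def write_manifest(selection, records: Sequence[SNPRecord], path: str | Path) -> None:
    """Write the array-content manifest: one row per selected SNP plus a
    per-category count summary footer (comment lines prefixed ``#``).

    ``selection`` is a :class:`tagarray.design.DesignSelection`.
    """
    by_id = {r.snp_id: r for r in records}
    seen: set[str] = set()
    for entry in selection.entries:
        if entry.snp_id in seen:
            raise IntegrityError(f"duplicate snp_id in selection: {entry.snp_id}")
        seen.add(entry.snp_id)
        if entry.snp_id not in by_id:
            raise IntegrityError(f"selected SNP absent from panel: {entry.snp_id}")

    counts: dict[str, int] = {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["snp_id", "species", "chromosome", "position", "ref_allele",
             "alt_allele", "category", "tag_set_id", "n_tagged", "selection_rank"]
        )
        for entry in selection.entries:
            rec = by_id[entry.snp_id]
            writer.writerow(
                [entry.snp_id, rec.species, rec.chromosome, rec.position,
                 rec.ref_allele, rec.alt_allele, entry.category,
                 entry.tag_set_id or "", entry.n_tagged, entry.selection_rank]
            )
            counts[entry.category] = counts.get(entry.category, 0) + 1
        fh.write("# summary\n")
        for category in sorted(counts):
            fh.write(f"# {category},{counts[category]}\n")
        fh.write(f"# total,{sum(counts.values())}\n")
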