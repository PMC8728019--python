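"""Windowed pairwise LD (r²) and tag-SNP equivalence sets.

r² is the squared Pearson correlation of unphased genotype dosages
(composite LD) over pairwise-complete samples, computed per chromosome for
pairs within a physical window. The default window is 2 Mb of total span,
i.e. a pair distance of at most ±1 Mb from the focal SNP, so any tag set
spans at most 2 Mb.

The tag set of a focal SNP s at threshold q, T^q_s, contains s itself plus
every SNP whose r² with s is at least q; its size ranks SNPs by
informativeness, and tag sets ordered by decreasing size drive the greedy
selection in :mod:`tagarray.design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from tagarray.genodata import MISSING, GenotypeMatrix, SNPRecord

DEFAULT_WINDOW_BP = 2_000_000


@dataclass
class LDTable:
    """Sparse intra-chromosome pairwise r² within a window.

    Pairs are stored once with ``snp_a`` before ``snp_b`` in (chromosome,
    position, snp_id) order; symmetry is implicit.
    """

    snp_a: list[str]
    snp_b: list[str]
    r2: np.ndarray
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        if len(self.snp_a) != len(self.snp_b) or len(self.snp_a) != self.r2.size:
            raise ValueError("LDTable column lengths differ")
        if self.r2.size and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValueError("r2 outside [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._adj: dict[str, list[tuple[str, float]]] | None = None

    def __len__(self) -> int:
        return self.r2.size

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        for a, b, v in zip(self.snp_a, self.snp_b, self.r2):
            yield a, b, float(v)

    def _adjacency(self) -> dict[str, list[tuple[str, float]]]:
        if self._adj is None:
            adj: dict[str, list[tuple[str, float]]] = {}
            for a, b, v in self.iter_pairs():
                adj.setdefault(a, []).append((b, v))
                adj.setdefault(b, []).append((a, v))
            self._adj = adj
        return self._adj

    def partners(self, snp_id: str, q: float = 0.0) -> list[tuple[str, float]]:
        """All partners of ``snp_id`` with r² >= q (excluding itself)."""
        return [(s, v) for s, v in self._adjacency().get(snp_id, []) if v >= q]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_a": self.snp_a, "snp_b": self.snp_b, "r2": self.r2})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, window_bp: int = DEFAULT_WINDOW_BP) -> "LDTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        return cls(df["snp_a"].tolist(), df["snp_b"].tolist(),
                   df["r2"].to_numpy(), window_bp)


def pairwise_r2(
    panel: GenotypeMatrix,
    records: Sequence[SNPRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    min_overlap: int = 4,
) -> LDTable:
    """Pairwise r² for all intra-chromosome pairs within the window.

    r² is the squared Pearson correlation of the two dosage columns over
    samples called at both SNPs. Pairs with fewer than ``min_overlap``
    shared calls, or with zero dosage variance over the shared calls, are
    omitted (r² undefined) rather than assigned 0, to avoid spuriously
    breaking tag sets.

    ``window_bp`` is the total tag-set span, so the maximum pair distance
    is ``window_bp // 2``.
    """
    max_dist = window_bp // 2
    by_id = {r.snp_id: r for r in records}
    order = sorted(
        panel.snp_ids,
        key=lambda s: (by_id[s].chromosome, by_id[s].position, s),
    )

    X = panel.as_float()
    called = ~np.isnan(X)
    Xz = np.where(called, X, 0.0)

    out_a: list[str] = []
    out_b: list[str] = []
    out_r2: list[float] = []

    # group by chromosome, keeping (chromosome, position) order
    chrom_groups: dict[str, list[str]] = {}
    for snp in order:
        chrom_groups.setdefault(by_id[snp].chromosome, []).append(snp)

    for chrom, snps in chrom_groups.items():
        cols = np.array([panel.snp_index(s) for s in snps])
        positions = np.array([by_id[s].position for s in snps])
        G = Xz[:, cols]          # zero-filled dosages
        C = called[:, cols]      # call mask
        k = len(snps)
        for i in range(k - 1):
            # partners ahead of i within the window
            j_hi = int(np.searchsorted(positions, positions[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            sl = slice(i + 1, j_hi)
            ci = C[:, i][:, None] & C[:, sl]
            n = ci.sum(axis=0).astype(float)
            xi = np.where(ci, G[:, i][:, None], 0.0)
            yj = np.where(ci, G[:, sl], 0.0)
            sx = xi.sum(axis=0)
            sy = yj.sum(axis=0)
            sxx = (xi * xi).sum(axis=0)
            syy = (yj * yj).sum(axis=0)
            sxy = (xi * yj).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / n
                varx = sxx - sx * sx / n
                vary = syy - sy * sy / n
                r2 = (cov * cov) / (varx * vary)
            valid = (n >= min_overlap) & (varx > 1e-12) & (vary > 1e-12)
            for off in np.nonzero(valid)[0]:
                out_a.append(snps[i])
                out_b.append(snps[i + 1 + off])
                out_r2.append(float(r2[off]))
    return LDTable(out_a, out_b, np.array(out_r2), window_bp)


@dataclass
class TagSet:
    """The tag set T^q of a focal SNP: itself plus all partners at r² >= q."""

    focal_snp: str
    members: frozenset[str]
    q: float
    span_bp: int = 0

    def __post_init__(self) -> None:
        if self.focal_snp not in self.members:
            raise ValueError("focal SNP must be a member of its own tag set")

    @property
    def size(self) -> int:
        return len(self.members)


def build_tag_sets(
    ld: LDTable,
    candidates: Iterable[str],
    q: float,
    records: Sequence[SNPRecord] | None = None,
) -> list[TagSet]:
    """One TagSet per candidate focal SNP at threshold q.

    Membership is symmetric by construction (a ∈ T(b) ⇔ b ∈ T(a) whenever
    both are candidates). ``records``, if given, provide positions for the
    span computation; otherwise spans are 0.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q={q} outside (0, 1]")
    pos = {r.snp_id: r.position for r in records} if records else {}
    sets: list[TagSet] = []
    for focal in candidates:
        members = frozenset([focal]) | frozenset(
            s for s, _ in ld.partners(focal, q)
        )
        span = 0
        if pos:
            p = [pos[m] for m in members if m in pos]
            span = max(p) - min(p) if p else 0
        sets.append(TagSet(focal, members, q, span))
    return sets


@dataclass
class TagSetOrder:
    """Tag sets sorted by decreasing size with a deterministic tie rule:
    ties broken by (chromosome, position, snp_id) of the focal SNP ascending.
    """

    sets: list[TagSet]
    sort_keys: dict[str, tuple] = field(default_factory=dict)

    def __iter__(self) -> Iterator[TagSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def order_tag_sets(
    sets: Sequence[TagSet], records: Sequence[SNPRecord] | None = None
) -> TagSetOrder:
    """Stable deterministic informativeness ordering of tag sets."""
    if records:
        locus = {r.snp_id: (r.chromosome, r.position) for r in records}
    else:
        locus = {}
    def key(t: TagSet) -> tuple:
        chrom, pos = locus.get(t.focal_snp, ("", 0))
        return (-t.size, chrom, pos, t.focal_snp)
    ordered = sorted(sets, key=key)
    return TagSetOrder(ordered, {t.focal_snp: key(t) for t in ordered})


def cumulative_tagging_curve(
    selected_focals: Sequence[str],
    ld: LDTable,
    thresholds: Sequence[float] = (0.9, 0.7, 0.5),
) -> pd.DataFrame:
    """Cumulative distinct SNPs tagged by successive tag SNPs.

    For each prefix of the selection (in selection order) and each
    threshold q', counts the distinct SNPs tagged at r² >= q' (tag SNPs
    included). Rows: n_tsnp = 1..len(selection); columns: one per q'.
    """
    tagged: dict[float, set[str]] = {q: set() for q in thresholds}
    rows = []
    for n, focal in enumerate(selected_focals, start=1):
        row: dict[str, float] = {"n_tsnp": n}
        for q in thresholds:
            tagged[q].add(focal)
            tagged[q].update(s for s, _ in ld.partners(focal, q))
            row[f"n_tagged_q{q:g}"] = len(tagged[q])
        rows.append(row)
    return pd.DataFrame(rows)
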