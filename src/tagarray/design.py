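"""Greedy tag-SNP selection and context-specific array content rules.

The selection algorithm treats tag sets as an informativeness-ordered
sequence and repeatedly commits the focal SNP of the largest remaining set
whose focal passes the design filters, then discards every remaining set
that intersects the committed set. This guarantees that no SNP is directly
tagged at r² >= q by two selected tag SNPs, and makes the selected panel a
greedy minimal cover of the taggable SNPs. The main (strict-filter) pass is
followed by:

* a redundancy step — extra member tags for large sets, insuring against
  assay failure,
* a relaxed-filter rescue pass over the untouched sets,
* a gap-fill pass for sparse-but-high-LD regions (small sets with a large
  physical span), and
* a coverage-fill pass adding the best remaining SNP in genomic windows
  still empty of array content.

Content rules for population structure (Weir–Cockerham F_st top fraction,
subgroup private / high-MAF / neutral classes, and the differential-MAF
rule for diversity introgressed from a donor collection) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tagarray.genodata import MISSING, GenotypeMatrix, SNPRecord, SubgroupSpec
from tagarray.ldtag import LDTable, TagSet, TagSetOrder

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the greedy selection.

    ``m`` is the minimum tag-set size worth an assay (sets below it fall
    through to gap-fill). ``redundancy_tiers`` maps a minimum set size to a
    TOTAL number of tags for that set: by default 3 tags for sets of >= 50
    members, 2 for >= 20, 1 for >= 10. ``span_min_bp`` is the minimum
    physical span for gap-fill (wheat default 500 kb; barley uses 1 Mb).
    Set sizes count members including the focal SNP.
    """

    q: float = 0.9
    m: int = 10
    redundancy_tiers: tuple[tuple[int, int], ...] = ((50, 3), (20, 2), (10, 1))
    span_min_bp: int = 500_000
    coverage_window_bp: int = 10_000_000
    target_count: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"q={self.q} outside (0, 1]")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        sizes = [s for s, _ in self.redundancy_tiers]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("redundancy tier thresholds must descend")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "SelectionConfig":
        if species == "barley":
            overrides.setdefault("span_min_bp", 1_000_000)
        return cls(**overrides)

    def n_tags_for(self, set_size: int) -> int:
        for threshold, n in self.redundancy_tiers:
            if set_size >= threshold:
                return n
        return 1


CATEGORIES = (
    "tag_strict", "tag_redundant", "tag_relaxed", "gap_fill", "coverage_fill",
    "content_differentiating", "content_private", "content_high_maf",
    "content_neutral", "content_dgenome",
)


@dataclass(frozen=True)
class SelectionEntry:
    snp_id: str
    category: str
    tag_set_id: str | None
    n_tagged: int
    selection_rank: int


@dataclass
class DesignSelection:
    """The chosen array content with per-SNP category labels."""

    entries: list[SelectionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ids = {e.snp_id for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._ids

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def next_rank(self) -> int:
        return len(self.entries) + 1

    def add(self, snp_id: str, category: str, tag_set_id: str | None = None,
            n_tagged: int = 0) -> SelectionEntry:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if snp_id in self._ids:
            raise ValueError(f"SNP {snp_id} already selected")
        entry = SelectionEntry(snp_id, category, tag_set_id, n_tagged, self.next_rank())
        self.entries.append(entry)
        self._ids.add(snp_id)
        return entry

    def by_category(self, *categories: str) -> list[SelectionEntry]:
        return [e for e in self.entries if e.category in categories]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


class _GreedyState:
    """Shared mutable state across the strict / relaxed / gap-fill passes.

    Holds the informativeness-ordered tag sets, an aliveness flag per set
    (a set dies when it intersects a committed set), and an inverted index
    member SNP -> set indices for O(members) removal.
    """

    def __init__(self, order: TagSetOrder):
        self.sets: list[TagSet] = list(order)
        self.alive = [True] * len(self.sets)
        self.member_index: dict[str, list[int]] = {}
        for k, t in enumerate(self.sets):
            for s in t.members:
                self.member_index.setdefault(s, []).append(k)

    def commit(self, k: int) -> None:
        """Kill set k and every alive set sharing a member with it."""
        for s in self.sets[k].members:
            for j in self.member_index.get(s, ()):
                self.alive[j] = False

    def alive_sets(self) -> list[TagSet]:
        return [t for t, a in zip(self.sets, self.alive) if a]


def _redundant_members(
    tag_set: TagSet, eligible: set[str], selection: DesignSelection,
    ld: LDTable, records_by_id: Mapping[str, SNPRecord], n_extra: int,
) -> list[str]:
    """Highest-r²-to-focal eligible members, ties by (position, snp_id)."""
    r2_to_focal = dict(ld.partners(tag_set.focal_snp))
    pool = [
        s for s in tag_set.members
        if s != tag_set.focal_snp and s in eligible and s not in selection
    ]
    pool.sort(
        key=lambda s: (
            -r2_to_focal.get(s, 0.0),
            records_by_id[s].position if s in records_by_id else 0,
            s,
        )
    )
    return pool[:n_extra]


def _greedy_pass(
    state: _GreedyState,
    eligible: set[str],
    selection: DesignSelection,
    config: SelectionConfig,
    category: str,
    ld: LDTable | None = None,
    records: Sequence[SNPRecord] | None = None,
    redundancy: bool = False,
) -> None:
    """One head-of-sequence greedy sweep over the alive sets.

    Sizes never change (removal is whole-set), so a monotone pointer over
    the pre-sorted sequence always finds the current head among sets whose
    focal SNP is eligible; the sweep stops when that head is smaller than m.
    """
    records_by_id = {r.snp_id: r for r in records} if records else {}
    n_primary = sum(1 for e in selection.entries if e.category == category)
    ptr = 0
    while ptr < len(state.sets):
        t = state.sets[ptr]
        if not state.alive[ptr] or t.focal_snp not in eligible:
            ptr += 1
            continue
        if t.size < config.m:
            break
        if config.target_count is not None and n_primary >= config.target_count:
            break
        selection.add(t.focal_snp, category, tag_set_id=t.focal_snp, n_tagged=t.size)
        n_primary += 1
        if redundancy and ld is not None:
            n_extra = config.n_tags_for(t.size) - 1
            if n_extra > 0:
                for s in _redundant_members(
                    t, eligible, selection, ld, records_by_id, n_extra
                ):
                    selection.add(s, "tag_redundant", tag_set_id=t.focal_snp,
                                  n_tagged=t.size)
        state.commit(ptr)
        ptr += 1


def select_tsnps(
    order: TagSetOrder,
    F: Iterable[str],
    config: SelectionConfig | None = None,
    ld: LDTable | None = None,
    records: Sequence[SNPRecord] | None = None,
    state: _GreedyState | None = None,
) -> tuple[DesignSelection, _GreedyState]:
    """Main greedy pass over strict-filtered SNPs, with redundancy.

    Repeatedly selects the focal SNP of the largest remaining tag set whose
    focal is in ``F``, then discards every remaining set intersecting the
    selected set, stopping when the largest eligible set has fewer than
    ``config.m`` members. For selected sets large enough to hit a
    redundancy tier, extra member SNPs from ``F`` (highest r² to the focal)
    are added as ``tag_redundant``.

    Returns the selection and the greedy state, which carries the untouched
    sets into :func:`relaxed_rescue` and :func:`gap_fill`.
    """
    config = config or SelectionConfig()
    selection = DesignSelection()
    state = state or _GreedyState(order)
    _greedy_pass(state, set(F), selection, config, "tag_strict",
                 ld=ld, records=records, redundancy=True)
    return selection, state


def relaxed_rescue(
    state: _GreedyState,
    F_relaxed: Iterable[str],
    selection: DesignSelection,
    config: SelectionConfig | None = None,
) -> list[SelectionEntry]:
    """Rescue pass: same greedy loop over the sets untouched by the strict
    pass, with relaxed-filter eligibility; additions labelled tag_relaxed."""
    config = config or SelectionConfig()
    before = len(selection)
    _greedy_pass(state, set(F_relaxed), selection, config, "tag_relaxed")
    return selection.entries[before:]


def gap_fill(
    state: _GreedyState,
    eligible: Iterable[str],
    selection: DesignSelection,
    records: Sequence[SNPRecord],
    config: SelectionConfig | None = None,
) -> list[SelectionEntry]:
    """Tag sparse-but-high-LD regions: remaining disjoint sets with
    2 <= size < m whose members span at least ``span_min_bp``.

    Candidates are ranked by span × size descending (ties by focal locus),
    and committed greedily with the same intersection-removal rule.
    """
    config = config or SelectionConfig()
    eligible = set(eligible)
    locus = {r.snp_id: (r.chromosome, r.position) for r in records}
    before = len(selection)

    candidates = [
        (k, t) for k, t in enumerate(state.sets)
        if state.alive[k]
        and t.focal_snp in eligible
        and 2 <= t.size < config.m
        and t.span_bp >= config.span_min_bp
    ]
    candidates.sort(
        key=lambda kt: (
            -kt[1].span_bp * kt[1].size,
            locus.get(kt[1].focal_snp, ("", 0)),
            kt[1].focal_snp,
        )
    )
    for k, t in candidates:
        if not state.alive[k]:
            continue
        selection.add(t.focal_snp, "gap_fill", tag_set_id=t.focal_snp,
                      n_tagged=t.size)
        state.commit(k)
    return selection.entries[before:]


def coverage_fill(
    records: Sequence[SNPRecord],
    eligible: Iterable[str],
    selection: DesignSelection,
    config: SelectionConfig | None = None,
) -> list[SelectionEntry]:
    """Final fill: scan each chromosome in non-overlapping windows of
    ``coverage_window_bp``; any window holding at least one eligible SNP
    but no selected SNP contributes its highest-MAF eligible SNP."""
    config = config or SelectionConfig()
    eligible = set(eligible)
    W = config.coverage_window_bp
    before = len(selection)

    by_window: dict[tuple[str, int], list[SNPRecord]] = {}
    covered: set[tuple[str, int]] = set()
    for rec in records:
        key = (rec.chromosome, (rec.position - 1) // W)
        if rec.snp_id in selection:
            covered.add(key)
        if rec.snp_id in eligible:
            by_window.setdefault(key, []).append(rec)

    for key in sorted(by_window):
        if key in covered:
            continue
        pool = [r for r in by_window[key] if r.snp_id not in selection]
        if not pool:
            continue
        best = max(pool, key=lambda r: (r.maf, -r.position, r.snp_id))
        selection.add(best.snp_id, "coverage_fill", n_tagged=1)
    return selection.entries[before:]


def tagged_at(
    selection: DesignSelection, ld: LDTable, q: float,
    design_q: float | None = None,
) -> set[str]:
    """All SNPs tagged by the selection at r² >= q: the union over selected
    SNPs of their partners at or above q, plus the selected SNPs themselves.

    Tagging claims are normally made at q at or below the design threshold;
    a higher q is permitted but warned about.
    """
    if design_q is not None and q > design_q:
        logger.warning("tagged_at called with q=%.3g above the design q=%.3g", q, design_q)
    out: set[str] = set()
    for entry in selection.entries:
        out.add(entry.snp_id)
        out.update(s for s, _ in ld.partners(entry.snp_id, q))
    return out


def sample_size_compensation(q: float) -> float:
    """Percent extra GWAS samples needed to offset tagging at r² >= q.

    Power with an imperfect tag scales as r² × n, so holding power fixed
    requires n/q samples — a (1/q − 1) relative increase. At the design
    threshold q = 0.9 this is ~11%.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q={q} outside (0, 1]")
    return 100.0 * (1.0 / q - 1.0)


# ---------------------------------------------------------------------------
# F_st and content classes
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-SNP two-population Weir–Cockerham θ with rank percentiles."""

    snp_ids: list[str]
    theta: np.ndarray
    group_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        defined = np.isfinite(self.theta)
        self.percentile = np.full(self.theta.shape, np.nan)
        if defined.any():
            from scipy.stats import rankdata
            ranks = rankdata(self.theta[defined], method="max")
            self.percentile[defined] = 100.0 * ranks / defined.sum()

    def to_series(self) -> pd.Series:
        return pd.Series(self.theta, index=self.snp_ids, name="theta")

    def top_fraction(self, percent: float = 2.0) -> set[str]:
        """SNPs in the top ``percent``% of defined θ, ties toward inclusion."""
        defined = np.isfinite(self.theta)
        if not defined.any():
            return set()
        cutoff = np.quantile(self.theta[defined], 1.0 - percent / 100.0)
        keep = defined & (self.theta >= cutoff)
        return {s for s, k in zip(self.snp_ids, keep) if k}


def fst_weir_cockerham(
    panel: GenotypeMatrix,
    groups: SubgroupSpec | tuple[Sequence[str], Sequence[str]],
) -> FstResult:
    """Per-SNP Weir & Cockerham (1984) θ between two sample groups.

    Uses the genotype-count form of the two-population estimator (variance
    components a, b, c from allele frequencies, sample sizes and observed
    heterozygosity). SNPs with fewer than 2 called samples in either group
    get θ = NaN. θ can be negative (no differentiation) and equals 1 for a
    fixed difference.
    """
    if isinstance(groups, SubgroupSpec):
        groups.validate_against(panel)
        labelled = groups.groups()
        if len(labelled) != 2:
            raise ValueError(
                f"fst_weir_cockerham needs exactly 2 groups, got {len(labelled)}"
            )
        (_, g1), (_, g2) = sorted(labelled.items())
    else:
        g1, g2 = groups
        if not g1 or not g2:
            raise ValueError("both groups must be non-empty")

    idx1 = [panel.sample_index(s) for s in g1]
    idx2 = [panel.sample_index(s) for s in g2]
    X = panel.as_float()

    def stats(idx):
        sub = X[idx, :]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)            # diploid individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)      # ALT frequency
            h = (sub == 1).sum(axis=0) / n              # observed het freq
        return n, p, h

    n1, p1, h1 = stats(idx1)
    n2, p2, h2 = stats(idx2)

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 1e-300, a / denom, np.nan)

    theta = np.where((n1 >= 2) & (n2 >= 2), theta, np.nan)
    return FstResult(list(panel.snp_ids), theta, (len(idx1), len(idx2)))


def subgroup_mafs(panel: GenotypeMatrix, groups: SubgroupSpec) -> pd.DataFrame:
    """Per-subgroup MAF table (SNPs × subgroups)."""
    groups.validate_against(panel)
    cols = {}
    for label, samples in sorted(groups.groups().items()):
        cols[label] = panel.subset_samples(samples).maf()
    return pd.DataFrame(cols, index=panel.snp_ids)


def classify_content(
    subgroup_maf: pd.DataFrame,
    fst_top: set[str] | None = None,
    overall_maf: pd.Series | None = None,
    private_min: float = 0.1,
    private_other_max: float = 0.05,
    high_maf_min: float = 0.3,
    neutral_overall_min: float = 0.4,
) -> pd.Series:
    """Assign population-structure content classes to SNPs.

    First matching class wins, in order:

    1. ``content_differentiating`` — SNP in the F_st top fraction,
    2. ``content_private`` — MAF >= 0.1 in exactly one subgroup and
       monomorphic or MAF < 0.05 in every other,
    3. ``content_high_maf`` — MAF >= 0.3 in any subgroup,
    4. ``content_neutral`` — polymorphic in all subgroups with overall
       MAF >= 0.4.

    Returns a Series indexed by snp_id with the class label or ``None``.
    """
    if subgroup_maf.shape[1] < 2:
        raise ValueError("need >= 2 subgroups")
    fst_top = fst_top or set()
    M = subgroup_maf.to_numpy(dtype=float)
    if overall_maf is None:
        overall = np.nanmean(M, axis=1)
    else:
        overall = overall_maf.reindex(subgroup_maf.index).to_numpy(dtype=float)

    out = []
    for i, snp in enumerate(subgroup_maf.index):
        row = M[i]
        if snp in fst_top:
            out.append("content_differentiating")
        elif np.any(
            [row[j] >= private_min and np.all(np.delete(row, j) < private_other_max)
             for j in range(row.size)]
        ):
            out.append("content_private")
        elif np.nanmax(row) >= high_maf_min:
            out.append("content_high_maf")
        elif np.all(row > 0) and overall[i] >= neutral_overall_min:
            out.append("content_neutral")
        else:
            out.append(None)
    return pd.Series(out, index=subgroup_maf.index, name="content_class")


def select_dgenome_content(
    maf_derived: Mapping[str, float] | pd.Series,
    maf_global: Mapping[str, float] | pd.Series,
    maf_min: float = 0.1,
    maf_max: float = 0.1,
) -> set[str]:
    """SNPs carrying donor-collection diversity: MAF > 0.1 in the
    synthetic-derivative group and MAF < 0.1 in the globally diverse group."""
    maf_derived = pd.Series(maf_derived)
    maf_global = pd.Series(maf_global)
    common = maf_derived.index.intersection(maf_global.index)
    keep = (maf_derived[common] > maf_min) & (maf_global[common] < maf_max)
    return set(common[keep])


# ---------------------------------------------------------------------------
# Convenience: full tagging pipeline
# ---------------------------------------------------------------------------

def run_design(
    panel: GenotypeMatrix,
    records: Sequence[SNPRecord],
    filter_config=None,
    selection_config: SelectionConfig | None = None,
    window_bp: int = 2_000_000,
):
    """QC → LD → singleton exclusion → tag sets → all selection passes.

    Returns ``(selection, ld, order)``. The individual passes are exposed
    separately; this wrapper wires them in the canonical order.
    """
    from tagarray import ldtag, qc

    filter_config = filter_config or qc.FilterConfig()
    selection_config = selection_config or SelectionConfig()

    verdicts = qc.filter_panel(records, filter_config)
    ld = ldtag.pairwise_r2(panel, records, window_bp=window_bp)
    singletons = qc.detect_singletons(ld, records, filter_config)
    candidates = [s for s in panel.snp_ids if s not in singletons]

    sets = ldtag.build_tag_sets(ld, candidates, selection_config.q, records)
    order = ldtag.order_tag_sets(sets, records)

    F_strict = {s for s, v in verdicts.items()
                if v.designable_strict and s not in singletons}
    F_relaxed = {s for s, v in verdicts.items()
                 if v.designable_relaxed and s not in singletons}

    selection, state = select_tsnps(order, F_strict, selection_config,
                                    ld=ld, records=records)
    relaxed_rescue(state, F_relaxed, selection, selection_config)
    gap_fill(state, F_relaxed, selection, records, selection_config)
    qc_pass = {s for s, v in verdicts.items() if v.designable_relaxed}
    coverage_fill(records, qc_pass, selection, selection_config)
    return selection, ld, order
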