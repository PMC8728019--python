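"""Masking-based cross-validation of an array design.

A designed panel is evaluated by repeatedly masking a random subset of
lines down to the selected tag SNPs, imputing the masked genotypes back
from the remaining lines, and scoring the imputed against the true calls.
Two accuracy metrics are used, each computed including and excluding
heterozygous calls:

* concordance — the fraction of exact genotype matches over positions
  called in both vectors, and
* correlation squared — the squared Pearson correlation over the same
  positions.

The imputer is a deliberately simple tag-conditional model: each target
SNP is predicted from its single best tagging SNP (highest r² among the
selected SNPs) through a conditional dosage map estimated from the
reference lines (tag dosages unseen in the reference are extrapolated from
the reference linear fit, with the marginal mode as a last resort). Because the
design guarantees every target a tag at r² >= q, this recovers the
haplotype-block signal that a full hidden-Markov imputer would use, while
remaining deterministic and dependency-free; it is a stand-in, not a
replacement, for production imputation software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tagarray.genodata import MISSING, GenotypeMatrix
from tagarray.ldtag import LDTable
from tagarray.design import DesignSelection, tagged_at

logger = logging.getLogger(__name__)

THRESHOLDS_DEFAULT = (0.5, 0.7, 0.9)


def _comparison_mask(g1: np.ndarray, g2: np.ndarray, include_het: bool) -> np.ndarray:
    both = ~np.isnan(g1) & ~np.isnan(g2)
    if not include_het:
        both &= (g1 != 1) & (g2 != 1)
    return both


def concordance(g1, g2, include_het: bool = True) -> float:
    """Fraction of exact matches over positions called in both vectors.

    With ``include_het=False``, positions where either call is heterozygous
    are dropped first. Returns NaN when the comparison set is empty.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("vectors differ in length")
    m = _comparison_mask(g1, g2, include_het)
    if not m.any():
        return float("nan")
    return float((g1[m] == g2[m]).mean())


def correlation_squared(g1, g2, include_het: bool = True) -> float:
    """Squared Pearson correlation over the comparison set (NaN if undefined)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("vectors differ in length")
    m = _comparison_mask(g1, g2, include_het)
    if m.sum() < 2:
        return float("nan")
    x, y = g1[m], g2[m]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class ImputerModel:
    """Per-target conditional dosage maps keyed by the best tagging SNP.

    ``models[target] = (tag_snp, {tag_dosage: predicted_dosage}, fallback)``
    where ``fallback`` is the reference marginal mode of the target.
    """

    models: dict[str, tuple[str, dict[int, int], int]] = field(default_factory=dict)

    @property
    def targets(self) -> list[str]:
        return list(self.models)


def _mode(values: np.ndarray) -> int:
    """Most frequent dosage; ties broken toward the lower dosage."""
    counts = np.bincount(values.astype(int), minlength=3)
    return int(np.argmax(counts))


def fit_imputer(
    reference: GenotypeMatrix,
    selection: DesignSelection,
    ld: LDTable,
    q: float,
) -> ImputerModel:
    """Fit conditional maps for every SNP tagged at r² >= q but not selected.

    For each target: the best tag is the selected SNP with the highest r²
    to it (ties by snp_id); the conditional map sends each tag dosage seen
    in the reference to the modal target dosage among reference lines
    carrying it. A tag dosage never observed in the reference is filled by
    the rounded linear regression of target on tag over the reference —
    exact under perfect LD, where the relation is target = a ± tag — and
    only when that fit is undefined does the target's marginal mode serve
    as the fallback. Targets with no selected tag at q are excluded with a
    warning.
    """
    selected = set(selection.snp_ids)
    targets = tagged_at(selection, ld, q) - selected
    model = ImputerModel()
    n_untagged = 0
    for target in sorted(targets):
        tags = [(s, v) for s, v in ld.partners(target, q) if s in selected]
        if not tags:
            n_untagged += 1
            continue
        tag, _ = max(tags, key=lambda sv: (sv[1], sv[0]))
        t_col = reference.dosages(target)
        g_col = reference.dosages(tag)
        called = ~np.isnan(t_col)
        if not called.any():
            n_untagged += 1
            continue
        fallback = _mode(t_col[called])
        cmap: dict[int, int] = {}
        unseen = []
        for dose in (0, 1, 2):
            sel = called & (g_col == dose)
            if sel.any():
                cmap[dose] = _mode(t_col[sel])
            else:
                unseen.append(dose)
        if unseen:
            both = called & ~np.isnan(g_col)
            x, y = g_col[both], t_col[both]
            if both.sum() >= 2 and x.std() > 0:
                slope, intercept = np.polyfit(x, y, 1)
                for dose in unseen:
                    cmap[dose] = int(np.clip(round(intercept + slope * dose), 0, 2))
        model.models[target] = (tag, cmap, fallback)
    if n_untagged:
        logger.warning("fit_imputer: %d targets dropped (no usable tag)", n_untagged)
    return model


def impute(masked: GenotypeMatrix, model: ImputerModel) -> GenotypeMatrix:
    """Impute every model target for every sample of the masked panel.

    A missing tag call yields a missing target call. Raises if a tag SNP
    required by the model is absent from the masked panel.
    """
    targets = model.targets
    calls = np.full((masked.n_samples, len(targets)), MISSING, dtype=np.int8)
    for j, target in enumerate(targets):
        tag, cmap, fallback = model.models[target]
        if tag not in masked._snp_index:
            raise KeyError(f"tag SNP {tag} absent from the masked panel")
        g = masked.dosages(tag)
        for i in range(masked.n_samples):
            if np.isnan(g[i]):
                continue
            calls[i, j] = cmap.get(int(g[i]), fallback)
    return GenotypeMatrix(list(masked.sample_ids), targets, calls)


@dataclass
class CrossValReport:
    """Per-line and averaged imputation accuracies per tagged-set threshold.

    ``per_line`` has one row per (sample, threshold) with the four metrics,
    each averaged over the repetitions in which the sample was masked;
    ``summary`` holds the across-line mean and SD for each metric and
    threshold (the conventional reporting layout).
    """

    per_line: pd.DataFrame
    summary: pd.DataFrame
    n_reps: int
    seed: int

    def mean(self, metric: str, q: float) -> float:
        row = self.summary[(self.summary["metric"] == metric)
                           & (self.summary["q"] == q)]
        return float(row["mean"].iloc[0])


METRICS = (
    "correlation_squared_incl_het",
    "correlation_squared_excl_het",
    "concordance_incl_het",
    "concordance_excl_het",
)


def _score_line(truth: np.ndarray, imputed: np.ndarray) -> dict[str, float]:
    return {
        "correlation_squared_incl_het": correlation_squared(truth, imputed, True),
        "correlation_squared_excl_het": correlation_squared(truth, imputed, False),
        "concordance_incl_het": concordance(truth, imputed, True),
        "concordance_excl_het": concordance(truth, imputed, False),
    }


def cross_validate(
    panel: GenotypeMatrix,
    selection: DesignSelection,
    ld: LDTable,
    n_mask: int = 10,
    n_reps: int = 100,
    thresholds: Sequence[float] = THRESHOLDS_DEFAULT,
    seed: int = 0,
) -> CrossValReport:
    """Masking cross-validation of a design.

    Each repetition: draw ``n_mask`` lines without replacement (seeded),
    mask them down to the selected SNPs, fit the imputer on the remaining
    lines, impute each threshold's target set and score every masked line
    with all four metrics. Per-line values are averaged over the
    repetitions in which the line was drawn; the summary reports the mean
    and SD of those per-line averages.
    """
    for q in thresholds:
        if not 0.0 < q <= 1.0:
            raise ValueError(f"threshold {q} outside (0, 1]")
    if n_mask >= panel.n_samples:
        raise ValueError("n_mask must be smaller than the panel")

    rng = np.random.default_rng(seed)
    tag_ids = [s for s in selection.snp_ids if s in panel._snp_index]
    acc: dict[tuple[str, float, str], list[float]] = {}

    for _ in range(n_reps):
        masked_idx = rng.choice(panel.n_samples, size=n_mask, replace=False)
        masked_samples = [panel.sample_ids[i] for i in masked_idx]
        ref_samples = [s for s in panel.sample_ids if s not in set(masked_samples)]
        reference = panel.subset_samples(ref_samples)
        masked = panel.subset_samples(masked_samples).subset_snps(tag_ids)

        for q in thresholds:
            model = fit_imputer(reference, selection, ld, q)
            if not model.targets:
                continue
            imputed = impute(masked, model)
            truth = panel.subset_samples(masked_samples).subset_snps(model.targets)
            T, I = truth.as_float(), imputed.as_float()
            for i, sample in enumerate(masked_samples):
                for metric, value in _score_line(T[i], I[i]).items():
                    if np.isfinite(value):
                        acc.setdefault((sample, q, metric), []).append(value)

    per_line_rows = [
        {"sample": s, "q": q, "metric": metric, "value": float(np.mean(vals)),
         "n_occurrences": len(vals)}
        for (s, q, metric), vals in sorted(acc.items())
    ]
    per_line = pd.DataFrame(per_line_rows)

    summary_rows = []
    for q in thresholds:
        for metric in METRICS:
            vals = per_line.query("q == @q and metric == @metric")["value"]
            summary_rows.append({
                "metric": metric, "q": q,
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n_lines": int(len(vals)),
            })
    summary = pd.DataFrame(summary_rows)
    return CrossValReport(per_line, summary, n_reps, seed)
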