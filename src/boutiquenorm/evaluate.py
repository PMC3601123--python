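"""Normalization-evaluation harness.

The central question for a boutique array is whether a normalization
restricted to its few hundred probe sets reproduces what whole-array
normalization would have given had the same genes sat on a genome-wide
chip.  This module compares a boutique-normalized matrix to a whole-array
reference (pooled / per-category / per-array Pearson r and RMS
difference), averages replicates for cross-platform comparison, profiles
raw intensity densities, and exposes the three-method comparison
(SBQ vs RMAPS vs RIMS against whole-array RMA) as one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import (
    Category,
    ExpressionMatrix,
    ProbeLevelMatrix,
    ProbeSetAnnotation,
    SampleMeta,
)
from .normalize import rims_normalize, rmaps_normalize, sbq_normalize
from .summarize import mas5_detection, rma_summarize

__all__ = [
    "ComparisonReport",
    "compare_to_reference",
    "replicate_average",
    "intensity_density",
    "fold_change_error",
    "boutique_method_comparison",
]


@dataclass
class ComparisonReport:
    """Agreement between a test and a reference expression matrix."""

    overall_r: float
    per_category_r: dict[str, float]
    per_array_r: dict[str, float]
    rms_difference: float
    n_values: int
    scatter: pd.DataFrame  # probeset_id, sample_id, category, test, reference


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def compare_to_reference(
    test: ExpressionMatrix,
    reference: ExpressionMatrix,
    annotation: ProbeSetAnnotation,
) -> ComparisonReport:
    """Pearson agreement of two log2 matrices on their intersection.

    Computes pooled r over all shared probe-set x array pairs, r per
    annotation category (defl / invariant / marker), r per array, and the
    root-mean-square difference; also emits the scatter-point table.
    """
    shared_ps = [p for p in test.probesets if p in set(reference.probesets)]
    shared_arr = [s for s in test.sample_ids if s in set(reference.sample_ids)]
    if not shared_ps or not shared_arr:
        raise ValidationError("test and reference share no probe sets or arrays")
    T = test.values.loc[shared_ps, shared_arr]
    R = reference.values.loc[shared_ps, shared_arr]
    t, r = T.to_numpy().ravel(), R.to_numpy().ravel()
    cats = pd.Series(
        [annotation.category_of(p).value if p in annotation else "unknown"
         for p in shared_ps],
        index=shared_ps,
    )
    per_cat = {}
    for cat in (Category.DEFL, Category.INVARIANT, Category.MARKER):
        ids = cats.index[cats == cat.value]
        if len(ids):
            per_cat[cat.value] = _pearson(
                T.loc[ids].to_numpy().ravel(), R.loc[ids].to_numpy().ravel()
            )
    per_array = {
        sid: _pearson(T[sid].to_numpy(), R[sid].to_numpy()) for sid in shared_arr
    }
    scatter = pd.DataFrame(
        {
            "probeset_id": np.repeat(shared_ps, len(shared_arr)),
            "sample_id": np.tile(shared_arr, len(shared_ps)),
            "category": np.repeat(cats.to_numpy(), len(shared_arr)),
            "test": t,
            "reference": r,
        }
    )
    return ComparisonReport(
        overall_r=_pearson(t, r),
        per_category_r=per_cat,
        per_array_r=per_array,
        rms_difference=float(np.sqrt(np.mean((t - r) ** 2))),
        n_values=t.size,
        scatter=scatter,
    )


def replicate_average(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Mean log2 signal within each replicate group; one column per group.

    Used before cross-platform comparison.  Idempotent: averaging data
    whose groups are single arrays returns it unchanged.
    """
    groups = expr.groups()
    values = pd.DataFrame(
        {g: expr.values[sids].mean(axis=1) for g, sids in groups.items()}
    )
    rep = {s.replicate_group: s for s in expr.samples}
    samples = [
        SampleMeta(g, rep[g].tissue, rep[g].condition, g, 1) for g in groups
    ]
    values.columns = list(groups)
    return ExpressionMatrix(values=values, method_tag=expr.method_tag, samples=samples)


def intensity_density(
    plm: ProbeLevelMatrix, n_grid: int = 512
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-array Gaussian KDE of log2(PM) on a shared grid.

    Bandwidth by Silverman's rule; the grid spans the pooled log2 range
    padded by five bandwidths so each curve integrates to 1 within 1e-3.
    Returns (grid, densities) with one column per array.
    """
    logpm = np.log2(plm.pm)
    kdes = [stats.gaussian_kde(logpm[:, j], bw_method="silverman")
            for j in range(plm.n_arrays)]
    bw = max(float(np.sqrt(k.covariance[0, 0])) for k in kdes)
    lo, hi = logpm.min() - 5 * bw, logpm.max() + 5 * bw
    grid = np.linspace(lo, hi, n_grid)
    dens = pd.DataFrame(
        {sid: k(grid) for sid, k in zip(plm.sample_ids, kdes)}
    )
    return grid, dens


def fold_change_error(
    expr: ExpressionMatrix,
    true_condition_log2: pd.DataFrame,
    baseline: str,
    contrast: str,
) -> float:
    """Mean absolute error of estimated vs true log2 fold changes.

    Estimated fold change per probe set = mean over the contrast
    condition's arrays minus mean over the baseline condition's arrays;
    truth comes from a simulation's per-condition log2 table.
    """
    by_cond: dict[str, list[str]] = {}
    for s in expr.samples:
        by_cond.setdefault(s.condition, []).append(s.sample_id)
    for c in (baseline, contrast):
        if c not in by_cond:
            raise ValidationError(f"condition {c!r} not present in samples")
    est = (
        expr.values[by_cond[contrast]].mean(axis=1)
        - expr.values[by_cond[baseline]].mean(axis=1)
    )
    truth = (
        true_condition_log2.loc[expr.probesets, contrast]
        - true_condition_log2.loc[expr.probesets, baseline]
    )
    return float(np.abs(est - truth).mean())


def boutique_method_comparison(
    boutique_plm: ProbeLevelMatrix,
    reference: ExpressionMatrix,
    annotation: ProbeSetAnnotation,
    invariant_ids: list[str] | None = None,
) -> dict[str, ComparisonReport]:
    """Run SBQ, RMAPS and RIMS on a boutique array and score each vs RMA.

    ``reference`` is whole-array RMA expression covering the boutique
    probe sets.  SBQ uses the annotation's invariant category (or
    ``invariant_ids``) as its stable set; RMAPS derives its absent set
    from MAS5 calls on the boutique data.  Returns one
    :class:`ComparisonReport` per method keyed ``sbq``/``rmaps``/``rims``.
    """
    invariant_ids = invariant_ids or annotation.ids_in_category(Category.INVARIANT)
    raw = rma_summarize(boutique_plm, quantile=False)
    sbq = sbq_normalize(raw, invariant_ids)
    calls = mas5_detection(boutique_plm)
    rmaps, _ = rmaps_normalize(boutique_plm, calls)
    rims, _ = rims_normalize(boutique_plm, invariant_ids)
    return {
        "sbq": compare_to_reference(sbq, reference, annotation),
        "rmaps": compare_to_reference(rmaps, reference, annotation),
        "rims": compare_to_reference(rims, reference, annotation),
    }
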