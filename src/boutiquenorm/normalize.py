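"""Boutique-array normalization schemes.

A boutique array's probe content is biased toward one gene family, so the
global assumptions behind whole-array normalization (most genes unchanged,
similar intensity distributions across arrays) fail.  Three schemes that
survive this pathology are implemented:

* **SBQ** (stable-gene based quantile): quantile normalization anchored on
  a designated set of stably expressed genes, with every other gene mapped
  by monotone piecewise-linear interpolation between the stable anchors.
* **RMAPS** (RMA + median absent probe-set scaling): RMA run separately
  within each biological replicate group (where the distributional
  assumptions hold), then a single additive log2 shift per group equalizing
  the median of the probe sets called Absent in every array.
* **RIMS** (RMA + invariant median scaling): as RMAPS but anchored on the
  median of designated invariant genes.

Also here: coefficient-of-variation selection of invariant genes and the
row-median scaling used for heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyAbsentSetError,
    InsufficientStableGenesError,
    UnknownProbeSetError,
    ValidationError,
)
from .model import (
    DetectionCalls,
    ExpressionMatrix,
    ProbeLevelMatrix,
)
from .summarize import rma_summarize

__all__ = [
    "ScalingReport",
    "sbq_normalize",
    "rmaps_normalize",
    "rims_normalize",
    "select_invariants",
    "median_scale_rows",
]


@dataclass
class ScalingReport:
    """Per-replicate-group additive log2 offsets and their anchor.

    ``anchor`` names the statistic ("median_absent" or "median_invariant");
    after application the anchor statistic is equal across groups.
    """

    anchor: str
    anchor_n: int
    offsets: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate_group": list(self.offsets),
                "offset_log2": list(self.offsets.values()),
                "anchor": self.anchor,
                "anchor_n": self.anchor_n,
            }
        )


def sbq_normalize(expr: ExpressionMatrix, stable_ids: list[str]) -> ExpressionMatrix:
    """Stable-gene based quantile normalization of summarized log2 values.

    The reference distribution is the across-array mean of the sorted
    stable-gene values.  Per array, stable genes are rank-mapped onto the
    reference; non-stable genes are mapped by monotone piecewise-linear
    interpolation between the (observed value -> reference value) anchor
    pairs, and values outside the stable range are shifted by the boundary
    anchor's offset.  With ``stable_ids`` equal to all probe sets this
    degenerates to full quantile normalization.
    """
    if len(stable_ids) < 10:
        raise InsufficientStableGenesError(
            f"SBQ needs >= 10 stable genes, got {len(stable_ids)}"
        )
    missing = set(stable_ids) - set(expr.probesets)
    if missing:
        raise UnknownProbeSetError(f"stable ids not in matrix: {sorted(missing)[:5]}")
    V = expr.values.to_numpy()
    if not np.all(np.isfinite(V)):
        raise ValidationError("expression values must be finite")
    stable_idx = expr.values.index.get_indexer(stable_ids)
    S = V[stable_idx, :]
    ref = np.sort(S, axis=0).mean(axis=1)
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        s = S[:, j]
        order = np.argsort(s, kind="stable")
        anchor_y_full = np.empty_like(ref)
        anchor_y_full[:] = ref
        x_sorted = s[order]
        # collapse tied anchor x-values to the mean reference of their ranks
        uniq_x, inv = np.unique(x_sorted, return_inverse=True)
        sums = np.bincount(inv, weights=anchor_y_full)
        cnts = np.bincount(inv)
        uniq_y = sums / cnts
        v = V[:, j]
        y = np.interp(v, uniq_x, uniq_y)
        below = v < uniq_x[0]
        above = v > uniq_x[-1]
        y[below] = v[below] + (uniq_y[0] - uniq_x[0])
        y[above] = v[above] + (uniq_y[-1] - uniq_x[-1])
        out[:, j] = y
    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=values, method_tag="sbq", samples=list(expr.samples))


def _per_group_rma(
    plm: ProbeLevelMatrix, **rma_kwargs
) -> tuple[pd.DataFrame, dict[str, list[str]], list]:
    """RMA each replicate group separately; reassemble in sample order."""
    groups: dict[str, list[str]] = {}
    for s in plm.samples:
        groups.setdefault(s.replicate_group, []).append(s.sample_id)
    pieces = {}
    for g, sids in groups.items():
        sub = plm.subset_arrays(sids)
        pieces[g] = rma_summarize(sub, **rma_kwargs).values
    values = pd.concat([pieces[g] for g in groups], axis=1)
    values = values[plm.sample_ids]
    return values, groups, list(plm.samples)


def _scale_groups_to_anchor(
    values: pd.DataFrame,
    groups: dict[str, list[str]],
    anchor_ids: list[str],
    anchor_name: str,
) -> tuple[pd.DataFrame, ScalingReport]:
    """Shift each group additively so its anchor median hits the grand median."""
    stats = {
        g: float(np.median(values.loc[anchor_ids, sids].to_numpy()))
        for g, sids in groups.items()
    }
    target = float(np.median(list(stats.values())))
    report = ScalingReport(anchor=anchor_name, anchor_n=len(anchor_ids))
    out = values.copy()
    for g, sids in groups.items():
        offset = target - stats[g]
        out.loc[:, sids] = out.loc[:, sids] + offset
        report.offsets[g] = offset
    return out, report


def rmaps_normalize(
    plm: ProbeLevelMatrix,
    detection: DetectionCalls,
    **rma_kwargs,
) -> tuple[ExpressionMatrix, ScalingReport]:
    """RMA per replicate group + median-absent-probe-set scaling.

    The anchor set is the probe sets called Absent in every array of every
    sampled condition; their median log2 level is assumed comparable across
    conditions, so each group is shifted by one additive constant to
    equalize it.  A single replicate group passes through with zero offset.
    """
    values, groups, samples = _per_group_rma(plm, **rma_kwargs)
    if len(groups) < 2:
        report = ScalingReport(anchor="median_absent", anchor_n=0,
                               offsets={g: 0.0 for g in groups})
        return (
            ExpressionMatrix(values=values, method_tag="rmaps", samples=samples),
            report,
        )
    absent = [p for p in detection.absent_everywhere() if p in values.index]
    if not absent:
        raise EmptyAbsentSetError(
            "no probe set is Absent in every array; RMAPS is inapplicable — "
            "use RIMS or SBQ instead"
        )
    values, report = _scale_groups_to_anchor(values, groups, absent, "median_absent")
    return (
        ExpressionMatrix(values=values, method_tag="rmaps", samples=samples),
        report,
    )


def rims_normalize(
    plm: ProbeLevelMatrix,
    invariant_ids: list[str],
    **rma_kwargs,
) -> tuple[ExpressionMatrix, ScalingReport]:
    """RMA per replicate group + invariant-gene median scaling."""
    missing = set(invariant_ids) - set(plm.probesets)
    if missing:
        raise UnknownProbeSetError(
            f"invariant ids not on the array: {sorted(missing)[:5]}"
        )
    if len(invariant_ids) < 10:
        raise InsufficientStableGenesError(
            f"RIMS needs >= 10 invariant genes, got {len(invariant_ids)}"
        )
    values, groups, samples = _per_group_rma(plm, **rma_kwargs)
    if len(groups) < 2:
        report = ScalingReport(anchor="median_invariant", anchor_n=len(invariant_ids),
                               offsets={g: 0.0 for g in groups})
        return (
            ExpressionMatrix(values=values, method_tag="rims", samples=samples),
            report,
        )
    values, report = _scale_groups_to_anchor(
        values, groups, list(invariant_ids), "median_invariant"
    )
    return (
        ExpressionMatrix(values=values, method_tag="rims", samples=samples),
        report,
    )


def select_invariants(
    expr: ExpressionMatrix, cv_threshold: float = 0.10, *, linear_scale: bool = True
) -> list[str]:
    """Probe sets with coefficient of variation strictly below the threshold.

    CV = sample standard deviation / mean, computed by default on the
    linear scale (2^log2 values) across all arrays; set
    ``linear_scale=False`` to compute it on the log2 values directly.
    """
    if len(expr.sample_ids) < 3:
        raise ValidationError("invariant selection needs >= 3 arrays")
    X = expr.values.to_numpy()
    if linear_scale:
        X = 2.0 ** X
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    cv = np.divide(sd, np.abs(mean), out=np.full(len(mean), np.inf),
                   where=mean != 0)
    return [p for p, c in zip(expr.probesets, cv) if c < cv_threshold]


def median_scale_rows(expr: ExpressionMatrix) -> pd.DataFrame:
    """Subtract each probe-set row's median log2 value (heat-map scaling)."""
    V = expr.values
    return V.sub(V.median(axis=1), axis=0)
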