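"""Downstream expression analysis for gene-family cataloging.

Detection-based expression catalogs (expressed / unique-to-one-tissue /
constitutive classes and Venn counts), differential expression with
Benjamini-Hochberg q-values, Pearson co-expression screening, average-
linkage (UPGMA) hierarchical clustering with a deterministic tie-break,
and geNorm-style reference-gene stability ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UnknownProbeSetError, ValidationError
from .model import AnalysisConfig, DetectionCalls, ExpressionMatrix, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCatalog",
    "DEResult",
    "StabilityRanking",
    "ClusterResult",
    "catalog_expression",
    "venn_counts",
    "differential_expression",
    "coexpression_screen",
    "cluster_expression",
    "genorm_stability",
    "plot_expression_heatmap",
]


@dataclass
class ExpressionCatalog:
    """Per-tissue expressed flags and tissue-specificity class labels.

    ``flags`` is probe sets x tissues (bool); ``classes`` maps each probe
    set to one of ``constitutive`` (expressed in all tissues),
    ``unique_to_one_tissue``, ``multi_tissue`` or ``not_expressed``;
    ``unique_tissue`` records the tissue for unique cases.
    """

    flags: pd.DataFrame
    classes: pd.Series
    unique_tissue: pd.Series

    @property
    def tissues(self) -> list[str]:
        return list(self.flags.columns)

    def expressed_in(self, tissue: str) -> list[str]:
        if tissue not in self.flags.columns:
            raise ValidationError(f"unknown tissue {tissue!r}")
        return list(self.flags.index[self.flags[tissue]])


def catalog_expression(
    calls: DetectionCalls,
    samples: list[SampleMeta],
    config: AnalysisConfig | None = None,
) -> ExpressionCatalog:
    """Catalog expression from replicate detection calls.

    A probe set is "expressed" in a tissue iff it is called Present in at
    least ``config.expressed_rule_min_present`` of that tissue's
    replicates (majority rule by default, robust to one failed
    hybridization).
    """
    config = config or AnalysisConfig()
    by_tissue: dict[str, list[str]] = {}
    for s in samples:
        by_tissue.setdefault(s.tissue, []).append(s.sample_id)
    for tissue, sids in by_tissue.items():
        if not sids:
            raise ValidationError(f"tissue {tissue!r} has no arrays")
    present = calls.present_mask()
    flags = pd.DataFrame(
        {
            tissue: present[sids].sum(axis=1) >= config.expressed_rule_min_present
            for tissue, sids in by_tissue.items()
        },
        index=calls.calls.index,
    )
    n_tissues = flags.shape[1]
    n_expr = flags.sum(axis=1)
    classes = pd.Series("multi_tissue", index=flags.index)
    classes[n_expr == 0] = "not_expressed"
    if n_tissues > 1:
        classes[n_expr == n_tissues] = "constitutive"
    classes[n_expr == 1] = "unique_to_one_tissue"
    unique_tissue = pd.Series(None, index=flags.index, dtype=object)
    uniq = flags.index[n_expr == 1]
    unique_tissue[uniq] = flags.loc[uniq].idxmax(axis=1)
    return ExpressionCatalog(flags=flags, classes=classes, unique_tissue=unique_tissue)


def venn_counts(
    catalog: ExpressionCatalog, tissue_sets: dict[str, list[str]]
) -> dict[tuple[str, ...], int]:
    """Counts per exclusive region of the set diagram over named tissue groups.

    A probe set belongs to a named set if it is expressed in at least one
    of its tissues.  Keys are sorted tuples of the set names a region
    belongs to; the empty region is omitted, so values sum to the union
    size.
    """
    if len(tissue_sets) > 4:
        raise ValidationError("venn_counts supports at most 4 sets")
    known = set(catalog.tissues)
    membership = {}
    for name, tissues in tissue_sets.items():
        unknown = set(tissues) - known
        if unknown:
            raise ValidationError(f"unknown tissue name(s): {sorted(unknown)}")
        membership[name] = catalog.flags[list(tissues)].any(axis=1)
    memb = pd.DataFrame(membership)
    regions: dict[tuple[str, ...], int] = {}
    names = list(tissue_sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            in_all = memb[list(combo)].all(axis=1)
            out_rest = ~memb[[n for n in names if n not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=memb.index)
            regions[tuple(sorted(combo))] = int((in_all & out_rest).sum())
    return regions


@dataclass
class DEResult:
    """Per-probe-set differential expression results.

    ``table`` columns: ``lfc`` (log2 fold change, second group minus
    first; NaN for >2 groups), ``pvalue``, ``qvalue`` (Benjamini-Hochberg)
    and ``significant`` (q < de_alpha).  ``group_means`` holds per-level
    means for the ANOVA case.
    """

    table: pd.DataFrame
    group_means: pd.DataFrame
    de_alpha: float

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    design: dict[str, list[str]],
    config: AnalysisConfig | None = None,
    *,
    equal_var: bool = True,
) -> DEResult:
    """Two-sided t-test (2 groups) or one-way ANOVA (k > 2) per probe set.

    ``design`` maps group names to sample_ids.  The two-group test is the
    pooled-variance Student t by default — with 3 replicates per group
    the pooled estimate is what keeps power usable; pass
    ``equal_var=False`` for Welch.  Probe sets with zero variance in
    every group and equal means get p = 1.  Raw p-values are BH-corrected
    into q-values; the significance flag is q < de_alpha.
    """
    config = config or AnalysisConfig()
    if len(design) < 2:
        raise ValidationError("need at least two groups")
    for g, sids in design.items():
        if len(sids) < 2:
            raise ValidationError(f"group {g!r} has < 2 replicates")
    groups = [expr.values[sids].to_numpy() for sids in design.values()]
    means = {g: expr.values[sids].mean(axis=1) for g, sids in design.items()}
    group_means = pd.DataFrame(means)
    if len(groups) == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(groups[0], groups[1], axis=1,
                                   equal_var=equal_var)
        lfc = (group_means.iloc[:, 1] - group_means.iloc[:, 0]).to_numpy()
        # 0/0 statistic: no variance and no mean difference -> no evidence
        p = np.where(np.isnan(p), 1.0, p)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.f_oneway(*groups, axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        lfc = np.full(len(expr.probesets), np.nan)
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {"lfc": lfc, "pvalue": p, "qvalue": q, "significant": q < config.de_alpha},
        index=expr.values.index,
    )
    return DEResult(table=table, group_means=group_means, de_alpha=config.de_alpha)


def coexpression_screen(
    expr: ExpressionMatrix,
    seed_probeset: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Genes co-regulated with a seed: Pearson r > 0 and r^2 >= threshold.

    Returns a DataFrame (probeset_id index, columns ``r`` and ``r2``)
    sorted by r descending.  The positive-r restriction encodes
    "co-regulated" as same-direction regulation; anti-correlated genes
    are excluded even though their r^2 passes.
    """
    config = config or AnalysisConfig()
    if seed_probeset not in expr.values.index:
        raise UnknownProbeSetError(f"seed {seed_probeset!r} not in matrix")
    if len(expr.sample_ids) < 3:
        raise ValidationError("co-expression screening needs >= 3 arrays")
    seed = expr.values.loc[seed_probeset].to_numpy()
    if np.std(seed) == 0:
        raise ValidationError("seed probe set has zero variance")
    X = expr.values.to_numpy()
    xc = X - X.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (sc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ sc) / denom, 0.0)
    keep = (r > 0) & (r ** 2 >= config.coexpression_r2_threshold)
    out = pd.DataFrame({"r": r[keep], "r2": r[keep] ** 2},
                       index=expr.values.index[keep])
    return out.sort_values("r", ascending=False)


@dataclass
class ClusterResult:
    """UPGMA merge tree over probe-set rows.

    ``merges`` lists (members_a, members_b, height) with members as sorted
    tuples of row ids; ``linkage`` is a scipy-compatible (n-1, 4) matrix;
    ``leaf_order`` is the dendrogram leaf ordering for heat maps.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    linkage: np.ndarray
    leaf_order: list[str]


def cluster_expression(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering with Pearson distance d = 1 - r.

    Ties in the minimum distance are broken lexicographically on the
    sorted member identifiers of the candidate pair, making the merge
    sequence deterministic.  Zero-variance rows get r = 0 (d = 1) against
    everything, with a logged warning.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("clustering needs >= 2 rows")
    ids = [str(i) for i in matrix.index]
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        logger.warning("%d zero-variance row(s): correlations set to 0",
                       int((sd == 0).sum()))
    xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc @ xc.T) / np.outer(norms, norms)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr

    n = len(ids)
    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    D[:n, :n] = dist
    np.fill_diagonal(D, np.inf)
    members: list[tuple[str, ...]] = [(ids[i],) for i in range(n)]
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    alive = np.zeros(total, dtype=bool)
    alive[:n] = True
    merges = []
    linkage_rows = []
    children: dict[int, tuple[int, int]] = {}
    for new in range(n, total):
        act = np.flatnonzero(alive)
        sub = D[np.ix_(act, act)]
        h = float(sub.min())
        ti, tj = np.where(sub == h)
        # tie-break: lexicographically smallest sorted member tuple of the pair
        best = None
        for x, y in zip(ti, tj):
            if x >= y:
                continue
            a, b = int(act[x]), int(act[y])
            cand = tuple(sorted(members[a] + members[b]))
            if best is None or cand < best[0]:
                best = (cand, a, b)
        merged_members, a, b = best
        ma, mb = members[a], members[b]
        merges.append((min(ma, mb), max(ma, mb), h))
        linkage_rows.append([a, b, h, int(sizes[a] + sizes[b])])
        children[new] = (a, b) if min(ma) <= min(mb) else (b, a)
        rest = act[(act != a) & (act != b)]
        D[new, rest] = D[rest, new] = (
            sizes[a] * D[a, rest] + sizes[b] * D[b, rest]
        ) / (sizes[a] + sizes[b])
        members.append(merged_members)
        sizes[new] = sizes[a] + sizes[b]
        alive[a] = alive[b] = False
        alive[new] = True

    leaf_names = {i: ids[i] for i in range(n)}

    def _leaves(node: int) -> list[str]:
        if node < n:
            return [leaf_names[node]]
        left, right = children[node]
        return _leaves(left) + _leaves(right)

    leaf_order = _leaves(total - 1)
    return ClusterResult(
        merges=merges,
        linkage=np.array(linkage_rows, dtype=float),
        leaf_order=leaf_order,
    )


@dataclass
class StabilityRanking:
    """geNorm-style expression-stability ranking (lower M = more stable)."""

    table: pd.DataFrame  # columns: M, rank; ascending in M
    exclusion_order: list[str] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)


def genorm_stability(
    expr: pd.DataFrame, *, iterative: bool = False
) -> StabilityRanking:
    """Reference-gene stability M from pairwise log-ratio variation.

    ``expr`` is genes x samples on the *linear* scale (the original
    method's convention).  For each gene pair (j, k) the per-sample log2
    ratios A_jk have sample standard deviation V_jk; a gene's stability
    M_j is the mean of V_jk over all other genes.  With
    ``iterative=True`` the least stable gene is repeatedly excluded and
    the order recorded.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 3:
        raise ValidationError("need >= 3 candidate genes and >= 3 samples")
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValidationError("expression values must be positive and finite")
    L = np.log2(X)

    def m_values(log_x: np.ndarray) -> np.ndarray:
        g = log_x.shape[0]
        M = np.empty(g)
        for j in range(g):
            ratios = log_x[j][None, :] - log_x  # A_jk per sample, all k
            v = ratios.std(axis=1, ddof=1)
            M[j] = v[np.arange(g) != j].mean()
        return M

    M = m_values(L)
    order = np.argsort(M, kind="stable")
    table = pd.DataFrame(
        {"M": M[order], "rank": np.arange(1, len(M) + 1)},
        index=expr.index[order],
    )
    exclusion: list[str] = []
    if iterative:
        idx = list(range(L.shape[0]))
        while len(idx) > 2:
            M_cur = m_values(L[idx])
            worst = int(np.argmax(M_cur))
            exclusion.append(str(expr.index[idx[worst]]))
            idx.pop(worst)
    return StabilityRanking(table=table, exclusion_order=exclusion)


def plot_expression_heatmap(
    matrix: pd.DataFrame,
    path: str,
    *,
    cluster_rows: bool = True,
    title: str | None = None,
) -> None:
    """Render a magenta/white/green heat map of (row-median-scaled) values.

    Magenta marks high transcript abundance relative to the row median,
    green low, white average.  Rows are UPGMA-ordered by default.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    data = matrix
    if cluster_rows and matrix.shape[0] >= 2:
        order = cluster_expression(matrix).leaf_order
        data = matrix.loc[order]
    cmap = LinearSegmentedColormap.from_list(
        "green_white_magenta", ["#00a000", "#ffffff", "#d000d0"]
    )
    vmax = float(np.abs(data.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * data.shape[1] + 2), max(3, 0.08 * data.shape[0] + 1))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), labels=data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 relative to row median")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
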