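"""Domain types and TSV readers/writers for the boutique-array data model.

The chip model is an Affymetrix-style custom array: each probe set
interrogates one transcript with ``probes_per_set`` perfect-match (PM) /
single-mismatch (MM) probe pairs.  Probe-level intensities are stored on
the linear scale; all log2 transforms happen inside operations.

File dialects (tab-separated, UTF-8, ``#``-prefixed comment lines ignored):

* probe-level: ``probeset_id, probe_index, sample_id, pm, mm`` — one row
  per probe per array;
* annotation: ``probeset_id, species, category, suffix_class, gene_ids``
  (gene_ids semicolon-delimited);
* sample metadata: ``sample_id, tissue, condition, replicate_group,
  replicate_index``;
* expression matrix: ``# method=<tag>`` comment, then a header row of
  sample ids and one row per probe set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    MalformedHeaderError,
    NonPositiveIntensityError,
    ProbeCountError,
    UnknownProbeSetError,
    ValidationError,
)

__all__ = [
    "Species",
    "Category",
    "SuffixClass",
    "ProbeSetAnnotation",
    "SampleMeta",
    "ProbeLevelMatrix",
    "ExpressionMatrix",
    "DetectionCalls",
    "DetectionParams",
    "AnalysisConfig",
    "read_annotation",
    "write_annotation",
    "read_samples",
    "write_samples",
    "read_probe_level",
    "write_probe_level",
    "read_expression",
    "write_expression",
    "read_calls",
    "write_calls",
]


class Species(str, Enum):
    ARABIDOPSIS = "arabidopsis"
    MEDICAGO = "medicago"


class Category(str, Enum):
    DEFL = "defl"
    MEG = "meg"
    MARKER = "marker"
    INVARIANT = "invariant"
    CONTROL = "control"


class SuffixClass(str, Enum):
    """Cross-hybridization suffix semantics of Affymetrix probe-set names."""

    UNIQUE = "unique"        # "_at": probes match a single transcript
    SHARED = "shared"        # "_s_at": probes shared by gene-family members
    CROSS_HYB = "cross_hyb"  # "_x_at": probes may cross-hybridize


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one hybridized array (one biological sample)."""

    sample_id: str
    tissue: str
    condition: str
    replicate_group: str
    replicate_index: int


class ProbeSetAnnotation:
    """The chip description: one record per probe set.

    Parameters
    ----------
    records : DataFrame
        Columns ``probeset_id, species, category, suffix_class, gene_ids``;
        ``gene_ids`` is a list of strings.
    """

    COLUMNS = ("probeset_id", "species", "category", "suffix_class", "gene_ids")

    def __init__(self, records: pd.DataFrame):
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise MalformedHeaderError(f"annotation missing columns: {sorted(missing)}")
        if records["probeset_id"].duplicated().any():
            dup = records.loc[records["probeset_id"].duplicated(), "probeset_id"].iloc[0]
            raise ValidationError(f"duplicate probeset_id in annotation: {dup!r}")
        tbl = records.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        tbl["species"] = tbl["species"].map(Species)
        tbl["category"] = tbl["category"].map(Category)
        tbl["suffix_class"] = tbl["suffix_class"].map(SuffixClass)
        self.table = tbl
        self._index = {p: i for i, p in enumerate(tbl["probeset_id"])}

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.table["probeset_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self._index

    def category_of(self, probeset_id: str) -> Category:
        return self.table.loc[self._index[probeset_id], "category"]

    def ids_in_category(self, category: Category | str) -> list[str]:
        category = Category(category)
        mask = self.table["category"] == category
        return list(self.table.loc[mask, "probeset_id"])

    def subset(self, probeset_ids: Sequence[str]) -> "ProbeSetAnnotation":
        """Restrict to ``probeset_ids``, preserving annotation order."""
        wanted = set(probeset_ids)
        unknown = wanted - set(self._index)
        if unknown:
            raise UnknownProbeSetError(f"unknown probeset_id(s): {sorted(unknown)[:5]}")
        mask = self.table["probeset_id"].isin(wanted)
        tbl = self.table.loc[mask].copy()
        tbl["species"] = tbl["species"].map(lambda s: s.value)
        tbl["category"] = tbl["category"].map(lambda c: c.value)
        tbl["suffix_class"] = tbl["suffix_class"].map(lambda s: s.value)
        return ProbeSetAnnotation(tbl)


@dataclass
class ProbeLevelMatrix:
    """PM and MM intensities, probes x arrays, probe-set-major row order.

    Row ``i*probes_per_set + j`` holds probe ``j`` of probe set
    ``probesets[i]``.  Intensities are linear-scale, strictly positive.
    """

    probesets: list[str]
    probes_per_set: int
    pm: np.ndarray
    mm: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_rows = len(self.probesets) * self.probes_per_set
        if self.pm.shape != self.mm.shape:
            raise ValidationError(
                f"pm shape {self.pm.shape} != mm shape {self.mm.shape}"
            )
        if self.pm.shape != (n_rows, len(self.samples)):
            raise ValidationError(
                f"expected shape {(n_rows, len(self.samples))}, got {self.pm.shape}"
            )
        for name, arr in (("pm", self.pm), ("mm", self.mm)):
            if not np.all(np.isfinite(arr)):
                raise NonPositiveIntensityError(f"{name} contains non-finite values")
            if np.any(arr <= 0):
                raise NonPositiveIntensityError(f"{name} contains non-positive values")
        pairs = [(s.replicate_group, s.replicate_index) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("(replicate_group, replicate_index) pairs not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_arrays(self) -> int:
        return len(self.samples)

    def block_slice(self, i: int) -> slice:
        """Row slice of probe set ``i`` (probe-set-major storage)."""
        return slice(i * self.probes_per_set, (i + 1) * self.probes_per_set)

    def pm_stack(self) -> np.ndarray:
        """PM reshaped to (probe sets, probes_per_set, arrays)."""
        return self.pm.reshape(len(self.probesets), self.probes_per_set, -1)

    def mm_stack(self) -> np.ndarray:
        return self.mm.reshape(len(self.probesets), self.probes_per_set, -1)

    def subset_probesets(self, probeset_ids: Sequence[str]) -> "ProbeLevelMatrix":
        """Keep the given probe sets, in current storage order."""
        wanted = set(probeset_ids)
        unknown = wanted - set(self.probesets)
        if unknown:
            raise UnknownProbeSetError(f"unknown probeset_id(s): {sorted(unknown)[:5]}")
        keep_idx = [i for i, p in enumerate(self.probesets) if p in wanted]
        rows = np.concatenate([np.arange(self.block_slice(i).start, self.block_slice(i).stop)
                               for i in keep_idx])
        return ProbeLevelMatrix(
            probesets=[self.probesets[i] for i in keep_idx],
            probes_per_set=self.probes_per_set,
            pm=self.pm[rows],
            mm=self.mm[rows],
            samples=list(self.samples),
        )

    def subset_arrays(self, sample_ids: Sequence[str]) -> "ProbeLevelMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [order[s] for s in sample_ids]
        return ProbeLevelMatrix(
            probesets=list(self.probesets),
            probes_per_set=self.probes_per_set,
            pm=self.pm[:, cols],
            mm=self.mm[:, cols],
            samples=[self.samples[i] for i in cols],
        )


METHOD_TAGS = ("raw_summary", "rma", "sbq", "rmaps", "rims")


@dataclass
class ExpressionMatrix:
    """Summarized log2 expression, probe sets x arrays.

    ``values`` is a DataFrame indexed by probeset_id with sample_id columns.
    ``method_tag`` records the normalization that produced it.
    """

    values: pd.DataFrame
    method_tag: str
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.method_tag not in METHOD_TAGS:
            raise ValidationError(
                f"method_tag {self.method_tag!r} not in {METHOD_TAGS}"
            )
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValidationError("expression columns do not match sample metadata")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("expression values must be finite")

    @property
    def probesets(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> dict[str, list[str]]:
        """Replicate-group name -> sample_ids, in first-seen order."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.replicate_group, []).append(s.sample_id)
        return out

    def with_values(self, values: pd.DataFrame, method_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, method_tag=method_tag or self.method_tag,
                                samples=list(self.samples))


@dataclass
class DetectionCalls:
    """Present/Marginal/Absent call and detection p-value per probe set per array."""

    calls: pd.DataFrame     # entries in {"P", "M", "A"}
    pvalues: pd.DataFrame   # entries in [0, 1]

    def __post_init__(self) -> None:
        if self.calls.shape != self.pvalues.shape:
            raise ValidationError("calls and pvalues shapes differ")
        bad = ~self.calls.isin(["P", "M", "A"]).to_numpy()
        if bad.any():
            raise ValidationError("calls must be one of P, M, A")
        p = self.pvalues.to_numpy()
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValidationError("detection p-values must lie in [0, 1]")

    def absent_everywhere(self) -> list[str]:
        """Probe sets called A in every array of every condition."""
        mask = (self.calls == "A").all(axis=1)
        return list(self.calls.index[mask])

    def present_mask(self) -> pd.DataFrame:
        return self.calls == "P"


@dataclass(frozen=True)
class DetectionParams:
    """MAS5 detection-call parameters.

    alpha1/alpha2 split the one-sided signed-rank p-value into
    Present (p < alpha1), Marginal (alpha1 <= p < alpha2) and Absent;
    tau is the discrimination-score threshold.  alpha1 defaults to 0.05,
    the recommended value for 11 probe pairs per probe set; alpha2 and
    tau keep the vendor defaults.
    """

    alpha1: float = 0.05
    alpha2: float = 0.065
    tau: float = 0.015

    def __post_init__(self) -> None:
        if not (0 < self.alpha1 < self.alpha2 < 0.5):
            raise ValidationError("require 0 < alpha1 < alpha2 < 0.5")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for the downstream expression analysis."""

    invariant_cv_threshold: float = 0.10
    coexpression_r2_threshold: float = 0.70
    de_alpha: float = 0.05
    expressed_rule_min_present: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("invariant_cv_threshold", "coexpression_r2_threshold", "de_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")
        if self.expressed_rule_min_present < 1:
            raise ValidationError("expressed_rule_min_present must be >= 1")


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path: str | Path, expected_cols: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != list(expected_cols):
        raise MalformedHeaderError(
            f"{path}: expected columns {list(expected_cols)}, got {list(df.columns)}"
        )
    return df


def read_annotation(path: str | Path) -> ProbeSetAnnotation:
    df = _read_tsv(path, ProbeSetAnnotation.COLUMNS)
    df["gene_ids"] = df["gene_ids"].fillna("").map(
        lambda s: [g for g in s.split(";") if g]
    )
    return ProbeSetAnnotation(df)


def write_annotation(annot: ProbeSetAnnotation, path: str | Path) -> None:
    df = annot.table.copy()
    df["species"] = df["species"].map(lambda s: s.value)
    df["category"] = df["category"].map(lambda c: c.value)
    df["suffix_class"] = df["suffix_class"].map(lambda s: s.value)
    df["gene_ids"] = df["gene_ids"].map(";".join)
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[SampleMeta]:
    cols = ("sample_id", "tissue", "condition", "replicate_group", "replicate_index")
    df = _read_tsv(path, cols)
    return [
        SampleMeta(r.sample_id, r.tissue, r.condition, r.replicate_group,
                   int(r.replicate_index))
        for r in df.itertuples()
    ]


def write_samples(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(path, sep="\t", index=False)


def read_probe_level(
    path: str | Path,
    annotation: ProbeSetAnnotation,
    samples: Sequence[SampleMeta] | None = None,
    probes_per_set: int = 11,
) -> ProbeLevelMatrix:
    """Read a probe-level TSV into a validated :class:`ProbeLevelMatrix`.

    Row order in the result is probe-set-major in annotation order.  If
    ``samples`` is omitted, minimal metadata is synthesized from the
    sample ids found in the file.
    """
    df = _read_tsv(path, ("probeset_id", "probe_index", "sample_id", "pm", "mm"))
    df["probe_index"] = df["probe_index"].astype(int)
    df["pm"] = df["pm"].astype(float)
    df["mm"] = df["mm"].astype(float)

    unknown = set(df["probeset_id"]) - set(annotation.probeset_ids)
    if unknown:
        raise UnknownProbeSetError(f"unknown probeset_id(s): {sorted(unknown)[:5]}")

    present = set(df["probeset_id"])
    probesets = [p for p in annotation.probeset_ids if p in present]
    file_sample_ids = list(dict.fromkeys(df["sample_id"]))
    if samples is None:
        samples = [SampleMeta(s, s, s, s, 1) for s in file_sample_ids]
    else:
        samples = list(samples)
        if {s.sample_id for s in samples} != set(file_sample_ids):
            raise ValidationError("sample metadata does not match file sample ids")
    sample_ids = [s.sample_id for s in samples]

    counts = df.groupby(["probeset_id", "sample_id"]).size()
    if (counts != probes_per_set).any():
        bad = counts[counts != probes_per_set].index[0]
        raise ProbeCountError(
            f"probe set {bad[0]!r} sample {bad[1]!r}: expected "
            f"{probes_per_set} probes, got {counts[bad]}"
        )

    pm_wide = df.pivot_table(index=["probeset_id", "probe_index"], columns="sample_id",
                             values="pm", aggfunc="first")
    mm_wide = df.pivot_table(index=["probeset_id", "probe_index"], columns="sample_id",
                             values="mm", aggfunc="first")
    row_index = pd.MultiIndex.from_product([probesets, range(probes_per_set)],
                                           names=["probeset_id", "probe_index"])
    try:
        pm = pm_wide.reindex(row_index)[sample_ids].to_numpy()
        mm = mm_wide.reindex(row_index)[sample_ids].to_numpy()
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(str(exc)) from exc
    if np.isnan(pm).any() or np.isnan(mm).any():
        raise ProbeCountError("probe indices must be 0..probes_per_set-1 for every set")
    return ProbeLevelMatrix(probesets=probesets, probes_per_set=probes_per_set,
                            pm=pm, mm=mm, samples=samples)


def write_probe_level(plm: ProbeLevelMatrix, path: str | Path) -> None:
    """Write the probe-level TSV dialect with full float precision."""
    buf = io.StringIO()
    buf.write("probeset_id\tprobe_index\tsample_id\tpm\tmm\n")
    for i, ps in enumerate(plm.probesets):
        sl = plm.block_slice(i)
        for j, row in enumerate(range(sl.start, sl.stop)):
            for k, sid in enumerate(plm.sample_ids):
                buf.write(
                    f"{ps}\t{j}\t{sid}\t{float(plm.pm[row, k])!r}"
                    f"\t{float(plm.mm[row, k])!r}\n"
                )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={matrix.method_tag}\n")
        fh.write("probeset_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for ps, row in matrix.values.iterrows():
            fh.write(ps + "\t" + "\t".join(repr(float(v)) for v in row.to_numpy()) + "\n")


def read_expression(path: str | Path,
                    samples: Sequence[SampleMeta] | None = None) -> ExpressionMatrix:
    method_tag = "raw_summary"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# method="):
                method_tag = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "probeset_id"
    if samples is None:
        samples = [SampleMeta(c, c, c, c, 1) for c in df.columns]
    return ExpressionMatrix(values=df, method_tag=method_tag, samples=list(samples))


def write_calls(calls: DetectionCalls, path: str | Path) -> None:
    long = (
        calls.calls.stack().rename("call").to_frame()
        .join(calls.pvalues.stack().rename("pvalue"))
        .reset_index()
    )
    long.columns = ["probeset_id", "sample_id", "call", "pvalue"]
    long.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> DetectionCalls:
    df = _read_tsv(path, ("probeset_id", "sample_id", "call", "pvalue"))
    df["pvalue"] = df["pvalue"].astype(float)
    calls = df.pivot(index="probeset_id", columns="sample_id", values="call")
    pvals = df.pivot(index="probeset_id", columns="sample_id", values="pvalue")
    return DetectionCalls(calls=calls, pvalues=pvals)
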