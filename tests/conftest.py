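import numpy as np
import pandas as pd
import pytest

from boutiquenorm import (
    ExpressionMatrix,
    ProbeLevelMatrix,
    ProbeSetAnnotation,
    SampleMeta,
)


def make_annotation(probeset_ids, categories=None, species="arabidopsis"):
    categories = categories or ["defl"] * len(probeset_ids)
    return ProbeSetAnnotation(
        pd.DataFrame(
            {
                "probeset_id": probeset_ids,
                "species": species,
                "category": categories,
                "suffix_class": "unique",
                "gene_ids": [[f"g_{p}"] for p in probeset_ids],
            }
        )
    )


def make_samples(n, group="grp", tissue="leaf", condition="ctl"):
    return [
        SampleMeta(f"{group}_r{i+1}", tissue, condition, group, i + 1)
        for i in range(n)
    ]


def make_plm(pm, mm, probesets, samples, probes_per_set=11):
    return ProbeLevelMatrix(
        probesets=list(probesets),
        probes_per_set=probes_per_set,
        pm=np.asarray(pm, float),
        mm=np.asarray(mm, float),
        samples=samples,
    )


def make_expr(values, probesets, samples, tag="raw_summary"):
    df = pd.DataFrame(
        np.asarray(values, float),
        index=list(probesets),
        columns=[s.sample_id for s in samples],
    )
    df.index.name = "probeset_id"
    return ExpressionMatrix(values=df, method_tag=tag, samples=list(samples))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_plm(rng):
    """5 probe sets x 4 arrays of plausible raw intensities, 2 groups."""
    probesets = [f"ps{i}_at" for i in range(5)]
    samples = (
        make_samples(2, group="ctl", tissue="root", condition="ctl")
        + [
            SampleMeta(f"trt_r{i+1}", "nodule", "trt", "trt", i + 1)
            for i in range(2)
        ]
    )
    pm = rng.exponential(300, (55, 4)) + rng.normal(100, 10, (55, 4))
    mm = 0.3 * (pm - 100) + rng.normal(100, 10, (55, 4))
    pm = np.clip(pm, 1.0, None)
    mm = np.clip(mm, 1.0, None)
    return make_plm(pm, mm, probesets, samples)
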