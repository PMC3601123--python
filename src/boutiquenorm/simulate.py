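"""Probe-level microarray simulator with full ground truth.

Emulates the statistical structure a boutique gene-family array presents
to normalization: a few hundred probe sets of which a large fraction
shift together in one condition (e.g. family members induced in one
tissue), a block of invariant probe sets with linear-scale CV below 10%,
11 PM/MM probe pairs per probe set, and 3 biological replicates per
condition.  Intensities follow the exponential-signal-plus-Gaussian-
background convolution that RMA assumes: per-probe multiplicative
affinities are drawn once and shared across arrays, PM observes the true
signal plus background noise, MM observes a cross-hybridized fraction of
the signal plus background.

Everything is reproducible bit-for-bit from (config, seed), and the
returned :class:`SimulationTruth` carries the true per-condition and
per-array log2 expression for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    ProbeLevelMatrix,
    ProbeSetAnnotation,
    SampleMeta,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_experiment",
           "make_boutique_subset"]

# Additive background is truncated at this positive floor so intensities
# stay strictly positive; the truncation slightly raises the background
# mean for probes whose signal is near zero.
_INTENSITY_FLOOR = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults mirror a boutique family chip.

    The default composition — ~700 family probe sets, 171 invariants, a
    handful of markers, 11 probe pairs, 3 biological replicates per
    condition, and 70% of family genes strongly induced in the treated
    condition — reproduces the distribution-shift pathology that breaks
    whole-array normalization on such chips.
    """

    n_probesets: int = 700
    n_invariant: int = 171
    n_marker: int = 30
    probes_per_set: int = 11
    conditions: tuple[tuple[str, int], ...] = (("control", 3), ("treated", 3))
    shifted_condition: str = "treated"
    frac_shifted: float = 0.70
    effect_log2: float = 2.0
    tissue_frac_shifted: float = 0.20
    frac_never_expressed: float = 0.10
    unexpressed_log2: float = 0.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    invariant_log2_range: tuple[float, float] = (4.0, 10.0)
    probe_affinity_sd: float = 0.5
    bg_mu: float = 100.0
    bg_sd: float = 10.0
    mm_crosshyb: float = 0.10
    biological_sd_log2: float = 0.25
    invariant_sd_log2: float = 0.05
    array_gain_log2_sd: float = 0.50
    array_slope_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_probesets, self.probes_per_set) <= 0:
            raise ValidationError("counts must be positive")
        if self.n_invariant + self.n_marker > self.n_probesets:
            raise ValidationError("invariant + marker exceed n_probesets")
        for frac in (self.frac_shifted, self.mm_crosshyb,
                     self.frac_never_expressed, self.tissue_frac_shifted):
            if not (0 <= frac <= 1):
                raise ValidationError("fractions must lie in [0, 1]")
        for name in ("baseline_log2_sd", "probe_affinity_sd", "bg_sd",
                     "biological_sd_log2", "invariant_sd_log2",
                     "array_gain_log2_sd", "array_slope_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.shifted_condition not in {c for c, _ in self.conditions}:
            raise ValidationError("shifted_condition not among conditions")
        if any(n < 1 for _, n in self.conditions):
            raise ValidationError("every condition needs >= 1 replicate")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    condition_log2: pd.DataFrame   # genes x conditions, true mean log2
    sample_log2: pd.DataFrame      # genes x arrays, incl. biological noise
    shifted_ids: list[str]
    never_expressed_ids: list[str]
    effects: pd.Series             # effect in the designated condition
    effects_by_condition: pd.DataFrame  # genes x conditions
    affinities: np.ndarray         # (genes, probes_per_set) log2 affinities
    array_gain_log2: pd.Series     # per-array technical gain offset
    array_slope: pd.Series         # per-array intensity response slope
    config: SimulationConfig = field(repr=False, default=None)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    n_defl = config.n_probesets - config.n_invariant - config.n_marker
    inv = [f"inv{i:05d}_at" for i in range(config.n_invariant)]
    mrk = [f"mrk{i:05d}_at" for i in range(config.n_marker)]
    defl = [f"defl{i:05d}_at" for i in range(n_defl)]
    return inv, mrk, defl


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ProbeLevelMatrix, ProbeSetAnnotation, SimulationTruth]:
    """Generate a probe-level dataset plus annotation and ground truth.

    Per gene g and condition c the true log2 level is
    theta_gc = baseline_g + effect_g * 1[g shifted, c = shifted
    condition]; each replicate adds N(0, biological_sd) (invariant genes
    use the smaller invariant sd and zero effect, keeping their
    linear-scale CV below 10% in expectation).  Each array j carries a
    technical gain offset gamma_j and an intensity response slope b_j
    near 1, so the observed log2 signal of probe p on array j is
    gamma_j + b_j * (theta_g + affinity_p): arrays differ in brightness
    and in the shape of their response curve, which is what
    normalization must remove.  Probe intensities are then
    PM = signal + N(bg_mu, bg_sd) and MM = crosshyb-attenuated signal +
    N(bg_mu, bg_sd), both truncated at a positive floor.
    """
    rng = np.random.default_rng(config.seed)
    inv_ids, mrk_ids, defl_ids = _gene_ids(config)
    ids = inv_ids + mrk_ids + defl_ids
    n = len(ids)
    categories = (["invariant"] * len(inv_ids) + ["marker"] * len(mrk_ids)
                  + ["defl"] * len(defl_ids))
    annot = ProbeSetAnnotation(pd.DataFrame({
        "probeset_id": ids,
        "species": "arabidopsis",
        "category": categories,
        "suffix_class": "unique",
        "gene_ids": [[f"gene_{p}"] for p in ids],
    }))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    # invariant sets on real chips are picked to cover the intensity
    # range (they anchor quantile maps at every level); draw them uniform
    lo, hi = config.invariant_log2_range
    baseline[:config.n_invariant] = rng.uniform(lo, hi, config.n_invariant)
    # a fraction of family genes is never expressed in the sampled
    # conditions: near-zero signal in every array, hence Absent calls —
    # the anchor RMAPS relies on
    n_never = int(round(config.frac_never_expressed * len(defl_ids)))
    never_pick = rng.choice(len(defl_ids), size=n_never, replace=False)
    never_ids = sorted(defl_ids[i] for i in never_pick)
    id_pos = {p: i for i, p in enumerate(ids)}
    for p in never_ids:
        baseline[id_pos[p]] = config.unexpressed_log2
    expressed_defl = [p for p in defl_ids if p not in set(never_ids)]

    # the designated condition induces frac_shifted of expressed family
    # genes; every other condition expresses its own tissue-specific
    # subset (tissue_frac_shifted), mirroring family chips where each
    # tissue lights up different members
    cond_names = [c for c, _ in config.conditions]
    effects_by_condition = pd.DataFrame(0.0, index=ids, columns=cond_names)
    for c in cond_names:
        frac = (config.frac_shifted if c == config.shifted_condition
                else config.tissue_frac_shifted)
        n_s = int(round(frac * len(expressed_defl)))
        pick = rng.choice(len(expressed_defl), size=n_s, replace=False)
        effects_by_condition.loc[[expressed_defl[i] for i in pick], c] = (
            config.effect_log2
        )
    effects = effects_by_condition[config.shifted_condition]
    shifted_ids = sorted(effects.index[effects > 0])
    condition_log2 = effects_by_condition.add(baseline, axis=0)

    samples: list[SampleMeta] = []
    for cond, reps in config.conditions:
        for r in range(1, reps + 1):
            samples.append(SampleMeta(f"{cond}_r{r}", cond, cond, cond, r))

    is_inv = np.array([c == "invariant" for c in categories])
    bio_sd = np.where(is_inv, config.invariant_sd_log2, config.biological_sd_log2)
    theta = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        theta[:, j] = condition_log2[s.condition].to_numpy() + rng.normal(
            0.0, bio_sd, n
        )
    sample_log2 = pd.DataFrame(theta, index=ids,
                               columns=[s.sample_id for s in samples])

    affinities = rng.normal(0.0, config.probe_affinity_sd,
                            (n, config.probes_per_set))
    n_arr = len(samples)
    gains = rng.normal(0.0, config.array_gain_log2_sd, n_arr)
    slopes = rng.normal(1.0, config.array_slope_sd, n_arr)
    log_sig = theta[:, None, :] + affinities[:, :, None]
    pm_sig = 2.0 ** (gains + slopes * log_sig)
    mm_sig = 2.0 ** (gains + slopes * (np.log2(config.mm_crosshyb) + log_sig)) \
        if config.mm_crosshyb > 0 else np.zeros_like(pm_sig)
    shape = pm_sig.shape
    pm = np.maximum(pm_sig + rng.normal(config.bg_mu, config.bg_sd, shape),
                    _INTENSITY_FLOOR)
    mm = np.maximum(mm_sig + rng.normal(config.bg_mu, config.bg_sd, shape),
                    _INTENSITY_FLOOR)

    plm = ProbeLevelMatrix(
        probesets=ids,
        probes_per_set=config.probes_per_set,
        pm=pm.reshape(n * config.probes_per_set, len(samples)),
        mm=mm.reshape(n * config.probes_per_set, len(samples)),
        samples=samples,
    )
    truth = SimulationTruth(
        condition_log2=condition_log2,
        sample_log2=sample_log2,
        shifted_ids=shifted_ids,
        never_expressed_ids=never_ids,
        effects=effects,
        effects_by_condition=effects_by_condition,
        affinities=affinities,
        array_gain_log2=pd.Series(gains, index=[s.sample_id for s in samples]),
        array_slope=pd.Series(slopes, index=[s.sample_id for s in samples]),
        config=config,
    )
    return plm, annot, truth


def make_boutique_subset(
    plm: ProbeLevelMatrix,
    annot: ProbeSetAnnotation,
    truth: SimulationTruth,
    subset_size: int,
    invariant_keep: int,
    shifted_fraction: float = 0.70,
) -> tuple[ProbeLevelMatrix, ProbeSetAnnotation]:
    """Extract a boutique chip as a biased subset of a whole-array sim.

    Keeps the first ``invariant_keep`` invariant probe sets and fills the
    remaining slots with family genes, oversampling truly shifted genes
    to ``shifted_fraction`` of the non-invariant content (the boutique
    pathology: the chip is enriched for the very genes that move).  The
    non-shifted fill is stratified so never-expressed family members
    appear at their full-array proportion — a family chip carries its
    silent members too, which is what gives detection-based scaling
    (RMAPS) its always-absent anchor.  Selection is deterministic
    (first-k in annotation order within each stratum).
    """
    if subset_size > len(plm.probesets):
        raise ValidationError("subset_size exceeds available probe sets")
    inv_ids = annot.ids_in_category("invariant")
    if invariant_keep > len(inv_ids):
        raise ValidationError("invariant_keep exceeds available invariants")
    if subset_size == len(plm.probesets):
        return plm, annot
    keep = list(inv_ids[:invariant_keep])
    n_rest = subset_size - len(keep)
    if n_rest < 0:
        raise ValidationError("invariant_keep exceeds subset_size")
    n_shift = int(round(shifted_fraction * n_rest))
    shifted = [p for p in truth.shifted_ids if p in set(plm.probesets)]
    if n_shift > len(shifted):
        raise ValidationError(
            f"requested {n_shift} shifted genes, only {len(shifted)} available"
        )
    keep += shifted[:n_shift]
    chosen = set(keep) | set(inv_ids) | set(truth.shifted_ids)
    never = set(truth.never_expressed_ids)
    pool_never = [p for p in plm.probesets if p not in chosen and p in never]
    pool_expr = [p for p in plm.probesets if p not in chosen and p not in never]
    n_fill = n_rest - n_shift
    if n_fill > len(pool_never) + len(pool_expr):
        raise ValidationError("not enough unshifted genes to fill the subset")
    pool_total = len(pool_never) + len(pool_expr)
    n_fill_never = min(
        len(pool_never), int(round(n_fill * len(pool_never) / pool_total))
    )
    keep += pool_never[:n_fill_never]
    keep += pool_expr[: n_fill - n_fill_never]
    keep_ordered = [p for p in plm.probesets if p in set(keep)]
    return plm.subset_probesets(keep_ordered), annot.subset(keep_ordered)
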