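"""Synthetic methylation-array cohorts with planted carrier effects.

Emulates the statistical structure of a blood-cell EWAS study design:
a discovery cohort of mutation carriers vs wildtype controls assayed on
a bimodal beta-valued array, and prospective case-control cohorts drawn
from the same CpG universe with attenuated effects and right-censored
follow-up.  Effects are additive on the logit scale so betas stay in
(0, 1); per-CpG baselines come from a two-component logit-normal mixture
(unmethylated mode near beta 0.1, methylated mode near beta 0.85) to
mimic array bimodality.  Age, batch and cancer-status terms provide the
confounding the downstream regression is meant to adjust away, and a
polycomb-target-like gene set can be over-represented among the
hypermethylated planted CpGs to give the enrichment stage real signal.

A :class:`TruthTable` records which CpGs carry planted effects (and the
shared per-CpG baselines), serving as the recovery oracle for the rest
of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .methio import BetaMatrix, CpGAnnotation, GeneSetCollection, SampleSheet

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_annotation",
    "simulate_discovery",
    "simulate_prospective",
    "platform_subset",
]

# logit-normal mixture for per-CpG baselines; modes at beta ~0.1 / ~0.85
_UNMETH_MODE = logit(0.1)
_METH_MODE = logit(0.85)
_MODE_SD = 0.5
_METH_WEIGHT = 0.4  # fraction of CpGs in the methylated mode
# small per-CpG covariate slopes (logit units): confounders, not signal
_AGE_SLOPE_SD = 0.005   # per year
_CANCER_SLOPE_SD = 0.1


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters for one simulated discovery/validation run.

    Defaults are desk-scale: 5,000 CpGs, 72 carriers + 72 wildtype in
    discovery, 120 cases + 120 controls prospectively, 500 planted CpGs
    with a 57% hypermethylated direction mix.
    """

    n_cpgs: int = 5000
    n_carriers: int = 72
    n_wildtype: int = 72
    n_cases: int = 120
    n_controls: int = 120
    n_planted: int = 500
    hyper_fraction: float = 0.57
    effect_delta: float = 2.0
    attenuation: float = 0.5
    noise_sd: float = 1.0
    batch_sd: float = 0.3
    n_batches: int = 3
    age_range: tuple[float, float] = (40.0, 70.0)
    cancer_fraction: float = 0.5
    censor_rate: float = 0.8
    followup_max: float = 10.0
    pcgt_enrichment: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cpgs", "n_carriers", "n_wildtype", "n_cases",
                     "n_controls", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_planted < 0:
            raise ConfigError("n_planted must be >= 0")
        for name in ("hyper_fraction", "attenuation", "cancer_fraction",
                     "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.effect_delta < 0:
            raise ConfigError("effect_delta must be >= 0")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ConfigError("noise/batch SDs must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be (low, high)")
        if self.pcgt_enrichment < 1.0:
            raise ConfigError("pcgt_enrichment must be >= 1")


@dataclass
class TruthTable:
    """Ground truth of a simulated discovery cohort.

    Besides the planted CpG ids with their directions (+1 hyper / -1
    hypo in carriers) and logit-scale effect sizes, it carries the
    per-CpG baselines and covariate slopes of the simulated array so
    that prospective cohorts share the same platform.
    """

    planted_cpg_ids: list[str]
    direction: np.ndarray
    effect_size: np.ndarray
    cpg_ids: pd.Index = field(repr=False, default=None)
    baseline_logit: np.ndarray = field(repr=False, default=None)
    age_slope: np.ndarray = field(repr=False, default=None)
    cancer_slope: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=int)
        self.effect_size = np.asarray(self.effect_size, dtype=float)
        if not np.all(np.isin(self.direction, (-1, 1))):
            raise ValueError("directions must be +/-1")
        if len(self.planted_cpg_ids) != len(self.direction):
            raise ValueError("planted ids / direction length mismatch")

    @property
    def n_planted(self) -> int:
        return len(self.planted_cpg_ids)

    def as_series(self) -> pd.Series:
        """Signed effect per planted CpG (direction * effect size)."""
        return pd.Series(self.direction * self.effect_size,
                         index=pd.Index(self.planted_cpg_ids, name="cpg_id"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # all sub-streams derive deterministically from the one global seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _cpg_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:07d}" for i in range(n)], name="cpg_id")


def make_annotation(n_cpgs: int, n_genes: int, target_set_fraction: float,
                    seed: int) -> tuple[CpGAnnotation, GeneSetCollection]:
    """Random CpG -> gene map plus a polycomb-target-like gene set.

    Every CpG maps to exactly one gene and every gene receives at least
    one CpG.  The collection holds ``PCGT_like`` (``target_set_fraction``
    of the genes) plus two size-matched random decoy sets for
    null-enrichment comparisons.
    """
    if not 0.0 < target_set_fraction < 1.0:
        raise ConfigError("target_set_fraction must be in (0, 1)")
    if n_cpgs < 1 or n_genes < 1:
        raise ConfigError("n_cpgs and n_genes must be >= 1")
    if n_genes > n_cpgs:
        raise ConfigError(f"n_genes ({n_genes}) exceeds n_cpgs ({n_cpgs})")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100,)))
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    # first n_genes CpGs cover every gene once; the rest map at random
    assignment = np.concatenate([
        np.arange(n_genes), rng.integers(0, n_genes, size=n_cpgs - n_genes)])
    rng.shuffle(assignment)
    ann = CpGAnnotation(pd.DataFrame(
        {"gene_symbol": genes[assignment]}, index=_cpg_ids(n_cpgs)))
    set_size = max(1, round(target_set_fraction * n_genes))
    pcgt = rng.choice(genes, size=set_size, replace=False)
    sets = {"PCGT_like": frozenset(pcgt)}
    for k in range(2):
        decoy = rng.choice(genes, size=set_size, replace=False)
        sets[f"DECOY_like_{k + 1}"] = frozenset(decoy)
    desc = {"PCGT_like": "stem-cell polycomb-target-like genes",
            "DECOY_like_1": "random decoy set", "DECOY_like_2": "random decoy set"}
    return ann, GeneSetCollection(sets, desc)


def _plant_truth(config: SimConfig, rng: np.random.Generator,
                 annotation: CpGAnnotation | None,
                 gene_sets: GeneSetCollection | None) -> TruthTable:
    cpgs = _cpg_ids(config.n_cpgs)
    n_hyper = int(round(config.hyper_fraction * config.n_planted))
    n_hypo = config.n_planted - n_hyper
    weights = np.ones(config.n_cpgs)
    if annotation is not None and gene_sets is not None and "PCGT_like" in gene_sets.sets:
        pcgt = gene_sets["PCGT_like"]
        in_pcgt = annotation.data.reindex(cpgs)["gene_symbol"].isin(pcgt).to_numpy()
        weights[in_pcgt] = config.pcgt_enrichment
    order = np.arange(config.n_cpgs)
    hyper_idx = rng.choice(order, size=n_hyper, replace=False,
                           p=weights / weights.sum())
    remaining = np.setdiff1d(order, hyper_idx)
    hypo_idx = rng.choice(remaining, size=n_hypo, replace=False)
    planted = np.concatenate([hyper_idx, hypo_idx])
    direction = np.concatenate([np.ones(n_hyper, int), -np.ones(n_hypo, int)])
    srt = np.argsort(planted)
    return TruthTable(
        planted_cpg_ids=[cpgs[i] for i in planted[srt]],
        direction=direction[srt],
        effect_size=np.full(config.n_planted, config.effect_delta)[srt],
    )


def _baselines(config: SimConfig, rng: np.random.Generator):
    meth = rng.random(config.n_cpgs) < _METH_WEIGHT
    mode = np.where(meth, _METH_MODE, _UNMETH_MODE)
    baseline = mode + _MODE_SD * rng.standard_normal(config.n_cpgs)
    age_slope = _AGE_SLOPE_SD * rng.standard_normal(config.n_cpgs)
    cancer_slope = _CANCER_SLOPE_SD * rng.standard_normal(config.n_cpgs)
    return baseline, age_slope, cancer_slope


def _cohort_betas(config: SimConfig, truth: TruthTable, group: np.ndarray,
                  age: np.ndarray, batch: np.ndarray, cancer: np.ndarray,
                  effect_scale: float, rng: np.random.Generator) -> np.ndarray:
    n_samples = group.size
    n_cpgs = truth.baseline_logit.size
    signed = np.zeros(n_cpgs)
    planted_pos = truth.cpg_ids.get_indexer(truth.planted_cpg_ids)
    signed[planted_pos] = truth.direction * truth.effect_size * effect_scale
    batch_eff = config.batch_sd * rng.standard_normal((config.n_batches, n_cpgs))
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    eta = (
        truth.baseline_logit[:, None]
        + signed[:, None] * group[None, :]
        + batch_eff[batch, :].T
        + truth.age_slope[:, None] * (age - mid_age)[None, :]
        + truth.cancer_slope[:, None] * cancer[None, :]
        + config.noise_sd * rng.standard_normal((n_cpgs, n_samples))
    )
    return expit(eta)


def simulate_discovery(config: SimConfig,
                       annotation: CpGAnnotation | None = None,
                       gene_sets: GeneSetCollection | None = None,
                       ) -> tuple[BetaMatrix, SampleSheet, TruthTable]:
    """Simulate a carrier-vs-wildtype discovery cohort.

    Carriers receive the planted logit-scale shifts; batch, age and
    cancer-status act as confounders on all samples.  Passing the
    annotation and gene sets makes ``PCGT_like`` genes over-represented
    (by ``config.pcgt_enrichment``) among hypermethylated planted CpGs.
    """
    if config.n_planted > config.n_cpgs:
        raise ConfigError("n_planted exceeds n_cpgs")
    rng = _rng(config.seed, 1)
    truth = _plant_truth(config, rng, annotation, gene_sets)
    truth.cpg_ids = _cpg_ids(config.n_cpgs)
    truth.baseline_logit, truth.age_slope, truth.cancer_slope = _baselines(config, rng)

    n = config.n_carriers + config.n_wildtype
    group = np.concatenate([np.ones(config.n_carriers, int),
                            np.zeros(config.n_wildtype, int)])
    age = rng.uniform(*config.age_range, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    cancer = (rng.random(n) < config.cancer_fraction).astype(int)
    betas = _cohort_betas(config, truth, group, age, batch, cancer, 1.0, rng)

    samples = pd.Index([f"D{i:04d}" for i in range(n)], name="sample_id")
    matrix = BetaMatrix(pd.DataFrame(betas, index=truth.cpg_ids, columns=samples))
    sheet = SampleSheet(pd.DataFrame({
        "group": group, "age": age,
        "batch": [f"b{b + 1}" for b in batch], "cancer_status": cancer,
    }, index=samples))
    return matrix, sheet, truth


def simulate_prospective(config: SimConfig, truth: TruthTable,
                         ) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate a prospective case-control cohort on the same platform.

    Future cases carry ``attenuation * effect_size`` at the planted
    CpGs.  The sample sheet adds uniform follow-up times, an event flag
    for the uncensored subset of cases, and epidemiological factors
    drawn independently of case status.
    """
    if truth.cpg_ids is None or truth.baseline_logit is None:
        raise ValueError("truth table lacks platform bookkeeping; "
                         "use the table returned by simulate_discovery")
    if len(truth.cpg_ids) != config.n_cpgs:
        raise ValueError(
            f"CpG universe mismatch: truth has {len(truth.cpg_ids)}, "
            f"config expects {config.n_cpgs}")
    rng = _rng(config.seed, 2)
    n = config.n_cases + config.n_controls
    case = np.concatenate([np.ones(config.n_cases, int),
                           np.zeros(config.n_controls, int)])
    age = rng.uniform(*config.age_range, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    cancer = np.zeros(n, int)  # blood drawn before any diagnosis
    betas = _cohort_betas(config, truth, case, age, batch, cancer,
                          config.attenuation, rng)

    followup = rng.uniform(0.0, config.followup_max, size=n)
    event = (case == 1) & (rng.random(n) >= config.censor_rate)
    samples = pd.Index([f"P{i:04d}" for i in range(n)], name="sample_id")
    matrix = BetaMatrix(pd.DataFrame(betas, index=truth.cpg_ids, columns=samples))
    sheet = SampleSheet(pd.DataFrame({
        "group": case, "age": age,
        "batch": [f"b{b + 1}" for b in batch], "cancer_status": cancer,
        "followup_time": followup, "event": event.astype(int),
        "ocp_use": (rng.random(n) < 0.5).astype(int),
        "smoker": (rng.random(n) < 0.4).astype(int),
        "family_history": (rng.random(n) < 0.2).astype(int),
        "bmi": rng.normal(27.0, 5.0, size=n),
    }, index=samples))
    return matrix, sheet


def platform_subset(matrix: BetaMatrix, keep_fraction: float,
                    seed: int) -> BetaMatrix:
    """Random fixed-seed subset of CpG rows, emulating a platform change
    (e.g. a 27k-derived signature intersected with a 450k array)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ConfigError("keep_fraction must be in (0, 1]")
    n_rows = matrix.shape[0]
    n_keep = int(round(keep_fraction * n_rows))
    if n_keep == 0:
        raise ConfigError("keep_fraction rounds to zero rows")
    if n_keep == n_rows:
        return BetaMatrix(matrix.values.copy())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    keep = np.sort(rng.choice(n_rows, size=n_keep, replace=False))
    return BetaMatrix(matrix.values.iloc[keep])
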