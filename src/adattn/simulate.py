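"""Seeded synthetic clinical cohorts with latent subtype severities.

The study cohort behind the method (430 memory-clinic patients) is not
public, so this module generates cohorts with the statistical structure the
model assumes, latent-first: each patient draws a target overall-severity
level from a four-level mixture, then three subtype severities uniformly on
[0, 1]³ by rejection until their mean lands in that level's bin.  Features
are then caused by the severities:

* within each attention group, a seeded subset (``informative_fraction``) of
  features follows logistic(β·(a_g·s) + ε), ε ~ N(0, noise_sd), with a fixed
  group loading a_g over the three severities — the Logopenic signal
  concentrates in the biochemical group, Posterior Cortical Atrophy in the
  endocrine group, Frontal Variant in the lifestyle group, and the blood
  group carries a shared signal — then maps linearly into the feature's
  clinical reference range;
* the DIRECT markers are monotone in overall severity (β2-microglobulin
  increasing, MMSE decreasing) with slope scaled by β/5, so β = 0 renders
  every feature independent of the latents;
* demographics pinned by the study's descriptive table (age ~ N(77.22,
  8.87²), 50% female, 59.07% married, BMI ~ N(24.83, 7.16²), 21.16% smoking,
  11.16% drinking, 59.98% diabetes, 11.40% hypertension, disease duration
  log-normal with median 5.5 y) never carry subtype signal;
* the remaining features are in-range noise.

Missingness is injected cell-wise completely at random (MCAR).  Everything
is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ID_COLUMN, SUBTYPES, CohortTable
from .evaluate import SEVERITY_THRESHOLDS, bin_severity
from .schema import FeatureSchema, default_schema

# Demographic marginals of the study cohort (descriptive table):
# mean/sd for continuous, prevalence for binary, median for duration.
TABLE1_MARGINALS = {
    "age": ("normal", 77.22, 8.87),
    "sex": ("bernoulli", 0.50),  # female = 1
    "marriage": ("bernoulli", 0.5907),
    "BMI": ("normal", 24.83, 7.16),
    "smoking": ("bernoulli", 0.2116),
    "alcohol": ("bernoulli", 0.1116),
    "DM": ("bernoulli", 0.5998),
    "HT": ("bernoulli", 0.1140),
    "duration": ("lognormal_median", 5.5, 0.8),
}

# Fixed loading vectors over (lv, pca, fv): each subtype's signal concentrates
# in a different group; the blood group carries the shared signal.
GROUP_LOADINGS = {
    "G1_blood": np.array([1.0, 1.0, 1.0]) / 3.0,
    "G2_biochem": np.array([1.0, 0.0, 0.0]),
    "G3_endocrine": np.array([0.0, 1.0, 0.0]),
    "G4_lifestyle": np.array([0.0, 0.0, 1.0]),
}

# G4 features eligible to carry signal (the pinned demographics never do).
G4_INFORMATIVE_POOL = ("education", "CHD", "ADL")


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation knobs.

    ``beta`` is the signal strength linking severities to informative
    features (0 = pure noise); ``informative_fraction`` the share of each
    group's eligible features that carry signal; ``noise_sd`` the sd of the
    logit-scale noise; ``level_weights`` the mixture over the four true
    severity levels; ``missing_rate`` the MCAR cell-masking probability.
    """

    n: int = 430
    beta: float = 5.0
    informative_fraction: float = 0.5
    noise_sd: float = 0.1
    missing_rate: float = 0.02
    level_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeneratorError("n must be positive")
        if self.beta < 0:
            raise GeneratorError("beta must be >= 0")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise GeneratorError("informative_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise GeneratorError("missing_rate must be in [0, 1)")
        w = np.asarray(self.level_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise GeneratorError("level_weights must be 4 non-negatives summing to 1")


@dataclass
class GroundTruth:
    """True per-patient subtype severities plus derived overall level."""

    labels: pd.DataFrame  # patient_id, lv, pca, fv
    levels: np.ndarray  # true overall-severity level index 0..3

    @property
    def severities(self) -> np.ndarray:
        return self.labels[list(SUBTYPES)].to_numpy(dtype=float)

    @property
    def overall(self) -> np.ndarray:
        return self.severities.mean(axis=1)


def _level_bounds(level: int) -> tuple[float, float]:
    low = 0.0 if level == 0 else SEVERITY_THRESHOLDS[level - 1]
    return low, SEVERITY_THRESHOLDS[level]


def sample_latents(config: GeneratorConfig) -> GroundTruth:
    """Draw per-patient severities: level from the mixture, then severities
    uniform on [0, 1]³ rejected until their mean falls in the level's bin."""
    rng = np.random.default_rng(config.seed)
    levels = rng.choice(4, size=config.n, p=np.asarray(config.level_weights))
    sev = np.empty((config.n, 3))
    for i, lvl in enumerate(levels):
        low, high = _level_bounds(int(lvl))
        while True:
            y = rng.uniform(0.0, 1.0, size=3)
            m = y.mean()
            # upper-edge bins: asymptomatic includes 0, each bin its top edge
            if (m <= high) and (m > low or (lvl == 0 and m >= 0.0)):
                sev[i] = y
                break
    labels = pd.DataFrame(sev, columns=list(SUBTYPES))
    labels.insert(0, ID_COLUMN, [f"P{i:05d}" for i in range(config.n)])
    return GroundTruth(labels=labels, levels=levels.astype(int))


def _map_to_range(p: np.ndarray, spec, rng: np.random.Generator) -> np.ndarray:
    """Map probabilities in (0, 1) into a feature's clinical range/kind."""
    low, high = spec.reference_range
    if spec.value_kind == "binary":
        return (rng.uniform(size=p.shape) < p).astype(float)
    values = low + p * (high - low)
    if spec.value_kind == "ordinal":
        return np.round(values)
    return values


def informative_features(
    schema: FeatureSchema, config: GeneratorConfig
) -> dict[str, list[str]]:
    """The seeded per-group choice of signal-carrying features."""
    rng = np.random.default_rng(config.seed + 1)
    chosen: dict[str, list[str]] = {}
    for group, members in schema.group_index.items():
        if group == "DIRECT":
            continue
        pool = [
            m
            for m in members
            if group != "G4_lifestyle" or m in G4_INFORMATIVE_POOL
        ]
        if not pool:
            chosen[group] = []
            continue
        k = max(1, int(np.ceil(config.informative_fraction * len(pool))))
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        chosen[group] = [pool[i] for i in sorted(picks)]
    return chosen


def generate_features(
    truth: GroundTruth, schema: FeatureSchema, config: GeneratorConfig
) -> CohortTable:
    """Realize the feature matrix in clinical units from the latent severities."""
    rng = np.random.default_rng(config.seed + 2)
    n = len(truth.labels)
    sev = truth.severities
    overall = truth.overall
    chosen = informative_features(schema, config)
    signal_of = {
        name: GROUP_LOADINGS[g] for g, names in chosen.items() for name in names
    }

    no_range = [
        f.name
        for f in schema.features
        if f.name in signal_of and f.reference_range is None
    ]
    if no_range:
        raise GeneratorError(
            f"informative feature(s) lack a reference range: {no_range}"
        )

    direct_slope = min(1.0, config.beta / 5.0)
    values = np.empty((n, len(schema)))
    for j, spec in enumerate(schema.features):
        name = spec.name
        if name in TABLE1_MARGINALS:
            kind, *params = TABLE1_MARGINALS[name]
            if kind == "normal":
                mu, sd = params
                col = rng.normal(mu, sd, size=n)
            elif kind == "bernoulli":
                col = (rng.uniform(size=n) < params[0]).astype(float)
            else:  # lognormal with the stated median
                median, sigma = params
                col = rng.lognormal(np.log(median), sigma, size=n)
            if spec.reference_range is not None:
                col = np.clip(col, *spec.reference_range)
            values[:, j] = col
        elif spec.group == "DIRECT":
            eps = rng.normal(0.0, config.noise_sd, size=n)
            p = np.clip(0.5 + direct_slope * (overall - 0.5) + eps, 0.0, 1.0)
            if name == "MMSE":
                p = 1.0 - p  # cognition declines with severity
            values[:, j] = _map_to_range(p, spec, rng)
        elif name in signal_of:
            eps = rng.normal(0.0, config.noise_sd, size=n)
            logit = config.beta * (sev @ signal_of[name]) + eps
            p = 1.0 / (1.0 + np.exp(-logit))
            values[:, j] = _map_to_range(p, spec, rng)
        else:
            # pure in-range noise
            if spec.reference_range is not None:
                p = rng.uniform(size=n)
                if spec.value_kind == "binary":
                    values[:, j] = (p < 0.5).astype(float)
                else:
                    values[:, j] = _map_to_range(p, spec, rng)
            else:
                values[:, j] = rng.normal(0.0, 1.0, size=n)

    return CohortTable(
        truth.labels[ID_COLUMN].tolist(),
        list(schema.names),
        values,
        np.zeros((n, len(schema)), dtype=bool),
    )


def inject_missing(table: CohortTable, rate: float, seed: int = 0) -> CohortTable:
    """Mask each cell independently with probability ``rate`` (MCAR)."""
    if not (0.0 <= rate < 1.0):
        raise GeneratorError("missing rate must be in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=out.values.shape) < rate
    out.missing_mask = out.missing_mask | mask
    out.values = np.where(mask, np.nan, out.values)
    return out


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    schema: FeatureSchema | None = None,
) -> tuple[CohortTable, GroundTruth]:
    """Latents → features → MCAR missingness, all seeded from the config."""
    if schema is None:
        schema = default_schema()
    truth = sample_latents(config)
    table = generate_features(truth, schema, config)
    table = inject_missing(table, config.missing_rate, seed=config.seed + 3)
    return table, truth


def truth_manifest(
    truth: GroundTruth, config: GeneratorConfig, schema: FeatureSchema
) -> dict:
    """Declared generative structure, for companion manifests."""
    chosen = informative_features(schema, config)
    counts = np.bincount(truth.levels, minlength=4).tolist()
    return {
        "n": len(truth.labels),
        "config": {
            "beta": config.beta,
            "informative_fraction": config.informative_fraction,
            "noise_sd": config.noise_sd,
            "missing_rate": config.missing_rate,
            "level_weights": list(config.level_weights),
            "seed": config.seed,
        },
        "informative_features": chosen,
        "group_loadings": {k: v.tolist() for k, v in GROUP_LOADINGS.items()},
        "true_level_counts": counts,
    }
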