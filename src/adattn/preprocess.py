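"""Preprocessing pipeline: mean imputation, reference-range min-max scaling,
70/15/15 splitting, and SMOTE oversampling of the training set.

The pipeline order is fixed and leakage-safe: imputer and normalizer
statistics are fit on the training split only and applied unchanged to the
validation and test splits; SMOTE touches only the training set.  Min-max
scaling uses a feature's clinical reference range when the schema provides
one (e.g. β2-microglobulin 1–3 mg/L, so 1 mg/L ↦ 0 and 3 mg/L ↦ 1), falling
back to the observed training min/max otherwise; out-of-range values clip
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .cohort import CohortTable
from .schema import FeatureSchema


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mean imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImputerStats:
    """Per-feature means over the non-missing training entries."""

    feature_names: tuple[str, ...]
    means: np.ndarray

    def mean_of(self, name: str) -> float:
        return float(self.means[self.feature_names.index(name)])


def fit_imputer(train: CohortTable) -> ImputerStats:
    """Compute each feature's arithmetic mean over observed training entries."""
    observed = ~train.missing_mask
    counts = observed.sum(axis=0)
    empty = [n for n, c in zip(train.feature_names, counts) if c == 0]
    if empty:
        raise PreprocessError(
            f"cannot fit imputer: feature(s) with no observed values: {empty}"
        )
    vals = np.where(observed, train.values, 0.0)
    means = vals.sum(axis=0) / counts
    return ImputerStats(tuple(train.feature_names), means)


def apply_imputer(table: CohortTable, stats: ImputerStats) -> CohortTable:
    """Replace masked cells by the fitted means; observed entries unchanged."""
    missing = [n for n in table.feature_names if n not in stats.feature_names]
    if missing:
        raise PreprocessError(f"imputer has no statistics for feature(s): {missing}")
    cols = [stats.feature_names.index(n) for n in table.feature_names]
    means = stats.means[cols]
    values = np.where(table.missing_mask, means[None, :], table.values)
    return CohortTable(
        list(table.patient_ids),
        list(table.feature_names),
        values,
        np.zeros_like(table.missing_mask),
    )


# ---------------------------------------------------------------------------
# Reference-range min-max normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizerSpec:
    """Per-feature (low, high) scaling bounds."""

    feature_names: tuple[str, ...]
    lows: np.ndarray
    highs: np.ndarray

    def __post_init__(self) -> None:
        if not (self.lows < self.highs).all():
            bad = [
                n
                for n, lo, hi in zip(self.feature_names, self.lows, self.highs)
                if not lo < hi
            ]
            raise PreprocessError(f"degenerate normalization bounds for: {bad}")


def fit_normalizer(train: CohortTable, schema: FeatureSchema) -> NormalizerSpec:
    """Bounds per feature: the schema reference range when present, else the
    observed training min/max."""
    if train.missing_mask.any():
        raise PreprocessError("fit_normalizer expects an imputed (complete) table")
    lows = np.empty(len(train.feature_names))
    highs = np.empty(len(train.feature_names))
    for j, name in enumerate(train.feature_names):
        ref = schema[name].reference_range if name in schema else None
        if ref is not None:
            lows[j], highs[j] = ref
        else:
            lows[j] = train.values[:, j].min()
            highs[j] = train.values[:, j].max()
    return NormalizerSpec(tuple(train.feature_names), lows, highs)


def normalize(table: CohortTable, spec: NormalizerSpec) -> CohortTable:
    """x ↦ (x − low)/(high − low), clipped to [0, 1]."""
    if table.missing_mask.any():
        raise PreprocessError("normalize expects an imputed (complete) table")
    if tuple(table.feature_names) != spec.feature_names:
        raise PreprocessError("normalizer spec does not match table features")
    scaled = (table.values - spec.lows[None, :]) / (spec.highs - spec.lows)[None, :]
    scaled = np.clip(scaled, 0.0, 1.0)
    return CohortTable(
        list(table.patient_ids),
        list(table.feature_names),
        scaled,
        np.zeros_like(table.missing_mask),
    )


# ---------------------------------------------------------------------------
# 70/15/15 split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Split fractions (train, val, test) plus shuffle seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise PreprocessError("split fractions must be positive and sum to 1")


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder rounding of n·fractions; ties go to the earlier split
    in (train, val, test) order."""
    exact = np.asarray(fractions, dtype=float) * n
    base = np.floor(exact).astype(int)
    remainder = exact - base
    leftover = n - int(base.sum())
    # stable sort on -remainder keeps listed order among ties
    for idx in np.argsort(-remainder, kind="stable")[:leftover]:
        base[idx] += 1
    return tuple(int(b) for b in base)  # type: ignore[return-value]


def split_cohort(
    table: CohortTable, labels: np.ndarray, spec: SplitSpec
) -> tuple[
    tuple[CohortTable, np.ndarray],
    tuple[CohortTable, np.ndarray],
    tuple[CohortTable, np.ndarray],
]:
    """Disjoint, exhaustive train/val/test partition, deterministic under seed."""
    n = table.n_patients
    if n < 3:
        raise PreprocessError("need at least 3 patients to split")
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != n:
        raise PreprocessError("labels not aligned to patients")
    n_train, n_val, n_test = split_sizes(n, spec.fractions)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    parts = (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )
    return tuple((table.subset(p), labels[p]) for p in parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote(
    features: np.ndarray,
    strata: np.ndarray,
    k: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling: equalize stratum counts by
    interpolation between same-stratum nearest neighbors.

    Each synthetic point is ``x + u·(z − x)`` with ``u ~ Uniform(0, 1)`` and
    ``z`` one of x's k nearest same-stratum neighbors (Euclidean); k is capped
    at stratum size − 1.  Original rows are preserved verbatim.  When a
    ``labels`` matrix is given, synthetic labels interpolate the two parents'
    label vectors with the same ``u``.
    """
    if k < 1:
        raise PreprocessError("SMOTE neighbor count k must be >= 1")
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise PreprocessError("SMOTE requires fully numeric, finite features")
    strata = np.asarray(strata)
    if strata.shape[0] != X.shape[0]:
        raise PreprocessError("strata not aligned to feature rows")
    y = None if labels is None else np.asarray(labels, dtype=float)

    keys, counts = np.unique(strata, return_counts=True)
    target = counts.max()
    rng = np.random.default_rng(seed)

    new_X, new_s, new_y = [], [], []
    for key, count in zip(keys, counts):
        deficit = target - count
        if deficit == 0:
            continue
        if count < 2:
            raise PreprocessError(
                f"stratum {key!r} has a single member; SMOTE needs >= 2"
            )
        idx = np.flatnonzero(strata == key)
        Xs = X[idx]
        kk = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(Xs)
        neigh = nn.kneighbors(Xs, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, kk, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        x = Xs[base]
        z = Xs[neigh[base, pick]]
        new_X.append(x + u[:, None] * (z - x))
        new_s.append(np.full(deficit, key, dtype=strata.dtype))
        if y is not None:
            yx = y[idx][base]
            yz = y[idx][neigh[base, pick]]
            new_y.append(yx + u[:, None] * (yz - yx))

    if not new_X:
        return (X, strata) if y is None else (X, strata, y)
    X_out = np.vstack([X, *new_X])
    s_out = np.concatenate([strata, *new_s])
    if y is None:
        return X_out, s_out
    return X_out, s_out, np.vstack([y, *new_y])


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessedData:
    """Output of the full preprocessing pipeline.

    ``train_X``/``train_y`` include SMOTE-synthesized rows; ``val``/``test``
    are untouched beyond imputation and normalization (SMOTE is not applicable
    to them through this API).
    """

    train_X: np.ndarray
    train_y: np.ndarray
    val: CohortTable
    val_y: np.ndarray
    test: CohortTable
    test_y: np.ndarray
    train_table: CohortTable  # pre-SMOTE normalized training table
    imputer: ImputerStats
    normalizer: NormalizerSpec
    field_names: tuple[str, ...] = field(default_factory=tuple)


def preprocess(
    table: CohortTable,
    labels: np.ndarray,
    schema: FeatureSchema,
    split: SplitSpec = SplitSpec(),
    smote_k: int = 5,
    apply_smote: bool = True,
    presence_threshold: float = 0.5,
) -> PreprocessedData:
    """Impute → normalize → split → SMOTE(train only).

    The SMOTE stratum key is the triple of binarized subtype presences of the
    ground-truth severities at ``presence_threshold``; synthetic rows carry
    labels interpolated alongside the features.
    """
    (tr, tr_y), (va, va_y), (te, te_y) = split_cohort(table, labels, split)
    imputer = fit_imputer(tr)
    tr_i = apply_imputer(tr, imputer)
    normalizer = fit_normalizer(tr_i, schema)
    tr_n = normalize(tr_i, normalizer)
    va_n = normalize(apply_imputer(va, imputer), normalizer)
    te_n = normalize(apply_imputer(te, imputer), normalizer)

    if apply_smote:
        calls = (tr_y >= presence_threshold).astype(int)
        strata = np.array(["".join(map(str, row)) for row in calls])
        X_aug, _, y_aug = smote(
            tr_n.values, strata, k=smote_k, seed=split.seed, labels=tr_y
        )
    else:
        X_aug, y_aug = tr_n.values, tr_y

    return PreprocessedData(
        train_X=X_aug,
        train_y=y_aug,
        val=va_n,
        val_y=va_y,
        test=te_n,
        test_y=te_y,
        train_table=tr_n,
        imputer=imputer,
        normalizer=normalizer,
        field_names=tuple(table.feature_names),
    )
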