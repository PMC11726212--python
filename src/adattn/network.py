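"""Modular attention network, parameter-matched MLP baseline, and training.

The proposed model routes each of the four feature groups through its own
scalar-to-d token embedding and scaled dot-product self-attention block,
mean-pools each block's context rows into a d-vector, concatenates the four
pooled vectors with the DIRECT markers (β2-microglobulin, MMSE), and passes
the combined vector through a fully connected trunk ending in three
per-output logistic units — one severity in [0, 1] per subtype (Logopenic
Variant, Posterior Cortical Atrophy, Frontal Variant).  The baseline is a
plain fully connected network over the full normalized feature vector with
hidden widths solved so its trainable-parameter count lands within ±10% of
the proposed model's.

Everything is plain numpy with explicit reverse-mode gradients and an Adam
optimizer, fully deterministic under the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .attention import softmax_rows
from .cohort import ID_COLUMN, SUBTYPES, CohortTable
from .schema import DIRECT, GROUPS, FeatureSchema

_EPS = 1e-12


class ModelError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs: token embedding dim, trunk widths, activations."""

    embed_dim: int = 8
    hidden: tuple[int, ...] = (64, 32)
    activation: str = "relu"
    output_activation: str = "sigmoid"  # 'sigmoid' (independent) | 'softmax'
    score_scale: str = "sqrt"  # 'sqrt' | 'linear' attention scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or any(h < 1 for h in self.hidden):
            raise ModelError("embed_dim and hidden sizes must be positive")
        if self.output_activation not in ("sigmoid", "softmax"):
            raise ModelError(f"unknown output activation {self.output_activation!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization knobs; the loss is BCE against continuous severities."""

    loss: str = "bce"  # 'bce' | 'mse'
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ModelError("learning rate, batch size, max epochs must be positive")
        if self.patience < 1:
            raise ModelError("patience must be >= 1")
        if self.loss not in ("bce", "mse"):
            raise ModelError(f"unknown loss {self.loss!r}")


def _validate_inputs(V: np.ndarray, n_features: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    if V.shape[1] != n_features:
        raise ModelError(f"expected {n_features} features, got {V.shape[1]}")
    if not np.isfinite(V).all():
        raise ModelError("model inputs must be finite")
    if V.min() < -1e-9 or V.max() > 1.0 + 1e-9:
        raise ModelError("model inputs must be normalized to [0, 1]")
    return V


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _TrunkMixin:
    """Fully connected trunk shared by both architectures."""

    params: dict[str, np.ndarray]
    config: ModelConfig

    def _init_trunk(self, rng: np.random.Generator, in_dim: int) -> None:
        dims = [in_dim, *self.config.hidden, 3]
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            scale = np.sqrt(2.0 / fan_in) if i < len(dims) - 2 else np.sqrt(1.0 / fan_in)
            self.params[f"W{i}"] = rng.normal(0.0, scale, size=(dims[i], dims[i + 1]))
            self.params[f"c{i}"] = np.zeros(dims[i + 1])
        self._n_layers = len(dims) - 1

    def _trunk_forward(self, H: np.ndarray) -> tuple[np.ndarray, dict]:
        hs, pres = [H], []
        for i in range(self._n_layers - 1):
            Z = H @ self.params[f"W{i}"] + self.params[f"c{i}"]
            pres.append(Z)
            H = _relu(Z)
            hs.append(H)
        logits = H @ self.params[f"W{self._n_layers - 1}"] + self.params[
            f"c{self._n_layers - 1}"
        ]
        if self.config.output_activation == "sigmoid":
            out = _sigmoid(logits)
        else:
            out = softmax_rows(logits)
        return out, {"hs": hs, "pres": pres, "out": out}

    def _trunk_backward(
        self, cache: dict, dlogits: np.ndarray, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        i = self._n_layers - 1
        H = cache["hs"][-1]
        grads[f"W{i}"] = H.T @ dlogits
        grads[f"c{i}"] = dlogits.sum(axis=0)
        dH = dlogits @ self.params[f"W{i}"].T
        for i in range(self._n_layers - 2, -1, -1):
            dZ = dH * (cache["pres"][i] > 0)
            grads[f"W{i}"] = cache["hs"][i].T @ dZ
            grads[f"c{i}"] = dZ.sum(axis=0)
            dH = dZ @ self.params[f"W{i}"].T
        return dH  # gradient w.r.t. trunk input


class ModularAttentionModel(_TrunkMixin):
    """Four attention group modules + DIRECT pass-through + trunk."""

    kind = "modular"

    def __init__(self, schema: FeatureSchema, config: ModelConfig = ModelConfig()):
        missing = [g for g in GROUPS if not schema.group_index.get(g)]
        if missing:
            raise ModelError(f"schema has empty or missing group(s): {missing}")
        self.schema = schema
        self.config = config
        self.feature_names = list(schema.names)
        self.groups = {g: list(schema.group_index[g]) for g in GROUPS}
        self.direct = list(schema.direct_names)
        self._gidx = {
            g: np.array(schema.column_indices(m), dtype=int)
            for g, m in self.groups.items()
        }
        self._didx = np.array(schema.column_indices(self.direct), dtype=int)
        d = config.embed_dim
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for g in GROUPS:
            n = len(self.groups[g])
            self.params[f"{g}_w"] = rng.normal(0.0, 1.0, size=(n, d))
            self.params[f"{g}_b"] = rng.normal(0.0, 0.5, size=(n, d))
        self._init_trunk(rng, 4 * d + len(self.direct))
        self._scale = float(np.sqrt(d)) if config.score_scale == "sqrt" else float(d)

    @property
    def trunk_in_dim(self) -> int:
        return 4 * self.config.embed_dim + len(self.direct)

    # -- forward ---------------------------------------------------------------

    def _forward_cache(self, V: np.ndarray) -> tuple[np.ndarray, dict]:
        V = _validate_inputs(V, len(self.feature_names))
        parts, gcache = [], {}
        for g in GROUPS:
            Vg = V[:, self._gidx[g]]  # (B, n)
            w, b = self.params[f"{g}_w"], self.params[f"{g}_b"]
            X = Vg[:, :, None] * w[None] + b[None]  # (B, n, d)
            S = X @ X.transpose(0, 2, 1) / self._scale
            A = softmax_rows(S)
            C = A @ X
            parts.append(C.mean(axis=1))
            gcache[g] = (Vg, X, A)
        if len(self._didx):
            parts.append(V[:, self._didx])
        H0 = np.concatenate(parts, axis=1)
        out, tcache = self._trunk_forward(H0)
        return out, {"groups": gcache, "trunk": tcache}

    def forward(self, V: np.ndarray) -> np.ndarray:
        """Severity predictions in [0, 1]^3 for a batch of normalized rows."""
        return self._forward_cache(V)[0]

    def attention_maps(self, V: np.ndarray) -> dict[str, np.ndarray]:
        """Per-group row-stochastic attention weights, for interpretability."""
        V = _validate_inputs(V, len(self.feature_names))
        maps = {}
        for g in GROUPS:
            Vg = V[:, self._gidx[g]]
            w, b = self.params[f"{g}_w"], self.params[f"{g}_b"]
            X = Vg[:, :, None] * w[None] + b[None]
            maps[g] = softmax_rows(X @ X.transpose(0, 2, 1) / self._scale)
        return maps

    # -- backward --------------------------------------------------------------

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dH0 = self._trunk_backward(cache["trunk"], dlogits, grads)
        d = self.config.embed_dim
        offset = 0
        for g in GROUPS:
            dP = dH0[:, offset : offset + d]  # (B, d)
            offset += d
            Vg, X, A = cache["groups"][g]
            n = X.shape[1]
            dC = np.broadcast_to(dP[:, None, :] / n, X.shape)
            dA = dC @ X.transpose(0, 2, 1)
            dX = A.transpose(0, 2, 1) @ dC
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dX = dX + (dS + dS.transpose(0, 2, 1)) @ X / self._scale
            grads[f"{g}_w"] = (Vg[:, :, None] * dX).sum(axis=0)
            grads[f"{g}_b"] = dX.sum(axis=0)
        return grads

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "config": {
                "embed_dim": self.config.embed_dim,
                "hidden": list(self.config.hidden),
                "activation": self.config.activation,
                "output_activation": self.config.output_activation,
                "score_scale": self.config.score_scale,
                "seed": self.config.seed,
            },
            "feature_names": self.feature_names,
            "groups": self.groups,
            "direct": self.direct,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }


class BaselineModel(_TrunkMixin):
    """Plain fully connected network over the full normalized feature vector."""

    kind = "baseline"

    def __init__(
        self,
        schema: FeatureSchema,
        hidden: tuple[int, ...],
        config: ModelConfig = ModelConfig(),
    ):
        self.schema = schema
        self.config = replace(config, hidden=tuple(hidden))
        self.feature_names = list(schema.names)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_trunk(rng, len(self.feature_names))

    def _forward_cache(self, V: np.ndarray) -> tuple[np.ndarray, dict]:
        V = _validate_inputs(V, len(self.feature_names))
        out, tcache = self._trunk_forward(V)
        return out, {"trunk": tcache}

    def forward(self, V: np.ndarray) -> np.ndarray:
        return self._forward_cache(V)[0]

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        self._trunk_backward(cache["trunk"], dlogits, grads)
        return grads

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "config": {
                "embed_dim": self.config.embed_dim,
                "hidden": list(self.config.hidden),
                "activation": self.config.activation,
                "output_activation": self.config.output_activation,
                "score_scale": self.config.score_scale,
                "seed": self.config.seed,
            },
            "feature_names": self.feature_names,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }


Model = ModularAttentionModel | BaselineModel


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------


def build_model(
    schema: FeatureSchema, config: ModelConfig = ModelConfig()
) -> ModularAttentionModel:
    """Build the proposed model; deterministic under ``config.seed``."""
    return ModularAttentionModel(schema, config)


def count_parameters(model: Model) -> int:
    """Exact count of trainable scalars."""
    return int(sum(v.size for v in model.params.values()))


def build_matched_baseline(
    schema: FeatureSchema,
    config: ModelConfig = ModelConfig(),
    tolerance: float = 0.10,
    max_width: int = 4096,
) -> BaselineModel:
    """Solve baseline hidden widths so its parameter count is within
    ``tolerance`` of the proposed model's (same depth, widths scaled
    proportionally, integer search over the leading width)."""
    target = count_parameters(build_model(schema, config))
    base = config.hidden
    best: tuple[float, tuple[int, ...]] | None = None
    for h1 in range(1, max_width + 1):
        widths = tuple(
            max(1, round(h1 * h / base[0])) for h in base
        )
        n_in = len(schema)
        dims = [n_in, *widths, 3]
        count = sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))
        rel = abs(count - target) / target
        if best is None or rel < best[0]:
            best = (rel, widths)
        if count > target * (1 + tolerance) and rel > best[0]:
            break
    assert best is not None
    if best[0] > tolerance:
        raise ModelError(
            f"cannot parameter-match baseline within {tolerance:.0%} at this "
            f"depth; closest widths {best[1]} (relative gap {best[0]:.1%}); "
            f"try widths up to {max_width} or a different depth"
        )
    return BaselineModel(schema, best[1], config)


# ---------------------------------------------------------------------------
# Loss and optimization
# ---------------------------------------------------------------------------


def loss_and_dlogits(
    out: np.ndarray, y: np.ndarray, loss: str, output_activation: str
) -> tuple[float, np.ndarray]:
    """Mean-over-samples loss (summed over the 3 outputs) and its gradient
    with respect to the pre-activation logits."""
    B = out.shape[0]
    p = np.clip(out, _EPS, 1.0 - _EPS)
    if loss == "bce":
        value = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum() / B)
        dp = (p - y) / (p * (1 - p)) / B
    else:  # mse
        value = float(((out - y) ** 2).sum() / B)
        dp = 2.0 * (out - y) / B
    if output_activation == "sigmoid":
        dlogits = dp * p * (1 - p)
    else:  # softmax jacobian
        dlogits = out * (dp - (dp * out).sum(axis=-1, keepdims=True))
    return value, dlogits


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def train(
    model: Model,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    tc: TrainConfig = TrainConfig(),
) -> tuple[Model, dict]:
    """Minibatch Adam with early stopping on validation loss.

    Returns the model with the best-validation-epoch parameters restored and
    a history dict with per-epoch train/val losses.  Reproducible under
    ``tc.seed``; aborts with diagnostics if the loss turns non-finite.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    if train_X.shape[0] == 0:
        raise TrainingError("empty training set")
    if train_y.shape != (train_X.shape[0], 3):
        raise TrainingError("training labels must be (n, 3) severities")
    if (train_y < 0).any() or (train_y > 1).any():
        raise TrainingError("severity targets must lie in [0, 1]")

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.params, tc.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0

    for epoch in range(tc.max_epochs):
        epoch_loss = 0.0
        for idx in _batches(train_X.shape[0], tc.batch_size, rng):
            out, cache = model._forward_cache(train_X[idx])
            value, dlogits = loss_and_dlogits(
                out, train_y[idx], tc.loss, model.config.output_activation
            )
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {value!r}; "
                    f"output range [{out.min()}, {out.max()}]"
                )
            grads = model._backward(cache, dlogits)
            opt.step(model.params, grads)
            epoch_loss += value * len(idx)
        history["train_loss"].append(epoch_loss / train_X.shape[0])

        val_out = model.forward(val_X)
        val_loss, _ = loss_and_dlogits(
            val_out, val_y, tc.loss, model.config.output_activation
        )
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            history["best_epoch"] = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break

    if best_params is not None:
        for k in model.params:
            model.params[k] = best_params[k]
    return model, history


def predict(model: Model, table: CohortTable) -> pd.DataFrame:
    """Per-patient subtype severities for a preprocessed (normalized) cohort."""
    if list(table.feature_names) != model.feature_names:
        raise ModelError("cohort features do not match the model's schema")
    if table.missing_mask.any():
        raise ModelError("cohort must be imputed before prediction")
    out = model.forward(table.values)
    df = pd.DataFrame(out, columns=list(SUBTYPES))
    df.insert(0, ID_COLUMN, table.patient_ids)
    return df


# ---------------------------------------------------------------------------
# Serialization (architecture + flat weight arrays as JSON text)
# ---------------------------------------------------------------------------


def save_model(model: Model, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)
    return path


def load_model(path: str | Path) -> Model:
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    config = ModelConfig(
        embed_dim=cfg["embed_dim"],
        hidden=tuple(cfg["hidden"]),
        activation=cfg["activation"],
        output_activation=cfg["output_activation"],
        score_scale=cfg["score_scale"],
        seed=cfg["seed"],
    )
    if payload["kind"] == "modular":
        from .schema import FeatureSchema, FeatureSpec

        # rebuild a minimal schema carrying names and group routing
        specs = []
        member_of = {
            name: g for g, members in payload["groups"].items() for name in members
        }
        for name in payload["feature_names"]:
            if name in member_of:
                cat = {
                    "G1_blood": "blood_chemistry",
                    "G2_biochem": "biochemical",
                    "G3_endocrine": "endocrine_immune",
                    "G4_lifestyle": "lifestyle",
                }[member_of[name]]
                specs.append(FeatureSpec(name, cat, member_of[name]))
            else:
                specs.append(FeatureSpec(name, "neurological", DIRECT))
        model: Model = ModularAttentionModel(FeatureSchema(tuple(specs)), config)
    else:
        from .schema import FeatureSchema, FeatureSpec

        specs = [
            FeatureSpec(name, "biochemical", "G2_biochem")
            for name in payload["feature_names"]
        ]
        model = BaselineModel(FeatureSchema(tuple(specs)), config.hidden, config)
    for k, v in payload["params"].items():
        model.params[k] = np.asarray(v, dtype=float)
    return model
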