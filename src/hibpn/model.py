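"""The bidirectional prediction network (HIBPN) and its feature encoding.

The network is a modular feed-forward architecture with three encoders
and two prediction heads:

* human-environment encoder — a two-layer MLP that first *upscales*
  the demographic/situational features to a wider hidden layer, then
  *downscales* back to a compact representation ``A_he``;
* narcissism encoder — a one-layer upscaling MLP over the two trait
  totals (NPI-16, HSNS) giving ``A_n``;
* hostile-interpretation encoder — a one-layer MLP over the hostile /
  non-hostile totals giving the intermediate feature ``A_h_mid``.

The fused vector ``A_hen = A_he (+) A_n`` (feature concatenation)
feeds the *reverse* head, which predicts hostile-interpretation bias
(a continuous value plus a sigmoid high/low classification head); the
further fusion ``A_all = A_hen (+) A_h_mid`` feeds the *forward* head,
a sigmoid binary classifier of the social-exclusion state.

Hidden layers use ReLU except the forward head's hidden layer, which
is sigmoid like its output.  All functions here are pure: outputs
depend only on inputs and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np

from .cohort import ParticipantRecord

__all__ = [
    "LayerParams",
    "HibpnDims",
    "HibpnParams",
    "FeatureMatrix",
    "Standardizer",
    "build_features",
    "init_params",
    "relu",
    "sigmoid",
    "human_env_encode",
    "narcissism_encode",
    "fuse",
    "hostile_intermediate",
    "forward_chain",
    "reverse_chain",
    "save_params",
    "load_params",
]

Chain = Literal["forward", "reverse"]


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LayerParams:
    """One dense layer: ``weights`` is (out_dim, in_dim), ``bias`` (out_dim,)."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.ndim != 1:
            raise ValueError("weights must be 2-D and bias 1-D")
        if self.weights.shape[0] != self.bias.shape[0]:
            raise ValueError("weights/bias out_dim mismatch")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("layer parameters must be finite")

    @property
    def out_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def in_dim(self) -> int:
        return self.weights.shape[1]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Affine map for a batch ``x`` of shape (n, in_dim)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected input dim {self.in_dim}, got {x.shape[1]}")
        return x @ self.weights.T + self.bias


@dataclass
class HibpnDims:
    """Layer widths.  Defaults suit a few-hundred-participant cohort."""

    he_in: int = 8
    he_up: int = 32
    he_down: int = 8
    narc_in: int = 2
    narc_up: int = 8
    hostile_in: int = 2
    hostile_mid: int = 4
    env_hidden: int = 16
    hostile_hidden: int = 16

    def validate(self) -> None:
        if self.he_in < 1 or self.env_hidden < 1 or self.hostile_hidden < 1:
            raise ValueError("he_in, env_hidden and hostile_hidden must be >= 1")
        if self.he_up <= self.he_in:
            raise ValueError("human-env encoder must upscale: he_up > he_in")
        if self.he_down >= self.he_up:
            raise ValueError("human-env encoder must then downscale: he_down < he_up")
        # A block may be absent entirely (ablation); then its encoder width is 0.
        if self.narc_in == 0:
            if self.narc_up != 0:
                raise ValueError("narc_up must be 0 when the narcissism block is absent")
        elif self.narc_up <= self.narc_in:
            raise ValueError("narcissism encoder must upscale: narc_up > narc_in")
        if self.hostile_in == 0:
            if self.hostile_mid != 0:
                raise ValueError("hostile_mid must be 0 when the hostile block is absent")
        elif self.hostile_mid < 1:
            raise ValueError("hostile_mid must be >= 1")

    @property
    def fused_dim(self) -> int:
        return self.he_down + self.narc_up

    @property
    def all_dim(self) -> int:
        return self.fused_dim + self.hostile_mid


@dataclass
class HibpnParams:
    """All weights of the network, keyed by module."""

    he_up: LayerParams
    he_down: LayerParams
    narc_up: LayerParams
    hostile_mid: LayerParams
    env_hidden: LayerParams
    env_out: LayerParams
    hostile_hidden: LayerParams
    hostile_out: LayerParams  # regression head (continuous bias value)
    hostile_out_clf: LayerParams  # sigmoid head on the high/low bin
    dims: HibpnDims
    activation: str = "relu"

    def layers(self) -> dict[str, LayerParams]:
        return {
            name: getattr(self, name)
            for name in (
                "he_up", "he_down", "narc_up", "hostile_mid", "env_hidden",
                "env_out", "hostile_hidden", "hostile_out", "hostile_out_clf",
            )
        }


def init_params(dims: HibpnDims, seed: int) -> HibpnParams:
    """Seed-deterministic initialization.

    ReLU layers use He-normal weights, sigmoid/linear layers
    Glorot-normal; biases start at zero.
    """
    dims.validate()
    rng = np.random.default_rng(seed)

    def he_layer(n_in: int, n_out: int) -> LayerParams:
        w = rng.normal(0.0, np.sqrt(2.0 / max(n_in, 1)), size=(n_out, n_in))
        return LayerParams(w, np.zeros(n_out))

    def glorot_layer(n_in: int, n_out: int) -> LayerParams:
        w = rng.normal(0.0, np.sqrt(2.0 / max(n_in + n_out, 1)), size=(n_out, n_in))
        return LayerParams(w, np.zeros(n_out))

    return HibpnParams(
        he_up=he_layer(dims.he_in, dims.he_up),
        he_down=he_layer(dims.he_up, dims.he_down),
        narc_up=he_layer(dims.narc_in, dims.narc_up),
        hostile_mid=he_layer(dims.hostile_in, dims.hostile_mid),
        env_hidden=glorot_layer(dims.all_dim, dims.env_hidden),
        env_out=glorot_layer(dims.env_hidden, 1),
        hostile_hidden=he_layer(dims.fused_dim, dims.hostile_hidden),
        hostile_out=glorot_layer(dims.hostile_hidden, 1),
        hostile_out_clf=glorot_layer(dims.hostile_hidden, 1),
        dims=dims,
    )


# ---------------------------------------------------------------------------
# module forward passes


def human_env_encode(x_he: np.ndarray, params: HibpnParams) -> np.ndarray:
    """Upscale-then-downscale encoding of the human/situational features."""
    a1 = relu(params.he_up.apply(x_he))
    return relu(params.he_down.apply(a1))


def narcissism_encode(x_n: np.ndarray, params: HibpnParams) -> np.ndarray:
    """One-layer upscaling of the (NPI-16, HSNS) trait totals."""
    return relu(params.narc_up.apply(x_n))


def fuse(a_he: np.ndarray, a_n: np.ndarray) -> np.ndarray:
    """Feature concatenation ``A_he (+) A_n`` (human-env block first)."""
    a_he = np.atleast_2d(np.asarray(a_he, dtype=float))
    a_n = np.atleast_2d(np.asarray(a_n, dtype=float))
    if a_n.shape[1] == 0:
        return a_he
    if not (np.isfinite(a_he).all() and np.isfinite(a_n).all()):
        raise ValueError("fused features must be finite")
    return np.concatenate([a_he, a_n], axis=1)


def hostile_intermediate(x_h: np.ndarray, params: HibpnParams) -> np.ndarray:
    """One-layer encoding of the (hostile, non-hostile) totals."""
    return relu(params.hostile_mid.apply(x_h))


def forward_chain(
    a_hen: np.ndarray, a_h_mid: np.ndarray, params: HibpnParams
) -> np.ndarray:
    """Probability of the social-exclusion state.

    ``A_all = A_hen (+) A_h_mid`` passes through a sigmoid hidden layer
    and a sigmoid output; the predicted label is ``p >= 0.5``.
    """
    a_all = fuse(a_hen, a_h_mid)
    h = sigmoid(params.env_hidden.apply(a_all))
    return sigmoid(params.env_out.apply(h))[:, 0]


def reverse_chain(a_hen: np.ndarray, params: HibpnParams) -> tuple[np.ndarray, np.ndarray]:
    """Hostile-interpretation bias from the fused trait/situation features.

    Returns ``(y_continuous, p_high)``: the unbounded regression output
    and the sigmoid probability of the high-hostility bin.  The
    classification output is what the accuracy/F1/AUC evaluation uses.
    """
    h = relu(params.hostile_hidden.apply(a_hen))
    y_cont = params.hostile_out.apply(h)[:, 0]
    p_high = sigmoid(params.hostile_out_clf.apply(h))[:, 0]
    return y_cont, p_high


# ---------------------------------------------------------------------------
# feature encoding

#: column -> dimension-group map used by ablation and grouped importance.
DIMENSION_GROUPS: Mapping[str, str] = {
    "gender_male": "demographics",
    "age": "demographics",
    "basic_needs": "social_exclusion",
    "estimated_catch_pct": "social_exclusion",
    "condition_exclusion": "social_exclusion",
    "group_dominant": "narcissism",
    "group_implicit": "narcissism",
    "npi16_score": "narcissism",
    "hsns_score": "narcissism",
    "hostile_score": "hostile_interpretation",
    "non_hostile_score": "hostile_interpretation",
}

_CONTINUOUS = {
    "age", "basic_needs", "estimated_catch_pct",
    "npi16_score", "hsns_score", "hostile_score", "non_hostile_score",
}


@dataclass
class Standardizer:
    """Per-column z-standardization fitted on the training rows only."""

    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...]

    @classmethod
    def fit(cls, x: np.ndarray, columns: Sequence[str]) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
        for j, col in enumerate(columns):
            if col in _CONTINUOUS:
                mean[j] = x[:, j].mean()
                sd = x[:, j].std()
                scale[j] = sd if sd > 0 else 1.0
        return cls(mean=mean, scale=scale, columns=tuple(columns))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


@dataclass
class FeatureMatrix:
    """Encoded model inputs for one chain, with the column-group map."""

    he: np.ndarray
    narc: np.ndarray
    hostile: np.ndarray
    he_columns: tuple[str, ...]
    narc_columns: tuple[str, ...]
    hostile_columns: tuple[str, ...]
    y_forward: np.ndarray  # 1 = social exclusion
    y_reverse: np.ndarray  # 1 = high hostile-interpretation bin
    y_reverse_cont: np.ndarray  # raw hostile totals
    chain: Chain
    dimension_group_map: Mapping[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.he.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            he=self.he[idx], narc=self.narc[idx], hostile=self.hostile[idx],
            he_columns=self.he_columns, narc_columns=self.narc_columns,
            hostile_columns=self.hostile_columns,
            y_forward=self.y_forward[idx], y_reverse=self.y_reverse[idx],
            y_reverse_cont=self.y_reverse_cont[idx], chain=self.chain,
            dimension_group_map=self.dimension_group_map,
        )

    def flat(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """All feature blocks concatenated, with column names."""
        blocks, cols = [self.he], list(self.he_columns)
        if self.narc.shape[1]:
            blocks.append(self.narc)
            cols += list(self.narc_columns)
        if self.hostile.shape[1]:
            blocks.append(self.hostile)
            cols += list(self.hostile_columns)
        return np.concatenate(blocks, axis=1), tuple(cols)


def build_features(
    records: Sequence[ParticipantRecord],
    chain: Chain,
    drop_groups: Sequence[str] = (),
) -> FeatureMatrix:
    """Encode a cohort for one prediction chain.

    The forward chain predicts the exclusion/acceptance state, so the
    condition indicator is *excluded* from its inputs (anti-leakage)
    while the hostile-interpretation block is included.  The reverse
    chain predicts the hostile bin, so the condition indicator is
    included and the hostile block is excluded.  ``drop_groups``
    removes whole dimension groups (for ablation).
    """
    if chain not in ("forward", "reverse"):
        raise ValueError(f"unknown chain {chain!r}")
    drop = set(drop_groups)
    unknown = drop - set(DIMENSION_GROUPS.values())
    if unknown:
        raise ValueError(f"unknown dimension groups: {sorted(unknown)}")

    he_cols = ["gender_male", "age", "basic_needs", "estimated_catch_pct",
               "group_dominant", "group_implicit"]
    if chain == "reverse":
        he_cols.append("condition_exclusion")
    narc_cols = ["npi16_score", "hsns_score"]
    hostile_cols = ["hostile_score", "non_hostile_score"] if chain == "forward" else []

    def col_values(col: str) -> np.ndarray:
        getters = {
            "gender_male": lambda r: 1.0 if r.gender == "male" else 0.0,
            "age": lambda r: float(r.age),
            "basic_needs": lambda r: float(r.basic_needs_score),
            "estimated_catch_pct": lambda r: float(r.estimated_catch_pct),
            "group_dominant": lambda r: 1.0 if r.trait_group == "dominant" else 0.0,
            "group_implicit": lambda r: 1.0 if r.trait_group == "implicit" else 0.0,
            "condition_exclusion": lambda r: 1.0 if r.condition == "exclusion" else 0.0,
            "npi16_score": lambda r: float(r.npi16_score),
            "hsns_score": lambda r: float(r.hsns_score),
            "hostile_score": lambda r: float(r.hostile_score),
            "non_hostile_score": lambda r: float(r.non_hostile_score),
        }
        return np.array([getters[col](r) for r in records])

    def keep(cols: list[str]) -> list[str]:
        return [c for c in cols if DIMENSION_GROUPS[c] not in drop]

    he_cols, narc_cols, hostile_cols = keep(he_cols), keep(narc_cols), keep(hostile_cols)

    def block(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.zeros((len(records), 0))
        return np.column_stack([col_values(c) for c in cols])

    gmap = {c: DIMENSION_GROUPS[c] for c in he_cols + narc_cols + hostile_cols}
    return FeatureMatrix(
        he=block(he_cols), narc=block(narc_cols), hostile=block(hostile_cols),
        he_columns=tuple(he_cols), narc_columns=tuple(narc_cols),
        hostile_columns=tuple(hostile_cols),
        y_forward=np.array([1.0 if r.condition == "exclusion" else 0.0 for r in records]),
        y_reverse=np.array([1.0 if r.hostile_bin == "high" else 0.0 for r in records]),
        y_reverse_cont=np.array([float(r.hostile_score) for r in records]),
        chain=chain,
        dimension_group_map=gmap,
    )


# ---------------------------------------------------------------------------
# parameter serialization


def save_params(params: HibpnParams, path: str) -> None:
    """Write all layers plus dims to a single .npz archive (bit-exact round trip)."""
    arrays: dict[str, np.ndarray] = {}
    for name, layer in params.layers().items():
        arrays[f"{name}__w"] = layer.weights
        arrays[f"{name}__b"] = layer.bias
    dims = asdict(params.dims)
    arrays["__dims_keys"] = np.array(sorted(dims), dtype="U32")
    arrays["__dims_vals"] = np.array([dims[k] for k in sorted(dims)], dtype=int)
    np.savez(path, **arrays)


def load_params(path: str) -> HibpnParams:
    with np.load(path) as data:
        dims = HibpnDims(**{
            str(k): int(v) for k, v in zip(data["__dims_keys"], data["__dims_vals"])
        })
        layers = {
            name: LayerParams(data[f"{name}__w"], data[f"{name}__b"])
            for name in (
                "he_up", "he_down", "narc_up", "hostile_mid", "env_hidden",
                "env_out", "hostile_hidden", "hostile_out", "hostile_out_clf",
            )
        }
    return HibpnParams(dims=dims, **layers)
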