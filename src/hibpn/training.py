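"""Data splitting and gradient-descent training for both prediction chains.

The validation protocol is deliberately austere: a 1:9 train:test
split (10% of records train the network, 90% measure generalization)
with binary cross-entropy as the classification loss.  Each chain is
trained independently end to end — the forward chain optimizes its
encoders plus the sigmoid exclusion head, the reverse chain its
encoders plus the hostile-bin classification head (and, jointly, the
continuous regression head via mean squared error).

The optimizer is full-batch gradient descent with a fixed learning
rate; with a few dozen training records there is nothing to gain from
stochasticity and determinism is worth more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cohort import ParticipantRecord
from .model import (
    Chain,
    FeatureMatrix,
    HibpnDims,
    HibpnParams,
    LayerParams,
    Standardizer,
    build_features,
    init_params,
    relu,
    sigmoid,
)

__all__ = [
    "TrainConfig",
    "ChainModel",
    "TrainedHibpn",
    "split_1_9",
    "train_chain",
    "train_hibpn",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``split_ratio`` is the *training* fraction: the default 0.10
    realises the 1:9 train:test protocol.  ``reverse_mse_weight``
    scales the auxiliary regression loss of the reverse chain.
    """

    split_ratio: float = 0.10
    stratify: bool = True
    epochs: int = 500
    learning_rate: float = 0.3
    batch_size: int | None = None  # None = full batch
    reverse_mse_weight: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def split_1_9(
    records: Sequence[ParticipantRecord],
    config: TrainConfig,
    label_fn: Callable[[ParticipantRecord], int] | None = None,
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Seed-deterministic train/test partition.

    ``|train| = round(split_ratio * n)``; with ``stratify`` on, the
    train set preserves class proportions of ``label_fn`` (default:
    the exclusion condition) by largest-remainder allocation, and must
    contain at least one record of each class.
    """
    config.validate()
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split 1:9")
    rng = np.random.default_rng(config.seed)
    n_train = int(round(config.split_ratio * n))
    n_train = min(max(n_train, 1), n - 1)

    if not config.stratify:
        perm = rng.permutation(n)
        train_idx = set(perm[:n_train].tolist())
    else:
        if label_fn is None:
            label_fn = lambda r: 1 if r.condition == "exclusion" else 0
        labels = np.array([label_fn(r) for r in records])
        classes = np.unique(labels)
        exact = {c: n_train * (labels == c).sum() / n for c in classes}
        counts = {c: int(np.floor(exact[c])) for c in classes}
        # largest remainders fill up to n_train; every class gets >= 1
        for c in classes:
            counts[c] = max(counts[c], 1)
        while sum(counts.values()) < n_train:
            c = max(classes, key=lambda c: exact[c] - counts[c])
            counts[c] += 1
        while sum(counts.values()) > n_train:
            c = min(classes, key=lambda c: exact[c] - counts[c])
            if counts[c] <= 1:
                raise ValueError("train set too small to hold every class")
            counts[c] -= 1
        train_idx = set()
        for c in classes:
            members = np.flatnonzero(labels == c)
            if counts[c] > members.size:
                raise ValueError(f"class {c} has too few records for the split")
            take = rng.permutation(members)[: counts[c]]
            train_idx.update(take.tolist())

    train = [records[i] for i in range(n) if i in train_idx]
    test = [records[i] for i in range(n) if i not in train_idx]
    return train, test


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


@dataclass
class ChainModel:
    """A trained chain: parameters plus the train-set standardizers."""

    chain: Chain
    params: HibpnParams
    std_he: Standardizer
    std_narc: Standardizer
    std_host: Standardizer | None
    columns: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    drop_groups: tuple[str, ...] = ()
    loss_history: list[float] = field(default_factory=list)

    def _encode(self, fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if (fm.he_columns, fm.narc_columns, fm.hostile_columns) != self.columns:
            raise ValueError("feature columns do not match the trained model")
        x_he = self.std_he.transform(fm.he)
        x_n = self.std_narc.transform(fm.narc) if fm.narc.shape[1] else fm.narc
        x_h = (
            self.std_host.transform(fm.hostile)
            if self.std_host is not None and fm.hostile.shape[1]
            else fm.hostile
        )
        return x_he, x_n, x_h

    def predict_scores(self, fm: FeatureMatrix) -> np.ndarray:
        """Probability of the positive class (exclusion / high-hostile)."""
        from .model import (
            forward_chain, fuse, hostile_intermediate,
            human_env_encode, narcissism_encode, reverse_chain,
        )

        x_he, x_n, x_h = self._encode(fm)
        a_he = human_env_encode(x_he, self.params)
        a_n = narcissism_encode(x_n, self.params)
        a_hen = fuse(a_he, a_n)
        if self.chain == "forward":
            a_mid = hostile_intermediate(x_h, self.params)
            return forward_chain(a_hen, a_mid, self.params)
        return reverse_chain(a_hen, self.params)[1]

    def predict_labels(self, fm: FeatureMatrix) -> np.ndarray:
        return (self.predict_scores(fm) >= 0.5).astype(int)

    def predict_continuous(self, fm: FeatureMatrix) -> np.ndarray:
        """Reverse chain only: the unbounded regression output."""
        from .model import fuse, human_env_encode, narcissism_encode, reverse_chain

        if self.chain != "reverse":
            raise ValueError("continuous output exists only for the reverse chain")
        x_he, x_n, _ = self._encode(fm)
        a_hen = fuse(human_env_encode(x_he, self.params), narcissism_encode(x_n, self.params))
        return reverse_chain(a_hen, self.params)[0]


def _dims_for(fm: FeatureMatrix, **overrides: int) -> HibpnDims:
    d1, d2, d3 = fm.he.shape[1], fm.narc.shape[1], fm.hostile.shape[1]
    kw = dict(
        he_in=d1, he_up=32, he_down=8,
        narc_in=d2, narc_up=8 if d2 else 0,
        hostile_in=d3, hostile_mid=4 if d3 else 0,
        env_hidden=16, hostile_hidden=16,
    )
    kw.update(overrides)
    return HibpnDims(**kw)


def train_chain(
    fm_train: FeatureMatrix,
    config: TrainConfig,
    dims: HibpnDims | None = None,
) -> ChainModel:
    """Fit one chain by full-batch gradient descent on cross-entropy.

    The reverse chain additionally fits its regression head with a
    weighted MSE term on the z-scored hostile totals.  Returns the
    trained :class:`ChainModel` with its per-epoch loss history.
    """
    config.validate()
    y = fm_train.y_forward if fm_train.chain == "forward" else fm_train.y_reverse
    if config.epochs > 0 and len(np.unique(y)) < 2:
        raise ValueError("training target has a single class")

    dims = _dims_for(fm_train) if dims is None else dims
    params = init_params(dims, config.seed)

    std_he = Standardizer.fit(fm_train.he, fm_train.he_columns)
    std_narc = Standardizer.fit(fm_train.narc, fm_train.narc_columns)
    std_host = (
        Standardizer.fit(fm_train.hostile, fm_train.hostile_columns)
        if fm_train.hostile.shape[1]
        else None
    )
    x_he = std_he.transform(fm_train.he)
    x_n = std_narc.transform(fm_train.narc) if fm_train.narc.shape[1] else fm_train.narc
    x_h = std_host.transform(fm_train.hostile) if std_host is not None else fm_train.hostile

    y_cont = fm_train.y_reverse_cont
    yc_mean, yc_sd = y_cont.mean(), y_cont.std() or 1.0
    y_cont_std = (y_cont - yc_mean) / yc_sd

    model = ChainModel(
        chain=fm_train.chain, params=params,
        std_he=std_he, std_narc=std_narc, std_host=std_host,
        columns=(fm_train.he_columns, fm_train.narc_columns, fm_train.hostile_columns),
    )

    n = x_he.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    lr = config.learning_rate
    for _ in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, int(np.ceil(n / config.batch_size)))
        epoch_loss = 0.0
        for idx in batches:
            loss = _gd_step(
                params, fm_train.chain,
                x_he[idx], x_n[idx], x_h[idx], y[idx], y_cont_std[idx],
                lr, config.reverse_mse_weight,
            )
            epoch_loss += loss * idx.size
        model.loss_history.append(epoch_loss / n)
        if not np.isfinite(model.loss_history[-1]):
            raise FloatingPointError(
                f"training diverged (loss {model.loss_history[-1]}) at epoch "
                f"{len(model.loss_history)}; lower the learning rate"
            )
    return model


def _gd_step(
    params: HibpnParams,
    chain: Chain,
    x_he: np.ndarray,
    x_n: np.ndarray,
    x_h: np.ndarray,
    y: np.ndarray,
    y_cont_std: np.ndarray,
    lr: float,
    mse_weight: float,
) -> float:
    """One full-batch gradient step; returns the pre-step loss."""
    n = x_he.shape[0]
    # shared encoder forward pass (with caches)
    z1 = params.he_up.apply(x_he)
    a1 = relu(z1)
    z2 = params.he_down.apply(a1)
    a_he = relu(z2)
    zn = params.narc_up.apply(x_n) if x_n.shape[1] else np.zeros((n, 0))
    a_n = relu(zn)
    a_hen = np.concatenate([a_he, a_n], axis=1)

    grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def affine_grad(name: str, layer: LayerParams, x_in: np.ndarray, dz: np.ndarray) -> np.ndarray:
        grads[name] = (dz.T @ x_in, dz.sum(axis=0))
        return dz @ layer.weights

    if chain == "forward":
        zm = params.hostile_mid.apply(x_h) if x_h.shape[1] else np.zeros((n, 0))
        a_m = relu(zm)
        a_all = np.concatenate([a_hen, a_m], axis=1)
        zh = params.env_hidden.apply(a_all)
        h = sigmoid(zh)
        p = sigmoid(params.env_out.apply(h))[:, 0]
        loss = _bce(p, y)

        dz_out = ((p - y) / n)[:, None]
        dh = affine_grad("env_out", params.env_out, h, dz_out)
        dzh = dh * h * (1 - h)
        da_all = affine_grad("env_hidden", params.env_hidden, a_all, dzh)
        da_hen = da_all[:, : a_hen.shape[1]]
        da_m = da_all[:, a_hen.shape[1]:]
        if x_h.shape[1]:
            dzm = da_m * (zm > 0)
            affine_grad("hostile_mid", params.hostile_mid, x_h, dzm)
    else:
        zh = params.hostile_hidden.apply(a_hen)
        h = relu(zh)
        p = sigmoid(params.hostile_out_clf.apply(h))[:, 0]
        y_reg = params.hostile_out.apply(h)[:, 0]
        loss = _bce(p, y) + mse_weight * float(np.mean((y_reg - y_cont_std) ** 2))

        dz_clf = ((p - y) / n)[:, None]
        dz_reg = (2.0 * mse_weight * (y_reg - y_cont_std) / n)[:, None]
        dh = affine_grad("hostile_out_clf", params.hostile_out_clf, h, dz_clf)
        dh = dh + affine_grad("hostile_out", params.hostile_out, h, dz_reg)
        dzh = dh * (zh > 0)
        da_hen = affine_grad("hostile_hidden", params.hostile_hidden, a_hen, dzh)

    # back through the shared encoders
    da_he = da_hen[:, : a_he.shape[1]]
    da_n = da_hen[:, a_he.shape[1]:]
    if x_n.shape[1]:
        dzn = da_n * (zn > 0)
        affine_grad("narc_up", params.narc_up, x_n, dzn)
    dz2 = da_he * (z2 > 0)
    da1 = affine_grad("he_down", params.he_down, a1, dz2)
    dz1 = da1 * (z1 > 0)
    affine_grad("he_up", params.he_up, x_he, dz1)

    for name, (dw, db) in grads.items():
        layer: LayerParams = getattr(params, name)
        layer.weights -= lr * dw
        layer.bias -= lr * db
    return loss


@dataclass
class TrainedHibpn:
    """Both trained chains plus the ablation configuration they used."""

    forward: ChainModel
    reverse: ChainModel

    def predict_forward(self, records: Sequence[ParticipantRecord]) -> np.ndarray:
        fm = build_features(records, "forward", drop_groups=self.forward.drop_groups)
        return self.forward.predict_scores(fm)

    def predict_reverse(self, records: Sequence[ParticipantRecord]) -> np.ndarray:
        fm = build_features(records, "reverse", drop_groups=self.reverse.drop_groups)
        return self.reverse.predict_scores(fm)


def train_hibpn(
    train_records: Sequence[ParticipantRecord],
    config: TrainConfig,
    drop_groups: Sequence[str] = (),
    dims_overrides: dict[str, int] | None = None,
) -> TrainedHibpn:
    """Train both chains on the same records, each on its permitted inputs."""
    chains = {}
    for chain in ("forward", "reverse"):
        fm = build_features(train_records, chain, drop_groups=drop_groups)  # type: ignore[arg-type]
        dims = _dims_for(fm, **(dims_overrides or {}))
        cm = train_chain(fm, config, dims=dims)
        cm.drop_groups = tuple(drop_groups)
        chains[chain] = cm
    return TrainedHibpn(forward=chains["forward"], reverse=chains["reverse"])
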