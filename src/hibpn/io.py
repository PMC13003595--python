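"""File formats, manifests and deterministic report serialization.

Cohorts travel as plain UTF-8 CSV (one row per participant, header
required); reports as CSV or JSON with sorted keys and fixed float
formatting (metrics to 4 decimals, percentages to 2) so identical
results serialize to identical bytes.  Every CLI command drops a run
manifest beside its output: the command, the config snapshot, all
seeds and SHA-256 digests of inputs/outputs — enough to reproduce the
run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord
from .evaluation import MetricsReport
from .model import HibpnDims, HibpnParams, LayerParams, Standardizer
from .training import ChainModel, TrainedHibpn

__all__ = [
    "COHORT_COLUMNS",
    "RunManifest",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_report",
    "save_trained",
    "load_trained",
    "file_digest",
]

COHORT_COLUMNS = (
    "id", "gender", "age", "trait_group", "condition",
    "npi16_score", "hsns_score", "basic_needs_score", "estimated_catch_pct",
    "hostile_score", "non_hostile_score", "hostile_bin", "intervention",
)

_INT_COLUMNS = {
    "id", "age", "npi16_score", "hsns_score", "basic_needs_score",
    "hostile_score", "non_hostile_score",
}


def read_cohort_csv(path: str | Path) -> list[ParticipantRecord]:
    """Load and validate a cohort CSV; errors name the offending cell."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: cohort has no rows")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            v = row[col]
            kwargs[col] = int(v) if col in _INT_COLUMNS else (
                float(v) if col == "estimated_catch_pct" else str(v)
            )
        rec = ParticipantRecord(**kwargs)
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def write_cohort_csv(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.as_dict() for r in records], columns=list(COHORT_COLUMNS))
    df["estimated_catch_pct"] = df["estimated_catch_pct"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report, path: str | Path, fmt: str = "json", ndigits: int = 4) -> None:
    """Serialize a report deterministically.

    ``report`` may be a :class:`MetricsReport` or any object with an
    ``as_dict`` method / plain dict.  JSON gets sorted keys; CSV (for
    metric tables) fixed 4-decimal floats.
    """
    path = Path(path)
    if fmt not in ("json", "csv"):
        raise ValueError(f"unknown report format {fmt!r}")
    if isinstance(report, MetricsReport):
        rows = [r.as_dict() for r in report.rows]
        if fmt == "csv":
            df = pd.DataFrame(rows)
            for col in ("acc", "f1", "auc"):
                df[col] = df[col].map(lambda v: f"{v:.{ndigits}f}")
            df.to_csv(path, index=False)
            return
        payload = {"rows": rows}
    else:
        payload = report.as_dict() if hasattr(report, "as_dict") else report
        if fmt == "csv":
            pd.json_normalize(payload).to_csv(path, index=False)
            return
    path.write_text(
        json.dumps(_round_floats(payload, ndigits), sort_keys=True, indent=2) + "\n"
    )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce one CLI run byte for byte."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


# ---------------------------------------------------------------------------
# trained-model archives (both chains + standardizers, bit-exact round trip)

_LAYER_NAMES = (
    "he_up", "he_down", "narc_up", "hostile_mid", "env_hidden",
    "env_out", "hostile_hidden", "hostile_out", "hostile_out_clf",
)


def _pack_chain(prefix: str, cm: ChainModel, arrays: dict) -> None:
    for name, layer in cm.params.layers().items():
        arrays[f"{prefix}{name}__w"] = layer.weights
        arrays[f"{prefix}{name}__b"] = layer.bias
    dims = vars(cm.params.dims)
    arrays[f"{prefix}dims_keys"] = np.array(sorted(dims), dtype="U32")
    arrays[f"{prefix}dims_vals"] = np.array([dims[k] for k in sorted(dims)], dtype=int)
    for block, std in (("he", cm.std_he), ("narc", cm.std_narc), ("host", cm.std_host)):
        if std is None:
            continue
        arrays[f"{prefix}std_{block}__mean"] = std.mean
        arrays[f"{prefix}std_{block}__scale"] = std.scale
        arrays[f"{prefix}std_{block}__cols"] = np.array(std.columns, dtype="U32")
    arrays[f"{prefix}drop_groups"] = np.array(cm.drop_groups, dtype="U40")


def _unpack_chain(prefix: str, chain: str, data) -> ChainModel:
    dims = HibpnDims(**{
        str(k): int(v) for k, v in zip(data[f"{prefix}dims_keys"], data[f"{prefix}dims_vals"])
    })
    layers = {
        name: LayerParams(data[f"{prefix}{name}__w"], data[f"{prefix}{name}__b"])
        for name in _LAYER_NAMES
    }
    params = HibpnParams(dims=dims, **layers)

    def std(block: str) -> Standardizer | None:
        key = f"{prefix}std_{block}__mean"
        if key not in data:
            return None
        return Standardizer(
            mean=data[key],
            scale=data[f"{prefix}std_{block}__scale"],
            columns=tuple(str(c) for c in data[f"{prefix}std_{block}__cols"]),
        )

    std_he, std_narc, std_host = std("he"), std("narc"), std("host")
    assert std_he is not None and std_narc is not None
    return ChainModel(
        chain=chain, params=params,  # type: ignore[arg-type]
        std_he=std_he, std_narc=std_narc, std_host=std_host,
        columns=(
            std_he.columns,
            std_narc.columns,
            std_host.columns if std_host is not None else (),
        ),
        drop_groups=tuple(str(g) for g in data[f"{prefix}drop_groups"]),
    )


def save_trained(model: TrainedHibpn, path: str | Path) -> None:
    """Write both trained chains to one .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    _pack_chain("fwd__", model.forward, arrays)
    _pack_chain("rev__", model.reverse, arrays)
    np.savez(path, **arrays)


def load_trained(path: str | Path) -> TrainedHibpn:
    with np.load(str(path)) as data:
        return TrainedHibpn(
            forward=_unpack_chain("fwd__", "forward", data),
            reverse=_unpack_chain("rev__", "reverse", data),
        )
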