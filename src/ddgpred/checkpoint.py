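"""Single-file model checkpoints.

A checkpoint is one ``.npz`` container holding the head's weight arrays, a
JSON-encoded hyperparameter block, and — for the mock backbone — the
backbone's own state, so a reloaded model reproduces predictions bitwise.
A real language-model backbone is stored only by reference (its name);
loading such a checkpoint requires the optional backbone dependency.
"""

from __future__ import annotations

import json

import numpy as np

from .embedding import MockBackbone
from .heads import ADMISSIBLE_HEADS, EnsembleRegressor, HeadRegressor

_HEAD_KEYS = ("embedding_source", "merge", "hidden_width", "antisymmetric",
              "learning_rate", "warmup_fraction", "epochs", "batch_size",
              "seed", "freeze_backbone", "outer_cap")


def _backbone_config(bb) -> dict:
    if isinstance(bb, MockBackbone):
        return {"kind": "mock", "width": bb.width, "seed": bb.seed,
                "max_length": bb.max_length,
                "locality_window": bb.locality_window, "trainable": bb.trainable}
    return {"kind": "esm", "model_name": getattr(bb, "model_name", "esm2")}


def _pack_head(model: HeadRegressor, prefix: str, arrays: dict, meta: dict) -> None:
    model._check_initialized()
    cfg = {k: getattr(model, k) for k in _HEAD_KEYS}
    cfg["backbone"] = _backbone_config(model.backbone_)
    meta[prefix.rstrip("/") or "head"] = cfg
    for k, v in model.params_.items():
        arrays[f"{prefix}param.{k}"] = v
    if isinstance(model.backbone_, MockBackbone):
        arrays[f"{prefix}bb.proj"] = model.backbone_.proj
        arrays[f"{prefix}bb.bias"] = model.backbone_.bias


def _unpack_head(prefix: str, arrays, cfg: dict) -> HeadRegressor:
    bb_cfg = cfg.pop("backbone")
    if bb_cfg["kind"] == "mock":
        bb = MockBackbone(**{k: v for k, v in bb_cfg.items() if k != "kind"})
        if f"{prefix}bb.proj" in arrays:
            bb.proj = arrays[f"{prefix}bb.proj"]
            bb.bias = arrays[f"{prefix}bb.bias"]
    else:  # pragma: no cover - needs the optional LM dependency
        from .embedding import EsmBackbone
        bb = EsmBackbone(model_name=bb_cfg.get("model_name", EsmBackbone.DEFAULT_MODEL))
    model = HeadRegressor(backbone=bb, **cfg)
    model.backbone_ = bb
    model.params_ = {k.split("param.", 1)[1]: arrays[k] for k in arrays.files
                     if k.startswith(f"{prefix}param.")}
    model.loss_trace_ = np.empty(0)
    return model


def save_model(model, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {}
    if isinstance(model, EnsembleRegressor):
        model._check_members()
        meta["kind"] = "ensemble"
        for name, member in model.members_.items():
            _pack_head(member, f"{name}/", arrays, meta)
    elif isinstance(model, HeadRegressor):
        meta["kind"] = "head"
        _pack_head(model, "", arrays, meta)
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["kind"] == "head":
            return _unpack_head("", data, meta["head"])
        ensemble = EnsembleRegressor()
        ensemble.members_ = {}
        for source, merge in ADMISSIBLE_HEADS:
            name = f"{source}-{merge}"
            ensemble.members_[name] = _unpack_head(f"{name}/", data, meta[name])
        return ensemble
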