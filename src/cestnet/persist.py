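"""Save/load trained networks as a directory of (params.json, weights.npz)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cs_net import ChemicalShiftNetwork
from .scenarios import ValidationError
from .tr_net import TransformationNetwork

__all__ = ["save_model", "load_model"]

_CLASSES = {
    "TransformationNetwork": TransformationNetwork,
    "ChemicalShiftNetwork": ChemicalShiftNetwork,
}


def save_model(model, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "class": type(model).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "fitted": {},
    }
    if hasattr(model, "k_unitless_"):
        meta["fitted"]["k_unitless_"] = model.k_unitless_
    if hasattr(model, "history_"):
        meta["fitted"]["history_"] = model.history_
    if hasattr(model, "n_params_"):
        meta["fitted"]["n_params_"] = model.n_params_
    (path / "params.json").write_text(json.dumps(meta, indent=1))
    weights = model.model_.get_weights()
    np.savez(path / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})


def load_model(path: str | Path):
    path = Path(path)
    meta = json.loads((path / "params.json").read_text())
    cls = _CLASSES.get(meta["class"])
    if cls is None:
        raise ValidationError(f"unknown model class {meta['class']!r}")
    params = {k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()}
    model = cls(**params)
    model.model_ = model._build()
    data = np.load(path / "weights.npz")
    model.model_.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    model.n_params_ = model.model_.n_params
    for key, val in meta["fitted"].items():
        setattr(model, key, val)
    return model
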