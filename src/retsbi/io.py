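"""Config and trace I/O.

Configuration files are YAML (or JSON, which YAML subsumes): penalty-bound
tables, prior tables and field-model geometry all round-trip through plain
mappings.  Traces travel as whitespace-separated columnar text with a
``#``-comment header naming the columns.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .discrepancy import PenaltyBounds
from .efield import RetinaFieldModel
from .sbi import TruncatedNormalPrior

__all__ = [
    "save_trace",
    "load_trace",
    "penalty_bounds_to_file",
    "penalty_bounds_from_file",
    "prior_to_file",
    "prior_from_file",
    "field_model_to_file",
    "field_model_from_file",
]

_INF = "inf"


def save_trace(path, t: np.ndarray, columns: dict) -> None:
    """Write a columnar text table: time plus named value columns."""
    names = ["t", *columns.keys()]
    data = np.column_stack([np.asarray(t, float)]
                           + [np.asarray(v, float) for v in columns.values()])
    np.savetxt(path, data, header=" ".join(names))


def load_trace(path):
    """Read a columnar text table; returns ``(t, {name: column})``."""
    with open(path) as fh:
        header = fh.readline()
    names = header.lstrip("#").split()
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] != len(names):
        raise ValueError(f"{path}: {data.shape[1]} columns, header names "
                         f"{len(names)}")
    return data[:, 0], {n: data[:, i] for i, n in enumerate(names[1:], 1)}


def _enc(x: float):
    if math.isinf(x):
        return _INF if x > 0 else "-" + _INF
    return float(x)


def _dec(x):
    if isinstance(x, str):
        return math.inf if not x.startswith("-") else -math.inf
    return float(x)


def penalty_bounds_to_file(path, bounds: dict) -> None:
    """Write a per-component penalty-bound table (the per-cell-class
    defaults in :mod:`discrepancy` have this shape)."""
    doc = {name: {k: _enc(getattr(b, k)) for k in ("pl", "tl", "tu", "pu")}
           for name, b in bounds.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def penalty_bounds_from_file(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    return {name: PenaltyBounds(**{k: _dec(v) for k, v in row.items()})
            for name, row in doc.items()}


def prior_to_file(path, prior: TruncatedNormalPrior,
                  names: list | None = None) -> None:
    """Write a truncated-normal prior table (mean, std, lower, upper per
    parameter)."""
    names = names or [f"p{i}" for i in range(prior.dim)]
    doc = {n: {"mean": float(prior.mean[i]), "std": float(prior.std[i]),
               "lower": _enc(prior.box[i, 0]), "upper": _enc(prior.box[i, 1])}
           for i, n in enumerate(names)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def prior_from_file(path):
    """Read a prior table; returns ``(prior, parameter_names)``."""
    doc = yaml.safe_load(Path(path).read_text())
    names = list(doc)
    mean = [doc[n]["mean"] for n in names]
    std = [doc[n]["std"] for n in names]
    box = [[_dec(doc[n]["lower"]), _dec(doc[n]["upper"])] for n in names]
    return TruncatedNormalPrior(mean, std, box), names


_FIELD_KEYS = ("sigma_retina", "eps_retina", "sigma_ames", "eps_ames",
               "radius", "h_retina", "h_bath", "electrode_diameter",
               "electrode_pitch", "grid_nr", "grid_nz")


def field_model_to_file(path, model: RetinaFieldModel) -> None:
    doc = asdict(model)
    doc["electrode_centers"] = [list(map(float, c))
                                for c in doc["electrode_centers"]]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def field_model_from_file(path) -> RetinaFieldModel:
    doc = yaml.safe_load(Path(path).read_text())
    doc["electrode_centers"] = tuple(tuple(c)
                                     for c in doc["electrode_centers"])
    return RetinaFieldModel(**doc)
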