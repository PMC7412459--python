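"""The tanh quasi-color network family and the published predictor.

A network in this family maps the transformed pigment pair (SR-S, Lb-A) to
the three CMQ coordinates (qL*, qa*, qb*) through a single hidden layer of
tanh units:

    H_j   = tanh( s * (c_j + w_j1 * SR-S + w_j2 * Lb-A) )
    y_r   = d_r + sum_j v_rj * H_j

with a fixed pre-activation scale s (0.5 in the published model; stored
explicitly so the published coefficients can be carried verbatim).  Because
|tanh| <= 1, each response is confined to the envelope
d_r +/- sum_j |v_rj| for every input whatsoever.

The published 2-3-3 model, fitted to 480 lettuce leaves, ships as a packaged
JSON asset and is returned by :func:`published_cmq_network`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

from .colorimetry import CMQCoordinates
from .pigments import PigmentLevel

__all__ = [
    "TanhNetwork",
    "published_cmq_network",
    "hidden_activations",
    "predict_cmq",
    "predict_cmq_batch",
]

_RESPONSE_NAMES = ("qL", "qa", "qb")


@dataclass(frozen=True)
class TanhNetwork:
    """Weights of a 2-H-3 tanh regression network (immutable).

    Attributes
    ----------
    hidden_weights : (H, 2) array
        Coefficients of each hidden unit on (srs, lba).
    hidden_biases : (H,) array
    output_weights : (3, H) array
        Response rows in the order (qL, qa, qb).
    output_biases : (3,) array
    pre_activation_scale : float
        Scalar multiplying every pre-activation before tanh.
    """

    hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_biases: np.ndarray
    pre_activation_scale: float = 0.5
    hidden_names: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        hw = np.asarray(self.hidden_weights, dtype=float)
        hb = np.asarray(self.hidden_biases, dtype=float)
        ow = np.asarray(self.output_weights, dtype=float)
        ob = np.asarray(self.output_biases, dtype=float)
        h = hb.shape[0]
        if hw.shape != (h, 2) or ow.shape != (3, h) or ob.shape != (3,):
            raise ValueError(
                f"inconsistent shapes: hidden_weights {hw.shape}, "
                f"hidden_biases {hb.shape}, output_weights {ow.shape}, "
                f"output_biases {ob.shape}"
            )
        for arr in (hw, hb, ow, ob):
            if not np.isfinite(arr).all():
                raise ValueError("network coefficients must be finite")
        if not np.isfinite(self.pre_activation_scale):
            raise ValueError("pre_activation_scale must be finite")
        object.__setattr__(self, "hidden_weights", hw)
        object.__setattr__(self, "hidden_biases", hb)
        object.__setattr__(self, "output_weights", ow)
        object.__setattr__(self, "output_biases", ob)
        for arr in (hw, hb, ow, ob):
            arr.setflags(write=False)

    @property
    def hidden_count(self) -> int:
        return self.hidden_biases.shape[0]

    @property
    def parameter_count(self) -> int:
        return 3 * self.hidden_count + 3 * (self.hidden_count + 1)

    def output_bounds(self) -> np.ndarray:
        """(3, 2) attainable [low, high] envelope per response, bias ± Σ|v|."""
        reach = np.abs(self.output_weights).sum(axis=1)
        return np.stack([self.output_biases - reach, self.output_biases + reach], axis=1)

    def lipschitz_bound(self) -> float:
        """Bound on the prediction's rate of change w.r.t. the pigment inputs.

        |tanh'| <= 1, so ||dy/dx||_2 <= s * ||V||_2 * ||W||_2.
        """
        s = abs(self.pre_activation_scale)
        return s * np.linalg.norm(self.output_weights, 2) * np.linalg.norm(
            self.hidden_weights, 2
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        names = self.hidden_names or tuple(
            f"H{j + 1}" for j in range(self.hidden_count)
        )
        return {
            "pre_activation_scale": self.pre_activation_scale,
            "hidden": [
                {
                    "name": names[j],
                    "bias": float(self.hidden_biases[j]),
                    "srs": float(self.hidden_weights[j, 0]),
                    "lba": float(self.hidden_weights[j, 1]),
                }
                for j in range(self.hidden_count)
            ],
            "output": [
                {
                    "name": _RESPONSE_NAMES[r],
                    "bias": float(self.output_biases[r]),
                    "weights": [float(w) for w in self.output_weights[r]],
                }
                for r in range(3)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TanhNetwork":
        hidden = d["hidden"]
        return cls(
            hidden_weights=np.array([[u["srs"], u["lba"]] for u in hidden]),
            hidden_biases=np.array([u["bias"] for u in hidden]),
            output_weights=np.array([r["weights"] for r in d["output"]]),
            output_biases=np.array([r["bias"] for r in d["output"]]),
            pre_activation_scale=float(d["pre_activation_scale"]),
            hidden_names=tuple(u.get("name", f"H{i+1}") for i, u in enumerate(hidden)),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TanhNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


@lru_cache(maxsize=1)
def published_cmq_network() -> TanhNetwork:
    """The published 2-3-3 CMQ predictor, coefficients exactly as printed."""
    text = (
        resources.files("cmqleaf").joinpath("data/published_cmq_network.json").read_text()
    )
    return TanhNetwork.from_dict(json.loads(text))


def _as_xy(p) -> np.ndarray:
    if isinstance(p, PigmentLevel):
        return np.array([p.srs, p.lba], dtype=float)
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise ValueError("expected a PigmentLevel or (srs, lba) pair")
    return arr


def hidden_activations(net: TanhNetwork, p) -> np.ndarray:
    """Hidden-layer activations tanh(s * (c + W x)) at one pigment level."""
    x = _as_xy(p)
    return np.tanh(net.pre_activation_scale * (net.hidden_biases + net.hidden_weights @ x))


def predict_cmq_batch(net: TanhNetwork, srs, lba) -> np.ndarray:
    """Vectorized prediction; returns an (n, 3) array of (qL, qa, qb) rows."""
    X = np.column_stack([np.asarray(srs, dtype=float), np.asarray(lba, dtype=float)])
    H = np.tanh(
        net.pre_activation_scale * (net.hidden_biases + X @ net.hidden_weights.T)
    )
    return net.output_biases + H @ net.output_weights.T


def predict_cmq(net: TanhNetwork, p: PigmentLevel) -> CMQCoordinates:
    """Predict the quasi-color at one pigment level.

    Levels outside the calibrated range are accepted (the model is
    deliberately applied beyond the lettuce training range) but raise a
    :class:`~cmqleaf.pigments.CalibrationWarning`.
    """
    if isinstance(p, PigmentLevel):
        p.warn_if_uncalibrated()
    h = hidden_activations(net, p)
    y = net.output_biases + net.output_weights @ h
    return CMQCoordinates(qL=float(y[0]), qa=float(y[1]), qb=float(y[2]))
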