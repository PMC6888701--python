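"""Declarative network descriptions and trained-model containers.

A :class:`ModelSpec` records what a network *is* — its kind, input
geometry, output arity and an enumeration of its convolutions — so that
parameter counts and shape laws can be checked without instantiating
weights, and so a checkpoint can be rebuilt from its JSON sidecar.
:class:`TrainedModel` couples a spec with an instantiated network.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .nn.layers import Module

__all__ = ["ConvDesc", "ModelSpec", "TrainedModel",
           "separable_param_count", "standard_param_count"]


def standard_param_count(k: int, c_in: int, c_out: int) -> int:
    """Weights of a k x k standard convolution (bias excluded)."""
    if min(k, c_in, c_out) < 1:
        raise ValueError("k, c_in, c_out must be >= 1")
    return k * k * c_in * c_out


def separable_param_count(k: int, c_in: int, c_out: int) -> int:
    """Weights of the depthwise-separable factorization: a k x k depthwise
    filter per input channel plus a 1x1 pointwise mixer (bias excluded).

    For k > 1 this is smaller than the standard count whenever
    c_out > k^2 / (k^2 - 1); at k = 1 the factorization adds parameters,
    which is why 1x1 convolutions are never separated.
    """
    if min(k, c_in, c_out) < 1:
        raise ValueError("k, c_in, c_out must be >= 1")
    return k * k * c_in + c_in * c_out


@dataclass(frozen=True)
class ConvDesc:
    """One convolution in a network, for parameter accounting."""

    name: str
    k: int
    c_in: int
    c_out: int
    kind: str = "standard"       # standard | separable | transpose

    def param_count(self) -> int:
        if self.kind == "separable":
            return separable_param_count(self.k, self.c_in, self.c_out)
        return standard_param_count(self.k, self.c_in, self.c_out)


@dataclass
class ModelSpec:
    """Backend-independent description of a network."""

    kind: str                       # densenet | litesegnet | unet_generator | patch_discriminator
    input_size: tuple[int, int]     # (height, width)
    in_channels: int
    output_arity: int               # classes (classifiers/segmenter) or channels out
    config: dict[str, Any] = field(default_factory=dict)
    convs: list[ConvDesc] = field(default_factory=list)

    def param_count(self) -> int:
        """Analytic weight count over the enumerated convolutions."""
        return int(sum(c.param_count() for c in self.convs))

    def to_json(self) -> str:
        d = {"kind": self.kind, "input_size": list(self.input_size),
             "in_channels": self.in_channels, "output_arity": self.output_arity,
             "config": self.config,
             "convs": [vars(c) for c in self.convs]}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(kind=d["kind"], input_size=tuple(d["input_size"]),
                   in_channels=d["in_channels"], output_arity=d["output_arity"],
                   config=d["config"], convs=[ConvDesc(**c) for c in d["convs"]])


@dataclass
class TrainedModel:
    """A ModelSpec plus instantiated weights and (optionally) its history."""

    spec: ModelSpec
    net: Module
    history: dict = field(default_factory=dict)

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (spec)."""
        os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
        arrs = {f"a{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path_prefix + ".npz", **arrs)
        with open(path_prefix + ".json", "w") as fh:
            fh.write(self.spec.to_json())

    @classmethod
    def load(cls, path_prefix: str, instantiate) -> "TrainedModel":
        """``instantiate`` maps a ModelSpec to a fresh network (each network
        module exports one)."""
        with open(path_prefix + ".json") as fh:
            spec = ModelSpec.from_json(fh.read())
        net = instantiate(spec, seed=0)
        data = np.load(path_prefix + ".npz")
        net.load_state_arrays([data[f"a{i}"] for i in range(len(data.files))])
        return cls(spec=spec, net=net)
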