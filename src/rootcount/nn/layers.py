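"""Layer modules over the autograd ops: parameter containers, initialisation,
and the train/eval distinction (batch-norm statistics, dropout)."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "SeparableConv2d",
    "ConvTranspose2d", "BatchNorm2d", "Dense", "Dropout",
    "ReLU", "LeakyReLU", "Tanh",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: recursive parameter discovery and mode flag."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        """Flat list of arrays (parameters + batch-norm running stats) for
        checkpointing; order is deterministic."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrs):
        arrs = list(arrs)
        for p in self.parameters():
            p.data = np.asarray(arrs.pop(0), dtype=np.float32)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(arrs.pop(0), dtype=np.float64)
                m.running_var = np.asarray(arrs.pop(0), dtype=np.float64)

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, bias=True, *, rng):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.w = Parameter(_he(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.b = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class SeparableConv2d(Module):
    """Depthwise spatial filter followed by a pointwise 1x1 channel mixer.

    Parameter count k*k*c_in + c_in*c_out versus k*k*c_in*c_out for the
    standard convolution it replaces.
    """

    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, bias=True, *, rng):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.dw = Parameter(_he(rng, (in_ch, k, k), k * k))
        self.pw = Parameter(_he(rng, (out_ch, in_ch, 1, 1), in_ch))
        self.b = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        x = ag.depthwise_conv2d(x, self.dw, stride=self.stride, pad=self.pad)
        return ag.conv2d(x, self.pw, self.b, stride=1, pad=0)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=2, pad=1, bias=True, *, rng):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.w = Parameter(_he(rng, (in_ch, out_ch, k, k), in_ch * k * k))
        self.b = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ag.conv_transpose2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.momentum, self.eps, self.training)


def recalibrate_batchnorm(net: Module, forward_fn, batches) -> None:
    """Replace running batch-norm statistics with the exact average of the
    per-batch statistics over ``batches``.

    Running averages with a small momentum lag badly after short trainings;
    this pass re-estimates them the way the original batch-norm procedure
    prescribes for inference.  ``forward_fn(batch)`` must run the network
    forward in training mode.
    """
    bns = [m for m in net.modules() if isinstance(m, BatchNorm2d)]
    saved = [(m.momentum, m.running_mean.copy(), m.running_var.copy()) for m in bns]
    net.train()
    for i, batch in enumerate(batches, start=1):
        for m in bns:
            m.momentum = 1.0 / i
        forward_fn(batch)
    for m, (mom, rm, rv) in zip(bns, saved):
        m.momentum = mom
        if not np.isfinite(m.running_mean).all() or not np.isfinite(m.running_var).all():
            m.running_mean, m.running_var = rm, rv
    net.eval()


class Dense(Module):
    def __init__(self, in_f, out_f, *, rng):
        super().__init__()
        self.w = Parameter(_he(rng, (in_f, out_f), in_f))
        self.b = Parameter(np.zeros(out_f))

    def forward(self, x):
        return ag.linear(x, self.w, self.b)


class Dropout(Module):
    def __init__(self, p, *, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        return ag.dropout(x, self.p, self.rng, self.training)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        return ag.leaky_relu(x, self.alpha)


class Tanh(Module):
    def forward(self, x):
        return ag.tanh(x)
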