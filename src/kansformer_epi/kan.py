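"""Kolmogorov–Arnold network layers with B-spline edge activations.

Instead of fixed node nonlinearities, every edge (p, q) of a layer carries a
learnable univariate function

    phi_{q,p}(x) = w_b[p, q] * silu(x) + w_s[p, q] * sum_j c[p, q, j] B_j(x)

where the B_j are B-spline basis functions on a fixed uniform grid.  A node's
activation is the sum of its incoming edge activations,

    out[q] = sum_p phi_{q,p}(in[p]),

and a network is the left-to-right composition of such layers.  The forward
pass is fully vectorised (basis expansion + one matrix contraction); there is
no per-edge scalar loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Dropout, Module, Parameter


@dataclass(frozen=True)
class SplineBasisSpec:
    """Uniform B-spline basis: ``grid_size`` intervals on ``grid_range``.

    ``order`` is the polynomial degree (cubic by default).  The extended knot
    vector adds ``order`` uniform knots on each side, giving
    ``grid_size + order`` basis functions that form a partition of unity on
    the grid range.  Outside the range each basis function is continued
    linearly from the boundary, so z-scored inputs that occasionally escape
    [-1, 1] still receive bounded, differentiable activations.
    """

    order: int = 3
    grid_size: int = 5
    grid_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        lo, hi = self.grid_range
        if not lo < hi:
            raise ValueError("grid_range must satisfy lo < hi")

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.order

    def knots(self) -> np.ndarray:
        lo, hi = self.grid_range
        step = (hi - lo) / self.grid_size
        return lo + step * np.arange(-self.order, self.grid_size + self.order + 1)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix at ``x`` (numpy, no autodiff); shape x.shape + (n_basis,)."""
        return ad.bspline_basis(Tensor(x), self.knots(), self.order,
                                *self.grid_range).data

    def to_dict(self) -> dict:
        return {"order": self.order, "grid_size": self.grid_size,
                "grid_range": list(self.grid_range)}

    @staticmethod
    def from_dict(d: dict) -> "SplineBasisSpec":
        return SplineBasisSpec(order=d["order"], grid_size=d["grid_size"],
                               grid_range=tuple(d["grid_range"]))


def edge_activation(x: np.ndarray, coeff: np.ndarray, w_b: float, w_s: float,
                    basis: SplineBasisSpec) -> np.ndarray:
    """Evaluate one edge activation phi(x) (numpy convenience, no autodiff)."""
    xt = Tensor(np.asarray(x, dtype=float))
    design = ad.bspline_basis(xt, basis.knots(), basis.order, *basis.grid_range)
    return w_b * ad.silu(xt).data + w_s * (design.data @ np.asarray(coeff))


def fit_edge_coefficients(f, basis: SplineBasisSpec, n_points: int = 256,
                          w_b: float = 0.0) -> np.ndarray:
    """Least-squares spline coefficients so that phi (with w_s=1) matches f."""
    lo, hi = basis.grid_range
    x = np.linspace(lo, hi, n_points)
    design = basis.design(x)
    target = np.asarray([f(v) for v in x], dtype=float)
    if w_b:
        target = target - w_b * (x / (1.0 + np.exp(-x)))
    coeff, *_ = np.linalg.lstsq(design, target, rcond=None)
    return coeff


class KANLayer(Module):
    """One spline layer: n_in -> n_out with per-edge learnable activations."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 basis: SplineBasisSpec | None = None):
        super().__init__()
        self.n_in = n_in
        self.n_out = n_out
        self.basis = basis or SplineBasisSpec()
        nb = self.basis.n_basis
        # symmetric fan-in-scaled base weights: silu has a positive mean, so a
        # constant w_b makes wide layers drift by n_in * E[silu] and saturate
        # downstream sigmoids; zero-mean init keeps activations O(1)
        scale = np.sqrt(3.0 / n_in)
        self.coeff = Parameter(rng.normal(0.0, 0.1 / nb, size=(n_in, n_out, nb)))
        self.w_base = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.w_spline = Parameter(np.ones((n_in, n_out)))
        self._knots = self.basis.knots()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_in:
            raise ValueError(
                f"KAN layer expects width {self.n_in}, got {x.shape[-1]}")
        lead = x.shape[:-1]
        flat = x.reshape(int(np.prod(lead)) if lead else 1, self.n_in)
        design = ad.bspline_basis(flat, self._knots, self.basis.order,
                                  *self.basis.grid_range)   # (N, n_in, nb)
        nb = self.basis.n_basis
        # fold the per-edge spline weight into the coefficient tensor, then
        # contract over (input, basis) in one matmul
        cs = self.coeff * self.w_spline.reshape(self.n_in, self.n_out, 1)
        wmat = cs.transpose(0, 2, 1).reshape(self.n_in * nb, self.n_out)
        spline_part = design.reshape(flat.shape[0], self.n_in * nb) @ wmat
        base_part = ad.silu(flat) @ self.w_base
        out = spline_part + base_part
        return out.reshape(*lead, self.n_out)


class KANNetwork(Module):
    """Composition of KAN layers, first layer applied first.

    ``dropout`` > 0 inserts dropout between consecutive layers (used by the
    classification and distance heads).
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 basis: SplineBasisSpec | None = None, dropout: float = 0.0):
        super().__init__()
        if len(widths) < 2:
            raise ValueError("need at least an input and an output width")
        self.widths = list(widths)
        self.layers = [KANLayer(a, b, rng, basis)
                       for a, b in zip(widths[:-1], widths[1:])]
        self.dropouts = ([Dropout(dropout, rng) for _ in self.layers[:-1]]
                         if dropout > 0 else [])

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if self.dropouts and i < len(self.layers) - 1:
                x = self.dropouts[i](x)
        return x

    def spec_dict(self) -> dict:
        return {"widths": self.widths,
                "basis": self.layers[0].basis.to_dict() if self.layers else None}
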