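"""Parametric axis transforms used by cytometry display scales.

All four families map the instrument range onto a display scale where the
top-of-scale value T lands at 1.  The logicle forward map has no closed
form: its inverse is the Parks-Moore biexponential

    B(y) = a * exp(b*y) - c * exp(-d*y) - f,

and the forward map solves B(y) = x by root-finding.  The parameters
(a, b, c, d, f) are determined by (T, W, M, A): b = (M+A) ln 10, d solves
2 (ln d - ln b) + w (b + d) = 0 with w = W/(M+A), and a, c, f are fixed by
requiring B(1) = T, B(x1) = 0 and slope matching at the linearization
width.  Near zero the scale is effectively linear over roughly [-W, W]
decades; far from zero it is logarithmic.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidTransformError, UnsupportedTransformError
from .model import TransformDef

log = logging.getLogger(__name__)

LN10 = math.log(10.0)


# --------------------------------------------------------------------------
# closed-form families

def flin(x, T: float, A: float = 0.0):
    """Linear display scale: y = (x + A) / (T + A); flin(T) = 1."""
    if T <= 0 or A < 0:
        raise InvalidTransformError("linear transform requires T > 0 and A >= 0")
    return (np.asarray(x, dtype=float) + A) / (T + A)


def flin_inv(y, T: float, A: float = 0.0):
    return np.asarray(y, dtype=float) * (T + A) - A


def flog(x, T: float, M: float):
    """Log display scale: y = log10(x/T)/M + 1 over M decades below T.

    Non-positive inputs are clamped to T*10^(-M-1), one decade below the
    display floor, rather than erroring: compensated cytometry data contain
    negatives and import must not fail on them.
    """
    if T <= 0 or M <= 0:
        raise InvalidTransformError("log transform requires T > 0 and M > 0")
    floor = T * 10.0 ** (-M - 1)
    xc = np.maximum(np.asarray(x, dtype=float), floor)
    return np.log10(xc / T) / M + 1.0


def flog_inv(y, T: float, M: float):
    return T * 10.0 ** (M * (np.asarray(y, dtype=float) - 1.0))


def fasinh(x, T: float, M: float, A: float = 0.0):
    """Inverse-hyperbolic-sine scale (arcsinh), the mass-cytometry staple.

    y = (asinh(x * sinh(M ln10) / T) + A ln10) / ((M + A) ln10);
    fasinh(T) = 1 and fasinh(0) = A / (M + A).
    """
    if T <= 0 or M <= 0 or A < 0:
        raise InvalidTransformError("asinh transform requires T > 0, M > 0, A >= 0")
    x = np.asarray(x, dtype=float)
    return (np.arcsinh(x * math.sinh(M * LN10) / T) + A * LN10) / ((M + A) * LN10)


def fasinh_inv(y, T: float, M: float, A: float = 0.0):
    y = np.asarray(y, dtype=float)
    return T * np.sinh(y * (M + A) * LN10 - A * LN10) / math.sinh(M * LN10)


# --------------------------------------------------------------------------
# logicle

def _check_logicle_params(T: float, W: float, M: float, A: float) -> None:
    if not (T > 0 and M > 0 and 0 <= W <= M / 2 and A >= 0 and A + W <= M):
        raise InvalidTransformError(
            f"logicle parameters out of range: T={T}, W={W}, M={M}, A={A} "
            f"(need T>0, M>0, 0<=W<=M/2, A>=0, A+W<=M)")


class _LogicleParams:
    """Biexponential coefficients (a, b, c, d, f) derived from (T, W, M, A)."""

    def __init__(self, T: float, W: float, M: float, A: float):
        _check_logicle_params(T, W, M, A)
        self.T, self.W, self.M, self.A = T, W, M, A
        b = (M + A) * LN10
        w = W / (M + A)
        x2 = A / (M + A)
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        if w == 0.0:
            d = b
        else:
            # root of 2(ln d - ln b) + w(b + d) = 0 on (0, b)
            d = brentq(lambda dd: 2.0 * (math.log(dd) - math.log(b)) + w * (b + dd),
                       1e-12 * b, b, xtol=1e-300, rtol=8.9e-16)
        c_a = math.exp(x0 * (b + d))
        mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
        a = T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
        c = c_a * a
        f = mf_a * a  # so that B(x1) = 0, i.e. raw 0 maps to display x1
        self.a, self.b, self.c, self.d, self.f = a, b, c, d, f
        self.x1 = x1

    def biexp(self, y):
        """B(y): the closed-form inverse of the logicle display map."""
        y = np.asarray(y, dtype=float)
        return self.a * np.exp(self.b * y) - self.c * np.exp(-self.d * y) - self.f

    def biexp_deriv(self, y):
        y = np.asarray(y, dtype=float)
        return self.a * self.b * np.exp(self.b * y) + self.c * self.d * np.exp(-self.d * y)


def logicle_inverse(y, T: float = 262144.0, W: float = 0.5, M: float = 4.5,
                    A: float = 0.0):
    """Display -> raw: the closed-form Parks-Moore biexponential B(y)."""
    return _LogicleParams(T, W, M, A).biexp(y)


def logicle_forward(x, T: float = 262144.0, W: float = 0.5, M: float = 4.5,
                    A: float = 0.0):
    """Raw -> display: solves B(y) = x to |B(y) - x| <= 1e-10 * T.

    Warm-started by monotone interpolation on a dense grid, then polished
    with safeguarded Newton steps; the tolerance is on the raw axis so
    precision is uniform across the scale.
    """
    p = _LogicleParams(T, W, M, A)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x).astype(float)

    lo_y = -A / (M + A) - 1.0
    hi_y = 2.0
    grid_y = np.linspace(lo_y, hi_y, 513)
    grid_x = p.biexp(grid_y)  # strictly increasing
    y = np.interp(xf, grid_x, grid_y)
    # values beyond the bracket extrapolate via Newton from the bracket edge
    y = np.clip(y, lo_y, hi_y)

    lo = np.full_like(y, lo_y)
    hi = np.full_like(y, hi_y)
    tol = 1e-10 * T
    for _ in range(100):
        fx = p.biexp(y) - xf
        step = fx / p.biexp_deriv(y)
        # converged on both axes: raw residual and display-scale step size
        if np.all(np.abs(fx) <= tol) and np.all(np.abs(step) <= 1e-12):
            break
        lo = np.where(fx < 0, y, lo)
        hi = np.where(fx > 0, y, hi)
        y_newton = y - step
        inside = (y_newton > lo) & (y_newton < hi)
        y = np.where(inside, y_newton, 0.5 * (lo + hi))
    out = y.reshape(x.shape) if not scalar else float(y[0])
    return out


# --------------------------------------------------------------------------
# dispatch

class Transform:
    """Callable forward/inverse pair for one TransformDef, vectorized."""

    def __init__(self, tdef: TransformDef):
        self.tdef = tdef
        fam = tdef.family
        if fam == "linear":
            self.forward = lambda x: flin(x, tdef.T, tdef.A)
            self.inverse = lambda y: flin_inv(y, tdef.T, tdef.A)
        elif fam == "log":
            self.forward = lambda x: flog(x, tdef.T, tdef.M)
            self.inverse = lambda y: flog_inv(y, tdef.T, tdef.M)
        elif fam == "asinh":
            self.forward = lambda x: fasinh(x, tdef.T, tdef.M, tdef.A)
            self.inverse = lambda y: fasinh_inv(y, tdef.T, tdef.M, tdef.A)
        elif fam == "logicle":
            _check_logicle_params(tdef.T, tdef.W, tdef.M, tdef.A)
            self.forward = lambda x: logicle_forward(x, tdef.T, tdef.W, tdef.M, tdef.A)
            self.inverse = lambda y: logicle_inverse(y, tdef.T, tdef.W, tdef.M, tdef.A)
        else:
            raise UnsupportedTransformError(f"unknown transform family {fam!r}")


def make_transform(tdef: TransformDef) -> Transform:
    """Build the forward/inverse pair for a transform declaration."""
    return Transform(tdef)


class IdentityTransform:
    """No-op transform used for gates drawn on the linear scale."""

    def forward(self, x):
        return np.asarray(x, dtype=float)

    inverse = forward


IDENTITY_TRANSFORM = IdentityTransform()


def flowjo_width_basis_to_W(wb: float, T: float, M: float) -> float:
    """Map a FlowJo biexponential width basis onto the logicle W parameter.

    W = max(0, (M - log10(T/|wb|)) / 2); a documented approximation to how
    FlowJo's width slider relates to the logicle linearization width.
    """
    if wb == 0:
        return 0.0
    return max(0.0, (M - math.log10(T / abs(wb))) / 2.0)
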