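"""Intensity transformations: logicle, arcsinh, linear, and per-file z-score.

Fluorescence intensities span several decades and include genuinely negative
values (compensation spill, baseline noise), so a pure log display is both
undefined below zero and visually misleading near it. The logicle transform
is the inverse of a biexponential

    B(y) = a e^{b y} - c e^{-d y} - f

whose constants are chosen from four interpretable parameters: ``T`` the top
of scale, ``M`` the total display decades, ``W`` the width (in decades) of
the quasi-linear region around zero, and ``A`` additional negative display
decades. ``B(1) = T`` and ``B`` is smoothly linear near zero and
logarithmic at high intensity. The parameterization follows the published
logicle definition used by Gating-ML; the forward transform inverts ``B``
numerically (vectorized bisection with a Newton polish).

Per-file z-score normalization is provided but OFF by default: on panels
whose files differ in population composition it perturbs the regression
inputs and introduces imputation artifacts, so the default pipeline runs on
the logicle scale without it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LogicleParams",
    "TransformSpec",
    "logicle",
    "inverse_logicle",
    "arcsinh_transform",
    "zscore_normalize",
    "estimate_logicle_width",
    "apply_transform",
]


@dataclass(frozen=True)
class LogicleParams:
    """Logicle display parameters ``(T, W, M, A)``.

    Defaults suit a 18-bit digital cytometer: full scale ``T = 262144``,
    ``M = 4.5`` display decades, no extra negative decades. ``W`` defaults
    to 0.5 decades of linearization; per-channel values are usually
    estimated from the negative tail (see :func:`estimate_logicle_width`).
    """

    T: float = 262144.0
    W: float = 0.5
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("logicle T must be > 0")
        if self.M <= 0:
            raise ValueError("logicle M must be > 0")
        if not 0 <= self.W <= self.M / 2:
            raise ValueError(f"logicle W must lie in [0, M/2]; got W={self.W}, M={self.M}")
        if self.A < 0 or self.A > self.M - 2 * self.W:
            raise ValueError(
                f"logicle A must lie in [0, M - 2W]; got A={self.A}, "
                f"M={self.M}, W={self.W}"
            )


class _Biexp:
    """Constants (a, b, c, d, f) of the biexponential for given (T, W, M, A).

    Derivation: with w = W/(M+A), x2 = A/(M+A), x1 = x2 + w, x0 = x2 + 2w
    and b = (M+A) ln 10, the decay rate d solves
    ``2 (ln d - ln b) + w (b + d) = 0`` so that the quasi-linear region has
    width W decades; the remaining constants pin B(x1) = 0 and B(1) = T.
    Below x1 the curve is the point reflection of the upper branch about
    (x1, 0), which keeps it strictly increasing and smooth through zero.
    """

    def __init__(self, p: LogicleParams) -> None:
        T, W, M, A = p.T, p.W, p.M, p.A
        w = W / (M + A)
        x2 = A / (M + A)
        self.x1 = x2 + w
        b = (M + A) * np.log(10.0)
        if w == 0:
            d = b
        else:
            fn = lambda d: 2.0 * (np.log(d) - np.log(b)) + w * (b + d)
            d = brentq(fn, 1e-12, b, xtol=1e-14, rtol=8.9e-16)
        x0 = x2 + 2 * w
        c_a = np.exp(x0 * (b + d))
        f_a = np.exp(b * self.x1) - c_a * np.exp(-d * self.x1)
        self.a = T / (np.exp(b) - c_a * np.exp(-d) - f_a)
        self.b = b
        self.c = c_a * self.a
        self.d = d
        self.f = f_a * self.a
        self.T = T

    def _upper(self, y: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * y) - self.c * np.exp(-self.d * y) - self.f

    def value(self, y: np.ndarray) -> np.ndarray:
        """B(y), with the branch below x1 reflected about (x1, 0)."""
        y = np.asarray(y, dtype=np.float64)
        hi = y >= self.x1
        out = np.empty_like(y)
        out[hi] = self._upper(y[hi])
        out[~hi] = -self._upper(2 * self.x1 - y[~hi])
        return out

    def derivative(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        yy = np.where(y >= self.x1, y, 2 * self.x1 - y)
        return self.a * self.b * np.exp(self.b * yy) + self.c * self.d * np.exp(
            -self.d * yy
        )


def _biexp_cache(p: LogicleParams) -> _Biexp:
    # tiny memo so repeated vector calls don't re-solve for d
    key = (p.T, p.W, p.M, p.A)
    hit = _biexp_cache._store.get(key)
    if hit is None:
        hit = _Biexp(p)
        _biexp_cache._store[key] = hit
    return hit


_biexp_cache._store = {}  # type: ignore[attr-defined]


def inverse_logicle(y, p: LogicleParams = LogicleParams()):
    """Evaluate the biexponential ``B(y)`` (the closed-form logicle inverse)."""
    bx = _biexp_cache(p)
    arr = bx.value(np.asarray(y, dtype=np.float64))
    return float(arr) if np.isscalar(y) else arr


def logicle(x, p: LogicleParams = LogicleParams()):
    """Logicle-transform intensities ``x`` onto the display scale.

    Solves ``B(y) = x`` per element to ``|B(y) - x| <= T * 1e-10`` by
    bisection followed by a Newton polish; strictly increasing in ``x``,
    with ``logicle(T) = 1``.
    """
    bx = _biexp_cache(p)
    scalar = np.isscalar(x)
    x_arr = np.atleast_1d(np.asarray(x, dtype=np.float64))
    # bracket on display scale: generous below the negative decades, above 1
    lo_y = -(p.A / (p.M + p.A)) - p.W / (p.M + p.A) - 1.5
    hi_y = 1.5
    lo = np.full(x_arr.shape, lo_y)
    hi = np.full(x_arr.shape, hi_y)
    # grow the bracket for values beyond it (rare; off-scale events)
    for _ in range(60):
        bad = bx.value(lo) > x_arr
        if not bad.any():
            break
        lo[bad] -= 1.0
    for _ in range(60):
        bad = bx.value(hi) < x_arr
        if not bad.any():
            break
        hi[bad] += 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = bx.value(mid) < x_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    y = 0.5 * (lo + hi)
    tol = bx.T * 1e-10
    for _ in range(4):
        resid = bx.value(y) - x_arr
        if np.all(np.abs(resid) <= tol):
            break
        step = resid / bx.derivative(y)
        y_new = np.clip(y - step, lo, hi)
        y = y_new
    return float(y[0]) if scalar else y


def estimate_logicle_width(
    x: np.ndarray, T: float = 262144.0, M: float = 4.5
) -> float:
    """Estimate the linearization width W from the negative tail of ``x``.

    Uses the 5th percentile of the negative events, ``W = (M - log10(T/|r|)) / 2``,
    clamped to ``[0.25, M/2]``; with no negative events returns the 0.25 floor.
    """
    x = np.asarray(x, dtype=np.float64)
    neg = x[x < 0]
    if neg.size == 0:
        return 0.25
    r = np.percentile(neg, 5.0)
    w = (M - np.log10(T / abs(r))) / 2.0
    return float(np.clip(w, 0.25, M / 2))


def arcsinh_transform(x, cofactor: float = 150.0):
    """Elementwise ``asinh(x / cofactor)``; ``cofactor`` must be positive."""
    if cofactor <= 0:
        raise ValueError(f"arcsinh cofactor must be > 0, got {cofactor}")
    out = np.arcsinh(np.asarray(x, dtype=np.float64) / cofactor)
    return float(out) if np.isscalar(x) else out


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Center and scale ``x`` to mean 0, sample sd 1 (n-1 denominator).

    Applied per channel per source file when enabled. A constant vector has
    no scale; it maps to zeros with a warning. Disabled in the default
    pipeline: per-file standardization distorts imputation when files differ
    in population composition.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("z-score of a constant vector: returning zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class TransformSpec:
    """Which transform applies to which channel.

    ``kind`` is the default for fluorescence channels (``logicle``,
    ``arcsinh``, ``linear`` or ``zscore``); scatter and time channels are
    always left linear. ``per_channel`` overrides the kind for named
    channels. ``logicle_w`` fixes W globally; when None, W is estimated per
    channel from its negative tail.
    """

    kind: str = "logicle"
    T: float = 262144.0
    M: float = 4.5
    A: float = 0.0
    logicle_w: float | None = None
    cofactor: float = 150.0
    per_channel: Mapping[str, str] = field(default_factory=dict)

    _KINDS = ("logicle", "arcsinh", "linear", "zscore")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        for ch, k in self.per_channel.items():
            if k not in self._KINDS:
                raise ValueError(f"unknown transform kind {k!r} for channel {ch!r}")

    def kind_for(self, channel_name: str, role: str = "passthrough") -> str:
        if channel_name in self.per_channel:
            return self.per_channel[channel_name]
        if role in ("scatter", "time"):
            return "linear"
        return self.kind

    def logicle_params_for(self, column: np.ndarray) -> LogicleParams:
        w = (
            self.logicle_w
            if self.logicle_w is not None
            else estimate_logicle_width(column, self.T, self.M)
        )
        return LogicleParams(T=self.T, W=w, M=self.M, A=self.A)


def apply_transform(
    column: np.ndarray,
    spec: TransformSpec,
    channel_name: str,
    role: str = "passthrough",
) -> np.ndarray:
    """Transform one channel's column per ``spec`` (z-score handled upstream)."""
    kind = spec.kind_for(channel_name, role)
    if kind == "linear":
        return np.asarray(column, dtype=np.float64)
    if kind == "arcsinh":
        return arcsinh_transform(column, spec.cofactor)
    if kind == "logicle":
        return logicle(column, spec.logicle_params_for(column))
    if kind == "zscore":
        return zscore_normalize(column)
    raise AssertionError(kind)
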