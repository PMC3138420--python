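"""Length normalization of numeric vectors by interpolation.

A vector of L values is treated as samples of a function at knot positions
1..L.  To change its length to D, the vector is interpolated — by a straight
line between neighbours, or by a cubic spline with one of three boundary
treatments — and the interpolant is evaluated on the uniform target grid

    x_j = 1 + (j - 1) (L - 1) / (D - 1),   j = 1..D,

which spans [1, L] inclusively, so the first and last output values always
equal the first and last input values.

The cubic splines are solved in second-derivative (moment) form: with unit
knot spacing, interior continuity of the first derivative gives the
tridiagonal system

    (1/6) M_{i-1} + (2/3) M_i + (1/6) M_{i+1} = y_{i+1} - 2 y_i + y_{i-1}

closed by the boundary condition:

``natural``
    M_1 = M_L = 0 (zero curvature at the ends).
``periodic``
    equal first and second derivatives at the two endpoints (requires
    y_1 = y_L); the resulting cyclic-tridiagonal system is solved by
    Sherman--Morrison reduction to two Thomas solves.
``fmm``
    the Forsythe--Malcolm--Moler condition: the third derivative of each
    end piece equals the third derivative of the exact cubic through the
    outermost four points at that end.  This reproduces any global cubic
    exactly.  Requires L >= 4; L = 3 falls back to natural and L = 2 to
    linear (with a warning).
``spline``
    accepted as an alias of ``fmm``.

All systems are solved directly (Thomas algorithm); there is no iteration
and no extrapolation — evaluation outside [1, L] is an error.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Endpoint-equality tolerance for the periodic boundary condition.
PERIODIC_ENDPOINT_TOL = 1e-9


class InterpolationMethod(enum.Enum):
    """The five public method names."""

    LINEAR = "linear"
    SPLINE = "spline"
    FMM = "fmm"
    NATURAL = "natural"
    PERIODIC = "periodic"

    @classmethod
    def parse(cls, name: "str | InterpolationMethod") -> "InterpolationMethod":
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name).lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown interpolation method {name!r}; valid names: {valid}"
            ) from None


@dataclass(frozen=True)
class CubicSplineModel:
    """A fitted cubic spline: knot values y at positions 1..L and the
    second derivatives (moments) M at the knots."""

    knot_values: np.ndarray
    second_derivatives: np.ndarray
    boundary: str

    @property
    def n_knots(self) -> int:
        return len(self.knot_values)


def _as_vector(values, min_len: int = 2) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if len(v) < min_len:
        raise ValueError(f"need at least {min_len} values, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v


def _thomas(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Direct solve of a tridiagonal system (Thomas algorithm).

    ``lower``/``upper`` have length n-1.  No pivoting: every system built
    here is strictly diagonally dominant.
    """
    n = len(diag)
    b = diag.astype(float).copy()
    d = rhs.astype(float).copy()
    for i in range(1, n):
        w = lower[i - 1] / b[i - 1]
        b[i] -= w * upper[i - 1]
        d[i] -= w * d[i - 1]
    x = np.empty(n)
    x[-1] = d[-1] / b[-1]
    for i in range(n - 2, -1, -1):
        x[i] = (d[i] - upper[i] * x[i + 1]) / b[i]
    return x


def _solve_cyclic(diag_val: float, off_val: float, rhs: np.ndarray) -> np.ndarray:
    """Solve the n x n cyclic-tridiagonal system with constant diagonal
    ``diag_val``, constant off-diagonal/corner ``off_val``.

    n >= 3 uses Sherman--Morrison: the corner entries are removed by a
    rank-one update A = T + u v^T and the two resulting tridiagonal systems
    are solved with the Thomas algorithm.  n <= 2 is solved in closed form.
    """
    n = len(rhs)
    if n == 1:
        # single unknown: diagonal plus both corners folded onto it
        return rhs / (diag_val + 2 * off_val)
    if n == 2:
        # both off-diagonal and corner couple the same pair of unknowns
        a, b = diag_val, 2 * off_val
        det = a * a - b * b
        return np.array(
            [(a * rhs[0] - b * rhs[1]) / det, (a * rhs[1] - b * rhs[0]) / det]
        )
    gamma = -diag_val  # conventional choice keeping T well conditioned
    diag = np.full(n, diag_val)
    diag[0] -= gamma
    diag[-1] -= off_val * off_val / gamma
    lower = np.full(n - 1, off_val)
    upper = np.full(n - 1, off_val)
    u = np.zeros(n)
    u[0] = gamma
    u[-1] = off_val
    v = np.zeros(n)
    v[0] = 1.0
    v[-1] = off_val / gamma
    y = _thomas(lower, diag, upper, rhs)
    q = _thomas(lower, diag, upper, u)
    factor = (v @ y) / (1.0 + v @ q)
    return y - factor * q


def fit_cubic_spline(values, boundary: str = "natural") -> CubicSplineModel:
    """Fit the knot second derivatives for the given boundary condition.

    ``boundary`` is one of ``natural``, ``periodic``, ``fmm`` (``spline``
    accepted as an fmm alias).  See the module docstring for definitions
    and the small-L fallback rules for fmm.
    """
    if boundary == "spline":
        boundary = "fmm"
    if boundary not in ("natural", "periodic", "fmm"):
        raise ValueError(
            f"unknown boundary {boundary!r}; valid: natural, periodic, fmm"
        )
    y = _as_vector(values)
    L = len(y)

    if boundary == "fmm" and L == 3:
        logger.warning("fmm requires >= 4 knots; falling back to natural for L=3")
        boundary = "natural"
    if boundary == "fmm" and L == 2:
        raise ValueError(
            "fmm requires >= 4 knots and has no cubic meaning for L=2; "
            "use the linear method"
        )

    if boundary == "natural":
        M = np.zeros(L)
        if L > 2:
            d = y[2:] - 2 * y[1:-1] + y[:-2]
            n = L - 2
            M[1:-1] = _thomas(
                np.full(n - 1, 1 / 6), np.full(n, 2 / 3), np.full(n - 1, 1 / 6), d
            )
        return CubicSplineModel(y, M, "natural")

    if boundary == "periodic":
        if abs(y[0] - y[-1]) > PERIODIC_ENDPOINT_TOL:
            raise ValueError(
                "periodic boundary requires equal endpoint values "
                f"(got {y[0]!r} and {y[-1]!r}); pass coerce_periodic=True to "
                "resample() to overwrite the last value with the first"
            )
        if L == 2:
            return CubicSplineModel(y, np.zeros(2), "periodic")
        # unknowns M_1..M_{L-1}, with M_L identified with M_1
        yc = y[:-1]
        n = L - 1
        rhs = np.empty(n)
        rhs[0] = y[1] - 2 * y[0] + y[-2]
        for i in range(1, n):
            rhs[i] = y[i + 1] - 2 * y[i] + y[i - 1]
        Mc = _solve_cyclic(2 / 3, 1 / 6, rhs)
        M = np.empty(L)
        M[:-1] = Mc
        M[-1] = Mc[0]
        return CubicSplineModel(y, M, "periodic")

    # fmm, L >= 4: third-derivative end conditions from the 4-point cubics.
    # With unit spacing, 6 * f[x1..x4] = y4 - 3 y3 + 3 y2 - y1, and the end
    # piece's third derivative is M_2 - M_1, giving M_1 = M_2 - dl.
    dl = y[3] - 3 * y[2] + 3 * y[1] - y[0]
    dr = y[-1] - 3 * y[-2] + 3 * y[-3] - y[-4]
    d = y[2:] - 2 * y[1:-1] + y[:-2]
    n = L - 2
    diag = np.full(n, 2 / 3)
    rhs = d.copy()
    diag[0] = 5 / 6
    rhs[0] = d[0] + dl / 6
    diag[-1] = 5 / 6
    rhs[-1] = d[-1] - dr / 6
    Mm = _thomas(np.full(n - 1, 1 / 6), diag, np.full(n - 1, 1 / 6), rhs)
    M = np.empty(L)
    M[1:-1] = Mm
    M[0] = M[1] - dl
    M[-1] = M[-2] + dr
    return CubicSplineModel(y, M, "fmm")


def evaluate_spline(model: CubicSplineModel, x) -> np.ndarray | float:
    """Evaluate the piecewise cubic at position(s) x in [1, L].

    On interval [i, i+1] with t = x - i (unit spacing):

        S(x) = M_i (1-t)^3/6 + M_{i+1} t^3/6
               + (y_i - M_i/6)(1-t) + (y_{i+1} - M_{i+1}/6) t
    """
    y = model.knot_values
    M = model.second_derivatives
    L = model.n_knots
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    if np.any(xa < 1.0) or np.any(xa > L):
        raise ValueError(f"evaluation position outside knot range [1, {L}]")
    i = np.clip(np.floor(xa).astype(int), 1, L - 1) - 1
    t = xa - (i + 1)
    s = 1.0 - t
    out = (
        M[i] * s**3 / 6
        + M[i + 1] * t**3 / 6
        + (y[i] - M[i] / 6) * s
        + (y[i + 1] - M[i + 1] / 6) * t
    )
    return float(out[0]) if scalar else out


def linear_interpolant(values, x) -> np.ndarray | float:
    """Piecewise-linear interpolant of values at knots 1..L, evaluated at x.

    Connects neighbouring data points with straight segments; exact at the
    integer knots.  No extrapolation: x outside [1, L] is an error.
    """
    y = _as_vector(values)
    L = len(y)
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    if np.any(xa < 1.0) or np.any(xa > L):
        raise ValueError(f"evaluation position outside [1, {L}]")
    i = np.clip(np.floor(xa).astype(int), 1, L - 1) - 1
    t = xa - (i + 1)
    out = y[i] + t * (y[i + 1] - y[i])
    return float(out[0]) if scalar else out


def target_grid(source_length: int, dims: int) -> np.ndarray:
    """The uniform target grid x_j = 1 + (j-1)(L-1)/(D-1) spanning [1, L]."""
    if dims < 2:
        raise ValueError(f"target dimension must be >= 2, got {dims}")
    if source_length < 2:
        raise ValueError(f"source length must be >= 2, got {source_length}")
    xs = 1.0 + np.arange(dims) * (source_length - 1) / (dims - 1)
    xs[-1] = float(source_length)  # guard against rounding past the last knot
    return xs


def resample(
    values,
    dims: int,
    method: str | InterpolationMethod = InterpolationMethod.LINEAR,
    *,
    coerce_periodic: bool = False,
) -> np.ndarray:
    """Resample a length-L vector to length ``dims``.

    The chosen interpolant is evaluated on :func:`target_grid`; the first
    and last outputs therefore always equal the first and last inputs.
    ``coerce_periodic`` overwrites the last value with the first (with a
    warning) before a periodic fit, for data whose endpoints differ.
    """
    method = InterpolationMethod.parse(method)
    y = _as_vector(values)
    L = len(y)
    xs = target_grid(L, dims)

    if method is InterpolationMethod.PERIODIC and coerce_periodic:
        if abs(y[0] - y[-1]) > PERIODIC_ENDPOINT_TOL:
            logger.warning(
                "periodic coercion: overwriting last value %g with first %g",
                y[-1],
                y[0],
            )
            y = y.copy()
            y[-1] = y[0]

    if method is InterpolationMethod.LINEAR:
        out = np.asarray(linear_interpolant(y, xs))
    elif method in (InterpolationMethod.SPLINE, InterpolationMethod.FMM) and L == 2:
        logger.warning("fmm/spline with L=2 falls back to linear interpolation")
        out = np.asarray(linear_interpolant(y, xs))
    else:
        model = fit_cubic_spline(y, method.value)
        out = np.asarray(evaluate_spline(model, xs))
    # evaluation at the end knots is exact in exact arithmetic; pin them so
    # the endpoint-preservation contract holds bitwise in floating point too
    out[0] = y[0]
    out[-1] = y[-1]
    return out
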