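"""General conic fitting and shape descriptors for anterior-capsule arcs.

A radial Scheimpflug cut shows the anterior lens capsule as a planar curve.
Fitting the general conic

    a x^2 + 2 h x y + b y^2 + 2 g x + 2 f y + n = 0

through annotated capsule points characterises the local surface geometry.
For an elliptical fit the eccentricity ``e``, asphericity ``Q = -e**2`` and
shape factor ``SF = 1 - e**2`` summarise how prolate the meridional section
is; a steepening surface (accommodation) shows up as a drop in ``e``.

The equation is homogeneous, so the coefficient vector is only defined up to
scale: we store it with unit Euclidean norm and the sign fixed so that
``a + b >= 0`` (first nonzero coefficient positive when ``a + b == 0``).
Five points in general position determine the conic exactly; the fit is the
null direction of the design matrix with rows ``(x^2, 2xy, y^2, 2x, 2y, 1)``,
which doubles as the total-least-squares solution when more than five points
are given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConicCoefficients",
    "CanonicalConic",
    "LensShapeParams",
    "ConicFitError",
    "DegenerateConicError",
    "UnsupportedShapeError",
    "ConicModel",
    "ConicFitResults",
    "fit_conic_through_points",
    "classify_conic",
    "canonical_form",
    "eccentricity",
]

#: classification tolerance on unit-norm coefficients (double precision with
#: pixel coordinates up to ~1e4)
_CLASSIFY_TOL = 1e-12

#: null-space ambiguity ratio above which a fit is flagged as ill-conditioned
#: (short arcs barely constrain the conic)
_CONDITION_WARN_RATIO = 0.1


class ConicFitError(ValueError):
    """Input points cannot support a conic fit."""


class DegenerateConicError(ValueError):
    """The configuration or coefficients describe a degenerate conic."""


class UnsupportedShapeError(ValueError):
    """Shape parameters requested for a conic class that has none here."""


@dataclass(frozen=True)
class ConicCoefficients:
    """Unit-norm coefficients of ``a x^2 + 2hxy + b y^2 + 2gx + 2fy + n = 0``."""

    a: float
    h: float
    b: float
    g: float
    f: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.h, self.b, self.g, self.f, self.n])

    @staticmethod
    def from_array(v: np.ndarray) -> "ConicCoefficients":
        v = np.asarray(v, dtype=float)
        if v.shape != (6,):
            raise ValueError("coefficient vector must have 6 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("coefficients must be finite")
        if np.allclose(v[:3], 0.0) and np.allclose(v[3:], 0.0):
            raise ValueError("zero coefficient vector")
        v = v / np.linalg.norm(v)
        s = v[0] + v[2]  # a + b
        if s < 0:
            v = -v
        elif s == 0:
            nz = v[np.nonzero(v)[0]]
            if nz.size and nz[0] < 0:
                v = -v
        return ConicCoefficients(*v)

    def evaluate(self, x, y):
        """Conic polynomial value at point(s); zero on the curve."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            self.a * x * x
            + 2 * self.h * x * y
            + self.b * y * y
            + 2 * self.g * x
            + 2 * self.f * y
            + self.n
        )


@dataclass(frozen=True)
class CanonicalConic:
    """Centre, semi-axes and major-axis orientation of a central conic."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians in (-pi/2, pi/2]


@dataclass(frozen=True)
class LensShapeParams:
    """Eccentricity ``e``, asphericity ``Q = -e^2``, shape factor ``SF = 1 - e^2``."""

    e: float
    q: float
    sf: float


def _design_matrix(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([x * x, 2 * x * y, y * y, 2 * x, 2 * y, np.ones_like(x)])


def _validate_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConicFitError("points must be an (n, 2) array-like")
    if pts.shape[0] < 5:
        raise ConicFitError(f"need at least 5 points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ConicFitError("points must be finite")
    # pairwise-distinct check; n is tiny (5..~50) so O(n^2) is fine
    d = pts[:, None, :] - pts[None, :, :]
    dist2 = (d * d).sum(-1)
    np.fill_diagonal(dist2, np.inf)
    if dist2.min() == 0.0:
        raise ConicFitError("points must be pairwise distinct")
    return pts


def fit_conic_through_points(points: Sequence) -> ConicCoefficients:
    """Fit the general conic through >= 5 planar points.

    Exactly five points in general position give the unique interpolating
    conic (smallest-singular-value direction of the 5x6 design matrix); more
    points give the total-least-squares conic.  Points are centred and
    isotropically scaled before the solve for numerical conditioning, and the
    coefficients are mapped back to the input frame.

    Raises
    ------
    ConicFitError
        Fewer than 5 points, non-finite or duplicated points.
    DegenerateConicError
        Five points whose design matrix has rank < 5 (e.g. four collinear),
        so no unique conic exists.
    """
    pts = _validate_points(points)
    n_pts = pts.shape[0]

    t = pts.mean(axis=0)
    rms = np.sqrt(((pts - t) ** 2).sum(axis=1).mean())
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    work = (pts - t) * s

    D = _design_matrix(work)
    _, sv, vt = np.linalg.svd(D, full_matrices=True)

    if n_pts == 5 and (sv.size < 5 or sv[4] <= 1e-10 * sv[0]):
        raise DegenerateConicError(
            "degenerate 5-point configuration (design matrix rank < 5)"
        )

    # null-direction ambiguity: ratio of the two smallest singular values of
    # the full 6-column system (near 1 means the data barely prefer one conic
    # over another).  With exactly 5 rows the 6th singular value is 0.
    sv6 = np.concatenate([sv, np.zeros(6 - sv.size)]) if sv.size < 6 else sv
    cond_ratio = float(sv6[5] / sv6[4]) if sv6[4] > 0 else 1.0
    if cond_ratio > _CONDITION_WARN_RATIO:
        warnings.warn(
            f"ill-conditioned conic fit (null-space ambiguity {cond_ratio:.3g});"
            " arc may be too short to constrain the conic",
            stacklevel=2,
        )

    ap, hp, bp, gp, fp, np_ = vt[-1]

    # substitute x' = s (x - tx), y' = s (y - ty) back into the conic
    tx, ty = t
    s2 = s * s
    a = ap * s2
    h = hp * s2
    b = bp * s2
    g = -ap * s2 * tx - hp * s2 * ty + gp * s
    f = -hp * s2 * tx - bp * s2 * ty + fp * s
    const = (
        ap * s2 * tx * tx
        + 2 * hp * s2 * tx * ty
        + bp * s2 * ty * ty
        - 2 * gp * s * tx
        - 2 * fp * s * ty
        + np_
    )
    return ConicCoefficients.from_array(np.array([a, h, b, g, f, const]))


def classify_conic(c: ConicCoefficients) -> str:
    """Classify unit-norm coefficients.

    Returns one of ``ellipse``, ``circle``, ``parabola``, ``hyperbola``,
    ``degenerate`` from the discriminant ``delta = h^2 - a b`` and the full
    3x3 determinant.  Both invariants are measured relative to the norm of
    the quadratic part ``(a, h, b)``: for a conic far from the origin the
    unit-norm vector is dominated by the constant term and the raw
    determinant shrinks like the cube of the quadratic scale, so an absolute
    threshold would spuriously flag translated ellipses as degenerate (and
    break the similarity invariance of the eccentricity).
    """
    a, h, b, g, f, n = c.a, c.h, c.b, c.g, c.f, c.n
    q = np.linalg.norm([a, h, b])
    if q <= _CLASSIFY_TOL:
        return "degenerate"  # no quadratic part: a line, not a conic
    a, h, b, g, f, n = (v / q for v in (a, h, b, g, f, n))
    delta = h * h - a * b
    full = np.linalg.det(np.array([[a, h, g], [h, b, f], [g, f, n]]))
    if abs(full) <= _CLASSIFY_TOL:
        return "degenerate"
    if delta < -_CLASSIFY_TOL:
        if abs(a - b) <= _CLASSIFY_TOL and abs(h) <= _CLASSIFY_TOL:
            return "circle"
        return "ellipse"
    if delta <= _CLASSIFY_TOL:
        return "parabola"
    return "hyperbola"


def canonical_form(c: ConicCoefficients) -> CanonicalConic:
    """Centre, semi-axes and orientation of an elliptical conic.

    The centre solves ``[[a, h], [h, b]] (cx, cy) = (-g, -f)``; the semi-axes
    come from the eigenvalues of the quadratic-part matrix.

    Raises
    ------
    DegenerateConicError
        Non-central conic, or an imaginary ellipse (no real points).
    """
    label = classify_conic(c)
    if label not in ("ellipse", "circle"):
        raise DegenerateConicError(f"canonical form requires an ellipse, got {label}")
    M = np.array([[c.a, c.h], [c.h, c.b]])
    center = np.linalg.solve(M, np.array([-c.g, -c.f]))
    c0 = c.g * center[0] + c.f * center[1] + c.n
    lam, vec = np.linalg.eigh(M)
    ratios = -c0 / lam
    if np.any(ratios <= 0):
        raise DegenerateConicError("imaginary ellipse (no real locus)")
    axes = np.sqrt(ratios)
    i_major = int(np.argmax(axes))
    v = vec[:, i_major]
    theta = float(np.arctan2(v[1], v[0]))
    while theta <= -np.pi / 2:
        theta += np.pi
    while theta > np.pi / 2:
        theta -= np.pi
    return CanonicalConic(
        center=(float(center[0]), float(center[1])),
        semi_major=float(axes[i_major]),
        semi_minor=float(axes[1 - i_major]),
        orientation=theta,
    )


def _eccentricity_invariant(c: ConicCoefficients) -> float:
    """Closed-form e^2 from the coefficient invariants (real-ellipse branch)."""
    a, b, h = c.a, c.b, c.h
    r = np.sqrt((a - b) ** 2 + 4 * h * h)
    eta = 1.0 if (a + b) >= 0 else -1.0
    denom = eta * (a + b) + r
    return float(np.sqrt(2 * r / denom))


def eccentricity(c: ConicCoefficients) -> LensShapeParams:
    """Eccentricity / asphericity / shape factor of an elliptical or parabolic fit.

    For an ellipse ``e = sqrt(1 - (semi_minor/semi_major)^2)`` via the
    canonical form, cross-checked against the invariant formula
    ``e^2 = 2 sqrt((a-b)^2 + 4h^2) / (eta (a+b) + sqrt((a-b)^2 + 4h^2))``.
    Parabolas return ``e = 1`` exactly.  ``Q = -e^2`` and ``SF = 1 - e^2``.

    Raises
    ------
    UnsupportedShapeError
        Hyperbolic or degenerate coefficients; callers treat the cut as
        flagged rather than silently coercing the fit.
    """
    label = classify_conic(c)
    if label == "parabola":
        return LensShapeParams(e=1.0, q=-1.0, sf=0.0)
    if label == "circle":
        return LensShapeParams(e=0.0, q=0.0, sf=1.0)
    if label != "ellipse":
        raise UnsupportedShapeError(
            f"eccentricity undefined for a {label} fit; cut should be flagged"
        )
    can = canonical_form(c)
    ratio = can.semi_minor / can.semi_major
    e = float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))
    e_inv = _eccentricity_invariant(c)
    # near e = 0 the sqrt amplifies rounding noise, so also accept agreement
    # on e^2 (the invariant formula's native scale)
    if abs(e - e_inv) > 1e-10 and abs(e * e - e_inv * e_inv) > 1e-12:
        raise DegenerateConicError(
            f"eccentricity routes disagree (eigen {e!r} vs invariant {e_inv!r}); "
            "coefficients are numerically inconsistent"
        )
    return LensShapeParams(e=e, q=-e * e, sf=1.0 - e * e)


class ConicModel:
    """Conic section fitted to planar capsule points.

    A thin modelling surface over :func:`fit_conic_through_points`:
    ``ConicModel(points).fit()`` returns a :class:`ConicFitResults` carrying
    the coefficients, classification, canonical geometry (when elliptical),
    shape parameters and interpolation residuals.
    """

    def __init__(self, points: Sequence):
        self.points = _validate_points(points)

    def fit(self) -> "ConicFitResults":
        coeffs = fit_conic_through_points(self.points)
        return ConicFitResults(self, coeffs)


class ConicFitResults:
    """Fitted conic with derived geometry and diagnostics."""

    def __init__(self, model: ConicModel, coefficients: ConicCoefficients):
        self.model = model
        self.coefficients = coefficients
        self.conic_class = classify_conic(coefficients)

    @property
    def residuals(self) -> np.ndarray:
        """Algebraic residuals at the input points (unit-norm coefficients)."""
        pts = self.model.points
        return self.coefficients.evaluate(pts[:, 0], pts[:, 1])

    @property
    def canonical(self) -> CanonicalConic:
        return canonical_form(self.coefficients)

    @property
    def shape(self) -> LensShapeParams:
        return eccentricity(self.coefficients)

    def summary(self) -> str:
        c = self.coefficients
        lines = [
            "Conic fit",
            "=" * 40,
            f"n points       : {self.model.points.shape[0]}",
            f"class          : {self.conic_class}",
            "coefficients   : a={:+.6f} h={:+.6f} b={:+.6f}".format(c.a, c.h, c.b),
            "                 g={:+.6f} f={:+.6f} n={:+.6f}".format(c.g, c.f, c.n),
            f"max |residual| : {np.abs(self.residuals).max():.3e}",
        ]
        if self.conic_class in ("ellipse", "circle"):
            can = self.canonical
            sh = self.shape
            lines += [
                f"center         : ({can.center[0]:.4f}, {can.center[1]:.4f})",
                f"semi-axes      : {can.semi_major:.4f} / {can.semi_minor:.4f}",
                f"orientation    : {np.degrees(can.orientation):.2f} deg",
                f"e / Q / SF     : {sh.e:.4f} / {sh.q:.4f} / {sh.sf:.4f}",
            ]
        return "\n".join(lines)
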