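"""Box-counting fractal dimension of a binary collagen mask.

The 2-D box-counting dimension D measures how completely a planar set fills
space: the frame is partitioned into grids of ε×ε boxes, N(ε) counts the
boxes containing at least one foreground pixel, and D is the slope d of
log N(ε) against log(1/ε).  Because the ε→0 limit cannot be taken on a
finite raster, D is estimated as the slope of the most linear contiguous
segment of the log–log plot, with the slope itself computed by Tukey's
iterated three-group resistant line — robust to single outlying ladder
points — rather than plain least squares.

For planar masks 0 ≤ D ≤ 2: a single pixel has D = 0, a straight line D = 1,
and a space-filling region D = 2.  The closer D is to 2, the more the
collagen conformation fills the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .imaging import BinaryMask


def dyadic_epsilons(shape: tuple[int, int], max_divisor: int = 4) -> list[int]:
    """Default box-size ladder: powers of 2 from 2 up to
    ``floor(min(H, W) / max_divisor)``, in descending order."""
    cap = min(shape) // max_divisor
    eps = []
    e = 2
    while e <= cap:
        eps.append(e)
        e *= 2
    return eps[::-1]


def geometric_epsilons(shape: tuple[int, int], base: int = 3, start: int = 1) -> list[int]:
    """Ladder of powers of ``base`` from ``start`` up to min(H, W), descending.

    A base-3 ladder is the natural calibration grid for triadic constructions
    such as the Sierpinski carpet, where N(3^-k) follows an exact power law.
    """
    cap = min(shape)
    eps = []
    e = start
    while e <= cap:
        eps.append(e)
        e *= base
    if not eps:
        raise ValidationError(f"no ladder points: start={start} exceeds min(shape)={cap}")
    return eps[::-1]


def box_counts(mask: BinaryMask, epsilons: "list[int]") -> list[int]:
    """Count, for each box side ε, the ε×ε grid boxes (anchored at the
    top-left corner) containing at least one foreground pixel."""
    grid = mask.grid
    if not grid.any():
        raise DegenerateInputError("box counting is undefined on an empty mask")
    H, W = grid.shape
    counts = []
    for e in epsilons:
        e = int(e)
        if e < 1 or e > min(H, W):
            raise ValidationError(f"box size {e} outside [1, {min(H, W)}]")
        nh, nw = -(-H // e), -(-W // e)
        padded = np.zeros((nh * e, nw * e), bool)
        padded[:H, :W] = grid
        counts.append(int(padded.reshape(nh, e, nw, e).any(axis=(1, 3)).sum()))
    return counts


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R²; constant y is a perfect (horizontal) fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0, 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return float(slope), float(min(max(r2, 0.0), 1.0))


def select_linear_segment(
    log_points: "list[tuple[float, float]]",
    min_points: int = 5,
) -> tuple[int, int]:
    """Select the most linear contiguous window of the log–log plot.

    Among all contiguous windows of length ≥ ``min_points``, returns the
    half-open index range ``(start, stop)`` maximizing ordinary-least-squares
    R².  Ties are broken in favour of the longer window, then the window
    lying toward smaller ε (larger log(1/ε), i.e. later indices when points
    are ordered by descending ε).
    """
    if min_points < 4:
        raise ValidationError("min_points must be >= 4")
    n = len(log_points)
    if n < min_points:
        raise ValidationError(f"need at least {min_points} log-log points, got {n}")
    xs = np.array([p[0] for p in log_points], float)
    ys = np.array([p[1] for p in log_points], float)
    best: "tuple[float, int, int] | None" = None  # (r2, length, start)
    best_range = (0, n)
    for length in range(min_points, n + 1):
        for start in range(0, n - length + 1):
            stop = start + length
            _, r2 = _ols(xs[start:stop], ys[start:stop])
            key = (round(r2, 12), length, start)
            if best is None or key > best:
                best = key
                best_range = (start, stop)
    return best_range


def resistant_line_slope(
    points: "list[tuple[float, float]]",
    max_iter: int = 10,
    tol: float = 1e-6,
) -> tuple[float, int]:
    """Tukey three-group resistant-line slope, iterated on residuals.

    Points are sorted by x and split into left / middle / right thirds (the
    remainder goes to the middle).  The slope is the ratio of the differences
    of the group medians of y and of x between the right and left thirds.
    Each iteration refits the rule to the residuals and accumulates the
    correction until it falls below ``tol`` or ``max_iter`` is reached.

    Returns ``(slope, n_iterations)``.
    """
    pts = sorted(points, key=lambda p: p[0])
    n = len(pts)
    if n < 4:
        raise ValidationError(f"resistant line needs >= 4 points, got {n}")
    xs = np.array([p[0] for p in pts], float)
    ys = np.array([p[1] for p in pts], float)
    if len(np.unique(xs)) < 3:
        raise ValidationError("resistant line needs >= 3 distinct x values")

    k = n // 3
    left = slice(0, k)
    right = slice(n - k, n)
    x_l, x_r = float(np.median(xs[left])), float(np.median(xs[right]))
    if x_r == x_l:
        raise ValidationError("left and right thirds share the same median x")

    slope = 0.0
    iterations = 0
    resid = ys.copy()
    for _ in range(max_iter):
        delta = (float(np.median(resid[right])) - float(np.median(resid[left]))) / (x_r - x_l)
        slope += delta
        resid = ys - slope * xs
        iterations += 1
        if abs(delta) < tol:
            break
    return slope, iterations


@dataclass(frozen=True)
class FractalConfig:
    """Ladder and fitting settings for the dimension estimate.

    ``epsilons=None`` uses the dyadic default ladder for the mask's frame.
    ``min_points`` is clamped down to the number of available ladder points
    when a small frame yields fewer (but never below 4).
    """

    epsilons: "tuple[int, ...] | None" = None
    min_points: int = 5
    max_iter: int = 10
    tol: float = 1e-6


@dataclass(frozen=True)
class FractalFit:
    """Full audit record of one dimension estimate."""

    epsilons: tuple[int, ...]          # descending box sides
    counts: tuple[int, ...]            # N(ε), same order
    log_points: tuple[tuple[float, float], ...]  # (log 1/ε, log N(ε))
    segment: tuple[int, int]           # half-open index range of the fit
    slope_d: float
    dimension_D: float
    r_squared: float
    n_iterations: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "epsilons": list(self.epsilons),
                "counts": list(self.counts),
                "log_points": [list(p) for p in self.log_points],
                "segment": list(self.segment),
                "slope_d": self.slope_d,
                "dimension_D": self.dimension_D,
                "r_squared": self.r_squared,
                "n_iterations": self.n_iterations,
            },
            indent=2,
        )


def estimate_fractal_dimension(
    mask: BinaryMask,
    config: "FractalConfig | None" = None,
) -> FractalFit:
    """Estimate D for a nonempty mask: box counts → log–log points → linear
    segment selection → resistant-line slope on that segment.

    The reported ``dimension_D`` equals the slope clipped into [0, 2], the
    admissible range for planar sets; ``slope_d`` keeps the raw value.
    """
    config = config or FractalConfig()
    if mask.is_empty():
        raise DegenerateInputError("fractal dimension is undefined on an empty mask")
    eps = (
        list(config.epsilons)
        if config.epsilons is not None
        else dyadic_epsilons(mask.shape)
    )
    if len(eps) < 4:
        raise ValidationError(
            f"epsilon ladder yields only {len(eps)} points; need >= 4 "
            f"(frame {mask.shape} too small for the configured ladder)"
        )
    counts = box_counts(mask, eps)
    log_points = [(float(np.log(1.0 / e)), float(np.log(c))) for e, c in zip(eps, counts)]
    min_points = min(config.min_points, len(log_points))
    start, stop = select_linear_segment(log_points, min_points=max(min_points, 4))
    slope, n_iter = resistant_line_slope(
        log_points[start:stop], max_iter=config.max_iter, tol=config.tol
    )
    xs = np.array([p[0] for p in log_points[start:stop]])
    ys = np.array([p[1] for p in log_points[start:stop]])
    _, r2 = _ols(xs, ys)
    return FractalFit(
        epsilons=tuple(int(e) for e in eps),
        counts=tuple(counts),
        log_points=tuple(log_points),
        segment=(start, stop),
        slope_d=float(slope),
        dimension_D=float(min(max(slope, 0.0), 2.0)),
        r_squared=r2,
        n_iterations=n_iter,
    )
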