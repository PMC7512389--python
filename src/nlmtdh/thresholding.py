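"""Minimum relative-entropy threshold selection on a 2-D histogram.

A threshold vector (s, t) splits the joint histogram into a background box
(i <= s, j <= t, class 0) and an object box (i > s, j > t, class 1). Each
class is summarized by its mass P_k and mean vector mu_k = (mu_ki, mu_kj).
The selection criterion is the cross-entropy-style objective

    D(s, t) = C - P0 (mu_0i log mu_0i + mu_0j log mu_0j)
                - P1 (mu_1i log mu_1i + mu_1j log mu_1j),

with the image-wide constant C = sum_ij (i p_ij log i + j p_ij log j). The
selected threshold vector minimizes D over the full (s, t) grid. Because C
counts every histogram cell while the class terms only recover mass in the
two diagonal boxes, D charges the gray-level "energy" of the off-diagonal
quadrants (edges and noise) in full, so the minimizer must keep most mass
in the diagonal boxes while making each class tight around its mean.

A related *direct* form accumulates the Kullback-Leibler discrepancy of the
two diagonal boxes only:

    D_direct(s, t) = sum_{i<=s, j<=t} [ i p log(i/mu_0i) + j p log(j/mu_0j) ]
                   + sum_{i>s, j>t}   [ i p log(i/mu_1i) + j p log(j/mu_1j) ].

The two differ by exactly the off-diagonal entropy term
sum_{quadrants 2, 4} (i p log i + j p log j), which depends on (s, t): the
forms are equivalent only when the histogram carries no off-diagonal mass.
The direct form is minimized trivially by corner thresholds that dump the
image into quadrants 2/4, so the reduced form above is the operative
criterion; the direct form is exposed for analysis
(``relative_entropy_objective(..., form="direct")``).

Conventions: natural logarithm; terms with gray level 0 or p_ij = 0
contribute zero; a vector leaving either class empty is infeasible and
skipped by the search. Ties are broken toward the lexicographically
smallest (s, t).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import rel_entr, xlogy

from ._util import DEFAULT_LEVELS, validate_gray_image
from .exceptions import DegenerateInputError, InfeasibleThresholdError, InputError
from .histogram2d import Histogram2D, build_joint_histogram

__all__ = [
    "ThresholdVector",
    "ClassStatistics",
    "ObjectiveValue",
    "class_statistics",
    "relative_entropy_objective",
    "objective_constant",
    "select_threshold",
    "binarize",
    "kl_divergence",
]

# Masses below this are treated as empty when deciding feasibility; counts of
# at least one pixel out of any realistic image are far above it, while
# accumulated float dust from prefix sums stays far below.
_MASS_EPS = 1e-12


@dataclass(frozen=True)
class ThresholdVector:
    """A pair of cut-offs: s on the original image, t on the companion."""

    s: int
    t: int

    def __iter__(self):
        return iter((self.s, self.t))


@dataclass(frozen=True)
class ClassStatistics:
    """Masses and mean vectors of the two diagonal classes at one (s, t)."""

    P0: float
    P1: float
    mu0: tuple[float, float]
    mu1: tuple[float, float]

    @property
    def feasible(self) -> bool:
        return self.P0 > _MASS_EPS and self.P1 > _MASS_EPS


@dataclass(frozen=True)
class ObjectiveValue:
    """Relative-entropy objective D together with the class statistics."""

    D: float
    P0: float
    P1: float
    mu0: tuple[float, float]
    mu1: tuple[float, float]


def class_statistics(h: Histogram2D, tv: ThresholdVector) -> ClassStatistics:
    """Class masses P0, P1 and mean vectors mu0, mu1 at threshold vector tv.

    Class 0 occupies the box i <= s, j <= t; class 1 the box i > s, j > t.
    A mean vector is reported as (nan, nan) when its class carries no mass;
    the ``feasible`` flag on the result is then False.
    """
    s, t = tv
    L = h.levels
    p = h.p
    i = np.arange(L, dtype=np.float64)

    q0 = p[: s + 1, : t + 1]
    q1 = p[s + 1 :, t + 1 :]
    P0 = float(q0.sum())
    P1 = float(q1.sum())

    def mean_vec(q: np.ndarray, rows: np.ndarray, cols: np.ndarray, mass: float):
        if mass <= _MASS_EPS:
            return (float("nan"), float("nan"))
        mi = float((q.sum(axis=1) * rows).sum() / mass)
        mj = float((q.sum(axis=0) * cols).sum() / mass)
        return (mi, mj)

    mu0 = mean_vec(q0, i[: s + 1], i[: t + 1], P0)
    mu1 = mean_vec(q1, i[s + 1 :], i[t + 1 :], P1)
    return ClassStatistics(P0=P0, P1=P1, mu0=mu0, mu1=mu1)


def _level_entropy_cell_terms(h: Histogram2D) -> np.ndarray:
    """Per-cell values i p_ij log i + j p_ij log j (zero at level 0)."""
    L = h.levels
    i = np.arange(L, dtype=np.float64)
    li = np.where(i > 0, np.log(np.where(i > 0, i, 1.0)), 0.0)
    ipli = (i * li)[:, None] * h.p
    jplj = (i * li)[None, :] * h.p
    return ipli + jplj


def objective_constant(h: Histogram2D) -> float:
    """The image-wide constant C = sum_ij (i p_ij log i + j p_ij log j)."""
    return float(_level_entropy_cell_terms(h).sum())


def relative_entropy_objective(
    h: Histogram2D, tv: ThresholdVector, form: str = "reduced"
) -> float:
    """Relative-entropy objective D between the image and its two-class
    approximation at threshold vector ``tv``.

    ``form="reduced"`` (default) evaluates the operative criterion
    C - P0 (mu_0i log mu_0i + mu_0j log mu_0j) - P1 (...), the quantity
    :func:`select_threshold` minimizes. ``form="direct"`` evaluates the
    diagonal-boxes-only Kullback-Leibler sum instead (see module docstring
    for how the two relate). Raises :class:`InfeasibleThresholdError` when
    either class is empty at ``tv``.
    """
    if form not in ("reduced", "direct"):
        raise InputError(f"form must be 'reduced' or 'direct', got {form!r}")
    stats = class_statistics(h, tv)
    if not stats.feasible:
        raise InfeasibleThresholdError(
            f"threshold vector ({tv.s}, {tv.t}) leaves a class empty "
            f"(P0={stats.P0:.3g}, P1={stats.P1:.3g})"
        )
    s, t = tv
    L = h.levels
    idx = np.arange(L, dtype=np.float64)

    def box_term(q: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 mu: tuple[float, float]) -> float:
        # sum of i*p*log(i/mu_i) + j*p*log(j/mu_j); zero-level terms vanish
        ri = rows[:, None]
        cj = cols[None, :]
        ti = np.where(ri > 0, ri * q * (np.log(np.where(ri > 0, ri, 1.0)) - np.log(mu[0])), 0.0)
        tj = np.where(cj > 0, cj * q * (np.log(np.where(cj > 0, cj, 1.0)) - np.log(mu[1])), 0.0)
        return float(ti.sum() + tj.sum())

    d = box_term(h.p[: s + 1, : t + 1], idx[: s + 1], idx[: t + 1], stats.mu0)
    d += box_term(h.p[s + 1 :, t + 1 :], idx[s + 1 :], idx[t + 1 :], stats.mu1)
    if form == "direct":
        return d
    # reduced = direct + entropy carried by the off-diagonal quadrants
    cells = _level_entropy_cell_terms(h)
    off_diag = float(cells[: s + 1, t + 1 :].sum() + cells[s + 1 :, : t + 1].sum())
    return d + off_diag


def _corner_sums(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative low-low box sums C[s, t] and the complementary high-high
    box sums for every (s, t), via inclusion-exclusion on one prefix table."""
    c = np.cumsum(np.cumsum(a, axis=0), axis=1)
    total = c[-1, -1]
    high = total - c[:, -1:] - c[-1:, :] + c
    return c, high


def _objective_surface(h: Histogram2D) -> tuple[np.ndarray, np.ndarray]:
    """Reduced-form D over the full (s, t) grid (inf where infeasible) and
    the feasibility mask.

    Built from prefix tables of p, i*p and j*p, so the whole L x L surface
    costs O(L^2). The value at each feasible (s, t) equals the per-vector
    evaluation of :func:`relative_entropy_objective` up to float round-off.
    """
    L = h.levels
    p = h.p
    i = np.arange(L, dtype=np.float64)
    ip = p * i[:, None]
    jp = p * i[None, :]

    P0, P1 = _corner_sums(p)
    Si0, Si1 = _corner_sums(ip)
    Sj0, Sj1 = _corner_sums(jp)
    const = objective_constant(h)

    feasible = (P0 > _MASS_EPS) & (P1 > _MASS_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        # S * log(mu) with mu = S / P; xlogy handles empty moment sums (S = 0)
        def moment_term(S: np.ndarray, P: np.ndarray) -> np.ndarray:
            return xlogy(S, S) - xlogy(S, P)

        D = const - (
            moment_term(Si0, P0)
            + moment_term(Sj0, P0)
            + moment_term(Si1, P1)
            + moment_term(Sj1, P1)
        )
    D = np.where(feasible, D, np.inf)
    return D, feasible


def select_threshold(
    h: Histogram2D, surface_csv: Optional[str | Path] = None
) -> tuple[ThresholdVector, ObjectiveValue]:
    """Exhaustive minimization of the relative-entropy objective.

    Scans every (s, t) in [0, L-1]^2, skipping vectors that leave a class
    empty, and returns the feasible vector with minimal D; ties break toward
    the smallest s, then the smallest t. Optionally writes the objective
    surface (one CSV row per s, ``inf`` at infeasible cells) for inspection.

    Raises :class:`DegenerateInputError` when no vector is feasible, e.g.
    for the histogram of a constant image.
    """
    D, feasible = _objective_surface(h)
    if surface_csv is not None:
        np.savetxt(surface_csv, D, delimiter=",", fmt="%.17g")
    if not feasible.any():
        raise DegenerateInputError(
            "no feasible threshold vector: every (s, t) leaves a class empty "
            "(the histogram may come from a constant image)"
        )
    flat = int(np.argmin(D))  # row-major scan == lexicographic tie-break
    s, t = divmod(flat, h.levels)
    tv = ThresholdVector(s=int(s), t=int(t))
    stats = class_statistics(h, tv)
    return tv, ObjectiveValue(
        D=float(D[s, t]), P0=stats.P0, P1=stats.P1, mu0=stats.mu0, mu1=stats.mu1
    )


def binarize(
    original: np.ndarray,
    companion: np.ndarray,
    tv: ThresholdVector,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Binary mask from a threshold vector on the (original, companion) pair.

    Pixels in the low-low box (I <= s and J <= t) are background, pixels in
    the high-high box are foreground. Pixels in the off-diagonal quadrants
    (edges and noise) are attached to whichever class mean vector is nearer
    in the (i, j) gray-level plane, ties going to the background.
    """
    a = validate_gray_image(original, levels)
    b = validate_gray_image(companion, levels)
    if a.shape != b.shape:
        raise InputError(f"image shapes differ: {a.shape} vs {b.shape}")
    s, t = tv
    low = (a <= s) & (b <= t)
    high = (a > s) & (b > t)
    mask = high.copy()

    mixed = ~(low | high)
    if mixed.any():
        stats = class_statistics(build_joint_histogram(a, b, levels), tv)

        def dist2(mu: tuple[float, float]) -> np.ndarray:
            if not np.isfinite(mu[0]):
                return np.full(a.shape, np.inf)
            return (a - mu[0]) ** 2 + (b - mu[1]) ** 2

        mask[mixed] = (dist2(stats.mu1) < dist2(stats.mu0))[mixed]
    return mask


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum_i p_i log(p_i / q_i) between two
    discrete distributions, with 0 log(0/q) = 0.

    Both arguments must be same-length probability vectors; q may vanish
    only where p does.
    """
    pa = np.asarray(p, dtype=np.float64)
    qa = np.asarray(q, dtype=np.float64)
    if pa.shape != qa.shape or pa.ndim != 1:
        raise InputError(f"p and q must be same-length vectors, got {pa.shape} and {qa.shape}")
    if np.any(pa < 0) or np.any(qa < 0):
        raise InputError("probabilities must be nonnegative")
    if abs(pa.sum() - 1.0) > 1e-6 or abs(qa.sum() - 1.0) > 1e-6:
        raise InputError("p and q must each sum to 1")
    if np.any((qa == 0) & (pa > 0)):
        raise InputError("q vanishes where p has mass: divergence is infinite")
    return float(rel_entr(pa, qa).sum())
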