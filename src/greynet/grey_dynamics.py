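"""Dynamic grey association (DGA) over entropy-adaptive sliding windows.

Grey relational analysis (GRA) scores how closely the trajectory of a
comparative series tracks a reference series.  For a target gene y and
comparative gene x the per-position relational coefficient inside a
window of length L is

    xi_ki = (min_k min_i D + rho * max_k max_i D) / (D_ki + rho * max_k max_i D)

where D_ki = |y_i - x_ki| is the absolute residual, the extrema pool
over all comparative genes and in-window positions, and rho in (0, 1]
is the distinguished coefficient (conventionally 0.5).  The per-window
grade is the mean of xi over the window, and the dynamic grey
association is the mean grade over all windows of an adaptive schedule.

The schedule adapts window length to local signal complexity: each
completed window's absolute first differences are softmax-normalised
into probabilities, their Shannon entropy E_i (bits) is computed, and
the next length is L_{i+1} = round(E_i / E_{i-1} * L_i), clamped to
[L_min, L_max].  High-entropy (busy) stretches therefore stretch the
window while quiet stretches shrink it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ExpressionTable, ValidationError

__all__ = [
    "first_difference",
    "softmax_entropy",
    "next_window_length",
    "build_window_schedule",
    "window_relational_grade",
    "dynamic_grey_association",
    "WindowSchedule",
    "EntropyRecord",
    "GreyWindowResult",
    "AssociationMatrix",
    "DgaParams",
    "normalize_block",
]


@dataclass
class EntropyRecord:
    probabilities: np.ndarray
    entropy: float  # bits, in [0, log2(len(p))]


@dataclass
class WindowSchedule:
    """Consecutive non-overlapping ``(start, length)`` windows tiling the
    difference axis of one series."""

    windows: list[tuple[int, int]]
    bounds: tuple[int, int]
    L_init: int

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)


@dataclass
class GreyWindowResult:
    xi: np.ndarray        # (n_comparatives, L) grey coefficients
    grade: np.ndarray     # (n_comparatives,) per-gene window means
    rho: float


@dataclass
class AssociationMatrix:
    """m x m dynamic grey association scores; entry (k, j) scores
    comparative gene k against target gene j; diagonal fixed at 0."""

    scores: np.ndarray
    gene_ids: list[str]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        m = len(self.gene_ids)
        if self.scores.shape != (m, m):
            raise ValidationError("association matrix shape mismatch")


@dataclass
class DgaParams:
    """Tunables of the dynamic grey association.

    rho : distinguished coefficient of the relational coefficient.
    L_init : first window length; default max(3, round((n-1)/5)).
    bounds : (L_min, L_max) clamp on adapted lengths; default (2, n-1).
    normalization : per-gene, per-block rescaling before residuals.
    pool_extrema : pool Eq.-8 extrema per window or across all windows.
    """

    rho: float = 0.5
    L_init: int | None = None
    bounds: tuple[int | None, int | None] = (None, None)
    normalization: str = "zscore"   # zscore | minmax | none
    pool_extrema: str = "window"    # window | global

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValidationError(f"rho must be in (0, 1], got {self.rho}")
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.pool_extrema not in ("window", "global"):
            raise ValidationError(f"unknown pool_extrema {self.pool_extrema!r}")

    def resolved(self, n_timepoints: int) -> tuple[int, tuple[int, int]]:
        """Concrete (L_init, (L_min, L_max)) for a block of n timepoints."""
        n_diff = n_timepoints - 1
        L_init = self.L_init if self.L_init is not None else max(3, round(n_diff / 5))
        L_min = self.bounds[0] if self.bounds[0] is not None else 2
        L_max = self.bounds[1] if self.bounds[1] is not None else n_diff
        if L_min < 2:
            raise ValidationError("L_min must be >= 2")
        if L_max < L_min:
            raise ValidationError("L_max must be >= L_min")
        L_init = int(np.clip(L_init, L_min, L_max))
        return L_init, (L_min, L_max)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def first_difference(series: Sequence[float]) -> np.ndarray:
    """Consecutive differences ``series[i+1] - series[i]`` (length n-1)."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("first_difference needs a 1-D series of length >= 2")
    return np.diff(arr)


def softmax_entropy(diff_segment: Sequence[float]) -> EntropyRecord:
    """Softmax the absolute differences and take their Shannon entropy.

    Returns probabilities ``p_i = exp(|d_i|) / sum exp(|d_j|)`` and
    ``E = -sum p_i log2 p_i`` in bits; zero-probability terms contribute 0.
    """
    seg = np.abs(np.asarray(diff_segment, dtype=float))
    if seg.ndim != 1 or seg.size == 0:
        raise ValidationError("softmax_entropy needs a nonempty 1-D segment")
    z = seg - seg.max()  # stable softmax
    p = np.exp(z)
    p /= p.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    # clip the tiny negative round-off a singleton can produce
    return EntropyRecord(probabilities=p, entropy=max(entropy, 0.0))


def next_window_length(
    E_curr: float, E_prev: float, L_prev: int, bounds: tuple[int, int]
) -> int:
    """Entropy-ratio update of the window length, rounded half-to-even
    and clamped to bounds.  A degenerate previous entropy (E_prev = 0)
    keeps the length unchanged."""
    L_min, L_max = bounds
    if L_prev < 2:
        raise ValidationError("L_prev must be >= 2")
    if E_prev <= 0:
        return int(np.clip(L_prev, L_min, L_max))
    raw = E_curr / E_prev * L_prev
    return int(np.clip(round(raw), L_min, L_max))


def build_window_schedule(
    target_series: Sequence[float],
    L_init: int,
    bounds: tuple[int, int],
) -> WindowSchedule:
    """Tile the difference axis of one target series with adaptive windows.

    The first window has length ``L_init``; afterwards each completed
    window's softmax entropy of |first differences| drives the next
    length through :func:`next_window_length`.  The pre-history entropy
    is taken as ``log2(L_init)`` (maximum-entropy baseline), so the
    second window only shrinks if the first was genuinely low-entropy.
    Trailing points shorter than ``L_min`` become a final short window
    when at least 2 remain, otherwise they join the previous window.
    """
    diffs = first_difference(target_series)
    n = diffs.size
    L_min, L_max = bounds
    if n < L_init:
        raise ValidationError(
            f"series too short: {n} difference points < L_init={L_init}"
        )
    windows: list[tuple[int, int]] = []
    E_prev = float(np.log2(L_init))  # maximum-entropy prior for window 0
    L = L_init
    start = 0
    while n - start >= L_min:
        L_take = min(L, n - start)
        windows.append((start, L_take))
        E_curr = softmax_entropy(diffs[start : start + L_take]).entropy
        L = next_window_length(E_curr, E_prev, L_take, bounds)
        E_prev = E_curr
        start += L_take
    rem = n - start
    if rem >= 2:
        windows.append((start, rem))
    elif rem == 1:
        s, l = windows[-1]
        windows[-1] = (s, l + 1)
    return WindowSchedule(windows=windows, bounds=bounds, L_init=L_init)


def window_relational_grade(
    y_window: Sequence[float],
    X_windows: np.ndarray,
    rho: float = 0.5,
    pooled_extrema: tuple[float, float] | None = None,
) -> GreyWindowResult:
    """Grey relational coefficients and grades for one window.

    Parameters
    ----------
    y_window : (L,) reference values.
    X_windows : (n_comparatives, L) comparative values.
    rho : distinguished coefficient in (0, 1].
    pooled_extrema : optionally impose externally pooled (min, max)
        residual extrema (used for global pooling across windows).
    """
    y = np.asarray(y_window, dtype=float)
    X = np.atleast_2d(np.asarray(X_windows, dtype=float))
    if X.shape[0] == 0:
        raise ValidationError("need at least one comparative gene")
    if X.shape[1] != y.size:
        raise ValidationError("window length mismatch")
    resid = np.abs(y[None, :] - X)
    if pooled_extrema is None:
        lo, hi = float(resid.min()), float(resid.max())
    else:
        lo, hi = pooled_extrema
    if hi <= 0:
        xi = np.ones_like(resid)  # all-coincident degenerate window
    else:
        xi = (lo + rho * hi) / (resid + rho * hi)
    return GreyWindowResult(xi=xi, grade=xi.mean(axis=1), rho=rho)


# ---------------------------------------------------------------------------
# normalisation and the full DGA matrix
# ---------------------------------------------------------------------------


def normalize_block(block: np.ndarray, method: str) -> np.ndarray:
    """Per-gene rescale of one (m, n) block; constant genes map to 0."""
    block = np.asarray(block, dtype=float)
    if method == "none":
        return block.copy()
    if method == "zscore":
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (block - mu) / sd
    if method == "minmax":
        lo = block.min(axis=1, keepdims=True)
        rng = block.max(axis=1, keepdims=True) - lo
        rng[rng == 0] = 1.0
        return (block - lo) / rng
    raise ValidationError(f"unknown normalization {method!r}")


def _window_values(norm: np.ndarray, start: int, length: int) -> np.ndarray:
    # window (start, length) on the difference axis samples the expression
    # values at timepoints start+1 .. start+length (difference endpoints)
    return norm[:, start + 1 : start + 1 + length]


def dynamic_grey_association(
    table: ExpressionTable, params: DgaParams | None = None
) -> AssociationMatrix:
    """Full genes x genes dynamic grey association matrix.

    For every target gene an adaptive window schedule is built on its
    first-differenced (normalised) series, per-window grey relational
    grades against all other genes are averaged over windows, and with
    several replicate blocks the block scores are averaged.  Entry
    ``(k, j)`` scores comparative gene k against target j; the diagonal
    is fixed at 0.
    """
    params = params or DgaParams()
    m = table.n_genes
    acc = np.zeros((m, m))
    others = [np.array([k for k in range(m) if k != j]) for j in range(m)]
    for block in table.blocks:
        L_init, bounds = params.resolved(block.shape[1])
        norm = normalize_block(block, params.normalization)
        block_scores = np.zeros((m, m))
        for j in range(m):
            schedule = build_window_schedule(norm[j], L_init, bounds)
            ks = others[j]
            if params.pool_extrema == "global":
                pooled = _pool_global_extrema(norm, j, ks, schedule)
            grades = np.zeros((len(schedule), m - 1))
            for wi, (s, L) in enumerate(schedule):
                vals = _window_values(norm, s, L)
                res = window_relational_grade(
                    vals[j],
                    vals[ks],
                    rho=params.rho,
                    pooled_extrema=pooled if params.pool_extrema == "global" else None,
                )
                grades[wi] = res.grade
            block_scores[ks, j] = grades.mean(axis=0)
        acc += block_scores
    scores = acc / table.n_blocks
    np.fill_diagonal(scores, 0.0)
    return AssociationMatrix(scores=scores, gene_ids=list(table.gene_ids))


def _pool_global_extrema(norm, j, ks, schedule):
    lo, hi = np.inf, -np.inf
    for s, L in schedule:
        vals = _window_values(norm, s, L)
        resid = np.abs(vals[j][None, :] - vals[ks])
        lo = min(lo, float(resid.min()))
        hi = max(hi, float(resid.max()))
    return lo, hi
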