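"""Sliding-window histogram equalization against a learned target distribution.

The expression matrix is tiled into rectangular regions of interest (ROIs).
Within each ROI, values are discretized to L levels over the matrix-wide
value range, the level histogram and its CDF F are computed, and each level
k is remapped through the target family's inverse CDF:

    u(k)  = G^{-1}( min(F(k), 1 - eps) )          eps = 1/(2 * ROI size)
    T(k)  = floor( u(k) / G^{-1}(1 - eps) * (L-1) )

i.e. discrete inverse-transform sampling: F maps the ROI's levels to
(approximately) uniform [0, 1] mass, and G^{-1} carries that mass onto the
target distribution.  The lookup table T is monotone, so ranks within an
ROI are preserved; zeros whose cumulative mass is positive are lifted to a
nonzero target quantile -- this is the imputation mechanism.  New levels are
mapped back to expression units linearly over the global value range, so
the matrix maximum is preserved.

When windows tile the matrix without overlap, a final bilinear resampling
pass (diagonal-neighbor averaging with zero padding) blends adjacent ROIs
into a globally consistent matrix; with overlapping windows the per-element
average over windows provides that consistency instead.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .distribution import EmpiricalDistribution, FittedDistribution, HistogramModel
from .errors import ContractError, ParameterError
from .io import ExpressionMatrix

Roi = tuple[int, int, int, int]  # (row_start, row_end, col_start, col_end), half-open


@dataclasses.dataclass
class RoiGrid:
    """Window geometry: window/step sizes and the list of ROIs covering the matrix."""

    window_rows: int
    window_cols: int
    step_rows: int
    step_cols: int
    roi_list: list[Roi]

    @property
    def n_rois(self) -> int:
        return len(self.roi_list)

    @property
    def overlapping(self) -> bool:
        return self.step_rows < self.window_rows or self.step_cols < self.window_cols


@dataclasses.dataclass
class EqualizationTransform:
    """Per-ROI level remapping: CDF, lookup table and level-to-value map."""

    levels: int
    cdf: np.ndarray
    lut: np.ndarray
    target: FittedDistribution | EmpiricalDistribution
    value_map: np.ndarray | None = None


def _partition(n: int, k: int) -> list[tuple[int, int]]:
    """Split [0, n) into k contiguous blocks; the last absorbs the remainder."""
    if k < 1 or k > n:
        raise ParameterError(f"cannot split {n} indices into {k} blocks")
    base = n // k
    edges = [i * base for i in range(k)] + [n]
    return [(edges[i], edges[i + 1]) for i in range(k)]


def _tiles(n: int, window: int, step: int) -> list[tuple[int, int]]:
    if window >= n:
        return [(0, n)]
    if step == window:
        k = n // window
        return _partition(n, k)
    # Overlapping slide: regular starts, plus a final window flushed to the edge.
    starts = list(range(0, n - window + 1, step))
    if starts[-1] + window < n:
        starts.append(n - window)
    return [(s, s + window) for s in starts]


def make_roi_grid(
    q: int,
    m: int,
    window_frac: float = 0.5,
    step_frac: float | None = None,
    grid_override: tuple[int, int] | None = None,
) -> RoiGrid:
    """Build the ROI tiling of a q x m matrix.

    By default the window is half the matrix in each axis and the step
    equals the window, giving a non-overlapping 2 x 2 tiling (N = 4); when a
    dimension is not divisible, the last ROI in that axis extends to the
    matrix edge.  ``grid_override=(R, C)`` forces an explicit R x C tiling
    instead.  A window larger than the matrix degrades to a single ROI with
    a warning.
    """
    if q < 2 or m < 2:
        raise ParameterError(f"matrix of shape ({q}, {m}) is too small to tile")
    if grid_override is not None:
        rows, cols = grid_override
        row_blocks = _partition(q, rows)
        col_blocks = _partition(m, cols)
        wr, wc = q // rows, m // cols
        rois = [(r0, r1, c0, c1) for r0, r1 in row_blocks for c0, c1 in col_blocks]
        return RoiGrid(wr, wc, wr, wc, rois)
    if not 0 < window_frac:
        raise ParameterError(f"window_frac must be positive, got {window_frac}")
    wr = max(int(q * window_frac), 1)
    wc = max(int(m * window_frac), 1)
    if step_frac is None:
        sr, sc = wr, wc
    else:
        sr = max(int(q * step_frac), 1)
        sc = max(int(m * step_frac), 1)
        sr, sc = min(sr, wr), min(sc, wc)
    if wr >= q and wc >= m:
        warnings.warn("window covers the whole matrix; using a single ROI")
    row_blocks = _tiles(q, wr, sr)
    col_blocks = _tiles(m, wc, sc)
    rois = [(r0, r1, c0, c1) for r0, r1 in row_blocks for c0, c1 in col_blocks]
    return RoiGrid(wr, wc, sr, sc, rois)


def _levels_of(values: np.ndarray, lo: float, hi: float, L: int) -> np.ndarray:
    """Discretize values to integer levels 0..L-1 over [lo, hi]."""
    if hi <= lo:
        return np.zeros(values.shape, dtype=int)
    k = np.floor((values - lo) / (hi - lo) * L).astype(int)
    return np.clip(k, 0, L - 1)


def clip_histogram(p: np.ndarray, clip_limit: float) -> np.ndarray:
    """Contrast-limited clipping: cap bin mass at clip_limit/L and redistribute.

    ``clip_limit`` is expressed as a multiple of the uniform bin mass 1/L
    (values <= 1 make the histogram uniform).  The excess mass above the cap
    is spread evenly over all bins, as in contrast-limited adaptive
    histogram equalization.
    """
    if clip_limit <= 0:
        raise ParameterError(f"clip_limit must be positive, got {clip_limit}")
    cap = clip_limit / len(p)
    excess = np.clip(p - cap, 0.0, None).sum()
    return np.minimum(p, cap) + excess / len(p)


def roi_histogram(
    values: np.ndarray,
    levels: int,
    global_range: tuple[float, float],
    clip_limit: float | None = None,
) -> HistogramModel:
    """Level histogram of one ROI on the matrix-wide value range."""
    lo, hi = global_range
    k = _levels_of(np.asarray(values, dtype=float), lo, hi, levels)
    counts = np.bincount(k.ravel(), minlength=levels)
    total = k.size
    p = counts / total
    if clip_limit is not None:
        p = clip_histogram(p, clip_limit)
    edges = np.linspace(lo, hi, levels + 1) if hi > lo else np.array([lo])
    return HistogramModel(bin_edges=edges, counts=counts, p=p, total=total)


def roi_cdf(hist: HistogramModel, scale_by_count: bool = False) -> np.ndarray:
    """Cumulative distribution F(n) = sum_{k<=n} p(k) of an ROI histogram.

    ``scale_by_count`` additionally divides by the ROI element count -- an
    alternative normalization retained for auditability; it caps the CDF at
    1/N and is never used by the pipeline.
    """
    F = np.cumsum(hist.p)
    if scale_by_count:
        F = F / hist.total
    return F


def raw_transform(
    cdf: np.ndarray,
    target: FittedDistribution,
    n_elements: int | None = None,
) -> np.ndarray:
    """The literal floored inverse-CDF transform, kept as a closed-form reference.

    For the exponential family this is t(k) = -floor((1/lambda) ln(1 - F(k)));
    Rayleigh and half-Gaussian analogues floor their inverse CDFs directly.
    The dynamic range of these integers is tiny (a handful of levels), which
    is why the production lookup table rescales before flooring instead.
    """
    F = _clip_cdf(cdf, n_elements)
    u = target.inverse_cdf(F)
    if target.family == "exponential":
        return (-np.floor(-u)).astype(int)
    return np.floor(u).astype(int)


def _clip_cdf(cdf: np.ndarray, n_elements: int | None) -> np.ndarray:
    cdf = np.asarray(cdf, dtype=float)
    if (cdf > 1.0 + 1e-9).any():
        raise ContractError(f"CDF exceeds 1 (max {cdf.max()})")
    eps = 1.0 / (2.0 * n_elements) if n_elements else 1e-6
    return np.minimum(cdf, 1.0 - eps)


def equalization_transform(
    cdf: np.ndarray,
    target: FittedDistribution | EmpiricalDistribution,
    n_elements: int | None = None,
) -> EqualizationTransform:
    """Build the monotone lookup table mapping ROI levels to target quantiles.

    Each level's cumulative mass is taken at its midpoint, F~(k) =
    F(k) - p(k)/2 (the half-count convention for discrete inverse sampling;
    the right-edge convention would bias every transformed level upward by
    half a bin).  The result is pushed through the target's inverse CDF,
    capped at 1 - 1/(2N), and affinely rescaled onto the integer levels
    {0, ..., L-1}, flooring last so the full level resolution is kept.
    """
    cdf = np.asarray(cdf, dtype=float)
    if (cdf > 1.0 + 1e-9).any():
        raise ContractError(f"CDF exceeds 1 (max {cdf.max()})")
    L = len(cdf)
    eps = 1.0 / (2.0 * n_elements) if n_elements else 1e-6
    edge = np.minimum(cdf, 1.0)
    p = np.diff(edge, prepend=0.0)
    F = np.minimum(np.clip(edge - 0.5 * p, 0.0, None), 1.0 - eps)
    u = target.inverse_cdf(F)
    umax = float(target.inverse_cdf(np.asarray(1.0 - eps)))
    if umax <= 0:
        lut = np.zeros(L, dtype=int)
    else:
        lut = np.clip(np.floor(u / umax * (L - 1)).astype(int), 0, L - 1)
    return EqualizationTransform(levels=L, cdf=F, lut=lut, target=target)


def apply_transform(
    roi_values: np.ndarray,
    transform: EqualizationTransform,
    global_range: tuple[float, float],
) -> np.ndarray:
    """Remap every ROI value through the lookup table, back to expression units."""
    lo, hi = global_range
    L = transform.levels
    if transform.value_map is None:
        transform.value_map = np.linspace(lo, hi, L) if L > 1 else np.array([hi])
    k = _levels_of(np.asarray(roi_values, dtype=float), lo, hi, L)
    return transform.value_map[transform.lut[k]]


def equalize_all(
    S: ExpressionMatrix,
    grid: RoiGrid,
    target: FittedDistribution | EmpiricalDistribution,
    levels: int = 100,
    clip_limit: float | None = None,
) -> ExpressionMatrix:
    """Equalize every ROI of the matrix against the target distribution.

    Overlapping window outputs are averaged per element.  For integer count
    matrices whose range is smaller than ``levels``, the levels collapse to
    the distinct integer counts so that discretization is lossless.
    """
    V = S.values
    lo, hi = float(V.min()), float(V.max())
    if hi <= lo:
        return S.copy()
    L = levels
    if np.all(V == np.floor(V)) and (hi - lo) + 1 <= levels:
        L = int(hi - lo) + 1
    accum = np.zeros_like(V, dtype=float)
    count = np.zeros_like(V, dtype=float)
    for r0, r1, c0, c1 in grid.roi_list:
        sub = V[r0:r1, c0:c1]
        hist = roi_histogram(sub, L, (lo, hi), clip_limit=clip_limit)
        F = roi_cdf(hist)
        tr = equalization_transform(F, target, n_elements=sub.size)
        accum[r0:r1, c0:c1] += apply_transform(sub, tr, (lo, hi))
        count[r0:r1, c0:c1] += 1.0
    if (count == 0).any():
        raise ContractError("ROI grid does not cover the matrix")
    out = accum / count
    return ExpressionMatrix(out, list(S.cell_ids), list(S.gene_ids))


def equalize_blend(
    S: ExpressionMatrix,
    grid: RoiGrid,
    target: FittedDistribution | EmpiricalDistribution,
    levels: int = 100,
    clip_limit: float | None = None,
) -> ExpressionMatrix:
    """Equalize with bilinear blending of the per-tile mappings (CLAHE-style).

    Every element is remapped through the lookup tables of the (up to) four
    tiles whose centers surround it, and the four mapped values are combined
    with bilinear weights given by the element's position between those
    centers.  Unlike a post-hoc smoothing of the imputed matrix, this blends
    the *transforms*, so each element's value depends only on its own input
    value -- adjacent cells and genes are never mixed -- while mapping
    discontinuities at tile borders are removed.  Requires a non-overlapping
    tiling (``grid.overlapping == False``).
    """
    if grid.overlapping:
        raise ParameterError("transform blending requires a non-overlapping tiling")
    V = S.values
    lo, hi = float(V.min()), float(V.max())
    if hi <= lo:
        return S.copy()
    L = levels
    if np.all(V == np.floor(V)) and (hi - lo) + 1 <= levels:
        L = int(hi - lo) + 1
    row_edges = sorted({r0 for r0, _, _, _ in grid.roi_list} | {r1 for _, r1, _, _ in grid.roi_list})
    col_edges = sorted({c0 for _, _, c0, _ in grid.roi_list} | {c1 for _, _, _, c1 in grid.roi_list})
    R, C = len(row_edges) - 1, len(col_edges) - 1
    value_map = np.linspace(lo, hi, L) if L > 1 else np.array([hi])
    # Per-tile lut table and tile centers.
    luts = np.empty((R, C, L), dtype=int)
    for a in range(R):
        for b in range(C):
            sub = V[row_edges[a]:row_edges[a + 1], col_edges[b]:col_edges[b + 1]]
            hist = roi_histogram(sub, L, (lo, hi), clip_limit=clip_limit)
            tr = equalization_transform(roi_cdf(hist), target, n_elements=sub.size)
            luts[a, b] = tr.lut
    r_centers = np.array([(row_edges[a] + row_edges[a + 1] - 1) / 2.0 for a in range(R)])
    c_centers = np.array([(col_edges[b] + col_edges[b + 1] - 1) / 2.0 for b in range(C)])

    def _axis_weights(n: int, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = np.arange(n, dtype=float)
        i1 = np.searchsorted(centers, pos)           # first center >= pos
        i0 = np.clip(i1 - 1, 0, len(centers) - 1)
        i1 = np.clip(i1, 0, len(centers) - 1)
        span = centers[i1] - centers[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            w1 = np.where(span > 0, (pos - centers[i0]) / np.where(span > 0, span, 1.0), 0.0)
        return i0, i1, np.clip(w1, 0.0, 1.0)

    r0, r1, wr = _axis_weights(V.shape[0], r_centers)
    c0, c1, wc = _axis_weights(V.shape[1], c_centers)
    k = _levels_of(V, lo, hi, L)
    out = np.zeros_like(V, dtype=float)
    for ri, rw in ((r0, 1.0 - wr), (r1, wr)):
        for ci, cw in ((c0, 1.0 - wc), (c1, wc)):
            w = rw[:, None] * cw[None, :]
            if not w.any():
                continue
            mapped = value_map[luts[ri[:, None], ci[None, :], k]]
            out += w * mapped
    return ExpressionMatrix(out, list(S.cell_ids), list(S.gene_ids))


def bilinear_resample(S_hat: ExpressionMatrix | np.ndarray) -> ExpressionMatrix | np.ndarray:
    """Blend adjacent ROIs: each element becomes the mean of its 4 diagonal
    neighbors, with zero padding outside the matrix (boundaries included)."""
    is_matrix = isinstance(S_hat, ExpressionMatrix)
    V = S_hat.values if is_matrix else np.asarray(S_hat, dtype=float)
    P = np.pad(V, 1, mode="constant")
    out = 0.25 * (P[:-2, :-2] + P[:-2, 2:] + P[2:, 2:] + P[2:, :-2])
    if is_matrix:
        return ExpressionMatrix(out, list(S_hat.cell_ids), list(S_hat.gene_ids))
    return out
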