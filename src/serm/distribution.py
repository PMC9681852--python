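"""Learning the target expression distribution.

A random subsample of the matrix is denoised by a small autoencoder
(:mod:`serm.autoencoder`); the histogram of the reconstruction is then
fitted, on a [0, 1]-normalized value domain, with three candidate decay
shapes -- half-Gaussian, Rayleigh and exponential, each governed by one
scale/decay parameter lambda -- and the family with minimum RMSE becomes
the target of histogram equalization.

The candidate densities are

    f_g(x) = exp(-(x/lambda)^2) / (lambda sqrt(pi))      (half-Gaussian shape)
    f_r(x) = 2 x / lambda^2 * exp(-(x/lambda)^2)         (Rayleigh)
    f_e(x) = lambda * exp(-lambda x)                     (exponential)

fitted by bounded trust-region least squares of f(center) * bin_width
against the normalized histogram mass p(n).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.special import erf, erfinv

from .autoencoder import Autoencoder, AutoencoderConfig
from .errors import FitError, ParameterError
from .io import ExpressionMatrix

DEFAULT_FAMILIES = ("gaussian", "rayleigh", "exponential")

#: Per-family (start, lower, upper) bounds for lambda on the [0, 1] fit domain.
DEFAULT_BOUNDS: dict[str, tuple[float, float, float]] = {
    "gaussian": (0.2, 0.01, 1.0),
    "rayleigh": (0.2, 0.01, 1.0),
    "exponential": (5.0, 5.0, 20.0),
}


@dataclasses.dataclass
class HistogramModel:
    """A normalized histogram: L bins, probabilities summing to one."""

    bin_edges: np.ndarray
    counts: np.ndarray
    p: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        self.p = np.asarray(self.p, dtype=float)
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ParameterError(f"histogram probabilities sum to {self.p.sum()}, not 1")

    @property
    def n_bins(self) -> int:
        return len(self.p)

    @property
    def centers(self) -> np.ndarray:
        if len(self.bin_edges) == 1:
            return self.bin_edges
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def pdf(family: str, x: np.ndarray, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "gaussian":
        # Half-Gaussian on x >= 0, normalized so that it is the derivative of
        # the CDF erf(x/lam) used for equalization (integrates to 1).
        return 2.0 * np.exp(-((x / lam) ** 2)) / (lam * np.sqrt(np.pi))
    if family == "rayleigh":
        return 2.0 * x / lam ** 2 * np.exp(-((x / lam) ** 2))
    if family == "exponential":
        return lam * np.exp(-lam * x)
    raise ParameterError(f"unknown family {family!r}")


def inverse_cdf(family: str, F: np.ndarray, lam: float) -> np.ndarray:
    """Inverse CDF of each candidate family on its nonnegative support."""
    F = np.asarray(F, dtype=float)
    if family == "gaussian":
        return lam * erfinv(F)
    if family == "rayleigh":
        return lam * np.sqrt(-np.log1p(-F))
    if family == "exponential":
        return -np.log1p(-F) / lam
    raise ParameterError(f"unknown family {family!r}")


@dataclasses.dataclass
class FittedDistribution:
    """The selected parametric target: family, decay parameter and fit RMSE."""

    family: str
    lam: float
    rmse: float
    fit_domain: tuple[float, float] = (0.0, 1.0)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return pdf(self.family, x, self.lam)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            return erf(x / self.lam)
        if self.family == "rayleigh":
            return 1.0 - np.exp(-((x / self.lam) ** 2))
        return 1.0 - np.exp(-self.lam * x)

    def inverse_cdf(self, F: np.ndarray) -> np.ndarray:
        return inverse_cdf(self.family, F, self.lam)


@dataclasses.dataclass
class EmpiricalDistribution:
    """Empirical alternative to the parametric families (off by default).

    Stores the CDF of the reconstructed subsample on a [0, 1]-normalized
    domain; the inverse CDF is linear interpolation between bin edges.
    """

    bin_edges: np.ndarray
    cdf_values: np.ndarray
    family: str = "empirical"
    lam: float = float("nan")
    rmse: float = float("nan")

    @classmethod
    def from_histogram(cls, hist: HistogramModel) -> "EmpiricalDistribution":
        lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
        span = hi - lo if hi > lo else 1.0
        edges = (hist.bin_edges - lo) / span
        cdf = np.concatenate([[0.0], np.cumsum(hist.p)])
        return cls(bin_edges=edges, cdf_values=np.minimum(cdf, 1.0))

    def inverse_cdf(self, F: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(F, dtype=float), self.cdf_values, self.bin_edges)


@dataclasses.dataclass
class TrainedAutoencoder:
    """Training result: the fitted network, its denoised reconstruction and losses."""

    model: Autoencoder
    reconstruction: ExpressionMatrix
    epoch_losses: list[float]
    scale: tuple[float, float]  # (min, max) used for [0, 1] input scaling


def subsample_matrix(S: ExpressionMatrix, n_rows: int = 2000, seed: int = 0) -> ExpressionMatrix:
    """Uniform without-replacement row subsample (clamped to the matrix height)."""
    if n_rows <= 0:
        raise ParameterError(f"n_rows must be positive, got {n_rows}")
    rng = np.random.default_rng(seed)
    k = min(n_rows, S.n_cells)
    rows = np.sort(rng.choice(S.n_cells, size=k, replace=False))
    return S.subset(rows=rows)


def train_autoencoder(S_s: ExpressionMatrix, cfg: AutoencoderConfig | None = None) -> TrainedAutoencoder:
    """Train the denoising autoencoder and reconstruct every row of the subsample.

    The input is min-max scaled to [0, 1] (a sigmoid encoder with uniform
    [0, 1] weight initialization needs inputs on that scale) and the
    reconstruction is mapped back to the input value range.
    """
    cfg = cfg if cfg is not None else AutoencoderConfig()
    lo = float(S_s.values.min())
    hi = float(S_s.values.max())
    span = hi - lo if hi > lo else 1.0
    X = (S_s.values - lo) / span
    model = Autoencoder(S_s.n_genes, cfg)
    losses = model.fit(X)
    recon = model.reconstruct(X) * span + lo
    recon = np.clip(recon, 0.0, None)  # expression values are nonnegative
    out = ExpressionMatrix(recon, list(S_s.cell_ids), list(S_s.gene_ids))
    return TrainedAutoencoder(model=model, reconstruction=out, epoch_losses=losses, scale=(lo, hi))


def compute_histogram(
    M: ExpressionMatrix | np.ndarray,
    n_bins: int = 100,
    value_range: tuple[float, float] | None = None,
) -> HistogramModel:
    """Equal-width normalized histogram over [min, max] (or a supplied range).

    A constant matrix yields a single degenerate bin with p = [1].
    """
    values = M.values if isinstance(M, ExpressionMatrix) else np.asarray(M, dtype=float)
    if not np.isfinite(values).all():
        raise ParameterError("histogram input contains non-finite values")
    if n_bins <= 0:
        raise ParameterError(f"n_bins must be positive, got {n_bins}")
    flat = values.ravel()
    lo, hi = value_range if value_range is not None else (float(flat.min()), float(flat.max()))
    if hi <= lo:
        return HistogramModel(
            bin_edges=np.array([lo]), counts=np.array([flat.size]),
            p=np.array([1.0]), total=flat.size,
        )
    counts, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    total = flat.size
    return HistogramModel(bin_edges=edges, counts=counts, p=counts / total, total=total)


def _fit_family(
    family: str, x: np.ndarray, width: float, p: np.ndarray,
    start: float, lower: float, upper: float,
) -> tuple[float, float]:
    """Bounded least-squares fit of one family; returns (lambda, rmse)."""

    def residuals(lam: np.ndarray) -> np.ndarray:
        return pdf(family, x, float(lam[0])) * width - p

    if lower == upper:
        lam = lower
    else:
        result = optimize.least_squares(
            residuals, x0=[start], bounds=([lower], [upper]), method="trf"
        )
        if not result.success:
            raise FitError(f"{family}: optimizer failed ({result.message})")
        lam = float(result.x[0])
    rmse = float(np.sqrt(np.mean(residuals([lam]) ** 2)))
    return lam, rmse


def fit_distribution(
    hist: HistogramModel,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    bounds: dict[str, tuple[float, float, float]] | None = None,
) -> FittedDistribution:
    """Fit every candidate family to the histogram and keep the minimum-RMSE one.

    The histogram's value domain is normalized to [0, 1] before fitting, so
    the lambda bounds are scale-free.  The comparison target is the bin mass
    p(n), matched by pdf(center) * bin_width, with zero bins included.
    """
    if not families:
        raise ParameterError("at least one family is required")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    span = hi - lo if hi > lo else 1.0
    x = (hist.centers - lo) / span
    width = 1.0 / hist.n_bins

    best: FittedDistribution | None = None
    failures: list[str] = []
    for family in families:
        if family not in bounds:
            raise ParameterError(f"no lambda bounds registered for family {family!r}")
        start, lower, upper = bounds[family]
        try:
            lam, rmse = _fit_family(family, x, width, hist.p, start, lower, upper)
        except (FitError, FloatingPointError) as exc:
            failures.append(str(exc))
            continue
        if best is None or rmse < best.rmse:
            best = FittedDistribution(family=family, lam=lam, rmse=rmse, fit_domain=(0.0, 1.0))
    if best is None:
        raise FitError("all families failed to fit: " + "; ".join(failures))
    return best
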