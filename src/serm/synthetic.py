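"""Synthetic benchmark data: group-structured counts and efficiency-loss dropout.

The generator emulates a Splat-style "groups" simulation: baseline gene
means are Gamma distributed, each group up/down-regulates a random subset of
genes by log-normal factors, per-cell library sizes are log-normal, and
counts are Poisson around the cell-scaled group means.  Dropout is then
simulated as capture-efficiency loss: each cell gets an efficiency
tau_c ~ Gamma(shape=10, rate) whose mean is the nominal efficiency
(10/1000 = 1% etc.), and observed counts are Poisson(tau_c * lambda_gc)
around the true expression lambda_gc.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ParameterError
from .io import ExpressionMatrix, default_ids

#: Nominal capture efficiency (percent) -> Gamma rate; the shape is always 10,
#: so the expected efficiency is shape/rate.
EFFICIENCY_RATES: dict[float, int] = {
    10.0: 100,
    5.0: 200,
    2.0: 500,
    1.0: 1000,
    0.5: 2000,
    0.2: 5000,
    0.1: 10000,
}

GAMMA_SHAPE = 10.0


def _parse_efficiency(level: float | str) -> float:
    if isinstance(level, str):
        level = level.rstrip("%").strip()
        try:
            level = float(level)
        except ValueError as exc:
            raise ParameterError(f"unparseable efficiency level {level!r}") from exc
    level = float(level)
    if level not in EFFICIENCY_RATES:
        raise ParameterError(
            f"efficiency {level}% is not one of {sorted(EFFICIENCY_RATES)} percent"
        )
    return level


@dataclasses.dataclass
class GroupSimParams:
    """Parameters of the group-structured count simulation.

    Defaults reproduce the benchmark conditions: 5 groups with probability
    0.2 each, 500 cells per group and 1200 genes.
    """

    n_groups: int = 5
    group_probs: tuple[float, ...] | None = None
    n_cells_per_group: int = 500
    n_genes: int = 1200
    gene_mean_shape: float = 0.6
    gene_mean_rate: float = 0.3
    de_prob: float = 0.1
    de_factor_sd: float = 0.4
    libsize_log_mean: float = 11.0
    libsize_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_probs is None:
            self.group_probs = tuple([1.0 / self.n_groups] * self.n_groups)
        self.group_probs = tuple(float(p) for p in self.group_probs)
        if len(self.group_probs) != self.n_groups:
            raise ParameterError(
                f"{len(self.group_probs)} group probabilities for {self.n_groups} groups"
            )
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ParameterError(f"group probabilities sum to {sum(self.group_probs)}, not 1")
        for name in (
            "n_groups", "n_cells_per_group", "n_genes", "gene_mean_shape",
            "gene_mean_rate", "de_factor_sd", "libsize_log_sd",
        ):
            if getattr(self, name) <= 0 and name != "de_factor_sd":
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ParameterError(f"de_prob must be in [0, 1], got {self.de_prob}")


@dataclasses.dataclass
class DropoutModel:
    """Per-cell capture efficiencies tau_c for one nominal efficiency level."""

    efficiency_percent: float
    gamma_shape: float
    gamma_rate: float
    tau: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if (self.tau < 0).any() or not np.isfinite(self.tau).all():
            raise ParameterError("all efficiencies tau_c must be finite and nonnegative")

    @property
    def nominal_efficiency(self) -> float:
        """Expected tau = shape/rate, as a fraction (0.01 for the 1% level)."""
        return self.gamma_shape / self.gamma_rate


@dataclasses.dataclass
class LabeledDataset:
    """A reference/observed matrix pair with ground-truth group labels."""

    reference: ExpressionMatrix
    observed: ExpressionMatrix
    labels: np.ndarray
    dropout: DropoutModel | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.reference.shape != self.observed.shape:
            raise ParameterError("reference and observed matrices differ in shape")
        if len(self.labels) != self.reference.n_cells:
            raise ParameterError("labels length does not match number of cells")


def simulate_groups(params: GroupSimParams) -> LabeledDataset:
    """Simulate group-structured counts without dropout (observed == reference).

    Each cell's group is drawn from ``group_probs``; its expected expression
    is its library size distributed over genes proportionally to the group's
    mean-expression profile, and the final counts are Poisson.
    """
    rng = np.random.default_rng(params.seed)
    n_cells = params.n_groups * params.n_cells_per_group
    labels = rng.choice(params.n_groups, size=n_cells, p=params.group_probs)

    base_means = rng.gamma(params.gene_mean_shape, 1.0 / params.gene_mean_rate, params.n_genes)
    base_means = np.maximum(base_means, 1e-12)
    de_mask = rng.random((params.n_groups, params.n_genes)) < params.de_prob
    log_factors = rng.normal(0.0, params.de_factor_sd, (params.n_groups, params.n_genes))
    factors = np.where(de_mask, np.exp(log_factors), 1.0)
    group_means = base_means[None, :] * factors

    libsize = rng.lognormal(params.libsize_log_mean, params.libsize_log_sd, n_cells)
    props = group_means / group_means.sum(axis=1, keepdims=True)
    lam = libsize[:, None] * props[labels]
    counts = rng.poisson(lam).astype(float)

    matrix = ExpressionMatrix(
        counts, default_ids("cell", n_cells), default_ids("gene", params.n_genes)
    )
    return LabeledDataset(reference=matrix, observed=matrix.copy(), labels=labels, dropout=None)


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to one million total (length-free TPM for UMI-style counts)."""
    totals = matrix.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ParameterError(
            f"cell {zero[0]} ({matrix.cell_ids[zero[0]]}) has zero total expression"
        )
    values = matrix.values / totals[:, None] * 1e6
    return ExpressionMatrix(values, list(matrix.cell_ids), list(matrix.gene_ids))


def build_reference(
    raw: ExpressionMatrix,
    gene_frac: float = 0.2,
    cell_frac: float = 0.6,
    allow_out_of_range: bool = False,
) -> ExpressionMatrix:
    """Filter a raw dataset down to a dropout-free reference.

    The matrix is TPM-normalized, then the top ``gene_frac`` of genes by the
    proportion of cells with nonzero expression and the top ``cell_frac`` of
    cells by (pre-TPM) library size are retained.  The documented protocol
    uses gene_frac in [0.1, 0.2] and cell_frac in [0.5, 0.6]; other values
    require ``allow_out_of_range=True``.
    """
    if not allow_out_of_range:
        if not 0.1 <= gene_frac <= 0.2:
            raise ParameterError(f"gene_frac {gene_frac} outside [0.1, 0.2]")
        if not 0.5 <= cell_frac <= 0.6:
            raise ParameterError(f"cell_frac {cell_frac} outside [0.5, 0.6]")
    if raw.n_genes < 10 or raw.n_cells < 4:
        raise ParameterError(
            f"reference filtering needs >= 10 genes and >= 4 cells, got {raw.shape}"
        )
    library = raw.values.sum(axis=1)
    nonzero_prop = (raw.values > 0).mean(axis=0)
    tpm = tpm_normalize(raw)

    n_genes = math.ceil(gene_frac * raw.n_genes)
    n_cells = math.ceil(cell_frac * raw.n_cells)
    # Descending rank; ties broken by lower index for determinism.
    gene_order = np.argsort(-nonzero_prop, kind="stable")[:n_genes]
    cell_order = np.argsort(-library, kind="stable")[:n_cells]
    return tpm.subset(rows=np.sort(cell_order), cols=np.sort(gene_order))


def sample_efficiency(level: float | str, n_cells: int, seed: int = 0) -> DropoutModel:
    """Draw per-cell efficiencies tau_c ~ Gamma(10, rate) for a nominal level.

    ``level`` is the efficiency in percent (10, 5, 2, 1, 0.5, 0.2 or 0.1,
    optionally as a string with a trailing ``%``).
    """
    if n_cells <= 0:
        raise ParameterError(f"n_cells must be positive, got {n_cells}")
    percent = _parse_efficiency(level)
    rate = EFFICIENCY_RATES[percent]
    rng = np.random.default_rng(seed)
    tau = rng.gamma(GAMMA_SHAPE, 1.0 / rate, n_cells)
    return DropoutModel(
        efficiency_percent=percent, gamma_shape=GAMMA_SHAPE, gamma_rate=rate,
        tau=tau, seed=seed,
    )


def apply_dropout(reference: ExpressionMatrix, model: DropoutModel) -> ExpressionMatrix:
    """Resample the reference through the efficiency model: Poisson(tau_c * lambda_gc)."""
    if len(model.tau) != reference.n_cells:
        raise ParameterError(
            f"{len(model.tau)} efficiencies for {reference.n_cells} cells"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), 1]))
    observed = rng.poisson(model.tau[:, None] * reference.values).astype(float)
    return ExpressionMatrix(observed, list(reference.cell_ids), list(reference.gene_ids))


def simulate_benchmark(
    params: GroupSimParams | None = None,
    efficiency: float | str = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Full benchmark protocol: simulate groups, then degrade at one efficiency."""
    params = params if params is not None else GroupSimParams(seed=seed)
    clean = simulate_groups(params)
    model = sample_efficiency(efficiency, clean.reference.n_cells, seed=seed)
    observed = apply_dropout(clean.reference, model)
    return LabeledDataset(
        reference=clean.reference, observed=observed, labels=clean.labels, dropout=model
    )
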