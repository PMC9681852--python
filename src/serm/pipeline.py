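"""End-to-end orchestration: learn the distribution, equalize, blend, report.

The full imputation of a matrix S proceeds as:

1. subsample rows of S,
2. denoise the subsample with the autoencoder,
3. histogram the reconstruction,
4. fit the parametric target distribution (min-RMSE family),
5. tile S into ROIs,
6. equalize every ROI against the target, and
7. bilinearly resample to blend non-overlapping ROIs.

An optional row/column randomization can be applied before imputation and
inverted afterwards; with sufficiently large ROIs the value distribution in
each window is insensitive to row/column order, so this is off by default.
Multi-batch data is handled by learning the distribution on one reference
batch, equalizing every batch against it, and integrating via per-batch,
per-gene z-scoring.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import numpy as np

from .autoencoder import AutoencoderConfig
from .distribution import (
    DEFAULT_BOUNDS,
    DEFAULT_FAMILIES,
    EmpiricalDistribution,
    FittedDistribution,
    compute_histogram,
    fit_distribution,
    subsample_matrix,
    train_autoencoder,
)
from .equalize import (
    RoiGrid,
    bilinear_resample,
    equalize_all,
    equalize_blend,
    make_roi_grid,
)
from .errors import AlignmentError, ParameterError
from .io import ExpressionMatrix


@dataclasses.dataclass
class SermConfig:
    """Every tunable of the pipeline, serializable to a key=value text file."""

    # autoencoder
    latent_dim: int = 2
    encoder_activation: str = "sigmoid"
    l2_weight: float = 0.05
    sparsity_weight: float = 0.9
    sparsity_target: float = 0.05
    learning_rate: float = 1e-5
    max_epochs: int = 20
    batch_size: int = 64
    init: str = "uniform"
    # distribution learning
    subsample_rows: int = 2000
    bins: int = 100
    families: tuple[str, ...] = DEFAULT_FAMILIES
    fit_bounds: dict | None = None
    use_empirical: bool = False
    # equalization
    window_frac: float = 0.5
    step_frac: float | None = None
    grid_override: tuple[int, int] | None = None
    clip_limit: float | None = None
    #: cross-window consistency for non-overlapping tilings: "blend"
    #: interpolates the per-tile mappings bilinearly (each element keeps its
    #: own identity), "resample" applies the diagonal-neighbor averaging
    #: filter to the imputed matrix, "none" leaves hard tile borders.
    consistency: str = "blend"
    # orchestration
    randomize: bool = False
    seed: int = 0

    def autoencoder_config(self, seed: int) -> AutoencoderConfig:
        return AutoencoderConfig(
            latent_dim=self.latent_dim,
            encoder_activation=self.encoder_activation,
            l2_weight=self.l2_weight,
            sparsity_weight=self.sparsity_weight,
            sparsity_target=self.sparsity_target,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            init=self.init,
            seed=seed,
        )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if value is None:
                rendered = "none"
            elif field.name == "families":
                rendered = ",".join(value)
            elif field.name == "grid_override":
                rendered = f"{value[0]}x{value[1]}"
            elif field.name == "fit_bounds":
                rendered = ";".join(
                    f"{fam}:{s},{lo},{hi}" for fam, (s, lo, hi) in value.items()
                )
            else:
                rendered = str(value)
            lines.append(f"{field.name}={rendered}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SermConfig":
        kwargs: dict = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ParameterError(f"unknown config key {key!r}")
            if raw == "none":
                kwargs[key] = None
            elif key == "families":
                kwargs[key] = tuple(t.strip() for t in raw.split(",") if t.strip())
            elif key == "grid_override":
                r, _, c = raw.partition("x")
                kwargs[key] = (int(r), int(c))
            elif key == "fit_bounds":
                bounds = {}
                for part in raw.split(";"):
                    fam, _, nums = part.partition(":")
                    s, lo, hi = (float(v) for v in nums.split(","))
                    bounds[fam.strip()] = (s, lo, hi)
                kwargs[key] = bounds
            elif key in ("randomize", "use_empirical"):
                kwargs[key] = raw.lower() in ("true", "1", "yes")
            elif key in ("latent_dim", "max_epochs", "batch_size", "subsample_rows", "bins", "seed"):
                kwargs[key] = int(raw)
            elif key in ("encoder_activation", "init", "consistency"):
                kwargs[key] = raw
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclasses.dataclass
class PermutationRecord:
    """Row/column permutations applied before imputation, for exact inversion."""

    row_perm: np.ndarray
    col_perm: np.ndarray
    seed: int


@dataclasses.dataclass
class ImputationReport:
    """Provenance of one imputation run."""

    family: str
    lam: float
    rmse: float
    grid: tuple[int, int, int, int]  # window_rows, window_cols, step_rows, step_cols
    n_rois: int
    seeds: dict[str, int]
    epoch_losses: list[float]
    timings: dict[str, float]
    randomized: bool


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    names = ("subsample", "autoencoder", "permutation")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def permute_randomize(S: ExpressionMatrix, seed: int = 0) -> tuple[ExpressionMatrix, PermutationRecord]:
    """Randomly permute rows and columns; returns the permuted matrix and record."""
    rng = np.random.default_rng(seed)
    row_perm = rng.permutation(S.n_cells)
    col_perm = rng.permutation(S.n_genes)
    permuted = ExpressionMatrix(
        S.values[np.ix_(row_perm, col_perm)].copy(),
        [S.cell_ids[i] for i in row_perm],
        [S.gene_ids[j] for j in col_perm],
    )
    return permuted, PermutationRecord(row_perm=row_perm, col_perm=col_perm, seed=seed)


def invert_permutation(S: ExpressionMatrix, record: PermutationRecord) -> ExpressionMatrix:
    """Undo :func:`permute_randomize` exactly."""
    if len(record.row_perm) != S.n_cells or len(record.col_perm) != S.n_genes:
        raise ParameterError(
            f"permutation record of shape ({len(record.row_perm)}, {len(record.col_perm)}) "
            f"does not match matrix {S.shape}"
        )
    inv_rows = np.argsort(record.row_perm)
    inv_cols = np.argsort(record.col_perm)
    return ExpressionMatrix(
        S.values[np.ix_(inv_rows, inv_cols)].copy(),
        [S.cell_ids[i] for i in inv_rows],
        [S.gene_ids[j] for j in inv_cols],
    )


def learn_distribution(
    S: ExpressionMatrix, cfg: SermConfig, seeds: dict[str, int] | None = None
) -> tuple[FittedDistribution | EmpiricalDistribution, dict]:
    """Stages 1-4: subsample, denoise, histogram, fit.  Returns (target, diagnostics)."""
    seeds = seeds if seeds is not None else _stage_seeds(cfg.seed)
    t0 = time.perf_counter()
    S_s = subsample_matrix(S, n_rows=cfg.subsample_rows, seed=seeds["subsample"])
    trained = train_autoencoder(S_s, cfg.autoencoder_config(seeds["autoencoder"]))
    t_train = time.perf_counter()
    hist = compute_histogram(trained.reconstruction, n_bins=cfg.bins)
    if cfg.use_empirical:
        target: FittedDistribution | EmpiricalDistribution = EmpiricalDistribution.from_histogram(hist)
    else:
        target = fit_distribution(hist, families=cfg.families, bounds=cfg.fit_bounds)
    t_fit = time.perf_counter()
    diagnostics = {
        "epoch_losses": trained.epoch_losses,
        "timings": {"train": t_train - t0, "fit": t_fit - t_train},
    }
    return target, diagnostics


def apply_equalization(
    S: ExpressionMatrix,
    target: FittedDistribution | EmpiricalDistribution,
    cfg: SermConfig,
) -> tuple[ExpressionMatrix, RoiGrid]:
    """Stages 5-7: tile, equalize, and (for non-overlapping tilings) resample."""
    grid = make_roi_grid(
        S.n_cells, S.n_genes,
        window_frac=cfg.window_frac, step_frac=cfg.step_frac,
        grid_override=cfg.grid_override,
    )
    if cfg.consistency not in ("blend", "resample", "none"):
        raise ParameterError(f"unknown consistency mode {cfg.consistency!r}")
    if not grid.overlapping and cfg.consistency == "blend":
        S_hat = equalize_blend(S, grid, target, levels=cfg.bins, clip_limit=cfg.clip_limit)
    else:
        S_hat = equalize_all(S, grid, target, levels=cfg.bins, clip_limit=cfg.clip_limit)
        if not grid.overlapping and cfg.consistency == "resample":
            S_hat = bilinear_resample(S_hat)
    return S_hat, grid


def impute(S: ExpressionMatrix, cfg: SermConfig | None = None) -> tuple[ExpressionMatrix, ImputationReport]:
    """Run the full pipeline on one matrix; deterministic under ``cfg.seed``."""
    cfg = cfg if cfg is not None else SermConfig()
    seeds = _stage_seeds(cfg.seed)
    record = None
    work = S
    if cfg.randomize:
        work, record = permute_randomize(S, seeds["permutation"])
    target, diagnostics = learn_distribution(work, cfg, seeds)
    t0 = time.perf_counter()
    result, grid = apply_equalization(work, target, cfg)
    diagnostics["timings"]["equalize"] = time.perf_counter() - t0
    if record is not None:
        result = invert_permutation(result, record)
    report = ImputationReport(
        family=target.family,
        lam=float(getattr(target, "lam", float("nan"))),
        rmse=float(getattr(target, "rmse", float("nan"))),
        grid=(grid.window_rows, grid.window_cols, grid.step_rows, grid.step_cols),
        n_rois=grid.n_rois,
        seeds=seeds,
        epoch_losses=diagnostics["epoch_losses"],
        timings=diagnostics["timings"],
        randomized=cfg.randomize,
    )
    return result, report


def _zscore_per_gene(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)
    out = np.zeros_like(values)
    ok = sd[0] > 0
    out[:, ok] = (values[:, ok] - mean[:, ok]) / sd[:, ok]
    return out


def batch_impute(
    batches: list[ExpressionMatrix],
    reference_index: int = 0,
    cfg: SermConfig | None = None,
) -> ExpressionMatrix:
    """Impute multiple batches with one distribution learned on a reference batch.

    Every batch is equalized independently against the reference batch's
    fitted distribution (randomization, when enabled, stays within each
    batch and is undone afterwards), z-scored per gene within its batch
    (zero-variance genes map to 0), and the batches are row-concatenated.
    """
    cfg = cfg if cfg is not None else SermConfig()
    if not batches:
        raise ParameterError("no batches given")
    if not 0 <= reference_index < len(batches):
        raise ParameterError(f"reference_index {reference_index} out of range")
    genes = batches[0].gene_ids
    for i, batch in enumerate(batches[1:], start=1):
        if batch.gene_ids != genes:
            offenders = [
                (a, b) for a, b in zip(genes, batch.gene_ids) if a != b
            ][:5]
            raise AlignmentError(
                f"batch {i} gene axis differs from batch 0 (first mismatches: {offenders})"
            )
    seeds = _stage_seeds(cfg.seed)
    target, _ = learn_distribution(batches[reference_index], cfg, seeds)
    pieces = []
    cell_ids = []
    for i, batch in enumerate(batches):
        work, record = batch, None
        if cfg.randomize:
            work, record = permute_randomize(batch, seeds["permutation"] + i)
        imputed, _ = apply_equalization(work, target, cfg)
        if record is not None:
            imputed = invert_permutation(imputed, record)
        pieces.append(_zscore_per_gene(imputed.values))
        cell_ids.extend(f"b{i}:{c}" for c in batch.cell_ids)
    stacked = np.vstack(pieces)
    return ExpressionMatrix(stacked, cell_ids, list(genes), allow_negative=True)
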