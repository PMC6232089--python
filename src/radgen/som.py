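"""Self-organizing-map metagenes and pairwise sample correlation.

A genome-wide feature-by-sample matrix (here: per-probe log2 ratios across
biopsy cores) is compressed onto a 20 x 20 SOM grid — 400 metagenes, each
the centroid of the feature profiles mapped to that unit — and samples are
then compared by Pearson correlation over their 400 metagene values. On
cohorts with patient-specific trunk CNAs this reproduces patient-wise
clustering and the separation of CNA-positive from CNA-negative cores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SomConfig:
    """Batch-SOM training configuration.

    20 x 20 grid (400 metagenes), Gaussian neighbourhood shrinking linearly
    from ``radius_start`` to ``radius_end`` over ``epochs`` batch updates,
    PCA-plane initialization (deterministic; the seed only matters for the
    random fallback used when the feature cloud is degenerate).
    """

    grid_shape: tuple[int, int] = (20, 20)
    epochs: int = 20
    radius_start: float = 10.0
    radius_end: float = 1.0
    seed: int = 0
    standardize: bool = True

    @property
    def n_units(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]


@dataclass
class SomModel:
    weights: np.ndarray        # (n_units, n_samples)
    grid_shape: tuple[int, int]
    bmu: np.ndarray            # (n_features,) best-matching unit per feature
    config: SomConfig
    sample_ids: list[str]

    def metagene_matrix(self) -> np.ndarray:
        """400 x n_samples metagenes: mean of assigned feature profiles per
        unit; units with no assigned feature keep their trained weight."""
        return self._metagenes

    _metagenes: np.ndarray = None  # set by train_som


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def train_som(matrix: pd.DataFrame | np.ndarray,
              config: SomConfig | None = None) -> SomModel:
    """Train a batch SOM on the rows (features) of a feature-by-sample matrix.

    Rows are z-scored first (configurable). Deterministic under a fixed
    config: PCA-plane initialization and batch updates involve no sampling.
    """
    cfg = config or SomConfig()
    if isinstance(matrix, pd.DataFrame):
        sample_ids = [str(c) for c in matrix.columns]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        sample_ids = [f"s{i}" for i in range(x.shape[1])]
    if x.shape[1] < 2:
        raise ValueError("train_som requires >= 2 samples")
    if cfg.standardize:
        x = _standardize_rows(x)

    gx, gy = cfg.grid_shape
    coords = np.stack(np.meshgrid(np.arange(gx), np.arange(gy),
                                  indexing="ij"), axis=-1).reshape(-1, 2).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    weights = _pca_plane_init(x, coords, gx, gy, cfg.seed)

    for epoch in range(cfg.epochs):
        frac = epoch / max(cfg.epochs - 1, 1)
        radius = cfg.radius_start + frac * (cfg.radius_end - cfg.radius_start)
        bmu = _best_matching_units(x, weights)
        h = np.exp(-grid_d2[:, bmu] / (2.0 * radius * radius))  # (units, feats)
        denom = h.sum(axis=1, keepdims=True)
        upd = h @ x
        nz = denom[:, 0] > 1e-12
        weights[nz] = upd[nz] / denom[nz]

    bmu = _best_matching_units(x, weights)
    metagenes = weights.copy()
    for u in range(cfg.n_units):
        assigned = bmu == u
        if np.any(assigned):
            metagenes[u] = x[assigned].mean(axis=0)
    model = SomModel(weights=weights, grid_shape=cfg.grid_shape, bmu=bmu,
                     config=cfg, sample_ids=sample_ids)
    model._metagenes = metagenes
    return model


def _best_matching_units(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # argmin over units of ||x_f - w_u||^2, chunked to bound memory
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    w_sq = (weights ** 2).sum(axis=1)
    step = 4096
    for a in range(0, n, step):
        xb = x[a:a + step]
        d2 = w_sq[None, :] - 2.0 * xb @ weights.T
        out[a:a + step] = np.argmin(d2, axis=1)
    return out


def _pca_plane_init(x: np.ndarray, coords: np.ndarray, gx: int, gy: int,
                    seed: int) -> np.ndarray:
    center = x.mean(axis=0)
    xc = x - center
    try:
        _, sval, vt = np.linalg.svd(xc, full_matrices=False)
    except np.linalg.LinAlgError:
        sval = np.zeros(2)
        vt = np.zeros((2, x.shape[1]))
    if len(sval) < 2 or sval[1] <= 1e-12:
        rng = np.random.default_rng(seed)
        return center + 0.01 * rng.standard_normal((gx * gy, x.shape[1]))
    n = max(len(x) - 1, 1)
    span = 2.0 * sval[:2] / np.sqrt(n)
    u = (coords[:, 0] / max(gx - 1, 1) - 0.5) * span[0]
    v = (coords[:, 1] / max(gy - 1, 1) - 0.5) * span[1]
    return center + u[:, None] * vt[0] + v[:, None] * vt[1]


def pairwise_sample_correlation(metagenes: np.ndarray | pd.DataFrame,
                                sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation between samples over their metagene values.

    Zero-variance sample columns yield NaN rows/columns (flagged missing,
    never fabricated); the diagonal is exactly 1 for defined samples.
    """
    if isinstance(metagenes, pd.DataFrame):
        sample_ids = sample_ids or [str(c) for c in metagenes.columns]
        m = metagenes.to_numpy(dtype=float)
    else:
        m = np.asarray(metagenes, dtype=float)
        sample_ids = sample_ids or [f"s{i}" for i in range(m.shape[1])]
    if m.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sd = m.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(m, rowvar=False)
    r = np.asarray(r, dtype=float)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)  # NaN passes through unchanged
    return pd.DataFrame(r, index=sample_ids, columns=sample_ids)


def som_sample_correlation(matrix: pd.DataFrame,
                           config: SomConfig | None = None) -> pd.DataFrame:
    """Convenience: train the SOM and return the sample correlation matrix."""
    model = train_som(matrix, config)
    return pairwise_sample_correlation(model.metagene_matrix(),
                                       model.sample_ids)


def plot_correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Render the sample correlation matrix to PNG/SVG (by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r",
                   interpolation="nearest")
    ax.set_xticks(range(len(corr)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)))
    ax.set_yticklabels(corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r (400 metagenes)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
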