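"""Training, leave-one-section-out evaluation, and benchmark statistics.

The protocol mirrors the study design: mean-squared-error regression with
Adam (batch size 32, 81 epochs by default), leave-one-section-out
cross-validation, per-gene Pearson correlation across spots as the accuracy
metric, Wilcoxon signed-rank tests for model comparisons, a one-sided
positive-correlation test with Benjamini–Hochberg adjustment to rank
well-predicted genes, and a per-section dispersion score summarising how far
the best-predicted genes exceed the section median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datasets import SpotDataset
from .model import SciStModel, normalize_patches, transform_ie
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "PCCResult", "loso_folds", "train", "per_sample_pcc",
    "compare_models_wilcoxon", "gene_positive_correlation_test",
    "dispersion_score", "geneset_spatial_map", "pseudo_bulk", "inject_noise",
]


@dataclass
class TrainConfig:
    """MSE/Adam training protocol (identical across compared variants)."""

    batch_size: int = 32
    epochs: int = 81
    learning_rate: float = 1e-4
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")


def loso_folds(sections: list) -> list[tuple[list, object]]:
    """Leave-one-section-out folds: each section held out exactly once."""
    if len(sections) < 2:
        raise ValueError("leave-one-section-out needs at least 2 sections")
    return [([s for j, s in enumerate(sections) if j != i], sections[i])
            for i in range(len(sections))]


def train(model: SciStModel, dataset: SpotDataset, cfg: TrainConfig,
          refs=None, images: np.ndarray | None = None
          ) -> tuple[SciStModel, list[float]]:
    """Minimise MSE over (prediction, normalised label) pairs.

    Returns the trained model and the per-epoch mean training loss.
    Deterministic given ``cfg.seed`` on one machine.  IE-level ablations
    (random prompt, cell-ratio noise) are applied once, up front, so each
    spot sees the same prompt every epoch.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    dt = model.dtype
    if images is None:
        images = normalize_patches(dataset.patches)
    images = images.astype(dt, copy=False)
    ie = transform_ie(dataset.ie, model.cfg, dataset.spot_ids,
                      counts=dataset.counts, refs=refs).astype(dt)
    labels = np.asarray(dataset.labels, dtype=dt)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    curve: list[float] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model.forward(images[idx], ie[idx])
            diff = pred - Tensor(labels[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {start // cfg.batch_size} "
                    f"(lr={cfg.learning_rate}, seed={cfg.seed})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
        logger.debug("epoch %d: train MSE %.5f", epoch, curve[-1])
    model.eval()
    return model, curve


@dataclass
class PCCResult:
    """Per-gene Pearson correlations for one (section, model) pair."""

    pcc: np.ndarray  # [N_G], NaN where undefined (zero variance)
    mean: float
    median: float
    n_undefined: int = 0

    @property
    def defined(self) -> np.ndarray:
        return self.pcc[np.isfinite(self.pcc)]


def per_sample_pcc(pred: np.ndarray, truth: np.ndarray) -> PCCResult:
    """Pearson correlation per gene across spots.

    Genes with zero variance in either argument are flagged undefined (NaN)
    and excluded from the mean/median, with the count reported.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 spots for a correlation")
    pc = pred - pred.mean(axis=0)
    tc = truth - truth.mean(axis=0)
    sp = np.sqrt((pc * pc).sum(axis=0))
    st = np.sqrt((tc * tc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * tc).sum(axis=0) / (sp * st)
    r = np.where((sp == 0) | (st == 0), np.nan, r)
    defined = r[np.isfinite(r)]
    if defined.size == 0:
        return PCCResult(r, np.nan, np.nan, int(np.isnan(r).sum()))
    return PCCResult(r, float(defined.mean()), float(np.median(defined)),
                     int(np.isnan(r).sum()))


def compare_models_wilcoxon(metric_a: np.ndarray, metric_b: np.ndarray,
                            alternative: str = "two-sided"
                            ) -> tuple[float, bool]:
    """Wilcoxon signed-rank test on paired per-section metrics.

    Zeros are dropped (signed-rank convention); the exact null is used for
    small samples without ties, the normal approximation otherwise.  Returns
    ``(p_value, defined)``; all-zero differences give ``(1.0, False)``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metrics must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired sections")
    d = a - b
    if np.all(d == 0):
        return 1.0, False
    d = d[d != 0]  # signed-rank convention: zeros dropped
    if d.size <= 12:
        return _exact_signed_rank_p(d, alternative), True
    res = scipy.stats.wilcoxon(d, zero_method="wilcox",
                               alternative=alternative, method="approx")
    return float(res.pvalue), True


def _exact_signed_rank_p(d: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign patterns.

    Ranks of |d| use midranks for ties (so the null remains exact under
    ties, unlike the standard no-tie tables).  Two-sided p is the doubled
    smaller tail, capped at 1.
    """
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = 0.0
    w_all = np.zeros(2 ** n)
    for pattern in range(2 ** n):
        mask = (pattern >> np.arange(n)) & 1
        w_all[pattern] = ranks[mask == 1].sum()
    m = 2.0 ** n
    p_le = float((w_all <= w_obs + 1e-9).sum() / m)
    p_ge = float((w_all >= w_obs - 1e-9).sum() / m)
    if alternative == "greater":
        return min(p_ge, 1.0)
    if alternative == "less":
        return min(p_le, 1.0)
    return min(2.0 * min(p_le, p_ge), 1.0)


def gene_positive_correlation_test(pcc: np.ndarray, n_spots: int
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided test of rho > 0 per gene, Benjamini–Hochberg adjusted.

    Uses t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom; r = 1
    maps to the numerical floor (p -> 0).  Undefined (NaN) correlations get
    NaN p-values and are excluded from the adjustment.  Returns
    ``(raw_p, adjusted_p)``.
    """
    if n_spots < 4:
        raise ValueError("need at least 4 spots")
    r = np.asarray(pcc, dtype=float)
    raw = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    rr = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n_spots - 2) / (1.0 - rr * rr))
    t = np.where(rr >= 1.0, np.inf, np.where(rr <= -1.0, -np.inf, t))
    raw[ok] = scipy.stats.t.sf(t, df=n_spots - 2)
    adj = np.full(r.shape, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    return raw, adj


def dispersion_score(pcc: np.ndarray) -> float:
    """Mean excess over the section median among the top-decile genes.

    Defined as mean(PCC_g - median(PCC)) over the ceil(n/10) genes with the
    highest PCC; non-negative by construction.  Needs >= 10 defined
    correlations, else NaN.
    """
    r = np.asarray(pcc, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 10:
        return float("nan")
    k = int(np.ceil(r.size / 10))
    top = np.sort(r)[-k:]
    return float(np.mean(top - np.median(r)))


def geneset_spatial_map(pred: np.ndarray, genes: list[str],
                        gene_set: list[str]) -> np.ndarray:
    """Per-spot mean predicted expression over a gene set."""
    idx = [i for i, g in enumerate(genes) if g in set(gene_set)]
    if not idx:
        raise ValueError("gene set does not intersect the panel")
    return np.asarray(pred, dtype=float)[:, idx].mean(axis=1)


def pseudo_bulk(pred: np.ndarray) -> np.ndarray:
    """Slide-level expression: mean over all spots/patches."""
    pred = np.asarray(pred, dtype=float)
    if pred.shape[0] < 1:
        raise ValueError("need at least one spot")
    return pred.mean(axis=0)


def _shift_patch(patch: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Displace patch content by (dx, dy) with reflect fill (crop-window
    displacement for datasets that carry per-spot patches, not whole slides)."""
    H, W = patch.shape[:2]
    pad = max(abs(dx), abs(dy))
    padded = np.pad(patch, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    return padded[pad + dy:pad + dy + H, pad + dx:pad + dx + W]


def inject_noise(dataset: SpotDataset, kind: str, level: float,
                 seed: int = 0, magnitude: float = 0.1) -> SpotDataset:
    """Evaluation-time robustness injections; labels are never touched.

    ``spot`` noise displaces the patch window of round(level * n) seeded
    spots by a nonzero random offset of up to one spot radius (half the
    patch size).  ``stain`` noise applies a seeded hue/saturation/value
    perturbation of the given magnitude to round(level * n) patches.
    Level 0 is a bit-exact no-op.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"noise level {level} outside [0, 1]")
    if kind not in ("spot", "stain"):
        raise ValueError(f"unknown noise kind {kind!r}")
    out = dataset.copy()
    n = len(dataset)
    k = int(round(level * n))
    if k == 0:
        return out
    rng = np.random.default_rng((seed, 0xA015E))
    chosen = rng.choice(n, size=k, replace=False)
    radius = dataset.patches.shape[1] // 2
    for i in chosen:
        if kind == "spot":
            dx = dy = 0
            while dx == 0 and dy == 0:
                dx = int(rng.integers(-radius, radius + 1))
                dy = int(rng.integers(-radius, radius + 1))
            out.patches[i] = _shift_patch(dataset.patches[i], dx, dy)
            if out.centers is not None:
                out.centers[i] = out.centers[i] + np.array([dx, dy])
        else:
            from skimage.color import rgb2hsv, hsv2rgb
            hsv = rgb2hsv(dataset.patches[i].astype(float) / 255.0)
            hsv[..., 0] = np.mod(hsv[..., 0]
                                 + rng.uniform(-magnitude, magnitude), 1.0)
            hsv[..., 1] = np.clip(hsv[..., 1]
                                  * (1 + rng.uniform(-magnitude, magnitude)),
                                  0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2]
                                  * (1 + rng.uniform(-magnitude, magnitude)),
                                  0, 1)
            out.patches[i] = np.clip(hsv2rgb(hsv) * 255.0, 0, 255) \
                .astype(np.uint8)
    return out
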