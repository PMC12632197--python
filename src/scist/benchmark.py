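"""Desk-scale benchmark routines on the synthetic study.

These reproduce, at CPU scale, the qualitative comparisons of the full
study: leave-one-section-out training of the default model against the
random-prompt and concatenation ablations, a noiseless sanity study in
which the labels equal the IE prior exactly, and the analytic attenuation
check of the generator (with morphology off, the squared correlation of the
IE prior with the labels is var / (var + sigma^2) per gene).

Problem sizes follow the generator defaults (3 sections x 200 spots, 60
genes) with the small-CNN model on 64x64 patches and a 30-epoch training
run — the package's desk-scale protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import make_variant, small_config
from .simulate import SimConfig, generate_study, SyntheticStudy
from .train_eval import TrainConfig, loso_folds, per_sample_pcc, train

logger = logging.getLogger(__name__)

__all__ = ["desk_sim_config", "desk_train_config", "held_out_mean_pcc",
           "LearnabilityResult", "run_learnability_benchmark",
           "noiseless_heldout_pcc", "attenuation_check"]


def desk_sim_config(seed: int, **overrides) -> SimConfig:
    """The default desk-scale study, rendered at the small model's 64 px."""
    kw = dict(patch_size=64, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def desk_train_config(seed: int, epochs: int = 30) -> TrainConfig:
    return TrainConfig(batch_size=32, epochs=epochs, learning_rate=3e-3,
                       seed=seed)


def held_out_mean_pcc(study: SyntheticStudy, variant: str, model_seed: int,
                      train_cfg: TrainConfig,
                      norm_images: np.ndarray | None = None) -> float:
    """LOSO train/evaluate one variant; mean over folds of per-section mean
    PCC between predictions and labels on the held-out section.

    Desk-scale runs use float32 arithmetic; ``norm_images`` lets callers
    normalise the patch stack once and reuse it across folds and variants.
    """
    from .model import transform_ie, normalize_patches
    from .nn import Tensor

    ds = study.dataset
    if norm_images is None:
        norm_images = normalize_patches(ds.patches).astype(np.float32)
    fold_means = []
    sections = np.asarray(ds.section_ids)
    for _, held in loso_folds(ds.sections):
        mask = sections == held
        tr = ds.subset(np.flatnonzero(~mask))
        te = ds.subset(np.flatnonzero(mask))
        model = make_variant(small_config(
            len(ds.genes), variant=variant, seed=model_seed,
            image_size=ds.patches.shape[1]))
        model.cast(np.float32)
        model, _ = train(model, tr, train_cfg, refs=study.refs,
                         images=norm_images[~mask])
        ie = transform_ie(te.ie, model.cfg, te.spot_ids, counts=te.counts,
                          refs=study.refs).astype(np.float32)
        model.eval()
        pred = model.forward(Tensor(norm_images[mask]), ie).data
        res = per_sample_pcc(pred, te.labels)
        fold_means.append(res.mean)
        logger.info("variant=%s fold=%s mean PCC %.3f", variant, held,
                    res.mean)
    return float(np.mean(fold_means))


@dataclass
class LearnabilityResult:
    per_replicate: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, variant: str) -> float:
        return float(np.mean(self.per_replicate[variant]))

    def wins(self, better: str, worse: str) -> int:
        a, b = self.per_replicate[better], self.per_replicate[worse]
        return int(sum(x > y for x, y in zip(a, b)))


def run_learnability_benchmark(seed: int, n_replicates: int = 5,
                               variants: tuple[str, ...] = ("scist",
                                                            "random_ie",
                                                            "concat"),
                               ) -> LearnabilityResult:
    """Train the listed variants identically on seeded study replicates."""
    from .model import normalize_patches

    result = LearnabilityResult({v: [] for v in variants})
    for r in range(n_replicates):
        study = generate_study(desk_sim_config(seed=(seed * 1000 + r) % (2**31)))
        norm = normalize_patches(study.dataset.patches).astype(np.float32)
        for v in variants:
            pcc = held_out_mean_pcc(study, v, model_seed=seed + r,
                                    train_cfg=desk_train_config(seed + r),
                                    norm_images=norm)
            result.per_replicate[v].append(pcc)
    return result


def noiseless_heldout_pcc(seed: int, epochs: int = 60) -> float:
    """With alpha = 0 and sigma = 0 the labels equal the IE prior exactly;
    a trained default model should track them almost perfectly held out.

    This is a capacity/learnability check, so it trains to near convergence
    (60 epochs) rather than the comparison protocol's 30.
    """
    study = generate_study(desk_sim_config(
        seed=seed, morph_signal_strength=0.0, noise_sd=0.0))
    return held_out_mean_pcc(study, "scist", model_seed=seed,
                             train_cfg=desk_train_config(seed, epochs=epochs))


def attenuation_check(seed: int, n_spots: int = 500,
                      sigma: float = 0.3) -> dict[str, float]:
    """Generator self-consistency: with morphology off, labels = IE + eps, so
    per gene PCC(IE, label)^2 = var(IE) / (var(IE) + sigma^2).

    Returns the mean and max absolute deviation between the measured squared
    correlation and the analytic value across genes.
    """
    cfg = SimConfig(n_sections=1, spots_per_section=n_spots,
                    morph_signal_strength=0.0, noise_sd=sigma,
                    patch_size=64, seed=seed)
    study = generate_study(cfg, render=False)
    ds = study.dataset
    res = per_sample_pcc(ds.ie, ds.labels)
    v = ds.ie.var(axis=0)
    analytic = v / (v + sigma ** 2)
    ok = np.isfinite(res.pcc)
    err = np.abs(res.pcc[ok] ** 2 - analytic[ok])
    return {"mean_abs_err": float(err.mean()),
            "max_abs_err": float(err.max()),
            "n_genes": int(ok.sum()),
            "n_spots": n_spots}
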