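"""Self-contained synthetic studies: reference atlas, nucleus-rendered
patches with known type counts, and spot expression with known IE-linked
structure.

The generator emulates the data regime the pipeline consumes — a labelled
single-cell reference with planted subtype structure, per-spot cell-type
counts, toy H&E-like patches in which each nucleus is an ellipse in a
type-specific colour, and spot labels built as

    label = IE(counts, reference) + alpha * m(patch) + eps,

where ``m`` is a fixed seeded linear map of the per-type count vector (a
morphology feature the image carries beyond the composition prior) and
``eps`` is i.i.d. Gaussian gene noise.  The generator composes IE with its
own double-loop weighted sum, independent of
:func:`scist.initial_expression.compose_initial_expression`, so the pipeline
can be checked against it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltypes import CELL_TYPES, DEAD
from .datasets import SpotDataset
from .initial_expression import CellTypeCounts
from .preprocess import GenePanel
from .reference import SCRDataset, ReferencePanel, build_reference_panel
from . import io as scio

__all__ = ["SimConfig", "SyntheticStudy", "generate_reference", "render_patch",
           "generate_study", "count_cells_by_color", "save_study", "load_study",
           "TYPE_COLORS", "BACKGROUND_COLOR"]

#: Distinct render colours per class (R, G, B); background is H&E-like pink.
TYPE_COLORS: dict[str, tuple[int, int, int]] = {
    CELL_TYPES[0]: (120, 40, 140),   # neoplastic: purple
    CELL_TYPES[1]: (40, 60, 170),    # inflammatory: blue
    CELL_TYPES[2]: (205, 120, 60),   # connective: orange
    CELL_TYPES[3]: (40, 150, 80),    # epithelial: green
    DEAD: (90, 90, 90),              # dead: grey
}
BACKGROUND_COLOR = (238, 210, 225)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults define the desk-scale study: 60 genes, 3 sections of 200 spots,
    4 non-dead cell types, moderate morphology signal (``alpha``) and gene
    noise (``sigma``) on the log1p expression scale.
    """

    n_genes: int = 60
    n_types: int = 4
    cells_per_type: int = 200
    n_sections: int = 3
    spots_per_section: int = 200
    morph_signal_strength: float = 0.4   # alpha
    noise_sd: float = 0.3                # sigma
    patch_size: int = 224
    seed: int = 0
    include_dead: bool = True
    nb_dispersion: float = 2.0
    separation: float = 2.0
    mean_cells_per_patch: float = 12.0
    target_sum: float = 1e4
    subtype_split: tuple[float, ...] = (0.6, 0.4)

    def __post_init__(self):
        if not (1 <= self.n_types <= len(CELL_TYPES)):
            raise ValueError(f"n_types must be in [1, {len(CELL_TYPES)}]")
        if self.noise_sd < 0 or self.morph_signal_strength < 0:
            raise ValueError("noise_sd and morph_signal_strength must be >= 0")
        for f in ("n_genes", "cells_per_type", "n_sections",
                  "spots_per_section"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def types(self) -> tuple[str, ...]:
        return CELL_TYPES[:self.n_types]

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


def generate_reference(cfg: SimConfig) -> SCRDataset:
    """Labelled single-cell counts with well-separated type centroids.

    Each type up-regulates its own gene block by ``cfg.separation`` on the
    log scale; counts are negative-binomial around the exponentiated
    centroid (overdispersion ``nb_dispersion``).  Two minor subtypes are
    planted per type with a known 60/40 split so the most-populous-subtype
    criterion has a known answer; optional dead cells exercise exclusion.
    """
    rng = np.random.default_rng((cfg.seed, 0x5EF))
    base = rng.uniform(0.5, 2.0, cfg.n_genes)
    block = cfg.n_genes // cfg.n_types
    counts_rows, majors, minors = [], [], []

    def draw_cells(centroid: np.ndarray, n: int) -> np.ndarray:
        mu = np.exp(centroid)
        lib = rng.lognormal(0.0, 0.2, (n, 1))
        mean = mu * lib
        r = cfg.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    for t_idx, ct in enumerate(cfg.types):
        centroid = base.copy()
        lo = t_idx * block
        hi = cfg.n_genes if t_idx == cfg.n_types - 1 else lo + block
        centroid[lo:hi] += cfg.separation
        sizes = [int(round(f * cfg.cells_per_type)) for f in cfg.subtype_split]
        sizes[0] += cfg.cells_per_type - sum(sizes)
        for s_idx, size in enumerate(sizes):
            shift = centroid + rng.normal(0.0, 0.05, cfg.n_genes)
            counts_rows.append(draw_cells(shift, size))
            majors.extend([ct] * size)
            minors.extend([f"{ct}.s{s_idx}"] * size)
    if cfg.include_dead:
        n_dead = max(1, cfg.cells_per_type // 4)
        counts_rows.append(draw_cells(base * 0.5, n_dead))
        majors.extend([DEAD] * n_dead)
        minors.extend([f"{DEAD}.s0"] * n_dead)
    return SCRDataset(np.concatenate(counts_rows, axis=0), cfg.gene_names,
                      np.array(majors, dtype=object),
                      np.array(minors, dtype=object))


def render_patch(counts: CellTypeCounts, cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw each nucleus as an ellipse in its type colour on a noisy pink
    background.  Nuclei occupy disjoint grid cells so connected-component
    counting recovers the planted counts exactly."""
    from skimage.draw import ellipse

    if rng is None:
        rng = np.random.default_rng(0)
    size = cfg.patch_size
    total = sum(counts.counts.values())
    grid = int(np.ceil(np.sqrt(max(total, 1))))
    cell = size // grid if grid else size
    if cell < 6:
        raise ValueError(f"{total} nuclei do not fit in a {size}x{size} patch")
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[...] = np.array(BACKGROUND_COLOR, dtype=np.uint8)
    noise = rng.integers(-6, 7, (size, size, 1))
    img = np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)

    slots = [(i, j) for i in range(grid) for j in range(grid)]
    rng.shuffle(slots)
    k = 0
    for ct, n in counts.counts.items():
        color = np.array(TYPE_COLORS[ct], dtype=np.uint8)
        for _ in range(n):
            gi, gj = slots[k]
            k += 1
            cy = gi * cell + cell // 2 + int(rng.integers(-cell // 8, cell // 8 + 1))
            cx = gj * cell + cell // 2 + int(rng.integers(-cell // 8, cell // 8 + 1))
            ry = max(2, cell // 4 + int(rng.integers(-1, 2)))
            rx = max(2, cell // 4 + int(rng.integers(-1, 2)))
            rr, cc = ellipse(cy, cx, ry, rx, shape=(size, size))
            img[rr, cc] = color
    return img


def count_cells_by_color(patch: np.ndarray) -> CellTypeCounts:
    """Trivial colour-based nucleus counter for rendered patches (a stand-in
    for an external segmenter on synthetic data)."""
    from skimage.measure import label

    counts = {}
    for ct, color in TYPE_COLORS.items():
        mask = np.all(patch == np.array(color, dtype=patch.dtype), axis=-1)
        counts[ct] = int(label(mask).max())
    return CellTypeCounts(counts)


def _oracle_ie(counts: CellTypeCounts, refs: ReferencePanel) -> np.ndarray:
    """Independent double-loop weighted mixture (the generator's own IE)."""
    types = refs.cell_types
    total = 0
    for ct in types:
        total += counts.counts.get(ct, 0)
    n_genes = len(refs.panel)
    out = np.zeros(n_genes)
    if total == 0:
        for ct in types:
            for g in range(n_genes):
                out[g] += refs.vectors[ct][g] / len(types)
        return out
    for ct in types:
        w = counts.counts.get(ct, 0) / total
        for g in range(n_genes):
            out[g] += w * refs.vectors[ct][g]
    return out


@dataclass
class SyntheticStudy:
    cfg: SimConfig
    scr: SCRDataset
    refs: ReferencePanel
    dataset: SpotDataset
    morph_map: np.ndarray  # [n_types, n_genes]
    section_compositions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ie_oracle(self) -> np.ndarray:
        return self.dataset.ie


def generate_study(cfg: SimConfig, render: bool = True) -> SyntheticStudy:
    """Full synthetic study in the formats the pipeline consumes.

    Per spot: type counts from a section-specific Dirichlet-multinomial
    composition prior; IE from the generator's own weighted-sum oracle;
    labels = IE + alpha * m(counts) + Gaussian noise.  ``render=False``
    skips patch rasterisation (patches become background-only) when only the
    expression side is needed.
    """
    rng = np.random.default_rng(cfg.seed)
    scr = generate_reference(cfg)
    panel = GenePanel(tuple(cfg.gene_names))
    refs = build_reference_panel(scr, panel, target_sum=cfg.target_sum)
    morph_map = rng.normal(0.0, 1.0, (cfg.n_types, cfg.n_genes)) \
        / np.sqrt(cfg.n_types)

    patches, ies, labels = [], [], []
    spot_ids, section_ids, patient_ids, all_counts = [], [], [], []
    centers = []
    compositions: dict[str, np.ndarray] = {}
    for s in range(cfg.n_sections):
        sec = f"sec{s}"
        p_sec = rng.dirichlet(np.full(cfg.n_types, 2.0))
        compositions[sec] = p_sec
        for j in range(cfg.spots_per_section):
            n_total = 1 + rng.poisson(cfg.mean_cells_per_patch - 1)
            p_spot = rng.dirichlet(10.0 * p_sec + 1e-3)
            vec = rng.multinomial(n_total, p_spot)
            cdict = {ct: int(v) for ct, v in zip(cfg.types, vec)}
            if cfg.include_dead:
                cdict[DEAD] = int(rng.poisson(0.5))
            counts = CellTypeCounts(cdict, patch_id=f"{sec}_s{j:03d}")
            ie = _oracle_ie(counts, refs)
            m = vec.astype(float) @ morph_map
            eps = rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
            label_row = ie + cfg.morph_signal_strength * m + eps
            if render:
                patch = render_patch(counts, cfg, rng)
            else:
                patch = np.full((cfg.patch_size, cfg.patch_size, 3),
                                np.array(BACKGROUND_COLOR, dtype=np.uint8))
            patches.append(patch)
            ies.append(ie)
            labels.append(label_row)
            all_counts.append(counts)
            spot_ids.append(counts.patch_id)
            section_ids.append(sec)
            patient_ids.append(f"patient{s}")
            centers.append((cfg.patch_size // 2, cfg.patch_size // 2))
    dataset = SpotDataset(
        patches=np.stack(patches), ie=np.stack(ies), labels=np.stack(labels),
        spot_ids=spot_ids, section_ids=section_ids, patient_ids=patient_ids,
        genes=cfg.gene_names, counts=all_counts,
        centers=np.array(centers, dtype=float))
    return SyntheticStudy(cfg, scr, refs, dataset, morph_map, compositions)


def save_study(study: SyntheticStudy, out_dir: str) -> None:
    """Write the study in the pipeline's file dialects.

    spots TSV; raw counts MTX (integerised from the labels) + sidecars;
    labels and IE as dense TSV; per-spot PNG patches; a flat segmentation
    TSV (patch_id / class / count); the reference as MTX + cell-metadata
    TSV; the gene panel as a one-column list; the reference panel TSV.
    """
    os.makedirs(out_dir, exist_ok=True)
    ds = study.dataset
    spots = pd.DataFrame({
        "spot_id": ds.spot_ids, "section_id": ds.section_ids,
        "patient_id": ds.patient_ids,
        "x": ds.centers[:, 0].astype(int), "y": ds.centers[:, 1].astype(int),
        "background": 0})
    scio.write_spot_table(spots, os.path.join(out_dir, "spots.tsv"))
    raw = np.rint(np.expm1(np.clip(ds.labels, 0, None))).astype(int)
    scio.write_mtx(raw, ds.genes, ds.spot_ids, out_dir, prefix="st_")
    scio.write_expression_tsv(ds.labels, ds.genes, ds.spot_ids,
                              os.path.join(out_dir, "labels.tsv"))
    scio.write_expression_tsv(ds.ie, ds.genes, ds.spot_ids,
                              os.path.join(out_dir, "ie_matrix.tsv"))
    patch_dir = os.path.join(out_dir, "patches")
    os.makedirs(patch_dir, exist_ok=True)
    for sid, patch in zip(ds.spot_ids, ds.patches):
        scio.write_image(patch, os.path.join(patch_dir, f"{sid}.png"))
    seg_rows = []
    for c in ds.counts:
        for ct, n in c.counts.items():
            seg_rows.append((c.patch_id, ct, n))
    pd.DataFrame(seg_rows, columns=["patch_id", "cell_type", "count"]) \
        .to_csv(os.path.join(out_dir, "segmentation.tsv"), sep="\t",
                index=False)
    scio.write_mtx(study.scr.counts, study.scr.gene_names,
                   [f"cell{i}" for i in range(study.scr.counts.shape[0])],
                   out_dir, prefix="scr_")
    pd.DataFrame({"cell_id": [f"cell{i}" for i in
                              range(study.scr.counts.shape[0])],
                  "major_type": study.scr.major_type,
                  "minor_type": study.scr.minor_type}) \
        .to_csv(os.path.join(out_dir, "scr_meta.tsv"), sep="\t", index=False)
    scio.write_gene_list(ds.genes, os.path.join(out_dir, "genes.txt"))
    study.refs.save(os.path.join(out_dir, "reference_panel.tsv"),
                    os.path.join(out_dir, "reference_provenance.tsv"))


def load_study(out_dir: str) -> SpotDataset:
    """Read back a saved study directory into a :class:`SpotDataset`."""
    spots = scio.read_spot_table(os.path.join(out_dir, "spots.tsv"))
    labels, genes, ids = scio.read_expression_tsv(
        os.path.join(out_dir, "labels.tsv"))
    ie, _, ie_ids = scio.read_expression_tsv(
        os.path.join(out_dir, "ie_matrix.tsv"))
    if ie_ids != ids:
        raise ValueError("IE and label spot order disagree")
    seg = pd.read_csv(os.path.join(out_dir, "segmentation.tsv"), sep="\t")
    counts_by_id: dict[str, dict[str, int]] = {}
    for _, row in seg.iterrows():
        counts_by_id.setdefault(row.patch_id, {})[row.cell_type] = int(row["count"])
    counts = [CellTypeCounts(counts_by_id[s], patch_id=s) for s in ids]
    patches = np.stack([scio.read_image(
        os.path.join(out_dir, "patches", f"{s}.png")) for s in ids])
    order = {s: i for i, s in enumerate(spots.spot_id)}
    idx = [order[s] for s in ids]
    return SpotDataset(
        patches=patches, ie=ie, labels=labels, spot_ids=ids,
        section_ids=[str(spots.section_id.iloc[i]) for i in idx],
        patient_ids=[str(spots.patient_id.iloc[i]) for i in idx],
        genes=genes, counts=counts,
        centers=spots[["x", "y"]].to_numpy(float)[idx])
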