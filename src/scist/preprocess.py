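"""Section preprocessing: patch extraction, gene-panel selection, label
normalisation and section filtering.

A *section* is one tissue slice: a whole-slide image, a table of barcoded
spots with pixel centre coordinates, and a spot x gene count matrix.  The
model consumes 224x224 patches centred on each spot, a panel of highly
variable genes shared with the single-cell reference, and spot-level
library-size-normalised log1p expression as regression labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpotRecord", "SectionData", "GenePanel", "extract_patch",
    "select_gene_panel", "compute_target_sum", "normalize_labels",
    "filter_sections",
]


@dataclass(frozen=True)
class SpotRecord:
    """One barcoded capture spot and its pixel centre on the slide."""

    spot_id: str
    section_id: str
    patient_id: str
    center_x: int
    center_y: int
    is_background: bool = False

    def __post_init__(self):
        if self.center_x < 0 or self.center_y < 0:
            raise ValueError(
                f"spot {self.spot_id}: negative centre "
                f"({self.center_x}, {self.center_y})")


@dataclass
class SectionData:
    """One tissue section: spots plus its raw count matrix."""

    section_id: str
    patient_id: str
    spots: list[SpotRecord]
    counts: np.ndarray  # [n_spots, n_genes_raw], non-negative
    gene_names: list[str]
    image: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != len(self.spots):
            raise ValueError(
                f"section {self.section_id}: {self.counts.shape[0]} count rows "
                f"for {len(self.spots)} spots")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError(f"section {self.section_id}: duplicate gene names")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError(f"section {self.section_id}: duplicate spot ids")

    @property
    def n_nonbackground(self) -> int:
        return sum(not s.is_background for s in self.spots)


@dataclass(frozen=True)
class GenePanel:
    """Ordered panel of gene symbols shared by ST data and the reference."""

    genes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene panel contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def indices_in(self, gene_names: list[str]) -> np.ndarray:
        """Column indices of the panel genes inside ``gene_names``."""
        pos = {g: i for i, g in enumerate(gene_names)}
        missing = [g for g in self.genes if g not in pos]
        if missing:
            raise KeyError(f"panel genes missing from data: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        return np.array([pos[g] for g in self.genes], dtype=int)


def extract_patch(image: np.ndarray, spot: SpotRecord,
                  half_size: int = 112) -> np.ndarray:
    """Crop the square window ``[c - half, c + half)`` around a spot centre.

    The window is half-open in both axes, with (row, col) = (y, x) and the
    origin at the top-left, so the output is exactly ``2*half_size`` square.
    Windows that overhang the slide edge are reflect-padded (with a logged
    warning); a centre outside the slide is an error.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB raster, got shape {img.shape}")
    H, W = img.shape[:2]
    cx, cy = spot.center_x, spot.center_y
    if not (0 <= cx < W and 0 <= cy < H):
        raise ValueError(
            f"spot {spot.spot_id}: centre ({cx}, {cy}) outside image {W}x{H}")
    r0, r1 = cy - half_size, cy + half_size
    c0, c1 = cx - half_size, cx + half_size
    if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
        pad = half_size
        logger.warning("spot %s: window [%d:%d, %d:%d) overhangs the %dx%d "
                       "slide; reflect-padding", spot.spot_id, r0, r1, c0, c1,
                       H, W)
        img = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        r0, r1, c0, c1 = r0 + pad, r1 + pad, c0 + pad, c1 + pad
    return img[r0:r1, c0:c1]


def compute_target_sum(sections: list[SectionData], panel: GenePanel) -> float:
    """Median panel-gene library size across all spots of the training split.

    Frozen once on the training split and stored with the model so that
    labels, reference vectors and the IE prior share one expression scale.
    """
    libs = []
    for sec in sections:
        idx = panel.indices_in(sec.gene_names)
        libs.append(np.asarray(sec.counts)[:, idx].sum(axis=1))
    libs = np.concatenate(libs).astype(float)
    libs = libs[libs > 0]
    if libs.size == 0:
        raise ValueError("all spots have zero panel-gene counts")
    return float(np.median(libs))


def normalize_labels(counts_row: np.ndarray, panel: GenePanel,
                     gene_names: list[str], target_sum: float) -> np.ndarray:
    """Restrict one spot's counts to the panel, depth-normalise, log1p.

    The row is scaled so its panel-gene sum equals ``target_sum``, then
    transformed ``x -> ln(1 + x)``.  All-zero rows map to all-zero output.
    """
    row = np.asarray(counts_row, dtype=float)
    if (row < 0).any():
        raise ValueError("negative count in expression row")
    sub = row[panel.indices_in(gene_names)]
    total = sub.sum()
    if total == 0:
        return np.zeros(len(panel))
    return np.log1p(sub * (target_sum / total))


def select_gene_panel(sections: list[SectionData], scr_genes: list[str],
                      top_k: int = 785) -> GenePanel:
    """Pick the ``top_k`` most variable genes also present in the reference.

    Variance is computed on log1p(library-size-normalised) expression pooled
    over every spot of every section.  Ties are broken lexicographically by
    gene symbol, so the panel is deterministic given its inputs.  If fewer
    than ``top_k`` genes are shared between the ST sections and the
    reference, all shared genes are returned with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not sections:
        raise ValueError("no sections given")
    shared = set(sections[0].gene_names)
    for sec in sections[1:]:
        shared &= set(sec.gene_names)
    shared &= set(scr_genes)
    if not shared:
        raise ValueError("no genes shared between ST sections and reference")
    genes = sorted(shared)

    rows = []
    for sec in sections:
        pos = {g: i for i, g in enumerate(sec.gene_names)}
        idx = np.array([pos[g] for g in genes])
        sub = np.asarray(sec.counts, dtype=float)[:, idx]
        lib = sub.sum(axis=1, keepdims=True)
        med = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(lib > 0, sub / lib * med, 0.0)
        rows.append(np.log1p(norm))
    pooled = np.concatenate(rows, axis=0)
    var = pooled.var(axis=0)

    if len(genes) < top_k:
        logger.warning("only %d genes shared with the reference (< top_k=%d); "
                       "returning all of them", len(genes), top_k)
        top_k = len(genes)
    # sort by (-variance, name): highest variance first, lexicographic ties
    order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
    return GenePanel(tuple(genes[i] for i in order[:top_k]))


def filter_sections(sections: list[SectionData],
                    min_spots: int = 180) -> list[SectionData]:
    """Drop sections with fewer than ``min_spots`` nonbackground spots.

    The comparison is strict ("fewer than"), so a section with exactly
    ``min_spots`` nonbackground spots is retained.  Input order is preserved.
    """
    return [s for s in sections if s.n_nonbackground >= min_spots]
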