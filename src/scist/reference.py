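"""Canonical per-cell-type reference vectors from a labelled scRNA-seq atlas.

For every non-dead PanNuke class present in the single-cell reference (SCR),
one representative minor subtype is chosen (the most populous; ties broken
lexicographically), its cells are library-size normalised, averaged, and
log1p-transformed into a single canonical expression vector over the gene
panel.  Dead cells never enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltypes import ALL_CELL_TYPES, DEAD
from .preprocess import GenePanel

__all__ = ["SCRDataset", "ReferencePanel", "select_representative_subtype",
           "build_reference_vector", "build_reference_panel"]


@dataclass
class SCRDataset:
    """A single-cell reference: counts plus major/minor type labels.

    ``major_type`` must come from the five-class PanNuke vocabulary; mapping
    an atlas's own ontology onto these five classes is dataset-specific and
    is supplied by the user (typically as a column pre-computed in the cell
    metadata).  ``minor_type`` is a free-text subtype label and may be empty.
    """

    counts: np.ndarray  # [n_cells, n_genes]
    gene_names: list[str]
    major_type: np.ndarray  # [n_cells] str
    minor_type: np.ndarray  # [n_cells] str ("" = unlabelled)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.major_type = np.asarray(self.major_type, dtype=object)
        self.minor_type = np.asarray(self.minor_type, dtype=object)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names in reference")
        n = self.counts.shape[0]
        if not (len(self.major_type) == len(self.minor_type) == n):
            raise ValueError("label arrays do not match cell count")
        bad = set(self.major_type) - set(ALL_CELL_TYPES)
        if bad:
            raise ValueError(f"unknown major cell types: {sorted(bad)}; "
                             f"expected one of {list(ALL_CELL_TYPES)}")

    @classmethod
    def from_anndata(cls, adata, major_key: str = "major_type",
                     minor_key: str = "minor_type") -> "SCRDataset":
        X = adata.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        minor = (adata.obs[minor_key].astype(str).to_numpy()
                 if minor_key in adata.obs else np.array([""] * adata.n_obs))
        return cls(X, [str(g) for g in adata.var_names],
                   adata.obs[major_key].astype(str).to_numpy(), minor)


@dataclass
class ReferencePanel:
    """One canonical log-expression vector per non-dead cell type."""

    panel: GenePanel
    vectors: dict[str, np.ndarray]  # cell type -> [N_G]
    provenance: dict[str, str] = field(default_factory=dict)
    target_sum: float = 1.0

    def __post_init__(self):
        if DEAD in self.vectors:
            raise ValueError("dead cells must not appear in a reference panel")
        for ct, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.panel),):
                raise ValueError(f"vector for {ct!r} has shape {v.shape}, "
                                 f"expected ({len(self.panel)},)")
            if (v < 0).any():
                raise ValueError(f"negative entries in reference vector {ct!r}")
            self.vectors[ct] = v

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.vectors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({ct: v for ct, v in self.vectors.items()},
                            index=list(self.panel.genes))

    def save(self, path: str, provenance_path: str | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")
        if provenance_path:
            pd.DataFrame({"major_type": list(self.provenance),
                          "chosen_subtype": list(self.provenance.values())}) \
                .to_csv(provenance_path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str, target_sum: float = 1.0) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        panel = GenePanel(tuple(str(g) for g in df.index))
        return cls(panel, {str(c): df[c].to_numpy(dtype=float)
                           for c in df.columns}, target_sum=target_sum)


def select_representative_subtype(scr: SCRDataset, major_type: str) -> str:
    """Most populous minor subtype within ``major_type`` (ties: lexicographic).

    When the atlas provides no minor labels for the group, the empty label is
    returned and the whole major group is used (flagged in provenance).
    """
    if major_type == DEAD:
        raise ValueError("dead cells are excluded from all computations")
    mask = scr.major_type == major_type
    if not mask.any():
        available = sorted(set(scr.major_type))
        raise ValueError(f"no cells with major type {major_type!r}; "
                         f"available: {available}")
    labels = scr.minor_type[mask]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    # max count, then lexicographically smallest label
    return min(counts, key=lambda k: (-counts[k], k))


def build_reference_vector(scr: SCRDataset, cell_ids: np.ndarray,
                           panel: GenePanel, target_sum: float) -> np.ndarray:
    """normalise-per-cell -> mean over cells -> ln(1 + x), on panel genes.

    Library-size normalisation uses the same frozen target sum as the spot
    labels so the mixture prior and the regression target share one scale.
    """
    cell_ids = np.asarray(cell_ids)
    if cell_ids.size == 0:
        raise ValueError("empty cell selection")
    idx = panel.indices_in(scr.gene_names)
    sub = np.asarray(scr.counts, dtype=float)[cell_ids][:, idx]
    lib = sub.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(lib > 0, sub / lib * target_sum, 0.0)
    return np.log1p(norm.mean(axis=0))


def build_reference_panel(scr: SCRDataset, panel: GenePanel,
                          target_sum: float = 1e4) -> ReferencePanel:
    """One canonical vector per non-dead major type present in the SCR."""
    majors = [t for t in sorted(set(scr.major_type)) if t != DEAD]
    if not majors:
        raise ValueError("reference contains no non-dead cells")
    vectors: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for mt in majors:
        sub = select_representative_subtype(scr, mt)
        mask = (scr.major_type == mt) & (scr.minor_type == sub)
        ids = np.flatnonzero(mask)
        vectors[mt] = build_reference_vector(scr, ids, panel, target_sum)
        provenance[mt] = sub if sub else "<whole major group: no minor labels>"
    return ReferencePanel(panel, vectors, provenance, target_sum)
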