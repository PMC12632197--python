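"""The initial-expression (IE) prior: a cell-count-weighted reference mixture.

For a patch with per-type nucleus counts N_ci, the mixture weights are
pi_i = N_ci / sum_j N_cj over the non-dead classes, and the prior is the
weighted sum Expr = sum_i pi_i * Ref_ci of the already-logged canonical
reference vectors.  The result is not renormalised or re-logged.  Patches
with zero segmented (non-dead) nuclei fall back to uniform weights over the
reference panel's types and carry a ``degenerate`` flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltypes import CELL_TYPES, DEAD, PANNUKE_CODE_TO_NAME
from .reference import ReferencePanel

__all__ = ["CellTypeCounts", "InitialExpression", "compute_weights",
           "compose_initial_expression", "parse_segmentation_counts",
           "ie_matrix"]


@dataclass
class CellTypeCounts:
    """Per-patch nucleus tallies for the five PanNuke classes."""

    counts: dict[str, int]
    patch_id: str = ""
    rejected: int = 0  # nuclei with labels outside the five-class vocabulary

    def __post_init__(self):
        for ct, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {ct!r} in patch "
                                 f"{self.patch_id!r}")

    def nondead(self) -> dict[str, int]:
        return {ct: n for ct, n in self.counts.items() if ct != DEAD}

    @property
    def n_total(self) -> int:
        """Total non-dead nuclei (dead is excluded from all computations)."""
        return sum(self.nondead().values())


@dataclass
class InitialExpression:
    """The IE prior vector for one patch plus its mixture weights."""

    values: np.ndarray  # [N_G]
    weights: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.degenerate and self.weights:
            s = sum(self.weights.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"weights sum to {s}, expected 1")


def compute_weights(counts: CellTypeCounts,
                    types: tuple[str, ...] | None = None
                    ) -> tuple[dict[str, float], bool]:
    """Mixture weights pi_i = N_ci / N_total over the non-dead classes.

    Returns ``(weights, degenerate)``; a patch with no non-dead nuclei gets
    uniform weights over ``types`` (default: the four non-dead PanNuke
    classes) and ``degenerate=True``.
    """
    if types is None:
        types = CELL_TYPES
    nd = counts.nondead()
    total = sum(nd.get(ct, 0) for ct in types)
    if total == 0:
        return {ct: 1.0 / len(types) for ct in types}, True
    return {ct: nd.get(ct, 0) / total for ct in types}, False


def compose_initial_expression(counts: CellTypeCounts,
                               refs: ReferencePanel) -> InitialExpression:
    """Expr = sum_i pi_i * Ref_ci — an exact weighted sum, no renormalisation."""
    weights, degenerate = compute_weights(counts, refs.cell_types)
    nd = counts.nondead()
    extra = {ct for ct, n in nd.items() if n > 0} - set(refs.cell_types)
    if extra:
        raise KeyError(f"cell types with nonzero counts missing from the "
                       f"reference panel: {sorted(extra)}")
    values = np.zeros(len(refs.panel))
    for ct, w in weights.items():
        if w:
            values = values + w * refs.vectors[ct]
    return InitialExpression(values, weights, degenerate)


def parse_segmentation_counts(seg_output, patch_id: str = "") -> CellTypeCounts:
    """Tally per-class nuclei from nucleus-segmenter output.

    Accepts either the JSON instance-dictionary dialect of the common
    HoverNet-style segmenter (``{"nuc": {id: {"type": code}}}`` with PanNuke
    integer codes) or an iterable of per-nucleus records, each a class name
    or a ``{"type": ...}`` mapping.  Labels outside the five-class vocabulary
    are counted in a reject bucket and reported on the result.
    """
    if isinstance(seg_output, str):
        seg_output = json.loads(seg_output)
    if isinstance(seg_output, dict) and "nuc" in seg_output:
        records = [v for v in seg_output["nuc"].values()]
    else:
        records = list(seg_output)

    counts = {ct: 0 for ct in PANNUKE_CODE_TO_NAME.values()}
    rejected = 0
    for i, rec in enumerate(records):
        if isinstance(rec, dict):
            if "type" not in rec:
                raise ValueError(f"malformed segmentation record {i}: {rec!r}")
            label = rec["type"]
        else:
            label = rec
        if isinstance(label, (int, np.integer)) and not isinstance(label, bool):
            name = PANNUKE_CODE_TO_NAME.get(int(label))
        elif isinstance(label, str):
            name = label if label in counts else None
        else:
            raise ValueError(f"malformed segmentation record {i}: {rec!r}")
        if name is None:
            rejected += 1
        else:
            counts[name] += 1
    return CellTypeCounts(counts, patch_id=patch_id, rejected=rejected)


def ie_matrix(counts_per_patch: list[CellTypeCounts],
              refs: ReferencePanel) -> pd.DataFrame:
    """IE vectors for a list of patches, as a patch x gene DataFrame."""
    rows, ids = [], []
    for c in counts_per_patch:
        rows.append(compose_initial_expression(c, refs).values)
        ids.append(c.patch_id)
    return pd.DataFrame(np.stack(rows), index=ids, columns=list(refs.panel.genes))
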