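"""The aligned per-spot training container.

A :class:`SpotDataset` holds, for every spot: the RGB patch, the IE prior,
the normalised label expression, and section/patient metadata — plus,
optionally, the per-patch cell-type counts (needed by the cell-ratio-noise
ablation) and the patch centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .initial_expression import CellTypeCounts

__all__ = ["SpotDataset"]


@dataclass
class SpotDataset:
    patches: np.ndarray          # [n, H, W, 3] uint8
    ie: np.ndarray               # [n, N_G]
    labels: np.ndarray           # [n, N_G]
    spot_ids: list[str]
    section_ids: list[str]
    patient_ids: list[str]
    genes: list[str]
    counts: list[CellTypeCounts] | None = None
    centers: np.ndarray | None = None  # [n, 2] (x, y)
    degenerate: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.spot_ids)
        for name in ("patches", "ie", "labels"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows for {n} spots")
        if self.ie.shape[1] != len(self.genes) or \
                self.labels.shape[1] != len(self.genes):
            raise ValueError("IE/label width does not match the gene panel")

    def __len__(self) -> int:
        return len(self.spot_ids)

    @property
    def sections(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.section_ids:
            seen.setdefault(s, None)
        return list(seen)

    def subset(self, indices: np.ndarray) -> "SpotDataset":
        indices = np.asarray(indices)
        return replace(
            self,
            patches=self.patches[indices],
            ie=self.ie[indices],
            labels=self.labels[indices],
            spot_ids=[self.spot_ids[i] for i in indices],
            section_ids=[self.section_ids[i] for i in indices],
            patient_ids=[self.patient_ids[i] for i in indices],
            counts=None if self.counts is None
            else [self.counts[i] for i in indices],
            centers=None if self.centers is None else self.centers[indices],
            degenerate=None if self.degenerate is None
            else self.degenerate[indices],
        )

    def split_sections(self, held_out: str
                       ) -> tuple["SpotDataset", "SpotDataset"]:
        mask = np.array([s == held_out for s in self.section_ids])
        if not mask.any():
            raise KeyError(f"section {held_out!r} not in dataset")
        return self.subset(np.flatnonzero(~mask)), \
            self.subset(np.flatnonzero(mask))

    def copy(self) -> "SpotDataset":
        return replace(
            self,
            patches=self.patches.copy(),
            ie=self.ie.copy(),
            labels=self.labels.copy(),
            spot_ids=list(self.spot_ids),
            section_ids=list(self.section_ids),
            patient_ids=list(self.patient_ids),
            counts=None if self.counts is None else list(self.counts),
            centers=None if self.centers is None else self.centers.copy(),
            degenerate=None if self.degenerate is None
            else self.degenerate.copy(),
        )
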