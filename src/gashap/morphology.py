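"""Chromosome -> binary mask via per-region morphological operators.

Each gene modulates the spatial extent of its region's contribution to the
final binary mask: gene 0 omits the region, gene 1 shrinks it by binary
erosion, gene 2 keeps it unchanged, gene 3 grows it by binary dilation
(clipped at the grid boundary, no wraparound).  The mask is the union of
all contributions, so a dilated region may well overlap its neighbours —
region identity is deliberately not retained in the binary mask.

The structuring element defaults to the 6-connected 3x3x3 cross, the
smallest symmetric 3D element; 26-connectivity and multiple iterations are
available.  Erosion can empty a thin region entirely, which is the intended
behaviour for a low-importance region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelAtlas, Volume
from .scoring import GENE_OPERATIONS, check_chromosome

__all__ = ["StructuringElement", "BrainMask", "build_mask", "apply_mask"]


@dataclass(frozen=True)
class StructuringElement:
    """6- or 26-connected 3D neighbourhood, applied ``iterations`` times."""

    connectivity: int = 6
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


@dataclass
class BrainMask:
    """Binary voxel mask plus the chromosome/element that produced it."""

    mask: np.ndarray
    genes: np.ndarray | None = None
    element: StructuringElement | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def provenance_table(self, atlas: LabelAtlas) -> pd.DataFrame:
        if self.genes is None:
            raise ValueError("mask carries no chromosome provenance")
        df = atlas.names_table()
        df["gene"] = self.genes.astype(int)
        df["operation"] = [GENE_OPERATIONS[int(g)] for g in self.genes]
        return df


def region_contribution(
    support: np.ndarray, gene: int, se: StructuringElement
) -> np.ndarray:
    """The voxel set one region contributes to the mask, per its gene."""
    if gene == 0:
        return np.zeros_like(support, dtype=bool)
    if gene == 1:
        return ndimage.binary_erosion(support, structure=se.structure, iterations=se.iterations)
    if gene == 2:
        return support.astype(bool)
    if gene == 3:
        return ndimage.binary_dilation(support, structure=se.structure, iterations=se.iterations)
    raise ValueError(f"invalid gene value {gene}")


def build_mask(
    genes: np.ndarray, atlas: LabelAtlas, se: StructuringElement | None = None
) -> BrainMask:
    """Union of per-region contributions (omit/erode/keep/dilate by gene)."""
    se = se or StructuringElement()
    genes = check_chromosome(genes, atlas.R)
    out = np.zeros(atlas.shape, dtype=bool)
    if (genes == 2).any():  # unchanged supports in one vectorized pass
        out |= np.isin(atlas.labels, np.flatnonzero(genes == 2) + 1)
    for r in np.flatnonzero((genes == 1) | (genes == 3)) + 1:
        out |= region_contribution(atlas.region_support(r), int(genes[r - 1]), se)
    return BrainMask(mask=out, genes=genes, element=se)


def apply_mask(v: Volume, m: BrainMask | np.ndarray, fill: float = 0.0) -> Volume:
    """Keep voxels where the mask is set; fill everywhere else."""
    mask = m.mask if isinstance(m, BrainMask) else np.asarray(m).astype(bool)
    if mask.shape != v.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {v.shape}")
    data = np.where(mask, v.data, np.float32(fill))
    return Volume(data=data.astype(np.float32), affine=v.affine)
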