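"""Collapse voxel heatmaps into per-region scores and chromosomes.

Each atlas region r of a heatmap h receives the score

    score(r) = sum of strictly positive h-values in r
               / (voxel count of r * max h-value in r)

which lies in [0, 1]: the positive sum is at most ``n_r * max``, with
equality exactly when every voxel of the region carries the same positive
value.  Regions whose maximum is not positive score 0 — negative and zero
attributions carry no credit.

The R scores of one heatmap are then rank-percentile binned into gene
values {0, 1, 2, 3} (unimportant / important / very important / very very
important): with ascending rank k of R (ties broken by region index), the
percentile is ``100*k/R`` and the gene is the band index of the binning
scheme.  The default schemes are A = (30, 50, 70) and B = (40, 60, 80)
percent cut points.  One chromosome per heatmap forms the genetic
algorithm's initial population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import Heatmap
from .io import LabelAtlas

__all__ = [
    "BinningScheme",
    "SCHEME_A",
    "SCHEME_B",
    "GENE_VALUES",
    "GENE_LABELS",
    "GENE_OPERATIONS",
    "region_scores",
    "encode_chromosome",
    "heatmaps_to_population",
    "check_chromosome",
    "chromosome_table",
]

GENE_VALUES = (0, 1, 2, 3)
GENE_LABELS = {0: "UR", 1: "IR", 2: "VIR", 3: "VVIR"}
GENE_OPERATIONS = {0: "Omitted", 1: "Erosion", 2: "No operation", 3: "Dilation"}


@dataclass(frozen=True)
class BinningScheme:
    """Ascending percentile cut points splitting ranks into 4 gene bands."""

    breakpoints: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        b = self.breakpoints
        if len(b) != 3 or not all(0 < x < 100 for x in b) or not b[0] < b[1] < b[2]:
            raise ValueError("breakpoints must be strictly ascending within (0, 100)")

    def gene_of_percentile(self, p: np.ndarray) -> np.ndarray:
        """Right-closed bands: gene g iff b_g < p <= b_{g+1}."""
        edges = np.array(self.breakpoints)
        return np.searchsorted(edges, p, side="left").astype(np.uint8)


SCHEME_A = BinningScheme((30.0, 50.0, 70.0), name="A")
SCHEME_B = BinningScheme((40.0, 60.0, 80.0), name="B")


def check_chromosome(genes: np.ndarray, R: int | None = None) -> np.ndarray:
    """Validate a gene vector; returns it as a uint8 array."""
    genes = np.asarray(genes)
    if genes.ndim != 1:
        raise ValueError("chromosome must be a 1D gene vector")
    if R is not None and len(genes) != R:
        raise ValueError(f"chromosome length {len(genes)} != atlas region count {R}")
    if not np.isin(genes, GENE_VALUES).all():
        raise ValueError("gene values must come from {0, 1, 2, 3}")
    return genes.astype(np.uint8)


def region_scores(h: Heatmap, atlas: LabelAtlas) -> np.ndarray:
    """Length-R vector of region scores in [0, 1], internal atlas order.

    Background voxels (label 0) never contribute.
    """
    values = h.values
    if values.shape != atlas.shape:
        raise ValueError(f"heatmap shape {values.shape} != atlas shape {atlas.shape}")
    flat_labels = atlas.labels.ravel()
    flat_vals = values.ravel()
    R = atlas.R
    pos_sum = np.bincount(
        flat_labels, weights=np.where(flat_vals > 0, flat_vals, 0.0), minlength=R + 1
    )[1:]
    sizes = atlas.region_sizes()
    # per-region max via reduceat on label-sorted values
    order = np.argsort(flat_labels, kind="stable")
    sorted_vals = flat_vals[order]
    sorted_labels = flat_labels[order]
    starts = np.searchsorted(sorted_labels, np.arange(1, R + 1), side="left")
    maxima = np.maximum.reduceat(sorted_vals, starts)
    scores = np.zeros(R)
    good = maxima > 0
    scores[good] = pos_sum[good] / (sizes[good] * maxima[good])
    # mathematically bounded by 1; clip floating-point overshoot
    return np.clip(scores, 0.0, 1.0)


def encode_chromosome(scores: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """Rank-percentile encode R scores into genes {0,1,2,3}.

    Regions are ranked ascending by score with ties broken by region index
    (ascending), so the encoding is deterministic; the region at 1-based
    rank k maps to percentile ``100*k/R``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or len(scores) < 1:
        raise ValueError("scores must be a nonempty 1D vector")
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("region scores must lie in [0, 1]")
    R = len(scores)
    order = np.lexsort((np.arange(R), scores))  # ascending score, index tie-break
    ranks = np.empty(R, dtype=np.int64)
    ranks[order] = np.arange(1, R + 1)
    percentiles = 100.0 * ranks / R
    return scheme.gene_of_percentile(percentiles)


def heatmaps_to_population(
    heatmaps: list[Heatmap], atlas: LabelAtlas, scheme: BinningScheme
) -> list[np.ndarray]:
    """One chromosome per heatmap, order preserved."""
    if not heatmaps:
        raise ValueError("need at least one heatmap to build a population")
    return [encode_chromosome(region_scores(h, atlas), scheme) for h in heatmaps]


def chromosome_table(
    genes: np.ndarray, atlas: LabelAtlas, scores: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-region table (ID, name, score, gene, labels) for export."""
    genes = check_chromosome(genes, atlas.R)
    df = atlas.names_table()
    if scores is not None:
        df["score"] = np.asarray(scores, dtype=float)
    df["gene"] = genes.astype(int)
    df["importance"] = [GENE_LABELS[int(g)] for g in genes]
    df["operation"] = [GENE_OPERATIONS[int(g)] for g in genes]
    return df
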