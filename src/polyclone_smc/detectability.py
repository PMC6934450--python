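"""Analytic detection-limit model for clone-private mutations in bulk tissue.

A heterozygous mutation private to a clone occupying cell fraction f of a
diploid sample has expected VAF f/2.  A caller demanding a minimal VAF t
therefore needs f >= 2t of the sampled cells to carry the mutation — at the
typical t = 0.15, about 30% of cells.  At finite read depth D the call
succeeds when the sampled alt-read count X ~ Binomial(D, f/2) reaches both
the VAF threshold (k >= t*D) and a minimal supporting-read count m; the
detection probability is the exact binomial tail, with no normal
approximation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import binom

from .model import ValidationError


def _copies(zygosity: str) -> int:
    if zygosity == "het":
        return 1
    if zygosity == "hom":
        return 2
    raise ValidationError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")


def min_cell_fraction(vaf_threshold: float, zygosity: str = "het", ploidy: int = 2) -> float:
    """Smallest cell fraction whose expected VAF reaches the calling threshold.

    Returns vaf_threshold * ploidy / copies, capped at 1.  For the typical
    threshold 0.15 and a heterozygous mutation in a diploid genome: 0.30.
    """
    if vaf_threshold <= 0 or vaf_threshold > 1:
        raise ValidationError("vaf_threshold must be in (0, 1]")
    if ploidy < 1:
        raise ValidationError("ploidy must be >= 1")
    return min(1.0, vaf_threshold * ploidy / _copies(zygosity))


@dataclass
class DetectionQuery:
    """Parameters of one detectability evaluation."""

    clone_fraction: float
    depth: int
    zygosity: str = "het"
    ploidy: int = 2
    vaf_threshold: float = 0.15
    min_alt_reads: int = 3

    def __post_init__(self):
        if not (0.0 <= self.clone_fraction <= 1.0):
            raise ValidationError("clone_fraction must be in [0,1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not (0.0 <= self.vaf_threshold <= 1.0):
            raise ValidationError("vaf_threshold must be in [0,1]")
        if self.min_alt_reads < 0:
            raise ValidationError("min_alt_reads must be >= 0")

    @property
    def expected_vaf(self) -> float:
        return self.clone_fraction * _copies(self.zygosity) / self.ploidy


def required_alt_reads(query: DetectionQuery) -> int:
    """Smallest alt-read count satisfying both VAF threshold and read floor.

    t*D is rounded at 1e-9 before the ceiling so float noise on products
    that are mathematically integral does not raise the requirement.
    """
    k_vaf = math.ceil(round(query.vaf_threshold * query.depth, 9))
    return max(query.min_alt_reads, k_vaf)


def detection_probability(query: DetectionQuery) -> float:
    """P[X >= max(m, ceil(t*D))] with X ~ Binomial(D, expected VAF); exact tail."""
    k = required_alt_reads(query)
    if k <= 0:
        return 1.0
    p = query.expected_vaf
    if p <= 0.0:
        return 0.0
    return float(binom.sf(k - 1, query.depth, p))


def detectability_curve(
    f_grid: Sequence[float],
    depth_grid: Sequence[int],
    vaf_threshold: float = 0.15,
    min_alt_reads: int = 3,
    zygosity: str = "het",
    ploidy: int = 2,
) -> pd.DataFrame:
    """Detection probability over a (clone fraction x depth) grid."""
    if len(f_grid) == 0 or len(depth_grid) == 0:
        raise ValidationError("grids must be non-empty")
    rows = []
    for f in f_grid:
        for d in depth_grid:
            q = DetectionQuery(
                clone_fraction=float(f),
                depth=int(d),
                zygosity=zygosity,
                ploidy=ploidy,
                vaf_threshold=vaf_threshold,
                min_alt_reads=min_alt_reads,
            )
            rows.append(
                {
                    "clone_fraction": float(f),
                    "depth": int(d),
                    "expected_vaf": q.expected_vaf,
                    "detection_probability": detection_probability(q),
                }
            )
    return pd.DataFrame(rows)
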