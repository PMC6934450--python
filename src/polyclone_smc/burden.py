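"""Mutational burden metrics: callable genome (SMC power), calls per Mb,
and intermutation distances for rainfall-style clustering review.

SMC power is the number of base pairs with read depth >= a threshold
(default 10) in both the affected and the reference tissue — the genome
fraction where somatic calling was possible at all.  Burden normalizes the
call count by that callable size.

Intermutation distances (IMDs) are computed within chromosomes only; the
rainfall table adds cumulative chromosome offsets for a genome-wide x-axis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    CallSet,
    DepthProfile,
    ValidationError,
    chrom_sort_key,
    fold_substitution,
    normalize_chrom,
)


@dataclass
class PowerResult:
    callable_bp: int
    threshold: int
    assessed_bp: int

    @property
    def callable_mb(self) -> float:
        return self.callable_bp / 1e6


def smc_power(
    depth_target: DepthProfile,
    depth_reference: DepthProfile,
    threshold: int = 10,
) -> PowerResult:
    """Count positions where both tissues reach the depth threshold."""
    regions_t = depth_target.region_set()
    regions_r = depth_reference.region_set()
    if regions_t != regions_r:
        raise ValidationError(
            f"depth profiles cover different regions: {regions_t} vs {regions_r}"
        )
    arrays_t = depth_target.arrays()
    arrays_r = depth_reference.arrays()
    callable_bp = 0
    assessed = 0
    for chrom, (_, dt) in arrays_t.items():
        dr = arrays_r[chrom][1]
        callable_bp += int(((dt >= threshold) & (dr >= threshold)).sum())
        assessed += len(dt)
    return PowerResult(callable_bp=callable_bp, threshold=threshold, assessed_bp=assessed)


@dataclass
class BurdenResult:
    n_calls: int
    callable_bp: int

    @property
    def calls_per_mb(self) -> float:
        return self.n_calls / (self.callable_bp / 1e6)


def burden(callset: CallSet, power: PowerResult) -> BurdenResult:
    """Calls per callable megabase; undefined (error) at zero callable bp."""
    if power.callable_bp <= 0:
        raise ValidationError("burden undefined: callable_bp is 0")
    return BurdenResult(n_calls=len(callset), callable_bp=power.callable_bp)


@dataclass
class ImdSeries:
    """Per chromosome: sorted call positions and distances to the previous call."""

    positions: dict[str, list[int]]
    distances: dict[str, list[int]]

    def all_distances(self) -> list[int]:
        return [d for ds in self.distances.values() for d in ds]

    def min_distance(self) -> Optional[int]:
        ds = self.all_distances()
        return min(ds) if ds else None


def imd(callset: CallSet) -> ImdSeries:
    """Intermutation distances, within chromosomes only."""
    per_chrom: dict[str, list[int]] = {}
    for call in callset.calls:
        per_chrom.setdefault(normalize_chrom(call.position.chrom), []).append(
            call.position.pos
        )
    positions = {}
    distances = {}
    for chrom in sorted(per_chrom, key=chrom_sort_key):
        pos = sorted(per_chrom[chrom])
        positions[chrom] = pos
        distances[chrom] = [b - a for a, b in zip(pos[:-1], pos[1:])]
    return ImdSeries(positions=positions, distances=distances)


def rainfall_table(
    callset: CallSet,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Rainfall TSV content: cumulative position, IMD, substitution class."""
    offsets: dict[str, int] = {}
    cursor = 0
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        offsets[normalize_chrom(chrom)] = cursor
        cursor += chrom_lengths[chrom]
    series = imd(callset)
    by_key = {c.key: c for c in callset.calls}
    rows = []
    for chrom, pos in series.positions.items():
        dists = [np.nan] + series.distances[chrom]
        for p, d in zip(pos, dists):
            call = by_key[(chrom, p)]
            rows.append(
                {
                    "chrom": chrom,
                    "pos": p,
                    "cumulative_pos": offsets.get(chrom, 0) + p,
                    "imd": d,
                    "substitution": fold_substitution(call.ref_allele, call.alt_allele),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "cumulative_pos", "imd", "substitution"])
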