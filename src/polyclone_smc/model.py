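"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
Variant calls and all public reporting are 1-based (VCF convention).
Annotation tracks are 0-based half-open (BED convention).  The conversion
between the two happens exactly once, inside :meth:`Track.contains`.

Chromosome names are normalized for matching by stripping a leading
``chr`` prefix; original spellings are preserved for output.
"""
from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

logger = logging.getLogger("polyclone_smc")

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ValidationError(ValueError):
    """A domain object violates its invariants."""


class ConfigurationError(RuntimeError):
    """A required track, key or parameter is missing or out of range."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix for cross-source position matching."""
    if not chrom:
        raise ValidationError("empty chromosome name")
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: 1..22 numerically, then X, Y, MT, others."""
    name = normalize_chrom(chrom)
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@functools.total_ordering
@dataclass(frozen=True, eq=False)
class GenomicPosition:
    """A 1-based genomic coordinate."""

    chrom: str
    pos: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        """Matching key: (normalized chromosome, position)."""
        return (normalize_chrom(self.chrom), self.pos)

    @property
    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos)

    def __eq__(self, other):
        if not isinstance(other, GenomicPosition):
            return NotImplemented
        return self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __lt__(self, other):
        return self.sort_key < other.sort_key

    def __str__(self):
        return f"{self.chrom}:{self.pos}"


class Tissue(str, Enum):
    BLOOD = "blood"
    LOWER_LOBE = "lower_lobe"
    UPPER_LOBE = "upper_lobe"


class FunctionalClass(str, Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SPLICE_SITE = "splice_site"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass
class VariantCall:
    """One called somatic single-nucleotide mutation.

    ``vaf_*`` / ``depth_*`` may be ``None`` when the source VCF dialect does
    not expose them (graceful degradation to "unknown", never silent zeros).
    """

    position: GenomicPosition
    ref_allele: str
    alt_allele: str
    caller: str = "unknown"
    subject: str = "unknown"
    tissue: Tissue = Tissue.LOWER_LOBE
    vaf_target: Optional[float] = None
    vaf_reference: Optional[float] = None
    depth_target: Optional[int] = None
    depth_reference: Optional[int] = None
    functional_class: FunctionalClass = FunctionalClass.UNKNOWN

    def __post_init__(self):
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValidationError(
                f"alleles must be single bases in ACGT: {self.ref_allele}>{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt allele must differ")
        for v in (self.vaf_target, self.vaf_reference):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"VAF out of [0,1]: {v}")
        for d in (self.depth_target, self.depth_reference):
            if d is not None and d < 0:
                raise ValidationError(f"negative depth: {d}")

    @property
    def key(self) -> tuple[str, int]:
        return self.position.key


@dataclass
class CallSet:
    """Sorted, position-unique set of calls for one subject x tissue x caller."""

    subject: str
    tissue: Tissue
    caller: str
    calls: list[VariantCall] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        subject: str,
        tissue: Tissue,
        caller: str,
        calls: Iterable[VariantCall],
    ) -> "CallSet":
        """Sort by position and drop duplicate positions (keep first, log)."""
        ordered = sorted(calls, key=lambda c: c.position.sort_key)
        unique: list[VariantCall] = []
        seen: set[tuple[str, int]] = set()
        dropped = 0
        for call in ordered:
            if call.key in seen:
                dropped += 1
                continue
            seen.add(call.key)
            unique.append(call)
        if dropped:
            logger.warning(
                "%s/%s/%s: dropped %d duplicate-position calls (kept first)",
                subject, tissue.value, caller, dropped,
            )
        return cls(subject=subject, tissue=tissue, caller=caller, calls=unique)

    def position_keys(self) -> set[tuple[str, int]]:
        return {c.key for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)


class Track:
    """A named set of genomic intervals (0-based half-open), merged on load.

    Intervals are stored per chromosome as sorted, non-overlapping numpy
    start/end arrays; point membership is a binary search.  Original
    chromosome spellings are remembered for output.
    """

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]):
        self.name = name
        self._display: dict[str, str] = {}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValidationError(f"interval start >= end: {chrom}:{start}-{end}")
            if start < 0:
                raise ValidationError(f"negative interval start: {chrom}:{start}")
            key = normalize_chrom(chrom)
            self._display.setdefault(key, chrom)
            per_chrom.setdefault(key, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for key, ivs in per_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            self._starts[key] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[key] = np.array([m[1] for m in merged], dtype=np.int64)

    # -- queries ----------------------------------------------------------

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position falls inside any interval."""
        return bool(self.contains_many(chrom, np.asarray([pos]))[0])

    def contains_position(self, position: GenomicPosition) -> bool:
        return self.contains(position.chrom, position.pos)

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership for 1-based positions on one chromosome."""
        key = normalize_chrom(chrom)
        starts = self._starts.get(key)
        if starts is None or len(starts) == 0:
            return np.zeros(len(positions), dtype=bool)
        q = np.asarray(positions, dtype=np.int64) - 1  # 1-based -> 0-based
        idx = np.searchsorted(starts, q, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(q), dtype=bool)
        hit[ok] = q[ok] < self._ends[key][idx[ok]]
        return hit

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for key in sorted(self._starts, key=chrom_sort_key):
            chrom = self._display[key]
            for s, e in zip(self._starts[key], self._ends[key]):
                yield (chrom, int(s), int(e))

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def coverage_bp(self) -> int:
        return int(
            sum((self._ends[k] - self._starts[k]).sum() for k in self._starts)
        )

    # -- set operations (used by the synthetic generator) -----------------

    def union(self, other: "Track", name: Optional[str] = None) -> "Track":
        return Track(name or f"{self.name}|{other.name}",
                     list(self.intervals()) + list(other.intervals()))

    def complement(self, chrom_lengths: Mapping[str, int],
                   name: Optional[str] = None) -> "Track":
        """Intervals of the genome not covered by this track."""
        out: list[tuple[str, int, int]] = []
        for chrom, length in chrom_lengths.items():
            key = normalize_chrom(chrom)
            cursor = 0
            for s, e in zip(self._starts.get(key, []), self._ends.get(key, [])):
                s, e = int(s), min(int(e), length)
                if s > cursor:
                    out.append((chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < length:
                out.append((chrom, cursor, length))
        return Track(name or f"not_{self.name}", out)

    def sample_positions(self, n: int, rng: np.random.Generator) -> list[GenomicPosition]:
        """Draw n 1-based positions uniformly over the covered bases."""
        chroms = sorted(self._starts, key=chrom_sort_key)
        lens = [self._ends[k] - self._starts[k] for k in chroms]
        totals = np.array([int(l.sum()) for l in lens])
        total = int(totals.sum())
        if total == 0:
            raise ValidationError(f"track {self.name} is empty; cannot sample")
        u = rng.integers(0, total, size=n)
        bounds = np.cumsum(totals)
        out = []
        for x in u:
            ci = int(np.searchsorted(bounds, x, side="right"))
            offset = int(x - (bounds[ci - 1] if ci else 0))
            cum = np.cumsum(lens[ci])
            ii = int(np.searchsorted(cum, offset, side="right"))
            within = offset - (int(cum[ii - 1]) if ii else 0)
            start0 = int(self._starts[chroms[ci]][ii]) + within
            out.append(GenomicPosition(self._display[chroms[ci]], start0 + 1))
        return out


class DepthProfile:
    """Per-position read depth for one sample; query returns 0 if uncovered."""

    def __init__(self, arrays: Mapping[str, tuple[int, np.ndarray]]):
        # arrays: normalized chrom -> (1-based start position, depth vector)
        self._arrays: dict[str, tuple[int, np.ndarray]] = {}
        for chrom, (start, depths) in arrays.items():
            depths = np.asarray(depths, dtype=np.int64)
            if start < 1:
                raise ValidationError("depth profile start must be >= 1")
            if (depths < 0).any():
                raise ValidationError("negative depth in profile")
            self._arrays[normalize_chrom(chrom)] = (start, depths)

    def query(self, chrom: str, pos: int) -> int:
        entry = self._arrays.get(normalize_chrom(chrom))
        if entry is None:
            return 0
        start, depths = entry
        i = pos - start
        if 0 <= i < len(depths):
            return int(depths[i])
        return 0

    def region_set(self) -> dict[str, tuple[int, int]]:
        """chrom -> (start, length) of the assessed region."""
        return {c: (s, len(d)) for c, (s, d) in self._arrays.items()}

    def arrays(self) -> dict[str, tuple[int, np.ndarray]]:
        return dict(self._arrays)


@dataclass
class PileupObservation:
    """One amplicon re-sequencing measurement: sample x position."""

    subject: str
    tissue: Tissue
    position: GenomicPosition
    depth: int
    alt_count: int

    def __post_init__(self):
        if self.depth < 0:
            raise ValidationError(f"negative depth: {self.depth}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValidationError(
                f"alt count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else float("nan")

    @property
    def sample(self) -> tuple[str, str]:
        return (self.subject, self.tissue.value)


def fold_substitution(ref: str, alt: str) -> str:
    """Collapse a substitution to the 6 pyrimidine-context classes.

    Purine-reference changes are complemented, e.g. G>T counts as C>A.
    """
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
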