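"""Confidence tiering of consensus calls from annotation tracks.

The tier of a call depends on three booleans — overlap with a common SNP
(minor allele frequency >= 1%), overlap with a repetitive region, and
non-uniqueness under the 50-mer mappability filter:

* high   — not a SNP, not repetitive, unique;
* low    — on a SNP position, or both repetitive and non-unique;
* medium — not a SNP, and exactly one of {repetitive, non-unique}.

"Medium" as exactly-one-of is the only reading consistent with the other
two definitions over the 8 possible flag combinations.

Rare or unknown-frequency SNPs (the all-SNP track minus the common-SNP
track) never influence the tier; they enter only the stringent
re-assessment flags, together with depth >= 20 in both tissues and a
reference-tissue VAF of exactly zero.
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

from .model import (
    CallSet,
    ConfigurationError,
    SPECTRUM_CLASSES,
    Track,
    VariantCall,
    fold_substitution,
    normalize_chrom,
)

logger = logging.getLogger("polyclone_smc")

REQUIRED_TRACKS = ("common_snp", "repeat", "mappability_unique")


class ConfidenceTier(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


def assign_tier(in_common_snp: bool, in_repeat: bool, non_unique: bool) -> ConfidenceTier:
    """Tier from the three annotation booleans (see module docstring)."""
    if in_common_snp or (in_repeat and non_unique):
        return ConfidenceTier.LOW
    if not in_repeat and not non_unique:
        return ConfidenceTier.HIGH
    return ConfidenceTier.MEDIUM


@dataclass
class StringentFlags:
    depth_ge20_both: bool
    ref_vaf_zero: bool
    not_in_any_snp: bool

    @property
    def passes(self) -> bool:
        return self.depth_ge20_both and self.ref_vaf_zero and self.not_in_any_snp


@dataclass
class AnnotatedCall:
    call: VariantCall
    in_common_snp: bool
    in_repeat: bool
    non_unique: bool
    in_all_snp: bool
    tier: ConfidenceTier
    stringent_flags: StringentFlags

    @property
    def stringent_pass(self) -> bool:
        return self.stringent_flags.passes


def _require_tracks(tracks: Mapping[str, Track], names: Iterable[str]) -> None:
    missing = [n for n in names if n not in tracks]
    if missing:
        raise ConfigurationError(f"missing annotation tracks: {missing}")


def annotate_call(call: VariantCall, tracks: Mapping[str, Track]) -> AnnotatedCall:
    """Overlap a call with the annotation tracks and assign its tier."""
    _require_tracks(tracks, REQUIRED_TRACKS)
    pos = call.position
    in_common = tracks["common_snp"].contains_position(pos)
    in_repeat = tracks["repeat"].contains_position(pos)
    non_unique = not tracks["mappability_unique"].contains_position(pos)
    in_all = tracks["all_snp"].contains_position(pos) if "all_snp" in tracks else in_common

    if call.depth_target is None or call.depth_reference is None:
        logger.warning("%s: unknown depth; stringent depth flag set to False", pos)
        depth_ok = False
    else:
        depth_ok = call.depth_target >= 20 and call.depth_reference >= 20
    if call.vaf_reference is None:
        logger.warning("%s: unknown reference VAF; stringent flag set to False", pos)
        ref_zero = False
    else:
        ref_zero = call.vaf_reference == 0.0

    return AnnotatedCall(
        call=call,
        in_common_snp=in_common,
        in_repeat=in_repeat,
        non_unique=non_unique,
        in_all_snp=in_all,
        tier=assign_tier(in_common, in_repeat, non_unique),
        stringent_flags=StringentFlags(
            depth_ge20_both=depth_ok,
            ref_vaf_zero=ref_zero,
            not_in_any_snp=not in_all,
        ),
    )


def annotate_callset(callset: CallSet, tracks: Mapping[str, Track]) -> list[AnnotatedCall]:
    return [annotate_call(c, tracks) for c in callset.calls]


def stringent_reassess(annotated: AnnotatedCall) -> bool:
    """True iff depth >= 20 in both tissues, reference VAF exactly 0, and the
    position overlaps no dbSNP entry at all (common, rare or unknown)."""
    return annotated.stringent_pass


def tier_counts(annotated: Iterable[AnnotatedCall]) -> dict[ConfidenceTier, int]:
    counts = {t: 0 for t in ConfidenceTier}
    for a in annotated:
        counts[a.tier] += 1
    return counts


@dataclass
class CallSetSummary:
    """Call-set characteristics: substitution spectrum, track overlap, VAF/depth."""

    n_calls: int
    spectrum: dict[str, float]  # fractions over the 6 pyrimidine-context classes
    track_overlap_fraction: dict[str, float]
    median_vaf: Optional[float]
    fraction_depth_ge20_both: Optional[float]
    per_chromosome_counts: dict[str, int]


def summarize(callset: CallSet, tracks: Mapping[str, Track]) -> CallSetSummary:
    """Fig.-2-style summary.  Substitutions are folded to pyrimidine context
    (e.g. G>T counted as C>A); medians are over calls with known values."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for call in callset.calls:
        counts[fold_substitution(call.ref_allele, call.alt_allele)] += 1
    classified = sum(counts.values())
    spectrum = {
        c: (counts[c] / classified if classified else 0.0) for c in SPECTRUM_CLASSES
    }

    overlap = {}
    for name, track in tracks.items():
        hits = sum(track.contains_position(c.position) for c in callset.calls)
        overlap[name] = hits / len(callset) if len(callset) else 0.0

    vafs = [c.vaf_target for c in callset.calls if c.vaf_target is not None]
    depths = [
        c for c in callset.calls
        if c.depth_target is not None and c.depth_reference is not None
    ]
    frac20 = (
        sum(c.depth_target >= 20 and c.depth_reference >= 20 for c in depths) / len(depths)
        if depths else None
    )
    per_chrom: dict[str, int] = {}
    for call in callset.calls:
        key = normalize_chrom(call.position.chrom)
        per_chrom[key] = per_chrom.get(key, 0) + 1

    return CallSetSummary(
        n_calls=len(callset),
        spectrum=spectrum,
        track_overlap_fraction=overlap,
        median_vaf=statistics.median(vafs) if vafs else None,
        fraction_depth_ge20_both=frac20,
        per_chromosome_counts=per_chrom,
    )
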