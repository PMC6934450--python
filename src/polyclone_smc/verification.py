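"""Amplicon verification: candidate selection, the VAF decision matrix,
cross-sample adjudication, outcome categories, and extrapolation of the
confirmed count to a genome-wide false-positive estimate.

The VAF decision matrix for ultra-deep pileups classifies each sample at
each candidate position: VAF below 1% supports the reference allele; 20–80%
suggests a heterozygous and over 80% a homozygous variant position; 5–20%
at good coverage (>1000 reads) suggests subclonal presence of the variant.
Everything else (1–5%, or 5–20% at suboptimal coverage) is indeterminate
and is adjudicated against the same position in the other samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from statistics import median
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .confidence import AnnotatedCall, ConfidenceTier
from .model import (
    FunctionalClass,
    PileupObservation,
    Tissue,
    ValidationError,
    normalize_chrom,
)

logger = logging.getLogger("polyclone_smc")

FORCED_CLASSES = {FunctionalClass.NONSYNONYMOUS, FunctionalClass.SPLICE_SITE}


class VafClass(str, Enum):
    REFERENCE = "reference"
    SUBCLONAL = "subclonal"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    INDETERMINATE = "indeterminate"
    NO_DATA = "no_data"  # depth 0; distinct from indeterminate

    @property
    def is_variant(self) -> bool:
        return self in (VafClass.SUBCLONAL, VafClass.HETEROZYGOUS, VafClass.HOMOZYGOUS)


@dataclass(frozen=True)
class VafBoundaries:
    """Decision-matrix boundaries; the defaults are the normative reading:
    left-closed subclonal and heterozygous intervals, strict > for
    homozygous and for good coverage."""

    reference_max: float = 0.01     # vaf <  this  -> reference
    subclonal_min: float = 0.05     # vaf >= this (with good coverage) -> subclonal
    heterozygous_min: float = 0.20  # this <= vaf <= heterozygous_max -> het
    heterozygous_max: float = 0.80  # vaf >  this  -> homozygous


DEFAULT_BOUNDARIES = VafBoundaries()


def classify_vaf(
    observation: PileupObservation,
    good_coverage: int = 1000,
    boundaries: VafBoundaries = DEFAULT_BOUNDARIES,
) -> VafClass:
    """Classify one pileup observation with the VAF decision matrix."""
    if observation.depth == 0:
        return VafClass.NO_DATA
    vaf = observation.vaf
    b = boundaries
    if vaf < b.reference_max:
        return VafClass.REFERENCE
    if b.heterozygous_min <= vaf <= b.heterozygous_max:
        return VafClass.HETEROZYGOUS
    if vaf > b.heterozygous_max:
        return VafClass.HOMOZYGOUS
    if b.subclonal_min <= vaf < b.heterozygous_min and observation.depth > good_coverage:
        return VafClass.SUBCLONAL
    return VafClass.INDETERMINATE


@dataclass
class AdjudicationResult:
    """Per-sample classes at one position, with indeterminates resolved."""

    classes: dict[tuple[str, str], VafClass]
    resolutions: list[dict]          # evidence used for each resolved call
    unresolved: set[tuple[str, str]] # single-sample positions, flagged unclear


def adjudicate(
    observations: Sequence[PileupObservation],
    good_coverage: int = 1000,
    boundaries: VafBoundaries = DEFAULT_BOUNDARIES,
    background_multiplier: float = 2.0,
    background_floor: float = 0.01,
) -> AdjudicationResult:
    """Resolve indeterminate classes against the other samples.

    For an indeterminate observation, let b be the median VAF across all
    other samples at the position: a VAF <= max(background_multiplier * b,
    background_floor) is shared background and resolves to reference,
    anything higher is a sample-elevated (subclonal) signal.  Positions
    observed in a single sample cannot be adjudicated and stay flagged.
    """
    keys = {o.position.key for o in observations}
    if len(keys) > 1:
        raise ValidationError(f"adjudicate expects one position, got {keys}")
    classes: dict[tuple[str, str], VafClass] = {}
    resolutions: list[dict] = []
    unresolved: set[tuple[str, str]] = set()
    initial = {o.sample: classify_vaf(o, good_coverage, boundaries) for o in observations}
    by_sample = {o.sample: o for o in observations}
    for sample, cls in initial.items():
        if cls is not VafClass.INDETERMINATE:
            classes[sample] = cls
            continue
        others = [
            by_sample[s].vaf
            for s in by_sample
            if s != sample and by_sample[s].depth > 0
        ]
        if not others:
            classes[sample] = VafClass.INDETERMINATE
            unresolved.add(sample)
            logger.warning(
                "position %s observed in a single sample: indeterminate stands",
                by_sample[sample].position,
            )
            continue
        background = median(others)
        cutoff = max(background_multiplier * background, background_floor)
        vaf = by_sample[sample].vaf
        resolved = VafClass.REFERENCE if vaf <= cutoff else VafClass.SUBCLONAL
        classes[sample] = resolved
        resolutions.append(
            {
                "sample": sample,
                "vaf": vaf,
                "background_median": background,
                "cutoff": cutoff,
                "resolved_to": resolved.value,
            }
        )
    return AdjudicationResult(classes=classes, resolutions=resolutions, unresolved=unresolved)


class VerificationOutcome(str, Enum):
    CONFIRMED_SOMATIC = "confirmed_somatic"
    SUBCLONAL_SHARED = "subclonal_shared"
    GERMLINE_POLYMORPHISM = "germline_polymorphism"
    UNCLEAR = "unclear"
    ABSENT = "absent"


@dataclass
class OutcomeRecord:
    outcome: VerificationOutcome
    subject_specific: bool


def assign_outcome(
    classes_by_sample: Mapping[tuple[str, str], VafClass],
    target_subject: str,
    target_tissue: Tissue = Tissue.LOWER_LOBE,
    reference_tissue: Tissue = Tissue.BLOOD,
) -> OutcomeRecord:
    """Assign the verification outcome category for one candidate.

    A call is confirmed somatic only when the target subject's sampled
    tissue shows the variant subclonally, its reference tissue supports the
    reference allele, and no sample of any other subject shows the variant
    (subject-specific) — the strictest reading of "clearly higher VAF in
    the sampled tissue than in blood".
    """
    brush = classes_by_sample.get((target_subject, target_tissue.value))
    blood = classes_by_sample.get((target_subject, reference_tissue.value))
    other_variant = any(
        cls.is_variant
        for (subject, _), cls in classes_by_sample.items()
        if subject != target_subject
    )
    subject_specific = not other_variant

    undecided = (VafClass.INDETERMINATE, VafClass.NO_DATA, None)
    if brush in undecided or blood in undecided:
        return OutcomeRecord(VerificationOutcome.UNCLEAR, subject_specific)
    if brush is VafClass.REFERENCE and blood is VafClass.REFERENCE:
        return OutcomeRecord(VerificationOutcome.ABSENT, subject_specific)
    if brush in (VafClass.HETEROZYGOUS, VafClass.HOMOZYGOUS) and blood in (
        VafClass.HETEROZYGOUS,
        VafClass.HOMOZYGOUS,
    ):
        return OutcomeRecord(VerificationOutcome.GERMLINE_POLYMORPHISM, subject_specific)
    if (
        brush is VafClass.SUBCLONAL
        and blood is VafClass.REFERENCE
        and subject_specific
    ):
        return OutcomeRecord(VerificationOutcome.CONFIRMED_SOMATIC, True)
    # variant present in both target tissues, shared across subjects, or an
    # out-of-matrix pattern (e.g. heterozygous in one tissue only)
    return OutcomeRecord(VerificationOutcome.SUBCLONAL_SHARED, subject_specific)


# ---------------------------------------------------------------------------
# candidate selection


@dataclass
class CandidateSet:
    by_tier: dict[ConfidenceTier, list[AnnotatedCall]]
    seed: Optional[int]
    report: dict

    def all_candidates(self) -> list[AnnotatedCall]:
        return [a for tier in ConfidenceTier for a in self.by_tier.get(tier, [])]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_tier.values())


def select_candidates(
    annotated_calls: Sequence[AnnotatedCall],
    n_per_tier: int = 30,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CandidateSet:
    """Constrained random selection of verification candidates.

    Per confidence tier, up to ``n_per_tier`` calls are chosen: first every
    call with a non-synonymous or splice-site consequence (forced), then one
    random call for each subject not yet represented (greedy repair, subjects
    in sorted order, placed in its own tier's quota), then uniform sampling
    without replacement.  Y-chromosome calls are never considered.
    Deterministic under ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    warnings: list[str] = []

    excluded_y = [a for a in annotated_calls if normalize_chrom(a.call.position.chrom) == "Y"]
    eligible = [a for a in annotated_calls if normalize_chrom(a.call.position.chrom) != "Y"]

    all_subjects = {a.call.subject for a in annotated_calls}
    eligible_subjects = {a.call.subject for a in eligible}
    for subject in sorted(all_subjects - eligible_subjects):
        warnings.append(f"subject {subject} has only chrY calls; cannot be represented")
        logger.warning("subject %s has only chrY calls; constraint unsatisfiable", subject)

    by_tier: dict[ConfidenceTier, list[AnnotatedCall]] = {t: [] for t in ConfidenceTier}
    for a in eligible:
        by_tier[a.tier].append(a)
    for tier in by_tier:  # deterministic base order
        by_tier[tier].sort(key=lambda a: (a.call.subject, a.call.position.sort_key))

    selected: dict[ConfidenceTier, list[AnnotatedCall]] = {t: [] for t in ConfidenceTier}
    chosen_ids: set[int] = set()

    def take(a: AnnotatedCall) -> None:
        selected[a.tier].append(a)
        chosen_ids.add(id(a))

    forced = [a for a in eligible if a.call.functional_class in FORCED_CLASSES]
    for a in forced:
        if len(selected[a.tier]) >= n_per_tier:
            warnings.append(f"forced call {a.call.position} overflows tier {a.tier.value} quota")
        take(a)

    covered = {a.call.subject for t in selected.values() for a in t}
    for subject in sorted(eligible_subjects):
        if subject in covered:
            continue
        pool = [a for a in eligible if a.call.subject == subject and id(a) not in chosen_ids]
        pick = pool[int(rng.integers(0, len(pool)))]
        take(pick)
        covered.add(subject)

    for tier in ConfidenceTier:
        remaining = [a for a in by_tier[tier] if id(a) not in chosen_ids]
        need = n_per_tier - len(selected[tier])
        if need <= 0:
            continue
        if len(remaining) <= need:
            if len(remaining) < need:
                warnings.append(
                    f"tier {tier.value}: only {len(selected[tier]) + len(remaining)} "
                    f"eligible calls for quota {n_per_tier}; selecting all"
                )
                logger.warning("%s", warnings[-1])
            for a in remaining:
                take(a)
        else:
            idx = rng.choice(len(remaining), size=need, replace=False)
            for i in sorted(int(x) for x in idx):
                take(remaining[i])

    for tier in ConfidenceTier:
        selected[tier].sort(key=lambda a: (a.call.subject, a.call.position.sort_key))

    per_subject: dict[str, int] = {}
    for tier_calls in selected.values():
        for a in tier_calls:
            per_subject[a.call.subject] = per_subject.get(a.call.subject, 0) + 1

    return CandidateSet(
        by_tier=selected,
        seed=seed,
        report={
            "n_forced": len(forced),
            "n_excluded_chry": len(excluded_y),
            "per_subject": per_subject,
            "warnings": warnings,
        },
    )


# ---------------------------------------------------------------------------
# outcome tables and extrapolation


def outcome_table(
    outcomes_by_tier: Mapping[ConfidenceTier, Sequence[VerificationOutcome]],
) -> pd.DataFrame:
    """Contingency table: outcome categories (rows) x confidence tiers
    (columns); column sums equal the tested counts."""
    data = {}
    for tier in ConfidenceTier:
        outcomes = list(outcomes_by_tier.get(tier, []))
        data[tier.value] = {
            o.value: sum(1 for x in outcomes if x is o) for o in VerificationOutcome
        }
    df = pd.DataFrame(data)
    df.index.name = "outcome"
    return df


def outcome_proportions(
    outcomes_by_tier: Mapping[ConfidenceTier, Sequence[VerificationOutcome]],
    outcome: VerificationOutcome,
) -> dict[ConfidenceTier, float]:
    """Per-tier percentage of tested candidates with the given outcome."""
    out = {}
    for tier, outcomes in outcomes_by_tier.items():
        outcomes = list(outcomes)
        if outcomes:
            out[tier] = 100.0 * sum(1 for x in outcomes if x is outcome) / len(outcomes)
    return out


@dataclass
class TierExtrapolation:
    tested: int
    confirmed: int
    tier_total: int
    estimated_true: float


@dataclass
class ExtrapolationResult:
    per_tier: dict[ConfidenceTier, TierExtrapolation]

    @property
    def estimated_true_total(self) -> float:
        return sum(t.estimated_true for t in self.per_tier.values())

    @property
    def total_calls(self) -> int:
        return sum(t.tier_total for t in self.per_tier.values())

    @property
    def estimated_fp_fraction(self) -> float:
        return 1.0 - self.estimated_true_total / self.total_calls


def extrapolate(
    confirmed_by_tier: Mapping[ConfidenceTier, int],
    tested_by_tier: Mapping[ConfidenceTier, int],
    tier_totals: Mapping[ConfidenceTier, int],
) -> ExtrapolationResult:
    """Scale each tier's confirmed fraction to the tier's total call count.

    estimated_true(tier) = confirmed/tested * total; the overall
    false-positive fraction is 1 - estimated_true_total / sum(totals).
    """
    per_tier = {}
    for tier in ConfidenceTier:
        total = int(tier_totals.get(tier, 0))
        tested = int(tested_by_tier.get(tier, 0))
        confirmed = int(confirmed_by_tier.get(tier, 0))
        if confirmed > tested:
            raise ValidationError(f"tier {tier.value}: confirmed > tested")
        if total > 0 and tested == 0:
            raise ValidationError(
                f"tier {tier.value}: {total} calls but none tested; estimate undefined"
            )
        estimated = (confirmed / tested * total) if tested > 0 else 0.0
        per_tier[tier] = TierExtrapolation(
            tested=tested, confirmed=confirmed, tier_total=total, estimated_true=estimated
        )
    result = ExtrapolationResult(per_tier=per_tier)
    if result.total_calls == 0:
        raise ValidationError("no calls in any tier; extrapolation undefined")
    return result
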