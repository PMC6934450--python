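"""Multi-caller consensus building, concordance, and truth-set evaluation.

Calls are matched on genomic position only (normalized chromosome + 1-based
position), not on alleles: precision and recall against a truth set and the
Dice concordance are position-based.  An optional strict allele-matching
mode exists but is off by default.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import CallSet, GenomicPosition, ValidationError, VariantCall

logger = logging.getLogger("polyclone_smc")

Key = tuple

CONSENSUS_CALLER = "consensus"


def _keys(callset: CallSet, match_alleles: bool) -> set:
    if match_alleles:
        return {(c.key, c.ref_allele, c.alt_allele) for c in callset.calls}
    return callset.position_keys()


@dataclass
class ConsensusResult:
    """Outcome of combining per-caller call sets."""

    strategy: str
    k: Optional[int]
    calls: CallSet
    per_caller_counts: dict[str, int]
    venn_counts: dict[frozenset, int]  # exactly-these-callers partition

    @property
    def union_size(self) -> int:
        return sum(self.venn_counts.values())


def combine(
    callsets: Sequence[CallSet],
    strategy: str = "intersection",
    k: Optional[int] = None,
    reporting_caller: Optional[str] = None,
    match_alleles: bool = False,
) -> ConsensusResult:
    """Combine >= 2 call sets of one subject x tissue.

    strategy: "intersection" (all callers), "union", or "k_of_n" with ``k``.
    Attributes of a consensus call (VAF, depths) are taken from the
    ``reporting_caller``; by default the caller with the fewest calls, i.e.
    the most restrictive one.
    """
    if len(callsets) < 2:
        raise ValidationError("need at least two call sets to combine")
    subjects = {cs.subject for cs in callsets}
    tissues = {cs.tissue for cs in callsets}
    if len(subjects) != 1 or len(tissues) != 1:
        raise ValidationError(
            f"call sets must share subject and tissue, got {subjects} x {tissues}"
        )
    if strategy == "k_of_n":
        if k is None or not (1 <= k <= len(callsets)):
            raise ValidationError(f"k_of_n requires 1 <= k <= {len(callsets)}")
        need = k
    elif strategy == "intersection":
        need = len(callsets)
    elif strategy == "union":
        need = 1
    else:
        raise ValidationError(f"unknown strategy: {strategy}")

    keysets = [(i, cs.caller, _keys(cs, match_alleles)) for i, cs in enumerate(callsets)]
    membership: dict = {}  # key -> set of call-set indices (robust to repeated names)
    for i, _, keys in keysets:
        for key in keys:
            membership.setdefault(key, set()).add(i)

    venn: dict[frozenset, int] = {}
    for key, members in membership.items():
        names = frozenset(callsets[i].caller for i in members)
        venn[names] = venn.get(names, 0) + 1

    selected = {key for key, members in membership.items() if len(members) >= need}

    if reporting_caller is None:
        reporting_caller = min(callsets, key=lambda cs: len(cs)).caller
    by_priority = sorted(callsets, key=lambda cs: cs.caller != reporting_caller)
    chosen: dict = {}
    for cs in by_priority:
        for call in cs.calls:
            key = (call.key, call.ref_allele, call.alt_allele) if match_alleles else call.key
            if key in selected and key not in chosen:
                chosen[key] = call

    consensus_calls = [
        VariantCall(
            position=c.position,
            ref_allele=c.ref_allele,
            alt_allele=c.alt_allele,
            caller=CONSENSUS_CALLER,
            subject=c.subject,
            tissue=c.tissue,
            vaf_target=c.vaf_target,
            vaf_reference=c.vaf_reference,
            depth_target=c.depth_target,
            depth_reference=c.depth_reference,
            functional_class=c.functional_class,
        )
        for c in chosen.values()
    ]
    result_set = CallSet.build(
        callsets[0].subject, callsets[0].tissue, CONSENSUS_CALLER, consensus_calls
    )
    return ConsensusResult(
        strategy=strategy,
        k=need if strategy == "k_of_n" else None,
        calls=result_set,
        per_caller_counts={cs.caller: len(cs) for cs in callsets},
        venn_counts=venn,
    )


def dice(callset_a: CallSet, callset_b: CallSet) -> float:
    """Dice similarity S = 2*C / (N1 + N2) on position-matched calls.

    Returns NaN (with a logged warning) when both sets are empty.
    """
    a, b = callset_a.position_keys(), callset_b.position_keys()
    if not a and not b:
        logger.warning("dice undefined for two empty call sets; returning NaN")
        return math.nan
    return 2.0 * len(a & b) / (len(a) + len(b))


TruthLike = Union[CallSet, Iterable]


def _truth_keys(truth: TruthLike) -> set:
    if isinstance(truth, CallSet):
        return truth.position_keys()
    keys = set()
    for item in truth:
        if isinstance(item, GenomicPosition):
            keys.add(item.key)
        elif isinstance(item, tuple) and len(item) == 2:
            keys.add(GenomicPosition(str(item[0]), int(item[1])).key)
        else:
            raise ValidationError(f"cannot interpret truth item: {item!r}")
    return keys


@dataclass
class EvaluationResult:
    """Position-based precision/recall against a curated truth set."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float


def evaluate(callset: CallSet, truth: TruthLike) -> EvaluationResult:
    """Score a call set against truth positions (mutation type ignored)."""
    truth_keys = _truth_keys(truth)
    calls = callset.position_keys()
    tp = len(calls & truth_keys)
    fp = len(calls - truth_keys)
    fn = len(truth_keys - calls)
    if tp + fp == 0:
        logger.warning("empty call set: precision reported as 0 by convention")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return EvaluationResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
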