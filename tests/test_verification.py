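"""VAF decision matrix, adjudication, outcome categories, candidate
selection, and extrapolation."""
import numpy as np
import pytest

from polyclone_smc.confidence import ConfidenceTier
from polyclone_smc.model import (
    FunctionalClass,
    GenomicPosition,
    PileupObservation,
    Tissue,
    ValidationError,
)
from polyclone_smc.simulate import (
    Clone,
    CloneMixture,
    GermlineVariant,
    SimulationConfig,
    SomaticMutation,
    simulate_pileups,
)
from polyclone_smc.verification import (
    VafClass,
    VerificationOutcome,
    adjudicate,
    assign_outcome,
    classify_vaf,
    extrapolate,
    outcome_table,
    select_candidates,
)

from conftest import build_tiered_calls, make_annotated


def obs(vaf, depth, subject="S01", tissue=Tissue.LOWER_LOBE, pos=100):
    return PileupObservation(
        subject=subject,
        tissue=tissue,
        position=GenomicPosition("chr1", pos),
        depth=depth,
        alt_count=int(round(vaf * depth)),
    )


class TestClassifyVaf:
    @pytest.mark.parametrize(
        "vaf,depth,expected",
        [
            (0.5, 5000, VafClass.HETEROZYGOUS),
            (0.004, 20000, VafClass.REFERENCE),
            (0.10, 2000, VafClass.SUBCLONAL),
            (0.10, 300, VafClass.INDETERMINATE),   # suboptimal coverage
            (0.03, 20000, VafClass.INDETERMINATE),  # the 1-5% band
            (0.95, 20000, VafClass.HOMOZYGOUS),
        ],
    )
    def test_decision_matrix(self, vaf, depth, expected):
        assert classify_vaf(obs(vaf, depth)) is expected

    @pytest.mark.parametrize(
        "vaf,depth,expected",
        [
            (0.01, 100_000, VafClass.INDETERMINATE),  # exactly 1%: no longer reference
            (0.05, 100_000, VafClass.SUBCLONAL),      # subclonal is left-closed
            (0.20, 100_000, VafClass.HETEROZYGOUS),   # het is left-closed
            (0.80, 100_000, VafClass.HETEROZYGOUS),   # het is right-closed
            (0.10, 1000, VafClass.INDETERMINATE),     # good coverage is strictly >1000
            (0.10, 1001, VafClass.SUBCLONAL),
        ],
    )
    def test_boundary_values(self, vaf, depth, expected):
        assert classify_vaf(obs(vaf, depth)) is expected

    def test_partition_is_total_on_grid(self):
        """Every (vaf, depth>0) pair maps to exactly one of the five classes."""
        vafs = [0.0, 0.005, 0.01, 0.03, 0.05, 0.10, 0.19, 0.20, 0.5, 0.80, 0.81, 1.0]
        real_classes = {c for c in VafClass if c is not VafClass.NO_DATA}
        for vaf in vafs:
            for depth in (200, 1000, 1001, 100_000):
                assert classify_vaf(obs(vaf, depth)) in real_classes

    def test_zero_depth_is_distinct_no_data(self):
        assert classify_vaf(obs(0.0, 0)) is VafClass.NO_DATA


class TestAdjudicate:
    def test_shared_background_resolves_to_reference(self):
        samples = [obs(0.03, 10_000, subject=f"S{i:02d}") for i in range(6)]
        result = adjudicate(samples)
        assert all(c is VafClass.REFERENCE for c in result.classes.values())
        assert result.resolutions

    def test_sample_elevated_signal_resolves_to_subclonal(self):
        others = [obs(0.001, 10_000, subject=f"S{i:02d}") for i in range(2, 7)]
        target = obs(0.03, 10_000, subject="S01")
        result = adjudicate([target] + others)
        assert result.classes[("S01", "lower_lobe")] is VafClass.SUBCLONAL
        for other in others:
            assert result.classes[other.sample] is VafClass.REFERENCE

    def test_single_sample_position_stays_flagged(self, caplog):
        result = adjudicate([obs(0.03, 10_000)])
        assert result.classes[("S01", "lower_lobe")] is VafClass.INDETERMINATE
        assert result.unresolved == {("S01", "lower_lobe")}

    def test_mixed_positions_rejected(self):
        with pytest.raises(ValidationError):
            adjudicate([obs(0.1, 2000, pos=1), obs(0.1, 2000, pos=2, subject="S02")])


def classes(brush, blood, others=(), target="S01"):
    mapping = {
        (target, "lower_lobe"): brush,
        (target, "blood"): blood,
    }
    for i, cls in enumerate(others):
        mapping[(f"Z{i:02d}", "lower_lobe")] = cls
        mapping[(f"Z{i:02d}", "blood")] = VafClass.REFERENCE
    return mapping


class TestAssignOutcome:
    R, S, H = VafClass.REFERENCE, VafClass.SUBCLONAL, VafClass.HETEROZYGOUS

    def test_subject_specific_subclonal_is_confirmed(self):
        record = assign_outcome(classes(self.S, self.R, [self.R, self.R]), "S01")
        assert record.outcome is VerificationOutcome.CONFIRMED_SOMATIC
        assert record.subject_specific

    def test_het_in_both_tissues_is_germline(self):
        record = assign_outcome(classes(self.H, self.H), "S01")
        assert record.outcome is VerificationOutcome.GERMLINE_POLYMORPHISM

    def test_subclonal_in_both_tissues_is_shared(self):
        record = assign_outcome(classes(self.S, self.S), "S01")
        assert record.outcome is VerificationOutcome.SUBCLONAL_SHARED

    def test_reference_in_both_tissues_is_absent(self):
        record = assign_outcome(classes(self.R, self.R), "S01")
        assert record.outcome is VerificationOutcome.ABSENT

    def test_variant_in_other_subject_blocks_confirmation(self):
        record = assign_outcome(classes(self.S, self.R, [self.S]), "S01")
        assert record.outcome is VerificationOutcome.SUBCLONAL_SHARED
        assert not record.subject_specific

    def test_missing_or_undecided_target_data_is_unclear(self):
        assert assign_outcome(classes(self.S, VafClass.NO_DATA), "S01").outcome \
            is VerificationOutcome.UNCLEAR
        assert assign_outcome({("S01", "lower_lobe"): self.S}, "S01").outcome \
            is VerificationOutcome.UNCLEAR

    def test_outcome_is_total_and_single_valued(self):
        """Any combination of classified target tissues yields exactly one outcome."""
        for brush in VafClass:
            for blood in VafClass:
                for other in ([], [self.S]):
                    record = assign_outcome(classes(brush, blood, other), "S01")
                    assert record.outcome in VerificationOutcome


annotated = make_annotated


class TestSelectCandidates:
    def test_constraints_hold_across_seeds(self):
        calls = build_tiered_calls()
        forced_keys = {
            a.call.key for a in calls
            if a.call.functional_class in (FunctionalClass.NONSYNONYMOUS,
                                           FunctionalClass.SPLICE_SITE)
        }
        for seed in range(10):
            selection = select_candidates(calls, n_per_tier=30, seed=seed)
            chosen = selection.all_candidates()
            assert len(chosen) == 90
            assert all(len(v) == 30 for v in selection.by_tier.values())
            keys = {a.call.key for a in chosen}
            assert forced_keys <= keys
            assert {a.call.subject for a in chosen} == {f"S{i + 1:02d}" for i in range(12)}
            assert all(a.call.position.chrom != "chrY" for a in chosen)

    def test_deterministic_under_seed(self):
        calls = build_tiered_calls()
        a = select_candidates(calls, seed=42)
        b = select_candidates(calls, seed=42)
        assert [x.call.key for x in a.all_candidates()] == \
            [x.call.key for x in b.all_candidates()]
        c = select_candidates(calls, seed=43)
        assert [x.call.key for x in a.all_candidates()] != \
            [x.call.key for x in c.all_candidates()]

    def test_tier_with_exactly_quota_selected_entirely(self):
        calls = [annotated("S01", "chr1", 100 + i * 7, ConfidenceTier.HIGH)
                 for i in range(30)]
        for seed in (0, 1, 2):
            selection = select_candidates(calls, n_per_tier=30, seed=seed)
            assert len(selection.by_tier[ConfidenceTier.HIGH]) == 30

    def test_small_tier_selects_all_with_warning(self):
        calls = [annotated("S01", "chr1", 100 + i * 7, ConfidenceTier.HIGH)
                 for i in range(5)]
        selection = select_candidates(calls, n_per_tier=30, seed=0)
        assert len(selection.by_tier[ConfidenceTier.HIGH]) == 5
        assert any("quota" in w for w in selection.report["warnings"])

    def test_subject_with_only_y_calls_warned(self):
        calls = build_tiered_calls(n_subjects=11)
        calls.append(annotated("S12", "chrY", 99999, ConfidenceTier.LOW))
        selection = select_candidates(calls, seed=0)
        assert any("S12" in w for w in selection.report["warnings"])
        assert all(a.call.subject != "S12" for a in selection.all_candidates())


class TestExtrapolate:
    TIERS = list(ConfidenceTier)

    def by_tier(self, high, medium, low):
        return dict(zip(self.TIERS, (high, medium, low)))

    def test_reported_verification_outcome_scales_to_fp_over_99_percent(self):
        result = extrapolate(
            confirmed_by_tier=self.by_tier(1, 0, 0),
            tested_by_tier=self.by_tier(28, 29, 28),
            tier_totals=self.by_tier(156, 711, 784),
        )
        assert result.estimated_true_total == pytest.approx(156 / 28, rel=1e-9)
        assert result.total_calls == 1651
        assert result.estimated_fp_fraction > 0.99

    def test_all_confirmed_gives_zero_fp_fraction(self):
        result = extrapolate(self.by_tier(10, 10, 10), self.by_tier(10, 10, 10),
                             self.by_tier(100, 100, 100))
        assert result.estimated_fp_fraction == pytest.approx(0.0)

    def test_none_confirmed_gives_fp_fraction_one(self):
        result = extrapolate(self.by_tier(0, 0, 0), self.by_tier(10, 10, 10),
                             self.by_tier(100, 100, 100))
        assert result.estimated_fp_fraction == pytest.approx(1.0)

    def test_scale_equivariance(self):
        base = extrapolate(self.by_tier(1, 2, 0), self.by_tier(10, 20, 10),
                           self.by_tier(100, 200, 50))
        doubled = extrapolate(self.by_tier(1, 2, 0), self.by_tier(10, 20, 10),
                              self.by_tier(200, 400, 100))
        assert doubled.estimated_true_total == pytest.approx(2 * base.estimated_true_total)
        assert doubled.estimated_fp_fraction == pytest.approx(base.estimated_fp_fraction)

    def test_untested_nonempty_tier_is_error(self):
        with pytest.raises(ValidationError):
            extrapolate(self.by_tier(0, 0, 0), self.by_tier(0, 10, 10),
                        self.by_tier(100, 100, 100))


class TestOutcomeTable:
    def test_column_sums_equal_tested_counts(self):
        outcomes = {
            ConfidenceTier.HIGH: [VerificationOutcome.ABSENT] * 3
            + [VerificationOutcome.CONFIRMED_SOMATIC],
            ConfidenceTier.MEDIUM: [VerificationOutcome.UNCLEAR] * 2,
            ConfidenceTier.LOW: [],
        }
        table = outcome_table(outcomes)
        assert table["high"].sum() == 4
        assert table["medium"].sum() == 2
        assert table["low"].sum() == 0
        assert table.loc["confirmed_somatic", "high"] == 1


class TestEndToEndRecovery:
    """Planted truth is recovered through pileups -> classes -> outcomes."""

    def build_cohort(self, clone_fraction):
        config = SimulationConfig(genome_length=100_000, pileup_depth_mean=10_000,
                                  seed=0)
        germline = [GermlineVariant(GenomicPosition("chr1", 10 + i), "A", "G", "het")
                    for i in range(10)]
        somatic = [SomaticMutation(GenomicPosition("chr1", 5000 + i * 17), "A", "C")
                   for i in range(10)]
        clean = [GenomicPosition("chr1", 90_000 + i * 13) for i in range(10)]
        target = CloneMixture(
            "S01", [Clone(clone_fraction, somatic)], germline=germline,
            infiltrate_fraction=1.0 - clone_fraction,
        )
        others = {f"S{i:02d}": CloneMixture(f"S{i:02d}", [], infiltrate_fraction=1.0)
                  for i in range(2, 5)}
        mixtures = {"S01": target, **others}
        return config, mixtures, germline, somatic, clean

    def run_outcomes(self, positions, mixtures, config, seed):
        rng = np.random.default_rng(seed)
        pileups = simulate_pileups(mixtures, positions, config, rng)
        by_pos = {}
        for o in pileups:
            by_pos.setdefault(o.position.key, []).append(o)
        return {
            key: assign_outcome(adjudicate(group).classes, "S01")
            for key, group in by_pos.items()
        }

    def test_planted_candidates_recovered(self):
        config, mixtures, germline, somatic, clean = self.build_cohort(0.2)
        outcomes = {}
        for seed in range(3):
            outcomes.update(
                {(seed, k): v for k, v in self.run_outcomes(
                    [g.position for g in germline]
                    + [m.position for m in somatic] + clean,
                    mixtures, config, seed,
                ).items()}
            )
        germ_keys = {g.position.key for g in germline}
        som_keys = {m.position.key for m in somatic}
        clean_keys = {p.key for p in clean}
        germ = [v for (s, k), v in outcomes.items() if k in germ_keys]
        som = [v for (s, k), v in outcomes.items() if k in som_keys]
        absent = [v for (s, k), v in outcomes.items() if k in clean_keys]
        frac = lambda records, outcome: (
            sum(r.outcome is outcome for r in records) / len(records)
        )
        assert frac(germ, VerificationOutcome.GERMLINE_POLYMORPHISM) >= 0.95
        assert frac(som, VerificationOutcome.CONFIRMED_SOMATIC) >= 0.90
        assert frac(absent, VerificationOutcome.ABSENT) == 1.0
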