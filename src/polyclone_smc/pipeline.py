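"""End-to-end orchestration: simulate -> per-caller calls -> consensus ->
annotate/tier -> burden metrics -> candidate selection -> amplicon
verification -> extrapolation, from a single declarative config, with a
manifest recording counts, checksums and the effective configuration.

Two built-in regimes bracket the biology:

* ``brushing`` — many small clones (symmetric Dirichlet over ~200 clones),
  every clone far below the VAF detection limit.  The consensus set is then
  dominated by shared artifacts, verification confirms essentially nothing,
  and the extrapolated false-positive fraction approaches 1.
* ``cancer``   — one dominant clone, the situation the intersection
  strategy was validated on: high recall and precision against truth.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .burden import burden, imd, rainfall_table, smc_power
from .confidence import ConfidenceTier, annotate_callset, tier_counts
from .consensus import combine, evaluate
from .io import (
    write_bed_track,
    write_depth_profile,
    write_pileups,
    write_truth_positions,
    write_vcf,
)
from .model import GenomicPosition, ValidationError
from .simulate import (
    CallerProfile,
    SimulationConfig,
    brushing_clone_fractions,
    cancer_clone_fractions,
    default_caller_profiles,
    emulate_caller,
    sample_observations,
    simulate_depth_profile,
    simulate_mixture,
    simulate_pileups,
    simulate_tracks,
)
from .verification import (
    adjudicate,
    assign_outcome,
    extrapolate,
    outcome_table,
    select_candidates,
    VerificationOutcome,
)

logger = logging.getLogger("polyclone_smc")


@dataclass
class RunConfig:
    """Declarative configuration of one full analysis run."""

    seed: int
    outdir: str = "polyclone_smc_run"
    regime: str = "brushing"  # "brushing" | "cancer"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    callers: list[CallerProfile] = field(default_factory=default_caller_profiles)
    consensus_strategy: str = "intersection"
    consensus_k: Optional[int] = None
    n_per_tier: int = 30
    good_coverage: int = 1000
    power_threshold: int = 10
    # regime parameters
    n_clones: int = 200
    mutations_per_clone: int = 10
    dominant_clone_fraction: float = 0.9
    cancer_mutations: int = 50
    infiltrate_fraction: float = 0.1
    # output toggles
    write_vcfs: bool = True
    write_depth_profiles: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        callers = [CallerProfile(**c) for c in raw.pop("callers", [])] or default_caller_profiles()
        return cls(sim=sim, callers=callers, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _clone_fractions(config: RunConfig, rng: np.random.Generator) -> tuple[list[float], int]:
    if config.regime == "brushing":
        fractions = brushing_clone_fractions(
            rng, n_clones=config.n_clones, infiltrate_fraction=config.infiltrate_fraction
        )
        return fractions, config.mutations_per_clone
    if config.regime == "cancer":
        return cancer_clone_fractions(config.dominant_clone_fraction), config.cancer_mutations
    raise ValidationError(f"unknown regime: {config.regime}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON).

    On a fatal stage error, a partial manifest naming the failed stage is
    written to the output directory and a :class:`StageError` is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict = {}
    stage = "setup"
    try:
        return _run(config, outdir, stage_counts, lambda s: stage_counts.setdefault("_stage_order", []).append(s) or s)
    except Exception as exc:
        stage = (stage_counts.get("_stage_order") or ["setup"])[-1]
        partial = {
            "version": __version__,
            "failed_stage": stage,
            "error": str(exc),
            "stage_counts": {k: v for k, v in stage_counts.items() if k != "_stage_order"},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(partial, indent=2, sort_keys=True, default=str) + "\n"
        )
        raise StageError(stage, exc) from exc


def _run(config: RunConfig, outdir: Path, stage_counts: dict, enter_stage) -> dict:
    sim = dataclasses.replace(config.sim, seed=config.seed)
    root = np.random.SeedSequence(config.seed)
    (ss_tracks, ss_subjects, ss_select, ss_pileups) = root.spawn(4)

    files: list[Path] = []

    # --- tracks -----------------------------------------------------------
    enter_stage("tracks")
    tracks = simulate_tracks(sim, np.random.default_rng(ss_tracks))
    for name, track in tracks.items():
        path = outdir / f"track_{name}.bed"
        write_bed_track(track, path)
        files.append(path)
    stage_counts["tracks"] = {n: t.n_intervals for n, t in tracks.items()}

    # --- per-subject simulation, calling, consensus, metrics --------------
    enter_stage("simulate_and_call")
    subject_ids = [f"S{i + 1:02d}" for i in range(sim.n_subjects)]
    subject_seeds = ss_subjects.spawn(sim.n_subjects)
    mixtures = {}
    consensus_by_subject = {}
    annotated_pooled = []
    per_subject_stats = {}
    for subject, ss in zip(subject_ids, subject_seeds):
        rng = np.random.default_rng(ss)
        fractions, muts_per_clone = _clone_fractions(config, rng)
        mixture = simulate_mixture(
            sim,
            clone_fractions=fractions,
            mutations_per_clone=muts_per_clone,
            rng=rng,
            subject=subject,
            infiltrate_fraction=None,
            tracks=tracks,
        )
        mixtures[subject] = mixture
        truth = {GenomicPosition(c, p) for c, p in mixture.somatic_positions()}
        truth_path = outdir / f"{subject}.truth.tsv"
        write_truth_positions(truth, truth_path)
        files.append(truth_path)

        observations = sample_observations(mixture, sim, rng, tracks)
        callsets = [
            emulate_caller(mixture, profile, sim, rng, observations=observations, tracks=tracks)
            for profile in config.callers
        ]
        if config.write_vcfs:
            for cs in callsets:
                path = outdir / f"{subject}.{cs.caller}.vcf"
                write_vcf(cs, path)
                files.append(path)

        consensus = combine(callsets, strategy=config.consensus_strategy, k=config.consensus_k)
        union = combine(callsets, strategy="union")
        consensus_by_subject[subject] = consensus
        if config.write_vcfs:
            path = outdir / f"{subject}.consensus.vcf"
            write_vcf(consensus.calls, path)
            files.append(path)

        eval_consensus = evaluate(consensus.calls, truth)
        eval_union = evaluate(union.calls, truth)

        depth_t = simulate_depth_profile(sim, rng, sim.depth_target_mean)
        depth_r = simulate_depth_profile(sim, rng, sim.depth_reference_mean)
        if config.write_depth_profiles:
            for label, profile in (("target", depth_t), ("reference", depth_r)):
                path = outdir / f"{subject}.depth_{label}.tsv"
                write_depth_profile(profile, path)
                files.append(path)
        power = smc_power(depth_t, depth_r, threshold=config.power_threshold)
        subject_burden = burden(consensus.calls, power)
        imd_series = imd(consensus.calls)

        annotated = annotate_callset(consensus.calls, tracks)
        annotated_pooled.extend(annotated)

        per_subject_stats[subject] = {
            "n_true_somatic": len(truth),
            "per_caller_counts": consensus.per_caller_counts,
            "n_consensus": len(consensus.calls),
            "n_union": union.union_size,
            "consensus_precision": eval_consensus.precision,
            "consensus_recall": eval_consensus.recall,
            "union_precision": eval_union.precision,
            "union_recall": eval_union.recall,
            "callable_bp": power.callable_bp,
            "consensus_calls_per_mb": subject_burden.calls_per_mb,
            "min_imd": imd_series.min_distance(),
        }

    enter_stage("metrics")
    rainfall_rows = []
    for subject, consensus in consensus_by_subject.items():
        df = rainfall_table(consensus.calls, sim.chrom_lengths())
        df.insert(0, "subject", subject)
        rainfall_rows.append(df)
    import pandas as pd

    rainfall = pd.concat(rainfall_rows, ignore_index=True) if rainfall_rows else pd.DataFrame()
    rainfall_path = outdir / "rainfall.tsv"
    rainfall.to_csv(rainfall_path, sep="\t", index=False)
    files.append(rainfall_path)

    totals = tier_counts(annotated_pooled)
    stage_counts["consensus_total"] = sum(len(c.calls) for c in consensus_by_subject.values())
    stage_counts["tier_totals"] = {t.value: n for t, n in totals.items()}
    if sum(totals.values()) != stage_counts["consensus_total"]:
        raise ValidationError("tier counts do not sum to the consensus call count")

    # --- verification -----------------------------------------------------
    enter_stage("verification")
    candidates = select_candidates(
        annotated_pooled,
        n_per_tier=config.n_per_tier,
        rng=np.random.default_rng(ss_select),
    )
    candidate_rows = [
        {
            "subject": a.call.subject,
            "chrom": a.call.position.chrom,
            "pos": a.call.position.pos,
            "tier": a.tier.value,
            "functional_class": a.call.functional_class.value,
        }
        for a in candidates.all_candidates()
    ]
    cand_path = outdir / "candidates.tsv"
    pd.DataFrame(candidate_rows).to_csv(cand_path, sep="\t", index=False)
    files.append(cand_path)
    stage_counts["candidates"] = {t.value: len(v) for t, v in candidates.by_tier.items()}

    positions = sorted(
        {a.call.position for a in candidates.all_candidates()}, key=lambda p: p.sort_key
    )
    pileups = simulate_pileups(
        mixtures, positions, sim, np.random.default_rng(ss_pileups)
    )
    pileup_path = outdir / "pileups.tsv"
    write_pileups(pileups, pileup_path)
    files.append(pileup_path)

    by_position: dict = {}
    for obs in pileups:
        by_position.setdefault(obs.position.key, []).append(obs)
    classes_by_position = {
        key: adjudicate(obs_list, good_coverage=config.good_coverage).classes
        for key, obs_list in by_position.items()
    }

    outcomes_by_tier: dict[ConfidenceTier, list[VerificationOutcome]] = {
        t: [] for t in ConfidenceTier
    }
    confirmed_by_tier = {t: 0 for t in ConfidenceTier}
    for tier, tier_candidates in candidates.by_tier.items():
        for a in tier_candidates:
            record = assign_outcome(
                classes_by_position[a.call.position.key], target_subject=a.call.subject
            )
            outcomes_by_tier[tier].append(record.outcome)
            if record.outcome is VerificationOutcome.CONFIRMED_SOMATIC:
                confirmed_by_tier[tier] += 1

    table = outcome_table(outcomes_by_tier)
    table_path = outdir / "outcome_table.tsv"
    table.to_csv(table_path, sep="\t")
    files.append(table_path)
    tested_by_tier = {t: len(v) for t, v in outcomes_by_tier.items()}
    for tier in ConfidenceTier:
        if int(table[tier.value].sum()) != tested_by_tier[tier]:
            raise ValidationError("outcome table column sums != tested counts")

    enter_stage("extrapolation")
    result = extrapolate(confirmed_by_tier, tested_by_tier, totals)
    extrapolation = {
        "per_tier": {
            t.value: dataclasses.asdict(x) for t, x in result.per_tier.items()
        },
        "estimated_true_total": result.estimated_true_total,
        "estimated_fp_fraction": result.estimated_fp_fraction,
        "confirmed_total": sum(confirmed_by_tier.values()),
    }
    extrap_path = outdir / "extrapolation.json"
    extrap_path.write_text(json.dumps(extrapolation, indent=2, sort_keys=True) + "\n")
    files.append(extrap_path)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_counts": {k: v for k, v in stage_counts.items() if k != "_stage_order"},
        "per_subject": per_subject_stats,
        "verification": {
            "tested": {t.value: n for t, n in tested_by_tier.items()},
            "confirmed": {t.value: n for t, n in confirmed_by_tier.items()},
            "outcome_table": {c: table[c].to_dict() for c in table.columns},
        },
        "extrapolation": extrapolation,
        "checksums": {p.name: _sha256(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
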