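"""Synthetic polyclonal-tissue data generator.

The generator emulates the inputs of the analysis: a diploid genome slice
carrying germline variants, a mixture of cellular clones each with private
heterozygous somatic mutations (expected VAF = clone fraction / 2 in the
sampled tissue, 0 in the reference tissue), binomial read sampling at
configurable depth, three somatic-caller "personalities" (two permissive,
one restrictive), annotation tracks with realistic genome fractions, and
ultra-deep amplicon pileups for verification.

Two artifact channels make the simulated call sets behave like real ones:

* *mapping artifacts* — positions where the sampled tissue shows spurious
  alt reads (VAF drawn well above the calling threshold), preferentially in
  repetitive or non-unique regions.  All callers see the same reads, so
  these survive intersection; ultra-deep amplicon re-sequencing shows no
  variant there.
* *hidden germline variants* — heterozygous SNPs whose reference-tissue
  read draw is conditioned on zero alt reads (the low-depth miss that turns
  a germline SNP into a spurious "somatic" call).  Amplicon re-sequencing
  reveals them as heterozygous in both tissues.

Per-caller false positives are placed independently, enriched on common-SNP
positions, so intersections remove them while unions retain them.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    CallSet,
    DepthProfile,
    GenomicPosition,
    PileupObservation,
    Tissue,
    Track,
    ValidationError,
    VariantCall,
)

logger = logging.getLogger("polyclone_smc")

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the sequencing design being emulated: medium-coverage
    whole genomes (brush ~20x, blood ~27x) and ~27,000x amplicon pileups.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    n_subjects: int = 12
    depth_target_mean: float = 20.0
    depth_reference_mean: float = 27.0
    pileup_depth_mean: float = 27_000.0
    depth_dispersion: Optional[float] = None  # None = Poisson limit
    seq_error_rate: float = 0.0
    seed: int = 0
    # germline background
    germline_het_per_mb: float = 500.0
    germline_hom_per_mb: float = 300.0
    germline_on_common_snp_fraction: float = 0.7
    # shared artifact channels (see module docstring)
    artifact_rate_per_mb: float = 50.0
    artifact_germline_fraction: float = 0.3
    artifact_vaf_low: float = 0.20
    artifact_vaf_high: float = 0.45
    artifact_region_fraction: float = 0.6  # mapping artifacts placed in repeat/non-unique
    artifact_blood_depth_mean: float = 4.0

    def __post_init__(self):
        for name in ("genome_length", "n_chromosomes", "n_subjects"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("depth_target_mean", "depth_reference_mean", "pileup_depth_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def chrom_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {}
        for i in range(self.n_chromosomes):
            extra = self.genome_length - base * self.n_chromosomes if i == 0 else 0
            lengths[f"chr{i + 1}"] = base + extra
        return lengths


@dataclass
class CallerProfile:
    """Behavioural caricature of one somatic mutation caller."""

    name: str
    vaf_call_threshold: float = 0.15
    fp_rate_per_mb: float = 1.0
    fp_snp_enrichment: float = 10.0
    fn_rate: float = 0.02
    min_alt_reads: int = 3

    def __post_init__(self):
        if not (0.0 <= self.vaf_call_threshold <= 1.0):
            raise ValidationError("vaf_call_threshold must be in [0,1]")
        for name in ("fp_rate_per_mb", "fp_snp_enrichment", "fn_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def default_caller_profiles() -> list[CallerProfile]:
    """Two permissive callers and one restrictive one.

    The permissive pair emits roughly ten times more calls than the
    restrictive caller, which additionally demands one more supporting read.
    """
    return [
        CallerProfile("permissive_a", fp_rate_per_mb=400.0),
        CallerProfile("permissive_b", fp_rate_per_mb=400.0),
        CallerProfile("restrictive", fp_rate_per_mb=40.0, min_alt_reads=4),
    ]


# ---------------------------------------------------------------------------
# clone mixtures


@dataclass(frozen=True)
class SomaticMutation:
    position: GenomicPosition
    ref: str
    alt: str
    zygosity: str = "het"  # "het" | "hom"


@dataclass(frozen=True)
class GermlineVariant:
    position: GenomicPosition
    ref: str
    alt: str
    zygosity: str = "het"
    on_common_snp: bool = False


@dataclass
class Clone:
    fraction: float
    mutations: list[SomaticMutation] = field(default_factory=list)


@dataclass
class CloneMixture:
    """Synthetic bulk tissue: clones with private mutations over a shared germline."""

    subject: str
    clones: list[Clone]
    germline: list[GermlineVariant] = field(default_factory=list)
    infiltrate_fraction: float = 0.0

    def __post_init__(self):
        total = sum(c.fraction for c in self.clones) + self.infiltrate_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"clone fractions + infiltrate must sum to 1, got {total}"
            )
        for c in self.clones:
            if not (0.0 < c.fraction <= 1.0):
                raise ValidationError(f"clone fraction out of (0,1]: {c.fraction}")
        somatic = {}
        for c in self.clones:
            for m in c.mutations:
                if m.position.key in somatic:
                    raise ValidationError(f"somatic position duplicated: {m.position}")
                somatic[m.position.key] = None
        germ_keys = {g.position.key for g in self.germline}
        if somatic.keys() & germ_keys:
            raise ValidationError("somatic and germline positions must be disjoint")
        self._somatic: dict = {
            m.position.key: (c.fraction, m) for c in self.clones for m in c.mutations
        }
        self._germ: dict = {g.position.key: g for g in self.germline}

    def somatic_mutations(self) -> list[tuple[float, SomaticMutation]]:
        return list(self._somatic.values())

    def somatic_positions(self) -> set[tuple[str, int]]:
        return set(self._somatic.keys())

    def expected_vaf(self, position: GenomicPosition, tissue: Tissue) -> float:
        """Expected variant allele frequency of a position in a tissue.

        Germline variants read 0.5 (het) or 1.0 (hom) in every tissue; a
        clone-private mutation reads fraction * copies / 2 in the sampled
        tissue and 0 in blood.
        """
        g = self._germ.get(position.key)
        if g is not None:
            return 0.5 if g.zygosity == "het" else 1.0
        s = self._somatic.get(position.key)
        if s is not None and tissue is not Tissue.BLOOD:
            fraction, mut = s
            copies = 1 if mut.zygosity == "het" else 2
            return fraction * copies / 2.0
        return 0.0


def _index_to_position(index: np.ndarray, chrom_lengths: Mapping[str, int]) -> list[GenomicPosition]:
    chroms = list(chrom_lengths)
    bounds = np.cumsum([chrom_lengths[c] for c in chroms])
    out = []
    for x in np.asarray(index):
        ci = int(np.searchsorted(bounds, x, side="right"))
        offset = int(x - (bounds[ci - 1] if ci else 0))
        out.append(GenomicPosition(chroms[ci], offset + 1))
    return out


def _distinct_indices(rng: np.random.Generator, total: int, n: int,
                      exclude: set[int] = frozenset()) -> np.ndarray:
    """n distinct linear genome indices, avoiding `exclude`."""
    picked: list[int] = []
    seen = set(exclude)
    while len(picked) < n:
        draw = rng.integers(0, total, size=max(2 * (n - len(picked)), 16))
        for x in draw:
            x = int(x)
            if x not in seen:
                seen.add(x)
                picked.append(x)
                if len(picked) == n:
                    break
    return np.array(picked, dtype=np.int64)


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = str(rng.choice(BASES))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def simulate_mixture(
    config: SimulationConfig,
    clone_fractions: Sequence[float],
    mutations_per_clone: int,
    rng: np.random.Generator,
    subject: str = "S1",
    infiltrate_fraction: Optional[float] = None,
    tracks: Optional[Mapping[str, Track]] = None,
) -> CloneMixture:
    """Build one subject's clone mixture.

    If ``infiltrate_fraction`` is None it is set to 1 - sum(fractions), the
    cells carrying no somatic mutation.  With annotation ``tracks`` given, a
    fraction of germline heterozygous variants is planted on common-SNP
    positions, as real inherited variation overwhelmingly is.
    """
    fractions = [float(f) for f in clone_fractions]
    if infiltrate_fraction is None:
        infiltrate_fraction = 1.0 - sum(fractions)
    if infiltrate_fraction < -1e-9:
        raise ValidationError("clone fractions sum to more than 1")
    infiltrate_fraction = max(infiltrate_fraction, 0.0)

    chrom_lengths = config.chrom_lengths()
    total = sum(chrom_lengths.values())
    mb = config.genome_length / 1e6

    n_het = rng.poisson(config.germline_het_per_mb * mb)
    n_hom = rng.poisson(config.germline_hom_per_mb * mb)
    n_som = len(fractions) * mutations_per_clone

    germline: list[GermlineVariant] = []
    used_keys: set[tuple[str, int]] = set()
    common = tracks.get("common_snp") if tracks else None
    if common is not None and common.coverage_bp() > 0:
        n_on_snp = int(round(n_het * config.germline_on_common_snp_fraction))
        for pos in common.sample_positions(n_on_snp, rng):
            if pos.key in used_keys:
                continue
            used_keys.add(pos.key)
            ref, alt = _random_substitution(rng)
            germline.append(GermlineVariant(pos, ref, alt, "het", on_common_snp=True))
        n_het -= len(germline)

    idx = _distinct_indices(rng, total, n_het + n_hom + n_som)
    positions = _index_to_position(idx, chrom_lengths)
    positions = [p for p in positions if p.key not in used_keys]
    # top up in the (rare) collision case
    while len(positions) < n_het + n_hom + n_som:
        extra = _index_to_position(_distinct_indices(rng, total, 1), chrom_lengths)[0]
        if extra.key not in used_keys and all(extra.key != p.key for p in positions):
            positions.append(extra)

    cursor = 0
    for zyg, count in (("het", n_het), ("hom", n_hom)):
        for pos in positions[cursor:cursor + count]:
            ref, alt = _random_substitution(rng)
            germline.append(GermlineVariant(pos, ref, alt, zyg))
        cursor += count

    clones = []
    for f in fractions:
        muts = []
        for pos in positions[cursor:cursor + mutations_per_clone]:
            ref, alt = _random_substitution(rng)
            muts.append(SomaticMutation(pos, ref, alt, "het"))
        cursor += mutations_per_clone
        clones.append(Clone(fraction=f, mutations=muts))

    return CloneMixture(
        subject=subject,
        clones=clones,
        germline=germline,
        infiltrate_fraction=infiltrate_fraction,
    )


def brushing_clone_fractions(
    rng: np.random.Generator,
    n_clones: int = 200,
    infiltrate_fraction: float = 0.1,
    concentration: float = 1.0,
) -> list[float]:
    """Many small clones (symmetric Dirichlet), the polyclonal-brush regime."""
    w = rng.dirichlet(np.full(n_clones, concentration))
    return list(w * (1.0 - infiltrate_fraction))


def cancer_clone_fractions(dominant_fraction: float = 0.9) -> list[float]:
    """A single dominant clone, the regime the calling strategy was validated on."""
    return [dominant_fraction]


# ---------------------------------------------------------------------------
# read sampling


def draw_depth(
    rng: np.random.Generator,
    mean: float,
    size: Optional[int] = None,
    dispersion: Optional[float] = None,
):
    """Read depth draw: Poisson by default, negative binomial if dispersed."""
    if dispersion is None:
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _alt_probability(expected_vaf: float, error_rate: float) -> float:
    # an erroneous base matches the alt allele a third of the time
    return expected_vaf * (1.0 - error_rate) + (1.0 - expected_vaf) * error_rate / 3.0


def simulate_reads(
    mixture: CloneMixture,
    position: GenomicPosition,
    tissue: Tissue,
    config: SimulationConfig,
    rng: np.random.Generator,
    depth_mean: Optional[float] = None,
) -> tuple[int, int]:
    """Sample (depth, alt_count) at one position: alt ~ Binomial(depth, E[VAF])."""
    mean = depth_mean if depth_mean is not None else (
        config.depth_reference_mean if tissue is Tissue.BLOOD else config.depth_target_mean
    )
    depth = int(draw_depth(rng, mean, dispersion=config.depth_dispersion))
    p = _alt_probability(mixture.expected_vaf(position, tissue), config.seq_error_rate)
    alt = int(rng.binomial(depth, p)) if depth > 0 else 0
    return depth, alt


# ---------------------------------------------------------------------------
# shared site observations and caller emulation


@dataclass
class SiteObservation:
    """The WGS read evidence at one candidate site, shared by all callers."""

    position: GenomicPosition
    ref: str
    alt: str
    depth_target: int
    alt_target: int
    depth_reference: int
    alt_reference: int
    true_somatic: bool
    kind: str  # "somatic" | "mapping_artifact" | "hidden_germline"

    @property
    def vaf_target(self) -> float:
        return self.alt_target / self.depth_target if self.depth_target else 0.0


def sample_observations(
    mixture: CloneMixture,
    config: SimulationConfig,
    rng: np.random.Generator,
    tracks: Optional[Mapping[str, Track]] = None,
) -> list[SiteObservation]:
    """Draw the shared WGS evidence every caller will look at.

    Covers all planted somatic mutations plus the two artifact channels.
    """
    obs: list[SiteObservation] = []
    for fraction, mut in mixture.somatic_mutations():
        copies = 1 if mut.zygosity == "het" else 2
        evaf = fraction * copies / 2.0
        dt = int(draw_depth(rng, config.depth_target_mean, dispersion=config.depth_dispersion))
        at = int(rng.binomial(dt, _alt_probability(evaf, config.seq_error_rate))) if dt else 0
        dr = int(draw_depth(rng, config.depth_reference_mean, dispersion=config.depth_dispersion))
        ar = int(rng.binomial(dr, _alt_probability(0.0, config.seq_error_rate))) if dr else 0
        obs.append(SiteObservation(mut.position, mut.ref, mut.alt, dt, at, dr, ar,
                                   True, "somatic"))

    mb = config.genome_length / 1e6
    chrom_lengths = config.chrom_lengths()

    # mapping artifacts: spurious target-tissue alt reads, repeat/non-unique enriched
    n_map = rng.poisson(config.artifact_rate_per_mb * (1 - config.artifact_germline_fraction) * mb)
    difficult = None
    if tracks and "repeat" in tracks and "mappability_unique" in tracks:
        difficult = tracks["repeat"].union(
            tracks["mappability_unique"].complement(chrom_lengths), name="difficult"
        )
    for _ in range(int(n_map)):
        if difficult is not None and rng.random() < config.artifact_region_fraction:
            pos = difficult.sample_positions(1, rng)[0]
        else:
            pos = _index_to_position(
                rng.integers(0, config.genome_length, size=1), chrom_lengths
            )[0]
        ref, alt = _random_substitution(rng)
        vaf = rng.uniform(config.artifact_vaf_low, config.artifact_vaf_high)
        dt = int(draw_depth(rng, config.depth_target_mean, dispersion=config.depth_dispersion))
        at = int(rng.binomial(dt, vaf)) if dt else 0
        dr = int(draw_depth(rng, config.depth_reference_mean, dispersion=config.depth_dispersion))
        obs.append(SiteObservation(pos, ref, alt, dt, at, dr, 0, False, "mapping_artifact"))

    # hidden germline: het SNPs whose blood draw happened to contain no alt read
    n_hidden = int(rng.poisson(config.artifact_rate_per_mb * config.artifact_germline_fraction * mb))
    on_snp = [g for g in mixture.germline if g.zygosity == "het" and g.on_common_snp]
    rng.shuffle(on_snp)
    for g in on_snp[:n_hidden]:
        dt = int(draw_depth(rng, config.depth_target_mean, dispersion=config.depth_dispersion))
        at = int(rng.binomial(dt, 0.5)) if dt else 0
        dr = max(1, int(draw_depth(rng, config.artifact_blood_depth_mean,
                                   dispersion=config.depth_dispersion)))
        obs.append(SiteObservation(g.position, g.ref, g.alt, dt, at, dr, 0,
                                   False, "hidden_germline"))
    return obs


def emulate_caller(
    mixture: CloneMixture,
    profile: CallerProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    observations: Optional[Sequence[SiteObservation]] = None,
    tracks: Optional[Mapping[str, Track]] = None,
    tissue: Tissue = Tissue.LOWER_LOBE,
) -> CallSet:
    """Apply one caller personality to the shared read evidence.

    A site is called when its sampled target VAF reaches the caller's
    threshold with at least ``min_alt_reads`` supporting reads and the
    reference tissue shows no alt read, minus ``fn_rate`` random misses.
    Independent false positives (Poisson per Mb, common-SNP enriched) are
    fabricated on top.

    Pass the same ``observations`` to every caller of one subject so that
    they share the underlying reads, as real callers do.
    """
    if observations is None:
        observations = sample_observations(mixture, config, rng, tracks)
    calls: list[VariantCall] = []
    for o in observations:
        if o.depth_target == 0:
            continue
        vaf_t = o.alt_target / o.depth_target
        if (
            o.alt_target >= profile.min_alt_reads
            and vaf_t >= profile.vaf_call_threshold
            and o.alt_reference == 0
            and rng.random() >= profile.fn_rate
        ):
            calls.append(
                VariantCall(
                    position=o.position,
                    ref_allele=o.ref,
                    alt_allele=o.alt,
                    caller=profile.name,
                    subject=mixture.subject,
                    tissue=tissue,
                    vaf_target=vaf_t,
                    vaf_reference=(o.alt_reference / o.depth_reference
                                   if o.depth_reference else None),
                    depth_target=o.depth_target,
                    depth_reference=o.depth_reference,
                )
            )

    # caller-private false positives
    mb = config.genome_length / 1e6
    n_fp = int(rng.poisson(profile.fp_rate_per_mb * mb))
    common = tracks.get("common_snp") if tracks else None
    snp_fraction = (common.coverage_bp() / config.genome_length) if common else 0.0
    p_snp = 0.0
    if snp_fraction > 0:
        e = profile.fp_snp_enrichment
        p_snp = min(1.0, e * snp_fraction / (e * snp_fraction + (1 - snp_fraction)))
    chrom_lengths = config.chrom_lengths()
    for _ in range(n_fp):
        if common is not None and rng.random() < p_snp:
            pos = common.sample_positions(1, rng)[0]
        else:
            pos = _index_to_position(
                rng.integers(0, config.genome_length, size=1), chrom_lengths
            )[0]
        ref, alt = _random_substitution(rng)
        dt = max(1, int(draw_depth(rng, config.depth_target_mean,
                                   dispersion=config.depth_dispersion)))
        vaf = rng.uniform(profile.vaf_call_threshold, 0.6)
        at = min(dt, max(profile.min_alt_reads, int(round(vaf * dt))))
        dr = int(draw_depth(rng, config.depth_reference_mean,
                            dispersion=config.depth_dispersion))
        calls.append(
            VariantCall(
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                caller=profile.name,
                subject=mixture.subject,
                tissue=tissue,
                vaf_target=at / dt,
                vaf_reference=0.0 if dr else None,
                depth_target=dt,
                depth_reference=dr,
            )
        )
    return CallSet.build(mixture.subject, tissue, profile.name, calls)


# ---------------------------------------------------------------------------
# annotation tracks


def _random_cover(
    length: int,
    fraction: float,
    mean_interval: int,
    rng: np.random.Generator,
    chrom: str,
) -> list[tuple[str, int, int]]:
    """Random intervals covering exactly round(fraction * length) bases."""
    covered = int(round(fraction * length))
    if covered <= 0:
        return []
    n = max(1, int(round(covered / mean_interval)))
    n = min(n, covered)
    # split covered bases into n parts of size >= 1, gaps into n+1 parts >= 0
    cov_parts = rng.multinomial(covered - n, np.full(n, 1.0 / n)) + 1
    gap_total = length - covered
    gap_parts = rng.multinomial(gap_total, np.full(n + 1, 1.0 / (n + 1)))
    out = []
    cursor = 0
    for i in range(n):
        cursor += int(gap_parts[i])
        out.append((chrom, cursor, cursor + int(cov_parts[i])))
        cursor += int(cov_parts[i])
    return out


def simulate_tracks(
    config: SimulationConfig,
    rng: np.random.Generator,
    repeat_fraction: float = 0.55,
    unique_fraction: float = 0.77,
    all_snp_fraction: float = 0.05,
    common_snp_fraction: float = 0.005,
    dhs_fraction: float = 0.03,
    mean_interval: int = 300,
) -> dict[str, Track]:
    """Generate annotation tracks at the genome fractions being emulated.

    Defaults: ~55% repetitive (leaving ~45% non-repetitive), 77% unique by
    50-mer mappability, common SNPs ~0.5% of the genome, all SNPs ~5%, with
    common_snp a subset of all_snp.
    """
    chrom_lengths = config.chrom_lengths()
    repeat_ivs, unique_ivs, dhs_ivs = [], [], []
    snp_positions: list[tuple[str, np.ndarray]] = []
    for chrom, length in chrom_lengths.items():
        repeat_ivs += _random_cover(length, repeat_fraction, mean_interval, rng, chrom)
        unique_ivs += _random_cover(length, unique_fraction, mean_interval * 3, rng, chrom)
        dhs_ivs += _random_cover(length, dhs_fraction, mean_interval, rng, chrom)
        n_all = int(round(all_snp_fraction * length))
        pos0 = np.sort(rng.choice(length, size=n_all, replace=False))
        snp_positions.append((chrom, pos0))
    all_snp_ivs = [
        (chrom, int(p), int(p) + 1) for chrom, pos0 in snp_positions for p in pos0
    ]
    keep = common_snp_fraction / all_snp_fraction
    common_ivs = []
    for chrom, pos0 in snp_positions:
        n_common = int(round(keep * len(pos0)))
        chosen = rng.choice(pos0, size=n_common, replace=False)
        common_ivs += [(chrom, int(p), int(p) + 1) for p in np.sort(chosen)]
    return {
        "repeat": Track("repeat", repeat_ivs),
        "mappability_unique": Track("mappability_unique", unique_ivs),
        "all_snp": Track("all_snp", all_snp_ivs),
        "common_snp": Track("common_snp", common_ivs),
        "dhs": Track("dhs", dhs_ivs),
    }


# ---------------------------------------------------------------------------
# depth profiles and amplicon pileups


def simulate_depth_profile(
    config: SimulationConfig,
    rng: np.random.Generator,
    mean: float,
) -> DepthProfile:
    arrays = {}
    for chrom, length in config.chrom_lengths().items():
        arrays[chrom] = (1, draw_depth(rng, mean, size=length,
                                       dispersion=config.depth_dispersion))
    return DepthProfile(arrays)


def simulate_pileups(
    mixtures: Mapping[str, CloneMixture],
    candidates: Sequence[GenomicPosition],
    config: SimulationConfig,
    rng: np.random.Generator,
    tissues: Sequence[Tissue] = (Tissue.LOWER_LOBE, Tissue.BLOOD),
) -> list[PileupObservation]:
    """Ultra-deep amplicon pileups: one observation per candidate x sample.

    The amplicon VAF at a position is the mixture-implied expectation of the
    owning subject (germline: ~0.5/1.0 in both tissues; clone-private:
    fraction/2 in the sampled tissue only; artifact positions: background).
    """
    out = []
    for subject in sorted(mixtures):
        mixture = mixtures[subject]
        for tissue in tissues:
            for pos in candidates:
                depth = int(draw_depth(rng, config.pileup_depth_mean,
                                       dispersion=config.depth_dispersion))
                p = _alt_probability(mixture.expected_vaf(pos, tissue),
                                     config.seq_error_rate)
                alt = int(rng.binomial(depth, p)) if depth else 0
                out.append(PileupObservation(subject, tissue, pos, depth, alt))
    return out


def write_manifest(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps({"config": asdict(config)}, indent=2) + "\n")
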