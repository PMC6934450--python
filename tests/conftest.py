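import numpy as np
import pytest

from polyclone_smc.confidence import AnnotatedCall, ConfidenceTier, StringentFlags
from polyclone_smc.model import FunctionalClass, GenomicPosition, Tissue, VariantCall
from polyclone_smc.simulate import SimulationConfig, simulate_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(genome_length=200_000, n_chromosomes=2, seed=7)


@pytest.fixture(scope="session")
def small_tracks(small_config):
    return simulate_tracks(small_config, np.random.default_rng(7))


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="C",
    subject="S01",
    caller="c1",
    vaf_target=0.3,
    vaf_reference=0.0,
    depth_target=30,
    depth_reference=30,
    **kwargs,
):
    return VariantCall(
        position=GenomicPosition(chrom, pos),
        ref_allele=ref,
        alt_allele=alt,
        caller=caller,
        subject=subject,
        tissue=kwargs.pop("tissue", Tissue.LOWER_LOBE),
        vaf_target=vaf_target,
        vaf_reference=vaf_reference,
        depth_target=depth_target,
        depth_reference=depth_reference,
        **kwargs,
    )


def make_annotated(subject, chrom, pos, tier, functional=FunctionalClass.OTHER):
    call = make_call(chrom=chrom, pos=pos, subject=subject, functional_class=functional)
    return AnnotatedCall(
        call=call,
        in_common_snp=tier is ConfidenceTier.LOW,
        in_repeat=tier is not ConfidenceTier.HIGH,
        non_unique=False,
        in_all_snp=tier is ConfidenceTier.LOW,
        tier=tier,
        stringent_flags=StringentFlags(True, True, True),
    )


def build_tiered_calls(n_per_tier=40, n_subjects=12, n_forced=4, with_y=True):
    """Synthetic tiered call sets: subjects round-robin per tier, a few
    forced nonsynonymous/splice calls, and some Y-chromosome calls."""
    calls = []
    pos = 1000
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    for t_index, tier in enumerate(ConfidenceTier):
        for i in range(n_per_tier):
            pos += 101
            calls.append(make_annotated(subjects[i % n_subjects],
                                        f"chr{t_index + 1}", pos, tier))
    for i in range(n_forced):
        pos += 101
        calls.append(
            make_annotated(subjects[i], "chr5", pos, list(ConfidenceTier)[i % 3],
                           functional=FunctionalClass.NONSYNONYMOUS if i % 2 == 0
                           else FunctionalClass.SPLICE_SITE)
        )
    if with_y:
        for i in range(9):
            pos += 101
            calls.append(make_annotated(subjects[i % n_subjects], "chrY", pos,
                                        ConfidenceTier.LOW))
    return calls
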