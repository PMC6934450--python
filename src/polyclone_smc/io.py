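"""Readers and writers for the standard interchange formats.

VCF 4.x is read through :mod:`cyvcf2`; only SNV records are retained
(multi-allelic records are split per alt allele, indels are skipped with a
logged count).  Which FORMAT keys hold per-tissue depth and alt counts is
configurable per caller dialect, because somatic callers emit different VCF
dialects; unknown keys degrade to ``None`` ("unknown"), never to silent
zeros.

BED tracks are 0-based half-open; malformed records (start >= end) are
collected and skipped while parsing continues.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    CallSet,
    DepthProfile,
    GenomicPosition,
    PileupObservation,
    Tissue,
    Track,
    VALID_BASES,
    VariantCall,
    normalize_chrom,
)

logger = logging.getLogger("polyclone_smc")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class CallerDialect:
    """Mapping from VCF FORMAT keys/sample names to per-tissue depth and alt counts.

    ``alt_key`` is interpreted as an AD-style per-allele depth field when it
    holds one value per allele (ref first), or as a plain alt-read count when
    it holds a single value.
    """

    tumor_sample: str = "TUMOR"
    normal_sample: str = "NORMAL"
    depth_key: str = "DP"
    alt_key: str = "AD"


DEFAULT_DIALECT = CallerDialect()


def _sample_value(arr, sample_idx: int, alt_idx: int) -> Optional[int]:
    if arr is None:
        return None
    row = np.atleast_2d(arr)[sample_idx]
    row = np.asarray(row).ravel()
    row = row[row >= 0] if row.dtype.kind in "iu" else row
    if len(row) == 0:
        return None
    if len(row) == 1:
        return int(row[0])
    # AD-style: ref count first, then one count per alt allele
    idx = alt_idx + 1
    if idx < len(row):
        return int(row[idx])
    return None


def read_vcf(
    path: PathLike,
    subject: str = "unknown",
    tissue: Tissue = Tissue.LOWER_LOBE,
    caller: str = "unknown",
    dialect: CallerDialect = DEFAULT_DIALECT,
) -> CallSet:
    """Parse SNV records of a VCF into a :class:`CallSet`.

    Non-SNV records are skipped with a logged count; records that fail to
    parse are collected as record-level errors and parsing continues.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    tumor_idx = samples.index(dialect.tumor_sample) if dialect.tumor_sample in samples else None
    normal_idx = samples.index(dialect.normal_sample) if dialect.normal_sample in samples else None
    if samples and tumor_idx is None:
        logger.warning("%s: tumor sample %r not in VCF samples %s; depths unknown",
                       path, dialect.tumor_sample, samples)
    calls: list[VariantCall] = []
    skipped_non_snv = 0
    record_errors = 0
    for variant in vcf:
        try:
            ref = variant.REF.upper()
            dp = ad = None
            if tumor_idx is not None or normal_idx is not None:
                try:
                    dp = variant.format(dialect.depth_key)
                except KeyError:
                    dp = None
                try:
                    ad = variant.format(dialect.alt_key)
                except KeyError:
                    ad = None
            for alt_idx, alt in enumerate(variant.ALT):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                    skipped_non_snv += 1
                    continue
                depth_t = depth_r = alt_t = alt_r = None
                if tumor_idx is not None:
                    depth_t = _sample_value(dp, tumor_idx, -1) if dp is not None else None
                    alt_t = _sample_value(ad, tumor_idx, alt_idx) if ad is not None else None
                if normal_idx is not None:
                    depth_r = _sample_value(dp, normal_idx, -1) if dp is not None else None
                    alt_r = _sample_value(ad, normal_idx, alt_idx) if ad is not None else None
                vaf_t = alt_t / depth_t if alt_t is not None and depth_t else None
                vaf_r = alt_r / depth_r if alt_r is not None and depth_r else None
                calls.append(
                    VariantCall(
                        position=GenomicPosition(variant.CHROM, variant.POS),
                        ref_allele=ref,
                        alt_allele=alt,
                        caller=caller,
                        subject=subject,
                        tissue=tissue,
                        vaf_target=vaf_t,
                        vaf_reference=vaf_r,
                        depth_target=depth_t,
                        depth_reference=depth_r,
                    )
                )
        except (ValueError, TypeError, AttributeError) as exc:  # record-level
            record_errors += 1
            logger.warning("%s: skipping malformed record: %s", path, exc)
    if skipped_non_snv:
        logger.info("%s: skipped %d non-SNV allele records", path, skipped_non_snv)
    if record_errors:
        logger.warning("%s: %d records failed to parse", path, record_errors)
    return CallSet.build(subject=subject, tissue=tissue, caller=caller, calls=calls)


def write_vcf(
    callset: CallSet,
    path: PathLike,
    dialect: CallerDialect = DEFAULT_DIALECT,
    extra_header: Iterable[str] = (),
) -> None:
    """Write a CallSet as an uncompressed two-sample somatic VCF.

    VAFs are stored as read counts (alt = round(vaf * depth)), so a
    round trip preserves them exactly whenever they originated from counts.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=polyclone_smc",
        f'##FORMAT=<ID={dialect.depth_key},Number=1,Type=Integer,Description="Read depth">',
        f'##FORMAT=<ID={dialect.alt_key},Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    ]
    lines.extend(extra_header)
    chroms = []
    for call in callset.calls:
        if call.position.chrom not in chroms:
            chroms.append(call.position.chrom)
    lines.extend(f"##contig=<ID={c}>" for c in chroms)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{dialect.tumor_sample}\t{dialect.normal_sample}"
    )

    def fmt(depth: Optional[int], vaf: Optional[float]) -> str:
        if depth is None:
            return ".:."
        alt = int(round((vaf or 0.0) * depth))
        return f"{depth}:{depth - alt},{alt}"

    for call in callset.calls:
        lines.append(
            "\t".join(
                [
                    call.position.chrom,
                    str(call.position.pos),
                    ".",
                    call.ref_allele,
                    call.alt_allele,
                    ".",
                    "PASS",
                    "SOMATIC",
                    f"{dialect.depth_key}:{dialect.alt_key}",
                    fmt(call.depth_target, call.vaf_target),
                    fmt(call.depth_reference, call.vaf_reference),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_track(path: PathLike, name: str) -> Track:
    """Read a BED3+ file into a merged :class:`Track`.

    Records with start >= end are skipped (logged); an empty file yields an
    empty, valid track.
    """
    intervals: list[tuple[str, int, int]] = []
    bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError):
                bad += 1
                logger.warning("%s:%d: malformed BED record skipped", path, lineno)
                continue
            if start >= end:
                bad += 1
                logger.warning("%s:%d: start >= end, record skipped", path, lineno)
                continue
            intervals.append((chrom, start, end))
    if bad:
        logger.warning("%s: skipped %d bad BED records", path, bad)
    return Track(name, intervals)


def write_bed_track(track: Track, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def overlaps(track: Track, position: GenomicPosition) -> bool:
    """True iff the 1-based position falls in the track (converted internally)."""
    return track.contains_position(position)


def read_depth_profile(path: PathLike) -> DepthProfile:
    """Read a depth profile from TSV.

    Accepts either 3 columns (chrom, pos, depth; 1-based positions) or a
    bedGraph-like 4 columns (chrom, start, end, depth; 0-based half-open,
    run-length encoded).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    arrays: dict[str, tuple[int, np.ndarray]] = {}
    if df.shape[1] == 3:
        df.columns = ["chrom", "pos", "depth"]
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            start = int(grp["pos"].iloc[0])
            span = int(grp["pos"].iloc[-1]) - start + 1
            depths = np.zeros(span, dtype=np.int64)
            depths[grp["pos"].to_numpy() - start] = grp["depth"].to_numpy()
            arrays[str(chrom)] = (start, depths)
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "depth"]
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            start0 = int(grp["start"].iloc[0])
            span = int(grp["end"].iloc[-1]) - start0
            depths = np.zeros(span, dtype=np.int64)
            for _, row in grp.iterrows():
                depths[int(row.start) - start0:int(row.end) - start0] = int(row.depth)
            arrays[str(chrom)] = (start0 + 1, depths)
    else:
        raise ValueError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    return DepthProfile(arrays)


def write_depth_profile(profile: DepthProfile, path: PathLike) -> None:
    """Write a depth profile as a run-length encoded bedGraph-like TSV."""
    with open(path, "w") as fh:
        for chrom, (start, depths) in sorted(profile.arrays().items()):
            if len(depths) == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            edges = np.concatenate(([0], change, [len(depths)]))
            for a, b in zip(edges[:-1], edges[1:]):
                fh.write(f"{chrom}\t{start - 1 + a}\t{start - 1 + b}\t{int(depths[a])}\n")


def read_truth_positions(path: PathLike) -> set[tuple[str, int]]:
    """Read a truth set TSV (columns: chrom, pos) into matching keys."""
    df = pd.read_csv(path, sep="\t")
    return {
        (normalize_chrom(str(c)), int(p))
        for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def write_truth_positions(positions: Iterable[GenomicPosition], path: PathLike) -> None:
    rows = sorted(positions, key=lambda p: p.sort_key)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for p in rows:
            fh.write(f"{p.chrom}\t{p.pos}\n")


PILEUP_COLUMNS = ["subject", "tissue", "chrom", "pos", "depth", "alt_count"]


def write_pileups(observations: Iterable[PileupObservation], path: PathLike) -> None:
    rows = [
        (o.subject, o.tissue.value, o.position.chrom, o.position.pos, o.depth, o.alt_count)
        for o in observations
    ]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileups(path: PathLike) -> list[PileupObservation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PileupObservation(
            subject=str(r.subject),
            tissue=Tissue(r.tissue),
            position=GenomicPosition(str(r.chrom), int(r.pos)),
            depth=int(r.depth),
            alt_count=int(r.alt_count),
        )
        for r in df.itertuples()
    ]
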