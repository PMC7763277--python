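"""Variant-level quality filters and read-ratio CNV calling.

The QC thresholds mirror germline short-variant practice: calls supported by
fewer than 20 reads are set aside as low-coverage, and calls with a
Phred-scaled Fisher strand-bias (FS) above 60 are set aside as strand-biased.
Both removals are recorded with machine-readable reasons so a later recovery
step can re-admit them.

CNV calling works on per-target coverage ratios. Each target's sample depth
and reference depth are median-normalised independently, and the ratio of the
two normalised depths is screened against a deletion cutoff (< 0.6) and a
duplication cutoff (> 1.40). Runs of consecutive out-of-range targets within
a gene become single calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_model import AnnotatedVariant, GenomicInterval

LOW_COVERAGE = "low_coverage"
STRAND_BIAS = "strand_bias"

DEFAULT_MIN_DEPTH = 20
DEFAULT_MAX_FS = 60.0
DEFAULT_DELETION_CUTOFF = 0.6
DEFAULT_DUPLICATION_CUTOFF = 1.40


@dataclass(frozen=True)
class CoverageTarget:
    interval: GenomicInterval
    gene: str
    exon: str
    sample_depth: float
    reference_depth: float

    def __post_init__(self) -> None:
        if self.sample_depth < 0:
            raise ValueError("sample_depth must be >= 0")
        if self.reference_depth <= 0:
            raise ValueError("reference_depth must be > 0")


@dataclass
class CoverageProfile:
    targets: list[CoverageTarget]

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class CnvCall:
    intervals: tuple[GenomicInterval, ...]
    gene: str
    exons: str
    ratio: float
    call: str  # "deletion" | "duplication"
    zygosity_hint: str  # "het" | "hom" | "none"

    @property
    def span(self) -> int:
        """Number of consecutive targets in the call."""
        return len(self.intervals)


def apply_qc_filters(
    variants: Iterable[AnnotatedVariant],
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_fs: float = DEFAULT_MAX_FS,
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, list[str]]]]:
    """Split variants into (kept, removed-with-reasons).

    A variant is removed when depth < ``min_depth`` (reason ``low_coverage``)
    or FS > ``max_fs`` (reason ``strand_bias``); values exactly at a
    threshold are kept. Missing FS is treated as 0.
    """
    kept: list[AnnotatedVariant] = []
    removed: list[tuple[AnnotatedVariant, list[str]]] = []
    for v in variants:
        if v.depth < 0:
            raise ValueError(f"negative depth for {v.key}")
        reasons = []
        if v.depth < min_depth:
            reasons.append(LOW_COVERAGE)
        if (v.fs_phred or 0.0) > max_fs:
            reasons.append(STRAND_BIAS)
        (removed.append((v, reasons)) if reasons else kept.append(v))
    return kept, removed


def normalize_ratios(profile: CoverageProfile) -> pd.DataFrame:
    """Per-target sample/reference coverage ratios.

    ratio_i = (s_i / median(s)) / (r_i / median(r)). Dividing each track by
    its own median removes library-size differences, so the ratio is
    invariant to rescaling either track by a constant.
    """
    if len(profile) == 0:
        raise ValueError("empty coverage profile")
    s = np.array([t.sample_depth for t in profile.targets], dtype=float)
    r = np.array([t.reference_depth for t in profile.targets], dtype=float)
    s_med, r_med = float(np.median(s)), float(np.median(r))
    if s_med <= 0 or r_med <= 0:
        raise ValueError("degenerate profile: zero median depth")
    ratio = (s / s_med) / (r / r_med)
    return pd.DataFrame(
        {
            "chrom": [t.interval.chrom for t in profile.targets],
            "start": [t.interval.start for t in profile.targets],
            "end": [t.interval.end for t in profile.targets],
            "gene": [t.gene for t in profile.targets],
            "exon": [t.exon for t in profile.targets],
            "ratio": ratio,
        }
    )


def call_cnvs(
    ratio_table: pd.DataFrame,
    deletion_cutoff: float = DEFAULT_DELETION_CUTOFF,
    duplication_cutoff: float = DEFAULT_DUPLICATION_CUTOFF,
    min_consecutive_targets: int = 2,
) -> list[CnvCall]:
    """Seed-and-extend merging of out-of-range targets into calls.

    Targets beyond a strict cutoff seed an event; the event extends through
    adjacent targets whose ratio is on the same side of the midpoint between
    the cutoff and 1.0 (so a target that jitters marginally across the
    cutoff does not split or truncate a real event). A block becomes a call
    when it spans at least ``min_consecutive_targets`` targets, contains at
    least one seed, and its mean ratio is itself beyond the cutoff. Targets
    are screened in table order within each gene. A deletion call with mean
    ratio below 0.25 is hinted homozygous, otherwise heterozygous.
    """
    if not np.isfinite(ratio_table["ratio"]).all():
        raise ValueError("non-finite ratio in table")
    del_extend = (deletion_cutoff + 1.0) / 2
    dup_extend = (duplication_cutoff + 1.0) / 2
    calls: list[CnvCall] = []
    for gene, sub in ratio_table.groupby("gene", sort=False):
        rows = sub.reset_index(drop=True)
        ratios = rows["ratio"].to_numpy()
        n = len(ratios)
        for d, seed_ok, ext_ok in (
            ("deletion", ratios < deletion_cutoff, ratios < del_extend),
            ("duplication", ratios > duplication_cutoff, ratios > dup_extend),
        ):
            i = 0
            while i < n:
                if not ext_ok[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and ext_ok[j + 1]:
                    j += 1
                block = rows.iloc[i : j + 1]
                mean_ratio = float(block["ratio"].mean())
                beyond = (
                    mean_ratio < deletion_cutoff
                    if d == "deletion"
                    else mean_ratio > duplication_cutoff
                )
                if (
                    j - i + 1 >= min_consecutive_targets
                    and seed_ok[i : j + 1].any()
                    and beyond
                ):
                    hint = (
                        ("hom" if mean_ratio < 0.25 else "het")
                        if d == "deletion"
                        else "none"
                    )
                    calls.append(
                        CnvCall(
                            intervals=tuple(
                                GenomicInterval(c, int(s), int(e))
                                for c, s, e in zip(
                                    block["chrom"], block["start"], block["end"]
                                )
                            ),
                            gene=gene,
                            exons=f"{block['exon'].iloc[0]}-{block['exon'].iloc[-1]}"
                            if len(block) > 1
                            else str(block["exon"].iloc[0]),
                            ratio=mean_ratio,
                            call=d,
                            zygosity_hint=hint,
                        )
                    )
                i = j + 1
    calls.sort(key=lambda c: (c.gene, c.intervals[0].start))
    return calls


# ---------------------------------------------------------------------------
# TSV I/O


def read_coverage_profile(path: str | Path) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    targets = [
        CoverageTarget(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            gene=r.gene,
            exon=str(r.exon),
            sample_depth=float(r.sample_depth),
            reference_depth=float(r.reference_depth),
        )
        for r in df.itertuples()
    ]
    return CoverageProfile(targets)


def write_coverage_profile(profile: CoverageProfile, path: str | Path) -> None:
    lines = ["chrom\tstart\tend\tgene\texon\tsample_depth\treference_depth"]
    for t in profile.targets:
        lines.append(
            f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t{t.gene}\t"
            f"{t.exon}\t{t.sample_depth:.4f}\t{t.reference_depth:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cnv_bed(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Emit CNV calls as annotated BED (0-based half-open)."""
    lines = []
    for c in calls:
        start = min(iv.start for iv in c.intervals) - 1
        end = max(iv.end for iv in c.intervals)
        chrom = c.intervals[0].chrom
        lines.append(
            f"{chrom}\t{start}\t{end}\t{c.gene}:{c.exons}:{c.call}:"
            f"{c.zygosity_hint}:{c.ratio:.3f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
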