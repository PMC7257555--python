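"""Per-locus repeat-length profiling of aligned tumor/normal reads.

Each microsatellite locus is summarised, per sample, as a histogram of
observed repeat counts over the reads that fully span the tract plus a few
anchor bases of flank on each side.  Reads are pre-filtered on length and
mean base quality; loci are later QC'd on coverage and tract base quality,
and weakly supported alleles are pruned before scoring.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .catalog import MicrosatelliteLocus


class MissingQualitiesError(ValueError):
    """Raised when a read carries no per-base quality values."""


class MissingIndexError(FileNotFoundError):
    """Raised when a coordinate query needs a BAM index that is absent."""


class LocusMismatchError(ValueError):
    """Raised when paired distributions refer to different loci."""


@dataclass
class QCThresholds:
    """Read- and locus-level quality thresholds.

    All failure conditions are strict less-than: a 35 bp read, a mean read
    quality of exactly 25, 30x coverage and tract quality 30.0 all pass.
    """

    min_read_len: int = 35
    min_read_qual: float = 25.0
    min_locus_qual: float = 30.0
    min_coverage: int = 30
    min_allele_support: int = 3

    def __post_init__(self) -> None:
        for name in ("min_read_len", "min_read_qual", "min_locus_qual",
                     "min_coverage", "min_allele_support"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RepeatLengthDistribution:
    """Histogram of observed repeat counts at one locus in one sample."""

    locus_key: str
    counts: dict[int, int] = field(default_factory=dict)
    mean_tract_quality: float = float("nan")

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[int, float]:
        cov = self.coverage
        if cov == 0:
            raise ZeroDivisionError("empty distribution has no proportions")
        return {k: v / cov for k, v in self.counts.items()}

    def pruned(self, min_support: int) -> "RepeatLengthDistribution":
        """Drop repeat-count alleles supported by fewer than *min_support* reads."""
        kept = {k: v for k, v in self.counts.items() if v >= min_support}
        return replace(self, counts=kept)


def filter_read(read, qc: QCThresholds | None = None) -> bool:
    """Keep/drop decision for one read; True means keep.

    Drops a read iff its length is below ``min_read_len`` or its mean Phred
    quality over the whole read is below ``min_read_qual``.  Accepts a
    ``pysam.AlignedSegment`` or any object with ``query_sequence`` and
    ``query_qualities``.
    """
    qc = qc or QCThresholds()
    quals = read.query_qualities
    if quals is None:
        raise MissingQualitiesError(f"read {read.query_name!r} has no base qualities")
    length = len(read.query_sequence)
    if length < qc.min_read_len:
        return False
    if float(np.mean(quals)) < qc.min_read_qual:
        return False
    return True


def _ref_to_query_map(read) -> dict[int, int]:
    return {
        rpos: qpos
        for qpos, rpos in read.get_aligned_pairs(matches_only=True)
    }


def _anchor_ok(read, r2q: dict[int, int], ref: str, lo: int, hi: int) -> bool:
    """Anchor bases [lo, hi) must be aligned gap-free and match the reference."""
    qpositions = []
    seq = read.query_sequence
    for rpos in range(lo, hi):
        qpos = r2q.get(rpos)
        if qpos is None:
            return False
        if seq[qpos] != ref[rpos]:
            return False
        qpositions.append(qpos)
    return all(b - a == 1 for a, b in zip(qpositions, qpositions[1:]))


def count_repeats(segment: str, unit: str) -> int:
    """Head-anchored count of complete unit copies; a mismatch truncates."""
    k = len(unit)
    m = 0
    while segment[m * k : (m + 1) * k] == unit:
        m += 1
    return m


def profile_locus(
    reads: Iterable,
    locus: MicrosatelliteLocus,
    ref_seq: str,
    anchor: int = 3,
    require_full_tract_match: bool = False,
) -> RepeatLengthDistribution:
    """Build the repeat-length distribution of one locus from aligned reads.

    A read contributes iff it spans ``[start - anchor, end + anchor)``, both
    flank anchors align gap-free and match the reference, and (optionally)
    the whole tract segment is an exact unit tiling.  The observed repeat
    count is the number of complete unit copies between the anchors,
    truncated at the first internal mismatch.

    Parameters
    ----------
    reads
        Aligned reads on the locus contig (already read-filtered).
    locus
        The tract to profile.
    ref_seq
        Full reference sequence of the locus contig (for anchor checks).
    anchor
        Flank bases that must match on each side of the tract.
    require_full_tract_match
        If True, reads with any mismatch inside the tract segment are
        excluded instead of contributing a truncated count.
    """
    if anchor < 1:
        raise ValueError("anchor must be >= 1 (reads must span both flanks)")
    counts: dict[int, int] = {}
    tract_quals: list[float] = []
    lo, hi = locus.start - anchor, locus.end + anchor
    ref = ref_seq.upper()
    for read in reads:
        if read.reference_start is None or read.reference_start > lo:
            continue
        if read.reference_end is None or read.reference_end < hi:
            continue
        r2q = _ref_to_query_map(read)
        if not _anchor_ok(read, r2q, ref, lo, locus.start):
            continue
        if not _anchor_ok(read, r2q, ref, locus.end, hi):
            continue
        q_left = r2q[locus.start - 1] + 1
        q_right = r2q[locus.end]
        segment = read.query_sequence[q_left:q_right]
        m = count_repeats(segment, locus.unit)
        if require_full_tract_match and m * locus.unit_len != len(segment):
            continue
        counts[m] = counts.get(m, 0) + 1
        if q_right > q_left and read.query_qualities is not None:
            tract_quals.append(float(np.mean(read.query_qualities[q_left:q_right])))
    mean_q = float(np.mean(tract_quals)) if tract_quals else float("nan")
    return RepeatLengthDistribution(locus.key, counts, mean_q)


def profile_sample(
    alignment_path: str,
    catalog: Sequence[MicrosatelliteLocus],
    reference: Mapping[str, str],
    qc: QCThresholds | None = None,
    anchor: int = 3,
    require_full_tract_match: bool = False,
) -> dict[str, RepeatLengthDistribution]:
    """Profile every catalog locus from a SAM/BAM file in one pass.

    Reads are streamed once and assigned to the loci they span, so plain
    SAM files work; BAM files must be indexed only when random access is
    requested elsewhere.  Unmapped and secondary/supplementary records are
    ignored.
    """
    qc = qc or QCThresholds()
    by_contig: dict[str, list[MicrosatelliteLocus]] = {}
    for locus in catalog:
        by_contig.setdefault(locus.contig, []).append(locus)
    for loci in by_contig.values():
        loci.sort(key=lambda l: l.start)
    starts = {c: [l.start for l in loci] for c, loci in by_contig.items()}
    bucket: dict[str, list] = {l.key: [] for l in catalog}

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            contig = read.reference_name
            loci = by_contig.get(contig)
            if not loci:
                continue
            if not filter_read(read, qc):
                continue
            rstart, rend = read.reference_start, read.reference_end
            # candidate loci have start within the read's reference span
            i = bisect.bisect_left(starts[contig], rstart)
            j = bisect.bisect_right(starts[contig], rend)
            for locus in loci[i:j]:
                if rstart <= locus.start - anchor and rend >= locus.end + anchor:
                    bucket[locus.key].append(read)

    profiles: dict[str, RepeatLengthDistribution] = {}
    for locus in catalog:
        profiles[locus.key] = profile_locus(
            bucket[locus.key],
            locus,
            reference[locus.contig],
            anchor=anchor,
            require_full_tract_match=require_full_tract_match,
        )
    return profiles


def qc_locus(
    tumor: RepeatLengthDistribution,
    normal: RepeatLengthDistribution,
    qc: QCThresholds | None = None,
    mode: str = "allele_support",
) -> tuple[bool, RepeatLengthDistribution, RepeatLengthDistribution]:
    """Joint tumor/normal locus QC; returns (passed, tumor', normal').

    The pair fails when either sample has coverage below ``min_coverage``
    or mean tract quality below ``min_locus_qual`` (strict less-than).  In
    the default ``allele_support`` mode, alleles supported by fewer than
    ``min_allele_support`` reads are pruned from each passing distribution
    before scoring; pruning the distribution to nothing fails the locus.
    The alternative ``distinct_lengths`` mode instead fails loci showing
    fewer than ``min_allele_support`` distinct repeat lengths (a stricter
    reading that also discards perfectly stable loci).
    """
    qc = qc or QCThresholds()
    if tumor.locus_key != normal.locus_key:
        raise LocusMismatchError(
            f"distributions refer to different loci: "
            f"{tumor.locus_key!r} vs {normal.locus_key!r}"
        )
    if mode not in ("allele_support", "distinct_lengths"):
        raise ValueError(f"unknown qc mode {mode!r}")
    for dist in (tumor, normal):
        if dist.coverage < qc.min_coverage:
            return False, tumor, normal
        if not (dist.mean_tract_quality >= qc.min_locus_qual):  # NaN fails
            return False, tumor, normal
    if mode == "distinct_lengths":
        if min(len(tumor.counts), len(normal.counts)) < qc.min_allele_support:
            return False, tumor, normal
        return True, tumor, normal
    t, n = tumor.pruned(qc.min_allele_support), normal.pruned(qc.min_allele_support)
    if t.coverage == 0 or n.coverage == 0:
        return False, tumor, normal
    return True, t, n
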