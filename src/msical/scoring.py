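"""L1 instability scores and sample-level MSI classification.

For one locus, the tumor and normal repeat-length histograms are each
normalized to proportions and compared with the L1 distance

    l1 = sum_k | p_T(k) - p_N(k) |

over the union of observed repeat counts.  The score lives in [0, 2]: 0
for identical distributions, 2 for disjoint supports.  A sample's MSI
score is the unweighted mean of l1 over QC-passing loci, and the sample is
called MSI-H when that mean reaches the cutoff (default 0.4, with the
boundary score itself counted as MSI-H).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .profiler import (
    LocusMismatchError,
    QCThresholds,
    RepeatLengthDistribution,
    qc_locus,
)

MSI_H = "MSI-H"
MSS = "MSS"

DEFAULT_CUTOFF = 0.4
DEFAULT_MIN_PASSING_LOCI = 5


class ZeroCoverageError(ValueError):
    """Raised when an empty distribution reaches the scoring step."""


class InsufficientLociError(ValueError):
    """Raised when too few loci pass QC for the sample to be callable."""


@dataclass(frozen=True)
class LocusScore:
    locus_key: str
    l1: float | None
    qc_pass: bool


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    msi_score: float
    n_loci_evaluated: int
    n_loci_passing: int
    status: str
    cutoff_used: float


def locus_l1(
    tumor: RepeatLengthDistribution, normal: RepeatLengthDistribution
) -> float:
    """L1 distance between proportion-normalized repeat-length histograms."""
    if tumor.locus_key != normal.locus_key:
        raise LocusMismatchError(
            f"{tumor.locus_key!r} vs {normal.locus_key!r}"
        )
    if tumor.coverage == 0 or normal.coverage == 0:
        raise ZeroCoverageError(
            f"locus {tumor.locus_key}: zero-coverage distribution must be "
            "QC-failed upstream"
        )
    pt, pn = tumor.proportions(), normal.proportions()
    return float(sum(abs(pt.get(k, 0.0) - pn.get(k, 0.0))
                     for k in set(pt) | set(pn)))


def score_locus_pair(
    tumor: RepeatLengthDistribution,
    normal: RepeatLengthDistribution,
    qc: QCThresholds | None = None,
    mode: str = "allele_support",
) -> LocusScore:
    """QC a tumor/normal pair and score it if it passes."""
    passed, t, n = qc_locus(tumor, normal, qc, mode=mode)
    if not passed:
        return LocusScore(tumor.locus_key, None, False)
    return LocusScore(tumor.locus_key, locus_l1(t, n), True)


def sample_score(
    scores: Iterable[LocusScore],
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI,
) -> float:
    """Unweighted mean l1 over QC-passing loci.

    Failed loci are excluded from numerator and denominator alike; a
    sample with fewer than *min_passing_loci* passing loci is uncallable,
    which is distinct from being MSS.
    """
    passing = [s.l1 for s in scores if s.qc_pass and s.l1 is not None]
    if len(passing) < min_passing_loci:
        raise InsufficientLociError(
            f"only {len(passing)} loci passed QC "
            f"(minimum {min_passing_loci}): sample is uncallable"
        )
    return float(sum(passing) / len(passing))


def classify(msi_score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """MSI-H iff the score reaches the cutoff (boundary counts as MSI-H)."""
    if not math.isfinite(msi_score) or msi_score < 0:
        raise ValueError(f"MSI score must be finite and >= 0, got {msi_score}")
    return MSI_H if msi_score >= cutoff else MSS


def call_sample(
    sample_id: str,
    locus_scores: Sequence[LocusScore],
    cutoff: float = DEFAULT_CUTOFF,
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI,
) -> SampleResult:
    """Aggregate per-locus scores into a sample verdict."""
    score = sample_score(locus_scores, min_passing_loci)
    n_pass = sum(1 for s in locus_scores if s.qc_pass)
    return SampleResult(
        sample_id=sample_id,
        msi_score=score,
        n_loci_evaluated=len(locus_scores),
        n_loci_passing=n_pass,
        status=classify(score, cutoff),
        cutoff_used=cutoff,
    )


def score_sample_pair(
    sample_id: str,
    tumor_profiles: Mapping[str, RepeatLengthDistribution],
    normal_profiles: Mapping[str, RepeatLengthDistribution],
    locus_keys: Sequence[str] | None = None,
    qc: QCThresholds | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI,
    mode: str = "allele_support",
) -> tuple[SampleResult, list[LocusScore]]:
    """Score a full tumor/normal profile pair over a locus set.

    *locus_keys* defaults to the keys shared by both profile mappings, in
    tumor-profile order.
    """
    if locus_keys is None:
        locus_keys = [k for k in tumor_profiles if k in normal_profiles]
    scores = [
        score_locus_pair(tumor_profiles[k], normal_profiles[k], qc, mode=mode)
        for k in locus_keys
    ]
    return call_sample(sample_id, scores, cutoff, min_passing_loci), scores
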