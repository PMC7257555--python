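"""Marker-locus panel training from a labeled tumor/normal cohort.

The discriminative marker set is derived with a rank-overlap rule: per
locus, mean L1 instability scores are computed separately over MSI-H and
MSS samples; the loci ranking in the top k (most unstable) of the MSI-H
ordering AND in the bottom k (most stable) of the MSS ordering are kept.
Such loci respond strongly to mismatch-repair deficiency yet are quiet in
stable tumors, which is exactly what a small diagnostic panel needs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MicrosatelliteLocus
from .profiler import QCThresholds, RepeatLengthDistribution
from .scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_PASSING_LOCI,
    MSI_H,
    MSS,
    score_locus_pair,
)

DEFAULT_K = 50
DEFAULT_EVALUABILITY_FRACTION = 0.9
MODEL_FORMAT_VERSION = 1


class EmptyClassError(ValueError):
    """Raised when a sample class (MSI-H or MSS) has no samples."""


class NotEnoughRankableLociError(ValueError):
    """Raised when fewer than k loci are rankable in both classes."""


class SampleSetMismatchError(ValueError):
    """Raised when prediction and label sample ids differ."""


@dataclass
class CohortScoreMatrix:
    """Per-locus x per-sample L1 scores with class labels.

    ``scores`` is a loci-by-samples DataFrame; missing values (NaN) mark
    locus/sample pairs that failed QC.  ``labels`` maps sample id to
    "MSI-H" or "MSS".
    """

    scores: pd.DataFrame
    labels: dict[str, str]
    loci: list[MicrosatelliteLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.scores.columns) - set(self.labels)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")
        if self.loci and [l.key for l in self.loci] != list(self.scores.index):
            raise ValueError("locus list does not match score-matrix index")

    def samples_in_class(self, label: str) -> list[str]:
        return [s for s in self.scores.columns if self.labels[s] == label]


def build_score_matrix(
    cohort_profiles: Mapping[str, tuple[Mapping[str, RepeatLengthDistribution],
                                        Mapping[str, RepeatLengthDistribution]]],
    labels: Mapping[str, str],
    loci: Sequence[MicrosatelliteLocus],
    qc: QCThresholds | None = None,
    mode: str = "allele_support",
) -> CohortScoreMatrix:
    """Score every (locus, sample) pair of a cohort into a matrix.

    *cohort_profiles* maps sample id to ``(tumor_profiles, normal_profiles)``
    as produced by :func:`msical.profiler.profile_sample`.
    """
    keys = [l.key for l in loci]
    data = {}
    for sample_id, (tumor, normal) in cohort_profiles.items():
        col = []
        for key in keys:
            ls = score_locus_pair(tumor[key], normal[key], qc, mode=mode)
            col.append(ls.l1 if ls.qc_pass else np.nan)
        data[sample_id] = col
    scores = pd.DataFrame(data, index=keys, dtype=float)
    return CohortScoreMatrix(scores, dict(labels), list(loci))


def group_mean_scores(
    matrix: CohortScoreMatrix,
    evaluability_fraction: float = DEFAULT_EVALUABILITY_FRACTION,
) -> pd.DataFrame:
    """Per-locus class means and evaluability.

    Returns a DataFrame indexed by locus key with columns ``mean_msih``,
    ``mean_mss``, ``frac_eval_msih``, ``frac_eval_mss`` and ``rankable``.
    Means are taken over non-missing entries only; a locus evaluable in
    less than *evaluability_fraction* of either class is flagged
    non-rankable so a handful of lucky observations cannot put a sparsely
    covered locus into the panel.
    """
    msih = matrix.samples_in_class(MSI_H)
    mss = matrix.samples_in_class(MSS)
    if not msih or not mss:
        raise EmptyClassError(
            f"both classes need samples (MSI-H: {len(msih)}, MSS: {len(mss)})"
        )
    sub_h, sub_s = matrix.scores[msih], matrix.scores[mss]
    out = pd.DataFrame(
        {
            "mean_msih": sub_h.mean(axis=1),
            "mean_mss": sub_s.mean(axis=1),
            "frac_eval_msih": sub_h.notna().mean(axis=1),
            "frac_eval_mss": sub_s.notna().mean(axis=1),
        }
    )
    out["rankable"] = (
        (out["frac_eval_msih"] >= evaluability_fraction)
        & (out["frac_eval_mss"] >= evaluability_fraction)
        & out["mean_msih"].notna()
        & out["mean_mss"].notna()
    )
    return out


def _coord_rank(means: pd.DataFrame,
                loci: Sequence[MicrosatelliteLocus]) -> pd.Series:
    by_key = {l.key: (l.contig, l.start) for l in loci}
    coords = [by_key.get(k, ("", -1)) for k in means.index]
    order = sorted(range(len(coords)), key=lambda i: coords[i])
    rank = np.empty(len(coords), dtype=int)
    rank[order] = np.arange(len(coords))
    return pd.Series(rank, index=means.index)


def select_markers(
    means: pd.DataFrame,
    loci: Sequence[MicrosatelliteLocus],
    k: int = DEFAULT_K,
) -> list[MicrosatelliteLocus]:
    """Overlap of the top-k MSI-H-unstable and bottom-k MSS-stable loci.

    Only rankable loci compete.  Ties in either ranking are broken by
    genomic coordinate (contig, start), so the selection is deterministic
    and invariant to the input order of loci.  The returned markers are in
    genomic order.
    """
    rankable = means[means["rankable"]] if "rankable" in means else means
    if len(rankable) < k:
        raise NotEnoughRankableLociError(
            f"{len(rankable)} rankable loci < k={k}"
        )
    coord = _coord_rank(rankable, loci)
    top_h = rankable.assign(_c=coord).sort_values(
        ["mean_msih", "_c"], ascending=[False, True], kind="mergesort"
    ).head(k)
    bot_s = rankable.assign(_c=coord).sort_values(
        ["mean_mss", "_c"], ascending=[True, True], kind="mergesort"
    ).head(k)
    chosen = set(top_h.index) & set(bot_s.index)
    by_key = {l.key: l for l in loci}
    markers = [by_key[key] for key in chosen]
    markers.sort(key=lambda l: (l.contig, l.start))
    return markers


@dataclass
class MarkerModel:
    """A trained marker panel plus everything needed to reuse and audit it."""

    marker_loci: list[MicrosatelliteLocus]
    cutoff: float = DEFAULT_CUTOFF
    k: int = DEFAULT_K
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI
    evaluability_fraction: float = DEFAULT_EVALUABILITY_FRACTION
    qc: QCThresholds = field(default_factory=QCThresholds)
    provenance: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if not self.marker_loci:
            raise ValueError("marker_loci must be non-empty")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    @property
    def marker_keys(self) -> list[str]:
        return [l.key for l in self.marker_loci]


def _cohort_fingerprint(matrix: CohortScoreMatrix) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(sorted(matrix.labels.items())).encode())
    arr = matrix.scores.fillna(-1.0).round(9).to_numpy()
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def train_model(
    matrix: CohortScoreMatrix,
    k: int = DEFAULT_K,
    cutoff: float = DEFAULT_CUTOFF,
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI,
    evaluability_fraction: float = DEFAULT_EVALUABILITY_FRACTION,
    qc: QCThresholds | None = None,
    seed: int | None = None,
) -> MarkerModel:
    """Train a marker model from a labeled cohort score matrix."""
    means = group_mean_scores(matrix, evaluability_fraction)
    markers = select_markers(means, matrix.loci, k=k)
    n_h = len(matrix.samples_in_class(MSI_H))
    n_s = len(matrix.samples_in_class(MSS))
    provenance = {
        "n_msih": n_h,
        "n_mss": n_s,
        "n_loci": len(matrix.scores),
        "seed": seed,
        "date": _dt.date.today().isoformat(),
        "cohort_fingerprint": _cohort_fingerprint(matrix),
    }
    return MarkerModel(
        marker_loci=markers,
        cutoff=cutoff,
        k=k,
        min_passing_loci=min_passing_loci,
        evaluability_fraction=evaluability_fraction,
        qc=qc or QCThresholds(),
        provenance=provenance,
    )


def evaluate(
    predictions: Mapping[str, str], labels: Mapping[str, str]
) -> dict[str, float]:
    """Sensitivity, specificity and overall percent agreement vs labels.

    MSI-H is the positive class.  Values are proportions in [0, 1].
    """
    if set(predictions) != set(labels):
        raise SampleSetMismatchError(
            f"sample ids differ: {sorted(set(predictions) ^ set(labels))}"
        )
    tp = sum(1 for s in labels if labels[s] == MSI_H and predictions[s] == MSI_H)
    fn = sum(1 for s in labels if labels[s] == MSI_H and predictions[s] != MSI_H)
    tn = sum(1 for s in labels if labels[s] == MSS and predictions[s] == MSS)
    fp = sum(1 for s in labels if labels[s] == MSS and predictions[s] != MSS)
    agree = sum(1 for s in labels if labels[s] == predictions[s])
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "opa": agree / len(labels),
    }
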