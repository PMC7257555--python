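"""On-disk formats: catalog TSV/BED, profiles, score matrices, models.

All artifacts are plain text (TSV or JSON) and every writer has a reader
that restores the object field-for-field, so pipelines can be stopped and
resumed at any stage and results audited by eye.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import platform
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import MicrosatelliteLocus
from .profiler import QCThresholds, RepeatLengthDistribution
from .scoring import LocusScore, SampleResult
from .training import MODEL_FORMAT_VERSION, CohortScoreMatrix, MarkerModel


class ModelVersionError(ValueError):
    """Raised when a model file was written by an incompatible version."""


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["contig", "start", "end", "name", "ref_repeat_count", "unit"]


def write_catalog(path: str, catalog: Sequence[MicrosatelliteLocus]) -> None:
    """BED6-like TSV: contig, start, end, name, ref_repeat_count, unit."""
    rows = [
        (l.contig, l.start, l.end, l.name or ".", l.ref_repeat_count, l.unit)
        for l in catalog
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    loci = []
    for row in df.itertuples(index=False):
        name = None if row.name in (".", "", None) or pd.isna(row.name) else str(row.name)
        loci.append(
            MicrosatelliteLocus(
                str(row.contig), int(row.start), int(row.end), str(row.unit), name
            )
        )
    return loci


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """BED3+ intervals (0-based half-open), comment/track lines ignored."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals


def write_bed(path: str, catalog: Sequence[MicrosatelliteLocus]) -> None:
    with open(path, "w") as fh:
        for l in catalog:
            fh.write(f"{l.contig}\t{l.start}\t{l.end}\t{l.name or '.'}\n")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _counts_to_str(counts: Mapping[int, int]) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(counts.items())) or "."


def _counts_from_str(s: str) -> dict[int, int]:
    if s in (".", "", None) or (isinstance(s, float) and np.isnan(s)):
        return {}
    return {
        int(k): int(v) for k, v in (pair.split(":") for pair in str(s).split(","))
    }


def write_profiles(
    path: str, profiles: Mapping[str, RepeatLengthDistribution]
) -> None:
    """Per-sample locus profile TSV: locus, coverage, tract quality, counts."""
    rows = [
        (
            key,
            d.coverage,
            round(d.mean_tract_quality, 4) if d.coverage else "nan",
            _counts_to_str(d.counts),
        )
        for key, d in profiles.items()
    ]
    pd.DataFrame(
        rows, columns=["locus", "coverage", "mean_tract_quality", "counts"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str) -> dict[str, RepeatLengthDistribution]:
    df = pd.read_csv(path, sep="\t", dtype={"counts": str})
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.locus)] = RepeatLengthDistribution(
            str(row.locus),
            _counts_from_str(row.counts),
            float(row.mean_tract_quality),
        )
    return out


# ---------------------------------------------------------------------------
# Cohort matrix
# ---------------------------------------------------------------------------

def write_matrix(path: str, matrix: CohortScoreMatrix) -> None:
    """Loci x samples TSV with a second header row of class labels."""
    df = matrix.scores.copy()
    df.index.name = "locus"
    labeled = pd.concat(
        [pd.DataFrame([{s: matrix.labels[s] for s in df.columns}], index=["#label"]), df]
    )
    labeled.to_csv(path, sep="\t")


def read_matrix(
    path: str, loci: Sequence[MicrosatelliteLocus] | None = None
) -> CohortScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = {s: str(df.loc["#label", s]) for s in df.columns}
    scores = df.drop(index="#label").astype(float)
    scores.index.name = None
    return CohortScoreMatrix(scores, labels, list(loci) if loci else [])


# ---------------------------------------------------------------------------
# Marker model
# ---------------------------------------------------------------------------

def _locus_to_dict(l: MicrosatelliteLocus) -> dict:
    return {
        "contig": l.contig,
        "start": l.start,
        "end": l.end,
        "unit": l.unit,
        "name": l.name,
    }


def write_model(path: str, model: MarkerModel) -> None:
    payload = {
        "format_version": model.format_version,
        "tool_version": __version__,
        "marker_loci": [_locus_to_dict(l) for l in model.marker_loci],
        "cutoff": model.cutoff,
        "k": model.k,
        "min_passing_loci": model.min_passing_loci,
        "evaluability_fraction": model.evaluability_fraction,
        "qc": dataclasses.asdict(model.qc),
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str) -> MarkerModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"model file {path!r} has format_version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    loci = [MicrosatelliteLocus(**d) for d in payload["marker_loci"]]
    return MarkerModel(
        marker_loci=loci,
        cutoff=payload["cutoff"],
        k=payload["k"],
        min_passing_loci=payload["min_passing_loci"],
        evaluability_fraction=payload["evaluability_fraction"],
        qc=QCThresholds(**payload["qc"]),
        provenance=payload.get("provenance", {}),
        format_version=version,
    )


# ---------------------------------------------------------------------------
# Results and provenance
# ---------------------------------------------------------------------------

def write_sample_results(path: str, results: Sequence[SampleResult]) -> None:
    pd.DataFrame(
        [
            (r.sample_id, round(r.msi_score, 6), r.n_loci_evaluated,
             r.n_loci_passing, r.status, r.cutoff_used)
            for r in results
        ],
        columns=["sample", "msi_score", "n_loci", "n_pass", "status", "cutoff"],
    ).to_csv(path, sep="\t", index=False)


def write_locus_scores(path: str, scores: Sequence[LocusScore]) -> None:
    pd.DataFrame(
        [
            (s.locus_key, "" if s.l1 is None else round(s.l1, 6), s.qc_pass)
            for s in scores
        ],
        columns=["locus", "l1", "qc_pass"],
    ).to_csv(path, sep="\t", index=False)


def result_to_dict(r: SampleResult) -> dict:
    return dataclasses.asdict(r)


def write_provenance(path: str, config_digest: str, seed: int,
                     extra: dict | None = None) -> None:
    """Record enough to reproduce a run exactly."""
    record = {
        "tool": "msical",
        "version": __version__,
        "config_digest": config_digest,
        "seed": seed,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "python": platform.python_version(),
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
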