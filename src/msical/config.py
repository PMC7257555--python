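"""Run configuration: every tunable in one serializable, loggable object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .catalog import ScanParams
from .profiler import QCThresholds
from .scoring import DEFAULT_CUTOFF, DEFAULT_MIN_PASSING_LOCI
from .training import DEFAULT_EVALUABILITY_FRACTION, DEFAULT_K


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML/JSON."""

    scan: ScanParams = field(default_factory=ScanParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    cutoff: float = DEFAULT_CUTOFF
    k: int = DEFAULT_K
    min_passing_loci: int = DEFAULT_MIN_PASSING_LOCI
    evaluability_fraction: float = DEFAULT_EVALUABILITY_FRACTION
    anchor: int = 3
    qc_mode: str = "allele_support"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "scan": dataclasses.asdict(self.scan),
            "qc": dataclasses.asdict(self.qc),
            "cutoff": self.cutoff,
            "k": self.k,
            "min_passing_loci": self.min_passing_loci,
            "evaluability_fraction": self.evaluability_fraction,
            "anchor": self.anchor,
            "qc_mode": self.qc_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scan = ScanParams(**d.pop("scan", {}))
        qc = QCThresholds(**d.pop("qc", {}))
        return cls(scan=scan, qc=qc, **d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} is not a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
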