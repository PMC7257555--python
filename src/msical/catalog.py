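"""Microsatellite locus discovery in reference sequences.

A microsatellite locus is a maximal tract of tandemly repeated copies of a
short primitive unit (1-5 bp).  The scanner reports every such tract whose
whole-copy length falls inside configurable bounds (default 10-100 bp),
which restricts it to tracts short enough to slip during PCR yet long
enough to be informative.  Tracts are canonicalized so a repeat region is
reported exactly once: the unit is primitive (not itself a repetition of a
shorter string) and the tract is anchored at the leftmost position where
its periodicity starts, ruling out duplicate reports under unit rotation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np

_VALID_BYTES = frozenset(b"ACGTN")
_N = ord("N")


class MalformedSequenceError(ValueError):
    """Raised when a reference sequence contains non-ACGTN characters."""


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One repeat tract in reference coordinates (0-based, half-open)."""

    contig: str
    start: int
    end: int
    unit: str
    name: str | None = None

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def ref_repeat_count(self) -> int:
        return (self.end - self.start) // len(self.unit)

    @property
    def key(self) -> str:
        """Stable string identifier used across profiles, matrices and models."""
        return f"{self.contig}:{self.start}-{self.end}:{self.unit}"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty locus interval [{self.start},{self.end})")
        if not (1 <= len(self.unit)):
            raise ValueError("unit must be non-empty")
        if (self.end - self.start) % len(self.unit) != 0:
            raise ValueError("tract length must be a whole number of unit copies")


@dataclass
class ScanParams:
    """Bounds on unit size and tract length for the scanner."""

    min_unit: int = 1
    max_unit: int = 5
    min_tract: int = 10
    max_tract: int = 100

    def __post_init__(self) -> None:
        if self.min_unit < 1:
            raise ValueError("min_unit must be >= 1")
        if self.max_unit < self.min_unit:
            raise ValueError("max_unit must be >= min_unit")
        if self.min_tract < self.min_unit:
            raise ValueError("min_tract must be >= min_unit")
        if self.max_tract < self.min_tract:
            raise ValueError("max_tract must be >= min_tract")


def is_primitive(unit: str) -> bool:
    """True if *unit* is not a whole-number repetition of a shorter string."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def _iter_sequences(
    sequences: Mapping[str, str] | Iterable[Tuple[str, str]]
) -> Iterator[Tuple[str, str]]:
    if isinstance(sequences, Mapping):
        yield from sequences.items()
    else:
        for name, seq in sequences:
            yield name, str(seq)


def _scan_contig(contig: str, seq: str, params: ScanParams) -> list[MicrosatelliteLocus]:
    raw = seq.upper().encode("ascii", errors="replace")
    bad = set(raw) - _VALID_BYTES
    if bad:
        raise MalformedSequenceError(
            f"contig {contig!r} contains non-ACGTN characters: "
            f"{sorted(chr(b) for b in bad)}"
        )
    a = np.frombuffer(raw, dtype=np.uint8)
    n = a.size
    loci: list[MicrosatelliteLocus] = []
    is_n = a == _N
    for k in range(params.min_unit, params.max_unit + 1):
        if n < 2 * k:
            continue
        # eq[j] marks period-k agreement between positions j and j+k;
        # N never matches, so tracts break at undefined bases.
        eq = (a[k:] == a[:-k]) & ~is_n[k:] & ~is_n[:-k]
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[0::2], edges[1::2]
        for i, e in zip(starts, ends):
            run_len = int(e - i)           # consecutive period-k agreements
            stretch = run_len + k          # periodic region [i, i+stretch)
            m = stretch // k               # whole unit copies, head-anchored
            tract_len = m * k
            if m < 2 or not (params.min_tract <= tract_len <= params.max_tract):
                continue
            unit = raw[i : i + k].decode("ascii")
            if not is_primitive(unit):
                continue  # the same region is reported under its true period
            loci.append(MicrosatelliteLocus(contig, int(i), int(i) + tract_len, unit))
    loci.sort(key=lambda l: (l.start, l.end, l.unit))
    return loci


def scan_reference(
    sequences: Mapping[str, str] | Iterable[Tuple[str, str]],
    params: ScanParams | None = None,
) -> list[MicrosatelliteLocus]:
    """Find every maximal microsatellite tract in a set of named sequences.

    Parameters
    ----------
    sequences
        Mapping or iterable of ``(name, sequence)``; sequences are uppercased
        before scanning, so soft-masked reference regions are scanned as
        ordinary sequence.  ``pyfaidx.Fasta.items()`` works directly.
    params
        Unit-size and tract-length bounds; defaults to 1-5 bp units and
        10-100 bp tracts.

    Returns
    -------
    list of :class:`MicrosatelliteLocus`, sorted by (contig, start).

    Raises
    ------
    MalformedSequenceError
        If a sequence contains characters outside ACGTN (case-insensitive).
    """
    params = params or ScanParams()
    per_contig: dict[str, list[MicrosatelliteLocus]] = {}
    for name, seq in _iter_sequences(sequences):
        per_contig[name] = _scan_contig(name, seq, params)
    out: list[MicrosatelliteLocus] = []
    for name in sorted(per_contig):
        out.extend(per_contig[name])
    return out


def intersect_panel(
    catalog: Sequence[MicrosatelliteLocus],
    panel: Iterable[Tuple[str, int, int]],
) -> list[MicrosatelliteLocus]:
    """Keep loci wholly contained in some panel interval (order preserved).

    Containment, not mere overlap, is required: profiling needs reads that
    span the entire tract, so a tract hanging off the edge of a captured
    region cannot be evaluated.
    """
    by_contig: dict[str, list[Tuple[int, int]]] = {}
    for contig, start, end in panel:
        by_contig.setdefault(contig, []).append((int(start), int(end)))
    starts_by_contig: dict[str, list[int]] = {}
    for contig, ivals in by_contig.items():
        ivals.sort()
        starts_by_contig[contig] = [s for s, _ in ivals]

    kept = []
    for locus in catalog:
        ivals = by_contig.get(locus.contig)
        if not ivals:
            continue
        # only intervals starting at or before the locus can contain it
        idx = bisect.bisect_right(starts_by_contig[locus.contig], locus.start)
        if any(locus.end <= e for _, e in ivals[:idx]):
            kept.append(locus)
    return kept


def select_mononucleotide(
    catalog: Sequence[MicrosatelliteLocus],
) -> list[MicrosatelliteLocus]:
    """Subset of the catalog with single-base repeat units (homopolymers)."""
    return [locus for locus in catalog if locus.unit_len == 1]


def validate_locus(locus: MicrosatelliteLocus, seq: str) -> bool:
    """Re-check tiling and maximality of a locus against its reference.

    The substring [start, end) must be an exact head-anchored tiling of the
    unit, and the tract must not be extendable by one whole unit copy on
    either side.
    """
    s = seq.upper()
    unit, k = locus.unit, locus.unit_len
    tract = s[locus.start : locus.end]
    if tract != unit * locus.ref_repeat_count:
        return False
    if locus.start >= k and s[locus.start - k : locus.start] == unit:
        return False
    if s[locus.end : locus.end + k] == unit:
        return False
    return True
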