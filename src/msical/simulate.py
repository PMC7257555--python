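"""Ground-truthed synthetic data: references, reads, cohorts, dilutions.

Everything downstream of sequencing is exercisable from this module alone:
it builds a reference contig embedding homopolymer tracts at known
coordinates, emits pre-aligned tumor/normal reads with a PCR-stutter noise
model and somatic repeat-unit shifts at a given tumor purity, mixes tumor
with matched normal reads to emulate dilution series, and assembles whole
labeled cohorts for panel training.

The stutter model is per read: with probability ``stutter_prob`` a read's
observed repeat count deviates from its template by ``d`` units, where
|d| follows a truncated geometric law (``step_decay``) and deviations are
contractions with probability ``deletion_bias``.  Slippage is more likely
the longer the tract, so the per-locus stutter probability grows linearly
with template length (``length_slope`` per base away from a 13 bp
reference length); that heterogeneity is what makes some loci intrinsically
quiet in stable samples and is the reality that rank-overlap marker
selection exploits.

Determinism contract: identical seed and parameters give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pysam

from .catalog import MicrosatelliteLocus, ScanParams, scan_reference
from .profiler import QCThresholds, RepeatLengthDistribution, profile_locus
from .scoring import MSI_H, MSS

_BASES = "ACGT"
DEFAULT_SOMATIC_SHIFT = -3


@dataclass
class StutterModel:
    """Per-read PCR/sequencing slippage model for repeat tracts."""

    stutter_prob: float = 0.10        # deviation probability at ref_tract_len
    step_decay: float = 0.3           # geometric decay of |deviation|
    deletion_bias: float = 0.8        # fraction of deviations that contract
    length_slope: float = 0.02        # stutter-probability change per base
    ref_tract_len: int = 13           # tract length where stutter_prob applies
    max_step: int = 5                 # deviations truncated to +/- max_step
    min_prob: float = 0.01
    max_prob: float = 0.60

    def __post_init__(self) -> None:
        for name in ("stutter_prob", "step_decay", "deletion_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def locus_stutter_prob(self, tract_len: int) -> float:
        p = self.stutter_prob + self.length_slope * (tract_len - self.ref_tract_len)
        lo = min(self.min_prob, self.stutter_prob)  # explicit 0 stays 0
        return float(min(max(p, lo), self.max_prob))

    def deviation_probs(self, tract_len: int) -> tuple[np.ndarray, np.ndarray]:
        """Deviations -max_step..+max_step and their probabilities (sum 1)."""
        s = self.locus_stutter_prob(tract_len)
        steps = np.arange(1, self.max_step + 1)
        w = self.step_decay ** (steps - 1)
        w = w / w.sum()
        devs = np.arange(-self.max_step, self.max_step + 1)
        probs = np.zeros_like(devs, dtype=float)
        probs[self.max_step] = 1.0 - s
        probs[self.max_step - steps] = s * self.deletion_bias * w
        probs[self.max_step + steps] = s * (1.0 - self.deletion_bias) * w
        return devs, probs


@dataclass
class LocusTruth:
    """Ground truth for one locus in one simulated tumor."""

    locus: MicrosatelliteLocus
    germline: int                  # germline repeat count (units)
    somatic_shift: int = 0         # units gained/lost by the somatic allele


@dataclass
class SimTruth:
    """Ground truth and generation parameters for one simulated sample."""

    loci: list[LocusTruth]
    purity: float                  # tumor-cell fraction of the specimen
    somatic_fraction: float = 1.0  # fraction of tumor cells with the shift
    coverage: int = 100            # spanning reads per locus
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if not (0.0 <= self.somatic_fraction <= 1.0):
            raise ValueError("somatic_fraction must be in [0,1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SimulatedRead:
    """A pre-aligned read with its per-read ground truth."""

    name: str
    contig: str
    pos: int                        # 0-based leftmost reference position
    cigar: str
    sequence: str
    qualities: list[int]
    locus_key: str
    template_count: int
    observed_count: int
    is_somatic: bool


def truth_from_catalog(
    catalog: Sequence[MicrosatelliteLocus],
    purity: float,
    unstable_keys: Sequence[str] = (),
    somatic_shift: int = DEFAULT_SOMATIC_SHIFT,
    somatic_fraction: float = 1.0,
    coverage: int = 100,
    read_length: int = 100,
    seed: int = 0,
) -> SimTruth:
    """SimTruth with germline counts equal to the reference repeat counts."""
    unstable = set(unstable_keys)
    loci = [
        LocusTruth(
            locus=l,
            germline=l.ref_repeat_count,
            somatic_shift=somatic_shift if l.key in unstable else 0,
        )
        for l in catalog
    ]
    return SimTruth(loci, purity, somatic_fraction, coverage, read_length, seed)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_flank(
    rng: np.random.Generator,
    length: int,
    context: str,
    next_base: str | None,
    max_stretch: int = 8,
) -> str | None:
    """Random flank with no microsatellite-forming periodicity.

    Bases never equal either of the two preceding bases (killing 1- and
    2-periodic runs outright) and never extend a 3/4/5-periodic stretch,
    measured over *context* + flank, beyond *max_stretch* bases.  Returns
    None if the constraints dead-end (caller retries).
    """
    tail = list(context[-5:])
    runs = {k: 0 for k in (3, 4, 5)}  # current lag-k match run ending at tail
    for k in runs:
        r = 0
        while (
            r + k < len(tail)
            and tail[-1 - r] == tail[-1 - r - k]
        ):
            r += 1
        runs[k] = r
    out: list[str] = []
    for i in range(length):
        banned = set(tail[-2:]) if len(tail) >= 2 else set(tail)
        for k, r in runs.items():
            if len(tail) >= k and r + 1 + k > max_stretch:
                banned.add(tail[-k])
        if i == length - 1 and next_base is not None:
            banned.add(next_base)
        choices = [b for b in _BASES if b not in banned]
        if not choices:
            return None
        b = choices[int(rng.integers(len(choices)))]
        for k in list(runs):
            runs[k] = runs[k] + 1 if len(tail) >= k and tail[-k] == b else 0
        out.append(b)
        tail.append(b)
    return "".join(out)


def make_reference(
    n_loci: int,
    tract_lengths: int | Sequence[int] = 14,
    spacing: int = 250,
    seed: int = 0,
    read_length: int = 100,
    contig: str = "sim1",
    units: Sequence[str] | None = None,
) -> tuple[dict[str, str], list[MicrosatelliteLocus]]:
    """One contig embedding homopolymer tracts at exactly known coordinates.

    Parameters
    ----------
    n_loci
        Number of mononucleotide tracts to embed.
    tract_lengths
        One length for all loci, or a per-locus sequence (cycled if
        shorter than *n_loci*).
    spacing
        Flank length between tracts; must exceed *read_length* so reads
        never span two loci.
    seed
        Drives flank sequence and unit choice; two seeds give different
        flanks but identical locus geometry.

    Returns
    -------
    (sequences, catalog) where ``sequences`` maps the contig name to its
    sequence and ``catalog`` lists the embedded loci in order.  The
    construction is verified by re-scanning: the scanner must recover
    exactly the truth catalog, otherwise the flanks are regenerated.
    """
    if spacing <= read_length:
        raise ValueError(
            f"spacing ({spacing}) must exceed read length ({read_length})"
        )
    if isinstance(tract_lengths, int):
        lengths = [tract_lengths] * n_loci
    else:
        tl = list(tract_lengths)
        lengths = [tl[i % len(tl)] for i in range(n_loci)]

    for attempt in range(20):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        if units is None:
            chosen_units = [_BASES[int(rng.integers(4))] for _ in range(n_loci)]
        else:
            chosen_units = [units[i % len(units)] for i in range(n_loci)]
        parts: list[str] = []
        loci: list[MicrosatelliteLocus] = []
        pos = 0
        context = "TGCA"  # harmless bootstrap context
        ok = True
        for i in range(n_loci):
            flank = None
            for _ in range(10):
                flank = _random_flank(rng, spacing, context, chosen_units[i])
                if flank is not None:
                    break
            if flank is None:
                ok = False
                break
            parts.append(flank)
            pos += len(flank)
            tract = chosen_units[i] * lengths[i]
            loci.append(
                MicrosatelliteLocus(
                    contig, pos, pos + lengths[i], chosen_units[i],
                    name=f"ms{i:04d}",
                )
            )
            parts.append(tract)
            pos += lengths[i]
            context = (flank + tract)[-5:]
        if not ok:
            continue
        final = None
        for _ in range(10):
            final = _random_flank(rng, spacing, context, None)
            if final is not None:
                break
        if final is None:
            continue
        parts.append(final)
        seq = "".join(parts)
        params = ScanParams(min_tract=min(10, min(lengths))) if lengths else ScanParams()
        found = scan_reference({contig: seq}, params)
        truth_set = {(l.start, l.end, l.unit) for l in loci}
        found_set = {(l.start, l.end, l.unit) for l in found}
        if truth_set == found_set:
            return {contig: seq}, loci
    raise RuntimeError("could not build a clean reference in 20 attempts")


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def _draw_observed(
    rng: np.random.Generator, template: int, stutter: StutterModel
) -> int:
    devs, probs = stutter.deviation_probs(template)
    d = int(rng.choice(devs, p=probs))
    return max(template + d, 0)


def simulate_sample(
    truth: SimTruth,
    reference: Mapping[str, str],
    stutter: StutterModel | None = None,
    sample_tag: str = "s0",
) -> list[SimulatedRead]:
    """Emit pre-aligned spanning reads for every locus of one sample.

    Each read's template allele is the shifted somatic allele with
    probability ``purity * somatic_fraction`` (at loci with a non-zero
    shift), otherwise the germline allele; the observed repeat count adds
    a stutter deviation.  Placement, CIGAR and per-read truth are exact by
    construction, so no aligner is needed downstream.  Base qualities are
    drawn around Phred 35 (SD 3) so default read/locus QC passes.
    """
    stutter = stutter or StutterModel()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 911]))
    reads: list[SimulatedRead] = []
    rl = truth.read_length
    margin = 8  # minimum flank bases inside the read on each side
    p_som = truth.purity * truth.somatic_fraction
    for li, lt in enumerate(truth.loci):
        locus = lt.locus
        ref = reference[locus.contig]
        ref_tract = locus.end - locus.start
        for ri in range(truth.coverage):
            somatic = lt.somatic_shift != 0 and rng.random() < p_som
            template = lt.germline + (lt.somatic_shift if somatic else 0)
            template = max(template, 0)
            obs = _draw_observed(rng, template, stutter)
            max_obs = lt.germline + stutter.max_step
            left_hi = rl - max_obs - margin
            left = int(rng.integers(margin, max(left_hi, margin + 1)))
            right = rl - left - obs
            rstart = locus.start - left
            seq = (
                ref[rstart : locus.start]
                + locus.unit * obs
                + ref[locus.end : locus.end + right]
            )
            cig: list[tuple[int, int]] = [(0, left)]
            common = min(obs, ref_tract)
            if common:
                cig.append((0, common))
            if obs < ref_tract:
                cig.append((2, ref_tract - obs))       # deletion
            elif obs > ref_tract:
                cig.append((1, obs - ref_tract))       # insertion
            cig.append((0, right))
            merged: list[tuple[int, int]] = []
            for op, ln in cig:
                if ln == 0:
                    continue
                if merged and merged[-1][0] == op:
                    merged[-1] = (op, merged[-1][1] + ln)
                else:
                    merged.append((op, ln))
            cigar = "".join(f"{ln}{'MID'[op]}" for op, ln in merged)
            quals = np.clip(
                np.rint(rng.normal(35.0, 3.0, size=len(seq))), 2, 40
            ).astype(int)
            reads.append(
                SimulatedRead(
                    name=f"{sample_tag}_l{li:04d}_r{ri:04d}",
                    contig=locus.contig,
                    pos=rstart,
                    cigar=cigar,
                    sequence=seq,
                    qualities=[int(q) for q in quals],
                    locus_key=locus.key,
                    template_count=template,
                    observed_count=obs,
                    is_somatic=somatic,
                )
            )
    reads.sort(key=lambda r: (r.contig, r.pos, r.name))
    return reads


def _sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
        }
    )


def to_pysam(read: SimulatedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.name
    seg.query_sequence = read.sequence
    seg.flag = 0
    seg.reference_id = header.get_tid(read.contig)
    seg.reference_start = read.pos
    seg.mapping_quality = 60
    seg.cigarstring = read.cigar
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.qualities)
    )
    return seg


def write_sam(
    path: str, reads: Sequence[SimulatedRead], reference: Mapping[str, str]
) -> None:
    """Write reads as coordinate-sorted SAM (.sam) or BAM (.bam)."""
    header = _sam_header(reference)
    mode = "wb" if str(path).endswith(".bam") else "w"
    ordered = sorted(reads, key=lambda r: (r.contig, r.pos, r.name))
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for read in ordered:
            out.write(to_pysam(read, header))


def write_fastq(path: str, reads: Sequence[SimulatedRead]) -> None:
    """Optional FASTQ export for users who want to run their own aligner."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in read.qualities) + "\n")


def write_fasta(path: str, reference: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def reads_to_profiles(
    reads: Sequence[SimulatedRead],
    catalog: Sequence[MicrosatelliteLocus],
    reference: Mapping[str, str],
    anchor: int = 3,
) -> dict[str, RepeatLengthDistribution]:
    """Profile simulated reads in memory (no SAM round-trip)."""
    header = _sam_header(reference)
    by_key: dict[str, list[pysam.AlignedSegment]] = {l.key: [] for l in catalog}
    for read in reads:
        if read.locus_key in by_key:
            by_key[read.locus_key].append(to_pysam(read, header))
    return {
        l.key: profile_locus(by_key[l.key], l, reference[l.contig], anchor=anchor)
        for l in catalog
    }


# ---------------------------------------------------------------------------
# Dilution
# ---------------------------------------------------------------------------

def effective_purity(fraction: float, purity: float) -> float:
    """Tumor purity after diluting tumor DNA into matched normal DNA."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"dilution fraction must be in [0,1], got {fraction}")
    return fraction * purity


def dilute(
    tumor_reads: Sequence[SimulatedRead],
    normal_reads: Sequence[SimulatedRead],
    fraction: float,
    target_coverage: int | None = None,
    seed: int = 0,
    tumor_purity: float | None = None,
) -> tuple[list[SimulatedRead], dict]:
    """In-silico dilution: per locus, draw reads from the tumor pool with
    probability *fraction*, otherwise from the matched normal pool.

    Returns the mixed reads and a metadata dict recording the fraction and
    (when the tumor purity is supplied) the effective purity
    ``fraction * purity``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"dilution fraction must be in [0,1], got {fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2718]))
    by_key_t: dict[str, list[SimulatedRead]] = {}
    by_key_n: dict[str, list[SimulatedRead]] = {}
    for r in tumor_reads:
        by_key_t.setdefault(r.locus_key, []).append(r)
    for r in normal_reads:
        by_key_n.setdefault(r.locus_key, []).append(r)
    mixed: list[SimulatedRead] = []
    for key in sorted(by_key_t):
        t_pool = by_key_t[key]
        n_pool = by_key_n.get(key, [])
        n_out = target_coverage if target_coverage is not None else len(t_pool)
        n_t = int(rng.binomial(n_out, fraction))
        n_t = min(n_t, len(t_pool))
        n_n = min(n_out - n_t, len(n_pool))
        idx_t = rng.choice(len(t_pool), size=n_t, replace=False)
        idx_n = rng.choice(len(n_pool), size=n_n, replace=False) if n_pool else []
        mixed.extend(t_pool[i] for i in idx_t)
        mixed.extend(n_pool[i] for i in idx_n)
    mixed.sort(key=lambda r: (r.contig, r.pos, r.name))
    meta = {
        "fraction": fraction,
        "effective_purity": (
            effective_purity(fraction, tumor_purity)
            if tumor_purity is not None
            else None
        ),
    }
    return mixed, meta


# ---------------------------------------------------------------------------
# Distribution-level sampling and cohorts
# ---------------------------------------------------------------------------

def sample_profile(
    rng: np.random.Generator,
    lt: LocusTruth,
    p_somatic: float,
    coverage: int,
    stutter: StutterModel,
) -> RepeatLengthDistribution:
    """Draw one locus's repeat-length histogram directly.

    Statistically identical to simulating *coverage* error-free spanning
    reads and profiling them: each read's template is somatic with
    probability *p_somatic*, and stutter deviations are multinomial.
    """
    counts: dict[int, int] = {}
    n_som = int(rng.binomial(coverage, p_somatic)) if lt.somatic_shift != 0 else 0
    for template, n in (
        (lt.germline, coverage - n_som),
        (max(lt.germline + lt.somatic_shift, 0), n_som),
    ):
        if n == 0:
            continue
        devs, probs = stutter.deviation_probs(template)
        draws = rng.multinomial(n, probs)
        for d, c in zip(devs, draws):
            if c:
                k = max(template + int(d), 0)
                counts[k] = counts.get(k, 0) + int(c)
    mean_q = float(35.0 + rng.normal(0.0, 3.0 / math.sqrt(coverage)))
    return RepeatLengthDistribution(lt.locus.key, counts, mean_q)


@dataclass
class CohortSample:
    sample_id: str
    label: str
    purity: float
    tumor_profiles: dict[str, RepeatLengthDistribution]
    normal_profiles: dict[str, RepeatLengthDistribution]


@dataclass
class Cohort:
    """A labeled synthetic cohort with full ground truth."""

    samples: list[CohortSample]
    catalog: list[MicrosatelliteLocus]
    reference: dict[str, str]
    informative_keys: list[str]
    somatic_shift: int
    seed: int

    @property
    def labels(self) -> dict[str, str]:
        return {s.sample_id: s.label for s in self.samples}

    @property
    def profiles(self) -> dict[str, tuple[dict, dict]]:
        return {
            s.sample_id: (s.tumor_profiles, s.normal_profiles)
            for s in self.samples
        }


def make_cohort(
    n_msih: int = 7,
    n_mss: int = 21,
    n_loci: int = 363,
    n_informative: int = 9,
    seed: int = 0,
    coverage: int = 100,
    somatic_shift: int = DEFAULT_SOMATIC_SHIFT,
    somatic_fraction: float = 1.0,
    purity_range: tuple[float, float] = (0.25, 0.65),
    stutter: StutterModel | None = None,
    read_level: bool = False,
    read_length: int = 100,
    spacing: int = 250,
    informative_tract_len: int = 10,
    background_tract_lens: Sequence[int] = tuple(range(11, 25)),
    sample_prefix: str = "S",
    sample_seed: int | None = None,
) -> Cohort:
    """Generate a labeled cohort of paired tumor/normal samples.

    MSI-H tumors carry clonal somatic contractions (*somatic_shift* units)
    at *n_informative* designated loci, at a per-sample purity drawn from
    *purity_range*; MSS tumors carry no somatic shifts anywhere.  The
    informative loci are given the shortest (lowest-stutter) tracts so the
    marker-selection problem is identifiable, mirroring the fact that
    clinically useful marker loci are unusually quiet in stable samples.

    With ``read_level=True`` every sample is simulated as aligned reads
    and pushed through the read profiler (slow; meant for small *n_loci*);
    the default draws the per-locus histograms directly from the same
    generative law.

    *seed* fixes the reference geometry (flanks, units, which loci are
    informative); *sample_seed* (default: same as *seed*) fixes the sample
    draws.  Keeping *seed* and varying *sample_seed* yields independent
    cohorts over the same locus catalog, e.g. a validation cohort for a
    model trained on another cohort's scores.
    """
    if n_informative > n_loci:
        raise ValueError("n_informative must be <= n_loci")
    stutter = stutter or StutterModel()
    master = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    bg = list(background_tract_lens)
    lengths = [bg[i % len(bg)] for i in range(n_loci)]
    informative_idx = sorted(
        int(i) for i in master.choice(n_loci, size=n_informative, replace=False)
    )
    for i in informative_idx:
        lengths[i] = informative_tract_len
    reference, catalog = make_reference(
        n_loci,
        tract_lengths=lengths,
        spacing=spacing,
        seed=int(master.integers(2**31 - 1)),
        read_length=read_length,
    )
    informative_keys = [catalog[i].key for i in informative_idx]

    samples: list[CohortSample] = []
    labels = [MSI_H] * n_msih + [MSS] * n_mss
    draw_seed = seed if sample_seed is None else sample_seed
    for si, label in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([draw_seed, 202, si]))
        purity = (
            float(rng.uniform(*purity_range)) if label == MSI_H else 0.0
        )
        sample_id = f"{sample_prefix}{si:03d}"
        if read_level:
            truth_t = truth_from_catalog(
                catalog, purity, informative_keys if label == MSI_H else (),
                somatic_shift, somatic_fraction, coverage, read_length,
                seed=int(rng.integers(2**31 - 1)),
            )
            truth_n = truth_from_catalog(
                catalog, 0.0, (), 0, somatic_fraction, coverage, read_length,
                seed=int(rng.integers(2**31 - 1)),
            )
            t_reads = simulate_sample(truth_t, reference, stutter, f"{sample_id}T")
            n_reads = simulate_sample(truth_n, reference, stutter, f"{sample_id}N")
            tumor = reads_to_profiles(t_reads, catalog, reference)
            normal = reads_to_profiles(n_reads, catalog, reference)
        else:
            p_som = purity * somatic_fraction if label == MSI_H else 0.0
            tumor, normal = {}, {}
            for li, locus in enumerate(catalog):
                lt = LocusTruth(
                    locus,
                    germline=locus.ref_repeat_count,
                    somatic_shift=(
                        somatic_shift
                        if label == MSI_H and locus.key in set(informative_keys)
                        else 0
                    ),
                )
                tumor[locus.key] = sample_profile(rng, lt, p_som, coverage, stutter)
                normal[locus.key] = sample_profile(rng, lt, 0.0, coverage, stutter)
        samples.append(CohortSample(sample_id, label, purity, tumor, normal))
    return Cohort(
        samples=samples,
        catalog=list(catalog),
        reference=dict(reference),
        informative_keys=informative_keys,
        somatic_shift=somatic_shift,
        seed=seed,
    )
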