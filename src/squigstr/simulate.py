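"""Synthetic nanopore-like data with known repeat alleles.

Nanopore current for a sequence context is a distribution, not a value: the
simulator realizes this premise with a per-k-mer Gaussian pore model (mean,
sd per k-mer, in normalized signal units) and a per-event dwell drawn from a
shifted geometric distribution (several raw samples per base).  Given a
locus specification (flanks, unit, 1-2 alleles with read fractions, jitter,
truncation), it emits raw traces, event tables, per-base truth labels, and
exact alignment records against the flank+array reference, so every stage of
the detector is trainable and testable without real sequencing data.

It does not model pore chemistry, homopolymer compression, systematic
miscalls, or modified-base effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .events import EventTable, Event, RawRead, SIGNAL_MAX, SIGNAL_MIN
from .imaging import Label
from .motifs import STRRegion, canonical_group

__all__ = [
    "PoreModel",
    "DwellModel",
    "SimLocusSpec",
    "SimDataset",
    "make_pore_model",
    "simulate_read",
    "simulate_locus_dataset",
    "random_flank",
]

#: device-unit emulation: sample = DEVICE_OFFSET + DEVICE_SCALE * normalized
DEVICE_OFFSET, DEVICE_SCALE = 100.0, 20.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_index(seq: str) -> int:
    idx = 0
    for c in seq:
        idx = idx * 4 + _BASE_INDEX[c]
    return idx


@dataclass(frozen=True)
class PoreModel:
    """Per-k-mer Gaussian current model in normalized units."""

    k: int
    means: np.ndarray   # (4**k,), within [-4, 4]
    sds: np.ndarray     # (4**k,), > 0
    seed: int

    def lookup(self, kmer: str) -> tuple[float, float]:
        i = _kmer_index(kmer)
        return float(self.means[i]), float(self.sds[i])


@dataclass(frozen=True)
class DwellModel:
    """Samples per event: ``min_dwell`` plus a geometric tail (mean ``mean_dwell``)."""

    mean_dwell: float = 9.0
    min_dwell: int = 3

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        extra_mean = self.mean_dwell - self.min_dwell
        # geometric(p) on {1, 2, ...} has mean 1/p
        p = 1.0 / (extra_mean + 1.0)
        return (self.min_dwell - 1) + rng.geometric(p, size=n)


def _unit_interior_kmers(unit: str, k: int) -> list[str]:
    """The k-mers a pore sees while fully inside a long tandem array."""
    tiled = unit * (k // len(unit) + 2)
    return sorted({tiled[i : i + k] for i in range(len(unit))})


def make_pore_model(
    seed: int,
    k: int = 6,
    preset: str = "random",
    unit: str | None = None,
) -> PoreModel:
    """Build a seeded pore model.

    ``preset="random"``: means i.i.d. uniform in [-4, 4], sds uniform in
    [0.15, 0.5].  ``preset="separable"`` (requires ``unit``): the repeat
    unit's interior k-mers get means in [2.5, 4] while every other k-mer
    stays in [-4, 0.5], guaranteeing >= 2 normalized units of separation
    between unit-interior and flanking contexts.
    """
    if k not in (4, 5, 6):
        raise ValueError("k must be 4, 5, or 6")
    rng = np.random.default_rng(seed)
    n = 4**k
    sds = rng.uniform(0.15, 0.5, size=n)
    if preset == "random":
        means = rng.uniform(-4.0, 4.0, size=n)
    elif preset == "separable":
        if unit is None:
            raise ValueError("the separable preset needs the repeat unit")
        means = rng.uniform(-4.0, 0.5, size=n)
        for km in _unit_interior_kmers(unit.upper(), k):
            means[_kmer_index(km)] = rng.uniform(2.5, 4.0)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return PoreModel(k=k, means=means, sds=sds, seed=seed)


def simulate_read(
    template: str,
    pore: PoreModel,
    dwell: DwellModel,
    seed: int,
    *,
    read_id: str = "sim",
    repeat_interval: tuple[int, int] | None = None,
    truth_override: np.ndarray | None = None,
    device_units: bool = False,
) -> tuple[RawRead, EventTable, np.ndarray]:
    """Draw one read: per-base events with Gaussian samples from the k-mer context.

    The context of base i is the k-mer starting at min(i, L-k).  Truth labels
    are REPEAT inside ``repeat_interval`` (read coordinates, half-open) and
    NOT_REPEAT outside, unless ``truth_override`` supplies per-base labels
    (used for injected 1-bp indels).  ``device_units`` re-expresses samples
    as offset + scale * normalized to exercise read normalization.
    """
    template = template.upper()
    if any(c not in _BASE_INDEX for c in template):
        raise ValueError("template contains non-ACGT symbols")
    L = len(template)
    if L < 2 * pore.k:
        raise ValueError(f"template must be >= {2 * pore.k} bases")
    rng = np.random.default_rng(seed)
    dwells = dwell.draw(rng, L)
    total = int(dwells.sum())
    samples = np.empty(total, dtype=np.float64)
    events = []
    pos = 0
    for i in range(L):
        c = min(i, L - pore.k)
        mu, sd = pore.lookup(template[c : c + pore.k])
        n = int(dwells[i])
        samples[pos : pos + n] = rng.normal(mu, sd, size=n)
        events.append(Event(base=template[i], start=pos, length=n))
        pos += n
    samples = np.clip(samples, SIGNAL_MIN, SIGNAL_MAX)
    normalized = True
    if device_units:
        samples = DEVICE_OFFSET + DEVICE_SCALE * samples
        normalized = False
    if truth_override is not None:
        truth = np.asarray(truth_override, dtype=np.int8)
        if truth.size != L:
            raise ValueError("truth_override length mismatch")
    else:
        truth = np.full(L, Label.NOT_REPEAT, dtype=np.int8)
        if repeat_interval is not None:
            a, b = repeat_interval
            truth[a:b] = Label.REPEAT
    raw = RawRead(read_id=read_id, samples=samples, source="simulator")
    table = EventTable(read_id=read_id, events=tuple(events), normalized=normalized)
    return raw, table, truth


@dataclass(frozen=True)
class SimLocusSpec:
    """Study design for one simulated locus.

    ``alleles`` holds 1-2 repeat counts and ``fractions`` their per-read
    sampling probabilities (summing to 1).  ``jitter_sd`` perturbs each
    read's true count (Normal, rounded, floored at 3), emulating within-array
    mosaicism and segmentation noise.  ``ref_count`` is the repeat count in
    the alignment reference (defaults to the first allele).
    """

    unit: str
    left_flank: str
    right_flank: str
    alleles: tuple[int, ...]
    fractions: tuple[float, ...]
    n_reads: int
    jitter_sd: float = 0.0
    truncation_prob: float = 0.0
    indel_rate: float = 0.0
    ref_count: int | None = None
    seed: int = 0
    chrom: str = "simchr"

    def __post_init__(self) -> None:
        if not self.alleles or len(self.alleles) > 2:
            raise ValueError("1 or 2 alleles required")
        if len(self.fractions) != len(self.alleles):
            raise ValueError("one fraction per allele")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(a < 3 for a in self.alleles):
            raise ValueError("allele repeat counts must be >= 3")


@dataclass
class SimDataset:
    """Everything the simulator knows about one locus' reads."""

    spec: SimLocusSpec
    reference: str
    region: STRRegion
    reads: list[tuple[RawRead, EventTable]]
    truth_labels: dict[str, np.ndarray]
    truth_counts: dict[str, int]
    truth_alleles: dict[str, int]
    truncated: dict[str, bool]
    alignments: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader

    def write(self, outdir: str, events_format: str = "hdf5", fastq: bool = False) -> None:
        """Write events, reference FASTA, SAM alignments, and the truth TSV."""
        import os

        from .events import write_event_table

        os.makedirs(outdir, exist_ok=True)
        ev_path = os.path.join(outdir, "events.h5" if events_format == "hdf5" else "events")
        write_event_table(ev_path, self.reads, format=events_format)
        with open(os.path.join(outdir, "reference.fa"), "w") as fh:
            fh.write(f">{self.spec.chrom}\n{self.reference}\n")
        with pysam.AlignmentFile(
            os.path.join(outdir, "alignments.sam"), "w", header=self.header
        ) as bam:
            for aln in self.alignments:
                bam.write(aln)
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("read_id\tallele\tcount\ttruncated\n")
            for rid in sorted(self.truth_counts):
                fh.write(
                    f"{rid}\t{self.truth_alleles[rid]}\t{self.truth_counts[rid]}\t"
                    f"{int(self.truncated[rid])}\n"
                )
        if fastq:
            with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
                for raw, table in self.reads:
                    seq = table.sequence
                    fh.write(f"@{raw.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _make_alignment(
    header: pysam.AlignmentHeader,
    read_id: str,
    seq: str,
    flank_left: int,
    read_rep: int,
    ref_rep: int,
    right_len: int,
) -> pysam.AlignedSegment:
    """Exact-by-construction alignment: flanks match; the repeat-length
    difference becomes one insertion or deletion at the array's 3' end."""
    a = pysam.AlignedSegment(header)
    a.query_name = read_id
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = 0
    a.reference_start = 0
    a.mapping_quality = 60
    cigar: list[tuple[int, int]] = []
    m = flank_left + min(read_rep, ref_rep)
    cigar.append((0, m))
    if read_rep > ref_rep:
        cigar.append((1, read_rep - ref_rep))
    elif read_rep < ref_rep:
        cigar.append((2, ref_rep - read_rep))
    if right_len:
        cigar.append((0, right_len))
    # drop a trailing deletion (truncated reads end before the array does)
    if cigar[-1][0] == 2:
        cigar.pop()
    a.cigartuples = cigar
    return a


def simulate_locus_dataset(
    spec: SimLocusSpec,
    pore: PoreModel | None = None,
    dwell: DwellModel | None = None,
    *,
    device_units: bool = False,
) -> SimDataset:
    """Simulate all reads of one locus, with truth and exact alignments.

    Per read: an allele is drawn by fraction, its count jittered (Normal,
    rounded, floored at 3); optional 1-bp indels are injected inside the
    array (insertion duplicates a base, deletion drops one, with truth
    labels INS/DEL on the read base carrying the evidence); with probability
    ``truncation_prob`` the read ends uniformly inside the array.  An empty
    right flank gives the single-flank (telomeric) geometry.
    """
    rng = np.random.default_rng(spec.seed)
    pore = pore or make_pore_model(seed=spec.seed + 1, preset="separable", unit=spec.unit)
    dwell = dwell or DwellModel()
    unit = spec.unit.upper()
    R = len(unit)
    ref_count = spec.ref_count if spec.ref_count is not None else spec.alleles[0]
    reference = spec.left_flank + unit * ref_count + spec.right_flank
    region = STRRegion(
        chrom=spec.chrom,
        start=len(spec.left_flank),
        end=len(spec.left_flank) + R * ref_count,
        group=canonical_group(unit),
    )
    header = pysam.AlignmentHeader.from_references([spec.chrom], [len(reference)])

    reads, alignments = [], []
    truth_labels: dict[str, np.ndarray] = {}
    truth_counts: dict[str, int] = {}
    truth_alleles: dict[str, int] = {}
    truncated: dict[str, bool] = {}
    for r in range(spec.n_reads):
        rid = f"read{r:04d}"
        allele = int(rng.choice(spec.alleles, p=spec.fractions))
        count = max(3, int(np.rint(rng.normal(allele, spec.jitter_sd)))) if spec.jitter_sd else allele
        rep_seq = unit * count
        rep_truth = np.full(len(rep_seq), Label.REPEAT, dtype=np.int8)
        if spec.indel_rate > 0:
            rep_chars = list(rep_seq)
            rep_lab = list(rep_truth)
            i = 1
            while i < len(rep_chars) - 1:
                u = rng.random()
                if u < spec.indel_rate / 2:       # 1-bp insertion: duplicate this base
                    rep_chars.insert(i, rep_chars[i])
                    rep_lab.insert(i, int(Label.INS_IN_REPEAT))
                    i += 2
                elif u < spec.indel_rate:         # 1-bp deletion: drop, mark next base
                    del rep_chars[i]
                    del rep_lab[i]
                    if i < len(rep_lab):
                        rep_lab[i] = int(Label.DEL_IN_REPEAT)
                i += 1
            rep_seq = "".join(rep_chars)
            rep_truth = np.array(rep_lab, dtype=np.int8)

        is_trunc = bool(rng.random() < spec.truncation_prob)
        if is_trunc and len(rep_seq) > 3 * R:
            cut = int(rng.integers(3 * R, len(rep_seq)))
            rep_seq, rep_truth = rep_seq[:cut], rep_truth[:cut]
            right = ""
        else:
            is_trunc = False
            right = spec.right_flank
        template = spec.left_flank + rep_seq + right
        truth = np.concatenate(
            [
                np.full(len(spec.left_flank), Label.NOT_REPEAT, dtype=np.int8),
                rep_truth,
                np.full(len(right), Label.NOT_REPEAT, dtype=np.int8),
            ]
        )
        raw, table, _ = simulate_read(
            template,
            pore,
            dwell,
            seed=int(rng.integers(0, 2**31 - 1)),
            read_id=rid,
            truth_override=truth,
            device_units=device_units,
        )
        aln = _make_alignment(
            header,
            rid,
            template,
            len(spec.left_flank),
            len(rep_seq),
            R * ref_count,
            len(right),
        )
        reads.append((raw, table))
        alignments.append(aln)
        truth_labels[rid] = truth
        truth_counts[rid] = int(round(len(rep_seq) / R))
        truth_alleles[rid] = allele
        truncated[rid] = is_trunc
    return SimDataset(
        spec=spec,
        reference=reference,
        region=region,
        reads=reads,
        truth_labels=truth_labels,
        truth_counts=truth_counts,
        truth_alleles=truth_alleles,
        truncated=truncated,
        alignments=alignments,
        header=header,
    )
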