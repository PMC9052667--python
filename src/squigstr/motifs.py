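"""STR motif canonicalization and tandem-repeat region refinement.

A tandem array of unit ``CAG`` also contains the units ``AGC`` and ``GCA``
(cyclic rotations), and its reverse strand contains ``CTG``/``TGC``/``GCT``.
All six describe the same locus, so motifs are grouped by the closure under
cyclic rotation and reverse complement; one classifier model serves a whole
group, represented by its lexicographically smallest member.

Raw tandem-repeat-finder records are often overlapping or imperfect.  They
are refined by semi-globally aligning each record's sequence against a
perfect tandem array of its unit (free end gaps; match +1, mismatch -1,
gap -1), keeping maximal matched blocks at least three units long (or
>= 12 bases for dinucleotides) after merging blocks separated by small
unmatched gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "Motif",
    "MotifGroup",
    "STRRegion",
    "TRFRecord",
    "canonical_group",
    "enumerate_groups",
    "refine_trf_record",
    "read_trf_dat",
    "read_regions_bed",
    "write_regions_bed",
    "filter_isolated_regions",
]

_COMP = str.maketrans("ACGT", "TGCA")
MAX_UNIT_LEN = 6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _check_acgt(seq: str) -> None:
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError(f"motif/sequence must be nonempty over ACGT, got {seq!r}")


@dataclass(frozen=True)
class Motif:
    """A repeat unit of 1-6 bases; homopolymers are flagged, not rejected."""

    sequence: str

    def __post_init__(self) -> None:
        _check_acgt(self.sequence)
        if len(self.sequence) > MAX_UNIT_LEN:
            raise ValueError(f"unit length {len(self.sequence)} unsupported (max {MAX_UNIT_LEN})")

    @property
    def unit_len(self) -> int:
        return len(self.sequence)

    @property
    def is_homopolymer(self) -> bool:
        return len(set(self.sequence)) == 1


@dataclass(frozen=True)
class MotifGroup:
    """Closure of a motif under cyclic rotation and reverse complement."""

    representative: str
    members: frozenset[str]

    @property
    def unit_len(self) -> int:
        return len(self.representative)

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


def _rotations(seq: str) -> set[str]:
    return {seq[i:] + seq[:i] for i in range(len(seq))}


def canonical_group(motif: Motif | str) -> MotifGroup:
    """Group a motif with all its rotations and their reverse complements.

    The representative is the lexicographic minimum (A < C < G < T).
    """
    seq = motif.sequence if isinstance(motif, Motif) else motif
    _check_acgt(seq)
    members = _rotations(seq) | _rotations(reverse_complement(seq))
    return MotifGroup(representative=min(members), members=frozenset(members))


def enumerate_groups(unit_len: int) -> list[MotifGroup]:
    """Partition all non-homopolymer units of a given length into motif groups.

    Homopolymers are excluded (signal self-similarity cannot delimit them),
    so ``unit_len=1`` yields an empty list.  For trinucleotides this yields
    10 groups of 6 covering all 60 non-homopolymer motifs.
    """
    if not 1 <= unit_len <= MAX_UNIT_LEN:
        raise ValueError(f"unit length must be in 1..{MAX_UNIT_LEN}")
    seen: set[str] = set()
    groups: list[MotifGroup] = []
    for chars in product("ACGT", repeat=unit_len):
        seq = "".join(chars)
        if len(set(seq)) == 1 or seq in seen:
            continue
        grp = canonical_group(seq)
        seen |= grp.members
        groups.append(grp)
    return sorted(groups, key=lambda g: g.representative)


@dataclass(frozen=True)
class STRRegion:
    """A refined reference STR interval (0-based half-open) with its motif group."""

    chrom: str
    start: int
    end: int
    group: MotifGroup

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        r = self.group.unit_len
        m = self.end - self.start
        min_len = 12 if r == 2 else 3 * r
        if m < min_len:
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end} shorter than "
                f"{min_len} bases for unit length {r}"
            )

    @property
    def unit_len(self) -> int:
        return self.group.unit_len

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TRFRecord:
    """One raw tandem-repeat-finder record: interval, reported unit, sequence."""

    chrom: str
    start: int
    end: int
    motif: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != interval length {self.end - self.start}"
            )


# ---------------------------------------------------------------------------
# Semi-global refinement of TRF records
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _GAP = 1, -1, -1


def _semi_global_matches(query: str, ref: str) -> np.ndarray:
    """Boolean per-query-base match mask from a free-end-gap alignment.

    Needleman-Wunsch with zero-cost leading/trailing gaps on both sequences;
    traceback from the best cell on the last row/column.  Ties prefer
    diagonal moves so exact repeats align gap-free.
    """
    n, m = len(query), len(ref)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=diag, 1=up(gap in ref), 2=left(gap in query)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        sub = np.where(r == q[i - 1], _MATCH, _MISMATCH)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + _GAP
        prev = score[i]
        row = prev.copy()
        # left-dependency forces a scan within the row
        for j in range(1, m + 1):
            best = diag[j - 1]
            move = 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            left = row[j - 1] + _GAP
            if left > best:
                best, move = left, 2
            row[j] = best
            ptr[i, j] = move
        score[i] = row
    # free end gaps: start traceback at the best cell of last row/column
    last_row = score[n, :]
    last_col = score[:, m]
    if last_row.max() >= last_col.max():
        i, j = n, int(last_row.argmax())
    else:
        i, j = int(last_col.argmax()), m
    matched = np.zeros(n, dtype=bool)
    refidx = np.full(n, -1, dtype=np.int64)
    while i > 0 and j > 0:
        move = ptr[i, j]
        if move == 0:
            matched[i - 1] = q[i - 1] == r[j - 1]
            refidx[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    return matched, refidx


def _extend_runs_periodic(query: str, unit: str, matched: np.ndarray, refidx: np.ndarray) -> np.ndarray:
    """Mark every query position consistent with an aligned run's phase.

    Free end gaps leave score-tied boundary matches unaligned; since the
    reference array is periodic in the unit, the phases realized by the
    traceback determine which bases count as matched, and the gap-merge /
    minimum-length rules decide which survive.
    """
    r = len(unit)
    out = matched.copy()
    idx = np.flatnonzero(matched)
    if idx.size == 0:
        return out
    phases = sorted({(int(refidx[i]) - int(i)) % r for i in idx})
    pos = np.arange(len(query))
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    uarr = np.frombuffer(unit.encode(), dtype=np.uint8)
    for p in phases:
        out |= qarr == uarr[(pos + p) % r]
    return out


def _blocks_from_mask(matched: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal matched runs, merging runs separated by <= max_gap unmatched bases."""
    idx = np.flatnonzero(matched)
    if idx.size == 0:
        return []
    blocks: list[list[int]] = [[int(idx[0]), int(idx[0]) + 1]]
    for i in idx[1:]:
        if i - blocks[-1][1] <= max_gap:
            blocks[-1][1] = int(i) + 1
        else:
            blocks.append([int(i), int(i) + 1])
    return [(a, b) for a, b in blocks]


def refine_trf_record(
    rec: TRFRecord,
    *,
    max_gap: int | None = None,
) -> list[STRRegion]:
    """Refine one raw record into perfect, non-overlapping STR regions.

    The record sequence is aligned semi-globally against a perfect tandem
    array of its unit tiled to a comparable length; matched blocks separated
    by unmatched gaps of at most ``max_gap`` bases (default: the unit length)
    are merged, and blocks at least 3 units long (>= 12 bases for
    dinucleotides) become regions in reference coordinates.
    """
    if not rec.sequence:
        raise ValueError("TRF record has an empty sequence")
    _check_acgt(rec.motif)
    r = len(rec.motif)
    if r < 2:
        raise ValueError("unit length must be >= 2 for refinement")
    if max_gap is None:
        max_gap = r
    n_units = -(-len(rec.sequence) // r) + 1  # ceil + 1 unit of slack
    ref = rec.motif * n_units
    seq = rec.sequence.upper()
    matched, refidx = _semi_global_matches(seq, ref)
    matched = _extend_runs_periodic(seq, rec.motif, matched, refidx)
    min_len = 12 if r == 2 else 3 * r
    group = canonical_group(rec.motif)
    regions = []
    for a, b in _blocks_from_mask(matched, max_gap):
        if b - a >= min_len:
            regions.append(STRRegion(chrom=rec.chrom, start=rec.start + a, end=rec.start + b, group=group))
    return regions


def filter_isolated_regions(regions: list[STRRegion], min_distance: int = 500) -> list[STRRegion]:
    """Drop regions lying within ``min_distance`` bases of another region.

    Mirrors the long-STR evaluation rule for assemblies where adjacent,
    similar repeats cannot be unambiguously merged.  Off the default paths;
    opt-in.
    """
    out = []
    by_chrom: dict[str, list[STRRegion]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    for chrom, regs in by_chrom.items():
        regs = sorted(regs, key=lambda x: x.start)
        for i, reg in enumerate(regs):
            near_prev = i > 0 and reg.start - regs[i - 1].end < min_distance
            near_next = i + 1 < len(regs) and regs[i + 1].start - reg.end < min_distance
            if not (near_prev or near_next):
                out.append(reg)
    return sorted(out, key=lambda x: (x.chrom, x.start))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trf_dat(path: str, chrom: str | None = None) -> list[TRFRecord]:
    """Parse tandem-repeat-finder .dat output into raw records.

    Tracks ``Sequence:`` headers for the chromosome name; data lines are the
    standard 15-column TRF table whose 14th/15th columns are the consensus
    unit and the repeat region sequence.  1-based inclusive TRF coordinates
    become 0-based half-open.
    """
    records = []
    current = chrom or "unknown"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                current = line.split(None, 1)[1].split()[0]
                continue
            parts = line.split()
            if len(parts) >= 15 and parts[0].isdigit() and parts[1].isdigit():
                start, end = int(parts[0]) - 1, int(parts[1])
                records.append(
                    TRFRecord(chrom=current, start=start, end=end, motif=parts[13].upper(), sequence=parts[14].upper())
                )
    return records


def read_regions_bed(path: str) -> list[STRRegion]:
    """Read refined regions from BED (4th column motif, 5th unit length)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, motif = parts[0], int(parts[1]), int(parts[2]), parts[3].upper()
            regions.append(STRRegion(chrom=chrom, start=start, end=end, group=canonical_group(motif)))
    return regions


def write_regions_bed(path: str, regions: list[STRRegion]) -> None:
    with open(path, "w") as fh:
        for reg in sorted(regions, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.group.representative}\t{reg.unit_len}\n")
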