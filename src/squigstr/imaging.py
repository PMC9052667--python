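"""Signal-to-image conversion and training-label assignment.

The detector's core representation: for a unit length R, the 50-bin vectors
of the R events starting at anchor ``j`` form one 50 x R greyscale image, and
the images of the adjacent upstream (``j-R``) and downstream (``j+R``)
R-windows are stacked as the three channels of a color image.  Inside a
tandem array all three windows cover copies of the same unit, so their
signal distributions coincide and the image collapses to aligned white dots;
outside, the channels disagree and colors disperse.  Classifying these
images is what turns STR detection into image recognition.

Training labels come from read-to-reference alignments and refined STR
regions: aligned bases inside a region of the trained motif group are
"in repeat"; 1-bp insertions/deletions inside a region get their own
classes; bases near a region (closer than 1.5x its length), clipped bases,
large insertions, and bases aligned to regions of other motif groups are
left unlabeled and excluded from training.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .events import N_BINS
from .motifs import MotifGroup, STRRegion

__all__ = [
    "Label",
    "BaseStatus",
    "AlignedBaseMap",
    "RepeatImage",
    "TrainingSet",
    "build_image",
    "build_read_images",
    "aligned_base_map",
    "label_anchor",
    "label_read",
    "generate_training_set",
    "sample_regions",
    "save_training_set",
    "load_training_set",
]

#: margin factor: a base is "not in repeat" only if >= 1.5*M bases from every
#: region of interest of length M
FLANK_MARGIN = 1.5


class Label(IntEnum):
    NOT_REPEAT = 0
    REPEAT = 1
    DEL_IN_REPEAT = 2
    INS_IN_REPEAT = 3
    NO_LABEL = -1


#: classes counted as in-repeat when merging per-base predictions
IN_REPEAT_CLASSES = (Label.REPEAT, Label.DEL_IN_REPEAT, Label.INS_IN_REPEAT)


class BaseStatus(IntEnum):
    MATCH = 0
    MISMATCH = 1
    INS_1BP = 2
    DEL_1BP = 3       # read base immediately following a 1-bp deletion
    CLIPPED = 4
    LARGE_INS = 5
    UNMAPPED = 6


@dataclass(frozen=True)
class AlignedBaseMap:
    """Per-read-base alignment status derived from one primary alignment's CIGAR.

    ``status[i]`` classifies read base ``i`` (soft-clipped bases included);
    ``ref_pos[i]`` is its 0-based reference coordinate, the flanking deleted
    position for DEL_1BP bases, and -1 where undefined.
    """

    read_id: str
    chrom: str
    strand: str
    status: np.ndarray
    ref_pos: np.ndarray

    def __len__(self) -> int:
        return len(self.status)


def aligned_base_map(aln, ref_seq: str | None = None) -> AlignedBaseMap:
    """Build an AlignedBaseMap from a pysam AlignedSegment (primary only).

    With ``ref_seq`` (full chromosome sequence) matches and mismatches are
    distinguished; otherwise aligned bases are reported as MATCH.  Multi-base
    deletions mark the following read base DEL_1BP at the first deleted
    position (consecutive 1-bp deletion convention).
    """
    if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
        raise ValueError(f"read {aln.query_name!r}: need a mapped primary alignment")
    query = aln.query_sequence
    n = len(query)
    status = np.full(n, BaseStatus.UNMAPPED, dtype=np.int8)
    ref_pos = np.full(n, -1, dtype=np.int64)
    qpos, rpos = 0, aln.reference_start
    pending_del: int | None = None
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                st = BaseStatus.MATCH
                if ref_seq is not None and query[qpos].upper() != ref_seq[rpos].upper():
                    st = BaseStatus.MISMATCH
                if pending_del is not None:
                    status[qpos] = BaseStatus.DEL_1BP
                    ref_pos[qpos] = pending_del
                    pending_del = None
                else:
                    status[qpos] = st
                    ref_pos[qpos] = rpos
                qpos += 1
                rpos += 1
        elif op == 1:  # I
            st = BaseStatus.INS_1BP if length == 1 else BaseStatus.LARGE_INS
            status[qpos : qpos + length] = st
            qpos += length
        elif op in (2, 3):  # D, N
            pending_del = rpos
            rpos += length
        elif op == 4:  # S
            status[qpos : qpos + length] = BaseStatus.CLIPPED
            qpos += length
        # H (5) and P (6) consume nothing in query_sequence
    return AlignedBaseMap(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        strand="-" if aln.is_reverse else "+",
        status=status,
        ref_pos=ref_pos,
    )


@dataclass(frozen=True)
class RepeatImage:
    """One anchor's 50 x R x 3 image with optional training label."""

    tensor: np.ndarray
    read_id: str
    anchor: int
    motif_group_id: str
    label: Label = Label.NO_LABEL


def build_image(bins: np.ndarray, j: int, unit_len: int) -> np.ndarray | None:
    """Stack the upstream / center / downstream R-windows at anchor ``j``.

    ``bins`` is the (L, 50) per-event bin matrix of one read.  Returns a
    (50, R, 3) uint8 tensor, or None when either neighbor window would fall
    off the read (the caller skips such anchors).  The center window is
    anchor-leading: events ``j .. j+R-1``.
    """
    if unit_len < 2:
        raise ValueError("unit length must be >= 2")
    L = bins.shape[0]
    if j - unit_len < 0 or j + 2 * unit_len - 1 >= L:
        return None
    up = bins[j - unit_len : j].T
    center = bins[j : j + unit_len].T
    down = bins[j + unit_len : j + 2 * unit_len].T
    return np.stack([up, center, down], axis=2).astype(np.uint8)


def build_read_images(bins: np.ndarray, unit_len: int, anchors=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized image construction for many anchors of one read.

    Returns ``(tensor (N, 50, R, 3), anchors (N,))`` keeping only feasible
    anchors.  Equivalent to stacking :func:`build_image` per anchor.
    """
    L = bins.shape[0]
    R = unit_len
    if anchors is None:
        anchors = np.arange(L)
    anchors = np.asarray(anchors, dtype=np.int64)
    anchors = anchors[(anchors - R >= 0) & (anchors + 2 * R - 1 < L)]
    if anchors.size == 0:
        return np.empty((0, N_BINS, R, 3), dtype=np.uint8), anchors
    offs = np.arange(R)
    up = bins[(anchors[:, None] - R) + offs]        # (N, R, 50)
    center = bins[anchors[:, None] + offs]
    down = bins[(anchors[:, None] + R) + offs]
    tensor = np.stack([up, center, down], axis=3).transpose(0, 2, 1, 3)
    return np.ascontiguousarray(tensor, dtype=np.uint8), anchors


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


def _containing(regions: list[STRRegion], chrom: str, pos: int) -> STRRegion | None:
    for reg in regions:
        if reg.chrom == chrom and reg.start <= pos < reg.end:
            return reg
    return None


def _far_from_all(regions: list[STRRegion], chrom: str, pos: int) -> bool:
    """True when ``pos`` lies >= FLANK_MARGIN * M from every region (length M)."""
    for reg in regions:
        if reg.chrom != chrom:
            continue
        if pos < reg.start:
            dist = reg.start - pos
        elif pos >= reg.end:
            dist = pos - reg.end + 1
        else:
            return False
        if dist < FLANK_MARGIN * reg.length:
            return False
    return True


def _nearest_aligned(map_: AlignedBaseMap, j: int, direction: int) -> int:
    """Ref pos of the nearest positioned read base from j in +-1 direction, or -1."""
    i = j + direction
    while 0 <= i < len(map_):
        if map_.ref_pos[i] >= 0:
            return int(map_.ref_pos[i])
        i += direction
    return -1


def label_anchor(
    map_: AlignedBaseMap,
    regions: list[STRRegion],
    j: int,
    other_regions: list[STRRegion] = (),
) -> Label:
    """Assign the 4-class training label (or NO_LABEL) to read base ``j``.

    ``regions`` are the refined regions of the motif group being trained;
    ``other_regions`` are STR regions of other groups (or unsampled regions),
    which silence the base rather than label it.
    """
    if j < 0 or j >= len(map_):
        return Label.NO_LABEL
    st = BaseStatus(map_.status[j])
    chrom = map_.chrom

    if st in (BaseStatus.CLIPPED, BaseStatus.LARGE_INS, BaseStatus.UNMAPPED):
        return Label.NO_LABEL

    if st in (BaseStatus.MATCH, BaseStatus.MISMATCH):
        pos = int(map_.ref_pos[j])
        if _containing(regions, chrom, pos) is not None:
            return Label.REPEAT
        if _containing(list(other_regions), chrom, pos) is not None:
            return Label.NO_LABEL
        return Label.NOT_REPEAT if _far_from_all(regions, chrom, pos) else Label.NO_LABEL

    if st == BaseStatus.DEL_1BP:
        pos = int(map_.ref_pos[j])
        if _containing(regions, chrom, pos) is not None:
            return Label.DEL_IN_REPEAT
        if _containing(list(other_regions), chrom, pos) is not None:
            return Label.NO_LABEL
        return Label.NOT_REPEAT if _far_from_all(regions, chrom, pos) else Label.NO_LABEL

    # INS_1BP: look at the flanking aligned bases
    left = _nearest_aligned(map_, j, -1)
    right = _nearest_aligned(map_, j, +1)
    if left >= 0 and right >= 0:
        if (
            _containing(regions, chrom, left) is not None
            and _containing(regions, chrom, right) is not None
        ):
            return Label.INS_IN_REPEAT
    anchor_pos = left if left >= 0 else right
    if anchor_pos < 0:
        return Label.NO_LABEL
    if _containing(regions, chrom, anchor_pos) is not None:
        return Label.NO_LABEL
    if _containing(list(other_regions), chrom, anchor_pos) is not None:
        return Label.NO_LABEL
    return Label.NOT_REPEAT if _far_from_all(regions, chrom, anchor_pos) else Label.NO_LABEL


def label_read(
    map_: AlignedBaseMap,
    regions: list[STRRegion],
    other_regions: list[STRRegion] = (),
) -> np.ndarray:
    """Vector of labels over all read bases (int8, NO_LABEL = -1)."""
    return np.array(
        [label_anchor(map_, regions, j, other_regions) for j in range(len(map_))],
        dtype=np.int8,
    )


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Labeled images plus the non-repeat chunk plan for balanced epochs.

    ``repeat_idx`` indexes images labeled in-repeat (REPEAT/DEL/INS);
    ``chunks`` partitions the non-repeat images into ceil(Nn/Nr) disjoint
    groups of roughly repeat-set size, cycled one per epoch during training.
    """

    images: np.ndarray            # (N, 50, R, 3) uint8
    labels: np.ndarray            # (N,) int8
    anchors: np.ndarray           # (N,) int64
    read_ids: list[str]
    group_id: str
    unit_len: int
    repeat_idx: np.ndarray
    chunks: list[np.ndarray]

    def epoch_indices(self, epoch: int) -> np.ndarray:
        """Indices consumed in a given epoch: repeat set + scheduled chunk."""
        if not self.chunks:
            return self.repeat_idx
        return np.concatenate([self.repeat_idx, self.chunks[epoch % len(self.chunks)]])


def sample_regions(
    regions: list[STRRegion], max_per_chrom: int, rng: np.random.Generator
) -> tuple[list[STRRegion], list[STRRegion]]:
    """Per-chromosome seeded subsample; returns (sampled, left out)."""
    sampled: list[STRRegion] = []
    left_out: list[STRRegion] = []
    by_chrom: dict[str, list[STRRegion]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda x: x.start)
        if len(regs) > max_per_chrom:
            pick = set(rng.choice(len(regs), size=max_per_chrom, replace=False).tolist())
            sampled.extend(regs[i] for i in sorted(pick))
            left_out.extend(regs[i] for i in range(len(regs)) if i not in pick)
        else:
            sampled.extend(regs)
    return sampled, left_out


def generate_training_set(
    binned_reads: dict[str, np.ndarray],
    maps: dict[str, AlignedBaseMap],
    regions: list[STRRegion],
    group: MotifGroup,
    *,
    max_regions_per_chrom: int = 100,
    max_images: int | None = None,
    other_regions: list[STRRegion] = (),
    seed: int = 0,
) -> TrainingSet:
    """Build the labeled, balanced image collection for one motif group.

    Per chromosome at most ``max_regions_per_chrom`` regions are sampled
    (seeded); unsampled regions of the group join ``other_regions`` so their
    bases are silenced, not mislabeled.  NO_LABEL images are dropped;
    non-repeat images are partitioned into chunks of roughly repeat-set size.
    """
    rng = np.random.default_rng(seed)
    R = group.unit_len
    group_regions = [r for r in regions if r.group.representative == group.representative]
    if not group_regions:
        raise ValueError(
            f"no STR regions for motif group {group.representative!r}; "
            "train a different group or provide more regions"
        )
    sampled, left_out = sample_regions(group_regions, max_regions_per_chrom, rng)
    silenced = (
        list(other_regions)
        + [r for r in regions if r.group.representative != group.representative]
        + left_out
    )

    img_parts, lbl_parts, anc_parts, rid_parts = [], [], [], []
    for read_id in sorted(binned_reads):
        if read_id not in maps:
            continue
        bins = binned_reads[read_id]
        labels = label_read(maps[read_id], sampled, silenced)
        keep = np.flatnonzero(labels != Label.NO_LABEL)
        tensor, anchors = build_read_images(bins, R, keep)
        if anchors.size == 0:
            continue
        img_parts.append(tensor)
        lbl_parts.append(labels[anchors])
        anc_parts.append(anchors)
        rid_parts.extend([read_id] * anchors.size)

    if not img_parts:
        raise ValueError(
            f"no labeled images for motif group {group.representative!r}; "
            "train a different group or provide more data"
        )
    images = np.concatenate(img_parts)
    labels = np.concatenate(lbl_parts)
    anchors = np.concatenate(anc_parts)
    read_ids = rid_parts

    if max_images is not None and images.shape[0] > max_images:
        pick = np.sort(rng.choice(images.shape[0], size=max_images, replace=False))
        images, labels, anchors = images[pick], labels[pick], anchors[pick]
        read_ids = [read_ids[i] for i in pick]

    repeat_idx = np.flatnonzero(np.isin(labels, IN_REPEAT_CLASSES))
    nonrep_idx = np.flatnonzero(labels == Label.NOT_REPEAT)
    if repeat_idx.size == 0:
        raise ValueError(
            f"zero in-repeat images for motif group {group.representative!r}; "
            "train a different group or provide more data"
        )
    if nonrep_idx.size == 0:
        import warnings

        warnings.warn(
            "no not-in-repeat images: reads have no aligned bases farther than "
            f"{FLANK_MARGIN}x a region length from the regions of interest; "
            "a classifier trained on this set cannot learn the contrast",
            stacklevel=2,
        )
    nonrep_idx = rng.permutation(nonrep_idx)
    step = repeat_idx.size
    chunks = [
        np.sort(nonrep_idx[i : i + step]) for i in range(0, nonrep_idx.size, step)
    ]
    return TrainingSet(
        images=images,
        labels=labels,
        anchors=anchors,
        read_ids=read_ids,
        group_id=group.representative,
        unit_len=R,
        repeat_idx=repeat_idx,
        chunks=chunks,
    )


def save_training_set(path: str, ts: TrainingSet) -> None:
    np.savez_compressed(
        path,
        images=ts.images,
        labels=ts.labels,
        anchors=ts.anchors,
        read_ids=np.array(ts.read_ids, dtype=object),
        group_id=ts.group_id,
        unit_len=ts.unit_len,
        repeat_idx=ts.repeat_idx,
        n_chunks=len(ts.chunks),
        **{f"chunk_{i}": c for i, c in enumerate(ts.chunks)},
    )


def load_training_set(path: str) -> TrainingSet:
    with np.load(path, allow_pickle=True) as z:
        return TrainingSet(
            images=z["images"],
            labels=z["labels"],
            anchors=z["anchors"],
            read_ids=[str(s) for s in z["read_ids"]],
            group_id=str(z["group_id"]),
            unit_len=int(z["unit_len"]),
            repeat_idx=z["repeat_idx"],
            chunks=[z[f"chunk_{i}"] for i in range(int(z["n_chunks"]))],
        )
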