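"""Per-read signal/event containers, normalization, and 50-bin discretization.

A nanopore read is a raw current trace plus an *event table*: one event per
basecalled nucleotide, anchoring a contiguous slice of the trace.  Events are
produced upstream (an event-aware basecaller) or by :mod:`squigstr.simulate`;
this module only validates, normalizes, and discretizes them.

Normalization is per-read median/MAD z-scaling (consistency constant 1.4826)
clipped to [-5, 5], so a read's signal range is comparable across reads and
flow cells.  Each event's normalized samples are then histogrammed into 50
non-overlapping bins of width 0.2 spanning [-5, 5]; the per-bin fraction of
the event's samples is rescaled to the 0-255 intensity range of an image
channel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RawRead",
    "Event",
    "EventTable",
    "EventFormatError",
    "normalize_read",
    "bin_event",
    "bin_events",
    "prepare_bins",
    "read_event_table",
    "write_event_table",
    "read_fast5_events",
]

#: number of signal bins per event (image height)
N_BINS = 50
#: bin width in normalized signal units
BIN_STEP = 0.2
#: normalized signal range
SIGNAL_MIN, SIGNAL_MAX = -5.0, 5.0
#: MAD -> sigma consistency constant for a normal distribution
MAD_SCALE = 1.4826

_VALID_BASES = frozenset("ACGT")


class EventFormatError(ValueError):
    """Raised when an event table violates the format contract."""


@dataclass(frozen=True)
class RawRead:
    """A read's raw current trace in device units (or normalized units)."""

    read_id: str
    samples: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError(f"read {self.read_id!r}: samples must be a nonempty 1-D array")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class Event:
    """One basecalled nucleotide's slice of the raw trace."""

    base: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.base not in _VALID_BASES:
            raise EventFormatError(f"unknown base symbol {self.base!r}")
        if self.length < 1:
            raise EventFormatError(f"event length must be >= 1, got {self.length}")
        if self.start < 0:
            raise EventFormatError(f"event start must be >= 0, got {self.start}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class EventTable:
    """Ordered per-base events of one read.

    ``normalized`` records whether the referenced samples are already on the
    [-5, 5] normalized scale; ``norm_params`` is the (center, scale) pair
    applied, for audit.
    """

    read_id: str
    events: tuple[Event, ...]
    normalized: bool = False
    norm_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    def __len__(self) -> int:
        return len(self.events)

    @property
    def sequence(self) -> str:
        """Basecalled sequence (concatenated event bases)."""
        return "".join(e.base for e in self.events)

    def validate(self, n_samples: int) -> None:
        """Check contiguity, ordering, and bounds against the sample count."""
        for i, ev in enumerate(self.events):
            if ev.end > n_samples:
                raise EventFormatError(
                    f"read {self.read_id!r}: event {i} (start={ev.start}, "
                    f"length={ev.length}) exceeds {n_samples} samples"
                )
            if i > 0:
                prev = self.events[i - 1]
                if ev.start != prev.end:
                    raise EventFormatError(
                        f"read {self.read_id!r}: events {i - 1} and {i} are not "
                        f"contiguous at sample offset {prev.end} (next start {ev.start})"
                    )


def normalize_read(raw: RawRead) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Median/MAD z-scale a read's trace and clip to [-5, 5].

    Returns ``(normalized_samples, (center, scale), degenerate)``.  A read
    whose MAD is zero (constant trace) yields all zeros with the degenerate
    flag set rather than crashing.
    """
    x = np.asarray(raw.samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError(f"read {raw.read_id!r}: need >= 2 samples to normalize")
    center = float(np.median(x))
    scale = MAD_SCALE * float(np.median(np.abs(x - center)))
    if scale == 0.0:
        return np.zeros_like(x), (center, 0.0), True
    out = np.clip((x - center) / scale, SIGNAL_MIN, SIGNAL_MAX)
    return out, (center, scale), False


def bin_event(samples: np.ndarray) -> np.ndarray:
    """Discretize one event's normalized samples into the 50-bin intensity vector.

    Bin ``b = min(49, floor((x + 5) / 0.2))`` (bins half-open, top edge closed);
    each bin holds ``round(255 * count_b / n)`` as uint8.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty event cannot be binned")
    if x.min() < SIGNAL_MIN - 1e-9 or x.max() > SIGNAL_MAX + 1e-9:
        raise ValueError("samples outside the normalized range [-5, 5]")
    idx = np.floor((x - SIGNAL_MIN) / BIN_STEP + 1e-9).astype(np.int64)
    idx = np.clip(idx, 0, N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)
    vec = np.rint(255.0 * counts / x.size).astype(np.uint8)
    return vec


def prepare_bins(raw: RawRead, table: EventTable) -> tuple[np.ndarray, EventTable]:
    """Normalize a read if needed and bin every event.

    Returns the (L, 50) uint8 bin matrix and the table annotated with the
    normalization parameters used.  Tables already flagged normalized are
    binned directly (clipped to the normalized range).
    """
    if table.normalized:
        samples = np.clip(np.asarray(raw.samples, dtype=np.float64), SIGNAL_MIN, SIGNAL_MAX)
        out_table = table
    else:
        samples, params, _ = normalize_read(raw)
        out_table = replace(table, normalized=True, norm_params=params)
    return bin_events(out_table, samples), out_table


def bin_events(table: EventTable, normalized_samples: np.ndarray) -> np.ndarray:
    """Bin every event of a read; returns an (L, 50) uint8 matrix."""
    out = np.empty((len(table), N_BINS), dtype=np.uint8)
    for i, ev in enumerate(table.events):
        out[i] = bin_event(normalized_samples[ev.start : ev.end])
    return out


# ---------------------------------------------------------------------------
# I/O: HDF5 container and TSV mirror
# ---------------------------------------------------------------------------

_EVENT_DTYPE = np.dtype([("base", "u1"), ("start", "<i8"), ("length", "<i4")])


def _events_to_array(table: EventTable) -> np.ndarray:
    arr = np.empty(len(table), dtype=_EVENT_DTYPE)
    for i, ev in enumerate(table.events):
        arr[i] = (ord(ev.base), ev.start, ev.length)
    return arr


def _events_from_array(read_id: str, arr: np.ndarray) -> tuple[Event, ...]:
    events = []
    for i, row in enumerate(arr):
        base = chr(int(row["base"]))
        if base not in _VALID_BASES:
            raise EventFormatError(f"read {read_id!r}: unknown base symbol {base!r} at event {i}")
        events.append(Event(base=base, start=int(row["start"]), length=int(row["length"])))
    return tuple(events)


def write_event_table(path: str, records: list[tuple[RawRead, EventTable]], format: str = "hdf5") -> None:
    """Write (raw read, event table) pairs to an HDF5 container or TSV pair.

    For ``format="tsv"``, ``path`` is a prefix: ``<path>.events.tsv`` holds the
    event table (read_id, idx, base, start, length) and ``<path>.samples.tsv``
    the raw samples (read_id, value), row order = sample order.
    """
    if format == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("reads")
            for raw, table in records:
                g = grp.create_group(raw.read_id)
                g.create_dataset("samples", data=raw.samples.astype(np.float32))
                g.create_dataset("events", data=_events_to_array(table))
                g.attrs["normalized"] = bool(table.normalized)
                if table.norm_params is not None:
                    g.attrs["norm_center"] = table.norm_params[0]
                    g.attrs["norm_scale"] = table.norm_params[1]
                if raw.source is not None:
                    g.attrs["source"] = raw.source
    elif format == "tsv":
        ev_rows, sm_rows = [], []
        for raw, table in records:
            for i, ev in enumerate(table.events):
                ev_rows.append((raw.read_id, i, ev.base, ev.start, ev.length))
            for v in raw.samples:
                sm_rows.append((raw.read_id, float(np.float32(v))))
        pd.DataFrame(ev_rows, columns=["read_id", "idx", "base", "start", "length"]).to_csv(
            path + ".events.tsv", sep="\t", index=False
        )
        pd.DataFrame(sm_rows, columns=["read_id", "value"]).to_csv(
            path + ".samples.tsv", sep="\t", index=False, float_format="%.6g"
        )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'hdf5' or 'tsv')")


def read_event_table(path: str, format: str = "hdf5") -> list[tuple[RawRead, EventTable]]:
    """Read and validate (raw read, event table) pairs written by write_event_table."""
    records: list[tuple[RawRead, EventTable]] = []
    if format == "hdf5":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with h5py.File(path, "r") as fh:
            for read_id in fh["reads"]:
                g = fh["reads"][read_id]
                samples = np.asarray(g["samples"], dtype=np.float64)
                events = _events_from_array(read_id, np.asarray(g["events"]))
                norm_params = None
                if "norm_center" in g.attrs:
                    norm_params = (float(g.attrs["norm_center"]), float(g.attrs["norm_scale"]))
                table = EventTable(
                    read_id=read_id,
                    events=events,
                    normalized=bool(g.attrs.get("normalized", False)),
                    norm_params=norm_params,
                )
                raw = RawRead(read_id=read_id, samples=samples, source=g.attrs.get("source"))
                table.validate(samples.size)
                records.append((raw, table))
    elif format == "tsv":
        ev_path, sm_path = path + ".events.tsv", path + ".samples.tsv"
        if not os.path.exists(ev_path):
            raise FileNotFoundError(ev_path)
        ev = pd.read_csv(ev_path, sep="\t", dtype={"read_id": str, "base": str})
        sm = pd.read_csv(sm_path, sep="\t", dtype={"read_id": str})
        for read_id, sub in ev.groupby("read_id", sort=True):
            sub = sub.sort_values("idx")
            try:
                events = tuple(
                    Event(base=r.base, start=int(r.start), length=int(r.length))
                    for r in sub.itertuples()
                )
            except EventFormatError as exc:
                raise EventFormatError(f"read {read_id!r}: {exc}") from exc
            samples = sm.loc[sm.read_id == read_id, "value"].to_numpy(dtype=np.float64)
            raw = RawRead(read_id=read_id, samples=samples)
            table = EventTable(read_id=read_id, events=events)
            table.validate(samples.size)
            records.append((raw, table))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'hdf5' or 'tsv')")
    return records


def read_fast5_events(path: str, read_id: str | None = None) -> list[tuple[RawRead, EventTable]]:
    """Adapter for single-read fast5 files carrying a basecaller event table.

    Read-only and isolated from the core formats: expects ``Raw/Reads/*/Signal``
    and an ``Analyses/Basecall_1D_*/BaseCalled_template/Events`` table with
    per-event ``base`` (or ``model_state``), ``start`` and ``length`` columns
    expressed in samples.  Events that annotate multi-base model states use the
    last base of the state as the anchored nucleotide.
    """
    out: list[tuple[RawRead, EventTable]] = []
    with h5py.File(path, "r") as fh:
        raw_grp = fh["Raw/Reads"]
        names = list(raw_grp)
        for name in names:
            rid = raw_grp[name].attrs.get("read_id", name)
            rid = rid.decode() if isinstance(rid, bytes) else str(rid)
            if read_id is not None and rid != read_id:
                continue
            samples = np.asarray(raw_grp[name]["Signal"], dtype=np.float64)
            ev_ds = None
            for key in fh.get("Analyses", {}):
                if key.startswith("Basecall_1D"):
                    cand = fh[f"Analyses/{key}"].get("BaseCalled_template/Events")
                    if cand is not None:
                        ev_ds = np.asarray(cand)
                        break
            if ev_ds is None:
                raise EventFormatError(f"{path}: no basecalled event table found")
            fields = ev_ds.dtype.names
            base_col = "base" if "base" in fields else "model_state"
            events = []
            for row in ev_ds:
                sym = row[base_col]
                sym = sym.decode() if isinstance(sym, bytes) else str(sym)
                events.append(Event(base=sym[-1], start=int(row["start"]), length=int(row["length"])))
            table = EventTable(read_id=rid, events=tuple(events))
            table.validate(samples.size)
            out.append((RawRead(read_id=rid, samples=samples, source="fast5"), table))
    return out
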