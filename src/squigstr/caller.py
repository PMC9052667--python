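"""Per-read repeat quantification and Gaussian-mixture allele calling.

Per read, consecutive in-repeat base predictions are merged into runs: runs
at least three units long are retained, and retained runs closer than one
unit length are joined (gap bases count toward the merged length).  The
merged length divided by the unit length, rounded half-up, is that read's
repeat count.  Counts from all reads at a locus form a histogram, which a
1-D Gaussian mixture summarizes: components k in 3..7 are each fitted 20
times with random restarts, the fit with the best (lowest) AIC wins, and
alleles are the rounded means of the highest-weight components — a second
allele is reported only with enough mixture weight and separation from the
first.  A telomere mode quantifies runs anchored at a single subtelomeric
flank, since chromosome ends have no second flanking sequence to align.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .imaging import IN_REPEAT_CLASSES

__all__ = [
    "CallerConfig",
    "PerReadCall",
    "CountHistogram",
    "GenotypeCall",
    "TelomereSummary",
    "merge_predictions",
    "per_read_count",
    "call_genotype",
    "quantify_telomere",
]

_IN_REPEAT = frozenset(int(c) for c in IN_REPEAT_CLASSES)


@dataclass(frozen=True)
class CallerConfig:
    """Peak-calling knobs; defaults are explicit substitutes for thresholds
    the upstream method inherits from its HMM-based predecessor."""

    min_reads: int = 10            # below this, only the histogram is reported
    het_min_weight: float = 0.2    # weight needed to report a second allele
    het_min_sep: int = 2           # minimum |allele mean difference|
    support_window: int = 2        # reads within +- this of a mean support it
    n_gmm_fits: int = 20           # random restarts per component count
    k_min: int = 3
    k_max: int = 7
    gmm_reg_covar: float = 0.25    # variance floor: counts are integers, so
                                   # components narrower than ~0.5 sd are noise
    min_mapq: int = 20             # telomere mode: flank mapping quality gate
    indel_adjust: bool = False     # reserved: length correction for del/ins bases
    count_merged_gaps: bool = True # include merge-gap bases in merged length


@dataclass(frozen=True)
class PerReadCall:
    """One read's merged repeat length and count at a locus."""

    read_id: str
    region: str
    merged_len: int
    unit_len: int

    @property
    def count_raw(self) -> float:
        return self.merged_len / self.unit_len

    @property
    def count(self) -> int:
        return _round_half_up(self.count_raw)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CountHistogram:
    """Supporting-read counts per repeat count."""

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_values(cls, values) -> "CountHistogram":
        counts: dict[int, int] = {}
        for v in values:
            counts[int(v)] = counts.get(int(v), 0) + 1
        return cls(counts=dict(sorted(counts.items())))


@dataclass(frozen=True)
class GenotypeCall:
    """1-2 allele repeat counts with mixture weights and supporting reads."""

    alleles: tuple[int, ...]
    weights: tuple[float, ...]
    support: tuple[int, ...]
    k: int | None
    aic: float | None
    low_coverage: bool
    degenerate: bool
    histogram: CountHistogram

    def to_json(self) -> str:
        return json.dumps(
            {
                "alleles": list(self.alleles),
                "weights": [round(w, 6) for w in self.weights],
                "support": list(self.support),
                "k": self.k,
                "aic": None if self.aic is None else round(self.aic, 6),
                "low_coverage": self.low_coverage,
                "degenerate": self.degenerate,
                "histogram": {str(c): n for c, n in self.histogram.counts.items()},
            }
        )


def merge_predictions(labels, unit_len: int) -> list[tuple[int, int]]:
    """Merge per-base class predictions into repeat segments (read coords).

    Maximal runs of in-repeat classes (repeat / deletion-in / insertion-in)
    are kept when at least ``3 * unit_len`` bases long; retained runs whose
    separating gap is shorter than one unit are merged, gap included.
    Returns sorted, non-overlapping half-open ``(start, end)`` segments.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    inrep = np.isin(labels, list(_IN_REPEAT))
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(inrep):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, inrep.size))
    kept = [(a, b) for a, b in runs if b - a >= 3 * unit_len]
    merged: list[list[int]] = []
    for a, b in kept:
        if merged and a - merged[-1][1] < unit_len:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def per_read_count(
    segments: list[tuple[int, int]],
    unit_len: int,
    *,
    read_id: str = "",
    region: str = "",
    locus_span: tuple[int, int] | None = None,
) -> PerReadCall | None:
    """Select the segment for a locus and convert its length to a repeat count.

    In targeted mode ``locus_span`` restricts segments to those overlapping
    the locus in read coordinates; with several candidates the longest wins.
    Returns None when no segment qualifies (the read contributes nothing).
    """
    if not segments:
        return None
    if locus_span is not None:
        lo, hi = locus_span
        segments = [(a, b) for a, b in segments if a < hi and b > lo]
        if not segments:
            return None
    a, b = max(segments, key=lambda s: (s[1] - s[0], -s[0]))
    return PerReadCall(read_id=read_id, region=region, merged_len=b - a, unit_len=unit_len)


def call_genotype(
    counts,
    cfg: CallerConfig | None = None,
    seed: int = 0,
) -> GenotypeCall:
    """Call 1-2 alleles from per-read repeat counts with a GMM + AIC.

    For each component count k (3..7, clipped to the number of distinct
    values) the mixture is fitted ``n_gmm_fits`` times from seeded random
    initializations; the single fit with the lowest AIC anywhere wins.
    Components are ranked by weight: allele 1 is the top component's rounded
    mean; allele 2 is the first lower-ranked component with weight >=
    ``het_min_weight`` and mean separation >= ``het_min_sep``.  Fewer than
    ``min_reads`` counts yields only the histogram (low-coverage flag).
    """
    cfg = cfg or CallerConfig()
    values = np.asarray(list(counts), dtype=np.int64)
    hist = CountHistogram.from_values(values)
    if values.size < cfg.min_reads:
        return GenotypeCall(
            alleles=(), weights=(), support=(), k=None, aic=None,
            low_coverage=True, degenerate=False, histogram=hist,
        )
    distinct = np.unique(values)
    if distinct.size == 1:
        val = int(distinct[0])
        return GenotypeCall(
            alleles=(val,), weights=(1.0,), support=(int(values.size),),
            k=1, aic=None, low_coverage=False, degenerate=True, histogram=hist,
        )

    x = values.astype(np.float64).reshape(-1, 1)
    k_lo = min(cfg.k_min, distinct.size)
    k_hi = min(cfg.k_max, distinct.size)
    rng = np.random.default_rng(seed)
    best_aic, best_gmm = np.inf, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(k_lo, k_hi + 1):
            for _ in range(cfg.n_gmm_fits):
                gmm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    init_params="random_from_data",
                    n_init=1,
                    max_iter=200,
                    reg_covar=cfg.gmm_reg_covar,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                try:
                    gmm.fit(x)
                except ValueError:
                    continue
                aic = gmm.aic(x)
                if aic < best_aic:
                    best_aic, best_gmm = aic, gmm
    if best_gmm is None:  # pathological data; fall back to the histogram mode
        mode = max(hist.counts.items(), key=lambda kv: kv[1])[0]
        support = int(np.sum(np.abs(values - mode) <= cfg.support_window))
        return GenotypeCall(
            alleles=(mode,), weights=(1.0,), support=(support,), k=None, aic=None,
            low_coverage=False, degenerate=True, histogram=hist,
        )

    # Aggregate components into peaks: the mixture often shards one allele's
    # cluster across several narrow components, so components whose means lie
    # within het_min_sep are merged (weight-averaged mean, summed weight)
    # before peaks are ranked by supporting weight.
    order = np.argsort(best_gmm.means_.ravel())
    means = best_gmm.means_.ravel()[order]
    weights = best_gmm.weights_[order]
    peaks: list[list[float]] = []  # [mean, weight]
    for mu, w in zip(means, weights):
        if peaks and mu - peaks[-1][0] < cfg.het_min_sep:
            total = peaks[-1][1] + w
            peaks[-1][0] = (peaks[-1][0] * peaks[-1][1] + mu * w) / total
            peaks[-1][1] = total
        else:
            peaks.append([float(mu), float(w)])
    peaks.sort(key=lambda p: -p[1])
    allele1_mean = peaks[0][0]
    alleles = [_round_half_up(allele1_mean)]
    allele_w = [peaks[0][1]]
    for mu, w in peaks[1:]:
        if w >= cfg.het_min_weight and abs(mu - allele1_mean) >= cfg.het_min_sep:
            alleles.append(_round_half_up(mu))
            allele_w.append(w)
            break
    pairs = sorted(zip(alleles, allele_w))
    alleles = [a for a, _ in pairs]
    allele_w = [w for _, w in pairs]
    support = [int(np.sum(np.abs(values - a) <= cfg.support_window)) for a in alleles]
    return GenotypeCall(
        alleles=tuple(alleles),
        weights=tuple(allele_w),
        support=tuple(support),
        k=int(best_gmm.n_components),
        aic=float(best_aic),
        low_coverage=False,
        degenerate=False,
        histogram=hist,
    )


@dataclass(frozen=True)
class TelomereSummary:
    """Per-read telomere repeat counts with cohort median and spread."""

    per_read: dict[str, int]
    median: float | None
    sd: float | None


def quantify_telomere(
    reads: list[tuple[str, np.ndarray, int, int]],
    unit_len: int,
    cfg: CallerConfig | None = None,
) -> TelomereSummary:
    """Quantify a telomeric repeat from single-flank-anchored reads.

    ``reads`` holds ``(read_id, per-base labels, flank_anchor, mapq)``
    tuples; the anchor is the read coordinate where the subtelomeric flank
    ends and the repeat may begin.  Only reads confidently mapped to the
    flank (mapq >= ``min_mapq``) contribute.  Per read, the count is the
    merged in-repeat run extending from the anchor toward the read end
    divided by the unit length; no second flank is required, so counts are
    lower bounds when reads end inside the repeat.
    """
    cfg = cfg or CallerConfig()
    per_read: dict[str, int] = {}
    for read_id, labels, anchor, mapq in reads:
        if mapq < cfg.min_mapq:
            continue
        segments = merge_predictions(np.asarray(labels)[anchor:], unit_len)
        if not segments:
            continue
        # the run anchored at (or nearest to) the flank, toward the read end
        a, b = segments[0]
        if a >= unit_len:  # not anchored at the flank
            continue
        per_read[read_id] = _round_half_up((b - a) / unit_len)
    if not per_read:
        warnings.warn("no anchored reads passed the mapping-quality gate", stacklevel=2)
        return TelomereSummary(per_read={}, median=None, sd=None)
    vals = np.array(list(per_read.values()), dtype=np.float64)
    return TelomereSummary(
        per_read=per_read,
        median=float(np.median(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    )
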