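"""Promoter/enhancer classification, super-enhancer calling, and domain pooling.

The stage mirrors the standard H3K27ac workflow: peaks landing within a
configurable window of an annotated TSS (default 2.5 kb) are promoters; the
rest are enhancers.  Each enhancer is scored by the summed normalized H3K27ac
density over its bases, and the rank-ordered score curve is cut at the
slope-1 tangent point (the ROSE criterion) to separate typical enhancers from
super-enhancers, per sample.  Elements of one class are then pooled across
samples into promoter/enhancer/super-enhancer *domains* (PD/ED/SED) by taking
the union of overlapping intervals, and each domain is labelled
tumor-specific (T), normal-specific (N) or common (C) according to the
conditions of the samples that support it.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .genomic_core import GeneAnnotation, GenomicInterval, merge_intervals

__all__ = [
    "Peak",
    "RegulatoryElement",
    "Domain",
    "ElementConfig",
    "classify_peaks",
    "score_enhancers",
    "rose_cutoff",
    "call_elements",
    "pool_domains",
]

CATEGORIES = ("PD", "ED", "SED")
ELEMENT_FOR_CATEGORY = {"P": "PD", "E": "ED", "SE": "SED"}


@dataclass(frozen=True)
class Peak:
    """An H3K27ac peak with its normalized signal density (CNV/GC corrected upstream)."""

    interval: GenomicInterval
    signal: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative signal {self.signal} in {self.sample_id}")


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # promoter | enhancer | super_enhancer
    sample_id: str
    se_score: float | None = None  # present for enhancer classes only

    def __post_init__(self) -> None:
        if self.element_class not in ("promoter", "enhancer", "super_enhancer"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if (self.se_score is None) != (self.element_class == "promoter"):
            raise ValueError("se_score must be present iff the element is not a promoter")


@dataclass(frozen=True)
class Domain:
    """A cross-sample union of overlapping elements of one category."""

    interval: GenomicInterval
    category: str  # PD | ED | SED
    specificity: str  # T | N | C
    supporting_samples: frozenset = field(default_factory=frozenset)
    domain_id: str | None = None

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class ElementConfig:
    promoter_window: int = 2500
    stitch_distance: int = 0  # gap for stitching enhancers before SE scoring

    def __post_init__(self) -> None:
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")


def classify_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    cfg: ElementConfig = ElementConfig(),
) -> list[RegulatoryElement]:
    """Partition peaks into promoters and enhancers by TSS proximity.

    A peak is a promoter iff its interval intersects the closed window
    ``[TSS - w, TSS + w]`` of any gene; otherwise it is an enhancer.  At this
    stage enhancers carry a provisional ``se_score`` of 0; scoring happens in
    :func:`score_enhancers`.
    """
    if len(genes) == 0:
        raise ValueError("classify_peaks requires a nonempty gene annotation")
    w = cfg.promoter_window
    # promoter windows as half-open intervals [tss-w, tss+w+1), merged per chrom
    windows = merge_intervals(
        [
            GenomicInterval(g.chrom, max(0, g.tss - w), g.tss + w + 1)
            for g in genes
        ],
        merge_distance=0,
    )
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in windows}:
        chrom_ivs = [iv for iv in windows if iv.chrom == chrom]
        starts[chrom] = np.asarray([iv.start for iv in chrom_ivs])
        ends[chrom] = np.asarray([iv.end for iv in chrom_ivs])

    out: list[RegulatoryElement] = []
    for pk in peaks:
        iv = pk.interval
        is_promoter = False
        if iv.chrom in starts:
            s, e = starts[iv.chrom], ends[iv.chrom]
            # merged windows are disjoint and sorted, so only the last window
            # starting before iv.end can overlap iv
            j = int(np.searchsorted(s, iv.end))
            is_promoter = j > 0 and bool(e[j - 1] > iv.start)
        cls = "promoter" if is_promoter else "enhancer"
        out.append(
            RegulatoryElement(
                iv, cls, pk.sample_id, se_score=None if is_promoter else 0.0
            )
        )
    return out


def score_enhancers(
    elements: Sequence[RegulatoryElement], peaks: Sequence[Peak]
) -> list[RegulatoryElement]:
    """Assign each enhancer the sum of signal x overlap-length of its peak bases."""
    by_chrom: dict[str, list[Peak]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.interval.chrom, []).append(pk)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.interval.start)
    out: list[RegulatoryElement] = []
    for el in elements:
        if el.element_class == "promoter":
            out.append(el)
            continue
        iv = el.interval
        score = 0.0
        for pk in by_chrom.get(iv.chrom, []):
            if pk.sample_id != el.sample_id:
                continue
            if pk.interval.start >= iv.end:
                break
            ov = min(iv.end, pk.interval.end) - max(iv.start, pk.interval.start)
            if ov > 0:
                score += pk.signal * ov
        out.append(RegulatoryElement(iv, el.element_class, el.sample_id, se_score=score))
    return out


def rose_cutoff(scores: Sequence[float]) -> float:
    """Score threshold at the slope-1 tangent of the [0,1]-scaled rank curve.

    Scores are sorted ascending; both the rank index and the score are scaled
    to [0, 1] and the cutoff index is ``argmax_i (x_i - y_i)`` -- for a convex
    curve this is the point where the tangent has slope 1.  Ties break to the
    largest index (fewest super-enhancers).  Elements whose score is strictly
    greater than the returned value are super-enhancers; a constant score
    vector therefore yields none.
    """
    if len(scores) < 3:
        raise ValueError(f"rose_cutoff requires >= 3 scores, got {len(scores)}")
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    if s[-1] == s[0]:
        return float(s[-1])  # constant vector: nothing strictly above
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    diff = x - y
    # argmax with ties to the largest index
    cut = n - 1 - int(np.argmax(diff[::-1]))
    return float(s[cut])


def call_elements(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    cfg: ElementConfig = ElementConfig(),
) -> list[RegulatoryElement]:
    """Classify, (optionally) stitch, score, and threshold a single sample's peaks.

    Returns the sample's promoters, typical enhancers, and super-enhancers.
    With ``stitch_distance > 0`` nearby enhancers are first merged into one
    stitched element whose score sums its constituent peaks.
    """
    sample_ids = {pk.sample_id for pk in peaks}
    if len(sample_ids) > 1:
        raise ValueError(f"call_elements expects one sample, got {sorted(sample_ids)}")
    classified = classify_peaks(peaks, genes, cfg)
    promoters = [el for el in classified if el.element_class == "promoter"]
    enhancers = [el for el in classified if el.element_class == "enhancer"]
    if not enhancers:
        return promoters
    sample_id = next(iter(sample_ids))
    if cfg.stitch_distance > 0:
        stitched = merge_intervals([el.interval for el in enhancers], cfg.stitch_distance)
        enhancers = [
            RegulatoryElement(iv, "enhancer", sample_id, se_score=0.0) for iv in stitched
        ]
    enhancers = score_enhancers(enhancers, peaks)
    scores = [el.se_score for el in enhancers]
    if len(scores) >= 3:
        cutoff = rose_cutoff(scores)
    else:
        cutoff = max(scores)  # too few enhancers to define a tangent: call none
    out = list(promoters)
    for el in enhancers:
        cls = "super_enhancer" if el.se_score > cutoff else "enhancer"
        out.append(RegulatoryElement(el.interval, cls, sample_id, se_score=el.se_score))
    return out


_CLASS_FOR_CATEGORY = {"P": "promoter", "E": "enhancer", "SE": "super_enhancer"}


def pool_domains(
    element_sets: Mapping[str, Sequence[RegulatoryElement]],
    category: str,
    sample_conditions: Mapping[str, str],
    pool_gap: int = 0,
) -> list[Domain]:
    """Pool one element category across samples into specificity-labelled domains.

    ``element_sets`` maps sample_id -> that sample's elements;
    ``sample_conditions`` maps sample_id -> ``tumor`` | ``normal``.
    ``category`` is ``P``, ``E`` or ``SE``.  Domains are the union of
    overlapping member intervals (gap ``pool_gap``, default strict overlap);
    a domain is T if all supporters are tumor samples, N if all normal,
    C otherwise.
    """
    if category not in _CLASS_FOR_CATEGORY:
        raise ValueError(f"unknown category {category!r}; expected one of P, E, SE")
    if len(element_sets) == 0:
        raise ValueError("pool_domains requires >= 1 sample")
    for sid in element_sets:
        if sid not in sample_conditions:
            raise ValueError(f"sample {sid!r} missing from sample_conditions")
        if sample_conditions[sid] not in ("tumor", "normal"):
            raise ValueError(f"condition for {sid!r} must be 'tumor' or 'normal'")
    wanted = _CLASS_FOR_CATEGORY[category]
    members: list[tuple[GenomicInterval, str]] = []
    for sid in sorted(element_sets):
        for el in element_sets[sid]:
            if el.element_class == wanted:
                members.append((el.interval, sid))
    if not members:
        return []
    merged = merge_intervals([iv for iv, _ in members], merge_distance=pool_gap)

    # index member starts per chrom for supporter lookup
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv, sid in members:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, sid))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    cat_name = ELEMENT_FOR_CATEGORY[category]
    domains: list[Domain] = []
    for i, dom_iv in enumerate(merged):
        supporters = set()
        for s, e, sid in by_chrom.get(dom_iv.chrom, []):
            if s >= dom_iv.end:
                break
            if e > dom_iv.start:
                supporters.add(sid)
        conds = {sample_conditions[sid] for sid in supporters}
        spec = "T" if conds == {"tumor"} else "N" if conds == {"normal"} else "C"
        domains.append(
            Domain(
                dom_iv,
                cat_name,
                spec,
                frozenset(supporters),
                domain_id=f"{cat_name}{i + 1:05d}",
            )
        )
    return domains
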