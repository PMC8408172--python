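"""Double/single IBS classification and runs of homozygosity.

From unphased data, "double IBS" is operationalised as genotype identity
(both alleles match as multisets) at fully-called markers; "single IBS" is
allele sharing without identity; "none" is a fully-called disjoint pair.
Markers with any missing allele are uninformative: they bridge runs but
never start, end, or break them.  Genome fractions are reported relative to
total genetic map span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import MISSING, GeneticMap, SharedSegment
from .splosh import mark_states, segments_from_states

DOUBLE, SINGLE, NONE, UNINF = np.int8(2), np.int8(1), np.int8(0), np.int8(-1)

CLASS_NAMES = {DOUBLE: "DOUBLE", SINGLE: "SINGLE", NONE: "NONE", UNINF: "UNINFORMATIVE"}

__all__ = ["IBSClassTrack", "ROHSegment", "classify_ibs", "find_roh", "coinciding_roh"]


@dataclass
class IBSClassTrack:
    """Per-marker IBS class plus merged per-class intervals and fractions."""

    classes: np.ndarray  # int8 per marker
    intervals: dict[str, list[SharedSegment]]  # class name -> segments >= min_length
    fractions: dict[str, float]  # class name -> summed length / total span
    min_length: float


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chromosome: str
    start_cM: float
    end_cM: float
    start_marker: str
    end_marker: str

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def _marker_classes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a0, a1 = a[:, 0], a[:, 1]
    b0, b1 = b[:, 0], b[:, 1]
    full = (a0 != MISSING) & (a1 != MISSING) & (b0 != MISSING) & (b1 != MISSING)
    # multiset identity for unordered pairs
    ident = ((a0 == b0) & (a1 == b1)) | ((a0 == b1) & (a1 == b0))
    share = np.zeros(len(a0), dtype=bool)
    for x in (a0, a1):
        for y in (b0, b1):
            share |= (x == y) & (x != MISSING)
    out = np.full(len(a0), UNINF, dtype=np.int8)
    out[full & ident] = DOUBLE
    out[full & share & ~ident] = SINGLE
    out[full & ~share] = NONE
    return out


def _subtract_intervals(
    base: list[SharedSegment], minus: list[SharedSegment]
) -> list[tuple[str, float, float]]:
    """Per-chromosome set difference of closed cM intervals."""
    out: list[tuple[str, float, float]] = []
    for s in base:
        pieces = [(s.start_cM, s.end_cM)]
        for m in minus:
            if m.chromosome != s.chromosome:
                continue
            nxt = []
            for lo, hi in pieces:
                if m.end_cM <= lo or m.start_cM >= hi:
                    nxt.append((lo, hi))
                    continue
                if m.start_cM > lo:
                    nxt.append((lo, m.start_cM))
                if m.end_cM < hi:
                    nxt.append((m.end_cM, hi))
            pieces = nxt
        out.extend((s.chromosome, lo, hi) for lo, hi in pieces if hi > lo)
    return out


def classify_ibs(
    a: np.ndarray,
    b: np.ndarray,
    gmap: GeneticMap,
    min_length: float = 10.0,
    *,
    id_a: str = "a",
    id_b: str = "b",
) -> IBSClassTrack:
    """Classify each marker of a pair and build per-class genome intervals.

    DOUBLE intervals are maximal runs of genotype identity (uninformative
    markers bridge; any other fully-called class breaks).  SINGLE intervals
    are the shared-haplotype (>= 1 allele in common, missing bridges)
    coverage with the DOUBLE intervals subtracted: inside a region sharing
    exactly one homolog the second pair of homologs still matches by chance
    at many markers, so marker-level SINGLE calls alone fragment into runs
    far shorter than any reporting threshold.  NONE intervals are maximal
    runs of fully-called disjoint genotypes.  Intervals with length >=
    ``min_length`` are kept; fractions are kept-length sums over the map
    span.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    classes = _marker_classes(a, b)
    intervals: dict[str, list[SharedSegment]] = {}
    fractions: dict[str, float] = {}
    span = gmap.total_span

    def _runs_for(cls):
        states = np.where(classes == cls, 1, np.where(classes == UNINF, 0, -1)).astype(np.int8)
        return segments_from_states(
            states, gmap, 0.0, id_a=id_a, id_b=id_b, segment_class=CLASS_NAMES[cls]
        )

    double_all = _runs_for(DOUBLE)
    intervals["DOUBLE"] = [s for s in double_all if s.length_cM >= min_length]

    match_states = mark_states(a, b, gmap)
    match_segs = segments_from_states(match_states, gmap, 0.0, id_a=id_a, id_b=id_b)
    single: list[SharedSegment] = []
    pos = gmap.position
    slices = gmap.chrom_slices()
    for chrom, lo_cM, hi_cM in _subtract_intervals(match_segs, intervals["DOUBLE"]):
        if hi_cM - lo_cM < min_length:
            continue
        lo, hi = slices[chrom]
        i = lo + int(np.searchsorted(pos[lo:hi], lo_cM, side="left"))
        j = lo + int(np.searchsorted(pos[lo:hi], hi_cM, side="right")) - 1
        single.append(
            SharedSegment(
                id_a=id_a,
                id_b=id_b,
                chromosome=chrom,
                start_cM=lo_cM,
                end_cM=hi_cM,
                start_marker=gmap.markers[min(i, j)],
                end_marker=gmap.markers[max(i, j)],
                segment_class="SINGLE",
            )
        )
    intervals["SINGLE"] = single
    intervals["NONE"] = [s for s in _runs_for(NONE) if s.length_cM >= min_length]

    for name, segs in intervals.items():
        fractions[name] = sum(s.length_cM for s in segs) / span if span else 0.0
    return IBSClassTrack(classes=classes, intervals=intervals, fractions=fractions, min_length=min_length)


def find_roh(
    g: np.ndarray,
    gmap: GeneticMap,
    min_length: float = 10.0,
    *,
    individual: str = "?",
) -> list[ROHSegment]:
    """Runs of homozygosity: maximal runs bounded by fully-called homozygous
    markers, heterozygous markers break, missing data bridges; runs with
    length >= ``min_length`` kept (default 10 cM)."""
    g = np.asarray(g)
    a0, a1 = g[:, 0], g[:, 1]
    full = (a0 != MISSING) & (a1 != MISSING)
    hom = full & (a0 == a1)
    states = np.where(hom, 1, np.where(full, -1, 0)).astype(np.int8)
    segs = segments_from_states(states, gmap, min_length, id_a=individual, id_b=individual, segment_class="ROH")
    return [
        ROHSegment(individual, s.chromosome, s.start_cM, s.end_cM, s.start_marker, s.end_marker)
        for s in segs
    ]


def coinciding_roh(
    rohs_a: list[ROHSegment], rohs_b: list[ROHSegment]
) -> tuple[list[tuple[str, float, float]], float]:
    """Pairwise intersections of two ROH sets on the same map.

    Returns (list of (chromosome, start_cM, end_cM), total cM).
    """
    out: list[tuple[str, float, float]] = []
    total = 0.0
    for ra in rohs_a:
        for rb in rohs_b:
            if ra.chromosome != rb.chromosome:
                continue
            s = max(ra.start_cM, rb.start_cM)
            e = min(ra.end_cM, rb.end_cM)
            if s <= e:
                out.append((ra.chromosome, s, e))
                total += e - s
    return out, total
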