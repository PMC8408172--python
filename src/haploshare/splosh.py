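"""Shared-haplotype (IBS segment) detection and SPLoSH.

A shared haplotype between two individuals is a region that starts and ends
with markers where the pair has at least one allele in common, and where
every marker in between either also shares an allele or carries missing data
on one or both sides (missing data bridges, so occasional no-calls do not
truncate a true shared stretch).  Segment lengths in cM that pass a
user-chosen threshold are summed into SPLoSH, the "summed potential lengths
of shared haplotypes", for each pair.

Matching works on unphased genotypes; a phased homolog participates as a
doubled genotype (allele ``a`` -> genotype ``aa``), which makes homolog
matching strictly stronger than genotype sharing.  The null allele ``C`` is
an ordinary third allele: it matches only ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeSet,
    SharedSegment,
)

MATCH = np.int8(1)
UNINFORMATIVE = np.int8(0)
MISMATCH = np.int8(-1)

DEFAULT_THRESHOLDS = (20.0, 25.0, 30.0, 35.0, 40.0)

__all__ = [
    "MATCH",
    "MISMATCH",
    "UNINFORMATIVE",
    "DEFAULT_THRESHOLDS",
    "mark_states",
    "find_shared_segments",
    "segments_from_states",
    "pair_splosh",
    "compute_splosh",
]


def mark_states(a: np.ndarray, b: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Per-marker MATCH / MISMATCH / UNINFORMATIVE vector for a pair.

    ``a`` and ``b`` are (n_markers, 2) allele-code arrays aligned to ``gmap``.
    MATCH: the called alleles intersect.  MISMATCH: both genotypes fully
    called and disjoint.  UNINFORMATIVE: anything else (a half-called
    genotype can match through its called allele but can never mismatch).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != (gmap.n_markers, 2) or b.shape != (gmap.n_markers, 2):
        raise ValueError("genotype track length does not match the map")
    a0, a1 = a[:, 0], a[:, 1]
    b0, b1 = b[:, 0], b[:, 1]
    match = np.zeros(gmap.n_markers, dtype=bool)
    for x in (a0, a1):
        for y in (b0, b1):
            match |= (x == y) & (x != MISSING)
    full_a = (a0 != MISSING) & (a1 != MISSING)
    full_b = (b0 != MISSING) & (b1 != MISSING)
    states = np.zeros(gmap.n_markers, dtype=np.int8)
    states[match] = MATCH
    states[~match & full_a & full_b] = MISMATCH
    return states


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (first, last) MATCH-bounded runs in a single-chromosome state
    vector: no MISMATCH inside, UNINFORMATIVE allowed inside but trimmed
    from the ends.  Indices are inclusive."""
    out: list[tuple[int, int]] = []
    n = len(states)
    block_start = 0
    mis = np.flatnonzero(states == MISMATCH)
    bounds = list(mis) + [n]
    for b in bounds:
        if b > block_start:
            seg = states[block_start:b]
            hits = np.flatnonzero(seg == MATCH)
            if hits.size:
                out.append((block_start + int(hits[0]), block_start + int(hits[-1])))
        block_start = b + 1
    return out


def segments_from_states(
    states: np.ndarray,
    gmap: GeneticMap,
    min_length: float = 0.0,
    *,
    id_a: str = "a",
    id_b: str = "b",
    segment_class: str = "IBS",
    hom_a: int | None = None,
    hom_b: int | None = None,
) -> list[SharedSegment]:
    """Build maximal segments per chromosome from a state vector and keep
    those with length >= ``min_length`` (ties kept)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    segs: list[SharedSegment] = []
    pos = gmap.position
    for chrom, (lo, hi) in gmap.chrom_slices().items():
        for i, j in _runs(states[lo:hi]):
            i += lo
            j += lo
            length = float(pos[j] - pos[i])
            if length >= min_length:
                segs.append(
                    SharedSegment(
                        id_a=id_a,
                        id_b=id_b,
                        chromosome=chrom,
                        start_cM=float(pos[i]),
                        end_cM=float(pos[j]),
                        start_marker=gmap.markers[i],
                        end_marker=gmap.markers[j],
                        segment_class=segment_class,
                        hom_a=hom_a,
                        hom_b=hom_b,
                    )
                )
    return segs


def find_shared_segments(
    a: np.ndarray,
    b: np.ndarray,
    gmap: GeneticMap,
    min_length: float = 0.0,
    **meta,
) -> list[SharedSegment]:
    """Shared IBS segments between two genotype (or doubled-homolog) tracks."""
    return segments_from_states(mark_states(a, b, gmap), gmap, min_length, **meta)


# ---------------------------------------------------------------------------
# SPLoSH
# ---------------------------------------------------------------------------


def _sum_lengths(segs: Iterable[SharedSegment]) -> float:
    return float(sum(s.length_cM for s in segs))


def _union_length(intervals: list[tuple[str, float, float]]) -> float:
    """Total length of the union of (chromosome, start, end) intervals."""
    total = 0.0
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def _splosh_uu(ga, gb, gmap, threshold):
    return _sum_lengths(find_shared_segments(ga, gb, gmap, threshold))


def _splosh_pu(haps: HaplotypeSet, ind_p: str, g_other: np.ndarray, gmap, threshold):
    """Phased x unphased: sum kept segment lengths over the two homologs of
    the phased individual against the other's unphased genotype.  Homozygous
    stretches of the phased side are consequently counted twice."""
    total = 0.0
    for hom in (0, 1):
        total += _sum_lengths(find_shared_segments(haps.doubled(ind_p, hom), g_other, gmap, threshold))
    return total


def _splosh_pp_directed(haps: HaplotypeSet, a: str, b: str, gmap, threshold):
    """A -> B direction: per homolog of A, length of the union of kept
    segments against either homolog of B; summed over A's homologs."""
    total = 0.0
    for hom_a in (0, 1):
        ivs: list[tuple[str, float, float]] = []
        da = haps.doubled(a, hom_a)
        for hom_b in (0, 1):
            for s in find_shared_segments(da, haps.doubled(b, hom_b), gmap, threshold):
                ivs.append((s.chromosome, s.start_cM, s.end_cM))
        if ivs:
            total += _union_length(ivs)
    return total


def pair_splosh(
    id_a: str,
    id_b: str,
    gmap: GeneticMap,
    threshold: float,
    mode: str,
    genotypes: GenotypeMatrix | None = None,
    haplotypes: HaplotypeSet | None = None,
) -> float:
    """SPLoSH (cM) for one pair at one threshold in one phasing mode.

    Modes: ``UU`` unphased x unphased; ``PU`` a phased x b unphased; ``UP``
    a unphased x b phased; ``PU/UP`` the average of the two arrangements
    (the statistic reported when both forms exist); ``PP`` both phased
    (per-homolog union, symmetrised by averaging the two directions).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")

    def geno(ind):
        if genotypes is not None and ind in genotypes:
            return genotypes.get(ind)
        if haplotypes is not None and ind in haplotypes:
            return haplotypes.genotype(ind)
        raise KeyError(f"no unphased genotype for {ind!r}")

    if mode == "UU":
        return _splosh_uu(geno(id_a), geno(id_b), gmap, threshold)
    if mode == "PU":
        if haplotypes is None or id_a not in haplotypes:
            raise KeyError(f"no phased data for {id_a!r}")
        return _splosh_pu(haplotypes, id_a, geno(id_b), gmap, threshold)
    if mode == "UP":
        if haplotypes is None or id_b not in haplotypes:
            raise KeyError(f"no phased data for {id_b!r}")
        return _splosh_pu(haplotypes, id_b, geno(id_a), gmap, threshold)
    if mode == "PU/UP":
        return 0.5 * (
            pair_splosh(id_a, id_b, gmap, threshold, "PU", genotypes, haplotypes)
            + pair_splosh(id_a, id_b, gmap, threshold, "UP", genotypes, haplotypes)
        )
    if mode == "PP":
        if haplotypes is None or id_a not in haplotypes or id_b not in haplotypes:
            raise KeyError("PP mode needs phased data for both individuals")
        return 0.5 * (
            _splosh_pp_directed(haplotypes, id_a, id_b, gmap, threshold)
            + _splosh_pp_directed(haplotypes, id_b, id_a, gmap, threshold)
        )
    raise ValueError(f"unknown phasing mode {mode!r}")


def compute_splosh(
    pairs: Sequence[tuple[str, str]] | None,
    gmap: GeneticMap,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    genotypes: GenotypeMatrix | None = None,
    haplotypes: HaplotypeSet | None = None,
    modes: Sequence[str] = ("UU",),
) -> pd.DataFrame:
    """SPLoSH table over pairs x thresholds x phasing modes.

    ``pairs=None`` means all unordered pairs of available individuals.
    Columns: id_a, id_b, phasing_type, threshold_cM, splosh_cM.
    """
    if pairs is None:
        inds = list(genotypes.individuals if genotypes is not None else haplotypes.individuals)
        pairs = list(combinations(inds, 2))
    rows = []
    for id_a, id_b in pairs:
        for mode in modes:
            # states are threshold-independent; reuse across thresholds
            for t in thresholds:
                rows.append((id_a, id_b, mode, float(t), pair_splosh(id_a, id_b, gmap, t, mode, genotypes, haplotypes)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "phasing_type", "threshold_cM", "splosh_cM"])
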