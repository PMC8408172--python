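"""Gene-dropping pedigree simulator with founder-origin bookkeeping.

Meiosis follows the Haldane (no-interference) model: per chromosome the
crossover count is Poisson with mean span/100 (cM), crossover positions are
uniform on the span, and the starting homolog is chosen with probability
1/2.  Every simulated homolog carries a piecewise-constant founder-origin
label track alongside its allele sequence, so true IBD between any two
individuals can be read off exactly — this is the ground truth every
detection-level statistic is validated against.

Relationship templates instantiate the pair classes used for reference
distributions: FSIB, HSIB, GPGC, HAAM, OSGP and NKCR, with fresh founders
per family (unless endogamy is requested, which reuses a shared founder
pool to inflate background sharing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeSet,
    Pedigree,
    RelationshipCatalog,
)

__all__ = [
    "LabelledHomolog",
    "FounderLabelledGenome",
    "SimDesign",
    "cherry_like_map",
    "apple_like_map",
    "random_map",
    "make_founder",
    "simulate_gamete",
    "simulate_population",
    "SimResult",
    "true_ibd_segments",
    "ibd_totals",
]


@dataclass
class LabelledHomolog:
    """One homolog: founder-origin label track + allele vector.

    ``breaks[chrom]`` are segment start positions (cM, first always the
    chromosome start) and ``labels[chrom]`` the founder-homolog id active
    from each start; ``alleles`` is aligned to the map's markers.
    """

    breaks: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    alleles: np.ndarray  # int8 (n_markers,)

    def label_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks[chrom], pos, side="right") - 1
        return self.labels[chrom][idx]


@dataclass
class FounderLabelledGenome:
    """Two labelled homologs for one individual."""

    homologs: tuple[LabelledHomolog, LabelledHomolog]


def _chrom_bounds(gmap: GeneticMap) -> dict[str, tuple[float, float]]:
    out = {}
    for c, (lo, hi) in gmap.chrom_slices().items():
        out[c] = (float(gmap.position[lo]), float(gmap.position[hi - 1]))
    return out


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------


def random_map(
    n_chromosomes: int,
    total_span: float,
    n_markers: int,
    rng: np.random.Generator,
    prefix: str = "chr",
) -> GeneticMap:
    """Multi-chromosome map of the given total span with markers placed
    uniformly at random; both chromosome ends always carry a marker."""
    spans = np.full(n_chromosomes, total_span / n_chromosomes)
    markers, chroms, pos = [], [], []
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    for i in range(n_chromosomes):
        k = max(int(per[i]), 2)
        p = np.sort(rng.uniform(0, spans[i], size=k - 2)) if k > 2 else np.array([])
        p = np.concatenate([[0.0], p, [spans[i]]])
        for j, x in enumerate(p):
            markers.append(f"{prefix}{i + 1}_m{j + 1}")
            chroms.append(f"{prefix}{i + 1}")
            pos.append(float(x))
    return GeneticMap(tuple(markers), tuple(chroms), np.array(pos))


def cherry_like_map(rng: np.random.Generator, n_markers: int = 1617) -> GeneticMap:
    """Map emulating the sweet-cherry reference: 8 chromosomes, 655 cM."""
    return random_map(8, 655.0, n_markers, rng)


def apple_like_map(rng: np.random.Generator, n_markers: int = 10295) -> GeneticMap:
    """Map emulating the apple reference: 17 chromosomes, 1267 cM."""
    return random_map(17, 1267.0, n_markers, rng)


# ---------------------------------------------------------------------------
# Founders and meiosis
# ---------------------------------------------------------------------------


def make_founder(
    gmap: GeneticMap,
    freqs: np.ndarray,
    null_freq: float,
    rng: np.random.Generator,
    label_start: int,
) -> FounderLabelledGenome:
    """Founder with two fresh homolog labels; B-allele frequency per marker
    from ``freqs``, then a ``null_freq`` chance of replacing with C."""
    bounds = _chrom_bounds(gmap)
    homs = []
    for h in range(2):
        alleles = (rng.random(gmap.n_markers) < freqs).astype(np.int8)  # 0=A, 1=B
        if null_freq > 0:
            alleles[rng.random(gmap.n_markers) < null_freq] = 2  # C
        breaks = {c: np.array([b[0]]) for c, b in bounds.items()}
        labels = {c: np.array([label_start + h]) for c in bounds}
        homs.append(LabelledHomolog(breaks, labels, alleles))
    return FounderLabelledGenome((homs[0], homs[1]))


def simulate_gamete(
    parent: FounderLabelledGenome, gmap: GeneticMap, rng: np.random.Generator
) -> LabelledHomolog:
    """One meiotic product of ``parent`` under the Haldane model."""
    bounds = _chrom_bounds(gmap)
    slices = gmap.chrom_slices()
    alleles = np.empty(gmap.n_markers, dtype=np.int8)
    breaks: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    h0, h1 = parent.homologs
    for chrom, (start, end) in bounds.items():
        span = end - start
        k = rng.poisson(span / 100.0) if span > 0 else 0
        xovers = np.sort(rng.uniform(start, end, size=k))
        first = int(rng.integers(2))
        lo, hi = slices[chrom]
        pos = gmap.position[lo:hi]
        # source homolog flips at each crossover
        src = (first + np.searchsorted(xovers, pos, side="right")) % 2
        alleles[lo:hi] = np.where(src == 0, h0.alleles[lo:hi], h1.alleles[lo:hi])
        # label track: combine crossover breakpoints with parental segment breakpoints
        bps = np.unique(np.concatenate([[start], xovers, h0.breaks[chrom], h1.breaks[chrom]]))
        bps = bps[(bps >= start) & (bps <= end)]
        seg_src = (first + np.searchsorted(xovers, bps, side="right")) % 2
        seg_lab = np.where(
            seg_src == 0,
            h0.label_at(chrom, bps),
            h1.label_at(chrom, bps),
        )
        # merge adjacent equal labels
        keep = np.concatenate([[True], seg_lab[1:] != seg_lab[:-1]])
        breaks[chrom] = bps[keep]
        labels[chrom] = seg_lab[keep]
    return LabelledHomolog(breaks, labels, alleles)


def mate(
    p1: FounderLabelledGenome, p2: FounderLabelledGenome, gmap: GeneticMap, rng: np.random.Generator
) -> FounderLabelledGenome:
    return FounderLabelledGenome((simulate_gamete(p1, gmap, rng), simulate_gamete(p2, gmap, rng)))


# ---------------------------------------------------------------------------
# Population templates
# ---------------------------------------------------------------------------


@dataclass
class SimDesign:
    """Study conditions for a simulated dataset.

    Defaults emulate the cherry-scale reference setting: 8 chromosomes,
    655 cM, 1617 biallelic SNPs, founder B-allele frequencies uniform on
    (0.2, 0.8).  Missing/error/null rates default to 0 (error-free truth);
    realistic array noise can be switched on per run.
    """

    n_chromosomes: int = 8
    total_span: float = 655.0
    n_markers: int = 1617
    freq_low: float = 0.2
    freq_high: float = 0.8
    missing_rate: float = 0.0
    error_rate: float = 0.0
    null_freq: float = 0.0
    templates: dict[str, int] = field(default_factory=dict)  # label -> n pairs
    endogamy: bool = False
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.error_rate, self.null_freq):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SimResult:
    map: GeneticMap
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeSet
    pedigree: Pedigree
    catalog: RelationshipCatalog
    truth: dict[str, FounderLabelledGenome]


def _template_builders() -> dict[str, Callable]:
    """Each builder returns (pair ids, new individuals dict, pedigree records).

    Builders draw fresh founders via the supplied factory; intermediate
    (non-pair) individuals are kept so parent links resolve.
    """

    def fsib(new_founder, cross, tag):
        f1, f2 = new_founder(f"{tag}_P1"), new_founder(f"{tag}_P2")
        a = cross(f"{tag}_A", f1, f2)
        b = cross(f"{tag}_B", f1, f2)
        return a, b

    def hsib(new_founder, cross, tag):
        shared = new_founder(f"{tag}_P")
        m1, m2 = new_founder(f"{tag}_M1"), new_founder(f"{tag}_M2")
        a = cross(f"{tag}_A", shared, m1)
        b = cross(f"{tag}_B", shared, m2)
        return a, b

    def gpgc(new_founder, cross, tag):
        g1, g2 = new_founder(f"{tag}_G1"), new_founder(f"{tag}_G2")
        parent = cross(f"{tag}_P", g1, g2)
        mate_ = new_founder(f"{tag}_M")
        child = cross(f"{tag}_C", parent, mate_)
        return g1, child

    def haam(new_founder, cross, tag):
        # half-sibs X and Y; Z = child of Y: (X, Z) is half-avuncular, COR 1/8
        shared = new_founder(f"{tag}_P")
        m1, m2, m3 = (new_founder(f"{tag}_M{i}") for i in (1, 2, 3))
        x = cross(f"{tag}_X", shared, m1)
        y = cross(f"{tag}_Y", shared, m2)
        z = cross(f"{tag}_Z", y, m3)
        return x, z

    def osgp(new_founder, cross, tag):
        # half first cousins: one shared grandparent, COR 1/16
        g = new_founder(f"{tag}_G")
        m1, m2, m3, m4 = (new_founder(f"{tag}_M{i}") for i in (1, 2, 3, 4))
        p1 = cross(f"{tag}_P1", g, m1)
        p2 = cross(f"{tag}_P2", g, m2)
        a = cross(f"{tag}_A", p1, m3)
        b = cross(f"{tag}_B", p2, m4)
        return a, b

    def nkcr(new_founder, cross, tag):
        return new_founder(f"{tag}_A"), new_founder(f"{tag}_B")

    return {"FSIB": fsib, "HSIB": hsib, "GPGC": gpgc, "HAAM": haam, "OSGP": osgp, "NKCR": nkcr}


def simulate_population(design: SimDesign) -> SimResult:
    """Instantiate the relationship templates of ``design`` and observe them.

    Returns truth-phased haplotypes, an observation-layer unphased genotype
    matrix (with missingness / allele-call errors applied), the pedigree,
    the labelled pair catalog and the founder-origin truth.
    """
    rng = np.random.default_rng(design.seed)
    gmap = random_map(design.n_chromosomes, design.total_span, design.n_markers, rng)
    return _simulate_on_map(design, gmap, rng)


def _simulate_on_map(design: SimDesign, gmap: GeneticMap, rng: np.random.Generator) -> SimResult:
    freqs = rng.uniform(design.freq_low, design.freq_high, size=gmap.n_markers)
    truth: dict[str, FounderLabelledGenome] = {}
    records: dict[str, tuple[str | None, str | None]] = {}
    label_counter = [0]
    founder_pool: list[str] = []

    def new_founder(name: str) -> str:
        if design.endogamy and founder_pool and rng.random() < 0.5:
            # reuse an existing founder: shared recent ancestry across families
            return str(rng.choice(founder_pool))
        truth[name] = make_founder(gmap, freqs, design.null_freq, rng, label_counter[0])
        label_counter[0] += 2
        records[name] = (None, None)
        founder_pool.append(name)
        return name

    def cross(name: str, p1: str, p2: str) -> str:
        truth[name] = mate(truth[p1], truth[p2], gmap, rng)
        records[name] = (p1, p2)
        return name

    builders = _template_builders()
    pair_rows = []
    for label, n_pairs in design.templates.items():
        if label not in builders:
            raise ValueError(f"unknown relationship template {label!r}")
        for i in range(n_pairs):
            a, b = builders[label](new_founder, cross, f"{label}{i}")
            pair_rows.append((a, b, label))

    individuals = list(truth)
    n_ind = len(individuals)
    haps = np.empty((n_ind, 2, gmap.n_markers), dtype=np.int8)
    for i, ind in enumerate(individuals):
        haps[i, 0] = truth[ind].homologs[0].alleles
        haps[i, 1] = truth[ind].homologs[1].alleles
    haplotypes = HaplotypeSet(gmap, individuals, haps.copy())

    calls = np.transpose(haps, (0, 2, 1)).copy()
    if design.error_rate > 0:
        flip = rng.random(calls.shape) < design.error_rate
        # an allele-call error replaces the allele with a random A/B call
        calls[flip] = rng.integers(0, 2, size=int(flip.sum()), dtype=np.int8)
    if design.missing_rate > 0:
        # whole-genotype no-calls, as on arrays
        miss = rng.random((n_ind, gmap.n_markers)) < design.missing_rate
        calls[miss] = MISSING
    genotypes = GenotypeMatrix(gmap, individuals, calls)

    catalog = RelationshipCatalog(pd.DataFrame(pair_rows, columns=["id_a", "id_b", "label"]))
    return SimResult(gmap, genotypes, haplotypes, Pedigree(records), catalog, truth)


# ---------------------------------------------------------------------------
# True IBD
# ---------------------------------------------------------------------------


def true_ibd_segments(
    truth: dict[str, FounderLabelledGenome], a: str, b: str, gmap: GeneticMap
) -> pd.DataFrame:
    """Exact IBD intervals between two individuals from founder labels.

    Multiplicity 1: at least one homolog pairing shares a founder label.
    Multiplicity 2: both homologs of each individual are matched under a
    disjoint pairing.  Returns columns chromosome, start_cM, end_cM,
    multiplicity (rows for multiplicity >= 1 and >= 2 separately merged).
    """
    ga, gb = truth[a], truth[b]
    rows = []
    bounds = _chrom_bounds(gmap)
    for chrom, (start, end) in bounds.items():
        bps = np.unique(
            np.concatenate(
                [[start, end]]
                + [h.breaks[chrom] for h in ga.homologs]
                + [h.breaks[chrom] for h in gb.homologs]
            )
        )
        bps = bps[(bps >= start) & (bps <= end)]
        mids = 0.5 * (bps[:-1] + bps[1:])
        la1, la2 = (h.label_at(chrom, mids) for h in ga.homologs)
        lb1, lb2 = (h.label_at(chrom, mids) for h in gb.homologs)
        m11, m12, m21, m22 = la1 == lb1, la1 == lb2, la2 == lb1, la2 == lb2
        any1 = m11 | m12 | m21 | m22
        both = (m11 & m22) | (m12 & m21)
        for mult, mask in ((1, any1), (2, both)):
            i = 0
            n = len(mask)
            while i < n:
                if mask[i]:
                    j = i
                    while j + 1 < n and mask[j + 1]:
                        j += 1
                    rows.append((chrom, float(bps[i]), float(bps[j + 1]), mult))
                    i = j + 1
                i += 1
    return pd.DataFrame(rows, columns=["chromosome", "start_cM", "end_cM", "multiplicity"])


def ibd_totals(segments: pd.DataFrame) -> dict[int, float]:
    """Summed cM of IBD coverage at multiplicity >= 1 and >= 2."""
    out = {1: 0.0, 2: 0.0}
    for mult in (1, 2):
        sub = segments[segments["multiplicity"] == mult]
        out[mult] = float((sub["end_cM"] - sub["start_cM"]).sum())
    return out
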