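"""Case-study operators for pedigree reconstruction.

These implement the manual procedures a breeder applies once SPLoSH has
flagged a likely relationship: deduce the alleles a child inherited from an
unknown parent, impute that parent's genome from a half-sib group, test a
candidate grandparent couple through Mendelian inconsistencies, rank
candidate ancestors by haplotype sharing, and check the grandparent-
grandchild evidence criteria on phased data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import MISSING, GeneticMap, GenotypeMatrix, HaplotypeSet, SharedSegment
from .splosh import find_shared_segments, pair_splosh

logger = logging.getLogger(__name__)

UNDETERMINED = np.int8(-1)
CONFLICT = np.int8(-2)

__all__ = [
    "UNDETERMINED",
    "CONFLICT",
    "ObligateAlleleTrack",
    "ImputedParent",
    "GrandparentTestResult",
    "deduce_parental_homologs",
    "impute_group_parent",
    "verify_half_sib",
    "test_grandparent_couple",
    "rank_candidate_ancestors",
    "check_gpgc_criteria",
    "GPGCReport",
]


@dataclass
class ObligateAlleleTrack:
    """Per-marker allele the child necessarily inherited from its unknown
    parent: an allele code, UNDETERMINED (-1), or CONFLICT (-2)."""

    child: str
    alleles: np.ndarray  # int8 (n_markers,)

    @property
    def n_determined(self) -> int:
        return int(np.sum(self.alleles >= 0))

    @property
    def conflicts(self) -> np.ndarray:
        return np.flatnonzero(self.alleles == CONFLICT)


def deduce_parental_homologs(
    child: np.ndarray,
    known_parent: np.ndarray | None,
    gmap: GeneticMap,
    child_id: str = "child",
) -> ObligateAlleleTrack:
    """Deduce the allele the child inherited from its (other, unknown) parent.

    Child homozygous aa -> obligate a.  Child heterozygous ab with the known
    parent homozygous aa -> obligate b (the known parent must have passed a).
    Child heterozygous with the known parent heterozygous, missing, or not
    supplied -> undetermined.  Child aa with a fully-called known parent
    lacking a entirely -> conflict (Mendelian impossibility, typically an
    uncalled null or a bad call).
    """
    child = np.asarray(child)
    n = gmap.n_markers
    if child.shape != (n, 2):
        raise ValueError("child track length does not match the map")
    c0, c1 = child[:, 0], child[:, 1]
    out = np.full(n, UNDETERMINED, dtype=np.int8)

    full_child = (c0 != MISSING) & (c1 != MISSING)
    hom = full_child & (c0 == c1)
    het = full_child & (c0 != c1)
    out[hom] = c0[hom]

    if known_parent is not None:
        known_parent = np.asarray(known_parent)
        p0, p1 = known_parent[:, 0], known_parent[:, 1]
        full_p = (p0 != MISSING) & (p1 != MISSING)
        p_hom = full_p & (p0 == p1)
        # child het, parent homozygous for one of the child's alleles:
        # the other child allele is the obligate one
        m = het & p_hom & (p0 == c0)
        out[m] = c1[m]
        m = het & p_hom & (p0 == c1)
        out[m] = c0[m]
        # Mendelian impossibilities
        p_has = lambda x: ((p0 == x) | (p1 == x)) & full_p
        out[hom & full_p & ~p_has(c0)] = CONFLICT
        out[het & p_hom & (p0 != c0) & (p0 != c1)] = CONFLICT
    return ObligateAlleleTrack(child=child_id, alleles=out)


# ---------------------------------------------------------------------------
# Group-parent imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputedParent:
    """Hypothetical shared parent resolved from a half-sib group."""

    alleles: np.ndarray  # int8 (n_markers, 2); -1 = unresolved slot
    conflict_markers: np.ndarray  # indices where > 2 distinct obligate alleles
    member_tracks: dict[str, ObligateAlleleTrack]
    member_switches: dict[str, dict[str, int]]  # member -> chromosome -> switch count
    member_assignments: dict[str, np.ndarray]  # member -> per-marker homolog (0/1/-1)

    @property
    def fraction_fully_resolved(self) -> float:
        both = np.sum(np.all(self.alleles >= 0, axis=1))
        return float(both) / self.alleles.shape[0]


def _assign_homologs(
    track: np.ndarray, parent_alleles: np.ndarray, gmap: GeneticMap
) -> tuple[np.ndarray, dict[str, int], int]:
    """Greedy left-to-right assignment of an obligate track to the two
    imputed parental homologs, minimising switches per chromosome.

    Markers are informative when the parent is resolved-heterozygous and the
    obligate allele equals one of the two parental alleles.  Returns the
    per-marker homolog choice (0/1, -1 uninformative), per-chromosome switch
    counts, and the number of allele-level conflicts (obligate allele not
    carried by the resolved parent at all).
    """
    p0, p1 = parent_alleles[:, 0], parent_alleles[:, 1]
    det = track >= 0
    resolved = (p0 >= 0) & (p1 >= 0)
    conflict = det & resolved & (track != p0) & (track != p1)
    informative = det & resolved & (p0 != p1) & ~conflict
    choice = np.full(gmap.n_markers, -1, dtype=np.int8)
    choice[informative & (track == p0)] = 0
    choice[informative & (track == p1)] = 1
    switches: dict[str, int] = {}
    for chrom, (lo, hi) in gmap.chrom_slices().items():
        seq = choice[lo:hi]
        seq = seq[seq >= 0]
        switches[chrom] = int(np.sum(seq[1:] != seq[:-1])) if seq.size > 1 else 0
    return choice, switches, int(conflict.sum())


def _phase_imputed(
    alleles: np.ndarray, tracks: list[np.ndarray], gmap: GeneticMap
) -> np.ndarray:
    """Orient the allele pair at each resolved-heterozygous marker into two
    coherent parental homologs by majority linkage vote across the group.

    Each member's obligate track is a mosaic of the two parental homologs
    with few crossovers, so between neighbouring het markers most members
    stay on the same homolog; the orientation maximising that agreement is
    chosen greedily left to right.  Column 0 of the result is homolog 1.
    """
    out = alleles.copy()
    het = (alleles[:, 0] >= 0) & (alleles[:, 1] >= 0) & (alleles[:, 0] != alleles[:, 1])
    stacked = np.stack(tracks)  # (n_members, n_markers)
    for _, (lo, hi) in gmap.chrom_slices().items():
        idx = np.flatnonzero(het[lo:hi]) + lo
        for prev, cur in zip(idx[:-1], idx[1:]):
            votes = 0
            for m in range(stacked.shape[0]):
                op, oc = stacked[m, prev], stacked[m, cur]
                if op < 0 or oc < 0:
                    continue
                on_h1_prev = op == out[prev, 0]
                on_h1_cur = oc == out[cur, 0]
                if (op not in out[prev]) or (oc not in out[cur]):
                    continue
                votes += 1 if on_h1_prev == on_h1_cur else -1
            if votes < 0:
                out[cur] = out[cur, ::-1]
    return out


def impute_group_parent(
    group: list[tuple[np.ndarray, np.ndarray | None]],
    gmap: GeneticMap,
    member_ids: list[str] | None = None,
    min_homozygous_evidence: int = 12,
) -> ImputedParent:
    """Impute the shared unknown parent of a putative half-sib group.

    ``group`` holds (child genotype, known other-parent genotype or None)
    tracks.  Per marker the distinct obligate alleles across members resolve
    the parent: two distinct alleles -> both slots resolved; more than two
    -> conflict (impossible for one diploid parent; marker flagged).  A
    single distinct allele resolves one slot; the parent is additionally
    called homozygous when at least ``min_homozygous_evidence`` members have
    a determined obligate there, since a heterozygous parent transmits the
    same allele to n offspring with probability 2^(1-n) (< 0.1% at n = 12).
    Groups smaller than that leave the second slot open, as only large
    groups can certify homozygosity with biallelic markers.

    Each member's obligate track is then assigned to the two imputed
    homologs greedily, reporting per-chromosome recombination (switch)
    counts.
    """
    if len(group) < 2:
        raise ValueError("need at least 2 group members to impute a parent")
    if len(group) < 3:
        logger.warning("fewer than 3 group members; imputation will be weakly constrained")
    if member_ids is None:
        member_ids = [f"member{i}" for i in range(len(group))]

    tracks = {
        mid: deduce_parental_homologs(child, parent, gmap, child_id=mid)
        for mid, (child, parent) in zip(member_ids, group)
    }
    n = gmap.n_markers
    alleles = np.full((n, 2), -1, dtype=np.int8)
    conflict_markers = []
    stacked = np.stack([t.alleles for t in tracks.values()])
    for i in range(n):
        col = stacked[:, i]
        obs = np.unique(col)
        obs = obs[obs >= 0]
        if len(obs) == 1:
            alleles[i, 0] = obs[0]
            if int(np.sum(col >= 0)) >= min_homozygous_evidence:
                alleles[i, 1] = obs[0]
        elif len(obs) == 2:
            alleles[i] = obs
        elif len(obs) > 2:
            conflict_markers.append(i)

    alleles = _phase_imputed(alleles, [t.alleles for t in tracks.values()], gmap)

    assignments: dict[str, np.ndarray] = {}
    switches: dict[str, dict[str, int]] = {}
    for mid, t in tracks.items():
        choice, sw, _ = _assign_homologs(t.alleles, alleles, gmap)
        assignments[mid] = choice
        switches[mid] = sw
    return ImputedParent(
        alleles=alleles,
        conflict_markers=np.array(conflict_markers, dtype=int),
        member_tracks=tracks,
        member_switches=switches,
        member_assignments=assignments,
    )


def verify_half_sib(
    imputed: ImputedParent,
    candidate: tuple[np.ndarray, np.ndarray | None],
    gmap: GeneticMap,
    max_switches_per_chrom: int = 2,
    candidate_id: str = "candidate",
) -> tuple[bool, int, int]:
    """Is a candidate a half-sib through the imputed parent?

    Consistent when the candidate's obligate track has zero allele-level
    conflicts with the imputed parent and each chromosome's homolog
    assignment needs at most ``max_switches_per_chrom`` switches
    (occasional recombination consistent with Mendelian inheritance).
    Returns (is_consistent, total recombinations, conflicts).
    """
    child, parent = candidate
    track = deduce_parental_homologs(child, parent, gmap, child_id=candidate_id)
    _, switches, conflicts = _assign_homologs(track.alleles, imputed.alleles, gmap)
    total_sw = sum(switches.values())
    ok = conflicts == 0 and all(v <= max_switches_per_chrom for v in switches.values())
    return ok, total_sw, conflicts


# ---------------------------------------------------------------------------
# Grandparent-couple test
# ---------------------------------------------------------------------------


@dataclass
class GrandparentTestResult:
    gp1: str
    gp2: str
    n_inconsistent: int
    inconsistent_markers: list[str]
    n_excluded: int
    excluded_markers: list[str]

    @property
    def verdict(self) -> str:
        if self.n_inconsistent == 0:
            return "consistent: the couple can account for the deduced parental contribution"
        return f"inconsistent at {self.n_inconsistent} markers"


def test_grandparent_couple(
    target: ObligateAlleleTrack,
    gp1: np.ndarray,
    gp2: np.ndarray,
    gmap: GeneticMap,
    gp1_id: str = "gp1",
    gp2_id: str = "gp2",
) -> GrandparentTestResult:
    """Could this couple have produced the missing parent of the grandchild?

    The unknown parent got one homolog from each grandparent, so every
    obligate allele the grandchild inherited from it must be present in at
    least one of the two candidates.  A marker is Mendelian-inconsistent
    when the obligate allele is absent from the called alleles of BOTH
    candidates.  Markers where either candidate has a missing call are
    excluded from the count and reported separately for manual review.
    """
    gp1 = np.asarray(gp1)
    gp2 = np.asarray(gp2)
    det = target.alleles >= 0
    full1 = (gp1[:, 0] != MISSING) & (gp1[:, 1] != MISSING)
    full2 = (gp2[:, 0] != MISSING) & (gp2[:, 1] != MISSING)
    excluded = det & ~(full1 & full2)
    testable = det & full1 & full2
    t = target.alleles
    in1 = (gp1[:, 0] == t) | (gp1[:, 1] == t)
    in2 = (gp2[:, 0] == t) | (gp2[:, 1] == t)
    bad = testable & ~in1 & ~in2
    return GrandparentTestResult(
        gp1=gp1_id,
        gp2=gp2_id,
        n_inconsistent=int(bad.sum()),
        inconsistent_markers=[gmap.markers[i] for i in np.flatnonzero(bad)],
        n_excluded=int(excluded.sum()),
        excluded_markers=[gmap.markers[i] for i in np.flatnonzero(excluded)],
    )


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------


def rank_candidate_ancestors(
    target_id: str,
    population: GenotypeMatrix,
    gmap: GeneticMap,
    threshold: float,
    haplotypes: HaplotypeSet | None = None,
    target_homolog: int | None = None,
) -> pd.DataFrame:
    """Shortlist candidate ancestors by SPLoSH with the target, descending.

    With ``target_homolog`` set (requires phased target), each candidate is
    scored against that single homolog doubled — the targeted-homolog search
    used when hunting ancestors of one unknown parent.  Ties break by
    candidate id.  A shortlist, not proof.
    """
    rows = []
    for cand in population.individuals:
        if cand == target_id:
            continue
        if target_homolog is not None:
            if haplotypes is None:
                raise ValueError("targeted-homolog ranking needs phased data for the target")
            segs = find_shared_segments(
                haplotypes.doubled(target_id, target_homolog), population.get(cand), gmap, threshold
            )
            val = float(sum(s.length_cM for s in segs))
        else:
            val = pair_splosh(target_id, cand, gmap, threshold, "UU", genotypes=population, haplotypes=haplotypes)
        rows.append((cand, val))
    df = pd.DataFrame(rows, columns=["candidate", "splosh_cM"])
    return df.sort_values(["splosh_cM", "candidate"], ascending=[False, True], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GPGC criteria
# ---------------------------------------------------------------------------


@dataclass
class GPGCReport:
    """Evidence summary for a candidate grandparent-grandchild relationship."""

    coverage_fraction: float  # shared-haplotype coverage of the grandchild genome
    single_recombination_chromosomes: int  # homologs explainable by one recombination
    covered_chromosome_ends: int  # homolog-ends (4/chromosome) reached by sharing
    total_chromosome_ends: int
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def end_coverage_fraction(self) -> float:
        return self.covered_chromosome_ends / self.total_chromosome_ends


def check_gpgc_criteria(
    grandchild: HaplotypeSet,
    grandchild_id: str,
    candidate_gp: np.ndarray,
    gmap: GeneticMap,
    display_threshold: float = 5.0,
    coverage_range: tuple[float, float] = (0.15, 0.60),
    min_single_recomb: int = 2,
    end_fraction_range: tuple[float, float] = (0.10, 0.45),
) -> GPGCReport:
    """Check grandparent-grandchild evidence on phased grandchild data.

    Coverage and recombination evidence consider, per chromosome, the
    homolog sharing more cM with the candidate (the putative contribution of
    the hypothetical parent).  End coverage counts every homolog-end — two
    ends on each of the two homolog copies, four per chromosome — reached by
    a shared haplotype; for a true grandparent roughly a quarter of these
    ends is expected (each end traces back to the candidate with probability
    1/4).  The boolean criteria use the configurable cutoffs.
    """
    if grandchild_id not in grandchild:
        raise ValueError("grandchild must be phased (present in the haplotype set)")
    candidate_gp = np.asarray(candidate_gp)
    slices = gmap.chrom_slices()
    pos = gmap.position
    eps = 1e-9
    covered_ends = 0
    single_recomb = 0
    coverage = 0.0
    per_hom_segs = {
        hom: find_shared_segments(grandchild.doubled(grandchild_id, hom), candidate_gp, gmap, display_threshold)
        for hom in (0, 1)
    }
    for chrom, (lo, hi) in slices.items():
        c_start, c_end = float(pos[lo]), float(pos[hi - 1])
        best_len, best_segs = -1.0, []
        for hom in (0, 1):
            segs = [s for s in per_hom_segs[hom] if s.chromosome == chrom]
            tot = sum(s.length_cM for s in segs)
            if tot > best_len:
                best_len, best_segs = tot, segs
            covered_ends += int(any(abs(s.start_cM - c_start) < eps for s in segs))
            covered_ends += int(any(abs(s.end_cM - c_end) < eps for s in segs))
        coverage += max(best_len, 0.0)
        touches_start = any(abs(s.start_cM - c_start) < eps for s in best_segs)
        touches_end = any(abs(s.end_cM - c_end) < eps for s in best_segs)
        full = len(best_segs) == 1 and touches_start and touches_end
        if len(best_segs) == 1 and (touches_start != touches_end) and not full:
            single_recomb += 1
    span = gmap.total_span
    report = GPGCReport(
        coverage_fraction=coverage / span if span else 0.0,
        single_recombination_chromosomes=single_recomb,
        covered_chromosome_ends=covered_ends,
        total_chromosome_ends=4 * len(slices),
    )
    report.criteria = {
        "haplotype_sharing": coverage_range[0] <= report.coverage_fraction <= coverage_range[1],
        "single_recombinations": single_recomb >= min_single_recomb,
        "chromosome_end_coverage": end_fraction_range[0]
        <= report.end_coverage_fraction
        <= end_fraction_range[1],
    }
    return report
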