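import numpy as np
import pytest

from haploshare.pedsim import SimDesign, simulate_population
from haploshare.reconstruction import (
    CONFLICT,
    UNDETERMINED,
    check_gpgc_criteria,
    deduce_parental_homologs,
    impute_group_parent,
    rank_candidate_ancestors,
    test_grandparent_couple as grandparent_couple_test,
    verify_half_sib,
)

from .conftest import geno


class TestDeduceParentalHomologs:
    @pytest.mark.parametrize(
        "child, parent, expected",
        [
            ("AB", "AA", 1),  # known parent passed A, so the other passed B
            ("BB", "AB", 1),  # child homozygous: obligate allele regardless
            ("BB", None, 1),
            ("AA", "BB", CONFLICT),  # Mendelian impossibility
            ("AB", "AB", UNDETERMINED),  # het parent: ambiguous
            ("AB", "--", UNDETERMINED),
            ("AB", None, UNDETERMINED),
            ("A-", None, UNDETERMINED),
            ("AB", "CC", CONFLICT),  # parent shares neither child allele
        ],
    )
    def test_single_marker_rules(self, child, parent, expected):
        from haploshare.formats_io import GeneticMap

        m = GeneticMap(("m1",), ("1",), np.array([0.0]))
        kp = None if parent is None else geno([parent])
        track = deduce_parental_homologs(geno([child]), kp, m)
        assert track.alleles[0] == expected

    def test_matches_simulated_transmission(self):
        """On error-free simulated trios the deduced obligate allele equals
        the truly transmitted allele at every determined marker."""
        design = SimDesign(templates={"HSIB": 5}, n_markers=300, seed=23)
        sim = simulate_population(design)
        for i in range(5):
            child, shared, other = f"HSIB{i}_A", f"HSIB{i}_P", f"HSIB{i}_M1"
            track = deduce_parental_homologs(
                sim.genotypes.get(child), sim.genotypes.get(other), sim.map
            )
            # truth: child's homolog 0 is the gamete from the shared parent
            true_allele = sim.truth[child].homologs[0].alleles
            det = track.alleles >= 0
            assert det.any()
            assert np.array_equal(track.alleles[det], true_allele[det])
            assert len(track.conflicts) == 0


class TestImputeGroupParent:
    def _marker_map(self, n):
        from haploshare.formats_io import GeneticMap

        return GeneticMap(
            tuple(f"m{i}" for i in range(n)), ("1",) * n, np.linspace(0, 10.0 * (n - 1), n)
        )

    def test_two_distinct_obligates_resolve_both_alleles(self):
        m = self._marker_map(1)
        # three half-sibs homozygous A, A, B -> parent carries {A, B}
        group = [(geno(["AA"]), None), (geno(["AA"]), None), (geno(["BB"]), None)]
        imp = impute_group_parent(group, m)
        assert sorted(imp.alleles[0]) == [0, 1]

    def test_single_obligate_leaves_second_slot_open(self):
        m = self._marker_map(1)
        group = [(geno(["AA"]), None), (geno(["AA"]), None), (geno(["AA"]), None)]
        imp = impute_group_parent(group, m)
        assert imp.alleles[0, 0] == 0 and imp.alleles[0, 1] == -1

    def test_three_distinct_obligates_flag_conflict(self):
        m = self._marker_map(1)
        group = [(geno(["AA"]), None), (geno(["BB"]), None), (geno(["CC"]), None)]
        imp = impute_group_parent(group, m)
        assert list(imp.conflict_markers) == [0]

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            impute_group_parent([(geno(["AA"]), None)], self._marker_map(1))

    def test_recovers_simulated_parent(self):
        """>= 99% of fully-resolved imputed markers match the true shared
        parent with 8 informative half-sibs, error-free."""
        design = SimDesign(templates={"HSIB": 4}, n_markers=1000, seed=31)
        sim = simulate_population(design)
        # build one 8-member half-sib family by hand around HSIB0_P
        from haploshare.pedsim import mate

        rng = np.random.default_rng(77)
        truth = dict(sim.truth)
        shared = truth["HSIB0_P"]
        from haploshare.pedsim import make_founder

        group, ids = [], []
        freqs = rng.uniform(0.2, 0.8, sim.map.n_markers)
        for k in range(8):
            other = make_founder(sim.map, freqs, 0.0, rng, 10_000 + 2 * k)
            child = mate(shared, other, sim.map, rng)
            group.append(
                (np.sort(np.stack([child.homologs[0].alleles, child.homologs[1].alleles], 1), 1),
                 np.sort(np.stack([other.homologs[0].alleles, other.homologs[1].alleles], 1), 1))
            )
            ids.append(f"kid{k}")
        imp = impute_group_parent(group, sim.map, member_ids=ids)
        resolved = np.all(imp.alleles >= 0, axis=1)
        true_pair = np.sort(
            np.stack([shared.homologs[0].alleles, shared.homologs[1].alleles], 1), 1
        )
        got = np.sort(imp.alleles[resolved], 1)
        agree = np.all(got == true_pair[resolved], axis=1).mean()
        assert agree >= 0.99
        # both slots resolve only where the parent is heterozygous AND both
        # alleles were transmitted and deduced; roughly the parent's
        # heterozygosity is an upper bound
        assert 0.2 < resolved.mean() < 0.8
        assert len(imp.conflict_markers) == 0

    def test_verify_half_sib_accepts_true_and_rejects_unrelated(self):
        design = SimDesign(templates={"HSIB": 6, "NKCR": 1}, n_markers=600, seed=37)
        sim = simulate_population(design)
        group = [
            (sim.genotypes.get(f"HSIB{i}_A"), sim.genotypes.get(f"HSIB{i}_M1"))
            for i in range(6)
        ]
        # all six share no parent (independent families) except... build a real
        # family instead: use members sharing HSIB0_P
        from haploshare.pedsim import make_founder, mate

        rng = np.random.default_rng(41)
        freqs = rng.uniform(0.2, 0.8, sim.map.n_markers)
        shared = sim.truth["HSIB0_P"]
        fam = []
        for k in range(25):
            other = make_founder(sim.map, freqs, 0.0, rng, 20_000 + 2 * k)
            child = mate(shared, other, sim.map, rng)
            fam.append(
                (np.stack([child.homologs[0].alleles, child.homologs[1].alleles], 1),
                 np.stack([other.homologs[0].alleles, other.homologs[1].alleles], 1))
            )
        imp = impute_group_parent(fam, sim.map)
        # a sixth true half-sib is consistent
        other = make_founder(sim.map, freqs, 0.0, rng, 30_000)
        child = mate(shared, other, sim.map, rng)
        ok, recomb, conflicts = verify_half_sib(
            imp,
            (np.stack([child.homologs[0].alleles, child.homologs[1].alleles], 1),
             np.stack([other.homologs[0].alleles, other.homologs[1].alleles], 1)),
            sim.map,
            max_switches_per_chrom=4,
        )
        assert ok and conflicts == 0
        # an unrelated individual is not
        ok2, _, conflicts2 = verify_half_sib(
            imp, (sim.genotypes.get("NKCR0_A"), None), sim.map
        )
        assert not ok2 and conflicts2 > 10


class TestGrandparentCouple:
    def test_obligate_absent_from_both_grandparents_is_inconsistent(self):
        from haploshare.formats_io import GeneticMap
        from haploshare.reconstruction import ObligateAlleleTrack

        m = GeneticMap(("m1", "m2", "m3"), ("1",) * 3, np.array([0.0, 10.0, 20.0]))
        track = ObligateAlleleTrack("c", np.array([0, 0, 0], dtype=np.int8))  # obligate A
        gp1 = geno(["BB", "AB", "B-"])
        gp2 = geno(["BB", "BB", "BB"])
        res = grandparent_couple_test(track, gp1, gp2, m)
        assert res.n_inconsistent == 1  # m1: A absent from both
        assert res.inconsistent_markers == ["m1"]
        assert res.n_excluded == 1  # m3: gp1 half-called, set aside
        assert "inconsistent" in res.verdict

    def test_true_couple_clean_random_couples_flagged(self):
        """True grandparent couple: 0 inconsistencies; random couples nearly
        always leave unexplained obligate alleles (error-free, MAF >= 0.2)."""
        design = SimDesign(templates={"GPGC": 1, "NKCR": 30}, n_markers=600, seed=43)
        sim = simulate_population(design)
        # GPGC0: grandparents G1 x G2 -> parent P; child C = P x M
        track = deduce_parental_homologs(
            sim.genotypes.get("GPGC0_C"), sim.genotypes.get("GPGC0_M"), sim.map
        )
        res = grandparent_couple_test(
            track, sim.genotypes.get("GPGC0_G1"), sim.genotypes.get("GPGC0_G2"), sim.map
        )
        assert res.n_inconsistent == 0
        flagged = 0
        couples = [(f"NKCR{i}_A", f"NKCR{i}_B") for i in range(30)]
        for g1, g2 in couples:
            r = grandparent_couple_test(
                track, sim.genotypes.get(g1), sim.genotypes.get(g2), sim.map
            )
            flagged += r.n_inconsistent > 0
        assert flagged == len(couples)


class TestRankCandidateAncestors:
    def test_identical_member_ranks_first_with_full_span(self, mixed_population):
        sim = mixed_population
        target = "FSIB0_A"
        ranked = rank_candidate_ancestors(target, sim.genotypes, sim.map, threshold=0.0)
        assert target not in set(ranked["candidate"])
        # compare against a clone: self-splosh equals the whole map
        from haploshare.splosh import pair_splosh

        assert (
            pair_splosh(target, target, sim.map, 0.0, "UU", genotypes=sim.genotypes)
            == sim.map.total_span
        )

    def test_grandparent_outranks_unrelated(self):
        design = SimDesign(templates={"GPGC": 6, "NKCR": 12}, n_markers=600, seed=47)
        sim = simulate_population(design)
        wins = 0
        for i in range(6):
            ranked = rank_candidate_ancestors(
                f"GPGC{i}_C", sim.genotypes, sim.map, threshold=20.0
            )
            scores = dict(zip(ranked["candidate"], ranked["splosh_cM"]))
            gp = scores[f"GPGC{i}_G1"]
            nk = max(scores[f"NKCR{j}_{s}"] for j in range(12) for s in "AB")
            wins += gp > nk
        assert wins >= 5

    def test_ties_break_by_candidate_id(self, six_marker_map):
        from haploshare.formats_io import GenotypeMatrix

        calls = np.tile(geno(["AA"] * 6)[None, :, :], (3, 1, 1))
        g = GenotypeMatrix(six_marker_map, ["t", "zz", "aa"], calls)
        ranked = rank_candidate_ancestors("t", g, six_marker_map, threshold=0.0)
        assert list(ranked["candidate"]) == ["aa", "zz"]


class TestGPGCCriteria:
    def test_identical_homolog_covers_both_ends_no_recombination(self):
        from haploshare.formats_io import GeneticMap, HaplotypeSet

        m = GeneticMap(tuple(f"m{i}" for i in range(6)), ("1",) * 6, np.linspace(0, 50, 6))
        rng = np.random.default_rng(3)
        gp_h = rng.integers(0, 2, 6).astype(np.int8)
        child = HaplotypeSet(m, ["C"], np.stack([gp_h, 1 - gp_h])[None, :, :])
        gp = np.stack([gp_h, gp_h], axis=1)
        rep = check_gpgc_criteria(child, "C", gp, m, display_threshold=5.0)
        assert rep.covered_chromosome_ends == 2
        assert rep.single_recombination_chromosomes == 0

    def test_unphased_grandchild_rejected(self, six_marker_map):
        from haploshare.formats_io import HaplotypeSet

        h = HaplotypeSet(six_marker_map, ["X"], np.zeros((1, 2, 6), dtype=np.int8))
        with pytest.raises(ValueError):
            check_gpgc_criteria(h, "not-there", geno(["AA"] * 6), six_marker_map)

    def test_true_gpgc_end_coverage_near_one_quarter(self):
        """Over replicates a true grandparent covers ~25% of the grandchild's
        chromosome ends (one homolog per pair considered)."""
        fracs = []
        for seed in range(8):
            design = SimDesign(
                n_chromosomes=17, total_span=1267.0, n_markers=6000,
                templates={"GPGC": 3}, seed=100 + seed,
            )
            sim = simulate_population(design)
            for i in range(3):
                rep = check_gpgc_criteria(
                    sim.haplotypes, f"GPGC{i}_C", sim.genotypes.get(f"GPGC{i}_G1"),
                    sim.map, display_threshold=5.0,
                )
                fracs.append(rep.end_coverage_fraction)
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.08)

    def test_unrelated_pair_fails_criteria(self):
        design = SimDesign(
            n_chromosomes=17, total_span=1267.0, n_markers=1700,
            templates={"NKCR": 2}, seed=53,
        )
        sim = simulate_population(design)
        rep = check_gpgc_criteria(
            sim.haplotypes, "NKCR0_A", sim.genotypes.get("NKCR1_B"), sim.map,
            display_threshold=5.0,
        )
        assert not all(rep.criteria.values())
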