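"""Feature mapping: CDS/promoter assignment, mononucleotide runs,
transition strand placement, and the -10 element scan."""

import numpy as np
import pytest

from oriconflict.catalog import Mutation
from oriconflict.features import (
    assign_indels_to_runs,
    assign_to_cds,
    classify_transition_placement,
    find_runs,
    placement_counts,
    promoter_window,
    run_census,
    scan_minus10,
)
from oriconflict.genome import Gene, GenomeAnnotation, Promoter, revcomp, strand_template


def _bps(pos, ref, alt, mid="m1"):
    return Mutation(mid, "e", "L1", pos, "BPS", ref, alt)


class TestFindRuns:
    def test_basic_runs(self):
        runs = find_runs("AAAAAGTTTTT", min_len=5)
        assert [(r.start, r.end, r.base) for r in runs] == [(1, 5, "A"), (7, 11, "T")]

    def test_no_runs_in_alternating_sequence(self):
        assert find_runs("ACGTACGT", min_len=5) == []
        census = run_census("ACGTACGT")
        assert census == {1: 1.0}

    def test_census_matches_brute_force_on_random_10kb(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        census = run_census(seq)
        # brute force: for each position find its maximal run by scanning
        brute: dict[int, int] = {}
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            brute[j - i] = brute.get(j - i, 0) + (j - i)
            i = j
        assert census == {k: v / len(seq) for k, v in sorted(brute.items())}

    def test_census_sums_to_one(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        assert sum(run_census(seq).values()) == pytest.approx(1.0)

    def test_circular_wrap_merges_terminal_runs(self):
        runs = find_runs("AAGTCGAAA", min_len=5, circular=True)
        assert len(runs) == 1
        r = runs[0]
        assert (r.start, r.end, r.base, r.wraps_origin) == (7, 2, "A", True)
        assert r.run_len(9) == 5

    def test_maximality(self):
        for r in find_runs("CCCCCA" * 3, min_len=5):
            assert r.run_len() == 5


class TestPromoterWindow:
    def test_forward_window(self, toy_genome):
        p = Promoter("p", 1000, "forward")
        g = GenomeAnnotation("g", 2000, 1, "A" * 2000)
        assert promoter_window(p, g) == [(940, 1000)]

    def test_reverse_window(self):
        g = GenomeAnnotation("g", 2000, 1, "A" * 2000)
        assert promoter_window(Promoter("p", 1000, "reverse"), g) == [(1000, 1060)]

    def test_circular_wrap(self):
        g = GenomeAnnotation("g", 100, 1, "A" * 100)
        segs = promoter_window(Promoter("p", 30, "forward"), g)
        assert segs == [(70, 100), (1, 30)]
        assert sum(e - s + 1 for s, e in segs) == 61

    def test_window_length_is_61(self):
        g = GenomeAnnotation("g", 2000, 1, "A" * 2000)
        for strand in ("forward", "reverse"):
            segs = promoter_window(Promoter("p", 500, strand), g)
            assert sum(e - s + 1 for s, e in segs) == 61


class TestAssignToCds:
    def test_unique_intergenic_and_overlap_accounting(self):
        seq = "A" * 100
        genes = [Gene("g1", 10, 40, "forward"), Gene("g2", 30, 60, "forward")]
        g = GenomeAnnotation("g", 100, 1, seq, genes=genes)
        muts = [
            _bps(15, "A", "G", "m1"),   # only g1
            _bps(35, "A", "G", "m2"),   # overlap: both
            _bps(50, "A", "G", "m3"),   # only g2
            _bps(90, "A", "G", "m4"),   # intergenic
            Mutation("m5", "e", "L1", 12, "insertion", "", "A", 1),
        ]
        res = assign_to_cds(muts, g)
        assert res.gene_counts.loc["g1", "n_bps"] == 2
        assert res.gene_counts.loc["g2", "n_bps"] == 2
        assert res.gene_counts.loc["g1", "n_indel"] == 1
        assert res.n_multi == 1
        assert res.n_intergenic == 1
        assert res.mutation_genes["m2"] == ["g1", "g2"]
        # conservation: unique + multi + intergenic = catalog size
        n_unique = sum(1 for v in res.mutation_genes.values() if len(v) == 1)
        assert n_unique + res.n_multi + res.n_intergenic == len(muts)

    def test_matches_naive_interval_scan(self, small_sim):
        res = assign_to_cds(small_sim.mutations, small_sim.genome)
        rng = np.random.default_rng(2)
        sample = rng.choice(len(small_sim.mutations), size=50, replace=False)
        for i in sample:
            m = small_sim.mutations[i]
            naive = sorted(
                g.gene_id for g in small_sim.genome.genes if g.start <= m.pos <= g.end
            )
            assert res.mutation_genes[m.mutation_id] == naive

    def test_per_class_counts_partition_bps(self, small_sim):
        res = assign_to_cds(small_sim.mutations, small_sim.genome)
        c = res.gene_counts
        assert (
            c["n_at_transition"] + c["n_gc_transition"]
            + c["n_at_transversion"] + c["n_gc_transversion"]
        ).equals(c["n_bps"])


class TestAssignIndelsToRuns:
    def _runs(self):
        #         1234567890123456789
        seq = "TGAAAAAATCCCCCTTTGGG"
        return seq, find_runs(seq, min_len=4)

    def test_matching_insertion_at_run_start(self):
        seq, runs = self._runs()
        ins = Mutation("i1", "e", "L1", 3, "insertion", "", "A", 1)
        mapping, per_run = assign_indels_to_runs([ins], runs)
        assert mapping["i1"] == 0
        assert per_run[0] == 1

    def test_base_mismatch_is_non_run(self):
        seq, runs = self._runs()
        ins = Mutation("i1", "e", "L1", 3, "insertion", "", "G", 1)
        mapping, _ = assign_indels_to_runs([ins], runs)
        assert mapping["i1"] is None

    def test_five_prime_adjacent_position(self):
        seq, runs = self._runs()
        # A-run at 3..8; position 2 is immediately 5'-adjacent
        ins = Mutation("i1", "e", "L1", 2, "insertion", "", "A", 1)
        mapping, _ = assign_indels_to_runs([ins], runs)
        assert mapping["i1"] == 0

    def test_matches_exhaustive_compatibility_check(self):
        seq, runs = self._runs()
        rng = np.random.default_rng(9)
        muts = []
        for i in range(20):
            pos = int(rng.integers(1, len(seq) + 1))
            base = rng.choice(list("ACGT"))
            kind = "insertion" if rng.random() < 0.5 else "deletion"
            muts.append(Mutation(
                f"i{i}", "e", "L1", pos, kind,
                "" if kind == "insertion" else base,
                base if kind == "insertion" else "", 1,
            ))
        mapping, _ = assign_indels_to_runs(muts, runs)
        for m in muts:
            expected = None
            for k, r in enumerate(runs):
                if m.indel_unit == r.base and (r.start - 1 <= m.pos <= r.end):
                    expected = k
                    break
            assert mapping[m.mutation_id] == expected

    def test_multibase_indel_requires_full_compatibility(self):
        seq, runs = self._runs()
        ok = Mutation("i1", "e", "L1", 10, "deletion", "CC", "", 2)
        bad = Mutation("i2", "e", "L1", 13, "deletion", "CT", "", 2)
        mapping, _ = assign_indels_to_runs([ok, bad], runs)
        assert mapping["i1"] == 1
        assert mapping["i2"] is None


class TestTransitionPlacement:
    def test_exhaustive_truth_table(self, toy_genome):
        """2 replichores x 2 ref strands x 2 pair classes, derived from the
        strand_template rule independently."""
        cases = [(10, "right"), (60, "left")]  # one position per replichore
        for pos, _rep in cases:
            for ref, alt, base, strand_of_base in [
                ("A", "G", "A", "forward"),
                ("T", "C", "A", "reverse"),
                ("C", "T", "C", "forward"),
                ("G", "A", "C", "reverse"),
            ]:
                m = _bps(pos, ref, alt)
                expected = f"{base}_on_{strand_template(pos, strand_of_base, toy_genome)}"
                assert classify_transition_placement(m, toy_genome) == expected

    def test_right_replichore_examples(self, toy_genome):
        assert classify_transition_placement(_bps(10, "A", "G"), toy_genome) == "A_on_LGST"
        assert classify_transition_placement(_bps(10, "T", "C"), toy_genome) == "A_on_LDST"
        assert classify_transition_placement(_bps(60, "G", "A"), toy_genome) == "C_on_LGST"

    def test_transversion_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            classify_transition_placement(_bps(10, "A", "T"), toy_genome)

    def test_placement_partitions_transitions(self, small_sim):
        counts = placement_counts(small_sim.mutations, small_sim.genome)
        n_at = sum(
            1 for m in small_sim.mutations
            if m.is_bps and m.bps_class().change_class == "transition"
            and m.bps_class().pair_class == "AT"
        )
        n_gc = sum(
            1 for m in small_sim.mutations
            if m.is_bps and m.bps_class().change_class == "transition"
            and m.bps_class().pair_class == "GC"
        )
        assert counts["A_on_LGST"] + counts["A_on_LDST"] == n_at
        assert counts["C_on_LGST"] + counts["C_on_LDST"] == n_gc

    def test_reverse_complement_invariance(self, small_sim):
        """Reverse-complementing the genome (flipping the coordinate frame)
        must leave physical placement-class counts unchanged."""
        g = small_sim.genome
        L = g.length
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        flipped = GenomeAnnotation(
            genome_id="flip", length=L,
            origin_pos=L - g.origin_pos + 1,
            terminus_pos=L - g.terminus_pos + 1,
            sequence=revcomp(g.sequence),
        )
        fw = placement_counts(small_sim.mutations, g)
        remapped = [
            Mutation(m.mutation_id, m.experiment_id, m.line_id, L - m.pos + 1,
                     "BPS", comp[m.ref], comp[m.alt])
            for m in small_sim.mutations if m.is_bps
        ]
        rc = placement_counts(remapped, flipped)
        assert fw.to_dict() == rc.to_dict()


class TestScanMinus10:
    def _promoter_genome(self):
        # forward promoter with TSS at 101; sense -10 element TATAAT with
        # its 3' T exactly 7 nt upstream (positions 89..94)
        seq = list("G" * 120)
        seq[88:94] = list("TATAAT")
        seq = "".join(seq)
        g = GenomeAnnotation("g", 120, 1, seq,
                             promoters=[Promoter("p1", 101, "forward")])
        return g

    def test_hit_at_t_minus7(self):
        g = self._promoter_genome()
        m = _bps(94, "T", "C")  # the 3' T of the element
        hits = scan_minus10(g.promoters, [m], g)
        assert len(hits) == 1
        assert hits[0].is_t_minus7
        assert hits[0].hexamer == "TATAAT"
        # TSS 101 is past the terminus (61): left replichore, forward = HO
        assert hits[0].orientation == "HO"

    def test_transition_outside_window_not_scanned(self):
        g = self._promoter_genome()
        far = _bps(60, "T", "C")  # >20 nt upstream (G at 60 in seq? use T site)
        # position 60 is G in the construct; place a synthetic T transition
        seq = list(g.sequence)
        seq[59] = "T"
        g2 = GenomeAnnotation("g", 120, 1, "".join(seq), promoters=g.promoters)
        assert scan_minus10(g2.promoters, [far], g2) == []

    def test_gc_transition_not_scanned(self):
        g = self._promoter_genome()
        m = _bps(95, "G", "A")  # G:C transition cannot be a T-7 hit
        assert scan_minus10(g.promoters, [m], g) == []

    def test_reverse_strand_promoter(self):
        # reverse promoter TSS at 20; sense upstream runs rightward, so the
        # element lies at genomic 26..31 as the reverse complement ATTATA
        seq = list("G" * 120)
        seq[25:31] = list("ATTATA")  # revcomp(TATAAT)
        g = GenomeAnnotation("g", 120, 1, "".join(seq),
                             promoters=[Promoter("p1", 20, "reverse")])
        m = _bps(26, "A", "G")  # sense-strand T (ref A on forward)
        hits = scan_minus10(g.promoters, [m], g)
        assert len(hits) == 1
        assert hits[0].hexamer.endswith("T")
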