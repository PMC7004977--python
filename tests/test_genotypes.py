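import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildens import genotypes as gt

LOCI = [f"L{i}" for i in range(1, 10)]


def make_sample(sample_id, geno, cts=(30.0, 30.0), n_reps=3, occasion=1, habitat="a",
                transect=1):
    return gt.GenotypeSample(
        sample_id=sample_id,
        transect=transect,
        occasion=occasion,
        habitat=habitat,
        ct_values=cts,
        replicates=[dict(geno) for _ in range(n_reps)],
    )


def base_geno(shift=0):
    return {loc: (10 + shift, 12 + shift) for loc in LOCI}


class TestScreen:
    def test_threshold_is_inclusive(self):
        samples = [
            make_sample("a", base_geno(), cts=(30, 30)),
            make_sample("b", base_geno(), cts=(36, 36)),
            make_sample("c", base_geno(), cts=(36.5, 30)),
        ]
        kept = gt.screen_qpcr(samples)
        assert [s.sample_id for s in kept] == ["a", "b"]

    def test_empty_input(self):
        assert gt.screen_qpcr([]) == []

    def test_missing_ct_rejected(self):
        s = make_sample("a", base_geno(), cts=(np.nan, 30))
        assert gt.screen_qpcr([s]) == []


class TestConsensus:
    def test_unanimous_replicates(self):
        s = make_sample("a", base_geno())
        cons = gt.consensus_genotype(s)
        assert cons.n_typed_loci == 9
        assert cons.consensus == base_geno()

    def test_dropout_pattern_calls_heterozygote(self):
        # two het replicates plus one dropout homozygote: both alleles
        # still reach the 2-replicate support threshold
        s = make_sample("a", base_geno())
        s.replicates = [
            {**base_geno(), "L1": (12, 14)},
            {**base_geno(), "L1": (12, 14)},
            {**base_geno(), "L1": (12, 12)},
        ]
        cons = gt.consensus_genotype(s, min_replicates_per_allele=2)
        assert cons.consensus["L1"] == (12, 14)
        assert "L1" in cons.het_in_replicates

    def test_single_observation_insufficient(self):
        s = make_sample("a", base_geno(), n_reps=1)
        cons = gt.consensus_genotype(s, min_replicates_per_allele=2)
        assert cons.n_typed_loci == 0


class TestAlleleMismatch:
    def test_identity_is_zero(self):
        g = gt.consensus_genotype(make_sample("a", base_geno()))
        assert gt.allele_mismatch(g, g) == (0, [])

    def test_single_dropout_is_one(self):
        g1 = gt.consensus_genotype(make_sample("a", {**base_geno(), "L3": (12, 14)}))
        g2 = gt.consensus_genotype(make_sample("b", {**base_geno(), "L3": (12, 12)}))
        n, loci = gt.allele_mismatch(g1, g2)
        assert (n, loci) == (1, ["L3"])

    def test_disjoint_pair_is_two(self):
        g1 = gt.consensus_genotype(make_sample("a", {**base_geno(), "L3": (12, 14)}))
        g2 = gt.consensus_genotype(make_sample("b", {**base_geno(), "L3": (16, 18)}))
        assert gt.allele_mismatch(g1, g2)[0] == 2

    def test_no_shared_loci_errors(self):
        g1 = gt.ConsensusGenotype("a", {"L1": (10, 10), "L2": None})
        g2 = gt.ConsensusGenotype("b", {"L1": None, "L2": (10, 10)})
        with pytest.raises(ValueError):
            gt.allele_mismatch(g1, g2)

    @settings(deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(10, 16), st.integers(10, 16)),
            min_size=9,
            max_size=9,
        ),
        pairs2=st.lists(
            st.tuples(st.integers(10, 16), st.integers(10, 16)),
            min_size=9,
            max_size=9,
        ),
    )
    def test_symmetry(self, pairs, pairs2):
        g1 = gt.consensus_genotype(make_sample("a", dict(zip(LOCI, pairs))))
        g2 = gt.consensus_genotype(make_sample("b", dict(zip(LOCI, pairs2))))
        assert gt.allele_mismatch(g1, g2) == gt.allele_mismatch(g2, g1)


class TestMatchIndividuals:
    def _quad(self):
        """2 identical, 1 one-mismatch-at-het-locus, 1 two-mismatch sample."""
        het = {**base_geno(), "L1": (10, 14)}
        a = make_sample("s1", het)
        b = make_sample("s2", het)
        c = make_sample("s3", {**base_geno(), "L1": (10, 10)})  # dropout of the 14
        d = make_sample("s4", {**base_geno(), "L1": (20, 22)})
        return [gt.consensus_genotype(s) for s in (a, b, c, d)]

    def test_dropout_rule_merges_to_two_individuals(self):
        report = gt.match_individuals(self._quad())
        assert report.n_individuals == 2
        assert ["s1", "s2", "s3"] in report.individuals
        assert ["s4"] in report.individuals
        assert len(report.putative_matches) >= 1

    def test_one_mismatch_without_het_evidence_stays_separate(self):
        a = gt.consensus_genotype(make_sample("s1", {**base_geno(), "L1": (10, 10)}))
        b = gt.consensus_genotype(make_sample("s2", {**base_geno(), "L1": (14, 14)}))
        report = gt.match_individuals([a, b])
        assert report.n_individuals == 2

    def test_all_distinct(self):
        genos = [
            gt.consensus_genotype(make_sample(f"s{i}", base_geno(shift=4 * i)))
            for i in range(4)
        ]
        assert gt.match_individuals(genos).n_individuals == 4

    def test_low_locus_samples_excluded(self):
        geno = base_geno()
        partial = {loc: (geno[loc] if i < 7 else None) for i, loc in enumerate(LOCI)}
        g = gt.ConsensusGenotype("s1", partial)
        report = gt.match_individuals([g], min_loci=8)
        assert report.excluded == ["s1"]
        assert report.n_individuals == 0

    def test_partition_invariant_to_input_order(self):
        genos = self._quad()
        fwd = gt.match_individuals(genos)
        rev = gt.match_individuals(genos[::-1])
        assert fwd.individuals == rev.individuals

    def test_never_merges_two_allele_differences(self):
        a = gt.consensus_genotype(make_sample("s1", {**base_geno(), "L1": (10, 14)}))
        b = gt.consensus_genotype(
            make_sample("s2", {**base_geno(), "L1": (10, 14), "L2": (14, 14), "L3": (14, 14)})
        )
        assert gt.match_individuals([a, b]).n_individuals == 2


class TestPSib:
    def test_two_even_alleles_closed_form(self):
        per_locus, overall = gt.p_sib({"L1": [0.5, 0.5]})
        assert per_locus["L1"] == pytest.approx(0.59375, abs=1e-12)
        assert overall == pytest.approx(0.59375, abs=1e-12)

    def test_monomorphic_locus_cannot_discriminate(self):
        _, overall = gt.p_sib({"L1": [1.0]})
        assert overall == 1.0

    def test_product_over_loci(self):
        freqs = {loc: [0.5, 0.5] for loc in LOCI}
        _, overall = gt.p_sib(freqs)
        assert overall == pytest.approx(0.59375**9, rel=1e-12)
        assert overall == pytest.approx(9.2e-3, rel=0.01)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gt.p_sib({"L1": [0.5, 0.4]})

    def test_bounds_and_evenness_monotonicity(self):
        # two-allele sweep: more even frequencies discriminate better
        values = []
        for p in np.linspace(0.5, 0.99, 20):
            per_locus, _ = gt.p_sib({"L1": [p, 1 - p]})
            v = per_locus["L1"]
            assert 0.25 <= v <= 1.0
            values.append(v)
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


class TestCaptureHistory:
    def test_same_day_duplicates_collapse(self):
        g = base_geno()
        samples = [
            make_sample("s1", g, occasion=3),
            make_sample("s2", g, occasion=3),
        ]
        report = gt.match_individuals([gt.consensus_genotype(s) for s in samples])
        hists = gt.build_capture_history(report, samples, n_occasions=6)
        assert hists["a"].matrix.sum() == 1
        assert hists["a"].matrix[0, 2] == 1

    def test_redetection_on_later_day(self):
        g = base_geno()
        samples = [
            make_sample("s1", g, occasion=1),
            make_sample("s2", g, occasion=5),
        ]
        report = gt.match_individuals([gt.consensus_genotype(s) for s in samples])
        hists = gt.build_capture_history(report, samples, n_occasions=6)
        assert hists["a"].n_redetections == 1

    def test_empty_partition(self):
        report = gt.MatchReport([], [], [])
        assert gt.build_capture_history(report, [], 6) == {}


def test_csv_roundtrip(tmp_path):
    samples = [
        make_sample("s1", base_geno(), cts=(30.5, 31.5)),
        make_sample("s2", {**base_geno(), "L1": None}, occasion=2),
    ]
    path = tmp_path / "geno.csv"
    gt.write_genotype_csv(samples, path)
    back = gt.read_genotype_csv(path)
    assert [s.sample_id for s in back] == ["s1", "s2"]
    assert back[0].ct_values == (30.5, 31.5)
    assert back[1].replicates[0]["L1"] is None
    assert back[0].replicates[2] == base_geno()
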