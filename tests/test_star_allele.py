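"""Star-allele definitions, EM haplotype frequencies, diplotype calling."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nat2kit.errors import (
    CompoundHaplotypeError,
    DefinitionError,
    UnknownSiteError,
)
from nat2kit.star_allele import (
    Diplotype,
    GenotypeCall,
    HaplotypeFrequencySet,
    canonical_label,
    call_diplotype,
    em_haplotype_frequencies,
    estimate_allele_frequencies,
    load_allele_definitions,
)
from nat2kit.synthetic_data import CohortSpec, simulate_cohort_hwe

SITES = ("rs1801280", "rs1799930", "rs1799931")  # *5, *6, *7


def _call(ident, d5=0, d6=0, d7=0):
    return GenotypeCall(ident, dict(zip(SITES, (d5, d6, d7))))


# ----------------------------------------------------------- definitions

class TestDefinitions:
    def test_builtin_nat2(self, defs):
        assert defs.sites == SITES
        assert defs.allele_names == ("*4", "*5", "*6", "*7")
        assert defs.alleles["*4"].variant_rsids == frozenset()
        for name, rsid in zip(("*5", "*6", "*7"), SITES):
            assert defs.alleles[name].variant_rsids == {rsid}
        assert defs.pattern_allele((0, 0, 0)) == "*4"
        assert defs.pattern_allele((0, 1, 0)) == "*6"
        assert defs.pattern_allele((1, 1, 0)) is None  # compound

    def test_tsv_with_extra_allele_loads(self, tmp_path):
        p = tmp_path / "defs.tsv"
        p.write_text(
            "rsid\tref\talt\tallele\n"
            "rs1801280\tT\tC\t*5\n"
            "rs1799930\tG\tA\t*6\n"
            "rs1799931\tG\tA\t*7\n"
            "rs1801279\tG\tA\t*14\n"
        )
        d = load_allele_definitions(p)
        assert "*14" in d.alleles
        assert d.allele_pattern("*14") == (0, 0, 0, 1)

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("rsid\tref\talt\tallele\n")
        with pytest.raises(DefinitionError, match="no signature variants"):
            load_allele_definitions(p)

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("rsid\tref\talt\tallele\n"
                     "rs1801280\tT\tC\t*5\n"
                     "rs1801280\tT\tC\t*5B\n")
        with pytest.raises(DefinitionError, match="duplicate"):
            load_allele_definitions(p)

    def test_two_variants_one_allele_rejected(self, tmp_path):
        p = tmp_path / "multi.tsv"
        p.write_text("rsid\tref\talt\tallele\n"
                     "rs1801280\tT\tC\t*5\n"
                     "rs1041983\tC\tT\t*5\n")
        with pytest.raises(DefinitionError, match="unsupported"):
            load_allele_definitions(p)


# -------------------------------------------------------------------- EM

class TestEMFrequencies:
    def test_variant_free_cohort(self):
        freqs = em_haplotype_frequencies([_call(f"i{i}") for i in range(5)],
                                         sites=SITES)
        assert freqs.frequency((0, 0, 0)) == pytest.approx(1.0)
        assert sum(freqs.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_equals_gamete_counting_on_unambiguous_cohort(self, defs):
        # at most one heterozygous site each: phase is forced, so EM must
        # equal direct gamete counting
        cohort = [
            _call("a", d5=0, d6=0, d7=0),   # *4/*4
            _call("b", d5=1, d6=0, d7=0),   # *4/*5
            _call("c", d5=0, d6=2, d7=0),   # *6/*6
            _call("d", d5=0, d6=1, d7=0),   # *4/*6
            _call("e", d5=0, d6=0, d7=1),   # *4/*7
            _call("f", d5=0, d6=2, d7=0),   # *6/*6
        ]
        # independent oracle: count gametes directly
        gametes = Counter()
        for c in cohort:
            d = [c.dosages[s] for s in SITES]
            h_common = tuple(1 if x == 2 else 0 for x in d)
            het = [i for i, x in enumerate(d) if x == 1]
            assert len(het) <= 1
            h_other = list(h_common)
            for i in het:
                h_other[i] = 1
            gametes[h_common] += 1
            gametes[tuple(h_other)] += 1
        expected = {p: n / (2 * len(cohort)) for p, n in gametes.items()}

        freqs = em_haplotype_frequencies(cohort, sites=SITES)
        for pattern, f in freqs.frequencies.items():
            assert f == pytest.approx(expected.get(pattern, 0.0), abs=1e-6)

    def test_log_likelihood_monotone(self):
        cohort = [_call("a", 1, 1, 0), _call("b", 0, 1, 1),
                  _call("c", 1, 0, 0), _call("d", 0, 0, 2)]
        freqs = em_haplotype_frequencies(cohort, sites=SITES)
        trace = freqs.ll_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert freqs.log_likelihood == trace[-1]

    def test_recovers_simulation_truth_within_3se(self, defs):
        truth = {"*4": 0.55, "*5": 0.05, "*6": 0.25, "*7": 0.15}
        sim = simulate_cohort_hwe(CohortSpec(truth, 100, seed=42), defs)
        freqs = em_haplotype_frequencies(sim.calls, sites=SITES)
        est = freqs.allele_frequencies(defs)
        n_gametes = 2 * 100
        for allele, p in truth.items():
            se = math.sqrt(p * (1 - p) / n_gametes)
            assert abs(est.get(allele, 0.0) - p) <= 3 * se

    def test_missing_data_handling(self, caplog):
        cohort = [_call("a", 0, 1, 0),
                  GenotypeCall("b", {SITES[0]: 0, SITES[1]: 1})]
        with caplog.at_level("WARNING"):
            freqs = em_haplotype_frequencies(cohort, sites=SITES)
        # rs1799931 observed only in 'a'; 'b' lacks it -> excluded
        assert freqs.excluded == ("b",)
        # a site nobody has data for is dropped with a warning
        cohort2 = [GenotypeCall("a", {SITES[0]: 1}),
                   GenotypeCall("b", {SITES[0]: 0})]
        with caplog.at_level("WARNING"):
            freqs2 = em_haplotype_frequencies(cohort2, sites=SITES)
        assert freqs2.sites == (SITES[0],)
        assert "dropping" in caplog.text

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2),
                              st.integers(0, 2)),
                    min_size=1, max_size=20))
    def test_frequencies_valid_and_ll_monotone(self, dosage_rows):
        cohort = [_call(f"i{i}", *row) for i, row in enumerate(dosage_rows)]
        freqs = em_haplotype_frequencies(cohort, sites=SITES)
        assert sum(freqs.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(f >= 0 for f in freqs.frequencies.values())
        trace = freqs.ll_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


# -------------------------------------------------------- diplotype calls

def _uniform_freqs():
    patterns = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    return HaplotypeFrequencySet(
        SITES, {p: 1 / 8 for p in patterns}, 0.0, 1)


def _freqs(weights):
    total = sum(weights.values())
    patterns = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    return HaplotypeFrequencySet(
        SITES, {p: weights.get(p, 0.0) / total for p in patterns}, 0.0, 1)


class TestCallDiplotype:
    def test_single_het_is_unambiguous(self, defs):
        d = call_diplotype(_call("x", 0, 1, 0), _uniform_freqs(), defs)
        assert d.label == "*4/*6"
        assert not d.ambiguous and d.posterior == pytest.approx(1.0)

    def test_homozygote(self, defs):
        d = call_diplotype(_call("x", 2, 0, 0), _uniform_freqs(), defs)
        assert d.label == "*5/*5" and d.posterior == pytest.approx(1.0)

    def test_double_het_resolved_when_compound_has_zero_frequency(self, defs):
        # *6/*7 vs (*4, *6+*7-compound): the compound pattern has frequency
        # zero, so the trans configuration takes all the posterior mass
        freqs = _freqs({(0, 0, 0): .55, (1, 0, 0): .05,
                        (0, 1, 0): .25, (0, 0, 1): .15})
        d = call_diplotype(_call("x", 0, 1, 1), freqs, defs)
        assert d.label == "*6/*7"
        assert d.posterior == pytest.approx(1.0)
        assert not d.ambiguous

    def test_double_het_ambiguous_when_compound_supported(self, defs):
        # trans weight 2(.20)(.20) beats cis weight 2(.50)(.02), but the cis
        # configuration keeps posterior mass, so the call is flagged ambiguous
        freqs = _freqs({(0, 0, 0): .50, (0, 1, 0): .20, (0, 0, 1): .20,
                        (0, 1, 1): .02, (1, 0, 0): .08})
        d = call_diplotype(_call("x", 0, 1, 1), freqs, defs)
        assert d.label == "*6/*7"
        assert d.ambiguous
        w_trans = 2 * .20 * .20
        w_cis = 2 * .50 * .02
        assert d.posterior == pytest.approx(w_trans / (w_trans + w_cis))

    def test_compound_selection_is_hard_error(self, defs):
        freqs = _freqs({(0, 0, 0): .60, (0, 1, 1): .30,
                        (0, 1, 0): .05, (0, 0, 1): .05})
        with pytest.raises(CompoundHaplotypeError,
                           match="rs1799930 and rs1799931"):
            call_diplotype(_call("x", 0, 1, 1), freqs, defs)

    def test_unknown_rsid_rejected(self, defs):
        with pytest.raises(UnknownSiteError, match="rs9999"):
            call_diplotype(GenotypeCall("x", {"rs9999": 1, SITES[0]: 0}),
                           _uniform_freqs(), defs)

    def test_round_trip_on_simulated_cohort(self, defs):
        truth = {"*4": 0.55, "*5": 0.05, "*6": 0.25, "*7": 0.15}
        sim = simulate_cohort_hwe(CohortSpec(truth, 200, seed=11), defs)
        freqs = em_haplotype_frequencies(sim.calls, sites=SITES)
        for call, expected in zip(sim.calls, sim.diplotypes):
            got = call_diplotype(call, freqs, defs)
            assert got.label == expected.label

    def test_unambiguous_calls_independent_of_frequencies(self, defs):
        skewed = _freqs({(0, 0, 0): .97, (1, 0, 0): .01,
                         (0, 1, 0): .01, (0, 0, 1): .01})
        for call in (_call("a", 0, 1, 0), _call("b", 2, 0, 0),
                     _call("c", 0, 0, 0)):
            assert (call_diplotype(call, skewed, defs).label
                    == call_diplotype(call, _uniform_freqs(), defs).label)


# ------------------------------------------------------ allele frequencies

class TestAlleleFrequencies:
    def test_japanese_cohort_reference_value(self, cohorts):
        diplotypes = [
            Diplotype.from_label(g)
            for g, c in cohorts["Japanese"].counts.items() for _ in range(c)
        ]
        freqs = estimate_allele_frequencies(diplotypes)
        expected4 = (2 * 480 + 23 + 260 + 125) / (2 * 990)
        assert freqs["*4"] == pytest.approx(expected4, abs=1e-12)
        assert round(freqs["*4"], 3) == 0.691
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_trivial_cohorts(self):
        assert estimate_allele_frequencies(
            [Diplotype("*4", "*4")] * 3) == {"*4": 1.0}
        assert estimate_allele_frequencies(
            [Diplotype("*5", "*6")]) == {"*5": 0.5, "*6": 0.5}
        with pytest.raises(ValueError):
            estimate_allele_frequencies([])


def test_canonical_labels_sorted_numerically():
    assert canonical_label("*6", "*4") == "*4/*6"
    assert canonical_label("*14", "*5") == "*5/*14"
    assert Diplotype("*7", "*5").label == "*5/*7"
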