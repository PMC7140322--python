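"""Variant calling, singleton filtering, CpG classification, normalization."""

import numpy as np
import pytest

from retrocomp.mutation_spectrum import (
    branch_mutation_probability,
    call_variants,
    classify_cpg_context,
    context_opportunities,
    divergence_matched_subsets,
    family_spectrum,
    filter_families_by_divergence,
    filter_singletons,
    gc_to_at_excess,
    normalize_spectrum,
)
from retrocomp.seq_io import CodingSequence, FamilyBundle
from retrocomp.synthetic_data import FamilySimConfig, simulate_element_consensus, simulate_family


def bundle_from(consensus: str, copies: list[str], consensus_aligned=None) -> FamilyBundle:
    return FamilyBundle(
        consensus=CodingSequence(id="fam", sequence=consensus.replace("-", "")),
        consensus_aligned=consensus_aligned or consensus,
        copies=copies,
        copy_ids=[f"c{i}" for i in range(len(copies))],
    )


class TestCallVariants:
    def test_identical_copy_gives_empty_list(self):
        assert call_variants(bundle_from("ACGT", ["ACGT"])) == [[]]

    def test_single_substitution(self):
        assert call_variants(bundle_from("ACGT", ["ATGT"])) == [[(1, "C", "T")]]

    def test_gap_and_n_columns_skipped(self):
        b = bundle_from("AC-GT", ["ATNGA"], consensus_aligned="AC-GT")
        # col1 C->T called; col2 consensus gap skipped; col3 copy N... wait N is copy base
        assert call_variants(b) == [[(1, "C", "T"), (3, "T", "A")]]

    def test_positions_in_consensus_coordinates(self):
        b = bundle_from("A-CGT", ["AACGA"], consensus_aligned="A-CGT")
        # aligned col 4 (T->A) is consensus position 3
        assert call_variants(b) == [[(3, "T", "A")]]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            bundle_from("ACGT", ["ACG"])

    def test_recall_is_one_against_injection_log(self):
        cons = simulate_element_consensus(length_codons=200, seed=4)
        cfg = FamilySimConfig(n_copies=8, shared_fraction=0.0, seed=5)
        bundle, log = simulate_family(cons, cfg)
        called = call_variants(bundle)
        logged_by_copy: dict[int, set] = {}
        for entry in log:
            i = int(entry["branch"].split("_")[1])
            logged_by_copy.setdefault(i, set()).add(
                (entry["position"], entry["from"], entry["to"])
            )
        for i, variants in enumerate(called):
            assert set(variants) == logged_by_copy.get(i, set())


class TestFilterSingletons:
    def test_shared_variant_removed(self):
        per_copy = [
            [(10, "C", "T")],
            [(10, "C", "T")],
            [(3, "G", "A")],
        ]
        assert filter_singletons(per_copy) == [(3, "G", "A")]

    def test_all_unique_unchanged(self):
        per_copy = [[(1, "A", "C")], [(2, "G", "T")]]
        assert sorted(filter_singletons(per_copy)) == [(1, "A", "C"), (2, "G", "T")]

    def test_different_substitutions_at_same_position_stay(self):
        per_copy = [[(5, "C", "T")], [(5, "C", "A")]]
        assert sorted(filter_singletons(per_copy)) == [(5, "C", "A"), (5, "C", "T")]

    def test_fewer_than_two_copies_errors(self):
        with pytest.raises(ValueError):
            filter_singletons([[(1, "A", "C")]])

    def test_ancestral_mutations_removed_in_simulation(self):
        cons = simulate_element_consensus(length_codons=300, seed=6)
        cfg = FamilySimConfig(n_copies=12, shared_fraction=0.5, seed=7)
        bundle, log = simulate_family(cons, cfg)
        singles = set(filter_singletons(call_variants(bundle)))
        ancestral = {
            (e["position"], e["from"], e["to"])
            for e in log
            if e["branch"] == "ancestral"
        }
        # every purely ancestral variant (not re-hit on a copy branch) is shared
        copy_positions = {e["position"] for e in log if e["branch"] != "ancestral"}
        for v in ancestral:
            if v[0] not in copy_positions:
                assert v not in singles


class TestClassifyCpgContext:
    @pytest.mark.parametrize(
        "consensus,variant,expected",
        [
            ("ACGT", (1, "C", "T"), "CpG"),
            ("ACTT", (1, "C", "T"), "nonCpG"),
            ("ACGT", (2, "G", "A"), "CpG"),
            ("TTGC", (2, "G", "A"), "nonCpG"),
            ("ACGT", (0, "A", "G"), "nonCpG"),
            ("CGTT", (0, "C", "T"), "CpG"),
            ("GTTC", (0, "G", "A"), "nonCpG"),  # edge: no 5' neighbor
        ],
    )
    def test_known_contexts(self, consensus, variant, expected):
        assert classify_cpg_context(variant, consensus) == expected

    def test_matches_brute_force_dinucleotide_scan(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        cpg_positions = set()
        for i in range(len(seq) - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                cpg_positions.update({i, i + 1})
        for pos in range(len(seq)):
            base = seq[pos]
            if base in "CG":
                expected = "CpG" if pos in cpg_positions else "nonCpG"
                assert classify_cpg_context((pos, base, "T"), seq) == expected


class TestNormalizeSpectrum:
    def test_uniform_composition_equal_counts_equal_pct(self):
        counts = {sub: 3 for sub in [("A", "C"), ("C", "A")]}
        rates, pct = normalize_spectrum(counts, {"A": 10, "C": 10, "G": 10, "T": 10})
        assert pct[("A", "C")] == pct[("C", "A")]

    def test_arithmetic_oracle(self):
        counts = {("C", "T"): 2, ("A", "G"): 1}
        rates, pct = normalize_spectrum(counts, {"C": 10, "A": 20, "G": 5, "T": 5})
        assert rates[("C", "T")] == pytest.approx(0.2)
        assert rates[("A", "G")] == pytest.approx(0.05)
        assert pct[("C", "T")] == pytest.approx(80.0)
        assert pct[("A", "G")] == pytest.approx(20.0)

    def test_pct_sums_to_100(self):
        counts = {("C", "T"): 5, ("G", "A"): 3, ("T", "C"): 1}
        _, pct = normalize_spectrum(counts, {"A": 7, "C": 9, "G": 11, "T": 13})
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_absent_source_base_excluded(self):
        rates, _ = normalize_spectrum({("C", "T"): 1}, {"A": 5, "C": 5, "G": 5, "T": 0})
        assert ("T", "C") not in rates


class TestGcToAtExcess:
    def test_symmetric_rates_give_1(self):
        rates = {sub: 0.1 for sub in [("C", "T"), ("C", "A"), ("G", "A"), ("G", "T"),
                                      ("T", "C"), ("A", "C"), ("A", "G"), ("T", "G")]}
        assert gc_to_at_excess(rates) == pytest.approx(1.0)

    def test_doubling_gc_to_at_doubles_ratio(self):
        base = {sub: 0.1 for sub in [("C", "T"), ("G", "A"), ("T", "C"), ("A", "G")]}
        r1 = gc_to_at_excess(base)
        doubled = dict(base)
        doubled[("C", "T")] *= 2
        doubled[("G", "A")] *= 2
        assert gc_to_at_excess(doubled) == pytest.approx(2 * r1)

    def test_zero_denominator_is_inf(self):
        assert gc_to_at_excess({("C", "T"): 0.1}) == float("inf")


class TestDivergenceFilter:
    def _bundle_at(self, divergence: float) -> FamilyBundle:
        n = 200
        cons = "ACGT" * (n // 4)
        k = int(divergence * n)
        copy = "T" * k + cons[k:] if k else cons
        copy = "".join(
            ("A" if cons[i] == "C" else "C") if i < k else cons[i] for i in range(n)
        )
        return bundle_from(cons, [copy, cons])

    def test_low_divergence_retained(self):
        kept, dropped = filter_families_by_divergence([self._bundle_at(0.03)], 0.05)
        assert len(kept) == 1 and dropped == 0

    def test_high_divergence_dropped(self):
        kept, dropped = filter_families_by_divergence([self._bundle_at(0.14)], 0.05)
        assert kept == [] and dropped == 1

    def test_mixed_set_matches_brute_force(self):
        bundles = [self._bundle_at(d) for d in (0.01, 0.04, 0.12, 0.2, 0.02)]
        kept, dropped = filter_families_by_divergence(bundles, 0.05)
        expected = [b for b in bundles if b.mean_divergence() < 0.05]
        assert kept == expected and dropped == len(bundles) - len(expected)


class TestSpectrumEndToEnd:
    def test_spectrum_invariant_under_copy_permutation(self):
        cons = simulate_element_consensus(length_codons=200, seed=12)
        bundle, _ = simulate_family(cons, FamilySimConfig(n_copies=6, seed=13))
        spec1 = family_spectrum(bundle)
        shuffled = FamilyBundle(
            consensus=bundle.consensus,
            consensus_aligned=bundle.consensus_aligned,
            copies=list(reversed(bundle.copies)),
            copy_ids=list(reversed(bundle.copy_ids)),
        )
        spec2 = family_spectrum(shuffled)
        assert spec1.raw_counts == spec2.raw_counts
        assert spec1.normalized_pct == spec2.normalized_pct

    def test_normalized_pct_sums_to_100(self):
        cons = simulate_element_consensus(length_codons=300, seed=14)
        bundle, _ = simulate_family(cons, FamilySimConfig(seed=15))
        spec = family_spectrum(bundle)
        assert sum(spec.normalized_pct.values()) == pytest.approx(100.0)
        assert spec.n_singletons == sum(spec.raw_counts.values())

    def test_cpg_counts_only_for_c_and_g_sources(self):
        cons = simulate_element_consensus(length_codons=300, seed=16)
        bundle, _ = simulate_family(cons, FamilySimConfig(seed=17))
        spec = family_spectrum(bundle)
        for (src, _), count in spec.cpg_counts.items():
            if src in "AT":
                assert count == 0

    def test_skipping_singleton_filter_biases_toward_ancestral(self):
        # with shared mutations present, the unfiltered spectrum over-counts
        # the ancestral branch; the filtered one does not
        cons = simulate_element_consensus(length_codons=1000, seed=18)
        cfg = FamilySimConfig(n_copies=10, shared_fraction=0.5, seed=19)
        bundle, log = simulate_family(cons, cfg)
        per_copy = call_variants(bundle)
        filtered = filter_singletons(per_copy)
        unfiltered = [v for variants in per_copy for v in variants]
        ancestral = {
            (e["position"], e["from"], e["to"]) for e in log if e["branch"] == "ancestral"
        }
        frac_anc_unfiltered = sum(v in ancestral for v in unfiltered) / len(unfiltered)
        frac_anc_filtered = sum(v in ancestral for v in filtered) / len(filtered)
        assert frac_anc_unfiltered > frac_anc_filtered


class TestBranchProbabilityInversion:
    def test_round_trip(self):
        n = 10
        for q in (1e-4, 0.002, 0.05, 0.09):
            r = q * (1 - q) ** (n - 1)
            assert branch_mutation_probability(
                round(r * 1e7), int(1e6), n
            ) == pytest.approx(q, rel=0.05)

    def test_zero_count(self):
        assert branch_mutation_probability(0, 100, 10) == 0.0


class TestDivergenceMatching:
    def test_pairs_nearest_divergence(self):
        def fam(d, tag):
            n = 300
            cons = "ACGT" * (n // 4)
            k = int(d * n)
            copy = "".join(
                ("A" if cons[i] == "C" else "C") if i < k else cons[i] for i in range(n)
            )
            b = bundle_from(cons, [copy, cons])
            b.consensus.id = tag
            return b

        group_a = [fam(0.01, "a1"), fam(0.04, "a2")]
        group_b = [fam(0.011, "b1"), fam(0.045, "b2"), fam(0.3, "b3")]
        sel_a, sel_b = divergence_matched_subsets(group_a, group_b, seed=1)
        assert {b.consensus.id for b in sel_b} == {"b1", "b2"}
        assert len(sel_a) == len(sel_b) == 2
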