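import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oligopipe import oligotyping as ot
from oligopipe.oligotyping import (
    FilterParams,
    apply_noise_filters,
    decompose,
    filter_params_for_depth,
    individual_level_params,
    max_unique_sequence_counts,
    positional_entropy,
    select_components,
)
from oligopipe.synthetic_data import TaxonSimSpec, simulate_taxon_reads

from conftest import column_readset, make_readset


class TestPositionalEntropy:
    @pytest.mark.parametrize("column, expected", [
        ("AAAA", 0.0),
        ("AACC", 1.0),
        ("AAAC", -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ("ACGT-", np.log2(5)),  # uniform over the full 5-symbol alphabet
    ])
    def test_known_columns(self, column, expected):
        h = positional_entropy(column_readset(column))
        assert h[0] == pytest.approx(expected, abs=1e-9)

    def test_n_excluded_from_frequencies(self):
        # 'N' does not count: ANN has only A observed -> entropy 0
        assert positional_entropy(column_readset("ANN"))[0] == 0.0

    def test_empty_read_set_errors(self):
        empty = make_readset([])
        with pytest.raises(ValueError):
            positional_entropy(empty)

    @given(st.lists(st.lists(st.sampled_from("ACGT-"), min_size=4, max_size=4)
                    .map("".join), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_and_monomorphic_zero(self, seqs):
        rs = make_readset(seqs)
        h = positional_entropy(rs)
        assert (h >= 0).all() and (h <= np.log2(5) + 1e-12).all()
        for j in range(rs.alignment_length):
            monomorphic = len({s[j] for s in seqs}) == 1
            assert (h[j] == 0.0) == monomorphic


class TestSelectComponents:
    def test_single_polymorphic_column(self):
        rs = make_readset(["AAC", "AGC", "AAC", "AGC"])
        sel = select_components(rs, tau=0.2)
        assert sel.positions == [1]
        assert sel.converged

    def test_monomorphic_alignment_selects_nothing(self):
        rs = make_readset(["ACGT"] * 5)
        sel = select_components(rs, tau=0.2)
        assert sel.positions == []

    def test_recovers_planted_independent_positions(self):
        spec = TaxonSimSpec.independent_positions(
            taxon="t", positions=(10, 40, 70),
            allele_freqs_by_group={"g1": [(0.7, 0.3)] * 3},
            alleles=[("A", "G"), ("C", "T"), ("G", "A")],
            alignment_length=100, error_rate=0.0,
            depths={"g1": 2000})
        rs, truth = simulate_taxon_reads(spec, seed=5)
        sel = select_components(rs, tau=0.2)
        assert sorted(sel.positions) == [10, 40, 70]
        assert sel.converged

    def test_max_components_flag(self):
        spec = TaxonSimSpec.independent_positions(
            taxon="t", positions=(1, 5, 9),
            allele_freqs_by_group={"g1": [(0.5, 0.5)] * 3},
            alignment_length=12, error_rate=0.0, depths={"g1": 400})
        rs, _ = simulate_taxon_reads(spec, seed=1)
        sel = select_components(rs, tau=0.2, max_components=2)
        assert len(sel.positions) == 2
        assert not sel.converged


class TestDecompose:
    def test_single_position(self):
        a = decompose(make_readset(["AAAA", "AATA"]), [2])
        assert a.counts.sum(axis=1).to_dict() == {"A": 1, "T": 1}

    def test_empty_components_single_oligotype(self):
        a = decompose(make_readset(["AAAA", "AATA"]), [])
        assert a.counts.sum(axis=1).to_dict() == {"": 2}

    def test_n_at_component_excluded(self):
        a = decompose(make_readset(["AAAA", "AANA"]), [2])
        assert a.counts.sum(axis=1).to_dict() == {"A": 1}
        assert a.excluded == {"ambiguous_N": 1}
        a.check_conservation()

    def test_out_of_range_component_errors(self):
        with pytest.raises(IndexError):
            decompose(make_readset(["AAAA"]), [4])

    def test_planted_frequencies_recovered_exactly_without_noise(self):
        spec = TaxonSimSpec(
            taxon="t", component_positions=(3, 7), variants=("AT", "GC"),
            group_freqs={"g1": (0.6, 0.4)}, alignment_length=10,
            error_rate=0.0, depths={"g1": 1000})
        rs, truth = simulate_taxon_reads(spec, seed=11)
        a = decompose(rs, (3, 7))
        for variant in spec.variants:
            assert a.counts.loc[variant, "g1"] == truth.group_counts.loc[
                variant, "g1"]


class TestFilterParams:
    @pytest.mark.parametrize("depth, expected", [
        (100_000, (1, 50, 500)),
        (50_000, (1, 50, 500)),   # shared endpoint: upper tier wins
        (40_000, (1, 25, 250)),
        (30_000, (1, 25, 250)),
        (20_000, (1, 10, 50)),
        (10_000, (1, 10, 50)),
        (5_000, (1, 5, 10)),
        (750, (1, 5, 10)),
        (100, (1, 5, 10)),        # below lowest tier: tier-4 values
    ])
    def test_tier_lookup(self, depth, expected):
        p = filter_params_for_depth(depth)
        assert (p.a, p.M, p.A) == expected

    def test_non_positive_depth_errors(self):
        with pytest.raises(ValueError):
            filter_params_for_depth(0)

    def test_individual_level_params(self):
        p = individual_level_params()
        assert (p.a, p.M, p.A) == (5, 0, 0)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(a=-1, M=0, A=0)


def assignment_from_counts(counts_by_group, n_extra_excluded=0):
    counts = pd.DataFrame(counts_by_group).fillna(0).astype(np.int64)
    counts.index.name = "oligotype"
    n_input = int(counts.to_numpy().sum()) + n_extra_excluded
    excluded = {"ambiguous_N": n_extra_excluded} if n_extra_excluded else {}
    return ot.OligotypeAssignment(
        components=(0,), counts=counts, excluded=excluded, n_input=n_input,
        read_oligotype=None)


class TestNoiseFilters:
    def test_abundance_filter_strict(self):
        # Y at 0.9% fails the strict >1% rule; Z at 0.1% fails too
        a = assignment_from_counts({"g1": {"X": 990, "Y": 9, "Z": 1}})
        out = apply_noise_filters(a, FilterParams(a=1, M=0, A=0))
        assert out.oligotypes == ["X"]
        assert out.excluded["filtered_aMA"] == 10
        out.check_conservation()

    def test_zero_params_keep_everything(self):
        a = assignment_from_counts({"g1": {"X": 990, "Y": 9, "Z": 1}},
                                   n_extra_excluded=5)
        out = apply_noise_filters(a, FilterParams(a=0, M=0, A=0))
        assert set(out.oligotypes) == {"X", "Y", "Z"}
        assert out.excluded == {"ambiguous_N": 5}

    def test_total_abundance_filter_pools_groups(self):
        a = assignment_from_counts({
            "cheetah": {"X": 400, "Y": 225}, "jackal": {"X": 200, "Y": 225}})
        out = apply_noise_filters(a, FilterParams(a=1, M=0, A=500))
        # X: 600 > 500 kept; Y: 450 <= 500 dropped despite presence in both
        assert out.oligotypes == ["X"]

    def test_unique_sequence_filter(self):
        a = assignment_from_counts({"g1": {"X": 80, "Y": 20}})
        out = apply_noise_filters(a, FilterParams(a=0, M=30, A=0),
                                  unique_sequences={"X": 70, "Y": 15})
        assert out.oligotypes == ["X"]

    def test_individual_level_example(self):
        a = assignment_from_counts({"g1": {"X": 96, "Y": 4}})
        out = apply_noise_filters(a, individual_level_params())
        assert out.oligotypes == ["X"]
        both = assignment_from_counts({"g1": {"X": 50, "Y": 50}})
        out2 = apply_noise_filters(both, individual_level_params())
        assert set(out2.oligotypes) == {"X", "Y"}

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_and_conservative_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 8)
        counts = {
            "g1": {f"o{i}": int(rng.integers(0, 300)) for i in range(k)},
            "g2": {f"o{i}": int(rng.integers(0, 300)) for i in range(k)},
        }
        a = assignment_from_counts(counts)
        uniq = {f"o{i}": int(rng.integers(0, 100)) for i in range(k)}
        base = FilterParams(a=float(rng.uniform(0, 3)),
                            M=int(rng.integers(0, 40)),
                            A=int(rng.integers(0, 400)))
        out = apply_noise_filters(a, base, uniq)
        out.check_conservation()
        for stricter in (
            FilterParams(base.a + 1, base.M, base.A),
            FilterParams(base.a, base.M + 10, base.A),
            FilterParams(base.a, base.M, base.A + 100),
        ):
            tighter = apply_noise_filters(a, stricter, uniq)
            tighter.check_conservation()
            assert set(tighter.oligotypes) <= set(out.oligotypes)


class TestNoiseRejection:
    def test_error_derived_oligotypes_filtered_out(self):
        # one true oligotype + 0.5% substitution noise: the a/M/A filter
        # must reduce the decomposition back to a single oligotype
        spec = TaxonSimSpec(
            taxon="t", component_positions=(10, 60, 110),
            variants=("ACT",), group_freqs={"g1": (1.0,)},
            alignment_length=150, error_rate=0.005, depths={"g1": 20_000})
        rs, _ = simulate_taxon_reads(spec, seed=3)
        sel = select_components(rs, tau=0.2)
        a = decompose(rs, sel.positions)
        uniq = max_unique_sequence_counts(rs, a)
        out = apply_noise_filters(a, filter_params_for_depth(20_000), uniq)
        assert len(out.oligotypes) == 1
        out.check_conservation()


def test_max_unique_sequence_counts_identifies_duplicates():
    rs = make_readset(["AAAA", "AAAA", "AAAT", "CAAA"])
    a = decompose(rs, [0])
    uniq = max_unique_sequence_counts(rs, a)
    assert uniq["A"] == 2  # two identical AAAA reads dominate oligotype A
    assert uniq["C"] == 1
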