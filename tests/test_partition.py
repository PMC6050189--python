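import math

import numpy as np
import pandas as pd
import pytest

from hierdiv import (
    AbundanceTable,
    HierarchySpec,
    ValidationError,
    allele_counts_from_genotypes,
    average_over_loci,
    compute_weights,
    decompose,
    differentiation,
    level_alpha_entropy,
    pooled_frequencies,
    weight_entropy_normalizer,
)
from hierdiv.partition import decompose_per_locus

from conftest import random_instance, two_pop_delta


class TestWeights:
    @pytest.mark.parametrize(
        "sums, expected",
        [((10, 30), (0.25, 0.75)), ((7, 7, 7), (1 / 3,) * 3), ((8, 2), (0.8, 0.2))],
    )
    def test_proportional_to_column_sums(self, sums, expected):
        counts = np.array([list(sums)], dtype=float)
        t = AbundanceTable.from_arrays(counts, ["a"], [f"u{i}" for i in range(len(sums))])
        assert compute_weights(t).to_numpy() == pytest.approx(expected)

    def test_equal_weights_option(self):
        t = AbundanceTable.from_arrays([[10, 30]], ["a"], ["u1", "u2"])
        assert compute_weights(t, equal=True).to_numpy() == pytest.approx([0.5, 0.5])


class TestPooledFrequencies:
    def test_equal_weight_mixture(self):
        t = AbundanceTable.from_arrays([[5, 0], [0, 5]], ["a", "b"], ["u1", "u2"])
        w = compute_weights(t)
        assert pooled_frequencies(t, w, ["u1", "u2"]) == pytest.approx([0.5, 0.5])

    def test_weighted_mixture(self):
        t = AbundanceTable.from_arrays([[30, 0], [0, 10]], ["a", "b"], ["u1", "u2"])
        w = compute_weights(t)
        assert pooled_frequencies(t, w, ["u1", "u2"]) == pytest.approx([0.75, 0.25])

    def test_single_unit_identity(self):
        t = AbundanceTable.from_arrays([[3, 1], [1, 9]], ["a", "b"], ["u1", "u2"])
        w = compute_weights(t)
        assert pooled_frequencies(t, w, ["u2"]) == pytest.approx([0.1, 0.9])

    def test_route_equivalence_with_raw_counts(self, rng):
        """Weight-mixture pooling equals renormalised summed raw counts."""
        for _ in range(50):
            table, hierarchy = random_instance(rng, n_levels=3)
            w = compute_weights(table)
            units = hierarchy.units
            group = list(rng.choice(units, size=rng.integers(1, len(units) + 1), replace=False))
            mixture = pooled_frequencies(table, w, group)
            raw = table.data[group].to_numpy().sum(axis=1)
            assert mixture == pytest.approx(raw / raw.sum(), abs=1e-12)

    def test_empty_group_rejected(self):
        t = AbundanceTable.from_arrays([[1.0]], ["a"], ["u1"])
        with pytest.raises(ValidationError, match="empty"):
            pooled_frequencies(t, compute_weights(t), [])


class TestLevelAlphaEntropy:
    def test_identical_units_every_level(self, rng):
        counts = np.tile([[6.0], [3.0], [1.0]], (1, 4))
        t = AbundanceTable.from_arrays(counts, ["a", "b", "c"], ["u1", "u2", "u3", "u4"])
        h = HierarchySpec.from_mapping(
            ["unit", "region", "eco"],
            {"u1": ("r1", "e"), "u2": ("r1", "e"), "u3": ("r2", "e"), "u4": ("r2", "e")},
        )
        w = compute_weights(t)
        expected = -(0.6 * math.log(0.6) + 0.3 * math.log(0.3) + 0.1 * math.log(0.1))
        for level in (1, 2, 3):
            assert level_alpha_entropy(t, h, w, level) == pytest.approx(expected, abs=1e-12)

    def test_shared_allele_example_entropies(self, sixty_percent):
        table, hierarchy = sixty_percent
        w = compute_weights(table)
        assert level_alpha_entropy(table, hierarchy, w, 1) == pytest.approx(
            math.log(10), abs=1e-12
        )
        # pooled system: 4 alleles at 0.1, 12 at 0.05
        h_gamma = 0.4 * math.log(10) + 0.6 * math.log(20)
        assert level_alpha_entropy(table, hierarchy, w, 2) == pytest.approx(
            h_gamma, abs=1e-12
        )


class TestDecompose:
    def test_shared_allele_example(self, sixty_percent):
        table, hierarchy = sixty_percent
        dec = decompose(table, hierarchy)
        assert dec.d_alpha[0] == pytest.approx(10.0, rel=1e-12)
        h_gamma = 0.4 * math.log(10) + 0.6 * math.log(20)
        assert dec.d_gamma == pytest.approx(math.exp(h_gamma), rel=1e-12)
        assert dec.d_beta[0] == pytest.approx(math.exp(h_gamma) / 10, rel=1e-12)
        assert dec.differentiation[0] == pytest.approx(0.6, abs=1e-12)

    def test_identical_units_degenerate(self):
        counts = np.tile([[6.0], [4.0]], (1, 3))
        t = AbundanceTable.from_arrays(counts, ["a", "b"], ["u1", "u2", "u3"])
        h = HierarchySpec.from_mapping(
            ["unit", "eco"], {"u1": ("e",), "u2": ("e",), "u3": ("e",)}
        )
        dec = decompose(t, h)
        assert dec.d_beta[0] == pytest.approx(1.0, abs=1e-12)
        assert dec.differentiation[0] == 0.0
        assert dec.beta_info_share[0] == 0.0
        assert dec.no_beta_information

    def test_completely_distinct_units_replication(self):
        """Two equal, disjoint, uniform units: beta = 2, gamma = 2S."""
        s = 5
        counts = np.zeros((2 * s, 2))
        counts[:s, 0] = 3.0
        counts[s:, 1] = 3.0
        t = AbundanceTable.from_arrays(counts, [f"a{i}" for i in range(2 * s)], ["u1", "u2"])
        h = HierarchySpec.from_mapping(["unit", "eco"], {"u1": ("e",), "u2": ("e",)})
        dec = decompose(t, h)
        assert dec.d_beta[0] == pytest.approx(2.0, rel=1e-12)
        assert dec.d_gamma == pytest.approx(2 * s, rel=1e-12)
        assert dec.differentiation[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_levels", [3, 4])
    def test_multiplicative_chain(self, rng, n_levels):
        for _ in range(40):
            table, hierarchy = random_instance(rng, n_levels=n_levels)
            dec = decompose(table, hierarchy)
            chained = dec.d_alpha[0] * np.prod(dec.d_beta)
            assert chained == pytest.approx(dec.d_gamma, rel=1e-9)
            assert (dec.d_beta >= 1 - 1e-12).all()
            if not dec.no_beta_information:
                assert dec.beta_info_share.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fast_path_matches_per_operation_route(self, rng):
        """decompose() agrees with the level-entropy / normalizer operations."""
        for _ in range(20):
            table, hierarchy = random_instance(rng, n_levels=4)
            dec = decompose(table, hierarchy)
            w = compute_weights(table)
            for level in range(1, hierarchy.n_levels + 1):
                assert dec.h_alpha[level - 1] == pytest.approx(
                    level_alpha_entropy(table, hierarchy, w, level), abs=1e-10
                )
            for level in range(1, hierarchy.n_levels):
                assert dec.differentiation[level - 1] == pytest.approx(
                    differentiation(table, hierarchy, w, level), abs=1e-10
                )

    def test_beta_bounded_by_children_count(self):
        """Equally weighted children: 1 <= D_beta <= number of children."""
        rng = np.random.default_rng(5)
        for n_children in (2, 3, 4):
            counts = rng.integers(1, 10, size=(6, n_children)).astype(float)
            counts = counts / counts.sum(axis=0, keepdims=True)  # equal unit totals
            t = AbundanceTable.from_arrays(
                counts, [f"a{i}" for i in range(6)], [f"u{j}" for j in range(n_children)]
            )
            h = HierarchySpec.from_mapping(
                ["unit", "eco"], {f"u{j}": ("e",) for j in range(n_children)}
            )
            beta = decompose(t, h).d_beta[0]
            assert 1 - 1e-12 <= beta <= n_children + 1e-12

    def test_rescaling_invariance(self, rng):
        table, hierarchy = random_instance(rng, n_levels=3)
        scaled = AbundanceTable(table.data * 37.5)
        a, b = decompose(table, hierarchy), decompose(scaled, hierarchy)
        assert a.d_alpha == pytest.approx(b.d_alpha, rel=1e-12)
        assert a.differentiation == pytest.approx(b.differentiation, abs=1e-12)

    def test_mismatched_units_rejected(self, sixty_percent):
        table, _ = sixty_percent
        bad = HierarchySpec.from_mapping(["population", "eco"], {"pop1": ("e",), "popX": ("e",)})
        with pytest.raises(ValidationError, match="popX"):
            decompose(table, bad)


class TestDifferentiation:
    @pytest.mark.parametrize("n", [2, 3, 4])
    @pytest.mark.parametrize("s", [5, 10])
    def test_true_dissimilarity_grid(self, n, s):
        """N equal units, S uniform alleles, A shared by all: Delta = 1 - A/S."""
        from hierdiv.datasets import shared_allele_example

        for a in range(s + 1):
            table, hierarchy = shared_allele_example(n_units=n, s=s, shared=a)
            dec = decompose(table, hierarchy)
            assert dec.differentiation[0] == pytest.approx(1 - a / s, abs=1e-12)

    def test_monotone_under_unshared_allele_addition(self, rng):
        for _ in range(500):
            s = int(rng.integers(2, 8))
            counts = rng.integers(0, 20, size=(s, 2)).astype(float)
            counts[rng.integers(0, s), 0] += 1
            counts[rng.integers(0, s), 1] += 1
            base = two_pop_delta(counts)
            added = np.vstack([counts, [float(rng.integers(1, 15)), 0.0]])
            assert two_pop_delta(added) >= base - 1e-12

    def test_monotone_under_shared_to_unshared_replacement(self, rng):
        done = 0
        while done < 500:
            s = int(rng.integers(2, 8))
            counts = rng.integers(0, 20, size=(s, 2)).astype(float)
            counts[rng.integers(0, s), 0] += 1
            counts[rng.integers(0, s), 1] += 1
            shared = np.flatnonzero((counts[:, 0] > 0) & (counts[:, 1] > 0))
            if not len(shared):
                continue
            base = two_pop_delta(counts)
            i = rng.choice(shared)
            x = float(rng.integers(1, counts[i, 0] + 1))
            replaced = np.vstack([counts, [0.0, 0.0]])
            replaced[i, 0] -= x
            replaced[-1, 0] = x
            assert two_pop_delta(replaced) >= base - 1e-12
            done += 1

    def test_top_level_rejected(self, sixty_percent):
        table, hierarchy = sixty_percent
        w = compute_weights(table)
        with pytest.raises(ValidationError, match="top level"):
            differentiation(table, hierarchy, w, hierarchy.n_levels)

    def test_single_child_parents_give_zero_normalizer(self):
        t = AbundanceTable.from_arrays([[1, 2], [3, 4]], ["a", "b"], ["u1", "u2"])
        h = HierarchySpec.from_mapping(
            ["unit", "sub", "eco"], {"u1": ("s1", "e"), "u2": ("s2", "e")}
        )
        w = compute_weights(t)
        assert weight_entropy_normalizer(h, w, 1) == 0.0
        assert differentiation(t, h, w, 1) == 0.0


class TestBetaInformationShares:
    def test_two_level_single_share(self, sixty_percent):
        table, hierarchy = sixty_percent
        assert decompose(table, hierarchy).beta_info_share == pytest.approx([1.0])

    def test_shares_are_entropy_gap_ratios(self, rng):
        table, hierarchy = random_instance(rng, n_levels=4)
        dec = decompose(table, hierarchy)
        gaps = np.diff(dec.h_alpha)
        assert dec.beta_info_share == pytest.approx(gaps / gaps.sum(), abs=1e-10)


class TestGenotypes:
    def test_copy_counting(self):
        rows = pd.DataFrame(
            {
                "unit": ["p1", "p1"],
                "locus": ["loc1", "loc1"],
                "allele1": ["A", "A"],
                "allele2": ["B", "A"],
            }
        )
        tables = allele_counts_from_genotypes(rows)
        t = tables["loc1"].data
        assert t.loc["A", "p1"] == 3 and t.loc["B", "p1"] == 1

    def test_column_sums_twice_individuals(self):
        rows = pd.DataFrame(
            {
                "unit": ["p1"] * 10,
                "locus": ["loc1"] * 10,
                "allele1": ["A"] * 10,
                "allele2": ["B"] * 10,
            }
        )
        t = allele_counts_from_genotypes(rows)["loc1"].data
        assert t["p1"].sum() == 20
        assert t.loc["A", "p1"] == 10 and t.loc["B", "p1"] == 10

    def test_unknown_population_listed(self):
        rows = pd.DataFrame(
            {"unit": ["p9"], "locus": ["l"], "allele1": ["A"], "allele2": ["A"]}
        )
        with pytest.raises(ValidationError, match="p9"):
            allele_counts_from_genotypes(rows, known_units=["p1", "p2"])


class TestAverageOverLoci:
    def test_single_locus_identity(self, sixty_percent):
        table, hierarchy = sixty_percent
        dec = decompose(table, hierarchy)
        avg = average_over_loci([dec], loci=["loc1"])
        assert avg.d_gamma == dec.d_gamma
        assert list(avg.per_locus) == ["loc1"]

    def test_arithmetic_mean_of_effective_numbers(self):
        t1 = AbundanceTable.from_arrays([[5, 0], [0, 5]], ["a", "b"], ["u1", "u2"])
        t2 = AbundanceTable.from_arrays(
            np.eye(4) * 5, [f"a{i}" for i in range(4)], ["u1", "u2", "u3", "u4"]
        )
        h1 = HierarchySpec.from_mapping(["unit", "eco"], {"u1": ("e",), "u2": ("e",)})
        h2 = HierarchySpec.from_mapping(
            ["unit", "eco"], {f"u{j}": ("e",) for j in (1, 2, 3, 4)}
        )
        d1, d2 = decompose(t1, h1), decompose(t2, h2)
        assert d1.d_gamma == pytest.approx(2.0)
        assert d2.d_gamma == pytest.approx(4.0)
        avg = average_over_loci([d1, d2], loci=["l1", "l2"])
        assert avg.d_gamma == pytest.approx(3.0)
        assert set(avg.per_locus) == {"l1", "l2"}

    def test_mismatched_hierarchies_rejected(self, sixty_percent, toy3):
        d1 = decompose(*sixty_percent)
        d2 = decompose(*toy3)
        with pytest.raises(ValidationError, match="mismatch"):
            average_over_loci([d1, d2])

    def test_zero_count_units_dropped_per_locus(self, caplog):
        t_ok = AbundanceTable.from_arrays([[5, 5], [5, 5]], ["a", "b"], ["u1", "u2"])
        t_zero = AbundanceTable.from_arrays(
            [[5, 0], [5, 0]], ["a", "b"], ["u1", "u2"], allow_empty_units=True
        )
        h = HierarchySpec.from_mapping(["unit", "eco"], {"u1": ("e",), "u2": ("e",)})
        avg = decompose_per_locus({"l1": t_ok, "l2": t_zero}, h)
        assert len(avg.per_locus) == 2  # l2 analysed on the single surviving unit
        assert avg.per_locus["l2"].d_beta[0] == pytest.approx(1.0)


class TestTableAndHierarchyValidation:
    def test_negative_abundance_named(self):
        frame = pd.DataFrame({"u1": [1.0, -2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="'b'"):
            AbundanceTable(frame)

    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame([[1.0], [1.0]], index=["a", "a"], columns=["u1"])
        with pytest.raises(ValidationError, match="duplicate element"):
            AbundanceTable(frame)

    def test_zero_column_rejected_by_default(self):
        frame = pd.DataFrame({"u1": [1.0], "u2": [0.0]}, index=["a"])
        with pytest.raises(ValidationError, match="u2"):
            AbundanceTable(frame)
        table = AbundanceTable(frame, allow_empty_units=True)
        kept, dropped = table.drop_empty_units()
        assert dropped == ["u2"] and kept.units == ["u1"]

    def test_non_nested_hierarchy_rejected(self):
        with pytest.raises(ValidationError, match="non-nested"):
            HierarchySpec.from_mapping(
                ["unit", "sub", "region", "eco"],
                {
                    "u1": ("s1", "r1", "e"),
                    "u2": ("s1", "r2", "e"),  # s1 cannot span r1 and r2
                    "u3": ("s2", "r2", "e"),
                },
            )

    def test_multiple_top_aggregates_rejected(self):
        with pytest.raises(ValidationError, match="exactly one"):
            HierarchySpec.from_mapping(
                ["unit", "eco"], {"u1": ("e1",), "u2": ("e2",)}
            )
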