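"""Profile-builder tests, checked against independent exact-arithmetic oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habmock.classification import ClassificationSet, ReadAssignment
from habmock.errors import ConfigurationError
from habmock.profile import (
    ABOVE_SPECIES,
    NO_REFERENCE,
    CountTable,
    count_assignments,
    distribute_species_counts,
    filter_domains,
    integerize,
    promote_orphan_strains,
    scale_counts,
)

from conftest import make_catalog, make_tree


# ---------------------------------------------------------------- oracles
def oracle_distribute(species_mass, strain_counts):
    """Exact ratio split of one species' mass over its strains.

    strain_counts: {taxid: already-assigned count}. Returns final counts.
    Independent of the implementation: pure Fraction arithmetic.
    """
    mass = Fraction(species_mass)
    counts = {t: Fraction(c) for t, c in strain_counts.items()}
    denom = sum(counts.values())
    out = {}
    for t, c in counts.items():
        share = mass * c / denom if denom else mass / len(counts)
        out[t] = c + share
    return out


def oracle_largest_remainder(fractional):
    """Largest-remainder apportionment via exact Fractions.

    fractional: {key: count}. Floors everything, then hands the missing
    units to the largest remainders (ties: larger count, then key).
    """
    fracs = {k: Fraction(v).limit_denominator(10**9) for k, v in fractional.items()}
    total = sum(fracs.values())
    rounded_total = int(total + Fraction(1, 2)) if total >= 0 else 0
    alloc = {k: int(v) for k, v in fracs.items()}  # int() floors positives
    remaining = rounded_total - sum(alloc.values())
    order = sorted(fracs, key=lambda k: (-(fracs[k] - int(fracs[k])), -fracs[k], k))
    for k in order[:remaining]:
        alloc[k] += 1
    return alloc


# ------------------------------------------------------- shared scenario
@pytest.fixture()
def tree():
    return make_tree(
        {
            2: (1, "superkingdom"),      # Bacteria
            2759: (1, "superkingdom"),   # Eukaryota
            100: (2, "genus"),
            200: (100, "species"),
            201: (100, "species"),
            301: (200, "strain"),
            302: (200, "no rank"),
            303: (200, "strain"),
            311: (201, "strain"),
            9606: (2759, "species"),
        }
    )


class TestCountAssignments:
    def test_three_taxa_one_third_each(self, tree):
        cs = ClassificationSet(assigned=[ReadAssignment("r1", frozenset({301, 302, 303}))])
        table = count_assignments(cs, tree)
        assert table.counts == pytest.approx({301: 1 / 3, 302: 1 / 3, 303: 1 / 3})

    def test_genus_level_mass_dropped(self, tree):
        cs = ClassificationSet(assigned=[ReadAssignment("r1", frozenset({100}))])
        table = count_assignments(cs, tree)
        assert table.counts == {}
        (drop,) = table.drop_report
        assert (drop.taxid, drop.count, drop.reason) == (100, 1.0, ABOVE_SPECIES)

    def test_repeated_pairs_sum(self, tree):
        cs = ClassificationSet(
            assigned=[ReadAssignment(f"r{i}", frozenset({301, 302})) for i in range(6)]
        )
        table = count_assignments(cs, tree)
        assert table.counts == pytest.approx({301: 3.0, 302: 3.0})
        assert table.total() == pytest.approx(6.0)

    def test_unresolved_taxid_goes_to_drop_report(self, tree):
        cs = ClassificationSet(assigned=[ReadAssignment("r1", frozenset({999999}))])
        table = count_assignments(cs, tree)
        assert table.counts == {}
        assert table.drop_report[0].reason == "unresolved_taxid"

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.sets(st.sampled_from([301, 302, 303, 311, 200, 100, 999]), min_size=1, max_size=4),
            min_size=1,
            max_size=30,
        )
    )
    def test_mass_conservation_property(self, taxa_sets):
        tree = make_tree(
            {
                2: (1, "superkingdom"),
                100: (2, "genus"),
                200: (100, "species"),
                201: (100, "species"),
                301: (200, "strain"),
                302: (200, "no rank"),
                303: (200, "strain"),
                311: (201, "strain"),
            }
        )
        cs = ClassificationSet(
            assigned=[ReadAssignment(f"r{i}", frozenset(s)) for i, s in enumerate(taxa_sets)]
        )
        table = count_assignments(cs, tree)
        assert table.total() + table.dropped_total() == pytest.approx(len(taxa_sets), abs=1e-9)


class TestPromoteOrphanStrains:
    def test_orphan_count_moves_to_species(self, tree):
        catalog = make_catalog([("GCF_A", 301, 200)])
        table = CountTable(counts={302: 5.0, 200: 2.0})
        out = promote_orphan_strains(table, catalog, tree)
        assert out.counts.get(200) == pytest.approx(7.0)
        assert 302 not in out.counts
        assert out.total() == pytest.approx(table.total())

    def test_strain_with_genome_unchanged(self, tree):
        catalog = make_catalog([("GCF_A", 301, 200)])
        table = CountTable(counts={301: 5.0})
        out = promote_orphan_strains(table, catalog, tree)
        assert out.counts == {301: 5.0}

    def test_two_orphans_sum_onto_species(self, tree):
        catalog = make_catalog([("GCF_A", 303, 200)])
        table = CountTable(counts={301: 1.0, 302: 2.0})
        out = promote_orphan_strains(table, catalog, tree)
        assert out.counts == pytest.approx({200: 3.0})


class TestDistributeSpeciesCounts:
    def test_ratio_split_matches_worked_arithmetic(self, tree):
        # species 10 over strains already holding 6 and 2 -> 13.5 and 4.5
        catalog = make_catalog([("GCF_A", 301, 200), ("GCF_B", 302, 200)])
        table = CountTable(counts={200: 10.0, 301: 6.0, 302: 2.0})
        out = distribute_species_counts(table, catalog, tree)
        expected = oracle_distribute(10, {301: 6, 302: 2})
        assert out.counts == pytest.approx({t: float(v) for t, v in expected.items()})
        assert out.counts == pytest.approx({301: 13.5, 302: 4.5})

    def test_single_strain_takes_everything(self, tree):
        catalog = make_catalog([("GCF_A", 301, 200)])
        table = CountTable(counts={200: 10.0, 301: 1.0})
        out = distribute_species_counts(table, catalog, tree)
        assert out.counts == pytest.approx({301: 11.0})

    def test_uniform_fallback_when_all_strains_zero(self, tree):
        catalog = make_catalog([("GCF_A", 301, 200), ("GCF_B", 302, 200)])
        table = CountTable(counts={200: 9.0})
        out = distribute_species_counts(table, catalog, tree)
        assert out.counts == pytest.approx({301: 4.5, 302: 4.5})
        assert out.total() == pytest.approx(9.0)

    def test_species_own_assembly_keeps_count(self, tree):
        catalog = make_catalog([("GCF_S", 200, 200)])
        table = CountTable(counts={200: 4.0})
        out = distribute_species_counts(table, catalog, tree)
        assert out.counts == pytest.approx({200: 4.0})

    def test_no_reference_anywhere_drops_mass(self, tree):
        table = CountTable(counts={201: 3.0})
        out = distribute_species_counts(table, make_catalog([]), tree)
        assert out.counts == {}
        (drop,) = out.drop_report
        assert (drop.taxid, drop.count, drop.reason) == (201, 3.0, NO_REFERENCE)

    def test_taxid_relabeling_equivariance(self, tree):
        """Permuting strain taxids permutes the result identically."""
        catalog = make_catalog([("GCF_A", 301, 200), ("GCF_B", 302, 200), ("GCF_C", 303, 200)])
        table = CountTable(counts={200: 12.0, 301: 1.0, 302: 2.0, 303: 3.0})
        out = distribute_species_counts(table, catalog, tree)
        # relabel 301<->303 (swap their counts); accessions follow taxids
        catalog2 = make_catalog([("GCF_A", 303, 200), ("GCF_B", 302, 200), ("GCF_C", 301, 200)])
        table2 = CountTable(counts={200: 12.0, 303: 1.0, 302: 2.0, 301: 3.0})
        out2 = distribute_species_counts(table2, catalog2, tree)
        assert out.counts[301] == pytest.approx(out2.counts[303])
        assert out.counts[303] == pytest.approx(out2.counts[301])
        assert out.counts[302] == pytest.approx(out2.counts[302])


class TestFilterDomains:
    def test_default_bacteria_partition(self, tree):
        table = CountTable(counts={301: 5.0, 9606: 7.0})
        selected, excluded = filter_domains(table, tree, {"Bacteria"})
        assert selected.counts == {301: 5.0}
        assert excluded.counts == {9606: 7.0}

    def test_all_domains_selected_leaves_nothing_excluded(self, tree):
        table = CountTable(counts={301: 5.0, 9606: 7.0})
        selected, excluded = filter_domains(
            table, tree, {"Bacteria", "Archaea", "Eukaryota", "Viruses"}
        )
        assert excluded.counts == {}
        assert selected.total() == pytest.approx(12.0)

    def test_no_superkingdom_is_conservatively_excluded(self):
        tree = make_tree({42: (1, "species")})
        selected, excluded = filter_domains(CountTable(counts={42: 1.0}), tree, {"Bacteria"})
        assert excluded.counts == {42: 1.0}

    def test_empty_domain_set_rejected(self, tree):
        with pytest.raises(ConfigurationError):
            filter_domains(CountTable(), tree, set())


class TestScaleCounts:
    def test_scale_factor_applied_uniformly(self):
        table = CountTable(counts={1: 600.0, 2: 400.0})
        out = scale_counts(table, 1500)
        assert out.counts == pytest.approx({1: 900.0, 2: 600.0})
        assert out.total() == pytest.approx(1500.0)

    def test_identity_when_target_equals_total(self):
        table = CountTable(counts={1: 6.0, 2: 2.0})
        assert scale_counts(table, 8).counts == pytest.approx(table.counts)

    def test_downscaling(self):
        out = scale_counts(CountTable(counts={1: 6.0, 2: 2.0}), 4)
        assert out.counts == pytest.approx({1: 3.0, 2: 1.0})

    def test_zero_total_rejected(self):
        with pytest.raises(ConfigurationError):
            scale_counts(CountTable(), 100)


class TestIntegerize:
    def catalog_for(self, taxids):
        return make_catalog([(f"GCF_{t}", t, t) for t in taxids])

    def test_equal_remainders_larger_count_wins(self):
        budget = integerize(CountTable(counts={10: 13.5, 11: 4.5}), self.catalog_for([10, 11]))
        assert budget.allocations == {"GCF_10": 14, "GCF_11": 4}

    def test_integer_table_unchanged(self):
        budget = integerize(CountTable(counts={10: 3.0, 11: 7.0}), self.catalog_for([10, 11]))
        assert budget.allocations == {"GCF_10": 3, "GCF_11": 7}

    def test_single_unit_to_largest_remainder(self):
        budget = integerize(
            CountTable(counts={10: 0.4, 11: 0.3, 12: 0.3}), self.catalog_for([10, 11, 12])
        )
        assert budget.allocations == {"GCF_10": 1, "GCF_11": 0, "GCF_12": 0}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(min_value=10, max_value=30),
            st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_apportionment_properties(self, counts):
        budget = integerize(CountTable(counts=counts), self.catalog_for(counts))
        total = sum(counts.values())
        assert budget.total() == round(total)
        for taxid, count in counts.items():
            assert abs(budget.allocations[f"GCF_{taxid}"] - count) < 1.0

    def test_matches_exact_oracle(self):
        counts = {10: 2.25, 11: 0.5, 12: 1.25, 13: 3.0}
        budget = integerize(CountTable(counts=counts), self.catalog_for(counts))
        expected = oracle_largest_remainder({f"GCF_{t}": c for t, c in counts.items()})
        assert budget.allocations == expected


class TestPipelineConservation:
    def random_scenario(self, rng):
        n_species = rng.integers(1, 5)
        tree_spec = {2: (1, "superkingdom"), 100: (2, "genus")}
        catalog_entries = []
        counts = {}
        for i in range(n_species):
            sp = 200 + i
            tree_spec[sp] = (100, "species")
            if rng.random() < 0.5:
                counts[sp] = float(rng.uniform(0, 20))
            n_strains = rng.integers(0, 4)
            for k in range(n_strains):
                t = 1000 + 10 * i + k
                tree_spec[t] = (sp, "strain")
                if rng.random() < 0.7:
                    counts[t] = float(rng.uniform(0, 20))
                if rng.random() < 0.6:
                    catalog_entries.append((f"GCF_{t}", t, sp))
            if rng.random() < 0.2:
                catalog_entries.append((f"GCF_S{sp}", sp, sp))
        return make_tree(tree_spec), make_catalog(catalog_entries), CountTable(counts=counts)

    def test_mass_conserved_through_promotion_and_distribution(self):
        """Promotion and ratio distribution never create or lose mass
        beyond itemized no-reference drops (200 randomized tables)."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            tree, catalog, table = self.random_scenario(rng)
            total_in = table.total()
            promoted = promote_orphan_strains(table, catalog, tree)
            assert promoted.total() == pytest.approx(total_in, abs=1e-9)
            distributed = distribute_species_counts(promoted, catalog, tree)
            assert distributed.total() + distributed.dropped_total() == pytest.approx(
                total_in, abs=1e-9
            )
            if distributed.counts:
                budget = integerize(distributed, catalog, tree)
                assert budget.total() == round(distributed.total())
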