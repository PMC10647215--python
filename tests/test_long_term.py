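import itertools

import numpy as np
import pytest

import driversel as d
from driversel.io_formats import ValidationError
from driversel.long_term import MappingError
from tests.conftest import make_records


def exhaustive_parsimony(column, tree):
    """Independent oracle: minimum substitutions over all internal labelings."""
    nodes = list(tree.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    observed = sorted({r for r in column.values() if r not in d.long_term.GAP_CHARS})
    alphabet = observed or ["A"]
    best = None
    for labels in itertools.product(alphabet, repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), labels))
        cost = 0
        feasible = True
        for n in nodes:
            if n.parent_node is None:
                continue
            parent_state = assign[id(n.parent_node)]
            if n.is_leaf():
                res = column.get(n.taxon.label)
                if res is None or res in d.long_term.GAP_CHARS:
                    continue  # wildcard leaf matches anything
                child_state = res
            else:
                child_state = assign[id(n)]
            if child_state != parent_state:
                cost += 1
        if feasible and (best is None or cost < best):
            best = cost
    return best


class TestProjection:
    def test_reference_gaps_are_dropped_with_position_map(self):
        msa = d.SpeciesAlignment(
            sequences={"ref": "M-KT", "sp2": "MAKT"}, reference_species="ref"
        )
        proj = d.project_to_reference(msa)
        assert proj.sequences["ref"] == "MKT"
        assert proj.column_map == [0, 2, 3]

    def test_gapless_reference_is_identity(self):
        msa = d.SpeciesAlignment(sequences={"ref": "MKT", "sp2": "MRT"}, reference_species="ref")
        proj = d.project_to_reference(msa)
        assert proj.sequences == msa.sequences
        assert proj.column_map == [0, 1, 2]

    def test_all_gap_reference_rejected(self):
        msa = d.SpeciesAlignment(sequences={"ref": "---", "sp2": "MKT"}, reference_species="ref")
        with pytest.raises(ValidationError):
            d.project_to_reference(msa)


class TestFitch:
    def test_invariant_column_needs_no_substitution(self, balanced_quartet_tree):
        col = {f"s{i}": "A" for i in range(1, 5)}
        assert d.fitch_site_substitutions(col, balanced_quartet_tree) == 0

    def test_clade_concordant_column_costs_one(self, balanced_quartet_tree):
        col = {"s1": "A", "s2": "A", "s3": "G", "s4": "G"}
        assert d.fitch_site_substitutions(col, balanced_quartet_tree) == 1

    def test_clade_discordant_column_costs_two(self, balanced_quartet_tree):
        col = {"s1": "A", "s2": "G", "s3": "A", "s4": "G"}
        assert d.fitch_site_substitutions(col, balanced_quartet_tree) == 2

    def test_unknown_species_raises(self, balanced_quartet_tree):
        with pytest.raises(MappingError):
            d.fitch_site_substitutions({"sX": "A"}, balanced_quartet_tree)

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(20):
            n_leaves = int(rng.integers(3, 7))
            _, tree = d.gen_toy_phylo(n_leaves, 1.0, np.ones(1), rng)
            for _ in range(5):
                k = int(rng.integers(1, 5))
                col = {
                    f"sp{i + 1}": str(rng.choice(list("ACGT")[:k]))
                    for i in range(n_leaves)
                }
                if rng.random() < 0.3:  # sprinkle missing data
                    col[f"sp{int(rng.integers(1, n_leaves + 1))}"] = "-"
                assert d.fitch_site_substitutions(col, tree) == exhaustive_parsimony(col, tree)
                checked += 1
        assert checked == 100

    def test_count_is_rooting_invariant(self):
        rng = np.random.default_rng(7)
        _, tree = d.gen_toy_phylo(6, 1.0, np.ones(1), rng)
        col = {f"sp{i + 1}": str(rng.choice(list("ACG"))) for i in range(6)}
        base = d.fitch_site_substitutions(col, tree)
        for leaf in list(tree.tree.leaf_node_iter())[:3]:
            clone = tree.tree.clone(depth=1)
            target = [l for l in clone.leaf_node_iter() if l.taxon.label == leaf.taxon.label][0]
            clone.reroot_at_edge(target.edge, update_bipartitions=False)
            assert d.fitch_site_substitutions(col, d.PhyloTree(clone)) == base


class TestSiteRate:
    def test_rate_is_count_over_total_length(self, balanced_quartet_tree):
        assert balanced_quartet_tree.total_branch_length == pytest.approx(5.0)
        assert d.site_rate(2, balanced_quartet_tree) == pytest.approx(0.4)
        assert d.site_rate(0, balanced_quartet_tree) == 0.0

    def test_rate_scales_inversely_with_branch_lengths(self, balanced_quartet_tree):
        doubled = balanced_quartet_tree.scaled(2.0)
        assert d.site_rate(3, doubled) == pytest.approx(d.site_rate(3, balanced_quartet_tree) / 2)

    def test_zero_length_tree_rejected(self):
        tree = d.PhyloTree.from_newick("(s1:0.0,s2:0.0);")
        with pytest.raises(ValidationError):
            d.site_rate(1, tree)


class TestGeneRateFeatures:
    def test_mean_over_distinct_positions_and_summit_rate(self):
        rates = {1: 0.2, 5: 0.8}
        muts = make_records("G", [(1, "missense", 3), (5, "missense", 1)])
        rf = d.gene_rate_features(rates, muts)
        assert rf.e_gene == pytest.approx(0.5)
        assert rf.e_summit == pytest.approx(0.2)  # position 1 carries most mutations
        assert not rf.imputed

    def test_single_position_makes_features_equal(self):
        rf = d.gene_rate_features({3: 0.7}, make_records("G", [(3, "missense", 2)]))
        assert rf.e_gene == rf.e_summit == pytest.approx(0.7)

    def test_summit_tie_breaks_to_lowest_position(self):
        rates = {2: 0.1, 7: 0.9}
        muts = make_records("G", [(2, "missense", 2), (7, "nonsense", 2)])
        assert d.gene_rate_features(rates, muts).e_summit == pytest.approx(0.1)

    def test_no_coverage_imputes_with_warning(self):
        rf = d.gene_rate_features({}, make_records("G", [(4, "missense")]), impute_value=0.33)
        assert rf == (0.33, 0.33, True)

    def test_e_gene_bounded_by_site_rates(self):
        rng = np.random.default_rng(3)
        rates = {p: float(rng.uniform(0, 2)) for p in range(1, 30)}
        muts = make_records("G", [(int(p), "missense") for p in rng.integers(1, 30, size=10)])
        rf = d.gene_rate_features(rates, muts)
        used = [rates[r.protein_pos] for r in muts]
        assert min(used) <= rf.e_gene <= max(used)


class TestSimulatedColumns:
    def test_zero_rate_columns_are_invariant(self):
        rng = np.random.default_rng(0)
        aln, tree = d.gen_toy_phylo(5, 2.0, np.zeros(10), rng)
        rates = d.compute_site_rates(aln, tree)
        assert all(r == 0.0 for r in rates.values())

    def test_fast_columns_accumulate_more_substitutions(self):
        rng = np.random.default_rng(1)
        profile = np.concatenate([np.full(150, 0.2), np.full(150, 3.0)])
        aln, tree = d.gen_toy_phylo(6, 2.0, profile, rng)
        rates = d.compute_site_rates(aln, tree)
        slow = np.mean([rates[p] for p in range(1, 151)])
        fast = np.mean([rates[p] for p in range(151, 301)])
        assert fast > slow
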