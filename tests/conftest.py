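import numpy as np
import pytest

import driversel as d


def make_records(gene, spec, sample="s0"):
    """spec: list of (protein_pos, consequence[, count])."""
    out = []
    for item in spec:
        pos, cons, *rest = item
        for _ in range(rest[0] if rest else 1):
            out.append(d.MutationRecord(gene=gene, sample=sample, protein_pos=pos, consequence=cons))
    return out


@pytest.fixture(scope="session")
def small_domain():
    """A small but complete source/target scenario with a trained forest.

    Session-scoped: several structural tests reuse it.  Sizes are reduced
    from the default scenario to keep the unit suite fast; the full-size
    conditions are exercised by the acceptance tests.
    """
    scenario = d.SyntheticScenario(seed=11, n_source_per_class=60, n_target_per_class=25)
    tables = d.gen_domain_tables(scenario)
    X = d.feature_array(tables.source_features)
    y = np.array([d.CLASSES.index(c) for c in tables.source_features["label"]])
    params = d.StandardizationParams.fit(X)
    forest = d.train_forest(params.transform(X), y, d.TrainConfig(n_trees=50, seed=11))
    forest.standardization = params
    return {
        "scenario": scenario,
        "tables": tables,
        "X": X,
        "y": y,
        "params": params,
        "forest": forest,
        "targets": d.standardize(tables.target_features, params),
    }


@pytest.fixture
def balanced_quartet_tree():
    return d.PhyloTree.from_newick("((s1:1.0,s2:1.0):0.5,(s3:1.0,s4:1.0):0.5);")
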