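import numpy as np
import pytest

import qphylo as q


def edge_mutation_map(tree, retained=None):
    """Bipartition -> mutation set in the unrooted sense: the two edges
    adjacent to the root describe the same unrooted edge and are merged, so
    the map is invariant to where the tree is rooted."""
    all_leaves = frozenset(tree.leaf_labels())
    anchor = min(all_leaves)
    below = {}
    for n in tree.postorder():
        below[id(n)] = (
            frozenset([n.label])
            if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    out = {}
    for n in tree.postorder():
        if n.parent is None:
            continue
        side = below[id(n)]
        if anchor in side:
            side = all_leaves - side
        muts = set(n.mutations)
        if retained is not None:
            muts &= retained
        out.setdefault(side, set()).update(muts)
    return {k: v for k, v in out.items() if v}


def make_noiseless_dataset(n_tips=8, seed=3, region_length=200_000,
                           mutation_rate=5e-8, mode="yule"):
    """Full-coverage, zero-error simulation: truth tree, reference,
    observations, and the filtered matrix."""
    cfg = q.SimulationConfig(
        n_tips=n_tips,
        tmrca_years=15_100,
        region_length=region_length,
        mutation_rate=mutation_rate,
        platform_profiles=(
            q.PlatformProfile(
                name="full", intervals=((0, region_length),), depth_min=2,
                base_quality=(40.0, 2.0), mapping_quality=(55.0, 2.0),
            ),
        ),
        seed=seed,
    )
    truth = q.drop_mutations(q.simulate_genealogy(cfg, mode=mode), cfg)
    ref = q.simulate_reference(cfg.region_length, seed=seed)
    obs = q.simulate_observations(truth, ref, cfg)
    matrix = q.build_matrix(obs, ref, q.FilterConfig())
    return cfg, truth, ref, obs, matrix


@pytest.fixture(scope="session")
def noiseless8():
    return make_noiseless_dataset(n_tips=8, seed=3)


@pytest.fixture
def star_annotated():
    """Three-tip star genealogy with 2, 3, 4 mutations on the pendant
    branches — the worked example for rho arithmetic."""
    cfg = q.SimulationConfig(n_tips=3, tmrca_years=15_100, seed=1)
    tree = q.simulate_genealogy(cfg, mode="star")
    for tip, muts in zip(tree.leaves(), ([0, 1], [2, 3, 4], [5, 6, 7, 8])):
        tip.mutations = list(muts)
    return tree


def random_matrix(rng, n_samples, n_sites, missing_rate=0.1):
    labels = [f"s{i}" for i in range(n_samples)]
    probs = [(1 - missing_rate) / 4] * 4 + [missing_rate]
    alleles = rng.choice(list("ACGTN"), size=(n_samples, n_sites), p=probs)
    return q.VariantMatrix(
        samples=labels,
        positions=np.arange(n_sites),
        alleles=alleles.astype("<U1"),
        ancestral=np.array(["A"] * n_sites, dtype="<U1"),
        region_length=n_sites * 100,
    )
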