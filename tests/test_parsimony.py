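import itertools

import numpy as np
import pytest

import qphylo as q
from qphylo.parsimony import _all_topologies
from qphylo.tree import Tree

from conftest import edge_mutation_map, make_noiseless_dataset, random_matrix


def matrix_from_columns(samples, columns, ancestral=None):
    if columns:
        alleles = np.array(columns, dtype="<U1").T
    else:
        alleles = np.empty((len(samples), 0), dtype="<U1")
    n_pos = alleles.shape[1]
    return q.VariantMatrix(
        samples=list(samples),
        positions=np.arange(n_pos),
        alleles=alleles,
        ancestral=np.array(ancestral or ["A"] * n_pos, dtype="<U1"),
        region_length=n_pos * 10,
    )


def brute_force_parsimony(tree, matrix):
    """Independent oracle: enumerate every labeling of internal nodes (and of
    missing-data leaves) and take the minimal change count per site."""
    nodes = list(tree.postorder())
    total = 0
    for j in range(matrix.n_positions):
        col = {s: matrix.alleles[i, j] for i, s in enumerate(matrix.samples)}
        free = [n for n in nodes if (not n.is_leaf) or col[n.label] == q.MISSING]
        fixed = {
            id(n): col[n.label]
            for n in nodes
            if n.is_leaf and col[n.label] != q.MISSING
        }
        best = None
        for assign in itertools.product("ACGT", repeat=len(free)):
            st = dict(fixed)
            st.update({id(n): a for n, a in zip(free, assign)})
            cost = sum(
                1
                for n in nodes
                if n.parent is not None and st[id(n)] != st[id(n.parent)]
            )
            best = cost if best is None else min(best, cost)
        total += best
    return total


QUARTET = "((s0,s1),(s2,s3));"


@pytest.mark.parametrize(
    "column,expected",
    [
        (list("AAGG"), 1),   # single clean split character
        (list("AGAG"), 2),   # conflicting character: two changes
        (list("ANGG"), 1),   # missing data never forces a change
        (list("AAAA"), 0),   # constant
    ],
)
def test_fitch_score_quartet_examples(column, expected):
    tree = Tree.from_newick(QUARTET)
    matrix = matrix_from_columns(["s0", "s1", "s2", "s3"], [column])
    assert q.fitch_score(tree, matrix) == expected


def test_fitch_score_missing_leaf_raises():
    tree = Tree.from_newick("((s0,s1),(s2,zzz));")
    matrix = matrix_from_columns(["s0", "s1", "s2", "s3"], [list("AAGG")])
    with pytest.raises(ValueError):
        q.fitch_score(tree, matrix)


def test_fitch_matches_brute_force_on_random_characters():
    """Hartigan scoring equals exhaustive internal-labeling minimisation on
    random characters with missing data, across tree shapes up to 7 taxa."""
    rng = np.random.default_rng(7)
    for n in (4, 5, 6, 7):
        labels = [f"s{i}" for i in range(n)]
        topos = list(_all_topologies(labels[:5])) if n == 5 else None
        for rep in range(3):
            cfg = q.SimulationConfig(n_tips=n, seed=int(rng.integers(2**31)))
            tree = q.simulate_genealogy(cfg, mode="yule")
            tree_labels = tree.leaf_labels()
            matrix = random_matrix(rng, n, 12, missing_rate=0.15)
            matrix.samples = tree_labels
            assert q.fitch_score(tree, matrix) == brute_force_parsimony(tree, matrix)


def test_fitch_score_invariant_under_leaf_and_site_permutation():
    rng = np.random.default_rng(8)
    matrix = random_matrix(rng, 6, 20)
    cfg = q.SimulationConfig(n_tips=6, seed=3)
    tree = q.simulate_genealogy(cfg, mode="yule")
    matrix.samples = tree.leaf_labels()
    score = q.fitch_score(tree, matrix)
    perm = rng.permutation(20)
    shuffled_sites = q.VariantMatrix(
        samples=matrix.samples,
        positions=matrix.positions[perm],
        alleles=matrix.alleles[:, perm],
        ancestral=matrix.ancestral[perm],
        region_length=matrix.region_length,
    )
    assert q.fitch_score(tree, shuffled_sites) == score
    rows = rng.permutation(6)
    shuffled_samples = q.VariantMatrix(
        samples=[matrix.samples[i] for i in rows],
        positions=matrix.positions,
        alleles=matrix.alleles[rows],
        ancestral=matrix.ancestral,
        region_length=matrix.region_length,
    )
    assert q.fitch_score(tree, shuffled_samples) == score


def test_exact_search_recovers_supported_quartet():
    samples = ["s0", "s1", "s2", "s3"]
    columns = [list("AAGG")] * 10
    matrix = matrix_from_columns(samples, columns)
    trees = q.mp_search(matrix, mode="exact")
    assert len(trees) == 1
    assert trees[0].bipartitions() == {frozenset({"s2", "s3"})}


def test_zero_variable_sites_flags_unresolved():
    samples = ["s0", "s1", "s2", "s3"]
    matrix = matrix_from_columns(samples, [])
    trees = q.mp_search(matrix, mode="exact")
    assert q.mp_search.last_report["unresolved"]
    assert len(trees) == 3  # all quartets co-optimal


def test_exact_mode_refuses_large_matrices():
    rng = np.random.default_rng(0)
    matrix = random_matrix(rng, 12, 5)
    with pytest.raises(ValueError):
        q.mp_search(matrix, mode="exact")


def test_heuristic_matches_exact_optimum_on_random_matrices():
    """Stepwise addition + NNI with restarts attains the exhaustively
    verified optimum on random 7-taxon matrices."""
    rng = np.random.default_rng(9)
    for rep in range(10):
        matrix = random_matrix(rng, 7, 15, missing_rate=0.1)
        q.mp_search(matrix, mode="exact")
        exact_score = q.mp_search.last_report["score"]
        q.mp_search(matrix, mode="heuristic", seed=rep, n_restarts=10)
        assert q.mp_search.last_report["score"] == exact_score


def test_homoplasy_counting():
    tree = Tree.from_newick(QUARTET)
    samples = ["s0", "s1", "s2", "s3"]
    # clean split site + convergent site
    matrix = matrix_from_columns(samples, [list("AAGG"), list("AGAG")])
    assert q.homoplasy_count(tree, matrix) == 1


def test_homoplasy_zero_on_clean_simulation(noiseless8):
    cfg, truth, ref, obs, matrix = noiseless8
    assert q.homoplasy_count(truth, matrix) == 0


def test_forced_recurrent_mutations_counted_on_true_tree():
    """Columns made homoplastic by construction are counted exactly."""
    cfg = q.SimulationConfig(n_tips=8, tmrca_years=15_100, seed=21,
                             region_length=50_000, mutation_rate=2e-7)
    truth = q.drop_mutations(q.simulate_genealogy(cfg, mode="yule"), cfg)
    ref = q.simulate_reference(cfg.region_length, seed=21)
    obs = q.simulate_observations(truth, ref, cfg)
    matrix = q.build_matrix(obs, ref, q.FilterConfig(entropy_min=0.0))
    assert q.homoplasy_count(truth, matrix) == 0
    # flip one sample's allele at k sites to fabricate parallel changes on
    # tips that are not sisters of the existing carrier
    k = 3
    flipped = 0
    alleles = matrix.alleles.copy()
    for j in range(matrix.n_positions):
        if flipped == k:
            break
        col = alleles[:, j]
        carriers = np.nonzero(col != matrix.ancestral[j])[0]
        if len(carriers) != 1:
            continue
        other = (carriers[0] + 4) % matrix.n_samples
        col[other] = col[carriers[0]]
        flipped += 1
    noisy = q.VariantMatrix(
        samples=matrix.samples, positions=matrix.positions, alleles=alleles,
        ancestral=matrix.ancestral, region_length=matrix.region_length,
    )
    assert q.homoplasy_count(truth, noisy) >= k - 1  # sisters can be lucky
    assert q.homoplasy_count(truth, noisy) <= k


def test_mutation_mapping_recovers_truth_per_edge(noiseless8):
    cfg, truth, ref, obs, matrix = noiseless8
    best = q.mp_search(matrix, seed=0, n_restarts=5)[0]
    outgroup = truth.leaf_labels()[0]
    annotated = q.map_mutations(best.reroot_on_outgroup(outgroup), matrix)
    retained = set(int(p) for p in matrix.positions)
    assert edge_mutation_map(annotated) == edge_mutation_map(truth, retained)


def test_mapped_changes_sum_to_fitch_score(noiseless8):
    cfg, truth, ref, obs, matrix = noiseless8
    best = q.mp_search(matrix, seed=0, n_restarts=5)[0]
    annotated = q.map_mutations(best, matrix)
    total = sum(len(n.mutations) for n in annotated.postorder())
    assert total == q.fitch_score(best, matrix)


def test_constant_site_assigned_to_no_branch():
    tree = Tree.from_newick(QUARTET)
    samples = ["s0", "s1", "s2", "s3"]
    matrix = matrix_from_columns(samples, [list("AAAA"), list("AAGG")],
                                 ancestral=["A", "A"])
    annotated = q.map_mutations(tree, matrix)
    mapped = {p for n in annotated.postorder() for p in n.mutations}
    assert 0 not in mapped and 1 in mapped


def test_root_leaf_distances_star_example(star_annotated):
    counts, mean, sd = q.root_leaf_distances(star_annotated)
    assert sorted(counts.values()) == [2, 3, 4]
    assert mean == pytest.approx(3.0)
    assert sd == pytest.approx(1.0)


def test_root_leaf_sd_zero_when_counts_equal():
    cfg = q.SimulationConfig(n_tips=4, seed=0)
    tree = q.simulate_genealogy(cfg, mode="star")
    for tip in tree.leaves():
        tip.mutations = [1, 2, 3]
    _, mean, sd = q.root_leaf_distances(tree)
    assert (mean, sd) == (3.0, 0.0)


def test_clocklike_simulation_has_low_root_leaf_dispersion():
    """With equal truth ages, root-leaf mutation counts are Poisson with a
    common mean, so the coefficient of variation stays small once the
    expected count is large (>= 50)."""
    ratios = []
    for seed in range(30):
        cfg = q.SimulationConfig(n_tips=12, tmrca_years=15_100,
                                 region_length=9_340_000,
                                 mutation_rate=0.78e-9, seed=seed)
        truth = q.drop_mutations(q.simulate_genealogy(cfg, mode="yule"), cfg)
        counts, mean, sd = q.root_leaf_distances(truth)
        assert mean >= 50
        ratios.append(sd / mean)
    assert np.mean(ratios) < 0.15


def test_bootstrap_support_high_for_clean_splits_and_deterministic():
    samples = [f"s{i}" for i in range(6)]
    split_ab = ["A", "A", "G", "G", "G", "G"]
    split_cd = ["C", "C", "A", "A", "C", "C"]
    columns = [split_ab] * 20 + [split_cd] * 20
    matrix = matrix_from_columns(samples, columns)
    best = q.mp_search(matrix, seed=0, n_restarts=5)[0]
    sup1 = q.bootstrap_support(matrix, n_reps=50, seed=1, reference_tree=best)
    sup2 = q.bootstrap_support(matrix, n_reps=50, seed=1, reference_tree=best)
    assert sup1 == sup2
    assert sup1[frozenset({"s2", "s3"})] > 90.0


def test_bootstrap_flags_unsupported_branches():
    """A branch present in the best tree but defined by no site gets weak
    support, below the 50% reporting threshold."""
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(6)]
    # signal for {s0,s1} only; everything else unresolved
    columns = [["A", "A", "G", "G", "G", "G"]] * 10
    matrix = matrix_from_columns(samples, columns)
    best = q.mp_search(matrix, seed=2, n_restarts=3)[0]
    support = q.bootstrap_support(matrix, n_reps=50, seed=3, reference_tree=best)
    strong = frozenset(
        s for s in best.bipartitions() if s in ({frozenset({"s0", "s1"})} | {frozenset({"s2","s3","s4","s5"})})
    )
    for split, value in support.items():
        if split not in strong and len(split) < 5:
            assert value < 50.0
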