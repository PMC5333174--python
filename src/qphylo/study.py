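"""A study-design-scale synthetic dataset: a dated haplogroup genealogy with
named clades, platform-heterogeneous sequencing, and a platform-consistent
dating subset.

This module wires the generators into the design of a full-Y phylogeography
analysis of a rare haplogroup: 47 carriers plus one outgroup, five principal
branches (Q3a..Q3e-style) arising in the early Holocene from an Upper
Paleolithic root, a young expanding subclade (Q3a1-style), 30 samples
sequenced on one deep platform (BigY-like, used for dating) and the rest on
a mix of longer- and shorter-range platforms.  Every age is simulation truth,
so the pipeline's age estimates can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import PlatformProfile, SimulationConfig
from .tree import Node, Tree

__all__ = ["StudyDesign", "study_genealogy", "study_config", "run_study"]

# named clade ages (years) of the demo genealogy; root = haplogroup TMRCA
CLADE_AGES = {
    "Q3": 15_100.0,
    "Q3e": 6_900.0,
    "Q3ad": 7_400.0,
    "Q3ac": 6_900.0,
    "Q3b": 5_100.0,
    "Q3a": 4_100.0,
    "Q3a6": 4_000.0,
    "Q3a15": 3_900.0,
    "Q3a5": 2_500.0,
    "Q3a1": 1_600.0,
    "Q3a1a": 1_170.0,
    "Q3a1b": 1_500.0,
}


@dataclass
class StudyDesign:
    tree: Tree
    config: SimulationConfig
    platform_map: dict[str, str]
    dating_subset: list[str]
    outgroup: str
    clade_ages: dict[str, float]


def _star(parent: Node, prefix: str, k: int) -> list[str]:
    labels = []
    for i in range(k):
        label = f"{prefix}_{i:02d}"
        parent.add_child(Node(label, 0.0))
        labels.append(label)
    return labels


def study_genealogy() -> Tree:
    """Dated genealogy with the named clade structure above (48 tips: 47
    ingroup + 1 outgroup). Within-clade structure is star-like, so each named
    clade's TMRCA equals its listed age."""
    a = CLADE_AGES
    root = Node("rootQ", 30_000.0)
    root.add_child(Node("Q1_outgroup", 0.0))
    q3 = root.add_child(Node("Q3", a["Q3"]))

    q3e = q3.add_child(Node("Q3e", a["Q3e"]))
    _star(q3e, "q3e", 9)

    q3ad = q3.add_child(Node("Q3ad", a["Q3ad"]))
    q3ad.add_child(Node("q3d_00", 0.0))  # singleton branch
    q3ac = q3ad.add_child(Node("Q3ac", a["Q3ac"]))
    q3ac.add_child(Node("q3c_00", 0.0))  # singleton branch

    q3b = q3ac.add_child(Node("Q3b", a["Q3b"]))
    _star(q3b, "q3b", 7)

    q3a = q3ac.add_child(Node("Q3a", a["Q3a"]))
    q3a.add_child(Node("q3a7_00", 0.0))
    q3a6 = q3a.add_child(Node("Q3a6", a["Q3a6"]))
    _star(q3a6, "q3a6", 6)

    q3a15 = q3a.add_child(Node("Q3a15", a["Q3a15"]))
    q3a15.add_child(Node("q3a3_00", 0.0))
    q3a15.add_child(Node("q3a4_00", 0.0))
    q3a5 = q3a15.add_child(Node("Q3a5", a["Q3a5"]))
    _star(q3a5, "q3a5", 4)

    q3a1 = q3a15.add_child(Node("Q3a1", a["Q3a1"]))
    q3a1a = q3a1.add_child(Node("Q3a1a", a["Q3a1a"]))
    _star(q3a1a, "q3a1a", 8)
    q3a1b = q3a1.add_child(Node("Q3a1b", a["Q3a1b"]))
    _star(q3a1b, "q3a1b", 8)

    tree = Tree(root)
    tree.validate()
    assert len(tree.leaves()) == 48
    return tree


def study_config(seed: int = 0, region_length: int = 9_340_000) -> StudyDesign:
    """Assemble the full study design around :func:`study_genealogy`.

    Platforms: "bigy" covers the whole analysable region at depth ~60 and is
    used by 30 ingroup samples plus the outgroup; "long" covers ~1.5x the
    bigy range (here the same region, deeper is not needed); "short" covers
    only the central ~70%. The dating subset is the 30 bigy ingroup samples.
    """
    L = region_length
    profiles = (
        PlatformProfile(
            name="bigy", intervals=((0, L),), depth_mean=60.0,
            depth_dispersion=8.0, depth_min=2,
            base_quality=(35.0, 3.0), mapping_quality=(55.0, 4.0),
        ),
        PlatformProfile(
            name="long", intervals=((0, L),), depth_mean=30.0,
            depth_dispersion=5.0, depth_min=2,
            base_quality=(33.0, 3.0), mapping_quality=(52.0, 4.0),
        ),
        PlatformProfile(
            name="short", intervals=((int(0.15 * L), int(0.85 * L)),),
            depth_mean=15.0, depth_dispersion=4.0, depth_min=2,
            base_quality=(30.0, 4.0), mapping_quality=(50.0, 5.0),
        ),
    )
    tree = study_genealogy()
    tips = [t for t in tree.leaf_labels() if t != "Q1_outgroup"]
    # 30 bigy samples spread so every major clade keeps >= 2 of them;
    # the remaining 17 split between longer- and shorter-range platforms
    quota = {"q3a1a": 8, "q3a1b": 8, "q3a5": 4, "q3a6": 4, "q3b": 4, "q3e": 2}
    bigy = []
    for prefix, k in quota.items():
        bigy += sorted(t for t in tips if t.startswith(prefix + "_"))[:k]
    assert len(bigy) == 30
    platform_map = {}
    rest = [t for t in tips if t not in bigy]
    for i, t in enumerate(rest):
        platform_map[t] = "long" if i % 2 == 0 else "short"
    for t in bigy:
        platform_map[t] = "bigy"
    platform_map["Q1_outgroup"] = "bigy"

    config = SimulationConfig(
        n_tips=48,
        tmrca_years=CLADE_AGES["Q3"],
        region_length=L,
        mutation_rate=0.78e-9,
        platform_profiles=profiles,
        base_error_rate=0.002,
        seed=seed,
    )
    return StudyDesign(
        tree=tree,
        config=config,
        platform_map=platform_map,
        dating_subset=sorted(bigy),
        outgroup="Q1_outgroup",
        clade_ages=dict(CLADE_AGES),
    )


def run_study(
    seed: int = 0,
    *,
    n_restarts: int = 2,
    use_mask: bool = False,
    region_length: int = 9_340_000,
) -> dict:
    """Simulate one study-scale dataset and run the full analysis chain:
    filter -> parsimony search -> outgroup rooting -> mutation mapping ->
    clock check -> subset rho dating. Returns the summary statistics.

    ``use_mask`` enables dimeric-entropy masking of the megabase reference
    (a few extra seconds per replicate; the background carries no embedded
    tracts, so it mainly exercises the code path).
    """
    from . import (
        FilterConfig,
        build_matrix,
        date_all_clades,
        drop_mutations,
        map_mutations,
        mp_search,
        root_leaf_distances,
        simulate_observations,
        simulate_reference,
    )
    from .dating import MU_DEFAULT

    design = study_config(seed=seed, region_length=region_length)
    truth = drop_mutations(design.tree, design.config)
    ref = simulate_reference(region_length, design.config.str_tracts, seed)
    obs = simulate_observations(truth, ref, design.config, design.platform_map)
    matrix = build_matrix(obs, ref if use_mask else None, FilterConfig())
    if not use_mask:
        # ancestral states still come from the reference
        import numpy as np

        matrix.ancestral = np.array(
            [str(ref)[int(p)] for p in matrix.positions], dtype="<U1"
        )
        matrix.region_length = region_length

    # NNI-only hill-climbing: at this matrix size the signal is strong enough
    # that stepwise addition + NNI recovers every supported split, and the
    # O(n^2) SPR sweep would dominate the runtime
    best = mp_search(
        matrix, mode="heuristic", seed=seed, n_restarts=n_restarts, spr=False
    )[0]
    truth_splits = truth.bipartitions()
    missing = truth_splits - best.bipartitions()
    # a missing split is only a reconstruction failure if some retained site
    # actually supports it; short stems can receive zero mutations and are
    # then unresolvable from the data
    supported_missing = 0
    all_tips = frozenset(matrix.samples)
    import numpy as np

    carrier_sets = set()
    for j in range(matrix.n_positions):
        col = matrix.alleles[:, j]
        carriers = frozenset(
            s for s, a in zip(matrix.samples, col)
            if a != "N" and a != matrix.ancestral[j]
        )
        carrier_sets.add(carriers)
        carrier_sets.add(all_tips - carriers)
    for split in missing:
        if split in carrier_sets or (all_tips - split) in carrier_sets:
            supported_missing += 1

    rooted = best.reroot_on_outgroup(design.outgroup)
    annotated = map_mutations(rooted, matrix)
    ingroup = annotated.prune_to(
        [t for t in annotated.leaf_labels() if t != design.outgroup]
    )
    _, rl_mean, rl_sd = root_leaf_distances(ingroup)

    clades = {
        "Q3": {t for t in design.tree.leaf_labels() if t != design.outgroup},
        "Q3a1": {
            t for t in design.tree.leaf_labels() if t.startswith("q3a1")
        },
    }
    table = date_all_clades(
        annotated,
        subset=design.dating_subset,
        mu=MU_DEFAULT,
        length_bp=matrix.region_length,
        clades=clades,
    )
    by_clade = table.set_index("clade")
    return {
        "n_variable_positions": matrix.n_positions,
        "region_length": matrix.region_length,
        "missing_truth_splits": len(missing),
        "missed_supported_splits": supported_missing,
        "root_leaf_mean": rl_mean,
        "root_leaf_sd": rl_sd,
        "q3_rho": float(by_clade.loc["Q3", "rho"]),
        "q3_age": float(by_clade.loc["Q3", "age_years"]),
        "q3_age_se": float(by_clade.loc["Q3", "age_se_years"]),
        "q3a1_age": float(by_clade.loc["Q3a1", "age_years"]),
        "q3a1_age_se": float(by_clade.loc["Q3a1", "age_se_years"]),
        "truth": design.clade_ages,
    }
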