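"""Maximum-parsimony tree reconstruction and phylogenetic quality control.

Parsimony lengths are computed with Hartigan's generalisation of the Fitch
algorithm (exact for multifurcating trees, identical to Fitch on binary
trees), with missing data treated as the full state set so it never forces a
change. The search enumerates all unrooted topologies exactly for small
matrices and uses random-order stepwise addition plus NNI hill-climbing with
restarts otherwise. Trees are searched unrooted and rooted afterwards on a
declared outgroup.

Quality control mirrors how a haploid SNP alignment of mixed provenance is
judged: the spread (mean pairwise Robinson-Foulds distance) of co-optimal
trees, the number of characters with parallel or recurrent changes
(homoplasies, an error signal for unique-event Y-SNPs), the variation of
root-to-leaf mutation counts (clock-likeness), and site-resampling
(parsimony bootstrap) supports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .filtering import MISSING, VariantMatrix
from .tree import Node, Tree, rf_distance

__all__ = [
    "fitch_score",
    "mp_search",
    "homoplasy_count",
    "map_mutations",
    "root_leaf_distances",
    "bootstrap_support",
    "QCReport",
    "qc_report",
    "rf_distance",
]

_STATE_BITS = (1, 2, 4, 8)
_BIT_TO_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}
_BASE_TO_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, MISSING: 15}

EXACT_LIMIT_DEFAULT = 9


# --------------------------------------------------------------------------- #
# encoding


def _leaf_masks(matrix: VariantMatrix) -> dict[str, np.ndarray]:
    bits = matrix.to_bitmask()
    return {s: bits[i] for i, s in enumerate(matrix.samples)}


def _hartigan_up(tree: Tree, masks: dict[str, np.ndarray]):
    """Upward pass: per-node state-set bitmasks and total changes per site.

    Returns (sets: dict id(node)->mask array, changes: per-site int array).
    """
    n_sites = next(iter(masks.values())).size if masks else 0
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(n_sites, dtype=np.int32)
    for node in tree.postorder():
        if node.is_leaf:
            try:
                sets[id(node)] = masks[node.label]
            except KeyError:
                raise ValueError(f"leaf {node.label!r} absent from matrix") from None
            continue
        child_masks = np.stack([sets[id(c)] for c in node.children])
        c = child_masks.shape[0]
        k = np.stack([(child_masks & b).astype(bool).sum(axis=0) for b in _STATE_BITS])
        kmax = k.max(axis=0)
        node_mask = np.zeros(n_sites, dtype=np.uint8)
        for bi, b in enumerate(_STATE_BITS):
            node_mask |= np.where(k[bi] == kmax, b, 0).astype(np.uint8)
        sets[id(node)] = node_mask
        changes += c - kmax
    return sets, changes


def fitch_score(
    tree: Tree, matrix: VariantMatrix, per_site: bool = False
) -> int | np.ndarray:
    """Minimum number of state changes the tree requires for the matrix.

    MISSING leaves carry the full state set {A,C,G,T} and never force a
    change. ``per_site=True`` returns the per-site change counts.
    """
    masks = _leaf_masks(matrix)
    _, changes = _hartigan_up(tree, masks)
    return changes if per_site else int(changes.sum())


def _score_masks(tree: Tree, masks: dict[str, np.ndarray]) -> int:
    _, changes = _hartigan_up(tree, masks)
    return int(changes.sum())


# --------------------------------------------------------------------------- #
# topology enumeration and search


def _all_topologies(labels: list[str]):
    """Yield all unrooted topologies over ``labels`` as Trees rooted at an
    arbitrary internal vertex (the scoring is rooting-invariant)."""
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    def build(current: Tree, remaining: list[str]):
        if not remaining:
            yield current
            return
        label = remaining[0]
        # insert the new leaf into every branch of the current tree
        nodes = [n for n in current.postorder() if n.parent is not None]
        for target_idx in range(len(nodes)):
            dup = current.copy()
            dup_nodes = [n for n in dup.postorder() if n.parent is not None]
            target = dup_nodes[target_idx]
            parent = target.parent
            mid = Node(None)
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(Node(label))
            yield from build(dup, remaining[1:])

    base = Node(None)
    for lab in labels[:3]:
        base.add_child(Node(lab))
    yield from build(Tree(base), labels[3:])


def _random_addition_tree(labels: list[str], masks, rng) -> Tree:
    """Greedy stepwise addition in a random taxon order."""
    order = list(labels)
    rng.shuffle(order)
    base = Node(None)
    for lab in order[:3]:
        base.add_child(Node(lab))
    tree = Tree(base)
    for lab in order[3:]:
        best_score, best_tree = None, None
        nodes = [n for n in tree.postorder() if n.parent is not None]
        for target_idx in range(len(nodes)):
            dup = tree.copy()
            dup_nodes = [n for n in dup.postorder() if n.parent is not None]
            target = dup_nodes[target_idx]
            parent = target.parent
            mid = Node(None)
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(Node(lab))
            s = _score_masks(dup, masks)
            if best_score is None or s < best_score:
                best_score, best_tree = s, dup
        tree = best_tree
    return tree


def _nni_neighbors(tree: Tree):
    """Yield NNI rearrangements around every internal edge."""
    inner = [
        n
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf
    ]
    for idx in range(len(inner)):
        for swap in (0, 1):
            dup = tree.copy()
            dup_inner = [
                n
                for n in dup.postorder()
                if n.parent is not None and not n.is_leaf
            ]
            node = dup_inner[idx]
            parent = node.parent
            siblings = [c for c in parent.children if c is not node]
            if not siblings or len(node.children) < 2:
                continue
            child = node.children[swap % len(node.children)]
            for sib in siblings:
                # swap sib <-> child across the internal edge
                parent.children[parent.children.index(sib)] = child
                node.children[node.children.index(child)] = sib
                child.parent, sib.parent = parent, node
                yield dup.copy()
                # undo for the next sibling
                parent.children[parent.children.index(child)] = sib
                node.children[node.children.index(sib)] = child
                sib.parent, child.parent = parent, node


def _spr_neighbors(tree: Tree):
    """Yield subtree-prune-regraft rearrangements (all prune/regraft pairs)."""
    n_branches = len([n for n in tree.postorder() if n.parent is not None])
    for i in range(n_branches):
        dup = tree.copy()
        nodes = [n for n in dup.postorder() if n.parent is not None]
        target = nodes[i]
        parent = target.parent
        parent.children.remove(target)
        target.parent = None
        root = dup.root
        if parent is root and len(root.children) == 1:
            only = root.children[0]
            if only.is_leaf:
                continue  # nothing left to regraft into
            only.parent = None
            dup = Tree(only)
        elif parent is not root and len(parent.children) == 1:
            child = parent.children[0]
            gp = parent.parent
            gp.children[gp.children.index(parent)] = child
            child.parent = gp
        edges = [n for n in dup.postorder() if n.parent is not None]
        for e in edges:
            p = e.parent
            mid = Node(None)
            p.children[p.children.index(e)] = mid
            mid.parent = p
            mid.add_child(e)
            mid.add_child(target)
            yield dup.copy()
            # undo the insertion
            p.children[p.children.index(mid)] = e
            e.parent = p
            target.parent = None


def mp_search(
    matrix: VariantMatrix,
    mode: str = "heuristic",
    seed: int = 0,
    *,
    n_restarts: int = 10,
    exact_limit: int = EXACT_LIMIT_DEFAULT,
    max_trees: int = 100,
    outgroup: str | None = None,
    spr: bool = True,
) -> list[Tree]:
    """Search for maximum-parsimony trees.

    Returns the co-optimal trees found (capped at ``max_trees``; a
    ``truncated`` flag is placed on the returned list via the ``mp_search
    .last_report`` attribute). Exact mode enumerates all unrooted topologies
    (refused above ``exact_limit`` taxa). Heuristic mode runs random-order
    stepwise addition followed by NNI hill-climbing, across restarts.
    If ``outgroup`` is given, returned trees are rooted on its branch.
    """
    labels = list(matrix.samples)
    if len(labels) < 3:
        raise ValueError("need at least 3 samples for tree search")
    masks = _leaf_masks(matrix)
    report = {"truncated": False, "unresolved": matrix.n_positions == 0}

    best_score = None
    best: list[Tree] = []
    seen: set[frozenset] = set()

    def consider(tree: Tree, score: int):
        nonlocal best_score
        if best_score is None or score < best_score:
            best_score = score
            best.clear()
            seen.clear()
        if score == best_score:
            key = frozenset(tree.bipartitions())
            if key not in seen:
                seen.add(key)
                if len(best) < max_trees:
                    best.append(tree)
                else:
                    report["truncated"] = True

    if mode == "exact":
        if len(labels) > exact_limit:
            raise ValueError(
                f"exact search limited to {exact_limit} taxa "
                f"({len(labels)} given); use mode='heuristic'"
            )
        for tree in _all_topologies(labels):
            consider(tree, _score_masks(tree, masks))
    elif mode == "heuristic":
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            tree = _random_addition_tree(labels, masks, rng)
            score = _score_masks(tree, masks)
            improved = True
            while improved:
                improved = False
                # cheap NNI sweep first, SPR only once NNI stalls
                for cand in _nni_neighbors(tree):
                    s = _score_masks(cand, masks)
                    if s < score:
                        tree, score = cand, s
                        improved = True
                        break
                if not improved and spr:
                    for cand in _spr_neighbors(tree):
                        s = _score_masks(cand, masks)
                        if s < score:
                            tree, score = cand, s
                            improved = True
                            break
            consider(tree, score)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    report["score"] = best_score
    report["n_cooptimal"] = len(best)
    mp_search.last_report = report
    if outgroup is not None:
        best = [t.reroot_on_outgroup(outgroup) for t in best]
    return best


# --------------------------------------------------------------------------- #
# homoplasy, mutation mapping, clock checks


def homoplasy_count(tree: Tree, matrix: VariantMatrix) -> int:
    """Number of characters with parallel or recurrent changes: sites whose
    changes on the tree exceed (number of observed distinct alleles - 1)."""
    per_site = fitch_score(tree, matrix, per_site=True)
    minima = np.array(
        [
            max(len(set(col[col != MISSING])) - 1, 0)
            for col in matrix.alleles.T
        ],
        dtype=np.int64,
    )
    return int((per_site > minima).sum())


def map_mutations(tree: Tree, matrix: VariantMatrix) -> Tree:
    """Assign each site's state changes to branches (annotated copy).

    The tree must be rooted (root with >= 2 children, outgroup-style). The
    root state is the ancestral allele when it is in the root's Hartigan
    state set, otherwise the first member of that set in A<C<G<T order; at
    each node the parental state is retained whenever allowed (so changes
    are placed as tipward as the first-pass sets permit), other ties broken
    by the same fixed base order.
    """
    annotated = tree.copy()
    for node in annotated.postorder():
        node.mutations = []
    masks = _leaf_masks(matrix)
    sets, _ = _hartigan_up(annotated, masks)
    anc_bits = np.array(
        [_BASE_TO_BIT[a] for a in matrix.ancestral], dtype=np.uint8
    )

    def choose(mask: np.ndarray, preferred: np.ndarray) -> np.ndarray:
        ok = (mask & preferred) > 0
        lowest = mask & (-mask).astype(np.uint8)  # lowest set bit = A<C<G<T order
        return np.where(ok, preferred, lowest).astype(np.uint8)

    states: dict[int, np.ndarray] = {}
    positions = matrix.positions
    for node in annotated.preorder():
        if node.parent is None:
            states[id(node)] = choose(sets[id(node)], anc_bits)
            continue
        parent_state = states[id(node.parent)]
        if node.is_leaf:
            mask = masks[node.label]
        else:
            mask = sets[id(node)]
        state = choose(mask, parent_state)
        states[id(node)] = state
        changed = state != parent_state
        node.mutations = [int(positions[i]) for i in np.nonzero(changed)[0]]
    return annotated


def root_leaf_distances(annotated: Tree) -> tuple[dict[str, int], float, float]:
    """Mutation counts along each root-to-tip path, with mean and sample sd."""
    counts: dict[str, int] = {}

    def rec(node: Node, acc: int):
        acc += len(node.mutations)
        if node.is_leaf:
            counts[node.label] = acc
        for ch in node.children:
            rec(ch, acc)

    rec(annotated.root, 0)
    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return counts, mean, sd


# --------------------------------------------------------------------------- #
# bootstrap


def bootstrap_support(
    matrix: VariantMatrix,
    n_reps: int = 100,
    seed: int = 0,
    *,
    reference_tree: Tree | None = None,
    search_kwargs: dict | None = None,
) -> dict[frozenset, float]:
    """Parsimony bootstrap: resample sites with replacement, rerun the
    search, and report the percentage of replicates containing each
    non-trivial bipartition of the reference best tree."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    search_kwargs = dict(search_kwargs or {})
    search_kwargs.setdefault("n_restarts", 3)
    rng = np.random.default_rng(seed)
    if reference_tree is None:
        reference_tree = mp_search(matrix, seed=seed, **search_kwargs)[0]
    ref_splits = reference_tree.bipartitions()
    hits = {split: 0 for split in ref_splits}
    m = matrix.n_positions
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m) if m else np.array([], dtype=int)
        resampled = VariantMatrix(
            samples=matrix.samples,
            positions=np.arange(idx.size),
            alleles=matrix.alleles[:, idx],
            ancestral=matrix.ancestral[idx],
            region_length=matrix.region_length,
        )
        rep_tree = mp_search(
            resampled, seed=int(rng.integers(0, 2**31 - 1)), **search_kwargs
        )[0]
        rep_splits = rep_tree.bipartitions()
        for split in ref_splits:
            if split in rep_splits:
                hits[split] += 1
    return {split: 100.0 * h / n_reps for split, h in hits.items()}


# --------------------------------------------------------------------------- #
# QC report


@dataclass
class QCReport:
    """Phylogenetic quality summary of a filtered matrix."""

    parsimony_score: int
    n_cooptimal: int
    truncated: bool
    mean_rf: float
    homoplasies: int
    root_leaf_mean: float
    root_leaf_sd: float
    bootstrap: dict = field(default_factory=dict)
    flagged: bool = False
    rf_flag_threshold: float = 0.15

    def to_dict(self) -> dict:
        out = {
            "parsimony_score": self.parsimony_score,
            "n_cooptimal": self.n_cooptimal,
            "truncated": self.truncated,
            "mean_rf": self.mean_rf,
            "homoplasies": self.homoplasies,
            "root_leaf_mean": self.root_leaf_mean,
            "root_leaf_sd": self.root_leaf_sd,
            "flagged": self.flagged,
        }
        if self.bootstrap:
            out["bootstrap"] = {
                "|".join(sorted(k)): v for k, v in self.bootstrap.items()
            }
        return out


def qc_report(
    matrix: VariantMatrix,
    outgroup: str | None = None,
    *,
    seed: int = 0,
    n_bootstrap: int = 0,
    rf_flag_threshold: float = 0.15,
    search_kwargs: dict | None = None,
) -> tuple[Tree, QCReport]:
    """Run the search and assemble the QC metrics for one matrix."""
    search_kwargs = dict(search_kwargs or {})
    trees = mp_search(matrix, seed=seed, **search_kwargs)
    report = dict(mp_search.last_report)
    pairs = list(itertools.combinations(trees, 2))
    mean_rf = (
        float(np.mean([rf_distance(a, b)[1] for a, b in pairs])) if pairs else 0.0
    )
    best = trees[0]
    rooted = best.reroot_on_outgroup(outgroup) if outgroup else best
    annotated = map_mutations(rooted, matrix)
    _, rl_mean, rl_sd = root_leaf_distances(annotated)
    supports = (
        bootstrap_support(
            matrix, n_bootstrap, seed=seed, reference_tree=best,
            search_kwargs=search_kwargs,
        )
        if n_bootstrap
        else {}
    )
    qc = QCReport(
        parsimony_score=report["score"],
        n_cooptimal=len(trees),
        truncated=report["truncated"],
        mean_rf=mean_rf,
        homoplasies=homoplasy_count(best, matrix),
        root_leaf_mean=rl_mean,
        root_leaf_sd=rl_sd,
        bootstrap=supports,
        flagged=mean_rf > rf_flag_threshold,
        rf_flag_threshold=rf_flag_threshold,
    )
    return annotated, qc
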