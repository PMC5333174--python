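"""Rho-statistic clade dating.

The rho statistic is the mean number of mutations on the paths from a clade's
root to its tips; dividing by the per-lineage mutation intensity L*mu
(analysable length in bp times the per-bp per-year SNP rate) converts it to a
TMRCA in years. The standard error follows Saillard et al.'s variance,
sigma^2 = sum_b m_b * n_b^2 / n^2 over the clade's branches, where m_b is the
branch's mutation count and n_b the number of clade tips below it.

The default calibration is the pedigree-derived SNP rate 0.78e-9
mutations/bp/year; L defaults to the analysable-region length carried by the
variant matrix the tree was built from. Because platform-restricted dating
subsets are common (only samples sequenced alike are compared), clades are
re-pruned to the subset before branch tip-counts are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import pandas as pd

from .tree import Node, Tree

__all__ = [
    "MU_DEFAULT",
    "RhoResult",
    "rho_statistic",
    "rho_sigma",
    "age_estimate",
    "date_all_clades",
]

MU_DEFAULT = 0.78e-9  # SNP mutations per bp per year (pedigree calibration)


class SingletonCladeError(ValueError):
    pass


@dataclass(frozen=True)
class RhoResult:
    clade: str
    n_tips: int
    rho: float
    sigma_rho: float
    length_bp: float
    mu: float
    age_years: Optional[float]
    age_se_years: Optional[float]

    def as_row(self) -> dict:
        return {
            "clade": self.clade,
            "n_tips": self.n_tips,
            "rho": self.rho,
            "sigma_rho": self.sigma_rho,
            "L_bp": self.length_bp,
            "mu": self.mu,
            "age_years": self.age_years,
            "age_se_years": self.age_se_years,
        }


def _clade_branches(clade_root: Node) -> list[tuple[Node, int]]:
    """(node, tips below) for every branch inside the clade."""
    tips_below: dict[int, int] = {}
    order: list[Node] = []
    stack = [clade_root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for n in reversed(order):
        tips_below[id(n)] = 1 if n.is_leaf else sum(
            tips_below[id(c)] for c in n.children
        )
    return [
        (n, tips_below[id(n)]) for n in order if n is not clade_root
    ], tips_below[id(clade_root)]


def rho_statistic(annotated: Tree, clade_root: Optional[Node] = None) -> float:
    """rho = mean mutations on root->tip paths, computed in the equivalent
    branch-weighted form sum_b m_b * n_b / n."""
    root = clade_root or annotated.root
    branches, n = _clade_branches(root)
    if n < 2:
        raise SingletonCladeError("rho undefined for a singleton clade")
    return sum(len(b.mutations) * nb for b, nb in branches) / n


def rho_sigma(annotated: Tree, clade_root: Optional[Node] = None) -> float:
    """Saillard standard error: sigma^2 = sum_b m_b * n_b^2 / n^2."""
    root = clade_root or annotated.root
    branches, n = _clade_branches(root)
    if n < 2:
        raise SingletonCladeError("sigma undefined for a singleton clade")
    var = sum(len(b.mutations) * nb * nb for b, nb in branches) / (n * n)
    return math.sqrt(var)


def age_estimate(
    rho: float, sigma: float, length_bp: float, mu: float = MU_DEFAULT
) -> tuple[float, float]:
    """Convert (rho, sigma) to (age, se) in years: age = rho / (L * mu)."""
    if length_bp <= 0 or mu <= 0:
        raise ValueError("length and mutation rate must be positive")
    scale = length_bp * mu
    return rho / scale, sigma / scale


def date_all_clades(
    annotated: Tree,
    subset: Optional[Sequence[str]] = None,
    mu: float = MU_DEFAULT,
    length_bp: Optional[float] = None,
    min_tips: int = 2,
    clades: Optional[dict[str, set[str]]] = None,
) -> pd.DataFrame:
    """One RhoResult row per named clade.

    Clades default to the labeled internal nodes of the tree (plus the
    root); inferred trees have anonymous internals, so ``clades`` may supply
    an explicit {name: tip labels} mapping instead (each clade is then dated
    from the MRCA of its tips). ``subset`` restricts to a platform-consistent
    set of samples: the tree is pruned to the subset (branch mutations
    merging along suppressed paths) before tip counts are taken. Clades left
    with fewer than ``min_tips`` subset tips are reported undated (age
    columns NA), mirroring how clades whose carriers were sequenced
    differently are left out of a dating table.
    """
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty dating subset")
    if length_bp is None:
        raise ValueError("length_bp is required (analysable region length)")

    # collect the named clades, then re-evaluate each on the pruned tree via
    # its subset tip set
    named: list[tuple[str, set[str]]] = []
    if clades is not None:
        named = [(name, set(tips)) for name, tips in clades.items()]
    else:
        for node in annotated.preorder():
            if node.is_leaf:
                continue
            name = node.label or ("root" if node.parent is None else None)
            if name is None:
                continue
            tips = {t.label for t in annotated.tips_below(node)}
            named.append((name, tips))

    pruned = annotated.prune_to(subset) if subset is not None else annotated
    kept = set(pruned.leaf_labels())

    tipsets: dict[int, frozenset] = {}
    for node in pruned.postorder():
        tipsets[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(tipsets[id(c)] for c in node.children))
        )

    def mrca(targets: frozenset) -> Optional[Node]:
        node = pruned.root
        if not targets <= tipsets[id(node)]:
            return None
        while True:
            nxt = [c for c in node.children if targets <= tipsets[id(c)]]
            if not nxt:
                return node
            node = nxt[0]

    rows = []
    for name, tips in named:
        sub_tips = frozenset(tips & kept)
        node = mrca(sub_tips) if len(sub_tips) >= min_tips else None
        if node is None or node.is_leaf:
            rows.append(
                RhoResult(
                    clade=name,
                    n_tips=len(sub_tips),
                    rho=float("nan"),
                    sigma_rho=float("nan"),
                    length_bp=length_bp,
                    mu=mu,
                    age_years=None,
                    age_se_years=None,
                ).as_row()
            )
            continue
        rho = rho_statistic(pruned, node)
        sigma = rho_sigma(pruned, node)
        age, se = age_estimate(rho, sigma, length_bp, mu)
        row = RhoResult(
            clade=name,
            n_tips=len(sub_tips),
            rho=rho,
            sigma_rho=sigma,
            length_bp=length_bp,
            mu=mu,
            age_years=age,
            age_se_years=se,
        ).as_row()
        row["monophyletic"] = tipsets[id(node)] == sub_tips
        rows.append(row)
    return pd.DataFrame(rows)
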