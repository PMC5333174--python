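"""Synthetic ground-truth data for the whole analysis chain.

The real inputs of a Y-chromosome phylogeography study — dated patrilineal
genealogies, heterogeneous NGS coverage from several sequencing platforms,
population frequency point samples, Y-STR panels — are emulated here with
explicit, seedable generators so that every downstream stage (filtering, tree
search, dating, mapping, prediction) can be tested against a known truth.

Model summary
-------------
* Genealogy: a random-coalescence ("yule"-style) or star topology with node
  ages scaled so the root sits at a chosen TMRCA (years); tips at age 0.
* Mutations: each branch of duration ``t`` years receives Poisson(t * L * mu)
  SNPs; sites are unique-event (infinite sites) by default, matching how
  Y-SNPs behave at these time depths; recurrent mutation is opt-in to
  exercise homoplasy detection.
* Sequencing evidence: per platform, a set of covered intervals plus a
  negative-binomial read depth per site; sequencing error converts a fraction
  of reads into spurious minor alleles, producing the false "heterozygous"
  haploid sites the filtering rules must handle.
* Geography: carrier counts at sampling sites are Binomial(n, f(lat, lon))
  draws from a supplied frequency surface.
* Y-STRs: the stepwise mutation model — Poisson(t * rate) events per marker
  per branch, each changing the repeat count by +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .tree import Node, Tree

__all__ = [
    "PlatformProfile",
    "SimulationConfig",
    "ReferenceSequence",
    "ObservationSet",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_reference",
    "simulate_observations",
    "simulate_geo_samples",
    "simulate_str_haplotypes",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlatformProfile:
    """Coverage and noise characteristics of one sequencing platform.

    intervals: covered regions, 0-based half-open (start, end) pairs.
    depth_mean / depth_dispersion: negative-binomial site depth (dispersion =
    NB size parameter; larger means closer to Poisson).
    base_quality / mapping_quality: (mean, sd) of per-allele phred scores.
    """

    name: str
    intervals: tuple[tuple[int, int], ...]
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    depth_min: int = 0  # floor on drawn depths (full-coverage designs use >= 2)
    base_quality: tuple[float, float] = (30.0, 4.0)
    mapping_quality: tuple[float, float] = (50.0, 8.0)

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)

    def covered_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the sequencing design the analysis is built around:
    a ~15.1 ky-old haplogroup of 47 carriers plus one outgroup, a 9.34 Mb
    analysable region, and the pedigree-calibrated SNP rate of
    0.78e-9 mutations/bp/year.
    """

    n_tips: int = 48
    tmrca_years: float = 15100.0
    region_length: int = 9_340_000
    mutation_rate: float = 0.78e-9
    platform_profiles: Optional[Sequence[PlatformProfile]] = None
    base_error_rate: float = 0.0
    str_tracts: tuple[tuple[int, str, int], ...] = ()  # (start, motif, repeats)
    allow_recurrent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise InvalidConfigError("need at least 2 tips")
        if self.mutation_rate <= 0:
            raise InvalidConfigError("mutation rate must be > 0")
        if self.region_length <= 0:
            raise InvalidConfigError("region length must be > 0")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise InvalidConfigError("base error rate must be in [0, 1)")

    def profiles(self) -> list[PlatformProfile]:
        if self.platform_profiles:
            return list(self.platform_profiles)
        # one BigY-like platform covering the whole region
        return [
            PlatformProfile(
                name="bigy", intervals=((0, self.region_length),)
            )
        ]


@dataclass
class ReferenceSequence:
    """Reference with ground-truth coordinates of embedded STR tracts."""

    seq: np.ndarray  # dtype S1
    tracts: tuple[tuple[int, int], ...]  # 0-based half-open truth intervals

    def __len__(self) -> int:
        return self.seq.size

    def __str__(self) -> str:
        return self.seq.tobytes().decode()


@dataclass
class ObservationSet:
    """Raw per-sample, per-site sequencing evidence.

    ``table`` is a pandas DataFrame in the TSV site-observation dialect
    (sample, pos, base, count, base_quality, mapping_quality, is_indel);
    ``coverage`` maps sample -> covered intervals, used for call-rate
    denominators and for the analysable-region length L.
    """

    table: "object"
    coverage: dict[str, tuple[tuple[int, int], ...]]
    samples: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------- #
# genealogy


def simulate_genealogy(
    config: SimulationConfig, mode: str = "yule", topology: Optional[Tree] = None
) -> Tree:
    """Simulate a dated rooted genealogy.

    mode="star": all tips attach directly to the root (every root-tip path
    has length tmrca). mode="yule": random sequential coalescence of
    lineages, ages rescaled so the root age equals the TMRCA.  A
    user-supplied dated ``topology`` is validated and returned as-is.
    """
    if topology is not None:
        topology.validate()
        return topology
    n = config.n_tips
    if n < 2:
        raise InvalidConfigError("need at least 2 tips")
    rng = np.random.default_rng(config.seed)
    tips = [Node(f"s{i:03d}", 0.0) for i in range(n)]

    if mode == "star":
        root = Node("root", config.tmrca_years)
        for t in tips:
            root.add_child(t)
        return Tree(root)
    if mode != "yule":
        raise InvalidConfigError(f"unknown mode {mode!r}")

    lineages = list(tips)
    age = 0.0
    k = n
    while len(lineages) > 1:
        # exponential waiting times give a realistic mix of short internal
        # and long basal branches; absolute scale fixed by the TMRCA below
        age += rng.exponential(1.0 / len(lineages))
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node(None, age)
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[i] = parent
        del lineages[j]
        k -= 1
    root = lineages[0]
    root.label = "root"
    scale = config.tmrca_years / root.age
    tree = Tree(root)
    for node in tree.postorder():
        if not node.is_leaf:
            node.age *= scale
    return tree


def drop_mutations(tree: Tree, config: SimulationConfig) -> Tree:
    """Scatter SNP mutations on a dated genealogy (annotates a copy).

    Each branch of duration t years gets Poisson(t * L * mu) mutations.
    Under the default infinite-sites model all positions are distinct across
    the whole tree; with ``allow_recurrent`` positions are drawn with
    replacement (independently per branch), so a site may change repeatedly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    annotated = tree.copy()
    L = config.region_length
    rate = config.mutation_rate
    branches = [n for n in annotated.postorder() if n.parent is not None]
    counts = [rng.poisson(max(n.branch_years, 0.0) * L * rate) for n in branches]
    total = int(sum(counts))
    if config.allow_recurrent:
        positions = rng.integers(0, L, size=total)
    else:
        if total > L:
            raise InvalidConfigError(
                f"{total} unique-event mutations do not fit in {L} bp"
            )
        positions = _sample_distinct(rng, L, total)
    offset = 0
    for node, c in zip(branches, counts):
        node.mutations = sorted(int(p) for p in positions[offset : offset + c])
        offset += c
    return annotated


def _sample_distinct(rng: np.random.Generator, L: int, total: int) -> np.ndarray:
    """``total`` distinct uniform positions in [0, L) without materialising a
    full permutation (rejection sampling; falls back when density is high)."""
    if total > L // 2:
        return rng.choice(L, size=total, replace=False)
    out: set[int] = set()
    while len(out) < total:
        draw = rng.integers(0, L, size=(total - len(out)) * 2 + 8)
        for v in draw:
            out.add(int(v))
            if len(out) == total:
                break
    arr = np.fromiter(out, dtype=np.int64, count=total)
    rng.shuffle(arr)  # so the partition across branches stays exchangeable
    return arr


# --------------------------------------------------------------------------- #
# reference with STR tracts


def simulate_reference(
    length: int,
    str_tracts: Sequence[tuple[int, str, int]] = (),
    seed: int = 0,
) -> ReferenceSequence:
    """Random base background with exact-repeat tracts embedded at given
    coordinates; tract truth intervals are recorded for mask validation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    seq = _BASES[rng.integers(0, 4, size=length)].copy()
    intervals: list[tuple[int, int]] = []
    for start, motif, repeats in sorted(str_tracts):
        tract = (motif * repeats).encode()
        end = start + len(tract)
        if start < 0 or end > length:
            raise InvalidConfigError(f"tract [{start},{end}) outside reference")
        if intervals and start < intervals[-1][1]:
            raise InvalidConfigError("overlapping STR tracts")
        seq[start:end] = np.frombuffer(tract, dtype="S1")
        intervals.append((start, end))
    return ReferenceSequence(seq=seq, tracts=tuple(intervals))


# --------------------------------------------------------------------------- #
# sequencing evidence


def _tip_mutation_sites(annotated: Tree) -> dict[str, frozenset[int]]:
    """Per tip: the set of sites carrying a derived allele (odd number of
    changes on the root path; with unique-event mutations, simply the union
    of root-path branch mutations)."""
    from collections import Counter

    out: dict[str, frozenset[int]] = {}

    def rec(node: Node, acc: Counter):
        acc = acc.copy()
        acc.update(node.mutations)
        if node.is_leaf:
            out[node.label] = frozenset(p for p, c in acc.items() if c % 2 == 1)
        for ch in node.children:
            rec(ch, acc)

    rec(annotated.root, Counter())
    return out


def simulate_observations(
    annotated: Tree,
    ref: ReferenceSequence,
    config: SimulationConfig,
    platform_map: Optional[dict[str, str]] = None,
) -> ObservationSet:
    """Emit raw site evidence per tip: read counts for the true allele plus
    error reads, with platform-specific depth and quality draws.

    Observations are produced at the union of mutated sites (non-variant
    sites carry no phylogenetic signal and are represented implicitly by the
    coverage intervals). Derived alleles differ from the reference base;
    with multiple hits at a site the allele toggles between reference and
    derived state per change.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    profiles = config.profiles()
    by_name = {p.name: p for p in profiles}
    tips = annotated.leaves()
    tip_platform = {}
    for i, tip in enumerate(tips):
        if platform_map is not None:
            prof = by_name[platform_map[tip.label]]
        else:
            prof = profiles[i % len(profiles)]
        tip.platform = prof.name
        tip_platform[tip.label] = prof

    derived_sites = _tip_mutation_sites(annotated)
    all_sites = sorted(set().union(*derived_sites.values())) if tips else []
    ref_bytes = ref.seq
    # derived allele per site: uniform over the three non-reference bases
    derived_allele: dict[int, bytes] = {}
    for pos in all_sites:
        ref_base = ref_bytes[pos]
        alts = [b for b in b"ACGT" if bytes([b]) != ref_base.tobytes()]
        derived_allele[pos] = bytes([alts[rng.integers(0, 3)]])

    rows = []
    e = config.base_error_rate
    for tip in tips:
        prof = tip_platform[tip.label]
        covered = [p for p in all_sites if prof.covers(p)]
        if not covered:
            continue
        m = len(covered)
        if prof.depth_dispersion <= 0:
            depths = rng.poisson(prof.depth_mean, size=m)
        else:
            r = prof.depth_dispersion
            p = r / (r + prof.depth_mean)
            depths = rng.negative_binomial(r, p, size=m)
        if prof.depth_min > 0:
            depths = np.maximum(depths, prof.depth_min)
        bq = rng.normal(*prof.base_quality, size=m).clip(2, 60)
        mq = rng.normal(*prof.mapping_quality, size=m).clip(2, 60)
        mine = derived_sites[tip.label]
        for pos, depth, b, q in zip(covered, depths, bq, mq):
            depth = int(depth)
            if depth == 0:
                continue
            true_base = (
                derived_allele[pos]
                if pos in mine
                else ref_bytes[pos].tobytes()
            )
            n_err = rng.binomial(depth, e) if e > 0 else 0
            n_true = depth - n_err
            if n_true > 0:
                rows.append(
                    (tip.label, pos, true_base.decode(), n_true, round(b, 1), round(q, 1))
                )
            if n_err > 0:
                others = [c for c in "ACGT" if c != true_base.decode()]
                split = rng.multinomial(n_err, [1 / 3] * 3)
                for base, cnt in zip(others, split):
                    if cnt > 0:
                        rows.append(
                            (tip.label, pos, base, int(cnt), round(b, 1), round(q, 1))
                        )

    table = pd.DataFrame(
        rows,
        columns=["sample", "pos", "base", "count", "base_quality", "mapping_quality"],
    )
    table["is_indel"] = False
    coverage = {t.label: tip_platform[t.label].intervals for t in tips}
    return ObservationSet(
        table=table, coverage=coverage, samples=[t.label for t in tips]
    )


# --------------------------------------------------------------------------- #
# geography


def simulate_geo_samples(
    surface_fn: Callable[[float, float], float],
    sites: Sequence[tuple[float, float, int]],
    seed: int = 0,
):
    """Binomial carrier counts at sampling sites from a true frequency
    surface; returns a list of GeoSample."""
    from .geomap import GeoSample

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    out = []
    for i, (lat, lon, n) in enumerate(sites):
        if n <= 0:
            raise InvalidConfigError("site sample size must be > 0")
        f = float(surface_fn(lat, lon))
        if not 0.0 <= f <= 1.0:
            raise InvalidConfigError(f"surface value {f} outside [0, 1]")
        k = int(rng.binomial(n, f))
        out.append(GeoSample(label=f"site{i:03d}", lat=lat, lon=lon, n=n, k=k))
    return out


# --------------------------------------------------------------------------- #
# Y-STR haplotypes


def simulate_str_haplotypes(
    tree: Tree,
    markers: Sequence[str],
    str_rate: float,
    seed: int = 0,
    root_repeats: Optional[dict[str, int]] = None,
):
    """Stepwise mutation model along the genealogy.

    Each marker accumulates Poisson(branch_years * str_rate) events per
    branch, each event moving the repeat count by +1 or -1 with equal
    probability. Returns {tip label: STRHaplotype}.
    """
    from .strpredict import STRHaplotype

    if str_rate < 0:
        raise InvalidConfigError("STR rate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    markers = list(markers)
    if root_repeats is None:
        root_state = np.full(len(markers), 13, dtype=int)
    else:
        root_state = np.array([root_repeats[m] for m in markers], dtype=int)

    out: dict[str, STRHaplotype] = {}

    def rec(node: Node, state: np.ndarray):
        if node.parent is not None and str_rate > 0:
            t = max(node.branch_years, 0.0)
            events = rng.poisson(t * str_rate, size=len(markers))
            steps = np.array(
                [
                    int(rng.choice([-1, 1], size=e).sum()) if e else 0
                    for e in events
                ]
            )
            state = np.maximum(state + steps, 1)  # repeat counts stay positive
        if node.is_leaf:
            out[node.label] = STRHaplotype(
                sample_id=node.label,
                repeats={m: int(v) for m, v in zip(markers, state)},
            )
        for ch in node.children:
            rec(ch, state)

    rec(tree.root, root_state)
    return out
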