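"""Y-STR haplotype distances, haplogroup gating rules, and branch prediction.

A Y-STR haplotype is a vector of repeat counts over a named marker panel
(standard genealogical panels have 12, 37, 67 or 111 markers). The mutation-
step distance between two haplotypes is the sum of absolute repeat
differences over shared markers; multi-copy loci (e.g. DYS385a/b) are
compared as multisets under a minimal assignment, so copy order never adds
steps.

Branch prediction is nearest-reference assignment against a panel of
SNP-confirmed exemplars, with the acceptance threshold depending on panel
resolution: a query typed at >= 67 markers is assigned when it is fewer than
6 mutation steps from a confirmed reference; low-resolution queries (12/37
markers) only at zero or one step. Ties between different branches leave the
query UNASSIGNED with a tie report. Rule-based haplogroup gating (per-marker
allele range constraints) pre-screens candidates the way published repeat-
count signatures are used to spot likely carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "UNASSIGNED",
    "STRHaplotype",
    "ReferencePanel",
    "PredictionRule",
    "str_distance",
    "predict_branch",
    "apply_rules",
]

UNASSIGNED = "UNASSIGNED"

Repeat = Union[int, tuple[int, ...]]

HIGH_RES_MIN_MARKERS = 67   # panels this large use the < 6 steps rule
HIGH_RES_MAX_STEPS = 6      # strict: 5 steps assign, 6 reject
LOW_RES_MAX_STEPS = 1       # 12/37-marker panels: zero or one step


@dataclass(frozen=True)
class STRHaplotype:
    """Marker -> repeat count(s); multi-copy loci hold tuples."""

    sample_id: str
    repeats: Mapping[str, Repeat]

    def __post_init__(self):
        for marker, value in self.repeats.items():
            values = value if isinstance(value, tuple) else (value,)
            if not all(isinstance(v, int) and v > 0 for v in values):
                raise ValueError(
                    f"{marker}: repeat counts must be positive integers, got {value!r}"
                )

    @property
    def panel_size(self) -> int:
        return len(self.repeats)

    def markers(self) -> set[str]:
        return set(self.repeats)


@dataclass
class ReferencePanel:
    """SNP-confirmed exemplars: (haplotype, branch label) pairs."""

    references: list[tuple[STRHaplotype, str]] = field(default_factory=list)

    def add(self, haplotype: STRHaplotype, branch: str) -> None:
        self.references.append((haplotype, branch))

    def __len__(self) -> int:
        return len(self.references)


def _multiset_steps(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Minimal-assignment step count between multi-copy alleles.

    For one-dimensional values under L1 cost the optimal matching pairs the
    sorted orders; unequal copy numbers are matched on the shorter length
    (extra copies do not count steps)."""
    sa, sb = sorted(a), sorted(b)
    m = min(len(sa), len(sb))
    if m == 0:
        return 0
    if len(sa) == len(sb):
        return sum(abs(x - y) for x, y in zip(sa, sb))
    # match the shorter multiset into the longer one optimally
    from scipy.optimize import linear_sum_assignment

    short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    cost = np.abs(
        np.array(short)[:, None] - np.array(long_)[None, :]
    )
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def str_distance(h1: STRHaplotype, h2: STRHaplotype) -> tuple[int, int]:
    """(mutation steps, number of shared markers).

    Steps sum |repeat difference| over shared single-copy markers; multi-copy
    markers contribute their minimal-assignment matching cost.
    """
    shared = h1.markers() & h2.markers()
    if not shared:
        raise ValueError("haplotypes share no markers")
    steps = 0
    for marker in shared:
        a, b = h1.repeats[marker], h2.repeats[marker]
        ta = a if isinstance(a, tuple) else (a,)
        tb = b if isinstance(b, tuple) else (b,)
        steps += _multiset_steps(ta, tb)
    return steps, len(shared)


def _threshold_for(panel_size: int) -> int:
    """Maximum accepted steps (inclusive) for a query panel size."""
    if panel_size >= HIGH_RES_MIN_MARKERS:
        return HIGH_RES_MAX_STEPS - 1  # "< 6" is strict
    return LOW_RES_MAX_STEPS


def predict_branch(
    query: STRHaplotype,
    panel: ReferencePanel,
    *,
    max_steps: Optional[int] = None,
) -> tuple[str, dict]:
    """Assign the query to the branch of its nearest SNP-confirmed reference.

    Returns (branch | UNASSIGNED, evidence dict). ``max_steps`` overrides the
    panel-size-dependent threshold (inclusive upper bound on steps).
    """
    if not len(panel):
        raise ValueError("empty reference panel")
    threshold = max_steps if max_steps is not None else _threshold_for(query.panel_size)
    distances = []
    for ref, branch in panel.references:
        try:
            steps, shared = str_distance(query, ref)
        except ValueError:
            continue
        distances.append((steps, shared, branch, ref.sample_id))
    if not distances:
        raise ValueError("query shares no markers with any reference")
    distances.sort(key=lambda t: t[0])
    best_steps = distances[0][0]
    nearest = [d for d in distances if d[0] == best_steps]
    branches = sorted({d[2] for d in nearest})
    evidence = {
        "best_steps": best_steps,
        "threshold": threshold,
        "nearest": [
            {"branch": b, "reference": r, "steps": s, "shared_markers": sh}
            for s, sh, b, r in nearest
        ],
        "panel_size": query.panel_size,
    }
    if best_steps > threshold:
        evidence["reason"] = "nearest reference beyond step threshold"
        return UNASSIGNED, evidence
    if len(branches) > 1:
        evidence["reason"] = "tie between branches"
        evidence["tied_branches"] = branches
        return UNASSIGNED, evidence
    return branches[0], evidence


@dataclass(frozen=True)
class PredictionRule:
    """Haplogroup gating rule: every constrained marker present in the query
    must fall in its allowed range; at least ``min_markers_matched`` of the
    constrained markers must be present."""

    label: str
    constraints: Mapping[str, tuple[int, int]]  # marker -> (lo, hi) inclusive
    min_markers_matched: int = 1

    def __post_init__(self):
        for marker, (lo, hi) in self.constraints.items():
            if lo > hi:
                raise ValueError(f"rule {self.label}: empty range for {marker}")
        if self.min_markers_matched < 0:
            raise ValueError("min_markers_matched must be >= 0")


def apply_rules(
    query: STRHaplotype, rules: Sequence[PredictionRule]
) -> list[str]:
    """Labels of all rules the query satisfies.

    A missing marker does not violate a constraint but counts against the
    rule's minimum matched-marker requirement.
    """
    out = []
    for rule in rules:
        matched = 0
        ok = True
        for marker, (lo, hi) in rule.constraints.items():
            if marker not in query.repeats:
                continue
            value = query.repeats[marker]
            values = value if isinstance(value, tuple) else (value,)
            if all(lo <= v <= hi for v in values):
                matched += 1
            else:
                ok = False
                break
        if ok and matched >= rule.min_markers_matched:
            out.append(rule.label)
    return out
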