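"""Haploid site calling and filtering for heterogeneous Y-chromosome data.

Converts raw per-sample site evidence (read counts with base/mapping
qualities) into a filtered matrix of variable positions, applying the rule
set tuned for merging sequences from different platforms:

* per-read-set quality gates: base quality >= 15, mapping quality >= 10;
* minimum read depth 2 ("relaxed") or 10 with a single allele ("stringent");
* false "heterozygous" haploid sites: a sample's call is discarded only when
  the minor-allele fraction exceeds 10%;
* STR masking: positions whose surrounding window has dimeric (dinucleotide)
  entropy below 0.44 are removed, the repeat-prone regions where alignment
  artefacts concentrate;
* indel positions excluded; SNPs near indels kept unless STR-masked;
* call rate: a position must be confidently called in >= 60% of samples,
  with a whitelist for branch-naming SNPs where a lower rate is acceptable.

Coordinates are 0-based half-open internally; VCF I/O converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .simulate import ObservationSet, ReferenceSequence

__all__ = [
    "MISSING",
    "FilterConfig",
    "VariantMatrix",
    "dimeric_entropy",
    "mask_str_regions",
    "call_sample_site",
    "build_matrix",
    "sweep_configs",
]

MISSING = "N"


class MalformedInputError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for calling and filtering.

    The "relaxed" preset is the rule set the final tree is built under;
    "stringent" requires depth >= 10 and exactly one observed allele.
    """

    min_depth: int = 2
    min_base_quality: float = 15.0
    min_mapping_quality: float = 10.0
    max_minor_fraction: float = 0.10
    entropy_min: float = 0.44
    entropy_window: int = 30
    min_call_rate: float = 0.6
    whitelist: frozenset[int] = frozenset()
    preset: str = "relaxed"

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 <= self.max_minor_fraction <= 1:
            raise ValueError("max_minor_fraction must be in [0, 1]")
        if not 0 <= self.entropy_min <= 1:
            raise ValueError("entropy_min must be in [0, 1]")
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        if self.entropy_window < 2:
            raise ValueError("entropy window must span at least one dimer")

    @classmethod
    def relaxed(cls, **kw) -> "FilterConfig":
        return cls(preset="relaxed", **kw)

    @classmethod
    def stringent(cls, **kw) -> "FilterConfig":
        kw.setdefault("min_depth", 10)
        kw.setdefault("max_minor_fraction", 0.0)
        return cls(preset="stringent", **kw)

    def with_(self, **kw) -> "FilterConfig":
        return replace(self, **kw)


@dataclass
class VariantMatrix:
    """Samples x variable positions alignment with per-site ancestral allele.

    ``alleles`` holds single characters in {A,C,G,T} or ``MISSING``;
    ``region_length`` is the analysable-region length L (bp) — positions
    unmasked and covered in at least ``min_call_rate`` of samples — the
    denominator later used to convert mutation counts into years.
    """

    samples: list[str]
    positions: np.ndarray  # int, 0-based
    alleles: np.ndarray  # (n_samples, n_positions) dtype <U1
    ancestral: np.ndarray  # (n_positions,) dtype <U1
    region_length: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_positions(self) -> int:
        return int(self.positions.size)

    def is_empty(self) -> bool:
        return self.n_positions == 0

    def call_rate(self) -> np.ndarray:
        return (self.alleles != MISSING).mean(axis=0)

    def to_bitmask(self) -> np.ndarray:
        """Encode alleles as bitmasks A=1 C=2 G=4 T=8, MISSING=15."""
        lut = {"A": 1, "C": 2, "G": 4, "T": 8, MISSING: 15}
        out = np.empty(self.alleles.shape, dtype=np.uint8)
        for ch, v in lut.items():
            out[self.alleles == ch] = v
        return out

    def subset(self, samples: Sequence[str]) -> "VariantMatrix":
        idx = [self.samples.index(s) for s in samples]
        sub = self.alleles[idx]
        keep = np.array(
            [len(set(col[col != MISSING])) >= 2 for col in sub.T], dtype=bool
        )
        return VariantMatrix(
            samples=list(samples),
            positions=self.positions[keep],
            alleles=sub[:, keep],
            ancestral=self.ancestral[keep],
            region_length=self.region_length,
        )


# --------------------------------------------------------------------------- #
# dimeric entropy and STR masking


def dimeric_entropy(window: str) -> float:
    """Normalised Shannon entropy of overlapping dinucleotides.

    H = -sum p_d log2 p_d over the 16 possible dimers, divided by 4
    (= log2 16), so values lie in [0, 1]. Dimers containing N are ignored.
    A window with a single distinct dimer (homopolymer) scores 0.
    """
    if len(window) < 2:
        raise ValueError("window must be at least 2 bases")
    from collections import Counter

    counts = Counter(
        window[i : i + 2]
        for i in range(len(window) - 1)
        if "N" not in window[i : i + 2]
    )
    total = sum(counts.values())
    if total == 0:
        return 0.0
    p = np.array(list(counts.values()), dtype=float) / total
    h = -(p * np.log2(p)).sum()
    return float(max(0.0, h / 4.0))


def _dimer_codes(seq_bytes: np.ndarray) -> np.ndarray:
    """Map a byte sequence to dimer codes 0..15 (-1 where a dimer has N)."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    base = lut[seq_bytes.view(np.uint8)]
    codes = base[:-1] * 4 + base[1:]
    codes[(base[:-1] < 0) | (base[1:] < 0)] = -1
    return codes


def windowed_entropy(ref: ReferenceSequence | str, window: int = 30) -> np.ndarray:
    """Per-position dimeric entropy of the centered window (vectorised).

    Edge positions use the truncated window. Entropy of windows whose every
    dimer contains N is 0.
    """
    seq = ref.seq if isinstance(ref, ReferenceSequence) else np.frombuffer(
        ref.encode(), dtype="S1"
    )
    L = seq.size
    if L < 2:
        return np.zeros(L)
    codes = _dimer_codes(seq)
    half = window // 2
    n_dimers = codes.size
    out = np.empty(L)
    chunk = 1 << 20  # bounded working memory for megabase-scale references
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        # dimer index range this chunk's windows can touch
        lo = max(start - half, 0)
        hi = min(stop - half + window - 1, n_dimers)
        local = codes[lo:hi]
        cum = np.zeros((16, local.size + 1), dtype=np.int32)
        for c in range(16):
            cum[c, 1:] = np.cumsum(local == c)
        pos = np.arange(start, stop)
        a = np.clip(pos - half, 0, n_dimers) - lo
        b = np.clip(pos - half + window - 1, 0, n_dimers) - lo
        cnt = cum[:, b] - cum[:, a]
        tot = cnt.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(
                tot > 0,
                np.log2(np.maximum(tot, 1))
                - (xlogy(cnt, cnt) / np.log(2)).sum(axis=0) / np.maximum(tot, 1),
                0.0,
            )
        out[start:stop] = h
    return np.maximum(out / 4.0, 0.0)


def mask_str_regions(
    ref: ReferenceSequence | str, config: FilterConfig
) -> list[tuple[int, int]]:
    """Half-open intervals of positions whose windowed dimeric entropy falls
    below ``entropy_min`` (likely STR/homopolymer tracts)."""
    ent = windowed_entropy(ref, config.entropy_window)
    masked = ent < config.entropy_min
    return _runs(masked)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _in_intervals(pos: np.ndarray, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    out = np.zeros(pos.shape, dtype=bool)
    for s, e in intervals:
        out |= (pos >= s) & (pos < e)
    return out


# --------------------------------------------------------------------------- #
# per-sample-site calling


def call_sample_site(
    observations: Iterable[tuple[str, int, float, float]] | pd.DataFrame,
    config: FilterConfig,
) -> str:
    """Call one sample at one position.

    Input rows are (base, count, base_quality, mapping_quality) —
    optionally with an is_indel flag as a fifth element. Reads whose allele
    fails a quality gate are discarded; remaining depth below ``min_depth``
    or a minor-allele fraction above ``max_minor_fraction`` yields MISSING,
    otherwise the majority allele is returned.
    """
    if isinstance(observations, pd.DataFrame):
        rows = list(
            observations[["base", "count", "base_quality", "mapping_quality"]]
            .itertuples(index=False, name=None)
        )
        indels = set(observations.get("is_indel", pd.Series(dtype=bool)))
        if len(indels) > 1:
            raise MalformedInputError("conflicting is_indel flags at one site")
    else:
        rows = []
        indel_flags = set()
        for row in observations:
            if len(row) == 5:
                indel_flags.add(bool(row[4]))
                row = row[:4]
            rows.append(tuple(row))
        if len(indel_flags) > 1:
            raise MalformedInputError("conflicting is_indel flags at one site")

    counts: dict[str, int] = {}
    for base, count, bq, mq in rows:
        if bq < config.min_base_quality or mq < config.min_mapping_quality:
            continue
        counts[base] = counts.get(base, 0) + int(count)
    depth = sum(counts.values())
    if depth < config.min_depth:
        return MISSING
    if len(counts) >= 2:
        major = max(counts.values())
        minor_fraction = 1.0 - major / depth
        if minor_fraction > config.max_minor_fraction:
            return MISSING
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def _call_all(
    table: pd.DataFrame,
    samples: Sequence[str],
    candidates: np.ndarray,
    config: FilterConfig,
) -> np.ndarray:
    """Vectorised equivalent of :func:`call_sample_site` over the whole
    observation table, for the candidate positions only."""
    n = len(samples)
    out = np.full((n, candidates.size), MISSING, dtype="<U1")
    t = table[
        (table["base_quality"] >= config.min_base_quality)
        & (table["mapping_quality"] >= config.min_mapping_quality)
        & table["pos"].isin(set(int(p) for p in candidates))
        & table["sample"].isin(set(samples))
    ]
    if not len(t):
        return out
    # aggregate read counts per (sample, pos, base); ties broken by base order
    agg = (
        t.groupby(["sample", "pos", "base"], sort=True)["count"].sum().reset_index()
    )
    per_site = agg.groupby(["sample", "pos"], sort=False)
    depth = per_site["count"].sum()
    # majority allele: stable sort by (count desc, base asc) then take first
    ordered = agg.sort_values(["sample", "pos", "count", "base"],
                              ascending=[True, True, False, True],
                              kind="mergesort")
    firsts = ordered.drop_duplicates(["sample", "pos"])
    major = firsts.set_index(["sample", "pos"])["count"]
    n_alleles = per_site["base"].nunique()
    calls = firsts.set_index(["sample", "pos"])["base"]

    ok_depth = depth >= config.min_depth
    minor_fraction = 1.0 - major / depth
    ok_minor = (n_alleles < 2) | (minor_fraction <= config.max_minor_fraction)
    valid = calls[ok_depth & ok_minor]

    sample_index = {s: i for i, s in enumerate(samples)}
    cand_index = {int(p): j for j, p in enumerate(candidates)}
    for (sample, pos), base in valid.items():
        out[sample_index[sample], cand_index[int(pos)]] = base
    return out


# --------------------------------------------------------------------------- #
# matrix construction


def build_matrix(
    obs: ObservationSet,
    ref: Optional[ReferenceSequence],
    config: FilterConfig,
) -> VariantMatrix:
    """Assemble the filtered variable-position matrix.

    Pipeline: drop indel positions; drop STR-masked positions; call each
    sample at each remaining candidate position; drop positions with call
    rate below ``min_call_rate`` (whitelisted positions exempt); drop
    invariant positions. The analysable length L counts reference positions
    that are unmasked and covered by >= ceil(min_call_rate * n) samples.
    """
    table = obs.table
    samples = obs.samples or sorted(table["sample"].unique())
    n = len(samples)
    if n < 2:
        raise MalformedInputError("need at least 2 samples")

    diagnostics: dict = {"n_samples": n}

    masked_intervals: list[tuple[int, int]] = []
    if ref is not None:
        masked_intervals = mask_str_regions(ref, config)
    diagnostics["masked_intervals"] = masked_intervals

    if len(table):
        indel_positions = set(table.loc[table["is_indel"], "pos"].unique())
    else:
        indel_positions = set()
    diagnostics["n_indel_positions"] = len(indel_positions)

    candidates = np.array(sorted(set(table["pos"].unique()) - indel_positions))
    if candidates.size and masked_intervals:
        candidates = candidates[~_in_intervals(candidates, masked_intervals)]
    diagnostics["n_candidates"] = int(candidates.size)

    # per-sample calls (vectorised; call_sample_site is the scalar reference)
    alleles = np.full((n, candidates.size), MISSING, dtype="<U1")
    if candidates.size:
        alleles = _call_all(table, samples, candidates, config)

    call_rate = (alleles != MISSING).mean(axis=0) if candidates.size else np.array([])
    whitelisted = (
        np.isin(candidates, list(config.whitelist))
        if candidates.size
        else np.array([], dtype=bool)
    )
    keep_rate = (call_rate >= config.min_call_rate) | whitelisted
    variable = np.array(
        [len(set(col[col != MISSING])) >= 2 for col in alleles.T], dtype=bool
    ) if candidates.size else np.array([], dtype=bool)
    keep = keep_rate & variable
    diagnostics["n_dropped_call_rate"] = int((~keep_rate & variable).sum())
    diagnostics["n_dropped_invariant"] = int((~variable).sum())

    positions = candidates[keep] if candidates.size else candidates
    alleles = alleles[:, keep] if candidates.size else alleles

    if ref is not None:
        ancestral = np.array(
            [ref.seq[int(p)].tobytes().decode() for p in positions], dtype="<U1"
        )
    else:
        # fall back to majority allele as the putative ancestral state
        ancestral = np.array(
            [
                max(
                    ((a, (col == a).sum()) for a in set(col[col != MISSING])),
                    key=lambda kv: (kv[1], kv[0]),
                )[0]
                for col in alleles.T
            ],
            dtype="<U1",
        ) if positions.size else np.array([], dtype="<U1")

    L = _analysable_length(obs, ref, masked_intervals, config)
    diagnostics["region_length"] = L
    return VariantMatrix(
        samples=list(samples),
        positions=positions,
        alleles=alleles,
        ancestral=ancestral,
        region_length=L,
        diagnostics=diagnostics,
    )


def _analysable_length(
    obs: ObservationSet,
    ref: Optional[ReferenceSequence],
    masked_intervals: Sequence[tuple[int, int]],
    config: FilterConfig,
) -> int:
    """Length of the region covered by >= ceil(min_call_rate * n) samples
    and not STR-masked, via an interval sweep."""
    import math

    n = len(obs.coverage)
    if n == 0:
        return 0
    need = math.ceil(config.min_call_rate * n)
    events: list[tuple[int, int]] = []
    for intervals in obs.coverage.values():
        for s, e in intervals:
            events.append((s, 1))
            events.append((e, -1))
    for s, e in masked_intervals:
        events.append((s, -n))  # masking forces the count below any threshold
        events.append((e, n))
    events.sort()
    length = 0
    depth = 0
    prev = None
    for x, d in events:
        if prev is not None and depth >= need:
            length += x - prev
        depth += d
        prev = x
    if ref is not None:
        length = min(length, len(ref))
    return int(length)


# --------------------------------------------------------------------------- #
# rule sweeps with phylogenetic QC


def sweep_configs(
    obs: ObservationSet,
    ref: Optional[ReferenceSequence],
    configs: Sequence[FilterConfig],
    *,
    seed: int = 0,
    rf_flag_threshold: float = 0.15,
    search_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Build a matrix per config, run the parsimony search, and report
    phylogenetic quality: mean pairwise RF among co-optimal trees and the
    homoplasy count of the best tree. Configs whose mean RF exceeds the
    threshold are flagged as unreliable.
    """
    from itertools import combinations

    from .parsimony import homoplasy_count, mp_search
    from .tree import rf_distance

    if not configs:
        raise ValueError("empty config grid")
    search_kwargs = dict(search_kwargs or {})
    search_kwargs.setdefault("mode", "heuristic")
    rows = []
    for idx, cfg in enumerate(configs):
        row = {
            "config": idx,
            "preset": cfg.preset,
            "min_depth": cfg.min_depth,
            "min_base_quality": cfg.min_base_quality,
            "entropy_min": cfg.entropy_min,
            "min_call_rate": cfg.min_call_rate,
        }
        try:
            matrix = build_matrix(obs, ref, cfg)
            row["n_positions"] = matrix.n_positions
            if matrix.is_empty() or matrix.n_samples < 3:
                row.update(mean_rf=np.nan, homoplasies=np.nan, flagged=True)
            else:
                trees = mp_search(matrix, seed=seed, **search_kwargs)
                pairs = list(combinations(trees, 2))
                mean_rf = (
                    float(np.mean([rf_distance(a, b)[1] for a, b in pairs]))
                    if pairs
                    else 0.0
                )
                row["mean_rf"] = mean_rf
                row["n_cooptimal"] = len(trees)
                row["homoplasies"] = homoplasy_count(trees[0], matrix)
                row["flagged"] = mean_rf > rf_flag_threshold
        except Exception as exc:  # noqa: BLE001 - sweep must not abort
            row.update(error=str(exc), flagged=True)
        rows.append(row)
    return pd.DataFrame(rows)
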