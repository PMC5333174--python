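"""File formats: FASTA references, VCF / TSV site observations, alignments,
BED masks, CSV geo samples and STR panels, YAML rules and configs.

All coordinates are 0-based half-open in memory; VCF conversion adds/strips
the 1-based offset at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .filtering import MISSING, VariantMatrix
from .geomap import GeoSample
from .simulate import ObservationSet, ReferenceSequence
from .strpredict import PredictionRule, ReferencePanel, STRHaplotype

OBS_COLUMNS = [
    "sample", "pos", "base", "count", "base_quality", "mapping_quality", "is_indel",
]


# --------------------------------------------------------------------------- #
# FASTA


def write_fasta(ref: ReferenceSequence, path, name: str = "ref") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(str(ref)), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path) -> ReferenceSequence:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    seq = np.frombuffer(str(record.seq).upper().encode(), dtype="S1").copy()
    return ReferenceSequence(seq=seq, tracts=())


# --------------------------------------------------------------------------- #
# observation TSV dialect


def write_observations_tsv(obs: ObservationSet, path) -> None:
    obs.table[OBS_COLUMNS].to_csv(path, sep="\t", index=False)
    cov_path = Path(str(path)).with_suffix(".coverage.json")
    cov_path.write_text(
        json.dumps(
            {
                "samples": obs.samples,
                "coverage": {s: list(map(list, iv)) for s, iv in obs.coverage.items()},
            },
            indent=1,
        )
    )


def read_observations_tsv(path, coverage_path=None) -> ObservationSet:
    table = pd.read_csv(path, sep="\t")
    missing = set(OBS_COLUMNS[:6]) - set(table.columns)
    if missing:
        raise ValueError(f"TSV lacks columns: {sorted(missing)}")
    if "is_indel" not in table.columns:
        table["is_indel"] = False
    cov_path = Path(coverage_path) if coverage_path else Path(str(path)).with_suffix(
        ".coverage.json"
    )
    if cov_path.exists():
        blob = json.loads(cov_path.read_text())
        samples = blob["samples"]
        coverage = {
            s: tuple(tuple(iv) for iv in ivs) for s, ivs in blob["coverage"].items()
        }
    else:
        samples = sorted(table["sample"].unique())
        lo, hi = int(table["pos"].min()), int(table["pos"].max()) + 1
        coverage = {s: ((lo, hi),) for s in samples}
    return ObservationSet(table=table, coverage=coverage, samples=samples)


# --------------------------------------------------------------------------- #
# VCF (multi-sample, haploid) for matrices and observations


def write_matrix_vcf(matrix: VariantMatrix, path, contig: str = "chrY") -> None:
    """Write the filtered matrix as an uncompressed multi-sample VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##qphylo_region_length={matrix.region_length}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for j, pos in enumerate(matrix.positions):
        col = matrix.alleles[:, j]
        ref = matrix.ancestral[j]
        alts = sorted(set(col[(col != MISSING) & (col != ref)]))
        allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        gts = [
            "." if col[i] == MISSING else str(allele_index[col[i]])
            for i in range(len(matrix.samples))
        ]
        lines.append(
            f"{contig}\t{int(pos) + 1}\t.\t{ref}\t{','.join(alts) or '.'}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(str(path)).write_text("\n".join(lines) + "\n")


def read_matrix_vcf(path) -> VariantMatrix:
    """Read a matrix VCF written by :func:`write_matrix_vcf` (or any haploid
    multi-sample VCF with GT fields)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    region_length = 0
    for rec_line in str(vf.header).splitlines():
        if rec_line.startswith("##qphylo_region_length="):
            region_length = int(rec_line.split("=", 1)[1])
    positions, ancestral, columns = [], [], []
    for rec in vf:
        alleles = (rec.ref,) + tuple(rec.alts or ())
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            idx = gt[0] if gt else None
            if idx is None:
                col.append(MISSING)
            else:
                col.append(alleles[idx])
        positions.append(rec.pos - 1)
        ancestral.append(rec.ref)
        columns.append(col)
    alleles_arr = (
        np.array(columns, dtype="<U1").T
        if columns
        else np.empty((len(samples), 0), dtype="<U1")
    )
    return VariantMatrix(
        samples=samples,
        positions=np.array(positions, dtype=int),
        alleles=alleles_arr,
        ancestral=np.array(ancestral, dtype="<U1"),
        region_length=region_length,
    )


def read_observations_vcf(path) -> ObservationSet:
    """Read per-sample site evidence from a multi-sample VCF with AD (allelic
    depth) and optional GQ/MQ fields."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows = []
    positions = []
    for rec in vf:
        positions.append(rec.pos - 1)
        alleles = (rec.ref,) + tuple(rec.alts or ())
        mq = rec.info.get("MQ", 60.0)
        is_indel = any(len(a) != 1 for a in alleles if a)
        for s in samples:
            sample = rec.samples[s]
            ad = sample.get("AD")
            gq = sample.get("GQ", 60.0)
            if ad is None:
                gt = sample.get("GT")
                if gt and gt[0] is not None:
                    rows.append(
                        (s, rec.pos - 1, alleles[gt[0]], 1, float(gq), float(mq), is_indel)
                    )
                continue
            for allele, depth in zip(alleles, ad):
                if depth:
                    rows.append(
                        (s, rec.pos - 1, allele, int(depth), float(gq), float(mq), is_indel)
                    )
    table = pd.DataFrame(rows, columns=OBS_COLUMNS)
    lo = min(positions) if positions else 0
    hi = max(positions) + 1 if positions else 1
    coverage = {s: ((int(lo), int(hi)),) for s in samples}
    return ObservationSet(table=table, coverage=coverage, samples=samples)


# --------------------------------------------------------------------------- #
# alignment / sites table / BED


def write_alignment(matrix: VariantMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            fh.write(f"{sample}\t{''.join(matrix.alleles[i])}\n")


def write_sites_table(matrix: VariantMatrix, path) -> None:
    rate = matrix.call_rate() if matrix.n_positions else np.array([])
    rows = []
    for j, pos in enumerate(matrix.positions):
        col = matrix.alleles[:, j]
        alleles = sorted(set(col[col != MISSING]))
        rows.append(
            {
                "pos": int(pos),
                "ref": matrix.ancestral[j],
                "alleles": ",".join(alleles),
                "call_rate": round(float(rate[j]), 4),
            }
        )
    pd.DataFrame(rows, columns=["pos", "ref", "alleles", "call_rate"]).to_csv(
        path, sep="\t", index=False
    )


def write_bed(intervals: Sequence[tuple[int, int]], path, name: str = "chrY") -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{name}\t{s}\t{e}\n")


# --------------------------------------------------------------------------- #
# geo samples and STR CSV


def read_geo_csv(path) -> list[GeoSample]:
    df = pd.read_csv(path)
    need = {"label", "lat", "lon", "n", "k"}
    if not need <= set(df.columns):
        raise ValueError(f"geo CSV needs columns {sorted(need)}")
    return [
        GeoSample(
            label=str(r.label), lat=float(r.lat), lon=float(r.lon),
            n=int(r.n), k=int(r.k),
        )
        for r in df.itertuples(index=False)
    ]


def write_geo_csv(samples: Sequence[GeoSample], path) -> None:
    pd.DataFrame(
        [
            {"label": s.label, "lat": s.lat, "lon": s.lon, "n": s.n, "k": s.k}
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_str_csv(path) -> list[STRHaplotype]:
    """CSV with a 'sample' column (and optional 'branch') plus one column per
    marker; multi-copy loci as dash-separated values (e.g. '11-14')."""
    df = pd.read_csv(path)
    marker_cols = [c for c in df.columns if c not in ("sample", "branch")]
    out = []
    for r in df.itertuples(index=False):
        repeats = {}
        for m in marker_cols:
            raw = getattr(r, m)
            if pd.isna(raw):
                continue
            if isinstance(raw, str) and "-" in raw:
                repeats[m] = tuple(int(x) for x in raw.split("-"))
            else:
                repeats[m] = int(raw)
        out.append(STRHaplotype(sample_id=str(r.sample), repeats=repeats))
    return out


def read_reference_panel_csv(path) -> ReferencePanel:
    df = pd.read_csv(path)
    if "branch" not in df.columns:
        raise ValueError("reference panel CSV needs a 'branch' column")
    haplotypes = read_str_csv(path)
    panel = ReferencePanel()
    for h, branch in zip(haplotypes, df["branch"]):
        panel.add(h, str(branch))
    return panel


def write_str_csv(haplotypes: Sequence[STRHaplotype], path,
                  branches: Optional[dict[str, str]] = None) -> None:
    markers = sorted({m for h in haplotypes for m in h.repeats})
    rows = []
    for h in haplotypes:
        row = {"sample": h.sample_id}
        if branches is not None:
            row["branch"] = branches.get(h.sample_id, "")
        for m in markers:
            v = h.repeats.get(m)
            if v is None:
                row[m] = ""
            elif isinstance(v, tuple):
                row[m] = "-".join(str(x) for x in v)
            else:
                row[m] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# rules YAML


def read_rules_yaml(path) -> list[PredictionRule]:
    blob = yaml.safe_load(Path(str(path)).read_text())
    rules = []
    for entry in blob.get("rules", []):
        constraints = {
            m: (int(lo), int(hi)) for m, (lo, hi) in entry["constraints"].items()
        }
        rules.append(
            PredictionRule(
                label=entry["label"],
                constraints=constraints,
                min_markers_matched=int(entry.get("min_markers_matched", 1)),
            )
        )
    return rules


def write_rules_yaml(rules: Sequence[PredictionRule], path) -> None:
    blob = {
        "rules": [
            {
                "label": r.label,
                "constraints": {m: list(c) for m, c in r.constraints.items()},
                "min_markers_matched": r.min_markers_matched,
            }
            for r in rules
        ]
    }
    Path(str(path)).write_text(yaml.safe_dump(blob, sort_keys=True))
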