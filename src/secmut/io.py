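"""Plain-text readers and writers for the pipeline's tables.

Formats: MAF-like TSV and minimal VCF 4.2 for mutation catalogs, long-format
TSV for microsatellite repeat-length counts, BED-like TSV for exon statistics
(0-based half-open), SEG-style TSV for segment calls, genes-by-samples TSV for
expression, and a JSON sidecar for simulation ground truth.  Every writer has
a matching reader and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .records import (
    ExonStat,
    MicrosatelliteLocus,
    MutationRecord,
    RepeatLengthDistribution,
    Segment,
)
from .synthetic_data import SimulationTruth

PathLike = Union[str, Path]

_MAF_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_class", "context",
    "tumor_depth", "normal_depth", "tumor_alt_depth", "normal_alt_depth",
    "mq0_reads", "alt_fwd", "alt_rev", "mismatch_quality_sum",
    "avg_mismatches", "dist_to_3prime", "somatic_score", "genotype_quality",
    "gene", "consequence", "origin",
]


def write_maf(records: Sequence[MutationRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _MAF_COLUMNS}
        row["alt_allele_support"] = (
            json.dumps(r.alt_allele_support) if r.alt_allele_support else ""
        )
        if r.truth_failed is None:
            row["truth_failed"] = ""
        else:  # "-" marks a present-but-empty label (passes every filter)
            row["truth_failed"] = ",".join(sorted(r.truth_failed)) or "-"
        rows.append(row)
    pd.DataFrame(rows, columns=_MAF_COLUMNS + ["alt_allele_support", "truth_failed"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_maf(path: PathLike) -> list[MutationRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    records = []
    for row in df.to_dict("records"):
        support = row.pop("alt_allele_support", "")
        truth = row.pop("truth_failed", "")
        kwargs = {}
        for key, val in row.items():
            if pd.isna(val):
                kwargs[key] = None
            elif key in {"pos", "tumor_depth", "normal_depth", "tumor_alt_depth",
                         "normal_alt_depth", "mq0_reads", "alt_fwd", "alt_rev"}:
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        if isinstance(support, str) and support:
            kwargs["alt_allele_support"] = json.loads(support)
        if isinstance(truth, str) and truth:
            kwargs["truth_failed"] = (
                frozenset() if truth == "-" else frozenset(truth.split(","))
            )
        records.append(MutationRecord(**kwargs))
    return records


def write_vcf(
    records: Sequence[MutationRecord],
    path: PathLike,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Minimal VCF 4.2 with per-site metrics as INFO and failed filters in FILTER."""
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    for name in ("DPT", "DPN", "ADT", "ADN", "MQ0", "SAF", "SAR"):
        lines.append(
            f'##INFO=<ID={name},Number=1,Type=Integer,Description="{name}">'
        )
    for name in ("MMQS", "AMM", "DETP", "SS", "GQX"):
        lines.append(
            f'##INFO=<ID={name},Number=1,Type=Float,Description="{name}">'
        )
    lines.append('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">')
    for f in ("conf", "dp", "mq0", "sb", "mmqs", "amm", "detp", "ad", "gad", "ma"):
        lines.append(f'##FILTER=<ID={f},Description="Site filter {f}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def _info(r: MutationRecord) -> str:
        pairs = [
            ("DPT", r.tumor_depth), ("DPN", r.normal_depth),
            ("ADT", r.tumor_alt_depth), ("ADN", r.normal_alt_depth),
            ("MQ0", r.mq0_reads), ("SAF", r.alt_fwd), ("SAR", r.alt_rev),
            ("MMQS", r.mismatch_quality_sum), ("AMM", r.avg_mismatches),
            ("DETP", r.dist_to_3prime), ("SS", r.somatic_score),
            ("GQX", r.genotype_quality), ("VC", r.variant_class),
        ]
        return ";".join(f"{k}={v}" for k, v in pairs if v is not None) or "."

    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if r.failed_filters is None:
            filt = "."
        elif not r.failed_filters:
            filt = "PASS"
        else:
            filt = ";".join(sorted(r.failed_filters))
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t{_info(r)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_loci(loci: Sequence[MicrosatelliteLocus], path: PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(l) for l in loci]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_loci(path: PathLike) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "locus_id": str},
        float_precision="round_trip",
    )
    return [MicrosatelliteLocus(**row) for row in df.to_dict("records")]


def write_repeat_counts(
    dists: dict[str, RepeatLengthDistribution], path: PathLike, sample: str
) -> None:
    rows = [
        {"sample": sample, "locus_id": lid, "repeat_length": length, "read_count": c}
        for lid, dist in sorted(dists.items())
        for length, c in sorted(dist.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample", "locus_id", "repeat_length", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_repeat_counts(path: PathLike) -> dict[str, RepeatLengthDistribution]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    out: dict[str, RepeatLengthDistribution] = {}
    for lid, grp in df.groupby("locus_id"):
        out[str(lid)] = RepeatLengthDistribution(
            str(lid),
            {int(r.repeat_length): int(r.read_count) for r in grp.itertuples()},
        )
    return out


def write_exon_stats(exons: Sequence[ExonStat], path: PathLike) -> None:
    rows = [
        {
            "chrom": e.chrom, "start": e.start, "end": e.end,
            "rc_mean": e.rc_mean, "rc_sd": e.rc_sd,
            "af_t": ";".join(f"{v:.6g}" for v in e.af_t),
            "af_n": ";".join(f"{v:.6g}" for v in e.af_n),
        }
        for e in exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exon_stats(path: PathLike) -> list[ExonStat]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExonStat(
                str(row.chrom), int(row.start), int(row.end),
                float(row.rc_mean), float(row.rc_sd),
                af_t=[float(v) for v in str(row.af_t).split(";") if v],
                af_n=[float(v) for v in str(row.af_n).split(";") if v],
            )
        )
    return out


def write_segments(segments: Sequence[Segment], path: PathLike) -> None:
    """SEG-style TSV of segment calls."""
    rows = []
    for s in segments:
        rows.append(
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "n_exons": s.n_exons, "n_het_snps": s.n_het_snps,
                "rc_mean": s.rc_mean, "rc_sd": s.rc_sd,
                "af_corr": "" if s.af_corr is None else s.af_corr,
                "state": s.state.label() if s.state else "",
                "deviation_p": "" if s.deviation_p is None else s.deviation_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_truth(truth: SimulationTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2) + "\n")


def read_truth(path: PathLike) -> SimulationTruth:
    data = json.loads(Path(path).read_text())
    data["segment_truth"] = [tuple(s) for s in data.get("segment_truth", [])]
    return SimulationTruth(**data)
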