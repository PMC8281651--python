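"""Readers and writers for the pipeline's tabular formats.

Variants come in either as VCF (alt/depth pulled from the AD/DP FORMAT
fields via cyvcf2) or as a documented TSV dialect; copy-number segments as
a SEG-like TSV; expression and methylation as genes/CpGs x samples TSV
matrices.  All writers emit plain TSV so outputs stay diff-able.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .clonality import CopySegment, VariantObservation

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "alt_count", "depth",
    "gene", "consequence", "sift", "polyphen", "cancer_gene",
]

SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end",
    "total_cn", "major_cn", "minor_cn", "cellular_fraction",
]


def read_variants_tsv(path: str | Path) -> list[VariantObservation]:
    """Read the variant TSV dialect (one row per variant per sample).

    Required columns: sample_id, chrom, pos, ref, alt, alt_count, depth.
    Optional: gene, consequence, sift, polyphen, cancer_gene (0/1).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise ValueError(f"malformed variant table {path}: {exc}") from exc
    required = {"sample_id", "chrom", "pos", "ref", "alt", "alt_count", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantObservation(
                    sample_id=str(row["sample_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    alt_count=int(row["alt_count"]),
                    depth=int(row["depth"]),
                    gene=None if pd.isna(row.get("gene")) else str(row["gene"]),
                    consequence=None
                    if pd.isna(row.get("consequence"))
                    else str(row["consequence"]),
                    sift=None if pd.isna(row.get("sift")) else str(row["sift"]),
                    polyphen=None
                    if pd.isna(row.get("polyphen"))
                    else str(row["polyphen"]),
                    cancer_gene=bool(row.get("cancer_gene", False))
                    and not pd.isna(row.get("cancer_gene")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_variants_tsv(
    variants: Iterable[VariantObservation], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "alt_count": v.alt_count,
            "depth": v.depth, "gene": v.gene, "consequence": v.consequence,
            "sift": v.sift, "polyphen": v.polyphen,
            "cancer_gene": int(v.cancer_gene),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantObservation]:
    """Read somatic variants from a VCF; alt/depth from the AD field.

    Single-sample VCFs only unless ``sample_id`` picks a column.  The gene
    symbol is taken from a GENE INFO key when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError(
                f"{path} has {len(samples)} samples; pass sample_id to pick one"
            )
        sample_id = samples[0]
    try:
        idx = samples.index(sample_id)
    except ValueError as exc:
        raise ValueError(f"sample {sample_id} not in {path}") from exc

    out = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD")
        ref_count, alt_count = int(ad[idx][0]), int(ad[idx][1])
        depth = ref_count + alt_count
        if depth <= 0:
            continue
        gene = rec.INFO.get("GENE")
        out.append(
            VariantObservation(
                sample_id=sample_id,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                alt_count=alt_count,
                depth=depth,
                gene=gene,
            )
        )
    return out


def read_segments_tsv(path: str | Path) -> list[CopySegment]:
    """Read a SEG-like allele-specific copy-number table."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed segment table {path}: {exc}") from exc
    missing = set(SEGMENT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            cf = row.get("cellular_fraction")
            out.append(
                CopySegment(
                    sample_id=str(row["sample_id"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    total_cn=int(row["total_cn"]),
                    major_cn=int(row["major_cn"]),
                    minor_cn=int(row["minor_cn"]),
                    cellular_fraction=None if pd.isna(cf) else float(cf),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_segments_tsv(segments: Iterable[CopySegment], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
            "end": s.end, "total_cn": s.total_cn, "major_cn": s.major_cn,
            "minor_cn": s.minor_cn, "cellular_fraction": s.cellular_fraction,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix (first column = feature id)."""
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed matrix {path}: {exc}") from exc


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_annotation_tsv(path: str | Path) -> dict[str, str | None]:
    """CpG -> gene annotation (columns: cpg_id, gene; empty gene = None)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cpg_id", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns cpg_id, gene")
    return {
        str(r["cpg_id"]): (None if pd.isna(r["gene"]) else str(r["gene"]))
        for _, r in df.iterrows()
    }


def read_signatures_tsv(path: str | Path) -> dict[str, list[str]]:
    """Population signatures (columns: population, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"population", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns population, gene")
    sigs: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        sigs.setdefault(str(r["population"]), []).append(str(r["gene"]))
    return sigs


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: patient, sample, site, purity, dataset + layer paths."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "sample": str})
    required = {"patient", "sample", "site", "purity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "dataset" not in df.columns:
        df["dataset"] = "cohort"
    return df
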