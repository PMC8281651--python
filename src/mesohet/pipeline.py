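"""End-to-end per-patient orchestration of the heterogeneity analyses.

A YAML config names a sample sheet (two biopsies per patient) plus
cohort-level matrices and resources; ``run_pipeline`` executes, for every
patient, whichever stages have their inputs available — clonality,
expression, methylation, pathways, microenvironment — writes each stage's
tidy TSV next to a machine-readable per-patient report JSON, and returns
the reports.  Runs are deterministic: the same config and inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .clonality import (
    build_clonal_tree,
    calls_to_frame,
    classify_variant,
    detect_shared_subclone,
    estimate_ccf,
    match_and_classify_cnv,
)
from .expression import (
    ExpressionPair,
    call_de_genes,
    deconvolve_es,
    es_heterogeneity,
    predict_subtype,
)
from .methylation import (
    MethylationPair,
    call_dm_cpg,
    de_dm_genes,
    direction_consistency_filter,
)
from .microenv import (
    SignatureSet,
    checkpoint_de,
    hot_cold_assign,
    mcp_scores,
    paired_population_test,
    refine_signatures,
    standardize_per_dataset,
)
from .pathways import delta_ssgsea, ora, read_gmt_collection, ssgsea_scores

logger = logging.getLogger("mesohet")

REPORT_SCHEMA_VERSION = "1.0"

DEFAULT_THRESHOLDS = {
    "ccf_subclonal": 0.5,
    "ci_limit": 1.0,
    "vst_delta": 1.0,
    "beta_delta": 0.2,
    "detection_p": 0.05,
    "fdr": 0.05,
    "fold_change": 2.0,
    "es_heterogeneity": 0.10,
    "fpkm_min": 1.0,
    "min_shared_subclone_variants": 2,
}

VALID_SITES = {"A", "B", "C", "D"}


class ValidationError(Exception):
    """Fatal input-validation failure."""


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def select_pair(samples: pd.DataFrame) -> pd.DataFrame:
    """Among >2 samples of a patient, keep the pair with the closest purity."""
    if len(samples) <= 2:
        return samples
    best = None
    best_diff = np.inf
    rows = samples.reset_index(drop=True)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            diff = abs(rows.loc[i, "purity"] - rows.loc[j, "purity"])
            if diff < best_diff:
                best_diff = diff
                best = rows.loc[[i, j]]
    return best


def validate_inputs(
    sheet: pd.DataFrame,
    fpkm: pd.DataFrame | None = None,
    vst: pd.DataFrame | None = None,
    min_gene_overlap: float = 0.9,
) -> ValidationReport:
    """Check pairing, purity ranges and cross-layer gene-universe agreement."""
    report = ValidationReport()
    for patient, group in sheet.groupby("patient"):
        if len(group) != 2:
            report.warnings.append(
                f"patient {patient} has {len(group)} samples; paired analyses "
                "need exactly 2 (patient will be skipped)"
            )
    bad_purity = sheet[(sheet["purity"] <= 0) | (sheet["purity"] > 1)]
    for _, row in bad_purity.iterrows():
        report.errors.append(
            f"sample {row['sample']}: purity {row['purity']} outside (0, 1]"
        )
    bad_site = sheet[~sheet["site"].isin(VALID_SITES)]
    for _, row in bad_site.iterrows():
        report.errors.append(
            f"sample {row['sample']}: site {row['site']!r} not in "
            f"{sorted(VALID_SITES)}"
        )
    if fpkm is not None and vst is not None:
        overlap = len(fpkm.index.intersection(vst.index)) / max(
            len(fpkm.index.union(vst.index)), 1
        )
        if overlap < min_gene_overlap:
            report.errors.append(
                f"FPKM/VST gene universes overlap only {overlap:.0%} "
                f"(< {min_gene_overlap:.0%})"
            )
        for df, name in ((fpkm, "FPKM"), (vst, "VST")):
            missing = set(sheet["sample"]) - set(df.columns)
            if missing:
                report.warnings.append(
                    f"{name} matrix lacks columns for samples {sorted(missing)}"
                )
    return report


def _load_config(config_path: str | Path) -> dict:
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "sample_sheet" not in cfg:
        raise ValidationError(f"{config_path}: config must define sample_sheet")
    base = config_path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    cfg["sample_sheet"] = _resolve(cfg["sample_sheet"])
    cfg["outdir"] = _resolve(cfg.get("outdir", "mesohet_out"))
    cfg["paths"] = {k: _resolve(v) for k, v in (cfg.get("paths") or {}).items()}
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds") or {})
    cfg["thresholds"] = thresholds
    cfg.setdefault("seed", 0)
    cfg.setdefault("checkpoint_genes", [])
    return cfg


def _clonality_stage(patient, pair_rows, variants, segments, thr, outdir):
    sample_a, sample_b = pair_rows["sample"].tolist()
    purity = dict(zip(pair_rows["sample"], pair_rows["purity"]))
    by_key: dict[str, dict[str, object]] = {}
    meta: dict[str, dict] = {}
    for v in variants:
        if v.sample_id not in (sample_a, sample_b):
            continue
        by_key.setdefault(v.key, {})[v.sample_id] = v
        meta.setdefault(v.key, {"gene": v.gene, "cancer_gene": v.cancer_gene})

    seg_by_sample: dict[str, list] = {sample_a: [], sample_b: []}
    for s in segments:
        if s.sample_id in seg_by_sample:
            seg_by_sample[s.sample_id].append(s)

    def _covering(sample, v):
        for s in seg_by_sample[sample]:
            if s.chrom == v.chrom and s.start <= v.pos <= s.end:
                return s
        return None

    calls = []
    for key in sorted(by_key):
        ests = {}
        for sample in (sample_a, sample_b):
            v = by_key[key].get(sample)
            if v is None:
                ests[sample] = None
                continue
            ests[sample] = estimate_ccf(
                v, purity[sample], segment=_covering(sample, v)
            )
        calls.append(
            classify_variant(
                ests[sample_a],
                ests[sample_b],
                key=key,
                ccf_threshold=thr["ccf_subclonal"],
                ci_limit=thr["ci_limit"],
                gene=meta[key]["gene"],
                cancer_gene=meta[key]["cancer_gene"],
            )
        )
    cnv_calls, homdels = [], []
    if seg_by_sample[sample_a] or seg_by_sample[sample_b]:
        cnv_calls, homdels = match_and_classify_cnv(
            seg_by_sample[sample_a],
            seg_by_sample[sample_b],
            purity[sample_a],
            purity[sample_b],
            ccf_threshold=thr["ccf_subclonal"],
        )
    all_calls = calls + cnv_calls
    frame = calls_to_frame(all_calls)
    frame.to_csv(outdir / f"{patient}.clonality.tsv", sep="\t", index=False)
    subclone = detect_shared_subclone(
        calls, min_variants=thr["min_shared_subclone_variants"]
    )
    tree = build_clonal_tree(all_calls, site_a=sample_a, site_b=sample_b)
    with open(outdir / f"{patient}.clonal_tree.json", "w") as fh:
        json.dump(tree, fh, indent=1, sort_keys=True)
    counts = frame[frame["kind"] == "variant"]["category"].value_counts().to_dict()
    return {
        "category_counts": {
            cat: int(counts.get(cat, 0))
            for cat in (
                "clonal_shared", "subclonal_shared",
                "clonal_private", "subclonal_private",
            )
        },
        "shared_subclone": {
            "flag": subclone.flag,
            "supporting_variants": subclone.supporting_variants,
            "cancer_gene_members": subclone.cancer_gene_members,
            "cnv_support": subclone.cnv_support,
        },
        "n_cnv_calls": len(cnv_calls),
        "n_homozygous_deletions": len(homdels),
        "clonal_tree": tree,
    }


def run_pipeline(config_path: str | Path) -> dict[str, dict]:
    """Run every stage whose inputs are configured, for every valid patient.

    Returns ``{patient: report}``; the same reports are written as JSON under
    ``outdir`` along with per-stage TSV tables and a run manifest recording
    the package version, seed and thresholds.
    """
    cfg = _load_config(config_path)
    thr = cfg["thresholds"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    paths = cfg["paths"]

    sheet = mio.read_sample_sheet(cfg["sample_sheet"])
    fpkm = mio.read_matrix_tsv(paths["fpkm"]) if "fpkm" in paths else None
    vst = mio.read_matrix_tsv(paths["vst"]) if "vst" in paths else None
    validation = validate_inputs(sheet, fpkm, vst)
    for w in validation.warnings:
        logger.warning(w)
    if not validation.ok:
        raise ValidationError("; ".join(validation.errors))

    beta = mio.read_matrix_tsv(paths["beta"]) if "beta" in paths else None
    detp = (
        mio.read_matrix_tsv(paths["detection_p"])
        if "detection_p" in paths
        else None
    )
    annotation = (
        mio.read_annotation_tsv(paths["cpg_annotation"])
        if "cpg_annotation" in paths
        else None
    )
    profiles = (
        mio.read_matrix_tsv(paths["profiles"]) if "profiles" in paths else None
    )
    es_table = None
    if "es_correlated" in paths:
        df = pd.read_csv(paths["es_correlated"], sep="\t", dtype=str)
        es_table = dict(zip(df["gene"], df["pole"]))
    collection = None
    if "gene_sets" in paths and vst is not None:
        collection = read_gmt_collection(paths["gene_sets"], set(vst.index))
    signatures = None
    if "signatures" in paths:
        signatures = SignatureSet(mio.read_signatures_tsv(paths["signatures"]))
        if "cell_line_fpkm" in paths:
            signatures = refine_signatures(
                signatures,
                mio.read_matrix_tsv(paths["cell_line_fpkm"]),
                expr_threshold=thr["fpkm_min"],
                exclude=cfg.get("signature_exclude", []),
            )

    manifest = {
        "version": __version__,
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg["seed"],
        "thresholds": thr,
        "stages": sorted(paths),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    pairs: dict[str, tuple[str, str]] = {}
    pair_rows_by_patient: dict[str, pd.DataFrame] = {}
    for patient, group in sheet.groupby("patient", sort=True):
        if len(group) != 2:
            logger.warning(
                "skipping patient %s: %d tumor samples (need exactly 2)",
                patient, len(group),
            )
            continue
        group = group.sort_values("site")
        pairs[patient] = tuple(group["sample"].tolist())
        pair_rows_by_patient[patient] = group

    # cohort-level microenvironment (needs all samples at once)
    microenv_cohort = None
    if signatures is not None and fpkm is not None:
        samples = [s for p in pairs.values() for s in p if s in fpkm.columns]
        log2 = np.log2(fpkm[samples] + 1.0)
        scores = mcp_scores(log2, signatures)
        datasets = dict(zip(sheet["sample"], sheet["dataset"]))
        standardized = standardize_per_dataset(scores, datasets)
        mio.write_matrix_tsv(scores, outdir / "microenv_scores.tsv", "population")
        mio.write_matrix_tsv(
            standardized, outdir / "microenv_scores_standardized.tsv", "population"
        )
        usable_pairs = {
            p: ab for p, ab in pairs.items() if all(s in scores.columns for s in ab)
        }
        hotcold = hot_cold_assign(standardized, usable_pairs)
        hotcold.labels.to_frame().to_csv(outdir / "immune_profiles.tsv", sep="\t")
        microenv_cohort = (scores, standardized, hotcold)

    ssgsea = None
    if collection is not None and vst is not None:
        samples = [s for p in pairs.values() for s in p if s in vst.columns]
        ssgsea = ssgsea_scores(
            vst[samples], collection, fpkm=fpkm[samples] if fpkm is not None else None,
            fpkm_min=thr["fpkm_min"],
        )
        mio.write_matrix_tsv(ssgsea, outdir / "ssgsea_scores.tsv", "set")

    reports: dict[str, dict] = {}
    for patient, pair_rows in pair_rows_by_patient.items():
        sample_a, sample_b = pairs[patient]
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "patient": patient,
            "samples": {"A": sample_a, "B": sample_b},
            "stages": {},
        }

        variants, segments = [], []
        var_paths = {
            Path(p) for p in pair_rows.get("variants", pd.Series(dtype=str)).dropna()
        } if "variants" in pair_rows else set()
        for vp in sorted(var_paths):
            variants.extend(
                mio.read_variants_vcf(vp)
                if str(vp).endswith(".vcf")
                else mio.read_variants_tsv(vp)
            )
        seg_paths = {
            Path(p) for p in pair_rows.get("segments", pd.Series(dtype=str)).dropna()
        } if "segments" in pair_rows else set()
        for sp in sorted(seg_paths):
            segments.extend(mio.read_segments_tsv(sp))
        if variants:
            report["stages"]["clonality"] = _clonality_stage(
                patient, pair_rows, variants, segments, thr, outdir
            )

        de_frame = None
        es_delta = None
        if fpkm is not None and vst is not None and all(
            s in fpkm.columns and s in vst.columns for s in (sample_a, sample_b)
        ):
            pair = ExpressionPair(
                fpkm=fpkm[[sample_a, sample_b]], vst=vst[[sample_a, sample_b]]
            )
            de_frame = call_de_genes(
                pair, fpkm_min=thr["fpkm_min"], vst_delta=thr["vst_delta"]
            )
            de_frame.to_csv(outdir / f"{patient}.de_genes.tsv", sep="\t", index=False)
            expr_report = {"n_de_genes": int(len(de_frame))}
            if profiles is not None and {"E", "S"} <= set(profiles.columns):
                scores = {}
                for s in (sample_a, sample_b):
                    scores[s] = deconvolve_es(
                        vst[s], profiles["E"], profiles["S"]
                    )
                flag, delta = es_heterogeneity(
                    scores[sample_a], scores[sample_b],
                    threshold=thr["es_heterogeneity"],
                )
                es_delta = scores[sample_a].e_score - scores[sample_b].e_score
                expr_report["es_scores"] = {
                    s: {"e_score": sc.e_score, "s_score": sc.s_score}
                    for s, sc in scores.items()
                }
                expr_report["es_heterogeneity"] = {"flag": flag, "delta": delta}
                expr_report["subtype"] = {
                    s: predict_subtype(vst[s], profiles) for s in (sample_a, sample_b)
                }
            report["stages"]["expression"] = expr_report

        if beta is not None and detp is not None and annotation is not None and all(
            s in beta.columns for s in (sample_a, sample_b)
        ):
            mpair = MethylationPair(
                betas=beta[[sample_a, sample_b]],
                detection_p=detp[[sample_a, sample_b]],
                annotation=annotation,
            )
            dm = call_dm_cpg(
                mpair, p_max=thr["detection_p"], beta_delta=thr["beta_delta"]
            )
            dm.to_csv(outdir / f"{patient}.dm_cpgs.tsv", sep="\t", index=False)
            meth_report = {"n_dm_cpgs": int(len(dm))}
            if de_frame is not None:
                de_set = set(de_frame["gene"])
                de_dm, pct = de_dm_genes(de_set, set(dm["cpg"]), annotation)
                meth_report["n_de_dm_genes"] = len(de_dm)
                meth_report["pct_de_with_dm"] = pct
                if es_table is not None and es_delta is not None:
                    signs = dict(zip(de_frame["gene"], de_frame["sign"]))
                    kept, prop, n_un = direction_consistency_filter(
                        {g: signs[g] for g in de_dm}, es_table, es_delta
                    )
                    meth_report["direction_consistent"] = {
                        "n_consistent": len(kept),
                        "proportion": prop,
                        "n_unannotated": n_un,
                    }
            report["stages"]["methylation"] = meth_report

        if collection is not None and de_frame is not None:
            res = ora(set(de_frame["gene"]), collection, fdr_max=thr["fdr"])
            res.to_csv(outdir / f"{patient}.ora.tsv", sep="\t", index=False)
            pw_report = {
                "significant_pathways": res.loc[res["significant"], "set"].tolist()
            }
            if ssgsea is not None and all(
                s in ssgsea.columns for s in (sample_a, sample_b)
            ):
                deltas = delta_ssgsea(ssgsea, {patient: (sample_a, sample_b)})
                top = (
                    deltas[patient]
                    .sort_values(ascending=False, kind="mergesort")
                    .head(5)
                )
                pw_report["top_delta_ssgsea"] = {
                    k: float(v) for k, v in top.items()
                }
            report["stages"]["pathways"] = pw_report

        if microenv_cohort is not None:
            scores, standardized, hotcold = microenv_cohort
            if all(s in scores.columns for s in (sample_a, sample_b)):
                stat, p = paired_population_test(
                    scores[sample_a], scores[sample_b]
                )
                me_report = {
                    "labels": {
                        sample_a: hotcold.labels.get(sample_a),
                        sample_b: hotcold.labels.get(sample_b),
                    },
                    "mixed_pair": patient in hotcold.mixed_pairs,
                    "wilcoxon": {"statistic": stat, "p": p},
                }
                if cfg["checkpoint_genes"] and fpkm is not None:
                    ck = checkpoint_de(
                        fpkm[sample_a], fpkm[sample_b], cfg["checkpoint_genes"],
                        fpkm_min=thr["fpkm_min"], fc_min=thr["fold_change"],
                    )
                    ck.to_csv(
                        outdir / f"{patient}.checkpoints.tsv", sep="\t", index=False
                    )
                    me_report["checkpoint_flags"] = ck.loc[ck["flag"], "gene"].tolist()
                report["stages"]["microenvironment"] = me_report

        with open(outdir / f"{patient}.report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        reports[patient] = report

    logger.info(
        "pipeline v%s complete: %d patients, seed %s",
        __version__, len(reports), cfg["seed"],
    )
    return reports
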