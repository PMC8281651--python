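"""Write a full synthetic multi-site cohort to disk in pipeline formats.

Bundles the per-patient generators into a cohort: clone structures and
reads per patient, cohort-wide expression and methylation matrices, immune
signatures and a tumor cell-line panel, a small gene-set collection, the
E/S reference profiles, a sample sheet and a ready-to-run pipeline config
— plus a truth JSON for test harnesses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clonality import CopySegment
from .synthetic import (
    SCENARIOS,
    build_truth,
    make_immune_signatures,
    make_reference_profiles,
    simulate_clone_structure,
    simulate_expression_pair,
    simulate_methylation_pair,
    simulate_variant_reads,
)

__all__ = ["simulate_cohort"]


def _write_gmt(sets: dict[str, list[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "synthetic"] + sorted(sets[name])) + "\n")


def simulate_cohort(
    outdir: str | Path,
    n_patients: int = 8,
    seed: int = 0,
    n_trunk_mut: int = 10,
    n_subclones: int = 2,
    muts_per_subclone: int = 5,
    mean_depth: int = 500,
    n_genes: int = 1500,
    n_cpg: int = 2000,
    purity_range: tuple[float, float] = (0.3, 0.9),
    noise_sd: float = 0.3,
    n_hot: int | None = None,
) -> Path:
    """Simulate a paired-biopsy cohort and write it in pipeline formats.

    Patients cycle through the clonal scenarios (mixed, shared_subclone,
    private_subclones).  Half the patients (rounded up) are given an
    elevated immune component (hot profile candidates) unless ``n_hot``
    overrides it.  Returns the path of the written pipeline config; the
    ground truth lands in ``truth.json`` alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    e_profile, s_profile = make_reference_profiles(n_genes, seed=seed)
    genes = list(e_profile.index)
    signatures = make_immune_signatures(genes, seed=seed)
    populations = sorted(signatures)
    if n_hot is None:
        n_hot = (n_patients + 1) // 2

    # tumor cell-line panel: signature markers silent, other genes expressed
    lines = [f"CL{i:02d}" for i in range(22)]
    marker_genes = {g for gs in signatures.values() for g in gs}
    cl = pd.DataFrame(
        rng.uniform(2, 50, size=(n_genes, len(lines))), index=genes, columns=lines
    )
    cl.loc[sorted(marker_genes)] = rng.uniform(0, 0.5, size=(len(marker_genes), len(lines)))
    mio.write_matrix_tsv(cl, outdir / "cell_line_fpkm.tsv", "gene")

    # gene sets: random slices of the universe
    sets = {}
    for i in range(12):
        size = int(rng.integers(15, 60))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET_{i:02d}"] = sorted(members)
    _write_gmt(sets, outdir / "gene_sets.gmt")

    profiles = pd.DataFrame({"E": e_profile, "S": s_profile})
    mio.write_matrix_tsv(profiles, outdir / "es_profiles.tsv", "gene")

    # genes correlated with the E or S pole, from the profile contrast
    contrast = e_profile - s_profile
    es_rows = [
        {"gene": g, "pole": "E" if contrast[g] > 0.5 else "S"}
        for g in genes
        if abs(contrast[g]) > 0.5
    ]
    pd.DataFrame(es_rows).to_csv(outdir / "es_correlated.tsv", sep="\t", index=False)

    sig_rows = [
        {"population": pop, "gene": g}
        for pop in populations
        for g in signatures[pop]
    ]
    pd.DataFrame(sig_rows).to_csv(outdir / "signatures.tsv", sep="\t", index=False)

    sheet_rows = []
    fpkm_cols, vst_cols, beta_cols, detp_cols = {}, {}, {}, {}
    annotation = None
    truth_out = {}
    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        scenario = SCENARIOS[p % len(SCENARIOS)]
        pseed = int(rng.integers(2**31 - 1))
        tree, comps = simulate_clone_structure(
            n_trunk_mut, n_subclones, muts_per_subclone, scenario,
            seed=pseed, purity_range=purity_range,
        )
        truth = build_truth(tree, comps)
        reads = simulate_variant_reads(truth, mean_depth=mean_depth, seed=pseed + 1)

        sample_ids = {s: f"{patient}_{s}" for s in truth.sites}
        variants = []
        for site, obs in reads.items():
            for v in obs:
                variants.append(
                    type(v)(
                        sample_id=sample_ids[site], chrom=v.chrom, pos=v.pos,
                        ref=v.ref, alt=v.alt, alt_count=v.alt_count,
                        depth=v.depth, gene=v.gene,
                    )
                )
        vpath = outdir / f"{patient}.variants.tsv"
        mio.write_variants_tsv(variants, vpath)

        # one clonal whole-arm gain per patient as a minimal CNV layer
        segs = []
        for site, comp in zip(truth.sites, comps):
            segs.append(
                CopySegment(
                    sample_id=sample_ids[site], chrom="chr5", start=1,
                    end=50_000_000, total_cn=3, major_cn=2, minor_cn=1,
                    cellular_fraction=comp.purity,
                )
            )
        spath = outdir / f"{patient}.segments.tsv"
        mio.write_segments_tsv(segs, spath)

        hot = p < n_hot
        immune = {
            s: {
                pop: float(rng.uniform(2.0, 4.0) if hot else rng.uniform(0.0, 0.5))
                for pop in populations
            }
            for s in truth.sites
        }
        expr = simulate_expression_pair(
            truth, n_genes=n_genes, e_profile=e_profile, s_profile=s_profile,
            immune_signatures=signatures, noise_sd=noise_sd,
            seed=pseed + 2, immune=immune,
        )
        meth = simulate_methylation_pair(
            truth, n_cpg=n_cpg, seed=pseed + 3, genes=genes
        )
        if annotation is None:
            annotation = meth.annotation
            pd.DataFrame(
                [{"cpg_id": c, "gene": g} for c, g in annotation.items()]
            ).to_csv(outdir / "cpg_annotation.tsv", sep="\t", index=False)

        for site in truth.sites:
            sid = sample_ids[site]
            fpkm_cols[sid] = expr.fpkm[site]
            vst_cols[sid] = expr.vst[site]
            beta_cols[sid] = meth.betas[site]
            detp_cols[sid] = meth.detection_p[site]
            comp = comps[0] if comps[0].site_id == site else comps[1]
            sheet_rows.append(
                {
                    "patient": patient, "sample": sid, "site": site,
                    "purity": round(comp.purity, 4), "dataset": "synthetic",
                    "variants": str(vpath), "segments": str(spath),
                }
            )

        truth_out[patient] = {
            "scenario": scenario,
            "true_category": truth.true_category,
            "true_ccf": truth.true_ccf,
            "es_scores": {s: list(v) for s, v in truth.es_scores.items()},
            "immune_hot": hot,
            "de_genes": truth.de_genes,
            "dm_cpgs": sorted(truth.dm_cpgs),
            "purity": {s: comp.purity for s, comp in zip(truth.sites, comps)},
        }

    mio.write_matrix_tsv(pd.DataFrame(fpkm_cols), outdir / "fpkm.tsv", "gene")
    mio.write_matrix_tsv(pd.DataFrame(vst_cols), outdir / "vst.tsv", "gene")
    mio.write_matrix_tsv(pd.DataFrame(beta_cols), outdir / "beta.tsv", "cpg")
    mio.write_matrix_tsv(pd.DataFrame(detp_cols), outdir / "detection_p.tsv", "cpg")
    pd.DataFrame(sheet_rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_out, fh, indent=1, sort_keys=True)

    config = {
        "sample_sheet": "samples.tsv",
        "outdir": "results",
        "seed": seed,
        "paths": {
            "fpkm": "fpkm.tsv",
            "vst": "vst.tsv",
            "beta": "beta.tsv",
            "detection_p": "detection_p.tsv",
            "cpg_annotation": "cpg_annotation.tsv",
            "gene_sets": "gene_sets.gmt",
            "signatures": "signatures.tsv",
            "cell_line_fpkm": "cell_line_fpkm.tsv",
            "profiles": "es_profiles.tsv",
            "es_correlated": "es_correlated.tsv",
        },
        "checkpoint_genes": sorted(
            str(g)
            for g in np.random.default_rng(seed).choice(genes, size=8, replace=False)
        ),
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
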