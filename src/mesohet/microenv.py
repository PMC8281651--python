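"""Tumor microenvironment profiling from marker-gene signatures.

Immune and stromal cell populations are quantified per sample as the mean
log2-scale expression of population-specific marker genes (the MCP-counter
estimator).  Marker lists are first refined against a panel of tumor cell
lines — a marker expressed by the tumor cells themselves would confound the
infiltration signal.  For cross-cohort integration, expression is
standardized per dataset (mean 0, sd 1 per gene within each dataset).
Samples then cluster into hot (high-infiltration) and cold profiles, and
paired biopsies are compared by an exact Wilcoxon signed-rank test plus an
immune-checkpoint fold-change rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .expression import cosine_ward_cluster

__all__ = [
    "SignatureSet",
    "HotColdResult",
    "refine_signatures",
    "mcp_scores",
    "standardize_per_dataset",
    "hot_cold_assign",
    "paired_population_test",
    "checkpoint_de",
]


@dataclass
class SignatureSet:
    """Marker-gene lists per cell population."""

    populations: dict[str, list[str]]
    refined: bool = False

    def __post_init__(self) -> None:
        empty = [p for p, genes in self.populations.items() if not genes]
        if empty:
            raise ValueError(f"empty signature(s): {empty}")


def refine_signatures(
    signatures: SignatureSet,
    cell_line_fpkm: pd.DataFrame,
    expr_threshold: float = 1.0,
    exclude: Sequence[str] = (),
) -> SignatureSet:
    """Drop markers expressed in any tumor cell line.

    ``cell_line_fpkm`` is genes x cell lines.  A marker is kept only if its
    FPKM is below ``expr_threshold`` in ALL lines; markers absent from the
    matrix are treated as not expressed (with a warning).  ``exclude`` names
    genes removed unconditionally (e.g. genes missing from one of the
    cohorts being integrated).  A population losing all its markers is an
    error — its score would be undefined.
    """
    refined: dict[str, list[str]] = {}
    missing: list[str] = []
    emptied: list[str] = []
    for pop, genes in signatures.populations.items():
        kept = []
        for g in genes:
            if g in exclude:
                continue
            if g not in cell_line_fpkm.index:
                missing.append(g)
                kept.append(g)
                continue
            if (cell_line_fpkm.loc[g] < expr_threshold).all():
                kept.append(g)
        if kept:
            refined[pop] = kept
        else:
            emptied.append(pop)
    if missing:
        warnings.warn(
            f"{len(missing)} marker(s) absent from the cell-line matrix; "
            "treated as not expressed",
            stacklevel=2,
        )
    if emptied:
        raise ValueError(f"refinement emptied population(s): {emptied}")
    return SignatureSet(populations=refined, refined=True)


def mcp_scores(
    log2_expression: pd.DataFrame, signatures: SignatureSet
) -> pd.DataFrame:
    """Population infiltration scores: mean marker expression per sample.

    ``log2_expression`` is genes x samples on a log2 scale (use
    ``np.log2(fpkm + 1)`` for raw FPKM; variance-stabilized values work
    directly).  Markers missing from the matrix are dropped with a warning.
    Returns populations x samples.
    """
    rows = {}
    for pop, genes in signatures.populations.items():
        present = [g for g in genes if g in log2_expression.index]
        absent = len(genes) - len(present)
        if absent:
            warnings.warn(
                f"{absent} marker(s) of {pop} missing from the expression matrix",
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"no marker of {pop} present in the expression matrix")
        rows[pop] = log2_expression.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def standardize_per_dataset(
    matrix: pd.DataFrame, dataset_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Z-standardize each row within each dataset (population sd).

    ``matrix`` is features x samples; ``dataset_labels`` maps each sample
    column to its cohort.  Within each cohort, every feature row gets mean 0
    and sd 1; constant rows become all zeros with a warning.  Idempotent.
    """
    missing = [s for s in matrix.columns if s not in dataset_labels]
    if missing:
        raise ValueError(f"samples without dataset label: {missing}")
    out = matrix.copy().astype(float)
    warned = False
    for dataset in sorted(set(dataset_labels[s] for s in matrix.columns)):
        cols = [s for s in matrix.columns if dataset_labels[s] == dataset]
        block = out[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        constant = sd == 0
        if constant.any() and not warned:
            warnings.warn(
                f"{int(constant.sum())} constant row(s) set to 0 in dataset "
                f"{dataset}",
                stacklevel=2,
            )
            warned = True
        sd_safe = sd.replace(0, 1.0)
        out[cols] = block.sub(mean, axis=0).div(sd_safe, axis=0)
        out.loc[constant, cols] = 0.0
    return out


@dataclass
class HotColdResult:
    """Hot/cold immune-profile assignment of a cohort."""

    labels: pd.Series  # sample -> "hot" | "cold"
    mixed_pairs: list[str] = field(default_factory=list)


def hot_cold_assign(
    scores: pd.DataFrame,
    pairs: Mapping[str, tuple[str, str]] | None = None,
) -> HotColdResult:
    """Split samples into hot and cold immune profiles.

    Cosine/Ward hierarchical clustering of the samples (rows = samples,
    features = population scores) cut at k = 2; the cluster with the higher
    grand-mean score is labeled hot.  Pass standardized scores (see
    ``standardize_per_dataset``): after per-population z-scoring, high- and
    low-infiltration samples point in opposite directions, which is what a
    cosine metric separates.  When a patient pair map is given, patients
    whose two biopsies land in different clusters are flagged mixed — the
    hot/cold switching phenotype.
    """
    if scores.T.var(ddof=0).sum() == 0 or scores.var(axis=1, ddof=0).sum() == 0:
        raise ValueError("zero-variance score matrix: no hot/cold structure")
    samples = scores.T  # samples x populations
    _, clusters = cosine_ward_cluster(samples, k=2)
    means = {
        c: samples.loc[clusters == c].to_numpy().mean() for c in (1, 2)
    }
    hot_cluster = max(means, key=lambda c: (means[c], -c))
    labels = clusters.map(lambda c: "hot" if c == hot_cluster else "cold")
    labels.name = "immune_profile"
    mixed = []
    if pairs is not None:
        for patient, (a, b) in pairs.items():
            if labels[a] != labels[b]:
                mixed.append(patient)
    return HotColdResult(labels=labels, mixed_pairs=sorted(mixed))


def paired_population_test(
    scores_a: pd.Series, scores_b: pd.Series
) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test over the population score vector.

    Compares the infiltration profile of the two biopsies of one patient
    (paired over populations).  The exact null distribution is used for up
    to 25 populations; identical vectors return p = 1.
    """
    common = scores_a.index.intersection(scores_b.index)
    diff = scores_a.loc[common] - scores_b.loc[common]
    if (diff == 0).all():
        return 0.0, 1.0
    method = "exact" if len(common) <= 25 else "auto"
    res = wilcoxon(
        scores_a.loc[common], scores_b.loc[common], method=method,
        zero_method="wilcox",
    )
    return float(res.statistic), float(res.pvalue)


def checkpoint_de(
    fpkm_a: pd.Series,
    fpkm_b: pd.Series,
    genes: Sequence[str],
    fpkm_min: float = 1.0,
    fc_min: float = 2.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Immune-checkpoint fold-change rule for a biopsy pair.

    A gene with FPKM not above ``fpkm_min`` in either biopsy is reported
    with difference 0 and never flagged.  Otherwise the fold change is
    max / min of the two FPKM values (with ``pseudocount`` added to the
    denominator to tolerate zeros) and the gene is flagged when the fold
    change is at least ``fc_min``.
    """
    rows = []
    for g in genes:
        a = float(fpkm_a.get(g, np.nan))
        b = float(fpkm_b.get(g, np.nan))
        if np.isnan(a) or np.isnan(b):
            rows.append({"gene": g, "fpkm_a": a, "fpkm_b": b,
                         "difference": np.nan, "fold_change": np.nan,
                         "flag": False})
            continue
        if max(a, b) <= fpkm_min:
            rows.append({"gene": g, "fpkm_a": a, "fpkm_b": b,
                         "difference": 0.0, "fold_change": np.nan,
                         "flag": False})
            continue
        fc = max(a, b) / (min(a, b) + pseudocount)
        rows.append({"gene": g, "fpkm_a": a, "fpkm_b": b,
                     "difference": a - b, "fold_change": fc,
                     "flag": fc >= fc_min})
    return pd.DataFrame(
        rows, columns=["gene", "fpkm_a", "fpkm_b", "difference",
                       "fold_change", "flag"]
    )
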