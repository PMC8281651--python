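"""Paired differential methylation and its intersection with expression.

Methylation arrays report a beta-value (methylated fraction, in [0, 1]) and
a detection p-value per CpG.  Between the two biopsies of a pair, a CpG is
differentially methylated (DM) when both probes detect reliably and the
beta-values differ by at least 0.2.  DM CpGs are mapped to genes and
intersected with the differentially expressed (DE) set; the resulting DE_DM
genes can further be filtered for direction-consistency with the
epithelioid/sarcomatoid gradient change of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import top_variable_genes

__all__ = [
    "MethylationPair",
    "call_dm_cpg",
    "de_dm_genes",
    "direction_consistency_filter",
    "top_variable_cpg",
]


@dataclass
class MethylationPair:
    """Beta-values and detection p-values for one biopsy pair.

    ``betas`` and ``detection_p`` are CpG x 2 frames with identical index
    and columns (the two site ids).  ``annotation`` maps each CpG to a gene
    symbol or None (many CpGs per gene allowed; unannotated CpGs allowed).
    """

    betas: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: Mapping[str, str | None]

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.detection_p.index):
            raise ValueError("beta and detection-p matrices must share CpGs")
        if list(self.betas.columns) != list(self.detection_p.columns):
            raise ValueError("beta and detection-p matrices must share samples")
        if len(self.betas.columns) != 2:
            raise ValueError("a methylation pair has exactly two sample columns")
        vals = self.betas.values
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        p = self.detection_p.values
        if np.nanmin(p) < 0 or np.nanmax(p) > 1:
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def sites(self) -> tuple[str, str]:
        a, b = self.betas.columns
        return (a, b)


def call_dm_cpg(
    pair: MethylationPair,
    p_max: float = 0.05,
    beta_delta: float = 0.2,
) -> pd.DataFrame:
    """Call differentially methylated CpGs between the two biopsies.

    A CpG is DM iff both detection p-values are strictly below ``p_max`` and
    the absolute beta difference is at least ``beta_delta`` (inclusive).
    Returns one row per DM CpG with the signed delta (A - B) and the
    hyper/hypo direction of site A relative to site B — reported for
    interpretation, not used by any downstream filter.
    """
    a, b = pair.sites
    detected = (pair.detection_p[a] < p_max) & (pair.detection_p[b] < p_max)
    delta = pair.betas[a] - pair.betas[b]
    # inclusive threshold, padded by an ulp-scale tolerance so a shift of
    # exactly 0.2 is not lost to floating-point rounding
    dm = detected & (delta.abs() >= beta_delta - 1e-12)
    return pd.DataFrame(
        {
            "cpg": pair.betas.index[dm],
            "delta_beta": delta[dm].values,
            "direction": np.where(delta[dm].values > 0, "hyper", "hypo"),
        }
    ).reset_index(drop=True)


def de_dm_genes(
    de_genes: set[str],
    dm_cpgs: set[str],
    annotation: Mapping[str, str | None],
    protein_coding: set[str] | None = None,
) -> tuple[set[str], float]:
    """Intersect the DE gene set with genes carrying at least one DM CpG.

    Returns the DE_DM gene set and the percentage of DE (protein-coding,
    when a coding list is given) genes that have >= 1 DM CpG.  The
    percentage is 0 when the denominator is empty.
    """
    dm_genes = {
        g for cpg in dm_cpgs if (g := annotation.get(cpg)) is not None
    }
    denominator = de_genes & protein_coding if protein_coding is not None else de_genes
    de_dm = denominator & dm_genes
    pct = 100.0 * len(de_dm) / len(denominator) if denominator else 0.0
    return de_dm, pct


def direction_consistency_filter(
    de_signs: Mapping[str, int],
    es_table: Mapping[str, str],
    es_delta: float,
) -> tuple[set[str], float, int]:
    """Keep genes whose expression change matches the E/S gradient change.

    ``de_signs`` maps each candidate gene to the sign of its VST change
    (site A minus site B); ``es_table`` labels genes as correlated with the
    epithelioid pole (``"E"``) or the sarcomatoid pole (``"S"``);
    ``es_delta`` is the signed E-score change A - B.  An E-correlated gene
    is consistent when its expression moves with the E score, an
    S-correlated gene when it moves against it.  Genes absent from
    ``es_table`` do not enter the denominator; their count is returned
    separately.  With ``es_delta == 0`` the expected direction is undefined:
    an empty set is returned with a warning.

    Returns ``(consistent genes, proportion among annotated candidates,
    n unannotated)``.
    """
    for gene, label in es_table.items():
        if label not in ("E", "S"):
            raise ValueError(f"es_table label for {gene} must be 'E' or 'S'")
    unannotated = sum(1 for g in de_signs if g not in es_table)
    if es_delta == 0:
        warnings.warn(
            "E-score change is 0: direction-consistency is undefined", stacklevel=2
        )
        return set(), 0.0, unannotated

    es_sign = 1 if es_delta > 0 else -1
    annotated = [g for g in de_signs if g in es_table]
    kept = {
        g
        for g in annotated
        if (es_table[g] == "E" and np.sign(de_signs[g]) == es_sign)
        or (es_table[g] == "S" and np.sign(de_signs[g]) == -es_sign)
    }
    proportion = len(kept) / len(annotated) if annotated else 0.0
    return kept, proportion, unannotated


def top_variable_cpg(betas: pd.DataFrame, n: int = 500) -> list[str]:
    """The ``n`` CpGs with the largest beta-value range across samples.

    Ties break lexicographically by CpG id; the result feeds the same
    cosine/Ward clustering used for expression.
    """
    return top_variable_genes(betas, n=n, criterion="range")
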