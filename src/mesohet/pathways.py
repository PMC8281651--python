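"""Pathway over-representation and single-sample enrichment scoring.

Two complementary views of pathway dysregulation: over-representation
analysis (ORA) asks whether a DE gene list overlaps a gene set more than
the hypergeometric null expects, with Benjamini-Hochberg control across the
sets of a collection; single-sample GSEA (ssGSEA) scores each sample's
coordinate up/down ranking of a set, and the absolute per-pair score delta
measures intra-tumor pathway heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "ora",
    "ssgsea_scores",
    "delta_ssgsea",
    "read_gmt_collection",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    Sets are intersected with the universe on construction; sets that become
    empty are dropped (their names recorded in ``dropped``).
    """

    sets: dict[str, set[str]]
    universe: set[str]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        cleaned: dict[str, set[str]] = {}
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            if inter:
                cleaned[name] = inter
            else:
                self.dropped.append(name)
        self.sets = cleaned


def read_gmt_collection(path: str, universe: set[str]) -> GeneSetCollection:
    """Load a GMT file into a collection restricted to ``universe``."""
    from gseapy.parser import read_gmt

    raw = read_gmt(str(path))
    return GeneSetCollection(
        sets={name: set(genes) for name, genes in raw.items()}, universe=universe
    )


def ora(
    de_genes: set[str],
    collection: GeneSetCollection,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    For a universe of M genes, a set of size K and a query of size N with
    overlap k, the p-value is P[X >= k] for X ~ Hypergeom(M, K, N).
    Query genes outside the universe are dropped with a warning recorded in
    ``result.attrs["n_outside_universe"]``.  FDR is Benjamini-Hochberg over
    all sets of the collection; ``gene_ratio`` is overlap / set size.
    """
    outside = de_genes - collection.universe
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    query = de_genes & collection.universe
    m = len(collection.universe)
    n_query = len(query)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        k = len(query & genes)
        # upper tail including the observed overlap
        p = float(hypergeom.sf(k - 1, m, len(genes), n_query))
        rows.append(
            {
                "set": name,
                "set_size": len(genes),
                "overlap": k,
                "gene_ratio": k / len(genes),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "gene_ratio", "p"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p"].values, method="fdr_bh")
        out["fdr"] = fdr
        out["significant"] = out["fdr"] < fdr_max
    else:
        out["fdr"] = []
        out["significant"] = []
    out.attrs["n_outside_universe"] = len(outside)
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def ssgsea_scores(
    vst: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    fpkm: pd.DataFrame | None = None,
    fpkm_min: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA scores (rank-weighted ECDF difference).

    ``vst`` is genes x samples on a log2-like scale.  When ``fpkm`` is
    supplied, genes with FPKM below ``fpkm_min`` in ALL samples are removed
    before ranking.  Per sample, genes are ordered by decreasing expression;
    the score of a set is the sum over the ordered list of the difference
    between the weighted ECDF of in-set genes (weights = expression
    rank^alpha) and the unweighted ECDF of out-of-set genes.  With
    ``normalize=True`` all scores are rescaled by the global score range
    across the matrix.  Sets with no expressed member yield NaN (flagged in
    ``result.attrs["undefined_sets"]``), never 0.
    """
    expr = vst
    if fpkm is not None:
        keep = ~(fpkm < fpkm_min).all(axis=1)
        expr = vst.loc[keep.index[keep].intersection(vst.index)]
    expr = expr.sort_index()  # gene-order invariance
    n = len(expr)
    if n == 0:
        raise ValueError("no genes left after the expression filter")

    scores = pd.DataFrame(
        index=sorted(collection.sets), columns=expr.columns, dtype=float
    )
    undefined = []
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    memberships = {}
    for name in scores.index:
        idx = np.array(
            sorted(gene_pos[g] for g in collection.sets[name] if g in gene_pos),
            dtype=int,
        )
        memberships[name] = idx
        if idx.size == 0:
            undefined.append(name)

    values = expr.to_numpy(float)
    for j, sample in enumerate(expr.columns):
        col = values[:, j]
        # ranks: highest expression gets rank n (ties averaged)
        ranks = rankdata(col, method="average")
        order = np.lexsort((np.arange(n), -col))  # decreasing, stable
        in_order_rank = ranks[order]
        for name, idx in memberships.items():
            if idx.size == 0:
                scores.loc[name, sample] = np.nan
                continue
            member = np.zeros(n, dtype=bool)
            member[idx] = True
            member = member[order]
            w = np.where(member, in_order_rank**alpha, 0.0)
            ecdf_in = np.cumsum(w) / w.sum()
            n_out = n - idx.size
            if n_out == 0:
                ecdf_out = np.zeros(n)
            else:
                ecdf_out = np.cumsum(~member) / n_out
            scores.loc[name, sample] = float(np.sum(ecdf_in - ecdf_out))

    if normalize:
        finite = scores.to_numpy(float)
        finite = finite[np.isfinite(finite)]
        if finite.size:
            rng = finite.max() - finite.min()
            if rng > 0:
                scores = scores / rng
    scores.attrs["undefined_sets"] = undefined
    return scores


def delta_ssgsea(
    scores: pd.DataFrame,
    pairs: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Absolute per-pair ssGSEA score differences (sets x patients).

    ``pairs`` maps a patient id to its two sample columns.  The returned
    frame carries a ``ranking`` attr listing, per patient, the sets ordered
    by decreasing delta — the pathways most heterogeneous within that tumor.
    """
    out = pd.DataFrame(index=scores.index, dtype=float)
    for patient, (a, b) in pairs.items():
        out[patient] = (scores[a] - scores[b]).abs()
    out.attrs["ranking"] = {
        patient: out[patient]
        .sort_values(ascending=False, kind="mergesort")
        .index.tolist()
        for patient in out.columns
    }
    return out
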