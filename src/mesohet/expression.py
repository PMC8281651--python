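"""Paired differential expression and histo-molecular (E/S) deconvolution.

A biopsy pair is compared gene-by-gene on two scales: FPKM (to drop genes
not expressed in either biopsy) and variance-stabilized values (VST, a
log2-like scale on which expression differences are taken).  Samples are
also placed on the epithelioid-sarcomatoid continuum: a nearest-centroid
classifier assigns discrete molecular subtypes, while a two-component
simplex-constrained least-squares deconvolution yields continuous E/S
scores whose change across a pair quantifies histo-molecular heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionPair",
    "ESScores",
    "call_de_genes",
    "top_variable_genes",
    "cosine_ward_cluster",
    "predict_subtype",
    "deconvolve_es",
    "es_heterogeneity",
]


@dataclass
class ExpressionPair:
    """FPKM and variance-stabilized expression for one biopsy pair.

    Both frames are genes x 2 with identical index and column order; the
    columns are the two site ids.
    """

    fpkm: pd.DataFrame
    vst: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.fpkm.index.equals(self.vst.index):
            raise ValueError("FPKM and VST must share the same gene universe")
        if list(self.fpkm.columns) != list(self.vst.columns):
            raise ValueError("FPKM and VST must share the same sample columns")
        if len(self.fpkm.columns) != 2:
            raise ValueError("an expression pair has exactly two sample columns")
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def sites(self) -> tuple[str, str]:
        a, b = self.fpkm.columns
        return (a, b)


@dataclass(frozen=True)
class ESScores:
    """Deconvolved epithelioid-like / sarcomatoid-like proportions."""

    e_score: float
    s_score: float

    def __post_init__(self) -> None:
        if abs(self.e_score + self.s_score - 1.0) > 1e-6:
            raise ValueError("E and S scores must sum to 1")
        if not (0 <= self.e_score <= 1 and 0 <= self.s_score <= 1):
            raise ValueError("scores must lie in [0, 1]")


def call_de_genes(
    pair: ExpressionPair,
    fpkm_min: float = 1.0,
    vst_delta: float = 1.0,
) -> pd.DataFrame:
    """Call differentially expressed genes between the two biopsies of a pair.

    A gene is DE iff it is expressed in at least one biopsy (NOT both FPKM
    values below ``fpkm_min``) and the absolute VST difference is strictly
    above ``vst_delta``.  The sign is that of VST(A) - VST(B).  Genes with
    missing values are skipped; their count is attached as
    ``result.attrs["n_skipped"]``.
    """
    a, b = pair.sites
    ok = pair.fpkm[[a, b]].notna().all(axis=1) & pair.vst[[a, b]].notna().all(axis=1)
    n_skipped = int((~ok).sum())
    fpkm = pair.fpkm.loc[ok]
    vst = pair.vst.loc[ok]

    expressed = ~((fpkm[a] < fpkm_min) & (fpkm[b] < fpkm_min))
    delta = vst[a] - vst[b]
    de = expressed & (delta.abs() > vst_delta)
    out = pd.DataFrame(
        {
            "gene": vst.index[de],
            "delta_vst": delta[de].values,
            "sign": np.sign(delta[de].values).astype(int),
        }
    ).reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def top_variable_genes(
    values: pd.DataFrame, n: int = 500, criterion: str = "range"
) -> list[str]:
    """Select the ``n`` most variable features across a cohort.

    ``values`` is features x samples.  Variability is the per-feature range
    (max - min) by default, or variance.  Ties break lexicographically by
    feature id, so the selection is fully deterministic.
    """
    if criterion == "range":
        score = values.max(axis=1) - values.min(axis=1)
    elif criterion == "variance":
        score = values.var(axis=1, ddof=0)
    else:
        raise ValueError("criterion must be 'range' or 'variance'")
    if n > len(values):
        warnings.warn(
            f"requested {n} features but universe has {len(values)}; returning all",
            stacklevel=2,
        )
        n = len(values)
    order = pd.DataFrame({"score": score, "id": score.index}).sort_values(
        ["score", "id"], ascending=[False, True], kind="mergesort"
    )
    return order["id"].head(n).tolist()


def cosine_ward_cluster(
    samples: pd.DataFrame, k: int | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """Hierarchical clustering with cosine distance and Ward's linkage.

    ``samples`` is samples x features.  Returns the SciPy linkage matrix and,
    when ``k`` is given, flat cluster labels (1..k) indexed by sample.
    """
    if len(samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    norms = np.linalg.norm(samples.values, axis=1)
    if (norms == 0).any():
        bad = samples.index[norms == 0].tolist()
        raise ValueError(f"zero-norm sample vector(s): {bad}")
    dist = pdist(samples.values, metric="cosine")
    z = linkage(dist, method="ward")
    labels = None
    if k is not None:
        labels = pd.Series(
            fcluster(z, t=k, criterion="maxclust"), index=samples.index, name="cluster"
        )
    return z, labels


def predict_subtype(sample: pd.Series, centroids: pd.DataFrame) -> str:
    """Nearest-centroid molecular subtype by Pearson correlation.

    ``centroids`` is genes x subtypes (2-, 3- or 4-class schemes all work).
    Only genes shared between the sample and the centroid table are used.
    Ties resolve to the lexicographically first label with a warning.
    """
    common = centroids.index.intersection(sample.index)
    if len(common) < 3:
        raise ValueError("too few genes shared with the centroid table")
    x = sample.loc[common].astype(float)
    corr = centroids.loc[common].corrwith(x)
    best = corr.max()
    winners = sorted(corr.index[np.isclose(corr, best)])
    if len(winners) > 1:
        warnings.warn(
            f"centroid correlation tie among {winners}; keeping {winners[0]}",
            stacklevel=2,
        )
    return winners[0]


def deconvolve_es(
    sample: pd.Series, e_profile: pd.Series, s_profile: pd.Series
) -> ESScores:
    """Two-component deconvolution onto the E/S histo-molecular gradient.

    Solves ``min_w || x - (w * E + (1 - w) * S) ||^2`` with ``w`` in [0, 1]
    over the shared marker genes; for two components the simplex-constrained
    least-squares solution is closed-form: project onto the E-S axis and
    clip.  Near-collinear profiles carry no mixing information and raise.
    """
    common = e_profile.index.intersection(s_profile.index).intersection(sample.index)
    if len(common) < 2:
        raise ValueError("profiles and sample share too few marker genes")
    x = sample.loc[common].to_numpy(float)
    e = e_profile.loc[common].to_numpy(float)
    s = s_profile.loc[common].to_numpy(float)
    if abs(np.corrcoef(e, s)[0, 1]) > 0.999:
        raise ValueError("E and S profiles are collinear; deconvolution undefined")
    d = e - s
    w = float(np.dot(x - s, d) / np.dot(d, d))
    w = float(np.clip(w, 0.0, 1.0))
    return ESScores(e_score=w, s_score=1.0 - w)


def es_heterogeneity(
    scores_a: ESScores, scores_b: ESScores, threshold: float = 0.10
) -> tuple[bool, float]:
    """Histo-molecular heterogeneity call for a biopsy pair.

    Returns ``(flag, delta)`` where ``delta = |E_A - E_B|`` and the flag is
    raised when the change is strictly greater than ``threshold`` (default:
    a 10% change in the E score).
    """
    delta = abs(scores_a.e_score - scores_b.e_score)
    return delta > threshold, delta
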