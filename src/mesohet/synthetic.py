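"""Synthetic multi-site tumor cohorts with known ground truth.

Generates paired-biopsy data whose statistical structure mirrors a
multi-region tumor sequencing study: a shared clonal trunk plus private or
shared subclones per patient, depth-dependent binomial read sampling,
expression as a mixture of epithelioid-like and sarcomatoid-like reference
profiles with additive immune-infiltration components, and beta-distributed
methylation.  Every generator records its ground truth (clone tree, true
CCFs, true categories, planted DE genes and DM CpGs, E/S scores, immune
abundances) so downstream estimators can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonality import VariantObservation
from .expression import ExpressionPair
from .methylation import MethylationPair

__all__ = [
    "Clone",
    "CloneTree",
    "SiteComposition",
    "SyntheticTruth",
    "simulate_clone_structure",
    "simulate_variant_reads",
    "simulate_expression_pair",
    "simulate_methylation_pair",
    "make_reference_profiles",
    "make_immune_signatures",
    "SCENARIOS",
]

SCENARIOS = ("private_subclones", "shared_subclone", "mixed")

# Highest total fraction the subclones may occupy at one site; the remainder
# is cells carrying only trunk mutations, so the trunk never vanishes.
_MAX_SUBCLONE_MASS = 0.8


@dataclass(frozen=True)
class Clone:
    """A clone in the tree; ``mutations`` is cumulative (includes ancestors)."""

    id: str
    parent: str | None
    mutations: frozenset[str]
    segments: frozenset[str] = frozenset()


@dataclass
class CloneTree:
    clones: list[Clone]

    def __post_init__(self) -> None:
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        ids = {c.id for c in self.clones}
        by_id = {c.id: c for c in self.clones}
        for c in self.clones:
            if c.parent is not None:
                if c.parent not in ids:
                    raise ValueError(f"clone {c.id} has unknown parent {c.parent}")
                if not by_id[c.parent].mutations <= c.mutations:
                    raise ValueError(
                        f"clone {c.id} does not carry all mutations of its parent"
                    )
        # each mutation id must first appear in exactly one clone
        for c in self.clones:
            novel = c.mutations - (
                by_id[c.parent].mutations if c.parent is not None else frozenset()
            )
            for other in self.clones:
                if other.id == c.id or other.parent == c.id:
                    continue
                if c.parent is not None and other.id == c.parent:
                    continue
                if novel & other.mutations and not (c.mutations <= other.mutations):
                    raise ValueError(
                        f"mutation ids of clone {c.id} reappear outside its subtree"
                    )

    @property
    def root(self) -> Clone:
        return next(c for c in self.clones if c.parent is None)

    @property
    def mutation_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clones:
            out |= c.mutations
        return out

    def carriers(self, mutation_id: str) -> set[str]:
        return {c.id for c in self.clones if mutation_id in c.mutations}


@dataclass
class SiteComposition:
    """Tumor-cell composition of one biopsy site."""

    site_id: str
    clone_fractions: dict[str, float]
    purity: float

    def __post_init__(self) -> None:
        total = sum(self.clone_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, not 1")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated patient (two biopsy sites A and B)."""

    tree: CloneTree
    compositions: tuple[SiteComposition, SiteComposition]
    true_ccf: dict[str, dict[str, float]] = field(default_factory=dict)
    true_category: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> sign of A-B
    dm_cpgs: set[str] = field(default_factory=set)
    es_scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    immune: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def sites(self) -> tuple[str, str]:
        return (self.compositions[0].site_id, self.compositions[1].site_id)


def _true_ccf(tree: CloneTree, comp: SiteComposition, mutation: str) -> float:
    return sum(comp.clone_fractions.get(cid, 0.0) for cid in tree.carriers(mutation))


def _truth_category(ccf_a: float, ccf_b: float, threshold: float = 0.5) -> str:
    present = [c for c in (ccf_a, ccf_b) if c > 0]
    shared = len(present) == 2
    subclonal = all(c < threshold for c in present)
    return ("subclonal" if subclonal else "clonal") + (
        "_shared" if shared else "_private"
    )


def simulate_clone_structure(
    n_trunk_mut: int,
    n_subclones: int,
    muts_per_subclone: int,
    scenario: str = "mixed",
    seed: int = 0,
    purity_range: tuple[float, float] = (0.3, 0.9),
    sites: tuple[str, str] = ("A", "B"),
) -> tuple[CloneTree, tuple[SiteComposition, SiteComposition]]:
    """Simulate a clone tree and its composition at two biopsy sites.

    Scenarios
    ---------
    ``private_subclones``
        every subclone is present at exactly one site (fraction in (0, 0.5)).
    ``shared_subclone``
        the first subclone is present below 0.5 at BOTH sites — the
        configuration whose detection signals polyclonal dissemination;
        further subclones are private.
    ``mixed``
        each subclone is independently shared-subclonal, private-subclonal,
        or private-clonal (fraction above 0.5 at its one site), giving all
        four truth categories.

    Deterministic for a given seed.  Purities are drawn uniformly from
    ``purity_range`` — by default (0.3, 0.9), reflecting that biopsy purity
    varies widely and low-purity samples make clonality calls unreliable.
    """
    if n_trunk_mut < 1:
        raise ValueError("n_trunk_mut must be >= 1")
    if n_subclones < 0 or muts_per_subclone < 0:
        raise ValueError("counts must be non-negative")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if scenario == "shared_subclone" and n_subclones < 1:
        raise ValueError("shared_subclone scenario requires n_subclones >= 1")

    rng = np.random.default_rng(seed)
    trunk_muts = frozenset(f"m{i:04d}" for i in range(n_trunk_mut))
    clones = [Clone(id="trunk", parent=None, mutations=trunk_muts)]
    # per-site mass still available to subclones
    budget = {s: _MAX_SUBCLONE_MASS for s in sites}
    fractions: dict[str, dict[str, float]] = {s: {} for s in sites}

    next_mut = n_trunk_mut
    for k in range(n_subclones):
        muts = frozenset(
            f"m{i:04d}" for i in range(next_mut, next_mut + muts_per_subclone)
        )
        next_mut += muts_per_subclone
        cid = f"sub{k + 1}"
        clones.append(Clone(id=cid, parent="trunk", mutations=trunk_muts | muts))

        if scenario == "shared_subclone" and k == 0:
            kind = "shared_subclonal"
        elif scenario == "private_subclones":
            kind = "private_subclonal"
        elif scenario == "shared_subclone":
            kind = "private_subclonal"
        else:
            kind = rng.choice(
                ["shared_subclonal", "private_subclonal", "private_clonal"],
                p=[0.4, 0.4, 0.2],
            )

        if kind == "shared_subclonal":
            for s in sites:
                f = min(float(rng.uniform(0.1, 0.45)), budget[s])
                f = max(f, 0.01)  # keep strictly present at both sites
                fractions[s][cid] = f
                budget[s] -= f
        else:
            site = sites[k % 2] if scenario == "private_subclones" else sites[
                int(rng.integers(2))
            ]
            if kind == "private_clonal":
                f = min(float(rng.uniform(0.55, 0.75)), budget[site])
            else:
                f = min(float(rng.uniform(0.1, 0.45)), budget[site])
            f = max(f, 0.01)
            fractions[site][cid] = f
            budget[site] -= f

    comps = []
    for s in sites:
        fr = dict(fractions[s])
        fr["trunk"] = 1.0 - sum(fr.values())
        purity = float(rng.uniform(*purity_range))
        comps.append(SiteComposition(site_id=s, clone_fractions=fr, purity=purity))

    tree = CloneTree(clones=clones)
    return tree, (comps[0], comps[1])


def build_truth(
    tree: CloneTree,
    compositions: tuple[SiteComposition, SiteComposition],
) -> SyntheticTruth:
    """Derive per-mutation true CCFs and categories from a clone structure."""
    truth = SyntheticTruth(tree=tree, compositions=compositions)
    comp_a, comp_b = compositions
    for mut in sorted(tree.mutation_ids):
        ccf_a = _true_ccf(tree, comp_a, mut)
        ccf_b = _true_ccf(tree, comp_b, mut)
        truth.true_ccf[mut] = {comp_a.site_id: ccf_a, comp_b.site_id: ccf_b}
        truth.true_category[mut] = _truth_category(ccf_a, ccf_b)
    return truth


def simulate_variant_reads(
    truth: SyntheticTruth,
    mean_depth: int = 500,
    seed: int = 0,
    multiplicity: int = 1,
    total_cn: int = 2,
) -> dict[str, list[VariantObservation]]:
    """Draw sequencing reads for every mutation at each biopsy site.

    The expected VAF follows the purity/copy-number algebra of the CCF model:
    ``vaf = CCF * multiplicity * purity / (purity * CN_tumor + (1-purity) * 2)``.
    Depth is Poisson around ``mean_depth`` floored at 20; the alt count is
    binomial.  A mutation drawing zero alt reads is emitted as absent (not
    called) at that site, the same convention real variant callers impose.
    """
    if mean_depth < 20:
        raise ValueError("mean_depth must be >= 20")
    rng = np.random.default_rng(seed)
    out: dict[str, list[VariantObservation]] = {}
    for comp in truth.compositions:
        site = comp.site_id
        obs: list[VariantObservation] = []
        for i, mut in enumerate(sorted(truth.tree.mutation_ids)):
            ccf = truth.true_ccf[mut][site]
            depth = max(int(rng.poisson(mean_depth)), 20)
            evaf = (
                ccf
                * multiplicity
                * comp.purity
                / (comp.purity * total_cn + (1 - comp.purity) * 2)
            )
            alt = int(rng.binomial(depth, evaf)) if evaf > 0 else 0
            if alt == 0:
                continue
            obs.append(
                VariantObservation(
                    sample_id=site,
                    chrom="chr1",
                    pos=1000 + i,
                    ref="A",
                    alt="T",
                    alt_count=alt,
                    depth=depth,
                    gene=mut,
                )
            )
        out[site] = obs
    return out


def make_reference_profiles(
    n_genes: int, seed: int = 0, separation: float = 2.0
) -> tuple[pd.Series, pd.Series]:
    """Epithelioid-like and sarcomatoid-like reference expression profiles.

    Both profiles share a common baseline on a log2-like scale; a subset of
    genes is shifted up in one profile and down in the other so the two
    histo-molecular poles are distinguishable.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.normal(6.0, 1.5, n_genes).clip(0)
    e = base.copy()
    s = base.copy()
    n_marker = max(n_genes // 10, 2)
    idx = rng.choice(n_genes, size=2 * n_marker, replace=False)
    e[idx[:n_marker]] += separation
    s[idx[:n_marker]] -= separation / 2
    s[idx[n_marker:]] += separation
    e[idx[n_marker:]] -= separation / 2
    return (
        pd.Series(e.clip(0), index=genes, name="E"),
        pd.Series(s.clip(0), index=genes, name="S"),
    )


def make_immune_signatures(
    gene_universe: list[str],
    populations: tuple[str, ...] = (
        "T_cells",
        "B_cells",
        "NK_cells",
        "Monocytes",
        "Neutrophils",
        "Endothelial",
        "Fibroblasts",
    ),
    markers_per_population: int = 10,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Disjoint marker-gene signatures over the simulated gene universe."""
    rng = np.random.default_rng(seed)
    need = markers_per_population * len(populations)
    if need > len(gene_universe):
        raise ValueError("gene universe too small for requested signatures")
    chosen = rng.choice(len(gene_universe), size=need, replace=False)
    sigs = {}
    for p, pop in enumerate(populations):
        idx = chosen[p * markers_per_population : (p + 1) * markers_per_population]
        sigs[pop] = sorted(gene_universe[i] for i in idx)
    return sigs


def simulate_expression_pair(
    truth: SyntheticTruth,
    n_genes: int = 2000,
    e_profile: pd.Series | None = None,
    s_profile: pd.Series | None = None,
    immune_signatures: dict[str, list[str]] | None = None,
    noise_sd: float = 0.3,
    n_de: int = 100,
    de_shift: float = 1.5,
    seed: int = 0,
    es_scores: dict[str, tuple[float, float]] | None = None,
    immune: dict[str, dict[str, float]] | None = None,
) -> ExpressionPair:
    """Simulate the paired expression matrices (variance-stabilized + FPKM).

    Per site, the variance-stabilized value of a gene is the E/S mixture of
    the two reference profiles, plus each immune population's abundance on
    its marker genes, plus Gaussian noise; ``n_de`` designated genes receive
    an extra per-site shift of ``de_shift`` (> 1 so the paired DE rule can
    recover them) and are recorded in the truth with their signs.  FPKM is
    linked as ``2^v - 1`` floored at 0, so the FPKM < 1 and VST < 1 filters
    coincide.
    """
    rng = np.random.default_rng(seed)
    if e_profile is None or s_profile is None:
        e_profile, s_profile = make_reference_profiles(n_genes, seed=seed)
    genes = list(e_profile.index)
    if immune_signatures is None:
        immune_signatures = make_immune_signatures(genes, seed=seed)
    for pop, markers in immune_signatures.items():
        missing = set(markers) - set(genes)
        if missing:
            raise ValueError(
                f"signature genes absent from universe for {pop}: {sorted(missing)[:5]}"
            )

    sites = truth.sites
    if es_scores is None:
        e_a = float(rng.uniform(0.2, 0.8))
        # second site shifted to create occasional >10% heterogeneity
        e_b = float(np.clip(e_a + rng.normal(0, 0.12), 0.0, 1.0))
        es_scores = {sites[0]: (e_a, 1 - e_a), sites[1]: (e_b, 1 - e_b)}
    if immune is None:
        immune = {
            s: {pop: float(rng.uniform(0.0, 1.5)) for pop in immune_signatures}
            for s in sites
        }
    truth.es_scores = dict(es_scores)
    truth.immune = {s: dict(immune[s]) for s in sites}

    n_de = min(n_de, len(genes))
    de_idx = rng.choice(len(genes), size=n_de, replace=False) if n_de else []
    de_signs = rng.choice([-1, 1], size=n_de) if n_de else []
    truth.de_genes = {genes[i]: int(sg) for i, sg in zip(de_idx, de_signs)}

    cols = {}
    for s in sites:
        e_w, s_w = es_scores[s]
        v = e_w * e_profile.values + s_w * s_profile.values
        for pop, markers in immune_signatures.items():
            v = v + immune[s].get(pop, 0.0) * np.isin(genes, markers)
        if noise_sd > 0:
            v = v + rng.normal(0, noise_sd, len(genes))
        cols[s] = v
    # DE shift applied to site A only, with the planted sign (A - B)
    a, b = sites
    for i, sg in zip(de_idx, de_signs):
        cols[a][i] += sg * de_shift

    vst = pd.DataFrame(cols, index=genes)
    fpkm = (np.power(2.0, vst) - 1.0).clip(lower=0.0)
    return ExpressionPair(fpkm=fpkm, vst=vst)


def simulate_methylation_pair(
    truth: SyntheticTruth,
    n_cpg: int = 3000,
    n_dm: int = 150,
    delta: float = 0.3,
    noise_sd: float = 0.02,
    detection_failure_fraction: float = 0.0,
    seed: int = 0,
    genes: list[str] | None = None,
) -> MethylationPair:
    """Simulate paired methylation beta-values with planted DM CpGs.

    Baseline betas come from a bimodal Beta mixture (mostly unmethylated or
    mostly methylated loci, as on methylation arrays).  ``n_dm`` designated
    CpGs are shifted by ±``delta`` in site A (clipped to [0, 1]) and recorded
    in the truth.  Detection p-values are small except for a configurable
    fraction of failed probes (p = 0.5).  CpGs are annotated to genes
    round-robin when a gene list is given.
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    if n_dm > n_cpg:
        raise ValueError("n_dm cannot exceed n_cpg")
    rng = np.random.default_rng(seed)
    cpgs = [f"cg{i:06d}" for i in range(n_cpg)]
    sites = truth.sites

    hyper = rng.random(n_cpg) < 0.5
    base = np.where(hyper, rng.beta(10, 2, n_cpg), rng.beta(2, 10, n_cpg))
    betas = {s: base.copy() for s in sites}
    dm_idx = rng.choice(n_cpg, size=n_dm, replace=False) if n_dm else []
    a = sites[0]
    for i in dm_idx:
        direction = -1.0 if base[i] > 0.5 else 1.0  # shift toward the free end
        betas[a][i] = float(np.clip(base[i] + direction * delta, 0.0, 1.0))
    truth.dm_cpgs = {cpgs[i] for i in dm_idx}

    for s in sites:
        if noise_sd > 0:
            betas[s] = np.clip(betas[s] + rng.normal(0, noise_sd, n_cpg), 0, 1)

    detect = {}
    for s in sites:
        p = rng.uniform(0.0, 0.01, n_cpg)
        if detection_failure_fraction > 0:
            fail = rng.random(n_cpg) < detection_failure_fraction
            p = np.where(fail, 0.5, p)
        detect[s] = p

    annotation: dict[str, str | None] = {}
    for i, cpg in enumerate(cpgs):
        annotation[cpg] = genes[i % len(genes)] if genes else None
    return MethylationPair(
        betas=pd.DataFrame(betas, index=cpgs),
        detection_p=pd.DataFrame(detect, index=cpgs),
        annotation=annotation,
    )
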