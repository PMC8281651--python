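"""Cancer-cell-fraction estimation and clonality classification for paired biopsies.

Multi-region sequencing of a tumor yields, for each somatic variant, read
counts in two (or more) anatomically distinct biopsies.  Correcting the
variant allele frequency (VAF) for tumor purity, local copy number and
mutation multiplicity gives the cancer cell fraction (CCF): the fraction of
tumor cells that carry the variant.  Comparing CCFs across a biopsy pair
sorts variants into four categories — clonal/subclonal x shared/private —
from which shared subclonal populations (the genomic signal of polyclonal
dissemination) can be detected and a schematic clonal tree assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "VariantObservation",
    "CopySegment",
    "CCFEstimate",
    "ClonalityCall",
    "SharedSubcloneReport",
    "is_damaging",
    "estimate_ccf",
    "classify_variant",
    "cnv_ccf",
    "match_and_classify_cnv",
    "detect_shared_subclone",
    "build_clonal_tree",
    "section_vaf_profile",
    "CATEGORIES",
]

CATEGORIES = (
    "clonal_shared",
    "subclonal_shared",
    "clonal_private",
    "subclonal_private",
)

SIFT_LABELS = frozenset({"deleterious", "tolerated", "unknown"})
POLYPHEN_LABELS = frozenset(
    {"probably_damaging", "possibly_damaging", "benign", "unknown"}
)
_POLYPHEN_DAMAGING = frozenset({"probably_damaging", "possibly_damaging"})


@dataclass(frozen=True)
class VariantObservation:
    """One somatic variant observed in one sample.

    Coordinates are 1-based (VCF convention).  ``alt_count``/``depth`` are
    read counts at the locus; ``vaf`` is their ratio.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    gene: str | None = None
    consequence: str | None = None
    sift: str | None = None
    polyphen: str | None = None
    cancer_gene: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CopySegment:
    """Allele-specific copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: int
    minor_cn: int
    cellular_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError(
                f"need major_cn >= minor_cn >= 0, got {self.major_cn}/{self.minor_cn}"
            )
        if self.major_cn + self.minor_cn != self.total_cn:
            raise ValueError("major_cn + minor_cn must equal total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state_class(self) -> str:
        """Copy-number state class used to match segments across samples."""
        if self.total_cn == 0:
            return "homdel"
        if self.total_cn > 2:
            return "gain"
        if self.total_cn < 2:
            return "loss"
        if self.minor_cn == 0:
            return "cnloh"
        return "neutral"


@dataclass(frozen=True)
class CCFEstimate:
    """Point estimate of the cancer cell fraction with a 95% interval."""

    ccf: float
    ci_low: float
    ci_high: float
    multiplicity: int
    purity: float
    total_cn: int
    capped: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ccf <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class ClonalityCall:
    """Four-way clonality category for a variant or CNV segment."""

    key: str
    category: str
    site_a: CCFEstimate | float | None = None
    site_b: CCFEstimate | float | None = None
    gene: str | None = None
    cancer_gene: bool = False
    kind: str = "variant"  # "variant" or "cnv"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def shared(self) -> bool:
        return self.category.endswith("_shared")

    @property
    def subclonal(self) -> bool:
        return self.category.startswith("subclonal")


def is_damaging(sift_label: str | None, polyphen_label: str | None) -> bool:
    """Consensus pathogenicity: damaging if at least one predictor says so.

    SIFT labels: deleterious / tolerated / unknown.  PolyPhen labels:
    probably_damaging / possibly_damaging / benign / unknown.  ``None`` is
    treated as "unknown"; unknown never counts as damaging.
    """
    sift = sift_label if sift_label is not None else "unknown"
    polyphen = polyphen_label if polyphen_label is not None else "unknown"
    if sift not in SIFT_LABELS:
        raise ValueError(
            f"unrecognized SIFT label {sift!r}; accepted: {sorted(SIFT_LABELS)}"
        )
    if polyphen not in POLYPHEN_LABELS:
        raise ValueError(
            f"unrecognized PolyPhen label {polyphen!r}; "
            f"accepted: {sorted(POLYPHEN_LABELS)}"
        )
    return sift == "deleterious" or polyphen in _POLYPHEN_DAMAGING


def estimate_ccf(
    obs: VariantObservation,
    purity: float,
    segment: CopySegment | None = None,
    normal_cn: int = 2,
    ccf_cap: float = 1.5,
) -> CCFEstimate:
    """Estimate the cancer cell fraction of a variant in one sample.

    The VAF is rescaled to the tumor-cell compartment:

        raw = vaf * (purity * CN_tumor + (1 - purity) * CN_normal) / purity

    ``raw`` estimates CCF x multiplicity; the multiplicity (mutated copies
    per tumor cell) is the nearest integer of ``raw`` clamped to
    [1, major_cn], and CCF = raw / multiplicity.  The 95% interval applies
    the same linear transform to an exact Clopper-Pearson binomial interval
    on the VAF.  Estimates above ``ccf_cap`` (over-unity CCFs arise from
    purity misestimation) are capped with a warning, never silently
    renormalized.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if segment is not None:
        if segment.total_cn == 0:
            raise ValueError(
                "variant cannot reside on a homozygously deleted segment "
                f"(total_cn=0 at {segment.chrom}:{segment.start}-{segment.end})"
            )
        if segment.chrom != obs.chrom or not (
            segment.start <= obs.pos <= segment.end
        ):
            raise ValueError(
                f"variant {obs.key} not covered by segment "
                f"{segment.chrom}:{segment.start}-{segment.end}"
            )
        total_cn = segment.total_cn
        major_cn = segment.major_cn
    else:
        total_cn, major_cn = normal_cn, 1

    factor = (purity * total_cn + (1.0 - purity) * normal_cn) / purity
    raw = obs.vaf * factor
    multiplicity = int(np.clip(np.round(raw), 1, max(major_cn, 1)))
    ccf = raw / multiplicity

    vaf_low, vaf_high = proportion_confint(
        obs.alt_count, obs.depth, alpha=0.05, method="beta"
    )
    ci_low = float(vaf_low) * factor / multiplicity
    ci_high = float(vaf_high) * factor / multiplicity

    capped = ccf > ccf_cap
    if capped:
        warnings.warn(
            f"CCF {ccf:.3f} of {obs.key} exceeds cap {ccf_cap}; capped "
            "(check purity / copy-number inputs)",
            stacklevel=2,
        )
    return CCFEstimate(
        ccf=min(ccf, ccf_cap),
        ci_low=min(ci_low, ccf_cap),
        ci_high=min(ci_high, ccf_cap),
        multiplicity=multiplicity,
        purity=purity,
        total_cn=total_cn,
        capped=capped,
    )


def classify_variant(
    estimate_a: CCFEstimate | None,
    estimate_b: CCFEstimate | None,
    key: str = "",
    ccf_threshold: float = 0.5,
    ci_limit: float = 1.0,
    gene: str | None = None,
    cancer_gene: bool = False,
) -> ClonalityCall:
    """Classify a variant as clonal/subclonal x shared/private.

    Shared means observed in both biopsies.  A shared variant is subclonal
    only if the CCF is below ``ccf_threshold`` in BOTH samples and the upper
    95% bound is below ``ci_limit`` in both; a private variant applies the
    same two conditions to its single observed sample.  Anything else is
    clonal.
    """
    if estimate_a is None and estimate_b is None:
        raise ValueError("variant observed in neither sample")

    present = [e for e in (estimate_a, estimate_b) if e is not None]
    shared = len(present) == 2
    subclonal = all(
        e.ccf < ccf_threshold and e.ci_high < ci_limit for e in present
    )
    category = ("subclonal" if subclonal else "clonal") + (
        "_shared" if shared else "_private"
    )
    return ClonalityCall(
        key=key,
        category=category,
        site_a=estimate_a,
        site_b=estimate_b,
        gene=gene,
        cancer_gene=cancer_gene,
    )


def cnv_ccf(
    cellular_fraction: float, purity: float, tolerance: float = 0.1
) -> float:
    """CCF of a copy-number event: cellular fraction divided by tumor purity.

    Quotients above 1 are capped at 1; beyond ``1 + tolerance`` a warning is
    issued because the excess indicates inconsistent purity estimates.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    if not 0 <= cellular_fraction <= 1:
        raise ValueError(
            f"cellular_fraction must be in [0, 1], got {cellular_fraction}"
        )
    quotient = cellular_fraction / purity
    if quotient > 1.0 + tolerance:
        warnings.warn(
            f"CNV CCF {quotient:.3f} exceeds 1 + {tolerance}; capped at 1",
            stacklevel=2,
        )
    return min(quotient, 1.0)


def _check_segmentation(segments: Sequence[CopySegment]) -> None:
    by_chrom: dict[str, list[CopySegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}; "
                    "input must be a segmentation"
                )


def _reciprocal_overlap(a: CopySegment, b: CopySegment) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def match_and_classify_cnv(
    segments_a: Sequence[CopySegment],
    segments_b: Sequence[CopySegment],
    purity_a: float,
    purity_b: float,
    min_reciprocal_overlap: float = 0.5,
    ccf_threshold: float = 0.5,
) -> tuple[list[ClonalityCall], list[CopySegment]]:
    """Match CNV segments across a biopsy pair and classify their clonality.

    Segments match when they lie on the same chromosome, share the same
    copy-number state class (gain / loss / copy-neutral LOH) and overlap
    reciprocally by at least ``min_reciprocal_overlap``.  Matched pairs are
    shared, the rest private.  A CNV is subclonal when its CCF (cellular
    fraction / purity) is below ``ccf_threshold`` — in both sites for shared
    events, in the single site for private ones; no confidence-interval rule
    applies to CNVs.  Copy-neutral heterozygous segments (2 copies, 1+1) are
    not events and are skipped; homozygous deletions are returned in a
    dedicated list (their cellular fraction on zero copies is not CCF-scaled).
    """
    _check_segmentation(segments_a)
    _check_segmentation(segments_b)

    homdels = [
        s for s in list(segments_a) + list(segments_b) if s.state_class == "homdel"
    ]
    events_a = [s for s in segments_a if s.state_class not in ("neutral", "homdel")]
    events_b = [s for s in segments_b if s.state_class not in ("neutral", "homdel")]

    def _seg_ccf(seg: CopySegment, purity: float) -> float:
        if seg.cellular_fraction is None:
            return 1.0  # absent cellular fraction: assume fully clonal
        return cnv_ccf(seg.cellular_fraction, purity)

    def _seg_key(seg: CopySegment) -> str:
        return f"{seg.chrom}:{seg.start}-{seg.end}:{seg.state_class}"

    calls: list[ClonalityCall] = []
    matched_b: set[int] = set()
    for seg_a in events_a:
        best_j, best_ov = None, 0.0
        for j, seg_b in enumerate(events_b):
            if j in matched_b:
                continue
            if seg_b.chrom != seg_a.chrom or seg_b.state_class != seg_a.state_class:
                continue
            ov = _reciprocal_overlap(seg_a, seg_b)
            if ov >= min_reciprocal_overlap and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            matched_b.add(best_j)
            seg_b = events_b[best_j]
            ccf_a = _seg_ccf(seg_a, purity_a)
            ccf_b = _seg_ccf(seg_b, purity_b)
            subclonal = ccf_a < ccf_threshold and ccf_b < ccf_threshold
            calls.append(
                ClonalityCall(
                    key=_seg_key(seg_a),
                    category=("subclonal" if subclonal else "clonal") + "_shared",
                    site_a=ccf_a,
                    site_b=ccf_b,
                    kind="cnv",
                )
            )
        else:
            ccf_a = _seg_ccf(seg_a, purity_a)
            calls.append(
                ClonalityCall(
                    key=_seg_key(seg_a),
                    category=("subclonal" if ccf_a < ccf_threshold else "clonal")
                    + "_private",
                    site_a=ccf_a,
                    kind="cnv",
                )
            )
    for j, seg_b in enumerate(events_b):
        if j in matched_b:
            continue
        ccf_b = _seg_ccf(seg_b, purity_b)
        calls.append(
            ClonalityCall(
                key=_seg_key(seg_b),
                category=("subclonal" if ccf_b < ccf_threshold else "clonal")
                + "_private",
                site_b=ccf_b,
                kind="cnv",
            )
        )
    return calls, homdels


@dataclass
class SharedSubcloneReport:
    """Evidence for a subclonal tumor population present in both biopsies."""

    flag: bool
    supporting_variants: list[str] = field(default_factory=list)
    cancer_gene_members: list[str] = field(default_factory=list)
    cnv_support: list[str] = field(default_factory=list)


def detect_shared_subclone(
    calls: Iterable[ClonalityCall], min_variants: int = 2
) -> SharedSubcloneReport:
    """Flag a shared subclonal population (polyclonal dissemination signal).

    The flag is raised when at least ``min_variants`` variant calls are
    subclonal and shared.  Subclonal shared CNV segments are reported as
    corroborating evidence but do not count toward the threshold.
    """
    supporters = [
        c for c in calls if c.kind == "variant" and c.category == "subclonal_shared"
    ]
    cnv = [
        c for c in calls if c.kind == "cnv" and c.category == "subclonal_shared"
    ]
    return SharedSubcloneReport(
        flag=len(supporters) >= min_variants,
        supporting_variants=[c.key for c in supporters],
        cancer_gene_members=[
            c.gene for c in supporters if c.cancer_gene and c.gene is not None
        ],
        cnv_support=[c.key for c in cnv],
    )


def build_clonal_tree(
    calls: Sequence[ClonalityCall],
    site_a: str = "A",
    site_b: str = "B",
) -> dict:
    """Assemble the schematic clonal tree of a biopsy pair.

    The trunk holds all clonal shared variants; subclonal shared variants
    form a child of the trunk present in both sites; each site gets a branch
    for its clonal private variants, with subclonal private variants as
    site-local leaves.  Each node carries its variant count (downstream, the
    drawn line width is proportional to it).  Returns a JSON-ready nested
    dict; nodes with zero variants are kept so the topology is stable.
    """
    sites = set()
    for c in calls:
        if c.kind != "variant":
            continue
        if c.site_a is not None:
            sites.add(site_a)
        if c.site_b is not None:
            sites.add(site_b)
    variant_calls = [c for c in calls if c.kind == "variant"]
    by_cat: dict[str, list[ClonalityCall]] = {cat: [] for cat in CATEGORIES}
    for c in variant_calls:
        by_cat[c.category].append(c)

    def node(name, cats, site=None, children=()):
        variants = sorted(v.key for v in cats)
        return {
            "name": name,
            "sites": [site] if site else sorted(sites) or [site_a, site_b],
            "n_variants": len(variants),
            "variants": variants,
            "children": list(children),
        }

    private_a = [c for c in by_cat["clonal_private"] if c.site_a is not None]
    private_b = [c for c in by_cat["clonal_private"] if c.site_b is not None]
    sub_priv_a = [c for c in by_cat["subclonal_private"] if c.site_a is not None]
    sub_priv_b = [c for c in by_cat["subclonal_private"] if c.site_b is not None]

    children = []
    if by_cat["subclonal_shared"]:
        children.append(node("shared_subclone", by_cat["subclonal_shared"]))
    branch_a_children = (
        [node(f"subclone_{site_a}", sub_priv_a, site=site_a)] if sub_priv_a else []
    )
    branch_b_children = (
        [node(f"subclone_{site_b}", sub_priv_b, site=site_b)] if sub_priv_b else []
    )
    if private_a or branch_a_children:
        children.append(
            node(f"branch_{site_a}", private_a, site=site_a, children=branch_a_children)
        )
    if private_b or branch_b_children:
        children.append(
            node(f"branch_{site_b}", private_b, site=site_b, children=branch_b_children)
        )
    return node("trunk", by_cat["clonal_shared"], children=children)


def section_vaf_profile(
    sections: pd.DataFrame,
    min_alt_reads: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Profile a query variant against a clonal anchor across tumor sections.

    ``sections`` needs columns section, query_alt, query_depth, anchor_alt,
    anchor_depth (one row per physical section of the sample).  Sections with
    zero depth for either variant are excluded with a warning.  Returns the
    per-section VAF table plus a summary: the fraction of sections where the
    query is detected (VAF > 0 with >= ``min_alt_reads`` alt reads) and the
    median query/anchor VAF ratio over the detected sections.
    A detection fraction well below 1 with a ratio well below 1 supports a
    subclonal status of the query relative to the clonal anchor.
    """
    required = {"section", "query_alt", "query_depth", "anchor_alt", "anchor_depth"}
    missing = required - set(sections.columns)
    if missing:
        raise ValueError(f"sections table missing columns: {sorted(missing)}")
    zero = (sections["query_depth"] <= 0) | (sections["anchor_depth"] <= 0)
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-depth section(s)", stacklevel=2
        )
    df = sections.loc[~zero].copy()
    df["query_vaf"] = df["query_alt"] / df["query_depth"]
    df["anchor_vaf"] = df["anchor_alt"] / df["anchor_depth"]
    df["query_detected"] = (df["query_vaf"] > 0) & (
        df["query_alt"] >= min_alt_reads
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["vaf_ratio"] = np.where(
            df["anchor_vaf"] > 0, df["query_vaf"] / df["anchor_vaf"], np.nan
        )
    # the ratio summarizes the query's frequency relative to the clonal
    # anchor where the query is present, so it is taken over detected
    # sections only; sections where the query is absent inform the
    # detection fraction instead
    detected_ratio = df.loc[df["query_detected"], "vaf_ratio"]
    summary = {
        "n_sections": int(len(df)),
        "detection_fraction": float(df["query_detected"].mean()) if len(df) else 0.0,
        "median_vaf_ratio": float(np.nanmedian(detected_ratio))
        if detected_ratio.notna().any()
        else float("nan"),
    }
    return df, summary


def calls_to_frame(calls: Iterable[ClonalityCall]) -> pd.DataFrame:
    """Flatten clonality calls into a tidy table (one row per call)."""
    rows = []
    for c in calls:
        def _unpack(est):
            if est is None:
                return (np.nan, np.nan, np.nan)
            if isinstance(est, CCFEstimate):
                return (est.ccf, est.ci_low, est.ci_high)
            return (float(est), np.nan, np.nan)

        ccf_a, lo_a, hi_a = _unpack(c.site_a)
        ccf_b, lo_b, hi_b = _unpack(c.site_b)
        rows.append(
            {
                "key": c.key,
                "kind": c.kind,
                "gene": c.gene,
                "cancer_gene": c.cancer_gene,
                "category": c.category,
                "ccf_a": ccf_a,
                "ci_low_a": lo_a,
                "ci_high_a": hi_a,
                "ccf_b": ccf_b,
                "ci_low_b": lo_b,
                "ci_high_b": hi_b,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "key", "kind", "gene", "cancer_gene", "category",
            "ccf_a", "ci_low_a", "ci_high_a", "ccf_b", "ci_low_b", "ci_high_b",
        ],
    )
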