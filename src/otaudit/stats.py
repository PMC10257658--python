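"""Control-cohort resampling null, group summaries and colony
heterogeneity.

The resampling null estimates how often naturally occurring variants in
unedited control animals land on predicted off-target sites by chance:
each control draws the median per-sample number of predicted sites from
the pooled prediction set (its own fixed seed, sampling without
replacement) and is intersected with its filtered variants under the
same overlap rule as the real audit.  Group comparisons use two-sided
Wilcoxon rank-sum tests with Bonferroni correction at alpha = 0.05.
Pairwise heterogeneity is the percentage of common variants between two
samples (percent Jaccard by default) fed to hierarchical clustering with
Euclidean distance and complete linkage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import mannwhitneyu

from .formats import Annotation, Genome, VariantRecord, variant_key
from .search import OfftargetSite

logger = logging.getLogger("otaudit")

__all__ = [
    "NullSamplingConfig",
    "HeterogeneityMatrix",
    "median_sites_per_sample",
    "sample_null_overlap",
    "summarize_groups",
    "pairwise_shared_matrix",
    "cluster_samples",
    "expected_incidental_hits",
]


@dataclass(frozen=True)
class NullSamplingConfig:
    """Seeded draw configuration for the control-cohort null.

    ``n_sites_per_control`` is normally the median predicted-site count
    per experimental sample.  By default control *i* (1-based, in cohort
    order) uses seed *i*, reproducing a fixed-seed-per-sampling design.
    """

    n_sites_per_control: int
    seeds: tuple[int, ...] | None = None  # one per control; default 1..n
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_sites_per_control < 1:
            raise ValueError("n_sites_per_control must be >= 1")
        if self.seeds is not None and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("per-control seeds must be unique")


def median_sites_per_sample(site_counts: list[int]) -> int:
    """Median predicted-site count, rounding half up when the median
    falls between two counts."""
    if not site_counts:
        raise ValueError("need at least one experimental sample")
    m = float(np.median(site_counts))
    return int(math.floor(m + 0.5))


def sample_null_overlap(
    pooled_sites: list[OfftargetSite],
    controls: dict[str, list[VariantRecord]],
    config: NullSamplingConfig,
) -> dict:
    """Seeded incidental-overlap null over the control cohort.

    Returns per-control hit lists and counts, the pooled total, and a
    reproducibility manifest (seed and drawn site indices per control).
    Re-running with the same config reproduces the draws exactly.
    """
    if not pooled_sites:
        raise ValueError("pooled site list is empty")
    n_pool = len(pooled_sites)
    n_draw = config.n_sites_per_control
    if not config.with_replacement and n_draw > n_pool:
        raise ValueError(
            f"cannot draw {n_draw} sites from a pool of {n_pool} without replacement"
        )
    seeds = config.seeds or tuple(range(1, len(controls) + 1))
    if len(seeds) < len(controls):
        raise ValueError("fewer seeds than controls")
    per_control_hits: dict[str, list[tuple[OfftargetSite, VariantRecord]]] = {}
    manifest: dict[str, dict] = {}
    for (sample, recs), seed in zip(controls.items(), seeds):
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_pool, size=n_draw, replace=config.with_replacement)
        trees: dict[str, IntervalTree] = {}
        for i in idx:
            s = pooled_sites[int(i)]
            iv = s.site_interval
            trees.setdefault(s.contig, IntervalTree()).addi(iv.start, iv.end, s)
        hits = []
        for v in recs:
            tree = trees.get(v.contig)
            if tree is None:
                continue
            iv = v.interval()
            for node in tree.overlap(iv.start, iv.end):
                hits.append((node.data, v))
        per_control_hits[sample] = hits
        manifest[sample] = {"seed": int(seed), "indices": sorted(int(i) for i in idx)}
    counts = {s: len(h) for s, h in per_control_hits.items()}
    return {
        "hits": per_control_hits,
        "counts": counts,
        "total_hits": sum(counts.values()),
        "n_controls_with_hits": sum(1 for c in counts.values() if c > 0),
        "manifest": manifest,
    }


def expected_incidental_hits(
    n_controls: int,
    n_sites_per_control: int,
    variants_per_control: float,
    site_footprint: float,
    genome_length: int,
    mean_variant_span: float = 1.0,
) -> float:
    """Closed-form expectation of the pooled null-overlap count when
    variants and sites are independently and uniformly placed: each
    (site, variant) pair overlaps with probability
    (footprint + span - 1) / L."""
    p = (site_footprint + mean_variant_span - 1.0) / genome_length
    return n_controls * n_sites_per_control * variants_per_control * p


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

_DEFAULT_FEATURES = ["total", "SNV", "indel", "het", "hom_alt"]
_GENIC_FEATURES = ["exonic", "intronic", "intergenic"]


def _sample_features(
    recs: list[VariantRecord], annotation: Annotation | None
) -> dict[str, int]:
    feats = {
        "total": len(recs),
        "SNV": sum(1 for v in recs if v.vtype == "SNV"),
        "indel": sum(1 for v in recs if v.vtype == "indel"),
        "het": sum(1 for v in recs if v.genotype == "het"),
        "hom_alt": sum(1 for v in recs if v.genotype == "hom_alt"),
    }
    if annotation is not None:
        for k in _GENIC_FEATURES:
            feats[k] = 0
        for v in recs:
            feats[annotation.classify(v.interval())] += 1
    return feats


def summarize_groups(
    variants: dict[str, list[VariantRecord]],
    groups: dict[str, str],
    annotation: Annotation | None = None,
    alpha: float = 0.05,
    features: list[str] | None = None,
) -> dict:
    """Per-group medians/quartiles of variant counts plus rank-sum tests.

    One two-sided Wilcoxon rank-sum (Mann-Whitney) test per feature in
    the family; Bonferroni adjustment multiplies each p-value by the
    family size (capped at 1).  Groups of size < 2 skip testing with a
    warning.
    """
    if features is None:
        features = list(_DEFAULT_FEATURES)
        if annotation is not None:
            features += _GENIC_FEATURES
    rows = []
    for sample, recs in variants.items():
        feats = _sample_features(recs, annotation)
        feats["sample"] = sample
        feats["group"] = groups[sample]
        rows.append(feats)
    df = pd.DataFrame(rows)
    group_names = sorted(df["group"].unique())
    summary = (
        df.groupby("group")[features]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .stack(level=0, future_stack=True)
        .rename_axis(["group", "feature"])[["25%", "50%", "75%"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
        .reset_index()
    )
    tests = []
    if len(group_names) == 2:
        a = df[df["group"] == group_names[0]]
        b = df[df["group"] == group_names[1]]
        if len(a) < 2 or len(b) < 2:
            logger.warning("a group has fewer than 2 samples; tests skipped")
        else:
            m = len(features)
            for feat in features:
                x, y = a[feat].to_numpy(), b[feat].to_numpy()
                if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                    p = 1.0  # identical constant groups: exchangeable
                else:
                    p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
                p_adj = min(1.0, p * m)
                tests.append(
                    {
                        "feature": feat,
                        "group_a": group_names[0],
                        "group_b": group_names[1],
                        "p": p,
                        "p_bonferroni": p_adj,
                        "significant": p_adj < alpha,
                    }
                )
    return {
        "per_sample": df,
        "summary": summary,
        "tests": pd.DataFrame(
            tests,
            columns=["feature", "group_a", "group_b", "p", "p_bonferroni", "significant"],
        ),
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# heterogeneity matrix and clustering
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityMatrix:
    """Pairwise percent-common-variant matrix (symmetric, diagonal 100)."""

    samples: list[str]
    matrix: np.ndarray
    group_labels: dict[str, str] = field(default_factory=dict)
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.samples), len(self.samples)):
            raise ValueError("matrix shape does not match sample list")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("diagonal must be 100")
        if m.min() < -1e-9 or m.max() > 100 + 1e-9:
            raise ValueError("entries must lie in [0, 100]")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def pairwise_shared_matrix(
    variants: dict[str, list[VariantRecord]],
    genome: Genome | None = None,
    group_labels: dict[str, str] | None = None,
    denominator: str = "jaccard",
) -> HeterogeneityMatrix:
    """Percentage of common variants between every pair of samples.

    ``denominator="jaccard"`` uses 100 * |Vi & Vj| / |Vi | Vj| (symmetric
    and bounded); ``"min"`` divides by the smaller set instead.  Pairs
    whose union is empty are defined as 100 and flagged.
    """
    if denominator not in ("jaccard", "min"):
        raise ValueError("denominator must be 'jaccard' or 'min'")
    samples = list(variants)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    keysets = {s: {variant_key(v, genome) for v in variants[s]} for s in samples}
    n = len(samples)
    m = np.zeros((n, n))
    np.fill_diagonal(m, 100.0)
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = keysets[samples[i]], keysets[samples[j]]
            inter = len(a & b)
            denom = len(a | b) if denominator == "jaccard" else min(len(a), len(b))
            if denom == 0:
                val = 100.0
                flagged.append((samples[i], samples[j]))
            else:
                val = 100.0 * inter / denom
            m[i, j] = m[j, i] = val
    return HeterogeneityMatrix(samples, m, group_labels or {}, flagged)


def cluster_samples(matrix: HeterogeneityMatrix, n_clusters: int = 2) -> dict:
    """Hierarchical clustering of the heterogeneity matrix rows
    (Euclidean distance, complete linkage — the conventional heatmap
    defaults); returns leaf order and the flat cut labels."""
    Z = linkage(matrix.matrix, method="complete", metric="euclidean")
    order = [matrix.samples[i] for i in leaves_list(Z)]
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(matrix.samples, flat)}
    return {"order": order, "labels": labels, "linkage": Z}
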