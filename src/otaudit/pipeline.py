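"""End-to-end orchestration: search -> filters -> intersection ->
classification -> on-target confirmation -> null sampling -> group
statistics -> heterogeneity, plus the headline summary ratios.

Percentages are reported at the precision conventional for each ratio
(``RATIO_DEFS``); ad-hoc percentages default to one decimal at >= 1%
and three decimals below 1%, rounding half up.  Every ratio in a
rendered summary is recomputed from its stored counts at render time;
a mismatch raises.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .audit import (
    classify_hits,
    confirm_on_target,
    intersect_sites_variants,
    summarize_hits,
)
from .cohort import Cohort
from .filters import (
    FilterConfig,
    callable_intersection,
    filter_callable,
    primary_filter,
    secondary_filter,
    sv_consensus_filter,
)
from .formats import (
    Annotation,
    Genome,
    Guide,
    Interval,
    SVRecord,
    VariantRecord,
    read_genome,
    read_intervals,
    read_svs,
    read_variants,
)
from .search import OfftargetSite, SearchConfig, enumerate_sites
from .stats import (
    NullSamplingConfig,
    cluster_samples,
    median_sites_per_sample,
    pairwise_shared_matrix,
    sample_null_overlap,
    summarize_groups,
)

logger = logging.getLogger("otaudit")

__all__ = [
    "PipelineInputs",
    "AuditSummary",
    "run_pipeline",
    "compute_summary_ratios",
    "percentage",
    "per_unit_rate",
    "RATIO_DEFS",
]


# ---------------------------------------------------------------------------
# ratio arithmetic
# ---------------------------------------------------------------------------


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(num: float, den: float, decimals: int | None = None) -> float | None:
    """100 * num / den, rounded half up; one decimal at >= 1%, three
    decimals below 1% when ``decimals`` is not given.  A zero denominator
    yields None (undefined, never 0)."""
    if den == 0:
        return None
    pct = 100.0 * num / den
    if decimals is None:
        decimals = 1 if pct >= 1 else 3
    return _round_half_up(pct, decimals)


def per_unit_rate(num: float, den: float, decimals: int = 1) -> float | None:
    if den == 0:
        return None
    return _round_half_up(num / den, decimals)


# name, numerator key, denominator key, kind, reporting decimals
RATIO_DEFS: list[tuple[str, str, str, str, int]] = [
    ("pct_guides_with_activity", "n_guides_with_activity", "n_guides", "pct", 1),
    ("pct_sites_with_variants", "n_sites_with_variants", "n_predicted_sites", "pct", 3),
    ("pct_founders_with_hits", "n_founders_with_hits", "n_founders", "pct", 0),
    ("pct_variants_validated", "n_variants_validated", "n_variants_detected", "pct", 0),
    ("pct_founders_validated", "n_founders_validated", "n_founders", "pct", 0),
    ("pct_ontarget_confirmed", "n_ontarget_confirmed", "n_founders", "pct", 0),
    ("pct_indels_nag", "n_indels_nag", "n_indels", "pct", 0),
    ("rate_offtarget_per_founder", "n_variants_validated", "n_founders", "rate", 1),
]


def compute_summary_ratios(counts: dict) -> dict:
    """Derive every reportable ratio whose numerator and denominator are
    present in ``counts`` (e.g. a pipeline summary, or a counts file of
    published figures)."""
    out = {}
    for name, num_key, den_key, kind, decimals in RATIO_DEFS:
        if num_key in counts and den_key in counts:
            fn = percentage if kind == "pct" else per_unit_rate
            out[name] = fn(counts[num_key], counts[den_key], decimals)
    return out


@dataclass
class AuditSummary:
    """Headline counts of one audit run plus their derived ratios."""

    counts: dict
    ratios: dict = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.ratios:
            self.ratios = compute_summary_ratios(self.counts)
        self.self_check()

    def self_check(self) -> None:
        """Re-derive every ratio from the stored counts; raises on any
        mismatch so a rendered report can never drift from its counts."""
        fresh = compute_summary_ratios(self.counts)
        if fresh != self.ratios:
            raise ValueError(f"ratio self-check failed: {fresh} != {self.ratios}")

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "ratios": self.ratios, "config_hash": self.config_hash},
            indent=1,
        )


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """Everything one audit run consumes."""

    genome: Genome
    repeats: list[Interval]
    annotation: Annotation
    guides_by_founder: dict[str, list[Guide]]
    variants: dict[str, list[VariantRecord]]
    svs: dict[str, list[SVRecord]]
    known: list[VariantRecord]
    callable_sets: dict[str, list[Interval]]
    groups: dict[str, str]  # sample -> control | experimental
    sites_by_guide: dict[str, list[OfftargetSite]] | None = None

    @classmethod
    def from_cohort(cls, cohort: Cohort, reuse_sites: bool = True) -> "PipelineInputs":
        return cls(
            genome=cohort.genome,
            repeats=cohort.repeats,
            annotation=cohort.annotation,
            guides_by_founder={
                fid: list(d.guides) for fid, d in cohort.designs.items()
            },
            variants=cohort.variants,
            svs=cohort.svs,
            known=cohort.known,
            callable_sets=cohort.callable_sets,
            groups=cohort.groups,
            sites_by_guide=cohort.sites_by_guide if reuse_sites else None,
        )

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "PipelineInputs":
        """Load an emitted cohort directory (see
        :func:`otaudit.cohort.emit_cohort` for the layout)."""
        d = Path(in_dir)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        groups = dict(manifest["samples"])
        genome = read_genome(d / "genome.fa")
        repeats = read_intervals(d / "repeats.bed")
        annotation = Annotation(
            read_intervals(d / "exons.bed"), read_intervals(d / "genes.bed")
        )
        gt = pd.read_csv(d / "guides.tsv", sep="\t", dtype=str)
        guides_by_founder: dict[str, list[Guide]] = {}
        for row in gt.itertuples(index=False):
            guides_by_founder.setdefault(row.founder_id, []).append(
                Guide(
                    row.guide_id,
                    row.protospacer,
                    row.pam_rule,
                    None if pd.isna(row.target_gene) else row.target_gene,
                )
            )
        variants = {
            s: read_variants(d / "vcf" / f"{s}.vcf", s) for s in groups
        }
        svs = {s: read_svs(d / "sv" / f"{s}.vcf", s) for s in groups}
        callable_sets = {
            s: read_intervals(d / "callable" / f"{s}.bed") for s in groups
        }
        known = read_variants(d / "known.vcf", "known_db")
        return cls(
            genome=genome,
            repeats=repeats,
            annotation=annotation,
            guides_by_founder=guides_by_founder,
            variants=variants,
            svs=svs,
            known=known,
            callable_sets=callable_sets,
            groups=groups,
        )


ALL_STAGES = (
    "search",
    "filter",
    "audit",
    "ontarget",
    "null",
    "stats",
    "heterogeneity",
)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_pipeline(
    inputs: PipelineInputs | Cohort,
    out_dir: str | Path | None = None,
    search_config: SearchConfig | None = None,
    filter_config: FilterConfig | None = None,
    prediction_ceiling: int = 5,
    null_seeds: tuple[int, ...] | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    make_plots: bool = False,
) -> dict:
    """Run the audit end to end; returns a results dict whose ``summary``
    is the :class:`AuditSummary`.

    Sites are enumerated at the sensitivity ceiling of ``search_config``
    (default mm <= 6 with bulges) and re-binned downstream; the headline
    predicted-site count is reported at ``prediction_ceiling``.
    """
    if isinstance(inputs, Cohort):
        inputs = PipelineInputs.from_cohort(inputs)
    search_config = search_config or SearchConfig(max_mismatches=6, allow_bulge=True)
    filter_config = filter_config or FilterConfig()
    results: dict = {"stages_run": []}
    cfg_text = json.dumps(
        {
            "search": vars(search_config) if hasattr(search_config, "__dict__") else str(search_config),
            "filter": str(filter_config),
            "prediction_ceiling": prediction_ceiling,
            "null_seeds": null_seeds,
            "stages": stages,
        },
        default=str,
        sort_keys=True,
    )
    config_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    logger.info("pipeline start (config %s)", config_hash)

    founders = sorted(inputs.guides_by_founder)
    controls = sorted(s for s, g in inputs.groups.items() if g == "control")
    all_guides = [g for fid in founders for g in inputs.guides_by_founder[fid]]

    def _fail(stage: str, exc: Exception):
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            (Path(out_dir) / "FAILED").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- search -----------------------------------------------------------
    sites_by_guide = inputs.sites_by_guide
    if "search" in stages and sites_by_guide is None:
        try:
            sites_by_guide = {
                g.guide_id: enumerate_sites(g, inputs.genome, search_config)
                for g in all_guides
            }
        except Exception as exc:  # pragma: no cover - defensive
            _fail("search", exc)
    if sites_by_guide is None:
        raise ValueError("sites_by_guide required when search stage is disabled")
    results["sites_by_guide"] = sites_by_guide
    results["stages_run"].append("search")

    offtarget_sites = {
        gid: [s for s in sl if not s.is_on_target]
        for gid, sl in sites_by_guide.items()
    }
    pred_sites = {
        gid: [s for s in sl if s.mismatches <= prediction_ceiling]
        for gid, sl in offtarget_sites.items()
    }
    n_predicted = sum(len(s) for s in pred_sites.values())

    # --- filters ----------------------------------------------------------
    try:
        svs_filtered, sv_report = sv_consensus_filter(inputs.svs, filter_config)
        post_primary, primary_report = primary_filter(
            inputs.variants,
            inputs.known,
            inputs.repeats,
            filter_config,
            inputs.genome,
        )
        intersection = callable_intersection(inputs.callable_sets)
        post_callable = filter_callable(post_primary, intersection, primary_report)
        final_variants, shared = secondary_filter(
            post_callable, filter_config, inputs.genome
        )
        for sample in post_callable:
            n_in = len(post_callable[sample])
            primary_report.add(
                "secondary", sample, n_in, n_in - len(final_variants[sample])
            )
    except Exception as exc:
        _fail("filter", exc)
    results.update(
        post_primary=post_primary,
        final_variants=final_variants,
        svs_filtered=svs_filtered,
        filter_report=primary_report,
        sv_report=sv_report,
        shared_variants=shared,
        callable_intersection=intersection,
    )
    results["stages_run"].append("filter")

    # --- audit ------------------------------------------------------------
    hits = []
    if "audit" in stages:
        try:
            sample_guides = {s: [] for s in inputs.groups}
            for fid in founders:
                sample_guides[fid] = [
                    g.guide_id for g in inputs.guides_by_founder[fid]
                ]
            hits = intersect_sites_variants(
                offtarget_sites,
                sample_guides,
                final_variants,
                svs_filtered,
                inputs.genome,
            )
            hits = classify_hits(hits, inputs.annotation)
        except Exception as exc:
            _fail("audit", exc)
        results["hits"] = hits
        results["hit_summaries"] = {
            ceiling: summarize_hits(hits, ceiling) for ceiling in (4, 5, 6)
        }
        results["stages_run"].append("audit")

    # --- on-target confirmation -------------------------------------------
    ontarget_calls = {}
    if "ontarget" in stages:
        try:
            for fid in founders:
                guides = inputs.guides_by_founder[fid]
                on_sites = {}
                for g in guides:
                    cands = [s for s in sites_by_guide[g.guide_id] if s.is_on_target]
                    if not cands:
                        raise ValueError(f"no on-target site found for {g.guide_id}")
                    on_sites[g.guide_id] = cands[0]
                ontarget_calls[fid] = confirm_on_target(
                    fid,
                    guides,
                    on_sites,
                    svs_filtered.get(fid, []),
                    final_variants.get(fid, []),
                )
        except Exception as exc:
            _fail("ontarget", exc)
        results["ontarget"] = ontarget_calls
        results["stages_run"].append("ontarget")

    # --- null sampling ----------------------------------------------------
    if "null" in stages and controls:
        try:
            per_founder_counts = [
                sum(len(pred_sites[g.guide_id]) for g in inputs.guides_by_founder[fid])
                for fid in founders
            ]
            n_draw = median_sites_per_sample(per_founder_counts)
            pooled = [s for sl in pred_sites.values() for s in sl]
            null_cfg = NullSamplingConfig(
                n_sites_per_control=min(n_draw, len(pooled)),
                seeds=null_seeds or tuple(range(1, len(controls) + 1)),
            )
            null = sample_null_overlap(
                pooled, {s: final_variants[s] for s in controls}, null_cfg
            )
        except Exception as exc:
            _fail("null", exc)
        results["null"] = null
        results["null_median_sites"] = n_draw
        results["stages_run"].append("null")

    # --- group statistics ---------------------------------------------------
    if "stats" in stages:
        try:
            results["group_stats"] = summarize_groups(
                final_variants, inputs.groups, inputs.annotation
            )
        except Exception as exc:
            _fail("stats", exc)
        results["stages_run"].append("stats")

    # --- heterogeneity ------------------------------------------------------
    if "heterogeneity" in stages:
        try:
            matrix = pairwise_shared_matrix(
                post_primary, inputs.genome, group_labels=inputs.groups
            )
            results["heterogeneity"] = matrix
            results["clustering"] = cluster_samples(matrix)
        except Exception as exc:
            _fail("heterogeneity", exc)
        results["stages_run"].append("heterogeneity")

    # --- summary ------------------------------------------------------------
    pred_hit_sites = {
        (h.site.guide_id, h.site.contig, h.site.site_interval.start)
        for h in hits
        if h.site.mismatches <= prediction_ceiling
    }
    founders_with_hits = {h.sample_id for h in hits}
    guides_with_hits = {h.site.guide_id for h in hits}
    counts = {
        "n_guides": len(all_guides),
        "n_founders": len(founders),
        "n_controls": len(controls),
        "n_predicted_sites": n_predicted,
        "n_sites_with_variants": len(pred_hit_sites),
        "n_hits": len(hits),
        "n_founders_with_hits": len(founders_with_hits),
        "n_guides_with_activity": len(guides_with_hits),
        "n_ontarget_confirmed": sum(
            1 for c in ontarget_calls.values() if c.confirmed
        ),
    }
    if "null" in results.get("stages_run", []):
        counts["null_total_hits"] = results["null"]["total_hits"]
        counts["null_controls_with_hits"] = results["null"]["n_controls_with_hits"]
    summary = AuditSummary(counts=counts, config_hash=config_hash)
    results["summary"] = summary

    if out_dir is not None:
        _write_outputs(results, inputs, Path(out_dir), make_plots)
    logger.info("pipeline done: %s", summary.counts)
    return results


# ---------------------------------------------------------------------------
# output rendering
# ---------------------------------------------------------------------------


def _hit_rows(hits) -> pd.DataFrame:
    rows = []
    for h in hits:
        v = h.variant
        rows.append(
            {
                "sample_id": h.sample_id,
                "guide_id": h.site.guide_id,
                "contig": h.site.contig,
                "site_start": h.site.site_interval.start,
                "site_end": h.site.site_interval.end,
                "strand": h.site.strand,
                "mismatches": h.site.mismatches,
                "bulge_type": h.site.bulge_type,
                "pam_class": h.pam_class,
                "mismatch_bin": h.mismatch_bin,
                "variant_class": h.variant_class,
                "genic_context": h.genic_context,
                "variant_pos": getattr(v, "pos", getattr(v, "start", None)),
                "variant_ref": getattr(v, "ref", ""),
                "variant_alt": getattr(v, "alt", getattr(v, "svtype", "")),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["sample_id", "contig", "site_start"]
    ) if rows else pd.DataFrame()


def _write_outputs(
    results: dict, inputs: PipelineInputs, out: Path, make_plots: bool
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(results["summary"].to_json())
    results["filter_report"].write(out / "filter_report.tsv")
    results["sv_report"].write(out / "sv_filter_report.tsv")
    if "hits" in results:
        _hit_rows(results["hits"]).to_csv(out / "hits.tsv", sep="\t", index=False)
        for ceiling, summ in results["hit_summaries"].items():
            summ["table"].to_csv(
                out / f"classification_mm{ceiling}.tsv", sep="\t", index=False
            )
    if "ontarget" in results:
        payload = {
            fid: {
                "confirmed": c.confirmed,
                "target_gene": c.target_gene,
                "expected_interval": [
                    c.expected_interval.contig,
                    c.expected_interval.start,
                    c.expected_interval.end,
                ],
                "evidence": list(c.supporting_evidence),
                "n_supporting_callers": c.n_supporting_callers,
            }
            for fid, c in results["ontarget"].items()
        }
        (out / "ontarget.json").write_text(json.dumps(payload, indent=1))
    if "null" in results:
        (out / "null_manifest.json").write_text(
            json.dumps(
                {
                    "median_sites": results["null_median_sites"],
                    "counts": results["null"]["counts"],
                    "total_hits": results["null"]["total_hits"],
                    "manifest": results["null"]["manifest"],
                },
                indent=1,
            )
        )
    if "group_stats" in results:
        results["group_stats"]["summary"].to_csv(
            out / "group_summary.tsv", sep="\t", index=False
        )
        results["group_stats"]["tests"].to_csv(
            out / "group_tests.tsv", sep="\t", index=False
        )
    if "heterogeneity" in results:
        results["heterogeneity"].write(out / "heterogeneity.tsv")
        (out / "dendrogram_order.txt").write_text(
            "\n".join(results["clustering"]["order"]) + "\n"
        )
    if make_plots:
        from .plots import plot_group_boxplot, plot_heterogeneity_heatmap

        if "heterogeneity" in results:
            plot_heterogeneity_heatmap(
                results["heterogeneity"],
                results["clustering"],
                out / "heterogeneity.png",
            )
        if "group_stats" in results:
            plot_group_boxplot(
                results["group_stats"]["per_sample"], out / "group_counts.png"
            )
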