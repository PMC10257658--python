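"""Intersect filtered variants with predicted off-target sites and
classify the hits.

A *hit* is any (site, variant) pair whose 0-based intervals overlap by
at least one base, with the site drawn from the guides actually used to
make that founder (a founder is never audited against another founder's
guides).  Hits are classified by variant class, PAM class, mismatch bin
(<=4 / 5 / 6) and genic context (exonic / intronic / intergenic, with
upstream/downstream folded into intergenic).  On-target confirmation
checks for a consensus deletion spanning the interval between the
outermost guide cut sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from intervaltree import IntervalTree

from .formats import Annotation, Genome, Interval, SVRecord, VariantRecord
from .search import Guide, OfftargetSite, cut_site

__all__ = [
    "OfftargetHit",
    "OnTargetCall",
    "intersect_sites_variants",
    "classify_hit",
    "classify_hits",
    "summarize_hits",
    "confirm_on_target",
    "compare_site_sets",
    "attribution_scores",
    "MISMATCH_BINS",
]

MISMATCH_BINS = ("<=4", "5", "6")
_SV_CLASS = {"DEL": "SV:del", "DUP": "SV:dup", "INV": "SV:inv", "INS": "SV:ins"}


def mismatch_bin(mismatches: int) -> str:
    if mismatches <= 4:
        return "<=4"
    return str(mismatches)


@dataclass(frozen=True)
class OfftargetHit:
    """One variant overlapping one predicted off-target site."""

    sample_id: str
    site: OfftargetSite
    variant: VariantRecord | SVRecord
    variant_class: str  # SNV | indel | SV:del | SV:dup | SV:inv | SV:ins
    mismatch_bin: str  # <=4 | 5 | 6
    pam_class: str
    genic_context: str = "unclassified"


@dataclass(frozen=True)
class OnTargetCall:
    """Confirmation status of a founder's designed exon deletion."""

    sample_id: str
    target_gene: str | None
    expected_interval: Interval
    confirmed: bool
    supporting_evidence: tuple[str, ...]
    n_supporting_callers: int


def _variant_class(v: VariantRecord | SVRecord) -> str:
    if isinstance(v, SVRecord):
        return _SV_CLASS.get(v.svtype, f"SV:{v.svtype.lower()}")
    return v.vtype


def intersect_sites_variants(
    sites_by_guide: dict[str, list[OfftargetSite]],
    sample_guides: dict[str, list[str]],
    variants: dict[str, list[VariantRecord]],
    svs: dict[str, list[SVRecord]] | None = None,
    genome: Genome | None = None,
) -> list[OfftargetHit]:
    """Emit a hit for every overlapping (site, variant) pair per sample.

    ``sample_guides`` scopes each sample to the guides used in its
    experiment.  On-target sites are excluded from the audit.  A small
    deletion and an SV deletion reporting the same event at one site
    (one interval containing the other) are deduplicated, keeping the
    SV record.
    """
    svs = svs or {}
    hits: list[OfftargetHit] = []
    for sample, guide_ids in sample_guides.items():
        trees: dict[str, IntervalTree] = {}
        for gid in guide_ids:
            for site in sites_by_guide.get(gid, []):
                if site.is_on_target:
                    continue
                if genome is not None and site.contig not in genome:
                    raise ValueError(
                        f"site contig {site.contig!r} absent from genome"
                    )
                iv = site.site_interval
                trees.setdefault(site.contig, IntervalTree()).addi(
                    iv.start, iv.end, site
                )
        sample_hits: list[OfftargetHit] = []
        for rec in list(variants.get(sample, [])) + list(svs.get(sample, [])):
            if genome is not None and rec.contig not in genome:
                raise ValueError(f"variant contig {rec.contig!r} absent from genome")
            tree = trees.get(rec.contig)
            if tree is None:
                continue
            iv = rec.interval()
            for node in tree.overlap(iv.start, iv.end):
                site = node.data
                sample_hits.append(
                    OfftargetHit(
                        sample_id=sample,
                        site=site,
                        variant=rec,
                        variant_class=_variant_class(rec),
                        mismatch_bin=mismatch_bin(site.mismatches),
                        pam_class=site.pam_class,
                    )
                )
        hits.extend(_dedup_del_pairs(sample_hits))
    return hits


def _dedup_del_pairs(hits: list[OfftargetHit]) -> list[OfftargetHit]:
    """Drop a small-variant deletion hit when an SV DEL hit at the same
    site describes the same event (interval containment)."""
    sv_dels = [
        h
        for h in hits
        if isinstance(h.variant, SVRecord) and h.variant.svtype == "DEL"
    ]
    if not sv_dels:
        return hits
    out = []
    for h in hits:
        if (
            isinstance(h.variant, VariantRecord)
            and len(h.variant.ref) > len(h.variant.alt)
        ):
            iv = h.variant.interval()
            dup = any(
                s.site == h.site
                and (
                    s.variant.interval().contains(iv)
                    or iv.contains(s.variant.interval())
                )
                for s in sv_dels
            )
            if dup:
                continue
        out.append(h)
    return out


def classify_hit(hit: OfftargetHit, annotation: Annotation) -> OfftargetHit:
    """Fill in the genic context of a hit from the annotation."""
    return replace(hit, genic_context=annotation.classify(hit.variant.interval()))


def classify_hits(
    hits: list[OfftargetHit], annotation: Annotation
) -> list[OfftargetHit]:
    return [classify_hit(h, annotation) for h in hits]


def summarize_hits(
    hits: list[OfftargetHit], mismatch_ceiling: int = 6
) -> dict:
    """Cross-tabulate hits by variant class x PAM class x mismatch bin,
    restricted to sites with mismatches <= ``mismatch_ceiling``; also
    return genic-context proportions."""
    kept = [h for h in hits if h.site.mismatches <= mismatch_ceiling]
    if kept:
        df = pd.DataFrame(
            {
                "variant_class": [h.variant_class for h in kept],
                "pam_class": [h.pam_class for h in kept],
                "mismatch_bin": [h.mismatch_bin for h in kept],
                "genic_context": [h.genic_context for h in kept],
            }
        )
        table = (
            df.groupby(["variant_class", "pam_class", "mismatch_bin"])
            .size()
            .rename("count")
            .reset_index()
        )
        genic = (df["genic_context"].value_counts(normalize=True)).to_dict()
    else:
        table = pd.DataFrame(
            columns=["variant_class", "pam_class", "mismatch_bin", "count"]
        )
        genic = {}
    return {"table": table, "genic_proportions": genic, "n_hits": len(kept)}


def confirm_on_target(
    sample_id: str,
    guides: list[Guide],
    on_target_sites: dict[str, OfftargetSite],
    svs: list[SVRecord],
    variants: list[VariantRecord],
    target_gene: str | None = None,
    min_callers: int = 2,
    min_small_del_cover: float = 0.5,
) -> OnTargetCall:
    """Confirm a founder's designed deletion between flanking guide cuts.

    Confirmed when a deletion-type record overlaps the expected interval:
    either an SV DEL independently called by >= ``min_callers`` programs,
    or a small-variant deletion covering >= ``min_small_del_cover`` of
    the expected interval.
    """
    if len(guides) < 2:
        raise ValueError(
            f"founder {sample_id}: deletion design requires >= 2 flanking guides"
        )
    cuts = []
    contig = None
    for g in guides:
        site = on_target_sites[g.guide_id]
        cuts.append(cut_site(site, g))
        contig = site.contig
    expected = Interval(contig, min(cuts), max(cuts))
    evidence: list[str] = []
    n_callers = 0
    for sv in svs:
        if sv.svtype != "DEL" or len(sv.callers) < min_callers:
            continue
        if sv.interval().overlaps(expected):
            evidence.append(f"SV:{sv.contig}:{sv.start}-{sv.end}")
            n_callers = max(n_callers, len(sv.callers))
    for v in variants:
        if len(v.ref) <= len(v.alt):
            continue
        iv = v.interval()
        if not iv.overlaps(expected):
            continue
        overlap = min(iv.end, expected.end) - max(iv.start, expected.start)
        if overlap / len(expected) >= min_small_del_cover:
            evidence.append(f"indel:{v.contig}:{v.pos}:{v.ref}>{v.alt}")
    return OnTargetCall(
        sample_id=sample_id,
        target_gene=target_gene
        or next((g.target_gene for g in guides if g.target_gene), None),
        expected_interval=expected,
        confirmed=bool(evidence),
        supporting_evidence=tuple(evidence),
        n_supporting_callers=n_callers,
    )


# ---------------------------------------------------------------------------
# three-way site-set comparison
# ---------------------------------------------------------------------------


def _sites_match(a: OfftargetSite, b: OfftargetSite, tol: int) -> bool:
    """Positional identity: same contig, intervals separated by at most
    ``tol`` bases (overlapping intervals have separation <= 0)."""
    if a.contig != b.contig:
        return False
    ia, ib = a.site_interval, b.site_interval
    return max(ia.start, ib.start) - min(ia.end, ib.end) <= tol


def compare_site_sets(
    set_a: list[OfftargetSite],
    set_b: list[OfftargetSite],
    set_c: list[OfftargetSite],
    tolerance: int = 10,
) -> dict[str, int]:
    """Three-way Venn region counts for site lists from different
    prediction sources (e.g. in-silico search, in-vitro assay, WGS
    evidence).

    Sites are identified positionally within ``tolerance``; the counting
    unit is a connected component of the cross-set match graph, labelled
    by the sources present in it.  Returns the 7 region counts keyed
    "A", "B", "C", "AB", "AC", "BC", "ABC".
    """
    labelled = (
        [("A", s) for s in set_a]
        + [("B", s) for s in set_b]
        + [("C", s) for s in set_c]
    )
    n = len(labelled)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    trees: dict[str, IntervalTree] = {}
    for idx, (_, s) in enumerate(labelled):
        iv = s.site_interval
        trees.setdefault(s.contig, IntervalTree()).addi(
            iv.start, iv.end + tolerance + 1, idx
        )
    for idx, (_, s) in enumerate(labelled):
        iv = s.site_interval
        for node in trees[s.contig].overlap(iv.start, iv.end + tolerance + 1):
            j = node.data
            if j != idx and _sites_match(s, labelled[j][1], tolerance):
                union(idx, j)
    members: dict[int, set[str]] = {}
    for idx, (label, _) in enumerate(labelled):
        members.setdefault(find(idx), set()).add(label)
    counts = {k: 0 for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
    for labels in members.values():
        counts["".join(sorted(labels))] += 1
    return counts


def attribution_scores(
    hits: list[OfftargetHit], truth: list[dict]
) -> dict[str, float]:
    """Precision/recall of hit attribution against a generator truth
    table whose rows carry sample_id, contig and 1-based pos."""
    hit_keys = {
        (h.sample_id, h.variant.contig, getattr(h.variant, "pos", None))
        for h in hits
        if isinstance(h.variant, VariantRecord)
    }
    truth_keys = {(t["sample_id"], t["contig"], t["pos"]) for t in truth}
    tp = len(hit_keys & truth_keys)
    precision = tp / len(hit_keys) if hit_keys else float("nan")
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    return {
        "tp": tp,
        "n_hits": len(hit_keys),
        "n_truth": len(truth_keys),
        "precision": precision,
        "recall": recall,
    }
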