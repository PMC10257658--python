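"""The variant filter cascade for de novo variant discovery in founders.

Primary filter (per sample, in order):

1. quality — retain ``QUAL > 30``, ``DP > 9``, ``GQ > 30`` and ``AF > 0.1``
   (all strict, exactly as the thresholds are stated);
2. repeats — drop any variant whose reference span overlaps a repeat or
   tandem-repeat interval padded by 2 bp on both sides (padding absorbs
   indels that straddle repeat boundaries);
3. known — drop variants present in the known-variant database
   (dbSNP/EVA stand-in), matched on the left-normalized identity tuple
   (contig, pos, ref, alt) or, optionally, on position only;
4. het-ratio — drop heterozygous calls whose alternate-allele read
   fraction ``ad_alt / (ad_ref + ad_alt)`` is below 0.2.

Callable filtering restricts variants to the intersection of all
samples' callable intervals, and the secondary filter removes any
variant observed in two or more independent samples, leaving each
animal's unique variants.  Structural variants pass a separate consensus
filter (>= 2 callers, >= 3 supporting reads, length strictly between
200 bp and 5 kb) followed by cross-sample breakpoint-pair matching.

Every stage is a pure removal; counts are tracked in a
:class:`FilterReport` whose per-stage bookkeeping must reconcile
(in − removed = out).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .formats import Genome, Interval, SVRecord, VariantRecord, variant_key

logger = logging.getLogger("otaudit")

__all__ = [
    "FilterConfig",
    "FilterReport",
    "primary_filter",
    "callable_intersection",
    "filter_callable",
    "secondary_filter",
    "sv_consensus_filter",
    "known_variant_set",
]

PRIMARY_STAGES = ["quality", "repeats", "known", "het_ratio"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.  All printed thresholds are
    strict inequalities: a variant passes quality when QUAL > min_qual,
    DP > min_dp, GQ > min_gq and AF > min_af; an SV passes length when
    sv_min_len < length < sv_max_len."""

    min_qual: float = 30.0
    min_dp: int = 9
    min_gq: float = 30.0
    min_af: float = 0.1
    het_ratio_floor: float = 0.2
    repeat_pad: int = 2
    shared_min_samples: int = 2
    sv_min_callers: int = 2
    sv_min_reads: int = 3
    sv_min_len: int = 200
    sv_max_len: int = 5000
    known_match_positional: bool = False
    sv_breakpoint_tol: int = 100

    def __post_init__(self) -> None:
        if self.sv_min_len >= self.sv_max_len:
            raise ValueError("sv_min_len must be < sv_max_len")


class FilterReport:
    """Stage-by-stage per-sample accounting of a filter run."""

    def __init__(self) -> None:
        self.entries: list[dict] = []
        self.stage_order: list[str] = []

    def add(self, stage: str, sample: str, n_in: int, n_removed: int) -> None:
        if n_removed > n_in:
            raise ValueError("removed more records than entered a stage")
        if stage not in self.stage_order:
            self.stage_order.append(stage)
        self.entries.append(
            {
                "stage": stage,
                "sample": sample,
                "n_in": n_in,
                "n_removed": n_removed,
                "n_out": n_in - n_removed,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["stage", "sample", "n_in", "n_removed", "n_out"]
        )

    def to_json(self) -> str:
        return json.dumps({"stage_order": self.stage_order, "entries": self.entries})

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def totals(self, stage: str) -> tuple[int, int, int]:
        rows = [e for e in self.entries if e["stage"] == stage]
        return (
            sum(r["n_in"] for r in rows),
            sum(r["n_removed"] for r in rows),
            sum(r["n_out"] for r in rows),
        )


def known_variant_set(
    known: list[VariantRecord],
    genome: Genome | None = None,
    positional: bool = False,
) -> set:
    """Normalize a known-variant list to a matchable identity set."""
    if positional:
        out = set()
        for v in known:
            contig, pos, _, _ = variant_key(v, genome)
            out.add((contig, pos))
        return out
    return {variant_key(v, genome) for v in known}


def _passes_quality(v: VariantRecord, cfg: FilterConfig, warn: set) -> bool:
    checks = [
        ("QUAL", v.qual, cfg.min_qual),
        ("DP", float(v.depth), float(cfg.min_dp)),
        ("GQ", v.gq, cfg.min_gq),
        ("AF", v.af, cfg.min_af),
    ]
    for name, value, floor in checks:
        if value is None or (isinstance(value, float) and math.isnan(value)) or value < 0:
            # annotation absent: the rule cannot be applied; keep and warn once
            if (v.sample_id, name) not in warn:
                warn.add((v.sample_id, name))
                logger.warning(
                    "sample %s: %s missing on some records; quality rule skipped",
                    v.sample_id,
                    name,
                )
            continue
        if not value > floor:
            return False
    return True


def primary_filter(
    variants: dict[str, list[VariantRecord]],
    known: set | list[VariantRecord],
    repeats: list[Interval],
    config: FilterConfig | None = None,
    genome: Genome | None = None,
) -> tuple[dict[str, list[VariantRecord]], FilterReport]:
    """Apply the four primary stages per sample; returns survivors and a
    stage-by-stage :class:`FilterReport`."""
    cfg = config or FilterConfig()
    if not isinstance(known, (set, frozenset)):
        known = known_variant_set(known, genome, cfg.known_match_positional)
    repeat_trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        p = iv.padded(cfg.repeat_pad)
        repeat_trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end)
    report = FilterReport()
    out: dict[str, list[VariantRecord]] = {}
    warn: set = set()
    for sample, recs in variants.items():
        # stage 1: quality thresholds
        kept = [v for v in recs if _passes_quality(v, cfg, warn)]
        report.add("quality", sample, len(recs), len(recs) - len(kept))

        # stage 2: padded repeat overlap
        n_in = len(kept)
        kept2 = []
        for v in kept:
            iv = v.interval()
            tree = repeat_trees.get(v.contig)
            if tree is not None and tree.overlap(iv.start, iv.end):
                continue
            kept2.append(v)
        report.add("repeats", sample, n_in, n_in - len(kept2))

        # stage 3: known-variant database
        n_in = len(kept2)
        if cfg.known_match_positional:
            kept3 = [
                v for v in kept2 if (variant_key(v, genome)[:2]) not in known
            ]
        else:
            kept3 = [v for v in kept2 if variant_key(v, genome) not in known]
        report.add("known", sample, n_in, n_in - len(kept3))

        # stage 4: heterozygous allele-ratio floor
        n_in = len(kept3)
        kept4 = []
        for v in kept3:
            if v.genotype == "het":
                ratio = v.het_ratio
                if ratio is not None and not math.isnan(ratio):
                    if ratio < cfg.het_ratio_floor:
                        continue
                elif (v.sample_id, "het_ratio") not in warn:
                    warn.add((v.sample_id, "het_ratio"))
                    logger.warning(
                        "sample %s: AD and AF both missing on het records; "
                        "allele-ratio rule skipped",
                        v.sample_id,
                    )
            kept4.append(v)
        report.add("het_ratio", sample, n_in, n_in - len(kept4))
        out[sample] = kept4
    return out, report


def _merge(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, spans in by_contig.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[contig] = out
    return merged


def callable_intersection(
    callable_sets: dict[str, list[Interval]] | list[list[Interval]],
) -> list[Interval]:
    """Intersection of callable intervals across ALL samples.

    A sample with an empty callable set makes the intersection empty
    (with a logged warning).
    """
    if isinstance(callable_sets, dict):
        sets = list(callable_sets.values())
        names = list(callable_sets)
    else:
        sets = list(callable_sets)
        names = [str(i) for i in range(len(sets))]
    if not sets:
        raise ValueError("need at least one sample's callable intervals")
    for name, s in zip(names, sets):
        if not s:
            logger.warning("sample %s has no callable intervals; intersection empty", name)
            return []
    n = len(sets)
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for contig, spans in _merge(s).items():
            ev = events.setdefault(contig, [])
            for a, b in spans:
                ev.append((a, 1))
                ev.append((b, -1))
    out: list[Interval] = []
    for contig in sorted(events):
        ev = sorted(events[contig])
        depth, open_at = 0, None
        for pos, delta in ev:
            prev = depth
            depth += delta
            if prev < n <= depth:
                open_at = pos
            elif prev >= n > depth:
                if open_at is not None and pos > open_at:
                    out.append(Interval(contig, open_at, pos))
                open_at = None
    return out


def filter_callable(
    variants: dict[str, list[VariantRecord]],
    intersection: list[Interval],
    report: FilterReport | None = None,
) -> dict[str, list[VariantRecord]]:
    """Keep only variants whose full reference span lies inside the
    callable intersection (a variant partially outside is not confidently
    callable in every sample)."""
    trees: dict[str, IntervalTree] = {}
    for iv in intersection:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    out: dict[str, list[VariantRecord]] = {}
    for sample, recs in variants.items():
        kept = []
        for v in recs:
            iv = v.interval()
            tree = trees.get(v.contig)
            if tree is None:
                continue
            hits = tree.overlap(iv.start, iv.end)
            if any(h.begin <= iv.start and iv.end <= h.end for h in hits):
                kept.append(v)
        if report is not None:
            report.add("callable", sample, len(recs), len(recs) - len(kept))
        out[sample] = kept
    return out


def secondary_filter(
    variants: dict[str, list[VariantRecord]],
    config: FilterConfig | None = None,
    genome: Genome | None = None,
) -> tuple[dict[str, list[VariantRecord]], set]:
    """Remove variants observed in ``shared_min_samples`` or more distinct
    samples; returns per-sample unique variants and the shared identity
    set."""
    cfg = config or FilterConfig()
    seen: dict[tuple, set[str]] = {}
    keys: dict[str, list[tuple]] = {}
    for sample, recs in variants.items():
        keys[sample] = [variant_key(v, genome) for v in recs]
        for k in keys[sample]:
            seen.setdefault(k, set()).add(sample)
    shared = {k for k, samples in seen.items() if len(samples) >= cfg.shared_min_samples}
    out = {
        sample: [v for v, k in zip(recs, keys[sample]) if k not in shared]
        for sample, recs in variants.items()
    }
    return out, shared


def sv_consensus_filter(
    svs: dict[str, list[SVRecord]],
    config: FilterConfig | None = None,
) -> tuple[dict[str, list[SVRecord]], FilterReport]:
    """SV consensus and shared-SV filtering.

    Removes missing/hom-ref genotypes, then requires >= sv_min_callers
    independent callers, >= sv_min_reads supporting reads and a length
    strictly between sv_min_len and sv_max_len; finally removes SVs whose
    breakpoint pair matches another sample's SV of the same type within
    ``sv_breakpoint_tol`` bp per breakpoint (strand ignored).
    """
    cfg = config or FilterConfig()
    report = FilterReport()
    stage1: dict[str, list[SVRecord]] = {}
    for sample, recs in svs.items():
        kept = [r for r in recs if r.genotype not in ("missing", "hom_ref")]
        report.add("genotype", sample, len(recs), len(recs) - len(kept))
        kept2 = []
        for r in kept:
            if not r.callers:
                logger.warning(
                    "sample %s: SV %s:%d-%d has no caller annotation; removed "
                    "(consensus cannot be established)",
                    sample,
                    r.contig,
                    r.start,
                    r.end,
                )
                continue
            if len(r.callers) < cfg.sv_min_callers:
                continue
            if r.support_reads < cfg.sv_min_reads:
                continue
            if not (cfg.sv_min_len < r.sv_length < cfg.sv_max_len):
                continue
            kept2.append(r)
        report.add("consensus", sample, len(kept), len(kept) - len(kept2))
        stage1[sample] = kept2

    # shared-SV removal: breakpoint-pair matching across samples
    flat = [(sample, r) for sample, recs in stage1.items() for r in recs]
    tol = cfg.sv_breakpoint_tol
    shared_idx: set[int] = set()
    for i in range(len(flat)):
        si, ri = flat[i]
        for j in range(i + 1, len(flat)):
            sj, rj = flat[j]
            if si == sj or ri.svtype != rj.svtype or ri.contig != rj.contig:
                continue
            if abs(ri.start - rj.start) <= tol and abs(ri.end - rj.end) <= tol:
                shared_idx.add(i)
                shared_idx.add(j)
    out: dict[str, list[SVRecord]] = {s: [] for s in stage1}
    for idx, (sample, r) in enumerate(flat):
        if idx not in shared_idx:
            out[sample].append(r)
    for sample in stage1:
        n_in = len(stage1[sample])
        report.add("shared", sample, n_in, n_in - len(out[sample]))
    return out, report
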