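"""Synthetic study generator: a complete toy editing experiment with a
full truth ledger.

The generator emulates the structure of a multi-centre founder-audit
study on a desk-scale genome (default 3 contigs x 300 kb): an inbred
colony carrying substrain-shared homozygous variants, a colony-wide
"ancestral" pool partly present in the known-variant database,
per-mouse private variants (~756 SNVs and ~276 indels, ~80% het, plus
spontaneous de novo variants at ~25 SNVs and 1-2 indels per
generation), founders made with 2-4 guides flanking a critical exon,
an on-target deletion observed by a panel of synthetic SV callers, and
off-target indels injected at predicted sites with a probability that
decays with mismatch count.

The per-mismatch edit-probability decay is a synthetic stand-in (no
published per-mismatch rate exists); its defaults are chosen so both
positive and negative recovery cases occur at the default cohort size.
Background variant identity tuples are drawn globally without
replacement, so "private" variants are genuinely private and the filter
cascade's expected behaviour is exact against the truth ledger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats import (
    Annotation,
    Genome,
    Guide,
    Interval,
    PAM_NGG_NAG,
    SVRecord,
    VariantRecord,
    left_normalize,
    revcomp,
    write_genome,
    write_guides,
    write_intervals,
    write_svs,
    write_variants,
)
from .search import OfftargetSite, SearchConfig, cut_site, enumerate_sites

logger = logging.getLogger("otaudit")

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "FounderDesign",
    "generate_cohort",
    "check_design_rule",
    "emit_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Counts and rates default to the emulated study design: 28 controls
    and 50 founders, 2-4 guides per founder, ~756 private SNVs and ~276
    private indels per mouse (~80% heterozygous), de novo rates of 25
    SNVs and 1.5 indels per generation, and two substrains with shared
    homozygous variant pools.  ``offtarget_decay`` maps mismatch count
    to edit probability (``p_far`` beyond the listed entries) and is a
    synthetic stand-in.
    """

    seed: int = 1
    n_contigs: int = 3
    contig_length: int = 300_000
    n_controls: int = 28
    n_founders: int = 50
    guides_min: int = 2
    guides_max: int = 4
    substrains: tuple[str, str] = ("NJ", "NCrl")
    shared_per_substrain: int = 120
    snv_mean: float = 756.0
    indel_mean: float = 276.0
    het_fraction: float = 0.8
    de_novo_snv_rate: float = 25.0
    de_novo_indel_rate: float = 1.5
    n_ancestral: int = 400
    known_db_fraction: float = 0.7
    repeat_fraction: float = 0.05
    repeat_variants_per_sample: int = 15
    callable_fraction: float = 1.0
    offtarget_decay: tuple[tuple[int, float], ...] = (
        (0, 1.0),
        (1, 0.25),
        (2, 0.05),
        (3, 0.01),
    )
    p_far: float = 0.001
    decoy_mismatches: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    sv_caller_panel: tuple[str, ...] = ("lumpy", "manta", "cnvkit", "wham")
    sv_caller_detect_p: float = 0.9
    n_single_caller_founders: int = 1
    background_svs_mean: float = 3.0
    fail_fraction: float = 0.0
    search_max_mismatches: int = 6
    allow_rule_violating_decoys: bool = False

    def edit_probability(self, mismatches: int) -> float:
        for mm, p in self.offtarget_decay:
            if mm == mismatches:
                return p
        return self.p_far


@dataclass
class FounderDesign:
    founder_id: str
    guides: list[Guide]
    critical_exon: Interval
    expected_deletion: Interval  # 0-based, between outermost cut sites


@dataclass
class CohortTruth:
    """Ledger of every planted event, consistent record-for-record with
    the emitted call sets."""

    background: list[dict] = field(default_factory=list)
    offtarget_edits: list[dict] = field(default_factory=list)
    ontarget: dict[str, dict] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)
    injection_expected: float = 0.0
    injection_variance: float = 0.0

    def background_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.background)

    def edits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.offtarget_edits)


@dataclass
class Cohort:
    config: CohortConfig
    genome: Genome
    repeats: list[Interval]
    annotation: Annotation
    designs: dict[str, FounderDesign]
    sites_by_guide: dict[str, list[OfftargetSite]]
    variants: dict[str, list[VariantRecord]]
    svs: dict[str, list[SVRecord]]
    known: list[VariantRecord]
    callable_sets: dict[str, list[Interval]]
    groups: dict[str, str]  # sample -> control | experimental
    substrain: dict[str, str]
    truth: CohortTruth

    @property
    def controls(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "control"]

    @property
    def founders(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "experimental"]

    def sample_guides(self) -> dict[str, list[str]]:
        out = {s: [] for s in self.groups}
        for fid, design in self.designs.items():
            out[fid] = [g.guide_id for g in design.guides]
        return out


# ---------------------------------------------------------------------------
# genome, repeats, annotation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_genome(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[list[str]], list[Interval], list[Interval], list[Interval]]:
    """Random contigs with embedded low-complexity repeat tracts and a
    gene/exon annotation placed clear of the founder design blocks.

    Returns mutable contig sequences (list of chars, finalized later),
    repeat intervals, exon intervals and gene-body intervals.
    """
    n_per_contig = -(-config.n_founders // config.n_contigs)
    design_end = 2_000 + n_per_contig * _BLOCK + 1_000
    if design_end + 40_000 > config.contig_length:
        raise ValueError(
            "contig_length too small for the requested founder designs"
        )
    contigs = [
        list(_random_seq(rng, config.contig_length)) for _ in range(config.n_contigs)
    ]
    repeats: list[Interval] = []
    exons: list[Interval] = []
    genes: list[Interval] = []
    target = int(config.repeat_fraction * config.contig_length)
    for ci, seq in enumerate(contigs):
        name = f"chr{ci + 1}"
        # repeat tracts: dinucleotide expansions in the non-design zone
        placed = 0
        cursor = design_end + rng.integers(200, 2_000)
        while placed < target and cursor < config.contig_length - 1_000:
            length = int(rng.integers(100, 500))
            unit = _random_seq(rng, 2)
            tract = (unit * (length // 2 + 1))[:length]
            seq[cursor : cursor + length] = list(tract)
            repeats.append(Interval(name, cursor, cursor + length, "repeat"))
            placed += length
            cursor += length + int(rng.integers(400, 3_000))
        # genes with exons, interleaved between repeat tracts
        gene_cursor = design_end + 500
        for gi in range(8):
            gene_len = int(rng.integers(3_000, 8_000))
            gs = gene_cursor + int(rng.integers(0, 2_000))
            ge = gs + gene_len
            if ge > config.contig_length - 500:
                break
            genes.append(Interval(name, gs, ge, f"gene_{name}_{gi}"))
            n_ex = int(rng.integers(2, 6))
            ex_positions = np.sort(rng.choice(gene_len - 400, size=n_ex, replace=False))
            last_end = gs
            for k, off in enumerate(ex_positions):
                es = gs + int(off)
                ee = es + int(rng.integers(150, 300))
                if es < last_end or ee > ge:
                    continue
                exons.append(Interval(name, es, ee, f"exon_{name}_{gi}_{k}"))
                last_end = ee
            gene_cursor = ge + int(rng.integers(1_000, 4_000))
    return contigs, repeats, exons, genes


_BLOCK = 13_000  # per-founder design block (guides + critical exon + decoys)


# ---------------------------------------------------------------------------
# guides and decoys
# ---------------------------------------------------------------------------


def _embed(contigs: list[list[str]], ci: int, pos: int, seq: str) -> None:
    contigs[ci][pos : pos + len(seq)] = list(seq)


def _mutate(rng: np.random.Generator, proto: str, n_mm: int) -> str:
    pos = rng.choice(20, size=n_mm, replace=False)
    chars = list(proto)
    for p in pos:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def plant_guides(
    contigs: list[list[str]],
    config: CohortConfig,
    rng: np.random.Generator,
    reserved: dict[str, IntervalTree],
    truth: CohortTruth,
) -> dict[str, FounderDesign]:
    """Plant per-founder guide on-targets flanking a critical exon, plus
    decoy near-match loci at controlled mismatch distances.

    Guides respect the design rule (no <3-mismatch site next to an NGG
    PAM): close decoys (1-2 mismatches) get NAG PAMs unless
    ``allow_rule_violating_decoys`` is set.
    """
    designs: dict[str, FounderDesign] = {}
    for i in range(config.n_founders):
        fid = f"F{i + 1:02d}"
        ci = i % config.n_contigs
        contig = f"chr{ci + 1}"
        slot = i // config.n_contigs
        block = 2_000 + slot * _BLOCK
        exon_start = block + 5_500
        exon = Interval(contig, exon_start, exon_start + 200, f"critical_{fid}")
        n_guides = int(rng.integers(config.guides_min, config.guides_max + 1))
        cut_left = exon_start - int(rng.integers(150, 600))
        cut_right = exon.end + int(rng.integers(150, 600))
        cuts = [cut_left, cut_right]
        for k in range(n_guides - 2):
            # inner cuts keep >= 30 bp from every other cut so embedded
            # guide windows (23 nt) never overwrite one another
            for _ in range(100):
                cand = int(rng.integers(cut_left + 40, cut_right - 40))
                if all(abs(cand - c) >= 30 for c in cuts):
                    cuts.append(cand)
                    break
            else:
                raise RuntimeError(f"could not place inner guide cut for {fid}")
        # reserve the whole expected deletion span before scattering decoys
        reserved.setdefault(contig, IntervalTree()).addi(
            min(cuts) - 30, max(cuts) + 30
        )
        guides: list[Guide] = []
        for k, cut in enumerate(sorted(cuts)):
            gid = f"{fid}_g{k + 1}"
            proto = _random_seq(rng, 20)
            s = cut - 17  # plus strand: cut = protospacer_start + 17
            pam = _random_seq(rng, 1) + "GG"
            _embed(contigs, ci, s, proto + pam)
            reserved[contig].addi(s - 2, s + 25)
            guides.append(
                Guide(gid, proto, PAM_NGG_NAG, target_gene=f"Gene{fid}")
            )
            truth.planted_sites.append(
                {
                    "guide_id": gid,
                    "contig": contig,
                    "start": s,
                    "end": s + 23,
                    "strand": "+",
                    "mismatches": 0,
                    "pam_class": "NGG",
                    "kind": "on_target",
                }
            )
            # decoy near-matches scattered in the design zone
            for mm in config.decoy_mismatches:
                decoy = _mutate(rng, proto, mm)
                if mm < 3 and not config.allow_rule_violating_decoys:
                    pam_tail = "AG"
                else:
                    pam_tail = "GG" if rng.random() < 0.5 else "AG"
                dseq = decoy + _random_seq(rng, 1) + pam_tail
                strand = "+" if rng.random() < 0.5 else "-"
                placed = _place_free(
                    contigs,
                    ci,
                    contig,
                    len(dseq),
                    rng,
                    reserved,
                    lo=block + 50,
                    hi=block + _BLOCK - 50,
                )
                _embed(
                    contigs, ci, placed, dseq if strand == "+" else revcomp(dseq)
                )
                truth.planted_sites.append(
                    {
                        "guide_id": gid,
                        "contig": contig,
                        "start": placed,
                        "end": placed + 23,
                        "strand": strand,
                        "mismatches": mm,
                        "pam_class": "NGG" if pam_tail == "GG" else "NAG",
                        "kind": "decoy",
                    }
                )
        designs[fid] = FounderDesign(
            founder_id=fid,
            guides=guides,
            critical_exon=exon,
            expected_deletion=Interval(contig, min(cuts), max(cuts)),
        )
    return designs


def _place_free(
    contigs: list[list[str]],
    ci: int,
    contig: str,
    length: int,
    rng: np.random.Generator,
    reserved: dict[str, IntervalTree],
    lo: int,
    hi: int,
) -> int:
    """Random locus in [lo, hi) not overlapping a reserved span.

    Keeping decoys inside the founder's design block keeps them clear of
    repeat tracts and other founders' deletion spans."""
    tree = reserved.setdefault(contig, IntervalTree())
    hi = min(hi, len(contigs[ci]) - length - 100)
    for _ in range(300):
        pos = int(rng.integers(lo, hi))
        if not tree.overlap(pos - 2, pos + length + 2):
            tree.addi(pos - 2, pos + length + 2)
            return pos
    raise RuntimeError(
        "could not place a decoy locus after 300 retries; use a larger genome"
    )


def check_design_rule(
    guide: Guide, sites: list[OfftargetSite], max_close_mm: int = 3
) -> list[OfftargetSite]:
    """Return sites violating the guide design rule: off-target loci with
    fewer than ``max_close_mm`` mismatches adjacent to an NGG PAM.

    The rule is evaluated the way guide-design tools score it: on gapless
    matches only, ignoring bulged re-alignments and any locus overlapping
    the on-target site itself.
    """
    on_ivs = [s.site_interval for s in sites if s.is_on_target]
    return [
        s
        for s in sites
        if not s.is_on_target
        and s.bulge_type == "none"
        and s.pam_class == "NGG"
        and s.mismatches < max_close_mm
        and not any(s.site_interval.overlaps(iv) for iv in on_ivs)
    ]


# ---------------------------------------------------------------------------
# colony background variants
# ---------------------------------------------------------------------------


class _TupleRegistry:
    """Global registry of used normalized identity tuples; guarantees
    cross-sample uniqueness of planted private variants."""

    def __init__(self, genome_seqs: dict[str, str]):
        self.seqs = genome_seqs
        self.used: set = set()

    def claim(self, contig: str, pos: int, ref: str, alt: str) -> bool:
        key = (contig,) + left_normalize(self.seqs[contig], pos, ref, alt)
        if key in self.used:
            return False
        self.used.add(key)
        return True


def _draw_alleles(
    rng: np.random.Generator, seq: str, pos0: int, vtype: str
) -> tuple[int, str, str]:
    """Alleles at 0-based position ``pos0``; returns (1-based pos, ref, alt)."""
    if vtype == "SNV":
        ref = seq[pos0]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return pos0 + 1, ref, str(alt)
    if rng.random() < 0.6:  # deletion
        k = int(rng.integers(1, 9))
        ref = seq[pos0 : pos0 + 1 + k]
        return pos0 + 1, ref, ref[0]
    k = int(rng.integers(1, 9))
    anchor = seq[pos0]
    return pos0 + 1, anchor, anchor + _random_seq(rng, k)


def _qualities(
    rng: np.random.Generator, genotype: str, fail: str | None = None
) -> tuple[float, int, float, int, int]:
    """(qual, dp, gq, ad_ref, ad_alt) from passing distributions, with
    deliberate failure tails on request."""
    dp = int(np.clip(round(rng.normal(36, 6)), 12, 80))
    qual = float(np.clip(rng.normal(250, 80), 40, None))
    gq = float(np.clip(rng.normal(75, 12), 35, 99))
    if genotype == "hom_alt":
        ad_alt = dp - int(rng.integers(0, 2))
    else:
        lo, hi = int(np.ceil(0.28 * dp)), int(np.floor(0.72 * dp))
        ad_alt = int(np.clip(rng.binomial(dp, 0.5), lo, hi))
    if fail == "qual":
        qual = float(rng.uniform(5, 30))
    elif fail == "dp":
        dp = int(rng.integers(3, 10))
        ad_alt = min(ad_alt, dp)
    elif fail == "gq":
        gq = float(rng.uniform(5, 30))
    elif fail == "af":
        ad_alt = max(1, int(0.08 * dp))
    elif fail == "het_ratio":
        ad_alt = max(2, int(0.15 * dp))
    return qual, dp, gq, dp - ad_alt, ad_alt


_FAIL_MODES = ["qual", "dp", "gq", "af", "het_ratio"]


def _make_record(
    sample: str,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    genotype: str,
    rng: np.random.Generator,
    fail: str | None = None,
) -> VariantRecord:
    qual, dp, gq, ad_ref, ad_alt = _qualities(rng, genotype, fail)
    denom = ad_ref + ad_alt
    return VariantRecord(
        sample_id=sample,
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        vtype="SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
        genotype=genotype,
        qual=qual,
        depth=dp,
        gq=gq,
        af=ad_alt / denom if denom else 0.0,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )


class _Placer:
    """Draws variant loci subject to placement constraints."""

    def __init__(
        self,
        genome: Genome,
        repeats: list[Interval],
        reserved: dict[str, IntervalTree],
        registry: _TupleRegistry,
        rng: np.random.Generator,
        repeat_pad: int = 2,
    ):
        self.genome = genome
        self.rng = rng
        self.registry = registry
        self.reserved = reserved
        self.repeat_trees: dict[str, IntervalTree] = {}
        for iv in repeats:
            p = iv.padded(repeat_pad)
            self.repeat_trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end)
        self.contigs = list(genome.sequences)
        lengths = np.array([genome.length(c) for c in self.contigs], dtype=float)
        self.weights = lengths / lengths.sum()
        self.repeats_by_contig: dict[str, list[Interval]] = {}
        for iv in repeats:
            self.repeats_by_contig.setdefault(iv.contig, []).append(iv)

    def in_repeat(self, contig: str, start: int, end: int) -> bool:
        tree = self.repeat_trees.get(contig)
        return bool(tree and tree.overlap(start, end))

    def in_reserved(self, contig: str, start: int, end: int) -> bool:
        tree = self.reserved.get(contig)
        return bool(tree and tree.overlap(start, end))

    def draw(
        self, vtype: str, avoid_repeats: bool = True, avoid_reserved: bool = True
    ) -> tuple[str, int, str, str]:
        for _ in range(500):
            contig = self.contigs[
                int(self.rng.choice(len(self.contigs), p=self.weights))
            ]
            seq = self.genome.sequences[contig]
            pos0 = int(self.rng.integers(20, len(seq) - 20))
            pos, ref, alt = _draw_alleles(self.rng, seq, pos0, vtype)
            iv_start, iv_end = pos - 1, pos - 1 + len(ref)
            if avoid_repeats and self.in_repeat(contig, iv_start, iv_end):
                continue
            if avoid_reserved and self.in_reserved(contig, iv_start, iv_end):
                continue
            if not self.registry.claim(contig, pos, ref, alt):
                continue
            return contig, pos, ref, alt
        raise RuntimeError("variant placement failed after 500 retries")

    def draw_in_repeat(self, vtype: str) -> tuple[str, int, str, str]:
        all_repeats = [iv for ivs in self.repeats_by_contig.values() for iv in ivs]
        for _ in range(500):
            iv = all_repeats[int(self.rng.integers(0, len(all_repeats)))]
            seq = self.genome.sequences[iv.contig]
            pos0 = int(self.rng.integers(iv.start + 2, iv.end - 12))
            pos, ref, alt = _draw_alleles(self.rng, seq, pos0, vtype)
            if not self.registry.claim(iv.contig, pos, ref, alt):
                continue
            return iv.contig, pos, ref, alt
        raise RuntimeError("repeat-variant placement failed")


def _pool_variants(
    placer: _Placer,
    rng: np.random.Generator,
    n: int,
    genotype: str | None = None,
) -> list[tuple[str, int, str, str, str]]:
    """Draw a pool of (contig,pos,ref,alt,genotype) shared loci."""
    out = []
    for i in range(n):
        vtype = "SNV" if i % 4 != 3 else "indel"  # ~3:1
        contig, pos, ref, alt = placer.draw(vtype)
        gt = genotype or ("het" if rng.random() < 0.5 else "hom_alt")
        out.append((contig, pos, ref, alt, gt))
    return out


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic study from a single seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    truth = CohortTruth()
    reserved: dict[str, IntervalTree] = {}

    contigs, repeats, exons, genes = generate_genome(config, rng)
    designs = plant_guides(contigs, config, rng, reserved, truth)

    genome = Genome(
        {f"chr{i + 1}": "".join(c) for i, c in enumerate(contigs)}
    )
    annotation = Annotation(exons, genes)

    # enumerate predicted sites for every guide (injection needs them)
    search_cfg = SearchConfig(
        max_mismatches=config.search_max_mismatches, allow_bulge=True
    )
    sites_by_guide: dict[str, list[OfftargetSite]] = {}
    for design in designs.values():
        for g in design.guides:
            sites_by_guide[g.guide_id] = enumerate_sites(g, genome, search_cfg)

    samples = [f"C{i + 1:02d}" for i in range(config.n_controls)] + list(designs)
    groups = {
        s: ("control" if s.startswith("C") else "experimental") for s in samples
    }
    substrain = {
        s: config.substrains[i % len(config.substrains)]
        for i, s in enumerate(samples)
    }

    registry = _TupleRegistry(genome.sequences)
    placer = _Placer(genome, repeats, reserved, registry, rng)

    # shared pools: substrain-fixed homozygous variants + colony-wide
    # ancestral pool (a fraction of which is in the known database)
    substrain_pools = {
        name: _pool_variants(placer, rng, config.shared_per_substrain, "hom_alt")
        for name in config.substrains
    }
    ancestral = _pool_variants(placer, rng, config.n_ancestral)
    n_known = int(round(config.known_db_fraction * len(ancestral)))
    known_flags = [i < n_known for i in range(len(ancestral))]
    perm = rng.permutation(len(ancestral))
    known_flags = [known_flags[int(i)] for i in perm]

    known_records = [
        _make_record("known_db", c, p, r, a, gt, rng)
        for (c, p, r, a, gt), flag in zip(ancestral, known_flags)
        if flag
    ]

    variants: dict[str, list[VariantRecord]] = {}
    for sample in samples:
        recs: list[VariantRecord] = []
        pool = substrain_pools[substrain[sample]]
        for c, p, r, a, gt in pool:
            recs.append(_make_record(sample, c, p, r, a, gt, rng))
            truth.background.append(
                _bg_row(sample, c, p, r, a, gt, "shared_substrain", False)
            )
        for (c, p, r, a, gt), flag in zip(ancestral, known_flags):
            recs.append(_make_record(sample, c, p, r, a, gt, rng))
            truth.background.append(
                _bg_row(sample, c, p, r, a, gt, "ancestral", flag)
            )
        counts = {
            "private_SNV": rng.poisson(config.snv_mean),
            "private_indel": rng.poisson(config.indel_mean),
            "de_novo_SNV": rng.poisson(config.de_novo_snv_rate),
            "de_novo_indel": rng.poisson(config.de_novo_indel_rate),
        }
        for label, n in counts.items():
            vtype = "SNV" if label.endswith("SNV") else "indel"
            category = "de_novo" if label.startswith("de_novo") else "private"
            for _ in range(int(n)):
                c, p, r, a = placer.draw(vtype)
                gt = "het" if rng.random() < config.het_fraction else "hom_alt"
                fail = None
                if config.fail_fraction > 0 and rng.random() < config.fail_fraction:
                    fail = _FAIL_MODES[int(rng.integers(0, len(_FAIL_MODES)))]
                    if fail == "het_ratio" and gt != "het":
                        gt = "het"
                recs.append(_make_record(sample, c, p, r, a, gt, rng, fail))
                truth.background.append(
                    _bg_row(
                        sample, c, p, r, a, gt,
                        category if fail is None else f"qc_fail:{fail}",
                        False,
                    )
                )
        for _ in range(config.repeat_variants_per_sample):
            vtype = "SNV" if rng.random() < 0.75 else "indel"
            c, p, r, a = placer.draw_in_repeat(vtype)
            gt = "het" if rng.random() < config.het_fraction else "hom_alt"
            recs.append(_make_record(sample, c, p, r, a, gt, rng))
            truth.background.append(_bg_row(sample, c, p, r, a, gt, "repeat", False))
        variants[sample] = recs

    # callable intervals
    callable_sets: dict[str, list[Interval]] = {}
    for sample in samples:
        if config.callable_fraction >= 1.0:
            callable_sets[sample] = [
                Interval(c, 0, genome.length(c)) for c in genome.sequences
            ]
        else:
            callable_sets[sample] = _gapped_callable(
                genome, config.callable_fraction, rng
            )

    svs = {s: [] for s in samples}
    _apply_cas9(
        config, rng, genome, designs, sites_by_guide, placer, variants, svs, truth
    )
    _background_svs(config, rng, genome, samples, svs)

    return Cohort(
        config=config,
        genome=genome,
        repeats=repeats,
        annotation=annotation,
        designs=designs,
        sites_by_guide=sites_by_guide,
        variants=variants,
        svs=svs,
        known=known_records,
        callable_sets=callable_sets,
        groups=groups,
        substrain=substrain,
        truth=truth,
    )


def _bg_row(sample, contig, pos, ref, alt, genotype, category, in_known) -> dict:
    return {
        "sample_id": sample,
        "contig": contig,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "vtype": "SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
        "genotype": genotype,
        "category": category,
        "in_known_db": in_known,
    }


def _gapped_callable(
    genome: Genome, fraction: float, rng: np.random.Generator
) -> list[Interval]:
    out = []
    for contig in genome.sequences:
        L = genome.length(contig)
        gap_total = int((1 - fraction) * L)
        n_gaps = max(1, gap_total // 2_000)
        gap_starts = np.sort(rng.choice(L - 3_000, size=n_gaps, replace=False))
        cursor = 0
        per_gap = max(1, gap_total // n_gaps)
        for gs in gap_starts:
            gs = int(gs)
            if gs <= cursor:
                continue
            out.append(Interval(contig, cursor, gs))
            cursor = gs + per_gap
        if cursor < L:
            out.append(Interval(contig, cursor, L))
    return out


# ---------------------------------------------------------------------------
# Cas9 edits
# ---------------------------------------------------------------------------


def _apply_cas9(
    config: CohortConfig,
    rng: np.random.Generator,
    genome: Genome,
    designs: dict[str, FounderDesign],
    sites_by_guide: dict[str, list[OfftargetSite]],
    placer: _Placer,
    variants: dict[str, list[VariantRecord]],
    svs: dict[str, list[SVRecord]],
    truth: CohortTruth,
) -> None:
    """Inject the on-target deletion (SV DEL seen by a caller subset) and
    probabilistic off-target indels at predicted sites."""
    founder_ids = list(designs)
    single_caller = set(
        founder_ids[i] for i in range(min(config.n_single_caller_founders, len(founder_ids)))
    )
    exp_sum = 0.0
    var_sum = 0.0
    for fid, design in designs.items():
        dele = design.expected_deletion
        if dele.end - dele.start >= genome.length(dele.contig):
            raise ValueError("on-target deletion span exceeds contig")
        panel = list(config.sv_caller_panel)
        if fid in single_caller:
            callers = frozenset({panel[int(rng.integers(0, len(panel)))]})
        else:
            while True:
                picked = [c for c in panel if rng.random() < config.sv_caller_detect_p]
                if len(picked) >= 2:
                    callers = frozenset(picked)
                    break
        svs[fid].append(
            SVRecord(
                sample_id=fid,
                contig=dele.contig,
                start=dele.start + 1,
                end=dele.end,
                svtype="DEL",
                callers=callers,
                support_reads=int(rng.poisson(12) + 3),
                sv_length=dele.end - dele.start,
                genotype="het",
            )
        )
        truth.ontarget[fid] = {
            "contig": dele.contig,
            "start": dele.start,
            "end": dele.end,
            "n_callers": len(callers),
            "callers": ",".join(sorted(callers)),
        }
        for g in design.guides:
            on_target_ivs = [
                s.site_interval for s in sites_by_guide[g.guide_id] if s.is_on_target
            ]
            for site in sites_by_guide[g.guide_id]:
                if site.is_on_target:
                    continue
                # shadow alignments of the on-target locus (bulged/shifted
                # re-alignments at adjacent PAMs) are the same physical cut,
                # already modelled by the on-target deletion
                if any(site.site_interval.overlaps(iv) for iv in on_target_ivs):
                    continue
                p = config.edit_probability(site.mismatches)
                exp_sum += p
                var_sum += p * (1 - p)
                if rng.random() >= p:
                    continue
                edit = _inject_indel(config, rng, genome, placer, fid, g, site)
                if edit is None:
                    continue
                rec, row = edit
                variants[fid].append(rec)
                truth.offtarget_edits.append(row)
    truth.injection_expected = exp_sum
    truth.injection_variance = var_sum


def _inject_indel(
    config: CohortConfig,
    rng: np.random.Generator,
    genome: Genome,
    placer: _Placer,
    fid: str,
    guide: Guide,
    site: OfftargetSite,
):
    seq = genome.sequences[site.contig]
    c = cut_site(site, guide)
    if c < 2 or c > len(seq) - 12:
        return None
    claimed = None
    if rng.random() < 0.7:  # deletion at the cut
        for k in list(rng.permutation(np.arange(1, 6))) + [6, 7, 8]:
            k = int(k)
            pos, ref, alt = c, seq[c - 1 : c + k], seq[c - 1]
            if placer.registry.claim(site.contig, pos, ref, alt):
                claimed = (pos, ref, alt)
                break
    if claimed is None:  # insertion fallback (or 30% of edits)
        for _ in range(20):
            ins = _random_seq(rng, int(rng.integers(1, 5)))
            pos, ref, alt = c, seq[c - 1], seq[c - 1] + ins
            if placer.registry.claim(site.contig, pos, ref, alt):
                claimed = (pos, ref, alt)
                break
    if claimed is None:
        logger.warning("could not inject unique indel at %s:%d", site.contig, c)
        return None
    pos, ref, alt = claimed
    fail = None
    if config.fail_fraction > 0 and rng.random() < config.fail_fraction:
        fail = _FAIL_MODES[int(rng.integers(0, len(_FAIL_MODES)))]
    rec = _make_record(fid, site.contig, pos, ref, alt, "het", rng, fail)
    in_repeat = placer.in_repeat(site.contig, pos - 1, pos - 1 + len(ref))
    row = {
        "sample_id": fid,
        "guide_id": guide.guide_id,
        "contig": site.contig,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "site_start": site.site_interval.start,
        "site_end": site.site_interval.end,
        "site_strand": site.strand,
        "mismatches": site.mismatches,
        "bulge_type": site.bulge_type,
        "pam_class": site.pam_class,
        "passes_quality": fail is None,
        "in_repeat": in_repeat,
        "expected_recovered": fail is None and not in_repeat,
    }
    return rec, row


def _background_svs(
    config: CohortConfig,
    rng: np.random.Generator,
    genome: Genome,
    samples: list[str],
    svs: dict[str, list[SVRecord]],
) -> None:
    """Random background SVs per sample, including deliberate consensus
    failures (single caller, out-of-bounds length, missing genotype)."""
    panel = list(config.sv_caller_panel)
    contigs = list(genome.sequences)
    for sample in samples:
        n = int(rng.poisson(config.background_svs_mean))
        for _ in range(n):
            contig = contigs[int(rng.integers(0, len(contigs)))]
            L = genome.length(contig)
            mode = rng.random()
            if mode < 0.5:  # passing consensus
                length = int(rng.integers(250, 4_800))
                n_callers = int(rng.integers(2, len(panel) + 1))
                su = int(rng.integers(3, 25))
                gt = "het"
            elif mode < 0.7:  # single caller
                length = int(rng.integers(250, 4_800))
                n_callers, su, gt = 1, int(rng.integers(3, 25)), "het"
            elif mode < 0.85:  # bad length
                length = int(rng.choice([int(rng.integers(50, 201)), int(rng.integers(5_000, 9_000))]))
                n_callers, su, gt = 2, int(rng.integers(3, 25)), "het"
            else:  # uncalled genotype
                length = int(rng.integers(250, 4_800))
                n_callers, su, gt = 2, int(rng.integers(3, 25)), "missing"
            start = int(rng.integers(1_000, L - length - 1_000))
            callers = frozenset(
                panel[int(i)] for i in rng.choice(len(panel), size=n_callers, replace=False)
            )
            svs[sample].append(
                SVRecord(
                    sample_id=sample,
                    contig=contig,
                    start=start + 1,
                    end=start + length,
                    svtype=str(rng.choice(["DEL", "DUP", "INV"])),
                    callers=callers,
                    support_reads=su,
                    sv_length=length,
                    genotype=gt,
                )
            )


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def emit_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the whole cohort to disk: FASTA, per-sample VCFs, BEDs,
    guide table, truth ledger and a manifest recording config and seed."""
    out = Path(out_dir)
    for sub in ("vcf", "sv", "callable", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    lengths = {c: cohort.genome.length(c) for c in cohort.genome.sequences}
    write_genome(cohort.genome, out / "genome.fa")
    write_intervals(cohort.repeats, out / "repeats.bed")
    write_intervals(cohort.annotation.exon_intervals, out / "exons.bed")
    write_intervals(cohort.annotation.gene_body_intervals, out / "genes.bed")
    all_guides, founder_col = [], []
    for fid, design in cohort.designs.items():
        for g in design.guides:
            all_guides.append(g)
            founder_col.append(fid)
    write_guides(all_guides, out / "guides.tsv", extra={"founder_id": founder_col})
    for sample in cohort.groups:
        write_variants(
            cohort.variants[sample], out / "vcf" / f"{sample}.vcf", sample, lengths
        )
        write_svs(cohort.svs[sample], out / "sv" / f"{sample}.vcf", sample, lengths)
        write_intervals(
            cohort.callable_sets[sample], out / "callable" / f"{sample}.bed"
        )
    write_variants(cohort.known, out / "known.vcf", "known_db", lengths)
    cohort.truth.background_frame().to_csv(
        out / "truth" / "background.tsv", sep="\t", index=False
    )
    cohort.truth.edits_frame().to_csv(
        out / "truth" / "offtarget_edits.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [dict(founder=k, **v) for k, v in cohort.truth.ontarget.items()]
    ).to_csv(out / "truth" / "ontarget.tsv", sep="\t", index=False)
    pd.DataFrame(cohort.truth.planted_sites).to_csv(
        out / "truth" / "planted_sites.tsv", sep="\t", index=False
    )
    manifest = {
        "config": asdict(cohort.config),
        "samples": {s: cohort.groups[s] for s in cohort.groups},
        "substrain": cohort.substrain,
        "injection_expected": cohort.truth.injection_expected,
        "injection_variance": cohort.truth.injection_variance,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
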