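"""Shared domain types and readers/writers for the standard formats.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open everywhere (``Interval``).  VCF
positions are 1-based and converted at the I/O boundary: a variant with
1-based position ``pos`` and reference allele ``ref`` occupies the interval
``[pos - 1, pos - 1 + len(ref))`` in 0-based space (the left anchor base of
an indel is included).  BED files are already 0-based half-open and pass
through unchanged.

Variant identity for every set operation in the pipeline is the 4-tuple
``(contig, pos, ref, alt)`` after left-normalization of indels against the
genome (see :func:`left_normalize`), so the same biological event called
with different right-paddings compares equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "PAM_NGG_ONLY",
    "PAM_NGG_NAG",
    "Genome",
    "Interval",
    "Guide",
    "VariantRecord",
    "SVRecord",
    "Annotation",
    "revcomp",
    "left_normalize",
    "variant_key",
    "read_genome",
    "write_genome",
    "read_intervals",
    "write_intervals",
    "read_guides",
    "write_guides",
    "read_variants",
    "write_variants",
    "read_svs",
    "write_svs",
]

PAM_NGG_ONLY = "NGG-only"
PAM_NGG_NAG = "NGG+NAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A reference genome held in memory as uppercase contig strings.

    Parameters
    ----------
    sequences
        Mapping from contig name to uppercase DNA (A/C/G/T/N only).
    canonical_contigs
        Ordered subset of contig names considered canonical (defaults to
        all contigs, in file order).
    """

    sequences: dict[str, str]
    canonical_contigs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.canonical_contigs:
            self.canonical_contigs = list(self.sequences)
        for name, seq in self.sequences.items():
            bad = set(seq) - _DNA_CHARS
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-DNA characters: {sorted(bad)}"
                )
        unknown = set(self.canonical_contigs) - set(self.sequences)
        if unknown:
            raise FormatError(f"canonical contigs absent from genome: {sorted(unknown)}")

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def padded(self, pad: int) -> "Interval":
        return Interval(self.contig, max(0, self.start - pad), self.end + pad, self.label)


@dataclass(frozen=True)
class Guide:
    """A single-guide RNA query: 20-nt protospacer plus a PAM rule.

    ``expected_cut_offset`` is the blunt-cut distance in bases 5' of the
    PAM (between protospacer positions 17 and 18 for the default 3).
    """

    guide_id: str
    protospacer: str
    pam_rule: str = PAM_NGG_NAG
    target_gene: str | None = None
    expected_cut_offset: int = 3

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise FormatError(
                f"guide {self.guide_id}: protospacer must be 20 nt, "
                f"got {len(self.protospacer)}"
            )
        bad = set(self.protospacer) - set("ACGT")
        if bad:
            raise FormatError(
                f"guide {self.guide_id}: protospacer contains {sorted(bad)}"
            )
        if self.pam_rule not in (PAM_NGG_ONLY, PAM_NGG_NAG):
            raise FormatError(f"unknown pam_rule {self.pam_rule!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One small-variant call (one ALT allele), sample-attributed.

    ``pos`` is 1-based as in VCF; :meth:`interval` exposes the 0-based
    half-open span of the reference allele.  ``af`` is the alternate
    allele fraction, derived from AD when available.
    """

    sample_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    vtype: str  # "SNV" | "indel"
    genotype: str  # "het" | "hom_alt" | "missing"
    qual: float
    depth: int
    gq: float
    af: float
    ad_ref: int = -1  # -1 = AD absent
    ad_alt: int = -1

    def __post_init__(self) -> None:
        expected = "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        if self.vtype != expected:
            raise FormatError(
                f"vtype {self.vtype!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.contig}:{self.pos}"
            )
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")

    def interval(self) -> Interval:
        return Interval(self.contig, self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def het_ratio(self) -> float:
        """ad_alt / (ad_ref + ad_alt); falls back to ``af`` when AD absent."""
        if self.ad_ref >= 0 and self.ad_alt >= 0 and (self.ad_ref + self.ad_alt) > 0:
            return self.ad_alt / (self.ad_ref + self.ad_alt)
        return self.af


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call with caller provenance and read support.

    ``start``/``end`` are the 1-based inclusive span as read from VCF
    (POS and INFO/END); :meth:`interval` is the 0-based half-open span.
    """

    sample_id: str
    contig: str
    start: int
    end: int
    svtype: str  # DEL | DUP | INV | INS | BND
    callers: frozenset[str]
    support_reads: int
    sv_length: int
    genotype: str  # het | hom_alt | hom_ref | missing

    def __post_init__(self) -> None:
        if self.sv_length < 0:
            raise FormatError("sv_length must be >= 0")
        if self.svtype != "BND" and self.end < self.start:
            raise FormatError(
                f"SV end < start at {self.contig}:{self.start}-{self.end}"
            )

    def interval(self) -> Interval:
        return Interval(self.contig, self.start - 1, max(self.end, self.start))


class Annotation:
    """Genic context lookup from exon and gene-body interval sets.

    A query interval is *exonic* if it overlaps any exon, else *intronic*
    if it overlaps a gene body, else *intergenic* (upstream/downstream
    variants fold into the intergenic class).
    """

    def __init__(
        self,
        exon_intervals: Sequence[Interval],
        gene_body_intervals: Sequence[Interval],
    ) -> None:
        self.exon_intervals = list(exon_intervals)
        self.gene_body_intervals = list(gene_body_intervals)
        for exon in self.exon_intervals:
            if not any(g.contains(exon) for g in self.gene_body_intervals):
                raise FormatError(
                    f"exon {exon.contig}:{exon.start}-{exon.end} lies in no gene body"
                )
        self._exon_trees = _build_trees(self.exon_intervals)
        self._gene_trees = _build_trees(self.gene_body_intervals)

    def classify(self, iv: Interval) -> str:
        etree = self._exon_trees.get(iv.contig)
        if etree is not None and etree.overlap(iv.start, iv.end):
            return "exonic"
        gtree = self._gene_trees.get(iv.contig)
        if gtree is not None and gtree.overlap(iv.start, iv.end):
            return "intronic"
        return "intergenic"


def _build_trees(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


# ---------------------------------------------------------------------------
# variant identity / normalization
# ---------------------------------------------------------------------------


def left_normalize(
    contig_seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against its contig sequence.

    ``pos`` is 1-based.  Standard normalization: trim shared suffix bases
    (extending left from the reference when an allele would empty), then
    trim shared prefix bases.  SNVs pass through unchanged.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    changed = True
    while changed:
        changed = False
        # trim identical last base; re-extend from the genome if either empties
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:  # cannot extend left; restore the trimmed base
                    base = contig_seq[pos - 1]
                    ref, alt = base + ref, base + alt
                    break
                base = contig_seq[pos - 2]
                pos -= 1
                ref, alt = base + ref, base + alt
            changed = True
        elif len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
    return pos, ref, alt


def variant_key(
    v: VariantRecord, genome: Genome | None = None
) -> tuple[str, int, str, str]:
    """Identity tuple (contig, pos, ref, alt), left-normalized when a genome
    is supplied."""
    if genome is None or v.contig not in genome:
        return (v.contig, v.pos, v.ref, v.alt)
    pos, ref, alt = left_normalize(genome.sequences[v.contig], v.pos, v.ref, v.alt)
    return (v.contig, pos, ref, alt)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome(path: str | Path, canonical_contigs: list[str] | None = None) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences upper-cased,
    record order preserved)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header: {first[:40]!r}")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return Genome(sequences, canonical_contigs or [])


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a BED3+ file; native 0-based half-open coordinates are kept."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            contig, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            label = parts[3] if len(parts) > 3 else None
            out.append(Interval(contig, start, end, label))
    return out


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# guide tables
# ---------------------------------------------------------------------------

_GUIDE_COLUMNS = ["guide_id", "protospacer", "pam_rule", "target_gene"]


def read_guides(path: str | Path) -> list[Guide]:
    """Read a tab-separated guide table (columns guide_id, protospacer,
    pam_rule, target_gene; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GUIDE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: guide table missing columns {missing}")
    guides = []
    for row in df.itertuples(index=False):
        target = getattr(row, "target_gene", None)
        if isinstance(target, float) or target in (None, "", "nan"):
            target = None
        guides.append(
            Guide(
                guide_id=row.guide_id,
                protospacer=row.protospacer.upper(),
                pam_rule=row.pam_rule,
                target_gene=target,
            )
        )
    return guides


def write_guides(
    guides: Sequence[Guide], path: str | Path, extra: Mapping[str, Sequence] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "guide_id": [g.guide_id for g in guides],
            "protospacer": [g.protospacer for g in guides],
            "pam_rule": [g.pam_rule for g in guides],
            "target_gene": [g.target_gene or "" for g in guides],
        }
    )
    if extra:
        for col, values in extra.items():
            df[col] = list(values)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# small-variant VCF
# ---------------------------------------------------------------------------


def _map_genotype(alleles: list[int], alt_index: int) -> str | None:
    """Map a genotype allele list to het/hom_alt/missing for ALT ``alt_index``
    (1-based allele number).  Returns None when the allele is not carried."""
    if not alleles or all(a < 0 for a in alleles):
        return "missing"
    n = sum(1 for a in alleles if a == alt_index)
    if n == 0:
        return None
    if n == len([a for a in alleles if a >= 0]) and n >= 2:
        return "hom_alt"
    return "het"


def read_variants(path: str | Path, sample_id: str) -> list[VariantRecord]:
    """Read a single-sample small-variant VCF into per-ALT records.

    Multi-allelic rows are split into one record per ALT allele before any
    filtering.  Genotypes are mapped to het/hom_alt/missing (phase is
    ignored); an ALT the sample does not carry is skipped.  ``af`` is
    AD-derived when AD is present, else the AF FORMAT/INFO field, else NaN.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            try:
                gts = v.genotypes[0][:-1] if v.genotypes else []
            except Exception:
                gts = []
            ad = None
            fmt_ad = v.format("AD")
            if fmt_ad is not None:
                ad = [int(x) for x in fmt_ad[0]]
            dp = _fmt_scalar(v, "DP", int, default=-1)
            gq = _fmt_scalar(v, "GQ", float, default=float("nan"))
            for k, alt in enumerate(v.ALT):
                if alt in (".", "*") or alt.startswith("<"):
                    continue
                geno = _map_genotype(gts, k + 1)
                if geno is None:
                    continue
                ad_ref = ad[0] if ad else -1
                ad_alt = ad[k + 1] if ad and len(ad) > k + 1 else -1
                if ad_ref >= 0 and ad_alt >= 0 and ad_ref + ad_alt > 0:
                    af = ad_alt / (ad_ref + ad_alt)
                else:
                    af = _fmt_scalar(v, "AF", float, default=float("nan"))
                ref, altseq = v.REF.upper(), alt.upper()
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        contig=v.CHROM,
                        pos=v.POS,
                        ref=ref,
                        alt=altseq,
                        vtype="SNV" if len(ref) == 1 and len(altseq) == 1 else "indel",
                        genotype=geno,
                        qual=v.QUAL if v.QUAL is not None else float("nan"),
                        depth=dp,
                        gq=gq,
                        af=af,
                        ad_ref=ad_ref,
                        ad_alt=ad_alt,
                    )
                )
    finally:
        vcf.close()
    return records


def _fmt_scalar(v, key: str, cast, default):
    arr = v.format(key)
    if arr is None:
        val = v.INFO.get(key)
        if val is None:
            return default
        try:
            return cast(val)
        except (TypeError, ValueError):
            return default
    try:
        x = arr[0]
        x = x[0] if hasattr(x, "__len__") else x
        if x is None or (isinstance(x, float) and x != x):
            return default
        return cast(x)
    except (TypeError, ValueError, IndexError):
        return default


_VCF_HEADER = """\
##fileformat=VCFv4.2
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_GT_STRING = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0", "missing": "./."}


def write_variants(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_id: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write per-ALT records back out as a sorted single-sample VCF."""
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    order = {name: i for i, name in enumerate(contig_lengths)} if contig_lengths else {}
    recs = sorted(records, key=lambda r: (order.get(r.contig, 0), r.contig, r.pos))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample_id))
        for r in recs:
            qual = "." if r.qual != r.qual else f"{r.qual:g}"
            gq = "." if r.gq != r.gq else f"{int(r.gq)}"
            dp = "." if r.depth < 0 else str(r.depth)
            ad = "." if r.ad_ref < 0 else f"{r.ad_ref},{r.ad_alt}"
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t.\t"
                f"GT:DP:GQ:AD\t{_GT_STRING[r.genotype]}:{dp}:{gq}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------


def read_svs(
    path: str | Path,
    sample_id: str,
    callers_key: str = "CALLERS",
    support_key: str = "SU",
) -> list[SVRecord]:
    """Read a structural-variant VCF.  Caller provenance comes from an INFO
    key (default ``CALLERS``, comma-separated) and read support from INFO
    ``SU``; both key names are configurable."""
    from cyvcf2 import VCF

    records: list[SVRecord] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            svtype = v.INFO.get("SVTYPE") or "BND"
            end = v.INFO.get("END")
            svlen = v.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if end is None:
                end = v.POS + (abs(int(svlen)) if svlen is not None else 0)
            if svlen is None:
                svlen = int(end) - v.POS + 1 if svtype != "INS" else 0
            callers_raw = v.INFO.get(callers_key)
            callers = (
                frozenset(str(callers_raw).split(",")) if callers_raw else frozenset()
            )
            su = v.INFO.get(support_key)
            if isinstance(su, (tuple, list)):
                su = su[0]
            gts = v.genotypes[0][:-1] if v.genotypes else []
            if not gts or all(a < 0 for a in gts):
                geno = "missing"
            elif all(a == 0 for a in gts):
                geno = "hom_ref"
            elif all(a == 1 for a in gts):
                geno = "hom_alt"
            else:
                geno = "het"
            records.append(
                SVRecord(
                    sample_id=sample_id,
                    contig=v.CHROM,
                    start=v.POS,
                    end=int(end),
                    svtype=str(svtype),
                    callers=callers,
                    support_reads=int(su) if su is not None else 0,
                    sv_length=abs(int(svlen)),
                    genotype=geno,
                )
            )
    finally:
        vcf.close()
    return records


_SV_HEADER = """\
##fileformat=VCFv4.2
{contigs}##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=SU,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Calling programs">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=INS,Description="Insertion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_svs(
    records: Sequence[SVRecord],
    path: str | Path,
    sample_id: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    order = {name: i for i, name in enumerate(contig_lengths)} if contig_lengths else {}
    recs = sorted(records, key=lambda r: (order.get(r.contig, 0), r.contig, r.start))
    with open(path, "w") as fh:
        fh.write(_SV_HEADER.format(contigs=contigs, sample=sample_id))
        for r in recs:
            length = -r.sv_length if r.svtype == "DEL" else r.sv_length
            info = (
                f"SVTYPE={r.svtype};END={r.end};SVLEN={length};"
                f"SU={r.support_reads};CALLERS={','.join(sorted(r.callers))}"
            )
            fh.write(
                f"{r.contig}\t{r.start}\t.\tN\t<{r.svtype}>\t.\t.\t{info}\t"
                f"GT\t{_GT_STRING[r.genotype]}\n"
            )
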