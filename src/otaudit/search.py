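"""Bulge-aware enumeration of candidate Cas9 off-target sites.

A site is any genomic locus, on either strand, where a 3-nt PAM
(N[G/A]G, depending on the configured rule) sits immediately 3' of a
protospacer-homologous region of 19, 20 or 21 nt:

* 20 nt — gapless alignment to the 20-nt protospacer;
* 21 nt — one unpaired genomic base (DNA bulge);
* 19 nt — one unpaired guide base (RNA bulge).

At most one bulge of either kind is allowed per site, and only
substitutions count toward the mismatch ceiling.  A locus is keyed by
(strand, PAM position); when several alignments of a locus satisfy the
configuration, the reported one is minimal under the lexicographic cost
(bulge_size, mismatches, bulge-preference none>DNA>RNA, leftmost gap).

:func:`enumerate_sites` scans PAM anchors with vectorized mismatch
counting; :func:`oracle_enumerate` is a deliberately naive re-derivation
(every window, every gap placement, no pruning) kept as the validation
oracle for the fast path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .formats import (
    Genome,
    Guide,
    Interval,
    PAM_NGG_NAG,
    PAM_NGG_ONLY,
    revcomp,
)

__all__ = [
    "SearchConfig",
    "OfftargetSite",
    "enumerate_sites",
    "oracle_enumerate",
    "cut_site",
    "mismatch_position_profile",
    "write_sites",
    "read_sites",
    "sites_to_bed",
]

# contig names treated as canonical nuclear chromosomes by default
_CANONICAL_RE = re.compile(r"^(chr)?(\d+|X|Y)$")
_MITO_NAMES = frozenset({"chrM", "chrMT", "M", "MT"})

_BULGE_PREF = {"none": 0, "DNA": 1, "RNA": 2}


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters.

    ``max_mismatches`` counts substitutions only (0-6).  When
    ``exclude_contigs`` is None, mitochondrial and non-canonical contigs
    (names not matching ``chr1..chrN/chrX/chrY``) are excluded; pass an
    explicit list (possibly empty) to override.
    """

    max_mismatches: int = 5
    allow_bulge: bool = True
    pam_rule: str = PAM_NGG_NAG
    exclude_contigs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches <= 6:
            raise ValueError("max_mismatches must be in [0, 6]")
        if self.pam_rule not in (PAM_NGG_ONLY, PAM_NGG_NAG):
            raise ValueError(f"unknown pam_rule {self.pam_rule!r}")

    def contig_excluded(self, contig: str) -> bool:
        if self.exclude_contigs is not None:
            return contig in self.exclude_contigs
        return contig in _MITO_NAMES or not _CANONICAL_RE.match(contig)


@dataclass(frozen=True)
class OfftargetSite:
    """One candidate cut locus with its minimal-cost alignment.

    ``site_interval`` covers the protospacer-homologous bases plus the
    PAM on forward-strand coordinates.  ``aligned_target`` is the genomic
    target region in protospacer orientation (reverse-complemented for
    minus-strand sites), with ``-`` marking the unpaired guide base of an
    RNA bulge; a DNA-bulged target is 21 nt with ``gap_pos`` giving the
    guide-gap placement.  ``mismatch_positions`` are 1-based protospacer
    positions, position 20 PAM-proximal.
    """

    guide_id: str
    contig: str
    strand: str
    site_interval: Interval
    aligned_target: str
    mismatches: int
    bulge_type: str  # none | DNA | RNA
    bulge_size: int
    pam_seq: str
    pam_class: str  # NGG | NAG
    is_on_target: bool = False
    gap_pos: int = -1
    mismatch_positions: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if (self.bulge_size == 0) != (self.bulge_type == "none"):
            raise ValueError("bulge_size=0 iff bulge_type=none")

    def sort_key(self):
        return (self.contig, self.site_interval.start, self.strand, self.guide_id)


def _pam_class(pam: str) -> str | None:
    if pam[1:3] == "GG":
        return "NGG"
    if pam[1:3] == "AG":
        return "NAG"
    return None


def _pam_allowed(pam: str, rule: str) -> bool:
    cls = _pam_class(pam)
    if cls is None or "N" in pam:
        return False
    return cls == "NGG" or rule == PAM_NGG_NAG


def _alignment_detail(proto: str, window: str, bulge: str, gap: int):
    """Mismatch positions (1-based guide coords) and aligned-target string
    for one explicit alignment."""
    if bulge == "none":
        mmpos = tuple(i + 1 for i in range(20) if window[i] != proto[i])
        return mmpos, window
    if bulge == "DNA":  # window is 21 nt, genomic base ``gap`` unpaired
        mmpos = []
        for i in range(20):
            w = window[i] if i < gap else window[i + 1]
            if w != proto[i]:
                mmpos.append(i + 1)
        return tuple(mmpos), window
    # RNA bulge: window is 19 nt, guide base ``gap`` unpaired
    mmpos = []
    for i in range(20):
        if i == gap:
            continue
        w = window[i] if i < gap else window[i - 1]
        if w != proto[i]:
            mmpos.append(i + 1)
    return tuple(mmpos), window[:gap] + "-" + window[gap:]


def _make_site(
    guide: Guide,
    contig: str,
    strand: str,
    contig_len: int,
    q: int,
    stranded_seq: str,
    bulge: str,
    gap: int,
    mismatches: int,
) -> OfftargetSite:
    w = {"none": 20, "DNA": 21, "RNA": 19}[bulge]
    window = stranded_seq[q - w : q]
    pam = stranded_seq[q : q + 3]
    mmpos, aligned = _alignment_detail(guide.protospacer, window, bulge, gap)
    if strand == "+":
        iv = Interval(contig, q - w, q + 3)
    else:
        iv = Interval(contig, contig_len - (q + 3), contig_len - (q - w))
    cls = _pam_class(pam)
    return OfftargetSite(
        guide_id=guide.guide_id,
        contig=contig,
        strand=strand,
        site_interval=iv,
        aligned_target=aligned,
        mismatches=mismatches,
        bulge_type=bulge,
        bulge_size=0 if bulge == "none" else 1,
        pam_seq=pam,
        pam_class=cls,
        is_on_target=(mismatches == 0 and bulge == "none" and cls == "NGG"),
        gap_pos=gap if bulge != "none" else -1,
        mismatch_positions=mmpos,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_enumerate(
    guide: Guide, genome: Genome, config: SearchConfig
) -> list[OfftargetSite]:
    """Exhaustive reference enumeration for small genomes (<= 100 kb).

    Tries every window of length 19/20/21 on both strands and every gap
    placement, with no indexing or pruning; used to validate
    :func:`enumerate_sites`.
    """
    if genome.total_length > 100_000:
        raise ValueError(
            f"oracle_enumerate refuses genomes > 100 kb "
            f"(got {genome.total_length} bp); use enumerate_sites"
        )
    proto = guide.protospacer
    mm_max = config.max_mismatches
    sites: list[OfftargetSite] = []
    for contig, fwd in genome.sequences.items():
        if config.contig_excluded(contig):
            continue
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            for q in range(19, L - 2):
                pam = seq[q : q + 3]
                if not _pam_allowed(pam, config.pam_rule):
                    continue
                best = None  # (bulge_size, mm, pref, gap, bulge_name)
                shapes = [("none", 20, (0,))]
                if config.allow_bulge:
                    shapes.append(("DNA", 21, range(21)))
                    shapes.append(("RNA", 19, range(20)))
                for bulge, w, gaps in shapes:
                    if q - w < 0:
                        continue
                    window = seq[q - w : q]
                    if "N" in window:
                        continue
                    for gap in gaps:
                        mmpos, _ = _alignment_detail(proto, window, bulge, gap)
                        mm = len(mmpos)
                        if mm > mm_max:
                            continue
                        key = (
                            0 if bulge == "none" else 1,
                            mm,
                            _BULGE_PREF[bulge],
                            gap,
                        )
                        if best is None or key < best:
                            best = key
                            best_shape = (bulge, gap, mm)
                if best is not None:
                    bulge, gap, mm = best_shape
                    sites.append(
                        _make_site(guide, contig, strand, L, q, seq, bulge, gap, mm)
                    )
    sites.sort(key=OfftargetSite.sort_key)
    return sites


# ---------------------------------------------------------------------------
# fast path
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def enumerate_sites(
    guide: Guide, genome: Genome, config: SearchConfig | None = None
) -> list[OfftargetSite]:
    """Enumerate all off-target sites of ``guide`` against ``genome``.

    PAM anchors are located first; mismatch counts for the gapless and
    single-bulge alignments of every anchored window are computed with
    vectorized prefix/suffix sums, and each surviving locus is reported
    once with its minimal-cost alignment (see module docstring).
    Windows containing N are skipped (N never matches).
    """
    if config is None:
        config = SearchConfig()
    proto = guide.protospacer
    g = _encode(proto)
    mm_max = config.max_mismatches
    sites: list[OfftargetSite] = []
    for contig, fwd in genome.sequences.items():
        if config.contig_excluded(contig):
            continue
        L = len(fwd)
        if L < 22:
            # too short for any anchored window; fall back to nothing
            continue
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            a = _encode(seq)
            n_cum = np.concatenate(([0], np.cumsum(a == ord("N"))))

            def window_clean(starts: np.ndarray, w: int) -> np.ndarray:
                return (n_cum[starts + w] - n_cum[starts]) == 0

            # PAM anchors: q = index of PAM base 1; need q >= 19, q + 3 <= L
            p2, p3 = a[1:], np.concatenate((a[2:], [0, 0]))[: len(a) - 1]
            is_gg = (p2 == ord("G")) & (p3 == ord("G"))
            if config.pam_rule == PAM_NGG_NAG:
                pam_ok = is_gg | ((p2 == ord("A")) & (p3 == ord("G")))
            else:
                pam_ok = is_gg
            q_all = np.nonzero(pam_ok)[0]
            q_all = q_all[(q_all >= 19) & (q_all + 3 <= L) & (a[q_all] != ord("N"))]
            if q_all.size == 0:
                continue

            INF = 99
            costs = []  # (bulge_size, mm, pref, gap) arrays per route

            # gapless route (w=20)
            ok20 = (q_all >= 20) & window_clean(np.maximum(q_all - 20, 0), 20)
            mm20 = np.full(q_all.shape, INF, dtype=np.int16)
            if ok20.any():
                qs = q_all[ok20]
                W = a[(qs - 20)[:, None] + np.arange(20)]
                mm20[ok20] = (W != g).sum(axis=1)
            costs.append(("none", mm20, np.zeros(q_all.shape, dtype=np.int16)))

            if config.allow_bulge:
                # DNA bulge (w=21): gap g in 0..20 over the 21-nt window
                mmd = np.full(q_all.shape, INF, dtype=np.int16)
                gapd = np.zeros(q_all.shape, dtype=np.int16)
                okd = (q_all >= 21) & window_clean(np.maximum(q_all - 21, 0), 21)
                if okd.any():
                    qs = q_all[okd]
                    W = a[(qs - 21)[:, None] + np.arange(21)]
                    c1 = (W[:, :20] != g).astype(np.int16)
                    c2 = (W[:, 1:21] != g).astype(np.int16)
                    pre = np.concatenate(
                        (np.zeros((len(qs), 1), np.int16), np.cumsum(c1, axis=1)),
                        axis=1,
                    )  # pre[:, gap]
                    suf = np.concatenate(
                        (
                            np.cumsum(c2[:, ::-1], axis=1)[:, ::-1],
                            np.zeros((len(qs), 1), np.int16),
                        ),
                        axis=1,
                    )  # suf[:, gap] = mismatches of pairs gap..19
                    tot = pre + suf  # (n, 21)
                    mmd[okd] = tot.min(axis=1)
                    gapd[okd] = tot.argmin(axis=1)  # leftmost minimum
                costs.append(("DNA", mmd, gapd))

                # RNA bulge (w=19): skipped guide base j in 0..19
                mmr = np.full(q_all.shape, INF, dtype=np.int16)
                gapr = np.zeros(q_all.shape, dtype=np.int16)
                okr = window_clean(q_all - 19, 19)
                if okr.any():
                    qs = q_all[okr]
                    W = a[(qs - 19)[:, None] + np.arange(19)]
                    c1 = (W != g[:19]).astype(np.int16)
                    c2 = (W != g[1:20]).astype(np.int16)
                    pre = np.concatenate(
                        (np.zeros((len(qs), 1), np.int16), np.cumsum(c1, axis=1)),
                        axis=1,
                    )  # pre[:, j], j = 0..19
                    suf = np.concatenate(
                        (
                            np.cumsum(c2[:, ::-1], axis=1)[:, ::-1],
                            np.zeros((len(qs), 1), np.int16),
                        ),
                        axis=1,
                    )  # suf[:, j] = mismatches of pairs j..18 of c2
                    tot = pre + suf  # both (n, 20), j = 0..19
                    mmr[okr] = tot.min(axis=1)
                    gapr[okr] = tot.argmin(axis=1)
                costs.append(("RNA", mmr, gapr))

            valid_any = np.zeros(q_all.shape, dtype=bool)
            for _, mm, _ in costs:
                valid_any |= mm <= mm_max
            for idx in np.nonzero(valid_any)[0]:
                best = None
                for bulge, mm, gap in costs:
                    m = int(mm[idx])
                    if m > mm_max:
                        continue
                    key = (
                        0 if bulge == "none" else 1,
                        m,
                        _BULGE_PREF[bulge],
                        int(gap[idx]),
                    )
                    if best is None or key < best:
                        best = key
                        choice = (bulge, int(gap[idx]) if bulge != "none" else 0, m)
                bulge, gap, m = choice
                sites.append(
                    _make_site(
                        guide, contig, strand, L, int(q_all[idx]), seq, bulge, gap, m
                    )
                )
    sites.sort(key=OfftargetSite.sort_key)
    return sites


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def cut_site(site: OfftargetSite, guide: Guide) -> int:
    """0-based genomic coordinate of the blunt cut (between protospacer
    positions 17 and 18 for the default offset of 3), strand-aware.

    For a bulged alignment the position is computed on the genomic
    coordinates of the aligned window.
    """
    off = guide.expected_cut_offset
    if site.strand == "+":
        pam_start = site.site_interval.end - 3
        return pam_start - off
    pam_end = site.site_interval.start + 3
    return pam_end + off


def mismatch_position_profile(sites: list[OfftargetSite]) -> dict:
    """Counts of mismatches by protospacer position across ``sites``.

    Keys 1..20 (1 = PAM-distal, 20 = PAM-proximal) plus ``"gap"`` for
    bulged positions (one per bulged site).
    """
    profile: dict = {i: 0 for i in range(1, 21)}
    profile["gap"] = 0
    for s in sites:
        for p in s.mismatch_positions:
            profile[p] += 1
        if s.bulge_type != "none":
            profile["gap"] += 1
    return profile


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "guide_id",
    "contig",
    "start",
    "end",
    "strand",
    "aligned_target",
    "mismatches",
    "bulge_type",
    "pam_seq",
    "pam_class",
]


def write_sites(sites: list[OfftargetSite], path) -> None:
    """Write a site list as the tab-separated site table."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.guide_id,
                        s.contig,
                        s.site_interval.start,
                        s.site_interval.end,
                        s.strand,
                        s.aligned_target,
                        s.mismatches,
                        s.bulge_type,
                        s.pam_seq,
                        s.pam_class,
                    )
                )
                + "\n"
            )


def read_sites(path) -> list[OfftargetSite]:
    """Read a site table written by :func:`write_sites` (external site
    lists, e.g. from in-vitro assays, may use the same schema)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    out = []
    for row in df.itertuples(index=False):
        bulge = getattr(row, "bulge_type", "none")
        out.append(
            OfftargetSite(
                guide_id=str(row.guide_id),
                contig=str(row.contig),
                strand=str(getattr(row, "strand", "+")),
                site_interval=Interval(str(row.contig), int(row.start), int(row.end)),
                aligned_target=str(getattr(row, "aligned_target", "")),
                mismatches=int(getattr(row, "mismatches", 0)),
                bulge_type=bulge,
                bulge_size=0 if bulge == "none" else 1,
                pam_seq=str(getattr(row, "pam_seq", "NGG")),
                pam_class=str(getattr(row, "pam_class", "NGG")),
            )
        )
    return out


def sites_to_bed(sites: list[OfftargetSite], path) -> None:
    """Write sites as BED6 (name = guide_id, score = mismatches)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=OfftargetSite.sort_key):
            fh.write(
                f"{s.contig}\t{s.site_interval.start}\t{s.site_interval.end}\t"
                f"{s.guide_id}\t{s.mismatches}\t{s.strand}\n"
            )
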