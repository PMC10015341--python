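"""Classification of RNA-seq reads at a predicted splice event.

Given a predicted event (donor/acceptor loss or gain) and its evaluation
position p, every read crossing p in a sample is classified as

* ``normal`` — consistent with canonical splicing: carries a canonical
  junction spanning p, or aligns contiguously where no splice is expected;
* ``abnormal_direct`` — supports the most direct consequence of the event:
  intron retention through a lost donor/acceptor, or a junction using the
  novel site for gain events;
* ``abnormal_other`` — shows some other non-canonical pattern at the
  boundary (cryptic-site junction, exon skipping);
* ``uninformative`` — soft-clipped at the decision point or carrying no
  usable signal; excluded from all denominators.

The binary abnormal/normal partition of the original method is recovered by
the two counting modes: ``direct`` counts only abnormal_direct against
normal (other abnormal reads are set aside), ``all`` counts any abnormal
read. Per-fragment counting merges paired mates by query name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from .genemodel import GeneModel
from .variants import SpliceEvent

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "Junction",
    "ReadCall",
    "CLIP_WINDOW",
    "reads_crossing",
    "junctions_of",
    "aligned_blocks",
    "evaluation_position",
    "classify_direct",
    "classify_all",
    "count_reads",
]

# CIGAR op codes (pysam numeric convention)
_MATCH_OPS = frozenset({0, 7, 8})  # M, =, X
_REF_OPS = frozenset({0, 2, 3, 7, 8})  # consume reference: M, D, N, =, X
_SOFT_CLIP = 4

#: Reads soft-clipped within this many bases of the decision point are
#: uninformative: the clip hides what the alignment would have shown.
CLIP_WINDOW = 3


@dataclass(frozen=True)
class AlignedRead:
    qname: str
    ref_start: int  # 0-based
    cigar: tuple[tuple[int, int], ...]  # (op, length) pairs, pysam op codes
    mapq: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the reference span (N gaps included)."""
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)


@dataclass(frozen=True)
class Junction:
    """A split-read junction: the reference gap of one N CIGAR operation."""

    donor_end: int  # 0-based exclusive: last aligned base before the gap is donor_end-1
    acceptor_start: int  # 0-based: first aligned base after the gap

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValueError("acceptor_start must exceed donor_end")

    @property
    def gap(self) -> tuple[int, int]:
        return (self.donor_end, self.acceptor_start)


@dataclass(frozen=True)
class ReadCall:
    qname: str
    call: str  # normal | abnormal_direct | abnormal_other | uninformative


# ---------------------------------------------------------------------------
# Read retrieval
# ---------------------------------------------------------------------------

def reads_crossing(
    bam: str,
    contig: str,
    p: int,
    min_mapq: int = 20,
    sample: str = "",
) -> list[AlignedRead]:
    """Reads whose reference span contains 1-based position ``p``.

    A read splicing over p (N gap containing p) crosses it and is returned.
    Duplicates, secondary and supplementary alignments, and reads below the
    mapping-quality cutoff are excluded. BAM input must be indexed; SAM
    input is scanned sequentially.
    """
    p0 = p - 1
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(bam)) as fh:
        if contig not in fh.references:
            logger.warning("contig %r absent from %s", contig, bam)
            return out
        if fh.is_bam or fh.is_cram:
            it = fh.fetch(contig, p0, p0 + 1)  # raises if index missing
        else:
            it = (r for r in fh.fetch(until_eof=True) if r.reference_name == contig)
        for r in it:
            if r.is_unmapped or r.is_secondary or r.is_supplementary or r.is_duplicate:
                continue
            if r.mapping_quality < min_mapq:
                continue
            if not (r.reference_start <= p0 < r.reference_end):
                continue
            out.append(
                AlignedRead(
                    qname=r.query_name,
                    ref_start=r.reference_start,
                    cigar=tuple(r.cigartuples or ()),
                    mapq=r.mapping_quality,
                    sample=sample,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CIGAR geometry
# ---------------------------------------------------------------------------

def junctions_of(r: AlignedRead) -> list[Junction]:
    """One junction per N operation; deletions do not produce junctions."""
    out: list[Junction] = []
    pos = r.ref_start
    for op, n in r.cigar:
        if op == 3:  # N
            out.append(Junction(donor_end=pos, acceptor_start=pos + n))
        if op in _REF_OPS:
            pos += n
    return out


def aligned_blocks(r: AlignedRead) -> list[tuple[int, int]]:
    """0-based half-open reference intervals covered by aligned bases."""
    out: list[tuple[int, int]] = []
    pos = r.ref_start
    for op, n in r.cigar:
        if op in _MATCH_OPS:
            if out and out[-1][1] == pos:
                out[-1] = (out[-1][0], pos + n)
            else:
                out.append((pos, pos + n))
        if op in _REF_OPS:
            pos += n
    return out


def _covers(blocks: Sequence[tuple[int, int]], pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in blocks)


def _clip_positions(r: AlignedRead) -> list[int]:
    """0-based reference coordinates where soft-clips abut the alignment."""
    out = []
    if r.cigar and r.cigar[0][0] == _SOFT_CLIP:
        out.append(r.ref_start)  # first aligned base
    # ignore hard clips: no sequence was present to align
    if r.cigar and r.cigar[-1][0] == _SOFT_CLIP:
        out.append(r.ref_end - 1)  # last aligned base
    return out


# ---------------------------------------------------------------------------
# Event geometry
# ---------------------------------------------------------------------------

def evaluation_position(e: SpliceEvent) -> int:
    """1-based position p at which reads are retrieved and classified.

    Loss events: the first intronic base adjacent to the lost essential site
    (every crossing read is then either retained or spliced). Gain events:
    the novel site itself.
    """
    if e.strand is None:
        raise ValueError("event must be annotated with strand (annotate_event)")
    if e.event_type == "DL":
        b = _require_boundary(e)
        return b + 1 if e.strand == "+" else b - 1
    if e.event_type == "AL":
        b = _require_boundary(e)
        return b - 1 if e.strand == "+" else b + 1
    return e.site_pos


def _require_boundary(e: SpliceEvent) -> int:
    if e.boundary is None:
        raise ValueError("loss event needs a canonical boundary (annotate_event)")
    return e.boundary


def _decision_pair(e: SpliceEvent) -> tuple[int, int]:
    """Adjacent 0-based bases straddling the splice cut being interrogated.

    For losses: the exon/intron boundary of the lost site. For gains: the
    cut the novel junction would introduce at the novel site.
    """
    if e.is_loss:
        b, p = _require_boundary(e), evaluation_position(e)
        lo = min(b, p) - 1
        return (lo, lo + 1)
    # gains: cut between the novel exonic boundary base and the gap side
    if _gap_side(e) == "right":
        return (e.site_pos - 1, e.site_pos)
    return (e.site_pos - 2, e.site_pos - 1)


def _gap_side(e: SpliceEvent) -> str:
    """Genomic side of the novel junction's gap relative to the novel site.

    A novel donor keeps exonic sequence upstream in transcript orientation,
    so the gap is genomically right of the site on plus strands and left on
    minus strands; a novel acceptor is the mirror image.
    """
    if e.strand is None:
        raise ValueError("event must be annotated with strand")
    right = (e.event_type == "DG") == (e.strand == "+")
    return "right" if right else "left"


def _novel_junction_matches(e: SpliceEvent, j: Junction) -> bool:
    if _gap_side(e) == "right":
        return j.donor_end == e.site_pos  # site is last exonic base (1-based)
    return j.acceptor_start == e.site_pos - 1  # site is first exonic base


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _analyze(r: AlignedRead, e: SpliceEvent, gm: GeneModel) -> dict:
    gene = e.variant.gene
    canon = gm.canonical_junctions(gene)
    p0 = evaluation_position(e) - 1
    pair = _decision_pair(e)
    blocks = aligned_blocks(r)
    juncs = junctions_of(r)

    clip_near = any(
        abs(c - pair[0]) <= CLIP_WINDOW or abs(c - pair[1]) <= CLIP_WINDOW
        for c in _clip_positions(r)
    )
    spans_cut = _covers(blocks, pair[0]) and _covers(blocks, pair[1])
    canonical_span = any(
        j.gap in canon and j.donor_end <= p0 < j.acceptor_start for j in juncs
    )
    novel_match = (not e.is_loss) and any(
        _novel_junction_matches(e, j) for j in juncs
    )
    noncanon_near = any(
        j.gap not in canon
        and j.donor_end - CLIP_WINDOW <= pair[1]
        and j.acceptor_start + CLIP_WINDOW > pair[0]
        for j in juncs
    )
    return {
        "clip_near": clip_near,
        "spans_cut": spans_cut,
        "canonical_span": canonical_span,
        "novel_match": novel_match,
        "noncanon_near": noncanon_near,
    }


def classify_all(r: AlignedRead, e: SpliceEvent, gm: GeneModel) -> ReadCall:
    """Full classification: any non-canonical pattern at the boundary is abnormal."""
    a = _analyze(r, e, gm)
    if a["clip_near"]:
        return ReadCall(r.qname, "uninformative")
    if e.is_loss:
        if a["spans_cut"]:  # retention through the lost essential site
            return ReadCall(r.qname, "abnormal_direct")
        if a["canonical_span"]:
            return ReadCall(r.qname, "normal")
        if a["noncanon_near"]:
            return ReadCall(r.qname, "abnormal_other")
        return ReadCall(r.qname, "uninformative")
    # gain events
    if a["novel_match"]:
        return ReadCall(r.qname, "abnormal_direct")
    if a["spans_cut"] or a["canonical_span"]:
        return ReadCall(r.qname, "normal")
    if a["noncanon_near"]:
        return ReadCall(r.qname, "abnormal_other")
    return ReadCall(r.qname, "uninformative")


def classify_direct(r: AlignedRead, e: SpliceEvent, gm: GeneModel) -> ReadCall:
    """Direct-consequence classification.

    Only reads supporting the event's most direct consequence count as
    abnormal; reads abnormal in some other way carry no evidence for or
    against the direct consequence and are set aside as uninformative.
    """
    full = classify_all(r, e, gm)
    if full.call == "abnormal_other":
        return ReadCall(r.qname, "uninformative")
    return full


def count_reads(
    calls: Iterable[ReadCall], mode: str = "all"
) -> tuple[int, int]:
    """Fragment-level (n_abnormal, n_normal) tallies.

    Mates sharing a query name are one fragment: abnormal if any informative
    mate is abnormal (a normal/abnormal conflict is resolved as abnormal),
    normal if all informative mates are normal, excluded otherwise.
    Uninformative calls never enter either tally. In ``direct`` mode only
    abnormal_direct counts as abnormal; abnormal_other fragments are
    excluded entirely.
    """
    if mode not in ("direct", "all"):
        raise ValueError(f"mode must be 'direct' or 'all', got {mode!r}")
    abnormal_calls = (
        {"abnormal_direct"} if mode == "direct" else {"abnormal_direct", "abnormal_other"}
    )
    drop = {"uninformative"} | ({"abnormal_other"} if mode == "direct" else set())
    frags: dict[str, set[str]] = {}
    for c in calls:
        frags.setdefault(c.qname, set()).add(c.call)
    n_a = n_n = 0
    for cs in frags.values():
        informative = cs - drop
        if not informative:
            continue
        if informative & abnormal_calls:
            n_a += 1
        else:
            n_n += 1
    return n_a, n_n
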