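"""Synthetic fixtures: gene models, spliced reads with truth labels, VCFs,
and signature-sampled mutation sets.

The read simulator emits pre-aligned reads (CIGAR strings constructed
analytically) around one splice event, covering the evidence classes seen in
real tumor RNA-seq:

* ``canonical`` — a read carrying the annotated junction (losses) or a
  contiguous alignment through the novel site (gains);
* ``retention`` — contiguous alignment across the exon-intron boundary;
* ``novel`` — a junction using the novel splice site (gain events);
* ``cryptic`` — a junction using a nearby unannotated site;
* ``skip`` — a junction skipping the event's exon entirely;
* ``clipped`` — a read soft-clipped at the decision point (uninformative).

Every read carries a truth label (the call a perfect classifier should
produce), so classification can be scored exactly. Reads are emitted as
coordinate-sorted, indexed BAM via pysam; no external aligner is involved,
so tests exercise classification, not alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genemodel import GeneModel, Transcript
from .signatures import SBS96_CONTEXTS, Exposures, SignatureCatalog
from .variants import SpliceEvent, SpliceVariant, annotate_event
from . import readclass

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "toy_gene_model",
    "write_gtf",
    "write_fasta",
    "event_for",
    "simulate_reads",
    "simulate_panels",
    "simulate_mutations",
    "simulate_spliceai_vcf",
]

#: Minimum aligned bases required on each side of a junction or boundary.
MIN_OVERHANG = 8

_CLASSES = ("canonical", "retention", "novel", "cryptic", "skip", "clipped")

# truth label per (event-category, read class)
_TRUTH = {
    "loss": {
        "retention": "abnormal_direct",
        "canonical": "normal",
        "cryptic": "abnormal_other",
        "skip": "abnormal_other",
        "clipped": "uninformative",
    },
    "gain": {
        "novel": "abnormal_direct",
        "canonical": "normal",
        "retention": "normal",
        "cryptic": "abnormal_other",
        "skip": "abnormal_other",
        "clipped": "uninformative",
    },
}


# ---------------------------------------------------------------------------
# Toy gene models
# ---------------------------------------------------------------------------

def toy_gene_model(
    strand: str = "+",
    chrom: str = "chrS",
    gene: str = "GENE1",
    n_exons: int = 4,
    exon_len: int = 200,
    intron_len: int = 300,
    offset: int = 1000,
) -> GeneModel:
    """A single-gene model with evenly spaced exons (0-based offset)."""
    exons = tuple(
        (offset + i * (exon_len + intron_len),
         offset + i * (exon_len + intron_len) + exon_len)
        for i in range(n_exons)
    )
    tx = Transcript(
        tx_id=f"{gene}.t1", gene=gene, chrom=chrom, strand=strand,
        exons=exons, canonical=True,
    )
    return GeneModel.from_transcripts([tx])


def write_gtf(gm: GeneModel, path: str) -> str:
    """Write the model's exon structures as GTF (1-based inclusive)."""
    lines = []
    for gene, txs in gm.transcripts.items():
        for tx in txs:
            tag = ' tag "canonical";' if tx.canonical else ""
            for s0, e0 in tx.exons:
                attrs = (
                    f'gene_id "{gene}"; gene_name "{gene}"; '
                    f'transcript_id "{tx.tx_id}";{tag}'
                )
                lines.append(
                    f"{tx.chrom}\trunjkit\texon\t{s0 + 1}\t{e0}\t.\t{tx.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
    return str(path)


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> str:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Event specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated splice event and its read mixture."""

    gm: GeneModel
    gene: str = "GENE1"
    event_type: str = "DL"  # AL | DL | AG | DG
    intron_index: int = 1
    f: float = 0.3  # abnormal (direct) fraction among crossing reads
    depth: int = 200
    read_length: int = 100
    seed: int = 0
    clip_fraction: float = 0.0
    other_fraction: float = 0.0  # cryptic/skip abnormal reads
    gain_offset: Optional[int] = None  # transcript-oriented shift of the novel site
    ds: float = 0.9
    sample: str = "sample"
    n_lowmapq: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0 and 0.0 <= self.clip_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f + self.clip_fraction + self.other_fraction > 1.0 + 1e-9:
            raise ValueError("class fractions exceed 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 2 * MIN_OVERHANG + 2:
            raise ValueError(
                f"read length {self.read_length} too short for junction "
                f"overhang {MIN_OVERHANG}"
            )


def _tx(spec: SimSpec) -> Transcript:
    return spec.gm.representative(spec.gene)


def _site_pos(spec: SimSpec) -> int:
    """1-based coordinate of the event's splice site.

    Losses sit at the canonical boundary. Gains default to a novel donor 10
    bases inside the exon (transcript orientation) or a novel acceptor 3
    bases into the exon, overridable via ``gain_offset``.
    """
    tx = _tx(spec)
    j = spec.intron_index
    sign = 1 if tx.strand == "+" else -1
    if spec.event_type == "DL":
        return tx.donors[j]
    if spec.event_type == "AL":
        return tx.acceptors[j]
    if spec.event_type == "DG":
        off = -10 if spec.gain_offset is None else spec.gain_offset
        return tx.donors[j] + sign * off
    off = 3 if spec.gain_offset is None else spec.gain_offset
    return tx.acceptors[j] + sign * off


def event_for(spec: SimSpec) -> SpliceEvent:
    """The annotated SpliceEvent this simulation realizes."""
    site = _site_pos(spec)
    tx = _tx(spec)
    # variant placed at the site itself; offsets are zero for losses
    kw = dict(ds_ag=0.0, ds_al=0.0, ds_dg=0.0, ds_dl=0.0,
              dp_ag=0, dp_al=0, dp_dg=0, dp_dl=0)
    kw[f"ds_{spec.event_type.lower()}"] = spec.ds
    v = SpliceVariant(
        chrom=tx.chrom, pos=site, ref="C", alt="T", gene=spec.gene,
        original_consequence="intronic", **kw,
    )
    e = SpliceEvent(variant=v, event_type=spec.event_type, ds=spec.ds,
                    site_pos=site)
    return annotate_event(e, spec.gm)


# ---------------------------------------------------------------------------
# Read geometry
# ---------------------------------------------------------------------------

def _geometry(spec: SimSpec) -> dict:
    """Reference coordinates needed to lay out each read class."""
    e = event_for(spec)
    tx = _tx(spec)
    introns = tx.introns
    j = spec.intron_index
    p0 = readclass.evaluation_position(e) - 1
    pair = readclass._decision_pair(e)
    if e.is_loss:
        canon = spec.gm.intron_at(spec.gene, e.boundary, e.kind)
        # cryptic site 10 bases into the exon adjacent to the lost boundary
        if canon[0] == e.boundary:  # exon genomically left of the intron
            cryptic = (canon[0] - 10, canon[1])
        else:
            cryptic = (canon[0], canon[1] + 10)
        novel = None
    else:
        side = readclass._gap_side(e)
        if side == "right":
            novel = (e.site_pos, introns[j][1])
            cryptic = (e.site_pos - 6, introns[j][1])
        else:
            novel = (introns[j][0], e.site_pos - 1)
            cryptic = (introns[j][0], e.site_pos + 5)
        canon = introns[j]
    if j >= 1:
        skip = (introns[j - 1][0], introns[j][1])
    else:
        skip = (introns[j][0], introns[j + 1][1])
    if not e.is_loss and readclass._gap_side(e) == "left":
        # novel site in the downstream exon: skip that exon instead
        if j + 1 < len(introns):
            skip = (introns[j][0], introns[j + 1][1])
    return {"event": e, "p0": p0, "pair": pair, "canon": canon,
            "cryptic": cryptic, "novel": novel, "skip": skip}


def _junction_read(start: int, left: int, gap: int, right: int) -> tuple[int, str, int]:
    return start, f"{left}M{gap}N{right}M", left + right


def _layout(spec: SimSpec, geo: dict, cls: str, rng: np.random.Generator
            ) -> tuple[int, str, int]:
    """(ref_start, cigar, query_length) for one read of class ``cls``."""
    L = spec.read_length
    a = int(rng.integers(MIN_OVERHANG, L - MIN_OVERHANG + 1))
    pair = geo["pair"]
    if cls == "retention" or (cls == "canonical" and geo["event"].is_loss is False):
        # contiguous alignment across the decision pair
        return pair[1] - a, f"{L}M", L
    if cls in ("canonical", "novel", "cryptic", "skip"):
        gap = geo["canon"] if cls == "canonical" else geo[cls]
        if gap is None:
            raise ValueError(f"class {cls!r} undefined for {spec.event_type}")
        g0, g1 = gap
        return _junction_read(g0 - a, a, g1 - g0, L - a)
    if cls == "clipped":
        return pair[1] + 2 - a, f"{a}M{L - a}S", L
    raise ValueError(f"unknown read class {cls!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _emit_bam(
    reads: list[tuple[str, int, str, int]],
    chrom: str,
    contig_len: int,
    out_bam: str,
) -> str:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": contig_len}],
    }
    reads = sorted(reads, key=lambda r: r[1])
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as fh:
        for qname, start, cigar, mapq in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = qname
            seg.reference_id = 0
            seg.reference_start = start
            seg.cigarstring = cigar
            seg.mapping_quality = mapq
            seg.flag = 0
            seg.query_sequence = "A" * seg.infer_query_length()
            fh.write(seg)
    pysam.index(str(out_bam))
    return str(out_bam)


def simulate_reads(
    spec: SimSpec,
    out_bam: str,
    class_counts: Optional[dict[str, int]] = None,
) -> tuple[str, pd.DataFrame]:
    """Simulate reads crossing the event position; returns (bam, truth table).

    By default each crossing read is abnormal-direct with probability
    ``spec.f``, cryptic/skip-abnormal with ``spec.other_fraction`` (split
    evenly), clipped with ``spec.clip_fraction`` and canonical otherwise.
    ``class_counts`` overrides the mixture with exact per-class counts.
    The truth table lists each read's intended classifier call.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _geometry(spec)
    cat = "loss" if geo["event"].is_loss else "gain"
    direct_cls = "retention" if cat == "loss" else "novel"

    if class_counts is None:
        draws = rng.random(spec.depth)
        classes = []
        f, g, c = spec.f, spec.other_fraction, spec.clip_fraction
        for u in draws:
            if u < f:
                classes.append(direct_cls)
            elif u < f + g:
                classes.append("cryptic" if rng.random() < 0.5 else "skip")
            elif u < f + g + c:
                classes.append("clipped")
            else:
                classes.append("canonical")
    else:
        bad = set(class_counts) - set(_CLASSES)
        if bad:
            raise ValueError(f"unknown read classes: {sorted(bad)}")
        classes = [cls for cls, n in class_counts.items() for _ in range(n)]

    reads, truth = [], []
    for i, cls in enumerate(classes):
        qname = f"{spec.sample}_r{i:06d}"
        start, cigar, _ = _layout(spec, geo, cls, rng)
        reads.append((qname, start, cigar, 60))
        truth.append((qname, cls, _TRUTH[cat][cls]))
    for i in range(spec.n_lowmapq):
        qname = f"{spec.sample}_lowq{i:04d}"
        start, cigar, _ = _layout(spec, geo, "retention", rng)
        reads.append((qname, start, cigar, 10))
        truth.append((qname, "retention", "filtered_mapq"))

    tx = _tx(spec)
    contig_len = tx.exons[-1][1] + 500
    _emit_bam(reads, tx.chrom, contig_len, out_bam)
    truth_df = pd.DataFrame(truth, columns=["qname", "read_class", "truth_call"])
    return str(out_bam), truth_df


def simulate_panels(
    spec: SimSpec,
    out_dir: str,
    n_samples: int = 5,
    panel_f: float = 0.0,
    kind: str = "PON",
) -> dict[str, str]:
    """Simulate a control panel: one BAM per sample, no (or low) abnormal signal.

    Per-sample seeds are derived deterministically from the master seed.
    """
    out = {}
    rng = np.random.default_rng(spec.seed + 104729)  # offset stream for panels
    for i in range(n_samples):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        name = f"{kind.lower()}{i + 1}"
        sub = replace(spec, f=panel_f, other_fraction=0.0, clip_fraction=0.0,
                      seed=sub_seed, sample=name)
        path = str(Path(out_dir) / f"{name}.bam")
        simulate_reads(sub, path)
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# Mutation sets drawn from signature mixtures
# ---------------------------------------------------------------------------

def simulate_mutations(
    catalog: SignatureCatalog,
    exposures: pd.Series,
    n: int,
    seed: int = 0,
    chrom: str = "chrM1",
    sample: str = "sim",
    spacing: int = 10,
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """Draw n mutations from a signature mixture.

    Each mutation's signature is drawn from the (normalized) exposures, its
    SBS-96 context from that signature's probability vector, and its strand
    orientation uniformly (so purine-reference records exercise the
    reverse-complement rule). Returns (MAF-like table, reference sequences,
    truth signatures).
    """
    w = exposures / exposures.sum()
    rng = np.random.default_rng(seed)
    seq = list("T" * (n * spacing + spacing))
    rows, truths = [], []
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(n):
        sig = str(rng.choice(w.index, p=w.to_numpy()))
        probs = catalog.probs[sig].to_numpy()
        ctx = SBS96_CONTEXTS[int(rng.choice(96, p=probs))]
        five, ref, alt, three = ctx[0], ctx[2], ctx[4], ctx[6]
        triplet = five + ref + three
        if rng.random() < 0.5:  # write the purine strand
            triplet = triplet.translate(comp)[::-1]
            ref, alt = triplet[1], alt.translate(comp)
        pos = (i + 1) * spacing  # 1-based
        seq[pos - 2 : pos + 1] = list(triplet)
        rows.append((sample, chrom, pos, ref, alt, "intronic", 0.0))
        truths.append(sig)
    maf = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "consequence", "ds"]
    )
    return maf, {chrom: "".join(seq)}, pd.Series(truths, name="true_signature")


# ---------------------------------------------------------------------------
# SpliceAI-annotated VCF emission
# ---------------------------------------------------------------------------

def _variant_pos_for_rel(gm: GeneModel, gene: str, kind: str, site: int, rel: int) -> int:
    """Invert the relative-position conventions to place a variant."""
    strand = gm.strand(gene)
    if kind == "donor":
        d = rel
    else:
        if rel == 0:
            raise ValueError("acceptor-relative positions have no 0")
        d = rel if rel < 0 else rel - 1
    return site + d if strand == "+" else site - d


def simulate_spliceai_vcf(
    gm: GeneModel,
    events: Sequence[dict],
    out_vcf: str,
) -> str:
    """Write a VCF with SpliceAI-style annotations realizing ``events``.

    Each event dict takes: gene, event_type, ds, intron_index (default 1),
    rel (variant position relative to the closest essential site, default 0
    for donors / +1 for acceptors), gain_offset (novel-site shift for
    gains), consequence (default "intronic").
    The annotation offsets are computed so that parsing the record recovers
    the intended site position exactly.
    """
    recs = []
    for ev in events:
        gene = ev.get("gene", "GENE1")
        etype = ev["event_type"]
        ds = float(ev.get("ds", 0.9))
        spec = SimSpec(
            gm=gm, gene=gene, event_type=etype,
            intron_index=ev.get("intron_index", 1),
            gain_offset=ev.get("gain_offset"), ds=ds,
        )
        site = _site_pos(spec)
        kind = "donor" if etype in ("DL", "DG") else "acceptor"
        default_rel = 0 if kind == "donor" else 1
        rel = ev.get("rel", default_rel)
        anchor = gm.nearest_site(gene, site, kind) if etype in ("DG", "AG") else site
        pos = _variant_pos_for_rel(gm, gene, kind, anchor, rel)
        dp = site - pos
        scores = {"AG": 0.0, "AL": 0.0, "DG": 0.0, "DL": 0.0}
        offsets = {"AG": 0, "AL": 0, "DG": 0, "DL": 0}
        scores[etype] = ds
        offsets[etype] = dp
        ann = (
            f"T|{gene}|{scores['AG']:.2f}|{scores['AL']:.2f}|{scores['DG']:.2f}"
            f"|{scores['DL']:.2f}|{offsets['AG']}|{offsets['AL']}|{offsets['DG']}"
            f"|{offsets['DL']}"
        )
        recs.append((gm.chrom(gene), pos, ev.get("consequence", "intronic"), ann))

    header = pysam.VariantHeader()
    chroms = {c for c, *_ in recs}
    for c in sorted(chroms):
        length = max(tx.exons[-1][1] for txs in gm.transcripts.values()
                     for tx in txs if tx.chrom == c) + 1000
        header.contigs.add(c, length=length)
    header.info.add("SpliceAI", ".", "String",
                    "SpliceAI-style annotation: "
                    "ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL")
    header.info.add("Consequence", "1", "String", "Original consequence category")
    with pysam.VariantFile(str(out_vcf), "w", header=header) as vcf:
        for chrom, pos, csq, ann in sorted(recs, key=lambda r: (r[0], r[1])):
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=("C", "T")
            )
            rec.info["SpliceAI"] = ann
            rec.info["Consequence"] = csq
            vcf.write(rec)
    return str(out_vcf)
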