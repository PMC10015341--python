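"""SpliceAI-annotated variants: parsing, event selection, position spectra.

SpliceAI reports, for each variant and gene, four delta scores — the
probability that the variant causes an acceptor gain (AG), acceptor loss
(AL), donor gain (DG) or donor loss (DL) — each with a signed base offset
locating the affected or created splice site relative to the variant. This
module parses that annotation from VCF INFO fields (dialect
``ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``), selects the
strongest predicted event per variant, places the mutated base relative to
the closest essential splice site, and reclassifies variant consequences
when the splicing impact is significant (delta score >= 0.5 by default).

Position conventions (used for the donor/acceptor spectra):

* donor-relative: 0 is the last exonic base, +k the k-th intronic base,
  negative values are exonic positions upstream of the donor;
* acceptor-relative: -k is the k-th intronic base upstream of the acceptor,
  +k the k-th exonic base; there is no 0.

Both are transcript-oriented, so a minus-strand gene mirrors genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .genemodel import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceVariant",
    "SpliceEvent",
    "RelativePosition",
    "EVENT_TYPES",
    "ESSENTIAL_SPLICE_CATEGORIES",
    "parse_spliceai_vcf",
    "select_top_event",
    "annotate_event",
    "filter_significant",
    "relative_position",
    "position_spectrum",
    "reclassify",
    "gene_splice_frequency",
    "events_table",
]

#: Tie-break / canonical ordering of the four event classes.
EVENT_TYPES = ("AL", "DL", "AG", "DG")

#: Consequence categories that already denote essential splice-site variants.
ESSENTIAL_SPLICE_CATEGORIES = frozenset(
    {
        "splice",
        "essential_splice",
        "essential-splice",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_acceptor",
        "splice_donor",
    }
)


@dataclass(frozen=True)
class SpliceVariant:
    """One variant x gene record with its four SpliceAI delta scores."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int
    original_consequence: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty")

    @property
    def max_ds(self) -> float:
        return max(self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)

    def ds_of(self, event_type: str) -> float:
        return getattr(self, f"ds_{event_type.lower()}")

    def dp_of(self, event_type: str) -> int:
        return getattr(self, f"dp_{event_type.lower()}")


@dataclass(frozen=True)
class SpliceEvent:
    """The strongest predicted splicing abnormality of one variant."""

    variant: SpliceVariant
    event_type: str  # AL | DL | AG | DG
    ds: float
    site_pos: int  # 1-based coordinate of the affected/created splice site
    strand: Optional[str] = None  # filled by annotate_event
    boundary: Optional[int] = None  # nearest canonical boundary, 1-based

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")

    @property
    def kind(self) -> str:
        """"donor" for DL/DG, "acceptor" for AL/AG."""
        return "donor" if self.event_type in ("DL", "DG") else "acceptor"

    @property
    def is_loss(self) -> bool:
        return self.event_type in ("AL", "DL")


@dataclass(frozen=True)
class RelativePosition:
    event_type: str
    rel: int


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def _parse_annotation(ann: str) -> Optional[dict]:
    parts = ann.split("|")
    if len(parts) < 10:
        return None
    try:
        return {
            "alt": parts[0],
            "gene": parts[1],
            "ds_ag": float(parts[2]),
            "ds_al": float(parts[3]),
            "ds_dg": float(parts[4]),
            "ds_dl": float(parts[5]),
            "dp_ag": int(parts[6]),
            "dp_al": int(parts[7]),
            "dp_dg": int(parts[8]),
            "dp_dl": int(parts[9]),
        }
    except ValueError:
        return None


def parse_spliceai_vcf(
    vcf_path: str,
    annotation_key: str = "SpliceAI",
    consequence_key: str = "Consequence",
) -> list[SpliceVariant]:
    """Read SpliceAI-annotated variants from a VCF.

    One :class:`SpliceVariant` is produced per annotated ALT x gene entry.
    Records without the annotation key are skipped (counted and logged);
    malformed annotation entries raise a per-record warning, never an error.
    """
    variants: list[SpliceVariant] = []
    n_skipped = 0
    n_malformed = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if annotation_key not in vcf.header.info:
            raise KeyError(f"{annotation_key!r} not declared in VCF header")
        for rec in vcf:
            anns = rec.info.get(annotation_key)
            if anns is None:
                n_skipped += 1
                continue
            if isinstance(anns, str):
                anns = (anns,)
            consequence = rec.info.get(consequence_key, "unknown")
            if isinstance(consequence, tuple):
                consequence = consequence[0]
            for ann in anns:
                fields = _parse_annotation(ann)
                if fields is None:
                    n_malformed += 1
                    logger.warning(
                        "malformed %s entry at %s:%d: %r",
                        annotation_key, rec.chrom, rec.pos, ann,
                    )
                    continue
                alt = fields.pop("alt")
                gene = fields.pop("gene")
                variants.append(
                    SpliceVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        original_consequence=str(consequence),
                        **fields,
                    )
                )
    if n_skipped:
        logger.info("skipped %d records without %s annotation", n_skipped, annotation_key)
    if n_malformed:
        logger.warning("dropped %d malformed %s entries", n_malformed, annotation_key)
    return variants


# ---------------------------------------------------------------------------
# Event selection and significance filtering
# ---------------------------------------------------------------------------

def select_top_event(v: SpliceVariant) -> Optional[SpliceEvent]:
    """The event with the maximal delta score, or None if all four are 0.

    Ties are broken by the fixed order AL > DL > AG > DG so the result never
    depends on iteration order.
    """
    best = max(EVENT_TYPES, key=lambda t: (v.ds_of(t), -EVENT_TYPES.index(t)))
    ds = v.ds_of(best)
    if ds == 0.0:
        return None
    return SpliceEvent(
        variant=v, event_type=best, ds=ds, site_pos=v.pos + v.dp_of(best)
    )


def annotate_event(e: SpliceEvent, gm: GeneModel) -> SpliceEvent:
    """Attach strand and the nearest canonical boundary from the gene model.

    For loss events the boundary is the essential site being destroyed (the
    canonical donor/acceptor closest to the predicted site); for gain events
    it is the canonical site of the same kind closest to the novel site.
    """
    gene = e.variant.gene
    if gene not in gm:
        raise KeyError(f"gene {gene!r} absent from gene model")
    return replace(
        e,
        strand=gm.strand(gene),
        boundary=gm.nearest_site(gene, e.site_pos, e.kind),
    )


def filter_significant(
    events: Iterable[SpliceEvent], threshold: float = 0.5
) -> list[SpliceEvent]:
    """Events whose delta score meets the significance threshold (>=)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [e for e in events if e.ds >= threshold]


# ---------------------------------------------------------------------------
# Relative positions and spectra
# ---------------------------------------------------------------------------

def relative_position(
    v: SpliceVariant, e: SpliceEvent, gm: GeneModel
) -> Optional[RelativePosition]:
    """Mutated-base position relative to the closest essential splice site.

    Returns None when the variant's gene is absent from the model (the
    position is then unresolvable and excluded from spectra).
    """
    if v.gene not in gm:
        return None
    strand = gm.strand(v.gene)
    site = gm.nearest_site(v.gene, v.pos, e.kind)
    # genomic offset oriented along the transcript
    d = v.pos - site if strand == "+" else site - v.pos
    if e.kind == "donor":
        rel = d  # 0 = last exonic base, +k = k-th intronic base
    else:
        # acceptor: -k intronic upstream, +k exonic, no 0
        rel = d if d < 0 else d + 1
    return RelativePosition(event_type=e.event_type, rel=rel)


def position_spectrum(
    events: Sequence[SpliceEvent], gm: GeneModel
) -> pd.DataFrame:
    """Tally of mutated-base positions per event type.

    Fractions are normalized within each event type over resolvable
    positions, matching per-class position histograms.
    """
    rows = []
    for e in events:
        rp = relative_position(e.variant, e, gm)
        if rp is None:
            continue
        rows.append((rp.event_type, rp.rel))
    if not rows:
        return pd.DataFrame(columns=["event_type", "rel", "count", "fraction"])
    df = (
        pd.DataFrame(rows, columns=["event_type", "rel"])
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["event_type", "rel"], ignore_index=True)
    )
    df["fraction"] = df["count"] / df.groupby("event_type")["count"].transform("sum")
    return df


# ---------------------------------------------------------------------------
# Consequence reclassification and gene-level splice frequencies
# ---------------------------------------------------------------------------

def reclassify(v: SpliceVariant, threshold: float = 0.5) -> str:
    """Consequence after accounting for the predicted splicing impact.

    Variants already annotated as essential splice stay "splice"; any other
    variant whose maximal delta score reaches the threshold is converted to
    "splice"; the rest keep their original category.
    """
    if v.original_consequence.lower() in ESSENTIAL_SPLICE_CATEGORIES:
        return "splice"
    if v.max_ds >= threshold:
        return "splice"
    return v.original_consequence


def gene_splice_frequency(
    mutations: pd.DataFrame,
    genes: Sequence[str],
    cohort_size: int,
) -> pd.DataFrame:
    """Per-gene fraction of samples carrying splice mutations.

    ``mutations`` needs columns sample, gene, consequence (original) and
    reclassified_consequence. Two definitions are tabulated: essential
    splice annotations only, and essential plus cryptic (reclassified)
    splice mutations. A sample counts once per gene under each definition.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    out = []
    ess_mask = (
        mutations["consequence"].str.lower().isin(ESSENTIAL_SPLICE_CATEGORIES)
        if len(mutations)
        else pd.Series(dtype=bool)
    )
    for gene in genes:
        sub = mutations[mutations["gene"] == gene] if len(mutations) else mutations
        if len(sub) == 0:
            out.append((gene, 0.0, 0.0))
            continue
        n_ess = sub.loc[ess_mask.reindex(sub.index, fill_value=False), "sample"].nunique()
        n_all = sub.loc[sub["reclassified_consequence"] == "splice", "sample"].nunique()
        out.append((gene, n_ess / cohort_size, n_all / cohort_size))
    return pd.DataFrame(out, columns=["gene", "freq_essential", "freq_with_cryptic"])


def events_table(
    variants: Sequence[SpliceVariant],
    gm: Optional[GeneModel] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One row per variant with its top event, used by the CLI TSV output."""
    rows = []
    for v in variants:
        e = select_top_event(v)
        if e is None:
            continue
        rel = None
        if gm is not None and v.gene in gm:
            e = annotate_event(e, gm)
            rp = relative_position(v, e, gm)
            rel = rp.rel if rp is not None else None
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "event_type": e.event_type,
                "ds": e.ds,
                "site_pos": e.site_pos,
                "rel": rel,
                "original_consequence": v.original_consequence,
                "reclassified_consequence": reclassify(v, threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "event_type", "ds",
            "site_pos", "rel", "original_consequence",
            "reclassified_consequence",
        ],
    )
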