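"""Gene models: exon structures and the canonical junction set.

A :class:`GeneModel` wraps the exon intervals of one or more genes, loaded
from a GTF (via gffutils) or built directly from interval lists, and derives
the quantities the rest of the package needs:

* the canonical junction set — the introns of annotated transcripts, as
  0-based half-open genomic gaps, exactly the coordinates a spliced read's
  ``N`` CIGAR operation produces;
* the essential donor and acceptor sites of the representative transcript,
  as 1-based genomic coordinates of the last exonic base (donor) and first
  exonic base (acceptor), in transcript orientation.

Coordinates follow the package-wide rule: 1-based inclusive at GTF/VCF-facing
boundaries, 0-based half-open for interval arithmetic.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import gffutils

__all__ = ["Transcript", "GeneModel"]


@dataclass(frozen=True)
class Transcript:
    """One transcript: sorted genomic exon intervals plus metadata."""

    tx_id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomically sorted
    canonical: bool = False
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be genomically sorted")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """0-based half-open gaps between consecutive genomic exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def donors(self) -> tuple[int, ...]:
        """1-based genomic coordinates of the last exonic base at each donor.

        On the plus strand the donor of intron i is the end of exon i; on the
        minus strand it is the genomic start of exon i+1 (transcription runs
        right to left).
        """
        if self.strand == "+":
            return tuple(e for _, e in self.exons[:-1])
        return tuple(s + 1 for s, _ in self.exons[1:])

    @property
    def acceptors(self) -> tuple[int, ...]:
        """1-based genomic coordinates of the first exonic base at each acceptor."""
        if self.strand == "+":
            return tuple(s + 1 for s, _ in self.exons[1:])
        return tuple(e for _, e in self.exons[:-1])


@dataclass
class GeneModel:
    """Exon structures for a set of genes with junction/site lookups."""

    transcripts: dict[str, list[Transcript]] = field(default_factory=dict)

    def add(self, tx: Transcript) -> None:
        self.transcripts.setdefault(tx.gene, []).append(tx)

    @classmethod
    def from_transcripts(cls, txs: list[Transcript]) -> "GeneModel":
        gm = cls()
        for tx in txs:
            gm.add(tx)
        return gm

    @classmethod
    def from_gtf(cls, gtf_path: str) -> "GeneModel":
        """Load exon structures from a GTF file.

        Transcripts flagged ``tag "canonical"`` are preferred as
        representatives; CDS features, when present, contribute to the
        longest-CDS fallback.
        """
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        exons: dict[str, list] = {}
        cds_len: dict[str, int] = {}
        meta: dict[str, tuple[str, str, str, bool]] = {}
        for f in db.all_features():
            if f.featuretype not in ("exon", "CDS"):
                continue
            tx_id = f.attributes["transcript_id"][0]
            gene = (f.attributes.get("gene_name") or f.attributes.get("gene_id"))[0]
            tags = f.attributes.get("tag", [])
            canonical = meta.get(tx_id, (None, None, None, False))[3] or (
                "canonical" in tags
            )
            meta[tx_id] = (gene, f.seqid, f.strand, canonical)
            if f.featuretype == "exon":
                exons.setdefault(tx_id, []).append((f.start - 1, f.end))
            else:
                cds_len[tx_id] = cds_len.get(tx_id, 0) + (f.end - f.start + 1)
        gm = cls()
        for tx_id, ivals in exons.items():
            gene, chrom, strand, canonical = meta[tx_id]
            gm.add(
                Transcript(
                    tx_id=tx_id,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(sorted(ivals)),
                    canonical=canonical,
                    cds_length=cds_len.get(tx_id, 0),
                )
            )
        return gm

    # -- lookups -----------------------------------------------------------

    def genes(self) -> list[str]:
        return list(self.transcripts)

    def __contains__(self, gene: str) -> bool:
        return gene in self.transcripts

    def representative(self, gene: str) -> Transcript:
        """The transcript used for boundaries and relative positions.

        Preference order: canonical tag, then longest CDS, then longest
        exonic span, with transcript id as the final deterministic tie-break.
        """
        txs = self.transcripts[gene]
        return max(
            txs,
            key=lambda t: (t.canonical, t.cds_length, t.exonic_length, t.tx_id),
        )

    def strand(self, gene: str) -> str:
        return self.representative(gene).strand

    def chrom(self, gene: str) -> str:
        return self.representative(gene).chrom

    def canonical_junctions(self, gene: str) -> frozenset[tuple[int, int]]:
        """All annotated introns of the gene (union over transcripts).

        A spliced read's junction is "canonical" if any annotated transcript
        of the gene contains it; novelty is judged against the union so that
        ordinary alternative isoforms are not mistaken for abnormal splicing.
        """
        out: set[tuple[int, int]] = set()
        for tx in self.transcripts[gene]:
            out.update(tx.introns)
        return frozenset(out)

    def donors(self, gene: str) -> tuple[int, ...]:
        return self.representative(gene).donors

    def acceptors(self, gene: str) -> tuple[int, ...]:
        return self.representative(gene).acceptors

    def nearest_site(self, gene: str, pos: int, kind: str) -> int:
        """Closest essential site of ``kind`` ("donor"/"acceptor") to 1-based ``pos``.

        Ties go to the smaller genomic coordinate (deterministic).
        """
        sites = self.donors(gene) if kind == "donor" else self.acceptors(gene)
        if not sites:
            raise ValueError(f"gene {gene} has no {kind} sites (single exon?)")
        return min(sites, key=lambda s: (abs(s - pos), s))

    def intron_at(self, gene: str, boundary: int, kind: str) -> tuple[int, int]:
        """The canonical intron whose donor/acceptor sits at 1-based ``boundary``."""
        tx = self.representative(gene)
        getter = operator.attrgetter("donors" if kind == "donor" else "acceptors")
        for site, intron in zip(getter(tx), _introns_in_tx_order(tx)):
            if site == boundary:
                return intron
        raise ValueError(f"no canonical {kind} at {boundary} in {gene}")


def _introns_in_tx_order(tx: Transcript) -> tuple[tuple[int, int], ...]:
    """Introns ordered to pair with tx.donors/tx.acceptors.

    For plus-strand transcripts donors/acceptors already follow genomic
    order; on the minus strand both site tuples are derived from genomically
    sorted exons, so genomic intron order still pairs correctly: the donor of
    minus-strand intron i is the start of exon i+1 and tx.donors lists exons
    1..n-1 in genomic order, matching introns 0..n-2.
    """
    return tx.introns
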