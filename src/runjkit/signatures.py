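"""Mutational-signature attribution and splice-enrichment testing.

Each single-base substitution is classified into one of the 96 SBS
trinucleotide contexts (pyrimidine-strand convention). Given a signature
catalog (per-signature probability over the 96 contexts) and per-sample
exposures (signature activities), the posterior probability that mutation m
arose from signature s is

    P(s | m) = e_s * f_s(ctx(m)) / sum_s' e_s' * f_s'(ctx(m))

The contribution of a signature to a mutation set is the sum of these
probabilities over the set, and splice-vs-other enrichment is tested per
signature with a two-sided Wilcoxon rank-sum test on the per-mutation
P(s | m) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SBS96_CONTEXTS",
    "SignatureCatalog",
    "Exposures",
    "AttributionMatrix",
    "context_of",
    "attribute",
    "attribute_table",
    "contribution",
    "enrichment_test",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _make_contexts() -> tuple[str, ...]:
    out = []
    for sub in _SUBSTITUTIONS:
        for five in "ACGT":
            for three in "ACGT":
                out.append(f"{five}[{sub}]{three}")
    return tuple(out)


#: Canonical COSMIC ordering of the 96 substitution contexts.
SBS96_CONTEXTS = _make_contexts()
_CONTEXT_INDEX = {c: i for i, c in enumerate(SBS96_CONTEXTS)}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def context_of(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_sequence: Union[Mapping[str, str], "object"],
) -> str:
    """SBS-96 context of a single-nucleotide substitution at 1-based ``pos``.

    Purine reference alleles are reverse-complemented together with their
    flanks so the mutated base is always reported as a pyrimidine.
    ``reference_sequence`` is anything indexable as seq[chrom][start:end]
    with 0-based slices (a pyfaidx.Fasta or a plain dict of strings).
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    triplet = str(reference_sequence[chrom][pos - 2 : pos + 1]).upper()
    if len(triplet) != 3:
        raise ValueError(f"cannot extract flanks at {chrom}:{pos}")
    if triplet[1] != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, found {triplet[1]}"
        )
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":  # purine: flip to the pyrimidine strand
        triplet, alt = _revcomp(triplet), _revcomp(alt)
        ref = triplet[1]
    label = f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"
    if label not in _CONTEXT_INDEX:
        raise ValueError(f"non-ACGT context at {chrom}:{pos}: {label}")
    return label


@dataclass
class SignatureCatalog:
    """96-context probability vectors for a named set of signatures."""

    probs: pd.DataFrame  # index: SBS96_CONTEXTS, columns: signature names

    def __post_init__(self) -> None:
        missing = set(SBS96_CONTEXTS) - set(self.probs.index)
        if missing:
            raise ValueError(f"catalog missing {len(missing)} contexts")
        self.probs = self.probs.loc[list(SBS96_CONTEXTS)].astype(float)
        if (self.probs.values < 0).any():
            raise ValueError("catalog probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    @property
    def signatures(self) -> list[str]:
        return list(self.probs.columns)

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureCatalog":
        """Load a COSMIC-style TSV: context labels in the first column."""
        df = pd.read_csv(path, sep="\t")
        return cls(df.set_index(df.columns[0]))

    def to_tsv(self, path: str) -> None:
        self.probs.rename_axis("Type").to_csv(path, sep="\t")


@dataclass
class Exposures:
    """Per-sample signature activities, normalized to sum 1 on load."""

    weights: pd.DataFrame  # index: sample, columns: signature names

    def __post_init__(self) -> None:
        if (self.weights.values < 0).any():
            raise ValueError("exposure weights must be non-negative")
        totals = self.weights.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("every sample needs positive total exposure")
        self.weights = self.weights.div(totals, axis=0)

    @classmethod
    def from_tsv(cls, path: str) -> "Exposures":
        df = pd.read_csv(path, sep="\t")
        return cls(df.set_index(df.columns[0]).astype(float))

    def for_sample(self, sample: str) -> pd.Series:
        return self.weights.loc[sample]

    def restrict(self, allowed: Sequence[str]) -> "Exposures":
        """Keep only an allow-list of signatures (e.g. per cancer type)."""
        return Exposures(self.weights[list(allowed)].copy())


@dataclass
class AttributionMatrix:
    """Per-mutation posterior probabilities over signatures.

    ``probs`` rows align with the mutation table rows that were
    attributable; each row sums to 1. ``splice`` flags mutations that are
    essential-splice or significant cryptic splice events.
    """

    probs: pd.DataFrame
    splice: pd.Series
    n_excluded: int = 0
    excluded_index: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1)
        if len(self.probs) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("attribution rows must sum to 1")


def attribute(
    context: str,
    exposures: pd.Series,
    catalog: SignatureCatalog,
) -> Optional[np.ndarray]:
    """Posterior P(signature | mutation) for one mutation context.

    None when no active signature has mass on the context (the mutation is
    unattributable and excluded from downstream sums).
    """
    f = catalog.probs.loc[context, exposures.index].to_numpy(dtype=float)
    w = exposures.to_numpy(dtype=float) * f
    total = w.sum()
    if total <= 0:
        return None
    return w / total


def attribute_table(
    mutations: pd.DataFrame,
    exposures: Exposures,
    catalog: SignatureCatalog,
    reference_sequence,
    ds_threshold: float = 0.5,
) -> AttributionMatrix:
    """Attribute every mutation in a MAF-like table.

    Required columns: sample, chrom, pos, ref, alt, consequence; optional
    ds (max SpliceAI delta score). The splice flag is true for
    essential-splice consequences and for cryptic events with ds >= the
    threshold. Indels, reference mismatches and unattributable mutations
    are excluded and counted.
    """
    from .variants import ESSENTIAL_SPLICE_CATEGORIES

    rows, keep_idx, splice_flags = [], [], []
    excluded = []
    sig_names = catalog.signatures
    for idx, m in mutations.iterrows():
        try:
            ctx = context_of(
                str(m["chrom"]), int(m["pos"]), m["ref"], m["alt"],
                reference_sequence,
            )
        except ValueError as err:
            logger.debug("excluded mutation at index %s: %s", idx, err)
            excluded.append(idx)
            continue
        expo = exposures.for_sample(m["sample"]).reindex(sig_names).fillna(0.0)
        p = attribute(ctx, expo, catalog)
        if p is None:
            excluded.append(idx)
            continue
        rows.append(p)
        keep_idx.append(idx)
        is_ess = str(m["consequence"]).lower() in ESSENTIAL_SPLICE_CATEGORIES
        ds = float(m["ds"]) if "ds" in m and pd.notna(m["ds"]) else 0.0
        splice_flags.append(bool(is_ess or ds >= ds_threshold))
    probs = pd.DataFrame(rows, index=keep_idx, columns=sig_names, dtype=float)
    if excluded:
        logger.info("excluded %d of %d mutations from attribution",
                    len(excluded), len(mutations))
    return AttributionMatrix(
        probs=probs,
        splice=pd.Series(splice_flags, index=keep_idx, dtype=bool),
        n_excluded=len(excluded),
        excluded_index=excluded,
    )


def contribution(
    attr: AttributionMatrix, subset: Optional[pd.Series] = None
) -> pd.Series:
    """Per-signature contribution sums over a mutation subset.

    ``subset`` is a boolean mask aligned with the attribution rows (all rows
    when omitted). The sums over signatures equal the number of attributed
    mutations in the subset.
    """
    probs = attr.probs if subset is None else attr.probs.loc[subset.reindex(attr.probs.index, fill_value=False)]
    return probs.sum(axis=0)


def enrichment_test(attr: AttributionMatrix) -> pd.DataFrame:
    """Splice-vs-other enrichment per signature.

    Two-sided Wilcoxon rank-sum test comparing the per-mutation P(s | m)
    distributions between splice and non-splice mutations; direction is the
    sign of (median_splice - median_other). Raw p-values are reported with a
    Benjamini-Hochberg column alongside.
    """
    rows = []
    splice = attr.probs.loc[attr.splice]
    other = attr.probs.loc[~attr.splice]
    for sig in attr.probs.columns:
        if len(splice) == 0 or len(other) == 0:
            rows.append((sig, np.nan, 0))
            continue
        x, y = splice[sig].to_numpy(), other[sig].to_numpy()
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        direction = int(np.sign(np.median(x) - np.median(y)))
        rows.append((sig, float(p), direction))
    df = pd.DataFrame(rows, columns=["signature", "p_value", "direction"])
    ok = df["p_value"].notna()
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = stats.false_discovery_control(
            df.loc[ok, "p_value"], method="bh"
        )
    return df
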