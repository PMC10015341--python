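"""RUNJ scores and validation of predicted splice events.

The Relative Usage of the Novel Junction compares the abnormal-read
fraction at the event position p in the mutated sample against the pooled
fraction in a control panel::

    RUNJ = #M_a / (#M_a + #M_n)  -  #C_a / (#C_a + #C_n)

where M_a/M_n are abnormal/normal informative reads crossing p in the
mutated sample and C_a/C_n the pooled counts across the panel. Two panels
are used per event: a Panel of Normals (PON, non-tumor samples) and a Panel
of Tumors (POT, tumors without a somatic mutation at the locus, controlling
for tumor-specific expression effects), and two counting modes (``direct``:
only reads supporting the event's most direct consequence; ``all``: any
abnormal pattern at the boundary), giving four scores.

A prediction is validated iff

1. #M_a >= 2 (abnormal reads in ``all`` mode by default),
2. RUNJ_direct,PON >= 0.01 or RUNJ_all,PON >= 0.01, and
3. RUNJ_direct,POT >= 0.01 or RUNJ_all,POT >= 0.01, or the POT criterion is
   not applicable (no eligible tumor, or no POT coverage at p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import readclass
from .genemodel import GeneModel
from .variants import SpliceEvent

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionCounts",
    "Panel",
    "ValidationResult",
    "runj",
    "build_pot",
    "validate",
    "validate_cohort",
    "RESULT_COLUMNS",
]

#: Paper-default thresholds, overridable everywhere they are used.
DEFAULT_MIN_READS = 2
DEFAULT_MIN_RUNJ = 0.01
DEFAULT_MIN_MAPQ = 20
DEFAULT_PANEL_SIZE = 5


@dataclass(frozen=True)
class JunctionCounts:
    """The four read tallies behind one RUNJ value."""

    m_a: int
    m_n: int
    c_a: int
    c_n: int
    mode: str = "all"  # direct | all
    panel_kind: str = "PON"  # PON | POT

    def __post_init__(self) -> None:
        if min(self.m_a, self.m_n, self.c_a, self.c_n) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def control_low_coverage(self) -> bool:
        return self.c_a + self.c_n == 0


@dataclass
class Panel:
    """A control panel: sample name -> alignment file path."""

    kind: str  # PON | POT
    samples: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("PON", "POT"):
            raise ValueError("panel kind must be PON or POT")

    @property
    def size(self) -> int:
        return len(self.samples)


@dataclass
class ValidationResult:
    runj_direct_pon: Optional[float]
    runj_all_pon: Optional[float]
    runj_direct_pot: Optional[float]
    runj_all_pot: Optional[float]
    m_a_direct: int
    m_a_all: int
    pot_applicable: bool
    validated: bool = False
    reasons: list[str] = field(default_factory=list)


def runj(c: JunctionCounts) -> Optional[float]:
    """The RUNJ score, or None when the mutated sample has no informative reads.

    Zero control coverage does not poison the score: the control fraction is
    taken as 0 and the condition is flagged via ``c.control_low_coverage``.
    """
    if c.m_a + c.m_n == 0:
        return None
    mut_frac = c.m_a / (c.m_a + c.m_n)
    ctl_frac = 0.0 if c.control_low_coverage else c.c_a / (c.c_a + c.c_n)
    return mut_frac - ctl_frac


def build_pot(
    tumors: dict[str, str],
    locus: tuple[str, int],
    mutation_table: pd.DataFrame,
    size: int = DEFAULT_PANEL_SIZE,
    seed: int = 0,
) -> Optional[Panel]:
    """Panel of Tumors: up to ``size`` tumors unmutated at ``locus``.

    ``mutation_table`` needs columns sample, chrom, pos. Eligible tumors are
    taken in a seeded deterministic order; None when no tumor is eligible
    (the POT criterion is then "not applicable").
    """
    chrom, pos = locus
    if len(mutation_table):
        hit = mutation_table[
            (mutation_table["chrom"].astype(str) == str(chrom))
            & (mutation_table["pos"] == pos)
        ]["sample"]
        mutated = set(hit)
    else:
        mutated = set()
    eligible = sorted(s for s in tumors if s not in mutated)
    if not eligible:
        return None
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    chosen = order[:size]
    if len(chosen) < size:
        logger.info(
            "POT undersized at %s:%d: %d of %d requested", chrom, pos, len(chosen), size
        )
    return Panel(kind="POT", samples={s: tumors[s] for s in chosen})


def _meets(value: Optional[float], threshold: float) -> bool:
    return value is not None and not math.isnan(value) and value >= threshold


def validate(
    runj_direct_pon: Optional[float],
    runj_all_pon: Optional[float],
    runj_direct_pot: Optional[float],
    runj_all_pot: Optional[float],
    m_a_direct: int,
    m_a_all: int,
    pot_applicable: bool = True,
    min_reads: int = DEFAULT_MIN_READS,
    min_runj: float = DEFAULT_MIN_RUNJ,
    criterion_counts: str = "all",
) -> ValidationResult:
    """Apply the three validation criteria to the computed scores.

    ``criterion_counts`` selects which abnormal count feeds the minimum-read
    criterion (the ``all`` count, a superset of ``direct``, by default).
    """
    m_a = m_a_all if criterion_counts == "all" else m_a_direct
    crit_reads = m_a >= min_reads
    crit_pon = _meets(runj_direct_pon, min_runj) or _meets(runj_all_pon, min_runj)
    crit_pot = (
        (not pot_applicable)
        or _meets(runj_direct_pot, min_runj)
        or _meets(runj_all_pot, min_runj)
    )
    reasons = [
        f"min_reads({m_a}>={min_reads}):{'pass' if crit_reads else 'fail'}",
        f"pon(runj>={min_runj}):{'pass' if crit_pon else 'fail'}",
        (
            "pot:not_applicable"
            if not pot_applicable
            else f"pot(runj>={min_runj}):{'pass' if crit_pot else 'fail'}"
        ),
    ]
    return ValidationResult(
        runj_direct_pon=runj_direct_pon,
        runj_all_pon=runj_all_pon,
        runj_direct_pot=runj_direct_pot,
        runj_all_pot=runj_all_pot,
        m_a_direct=m_a_direct,
        m_a_all=m_a_all,
        pot_applicable=pot_applicable,
        validated=bool(crit_reads and crit_pon and crit_pot),
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "event_type", "ds", "p",
    "m_a_direct", "m_n_direct", "m_a_all", "m_n_all",
    "c_a_direct_pon", "c_n_direct_pon", "c_a_all_pon", "c_n_all_pon",
    "c_a_direct_pot", "c_n_direct_pot", "c_a_all_pot", "c_n_all_pot",
    "runj_direct_pon", "runj_all_pon", "runj_direct_pot", "runj_all_pot",
    "pon_low_coverage", "pot_applicable",
    "crit_min_reads", "crit_pon", "crit_pot", "validated", "reasons",
]


def _sample_counts(
    bam: str, sample: str, e: SpliceEvent, gm: GeneModel, p: int, min_mapq: int
) -> dict[str, tuple[int, int]]:
    reads = readclass.reads_crossing(
        bam, gm.chrom(e.variant.gene), p, min_mapq=min_mapq, sample=sample
    )
    direct_calls = [readclass.classify_direct(r, e, gm) for r in reads]
    all_calls = [readclass.classify_all(r, e, gm) for r in reads]
    return {
        "direct": readclass.count_reads(direct_calls, "direct"),
        "all": readclass.count_reads(all_calls, "all"),
    }


def _panel_counts(
    panel: Optional[Panel], e: SpliceEvent, gm: GeneModel, p: int, min_mapq: int
) -> dict[str, tuple[int, int]]:
    totals = {"direct": [0, 0], "all": [0, 0]}
    if panel is not None:
        for sample, path in panel.samples.items():
            counts = _sample_counts(path, sample, e, gm, p, min_mapq)
            for mode in ("direct", "all"):
                totals[mode][0] += counts[mode][0]
                totals[mode][1] += counts[mode][1]
    return {m: (a, n) for m, (a, n) in totals.items()}


def validate_cohort(
    events: Sequence[SpliceEvent],
    tumor_bam: str,
    pon: Panel,
    pot: Optional[Panel],
    gm: GeneModel,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_reads: int = DEFAULT_MIN_READS,
    min_runj: float = DEFAULT_MIN_RUNJ,
    criterion_counts: str = "all",
) -> pd.DataFrame:
    """Score and validate every event; one row per event.

    Per-event failures are logged and the run continues; the summary
    validation rate is logged at the end.
    """
    rows = []
    n_validated = 0
    for e in events:
        try:
            rows.append(
                _validate_one(
                    e, tumor_bam, pon, pot, gm, min_mapq, min_reads, min_runj,
                    criterion_counts,
                )
            )
            n_validated += rows[-1]["validated"]
        except Exception:
            logger.exception(
                "validation failed for %s:%d %s",
                e.variant.chrom, e.variant.pos, e.event_type,
            )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        logger.info("validation rate: %d/%d = %.3f", n_validated, len(df),
                    n_validated / len(df))
    return df


def _validate_one(
    e: SpliceEvent,
    tumor_bam: str,
    pon: Panel,
    pot: Optional[Panel],
    gm: GeneModel,
    min_mapq: int,
    min_reads: int,
    min_runj: float,
    criterion_counts: str,
) -> dict:
    p = readclass.evaluation_position(e)
    tum = _sample_counts(tumor_bam, "tumor", e, gm, p, min_mapq)
    pon_c = _panel_counts(pon, e, gm, p, min_mapq)
    pot_c = _panel_counts(pot, e, gm, p, min_mapq)

    def jc(mode: str, panel_counts, kind: str) -> JunctionCounts:
        return JunctionCounts(
            m_a=tum[mode][0], m_n=tum[mode][1],
            c_a=panel_counts[mode][0], c_n=panel_counts[mode][1],
            mode=mode, panel_kind=kind,
        )

    jd_pon, ja_pon = jc("direct", pon_c, "PON"), jc("all", pon_c, "PON")
    jd_pot, ja_pot = jc("direct", pot_c, "POT"), jc("all", pot_c, "POT")
    pot_applicable = pot is not None and not (
        jd_pot.control_low_coverage and ja_pot.control_low_coverage
    )
    res = validate(
        runj_direct_pon=runj(jd_pon),
        runj_all_pon=runj(ja_pon),
        runj_direct_pot=runj(jd_pot) if pot_applicable else None,
        runj_all_pot=runj(ja_pot) if pot_applicable else None,
        m_a_direct=tum["direct"][0],
        m_a_all=tum["all"][0],
        pot_applicable=pot_applicable,
        min_reads=min_reads,
        min_runj=min_runj,
        criterion_counts=criterion_counts,
    )
    v = e.variant
    return {
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "gene": v.gene, "event_type": e.event_type, "ds": e.ds, "p": p,
        "m_a_direct": tum["direct"][0], "m_n_direct": tum["direct"][1],
        "m_a_all": tum["all"][0], "m_n_all": tum["all"][1],
        "c_a_direct_pon": pon_c["direct"][0], "c_n_direct_pon": pon_c["direct"][1],
        "c_a_all_pon": pon_c["all"][0], "c_n_all_pon": pon_c["all"][1],
        "c_a_direct_pot": pot_c["direct"][0], "c_n_direct_pot": pot_c["direct"][1],
        "c_a_all_pot": pot_c["all"][0], "c_n_all_pot": pot_c["all"][1],
        "runj_direct_pon": res.runj_direct_pon, "runj_all_pon": res.runj_all_pon,
        "runj_direct_pot": res.runj_direct_pot, "runj_all_pot": res.runj_all_pot,
        "pon_low_coverage": jd_pon.control_low_coverage and ja_pon.control_low_coverage,
        "pot_applicable": pot_applicable,
        "crit_min_reads": "pass" in res.reasons[0],
        "crit_pon": "pass" in res.reasons[1],
        "crit_pot": res.reasons[2].endswith(("pass", "not_applicable")),
        "validated": res.validated,
        "reasons": ";".join(res.reasons),
    }
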