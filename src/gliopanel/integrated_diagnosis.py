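"""Rule engine combining molecular calls into an integrated diagnosis.

Implements the WHO / cIMPACT-NOW decision structure for adult diffuse
gliomas on molecular grounds alone:

1. IDH-mutant and 1p/19q co-deleted → oligodendroglioma.
2. IDH-mutant, non-codeleted → IDH-mutant astrocytoma; grade 4 when CDKN2A
   is homozygously deleted, otherwise not gradeable without histology.
3. IDH-wildtype adult with at least one molecular alteration → IDH-wildtype
   glioblastoma when EGFR is amplified, or chromosome 7 gain co-occurs with
   chromosome 10 loss, or an externally supplied TERT-promoter mutation flag
   is set; otherwise diffuse glioma NOS with TERT promoter listed as
   unassessed (the panel does not cover it).
4. Pediatric or H3-altered cases, and cases with no molecular alterations at
   all, are routed to non-glioma/unclassified.

Contradictory inputs (co-deletion with wildtype IDH — a known copy-number
false-positive mode) are flagged as discordant and labeled diffuse glioma
NOS, never silently classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cn_calling import CDKN2AStatus, CodelResult, EGFRStatus
from .variant_interpretation import IDHCall, TP53Call

LABELS = (
    "oligodendroglioma",
    "astrocytoma_idh_mutant",
    "glioblastoma_idh_wt",
    "diffuse_glioma_nos",
    "non_glioma_or_unclassified",
)


@dataclass(frozen=True)
class GradingThresholds:
    """Panel-data operationalization of the +7/−10 criterion: chromosome-7
    background mean at or above ``chr7_gain`` together with chromosome-10 set
    mean at or below ``chr10_loss``.  The criterion itself is standard; these
    panel thresholds are configurable defaults."""

    chr7_gain: float = 2.5
    chr10_loss: float = 1.5


@dataclass
class ExternalFlags:
    """Markers the panel cannot assess, supplied externally when available."""

    pediatric: bool = False
    h3_mutant: Optional[bool] = None
    tert_promoter: Optional[bool] = None
    histology_grade: Optional[int] = None


@dataclass
class IntegratedDiagnosis:
    label: str
    grade: Optional[object]  # 2 | 3 | 4 | "not_gradeable"
    evidence: list[tuple[str, object]] = field(default_factory=list)
    unassessed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown diagnosis label {self.label!r}")


def integrate(
    idh: IDHCall,
    tp53: TP53Call,
    codel: Optional[CodelResult],
    egfr: Optional[EGFRStatus],
    cdkn2a: Optional[CDKN2AStatus],
    chr7_mean: Optional[float] = None,
    chr10_mean: Optional[float] = None,
    external_flags: Optional[ExternalFlags] = None,
    thresholds: GradingThresholds = GradingThresholds(),
) -> IntegratedDiagnosis:
    """Combine component calls into an integrated diagnosis with grade,
    supporting evidence, and unassessed-marker flags."""
    flags = external_flags or ExternalFlags()
    evidence: list[tuple[str, object]] = []
    unassessed: list[str] = []

    codeleted = codel.codeleted if codel is not None else None
    egfr_call = egfr.call if egfr is not None else None
    cdkn2a_call = cdkn2a.call if cdkn2a is not None else "not_assessed"

    if flags.tert_promoter is None:
        unassessed.append("TERT_promoter")
    if flags.histology_grade is None:
        unassessed.append("histology")
    if cdkn2a_call == "not_assessed":
        unassessed.append("CDKN2A")

    # contradictory molecular pattern: co-deletion requires IDH mutation
    if codeleted and not idh.mutant:
        evidence.append(("discordant", "1p/19q co-deletion with IDH-wildtype status"))
        return IntegratedDiagnosis(
            label="diffuse_glioma_nos", grade="not_gradeable", evidence=evidence, unassessed=unassessed
        )

    if idh.mutant:
        if codeleted is None:
            raise ValueError(
                "integration of an IDH-mutant case requires a 1p/19q co-deletion call"
            )
        evidence.append(("IDH", idh.variant.gene + " " + idh.variant.protein_change if idh.variant else "mutant"))
        if codeleted:
            evidence.append(("1p/19q", "codeleted"))
            return IntegratedDiagnosis(
                label="oligodendroglioma", grade="not_gradeable", evidence=evidence, unassessed=unassessed
            )
        evidence.append(("1p/19q", "not_codeleted"))
        if cdkn2a_call == "homozygous_deletion":
            evidence.append(("CDKN2A", "homozygous_deletion"))
            return IntegratedDiagnosis(
                label="astrocytoma_idh_mutant", grade=4, evidence=evidence, unassessed=unassessed
            )
        return IntegratedDiagnosis(
            label="astrocytoma_idh_mutant", grade="not_gradeable", evidence=evidence, unassessed=unassessed
        )

    # IDH-wildtype branch
    if flags.pediatric or flags.h3_mutant:
        if flags.h3_mutant:
            evidence.append(("H3", True))
        if flags.pediatric:
            evidence.append(("pediatric", True))
        return IntegratedDiagnosis(
            label="non_glioma_or_unclassified", grade="not_gradeable", evidence=evidence, unassessed=unassessed
        )

    plus7_minus10 = False
    if chr7_mean is not None and chr10_mean is not None:
        plus7_minus10 = chr7_mean >= thresholds.chr7_gain and chr10_mean <= thresholds.chr10_loss
    elif chr7_mean is not None and chr10_mean is None:
        unassessed.append("chr10")

    any_alteration = (
        tp53.mutated
        or bool(codeleted)
        or (egfr_call not in (None, "no_alteration"))
        or cdkn2a_call in ("loss", "homozygous_deletion")
        or plus7_minus10
        or bool(flags.tert_promoter)
    )
    if not any_alteration:
        return IntegratedDiagnosis(
            label="non_glioma_or_unclassified", grade="not_gradeable", evidence=[], unassessed=unassessed
        )

    gbm_criteria: list[tuple[str, object]] = []
    if egfr_call == "amplified":
        gbm_criteria.append(("EGFR", "amplified"))
    if plus7_minus10:
        gbm_criteria.append(("+7/-10", f"chr7 {chr7_mean:.2f}, chr10 {chr10_mean:.2f}"))
    if flags.tert_promoter:
        gbm_criteria.append(("TERT_promoter", "mutant"))

    if gbm_criteria:
        evidence.extend(gbm_criteria)
        return IntegratedDiagnosis(
            label="glioblastoma_idh_wt", grade=4, evidence=evidence, unassessed=unassessed
        )
    return IntegratedDiagnosis(
        label="diffuse_glioma_nos", grade="not_gradeable", evidence=evidence, unassessed=unassessed
    )
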