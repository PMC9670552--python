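"""End-to-end per-case calling: runs every interpretation stage on a
:class:`~gliopanel.panel_model.CaseRecord` and assembles the report object
consumed by :func:`gliopanel.panel_model.write_report`."""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from . import cn_calling, fusion_annotation, integrated_diagnosis, variant_interpretation
from .cn_calling import (
    CDKN2AThresholds,
    DEFAULT_CODEL_CUTOFF,
    EGFRThresholds,
    arm_average_cn,
)
from .errors import MissingDataError
from .fusion_annotation import FusionCatalog
from .integrated_diagnosis import ExternalFlags, GradingThresholds
from .panel_model import CaseRecord, PanelMap, default_panel_map


def call_case(
    case: CaseRecord,
    panel_map: Optional[PanelMap] = None,
    cutoff: float = DEFAULT_CODEL_CUTOFF,
    egfr_thresholds: EGFRThresholds = EGFRThresholds(),
    cdkn2a_thresholds: CDKN2AThresholds = CDKN2AThresholds(),
    grading_thresholds: GradingThresholds = GradingThresholds(),
    catalog: Optional[FusionCatalog] = None,
    external_flags: Optional[ExternalFlags] = None,
) -> dict:
    """Run all pipeline stages on one case and return the report dict with
    keys ``case_id, codel, egfr, cdkn2a, idh, tp53, atrx_prediction,
    fusions, integrated``.  Stages whose inputs are entirely absent are
    reported as not assessed rather than failing the whole case."""
    panel_map = panel_map or default_panel_map()
    catalog = catalog or fusion_annotation.load_catalog()
    profile = case.cn_profile

    flags = external_flags
    if flags is None:
        flags = ExternalFlags(pediatric=bool(case.pediatric))

    codel = None
    codel_report: dict = {"assessed": False}
    if profile is not None and len(profile):
        try:
            codel = cn_calling.call_codeletion(cn_calling.codel_score(profile, panel_map), cutoff)
            codel_report = {
                "assessed": True,
                "score": round(codel.score, 4),
                "cutoff": cutoff,
                "codeleted": codel.codeleted,
                "per_arm_means": {k: (round(v, 4) if v is not None else None)
                                  for k, v in codel.per_arm_means.items()},
                "n_genes_used": codel.n_genes_used,
            }
        except MissingDataError:
            pass

    egfr = None
    egfr_report: dict = {"assessed": False}
    if profile is not None and len(profile):
        try:
            egfr = cn_calling.egfr_status(profile, panel_map, egfr_thresholds)
            egfr_report = {
                "assessed": True,
                "egfr_cn": round(egfr.egfr_cn, 4),
                "chr7_background_mean": round(egfr.chr7_background_mean, 4),
                "ratio": round(egfr.ratio, 4),
                "call": egfr.call,
            }
        except MissingDataError:
            pass

    cdkn2a = cn_calling.cdkn2a_status(profile, case.variants, cdkn2a_thresholds, panel_map)
    cdkn2a_report = {
        "cn": round(cdkn2a.cn, 4) if cdkn2a.cn is not None else None,
        "call": cdkn2a.call,
        "broad_9p": cdkn2a.broad_9p,
        "coding_variants": [f"{v.protein_change} ({v.variant_class})" for v in cdkn2a.coding_variants],
    }

    idh = variant_interpretation.classify_idh(case.variants)
    idh_report = {
        "status": idh.status,
        "variant": f"{idh.variant.gene} {idh.variant.protein_change}" if idh.variant else None,
        "r132h": idh.r132h,
        "predicted_ihc": variant_interpretation.predict_idh_ihc(idh),
    }
    tp53 = variant_interpretation.classify_tp53(case.variants)
    tp53_report = {
        "mutated": tp53.mutated,
        "n_variants": tp53.n_variants,
        "classes": sorted(tp53.classes.elements()),
        "compound": tp53.compound,
        "predicted_p53_score": variant_interpretation.predict_p53_score(tp53),
    }

    pediatric_or_h3 = bool(flags.pediatric or flags.h3_mutant)
    try:
        atrx = variant_interpretation.predict_atrx(idh, tp53, codel, pediatric_or_h3)
        atrx_report = {"prediction": atrx.prediction, "rationale": atrx.rationale}
    except MissingDataError as exc:
        atrx_report = {"prediction": "indeterminate", "rationale": str(exc)}

    if case.modalities.rna_qc == "fail":
        fusions_report: dict = {"assessed": False, "events": []}
    else:
        events = []
        for event in case.fusions:
            ann = fusion_annotation.annotate_fusion(event, catalog)
            events.append({
                "event_name": event.event_name,
                "gene5": event.gene5,
                "gene3": event.gene3,
                "known_in_cns": ann.known_in_cns,
                "novel_in_cns": ann.novel_in_cns,
                "typical_context": ann.typical_context,
                "therapies": [{"drug": t.drug, "bbb_penetrant": t.bbb_penetrant} for t in ann.therapies],
                "egfrviii": fusion_annotation.is_egfrviii(event),
            })
        fusions_report = {"assessed": True, "events": events}

    chr7_mean = chr10_mean = None
    if profile is not None and len(profile):
        try:
            chr7_mean = arm_average_cn(profile, panel_map.arm_sets["chr7_background"]).mean
        except MissingDataError:
            pass
        if "chr10_set" in panel_map.arm_sets:
            try:
                chr10_mean = arm_average_cn(profile, panel_map.arm_sets["chr10_set"]).mean
            except MissingDataError:
                pass

    try:
        integrated = integrated_diagnosis.integrate(
            idh, tp53, codel, egfr, cdkn2a, chr7_mean, chr10_mean, flags, grading_thresholds
        )
        integrated_report = {
            "label": integrated.label,
            "grade": integrated.grade,
            "evidence": [[c, str(v)] for c, v in integrated.evidence],
            "unassessed": integrated.unassessed,
        }
    except ValueError as exc:
        integrated_report = {"label": None, "error": str(exc)}

    return {
        "case_id": case.case_id,
        "codel": codel_report,
        "egfr": egfr_report,
        "cdkn2a": cdkn2a_report,
        "idh": idh_report,
        "tp53": tp53_report,
        "atrx_prediction": atrx_report,
        "fusions": fusions_report,
        "integrated": integrated_report,
    }


def call_cohort(cases: Sequence[CaseRecord], **kwargs) -> list[dict]:
    """Run :func:`call_case` over a cohort."""
    return [call_case(case, **kwargs) for case in cases]
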