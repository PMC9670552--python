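"""Rule-based interpretation of IDH1/2 and TP53 variants, with predicted IHC
phenotypes and the IDH/TP53-based ATRX-status prediction.

IDH pathogenicity is a configurable hotspot table defaulting to the canonical
IDH1 codon-132 and IDH2 codon-172 missense sets; any other IDH1/2 change is a
variant of unknown significance (VUS), never silently pathogenic.  The p53
IHC score prediction encodes the standard staining biology: missense mutants
stabilize p53 (strong diffuse labeling, score 3), truncating mutants abolish
the epitope (completely negative, score 0), and wildtype tumors show weak
scattered labeling (score 1).  Score 2 (ambiguous staining) is an observed
IHC category only and is never predicted.

ATRX loss is predicted, rather than measured, from the mutual-exclusivity
structure of adult diffuse gliomas: IDH/TP53 double-mutant non-codeleted
astrocytomas almost always carry ATRX loss, while oligodendrogliomas and
adult IDH-wildtype astrocytomas almost never do.  Pediatric or histone
H3-altered tumors fall outside this structure and return indeterminate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cn_calling import CodelResult
from .errors import MissingDataError
from .panel_model import SequenceVariant

#: default hotspot table: gene -> set of pathogenic protein changes
DEFAULT_IDH_PATHOGENIC: Mapping[str, frozenset[str]] = {
    "IDH1": frozenset({"R132H", "R132C", "R132S", "R132G", "R132L", "R132V"}),
    "IDH2": frozenset({"R172K", "R172M", "R172W", "R172G", "R172S", "R172H"}),
}

TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift"})
STABILIZING_CLASSES = frozenset({"missense", "inframe_del"})


@dataclass
class IDHCall:
    status: str  # wildtype | mutant | vus_only
    variant: Optional[SequenceVariant] = None
    r132h: bool = False

    def __post_init__(self) -> None:
        if self.r132h and self.status != "mutant":
            raise ValueError("r132h implies mutant status")

    @property
    def mutant(self) -> bool:
        return self.status == "mutant"


@dataclass
class TP53Call:
    mutated: bool
    n_variants: int
    classes: Counter = field(default_factory=Counter)
    variants: list[SequenceVariant] = field(default_factory=list)

    @property
    def compound(self) -> bool:
        return self.n_variants >= 2


@dataclass
class ATRXPrediction:
    prediction: str  # loss_predicted | preserved_predicted | indeterminate
    rationale: str


def classify_idh(
    variants: Sequence[SequenceVariant],
    pathogenic_table: Mapping[str, frozenset[str]] = DEFAULT_IDH_PATHOGENIC,
) -> IDHCall:
    """Classify the case's IDH status from its variant list.

    Order-independent: the first pathogenic variant in a canonical
    (gene, protein-change) sort is reported.  Cases with IDH1/2 variants
    outside the hotspot table are ``vus_only``.
    """
    idh_variants = sorted(
        (v for v in variants if v.gene in ("IDH1", "IDH2")),
        key=lambda v: (v.gene, v.protein_change),
    )
    pathogenic = [
        v for v in idh_variants if v.protein_change in pathogenic_table.get(v.gene, frozenset())
    ]
    if pathogenic:
        chosen = pathogenic[0]
        r132h = any(v.gene == "IDH1" and v.protein_change == "R132H" for v in pathogenic)
        if r132h:
            chosen = next(v for v in pathogenic if v.gene == "IDH1" and v.protein_change == "R132H")
        return IDHCall(status="mutant", variant=chosen, r132h=r132h)
    if idh_variants:
        return IDHCall(status="vus_only", variant=idh_variants[0])
    return IDHCall(status="wildtype")


def predict_idh_ihc(call: IDHCall) -> str:
    """Predicted IDH1-R132H mutation-specific IHC: positive iff the detected
    pathogenic variant is IDH1 R132H (the stain sees no other variant)."""
    return "positive" if call.r132h else "negative"


def classify_tp53(variants: Sequence[SequenceVariant]) -> TP53Call:
    """Count and classify TP53 variants; ``compound`` when two or more."""
    tp53 = [v for v in variants if v.gene == "TP53"]
    return TP53Call(
        mutated=len(tp53) >= 1,
        n_variants=len(tp53),
        classes=Counter(v.variant_class for v in tp53),
        variants=list(tp53),
    )


def predict_p53_score(call: TP53Call) -> int:
    """Predicted p53 IHC score from the sequencing result: 1 for wildtype,
    3 when any stabilizing variant (missense or in-frame deletion) is present
    — missense dominates compound genotypes — and 0 for purely truncating or
    splice-site genotypes (absent protein).  Score 2 is never predicted."""
    if not call.mutated:
        return 1
    if any(cls in STABILIZING_CLASSES for cls in call.classes):
        return 3
    return 0


def predict_atrx(
    idh: IDHCall,
    tp53: TP53Call,
    codel: Optional[CodelResult],
    pediatric_or_h3: bool = False,
) -> ATRXPrediction:
    """Predict ATRX status from IDH/TP53/codeletion alone.

    * pediatric or H3-altered tumor → indeterminate (outside the adult
      mutual-exclusivity structure; H3 G34 tumors in particular frequently
      carry ATRX mutations despite being IDH-wildtype)
    * IDH-mutant and co-deleted (oligodendroglioma) → preserved
    * IDH-mutant, non-codeleted, TP53-mutant → loss predicted
    * IDH-mutant, non-codeleted, TP53-wildtype → preserved
    * IDH-wildtype adult → preserved

    Requires a co-deletion call for IDH-mutant cases.
    """
    if pediatric_or_h3:
        return ATRXPrediction(
            prediction="indeterminate",
            rationale="pediatric or H3-altered tumor: adult IDH/TP53 mutual-exclusivity "
            "structure does not apply",
        )
    if idh.mutant:
        if codel is None or codel.codeleted is None:
            raise MissingDataError(
                "ATRX prediction for an IDH-mutant case requires a 1p/19q co-deletion call"
            )
        if codel.codeleted:
            return ATRXPrediction(
                prediction="preserved_predicted",
                rationale="IDH-mutant and 1p/19q co-deleted (oligodendroglioma): ATRX "
                "alterations are rare in co-deleted tumors",
            )
        if tp53.mutated:
            return ATRXPrediction(
                prediction="loss_predicted",
                rationale="IDH/TP53 double-mutant non-codeleted astrocytoma: ATRX loss "
                "co-occurs in the large majority of such tumors",
            )
        return ATRXPrediction(
            prediction="preserved_predicted",
            rationale="IDH-mutant without TP53 mutation: no double-mutant signature",
        )
    return ATRXPrediction(
        prediction="preserved_predicted",
        rationale="IDH-wildtype adult diffuse glioma: ATRX alterations are infrequent",
    )
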