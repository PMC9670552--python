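"""Copy-number-derived calls.

Three calls are made from the per-case gene-level copy-number profile:

* **1p/19q co-deletion** — the mean copy number over all panel genes on 1p and
  19q pooled together (gene-weighted: the six 1p genes dominate the two 19q
  genes).  A case is called co-deleted when this score falls strictly below a
  cutoff, by default 1.65.  :func:`calibrate_cutoff` re-derives the cutoff from
  scored cases with FISH reference labels via an ROC sweep over midpoint
  thresholds, maximizing Youden's J (sensitivity + specificity − 1).

* **EGFR amplification vs chromosome-7 gain** — true amplification (often tens
  to hundreds of copies, frequently episomal) is distinguished from broad
  chromosome-7 polysomy by the ratio of the EGFR copy number to the mean of
  the remaining chromosome-7 panel genes.  A high EGFR copy number with a
  ratio near 1 indicates whole-chromosome gain, not amplification.

* **CDKN2A loss** — single-copy loss and homozygous deletion thresholds on the
  linear copy number, with concurrent broad-9p loss flagged when other 9p
  panel genes are configured.

All thresholds are configurable; the defaults are documented heuristics
(linear copy-number scale, diploid = 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import MissingDataError
from .panel_model import CopyNumberProfile, PanelMap, SequenceVariant, default_panel_map

#: default decision cutoff on the pooled 1p/19q mean copy number
DEFAULT_CODEL_CUTOFF = 1.65


# ---------------------------------------------------------------------------
# arm averages and codeletion score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmAverage:
    """Mean copy number over a gene set, with missing-gene accounting."""

    mean: float
    n_used: int
    n_missing: int

    def __float__(self) -> float:
        return self.mean


def arm_average_cn(profile: CopyNumberProfile, gene_set: Iterable[str]) -> ArmAverage:
    """Arithmetic mean of the copy numbers of the genes in ``gene_set`` that
    are present in ``profile``.

    Raises :class:`MissingDataError` when none of the genes is present.
    """
    gene_set = tuple(gene_set)
    values = [profile.entries[g] for g in gene_set if g in profile.entries]
    if not values:
        raise MissingDataError(
            f"case {profile.case_id}: no genes of {sorted(gene_set)} present in profile"
        )
    return ArmAverage(
        mean=float(np.mean(values)),
        n_used=len(values),
        n_missing=len(gene_set) - len(values),
    )


@dataclass
class CodelResult:
    """1p/19q co-deletion score and (once called) the binary call."""

    score: float
    n_genes_used: int
    per_arm_means: dict[str, Optional[float]]
    cutoff: Optional[float] = None
    codeleted: Optional[bool] = None
    pooling: str = "gene"


def codel_score(
    profile: CopyNumberProfile,
    panel_map: Optional[PanelMap] = None,
    pooling: str = "gene",
) -> CodelResult:
    """Compute the combined 1p/19q copy-number score (call deferred).

    ``pooling='gene'`` (default) averages all 1p and 19q gene values pooled
    together; ``pooling='arm'`` averages the two arm means instead.  Both arms
    must contribute at least one gene — co-deletion cannot be claimed from a
    single arm.
    """
    if panel_map is None:
        panel_map = default_panel_map()
    if pooling not in {"gene", "arm"}:
        raise ValueError(f"unknown pooling {pooling!r}")

    per_arm: dict[str, Optional[float]] = {}
    for label, set_name in (("1p", "arm_1p"), ("1q", "arm_1q"), ("19p", "arm_19p"), ("19q", "arm_19q")):
        try:
            per_arm[label] = arm_average_cn(profile, panel_map.arm_sets[set_name]).mean
        except MissingDataError:
            per_arm[label] = None

    for arm in ("1p", "19q"):
        if per_arm[arm] is None:
            raise MissingDataError(
                f"case {profile.case_id}: chromosome arm {arm} entirely missing; "
                "cannot compute the co-deletion score"
            )

    genes_1p = [g for g in panel_map.arm_sets["arm_1p"] if g in profile.entries]
    genes_19q = [g for g in panel_map.arm_sets["arm_19q"] if g in profile.entries]
    if pooling == "gene":
        pooled = [profile.entries[g] for g in genes_1p + genes_19q]
        score = float(np.mean(pooled))
    else:
        score = float((per_arm["1p"] + per_arm["19q"]) / 2.0)

    return CodelResult(
        score=score,
        n_genes_used=len(genes_1p) + len(genes_19q),
        per_arm_means=per_arm,
        pooling=pooling,
    )


def call_codeletion(result: CodelResult, cutoff: float = DEFAULT_CODEL_CUTOFF) -> CodelResult:
    """Fill in the binary co-deletion call: codeleted iff ``score < cutoff``
    (strict inequality; a score exactly at the cutoff is not co-deleted)."""
    return replace(result, cutoff=cutoff, codeleted=bool(result.score < cutoff))


# ---------------------------------------------------------------------------
# ROC cutoff calibration
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """ROC sweep for a "low score = positive" classifier.

    ``points`` are ordered by increasing threshold; each entry is
    (threshold, sensitivity, specificity).  Thresholds are midpoints between
    adjacent distinct scores plus the two infinite endpoints.
    """

    points: list[tuple[float, float, float]]
    chosen_cutoff: float
    chosen_sens: float
    chosen_spec: float

    @property
    def chosen_j(self) -> float:
        return self.chosen_sens + self.chosen_spec - 1.0


def _as_score_label_arrays(
    scores: Sequence[float] | Sequence[tuple[float, object]],
    labels: Optional[Sequence] = None,
    positive=True,
) -> tuple[np.ndarray, np.ndarray]:
    def _is_positive(lab) -> bool:
        if lab == positive:
            return True
        if isinstance(lab, str):
            return lab.lower() in {"codeleted", "positive", "true", "1"}
        return bool(lab)

    if labels is None:
        pairs = list(scores)
        score_arr = np.asarray([s for s, _ in pairs], dtype=float)
        label_arr = np.asarray([_is_positive(lab) for _, lab in pairs], dtype=bool)
    else:
        score_arr = np.asarray(scores, dtype=float)
        label_arr = np.asarray([_is_positive(lab) for lab in labels], dtype=bool)
    return score_arr, label_arr


def calibrate_cutoff(
    scores: Sequence[float] | Sequence[tuple[float, object]],
    labels: Optional[Sequence] = None,
    positive=True,
) -> ROCCurve:
    """Choose the co-deletion cutoff by an exhaustive midpoint ROC sweep.

    ``scores`` may be (score, label) pairs or a score array with a separate
    ``labels`` sequence; the positive class (FISH co-deleted) has *low*
    scores, and a case is classified positive when score < threshold.

    Every midpoint between adjacent distinct scores is evaluated; the chosen
    cutoff maximizes Youden's J = sensitivity + specificity − 1, ties broken
    toward the larger threshold.  Raises :class:`MissingDataError` when only
    one class is represented.
    """
    score_arr, label_arr = _as_score_label_arrays(scores, labels, positive)
    n_pos = int(label_arr.sum())
    n_neg = int((~label_arr).sum())
    if n_pos == 0 or n_neg == 0:
        raise MissingDataError("cutoff calibration requires both classes to be represented")

    distinct = np.unique(score_arr)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], midpoints, [np.inf]))

    pos_scores = score_arr[label_arr]
    neg_scores = score_arr[~label_arr]
    points = []
    best: Optional[tuple[float, float, float]] = None
    for t in thresholds:
        sens = float(np.mean(pos_scores < t))
        spec = float(np.mean(neg_scores >= t))
        points.append((float(t), sens, spec))
        if np.isfinite(t):
            j = sens + spec - 1.0
            # ties in J broken toward the larger threshold
            if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
                best = (j, float(t), sens, spec)
    assert best is not None
    _, cutoff, sens, spec = best
    return ROCCurve(points=points, chosen_cutoff=cutoff, chosen_sens=sens, chosen_spec=spec)


class CodeletionCaller(BaseEstimator, ClassifierMixin):
    """Threshold classifier for 1p/19q co-deletion from pooled copy-number
    scores, with an ROC-calibrated cutoff.

    Follows the scikit-learn estimator contract: ``fit(X, y)`` on per-case
    scores (shape ``(n,)`` or ``(n, 1)``) and boolean/binary reference labels
    (FISH co-deletion) calibrates ``cutoff_`` via :func:`calibrate_cutoff`;
    ``predict`` calls co-deletion where score < ``cutoff_``.  Passing a fixed
    ``cutoff`` skips calibration.

    Attributes
    ----------
    cutoff_ : float
        Decision threshold after fitting.
    roc_ : ROCCurve or None
        The calibration sweep (None when a fixed cutoff was supplied).
    """

    def __init__(self, cutoff: Optional[float] = None):
        self.cutoff = cutoff

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("X must be a 1-d score array or a single-column matrix")
        return arr

    def fit(self, X, y=None):
        scores = self._scores(X)
        if self.cutoff is not None:
            self.cutoff_ = float(self.cutoff)
            self.roc_ = None
        else:
            if y is None:
                raise ValueError("reference labels are required to calibrate the cutoff")
            self.roc_ = calibrate_cutoff(scores, labels=y)
            self.cutoff_ = self.roc_.chosen_cutoff
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("CodeletionCaller is not fitted")
        return self._scores(X) < self.cutoff_

    def decision_function(self, X) -> np.ndarray:
        """Signed margin: positive values favor the co-deleted class."""
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("CodeletionCaller is not fitted")
        return self.cutoff_ - self._scores(X)


# ---------------------------------------------------------------------------
# EGFR amplification vs chromosome-7 gain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EGFRThresholds:
    """Decision thresholds for the EGFR caller.

    Amplification requires both a high absolute EGFR copy number and a high
    ratio to the chromosome-7 background (mirroring the FISH criteria: mean
    EGFR signals/nucleus > 4 and EGFR/CEP7 ratio > 2); chromosome-7 gain is
    called on an elevated background mean.  Exact definitional thresholds for
    gain vs amplification are not settled in the field; these defaults are
    documented heuristics and fully configurable.
    """

    amplified_cn: float = 4.0
    amplified_ratio: float = 2.0
    chr7_gain_background: float = 2.5


@dataclass
class EGFRStatus:
    egfr_cn: float
    chr7_background_mean: float
    ratio: float
    call: str  # no_alteration | chr7_gain | amplified


def egfr_status(
    profile: CopyNumberProfile,
    panel_map: Optional[PanelMap] = None,
    thresholds: EGFRThresholds = EGFRThresholds(),
) -> EGFRStatus:
    """Classify EGFR as amplified, chromosome-7 gain, or no alteration.

    The ratio is EGFR copy number over the mean of the remaining chromosome-7
    panel genes; a raised EGFR with ratio near 1 reflects broad chromosome-7
    gain rather than focal amplification.
    """
    if panel_map is None:
        panel_map = default_panel_map()
    egfr_cn = profile.get("EGFR")
    if egfr_cn is None:
        raise MissingDataError(f"case {profile.case_id}: EGFR copy number absent")
    background = arm_average_cn(profile, panel_map.arm_sets["chr7_background"])
    if background.mean <= 0:
        raise MissingDataError(
            f"case {profile.case_id}: chromosome-7 background mean is zero; ratio undefined"
        )
    ratio = egfr_cn / background.mean
    if egfr_cn >= thresholds.amplified_cn and ratio >= thresholds.amplified_ratio:
        call = "amplified"
    elif background.mean >= thresholds.chr7_gain_background:
        call = "chr7_gain"
    else:
        call = "no_alteration"
    return EGFRStatus(
        egfr_cn=float(egfr_cn),
        chr7_background_mean=background.mean,
        ratio=float(ratio),
        call=call,
    )


# ---------------------------------------------------------------------------
# CDKN2A
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CDKN2AThresholds:
    """Linear-copy-number thresholds for single-copy loss and homozygous
    deletion; chosen so that typical class means of intact tumors (~1.9) and
    deeply deleted tumors (~1.1 with a focal-deletion tail) fall on opposite
    sides of the loss threshold."""

    loss: float = 1.3
    homozygous: float = 0.7


@dataclass
class CDKN2AStatus:
    cn: Optional[float]
    call: str  # intact | loss | homozygous_deletion | not_assessed
    broad_9p: bool
    coding_variants: list[SequenceVariant]


def cdkn2a_status(
    profile: Optional[CopyNumberProfile],
    variants: Sequence[SequenceVariant] = (),
    thresholds: CDKN2AThresholds = CDKN2AThresholds(),
    panel_map: Optional[PanelMap] = None,
) -> CDKN2AStatus:
    """Call CDKN2A copy-number status; coding variants are carried through.

    ``broad_9p`` is set when other configured 9p panel genes are concurrently
    below the loss threshold (a putative arm-level event rather than a focal
    deletion).  Absent copy number yields ``not_assessed``, never an error.
    """
    if panel_map is None:
        panel_map = default_panel_map()
    coding = [v for v in variants if v.gene == "CDKN2A"]
    cn = profile.get("CDKN2A") if profile is not None else None
    if cn is None:
        return CDKN2AStatus(cn=None, call="not_assessed", broad_9p=False, coding_variants=coding)
    if cn <= thresholds.homozygous:
        call = "homozygous_deletion"
    elif cn <= thresholds.loss:
        call = "loss"
    else:
        call = "intact"

    broad_9p = False
    other_9p = tuple(g for g in panel_map.arm_sets.get("chr9p_set", ()) if g != "CDKN2A")
    if call != "intact" and other_9p:
        present = [profile.entries[g] for g in other_9p if g in profile.entries]
        broad_9p = bool(present) and all(v <= thresholds.loss for v in present)
    return CDKN2AStatus(cn=float(cn), call=call, broad_9p=broad_9p, coding_variants=coding)
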