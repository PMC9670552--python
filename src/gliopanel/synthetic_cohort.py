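"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a single-institution CNS tumor cohort
(233 cases) as observed through a combined DNA/RNA targeted panel, so every
pipeline stage is testable without any clinical download:

* class mix defaulting to the study cohort: 14 oligodendroglioma, 29
  IDH-mutant astrocytoma, 112 IDH-wildtype astrocytoma, 11 pilocytic
  astrocytoma, 67 other;
* per-class chromosome-arm copy-number distributions with a two-level noise
  model (one deviation shared within each case, scaled per arm, plus
  independent per-gene jitter) calibrated so the across-case standard
  deviation of the per-case arm mean equals the configured value;
* mutation co-occurrence (IDH in all oligodendrogliomas and IDH-mutant
  astrocytomas with ~90% R132H; TP53 in 28/29 IDH-mutant astrocytomas and
  2/14 oligodendrogliomas);
* p53 IHC scores emitted through a confusion matrix conditional on true TP53
  status; IDH R132H IHC positive exactly for R132H carriers; ATRX IHC driven
  by the double-mutant structure;
* EGFR amplification (log-uniform 10-100 copies) vs chromosome-7 gain
  scenarios among IDH-wildtype cases, with matching FISH emissions;
* fusion events (EGFRvIII in IDH-wildtype GBM, BRAF-KIAA1549 in pilocytic
  astrocytoma) and an RNA-QC failure rate of 21/233.

Ground truth is stored in a separate table (:func:`truth_table`); the
observable :class:`~gliopanel.panel_model.CaseRecord` objects carry no truth
fields, so analysis code cannot leak it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_model import (
    CaseRecord,
    CopyNumberProfile,
    FishEGFR,
    FusionEvent,
    ModalityResults,
    PanelMap,
    SequenceVariant,
    default_panel_map,
)

#: alternative pathogenic IDH variants drawn when not R132H
ALT_IDH_VARIANTS = (
    ("IDH1", "R132S"),
    ("IDH1", "R132G"),
    ("IDH1", "R132C"),
    ("IDH2", "R172K"),
)

#: TP53 variant class mix (missense-dominant, with truncating and splice
#: minorities) and representative protein-change spellings per class
TP53_CLASS_PROBS = (
    ("missense", 0.68),
    ("frameshift", 0.14),
    ("splice_site", 0.08),
    ("nonsense", 0.06),
    ("inframe_del", 0.04),
)
TP53_CHANGES = {
    "missense": ("R273H", "R175H", "R248Q", "G245S", "Y220C"),
    "frameshift": ("P72fs", "K132fs"),
    "splice_site": ("c.559+1G>A", "c.375+1G>T"),
    "nonsense": ("R196*", "R342*"),
    "inframe_del": ("N131del",),
}


@dataclass
class ClassParams:
    """Generator parameters for one diagnosis class."""

    n: int
    #: per gene-group (mean, sd) of the per-case group mean copy number
    arm_cn: dict[str, tuple[float, float]]
    cdkn2a: tuple[float, float]
    codeleted: bool = False
    idh_mutant_prob: float = 0.0
    r132h_fraction: float = 0.9
    tp53_prob: float = 0.0
    egfr_amp_prob: float = 0.0
    chr7_gain_prob: float = 0.0
    egfrviii_prob: float = 0.0
    braf_kiaa_prob: float = 0.0
    age: tuple[float, float] = (50.0, 15.0)
    male_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("class size must be non-negative")
        for name, (_, sd) in self.arm_cn.items():
            if sd < 0:
                raise ConfigError(f"negative sd for group {name!r}")
        if self.cdkn2a[1] < 0:
            raise ConfigError("negative sd for CDKN2A")


def _default_classes() -> dict[str, ClassParams]:
    base_other = {"arm_1p": (2.0, 0.2), "arm_1q": (2.0, 0.2), "arm_19p": (2.0, 0.2),
                  "arm_19q": (2.0, 0.2), "chr7": (2.0, 0.2), "chr10": (2.0, 0.2)}
    return {
        "oligodendroglioma": ClassParams(
            n=14,
            arm_cn={"arm_1p": (1.15, 0.14), "arm_1q": (2.0, 0.2), "arm_19p": (2.22, 0.13),
                    "arm_19q": (1.23, 0.18), "chr7": (2.0, 0.2), "chr10": (2.0, 0.2)},
            cdkn2a=(1.94, 0.41),
            codeleted=True,
            idh_mutant_prob=1.0,
            r132h_fraction=0.9,
            tp53_prob=2 / 14,
            age=(48.5, 13.5),
            male_prob=10 / 14,
        ),
        "astrocytoma_idh_mutant": ClassParams(
            n=29,
            arm_cn={"arm_1p": (2.04, 0.37), "arm_1q": (2.0, 0.2), "arm_19p": (2.22, 0.29),
                    "arm_19q": (1.96, 0.29), "chr7": (2.0, 0.2), "chr10": (2.0, 0.2)},
            cdkn2a=(1.73, 0.68),
            idh_mutant_prob=1.0,
            r132h_fraction=0.9,
            tp53_prob=28 / 29,
            age=(38.2, 12.1),
            male_prob=20 / 29,
        ),
        "astrocytoma_idh_wildtype": ClassParams(
            n=112,
            arm_cn={"arm_1p": (1.97, 0.16), "arm_1q": (2.0, 0.2), "arm_19p": (2.44, 0.39),
                    "arm_19q": (2.24, 0.38), "chr7": (2.0, 0.2), "chr10": (2.0, 0.2)},
            cdkn2a=(1.09, 0.75),
            tp53_prob=38 / 112,
            egfr_amp_prob=35 / 112,
            chr7_gain_prob=0.35,
            egfrviii_prob=19 / 112,
            age=(61.9, 13.0),
            male_prob=51 / 112,
        ),
        "pilocytic_astrocytoma": ClassParams(
            n=11,
            arm_cn=dict(base_other),
            cdkn2a=(2.0, 0.3),
            braf_kiaa_prob=5 / 11,
            age=(10.0, 5.0),
            male_prob=0.5,
        ),
        "other": ClassParams(
            n=67,
            arm_cn=dict(base_other),
            cdkn2a=(2.0, 0.3),
            tp53_prob=0.05,
            age=(45.0, 20.0),
            male_prob=0.5,
        ),
    }


@dataclass
class CohortConfig:
    """Full generator configuration; defaults emulate the study cohort."""

    classes: dict[str, ClassParams] = field(default_factory=_default_classes)
    #: fraction of each group's variance assigned to the shared per-case
    #: deviation (the rest becomes per-gene jitter)
    case_variance_fraction: float = 0.8
    rna_fail_prob: float = 21 / 233
    #: P(observed p53 score | true TP53 status), scores 0..3; rows from the
    #: observed confusion counts (mutated: 2/22/13/33 of 70; wildtype:
    #: 4/103/17/0 of 124)
    p53_emission: dict[bool, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            True: (2 / 70, 22 / 70, 13 / 70, 33 / 70),
            False: (4 / 124, 103 / 124, 17 / 124, 0.0),
        }
    )
    #: probability each IHC stain was performed (191/233 IDH, 194/233 p53,
    #: 135/233 ATRX interpretable-request rate)
    ihc_idh_done_prob: float = 191 / 233
    ihc_p53_done_prob: float = 194 / 233
    ihc_atrx_done_prob: float = 0.6
    fish_codel_done_prob: float = 0.8
    fish_egfr_done_prob: float = 151 / 233

    def __post_init__(self) -> None:
        if not 0.0 <= self.case_variance_fraction <= 1.0:
            raise ConfigError("case_variance_fraction must lie in [0, 1]")
        if not 0.0 <= self.rna_fail_prob <= 1.0:
            raise ConfigError("rna_fail_prob must lie in [0, 1]")
        for row in self.p53_emission.values():
            if abs(sum(row) - 1.0) > 1e-9:
                raise ConfigError("p53 emission rows must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated case, kept apart from observables."""

    case_id: str
    true_class: str
    codeleted: bool
    egfr_state: str  # no_alteration | chr7_gain | amplified
    cdkn2a_state: str  # intact | loss | homozygous_deletion
    idh_mutant: bool
    idh_variant: Optional[str]
    tp53_mutated: bool
    atrx_mutated: bool


@dataclass
class SimulatedCohort:
    cases: list[CaseRecord]
    truth: list[TruthRecord]
    seed: int


def _sample_group_cn(
    rng: np.random.Generator,
    genes: Sequence[str],
    mean: float,
    sd: float,
    case_fraction: float,
    case_z: float,
) -> dict[str, float]:
    """Two-level noise: a deviation shared within the case (one standard
    normal ``case_z`` per case, scaled per group — modeling case-level
    effects such as tumor purity and ploidy) plus independent per-gene
    jitter.  Variances split so the per-case group mean has across-case
    sd == ``sd`` (sd_case² = f·sd², sd_gene² = (1−f)·n·sd²)."""
    n = len(genes)
    sd_case = np.sqrt(case_fraction) * sd
    sd_gene = np.sqrt((1.0 - case_fraction) * n) * sd
    values = mean + sd_case * case_z + rng.normal(0.0, sd_gene, size=n)
    return {g: float(max(v, 0.0)) for g, v in zip(genes, values)}


def _sample_tp53_variants(rng: np.random.Generator) -> list[SequenceVariant]:
    classes = [c for c, _ in TP53_CLASS_PROBS]
    probs = np.array([p for _, p in TP53_CLASS_PROBS])
    n_vars = 2 if rng.random() < 0.07 else 1  # compound heterozygous minority
    out = []
    for _ in range(n_vars):
        cls = classes[rng.choice(len(classes), p=probs)]
        change = TP53_CHANGES[cls][rng.integers(len(TP53_CHANGES[cls]))]
        out.append(SequenceVariant(gene="TP53", protein_change=change, variant_class=cls, origin="somatic"))
    return out


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    seed: int = 0,
    panel_map: Optional[PanelMap] = None,
) -> SimulatedCohort:
    """Generate a cohort of :class:`CaseRecord` observables plus a separate
    ground-truth table.  Identical (config, seed) pairs yield identical
    cohorts."""
    config = config or CohortConfig()
    panel_map = panel_map or default_panel_map()
    rng = np.random.default_rng(seed)

    group_genes = {
        "arm_1p": panel_map.arm_sets["arm_1p"],
        "arm_1q": panel_map.arm_sets["arm_1q"],
        "arm_19p": panel_map.arm_sets["arm_19p"],
        "arm_19q": panel_map.arm_sets["arm_19q"],
        "chr10": panel_map.arm_sets["chr10_set"],
    }
    chr7_bg = panel_map.arm_sets["chr7_background"]

    cases: list[CaseRecord] = []
    truth: list[TruthRecord] = []
    counter = 0
    for class_name, params in config.classes.items():
        for _ in range(params.n):
            counter += 1
            case_id = f"SYN-{counter:04d}"
            case = _simulate_case(rng, case_id, class_name, params, config, group_genes, chr7_bg)
            cases.append(case[0])
            truth.append(case[1])
    return SimulatedCohort(cases=cases, truth=truth, seed=seed)


def _simulate_case(
    rng: np.random.Generator,
    case_id: str,
    class_name: str,
    params: ClassParams,
    config: CohortConfig,
    group_genes: dict[str, Sequence[str]],
    chr7_bg: Sequence[str],
) -> tuple[CaseRecord, TruthRecord]:
    f = config.case_variance_fraction
    case_z = float(rng.normal())
    entries: dict[str, float] = {}
    for group, genes in group_genes.items():
        mean, sd = params.arm_cn[group]
        entries.update(_sample_group_cn(rng, genes, mean, sd, f, case_z))

    # chromosome 7 / EGFR scenario (IDH-wildtype classes only by default)
    u = rng.random()
    if u < params.egfr_amp_prob:
        egfr_state = "amplified"
    elif u < params.egfr_amp_prob + params.chr7_gain_prob:
        egfr_state = "chr7_gain"
    else:
        egfr_state = "no_alteration"

    chr7_mean, chr7_sd = params.arm_cn["chr7"]
    if egfr_state == "chr7_gain":
        chr7_mean, chr7_sd = 3.0, 0.3
    entries.update(_sample_group_cn(rng, chr7_bg, chr7_mean, chr7_sd, f, case_z))
    bg_mean = float(np.mean([entries[g] for g in chr7_bg]))
    if egfr_state == "amplified":
        entries["EGFR"] = float(np.exp(rng.uniform(np.log(10.0), np.log(100.0))))
    elif egfr_state == "chr7_gain":
        entries["EGFR"] = float(max(bg_mean * rng.uniform(1.0, 1.3), 0.0))
    else:
        entries["EGFR"] = float(max(rng.normal(chr7_mean, chr7_sd), 0.0))
    if egfr_state == "chr7_gain":
        # the +7/-10 signature: concurrent chromosome-10 loss
        entries.update(_sample_group_cn(rng, group_genes["chr10"], 1.3, 0.2, f, case_z))

    # CDKN2A: latent true value plus small measurement noise
    latent_cdkn2a = max(float(rng.normal(*params.cdkn2a)), 0.0)
    entries["CDKN2A"] = max(latent_cdkn2a + float(rng.normal(0.0, 0.1)), 0.0)
    entries["JAK2"] = max(float(rng.normal(2.0, 0.2)), 0.0)
    if latent_cdkn2a <= 0.7:
        cdkn2a_state = "homozygous_deletion"
    elif latent_cdkn2a <= 1.3:
        cdkn2a_state = "loss"
    else:
        cdkn2a_state = "intact"

    # variants
    variants: list[SequenceVariant] = []
    idh_mutant = rng.random() < params.idh_mutant_prob
    idh_variant = None
    if idh_mutant:
        if rng.random() < params.r132h_fraction:
            gene, change = "IDH1", "R132H"
        else:
            gene, change = ALT_IDH_VARIANTS[rng.integers(len(ALT_IDH_VARIANTS))]
        idh_variant = f"{gene} {change}"
        variants.append(SequenceVariant(gene=gene, protein_change=change, variant_class="missense", origin="somatic"))
    tp53_mutated = rng.random() < params.tp53_prob
    if tp53_mutated:
        variants.extend(_sample_tp53_variants(rng))
    atrx_mutated = bool(idh_mutant and tp53_mutated and not params.codeleted)

    # fusions
    fusions: list[FusionEvent] = []
    if rng.random() < params.egfrviii_prob:
        fusions.append(FusionEvent(gene5="EGFR", gene3="EGFR", event_name="EGFRvIII",
                                   breakpoint_note="deletion of exons 2-7"))
    if rng.random() < params.braf_kiaa_prob:
        fusions.append(FusionEvent(gene5="KIAA1549", gene3="BRAF", event_name="BRAF-KIAA1549"))
    rna_fail = rng.random() < config.rna_fail_prob
    if rna_fail:
        fusions = []

    # modality emissions
    if rng.random() < config.ihc_idh_done_prob:
        r132h_true = idh_variant == "IDH1 R132H"
        ihc_idh = "positive" if r132h_true else "negative"
    else:
        ihc_idh = "not_done"
    if rng.random() < config.ihc_p53_done_prob:
        probs = config.p53_emission[tp53_mutated]
        ihc_p53 = str(int(rng.choice(4, p=np.asarray(probs) / np.sum(probs))))
    else:
        ihc_p53 = "not_done"
    if rng.random() < config.ihc_atrx_done_prob:
        if rng.random() < 0.1:
            ihc_atrx = "inconclusive"
        elif atrx_mutated:
            ihc_atrx = "lost" if rng.random() < 0.55 else "preserved"
        else:
            ihc_atrx = "preserved"
    else:
        ihc_atrx = "not_done"
    if rng.random() < config.fish_codel_done_prob:
        fish_codel = "codeleted" if params.codeleted else "not_codeleted"
    else:
        fish_codel = "not_done"
    fish_egfr = None
    if rng.random() < config.fish_egfr_done_prob:
        if egfr_state == "amplified":
            signals, ratio = float(rng.uniform(8.0, 40.0)), float(rng.uniform(3.0, 10.0))
        elif egfr_state == "chr7_gain":
            if rng.random() < 0.1:
                # low-level events FISH still calls amplified (signals just
                # above 4, ratio just above 2)
                signals, ratio = float(rng.uniform(4.4, 6.7)), float(rng.uniform(2.1, 2.9))
            else:
                signals, ratio = float(rng.uniform(2.6, 4.0)), float(rng.uniform(0.9, 1.4))
        else:
            signals, ratio = float(rng.uniform(1.7, 2.3)), float(rng.uniform(0.9, 1.1))
        fish_egfr = FishEGFR(
            mean_egfr_signals=signals,
            egfr_cep7_ratio=ratio,
            amplified=signals > FishEGFR.SIGNAL_THRESHOLD and ratio > FishEGFR.RATIO_THRESHOLD,
        )

    age = float(np.clip(rng.normal(*params.age), 0.0, 95.0))
    sex = "M" if rng.random() < params.male_prob else "F"

    record = CaseRecord(
        case_id=case_id,
        age_years=round(age, 1),
        sex=sex,
        cn_profile=CopyNumberProfile(case_id=case_id, entries=entries),
        variants=variants,
        fusions=fusions,
        modalities=ModalityResults(
            ihc_idh1_r132h=ihc_idh,
            ihc_p53_score=ihc_p53,
            ihc_atrx=ihc_atrx,
            fish_codel=fish_codel,
            fish_egfr=fish_egfr,
            rna_qc="fail" if rna_fail else "pass",
        ),
    )
    truth = TruthRecord(
        case_id=case_id,
        true_class=class_name,
        codeleted=params.codeleted,
        egfr_state=egfr_state,
        cdkn2a_state=cdkn2a_state,
        idh_mutant=idh_mutant,
        idh_variant=idh_variant,
        tp53_mutated=tp53_mutated,
        atrx_mutated=atrx_mutated,
    )
    return record, truth


def truth_table(cohort: SimulatedCohort) -> pd.DataFrame:
    """Ground-truth table (one row per case), suitable as the reference side
    of concordance statistics.  Raises on inputs without attached truth."""
    if not isinstance(cohort, SimulatedCohort):
        raise TypeError("truth_table requires a SimulatedCohort (non-synthetic cases carry no truth)")
    rows = [vars(t).copy() for t in cohort.truth]
    return pd.DataFrame(rows, columns=[
        "case_id", "true_class", "codeleted", "egfr_state", "cdkn2a_state",
        "idh_mutant", "idh_variant", "tp53_mutated", "atrx_mutated",
    ])


# ---------------------------------------------------------------------------
# TSV export (the same four tables read_cohort consumes, plus truth.tsv)
# ---------------------------------------------------------------------------


def write_cohort_dir(cohort: SimulatedCohort, dir_path: str | Path, panel_map: Optional[PanelMap] = None) -> None:
    """Write cn.tsv / variants.tsv / fusions.tsv / modalities.tsv (readable by
    :func:`gliopanel.panel_model.read_cohort`) plus truth.tsv."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    panel_map = panel_map or default_panel_map()

    cn_rows, var_rows, fus_rows, mod_rows = [], [], [], []
    for case in cohort.cases:
        for gene, cn in case.cn_profile.entries.items():
            locus = panel_map.locus(gene)
            cn_rows.append((case.case_id, gene, locus.chromosome, locus.arm, f"{cn:.4f}"))
        for v in case.variants:
            var_rows.append((case.case_id, v.gene, v.protein_change, v.variant_class, v.origin))
        for fu in case.fusions:
            fus_rows.append((case.case_id, fu.gene5, fu.gene3, fu.event_name, fu.breakpoint_note or ""))
        m = case.modalities
        mod_rows.append((
            case.case_id, m.ihc_idh1_r132h, m.ihc_p53_score, m.ihc_atrx, m.fish_codel,
            f"{m.fish_egfr.mean_egfr_signals:.2f}" if m.fish_egfr else "",
            f"{m.fish_egfr.egfr_cep7_ratio:.2f}" if m.fish_egfr else "",
            m.rna_qc, f"{case.age_years:.1f}", case.sex,
        ))

    pd.DataFrame(cn_rows, columns=["case_id", "gene", "chromosome", "arm", "copy_number"]).to_csv(
        dir_path / "cn.tsv", sep="\t", index=False)
    pd.DataFrame(var_rows, columns=["case_id", "gene", "protein_change", "variant_class", "origin"]).to_csv(
        dir_path / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(fus_rows, columns=["case_id", "gene5", "gene3", "event_name", "breakpoint_note"]).to_csv(
        dir_path / "fusions.tsv", sep="\t", index=False)
    pd.DataFrame(mod_rows, columns=[
        "case_id", "ihc_idh1_r132h", "ihc_p53_score", "ihc_atrx", "fish_codel",
        "fish_egfr_mean", "fish_egfr_cep7_ratio", "rna_qc", "age_years", "sex",
    ]).to_csv(dir_path / "modalities.tsv", sep="\t", index=False)
    truth_table(cohort).to_csv(dir_path / "truth.tsv", sep="\t", index=False)
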