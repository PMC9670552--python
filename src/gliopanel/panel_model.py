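"""Domain types, panel configuration, and cohort I/O.

The pipeline consumes per-case tables exported from a targeted DNA/RNA
sequencing panel: gene-level copy-number estimates (linear scale, diploid =
2.0), small-variant calls, RNA fusion events, and orthogonal-modality results
(IHC, FISH).  Four UTF-8 TSV tables joined on ``case_id`` are the canonical
interchange format; see :func:`read_cohort`.

A :class:`PanelMap` assigns each panel gene to a chromosome arm and names the
gene groups the copy-number callers average over (1p, 1q, 19p, 19q, the
chromosome-7 background used for the EGFR ratio, and a chromosome-10 set for
the +7/−10 molecular-glioblastoma criterion).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])
VALID_ARMS = frozenset({"p", "q"})

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "inframe_del", "other"}
)
VARIANT_ORIGINS = frozenset({"somatic", "germline", "unknown"})

#: arm groups every panel map must define (chr10_set may be reconfigured but
#: defaults ship non-empty; chr9p_set is an optional extra for broad-9p calls)
REQUIRED_ARM_SETS = (
    "arm_1p",
    "arm_1q",
    "arm_19p",
    "arm_19q",
    "chr7_background",
    "chr10_set",
)

#: age below which a case is handled as pediatric
PEDIATRIC_AGE_CUTOFF = 21.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    """A panel gene with its chromosome-arm assignment."""

    gene: str
    chromosome: str
    arm: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ConfigError("gene symbol must be non-empty")
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ParseError(f"unknown chromosome token {self.chromosome!r} for gene {self.gene}")
        if self.arm not in VALID_ARMS:
            raise ParseError(f"unknown arm token {self.arm!r} for gene {self.gene}")


@dataclass
class PanelMap:
    """Gene→locus annotation plus the named arm/background gene groups."""

    loci: list[GeneLocus]
    arm_sets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        symbols = [locus.gene for locus in self.loci]
        if len(symbols) != len(set(symbols)):
            raise ConfigError("duplicate gene symbols in panel map")
        self._by_gene = {locus.gene: locus for locus in self.loci}
        for name in REQUIRED_ARM_SETS:
            if name not in self.arm_sets:
                raise ConfigError(f"panel map missing required arm group {name!r}")
        for name, genes in self.arm_sets.items():
            if len(genes) == 0:
                raise ConfigError(f"arm group {name!r} is empty")
            for gene in genes:
                if gene not in self._by_gene:
                    raise ConfigError(f"arm group {name!r} names unknown gene {gene!r}")

    def locus(self, gene: str) -> GeneLocus:
        try:
            return self._by_gene[gene]
        except KeyError:
            raise ConfigError(f"gene {gene!r} not in panel map") from None

    def genes(self) -> tuple[str, ...]:
        return tuple(locus.gene for locus in self.loci)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene


@dataclass
class CopyNumberProfile:
    """Per-case gene→copy-number map (linear scale; diploid = 2.0)."""

    case_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        for gene, cn in self.entries.items():
            cn = float(cn)
            if not cn >= 0.0:
                raise ValueError(f"copy number for {gene} in case {self.case_id} is negative or NaN: {cn}")
            self.entries[gene] = cn

    def get(self, gene: str) -> Optional[float]:
        return self.entries.get(gene)

    def __len__(self) -> int:
        return len(self.entries)


_PROTEIN_MISSENSE = re.compile(r"^[A-Z]\d+[A-Z]$")
_PROTEIN_NONSENSE = re.compile(r"^[A-Z]\d+(\*|X)$")


def _protein_change_class(protein_change: str) -> Optional[str]:
    """Infer the variant class from protein-level notation when unambiguous.

    Returns None when the notation is not parseable (e.g. intronic / cDNA
    descriptions for splice variants), in which case no consistency check
    applies.
    """
    pc = protein_change.strip()
    if not pc:
        return None
    if _PROTEIN_NONSENSE.match(pc):
        return "nonsense"
    if "fs" in pc:
        return "frameshift"
    if "del" in pc.lower():
        return "inframe_del"
    if _PROTEIN_MISSENSE.match(pc):
        return "missense"
    return None


@dataclass(frozen=True)
class SequenceVariant:
    """A small variant call (gene + protein-level change + class)."""

    gene: str
    protein_change: str
    variant_class: str
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.origin not in VARIANT_ORIGINS:
            raise ValueError(f"unknown variant origin {self.origin!r}")
        inferred = _protein_change_class(self.protein_change)
        # inframe deletions and frameshifts share 'del' notation; both accepted
        if inferred is not None and inferred != self.variant_class:
            compatible = {inferred, self.variant_class} <= {"frameshift", "inframe_del"}
            if not compatible:
                raise ValueError(
                    f"variant class {self.variant_class!r} inconsistent with "
                    f"protein change {self.protein_change!r} (looks like {inferred})"
                )


@dataclass(frozen=True)
class FusionEvent:
    """An RNA-level event: a two-partner fusion or an intragenic variant
    transcript such as EGFRvIII (gene5 == gene3 allowed)."""

    gene5: str
    gene3: str
    event_name: str
    breakpoint_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.event_name:
            raise ValueError("fusion event_name must be non-empty")

    @property
    def partners(self) -> frozenset[str]:
        return frozenset({self.gene5, self.gene3})


P53_SCORES = frozenset({"0", "1", "2", "3", "not_done"})
IHC_IDH_VALUES = frozenset({"positive", "negative", "not_done"})
IHC_ATRX_VALUES = frozenset({"preserved", "lost", "inconclusive", "not_done"})
FISH_CODEL_VALUES = frozenset({"codeleted", "not_codeleted", "not_done"})


@dataclass(frozen=True)
class FishEGFR:
    """Interphase-FISH EGFR result: mean signals/nucleus and EGFR/CEP7 ratio.

    The default interpretation rule calls amplification when the mean EGFR
    signal count exceeds 4 and the EGFR/CEP7 ratio exceeds 2.
    """

    mean_egfr_signals: float
    egfr_cep7_ratio: float
    amplified: bool

    SIGNAL_THRESHOLD = 4.0
    RATIO_THRESHOLD = 2.0

    def __post_init__(self) -> None:
        expected = (
            self.mean_egfr_signals > self.SIGNAL_THRESHOLD
            and self.egfr_cep7_ratio > self.RATIO_THRESHOLD
        )
        if self.amplified != expected:
            raise ValueError(
                "fish_egfr.amplified inconsistent with numeric fields "
                f"(signals={self.mean_egfr_signals}, ratio={self.egfr_cep7_ratio})"
            )


@dataclass
class ModalityResults:
    """Orthogonal-modality results for one case (IHC and FISH)."""

    ihc_idh1_r132h: str = "not_done"
    ihc_p53_score: str = "not_done"
    ihc_atrx: str = "not_done"
    fish_codel: str = "not_done"
    fish_egfr: Optional[FishEGFR] = None
    rna_qc: str = "pass"

    def __post_init__(self) -> None:
        if self.ihc_idh1_r132h not in IHC_IDH_VALUES:
            raise ValueError(f"bad ihc_idh1_r132h value {self.ihc_idh1_r132h!r}")
        if str(self.ihc_p53_score) not in P53_SCORES:
            raise ValueError(f"bad ihc_p53_score value {self.ihc_p53_score!r}")
        self.ihc_p53_score = str(self.ihc_p53_score)
        if self.ihc_atrx not in IHC_ATRX_VALUES:
            raise ValueError(f"bad ihc_atrx value {self.ihc_atrx!r}")
        if self.fish_codel not in FISH_CODEL_VALUES:
            raise ValueError(f"bad fish_codel value {self.fish_codel!r}")
        if self.rna_qc not in {"pass", "fail"}:
            raise ValueError(f"bad rna_qc value {self.rna_qc!r}")


@dataclass
class CaseRecord:
    """One tumor case: copy-number profile, variants, fusions, modalities."""

    case_id: str
    age_years: Optional[float] = None
    sex: str = "unknown"
    cn_profile: Optional[CopyNumberProfile] = None
    variants: list[SequenceVariant] = field(default_factory=list)
    fusions: list[FusionEvent] = field(default_factory=list)
    modalities: ModalityResults = field(default_factory=ModalityResults)
    diagnosis_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in {"M", "F", "unknown"}:
            raise ValueError(f"bad sex value {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def pediatric(self) -> Optional[bool]:
        """Age at diagnosis below 21 years; None when age is unknown."""
        if self.age_years is None:
            return None
        return self.age_years < PEDIATRIC_AGE_CUTOFF


# ---------------------------------------------------------------------------
# panel map loading
# ---------------------------------------------------------------------------


def _panel_from_mapping(cfg: Mapping) -> PanelMap:
    try:
        genes = cfg["genes"]
        arm_sets = cfg["arm_sets"]
    except (KeyError, TypeError):
        raise ConfigError("panel config must define 'genes' and 'arm_sets'") from None
    loci = [
        GeneLocus(gene=str(g), chromosome=str(spec["chromosome"]), arm=str(spec["arm"]))
        for g, spec in genes.items()
    ]
    sets = {str(name): tuple(str(g) for g in group or ()) for name, group in arm_sets.items()}
    return PanelMap(loci=loci, arm_sets=sets)


def load_panel_map(config_path: Optional[str | Path] = None) -> PanelMap:
    """Load a :class:`PanelMap` from a YAML file, or the bundled default.

    The default map carries the gene-arm assignment of the targeted panel:
    1p = {MTOR, MYCL, MPL, MAGOH, JAK1, NRAS}, 1q = {BCL9, MCL1, DDR2, MDM4},
    19p = {STK11, GNA11, MAP2K2, JAK3}, 19q = {CCNE1, PPP2R1A}, plus EGFR with
    a configurable chromosome-7 background set and a chromosome-10 set.
    """
    if config_path is None:
        text = resources.files("gliopanel.data").joinpath("panel.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    cfg = yaml.safe_load(text)
    return _panel_from_mapping(cfg)


def default_panel_map() -> PanelMap:
    """The bundled default panel map (see :func:`load_panel_map`)."""
    return load_panel_map(None)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

CN_COLUMNS = ("case_id", "gene", "chromosome", "arm", "copy_number")
VARIANT_COLUMNS = ("case_id", "gene", "protein_change", "variant_class", "origin")
FUSION_COLUMNS = ("case_id", "gene5", "gene3", "event_name")
MODALITY_COLUMNS = (
    "case_id",
    "ihc_idh1_r132h",
    "ihc_p53_score",
    "ihc_atrx",
    "fish_codel",
    "fish_egfr_mean",
    "fish_egfr_cep7_ratio",
    "rna_qc",
)


def _read_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        logger.warning("table %s missing; treated as empty", path.name)
        return pd.DataFrame(columns=list(required))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required columns {missing}")
    return df


def read_cohort(dir_path: str | Path, panel_map: Optional[PanelMap] = None) -> list[CaseRecord]:
    """Assemble :class:`CaseRecord` objects from the four TSV tables in a
    directory (``cn.tsv``, ``variants.tsv``, ``fusions.tsv``,
    ``modalities.tsv``), outer-joined on ``case_id``.

    Cases appearing only in the variant/fusion/modality tables still create a
    record with an empty copy-number profile (IHC-only cases exist); a warning
    is logged for each.  Every input row lands in exactly one record or raises.
    """
    dir_path = Path(dir_path)
    if panel_map is None:
        panel_map = default_panel_map()

    cn = _read_tsv(dir_path / "cn.tsv", CN_COLUMNS)
    variants = _read_tsv(dir_path / "variants.tsv", VARIANT_COLUMNS[:4])
    fusions = _read_tsv(dir_path / "fusions.tsv", FUSION_COLUMNS)
    modalities = _read_tsv(dir_path / "modalities.tsv", MODALITY_COLUMNS[:5])

    profiles: dict[str, dict[str, float]] = {}
    case_order: list[str] = []

    def _register(case_id: str) -> None:
        if case_id not in profiles:
            profiles[case_id] = {}
            case_order.append(case_id)

    for idx, row in cn.iterrows():
        case_id = row["case_id"]
        gene = row["gene"]
        _register(case_id)
        if gene in profiles[case_id]:
            raise ParseError(
                f"cn.tsv row {idx + 2}: duplicate copy-number entry for case "
                f"{case_id!r}, gene {gene!r}"
            )
        try:
            value = float(row["copy_number"])
        except ValueError:
            raise ParseError(
                f"cn.tsv row {idx + 2}: unparseable copy number {row['copy_number']!r}"
            ) from None
        profiles[case_id][gene] = value

    variant_lists: dict[str, list[SequenceVariant]] = {}
    for idx, row in variants.iterrows():
        case_id = row["case_id"]
        if case_id not in profiles:
            logger.warning(
                "variants.tsv row %d: case %r has no copy-number profile; "
                "creating record with empty CN profile",
                idx + 2,
                case_id,
            )
            _register(case_id)
        variant_lists.setdefault(case_id, []).append(
            SequenceVariant(
                gene=row["gene"],
                protein_change=row["protein_change"],
                variant_class=row["variant_class"],
                origin=row.get("origin", "unknown") or "unknown",
            )
        )

    fusion_lists: dict[str, list[FusionEvent]] = {}
    for idx, row in fusions.iterrows():
        case_id = row["case_id"]
        if case_id not in profiles:
            logger.warning("fusions.tsv row %d: case %r unseen; creating record", idx + 2, case_id)
            _register(case_id)
        fusion_lists.setdefault(case_id, []).append(
            FusionEvent(
                gene5=row["gene5"],
                gene3=row["gene3"],
                event_name=row["event_name"],
                breakpoint_note=row.get("breakpoint_note") or None,
            )
        )

    modality_map: dict[str, ModalityResults] = {}
    demo: dict[str, tuple[Optional[float], str]] = {}
    for idx, row in modalities.iterrows():
        case_id = row["case_id"]
        if case_id not in profiles:
            logger.warning("modalities.tsv row %d: case %r unseen; creating record", idx + 2, case_id)
            _register(case_id)
        if case_id in modality_map:
            raise ParseError(f"modalities.tsv row {idx + 2}: duplicate case {case_id!r}")
        fish_egfr = None
        mean_s = row.get("fish_egfr_mean", "")
        ratio = row.get("fish_egfr_cep7_ratio", "")
        if mean_s not in ("", "not_done") and ratio not in ("", "not_done"):
            mean_f, ratio_f = float(mean_s), float(ratio)
            fish_egfr = FishEGFR(
                mean_egfr_signals=mean_f,
                egfr_cep7_ratio=ratio_f,
                amplified=mean_f > FishEGFR.SIGNAL_THRESHOLD and ratio_f > FishEGFR.RATIO_THRESHOLD,
            )
        modality_map[case_id] = ModalityResults(
            ihc_idh1_r132h=row.get("ihc_idh1_r132h", "not_done") or "not_done",
            ihc_p53_score=row.get("ihc_p53_score", "not_done") or "not_done",
            ihc_atrx=row.get("ihc_atrx", "not_done") or "not_done",
            fish_codel=row.get("fish_codel", "not_done") or "not_done",
            fish_egfr=fish_egfr,
            rna_qc=row.get("rna_qc", "pass") or "pass",
        )
        age = row.get("age_years", "")
        demo[case_id] = (float(age) if age not in ("", None) else None, row.get("sex", "") or "unknown")

    records = []
    for case_id in case_order:
        age, sex = demo.get(case_id, (None, "unknown"))
        records.append(
            CaseRecord(
                case_id=case_id,
                age_years=age,
                sex=sex,
                cn_profile=CopyNumberProfile(case_id=case_id, entries=profiles[case_id]),
                variants=variant_lists.get(case_id, []),
                fusions=fusion_lists.get(case_id, []),
                modalities=modality_map.get(case_id, ModalityResults()),
            )
        )
    return records


REPORT_KEYS = ("codel", "egfr", "cdkn2a", "idh", "tp53", "atrx_prediction", "fusions", "integrated")


def write_report(cases_with_calls: Sequence[Mapping], path: str | Path, format: str = "json") -> None:
    """Write the per-case call report.

    ``format='json'`` writes the full structured report (one object per case,
    keys ``case_id`` plus :data:`REPORT_KEYS`); ``format='tsv'`` writes a flat
    one-row-per-case summary.  The JSON report round-trips through
    :func:`read_report`.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(list(cases_with_calls), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        rows = []
        for rec in cases_with_calls:
            flat = {"case_id": rec.get("case_id")}
            for key in REPORT_KEYS:
                value = rec.get(key)
                if isinstance(value, Mapping):
                    for k2, v2 in value.items():
                        if not isinstance(v2, (Mapping, list)):
                            flat[f"{key}_{k2}"] = v2
                elif isinstance(value, list):
                    flat[key] = ";".join(str(v) for v in value)
                else:
                    flat[key] = value
            rows.append(flat)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[dict]:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
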