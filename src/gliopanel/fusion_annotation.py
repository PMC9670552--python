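"""Catalog-driven annotation of RNA-level events.

The catalog (a versioned YAML file, bundled default in
``gliopanel/data/catalog.yaml``) maps fusions and variant transcripts to
their typical CNS context and candidate targeted therapies, each flagged for
blood-brain-barrier penetrance.  Lookup is partner-order-insensitive and
event names are normalized case-insensitively.  Events absent from the
catalog are annotated as not previously reported in CNS tumors with an empty
therapy list — annotation is a pure lookup and invents nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .panel_model import FusionEvent


@dataclass(frozen=True)
class Therapy:
    drug: str
    bbb_penetrant: bool


@dataclass
class CatalogEntry:
    name: str
    partners: frozenset[str]
    context: str
    therapies: tuple[Therapy, ...] = ()
    novel_in_cns: bool = False


@dataclass
class FusionAnnotation:
    event: FusionEvent
    known_in_cns: bool
    typical_context: str
    therapies: tuple[Therapy, ...]
    novel_in_cns: bool

    def __post_init__(self) -> None:
        if self.known_in_cns and self.novel_in_cns:
            raise ValueError("known_in_cns and novel_in_cns are mutually exclusive")


def _normalize_name(name: str) -> str:
    parts = name.upper().replace("/", "-").split("-")
    return "-".join(sorted(parts)) if len(parts) > 1 else parts[0]


class FusionCatalog:
    """Event catalog with partner-set and normalized-name lookup."""

    def __init__(self, entries: list[CatalogEntry], version: int = 1):
        self.version = version
        self.entries = list(entries)
        self._by_partners: dict[frozenset[str], CatalogEntry] = {}
        self._by_name: dict[str, CatalogEntry] = {}
        for entry in entries:
            self._by_partners[entry.partners] = entry
            self._by_name[_normalize_name(entry.name)] = entry

    def lookup(self, event: FusionEvent) -> Optional[CatalogEntry]:
        entry = self._by_name.get(_normalize_name(event.event_name))
        if entry is None:
            entry = self._by_partners.get(event.partners)
        return entry


def load_catalog(path: Optional[str | Path] = None) -> FusionCatalog:
    """Load a fusion catalog from YAML, or the bundled default."""
    if path is None:
        text = resources.files("gliopanel.data").joinpath("catalog.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    try:
        raw_entries = cfg["fusions"]
    except (KeyError, TypeError):
        raise ConfigError("fusion catalog must define a 'fusions' list") from None
    entries = []
    for raw in raw_entries:
        entries.append(
            CatalogEntry(
                name=str(raw["name"]),
                partners=frozenset(str(p) for p in raw.get("partners", ())),
                context=str(raw.get("context", "")),
                therapies=tuple(
                    Therapy(drug=str(t["drug"]), bbb_penetrant=bool(t["bbb_penetrant"]))
                    for t in raw.get("therapies", ())
                ),
                novel_in_cns=bool(raw.get("novel_in_cns", False)),
            )
        )
    return FusionCatalog(entries, version=int(cfg.get("version", 1)))


def annotate_fusion(event: FusionEvent, catalog: Optional[FusionCatalog] = None) -> FusionAnnotation:
    """Annotate one RNA event against the catalog (pure lookup)."""
    if catalog is None:
        catalog = load_catalog()
    entry = catalog.lookup(event)
    if entry is None:
        return FusionAnnotation(
            event=event,
            known_in_cns=False,
            typical_context="",
            therapies=(),
            novel_in_cns=True,
        )
    return FusionAnnotation(
        event=event,
        known_in_cns=not entry.novel_in_cns,
        typical_context=entry.context,
        therapies=entry.therapies,
        novel_in_cns=entry.novel_in_cns,
    )


_EGFRVIII_NOTE_TOKENS = ("2-7", "2_7", "2 to 7", "2–7")


def is_egfrviii(event: FusionEvent) -> bool:
    """True for the EGFRvIII variant transcript: either an event named
    EGFRvIII, or an intragenic EGFR event whose breakpoint note describes the
    exon 2-7 deletion."""
    if event.event_name.strip().upper() == "EGFRVIII":
        return True
    if event.gene5 == "EGFR" and event.gene3 == "EGFR" and event.breakpoint_note:
        note = event.breakpoint_note.lower()
        if ("ex" in note or "exon" in note) and any(tok in note for tok in _EGFRVIII_NOTE_TOKENS):
            return True
    return False
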