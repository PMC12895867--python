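"""Classification of reaction Preferred Terms into thromboembolic categories.

Reactions in spontaneous-report databases are coded at the MedDRA
Preferred Term (PT) level.  The thromboembolic-event (TEE) universe is the
"Embolic and thrombotic events" Standardised MedDRA Query (SMQ 20000081),
split into three disjoint top-level categories — venous (VTE), arterial
(ATE), and vessel-unspecified/mixed — with subtype lists for pulmonary
embolism (PE ⊆ VTE), myocardial infarction (MI ⊆ ATE) and cerebral ATE
(⊆ ATE).  MedDRA is licensed and cannot be redistributed, so the PT
membership of every list is user-supplied configuration; a small synthetic
fixture dictionary ships for tests and examples.

Matching is exact string equality on upper-cased, trimmed PTs — reaction
rows are already PT-coded, so no fuzzy matching is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .faers_io import SafetyReport

CATEGORIES = ("VTE", "ATE", "unspecified_mixed")
SUBTYPES = ("PE", "MI", "cerebral_ATE")
#: subtype → parent top-level category
SUBTYPE_PARENT = {"PE": "VTE", "MI": "ATE", "cerebral_ATE": "ATE"}
OVERALL = "overall_TEE"


@dataclass
class EventDictionary:
    """PT lists per category and subtype; overall TEE is their derived union."""

    categories: dict[str, frozenset[str]]
    subtypes: dict[str, frozenset[str]]
    smq_id: str = "20000081"

    def __post_init__(self) -> None:
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        self.subtypes = {k: frozenset(v) for k, v in self.subtypes.items()}
        for cat in CATEGORIES:
            self.categories.setdefault(cat, frozenset())
        for sub in SUBTYPES:
            self.subtypes.setdefault(sub, frozenset())
        self._validate()

    def _validate(self) -> None:
        cats = list(self.categories)
        for i, c1 in enumerate(cats):
            for c2 in cats[i + 1:]:
                overlap = self.categories[c1] & self.categories[c2]
                if overlap:
                    raise ValueError(
                        f"PT(s) {sorted(overlap)} appear in both {c1} and {c2}; "
                        "top-level categories must be disjoint"
                    )
        for sub, parent in SUBTYPE_PARENT.items():
            stray = self.subtypes[sub] - self.categories[parent]
            if stray:
                raise ValueError(
                    f"subtype {sub} PT(s) {sorted(stray)} not contained in parent "
                    f"category {parent}"
                )

    @property
    def overall_tee(self) -> frozenset[str]:
        """VTE ∪ ATE ∪ unspecified_mixed; derived, never stored."""
        out: frozenset[str] = frozenset()
        for pts in self.categories.values():
            out |= pts
        return out

    def label_sets(self) -> dict[str, frozenset[str]]:
        """Every label (categories, subtypes, overall) with its PT set."""
        out = dict(self.categories)
        out.update(self.subtypes)
        out[OVERALL] = self.overall_tee
        return out

    def all_pts(self) -> frozenset[str]:
        return self.overall_tee


def _normalize(pts: Iterable[str]) -> set[str]:
    out = set()
    for pt in pts or []:
        norm = str(pt).strip().upper()
        if norm:
            out.add(norm)
    return out


def load_dictionary(source: str | Path | Mapping) -> EventDictionary:
    """Load an event dictionary from a YAML file or an equivalent mapping.

    Expected keys: ``categories`` (VTE / ATE / unspecified_mixed → PT list),
    ``subtypes`` (PE / MI / cerebral_ATE → PT list), optional ``smq_id``.
    PTs are upper-cased and trimmed; containment and disjointness invariants
    are enforced and violations raise ``ValueError`` naming the PT.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ValueError("event dictionary config must be a mapping")
    categories = {
        name: _normalize(pts) for name, pts in (data.get("categories") or {}).items()
    }
    subtypes = {
        name: _normalize(pts) for name, pts in (data.get("subtypes") or {}).items()
    }
    for name in categories:
        if name not in CATEGORIES:
            raise ValueError(f"unknown top-level category {name!r}")
    for name in subtypes:
        if name not in SUBTYPES:
            raise ValueError(f"unknown subtype {name!r}")
    return EventDictionary(
        categories={k: frozenset(v) for k, v in categories.items()},
        subtypes={k: frozenset(v) for k, v in subtypes.items()},
        smq_id=str(data.get("smq_id", "20000081")),
    )


def example_dictionary() -> EventDictionary:
    """The synthetic fixture dictionary bundled with the package."""
    return load_dictionary(Path(__file__).parent / "data" / "example_event_dictionary.yaml")


def classify_pts(reaction_pts: Iterable[str], dictionary: EventDictionary) -> frozenset[str]:
    """Labels whose PT set intersects ``reaction_pts`` (already normalized)."""
    pts = frozenset(p.strip().upper() for p in reaction_pts)
    labels = {
        name
        for name, members in dictionary.label_sets().items()
        if name != OVERALL and pts & members
    }
    if any(label in CATEGORIES for label in labels):
        labels.add(OVERALL)
    return frozenset(labels)


def classify_report(report: SafetyReport, dictionary: EventDictionary) -> frozenset[str]:
    """Category/subtype labels carried by one report.

    A label is present iff any reaction PT is in that label's list;
    ``overall_TEE`` is present iff any top-level category is.  A report
    contributes each label at most once no matter how many matching PTs it
    lists.
    """
    return classify_pts(report.reaction_pts, dictionary)
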