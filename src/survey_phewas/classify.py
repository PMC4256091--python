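"""Classify retained PheWAS results against a prior-association catalog.

Each retained (SNP, class, stratum) group is labelled:

* ``replicated`` — the result's phenotype class exactly matches a catalog
  entry's prior class for that SNP;
* ``related``   — no exact match, but the SNP has a catalog entry whose
  related-group tag (e.g. one lipid group spanning HDL-C / LDL-C / total
  cholesterol / triglycerides) also covers the result's class;
* ``novel``     — otherwise (including SNPs absent from the catalog).

Classification depends only on (SNP, class, catalog) — never on p-values or
strata.  Direction agreement with the catalog is reported but never changes
the category.  Pleiotropy is a SNP with two or more distinct significant
phenotype classes (across strata jointly); generalization is a (SNP, class)
group retained with the same direction in two or more strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .replicate import ReplicatedResult

log = logging.getLogger(__name__)

CATEGORY_REPLICATED = "replicated"
CATEGORY_RELATED = "related"
CATEGORY_NOVEL = "novel"


@dataclass(frozen=True)
class CatalogEntry:
    """A previously reported SNP-phenotype association."""

    snp: str
    prior_class: str
    related_group: str | None = None
    direction: str | None = None  # "+", "-" or None when unreported
    source: str = ""

    def __post_init__(self):
        if not self.snp:
            raise ValueError("catalog entry requires a SNP id")
        if not self.prior_class and not self.related_group:
            raise ValueError(f"{self.snp}: catalog entry needs a prior class or related group")


@dataclass
class Catalog:
    """Prior-association catalog plus related-group membership.

    ``related_groups`` maps a group tag to the set of phenotype classes it
    covers; a result class shares a group with a catalog entry when the
    entry's tag covers that class.
    """

    entries: list[CatalogEntry] = field(default_factory=list)
    related_groups: dict[str, set[str]] = field(default_factory=dict)

    def for_snp(self, snp: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.snp == snp]

    @classmethod
    def from_frames(cls, entries: pd.DataFrame, groups: pd.DataFrame | None = None) -> "Catalog":
        """entries columns: snp, prior_class[, related_group, direction, source];
        groups columns: related_group, class_label."""
        recs = []
        for r in entries.itertuples(index=False):
            rg = getattr(r, "related_group", None)
            d = getattr(r, "direction", None)
            recs.append(
                CatalogEntry(
                    snp=str(r.snp),
                    prior_class=str(r.prior_class) if pd.notna(r.prior_class) else "",
                    related_group=str(rg) if rg is not None and pd.notna(rg) and str(rg) else None,
                    direction=str(d) if d is not None and pd.notna(d) and str(d) in "+-" else None,
                    source=str(getattr(r, "source", "") or ""),
                )
            )
        rg_map: dict[str, set[str]] = {}
        if groups is not None:
            for r in groups.itertuples(index=False):
                rg_map.setdefault(str(r.related_group), set()).add(str(r.class_label))
        return cls(entries=recs, related_groups=rg_map)

    @classmethod
    def read(cls, entries_path: str | Path, groups_path: str | Path | None = None) -> "Catalog":
        entries = pd.read_csv(entries_path, sep="\t", dtype=str)
        groups = pd.read_csv(groups_path, sep="\t", dtype=str) if groups_path else None
        return cls.from_frames(entries, groups)


@dataclass
class ClassifiedResult:
    result: ReplicatedResult
    category: str
    matched: list[CatalogEntry] = field(default_factory=list)
    direction_agreement: str = "unknown"  # same / opposite / unknown

    @property
    def snp(self) -> str:
        return self.result.snp

    @property
    def class_label(self) -> str:
        return self.result.class_label

    @property
    def stratum(self) -> str:
        return self.result.stratum

    @property
    def direction(self) -> str:
        return self.result.direction


@dataclass(frozen=True)
class PleiotropyRecord:
    """A SNP whose retained results span two or more distinct classes."""

    snp: str
    classes: tuple[tuple[str, str, str], ...]  # (class_label, stratum, direction)

    @property
    def n_classes(self) -> int:
        return len({c for c, _, _ in self.classes})


def classify_against_catalog(result: ReplicatedResult, catalog: Catalog) -> ClassifiedResult:
    """Label one retained group as replicated, related, or novel."""
    entries = catalog.for_snp(result.snp)
    if not entries:
        log.info("%s absent from catalog; classified novel", result.snp)
        return ClassifiedResult(result, CATEGORY_NOVEL)
    exact = [e for e in entries if e.prior_class == result.class_label]
    if exact:
        agreement = "unknown"
        directed = [e for e in exact if e.direction]
        if directed:
            agreement = "same" if directed[0].direction == result.direction else "opposite"
        return ClassifiedResult(result, CATEGORY_REPLICATED, exact, agreement)
    related = [
        e
        for e in entries
        if e.related_group and result.class_label in catalog.related_groups.get(e.related_group, ())
    ]
    if related:
        return ClassifiedResult(result, CATEGORY_RELATED, related)
    return ClassifiedResult(result, CATEGORY_NOVEL)


def classify_results(
    retained: Iterable[ReplicatedResult], catalog: Catalog
) -> list[ClassifiedResult]:
    return [classify_against_catalog(r, catalog) for r in retained]


def detect_pleiotropy(classified: Sequence[ClassifiedResult]) -> list[PleiotropyRecord]:
    """SNPs with two or more distinct significant phenotype classes.

    Classes are counted across strata jointly; per-class strata and signs
    are carried on the record.
    """
    by_snp: dict[str, list[ClassifiedResult]] = {}
    for c in classified:
        by_snp.setdefault(c.snp, []).append(c)
    records = []
    for snp in sorted(by_snp):
        group = by_snp[snp]
        classes = {c.class_label for c in group}
        if len(classes) >= 2:
            triples = tuple(
                sorted((c.class_label, c.stratum, c.direction) for c in group)
            )
            records.append(PleiotropyRecord(snp=snp, classes=triples))
    return records


def assess_generalization(classified: Sequence[ClassifiedResult]) -> pd.DataFrame:
    """(SNP, class) groups retained in two or more strata.

    Same direction in every stratum -> ``generalized``; mixed directions ->
    ``discordant``.  Single-stratum groups are not reported.
    """
    rows = []
    by_group: dict[tuple[str, str], list[ClassifiedResult]] = {}
    for c in classified:
        by_group.setdefault((c.snp, c.class_label), []).append(c)
    for (snp, class_label), group in sorted(by_group.items()):
        strata = sorted({c.stratum for c in group})
        if len(strata) < 2:
            continue
        directions = {c.direction for c in group}
        rows.append(
            {
                "snp": snp,
                "class_label": class_label,
                "strata": ",".join(strata),
                "n_strata": len(strata),
                "direction": group[0].direction if len(directions) == 1 else "mixed",
                "status": "generalized" if len(directions) == 1 else "discordant",
            }
        )
    return pd.DataFrame(rows, columns=["snp", "class_label", "strata", "n_strata", "direction", "status"])


def summarize_categories(classified: Sequence[ClassifiedResult]) -> dict:
    """Category counts (a partition of the retained set), pleiotropy and
    generalization counts."""
    counts = {CATEGORY_REPLICATED: 0, CATEGORY_RELATED: 0, CATEGORY_NOVEL: 0}
    for c in classified:
        counts[c.category] += 1
    pleio = detect_pleiotropy(classified)
    gen = assess_generalization(classified)
    return {
        "total": len(classified),
        **counts,
        "pleiotropic_snps": len(pleio),
        "generalized_groups": int((gen["status"] == "generalized").sum()) if len(gen) else 0,
        "discordant_groups": int((gen["status"] == "discordant").sum()) if len(gen) else 0,
    }


def classified_to_frame(classified: Sequence[ClassifiedResult]) -> pd.DataFrame:
    rows = [
        {
            "snp": c.snp,
            "class_label": c.class_label,
            "stratum": c.stratum,
            "direction": c.direction,
            "category": c.category,
            "matched_prior_classes": ";".join(sorted({e.prior_class for e in c.matched if e.prior_class})),
            "direction_agreement": c.direction_agreement,
        }
        for c in classified
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "snp", "class_label", "stratum", "direction",
            "category", "matched_prior_classes", "direction_agreement",
        ],
    )


def pleiotropy_to_frame(records: Sequence[PleiotropyRecord]) -> pd.DataFrame:
    rows = [
        {
            "snp": r.snp,
            "n_classes": r.n_classes,
            "classes": ";".join(f"{c} ({s} {d})" for c, s, d in r.classes),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["snp", "n_classes", "classes"])
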