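"""Region annotation, cohort configuration and summary reporting.

Annotation is deliberately coarse: a flat list of labeled genomic intervals
with one of five categories (exon > utr > intron > upstream > intergenic, in
priority order).  This matches what a candidate table's "Location" column
needs; full gene-model parsing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .somatic_filter import (
    FilterThresholds,
    POSSIBLE,
    REJECTED,
    TISSUE_SPECIFIC,
)

logger = logging.getLogger(__name__)

#: Annotation categories, highest priority first.
CATEGORY_PRIORITY = ("exon", "utr", "intron", "upstream", "intergenic")
GROUPS = ("EOAD", "LOAD", "control")


@dataclass(frozen=True)
class Feature:
    """One annotated interval: 0-based half-open span with category + label."""

    chrom: str
    start: int
    end: int
    category: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PRIORITY:
            raise ConfigurationError(
                f"unknown annotation category {self.category!r}; "
                f"expected one of {CATEGORY_PRIORITY}"
            )
        if self.start < 0 or self.start >= self.end:
            raise ConfigurationError(
                f"invalid feature interval [{self.start}, {self.end})"
            )


class RegionAnnotation:
    """Queryable set of labeled features; unannotated positions are intergenic."""

    def __init__(self, features=()) -> None:
        self._by_chrom: dict = {}
        for f in features:
            self._by_chrom.setdefault(f.chrom, []).append(f)
        for feats in self._by_chrom.values():
            feats.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def overlapping(self, chrom: str, pos: int) -> list:
        """Features containing 1-based ``pos`` (start <= pos-1 < end)."""
        p0 = pos - 1
        return [
            f
            for f in self._by_chrom.get(chrom, [])
            if f.start <= p0 < f.end
        ]


def read_annotation_tsv(path) -> RegionAnnotation:
    """Load a BED-like annotation: chrom, start, end, category[, label]."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected chrom/start/end/category[/label]"
                )
            label = parts[4] if len(parts) > 4 and parts[4] != "." else None
            try:
                features.append(
                    Feature(parts[0], int(parts[1]), int(parts[2]), parts[3], label)
                )
            except (ValueError, ConfigurationError) as exc:
                raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
    return RegionAnnotation(features)


def annotate_location(key, annotation: RegionAnnotation):
    """(category, label) of the highest-priority feature overlapping the site.

    Ties within a priority level break alphabetically by label; positions
    overlapping nothing are ("intergenic", None).
    """
    hits = annotation.overlapping(key.chrom, key.pos)
    if not hits:
        return ("intergenic", None)
    best = min(
        hits,
        key=lambda f: (CATEGORY_PRIORITY.index(f.category), f.label or "~"),
    )
    return (best.category, best.label)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort layout: individuals with group labels and per-caller VCF paths."""

    individuals: dict  # id -> {"group": str, "vcfs": {caller: path}}
    mask_path: str | None = None
    annotation_path: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    #: When set (e.g. "synthetic"), all VCFs are parsed with this dialect and
    #: calls keep their caller label from the vcfs mapping.
    vcf_dialect: str | None = None

    def __post_init__(self) -> None:
        for ind, spec in self.individuals.items():
            group = spec.get("group")
            if group not in GROUPS:
                raise ConfigurationError(
                    f"individual {ind!r}: group {group!r} not in {GROUPS}"
                )
            if not spec.get("vcfs"):
                raise ConfigurationError(
                    f"individual {ind!r}: needs at least one caller VCF path"
                )

    def group_of(self, individual: str) -> str:
        try:
            return self.individuals[individual]["group"]
        except KeyError:
            raise ConfigurationError(f"unknown individual {individual!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "individuals" not in raw:
            raise ConfigurationError(f"{path}: missing 'individuals' section")
        overrides = raw.get("thresholds") or {}
        try:
            thresholds = FilterThresholds(**overrides)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: bad thresholds: {exc}") from exc
        base = Path(path).parent

        def _resolve(p):
            if p is None:
                return None
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        individuals = {}
        for ind, spec in raw["individuals"].items():
            individuals[ind] = {
                "group": spec.get("group"),
                "vcfs": {c: _resolve(v) for c, v in (spec.get("vcfs") or {}).items()},
            }
        return cls(
            individuals=individuals,
            mask_path=_resolve(raw.get("mask")),
            annotation_path=_resolve(raw.get("annotation")),
            thresholds=thresholds,
            vcf_dialect=raw.get("dialect"),
        )


def to_yaml(config: CohortConfig, path) -> None:
    """Write a CohortConfig back to YAML (paths as given)."""
    raw = {
        "individuals": {
            ind: {"group": spec["group"], "vcfs": dict(spec["vcfs"])}
            for ind, spec in config.individuals.items()
        }
    }
    if config.vcf_dialect:
        raw["dialect"] = config.vcf_dialect
    if config.mask_path:
        raw["mask"] = config.mask_path
    if config.annotation_path:
        raw["annotation"] = config.annotation_path
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(
    results,
    group_by_individual: dict,
    annotation: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """Candidate counts per cohort group (and location category, if annotated).

    Counts possible and tissue_specific consensus calls; rejected sites are
    tallied in their own column so partitions stay auditable.
    """
    rows = []
    for r in results:
        group = group_by_individual.get(r.individual)
        if group is None:
            raise ConfigurationError(
                f"no group label for individual {r.individual!r}"
            )
        category, label = (
            annotate_location(r.key, annotation)
            if annotation is not None
            else (None, None)
        )
        rows.append(
            {
                "group": group,
                "classification": r.classification,
                "category": category,
                "label": label,
            }
        )
    index = pd.Index(GROUPS, name="group")
    out = pd.DataFrame(
        0,
        index=index,
        columns=[TISSUE_SPECIFIC, POSSIBLE, REJECTED, "candidates"],
    )
    for row in rows:
        out.loc[row["group"], row["classification"]] += 1
    out["candidates"] = out[TISSUE_SPECIFIC] + out[POSSIBLE]
    if annotation is not None:
        cat = pd.DataFrame(0, index=index, columns=list(CATEGORY_PRIORITY))
        for row in rows:
            if row["classification"] in (TISSUE_SPECIFIC, POSSIBLE):
                cat.loc[row["group"], row["category"]] += 1
        out = pd.concat([out, cat.add_prefix("loc_")], axis=1)
    return out
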