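"""Seven-criterion somatic filter and cross-caller consensus classification.

The filter judges paired brain/blood allele counts per caller:

i.   read depth >= 50x in both tissues of the pair;
ii.  >= 5 alternative-allele reads in brain;
iii. AAF < 20% in both tissues (removes germline heterozygotes);
iv.  brainAAF/bloodAAF ratio outside the closed interval [0.8, 1.2]
     (removes shared germline/artifact signal; ratio +inf when the blood AAF
     is zero passes — absence in blood is the strongest somatic evidence);
v.   Fisher's exact test on the 2x2 alt/ref x brain/blood table, p < 0.05
     (default: minimum-likelihood two-sided convention);
vi.  recurrent sites (passing in more than ``recurrence_max_individuals``
     distinct individuals of the cohort) are excluded as systematic artifacts;
vii. consensus across callers: a site supported by >= 3 of 4 callers is a
     possible tissue-specific variant, by all 4 a tissue-specific variant.

All criteria are evaluated and recorded even when an earlier one fails, so the
verdict table is fully auditable; ``passed`` is the conjunction.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .callset_io import (
    CallSet,
    GenomicMask,
    SiteKey,
    apply_mask,
    exclude_commented_calls,
    genome_order_key,
    DEFAULT_EXCLUDE_COMMENTS,
    DEFAULT_EXCLUDE_CALLERS,
)
from .errors import UndefinedInputError

logger = logging.getLogger(__name__)

TISSUE_SPECIFIC = "tissue_specific"
POSSIBLE = "possible"
REJECTED = "rejected"

#: Relative tolerance when comparing point probabilities in the two-sided test.
_MINLIK_RTOL = 1e-7


@dataclass(frozen=True)
class PairedSiteCounts:
    """Brain/blood ref+alt read counts at one site for one individual/caller."""

    key: SiteKey
    individual: str
    caller: str
    brain_ref: int
    brain_alt: int
    blood_ref: int
    blood_alt: int

    def __post_init__(self) -> None:
        for name in ("brain_ref", "brain_alt", "blood_ref", "blood_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def brain_depth(self) -> int:
        return self.brain_ref + self.brain_alt

    @property
    def blood_depth(self) -> int:
        return self.blood_ref + self.blood_alt

    @classmethod
    def from_site_call(cls, call) -> "PairedSiteCounts":
        return cls(
            key=call.key,
            individual=call.individual,
            caller=call.caller,
            brain_ref=call.brain_ref,
            brain_alt=call.brain_alt,
            blood_ref=call.blood_ref,
            blood_alt=call.blood_alt,
        )


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable thresholds of the somatic filter (defaults as published)."""

    min_depth: int = 50
    min_brain_alt: int = 5
    max_aaf: float = 0.20
    ratio_low: float = 0.8
    ratio_high: float = 1.2
    alpha: float = 0.05
    fisher_sidedness: str = "two_sided_minlik"
    min_callers_possible: int = 3
    min_callers_specific: int = 4
    recurrence_max_individuals: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.max_aaf < 1:
            raise ValueError("max_aaf must be in (0, 1)")
        if self.ratio_low >= self.ratio_high:
            raise ValueError("ratio_low must be < ratio_high")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not (
            1 <= self.min_callers_possible <= self.min_callers_specific <= 4
        ):
            raise ValueError("need 1 <= min_callers_possible <= min_callers_specific <= 4")
        if self.fisher_sidedness not in ("two_sided_minlik", "one_sided_brain_enriched"):
            raise ValueError(f"unknown fisher sidedness {self.fisher_sidedness!r}")


@dataclass
class FilterVerdict:
    """Per-criterion record for one site/caller/individual."""

    counts: PairedSiteCounts
    c1_depth: bool
    c2_brain_alt: bool
    c3_aaf: bool
    c4_ratio: bool
    c5_fisher: bool
    brain_aaf: float
    blood_aaf: float
    aaf_ratio: float  # may be +inf; nan means undefined (0/0)
    fisher_p: float
    c6_recurrent: bool | None = None  # None until cohort-wide recurrence resolved

    @property
    def passed(self) -> bool:
        """Conjunction of c1–c5, and c6 once resolved."""
        base = (
            self.c1_depth
            and self.c2_brain_alt
            and self.c3_aaf
            and self.c4_ratio
            and self.c5_fisher
        )
        if self.c6_recurrent is None:
            return base
        return base and self.c6_recurrent

    @property
    def passed_c1_to_c5(self) -> bool:
        return (
            self.c1_depth
            and self.c2_brain_alt
            and self.c3_aaf
            and self.c4_ratio
            and self.c5_fisher
        )


@dataclass
class ConsensusResult:
    """Cross-caller support and final classification for one (individual, site)."""

    key: SiteKey
    individual: str
    supporting_callers: frozenset
    classification: str
    verdicts: dict = field(default_factory=dict)  # caller -> FilterVerdict


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def aaf(ref_count: int, alt_count: int) -> float:
    """Alternative allele frequency alt/(ref+alt)."""
    total = ref_count + alt_count
    if total < 1:
        raise UndefinedInputError("AAF undefined at zero total depth")
    return alt_count / total


def aaf_ratio(brain_aaf: float, blood_aaf: float) -> float:
    """brainAAF/bloodAAF; +inf when blood AAF is 0 and brain AAF > 0; NaN for 0/0."""
    if blood_aaf == 0.0:
        return math.inf if brain_aaf > 0 else math.nan
    return brain_aaf / blood_aaf


def fisher_exact(
    brain_alt: int,
    brain_ref: int,
    blood_alt: int,
    blood_ref: int,
    sidedness: str = "two_sided_minlik",
) -> float:
    """Exact hypergeometric p-value for the 2x2 table [[brain_alt, brain_ref],
    [blood_alt, blood_ref]].

    ``two_sided_minlik`` sums, over all tables with the observed margins, the
    point probabilities not exceeding the observed one (within relative
    tolerance 1e-7) — the usual exact-test convention.
    ``one_sided_brain_enriched`` sums tables with brain alt count >= observed.
    """
    for v in (brain_alt, brain_ref, blood_alt, blood_ref):
        if v < 0:
            raise UndefinedInputError("counts must be non-negative")
    total = brain_alt + brain_ref + blood_alt + blood_ref
    if total < 1:
        raise UndefinedInputError("empty 2x2 table")
    n_alt = brain_alt + blood_alt      # successes in the urn
    n_brain = brain_alt + brain_ref    # draws
    k_min = max(0, n_brain - (total - n_alt))
    k_max = min(n_alt, n_brain)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, total, n_alt, n_brain)
    if sidedness == "one_sided_brain_enriched":
        p = float(pmf[support >= brain_alt].sum())
    elif sidedness == "two_sided_minlik":
        p_obs = float(hypergeom.pmf(brain_alt, total, n_alt, n_brain))
        p = float(pmf[pmf <= p_obs * (1.0 + _MINLIK_RTOL)].sum())
    else:
        raise UndefinedInputError(f"unknown sidedness {sidedness!r}")
    return min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# Criterion evaluation, recurrence, consensus
# ---------------------------------------------------------------------------

def evaluate_criteria(
    counts: PairedSiteCounts, thresholds: FilterThresholds = FilterThresholds()
) -> FilterVerdict:
    """Evaluate criteria i–v on one paired count record.

    Every criterion is computed (no short-circuiting).  The recurrence
    criterion (vi) is left unresolved until :func:`find_recurrent` has seen
    the whole cohort.
    """
    t = thresholds
    c1 = counts.brain_depth >= t.min_depth and counts.blood_depth >= t.min_depth
    c2 = counts.brain_alt >= t.min_brain_alt
    brain_aaf = aaf(counts.brain_ref, counts.brain_alt) if counts.brain_depth else math.nan
    blood_aaf = aaf(counts.blood_ref, counts.blood_alt) if counts.blood_depth else math.nan
    c3 = (
        not math.isnan(brain_aaf)
        and not math.isnan(blood_aaf)
        and brain_aaf < t.max_aaf
        and blood_aaf < t.max_aaf
    )
    if math.isnan(brain_aaf) or math.isnan(blood_aaf):
        ratio = math.nan
    else:
        ratio = aaf_ratio(brain_aaf, blood_aaf)
    # undefined ratio (0/0) fails; the closed exclusion window [low, high] fails
    c4 = not math.isnan(ratio) and not (t.ratio_low <= ratio <= t.ratio_high)
    p = fisher_exact(
        counts.brain_alt,
        counts.brain_ref,
        counts.blood_alt,
        counts.blood_ref,
        sidedness=t.fisher_sidedness,
    )
    c5 = p < t.alpha
    return FilterVerdict(
        counts=counts,
        c1_depth=c1,
        c2_brain_alt=c2,
        c3_aaf=c3,
        c4_ratio=c4,
        c5_fisher=c5,
        brain_aaf=brain_aaf,
        blood_aaf=blood_aaf,
        aaf_ratio=ratio,
        fisher_p=p,
    )


def find_recurrent(
    verdicts, thresholds: FilterThresholds = FilterThresholds()
) -> set:
    """Resolve criterion vi across the cohort.

    A SiteKey is recurrent when its c1–c5-passing verdicts span more than
    ``recurrence_max_individuals`` distinct individuals.  Every verdict at a
    recurrent key gets c6 = fail; all others get c6 = pass.  Returns the set of
    recurrent keys.
    """
    individuals_by_key: dict = defaultdict(set)
    for v in verdicts:
        if v.passed_c1_to_c5:
            individuals_by_key[v.counts.key].add(v.counts.individual)
    recurrent = {
        k
        for k, inds in individuals_by_key.items()
        if len(inds) > thresholds.recurrence_max_individuals
    }
    for v in verdicts:
        v.c6_recurrent = v.counts.key not in recurrent
    return recurrent


def consensus(
    verdicts_by_caller: dict,
    thresholds: FilterThresholds = FilterThresholds(),
) -> ConsensusResult:
    """Classify one (individual, site) from its per-caller verdicts.

    tissue_specific: supported by >= ``min_callers_specific`` callers;
    possible: >= ``min_callers_possible``; otherwise rejected.
    """
    if not verdicts_by_caller:
        raise UndefinedInputError("consensus needs at least one caller verdict")
    if not isinstance(verdicts_by_caller, dict):
        by_caller: dict = {}
        for v in verdicts_by_caller:
            if v.counts.caller in by_caller:
                raise UndefinedInputError(
                    f"duplicate verdict for caller {v.counts.caller!r}"
                )
            by_caller[v.counts.caller] = v
        verdicts_by_caller = by_caller
    any_v = next(iter(verdicts_by_caller.values()))
    supporting = frozenset(
        caller for caller, v in verdicts_by_caller.items() if v.passed
    )
    n = len(supporting)
    if n >= thresholds.min_callers_specific:
        cls = TISSUE_SPECIFIC
    elif n >= thresholds.min_callers_possible:
        cls = POSSIBLE
    else:
        cls = REJECTED
    return ConsensusResult(
        key=any_v.counts.key,
        individual=any_v.counts.individual,
        supporting_callers=supporting,
        classification=cls,
        verdicts=dict(verdicts_by_caller),
    )


def run_pipeline(
    callsets,
    mask: GenomicMask | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    comment_patterns=DEFAULT_EXCLUDE_COMMENTS,
    comment_callers=DEFAULT_EXCLUDE_CALLERS,
):
    """Run comment exclusion → masking → criteria → recurrence → consensus.

    Parameters
    ----------
    callsets : iterable of CallSet
        One per caller (each may span many individuals).
    mask : GenomicMask, optional
        Exclusion intervals (e.g. segmental duplications).
    thresholds : FilterThresholds
        Somatic-filter thresholds.

    Returns
    -------
    (results, summary) : (list of ConsensusResult, dict)
        Results sorted by (genome order, individual); summary holds per-caller
        attrition counts and per-class totals.
    """
    summary: dict = {"per_caller": {}, "classes": {TISSUE_SPECIFIC: 0, POSSIBLE: 0, REJECTED: 0}}
    verdicts: list = []
    for cs in callsets:
        raw = len(cs)
        cs = exclude_commented_calls(cs, comment_patterns, comment_callers)
        excluded = cs.provenance.get("comment_excluded", 0)
        if mask is not None:
            cs = apply_mask(cs, mask)
        masked = cs.provenance.get("mask_removed", 0)
        caller_verdicts = [
            evaluate_criteria(PairedSiteCounts.from_site_call(c), thresholds)
            for c in cs.calls
        ]
        verdicts.extend(caller_verdicts)
        crit_counts = {
            "c1_depth": sum(v.c1_depth for v in caller_verdicts),
            "c2_brain_alt": sum(v.c2_brain_alt for v in caller_verdicts),
            "c3_aaf": sum(v.c3_aaf for v in caller_verdicts),
            "c4_ratio": sum(v.c4_ratio for v in caller_verdicts),
            "c5_fisher": sum(v.c5_fisher for v in caller_verdicts),
            "pass_c1_c5": sum(v.passed_c1_to_c5 for v in caller_verdicts),
        }
        summary["per_caller"][cs.caller] = {
            "raw": raw,
            "comment_excluded": excluded,
            "mask_removed": masked,
            "evaluated": len(caller_verdicts),
            **crit_counts,
        }
    recurrent = find_recurrent(verdicts, thresholds)
    summary["recurrent_sites"] = len(recurrent)

    grouped: dict = defaultdict(dict)
    for v in verdicts:
        caller = v.counts.caller
        slot = grouped[(v.counts.individual, v.counts.key)]
        if caller in slot:
            raise UndefinedInputError(
                f"duplicate verdict for caller {caller!r} at "
                f"{v.counts.key} / {v.counts.individual}"
            )
        slot[caller] = v
    results = [consensus(by_caller, thresholds) for by_caller in grouped.values()]
    results.sort(key=lambda r: (genome_order_key(r.key), r.individual))
    for r in results:
        summary["classes"][r.classification] += 1
    logger.info(
        "pipeline: %d sites evaluated, %d recurrent, classes=%s",
        len(results),
        len(recurrent),
        summary["classes"],
    )
    return results, summary
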