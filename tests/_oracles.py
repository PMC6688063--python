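"""Independent oracles and verdict builders shared across test modules."""

from math import comb

from somatosift.callset_io import SiteKey
from somatosift.somatic_filter import (
    PairedSiteCounts,
    POSSIBLE,
    REJECTED,
    TISSUE_SPECIFIC,
    evaluate_criteria,
)

CALLERS = ("mutect1", "mutect2", "strelka2", "varscan2")
RANK = {REJECTED: 0, POSSIBLE: 1, TISSUE_SPECIFIC: 2}


def fisher_oracle(brain_alt, brain_ref, blood_alt, blood_ref, one_sided=False):
    """Brute-force enumeration of every 2x2 table with the observed margins,
    in exact integer arithmetic (independent of the implementation)."""
    total = brain_alt + brain_ref + blood_alt + blood_ref
    n_alt = brain_alt + blood_alt
    n_brain = brain_alt + brain_ref
    k_min = max(0, n_brain - (total - n_alt))
    k_max = min(n_alt, n_brain)
    weights = {
        k: comb(n_alt, k) * comb(total - n_alt, n_brain - k)
        for k in range(k_min, k_max + 1)
    }
    obs = weights[brain_alt]
    if one_sided:
        num = sum(w for k, w in weights.items() if k >= brain_alt)
    else:
        num = sum(w for w in weights.values() if w <= obs)
    return num / comb(total, n_brain)


def make_counts(brain_ref, brain_alt, blood_ref, blood_alt, pos=100,
                individual="i1", caller="varscan2"):
    return PairedSiteCounts(
        key=SiteKey("chr1", pos, "C", "T"),
        individual=individual,
        caller=caller,
        brain_ref=brain_ref,
        brain_alt=brain_alt,
        blood_ref=blood_ref,
        blood_alt=blood_alt,
    )


def passing_verdict(caller, individual="i1"):
    v = evaluate_criteria(
        make_counts(582, 6, 794, 0, caller=caller, individual=individual)
    )
    v.c6_recurrent = True
    return v


def failing_verdict(caller, individual="i1"):
    v = evaluate_criteria(
        make_counts(400, 4, 400, 0, caller=caller, individual=individual)
    )
    v.c6_recurrent = True
    return v
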