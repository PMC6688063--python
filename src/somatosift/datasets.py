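"""Bundled reference data: the published brain/blood validation cohort.

These are the printed per-caller allele counts, caller comments and ddPCR
validation measurements for the 11 brain-specific SNVs reported from an
ultra-deep (~700x) targeted sequencing study of paired temporal-cortex/blood
DNA in early- and late-onset Alzheimer disease patients.  They serve as a
worked example and as fixed inputs for end-to-end checks: feeding the printed
counts through the somatic filter reproduces the published pass/fail pattern.

Counts are (ref, alt) read pairs; ``None`` marks caller/tissue cells the
source reported as not available.  Printed percent AAFs are retained verbatim
alongside the count-derived values because a few printed AAFs are not equal to
alt/(ref+alt) on the printed counts (the source presumably printed a
caller-reported frequency there); both derivations are exposed.
"""

from __future__ import annotations

import pandas as pd

from .callset_io import CallSet, SiteCall, SiteKey

CALLERS = ("mutect1", "mutect2", "strelka2", "varscan2")

# Each record: group, individual (sample-pair label), locus region, location
# category/label, then per caller {blood: (ref, alt), brain: (ref, alt),
# printed blood/brain AAF %}.  comments: per-caller FILTER annotations.
REPORTED_SNVS = [
    {
        "group": "LOAD", "individual": "1/2",
        "key": SiteKey("chr1", 207351003, "C", "A"),
        "region": "CR1", "location": ("intergenic", None),
        "counts": {
            "mutect2": {"blood": (423, 0), "brain": (546, 8), "aaf_pct": (0.0, 1.2)},
            "strelka2": {"blood": (425, 0), "brain": (586, 8), "aaf_pct": (0.0, 1.3)},
            "varscan2": {"blood": (424, 0), "brain": (584, 7), "aaf_pct": (0.0, 1.2)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "LOAD", "individual": "19/20",
        "key": SiteKey("chr1", 207461994, "C", "T"),
        "region": "CR1", "location": ("upstream", "CD55"),
        "counts": {
            "mutect1": {"blood": (794, 0), "brain": (582, 6), "aaf_pct": (0.0, 1.0)},
            "mutect2": {"blood": (1472, 0), "brain": (997, 10), "aaf_pct": (0.0, 1.0)},
            "strelka2": {"blood": (1476, 0), "brain": (1002, 10), "aaf_pct": (0.0, 1.0)},
            "varscan2": {"blood": (1477, 1), "brain": (1001, 10), "aaf_pct": (0.0, 1.0)},
        },
        "comments": {
            "mutect1": ("possible_contamination",),
            "mutect2": ("PASS",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "27/28",
        "key": SiteKey("chr1", 207550332, "T", "C"),
        "region": "CR1", "location": ("intergenic", None),
        "counts": {
            "mutect2": {"blood": (697, 0), "brain": (398, 6), "aaf_pct": (0.0, 1.6)},
            "strelka2": {"blood": (701, 0), "brain": (400, 6), "aaf_pct": (0.0, 1.5)},
            "varscan2": {"blood": (700, 0), "brain": (400, 5), "aaf_pct": (0.0, 1.2)},
        },
        "comments": {
            "mutect1": ("possible_contamination",),
            "mutect2": ("PASS",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "27/28",
        "key": SiteKey("chr1", 227069718, "G", "T"),
        "region": "PSEN2", "location": ("exon", "PSEN2"),
        "counts": {
            "mutect2": {"blood": (491, 0), "brain": (290, 5), "aaf_pct": (0.0, 1.3)},
            "strelka2": {"blood": (490, 0), "brain": (289, 5), "aaf_pct": (0.0, 1.7)},
            "varscan2": {"blood": (490, 0), "brain": (287, 5), "aaf_pct": (0.0, 1.7)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "25/26",
        "key": SiteKey("chr2", 128054946, "G", "T"),
        "region": "BIN1", "location": ("upstream", "ERCC3"),
        "counts": {
            "mutect2": {"blood": (403, 0), "brain": (391, 5), "aaf_pct": (0.0, 1.0)},
            "strelka2": {"blood": (409, 0), "brain": (397, 5), "aaf_pct": (0.0, 1.2)},
            "varscan2": {"blood": (409, 0), "brain": (396, 5), "aaf_pct": (0.0, 1.2)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "11/12",
        "key": SiteKey("chr8", 27316070, "C", "A"),
        "region": "CLU/PTK2B", "location": ("utr", "PTK2B"),
        "counts": {
            "mutect2": {"blood": (332, 0), "brain": (414, 6), "aaf_pct": (0.0, 1.0)},
            "strelka2": {"blood": (334, 0), "brain": (417, 6), "aaf_pct": (0.0, 1.4)},
            "varscan2": {"blood": (330, 0), "brain": (413, 6), "aaf_pct": (0.0, 1.4)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "25/26",
        "key": SiteKey("chr11", 121250381, "G", "T"),
        "region": "SORL1", "location": ("intergenic", None),
        "counts": {
            "mutect2": {"blood": (394, 0), "brain": (467, 7), "aaf_pct": (0.0, 1.0)},
            "strelka2": {"blood": (394, 0), "brain": (473, 7), "aaf_pct": (0.0, 1.5)},
            "varscan2": {"blood": (393, 0), "brain": (472, 7), "aaf_pct": (0.0, 1.5)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "11/12",
        "key": SiteKey("chr11", 121363100, "C", "A"),
        "region": "SORL1", "location": ("intron", "SORL1"),
        "counts": {
            "mutect2": {"blood": (609, 1), "brain": (209, 6), "aaf_pct": (0.0, 2.6)},
            "strelka2": {"blood": (614, 1), "brain": (222, 6), "aaf_pct": (0.0, 2.6)},
            "varscan2": {"blood": (612, 0), "brain": (221, 6), "aaf_pct": (0.0, 2.6)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("PASS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "27/28",
        "key": SiteKey("chr11", 121401561, "A", "G"),
        "region": "SORL1", "location": ("intron", "SORL1"),
        "counts": {
            "mutect2": {"blood": (880, 0), "brain": (391, 6), "aaf_pct": (0.0, 1.1)},
            "strelka2": {"blood": (882, 0), "brain": (392, 6), "aaf_pct": (0.0, 1.5)},
            "varscan2": {"blood": (876, 0), "brain": (389, 6), "aaf_pct": (0.0, 1.5)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "11/12",
        "key": SiteKey("chr21", 27421506, "G", "T"),
        "region": "APP", "location": ("intron", "APP"),
        "counts": {
            "mutect2": {"blood": (696, 0), "brain": (371, 5), "aaf_pct": (0.0, 1.0)},
            "strelka2": {"blood": (704, 0), "brain": (428, 5), "aaf_pct": (0.0, 1.1)},
            "varscan2": {"blood": (697, 0), "brain": (427, 5), "aaf_pct": (0.0, 1.2)},
        },
        "comments": {
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
    {
        "group": "EOAD", "individual": "11/12",
        "key": SiteKey("chr21", 27489758, "G", "A"),
        "region": "APP", "location": ("intron", "APP"),
        "counts": {
            "mutect2": {"blood": (987, 0), "brain": (579, 6), "aaf_pct": (0.0, 0.7)},
            "strelka2": {"blood": (987, 0), "brain": (594, 6), "aaf_pct": (0.0, 1.0)},
            "varscan2": {"blood": (979, 0), "brain": (585, 6), "aaf_pct": (0.0, 1.0)},
        },
        "comments": {
            "mutect1": ("fstar_tumor_lod", "possible_contamination"),
            "mutect2": ("t_lod_fstar",),
            "strelka2": ("LowEVS",),
            "varscan2": ("PASS",),
        },
    },
]

#: ddPCR validation measurements (fractional abundance %, 95% CI %, input mass
#: ng, instrument-reported total haploid copies, printed "1 in X").  ``None``
#: marks assays not run or not detected.
DDPCR_VALIDATION = [
    {
        "individual": "19/20", "group": "LOAD", "snv": "chr1:207461994C>T",
        "region": "CR1", "caller_support": "all_four",
        "brain": {"fa_pct": 0.39, "ci_pct": (0.31, 0.47), "mass_ng": 151,
                  "haploid_copies": 45740, "one_in_x": 256},
        "blood": {"fa_pct": 0.0, "ci_pct": None, "mass_ng": 167,
                  "haploid_copies": 50725, "one_in_x": None},
    },
    {
        "individual": "1/2", "group": "LOAD", "snv": "chr8:26930598T>C",
        "region": "CLU/PTK2B", "caller_support": "mutect1+mutect2",
        "brain": {"fa_pct": 0.106, "ci_pct": (0.061, 0.145), "mass_ng": 215,
                  "haploid_copies": 65268, "one_in_x": 943},
        "blood": {"fa_pct": 0.097, "ci_pct": (0.05, 0.15), "mass_ng": 96,
                  "haploid_copies": 28988, "one_in_x": 1031},
    },
    {
        "individual": "21/22", "group": "control", "snv": "chr2:127905153G>T",
        "region": "BIN1", "caller_support": "mutect1+mutect2",
        "brain": {"fa_pct": 0.0, "ci_pct": None, "mass_ng": 88,
                  "haploid_copies": 20287, "one_in_x": None},
        "blood": None,
    },
    {
        "individual": "21/22", "group": "control", "snv": "chr11:121034807G>T",
        "region": "SORL1", "caller_support": "mutect1+varscan2",
        "brain": {"fa_pct": 0.0, "ci_pct": None, "mass_ng": 84,
                  "haploid_copies": 19288, "one_in_x": None},
        "blood": None,
    },
    {
        "individual": "25/26", "group": "EOAD", "snv": "chr11:121332780G>T",
        "region": "SORL1", "caller_support": "mutect1+mutect2",
        "brain": {"fa_pct": 0.0, "ci_pct": None, "mass_ng": 12,
                  "haploid_copies": 3681.8, "one_in_x": None},
        "blood": None,
    },
    {
        "individual": "23/24", "group": "control", "snv": "chr11:121415560G>T",
        "region": "SORL1", "caller_support": "mutect1+mutect2",
        "brain": {"fa_pct": 0.0, "ci_pct": None, "mass_ng": 34,
                  "haploid_copies": 10060, "one_in_x": None},
        "blood": None,
    },
]


def load_reported_snvs() -> pd.DataFrame:
    """Long-format DataFrame of the reported SNVs: one row per (site, caller)."""
    rows = []
    for rec in REPORTED_SNVS:
        for caller in CALLERS:
            cc = rec["counts"].get(caller)
            if cc is None:
                continue
            blood_ref, blood_alt = cc["blood"]
            brain_ref, brain_alt = cc["brain"]
            k = rec["key"]
            rows.append(
                {
                    "group": rec["group"],
                    "individual": rec["individual"],
                    "chrom": k.chrom,
                    "pos": k.pos,
                    "ref": k.ref,
                    "alt": k.alt,
                    "region": rec["region"],
                    "location_category": rec["location"][0],
                    "location_label": rec["location"][1],
                    "caller": caller,
                    "blood_ref": blood_ref,
                    "blood_alt": blood_alt,
                    "brain_ref": brain_ref,
                    "brain_alt": brain_alt,
                    "printed_blood_aaf_pct": cc["aaf_pct"][0],
                    "printed_brain_aaf_pct": cc["aaf_pct"][1],
                    "derived_brain_aaf_pct": round(
                        100 * brain_alt / (brain_ref + brain_alt), 1
                    ),
                    "comments": ",".join(rec["comments"].get(caller, ())),
                }
            )
    return pd.DataFrame(rows)


def reported_callsets():
    """The reported cohort as per-caller CallSets ready for the pipeline."""
    by_caller: dict = {c: [] for c in CALLERS}
    for rec in REPORTED_SNVS:
        for caller in CALLERS:
            cc = rec["counts"].get(caller)
            if cc is None:
                continue
            by_caller[caller].append(
                SiteCall(
                    key=rec["key"],
                    individual=rec["individual"],
                    caller=caller,
                    brain_ref=cc["brain"][0],
                    brain_alt=cc["brain"][1],
                    blood_ref=cc["blood"][0],
                    blood_alt=cc["blood"][1],
                    comments=frozenset(rec["comments"].get(caller, ())),
                )
            )
    return [
        CallSet(caller, calls, {"source": "bundled reference cohort"})
        for caller, calls in by_caller.items()
        if calls
    ]


def individual_groups() -> dict:
    """Map sample-pair label -> cohort group for the reported SNV cohort."""
    return {rec["individual"]: rec["group"] for rec in REPORTED_SNVS}
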