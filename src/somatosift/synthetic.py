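"""Synthetic paired brain/blood cohort generator with known ground truth.

Emulates the statistical structure of an ultra-deep (~700x) targeted
brain/blood sequencing study so that every pipeline stage is testable without
external data:

* per-site sequencing depth from a negative-binomial model whose
  across-individual spread matches a mean +/- SEM coverage report;
* rare somatic SNVs confined to brain at 0.4-3% allele frequency;
* germline heterozygotes (true AAF 0.5 in both tissues) with a multiplicative
  capture allelic-imbalance bias deflating the brain alt fraction;
* independent per-read sequencing noise in unaffected tissue;
* four emulated caller profiles with logistic detection-sensitivity curves in
  brain alt depth, caller-specific false-positive rates, and injected
  MuTect-style FILTER comments.

Everything is deterministic under a fixed seed, and each generated cohort
carries a truth table for recovery evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset_io import CallSet, SiteCall, SiteKey
from .errors import ConfigurationError, UndefinedInputError
from .somatic_filter import FilterThresholds, POSSIBLE, TISSUE_SPECIFIC

SOMATIC_BRAIN = "somatic_brain"
GERMLINE_HET = "germline_het"
ARTIFACT = "artifact"

_BASES = np.array(list("ACGT"))

#: Per-site depth coefficient of variation within an individual (capture
#: efficiency varies along the target; 15% is typical for hybrid capture).
SITE_DEPTH_CV = 0.15

COUNT_COLUMNS = [
    "individual", "group", "chrom", "pos", "ref", "alt", "class",
    "true_brain_aaf", "true_blood_aaf", "capture_bias",
    "brain_ref", "brain_alt", "blood_ref", "blood_alt",
]


@dataclass(frozen=True)
class CallerProfile:
    """Detection behavior of one emulated caller.

    ``sens_midpoint``/``sens_scale`` parameterize a logistic detection
    probability in brain alt read count; ``fp_per_mb`` is the expected number
    of fabricated calls per megabase per individual; ``comment_probs`` maps
    FILTER comment strings to independent injection probabilities.
    """

    sens_midpoint: float = 5.0
    sens_scale: float = 1.0
    fp_per_mb: float = 0.0
    fp_alt_range: tuple = (3, 9)  # half-open [low, high)
    comment_probs: tuple = ()     # ((comment, prob), ...)

    def detection_prob(self, brain_alt) -> np.ndarray:
        """Logistic sensitivity curve; a caller never reports 0-alt sites."""
        from scipy.special import expit

        x = (np.asarray(brain_alt, dtype=float) - self.sens_midpoint) / self.sens_scale
        return np.where(np.asarray(brain_alt) >= 1, expit(x), 0.0)


def default_caller_profiles() -> dict:
    """Profiles loosely mirroring the relative raw-call yields of the four
    callers (MuTect2 most permissive, MuTect1 most conservative)."""
    return {
        "mutect1": CallerProfile(
            sens_midpoint=9.0, sens_scale=1.5, fp_per_mb=15.0,
            comment_probs=(
                ("possible_contamination", 0.8),
                ("fstar_tumor_lod", 0.7),
                ("clustered_events", 0.02),
                ("strand_artifact", 0.02),
            ),
        ),
        "mutect2": CallerProfile(
            sens_midpoint=4.5, sens_scale=1.0, fp_per_mb=220.0,
            comment_probs=(
                ("t_lod_fstar", 0.8),
                ("clustered_events", 0.03),
                ("poor_mapping_region", 0.01),
            ),
        ),
        "strelka2": CallerProfile(
            sens_midpoint=6.0, sens_scale=1.2, fp_per_mb=60.0,
            comment_probs=(("LowEVS", 0.9),),
        ),
        "varscan2": CallerProfile(
            sens_midpoint=4.5, sens_scale=1.0, fp_per_mb=180.0,
            comment_probs=(),
        ),
    }


def perfect_caller_profiles() -> dict:
    """Degenerate profiles: every caller detects any site with >= 1 alt read,
    fabricates nothing and injects no comments.  The noise-free limit used by
    recovery calibration."""
    ideal = CallerProfile(sens_midpoint=-1e3, sens_scale=1.0, fp_per_mb=0.0)
    return {c: ideal for c in ("mutect1", "mutect2", "strelka2", "varscan2")}


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the cohort the pipeline was designed around: 14 retained
    sample pairs (4 EOAD + 4 LOAD + 6 controls), ~698x mean depth with +/-23
    SEM-scale spread across individuals, somatic brain-only SNVs at 0.4-3%
    AAF in AD individuals, and a 100 kb working region (a scaled-down stand-in
    for the 2.86 Mb capture design; configurable up to full scale).
    """

    groups: tuple = ("EOAD",) * 4 + ("LOAD",) * 4 + ("control",) * 6
    depth_mean: float = 698.0
    depth_dispersion: float = 23.0  # SEM-scale across-individual spread
    n_germline_het: int = 60
    n_somatic: int = 2              # per AD (non-control) individual
    somatic_aaf_range: tuple = (0.004, 0.03)
    error_rate: float = 2e-4
    imbalance_strength: float = 0.5  # SD of the unit-mean capture-bias factor
    bias_somatic_sites: bool = False
    n_background: int = 100          # monitored noise-only positions per individual
    region_size: int = 100_000
    chrom: str = "chr1"
    seed: int = 0
    caller_profiles: dict = field(default_factory=default_caller_profiles)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("cohort must have at least one individual")
        if not all(g in ("EOAD", "LOAD", "control") for g in self.groups):
            raise ConfigurationError("group labels must be EOAD/LOAD/control")
        lo, hi = self.somatic_aaf_range
        if not (0 < lo <= hi < 0.2):
            raise ConfigurationError("somatic_aaf_range must lie within (0, 0.2)")
        if not 0 <= self.error_rate <= 1:
            raise ConfigurationError("error_rate must be in [0, 1]")
        if self.imbalance_strength < 0:
            raise ConfigurationError("imbalance_strength must be >= 0")
        if self.depth_mean <= 0 or self.region_size < 10:
            raise ConfigurationError("depth_mean and region_size must be positive")
        needed = self.n_germline_het * 3 + len(self.groups) * (
            self.n_somatic + self.n_background
        )
        if needed > self.region_size:
            raise ConfigurationError(
                f"region_size={self.region_size} too small for the requested "
                f"number of planted sites (~{needed})"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.groups)

    def individuals(self) -> list:
        """Deterministic (id, group) labels: ind01..indNN."""
        return [
            (f"ind{i + 1:02d}", group) for i, group in enumerate(self.groups)
        ]


@dataclass
class RecoveryMetrics:
    """Recovery of the planted truth by the pipeline."""

    sensitivity: float | None  # over detectable planted somatic sites
    fdr: float | None          # over possible/tissue_specific calls
    n_detectable: int
    n_recovered: int
    n_positive_calls: int
    n_false_positive_calls: int
    confusion: dict = field(default_factory=dict)  # (true class, predicted) -> n


# ---------------------------------------------------------------------------
# Site allocation (cohort-level, so somatic positions never collide)
# ---------------------------------------------------------------------------

def _allocate_sites(params: SimParams, rng: np.random.Generator) -> dict:
    """Assign distinct genomic positions to the planted-site pools.

    Germline heterozygous sites are drawn per individual from a shared
    polymorphic-position panel (population SNPs recur across individuals);
    somatic positions are unique cohort-wide (a true somatic event is private,
    and criterion vi would otherwise discard colliding plants as recurrent);
    background positions are private noise-monitoring positions.
    """
    n_ind = params.n_individuals
    n_ad = sum(1 for g in params.groups if g != "control")
    panel_size = max(2 * params.n_germline_het, params.n_germline_het + 10)
    total = panel_size + n_ad * params.n_somatic + n_ind * params.n_background
    positions = rng.choice(params.region_size, size=total, replace=False) + 1
    refs = _BASES[rng.integers(0, 4, size=total)]
    alts = np.array(
        [_BASES[(np.flatnonzero(_BASES != r))[rng.integers(0, 3)]] for r in refs]
    )
    keys = [
        SiteKey(params.chrom, int(p), str(r), str(a))
        for p, r, a in zip(positions, refs, alts)
    ]
    i = panel_size
    somatic: dict = {}
    background: dict = {}
    for ind, group in params.individuals():
        if group != "control":
            somatic[ind] = keys[i : i + params.n_somatic]
            i += params.n_somatic
        else:
            somatic[ind] = []
    for ind, _ in params.individuals():
        background[ind] = keys[i : i + params.n_background]
        i += params.n_background
    return {"panel": keys[:panel_size], "somatic": somatic, "background": background}


def _draw_depth(n: int, individual_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site depth: negative binomial with per-site CV ~ SITE_DEPTH_CV."""
    m = max(individual_mean, 1.0)
    k = 1.0 / SITE_DEPTH_CV**2  # NB size; var = m + m^2/k
    depth = rng.negative_binomial(k, k / (k + m), size=n)
    return np.maximum(depth, 1)


def _capture_bias(n: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean gamma multiplicative capture-efficiency factor for the alt allele."""
    if strength == 0:
        return np.ones(n)
    shape = 1.0 / strength**2
    return rng.gamma(shape, 1.0 / shape, size=n)


def _biased_aaf(true_aaf: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Relative capture efficiency b of the alt allele shifts the sampled
    fraction to b*p / (b*p + (1-p)); unit-mean b still deflates on average
    (Jensen), matching the observed reference-ward brain imbalance."""
    num = bias * true_aaf
    return num / (num + (1.0 - true_aaf))


def simulate_pair_counts(
    params: SimParams,
    individual: str,
    allocation: dict | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the paired count table for one individual.

    Returns a DataFrame (one row per planted/monitored site) carrying both the
    realized brain/blood ref+alt counts and the ground-truth columns.  When
    called standalone (no cohort allocation), positions are allocated from
    ``params.seed`` exactly as :func:`simulate_cohort` would.
    """
    ids = dict(params.individuals())
    if individual not in ids:
        raise ConfigurationError(f"unknown individual {individual!r}")
    group = ids[individual]
    idx = [i for i, (ind, _) in enumerate(params.individuals()) if ind == individual][0]
    if allocation is None:
        allocation = _allocate_sites(
            params, np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1 + idx]))

    mean_i = params.depth_mean + params.depth_dispersion * math.sqrt(
        params.n_individuals
    ) * float(rng.standard_normal())
    mean_i = max(mean_i, 50.0)

    panel = allocation["panel"]
    het_idx = rng.choice(len(panel), size=params.n_germline_het, replace=False)
    het_keys = [panel[int(i)] for i in sorted(het_idx)]
    som_keys = allocation["somatic"][individual]
    bg_keys = allocation["background"][individual]

    keys = het_keys + list(som_keys) + list(bg_keys)
    classes = (
        [GERMLINE_HET] * len(het_keys)
        + [SOMATIC_BRAIN] * len(som_keys)
        + [ARTIFACT] * len(bg_keys)
    )
    n = len(keys)
    true_brain = np.zeros(n)
    true_blood = np.zeros(n)
    true_brain[: len(het_keys)] = 0.5
    true_blood[: len(het_keys)] = 0.5
    lo, hi = params.somatic_aaf_range
    n_som = len(som_keys)
    true_brain[len(het_keys) : len(het_keys) + n_som] = rng.uniform(lo, hi, size=n_som)

    bias = np.ones(n)
    is_het = np.array([c == GERMLINE_HET for c in classes])
    bias[is_het] = _capture_bias(int(is_het.sum()), params.imbalance_strength, rng)
    if params.bias_somatic_sites:
        is_som = np.array([c == SOMATIC_BRAIN for c in classes])
        bias[is_som] = _capture_bias(int(is_som.sum()), params.imbalance_strength, rng)

    brain_depth = _draw_depth(n, mean_i, rng)
    blood_depth = _draw_depth(n, mean_i, rng)
    brain_p = np.clip(_biased_aaf(true_brain, bias) + params.error_rate, 0.0, 1.0)
    blood_p = np.clip(true_blood + params.error_rate, 0.0, 1.0)
    brain_alt = rng.binomial(brain_depth, brain_p)
    blood_alt = rng.binomial(blood_depth, blood_p)

    return pd.DataFrame(
        {
            "individual": individual,
            "group": group,
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "class": classes,
            "true_brain_aaf": true_brain,
            "true_blood_aaf": true_blood,
            "capture_bias": bias,
            "brain_ref": brain_depth - brain_alt,
            "brain_alt": brain_alt,
            "blood_ref": blood_depth - blood_alt,
            "blood_alt": blood_alt,
        }
    )[COUNT_COLUMNS]


def simulate_cohort(params: SimParams) -> pd.DataFrame:
    """Simulate count tables for the whole cohort (deterministic under seed)."""
    alloc_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    allocation = _allocate_sites(params, alloc_rng)
    tables = [
        simulate_pair_counts(params, ind, allocation=allocation)
        for ind, _ in params.individuals()
    ]
    df = pd.concat(tables, ignore_index=True)
    return df.sort_values(["individual", "chrom", "pos"], kind="stable").reset_index(
        drop=True
    )


def truth_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth view of a generated count table (planted sites only)."""
    cols = [
        "individual", "group", "chrom", "pos", "ref", "alt", "class",
        "true_brain_aaf", "true_blood_aaf",
    ]
    return counts.loc[counts["class"] != ARTIFACT, cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------

def _sample_comments(profile: CallerProfile, rng: np.random.Generator) -> frozenset:
    out = [c for c, p in profile.comment_probs if rng.random() < p]
    return frozenset(out) if out else frozenset({"PASS"})


def emulate_callers(
    counts: pd.DataFrame,
    params: SimParams,
    seed: int | None = None,
) -> dict:
    """Emulate the four callers on a generated count table.

    Each caller reports a site with its logistic detection probability in the
    realized brain alt count (never reporting alt-free sites), fabricates
    false-positive calls at its per-Mb rate with low alt counts, and injects
    FILTER comments.  Returns caller -> CallSet spanning the cohort; each
    CallSet's provenance records its fabricated (individual, site) pairs.
    """
    if seed is None:
        seed = params.seed
    callsets = {}
    for ci, (caller, profile) in enumerate(sorted(params.caller_profiles.items())):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + ci]))
        calls = []
        detect_p = profile.detection_prob(counts["brain_alt"].to_numpy())
        detected = rng.random(len(counts)) < detect_p
        for row in counts.loc[detected].itertuples():
            calls.append(
                SiteCall(
                    key=SiteKey(row.chrom, int(row.pos), row.ref, row.alt),
                    individual=row.individual,
                    caller=caller,
                    brain_ref=int(row.brain_ref),
                    brain_alt=int(row.brain_alt),
                    blood_ref=int(row.blood_ref),
                    blood_alt=int(row.blood_alt),
                    comments=_sample_comments(profile, rng),
                )
            )
        # caller-private false positives at noise-level blood, low brain alt
        fp_records = []
        expected_fp = profile.fp_per_mb * params.region_size / 1e6
        taken = {
            (ind, pos)
            for ind, pos in zip(counts["individual"], counts["pos"])
        }
        for ind, _group in params.individuals():
            n_fp = int(rng.poisson(expected_fp))
            for _ in range(n_fp):
                pos = int(rng.integers(1, params.region_size + 1))
                if (ind, pos) in taken:
                    continue
                taken.add((ind, pos))
                ref = str(_BASES[rng.integers(0, 4)])
                alt = str(_BASES[(np.flatnonzero(_BASES != ref))[rng.integers(0, 3)]])
                depth = int(
                    _draw_depth(1, params.depth_mean, rng)[0]
                )
                lo, hi = profile.fp_alt_range
                brain_alt = min(int(rng.integers(lo, hi)), depth)
                blood_depth = int(_draw_depth(1, params.depth_mean, rng)[0])
                key = SiteKey(params.chrom, pos, ref, alt)
                calls.append(
                    SiteCall(
                        key=key,
                        individual=ind,
                        caller=caller,
                        brain_ref=depth - brain_alt,
                        brain_alt=brain_alt,
                        blood_ref=blood_depth,
                        blood_alt=0,
                        comments=_sample_comments(profile, rng),
                    )
                )
                fp_records.append((ind, str(key)))
        callsets[caller] = CallSet(
            caller,
            calls,
            provenance={
                "source": "synthetic",
                "n_detected": int(detected.sum()),
                "n_false_positives": len(fp_records),
                "fp_sites": fp_records,
            },
        ).deduplicate()
    return callsets


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(
    results,
    counts: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> RecoveryMetrics:
    """Compare pipeline consensus results against the generator's truth.

    A planted somatic site is *detectable* iff its realized counts satisfy
    criteria i-iii (depth, brain alt reads, AAF bounds) — a site the data do
    not support cannot be asked of any caller.  Sensitivity is the fraction of
    detectable planted somatic sites classified possible/tissue_specific; FDR
    is the fraction of possible/tissue_specific calls that are not truly
    somatic.
    """
    truth_inds = set(counts["individual"])
    result_inds = {r.individual for r in results}
    if not result_inds <= truth_inds:
        raise UndefinedInputError(
            f"results cover individuals {sorted(result_inds - truth_inds)} "
            "absent from the truth table"
        )
    t = thresholds
    som = counts[counts["class"] == SOMATIC_BRAIN]
    brain_depth = som["brain_ref"] + som["brain_alt"]
    blood_depth = som["blood_ref"] + som["blood_alt"]
    brain_aaf = som["brain_alt"] / brain_depth.clip(lower=1)
    blood_aaf = som["blood_alt"] / blood_depth.clip(lower=1)
    detectable = (
        (brain_depth >= t.min_depth)
        & (blood_depth >= t.min_depth)
        & (som["brain_alt"] >= t.min_brain_alt)
        & (brain_aaf < t.max_aaf)
        & (blood_aaf < t.max_aaf)
    )
    detectable_ids = {
        (r.individual, r.chrom, int(r.pos), r.ref, r.alt)
        for r in som.loc[detectable].itertuples()
    }
    somatic_ids = {
        (r.individual, r.chrom, int(r.pos), r.ref, r.alt)
        for r in som.itertuples()
    }
    class_by_id = {
        (r.individual, r.chrom, int(r.pos), r.ref, r.alt): r.cls
        for r in counts.rename(columns={"class": "cls"}).itertuples()
    }

    positive = [
        r for r in results if r.classification in (POSSIBLE, TISSUE_SPECIFIC)
    ]
    recovered = 0
    false_pos = 0
    confusion: dict = {}
    for r in results:
        rid = (r.individual, r.key.chrom, r.key.pos, r.key.ref, r.key.alt)
        true_cls = class_by_id.get(rid, "none")
        confusion[(true_cls, r.classification)] = (
            confusion.get((true_cls, r.classification), 0) + 1
        )
    for r in positive:
        rid = (r.individual, r.key.chrom, r.key.pos, r.key.ref, r.key.alt)
        if rid in somatic_ids:
            if rid in detectable_ids:
                recovered += 1
        else:
            false_pos += 1
    n_detectable = len(detectable_ids)
    sensitivity = recovered / n_detectable if n_detectable else None
    fdr = false_pos / len(positive) if positive else 0.0
    return RecoveryMetrics(
        sensitivity=sensitivity,
        fdr=fdr,
        n_detectable=n_detectable,
        n_recovered=recovered,
        n_positive_calls=len(positive),
        n_false_positive_calls=false_pos,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Synthetic VCF output (uniform dialect, lossless round trip)
# ---------------------------------------------------------------------------

def write_synthetic_vcfs(callsets: dict, directory, region_size: int = 100_000):
    """Write one VCF per (individual, caller) in the uniform synthetic dialect.

    Samples are named BRAIN and BLOOD; counts go in the AD field; comments
    become FILTER entries (spaces normalized to underscores).  Returns
    {(individual, caller): path}.
    """
    import pysam
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for caller in sorted(callsets):
        cs = callsets[caller]
        by_ind: dict = {}
        for c in cs.calls:
            by_ind.setdefault(c.individual, []).append(c)
        for ind in sorted(by_ind):
            calls = sorted(by_ind[ind], key=lambda c: (c.key.chrom, c.key.pos))
            path = directory / f"{ind}.{caller}.vcf"
            header = pysam.VariantHeader()
            chroms = sorted({c.key.chrom for c in calls}) or ["chr1"]
            max_pos = max((c.key.pos for c in calls), default=1)
            for chrom in chroms:
                header.contigs.add(chrom, length=max(region_size, max_pos + 1))
            header.formats.add("GT", 1, "String", "Genotype")
            header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
            header.formats.add("DP", 1, "Integer", "Read depth")
            filters = sorted(
                {
                    cm.replace(" ", "_")
                    for c in calls
                    for cm in c.comments
                    if cm != "PASS"
                }
            )
            for f in filters:
                header.filters.add(f, None, None, "caller comment (synthetic)")
            header.add_sample("BRAIN")
            header.add_sample("BLOOD")
            with pysam.VariantFile(str(path), "w", header=header) as out:
                for c in calls:
                    rec = out.new_record(
                        contig=c.key.chrom,
                        start=c.key.pos - 1,
                        alleles=(c.key.ref, c.key.alt),
                    )
                    rec.samples["BRAIN"]["GT"] = (0, 1)
                    rec.samples["BRAIN"]["AD"] = (c.brain_ref, c.brain_alt)
                    rec.samples["BRAIN"]["DP"] = c.brain_ref + c.brain_alt
                    rec.samples["BLOOD"]["GT"] = (0, 0)
                    rec.samples["BLOOD"]["AD"] = (c.blood_ref, c.blood_alt)
                    rec.samples["BLOOD"]["DP"] = c.blood_ref + c.blood_alt
                    comments = {cm.replace(" ", "_") for cm in c.comments}
                    if comments == {"PASS"} or not comments:
                        rec.filter.add("PASS")
                    else:
                        for cm in sorted(comments - {"PASS"}):
                            rec.filter.add(cm)
                    out.write(rec)
            written[(ind, caller)] = path
    return written
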