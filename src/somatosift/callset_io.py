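"""Read, normalize and mask per-caller variant call sets.

Variant calls from the four somatic callers (MuTect1, MuTect2, Strelka2,
Varscan2 — each with its own VCF dialect for per-sample allele counts) are
harmonized into :class:`SiteCall` records carrying brain/blood ref and alt
read counts.  A uniform ``synthetic`` dialect (plain AD field) is used by the
cohort simulator.  Caller FILTER values are retained as free-text comments and
are *never* used to reject records at read time; rejection happens only via
the explicit MuTect comment exclusion list and the genomic mask.

Coordinate conventions: VCF and all internal positions are 1-based; BED masks
are 0-based half-open.  Conversion happens only at the mask boundary.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field, replace

import pysam

from .errors import BedFormatError, ConfigurationError, VcfFormatError

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

#: Callers whose allele counts live in a (ref, alt) allelic-depth FORMAT field.
AD_DIALECTS = frozenset({"mutect1", "mutect2", "synthetic"})
KNOWN_DIALECTS = frozenset({"mutect1", "mutect2", "strelka2", "varscan2", "synthetic"})

#: MuTect comment strings that trigger exclusion (matched case-insensitively,
#: spaces and underscores interchangeable).
DEFAULT_EXCLUDE_COMMENTS = (
    "clustered events",
    "poor mapping region",
    "nearby gap",
    "triallelic sites",
    "strand artifact",
)

#: Callers the comment-exclusion rule applies to.
DEFAULT_EXCLUDE_CALLERS = frozenset({"mutect1", "mutect2"})

_TUMOR_NAMES = frozenset({"tumor", "brain"})
_NORMAL_NAMES = frozenset({"normal", "blood"})


@dataclass(frozen=True)
class SiteKey:
    """A single-nucleotide variant locus: chrom, 1-based pos, ref>alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # e.g. "chr1:207461994C>T"
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


_CHROM_NUM = re.compile(r"^(?:chr)?(\d+|[XYM]T?)$", re.IGNORECASE)
_CHROM_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def genome_order_key(key: SiteKey) -> tuple:
    """Sort key giving natural genome order (chr1 < chr2 < chr11 < chrX)."""
    m = _CHROM_NUM.match(key.chrom)
    if m:
        tok = m.group(1).upper()
        rank = (0, _CHROM_SPECIAL.get(tok) or int(tok))
    else:
        rank = (1, key.chrom)  # type: ignore[assignment]
    return (rank, key.pos, key.ref, key.alt)


@dataclass(frozen=True)
class SiteCall:
    """One caller's brain/blood allele counts at one site for one individual."""

    key: SiteKey
    individual: str
    caller: str
    brain_ref: int
    brain_alt: int
    blood_ref: int
    blood_alt: int
    comments: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("brain_ref", "brain_alt", "blood_ref", "blood_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.brain_ref + self.brain_alt < 1:
            raise ValueError(f"zero brain depth at {self.key}")


@dataclass
class CallSet:
    """All harmonized calls from one caller, with provenance bookkeeping."""

    caller: str
    calls: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def deduplicate(self) -> "CallSet":
        """Drop duplicate (individual, SiteKey) entries, keeping the first."""
        seen: set = set()
        out = []
        for c in self.calls:
            k = (c.individual, c.key)
            if k not in seen:
                seen.add(k)
                out.append(c)
        prov = dict(self.provenance)
        prov["duplicates_removed"] = len(self.calls) - len(out)
        return CallSet(self.caller, out, prov)


class GenomicMask:
    """Per-chromosome sorted, merged 0-based half-open intervals.

    Membership queries are deterministic; overlapping input intervals are
    merged at construction.
    """

    def __init__(self, intervals_by_chrom: dict | None = None) -> None:
        self._starts: dict = {}
        self._ends: dict = {}
        for chrom, ivals in (intervals_by_chrom or {}).items():
            merged = _merge_intervals(ivals)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @property
    def chroms(self) -> set:
        return set(self._starts)

    def intervals(self, chrom: str) -> list:
        return list(zip(self._starts.get(chrom, []), self._ends.get(chrom, [])))

    def total_length(self) -> int:
        return sum(
            e - s for c in self._starts for s, e in zip(self._starts[c], self._ends[c])
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 1-based ``pos`` falls in a mask interval (start <= pos-1 < end)."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p0 = pos - 1
        i = bisect.bisect_right(starts, p0) - 1
        return i >= 0 and p0 < self._ends[chrom][i]


def _merge_intervals(ivals) -> list:
    ivals = sorted((int(s), int(e)) for s, e in ivals)
    merged: list = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _identify_samples(samples, tumor_sample, normal_sample, path):
    """Map the VCF sample columns to (tumor=brain, normal=blood)."""
    samples = list(samples)
    if len(samples) < 2:
        raise VcfFormatError(
            f"{path}: expected two sample columns (brain/tumor and blood/normal), "
            f"found {samples!r}"
        )
    lower = {s.lower(): s for s in samples}
    tumor = tumor_sample
    normal = normal_sample
    if tumor is None:
        for name in _TUMOR_NAMES:
            if name in lower:
                tumor = lower[name]
                break
    if normal is None:
        for name in _NORMAL_NAMES:
            if name in lower:
                normal = lower[name]
                break
    if tumor is None and normal is not None and len(samples) == 2:
        tumor = next(s for s in samples if s != normal)
    if normal is None and tumor is not None and len(samples) == 2:
        normal = next(s for s in samples if s != tumor)
    if tumor is None or normal is None or tumor == normal:
        raise VcfFormatError(
            f"{path}: cannot identify tumor/normal columns among {samples!r}; "
            "pass tumor_sample=/normal_sample= explicitly"
        )
    for s in (tumor, normal):
        if s not in samples:
            raise VcfFormatError(f"{path}: sample {s!r} not in VCF columns {samples!r}")
    return tumor, normal


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return int(value[0])
    return int(value)


def _extract_counts(rec, sample, dialect, ref, alt):
    """Return (ref_count, alt_count) for one sample per the dialect rule."""
    fmt = rec.samples[sample]
    if dialect in AD_DIALECTS:
        ad = fmt.get("AD")
        if ad is None or ad[0] is None:
            raise VcfFormatError(f"missing AD field for sample {sample}")
        return int(ad[0]), int(ad[1])
    if dialect == "varscan2":
        rd = fmt.get("RD")
        ad = fmt.get("AD")
        if rd is None or ad is None:
            raise VcfFormatError(f"missing RD/AD fields for sample {sample}")
        return _scalar(rd), _scalar(ad)
    if dialect == "strelka2":
        ref_tier = fmt.get(f"{ref}U")
        alt_tier = fmt.get(f"{alt}U")
        if ref_tier is None or alt_tier is None:
            raise VcfFormatError(f"missing {ref}U/{alt}U tier counts for sample {sample}")
        return int(ref_tier[0]), int(alt_tier[0])
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def read_vcf_calls(
    path,
    dialect: str,
    individual: str,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> CallSet:
    """Read a paired tumor(brain)/normal(blood) VCF into a harmonized CallSet.

    One :class:`SiteCall` is produced per biallelic SNV record; multiallelic
    records and indels are skipped (counted in provenance).  All FILTER values
    are retained verbatim as comments and never cause rejection here.
    """
    path = str(path)
    if dialect not in KNOWN_DIALECTS:
        raise ConfigurationError(
            f"unknown caller dialect {dialect!r}; expected one of {sorted(KNOWN_DIALECTS)}"
        )
    calls: list = []
    skipped_non_snv = 0
    with pysam.VariantFile(path) as vf:
        tumor, normal = _identify_samples(
            vf.header.samples, tumor_sample, normal_sample, path
        )
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in BASES
                or alts[0].upper() not in BASES
            ):
                skipped_non_snv += 1
                continue
            key = SiteKey(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper())
            brain_ref, brain_alt = _extract_counts(rec, tumor, dialect, key.ref, key.alt)
            blood_ref, blood_alt = _extract_counts(rec, normal, dialect, key.ref, key.alt)
            comments = frozenset(rec.filter.keys())
            if brain_ref + brain_alt < 1:
                skipped_non_snv += 1
                continue
            calls.append(
                SiteCall(
                    key=key,
                    individual=individual,
                    caller=dialect,
                    brain_ref=brain_ref,
                    brain_alt=brain_alt,
                    blood_ref=blood_ref,
                    blood_alt=blood_alt,
                    comments=comments,
                )
            )
    if skipped_non_snv:
        logger.info("%s: skipped %d non-SNV/zero-depth records", path, skipped_non_snv)
    cs = CallSet(
        caller=dialect,
        calls=calls,
        provenance={
            "source": path,
            "dialect": dialect,
            "skipped_non_snv": skipped_non_snv,
        },
    )
    return cs.deduplicate()


# ---------------------------------------------------------------------------
# Comment exclusion and masking
# ---------------------------------------------------------------------------

def _norm_comment(s: str) -> str:
    return s.lower().replace("_", " ")


def comment_matches(comment: str, patterns) -> bool:
    """Case-insensitive substring match, spaces/underscores interchangeable."""
    c = _norm_comment(comment)
    return any(_norm_comment(p) in c for p in patterns)


def exclude_commented_calls(
    callset: CallSet,
    patterns=DEFAULT_EXCLUDE_COMMENTS,
    applies_to=DEFAULT_EXCLUDE_CALLERS,
) -> CallSet:
    """Drop calls carrying an excludable caller comment.

    Only callers in ``applies_to`` (default: the MuTect callers) are subject to
    the rule; other call sets pass through unchanged.
    """
    if not patterns:
        raise ConfigurationError("comment exclusion pattern list must be non-empty")
    if callset.caller not in applies_to:
        prov = dict(callset.provenance)
        prov["comment_excluded"] = 0
        return CallSet(callset.caller, list(callset.calls), prov)
    kept = [
        c
        for c in callset.calls
        if not any(comment_matches(cm, patterns) for cm in c.comments)
    ]
    prov = dict(callset.provenance)
    prov["comment_excluded"] = len(callset.calls) - len(kept)
    return CallSet(callset.caller, kept, prov)


def apply_mask(callset: CallSet, mask: GenomicMask) -> CallSet:
    """Remove calls falling inside the genomic mask (e.g. segmental duplications).

    A 1-based call position ``pos`` is masked iff ``start <= pos-1 < end`` for
    some interval.  Chromosome names absent from the mask are passed through
    with a warning (naming-convention mismatches are surfaced, not guessed).
    """
    kept = []
    removed = 0
    unmatched_chroms: set = set()
    mask_chroms = mask.chroms
    for c in callset.calls:
        if mask_chroms and c.key.chrom not in mask_chroms:
            unmatched_chroms.add(c.key.chrom)
        if mask.contains(c.key.chrom, c.key.pos):
            removed += 1
        else:
            kept.append(c)
    if unmatched_chroms and mask_chroms:
        logger.warning(
            "mask has no intervals for chromosome(s) %s; no masking applied there "
            "(check chr-prefix conventions)",
            sorted(unmatched_chroms),
        )
    prov = dict(callset.provenance)
    prov["mask_removed"] = removed
    prov["mask_unmatched_chroms"] = sorted(unmatched_chroms)
    return CallSet(callset.caller, kept, prov)


def read_bed_mask(path) -> GenomicMask:
    """Load a 3+ column BED (0-based half-open) as a normalized GenomicMask."""
    intervals: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            intervals.setdefault(chrom, []).append((start, end))
    mask = GenomicMask(intervals)
    logger.info("%s: %d intervals, %d bp masked", path, len(mask), mask.total_length())
    return mask


# ---------------------------------------------------------------------------
# Candidate table output
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "individual",
    "classification",
    "n_supporting",
    "supporting_callers",
)
_PER_CALLER_COLUMNS = ("blood_ref", "blood_alt", "blood_aaf_pct", "brain_ref", "brain_alt", "brain_aaf_pct")


def write_candidates_tsv(results, path, callers=None) -> None:
    """Write consensus results as a TSV candidate table.

    Layout mirrors a per-caller blood/brain Ref/Alt + AAF(%) table: one row per
    (individual, site) with per-caller count and percent-AAF columns.  AAF is
    alt/(ref+alt) formatted with one decimal.  Missing caller verdicts are "na".
    """
    from .somatic_filter import aaf  # local import to avoid cycle

    if callers is None:
        seen = sorted({c for r in results for c in r.verdicts})
        callers = seen or ["mutect1", "mutect2", "strelka2", "varscan2"]
    header = list(CANDIDATE_COLUMNS)
    for caller in callers:
        header.extend(f"{caller}_{col}" for col in _PER_CALLER_COLUMNS)
    lines = ["\t".join(header)]
    for r in results:
        row = [
            r.key.chrom,
            str(r.key.pos),
            r.key.ref,
            r.key.alt,
            r.individual,
            r.classification,
            str(len(r.supporting_callers)),
            ",".join(sorted(r.supporting_callers)) or "na",
        ]
        for caller in callers:
            v = r.verdicts.get(caller)
            if v is None:
                row.extend(["na"] * len(_PER_CALLER_COLUMNS))
            else:
                c = v.counts
                row.extend(
                    [
                        str(c.blood_ref),
                        str(c.blood_alt),
                        f"{100 * aaf(c.blood_ref, c.blood_alt):.1f}"
                        if c.blood_ref + c.blood_alt else "na",
                        str(c.brain_ref),
                        str(c.brain_alt),
                        f"{100 * aaf(c.brain_ref, c.brain_alt):.1f}",
                    ]
                )
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_candidates_tsv(path):
    """Read back a candidate table written by :func:`write_candidates_tsv`."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
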