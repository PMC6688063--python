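"""Rare-event droplet digital PCR quantification.

A ddPCR reaction is partitioned into ~20,000 nanoliter droplets; template
copies distribute over droplets approximately Poisson, so the mean copies per
droplet in a channel is recovered from the fraction of positive droplets:

    lambda = -ln(1 - positive/accepted)

Replicate wells are merged (droplet counts summed) before estimation.  The
fractional abundance of the mutant allele is

    FA = lambda_mut / (lambda_mut + lambda_wt)

with a 95% CI from delta-method propagation of the binomial sampling variance
of each channel's positive fraction, var(lambda_hat) ~= p / (N (1 - p)).

QC follows rare-event detection practice: >= 3 merged mutant-positive
droplets, >= 10,000 accepted droplets per well and >= 10 ng input DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import QuantificationError, UndefinedInputError

#: QX200-style partition volume in nanoliters.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Mass of one diploid human genome in picograms.
PG_PER_DIPLOID_CELL = 6.6
PG_PER_HAPLOID_GENOME = 3.3

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DdpcrWell:
    """Droplet counts for one well: accepted total plus per-channel positives."""

    well_id: str
    accepted: int
    mut_positive: int
    wt_positive: int

    def __post_init__(self) -> None:
        if self.accepted < 1:
            raise ValueError("accepted droplets must be >= 1")
        for name in ("mut_positive", "wt_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.accepted:
                raise ValueError(f"{name}={v} outside [0, accepted={self.accepted}]")


@dataclass
class DdpcrAssay:
    """Merged-well assay for one sample: wells plus input DNA mass."""

    sample_id: str
    wells: list
    input_mass_ng: float
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if not self.wells:
            raise UndefinedInputError("a ddPCR assay needs at least one well")
        if self.input_mass_ng <= 0:
            raise ValueError("input mass must be > 0 ng")


class MergedCounts(NamedTuple):
    accepted: int
    mut_positive: int
    wt_positive: int


@dataclass
class QcVerdict:
    passed: bool
    reasons: list = field(default_factory=list)


@dataclass
class QuantResult:
    """Full quantification output for one assay."""

    sample_id: str
    merged: MergedCounts
    lambda_mut: float
    lambda_wt: float
    conc_mut: float  # copies/uL
    conc_wt: float
    fractional_abundance: float | None
    ci_low: float | None
    ci_high: float | None
    one_in_x: int | None
    qc: QcVerdict
    total_copies: float  # (lambda_mut + lambda_wt) * accepted droplets


def merge_wells(assay: DdpcrAssay) -> MergedCounts:
    """Sum accepted and per-channel positive droplets over replicate wells."""
    return MergedCounts(
        accepted=sum(w.accepted for w in assay.wells),
        mut_positive=sum(w.mut_positive for w in assay.wells),
        wt_positive=sum(w.wt_positive for w in assay.wells),
    )


def qc_check(
    assay: DdpcrAssay,
    min_positive: int = 3,
    min_accepted_per_well: int = 10_000,
    min_mass_ng: float = 10.0,
) -> QcVerdict:
    """Rare-event acceptance QC on the merged assay."""
    merged = merge_wells(assay)
    reasons = []
    if merged.mut_positive < min_positive:
        reasons.append(
            f"below minimum positive droplets ({merged.mut_positive} < {min_positive})"
        )
    for w in assay.wells:
        if w.accepted < min_accepted_per_well:
            reasons.append(
                f"well {w.well_id}: accepted droplets {w.accepted} < {min_accepted_per_well}"
            )
    if assay.input_mass_ng < min_mass_ng:
        reasons.append(
            f"input mass {assay.input_mass_ng} ng < {min_mass_ng} ng"
        )
    return QcVerdict(passed=not reasons, reasons=reasons)


def lambda_hat(positive: int, accepted: int) -> float:
    """Poisson mean copies per droplet from the positive droplet fraction."""
    if accepted < 1 or not 0 <= positive <= accepted:
        raise UndefinedInputError("need 0 <= positive <= accepted, accepted >= 1")
    if positive == accepted:
        raise QuantificationError(
            "all droplets positive (saturation): concentration unquantifiable, "
            "dilute the sample and repeat"
        )
    return -math.log1p(-positive / accepted)


def _lambda_var(positive: int, accepted: int) -> float:
    """Delta-method sampling variance of lambda_hat: p / (N (1 - p))."""
    p = positive / accepted
    return p / (accepted * (1.0 - p))


def fractional_abundance(
    lambda_mut: float,
    lambda_wt: float,
    merged: MergedCounts,
):
    """Mutant fractional abundance with a delta-method 95% CI.

    Returns (fa, ci_low, ci_high); the CI is clipped to [0, 1].  Raises if both
    channel rates are zero (FA undefined).
    """
    total = lambda_mut + lambda_wt
    if total <= 0:
        raise UndefinedInputError("fractional abundance undefined: no template detected")
    fa = lambda_mut / total
    var_m = _lambda_var(merged.mut_positive, merged.accepted)
    var_w = _lambda_var(merged.wt_positive, merged.accepted)
    # FA = m/(m+w): dFA/dm = w/(m+w)^2, dFA/dw = -m/(m+w)^2
    var_fa = (lambda_wt**2 * var_m + lambda_mut**2 * var_w) / total**4
    half = _Z95 * math.sqrt(var_fa)
    return fa, max(0.0, fa - half), min(1.0, fa + half)


def one_in_x(fa: float) -> int | None:
    """"1 in X" mutant-allele proportion: nearest integer to 1/FA.

    Half-way cases round away from zero; FA = 0 yields None (not detected).
    """
    if fa < 0 or fa > 1:
        raise UndefinedInputError("fractional abundance must be in [0, 1]")
    if fa == 0:
        return None
    x = 1.0 / fa
    return int(math.floor(x + 0.5))


def concentration(lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    """Copies per microliter from copies per droplet."""
    if droplet_volume_nl <= 0:
        raise UndefinedInputError("droplet volume must be > 0")
    return lam / droplet_volume_nl * 1000.0


def cells_from_mass(mass_ug: float, pg_per_cell: float = PG_PER_DIPLOID_CELL) -> int:
    """Number of diploid genome equivalents in ``mass_ug`` micrograms of DNA."""
    if mass_ug <= 0:
        raise UndefinedInputError("mass must be > 0")
    return int(mass_ug * 1e6 / pg_per_cell)


def haploid_copies_from_mass(
    mass_ng: float, pg_per_haploid: float = PG_PER_HAPLOID_GENOME
) -> int:
    """Haploid genome copies expected from ``mass_ng`` nanograms of DNA.

    This is the mass-derived expectation; instrument-reported totals are
    measured independently and may differ by a fraction of a percent.
    """
    if mass_ng <= 0:
        raise UndefinedInputError("mass must be > 0")
    return round(mass_ng * 1000.0 / pg_per_haploid)


def quantify(assay: DdpcrAssay) -> QuantResult:
    """Full merged-well quantification: lambdas, concentrations, FA + CI, QC."""
    merged = merge_wells(assay)
    qc = qc_check(assay)
    lam_m = lambda_hat(merged.mut_positive, merged.accepted)
    lam_w = lambda_hat(merged.wt_positive, merged.accepted)
    if lam_m + lam_w > 0:
        fa, lo, hi = fractional_abundance(lam_m, lam_w, merged)
        oix = one_in_x(fa)
    else:
        fa = lo = hi = None
        oix = None
    return QuantResult(
        sample_id=assay.sample_id,
        merged=merged,
        lambda_mut=lam_m,
        lambda_wt=lam_w,
        conc_mut=concentration(lam_m, assay.droplet_volume_nl),
        conc_wt=concentration(lam_w, assay.droplet_volume_nl),
        fractional_abundance=fa,
        ci_low=lo,
        ci_high=hi,
        one_in_x=oix,
        qc=qc,
        total_copies=(lam_m + lam_w) * merged.accepted,
    )


# ---------------------------------------------------------------------------
# Simulation (per-droplet Poisson occupancy) and CSV input
# ---------------------------------------------------------------------------

def simulate_assay(
    lambda_mut: float,
    lambda_wt: float,
    n_droplets_per_well: int,
    n_wells: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
    input_mass_ng: float = 50.0,
) -> DdpcrAssay:
    """Simulate an assay with Poisson droplet occupancy at known channel rates.

    A droplet is positive in a channel iff it received >= 1 copy, so the
    positive count per well is Binomial(N, 1 - exp(-lambda)).
    """
    if lambda_mut < 0 or lambda_wt < 0:
        raise UndefinedInputError("rates must be >= 0")
    p_mut = -math.expm1(-lambda_mut)
    p_wt = -math.expm1(-lambda_wt)
    wells = [
        DdpcrWell(
            well_id=f"{sample_id}_w{i + 1}",
            accepted=n_droplets_per_well,
            mut_positive=int(rng.binomial(n_droplets_per_well, p_mut)),
            wt_positive=int(rng.binomial(n_droplets_per_well, p_wt)),
        )
        for i in range(n_wells)
    ]
    return DdpcrAssay(sample_id=sample_id, wells=wells, input_mass_ng=input_mass_ng)


def read_wells_csv(path, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL):
    """Read a wells CSV into assays, one per sample_id.

    Expected columns: sample_id, well_id, accepted, mut_positive, wt_positive,
    input_mass_ng (constant within a sample).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_id", "well_id", "accepted", "mut_positive", "wt_positive", "input_mass_ng"}
    missing = required - set(df.columns)
    if missing:
        raise UndefinedInputError(f"{path}: missing columns {sorted(missing)}")
    assays = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        wells = [
            DdpcrWell(
                well_id=str(r.well_id),
                accepted=int(r.accepted),
                mut_positive=int(r.mut_positive),
                wt_positive=int(r.wt_positive),
            )
            for r in grp.itertuples()
        ]
        assays.append(
            DdpcrAssay(
                sample_id=str(sample_id),
                wells=wells,
                input_mass_ng=float(grp["input_mass_ng"].iloc[0]),
                droplet_volume_nl=droplet_volume_nl,
            )
        )
    return assays
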