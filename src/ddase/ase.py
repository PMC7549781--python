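"""Allele-specific expression statistics and group comparisons.

Per-heterozygote ASE is tested on raw positive-droplet counts with an exact
conditional Poisson rate-ratio test: given the total k_L + k_E, the L count
is binomial with success probability determined by the null rate ratio, and
the two-sided p-value sums all outcomes no more likely than the observed
one ("minlike", the convention of the classical exact tests). Fractional
abundance, in contrast, uses lambda-corrected rates (the vendor
convention), so a near-saturated channel does not bias the allelic share.

The null rate ratio is calibrated per assay from heterozygous-DNA control
wells, where both alleles are present 1:1 and any deviation from 50%
reflects probe efficiency alone. Assays that cannot have a DNA control
(e.g. an intron-spanning 5'UTR assay) declare a null of exactly 0.5,
i.e. equal probe efficiencies are assumed.

The cis-contribution statistic compares the allelic difference inside
heterozygotes (both alleles share one trans environment, so the difference
is cis) with the group-mean difference between the two homozygotes (which
carry two doses of either allele):

    cis% = 2 (mean het L - mean het E) / (mean hom LL - mean hom EE) x 100

100% means linked (cis) regulation fully explains the homozygote gap; 0%
means the gap must arise in trans; signs are preserved, so anti-directional
cis effects come out negative.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import Z95, round_half_away
from .exceptions import SaturationError, ValidationError
from .quant import DropletRun, QuantResult, assay_of, estimate_lambda

DIRECTION_L = "L_HIGHER"
DIRECTION_E = "E_HIGHER"
DIRECTION_NS = "NS"


# ---------------------------------------------------------------------------
# Exact-test kernel
# ---------------------------------------------------------------------------

def exact_binomial_pvalue(k: int, n: int, p0: float,
                          alternative: str = "minlike") -> float:
    """Exact two-sided binomial p-value for ``k`` successes of ``n`` at ``p0``.

    ``minlike`` (default) sums the probability of every outcome whose
    likelihood does not exceed that of the observed count (with the usual
    1 + 1e-7 relative tolerance for floating-point ties); ``central``
    doubles the smaller tail.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"count {k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValidationError("p0 must lie strictly inside (0, 1)")
    if n == 0:
        return 1.0
    if alternative == "minlike":
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = float(pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum())
    elif alternative == "central":
        lo = float(stats.binom.cdf(k, n, p0))
        hi = float(stats.binom.sf(k - 1, n, p0))
        p = 2.0 * min(lo, hi)
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return min(1.0, p)


@dataclass
class RateRatioResult:
    """Exact conditional comparison of two Poisson counts."""

    p_value: float
    rate_ratio: float          # (k1/T1) / (k2/T2); inf when k2 == 0
    null_ratio: float
    ci95: tuple[float, float]
    undefined: bool = False    # both counts zero


def _conditional_ci(k1: int, n: int, t1: float, t2: float,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson-based) CI for the rate ratio given k1 + k2."""
    alpha = 1.0 - level
    if k1 == 0:
        p_lo = 0.0
    else:
        p_lo = float(stats.beta.ppf(alpha / 2, k1, n - k1 + 1))
    if k1 == n:
        p_hi = 1.0
    else:
        p_hi = float(stats.beta.ppf(1 - alpha / 2, k1 + 1, n - k1))
    def to_ratio(p):
        if p >= 1.0:
            return math.inf
        return (p / (1.0 - p)) * (t2 / t1)
    return to_ratio(p_lo), to_ratio(p_hi)


def rate_ratio_test(k1: int, k2: int, t1: float, t2: float,
                    null_ratio: float = 1.0,
                    alternative: str = "minlike") -> RateRatioResult:
    """Exact test of ``rate1 / rate2 = null_ratio`` for two Poisson counts.

    Conditional on ``k1 + k2``, ``k1`` is binomial with success probability
    ``null_ratio * t1 / (null_ratio * t1 + t2)``; the p-value comes from the
    shared exact kernel. With both counts zero the ratio is undefined and
    p = 1 is returned with a flag.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValidationError("exposures must be positive")
    if k1 < 0 or k2 < 0:
        raise ValidationError("counts must be non-negative")
    if null_ratio <= 0:
        raise ValidationError("null_ratio must be positive")
    n = k1 + k2
    if n == 0:
        return RateRatioResult(1.0, math.nan, null_ratio, (0.0, math.inf),
                               undefined=True)
    p0 = null_ratio * t1 / (null_ratio * t1 + t2)
    p = exact_binomial_pvalue(k1, n, p0, alternative=alternative)
    ratio = math.inf if k2 == 0 else (k1 / t1) / (k2 / t2)
    return RateRatioResult(p, ratio, null_ratio, _conditional_ci(k1, n, t1, t2))


def binomial_ase_test(k_ref: int, k_alt: int, p0: float = 0.5,
                      alternative: str = "minlike") -> float:
    """Exact binomial ASE test of ``k_ref`` vs ``k_alt`` reads against ``p0``.

    Identical kernel to :func:`rate_ratio_test` with equal exposures.
    """
    return exact_binomial_pvalue(k_ref, k_ref + k_alt, p0, alternative=alternative)


# ---------------------------------------------------------------------------
# Per-sample ASE
# ---------------------------------------------------------------------------

@dataclass
class ASEResult:
    sample_id: str
    assay: str
    k_l: int
    k_e: int
    n: int
    fa_l: float                # lambda-corrected L fraction
    p_value: float
    direction: str
    null_fraction_l: float


def fractional_abundance(lambda_l: float, lambda_e: float) -> float:
    """Lambda-corrected share of the L allele; NaN when both rates are zero."""
    if lambda_l < 0 or lambda_e < 0:
        raise ValidationError("rates must be non-negative")
    tot = lambda_l + lambda_e
    if tot == 0:
        return math.nan
    return lambda_l / tot


def calibrate_null(
    dna_controls: Iterable[DropletRun],
    *,
    no_dna_control: Iterable[str] = (),
) -> dict[str, float]:
    """Per-assay null L fraction from heterozygous-DNA control wells.

    The null is the mean lambda-corrected L-allele fraction across the
    control wells of each assay (orientation: L). Assays listed in
    ``no_dna_control`` — those that cannot amplify from genomic DNA — are
    assigned a declared null of exactly 0.5.
    """
    fractions: dict[str, list[float]] = {}
    for run in dna_controls:
        if run.material != "DNA":
            raise ValidationError(f"well {run.well_id} is not DNA material")
        channels = run.allele_channels()
        if set(channels) != {"L", "E"}:
            raise ValidationError(f"well {run.well_id} is not an allele duplex")
        assay = assay_of(run.channel_targets[channels["L"]])
        lam = {a: estimate_lambda(run.channel_positives[ch], run.accepted_droplets)
               for a, ch in channels.items()}
        fractions.setdefault(assay, []).append(fractional_abundance(lam["L"], lam["E"]))
    nulls = {assay: float(np.mean(v)) for assay, v in fractions.items()}
    for assay in no_dna_control:
        nulls[assay] = 0.5
    if not nulls:
        raise ValidationError("no DNA control wells and no exempt assays")
    return nulls


def test_sample_ase(run: DropletRun, null_fraction_l: float = 0.5,
                    alpha: float = 0.05,
                    alternative: str = "minlike") -> ASEResult:
    """Exact ASE call for one heterozygote duplex well.

    The rate test uses raw positive-droplet counts against the calibrated
    null (equal exposures of N accepted droplets each); the reported
    fractional abundance uses lambda-corrected rates.
    """
    if not 0.0 < null_fraction_l < 1.0:
        raise ValidationError("null_fraction_l must lie in (0, 1)")
    channels = run.allele_channels()
    if set(channels) != {"L", "E"}:
        raise ValidationError(f"well {run.well_id} is not an allele-specific duplex")
    n = run.accepted_droplets
    k_l = run.channel_positives[channels["L"]]
    k_e = run.channel_positives[channels["E"]]
    null_ratio = null_fraction_l / (1.0 - null_fraction_l)
    res = rate_ratio_test(k_l, k_e, n, n, null_ratio, alternative=alternative)
    lam_l = estimate_lambda(k_l, n)
    lam_e = estimate_lambda(k_e, n)
    fa_l = fractional_abundance(lam_l, lam_e)
    if res.undefined or res.p_value >= alpha:
        direction = DIRECTION_NS
    elif k_l / (k_l + k_e) > null_fraction_l:
        direction = DIRECTION_L
    else:
        direction = DIRECTION_E
    return ASEResult(
        sample_id=run.sample_id,
        assay=assay_of(run.channel_targets[channels["L"]]),
        k_l=k_l, k_e=k_e, n=n, fa_l=fa_l,
        p_value=res.p_value, direction=direction,
        null_fraction_l=null_fraction_l,
    )


test_sample_ase.__test__ = False  # library API, not a pytest case


@dataclass
class TallyResult:
    n_l_higher: int
    n_e_higher: int
    n_ns: int
    n_total: int
    pct_l_higher: int      # reported percentages: nearest int, half away from 0
    pct_e_higher: int
    pct_ns: int


def tally_significance(results: Iterable[ASEResult | str]) -> TallyResult:
    """Counts and reported percentages of ASE calls by direction."""
    directions = [r.direction if isinstance(r, ASEResult) else r for r in results]
    n = len(directions)
    n_l = directions.count(DIRECTION_L)
    n_e = directions.count(DIRECTION_E)
    n_ns = directions.count(DIRECTION_NS)
    if n_l + n_e + n_ns != n:
        raise ValidationError("unknown direction label in tally input")
    pct = lambda c: round_half_away(100.0 * c / n) if n else 0
    return TallyResult(n_l, n_e, n_ns, n, pct(n_l), pct(n_e), pct(n_ns))


# ---------------------------------------------------------------------------
# Cis contribution
# ---------------------------------------------------------------------------

@dataclass
class CisSummary:
    mean_het_l: float
    mean_het_e: float
    mean_hom_ll: float
    mean_hom_ee: float
    het_diff: float
    hom_diff: float
    cis_percent: float

    @property
    def cis_percent_reported(self) -> int:
        return round_half_away(self.cis_percent)


def cis_contribution(mean_het_l: float, mean_het_e: float,
                     mean_hom_ll: float, mean_hom_ee: float) -> CisSummary:
    """Share of the homozygote expression gap explained by cis regulation.

    The heterozygote allelic difference counts once per allele while
    homozygotes carry two copies of theirs, hence the factor 2. The volume
    constant of the copies/ng conversion cancels. Signs are preserved:
    a cis effect opposing the homozygote difference yields a negative
    percentage.
    """
    het_diff = mean_het_l - mean_het_e
    hom_diff = mean_hom_ll - mean_hom_ee
    if hom_diff == 0:
        raise ValidationError("homozygote means are equal; cis share undefined")
    return CisSummary(
        mean_het_l=mean_het_l, mean_het_e=mean_het_e,
        mean_hom_ll=mean_hom_ll, mean_hom_ee=mean_hom_ee,
        het_diff=het_diff, hom_diff=hom_diff,
        cis_percent=200.0 * het_diff / hom_diff,
    )


# ---------------------------------------------------------------------------
# amh/igf3 rate ratio, group comparison, temporal trend
# ---------------------------------------------------------------------------

def amh_igf3_ratio(run: DropletRun, *,
                   saturation_threshold: float = 0.98) -> RateRatioResult:
    """Observed amh/igf3 positive-droplet rate ratio with exact CI and test.

    Saturated wells are refused: the positive fraction no longer tracks
    abundance there.
    """
    targets = {v: k for k, v in run.channel_targets.items()}
    if "amh" not in targets or "igf3" not in targets:
        raise ValidationError(f"well {run.well_id} is not an amh/igf3 duplex")
    n = run.accepted_droplets
    k_amh = run.channel_positives[targets["amh"]]
    k_igf3 = run.channel_positives[targets["igf3"]]
    if max(k_amh, k_igf3) / n > saturation_threshold:
        raise SaturationError(f"well {run.well_id} is saturated")
    return rate_ratio_test(k_amh, k_igf3, n, n, 1.0)


@dataclass
class WelchResult:
    difference: float           # mean(a) - mean(b)
    ci95: tuple[float, float]
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test with Satterthwaite df and CI on the difference."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        p = 1.0 if diff == 0 else 0.0
        return WelchResult(diff, (diff, diff), float(len(a) + len(b) - 2), p,
                           float(a.mean()), float(b.mean()))
    se2 = va / len(a) + vb / len(b)
    df = se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1)
                     + (vb / len(b)) ** 2 / (len(b) - 1))
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df)) * math.sqrt(se2)
    return WelchResult(diff, (diff - half, diff + half), float(df), p,
                       float(a.mean()), float(b.mean()))


@dataclass
class TrendFit:
    """OLS fit of copies/ng on genotype (categorical) and days post-hatch."""

    full: object                 # statsmodels results, y ~ genotype + days
    genotype_only: object
    days_only: object
    day_slope: float
    day_slope_se: float
    day_p: float
    genotype_p: dict[str, float]


def fit_trend(samples: pd.DataFrame, *, response: str = "copies_per_ng",
              genotype_col: str = "genotype",
              days_col: str = "days_post_hatch") -> TrendFit:
    """Fit ``y = genotype + days + e`` plus the two single-term reductions."""
    import statsmodels.formula.api as smf

    df = samples.rename(columns={response: "_y", genotype_col: "_g",
                                 days_col: "_x"})[["_y", "_g", "_x"]].dropna()
    if df["_x"].nunique() < 3:
        raise ValidationError("need at least three distinct days post-hatch")
    if df["_g"].nunique() < 2:
        raise ValidationError("design is rank deficient: genotype has one level")
    if df["_x"].nunique() < 2:
        raise ValidationError("design is rank deficient: days post-hatch constant")
    full = smf.ols("_y ~ C(_g) + _x", data=df).fit()
    geno = smf.ols("_y ~ C(_g)", data=df).fit()
    days = smf.ols("_y ~ _x", data=df).fit()
    genotype_p = {name.split("[T.")[1].rstrip("]"): float(p)
                  for name, p in full.pvalues.items() if name.startswith("C(_g)")}
    return TrendFit(
        full=full, genotype_only=geno, days_only=days,
        day_slope=float(full.params["_x"]),
        day_slope_se=float(full.bse["_x"]),
        day_p=float(full.pvalues["_x"]),
        genotype_p=genotype_p,
    )


def group_mean_difference(group_a: Sequence[float] | float,
                          group_b: Sequence[float] | float) -> float:
    """Difference of group means (scalars are taken as the means themselves)."""
    ma = group_a if np.isscalar(group_a) else float(np.mean(group_a))
    mb = group_b if np.isscalar(group_b) else float(np.mean(group_b))
    return float(ma - mb)
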