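"""Absolute transcript quantification from droplet digital PCR well counts.

A duplex ddPCR reaction partitions the RT reaction into ~10^4 nanoliter
droplets. With template molecules distributed at random, the number of
molecules per droplet is Poisson, so the mean occupancy (lambda, molecules
per droplet) is recovered from the fraction of positive droplets as

    lambda_hat = -ln(1 - k / N)

for ``k`` positive of ``N`` accepted droplets. Absolute concentration in
copies per nanogram of input RNA follows by scaling with the (reaction
volume / droplet volume) partition constant and the input mass.

This module also implements the QC cascade applied before any statistics:
minimum accepted-droplet count, saturation, monoallelic heterozygote
outliers and genotype/signal mismatches, plus replicate averaging.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import Z95
from .exceptions import EmptyRunError, SaturationError, ValidationError

logger = logging.getLogger(__name__)

#: Default Bio-Rad-style volumes. Only the ratio enters copies/ng; both are
#: exposed everywhere so any vendor calibration can be substituted.
DROPLET_VOLUME_NL = 0.85
REACTION_VOLUME_UL = 20.0

#: QC defaults.
MIN_DROPLETS = 10_000
SATURATION_THRESHOLD = 0.98
MONOALLELIC_THRESHOLD = 0.90
SATURATION_TARGETS = ("amh", "igf3")

VALID_GENOTYPES = frozenset({"EE", "EL", "LE", "LL"})
HET_GENOTYPES = frozenset({"EL", "LE"})

QC_PASS = "PASS"
QC_TOO_FEW = "TOO_FEW_DROPLETS"
QC_SATURATED = "SATURATED"
QC_MONOALLELIC = "MONOALLELIC_OUTLIER"
QC_MISMATCH = "GENOTYPE_MISMATCH"


@dataclass
class DropletRun:
    """One ddPCR well: accepted droplets and per-channel positive counts.

    ``channel_targets`` names the assay target read on each channel; for
    allele-specific duplex assays targets end in ``_L`` / ``_E`` to mark
    the haplotype-specific probe.
    """

    well_id: str
    sample_id: str
    accepted_droplets: int
    channel_positives: dict[int, int]
    channel_targets: dict[int, str]
    input_ng: float
    material: str = "RNA"
    replicate: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.accepted_droplets < 0:
            raise ValidationError(f"negative accepted droplets in well {self.well_id}")
        for ch, k in self.channel_positives.items():
            if not 0 <= k <= self.accepted_droplets:
                raise ValidationError(
                    f"well {self.well_id} channel {ch}: positives {k} outside "
                    f"[0, {self.accepted_droplets}]"
                )
        if self.material not in ("RNA", "DNA"):
            raise ValidationError(f"unknown material {self.material!r}")
        if self.material == "RNA" and self.input_ng <= 0:
            raise ValidationError(f"well {self.well_id}: input_ng must be > 0 for RNA")

    def allele_channels(self) -> dict[str, int]:
        """Map allele letter ('L'/'E') -> channel for allele-specific targets."""
        out = {}
        for ch, target in self.channel_targets.items():
            allele = allele_of(target)
            if allele is not None:
                out[allele] = ch
        return out


@dataclass
class QuantResult:
    """Poisson-corrected concentration for one target in one well or sample."""

    sample_id: str
    target: str
    lambda_hat: float
    copies_per_ng: float
    ci95: tuple[float, float]
    qc: str = QC_PASS
    n_replicates_used: int = 1
    well_id: str | None = None
    replicate: int | None = None


def allele_of(target: str) -> str | None:
    """Allele letter encoded in a target name (``..._L`` / ``..._E``), else None."""
    if target.endswith("_L"):
        return "L"
    if target.endswith("_E"):
        return "E"
    return None


def assay_of(target: str) -> str:
    """Assay name with any allele suffix stripped."""
    return target[:-2] if allele_of(target) else target


def estimate_lambda(k: int, n: int) -> float:
    """Mean molecules per droplet from ``k`` positive of ``n`` accepted droplets.

    Raises
    ------
    EmptyRunError
        if ``n == 0``.
    SaturationError
        if ``k == n`` (every droplet positive; lambda diverges).
    """
    if n == 0:
        raise EmptyRunError("no accepted droplets")
    if not 0 <= k <= n:
        raise ValidationError(f"positives {k} outside [0, {n}]")
    if k == n:
        raise SaturationError(f"all {n} droplets positive; lambda undefined")
    return -math.log1p(-k / n)


def lambda_variance(k: int, n: int) -> float:
    """Large-sample (delta-method) variance of lambda_hat on the -ln scale."""
    if k == 0:
        return 0.0
    return k / (n * (n - k))


def copies_scale(droplet_volume_nl: float = DROPLET_VOLUME_NL,
                 reaction_volume_ul: float = REACTION_VOLUME_UL) -> float:
    """Droplets per reaction volume: multiply lambda by this for copies/reaction."""
    return reaction_volume_ul * 1000.0 / droplet_volume_nl


def estimate_copies_per_ng(
    run: DropletRun,
    channel: int,
    *,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    reaction_volume_ul: float = REACTION_VOLUME_UL,
) -> QuantResult:
    """Absolute concentration (copies per ng input RNA) for one channel of a well.

    The 95% CI propagates the delta-method variance of lambda_hat; with
    ``k == 0`` both the point estimate and the CI lower bound are zero.
    """
    if run.input_ng <= 0:
        raise ValidationError(f"well {run.well_id}: non-positive input mass")
    k = run.channel_positives[channel]
    n = run.accepted_droplets
    lam = estimate_lambda(k, n)
    scale = copies_scale(droplet_volume_nl, reaction_volume_ul) / run.input_ng
    copies = lam * scale
    se = math.sqrt(lambda_variance(k, n)) * scale
    ci = (max(0.0, copies - Z95 * se), copies + Z95 * se)
    return QuantResult(
        sample_id=run.sample_id,
        target=run.channel_targets.get(channel, f"ch{channel}"),
        lambda_hat=lam,
        copies_per_ng=copies,
        ci95=ci,
        well_id=run.well_id,
        replicate=run.replicate,
    )


def _allele_fraction(run: DropletRun) -> float | None:
    """Lambda-corrected L-allele fraction of a duplex allele-specific well."""
    channels = run.allele_channels()
    if set(channels) != {"L", "E"}:
        return None
    n = run.accepted_droplets
    lams = {}
    for allele, ch in channels.items():
        k = min(run.channel_positives[ch], n - 1)  # guard saturation for QC only
        lams[allele] = estimate_lambda(k, n)
    tot = lams["L"] + lams["E"]
    if tot == 0:
        return None
    return lams["L"] / tot


def qc_filter(
    runs: Iterable[DropletRun],
    genotypes: Mapping[str, str] | pd.DataFrame | None = None,
    *,
    min_droplets: int = MIN_DROPLETS,
    saturation_threshold: float = SATURATION_THRESHOLD,
    monoallelic_threshold: float = MONOALLELIC_THRESHOLD,
    saturation_targets: Iterable[str] = SATURATION_TARGETS,
) -> list[tuple[DropletRun, str]]:
    """Label every run PASS or with the first failing QC rule.

    Rules, in order: (1) fewer than ``min_droplets`` accepted droplets;
    (2) saturated signal (positives/accepted above threshold) on assays in
    ``saturation_targets``; (3) heterozygote RNA with near-monoallelic
    fractional abundance; (4) homozygote with signal exclusively on the
    opposite-allele channel. Labels never depend on the order runs arrive in.
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = dict(zip(genotypes["sample_id"], genotypes["genotype"]))
    genotypes = genotypes or {}
    for g in genotypes.values():
        if g not in VALID_GENOTYPES:
            raise ValidationError(f"unknown genotype code {g!r}")
    saturation_targets = set(saturation_targets)

    out: list[tuple[DropletRun, str]] = []
    for run in runs:
        out.append((run, _qc_label(run, genotypes, min_droplets,
                                   saturation_threshold, monoallelic_threshold,
                                   saturation_targets)))
    return out


def _qc_label(run, genotypes, min_droplets, sat_thr, mono_thr, sat_targets) -> str:
    n = run.accepted_droplets
    if n < min_droplets:
        return QC_TOO_FEW
    for ch, target in run.channel_targets.items():
        if target in sat_targets and run.channel_positives[ch] / n > sat_thr:
            return QC_SATURATED
    alleles = run.allele_channels()
    if set(alleles) == {"L", "E"}:
        genotype = genotypes.get(run.sample_id)
        if genotype is None:
            raise ValidationError(
                f"sample {run.sample_id!r} has allele-specific wells but no genotype"
            )
        if genotype in HET_GENOTYPES and run.material == "RNA":
            fa_l = _allele_fraction(run)
            if fa_l is not None and max(fa_l, 1 - fa_l) > mono_thr:
                return QC_MONOALLELIC
        elif genotype in ("EE", "LL"):
            own = genotype[0]
            other = "L" if own == "E" else "E"
            k_own = run.channel_positives[alleles[own]]
            k_other = run.channel_positives[alleles[other]]
            if k_own == 0 and k_other > 0:
                return QC_MISMATCH
    return QC_PASS


def average_replicates(results: Iterable[QuantResult]) -> list[QuantResult]:
    """Mean copies/ng across PASS replicates, grouped by (sample, target).

    Averaging happens *after* per-well normalization (mean of per-well
    copies/ng, not renormalization of pooled counts). Samples whose
    replicates all failed QC are dropped with a logged reason.
    """
    groups: dict[tuple[str, str], list[QuantResult]] = {}
    for r in results:
        groups.setdefault((r.sample_id, r.target), []).append(r)

    out = []
    for (sample_id, target), reps in sorted(groups.items()):
        passing = [r for r in reps if r.qc == QC_PASS]
        if not passing:
            reasons = {r.qc for r in reps}
            logger.info("sample %s target %s dropped: no PASS replicate (%s)",
                        sample_id, target, ",".join(sorted(reasons)))
            continue
        copies = float(np.mean([r.copies_per_ng for r in passing]))
        lam = float(np.mean([r.lambda_hat for r in passing]))
        # SE of the mean from per-well delta-method SEs
        ses = [(r.ci95[1] - r.copies_per_ng) / Z95 for r in passing]
        se = math.sqrt(sum(s * s for s in ses)) / len(passing)
        out.append(QuantResult(
            sample_id=sample_id,
            target=target,
            lambda_hat=lam,
            copies_per_ng=copies,
            ci95=(max(0.0, copies - Z95 * se), copies + Z95 * se),
            n_replicates_used=len(passing),
        ))
    return out


def quantify_runs(
    runs: Iterable[DropletRun],
    genotypes: Mapping[str, str] | pd.DataFrame | None = None,
    **kwargs,
) -> tuple[list[QuantResult], list[tuple[DropletRun, str]]]:
    """QC, per-well quantification and replicate averaging in one call.

    Returns the per-sample results and the full QC annotation (for audit).
    Saturated vgll3-type wells (k == N on a non-exempt assay) raise
    SaturationError rather than being silently excluded.
    """
    quant_kwargs = {k: kwargs.pop(k) for k in ("droplet_volume_nl", "reaction_volume_ul")
                    if k in kwargs}
    annotated = qc_filter(runs, genotypes, **kwargs)
    per_well = []
    for run, label in annotated:
        if label != QC_PASS:
            continue
        for ch in sorted(run.channel_targets):
            per_well.append(estimate_copies_per_ng(run, ch, **quant_kwargs))
    return average_replicates(per_well), annotated


class PoissonQuantifier(BaseEstimator, TransformerMixin):
    """Transformer from a well table to per-sample absolute concentrations.

    Accepts the well-table DataFrame dialect written by
    :mod:`ddase.simulate` (one row per well x channel) and produces a
    per-sample quantification frame, applying the QC cascade and replicate
    averaging. Genotypes (needed for the heterozygote/homozygote QC rules)
    are supplied at ``fit`` time.
    """

    def __init__(self, droplet_volume_nl=DROPLET_VOLUME_NL,
                 reaction_volume_ul=REACTION_VOLUME_UL,
                 min_droplets=MIN_DROPLETS,
                 saturation_threshold=SATURATION_THRESHOLD,
                 monoallelic_threshold=MONOALLELIC_THRESHOLD,
                 saturation_targets=SATURATION_TARGETS):
        self.droplet_volume_nl = droplet_volume_nl
        self.reaction_volume_ul = reaction_volume_ul
        self.min_droplets = min_droplets
        self.saturation_threshold = saturation_threshold
        self.monoallelic_threshold = monoallelic_threshold
        self.saturation_targets = saturation_targets

    def fit(self, X, y=None, genotypes=None):
        from .io import frame_to_runs  # local import to avoid cycle

        X = pd.DataFrame(X)
        frame_to_runs(X.head(0)) if len(X) == 0 else None  # schema check via converter
        self.genotypes_ = genotypes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        from .io import frame_to_runs

        if not hasattr(self, "genotypes_"):
            raise ValidationError("PoissonQuantifier must be fit before transform")
        runs = frame_to_runs(pd.DataFrame(X))
        results, annotated = quantify_runs(
            runs, self.genotypes_,
            droplet_volume_nl=self.droplet_volume_nl,
            reaction_volume_ul=self.reaction_volume_ul,
            min_droplets=self.min_droplets,
            saturation_threshold=self.saturation_threshold,
            monoallelic_threshold=self.monoallelic_threshold,
            saturation_targets=self.saturation_targets,
        )
        self.qc_annotations_ = pd.DataFrame(
            [{"well_id": r.well_id, "sample_id": r.sample_id, "qc": label}
             for r, label in annotated]
        )
        return pd.DataFrame(
            [{"sample_id": r.sample_id, "target": r.target,
              "copies_per_ng": r.copies_per_ng,
              "ci_low": r.ci95[0], "ci_high": r.ci95[1],
              "qc": r.qc, "n_replicates_used": r.n_replicates_used}
             for r in results]
        )
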