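"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here: duplex ddPCR
droplet runs (Poisson partitioning of template molecules, per-molecule
probe-efficiency thinning, optional cross-channel leakage), heterozygous
DNA control wells with a probe-efficiency skew, binomial RNA-seq allele
read counts, two-component Gaussian clusters in (amh/igf3, vgll3)
expression space, and cohorts with genotype-dependent binary maturation.

Molecules are simulated as a Poisson-drawn total assigned to droplets by
uniform multinomial placement — distributionally identical to independent
per-droplet Poisson counts, but conserving molecule totals exactly, which
the tests exploit. All randomness flows from one `numpy` Generator per
call; identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import as_rng
from .exceptions import SaturationError, ValidationError
from .quant import DropletRun

#: Refuse to simulate wells this far into saturation: with >20 expected
#: molecules per droplet essentially every droplet is positive and the run
#: carries no quantitative information.
MAX_LAMBDA = 20.0

#: Channel convention for allele-specific duplex assays: channel 1 reads the
#: late (L) probe, channel 2 the early (E) probe.
L_CHANNEL, E_CHANNEL = 1, 2


@dataclass(frozen=True)
class SimConfig:
    """Physical parameters of one simulated ddPCR well series."""

    seed: int = 0
    n_droplets: int = 15_000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    input_ng: float = 50.0
    probe_efficiency: tuple[float, float] = (1.0, 1.0)  # per channel
    cross_leak: float = 0.0
    n_replicates: int = 2

    def __post_init__(self):
        if self.n_droplets <= 0:
            raise ValidationError("n_droplets must be positive")
        for e in self.probe_efficiency:
            if not 0.0 < e <= 1.0:
                raise ValidationError("probe_efficiency must lie in (0, 1]")
        if not 0.0 <= self.cross_leak < 1.0:
            raise ValidationError("cross_leak must lie in [0, 1)")
        if self.n_replicates <= 0:
            raise ValidationError("n_replicates must be positive")

    @property
    def lambda_per_copy(self) -> float:
        """Mean molecules per droplet contributed by 1 copy/ng of template."""
        return self.input_ng * self.droplet_volume_nl / (self.reaction_volume_ul * 1000.0)


@dataclass(frozen=True)
class CohortSpec:
    """Composition and genotype-specific maturation rates of a male cohort."""

    n_per_genotype: dict[str, int] = field(default_factory=lambda: {
        "EE": 93, "EL": 100, "LE": 99, "LL": 92})
    maturation_prob: dict[str, float] = field(default_factory=lambda: {
        "EE": 0.207, "EL": 0.154, "LL": 0.03})
    tissues: tuple[str, ...] = ("testes",)
    timepoints: tuple[int, ...] = (270,)  # days post-hatch

    def __post_init__(self):
        for g, n in self.n_per_genotype.items():
            if n < 0:
                raise ValidationError(f"negative count for genotype {g}")
        for g, p in self.maturation_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"maturation probability for {g} outside [0,1]")

    def prob_for(self, genotype: str) -> float:
        """Maturation probability; heterozygote classes EL/LE share one rate."""
        key = "EL" if genotype in ("EL", "LE") else genotype
        return self.maturation_prob[key]


def simulate_droplet_run(
    config: SimConfig,
    targets: Sequence[tuple[str, float, int]],
    *,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
    well_id: str = "A01",
    replicate: int = 1,
    material: str = "RNA",
    keep_occupancy: bool = False,
) -> DropletRun:
    """Simulate one well given ``(name, true_copies_per_ng, channel)`` targets.

    A droplet reads positive on a channel when it holds at least one
    molecule of a target on that channel that survives the per-molecule
    efficiency thinning; cross-channel leakage then adds false positives on
    the opposite channel with probability ``config.cross_leak`` per
    positive droplet.
    """
    rng = as_rng(config.seed if rng is None else rng)
    n = config.n_droplets
    positive = {1: np.zeros(n, dtype=bool), 2: np.zeros(n, dtype=bool)}
    channel_targets: dict[int, str] = {}
    truth: dict[str, dict] = {}

    for name, copies_per_ng, channel in targets:
        if copies_per_ng < 0:
            raise ValidationError(f"negative concentration for target {name}")
        if channel not in (1, 2):
            raise ValidationError(f"channel must be 1 or 2, got {channel}")
        if channel in channel_targets:
            raise ValidationError(f"two targets on channel {channel}")
        channel_targets[channel] = name
        lam = copies_per_ng * config.lambda_per_copy
        if lam > MAX_LAMBDA:
            raise SaturationError(
                f"target {name}: {lam:.1f} expected molecules/droplet — fully "
                "saturated, uninformative")
        total = int(rng.poisson(lam * n))
        occupancy = np.bincount(rng.integers(0, n, size=total), minlength=n)
        detected = rng.binomial(occupancy, config.probe_efficiency[channel - 1])
        positive[channel] |= detected > 0
        truth[name] = {"molecules": total, "lambda": lam, "channel": channel}
        if keep_occupancy:
            truth[name]["occupancy"] = occupancy

    if config.cross_leak > 0:
        snapshot = {ch: positive[ch].copy() for ch in (1, 2)}
        for src, dst in ((1, 2), (2, 1)):
            leak = snapshot[src] & ~snapshot[dst] & (rng.random(n) < config.cross_leak)
            positive[dst] |= leak

    channel_positives = {ch: int(positive[ch].sum()) for ch in channel_targets}
    return DropletRun(
        well_id=well_id,
        sample_id=sample_id,
        accepted_droplets=n,
        channel_positives=channel_positives,
        channel_targets=channel_targets,
        input_ng=config.input_ng,
        material=material,
        replicate=replicate,
        meta={"truth": truth},
    )


def simulate_het_ase_run(
    config: SimConfig,
    total_copies_per_ng: float,
    l_fraction: float,
    *,
    assay: str = "vgll3_5utr",
    rng: np.random.Generator | None = None,
    **kwargs,
) -> DropletRun:
    """Duplex allele-specific well for a heterozygote.

    The L allele contributes ``total x l_fraction`` copies/ng on channel 1,
    the E allele the remainder on channel 2.
    """
    if not 0.0 <= l_fraction <= 1.0:
        raise ValidationError("l_fraction must lie in [0, 1]")
    targets = [
        (f"{assay}_L", total_copies_per_ng * l_fraction, L_CHANNEL),
        (f"{assay}_E", total_copies_per_ng * (1.0 - l_fraction), E_CHANNEL),
    ]
    return simulate_droplet_run(config, targets, rng=rng, **kwargs)


def simulate_dna_control(
    config: SimConfig,
    efficiency_ratio: float,
    *,
    assay: str = "vgll3_exon2",
    total_copies_per_ng: float = 100.0,
    sample_id: str = "DNA_CTRL",
    rng: np.random.Generator | None = None,
) -> list[DropletRun]:
    """Heterozygous-DNA control wells: equal template, skewed probe efficiency.

    ``efficiency_ratio`` is the L:E probe efficiency ratio, so the measured
    null L fraction converges to ``r / (1 + r)`` — e.g. r = 0.504/0.496
    yields the 50.4% null of a slightly L-favouring assay. Returns
    ``config.n_replicates`` wells.
    """
    if efficiency_ratio <= 0:
        raise ValidationError("efficiency_ratio must be positive")
    base = min(config.probe_efficiency)
    if efficiency_ratio >= 1.0:
        eff = (base, base / efficiency_ratio)
    else:
        eff = (base * efficiency_ratio, base)
    cfg = replace(config, probe_efficiency=eff)
    rng = as_rng(config.seed if rng is None else rng)
    half = total_copies_per_ng / 2.0
    runs = []
    for i in range(config.n_replicates):
        runs.append(simulate_droplet_run(
            cfg,
            [(f"{assay}_L", half, L_CHANNEL), (f"{assay}_E", half, E_CHANNEL)],
            rng=rng,
            sample_id=sample_id,
            well_id=f"{sample_id}_{i + 1}",
            replicate=i + 1,
            material="DNA",
        ))
    return runs


def simulate_ase_read_counts(
    depth: int, l_fraction: float, seed=None
) -> tuple[int, int]:
    """RNA-seq allele counts at one SNP: ``k_L ~ Binomial(depth, l_fraction)``."""
    if depth < 0:
        raise ValidationError("depth must be non-negative")
    if not 0.0 <= l_fraction <= 1.0:
        raise ValidationError("l_fraction must lie in [0, 1]")
    rng = as_rng(seed)
    k_l = int(rng.binomial(depth, l_fraction)) if depth else 0
    return k_l, depth - k_l


def simulate_expression_clusters(
    n1: int,
    n2: int,
    means: Sequence[Sequence[float]],
    covariances: Sequence[Sequence[Sequence[float]]],
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component Gaussian mixture sample in 2-D with known labels."""
    rng = as_rng(seed)
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covariances, dtype=float)
    for c in covs:
        if not np.allclose(c, c.T):
            raise ValidationError("covariance must be symmetric")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise ValidationError("covariance must be positive definite") from None
    parts, labels = [], []
    for comp, n in enumerate((n1, n2)):
        if n < 0:
            raise ValidationError("component sizes must be non-negative")
        if n:
            parts.append(rng.multivariate_normal(means[comp], covs[comp], size=n,
                                                 method="cholesky"))
            labels.append(np.full(n, comp))
    X = np.vstack(parts) if parts else np.empty((0, 2))
    y = np.concatenate(labels) if labels else np.empty(0, dtype=int)
    return X, y


def simulate_maturation_cohort(spec: CohortSpec, seed=None) -> pd.DataFrame:
    """Male cohort with binary maturity drawn per genotype-specific probability."""
    rng = as_rng(seed)
    rows = []
    i = 0
    for genotype in sorted(spec.n_per_genotype):
        p = spec.prob_for(genotype)
        n = spec.n_per_genotype[genotype]
        mature = rng.random(n) < p
        for j in range(n):
            i += 1
            rows.append({
                "individual_id": f"IND{i:05d}",
                "genotype": genotype,
                "sex": "M",
                "tissue": spec.tissues[j % len(spec.tissues)],
                "days_post_hatch": int(spec.timepoints[j % len(spec.timepoints)]),
                "maturity": int(mature[j]),
            })
    return pd.DataFrame(rows, columns=["individual_id", "genotype", "sex", "tissue",
                                       "days_post_hatch", "maturity"])


# ---------------------------------------------------------------------------
# Full-study scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """A paper-scale study: exon-2 ASE panel, DNA controls, amh/igf3 panel, cohort.

    Defaults follow the observed magnitudes of the salmon vgll3 system:
    immature-testes expression around 100 copies/ng with a modest (few
    percent) cis-driven allelic imbalance in heterozygotes, homozygote group
    means differing by ~15 copies/ng in the same direction, and a mature
    group with strongly reduced vgll3 and inverted amh/igf3 balance.
    """

    n_het: int = 47
    n_hom_ee: int = 12
    n_hom_ll: int = 22
    het_l_mean: float = 60.3
    het_e_mean: float = 53.5
    hom_ee_mean: float = 91.06
    hom_ll_mean: float = 106.35
    biological_cv: float = 0.12        # lognormal spread of per-individual truth
    het_fa_sd: float = 0.02            # individual spread of the true L fraction
    null_l_fraction: float = 0.504     # DNA-control probe skew, L orientation
    n_dna_controls: int = 10
    n_immature: int = 65
    n_mature: int = 14
    vgll3_immature: float = 107.0
    vgll3_mature: float = 37.0
    amh_igf3_immature: tuple[float, float] = (1200.0, 240.0)
    amh_igf3_mature: tuple[float, float] = (240.0, 1200.0)
    amh_input_ng: float = 2.0
    assay: str = "vgll3_exon2"
    cohort: CohortSpec = field(default_factory=CohortSpec)


def simulate_study(spec: StudySpec, config: SimConfig, seed=None):
    """Generate a coherent study: well table runs, genotype map and cohort table.

    Returns ``(runs, genotypes, cohort)`` where ``runs`` contains duplex
    allele-specific wells for heterozygotes and homozygotes (with
    ``config.n_replicates`` replicates each), DNA-control wells, and duplex
    amh/igf3 wells paired with singleplex vgll3 wells for the
    immature/mature panel.
    """
    rng = as_rng(seed)
    eff_ratio = spec.null_l_fraction / (1.0 - spec.null_l_fraction)
    runs: list[DropletRun] = []
    genotypes: dict[str, str] = {}

    def het_wells(i):
        sid = f"HET{i:03d}"
        genotypes[sid] = "EL" if i % 2 else "LE"
        scale = rng.lognormal(0.0, spec.biological_cv)
        total = (spec.het_l_mean + spec.het_e_mean) * scale
        fa = spec.het_l_mean / (spec.het_l_mean + spec.het_e_mean)
        fa = float(np.clip(fa + rng.normal(0.0, spec.het_fa_sd), 0.01, 0.99))
        for rep in range(1, config.n_replicates + 1):
            runs.append(simulate_het_ase_run(
                config, total, fa, assay=spec.assay, rng=rng,
                sample_id=sid, well_id=f"{sid}_r{rep}", replicate=rep))

    def hom_wells(i, genotype, mean):
        sid = f"{genotype}{i:03d}"
        genotypes[sid] = genotype
        total = mean * rng.lognormal(0.0, spec.biological_cv)
        allele = genotype[0]
        ch = L_CHANNEL if allele == "L" else E_CHANNEL
        other = "E" if allele == "L" else "L"
        other_ch = E_CHANNEL if ch == L_CHANNEL else L_CHANNEL
        for rep in range(1, config.n_replicates + 1):
            runs.append(simulate_droplet_run(
                config,
                [(f"{spec.assay}_{allele}", total, ch),
                 (f"{spec.assay}_{other}", 0.0, other_ch)],
                rng=rng, sample_id=sid, well_id=f"{sid}_r{rep}", replicate=rep))

    for i in range(1, spec.n_het + 1):
        het_wells(i)
    for i in range(1, spec.n_hom_ee + 1):
        hom_wells(i, "EE", spec.hom_ee_mean)
    for i in range(1, spec.n_hom_ll + 1):
        hom_wells(i, "LL", spec.hom_ll_mean)

    ctrl_cfg = replace(config, n_replicates=spec.n_dna_controls)
    runs.extend(simulate_dna_control(ctrl_cfg, eff_ratio, assay=spec.assay, rng=rng))
    genotypes["DNA_CTRL"] = "EL"

    amh_cfg = replace(config, input_ng=spec.amh_input_ng)
    for group, n_group, vgll3_mean, (amh, igf3) in (
        ("IMM", spec.n_immature, spec.vgll3_immature, spec.amh_igf3_immature),
        ("MAT", spec.n_mature, spec.vgll3_mature, spec.amh_igf3_mature),
    ):
        for i in range(1, n_group + 1):
            sid = f"{group}{i:03d}"
            genotypes.setdefault(sid, "EE")
            scale = rng.lognormal(0.0, spec.biological_cv)
            runs.append(simulate_droplet_run(
                amh_cfg, [("amh", amh * scale, 1), ("igf3", igf3 * scale, 2)],
                rng=rng, sample_id=sid, well_id=f"{sid}_ai", replicate=1))
            runs.append(simulate_droplet_run(
                config, [("vgll3_total", vgll3_mean * scale, 1)],
                rng=rng, sample_id=sid, well_id=f"{sid}_vg", replicate=1))

    # the cohort table doubles as the sample-metadata table for the assayed
    # individuals (genotype lookup joins on individual_id == sample_id)
    assayed = pd.DataFrame([{
        "individual_id": sid,
        "genotype": g,
        "sex": "NA" if sid == "DNA_CTRL" else "M",
        "tissue": "testes",
        "days_post_hatch": 270,
        "maturity": int(sid.startswith("MAT")),
    } for sid, g in genotypes.items()])
    cohort = pd.concat([assayed, simulate_maturation_cohort(spec.cohort, rng)],
                       ignore_index=True)
    return runs, genotypes, cohort
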