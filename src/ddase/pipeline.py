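"""End-to-end orchestration: QC -> quantify -> ASE -> cis -> clustering -> cohort.

The pipeline consumes either user-supplied tables (wells + cohort) or a
fully synthetic study generated in-package, and produces one
machine-readable JSON report plus human-readable TSVs. Every exclusion is
logged with the triggering rule; reruns with the same configuration and
seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import cluster as cluster_mod
from . import io as io_mod
from . import quant as quant_mod
from . import simulate as sim_mod
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, YAML-serializable configuration; every threshold is named."""

    seed: int = 0
    outdir: str = "ddase_out"
    wells: str | None = None          # paths; None => synthetic study
    cohort: str | None = None
    alpha: float = 0.05
    min_droplets: int = 10_000
    saturation_threshold: float = 0.98
    monoallelic_threshold: float = 0.90
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    no_dna_control: tuple[str, ...] = ()
    cluster_g_max: int = 3
    cluster_cov_models: tuple[str, ...] = ("full",)
    bootstrap_b: int = 199
    n_droplets: int = 15_000
    input_ng: float = 50.0
    n_replicates: int = 2

    def __post_init__(self):
        if self.min_droplets <= 0:
            raise ValidationError("min_droplets must be positive")
        for name in ("saturation_threshold", "monoallelic_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if (self.wells is None) != (self.cohort is None):
            raise ValidationError("provide both wells and cohort paths, or neither")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("no_dna_control", "cluster_cov_models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def maturation_frequencies(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype maturation counts and frequencies, males only.

    Heterozygote classes EL and LE are pooled into one EL class.
    """
    required = {"genotype", "sex", "maturity"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    bad = set(cohort["genotype"]) - quant_mod.VALID_GENOTYPES
    if bad:
        raise ValidationError(f"unknown genotype codes: {sorted(bad)}")
    males = cohort[cohort["sex"] == "M"].copy()
    if not males["maturity"].isin([0, 1]).all():
        raise ValidationError("maturity must be binary for males")
    males["genotype"] = males["genotype"].replace({"LE": "EL"})
    rows = []
    for genotype, grp in males.groupby("genotype"):
        n = len(grp)
        n_mature = int(grp["maturity"].sum())
        rows.append({"genotype": genotype, "n": n, "n_mature": n_mature,
                     "frequency": n_mature / n if n else math.nan})
    return pd.DataFrame(rows).sort_values("genotype").reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else round(v, 10)
    return obj


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    rng = np.random.default_rng(config.seed)
    sim_cfg = sim_mod.SimConfig(
        seed=config.seed, n_droplets=config.n_droplets,
        droplet_volume_nl=config.droplet_volume_nl,
        reaction_volume_ul=config.reaction_volume_ul,
        input_ng=config.input_ng, n_replicates=config.n_replicates)

    if config.wells is None:
        runs, genotypes, cohort = sim_mod.simulate_study(
            sim_mod.StudySpec(), sim_cfg, seed=rng)
        source = "synthetic"
    else:
        runs = io_mod.read_well_table(config.wells)
        cohort = io_mod.read_cohort_table(config.cohort)
        genotypes = dict(zip(cohort["individual_id"], cohort["genotype"]))
        source = "tables"

    # --- QC + quantification ---------------------------------------------
    results, annotated = quant_mod.quantify_runs(
        runs, genotypes,
        droplet_volume_nl=config.droplet_volume_nl,
        reaction_volume_ul=config.reaction_volume_ul,
        min_droplets=config.min_droplets,
        saturation_threshold=config.saturation_threshold,
        monoallelic_threshold=config.monoallelic_threshold)
    qc_counts: dict[str, int] = {}
    for run, label in annotated:
        qc_counts[label] = qc_counts.get(label, 0) + 1
        if label != quant_mod.QC_PASS:
            logger.info("excluded well %s (sample %s): %s",
                        run.well_id, run.sample_id, label)
    quant_frame = pd.DataFrame(
        [{"sample_id": r.sample_id, "target": r.target,
          "copies_per_ng": r.copies_per_ng, "ci_low": r.ci95[0],
          "ci_high": r.ci95[1], "qc": r.qc,
          "n_replicates_used": r.n_replicates_used} for r in results])

    passing = {run.well_id for run, label in annotated
               if label == quant_mod.QC_PASS}
    pass_runs = [run for run in runs if run.well_id in passing]

    # --- Null calibration + per-heterozygote ASE --------------------------
    dna_runs = [r for r in pass_runs if r.material == "DNA"
                and set(r.allele_channels()) == {"L", "E"}]
    try:
        nulls = ase_mod.calibrate_null(dna_runs,
                                       no_dna_control=config.no_dna_control)
    except ValidationError:
        nulls = {}

    het_ids = {s for s, g in genotypes.items() if g in quant_mod.HET_GENOTYPES}
    ase_rows = []
    by_sample: dict[tuple[str, str], list] = {}
    for run in pass_runs:
        if (run.material == "RNA" and run.sample_id in het_ids
                and set(run.allele_channels()) == {"L", "E"}):
            assay = quant_mod.assay_of(
                run.channel_targets[run.allele_channels()["L"]])
            by_sample.setdefault((run.sample_id, assay), []).append(run)
    for (sample_id, assay), sample_runs in sorted(by_sample.items()):
        # replicate wells are pooled: counts and exposures both add
        k_l = sum(r.channel_positives[r.allele_channels()["L"]]
                  for r in sample_runs)
        k_e = sum(r.channel_positives[r.allele_channels()["E"]]
                  for r in sample_runs)
        n = sum(r.accepted_droplets for r in sample_runs)
        pooled = quant_mod.DropletRun(
            well_id=f"{sample_id}:{assay}", sample_id=sample_id,
            accepted_droplets=n,
            channel_positives={1: k_l, 2: k_e},
            channel_targets={1: f"{assay}_L", 2: f"{assay}_E"},
            input_ng=sample_runs[0].input_ng)
        res = ase_mod.test_sample_ase(pooled, nulls.get(assay, 0.5),
                                      alpha=config.alpha)
        ase_rows.append(res)
    tally = ase_mod.tally_significance(ase_rows)
    ase_frame = pd.DataFrame(
        [{"sample_id": r.sample_id, "assay": r.assay, "k_l": r.k_l,
          "k_e": r.k_e, "fa_l": r.fa_l, "p_value": r.p_value,
          "direction": r.direction} for r in ase_rows])

    # --- Cis summary -------------------------------------------------------
    cis = None
    if not quant_frame.empty:
        tq = quant_frame.set_index(["sample_id", "target"])["copies_per_ng"]

        def group_mean(sample_filter, allele):
            vals = [v for (sid, tgt), v in tq.items()
                    if sample_filter(sid) and quant_mod.allele_of(tgt) == allele
                    and sid in genotypes]
            return float(np.mean(vals)) if vals else math.nan

        het_l = group_mean(lambda s: genotypes.get(s) in quant_mod.HET_GENOTYPES, "L")
        het_e = group_mean(lambda s: genotypes.get(s) in quant_mod.HET_GENOTYPES, "E")
        hom_ll = group_mean(lambda s: genotypes.get(s) == "LL", "L")
        hom_ee = group_mean(lambda s: genotypes.get(s) == "EE", "E")
        if all(map(math.isfinite, (het_l, het_e, hom_ll, hom_ee))) \
                and hom_ll != hom_ee:
            cis = ase_mod.cis_contribution(het_l, het_e, hom_ll, hom_ee)

    # --- Clustering in (log amh/igf3, vgll3 copies) space ------------------
    clustering = None
    features = _cluster_features(pass_runs, quant_frame)
    min_n = (config.cluster_g_max) * 3 + 1
    if len(features) > max(min_n, 6):
        X = features[["log_amh_igf3", "vgll3_copies"]].to_numpy()
        best, bic_table = cluster_mod.select_bic(
            X, g_range=range(1, config.cluster_g_max + 1),
            cov_models=config.cluster_cov_models,
            seed=int(rng.integers(2 ** 31)))
        lrt = cluster_mod.bootstrap_lrt(
            X, 1, 2, b=config.bootstrap_b, seed=int(rng.integers(2 ** 31)),
            covariance_type=config.cluster_cov_models[0])
        labels = best.model.predict(X)
        features = features.assign(component=labels)
        clustering = {
            "best_n_components": best.n_components,
            "covariance_type": best.covariance_type,
            "bic_table": bic_table.drop(columns="error").to_dict("records"),
            "bootstrap_lrt": {"observed": lrt.observed_lrt,
                              "p_value": lrt.p_value, "B": lrt.b},
            "ellipses": [{"center": e["center"], "semi_axes": e["semi_axes"],
                          "angle_deg": e["angle_deg"]}
                         for e in cluster_mod.confidence_ellipse(best)],
        }
        if best.n_components >= 2:
            means = [features.loc[features.component == c, "vgll3_copies"].mean()
                     for c in range(best.n_components)]
            low, high = int(np.argmin(means)), int(np.argmax(means))
            a = features.loc[features.component == high, "vgll3_copies"]
            b_ = features.loc[features.component == low, "vgll3_copies"]
            if len(a) >= 2 and len(b_) >= 2:
                w = ase_mod.welch_test(a, b_)
                clustering["component_vgll3_difference"] = {
                    "difference": w.difference, "ci95": list(w.ci95),
                    "df": w.df, "p_value": w.p_value,
                    "mean_high": w.mean_a, "mean_low": w.mean_b}

    # --- Cohort maturation frequencies -------------------------------------
    freqs = maturation_frequencies(cohort)

    report = {
        "source": source,
        "seed": config.seed,
        "qc": {"n_wells": len(annotated), "labels": qc_counts},
        "null_fractions": nulls,
        "ase": {
            "per_sample_n": len(ase_rows),
            "tally": asdict(tally),
        },
        "cis": None if cis is None else asdict(cis) | {
            "cis_percent_reported": cis.cis_percent_reported},
        "clustering": clustering,
        "maturation_frequencies": freqs.to_dict("records"),
        "audit": {
            "n_input_wells": len(runs),
            "n_pass_wells": qc_counts.get(quant_mod.QC_PASS, 0),
            "n_excluded_wells": len(runs) - qc_counts.get(quant_mod.QC_PASS, 0),
            "n_samples_quantified": int(quant_frame["sample_id"].nunique())
            if not quant_frame.empty else 0,
        },
    }
    report = _jsonable(report)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        quant_frame.to_csv(outdir / "quant.tsv", sep="\t", index=False)
        ase_frame.to_csv(outdir / "ase.tsv", sep="\t", index=False)
        freqs.to_csv(outdir / "maturation_frequencies.tsv", sep="\t", index=False)
        if clustering is not None:
            features.to_csv(outdir / "cluster_assignments.tsv", sep="\t",
                            index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _cluster_features(pass_runs, quant_frame) -> pd.DataFrame:
    """Per-sample (log amh/igf3 lambda ratio, vgll3 copies/ng) features."""
    ratios = {}
    for run in pass_runs:
        targets = {v: k for k, v in run.channel_targets.items()}
        if "amh" in targets and "igf3" in targets:
            try:
                lam_a = quant_mod.estimate_lambda(
                    run.channel_positives[targets["amh"]], run.accepted_droplets)
                lam_i = quant_mod.estimate_lambda(
                    run.channel_positives[targets["igf3"]], run.accepted_droplets)
            except Exception:
                continue
            if lam_a > 0 and lam_i > 0:
                ratios.setdefault(run.sample_id, []).append(
                    math.log(lam_a / lam_i))
    if quant_frame.empty:
        return pd.DataFrame(columns=["sample_id", "log_amh_igf3", "vgll3_copies"])
    vgll3 = quant_frame[quant_frame["target"] == "vgll3_total"] \
        .set_index("sample_id")["copies_per_ng"]
    rows = [{"sample_id": sid, "log_amh_igf3": float(np.mean(v)),
             "vgll3_copies": float(vgll3[sid])}
            for sid, v in sorted(ratios.items()) if sid in vgll3.index]
    return pd.DataFrame(rows, columns=["sample_id", "log_amh_igf3",
                                       "vgll3_copies"])
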