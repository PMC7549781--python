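"""Tab-separated table dialects shared across the package.

Well tables carry one row per (well, channel); rows of the same well share
accepted-droplet count, input mass, material and replicate. Cohort tables
carry one individual per row.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .exceptions import ValidationError
from .quant import DropletRun

WELL_COLUMNS = ["well_id", "sample_id", "target", "channel", "accepted_droplets",
                "positives", "input_ng", "replicate", "material"]
COHORT_COLUMNS = ["individual_id", "genotype", "sex", "tissue", "days_post_hatch",
                  "maturity"]


def runs_to_frame(runs: Iterable[DropletRun]) -> pd.DataFrame:
    rows = []
    for run in runs:
        for ch in sorted(run.channel_targets):
            rows.append({
                "well_id": run.well_id,
                "sample_id": run.sample_id,
                "target": run.channel_targets[ch],
                "channel": ch,
                "accepted_droplets": run.accepted_droplets,
                "positives": run.channel_positives[ch],
                "input_ng": run.input_ng,
                "replicate": run.replicate,
                "material": run.material,
            })
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def frame_to_runs(frame: pd.DataFrame) -> list[DropletRun]:
    missing = [c for c in WELL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"well table missing columns: {missing}")
    runs = []
    for well_id, grp in frame.groupby("well_id", sort=False):
        for col in ("sample_id", "accepted_droplets", "input_ng", "replicate",
                    "material"):
            if grp[col].nunique() > 1:
                raise ValidationError(
                    f"well {well_id}: inconsistent {col} across channel rows")
        first = grp.iloc[0]
        runs.append(DropletRun(
            well_id=str(well_id),
            sample_id=str(first["sample_id"]),
            accepted_droplets=int(first["accepted_droplets"]),
            channel_positives={int(r["channel"]): int(r["positives"])
                               for _, r in grp.iterrows()},
            channel_targets={int(r["channel"]): str(r["target"])
                             for _, r in grp.iterrows()},
            input_ng=float(first["input_ng"]),
            material=str(first["material"]),
            replicate=int(first["replicate"]),
        ))
    return runs


def write_well_table(runs: Iterable[DropletRun] | pd.DataFrame, path) -> None:
    frame = runs if isinstance(runs, pd.DataFrame) else runs_to_frame(runs)
    frame.to_csv(path, sep="\t", index=False)


def read_well_table(path) -> list[DropletRun]:
    return frame_to_runs(pd.read_csv(path, sep="\t"))


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    return frame
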