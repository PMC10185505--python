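"""Synthetic cohorts with a planted prognostic fingerprint.

The generator emulates the statistical structure the coherent voting
network assumes: two latent risk classes whose separation is carried by a
small coherent subset of features (the planted signature), survival times
consistent with the year-frame labeling rule, and right-censoring.  High-
class patients progress within the high-risk window (event time uniform on
(2, 12t] months); low-class patients survive event-free past the low
threshold (time uniform on [12(t+1), 12(t+1)+60)), with a mix of events
and censoring there.  An extra censoring pass truncates a configurable
fraction of patients uniformly over their follow-up, exercising the
indeterminate-label paths.

Signature features are shifted by ``effect_size`` standard deviations in
the high class; everything else is pure noise.  Optional clinical
covariates (two ordinals and one log-normal marker, all correlated with
the latent class) allow mixed clinical + omic fingerprints to be exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cvnprog.cohort_io import (
    Cohort,
    OmicsMatrix,
    SurvivalRecord,
    TimeFrame,
    assign_risk_labels,
)
from cvnprog.cvn import Fingerprint

__all__ = ["SimulationConfig", "generate_cohort", "write_cohort_files"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort simulator.

    effect_size is the standardized mean shift of the signature features
    between the risk classes; noise_sd the within-class standard deviation;
    high_fraction the latent high-risk prevalence; censor_fraction the
    fraction of patients whose follow-up is cut uniformly at random.
    """

    n_patients: int = 200
    n_features: int = 2000
    signature_size: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    censor_fraction: float = 0.15
    high_fraction: float = 0.5
    frame: TimeFrame = TimeFrame(3)
    seed: int = 0
    clinical_covariates: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.censor_fraction <= 1:
            raise ValueError("censor_fraction must lie in [0, 1]")
        if not 0 < self.high_fraction < 1:
            raise ValueError("high_fraction must lie in (0, 1)")
        if self.signature_size > self.n_features:
            raise ValueError("signature_size cannot exceed n_features")


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, Fingerprint]:
    """Draw one cohort; deterministic given ``config.seed``.

    Returns the labeled cohort (labels assigned by the year-frame rule from
    the generated survival records) and the planted signature.  By
    construction every non-censored patient's label reproduces the latent
    class.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_features
    digits = max(4, len(str(p)))
    patient_ids = [f"P{i:04d}" for i in range(n)]
    feature_ids = [f"g{i:0{digits}d}" for i in range(p)]

    latent_high = rng.random(n) < config.high_fraction
    # guarantee both classes exist even at tiny n
    if latent_high.all():
        latent_high[rng.integers(n)] = False
    elif not latent_high.any():
        latent_high[rng.integers(n)] = True

    values = rng.normal(0.0, config.noise_sd, size=(n, p))
    signature_idx = np.sort(rng.choice(p, size=config.signature_size, replace=False))
    shift = config.effect_size * config.noise_sd
    values[np.ix_(latent_high, signature_idx)] += shift

    hi_max = config.frame.high_threshold_months
    lo_min = config.frame.low_threshold_months
    times = np.where(
        latent_high,
        rng.uniform(2.0, hi_max, size=n),
        rng.uniform(lo_min, lo_min + 60.0, size=n),
    )
    # low-class patients: half observed progressing late, half censored late
    events = np.where(latent_high, True, rng.random(n) < 0.5)
    censored = rng.random(n) < config.censor_fraction
    times = np.where(censored, rng.uniform(0.0, 1.0, size=n) * times, times)
    events = np.where(censored, False, events)

    df = pd.DataFrame(values, index=patient_ids, columns=feature_ids)
    kinds = pd.Series("mrna", index=df.columns)
    if config.clinical_covariates:
        cls = latent_high.astype(float)
        gleason = np.clip(np.round(3.5 + cls + rng.normal(0, 0.6, n)), 3, 5)
        stage = np.clip(np.round(2.0 + cls + rng.normal(0, 0.7, n)), 1, 4)
        psa = np.exp(rng.normal(2.0 + 0.8 * cls, 0.5, n))
        for name, col in (("gleason_primary", gleason), ("tumor_stage", stage), ("psa", psa)):
            df[name] = col
            kinds[name] = "clinical"

    matrix = OmicsMatrix(values=df, feature_kinds=kinds)
    survival = [
        SurvivalRecord(pid, float(t), bool(e))
        for pid, t, e in zip(patient_ids, times, events)
    ]
    labels = assign_risk_labels(survival, config.frame)
    cohort = Cohort(matrix=matrix, survival=survival, labels=labels, frame=config.frame)
    signature = Fingerprint.from_features(
        [feature_ids[j] for j in signature_idx], matrix
    )
    return cohort, signature


def write_cohort_files(
    cohort: Cohort,
    signature: Fingerprint,
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write matrix.tsv, survival.tsv and a JSON sidecar with the planted
    signature and the generating configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / "matrix.tsv"
    survival_path = out_dir / "survival.tsv"
    sidecar_path = out_dir / "simulation.json"
    cohort.matrix.values.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort.survival],
            "pfs_months": [r.time_months for r in cohort.survival],
            "pfs_event": [int(r.event) for r in cohort.survival],
        }
    ).to_csv(survival_path, sep="\t", index=False)
    cfg = asdict(config)
    cfg["frame"] = str(config.frame)
    sidecar_path.write_text(
        json.dumps(
            {"planted_signature": list(signature.feature_ids), "config": cfg},
            indent=2,
        )
    )
    return {"matrix": matrix_path, "survival": survival_path, "sidecar": sidecar_path}
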