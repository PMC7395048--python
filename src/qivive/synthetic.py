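"""Seeded generators for every raw input the pipeline consumes.

Each generator emulates the statistical structure of the corresponding
laboratory dataset — sigmoidal FPDc concentration-response with
between-well noise and vehicle drift, Michaelis-Menten incubation rates
with multiplicative noise, equilibrium-dialysis chamber pairs, and
steady-state plasma kinetics from a perturbed PBK model — and returns the
generating ("truth") parameters alongside the data so that every
downstream stage has a recovery test.  Identical configurations produce
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import DialysisMeasurement
from .mea import WellRecording
from .mmkinetics import IncubationDataset
from .parameters import DoseRegimen, PbkParameterSet, build_default_model
from .pbk import simulate

__all__ = [
    "MeaCrcConfig", "MmIncubationConfig", "RedAssayConfig", "ClinicalPkConfig",
    "gen_mea_crc", "gen_mm_incubation", "gen_red_assay", "gen_clinical_pk",
    "hill_response", "hill_ec50_for_effect",
]

#: cumulative exposure grid used for the parent-compound assay (uM)
METHADONE_CONCENTRATIONS = (0.01, 0.03, 0.1, 0.2, 0.3, 0.4, 1.0, 3.0, 10.0, 30.0)


def hill_response(conc, emax: float, ec50: float, hill: float) -> np.ndarray:
    """FPDc effect (% points over baseline) of a sigmoidal concentration-response."""
    c = np.asarray(conc, dtype=float)
    return emax * c ** hill / (ec50 ** hill + c ** hill)


def hill_ec50_for_effect(effect: float, emax: float, hill: float,
                         conc_at_effect: float) -> float:
    """EC50 such that the curve passes ``effect`` points at ``conc_at_effect``."""
    if not 0 < effect < emax:
        raise ValueError("effect must lie strictly between 0 and Emax")
    return conc_at_effect * ((emax - effect) / effect) ** (1.0 / hill)


@dataclass
class MeaCrcConfig:
    """Design of a synthetic MEA concentration-response experiment.

    The effect curve is sigmoidal in FPDc percent points; by default its
    parameters are anchored so that the 20%-prolongation concentration is
    0.6 uM, the benchmark measured for the parent compound.  Irregular
    waveforms (arrhythmia-like traces, beating arrest at the top
    concentration) are injected from ``irregular_from_uM`` onward, which
    excludes those concentrations from FPD analysis downstream.
    """

    seed: int = 0
    concentrations: tuple = METHADONE_CONCENTRATIONS
    n_experiments: int = 4
    treated_wells_per_experiment: int = 2
    emax: float = 80.0
    hill: float = 1.5
    ec50: float = field(default=None)  # type: ignore[assignment]
    conc_at_20pct: float = 0.6
    baseline_fpd_s: float = 0.40
    baseline_rr_s: float = 1.25
    well_variability_sd: float = 0.03   # baseline FPD spread between wells (s)
    response_noise_cv: float = 0.10     # well-level noise, fraction of response
    vehicle_drift_per_step: float = -0.5  # % FPDc change per exposure step
    irregular_from_uM: float = 3.0
    arrest_at_uM: float = 30.0
    compound: str = "methadone"

    def __post_init__(self):
        if self.ec50 is None:
            self.ec50 = hill_ec50_for_effect(20.0, self.emax, self.hill,
                                             self.conc_at_20pct)
        if len(self.concentrations) == 0 or min(self.concentrations) <= 0:
            raise ValueError("concentration grid must be positive")

    def truth(self) -> dict:
        return {
            "emax": self.emax, "hill": self.hill, "ec50": self.ec50,
            "ec20_uM": self.ec50 * (20.0 / (self.emax - 20.0)) ** (1.0 / self.hill),
            "response_noise_cv": self.response_noise_cv,
            "vehicle_drift_per_step": self.vehicle_drift_per_step,
            "irregular_from_uM": self.irregular_from_uM,
        }


def gen_mea_crc(config: MeaCrcConfig) -> tuple[list[WellRecording], dict]:
    """Synthetic per-well MEA recordings plus the generating truth record.

    Each experiment carries one vehicle-control well (0.1% DMSO at every
    step) and ``treated_wells_per_experiment`` wells exposed cumulatively
    to the concentration grid.  The treated FPDc carries the truth effect
    plus the same vehicle drift, so the drift correction recovers the
    effect exactly in the noise-free limit.
    """
    rng = np.random.default_rng(config.seed)
    records: list[WellRecording] = []
    for e in range(config.n_experiments):
        exp = f"exp{e + 1}"
        # vehicle-control well: drift only
        base_fpd = config.baseline_fpd_s + rng.normal(0, config.well_variability_sd)
        for step in range(len(config.concentrations) + 1):
            drift_pct = config.vehicle_drift_per_step * step
            records.append(WellRecording(
                experiment=exp, well="vehicle", step=step, conc_uM=0.0,
                fpd_s=max(base_fpd * (100.0 + drift_pct) / 100.0, 1e-3),
                rr_s=config.baseline_rr_s,
                depol_uV=500.0, repol_uV=60.0))
        for wi in range(config.treated_wells_per_experiment):
            wid = f"w{wi + 1}"
            base_fpd = (config.baseline_fpd_s
                        + rng.normal(0, config.well_variability_sd))
            records.append(WellRecording(
                experiment=exp, well=wid, step=0, conc_uM=0.0,
                fpd_s=base_fpd, rr_s=config.baseline_rr_s,
                depol_uV=500.0, repol_uV=60.0))
            for step, conc in enumerate(config.concentrations, start=1):
                # drift enters additively in percent-of-baseline space, the
                # scale on which the vehicle correction subtracts it
                drift_pct = config.vehicle_drift_per_step * step
                effect = float(hill_response(conc, config.emax, config.ec50,
                                             config.hill))
                resp = 100.0 + effect + drift_pct
                if config.response_noise_cv > 0:
                    resp += rng.normal(0, config.response_noise_cv
                                       * (100.0 + effect))
                fpd = base_fpd * resp / 100.0
                flag = None
                if conc >= config.arrest_at_uM:
                    flag = "beating_arrest"
                elif conc >= config.irregular_from_uM:
                    flag = "arrhythmia"
                records.append(WellRecording(
                    experiment=exp, well=wid, step=step, conc_uM=conc,
                    fpd_s=max(fpd, 1e-3), rr_s=config.baseline_rr_s,
                    depol_uV=500.0, repol_uV=60.0, irregularity=flag))
    return records, config.truth()


@dataclass
class MmIncubationConfig:
    """Design of a synthetic microsomal incubation: 8 substrate levels
    spanning 10-1500 uM, triplicate, multiplicative rate noise."""

    seed: int = 0
    substrate_uM: tuple = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 1500.0)
    n_replicates: int = 3
    vmax: float = 0.82
    km: float = 275.0
    noise_cv: float = 0.05

    def truth(self) -> dict:
        return {"vmax": self.vmax, "km": self.km, "noise_cv": self.noise_cv}


def gen_mm_incubation(config: MmIncubationConfig
                      ) -> tuple[IncubationDataset, dict]:
    rng = np.random.default_rng(config.seed)
    s = np.repeat(np.asarray(config.substrate_uM, dtype=float),
                  config.n_replicates)
    rep = np.tile(np.arange(config.n_replicates), len(config.substrate_uM))
    v = config.vmax * s / (config.km + s)
    if config.noise_cv > 0:
        v = v * (1.0 + rng.normal(0, config.noise_cv, size=v.shape))
    v = np.clip(v, 0.0, None)
    return IncubationDataset(s, v, replicate=rep), config.truth()


@dataclass
class RedAssayConfig:
    """Synthetic rapid-equilibrium-dialysis design: nominal 150 uM sample,
    triplicate in two independent experiments."""

    seed: int = 0
    fu: float = 0.79
    nominal_sample_uM: float = 150.0
    n_replicates: int = 3
    n_experiments: int = 2
    noise_cv: float = 0.03
    matrix: str = "medium"
    compound: str = "methadone"

    def truth(self) -> dict:
        return {"fu": self.fu, "noise_cv": self.noise_cv}


def gen_red_assay(config: RedAssayConfig
                  ) -> tuple[list[DialysisMeasurement], dict]:
    rng = np.random.default_rng(config.seed)
    out = []
    for e in range(config.n_experiments):
        for r in range(config.n_replicates):
            sample = config.nominal_sample_uM * (
                1.0 + rng.normal(0, config.noise_cv))
            buffer = config.fu * sample * (1.0 + rng.normal(0, config.noise_cv))
            out.append(DialysisMeasurement(
                buffer_conc=max(buffer, 0.0), sample_conc=max(sample, 1e-9),
                matrix=config.matrix, compound=config.compound,
                replicate=e * config.n_replicates + r))
    return out, config.truth()


@dataclass
class ClinicalPkConfig:
    """Synthetic steady-state clinical kinetics: the PBK model with
    independently perturbed parameters stands in for a study population,
    sampled over the final dosing day with lognormal assay noise."""

    seed: int = 0
    dose_mg_per_day: float = 70.0
    bw: float = 74.0
    n_days: int = 30
    perturb_fraction: float = 0.2
    perturbed: tuple = ("ka", "Vmaxc", "Km", "RCLmet",
                        "PLmet", "PFmet", "PSmet", "PRmet")
    n_samples: int = 13
    noise_cv: float = 0.10

    def truth(self) -> dict:
        return {"dose_mg_per_day": self.dose_mg_per_day, "bw": self.bw,
                "perturb_fraction": self.perturb_fraction,
                "noise_cv": self.noise_cv}


def gen_clinical_pk(config: ClinicalPkConfig,
                    params: PbkParameterSet | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Plasma concentration-time samples over the last dosing interval.

    Blood concentrations from the perturbed model are converted to plasma
    by dividing by BPr.  Returns a tidy frame (time_h, plasma_ng_per_ml)
    and a truth record including the perturbation factors actually drawn.
    """
    if params is None:
        params = build_default_model()
    rng = np.random.default_rng(config.seed)
    factors = {}
    changes = {}
    for name in config.perturbed:
        f = 1.0 + rng.uniform(-config.perturb_fraction, config.perturb_fraction)
        factors[name] = f
        changes[name] = params.get(name) * f
    perturbed = params.updated({**changes, "BW": config.bw})
    res = simulate(perturbed, DoseRegimen(config.dose_mg_per_day,
                                          n_days=config.n_days))
    t = res.t
    mask = t >= t[-1] - res.regimen.interval - 1e-9
    tt = np.linspace(t[mask][0], t[-1], config.n_samples)
    blood = np.interp(tt, t[mask], res.venous_blood_conc("methadone")[mask])
    plasma_ngml = blood * params.methadone.MW / params.methadone.BPr
    if config.noise_cv > 0:
        plasma_ngml = plasma_ngml * np.exp(
            rng.normal(0, config.noise_cv, size=plasma_ngml.shape)
            - 0.5 * config.noise_cv ** 2)
    df = pd.DataFrame({"time_h": tt - tt[0], "plasma_ng_per_ml": plasma_ngml})
    truth = config.truth()
    truth["perturbation_factors"] = factors
    return df, truth
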