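"""Processing of multi-electrode-array (MEA) endpoint summaries.

hiPSC-CM cultures on MEA chips yield, per well and per exposure step, a
field potential duration (FPD, the in vitro analogue of the QT interval)
and an RR interval (beat period).  This module applies the rate
correction (Fridericia cube-root formula), the amplitude-based quality
filter, the vehicle/time drift correction and the irregularity exclusion
rules, and aggregates well recordings into a concentration-response
dataset expressed as FPDc percent of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRecording",
    "ConcentrationResponse",
    "fpdc_fridericia",
    "qc_filter",
    "vehicle_corrected_response",
    "concentration_response",
    "read_wells_csv",
    "wells_to_frame",
]

DEPOL_MIN_UV = 200.0
REPOL_MIN_UV = 20.0

IRREGULARITY_FLAGS = ("arrhythmia", "flattened_peak", "beating_arrest")


@dataclass
class WellRecording:
    """One 1-min recording of one well at one exposure step.

    ``step`` 0 is the pre-exposure baseline (vehicle only); a well whose
    concentration is 0 at every step is a time-matched vehicle control.
    ``fpd_s``/``rr_s`` may be scalars (already averaged over >= 30 beats)
    or per-beat sequences, in which case they are averaged here before
    rate correction.
    """

    experiment: str
    well: str
    step: int
    conc_uM: float
    fpd_s: float | Sequence[float]
    rr_s: float | Sequence[float]
    depol_uV: float = 500.0
    repol_uV: float = 50.0
    irregularity: str | None = None
    n_beats: int = 30

    def __post_init__(self):
        if np.any(np.asarray(self.fpd_s, dtype=float) <= 0):
            raise ValueError("FPD must be positive")
        if np.any(np.asarray(self.rr_s, dtype=float) <= 0):
            raise ValueError("RR interval must be positive")
        if self.depol_uV < 0 or self.repol_uV < 0:
            raise ValueError("peak amplitudes must be non-negative")
        if self.irregularity in ("", "none"):
            self.irregularity = None
        if self.irregularity is not None and \
                self.irregularity not in IRREGULARITY_FLAGS:
            raise ValueError(f"unknown irregularity flag {self.irregularity!r}")

    @property
    def mean_fpd(self) -> float:
        return float(np.mean(self.fpd_s))

    @property
    def mean_rr(self) -> float:
        return float(np.mean(self.rr_s))

    def fpdc(self, per_beat: bool = False) -> float:
        """Rate-corrected FPD.  By default the per-beat values are averaged
        before correction (mean FPD / cbrt(mean RR)); ``per_beat=True``
        corrects each beat and averages afterwards."""
        if per_beat:
            return float(np.mean(fpdc_fridericia(
                np.asarray(self.fpd_s, dtype=float),
                np.asarray(self.rr_s, dtype=float))))
        return float(fpdc_fridericia(self.mean_fpd, self.mean_rr))


def fpdc_fridericia(fpd_s, rr_s):
    """Fridericia rate correction FPDc = FPD / RR^(1/3), both in seconds."""
    fpd = np.asarray(fpd_s, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    if np.any(fpd <= 0) or np.any(rr <= 0):
        raise ValueError("FPD and RR must be positive (seconds)")
    out = fpd / np.cbrt(rr)
    return float(out) if out.ndim == 0 else out


def qc_filter(wells: Iterable[WellRecording]) -> list[WellRecording]:
    """Retain recordings with clearly visible peaks: depolarization
    >= 200 uV and repolarization >= 20 uV (boundary values pass)."""
    return [w for w in wells
            if w.depol_uV >= DEPOL_MIN_UV and w.repol_uV >= REPOL_MIN_UV]


def vehicle_corrected_response(treated_fpdc: float, baseline_fpdc: float,
                               vehicle_fpdc_t: float,
                               vehicle_fpdc_baseline: float) -> float:
    """FPDc percent of baseline, corrected for time/vehicle drift.

    response = 100 x treated/baseline - (100 x vehicle_t/vehicle_baseline - 100)
    """
    if baseline_fpdc <= 0 or vehicle_fpdc_baseline <= 0:
        raise ValueError("baseline FPDc values must be positive")
    drift = 100.0 * vehicle_fpdc_t / vehicle_fpdc_baseline - 100.0
    return 100.0 * treated_fpdc / baseline_fpdc - drift


@dataclass
class ConcentrationResponse:
    """Vehicle-corrected FPDc concentration-response summary.

    ``concentrations`` includes 0 for the baseline control.  Excluded
    concentrations (irregular waveforms, insufficient replication) are
    listed with reasons and are not part of the response arrays.
    """

    concentrations: np.ndarray        # uM
    response_mean: np.ndarray         # FPDc % of baseline
    response_sd: np.ndarray
    n: np.ndarray                     # independent experiments per point
    excluded: list[tuple[float, str]] = field(default_factory=list)
    compound: str = "methadone"

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response_mean = np.asarray(self.response_mean, dtype=float)
        self.response_sd = np.asarray(self.response_sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not np.all(np.isfinite(self.response_mean)):
            raise ValueError("responses must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "conc_uM": self.concentrations,
            "response_pct": self.response_mean,
            "sd": self.response_sd,
            "n": self.n,
        })


def concentration_response(wells: Iterable[WellRecording], *,
                           min_experiments: int = 3,
                           apply_qc: bool = True,
                           per_beat: bool = False,
                           compound: str = "methadone",
                           ) -> ConcentrationResponse:
    """Aggregate well recordings into a concentration-response dataset.

    Per experiment, vehicle wells (concentration 0 at every step) provide
    the time-matched drift reference; each treated well is normalized to
    its own baseline (step 0) and drift-corrected.  Well responses are
    averaged within an experiment, then summarized as mean +/- SD over
    experiments.  A concentration is excluded when any well shows an
    irregular waveform at it (FPD cannot be read there) or when fewer than
    ``min_experiments`` experiments remain.
    """
    wells = list(wells)
    if apply_qc:
        wells = qc_filter(wells)
    if not wells:
        return ConcentrationResponse(np.array([]), np.array([]), np.array([]),
                                     np.array([], dtype=int), [], compound)

    by_exp: dict[str, list[WellRecording]] = {}
    for w in wells:
        by_exp.setdefault(w.experiment, []).append(w)

    # well responses per (experiment, conc); irregularity bookkeeping
    responses: dict[float, dict[str, list[float]]] = {}
    flagged: dict[float, str] = {}
    for exp, recs in by_exp.items():
        wells_by_id: dict[str, list[WellRecording]] = {}
        for w in recs:
            wells_by_id.setdefault(w.well, []).append(w)
        vehicle_ids = [wid for wid, ws in wells_by_id.items()
                       if all(x.conc_uM == 0 for x in ws)]
        veh_fpdc: dict[int, list[float]] = {}
        for wid in vehicle_ids:
            for x in wells_by_id[wid]:
                veh_fpdc.setdefault(x.step, []).append(x.fpdc(per_beat))
        if 0 not in veh_fpdc:
            raise ValueError(f"experiment {exp!r}: vehicle well without "
                             "baseline (step 0) recording")
        veh_mean = {s: float(np.mean(v)) for s, v in veh_fpdc.items()}

        for wid, ws in wells_by_id.items():
            if wid in vehicle_ids:
                continue
            ws = sorted(ws, key=lambda x: x.step)
            base = [x for x in ws if x.step == 0]
            if not base:
                raise ValueError(f"well {exp}/{wid}: no baseline recording")
            base_fpdc = base[0].fpdc(per_beat)
            for x in ws:
                if x.step == 0 or x.conc_uM == 0:
                    continue
                if x.irregularity is not None:
                    flagged.setdefault(x.conc_uM, x.irregularity)
                    continue
                if x.step not in veh_mean:
                    raise ValueError(f"no vehicle recording for step {x.step} "
                                     f"in experiment {exp!r}")
                r = vehicle_corrected_response(
                    x.fpdc(per_beat), base_fpdc, veh_mean[x.step], veh_mean[0])
                responses.setdefault(x.conc_uM, {}).setdefault(exp, []).append(r)

    concs, means, sds, ns = [0.0], [100.0], [np.nan], [len(by_exp)]
    excluded: list[tuple[float, str]] = []
    for conc in sorted(set(responses) | set(flagged)):
        if conc in flagged:
            excluded.append((conc, f"irregular waveform: {flagged[conc]}"))
            continue
        exp_means = [float(np.mean(v)) for v in responses[conc].values()]
        if len(exp_means) < min_experiments:
            excluded.append((conc, f"only {len(exp_means)} experiments "
                                   f"(need >= {min_experiments})"))
            continue
        concs.append(conc)
        means.append(float(np.mean(exp_means)))
        sds.append(float(np.std(exp_means, ddof=1)))
        ns.append(len(exp_means))
    # normalizing every well to its own baseline pins the control response
    # at exactly 100; a nominal 1-point SD stands in for the FPDc
    # measurement resolution so likelihood-based fits stay well posed
    sds[0] = 1.0
    return ConcentrationResponse(np.array(concs), np.array(means),
                                 np.array(sds), np.array(ns, dtype=int),
                                 excluded, compound)


def significance_marks(crc: ConcentrationResponse,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Reporting-only significance annotation of treated concentrations.

    Per concentration, a one-sample t test of the experiment-mean responses
    against the control level (100%), Holm-adjusted across concentrations.
    Stars follow the usual convention (*, **, ***); the annotation never
    gates the pipeline.
    """
    from scipy import stats

    mask = crc.concentrations > 0
    mean = crc.response_mean[mask]
    sem = crc.response_sd[mask] / np.sqrt(crc.n[mask])
    df = crc.n[mask] - 1
    tstat = (mean - 100.0) / sem
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    # Holm step-down adjustment
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (len(p) - rank) * p[i])
        adj[i] = min(running, 1.0)
    stars = np.select([adj < 0.001, adj < 0.01, adj < alpha],
                      ["***", "**", "*"], default="")
    return pd.DataFrame({"conc_uM": crc.concentrations[mask],
                         "response_pct": mean, "p_holm": adj,
                         "significant": adj < alpha, "mark": stars})


def wells_to_frame(wells: Iterable[WellRecording]) -> pd.DataFrame:
    rows = [{"experiment": w.experiment, "well": w.well, "step": w.step,
             "conc_uM": w.conc_uM, "fpd_s": w.mean_fpd, "rr_s": w.mean_rr,
             "depol_uV": w.depol_uV, "repol_uV": w.repol_uV,
             "irregularity": w.irregularity or ""} for w in wells]
    return pd.DataFrame(rows)


def read_wells_csv(path) -> list[WellRecording]:
    """Read columns experiment, well, step, conc_uM, fpd_s, rr_s,
    depol_uV, repol_uV, irregularity."""
    df = pd.read_csv(path, keep_default_na=False)
    return [WellRecording(experiment=str(r.experiment), well=str(r.well),
                          step=int(r.step), conc_uM=float(r.conc_uM),
                          fpd_s=float(r.fpd_s), rr_s=float(r.rr_s),
                          depol_uV=float(r.depol_uV),
                          repol_uV=float(r.repol_uV),
                          irregularity=(r.irregularity or None))
            for r in df.itertuples()]
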