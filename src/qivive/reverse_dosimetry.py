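"""PBK model inversion: from in vitro effect concentrations to oral doses.

Reverse dosimetry finds, for each in vitro concentration, the daily oral
dose whose steady-state internal exposure matches it on an unbound basis:
the unbound in vitro concentration (C x fu_m) is set equal to the unbound
steady-state Cmax in heart venous blood (for methadone; systemic venous
blood for the EDDP screening case), converting plasma binding to blood
binding with fu_p/BPr.  Because the dose -> Cmax map is strictly
increasing, the inversion is a monotone root search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingScenario
from .mea import ConcentrationResponse
from .parameters import DoseRegimen, PbkParameterSet
from .pbk import simulate, steady_state_metrics

__all__ = [
    "DoseCmaxMap",
    "DoseResponsePrediction",
    "TargetOutOfRangeError",
    "dose_for_target",
    "translate_crc",
    "qtc_percent",
    "POPULATION_BASELINE_QTC_MS",
]

#: population baseline QTc (ms) used when a study reports none
#: (411 ms for females, 405 ms for males, 407 ms average)
POPULATION_BASELINE_QTC_MS = 407.0


class TargetOutOfRangeError(ValueError):
    """Requested internal concentration is unreachable within the dose bracket."""


class DoseCmaxMap:
    """Cached monotone map from daily dose to a steady-state Cmax output.

    Evaluations are full PBK simulations to steady state; the map caches
    them so that inverting many targets (a whole concentration-response
    curve, several binding scenarios) reuses earlier model runs.
    Inversion uses log-log regula falsi, which converges in a handful of
    simulations because the map is near power-law.
    """

    def __init__(self, params: PbkParameterSet, *, compound: str = "methadone",
                 output: str = "heart_venous", bw: float = 70.0,
                 bracket: tuple[float, float] = (1e-3, 1e4),
                 rtol: float = 2e-4, max_days: int = 120):
        if output not in ("heart_venous", "venous_blood"):
            raise ValueError("output must be 'heart_venous' or 'venous_blood'")
        self.params = params.updated({"BW": bw})
        self.compound = compound
        self.output = output
        self.bracket = bracket
        self.rtol = rtol
        self.max_days = max_days
        self._cache: dict[float, float] = {}

    def cmax(self, dose_mg_per_day: float) -> float:
        """Steady-state total Cmax (uM) of the configured output."""
        if dose_mg_per_day == 0:
            return 0.0
        if dose_mg_per_day not in self._cache:
            res = simulate(self.params, DoseRegimen(dose_mg_per_day),
                           until_steady_state=True, max_days=self.max_days)
            m = steady_state_metrics(res, self.compound)
            self._cache[dose_mg_per_day] = (
                m.Cmax_heart_venous_uM if self.output == "heart_venous"
                else m.Cmax_blood_uM)
        return self._cache[dose_mg_per_day]

    def check_monotone(self, n: int = 5) -> None:
        doses = np.geomspace(*self.bracket, n)
        vals = [self.cmax(d) for d in doses]
        if not np.all(np.diff(vals) > 0):
            raise RuntimeError(
                f"dose -> Cmax map is not strictly increasing over "
                f"{self.bracket}: {dict(zip(doses, vals))}")

    def dose_for(self, target_total_uM: float) -> float:
        """Daily dose whose Cmax equals the target within 0.1% relative."""
        if target_total_uM < 0:
            raise ValueError("target must be non-negative")
        if target_total_uM == 0:
            return 0.0
        lo, hi = self.bracket
        clo, chi = self.cmax(lo), self.cmax(hi)
        if not clo < chi:
            raise RuntimeError("dose -> Cmax map is not increasing at the "
                               "bracket endpoints")
        if not clo <= target_total_uM <= chi:
            raise TargetOutOfRangeError(
                f"target {target_total_uM:.4g} uM outside achievable Cmax "
                f"range [{clo:.4g}, {chi:.4g}] uM for doses in {self.bracket}")
        # tighten with any cached evaluations before interpolating
        for d, c in sorted(self._cache.items()):
            if c <= target_total_uM and d > lo:
                lo, clo = d, c
            if c >= target_total_uM and d < hi:
                hi, chi = d, c
                break
        lt = np.log(target_total_uM)
        for _ in range(60):
            llo, lhi = np.log(lo), np.log(hi)
            lclo, lchi = np.log(clo), np.log(chi)
            f = (lt - lclo) / (lchi - lclo)
            d = float(np.exp(llo + np.clip(f, 0.05, 0.95) * (lhi - llo)))
            c = self.cmax(d)
            if abs(c - target_total_uM) / target_total_uM <= self.rtol:
                return d
            if c < target_total_uM:
                lo, clo = d, c
            else:
                hi, chi = d, c
        raise RuntimeError("dose inversion did not converge to 0.1%")


def dose_for_target(params: PbkParameterSet, target_unbound_uM: float,
                    scenario: BindingScenario | None = None, *,
                    compound: str = "methadone", bw: float = 70.0,
                    output: str | None = None,
                    bracket: tuple[float, float] = (1e-3, 1e4),
                    mapper: DoseCmaxMap | None = None) -> float:
    """Daily oral methadone dose matching an unbound internal target (uM).

    The target is the unbound steady-state Cmax of ``compound`` in the
    output compartment: heart venous blood for methadone (the site used
    for effect translation), systemic venous blood for EDDP.  The unbound
    target is converted to a total-concentration target with BPr/fu_p
    (scenario values when given, otherwise the compound's defaults).
    """
    if target_unbound_uM < 0:
        raise ValueError("target must be non-negative")
    if target_unbound_uM == 0:
        return 0.0
    cp = params.compound(compound)
    fu_p = scenario.fu_p if scenario is not None else cp.fu_p
    bpr = scenario.BPr if scenario is not None else cp.BPr
    if output is None:
        output = "heart_venous" if cp.name == "methadone" else "venous_blood"
    if mapper is None:
        mapper = DoseCmaxMap(params, compound=compound, output=output,
                             bw=bw, bracket=bracket)
    target_total = target_unbound_uM * bpr / fu_p
    return mapper.dose_for(target_total)


@dataclass
class DoseResponsePrediction:
    """A translated in vivo dose-response curve for one binding scenario."""

    scenario: BindingScenario
    doses_mg_per_day: np.ndarray
    responses_pct: np.ndarray
    response_sd: np.ndarray
    n: np.ndarray
    compound: str = "methadone"
    bw: float = 70.0
    output: str = "heart_venous"
    out_of_range: list[tuple[float, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": self.scenario.label,
            "dose_mg_day": self.doses_mg_per_day,
            "response_pct": self.responses_pct,
            "sd": self.response_sd,
            "n": self.n,
        })

    def to_summary(self):
        from .bmd import ContinuousSummary
        return ContinuousSummary(self.doses_mg_per_day, self.responses_pct,
                                 self.response_sd, self.n)


def translate_crc(crc: ConcentrationResponse, scenario: BindingScenario,
                  params: PbkParameterSet, *, bw: float = 70.0,
                  output: str = "heart_venous",
                  mapper: DoseCmaxMap | None = None,
                  ) -> DoseResponsePrediction:
    """Translate a concentration-response curve into a dose-response curve.

    Each in vitro concentration C becomes the dose whose unbound
    steady-state Cmax equals C x fu_m; the effect percentage is carried
    over unchanged.  Targets beyond the achievable dose bracket are
    reported in ``out_of_range`` rather than silently dropped.  Pass a
    shared ``mapper`` when translating several scenarios to reuse PBK runs
    (the dose -> Cmax map does not depend on the binding scenario).
    """
    if mapper is None:
        mapper = DoseCmaxMap(params, compound=crc.compound, output=output, bw=bw)
    doses, resp, sds, ns = [], [], [], []
    oor: list[tuple[float, str]] = []
    # the control SD entry may be synthetic; keep the arrays aligned
    for c, r, s, n in zip(crc.concentrations, crc.response_mean,
                          crc.response_sd, crc.n):
        target_total = c * scenario.fu_m * scenario.BPr / scenario.fu_p
        try:
            d = mapper.dose_for(target_total)
        except TargetOutOfRangeError as err:
            oor.append((float(c), str(err)))
            continue
        doses.append(d)
        resp.append(r)
        sds.append(s)
        ns.append(n)
    return DoseResponsePrediction(
        scenario=scenario, doses_mg_per_day=np.asarray(doses),
        responses_pct=np.asarray(resp), response_sd=np.asarray(sds),
        n=np.asarray(ns, dtype=int), compound=crc.compound, bw=bw,
        output=mapper.output, out_of_range=oor)


def qtc_percent(qtc_ms: float,
                baseline_ms: float = POPULATION_BASELINE_QTC_MS) -> float:
    """QTc as percent of baseline (population baseline 407 ms by default)."""
    if baseline_ms <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * qtc_ms / baseline_ms
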