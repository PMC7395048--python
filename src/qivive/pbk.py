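"""Forward simulation of the methadone/EDDP PBK model.

The model is a stiff ODE system in amounts (umol).  Methadone occupies a
gut-lumen compartment plus nine perfused compartments; EDDP mirrors the
perfused compartments and is produced 1:1 on a molar basis by hepatic
metabolism of methadone.  Repeated oral dosing is implemented as
integration restarts with a gut-lumen bolus of ``Fa x dose`` at every
dosing time; the remaining ``(1 - Fa) x dose`` is booked as unabsorbed.

Tissue equations are perfusion-limited (well stirred): for a tissue T,
``dA_T/dt = Q_T (C_art - C_T / P_T)``.  The lung sits in series between
the venous and arterial blood pools.  Hepatic metabolism follows
Michaelis-Menten kinetics in the liver venous (blood-equivalent)
concentration ``CVL = C_liver / P_liver``.  Renal clearance removes drug
from the venous blood pool; biliary excretion removes EDDP from the liver
to a feces sink (no enterohepatic recirculation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import DoseRegimen, PbkParameterSet

__all__ = [
    "SimulationResult",
    "SteadyStateMetrics",
    "IntegrationError",
    "simulate",
    "steady_state_metrics",
    "mass_balance",
    "fit_eddp_clearance",
    "fold_difference",
]

# State vector layout (amounts, umol)
_M_GUT, _M_LIV, _M_FAT, _M_LUN, _M_KID, _M_HRT, _M_SLW, _M_RAP, _M_ART, _M_VEN, \
    _M_MET, _M_REN = range(12)
_E_LIV, _E_FAT, _E_LUN, _E_KID, _E_HRT, _E_SLW, _E_RAP, _E_ART, _E_VEN, \
    _E_REN, _E_BIL = range(12, 23)
_NSTATE = 23

_M_PERFUSED = (_M_LIV, _M_FAT, _M_LUN, _M_KID, _M_HRT, _M_SLW, _M_RAP, _M_ART, _M_VEN)
_E_PERFUSED = (_E_LIV, _E_FAT, _E_LUN, _E_KID, _E_HRT, _E_SLW, _E_RAP, _E_ART, _E_VEN)

# compartment name -> (methadone index, eddp index, volume-fraction attr, P attr)
_COMPARTMENTS = {
    "gut_lumen": (_M_GUT, None, None, None),
    "liver": (_M_LIV, _E_LIV, "VLc", "P_liver"),
    "fat": (_M_FAT, _E_FAT, "VFc", "P_fat"),
    "lung": (_M_LUN, _E_LUN, "VLuc", "P_lung"),
    "kidney": (_M_KID, _E_KID, "VKc", "P_kidney"),
    "heart": (_M_HRT, _E_HRT, "VHc", "P_heart"),
    "slowly_perfused": (_M_SLW, _E_SLW, "VSc", "P_slow"),
    "rapidly_perfused": (_M_RAP, _E_RAP, "VRc", "P_rapid"),
    "arterial_blood": (_M_ART, _E_ART, "VAc", None),
    "venous_blood": (_M_VEN, _E_VEN, "VVc", None),
}


class IntegrationError(RuntimeError):
    """ODE integration failed or produced physically impossible state."""


def scaled_vmax(params: PbkParameterSet) -> float:
    """In vivo hepatic Vmax (umol/h) from the microsomal rate.

    Vmax_c [nmol/min/mg] x 60 [min/h] / 1000 [nmol->umol] x MPL [mg/g]
    x liver mass [g] with liver mass = VLc x BW x 1000 g (density 1 g/ml).
    """
    ph, met = params.physiology, params.metabolism
    return met.Vmax_c * 60.0 * met.MPL * ph.VLc * ph.BW


def _make_rhs(params: PbkParameterSet):
    ph = params.physiology
    bw = ph.BW
    qc = ph.cardiac_output()
    VL, VF, VLu = ph.VLc * bw, ph.VFc * bw, ph.VLuc * bw
    VA, VV = ph.VAc * bw, ph.VVc * bw
    VK, VH, VS, VR = ph.VKc * bw, ph.VHc * bw, ph.VSc * bw, ph.VRc * bw
    QL, QF, QK = ph.QLc * qc, ph.QFc * qc, ph.QKc * qc
    QH, QS, QR = ph.QHc * qc, ph.QSc * qc, ph.QRc * qc
    # total tissue inflow; equals qc for balanced flow fractions but must be
    # used for the arterial outflow so that drug mass is conserved even under
    # one-at-a-time flow-fraction perturbations
    qtis = QL + QF + QK + QH + QS + QR

    m, e = params.methadone, params.eddp
    ka = params.absorption.ka
    vmax = scaled_vmax(params)
    km = params.metabolism.Km
    rclm, rcle, kbile = (params.clearance.RCLmet, params.clearance.RCLeddp,
                         params.clearance.kbile)

    PLm, PFm, PLum, PKm = m.P_liver, m.P_fat, m.P_lung, m.P_kidney
    PHm, PSm, PRm = m.P_heart, m.P_slow, m.P_rapid
    PLe, PFe, PLue, PKe = e.P_liver, e.P_fat, e.P_lung, e.P_kidney
    PHe, PSe, PRe = e.P_heart, e.P_slow, e.P_rapid

    def rhs(t, y):
        dy = np.empty(_NSTATE)
        # --- methadone -------------------------------------------------
        cart = y[_M_ART] / VA
        cven = y[_M_VEN] / VV
        cvl = y[_M_LIV] / VL / PLm          # liver venous (blood-equivalent)
        cvf = y[_M_FAT] / VF / PFm
        cvlu = y[_M_LUN] / VLu / PLum
        cvk = y[_M_KID] / VK / PKm
        cvh = y[_M_HRT] / VH / PHm
        cvs = y[_M_SLW] / VS / PSm
        cvr = y[_M_RAP] / VR / PRm
        r_abs = ka * y[_M_GUT]
        r_met = vmax * cvl / (km + cvl)
        dy[_M_GUT] = -r_abs
        dy[_M_LIV] = QL * (cart - cvl) + r_abs - r_met
        dy[_M_FAT] = QF * (cart - cvf)
        dy[_M_LUN] = qc * (cven - cvlu)
        dy[_M_KID] = QK * (cart - cvk)
        dy[_M_HRT] = QH * (cart - cvh)
        dy[_M_SLW] = QS * (cart - cvs)
        dy[_M_RAP] = QR * (cart - cvr)
        dy[_M_ART] = qc * cvlu - qtis * cart
        dy[_M_VEN] = (QL * cvl + QF * cvf + QK * cvk + QH * cvh
                      + QS * cvs + QR * cvr - qc * cven - rclm * cven)
        dy[_M_MET] = r_met
        dy[_M_REN] = rclm * cven
        # --- EDDP ------------------------------------------------------
        ecart = y[_E_ART] / VA
        ecven = y[_E_VEN] / VV
        ecvl = y[_E_LIV] / VL / PLe
        ecvf = y[_E_FAT] / VF / PFe
        ecvlu = y[_E_LUN] / VLu / PLue
        ecvk = y[_E_KID] / VK / PKe
        ecvh = y[_E_HRT] / VH / PHe
        ecvs = y[_E_SLW] / VS / PSe
        ecvr = y[_E_RAP] / VR / PRe
        r_bile = kbile * y[_E_LIV]
        dy[_E_LIV] = QL * (ecart - ecvl) + r_met - r_bile
        dy[_E_FAT] = QF * (ecart - ecvf)
        dy[_E_LUN] = qc * (ecven - ecvlu)
        dy[_E_KID] = QK * (ecart - ecvk)
        dy[_E_HRT] = QH * (ecart - ecvh)
        dy[_E_SLW] = QS * (ecart - ecvs)
        dy[_E_RAP] = QR * (ecart - ecvr)
        dy[_E_ART] = qc * ecvlu - qtis * ecart
        dy[_E_VEN] = (QL * ecvl + QF * ecvf + QK * ecvk + QH * ecvh
                      + QS * ecvs + QR * ecvr - qc * ecven - rcle * ecven)
        dy[_E_REN] = rcle * ecven
        dy[_E_BIL] = r_bile
        return dy

    return rhs


@dataclass
class SimulationResult:
    """Time courses of all compartment amounts for both compounds."""

    t: np.ndarray                      # h, strictly increasing
    y: np.ndarray                      # (23, len(t)) amounts, umol
    params: PbkParameterSet
    regimen: DoseRegimen
    n_doses: int

    @property
    def dose_umol(self) -> float:
        """Administered methadone per dosing event (umol of free base)."""
        return (self.regimen.dose_per_administration_mg
                / self.params.methadone.MW * 1000.0)

    @property
    def unabsorbed_umol(self) -> float:
        return self.n_doses * self.dose_umol * (1.0 - self.params.absorption.Fa)

    def _index(self, compound: str, compartment: str) -> int:
        try:
            im, ie, _, _ = _COMPARTMENTS[compartment]
        except KeyError:
            raise KeyError(f"unknown compartment {compartment!r}") from None
        c = compound.lower()
        if c == "methadone":
            return im
        if c == "eddp":
            if ie is None:
                raise KeyError(f"EDDP has no {compartment!r} compartment")
            return ie
        raise KeyError(f"unknown compound {compound!r}")

    def amount(self, compound: str, compartment: str) -> np.ndarray:
        return self.y[self._index(compound, compartment)]

    def concentration(self, compound: str, compartment: str) -> np.ndarray:
        """Total tissue concentration (uM)."""
        vattr = _COMPARTMENTS[compartment][2]
        if vattr is None:
            raise ValueError(f"{compartment!r} has no defined volume")
        vol = getattr(self.params.physiology, vattr) * self.params.physiology.BW
        return self.amount(compound, compartment) / vol

    def venous_blood_conc(self, compound: str) -> np.ndarray:
        return self.concentration(compound, "venous_blood")

    def heart_venous_conc(self, compound: str) -> np.ndarray:
        """Concentration in blood leaving the heart tissue: C_heart / P_heart."""
        p = self.params.compound(compound).P_heart
        return self.concentration(compound, "heart") / p

    def cumulative(self, which: str) -> np.ndarray:
        idx = {"metabolized": _M_MET, "renal_methadone": _M_REN,
               "renal_eddp": _E_REN, "bile_eddp": _E_BIL}[which]
        return self.y[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time_h, compound, compartment, amount_umol, conc_uM, conc_ng_per_ml."""
        rows = []
        for compartment, (im, ie, vattr, _) in _COMPARTMENTS.items():
            for compound, idx in (("methadone", im), ("eddp", ie)):
                if idx is None:
                    continue
                amount = self.y[idx]
                mw = self.params.compound(compound).MW
                if vattr is None:
                    conc = np.full_like(amount, np.nan)
                else:
                    vol = (getattr(self.params.physiology, vattr)
                           * self.params.physiology.BW)
                    conc = amount / vol
                rows.append(pd.DataFrame({
                    "time_h": self.t, "compound": compound,
                    "compartment": compartment, "amount_umol": amount,
                    "conc_uM": conc, "conc_ng_per_ml": conc * mw,
                }))
        return pd.concat(rows, ignore_index=True)


def simulate(params: PbkParameterSet, regimen: DoseRegimen, *,
             n_points_per_interval: int = 120,
             method: str = "LSODA", rtol: float = 1e-8, atol: float = 1e-10,
             until_steady_state: bool = False, ss_rtol: float = 1e-3,
             max_days: int = 120,
             allow_unnormalized: bool = False) -> SimulationResult:
    """Integrate the PBK model over the dosing regimen.

    With ``until_steady_state=True`` the regimen's ``n_days`` is ignored and
    dosing continues until the venous-blood Cmax of both compounds changes by
    less than ``ss_rtol`` between consecutive dosing intervals (capped at
    ``max_days``).
    """
    params.validate(allow_unnormalized=allow_unnormalized)
    regimen.validate()
    if n_points_per_interval < 100:
        raise ValueError("need >= 100 output points per dosing interval")

    mw = params.methadone.MW
    dose_umol = regimen.dose_per_administration_mg / mw * 1000.0
    fa = params.absorption.Fa
    interval = regimen.interval
    n_intervals = (int(round(max_days * 24.0 / interval)) if until_steady_state
                   else int(round(regimen.duration_h / interval)))
    rhs = _make_rhs(params)

    y0 = np.zeros(_NSTATE)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    prev_cmax = None
    n_doses = 0
    vv = params.physiology.VVc * params.physiology.BW

    for k in range(n_intervals):
        t0, t1 = k * interval, (k + 1) * interval
        y0 = y0.copy()
        y0[_M_GUT] += fa * dose_umol
        n_doses += 1
        t_eval = np.linspace(t0, t1, n_points_per_interval + 1)
        sol = solve_ivp(rhs, (t0, t1), y0, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(f"solver failed in interval {k}: {sol.message}")
        if sol.y.min() < -max(1e-6, 1e-9 * max(dose_umol, 1.0)):
            raise IntegrationError(
                f"negative amounts beyond tolerance (min {sol.y.min():.3e})")
        last = k == n_intervals - 1
        cmax_m = sol.y[_M_VEN].max() / vv
        cmax_e = sol.y[_E_VEN].max() / vv
        if until_steady_state and prev_cmax is not None and not last:
            pm, pe = prev_cmax
            scale = max(cmax_m, 1e-30)
            scale_e = max(cmax_e, 1e-30)
            if (abs(cmax_m - pm) / scale < ss_rtol
                    and abs(cmax_e - pe) / scale_e < ss_rtol):
                last = True
        prev_cmax = (cmax_m, cmax_e)
        if last:
            ts.append(sol.t)
            ys.append(sol.y)
            break
        ts.append(sol.t[:-1])
        ys.append(sol.y[:, :-1])
        y0 = sol.y[:, -1]

    t = np.concatenate(ts)
    y = np.clip(np.concatenate(ys, axis=1), 0.0, None)
    return SimulationResult(t=t, y=y, params=params, regimen=regimen,
                            n_doses=n_doses)


@dataclass
class SteadyStateMetrics:
    """Exposure metrics over the final dosing interval."""

    compound: str
    Cmax_blood_uM: float
    Cmax_blood_ng_per_ml: float
    AUC_interval_ng_h_per_ml: float
    Cmax_heart_venous_uM: float
    Cmax_unbound_blood_uM: float
    interval_h: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def steady_state_metrics(result: SimulationResult, compound: str = "methadone",
                         ) -> SteadyStateMetrics:
    """Cmax and trapezoidal AUC of venous blood over the final dosing interval.

    The unbound blood Cmax applies the plasma-binding correction
    ``fu_p / BPr`` of the requested compound.
    """
    interval = result.regimen.interval
    t = result.t
    if t[-1] - t[0] < interval - 1e-9:
        raise ValueError("result spans less than one full dosing interval")
    cp = result.params.compound(compound)
    mask = t >= t[-1] - interval - 1e-9
    conc = result.venous_blood_conc(compound)[mask]
    ngml = conc * cp.MW
    cmax = float(conc.max())
    auc = float(np.trapezoid(ngml, t[mask]))
    chv = float(result.heart_venous_conc(compound)[mask].max())
    return SteadyStateMetrics(
        compound=cp.name,
        Cmax_blood_uM=cmax,
        Cmax_blood_ng_per_ml=cmax * cp.MW,
        AUC_interval_ng_h_per_ml=auc,
        Cmax_heart_venous_uM=chv,
        Cmax_unbound_blood_uM=cmax * cp.fu_p / cp.BPr,
        interval_h=float(interval),
    )


def mass_balance(result: SimulationResult) -> float:
    """Maximum relative mass-balance residual over both compounds.

    Methadone: administered = unabsorbed + sum(compartments) + renal + metabolized.
    EDDP: formed (= methadone metabolized) = sum(compartments) + renal + biliary.
    Returns 0 by convention for a zero dose.
    """
    administered = result.n_doses * result.dose_umol
    if administered == 0:
        return 0.0
    yf = result.y[:, -1]
    m_total = (result.unabsorbed_umol + yf[_M_GUT]
               + sum(yf[i] for i in _M_PERFUSED) + yf[_M_MET] + yf[_M_REN])
    res_m = abs(administered - m_total) / administered
    formed = yf[_M_MET]
    if formed <= 0:
        return res_m
    e_total = sum(yf[i] for i in _E_PERFUSED) + yf[_E_REN] + yf[_E_BIL]
    res_e = abs(formed - e_total) / formed
    return max(res_m, res_e)


def _eddp_blood_cmax(params: PbkParameterSet, dose_mg_per_day: float,
                     bw: float) -> float:
    ps = params.updated({"BW": bw})
    res = simulate(ps, DoseRegimen(dose_mg_per_day=dose_mg_per_day),
                   until_steady_state=True)
    return steady_state_metrics(res, "eddp").Cmax_blood_uM


def fit_eddp_clearance(params: PbkParameterSet, dose_mg_per_day: float,
                       bw: float, target_blood_cmax_eddp: float,
                       free_param: str = "RCLeddp",
                       bounds: tuple[float, float] = (1e-4, 1e3),
                       ) -> "ClearanceParams":
    """Fit one EDDP clearance constant to a steady-state blood Cmax target.

    Returns a new :class:`ClearanceParams` in which ``free_param`` (either
    ``"RCLeddp"`` or ``"kbile"``) is adjusted so that the simulated
    steady-state EDDP venous-blood Cmax matches the target within 0.1%.
    Fitting both constants to a single Cmax target is under-determined and
    raises ``ValueError``.
    """
    from .parameters import ClearanceParams  # local to avoid cycle in __all__

    if target_blood_cmax_eddp <= 0:
        raise ValueError("target Cmax must be positive")
    if free_param == "both":
        raise ValueError(
            "fitting RCLeddp and kbile jointly to a single Cmax target is "
            "under-determined; fix one parameter or supply a second target")
    if free_param not in ("RCLeddp", "kbile"):
        raise ValueError(f"unknown free_param {free_param!r}")

    def f(logp: float) -> float:
        ps = params.updated({free_param: 10.0 ** logp})
        return (_eddp_blood_cmax(ps, dose_mg_per_day, bw)
                - target_blood_cmax_eddp)

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target {target_blood_cmax_eddp} uM not reachable for "
            f"{free_param} within bounds {bounds}: Cmax range "
            f"[{min(flo, fhi) + target_blood_cmax_eddp:.4g}, "
            f"{max(flo, fhi) + target_blood_cmax_eddp:.4g}] uM")
    root = brentq(f, lo, hi, xtol=1e-6, rtol=1e-12)
    fitted = 10.0 ** root
    achieved = f(root) + target_blood_cmax_eddp
    if abs(achieved - target_blood_cmax_eddp) / target_blood_cmax_eddp > 1e-3:
        raise RuntimeError("clearance fit did not reach 0.1% of target")
    new = dataclasses.replace(params.clearance)
    setattr(new, free_param, fitted)
    return new


def fold_difference(predicted: float, observed: float) -> float:
    """Ratio predicted/observed used to evaluate model predictions."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed
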