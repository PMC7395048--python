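"""Michaelis-Menten analysis of microsomal incubation data.

Estimates the apparent Vmax and Km for the hepatic conversion of methadone
to EDDP from substrate-rate data, and scales the microsomal Vmax to a
whole-liver in vivo rate for use in the PBK model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "IncubationDataset",
    "MichaelisMentenFit",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "scale_vmax_in_vivo",
    "intestinal_rate_negligible",
]

#: rates below this fraction of the hepatic rate are reported as negligible
INTESTINAL_FLOOR = 0.08


def _mm(s, vmax, km):
    return vmax * s / (km + s)


@dataclass
class IncubationDataset:
    """Substrate concentrations (uM) and metabolite formation rates
    (nmol/min/mg microsomal protein), optionally replicated."""

    substrate_uM: np.ndarray
    rate_nmol_min_mg: np.ndarray
    replicate: np.ndarray | None = None
    substrate: str = "methadone"
    metabolite: str = "EDDP"

    def __post_init__(self):
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.rate_nmol_min_mg = np.asarray(self.rate_nmol_min_mg, dtype=float)
        if self.substrate_uM.shape != self.rate_nmol_min_mg.shape:
            raise ValueError("substrate and rate arrays must have equal length")
        if np.any(self.substrate_uM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rate_nmol_min_mg < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.substrate_uM))

    @classmethod
    def from_csv(cls, path, **kw) -> "IncubationDataset":
        """Read columns substrate_uM, rate_nmol_min_mg[, replicate]."""
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(df["substrate_uM"].to_numpy(),
                   df["rate_nmol_min_mg"].to_numpy(), replicate=rep, **kw)


@dataclass
class MichaelisMentenFit:
    Vmax: float
    Km: float
    Vmax_sd: float
    Km_sd: float
    rss: float
    converged: bool
    reliable: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def catalytic_efficiency(self) -> float:
        """Vmax/Km x 1000 (ul/min/mg microsomal protein)."""
        return catalytic_efficiency(self.Vmax, self.Km)

    def predict(self, s):
        return _mm(np.asarray(s, dtype=float), self.Vmax, self.Km)


def fit_michaelis_menten(data: IncubationDataset) -> MichaelisMentenFit:
    """Unweighted nonlinear least squares of v = Vmax [S] / (Km + [S]).

    Initialization is Vmax0 = max(v) and Km0 = [S] at half-maximal rate
    (linear interpolation), which makes the fit deterministic given the
    data.  A Km estimate beyond 10x the largest tested concentration, or a
    non-converged optimizer, flags the result as unreliable.
    """
    if data.n_distinct < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    s, v = data.substrate_uM, data.rate_nmol_min_mg
    order = np.argsort(s)
    s_m = s[order]
    v_m = v[order]
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    km0 = float(np.interp(half, v_m, s_m)) if v_m.max() > half else float(np.median(s))
    km0 = max(km0, s.min())
    flags: list[str] = []
    try:
        popt, pcov = curve_fit(_mm, s, v, p0=[vmax0, km0],
                               bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                               maxfev=10000)
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
    except RuntimeError:
        popt, pcov = np.array([vmax0, km0]), np.full((2, 2), np.nan)
        converged = False
        flags.append("optimizer did not converge")
    vmax, km = float(popt[0]), float(popt[1])
    sds = np.sqrt(np.diag(pcov)) if converged else np.array([np.nan, np.nan])
    rss = float(np.sum((v - _mm(s, vmax, km)) ** 2))
    reliable = converged
    if km > 10 * s.max():
        reliable = False
        flags.append(f"Km estimate {km:.3g} uM exceeds 10x max tested "
                     f"concentration ({s.max():.3g} uM)")
    return MichaelisMentenFit(Vmax=vmax, Km=km, Vmax_sd=float(sds[0]),
                              Km_sd=float(sds[1]), rss=rss,
                              converged=bool(converged), reliable=reliable,
                              flags=flags)


def catalytic_efficiency(vmax: float, km: float) -> float:
    """Intrinsic clearance proxy Vmax/Km x 1000 (ul/min/mg)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    return vmax / km * 1000.0


def scale_vmax_in_vivo(vmax_c: float, mpl: float, vlc: float, bw: float) -> float:
    """Scale a microsomal Vmax (nmol/min/mg) to the whole liver (umol/h).

    Vmax_vivo = Vmax_c x 60/1000 x MPL x liver mass (g), with liver mass
    VLc x BW x 1000 g at a density of 1 g/ml.
    """
    if min(mpl, vlc, bw) <= 0:
        raise ValueError("MPL, VLc and BW must be positive")
    if vmax_c < 0:
        raise ValueError("Vmax_c must be non-negative")
    return vmax_c * 60.0 / 1000.0 * mpl * vlc * bw * 1000.0


def intestinal_rate_negligible(intestinal_rate: float, hepatic_rate: float,
                               floor: float = INTESTINAL_FLOOR) -> bool:
    """Whether an intestinal formation rate is below the reporting floor
    (default 8% of the hepatic rate) and therefore not fitted."""
    if hepatic_rate <= 0:
        raise ValueError("hepatic rate must be positive")
    return intestinal_rate < floor * hepatic_rate
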