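"""Benchmark dose/concentration estimation with AIC-weighted model averaging.

Continuous summary data (dose, mean, SD, n per group) are fitted by
maximum likelihood under normal errors on the group means to a set of
nested dose-response families (exponential and Hill mandatory;
inverse-exponential and log-normal optional).  The benchmark dose (BMD)
for a benchmark response (BMR), defined as a relative deviation from the
fitted control response, is read off the Akaike-weighted average of the
normalized fitted curves.  Confidence limits (BMDL/BMDU, 5th/95th
percentile) come from a parametric bootstrap that resamples the group
means with standard error SD/sqrt(n) and refits all models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares
from scipy.stats import norm

__all__ = [
    "ContinuousSummary",
    "DoseResponseModelFit",
    "BmdEstimate",
    "fit_family",
    "model_averaged_bmd",
    "bmc20",
    "fit_4pl",
    "FAMILIES",
    "DEFAULT_FAMILIES",
    "EXTENDED_FAMILIES",
]

DEFAULT_FAMILIES = ("exponential3", "exponential", "hill")
EXTENDED_FAMILIES = ("exponential3", "exponential", "hill",
                     "inverse-exponential", "log-normal")


@dataclass
class ContinuousSummary:
    """Per-group summary statistics of a continuous endpoint."""

    dose: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(self.sd < 0) or np.any(self.n < 1):
            raise ValueError("each group needs sd >= 0 and n >= 1")
        # degenerate (noise-free synthetic) groups: floor the SD so the
        # normal likelihood stays defined; weights become effectively equal
        floor = 1e-9 * max(1.0, float(np.max(np.abs(self.mean), initial=1.0)))
        self.sd = np.maximum(self.sd, floor)
        order = np.argsort(self.dose)
        for attr in ("dose", "mean", "sd", "n"):
            setattr(self, attr, getattr(self, attr)[order])

    @property
    def sem(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n)

    @classmethod
    def from_concentration_response(cls, crc) -> "ContinuousSummary":
        if len(crc.concentrations) < 2 or np.all(crc.concentrations == 0):
            raise ValueError("need dose groups beyond the control")
        return cls(crc.concentrations, crc.response_mean, crc.response_sd, crc.n)


# ---------------------------------------------------------------------------
# model families; x is the dose scaled by xscale (max dose), theta[0] = a is
# the control response, direction is carried by c (or the sign of b)

def _f_exp3(u, a, b, d):
    return a * np.exp(np.clip(b * u ** d, -700, 700))


def _f_exp5(u, a, b, c, d):
    return a * (c - (c - 1.0) * np.exp(-np.clip(b * u ** d, 0, 700)))


def _f_hill(u, a, b, c, d):
    ud = u ** d
    return a * (1.0 + (c - 1.0) * ud / (b ** d + ud))


def _f_invexp(u, a, b, c, d):
    with np.errstate(divide="ignore", over="ignore"):
        z = np.where(u > 0, np.exp(-np.clip(b * u ** (-d), 0, 700)), 0.0)
    return a * (1.0 + (c - 1.0) * z)


def _f_lognormal(u, a, b, c, d):
    with np.errstate(divide="ignore"):
        z = np.where(u > 0, norm.cdf(d * np.log(np.maximum(u, 1e-300) / b)), 0.0)
    return a * (1.0 + (c - 1.0) * z)


FAMILIES = {
    "exponential3": (_f_exp3, ("a", "b", "d")),
    "exponential": (_f_exp5, ("a", "b", "c", "d")),
    "hill": (_f_hill, ("a", "b", "c", "d")),
    "inverse-exponential": (_f_invexp, ("a", "b", "c", "d")),
    "log-normal": (_f_lognormal, ("a", "b", "c", "d")),
}

_D_BOUNDS = (0.25, 8.0)


def _loglik(data: ContinuousSummary, mu: np.ndarray) -> float:
    var = data.sem ** 2
    return float(-0.5 * np.sum(np.log(2 * np.pi * var)
                               + (data.mean - mu) ** 2 / var))


@dataclass
class DoseResponseModelFit:
    family: str
    params: np.ndarray
    param_names: tuple
    loglik: float
    aic: float
    converged: bool
    dose_related_trend: bool
    xscale: float
    data: ContinuousSummary = field(repr=False)

    def predict(self, x) -> np.ndarray:
        f = FAMILIES[self.family][0]
        return f(np.asarray(x, dtype=float) / self.xscale, *self.params)

    @property
    def control(self) -> float:
        return float(self.params[0])

    def bmd(self, bmr: float, direction: str = "increase") -> float | None:
        """Dose at which the fitted curve deviates by ``bmr`` (relative)
        from the fitted control; None when never reached."""
        return _invert_curve(lambda x: self.predict(x) / self.control,
                             bmr, direction, self.xscale)


def _invert_curve(g, bmr: float, direction: str, xscale: float) -> float | None:
    """First crossing of the normalized curve with 1 +/- bmr; ``g`` must be
    vectorized over dose."""
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    target = 1.0 + bmr if direction == "increase" else 1.0 - bmr
    grid = np.geomspace(xscale * 1e-6, xscale * 100.0, 300)
    vals = np.asarray(g(grid)) - target
    sign0 = np.sign(float(g(np.array([0.0]))[0]) - target)
    if sign0 == 0:
        sign0 = -1.0 if direction == "increase" else 1.0
    idx = np.nonzero(np.sign(vals) != sign0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    lo = grid[i - 1] if i > 0 else xscale * 1e-9
    h = lambda x: float(g(np.array([x]))[0]) - target
    return float(brentq(h, lo, grid[i], xtol=xscale * 1e-9, rtol=1e-10))


def _starts(data: ContinuousSummary, family: str):
    a0 = float(data.mean[data.dose == data.dose.min()].mean())
    yend = float(data.mean[-1])
    c0 = np.clip(yend / max(a0, 1e-9), 1e-3, 1e3)
    pos = data.dose[data.dose > 0]
    u_mid = float(np.median(pos) / data.dose.max()) if len(pos) else 0.3
    out = []
    for d0 in (0.5, 1.0, 2.0, 4.0):
        if family == "exponential3":
            b0 = np.log(max(c0, 1e-3))
            out.append([a0, b0, d0])
        elif family == "exponential":
            out.append([a0, 1.0 / max(u_mid, 1e-3) ** d0, c0, d0])
        elif family == "hill":
            out.append([a0, u_mid, c0, d0])
        elif family == "inverse-exponential":
            out.append([a0, max(u_mid, 1e-3) ** d0, c0, d0])
        elif family == "log-normal":
            out.append([a0, u_mid, c0, d0])
    return out


def _bounds(family: str):
    dlo, dhi = _D_BOUNDS
    if family == "exponential3":
        return ([1e-9, -50.0, dlo], [np.inf, 50.0, dhi])
    return ([1e-9, 1e-9, 1e-6, dlo], [np.inf, np.inf, 1e6, dhi])


def fit_family(data, family: str,
               p0: np.ndarray | None = None) -> DoseResponseModelFit:
    """Maximum-likelihood fit of one dose-response family to summary data.

    ``data`` may be a :class:`ContinuousSummary` or a concentration-response
    object.  The fit is flagged ``dose_related_trend=False`` when it does
    not beat a constant (no-effect) model on AIC.  ``p0`` replaces the
    default multi-start initialization (used by the bootstrap, which
    restarts from the original fit).
    """
    if not isinstance(data, ContinuousSummary):
        data = ContinuousSummary.from_concentration_response(data)
    if len(np.unique(data.dose[data.dose > 0])) < 3:
        raise ValueError("need >= 4 dose levels (incl. control) for fitting")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {list(FAMILIES)}")
    f, names = FAMILIES[family]
    xscale = float(data.dose.max())
    u = data.dose / xscale
    w = 1.0 / data.sem

    def resid(theta):
        return (f(u, *theta) - data.mean) * w

    lo, hi = _bounds(family)
    best = None
    starts = [p0] if p0 is not None else _starts(data, family)
    for start in starts:
        start = np.clip(start, np.asarray(lo) + 1e-12, np.asarray(hi) - 1e-12)
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseModelFit(family, np.array([np.nan]), names,
                                    -np.inf, np.inf, False, False, xscale, data)
    theta = best.x
    ll = _loglik(data, f(u, *theta))
    k = len(theta)
    aic = 2 * k - 2 * ll
    # constant-response reference model (one parameter)
    mu0 = np.sum(data.mean / data.sem ** 2) / np.sum(1.0 / data.sem ** 2)
    aic_null = 2 * 1 - 2 * _loglik(data, np.full_like(data.mean, mu0))
    return DoseResponseModelFit(family, theta, names, ll, aic,
                                converged=bool(best.success),
                                dose_related_trend=aic < aic_null,
                                xscale=xscale, data=data)


@dataclass
class BmdEstimate:
    """Model-averaged benchmark dose with bootstrap confidence limits."""

    bmr: float
    direction: str
    bmd: float
    bmdl: float
    bmdu: float
    weights: dict
    model_bmds: dict
    n_bootstrap: int
    n_bootstrap_failed: int = 0

    def to_dict(self) -> dict:
        return {"bmr": self.bmr, "direction": self.direction,
                "bmd": self.bmd, "bmdl": self.bmdl, "bmdu": self.bmdu,
                "weights": self.weights, "model_bmds": self.model_bmds,
                "n_bootstrap": self.n_bootstrap,
                "n_bootstrap_failed": self.n_bootstrap_failed}


def _akaike_weights(fits) -> np.ndarray:
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _ma_bmd(fits, weights, bmr, direction) -> float | None:
    xscale = fits[0].xscale

    def g(x):
        return sum(w * f.predict(x) / f.control
                   for w, f in zip(weights, fits))

    return _invert_curve(g, bmr, direction, xscale)


def model_averaged_bmd(fits, bmr: float, direction: str = "increase",
                       n_bootstrap: int = 200, seed: int | None = None,
                       ) -> BmdEstimate:
    """Akaike-weighted model-averaged BMD with parametric-bootstrap limits.

    ``fits`` are per-family fits of the same dataset; non-converged fits
    are excluded from averaging.  Weights are exp(-dAIC/2), normalized.
    The BMD solves the weighted average of the normalized fitted curves
    for a relative deviation ``bmr`` from control; BMDL/BMDU are the
    5th/95th percentiles over ``n_bootstrap`` refitted resamples of the
    group means (~ N(mean, SD/sqrt(n))).
    """
    if not 0 < bmr < 1:
        raise ValueError("BMR must lie in (0, 1)")
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged model fits to average")
    if not any(f.dose_related_trend for f in fits):
        raise ValueError("no dose-related trend: BMD is undefined for a "
                         "flat response")
    weights = _akaike_weights(fits)
    bmd = _ma_bmd(fits, weights, bmr, direction)
    if bmd is None:
        raise ValueError(f"averaged curve never reaches the {bmr:.0%} "
                         f"benchmark response ({direction})")
    data = fits[0].data
    rng = np.random.default_rng(seed)
    boot: list[float] = []
    failed = 0
    for _ in range(n_bootstrap):
        m = rng.normal(data.mean, data.sem)
        bdata = ContinuousSummary(data.dose, m, data.sd, data.n)
        bfits = [fit_family(bdata, f.family, p0=f.params) for f in fits]
        bfits = [f for f in bfits if f.converged]
        if not bfits:
            failed += 1
            continue
        b = _ma_bmd(bfits, _akaike_weights(bfits), bmr, direction)
        if b is None:
            failed += 1
            continue
        boot.append(b)
    if len(boot) < n_bootstrap // 2:
        raise RuntimeError(f"bootstrap failed in {failed}/{n_bootstrap} replicates")
    bmdl = float(np.percentile(boot, 5))
    bmdu = float(np.percentile(boot, 95))
    return BmdEstimate(
        bmr=bmr, direction=direction, bmd=bmd,
        bmdl=min(bmdl, bmd), bmdu=max(bmdu, bmd),
        weights={f.family: float(w) for f, w in zip(fits, weights)},
        model_bmds={f.family: f.bmd(bmr, direction) for f in fits},
        n_bootstrap=n_bootstrap, n_bootstrap_failed=failed)


def bmc20(crc, direction: str = "increase", *,
          extended_families: bool = False, n_bootstrap: int = 200,
          seed: int | None = None) -> BmdEstimate:
    """Benchmark concentration for a 20% FPDc change over control.

    Fits the model set to a concentration-response dataset and returns the
    model-averaged estimate at BMR = 0.20 in concentration units.
    """
    data = ContinuousSummary.from_concentration_response(crc)
    fams = EXTENDED_FAMILIES if extended_families else DEFAULT_FAMILIES
    fits = [fit_family(data, fam) for fam in fams]
    return model_averaged_bmd(fits, bmr=0.20, direction=direction,
                              n_bootstrap=n_bootstrap, seed=seed)


def fit_4pl(conc, response):
    """Four-parameter logistic fit (reporting/plotting).

    y = bottom + (top - bottom) / (1 + (ec50/x)^hill); returns a dict with
    bottom/top/ec50/hill, a ``converged`` flag and a ``predict`` callable.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    pos = x > 0
    if len(np.unique(x[pos])) < 4:
        raise ValueError("need >= 4 positive concentrations")

    def f(xx, bottom, top, ec50, hill):
        with np.errstate(divide="ignore", over="ignore"):
            z = np.where(xx > 0, (ec50 / np.maximum(xx, 1e-300)) ** hill, np.inf)
        return bottom + (top - bottom) / (1.0 + z)

    p0 = [float(y[~pos].mean() if np.any(~pos) else y.min()),
          float(y.max() if y[pos][-1] >= y[0] else y.min()),
          float(np.median(x[pos])), 1.0]
    try:
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt, converged = np.array(p0), False
    return {"bottom": float(popt[0]), "top": float(popt[1]),
            "ec50": float(popt[2]), "hill": float(popt[3]),
            "converged": converged,
            "predict": lambda xx: f(np.asarray(xx, dtype=float), *popt)}
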