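"""Local one-at-a-time sensitivity analysis of the PBK model.

The normalized sensitivity coefficient of an output C to a parameter P is

    SC = ((C' - C) / (P' - P)) x (P / C)

with C' the output after a small fractional increase of P (default 1%).
The default output is the steady-state methadone Cmax in heart venous
blood, the internal dose metric used for reverse dosimetry.  Parameters
with |SC| > 0.1 are flagged as influential.

Fractional-composition parameters (volume and flow fractions) are
perturbed one at a time without re-normalizing the remaining fractions;
the flow balance is therefore transiently violated by the perturbation
size, which is the standard practice for this type of local analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import DoseRegimen, FLAT_SYMBOLS, PbkParameterSet
from .pbk import simulate, steady_state_metrics

__all__ = ["normalized_sc", "sensitivity_report", "DEFAULT_PARAMETERS",
           "INFLUENTIAL_THRESHOLD"]

INFLUENTIAL_THRESHOLD = 0.1

#: parameters scanned by default (all with a causal path to methadone
#: kinetics, plus the EDDP clearances as negative controls)
DEFAULT_PARAMETERS = (
    "BW", "VLc", "VFc", "VLuc", "VAc", "VVc", "VKc", "VHc", "VSc", "VRc",
    "Qc", "QLc", "QFc", "QKc", "QHc", "QSc", "QRc",
    "ka", "Fa", "RCLmet", "Vmaxc", "Km", "MPL",
    "PLmet", "PFmet", "PSmet", "PRmet", "PLumet", "PKmet", "PHmet",
    "RCLeddp", "kbile",
)

_OUTPUTS = {
    "heart_venous_methadone": ("methadone", "Cmax_heart_venous_uM"),
    "heart_venous_eddp": ("eddp", "Cmax_heart_venous_uM"),
    "venous_blood_methadone": ("methadone", "Cmax_blood_uM"),
    "venous_blood_eddp": ("eddp", "Cmax_blood_uM"),
}


def _output_value(params: PbkParameterSet, dose_mg_per_day: float,
                  n_days: int, output: str, rtol: float) -> float:
    compound, attr = _OUTPUTS[output]
    res = simulate(params, DoseRegimen(dose_mg_per_day, n_days=n_days),
                   allow_unnormalized=True, rtol=rtol, atol=rtol * 1e-2)
    return getattr(steady_state_metrics(res, compound), attr)


def normalized_sc(params: PbkParameterSet, param_name: str,
                  dose_mg_per_day: float, *, delta: float = 0.01,
                  n_days: int = 35, output: str = "heart_venous_methadone",
                  rtol: float = 1e-8,
                  baseline: float | None = None) -> float:
    """Normalized sensitivity coefficient of a steady-state Cmax.

    ``baseline`` allows reusing a precomputed unperturbed output when many
    parameters are scanned.  A fixed simulation length (default 35 days,
    well past the ~25 h methadone half-life) is used for both runs so that
    the residual approach-to-steady-state error cancels.
    """
    if param_name not in FLAT_SYMBOLS:
        raise KeyError(f"unknown parameter {param_name!r}")
    p = params.get(param_name)
    if p <= 0:
        raise ValueError(f"{param_name} must be positive for a relative "
                         "perturbation")
    if dose_mg_per_day <= 0:
        raise ValueError("SC is undefined at zero dose (output is zero)")
    if baseline is None:
        baseline = _output_value(params, dose_mg_per_day, n_days, output, rtol)
    if baseline == 0:
        raise ValueError("model output is zero; SC undefined")
    perturbed = params.updated({param_name: p * (1.0 + delta)})
    c2 = _output_value(perturbed, dose_mg_per_day, n_days, output, rtol)
    return ((c2 - baseline) / baseline) / delta


def sensitivity_report(params: PbkParameterSet,
                       param_names=DEFAULT_PARAMETERS,
                       doses=(20.0, 200.0), *, delta: float = 0.01,
                       n_days: int = 35,
                       output: str = "heart_venous_methadone",
                       ) -> pd.DataFrame:
    """Tabulate SCs at each dose, sorted by magnitude.

    Columns: parameter, one ``SC_<dose>mg`` column per dose, ``max_abs_sc``
    and an ``influential`` flag (|SC| > 0.1 at any dose).  Signed values
    are reported; headline figures conventionally show magnitudes.
    """
    cols: dict[str, list[float]] = {f"SC_{dose:g}mg": [] for dose in doses}
    for dose in doses:
        base = _output_value(params, dose, n_days, output, 1e-8)
        for name in param_names:
            sc = normalized_sc(params, name, dose, delta=delta, n_days=n_days,
                               output=output, baseline=base)
            cols[f"SC_{dose:g}mg"].append(sc)
    df = pd.DataFrame({"parameter": list(param_names), **cols})
    sc_cols = [c for c in df.columns if c.startswith("SC_")]
    df["max_abs_sc"] = df[sc_cols].abs().max(axis=1)
    df["influential"] = df["max_abs_sc"] > INFLUENTIAL_THRESHOLD
    return df.sort_values("max_abs_sc", ascending=False,
                          ignore_index=True)
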