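"""Protein-binding measurements and conversions.

Fraction unbound is measured by rapid equilibrium dialysis (RED): at
equilibrium the free drug concentration is equal on both sides of the
dialysis membrane, so fu = C_buffer / C_sample.

Reverse dosimetry equates unbound concentrations between the in vitro
exposure medium and human blood:

    C_total,invitro x fu_m  =  C_total,blood x fu_p / BPr

where fu_m and fu_p are the fractions unbound in medium and plasma and
BPr the blood:plasma concentration ratio (the ratio fu_p/BPr converts a
plasma unbound fraction into a blood unbound fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DialysisMeasurement",
    "FractionUnbound",
    "BindingScenario",
    "fraction_unbound",
    "unbound_in_medium",
    "invitro_to_total_blood",
    "unbound_blood",
    "methadone_scenarios",
    "read_dialysis_csv",
]


@dataclass
class DialysisMeasurement:
    """One equilibrium-dialysis chamber pair (any consistent units)."""

    buffer_conc: float
    sample_conc: float
    matrix: str = "plasma"          # "plasma" | "medium"
    compound: str = "methadone"
    replicate: int = 0

    def __post_init__(self):
        if self.sample_conc <= 0:
            raise ValueError("sample-chamber concentration must be positive")
        if self.buffer_conc < 0:
            raise ValueError("buffer-chamber concentration must be non-negative")


@dataclass
class FractionUnbound:
    fu: float
    sd: float
    n: int
    exceeds_one: bool = False        # QC flag; value reported as computed


@dataclass
class BindingScenario:
    """A protein-binding scenario for reverse dosimetry."""

    label: str
    fu_m: float
    fu_p: float
    BPr: float

    def __post_init__(self):
        for name in ("fu_m", "fu_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} must lie in (0, 1]")
        if self.BPr <= 0:
            raise ValueError("BPr must be positive")


def fraction_unbound(measurements) -> FractionUnbound:
    """Mean fu = buffer/sample over replicates, with a QC flag when > 1.

    Accepts an iterable of :class:`DialysisMeasurement` or of
    (buffer, sample) pairs.  Values above 1 (possible with noisy data)
    are reported as computed but flagged, not truncated silently.
    """
    ratios = []
    for m in measurements:
        if isinstance(m, DialysisMeasurement):
            ratios.append(m.buffer_conc / m.sample_conc)
        else:
            buffer_conc, sample_conc = m
            if sample_conc <= 0:
                raise ValueError("sample-chamber concentration must be positive")
            ratios.append(buffer_conc / sample_conc)
    if not ratios:
        raise ValueError("no measurements supplied")
    arr = np.asarray(ratios, dtype=float)
    fu = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return FractionUnbound(fu=fu, sd=sd, n=len(arr), exceeds_one=fu > 1.0)


def unbound_in_medium(c_invitro: float, fu_m: float) -> float:
    """Unbound concentration in the exposure medium: C x fu_m."""
    return c_invitro * fu_m


def invitro_to_total_blood(c_invitro: float, scenario: BindingScenario) -> float:
    """Total blood concentration whose unbound level matches the in vitro one.

    C_blood = C_invitro x fu_m x BPr / fu_p.
    """
    if c_invitro < 0:
        raise ValueError("concentration must be non-negative")
    return c_invitro * scenario.fu_m * scenario.BPr / scenario.fu_p


def unbound_blood(c_total_blood: float, fu_p: float, bpr: float) -> float:
    """Unbound blood concentration: C_blood x fu_p / BPr."""
    if c_total_blood < 0 or fu_p < 0:
        raise ValueError("inputs must be non-negative")
    if bpr <= 0:
        raise ValueError("BPr must be positive")
    return c_total_blood * fu_p / bpr


def methadone_scenarios(fu_m: float = 0.79, bpr: float = 0.70
                        ) -> list[BindingScenario]:
    """The four plasma-binding scenarios spanning reported variability.

    fu_p of 0.22 and 0.034 are literature extremes, 0.15 an in silico
    prediction and 0.055 the equilibrium-dialysis measurement in pooled
    human plasma.
    """
    return [
        BindingScenario("fu_p=0.22 (literature high)", fu_m, 0.22, bpr),
        BindingScenario("fu_p=0.15 (in silico)", fu_m, 0.15, bpr),
        BindingScenario("fu_p=0.055 (dialysis)", fu_m, 0.055, bpr),
        BindingScenario("fu_p=0.034 (literature low)", fu_m, 0.034, bpr),
    ]


def read_dialysis_csv(path) -> list[DialysisMeasurement]:
    """Read columns compound, matrix, replicate, buffer_conc, sample_conc."""
    df = pd.read_csv(path)
    return [DialysisMeasurement(buffer_conc=row.buffer_conc,
                                sample_conc=row.sample_conc,
                                matrix=row.matrix, compound=row.compound,
                                replicate=int(row.replicate))
            for row in df.itertuples()]
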