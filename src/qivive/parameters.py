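"""Parameter sets for the methadone/EDDP physiologically based kinetic (PBK) model.

The model describes a human adult as nine perfusion-limited compartments
(liver, fat, lung, kidney, heart, slowly and rapidly perfused tissue,
arterial and venous blood) plus a gut lumen for oral absorption.  Methadone
is absorbed by a first-order process, distributed according to
tissue:blood partition coefficients, cleared by hepatic Michaelis-Menten
metabolism to its primary metabolite EDDP (modelled in a parallel submodel)
and by renal excretion.  EDDP is cleared renally and by biliary excretion.

All parameters carry the symbols conventionally used for this model family
(BW, VLc, Qc, QLc, ka, Fa, Vmax_c, Km, MPL, BPr, fu_p, P_*) so that YAML/JSON
configuration files read like the published parameter tables.

Units: volumes L, flows L/h, amounts umol, concentrations uM, time h,
masses kg (body) / mg (dose), Vmax_c nmol/min/mg microsomal protein, Km uM.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "PhysiologyParams",
    "CompoundParams",
    "AbsorptionParams",
    "MetabolismParams",
    "ClearanceParams",
    "DoseRegimen",
    "PbkParameterSet",
    "build_default_model",
    "FLAT_SYMBOLS",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass
class PhysiologyParams:
    """Reference human physiology: tissue volumes and perfusion.

    Volume fractions (``V*c``) are fractions of body mass (density 1 kg/L),
    flow fractions (``Q*c``) are fractions of cardiac output and must sum to
    exactly one.  ``Qc`` is the cardiac output of the ``BW_ref`` (70 kg)
    reference adult; for other body masses the model scales cardiac output
    allometrically as ``Qc * (BW / BW_ref) ** 0.75``.
    """

    BW: float = 70.0
    VLc: float = 0.0257
    VFc: float = 0.2142
    VLuc: float = 0.0076
    VAc: float = 0.0198
    VVc: float = 0.0593
    VKc: float = 0.004
    VHc: float = 0.0047
    VSc: float = 0.5318
    VRc: float = 0.052
    Qc: float = 347.9
    QLc: float = 0.227
    QFc: float = 0.052
    QKc: float = 0.175
    QHc: float = 0.04
    QSc: float = 0.188
    QRc: float = 0.318
    BW_ref: float = 70.0

    def volume_fractions(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("VLc", "VFc", "VLuc", "VAc", "VVc", "VKc", "VHc", "VSc", "VRc")}

    def flow_fractions(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("QLc", "QFc", "QKc", "QHc", "QSc", "QRc")}

    def cardiac_output(self) -> float:
        """Cardiac output (L/h) at the configured body mass."""
        return self.Qc * (self.BW / self.BW_ref) ** 0.75

    def validate(self, *, allow_unnormalized: bool = False) -> None:
        if self.BW <= 0:
            raise ParameterError("BW must be positive")
        if self.Qc <= 0:
            raise ParameterError("Qc must be positive")
        for name, frac in {**self.volume_fractions(), **self.flow_fractions()}.items():
            if not 0 < frac < 1:
                raise ParameterError(f"{name}={frac} must lie in (0, 1)")
        vsum = sum(self.volume_fractions().values())
        if vsum > 1 + 1e-9:
            raise ParameterError(f"volume fractions sum to {vsum} > 1")
        qsum = sum(self.flow_fractions().values())
        if abs(qsum - 1.0) > 1e-9 and not allow_unnormalized:
            raise ParameterError(
                f"flow fractions sum to {qsum}, expected 1.0 "
                "(pass allow_unnormalized=True to override, e.g. for "
                "one-at-a-time sensitivity perturbations)")


@dataclass
class CompoundParams:
    """Compound-specific distribution properties.

    ``P_*`` are tissue:blood partition coefficients, ``BPr`` the
    blood:plasma concentration ratio and ``fu_p`` the fraction unbound in
    plasma.  ``logP``/``pKa`` are carried as metadata only.
    """

    name: str
    MW: float
    BPr: float
    fu_p: float
    P_liver: float
    P_fat: float
    P_slow: float
    P_rapid: float
    P_lung: float
    P_kidney: float
    P_heart: float
    logP: float | None = None
    pKa: float | None = None

    def validate(self) -> None:
        if self.MW <= 0:
            raise ParameterError(f"{self.name}: MW must be positive")
        if self.BPr <= 0:
            raise ParameterError(f"{self.name}: BPr must be positive")
        if not 0 < self.fu_p <= 1:
            raise ParameterError(f"{self.name}: fu_p must lie in (0, 1]")
        for attr in ("P_liver", "P_fat", "P_slow", "P_rapid",
                     "P_lung", "P_kidney", "P_heart"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{self.name}: {attr} must be positive")


@dataclass
class AbsorptionParams:
    """First-order oral absorption: rate constant ka (1/h), fraction absorbed Fa."""

    ka: float = 0.59
    Fa: float = 0.88

    def validate(self) -> None:
        if self.ka <= 0:
            raise ParameterError("ka must be positive")
        if not 0 < self.Fa <= 1:
            raise ParameterError("Fa must lie in (0, 1]")


@dataclass
class MetabolismParams:
    """Hepatic Michaelis-Menten metabolism of methadone to EDDP.

    ``Vmax_c`` is the apparent microsomal maximum rate (nmol/min/mg
    microsomal protein), ``Km`` the apparent Michaelis constant (uM) and
    ``MPL`` the microsomal protein yield of liver (mg protein/g liver).
    """

    Vmax_c: float = 0.82
    Km: float = 275.0
    MPL: float = 32.0

    def validate(self) -> None:
        for attr in ("Vmax_c", "Km", "MPL"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be positive")


@dataclass
class ClearanceParams:
    """Excretion constants: renal clearances (L/h) and EDDP biliary rate (1/h)."""

    RCLmet: float = 1.45
    RCLeddp: float = 19.99
    kbile: float = 1.65

    def validate(self) -> None:
        for attr in ("RCLmet", "RCLeddp", "kbile"):
            if getattr(self, attr) < 0:
                raise ParameterError(f"{attr} must be non-negative")


@dataclass
class DoseRegimen:
    """Repeated oral dosing of methadone free base.

    ``dose_mg_per_day`` is divided evenly over the dosing ``interval`` (h);
    the default of 24 h gives one daily bolus for ``n_days`` days.
    """

    dose_mg_per_day: float
    interval: float = 24.0
    n_days: int = 30

    def validate(self) -> None:
        if self.dose_mg_per_day < 0:
            raise ParameterError("dose must be non-negative")
        if self.interval <= 0:
            raise ParameterError("interval must be positive")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")

    @property
    def dose_per_administration_mg(self) -> float:
        return self.dose_mg_per_day * self.interval / 24.0

    @property
    def duration_h(self) -> float:
        return self.n_days * 24.0


# Flat symbol table used for sensitivity analysis and quick overrides:
# symbol -> (section attribute on PbkParameterSet, field name).
FLAT_SYMBOLS: dict[str, tuple[str, str]] = {
    "BW": ("physiology", "BW"),
    "VLc": ("physiology", "VLc"), "VFc": ("physiology", "VFc"),
    "VLuc": ("physiology", "VLuc"), "VAc": ("physiology", "VAc"),
    "VVc": ("physiology", "VVc"), "VKc": ("physiology", "VKc"),
    "VHc": ("physiology", "VHc"), "VSc": ("physiology", "VSc"),
    "VRc": ("physiology", "VRc"),
    "Qc": ("physiology", "Qc"),
    "QLc": ("physiology", "QLc"), "QFc": ("physiology", "QFc"),
    "QKc": ("physiology", "QKc"), "QHc": ("physiology", "QHc"),
    "QSc": ("physiology", "QSc"), "QRc": ("physiology", "QRc"),
    "ka": ("absorption", "ka"), "Fa": ("absorption", "Fa"),
    "RCLmet": ("clearance", "RCLmet"),
    "RCLeddp": ("clearance", "RCLeddp"),
    "kbile": ("clearance", "kbile"),
    "Vmaxc": ("metabolism", "Vmax_c"),
    "Km": ("metabolism", "Km"),
    "MPL": ("metabolism", "MPL"),
    "PLmet": ("methadone", "P_liver"), "PFmet": ("methadone", "P_fat"),
    "PSmet": ("methadone", "P_slow"), "PRmet": ("methadone", "P_rapid"),
    "PLumet": ("methadone", "P_lung"), "PKmet": ("methadone", "P_kidney"),
    "PHmet": ("methadone", "P_heart"),
    "BPrmet": ("methadone", "BPr"), "fupmet": ("methadone", "fu_p"),
    "PLeddp": ("eddp", "P_liver"), "PFeddp": ("eddp", "P_fat"),
    "PSeddp": ("eddp", "P_slow"), "PReddp": ("eddp", "P_rapid"),
    "PLueddp": ("eddp", "P_lung"), "PKeddp": ("eddp", "P_kidney"),
    "PHeddp": ("eddp", "P_heart"),
    "BPreddp": ("eddp", "BPr"), "fupeddp": ("eddp", "fu_p"),
}


@dataclass
class PbkParameterSet:
    """Complete parameterization of the methadone/EDDP PBK model."""

    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    methadone: CompoundParams = None  # type: ignore[assignment]
    eddp: CompoundParams = None  # type: ignore[assignment]
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    clearance: ClearanceParams = field(default_factory=ClearanceParams)

    def validate(self, *, allow_unnormalized: bool = False) -> None:
        self.physiology.validate(allow_unnormalized=allow_unnormalized)
        self.methadone.validate()
        self.eddp.validate()
        self.absorption.validate()
        self.metabolism.validate()
        self.clearance.validate()

    def compound(self, name: str) -> CompoundParams:
        key = name.lower()
        if key in ("methadone", "met"):
            return self.methadone
        if key == "eddp":
            return self.eddp
        raise KeyError(f"unknown compound {name!r}; expected 'methadone' or 'eddp'")

    # -- flat-symbol access (sensitivity analysis, CLI overrides) --------
    def get(self, symbol: str) -> float:
        section, attr = FLAT_SYMBOLS[symbol]
        return getattr(getattr(self, section), attr)

    def updated(self, changes: dict[str, float]) -> "PbkParameterSet":
        """Deep copy with flat-symbol overrides applied (no re-normalization)."""
        new = copy.deepcopy(self)
        for symbol, value in changes.items():
            section, attr = FLAT_SYMBOLS[symbol]
            setattr(getattr(new, section), attr, value)
        return new

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "physiology": dataclasses.asdict(self.physiology),
            "methadone": dataclasses.asdict(self.methadone),
            "eddp": dataclasses.asdict(self.eddp),
            "absorption": dataclasses.asdict(self.absorption),
            "metabolism": dataclasses.asdict(self.metabolism),
            "clearance": dataclasses.asdict(self.clearance),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PbkParameterSet":
        return cls(
            physiology=PhysiologyParams(**d.get("physiology", {})),
            methadone=CompoundParams(**d["methadone"]),
            eddp=CompoundParams(**d["eddp"]),
            absorption=AbsorptionParams(**d.get("absorption", {})),
            metabolism=MetabolismParams(**d.get("metabolism", {})),
            clearance=ClearanceParams(**d.get("clearance", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PbkParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_methadone() -> CompoundParams:
    return CompoundParams(
        name="methadone", MW=309.45, logP=3.93, pKa=9.20,
        BPr=0.70, fu_p=0.15,
        P_liver=12.45, P_fat=0.46, P_slow=7.67, P_rapid=12.45,
        P_lung=1.77, P_kidney=7.56, P_heart=4.9,
    )


def _default_eddp() -> CompoundParams:
    return CompoundParams(
        name="eddp", MW=277.4, logP=4.63, pKa=9.64,
        BPr=0.87, fu_p=0.30,
        P_liver=11.51, P_fat=0.18, P_slow=7.06, P_rapid=11.51,
        P_lung=1.56, P_kidney=6.95, P_heart=4.48,
    )


def build_default_model() -> PbkParameterSet:
    """The fully parameterized human methadone/EDDP model.

    Physiology is the 70-kg reference adult; methadone absorption
    ka = 0.59/h, Fa = 0.88; hepatic metabolism Vmax_c = 0.82 nmol/min/mg,
    Km = 275 uM scaled with MPL = 32 mg/g liver; renal clearance of
    methadone 1.45 L/h; EDDP renal clearance 19.99 L/h and biliary rate
    constant 1.65/h (values calibrated against steady-state EDDP blood
    levels observed under 57.5 mg/day maintenance treatment).
    """
    ps = PbkParameterSet(
        physiology=PhysiologyParams(),
        methadone=_default_methadone(),
        eddp=_default_eddp(),
        absorption=AbsorptionParams(),
        metabolism=MetabolismParams(),
        clearance=ClearanceParams(),
    )
    ps.validate()
    return ps
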