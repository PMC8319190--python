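"""Model parameters and derived scalar quantities.

Units are fixed package-wide: time in seconds, volumes in mL, rate
constants in 1/s, concentrations in amount/mL.  Fractions are
dimensionless values in [0, 1].

The physiological picture: a tumor segment is perfused by plasma at rate
``F_p = v_p / TT`` (plasma volume fraction over microvascular transit
time).  Free drug exchanges between plasma and the extravascular-
extracellular space (EES) at a rate set by the permeability-surface-area
product ``PS``; the fraction of drug removed from plasma in a single
microvascular pass is the extraction fraction ``EF = 1 - exp(-PS/F_p)``.
Two dimensionless ratios govern triggered intravascular delivery: the
release index ``RI = t_rel / TT`` and the permeability index
``PI = PS / F_p``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .errors import InvalidParameterError, ValidationError

log = logging.getLogger(__name__)

#: Default microvascular hematocrit (red-cell volume fraction in tumor
#: microvessels); lower than systemic hematocrit.
DEFAULT_HCT_MV = 0.19


@dataclass
class TumorTransport:
    """Tumor transport parameters of the imaged tissue segment.

    Attributes
    ----------
    v_p : float
        Plasma volume fraction of tumor tissue.
    v_e_av : float
        Available extravascular volume fraction, ``k_av * v_e``.
    TT : float
        Tissue (microvascular) transit time, s.
    PS : float
        Vascular permeability-surface-area product, 1/s.
    Hct_mv : float
        Microvascular hematocrit.
    v_v, v_e, k_av : float, optional
        Vascular volume fraction, extravascular volume fraction and
        available fraction of the extravascular volume.  Optional because
        only the combinations ``v_p`` and ``v_e_av`` enter the model.
    F_p : float, optional
        Plasma perfusion, 1/s.  Derived from ``v_p / TT`` unless given,
        in which case consistency is checked to 10% and a warning logged.
    sd : mapping, optional
        Per-field standard deviations, keyed by field name; consumed by
        the uncertainty and sensitivity analyses.
    """

    v_p: float
    v_e_av: float
    TT: float
    PS: float
    Hct_mv: float = DEFAULT_HCT_MV
    v_v: Optional[float] = None
    v_e: Optional[float] = None
    k_av: Optional[float] = None
    F_p: Optional[float] = None
    sd: Mapping[str, float] = field(default_factory=dict)


@dataclass
class SystemicPK:
    """Systemic two-compartment pharmacokinetic parameters.

    ``k_p`` multiplies the systemic plasma concentration and ``k_t`` the
    systemic tissue concentration in the compartment equations (the rate
    constant *names* follow the source parameter table, whose directional
    labels are reversed relative to this usage; the equations win here —
    see docs/methods.md).
    """

    V_D: float            # initial volume of distribution, mL
    V_p_S: float          # systemic plasma volume, mL
    k_p: float            # 1/s, coefficient of systemic plasma concentration
    k_t: float            # 1/s, coefficient of systemic tissue concentration
    k_e: float            # 1/s, elimination rate constant
    sd: Mapping[str, float] = field(default_factory=dict)


@dataclass
class TumorGeometry:
    """Tumor volume and derived tumor plasma volume."""

    VT: float                       # tumor (segment) volume, mL
    V_p_T: Optional[float] = None   # tumor plasma volume = VT * v_p, mL
    sd: Mapping[str, float] = field(default_factory=dict)


@dataclass
class DoseSpec:
    """Injected dose and its form (free drug or encapsulated in a DDS)."""

    ID: float          # injected dose, amount
    form: str = "encapsulated"   # {"free", "encapsulated"}

    def __post_init__(self):
        if self.ID <= 0:
            raise InvalidParameterError("injected dose ID must be > 0")
        if self.form not in ("free", "encapsulated"):
            raise InvalidParameterError(
                f"dose form must be 'free' or 'encapsulated', got {self.form!r}")


@dataclass(frozen=True)
class IndexPair:
    """The two dimensionless delivery indices."""

    RI: float   # release index t_rel / TT
    PI: float   # permeability index PS / F_p


@dataclass
class ParameterBundle:
    """A validated, internally consistent parameter set.

    Produced by :func:`validate_params`; all derived fields
    (``F_p``, ``V_p_T``, ``EF``) are filled in.
    """

    tumor: TumorTransport
    pk: SystemicPK
    geometry: TumorGeometry
    EF: float = 0.0

    @property
    def F_p(self) -> float:
        return self.tumor.F_p

    @property
    def plasma_flow(self) -> float:
        """Tumor plasma volumetric flow Q = V_p_T * F_p / v_p, mL/s.

        Equals V_p_T / TT when F_p is the derived value v_p / TT.
        """
        return self.geometry.V_p_T * self.tumor.F_p / self.tumor.v_p

    def copy(self) -> "ParameterBundle":
        return ParameterBundle(
            tumor=replace(self.tumor, sd=dict(self.tumor.sd)),
            pk=replace(self.pk, sd=dict(self.pk.sd)),
            geometry=replace(self.geometry, sd=dict(self.geometry.sd)),
            EF=self.EF,
        )


def derive_perfusion(v_p: float, TT: float) -> float:
    """Plasma perfusion ``F_p = v_p / TT`` (1/s, i.e. mL plasma/mL tissue/s).

    The companion blood-perfusion relation is ``F / v_v = F_p / v_p = 1/TT``.
    """
    if not TT > 0 or not math.isfinite(TT):
        if TT == math.inf:
            return 0.0
        raise InvalidParameterError(f"transit time TT must be > 0, got {TT}")
    if not 0 < v_p <= 1:
        raise InvalidParameterError(f"plasma fraction v_p must be in (0, 1], got {v_p}")
    return v_p / TT


def extraction_fraction(PS: float, F_p: float) -> float:
    """First-pass extraction fraction ``EF = 1 - exp(-PS/F_p)``.

    Bounded in [0, 1) and strictly increasing in PS for fixed perfusion.
    """
    if not F_p > 0:
        raise InvalidParameterError(f"perfusion F_p must be > 0, got {F_p}")
    if PS < 0:
        raise InvalidParameterError(f"PS must be >= 0, got {PS}")
    return -math.expm1(-PS / F_p)


def compute_indices(t_rel: float, TT: float, PS: float, F_p: float) -> IndexPair:
    """Release index ``RI = t_rel/TT`` and permeability index ``PI = PS/F_p``."""
    if not (t_rel > 0 and TT > 0):
        raise InvalidParameterError("t_rel and TT must be > 0")
    if not F_p > 0:
        raise InvalidParameterError("F_p must be > 0")
    if not PS > 0:
        raise InvalidParameterError("PS must be > 0 for a finite permeability index")
    return IndexPair(RI=t_rel / TT, PI=PS / F_p)


def _check_fraction(problems, name, value, lo=0.0, hi=1.0):
    if value is None:
        return
    if not (lo <= value <= hi) or not math.isfinite(value):
        problems.append(f"{name}={value} outside [{lo}, {hi}]")


def validate_params(
    tumor: TumorTransport,
    pk: SystemicPK,
    geometry: TumorGeometry,
) -> ParameterBundle:
    """Check all invariants and fill in derived fields.

    Raises :class:`ValidationError` listing every offending field; on
    success returns a :class:`ParameterBundle` with ``F_p``, ``v_e_av``,
    ``V_p_T`` and ``EF`` populated.
    """
    problems: list[str] = []

    for name in ("v_p", "v_e_av", "v_v", "v_e", "k_av", "Hct_mv"):
        _check_fraction(problems, name, getattr(tumor, name))
    if tumor.TT is None or not tumor.TT > 0:
        problems.append(f"TT={tumor.TT} must be > 0")
    if tumor.PS is None or tumor.PS < 0:
        problems.append(f"PS={tumor.PS} must be >= 0")

    # cross-field consistency where the redundant primitives are supplied
    if tumor.v_v is not None:
        expect = tumor.v_v * (1.0 - tumor.Hct_mv)
        if not math.isclose(tumor.v_p, expect, rel_tol=1e-6):
            problems.append(
                f"v_p={tumor.v_p} inconsistent with v_v*(1-Hct_mv)={expect:.6g}")
    if tumor.v_e is not None and tumor.k_av is not None:
        expect = tumor.k_av * tumor.v_e
        if not math.isclose(tumor.v_e_av, expect, rel_tol=1e-6):
            problems.append(
                f"v_e_av={tumor.v_e_av} inconsistent with k_av*v_e={expect:.6g}")

    for name in ("V_D", "V_p_S"):
        v = getattr(pk, name)
        if v is None or not v > 0:
            problems.append(f"{name}={v} must be > 0")
    for name in ("k_p", "k_t", "k_e"):
        v = getattr(pk, name)
        if v is None or v < 0:
            problems.append(f"{name}={v} must be >= 0")

    if geometry.VT is None or not geometry.VT > 0:
        problems.append(f"VT={geometry.VT} must be > 0")

    if problems:
        raise ValidationError(problems)

    tumor = replace(tumor, sd=dict(tumor.sd))
    pk = replace(pk, sd=dict(pk.sd))
    geometry = replace(geometry, sd=dict(geometry.sd))

    f_p_derived = derive_perfusion(tumor.v_p, tumor.TT)
    if tumor.F_p is None:
        tumor.F_p = f_p_derived
    else:
        if abs(tumor.F_p - f_p_derived) > 0.10 * f_p_derived:
            raise ValidationError(
                [f"F_p={tumor.F_p} deviates >10% from v_p/TT={f_p_derived:.6g}"])
        if tumor.F_p != f_p_derived:
            log.warning(
                "F_p override %.4g differs from v_p/TT = %.4g (within 10%%); "
                "keeping the override", tumor.F_p, f_p_derived)

    vpt = geometry.VT * tumor.v_p
    if geometry.V_p_T is None:
        geometry.V_p_T = vpt
    elif not math.isclose(geometry.V_p_T, vpt, rel_tol=1e-6):
        raise ValidationError(
            [f"V_p_T={geometry.V_p_T} inconsistent with VT*v_p={vpt:.6g}"])
    if geometry.V_p_T > geometry.VT:
        raise ValidationError(["V_p_T exceeds VT"])

    EF = extraction_fraction(tumor.PS, tumor.F_p)
    return ParameterBundle(tumor=tumor, pk=pk, geometry=geometry, EF=EF)
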