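"""Closed-form hemodynamic estimators for aortic valve stenosis.

Everything here is pure, unit-explicit computation: conversions between
pascal and mmHg, the classical Bernoulli pressure-drop estimators, the
adjusted power-law Bernoulli model, the Gorlin valve-area formula, the
Borda-Carnot expansion loss, and the orifice Reynolds number.

Canonical units throughout the package: aortic valve area (AVA) in cm²,
volume flow rate Q in l/s, velocities in m/s, pressures in mmHg. With
those units the area-averaged velocity is ``v = 10 · Q / AVA`` m/s (the
factor 10 converts l/s per cm² to m/s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "FluidProperties",
    "ValveState",
    "ModelCoefficients",
    "GorlinInputs",
    "DEFAULT_FLUID",
    "REFERENCE_COEFFICIENTS",
    "mmhg_from_pa",
    "pa_from_mmhg",
    "average_velocity",
    "bernoulli_max_tpg",
    "bernoulli_avg_tpg",
    "bernoulli_coefficient",
    "adjusted_model_tpg",
    "adjusted_model_tpg_reduced",
    "gorlin_ava",
    "gorlin_tpg",
    "borda_carnot_loss",
    "characteristic_diameter",
    "reynolds_number",
    "peak_to_mean_tpg",
    "mean_to_peak_tpg",
]

#: Conventional range of the peak-to-mean transvalvular gradient ratio in
#: clinical guidelines; values outside it trigger a warning, not an error.
PEAK_TO_MEAN_RATIO_RANGE: Tuple[float, float] = (1.56, 1.68)


@dataclass(frozen=True)
class FluidProperties:
    """Physical constants of blood and the pressure-unit convention.

    Parameters
    ----------
    rho:
        Blood density [kg/m³]. Default 1050, the standard value for
        whole blood in hemodynamic modelling.
    eta:
        Dynamic viscosity [Pa·s]. Default 0.0035, the high-shear
        (threshold) viscosity of blood; used as a constant here.
    pa_per_mmhg:
        Pressure conversion factor [Pa/mmHg]. Default 133.32.
    """

    rho: float = 1050.0
    eta: float = 0.0035
    pa_per_mmhg: float = 133.32

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"blood density must be non-negative, got {self.rho}")
        if self.eta <= 0:
            raise ValueError(f"viscosity must be positive, got {self.eta}")
        if self.pa_per_mmhg <= 0:
            raise ValueError(
                f"Pa-per-mmHg conversion must be positive, got {self.pa_per_mmhg}"
            )


DEFAULT_FLUID = FluidProperties()


@dataclass(frozen=True)
class ValveState:
    """One quasi-steady valve state: orifice area, flow, optional peak velocity.

    ``v_max`` is the maximal through-valve velocity component normal to the
    annulus plane (the quantity Doppler echocardiography measures); it can
    never be smaller than the area-averaged velocity ``10·q/ava``.
    """

    ava: float  # aortic valve area [cm²]
    q: float  # volume flow rate [l/s]
    v_max: Optional[float] = None  # maximal through-valve velocity [m/s]

    def __post_init__(self) -> None:
        if self.ava <= 0:
            raise ValueError(f"aortic valve area must be positive, got {self.ava} cm²")
        if self.q < 0:
            raise ValueError(f"flow rate must be non-negative, got {self.q} l/s")
        if self.v_max is not None:
            v_avg = 10.0 * self.q / self.ava
            if self.v_max < v_avg * (1.0 - 1e-9):
                raise ValueError(
                    f"v_max={self.v_max} m/s is below the area-averaged velocity "
                    f"{v_avg:.6g} m/s implied by q={self.q} l/s over ava={self.ava} cm²"
                )


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients (c, alpha, beta) of the adjusted Bernoulli power law.

    The model reads ``TPG = c · AVA^alpha · Q^beta · v²`` with the
    area-averaged velocity v in m/s, AVA in cm² and Q in l/s. The
    algebraically equivalent *reduced* form eliminates v:
    ``TPG = c' · AVA^(alpha-2) · Q^(beta+2)`` with ``c' = 100·c``
    (the 100 is the square of the 10 in ``v = 10·Q/AVA``).

    Optional 95% confidence bounds are stored as (low, high) tuples.
    """

    c: float
    alpha: float
    beta: float
    ci_c: Optional[Tuple[float, float]] = None
    ci_alpha: Optional[Tuple[float, float]] = None
    ci_beta: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"multiplicative coefficient must be positive, got {self.c}")
        for name, point, ci in (
            ("c", self.c, self.ci_c),
            ("alpha", self.alpha, self.ci_alpha),
            ("beta", self.beta, self.ci_beta),
        ):
            if ci is not None and not (ci[0] <= point <= ci[1]):
                raise ValueError(
                    f"confidence interval {ci} for {name} does not contain "
                    f"the point estimate {point}"
                )

    # -- reduced-form view ------------------------------------------------
    @property
    def c_reduced(self) -> float:
        return 100.0 * self.c

    @property
    def alpha_reduced(self) -> float:
        return self.alpha - 2.0

    @property
    def beta_reduced(self) -> float:
        return self.beta + 2.0

    @classmethod
    def from_reduced(
        cls, c_reduced: float, alpha_reduced: float, beta_reduced: float
    ) -> "ModelCoefficients":
        """Build from reduced-form parameters (c', alpha', beta')."""
        return cls(c=c_reduced / 100.0, alpha=alpha_reduced + 2.0, beta=beta_reduced - 2.0)


#: Power-law coefficients fitted to CFD ground-truth gradients of a
#: mild-to-moderate stenosis training cohort; the package-wide default
#: for the adjusted model and for the synthetic ground-truth oracle.
REFERENCE_COEFFICIENTS = ModelCoefficients(c=3.007, alpha=-0.373, beta=-0.216)


@dataclass(frozen=True)
class GorlinInputs:
    """Inputs of the Gorlin valve-area formula, classical unit convention."""

    co: float  # cardiac output [mL/min]
    hr: float  # heart rate [beats/min]
    sep: float  # systolic ejection period [s/beat]
    tpg_mean: float  # mean transvalvular gradient [mmHg]

    def __post_init__(self) -> None:
        for name in ("co", "hr", "sep", "tpg_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Gorlin input {name} must be positive, got {getattr(self, name)}")


GORLIN_CONSTANT = 44.3


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def mmhg_from_pa(p: float, props: FluidProperties = DEFAULT_FLUID) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p / props.pa_per_mmhg


def pa_from_mmhg(p: float, props: FluidProperties = DEFAULT_FLUID) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p * props.pa_per_mmhg


# ---------------------------------------------------------------------------
# velocities and Bernoulli estimators
# ---------------------------------------------------------------------------

def average_velocity(state: ValveState) -> float:
    """Area-averaged through-valve velocity ``v = 10·Q/AVA`` [m/s]."""
    return 10.0 * state.q / state.ava


def bernoulli_max_tpg(v_max: float) -> float:
    """Classical clinical Bernoulli gradient ``TPG = 4·v_max²`` [mmHg].

    ``v_max`` is the peak through-valve velocity in m/s. The dimensional
    coefficient 4 folds blood density and the Pa→mmHg conversion
    (see :func:`bernoulli_coefficient`).
    """
    if v_max < 0:
        raise ValueError(f"velocity must be non-negative, got {v_max} m/s")
    return 4.0 * v_max * v_max


def bernoulli_coefficient(
    props: FluidProperties = DEFAULT_FLUID, rounded: bool = False
) -> float:
    """Dimensional Bernoulli coefficient ``0.5·rho/pa_per_mmhg`` [mmHg·s²/m²].

    With standard blood density this evaluates to 3.9378…, which clinical
    practice rounds to 4. Pass ``rounded=True`` for the clinical integer.
    """
    k = 0.5 * props.rho / props.pa_per_mmhg
    return float(round(k)) if rounded else k


def bernoulli_avg_tpg(state: ValveState) -> float:
    """Bernoulli gradient from the area-averaged velocity, ``4·(10·Q/AVA)²`` [mmHg]."""
    v = average_velocity(state)
    return 4.0 * v * v


# ---------------------------------------------------------------------------
# adjusted power-law model
# ---------------------------------------------------------------------------

def adjusted_model_tpg(state: ValveState, coeffs: ModelCoefficients = REFERENCE_COEFFICIENTS) -> float:
    """Adjusted Bernoulli gradient ``c · AVA^alpha · Q^beta · v²`` [mmHg].

    The exponents are negative for the reference fit, but the v² factor
    carries Q², so the zero-flow limit is 0; that degenerate case returns
    0.0 with a warning instead of evaluating ``0**beta``.
    """
    if state.q == 0.0:
        warnings.warn(
            "adjusted model evaluated at zero flow; returning the degenerate limit 0 mmHg",
            stacklevel=2,
        )
        return 0.0
    v = average_velocity(state)
    return coeffs.c * state.ava**coeffs.alpha * state.q**coeffs.beta * v * v


def adjusted_model_tpg_reduced(
    state: ValveState, coeffs: ModelCoefficients = REFERENCE_COEFFICIENTS
) -> float:
    """Reduced-form evaluation ``c' · AVA^(alpha-2) · Q^(beta+2)`` [mmHg].

    Algebraically identical to :func:`adjusted_model_tpg`; exposed so the
    identity can be verified numerically.
    """
    if state.q == 0.0:
        return 0.0
    return (
        coeffs.c_reduced
        * state.ava**coeffs.alpha_reduced
        * state.q**coeffs.beta_reduced
    )


# ---------------------------------------------------------------------------
# Gorlin
# ---------------------------------------------------------------------------

def gorlin_ava(g: GorlinInputs) -> float:
    """Gorlin effective valve area ``CO / (HR·SEP·sqrt(TPG_mean)·44.3)`` [cm²]."""
    return g.co / (g.hr * g.sep * math.sqrt(g.tpg_mean) * GORLIN_CONSTANT)


def gorlin_tpg(g: GorlinInputs, ava: float) -> float:
    """Mean gradient implied by the Gorlin formula for a given area [mmHg].

    Inverse of :func:`gorlin_ava` in the gradient argument:
    ``gorlin_tpg(g, gorlin_ava(g)) == g.tpg_mean``.
    """
    if ava <= 0:
        raise ValueError(f"valve area must be positive, got {ava} cm²")
    return (g.co / (g.hr * g.sep * ava * GORLIN_CONSTANT)) ** 2


# ---------------------------------------------------------------------------
# Borda-Carnot, geometry, Reynolds
# ---------------------------------------------------------------------------

def borda_carnot_loss(
    v1: float,
    v2: float,
    xi: float = 1.0,
    props: FluidProperties = DEFAULT_FLUID,
    as_pa: bool = False,
) -> float:
    """Irreversible pressure loss at a sudden expansion, ``xi·0.5·rho·(v1-v2)²``.

    ``xi`` is the empirical loss coefficient in [0, 1]; 1 corresponds to a
    sudden pipe expansion. Symmetric in (v1, v2). Returned in mmHg by
    default, in Pa with ``as_pa=True``.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"loss coefficient must lie in [0, 1], got {xi}")
    loss_pa = xi * 0.5 * props.rho * (v1 - v2) ** 2
    return loss_pa if as_pa else mmhg_from_pa(loss_pa, props)


def characteristic_diameter(ava: float) -> float:
    """Equivalent circular diameter ``2·sqrt(AVA/pi)`` of the orifice [cm]."""
    if ava < 0:
        raise ValueError(f"area must be non-negative, got {ava} cm²")
    return 2.0 * math.sqrt(ava / math.pi)


def reynolds_number(state: ValveState, props: FluidProperties = DEFAULT_FLUID) -> float:
    """Orifice Reynolds number ``rho·u·D/eta`` [-].

    u is the area-averaged velocity in the minimal cross-section [m/s] and
    D the equivalent circular diameter converted to metres. Viscosity is
    the constant high-shear value of ``props``.
    """
    u = average_velocity(state)
    d_m = characteristic_diameter(state.ava) / 100.0
    return props.rho * u * d_m / props.eta


# ---------------------------------------------------------------------------
# peak / mean gradient conversion
# ---------------------------------------------------------------------------

def _check_ratio(a: float) -> None:
    if a <= 0:
        raise ValueError(f"peak-to-mean ratio must be positive, got {a}")
    lo, hi = PEAK_TO_MEAN_RATIO_RANGE
    if not lo <= a <= hi:
        warnings.warn(
            f"peak-to-mean ratio {a} lies outside the conventional clinical "
            f"range [{lo}, {hi}]",
            stacklevel=3,
        )


def peak_to_mean_tpg(tpg_ps: float, a: float) -> float:
    """Mean gradient from the peak-systolic gradient, ``TPG_mean = TPG_ps / a``."""
    _check_ratio(a)
    return tpg_ps / a


def mean_to_peak_tpg(tpg_mean: float, a: float) -> float:
    """Peak-systolic gradient from the mean gradient, ``TPG_ps = a · TPG_mean``."""
    _check_ratio(a)
    return tpg_mean * a
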