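"""Synthetic stenosis cohorts with a ground-truth gradient oracle.

Emulates the statistical structure of a CT/CFD stenosis study: each
virtual patient contributes 1–4 open-valve systolic phases, each phase an
orifice area (truncated normal, 1.87 ± 0.87 cm² within [0.64, 4.37]) and
a base flow rate (truncated normal, 0.217 ± 0.109 l/s, positive); every
phase is replicated at a set of flow multipliers to widen the sampled
gradient range. The maximal velocity is derived from the area-averaged
velocity through a velocity-profile ratio v_avg/v_max drawn truncated
normal (0.85 ± 0.082 within [0.59, 0.96]).

The ground-truth gradient is produced by the adjusted power-law oracle
with multiplicative log-normal residual noise calibrated so the additive
residual spread at the cohort-mean gradient matches a configured value
(default 2.91 mmHg); an additive Gaussian alternative is available. A
Borda-Carnot-style oracle (sudden-expansion loss with pressure recovery)
can be selected to exercise the fitter under model misspecification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .hemodynamics import (
    DEFAULT_FLUID,
    REFERENCE_COEFFICIENTS,
    FluidProperties,
    ModelCoefficients,
)

__all__ = [
    "CohortConfig",
    "CaseRecord",
    "COHORT_COLUMNS",
    "flow_from_lv_volumes",
    "sample_cohort",
    "apply_exclusions",
]

#: Canonical column order of a serialized cohort table.
COHORT_COLUMNS = [
    "patient_id",
    "phase_id",
    "multiplier",
    "ava_cm2",
    "q_l_s",
    "v_max_m_s",
    "tpg_true_mmhg",
    "excluded",
    "exclusion_reason",
]


@dataclass(frozen=True)
class CaseRecord:
    """One simulated valve state of one patient at one flow multiplier."""

    patient_id: int
    phase_id: int
    multiplier: float
    ava: float  # [cm²]
    q: float  # [l/s]
    v_max: float  # [m/s]
    tpg_true: float  # [mmHg]
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions, oracle and exclusion rules of a virtual cohort.

    Defaults reproduce the training-cohort conditions: 21 patients, 1–4
    open-valve phases each, four flow multipliers, and the reference
    power-law oracle with 2.91 mmHg residual spread at the cohort mean.
    """

    n_patients: int = 21
    phases_range: Tuple[int, int] = (1, 4)
    ava_mean: float = 1.87  # [cm²]
    ava_sd: float = 0.87
    ava_range: Tuple[float, float] = (0.64, 4.37)
    q_mean: float = 0.217  # [l/s], unaltered base flow
    q_sd: float = 0.109
    q_range: Tuple[float, float] = (1e-6, math.inf)  # positivity truncation
    multipliers: Tuple[float, ...] = (1.0, 1.5, 2.5, 3.0)
    ratio_mean: float = 0.85  # v_avg / v_max profile ratio
    ratio_sd: float = 0.082
    ratio_range: Tuple[float, float] = (0.59, 0.96)
    truth_coeffs: ModelCoefficients = REFERENCE_COEFFICIENTS
    oracle: str = "power_law"  # or "borda_carnot"
    noise_sd_mmhg: float = 2.91  # residual spread at the cohort-mean TPG
    noise_model: str = "lognormal"  # or "additive"
    exclusion_vmax: float = 8.0  # [m/s]
    exclusion_tpg: float = 200.0  # [mmHg]
    fluid: FluidProperties = DEFAULT_FLUID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        lo, hi = self.phases_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid phases_range {self.phases_range}")
        for name in ("ava_sd", "q_sd", "ratio_sd", "noise_sd_mmhg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("ava_range", "q_range", "ratio_range"):
            r = getattr(self, name)
            if r[0] > r[1]:
                raise ValueError(f"{name} is not ordered: {r}")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("flow multipliers must be positive")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.oracle not in ("power_law", "borda_carnot"):
            raise ValueError(f"unknown oracle {self.oracle!r}")
        for mean, sd, rng, name in (
            (self.ava_mean, self.ava_sd, self.ava_range, "ava"),
            (self.q_mean, self.q_sd, self.q_range, "q"),
            (self.ratio_mean, self.ratio_sd, self.ratio_range, "ratio"),
        ):
            if sd > 0 and (rng[1] < mean - 6 * sd or rng[0] > mean + 6 * sd):
                raise ValueError(
                    f"{name} truncation range {rng} excludes mean ± 6 SD; "
                    "rejection sampling would not terminate"
                )

    @classmethod
    def training(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Training-study conditions (21 patients, multipliers 1/1.5/2.5/3)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def test(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Test-study conditions: 4 patients × 3 phases × 3 multipliers = 36 cases."""
        defaults = dict(
            n_patients=4,
            phases_range=(3, 3),
            multipliers=(1.0, 1.5, 2.5),
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# flow from LV volumes
# ---------------------------------------------------------------------------

def flow_from_lv_volumes(volumes: Sequence[float], dt: float = 0.095) -> np.ndarray:
    """Per-interval flow rate from an ordered series of LV volumes.

    ``Q_i = (V_i - V_{i+1}) / dt`` converted mL→l, so ejection (decreasing
    volume) yields positive flow. Negative values (filling) are returned
    as-is and are for the caller to flag.

    Parameters
    ----------
    volumes:
        Left-ventricular volumes [mL] at consecutive systolic phases.
    dt:
        Phase spacing [s]; default 0.095 (95 ms, a 63 bpm heart rate with
        ten phases per cycle).
    """
    v = np.asarray(volumes, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two LV volumes to form a flow rate")
    if dt <= 0:
        raise ValueError(f"phase spacing must be positive, got {dt} s")
    return (v[:-1] - v[1:]) / dt / 1000.0


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: Tuple[float, float], size: int
) -> np.ndarray:
    """Exact truncated-normal sampling by rejection."""
    if sd == 0:
        if not bounds[0] <= mean <= bounds[1]:
            raise ValueError(f"degenerate mean {mean} outside bounds {bounds}")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _borda_carnot_oracle(ava: np.ndarray, q: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Net-gradient oracle from a contraction + sudden-expansion loss model.

    The transvalvular jet decelerates into the ascending aorta (area taken
    as a fixed 7 cm² outflow) and the irrecoverable drop is the
    Borda-Carnot loss of that expansion with loss coefficient 1.
    """
    aorta_cm2 = 7.0
    v_jet = 10.0 * q / ava
    v_out = 10.0 * q / aorta_cm2
    loss_pa = 0.5 * cfg.fluid.rho * (v_jet - v_out) ** 2
    return loss_pa / cfg.fluid.pa_per_mmhg


def _deterministic_tpg(ava: np.ndarray, q: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    if cfg.oracle == "borda_carnot":
        return _borda_carnot_oracle(ava, q, cfg)
    co = cfg.truth_coeffs
    return co.c_reduced * ava**co.alpha_reduced * q**co.beta_reduced


def sample_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a virtual cohort; returns the canonical cohort table.

    For each patient a phase count is drawn uniformly on
    ``phases_range``; each phase receives an orifice area, a base flow
    and a velocity-profile ratio, and is expanded across the flow
    multipliers (area and profile ratio are geometric/flow-field
    properties of the phase, so they are shared across multipliers and
    both velocities scale linearly with the multiplier). Ground-truth
    gradients come from the configured oracle plus residual noise; the
    log-normal noise scale is set to ``noise_sd_mmhg / mean(TPG_det)`` so
    the additive spread at the cohort-mean gradient matches the
    configured value. Exclusion flags are applied before returning.

    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.phases_range

    rows = []
    for pid in range(1, config.n_patients + 1):
        n_phases = int(rng.integers(lo, hi + 1))
        ava = _truncated_normal(rng, config.ava_mean, config.ava_sd, config.ava_range, n_phases)
        q_base = _truncated_normal(rng, config.q_mean, config.q_sd, config.q_range, n_phases)
        ratio = _truncated_normal(
            rng, config.ratio_mean, config.ratio_sd, config.ratio_range, n_phases
        )
        for ph in range(n_phases):
            for mult in config.multipliers:
                q = q_base[ph] * mult
                v_avg = 10.0 * q / ava[ph]
                rows.append(
                    (pid, ph + 1, mult, ava[ph], q, v_avg / ratio[ph])
                )

    frame = pd.DataFrame(
        rows, columns=["patient_id", "phase_id", "multiplier", "ava_cm2", "q_l_s", "v_max_m_s"]
    )

    det = _deterministic_tpg(
        frame["ava_cm2"].to_numpy(), frame["q_l_s"].to_numpy(), config
    )
    if config.noise_sd_mmhg == 0:
        tpg = det
    elif config.noise_model == "lognormal":
        sigma_log = config.noise_sd_mmhg / float(det.mean())
        tpg = det * np.exp(rng.normal(0.0, sigma_log, size=det.size))
    else:  # additive Gaussian, floored to keep gradients physical
        tpg = np.maximum(det + rng.normal(0.0, config.noise_sd_mmhg, size=det.size), 0.0)
    frame["tpg_true_mmhg"] = tpg

    return apply_exclusions(frame, config)


def apply_exclusions(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Flag non-physiological cases; nothing is deleted.

    A record is flagged when ``v_max`` strictly exceeds the velocity
    threshold or the ground-truth gradient strictly exceeds the pressure
    threshold (either criterion suffices); values exactly at a threshold
    are retained. The triggering reason is recorded.
    """
    out = records.copy()
    vel = out["v_max_m_s"].to_numpy() > config.exclusion_vmax
    prs = out["tpg_true_mmhg"].to_numpy() > config.exclusion_tpg
    reason = np.where(
        vel & prs, "velocity+pressure", np.where(vel, "velocity", np.where(prs, "pressure", ""))
    )
    out["excluded"] = vel | prs
    out["exclusion_reason"] = reason
    return out[COHORT_COLUMNS]
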