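"""Phase-blended fuzzy fermentation simulator.

Dense, minute-scale wine-fermentation datasets are scarce, so the
package generates them: yeast alcoholic fermentation is split into the
four canonical phases (lag, exponential, stationary, death), each phase
carries a closed-form rule for every attribute (biomass, sugar, CO₂,
pH, temperature, alcohol), and fuzzy phase memberships over time blend
the per-phase expressions into smooth curves.  Fermentation-to-
fermentation variability comes from uniform draws of the kinetic
parameters (maximum biomass, growth rate, initial sugar, sugar
consumption rate); measurement noise is Gaussian per attribute except
CO₂, whose bursty release is modelled with positive exponential noise.

The four phase memberships (hours):

* lag         tri(0, 0, 20)
* exponential trap(15, 20, 70, 80)
* stationary  trap(70, 80, 150, 170)
* death       S(150, 336)

Where memberships overlap, attributes are the membership-weighted
average of the phase expressions (a Takagi–Sugeno reading of the rule
chain); noise is added after blending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fuzzy_core import smf, trapmf, trimf

__all__ = [
    "ATTRIBUTES",
    "ANTECEDENTS",
    "CONSEQUENT",
    "KineticParams",
    "ParameterDraw",
    "FermentationCurve",
    "phase_memberships",
    "phase_value",
    "generate_curve",
    "generate_dataset",
    "ode_consistency_check",
]

logger = logging.getLogger(__name__)

ATTRIBUTES = ("biomass_gL", "sugar_gL", "co2", "pH", "temp_C", "alcohol_gL")
ANTECEDENTS = ("sugar_gL", "pH", "co2", "biomass_gL", "temp_C")
CONSEQUENT = "alcohol_gL"

PHASES = ("lag", "exp", "stat", "death")

# Gaussian noise std per attribute per phase (lag, exp, stat, death);
# CO₂ uses exponential noise with the listed means instead.
_GAUSS_STD = {
    "biomass_gL": (0.02, 0.05, 0.03, 0.05),
    "sugar_gL": (0.5, 1.0, 0.8, 0.3),
    "pH": (0.05, 0.05, 0.1, 0.05),
    "temp_C": (0.05, 0.05, 0.05, 0.05),
    "alcohol_gL": (0.0, 0.0, 0.0, 0.0),
}
_CO2_EXP_MEAN = (0.1, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants and variability ranges of the fermentation model.

    Defaults describe a temperature-controlled (15 °C) white-wine
    fermentation: ~210 g/L initial sugar dropping to a 20 g/L residual,
    biomass growing from 0.5 g/L to ~3.5 g/L before declining.
    ``noise_scale`` multiplies every noise amplitude (1 = nominal).
    """

    X0: float = 0.5  # g/L initial biomass
    tau: float = 10.0  # h lag time constant
    Xmax_range: tuple = (3.0, 4.0)  # g/L maximum biomass (uniform draw)
    r_range: tuple = (0.25, 0.35)  # 1/h growth rate (uniform draw)
    tm: float = 45.0  # h exponential midpoint
    decline_alpha: float = 0.01  # g/L/h stationary decline rate
    death_beta: float = 0.005  # 1/h death decay rate
    S0_range: tuple = (200.0, 220.0)  # g/L initial sugar (uniform draw)
    ke_range: tuple = (0.01, 0.02)  # 1/h sugar consumption rate (uniform draw)
    Smin: float = 30.0  # g/L stationary residual sugar
    deltaS: float = 50.0  # g/L stationary transition amount
    ks: float = 0.02  # 1/h stationary stabilization rate
    Send: float = 20.0  # g/L final sugar
    temp_setpoint: float = 15.0  # °C controlled temperature
    yield_YXS: float = 0.5  # g/g biomass yield on sugar
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("X0", "tau", "decline_alpha", "death_beta", "Smin", "deltaS",
                     "ks", "Send", "yield_YXS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("Xmax_range", "r_range", "S0_range", "ke_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an ordered positive range")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    def with_noise_scale(self, scale: float) -> "KineticParams":
        return replace(self, noise_scale=scale)


@dataclass(frozen=True)
class ParameterDraw:
    """One fermentation's realized kinetic parameters."""

    Xmax: float
    r: float
    S0: float
    ke: float

    @classmethod
    def nominal(cls, params: KineticParams = KineticParams()) -> "ParameterDraw":
        """Midpoint draw — reproduces the reference rule-chain constants."""
        mid = lambda rng: (rng[0] + rng[1]) / 2.0
        return cls(
            Xmax=mid(params.Xmax_range),
            r=mid(params.r_range),
            S0=mid(params.S0_range),
            ke=mid(params.ke_range),
        )

    @classmethod
    def sample(cls, params: KineticParams, rng: np.random.Generator) -> "ParameterDraw":
        return cls(
            Xmax=float(rng.uniform(*params.Xmax_range)),
            r=float(rng.uniform(*params.r_range)),
            S0=float(rng.uniform(*params.S0_range)),
            ke=float(rng.uniform(*params.ke_range)),
        )


@dataclass
class FermentationCurve:
    """A time-indexed table of the six fermentation attributes.

    ``time`` is a uniform grid in hours; ``data`` holds one column per
    attribute.  The universal exchange object between the simulator,
    the alcohol soft sensor and the forecaster.
    """

    time: np.ndarray
    data: pd.DataFrame
    seed: int | None = None
    params: KineticParams | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.time) != len(self.data):
            raise ValueError("time grid and data table must have equal length")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def step_h(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "time_h", self.time)
        return out

    def resample(self, step_min: float) -> "FermentationCurve":
        """Linearly interpolate the curve onto a new uniform grid."""
        step_h = step_min / 60.0
        new_t = np.arange(self.time[0], self.time[-1] + 1e-12, step_h)
        cols = {
            c: np.interp(new_t, self.time, self.data[c].to_numpy())
            for c in self.data.columns
        }
        return FermentationCurve(
            time=new_t,
            data=pd.DataFrame(cols),
            seed=self.seed,
            params=self.params,
            metadata={**self.metadata, "resampled_step_min": step_min},
        )


# ---------------------------------------------------------------------------
# phase machinery


def phase_memberships(t):
    """Memberships of the four fermentation phases at time t (hours).

    Returns an array of shape (4, ...) ordered (lag, exp, stat, death).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return np.stack(
        [
            trimf(t, 0.0, 0.0, 20.0),
            trapmf(t, 15.0, 20.0, 70.0, 80.0),
            trapmf(t, 70.0, 80.0, 150.0, 170.0),
            smf(t, 150.0, 336.0),
        ]
    )


def _phase_biomass(t, p: KineticParams, d: ParameterDraw):
    return (
        p.X0 * (1.0 - np.exp(-t / p.tau)),
        p.X0 + d.Xmax / (1.0 + np.exp(-d.r * (t - p.tm))),
        d.Xmax - p.decline_alpha * (t - 100.0),
        (d.Xmax - 0.5) * np.exp(-p.death_beta * (t - 200.0)),
    )


def _phase_exprs(attribute, t, xbio, p: KineticParams, d: ParameterDraw):
    """Noise-free per-phase values; xbio is the concurrent biomass."""
    t = np.asarray(t, dtype=float)
    ones = np.ones_like(t)
    if attribute == "biomass_gL":
        return _phase_biomass(t, p, d)
    if attribute == "sugar_gL":
        return (
            d.S0 * ones,
            d.S0 * np.exp(-d.ke * t),
            p.Smin + p.deltaS * np.exp(-p.ks * (t - 100.0)),
            p.Send * ones,
        )
    if attribute == "pH":
        return (
            4.5 * ones,
            4.5 - 1.8 / (1.0 + np.exp(-0.15 * (t - 50.0))),
            3.2 * ones,
            3.0 + 0.5 * np.exp(-0.01 * (t - 150.0)),
        )
    if attribute == "temp_C":
        return (p.temp_setpoint * ones,) * 4
    if attribute == "co2":
        if xbio is None:
            raise ValueError("co2 phase expressions need the concurrent biomass")
        return (
            0.1 * xbio,
            12.0 * xbio * np.exp(-0.008 * (t - 60.0) ** 2),
            4.0 * xbio * np.exp(-0.01 * (t - 120.0) ** 2),
            0.5 * xbio,
        )
    if attribute == "alcohol_gL":
        if xbio is None:
            raise ValueError("alcohol phase expressions need the concurrent biomass")
        return (
            np.zeros_like(t),
            0.15 * xbio * (1.0 - 0.3 * np.sin(t / 50.0)),
            0.9 * xbio * (1.0 - 0.1 * np.sin(t / 30.0)),
            0.8 * xbio,
        )
    raise ValueError(f"unknown attribute {attribute!r}")


def phase_value(
    attribute: str,
    t,
    state=None,
    params: KineticParams = KineticParams(),
    draw: ParameterDraw | None = None,
    rng: np.random.Generator | None = None,
    noise_on: bool = False,
):
    """Evaluate the four per-phase rule expressions for one attribute.

    Returns a 4-tuple (lag, exponential, stationary, death) of values at
    t.  ``state`` supplies the concurrently generated biomass for the
    CO₂ and alcohol rows.  With ``noise_on`` the per-phase noise term is
    added (Gaussian, or exponential for CO₂); ``rng`` is then required.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if draw is None:
        draw = ParameterDraw.nominal(params)
    vals = [np.asarray(v, dtype=float) for v in _phase_exprs(attribute, t, state, params, draw)]
    if noise_on:
        if rng is None:
            raise ValueError("noise_on requires an rng")
        scaled = params.noise_scale
        if attribute == "co2":
            vals = [
                v + rng.exponential(scale=m * scaled, size=v.shape) if m * scaled > 0 else v
                for v, m in zip(vals, _CO2_EXP_MEAN)
            ]
        else:
            vals = [
                v + rng.normal(0.0, s * scaled, size=v.shape) if s * scaled > 0 else v
                for v, s in zip(vals, _GAUSS_STD[attribute])
            ]
    return tuple(vals)


def _blend(per_phase, mu):
    """Normalized membership-weighted average of per-phase values."""
    stacked = np.stack(per_phase)
    total = mu.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("zero total phase membership on the time grid")
    return (stacked * mu).sum(axis=0) / total


def generate_curve(
    params: KineticParams = KineticParams(),
    seed: int = 0,
    duration_h: float = 504.0,
    step_min: float = 5.0,
    noise: bool = True,
    controller=None,
    draw: ParameterDraw | None = None,
) -> FermentationCurve:
    """Generate one fermentation curve on a uniform [0, duration) grid.

    The number of samples is duration_h·60/step_min exactly (half-open
    grid).  Per-fermentation kinetic parameters are drawn once from
    their uniform ranges; per time point every attribute is the
    membership-weighted blend of its phase expressions, with noise
    (blended per-phase amplitude) added after blending.  The alcohol
    channel is produced by ``controller.infer_series`` when a trained
    alcohol soft sensor is supplied, else by the reference per-phase
    alcohol expressions.
    """
    n = duration_h * 60.0 / step_min
    if duration_h <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("step must divide the duration")
    n = int(round(n))
    t = np.arange(n) * (step_min / 60.0)
    rng = np.random.default_rng(seed)
    if draw is None:
        draw = ParameterDraw.sample(params, rng)

    mu = phase_memberships(t)
    total_mu = mu.sum(axis=0)
    if np.any(total_mu <= 0):
        raise ValueError("zero total phase membership on the time grid")
    weights = mu / total_mu

    xbio_clean = _blend(_phase_biomass(t, params, draw), mu)

    cols = {}
    for attr in ATTRIBUTES:
        if attr == CONSEQUENT and controller is not None:
            continue
        clean = _blend(_phase_exprs(attr, t, xbio_clean, params, draw), mu)
        if noise and params.noise_scale > 0:
            if attr == "co2":
                scale = (weights * np.array(_CO2_EXP_MEAN)[:, None]).sum(axis=0)
                clean = clean + rng.exponential(scale=params.noise_scale * scale)
            else:
                std = (weights * np.array(_GAUSS_STD[attr])[:, None]).sum(axis=0)
                if np.any(std > 0):
                    clean = clean + rng.normal(0.0, params.noise_scale * std)
        cols[attr] = clean

    data = pd.DataFrame({a: cols[a] for a in ATTRIBUTES if a in cols})
    metadata = {"alcohol_source": "reference", "draw": draw, "noise": bool(noise)}
    curve = FermentationCurve(
        time=t,
        data=data.reindex(columns=[a for a in ATTRIBUTES if a in data]),
        seed=seed,
        params=params,
        metadata=metadata,
    )
    if controller is not None:
        alcohol = controller.infer_series(curve)
        curve.data[CONSEQUENT] = alcohol
        curve.metadata["alcohol_source"] = "controller"
    curve.data = curve.data.reindex(columns=list(ATTRIBUTES))
    return curve


def generate_dataset(
    n_fermentations: int,
    seed: int = 0,
    params: KineticParams = KineticParams(),
    duration_h: float = 504.0,
    step_min: float = 5.0,
    noise: bool = True,
    controller=None,
) -> list:
    """Generate independent fermentation curves from child seeds.

    Each curve gets its own deterministic child seed spawned from the
    master seed, so datasets are bit-reproducible and chunkable (e.g.,
    groups of 100 fermentations).
    """
    if n_fermentations < 1:
        raise ValueError("need at least one fermentation")
    children = np.random.SeedSequence(seed).spawn(n_fermentations)
    curves = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        curves.append(
            generate_curve(
                params=params,
                seed=child_seed,
                duration_h=duration_h,
                step_min=step_min,
                noise=noise,
                controller=controller,
            )
        )
    return curves


def ode_consistency_check(curve: FermentationCurve, params: KineticParams | None = None) -> dict:
    """Diagnostic residuals of the growth-rate balance on a noise-free curve.

    The specific growth rate μ(t) is backed out from the finite-
    difference biomass derivative (μ = Ẋ/X); the sugar balance
    Ṡ = −μX/Y (maintenance term taken as 0) is then compared with the
    finite-difference sugar derivative.  Residual magnitudes are
    reported for inspection only — the generator uses the closed forms,
    not an integrated ODE.
    """
    if params is None:
        params = curve.params or KineticParams()
    if curve.metadata.get("noise", True):
        logger.warning("ODE residuals on a noisy curve are dominated by noise")
    x = curve.data["biomass_gL"].to_numpy()
    s = curve.data["sugar_gL"].to_numpy()
    dxdt = np.gradient(x, curve.time)
    dsdt = np.gradient(s, curve.time)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(np.abs(x) > 1e-12, dxdt / x, 0.0)
    sugar_residual = dsdt + mu * x / params.yield_YXS
    return {
        "mean_abs_sugar_residual": float(np.mean(np.abs(sugar_residual))),
        "mean_growth_rate": float(np.mean(mu)),
        "max_abs_sugar_residual": float(np.max(np.abs(sugar_residual))),
    }
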