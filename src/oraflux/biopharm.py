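"""Biopharmaceutical inputs: permeability, solubility, dissolution kinetics.

Apparent permeability from Caco-2 transport data and its conversion to a
human effective permeability, biorelevant solubility tables, Weibull
dissolution fitting, f1/f2 dissolution similarity factors, and gastric
saturation arithmetic for solubility-limited (BCS II) dosing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

__all__ = [
    "SolubilityEntry",
    "SolubilityTable",
    "ParticleSizeDistribution",
    "DrugProperties",
    "WeibullFit",
    "PermeabilityRecord",
    "DissolutionProfile",
    "compute_papp",
    "papp_to_peff",
    "fit_weibull",
    "similarity_factors",
    "gastric_saturation",
    "rivaroxaban_solubility",
    "rivaroxaban_properties",
]


@dataclass(frozen=True)
class SolubilityEntry:
    medium: str
    ph: float
    solubility: float  # ug/mL
    state: str  # "fasted", "fed" or "neutral"

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise ValueError("solubility must be > 0")
        if not 0 <= self.ph <= 14:
            raise ValueError("pH out of range")


@dataclass(frozen=True)
class SolubilityTable:
    entries: tuple[SolubilityEntry, ...]

    def lookup(self, state: str, ph: float) -> SolubilityEntry:
        """Nearest entry by prandial state then pH distance.

        Neutral (water) entries are eligible for either state.
        """
        pool = [e for e in self.entries if e.state in (state, "neutral")]
        if not pool:
            pool = list(self.entries)
        exact = [e for e in pool if e.state == state]
        if exact:
            pool = exact
        return min(pool, key=lambda e: abs(e.ph - ph))

    def require_fed_effect(self) -> None:
        states = {e.state for e in self.entries}
        if not {"fasted", "fed"} <= states:
            raise ValueError("need at least one fasted and one fed entry")


def rivaroxaban_solubility() -> SolubilityTable:
    """Measured equilibrium solubilities in biorelevant media (ug/mL)."""
    return SolubilityTable((
        SolubilityEntry("water", 7.0, 10.0, "neutral"),
        SolubilityEntry("FaSSGF", 1.6, 11.0, "fasted"),
        SolubilityEntry("FaSSIF", 6.5, 9.9, "fasted"),
        SolubilityEntry("FeSSGF", 4.5, 24.0, "fed"),
        SolubilityEntry("FeSSIF", 5.0, 16.8, "fed"),
    ))


@dataclass(frozen=True)
class ParticleSizeDistribution:
    """Particle radii (um) with mass fractions; optional d10/d50/d90 (um).

    d-values refer to diameters of the mass (volume) distribution, as
    conventionally reported by laser diffraction.
    """

    radii: np.ndarray
    fractions: np.ndarray
    d10: float | None = None
    d50: float | None = None
    d90: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if r.ndim != 1 or f.shape != r.shape:
            raise ValueError("radii and fractions must be 1-D, same length")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "fractions", f)

    @classmethod
    def monodisperse(cls, radius_um: float) -> "ParticleSizeDistribution":
        return cls(np.array([radius_um]), np.array([1.0]))

    @classmethod
    def from_d_values(cls, d10: float, d50: float, d90: float,
                      n_bins: int = 7) -> "ParticleSizeDistribution":
        """Log-normal mass distribution matched to d10/d50/d90.

        The geometric sigma is the average implied by the d10 and d90
        quantiles; bins are placed at equal-probability quantile midpoints
        with equal mass fractions.
        """
        z90 = norm.ppf(0.9)
        sigma = 0.5 * (math.log(d90 / d50) + math.log(d50 / d10)) / z90
        probs = (np.arange(n_bins) + 0.5) / n_bins
        diam = d50 * np.exp(sigma * norm.ppf(probs))
        radii = diam / 2.0
        frac = np.full(n_bins, 1.0 / n_bins)
        return cls(radii, frac, d10=d10, d50=d50, d90=d90)


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical inputs for the absorption model."""

    molecular_weight: float          # g/mol
    logp: float
    pka_acidic: float | None
    pka_basic: float | None
    diffusion_coefficient: float     # cm^2/s
    true_density: float              # g/mL
    solubility: SolubilityTable
    psd: ParticleSizeDistribution
    peff: float                      # 1e-4 cm/s
    precipitation_time: float = 900.0  # s

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.peff <= 0:
            raise ValueError("peff must be > 0")
        if self.true_density <= 0 or self.diffusion_coefficient <= 0:
            raise ValueError("density and diffusion coefficient must be > 0")


def rivaroxaban_properties(peff: float = 0.31,
                           precipitation_time: float = 900.0) -> DrugProperties:
    """Rivaroxaban inputs: MW 435.89 g/mol, logP 1.36, micronized PSD.

    ``peff`` defaults to the Caco-2-derived estimate 0.31e-4 cm/s; the
    diffusion coefficient uses the standard small-molecule estimate
    ~7.7e-6 cm^2/s (GastroPlus-style MW scaling) and true density 1.5 g/mL.
    """
    return DrugProperties(
        molecular_weight=435.89,
        logp=1.36,
        pka_acidic=13.6,
        pka_basic=1.6,
        diffusion_coefficient=7.7e-6,
        true_density=1.5,
        solubility=rivaroxaban_solubility(),
        psd=ParticleSizeDistribution.from_d_values(0.7, 3.8, 9.4),
        peff=peff,
        precipitation_time=precipitation_time,
    )


# ---------------------------------------------------------------------------
# Permeability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeabilityRecord:
    papp: float           # cm/s
    area: float           # cm^2
    donor_conc: float     # ng/mL
    flux: float           # ng/s
    peff_est: float | None = None  # 1e-4 cm/s


def compute_papp(receiver_amounts: Sequence[tuple[float, float]],
                 area: float, donor_conc: float) -> PermeabilityRecord:
    """Apparent permeability from cumulative receiver amounts.

    ``receiver_amounts`` are (time s, cumulative mass ng) pairs already
    corrected for sampling-volume replacement.  The flux dQ/dt is the slope
    of the cumulative-amount-vs-time regression and
    Papp = (dQ/dt) / (A * C0) in cm/s.
    """
    pts = np.asarray(receiver_amounts, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (time, amount) points")
    if area <= 0 or donor_conc <= 0:
        raise ValueError("area and donor concentration must be > 0")
    slope = float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
    if slope < 0:
        warnings.warn("negative flux slope; Papp clamped to 0")
        slope = 0.0
    papp = slope / (area * donor_conc)
    return PermeabilityRecord(papp=papp, area=area, donor_conc=donor_conc,
                              flux=slope)


# Caco-2 Papp 2.69e-6 cm/s corresponds to a human jejunal Peff of
# 0.31e-4 cm/s (single-point anchor, slope 1 on the log10 scale)
_PEFF_ANCHOR_PAPP = 2.69e-6
_PEFF_ANCHOR_PEFF = 0.31
DEFAULT_PEFF_CALIBRATION = (
    math.log10(_PEFF_ANCHOR_PEFF) - math.log10(_PEFF_ANCHOR_PAPP),  # intercept
    1.0,                                                             # slope
)


def papp_to_peff(papp: float,
                 calibration: tuple[float, float] = DEFAULT_PEFF_CALIBRATION,
                 ) -> float:
    """Effective permeability (1e-4 cm/s) from Caco-2 Papp (cm/s).

    log10(Peff) = intercept + slope * log10(Papp).
    """
    if papp <= 0:
        raise ValueError("papp must be > 0")
    intercept, slope = calibration
    return 10.0 ** (intercept + slope * math.log10(papp))


# ---------------------------------------------------------------------------
# Dissolution profiles and Weibull kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissolutionProfile:
    """Fraction-dissolved time course; times in minutes, fractions in [0,1]."""

    times: np.ndarray
    fractions: np.ndarray
    state: str = "fasted"
    replicate_id: int = 0
    media_switch_time: float = 30.0  # min, gastric -> intestinal

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or f.shape != t.shape:
            raise ValueError("times and fractions must be 1-D, same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1.05):
            raise ValueError("fractions must be within [0, 1.05]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class WeibullFit:
    """y(t) = F_inf * (1 - exp(-(t/MDT)^b)); MDT in hours."""

    f_inf: float
    mdt: float
    b: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.mdt <= 0 or self.b <= 0:
            raise ValueError("MDT and b must be > 0")
        if not 0 < self.f_inf <= 1.2:
            raise ValueError("f_inf must be in (0, 1.2]")

    def __call__(self, t_hours: np.ndarray | float) -> np.ndarray:
        t = np.maximum(np.asarray(t_hours, dtype=float), 0.0)
        return self.f_inf * (1.0 - np.exp(-((t / self.mdt) ** self.b)))

    def rate(self, t_hours: np.ndarray | float) -> np.ndarray:
        """d y / dt in 1/h (0 at t<=0)."""
        t = np.asarray(t_hours, dtype=float)
        out = np.zeros_like(t, dtype=float)
        pos = t > 0
        tp = t[pos]
        out[pos] = (self.f_inf * np.exp(-((tp / self.mdt) ** self.b))
                    * self.b / self.mdt * (tp / self.mdt) ** (self.b - 1.0))
        return out


def fit_weibull(profile: DissolutionProfile) -> WeibullFit:
    """Least-squares Weibull fit, multi-start over shape b in {0.5, 1, 2}.

    Rejects profiles whose release decreases by more than 10% absolute
    anywhere (not valid dissolution data).  The plateau F_inf is bounded
    by min(1.05, 1.15 * max observed release): extrapolating far beyond
    the last observed release is not identifiable on truncated profiles.
    """
    t_h = profile.times / 60.0
    y = profile.fractions
    if t_h.size < 4:
        raise ValueError("need >= 4 points")
    run_max = np.maximum.accumulate(y)
    if np.any(run_max - y > 0.10):
        raise ValueError("release decreases by >10%: invalid dissolution data")

    mask = t_h > 0
    tt, yy = t_h[mask], y[mask]

    def resid(p: np.ndarray) -> np.ndarray:
        f_inf, mdt, b = p
        return f_inf * (1 - np.exp(-((tt / mdt) ** b))) - yy

    best = None
    f_cap = min(1.05, 1.15 * float(y.max()))
    f0 = min(max(float(y.max()), 0.05), f_cap)
    t50_guess = float(np.interp(0.5 * f0, yy, tt))
    for b0 in (0.5, 1.0, 2.0):
        res = least_squares(resid, x0=[f0, max(t50_guess, 1e-3), b0],
                            bounds=([1e-6, 1e-6, 0.05], [f_cap, 1e3, 20.0]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    (f_inf, mdt, b), rss = best
    return WeibullFit(f_inf=float(f_inf), mdt=float(mdt), b=float(b), rss=rss)


# ---------------------------------------------------------------------------
# Similarity factors
# ---------------------------------------------------------------------------

def similarity_factors(reference: DissolutionProfile,
                       test: DissolutionProfile,
                       truncate_at_85: bool = True) -> tuple[float, float]:
    """Regulatory f1 (difference) and f2 (similarity) factors.

    The test profile is linearly interpolated onto the reference grid.
    With ``truncate_at_85`` only points up to the first reference point
    exceeding 85% release are used (standard guidance).  f1 is asymmetric
    in (reference, test); f2 is symmetric.
    """
    t_ref = reference.times
    if test.times[0] > t_ref[0] or test.times[-1] < t_ref[-1]:
        raise ValueError("test profile does not cover the reference time grid")
    r = reference.fractions * 100.0
    tst = np.interp(t_ref, test.times, test.fractions) * 100.0
    keep = r > 0
    r, tst = r[keep], tst[keep]
    if truncate_at_85:
        above = np.nonzero(r > 85.0)[0]
        if above.size:
            r, tst = r[: above[0] + 1], tst[: above[0] + 1]
    if r.size < 3:
        raise ValueError("need >= 3 usable time points")
    f1 = 100.0 * np.sum(np.abs(r - tst)) / np.sum(r)
    f2 = 50.0 * math.log10(100.0 / math.sqrt(1.0 + np.mean((r - tst) ** 2)))
    return float(f1), float(f2)


# ---------------------------------------------------------------------------
# Gastric saturation
# ---------------------------------------------------------------------------

def gastric_saturation(dose_mg: float, gastric_solubility_ug_per_ml: float,
                       volume_ml: float = 250.0) -> tuple[float, float]:
    """Solubilization capacity (mg) and supersaturation fold for a dose.

    capacity = solubility * volume; fold = dose / capacity.  With the
    fasted gastric solubility of 11 ug/mL and a 250 mL dosing volume the
    capacity is 2.75 mg, so a 10 mg dose is ~3.6-fold supersaturated.
    """
    if dose_mg <= 0 or gastric_solubility_ug_per_ml <= 0 or volume_ml <= 0:
        raise ValueError("all inputs must be > 0")
    capacity_mg = gastric_solubility_ug_per_ml * volume_ml / 1000.0
    return capacity_mg, dose_mg / capacity_mg
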