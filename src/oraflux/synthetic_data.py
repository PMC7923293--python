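"""Synthetic study inputs: anchored dissolution curves and noisy plasma data.

The USP-IV biphasic dissolution experiment (gastric medium for 30 min,
then intestinal medium) is emulated by a piecewise Weibull curve
constrained to printed anchor points — fasted: 11.0% released at 30 min
and 80% at 360 min; fed: 27.7% at 30 min, 80% at 210 min and ~90% at
5.5 h.  Plasma profiles are simulated from the disposition model with
first-order absorption, proportional log-normal noise and LLOQ censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .biopharm import DissolutionProfile
from .pk_disposition import (ConcentrationTimeProfile, DispositionParams,
                             FirstOrderOral, simulate_disposition)

__all__ = [
    "AnchorSet",
    "DEFAULT_FASTED_ANCHORS",
    "DEFAULT_FED_ANCHORS",
    "BiphasicDissolutionCurve",
    "gen_dissolution",
    "gen_plasma",
    "make_fixture_suite",
]

DEFAULT_FASTED_ANCHORS = ((30.0, 0.110), (360.0, 0.80))
DEFAULT_FED_ANCHORS = ((30.0, 0.277), (210.0, 0.80), (330.0, 0.90))
# terminal plateaus: ~80% (fasted) and ~90% (fed) released at the end of
# the 6 h run
_PLATEAU = {"fasted": 0.80, "fed": 0.90}

DEFAULT_SAMPLE_TIMES_MIN = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0,
                            120.0, 150.0, 180.0, 210.0, 240.0, 270.0,
                            300.0, 330.0, 360.0)


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSet:
    """(time min, fraction) constraints a generated curve must satisfy."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(f)) for t, f in self.anchors)
        times = [t for t, _ in pts]
        fracs = [f for _, f in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise AnchorError("anchor times must be strictly increasing")
        if any(f2 < f1 for f1, f2 in zip(fracs, fracs[1:])):
            raise AnchorError("anchor fractions must be nondecreasing")
        if any(not 0 <= f <= 1.05 for f in fracs):
            raise AnchorError("anchor fractions must lie in [0, 1.05]")
        object.__setattr__(self, "anchors", pts)


@dataclass(frozen=True)
class BiphasicDissolutionCurve:
    """Gastric first-order segment then intestinal Weibull segment.

    f(t) = f30 * (1-exp(-t/tau_g)) / (1-exp(-switch/tau_g))       t <= switch
    f(t) = f30 + (plateau - f30) * (1-exp(-(((t-switch)/m)**b)))  t >  switch
    """

    f_switch: float
    tau_gastric: float
    plateau: float
    mdt_min: float
    shape: float
    switch_min: float = 30.0

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        out = np.empty_like(t)
        g = t <= self.switch_min
        norm = 1.0 - np.exp(-self.switch_min / self.tau_gastric)
        out[g] = self.f_switch * (1.0 - np.exp(-t[g] / self.tau_gastric)) / norm
        ti = t[~g] - self.switch_min
        out[~g] = self.f_switch + (self.plateau - self.f_switch) * (
            1.0 - np.exp(-((ti / self.mdt_min) ** self.shape)))
        return out


def _fit_biphasic(state: str, anchors: AnchorSet,
                  switch_min: float = 30.0) -> BiphasicDissolutionCurve:
    pts = anchors.anchors
    gastric = [p for p in pts if p[0] <= switch_min]
    intestinal = [p for p in pts if p[0] > switch_min]
    if not gastric:
        raise AnchorError("need one anchor at or before the media switch")
    f_switch = gastric[-1][1]
    if gastric[-1][0] != switch_min:
        raise AnchorError("the gastric anchor must sit at the media switch")
    if not intestinal:
        raise AnchorError("need at least one anchor after the media switch")

    # asymptote allowed above the last anchor (the run is truncated at 6 h);
    # weak pulls toward first-order intestinal release (b = 1) and a
    # near-complete asymptote keep the underdetermined directions realistic
    plateau_nominal = min(1.0, max(f for _, f in intestinal) + 0.15)
    ta = np.array([t - switch_min for t, _ in intestinal])
    fa = np.array([f for _, f in intestinal])

    def resid(p):
        plateau, m, b = p
        pred = f_switch + (plateau - f_switch) * (1 - np.exp(-((ta / m) ** b)))
        anchor_res = 1e4 * (pred - fa)
        return np.concatenate([anchor_res,
                               [b - 1.0, plateau - plateau_nominal]])

    res = least_squares(
        resid, x0=[plateau_nominal, max(ta.mean(), 1.0), 1.0],
        bounds=([f_switch + 1e-4, 1.0, 0.2], [1.05, 2e3, 10.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    plateau, m, b = res.x
    curve = BiphasicDissolutionCurve(f_switch, 15.0, float(plateau),
                                     float(m), float(b), switch_min)
    worst = None
    for t, f in pts:
        err = abs(float(curve(t)[0]) - f)
        if err > 1e-3:
            worst = (t, f, err)
    if worst is not None:
        raise AnchorError(
            f"anchor at t={worst[0]:g} min, fraction {worst[1]:g} violated "
            f"by {worst[2]:.2e} (unsatisfiable with a biphasic Weibull)")
    return curve


def gen_dissolution(state: str = "fasted",
                    anchors: AnchorSet | None = None,
                    replicates: int = 3,
                    noise_cv: float = 0.05,
                    seed: int = 0,
                    sample_times_min: Sequence[float] = DEFAULT_SAMPLE_TIMES_MIN,
                    ) -> list[DissolutionProfile]:
    """Replicated dissolution profiles through the state's anchor points.

    Defaults reproduce the fasted anchors (30 min, 0.110) / (360 min, 0.80)
    and fed anchors (30 min, 0.277) / (210 min, 0.80) / (330 min, 0.90).
    Noise is multiplicative log-normal per point, truncated to [0, 1].
    """
    if anchors is None:
        anchors = AnchorSet(DEFAULT_FASTED_ANCHORS if state == "fasted"
                            else DEFAULT_FED_ANCHORS)
    curve = _fit_biphasic(state, anchors)
    t = np.asarray(sample_times_min, dtype=float)
    clean = curve(t)
    rng = np.random.default_rng(seed)
    profiles = []
    for rep in range(replicates):
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            noisy = clean * rng.lognormal(0.0, sigma, clean.size)
        else:
            noisy = clean.copy()
        noisy = np.clip(noisy, 0.0, 1.0)
        profiles.append(DissolutionProfile(t, noisy, state=state,
                                           replicate_id=rep,
                                           media_switch_time=curve.switch_min))
    return profiles


def gen_plasma(disposition: DispositionParams, ka: float, dose: float,
               grid: np.ndarray, noise_cv: float = 0.0, seed: int = 0,
               lloq: float = 0.5, t_lag: float = 0.0,
               ) -> ConcentrationTimeProfile:
    """Simulated oral plasma profile with proportional noise and LLOQ.

    Points censored below ``lloq`` (ug/L) are dropped, not imputed.
    """
    clean = simulate_disposition(disposition, FirstOrderOral(dose, ka, t_lag),
                                 np.asarray(grid, dtype=float))
    conc = clean.concentrations
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        conc = conc * rng.lognormal(0.0, sigma, conc.size)
    keep = conc >= lloq
    return ConcentrationTimeProfile(clean.times[keep], conc[keep], dose,
                                    clean.route)


def make_fixture_suite(seed: int, out_dir: str | Path) -> dict:
    """Write a self-contained CSV/JSON bundle driving the whole pipeline.

    Emits fasted/fed dissolution CSVs, a 10 mg oral-solution plasma CSV
    (the impulse reference), a 20 mg fasted tablet plasma CSV (simulated
    through the gut model from the fasted dissolution curve), a scenario
    JSON with the drug/physiology/disposition inputs, and a manifest
    recording every generation parameter.  Deterministic per seed.
    """
    from .acat import FormulationSpec, build_physiology, simulate_acat
    from .biopharm import fit_weibull, rivaroxaban_properties
    from .cli_io import (scenario_config_to_dict, write_dissolution,
                         write_plasma)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    drug = rivaroxaban_properties()
    disp = DispositionParams(2, 9.43, 0.47, 0.04, 0.21, v2_per_kg=0.09)
    manifest["disposition"] = {"n_compartments": 2, "clearance": 9.43,
                               "vc_per_kg": 0.47, "k12": 0.04, "k21": 0.21,
                               "v2_per_kg": 0.09, "body_mass": disp.body_mass}

    diss: dict[str, list[DissolutionProfile]] = {}
    for state in ("fasted", "fed"):
        profiles = gen_dissolution(state, replicates=3, noise_cv=0.05,
                                   seed=seed + (0 if state == "fasted" else 1))
        diss[state] = profiles
        path = out / f"dissolution_{state}.csv"
        write_dissolution(path, profiles)
        manifest["files"][path.name] = {"state": state, "replicates": 3,
                                        "noise_cv": 0.05}

    grid = np.arange(0.25, 24.01, 0.25)
    solution = gen_plasma(disp, ka=2.0, dose=10.0, grid=grid,
                          noise_cv=0.0, seed=seed + 2)
    write_plasma(out / "plasma_solution_10mg.csv", solution)
    manifest["files"]["plasma_solution_10mg.csv"] = {
        "dose_mg": 10.0, "ka_per_h": 2.0, "noise_cv": 0.0}

    clean_fasted = gen_dissolution("fasted", replicates=1, noise_cv=0.0,
                                   seed=seed)[0]
    w_fasted = fit_weibull(clean_fasted)
    phys = build_physiology("fasted")
    res = simulate_acat(drug, FormulationSpec("release_profile_driven", 20.0,
                                              release_curve=w_fasted),
                        phys, disp, grid)
    write_plasma(out / "plasma_tablet_20mg_fasted.csv", res.plasma)
    manifest["files"]["plasma_tablet_20mg_fasted.csv"] = {
        "dose_mg": 20.0, "source": "gut-model simulation from the fasted "
        "release curve", "noise_cv": 0.0}

    scenario = scenario_config_to_dict(drug, disp, state="fasted", dose=20.0)
    with open(out / "scenario.json", "w") as fh:
        json.dump(scenario, fh, indent=1, sort_keys=True)
    manifest["files"]["scenario.json"] = {"kind": "scenario config"}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
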