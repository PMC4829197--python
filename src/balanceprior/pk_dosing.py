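"""Posterior-predictive PK simulation and minimum-effective-dose search.

Downstream of the regression fits, the dosing pipeline works per age
group: draw structural Emax parameters from their posterior-mean /
posterior-SE normal approximations, evaluate clearance (CL, against
age) and the volumes/distributional clearance (V1, Q, V2, against body
weight), add an inter-individual deviation, then push each simulated
patient through a standard two-compartment constant-rate-infusion model
and score a dose against aminoglycoside-style targets:

- efficacy: concentration 1 h after infusion start >= 10 x MIC,
- safety: concentration 24 h after infusion start <= 1 mg/L.

The minimum effective dose for an age group is the smallest dose on an
integer mg/kg/day grid for which at least 90% of simulated patients
meet both targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_model import derive_seed

__all__ = [
    "PKParameterSet",
    "PredictiveDrawConfig",
    "DoseRegimen",
    "DoseEvaluation",
    "conc_two_compartment",
    "weight_for_age",
    "draw_pk_parameters",
    "evaluate_dose",
    "minimum_effective_dose",
    "MIC_DEFAULT",
]

#: Tobramycin MIC for Pseudomonas aeruginosa used in the dosing targets (mg/L).
MIC_DEFAULT = 2.0

PK_PARAMS = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class PKParameterSet:
    """Two-compartment PK parameters of one (simulated) patient.

    CL: elimination clearance (L/h); V1: central volume (L);
    Q: distributional clearance (L/h); V2: peripheral volume (L).
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        for name in PK_PARAMS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PredictiveDrawConfig:
    """Inputs of the posterior-predictive PK parameter simulation.

    ``fits`` maps each PK parameter name to its structural fit summary:
    a dict with ``kind`` (structural model kind), ``mean`` (coefficient
    posterior means) and ``se`` (posterior standard errors).  ``eta``
    maps each PK parameter to its inter-individual standard deviation
    (estimated from the adult stratum only).  ``weight_sd`` is the
    inter-individual SD of body weight (from the infant stratum),
    re-used as the weight jitter at every age.
    """

    fits: Mapping[str, Mapping]
    eta: Mapping[str, float]
    weight_curve: Mapping[float, float]  # age -> central weight (lowess)
    weight_sd: float
    n_patients: int = 10_000
    seed: int = 0
    lognormal_omega: bool = False
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(v < 0 for v in self.eta.values()):
            raise ValueError("eta must be non-negative")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be non-negative")
        for p, f in self.fits.items():
            if any(s < 0 for s in f["se"].values()):
                raise ValueError(f"negative posterior SE for {p}")


@dataclass(frozen=True)
class DoseRegimen:
    """A single constant-rate intravenous infusion dose.

    ``dose_mg_per_kg_day`` is scaled by body weight into the absolute
    single dose; ``eval_times`` are hours from infusion start.
    """

    dose_mg_per_kg_day: float
    body_weight_kg: float
    infusion_duration_h: float = 0.5
    eval_times: tuple[float, float] = (1.0, 24.0)

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg_day < 0:
            raise ValueError("dose must be non-negative")
        if not self.infusion_duration_h > 0:
            raise ValueError("infusion duration must be positive")
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be positive")

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_kg_day * self.body_weight_kg


@dataclass(frozen=True)
class DoseEvaluation:
    """Target-attainment fractions of one dose over simulated patients."""

    frac_peak: float
    frac_trough: float
    frac_joint: float

    def __post_init__(self) -> None:
        for v in (self.frac_peak, self.frac_trough, self.frac_joint):
            if not 0 <= v <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_joint > min(self.frac_peak, self.frac_trough) + 1e-12:
            raise ValueError("joint fraction cannot exceed marginal fractions")


# ---------------------------------------------------------------------------
# Two-compartment infusion concentration
# ---------------------------------------------------------------------------


def _hybrid_constants(CL, V1, Q, V2):
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return k21, alpha, beta


def conc_two_compartment(pk, dose_mg, infusion_duration, t):
    """Central concentration (mg/L) of a constant-rate infusion.

    Closed form for the standard two-compartment model: with
    micro-constants ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2`` the
    hybrid exponents alpha, beta are the roots of
    ``s^2 - (k10+k12+k21) s + k10 k21``, and the unit-bolus response is
    ``c(t) = [ (k21-alpha) e^{-alpha t}/(beta-alpha)
             + (k21-beta) e^{-beta t}/(alpha-beta) ] / V1``.
    Integrating over the infusion window gives the during/after pieces;
    a repeated root (alpha == beta within floating tolerance) switches
    to the analytic limit form.

    ``pk`` is a :class:`PKParameterSet` or any object with CL/V1/Q/V2
    attributes whose values may be numpy arrays (vectorised patients);
    ``t`` (hours from infusion start) may be scalar or array.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not infusion_duration > 0:
        raise ValueError("infusion duration must be positive")
    CL = np.asarray(pk.CL, float)
    V1 = np.asarray(pk.V1, float)
    Q = np.asarray(pk.Q, float)
    V2 = np.asarray(pk.V2, float)
    k21, alpha, beta = _hybrid_constants(CL, V1, Q, V2)
    rate = dose_mg / infusion_duration
    T = infusion_duration

    repeated = np.isclose(alpha, beta, rtol=1e-9, atol=0.0)
    beta_safe = np.where(repeated, np.where(beta == alpha, beta * (1 + 1e-9), beta), beta)

    # coefficients of the unit-bolus biexponential
    cA = (k21 - alpha) / (V1 * (beta_safe - alpha))
    cB = (k21 - beta_safe) / (V1 * (alpha - beta_safe))

    t_on = np.minimum(t, T)
    t_off = np.maximum(t - T, 0.0)

    def infusion_piece(c, lam):
        # integral of c*exp(-lam*u) over the infusion, propagated to t
        return c / lam * (1.0 - np.exp(-lam * t_on)) * np.exp(-lam * t_off)

    conc = rate * (infusion_piece(cA, alpha) + infusion_piece(cB, beta_safe))
    return np.maximum(conc, 0.0)


# ---------------------------------------------------------------------------
# Weight-for-age smoothing
# ---------------------------------------------------------------------------


def weight_for_age(
    population: pd.DataFrame,
    age_grid: Sequence[float] | None = None,
    infant_age_range: tuple[float, float] = (1.0, 2.0),
    lowess_frac: float = 0.4,
) -> tuple[pd.Series, float]:
    """Central weight-for-age curve and infant weight SD.

    Smooths weight on age with lowess, evaluated on ``age_grid``
    (default: 1-year steps across the observed age range); the grid
    must stay inside the observed range (no extrapolation).  The SD is
    the sample SD of weight in the infant stratum.
    Returns ``(pd.Series indexed by age, sd)``.
    """
    age = population["age"].to_numpy(float)
    weight = population["weight"].to_numpy(float)
    if age_grid is None:
        age_grid = np.arange(np.ceil(age.min()), np.floor(age.max()) + 1.0)
    grid = np.asarray(age_grid, float)
    if grid.min() < age.min() or grid.max() > age.max():
        raise ValueError("age grid outside the observed age range (no extrapolation)")
    smoothed = sm.nonparametric.lowess(weight, age, frac=lowess_frac, xvals=grid)
    infants = weight[(age >= infant_age_range[0]) & (age <= infant_age_range[1])]
    if len(infants) < 2:
        raise ValueError("not enough infant rows to estimate the weight SD")
    sd = float(infants.std(ddof=1))
    return pd.Series(smoothed, index=grid, name="weight"), sd


# ---------------------------------------------------------------------------
# Posterior-predictive parameter draws
# ---------------------------------------------------------------------------


def _eval_curve(fit: Mapping, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One curve evaluation per patient with coefficients drawn from
    their posterior-mean/SE normals."""
    from .core_model import StructuralModel, _predict_kind

    kind = fit["kind"]
    names = StructuralModel.PARAM_NAMES[kind]
    n = len(cov)
    theta = np.column_stack(
        [fit["mean"][p] + fit["se"][p] * rng.standard_normal(n) for p in names]
    )
    return _predict_kind(kind, theta, cov)


def draw_pk_parameters(config: PredictiveDrawConfig, age: float) -> pd.DataFrame:
    """Draw ``n_patients`` PK parameter sets for one age group.

    Per patient: body weight = lowess central weight at ``age`` plus
    Normal(0, weight_sd^2) jitter (clipped positive); CL evaluated
    against age, V1/Q/V2 against the patient's weight, each with
    coefficients drawn from the posterior normal approximation plus an
    inter-individual deviation omega ~ Normal(0, eta^2) (additive on
    the natural scale by default; multiplicative log-normal if
    ``lognormal_omega``).  Non-positive draws are redrawn up to
    ``max_redraws`` times, then truncated at 1e-6 of the central value;
    the count of truncations is attached as ``DataFrame.attrs["n_truncated"]``.
    """
    ages = np.asarray(sorted(config.weight_curve), float)
    if not ages.min() <= age <= ages.max():
        raise ValueError("age outside the modelled range")
    central_w = float(np.interp(age, ages, [config.weight_curve[a] for a in ages]))
    rng = np.random.default_rng(derive_seed(config.seed, "pk-draws", round(float(age), 6)))
    n = config.n_patients
    weight = central_w + config.weight_sd * rng.standard_normal(n)
    weight = np.clip(weight, 1e-6 * central_w, None)

    out = {}
    n_truncated = 0
    for p in PK_PARAMS:
        cov = np.full(n, float(age)) if p == "CL" else weight
        mu = _eval_curve(config.fits[p], cov, rng)
        eta = float(config.eta[p])
        if config.lognormal_omega:
            vals = mu * np.exp(eta * rng.standard_normal(n))
        else:
            vals = mu + eta * rng.standard_normal(n)
        central = max(float(np.median(np.abs(mu))), 1e-12)
        for _ in range(config.max_redraws):
            bad = vals <= 0
            if not bad.any():
                break
            mu_bad = _eval_curve(config.fits[p], cov[bad], rng)
            if config.lognormal_omega:
                vals[bad] = mu_bad * np.exp(eta * rng.standard_normal(bad.sum()))
            else:
                vals[bad] = mu_bad + eta * rng.standard_normal(bad.sum())
        bad = vals <= 0
        if bad.any():
            n_truncated += int(bad.sum())
            vals[bad] = 1e-6 * central
        out[p] = vals
    out["weight"] = weight
    df = pd.DataFrame(out)
    df.attrs["n_truncated"] = n_truncated
    df.attrs["age"] = float(age)
    return df


# ---------------------------------------------------------------------------
# Dose evaluation and search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ArrayPK:
    CL: np.ndarray
    V1: np.ndarray
    Q: np.ndarray
    V2: np.ndarray


def evaluate_dose(
    dose: DoseRegimen, draws: pd.DataFrame, mic: float = MIC_DEFAULT
) -> DoseEvaluation:
    """Fraction of simulated patients hitting the peak/trough targets.

    Peak target: C(eval_times[0]) >= 10 x MIC; trough target:
    C(eval_times[1]) <= 1 mg/L.  Per-patient doses scale with the
    patient's own simulated body weight when the draws carry one.
    """
    if len(draws) == 0:
        raise ValueError("no simulated patients")
    pk = _ArrayPK(*(draws[p].to_numpy(float) for p in PK_PARAMS))
    if "weight" in draws:
        dose_mg = dose.dose_mg_per_kg_day * draws["weight"].to_numpy(float)
    else:
        dose_mg = dose.dose_mg
    t_peak, t_trough = dose.eval_times
    c_peak = conc_two_compartment(pk, dose_mg, dose.infusion_duration_h, t_peak)
    c_trough = conc_two_compartment(pk, dose_mg, dose.infusion_duration_h, t_trough)
    hit_peak = c_peak >= 10.0 * mic
    hit_trough = c_trough <= 1.0
    return DoseEvaluation(
        frac_peak=float(hit_peak.mean()),
        frac_trough=float(hit_trough.mean()),
        frac_joint=float((hit_peak & hit_trough).mean()),
    )


def minimum_effective_dose(
    draws: pd.DataFrame,
    body_weight_kg: float | None = None,
    dose_grid: Sequence[float] = tuple(range(1, 21)),
    acceptance: float = 0.90,
    mic: float = MIC_DEFAULT,
    infusion_duration_h: float = 0.5,
    eval_times: tuple[float, float] = (1.0, 24.0),
) -> tuple[float | None, pd.DataFrame]:
    """Smallest grid dose whose joint target attainment >= ``acceptance``.

    Every grid dose is evaluated (no early exit), so the returned table
    carries the full attainment curve.  Returns ``(dose or None, table)``
    with table columns dose_mg_per_kg_day, frac_peak, frac_trough,
    frac_joint.
    """
    grid = list(dose_grid)
    if len(grid) == 0:
        raise ValueError("empty dose grid")
    if sorted(grid) != grid:
        raise ValueError("dose grid must be sorted ascending")
    if not 0 < acceptance <= 1:
        raise ValueError("acceptance must lie in (0, 1]")
    if body_weight_kg is None:
        if "weight" not in draws:
            raise ValueError("need body_weight_kg or per-patient weights in draws")
        body_weight_kg = float(draws["weight"].mean())
    rows = []
    for d in grid:
        ev = evaluate_dose(
            DoseRegimen(
                dose_mg_per_kg_day=d,
                body_weight_kg=body_weight_kg,
                infusion_duration_h=infusion_duration_h,
                eval_times=eval_times,
            ),
            draws,
            mic=mic,
        )
        rows.append(
            {
                "dose_mg_per_kg_day": d,
                "frac_peak": ev.frac_peak,
                "frac_trough": ev.frac_trough,
                "frac_joint": ev.frac_joint,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["frac_joint"] >= acceptance]
    best = None if ok.empty else float(ok["dose_mg_per_kg_day"].iloc[0])
    return best, table
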