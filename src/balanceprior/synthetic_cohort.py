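"""Seeded generator of a tobramycin-like PK parameter cohort.

The motivating application works from per-patient two-compartment PK
parameter estimates (CL, V1, Q, V2) of a paediatric-plus-adult cystic
fibrosis population treated with intravenous tobramycin.  No such
dataset is shipped here; this module generates a synthetic cohort with
the same *structure* — 570 subjects aged 1-25 years dominated by the
adult stratum, body weight following a saturating growth curve of age,
CL rising with age and the volumes/distributional clearance rising
with weight, all Emax-shaped with multiplicative log-normal
between-subject noise.  The generative parameter values are invented
plausible magnitudes (adult CL of order 6 L/h, V1 of order 0.2-0.3
L/kg), not estimates from any real dataset: tests assert recovery of
whatever values the configuration holds, never the values themselves.

Model-building subsets mirror the application design: 63 adults (18-25
y), 3 children (10-13 y) and 3 infants (1-2 y), with the six paediatric
rows labelled as the minority so the balancing prior up-weights them
roughly tenfold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import ImbalancedDataset, StructuralModel, derive_seed, predict

__all__ = ["CohortConfig", "generate_cohort", "make_model_building_subset"]


def _emax(A, B, C):
    return StructuralModel("emax", {"A": A, "B": B, "C": C})


#: Central curves: lean cystic-fibrosis-like anthropometry (adults ~50 kg),
#: clearance saturating early in childhood (CF patients clear
#: aminoglycosides fast), volumes/distributional clearance near-linear in
#: weight over the observed range (Emax with large C).  Magnitudes are
#: invented but sized to tobramycin pharmacology: adult CL ~7 L/h,
#: V1 ~0.2 L/kg.
DEFAULT_CURVES = {
    # weight (kg) as a saturating function of age (years)
    "weight": _emax(2.5, 75.0, 14.0),
    # CL (L/h) vs age (years)
    "CL": _emax(0.7, 5.1, 4.5),
    # V1 (L), Q (L/h), V2 (L) vs weight (kg); C within the observed
    # weight range so the curvature (hence C) is identifiable from a
    # 63-adult + 6-paediatric subset -- infants get the physiologically
    # higher per-kg volumes
    "V1": _emax(0.2, 11.0, 20.0),
    "Q": _emax(0.15, 2.2, 25.0),
    "V2": _emax(0.3, 4.5, 25.0),
}

#: Log-scale between-subject SDs.  Deliberately modest (7-15% CV): the
#: predictive protocol re-uses the adult stratum's *absolute* SD as the
#: inter-individual spread at every age, so paediatric target attainment
#: is only reachable when the adult stratum is not too dispersed.
DEFAULT_NOISE_SD = {"weight": 0.06, "CL": 0.06, "V1": 0.05, "Q": 0.12, "V2": 0.10}

#: Plausibility envelope for generated body weights (kg).
DEFAULT_WEIGHT_ENVELOPE = (4.0, 90.0)

#: Stratum definition: (age_low, age_high, count). Infants are kept at 60
#: so the infant weight SD is estimable the way the application derives it.
DEFAULT_STRATA = (
    (1.0, 2.0, 60),
    (2.0, 10.0, 100),
    (10.0, 18.0, 97),
    (18.0, 25.0, 313),
)


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration of the synthetic cohort.

    ``curves`` hold the Emax central curve per generated quantity;
    ``noise_sd`` the log-scale between-subject SDs.  The model-building
    subset sizes follow the 63/3/3 adult/child/infant design.
    """

    total_size: int = 570
    strata: tuple = DEFAULT_STRATA
    curves: Mapping[str, StructuralModel] = field(default_factory=lambda: dict(DEFAULT_CURVES))
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    subset_adults: int = 63
    subset_children: int = 3
    subset_infants: int = 3
    child_age_range: tuple[float, float] = (10.0, 13.0)
    infant_age_range: tuple[float, float] = (1.0, 2.0)
    adult_age_range: tuple[float, float] = (18.0, 25.0)
    minority_max_age: float = 13.0
    male_fraction: float = 204 / 570
    weight_envelope: tuple[float, float] = DEFAULT_WEIGHT_ENVELOPE
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(c for *_, c in self.strata) != self.total_size:
            raise ValueError("stratum counts must sum to total_size")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the synthetic cohort table.

    Columns: subject_id, age_y, weight_kg, sex, CL_L_per_h, V1_L,
    Q_L_per_h, V2_L.  Reproducible under ``config.seed``; with all
    noise SDs zero, subjects at equal age/weight get identical
    parameters.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    ages = np.concatenate(
        [rng.uniform(lo, hi, size=cnt) for lo, hi, cnt in config.strata]
    )
    rng.shuffle(ages)

    def noisy(curve_name, cov):
        mu = predict(config.curves[curve_name], cov)
        sd = config.noise_sd[curve_name]
        vals = np.asarray(mu) * np.exp(sd * rng.standard_normal(len(cov)))
        return np.clip(vals, 1e-9, None)

    weight = noisy("weight", ages)
    df = pd.DataFrame(
        {
            "subject_id": [f"c{i:04d}" for i in range(config.total_size)],
            "age_y": ages,
            "weight_kg": weight,
            "sex": np.where(
                rng.random(config.total_size) < config.male_fraction, "M", "F"
            ),
            "CL_L_per_h": noisy("CL", ages),
            "V1_L": noisy("V1", weight),
            "Q_L_per_h": noisy("Q", weight),
            "V2_L": noisy("V2", weight),
        }
    )
    return df


#: Covariate pairing of the application: CL is modelled against age,
#: the volumes and distributional clearance against body weight.
COVARIATE_FOR = {"CL": "age_y", "V1": "weight_kg", "Q": "weight_kg", "V2": "weight_kg"}
COLUMN_FOR = {"CL": "CL_L_per_h", "V1": "V1_L", "Q": "Q_L_per_h", "V2": "V2_L"}


def make_model_building_subset(
    cohort: pd.DataFrame, seed: int, config: CohortConfig | None = None
) -> dict[str, ImbalancedDataset]:
    """Draw one 63-adult / 3-child / 3-infant model-building subset.

    Returns one :class:`ImbalancedDataset` per PK parameter, with the
    application's covariate pairing (CL against age; V1, Q, V2 against
    weight).  All paediatric rows (age <= ``minority_max_age``, which
    spans both the infant and the child stratum) are labelled minority;
    adults are the majority, so the minority:majority ratio is
    3+3 : 63 ~ 0.1.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(derive_seed(seed, "subset"))
    age = cohort["age_y"].to_numpy(float)

    def pick(age_range, count, label):
        lo, hi = age_range
        pool = np.where((age >= lo) & (age <= hi))[0]
        if len(pool) < count:
            raise ValueError(f"not enough {label} rows: need {count}, have {len(pool)}")
        return rng.choice(pool, size=count, replace=False)

    idx = np.concatenate(
        [
            pick(config.adult_age_range, config.subset_adults, "adult"),
            pick(config.child_age_range, config.subset_children, "child"),
            pick(config.infant_age_range, config.subset_infants, "infant"),
        ]
    )
    sub = cohort.iloc[idx]
    minority = sub["age_y"].to_numpy(float) <= config.minority_max_age

    out = {}
    for p in ("CL", "V1", "Q", "V2"):
        out[p] = ImbalancedDataset.from_arrays(
            x=sub[COVARIATE_FOR[p]].to_numpy(float),
            y=sub[COLUMN_FOR[p]].to_numpy(float),
            minority_mask=minority,
            subject_ids=sub["subject_id"].to_numpy(),
        )
    return out
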