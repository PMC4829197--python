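"""Structural models and the balancing-precision construction.

An imbalanced regression dataset has a minority subgroup that is much
smaller than the majority subgroup, yet covers a covariate range of its
own (e.g. a handful of paediatric patients next to a large adult
cohort).  A conventional fit weights every row equally, so the majority
dominates the inference over the minority's covariate range.  The
balancing informative prior counteracts this: each observation carries a
latent-layer precision ``tau_int``, set to a large base value ``phi``
for majority rows and to ``phi * (n - m) / m`` for minority rows (``n``
total rows, ``m`` minority rows).  The precision ratio ``(n - m) / m``
makes the minority's aggregate influence on the fit equal to the
majority's — a Bayesian analogue of over-sampling the minority
``(n - m) / m``-fold.

Structural response curves supported here are the Emax model
``A + B * x / (C + x)``, its sigmoidal (Hill) extension
``A + B * x**h / (C**h + x**h)``, and the straight line ``a + b * x``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ImbalancedDataset",
    "StructuralModel",
    "BalancingPriorSpec",
    "compute_tau",
    "predict",
    "compute_rss",
    "all_beyond_bound_probability",
    "derive_seed",
    "DEFAULT_PHI",
]

#: Default base precision of the latent layer.  Large, so that for the
#: majority rows the latent layer adds negligible extra variability.
DEFAULT_PHI: float = 1e6

MINORITY = "minority"
MAJORITY = "majority"


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and tokens.

    Every stochastic stage of the package draws its seed through this
    helper so that one master seed reproduces a whole run while distinct
    stages (and replicate indices) get decorrelated streams.
    """
    payload = repr((int(master_seed),) + tuple(tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImbalancedDataset:
    """Covariate/response rows with a minority/majority subgroup label.

    Parameters
    ----------
    data
        One row per subject with columns ``subject_id``, ``x`` (covariate),
        ``y`` (response) and ``subgroup`` (``"minority"`` or ``"majority"``).
        Units of ``x`` and ``y`` are carried by the caller's configuration,
        not by the container.
    require_minority_smaller
        The balancing construction assumes the minority is strictly
        smaller than the majority; set to ``False`` only for balanced
        control experiments where no re-weighting is intended.
    """

    data: pd.DataFrame
    require_minority_smaller: bool = True

    def __post_init__(self) -> None:
        df = self.data
        missing = {"subject_id", "x", "y", "subgroup"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if len(df) < 2:
            raise ValueError("dataset needs at least 2 rows")
        bad = set(df["subgroup"].unique()) - {MINORITY, MAJORITY}
        if bad:
            raise ValueError(f"unknown subgroup labels: {sorted(bad)}")
        if not np.all(np.isfinite(df["x"].to_numpy(float))):
            raise ValueError("non-finite covariate values")
        if not np.all(np.isfinite(df["y"].to_numpy(float))):
            raise ValueError("non-finite response values")
        if self.m == 0:
            raise ValueError("no minority rows")
        if self.require_minority_smaller and self.m >= self.n - self.m:
            raise ValueError("minority not smaller than majority")

    @property
    def n(self) -> int:
        """Total number of rows."""
        return len(self.data)

    @property
    def m(self) -> int:
        """Number of minority rows."""
        return int((self.data["subgroup"] == MINORITY).sum())

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(float)

    @property
    def is_minority(self) -> np.ndarray:
        return (self.data["subgroup"] == MINORITY).to_numpy()

    @classmethod
    def from_arrays(
        cls,
        x: Iterable[float],
        y: Iterable[float],
        minority_mask: Iterable[bool],
        subject_ids: Iterable | None = None,
        require_minority_smaller: bool = True,
    ) -> "ImbalancedDataset":
        x = np.asarray(list(x), float)
        y = np.asarray(list(y), float)
        mask = np.asarray(list(minority_mask), bool)
        if subject_ids is None:
            subject_ids = [f"s{i:04d}" for i in range(len(x))]
        df = pd.DataFrame(
            {
                "subject_id": list(subject_ids),
                "x": x,
                "y": y,
                "subgroup": np.where(mask, MINORITY, MAJORITY),
            }
        )
        return cls(df, require_minority_smaller=require_minority_smaller)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ImbalancedDataset":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Structural models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralModel:
    """A structural response curve with fixed parameters.

    ``kind`` selects the curve:

    - ``"emax"``: ``A + B * x / (C + x)`` with parameters ``A`` (baseline,
      response units), ``B`` (maximal increment) and ``C`` (covariate value
      at half-maximal increment; must be positive).
    - ``"linear"``: ``a + b * x``.
    - ``"sigmoid_emax"``: ``A + B * x**h / (C**h + x**h)`` with Hill
      exponent ``h > 0``; reduces to ``emax`` at ``h = 1``.
    """

    kind: str
    params: dict = field(default_factory=dict)

    PARAM_NAMES = {
        "emax": ("A", "B", "C"),
        "linear": ("a", "b"),
        "sigmoid_emax": ("A", "B", "C", "h"),
    }

    def __post_init__(self) -> None:
        if self.kind not in self.PARAM_NAMES:
            raise ValueError(f"unknown structural model kind {self.kind!r}")
        names = self.PARAM_NAMES[self.kind]
        missing = set(names) - set(self.params)
        if missing:
            raise ValueError(f"{self.kind} model missing parameters {sorted(missing)}")
        if self.kind in ("emax", "sigmoid_emax") and not self.params["C"] > 0:
            raise ValueError("C must be positive")
        if self.kind == "sigmoid_emax" and not self.params["h"] > 0:
            raise ValueError("Hill exponent h must be positive")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.PARAM_NAMES[self.kind]], float)

    def predict(self, x) -> np.ndarray:
        return predict(self, x)


def _predict_kind(kind: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorised curve evaluation; ``theta`` may carry leading batch axes."""
    if kind == "emax":
        A, B, C = theta[..., 0], theta[..., 1], theta[..., 2]
        return A + B * x / (C + x)
    if kind == "linear":
        a, b = theta[..., 0], theta[..., 1]
        return a + b * x
    if kind == "sigmoid_emax":
        A, B, C, h = theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3]
        xh = np.power(x, h)
        return A + B * xh / (np.power(C, h) + xh)
    raise ValueError(f"unknown structural model kind {kind!r}")


def predict(model: StructuralModel, x) -> np.ndarray | float:
    """Evaluate the noise-free structural curve at covariate value(s) ``x``.

    Ages and weights are non-negative, so negative ``x`` is rejected.
    """
    xa = np.asarray(x, float)
    if np.any(xa < 0):
        raise ValueError("covariate values must be non-negative")
    out = _predict_kind(model.kind, model.theta, xa)
    if xa.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Balancing precision construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BalancingPriorSpec:
    """Per-observation latent-layer precisions ``tau_int``.

    The latent deviation of observation ``i`` has prior
    ``gamma_i ~ Normal(0, 1 / tau_int[i])``.  ``phi`` is the base
    precision shared by all majority rows; minority rows carry
    ``phi * multiplier`` with ``multiplier = (n - m) / m`` (or an
    explicitly supplied ratio such as ``1 / fraction`` in a designed
    subsampling experiment).
    """

    phi: float
    tau_int: np.ndarray

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        tau = np.asarray(self.tau_int, float)
        if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
            raise ValueError("all tau_int must be positive and finite")
        object.__setattr__(self, "tau_int", tau)

    @property
    def weights(self) -> np.ndarray:
        """Likelihood weights ``tau_int / phi`` (1 for majority rows)."""
        return self.tau_int / self.phi

    @classmethod
    def from_multiplier(
        cls, minority_mask: Iterable[bool], multiplier: float, phi: float = DEFAULT_PHI
    ) -> "BalancingPriorSpec":
        """Build the two-level precision vector from an explicit minority
        precision multiplier (e.g. ``1 / fraction`` in a designed study)."""
        mask = np.asarray(list(minority_mask), bool)
        if not multiplier > 0:
            raise ValueError("multiplier must be positive")
        tau = np.where(mask, phi * multiplier, phi)
        return cls(phi=phi, tau_int=tau)


def compute_tau(dataset: ImbalancedDataset, phi: float = DEFAULT_PHI) -> BalancingPriorSpec:
    """Balancing precision vector for a dataset: ``phi`` on the majority,
    ``phi * (n - m) / m`` on the minority.

    The minority:majority precision ratio equals ``(n - m) / m`` exactly
    (used as a real number; no rounding), which equalises the two
    subgroups' aggregate influence on the fit.
    """
    if not phi > 0:
        raise ValueError("phi must be positive")
    n, m = dataset.n, dataset.m
    if m == 0:
        raise ValueError("no minority rows")
    if m >= n - m:
        raise ValueError("minority not smaller than majority")
    return BalancingPriorSpec.from_multiplier(dataset.is_minority, (n - m) / m, phi=phi)


# ---------------------------------------------------------------------------
# Fit assessment
# ---------------------------------------------------------------------------


def compute_rss(model: StructuralModel, data: ImbalancedDataset | pd.DataFrame) -> float:
    """Residual sum of squares of ``data`` around a fixed structural curve.

    Accepts either an :class:`ImbalancedDataset` or any DataFrame with
    ``x`` and ``y`` columns (a subgroup slice, typically — e.g. the adult
    stratum only, to check that up-weighting the minority has not
    degraded the majority fit).
    """
    if isinstance(data, ImbalancedDataset):
        x, y = data.x, data.y
    else:
        if len(data) == 0:
            raise ValueError("empty data subset")
        x = np.asarray(data["x"], float)
        y = np.asarray(data["y"], float)
    if len(x) == 0:
        raise ValueError("empty data subset")
    resid = y - predict(model, x)
    return float(np.dot(resid, resid))


def all_beyond_bound_probability(n_points: int = 6, tail_prob: float = 0.05) -> float:
    """Chance that ``n_points`` independent observations all fall beyond a
    one-sided bound of tail probability ``tail_prob``.

    With six paediatric subjects and a 90% two-sided confidence bound
    (5% per tail), the chance that all six lie beyond the bound is
    ``0.05**6 = 1.5625e-8`` — the design rationale for requiring at
    least six minority data points.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not 0 < tail_prob < 1:
        raise ValueError("tail_prob must be in (0, 1)")
    return float(tail_prob**n_points)
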