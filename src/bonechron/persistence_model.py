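"""Log-linear bone-persistence-versus-temperature regression.

The duration a bone survives exposed on a landscape falls off steeply with
local mean annual temperature (MAT): cold Arctic surfaces keep identifiable,
DNA-bearing bone for millennia, warm ones for decades.  The model is an
ordinary least-squares regression of log10(persistence, years) on MAT
(degrees C), fitted separately per burial-history class:

* ``never_buried`` — fitted on never-buried bones only;
* ``potentially_never_buried`` — fitted on the union of both classes
  (a never-buried bone is a fortiori potentially never buried).

Predictions back-transform to years and report an upper confidence bound,
either on the mean regression line (default) or for a new observation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_io import BoneRecord, BurialClass
from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "PersistenceModel",
    "PersistencePrediction",
    "fit_persistence",
    "predict_persistence",
    "predict_at_sites",
    "model_to_json",
    "model_from_json",
]

IntervalKind = Literal["mean_confidence", "new_observation"]


@dataclass(frozen=True)
class PersistenceModel:
    """A fitted log10(persistence) ~ MAT regression for one burial class.

    ``mat_mean`` and ``mat_sxx`` (sum of squared MAT deviations) are the
    design sufficient statistics needed to compute confidence or prediction
    intervals at a new temperature; ``mat_min``/``mat_max`` delimit the
    fitted range so extrapolation can be flagged.
    """

    burial_class: BurialClass
    slope: float  # log10-years per degree C
    intercept: float  # log10-years
    n: int
    r_squared: float
    p_value: float  # two-sided p-value of the slope
    residual_variance: float  # (log10-years)^2, ssr / (n - 2)
    mat_mean: float
    mat_sxx: float
    mat_min: float
    mat_max: float


@dataclass(frozen=True)
class PersistencePrediction:
    """Predicted persistence window at one temperature, in years."""

    mat: float
    mean_persistence: float
    upper_ci: float
    ci_level: float
    interval_kind: IntervalKind
    extrapolated: bool


def _class_subset(
    records: Sequence[BoneRecord], burial_class: BurialClass
) -> list[BoneRecord]:
    burial_class = BurialClass(burial_class)
    if burial_class is BurialClass.NEVER_BURIED:
        return [r for r in records if r.burial_class is BurialClass.NEVER_BURIED]
    # The broader class is the union: never-buried bones are included.
    return list(records)


def fit_persistence(
    records: Sequence[BoneRecord],
    burial_class: BurialClass,
    weighted: bool = False,
) -> PersistenceModel:
    """Fit log10(persistence) on MAT by OLS for one burial class.

    Dating error is ignored by default (2-sigma errors are small relative
    to the persistence durations); ``weighted=True`` instead weights each
    point by 1/sigma^2 on the age axis, propagated to the log scale.
    """
    subset = _class_subset(records, burial_class)
    if len(subset) < 3:
        raise InsufficientDataError(
            f"need >= 3 records for class {BurialClass(burial_class).value}, "
            f"got {len(subset)}"
        )
    mat = np.array([r.mat for r in subset], dtype=float)
    age = np.array([r.age for r in subset], dtype=float)
    y = np.log10(age)
    if np.ptp(mat) == 0:
        raise DegenerateDesignError("zero variance in MAT; cannot fit a slope")
    X = sm.add_constant(mat)
    if weighted:
        # delta method: sd of log10(age) ~= sigma_age / (age * ln 10)
        sigma = np.array([max(r.age_2sigma / 2.0, 1e-12) for r in subset])
        sd_log = sigma / (age * math.log(10))
        fit = sm.WLS(y, X, weights=1.0 / sd_log**2).fit()
    else:
        fit = sm.OLS(y, X).fit()
    n = len(subset)
    return PersistenceModel(
        burial_class=BurialClass(burial_class),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=n,
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        residual_variance=float(fit.ssr / (n - 2)),
        mat_mean=float(mat.mean()),
        mat_sxx=float(((mat - mat.mean()) ** 2).sum()),
        mat_min=float(mat.min()),
        mat_max=float(mat.max()),
    )


def predict_persistence(
    model: PersistenceModel,
    mat: float,
    ci_level: float = 0.95,
    interval_kind: IntervalKind = "mean_confidence",
) -> PersistencePrediction:
    """Predict the persistence window (mean and upper bound) at one MAT.

    The mean is ``10**(intercept + slope * mat)``.  The upper bound is the
    back-transformed upper limit of, per ``interval_kind``, either the
    confidence interval of the regression line (``mean_confidence``) or the
    prediction interval for a single new bone (``new_observation``).
    Temperatures outside the fitted MAT range are allowed but flagged.
    """
    if not math.isfinite(mat):
        raise ValueError(f"mat must be finite, got {mat}")
    if not (0 < ci_level < 1):
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    if interval_kind not in ("mean_confidence", "new_observation"):
        raise ValueError(f"unknown interval_kind: {interval_kind!r}")
    mean_log = model.intercept + model.slope * mat
    leverage = 1.0 / model.n + (mat - model.mat_mean) ** 2 / model.mat_sxx
    if interval_kind == "new_observation":
        leverage += 1.0
    se = math.sqrt(model.residual_variance * leverage)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, model.n - 2))
    return PersistencePrediction(
        mat=float(mat),
        mean_persistence=float(10.0**mean_log),
        upper_ci=float(10.0 ** (mean_log + tcrit * se)),
        ci_level=float(ci_level),
        interval_kind=interval_kind,
        extrapolated=bool(mat < model.mat_min or mat > model.mat_max),
    )


def predict_at_sites(
    model: PersistenceModel,
    sites: Sequence[tuple[str, float]],
    ci_level: float = 0.95,
    interval_kind: IntervalKind = "mean_confidence",
) -> list[PersistencePrediction]:
    """Vectorised prediction: one :class:`PersistencePrediction` per site.

    Output order matches input order.  ``sites`` is a sequence of
    ``(site_id, mat)`` pairs; site ids are not stored on the predictions,
    whose alignment with the input carries the association.
    """
    return [
        predict_persistence(model, mat, ci_level, interval_kind)
        for _, mat in sites
    ]


def model_to_json(model: PersistenceModel, path: str | Path | None = None) -> str:
    """Serialize a fitted model to JSON (all fields round-trip)."""
    from .data_io import to_json

    return to_json(model, path)


def model_from_json(source: str | Path) -> PersistenceModel:
    """Load a model serialized by :func:`model_to_json`.

    ``source`` may be a JSON string or a path to a JSON file.
    """
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    data = json.loads(text)
    data["burial_class"] = BurialClass(data["burial_class"])
    return PersistenceModel(**data)
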