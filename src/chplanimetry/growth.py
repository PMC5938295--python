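"""Sex-specific linear growth models of carpal-bone area versus age.

Projected capitate/hamate areas grow close to linearly with
chronological age through childhood, so the model is ordinary least
squares on ``area = a + b * age`` per sex, hand and target bone
(capitate, hamate, or their sum CH). Bone age is then estimated by
inverting the fitted line: ``age = (area - a) / b``, clamped to
[0, 216] months.

The central object is :class:`BoneAgeLinearModel`, a scikit-learn-style
estimator (``fit`` / ``predict`` / ``get_params``); the module-level
functions are thin wrappers kept for pipeline and scripting use.
Correlation utilities (Pearson r with Fisher-z confidence intervals, the
z-test for comparing two correlations, and the weak/moderate/strong
categorisation) live here too because the model's headline diagnostic is
the age-area correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

TARGETS = ("capitate", "hamate", "CH")

#: default clamp range for inverted bone ages, months (0-18 years)
AGE_CLAMP_MONTHS = (0.0, 216.0)

#: published left-hand regression coefficients (intercept a mm²,
#: slope b mm²/month) for a Korean paediatric cohort; used as reference
#: models and as the synthetic generator's default growth coefficients.
REFERENCE_COEFFICIENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("male", "CH"): (-13.3391, 3.0571),
    ("female", "CH"): (-10.2867, 2.5856),
    ("male", "capitate"): (-6.6278, 1.8057),
    ("female", "capitate"): (-6.7608, 1.5303),
    ("male", "hamate"): (-7.2632, 1.2514),
    ("female", "hamate"): (-3.5258, 1.0552),
}


@dataclass(frozen=True)
class BoneAgeEstimate:
    subject_id: str
    method: str  # "CH_planimetry" or "GP_rater"
    reviewer_id: str
    estimated_age_months: float
    clamped: bool


class BoneAgeLinearModel(RegressorMixin, BaseEstimator):
    """OLS growth line ``area = a + b * age`` with bone-age inversion.

    Parameters
    ----------
    sex, hand, target
        Metadata identifying which stratum the model describes; not used
        numerically. ``target`` is one of ``capitate``, ``hamate``, ``CH``.
    clamp_range
        ``(low, high)`` months for inverted bone-age estimates.

    Fitted attributes
    -----------------
    intercept_ : float, mm²
    slope_ : float, mm²/month (must be positive for a valid growth fit)
    residual_sd_ : float, mm², with the n-2 OLS denominator
    r_ : float, Pearson correlation of age and area
    r_ci_ : (low, high), 95 % Fisher-z confidence interval for ``r_``
    n_ : int, number of (age, area) pairs
    """

    def __init__(
        self,
        sex: str | None = None,
        hand: str = "left",
        target: str = "CH",
        clamp_range: tuple[float, float] = AGE_CLAMP_MONTHS,
    ) -> None:
        self.sex = sex
        self.hand = hand
        self.target = target
        self.clamp_range = clamp_range

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _column(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single age feature")
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError("ages must be 1-d or a single-column 2-d array")
        if not np.all(np.isfinite(x)):
            raise ValueError("ages contain non-finite values")
        return x

    def fit(self, X, y) -> "BoneAgeLinearModel":
        ages = self._column(X)
        areas = np.asarray(y, dtype=float)
        if areas.shape != ages.shape:
            raise ValueError("ages and areas must have equal length")
        n = ages.size
        if n < 3:
            raise ValueError(f"need at least 3 pairs to fit, got {n}")
        if np.ptp(ages) == 0:
            raise ValueError("constant age vector: degenerate fit")
        res = stats.linregress(ages, areas)
        self.intercept_ = float(res.intercept)
        self.slope_ = float(res.slope)
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        resid = areas - (self.intercept_ + self.slope_ * ages)
        self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        # HC1 sandwich SEs: area noise grows with bone size, so the
        # homoscedastic OLS SEs under-cover; the robust ones are the default
        # for coefficient CIs.
        X = np.column_stack([np.ones(n), ages])
        xtx_inv = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * (resid**2)[:, None])
        V = xtx_inv @ meat @ xtx_inv * (n / (n - 2))
        self.intercept_se_robust_ = float(np.sqrt(V[0, 0]))
        self.slope_se_robust_ = float(np.sqrt(V[1, 1]))
        self.r_ = float(res.rvalue)
        if n >= 4 and abs(self.r_) < 1.0:
            self.r_ci_ = pearson_r_ci_from_r(self.r_, n)
        else:
            self.r_ci_ = (self.r_, self.r_)
        self.n_ = int(n)
        self.n_features_in_ = 1
        return self

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        slope: float,
        *,
        sex: str | None = None,
        hand: str = "left",
        target: str = "CH",
        n: int | None = None,
        r: float | None = None,
        r_ci: tuple[float, float] | None = None,
        residual_sd: float | None = None,
        clamp_range: tuple[float, float] = AGE_CLAMP_MONTHS,
    ) -> "BoneAgeLinearModel":
        """Build an already-'fitted' model from known coefficients."""
        m = cls(sex=sex, hand=hand, target=target, clamp_range=clamp_range)
        m.intercept_ = float(intercept)
        m.slope_ = float(slope)
        m.n_ = 0 if n is None else int(n)
        m.r_ = float("nan") if r is None else float(r)
        m.r_ci_ = (float("nan"), float("nan")) if r_ci is None else tuple(r_ci)
        m.residual_sd_ = float("nan") if residual_sd is None else float(residual_sd)
        m.n_features_in_ = 1
        return m

    def coef_ci(
        self, level: float = 0.95, robust: bool = True
    ) -> tuple[tuple[float, float], tuple[float, float]]:
        """t-based confidence intervals ``((slope_lo, slope_hi), (a_lo, a_hi))``.

        ``robust=True`` (default) uses the HC1 heteroscedasticity-consistent
        standard errors; ``robust=False`` the classical OLS ones.
        """
        if not hasattr(self, "slope_se_"):
            raise AttributeError("coefficient SEs require a data fit")
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n_ - 2)
        se_b = self.slope_se_robust_ if robust else self.slope_se_
        se_a = self.intercept_se_robust_ if robust else self.intercept_se_
        return (
            (self.slope_ - tcrit * se_b, self.slope_ + tcrit * se_b),
            (self.intercept_ - tcrit * se_a, self.intercept_ + tcrit * se_a),
        )

    # -- prediction and inversion -----------------------------------------

    def predict(self, X) -> np.ndarray:
        """Predicted area (mm²) at age (months): ``a + b * age``.

        Ages outside [1, 216] months raise a warning but are still
        evaluated (the line extrapolates).
        """
        ages = self._column(X)
        if np.any((ages < 1.0) | (ages > 216.0)):
            warnings.warn("age outside [1, 216] months: extrapolating", stacklevel=2)
        return self.intercept_ + self.slope_ * ages

    def estimate_age(self, area_mm2) -> tuple[np.ndarray, np.ndarray]:
        """Invert the growth line: bone age (months) for given CH area.

        Returns ``(ages, clamped)`` where ``clamped`` flags estimates
        that fell outside ``clamp_range`` before clamping.
        """
        if not hasattr(self, "slope_"):
            raise AttributeError("model is not fitted")
        if self.slope_ <= 0:
            raise ValueError("non-positive slope: growth model cannot be inverted")
        area = np.atleast_1d(np.asarray(area_mm2, dtype=float))
        raw = (area - self.intercept_) / self.slope_
        lo, hi = self.clamp_range
        clamped = (raw < lo) | (raw > hi)
        return np.clip(raw, lo, hi), clamped

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "hand": self.hand,
            "target": self.target,
            "intercept_a": self.intercept_,
            "slope_b": self.slope_,
            "n": self.n_,
            "r": self.r_,
            "ci_low": self.r_ci_[0],
            "ci_high": self.r_ci_[1],
            "residual_sd": self.residual_sd_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoneAgeLinearModel":
        m = cls.from_coefficients(
            d["intercept_a"],
            d["slope_b"],
            sex=d.get("sex"),
            hand=d.get("hand", "left"),
            target=d.get("target", "CH"),
            n=d.get("n"),
            r=d.get("r"),
            r_ci=(d.get("ci_low"), d.get("ci_high")),
            residual_sd=d.get("residual_sd"),
        )
        if m.n_ and m.n_ >= 3 and m.slope_ <= 0:
            raise ValueError("invalid serialized model: non-positive slope")
        return m


def reference_models() -> dict[tuple[str, str], BoneAgeLinearModel]:
    """The bundled left-hand reference models, keyed by (sex, target)."""
    return {
        (sex, target): BoneAgeLinearModel.from_coefficients(
            a, b, sex=sex, hand="left", target=target
        )
        for (sex, target), (a, b) in REFERENCE_COEFFICIENTS.items()
    }


# ---------------------------------------------------------------------------
# functional wrappers


def fit_growth_model(
    ages: Sequence[float],
    areas: Sequence[float],
    *,
    sex: str | None = None,
    hand: str = "left",
    target: str = "CH",
) -> BoneAgeLinearModel:
    return BoneAgeLinearModel(sex=sex, hand=hand, target=target).fit(ages, areas)


def predict_area(model: BoneAgeLinearModel, age_months) -> np.ndarray | float:
    out = model.predict(np.atleast_1d(age_months))
    return float(out[0]) if np.isscalar(age_months) else out


def estimate_bone_age(
    model: BoneAgeLinearModel,
    ch_area_mm2: float,
    *,
    subject_id: str = "",
    reviewer_id: str = "",
) -> BoneAgeEstimate:
    ages, clamped = model.estimate_age(ch_area_mm2)
    return BoneAgeEstimate(
        subject_id=subject_id,
        method="CH_planimetry",
        reviewer_id=reviewer_id,
        estimated_age_months=float(ages[0]),
        clamped=bool(clamped[0]),
    )


def save_models(models: Sequence[BoneAgeLinearModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2))


def load_models(path: str | Path) -> list[BoneAgeLinearModel]:
    return [BoneAgeLinearModel.from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# correlation statistics


def pearson_r_ci_from_r(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: degenerate confidence interval", stacklevel=2)
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_r_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with its Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("|r| = 1: degenerate confidence interval", stacklevel=2)
        return r, (r, r)
    if x.size == 3:
        warnings.warn("n = 3: Fisher-z interval undefined", stacklevel=2)
        return r, (float("nan"), float("nan"))
    return r, pearson_r_ci_from_r(r, x.size, level)


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Independent-samples Fisher z-test for two correlations.

    Returns ``(z, two_sided_p)`` with
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``. Assumes the
    two correlations come from independent samples.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlation must satisfy |r| < 1, got {r}")
        if n <= 3:
            raise ValueError(f"need n > 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def categorize_correlation(r: float) -> str:
    """weak (|r| <= 0.3), moderate (0.3 < |r| <= 0.7) or strong (> 0.7)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    a = abs(r)
    if a <= 0.3:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"
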