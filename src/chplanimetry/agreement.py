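"""Method-comparison and inter-rater agreement statistics.

Everything needed to validate one bone-age method against another and to
quantify reproducibility between two reviewers:

* accuracy — per-subject ``100 * (1 - |BA - CA| / CA)`` against
  chronological age (100 % at perfect agreement; unbounded below when an
  estimate overshoots by more than twice the truth);
* precision — per-subject percentage disagreement between two
  reviewers, ``100 * |a - b| / mean(a, b)``;
* paired t-test;
* Bland-Altman mean difference and 95 % limits of agreement (LOA),
  ``mean(d) ± 1.96 sd(d)``;
* Lin's concordance correlation coefficient ρ_c (population moments)
  with the poor/moderate/substantial/almost-perfect categorisation;
* Deming errors-in-variables regression with leave-one-out jackknife
  standard errors;
* :func:`build_agreement_report`, assembling the full two-method,
  two-reviewer comparison into one serialisable report.

The paired t, Bland-Altman, concordance and Deming computations are
implemented here directly from their defining formulas; p-values use
scipy's t and normal distributions. No multiple-testing correction is
applied — all p-values are reported raw.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "accuracy_percent",
    "precision_percent",
    "paired_t",
    "bland_altman",
    "lin_ccc",
    "categorize_ccc",
    "deming",
    "build_agreement_report",
    "AgreementReport",
    "BlandAltman",
    "DemingFit",
    "PairedT",
    "SummaryPct",
]


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length 1-d vectors")
    return a, b


@dataclass(frozen=True)
class SummaryPct:
    """A per-subject percentage summarised as mean ± sample SD."""

    per_subject: tuple
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryPct":
        return cls(
            per_subject=tuple(float(v) for v in values),
            mean=float(np.mean(values)),
            sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        )


def accuracy_percent(estimated, chronological) -> SummaryPct:
    """Accuracy of bone-age estimates against chronological age.

    Per subject: ``100 * (1 - |BA - CA| / CA)``. Equals 100 % iff the
    estimate matches chronological age exactly; goes negative when the
    estimate misses by more than the chronological age itself.
    """
    ba, ca = _pair(estimated, chronological)
    if np.any(ca <= 0):
        raise ValueError("chronological ages must be positive")
    return SummaryPct.from_values(100.0 * (1.0 - np.abs(ba - ca) / ca))


def precision_percent(est_rev_a, est_rev_b) -> SummaryPct:
    """Inter-reviewer precision: ``100 * |a - b| / mean(a, b)`` per subject.

    Symmetric in its arguments. Subjects whose two-reviewer mean is zero
    are excluded with a warning (the percentage is undefined there).
    """
    a, b = _pair(est_rev_a, est_rev_b)
    mean = 0.5 * (a + b)
    ok = mean != 0
    if not np.all(ok):
        import warnings

        warnings.warn(
            f"excluding {int((~ok).sum())} subject(s) with zero mean estimate",
            stacklevel=2,
        )
    return SummaryPct.from_values(100.0 * np.abs(a - b)[ok] / mean[ok])


@dataclass(frozen=True)
class PairedT:
    t: float
    df: int
    p: float


def paired_t(a, b) -> PairedT:
    """Two-sided paired t-test: ``t = mean(d) / (sd(d)/sqrt(n))``, df = n-1."""
    a, b = _pair(a, b)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero difference variance: paired t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedT(t=t, df=n - 1, p=p)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float

    @property
    def width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(a, b, multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement of two paired measurement series.

    Differences ``d = a - b``; limits of agreement are
    ``mean(d) ± multiplier * sd(d)`` with the sample (n-1) SD. The
    default multiplier 1.96 gives the conventional 95 % limits (no
    small-sample t correction).
    """
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    m = float(np.mean(d))
    s = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_diff=m, loa_low=m - multiplier * s, loa_high=m + multiplier * s, sd_diff=s
    )


def lin_ccc(a, b) -> float:
    """Lin's concordance correlation coefficient ρ_c.

    ``ρ_c = 2 s_ab / (s_a² + s_b² + (mean a - mean b)²)`` with population
    (n-denominator) moments. Penalises both scatter and departure of the
    best-fit line from the identity; 1 iff the two series are identical.
    """
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    va = float(np.var(a))
    vb = float(np.var(b))
    if va == 0 and vb == 0 and np.mean(a) == np.mean(b):
        raise ValueError("both vectors constant: concordance undefined")
    sab = float(np.mean((a - a.mean()) * (b - b.mean())))
    return 2.0 * sab / (va + vb + (float(a.mean()) - float(b.mean())) ** 2)


def categorize_ccc(rho_c: float) -> str:
    """poor (< 0.90), moderate [0.90, 0.95], substantial (0.95, 0.99], almost perfect (> 0.99)."""
    if not -1.0 <= rho_c <= 1.0:
        raise ValueError("rho_c must lie in [-1, 1]")
    if rho_c < 0.90:
        return "poor"
    if rho_c <= 0.95:
        return "moderate"
    if rho_c <= 0.99:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci_slope: tuple
    ci_intercept: tuple
    lam: float


def _deming_coef(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0:
        raise ValueError("zero covariance: Deming slope undefined")
    disc = (syy - lam * sxx) ** 2 + 4.0 * lam * sxy**2
    slope = (syy - lam * sxx + np.sqrt(disc)) / (2.0 * sxy)
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    return float(slope), float(intercept)


def deming(x, y, lam: float = 1.0) -> DemingFit:
    """Deming errors-in-variables regression of y on x.

    Both variables are treated as measured with error; ``lam`` is the
    error-variance ratio (1 = orthogonal regression; as lam grows the
    fit approaches ordinary least squares of y on x). Standard errors
    are leave-one-out jackknife; 95 % confidence intervals are
    ``estimate ± 1.96 SE``.
    """
    x, y = _pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 points for a Deming fit")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    slope, intercept = _deming_coef(x, y, lam)
    # leave-one-out jackknife
    idx = np.arange(n)
    reps = np.array(
        [_deming_coef(x[idx != i], y[idx != i], lam) for i in range(n)]
    )
    se = np.sqrt((n - 1) / n * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0))
    se_slope, se_intercept = float(se[0]), float(se[1])
    return DemingFit(
        slope=slope,
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_intercept,
        ci_slope=(slope - 1.96 * se_slope, slope + 1.96 * se_slope),
        ci_intercept=(intercept - 1.96 * se_intercept, intercept + 1.96 * se_intercept),
        lam=lam,
    )


# ---------------------------------------------------------------------------
# full report


@dataclass
class AgreementReport:
    """Two-method, two-reviewer bone-age validation summary.

    ``methods`` maps method name -> per-method block holding accuracy
    per reviewer, inter-reviewer precision, Bland-Altman limits of
    agreement (months), Lin's ρ_c with its category, and the
    reviewer-vs-reviewer paired t. ``between_methods`` holds the Deming
    fit of method B on method A (per reviewer) and the
    estimated-vs-chronological paired t per method/reviewer.
    """

    n_subjects: int
    methods: dict = field(default_factory=dict)
    between_methods: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "methods": self.methods,
            "between_methods": self.between_methods,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(
            n_subjects=d["n_subjects"],
            methods=d["methods"],
            between_methods=d["between_methods"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AgreementReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_markdown(self) -> str:
        lines = [f"# Agreement report (n = {self.n_subjects})", ""]
        for method, blk in self.methods.items():
            lines.append(f"## {method}")
            for rev, acc in blk["accuracy"].items():
                lines.append(
                    f"- accuracy ({rev}): {acc['mean']:.2f} % ± {acc['sd']:.2f} %"
                )
            prec = blk["precision"]
            lines.append(f"- precision: {prec['mean']:.2f} % ± {prec['sd']:.2f} %")
            ba = blk["bland_altman"]
            lines.append(
                f"- Bland-Altman: mean diff {ba['mean_diff']:.2f} months, "
                f"95 % LOA {ba['loa_low']:.1f} to {ba['loa_high']:.1f} months"
            )
            lines.append(
                f"- Lin's rho_c: {blk['lin_ccc']:.4f} ({blk['ccc_category']})"
            )
            t = blk["reviewer_paired_t"]
            lines.append(
                f"- reviewer paired t: t = {t['t']:.3f}, df = {t['df']}, p = {t['p']:.4f}"
            )
            lines.append("")
        for label, blk in self.between_methods.items():
            if "slope" in blk:
                lines.append(
                    f"- Deming {label}: slope {blk['slope']:.4f} "
                    f"(SE {blk['se_slope']:.4f}), intercept {blk['intercept']:.4f} "
                    f"(SE {blk['se_intercept']:.4f})"
                )
            else:
                lines.append(
                    f"- paired t {label}: t = {blk['t']:.3f}, df = {blk['df']}, "
                    f"p = {blk['p']:.4f}"
                )
        return "\n".join(lines) + "\n"


def _summary_dict(s: SummaryPct) -> dict:
    return {"mean": s.mean, "sd": s.sd}


def build_agreement_report(
    ch_estimates: Mapping[str, Sequence[float]],
    gp_estimates: Mapping[str, Sequence[float]],
    chronological: Sequence[float],
    subject_ids: Sequence[str] | None = None,
) -> AgreementReport:
    """Assemble the full CH-planimetry-vs-GP validation report.

    ``ch_estimates`` and ``gp_estimates`` each map two reviewer ids to
    aligned bone-age vectors (months); ``chronological`` is the aligned
    chronological-age vector. All vectors must be the same length (a
    misalignment raises with the offending lengths listed).
    """
    ca = np.asarray(chronological, dtype=float)
    blocks: dict[str, dict[str, np.ndarray]] = {}
    for method, est in (("CH_planimetry", ch_estimates), ("GP_method", gp_estimates)):
        if len(est) != 2:
            raise ValueError(f"{method}: expected exactly two reviewers, got {len(est)}")
        blocks[method] = {r: np.asarray(v, dtype=float) for r, v in est.items()}
        bad = {r: v.size for r, v in blocks[method].items() if v.size != ca.size}
        if bad:
            raise ValueError(
                f"{method}: estimate vectors misaligned with chronological "
                f"ages (n={ca.size}): {bad}"
            )

    report = AgreementReport(n_subjects=int(ca.size))
    for method, revs in blocks.items():
        (r1, v1), (r2, v2) = revs.items()
        blk = {
            "accuracy": {
                r: _summary_dict(accuracy_percent(v, ca)) for r, v in revs.items()
            },
            "precision": _summary_dict(precision_percent(v1, v2)),
            "bland_altman": asdict(bland_altman(v1, v2)),
            "lin_ccc": lin_ccc(v1, v2),
            "reviewer_paired_t": _safe_t(v1, v2),
        }
        blk["ccc_category"] = categorize_ccc(blk["lin_ccc"])
        report.methods[method] = blk

    ch = blocks["CH_planimetry"]
    gp = blocks["GP_method"]
    for (r_ch, v_ch), (r_gp, v_gp) in zip(ch.items(), gp.items()):
        dem = asdict(deming(v_ch, v_gp))
        dem["ci_slope"] = list(dem["ci_slope"])  # JSON-canonical
        dem["ci_intercept"] = list(dem["ci_intercept"])
        report.between_methods[f"GP_on_CH[{r_ch}|{r_gp}]"] = dem
        report.between_methods[f"CH_vs_GP_paired_t[{r_ch}|{r_gp}]"] = _safe_t(
            v_ch, v_gp
        )
    for method, revs in blocks.items():
        for r, v in revs.items():
            report.between_methods[f"{method}_vs_chronological[{r}]"] = _safe_t(v, ca)
    return report


def _safe_t(a, b) -> dict:
    """Paired t as a dict; degenerate (zero-variance) contrasts yield t=0, p=1."""
    try:
        return asdict(paired_t(a, b))
    except ValueError:
        return {"t": 0.0, "df": int(np.asarray(a).size - 1), "p": 1.0}
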