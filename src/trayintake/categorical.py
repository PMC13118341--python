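"""Ordinal agreement between diary categories and measured intake.

Continuous consumed fractions are discretized on the routine three-level
diary scale — none / half / all — using fixed thresholds: a fraction in
[0, 0.2] is "none", in (0.2, 0.7] "half", and in (0.7, 1] "all".  Agreement
between two categorical streams is summarised by the 3×3 concordance
matrix, percent agreement, and Cohen's kappa (unweighted and with quadratic
weights, the ordinal default), each with an asymptotic standard error and a
normal-theory 95% confidence interval.

The kappa standard error is the large-sample variance of weighted kappa
(Fleiss–Cohen–Everitt form); the unweighted case uses the same expression
with identity weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, InsufficientDataError, UndefinedFractionError

#: Upper edge of the "none" bin and of the "half" bin, on the fraction scale.
NONE_MAX = 0.2
HALF_MAX = 0.7

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class IntakeCategory(IntEnum):
    """Ordinal intake level on the three-point diary scale."""

    none = 0
    half = 1
    all = 2

    @classmethod
    def from_diary_score(cls, score: float) -> "IntakeCategory":
        mapping = {0.0: cls.none, 0.5: cls.half, 1.0: cls.all}
        if score not in mapping:
            raise DataError(f"diary score {score!r} not in {{0, 0.5, 1}}")
        return mapping[score]


def fraction_consumed(intake_g: float, served_g: float) -> float:
    """Consumed fraction intake/served, in [0, 1]."""
    if served_g <= 0:
        raise UndefinedFractionError(
            f"served weight {served_g} g: consumed fraction undefined"
        )
    frac = intake_g / served_g
    if not 0.0 <= frac <= 1.0:
        raise DataError(
            f"intake {intake_g} g outside [0, served={served_g} g]"
        )
    return frac


def categorize(fraction: float) -> IntakeCategory:
    """Map a consumed fraction to its diary category.

    [0, 0.2] → none, (0.2, 0.7] → half, (0.7, 1] → all.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DataError(f"fraction {fraction!r} outside [0, 1]")
    if fraction <= NONE_MAX:
        return IntakeCategory.none
    if fraction <= HALF_MAX:
        return IntakeCategory.half
    return IntakeCategory.all


def categorize_array(fractions: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize` returning integer codes 0/1/2."""
    f = np.asarray(fractions, dtype=float)
    if np.any((f < 0) | (f > 1) | ~np.isfinite(f)):
        raise DataError("fractions outside [0, 1]")
    return np.where(f <= NONE_MAX, 0, np.where(f <= HALF_MAX, 1, 2))


@dataclass
class ConcordanceMatrix:
    """3×3 cross-tabulation: rows = first rater (diary), cols = second (measured)."""

    counts: np.ndarray
    n: int

    @classmethod
    def from_counts(cls, counts) -> "ConcordanceMatrix":
        c = np.asarray(counts, dtype=float)
        if c.shape != (3, 3) or np.any(c < 0):
            raise DataError("concordance counts must be a non-negative 3×3 array")
        n = int(round(c.sum()))
        if n < 1:
            raise InsufficientDataError("empty concordance matrix")
        return cls(counts=c, n=n)


def concordance(
    diary: Sequence[IntakeCategory], measured: Sequence[IntakeCategory]
) -> ConcordanceMatrix:
    """Cross-tabulate two aligned category streams."""
    a = np.asarray([int(x) for x in diary])
    b = np.asarray([int(x) for x in measured])
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.size} diary vs {b.size} measured")
    if a.size == 0:
        raise InsufficientDataError("no category pairs")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    return ConcordanceMatrix(counts=counts, n=int(a.size))


def percent_agreement(m: ConcordanceMatrix) -> float:
    """100 × trace / n."""
    return 100.0 * float(np.trace(m.counts)) / m.n


@dataclass
class KappaResult:
    """Chance-corrected agreement with SE-based 95% confidence interval."""

    kappa: float
    weighting: str
    se: float
    ci_low: float
    ci_high: float
    po: float
    pe: float
    degenerate: bool = False


def _weight_matrix(weighting: str, k: int = 3) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "quadratic":
        return 1.0 - (i - j) ** 2 / (k - 1) ** 2
    if weighting == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weighting {weighting!r}")


def cohen_kappa(m: ConcordanceMatrix, weighting: str = "quadratic") -> KappaResult:
    """Cohen's kappa with asymptotic SE and normal 95% CI.

    kappa = (po − pe)/(1 − pe) with agreement weights w_ij = 1 − (i−j)²/(k−1)²
    for quadratic weighting and the identity matrix otherwise.  When both
    raters put all mass in a single cell (pe = 1) the result is flagged
    degenerate and reported as kappa 1 with a zero-width interval.
    """
    if m.n < 2:
        raise InsufficientDataError("kappa needs at least two rated pairs")
    w = _weight_matrix(weighting)
    p = m.counts / m.n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if abs(1.0 - pe) < 1e-15:
        return KappaResult(
            kappa=1.0, weighting=weighting, se=0.0, ci_low=1.0, ci_high=1.0,
            po=po, pe=pe, degenerate=True,
        )
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss–Cohen–Everitt large-sample variance of (weighted) kappa.
    wbar_row = w @ c           # w̄_i· = Σ_j p_·j w_ij
    wbar_col = r @ w           # w̄_·j = Σ_i p_i· w_ij
    term = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = (
        float((p * term**2).sum()) - (kappa - pe * (1.0 - kappa)) ** 2
    ) / (m.n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(-1.0, kappa - Z_95 * se)
    hi = min(1.0, kappa + Z_95 * se)
    return KappaResult(
        kappa=float(kappa), weighting=weighting, se=se,
        ci_low=lo, ci_high=hi, po=po, pe=pe,
    )


@dataclass
class CategoricalAgreementReport:
    """Concordance matrix plus agreement statistics for one comparison."""

    matrix: ConcordanceMatrix
    percent_agreement: float
    kappa_unweighted: KappaResult
    kappa_quadratic: KappaResult
    n_excluded_zero_served: int = 0

    def to_dict(self) -> dict:
        def _k(k: KappaResult) -> dict:
            return {"kappa": k.kappa, "se": k.se, "ci": [k.ci_low, k.ci_high]}

        return {
            "concordance_matrix": self.matrix.counts.astype(int).tolist(),
            "n": self.matrix.n,
            "percent_agreement": self.percent_agreement,
            "kappa": {
                "unweighted": _k(self.kappa_unweighted),
                "quadratic": _k(self.kappa_quadratic),
            },
            "n_excluded_zero_served": self.n_excluded_zero_served,
        }


def agreement_report(
    rater: Sequence[IntakeCategory],
    measured: Sequence[IntakeCategory],
    n_excluded_zero_served: int = 0,
) -> CategoricalAgreementReport:
    m = concordance(rater, measured)
    return CategoricalAgreementReport(
        matrix=m,
        percent_agreement=percent_agreement(m),
        kappa_unweighted=cohen_kappa(m, "unweighted"),
        kappa_quadratic=cohen_kappa(m, "quadratic"),
        n_excluded_zero_served=n_excluded_zero_served,
    )


def sensitivity_continuous(
    diary_scores: Sequence[float],
    ai_estimates_g: Optional[Sequence[float]],
    weighed_g: Sequence[float],
    served_g: Sequence[float],
) -> dict:
    """Primary vs sensitivity categorical agreement, side by side.

    Primary analysis: diary scores used directly as categories against
    categorized weighed fractions.  Sensitivity analysis: diary scores
    treated as fixed continuous proportions (0%, 50%, 100%) and passed
    through the same fraction→category mapping as the weighed (and, when
    available, AI) streams.  Trays with zero served weight are excluded
    and counted.
    """
    scores = np.asarray(diary_scores, dtype=float)
    gold = np.asarray(weighed_g, dtype=float)
    served = np.asarray(served_g, dtype=float)
    if not (scores.shape == gold.shape == served.shape):
        raise DataError("diary, weighed and served vectors must be aligned")
    ai = None if ai_estimates_g is None else np.asarray(ai_estimates_g, dtype=float)
    if ai is not None and ai.shape != gold.shape:
        raise DataError("AI vector not aligned with weighed vector")

    keep = served > 0
    n_excluded = int((~keep).sum())
    scores, gold, served = scores[keep], gold[keep], served[keep]
    if ai is not None:
        ai = ai[keep]

    measured_cat = categorize_array(np.clip(gold / served, 0, 1))
    diary_cat = np.asarray([int(IntakeCategory.from_diary_score(s)) for s in scores])
    # Sensitivity: diary as continuous 0/0.5/1 proportions re-discretized.
    diary_cat_sens = categorize_array(scores)

    out = {
        "primary": agreement_report(
            [IntakeCategory(i) for i in diary_cat],
            [IntakeCategory(i) for i in measured_cat],
            n_excluded,
        ).to_dict(),
        "sensitivity": agreement_report(
            [IntakeCategory(i) for i in diary_cat_sens],
            [IntakeCategory(i) for i in measured_cat],
            n_excluded,
        ).to_dict(),
    }
    if ai is not None:
        ai_cat = categorize_array(np.clip(ai / served, 0, 1))
        out["ai_vs_measured"] = agreement_report(
            [IntakeCategory(i) for i in ai_cat],
            [IntakeCategory(i) for i in measured_cat],
            n_excluded,
        ).to_dict()
    return out
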