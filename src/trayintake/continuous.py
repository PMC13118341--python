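"""Continuous-scale agreement against gold-standard weighed intake.

An estimate stream (nursing-diary grams or AI grams) is compared with the
weighed reference through signed errors e_i = estimate_i − gold_i:

* bias — mean signed error (negative = systematic underestimation),
* SD of signed errors (sample SD, n−1 denominator),
* RMSE = sqrt(mean e²), which satisfies rmse² = bias² + sd²·(n−1)/n,
* Bland–Altman 95% limits of agreement = bias ± 1.96·sd,
* P10/P15/P30 — percent of estimates within ±10/15/30% of gold,
* MAE and MAPE.

Percentile bootstrap confidence intervals (default 5000 resamples) are
available for any of these, resampling trays or — for synthetic data with
patient identifiers — whole patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .errors import (
    DataError,
    DegenerateResampleError,
    InsufficientDataError,
)

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class PairedIntake:
    """Gold (weighed) vs estimated consumed grams for one tray."""

    tray_id: str
    gold_g: float
    estimate_g: float
    method: str  # "nursing" or "ai"
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gold_g < 0 or self.estimate_g < 0:
            raise DataError(
                f"tray {self.tray_id!r}: negative mass in pair "
                f"(gold {self.gold_g}, estimate {self.estimate_g})"
            )


@dataclass
class AgreementMetrics:
    """Full continuous-agreement statistic set for one method."""

    n: int
    bias_g: float
    sd_signed_g: float
    rmse_g: float
    loa_low_g: float
    loa_high_g: float
    p10: float
    p15: float
    p30: float
    mae_g: float
    mape_pct: float
    n_gold_zero: int = 0
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "bias_g": self.bias_g,
            "sd_g": self.sd_signed_g,
            "rmse_g": self.rmse_g,
            "loa": [self.loa_low_g, self.loa_high_g],
            "p10": self.p10,
            "p15": self.p15,
            "p30": self.p30,
            "mae_g": self.mae_g,
            "mape_pct": self.mape_pct,
        }
        if self.ci:
            d["ci"] = self.ci
        return d


@dataclass
class BootstrapConfig:
    """Nonparametric bootstrap settings (percentile intervals)."""

    n_boot: int = 5000
    ci_level: float = 0.95
    seed: int = 0
    unit: str = "tray"  # "tray" or "patient"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise DataError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise DataError("ci_level must be in (0, 1)")
        if self.unit not in ("tray", "patient"):
            raise DataError(f"unknown bootstrap unit {self.unit!r}")


def diary_to_grams(score: float, served_g: float) -> float:
    """Convert a diary score to grams: recorded proportion × served weight."""
    if score not in (0.0, 0.5, 1.0):
        raise DataError(f"diary score {score!r} not in {{0, 0.5, 1}}")
    if served_g < 0:
        raise DataError(f"negative served weight {served_g}")
    return float(score) * float(served_g)


def loa(bias_g: float, sd_signed_g: float) -> tuple[float, float]:
    """Bland–Altman 95% limits of agreement: bias ± 1.96·sd."""
    return bias_g - 1.96 * sd_signed_g, bias_g + 1.96 * sd_signed_g


def _pairs_arrays(pairs: Sequence[PairedIntake]) -> tuple[np.ndarray, np.ndarray, list]:
    gold = np.asarray([p.gold_g for p in pairs], dtype=float)
    est = np.asarray([p.estimate_g for p in pairs], dtype=float)
    pid = [p.patient_id for p in pairs]
    return gold, est, pid


def pairs_from_arrays(
    gold_g: Sequence[float],
    estimate_g: Sequence[float],
    method: str,
    tray_ids: Optional[Sequence[str]] = None,
    patient_ids: Optional[Sequence[str]] = None,
) -> list[PairedIntake]:
    gold = list(gold_g)
    est = list(estimate_g)
    if len(gold) != len(est):
        raise DataError("gold and estimate vectors must be aligned")
    tids = tray_ids if tray_ids is not None else [f"T{i:05d}" for i in range(len(gold))]
    pids = patient_ids if patient_ids is not None else [None] * len(gold)
    return [
        PairedIntake(tray_id=str(t), gold_g=g, estimate_g=e, method=method, patient_id=p)
        for t, g, e, p in zip(tids, gold, est, pids)
    ]


def _metrics_from_errors(gold: np.ndarray, est: np.ndarray) -> dict:
    e = est - gold
    n = e.size
    bias = float(e.mean())
    sd = float(e.std(ddof=1))
    rmse = float(np.sqrt((e**2).mean()))
    lo, hi = loa(bias, sd)
    pos = gold > 0
    n_zero = int((~pos).sum())
    if pos.sum() == 0:
        raise InsufficientDataError(
            "all gold weights are zero: P-metrics and MAPE undefined"
        )
    rel = np.abs(e[pos]) / gold[pos]
    return {
        "n": n,
        "bias_g": bias,
        "sd_signed_g": sd,
        "rmse_g": rmse,
        "loa_low_g": lo,
        "loa_high_g": hi,
        "p10": 100.0 * float((rel <= 0.10).mean()),
        "p15": 100.0 * float((rel <= 0.15).mean()),
        "p30": 100.0 * float((rel <= 0.30).mean()),
        "mae_g": float(np.abs(e).mean()),
        "mape_pct": 100.0 * float(rel.mean()),
        "n_gold_zero": n_zero,
    }


def agreement_metrics(
    pairs: Sequence[PairedIntake],
    nonzero_filter: str = "gold",
) -> AgreementMetrics:
    """Compute the full agreement statistic set.

    ``nonzero_filter="gold"`` (default) restricts the analysis to trays with
    non-zero weighed intake, matching the study population used for the
    diary comparison; ``"none"`` keeps all pairs for bias/SD/RMSE while
    P-metrics and MAPE always exclude zero-gold pairs (their denominator).
    """
    if nonzero_filter not in ("gold", "none"):
        raise DataError(f"unknown non-zero-intake filter {nonzero_filter!r}")
    gold, est, _ = _pairs_arrays(pairs)
    if nonzero_filter == "gold":
        keep = gold > 0
        gold, est = gold[keep], est[keep]
    if gold.size < 2:
        raise InsufficientDataError(
            f"need >= 2 pairs after filtering, got {gold.size}"
        )
    return AgreementMetrics(**_metrics_from_errors(gold, est))


# ---------------------------------------------------------------------------
# Bootstrap machinery

def _stat_bias(gold, est, axis=None):
    return np.mean(est - gold, axis=axis)


def _stat_sd(gold, est, axis=None):
    return np.std(est - gold, ddof=1, axis=axis)


def _stat_rmse(gold, est, axis=None):
    return np.sqrt(np.mean((est - gold) ** 2, axis=axis))


def _stat_mae(gold, est, axis=None):
    return np.mean(np.abs(est - gold), axis=axis)


def _rel_errors(gold, est):
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(gold > 0, np.abs(est - gold) / np.where(gold > 0, gold, 1.0), np.nan)
    return rel


def _nanmean(a, axis=None):
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN resamples → NaN
        return np.nanmean(a, axis=axis)


def _stat_p(tol):
    def f(gold, est, axis=None):
        rel = _rel_errors(gold, est)
        ok = (rel <= tol).astype(float)
        ok[np.isnan(rel)] = np.nan
        return 100.0 * _nanmean(ok, axis=axis)

    return f


def _stat_mape(gold, est, axis=None):
    return 100.0 * _nanmean(_rel_errors(gold, est), axis=axis)


def _stat_loa(side):
    def f(gold, est, axis=None):
        b = _stat_bias(gold, est, axis=axis)
        s = _stat_sd(gold, est, axis=axis)
        return b + side * 1.96 * s

    return f


#: Named bootstrap statistics with vectorised (axis-aware) implementations.
NAMED_STATISTICS: dict[str, Callable] = {
    "bias": _stat_bias,
    "sd": _stat_sd,
    "rmse": _stat_rmse,
    "mae": _stat_mae,
    "mape": _stat_mape,
    "p10": _stat_p(0.10),
    "p15": _stat_p(0.15),
    "p30": _stat_p(0.30),
    "loa_low": _stat_loa(-1.0),
    "loa_high": _stat_loa(+1.0),
}


@dataclass
class BootstrapResult:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int = 0


def _patient_resample_indices(pid: list, rng: np.random.Generator, n_boot: int):
    labels = [p if p is not None else "?" for p in pid]
    uniq = sorted(set(labels))
    groups = {u: np.flatnonzero(np.asarray(labels, dtype=object) == u) for u in uniq}
    for _ in range(n_boot):
        chosen = rng.integers(0, len(uniq), size=len(uniq))
        yield np.concatenate([groups[uniq[c]] for c in chosen])


def bootstrap_ci(
    pairs: Sequence[PairedIntake],
    statistic: Union[str, Callable],
    config: Optional[BootstrapConfig] = None,
    nonzero_filter: str = "gold",
) -> BootstrapResult:
    """Percentile bootstrap CI for a named or callable agreement statistic.

    Named statistics (see :data:`NAMED_STATISTICS`) use a vectorised
    resampling path; a callable receives ``(gold, est)`` arrays for each
    resample.  Resampling is by tray, or by whole patients when
    ``config.unit == "patient"`` and patient identifiers are present.
    Resamples on which the statistic is undefined (NaN) are dropped; if they
    exceed 10% of ``n_boot`` a :class:`DegenerateResampleError` is raised.
    """
    config = config or BootstrapConfig()
    gold, est, pid = _pairs_arrays(pairs)
    if nonzero_filter == "gold":
        keep = gold > 0
        gold, est = gold[keep], est[keep]
        pid = [p for p, k in zip(pid, keep) if k]
    n = gold.size
    if n < 2:
        raise InsufficientDataError("bootstrap needs >= 2 pairs after filtering")

    if isinstance(statistic, str):
        if statistic not in NAMED_STATISTICS:
            raise ValueError(
                f"unknown statistic {statistic!r}; known: {sorted(NAMED_STATISTICS)}"
            )
        name, fn, vectorized = statistic, NAMED_STATISTICS[statistic], True
    else:
        name, fn, vectorized = getattr(statistic, "__name__", "custom"), statistic, False

    point = float(fn(gold, est)) if not vectorized else float(fn(gold, est, axis=None))
    if np.isnan(point):
        raise InsufficientDataError(f"statistic {name!r} undefined on the full sample")

    rng = np.random.default_rng(config.seed)
    if config.unit == "patient":
        if all(p is None for p in pid):
            raise DataError("patient-unit bootstrap requested but no patient ids present")
        vals = []
        for idx in _patient_resample_indices(pid, rng, config.n_boot):
            g, e = gold[idx], est[idx]
            vals.append(fn(g, e, axis=None) if vectorized else fn(g, e))
        vals = np.asarray(vals, dtype=float)
    elif vectorized:
        vals = np.empty(config.n_boot)
        chunk = max(1, min(config.n_boot, 20_000_000 // max(n, 1)))
        done = 0
        while done < config.n_boot:
            m = min(chunk, config.n_boot - done)
            idx = rng.integers(0, n, size=(m, n))
            vals[done : done + m] = fn(gold[idx], est[idx], axis=1)
            done += m
    else:
        vals = np.asarray(
            [
                fn(gold[i], est[i])
                for i in (rng.integers(0, n, size=(config.n_boot, n)))
            ],
            dtype=float,
        )

    bad = int(np.isnan(vals).sum())
    if bad > 0.10 * config.n_boot:
        raise DegenerateResampleError(
            f"statistic {name!r} undefined on {bad}/{config.n_boot} resamples"
        )
    good = vals[~np.isnan(vals)]
    alpha = 1.0 - config.ci_level
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        statistic=name, point=point, ci_low=float(lo), ci_high=float(hi),
        n_boot=config.n_boot, n_degenerate=bad,
    )


@dataclass
class MethodComparison:
    """Side-by-side continuous agreement for two estimate streams."""

    nursing: Optional[AgreementMetrics]
    ai: Optional[AgreementMetrics]
    note: str = (
        "Confidence intervals resample trays and ignore within-patient "
        "correlation; they may be overly narrow when patients contribute "
        "multiple trays."
    )

    def to_dict(self) -> dict:
        return {
            "nursing": self.nursing.to_dict() if self.nursing else None,
            "ai": self.ai.to_dict() if self.ai else None,
            "note": self.note,
        }


def compare_methods(
    pairs_nursing: Optional[Sequence[PairedIntake]],
    pairs_ai: Optional[Sequence[PairedIntake]],
    config: Optional[BootstrapConfig] = None,
    ci_statistics: Sequence[str] = ("bias", "rmse", "p10", "p15", "p30"),
    nonzero_filter: str = "gold",
) -> MethodComparison:
    """Agreement-table comparison of nursing and AI streams vs weighing.

    Either stream may be absent (``None`` or empty), in which case its row
    is reported as missing.  When a :class:`BootstrapConfig` is supplied,
    percentile CIs are attached for *ci_statistics*.
    """

    def one(pairs):
        if pairs is None or len(pairs) == 0:
            return None
        m = agreement_metrics(pairs, nonzero_filter)
        if config is not None:
            for s in ci_statistics:
                r = bootstrap_ci(pairs, s, config, nonzero_filter)
                m.ci[s] = [r.ci_low, r.ci_high]
        return m

    return MethodComparison(nursing=one(pairs_nursing), ai=one(pairs_ai))
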