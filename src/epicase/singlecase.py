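"""Single-case versus control-group statistics.

Compares one observation (a patient's methylation M value at a probe, or
any scalar score) against a small group of controls. Three tests are
provided:

* ``ch_t_test`` — the Crawford-Howell test, which treats the control mean
  and SD as sample statistics rather than population parameters. Its
  statistic is ``t = (x* - x̄) / (s * sqrt((n+1)/n))`` on ``n-1`` degrees
  of freedom and it holds the nominal type-I error rate even for small
  control groups.
* ``os_t_test`` — the classical one-sample t-test with the case score
  treated as the hypothesised population mean,
  ``t = (x̄ - x*) / (s / sqrt(n))``. Anti-conservative for this use:
  its type-I error is inflated because the case score carries the full
  population variance that the test ignores.
* ``wb_t_test`` — the Weisberg outlier test,
  ``t = (x* - x̄) / (s * sqrt(n/(n-1)))`` on ``n-2`` degrees of freedom;
  slightly more conservative than Crawford-Howell.

Effect sizes use the case-controls index ``z_cc = (x - x̄)/s`` with
confidence limits obtained by inverting the noncentral t distribution:
the interval endpoints are the noncentrality parameters whose
distributions place the observed ``z_cc*sqrt(n)`` at the (1±confidence)/2
quantiles, rescaled by ``1/sqrt(n)``. The companion "abnormality"
percentage estimates what fraction of the control population would score
below the case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Method",
    "ControlSummary",
    "TTestResult",
    "EffectSize",
    "DegenerateControlsError",
    "InsufficientControlsError",
    "ch_t_test",
    "os_t_test",
    "wb_t_test",
    "effect_size",
    "effect_size_interval",
    "batch_single_case",
]


class Method(str, Enum):
    """Which single-case test to apply."""

    CH = "CH"  # Crawford-Howell
    OS = "OS"  # one-sample
    WB = "WB"  # Weisberg


class DegenerateControlsError(ValueError):
    """Controls have zero spread but the case differs from their mean."""


class InsufficientControlsError(ValueError):
    """Too few controls for the requested test."""


@dataclass(frozen=True)
class ControlSummary:
    """Mean, sample SD (n-1 denominator) and count of control scores."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientControlsError(
                f"need at least 2 controls, got n={self.n}"
            )
        if self.sd < 0:
            raise ValueError(f"standard deviation must be >= 0, got {self.sd}")

    @classmethod
    def from_scores(cls, scores: Iterable[float]) -> "ControlSummary":
        arr = np.asarray(list(scores), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise InsufficientControlsError(
                f"need at least 2 non-missing control scores, got {arr.size}"
            )
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


@dataclass(frozen=True)
class TTestResult:
    """A single-case test outcome for one probe/score.

    ``p_lower`` is P(T_df <= statistic) under the central Student t —
    the lower tail, which is the hypomethylation direction for CH and WB
    (for OS the sign convention is reversed). ``p_two_sided`` is
    ``2 * min(p_lower, p_upper)``.
    """

    method: Method
    statistic: float
    df: int
    p_lower: float
    p_upper: float
    p_two_sided: float
    n: int  # effective number of controls used

    @property
    def untestable(self) -> bool:
        return math.isnan(self.statistic)


def _tails(statistic: float, df: int) -> tuple[float, float, float]:
    p_lower = float(stats.t.cdf(statistic, df))
    p_upper = float(stats.t.sf(statistic, df))
    return p_lower, p_upper, 2.0 * min(p_lower, p_upper)


def _check_sd(case: float, controls: ControlSummary) -> float | None:
    """Return the statistic for the degenerate sd=0 branch, else None."""
    if controls.sd > 0:
        return None
    if case == controls.mean:
        return 0.0
    raise DegenerateControlsError(
        "control SD is 0 but the case score differs from the control mean "
        f"(case={case}, mean={controls.mean}): statistic is infinite"
    )


def ch_t_test(case: float, controls: ControlSummary) -> TTestResult:
    """Crawford-Howell t-test of one case score against a control group.

    ``t = (x* - x̄) / (s * sqrt((n+1)/n))`` on ``n-1`` df.
    """
    if not math.isfinite(case):
        raise ValueError(f"case score must be finite, got {case}")
    n = controls.n
    t = _check_sd(case, controls)
    if t is None:
        t = (case - controls.mean) / (controls.sd * math.sqrt((n + 1) / n))
    df = n - 1
    p_lo, p_up, p2 = _tails(t, df)
    return TTestResult(Method.CH, t, df, p_lo, p_up, p2, n)


def os_t_test(case: float, controls: ControlSummary) -> TTestResult:
    """One-sample t-test with the case score as hypothesised mean.

    ``t = (x̄ - x*) / (s / sqrt(n))`` on ``n-1`` df. Note the reversed
    sign convention relative to the other two tests: a low case score
    yields a *positive* statistic.
    """
    if not math.isfinite(case):
        raise ValueError(f"case score must be finite, got {case}")
    n = controls.n
    t = _check_sd(case, controls)
    if t is None:
        t = (controls.mean - case) / (controls.sd / math.sqrt(n))
    df = n - 1
    p_lo, p_up, p2 = _tails(t, df)
    return TTestResult(Method.OS, t, df, p_lo, p_up, p2, n)


def wb_t_test(case: float, controls: ControlSummary) -> TTestResult:
    """Weisberg outlier t-test. ``t = (x* - x̄)/(s*sqrt(n/(n-1)))`` on n-2 df."""
    if not math.isfinite(case):
        raise ValueError(f"case score must be finite, got {case}")
    n = controls.n
    if n < 3:
        raise InsufficientControlsError(
            f"Weisberg test needs n >= 3 controls (df = n-2), got n={n}"
        )
    t = _check_sd(case, controls)
    if t is None:
        t = (case - controls.mean) / (controls.sd * math.sqrt(n / (n - 1)))
    df = n - 2
    p_lo, p_up, p2 = _tails(t, df)
    return TTestResult(Method.WB, t, df, p_lo, p_up, p2, n)


_DISPATCH = {Method.CH: ch_t_test, Method.OS: os_t_test, Method.WB: wb_t_test}


def effect_size(case: float, controls: ControlSummary) -> float:
    """Case-controls effect-size index ``z_cc = (x - x̄) / s``."""
    if controls.sd == 0:
        raise DegenerateControlsError("control SD is 0: effect size undefined")
    return (case - controls.mean) / controls.sd


@dataclass(frozen=True)
class EffectSize:
    """z_cc with its noncentral-t confidence interval.

    ``pct_point`` is the estimated percentage of the control population
    expected to score below the case (100 times the lower-tail CH
    probability); ``pct_lower``/``pct_upper`` map the z-scale interval
    through the standard normal CDF.
    """

    z_cc: float
    ci_lower: float
    ci_upper: float
    pct_point: float
    pct_lower: float
    pct_upper: float
    confidence: float = 0.95


class RootFindingError(RuntimeError):
    """Noncentrality root-finding failed to bracket or converge."""


def _nct_cdf(w: float, df: int, delta: float) -> float:
    """Noncentral-t CDF with a far-tail guard.

    scipy can return NaN deep in the tails; there the Abramowitz-Stegun
    normal approximation P(T<=t) ~ Phi((t(1-1/(4df)) - delta)/sqrt(1+t^2/(2df)))
    is accurate to far more digits than the root tolerance needs.
    """
    v = float(stats.nct.cdf(w, df, delta))
    if math.isnan(v):
        z = (w * (1 - 1 / (4 * df)) - delta) / math.sqrt(1 + w * w / (2 * df))
        v = float(stats.norm.cdf(z))
    return v


def _nct_delta_root(w: float, df: int, q: float) -> float:
    """Solve ``nct.cdf(w; df, delta) == q`` for the noncentrality delta.

    The CDF is strictly decreasing in delta, so a sign change brackets the
    unique root; the bracket grows geometrically from [w-10, w+10].
    """

    def f(delta: float) -> float:
        return _nct_cdf(w, df, delta) - q

    lo, hi = w - 10.0, w + 10.0
    f_lo, f_hi = f(lo), f(hi)
    # decreasing in delta: want f(lo) > 0 > f(hi)
    for _ in range(60):
        if f_lo > 0 and f_hi < 0:
            break
        if f_lo <= 0:
            lo -= 2.0 * (hi - lo)
            f_lo = f(lo)
        if f_hi >= 0:
            hi += 2.0 * (hi - lo)
            f_hi = f(hi)
    else:
        raise RootFindingError(
            f"could not bracket noncentrality root: w={w}, df={df}, q={q}, "
            f"bracket=({lo}, {hi}), f=({f_lo}, {f_hi})"
        )
    try:
        root = optimize.brentq(f, lo, hi, rtol=1e-8, maxiter=200)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics
        raise RootFindingError(
            f"noncentrality root-finding failed for w={w}, df={df}, q={q}: {exc}"
        ) from exc
    return float(root)


def effect_size_interval(
    case: float, controls: ControlSummary, confidence: float = 0.95
) -> EffectSize:
    """z_cc with a noncentral-t confidence interval and abnormality percentage.

    With ``w = z_cc * sqrt(n)``, the lower limit is the noncentrality
    ``delta_L`` whose noncentral t distribution (n-1 df) has ``w`` as its
    (1+confidence)/2 quantile, divided by ``sqrt(n)``; the upper limit uses
    the (1-confidence)/2 quantile. For the textbook case (x*=0.4, x̄=0.5,
    s=0.1, n=10, 95%) this gives z_cc=-1.0 with limits (-1.751, -0.214).
    """
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0,1), got {confidence}")
    z = effect_size(case, controls)
    n = controls.n
    df = n - 1
    w = z * math.sqrt(n)
    delta_l = _nct_delta_root(w, df, (1 + confidence) / 2)
    delta_u = _nct_delta_root(w, df, (1 - confidence) / 2)
    ci_lower = delta_l / math.sqrt(n)
    ci_upper = delta_u / math.sqrt(n)
    pct_point = 100.0 * ch_t_test(case, controls).p_lower
    pct_lower = 100.0 * float(stats.norm.cdf(ci_lower))
    pct_upper = 100.0 * float(stats.norm.cdf(ci_upper))
    return EffectSize(z, ci_lower, ci_upper, pct_point, pct_lower, pct_upper, confidence)


def batch_single_case(
    case_scores: Sequence[float],
    control_matrix: np.ndarray,
    method: Method | str = Method.CH,
) -> list[TTestResult]:
    """Apply one single-case test to every row of a probes-by-controls matrix.

    Missing control values (NaN) are dropped per row and the effective n
    recorded on the result. Rows with fewer than 2 usable controls (3 for
    Weisberg), or with zero control spread, are returned as untestable
    results (NaN statistic) rather than dropped.
    """
    method = Method(method)
    cases = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_matrix, dtype=float)
    if ctrl.ndim != 2 or ctrl.shape[0] != cases.shape[0]:
        raise ValueError(
            f"control matrix shape {ctrl.shape} does not match "
            f"{cases.shape[0]} case scores"
        )
    min_n = 3 if method is Method.WB else 2
    out: list[TTestResult] = []
    test = _DISPATCH[method]
    for x, row in zip(cases, ctrl):
        usable = row[~np.isnan(row)]
        if usable.size < min_n:
            out.append(
                TTestResult(method, math.nan, max(usable.size - 1, 0),
                            math.nan, math.nan, math.nan, int(usable.size))
            )
            continue
        summary = ControlSummary.from_scores(usable)
        try:
            out.append(test(float(x), summary))
        except DegenerateControlsError:
            out.append(
                TTestResult(method, math.nan, summary.n - 1,
                            math.nan, math.nan, math.nan, summary.n)
            )
    return out
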