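"""Method-agreement statistics for sensor vs. manual measurements.

Paired sensor estimates x and manual measurements y are compared with a
battery of statistics: coefficient of determination r², RMSE, MAE, bias
(mean difference d̄ with d = x − y, so negative bias means the sensor
underestimates), the 95% paired-t confidence interval of the mean
difference, Lin's concordance correlation coefficient (CCC), and a
paired two-sided t-test.

Two conventions are worth flagging. First, r² here defaults to
1 − Σ(y−x)² / Σ(y−x̄)² with x̄ the mean of the *sensor* estimates;
``conventional=True`` uses the mean of the measured values, the textbook
regression form. Second, CCC uses population (1/n) variances, the
convention under which Lin's estimator is defined; ``sample_var=True``
switches to n−1 denominators.

The three error statistics are tied by an exact identity,

    RMSE² = d̄² + (n−1)/n · s_d²,

which :func:`build_report` asserts and which also lets a report be
reconstructed from printed summaries: given bias, t and n,
s_d = |d̄|·√n / |t| recovers the standard deviation of differences, from
which CI and RMSE follow (:func:`reconstruct_from_bias_t`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class PairedSample:
    """Sensor-estimated values x paired with manual measurements y."""

    x: np.ndarray
    y: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 2:
            raise ValueError("paired statistics need at least 2 pairs")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


def r_squared(pairs: PairedSample, conventional: bool = False) -> float:
    """1 − SSres/SStot with SSres = Σ(y − x)².

    The default denominator centers y on the mean of the sensor
    estimates x̄; ``conventional=True`` centers on the measured mean ȳ.
    """
    ss_res = float(np.sum((pairs.y - pairs.x) ** 2))
    center = pairs.y.mean() if conventional else pairs.x.mean()
    ss_tot = float(np.sum((pairs.y - center) ** 2))
    if ss_tot == 0:
        raise ZeroDivisionError("r_squared undefined: zero total sum of squares")
    return 1.0 - ss_res / ss_tot


def error_metrics(pairs: PairedSample) -> tuple[float, float, float, float]:
    """(RMSE, MAE, bias, s_d) of the differences d = x − y.

    s_d is the sample standard deviation (n−1 denominator).
    """
    d = pairs.differences
    rmse = float(np.sqrt(np.mean(d**2)))
    mae = float(np.mean(np.abs(d)))
    bias = float(np.mean(d))
    s_d = float(np.std(d, ddof=1))
    return rmse, mae, bias, s_d


def mean_difference_ci(pairs: PairedSample, confidence: float = 0.95) -> tuple[float, float]:
    """d̄ ± t*(1−α/2, n−1) · s_d/√n."""
    d = pairs.differences
    n = pairs.n
    d_bar = float(d.mean())
    s_d = float(np.std(d, ddof=1))
    t_star = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = t_star * s_d / np.sqrt(n)
    return d_bar - half, d_bar + half


def concordance_ccc(pairs: PairedSample, sample_var: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·ρ·σx·σy / (σx² + σy² + (µx − µy)²), population variances by
    default. Combines precision (Pearson ρ) with accuracy (distance of
    the means from the identity line); |CCC| ≤ |ρ| always.
    """
    x, y = pairs.x, pairs.y
    ddof = 1 if sample_var else 0
    sx = float(np.std(x, ddof=ddof))
    sy = float(np.std(y, ddof=ddof))
    if sx == 0 or sy == 0:
        raise ZeroDivisionError("CCC undefined for zero-variance input")
    rho = float(np.corrcoef(x, y)[0, 1])
    return 2.0 * rho * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2)


def paired_t_test(pairs: PairedSample) -> tuple[float, float, int]:
    """(t, two-sided p, df) for H0: mean difference = 0."""
    d = pairs.differences
    n = pairs.n
    s_d = float(np.std(d, ddof=1))
    if s_d == 0:
        raise ZeroDivisionError("paired t-test undefined for zero-variance differences")
    t = float(d.mean() / (s_d / np.sqrt(n)))
    p = two_sided_p(t, n - 1)
    return t, p, n - 1


def two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t."""
    return float(2.0 * stats.t.sf(abs(t), df=df))


@dataclass
class AgreementReport:
    """All paired agreement statistics for one metric (a summary-table row)."""

    n: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    r2: float
    rmse: float
    mae: float
    bias: float
    s_d: float
    ci: tuple[float, float]
    ccc: float
    t: float
    p: float
    units: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n": self.n, "mean_sensor": self.mean_x, "mean_measured": self.mean_y,
            "sd_sensor": self.sd_x, "sd_measured": self.sd_y,
            "r2": self.r2, "rmse": self.rmse, "mae": self.mae, "bias": self.bias,
            "sd_diff": self.s_d, "ci_lower": self.ci[0], "ci_upper": self.ci[1],
            "ccc": self.ccc, "t": self.t, "p": self.p, "units": self.units,
        }
        out.update(self.extras)
        return out

    def format_row(self) -> str:
        return (
            f"n={self.n}  mean sensor/measured = {self.mean_x:.2f}/{self.mean_y:.2f} "
            f"{self.units}\n"
            f"  r2={self.r2:.2f}  RMSE={self.rmse:.2f}  MAE={self.mae:.2f}  "
            f"bias={self.bias:.2f}  CI=({self.ci[0]:.2f}, {self.ci[1]:.2f})\n"
            f"  CCC={self.ccc:.2f}  t={self.t:.2f}  p={self.p:.4f}"
        )


def build_report(
    pairs: PairedSample,
    confidence: float = 0.95,
    conventional_r2: bool = False,
) -> AgreementReport:
    """Compute the full battery; asserts the RMSE/bias/s_d identity."""
    rmse, mae, bias, s_d = error_metrics(pairs)
    n = pairs.n
    identity = bias**2 + (n - 1) / n * s_d**2
    assert abs(rmse**2 - identity) <= 1e-12 * max(1.0, rmse**2), "RMSE identity violated"
    try:
        r2 = r_squared(pairs, conventional=conventional_r2)
    except ZeroDivisionError:
        r2 = float("nan")
    try:
        ccc = concordance_ccc(pairs)
    except ZeroDivisionError:
        ccc = float("nan")
    if s_d > 0:
        t, p, _ = paired_t_test(pairs)
    else:
        t, p = float("nan"), float("nan")
    return AgreementReport(
        n=n,
        mean_x=float(pairs.x.mean()), mean_y=float(pairs.y.mean()),
        sd_x=float(np.std(pairs.x, ddof=1)), sd_y=float(np.std(pairs.y, ddof=1)),
        r2=r2, rmse=rmse, mae=mae, bias=bias, s_d=s_d,
        ci=mean_difference_ci(pairs, confidence), ccc=ccc, t=t, p=p,
        units=pairs.units,
    )


def reconstruct_from_bias_t(
    bias: float, t: float, n: int, confidence: float = 0.95
) -> dict[str, float]:
    """Recover s_d, CI and RMSE from a printed (bias, t, n) summary.

    Inverts t = d̄/(s_d/√n) to s_d = |d̄|·√n/|t|, then applies the CI
    formula and the identity RMSE² = d̄² + (n−1)/n·s_d². Useful for
    auditing published summary tables for internal consistency.
    """
    if t == 0:
        raise ZeroDivisionError("cannot reconstruct s_d from t = 0")
    s_d = abs(bias) * np.sqrt(n) / abs(t)
    t_star = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = t_star * s_d / np.sqrt(n)
    rmse = float(np.sqrt(bias**2 + (n - 1) / n * s_d**2))
    return {
        "s_d": float(s_d),
        "ci_lower": float(bias - half),
        "ci_upper": float(bias + half),
        "rmse": rmse,
    }
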