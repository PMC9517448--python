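"""Box-Cox normalization, standardization and the normality screen.

Maximum-likelihood covariance-structure estimation assumes multivariate
normality, but policy-adoption shares and financial indicators at the
prefecture level are right-skewed, sometimes severely.  Each candidate
variable is therefore (1) shifted to the positive half-line if needed,
(2) Box-Cox transformed at the profile-ML exponent, (3) tested for
approximate normality, and (4) z-standardized.  Variables that cannot be
brought to approximate normality — typically those with a large point
mass at 0% or 100% adoption — are excluded from modeling, with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data_model import RegionTable

__all__ = [
    "TransformResult",
    "box_cox",
    "estimate_lambda",
    "standardize",
    "normality_screen",
    "prepare_analysis_table",
]

#: shift target for variables containing zeros or negatives: the minimum
#: is moved to this value before the power transform
SHIFT_EPS = 1e-6

#: search interval for the Box-Cox exponent
LAMBDA_RANGE = (-3.0, 3.0)

#: Shapiro-Wilk significance level of the post-transform normality test
ALPHA = 0.05

#: a variable whose modal value holds more than this fraction of
#: observations is rejected outright (no power transform can spread a
#: point mass)
POINT_MASS_FRACTION = 0.30


@dataclass
class TransformResult:
    """Outcome of shifting, Box-Cox transforming and standardizing one
    variable, or the reason it was excluded."""

    variable_name: str
    lam: float | None
    shift: float
    values: np.ndarray | None
    mean_used: float | None
    sd_used: float | None
    passed: bool
    reason: str = ""


def box_cox(values: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox power transform: (x**lam - 1)/lam, with the log limit at
    lam = 0 (scipy's implementation is continuous in lam)."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; shift the variable first"
        )
    return special.boxcox(x, lam)


def estimate_lambda(values: np.ndarray) -> float:
    """Profile-ML Box-Cox exponent on [-3, 3].

    A 0.05-step grid locates the basin, then bounded golden-section /
    parabolic refinement polishes it.  Deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to estimate lambda")
    if np.any(x <= 0):
        raise ValueError("estimate_lambda requires strictly positive values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: Box-Cox exponent undefined")
    lo, hi = LAMBDA_RANGE
    grid = np.arange(lo, hi + 1e-12, 0.05)
    llf = np.array([stats.boxcox_llf(l, x) for l in grid])
    k = int(np.argmax(llf))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sd 1 (n - 1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def _shift_for(x: np.ndarray) -> float:
    mn = float(np.min(x))
    return SHIFT_EPS - mn if mn <= 0 else 0.0


def normality_screen(values: np.ndarray, name: str = "") -> TransformResult:
    """Shift, transform at the ML exponent, and test normality.

    Fails hard when the modal value's frequency exceeds
    ``POINT_MASS_FRACTION`` (a point mass survives any monotone
    transform) or when the Shapiro-Wilk test rejects at ``ALPHA`` after
    the best Box-Cox transform.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to screen")

    def failed(reason: str) -> TransformResult:
        return TransformResult(name, None, 0.0, None, None, None, False, reason)

    if np.ptp(x) == 0:
        return failed("constant variable")
    _, counts = np.unique(x, return_counts=True)
    modal_frac = counts.max() / x.size
    if modal_frac > POINT_MASS_FRACTION:
        return failed(
            f"point mass: modal value holds {100 * modal_frac:.0f}% of observations"
        )
    shift = _shift_for(x)
    lam = estimate_lambda(x + shift)
    t = box_cox(x + shift, lam)
    sw_p = float(stats.shapiro(t).pvalue)
    if sw_p < ALPHA:
        return failed(
            f"not normalizable: Shapiro-Wilk p = {sw_p:.4f} after "
            f"Box-Cox (lambda = {lam:.2f})"
        )
    mean, sd = float(t.mean()), float(t.std(ddof=1))
    z = standardize(t)
    return TransformResult(name, float(lam), shift, z, mean, sd, True)


def prepare_analysis_table(
    table: RegionTable,
    variables: list[str],
    required_groups: dict[str, list[str]] | None = None,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Build the n x k modeling matrix from a stratum table.

    Each requested variable is screened with :func:`normality_screen`;
    kept columns are the shifted, Box-Cox-transformed, standardized
    values in the original request order, dropped ones are reported as
    ``(name, reason)`` pairs.  ``required_groups`` maps a latent factor to
    its candidate indicators; losing *all* indicators of any group is an
    error because the downstream model would be unidentifiable.
    """
    kept: list[str] = []
    cols: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for name in variables:
        raw = table.variable(name).to_numpy(dtype=float)
        res = normality_screen(raw, name)
        if res.passed:
            kept.append(name)
            cols.append(res.values)
        else:
            dropped.append((name, res.reason))
    if required_groups:
        for latent, members in required_groups.items():
            if members and not any(m in kept for m in members):
                raise ValueError(
                    f"all candidate indicators of latent {latent!r} were "
                    f"excluded by the normality screen: {dict(dropped)}"
                )
    matrix = np.column_stack(cols) if cols else np.empty((table.n, 0))
    return matrix, kept, dropped
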