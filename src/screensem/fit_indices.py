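"""Chi-square model test and descriptive fit indices.

The model-fit statistic is ``T = n * F_ML`` with ``n`` the number of
areal units; the same ``n`` enters the RMSEA denominator.  Seven indices
are always reported (GFI, AGFI, PGFI, SRMR, CFI, RMSEA and the chi-square
p-value), but only four gate acceptance — a model is acceptable when

    p(chi^2) > 0.05,  RMSEA < 0.10,  SRMR < 0.10,  CFI > 0.90

all hold (strict inequalities).  GFI and AGFI are sensitive to sample
size and are reported for completeness only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sem import FitResult, ModelError, ml_discrepancy

__all__ = [
    "FitIndexReport",
    "chi_square_statistic",
    "rmsea",
    "srmr",
    "gfi_family",
    "baseline_model",
    "cfi",
    "evaluate_acceptance",
    "index_report",
    "report_from_statistics",
]

P_CUTOFF = 0.05
RMSEA_CUTOFF = 0.10
SRMR_CUTOFF = 0.10
CFI_CUTOFF = 0.90


@dataclass
class FitIndexReport:
    """Indices for one fitted model plus the four acceptance booleans."""

    chi_square: float
    df: int
    p_value: float
    gfi: float
    agfi: float
    pgfi: float
    srmr: float
    cfi: float
    rmsea: float
    baseline_chi_square: float
    baseline_df: int
    n: int
    p_ok: bool = False
    rmsea_ok: bool = False
    srmr_ok: bool = False
    cfi_ok: bool = False
    accepted: bool = False

    def __post_init__(self) -> None:
        self.chi_square = float(self.chi_square)
        self.p_value = float(self.p_value)
        self.p_ok = bool(self.p_value > P_CUTOFF)
        self.rmsea_ok = bool(self.rmsea < RMSEA_CUTOFF)
        self.srmr_ok = bool(self.srmr < SRMR_CUTOFF)
        self.cfi_ok = bool(self.cfi > CFI_CUTOFF)
        self.accepted = self.p_ok and self.rmsea_ok and self.srmr_ok and self.cfi_ok

    def to_dict(self) -> dict:
        return {
            "chi_square": round(float(self.chi_square), 3),
            "df": int(self.df),
            "p_value": round(float(self.p_value), 3),
            "gfi": round(float(self.gfi), 3),
            "agfi": round(float(self.agfi), 3),
            "pgfi": round(float(self.pgfi), 3),
            "srmr": round(float(self.srmr), 3),
            "cfi": round(float(self.cfi), 3),
            "rmsea": round(float(self.rmsea), 3),
            "baseline_chi_square": round(float(self.baseline_chi_square), 3),
            "baseline_df": int(self.baseline_df),
            "n": int(self.n),
            "criteria": {
                "p_gt_0.05": self.p_ok,
                "rmsea_lt_0.10": self.rmsea_ok,
                "srmr_lt_0.10": self.srmr_ok,
                "cfi_gt_0.90": self.cfi_ok,
            },
            "accepted": self.accepted,
        }


def chi_square_statistic(F: float, n: int, df: int) -> tuple[float, float]:
    """(T, p): T = n*F referred to a chi-square with ``df`` degrees of
    freedom.  A saturated model (df = 0) returns p = 1 by convention."""
    if df < 0:
        raise ModelError("negative degrees of freedom")
    if F < 0:
        raise ModelError("negative discrepancy")
    T = n * F
    if df == 0:
        return T, 1.0
    return T, float(stats.chi2.sf(T, df))


def rmsea(T: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(0, (T - df) / (df * n))); zero whenever T <= df."""
    if df <= 0:
        raise ModelError("RMSEA undefined for df <= 0")
    if n <= 1:
        raise ModelError("RMSEA requires n > 1")
    return float(np.sqrt(max(0.0, (T - df) / (df * n))))


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean square residual over the p(p+1)/2 unique
    cells of the correlation-metric difference between S and Sigma."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise ModelError("dimension mismatch between S and Sigma")
    ds = np.sqrt(np.diag(S))
    dsig = np.sqrt(np.diag(Sigma))
    if np.any(ds <= 0) or np.any(dsig <= 0):
        raise ModelError("non-positive diagonal entries")
    Rs = S / np.outer(ds, ds)
    Rsig = Sigma / np.outer(dsig, dsig)
    iu = np.triu_indices(S.shape[0])
    resid = (Rs - Rsig)[iu]
    return float(np.sqrt(np.mean(resid**2)))


def gfi_family(
    S: np.ndarray, Sigma: np.ndarray, df: int
) -> tuple[float, float, float]:
    """(GFI, AGFI, PGFI).

    GFI = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]; AGFI adjusts
    for df, PGFI weights GFI by the parsimony ratio 2 df / (p (p+1)).
    AGFI/PGFI are NaN at df = 0.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    ratio = np.linalg.solve(Sigma, S)
    num = np.trace((ratio - np.eye(p)) @ (ratio - np.eye(p)))
    den = np.trace(ratio @ ratio)
    gfi = float(1.0 - num / den)
    if df <= 0:
        return gfi, float("nan"), float("nan")
    c = p * (p + 1) / 2.0
    agfi = float(1.0 - (c / df) * (1.0 - gfi))
    pgfi = float((df / c) * gfi)
    return gfi, agfi, pgfi


def baseline_model(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model statistic: Sigma_b = diag(S), so
    T_b = n * F(S, diag S) = -n ln|R|, with df_b = p(p-1)/2."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    T_b = n * ml_discrepancy(S, np.diag(np.diag(S)))
    return float(T_b), p * (p - 1) // 2


def cfi(T: float, df: int, T_b: float, df_b: int) -> float:
    """Comparative fit index relative to the independence baseline,
    clipped to [0, 1]; 1 whenever T <= df."""
    if df_b < df:
        raise ModelError("baseline df must be at least the model df")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def evaluate_acceptance(report: FitIndexReport) -> bool:
    """Four-criterion acceptance rule (conjunction, strict cutoffs)."""
    return (
        report.p_value > P_CUTOFF
        and report.rmsea < RMSEA_CUTOFF
        and report.srmr < SRMR_CUTOFF
        and report.cfi > CFI_CUTOFF
    )


def index_report(result: FitResult) -> FitIndexReport:
    """Full index battery for a fitted model."""
    T, p_val = chi_square_statistic(result.discrepancy, result.n, result.df)
    T_b, df_b = baseline_model(result.sample_cov, result.n)
    gfi, agfi, pgfi = gfi_family(result.sample_cov, result.implied_cov, result.df)
    return FitIndexReport(
        chi_square=T,
        df=result.df,
        p_value=p_val,
        gfi=gfi,
        agfi=agfi,
        pgfi=pgfi,
        srmr=srmr(result.sample_cov, result.implied_cov),
        cfi=cfi(T, result.df, T_b, df_b),
        rmsea=rmsea(T, result.df, result.n) if result.df > 0 else 0.0,
        baseline_chi_square=T_b,
        baseline_df=df_b,
        n=result.n,
    )


def report_from_statistics(
    chi_square: float,
    df: int,
    n: int,
    *,
    srmr_value: float,
    cfi_value: float,
    gfi: float = float("nan"),
    agfi: float = float("nan"),
    pgfi: float = float("nan"),
) -> FitIndexReport:
    """Build a report from printed summary statistics (chi-square, df,
    SRMR, CFI) rather than a fitted model — the p-value and RMSEA are
    recomputed from chi-square, df and n."""
    _, p_val = chi_square_statistic(chi_square / n, n, df)
    return FitIndexReport(
        chi_square=chi_square,
        df=df,
        p_value=p_val,
        gfi=gfi,
        agfi=agfi,
        pgfi=pgfi,
        srmr=srmr_value,
        cfi=cfi_value,
        rmsea=rmsea(chi_square, df, n) if df > 0 else 0.0,
        baseline_chi_square=float("nan"),
        baseline_df=df,
        n=n,
    )
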