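"""Small quantitative models: one-site binding fits and metabolomics QC.

Fluorescence polarization titrations are fit with the one-site specific
binding law FP(c) = fp0 + (fpmax - fp0) * c / (Kd + c); Kd is the protein
concentration at half-saturation (nM). Metabolite feature tables pass through
probabilistic quotient normalization (PQN: divide each sample by the median
feature-wise ratio to a reference spectrum, removing dilution), a QC
coefficient-of-variation filter (keep CV < 25% across QC injections), and a
volcano selection (|log2 fold change| >= 0.4 and Welch two-sample t-test
p < 0.05 between knockdown and control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FPFit",
    "fp_one_site",
    "fit_fp",
    "pqn_normalize",
    "qc_cv_filter",
    "volcano_select",
    "pca_scores",
]


# ---------------------------------------------------------------------------
# fluorescence polarization


def fp_one_site(conc, kd: float, fp0: float, fpmax: float):
    """One-site specific binding law; ``conc`` in the same units as ``kd``."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return fp0 + (fpmax - fp0) * c / (kd + c)


@dataclass
class FPFit:
    kd: float
    fp0: float
    fpmax: float
    residual_sse: float
    kd_ci: tuple[float, float] | None
    n_points: int


def _fit_once(conc: np.ndarray, fp: np.ndarray) -> tuple[float, float, float]:
    fp0_init = float(fp.min())
    fpmax_init = float(fp.max())
    mid = fp0_init + 0.5 * (fpmax_init - fp0_init)
    pos = conc[conc > 0]
    kd_init = float(pos[np.argmin(np.abs(fp[conc > 0] - mid))]) if pos.size else 1.0
    popt, _ = optimize.curve_fit(
        lambda c, kd, fp0, fpmax: fp0 + (fpmax - fp0) * c / (kd + c),
        conc,
        fp,
        p0=[max(kd_init, 1e-6), fp0_init, fpmax_init],
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_fp(
    concentrations: Sequence[float],
    fp_values: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> FPFit:
    """Nonlinear least-squares fit of the one-site law to a titration.

    Initialization: fp0 from the minimum reading, fpmax from the maximum, Kd
    from the concentration nearest mid-saturation; Kd is bounded positive.
    The 95% Kd interval comes from case-resampling bootstrap (percentile,
    ``n_boot`` resamples; pass 0 to skip).
    """
    conc = np.asarray(concentrations, dtype=float)
    fp = np.asarray(fp_values, dtype=float)
    if conc.shape != fp.shape:
        raise ValueError("concentrations and fp_values must have equal length")
    if conc.size < 5:
        raise ValueError("need at least 5 titration points")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if np.ptp(fp) == 0:
        raise ValueError("degenerate flat titration: no binding signal to fit")

    kd, fp0, fpmax = _fit_once(conc, fp)
    sse = float(np.sum((fp_one_site(conc, kd, fp0, fpmax) - fp) ** 2))

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        kds = []
        for _ in range(n_boot):
            idx = rng.integers(0, conc.size, conc.size)
            if np.ptp(fp[idx]) == 0 or np.ptp(conc[idx]) == 0:
                continue
            try:
                kds.append(_fit_once(conc[idx], fp[idx])[0])
            except RuntimeError:  # non-converged resample
                continue
        if len(kds) >= max(10, n_boot // 10):
            ci = tuple(np.percentile(kds, [2.5, 97.5]).tolist())
    return FPFit(kd=kd, fp0=fp0, fpmax=fpmax, residual_sse=sse, kd_ci=ci, n_points=conc.size)


# ---------------------------------------------------------------------------
# metabolomics

QC_ROLE = "QC"


def _role_columns(roles: Mapping[str, str], role: str) -> list[str]:
    return [s for s, r in roles.items() if r == role]


def pqn_normalize(
    table: pd.DataFrame,
    roles: Mapping[str, str],
    reference: str = "median_of_QC",
) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization of a feature x sample table.

    The reference spectrum is the feature-wise median over QC samples (or
    over all samples with ``reference='median_of_all'``). Each sample's
    quotient is the median over features of sample/reference, excluding
    features where either value is zero or missing; the sample is divided by
    its quotient. Returns (normalized table, quotients).
    """
    if (table.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative intensities")
    if reference == "median_of_QC":
        ref_cols = _role_columns(roles, QC_ROLE)
        if not ref_cols:
            raise ValueError("no QC samples for the median_of_QC reference")
    elif reference == "median_of_all":
        ref_cols = list(table.columns)
    else:
        raise ValueError("reference must be 'median_of_QC' or 'median_of_all'")
    ref = table[ref_cols].median(axis=1)

    quotients = {}
    for col in table.columns:
        ratio = table[col] / ref
        ratio = ratio[(table[col] > 0) & (ref > 0)].replace([np.inf, -np.inf], np.nan).dropna()
        if ratio.empty:
            raise ValueError(f"no valid features to compute a quotient for sample {col}")
        quotients[col] = float(ratio.median())
    q = pd.Series(quotients)
    return table / q, q


def qc_cv_filter(
    table: pd.DataFrame,
    roles: Mapping[str, str],
    max_cv: float = 0.25,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep features whose QC coefficient of variation (sd/mean, ddof=1) is
    strictly below ``max_cv``; returns (filtered table, dropped features).
    Zero-mean features are dropped with a warning."""
    qc_cols = _role_columns(roles, QC_ROLE)
    if len(qc_cols) < 2:
        raise ValueError("need at least 2 QC samples for CV filtering")
    qc = table[qc_cols]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    zero_mean = mean == 0
    if zero_mean.any():
        warnings.warn(f"{int(zero_mean.sum())} zero-mean features dropped", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (~zero_mean) & (cv < max_cv)
    return table.loc[keep], table.index[~keep].tolist()


def volcano_select(
    table: pd.DataFrame,
    roles: Mapping[str, str],
    fc_threshold: float = 0.4,
    alpha: float = 0.05,
    case_role: str = "knockdown",
    control_role: str = "control",
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Volcano selection: effect-size gate AND Welch t-test significance.

    ``fc_scale='log2'`` (default) reads the 0.4 threshold on the log2 scale:
    selected iff |log2FC| >= fc_threshold and p < alpha, with log2FC the
    difference of group means of log2 intensities. ``fc_scale='linear'``
    reads it as a linear fold change bound: max(FC, 1/FC) >= 1 + fc_threshold
    on group means of raw intensities.
    """
    case_cols = _role_columns(roles, case_role)
    ctrl_cols = _role_columns(roles, control_role)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    case = table[case_cols].to_numpy(dtype=float)
    ctrl = table[ctrl_cols].to_numpy(dtype=float)

    if fc_scale == "log2":
        lc, lt = np.log2(case), np.log2(ctrl)
        log2fc = lc.mean(axis=1) - lt.mean(axis=1)
        _, p = stats.ttest_ind(lc, lt, axis=1, equal_var=False)
        gate = np.abs(log2fc) >= fc_threshold
    elif fc_scale == "linear":
        fc = case.mean(axis=1) / ctrl.mean(axis=1)
        log2fc = np.log2(fc)
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        gate = np.maximum(fc, 1 / fc) >= 1 + fc_threshold
    else:
        raise ValueError("fc_scale must be 'log2' or 'linear'")

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_p": p,
            "selected": gate & (p < alpha),
        },
        index=table.index,
    )


def pca_scores(table: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Descriptive PCA score matrix (samples x components) of the
    feature-standardized table, via SVD; for plotting only."""
    x = np.log2(table.to_numpy(dtype=float).T + 1e-12)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        scores, index=table.columns, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )
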