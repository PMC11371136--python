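"""Kinetics of the gravitropic re-bending response and derived traits.

After a 90-degree tilt the root tip direction (RTD) relaxes toward a
treatment-dependent asymptote.  The default temporal model is an
exponential decay

    y(t) = y0 + L * exp(-k * t)

where ``y0`` is the lower asymptote, ``L`` the initial decrease from the
starting value ``y0 + L`` to the asymptote, and ``k`` (1/h) the decay
rate.  A logistic variant ``y0 + L / (1 + exp(k * (t - t0)))`` is
available for trajectories with a lag phase.

Derived salt-response traits used as association inputs:

* ``K_ratio``  — k under NaCl divided by k under control (K^N/C),
* ``rtd_diff`` — RTD under NaCl minus under control at 5 h (RTD^N-C),
* ``rva_diff`` — RVA under NaCl minus under control at 23 h (RVA^N-C).

Broad-sense heritability is estimated from one-way ANOVA mean squares
across replicated accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DecayFit",
    "ResponseTraits",
    "PhaseSummary",
    "HeritabilityResult",
    "fit_decay",
    "response_traits",
    "phase_means",
    "broad_sense_heritability",
    "heritability_from_mean_squares",
]


@dataclass
class DecayFit:
    """Fitted decay-model parameters and diagnostics."""

    y0: float            # degrees, lower asymptote
    L: float             # degrees, initial decrease to the asymptote
    k: float             # 1/h, decay rate
    t0: float = math.nan  # h, inflection (logistic variant only)
    rss: float = math.nan
    k_se: float = math.nan  # asymptotic SE of k from the fit Jacobian
    converged: bool = True
    identifiable: bool = True
    reason: str = ""
    variant: str = "EXP"

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.variant == "EXP":
            return self.y0 + self.L * np.exp(-self.k * t)
        return self.y0 + self.L / (1.0 + np.exp(self.k * (t - self.t0)))


@dataclass
class ResponseTraits:
    K_ratio: float
    k_diff: float            # k_salt - k_ctrl, robust companion to the ratio
    rtd_diff_deg: float
    rva_diff_deg: float
    K_ratio_defined: bool = True
    rtd_diff_defined: bool = True
    rva_diff_defined: bool = True


@dataclass
class PhaseSummary:
    """Mean and least-squares slope of a trait within each response phase.

    Phase I (0-10 h) is the acceleration stage, Phase II (10-20 h) the
    steady re-bending stage, Phase III (>20 h) stabilization.  Boundaries
    are closed on both sides, so a frame exactly on a boundary counts in
    both adjacent phases.
    """

    means: dict[str, float]
    slopes: dict[str, float]
    boundaries_h: tuple[float, float]


@dataclass
class HeritabilityResult:
    H2: float
    sigma2_g: float
    sigma2_e: float
    ms_genotype: float
    ms_error: float
    r_bar: float   # harmonic-mean replicate count


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    y0, L, k = params
    return y0 + L * np.exp(-k * t)


def _logistic_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    y0, L, k, t0 = params
    z = np.clip(k * (t - t0), -500, 500)
    return y0 + L / (1.0 + np.exp(z))


def fit_decay(times: np.ndarray, angles: np.ndarray,
              variant: str = "EXP") -> DecayFit:
    """Nonlinear least-squares fit of the decay model to an angle series.

    Requires >= 4 finite points (>= 5 for the logistic variant) and
    non-decreasing times.  An all-constant series is flagged
    non-identifiable (L = 0, k = 0) rather than fitted.
    """
    if variant not in ("EXP", "LOGISTIC"):
        raise ValueError(f"unknown variant {variant!r}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(angles, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    min_pts = 4 if variant == "EXP" else 5
    if len(t) < min_pts:
        raise ValueError(f"need >= {min_pts} finite points for {variant}")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")

    if np.ptp(y) < 1e-12:
        return DecayFit(y0=float(y[0]), L=0.0, k=0.0, rss=0.0,
                        converged=True, identifiable=False,
                        reason="constant_series", variant=variant)

    # initialization: asymptote from the low end, rate from a log-linear fit
    y0_init = float(np.min(y))
    L_init = float(y[0] - y0_init)
    eps = 0.5
    resid0 = np.maximum(y - y0_init, eps)
    slope = np.polyfit(t, np.log(resid0), 1)[0]
    k_init = float(np.clip(-slope, 1e-3, 10.0))
    span = float(np.ptp(y))

    if variant == "EXP":
        x0 = np.array([y0_init, max(L_init, 1e-3), k_init])
        lo = [y0_init - 2 * span - 1.0, -4 * span - 1.0, 0.0]
        hi = [y0_init + 2 * span + 1.0, 4 * span + 1.0, 50.0]
        fun = lambda p: _exp_model(p, t) - y
    else:
        t0_init = float(t[len(t) // 3])
        x0 = np.array([y0_init, max(L_init, 1e-3), k_init, t0_init])
        lo = [y0_init - 2 * span - 1.0, -4 * span - 1.0, 0.0, t[0] - (t[-1] - t[0])]
        hi = [y0_init + 2 * span + 1.0, 4 * span + 1.0, 50.0, t[-1] + (t[-1] - t[0])]
        fun = lambda p: _logistic_model(p, t) - y

    sol = least_squares(fun, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12, max_nfev=500 * len(x0))
    rss = float(np.sum(sol.fun ** 2))
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    if rss > flat_rss + 1e-9:  # never do worse than the flat model
        return DecayFit(y0=float(y.mean()), L=0.0, k=0.0, rss=flat_rss,
                        converged=False, identifiable=False,
                        reason="fit_worse_than_flat", variant=variant)
    if variant == "EXP":
        y0_hat, L_hat, k_hat = sol.x
        t0_hat = math.nan
        k_idx = 2
    else:
        y0_hat, L_hat, k_hat, t0_hat = sol.x
        k_idx = 2
    k_se = math.nan
    dof = len(t) - len(sol.x)
    if dof > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
            k_se = float(math.sqrt(max(cov[k_idx, k_idx], 0.0)))
        except np.linalg.LinAlgError:
            pass
    return DecayFit(y0=float(y0_hat), L=float(L_hat), k=float(k_hat),
                    t0=float(t0_hat), rss=rss, k_se=k_se,
                    converged=bool(sol.success),
                    identifiable=True, variant=variant)


def _trait_at(table: pd.DataFrame, column: str, t_eval: float,
              tol_h: float = 1.0 / 6.0) -> float:
    """Trait value at the frame nearest ``t_eval`` within ``tol_h``."""
    times = table["time_h"].to_numpy(dtype=float)
    i = int(np.argmin(np.abs(times - t_eval)))
    if abs(times[i] - t_eval) > tol_h + 1e-12:
        raise KeyError(f"no frame within {tol_h:g} h of t={t_eval:g} h")
    return float(table[column].iloc[i])


def response_traits(fit_salt: DecayFit, fit_ctrl: DecayFit,
                    table_salt: pd.DataFrame, table_ctrl: pd.DataFrame,
                    t_eval_rtd: float = 5.0, t_eval_rva: float = 23.0,
                    tol_h: float = 1.0 / 6.0) -> ResponseTraits:
    """Salt-response traits from paired NaCl/control fits and tables.

    ``K_ratio = k_salt / k_ctrl`` is flagged undefined when the control
    rate is numerically zero; the angle differences are taken at the raw
    frames nearest the evaluation times (default 5 h for RTD, 23 h for
    RVA), within a +/-10 min lookup tolerance.
    """
    k_ratio_defined = fit_ctrl.k >= 1e-6
    K_ratio = fit_salt.k / fit_ctrl.k if k_ratio_defined else math.nan
    k_diff = fit_salt.k - fit_ctrl.k

    def diff(column: str, t_eval: float) -> tuple[float, bool]:
        try:
            s = _trait_at(table_salt, column, t_eval, tol_h)
            c = _trait_at(table_ctrl, column, t_eval, tol_h)
        except KeyError:
            return math.nan, False
        if not (math.isfinite(s) and math.isfinite(c)):
            return math.nan, False
        return s - c, True

    rtd_diff, rtd_ok = diff("rtd_deg", t_eval_rtd)
    rva_diff, rva_ok = diff("rva_deg", t_eval_rva)
    return ResponseTraits(K_ratio=K_ratio, k_diff=k_diff,
                          rtd_diff_deg=rtd_diff, rva_diff_deg=rva_diff,
                          K_ratio_defined=k_ratio_defined,
                          rtd_diff_defined=rtd_ok, rva_diff_defined=rva_ok)


def phase_means(table: pd.DataFrame, trait: str,
                boundaries_h: tuple[float, float] = (10.0, 20.0)
                ) -> PhaseSummary:
    """Per-phase mean and least-squares slope of a trait column."""
    b1, b2 = boundaries_h
    t = table["time_h"].to_numpy(dtype=float)
    y = table[trait].to_numpy(dtype=float)
    windows = {
        "I": (t >= 0.0) & (t <= b1),
        "II": (t >= b1) & (t <= b2),
        "III": t >= b2,
    }
    means, slopes = {}, {}
    for name, mask in windows.items():
        mask = mask & np.isfinite(y)
        if not mask.any():
            raise ValueError(f"empty phase window {name}")
        means[name] = float(y[mask].mean())
        if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
            slopes[name] = float(np.polyfit(t[mask], y[mask], 1)[0])
        else:
            slopes[name] = math.nan
    return PhaseSummary(means=means, slopes=slopes, boundaries_h=boundaries_h)


def heritability_from_mean_squares(ms_g: float, ms_e: float,
                                   r_bar: float) -> HeritabilityResult:
    """H^2 directly from ANOVA mean squares and a replicate count."""
    if r_bar <= 0:
        raise ValueError("replicate count must be positive")
    sigma2_g = max(0.0, (ms_g - ms_e) / r_bar)
    denom = sigma2_g + ms_e
    h2 = sigma2_g / denom if denom > 0 else 1.0
    return HeritabilityResult(H2=float(np.clip(h2, 0.0, 1.0)),
                              sigma2_g=sigma2_g, sigma2_e=ms_e,
                              ms_genotype=ms_g, ms_error=ms_e,
                              r_bar=float(r_bar))


def broad_sense_heritability(values: pd.DataFrame,
                             accession_col: str = "accession_id",
                             value_col: str = "value") -> HeritabilityResult:
    """Broad-sense heritability H^2 from one-way ANOVA mean squares.

    With genotype mean square MS_g, error mean square MS_e and
    harmonic-mean replicate count r_bar:

        sigma2_g = max(0, (MS_g - MS_e) / r_bar)
        sigma2_e = MS_e
        H^2 = sigma2_g / (sigma2_g + sigma2_e), clipped to [0, 1].

    Requires >= 2 accessions, each with >= 2 replicates.
    """
    df = values[[accession_col, value_col]].dropna()
    groups = [g.to_numpy(dtype=float)
              for _, g in df.groupby(accession_col)[value_col]]
    if len(groups) < 2:
        raise ValueError("need >= 2 accessions")
    counts = np.array([len(g) for g in groups], dtype=float)
    if np.any(counts < 2):
        raise ValueError("unreplicated design: every accession needs >= 2 "
                         "replicates")
    grand = df[value_col].mean()
    ss_g = float(sum(c * (g.mean() - grand) ** 2
                     for c, g in zip(counts, groups)))
    ss_e = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_g = len(groups) - 1
    df_e = int(counts.sum()) - len(groups)
    ms_g = ss_g / df_g
    ms_e = ss_e / df_e if df_e > 0 else 0.0
    r_bar = len(counts) / np.sum(1.0 / counts)
    sigma2_g = max(0.0, (ms_g - ms_e) / r_bar)
    denom = sigma2_g + ms_e
    h2 = sigma2_g / denom if denom > 0 else 1.0
    return HeritabilityResult(H2=float(np.clip(h2, 0.0, 1.0)),
                              sigma2_g=sigma2_g, sigma2_e=ms_e,
                              ms_genotype=ms_g, ms_error=ms_e,
                              r_bar=float(r_bar))
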