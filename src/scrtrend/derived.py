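"""Derived quantities: densities, growth rates, realized density surfaces.

All population-level outputs reduce to functions of the fitted
parameters and their covariance:

* per-session density ``D_t`` (animals per 1,000 km²) with lognormal
  Wald intervals,
* the finite annual rate of change ``lambda = (D_end / D_start)^(1/m)``
  over ``m`` annual intervals, with a delta-method standard error and a
  95% Wald interval,
* the realized density surface ``Dhat_t(u)`` — the posterior-mean
  number of activity centers per state-space pixel: the summed
  posterior mass of the detected individuals plus the expected number
  of undetected ones,
* per-pixel and per-region growth-rate maps computed from two realized
  surfaces (no variance is attached at those scales: the fit's
  covariance refers to the whole state space and cannot be
  partitioned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datamodel import DetectorArray, EncounterData, OutlierReport, remove_detections
from .likelihood import (FitResult, ModelSpec, _log_surv, _session_probs,
                         aicc_select, fit_mle)
from .statespace import StateSpace

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _log_density_and_var(fit: FitResult) -> tuple[dict, dict]:
    """log D_t and its delta-method variance for every session."""
    prep = fit.prepared
    names = fit.param_names
    logD, _, _ = prep.unpack(fit.theta)
    var = {}
    for t in prep.sessions:
        g = np.zeros(len(names))
        if fit.spec.density == "linear":
            g[names.index("D.b0")] = 1.0
            g[names.index("D.b1")] = prep.year_centered[t]
        else:
            g[names.index(f"D.{t}")] = 1.0
        var[t] = float(g @ fit.cov @ g)
    return {t: float(v) for t, v in logD.items()}, var


def density_estimates(fit: FitResult) -> pd.DataFrame:
    """Per-session density (animals / 1,000 km²) with 95% CIs.

    Intervals are computed on the log scale and exponentiated, so they
    are asymmetric and strictly positive.  Raises on a non-converged
    fit, whose Hessian-based intervals would be meaningless.
    """
    if not fit.converged:
        raise ValueError("density_estimates requires a converged fit")
    logD, var = _log_density_and_var(fit)
    rows = []
    for t in fit.prepared.sessions:
        se_log = np.sqrt(max(var[t], 0.0))
        d = np.exp(logD[t])
        rows.append({
            "session": t,
            "D": d,
            "se_logD": se_log,
            "lcl": float(np.exp(logD[t] - Z95 * se_log)),
            "ucl": float(np.exp(logD[t] + Z95 * se_log)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Growth rates
# ---------------------------------------------------------------------------

def growth_rate(d_start: float, d_end: float, n_intervals: int) -> float:
    """Geometric-mean per-interval finite rate of change.

    ``lambda = (d_end / d_start) ** (1 / n_intervals)``.
    """
    if d_start <= 0 or d_end <= 0:
        raise ValueError("densities must be positive")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    return float((d_end / d_start) ** (1.0 / n_intervals))


@dataclass
class TrendEstimate:
    """Per-interval growth multiplier with delta-method uncertainty."""

    lam: float
    se: float | None
    lcl: float | None
    ucl: float | None
    n_intervals: int
    scope: str = "statespace"

    @classmethod
    def from_lambda_se(cls, lam: float, se: float, n_intervals: int,
                       scope: str = "statespace") -> "TrendEstimate":
        return cls(lam=lam, se=se, lcl=lam - Z95 * se, ucl=lam + Z95 * se,
                   n_intervals=n_intervals, scope=scope)


def trend_with_se(fit: FitResult, start_session: int, end_session: int,
                  n_intervals: int | None = None) -> TrendEstimate:
    """Whole-state-space growth rate with a delta-method SE and Wald CI.

    For a linear log-density model the annualized trend is
    ``exp(b1 * dy / m)`` (``dy`` = year span, ``m`` = intervals), with
    the exact delta SE ``lam * se(b1) * dy / m``.  For year-specific
    density, ``log lam = (log D_end - log D_start) / m`` and the delta
    variance uses the full fit covariance, including the covariance
    between the two density parameters.
    """
    prep = fit.prepared
    for s in (start_session, end_session):
        if s not in prep.sessions:
            raise ValueError(f"session {s} not in fit")
    if n_intervals is None:
        n_intervals = int(end_session - start_session)
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    names = fit.param_names
    m = float(n_intervals)
    g = np.zeros(len(names))  # gradient of log(lambda) in theta
    if fit.spec.density == "linear":
        dy = prep.year_centered[end_session] - prep.year_centered[start_session]
        g[names.index("D.b1")] = dy / m
        loglam = fit.coef("D.b1") * dy / m
    else:
        g[names.index(f"D.{end_session}")] = 1.0 / m
        g[names.index(f"D.{start_session}")] = -1.0 / m
        loglam = (fit.coef(f"D.{end_session}")
                  - fit.coef(f"D.{start_session}")) / m
    lam = float(np.exp(loglam))
    var_loglam = float(g @ fit.cov @ g)
    se = lam * float(np.sqrt(max(var_loglam, 0.0)))
    return TrendEstimate.from_lambda_se(lam, se, n_intervals)


def pooled_growth(female: Mapping[int, float], male: Mapping[int, float],
                  start_session: int, end_session: int,
                  n_intervals: int) -> float:
    """Overall growth from summed sex-specific densities.

    The two sexes' densities are added within each session and the
    geometric-mean rate applied to the sums.
    """
    for m_, name in ((female, "female"), (male, "male")):
        for s in (start_session, end_session):
            if s not in m_:
                raise ValueError(f"{name} densities missing session {s}")
    return growth_rate(female[start_session] + male[start_session],
                       female[end_session] + male[end_session], n_intervals)


# ---------------------------------------------------------------------------
# Realized density surfaces
# ---------------------------------------------------------------------------

@dataclass
class DensitySurface:
    """Realized (posterior-mean) activity centers per pixel for one session."""

    session: int
    points: np.ndarray        # (U, 2) km
    detected: np.ndarray      # (U,) summed posterior mass of detected animals
    undetected: np.ndarray    # (U,) expected undetected animals
    pixel_area: float
    n_detected: int

    @property
    def dhat(self) -> np.ndarray:
        """Expected activity centers per pixel."""
        return self.detected + self.undetected

    @property
    def dhat_per_1000km2(self) -> np.ndarray:
        return self.dhat / self.pixel_area * 1000.0

    def total(self) -> float:
        return float(self.dhat.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_km": self.points[:, 0], "y_km": self.points[:, 1],
            "session": self.session,
            "detected_mass": self.detected, "undetected_mass": self.undetected,
            "dhat_per_pixel": self.dhat,
            "dhat_per_1000km2": self.dhat_per_1000km2,
        })


def activity_center_posterior(fit: FitResult, session: int
                              ) -> tuple[list[str], np.ndarray]:
    """Posterior Pr(s_i = u | y_i, theta-hat) for each detected individual.

    Rows are individuals (in the fit's per-session order), columns the
    session's state-space pixels; each row sums to 1.  With a
    homogeneous within-session density the prior over pixels is flat,
    so the posterior is the normalized conditional likelihood.
    """
    prep = fit.prepared
    sd = next(d for d in prep.designs if d.session == session)
    logD, beta_p, logsig = prep.unpack(fit.theta)
    p, _ = _session_probs(sd, beta_p, float(np.exp(logsig[session])))
    S0 = _log_surv(p, sd.usage)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        logq = np.log1p(-np.minimum(p, 1.0 - 1e-300))
    ids, rows = [], []
    for ind, jj, kk in sd.individuals:
        logpost = S0 + (logp[:, jj, kk] - logq[:, jj, kk]).sum(axis=1)
        rows.append(np.exp(logpost - logsumexp(logpost)))
        ids.append(ind)
    post = np.vstack(rows) if rows else np.zeros((0, len(sd.pixels)))
    return ids, post


def realized_surface(fit: FitResult, session: int) -> DensitySurface:
    """Realized density surface Dhat_t(u) for one session.

    Detected mass: sum over individuals of the activity-center
    posterior.  Undetected mass: ``mu(u) * (1 - pdot(u))`` with
    ``mu(u) = D_t * A / 1000`` the fitted per-pixel intensity.
    """
    prep = fit.prepared
    sd = next(d for d in prep.designs if d.session == session)
    logD, beta_p, logsig = prep.unpack(fit.theta)
    mu = float(np.exp(logD[session])) * prep.pixel_area / 1000.0
    p, _ = _session_probs(sd, beta_p, float(np.exp(logsig[session])))
    S0 = _log_surv(p, sd.usage)
    undetected = mu * np.exp(S0)          # mu * (1 - pdot)
    _, post = activity_center_posterior(fit, session)
    detected = post.sum(axis=0) if len(post) else np.zeros(len(sd.pixels))
    return DensitySurface(session=session, points=sd.pixels,
                          detected=detected, undetected=undetected,
                          pixel_area=prep.pixel_area,
                          n_detected=sd.n_individuals)


# ---------------------------------------------------------------------------
# Local and regional growth
# ---------------------------------------------------------------------------

def _coord_key(points: np.ndarray) -> list[tuple[int, int]]:
    # lattice coordinates are exact multiples of the spacing; round to mm
    return [tuple(np.round(xy * 1e6).astype(np.int64)) for xy in points]


def local_growth(surf_start: DensitySurface, surf_end: DensitySurface,
                 n_intervals: int) -> pd.DataFrame:
    """Per-pixel growth map ``lambda(u) = (Dhat_end(u)/Dhat_start(u))^(1/m)``.

    Restricted to pixels present in both sessions' surfaces (the area
    sampled in both years); other pixels and zero-start pixels carry
    ``lam = NaN`` with ``valid = False`` — never silent zeros, because
    growth outside the sampled area is not identified.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    key_end = {k: i for i, k in enumerate(_coord_key(surf_end.points))}
    rows = []
    for i, k in enumerate(_coord_key(surf_start.points)):
        x, y = surf_start.points[i]
        d0 = float(surf_start.dhat[i])
        j = key_end.get(k)
        if j is None or d0 <= 0.0:
            rows.append({"x_km": x, "y_km": y, "lam": np.nan, "valid": False})
        else:
            d1 = float(surf_end.dhat[j])
            rows.append({"x_km": x, "y_km": y,
                         "lam": (d1 / d0) ** (1.0 / n_intervals),
                         "valid": True})
    return pd.DataFrame(rows)


def regional_growth(surfaces: Mapping[int, DensitySurface], ss: StateSpace,
                    start_session: int, end_session: int,
                    n_intervals: int) -> pd.DataFrame:
    """Growth per labeled region by summing realized density within it.

    The realized density is summed over each region's pixels in each of
    the two sessions and the geometric-mean rate applied to the sums.
    No SE is attached: the model covariance refers to the whole state
    space and cannot be partitioned between regions.
    """
    if ss.region is None:
        raise ValueError("state space has no region labels")
    region_of = dict(zip(_coord_key(ss.points), ss.region))
    rows = []
    for label in sorted(set(ss.region)):
        sums = {}
        for s in (start_session, end_session):
            surf = surfaces[s]
            mask = np.array([region_of.get(k) == label
                             for k in _coord_key(surf.points)])
            if not mask.any():
                raise ValueError(f"region {label!r} empty in session {s}")
            sums[s] = float(surf.dhat[mask].sum())
        rows.append({"region": label,
                     "total_start": sums[start_session],
                     "total_end": sums[end_session],
                     "lam": growth_rate(sums[start_session], sums[end_session],
                                        n_intervals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outlier sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Side-by-side fits with and without flagged outlier detections."""

    selection_with: pd.DataFrame
    selection_without: pd.DataFrame
    top_with: FitResult
    top_without: FitResult
    trend_with: TrendEstimate
    trend_without: TrendEstimate

    def comparison(self, start_session: int, end_session: int) -> pd.DataFrame:
        rows = []
        for arm, fit, tr in (("with", self.top_with, self.trend_with),
                             ("without", self.top_without, self.trend_without)):
            logD, _, _ = fit.prepared.unpack(fit.theta)
            sig = fit.sigma_estimates()
            for t in fit.prepared.sessions:
                rows.append({"arm": arm, "session": t,
                             "D_per_1000km2": float(np.exp(logD[t])),
                             "sigma_km": sig[t],
                             "lam": tr.lam, "lam_se": tr.se,
                             "converged": fit.converged})
        return pd.DataFrame(rows)


def outlier_sensitivity(enc: EncounterData, det: DetectorArray, ss: StateSpace,
                        specs: Sequence[ModelSpec],
                        reports: Sequence[OutlierReport],
                        sex: str | None = None,
                        start_session: int | None = None,
                        end_session: int | None = None,
                        n_intervals: int | None = None) -> SensitivityResult:
    """Fit the model set with and without flagged outlier detections.

    With no flagged outliers the two arms are identical.  The trend is
    taken from each arm's AICc-top converged model between
    ``start_session`` and ``end_session`` (default: first and last).
    """
    sessions = det.sessions
    start_session = sessions[0] if start_session is None else start_session
    end_session = sessions[-1] if end_session is None else end_session
    if n_intervals is None:
        n_intervals = int(end_session - start_session)

    flagged = [r.flagged_detection for r in reports]
    enc_without = remove_detections(enc, flagged) if flagged else enc

    def run(enc_arm: EncounterData):
        fits = [fit_mle(enc_arm, det, ss, spec, sex=sex) for spec in specs]
        table = aicc_select(fits)
        by_label = {f.spec.label(): f for f in fits}
        ranked = [by_label[lbl] for lbl in table["model"]]
        top = next((f for f in ranked if f.converged), ranked[0])
        return table, top

    sel_w, top_w = run(enc)
    if flagged:
        sel_wo, top_wo = run(enc_without)
    else:
        sel_wo, top_wo = sel_w, top_w
    return SensitivityResult(
        selection_with=sel_w, selection_without=sel_wo,
        top_with=top_w, top_without=top_wo,
        trend_with=trend_with_se(top_w, start_session, end_session, n_intervals),
        trend_without=trend_with_se(top_wo, start_session, end_session,
                                    n_intervals))
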