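"""Maximum-likelihood spatial capture-recapture with a half-normal kernel.

Model
-----
Each individual has a latent activity center ``s`` on the discrete
state space.  Detection of an individual centered at ``s`` at detector
``x`` during one occasion is Bernoulli with

    p(x, s) = p0 * exp(-dist(x, s)^2 / (2 sigma^2))

where the baseline ``p0`` is logit-linear in detector-occasion
covariates and ``sigma`` (km) is the spatial scale of movement.
Density ``D`` (animals per 1,000 km²) is log-linear in year (either a
linear trend on the centered year or fully year-specific), ``sigma``
log-linear (constant or year-specific).  Sessions (years) are
independent; sexes are fitted separately.

The fit maximises the full Poisson point-process likelihood: with
per-pixel intensity ``mu_t(u) = D_t * A / 1000`` (``A`` = pixel area,
km²) the log-likelihood for session ``t`` is

    sum_i log( sum_u mu_t(u) Pr(y_i | u) ) - sum_u mu_t(u) pdot_t(u)

up to an additive constant ``-log n_t!`` that does not involve the
parameters.  ``Pr(y_i | u)`` is the Bernoulli product over usable
detector-occasions and ``pdot_t(u)`` the probability of at least one
detection anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

from .datamodel import DetectorArray, EncounterData
from .statespace import StateSpace

logger = logging.getLogger(__name__)

#: canonical ordering of optional baseline-detection terms
P0_TERMS = ("year", "dur", "jul", "jul2", "beh", "cover", "cover2", "curv", "sec")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model structure for (D, p0, sigma).

    ``density``: "linear" (log D = b0 + b1 * centered year) or "year"
    (one log-density per session).  ``p0_terms``: subset of
    :data:`P0_TERMS` added to the logit-scale intercept.  ``sigma``:
    "constant" or "year".
    """

    density: str = "linear"
    p0_terms: tuple[str, ...] = ()
    sigma: str = "constant"

    def __post_init__(self):
        if self.density not in ("linear", "year"):
            raise ValueError(f"unknown density formula {self.density!r}")
        if self.sigma not in ("constant", "year"):
            raise ValueError(f"unknown sigma formula {self.sigma!r}")
        bad = set(self.p0_terms) - set(P0_TERMS)
        if bad:
            raise ValueError(f"unknown p0 terms {sorted(bad)}")
        object.__setattr__(self, "p0_terms",
                           tuple(t for t in P0_TERMS if t in self.p0_terms))

    def label(self) -> str:
        p0 = " + ".join(("int",) + self.p0_terms)
        return f"D~{self.density} p0~{p0} sigma~{self.sigma}"


def detection_prob(p0, sigma, dist):
    """Half-normal encounter probability ``p0 * exp(-d^2 / (2 sigma^2))``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 must lie in [0, 1]")
    d = np.asarray(dist, dtype=float)
    return p0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def pdot_from_probs(p: np.ndarray, usage: np.ndarray | None = None):
    """1 - prod(1 - p) over the trailing detector(-occasion) axes.

    ``p`` has shape (..., J, K) (or (..., J)); ``usage`` masks unusable
    detector-occasions.
    """
    p = np.asarray(p, dtype=float)
    logq = np.log1p(-p)
    if usage is not None:
        logq = logq * usage
    axes = tuple(range(p.ndim - (2 if p.ndim >= 2 else 1), p.ndim))
    return -np.expm1(logq.sum(axis=axes))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass
class SessionDesign:
    session: int
    detector_ids: list[str]
    traps: np.ndarray            # (J, 2)
    usage: np.ndarray            # (J, Kmax) 0/1 float
    Xp: np.ndarray               # (J, Kmax, P) baseline-detection design
    dist2: np.ndarray            # (U_t, J) squared distances to session pixels
    pixels: np.ndarray           # (U_t, 2)
    individuals: list[tuple[str, np.ndarray, np.ndarray]]  # (id, jj, kk)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


@dataclass
class PreparedData:
    """Everything the likelihood needs, computed once per dataset/spec."""

    spec: ModelSpec
    sessions: list[int]
    year_centered: dict[int, float]
    designs: list[SessionDesign]
    p0_colnames: list[str]
    standardization: dict[str, tuple[float, float]]
    pixel_area: float
    n_individuals: int          # distinct individuals pooled over sessions

    @property
    def n_params(self) -> int:
        return len(self.param_names())

    def param_names(self) -> list[str]:
        if self.spec.density == "linear":
            names = ["D.b0", "D.b1"]
        else:
            names = [f"D.{t}" for t in self.sessions]
        names += [f"p0.{c}" for c in self.p0_colnames]
        if self.spec.sigma == "constant":
            names += ["sigma.log"]
        else:
            names += [f"sigma.{t}" for t in self.sessions]
        return names

    def unpack(self, theta: np.ndarray):
        """Split ``theta`` into (log D_t per session, beta_p, log sigma_t)."""
        theta = np.asarray(theta, dtype=float)
        T = len(self.sessions)
        if self.spec.density == "linear":
            nd = 2
            logD = {t: theta[0] + theta[1] * self.year_centered[t]
                    for t in self.sessions}
        else:
            nd = T
            logD = {t: theta[i] for i, t in enumerate(self.sessions)}
        P = len(self.p0_colnames)
        beta_p = theta[nd:nd + P]
        sig = theta[nd + P:]
        if self.spec.sigma == "constant":
            logsig = {t: sig[0] for t in self.sessions}
        else:
            logsig = {t: sig[i] for i, t in enumerate(self.sessions)}
        return logD, beta_p, logsig


def _behavior_matrix(enc_all: pd.DataFrame, det_ids: Sequence[str],
                     session: int, kmax: int) -> np.ndarray:
    """Site-level behavioral indicator per (detector, occasion).

    1 from the occasion after the detector's first detection of the
    season by any individual (of any sex): a rub that has been rubbed
    is more likely to be rubbed again.
    """
    beh = np.zeros((len(det_ids), kmax))
    sub = enc_all[enc_all["session"] == session]
    first = sub.groupby("detector_id")["occasion"].min()
    for j, d in enumerate(det_ids):
        if d in first.index:
            k0 = int(first.loc[d])          # 1-based occasion of first hit
            beh[j, k0:] = 1.0               # occasions k0+1.. (0-based k0..)
    return beh


def build_designs(enc: EncounterData, det: DetectorArray, ss: StateSpace,
                  spec: ModelSpec, sex: str | None = None,
                  beh_encounters: EncounterData | None = None) -> PreparedData:
    """Assemble per-session design matrices and distance tables.

    ``sex`` filters the encounter histories to one sex (the behavioral
    covariate still uses all detections unless ``beh_encounters``
    overrides the source).  Continuous covariates are standardized with
    means/SDs pooled over usable detector-occasions; the constants are
    stored so fitted coefficients can be interpreted and reused.
    """
    enc.validate(det)
    beh_src = (beh_encounters or enc).table
    enc_t = enc.table if sex is None else enc.for_sex(sex).table
    sessions = det.sessions
    yc_mid = 0.5 * (min(sessions) + max(sessions))
    year_centered = {t: float(t) - yc_mid for t in sessions}

    # ---- pooled standardization constants over usable detector-occasions
    pool = {"dur": [], "jul": [], "cover": [], "curv": [], "sec": []}
    per_session_raw = {}
    for t in sessions:
        sub = det.for_session(t)
        kmax = max(len(v) - 1 for v in sub["visit_dates"])
        J = len(sub)
        usage = np.zeros((J, kmax))
        dur = np.zeros((J, kmax))
        jul = np.zeros((J, kmax))
        for j, dates in enumerate(sub["visit_dates"]):
            for k in range(len(dates) - 1):
                usage[j, k] = 1.0
                dur[j, k] = dates[k + 1] - dates[k]
                jul[j, k] = 0.5 * (dates[k] + dates[k + 1])
        use = usage.astype(bool)
        pool["dur"].extend(dur[use])
        pool["jul"].extend(jul[use])
        pool["cover"].extend(np.repeat(sub["cover_pct"].to_numpy(float), use.sum(1)))
        pool["curv"].extend(np.repeat(sub["curv_sd"].to_numpy(float), use.sum(1)))
        pool["sec"].extend(np.repeat(sub["security"].to_numpy(float), use.sum(1)))
        per_session_raw[t] = (sub, kmax, usage, dur, jul)

    standardization = {}
    for name, vals in pool.items():
        v = np.asarray(vals, dtype=float)
        mu = float(v.mean()) if len(v) else 0.0
        sd = float(v.std()) if len(v) else 1.0
        standardization[name] = (mu, sd if sd > 0 else 1.0)

    def z(name, arr):
        mu, sd = standardization[name]
        return (arr - mu) / sd

    terms = spec.p0_terms
    colnames = ["int"]
    if "year" in terms:
        colnames += [f"year_{t}" for t in sessions[1:]]
    colnames += [t for t in terms if t != "year"]

    designs = []
    for t in sessions:
        sub, kmax, usage, dur, jul = per_session_raw[t]
        J = len(sub)
        cols = {"int": np.ones((J, kmax))}
        if "year" in terms:
            for t2 in sessions[1:]:
                cols[f"year_{t2}"] = np.full((J, kmax), 1.0 if t == t2 else 0.0)
        zjul = z("jul", jul)
        zcov = z("cover", np.repeat(sub["cover_pct"].to_numpy(float)[:, None],
                                    kmax, axis=1))
        cols["dur"] = z("dur", dur)
        cols["jul"] = zjul
        cols["jul2"] = zjul ** 2
        cols["beh"] = _behavior_matrix(beh_src, sub["detector_id"].tolist(), t, kmax)
        cols["cover"] = zcov
        cols["cover2"] = zcov ** 2
        cols["curv"] = z("curv", np.repeat(sub["curv_sd"].to_numpy(float)[:, None],
                                           kmax, axis=1))
        cols["sec"] = z("sec", np.repeat(sub["security"].to_numpy(float)[:, None],
                                         kmax, axis=1))
        Xp = np.stack([cols[c] for c in colnames], axis=-1)

        traps = sub[["x_km", "y_km"]].to_numpy(float)
        pixels = ss.points[ss.mask(t)]
        dist2 = ((pixels[:, None, :] - traps[None, :, :]) ** 2).sum(-1)

        det_index = {d: j for j, d in enumerate(sub["detector_id"])}
        individuals = []
        sess_enc = enc_t[enc_t["session"] == t]
        for ind, rows in sess_enc.groupby("individual_id", sort=True):
            jj = np.array([det_index[d] for d in rows["detector_id"]], dtype=int)
            kk = rows["occasion"].to_numpy(int) - 1
            individuals.append((ind, jj, kk))
        designs.append(SessionDesign(
            session=t, detector_ids=sub["detector_id"].tolist(), traps=traps,
            usage=usage, Xp=Xp, dist2=dist2, pixels=pixels,
            individuals=individuals))

    n_ind = pd.unique(enc_t["individual_id"]).size
    return PreparedData(spec=spec, sessions=sessions,
                        year_centered=year_centered, designs=designs,
                        p0_colnames=colnames, standardization=standardization,
                        pixel_area=ss.pixel_area, n_individuals=n_ind)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _session_probs(sd: SessionDesign, beta_p: np.ndarray, sigma: float):
    """Detection probabilities p[u, j, k] and baseline p0[j, k]."""
    eta = sd.Xp @ beta_p                       # (J, K)
    p0 = expit(eta)
    kernel = np.exp(-sd.dist2 / (2.0 * sigma ** 2))   # (U, J)
    p = kernel[:, :, None] * p0[None, :, :]           # (U, J, K)
    return p, p0


def _log_surv(p: np.ndarray, usage: np.ndarray) -> np.ndarray:
    """log prod_{j,k usable} (1 - p[u,j,k]) for every pixel u."""
    with np.errstate(divide="ignore"):
        lq = np.log1p(-np.minimum(p, 1.0 - 1e-300))
    return (lq * usage[None, :, :]).sum(axis=(1, 2))


def pdot(prepared: PreparedData, theta: np.ndarray, session: int) -> np.ndarray:
    """P(detected at least once) per state-space pixel of ``session``.

    Uses the observed (data-determined) behavioral covariate values, so
    the same baseline applies to detected and undetected individuals.
    """
    logD, beta_p, logsig = prepared.unpack(theta)
    sd = next(d for d in prepared.designs if d.session == session)
    p, _ = _session_probs(sd, beta_p, float(np.exp(logsig[session])))
    return -np.expm1(_log_surv(p, sd.usage))


def negloglik(theta: np.ndarray, prepared: PreparedData) -> float:
    """Negative marginal log-likelihood (up to the constant sum of log n_t!).

    Returns ``+inf`` (with a logged warning) on any non-finite
    intermediate so optimizers can recover.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        return np.inf
    try:
        logD, beta_p, logsig = prepared.unpack(theta)
        logA = np.log(prepared.pixel_area / 1000.0)
        total = 0.0
        for sd in prepared.designs:
            t = sd.session
            sigma = float(np.exp(logsig[t]))
            log_mu = logD[t] + logA            # per-pixel log intensity
            mu = np.exp(log_mu)
            p, _ = _session_probs(sd, beta_p, sigma)
            S0 = _log_surv(p, sd.usage)        # (U,)
            # Poisson thinning: sum_u mu * pdot(u)
            total -= mu * float((-np.expm1(S0)).sum())
            if sd.n_individuals and mu > 0:
                with np.errstate(divide="ignore"):
                    for _, jj, kk in sd.individuals:
                        pi = p[:, jj, kk]
                        delta = (np.log(pi)
                                 - np.log1p(-np.minimum(pi, 1.0 - 1e-300))
                                 ).sum(axis=1)
                        total += log_mu + logsumexp(S0 + delta)
            elif sd.n_individuals:
                return np.inf                  # detections but zero intensity
        if not np.isfinite(total):
            raise FloatingPointError("non-finite log-likelihood")
        return -total
    except FloatingPointError:
        logger.warning("non-finite likelihood at theta=%s", theta)
        return np.inf


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def finite_difference_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class FitResult:
    """MLEs with covariance from the inverse Hessian, plus AICc."""

    spec: ModelSpec
    theta: np.ndarray
    param_names: list[str]
    cov: np.ndarray
    loglik: float
    K: int
    n_individuals: int
    aicc: float
    converged: bool
    grad_norm: float
    message: str
    prepared: PreparedData = field(repr=False, default=None)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def coef(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se()[self.param_names.index(name)])

    def sigma_estimates(self) -> dict[int, float]:
        _, _, logsig = self.prepared.unpack(self.theta)
        return {t: float(np.exp(v)) for t, v in logsig.items()}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.theta, "se": self.se()},
                            index=self.param_names)


def aicc(nll: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return 2.0 * nll + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def default_start(prepared: PreparedData) -> np.ndarray:
    """Documented default starting values.

    log D from a naive closed-population count (detected individuals per
    unit area, a deliberate underestimate), logit p0 = -2, log sigma
    from half the mean maximum distance moved among recaptured
    individuals (falling back to twice the pixel spacing).
    """
    theta = []
    area_by_t = {sd.session: len(sd.pixels) * prepared.pixel_area / 1000.0
                 for sd in prepared.designs}
    naive = [max(sd.n_individuals, 1) / area_by_t[sd.session]
             for sd in prepared.designs]
    if prepared.spec.density == "linear":
        theta += [float(np.log(np.mean(naive))), 0.0]
    else:
        theta += [float(np.log(v)) for v in naive]
    theta += [-2.0] + [0.0] * (len(prepared.p0_colnames) - 1)

    mmd = []
    for sd in prepared.designs:
        for _, jj, _ in sd.individuals:
            pts = sd.traps[jj]
            if len(np.unique(jj)) >= 2:
                d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)).max()
                mmd.append(d)
    sigma0 = 0.5 * float(np.mean(mmd)) if mmd else 2.0 * np.sqrt(prepared.pixel_area)
    sigma0 = max(sigma0, 0.5 * np.sqrt(prepared.pixel_area))
    nsig = 1 if prepared.spec.sigma == "constant" else len(prepared.sessions)
    theta += [float(np.log(sigma0))] * nsig
    return np.asarray(theta, dtype=float)


def fit_mle(enc: EncounterData, det: DetectorArray, ss: StateSpace,
            spec: ModelSpec, sex: str | None = None,
            start: np.ndarray | None = None, gtol: float = 1e-5,
            beh_encounters: EncounterData | None = None) -> FitResult:
    """Fit one model by quasi-Newton minimisation of :func:`negloglik`.

    A fit is flagged non-converged when the optimizer fails or the
    finite-difference Hessian is not positive definite (its
    pseudo-inverse is still stored for diagnostics).
    """
    prepared = build_designs(enc, det, ss, spec, sex=sex,
                             beh_encounters=beh_encounters)
    for sd in prepared.designs:
        if sd.n_individuals == 0:
            warnings.warn(
                f"session {sd.session}: no detected individuals; it contributes "
                "only the thinning term", stacklevel=2)
    x0 = default_start(prepared) if start is None else np.asarray(start, float)
    if len(x0) != prepared.n_params:
        raise ValueError(
            f"start has {len(x0)} entries, model needs {prepared.n_params}")

    res = optimize.minimize(negloglik, x0, args=(prepared,), method="BFGS",
                            jac="3-point",
                            options={"gtol": gtol, "maxiter": 500})
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan

    H = finite_difference_hessian(lambda th: negloglik(th, prepared), theta)
    pos_def = True
    try:
        np.linalg.cholesky(H)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pos_def = False
        cov = np.linalg.pinv(H)
        logger.warning("Hessian not positive definite; fit flagged non-converged")
    cov = 0.5 * (cov + cov.T)

    k = prepared.n_params
    n = prepared.n_individuals
    return FitResult(
        spec=spec, theta=theta, param_names=prepared.param_names(), cov=cov,
        loglik=-float(res.fun), K=k, n_individuals=n,
        aicc=aicc(float(res.fun), k, n),
        converged=bool(res.success and pos_def), grad_norm=grad_norm,
        message=str(res.message), prepared=prepared)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def aicc_select(fits: Sequence[FitResult]) -> pd.DataFrame:
    """AICc ranking with Akaike weights and cumulative weights.

    All fits must be to the same data (checked via the pooled
    individual count).  Weights are ``exp(-dAICc/2)`` normalized to 1.
    """
    if not fits:
        raise ValueError("no fits to select among")
    ns = {f.n_individuals for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits use different sample sizes {sorted(ns)}; "
                         "selection requires identical data")
    rows = pd.DataFrame({
        "model": [f.spec.label() for f in fits],
        "K": [f.K for f in fits],
        "logLik": [f.loglik for f in fits],
        "AICc": [f.aicc for f in fits],
        "converged": [f.converged for f in fits],
    })
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    w = np.exp(-0.5 * rows["dAICc"].to_numpy())
    rows["weight"] = w / w.sum()
    rows = rows.sort_values("AICc", kind="stable").reset_index(drop=True)
    rows["cumwt"] = rows["weight"].cumsum()
    return rows
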