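"""Shared fixtures: tiny hand-built datasets, a desk-scale simulated fit,
and a pure-Python brute-force likelihood oracle."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import scrtrend as st
from scrtrend.likelihood import ModelSpec


# ---------------------------------------------------------------------------
# Hand-built micro data
# ---------------------------------------------------------------------------

def make_detectors(rows):
    """rows: (id, session, x, y, visit_dates) with default covariates."""
    recs = [{"detector_id": r[0], "session": r[1], "x_km": r[2], "y_km": r[3],
             "cover_pct": 40.0, "curv_sd": 1.0, "security": 10,
             "visit_dates": list(r[4])} for r in rows]
    return st.DetectorArray(pd.DataFrame(recs))


def make_encounters(rows):
    """rows: (individual, sex, session, detector, occasion)."""
    return st.EncounterData(pd.DataFrame(
        rows, columns=["individual_id", "sex", "session", "detector_id",
                       "occasion"]))


@pytest.fixture
def tiny_detectors():
    return make_detectors([
        ("A", 2020, 0.0, 0.0, [150, 210, 240]),
        ("B", 2020, 4.0, 0.0, [150, 200]),
        ("A", 2021, 0.0, 0.0, [155, 185]),
        ("B", 2021, 4.0, 0.0, [155, 185, 215]),
    ])


@pytest.fixture
def tiny_encounters(tiny_detectors):
    enc = make_encounters([
        ("f1", "F", 2020, "A", 1), ("f1", "F", 2020, "B", 1),
        ("f2", "F", 2020, "A", 2),
        ("f1", "F", 2021, "A", 1),
        ("m1", "M", 2021, "B", 2),
    ])
    enc.validate(tiny_detectors)
    return enc


# ---------------------------------------------------------------------------
# Desk-scale simulation + fit, reused by several modules (slow: session scope)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def desk_sim():
    return st.simulate_dataset(st.desk_scenario(), seed=7)


@pytest.fixture(scope="session")
def desk_fit(desk_sim):
    fit = st.fit_mle(desk_sim.encounters, desk_sim.detectors,
                     desk_sim.state_spaces["F"], ModelSpec(), sex="F")
    assert fit.converged
    return fit


# ---------------------------------------------------------------------------
# Brute-force likelihood oracle (pure Python, independent of the package's
# vectorized path)
# ---------------------------------------------------------------------------

def oracle_negloglik(enc, det, ss, params, sex=None):
    """Enumerate activity centers and sum the Poisson thinning term directly.

    ``params``: dict with ``logD[t]``, ``p0_int``, optional ``p0_year[t]``
    (0 for the first session), optional ``p0_beh``, and ``logsig[t]``.
    The behavioral indicator is recomputed here from the raw encounter
    table (any detection at the detector in an earlier occasion of the
    season, regardless of sex).
    """
    table = enc.table if sex is None else enc.table[enc.table["sex"] == sex]
    ll = 0.0
    for t in det.sessions:
        sub = det.for_session(t)
        pix = [tuple(p) for p in ss.points[ss.mask(t)]]
        area = ss.pixel_area
        mu = math.exp(params["logD"][t]) * area / 1000.0
        sig = math.exp(params["logsig"][t])

        def first_hit(did):
            occ = [int(r["occasion"]) for _, r in enc.table.iterrows()
                   if r["detector_id"] == did and r["session"] == t]
            return min(occ) if occ else None

        # p[(j, k)][pixel] detection probabilities
        p = {}
        for j, drow in sub.iterrows():
            n_occ = len(drow["visit_dates"]) - 1
            fh = first_hit(drow["detector_id"])
            for k in range(1, n_occ + 1):
                eta = params["p0_int"] + params.get("p0_year", {}).get(t, 0.0)
                if fh is not None and k > fh:
                    eta += params.get("p0_beh", 0.0)
                p0 = 1.0 / (1.0 + math.exp(-eta))
                probs = []
                for (ux, uy) in pix:
                    d2 = (drow["x_km"] - ux) ** 2 + (drow["y_km"] - uy) ** 2
                    probs.append(p0 * math.exp(-d2 / (2.0 * sig ** 2)))
                p[(drow["detector_id"], k)] = probs

        # thinning term: sum_u mu * (1 - prod (1 - p))
        for ui in range(len(pix)):
            surv = 1.0
            for key in p:
                surv *= 1.0 - p[key][ui]
            ll -= mu * (1.0 - surv)

        # detected individuals
        sess = table[table["session"] == t]
        for ind in sorted(sess["individual_id"].unique()):
            hits = {(r["detector_id"], int(r["occasion"]))
                    for _, r in sess[sess["individual_id"] == ind].iterrows()}
            total = 0.0
            for ui in range(len(pix)):
                pr = 1.0
                for key, probs in p.items():
                    pr *= probs[ui] if key in hits else 1.0 - probs[ui]
                total += mu * pr
            ll += math.log(total)
    return -ll


def random_micro_instance(rng):
    """A random tiny dataset (<=4 pixels, <=3 detectors, <=3 occasions)."""
    years = sorted(rng.choice(np.arange(2001, 2006), size=int(rng.integers(1, 3)),
                              replace=False).tolist())
    det_rows, enc_rows = [], []
    n_det = int(rng.integers(1, 4))
    for t in years:
        for j in range(n_det):
            start = int(rng.integers(140, 160))
            dates = [start]
            for _ in range(int(rng.integers(1, 4))):
                dates.append(dates[-1] + int(rng.integers(10, 40)))
            det_rows.append((f"D{j}", t, float(rng.uniform(0, 6)),
                             float(rng.uniform(0, 6)), dates))
    det = make_detectors(det_rows)
    pts = np.asarray([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0], [3.0, 3.0]])
    n_pix = int(rng.integers(2, 5))
    ss = st.StateSpace(points=pts[:n_pix], spacing=3.0)
    n_ind = int(rng.integers(0, 4))
    for i in range(n_ind):
        t = years[int(rng.integers(0, len(years)))]
        for _ in range(int(rng.integers(1, 4))):
            j = int(rng.integers(0, n_det))
            n_occ = next(len(r[4]) - 1 for r in det_rows
                         if r[0] == f"D{j}" and r[1] == t)
            enc_rows.append((f"i{i}", "F", t, f"D{j}",
                             int(rng.integers(1, n_occ + 1))))
    enc_df = pd.DataFrame(enc_rows, columns=["individual_id", "sex", "session",
                                             "detector_id", "occasion"])
    enc = st.EncounterData(
        enc_df.drop_duplicates().reset_index(drop=True))
    enc.validate(det)
    return det, enc, ss, years


def random_micro_params(rng, years, spec: ModelSpec):
    """Random link-scale parameters and the matching packed theta."""
    params = {"logD": {}, "logsig": {}, "p0_year": {},
              "p0_int": float(rng.normal(-1.5, 0.5))}
    if spec.density == "linear":
        b0, b1 = rng.normal(1.0, 0.5), rng.normal(0.0, 0.1)
        mid = 0.5 * (min(years) + max(years))
        params["logD"] = {t: b0 + b1 * (t - mid) for t in years}
        d_theta = [b0, b1]
    else:
        params["logD"] = {t: float(rng.normal(1.0, 0.5)) for t in years}
        d_theta = [params["logD"][t] for t in years]
    p_theta = [params["p0_int"]]
    if "year" in spec.p0_terms:
        for t in years[1:]:
            params["p0_year"][t] = float(rng.normal(0.0, 0.5))
        p_theta += [params["p0_year"][t] for t in years[1:]]
    if "beh" in spec.p0_terms:
        params["p0_beh"] = float(rng.normal(0.0, 0.5))
        p_theta.append(params["p0_beh"])
    if spec.sigma == "constant":
        s = float(rng.normal(0.7, 0.3))
        params["logsig"] = {t: s for t in years}
        s_theta = [s]
    else:
        params["logsig"] = {t: float(rng.normal(0.7, 0.3)) for t in years}
        s_theta = [params["logsig"][t] for t in years]
    return params, np.asarray(d_theta + p_theta + s_theta)
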