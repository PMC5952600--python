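"""Shared fixtures and independent oracle implementations.

The oracles deliberately take different computational routes from the package
(joint-covariance Gaussian density instead of the Kalman recursion, a
double-loop kernel sum instead of the vectorized grid, a literal re-reading
of the filter rules) so agreement is evidence, not tautology.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from coreud.ctcrw import VAR0_POS, _transition
from coreud.simulate import Landscape, HaulSite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def waterworld():
    """Mostly-water landscape with a thin western land strip and one haulout."""
    land = np.zeros((120, 120), dtype=bool)
    land[:, :3] = True
    ls = Landscape(0.0, 0.0, 1.0, land)
    ls.haulouts = [HaulSite("W0", 2.5, 60.5)]
    return ls


def brute_force_ctcrw_loglik(t, obs, obs_var, beta, sigma):
    """Joint multivariate-normal track likelihood via the full covariance.

    Builds the n x n covariance of observed positions from the integrated-OU
    moments (prior: position N(first obs, VAR0_POS), velocity stationary) and
    evaluates the Gaussian density directly — no Kalman recursion.
    """
    n = len(t)
    covs = []
    pxx, pxv, pvv = VAR0_POS, 0.0, sigma**2 / (2 * beta)
    for i in range(n):
        if i > 0:
            dt = t[i] - t[i - 1]
            e, g, qxx, qxv, qvv = _transition(beta, sigma, dt)
            pxx, pxv, pvv = (
                pxx + 2 * g * pxv + g * g * pvv + qxx,
                e * (pxv + g * pvv) + qxv,
                e * e * pvv + qvv,
            )
        covs.append((pxx, pxv, pvv))
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = covs[i][0]
        for j in range(i + 1, n):
            g = (1 - np.exp(-beta * (t[j] - t[i]))) / beta
            C[i, j] = C[j, i] = covs[i][0] + covs[i][1] * g
    S = C + np.diag(obs_var)
    ll = 0.0
    for c in range(2):
        mu = np.full(n, obs[0, c])
        ll += multivariate_normal.logpdf(obs[:, c], mean=mu, cov=S)
    return ll


def brute_force_kde(points, h, xs, ys):
    """Double-loop Gaussian kernel sum at grid centers (unnormalized mean)."""
    out = np.zeros((len(ys), len(xs)))
    for r, yc in enumerate(ys):
        for c, xc in enumerate(xs):
            s = 0.0
            for px, py in points:
                d2 = (px - xc) ** 2 + (py - yc) ** 2
                s += np.exp(-d2 / (2 * h * h))
            out[r, c] = s / (2 * np.pi * h * h * len(points))
    return out


def brute_force_speed_filter(times_s, x_km, y_km, vmax_ms):
    """Literal forward-pass rule: keep a fix iff speed from last kept <= vmax."""
    kept = [0]
    for j in range(1, len(times_s)):
        i = kept[-1]
        dt = times_s[j] - times_s[i]
        if dt <= 0:
            continue
        d_m = 1000.0 * np.hypot(x_km[j] - x_km[i], y_km[j] - y_km[i])
        if d_m / dt <= vmax_ms:
            kept.append(j)
    return kept


def make_fixes(times_h, x_km, y_km, lc=None, animal_id="T0",
               t0="2012-03-01") -> pd.DataFrame:
    times_h = np.asarray(times_h, dtype=float)
    n = len(times_h)
    return pd.DataFrame({
        "animal_id": animal_id,
        "time": pd.Timestamp(t0) + pd.to_timedelta(times_h, unit="h"),
        "x_km": np.asarray(x_km, dtype=float),
        "y_km": np.asarray(y_km, dtype=float),
        "lc": ["3"] * n if lc is None else list(lc),
    })


@pytest.fixture
def toy_track():
    """Irregular 6-fix track for likelihood-equality checks."""
    rng = np.random.default_rng(7)
    t = np.array([0.0, 1.3, 2.0, 5.5, 7.1, 9.0])
    obs = rng.normal(0, 3, (6, 2))
    return t, obs, np.full(6, 0.15**2)
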