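import numpy as np
import pandas as pd
import pytest

from seasonrhythm.timeangles import PERIOD_DAYS, TWO_PI


def make_cohort(n=200, amplitude=0.3, acrophase_rad=1.0, noise_sd=0.0,
                beta_age=0.0, seed=0, base_mean=0.0):
    """Minimal synthetic table with exact cosine structure (test-local oracle)."""
    rng = np.random.default_rng(seed)
    days = rng.uniform(0, 365, n)
    dates = pd.Timestamp("2012-01-01") + pd.to_timedelta(
        np.floor(days).astype(int), unit="D")
    theta = TWO_PI * np.floor(days) / PERIOD_DAYS
    age = rng.uniform(60, 90, n)
    y = (base_mean + amplitude * np.cos(theta - acrophase_rad)
         + beta_age * (age - 75.0) + rng.normal(0, noise_sd, n))
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "assess_date": dates,
        "outcome": y,
        "age_years": age,
        "sex": rng.binomial(1, 0.5, n),
        "education_years": rng.normal(16, 3, n),
    })


def grid_search_cosinor(theta, y, covariates=None, n_grid=3650, refine=2):
    """Independent brute-force oracle: scan phase phi maximizing fit quality.

    Fits outcome ~ cos(theta - phi) (+ covariates) on an n_grid phase lattice,
    then zooms twice around the best point so the located optimum is sharp to
    ~1e-9 rad.  Returns (amplitude, phi).
    """
    cols = [np.ones_like(y)]
    if covariates is not None:
        cols.extend(np.asarray(c, dtype=float) for c in covariates)

    def rss_amp(phi):
        X = np.column_stack(cols + [np.cos(theta - phi)])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2)), beta[-1]

    lo, hi = 0.0, 2 * np.pi
    best_phi, best_amp, best_rss = 0.0, 0.0, np.inf
    for _ in range(refine + 1):
        grid = np.linspace(lo, hi, n_grid, endpoint=False)
        for phi in grid:
            rss, amp = rss_amp(phi)
            if rss < best_rss:
                best_rss, best_amp, best_phi = rss, amp, phi
        step = (hi - lo) / n_grid
        lo, hi = best_phi - 2 * step, best_phi + 2 * step
    if best_amp < 0:
        best_amp, best_phi = -best_amp, (best_phi + np.pi) % (2 * np.pi)
    return best_amp, best_phi % (2 * np.pi)


@pytest.fixture
def cohort_noise_free():
    return make_cohort(n=300, amplitude=0.3, acrophase_rad=1.0, noise_sd=0.0)


@pytest.fixture
def cohort_noisy():
    return make_cohort(n=400, amplitude=0.3, acrophase_rad=2.2, noise_sd=0.5,
                       beta_age=-0.03, seed=7)
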