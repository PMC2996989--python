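"""Parametric-bootstrap significance for epistasis scores.

The null hypothesis of no epistasis is imposed by drawing the double-mutant
growth rate from a normal distribution whose mean ``m0`` is the rate
expected under multiplicative neutrality and whose variance is
``m0^2 * (cv1^2 + cv2^2)``, where ``cv1`` is the coefficient of variation
of the measured double-mutant rate and ``cv2`` the library-median CV over
all double-mutant rates.  P values follow the add-one rule,
``(1 + #more-extreme) / (n_trials + 1)``, and are two-sided by
absolute-value comparison.

All CV arguments refer to the uncertainty of the *measured mean rate*
(replicate-level cv divided by sqrt(n)); callers summarising replicate
tables should use :func:`cv_of_mean`.

Two null-mean modes exist for the F and S families:

* ``"per-trial"`` (default): the wildtype and single rates are redrawn each
  trial and ``m0`` recomputed from the draws, so reference uncertainty
  enters the null.  Algebraically the reference draws cancel from the trial
  statistic, leaving the trial score distributed as the relative deviation
  ``delta ~ N(0, cv1^2 + cv2^2)`` truncated to positive rates.
* ``"fixed"``: ``m0`` is held at the value implied by the observed means,
  the references are redrawn, and the trial score is recomputed in full.

The ES-score null (not detailed by the original method description) uses
the classic full-redraw construction: the three reference rates are drawn
around their observed means, the perturbed-environment mutant rate around
the gene-environment-neutral expectation, and the trial score is
recomputed; this construction is exactly calibrated under the synthetic
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = [
    "BootstrapNull",
    "SignificanceResult",
    "cv_of_mean",
    "bootstrap_p_fscore",
    "bootstrap_p_sscore",
    "bootstrap_p_esscore",
    "fscore_pvalues",
    "sscore_pvalues",
    "esscore_pvalues",
    "ttest_single_vs_wt",
    "assign_environment",
    "benjamini_hochberg",
]

DEFAULT_N_TRIALS = 300_000
_MAX_REDRAWS = 100
_CHUNK = 2_000_000  # max draws held in memory at once


@dataclass(frozen=True)
class BootstrapNull:
    """Description of one bootstrap null distribution."""

    m0: float
    cv1: float
    cv2: float
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_trials < 1000:
            raise ValidationError(f"n_trials must be >= 1000, got {self.n_trials}")

    @property
    def variance(self) -> float:
        return self.m0**2 * (self.cv1**2 + self.cv2**2)


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    epsilon_obs: float
    n_trials: int
    seed: int
    family: str
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value outside (0, 1]: {self.p_value}")


def cv_of_mean(cv_replicate: float, n: int) -> float:
    """CV of a mean rate from the replicate-level cv and replicate count."""
    if n < 1:
        raise ValidationError("replicate count must be >= 1")
    return cv_replicate / np.sqrt(n)


# ---------------------------------------------------------------------------
# draw helpers
# ---------------------------------------------------------------------------


def _draw_relative(sigma: np.ndarray, size: tuple, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Relative deviations 1+delta ~ N(1, sigma^2) with rejection of
    non-positive values (cap _MAX_REDRAWS, then NaN = discarded trial)."""
    x = rng.normal(1.0, sigma, size=size)
    bad = x <= 0
    tries = 0
    while bad.any() and tries < _MAX_REDRAWS:
        idx = np.nonzero(bad)
        x[idx] = rng.normal(1.0, np.broadcast_to(sigma, size)[idx])
        bad = x <= 0
        tries += 1
    n_discarded = int(bad.sum())
    if n_discarded:
        x[bad] = np.nan
    return x, n_discarded


def _addone_p(abs_obs: float, abs_trials: np.ndarray, n_trials: int) -> float:
    return (1.0 + np.nansum(abs_trials >= abs_obs)) / (n_trials + 1.0)


# ---------------------------------------------------------------------------
# vectorised cores (one entry per pair; trials along the second axis)
# ---------------------------------------------------------------------------


def fscore_pvalues(
    eps_obs: np.ndarray,
    cv_xy: np.ndarray,
    cv2_library: float,
    n_trials: int,
    rng: np.random.Generator,
    null_mean_mode: str = "per-trial",
    ref_means: tuple | None = None,
    ref_cvs: tuple | None = None,
) -> np.ndarray:
    """Two-sided bootstrap P for many F-scores at once.

    In ``per-trial`` mode only (eps_obs, cv_xy, cv2_library) matter; in
    ``fixed`` mode ``ref_means``/``ref_cvs`` supply (m_x, m_y, m_wt) and
    their CVs (arrays aligned with ``eps_obs``).
    """
    eps_obs = np.atleast_1d(np.asarray(eps_obs, dtype=float))
    cv_xy = np.broadcast_to(np.asarray(cv_xy, dtype=float), eps_obs.shape)
    sigma = np.sqrt(cv_xy**2 + cv2_library**2)
    out = np.empty_like(eps_obs)
    rows_per_chunk = max(1, _CHUNK // max(n_trials, 1))
    for lo in range(0, eps_obs.size, rows_per_chunk):
        hi = min(lo + rows_per_chunk, eps_obs.size)
        if null_mean_mode == "per-trial":
            # reference draws cancel exactly from the trial statistic
            x, _ = _draw_relative(sigma[lo:hi, None], (hi - lo, n_trials), rng)
            trials = x - 1.0
        elif null_mean_mode == "fixed":
            if ref_means is None or ref_cvs is None:
                raise ValidationError("fixed null-mean mode needs ref_means and ref_cvs")
            rx, ry, rwt = (np.asarray(a, dtype=float)[lo:hi, None] for a in ref_cvs)
            x, _ = _draw_relative(np.broadcast_to(rx, (hi - lo, n_trials)), (hi - lo, n_trials), rng)
            y, _ = _draw_relative(np.broadcast_to(ry, (hi - lo, n_trials)), (hi - lo, n_trials), rng)
            w, _ = _draw_relative(np.broadcast_to(rwt, (hi - lo, n_trials)), (hi - lo, n_trials), rng)
            d, _ = _draw_relative(sigma[lo:hi, None], (hi - lo, n_trials), rng)
            # trial F-score with m0 fixed at the observed-mean expectation:
            # eps = (m0*d)*(m_wt*w)/((m_x*x)*(m_y*y)) - 1 = d*w/(x*y) - 1
            trials = d * w / (x * y) - 1.0
        else:
            raise ValidationError(f"unknown null_mean_mode {null_mean_mode!r}")
        cmp = np.abs(trials) >= np.abs(eps_obs[lo:hi, None])
        out[lo:hi] = (1.0 + np.nansum(cmp, axis=1)) / (n_trials + 1.0)
    return out


def sscore_pvalues(
    eps_obs: np.ndarray,
    cv_xy_e1: np.ndarray,
    cv_xy_e2: np.ndarray,
    cv2_e1: float,
    cv2_e2: float,
    n_trials: int,
    rng: np.random.Generator,
    null_mean_mode: str = "per-trial",
    ref_cvs: tuple | None = None,
) -> np.ndarray:
    """Two-sided bootstrap P for many S-scores.

    Per trial the double-mutant rate in each environment is drawn around the
    mean that satisfies fitness neutrality for that trial's references,
    which jointly imposes sensitivity neutrality; the trial statistic is the
    S-score of the drawn library.  In ``fixed`` mode ``ref_cvs`` supplies
    the six reference CVs (x_e1, y_e1, wt_e1, x_e2, y_e2, wt_e2).
    """
    eps_obs = np.atleast_1d(np.asarray(eps_obs, dtype=float))
    s1 = np.sqrt(np.broadcast_to(np.asarray(cv_xy_e1, float), eps_obs.shape) ** 2 + cv2_e1**2)
    s2 = np.sqrt(np.broadcast_to(np.asarray(cv_xy_e2, float), eps_obs.shape) ** 2 + cv2_e2**2)
    out = np.empty_like(eps_obs)
    rows_per_chunk = max(1, _CHUNK // max(2 * n_trials, 1))
    for lo in range(0, eps_obs.size, rows_per_chunk):
        hi = min(lo + rows_per_chunk, eps_obs.size)
        d1, _ = _draw_relative(s1[lo:hi, None], (hi - lo, n_trials), rng)
        d2, _ = _draw_relative(s2[lo:hi, None], (hi - lo, n_trials), rng)
        if null_mean_mode == "per-trial":
            trials = d1 / d2 - 1.0
        elif null_mean_mode == "fixed":
            if ref_cvs is None:
                raise ValidationError("fixed null-mean mode needs ref_cvs")
            refs = []
            for cv in ref_cvs:
                r, _ = _draw_relative(
                    np.broadcast_to(np.asarray(cv, float)[lo:hi, None], (hi - lo, n_trials)),
                    (hi - lo, n_trials), rng,
                )
                refs.append(r)
            x1, y1, w1, x2, y2, w2 = refs
            trials = (d1 * w1 / (x1 * y1)) / (d2 * w2 / (x2 * y2)) - 1.0
        else:
            raise ValidationError(f"unknown null_mean_mode {null_mean_mode!r}")
        cmp = np.abs(trials) >= np.abs(eps_obs[lo:hi, None])
        out[lo:hi] = (1.0 + np.nansum(cmp, axis=1)) / (n_trials + 1.0)
    return out


def esscore_pvalues(
    eps_obs: np.ndarray,
    cv_x_e1: np.ndarray,
    cv_x_e2: np.ndarray,
    cv_wt_e1: np.ndarray,
    cv_wt_e2: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-sided bootstrap P for many ES-scores (full-redraw null)."""
    eps_obs = np.atleast_1d(np.asarray(eps_obs, dtype=float))
    cvs = [np.broadcast_to(np.asarray(c, float), eps_obs.shape) for c in (cv_x_e1, cv_x_e2, cv_wt_e1, cv_wt_e2)]
    out = np.empty_like(eps_obs)
    rows_per_chunk = max(1, _CHUNK // max(4 * n_trials, 1))
    for lo in range(0, eps_obs.size, rows_per_chunk):
        hi = min(lo + rows_per_chunk, eps_obs.size)
        draws = []
        for c in cvs:
            r, _ = _draw_relative(
                np.broadcast_to(c[lo:hi, None], (hi - lo, n_trials)), (hi - lo, n_trials), rng
            )
            draws.append(r)
        x1, x2, w1, w2 = draws
        # null: m(X,E2) centred at m(X,E1)*m(wt,E2)/m(wt,E1); relative form:
        # eps_trial = (x2 * w1) / (x1 * w2) - 1
        trials = x2 * w1 / (x1 * w2) - 1.0
        cmp = np.abs(trials) >= np.abs(eps_obs[lo:hi, None])
        out[lo:hi] = (1.0 + np.nansum(cmp, axis=1)) / (n_trials + 1.0)
    return out


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------


def bootstrap_p_fscore(
    m_xy_obs: float,
    cv_xy: float,
    m_x: float,
    cv_x: float,
    m_y: float,
    cv_y: float,
    m_wt: float,
    cv_wt: float,
    cv2_library: float,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    null_mean_mode: str = "per-trial",
) -> SignificanceResult:
    """Bootstrap P for one F-score.  CVs are mean-rate CVs (see module doc)."""
    null = BootstrapNull(m0=m_x * m_y / m_wt, cv1=cv_xy, cv2=cv2_library, n_trials=n_trials, seed=seed)
    eps_obs = m_xy_obs * m_wt / (m_x * m_y) - 1.0
    rng = np.random.default_rng(seed)
    p = fscore_pvalues(
        np.array([eps_obs]), np.array([cv_xy]), cv2_library, n_trials, rng,
        null_mean_mode=null_mean_mode,
        ref_means=(np.array([m_x]), np.array([m_y]), np.array([m_wt])),
        ref_cvs=(np.array([cv_x]), np.array([cv_y]), np.array([cv_wt])),
    )[0]
    return SignificanceResult(p_value=float(p), epsilon_obs=eps_obs, n_trials=n_trials, seed=seed, family="F")


def bootstrap_p_sscore(
    m_xy_e1: float, cv_xy_e1: float, m_x_e1: float, cv_x_e1: float,
    m_y_e1: float, cv_y_e1: float, m_wt_e1: float, cv_wt_e1: float,
    m_xy_e2: float, cv_xy_e2: float, m_x_e2: float, cv_x_e2: float,
    m_y_e2: float, cv_y_e2: float, m_wt_e2: float, cv_wt_e2: float,
    cv2_e1: float, cv2_e2: float,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    null_mean_mode: str = "per-trial",
) -> SignificanceResult:
    """Bootstrap P for one S-score from rates/CVs of all four strains in
    both environments."""
    BootstrapNull(m0=m_x_e1 * m_y_e1 / m_wt_e1, cv1=cv_xy_e1, cv2=cv2_e1, n_trials=n_trials, seed=seed)
    s_xy = (m_xy_e1 / m_xy_e2)
    s_wt = (m_wt_e1 / m_wt_e2)
    s_x = (m_x_e1 / m_x_e2)
    s_y = (m_y_e1 / m_y_e2)
    eps_obs = s_xy * s_wt / (s_x * s_y) - 1.0
    rng = np.random.default_rng(seed)
    p = sscore_pvalues(
        np.array([eps_obs]), np.array([cv_xy_e1]), np.array([cv_xy_e2]),
        cv2_e1, cv2_e2, n_trials, rng, null_mean_mode=null_mean_mode,
        ref_cvs=tuple(np.array([c]) for c in (cv_x_e1, cv_y_e1, cv_wt_e1, cv_x_e2, cv_y_e2, cv_wt_e2)),
    )[0]
    return SignificanceResult(p_value=float(p), epsilon_obs=eps_obs, n_trials=n_trials, seed=seed, family="S")


def bootstrap_p_esscore(
    m_x_e1: float, cv_x_e1: float, m_x_e2: float, cv_x_e2: float,
    m_wt_e1: float, cv_wt_e1: float, m_wt_e2: float, cv_wt_e2: float,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
) -> SignificanceResult:
    """Bootstrap P for one ES-score under the null S(X) = S(wt)."""
    if n_trials < 1000:
        raise ValidationError(f"n_trials must be >= 1000, got {n_trials}")
    eps_obs = (m_x_e2 * m_wt_e1) / (m_x_e1 * m_wt_e2) - 1.0
    rng = np.random.default_rng(seed)
    p = esscore_pvalues(
        np.array([eps_obs]), np.array([cv_x_e1]), np.array([cv_x_e2]),
        np.array([cv_wt_e1]), np.array([cv_wt_e2]), n_trials, rng,
    )[0]
    return SignificanceResult(p_value=float(p), epsilon_obs=eps_obs, n_trials=n_trials, seed=seed, family="ES")


# ---------------------------------------------------------------------------
# classical tests and environment assignment
# ---------------------------------------------------------------------------


def ttest_single_vs_wt(rates_mutant, rates_wt) -> float:
    """Two-sided Welch T-test of a mutant's replicate rates against the
    wildtype's.  Accepts ReplicateRates-like objects (with ``.rates``) or
    (mean, sd, n) summary tuples; both paths give identical results on the
    same data."""

    def unpack(x):
        if hasattr(x, "rates"):
            r = np.asarray(x.rates, dtype=float)
            if r.size < 2:
                raise ValidationError("t-test needs >= 2 replicates per group")
            return float(r.mean()), float(r.std(ddof=1)), int(r.size)
        mean, sd, n = x
        if n < 2:
            raise ValidationError("t-test needs >= 2 replicates per group")
        return float(mean), float(sd), int(n)

    m1, s1, n1 = unpack(rates_mutant)
    m2, s2, n2 = unpack(rates_wt)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(res.pvalue)


def assign_environment(p_e1: float, p_e2: float, alpha: float = 0.01) -> str:
    """Four-way environment assignment of an interaction from its per-
    environment P values: 'E1-only', 'E2-only', 'both' or 'none'."""
    for name, p in (("p_e1", p_e1), ("p_e2", p_e2)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} outside [0, 1]: {p}")
    in1, in2 = p_e1 < alpha, p_e2 < alpha
    if in1 and in2:
        return "both"
    if in1:
        return "E1-only"
    if in2:
        return "E2-only"
    return "none"


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional FDR adjustment (never applied by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
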