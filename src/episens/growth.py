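"""Growth-rate estimation from OD time courses.

Rates are logarithmic growth rates (1/min) obtained by ordinary least
squares on ln(OD) against time, restricted to the exponential window
(OD between 0.1 and 0.4, time between 60 and 360 minutes by default).
A fit is rejected — not raised — when too few points survive the window,
mirroring the practice of discarding replicates that never enter clean
exponential growth.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import PhenotypeTable, StrainKey, StrainPhenotype, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "FitWindow",
    "FitResult",
    "ReplicateRates",
    "EstimatedSingleRate",
    "fit_growth_rate",
    "summarize_replicates",
    "estimate_single_from_doubles",
    "read_od_table",
    "fit_od_table",
]


@dataclass
class GrowthCurve:
    """One replicate OD600 time course for one strain in one environment."""

    strain: StrainKey
    environment: str
    replicate_id: int
    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size < 2:
            raise ValidationError("a growth curve needs at least 2 points")
        if self.times.size != self.od.size:
            raise ValidationError("times and od must have the same length")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValidationError("optical density cannot be negative")


@dataclass(frozen=True)
class FitWindow:
    """Conjunctive OD and time bounds selecting the exponential phase."""

    od_min: float = 0.1
    od_max: float = 0.4
    t_min: float = 60.0
    t_max: float = 360.0
    min_points: int = 10
    r2_warn: float = 0.95

    def __post_init__(self) -> None:
        if not self.od_min < self.od_max:
            raise ValidationError("od_min must be < od_max")
        if not self.t_min < self.t_max:
            raise ValidationError("t_min must be < t_max")
        if self.min_points < 2:
            raise ValidationError("min_points must be >= 2")


@dataclass(frozen=True)
class FitResult:
    rate: float | None
    intercept: float | None
    n_points: int
    r_squared: float | None
    rejected: bool
    reason: str | None = None
    low_r2: bool = False


def fit_growth_rate(curve: GrowthCurve, window: FitWindow = FitWindow()) -> FitResult:
    """Least-squares slope of ln(OD) vs time inside the window.

    Non-positive OD readings inside the window are excluded before the log
    and count toward rejection.  Returns a rejection record (never raises)
    when fewer than ``window.min_points`` usable points remain.  Fits with
    R^2 below ``window.r2_warn`` are flagged but not rejected.
    """
    t, od = curve.times, curve.od
    in_window = (od >= window.od_min) & (od <= window.od_max) & (t >= window.t_min) & (t <= window.t_max)
    usable = in_window & (od > 0)
    n = int(usable.sum())
    if n < window.min_points:
        return FitResult(
            rate=None,
            intercept=None,
            n_points=n,
            r_squared=None,
            rejected=True,
            reason=f"only {n} usable points in window (need {window.min_points})",
        )
    res = stats.linregress(t[usable], np.log(od[usable]))
    r2 = float(res.rvalue**2)
    low = r2 < window.r2_warn
    if low:
        log.warning(
            "low-quality exponential fit for %s/%s rep %d: R^2 = %.3f",
            curve.strain.label(), curve.environment, curve.replicate_id, r2,
        )
    return FitResult(
        rate=float(res.slope),
        intercept=float(res.intercept),
        n_points=n,
        r_squared=r2,
        rejected=False,
        low_r2=low,
    )


@dataclass
class ReplicateRates:
    """Per-replicate rates and their summary for one strain/environment.

    With a single replicate the cv is unestimable (``cv is None``); the
    significance machinery must then substitute the library-median cv.
    """

    strain: StrainKey
    environment: str
    rates: list[float]
    mean: float = field(init=False)
    cv: float | None = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValidationError("cannot summarise zero accepted replicates")
        self.n = len(self.rates)
        self.mean = float(np.mean(self.rates))
        if self.mean <= 0:
            raise ValidationError("mean growth rate must be positive")
        self.cv = None if self.n == 1 else float(np.std(self.rates, ddof=1) / self.mean)

    @property
    def cv_unestimable(self) -> bool:
        return self.cv is None


def summarize_replicates(rates, strain: StrainKey, environment: str) -> ReplicateRates:
    return ReplicateRates(strain=strain, environment=environment, rates=[float(r) for r in rates])


@dataclass
class EstimatedSingleRate:
    """Pooled single-mutant rate estimated from its double-mutant panel.

    For each partner Yi with a measured single rate, the no-epistasis
    hypothesis gives mu_i(X) = m(X,Yi) * m(wt) / m(Yi); the estimate is the
    median over partners, which is robust to a minority of true
    interactions in the panel.
    """

    gene: str
    environment: str
    mu_values: np.ndarray
    estimate: float
    n_partners: int
    skipped_partners: list[str]
    measured_rate: float | None = None
    deviation_threshold: float = 0.05

    @property
    def deviates(self) -> bool | None:
        """True when the estimate differs from the measured single rate by
        more than ``deviation_threshold`` (relative); None if unmeasured."""
        if self.measured_rate is None:
            return None
        return abs(self.estimate - self.measured_rate) / self.measured_rate > self.deviation_threshold


def estimate_single_from_doubles(
    gene: str,
    doubles: PhenotypeTable,
    singles: PhenotypeTable,
    wt: StrainPhenotype,
    environment: str,
) -> EstimatedSingleRate:
    gene = gene.strip().upper()
    sub = doubles.subset(environment)
    sub = sub[(sub["gene2"] != "") & ((sub["gene1"] == gene) | (sub["gene2"] == gene))]
    if sub.empty:
        raise ValidationError(f"gene {gene} has no assayed double-mutant partners in {environment}")
    mu, skipped = [], []
    for row in sub.itertuples():
        partner = row.gene2 if row.gene1 == gene else row.gene1
        partner_single = singles.get(StrainKey.single(partner), environment)
        if partner_single is None:
            skipped.append(partner)
            log.warning("partner %s lacks a single-mutant rate in %s; skipped", partner, environment)
            continue
        mu.append(row.rate * wt.mean_rate / partner_single.mean_rate)
    if not mu:
        raise ValidationError(f"no partner of {gene} has a usable single-mutant rate in {environment}")
    measured = singles.get(StrainKey.single(gene), environment)
    return EstimatedSingleRate(
        gene=gene,
        environment=environment,
        mu_values=np.asarray(mu),
        estimate=float(statistics.median(mu)),
        n_partners=len(mu),
        skipped_partners=skipped,
        measured_rate=None if measured is None else measured.mean_rate,
    )


# ---------------------------------------------------------------------------
# OD table plumbing
# ---------------------------------------------------------------------------


def read_od_table(path) -> list[GrowthCurve]:
    """Read long-format OD courses: columns strain (optional), gene1, gene2,
    environment, replicate, time_min, od."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene1": str, "gene2": str})
    for col in ("gene1", "gene2", "environment", "replicate", "time_min", "od"):
        if col not in frame.columns:
            raise ValidationError(f"OD table is missing column {col!r}")
    curves = []
    for (g1, g2, env, rep), grp in frame.groupby(["gene1", "gene2", "environment", "replicate"], dropna=False):
        grp = grp.sort_values("time_min")
        strain = StrainKey.from_fields(g1 if isinstance(g1, str) else None, g2 if isinstance(g2, str) else None)
        curves.append(
            GrowthCurve(
                strain=strain,
                environment=str(env),
                replicate_id=int(rep),
                times=grp["time_min"].to_numpy(float),
                od=grp["od"].to_numpy(float),
            )
        )
    return curves


def fit_od_table(
    curves: list[GrowthCurve],
    window: FitWindow = FitWindow(),
    per_environment_min_points: dict[str, int] | None = None,
) -> tuple[PhenotypeTable, list[FitResult]]:
    """Fit every curve and summarise accepted replicates per strain/env.

    ``per_environment_min_points`` overrides ``window.min_points`` per
    environment (e.g. 10 untreated / 12 treated).  Returns the summary
    table and the list of rejected fits.
    """
    import pandas as pd

    rejected: list[FitResult] = []
    pooled: dict[tuple[StrainKey, str], list[float]] = {}
    rep_rows = []
    for curve in curves:
        w = window
        if per_environment_min_points and curve.environment in per_environment_min_points:
            w = FitWindow(
                od_min=window.od_min, od_max=window.od_max, t_min=window.t_min,
                t_max=window.t_max, min_points=per_environment_min_points[curve.environment],
                r2_warn=window.r2_warn,
            )
        res = fit_growth_rate(curve, w)
        if res.rejected:
            rejected.append(res)
            continue
        pooled.setdefault((curve.strain, curve.environment), []).append(res.rate)
        g = curve.strain.genes
        rep_rows.append(
            {
                "gene1": g[0] if g else "",
                "gene2": g[1] if len(g) == 2 else "",
                "environment": curve.environment,
                "replicate": curve.replicate_id,
                "rate": res.rate,
            }
        )
    records = []
    for (strain, env), rates in pooled.items():
        summary = summarize_replicates(rates, strain, env)
        # unestimable cv (single replicate) travels as NaN; the significance
        # layer substitutes the library-median cv for such rows
        records.append((strain, env, summary.mean, np.nan if summary.cv is None else summary.cv, summary.n))
    table = PhenotypeTable.from_records(records, replicates=pd.DataFrame(rep_rows) if rep_rows else None)
    return table, rejected
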