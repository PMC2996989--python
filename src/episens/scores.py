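"""Epistasis score families under multiplicative neutrality.

Three score families quantify departure from independence of two gene
deletions measured by growth in two environments:

* **F-score** (fitness-based, per environment):
  ``eps_fit = m(X,Y) * m(wt) / (m(X) * m(Y)) - 1``.
* **ES-score** (environmental sensitivity of one gene): with sensitivity
  ``S = m(E1)/m(E2)``, ``eps_env = S(ref)/S(mutant) - 1`` where the
  reference is the wildtype (or a single mutant when generalised to a
  deletion background).  Strains hypersensitive to the perturbed
  environment get negative scores.
* **S-score** (sensitivity-based, cross-environment):
  ``eps_sen = S(X,Y) * S(wt) / (S(X) * S(Y)) - 1``.

The S-score satisfies the exact identity
``eps_sen = (1 + eps_fit(E1)) / (1 + eps_fit(E2)) - 1``
when all scores are computed from the same mean rates, so it is nonzero
only for interactions that change between the two environments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import PhenotypeTable, StrainKey, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "DomainError",
    "SensitivityRecord",
    "EpistasisScore",
    "expected_double_rate",
    "f_score",
    "sensitivity",
    "es_score",
    "expected_double_sensitivity",
    "s_score",
    "score_library",
]


class DomainError(ValueError):
    """A rate or sensitivity outside the positive domain of the formulas."""


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class SensitivityRecord:
    """Ratio of growth rates across environments with propagated uncertainty.

    ``s_value`` is m(E1)/m(E2); ``cv`` is the first-order (delta-method)
    coefficient of variation sqrt(cv_E1^2 + cv_E2^2) when replicate CVs are
    supplied.  ``s_value`` is None when either environment is missing.
    """

    strain: StrainKey | None = None
    s_value: float | None = None
    cv: float | None = None

    @property
    def defined(self) -> bool:
        return self.s_value is not None


@dataclass(frozen=True)
class EpistasisScore:
    """A scored gene pair (or single gene, for the ES family)."""

    pair: StrainKey
    family: str  # "F", "ES" or "S"
    environment_context: str  # environment name for F; "cross-environment" otherwise
    epsilon: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("F", "ES", "S"):
            raise ValidationError(f"unknown score family {self.family!r}")
        if self.family == "F" and self.environment_context == "cross-environment":
            raise ValidationError("F-scores require a concrete environment context")
        if self.family in ("ES", "S") and self.environment_context != "cross-environment":
            raise ValidationError(f"{self.family}-scores are cross-environment")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# elementary score functions
# ---------------------------------------------------------------------------


def expected_double_rate(m_x: float, m_y: float, m_wt: float) -> float:
    """Double-mutant rate expected under multiplicative neutrality."""
    _require_positive(m_x=m_x, m_y=m_y, m_wt=m_wt)
    return m_x * m_y / m_wt


def f_score(m_xy: float, m_x: float, m_y: float, m_wt: float) -> float:
    """Fitness-based epistasis score; symmetric in the two singles."""
    _require_positive(m_xy=m_xy, m_x=m_x, m_y=m_y, m_wt=m_wt)
    return m_xy * m_wt / (m_x * m_y) - 1.0


def sensitivity(
    m_e1: float | None,
    m_e2: float | None,
    cv_e1: float | None = None,
    cv_e2: float | None = None,
    strain: StrainKey | None = None,
) -> SensitivityRecord:
    """S = m(E1)/m(E2); undefined (s_value None) when either rate is missing."""
    if m_e1 is None or m_e2 is None:
        return SensitivityRecord(strain=strain, s_value=None, cv=None)
    _require_positive(m_e1=m_e1, m_e2=m_e2)
    cv = None
    if cv_e1 is not None and cv_e2 is not None:
        cv = math.sqrt(cv_e1**2 + cv_e2**2)
    return SensitivityRecord(strain=strain, s_value=m_e1 / m_e2, cv=cv)


def _s_value(s) -> float | None:
    if isinstance(s, SensitivityRecord):
        return s.s_value
    return None if s is None else float(s)


def es_score(s_mutant, s_reference) -> float | None:
    """Environmental sensitivity score eps_env = S(ref)/S(mutant) - 1.

    The reference is the wildtype for a single mutant, or the Y single
    mutant when scoring deletion of X in a Y-deletion background.  Returns
    None when either sensitivity is undefined.
    """
    sm, sr = _s_value(s_mutant), _s_value(s_reference)
    if sm is None or sr is None:
        return None
    _require_positive(s_mutant=sm, s_reference=sr)
    return sr / sm - 1.0


def expected_double_sensitivity(s_x, s_y, s_wt) -> float:
    """Double-mutant sensitivity expected under sensitivity neutrality."""
    sx, sy, sw = _s_value(s_x), _s_value(s_y), _s_value(s_wt)
    if sx is None or sy is None or sw is None:
        raise DomainError("expected_double_sensitivity requires defined sensitivities")
    _require_positive(s_x=sx, s_y=sy, s_wt=sw)
    return sx * sy / sw


def s_score(s_xy, s_x, s_y, s_wt) -> float | None:
    """Sensitivity-based epistasis score; symmetric in the two singles.

    Returns None when any input sensitivity is undefined.
    """
    values = [_s_value(v) for v in (s_xy, s_x, s_y, s_wt)]
    if any(v is None for v in values):
        return None
    sxy, sx, sy, sw = values
    _require_positive(s_xy=sxy, s_x=sx, s_y=sy, s_wt=sw)
    return sxy * sw / (sx * sy) - 1.0


# ---------------------------------------------------------------------------
# library-level scoring
# ---------------------------------------------------------------------------


def _single_rate(
    gene: str,
    env: str,
    table: PhenotypeTable,
    estimated: Mapping[tuple[str, str], float] | None,
    overrides: frozenset,
) -> float | None:
    measured = table.get(StrainKey.single(gene), env)
    est = None if estimated is None else estimated.get((gene, env))
    if gene in overrides:
        if est is None:
            raise ValidationError(f"gene {gene} is on the estimated-rate override list but has no estimate for {env}")
        return est
    if measured is not None:
        return measured.mean_rate
    return est


def score_library(
    phenotypes: PhenotypeTable,
    families: Iterable[str] = ("F", "ES", "S"),
    e1: str | None = None,
    e2: str | None = None,
    estimated_singles: Mapping[tuple[str, str], float] | None = None,
    override_genes: Iterable[str] = (),
) -> list[EpistasisScore]:
    """Score every assayable pair/gene in the requested families.

    ``e1``/``e2`` name the reference and perturbed environments (default:
    the table's two environments in sorted order).  Measured single-mutant
    rates are used unless a gene is listed in ``override_genes``, in which
    case the pooled estimate from ``estimated_singles`` (keyed by
    (gene, environment)) substitutes for it.  Pairs missing a double-mutant
    measurement are skipped with a log message.
    """
    families = set(families)
    unknown = families - {"F", "ES", "S"}
    if unknown:
        raise ValidationError(f"unknown score families {sorted(unknown)}")
    if not families:
        return []
    envs = phenotypes.environments
    if e1 is None or e2 is None:
        if len(envs) != 2:
            raise ValidationError("e1/e2 must be named when the table does not have exactly 2 environments")
        e1 = e1 or envs[0]
        e2 = e2 or envs[1]
    overrides = frozenset(g.strip().upper() for g in override_genes)

    wt = {env: phenotypes.get(StrainKey.wildtype(), env) for env in (e1, e2)}
    need_envs = (e1, e2) if families & {"ES", "S"} else tuple(
        env for env in (e1, e2) if not phenotypes.subset(env).empty
    )
    for env in need_envs:
        if wt[env] is None:
            raise ValidationError(f"wildtype missing in environment {env!r}")

    def single(gene: str, env: str) -> float | None:
        return _single_rate(gene, env, phenotypes, estimated_singles, overrides)

    genes = phenotypes.genes
    doubles = phenotypes.frame[phenotypes.frame["gene2"] != ""]
    pairs = sorted({(r.gene1, r.gene2) for r in doubles.itertuples()})

    out: list[EpistasisScore] = []

    if "F" in families:
        for g1, g2 in pairs:
            for env in need_envs:
                d = phenotypes.get(StrainKey.double(g1, g2), env)
                mx, my = single(g1, env), single(g2, env)
                if d is None or mx is None or my is None or wt[env] is None:
                    log.info("F: pair (%s,%s) skipped in %s (missing rate)", g1, g2, env)
                    continue
                out.append(
                    EpistasisScore(
                        pair=StrainKey.double(g1, g2),
                        family="F",
                        environment_context=env,
                        epsilon=f_score(d.mean_rate, mx, my, wt[env].mean_rate),
                    )
                )

    if "ES" in families or "S" in families:
        s_wt = sensitivity(wt[e1].mean_rate, wt[e2].mean_rate)
        s_single = {g: sensitivity(single(g, e1), single(g, e2)) for g in genes}

    if "ES" in families:
        for g in genes:
            eps = es_score(s_single[g], s_wt)
            if eps is None:
                log.info("ES: gene %s skipped (sensitivity undefined)", g)
                continue
            out.append(
                EpistasisScore(
                    pair=StrainKey.single(g),
                    family="ES",
                    environment_context="cross-environment",
                    epsilon=eps,
                )
            )

    if "S" in families:
        for g1, g2 in pairs:
            d1 = phenotypes.get(StrainKey.double(g1, g2), e1)
            d2 = phenotypes.get(StrainKey.double(g1, g2), e2)
            s_xy = sensitivity(None if d1 is None else d1.mean_rate, None if d2 is None else d2.mean_rate)
            eps = s_score(s_xy, s_single[g1], s_single[g2], s_wt)
            if eps is None:
                log.info("S: pair (%s,%s) skipped (sensitivity undefined)", g1, g2)
                continue
            out.append(
                EpistasisScore(
                    pair=StrainKey.double(g1, g2),
                    family="S",
                    environment_context="cross-environment",
                    epsilon=eps,
                )
            )

    return out
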