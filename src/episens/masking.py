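"""Directional phenotypic masking within declared complexes and pathways.

In a positively regulated pathway where X acts upstream of Y, deleting X
conceals the phenotypic effect of deleting Y: the double mutant resembles
the X single mutant.  In score space, masking of Y by X corresponds to

* sensitivity family: ``eps_sen == eps_env(Y)``, i.e. the pair's S-score
  equals the masked gene's wildtype-background ES-score;
* fitness family: ``eps_fit == W_wt / W_Y - 1`` in the analysis
  environment, where W is relative fitness (growth rate).

A direction is called masking when the pairwise interaction is alleviating
(negative S-score, or positive F-score, by default), significant
(P < alpha), and the absolute difference statistic falls below the
equivalence threshold.  Both directions of every pair are always
evaluated; for genes in one physical complex, co-equivalence of mutant
phenotypes makes both directions mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenotypeTable, StrainKey, ValidationError

__all__ = [
    "MaskingRecord",
    "ComplexDefinition",
    "masking_delta",
    "detect_masking",
    "recovery_curve",
]

# alleviating sign per family: the S-family convention is negative within
# complexes (perturbation-enhanced alleviation); the fitness convention is
# a double mutant better than expected, i.e. positive eps_fit
ALLEVIATING_SIGN = {"S": -1.0, "F": +1.0}


@dataclass(frozen=True)
class MaskingRecord:
    masker: str  # upstream gene X
    masked: str  # downstream gene Y
    family: str
    delta: float
    epsilon: float
    alleviating_p: float
    is_masking: bool


@dataclass
class ComplexDefinition:
    """A named complex/pathway; every ordered pair of members is an
    expected masking direction (restricted downstream to assayed pairs)."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        self.members = {g.strip().upper() for g in self.members}
        if len(self.members) < 2:
            raise ValidationError(f"complex {self.name!r} needs >= 2 members")

    @property
    def expected_directed_interactions(self) -> set[tuple[str, str]]:
        return {(x, y) for x in self.members for y in self.members if x != y}


class _ScoreIndex:
    """Resolves the per-direction quantities from a tidy score frame and,
    for the fitness family, a phenotype table."""

    def __init__(self, scores: pd.DataFrame, phenotypes: PhenotypeTable | None = None, environment: str | None = None):
        self.environment = environment
        self.phenotypes = phenotypes
        s = scores[scores["family"] == "S"]
        self.s_pair = {(r.gene1, r.gene2): (float(r.epsilon), float(r.p_value)) for r in s.itertuples()}
        es = scores[scores["family"] == "ES"]
        self.es_gene = {r.gene1: float(r.epsilon) for r in es.itertuples()}
        f = scores[scores["family"] == "F"]
        if environment is not None:
            f = f[f["environment"] == environment]
        self.f_pair = {(r.gene1, r.gene2): (float(r.epsilon), float(r.p_value)) for r in f.itertuples()}

    def pair(self, family: str, x: str, y: str):
        key = tuple(sorted((x, y)))
        return (self.s_pair if family == "S" else self.f_pair).get(key)

    def reference(self, family: str, masked: str) -> float | None:
        if family == "S":
            return self.es_gene.get(masked)
        if self.phenotypes is None or self.environment is None:
            raise ValidationError("fitness-family masking needs phenotypes and an environment")
        wt = self.phenotypes.get(StrainKey.wildtype(), self.environment)
        single = self.phenotypes.get(StrainKey.single(masked), self.environment)
        if wt is None or single is None:
            return None
        return wt.mean_rate / single.mean_rate - 1.0

    def assayed_pairs(self, family: str) -> set[tuple[str, str]]:
        return set((self.s_pair if family == "S" else self.f_pair).keys())


def masking_delta(
    direction: tuple[str, str],
    scores: pd.DataFrame,
    family: str = "S",
    phenotypes: PhenotypeTable | None = None,
    environment: str | None = None,
) -> float | None:
    """Equivalence statistic for one directed pair (masker, masked).

    Sensitivity family: ``|eps_sen - eps_env(masked)|``; fitness family:
    ``|eps_fit - W_wt/W_masked + 1|``.  Returns None (and the direction is
    skipped by the detectors) when a required score is missing.
    """
    if family not in ("S", "F"):
        raise ValidationError(f"unknown masking family {family!r}")
    masker, masked = (g.strip().upper() for g in direction)
    index = _ScoreIndex(scores, phenotypes, environment)
    pair = index.pair(family, masker, masked)
    ref = index.reference(family, masked)
    if pair is None or ref is None:
        return None
    return abs(pair[0] - ref)


def detect_masking(
    complexes: list[ComplexDefinition],
    scores: pd.DataFrame,
    family: str = "S",
    delta_thr: float = 0.1,
    alpha: float = 0.05,
    phenotypes: PhenotypeTable | None = None,
    environment: str | None = None,
    alleviating_sign: float | None = None,
) -> list[MaskingRecord]:
    """Evaluate every directed assayed pair within the declared complexes.

    A record is masking when the interaction is alleviating (epsilon on the
    family's alleviating side), significant at ``alpha``, and its delta is
    strictly below ``delta_thr``.
    """
    sign = ALLEVIATING_SIGN[family] if alleviating_sign is None else alleviating_sign
    index = _ScoreIndex(scores, phenotypes, environment)
    records = []
    for cplx in complexes:
        for x, y in sorted(cplx.expected_directed_interactions):
            rec = _evaluate_direction(index, family, x, y, delta_thr, alpha, sign)
            if rec is not None:
                records.append(rec)
    return records


def _evaluate_direction(index: _ScoreIndex, family, x, y, delta_thr, alpha, sign) -> MaskingRecord | None:
    pair = index.pair(family, x, y)
    ref = index.reference(family, y)
    if pair is None or ref is None:
        return None
    eps, p = pair
    delta = abs(eps - ref)
    is_masking = (sign * eps > 0) and (p < alpha) and (delta < delta_thr)
    return MaskingRecord(masker=x, masked=y, family=family, delta=delta, epsilon=eps, alleviating_p=p, is_masking=is_masking)


def recovery_curve(
    complexes: list[ComplexDefinition],
    scores: pd.DataFrame,
    family: str = "S",
    delta_grid=None,
    alpha: float = 0.05,
    phenotypes: PhenotypeTable | None = None,
    environment: str | None = None,
    alleviating_sign: float | None = None,
) -> pd.DataFrame:
    """True/false positive masking rates along an equivalence-threshold grid.

    TPR is the fraction of expected (within-complex, assayed) directions
    recovered; FPR is computed over every other assayed direction in the
    scored pair universe.  Unassayed directions are excluded from both
    numerator and denominator.  Both rates are nondecreasing in the
    threshold.
    """
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 0.3, 31)
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if delta_grid.size == 0:
        raise ValidationError("empty equivalence-threshold grid")
    sign = ALLEVIATING_SIGN[family] if alleviating_sign is None else alleviating_sign
    index = _ScoreIndex(scores, phenotypes, environment)

    expected = set()
    for cplx in complexes:
        expected |= cplx.expected_directed_interactions
    directions = []
    for g1, g2 in index.assayed_pairs(family):
        directions.extend([(g1, g2), (g2, g1)])
    evaluated = []
    for x, y in directions:
        rec = _evaluate_direction(index, family, x, y, np.inf, alpha, sign)
        if rec is not None:
            evaluated.append(((x, y) in expected, rec))
    n_expected = sum(1 for is_exp, _ in evaluated if is_exp)
    n_other = len(evaluated) - n_expected
    if n_expected == 0:
        raise ValidationError("no expected masking direction is assayed")

    rows = []
    for thr in delta_grid:
        tp = sum(1 for is_exp, r in evaluated if is_exp and r.is_masking and r.delta < thr)
        fp = sum(1 for is_exp, r in evaluated if not is_exp and r.is_masking and r.delta < thr)
        rows.append(
            dict(
                delta_thr=float(thr), family=family,
                tpr=tp / n_expected,
                fpr=fp / n_other if n_other else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["delta_thr", "family", "tpr", "fpr"])
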