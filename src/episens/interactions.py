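"""Interaction calling, F-vs-S set comparison, and evidence enrichment.

Interactions are called either by a P-value threshold or as the top-k most
likely (lowest P) pairs.  For the fitness family a pair is called once,
with the smaller of its two per-environment P values, and labelled with
the four-way environment assignment.  Called sets are compared against
pairwise regulatory-evidence annotations (genetic buffering, direct
binding, shared targets) with hypergeometric over-representation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import EvidenceTable, ValidationError
from .significance import assign_environment

__all__ = [
    "CallRecord",
    "InteractionCallSet",
    "EnrichmentResult",
    "call_by_threshold",
    "call_top_k",
    "compare_call_sets",
    "delta_f_vs_s",
    "enrichment_test",
    "cobinding_test",
    "predictive_value_curve",
]


@dataclass(frozen=True)
class CallRecord:
    pair: frozenset
    epsilon: float
    p_value: float
    environment: str  # assignment label for F; "cross-environment" otherwise

    @property
    def genes(self) -> tuple[str, str]:
        return tuple(sorted(self.pair))


@dataclass
class InteractionCallSet:
    method: str  # "F" or "S" (or "ES")
    calls: list[CallRecord]
    selection_rule: str

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: (c.p_value, -abs(c.epsilon), c.genes))
        if len({c.pair for c in self.calls}) != len(self.calls):
            raise ValidationError("duplicate pairs in a call set")

    @property
    def pairs(self) -> set[frozenset]:
        return {c.pair for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)


def _pair_level(
    scores: pd.DataFrame,
    family: str,
    alpha_assign: float,
    env_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse a tidy score frame to one row per pair for one family.

    ``env_order`` names (reference, perturbed) for the F-family assignment
    labels; defaults to the sorted distinct environments of the F rows.
    """
    sub = scores[(scores["family"] == family) & (scores["gene2"] != "")]
    if family == "F":
        if env_order is None:
            env_order = tuple(sorted(sub["environment"].unique()))
        rows = []
        for (g1, g2), grp in sub.groupby(["gene1", "gene2"], sort=True):
            by_env = {r.environment: float(r.p_value) for r in grp.itertuples()}
            p1 = by_env.get(env_order[0], 1.0)
            p2 = by_env.get(env_order[1], 1.0) if len(env_order) > 1 else 1.0
            best = grp.loc[grp["p_value"].idxmin()]
            rows.append(
                dict(
                    gene1=g1, gene2=g2, epsilon=float(best["epsilon"]),
                    p_value=float(best["p_value"]),
                    environment=assign_environment(p1, p2, alpha_assign),
                )
            )
        return pd.DataFrame(rows, columns=["gene1", "gene2", "epsilon", "p_value", "environment"])
    out = sub[["gene1", "gene2", "epsilon", "p_value"]].copy()
    out["environment"] = "cross-environment"
    return out.reset_index(drop=True)


def call_by_threshold(
    scores: pd.DataFrame,
    alpha: float,
    family: str = "S",
    alpha_assign: float | None = None,
    env_order: tuple[str, str] | None = None,
) -> InteractionCallSet:
    """All pairs with P strictly below ``alpha``.

    For the F family, a pair significant in either environment is called
    once and labelled by :func:`assign_environment` (at ``alpha_assign``,
    default ``alpha``).
    """
    if scores["p_value"].isna().any():
        raise ValidationError("scores must carry P values before calling")
    level = _pair_level(scores, family, alpha if alpha_assign is None else alpha_assign, env_order)
    calls = [
        CallRecord(frozenset({r.gene1, r.gene2}), float(r.epsilon), float(r.p_value), r.environment)
        for r in level.itertuples()
        if r.p_value < alpha
    ]
    return InteractionCallSet(method=family, calls=calls, selection_rule=f"P < {alpha}")


def call_top_k(
    scores: pd.DataFrame,
    k: int,
    family: str = "S",
    alpha_assign: float = 0.01,
    env_order: tuple[str, str] | None = None,
) -> InteractionCallSet:
    """The k most likely interactions (lowest P; ties broken by larger
    absolute epsilon, then lexicographic pair name)."""
    level = _pair_level(scores, family, alpha_assign, env_order)
    if k > len(level):
        raise ValidationError(f"k = {k} exceeds the {len(level)} scored pairs")
    level = level.sort_values(
        by=["p_value", "epsilon", "gene1", "gene2"],
        key=lambda col: -col.abs() if col.name == "epsilon" else col,
        ascending=True,
    )
    calls = [
        CallRecord(frozenset({r.gene1, r.gene2}), float(r.epsilon), float(r.p_value), r.environment)
        for r in level.head(k).itertuples()
    ]
    return InteractionCallSet(method=family, calls=calls, selection_rule=f"top {k} by P")


@dataclass
class CallSetOverlap:
    shared: set[frozenset]
    only_a: set[frozenset]
    only_b: set[frozenset]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.only_a), len(self.only_b))


def compare_call_sets(a: InteractionCallSet, b: InteractionCallSet) -> CallSetOverlap:
    pa, pb = a.pairs, b.pairs
    return CallSetOverlap(shared=pa & pb, only_a=pa - pb, only_b=pb - pa)


@dataclass
class DeltaComparison:
    table: pd.DataFrame  # gene1, gene2, abs_s_score, abs_f_difference
    pearson_r: float | None
    n_excluded: int


def delta_f_vs_s(scores: pd.DataFrame, e1: str | None = None, e2: str | None = None) -> DeltaComparison:
    """Per pair: |eps_sen| against |eps_fit(E2) - eps_fit(E1)|.

    Pairs missing any of the three scores are excluded and counted.  The
    Pearson correlation is None when undefined (fewer than two pairs or a
    zero-variance column).
    """
    f = scores[(scores["family"] == "F")]
    envs = sorted(f["environment"].unique())
    if e1 is None or e2 is None:
        if len(envs) != 2:
            raise ValidationError("cannot infer the two environments from the F rows")
        e1, e2 = envs
    s = scores[scores["family"] == "S"].set_index(["gene1", "gene2"])["epsilon"]
    f1 = f[f["environment"] == e1].set_index(["gene1", "gene2"])["epsilon"]
    f2 = f[f["environment"] == e2].set_index(["gene1", "gene2"])["epsilon"]
    all_pairs = set(s.index) | set(f1.index) | set(f2.index)
    rows, excluded = [], 0
    for pair in sorted(all_pairs):
        if pair in s.index and pair in f1.index and pair in f2.index:
            rows.append(
                dict(gene1=pair[0], gene2=pair[1], abs_s_score=abs(s[pair]), abs_f_difference=abs(f2[pair] - f1[pair]))
            )
        else:
            excluded += 1
    table = pd.DataFrame(rows, columns=["gene1", "gene2", "abs_s_score", "abs_f_difference"])
    r = None
    if len(table) >= 2 and table["abs_s_score"].std() > 0 and table["abs_f_difference"].std() > 0:
        r = float(stats.pearsonr(table["abs_s_score"], table["abs_f_difference"]).statistic)
    return DeltaComparison(table=table, pearson_r=r, n_excluded=excluded)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    hits_in_calls: int
    hits_in_universe: int
    n_calls: int
    universe: int
    fold_r: float
    p_value: float


def enrichment_test(calls: InteractionCallSet, evidence: EvidenceTable, category: str = "any") -> EnrichmentResult:
    """Hypergeometric over-representation of evidence pairs among calls.

    P is the upper tail P(X >= hits_in_calls) for drawing ``len(calls)``
    pairs without replacement from a universe of ``evidence.universe_size``
    containing ``hits_in_universe`` evidence pairs; the fold enrichment R
    is the ratio of hit frequencies.
    """
    if len(calls) == 0:
        raise ValidationError("cannot test enrichment of an empty call set")
    hits_universe = evidence.count(category)
    evidence_pairs = evidence.pairs_with(category)
    hits_calls = sum(1 for p in calls.pairs if p in evidence_pairs)
    m, k_u, n = evidence.universe_size, hits_universe, len(calls)
    fold = (hits_calls / n) / (k_u / m) if k_u else float("nan")
    p = float(stats.hypergeom.sf(hits_calls - 1, m, k_u, n))
    return EnrichmentResult(
        category=category, hits_in_calls=hits_calls, hits_in_universe=k_u,
        n_calls=n, universe=m, fold_r=fold, p_value=p,
    )


def cobinding_test(targets_a, targets_b, de_universe, alpha_gene: float = 0.01) -> float:
    """Upper-tail hypergeometric P for two factors sharing bound targets.

    ``targets_a``/``targets_b`` are the differentially expressed genes bound
    by each factor; ``de_universe`` the differentially expressed gene set
    they were drawn from.  ``alpha_gene`` records the threshold used
    upstream to select differentially expressed genes (provenance only; it
    does not enter the test).
    """
    universe = set(de_universe)
    if not universe:
        raise ValidationError("empty differential-expression universe")
    a, b = set(targets_a) & universe, set(targets_b) & universe
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def predictive_value_curve(
    scores: pd.DataFrame,
    evidence: EvidenceTable,
    alphas,
    families=("F", "S"),
    alpha_assign: float = 0.01,
) -> pd.DataFrame:
    """Predictive value and TPR/FPR per method and threshold.

    Predictive value = fraction of called pairs with at least one line of
    evidence.  TPR = called evidence pairs / all evidence pairs; FPR =
    called non-evidence pairs / all non-evidence pairs, with the
    non-evidence count taken over the scored pair universe.  Thresholds
    with zero calls are omitted (flagged in the ``omitted`` column of a
    sentinel row-less frame via logging)."""
    import logging

    log = logging.getLogger(__name__)
    evidence_pairs = evidence.pairs_with("any")
    rows = []
    for family in families:
        level = _pair_level(scores, family, alpha_assign)
        universe_pairs = {frozenset({r.gene1, r.gene2}) for r in level.itertuples()}
        n_evid = len(universe_pairs & evidence_pairs)
        n_non = len(universe_pairs) - n_evid
        for alpha in alphas:
            called = {frozenset({r.gene1, r.gene2}) for r in level.itertuples() if r.p_value < alpha}
            if not called:
                log.warning("%s at alpha=%g: zero calls; point omitted", family, alpha)
                continue
            hits = len(called & evidence_pairs)
            rows.append(
                dict(
                    family=family, alpha=float(alpha), n_calls=len(called),
                    predictive_value=hits / len(called),
                    tpr=hits / n_evid if n_evid else float("nan"),
                    fpr=(len(called) - hits) / n_non if n_non else float("nan"),
                )
            )
    return pd.DataFrame(rows, columns=["family", "alpha", "n_calls", "predictive_value", "tpr", "fpr"])
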