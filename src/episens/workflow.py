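"""End-to-end scoring and significance testing of a deletion library.

:func:`analyze_library` takes a summarised phenotype table in two
environments and returns a tidy score frame with one row per
(pair-or-gene, family, environment context), carrying the epsilon and its
parametric-bootstrap P value.  This is the in-memory form the interaction,
masking and clustering analyses consume.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import PhenotypeTable, StrainKey, ValidationError
from .scores import EpistasisScore
from .significance import (
    DEFAULT_N_TRIALS,
    esscore_pvalues,
    fscore_pvalues,
    sscore_pvalues,
)

log = logging.getLogger(__name__)

__all__ = ["analyze_library", "scores_to_records", "records_to_frame"]

SCORE_COLUMNS = ["gene1", "gene2", "family", "environment", "epsilon", "p_value"]


def _env_frame(table: PhenotypeTable, env: str) -> pd.DataFrame:
    sub = table.subset(env).copy()
    if sub.empty:
        raise ValidationError(f"no phenotypes for environment {env!r}")
    # cv of the mean rate; unestimable (NaN) cvs take the library median of
    # their strain class before the 1/sqrt(n) scaling
    is_double = sub["gene2"] != ""
    for mask in (is_double, ~is_double):
        med = sub.loc[mask, "cv"].median()
        sub.loc[mask & sub["cv"].isna(), "cv"] = med
    if sub["cv"].isna().any():
        raise ValidationError(f"cannot impute replicate cvs in {env!r}: all values missing for a class")
    sub["cv_mean"] = sub["cv"] / np.sqrt(sub["n"])
    return sub


def _lookup(sub: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    return {
        (r.gene1, r.gene2): (r.rate, r.cv_mean)
        for r in sub.itertuples()
    }


def analyze_library(
    table: PhenotypeTable,
    e1: str | None = None,
    e2: str | None = None,
    families: Iterable[str] = ("F", "ES", "S"),
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    null_mean_mode: str = "per-trial",
    estimated_singles: Mapping[tuple[str, str], float] | None = None,
    override_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Score and test every assayable pair/gene of a two-environment library.

    Returns a DataFrame with columns gene1, gene2 (empty for ES rows),
    family ('F', 'ES', 'S'), environment (name for F rows,
    'cross-environment' otherwise), epsilon, p_value.  F rows additionally
    depend on both environments through the shared wildtype; the
    environment assignment of F calls is left to the interaction layer.
    """
    families = tuple(dict.fromkeys(families))
    unknown = set(families) - {"F", "ES", "S"}
    if unknown:
        raise ValidationError(f"unknown score families {sorted(unknown)}")
    envs = table.environments
    if e1 is None or e2 is None:
        if len(envs) != 2:
            raise ValidationError("e1/e2 must be named when the table does not have exactly 2 environments")
        e1, e2 = envs[0], envs[1]
    overrides = frozenset(g.strip().upper() for g in override_genes)
    rng = np.random.default_rng(seed)

    sub = {env: _env_frame(table, env) for env in (e1, e2)}
    look = {env: _lookup(sub[env]) for env in (e1, e2)}

    def wt(env):
        v = look[env].get(("", ""))
        if v is None:
            raise ValidationError(f"wildtype missing in environment {env!r}")
        return v

    m_wt = {env: wt(env) for env in (e1, e2)}

    def single(gene, env):
        measured = look[env].get((gene, ""))
        est = None if estimated_singles is None else estimated_singles.get((gene, env))
        if gene in overrides:
            if est is None:
                raise ValidationError(f"gene {gene} on override list but no estimate for {env}")
            # estimated rates inherit the measured cv when available
            cv = measured[1] if measured is not None else np.nan
            return (est, cv)
        return measured

    doubles = sorted(
        {(r.gene1, r.gene2) for env in (e1, e2) for r in sub[env].itertuples() if r.gene2 != ""}
    )
    genes = table.genes
    cv2 = {env: float(np.median([cv for (g1, g2), (r, cv) in look[env].items() if g2 != ""])) for env in (e1, e2)}

    rows: list[dict] = []

    if "F" in families:
        for env in (e1, e2):
            keep, eps, cvs = [], [], []
            for g1, g2 in doubles:
                d = look[env].get((g1, g2))
                sx, sy = single(g1, env), single(g2, env)
                if d is None or sx is None or sy is None:
                    log.info("F: pair (%s,%s) skipped in %s", g1, g2, env)
                    continue
                keep.append((g1, g2))
                eps.append(d[0] * m_wt[env][0] / (sx[0] * sy[0]) - 1.0)
                cvs.append(d[1])
            if keep:
                p = fscore_pvalues(
                    np.array(eps), np.array(cvs), cv2[env], n_trials, rng,
                    null_mean_mode=null_mean_mode,
                    ref_means=None if null_mean_mode == "per-trial" else _ref_means(keep, single, m_wt, env),
                    ref_cvs=None if null_mean_mode == "per-trial" else _ref_cvs(keep, single, m_wt, env),
                )
                for (g1, g2), e, pv in zip(keep, eps, p):
                    rows.append(dict(gene1=g1, gene2=g2, family="F", environment=env, epsilon=e, p_value=pv))

    if "ES" in families:
        keep, eps, cva1, cva2, cvw1, cvw2 = [], [], [], [], [], []
        for g in genes:
            s1v, s2v = single(g, e1), single(g, e2)
            if s1v is None or s2v is None:
                log.info("ES: gene %s skipped (missing an environment)", g)
                continue
            keep.append(g)
            eps.append(s2v[0] * m_wt[e1][0] / (s1v[0] * m_wt[e2][0]) - 1.0)
            cva1.append(s1v[1]); cva2.append(s2v[1])
            cvw1.append(m_wt[e1][1]); cvw2.append(m_wt[e2][1])
        if keep:
            p = esscore_pvalues(np.array(eps), np.array(cva1), np.array(cva2), np.array(cvw1), np.array(cvw2), n_trials, rng)
            for g, e, pv in zip(keep, eps, p):
                rows.append(dict(gene1=g, gene2="", family="ES", environment="cross-environment", epsilon=e, p_value=pv))

    if "S" in families:
        keep, eps, cvd1, cvd2 = [], [], [], []
        for g1, g2 in doubles:
            vals = {}
            ok = True
            for env in (e1, e2):
                d = look[env].get((g1, g2))
                sx, sy = single(g1, env), single(g2, env)
                if d is None or sx is None or sy is None:
                    ok = False
                    break
                vals[env] = (d, sx, sy)
            if not ok:
                log.info("S: pair (%s,%s) skipped", g1, g2)
                continue
            (d1, sx1, sy1), (d2, sx2, sy2) = vals[e1], vals[e2]
            s_xy = d1[0] / d2[0]
            s_wt = m_wt[e1][0] / m_wt[e2][0]
            s_x = sx1[0] / sx2[0]
            s_y = sy1[0] / sy2[0]
            keep.append((g1, g2))
            eps.append(s_xy * s_wt / (s_x * s_y) - 1.0)
            cvd1.append(d1[1]); cvd2.append(d2[1])
        if keep:
            p = sscore_pvalues(
                np.array(eps), np.array(cvd1), np.array(cvd2), cv2[e1], cv2[e2],
                n_trials, rng, null_mean_mode=null_mean_mode,
                ref_cvs=None if null_mean_mode == "per-trial" else _s_ref_cvs(keep, single, m_wt, e1, e2),
            )
            for (g1, g2), e, pv in zip(keep, eps, p):
                rows.append(dict(gene1=g1, gene2=g2, family="S", environment="cross-environment", epsilon=e, p_value=pv))

    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def _ref_means(pairs, single, m_wt, env):
    mx = np.array([single(g1, env)[0] for g1, _ in pairs])
    my = np.array([single(g2, env)[0] for _, g2 in pairs])
    mw = np.full(len(pairs), m_wt[env][0])
    return (mx, my, mw)


def _ref_cvs(pairs, single, m_wt, env):
    cx = np.array([single(g1, env)[1] for g1, _ in pairs])
    cy = np.array([single(g2, env)[1] for _, g2 in pairs])
    cw = np.full(len(pairs), m_wt[env][1])
    return (cx, cy, cw)


def _s_ref_cvs(pairs, single, m_wt, e1, e2):
    out = []
    for env in (e1, e2):
        out.append(np.array([single(g1, env)[1] for g1, _ in pairs]))
        out.append(np.array([single(g2, env)[1] for _, g2 in pairs]))
        out.append(np.full(len(pairs), m_wt[env][1]))
    x1, y1, w1, x2, y2, w2 = out
    return (x1, y1, w1, x2, y2, w2)


def scores_to_records(frame: pd.DataFrame) -> list[EpistasisScore]:
    """Convert a tidy score frame into EpistasisScore objects."""
    out = []
    for r in frame.itertuples():
        pair = StrainKey.from_fields(r.gene1 or None, r.gene2 or None)
        out.append(
            EpistasisScore(
                pair=pair, family=r.family, environment_context=r.environment,
                epsilon=float(r.epsilon),
                p_value=None if pd.isna(r.p_value) else float(r.p_value),
            )
        )
    return out


def records_to_frame(records: Iterable[EpistasisScore]) -> pd.DataFrame:
    rows = []
    for s in records:
        g = s.pair.genes
        rows.append(
            dict(
                gene1=g[0] if g else "",
                gene2=g[1] if len(g) == 2 else "",
                family=s.family,
                environment=s.environment_context,
                epsilon=s.epsilon,
                p_value=np.nan if s.p_value is None else s.p_value,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
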