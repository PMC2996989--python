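"""Synthetic two-environment deletion libraries with planted interactions.

The generator emulates a wildtype + single + double deletion library grown
in a reference environment (``untreated``) and a perturbed one (``mms``).
True double-mutant rates follow the multiplicative neutrality law
perturbed by a planted interaction strength:

    m(X,Y,E) = (1 + eps_fit(E)) * m(X,E) * m(Y,E) / m(wt,E)

Replicate rates are the true rate times ``1 + Normal(0, cv)`` (truncated
positive; lognormal optionally).  The planted truth is emitted alongside,
including the implied sensitivity-based scores via the exact identity
``eps_sen = (1 + eps_fit(E1)) / (1 + eps_fit(E2)) - 1``.

Replicate counts default to 19 for wildtype/single strains and 4 for
doubles, the floor of a realistic microplate screen; default replicate cv
is 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import PhenotypeTable, StrainKey, ValidationError
from .growth import GrowthCurve

__all__ = [
    "PlantedInteraction",
    "SyntheticLibrarySpec",
    "SyntheticTruth",
    "generate_library",
    "generate_od_curves",
    "sample_null_pair_stats",
    "standard_scenarios",
    "scenario_spec",
    "E1",
    "E2",
]

E1 = "untreated"
E2 = "mms"


@dataclass(frozen=True)
class PlantedInteraction:
    gene_a: str
    gene_b: str
    eps: Mapping[str, float]  # environment -> eps_fit

    def __post_init__(self) -> None:
        for env, e in self.eps.items():
            if e <= -1:
                raise ValidationError(f"planted eps_fit must be > -1, got {e} in {env}")


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Complete description of a synthetic library experiment."""

    n_genes: int = 26
    wt_rate: Mapping[str, float] = field(default_factory=lambda: {E1: 0.0077, E2: 0.0062})
    single_effects: Mapping[str, Mapping[str, float]] | None = None  # gene -> env -> relative fitness
    planted: tuple[PlantedInteraction, ...] = ()
    replicate_cv: Mapping[str, float] = field(default_factory=lambda: {E1: 0.03, E2: 0.03})
    n_replicates: Mapping[str, int] = field(default_factory=lambda: {"wildtype": 19, "single": 19, "double": 4})
    missing_fraction: float = 0.0
    seed: int = 0
    noise: str = "normal"  # or "lognormal"
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("need at least 2 genes")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in [0, 1)")
        for env, rate in self.wt_rate.items():
            if rate <= 0:
                raise ValidationError(f"wildtype rate must be positive in {env}")
        for env, cv in self.replicate_cv.items():
            if cv < 0:
                raise ValidationError(f"replicate cv must be >= 0 in {env}")
        if self.noise not in ("normal", "lognormal"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValidationError("gene_names length must equal n_genes")

    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(self.wt_rate.keys())

    def genes(self) -> tuple[str, ...]:
        if self.gene_names is not None:
            return tuple(g.upper() for g in self.gene_names)
        width = len(str(self.n_genes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-pair eps_fit in each environment, the
    implied eps_sen, and per-gene true ES-scores."""

    pair_truth: pd.DataFrame  # gene1, gene2, eps_<env>..., eps_sen, assayed
    gene_truth: pd.DataFrame  # gene, w_<env>..., es_true
    true_rates: pd.DataFrame  # gene1, gene2, environment, rate

    def planted_pairs(self, min_abs_eps: float = 0.0, env: str | None = None) -> set[frozenset]:
        cols = [c for c in self.pair_truth.columns if c.startswith("eps_") and c != "eps_sen"]
        if env is not None:
            cols = [f"eps_{env}"]
        sel = self.pair_truth[self.pair_truth[cols].abs().max(axis=1) > min_abs_eps]
        return {frozenset({r.gene1, r.gene2}) for r in sel.itertuples()}

    def modulated_pairs(self, min_abs_eps_sen: float = 0.0) -> set[frozenset]:
        sel = self.pair_truth[self.pair_truth["eps_sen"].abs() > min_abs_eps_sen]
        return {frozenset({r.gene1, r.gene2}) for r in sel.itertuples()}


def _default_effects(genes, envs, rng) -> dict[str, dict[str, float]]:
    # mild fitness defects untreated, broader defects under the perturbation
    lo = {0: 0.85, 1: 0.60}
    hi = {0: 1.00, 1: 1.00}
    return {
        g: {env: float(rng.uniform(lo[k], hi[k])) for k, env in enumerate(envs)}
        for g in genes
    }


def _draw_replicates(true_rate: float, cv: float, n: int, rng, noise: str) -> np.ndarray:
    if cv == 0:
        return np.full(n, true_rate)
    if noise == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return true_rate * rng.lognormal(-sigma**2 / 2, sigma, size=n)
    draws = true_rate * (1 + rng.normal(0, cv, size=n))
    bad = draws <= 0
    while bad.any():
        draws[bad] = true_rate * (1 + rng.normal(0, cv, size=int(bad.sum())))
        bad = draws <= 0
    return draws


def generate_library(spec: SyntheticLibrarySpec) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Draw a full replicate-level library and summarise it.

    Returns the summarised phenotype table (with the replicate draws
    attached as ``table.replicates``) and the planted truth.
    """
    rng = np.random.default_rng(spec.seed)
    envs = spec.environments
    if len(envs) != 2:
        raise ValidationError("the generator models exactly two environments")
    genes = spec.genes()
    effects = spec.single_effects or _default_effects(genes, envs, rng)
    for g in genes:
        if g not in effects:
            raise ValidationError(f"no single-mutant effect declared for gene {g}")
    planted = {}
    for p in spec.planted:
        key = tuple(sorted((p.gene_a.upper(), p.gene_b.upper())))
        if key[0] not in genes or key[1] not in genes:
            raise ValidationError(f"planted pair {key} outside the gene set")
        planted[key] = p.eps

    e1, e2 = envs
    true_rates: dict[tuple[str, str, str], float] = {}
    for env in envs:
        m_wt = spec.wt_rate[env]
        true_rates[("", "", env)] = m_wt
        for g in genes:
            true_rates[(g, "", env)] = effects[g][env] * m_wt
    pair_rows = []
    assay = {}
    all_pairs = [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]
    for g1, g2 in all_pairs:
        assay[(g1, g2)] = bool(rng.random() >= spec.missing_fraction)
        eps = planted.get((g1, g2), {})
        e_by_env = {env: float(eps.get(env, 0.0)) for env in envs}
        for env in envs:
            m_wt = spec.wt_rate[env]
            expected = true_rates[(g1, "", env)] * true_rates[(g2, "", env)] / m_wt
            true_rates[(g1, g2, env)] = (1.0 + e_by_env[env]) * expected
        eps_sen = (1.0 + e_by_env[e1]) / (1.0 + e_by_env[e2]) - 1.0
        pair_rows.append(
            dict(
                gene1=g1, gene2=g2,
                **{f"eps_{env}": e_by_env[env] for env in envs},
                eps_sen=eps_sen, assayed=assay[(g1, g2)],
            )
        )

    records, rep_rows = [], []
    for (g1, g2, env), rate in sorted(true_rates.items()):
        if g2 != "" and not assay[(g1, g2)]:
            continue
        if g1 == "":
            strain, n = StrainKey.wildtype(), spec.n_replicates["wildtype"]
        elif g2 == "":
            strain, n = StrainKey.single(g1), spec.n_replicates["single"]
        else:
            strain, n = StrainKey.double(g1, g2), spec.n_replicates["double"]
        draws = _draw_replicates(rate, spec.replicate_cv[env], n, rng, spec.noise)
        mean = float(draws.mean())
        cv = float(draws.std(ddof=1) / mean) if n > 1 else np.nan
        records.append((strain, env, mean, cv, n))
        for rep, value in enumerate(draws, start=1):
            rep_rows.append(dict(gene1=g1, gene2=g2, environment=env, replicate=rep, rate=float(value)))

    table = PhenotypeTable.from_records(records, replicates=pd.DataFrame(rep_rows))
    gene_truth = pd.DataFrame(
        [
            dict(
                gene=g,
                **{f"w_{env}": effects[g][env] for env in envs},
                es_true=effects[g][e2] / effects[g][e1] - 1.0,
            )
            for g in genes
        ]
    )
    rates_frame = pd.DataFrame(
        [dict(gene1=k[0], gene2=k[1], environment=k[2], rate=v) for k, v in sorted(true_rates.items())]
    )
    truth = SyntheticTruth(pair_truth=pd.DataFrame(pair_rows), gene_truth=gene_truth, true_rates=rates_frame)
    return table, truth


def generate_od_curves(
    phenotypes: PhenotypeTable,
    od0: float = 0.08,
    interval_min: float = 15.0,
    duration_min: float = 600.0,
    od_noise_cv: float = 0.0,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Exponential OD600 courses consistent with a phenotype table.

    One curve per replicate; replicate-level rates are used when the table
    carries them, otherwise the mean rate is reused for each replicate.
    OD(t) = od0 * exp(rate * t) with multiplicative noise of CV
    ``od_noise_cv``.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    curves = []
    if phenotypes.replicates is not None:
        iterator = [
            (StrainKey.from_fields(r.gene1 or None, r.gene2 or None), r.environment, int(r.replicate), float(r.rate))
            for r in phenotypes.replicates.itertuples()
        ]
    else:
        iterator = []
        for row in phenotypes.frame.itertuples():
            strain = StrainKey.from_fields(row.gene1 or None, row.gene2 or None)
            iterator.extend((strain, row.environment, rep, float(row.rate)) for rep in range(1, int(row.n) + 1))
    for strain, env, rep, rate in iterator:
        od = od0 * np.exp(rate * times)
        if od_noise_cv > 0:
            od = od * (1 + rng.normal(0, od_noise_cv, size=times.size))
            od = np.abs(od)  # OD readings cannot be negative
        curves.append(GrowthCurve(strain=strain, environment=env, replicate_id=rep, times=times, od=od))
    return curves


def sample_null_pair_stats(
    n_pairs: int,
    replicate_cv: float = 0.03,
    n_single: int = 19,
    n_double: int = 4,
    w_x: float = 0.9,
    w_y: float = 0.85,
    seed: int = 0,
    eps_true: tuple[float, float] = (0.0, 0.0),
    two_environments: bool = True,
) -> pd.DataFrame:
    """Independent pair experiments for significance calibration/power runs.

    Each of ``n_pairs`` pairs gets its own wildtype, single and double
    replicate sets in one or two environments (truth follows the
    multiplicative law perturbed by ``eps_true`` per environment).  Returns
    measured means and mean-rate CVs per strain and environment — the
    direct inputs of the bootstrap tests.
    """
    rng = np.random.default_rng(seed)
    envs = [E1, E2] if two_environments else [E1]
    wt_rate = {E1: 0.0077, E2: 0.0062}
    # gene Y carries an extra perturbed-environment defect; gene X does not,
    # so (X, wt) rows also satisfy the gene-environment null S(X) = S(wt)
    w2 = {E1: 1.0, E2: 0.8}
    rows = []
    for k, env in enumerate(envs):
        m_wt = wt_rate[env]
        m_x = w_x * m_wt
        m_y = w_y * w2[env] * m_wt
        m_xy = (1.0 + eps_true[k]) * m_x * m_y / m_wt
        for label, true, n in (
            ("wt", m_wt, n_single), ("x", m_x, n_single), ("y", m_y, n_single), ("xy", m_xy, n_double),
        ):
            draws = true * (1 + rng.normal(0, replicate_cv, size=(n_pairs, n)))
            bad = draws <= 0
            while bad.any():
                draws[bad] = true * (1 + rng.normal(0, replicate_cv, size=int(bad.sum())))
                bad = draws <= 0
            mean = draws.mean(axis=1)
            cvm = draws.std(axis=1, ddof=1) / mean / np.sqrt(n)
            rows.append(pd.DataFrame({"pair": np.arange(n_pairs), "strain": label, "environment": env, "mean": mean, "cv_mean": cvm}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# standard scenarios
# ---------------------------------------------------------------------------


def _complex_spec(seed: int) -> SyntheticLibrarySpec:
    """Three planted complexes on a 26-gene background.

    Complex members share a phenotype (equal relative fitness per
    environment).  The middle complex is purely co-equivalent (the double
    equals the single: masking holds for both fitness and sensitivity);
    the other two give the double an extra environment-independent defect
    g = 0.8, which preserves sensitivity masking (the factor cancels from
    the rate ratio) but breaks fitness masking.
    """
    rng = np.random.default_rng(seed + 1)
    n = 26
    width = len(str(n))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(n))
    complexes = {
        "rad6_like": (genes[0:3], {E1: 0.90, E2: 0.60}, 0.8),
        "shu_like": (genes[3:7], {E1: 0.95, E2: 0.70}, 1.0),
        "hrr_like": (genes[7:10], {E1: 0.85, E2: 0.55}, 0.8),
    }
    effects: dict[str, dict[str, float]] = {}
    planted: list[PlantedInteraction] = []
    for members, w, g_factor in complexes.values():
        for gene in members:
            effects[gene] = dict(w)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                planted.append(
                    PlantedInteraction(
                        members[i], members[j],
                        {env: g_factor / w[env] - 1.0 for env in (E1, E2)},
                    )
                )
    for gene in genes[10:]:
        effects[gene] = {E1: float(rng.uniform(0.85, 1.0)), E2: float(rng.uniform(0.6, 1.0))}
    return SyntheticLibrarySpec(
        n_genes=n, gene_names=genes, single_effects=effects,
        planted=tuple(planted), missing_fraction=0.028, seed=seed,
    )


def _all_pairs_planted(n_genes: int, eps: dict[str, float], seed: int, **kw) -> SyntheticLibrarySpec:
    width = len(str(n_genes))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(n_genes))
    planted = tuple(
        PlantedInteraction(genes[i], genes[j], eps)
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
    )
    return SyntheticLibrarySpec(n_genes=n_genes, gene_names=genes, planted=planted, seed=seed, **kw)


def _two_module_spec(seed: int, cv: float = 0.02) -> SyntheticLibrarySpec:
    n = 10
    genes = tuple(f"G{i + 1:02d}" for i in range(n))
    modules = [genes[:5], genes[5:]]
    within = {E1: 0.0, E2: 1.0 / 0.6 - 1.0}     # eps_sen = -0.4
    between = {E1: 0.0, E2: 1.0 / 1.3 - 1.0}    # eps_sen = +0.3
    planted = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (genes[i] in modules[0]) == (genes[j] in modules[0])
            planted.append(PlantedInteraction(genes[i], genes[j], within if same else between))
    return SyntheticLibrarySpec(
        n_genes=n, gene_names=genes, planted=tuple(planted), seed=seed,
        replicate_cv={E1: cv, E2: cv},
    )


def _null_spec(seed: int) -> SyntheticLibrarySpec:
    """No interactions of any kind: no planted pairwise epistasis and
    environment-independent single-mutant effects (every gene's relative
    fitness is the same in both environments, so true ES-scores are 0)."""
    rng = np.random.default_rng(seed + 1)
    n = 26
    width = len(str(n))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(n))
    effects = {}
    for g in genes:
        w = float(rng.uniform(0.85, 1.0))
        effects[g] = {E1: w, E2: w}
    return SyntheticLibrarySpec(
        n_genes=n, gene_names=genes, single_effects=effects,
        missing_fraction=0.028, seed=seed,
    )


def standard_scenarios(seed: int = 0) -> dict[str, SyntheticLibrarySpec]:
    """Named presets covering the analyses' designed contrasts.

    * ``null`` — 26 genes, no interactions, ~2.8% of doubles unassayed.
    * ``static`` — every pair interacts equally in both environments
      (eps_fit = 0.3): detectable by fitness, invisible to sensitivity.
    * ``modulated`` — every pair interacts only under the perturbation
      (eps_fit 0 vs -0.4): the sensitivity-based signature.
    * ``complex`` — three complexes with masking planted on sensitivity
      (one of them also on fitness) plus background genes.
    * ``two_module`` — two 5-gene modules with alleviating interactions
      within and aggravating between, for profile clustering.
    """
    return {
        "null": _null_spec(seed),
        "static": _all_pairs_planted(21, {E1: 0.3, E2: 0.3}, seed),
        "modulated": _all_pairs_planted(21, {E1: 0.0, E2: -0.4}, seed),
        "complex": _complex_spec(seed),
        "two_module": _two_module_spec(seed),
    }


def scenario_spec(name: str, seed: int = 0) -> SyntheticLibrarySpec:
    scenarios = standard_scenarios(seed)
    if name not in scenarios:
        raise ValidationError(f"unknown scenario {name!r}; known: {sorted(scenarios)}")
    return scenarios[name]
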