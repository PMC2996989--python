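"""Tabular input/output and strain identity.

All tables are tab-delimited UTF-8 text with a header row; lines starting
with ``#`` are treated as comments.  Gene symbols are upper-cased on read
(yeast convention) so that pair identity never depends on capitalisation,
and strain keys are unordered: the double deletion of X and Y is the same
strain as the double deletion of Y and X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "StrainKey",
    "EnvironmentLabel",
    "StrainPhenotype",
    "PhenotypeTable",
    "EvidenceTable",
    "EVIDENCE_CATEGORIES",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_score_table",
    "write_score_table",
    "read_evidence_table",
    "read_complex_table",
]

EVIDENCE_CATEGORIES = frozenset({"buffering", "direct_binding", "shared_target"})


class FormatError(ValueError):
    """A file does not have the expected layout (e.g. a missing column)."""


class ValidationError(ValueError):
    """Well-formed input that violates a type invariant; messages are
    row-addressed where a row is identifiable."""


# ---------------------------------------------------------------------------
# strain / environment identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainKey:
    """Unordered identity of a deletion strain.

    ``deleted_genes`` holds 0, 1 or 2 gene symbols; the empty set is the
    wildtype reference.  Keys compare equal regardless of gene order.
    """

    deleted_genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = frozenset(g.strip().upper() for g in self.deleted_genes)
        if len(genes) > 2:
            raise ValidationError(f"a strain carries at most 2 deletions, got {sorted(genes)}")
        if any(not g for g in genes):
            raise ValidationError("gene symbols must be non-empty strings")
        object.__setattr__(self, "deleted_genes", genes)

    @classmethod
    def wildtype(cls) -> "StrainKey":
        return cls(frozenset())

    @classmethod
    def single(cls, gene: str) -> "StrainKey":
        return cls(frozenset({gene}))

    @classmethod
    def double(cls, gene_a: str, gene_b: str) -> "StrainKey":
        key = cls(frozenset({gene_a, gene_b}))
        if len(key.deleted_genes) != 2:
            raise ValidationError(f"double mutant needs two distinct genes, got {gene_a!r}, {gene_b!r}")
        return key

    @classmethod
    def from_fields(cls, gene1: str | None, gene2: str | None) -> "StrainKey":
        genes = [g for g in (gene1, gene2) if g is not None and str(g).strip() not in ("", "nan")]
        return cls(frozenset(str(g) for g in genes))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.deleted_genes))

    @property
    def is_wildtype(self) -> bool:
        return len(self.deleted_genes) == 0

    @property
    def is_single(self) -> bool:
        return len(self.deleted_genes) == 1

    @property
    def is_double(self) -> bool:
        return len(self.deleted_genes) == 2

    def label(self) -> str:
        return ",".join(self.genes) if self.deleted_genes else "wt"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StrainKey({self.label()})"


@dataclass(frozen=True)
class EnvironmentLabel:
    """A named environment and its role in the two-environment design.

    ``role`` is ``"reference"`` (E1, untreated) or ``"perturbed"`` (E2,
    e.g. drug-treated).  Sensitivity is defined as rate(E1)/rate(E2).
    """

    name: str
    role: str = "reference"

    def __post_init__(self) -> None:
        if self.role not in ("reference", "perturbed"):
            raise ValidationError(f"environment role must be 'reference' or 'perturbed', got {self.role!r}")


@dataclass(frozen=True)
class StrainPhenotype:
    """Growth-rate summary of one strain in one environment."""

    strain: StrainKey
    environment: str
    mean_rate: float
    cv: float
    n: int


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = ["gene1", "gene2", "environment", "rate", "cv", "n"]


@dataclass
class PhenotypeTable:
    """Summarised growth rates: one row per (strain, environment).

    Backed by a DataFrame with columns gene1, gene2 (empty for wildtype /
    single), environment, rate (1/min), cv (dimensionless, replicate-level
    sd/mean), n (replicate count).  ``replicates`` optionally carries the
    per-replicate rates the summary was computed from.
    """

    frame: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.frame = _validate_phenotypes(self.frame)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def environments(self) -> list[str]:
        return sorted(self.frame["environment"].unique())

    @property
    def genes(self) -> list[str]:
        singles = self.frame.loc[self.frame["gene2"] == "", "gene1"]
        doubles = self.frame.loc[self.frame["gene2"] != "", ["gene1", "gene2"]]
        return sorted(set(singles[singles != ""]) | set(doubles.to_numpy().ravel()))

    def get(self, strain: StrainKey, environment: str) -> StrainPhenotype | None:
        g = strain.genes
        g1 = g[0] if len(g) >= 1 else ""
        g2 = g[1] if len(g) == 2 else ""
        sel = self.frame[
            (self.frame["gene1"] == g1)
            & (self.frame["gene2"] == g2)
            & (self.frame["environment"] == environment)
        ]
        if sel.empty:
            return None
        row = sel.iloc[0]
        return StrainPhenotype(strain, environment, float(row["rate"]), float(row["cv"]), int(row["n"]))

    def strains(self) -> list[StrainKey]:
        keys = {
            StrainKey.from_fields(r.gene1 or None, r.gene2 or None)
            for r in self.frame.itertuples()
        }
        return sorted(keys, key=lambda k: (len(k.genes), k.genes))

    def subset(self, environment: str) -> pd.DataFrame:
        return self.frame[self.frame["environment"] == environment]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[StrainKey, str, float, float, int]],
        replicates: pd.DataFrame | None = None,
    ) -> "PhenotypeTable":
        rows = []
        for strain, env, rate, cv, n in records:
            g = strain.genes
            rows.append(
                {
                    "gene1": g[0] if len(g) >= 1 else "",
                    "gene2": g[1] if len(g) == 2 else "",
                    "environment": env,
                    "rate": rate,
                    "cv": cv,
                    "n": n,
                }
            )
        return cls(pd.DataFrame(rows, columns=_PHENO_COLUMNS), replicates=replicates)


def _normalise_gene(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    s = str(value).strip().upper()
    return "" if s in ("", "NAN", "-") else s


def _validate_phenotypes(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for col in _PHENO_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"phenotype table is missing column {col!r}")
    frame["gene1"] = frame["gene1"].map(_normalise_gene)
    frame["gene2"] = frame["gene2"].map(_normalise_gene)
    # canonical order inside the pair; singles always occupy gene1
    swap = (frame["gene1"] == "") & (frame["gene2"] != "")
    frame.loc[swap, ["gene1", "gene2"]] = frame.loc[swap, ["gene2", "gene1"]].to_numpy()
    flip = (frame["gene2"] != "") & (frame["gene1"] > frame["gene2"])
    frame.loc[flip, ["gene1", "gene2"]] = frame.loc[flip, ["gene2", "gene1"]].to_numpy()
    frame["environment"] = frame["environment"].astype(str)
    for col, kind in (("rate", float), ("cv", float), ("n", int)):
        frame[col] = frame[col].astype(kind)
    for i, row in enumerate(frame.itertuples(), start=1):
        if row.gene1 != "" and row.gene1 == row.gene2:
            raise ValidationError(f"row {i}: duplicate gene symbol in pair ({row.gene1})")
        if not row.rate > 0:
            raise ValidationError(f"row {i}: non-positive growth rate {row.rate}")
        if row.cv < 0:
            raise ValidationError(f"row {i}: negative cv {row.cv}")
        if row.n < 1:
            raise ValidationError(f"row {i}: replicate count must be >= 1, got {row.n}")
    dup = frame.duplicated(subset=["gene1", "gene2", "environment"])
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise ValidationError(f"row {first}: duplicate (strain, environment) entry")
    return frame.reset_index(drop=True)


def read_phenotype_table(path: str | Path, dialect: str = "tsv") -> PhenotypeTable:
    """Read a summarised phenotype table.

    Expected columns: gene1, gene2, environment, rate, and either cv or sd
    (sd is converted to cv = sd/rate), plus n.  An optional ``strain`` label
    column is ignored for identity.
    """
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene1": str, "gene2": str})
    if "cv" not in frame.columns:
        if "sd" not in frame.columns:
            raise FormatError("phenotype table is missing column 'cv' (or 'sd')")
        if "rate" not in frame.columns:
            raise FormatError("phenotype table is missing column 'rate'")
        frame["cv"] = frame["sd"].astype(float) / frame["rate"].astype(float)
    frame = frame.drop(columns=[c for c in ("strain", "sd") if c in frame.columns])
    return PhenotypeTable(frame)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["gene1", "gene2", "score_type", "environment", "epsilon", "p_value"]


def write_score_table(scores, path: str | Path) -> None:
    """Write epistasis scores as TSV (gene1, gene2, score_type, environment,
    epsilon, p_value).  ``p_value`` is 'NA' when not computed."""
    scores = list(scores)
    if not scores:
        raise ValidationError("refusing to write an empty score table")
    rows = []
    for s in scores:
        g = s.pair.genes
        rows.append(
            {
                "gene1": g[0] if len(g) >= 1 else "",
                "gene2": g[1] if len(g) == 2 else "",
                "score_type": s.family,
                "environment": s.environment_context,
                "epsilon": s.epsilon,
                "p_value": "NA" if s.p_value is None else repr(float(s.p_value)),
            }
        )
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_table(path: str | Path):
    """Inverse of :func:`write_score_table`; returns a list of EpistasisScore."""
    from .scores import EpistasisScore  # local import to avoid a cycle

    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene1": str, "gene2": str})
    for col in _SCORE_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"score table is missing column {col!r}")
    out = []
    for row in frame.itertuples():
        pair = StrainKey.from_fields(row.gene1, row.gene2 if isinstance(row.gene2, str) else None)
        p = None if (isinstance(row.p_value, float) and np.isnan(row.p_value)) or row.p_value == "NA" else float(row.p_value)
        out.append(
            EpistasisScore(
                pair=pair,
                family=str(row.score_type),
                environment_context=str(row.environment),
                epsilon=float(row.epsilon),
                p_value=p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------


@dataclass
class EvidenceTable:
    """Pairwise regulatory-evidence annotations over a declared pair universe.

    ``pair_evidence`` maps an unordered gene pair to the set of evidence
    categories supporting it (genetic buffering, direct binding of one
    factor to the other's gene, shared differentially-expressed targets).
    ``universe_size`` is the number of pairs tested, which is generally
    larger than the number of annotated pairs.
    """

    pair_evidence: dict[frozenset, set[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < len(self.pair_evidence):
            raise ValidationError(
                f"universe_size {self.universe_size} smaller than the "
                f"{len(self.pair_evidence)} annotated pairs"
            )
        for pair, cats in self.pair_evidence.items():
            unknown = set(cats) - EVIDENCE_CATEGORIES
            if unknown:
                raise ValidationError(f"unknown evidence categories {sorted(unknown)} for pair {sorted(pair)}")

    def categories(self, gene_a: str, gene_b: str) -> set[str]:
        return set(self.pair_evidence.get(frozenset({gene_a.upper(), gene_b.upper()}), set()))

    def pairs_with(self, category: str) -> set[frozenset]:
        if category == "any":
            return set(self.pair_evidence)
        if category not in EVIDENCE_CATEGORIES:
            raise ValidationError(f"unknown evidence category {category!r}")
        return {p for p, cats in self.pair_evidence.items() if category in cats}

    def count(self, category: str) -> int:
        return len(self.pairs_with(category))


def read_evidence_table(path: str | Path, universe_size: int | None = None) -> EvidenceTable:
    """Read (gene1, gene2, category) rows; pairs are keyed unordered.

    The pair universe can be declared with a ``# universe=N`` comment line;
    otherwise it defaults to the number of distinct pairs listed (or the
    explicit ``universe_size`` argument).
    """
    path = Path(path)
    declared = None
    with path.open() as handle:
        for line in handle:
            if line.startswith("#") and "universe" in line:
                declared = int(line.split("=", 1)[1].strip())
                break
            if not line.startswith("#"):
                break
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene1", "gene2", "category"):
        if col not in frame.columns:
            raise FormatError(f"evidence table is missing column {col!r}")
    evidence: dict[frozenset, set[str]] = {}
    for i, row in enumerate(frame.itertuples(), start=1):
        cat = str(row.category).strip()
        if cat not in EVIDENCE_CATEGORIES:
            raise ValidationError(f"row {i}: unknown evidence category {cat!r}")
        pair = frozenset({_normalise_gene(row.gene1), _normalise_gene(row.gene2)})
        if len(pair) != 2 or "" in pair:
            raise ValidationError(f"row {i}: evidence rows need two distinct gene symbols")
        evidence.setdefault(pair, set()).add(cat)
    size = universe_size if universe_size is not None else (declared if declared is not None else len(evidence))
    return EvidenceTable(pair_evidence=evidence, universe_size=size)


def read_complex_table(path: str | Path) -> dict[str, set[str]]:
    """Read complex membership (columns complex_name, gene) into a mapping."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("complex_name", "gene"):
        if col not in frame.columns:
            raise FormatError(f"complex table is missing column {col!r}")
    out: dict[str, set[str]] = {}
    for row in frame.itertuples():
        out.setdefault(str(row.complex_name).strip(), set()).add(_normalise_gene(row.gene))
    return out
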