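"""Rank aggregation across the four stability algorithms.

Each algorithm orders the candidate reference genes from most to least
stable; the comprehensive ranking is the geometric mean of a gene's four
ranks (the RefFinder rule).  Ranks are competition ("min") ranks: tied
values share the smallest applicable rank, and the next distinct value
skips the absorbed positions — the convention required for the stepwise
pairwise-variation algorithm, whose final two genes are a structural tie
at rank 1 with the next gene at rank 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import ArityError, CtIntegrityError
from .stability import ALGORITHMS, StabilityTable

__all__ = [
    "ConsensusRanking",
    "assign_ranks",
    "geometric_mean_rank",
    "comprehensive_ranking",
    "ranks_from_ordering",
    "consensus_from_orderings",
]


def assign_ranks(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Ascending competition ranks ("min" method) for stability values.

    Lower value = better = smaller rank.  Ties (on the unrounded values)
    share the smallest applicable rank; the next distinct value receives
    1 + the count of strictly better genes.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ArityError("cannot rank an empty value vector")
    if (values < 0).any():
        raise ValueError("stability values must be >= 0")
    return stats.rankdata(values, method="min").astype(int)


def geometric_mean_rank(rank_vector: Sequence[int] | np.ndarray) -> float:
    """Geometric mean of a gene's per-algorithm ranks: (prod r)^(1/k)."""
    r = np.asarray(rank_vector, dtype=float)
    if r.size == 0:
        raise ArityError("rank vector is empty")
    if (r < 1).any():
        raise ValueError("ranks must be >= 1")
    return float(np.exp(np.mean(np.log(r))))


def ranks_from_ordering(
    ordering: Sequence, genes: Sequence[str] | None = None
) -> dict[str, int]:
    """Competition ranks from a best-to-worst ordering.

    Elements may be gene symbols or tuples of symbols for tied positions
    (e.g. the stepwise algorithm's tied best pair); every member of a tie
    shares the smallest applicable rank and subsequent genes skip the
    absorbed positions.
    """
    ranks: dict[str, int] = {}
    pos = 1
    for entry in ordering:
        group = (entry,) if isinstance(entry, str) else tuple(entry)
        for g in group:
            if g in ranks:
                raise CtIntegrityError(f"gene {g!r} listed twice in ordering")
            ranks[g] = pos
        pos += len(group)
    if genes is not None and set(genes) != set(ranks):
        raise CtIntegrityError(
            f"ordering covers {sorted(ranks)} but expected {sorted(genes)}"
        )
    return ranks


@dataclass
class ConsensusRanking:
    """Per-gene rank vector across algorithms plus the geomean consensus.

    ``rank_matrix`` has one row per gene (order = ``genes``) and one
    column per algorithm (order = ``algorithms``).  ``order`` lists genes
    best-first by geometric mean, ties broken alphabetically (flagged in
    ``tied_geomean``).
    """

    stratum: str
    genes: list[str]
    algorithms: tuple[str, ...]
    rank_matrix: np.ndarray
    geomean: np.ndarray = field(init=False)
    order: list[str] = field(init=False)
    tied_geomean: bool = field(init=False)

    def __post_init__(self) -> None:
        self.rank_matrix = np.asarray(self.rank_matrix, dtype=int)
        G = len(self.genes)
        if self.rank_matrix.shape != (G, len(self.algorithms)):
            raise CtIntegrityError("rank matrix shape mismatch")
        if (self.rank_matrix < 1).any() or (self.rank_matrix > G).any():
            raise ValueError("ranks must lie in [1, G]")
        self.geomean = np.array(
            [geometric_mean_rank(row) for row in self.rank_matrix]
        )
        key = sorted(range(G), key=lambda i: (self.geomean[i], self.genes[i]))
        self.order = [self.genes[i] for i in key]
        gm = np.sort(self.geomean)
        self.tied_geomean = bool(np.any(np.isclose(gm[1:], gm[:-1])))

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def worst(self) -> str:
        return self.order[-1]

    def gene_geomean(self, gene: str, decimals: int | None = 2) -> float:
        v = float(self.geomean[self.genes.index(gene)])
        return round(v, decimals) if decimals is not None else v

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per gene, best first."""
        rows = []
        for g in self.order:
            i = self.genes.index(g)
            row: dict = {"stratum": self.stratum, "gene": g,
                         "geomean": round(float(self.geomean[i]), 2)}
            for j, alg in enumerate(self.algorithms):
                row[f"rank_{alg}"] = int(self.rank_matrix[i, j])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "algorithms": list(self.algorithms),
            "genes": self.genes,
            "ranks": {g: self.rank_matrix[i].tolist() for i, g in enumerate(self.genes)},
            "geomean": {g: float(self.geomean[i]) for i, g in enumerate(self.genes)},
            "order": self.order,
            "tied_geomean": self.tied_geomean,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConsensusRanking":
        genes = list(d["genes"])
        rm = np.array([d["ranks"][g] for g in genes], dtype=int)
        return cls(
            stratum=d["stratum"],
            genes=genes,
            algorithms=tuple(d["algorithms"]),
            rank_matrix=rm,
        )


def comprehensive_ranking(
    tables: Sequence[StabilityTable] | Mapping[str, StabilityTable],
    stratum: str = "",
    algorithms: Sequence[str] = ALGORITHMS,
) -> ConsensusRanking:
    """Aggregate one :class:`StabilityTable` per algorithm into a consensus.

    Tables that carry structural ranks (the stepwise exclusion ranking)
    contribute them directly; for the others, ranks are assigned from the
    unrounded stability values by competition ranking.  All tables must
    share one gene set.
    """
    if isinstance(tables, Mapping):
        by_alg = dict(tables)
    else:
        by_alg = {t.algorithm: t for t in tables}
    missing = [a for a in algorithms if a not in by_alg]
    if missing:
        raise CtIntegrityError(f"missing stability table(s) for: {missing}")
    genes = list(by_alg[algorithms[0]].genes)
    for a in algorithms:
        if set(by_alg[a].genes) != set(genes):
            raise CtIntegrityError(f"gene-set mismatch in table for {a!r}")
    G = len(genes)
    rm = np.empty((G, len(algorithms)), dtype=int)
    for j, a in enumerate(algorithms):
        t = by_alg[a]
        if t.ranks is not None:
            ranks = {g: int(r) for g, r in zip(t.genes, t.ranks)}
        else:
            rr = assign_ranks(t.values)
            ranks = {g: int(r) for g, r in zip(t.genes, rr)}
        rm[:, j] = [ranks[g] for g in genes]
    return ConsensusRanking(
        stratum=stratum, genes=genes, algorithms=tuple(algorithms), rank_matrix=rm
    )


def consensus_from_orderings(
    orderings: Mapping[str, Sequence],
    stratum: str = "",
    algorithms: Sequence[str] = ALGORITHMS,
) -> ConsensusRanking:
    """Consensus straight from published best-to-worst orderings.

    ``orderings`` maps algorithm name to an ordering as accepted by
    :func:`ranks_from_ordering` (tuples mark tied positions).  This is
    how reported ranking tables — list position = rank — are re-aggregated
    without the underlying Ct data.
    """
    missing = [a for a in algorithms if a not in orderings]
    if missing:
        raise CtIntegrityError(f"missing ordering(s) for: {missing}")
    first = ranks_from_ordering(orderings[algorithms[0]])
    genes = sorted(first)
    rm = np.empty((len(genes), len(algorithms)), dtype=int)
    for j, a in enumerate(algorithms):
        ranks = ranks_from_ordering(orderings[a], genes=genes)
        rm[:, j] = [ranks[g] for g in genes]
    return ConsensusRanking(
        stratum=stratum, genes=genes, algorithms=tuple(algorithms), rank_matrix=rm
    )
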