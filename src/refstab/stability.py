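"""The four reference-gene stability algorithms.

Each algorithm maps a :class:`~refstab.ct_data.CtMatrix` stratum to a
:class:`StabilityTable` of per-gene stability values where *lower is
better*:

* :func:`genorm_m` / :func:`genorm_rank` — pairwise-ratio M-value with
  stepwise exclusion (geNorm).  The stepwise procedure cannot separate
  the final two genes, which are reported as a structurally tied best
  pair.
* :func:`normfinder_stability` — model-based variance-decomposition
  stability value (NormFinder) on log-scale quantities.
* :func:`bestkeeper` — descriptive dispersion of raw Ct plus correlation
  with a per-sample geometric-mean index (BestKeeper).
* :func:`delta_ct_stability` — mean SD of pairwise Ct differences
  (comparative delta-Ct method).

All standard deviations use the n-1 denominator and all logarithms are
base 2, the conventions of the cited tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import ArityError, CtMatrix, UnknownLabelError

__all__ = [
    "ALGORITHMS",
    "StabilityTable",
    "genorm_m",
    "genorm_rank",
    "normfinder_stability",
    "bestkeeper",
    "delta_ct_stability",
    "stability_table",
    "GENORM_STABLE_M",
]

#: Canonical algorithm order used throughout consensus reports.
ALGORITHMS = ("delta_ct", "bestkeeper", "normfinder", "genorm")

#: Conventional M-value threshold below which a gene counts as stable.
GENORM_STABLE_M = 1.5


@dataclass
class StabilityTable:
    """Per-gene stability values (lower = more stable) for one algorithm.

    ``ranks`` is populated structurally for geNorm (stepwise exclusion
    order, tied best pair at rank 1); for the other algorithms ranks are
    derived from the values at consensus time.
    """

    algorithm: str
    genes: list[str]
    values: np.ndarray
    ranks: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != len(self.values):
            raise ValueError("genes/values length mismatch")
        if (self.values < 0).any():
            raise ValueError("stability values must be >= 0")
        if self.ranks is not None:
            self.ranks = np.asarray(self.ranks, dtype=int)

    def value(self, gene: str) -> float:
        return float(self.values[self.genes.index(gene)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"algorithm": self.algorithm, "gene": self.genes, "value": self.values}
        )
        if self.ranks is not None:
            df["rank"] = self.ranks
        pair = self.extras.get("tied_best_pair")
        if pair is not None:
            df["tied_best_pair"] = [g in pair for g in self.genes]
        return df


def _check_arity(matrix: CtMatrix, min_genes: int, min_samples: int, what: str) -> None:
    if matrix.n_genes < min_genes:
        raise ArityError(
            f"{what} requires >= {min_genes} genes, got {matrix.n_genes}"
        )
    if matrix.n_samples < min_samples:
        raise ArityError(
            f"{what} requires >= {min_samples} samples, got {matrix.n_samples}"
        )


# -- geNorm ------------------------------------------------------------


def genorm_m(matrix: CtMatrix) -> pd.Series:
    """Average pairwise-variation M-value per gene.

    For gene g, M_g is the mean over all other genes h of the sample SD
    of log2(q_g / q_h), where q are linear-scale relative quantities.
    Constant multiplicative offsets between genes cancel, so M measures
    how inconsistently two genes co-vary, averaged over partners.
    """
    _check_arity(matrix, 2, 2, "geNorm M")
    y = matrix.log2_quantity()  # G x S
    G = matrix.n_genes
    m = np.empty(G)
    for g in range(G):
        sds = [np.std(y[g] - y[h], ddof=1) for h in range(G) if h != g]
        m[g] = float(np.mean(sds))
    return pd.Series(m, index=matrix.genes, name="M")


def genorm_rank(matrix: CtMatrix) -> StabilityTable:
    """Stepwise geNorm ranking: iteratively drop the least stable gene.

    The gene with the highest M is removed and M recomputed on the
    remainder until two genes are left; those two form the structurally
    tied best pair (shared rank 1, identical M from the two-gene round).
    Each gene's reported value is its M at the round of its exclusion.
    Equal worst M-values are resolved by removing the lexicographically
    later symbol, for determinism.
    """
    _check_arity(matrix, 3, 2, "geNorm ranking")
    remaining = list(matrix.genes)
    exclusion: list[tuple[str, float]] = []  # worst-first
    while len(remaining) > 2:
        sub = matrix.subset(genes=remaining)
        m = genorm_m(sub)
        worst = max(remaining, key=lambda g: (m[g], g))
        exclusion.append((worst, float(m[worst])))
        remaining.remove(worst)
    pair_m = genorm_m(matrix.subset(genes=remaining))
    pair = tuple(remaining)
    values = {g: v for g, v in exclusion}
    values.update({g: float(pair_m[g]) for g in pair})
    ranks = {g: 1 for g in pair}
    for back, (g, _) in enumerate(reversed(exclusion)):
        ranks[g] = 3 + back
    order = np.array([ranks[g] for g in matrix.genes])
    vals = np.array([values[g] for g in matrix.genes])
    return StabilityTable(
        algorithm="genorm",
        genes=list(matrix.genes),
        values=vals,
        ranks=order,
        extras={
            "tied_best_pair": pair,
            "exclusion_order": [g for g, _ in exclusion],
            "all_gene_m": genorm_m(matrix),
            "stable": vals < GENORM_STABLE_M,
        },
    )


# -- NormFinder --------------------------------------------------------


def _double_center_residuals(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()


def _ungrouped_variances(y: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variances of the additive gene + sample model.

    Residuals come from double centering; the raw per-gene residual
    variance s_g^2 (n-1 denominator) is inflated by the other genes'
    noise leaking through the sample means, which the G/(G-2) correction
    removes.  Negative corrected variances truncate at 0.
    """
    G, n = y.shape
    r = _double_center_residuals(y)
    s2 = (r**2).sum(axis=1) / (n - 1)
    total = G / (G - 1) * s2.sum()
    return np.maximum(0.0, G / (G - 2) * (s2 - total / G**2))


def normfinder_stability(
    matrix: CtMatrix, groups: Sequence[str] | None = None
) -> StabilityTable:
    """Model-based stability value (estimated SD) per gene.

    Ungrouped (default): fit y_gs = alpha_g + beta_s + eps_gs on log2
    quantities by double centering and report the bias-corrected residual
    SD per gene.  Grouped (opt-in, ``groups`` = condition labels to use):
    combine per-group intragroup variance with the shrunken absolute
    intergroup deviation, averaged over groups.
    """
    _check_arity(matrix, 3, 2, "NormFinder")
    y = matrix.log2_quantity()
    genes = list(matrix.genes)
    if groups is None:
        values = np.sqrt(_ungrouped_variances(y))
        return StabilityTable("normfinder", genes, values)

    labels = [s.condition for s in matrix.samples]
    unknown = set(groups) - set(labels)
    if unknown:
        raise UnknownLabelError(f"unknown group label(s): {sorted(unknown)}")
    idx = {g: [i for i, lab in enumerate(labels) if lab == g] for g in groups}
    for g, ii in idx.items():
        if len(ii) < 2:
            raise ArityError(f"group {g!r} has {len(ii)} sample(s); need >= 2")
    K = len(idx)
    G = matrix.n_genes
    if K < 2:
        raise ArityError("grouped NormFinder requires >= 2 groups")
    # per-group intragroup variances and group means of gene-centered data
    v = np.empty((G, K))
    z = np.empty((G, K))
    for k, (glab, ii) in enumerate(idx.items()):
        yk = y[:, ii]
        v[:, k] = _ungrouped_variances(yk)
        centered = yk - yk.mean(axis=0, keepdims=True)  # remove sample effects
        z[:, k] = centered.mean(axis=1)
    d = z - z.mean(axis=1, keepdims=True) - z.mean(axis=0, keepdims=True) + z.mean()
    n_k = np.array([len(ii) for ii in idx.values()])[None, :]
    vn = v / n_k
    gamma2 = max(0.0, (d**2).sum() / ((G - 1) * (K - 1)) - vn.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(gamma2 + vn > 0, gamma2 / (gamma2 + vn), 0.0)
    d_tilde = d * shrink
    stab = (np.abs(d_tilde) + np.sqrt(vn)).mean(axis=1)
    return StabilityTable(
        "normfinder",
        genes,
        stab,
        extras={"intragroup_variance": v, "intergroup_deviation": d, "groups": list(idx)},
    )


# -- BestKeeper --------------------------------------------------------


def bestkeeper(matrix: CtMatrix, dialect: str = "mad") -> StabilityTable:
    """Descriptive Ct dispersion per gene plus index correlations.

    The reported SD[+/-Ct] follows the original applet's dialect: the
    mean absolute deviation of Ct from the gene's arithmetic mean
    (``dialect="mad"``, default).  The conventional sample SD is
    available with ``dialect="sd"``.  The BestKeeper index is the
    per-sample geometric mean of Ct across genes; each gene's Pearson r
    against the index is reported alongside.  Ranking uses the
    dispersion only.
    """
    if dialect not in ("mad", "sd"):
        raise ValueError(f"unknown BestKeeper dialect {dialect!r}")
    _check_arity(matrix, 2, 2, "BestKeeper")
    ct = matrix.ct
    amean = ct.mean(axis=1)
    mad = np.abs(ct - amean[:, None]).mean(axis=1)
    sd = ct.std(axis=1, ddof=1)
    disp = mad if dialect == "mad" else sd
    cv = 100.0 * disp / amean
    index = stats.gmean(ct, axis=0)
    r = np.full(matrix.n_genes, np.nan)
    p = np.full(matrix.n_genes, np.nan)
    if matrix.n_samples >= 3:
        for gi in range(matrix.n_genes):
            if np.ptp(ct[gi]) == 0 or np.ptp(index) == 0:
                warnings.warn(
                    f"gene {matrix.genes[gi]!r} (or the index) is constant; "
                    "correlation with the BestKeeper index is undefined",
                    stacklevel=2,
                )
                continue
            r[gi], p[gi] = stats.pearsonr(ct[gi], index)
    descript = pd.DataFrame(
        {
            "gene": matrix.genes,
            "geo_mean": stats.gmean(ct, axis=1),
            "ar_mean": amean,
            "min_ct": ct.min(axis=1),
            "max_ct": ct.max(axis=1),
            "sd_ct": disp,
            "cv_pct": cv,
            "r_index": r,
            "p_index": p,
        }
    )
    return StabilityTable(
        "bestkeeper",
        list(matrix.genes),
        disp,
        extras={"descriptives": descript, "index": index, "dialect": dialect},
    )


# -- comparative delta-Ct ----------------------------------------------


def delta_ct_stability(matrix: CtMatrix) -> StabilityTable:
    """Mean pairwise-SD stability: S_g = mean_h SD_s(Ct_g - Ct_h)."""
    _check_arity(matrix, 2, 2, "comparative delta-Ct")
    ct = matrix.ct
    G = matrix.n_genes
    s = np.empty(G)
    for g in range(G):
        sds = [np.std(ct[g] - ct[h], ddof=1) for h in range(G) if h != g]
        s[g] = float(np.mean(sds))
    return StabilityTable("delta_ct", list(matrix.genes), s)


# -- dispatch ----------------------------------------------------------


def stability_table(matrix: CtMatrix, algorithm: str, **kwargs) -> StabilityTable:
    """Run one algorithm by name (``delta_ct``, ``bestkeeper``,
    ``normfinder`` or ``genorm``)."""
    if algorithm == "delta_ct":
        return delta_ct_stability(matrix)
    if algorithm == "bestkeeper":
        return bestkeeper(matrix, **kwargs)
    if algorithm == "normfinder":
        return normfinder_stability(matrix, **kwargs)
    if algorithm == "genorm":
        return genorm_rank(matrix)
    raise ValueError(f"unknown algorithm {algorithm!r}")
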