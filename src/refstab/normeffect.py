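"""Impact of normalizer choice on delta-delta-Ct fold-change conclusions.

Given a best and a worst reference gene for a condition comparison (as
chosen by the consensus ranking), this module computes per-donor
2^-ddCt fold changes of target genes under each normalizer, the
worst/best (W/B) ratio that quantifies the apparent-difference artifact,
and merged-donor one-sample t-tests of the fold changes against the null
value 1.

Algebraically the W/B ratio for a donor is E^(dW - dB), where dW and dB
are the two normalizers' own between-condition Ct differences for that
donor — the artifact depends only on how the reference genes moved, never
on the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import ArityError, CtDataError, CtMatrix, UnknownLabelError

__all__ = [
    "FoldChangeSet",
    "NormEffectReport",
    "CoverageError",
    "fold_change",
    "fold_change_set",
    "wb_ratio",
    "one_sample_t_vs_unity",
    "significance_tier",
    "merged_condition_report",
    "DEFAULT_WB_THRESHOLD",
]

DEFAULT_WB_THRESHOLD = 2.0

#: p-value cut-offs for the significance tiers ns / * / ** / *** / ****.
TIER_CUTOFFS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


class CoverageError(CtDataError):
    """A donor/condition cell required for a paired fold change is missing."""


@dataclass
class FoldChangeSet:
    """Per-donor 2^-ddCt fold changes of one target under one normalizer."""

    target: str
    hkg: str
    comparison: tuple[str, str]  # (numerator condition, reference condition)
    donors: list[str]
    fold_changes: np.ndarray

    def __post_init__(self) -> None:
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if len(self.donors) != len(self.fold_changes):
            raise ValueError("donors/fold_changes length mismatch")
        if (self.fold_changes <= 0).any():
            raise ValueError("fold changes must be > 0")

    @property
    def n(self) -> int:
        return len(self.donors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target,
                "hkg": self.hkg,
                "comparison": f"{self.comparison[0]} vs {self.comparison[1]}",
                "donor": self.donors,
                "fold_change": self.fold_changes,
            }
        )


def fold_change(
    matrix: CtMatrix,
    target: str,
    hkg: str,
    comparison: tuple[str, str],
    donor: str,
) -> float:
    """2^-ddCt fold change for one donor between two conditions.

    dCt_c = Ct_target,c - Ct_hkg,c per condition; the fold change is
    E^-(dCt_num - dCt_ref) with the target gene's efficiency E (default
    2).  Swapping the comparison order gives the reciprocal.
    """
    if target == hkg:
        raise ValueError("target and normalizer must differ")
    num, ref = comparison
    try:
        d_num = matrix.ct_value(target, donor, num) - matrix.ct_value(hkg, donor, num)
        d_ref = matrix.ct_value(target, donor, ref) - matrix.ct_value(hkg, donor, ref)
    except UnknownLabelError as exc:
        raise CoverageError(str(exc)) from None
    e = matrix.efficiency[target]
    return float(e ** -(d_num - d_ref))


def fold_change_set(
    matrix: CtMatrix,
    target: str,
    hkg: str,
    comparison: tuple[str, str],
    donors: Sequence[str] | None = None,
) -> FoldChangeSet:
    """Fold changes for every donor present in both conditions."""
    donors = list(donors) if donors is not None else matrix.donors
    fcs = [fold_change(matrix, target, hkg, comparison, d) for d in donors]
    return FoldChangeSet(target, hkg, tuple(comparison), donors, np.array(fcs))


def wb_ratio(
    fc_best: FoldChangeSet,
    fc_worst: FoldChangeSet,
    threshold: float = DEFAULT_WB_THRESHOLD,
) -> pd.DataFrame:
    """Per-donor worst/best fold-change ratios with >= threshold flags."""
    if fc_best.target != fc_worst.target or fc_best.comparison != fc_worst.comparison:
        raise CoverageError("fold-change sets compare different targets/conditions")
    if fc_best.donors != fc_worst.donors:
        raise CoverageError("donor coverage differs between best and worst sets")
    ratio = fc_worst.fold_changes / fc_best.fold_changes
    return pd.DataFrame(
        {
            "target": fc_best.target,
            "comparison": f"{fc_best.comparison[0]} vs {fc_best.comparison[1]}",
            "donor": fc_best.donors,
            "fc_best": fc_best.fold_changes,
            "fc_worst": fc_worst.fold_changes,
            "wb_ratio": ratio,
            "flag": ratio >= threshold,
        }
    )


def one_sample_t_vs_unity(
    fold_changes: Sequence[float] | np.ndarray, log_scale: bool = False
) -> tuple[float, float, str]:
    """Two-sided one-sample t-test of fold changes against the null mean 1.

    t = (mean - 1)/(SD/sqrt(n)) with df = n-1 on the raw fold changes
    (the study's convention).  ``log_scale=True`` instead tests log2 fold
    changes against 0, the statistically preferable variant, off by
    default.  Returns (t, p, tier) with tiers ns / * / ** / *** / ****
    at 0.05 / 0.01 / 0.001 / 0.0001.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size < 2:
        raise ArityError("t-test requires n >= 2 fold changes")
    if (fc <= 0).any():
        raise ValueError("fold changes must be > 0")
    if log_scale:
        x, null = np.log2(fc), 0.0
    else:
        x, null = fc, 1.0
    n = x.size
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0:
        if mean == null:
            return 0.0, 1.0, "ns"
        warnings.warn(
            "zero variance with mean != null value; p degenerates to 0",
            stacklevel=2,
        )
        return float(np.inf) if mean > null else float(-np.inf), 0.0, "****"
    t = (mean - null) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), significance_tier(p)


def significance_tier(p: float) -> str:
    """Map a p-value to ns / * / ** / *** / **** (cut-offs inclusive)."""
    for cut, tier in TIER_CUTOFFS:
        if p <= cut:
            return tier
    return "ns"


@dataclass
class NormEffectReport:
    """Per-donor and merged normalizer-impact results for one comparison."""

    comparison: tuple[str, str]
    best_hkg: str
    worst_hkg: str
    per_donor: pd.DataFrame  # one row per (target, donor)
    merged: pd.DataFrame  # one row per (target, hkg role)
    wb_condition_geomean: dict[str, float] = field(default_factory=dict)

    def write(self, donor_path, merged_path) -> None:
        self.per_donor.to_csv(donor_path, index=False)
        self.merged.to_csv(merged_path, index=False)


def merged_condition_report(
    matrix: CtMatrix,
    targets: Sequence[str],
    best_hkg: str,
    worst_hkg: str,
    comparison: tuple[str, str],
    threshold: float = DEFAULT_WB_THRESHOLD,
) -> NormEffectReport:
    """Full normalizer-impact report for one condition comparison.

    Per (target, donor): fold change under the best and the worst
    normalizer, their W/B ratio and the >= threshold flag.  Per target,
    merged over donors: arithmetic and geometric mean fold change plus
    the one-sample t-test against 1, under each normalizer.  Also reports
    the condition-level W/B geometric mean across donors and targets —
    the single number summarising the apparent fold-change inflation a
    poor normalizer causes for this comparison.
    """
    donor_rows = []
    merged_rows = []
    wb_all = []
    for target in targets:
        fc_b = fold_change_set(matrix, target, best_hkg, comparison)
        fc_w = fold_change_set(matrix, target, worst_hkg, comparison)
        tab = wb_ratio(fc_b, fc_w, threshold=threshold)
        tab.insert(3, "best_hkg", best_hkg)
        tab.insert(4, "worst_hkg", worst_hkg)
        donor_rows.append(tab)
        wb_all.append(tab["wb_ratio"].to_numpy())
        for role, fcs in (("best", fc_b), ("worst", fc_w)):
            t, p, tier = one_sample_t_vs_unity(fcs.fold_changes)
            merged_rows.append(
                {
                    "target": target,
                    "comparison": f"{comparison[0]} vs {comparison[1]}",
                    "hkg_role": role,
                    "hkg": fcs.hkg,
                    "n": fcs.n,
                    "mean_fc": float(fcs.fold_changes.mean()),
                    "geomean_fc": float(stats.gmean(fcs.fold_changes)),
                    "t": t,
                    "p": p,
                    "tier": tier,
                }
            )
    wb_flat = np.concatenate(wb_all)
    return NormEffectReport(
        comparison=tuple(comparison),
        best_hkg=best_hkg,
        worst_hkg=worst_hkg,
        per_donor=pd.concat(donor_rows, ignore_index=True),
        merged=pd.DataFrame(merged_rows),
        wb_condition_geomean={
            "all_targets": float(stats.gmean(wb_flat)),
            **{
                t: float(stats.gmean(w)) for t, w in zip(targets, wb_all)
            },
        },
    )
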