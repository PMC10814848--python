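"""Orchestration: stratified stability runs and normalizer-impact reports.

A :class:`RunSpec` names the input (a Ct table or a synthetic config),
the strata to analyse, and the output directory.  The ``"paper-preset"``
stratum set reproduces the emulated study's eleven strata: each
condition, the three condition pairs, all conditions together, and each
donor across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .consensus import ConsensusRanking, comprehensive_ranking
from .ct_data import CtDataError, CtMatrix
from .datasets import STUDY_TARGETS
from .normeffect import NormEffectReport, merged_condition_report
from .stability import ALGORITHMS, stability_table

__all__ = ["Stratum", "RunSpec", "study_strata", "run_stability", "run_normeffect"]

logger = logging.getLogger("refstab")


@dataclass(frozen=True)
class Stratum:
    """One analysis stratum: a label plus condition/donor restrictions."""

    label: str
    conditions: tuple[str, ...] | None = None
    donors: tuple[str, ...] | None = None

    def apply(self, matrix: CtMatrix) -> CtMatrix:
        return matrix.subset(conditions=self.conditions, donors=self.donors)


def study_strata(matrix: CtMatrix) -> list[Stratum]:
    """The study preset: conditions, condition pairs, ALL, and donors."""
    conds = matrix.conditions
    strata = [Stratum(c, conditions=(c,)) for c in conds]
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            strata.append(
                Stratum(f"{conds[i]}/{conds[j]}", conditions=(conds[i], conds[j]))
            )
    strata.append(Stratum("ALL"))
    strata.extend(Stratum(d, donors=(d,)) for d in matrix.donors)
    return strata


@dataclass
class RunSpec:
    """Declarative description of one full stability run."""

    strata: list[Stratum] | None = None  # None -> study preset
    algorithms: tuple[str, ...] = ALGORITHMS
    hkgs: tuple[str, ...] | None = None  # None -> all genes except targets
    targets: tuple[str, ...] = STUDY_TARGETS
    outdir: Path | None = None
    wb_threshold: float = 2.0
    extra: dict = field(default_factory=dict)


def _slug(label: str) -> str:
    return label.replace("/", "-").replace(" ", "_")


def run_stability(
    matrix: CtMatrix, spec: RunSpec | None = None
) -> dict[str, ConsensusRanking]:
    """Consensus ranking per stratum; failing strata are logged, not fatal.

    For each stratum the HKG submatrix is extracted, the four stability
    tables computed and aggregated.  Results are written as CSV + JSON
    under ``spec.outdir`` when set.  A stratum violating an algorithm's
    arity preconditions is skipped with a logged error; the remaining
    strata still complete.
    """
    spec = spec or RunSpec()
    hkgs = spec.hkgs
    if hkgs is None:
        hkgs = tuple(g for g in matrix.genes if g not in set(spec.targets))
    strata = spec.strata if spec.strata is not None else study_strata(matrix)
    results: dict[str, ConsensusRanking] = {}
    for stratum in strata:
        try:
            sub = stratum.apply(matrix).subset(genes=hkgs)
            logger.info(
                "stratum %s: %d genes x %d samples",
                stratum.label, sub.n_genes, sub.n_samples,
            )
            tables = {a: stability_table(sub, a) for a in spec.algorithms}
            results[stratum.label] = comprehensive_ranking(
                tables, stratum=stratum.label, algorithms=spec.algorithms
            )
        except CtDataError as exc:
            logger.error("stratum %s failed: %s", stratum.label, exc)
            continue
        if spec.outdir is not None:
            outdir = Path(spec.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            slug = _slug(stratum.label)
            results[stratum.label].to_frame().to_csv(
                outdir / f"ranking_{slug}.csv", index=False
            )
            results[stratum.label].to_json(outdir / f"ranking_{slug}.json")
    return results


def run_normeffect(
    matrix: CtMatrix,
    rankings: dict[str, ConsensusRanking],
    spec: RunSpec | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> dict[str, NormEffectReport]:
    """Best-vs-worst normalizer impact per condition comparison.

    For each comparison (numerator, reference) the best and worst
    normalizer are read off that comparison stratum's consensus (labelled
    ``"ref/num"`` in the study preset, falling back to ``"num/ref"``).
    """
    spec = spec or RunSpec()
    targets = [t for t in spec.targets if t in matrix.genes]
    if not targets:
        raise CtDataError("no target genes present in the matrix")
    if comparisons is None:
        conds = matrix.conditions
        comparisons = [
            (conds[j], conds[i])
            for i in range(len(conds))
            for j in range(i + 1, len(conds))
        ]
    reports: dict[str, NormEffectReport] = {}
    for num, ref in comparisons:
        for label in (f"{ref}/{num}", f"{num}/{ref}"):
            if label in rankings:
                break
        else:
            logger.error("no ranking for comparison %s vs %s; skipped", num, ref)
            continue
        ranking = rankings[label]
        report = merged_condition_report(
            matrix, targets, ranking.best, ranking.worst,
            comparison=(num, ref), threshold=spec.wb_threshold,
        )
        reports[f"{num} vs {ref}"] = report
        logger.info(
            "comparison %s vs %s: best=%s worst=%s W/B geomean=%.2f",
            num, ref, ranking.best, ranking.worst,
            report.wb_condition_geomean["all_targets"],
        )
        if spec.outdir is not None:
            outdir = Path(spec.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            slug = _slug(f"{num}_vs_{ref}")
            report.write(
                outdir / f"normeffect_donor_{slug}.csv",
                outdir / f"normeffect_merged_{slug}.csv",
            )
    return reports
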