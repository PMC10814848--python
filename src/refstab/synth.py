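"""Synthetic Ct data with the study design's statistical structure.

The generator emulates a 5-HKG x 3-target x 4-donor x 3-condition qPCR
layout: per-gene baseline Ct, additive per-condition shifts, a shared
Gaussian donor offset (the mechanism behind donor-dominant clustering of
Ct profiles), and per-gene Gaussian Ct noise.  Noise is Gaussian on the
cycle scale — i.e. log-normal on the expression scale — the standard
qPCR error model; a Student-t option provides heavier tails for
robustness checks.

Condition shifts are additive in Ct and therefore multiplicative in
expression, matching delta-delta-Ct algebra: a target with log2
fold change f in condition c relative to the first condition is shifted
by -f cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .ct_data import CtMatrix, CtValidationError, SampleMeta, UnknownLabelError

__all__ = [
    "GeneSpec",
    "TargetSpec",
    "SynthConfig",
    "default_study_config",
    "generate",
    "spiked_instability",
]


@dataclass(frozen=True)
class GeneSpec:
    """A candidate reference gene: baseline Ct, per-condition Ct shifts, noise SD."""

    symbol: str
    baseline: float
    noise_sd: float
    condition_shift: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.baseline < 45:
            raise CtValidationError(f"baseline Ct {self.baseline} outside (0, 45)")
        if self.noise_sd < 0:
            raise CtValidationError("noise SD must be >= 0")


@dataclass(frozen=True)
class TargetSpec:
    """A target gene: baseline Ct, per-condition log2 fold shifts, noise SD.

    ``log2_fc`` maps condition label -> log2 fold change of expression
    relative to baseline; the Ct shift applied is the negative of it.
    """

    symbol: str
    baseline: float
    log2_fc: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.baseline < 45:
            raise CtValidationError(f"baseline Ct {self.baseline} outside (0, 45)")
        if self.noise_sd < 0:
            raise CtValidationError("noise SD must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic study."""

    hkgs: tuple[GeneSpec, ...]
    targets: tuple[TargetSpec, ...]
    conditions: tuple[str, ...]
    n_donors: int = 4
    donor_sd: float = 0.3
    seed: int = 0
    noise: str = "gaussian"  # or "student_t"
    t_dof: float = 3.0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise CtValidationError("need at least one donor")
        if self.donor_sd < 0:
            raise CtValidationError("donor offset SD must be >= 0")
        if self.noise not in ("gaussian", "student_t"):
            raise CtValidationError(f"unknown noise model {self.noise!r}")
        symbols = [g.symbol for g in self.hkgs] + [t.symbol for t in self.targets]
        if len(set(symbols)) != len(symbols):
            raise CtValidationError("duplicate gene symbols in config")

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.hkgs] + [t.symbol for t in self.targets]

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "conditions": list(self.conditions),
            "n_donors": self.n_donors,
            "donor_sd": self.donor_sd,
            "seed": self.seed,
            "noise": self.noise,
            "t_dof": self.t_dof,
            "hkgs": [
                {
                    "symbol": g.symbol,
                    "baseline": g.baseline,
                    "noise_sd": g.noise_sd,
                    "condition_shift": dict(g.condition_shift),
                }
                for g in self.hkgs
            ],
            "targets": [
                {
                    "symbol": t.symbol,
                    "baseline": t.baseline,
                    "log2_fc": dict(t.log2_fc),
                    "noise_sd": t.noise_sd,
                }
                for t in self.targets
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            hkgs=tuple(
                GeneSpec(
                    g["symbol"],
                    g["baseline"],
                    g["noise_sd"],
                    g.get("condition_shift", {}),
                )
                for g in doc["hkgs"]
            ),
            targets=tuple(
                TargetSpec(
                    t["symbol"],
                    t["baseline"],
                    t.get("log2_fc", {}),
                    t.get("noise_sd", 0.3),
                )
                for t in doc.get("targets", [])
            ),
            conditions=tuple(doc["conditions"]),
            n_donors=doc.get("n_donors", 4),
            donor_sd=doc.get("donor_sd", 0.3),
            seed=doc.get("seed", 0),
            noise=doc.get("noise", "gaussian"),
            t_dof=doc.get("t_dof", 3.0),
        )


# Baseline mean Ct of the five candidate HKGs over all conditions, and
# their per-condition deviations from that mean, as reported for the
# emulated study design (condition mean minus overall mean, in cycles).
_HKG_BASELINES = {
    "ACTB": (12.72, {"FBS": -0.44, "X1": 0.08, "X2": 0.37}),
    "EF1A": (10.19, {"FBS": 0.23, "X1": -0.01, "X2": -0.21}),
    "GAPDH": (11.42, {"FBS": 0.17, "X1": -0.07, "X2": -0.08}),
    "RPLP0": (11.07, {"FBS": 0.20, "X1": 0.01, "X2": -0.22}),
    "TBP": (20.51, {"FBS": 0.34, "X1": -0.23, "X2": -0.12}),
}


def default_study_config(seed: int = 0) -> SynthConfig:
    """The emulated study design: 5 HKGs x 4 donors x 3 conditions.

    HKG baselines and per-condition shifts follow the reported
    condition-wise mean Ct values; donor offset SD and per-gene noise SD
    default to 0.3 cycles, a plausible spread for SYBR qPCR on
    preamplified cDNA.  The three secreted-factor targets carry
    condition effects relative to FBS: a strong IL6 reduction and a
    moderate LIF reduction in both synthetic media, and a mild CCL5
    increase.
    """
    hkgs = tuple(
        GeneSpec(sym, base, 0.3, shifts)
        for sym, (base, shifts) in _HKG_BASELINES.items()
    )
    targets = (
        TargetSpec("LIF", 16.0, {"X1": -1.0, "X2": -1.2}, 0.3),
        TargetSpec("CCL5", 18.0, {"X1": 0.5, "X2": 0.5}, 0.3),
        TargetSpec("IL6", 14.0, {"X1": -2.0, "X2": -2.5}, 0.3),
    )
    return SynthConfig(
        hkgs=hkgs,
        targets=targets,
        conditions=("FBS", "X1", "X2"),
        n_donors=4,
        donor_sd=0.3,
        seed=seed,
    )


def generate(config: SynthConfig) -> CtMatrix:
    """Draw one synthetic :class:`CtMatrix` from the generative model.

    Ct_gs = baseline_g + shift_{c(s),g} + donor_offset_{d(s)} + eps,
    eps ~ Normal(0, sigma_g) (or scaled Student-t).  Donor offsets are
    shared by all of a donor's samples across conditions and genes,
    which induces donor-dominant clustering.  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    donors = [f"ASC{i + 1}" for i in range(config.n_donors)]
    samples = [
        SampleMeta(f"{d}_{c}", d, c) for d in donors for c in config.conditions
    ]
    donor_offset = dict(zip(donors, rng.normal(0.0, config.donor_sd, len(donors))))

    def eps(sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.zeros(size)
        if config.noise == "student_t":
            scale = sd / np.sqrt(config.t_dof / (config.t_dof - 2))
            return scale * rng.standard_t(config.t_dof, size)
        return rng.normal(0.0, sd, size)

    rows = []
    genes = []
    for spec in config.hkgs:
        genes.append(spec.symbol)
        noise = eps(spec.noise_sd, len(samples))
        rows.append(
            [
                spec.baseline
                + spec.condition_shift.get(s.condition, 0.0)
                + donor_offset[s.donor]
                + e
                for s, e in zip(samples, noise)
            ]
        )
    for spec in config.targets:
        genes.append(spec.symbol)
        noise = eps(spec.noise_sd, len(samples))
        rows.append(
            [
                spec.baseline
                - spec.log2_fc.get(s.condition, 0.0)
                + donor_offset[s.donor]
                + e
                for s, e in zip(samples, noise)
            ]
        )
    return CtMatrix(genes=genes, samples=samples, ct=np.array(rows))


def spiked_instability(
    config: SynthConfig, gene: str, sd_multiplier: float
) -> SynthConfig:
    """Copy of ``config`` with one HKG's noise SD scaled up.

    Used to plant a detectably unstable gene; ``sd_multiplier`` must be
    >= 1 (spiking means adding noise, never removing it).
    """
    if sd_multiplier < 1:
        raise CtValidationError("sd_multiplier must be >= 1")
    if gene not in [g.symbol for g in config.hkgs]:
        raise UnknownLabelError(f"unknown HKG {gene!r}")
    new_hkgs = tuple(
        replace(g, noise_sd=g.noise_sd * sd_multiplier) if g.symbol == gene else g
        for g in config.hkgs
    )
    return replace(config, hkgs=new_hkgs)
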