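"""Data model, validation, I/O and descriptive statistics for Ct matrices.

The central container is :class:`CtMatrix`: a genes x samples grid of
quantification-cycle (Ct) values with per-sample annotations (donor,
condition) and a per-gene amplification efficiency E.  Every downstream
stage — the four stability algorithms, the rank consensus and the
delta-delta-Ct normalizer-impact analysis — consumes a ``CtMatrix`` or a
stratum of one.

Two CSV dialects are supported:

* *long*: one row per measurement with columns
  ``sample_id, donor, condition, gene, ct``;
* *wide*: genes as rows, samples as columns (the usual qPCR export
  layout), with sample metadata in a sidecar table keyed by ``sample_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleMeta",
    "CtMatrix",
    "CtDataError",
    "CtFormatError",
    "CtIntegrityError",
    "CtValidationError",
    "UnknownLabelError",
    "ArityError",
    "read_ct_table",
    "write_ct_table",
    "summarize",
    "load_config",
    "DEFAULT_CT_MAX",
    "DEFAULT_EFFICIENCY",
]

DEFAULT_CT_MAX = 45.0
DEFAULT_EFFICIENCY = 2.0

LONG_COLUMNS = ["sample_id", "donor", "condition", "gene", "ct"]


class CtDataError(ValueError):
    """Base class for Ct data-model errors."""


class CtFormatError(CtDataError):
    """A table does not conform to the expected dialect (missing columns...)."""


class CtIntegrityError(CtDataError):
    """Duplicate (gene, sample) pairs or inconsistent metadata."""


class CtValidationError(CtDataError):
    """A Ct value is missing, non-numeric or out of range."""


class UnknownLabelError(CtDataError, KeyError):
    """A requested gene/donor/condition label does not exist."""


class ArityError(CtDataError):
    """Too few genes or samples for the requested computation."""


@dataclass(frozen=True)
class SampleMeta:
    """Annotation for one sample: unique id, donor label, condition label."""

    sample_id: str
    donor: str
    condition: str

    def __post_init__(self) -> None:
        for fld in ("sample_id", "donor", "condition"):
            if not str(getattr(self, fld)):
                raise CtValidationError(f"SampleMeta.{fld} must be non-empty")


@dataclass
class CtMatrix:
    """Genes x samples grid of Ct values with sample metadata.

    Parameters
    ----------
    genes
        Ordered gene symbols (rows).
    samples
        Ordered :class:`SampleMeta` (columns).
    ct
        2-D float array of shape ``(len(genes), len(samples))``.
    efficiency
        Per-gene amplification efficiency E, ``1 < E <= 2``.  Defaults to
        perfect doubling (E = 2) for every gene, the implicit assumption
        when raw Ct values from SYBR chemistry are analysed directly.
    """

    genes: list[str]
    samples: list[SampleMeta]
    ct: np.ndarray
    efficiency: dict[str, float] = field(default_factory=dict)
    ct_max: float = DEFAULT_CT_MAX

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise CtIntegrityError(
                f"ct grid shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise CtIntegrityError("duplicate gene symbols")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CtIntegrityError("duplicate sample_id values")
        for g in self.efficiency:
            if g not in set(self.genes):
                raise UnknownLabelError(f"efficiency given for unknown gene {g!r}")
        self.efficiency = {
            g: float(self.efficiency.get(g, DEFAULT_EFFICIENCY)) for g in self.genes
        }
        for g, e in self.efficiency.items():
            if not 1.0 < e <= 2.0:
                raise CtValidationError(
                    f"efficiency for {g} is {e}; must satisfy 1 < E <= 2"
                )
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check the no-missing / in-range invariants, raising on violation."""
        bad = ~np.isfinite(self.ct)
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise CtValidationError(
                f"missing/non-numeric Ct for gene {self.genes[gi]!r}, "
                f"sample {self.samples[si].sample_id!r}"
            )
        out = (self.ct <= 0) | (self.ct > self.ct_max)
        if out.any():
            gi, si = np.argwhere(out)[0]
            raise CtValidationError(
                f"Ct {self.ct[gi, si]} out of range (0, {self.ct_max}] for gene "
                f"{self.genes[gi]!r}, sample {self.samples[si].sample_id!r}"
            )

    # -- basic introspection -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def donors(self) -> list[str]:
        """Donor labels in first-seen order."""
        return list(dict.fromkeys(s.donor for s in self.samples))

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-seen order."""
        return list(dict.fromkeys(s.condition for s in self.samples))

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise UnknownLabelError(f"unknown gene {gene!r}") from None

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise UnknownLabelError(f"unknown sample {sample_id!r}")

    def gene_ct(self, gene: str) -> np.ndarray:
        return self.ct[self.gene_index(gene)]

    def ct_value(self, gene: str, donor: str, condition: str) -> float:
        """Ct for one (gene, donor, condition) cell; exactly one must exist."""
        idx = [
            i
            for i, s in enumerate(self.samples)
            if s.donor == donor and s.condition == condition
        ]
        if not idx:
            raise UnknownLabelError(
                f"no sample for donor {donor!r} in condition {condition!r}"
            )
        if len(idx) > 1:
            raise CtIntegrityError(
                f"multiple samples for donor {donor!r} in condition {condition!r}"
            )
        return float(self.ct[self.gene_index(gene), idx[0]])

    # -- subsetting ----------------------------------------------------

    def subset(
        self,
        conditions: Iterable[str] | None = None,
        donors: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "CtMatrix":
        """Submatrix restricted to the given labels, order preserved.

        Unknown labels raise :class:`UnknownLabelError`; a selection that
        would produce an empty matrix is an error, never an empty object.
        """
        if conditions is not None:
            conditions = set(conditions)
            unknown = conditions - set(self.conditions)
            if unknown:
                raise UnknownLabelError(f"unknown condition(s): {sorted(unknown)}")
        if donors is not None:
            donors = set(donors)
            unknown = donors - set(self.donors)
            if unknown:
                raise UnknownLabelError(f"unknown donor(s): {sorted(unknown)}")
        if genes is not None:
            genes = list(genes)
            unknown = set(genes) - set(self.genes)
            if unknown:
                raise UnknownLabelError(f"unknown gene(s): {sorted(unknown)}")
            keep_g = [i for i, g in enumerate(self.genes) if g in set(genes)]
        else:
            keep_g = list(range(self.n_genes))
        keep_s = [
            i
            for i, s in enumerate(self.samples)
            if (conditions is None or s.condition in conditions)
            and (donors is None or s.donor in donors)
        ]
        if not keep_g or not keep_s:
            raise UnknownLabelError("selection produced an empty matrix")
        sub_genes = [self.genes[i] for i in keep_g]
        return CtMatrix(
            genes=sub_genes,
            samples=[self.samples[i] for i in keep_s],
            ct=self.ct[np.ix_(keep_g, keep_s)],
            efficiency={g: self.efficiency[g] for g in sub_genes},
            ct_max=self.ct_max,
        )

    # -- derived quantities --------------------------------------------

    def relative_quantity(self) -> np.ndarray:
        """Linear-scale relative quantities q_gs = E_g^(minCt_g - Ct_gs).

        Each gene is referenced to its own minimum Ct over the current
        samples, so the per-gene maximum quantity is exactly 1 and all
        quantities lie in (0, 1].  This is the linear-scale input that the
        model-based (NormFinder-style) estimator and the pairwise-ratio
        (geNorm-style) M-value operate on.
        """
        e = np.array([self.efficiency[g] for g in self.genes])[:, None]
        min_ct = self.ct.min(axis=1, keepdims=True)
        return e ** (min_ct - self.ct)

    def log2_quantity(self) -> np.ndarray:
        """log2 of :meth:`relative_quantity` (<= 0, gene-wise max exactly 0)."""
        e = np.array([self.efficiency[g] for g in self.genes])[:, None]
        min_ct = self.ct.min(axis=1, keepdims=True)
        return (min_ct - self.ct) * np.log2(e)

    # -- conversion ----------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.genes):
            for si, s in enumerate(self.samples):
                rows.append((s.sample_id, s.donor, s.condition, g, self.ct[gi, si]))
        return pd.DataFrame(rows, columns=LONG_COLUMNS)

    def to_wide_frame(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        wide = pd.DataFrame(self.ct, index=self.genes, columns=self.sample_ids)
        wide.index.name = "gene"
        meta = pd.DataFrame(
            [(s.sample_id, s.donor, s.condition) for s in self.samples],
            columns=["sample_id", "donor", "condition"],
        )
        return wide, meta

    def with_efficiency(self, efficiency: Mapping[str, float]) -> "CtMatrix":
        new = dict(self.efficiency)
        new.update(efficiency)
        return replace(self, efficiency=new)


# -- I/O ---------------------------------------------------------------


def _matrix_from_long(df: pd.DataFrame, strict: bool, ct_max: float) -> CtMatrix:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise CtFormatError(f"long table is missing column(s): {missing}")
    df = df.copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    dup = df.duplicated(subset=["gene", "sample_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CtIntegrityError(
            f"duplicate measurement for gene {row['gene']!r}, "
            f"sample {row['sample_id']!r}"
        )
    genes = list(dict.fromkeys(df["gene"]))
    meta: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        m = SampleMeta(sid, str(row["donor"]), str(row["condition"]))
        if sid in meta and meta[sid] != m:
            raise CtIntegrityError(f"conflicting metadata for sample {sid!r}")
        meta.setdefault(sid, m)
    samples = list(meta.values())
    grid = np.full((len(genes), len(samples)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s.sample_id: i for i, s in enumerate(samples)}
    for _, row in df.iterrows():
        grid[gi[row["gene"]], si[str(row["sample_id"])]] = row["ct"]
    if not strict:
        keep = ~np.isnan(grid).any(axis=0)
        if not keep.all():
            dropped = [s.sample_id for s, k in zip(samples, keep) if not k]
            warnings.warn(
                f"permissive mode: dropped sample(s) with missing Ct: {dropped}",
                stacklevel=3,
            )
        samples = [s for s, k in zip(samples, keep) if k]
        grid = grid[:, keep]
    return CtMatrix(genes=genes, samples=samples, ct=grid, ct_max=ct_max)


def read_ct_table(
    path: str | Path,
    format: str = "long",
    metadata: str | Path | None = None,
    strict: bool = True,
    ct_max: float = DEFAULT_CT_MAX,
    efficiency: Mapping[str, float] | None = None,
) -> CtMatrix:
    """Read a Ct table from CSV and return a validated :class:`CtMatrix`.

    ``format="long"`` expects columns ``sample_id, donor, condition, gene,
    ct``; ``format="wide"`` expects genes as rows and samples as columns,
    with a sidecar ``metadata`` CSV (``sample_id, donor, condition``).
    Gene and sample order are preserved as first seen.  In strict mode a
    missing or unparseable Ct raises :class:`CtValidationError` naming the
    offending cell; in permissive mode the affected sample is dropped
    listwise for all genes (the stability algorithms require a complete
    grid).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long":
        df = pd.read_csv(path, dtype={"sample_id": str, "donor": str,
                                      "condition": str, "gene": str},
                         float_precision="round_trip")
        mat = _matrix_from_long(df, strict=strict, ct_max=ct_max)
    elif format == "wide":
        if metadata is None:
            raise CtFormatError("wide format requires a sidecar metadata table")
        wide = pd.read_csv(path, index_col=0, float_precision="round_trip")
        meta = pd.read_csv(metadata, dtype=str)
        need = {"sample_id", "donor", "condition"}
        if not need.issubset(meta.columns):
            raise CtFormatError(
                f"metadata table is missing column(s): {sorted(need - set(meta.columns))}"
            )
        meta_by_id = {
            row["sample_id"]: SampleMeta(
                row["sample_id"], row["donor"], row["condition"]
            )
            for _, row in meta.iterrows()
        }
        unknown = [c for c in wide.columns if c not in meta_by_id]
        if unknown:
            raise CtIntegrityError(f"samples without metadata: {unknown}")
        long = wide.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample_id", value_name="ct"
        )
        long["donor"] = [meta_by_id[s].donor for s in long["sample_id"]]
        long["condition"] = [meta_by_id[s].condition for s in long["sample_id"]]
        mat = _matrix_from_long(long, strict=strict, ct_max=ct_max)
        # preserve metadata-table sample order only if wide columns differ
        order = [mat.sample_index(c) for c in wide.columns]
        mat = CtMatrix(
            genes=mat.genes,
            samples=[mat.samples[i] for i in order],
            ct=mat.ct[:, order],
            ct_max=ct_max,
        )
    else:
        raise CtFormatError(f"unknown format {format!r}; expected 'long' or 'wide'")
    if efficiency:
        mat = mat.with_efficiency(efficiency)
    return mat


def write_ct_table(
    matrix: CtMatrix,
    path: str | Path,
    format: str = "long",
    metadata: str | Path | None = None,
) -> None:
    """Write a :class:`CtMatrix` to CSV in the long or wide dialect."""
    path = Path(path)
    if format == "long":
        matrix.to_long_frame().to_csv(path, index=False)
    elif format == "wide":
        if metadata is None:
            raise CtFormatError("wide format requires a metadata output path")
        wide, meta = matrix.to_wide_frame()
        wide.to_csv(path)
        meta.to_csv(metadata, index=False)
    else:
        raise CtFormatError(f"unknown format {format!r}")


# -- descriptive statistics --------------------------------------------


def summarize(
    matrix: CtMatrix,
    strata: str | Sequence[str] | None = "condition",
) -> pd.DataFrame:
    """Per-(gene, stratum) mean, sample SD and SEM of Ct.

    ``strata`` may be ``"condition"``, ``"donor"``, a sequence of both, or
    ``None`` / ``"all"`` for a single stratum pooling every sample (the
    study's "ALL" row).  SEM = SD/sqrt(n) with the n-1 SD; a stratum of
    size 1 has no SD/SEM (reported as NaN, with a warning).
    """
    if strata is None or strata == "all" or strata == "ALL":
        keys = [("ALL",) for _ in matrix.samples]
        names = ["stratum"]
    else:
        if isinstance(strata, str):
            strata = [strata]
        for s in strata:
            if s not in ("condition", "donor"):
                raise UnknownLabelError(f"unknown grouping key {s!r}")
        keys = [tuple(getattr(m, s) for s in strata) for m in matrix.samples]
        names = list(strata)
    out = []
    seen: list[tuple] = []
    for k in keys:
        if k not in seen:
            seen.append(k)
    for k in seen:
        cols = [i for i, kk in enumerate(keys) if kk == k]
        n = len(cols)
        sub = matrix.ct[:, cols]
        mean = sub.mean(axis=1)
        if n > 1:
            sd = sub.std(axis=1, ddof=1)
            sem = sd / np.sqrt(n)
        else:
            warnings.warn(
                f"stratum {k} has a single sample; SD/SEM undefined", stacklevel=2
            )
            sd = np.full(matrix.n_genes, np.nan)
            sem = np.full(matrix.n_genes, np.nan)
        for gi, g in enumerate(matrix.genes):
            out.append((g, *k, n, mean[gi], sd[gi], sem[gi]))
    return pd.DataFrame(out, columns=["gene", *names, "n", "mean", "sd", "sem"])


# -- config ------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML config (efficiencies, ct_max, strict flag) as a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise CtFormatError("config must be a YAML mapping")
    return cfg
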