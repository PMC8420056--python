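"""Core in-memory containers shared across the pipeline.

All tabular payloads are pandas objects so that they round-trip cleanly
through the TSV writers in :mod:`mqtlkit.io`; the dataclasses here only add
the semantics (condition labels, ground truth, grouping metadata) that a
bare DataFrame cannot carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ionization modes for LC-MS features
MODES = ("positive", "negative")

#: growth conditions: well-watered / drought-stressed
CONDITIONS = ("WW", "DS")


@dataclass
class FeatureTable:
    """Raw LC-MS-like feature intensities for one growth condition.

    Parameters
    ----------
    meta
        One row per feature (index = feature id) with columns
        ``mz`` (Da), ``rt`` (minutes) and ``mode`` (positive|negative).
    intensities
        Features x lines nonnegative intensities; NaN marks a missing cell.
    condition
        ``"WW"`` or ``"DS"``.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensities must share the feature index")
        bad_mode = set(self.meta["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown ionization mode(s): {sorted(bad_mode)}")
        if (self.meta["rt"] < 0).any() or (self.meta["mz"] <= 0).any():
            raise ValueError("require rt >= 0 and mz > 0 for every feature")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("intensities must be nonnegative where present")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells within this condition."""
        return self.intensities.isna().mean(axis=1)


@dataclass
class MetaboliteMatrix:
    """Deduplicated metabolite abundances, lines x metabolites, one condition.

    ``values`` holds natural-log abundances once :func:`mqtlkit.features
    .normalize_and_log` has run (``log_transformed`` is then True); before
    that it holds raw representative intensities. ``group_map`` records, for
    every retained metabolite, the member feature ids it represents.
    """

    values: pd.DataFrame
    condition: str
    group_map: dict[str, list[str]] = field(default_factory=dict)
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def raw_values(self) -> pd.DataFrame:
        """Values on the raw (pre-log) scale; identity if not yet logged."""
        return np.exp(self.values) if self.log_transformed else self.values


@dataclass
class GenotypeMatrix:
    """Biallelic dosages in {0,1,2}, lines x SNPs; NaN marks missing calls.

    ``variants`` is indexed by SNP id with columns ``chrom`` (str),
    ``pos`` (1-based bp, strictly increasing within a chromosome),
    ``ref``, ``alt`` and ``maf``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            raise ValueError("dosage columns must equal the variant index")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within each chromosome")

    @property
    def line_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def filter_maf(self, maf_min: float) -> "GenotypeMatrix":
        keep = self.variants.index[self.variants["maf"] >= maf_min]
        return GenotypeMatrix(self.dosages[keep], self.variants.loc[keep])


@dataclass
class GeneModelSet:
    """Gene spans: DataFrame indexed by gene id with chrom/start/end (1-based,
    inclusive, per GFF3 convention) and strand."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.genes.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end (1-based inclusive)")

    def span(self, gene_id: str) -> tuple[str, int, int]:
        if gene_id not in self.genes.index:
            raise KeyError(f"gene {gene_id!r} absent from gene models")
        row = self.genes.loc[gene_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])


@dataclass
class ExpressionMatrix:
    """Gene expression, lines x genes, one growth condition."""

    values: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PhenotypeTable:
    """Long-format phenotypes: line, environment, replicate, trait, value."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line", "environment", "replicate", "trait", "value"}
        if not required <= set(self.table.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")

    def trait(self, name: str, environment: str | None = None) -> pd.Series:
        """Per-line mean of one trait (optionally within one environment)."""
        sub = self.table[self.table["trait"] == name]
        if environment is not None:
            sub = sub[sub["environment"] == environment]
        if sub.empty:
            raise KeyError(f"trait {name!r} not present")
        return sub.groupby("line")["value"].mean()


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the synthetic generators.

    trait_effects maps trait id -> (snp id, effect size, PVE fraction);
    drought_shifts maps metabolite id -> injected log2 fold change (DS/WW);
    feature_groups maps metabolite id -> redundant feature ids derived from
    it; metabolite_weights_on_phenotype maps metabolite id -> weight in the
    survival-rate driver sum.
    """

    seed: int
    causal_snp_ids: list[str] = field(default_factory=list)
    trait_effects: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    drought_shifts: dict[str, float] = field(default_factory=dict)
    hub_gene_ids: list[str] = field(default_factory=list)
    metabolite_weights_on_phenotype: dict[str, float] = field(default_factory=dict)
    feature_groups: dict[str, list[str]] = field(default_factory=dict)
    condition_specific: dict[str, str] = field(default_factory=dict)

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        missing = set(self.causal_snp_ids) - set(genotypes.snp_ids)
        if missing:
            raise ValueError(f"causal SNPs absent from genotypes: {sorted(missing)[:5]}")
        per_trait: dict[str, float] = {}
        for trait, (_, _, pve) in self.trait_effects.items():
            if not 0 < pve < 1:
                raise ValueError(f"PVE for {trait!r} outside (0,1): {pve}")
            per_trait[trait] = per_trait.get(trait, 0.0) + pve
        too_big = {t: v for t, v in per_trait.items() if v > 0.95}
        if too_big:
            raise ValueError(f"summed PVE exceeds 0.95 for traits: {too_big}")
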