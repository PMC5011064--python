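"""Core in-memory containers shared across the pipeline.

Expression, genotype and sample-metadata tables are thin wrappers around
pandas DataFrames with the invariants the pipeline relies on (aligned sample
IDs, dosage bounds, an explicit normalization-state machine) enforced at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed expression-matrix states, in pipeline order. Transitions may only
#: move rightwards through this tuple.
EXPRESSION_STATES = (
    "raw",
    "depth_normalized",
    "filtered",
    "int_transformed",
    "residualized",
)


class StateError(ValueError):
    """Raised when an expression matrix is used at the wrong pipeline stage."""


@dataclass(frozen=True)
class MetaExon:
    """Union of all overlapping exons of one gene (the quantification unit).

    Coordinates are 1-based inclusive internally; BED I/O converts to
    0-based half-open. The TSS is the start on the + strand and the end on
    the - strand.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"malformed interval for {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def meta_exon_id(self) -> str:
        return f"{self.gene_id}:{self.chromosome}:{self.start}-{self.end}"


class ExpressionMatrix:
    """Meta-exon x sample expression values with a normalization-state flag.

    Parameters
    ----------
    values
        DataFrame with meta-exon IDs as the index and sample IDs as columns.
    state
        One of :data:`EXPRESSION_STATES`.
    gene_ids
        Optional Series mapping meta-exon ID -> gene ID (defaults to the part
        of the meta-exon ID before the first ':').
    """

    def __init__(self, values: pd.DataFrame, state: str, gene_ids: pd.Series | None = None):
        if state not in EXPRESSION_STATES:
            raise StateError(f"unknown expression state {state!r}")
        if values.index.duplicated().any():
            raise ValueError("duplicate meta-exon IDs")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        self.values = values
        self.state = state
        if gene_ids is None:
            gene_ids = pd.Series(
                [str(i).split(":")[0] for i in values.index], index=values.index
            )
        self.gene_ids = gene_ids.reindex(values.index)

    @property
    def meta_exon_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise StateError(
                f"operation requires state in {states}, matrix is {self.state!r}"
            )

    def advance(self, values: pd.DataFrame, new_state: str) -> "ExpressionMatrix":
        """Return a new matrix in ``new_state``, enforcing forward transitions."""
        if EXPRESSION_STATES.index(new_state) <= EXPRESSION_STATES.index(self.state):
            raise StateError(
                f"cannot move from {self.state!r} back to / onto {new_state!r}"
            )
        return ExpressionMatrix(values, new_state, self.gene_ids.reindex(values.index))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.state, self.gene_ids.copy())


class GenotypeMatrix:
    """Sample x SNP allele dosages in [0, 2] with SNP positions and alleles.

    ``snp_info`` is indexed by SNP ID with columns ``chromosome``,
    ``position``, ``effect_allele``, ``other_allele``.
    """

    def __init__(self, dosages: pd.DataFrame, snp_info: pd.DataFrame):
        if dosages.shape[0] == 0 or dosages.shape[1] == 0:
            raise ValueError("genotype matrix must have at least one sample and one SNP")
        arr = dosages.to_numpy(dtype=float)
        if np.nanmin(arr) < -1e-9 or np.nanmax(arr) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        missing = snp_info.index.symmetric_difference(dosages.columns)
        if len(missing):
            raise ValueError(f"snp_info / dosage column mismatch: {list(missing)[:5]}")
        self.dosages = dosages
        self.snp_info = snp_info.loc[dosages.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def maf(self) -> pd.Series:
        freq = self.dosages.mean(axis=0) / 2.0
        return pd.concat([freq, 1 - freq], axis=1).min(axis=1)

    def filter_maf(self, min_maf: float = 0.05) -> "GenotypeMatrix":
        keep = self.maf[self.maf >= min_maf].index
        return GenotypeMatrix(self.dosages[keep], self.snp_info.loc[keep])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[sample_ids], self.snp_info)


REQUIRED_METADATA_COLUMNS = ("age", "family", "zygosity")


class SampleMetadata:
    """Per-sample phenotype, age, family/zygosity codes and technical covariates.

    Twin coding follows the family/zygosity convention: co-twins share
    ``family``; MZ co-twins additionally share ``zygosity`` while each DZ twin
    and each unrelated individual carries a unique ``zygosity`` code.
    """

    def __init__(self, table: pd.DataFrame, phenotype_columns: tuple[str, ...] = ("bmi",),
                 technical_columns: tuple[str, ...] = ()):
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        for c in phenotype_columns + tuple(technical_columns):
            if c not in table.columns:
                raise ValueError(f"metadata missing declared column {c!r}")
        if table.index.duplicated().any():
            raise ValueError("duplicate sample IDs in metadata")
        self.table = table
        self.phenotype_columns = tuple(phenotype_columns)
        self.technical_columns = tuple(technical_columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def phenotype(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"phenotype {name!r} not in metadata")
        return self.table[name]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(
            self.table.loc[sample_ids], self.phenotype_columns, self.technical_columns
        )


@dataclass
class PlantedEffect:
    """A simulated regulatory effect, recorded for later recovery testing.

    ``beta_snp`` is expression (latent-scale SD units) per effect allele,
    ``beta_pheno`` per phenotype unit, ``beta_interaction`` per
    (allele x phenotype unit). ``trans_mediated`` effects route
    ``mediation_fraction`` of the interaction signal through the realized
    expression of ``mediator_gene_id``.
    """

    kind: str  # main_eqtl | gxe_interaction | trans_mediated
    gene_id: str
    snp_id: str
    beta_snp: float = 0.0
    beta_pheno: float = 0.0
    beta_interaction: float = 0.0
    mediator_gene_id: str | None = None
    mediation_fraction: float = 1.0
    n_trans_targets: int = 0

    VALID_KINDS = ("main_eqtl", "gxe_interaction", "trans_mediated")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "trans_mediated":
            if self.mediator_gene_id is None:
                raise ValueError("trans_mediated effects require a mediator gene")
            if not 0.0 <= self.mediation_fraction <= 1.0:
                raise ValueError("mediation_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Realized planted effects plus per-sample latent factor scores."""

    effects: list[PlantedEffect] = field(default_factory=list)
    latent_scores: pd.DataFrame | None = None  # sample x factor

    def by_gene(self, gene_id: str) -> list[PlantedEffect]:
        return [e for e in self.effects if e.gene_id == gene_id]

    def add(self, effect: PlantedEffect) -> None:
        cis_kinds = {"main_eqtl", "gxe_interaction"}
        if effect.kind in cis_kinds:
            for prior in self.by_gene(effect.gene_id):
                if prior.kind in cis_kinds and prior.snp_id != effect.snp_id:
                    raise ValueError(
                        f"gene {effect.gene_id} already carries a cis effect at "
                        f"{prior.snp_id}; refusing conflicting plant at {effect.snp_id}"
                    )
        self.effects.append(effect)
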