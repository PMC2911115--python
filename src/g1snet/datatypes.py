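"""Core domain containers.

The analysis revolves around a fixed candidate list of genes (445 in the
default simulated design) observed across a Cln3-induction time course in
six genotypes, four genome-wide TF-binding studies, promoter sequences
anchored at the transcription start site (TSS), cell-cycle peak times and
two overexpression responses.  Everything downstream consumes the types
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateGeneError, ValidationError

#: Genotypes of the induction time course.  ``wt`` responds through both
#: MBF and SBF; ``swi6`` and ``swi4mbp1`` abolish both pathways;
#: ``cln3control`` carries no inducible Cln3 and stays flat.
STRAINS = ("wt", "mbp1", "swi4", "swi6", "swi4mbp1", "cln3control")

#: Sampling times (minutes after induction); values are log2 ratios vs t=0.
TIMEPOINTS = (20, 40, 60, 80)

TFS = ("Mbp1", "Swi4")

#: The four genome-wide location (ChIP-chip) studies.  ``iyer`` is the
#: Swi4-rich study whose SBF calls receive their own binding category;
#: ``harbison`` is the multi-condition study with the broadest Mbp1 coverage.
BINDING_STUDIES = ("iyer", "simon", "lee", "harbison")
SWI4_WEIGHTED_STUDY = "iyer"

PROMOTER_ALPHABET = frozenset("ACGTN")
TSS_ANCHORS = ("tss", "start_codon")


def normalize_gene_name(name: str) -> str:
    """Uppercase systematic name; comparisons are case-insensitive."""
    s = str(name).strip().upper()
    if not s:
        raise ValidationError("gene systematic name must be non-empty")
    return s


@dataclass(frozen=True)
class GeneId:
    """A gene keyed by its systematic name (e.g. YMR179W).

    The standard name (e.g. SPT21) is annotation only: equality and hashing
    use the uppercased systematic name exclusively.
    """

    systematic_name: str
    standard_name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "systematic_name", normalize_gene_name(self.systematic_name))

    def __eq__(self, other) -> bool:
        if isinstance(other, GeneId):
            return self.systematic_name == other.systematic_name
        if isinstance(other, str):
            return self.systematic_name == other.strip().upper()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.systematic_name)


@dataclass
class ExpressionPanel:
    """Log2 induction time courses, genes x (strain, timepoint).

    ``values`` is indexed by systematic gene name with a two-level column
    index (strain, minutes).  A (gene, strain) block is either fully
    observed at all four timepoints or wholly missing.
    """

    values: pd.DataFrame

    @classmethod
    def build(cls, genes, per_strain: dict[str, np.ndarray]) -> "ExpressionPanel":
        """Assemble from one (n_genes, 4) array per strain."""
        genes = [normalize_gene_name(g) for g in genes]
        if len(set(genes)) != len(genes):
            raise DuplicateGeneError("duplicate gene in expression panel")
        cols = pd.MultiIndex.from_product(
            [list(per_strain), list(TIMEPOINTS)], names=["strain", "minutes"]
        )
        data = np.hstack([np.asarray(per_strain[s], dtype=float) for s in per_strain])
        df = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cols)
        panel = cls(df)
        panel.validate()
        return panel

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns.get_level_values("strain").unique())

    def profile(self, gene: str, strain: str) -> np.ndarray | None:
        """Return the 4-point series for (gene, strain), or None if absent."""
        gene = normalize_gene_name(gene)
        if gene not in self.values.index or strain not in self.strains:
            return None
        row = self.values.loc[gene, strain].to_numpy(dtype=float)
        if np.isnan(row).all():
            return None
        return row

    def strain_matrix(self, strain: str) -> pd.DataFrame:
        """(n_genes, 4) frame of one strain's time courses."""
        return self.values[strain]

    def validate(self) -> None:
        for strain in self.strains:
            block = self.values[strain].to_numpy(dtype=float)
            miss = np.isnan(block)
            partial = miss.any(axis=1) & ~miss.all(axis=1)
            if partial.any():
                gene = self.values.index[int(np.flatnonzero(partial)[0])]
                raise ValidationError(
                    f"gene {gene!r}, strain {strain!r}: partially observed time course"
                )
            if np.isinf(block).any():
                raise ValidationError(f"non-finite expression value in strain {strain!r}")


@dataclass(frozen=True)
class BindingCallSet:
    """Bound-gene calls of one TF in one genome-wide location study."""

    study_id: str
    tf: str
    bound_genes: frozenset
    call_threshold_note: str = ""

    def __post_init__(self) -> None:
        if self.study_id not in BINDING_STUDIES:
            raise ValidationError(f"unknown binding study {self.study_id!r}")
        if self.tf not in TFS:
            raise ValidationError(f"unknown TF {self.tf!r}")
        object.__setattr__(
            self, "bound_genes", frozenset(normalize_gene_name(g) for g in self.bound_genes)
        )

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_name(gene) in self.bound_genes


@dataclass(frozen=True)
class PromoterRecord:
    gene: str
    sequence: str  # 5'->3'; the LAST base sits immediately upstream of the TSS
    anchor: str = "tss"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene_name(self.gene))
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.anchor not in TSS_ANCHORS:
            raise ValidationError(f"unknown promoter anchor {self.anchor!r}")
        bad = set(self.sequence) - PROMOTER_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValidationError(
                f"illegal character {self.sequence[pos]!r} at position {pos + 1} "
                f"in promoter of {self.gene}"
            )


@dataclass
class PromoterSet:
    """Upstream sequences, one per gene, each at most ``max_length`` bp.

    Coordinate convention: promoter position 1 is the base immediately
    upstream of the TSS (the last character of the stored string); position
    k is k bp upstream.  "Within the first 200 bp upstream" therefore means
    positions 1..200.
    """

    records: dict = field(default_factory=dict)
    max_length: int = 1000

    def add(self, record: PromoterRecord) -> None:
        if record.gene in self.records:
            raise DuplicateGeneError(f"duplicate promoter for {record.gene}")
        if len(record.sequence) > self.max_length:
            raise ValidationError(
                f"promoter of {record.gene} exceeds max_length={self.max_length}"
            )
        self.records[record.gene] = record

    def sequence(self, gene: str) -> str | None:
        rec = self.records.get(normalize_gene_name(gene))
        return rec.sequence if rec else None

    @property
    def genes(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_name(gene) in self.records


@dataclass
class CellCyclePeakMap:
    """Peak expression time as percent of cycle duration, in [0, 100).

    Missing entries (NaN) correspond to genes with no determined peak
    ("ND" in printed tables), e.g. genes not cell-cycle regulated.
    """

    peaks: pd.Series

    def __post_init__(self) -> None:
        self.peaks = self.peaks.astype(float)
        self.peaks.index = [normalize_gene_name(g) for g in self.peaks.index]
        vals = self.peaks.dropna()
        if ((vals < 0) | (vals >= 100)).any():
            raise ValidationError("cell-cycle peaks must lie in [0, 100)")

    def get(self, gene: str) -> float:
        """Peak percent, or NaN if missing/unknown gene."""
        return float(self.peaks.get(normalize_gene_name(gene), np.nan))


@dataclass
class OverexpressionResponse:
    """Per-gene log2 responses to Cln3 and Clb2 overexpression.

    Stored as a frame with columns ``cln3_induction`` and ``clb2_response``;
    either may be NaN for a given gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"cln3_induction", "clb2_response"}
        if not needed.issubset(self.table.columns):
            raise ValidationError(f"overexpression table needs columns {sorted(needed)}")
        self.table.index = [normalize_gene_name(g) for g in self.table.index]
        if np.isinf(self.table[list(needed)].to_numpy(dtype=float)).any():
            raise ValidationError("overexpression values must be finite where present")

    def get(self, gene: str, which: str) -> float:
        gene = normalize_gene_name(gene)
        if gene not in self.table.index:
            return float("nan")
        return float(self.table.loc[gene, which])
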