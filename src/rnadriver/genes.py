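"""Gene models: coordinates, exon structure, covariates and category flags.

Coordinates are 1-based, fully closed intervals. Genes on one chromosome
never overlap, so sorting by start position defines an unambiguous
neighbor order (``rank``), which the fusion stage uses for read-through
detection and flanking-gene scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import AnnotationError

#: Census-curated driver genes used to seed the simulated driver subset.
KNOWN_DRIVER_GENES: tuple[str, ...] = (
    "TLX1", "TLX3", "PHF6", "MYC", "BCL11B", "HOXA1", "SET", "MLL",
    "MLLT1", "PICALM", "MLLT10", "WT1", "MYB", "LEF1", "LMO2", "LMO1",
    "TAL1", "NUP98", "NOTCH1", "FBXW7", "CCND2", "PTEN", "PTPN2", "NF1",
    "FLT3", "JAK1", "NRAS", "LCK", "NUP214", "ABL1", "EZH2", "SETD2",
    "SUZ12", "JAK3", "MEF2C", "NKX2-1", "NKX2-2", "CDKN2A", "CDKN2B",
    "RUNX1", "KRAS", "EED", "ETV6", "RPL10", "DNM2", "IL7R", "CNOT3",
)

#: Transcription factors whose expression patterns define the subtypes.
SUBTYPE_TFS: tuple[str, ...] = ("TAL1", "TLX1", "TLX3", "NKX2-5", "LYL1", "LMO2")

#: Driver genes that act by loss of function.
TUMOR_SUPPRESSORS: frozenset[str] = frozenset(
    {"PTEN", "PTPN2", "NF1", "WT1", "CDKN2A", "CDKN2B", "FBXW7",
     "SUZ12", "EED", "ETV6", "PHF6", "TP53"}
)


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, exons, covariates and category flags."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    exons: tuple[tuple[int, int], ...]
    gc: float
    length: int  # exonic length in bp
    rank: int    # order index on its chromosome (0-based)
    is_coding: bool = True
    is_ribosomal: bool = False
    is_chrm: bool = False
    is_driver: bool = False
    is_tumor_suppressor: bool = False
    is_tf: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad span for {self.gene_id}: {self.start}-{self.end}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"GC fraction out of range for {self.gene_id}")


class GeneCatalog:
    """Indexed collection of :class:`GeneModel` with neighbor lookups."""

    def __init__(self, models: list[GeneModel]):
        self._models = {m.gene_id: m for m in models}
        if len(self._models) != len(models):
            raise ValueError("duplicate gene ids in catalog")
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        self._by_chrom = {c: sorted(ms, key=lambda m: m.start) for c, ms in by_chrom.items()}

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __iter__(self):
        return iter(self._models.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._models[gene_id]
        except KeyError:
            raise AnnotationError(f"gene {gene_id!r} absent from catalog") from None

    @property
    def gene_ids(self) -> list[str]:
        return list(self._models)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def chromosome_genes(self, chrom: str) -> list[GeneModel]:
        """Genes on ``chrom`` sorted by start coordinate."""
        return list(self._by_chrom.get(chrom, []))

    def are_adjacent(self, gene_a: str, gene_b: str) -> bool:
        """True if the two genes are rank-consecutive on one chromosome."""
        a, b = self[gene_a], self[gene_b]
        return a.chrom == b.chrom and abs(a.rank - b.rank) == 1

    def neighbors(self, gene_id: str, window: int) -> tuple[list[GeneModel], bool]:
        """Genes within ``window`` ranks of ``gene_id`` on its chromosome.

        Returns the neighbor list (the gene itself first, then by absolute
        rank offset, downstream before upstream at equal offset) and a flag
        marking a window truncated at a contig edge.
        """
        g = self[gene_id]
        chrom_genes = self._by_chrom[g.chrom]
        out = [g]
        truncated = False
        for off in range(1, window + 1):
            for idx in (g.rank + off, g.rank - off):
                if 0 <= idx < len(chrom_genes):
                    out.append(chrom_genes[idx])
                else:
                    truncated = True
        return out, truncated

    def to_frame(self) -> pd.DataFrame:
        """Flat per-gene table indexed by gene id."""
        rows = [
            {
                "gene_id": m.gene_id, "chrom": m.chrom, "start": m.start,
                "end": m.end, "strand": m.strand, "gc": m.gc, "length": m.length,
                "rank": m.rank, "n_exons": len(m.exons), "is_coding": m.is_coding,
                "is_ribosomal": m.is_ribosomal, "is_chrm": m.is_chrm,
                "is_driver": m.is_driver,
                "is_tumor_suppressor": m.is_tumor_suppressor, "is_tf": m.is_tf,
            }
            for m in self
        ]
        return pd.DataFrame(rows).set_index("gene_id", drop=False)


@dataclass
class SampleMeta:
    """Identity and grouping of one cohort sample."""

    sample_id: str
    sample_type: str  # patient | cell_line | thymus
    center: str
    cohort: str = "NA"  # adult | pediatric | NA
    subtype: str | None = field(default=None)

    VALID_TYPES = ("patient", "cell_line", "thymus")

    def __post_init__(self) -> None:
        if self.sample_type not in self.VALID_TYPES:
            raise ValueError(f"unknown sample type {self.sample_type!r}")


def sample_meta_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "sample_type": m.sample_type,
             "center": m.center, "cohort": m.cohort, "subtype": m.subtype}
            for m in metas
        ]
    )
    return df.set_index("sample_id", drop=False)
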