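"""RNA-seq vs exome callset comparison and allelic-imbalance breakdown.

Call categories (shared / RNA-only / exome-only) are computed only over
positions covered at >= ``min_depth`` in both assays. The heterozygous-site
breakdown classes each DNA-het site by its RNA genotype (absent but covered
counts as homozygous reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError, PairingError
from .variants import classify_genotype

_KEY = ["sample_id", "chrom", "pos", "alt"]


@dataclass
class HetBreakdown:
    """RNA genotype classes of DNA-heterozygous sites."""

    n_total: int
    n_het: int
    n_hom_ref: int
    n_hom_var: int
    n_uncovered_as_homref: int = 0

    def __post_init__(self) -> None:
        if self.n_het + self.n_hom_ref + self.n_hom_var != self.n_total:
            raise InputError("breakdown classes must partition the total")
        if min(self.n_total, self.n_het, self.n_hom_ref, self.n_hom_var) < 0:
            raise InputError("negative class count")

    @classmethod
    def from_counts(cls, total: int, het: int, hom_var: int) -> "HetBreakdown":
        """Complete a breakdown from the total and two class counts (the
        remaining class follows from the partition constraint)."""
        return cls(n_total=total, n_het=het,
                   n_hom_ref=total - het - hom_var, n_hom_var=hom_var)

    @property
    def het_fraction(self) -> float:
        return self.n_het / self.n_total

    @property
    def hom_var_fraction(self) -> float:
        return self.n_hom_var / self.n_total

    @property
    def het_percent(self) -> int:
        """Het-concordant fraction, integer percent."""
        return round(100.0 * self.het_fraction)

    @property
    def hom_var_percent(self) -> float:
        """Allelic-imbalance (hom-var) fraction, percent with one decimal."""
        return round(100.0 * self.hom_var_fraction, 1)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total, "n_het": self.n_het,
            "n_hom_ref": self.n_hom_ref, "n_hom_var": self.n_hom_var,
            "het_percent": self.het_percent, "hom_var_percent": self.hom_var_percent,
        }


@dataclass
class ConcordanceReport:
    n_both: int
    n_rna_only: int
    n_exome_only: int
    recall: float                     # coverage-conditioned
    recall_unconditioned: float
    vaf_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    het_breakdown: HetBreakdown | None = None

    def to_dict(self) -> dict:
        d = {"n_both": self.n_both, "n_rna_only": self.n_rna_only,
             "n_exome_only": self.n_exome_only, "recall": self.recall,
             "recall_unconditioned": self.recall_unconditioned}
        if self.het_breakdown is not None:
            d["het_breakdown"] = self.het_breakdown.to_dict()
        return d


def _covered(df: pd.DataFrame, min_depth: int, strict: bool) -> pd.Series:
    if strict:
        return (df["depth"] > min_depth) & (df["other_depth"] > min_depth)
    return (df["depth"] >= min_depth) & (df["other_depth"] >= min_depth)


def compare_callsets(exome_calls: pd.DataFrame, rna_calls: pd.DataFrame,
                     min_depth: int = 20, strict: bool = False) -> ConcordanceReport:
    """Three disjoint categories over positions covered in both assays,
    recall over exome calls, and the VAF scatter table for shared sites.

    Each table must carry ``depth`` (own assay) and ``other_depth`` (the
    other assay at the same position).
    """
    ex_samples = set(exome_calls["sample_id"].unique())
    rna_samples = set(rna_calls["sample_id"].unique())
    if ex_samples and rna_samples and not (rna_samples <= ex_samples or
                                           ex_samples <= rna_samples):
        raise PairingError(
            f"sample identifiers do not pair: {sorted(ex_samples ^ rna_samples)[:5]}")

    ex = exome_calls[_covered(exome_calls, min_depth, strict)]
    rna = rna_calls[_covered(rna_calls, min_depth, strict)]
    ex_keys = ex[_KEY].apply(tuple, axis=1)
    rna_keys = rna[_KEY].apply(tuple, axis=1)
    shared = set(ex_keys) & set(rna_keys)
    n_both = len(shared)
    n_exome_only = len(set(ex_keys) - shared)
    n_rna_only = len(set(rna_keys) - shared)
    recall = n_both / (n_both + n_exome_only) if (n_both + n_exome_only) else 1.0
    all_ex_keys = set(exome_calls[_KEY].apply(tuple, axis=1)) if len(exome_calls) else set()
    all_rna_keys = set(rna_calls[_KEY].apply(tuple, axis=1)) if len(rna_calls) else set()
    n_called_both = len(all_ex_keys & all_rna_keys)
    recall_unconditioned = n_called_both / len(all_ex_keys) if all_ex_keys else 1.0

    if n_both:
        pairs = ex[ex_keys.isin(shared)][_KEY + ["vaf"]].rename(
            columns={"vaf": "vaf_exome"})
        pairs = pairs.merge(rna[_KEY + ["vaf"]].rename(columns={"vaf": "vaf_rna"}),
                            on=_KEY)
    else:
        pairs = pd.DataFrame(columns=_KEY + ["vaf_exome", "vaf_rna"])
    return ConcordanceReport(
        n_both=n_both, n_rna_only=n_rna_only, n_exome_only=n_exome_only,
        recall=recall, recall_unconditioned=recall_unconditioned, vaf_pairs=pairs)


def allelic_imbalance_breakdown(dna_het_sites: pd.DataFrame,
                                rna_calls: pd.DataFrame,
                                min_depth: int = 20,
                                het_low: float = 0.2,
                                het_high: float = 0.8) -> HetBreakdown:
    """Class each DNA-heterozygous site by its RNA genotype.

    Sites with RNA coverage (``other_depth`` on the DNA table) below
    ``min_depth`` are excluded from the breakdown. Covered sites absent
    from the RNA callset count as homozygous reference; sites with no
    coverage information at all are counted homozygous reference with a
    warning.
    """
    dna = dna_het_sites.copy()
    if "other_depth" in dna.columns:
        dna = dna[dna["other_depth"] >= min_depth]
    else:
        warnings.warn("no RNA coverage information; uncovered sites counted hom_ref",
                      stacklevel=2)
    if dna.empty:
        raise InputError("no DNA-het sites with sufficient RNA coverage")
    merged = dna.merge(
        rna_calls[_KEY + ["vaf", "depth"]].rename(
            columns={"vaf": "rna_vaf", "depth": "rna_depth"}),
        on=_KEY, how="left")
    n_het = n_hom_ref = n_hom_var = n_uncov = 0
    for _, row in merged.iterrows():
        if pd.isna(row["rna_vaf"]):
            n_hom_ref += 1
            if "other_depth" not in dna_het_sites.columns:
                n_uncov += 1
            continue
        cls = classify_genotype(float(row["rna_vaf"]), int(row["rna_depth"]),
                                het_low, het_high)
        if cls == "het":
            n_het += 1
        elif cls == "hom_var":
            n_hom_var += 1
        else:
            n_hom_ref += 1
    return HetBreakdown(n_total=len(merged), n_het=n_het, n_hom_ref=n_hom_ref,
                        n_hom_var=n_hom_var, n_uncovered_as_homref=n_uncov)
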