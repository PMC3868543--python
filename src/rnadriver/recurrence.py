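"""Recurrence-based driver-gene selection and cohort mutation-burden statistics.

Recurrence counts distinct mutated *patient* samples per gene (multiple
hits in one sample count once; cell lines and thymus are excluded from
counting but annotated). Burden comparison uses a two-sided Mann-Whitney
test, exact when both groups are small and tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, StatisticsError


@dataclass
class RecurrenceResult:
    gene_patients: dict[str, frozenset[str]]
    selected: list[str]
    cellline_hits: dict[str, frozenset[str]] = field(default_factory=dict)
    per_sample_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    min_recurrence: int = 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, patients in sorted(self.gene_patients.items(),
                                     key=lambda kv: (-len(kv[1]), kv[0])):
            rows.append({
                "gene_id": gene,
                "n_patients": len(patients),
                "patients": ",".join(sorted(patients)),
                "n_celllines": len(self.cellline_hits.get(gene, frozenset())),
                "selected": gene in self.selected,
            })
        return pd.DataFrame(rows)


def select_recurrent_genes(protein_altering_calls: pd.DataFrame,
                           sample_meta: pd.DataFrame,
                           min_recurrence: int = 2) -> RecurrenceResult:
    """Genes with protein-altering mutations in >= ``min_recurrence``
    distinct patient samples."""
    unknown = set(protein_altering_calls["sample_id"]) - set(sample_meta.index)
    if unknown:
        raise PairingError(f"calls reference unknown samples: {sorted(unknown)[:5]}")
    types = sample_meta["sample_type"]
    calls = protein_altering_calls
    is_patient = calls["sample_id"].map(types).eq("patient")
    gene_patients = {
        g: frozenset(sub["sample_id"])
        for g, sub in calls[is_patient].groupby("gene_id")
    }
    cellline_hits = {
        g: frozenset(sub["sample_id"])
        for g, sub in calls[calls["sample_id"].map(types).eq("cell_line")]
        .groupby("gene_id")
    }
    selected = sorted(g for g, p in gene_patients.items()
                      if len(p) >= min_recurrence)
    per_sample = (calls.drop_duplicates(subset=["sample_id", "chrom", "pos", "alt"])
                  .groupby("sample_id").size()
                  .reindex(sample_meta.index, fill_value=0))
    return RecurrenceResult(gene_patients=gene_patients, selected=selected,
                            cellline_hits=cellline_hits,
                            per_sample_counts=per_sample,
                            min_recurrence=min_recurrence)


def compare_mutation_burden(per_sample_counts: pd.Series,
                            sample_meta: pd.DataFrame,
                            group_a: str = "cell_line",
                            group_b: str = "patient") -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-sample mutation counts between two
    sample types. Exact enumeration when both groups have <= 12 samples and
    no cross-group ties; tie-corrected normal approximation otherwise."""
    types = sample_meta["sample_type"]
    x = per_sample_counts[types.reindex(per_sample_counts.index).eq(group_a)].to_numpy()
    y = per_sample_counts[types.reindex(per_sample_counts.index).eq(group_b)].to_numpy()
    return mann_whitney_u(x, y)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2 or len(y) < 2:
        raise StatisticsError("each group needs >= 2 samples")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return u, 1.0
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))


def median_burden(per_sample_counts: pd.Series,
                  sample_meta: pd.DataFrame | None = None,
                  group: str | None = None) -> float:
    """Median count, optionally restricted to one sample type
    (mean of the central pair for even group sizes)."""
    counts = per_sample_counts
    if group is not None:
        if sample_meta is None:
            raise StatisticsError("sample_meta required when group is given")
        mask = sample_meta["sample_type"].reindex(counts.index).eq(group)
        counts = counts[mask]
    if len(counts) == 0:
        raise StatisticsError("empty group")
    return float(np.median(counts.to_numpy()))
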