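"""Template-matching co-expression and gene-set enrichment.

Template matching correlates every gene's expression profile with a
template gene's profile and converts Pearson r to a two-sided p-value via
the t transform on n-2 degrees of freedom. Enrichment uses the weighted
Kolmogorov-Smirnov running sum with a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GroupingError, InputError, StatisticsError
from .normalize import NormalizedMatrix


def pearson_template_pvalues(values: pd.DataFrame,
                             template: np.ndarray) -> pd.DataFrame:
    """Vectorized Pearson r of every row against a template profile with
    parametric two-sided p-values."""
    n = values.shape[1]
    if n < 4:
        raise StatisticsError("need at least 4 samples")
    t = np.asarray(template, dtype=float)
    if np.std(t) == 0:
        raise StatisticsError("zero-variance template profile")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ tc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame({"pearson_r": r, "p_value": p, "n_samples": n},
                        index=values.index)


def ptm_neighbors(data, template_gene: str,
                  p_threshold: float = 1e-5) -> pd.DataFrame:
    """Expression neighbors of a template gene: genes whose profiles
    correlate with the template at p <= threshold (template excluded)."""
    values = data.values if isinstance(data, NormalizedMatrix) else data
    if template_gene not in values.index:
        raise InputError(f"template gene {template_gene!r} absent")
    res = pearson_template_pvalues(values, values.loc[template_gene].to_numpy())
    res = res.drop(index=template_gene)
    hits = res[res["p_value"] <= p_threshold].sort_values("p_value")
    return hits.reset_index(names="gene_id")


def rank_by_group_lfc(data, marker_gene: str | None = None,
                      sample_groups: pd.Series | None = None,
                      expressing_quantile: float = 0.75) -> pd.Series:
    """Whole-genome ranking by mean log2 difference between samples
    expressing a marker gene (above its cohort quantile) and the rest.

    Alternatively pass ``sample_groups`` as a boolean series (True = in
    group). Returns a descending series gene -> log fold change.
    """
    values = data.values if isinstance(data, NormalizedMatrix) else data
    if sample_groups is None:
        if marker_gene is None:
            raise InputError("need marker_gene or sample_groups")
        if marker_gene not in values.index:
            raise InputError(f"marker gene {marker_gene!r} absent")
        profile = values.loc[marker_gene]
        cut = profile.quantile(expressing_quantile)
        sample_groups = profile > cut
    sample_groups = sample_groups.reindex(values.columns).astype(bool)
    if sample_groups.all() or not sample_groups.any():
        raise GroupingError("marker splits samples into an empty group")
    in_g = values.loc[:, sample_groups].mean(axis=1)
    out_g = values.loc[:, ~sample_groups].mean(axis=1)
    return (in_g - out_g).sort_values(ascending=False)


@dataclass
class EnrichmentResult:
    gene_set_id: str
    es: float
    p_value: float
    n_hits: int
    n_perm: int
    running_sum: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {"gene_set_id": self.gene_set_id, "es": self.es,
                "p_value": self.p_value, "n_hits": self.n_hits,
                "n_perm": self.n_perm}


def _enrichment_score(scores: np.ndarray, hit_mask: np.ndarray,
                      weight: float) -> tuple[float, np.ndarray]:
    n = len(scores)
    n_hit = int(hit_mask.sum())
    w = np.abs(scores) ** weight if weight > 0 else np.ones(n)
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit)) if n > n_hit else np.zeros(n)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_enrichment(ranking: pd.Series, gene_set, n_perm: int = 1000,
                    seed: int = 0, weight: float = 1.0,
                    gene_set_id: str = "gene_set") -> EnrichmentResult:
    """Weighted KS enrichment of a gene set in a ranked list.

    ES is the signed extremum of the running sum (hit increments weighted
    by |rank metric| ** weight). The p-value is a one-sided gene-label
    permutation test conditioned on the sign of the observed ES.
    """
    gene_set = set(gene_set)
    if len(gene_set) < 5:
        raise InputError("gene set must have >= 5 members")
    ranking = ranking.sort_values(ascending=False)
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(gene_set))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise InputError("gene set disjoint from the ranking")
    if n_hits == len(genes):
        raise InputError("gene set covers the whole ranking")
    es, running = _enrichment_score(scores, hit_mask, weight)

    rng = np.random.default_rng(seed)
    n = len(genes)
    same_sign = 0
    extreme = 0
    for _ in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
        perm_es, _ = _enrichment_score(scores, perm_mask, weight)
        if np.sign(perm_es) == np.sign(es) or es == 0:
            same_sign += 1
            if abs(perm_es) >= abs(es):
                extreme += 1
    p = (1 + extreme) / (1 + same_sign) if same_sign else 1.0 / (1 + n_perm)
    return EnrichmentResult(gene_set_id=gene_set_id, es=es, p_value=float(p),
                            n_hits=n_hits, n_perm=n_perm, running_sum=running)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
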