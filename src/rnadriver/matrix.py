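"""Gene-by-sample count container shared by the simulator and normalization."""

from __future__ import annotations

import pandas as pd

from .errors import InputError


class CountMatrix:
    """Integer gene-by-sample counts with gene and sample annotations.

    ``counts`` is genes x samples; ``gene_meta`` is indexed by gene id and
    must carry at least ``gc`` and ``length``; ``sample_meta`` is indexed by
    sample id and must carry ``sample_type`` and ``center``.
    """

    def __init__(self, counts: pd.DataFrame, gene_meta: pd.DataFrame,
                 sample_meta: pd.DataFrame):
        if (counts.values < 0).any():
            raise InputError("negative entries in count matrix")
        if not counts.index.isin(gene_meta.index).all():
            missing = counts.index.difference(gene_meta.index)
            raise InputError(f"genes missing from annotation: {list(missing[:5])}")
        if not counts.columns.isin(sample_meta.index).all():
            missing = counts.columns.difference(sample_meta.index)
            raise InputError(f"samples missing from metadata: {list(missing[:5])}")
        self.counts = counts
        self.gene_meta = gene_meta.loc[counts.index]
        self.sample_meta = sample_meta.loc[counts.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_meta,
                           self.sample_meta.loc[list(sample_ids)])
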