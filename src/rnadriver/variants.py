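"""SNV/INDEL filter cascade and protein-altering selection.

The cascade applies, in a fixed order, the read-position, depth, allele
frequency, population-database (with somatic-catalog rescue), repeat and
normal-panel/thymus filters; INDELs additionally pass an upstream
caller-quality flag and a homopolymer-context rule. Every decision is
recorded in a :class:`FilterTrace` whose counts telescope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError, StatisticsError

PROTEIN_ALTERING_SNV: frozenset[str] = frozenset({
    "splice-donor-variant", "splice-acceptor-variant", "stop-gained",
    "initiator-codon-variant", "missense-variant", "splice-region-variant",
})
PROTEIN_ALTERING_INDEL: frozenset[str] = PROTEIN_ALTERING_SNV | frozenset({
    "inframe-insertion", "inframe-deletion", "frameshift-variant",
})

#: Terms recognized as valid annotations even though they are not altering.
_KNOWN_NEUTRAL: frozenset[str] = frozenset({
    "synonymous-variant", "intron-variant", "3-prime-UTR-variant",
    "5-prime-UTR-variant", "upstream-gene-variant", "downstream-gene-variant",
    "non-coding-transcript-variant", "intergenic-variant", "stop-retained-variant",
})

SNV_CASCADE = ("read_end", "depth", "vaf", "population_db", "repeat",
               "normal_panel", "thymus")
INDEL_CASCADE = ("caller_qc", "homopolymer", "population_db", "repeat",
                 "normal_panel", "thymus")


@dataclass
class FilterConfig:
    min_depth: int = 20
    min_vaf: float = 0.20
    max_homopolymer: int = 5
    cosmic_rescue: bool = True
    protein_altering_terms_snv: frozenset[str] = PROTEIN_ALTERING_SNV
    protein_altering_terms_indel: frozenset[str] = PROTEIN_ALTERING_INDEL

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")
        if not 0.0 < self.min_vaf <= 1.0:
            raise ConfigurationError("min_vaf must be in (0, 1]")
        if self.max_homopolymer < 1:
            raise ConfigurationError("max_homopolymer must be >= 1")


@dataclass
class FilterTrace:
    """Per-rule removal counts (in cascade order) and per-variant status.

    ``status`` holds, for every input variant, either ``"retained"`` or the
    name of the first failing rule. Counts telescope:
    ``n_input == n_retained + sum(removed.values())``.
    """

    cascade: tuple[str, ...]
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    status: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows, remaining = [], self.n_input
        for rule in self.cascade:
            gone = self.removed.get(rule, 0)
            remaining -= gone
            rows.append({"rule": rule, "removed": gone, "retained": remaining})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"cascade": list(self.cascade), "n_input": self.n_input,
                "removed": dict(self.removed), "n_retained": self.n_retained}


def classify_genotype(vaf: float, depth: int, het_low: float = 0.2,
                      het_high: float = 0.8) -> str:
    """Genotype class from VAF bins: hom_ref < het_low <= het < het_high <= hom_var."""
    if depth < 1:
        raise StatisticsError("genotype undefined at zero depth")
    if not 0.0 <= vaf <= 1.0:
        raise InputError(f"VAF out of range: {vaf}")
    if vaf < het_low:
        return "hom_ref"
    if vaf < het_high:
        return "het"
    return "hom_var"


def homopolymer_run_length(context: str, anchor: int) -> int:
    """Length of the longest single-nucleotide run touching the INDEL anchor.

    ``anchor`` is the 0-based index of the INDEL anchor base within
    ``context``. A run touches the anchor when it covers it or ends/starts
    immediately next to it.
    """
    if not context:
        raise FormatError("empty homopolymer context")
    if any(c not in "ACGTN" for c in context.upper()):
        raise FormatError(f"non-nucleotide characters in context {context!r}")
    if not 0 <= anchor < len(context):
        raise FormatError(f"anchor {anchor} outside context of length {len(context)}")
    ctx = context.upper()
    best = 0
    start = 0
    for i in range(1, len(ctx) + 1):
        if i == len(ctx) or ctx[i] != ctx[start]:
            end = i - 1  # run is [start, end]
            if start <= anchor + 1 and end >= anchor - 1:
                best = max(best, end - start + 1)
            start = i
    return best


def _population_db_fail(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    in_db = df["in_dbsnp"] | df["in_1000g"] | df["in_cg"]
    if cfg.cosmic_rescue:
        return in_db & ~df["in_cosmic"]
    return in_db


def _run_cascade(df: pd.DataFrame, cascade: tuple[str, ...],
                 predicates: dict[str, pd.Series]) -> tuple[pd.DataFrame, FilterTrace]:
    trace = FilterTrace(cascade=cascade, n_input=len(df))
    status = pd.Series("retained", index=df.index, dtype=object)
    alive = pd.Series(True, index=df.index)
    for rule in cascade:
        fail = predicates[rule] & alive
        trace.removed[rule] = int(fail.sum())
        status[fail] = rule
        alive &= ~fail
    trace.status = status
    return df[alive].copy(), trace


def filter_snvs(calls: pd.DataFrame,
                config: FilterConfig | None = None) -> tuple[pd.DataFrame, FilterTrace]:
    """Apply the SNV cascade: read-end -> depth -> VAF -> population DB
    (with somatic-catalog rescue) -> repeat -> normal panel -> thymus."""
    cfg = config or FilterConfig()
    if len(calls) and calls["is_indel"].any():
        raise InputError("filter_snvs received INDEL records")
    preds = {
        "read_end": calls["read_end_only"].astype(bool),
        "depth": calls["depth"] < cfg.min_depth,
        "vaf": calls["vaf"] < cfg.min_vaf,
        "population_db": _population_db_fail(calls, cfg),
        "repeat": calls["in_repeat"].astype(bool),
        "normal_panel": calls["in_normal_panel"].astype(bool),
        "thymus": calls["in_thymus"].astype(bool),
    }
    return _run_cascade(calls, SNV_CASCADE, preds)


def filter_indels(calls: pd.DataFrame,
                  config: FilterConfig | None = None) -> tuple[pd.DataFrame, FilterTrace]:
    """Apply the INDEL cascade: upstream caller-quality flag -> homopolymer
    context -> population DB (with rescue) -> repeat -> normal panel -> thymus."""
    cfg = config or FilterConfig()
    if len(calls) and not calls["is_indel"].all():
        raise InputError("filter_indels received SNV records")
    if len(calls) and (calls["homopolymer_context"].astype(str) == "").any():
        raise FormatError("INDEL records missing homopolymer context")
    if len(calls):
        runs = calls.apply(
            lambda r: homopolymer_run_length(r["homopolymer_context"],
                                             int(r["anchor_offset"])), axis=1)
        homopoly = runs > cfg.max_homopolymer
    else:
        homopoly = pd.Series(dtype=bool)
    preds = {
        "caller_qc": ~calls["caller_pass"].astype(bool),
        "homopolymer": homopoly,
        "population_db": _population_db_fail(calls, cfg),
        "repeat": calls["in_repeat"].astype(bool),
        "normal_panel": calls["in_normal_panel"].astype(bool),
        "thymus": calls["in_thymus"].astype(bool),
    }
    return _run_cascade(calls, INDEL_CASCADE, preds)


def _terms(value) -> frozenset[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return frozenset(value)
    return frozenset(t.strip() for t in str(value).replace(";", ",").split(",") if t.strip())


def select_protein_altering(calls: pd.DataFrame,
                            config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep calls whose consequence terms intersect the class-appropriate
    protein-altering list; drop chrM variants; unknown terms warn and count
    as non-altering."""
    cfg = config or FilterConfig()
    known = cfg.protein_altering_terms_snv | cfg.protein_altering_terms_indel | _KNOWN_NEUTRAL
    keep = np.zeros(len(calls), dtype=bool)
    for i, (_, row) in enumerate(calls.iterrows()):
        terms = _terms(row["consequence"])
        if not terms:
            raise InputError("variant without consequence terms")
        unknown = terms - known
        if unknown:
            warnings.warn(f"unknown consequence terms treated as non-altering: "
                          f"{sorted(unknown)}", stacklevel=2)
        altering = (cfg.protein_altering_terms_indel if row["is_indel"]
                    else cfg.protein_altering_terms_snv)
        keep[i] = bool((terms & known) & altering)
    mito = calls["chrom"].astype(str).str.lower().isin({"chrm", "mt", "chrmt"})
    return calls[keep & ~mito.to_numpy()].copy()


def run_filter_cascade(calls: pd.DataFrame, config: FilterConfig | None = None
                       ) -> tuple[pd.DataFrame, dict[str, FilterTrace]]:
    """Full triage of a mixed table: SNV cascade + INDEL cascade, then
    protein-altering selection. Returns retained calls and both traces."""
    cfg = config or FilterConfig()
    snvs = calls[~calls["is_indel"]]
    indels = calls[calls["is_indel"]]
    kept_snv, tr_snv = filter_snvs(snvs, cfg)
    kept_indel, tr_indel = filter_indels(indels, cfg)
    kept = pd.concat([kept_snv, kept_indel]).sort_index()
    selected = select_protein_altering(kept, cfg)
    return selected, {"snv": tr_snv, "indel": tr_indel}
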