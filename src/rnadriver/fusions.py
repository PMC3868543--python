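"""Fusion-candidate triage and consequence classification.

Candidates are filtered on read support (both spanning and split
thresholds by default), ribosomal/mitochondrial partners and genomic
adjacency (read-through proxies). Retained candidates are classified into
chimeric-protein / partner-over-expression / partner-inactivation using
frame status, tumor-suppressor flags and the normalized expression matrix
(z-score vs the cohort, log2 fold vs the thymus control, and a
flanking-gene scan around each partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError
from .genes import GeneCatalog
from .normalize import NormalizedMatrix


@dataclass
class FusionThresholds:
    min_spanning: int = 8
    min_split: int = 5
    require_both: bool = True   # AND of the two support thresholds
    z_over: float = 2.0
    min_log2_fold_vs_control: float = 2.0  # fold >= 4 vs thymus
    z_under: float = -2.0
    flank_window: int = 2
    # ectopic activation must yield high absolute expression, not just a
    # relative blip on a silent gene: carrier-sample level must sit above
    # this quantile of the carrier's expression distribution
    carrier_level_quantile: float = 0.5


@dataclass
class FusionCall:
    fusion_id: str
    sample_id: str
    gene5p: str
    gene3p: str
    spanning_reads: int
    split_reads: int
    frame_status: str
    retained: bool
    rule: str  # "retained" or the first failing filter
    consequence_class: str = "unclassified"
    evidence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "fusion_id", "sample_id", "gene5p", "gene3p", "spanning_reads",
            "split_reads", "frame_status", "retained", "rule",
            "consequence_class")}
        d["evidence"] = dict(self.evidence)
        return d


def calls_to_frame(calls: list[FusionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = c.to_dict()
        ev = row.pop("evidence")
        row["affected_gene"] = ev.get("affected_gene")
        row["z_score"] = ev.get("z_score")
        row["log2_fold_vs_control"] = ev.get("log2_fold_vs_control")
        rows.append(row)
    return pd.DataFrame(rows)


def filter_fusion_candidates(candidates: pd.DataFrame, catalog: GeneCatalog,
                             thresholds: FusionThresholds | None = None
                             ) -> list[FusionCall]:
    """Support, ribosomal/chrM and adjacency filters, with per-candidate
    decisions. A candidate is retained only if it clears every rule."""
    th = thresholds or FusionThresholds()
    calls: list[FusionCall] = []
    for _, row in candidates.iterrows():
        g5, g3 = row["gene5p"], row["gene3p"]
        for g in (g5, g3):
            if g not in catalog:
                raise AnnotationError(f"fusion partner {g!r} absent from gene model")
        span_ok = row["spanning_reads"] >= th.min_spanning
        split_ok = row["split_reads"] >= th.min_split
        support_ok = (span_ok and split_ok) if th.require_both \
            else (span_ok or split_ok)
        rule = "retained"
        if not support_ok:
            rule = "low_support"
        elif catalog[g5].is_ribosomal or catalog[g3].is_ribosomal:
            rule = "ribosomal_partner"
        elif catalog[g5].is_chrm or catalog[g3].is_chrm:
            rule = "mitochondrial_partner"
        elif catalog.are_adjacent(g5, g3):
            rule = "adjacent_genes"
        calls.append(FusionCall(
            fusion_id=row.get("fusion_id", f"{g5}--{g3}"),
            sample_id=row["sample_id"], gene5p=g5, gene3p=g3,
            spanning_reads=int(row["spanning_reads"]),
            split_reads=int(row["split_reads"]),
            frame_status=row["frame_status"],
            retained=rule == "retained", rule=rule,
        ))
    return calls


def flanking_expression_scan(partner_gene: str, expression: NormalizedMatrix,
                             carrier_sample: str, control_sample: str,
                             catalog: GeneCatalog, window: int = 2
                             ) -> tuple[pd.DataFrame, bool]:
    """Expression evidence for a partner gene and its genomic neighbors.

    For each gene within ``window`` ranks: z-score of the carrier sample
    against the cohort and log2 fold vs the control (thymus) sample, sorted
    by descending z. Returns (table, truncated_at_contig_edge).
    """
    values = expression.values
    if carrier_sample not in values.columns:
        raise InputError(f"carrier sample {carrier_sample!r} missing from expression")
    if control_sample not in values.columns:
        raise InputError(f"control sample {control_sample!r} missing from expression")
    neighbors, truncated = catalog.neighbors(partner_gene, window)
    rows = []
    for g in neighbors:
        if g.gene_id not in values.index:
            continue
        profile = values.loc[g.gene_id]
        sd = float(profile.std())
        z = float((profile[carrier_sample] - profile.mean()) / sd) if sd > 0 else 0.0
        rows.append({
            "gene_id": g.gene_id,
            "rank_offset": g.rank - catalog[partner_gene].rank,
            "z_score": z,
            "log2_fold_vs_control": float(profile[carrier_sample]
                                          - profile[control_sample]),
        })
    table = pd.DataFrame(rows).sort_values("z_score", ascending=False,
                                           kind="stable").reset_index(drop=True)
    return table, truncated


def classify_fusion_consequence(call: FusionCall, expression: NormalizedMatrix,
                                catalog: GeneCatalog,
                                control_sample: str,
                                thresholds: FusionThresholds | None = None
                                ) -> FusionCall:
    """Decision tree over a retained candidate:

    1. in-frame with both partners coding -> chimeric_protein;
    2. a partner or flanking neighbor over-expressed (z and fold vs
       control above thresholds) -> partner_overexpression naming it;
    3. a tumor-suppressor partner, or a partner under-expressed
       (z below the negative threshold) -> partner_inactivation;
    4. otherwise unclassified.
    """
    th = thresholds or FusionThresholds()
    if not call.retained:
        return call
    if call.sample_id not in expression.values.columns:
        raise InputError(f"no expression column for carrier {call.sample_id!r}")

    g5, g3 = catalog[call.gene5p], catalog[call.gene3p]
    if call.frame_status == "in_frame" and g5.is_coding and g3.is_coding:
        call.consequence_class = "chimeric_protein"
        call.evidence = {"reason": "in_frame_coding_partners"}
        return call

    carrier_col = expression.values[call.sample_id]
    level_cut = float(carrier_col.quantile(th.carrier_level_quantile))
    best = None
    for partner in (call.gene3p, call.gene5p):
        scan, truncated = flanking_expression_scan(
            partner, expression, call.sample_id, control_sample, catalog,
            window=th.flank_window)
        scan = scan[scan["gene_id"].map(
            lambda g: float(carrier_col.get(g, -np.inf)) >= level_cut)]
        if len(scan) == 0:
            continue
        top = scan.iloc[0]
        if best is None or top["z_score"] > best[1]["z_score"]:
            best = (partner, top, truncated)
    if best is not None:
        partner, top, truncated = best
        if (top["z_score"] >= th.z_over
                and top["log2_fold_vs_control"] >= th.min_log2_fold_vs_control):
            call.consequence_class = "partner_overexpression"
            call.evidence = {
                "affected_gene": top["gene_id"], "partner": partner,
                "z_score": float(top["z_score"]),
                "log2_fold_vs_control": float(top["log2_fold_vs_control"]),
                "window_truncated": truncated,
            }
            return call

    for partner in (call.gene3p, call.gene5p):
        model = catalog[partner]
        if partner not in expression.values.index:
            continue
        profile = expression.values.loc[partner]
        sd = float(profile.std())
        z = float((profile[call.sample_id] - profile.mean()) / sd) if sd > 0 else 0.0
        if model.is_tumor_suppressor or z <= th.z_under:
            call.consequence_class = "partner_inactivation"
            call.evidence = {
                "affected_gene": partner, "z_score": z,
                "log2_fold_vs_control": float(profile[call.sample_id]
                                              - profile[control_sample]),
                "tumor_suppressor_flag": bool(model.is_tumor_suppressor),
            }
            return call

    call.consequence_class = "unclassified"
    return call


def triage_fusions(candidates: pd.DataFrame, catalog: GeneCatalog,
                   expression: NormalizedMatrix, control_sample: str,
                   thresholds: FusionThresholds | None = None
                   ) -> list[FusionCall]:
    """Filter all candidates, then classify the retained ones."""
    th = thresholds or FusionThresholds()
    calls = filter_fusion_candidates(candidates, catalog, th)
    return [
        classify_fusion_consequence(c, expression, catalog, control_sample, th)
        if c.retained else c
        for c in calls
    ]
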