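"""Junction-based exon-skipping quantification and testing.

For a candidate exon with inclusion junction counts A and B and skipping
junction count C, the skipping ratio is C / (A + B + C). Tumor-vs-control
comparison is a two-sided Fisher exact test on the 2x2 table
[(inclusion, skipping) x (tumor, control)]; cohort scans apply
Benjamini-Hochberg correction across all tested (event, sample) pairs.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def skipping_ratio(a: int, b: int, c: int) -> float:
    """C / (A + B + C); undefined when all counts are zero."""
    if min(a, b, c) < 0:
        raise InputError("junction counts must be non-negative")
    total = a + b + c
    if total == 0:
        raise InputError("skipping ratio undefined for all-zero counts")
    return c / total


def test_skipping_vs_control(tumor: tuple[int, int, int],
                             control: tuple[int, int, int]) -> float:
    """Two-sided Fisher exact p-value for differential exon skipping."""
    ta, tb, tc = tumor
    ca, cb, cc = control
    if min(ta, tb, tc, ca, cb, cc) < 0:
        raise InputError("junction counts must be non-negative")
    if ta + tb + tc == 0 or ca + cb + cc == 0:
        raise InputError("each event needs a positive junction total")
    table = [[ta + tb, tc], [ca + cb, cc]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def scan_events(junctions: pd.DataFrame, control_sample: str,
                alpha: float = 0.05,
                gene_list: list[str] | None = None) -> pd.DataFrame:
    """Test every (event, sample) pair against the control sample.

    Returns the BH-significant rows with the estimated skipping ratio of
    both sides, the raw p and the adjusted q. Events may be restricted to
    a supplied gene list.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must be in [0, 1]")
    if control_sample not in set(junctions["sample_id"]):
        raise InputError(f"control sample {control_sample!r} absent from junctions")
    df = junctions
    if gene_list is not None:
        df = df[df["gene_id"].isin(set(gene_list))]
    controls = df[df["sample_id"] == control_sample].set_index("event_id")
    rows = []
    for _, row in df[df["sample_id"] != control_sample].iterrows():
        if row["event_id"] not in controls.index:
            continue
        ctl = controls.loc[row["event_id"]]
        tumor = (int(row["A"]), int(row["B"]), int(row["C"]))
        control = (int(ctl["A"]), int(ctl["B"]), int(ctl["C"]))
        if sum(tumor) == 0 or sum(control) == 0:
            continue
        rows.append({
            "event_id": row["event_id"], "gene_id": row["gene_id"],
            "sample_id": row["sample_id"],
            "psi": skipping_ratio(*tumor),
            "psi_control": skipping_ratio(*control),
            "p_value": test_skipping_vs_control(tumor, control),
        })
    if not rows:
        return pd.DataFrame(columns=["event_id", "gene_id", "sample_id", "psi",
                                     "psi_control", "p_value", "q_value"])
    out = pd.DataFrame(rows)
    if alpha == 0.0:
        out["q_value"] = 1.0
        return out.iloc[0:0]
    reject, q, *_ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
    out["q_value"] = q
    return out[reject].sort_values("q_value").reset_index(drop=True)


def events_to_bed(significant: pd.DataFrame, junctions_meta: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Minimal BED-like table of significant events (one row per event/sample)."""
    cols = ["gene_id", "event_id", "sample_id", "psi", "p_value", "q_value"]
    return significant[cols].copy()
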