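import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnadriver.errors import ConfigurationError, FormatError, InputError, StatisticsError
from rnadriver.simulate import SimulationConfig, simulate_cohort
from rnadriver.variants import (
    FilterConfig,
    classify_genotype,
    filter_indels,
    filter_snvs,
    homopolymer_run_length,
    run_filter_cascade,
    select_protein_altering,
)


def make_call(**kw):
    base = dict(sample_id="P01", chrom="chr1", pos=100, ref="A", alt="T",
                gene_id="G1", depth=100, alt_depth=45, vaf=0.45,
                is_indel=False, read_end_only=False,
                consequence="missense-variant", in_dbsnp=False, in_1000g=False,
                in_cg=False, in_normal_panel=False, in_thymus=False,
                in_cosmic=False, in_repeat=False, caller_pass=True,
                homopolymer_context="", anchor_offset=-1, other_depth=50)
    base.update(kw)
    return base


def calls_frame(rows):
    return pd.DataFrame(rows)


class TestClassifyGenotype:
    @pytest.mark.parametrize("vaf,expected", [
        (1.0, "hom_var"),
        (0.5, "het"),
        (0.19, "hom_ref"),
        (0.20, "het"),       # boundary: het bin is [0.2, 0.8)
        (0.7999, "het"),
        (0.80, "hom_var"),
        (0.0, "hom_ref"),
    ])
    def test_bins(self, vaf, expected):
        assert classify_genotype(vaf, depth=50) == expected

    def test_zero_depth_error(self):
        with pytest.raises(StatisticsError):
            classify_genotype(0.5, depth=0)

    def test_bad_vaf(self):
        with pytest.raises(InputError):
            classify_genotype(1.5, depth=10)


class TestHomopolymer:
    def test_run_of_six(self):
        # anchor inside the A-run
        assert homopolymer_run_length("TTAAAAAAG", anchor=4) == 6

    def test_run_of_five_boundary(self):
        # 5 A's: at threshold "longer than 5" this is NOT filtered
        assert homopolymer_run_length("TTAAAAAG", anchor=4) == 5
        cfg = FilterConfig()
        assert not homopolymer_run_length("TTAAAAAG", 4) > cfg.max_homopolymer

    def test_adjacent_run_counts(self):
        # anchor right before a run: the run touches it
        assert homopolymer_run_length("TGGGGG", anchor=0) == 5

    def test_non_nucleotide_rejected(self):
        with pytest.raises(FormatError):
            homopolymer_run_length("TTAXAAG", anchor=3)

    def test_empty_rejected(self):
        with pytest.raises(FormatError):
            homopolymer_run_length("", anchor=0)

    @staticmethod
    def brute_force(context, anchor):
        best = 0
        for i in range(len(context)):
            for j in range(i, len(context)):
                seg = context[i:j + 1]
                if len(set(seg)) == 1 and i <= anchor + 1 and j >= anchor - 1:
                    best = max(best, len(seg))
        return best

    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_scan(self, context):
        anchor = 10
        assert homopolymer_run_length(context, anchor) == \
            self.brute_force(context, anchor)


class TestSnvCascade:
    def test_depth_boundary_removed(self):
        df = calls_frame([make_call(depth=19, alt_depth=9, vaf=0.5)])
        kept, trace = filter_snvs(df)
        assert len(kept) == 0
        assert trace.status.iloc[0] == "depth"

    def test_depth_boundary_retained(self):
        df = calls_frame([make_call(depth=20, alt_depth=10, vaf=0.5)])
        kept, _ = filter_snvs(df)
        assert len(kept) == 1

    def test_vaf_boundary(self):
        removed = calls_frame([make_call(vaf=0.19, alt_depth=19)])
        kept, trace = filter_snvs(removed)
        assert trace.status.iloc[0] == "vaf"
        retained = calls_frame([make_call(vaf=0.20, alt_depth=20)])
        kept, _ = filter_snvs(retained)
        assert len(kept) == 1

    def test_cosmic_rescue_overrides_population_db(self):
        # DB-listed driver retained thanks to somatic-catalog membership
        df = calls_frame([make_call(in_dbsnp=True, in_cosmic=True)])
        kept, _ = filter_snvs(df)
        assert len(kept) == 1

    def test_cosmic_does_not_rescue_repeat(self):
        df = calls_frame([make_call(in_repeat=True, in_cosmic=True)])
        kept, trace = filter_snvs(df)
        assert len(kept) == 0
        assert trace.status.iloc[0] == "repeat"

    def test_rescue_can_be_disabled(self):
        df = calls_frame([make_call(in_dbsnp=True, in_cosmic=True)])
        kept, _ = filter_snvs(df, FilterConfig(cosmic_rescue=False))
        assert len(kept) == 0

    def test_read_end_first_in_cascade(self):
        df = calls_frame([make_call(read_end_only=True, depth=5)])
        _, trace = filter_snvs(df)
        assert trace.status.iloc[0] == "read_end"

    def test_normal_panel_and_thymus_filters(self):
        for col in ("in_normal_panel", "in_thymus"):
            df = calls_frame([make_call(**{col: True})])
            kept, _ = filter_snvs(df)
            assert len(kept) == 0

    def test_indel_in_snv_path_rejected(self):
        df = calls_frame([make_call(is_indel=True, ref="A", alt="AT")])
        with pytest.raises(InputError):
            filter_snvs(df)

    def test_trace_telescopes(self):
        rows = [make_call(depth=d, alt_depth=int(d * v), vaf=v,
                          in_dbsnp=db)
                for d in (10, 30, 100) for v in (0.1, 0.5)
                for db in (False, True)]
        df = calls_frame(rows)
        kept, trace = filter_snvs(df)
        assert trace.n_input == len(df)
        assert trace.n_retained == len(kept)
        assert trace.n_input == trace.n_retained + sum(trace.removed.values())
        assert (trace.status == "retained").sum() == len(kept)


class TestIndelCascade:
    def indel(self, **kw):
        base = make_call(is_indel=True, ref="A", alt="AT",
                         homopolymer_context="TTAGCATAGCA", anchor_offset=5,
                         consequence="frameshift-variant")
        base.update(kw)
        return base

    def test_homopolymer_six_removed(self):
        df = calls_frame([self.indel(homopolymer_context="TTAAAAAAG",
                                     anchor_offset=4)])
        kept, trace = filter_indels(df)
        assert len(kept) == 0
        assert trace.status.iloc[0] == "homopolymer"

    def test_homopolymer_five_retained(self):
        df = calls_frame([self.indel(homopolymer_context="TTAAAAAG",
                                     anchor_offset=4)])
        kept, _ = filter_indels(df)
        assert len(kept) == 1

    def test_caller_flag_honored(self):
        df = calls_frame([self.indel(caller_pass=False)])
        kept, trace = filter_indels(df)
        assert len(kept) == 0
        assert trace.status.iloc[0] == "caller_qc"

    def test_missing_context_rejected(self):
        df = calls_frame([self.indel(homopolymer_context="")])
        with pytest.raises(FormatError):
            filter_indels(df)

    def test_snv_in_indel_path_rejected(self):
        df = calls_frame([make_call()])
        with pytest.raises(InputError):
            filter_indels(df)


class TestProteinAltering:
    def test_missense_kept(self):
        df = calls_frame([make_call(consequence="missense-variant")])
        assert len(select_protein_altering(df)) == 1

    def test_synonymous_dropped(self):
        df = calls_frame([make_call(consequence="synonymous-variant")])
        assert len(select_protein_altering(df)) == 0

    def test_indel_terms_only_for_indels(self):
        snv = calls_frame([make_call(consequence="frameshift-variant")])
        assert len(select_protein_altering(snv)) == 0
        indel = calls_frame([make_call(is_indel=True, ref="A", alt="AT",
                                       consequence="frameshift-variant")])
        assert len(select_protein_altering(indel)) == 1

    def test_chrm_dropped(self):
        df = calls_frame([make_call(chrom="chrM", is_indel=True, ref="A",
                                    alt="AT", consequence="frameshift-variant")])
        assert len(select_protein_altering(df)) == 0

    def test_unknown_term_warns_non_altering(self):
        df = calls_frame([make_call(consequence="mystery-term")])
        with pytest.warns(UserWarning, match="unknown consequence"):
            out = select_protein_altering(df)
        assert len(out) == 0

    def test_no_terms_rejected(self):
        df = calls_frame([make_call(consequence="")])
        with pytest.raises(InputError):
            select_protein_altering(df)


def brute_force_status(row, cfg: FilterConfig) -> str:
    """Independent per-rule re-implementation used as the oracle."""
    if not row["is_indel"]:
        rules = [
            ("read_end", row["read_end_only"]),
            ("depth", row["depth"] < cfg.min_depth),
            ("vaf", row["vaf"] < cfg.min_vaf),
            ("population_db", (row["in_dbsnp"] or row["in_1000g"] or row["in_cg"])
             and not (cfg.cosmic_rescue and row["in_cosmic"])),
            ("repeat", row["in_repeat"]),
            ("normal_panel", row["in_normal_panel"]),
            ("thymus", row["in_thymus"]),
        ]
    else:
        rules = [
            ("caller_qc", not row["caller_pass"]),
            ("homopolymer", homopolymer_run_length(
                row["homopolymer_context"], int(row["anchor_offset"]))
                > cfg.max_homopolymer),
            ("population_db", (row["in_dbsnp"] or row["in_1000g"] or row["in_cg"])
             and not (cfg.cosmic_rescue and row["in_cosmic"])),
            ("repeat", row["in_repeat"]),
            ("normal_panel", row["in_normal_panel"]),
            ("thymus", row["in_thymus"]),
        ]
    for name, fails in rules:
        if fails:
            return name
    return "retained"


def random_calls(n, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        indel = bool(rng.random() < 0.3)
        depth = int(rng.integers(1, 120))
        alt = int(rng.integers(0, depth + 1))
        ctx = "".join(np.array(list("ACGT"))[rng.integers(4, size=11)])
        rows.append(make_call(
            pos=i + 1, depth=depth, alt_depth=alt, vaf=alt / depth,
            is_indel=indel, ref="A", alt="AT" if indel else "T",
            read_end_only=bool(rng.random() < 0.1),
            in_dbsnp=bool(rng.random() < 0.4),
            in_1000g=bool(rng.random() < 0.2),
            in_cg=bool(rng.random() < 0.15),
            in_cosmic=bool(rng.random() < 0.2),
            in_repeat=bool(rng.random() < 0.1),
            in_normal_panel=bool(rng.random() < 0.15),
            in_thymus=bool(rng.random() < 0.1),
            caller_pass=bool(rng.random() < 0.9),
            homopolymer_context=ctx if indel else "",
            anchor_offset=5 if indel else -1))
    return calls_frame(rows)


class TestCascadeProperties:
    def test_oracle_equivalence_on_1000_variants(self):
        cfg = FilterConfig()
        df = random_calls(1000, seed=42)
        snvs = df[~df.is_indel]
        indels = df[df.is_indel]
        _, tr_snv = filter_snvs(snvs, cfg)
        _, tr_indel = filter_indels(indels, cfg)
        for table, trace in ((snvs, tr_snv), (indels, tr_indel)):
            expected = table.apply(brute_force_status, axis=1, cfg=cfg)
            assert (trace.status == expected).all()

    def test_idempotence(self):
        df = random_calls(400, seed=7)
        kept, _ = filter_snvs(df[~df.is_indel])
        again, trace = filter_snvs(kept)
        assert len(again) == len(kept)
        assert sum(trace.removed.values()) == 0

    @pytest.mark.parametrize("param", ["min_depth", "min_vaf"])
    def test_monotonicity(self, param):
        df = random_calls(500, seed=13)
        snvs = df[~df.is_indel]
        grid = {"min_depth": [1, 10, 20, 40, 80],
                "min_vaf": [0.05, 0.1, 0.2, 0.4, 0.8]}[param]
        sizes = []
        for v in grid:
            cfg = FilterConfig(**{param: v})
            kept, _ = filter_snvs(snvs, cfg)
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)

    def test_driver_recovery_and_germline_removal(self, bundle):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, _ = run_filter_cascade(bundle.rna_variants)
        truth = bundle.truth.variants.table
        keys = set(map(tuple, retained[["sample_id", "chrom", "pos"]].values))
        drivers = truth[(truth.origin == "driver")
                        & (truth.rna_class != "absent")]
        for rec in drivers[["sample_id", "chrom", "pos"]].values:
            assert tuple(rec) in keys
        germline = truth[(truth.origin == "germline")
                         & (truth.rna_class != "absent")]
        g_keys = set(map(tuple, germline[["sample_id", "chrom", "pos"]].values))
        leaked = len(g_keys & keys) / max(len(g_keys), 1)
        assert leaked <= 0.01


class TestFilterConfig:
    def test_invalid_depth(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(min_depth=0)

    def test_invalid_vaf(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(min_vaf=0.0)
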