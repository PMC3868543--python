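"""Synthetic cohort generator.

Produces gene models, exome/RNA variant tables, negative-binomial count
matrices with batch and subtype structure, fusion candidates with decoys,
and junction tables with planted exon-skipping events — together with a
truth record so every downstream stage can be tested for recovery of the
planted signal.

All randomness flows through :func:`numpy.random.default_rng`; identical
(config, seed) pairs reproduce every table exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genes import (
    KNOWN_DRIVER_GENES,
    SUBTYPE_TFS,
    TUMOR_SUPPRESSORS,
    GeneCatalog,
    GeneModel,
    SampleMeta,
    sample_meta_frame,
)
from .matrix import CountMatrix

BASES = np.array(list("ACGT"))

#: Consequence terms used for planted protein-altering SNVs.
DRIVER_SNV_TERMS = (
    "missense-variant", "stop-gained", "splice-donor-variant",
    "splice-acceptor-variant", "initiator-codon-variant", "splice-region-variant",
)
DRIVER_INDEL_TERMS = ("frameshift-variant", "inframe-deletion", "inframe-insertion")
NEUTRAL_TERMS = (
    "synonymous-variant", "intron-variant", "3-prime-UTR-variant",
    "5-prime-UTR-variant", "upstream-gene-variant",
)

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene_id", "depth", "alt_depth",
    "vaf", "is_indel", "read_end_only", "consequence", "in_dbsnp", "in_1000g",
    "in_cg", "in_normal_panel", "in_thymus", "in_cosmic", "in_repeat",
    "caller_pass", "homopolymer_context", "anchor_offset", "other_depth",
]

FUSION_COLUMNS = [
    "fusion_id", "sample_id", "gene5p", "gene3p", "chrom5p", "pos5p",
    "chrom3p", "pos3p", "spanning_reads", "split_reads", "frame_status",
]

JUNCTION_COLUMNS = ["event_id", "gene_id", "sample_id", "A", "B", "C"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort. Defaults give a small, fast cohort
    in which every planted signal is recoverable at default thresholds."""

    n_patients: int = 20
    n_celllines: int = 8
    include_thymus: bool = True
    n_genes: int = 400
    n_driver_genes: int = 8
    n_ribosomal_genes: int = 15
    n_chrm_genes: int = 5
    n_chromosomes: int = 4
    driver_recurrence: float = 3.0
    driver_indel_fraction: float = 0.1
    germline_rate: float = 30.0
    cosmic_overlap_rate: float = 0.2
    allelic_imbalance_fraction: float = 0.035
    rna_het_rate: float = 0.72
    rna_artifact_rate: float = 2.0
    mean_depth: float = 60.0
    n_centers: int = 2
    batch_labels: dict[str, str] | None = None
    batch_effect_sd: float = 0.7
    subtype_programs: dict[str, float] = field(
        default_factory=lambda: {tf: 4.0 for tf in SUBTYPE_TFS}
    )
    signature_size: int = 25
    signature_lfc: float = 2.0
    nb_dispersion: float = 0.15
    gc_bias_slope: float = 1.0
    length_bias_exponent: float = 0.3
    n_true_fusions: int = 6
    n_decoy_fusions: int = 8
    fusion_overexpression_lfc: float = 5.0
    fusion_inactivation_lfc: float = -4.0
    skipping_events: list[tuple[str | None, str | None, float]] = field(
        default_factory=lambda: [(None, None, 0.35), (None, None, 0.40)]
    )
    junction_depth: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        counts = ("n_patients", "n_celllines", "n_genes", "n_driver_genes",
                  "n_ribosomal_genes", "n_chrm_genes", "n_chromosomes",
                  "n_true_fusions", "n_decoy_fusions")
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_genes <= 0 or self.n_patients <= 0:
            raise ConfigurationError("n_genes and n_patients must be positive")
        fractions = ("cosmic_overlap_rate", "allelic_imbalance_fraction",
                     "rna_het_rate", "driver_indel_fraction")
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.allelic_imbalance_fraction + self.rna_het_rate > 1.0:
            raise ConfigurationError(
                "allelic_imbalance_fraction + rna_het_rate exceeds 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.batch_effect_sd > 0 and self.n_centers < 2 and self.batch_labels is None:
            raise ConfigurationError("batch_effect_sd > 0 requires >= 2 centers")
        if self.batch_effect_sd < 0 or self.mean_depth <= 0:
            raise ConfigurationError("batch_effect_sd >= 0 and mean_depth > 0 required")
        for _, _, psi in self.skipping_events:
            if not 0.0 <= psi <= 1.0:
                raise ConfigurationError("skipping PSI must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# truth records


@dataclass
class CountsTruth:
    batch_shift: pd.DataFrame          # genes x centers, log2 units
    subtype_of: pd.Series              # sample -> subtype (TF name) or None
    signature_genes: dict[str, list[str]]
    applied_effects: list[dict]


@dataclass
class VariantTruth:
    table: pd.DataFrame  # sample_id, chrom, pos, gene_id, origin, rna_class, is_indel


@dataclass
class FusionSpliceTruth:
    fusion_classes: pd.DataFrame       # fusion_id, class/decoy type, affected_gene
    expression_effects: list[dict]     # gene_id, sample_id, delta_log2
    psi: pd.DataFrame                  # event_id, gene_id, sample_id, true_psi


@dataclass
class CohortTruth:
    drivers: list[str]
    counts: CountsTruth | None = None
    variants: VariantTruth | None = None
    fusions: FusionSpliceTruth | None = None


@dataclass
class CohortBundle:
    config: SimulationConfig
    gene_models: GeneCatalog
    sample_meta: pd.DataFrame
    exome_variants: pd.DataFrame
    rna_variants: pd.DataFrame
    counts: CountMatrix
    fusions: pd.DataFrame
    junctions: pd.DataFrame
    truth: CohortTruth


def stage_seed(seed: int, stage: str) -> int:
    """Stable child seed for a named stage (so stages rerun independently)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(config: SimulationConfig, seed: int) -> GeneCatalog:
    """Lay out genes contiguously on several chromosomes plus a chrM contig.

    Driver genes take names from the curated driver list (transcription
    factors of the subtype programs are always present); ribosomal and
    chrM subsets are flagged; GC fractions fall in [0.2, 0.8].
    """
    config.validate()
    if config.n_genes < 10:
        raise ConfigurationError("need at least 10 genes")
    rng = np.random.default_rng(seed)

    tf_names = list(config.subtype_programs)
    driver_names = [g for g in KNOWN_DRIVER_GENES if g not in tf_names]
    driver_names = driver_names[: config.n_driver_genes]
    n_special = len(tf_names) + len(driver_names) + config.n_ribosomal_genes
    if n_special + config.n_chrm_genes > config.n_genes:
        raise ConfigurationError("n_genes too small for the flagged subsets")

    names: list[str] = []
    roles: list[str] = []
    for nm in driver_names:
        names.append(nm)
        roles.append("driver")
    for nm in tf_names:
        names.append(nm)
        roles.append("tf")
    for i in range(config.n_ribosomal_genes):
        names.append(f"RPL{i + 1:02d}")
        roles.append("ribosomal")
    n_filler = config.n_genes - len(names) - config.n_chrm_genes
    for i in range(n_filler):
        names.append(f"G{i + 1:05d}")
        roles.append("filler")
    order = rng.permutation(len(names))
    names = [names[i] for i in order]
    roles = [roles[i] for i in order]
    for i in range(config.n_chrm_genes):
        names.append(f"MT-G{i + 1}")
        roles.append("chrm")

    n_auto = config.n_genes - config.n_chrm_genes
    chrom_of = [f"chr{1 + i % config.n_chromosomes}" for i in range(n_auto)]
    chrom_of += ["chrM"] * config.n_chrm_genes

    models: list[GeneModel] = []
    cursor: dict[str, int] = {}
    rank: dict[str, int] = {}
    for name, role, chrom in zip(names, roles, chrom_of):
        exonic = int(np.clip(rng.lognormal(mean=7.5, sigma=0.6), 300, 30_000))
        n_exons = int(rng.integers(2, 12))
        gc = float(np.clip(rng.beta(5, 5) * 0.6 + 0.2, 0.2, 0.8))
        span = int(exonic * rng.uniform(1.5, 4.0))
        start = cursor.get(chrom, 1) + int(rng.integers(500, 5_000))
        end = start + span - 1
        cursor[chrom] = end
        bounds = np.sort(rng.choice(np.arange(1, span - 1), size=2 * n_exons - 2,
                                    replace=False)) if span > 2 * n_exons else np.array([])
        edges = np.concatenate(([0], bounds, [span - 1])).astype(int)
        exons = tuple(
            (start + int(edges[2 * i]), start + int(edges[2 * i + 1]))
            for i in range(len(edges) // 2)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(
                gene_id=name, chrom=chrom, start=start, end=end, strand=strand,
                exons=exons, gc=gc, length=exonic,
                rank=rank.setdefault(chrom, 0),
                is_coding=role != "chrm",
                is_ribosomal=role == "ribosomal",
                is_chrm=role == "chrm",
                is_driver=role in ("driver", "tf"),
                is_tumor_suppressor=name in TUMOR_SUPPRESSORS,
                is_tf=role == "tf",
            )
        )
        rank[chrom] += 1
    return GeneCatalog(models)


# ---------------------------------------------------------------------------
# samples


def simulate_samples(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Sample sheet: patients, cell lines, optional thymus; centers and subtypes."""
    config.validate()
    rng = np.random.default_rng(seed)
    metas: list[SampleMeta] = []
    ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    ids += [f"CL{i + 1:02d}" for i in range(config.n_celllines)]
    tumor_ids = list(ids)
    if config.include_thymus:
        ids.append("THYMUS")
    centers = [f"center{1 + i % config.n_centers}" for i in range(len(ids))]
    subtypes = list(config.subtype_programs) or [None]
    assigned = [subtypes[i % len(subtypes)] for i in range(len(tumor_ids))]
    assigned = list(np.array(assigned, dtype=object)[rng.permutation(len(assigned))])
    for i, sid in enumerate(ids):
        is_thymus = sid == "THYMUS"
        metas.append(
            SampleMeta(
                sample_id=sid,
                sample_type=("thymus" if is_thymus
                             else "patient" if sid.startswith("P") else "cell_line"),
                center=(config.batch_labels or {}).get(sid, centers[i]),
                cohort=("adult" if (sid.startswith("P") and i % 2 == 0)
                        else "pediatric" if sid.startswith("P") else "NA"),
                subtype=None if is_thymus else assigned[i],
            )
        )
    return sample_meta_frame(metas)


# ---------------------------------------------------------------------------
# counts


def draw_signature_genes(config: SimulationConfig, catalog: GeneCatalog,
                         seed: int) -> dict[str, list[str]]:
    """Disjoint co-expression signatures, one per subtype program, drawn
    from unflagged genes.

    Signatures are taken as contiguous blocks in genomic order (random
    rotation) so the bulk of the genome keeps signature-free flanking
    windows for the fusion-consequence couplings; block position carries
    no meaning for the expression analyses.
    """
    rng = np.random.default_rng(seed)
    gm = catalog.to_frame().sort_values(["chrom", "rank"])
    pool = gm.index[~(gm.is_driver | gm.is_ribosomal | gm.is_chrm)].to_numpy()
    pool = np.roll(pool, -int(rng.integers(len(pool))))
    return {
        tf: list(pool[k * config.signature_size:(k + 1) * config.signature_size])
        for k, tf in enumerate(config.subtype_programs)
    }


def _gc_trend(gc: np.ndarray, slope: float) -> np.ndarray:
    # quadratic in GC, peaked at 0.5 — smooth and removable by local regression
    return slope * (1.0 - ((gc - 0.5) / 0.25) ** 2)


def _length_trend(length: np.ndarray, exponent: float) -> np.ndarray:
    loglen = np.log2(length)
    return exponent * (loglen - loglen.mean())


def simulate_counts(
    config: SimulationConfig,
    catalog: GeneCatalog,
    seed: int,
    sample_meta: pd.DataFrame | None = None,
    expression_effects: list[dict] | None = None,
    signature_genes: dict[str, list[str]] | None = None,
) -> tuple[CountMatrix, CountsTruth]:
    """Negative-binomial counts with GC/length trends, per-gene batch shifts
    and subtype TF programs; optional per-(gene, sample) log2 tweaks couple
    fusion consequences into the matrix."""
    config.validate()
    rng = np.random.default_rng(seed)
    if sample_meta is None:
        sample_meta = simulate_samples(config, seed)
    gm = catalog.to_frame()
    genes = gm.index.to_numpy()
    samples = sample_meta.index.to_numpy()
    centers = sample_meta["center"].to_numpy()
    uniq_centers = list(dict.fromkeys(centers))
    if config.batch_effect_sd > 0 and len(uniq_centers) < 2:
        raise ConfigurationError("batch_effect_sd > 0 requires >= 2 batches")

    base = rng.normal(5.0, 1.5, size=len(genes))
    # planted driver genes are expressed by construction (their variants
    # must be callable from RNA), so floor their baseline
    base = np.where(gm["is_driver"].to_numpy(), np.maximum(base, 5.0), base)
    log_mu = np.tile(base[:, None], (1, len(samples)))
    log_mu += _gc_trend(gm["gc"].to_numpy(), config.gc_bias_slope)[:, None]
    log_mu += _length_trend(gm["length"].to_numpy(), config.length_bias_exponent)[:, None]

    shift = rng.normal(0.0, config.batch_effect_sd,
                       size=(len(genes), len(uniq_centers)))
    if config.batch_effect_sd == 0:
        shift[:] = 0.0
    batch_shift = pd.DataFrame(shift, index=genes, columns=uniq_centers)
    for j, c in enumerate(centers):
        log_mu[:, j] += batch_shift[c].to_numpy()

    # subtype programs: the TF itself plus a disjoint signature per subtype
    if signature_genes is None:
        signature_genes = draw_signature_genes(config, catalog,
                                               stage_seed(seed, "signatures"))
    gidx = {g: i for i, g in enumerate(genes)}
    sub_of = sample_meta["subtype"]
    for tf, lfc in config.subtype_programs.items():
        sig = signature_genes.get(tf, [])
        cols = np.flatnonzero(sub_of.to_numpy() == tf)
        if tf in gidx:
            log_mu[gidx[tf], cols] += lfc
        for g in sig:
            log_mu[gidx[g], cols] += config.signature_lfc

    applied: list[dict] = []
    for eff in expression_effects or []:
        g, s = eff["gene_id"], eff["sample_id"]
        if g in gidx and s in sample_meta.index:
            j = int(np.flatnonzero(samples == s)[0])
            if "set_base_log2" in eff:
                # pin the gene's baseline (silent target for ectopic
                # activation, expressed target for inactivation)
                log_mu[gidx[g], :] += eff["set_base_log2"] - base[gidx[g]]
            log_mu[gidx[g], j] += eff["delta_log2"]
            applied.append(dict(eff))

    mu = np.power(2.0, log_mu)
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(np.int64)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples),
                     gm, sample_meta)
    truth = CountsTruth(batch_shift=batch_shift, subtype_of=sub_of.copy(),
                        signature_genes=signature_genes, applied_effects=applied)
    return cm, truth


# ---------------------------------------------------------------------------
# variants


def _random_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    if not indel:
        ref, alt = rng.choice(4, size=2, replace=False)
        return str(BASES[ref]), str(BASES[alt])
    anchor = str(BASES[rng.integers(4)])
    ins = "".join(BASES[rng.integers(4, size=int(rng.integers(1, 4)))])
    if rng.random() < 0.5:
        return anchor, anchor + ins  # insertion
    return anchor + ins, anchor      # deletion


def _clean_context(rng: np.random.Generator) -> tuple[str, int]:
    """11-mer with no homopolymer run longer than 5 touching the center."""
    while True:
        ctx = "".join(BASES[rng.integers(4, size=11)])
        run, best = 1, 1
        for i in range(1, len(ctx)):
            run = run + 1 if ctx[i] == ctx[i - 1] else 1
            best = max(best, run)
        if best <= 5:
            return ctx, 5


def simulate_variant_tables(
    config: SimulationConfig,
    catalog: GeneCatalog,
    seed: int,
    counts: CountMatrix | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, VariantTruth]:
    """Exome and RNA variant tables plus truth.

    Every DNA variant is heterozygous in the exome. Germline variants carry
    population-database memberships and are re-emitted in RNA as
    het / hom-var / absent with probabilities (rna_het_rate,
    allelic_imbalance_fraction, remainder). Driver variants are always
    expressed (het, or hom-var at the imbalance rate) and carry
    protein-altering consequence terms; a configured fraction is also
    COSMIC-listed (and dbSNP-listed, to exercise the rescue rule).
    RNA depth scales with the gene's simulated expression when a count
    matrix is supplied.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if sample_meta is None:
        sample_meta = simulate_samples(config, seed)
    gm = catalog.to_frame()
    nuclear = gm.index[~gm.is_chrm].to_numpy()
    drivers = gm.index[gm.is_driver].to_list()
    patients = sample_meta.index[sample_meta.sample_type == "patient"].to_list()

    if counts is not None:
        med = np.median(counts.counts.values[counts.counts.values > 0]) or 1.0
        depth_scale = counts.counts / med
    else:
        depth_scale = None

    def rna_depth(gene: str, sample: str) -> int:
        if depth_scale is None:
            return int(rng.poisson(config.mean_depth))
        return int(rng.poisson(config.mean_depth * float(depth_scale.loc[gene, sample])))

    exome_rows: list[dict] = []
    rna_rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(sample: str, gene: str, origin: str, *, indel: bool,
             consequence: str, dbsnp: bool, kg: bool, cg: bool, normal: bool,
             thymus: bool, cosmic: bool, repeat: bool, force_expressed: bool):
        g = catalog[gene]
        pos = int(rng.integers(g.start, g.end + 1))
        ref, alt = _random_alleles(rng, indel)
        dna_depth = max(1, int(rng.poisson(config.mean_depth)))
        dna_alt = int(rng.binomial(dna_depth, 0.5))
        ctx, anchor = _clean_context(rng) if indel else ("", -1)
        u = rng.random()
        if u < config.allelic_imbalance_fraction:
            rna_class = "hom_var"
        elif force_expressed or u < config.allelic_imbalance_fraction + config.rna_het_rate:
            rna_class = "het"
        else:
            rna_class = "absent"
        rdepth = rna_depth(gene, sample)
        if force_expressed:
            # planted driver genes are expressed: depth never drops below
            # what a mean-depth library would give
            rdepth = max(rdepth, int(rng.poisson(config.mean_depth)))
        if rdepth == 0:
            rna_class = "absent"
        common = dict(
            sample_id=sample, chrom=g.chrom, pos=pos, ref=ref, alt=alt,
            gene_id=gene, is_indel=indel, read_end_only=False,
            consequence=consequence, in_dbsnp=dbsnp, in_1000g=kg, in_cg=cg,
            in_normal_panel=normal, in_thymus=thymus, in_cosmic=cosmic,
            in_repeat=repeat, caller_pass=True,
            homopolymer_context=ctx, anchor_offset=anchor,
        )
        exome_rows.append(dict(common, depth=dna_depth, alt_depth=dna_alt,
                               vaf=dna_alt / dna_depth, other_depth=rdepth))
        if rna_class != "absent":
            p_alt = 0.5 if rna_class == "het" else 0.97
            ralt = int(rng.binomial(rdepth, p_alt))
            rna_rows.append(dict(common, depth=rdepth, alt_depth=ralt,
                                 vaf=ralt / rdepth if rdepth else 0.0,
                                 other_depth=dna_depth))
        truth_rows.append(dict(sample_id=sample, chrom=g.chrom, pos=pos,
                               gene_id=gene, origin=origin,
                               rna_class=rna_class, is_indel=indel))

    # germline SNPs, all samples
    for sample in sample_meta.index:
        for _ in range(int(rng.poisson(config.germline_rate))):
            gene = str(rng.choice(nuclear))
            dbsnp = bool(rng.random() < 0.9)
            kg = bool(rng.random() < 0.5)
            cg = bool(rng.random() < 0.3)
            if not (dbsnp or kg or cg):
                dbsnp = True
            emit(sample, gene, "germline", indel=False,
                 consequence=str(rng.choice(NEUTRAL_TERMS)),
                 dbsnp=dbsnp, kg=kg, cg=cg,
                 normal=bool(rng.random() < 0.3), thymus=bool(rng.random() < 0.2),
                 cosmic=False, repeat=bool(rng.random() < 0.05),
                 force_expressed=False)

    # planted driver mutations: >= 2 distinct patients per driver gene
    for gene in drivers:
        n_mut = max(2, int(rng.poisson(config.driver_recurrence)))
        n_mut = min(n_mut, len(patients))
        carriers = list(rng.choice(patients, size=n_mut, replace=False))
        for sample in carriers:
            indel = bool(rng.random() < config.driver_indel_fraction)
            in_db = bool(rng.random() < config.cosmic_overlap_rate)
            emit(sample, gene, "driver", indel=indel,
                 consequence=str(rng.choice(DRIVER_INDEL_TERMS if indel
                                            else DRIVER_SNV_TERMS)),
                 dbsnp=in_db, kg=False, cg=False, normal=False, thymus=False,
                 cosmic=in_db, repeat=False, force_expressed=True)

    # RNA-only artifacts (low-VAF calls with no exome counterpart)
    for sample in sample_meta.index:
        for _ in range(int(rng.poisson(config.rna_artifact_rate))):
            gene = str(rng.choice(nuclear))
            g = catalog[gene]
            pos = int(rng.integers(g.start, g.end + 1))
            ref, alt = _random_alleles(rng, False)
            depth = max(20, int(rng.poisson(config.mean_depth)))
            vaf = float(rng.uniform(0.20, 0.35))
            rna_rows.append(dict(
                sample_id=sample, chrom=g.chrom, pos=pos, ref=ref, alt=alt,
                gene_id=gene, depth=depth, alt_depth=int(round(vaf * depth)),
                vaf=vaf, is_indel=False, read_end_only=False,
                consequence="missense-variant", in_dbsnp=False, in_1000g=False,
                in_cg=False, in_normal_panel=False, in_thymus=False,
                in_cosmic=False, in_repeat=False, caller_pass=True,
                homopolymer_context="", anchor_offset=-1,
                other_depth=int(rng.poisson(config.mean_depth)),
            ))
            truth_rows.append(dict(sample_id=sample, chrom=g.chrom, pos=pos,
                                   gene_id=gene, origin="rna_artifact",
                                   rna_class="rna_only", is_indel=False))

    exome = pd.DataFrame(exome_rows, columns=VARIANT_COLUMNS)
    rna = pd.DataFrame(rna_rows, columns=VARIANT_COLUMNS)
    truth = VariantTruth(table=pd.DataFrame(truth_rows))
    return exome, rna, truth


# ---------------------------------------------------------------------------
# fusions and junctions


def simulate_fusions_and_junctions(
    config: SimulationConfig,
    catalog: GeneCatalog,
    seed: int,
    sample_meta: pd.DataFrame | None = None,
    avoid_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FusionSpliceTruth]:
    """True fusions (chimeric / over-expression / inactivation classes, all
    above support thresholds), decoys (adjacent pair, ribosomal partner,
    chrM partner, low support), and junction tables with planted PSI.

    Expression consequences are returned as ``expression_effects`` (log2
    deltas) so :func:`simulate_counts` can couple them into the matrix.
    ``avoid_genes`` (e.g. subtype signature genes) are kept out of true
    partners' flanking windows so planted consequences stay unambiguous.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if sample_meta is None:
        sample_meta = simulate_samples(config, seed)
    gm = catalog.to_frame()
    tumors = sample_meta.index[sample_meta.sample_type != "thymus"].to_list()
    clean = gm[~(gm.is_ribosomal | gm.is_chrm) & gm.is_coding]
    avoid = set(avoid_genes or set()) | set(gm.index[gm.is_tf])

    def flank_clear(gene_id: str) -> bool:
        nbrs, _ = catalog.neighbors(gene_id, 3)
        return not any(n.gene_id in avoid for n in nbrs)
    # genes with a downstream rank-neighbor available for the coupling
    has_down = clean[
        clean.apply(lambda r: r["rank"] + 1 < len(catalog.chromosome_genes(r.chrom)),
                    axis=1)
    ] if len(clean) else clean

    def distant_pair(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                     clean_flanks: bool = False) -> tuple[str, str]:
        for attempt in range(400):
            a = str(rng.choice(frame_a.index))
            b = str(rng.choice(frame_b.index))
            if a == b or catalog.are_adjacent(a, b):
                continue
            if clean_flanks and attempt < 350 and not (flank_clear(a)
                                                       and flank_clear(b)):
                continue
            return a, b
        raise ConfigurationError("could not draw a non-adjacent gene pair")

    fusion_rows: list[dict] = []
    class_rows: list[dict] = []
    effects: list[dict] = []
    classes = ("chimeric", "overexpression", "inactivation")
    fid = 0

    def support(true_event: bool) -> tuple[int, int]:
        if true_event:
            return 8 + int(rng.poisson(12)), 5 + int(rng.poisson(8))
        # low-support decoy: below at least one threshold
        if rng.random() < 0.5:
            return int(rng.integers(1, 8)), 5 + int(rng.poisson(5))
        return 8 + int(rng.poisson(5)), int(rng.integers(0, 5))

    for i in range(config.n_true_fusions):
        cls = classes[i % 3]
        sample = str(rng.choice(tumors))
        if cls == "chimeric":
            g5, g3 = distant_pair(clean, clean, clean_flanks=True)
            frame, affected = "in_frame", None
        elif cls == "overexpression":
            g5, g3 = distant_pair(clean, has_down if len(has_down) else clean,
                                  clean_flanks=True)
            frame = "out_of_frame"
            nbrs = catalog.chromosome_genes(catalog[g3].chrom)
            affected = nbrs[catalog[g3].rank + 1].gene_id \
                if catalog[g3].rank + 1 < len(nbrs) else g3
            effects.append(dict(gene_id=affected, sample_id=sample,
                                delta_log2=config.fusion_overexpression_lfc,
                                set_base_log2=2.5))
        else:
            ts = clean[clean.is_tumor_suppressor]
            target_pool = ts if len(ts) else clean
            clear = [g for g in target_pool.index if flank_clear(g)]
            g3 = str(rng.choice(clear if clear else target_pool.index))
            for _ in range(400):
                g5, _ = distant_pair(clean, clean, clean_flanks=True)
                if g5 != g3 and not catalog.are_adjacent(g5, g3):
                    break
            frame, affected = "out_of_frame", g3
            effects.append(dict(gene_id=g3, sample_id=sample,
                                delta_log2=config.fusion_inactivation_lfc,
                                set_base_log2=6.0))
        spanning, split = support(True)
        fid += 1
        fusion_rows.append(dict(
            fusion_id=f"F{fid:03d}", sample_id=sample, gene5p=g5, gene3p=g3,
            chrom5p=catalog[g5].chrom, pos5p=catalog[g5].end,
            chrom3p=catalog[g3].chrom, pos3p=catalog[g3].start,
            spanning_reads=spanning, split_reads=split, frame_status=frame,
        ))
        class_rows.append(dict(fusion_id=f"F{fid:03d}", truth_class=cls,
                               affected_gene=affected, is_decoy=False))

    decoy_types = ("adjacent", "ribosomal", "chrm", "low_support")
    ribo = gm[gm.is_ribosomal]
    mito = gm[gm.is_chrm]
    for i in range(config.n_decoy_fusions):
        dtype = decoy_types[i % 4]
        sample = str(rng.choice(tumors))
        spanning, split = support(dtype != "low_support")
        if dtype == "low_support":
            spanning, split = support(False)
            g5, g3 = distant_pair(clean, clean)
        elif dtype == "adjacent":
            chrom = str(rng.choice([c for c in catalog.chromosomes if c != "chrM"]))
            chrom_genes = catalog.chromosome_genes(chrom)
            j = int(rng.integers(0, len(chrom_genes) - 1))
            g5, g3 = chrom_genes[j].gene_id, chrom_genes[j + 1].gene_id
        elif dtype == "ribosomal" and len(ribo):
            g5 = str(rng.choice(ribo.index))
            _, g3 = distant_pair(clean, clean)
        elif dtype == "chrm" and len(mito):
            g5, _ = distant_pair(clean, clean)
            g3 = str(rng.choice(mito.index))
        else:
            g5, g3 = distant_pair(clean, clean)
            spanning, split = support(False)
            dtype = "low_support"
        fid += 1
        fusion_rows.append(dict(
            fusion_id=f"F{fid:03d}", sample_id=sample, gene5p=g5, gene3p=g3,
            chrom5p=catalog[g5].chrom, pos5p=catalog[g5].end,
            chrom3p=catalog[g3].chrom, pos3p=catalog[g3].start,
            spanning_reads=spanning, split_reads=split, frame_status="out_of_frame",
        ))
        class_rows.append(dict(fusion_id=f"F{fid:03d}", truth_class=f"decoy_{dtype}",
                               affected_gene=None, is_decoy=True))

    # junction tables with planted exon skipping
    drivers = gm.index[gm.is_driver].to_list()
    junction_rows: list[dict] = []
    psi_rows: list[dict] = []
    for k, (gene, carrier, psi) in enumerate(config.skipping_events):
        gene = gene or str(rng.choice(drivers or gm.index))
        carrier = carrier or str(rng.choice(
            sample_meta.index[sample_meta.sample_type == "patient"]))
        event_id = f"SE{k + 1:02d}_{gene}"
        for sample in sample_meta.index:
            depth = max(1, int(rng.poisson(config.junction_depth)))
            true_psi = psi if sample == carrier else 0.0
            c = int(rng.binomial(depth, true_psi))
            a = int(rng.binomial(depth - c, 0.5))
            b = depth - c - a
            junction_rows.append(dict(event_id=event_id, gene_id=gene,
                                      sample_id=sample, A=a, B=b, C=c))
            psi_rows.append(dict(event_id=event_id, gene_id=gene,
                                 sample_id=sample, true_psi=true_psi))

    fusions = pd.DataFrame(fusion_rows, columns=FUSION_COLUMNS)
    junctions = pd.DataFrame(junction_rows, columns=JUNCTION_COLUMNS)
    truth = FusionSpliceTruth(
        fusion_classes=pd.DataFrame(class_rows),
        expression_effects=effects,
        psi=pd.DataFrame(psi_rows),
    )
    return fusions, junctions, truth


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortBundle:
    """Generate a complete coherent cohort bundle.

    Fusion expression consequences are applied to the count matrix, and
    RNA variant depths follow simulated expression, so downstream stages
    see the couplings they are designed to exploit.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    catalog = simulate_gene_models(config, stage_seed(seed, "genes"))
    samples = simulate_samples(config, stage_seed(seed, "samples"))
    counts_seed = stage_seed(seed, "counts")
    signatures = draw_signature_genes(config, catalog,
                                      stage_seed(counts_seed, "signatures"))
    avoid = {g for sig in signatures.values() for g in sig}
    fusions, junctions, fs_truth = simulate_fusions_and_junctions(
        config, catalog, stage_seed(seed, "fusions"), sample_meta=samples,
        avoid_genes=avoid)
    counts, counts_truth = simulate_counts(
        config, catalog, counts_seed, sample_meta=samples,
        expression_effects=fs_truth.expression_effects,
        signature_genes=signatures)
    exome, rna, var_truth = simulate_variant_tables(
        config, catalog, stage_seed(seed, "variants"), counts=counts,
        sample_meta=samples)
    truth = CohortTruth(
        drivers=catalog.to_frame().query("is_driver").index.to_list(),
        counts=counts_truth, variants=var_truth, fusions=fs_truth,
    )
    return CohortBundle(
        config=config, gene_models=catalog, sample_meta=samples,
        exome_variants=exome, rna_variants=rna, counts=counts,
        fusions=fusions, junctions=junctions, truth=truth,
    )
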