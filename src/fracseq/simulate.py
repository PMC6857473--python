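"""Synthetic fractionation-then-sequencing study generator.

Generates every input the pipeline consumes, with recorded ground truth:

* a small two-chromosome genome, a reference annotation with biotypes, and an
  "assembled" consensus catalog engineered so that every transfrag class code
  occurs and each candidate filter has a planted violator;
* paired cytoplasmic/nuclear FPKM matrices across cell lines in which mRNAs
  sit near log-ratio 0, housekeeping genes form a cytoplasm-shifted
  calibration band enclosing the typical mRNA spread, the lncRNA population
  is shifted nuclear, and planted nuclear/cytoplasmic genes sit beyond the
  band;
* a tumor/adjacent count cohort with negative-binomial noise, planted fold
  changes, per-sample assembly catalogs (tumor-specific transcripts never
  appear in adjacent samples), simulated external DE method tables, and a
  survival table with a planted hazard effect;
* H3K4me3 peak sets, a single-cell preimplantation embryo TPM table with
  planted lineage-restricted genes, and a latent-factor co-expression
  structure shared between candidate lncRNAs and their partner genes.

All randomness flows through numpy Generators seeded from ``cfg.seed``; equal
configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import TranscriptCatalog, TranscriptModel, write_catalog
from .characterization import STAGES, PeakSet
from .lncrna import CodingPotentialLabel, RepeatMask

PREDICTORS = ("cp_svm", "cp_bayes")  # the two pluggable coding-potential inputs

MARKERS = {"GAPDH": "cytoplasmic_enriched", "RPS14": "cytoplasmic_enriched", "MALAT1": "nuclear_enriched"}

#: epigenome counts per category (the four-category reference panel)
EPIGENOMES = {"ESC": 8, "ESC_derived": 9, "iPSC": 5, "cancer": 5}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real study's shape: 8 fractionated cell lines, 50
    tumor/tumor-adjacent pairs, a cytoplasm-shifted housekeeping band with a
    nuclear-shifted lncRNA population, and planted effect sizes chosen to be
    separable but noisy.
    """

    seed: int = 0
    n_genes: int = 2000
    n_lncrna: int = 300
    n_housekeeping: int = 200
    n_cell_lines: int = 8
    n_tumor_pairs: int = 50
    # fraction-enrichment structure
    planted_nuclear: int = 100
    planted_cytoplasmic: int = 100
    nuclear_shift: float = -3.5
    cytoplasmic_shift: float = 5.0
    line_noise_sd: float = 0.5
    hk_band_mean: float = 1.0
    hk_band_sd: float = 1.3
    lncrna_ratio_mean: float = -1.0
    mrna_ratio_sd: float = 0.6
    base_log2_expr_mean: float = 4.0
    base_log2_expr_sd: float = 1.5
    # tumor cohort
    planted_de: int = 50
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_candidates: int = 8
    # survival
    n_patients: int = 200
    planted_prognostic: int = 5
    n_null_survival_genes: int = 50
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.2
    # co-expression (a separate tumor-only expression panel)
    coexpr_factors: int = 3
    factor_loading: float = 1.5
    coexpr_noise_sd: float = 0.5
    n_coexpr_samples: int = 60
    partners_per_factor: int = 5
    # embryo profiling
    embryos_per_stage: int = 3
    cells_per_embryo: int = 8
    lineage_onset_stage: str = "4cell"
    # genome / catalog geometry
    annotated_lncrna_fraction: float = 0.4

    def validate(self) -> None:
        if self.n_housekeeping + self.n_lncrna + 3 > self.n_genes:
            raise ValueError("gene class counts exceed n_genes")
        if self.planted_nuclear + self.planted_cytoplasmic > self.n_genes:
            raise ValueError("planted enrichment counts exceed n_genes")
        if self.n_candidates > min(self.planted_nuclear, self.planted_de, self.n_lncrna):
            raise ValueError("n_candidates exceeds a planted pool")
        if self.lineage_onset_stage not in STAGES:
            raise ValueError(f"unknown onset stage {self.lineage_onset_stage!r}")


@dataclass
class GroundTruth:
    """Planted per-gene properties, recorded for recovery checks."""

    genes: pd.DataFrame
    transcript_of_gene: dict[str, str]
    gene_of_transcript: dict[str, str]
    partner_genes: dict[int, list[str]]
    realized_support: Optional[pd.DataFrame] = None

    @property
    def candidates(self) -> list[str]:
        return sorted(self.genes.index[self.genes["candidate"]])


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def make_truth(cfg: GeneratorConfig) -> GroundTruth:
    """Assign gene classes and planted properties; the seed fixes everything."""
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_genes
    ids = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    # named marker genes replace three generic ids (two housekeeping, one lncRNA)
    ids[0], ids[1] = "GAPDH", "RPS14"
    ids[cfg.n_housekeeping] = "MALAT1"

    gene_class = np.array(["mrna"] * n, dtype=object)
    gene_class[: cfg.n_housekeeping] = "housekeeping"
    gene_class[cfg.n_housekeeping : cfg.n_housekeeping + cfg.n_lncrna] = "lncrna"

    df = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    df["gene_class"] = gene_class
    df["is_lncrna"] = gene_class == "lncrna"
    lnc_idx = np.where(df["is_lncrna"])[0]
    annotated = np.zeros(n, dtype=bool)
    annotated[gene_class != "lncrna"] = True
    n_annot_lnc = int(round(cfg.annotated_lncrna_fraction * cfg.n_lncrna))
    annotated[rng.choice(lnc_idx, size=n_annot_lnc, replace=False)] = True
    df["annotated"] = annotated

    # candidates: lncRNA genes planted with up-DE + nuclear enrichment together
    candidates = rng.choice(lnc_idx, size=cfg.n_candidates, replace=False)
    is_candidate = np.zeros(n, dtype=bool)
    is_candidate[candidates] = True
    df["candidate"] = is_candidate

    # enrichment truth; housekeeping genes stay in the calibration band
    # (the marker pair GAPDH/RPS14 is the deliberate exception)
    enrichment = np.array(["none"] * n, dtype=object)
    enrichment[candidates] = "nuclear_enriched"
    pool = np.setdiff1d(np.arange(n), candidates)
    pool = pool[gene_class[pool] != "housekeeping"]
    pool = pool[~np.isin(pool, [0, 1, cfg.n_housekeeping])]  # markers handled below
    extra_nuc = rng.choice(pool, size=cfg.planted_nuclear - cfg.n_candidates - 1, replace=False)
    enrichment[extra_nuc] = "nuclear_enriched"
    enrichment[cfg.n_housekeeping] = "nuclear_enriched"  # MALAT1
    pool2 = np.setdiff1d(pool, extra_nuc)
    extra_cyto = rng.choice(pool2, size=cfg.planted_cytoplasmic - 2, replace=False)
    enrichment[extra_cyto] = "cytoplasmic_enriched"
    enrichment[[0, 1]] = "cytoplasmic_enriched"  # GAPDH, RPS14
    df["true_enrichment"] = enrichment

    # DE truth: the candidate lncRNAs are up in tumor. Non-candidate lncRNAs
    # may only be planted DOWN (an up-regulated background lncRNA could drift
    # nuclear and become an accidental candidate); the rest of the planted DE
    # genes are mRNAs in both directions, so the dysregulated lncRNA set
    # carries both signs for the separation clustering.
    de = np.array(["none"] * n, dtype=object)
    de[candidates] = "up"
    n_extra = cfg.planted_de - cfg.n_candidates
    n_lnc_down = n_extra // 3
    lnc_pool = np.setdiff1d(lnc_idx, candidates)
    lnc_down = rng.choice(lnc_pool, size=min(n_lnc_down, len(lnc_pool)), replace=False)
    de[lnc_down] = "down"
    mrna_pool = np.where(gene_class == "mrna")[0]
    mrna_pool = mrna_pool[~np.isin(mrna_pool, candidates)]
    extra_de = rng.choice(mrna_pool, size=n_extra - len(lnc_down), replace=False)
    halves = rng.permutation(extra_de)
    de[halves[: len(halves) // 2]] = "up"
    de[halves[len(halves) // 2 :]] = "down"
    df["true_de"] = de

    # survival truth: a subset of candidates is prognostic
    prognostic = np.zeros(n, dtype=bool)
    n_prog = min(cfg.planted_prognostic, cfg.n_candidates)
    prognostic[candidates[:n_prog]] = True
    df["prognostic"] = prognostic

    # co-expression blocks: candidates round-robin over latent factors,
    # partner genes drawn from unused mRNAs
    block = np.full(n, -1, dtype=int)
    for j, gi in enumerate(candidates):
        block[gi] = j % cfg.coexpr_factors
    partner_pool = np.where((gene_class == "mrna") & (de == "none") & ~is_candidate)[0]
    partner_pool = partner_pool[~np.isin(partner_pool, np.concatenate([extra_nuc, extra_cyto]))]
    chosen = rng.choice(partner_pool, size=cfg.coexpr_factors * cfg.partners_per_factor, replace=False)
    partner_genes: dict[int, list[str]] = {}
    for k in range(cfg.coexpr_factors):
        members = chosen[k * cfg.partners_per_factor : (k + 1) * cfg.partners_per_factor]
        block[members] = k
        partner_genes[k] = sorted(ids[members])
    df["coexpr_block"] = block

    # embryo truth: candidates are lineage-restricted from the onset stage
    df["lineage_specific"] = is_candidate
    df["tumor_specific_transcript"] = is_candidate

    transcript_of_gene = {g: f"{g}.T1" for g in ids}
    gene_of_transcript = {t: g for g, t in transcript_of_gene.items()}
    return GroundTruth(df, transcript_of_gene, gene_of_transcript, partner_genes)


# ---------------------------------------------------------------------------
# genome and catalogs


_EXON_LEN = 200
_INTRON_LEN = 300
_LOCUS_SPACING = 2600


def _gene_locus(i: int) -> tuple[str, int, str]:
    chrom = f"chr{(i % 2) + 1}"
    start = 1000 + (i // 2) * _LOCUS_SPACING
    strand = "+" if (i // 2) % 2 == 0 else "-"
    return chrom, start, strand


def _make_transcript(tid, gid, chrom, strand, start, n_exons=3, source="sim") -> TranscriptModel:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + _EXON_LEN))
        pos += _EXON_LEN + _INTRON_LEN
    return TranscriptModel(tid, gid, chrom, strand, tuple(exons), source)


def generate_genome_and_catalog(
    cfg: GeneratorConfig, truth: Optional[GroundTruth] = None
) -> tuple[dict[str, str], TranscriptCatalog, TranscriptCatalog, RepeatMask]:
    """Genome sequences, reference annotation, assembled catalog, repeat mask.

    The assembled catalog holds one consensus transcript per gene plus five
    planted filter violators; the reference is engineered per gene so every
    class code in {=, c, j, i, u, x, o} is realized among unannotated lncRNAs.
    """
    if truth is None:
        truth = make_truth(cfg)
    rng = _rng(cfg, 1)
    genes = truth.genes
    n = len(genes)

    assembled = TranscriptCatalog()
    reference = TranscriptCatalog()
    codes_cycle = ("j", "u", "i", "x", "o", "c")
    # paper-like proportions for unannotated lncRNA codes
    code_weights = {"j": 0.50, "u": 0.25, "i": 0.10, "x": 0.05, "o": 0.05, "c": 0.05}
    unannot_counter = 0

    for i, gene_id in enumerate(genes.index):
        chrom, start, strand = _gene_locus(i)
        tid = truth.transcript_of_gene[gene_id]
        query = _make_transcript(tid, gene_id, chrom, strand, start)
        assembled.add(query)
        row = genes.loc[gene_id]
        if row["annotated"]:
            biotype = "protein_coding"
            if row["is_lncrna"]:
                biotype = "lincRNA" if i % 2 == 0 else "antisense"
            # exact intron chain; terminal ends jittered (still class "=")
            ref = TranscriptModel(
                f"REF_{gene_id}",
                f"REFG_{gene_id}",
                chrom,
                strand,
                ((query.exons[0][0] - 50, query.exons[0][1]),)
                + query.exons[1:-1]
                + ((query.exons[-1][0], query.exons[-1][1] + 50),),
                source_label=biotype,
            )
            reference.add(ref)
        else:
            # unannotated lncRNA: realize a planted class code
            if unannot_counter < len(codes_cycle):
                code = codes_cycle[unannot_counter]  # guarantee every code occurs
            else:
                code = rng.choice(list(code_weights), p=list(code_weights.values()))
            unannot_counter += 1
            ref = _reference_for_code(code, query, gene_id)
            if ref is not None:
                reference.add(ref)

    _add_filter_violators(assembled)
    mask = RepeatMask([("chr1", assembled["BAD_repeat.T1"].exons[0][0],
                        assembled["BAD_repeat.T1"].exons[-1][1])])
    genome = _random_genome(cfg, assembled, reference, rng)
    return genome, reference, assembled, mask


def _reference_for_code(code: str, q: TranscriptModel, gene_id: str) -> Optional[TranscriptModel]:
    """Build a reference transcript standing in the given class-code relation
    to the 3-exon query."""
    e = q.exons
    rid, rgid = f"REF_{gene_id}", f"REFG_{gene_id}"
    if code == "u":
        return None
    if code == "j":
        # share the first intron, shift the second
        exons = (e[0], e[1], (e[2][0] + 80, e[2][1] + 80))
        return TranscriptModel(rid, rgid, q.chrom, q.strand, exons, "protein_coding")
    if code == "c":
        # query's chain contiguous inside a longer reference chain and span
        before = (e[0][0] - 500, e[0][0] - 300)
        after = (e[2][1] + 300, e[2][1] + 500)
        return TranscriptModel(rid, rgid, q.chrom, q.strand, (before,) + e + (after,), "protein_coding")
    if code == "i":
        # reference intron covers the whole query span
        span = q.span
        exons = ((span[0] - 400, span[0] - 200), (span[1] + 200, span[1] + 400))
        return TranscriptModel(rid, rgid, q.chrom, q.strand, exons, "protein_coding")
    if code == "x":
        other = "-" if q.strand == "+" else "+"
        return TranscriptModel(rid, rgid, q.chrom, other, e, "protein_coding")
    if code == "o":
        # same-strand mono-exonic overlap: no shared junction, no containment
        exons = ((e[0][0] - 100, e[0][1] + 50),)
        return TranscriptModel(rid, rgid, q.chrom, q.strand, exons, "protein_coding")
    raise ValueError(f"cannot construct reference for code {code!r}")


def _add_filter_violators(assembled: TranscriptCatalog) -> None:
    """Five extra transcripts, each violating exactly one candidate filter."""
    base = 1000 + (len(assembled) // 2 + 10) * _LOCUS_SPACING
    mk = _make_transcript
    assembled.add(
        TranscriptModel("BAD_mono.T1", "BAD_mono", "chr1", "+", ((base, base + 600),), "sim")
    )
    assembled.add(
        TranscriptModel(
            "BAD_short.T1", "BAD_short", "chr1", "+",
            ((base + 5000, base + 5100), (base + 5400, base + 5500)), "sim",
        )
    )
    assembled.add(
        TranscriptModel(
            "BAD_unstranded.T1", "BAD_unstranded", "chr1", ".",
            mk("x", "x", "chr1", "+", base + 10000).exons, "sim",
        )
    )
    assembled.add(mk("BAD_lowtpm.T1", "BAD_lowtpm", "chr1", "+", base + 20000))
    assembled.add(mk("BAD_repeat.T1", "BAD_repeat", "chr1", "+", base + 30000))


def _random_genome(cfg, assembled, reference, rng) -> dict[str, str]:
    ends: dict[str, int] = {"chr1": 0, "chr2": 0}
    for cat in (assembled, reference):
        for t in cat:
            ends[t.chrom] = max(ends.get(t.chrom, 0), t.span[1] + 1000)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, end in sorted(ends.items()):
        seq = alphabet[rng.integers(0, 4, size=end)]
        genome[chrom] = seq.tobytes().decode("ascii")
    return genome


def coding_potential_labels(truth: GroundTruth) -> list[CodingPotentialLabel]:
    """Noise-free predictor labels derived from the planted gene classes."""
    out = []
    for gene_id, row in truth.genes.iterrows():
        tid = truth.transcript_of_gene[gene_id]
        label = "noncoding" if row["is_lncrna"] else "coding"
        for predictor in PREDICTORS:
            out.append(CodingPotentialLabel(tid, predictor, label))
    for bad in ("BAD_mono", "BAD_short", "BAD_unstranded", "BAD_lowtpm", "BAD_repeat"):
        for predictor in PREDICTORS:
            out.append(CodingPotentialLabel(f"{bad}.T1", predictor, "noncoding"))
    return out


# ---------------------------------------------------------------------------
# fraction matrices


def generate_fraction_matrices(
    cfg: GeneratorConfig, truth: Optional[GroundTruth] = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], GroundTruth]:
    """Paired cytoplasmic/nuclear FPKM matrices (genes x cell lines).

    Per-gene mean log2(cyto/nuc) by class: neutral mRNAs ~ N(0, sd), the
    housekeeping band ~ N(band_mean, band_sd) (cytoplasm-shifted, wider
    than the mRNA spread so the calibration band encloses typical genes),
    non-planted lncRNAs ~ N(lncrna_mean, sd) (nuclear-shifted), planted
    enriched genes at band_mean +/- shift. Per-line ratios add N(0,
    line_noise_sd); per-library scale factors are applied so downstream
    normalization has work to do.
    """
    if truth is None:
        truth = make_truth(cfg)
    rng = _rng(cfg, 2)
    genes = truth.genes
    n = len(genes)
    cls = genes["gene_class"].to_numpy()
    enr = genes["true_enrichment"].to_numpy()

    mu = rng.normal(0.0, cfg.mrna_ratio_sd, size=n)
    is_hk = cls == "housekeeping"
    mu[is_hk] = rng.normal(cfg.hk_band_mean, cfg.hk_band_sd, size=int(is_hk.sum()))
    is_lnc = (cls == "lncrna") & (enr == "none")
    mu[is_lnc] = rng.normal(cfg.lncrna_ratio_mean, cfg.mrna_ratio_sd, size=int(is_lnc.sum()))
    mu[enr == "nuclear_enriched"] = cfg.hk_band_mean + cfg.nuclear_shift
    mu[enr == "cytoplasmic_enriched"] = cfg.hk_band_mean + cfg.cytoplasmic_shift

    base = rng.normal(cfg.base_log2_expr_mean, cfg.base_log2_expr_sd, size=n)
    base[is_hk] = rng.normal(cfg.base_log2_expr_mean + 2.0, 1.0, size=int(is_hk.sum()))

    lines = [f"HKCI-{i + 1}" for i in range(cfg.n_cell_lines)]
    ratios = mu[:, None] + rng.normal(0.0, cfg.line_noise_sd, size=(n, cfg.n_cell_lines))
    cyto = np.power(2.0, base[:, None] + ratios / 2.0)
    nuc = np.power(2.0, base[:, None] - ratios / 2.0)
    # library-specific depth factors, removed later by normalization
    cyto *= rng.uniform(0.6, 1.6, size=cfg.n_cell_lines)[None, :]
    nuc *= rng.uniform(0.6, 1.6, size=cfg.n_cell_lines)[None, :]

    cyto_df = pd.DataFrame(cyto, index=genes.index, columns=lines)
    nuc_df = pd.DataFrame(nuc, index=genes.index, columns=lines)
    housekeeping = sorted(genes.index[is_hk])
    return cyto_df, nuc_df, housekeeping, truth


# ---------------------------------------------------------------------------
# tumor cohort


@dataclass
class TumorCohort:
    counts_tumor: pd.DataFrame
    counts_adjacent: pd.DataFrame
    tpm: pd.DataFrame  # transcripts x all samples, for the expression filter
    sample_catalogs: list[tuple[TranscriptCatalog, str]]
    method_tables: dict[str, pd.DataFrame]
    survival: pd.DataFrame
    coexpr_tpm: pd.DataFrame  # genes x tumor-only samples, latent-factor structure
    truth: GroundTruth


def generate_tumor_cohort(
    cfg: GeneratorConfig,
    truth: Optional[GroundTruth] = None,
    assembled: Optional[TranscriptCatalog] = None,
) -> TumorCohort:
    """Tumor/adjacent counts, per-sample assembly catalogs, DE method tables,
    and a survival table, all tied to the planted truth."""
    if truth is None:
        truth = make_truth(cfg)
    rng = _rng(cfg, 3)
    genes = truth.genes
    n = len(genes)
    tids = [truth.transcript_of_gene[g] for g in genes.index]
    n_pairs = cfg.n_tumor_pairs

    base_log2 = rng.normal(6.0, 1.5, size=n)
    # planted disease lncRNAs are solidly expressed (detectable at this
    # cohort size); the TPM filter would discard undetectable ones anyway
    is_cand = genes["candidate"].to_numpy()
    base_log2[is_cand] = rng.normal(7.0, 0.8, size=int(is_cand.sum()))
    base_mean = np.power(2.0, base_log2)
    lfc = np.zeros(n)
    lfc[genes["true_de"] == "up"] = cfg.de_log2fc
    lfc[genes["true_de"] == "down"] = -cfg.de_log2fc
    mean_tumor = base_mean * np.power(2.0, lfc / 2.0)
    mean_adjacent = base_mean * np.power(2.0, -lfc / 2.0)

    def nb(mean: np.ndarray) -> np.ndarray:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    tum = np.empty((n, n_pairs))
    adj = np.empty((n, n_pairs))
    for s in range(n_pairs):
        tum[:, s] = nb(mean_tumor)
        adj[:, s] = nb(mean_adjacent)

    tumor_cols = [f"tumor_{i + 1}" for i in range(n_pairs)]
    adj_cols = [f"adjacent_{i + 1}" for i in range(n_pairs)]
    counts_tumor = pd.DataFrame(tum, index=tids, columns=tumor_cols)
    counts_adjacent = pd.DataFrame(adj, index=tids, columns=adj_cols)

    # TPM-like matrix for the expression filter (equal transcript lengths)
    all_counts = pd.concat([counts_tumor, counts_adjacent], axis=1)
    tpm = all_counts / all_counts.sum(axis=0) * 1e6
    if assembled is not None:
        extra = [t for t in assembled.transcript_ids if t not in tpm.index]
        planted = pd.DataFrame(50.0, index=extra, columns=tpm.columns)
        if "BAD_lowtpm.T1" in planted.index:
            planted.loc["BAD_lowtpm.T1"] = 0.2  # fails the TPM > 1 filter
        tpm = pd.concat([tpm, planted])

    sample_catalogs, realized = _sample_catalogs(
        cfg, truth, assembled, all_counts, rng
    )
    truth.realized_support = realized

    method_tables = _method_tables(cfg, truth, lfc, rng)
    survival = _survival_table(cfg, truth, rng)
    coexpr_tpm = _coexpression_panel(cfg, truth, rng)
    return TumorCohort(
        counts_tumor, counts_adjacent, tpm, sample_catalogs, method_tables,
        survival, coexpr_tpm, truth,
    )


def _coexpression_panel(cfg, truth, rng) -> pd.DataFrame:
    """Tumor-only expression panel with latent-factor co-expression.

    Genes in block k (candidate lncRNAs and their partner mRNAs) share factor
    k with the configured loading on the log2 scale; all other genes are
    independent noise around their baseline.
    """
    genes = truth.genes
    n = len(genes)
    m = cfg.n_coexpr_samples
    block = genes["coexpr_block"].to_numpy()
    base = rng.normal(4.0, 1.0, size=n)
    factors = rng.normal(0.0, 1.0, size=(cfg.coexpr_factors, m))
    noise = rng.normal(0.0, cfg.coexpr_noise_sd, size=(n, m))
    shared = np.where(
        (block >= 0)[:, None],
        cfg.factor_loading * factors[np.clip(block, 0, None), :],
        0.0,
    )
    log2x = base[:, None] + shared + noise
    cols = [f"coexpr_tumor_{i + 1}" for i in range(m)]
    return pd.DataFrame(np.power(2.0, log2x), index=genes.index, columns=cols)


def _sample_catalogs(cfg, truth, assembled, all_counts, rng):
    """Per-sample catalogs: transcript inclusion probability saturates with
    its counts in that sample; tumor-specific transcripts never enter
    adjacent catalogs."""
    genes = truth.genes
    tumor_specific = {
        truth.transcript_of_gene[g]
        for g in genes.index[genes["tumor_specific_transcript"]]
    }
    catalogs: list[tuple[TranscriptCatalog, str]] = []
    support = pd.DataFrame(
        0, index=all_counts.index, columns=["tumor_support", "adjacent_support"]
    )
    source = assembled if assembled is not None else None
    for col in all_counts.columns:
        condition = "tumor" if col.startswith("tumor") else "adjacent"
        counts = all_counts[col].to_numpy()
        prob = counts / (counts + 50.0)
        include = rng.random(len(counts)) < prob
        cat = TranscriptCatalog()
        for tid, keep in zip(all_counts.index, include):
            if not keep:
                continue
            if condition == "adjacent" and tid in tumor_specific:
                continue
            gene = truth.gene_of_transcript[tid]
            i = genes.index.get_loc(gene)
            if source is not None and tid in source:
                model = source[tid]
                cat.add(TranscriptModel(tid, gene, model.chrom, model.strand, model.exons, col))
            else:
                chrom, start, strand = _gene_locus(i)
                cat.add(_make_transcript(tid, gene, chrom, strand, start, source=col))
            support.loc[tid, f"{condition}_support"] += 1
        catalogs.append((cat, condition))
    return catalogs, support


def _method_tables(cfg, truth, lfc, rng) -> dict[str, pd.DataFrame]:
    """Simulated external DE result tables: one FDR-style, one posterior-style."""
    genes = truth.genes
    n = len(genes)
    tids = [truth.transcript_of_gene[g] for g in genes.index]
    is_de = (genes["true_de"] != "none").to_numpy()

    def noisy_lfc():
        return lfc + rng.normal(0.0, 0.15, size=n) + np.where(is_de, 0.0, rng.normal(0, 0.25, size=n))

    padj = np.where(is_de, np.power(10.0, rng.uniform(-6, -2.4, size=n)), rng.uniform(0.02, 1.0, size=n))
    fdr_table = pd.DataFrame(
        {
            "transcript_id": tids,
            "method": "nb_glm_sim",
            "log2fc": noisy_lfc(),
            "pvalue": padj / 2.0,
            "padj": padj,
            "ppde": np.nan,
        }
    )
    ppde = np.where(is_de, rng.uniform(0.992, 1.0, size=n), rng.uniform(0.0, 0.95, size=n))
    ppde_table = pd.DataFrame(
        {
            "transcript_id": tids,
            "method": "eb_posterior_sim",
            "log2fc": noisy_lfc(),
            "pvalue": np.nan,
            "padj": np.nan,
            "ppde": ppde,
        }
    )
    return {"nb_glm_sim": fdr_table, "eb_posterior_sim": ppde_table}


def _survival_table(cfg, truth, rng) -> pd.DataFrame:
    """Exponential survival with a planted hazard effect.

    A latent binary risk state drives both the hazard (rate x hazard_ratio
    when high-risk) and the expression of prognostic genes, so a median split
    on any prognostic gene recovers the risk groups; null genes are
    independent lognormal noise.
    """
    genes = truth.genes
    n_pat = cfg.n_patients
    risk = rng.random(n_pat) < 0.5
    rate0 = 1.0 / 1000.0
    rate = rate0 * np.power(cfg.hazard_ratio, risk.astype(float))
    time = rng.exponential(1.0 / rate)
    event = np.ones(n_pat, dtype=int)
    censor = rng.random(n_pat) < cfg.censoring_fraction
    time = np.where(censor, rng.uniform(0, time), time)
    time = np.maximum(time, 0.5)
    event[censor] = 0

    data = {"patient_id": [f"P{i:04d}" for i in range(n_pat)], "time": time, "event": event}
    prognostic = sorted(genes.index[genes["prognostic"]])
    for g in prognostic:
        data[g] = np.exp(rng.normal(0.0, 0.3, size=n_pat) + 2.0 * risk)
    null_genes = [f"NULLSURV{i:03d}" for i in range(cfg.n_null_survival_genes)]
    for g in null_genes:
        data[g] = np.exp(rng.normal(0.0, 1.0, size=n_pat))
    return pd.DataFrame(data).set_index("patient_id")


# ---------------------------------------------------------------------------
# characterization inputs


def generate_characterization_inputs(
    cfg: GeneratorConfig,
    catalog: TranscriptCatalog,
    truth: GroundTruth,
) -> tuple[list[PeakSet], pd.DataFrame]:
    """H3K4me3 peak sets per epigenome and a single-cell embryo TPM table.

    Candidate genes get a promoter peak in every stem-cell epigenome (and in
    half the cancer ones); other genes are marked per epigenome with
    probability 0.3. Candidates express in a minority (>=2 but <67%) of each
    embryo's cells from the onset stage onward.
    """
    rng = _rng(cfg, 4)
    genes = truth.genes
    peak_sets = []
    candidate_set = set(truth.candidates)
    for category, count in EPIGENOMES.items():
        for j in range(count):
            eid = f"{category[:3].upper()}{j + 1:02d}"
            peaks = []
            for gene_id in genes.index:
                tid = truth.transcript_of_gene[gene_id]
                if tid not in catalog:
                    continue
                t = catalog[tid]
                marked = (
                    category != "cancer" or rng.random() < 0.5
                    if gene_id in candidate_set
                    else rng.random() < 0.3
                )
                if marked:
                    tss = t.tss
                    peaks.append((t.chrom, max(0, tss - 200), tss + 200))
            peak_sets.append(PeakSet(eid, category, tuple(sorted(peaks))))

    onset = STAGES.index(cfg.lineage_onset_stage)
    index_rows = []
    for si, stage in enumerate(STAGES):
        for e in range(cfg.embryos_per_stage):
            embryo_id = f"{stage}_E{e + 1}"
            for c in range(cfg.cells_per_embryo):
                index_rows.append((si, stage, embryo_id, f"{embryo_id}_C{c + 1}"))
    embryo = pd.DataFrame(index_rows, columns=["_si", "stage", "embryo_id", "cell_id"])

    # >=2 expressing cells but below the lineage-specific 67% ceiling
    n_cells = cfg.cells_per_embryo
    k_expr = max(2, min(3, int(np.floor(0.66 * n_cells)) - 1))
    for g in truth.candidates:
        values = np.zeros(len(embryo))
        for (si, embryo_id), grp in embryo.groupby(["_si", "embryo_id"], sort=False):
            if si < onset:
                continue
            cells = rng.choice(len(grp), size=k_expr, replace=False)
            values[grp.index[cells]] = rng.uniform(2.0, 10.0, size=k_expr)
        embryo[g] = values
    embryo["EMB_BROAD"] = rng.uniform(3.0, 8.0, size=len(embryo))
    embryo["EMB_NULL"] = 0.0
    embryo = embryo.drop(columns="_si")
    return peak_sets, embryo


# ---------------------------------------------------------------------------
# bundle + disk output


@dataclass
class SimulatedStudy:
    cfg: GeneratorConfig
    truth: GroundTruth
    genome: dict[str, str]
    reference: TranscriptCatalog
    assembled: TranscriptCatalog
    mask: RepeatMask
    cyto: pd.DataFrame
    nuc: pd.DataFrame
    housekeeping: list[str]
    cohort: TumorCohort
    peak_sets: list[PeakSet]
    embryo: pd.DataFrame
    cp_labels: list[CodingPotentialLabel]
    markers: dict[str, str] = field(default_factory=lambda: dict(MARKERS))


def generate_study(cfg: GeneratorConfig) -> SimulatedStudy:
    """Generate the full synthetic study (all stages share one truth)."""
    truth = make_truth(cfg)
    genome, reference, assembled, mask = generate_genome_and_catalog(cfg, truth)
    cyto, nuc, housekeeping, _ = generate_fraction_matrices(cfg, truth)
    cohort = generate_tumor_cohort(cfg, truth, assembled)
    peak_sets, embryo = generate_characterization_inputs(cfg, assembled, truth)
    return SimulatedStudy(
        cfg, truth, genome, reference, assembled, mask, cyto, nuc, housekeeping,
        cohort, peak_sets, embryo, coding_potential_labels(truth),
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write all generated inputs as plain-text files; returns a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save_tsv(df: pd.DataFrame, name: str, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        manifest[name] = str(path)

    write_catalog(study.reference, out / "reference.gtf")
    write_catalog(study.assembled, out / "assembled.gtf")
    manifest["reference.gtf"] = str(out / "reference.gtf")
    manifest["assembled.gtf"] = str(out / "assembled.gtf")
    with open(out / "repeats.bed", "w") as fh:
        for chrom, s, e in study.mask.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")
    manifest["repeats.bed"] = str(out / "repeats.bed")

    save_tsv(study.cyto, "fpkm_cyto.tsv")
    save_tsv(study.nuc, "fpkm_nuc.tsv")
    (out / "housekeeping.txt").write_text("\n".join(study.housekeeping) + "\n")
    manifest["housekeeping.txt"] = str(out / "housekeeping.txt")

    save_tsv(study.cohort.counts_tumor, "counts_tumor.tsv")
    save_tsv(study.cohort.counts_adjacent, "counts_adjacent.tsv")
    save_tsv(study.cohort.tpm, "tpm.tsv")
    for name, table in study.cohort.method_tables.items():
        save_tsv(table, f"de_{name}.tsv", index=False)
    save_tsv(study.cohort.survival, "survival.tsv")
    save_tsv(study.cohort.coexpr_tpm, "coexpr_tumor_tpm.tsv")

    cp = pd.DataFrame(
        [
            {"transcript_id": l.transcript_id, "predictor": l.predictor_name, "label": l.label}
            for l in study.cp_labels
        ]
    )
    save_tsv(cp, "coding_potential.tsv", index=False)

    peak_rows = []
    for ps in study.peak_sets:
        bed = out / f"peaks_{ps.epigenome_id}.bed"
        with open(bed, "w") as fh:
            for chrom, s, e in ps.peaks:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        peak_rows.append({"epigenome_id": ps.epigenome_id, "category": ps.category, "path": bed.name})
    save_tsv(pd.DataFrame(peak_rows), "peaks_manifest.tsv", index=False)

    save_tsv(study.embryo, "embryo_tpm.tsv", index=False)

    truth_payload = {
        "genes": study.truth.genes.reset_index().to_dict(orient="list"),
        "partner_genes": study.truth.partner_genes,
        "candidates": study.truth.candidates,
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, sort_keys=True, default=str))
    manifest["truth.json"] = str(out / "truth.json")
    (out / "config.json").write_text(json.dumps(asdict(study.cfg), sort_keys=True))
    manifest["config.json"] = str(out / "config.json")
    return manifest
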