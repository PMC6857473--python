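"""End-to-end orchestration: simulate -> catalog -> identify -> DE -> enrich
-> characterize -> co-express -> report.

Stages communicate through plain-text files under the output directory. Each
stage records a hash of its parameters and input files; a completed stage is
skipped on rerun unless either changed. All thresholds default to the
decision rules the analysis is built around (TPM > 1, |log2FC| > 1,
adjusted p < 0.01, PPDE > 0.99, 5th/95th percentiles, >= 4 cell lines,
+/-1000 bp promoter window, PCC >= 0.6 at p < 0.05, 20% prevalence, k = 3).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from . import catalog as cat
from . import characterization as char
from . import coexpression as coex
from . import diffexpr as de
from . import enrichment as enr
from . import lncrna as lnc
from .simulate import MARKERS, GeneratorConfig, generate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "fracseq_out"
    simulate: bool = True
    input_dir: Optional[str] = None  # used when simulate is False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # lncRNA filter cascade
    min_exons: int = 2
    min_length: int = 200
    tpm_threshold: float = 1.0
    max_repeat_fraction: float = 0.0
    # differential expression
    lfc_cutoff: float = 1.0
    de_alpha: float = 0.01
    ppde_cutoff: float = 0.99
    # fraction enrichment
    fpkm_floor: float = 0.1
    percentiles: tuple[float, float] = (5.0, 95.0)
    required_lines: int = 4
    min_housekeeping: int = 30
    # characterization
    promoter_window: int = 1000
    embryo_min_embryos: int = 2
    embryo_min_cells: int = 2
    embryo_max_fraction: float = 0.67
    survival_alpha: float = 0.05
    not_expressed_floor: float = 0.5
    not_expressed_min_lines: int = 5
    # co-expression
    prevalence_min: float = 0.2
    pcc_min: float = 0.6
    coexpr_alpha: float = 0.05
    n_clusters: int = 3

    def __post_init__(self):
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        self.generator.seed = self.seed


REQUIRED_INPUTS = (
    "reference.gtf",
    "assembled.gtf",
    "repeats.bed",
    "tpm.tsv",
    "coding_potential.tsv",
    "counts_tumor.tsv",
    "counts_adjacent.tsv",
    "fpkm_cyto.tsv",
    "fpkm_nuc.tsv",
    "housekeeping.txt",
    "survival.tsv",
    "embryo_tpm.tsv",
    "peaks_manifest.tsv",
    "coexpr_tumor_tpm.tsv",
    "samples_manifest.tsv",
)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageRunner:
    """Runs named stages with parameter/input hashing and skip-on-rerun."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.state_dir = outdir / ".state"
        self.state_dir.mkdir(parents=True, exist_ok=True)
        self.log: list[str] = []

    def run(
        self,
        name: str,
        params: dict,
        inputs: Sequence[Path],
        outputs: Sequence[Path],
        fn: Callable[[], None],
    ) -> bool:
        """Execute ``fn`` unless this stage already ran with identical
        parameters and input bytes; returns True when executed."""
        h = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode())
        # hash by file name + content so equal runs in different directories
        # produce identical state files
        for p in sorted(inputs, key=lambda q: Path(q).name):
            h.update(Path(p).name.encode())
            h.update(_sha256_file(Path(p)).encode())
        digest = h.hexdigest()
        marker = self.state_dir / f"{name}.done.json"
        if marker.exists() and all(Path(o).exists() for o in outputs):
            if json.loads(marker.read_text()).get("hash") == digest:
                self.log.append(f"stage {name}: unchanged, skipped")
                return False
        try:
            fn()
        except Exception:
            (self.outdir / "FAILED").write_text(f"stage {name} failed\n")
            raise
        marker.write_text(json.dumps({"hash": digest}, sort_keys=True))
        self.log.append(f"stage {name}: executed")
        return True


def _read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, str]
    funnel: dict[str, int]
    candidates: list[str]
    stage_log: list[str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages in dependency order; returns the output manifest.

    With ``simulate`` enabled the synthetic study is generated under
    ``outdir/sim``; otherwise ``input_dir`` must already contain every
    required input file (validated before any stage runs).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    runner = _StageRunner(out)
    funnel: dict[str, int] = {}
    manifest: dict[str, str] = {}

    # ---- stage 0: inputs ----------------------------------------------------
    if config.simulate:
        sim_dir = out / "sim"

        def do_simulate():
            study = generate_study(config.generator)
            write_study(study, sim_dir)
            samples_dir = sim_dir / "samples"
            samples_dir.mkdir(exist_ok=True)
            rows = []
            for i, (sample_cat, condition) in enumerate(study.cohort.sample_catalogs):
                name = f"sample_{condition}_{i:03d}.gtf"
                cat.write_catalog(sample_cat, samples_dir / name)
                rows.append({"path": f"samples/{name}", "condition": condition})
            _tsv(pd.DataFrame(rows), sim_dir / "samples_manifest.tsv", index=False)
            study.truth.realized_support.to_csv(
                sim_dir / "truth_support.tsv", sep="\t"
            )

        runner.run(
            "simulate",
            {"generator": asdict(config.generator)},
            inputs=[],
            outputs=[sim_dir / f for f in REQUIRED_INPUTS],
            fn=do_simulate,
        )
        input_dir = sim_dir
    else:
        if config.input_dir is None:
            raise ValueError("input_dir is required when simulate is disabled")
        input_dir = Path(config.input_dir)
        missing = [f for f in REQUIRED_INPUTS if not (input_dir / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing required inputs in {input_dir}: {missing}")

    src = lambda name: input_dir / name

    assembled = cat.read_catalog(src("assembled.gtf"))
    reference = cat.read_catalog(src("reference.gtf"))
    gene_of_tid = {t.transcript_id: t.gene_id for t in assembled}
    funnel["assembled_transcripts"] = len(assembled)

    # ---- stage 1: catalog comparison and assembly support -------------------
    codes_path = out / "codes.tsv"
    support_path = out / "support.tsv"

    def do_catalog():
        biotype_by_key = {t.chain_key(): t.source_label for t in reference}
        codes = cat.assign_class_codes(assembled, reference)
        rows = []
        for tid in sorted(codes):
            t = assembled[tid]
            biotype = biotype_by_key.get(t.chain_key()) if codes[tid] == "=" else None
            rows.append(
                {"transcript_id": tid, "class_code": codes[tid], "ref_biotype": biotype}
            )
        _tsv(pd.DataFrame(rows), codes_path, index=False)

        sample_manifest = pd.read_csv(src("samples_manifest.tsv"), sep="\t")
        sample_catalogs = [
            (cat.read_catalog(input_dir / row["path"]), row["condition"])
            for _, row in sample_manifest.iterrows()
        ]
        support = cat.assembly_support_table(assembled, sample_catalogs)
        _tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": s.transcript_id,
                        "tumor_support": s.tumor_support,
                        "adjacent_support": s.adjacent_support,
                    }
                    for s in support
                ]
            ),
            support_path,
            index=False,
        )

    runner.run(
        "catalog",
        {},
        inputs=[src("assembled.gtf"), src("reference.gtf"), src("samples_manifest.tsv")],
        outputs=[codes_path, support_path],
        fn=do_catalog,
    )
    manifest["codes"] = str(codes_path)
    manifest["support"] = str(support_path)

    # ---- stage 2: lncRNA identification --------------------------------------
    status_path = out / "lncrna_status.tsv"

    def do_lncrna():
        tpm = _read_matrix(src("tpm.tsv"))
        mask = lnc.RepeatMask.from_bed(src("repeats.bed"))
        reasons: dict[str, str] = {}
        retained = lnc.filter_candidates(
            assembled,
            tpm,
            mask,
            min_exons=config.min_exons,
            min_length=config.min_length,
            tpm_threshold=config.tpm_threshold,
            max_repeat_fraction=config.max_repeat_fraction,
            reasons=reasons,
        )
        codes_df = pd.read_csv(codes_path, sep="\t").set_index("transcript_id")
        codes_map = {
            tid: (row["class_code"], row["ref_biotype"] if pd.notna(row["ref_biotype"]) else None)
            for tid, row in codes_df.iterrows()
        }
        cp_labels = lnc.read_cp_labels(src("coding_potential.tsv"))
        predictors = sorted({l.predictor_name for l in cp_labels})
        statuses = lnc.classify_transcripts(retained, codes_map, cp_labels, predictors)
        rows = [
            {
                "transcript_id": s.transcript_id,
                "gene_id": gene_of_tid[s.transcript_id],
                "class_code": s.class_code,
                "reference_biotype": s.reference_biotype,
                "category": s.category,
                "rejection_reason": s.rejection_reason,
            }
            for s in statuses
        ]
        for tid, reason in sorted(reasons.items()):
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene_of_tid[tid],
                    "class_code": None,
                    "reference_biotype": None,
                    "category": "rejected",
                    "rejection_reason": reason,
                }
            )
        _tsv(pd.DataFrame(rows), status_path, index=False)

    runner.run(
        "lncrna",
        {
            k: getattr(config, k)
            for k in ("min_exons", "min_length", "tpm_threshold", "max_repeat_fraction")
        },
        inputs=[src("tpm.tsv"), src("repeats.bed"), src("coding_potential.tsv"), codes_path],
        outputs=[status_path],
        fn=do_lncrna,
    )
    manifest["lncrna_status"] = str(status_path)
    status = pd.read_csv(status_path, sep="\t")
    lnc_tids = set(
        status.loc[
            status["category"].isin(["annotated_lncRNA", "unannotated_lncRNA"]),
            "transcript_id",
        ]
    )
    funnel["filter_survivors"] = int((status["rejection_reason"].isna()).sum())
    funnel["lncrna_transcripts"] = len(lnc_tids)

    # ---- stage 3: differential expression ------------------------------------
    builtin_path = out / "de_builtin.tsv"
    consensus_path = out / "consensus.tsv"
    separation_path = out / "separation.json"
    method_files = sorted(input_dir.glob("de_*.tsv"))

    def do_de():
        counts_tumor = _read_matrix(src("counts_tumor.tsv"))
        counts_adjacent = _read_matrix(src("counts_adjacent.tsv"))
        builtin = de.builtin_de_test(counts_tumor, counts_adjacent)
        de.write_de_table(builtin, builtin_path)

        call_sets = [
            de.threshold_method(
                builtin, "fdr", lfc_cutoff=config.lfc_cutoff, alpha=config.de_alpha
            )
        ]
        for mf in method_files:
            results = de.read_de_table(mf)
            rule = "ppde" if any(r.ppde is not None for r in results) else "fdr"
            call_sets.append(
                de.threshold_method(
                    results,
                    rule,
                    lfc_cutoff=config.lfc_cutoff,
                    alpha=config.de_alpha,
                    ppde_cutoff=config.ppde_cutoff,
                )
            )
        calls = de.consensus(call_sets)
        _tsv(
            pd.DataFrame(
                [{"transcript_id": c.transcript_id, "direction": c.direction} for c in calls]
            ),
            consensus_path,
            index=False,
        )

        # clustering validation on the dysregulated lncRNA transcripts
        tpm = _read_matrix(src("tpm.tsv"))
        dysregulated_lnc = sorted({c.transcript_id for c in calls} & lnc_tids)
        payload = {"n_dysregulated_lncrna": len(dysregulated_lnc)}
        if len(dysregulated_lnc) >= 2:
            sample_status = {
                s: ("tumor" if s.startswith("tumor") else "nontumor") for s in tpm.columns
            }
            _, chi2, p = de.validate_separation(tpm.loc[dysregulated_lnc], sample_status)
            payload.update({"chi_square": chi2, "p_value": p})
        separation_path.write_text(json.dumps(payload, sort_keys=True))

    runner.run(
        "de",
        {k: getattr(config, k) for k in ("lfc_cutoff", "de_alpha", "ppde_cutoff")},
        inputs=[src("counts_tumor.tsv"), src("counts_adjacent.tsv"), src("tpm.tsv"), *method_files],
        outputs=[builtin_path, consensus_path, separation_path],
        fn=do_de,
    )
    manifest["consensus"] = str(consensus_path)
    consensus_calls = pd.read_csv(consensus_path, sep="\t")
    funnel["consensus_de_transcripts"] = len(consensus_calls)

    # ---- stage 4: fraction enrichment ----------------------------------------
    calls_path = out / "enrichment_calls.tsv"
    range_path = out / "reference_range.json"
    markers_path = out / "marker_validation.json"

    def do_enrich():
        cyto = _read_matrix(src("fpkm_cyto.tsv"))
        nuc = _read_matrix(src("fpkm_nuc.tsv"))
        cyto_n, nuc_n, size_factors = enr.normalize_fraction_pair(cyto, nuc)
        ratios = enr.compute_log_ratios(cyto_n, nuc_n, floor=config.fpkm_floor)
        means = enr.mean_log_ratios(ratios)
        housekeeping = [
            line.strip()
            for line in open(src("housekeeping.txt"))
            if line.strip()
        ]
        rr = enr.reference_range(
            means,
            housekeeping,
            min_genes=config.min_housekeeping,
            percentiles=config.percentiles,
        )
        range_path.write_text(
            json.dumps(
                {
                    "lower_limit": rr.lower_limit,
                    "upper_limit": rr.upper_limit,
                    "n_housekeeping_used": rr.n_housekeeping_used,
                    "size_factors": size_factors.round(6).to_dict(),
                },
                sort_keys=True,
            )
        )
        calls = enr.classify_enrichment(ratios, rr, required_lines=config.required_lines)
        _tsv(enr.calls_to_frame(calls), calls_path)
        report = enr.validate_markers(calls, MARKERS)
        markers_path.write_text(
            json.dumps(
                {
                    "overall_pass": report.overall_pass,
                    "missing": list(report.missing),
                    "checks": [
                        {"gene": c.gene_id, "expected": c.expected, "observed": c.observed, "pass": c.passed}
                        for c in report.checks
                    ],
                },
                sort_keys=True,
            )
        )

    runner.run(
        "enrich",
        {
            k: getattr(config, k)
            for k in ("fpkm_floor", "percentiles", "required_lines", "min_housekeeping")
        },
        inputs=[src("fpkm_cyto.tsv"), src("fpkm_nuc.tsv"), src("housekeeping.txt")],
        outputs=[calls_path, range_path, markers_path],
        fn=do_enrich,
    )
    manifest["enrichment_calls"] = str(calls_path)
    manifest["reference_range"] = str(range_path)
    enrich_calls = pd.read_csv(calls_path, sep="\t").set_index("gene_id")
    nuclear_genes = set(enrich_calls.index[enrich_calls["status"] == enr.NUCLEAR])
    funnel["nuclear_enriched_genes"] = len(nuclear_genes)

    # ---- stage 5: candidate intersection --------------------------------------
    up_tids = set(
        consensus_calls.loc[consensus_calls["direction"] == de.UP, "transcript_id"]
    )
    up_lnc_genes = {gene_of_tid[t] for t in (up_tids & lnc_tids)}
    candidates = sorted(up_lnc_genes & nuclear_genes)
    funnel["up_regulated_lncrna_genes"] = len(up_lnc_genes)
    funnel["candidate_genes"] = len(candidates)
    candidates_path = out / "candidates.txt"
    candidates_path.write_text("".join(f"{g}\n" for g in candidates))
    manifest["candidates"] = str(candidates_path)

    # ---- stage 6: characterization --------------------------------------------
    report_path = out / "candidate_report.tsv"

    def do_characterize():
        peaks_manifest = pd.read_csv(src("peaks_manifest.tsv"), sep="\t")
        peak_sets = [
            char.read_peak_bed(input_dir / row["path"], row["epigenome_id"], row["category"])
            for _, row in peaks_manifest.iterrows()
        ]
        embryo = pd.read_csv(src("embryo_tpm.tsv"), sep="\t")
        survival = pd.read_csv(src("survival.tsv"), sep="\t", index_col=0)
        cyto = _read_matrix(src("fpkm_cyto.tsv"))
        nuc = _read_matrix(src("fpkm_nuc.tsv"))
        cellline_fpkm = (cyto + nuc) / 2.0

        promoter_counts = {}
        stage_calls = {}
        survival_p = {}
        tid_of_gene = {g: t for t, g in gene_of_tid.items()}
        for g in candidates:
            t = assembled[tid_of_gene[g]]
            promoter_counts[g] = char.promoter_mark_hits(
                t, peak_sets, window=config.promoter_window
            )
            if g in embryo.columns and (embryo[g] > 0).any():
                stage_calls[g] = char.embryo_expression_call(
                    g,
                    embryo,
                    min_embryos=config.embryo_min_embryos,
                    min_cells=config.embryo_min_cells,
                    max_fraction=config.embryo_max_fraction,
                )
            if g in survival.columns:
                survival_p[g] = char.km_logrank(survival, g).p_value
        reports = char.build_report(
            candidates,
            enrich_calls["status"].to_dict(),
            cellline_fpkm,
            promoter_counts=promoter_counts,
            stage_calls=stage_calls,
            survival_p=survival_p,
            fpkm_floor=config.not_expressed_floor,
            min_low_lines=config.not_expressed_min_lines,
        )
        _tsv(char.report_to_frame(reports, alpha=config.survival_alpha), report_path)

    runner.run(
        "characterize",
        {
            k: getattr(config, k)
            for k in (
                "promoter_window",
                "embryo_min_embryos",
                "embryo_min_cells",
                "embryo_max_fraction",
                "survival_alpha",
                "not_expressed_floor",
                "not_expressed_min_lines",
            )
        },
        inputs=[
            src("peaks_manifest.tsv"),
            src("embryo_tpm.tsv"),
            src("survival.tsv"),
            src("fpkm_cyto.tsv"),
            src("fpkm_nuc.tsv"),
            calls_path,
            candidates_path,
        ],
        outputs=[report_path],
        fn=do_characterize,
    )
    manifest["candidate_report"] = str(report_path)

    # ---- stage 7: co-expression -----------------------------------------------
    edges_path = out / "coexpression_edges.tsv"
    clusters_path = out / "coexpression_clusters.tsv"
    pmatrix_path = out / "partner_matrix.tsv"

    def do_coexpress():
        expr = _read_matrix(src("coexpr_tumor_tpm.tsv"))
        expr = coex.prevalence_filter(expr, config.prevalence_min)
        present = [g for g in candidates if g in expr.index]
        edges = coex.compute_edges(expr, present)
        selected = coex.select_partners(
            edges, pcc_min=config.pcc_min, alpha=config.coexpr_alpha
        )
        _tsv(coex.edges_to_frame(selected), edges_path, index=False)
        mat = coex.partner_matrix(edges, present, selected)
        _tsv(mat, pmatrix_path)
        rows = []
        if len(present) >= config.n_clusters and mat.shape[1] >= 1:
            clusters = coex.cluster_candidates(present, mat, k=config.n_clusters)
            for c in clusters:
                for g in c.member_lncrna_genes:
                    rows.append({"gene_id": g, "cluster_id": c.cluster_id})
        _tsv(pd.DataFrame(rows, columns=["gene_id", "cluster_id"]), clusters_path, index=False)

    runner.run(
        "coexpress",
        {k: getattr(config, k) for k in ("prevalence_min", "pcc_min", "coexpr_alpha", "n_clusters")},
        inputs=[src("coexpr_tumor_tpm.tsv"), candidates_path],
        outputs=[edges_path, clusters_path, pmatrix_path],
        fn=do_coexpress,
    )
    manifest["coexpression_edges"] = str(edges_path)
    manifest["coexpression_clusters"] = str(clusters_path)

    funnel_path = out / "funnel.json"
    funnel_path.write_text(json.dumps(funnel, sort_keys=True))
    manifest["funnel"] = str(funnel_path)
    (out / "manifest.json").write_text(
        json.dumps({k: str(Path(v).name) for k, v in manifest.items()}, sort_keys=True)
    )
    logger.info("pipeline funnel: %s", funnel)
    return PipelineResult(out, manifest, funnel, candidates, runner.log)
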