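"""End-to-end orchestration: QC -> typing -> DE -> GSEA -> ROE -> similarity -> TCR.

A single YAML config drives the run; one global seed is split into
per-stage seeds by hashing the stage name (so inserting a stage does not
perturb the randomness of the others).  Each stage writes its result table
under the output directory and the run ends with a machine-readable JSON
report of stage parameters, outputs and timings.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_typing, diffexpr, gsea, qc, roe, similarity, tcr
from .io import ExpressionMatrix, read_contigs, read_gmt, read_matrix_dir, concat_matrices
from .synthetic import CohortConfig, generate_reference

__all__ = ["PipelineConfig", "run_all", "stage_seed", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("qc", "typing", "de", "gsea", "roe", "similarity", "tcr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    sample_dirs: list[str]
    out_dir: str
    gmt_path: str | None = None
    seed: int = 0
    skip: tuple[str, ...] = ()
    qc: dict = field(default_factory=dict)
    typing: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)
    roe: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=dict)
    tcr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.sample_dirs:
            raise ValueError("config lists no sample directories")
        for d in self.sample_dirs:
            if not Path(d).is_dir():
                raise FileNotFoundError(f"sample directory does not exist: {d}")
        if "gsea" not in self.skip and self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(f"GMT file does not exist: {self.gmt_path}")
        if "gsea" not in self.skip and self.gmt_path is None:
            raise ValueError("GSEA enabled but no gmt_path configured (skip gsea or add one)")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in skip: {sorted(unknown)}")


def _timed(report: dict, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            report["stages"].setdefault(stage, {})
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            entry = report["stages"].setdefault(stage, {})
            entry["seconds"] = round(time.perf_counter() - self.t0, 3)
            entry["status"] = "failed" if exc_type else "completed"
            if exc_type:
                entry["error"] = str(exc)
                log.error("stage %s failed: %s", stage, exc)
            else:
                log.info("stage %s: done in %.2fs", stage, entry["seconds"])
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage in order and write the JSON run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "skip": list(config.skip),
        "stages": {},
        "outputs": {},
    }

    matrices = [read_matrix_dir(d) for d in config.sample_dirs]
    matrix = concat_matrices(matrices)
    norm = None
    annotations = None

    # --- QC -------------------------------------------------------------
    if "qc" not in config.skip:
        with _timed(report, "qc"):
            cfg = qc.QCConfig(**config.qc)
            before = matrix
            matrix = qc.filter_high_mito(matrix, cfg)
            summary = qc.qc_summary(before, matrix)
            summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
            report["outputs"]["qc"] = str(out / "qc_summary.tsv")
            report["stages"]["qc"].update(
                {"params": asdict(cfg), "cells_before": before.n_cells, "cells_after": matrix.n_cells}
            )
    norm = qc.lognormalize(matrix, qc.QCConfig(**config.qc))

    # --- typing ----------------------------------------------------------
    if "typing" not in config.skip:
        with _timed(report, "typing"):
            params = dict(config.typing)
            n_clusters = params.pop("n_clusters", 10)
            clusters = cell_typing.cluster_cells(
                norm, n_clusters=n_clusters, seed=stage_seed(config.seed, "typing")
            )
            scores = cell_typing.score_cell_types(norm, matrix.gene_symbols)
            mapping = cell_typing.annotate_clusters(scores, clusters)
            major = np.array([mapping[c] for c in clusters], dtype=object)
            subtype = cell_typing.classify_epithelial(matrix, major == "epithelial")
            annotations = cell_typing.annotation_table(matrix, clusters, mapping, subtype)
            annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
            cell_typing.major_type_summary(annotations).to_csv(
                out / "type_summary.tsv", sep="\t", index=False
            )
            report["outputs"]["typing"] = str(out / "annotations.tsv")
            report["stages"]["typing"].update({"n_clusters": n_clusters})

    # --- DE ---------------------------------------------------------------
    de_result = None
    if "de" not in config.skip:
        with _timed(report, "de"):
            est = diffexpr.ModeratedTTest(**config.de)
            # cells x genes on log2 scale
            est.fit((norm / diffexpr.LN2).T, matrix.group_of_cell)
            de_result = diffexpr.de_table(est, matrix.gene_symbols)
            de_result.to_csv(out / "de_table.tsv", sep="\t", index=False)
            diffexpr.ranked_list(de_result).to_csv(
                out / "ranked.rnk", sep="\t", index=False, header=False
            )
            report["outputs"]["de"] = str(out / "de_table.tsv")
            report["stages"]["de"].update(
                {
                    "n_up": int((de_result["call"] == "up").sum()),
                    "n_down": int((de_result["call"] == "down").sum()),
                    "prior_d0": est.prior_.d0 if np.isfinite(est.prior_.d0) else "inf",
                    "prior_s0_sq": est.prior_.s0_sq,
                }
            )

    # --- GSEA ---------------------------------------------------------------
    if "gsea" not in config.skip:
        with _timed(report, "gsea"):
            if de_result is None:
                raise RuntimeError("GSEA requires the DE stage (do not skip de)")
            sets = read_gmt(config.gmt_path)
            params = {"n_perm": 1000, **config.gsea}
            results = gsea.gsea_permutation(
                de_result["gene"].tolist(),
                de_result["log2FC"].to_numpy(),
                sets,
                seed=stage_seed(config.seed, "gsea"),
                **params,
            )
            gsea.enrichment_table(results).to_csv(out / "gsea.tsv", sep="\t", index=False)
            report["outputs"]["gsea"] = str(out / "gsea.tsv")
            report["stages"]["gsea"].update({"n_sets": len(results), **params})

    # --- ROE -----------------------------------------------------------------
    if "roe" not in config.skip:
        with _timed(report, "roe"):
            params = dict(config.roe)
            markers = tuple(params.pop("markers", roe.EMT_TF_PANEL))
            if annotations is not None:
                fib = (annotations["major_type"] == "fibroblast").to_numpy()
                target = matrix.subset_cells(fib) if fib.any() else matrix
            else:
                target = matrix
            results = roe.roe_panel(target, markers, **params)
            roe.roe_table(results).to_csv(out / "roe.tsv", sep="\t", index=False)
            report["outputs"]["roe"] = str(out / "roe.tsv")
            report["stages"]["roe"].update({"markers": list(markers)})

    # --- similarity ----------------------------------------------------------
    if "similarity" not in config.skip:
        with _timed(report, "similarity"):
            params = {"seed": stage_seed(config.seed, "similarity"), **config.similarity}
            ref_counts, ref_labels, ref_symbols = generate_reference(
                CohortConfig(), seed=stage_seed(config.seed, "similarity_ref")
            )
            shared = [g for g in ref_symbols if g in set(matrix.gene_symbols)]
            sym_to_row = {s: i for i, s in enumerate(matrix.gene_symbols)}
            ref_idx = {s: i for i, s in enumerate(ref_symbols)}
            rows = [sym_to_row[g] for g in shared]
            ref_cols = [ref_idx[g] for g in shared]
            ref_norm = np.log1p(
                ref_counts[:, ref_cols]
                / np.maximum(ref_counts.sum(axis=1, keepdims=True), 1)
                * 1e4
            )
            scorer = similarity.MNNSimilarityScorer(**params)
            scorer.fit(ref_norm, ref_labels)
            if annotations is not None:
                epi = (annotations["major_type"] == "epithelial").to_numpy()
            else:
                epi = np.ones(matrix.n_cells, dtype=bool)
            query = np.asarray(norm[rows][:, np.flatnonzero(epi)].todense()).T
            if annotations is not None:
                q_clusters = annotations.loc[epi, "cluster"].to_numpy()
            else:
                q_clusters = np.zeros(int(epi.sum()), dtype=int)
            sim = scorer.transform(query, q_clusters)
            similarity.similarity_table(sim).to_csv(out / "similarity.tsv", sep="\t", index=False)
            report["outputs"]["similarity"] = str(out / "similarity.tsv")
            report["stages"]["similarity"].update({"total_pairs": sim.total_pairs})

    # --- TCR ------------------------------------------------------------------
    if "tcr" not in config.skip:
        with _timed(report, "tcr"):
            params = dict(config.tcr)
            key = params.pop("clonotype_key", "cdr3_aa")
            contigs = []
            for d in config.sample_dirs:
                f = Path(d) / "filtered_contig_annotations.csv"
                if f.exists():
                    contigs.extend(read_contigs(f))
            if not contigs:
                raise FileNotFoundError("no filtered_contig_annotations.csv under sample dirs")
            paired = tcr.select_paired_cells(contigs)
            clonotypes = tcr.assign_clonotypes(paired, key=key)
            barcode_to_group = dict(zip(matrix.barcodes, matrix.group_of_cell))
            clonotypes = clonotypes[clonotypes["barcode"].isin(barcode_to_group)].reset_index(
                drop=True
            )
            clonotypes["group"] = [barcode_to_group[b] for b in clonotypes["barcode"]]
            # clonality statistics are computed on CD8+ cells, as paired-TCR
            # cells are T cells by construction
            col_of = {b: i for i, b in enumerate(matrix.barcodes)}
            tcr_cols = np.array([col_of[b] for b in clonotypes["barcode"]])
            t_mask = np.zeros(matrix.n_cells, dtype=bool)
            t_mask[tcr_cols] = True
            cd8 = tcr.cd8_mask(matrix, t_mask)
            clonotypes["cd8"] = cd8[tcr_cols]
            clonotypes.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
            cd8_clono = clonotypes[clonotypes["cd8"]]
            cont = tcr.clonality_contingency(
                cd8_clono["clonal"].to_numpy(), cd8_clono["group"].to_numpy()
            )
            exhaustion = tcr.exhaustion_analysis(matrix, norm, clonotypes, cell_mask=cd8)
            exhaustion.to_csv(out / "exhaustion.tsv", sep="\t", index=False)
            report["outputs"]["tcr"] = str(out / "clonotypes.tsv")
            report["stages"]["tcr"].update(
                {
                    "n_paired": int(len(clonotypes)),
                    "chi2": cont["chi2"],
                    "p": cont["p"],
                    "clonal_percent": cont["clonal_percent"],
                }
            )

    report["n_completed"] = sum(
        1 for s in report["stages"].values() if s.get("status") == "completed"
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
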