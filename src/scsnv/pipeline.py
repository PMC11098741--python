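"""End-to-end orchestration: simulate -> germline -> de novo -> somatic -> evaluate.

The pipeline mirrors the calling workflow: candidate scanning and genotype
likelihoods from pooled evidence, panel-based refinement (chunked over the
genome with an overlap margin so chunked and unchunked runs merge to
identical call sets), sequencing-error modelling from refinement
discordances, depth/BAF and SVM filtering of de novo candidates, and
cell-population LD refinement of the survivors. All randomness derives
from a single seed recorded, with every parameter, in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .error_model import SequencingErrorModel, discordance_category
from .genolike import genotype_likelihoods_from_counts
from .ld_refine import (
    DEFAULT_BIN_EDGES,
    CellAlleleMatrix,
    LDRefinementScorer,
)
from .panel_refine import PanelGenotypeRefiner, consensus_calls
from .simulate import (
    SomaticSite,
    clone_population,
    simulate_cells,
    simulate_panel,
    simulate_sample,
)
from .svm_filter import build_training_sets, classify_denovo, site_features

logger = logging.getLogger("scsnv")

__all__ = ["PipelineConfig", "run_pipeline"]


def _default_sim() -> dict:
    return {
        "n_hap": 40,
        "n_sites": 400,
        "span_bp": 400_000,
        "recomb_intensity": 1e-5,
        "maf_min": 0.05,
        "expected_breakpoints": 2.0,
        "n_cells": 100,
        "clone_fractions": [0.7, 0.3],
        "n_somatic": 4,
        "mean_depth": 2.0,
        "dropout": 0.1,
        "error_rate": 1e-3,
        "read_len": 100,
        "zero_inflation": 0.3,
        "artifact_clusters": 2,
        "artifact_sites_per_cluster": 4,
        "emit_pileups": True,
    }


@dataclass
class PipelineConfig:
    """All pipeline stages, defaults and paths in one place."""

    outdir: str = "scsnv_run"
    seed: int = 0
    # stage toggles
    stage_simulate: bool = True
    stage_germline: bool = True
    stage_denovo: bool = True
    stage_somatic: bool = True
    stage_evaluate: bool = True
    # read filtering defaults
    max_mismatch: int = 4
    min_mapq: int = 20
    # de novo filtering
    min_depth: int = 100
    svm_prob: float = 0.5
    svm_chunk_size: int = 50_000
    # somatic scoring
    ps_threshold: float = 0.25
    cap2: float = 100.0
    cap3: float = 10_000.0
    bin_edges: list = field(default_factory=lambda: DEFAULT_BIN_EDGES.tolist())
    # panel refinement
    theta: float = 1e-3
    rho_scale: float = 100_000.0
    count_error_rate: float = 1e-3
    # chunked execution
    n_chunks: int = 1
    chunk_overlap_bp: int = 500_000
    # synthetic data
    sim: dict = field(default_factory=_default_sim)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def parameter_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_stage(config: PipelineConfig):
    sim = dict(_default_sim(), **config.sim)
    seed = config.seed
    panel = simulate_panel(
        n_hap=sim["n_hap"], n_sites=sim["n_sites"], span_bp=sim["span_bp"],
        recomb_intensity=sim["recomb_intensity"], maf_min=sim["maf_min"],
        seed=seed,
    )
    sample = simulate_sample(panel, sim["expected_breakpoints"], seed=seed + 1)
    clones = clone_population(sim["clone_fractions"], sim["n_cells"], seed=seed + 2)
    # somatic sites in gaps between panel sites, away from existing loci
    rng = np.random.default_rng(seed + 3)
    gaps = np.argsort(np.diff(panel.positions))[::-1]
    somatic = []
    n_clones = len(sim["clone_fractions"])
    for i in range(sim["n_somatic"]):
        g = int(gaps[i % len(gaps)])
        pos = int((panel.positions[g] + panel.positions[g + 1]) // 2) + i
        somatic.append(
            SomaticSite(pos=pos, carrier_hap=1 + i % 2, clone=1 + i % max(n_clones - 1, 1))
        )
    artifact_spec = None
    if sim["artifact_clusters"]:
        artifact_spec = {
            "n_clusters": sim["artifact_clusters"],
            "sites_per_cluster": sim["artifact_sites_per_cluster"],
            "cell_fraction": 0.3,
        }
    dataset = simulate_cells(
        sample, clones, somatic,
        mean_depth=sim["mean_depth"], dropout=sim["dropout"],
        error_rate=sim["error_rate"], read_len=sim["read_len"],
        zero_inflation=sim["zero_inflation"], seed=seed + 4,
        emit_pileups=sim["emit_pileups"], artifact_spec=artifact_spec,
    )
    return panel, sample, dataset


def _chunk_bounds(positions: np.ndarray, n_chunks: int) -> list[tuple[int, int]]:
    lo, hi = int(positions[0]), int(positions[-1]) + 1
    edges = np.linspace(lo, hi, n_chunks + 1).astype(np.int64)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_chunks)]


def _refine_chunked(
    gl_log: np.ndarray,
    panel,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Chunked forward-backward refinement over all panel sites.

    Each chunk is refined together with the panel sites inside an overlap
    margin on both flanks; only core-chunk results are kept, which makes
    the merged result invariant to the chunking (the margin defaults to
    the largest profile bin edge, far beyond the switching scale).
    """
    positions = panel.positions
    n_sites = len(positions)
    gp = np.empty((n_sites, 3))
    phase = np.empty(n_sites)
    refiner = PanelGenotypeRefiner(theta=config.theta, rho_scale=config.rho_scale)
    refiner.fit(panel.haplotypes, positions)
    for lo, hi in _chunk_bounds(positions, max(config.n_chunks, 1)):
        core = (positions >= lo) & (positions < hi)
        if not core.any():
            continue
        ctx = (positions >= lo - config.chunk_overlap_bp) & (
            positions < hi + config.chunk_overlap_bp
        )
        idx = np.nonzero(ctx)[0]
        gps = refiner.transform(gl_log[idx], site_indices=idx)
        keep = core[idx]
        gp[np.nonzero(core)[0]] = np.vstack([t.probs for t in gps])[keep]
        phase[np.nonzero(core)[0]] = refiner.phase_posteriors_[keep]
        logger.info("germline chunk [%d, %d): %d sites (seed %d)", lo, hi, keep.sum(), config.seed)
    return gp, phase


def run_pipeline(config: PipelineConfig, dataset=None, panel=None, sample=None) -> dict:
    """Execute the configured stages; returns the in-memory results.

    A pre-built simulation (``dataset``/``panel``/``sample``) may be
    passed instead of running the simulate stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.parameter_hash()}

    if config.stage_simulate:
        panel, sample, dataset = _simulate_stage(config)
        sio.write_panel_vcf(panel, out / "panel.vcf")
        sio.write_matrix_tsv(dataset.matrix, out / "cells")
    if dataset is None or panel is None or sample is None:
        raise ValueError("no input data: enable stage_simulate or pass a dataset")
    results["dataset"] = dataset

    germ_rows = np.nonzero(dataset.truth["germline_site_mask"])[0]
    n_ref = dataset.ref_counts[germ_rows].sum(axis=1)
    n_alt = dataset.alt_counts[germ_rows].sum(axis=1)

    error_model = None
    germline_records = []
    if config.stage_germline:
        gl_log = np.vstack(
            [
                genotype_likelihoods_from_counts(
                    int(r), int(a), config.count_error_rate
                ).log_likelihoods
                for r, a in zip(n_ref, n_alt)
            ]
        )
        gp, phase_post = _refine_chunked(gl_log, panel, config)
        gls = [genotype_likelihoods_from_counts(int(r), int(a), config.count_error_rate)
               for r, a in zip(n_ref, n_alt)]
        from .panel_refine import GPTriplet

        gps = [GPTriplet(row) for row in gp]
        germline, error_loci = consensus_calls(gls, gps, phase_post)
        pooled_depth = n_ref + n_alt
        error_pairs = []
        for call in error_loci:
            m = germ_rows[call.site_index]
            baf = (
                dataset.alt_counts[m].sum() / pooled_depth[call.site_index]
                if pooled_depth[call.site_index]
                else 0.0
            )
            cat = discordance_category(
                (dataset.ref_alleles[m], dataset.alt_alleles[m]),
                dataset.ref_alleles[m],  # refined to homozygous reference
            )
            error_pairs.append((cat, float(baf)))
        error_model = SequencingErrorModel(min_depth=config.min_depth).fit(error_pairs)
        sio.write_error_model_tsv(error_model, out / "error_model.tsv")

        for call in germline:
            m = germ_rows[call.site_index]
            germline_records.append(
                {
                    "pos": int(dataset.positions[m]),
                    "ref": dataset.ref_alleles[m],
                    "alt": dataset.alt_alleles[m],
                    "genotype": call.genotype_refined,
                    "gp": call.gp.probs,
                    "status": call.status.value,
                    "phased": bool(call.p_alt_on_hap1 >= 0.5),
                    "site_row": int(m),
                }
            )
        sio.write_germline_vcf(
            out / "germline.vcf", dataset.matrix.chrom,
            [r for r in germline_records if r["genotype"] > 0],
            contig_len=int(dataset.positions[-1]) + 1,
        )
        results["germline_calls"] = germline_records
        results["error_model"] = error_model
        results["raw_genotypes"] = np.array([g.argmax() for g in gls])
        results["refined_genotypes"] = np.array([g.argmax() for g in gps])

    denovo_rows = np.nonzero(~dataset.truth["germline_site_mask"])[0]
    retained_rows = []
    if config.stage_denovo and error_model is not None and len(denovo_rows):
        depth = dataset.ref_counts[denovo_rows].sum(axis=1) + dataset.alt_counts[
            denovo_rows
        ].sum(axis=1)
        baf = np.divide(
            dataset.alt_counts[denovo_rows].sum(axis=1),
            np.maximum(depth, 1),
        )
        filter_status = {}
        survivors = []
        for i, m in enumerate(denovo_rows):
            res = error_model.predict_site(
                dataset.ref_alleles[m], dataset.alt_alleles[m], int(depth[i]), float(baf[i])
            )
            if res.passed:
                survivors.append(m)
            else:
                filter_status[int(m)] = res.reason
        # SVM: positives = germline calls, negatives from consecutive chunks
        if dataset.pileups is not None and survivors:
            pile_by_pos = {p.pos: p for p in dataset.pileups}
            germ_positions = sorted(
                r["pos"] for r in germline_records if r["genotype"] > 0
            )
            surv_positions = [int(dataset.positions[m]) for m in survivors]
            try:
                tset = build_training_sets(
                    germ_positions, surv_positions, chunk_size=config.svm_chunk_size
                )
            except ValueError as exc:
                logger.warning("SVM stage skipped: %s", exc)
                tset = None
            if tset is None:
                retained_rows = survivors
            else:
                X_pos = np.array([
                    site_features(pile_by_pos[p]) for p in germ_positions
                ])
                X_neg = np.array([
                    site_features(pile_by_pos[surv_positions[i]]) for i in tset.negatives
                ])
                test_rows = [survivors[i] for i in tset.test]
                retained_rows = []
                if test_rows:
                    X_test = np.array([
                        site_features(pile_by_pos[int(dataset.positions[m])]) for m in test_rows
                    ])
                    probs, keep = classify_denovo(
                        X_pos, X_neg, X_test,
                        prob_threshold=config.svm_prob, random_state=config.seed,
                    )
                    for m, k in zip(test_rows, keep):
                        if k:
                            retained_rows.append(m)
                        else:
                            filter_status[int(m)] = "svm_fail"
                for i in tset.negatives:
                    filter_status[int(survivors[i])] = "svm_fail"
        else:
            retained_rows = survivors
        results["denovo_retained_rows"] = retained_rows
        results["denovo_filter_status"] = filter_status

    if config.stage_somatic and germline_records and retained_rows:
        matrix = _build_matrix(dataset, germline_records, retained_rows)
        scorer = LDRefinementScorer(
            bin_edges=np.asarray(config.bin_edges, float),
            cap2=config.cap2, cap3=config.cap3, ps_threshold=config.ps_threshold,
        )
        scorer.fit(matrix)
        calls = scorer.predict(matrix)
        sio.write_profile_tsv(scorer.profile_, out / "ld_profile.tsv")
        alleles = {
            c.site_index: (
                matrix.allele1[c.site_index], matrix.allele2[c.site_index]
            )
            for c in calls
        }
        sio.write_denovo_vcf(
            out / "somatic.vcf", matrix.chrom, calls, alleles,
            contig_len=int(dataset.positions[-1]) + 1,
        )
        results["somatic_calls"] = calls
        results["ld_profile"] = scorer.profile_
        results["somatic_matrix"] = matrix

    if config.stage_evaluate and germline_records:
        from .evaluate import benchmark

        chrom = dataset.matrix.chrom
        truth_g = dataset.truth["germline_genotypes"]
        calls_map = {
            (chrom, r["pos"], r["ref"], r["alt"]): r["genotype"]
            for r in germline_records
        }
        truth_map = {
            (chrom, int(dataset.positions[m]), dataset.ref_alleles[m], dataset.alt_alleles[m]):
            int(truth_g[m])
            for m in germ_rows
        }
        report = benchmark(calls_map, truth_map)
        results["benchmark"] = report
        sio.write_manifest(
            out / "report.json",
            sensitivity=report.sensitivity,
            precision=report.precision,
            genotype_accuracy=report.genotype_accuracy,
            overall_accuracy=report.overall_accuracy,
        )

    sio.write_manifest(
        out / "manifest.json",
        seed=config.seed,
        parameter_hash=config.parameter_hash(),
        config=dataclasses.asdict(config),
    )
    return results


def _build_matrix(dataset, germline_records, retained_rows) -> CellAlleleMatrix:
    """Cell-allele matrix from refined (phased) het calls + retained de novo rows."""
    rows = []
    for r in germline_records:
        if r["genotype"] == 1:
            rows.append((r["site_row"], True, r["phased"]))
    for m in retained_rows:
        rows.append((int(m), False, False))
    rows.sort()
    n_cells = dataset.ref_counts.shape[1]
    c1 = np.empty((len(rows), n_cells), dtype=np.int32)
    c2 = np.empty_like(c1)
    phased = np.zeros(len(rows), dtype=bool)
    a1, a2 = [], []
    positions = []
    for i, (m, is_germ, alt_on_hap1) in enumerate(rows):
        positions.append(int(dataset.positions[m]))
        if is_germ and alt_on_hap1:
            c1[i], c2[i] = dataset.alt_counts[m], dataset.ref_counts[m]
            a1.append(dataset.alt_alleles[m]); a2.append(dataset.ref_alleles[m])
        else:
            c1[i], c2[i] = dataset.ref_counts[m], dataset.alt_counts[m]
            a1.append(dataset.ref_alleles[m]); a2.append(dataset.alt_alleles[m])
        phased[i] = is_germ
    return CellAlleleMatrix(
        positions=np.array(positions), c1=c1, c2=c2, phased=phased,
        chrom=dataset.matrix.chrom, allele1=a1, allele2=a2,
        cell_ids=dataset.matrix.cell_ids,
    )
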