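"""End-to-end orchestration: generate/ingest -> preprocess -> classify ->
fit -> motif -> enrich, with provenance and deterministic reruns.

A run directory receives each stage's tabular outputs plus a machine-readable
``summary.json`` (group counts, per-gene verdicts and weight signs, spacer
tallies, enrichment table).  The effective configuration is serialized into
the run directory, and a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import enrichment_stats as es
from . import expression_profiles as ep
from . import kinetic_model as km
from . import motif_tools as mt
from . import synthetic_data as sd
from .errors import ParameterError

logger = logging.getLogger("sigrekin")

FOCAL_CLASS = "Periplasmic/exported/lipoproteins"


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; schema-validated before any stage runs."""

    mode: str = "synthetic"          # "synthetic" | "user"
    seed: int = 0

    # synthetic cohort sizes
    n_sigE: int = 8
    n_hrdB: int = 5
    n_flat: int = 4
    n_repressed: int = 3
    n_genome: int = 2000             # annotation universe size

    # synthetic data regimes
    noise_sd_log2: float = 0.2
    gc_content: float = 0.72
    n_sequences: int = 100
    seq_length: int = 100
    planting_rate: float = 0.9

    # preprocessing
    sg_window: int = ep.DEFAULT_SG_WINDOW
    sg_polyorder: int = ep.DEFAULT_SG_POLYORDER
    resample_minutes: float = ep.DEFAULT_RESAMPLE_MINUTES

    # classification
    r_threshold: float = ep.DEFAULT_R_THRESHOLD
    flat_threshold: float = ep.DEFAULT_FLAT_THRESHOLD

    # kinetic fitting
    n_restarts: int = 64
    nsse_threshold: float = 0.2

    # motif scanning
    p_threshold: float = mt.DEFAULT_P_THRESHOLD
    granularity: float = mt.DEFAULT_GRANULARITY_BITS
    motif_source: str = "known"      # "known" | "discover"

    # enrichment
    focal_class: str = FOCAL_CLASS
    focal_class_fraction: float = 0.168

    # user-data inputs (mode == "user")
    expression_tsv: str | None = None
    sigE_id: str = "sigE"
    hrdB_id: str = "hrdB"
    promoter_fasta: str | None = None
    annotation_tsv: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode == "user":
            for name in ("expression_tsv", "promoter_fasta", "annotation_tsv"):
                if getattr(self, name) is None:
                    raise ParameterError(f"user mode requires {name}")
        if self.motif_source not in ("known", "discover"):
            raise ParameterError(f"unknown motif_source {self.motif_source!r}")
        if self.n_restarts < 1:
            raise ParameterError("n_restarts must be >= 1")
        # delegate range checks on the shared generator knobs
        self.simulation_config()

    def simulation_config(self) -> sd.SimulationConfig:
        return sd.SimulationConfig(
            master_seed=self.seed,
            noise_sd_log2=self.noise_sd_log2,
            gc_content=self.gc_content,
            n_sequences=self.n_sequences,
            seq_length=self.seq_length,
            planting_rate=self.planting_rate,
        )

    def fit_config(self) -> km.FitConfig:
        return km.FitConfig(nsse_threshold=self.nsse_threshold)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name, so a
    stage can be rerun in isolation with the same stream."""
    import zlib

    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0] % (2**31)
    )


def _preprocess(profiles, config: PipelineConfig):
    return [
        ep.preprocess_profile(
            p, window=config.sg_window, polyorder=config.sg_polyorder,
            interval_minutes=config.resample_minutes,
        )
        for p in profiles
    ]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    t_start = time.time()
    summary: dict = {"mode": config.mode, "seed": config.seed}

    # -- stage 1: generate or ingest -------------------------------------
    simcfg = config.simulation_config()
    if config.mode == "synthetic":
        logger.info("stage simulate: cohort + promoters + annotations")
        regulators, gene_profiles, truth = sd.generate_cohort(
            simcfg,
            n_sigE=config.n_sigE, n_hrdB=config.n_hrdB,
            n_flat=config.n_flat, n_repressed=config.n_repressed,
            seed=stage_seed(config.seed, "cohort"),
        )
        motifs = sd.default_composite_motifs(config.gc_content)
        seqs, site_truth = sd.generate_promoter_set(
            simcfg, motifs, seed=stage_seed(config.seed, "promoters")
        )
        truth = truth.merge(site_truth)
        gene_ids = [p.gene_id for p in gene_profiles]
        filler = [f"GENOME{i:05d}" for i in range(config.n_genome - len(gene_ids))]
        annotations = sd.generate_annotation_table(
            config.n_genome,
            {config.focal_class: config.focal_class_fraction},
            seed=stage_seed(config.seed, "annotations"),
            gene_ids=gene_ids + filler,
        )
        # persist generated inputs
        sigE_log = ep.log_expression(regulators["sigE"])
        hrdB_log = ep.log_expression(regulators["hrdB"])
        ep.write_expression_tsv([sigE_log, hrdB_log] + gene_profiles,
                                outdir / "expression.tsv")
        mt.write_fasta(seqs, outdir / "promoters.fasta")
        es.write_annotation_tsv(annotations, outdir / "annotations.tsv")
        sd.write_ground_truth_tsv(truth, outdir / "truth_genes.tsv",
                                  outdir / "truth_sites.tsv")
        sigE_raw, hrdB_raw = sigE_log, hrdB_log
    else:
        logger.info("stage ingest: reading user inputs")
        all_profiles = ep.read_expression_tsv(config.expression_tsv)
        by_id = {p.gene_id: p for p in all_profiles}
        for rid in (config.sigE_id, config.hrdB_id):
            if rid not in by_id:
                raise ParameterError(f"regulator {rid!r} not in expression table")
        sigE_raw = by_id.pop(config.sigE_id)
        hrdB_raw = by_id.pop(config.hrdB_id)
        gene_profiles = list(by_id.values())
        seqs = mt.read_fasta(config.promoter_fasta)
        annotations = es.read_annotation_tsv(config.annotation_tsv)
        motifs = None

    # -- stage 2: preprocess ----------------------------------------------
    logger.info("stage preprocess: delog -> smooth -> resample (%g min grid)",
                config.resample_minutes)
    sigE, hrdB = _preprocess([sigE_raw, hrdB_raw], config)
    genes = _preprocess(gene_profiles, config)
    ep.write_expression_tsv([sigE, hrdB] + genes, outdir / "preprocessed.tsv")

    # -- stage 3: classify -------------------------------------------------
    logger.info("stage classify: correlation grouping of %d genes", len(genes))
    assignments = [
        ep.assign_group(g, sigE, hrdB,
                        r_threshold=config.r_threshold,
                        flat_threshold=config.flat_threshold)
        for g in genes
    ]
    ep.write_group_assignments(assignments, outdir / "groups.tsv")
    group_counts = {g.value: 0 for g in ep.Group}
    for a in assignments:
        group_counts[a.group.value] += 1
    summary["groups"] = group_counts

    # -- stage 4: kinetic fits ----------------------------------------------
    # group A fits against the ECF sigma factor, group B against HrdB;
    # "other" profiles (e.g. anti-correlated candidates for repression) are
    # fitted against the ECF factor with an unconstrained signed weight.
    logger.info("stage fit: %d restarts per gene", config.n_restarts)
    fit_rows = []
    fits: dict[str, km.KineticFit] = {}
    by_gene = {g.gene_id: g for g in genes}
    for a in assignments:
        if a.group is ep.Group.C_FLAT:
            continue
        regulator = hrdB if a.group is ep.Group.B_HRDB else sigE
        fit = km.fit_single_regulator(
            by_gene[a.gene_id], regulator,
            n_restarts=config.n_restarts,
            master_seed=stage_seed(config.seed, f"fit:{a.gene_id}"),
            config=config.fit_config(),
        )
        fits[a.gene_id] = fit
        fit_rows.append({
            "gene_id": a.gene_id, "group": a.group.value,
            "regulator": regulator.gene_id,
            "k1": fit.params.k1, "k2": fit.params.k2, "b": fit.params.b,
            "w": fit.params.w[0], "sse": fit.sse,
            "normalized_sse": fit.normalized_sse, "verdict": fit.verdict.value,
        })
    pd.DataFrame(fit_rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)
    summary["fits"] = {
        r["gene_id"]: {
            "regulator": r["regulator"], "w": r["w"],
            "normalized_sse": r["normalized_sse"], "verdict": r["verdict"],
        }
        for r in fit_rows
    }
    summary["negative_w_genes"] = sorted(
        r["gene_id"] for r in fit_rows
        if r["w"] < 0 and r["verdict"] == "regulation_possible"
    )

    # -- stage 5: motif scan -------------------------------------------------
    logger.info("stage motif: scanning %d sequences", len(seqs))
    if config.motif_source == "discover" or motifs is None:
        motifs = derive_composite_motifs(
            seqs, seed=stage_seed(config.seed, "discover")
        )
    hits = mt.scan_sequences(
        list(motifs.values()), seqs,
        p_threshold=config.p_threshold, granularity=config.granularity,
    )
    best_per_seq = mt.dedupe_overlapping(hits)
    # one retained site per sequence for the tally: the lowest-p hit
    per_seq_best = {}
    for h in best_per_seq:
        cur = per_seq_best.get(h.seq_id)
        if cur is None or mt._hit_rank(h) < mt._hit_rank(cur):
            per_seq_best[h.seq_id] = h
    tally = mt.tally_spacers(list(per_seq_best.values()))
    mt.write_hits_tsv(hits, outdir / "hits.tsv")
    summary["n_hits"] = len(hits)
    summary["n_sequences_with_hit"] = len(per_seq_best)
    summary["spacer_tally"] = {str(k): v for k, v in sorted(tally.items())}

    # -- stage 6: enrichment ---------------------------------------------------
    logger.info("stage enrich: group A functional classes")
    group_a = es.GeneSet(
        "group_A",
        {a.gene_id for a in assignments if a.group is ep.Group.A_SIGE},
    )
    if len(group_a) > 0:
        rows = es.enrichment_report(group_a, annotations)
        es.write_enrichment_tsv(rows, outdir / "enrichment.tsv")
        summary["enrichment"] = [
            {"class": r.cls, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
             "fold": r.fold, "p": r.p_value}
            for r in rows
        ]
    else:
        summary["enrichment"] = []

    summary["runtime_seconds"] = round(time.time() - t_start, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline done in %.1f s", summary["runtime_seconds"])
    return summary


def derive_composite_motifs(
    seqs: Mapping[str, str],
    width10: int = 6,
    width35: int = 4,
    upstream_offset: int = 23,
    segment_length: int = 10,
    spacers=(16, 17, 18, 19),
    seed: int = 0,
) -> dict[int, mt.CompositeMotif]:
    """Derive a bipartite motif family from summit-window sequences.

    Discovers the -10 half-site with ZOOPS-EM on both strands, extracts the
    10 bp segments starting 23 bp upstream of confident -10 sites, discovers
    the -35 half-site in them (single strand: segments are already oriented),
    and joins the halves across each spacer length.

    A discovered motif's orientation is arbitrary (the EM may converge to the
    reverse complement).  Both orientations of the -10 are therefore tried —
    only one places a conserved -35 element inside the upstream segments — and
    the orientation whose -35 model gains the most likelihood per segment over
    the pure-background model is kept.
    """
    res10 = mt.discover_motif_zoops(seqs, width10, revcomp_scan=True, seed=seed)

    best = None
    for flip in (False, True):
        pwm10 = res10.pwm.reverse_complement() if flip else res10.pwm
        sites = {}
        for sid, (pos, strand, prob) in res10.sites.items():
            if prob <= 0.5:
                continue
            if flip:
                strand = "-" if strand == "+" else "+"
            sites[sid] = (pos, strand)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segments = mt.extract_upstream_segments(
                seqs, sites, site_width=width10,
                offset=upstream_offset, length=segment_length,
            )
        if len(segments) < 2:
            continue
        res35 = mt.discover_motif_zoops(
            segments, width35, revcomp_scan=False, seed=seed + 1
        )
        gain = res35.ll_gain / len(segments)
        if best is None or gain > best[0]:
            best = (gain, res35.pwm, pwm10)
    if best is None:
        raise ParameterError("too few -10 sites to derive a -35 element")
    _, pwm35, pwm10 = best
    return {s: mt.build_composite_motif(pwm35, pwm10, s) for s in spacers}


def make_fixtures(seed: int, outdir) -> dict:
    """Write the small packaged test dataset (deterministic given the seed).

    20 genes x 32 time points (plus the two regulator rows), 50 promoter
    sequences of 100 bp, and a 500-gene annotation table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(
        seed=seed, n_sigE=8, n_hrdB=5, n_flat=4, n_repressed=3,
        n_sequences=50, n_genome=500,
    )
    simcfg = config.simulation_config()
    regulators, profiles, truth = sd.generate_cohort(
        simcfg, n_sigE=8, n_hrdB=5, n_flat=4, n_repressed=3,
        seed=stage_seed(seed, "cohort"),
    )
    seqs, site_truth = sd.generate_promoter_set(
        simcfg, sd.default_composite_motifs(config.gc_content),
        seed=stage_seed(seed, "promoters"),
    )
    annotations = sd.generate_annotation_table(
        500, {FOCAL_CLASS: 0.168}, seed=stage_seed(seed, "annotations"),
        gene_ids=[p.gene_id for p in profiles]
                 + [f"GENOME{i:05d}" for i in range(500 - len(profiles))],
    )
    ep.write_expression_tsv(
        [ep.log_expression(regulators["sigE"]), ep.log_expression(regulators["hrdB"])]
        + profiles,
        outdir / "expression.tsv",
    )
    mt.write_fasta(seqs, outdir / "promoters.fasta")
    es.write_annotation_tsv(annotations, outdir / "annotations.tsv")
    sd.write_ground_truth_tsv(truth.merge(site_truth),
                              outdir / "truth_genes.tsv",
                              outdir / "truth_sites.tsv")
    config.to_yaml(outdir / "config.yaml")
    return {"n_genes": len(profiles), "n_sequences": len(seqs)}
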