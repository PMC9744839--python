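"""Pipeline orchestration: config, stage sequencing, run manifest.

``run_pipeline`` executes the stages in dependency order into a run
directory and records a manifest with the config hash and a SHA-256
checksum of every file written, so identical (config, seed) runs can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._stats import bh_adjust
from .cancer import call_frequent_events, overlap_enrichment, stage_stratified_enrichment
from .domains import map_domains_to_exons, merge_domain_intervals, test_domain_enrichment
from .exons import classify_exons, correlate_exon_pathways
from .pathways import classify_embryonic_pathways, score_pathway_activity, smooth_activity_pca
from .psi import write_events
from .regulators import (
    call_csfs,
    compare_effect_coefficients,
    compare_knockdown_fractions,
    filter_nonsense,
    fit_plsr,
    knockdown_response,
    mutation_effect,
    predict_median_ep,
)
from .simulate import SimConfig, Simulator
from .tf import chip_filter, combine_filters, correlation_filter, knockdown_filter, network_filter

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_to_dir"]

_KNOWN_KEYS = {"simulate", "sim", "inputs", "outdir", "seed", "thresholds"}
_KNOWN_THRESHOLDS = {
    "min_total_tpm", "fdr", "pos_frac", "neg_frac", "rule",
    "sd_mult", "min_frac", "csf_alpha", "top_k", "mutation_delta",
    "mutation_sd_max", "min_kd", "dpsi_cut",
}


@dataclasses.dataclass
class PipelineConfig:
    simulate: bool = True
    sim: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    outdir: str = "run"
    seed: int = 0
    thresholds: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - _KNOWN_THRESHOLDS
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(**{**self.sim, "seed": self.seed})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_to_dir(cfg: SimConfig, outdir: Path) -> dict[str, Path]:
    """Generate every synthetic input and write it as plain text."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = Simulator(cfg)
    dev = sim.development()
    truth = dev.truth
    can = sim.cancer(truth)
    ann = sim.annotation(truth)
    reg = sim.regulatory(truth)

    paths: dict[str, Path] = {}

    def put(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = path

    put("dev_expression.tsv", lambda p: io.write_matrix(dev.expr, p, "gene"))
    put("dev_psi.tsv", lambda p: io.write_matrix(dev.psi, p, "event"))
    put("dev_samples.tsv", lambda p: dev.meta.to_csv(p, sep="\t"))
    put("pathways.gmt", lambda p: io.write_gmt(dev.pathways, p))
    put("cancer_expression.tsv", lambda p: io.write_matrix(can.expr, p, "gene"))
    put("cancer_psi.tsv", lambda p: io.write_matrix(can.psi, p, "event"))
    put("cancer_samples.tsv", lambda p: can.meta.to_csv(p, sep="\t"))
    put("mutations.tsv", lambda p: can.mutations.to_csv(p, sep="\t", index=False))
    put("cnv.tsv", lambda p: io.write_matrix(can.cnv, p, "gene"))
    put("events.tsv", lambda p: write_events(ann.events, p))
    put("exons.bed", lambda p: io.write_bed(ann.exon_bed, p))
    put("domains.bed", lambda p: io.write_bed(ann.domain_bed, p))
    put("tss.tsv", lambda p: ann.tss.to_csv(p, sep="\t", index=False))
    put("tf_binding.gmt", lambda p: io.write_gmt(reg.binding, p))
    put("tf_knockdown.gmt", lambda p: io.write_gmt(reg.knockdown_sets, p))
    put("tf_expression.tsv", lambda p: io.write_matrix(reg.tf_expr, p, "tf"))
    put("kd_control_psi.tsv", lambda p: io.write_matrix(reg.assay.control_psi, p, "event"))
    kd_long = pd.concat(
        {f: df for f, df in reg.assay.kd_psi.items()}, names=["factor", "event"]
    ).reset_index()
    put("kd_psi.tsv", lambda p: kd_long.to_csv(p, sep="\t", index=False))
    put("kd_expression.tsv", lambda p: reg.assay.kd_expr.to_csv(p, sep="\t"))

    truth_payload = {
        "pathway_labels": truth.pathway_labels,
        "exon_labels": truth.exon_labels,
        "csf_set": sorted(truth.csf_set),
        "driver_weights": truth.driver_weights,
        "neg_regulators": truth.neg_regulators,
        "planted_tf": truth.planted_tf,
        "tf_targets": {k: sorted(v) for k, v in truth.tf_targets.items()},
        "mutated_samples": {k: sorted(v) for k, v in truth.mutated_samples.items()},
        "domain_planted": truth.domain_planted,
    }
    put("ground_truth.json", lambda p: p.write_text(json.dumps(truth_payload, indent=1)))
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    t_start = time.time()
    stage_times: dict[str, float] = {}

    def _tick(name: str) -> None:
        stage_times[name] = round(time.time() - t_start, 3)
        log.info("stage %s done at %.2fs", name, stage_times[name])

    if config.simulate:
        inputs_dir = outdir / "inputs"
        simulate_to_dir(config.sim_config(), inputs_dir)
        _tick("simulate")
    else:
        inputs_dir = None
        for key, path in config.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key!r}: no such file: {path}")

    def _inp(name: str, key: str) -> Path:
        if inputs_dir is not None:
            return inputs_dir / name
        if key not in config.inputs:
            raise FileNotFoundError(f"input {key!r} required when simulate is false")
        return Path(config.inputs[key])

    expr = io.read_matrix(_inp("dev_expression.tsv", "dev_expression"))
    psi = io.read_matrix(_inp("dev_psi.tsv", "dev_psi"))
    meta = io.read_sample_meta(_inp("dev_samples.tsv", "dev_samples"))
    pathways = io.read_gmt(_inp("pathways.gmt", "pathways"))

    # stage: pathway activity + embryonic labels
    activity = score_pathway_activity(expr, pathways)
    smoothed = smooth_activity_pca(activity)
    prenatal = meta.index[meta["stage"] == "prenatal"].tolist()
    labels = classify_embryonic_pathways(smoothed, prenatal)
    io.write_matrix(activity, outdir / "activity.tsv", "pathway")
    io.write_matrix(smoothed.values, outdir / "smoothed_activity.tsv", "pathway")
    pd.Series(labels, name="label").rename_axis("pathway").to_csv(
        outdir / "pathway_labels.tsv", sep="\t"
    )
    _tick("pathways")

    # stage: exon classification
    corr = correlate_exon_pathways(psi, activity, fdr=thr.get("fdr", 0.05))
    exon_table = classify_exons(
        corr,
        labels,
        pos_frac=thr.get("pos_frac", 0.10),
        neg_frac=thr.get("neg_frac", 0.05),
        rule=thr.get("rule", "positive_only"),
    )
    corr.to_long().to_csv(outdir / "exon_pathway_correlations.tsv", sep="\t", index=False)
    exon_table.rename_axis("event").to_csv(outdir / "exon_labels.tsv", sep="\t")
    ep = set(exon_table.index[exon_table["label"] == "EP"])
    en = set(exon_table.index[exon_table["label"] == "EN"])
    _tick("exons")

    # stage: cancer frequent events + enrichment
    can_expr = io.read_matrix(_inp("cancer_expression.tsv", "cancer_expression"))
    can_psi = io.read_matrix(_inp("cancer_psi.tsv", "cancer_psi"))
    can_meta = io.read_sample_meta(_inp("cancer_samples.tsv", "cancer_samples"))
    tumor_ids = can_meta.index[can_meta["cohort"] == "tumor"].tolist()
    normal_ids = can_meta.index[can_meta["cohort"] == "normal"].tolist()
    calls = call_frequent_events(
        can_psi[tumor_ids],
        can_psi[normal_ids],
        sd_mult=thr.get("sd_mult", 2.0),
        min_frac=thr.get("min_frac", 0.15),
    )
    calls.rename_axis("event").to_csv(outdir / "frequent_calls.tsv", sep="\t")
    increased = set(calls.index[calls["call"].isin(["increased", "both"])])
    decreased = set(calls.index[calls["call"].isin(["decreased", "both"])])
    universe = set(calls.index)
    rows = []
    for name, query, ref in (
        ("EP_in_increased", increased, ep),
        ("EN_in_decreased", decreased, en),
    ):
        res = overlap_enrichment(query, ref, universe)
        rows.append(
            {"test": name, "odds_ratio": res.odds_ratio, "p": res.p_value,
             "ci_low": np.exp(res.log_or_ci[0]), "ci_high": np.exp(res.log_or_ci[1])}
        )
    enr = pd.DataFrame(rows)
    enr["q"] = bh_adjust(enr["p"])
    enr.to_csv(outdir / "overlap_enrichment.tsv", sep="\t", index=False)
    stage_enr = stage_stratified_enrichment(
        can_psi[tumor_ids], can_psi[normal_ids], can_meta.loc[tumor_ids, "stage"],
        ep, en, universe,
    )
    stage_enr.to_csv(outdir / "stage_enrichment.tsv", sep="\t", index=False)
    _tick("cancer_events")

    # stage: PLSR model, CSFs, prediction
    sf_rows = [g for g in expr.index if g.startswith("SF")]
    sf_dev = np.log2(expr.loc[sf_rows] + 1.0)
    median_ep_dev = psi.loc[sorted(ep)].median(axis=0)
    model = fit_plsr(sf_dev, median_ep_dev)
    model.to_json(outdir / "plsr_model.json")
    csf_call = call_csfs(
        model, alpha=thr.get("csf_alpha", 0.05), top_k=thr.get("top_k", 100)
    )
    csf_call.table.rename_axis("factor").to_csv(outdir / "csf_calls.tsv", sep="\t")
    sf_can = np.log2(can_expr.loc[sf_rows] + 1.0)
    predicted = predict_median_ep(model, sf_can)
    predicted.rename_axis("sample_id").to_csv(outdir / "predicted_median_ep.tsv", sep="\t")
    _tick("plsr")

    # stage: mutation effects
    mutations = pd.read_csv(_inp("mutations.tsv", "mutations"), sep="\t")
    muts = filter_nonsense(mutations)
    median_ep_can = can_psi.loc[sorted(ep), tumor_ids].median(axis=0)
    effects = mutation_effect(
        median_ep_can,
        sf_can[tumor_ids],
        muts,
        delta=thr.get("mutation_delta", 0.05),
        sd_max=thr.get("mutation_sd_max", 0.1),
    )
    effects.to_csv(outdir / "mutation_effects.tsv", sep="\t")
    comp = compare_effect_coefficients(effects, model)
    (outdir / "mutation_comparison.json").write_text(json.dumps(comp))
    _tick("mutations")

    # stage: knockdown response
    kd_ctrl = io.read_matrix(_inp("kd_control_psi.tsv", "kd_control_psi"))
    kd_long = pd.read_csv(_inp("kd_psi.tsv", "kd_psi"), sep="\t")
    kd_psi = {
        f: grp.set_index("event")[["kd_rep1", "kd_rep2"]]
        for f, grp in kd_long.groupby("factor")
    }
    kd_expr = pd.read_csv(_inp("kd_expression.tsv", "kd_expression"), sep="\t", index_col=0)
    fractions = knockdown_response(
        kd_ctrl, kd_psi, kd_expr, ep,
        min_kd=thr.get("min_kd", 0.5), dpsi_cut=thr.get("dpsi_cut", -0.1),
    )
    fractions.to_csv(outdir / "knockdown_response.tsv", sep="\t")
    kd_cmp = compare_knockdown_fractions(fractions, csf_call.csf_set)
    (outdir / "knockdown_comparison.json").write_text(json.dumps(kd_cmp))
    _tick("knockdown")

    # stage: CNV stratification
    cnv = io.read_matrix(_inp("cnv.tsv", "cnv"))
    from .regulators import cnv_stratified_gain

    cnv_table, cnv_cmp = cnv_stratified_gain(
        sf_can[tumor_ids], cnv[tumor_ids], csf_call.csf_set
    )
    cnv_table.to_csv(outdir / "cnv_strata.tsv", sep="\t")
    (outdir / "cnv_comparison.json").write_text(json.dumps(cnv_cmp))
    _tick("cnv")

    # stage: domain enrichment
    domain_bed = io.read_bed(_inp("domains.bed", "domains"))
    exon_bed = io.read_bed(_inp("exons.bed", "exons"))
    merged = merge_domain_intervals(domain_bed)
    exon_map = {
        row["name"]: (row["chrom"], int(row["start"]), int(row["end"]))
        for _, row in exon_bed.iterrows()
    }
    mapping = map_domains_to_exons(merged, exon_map)
    background = set(exon_table.index[exon_table["label"] == "none"])
    dom = test_domain_enrichment(mapping, ep, en, background)
    dom.to_csv(outdir / "domain_enrichment.tsv", sep="\t", index=False)
    _tick("domains")

    # stage: TF cascade
    binding = io.read_gmt(_inp("tf_binding.gmt", "tf_binding"))
    knock_sets = io.read_gmt(_inp("tf_knockdown.gmt", "tf_knockdown"))
    tf_expr = io.read_matrix(_inp("tf_expression.tsv", "tf_expression"))
    top = set(csf_call.top)
    ncsf = set(model.factors) - top
    chip = chip_filter(binding, top, ncsf)
    candidates = chip.index.tolist()
    knock = knockdown_filter(knock_sets, top, ncsf, candidates)
    network = network_filter(binding, top, ncsf, candidates)
    corr_f = correlation_filter(tf_expr, can_expr.loc[sf_rows], top, ncsf)
    evidence = combine_filters(chip, knock, network, corr_f)
    evidence.rename_axis("tf").to_csv(outdir / "tf_evidence.tsv", sep="\t")
    _tick("tf")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seconds": stage_times,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
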