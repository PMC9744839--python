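"""End-to-end recovery evaluation on the synthetic generator.

``evaluate_seed`` runs the full pipeline on one simulated world and
returns per-seed recovery metrics; ``summarize_seeds`` aggregates them
over a seed sweep.  Both the acceptance test suite and
``scripts/acceptance.py`` are thin wrappers around these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .cancer import call_frequent_events, overlap_enrichment
from .domains import map_domains_to_exons, merge_domain_intervals, test_domain_enrichment
from .exons import classify_exons, correlate_exon_pathways
from .pathways import classify_embryonic_pathways, score_pathway_activity, smooth_activity_pca
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

__all__ = ["evaluate_seed", "summarize_seeds", "null_call_rate"]


def _auroc(scores: pd.Series, positives: set[str]) -> float:
    y = np.array([1 if f in positives else 0 for f in scores.index])
    s = scores.to_numpy()
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        return np.nan
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def _precision_recall(called: set, truth: set) -> tuple[float, float]:
    tp = len(called & truth)
    precision = tp / len(called) if called else np.nan
    recall = tp / len(truth) if truth else np.nan
    return precision, recall


def evaluate_seed(seed: int, config: SimConfig | None = None) -> dict:
    """Run the whole synthetic pipeline for one seed; return recovery metrics."""
    cfg = replace(config or SimConfig(), seed=seed)
    sim = Simulator(cfg)
    dev = sim.development()
    truth = dev.truth
    metrics: dict[str, float] = {}

    # --- pathway labeling -------------------------------------------------
    activity = score_pathway_activity(dev.expr, dev.pathways)
    smoothed = smooth_activity_pca(activity)
    prenatal = dev.meta.index[dev.meta["stage"] == "prenatal"].tolist()
    labels = classify_embryonic_pathways(smoothed, prenatal)
    want = {
        p: ("embryonic_positive" if lab == "prenatal" else "embryonic_negative")
        for p, lab in truth.pathway_labels.items()
    }
    agree = np.mean([labels.get(p) == want[p] for p in want])
    metrics["pathway_agreement"] = float(agree)

    # --- EP/EN classification --------------------------------------------
    corr = correlate_exon_pathways(dev.psi, activity)
    exon_table = classify_exons(corr, labels)
    called_ep = set(exon_table.index[exon_table["label"] == "EP"])
    called_en = set(exon_table.index[exon_table["label"] == "EN"])
    true_ep = truth.events_with_label("EP")
    true_en = truth.events_with_label("EN")
    true_null = truth.events_with_label("null")
    metrics["ep_precision"], metrics["ep_recall"] = _precision_recall(called_ep, true_ep)
    metrics["en_precision"], metrics["en_recall"] = _precision_recall(called_en, true_en)
    false_calls = len((called_ep | called_en) & true_null)
    metrics["null_false_call_rate"] = false_calls / len(true_null) if true_null else np.nan

    # --- cancer cohort: frequent events + headline enrichment -------------
    can = sim.cancer(truth)
    tumor_ids = can.meta.index[can.meta["cohort"] == "tumor"].tolist()
    normal_ids = can.meta.index[can.meta["cohort"] == "normal"].tolist()
    calls = call_frequent_events(can.psi[tumor_ids], can.psi[normal_ids])
    increased = set(calls.index[calls["call"].isin(["increased", "both"])])
    decreased = set(calls.index[calls["call"].isin(["decreased", "both"])])
    universe = set(calls.index)
    res_inc = overlap_enrichment(increased, called_ep, universe)
    res_dec = overlap_enrichment(decreased, called_en, universe)
    q_inc, q_dec = bh_adjust([res_inc.p_value, res_dec.p_value])
    metrics["headline_or_increased"] = res_inc.odds_ratio
    metrics["headline_or_decreased"] = res_dec.odds_ratio
    metrics["headline_pass"] = float(
        res_inc.odds_ratio > 1 and q_inc < 0.05 and res_dec.odds_ratio > 1 and q_dec < 0.05
    )

    # --- PLSR model of median EP inclusion --------------------------------
    sf_dev = np.log2(dev.expr.loc[truth.sf_ids] + 1.0)
    median_ep_dev = dev.psi.loc[sorted(called_ep)].median(axis=0)
    model = fit_plsr(sf_dev, median_ep_dev)
    csf_call = call_csfs(model)
    metrics["csf_auroc"] = _auroc(model.coef_std, truth.csf_set)

    sf_can = np.log2(can.expr.loc[truth.sf_ids] + 1.0)
    mutated = set().union(*can.mutations.loc[
        can.mutations["variant_class"] != "Missense_Mutation", "sample_id"
    ].pipe(lambda s: [set(s)]))
    clean = [s for s in tumor_ids if s not in mutated]
    predicted = predict_median_ep(model, sf_can[clean])
    actual = can.psi.loc[sorted(called_ep), clean].median(axis=0)
    metrics["prediction_r"] = float(np.corrcoef(predicted, actual)[0, 1])

    # --- mutation effects (tumor cohort only) -----------------------------
    muts = filter_nonsense(can.mutations)
    median_ep_can = can.psi.loc[sorted(called_ep), tumor_ids].median(axis=0)
    effects = mutation_effect(median_ep_can, sf_can[tumor_ids], muts)
    mutated_csfs = [f for f in muts if f in truth.csf_set]
    dec_ok = sum(effects.loc[f, "class"] == "decreased" for f in mutated_csfs)
    metrics["mutation_frac_decreased"] = dec_ok / len(mutated_csfs) if mutated_csfs else np.nan
    comp = compare_effect_coefficients(effects, model)
    metrics["mutation_coef_p"] = comp["p"]

    # --- knockdown assay --------------------------------------------------
    reg = sim.regulatory(truth)
    fractions = knockdown_response(
        reg.assay.control_psi, reg.assay.kd_psi, reg.assay.kd_expr, called_ep
    )
    kd_cmp = compare_knockdown_fractions(fractions, truth.csf_set)
    metrics["knockdown_p"] = kd_cmp["p"]

    # --- domain enrichment ------------------------------------------------
    ann = sim.annotation(truth)
    merged = merge_domain_intervals(ann.domain_bed)
    exon_map = {ev.event_id: (ev.chrom, ev.start, ev.end) for ev in ann.events}
    mapping = map_domains_to_exons(merged, exon_map)
    dom = test_domain_enrichment(mapping, called_ep, called_en, true_null - called_ep - called_en)
    planted = dom[(dom["domain"] == "DOM_planted") & (dom["class"] == "EP")]
    metrics["domain_planted_enriched"] = float(
        (not planted.empty) and bool(planted["enriched"].iloc[0])
    )

    # --- TF cascade -------------------------------------------------------
    top = set(csf_call.top)
    ncsf = set(model.factors) - top
    chip = chip_filter(reg.binding, top, ncsf)
    candidates = chip.index.tolist()
    knock = knockdown_filter(reg.knockdown_sets, top, ncsf, candidates)
    network = network_filter(truth.tf_targets, top, ncsf, candidates)
    corr_f = correlation_filter(reg.tf_expr, can.expr.loc[truth.sf_ids], top, ncsf)
    evidence = combine_filters(chip, knock, network, corr_f)
    final = set(evidence.index[evidence["final_pass"]])
    decoys = [t for t in evidence.index if t != truth.planted_tf]
    metrics["tf_unique_planted"] = float(final == {truth.planted_tf})
    metrics["tf_decoy_pass_rate"] = (
        len(final - {truth.planted_tf}) / len(decoys) if decoys else np.nan
    )
    return metrics


def null_call_rate(seed: int, n_tumor: int = 100, n_events: int = 2000) -> float:
    """Fraction of events called frequent when tumors match the normal state."""
    cfg = SimConfig(
        seed=seed,
        reactivation_strength=0.0,
        n_tumor=n_tumor,
        n_events=n_events,
        n_mut_csf=0,
        n_mut_neg=0,
    )
    sim = Simulator(cfg)
    truth = sim.development().truth
    can = sim.cancer(truth)
    tumor_ids = can.meta.index[can.meta["cohort"] == "tumor"].tolist()
    normal_ids = can.meta.index[can.meta["cohort"] == "normal"].tolist()
    calls = call_frequent_events(can.psi[tumor_ids], can.psi[normal_ids])
    return float((calls["call"] != "none").mean())


def summarize_seeds(seeds, config: SimConfig | None = None) -> pd.DataFrame:
    """Run :func:`evaluate_seed` over many seeds; rows = seeds."""
    return pd.DataFrame([evaluate_seed(s, config) for s in seeds], index=list(seeds))
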