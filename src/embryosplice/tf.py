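"""Four-filter cascade for upstream transcription-factor regulators.

A TF is proposed as a CSF regulator when it passes the promoter-binding
enrichment filter AND (the knockdown-downregulation filter OR both the
network-target and expression-correlation filters).  All enrichment tests
compare the top-k CSF foreground against the nCSF background through the
shared Fisher primitive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_adjust, pearson_with_p, set_enrichment

log = logging.getLogger(__name__)

__all__ = [
    "chip_filter",
    "knockdown_filter",
    "network_filter",
    "correlation_filter",
    "combine_filters",
]


def _enrich_table(
    target_sets: dict[str, set[str]], csf: set[str], ncsf: set[str]
) -> pd.DataFrame:
    universe = csf | ncsf
    rows = []
    for tf, targets in target_sets.items():
        bound = targets & universe
        res = set_enrichment(bound, csf, universe)
        rows.append(
            {
                "tf": tf,
                "n_bound_csf": len(bound & csf),
                "n_bound_ncsf": len(bound & ncsf),
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
                "zero_cell": res.haldane,
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def chip_filter(
    tf_targets: dict[str, set[str]],
    csf: set[str],
    ncsf: set[str],
    or_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Promoter-binding enrichment of CSFs; pass = OR > 2 and q < 0.05."""
    if csf & ncsf:
        raise ValueError("CSF and nCSF sets must be disjoint")
    out = _enrich_table(tf_targets, csf, ncsf)
    out["q"] = bh_adjust(out["p"])
    out["pass"] = (out["odds_ratio"] > or_threshold) & (out["q"] < alpha)
    return out


def knockdown_filter(
    downreg_sets: dict[str, set[str]],
    csf: set[str],
    ncsf: set[str],
    candidates: list[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """KnockTF-style filter over (TF, cell line) downregulated sets.

    ``downreg_sets`` keys are "TF:cellline".  BH runs once over all
    tested pairs; a TF passes when any of its pairs has OR > 1 and
    q < alpha.  TFs absent from the resource get tested=False.
    """
    universe = csf | ncsf
    pairs = []
    for key, targets in downreg_sets.items():
        tf = key.split(":", 1)[0]
        if tf not in candidates:
            continue
        res = set_enrichment(targets & universe, csf, universe)
        pairs.append({"tf": tf, "pair": key, "odds_ratio": res.odds_ratio, "p": res.p_value})
    pair_df = pd.DataFrame(pairs)
    rows = []
    if not pair_df.empty:
        pair_df["q"] = bh_adjust(pair_df["p"])
    for tf in candidates:
        sub = pair_df[pair_df["tf"] == tf] if not pair_df.empty else pair_df
        if sub is None or len(sub) == 0:
            rows.append({"tf": tf, "tested": False, "odds_ratio": np.nan, "q": np.nan, "pass": False})
            continue
        ok = (sub["odds_ratio"] > 1.0) & (sub["q"] < alpha)
        best = sub.loc[sub["q"].idxmin()]
        rows.append(
            {
                "tf": tf,
                "tested": True,
                "odds_ratio": float(best["odds_ratio"]),
                "q": float(best["q"]),
                "pass": bool(ok.any()),
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def network_filter(
    inferred_targets: dict[str, set[str]],
    csf: set[str],
    ncsf: set[str],
    candidates: list[str],
    or_threshold: float = 2.0,
    alpha: float = 0.2,
) -> pd.DataFrame:
    """Enrichment of CSFs among externally inferred network targets."""
    universe = csf | ncsf
    tested = {
        tf: targets
        for tf, targets in inferred_targets.items()
        if tf in candidates and targets & universe
    }
    out = _enrich_table(tested, csf, ncsf) if tested else pd.DataFrame()
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out["pass"] = (out["odds_ratio"] > or_threshold) & (out["q"] < alpha)
    rows = []
    for tf in candidates:
        if tf in out.index:
            r = out.loc[tf]
            rows.append(
                {"tf": tf, "tested": True, "odds_ratio": r["odds_ratio"], "q": r["q"], "pass": bool(r["pass"])}
            )
        else:
            rows.append({"tf": tf, "tested": False, "odds_ratio": np.nan, "q": np.nan, "pass": False})
    return pd.DataFrame(rows).set_index("tf")


def correlation_filter(
    tf_expr: pd.DataFrame,
    sf_expr: pd.DataFrame,
    csf: set[str],
    ncsf: set[str],
    min_diff: float = 0.2,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Pass TFs more correlated with median CSF than median nCSF expression.

    Expression is log2(TPM+1)-transformed; r_csf (r_ncsf) is the Pearson
    correlation of the TF with the per-sample median over CSFs (nCSFs).
    """
    shared = [s for s in tf_expr.columns if s in set(sf_expr.columns)]
    if len(shared) < min_samples:
        raise ValueError(f"need >= {min_samples} shared samples")
    logsf = np.log2(sf_expr[shared] + 1.0)
    logtf = np.log2(tf_expr[shared] + 1.0)
    med_csf = logsf.loc[[f for f in sf_expr.index if f in csf]].median(axis=0)
    med_ncsf = logsf.loc[[f for f in sf_expr.index if f in ncsf]].median(axis=0)
    rows = []
    for tf in tf_expr.index:
        x = logtf.loc[tf]
        if np.ptp(x.to_numpy()) == 0:
            rows.append({"tf": tf, "r_csf": np.nan, "r_ncsf": np.nan, "diff": np.nan, "pass": False})
            continue
        r_csf, _ = pearson_with_p(x, med_csf)
        r_ncsf, _ = pearson_with_p(x, med_ncsf)
        diff = r_csf - r_ncsf
        rows.append(
            {
                "tf": tf,
                "r_csf": r_csf,
                "r_ncsf": r_ncsf,
                "diff": diff,
                "pass": bool(np.isfinite(diff) and diff > min_diff),
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def combine_filters(
    chip: pd.DataFrame,
    knock: pd.DataFrame,
    network: pd.DataFrame,
    corr: pd.DataFrame,
) -> pd.DataFrame:
    """Evidence table with final_pass = chip & (knock | (network & corr))."""
    table = pd.DataFrame(index=chip.index)
    table["chip_pass"] = chip["pass"]
    table["chip_or"] = chip["odds_ratio"]
    table["chip_q"] = chip["q"]
    table["knock_pass"] = knock["pass"].reindex(chip.index, fill_value=False)
    table["knock_tested"] = knock["tested"].reindex(chip.index, fill_value=False)
    table["network_pass"] = network["pass"].reindex(chip.index, fill_value=False)
    table["network_tested"] = network["tested"].reindex(chip.index, fill_value=False)
    table["corr_pass"] = corr["pass"].reindex(chip.index, fill_value=False)
    table["corr_diff"] = corr["diff"].reindex(chip.index)
    table["final_pass"] = table["chip_pass"] & (
        table["knock_pass"] | (table["network_pass"] & table["corr_pass"])
    )
    return table
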