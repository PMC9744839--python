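"""Frequently altered splicing events in tumors and overlap enrichment.

An event is "frequently increased" when its PSI exceeds the normal-cohort
mean by ``sd_mult`` standard deviations in at least ``min_frac`` of tumors
with data (and symmetrically for "decreased").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import EnrichmentResult, bh_adjust, pearson_with_p, set_enrichment

log = logging.getLogger(__name__)

__all__ = [
    "call_frequent_events",
    "overlap_enrichment",
    "stage_stratified_enrichment",
    "signature_correlation",
    "correlation_set_enrichment",
]

DEFAULT_SD_MULT = 2.0
DEFAULT_MIN_FRAC = 0.15
DEFAULT_MIN_NORMAL_N = 10
DEFAULT_SD_FLOOR = 0.01


def call_frequent_events(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    sd_mult: float = DEFAULT_SD_MULT,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_normal_n: int = DEFAULT_MIN_NORMAL_N,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> pd.DataFrame:
    """Per-event deviation calls of tumors against the normal distribution.

    Tumors with missing PSI are excluded from both numerator and
    denominator of the per-direction fractions.  Events with fewer than
    ``min_normal_n`` non-missing normal values are skipped (call='none').
    """
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("both cohorts must be non-empty")
    if min_normal_n < 5:
        raise ValueError("min_normal_n must be >= 5")
    normal = normal.reindex(tumor.index)
    nv = normal.to_numpy(dtype=float)
    tv = tumor.to_numpy(dtype=float)

    n_norm = np.isfinite(nv).sum(axis=1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(nv, axis=1)
        sd = np.nanstd(nv, axis=1, ddof=1)
    sd = np.maximum(np.nan_to_num(sd, nan=0.0), sd_floor)

    up = tv > (mean + sd_mult * sd)[:, None]
    down = tv < (mean - sd_mult * sd)[:, None]
    has = np.isfinite(tv)
    n_t = has.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_up = np.where(n_t > 0, (up & has).sum(axis=1) / np.maximum(n_t, 1), np.nan)
        frac_down = np.where(n_t > 0, (down & has).sum(axis=1) / np.maximum(n_t, 1), np.nan)

    usable = n_norm >= min_normal_n
    inc = usable & (frac_up >= min_frac)
    dec = usable & (frac_down >= min_frac)
    call = np.where(inc & dec, "both", np.where(inc, "increased", np.where(dec, "decreased", "none")))
    return pd.DataFrame(
        {
            "normal_mean": np.where(usable, mean, np.nan),
            "normal_sd": np.where(usable, sd, np.nan),
            "n_up": (up & has).sum(axis=1),
            "n_down": (down & has).sum(axis=1),
            "frac_up": np.where(usable, frac_up, np.nan),
            "frac_down": np.where(usable, frac_down, np.nan),
            "call": call,
        },
        index=tumor.index,
    )


def overlap_enrichment(query: set, reference: set, universe: set) -> EnrichmentResult:
    """Fisher enrichment of two event sets within a universe."""
    return set_enrichment(set(query), set(reference), set(universe))


def stage_stratified_enrichment(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    stages: pd.Series,
    ep: set,
    en: set,
    universe: set,
    min_stratum: int = 10,
    **call_kwargs,
) -> pd.DataFrame:
    """Frequent-event calls and EP/EN enrichment per tumor stage stratum."""
    rows = []
    strata = [s for s in stages.dropna().unique() if s != "na"]
    usable = 0
    for stratum in sorted(strata):
        cols = stages.index[stages == stratum]
        cols = [c for c in cols if c in tumor.columns]
        if len(cols) < min_stratum:
            log.warning("stage %s: %d tumors < %d, dropped", stratum, len(cols), min_stratum)
            continue
        usable += 1
        calls = call_frequent_events(tumor[cols], normal, **call_kwargs)
        increased = set(calls.index[calls["call"].isin(["increased", "both"])])
        decreased = set(calls.index[calls["call"].isin(["decreased", "both"])])
        for name, query, ref in (("EP_in_increased", increased, ep), ("EN_in_decreased", decreased, en)):
            res = overlap_enrichment(query & universe, ref & universe, universe)
            rows.append(
                {
                    "stratum": stratum,
                    "test": name,
                    "n_tumors": len(cols),
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                }
            )
    if usable == 0:
        raise ValueError("no stage stratum reached the minimum size")
    if usable == 1:
        log.warning("only one usable stage stratum")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def signature_correlation(
    psi: pd.DataFrame,
    event_set: set,
    expr: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    min_samples: int = 10,
) -> pd.DataFrame:
    """Correlate median PSI of an event set with mean log2(TPM+1) per gene set."""
    shared = [c for c in psi.columns if c in set(expr.columns)]
    if len(shared) < min_samples:
        raise ValueError(f"need >= {min_samples} shared samples")
    events = [e for e in event_set if e in psi.index]
    med = psi.loc[events, shared].median(axis=0, skipna=True)
    logx = np.log2(expr[shared] + 1.0)
    rows = []
    for name, genes in gene_sets.items():
        present = sorted(genes & set(expr.index))
        if not present:
            log.warning("gene set %s: no genes matched, skipped", name)
            continue
        score = logx.loc[present].mean(axis=0)
        r, p = pearson_with_p(med, score)
        rows.append({"gene_set": name, "n_genes": len(present), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
    return out


def correlation_set_enrichment(
    psi: pd.DataFrame,
    phenotype: pd.Series,
    ep: set,
    en: set,
    pcc_threshold: float = 0.5,
    min_samples: int = 10,
) -> pd.DataFrame:
    """EP/EN enrichment among events correlated with a per-sample phenotype.

    Events are split into positively (r > threshold) and negatively
    (r < -threshold) correlated sets over the universe of events with a
    computable correlation; each (EP/EN x sign) cell is a Fisher test.
    """
    shared = [c for c in psi.columns if c in phenotype.index and np.isfinite(phenotype[c])]
    if len(shared) < min_samples:
        raise ValueError(f"need >= {min_samples} samples with phenotype")
    pheno = phenotype[shared]
    rs = {}
    for event in psi.index:
        r, _ = pearson_with_p(psi.loc[event, shared], pheno)
        if np.isfinite(r):
            rs[event] = r
    universe = set(rs)
    pos = {e for e, r in rs.items() if r > pcc_threshold}
    neg = {e for e, r in rs.items() if r < -pcc_threshold}
    underpowered = len(pos) < 2 or len(neg) < 2
    rows = []
    for sign, corr_set in (("positive", pos), ("negative", neg)):
        for cls, events in (("EP", ep), ("EN", en)):
            res = set_enrichment(corr_set, events & universe, universe)
            rows.append(
                {
                    "class": cls,
                    "sign": sign,
                    "n_correlated": len(corr_set),
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                    "underpowered": underpowered,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out
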