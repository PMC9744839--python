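"""Exon-pathway correlation screen and EP/EN classification.

Each event's PSI profile over developmental timepoints is correlated
(Pearson) with every pathway's activity; p-values are BH-adjusted within
each exon across its tested pathways; events are then labeled EP or EN by
the fraction of embryonic-positive pathways they are significantly
positively / negatively correlated with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust, pearson_with_p
from .psi import EventAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "ExonPathwayCorrelation",
    "correlate_exon_pathways",
    "classify_exons",
    "host_gene_coupling",
]

DEFAULT_MIN_PAIRS = 6
DEFAULT_FDR = 0.05
DEFAULT_POS_FRAC = 0.10
DEFAULT_NEG_FRAC = 0.05


@dataclass
class ExonPathwayCorrelation:
    """Event x pathway matrices of Pearson r, raw p and per-exon BH q."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    fdr: float

    def to_long(self) -> pd.DataFrame:
        out = (
            self.r.stack(future_stack=True).rename("r").to_frame()
            .join(self.p.stack(future_stack=True).rename("p"))
            .join(self.q.stack(future_stack=True).rename("q"))
        )
        out.index.names = ["event", "pathway"]
        return out.reset_index()


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r with n complete pairs (t distribution)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n - 2
        t = r * np.sqrt(df / np.clip(1.0 - r * r, 1e-300, None))
        p = 2.0 * sps.t.sf(np.abs(t), np.clip(df, 1, None))
    p[df < 1] = np.nan
    return p


def correlate_exon_pathways(
    psi: pd.DataFrame,
    activity: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    fdr: float = DEFAULT_FDR,
) -> ExonPathwayCorrelation:
    """Pearson correlation of every event against every pathway.

    Pairs with fewer than ``min_pairs`` complete observations, or with a
    zero-variance operand, get r = NaN and are excluded from that exon's
    BH family.
    """
    if min_pairs < 5:
        raise ValueError("min_pairs must be >= 5")
    shared = [c for c in activity.columns if c in set(psi.columns)]
    if not shared:
        raise ValueError("no shared timepoint columns between PSI and activity")
    x = psi[shared].to_numpy(dtype=float)          # events x T
    a = activity[shared].to_numpy(dtype=float)     # pathways x T

    n_ev, n_pw = x.shape[0], a.shape[0]
    r = np.full((n_ev, n_pw), np.nan)
    nobs = np.zeros((n_ev, n_pw))

    a_sd = a.std(axis=1)
    complete = np.isfinite(x).all(axis=1)

    # fast path: events with no missing values, vectorized across pathways
    if complete.any():
        xc = x[complete]
        xm = xc - xc.mean(axis=1, keepdims=True)
        am = a - a.mean(axis=1, keepdims=True)
        xs = xm.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (xm @ am.T) / xc.shape[1] / np.outer(xs, a_sd)
        rr[:, a_sd == 0] = np.nan
        rr[xs == 0, :] = np.nan
        r[complete] = np.clip(rr, -1.0, 1.0)
        nobs[complete] = xc.shape[1]

    # slow path: per-event masking
    for i in np.flatnonzero(~complete):
        mask = np.isfinite(x[i])
        m = int(mask.sum())
        if m < min_pairs:
            continue
        xi = x[i, mask]
        if np.ptp(xi) == 0:
            continue
        ai = a[:, mask]
        sd = ai.std(axis=1)
        xm = xi - xi.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (ai - ai.mean(axis=1, keepdims=True)) @ xm / m / (sd * xm.std())
        rr[sd == 0] = np.nan
        r[i] = np.clip(rr, -1.0, 1.0)
        nobs[i] = m

    valid = np.isfinite(r) & (nobs >= min_pairs)
    r[~valid] = np.nan
    p = np.where(valid, _pearson_p(np.nan_to_num(r), nobs), np.nan)
    q = np.vstack([bh_adjust(p[i]) for i in range(n_ev)])
    idx, cols = psi.index, activity.index
    return ExonPathwayCorrelation(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        fdr=fdr,
    )


def classify_exons(
    corr: ExonPathwayCorrelation,
    pathway_labels: dict[str, str],
    pos_frac: float = DEFAULT_POS_FRAC,
    neg_frac: float = DEFAULT_NEG_FRAC,
    fdr: float | None = None,
    rule: str = "positive_only",
) -> pd.DataFrame:
    """Label events EP / EN / none.

    Under ``rule='positive_only'`` both the >= pos_frac and the
    <= neg_frac conditions are evaluated on the embryonic-positive
    pathways; under ``rule='cross_class'`` the <= neg_frac condition moves
    to the embryonic-negative pathways.  Raw per-class significant-
    correlation counts are returned for audit either way.
    """
    if pos_frac <= neg_frac:
        raise ValueError("pos_frac must exceed neg_frac (rule would be vacuous)")
    if rule not in ("positive_only", "cross_class"):
        raise ValueError(f"unknown rule {rule!r}")
    alpha = corr.fdr if fdr is None else fdr

    pos_pw = [p for p in corr.r.columns if pathway_labels.get(p) == "embryonic_positive"]
    neg_pw = [p for p in corr.r.columns if pathway_labels.get(p) == "embryonic_negative"]
    if not pos_pw or not neg_pw:
        raise ValueError("need both embryonic_positive and embryonic_negative pathways")

    sig = (corr.q.to_numpy() < alpha) & np.isfinite(corr.r.to_numpy())
    pos_r = corr.r.to_numpy() > 0
    pos_cols = corr.r.columns.isin(pos_pw)
    neg_cols = corr.r.columns.isin(neg_pw)

    n_pos_sig_pos = (sig & pos_r)[:, pos_cols].sum(axis=1)
    n_pos_sig_neg = (sig & ~pos_r)[:, pos_cols].sum(axis=1)
    n_neg_sig_pos = (sig & pos_r)[:, neg_cols].sum(axis=1)
    n_neg_sig_neg = (sig & ~pos_r)[:, neg_cols].sum(axis=1)

    n_pos, n_neg = len(pos_pw), len(neg_pw)
    f_pp = n_pos_sig_pos / n_pos
    f_pn = n_pos_sig_neg / n_pos
    if rule == "positive_only":
        ep = (f_pp >= pos_frac) & (f_pn <= neg_frac)
        en = (f_pn >= pos_frac) & (f_pp <= neg_frac)
    else:
        ep = (f_pp >= pos_frac) & (n_neg_sig_pos / n_neg <= neg_frac)
        en = (f_pn >= pos_frac) & (n_neg_sig_neg / n_neg <= neg_frac)
    label = np.where(ep & ~en, "EP", np.where(en & ~ep, "EN", "none"))
    return pd.DataFrame(
        {
            "label": label,
            "n_pos_sig_pos": n_pos_sig_pos,
            "n_pos_sig_neg": n_pos_sig_neg,
            "n_neg_sig_pos": n_neg_sig_pos,
            "n_neg_sig_neg": n_neg_sig_neg,
        },
        index=corr.r.index,
    )


def host_gene_coupling(
    psi: pd.DataFrame, expr: pd.DataFrame, events: list[EventAnnotation]
) -> pd.Series:
    """Per-event Pearson r between PSI and log2(TPM+1) of the host gene."""
    logx = np.log2(expr + 1.0)
    out = {}
    for ev in events:
        if ev.gene_id not in logx.index:
            log.warning("host gene %s missing for %s", ev.gene_id, ev.event_id)
            out[ev.event_id] = np.nan
            continue
        r, _ = pearson_with_p(
            psi.loc[ev.event_id, expr.columns], logx.loc[ev.gene_id, expr.columns]
        )
        out[ev.event_id] = r
    return pd.Series(out, name="host_gene_r")
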