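"""Latent-component regression of median EP inclusion on splicing factors.

The model regresses the per-sample median EP PSI on z-scored splicing
factor expression with partial least squares, picks the component count by
leave-one-out cross-validation (minimum RMSEP), derives per-factor
significance from the jackknife variance of the coefficients across the
LOO refits, and calls critical splicing factors (CSFs) as factors with a
positive coefficient and BH-adjusted p below alpha.

The causal-validation statistics live here too: expression-matched
mutation effects, knockdown response fractions, and CNV stratification.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from ._stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "PlsrModel",
    "fit_plsr",
    "call_csfs",
    "predict_median_ep",
    "mutation_effect",
    "filter_nonsense",
    "compare_effect_coefficients",
    "knockdown_response",
    "compare_knockdown_fractions",
    "cnv_stratified_gain",
]

DEFAULT_MAX_COMPONENTS = 10
NONSENSE_CLASSES = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Nonstop_Mutation"}
)


@dataclass
class PlsrModel:
    """Fitted PLS regression with standardization state and significance."""

    factors: list[str]
    coef: pd.Series                  # on the original predictor scale
    coef_std: pd.Series              # per-SD of predictor (importance scale)
    p: pd.Series
    q: pd.Series
    x_mean: pd.Series
    x_sd: pd.Series
    y_mean: float
    n_components: int
    cv_rmsep: dict[int, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "factors": self.factors,
            "coef": self.coef.tolist(),
            "coef_std": self.coef_std.tolist(),
            "p": self.p.tolist(),
            "q": self.q.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "n_components": self.n_components,
            "cv_rmsep": {str(k): v for k, v in self.cv_rmsep.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlsrModel":
        with open(path) as fh:
            d = json.load(fh)
        idx = pd.Index(d["factors"])
        return cls(
            factors=d["factors"],
            coef=pd.Series(d["coef"], index=idx),
            coef_std=pd.Series(d["coef_std"], index=idx),
            p=pd.Series(d["p"], index=idx),
            q=pd.Series(d["q"], index=idx),
            x_mean=pd.Series(d["x_mean"], index=idx),
            x_sd=pd.Series(d["x_sd"], index=idx),
            y_mean=d["y_mean"],
            n_components=d["n_components"],
            cv_rmsep={int(k): v for k, v in d["cv_rmsep"].items()},
        )


def _pls_coef(xz: np.ndarray, yc: np.ndarray, ncomp: int) -> np.ndarray:
    """PLS1 coefficients mapping already-standardized X to centered y."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = PLSRegression(n_components=ncomp, scale=False)
        model.fit(xz, yc)
    return model.coef_.ravel()


def _pls_coef_path(xz: np.ndarray, yc: np.ndarray, kmax: int) -> list[np.ndarray]:
    """Coefficient vectors for 1..kmax components from a single NIPALS fit.

    NIPALS extracts components sequentially, so the k-component solution
    is W_k (P_k^T W_k)^{-1} Q_k^T over the leading k weight/loading
    columns of the kmax fit.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PLSRegression(n_components=kmax, scale=False)
            model.fit(xz, yc)
        w, p, q = model.x_weights_, model.x_loadings_, model.y_loadings_
        coefs = []
        for k in range(1, kmax + 1):
            b = w[:, :k] @ np.linalg.solve(p[:, :k].T @ w[:, :k], q[0, :k])
            coefs.append(b)
        return coefs
    except np.linalg.LinAlgError:
        return [_pls_coef(xz, yc, k) for k in range(1, kmax + 1)]


def fit_plsr(
    sf_expr: pd.DataFrame,
    median_ep: pd.Series,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> PlsrModel:
    """Fit the PLS regression of median EP inclusion on factor expression.

    ``sf_expr`` is factors x samples (any monotone transform of abundance;
    callers typically pass log2(TPM+1)); ``median_ep`` is indexed by the
    same samples.  Zero-variance factors are dropped with a warning.
    """
    samples = [s for s in sf_expr.columns if s in median_ep.index]
    n = len(samples)
    if n < 8:
        raise ValueError(f"need >= 8 samples, got {n}")
    y = median_ep[samples].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    x = sf_expr[samples].to_numpy(dtype=float).T  # samples x factors
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d zero-variance factors", int((~keep).sum()))
    factors = [f for f, k in zip(sf_expr.index, keep) if k]
    x = x[:, keep]
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    xz = (x - mu) / sd
    y_mean = float(y.mean())
    yc = y - y_mean

    kmax = max(1, min(max_components, n - 2, len(factors)))
    # leave-one-out CV: squared prediction errors per candidate ncomp
    sse = np.zeros(kmax)
    loo_coefs: dict[int, list[np.ndarray]] = {k: [] for k in range(1, kmax + 1)}
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        xt = x[tr]
        mt, st = xt.mean(axis=0), xt.std(axis=0, ddof=0)
        st = np.where(st > 0, st, 1.0)
        xzt = (xt - mt) / st
        yt = y[tr]
        ytc = yt - yt.mean()
        xq = (x[i] - mt) / st
        for k, b in enumerate(_pls_coef_path(xzt, ytc, kmax), start=1):
            pred = yt.mean() + xq @ b
            sse[k - 1] += (pred - y[i]) ** 2
            loo_coefs[k].append(b / st)  # original predictor scale
    rmsep = np.sqrt(sse / n)
    # parsimony: smallest component count within 5% of the minimum RMSEP
    best = rmsep.min()
    ncomp = int(np.flatnonzero(rmsep <= best * 1.05)[0]) + 1

    bz_full = _pls_coef(xz, yc, ncomp)
    b_full = bz_full / sd
    jack = np.asarray(loo_coefs[ncomp])                 # n x p
    jbar = jack.mean(axis=0)
    var = (n - 1) / n * ((jack - jbar) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, b_full / np.sqrt(var), np.inf * np.sign(b_full))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    q = bh_adjust(p)

    idx = pd.Index(factors)
    return PlsrModel(
        factors=factors,
        coef=pd.Series(b_full, index=idx),
        coef_std=pd.Series(bz_full, index=idx),
        p=pd.Series(p, index=idx),
        q=pd.Series(q, index=idx),
        x_mean=pd.Series(mu, index=idx),
        x_sd=pd.Series(sd, index=idx),
        y_mean=y_mean,
        n_components=ncomp,
        cv_rmsep={k + 1: float(v) for k, v in enumerate(rmsep)},
    )


@dataclass
class CsfCall:
    table: pd.DataFrame          # factor-indexed: coef, q, csf, rank
    top: list[str]               # top_k CSFs by coefficient, for TF filtering

    @property
    def csf_set(self) -> set[str]:
        return set(self.table.index[self.table["csf"]])

    @property
    def ncsf_set(self) -> set[str]:
        return set(self.table.index[~self.table["csf"]])


def call_csfs(model: PlsrModel, alpha: float = 0.05, top_k: int = 100) -> CsfCall:
    """CSF = positive coefficient and BH-adjusted p < alpha."""
    csf = (model.coef > 0) & (model.q < alpha)
    table = pd.DataFrame(
        {"coef": model.coef, "coef_std": model.coef_std, "p": model.p, "q": model.q, "csf": csf}
    )
    ranked = table[table["csf"]].sort_values("coef_std", ascending=False)
    table["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index, dtype="Int64"
    )
    if not csf.any():
        log.warning("no factor passed the CSF criterion")
    return CsfCall(table=table, top=ranked.index[:top_k].tolist())


def predict_median_ep(model: PlsrModel, new_expr: pd.DataFrame) -> pd.Series:
    """Apply the stored standardization and linear map to new samples.

    Predictions are not clipped to [0, 1]; out-of-range values are the
    caller's signal that the model is extrapolating.
    """
    missing = [f for f in model.factors if f not in new_expr.index]
    if missing:
        raise KeyError(f"factors absent from new expression matrix: {missing[:10]}")
    x = new_expr.loc[model.factors].to_numpy(dtype=float).T
    pred = model.y_mean + (x - model.x_mean.to_numpy()) @ model.coef.to_numpy()
    return pd.Series(pred, index=new_expr.columns, name="predicted_median_ep")


# ----------------------------------------------------------------------
# mutation analysis


def mutation_effect(
    median_ep: pd.Series,
    sf_expr: pd.DataFrame,
    mutations: dict[str, set[str]],
    k: int = 10,
    delta: float = 0.05,
    sd_max: float = 0.1,
    delta_mode: str = "relative",
) -> pd.DataFrame:
    """Classify mutated factors by the shift of median EP inclusion.

    For each mutant sample the ``k`` nearest non-mutant samples (Euclidean
    distance over z-scored factor expression, ties broken by sample id)
    form its matched background; backgrounds are pooled per factor.  A
    factor whose pooled background has SD of median EP above ``sd_max`` is
    discarded; otherwise it is 'increased'/'decreased' when the mutant
    median differs from the background median by at least ``delta``
    (relative by default, absolute PSI points with delta_mode='absolute').
    """
    if delta_mode not in ("relative", "absolute"):
        raise ValueError("delta_mode must be 'relative' or 'absolute'")
    samples = [s for s in sf_expr.columns if s in median_ep.index]
    all_mutated = set().union(*mutations.values()) if mutations else set()
    background = [s for s in samples if s not in all_mutated]
    if not background:
        raise ValueError("no background samples without splicing-factor mutations")

    x = sf_expr[samples].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    xz = (x - mu) / np.where(sd > 0, sd, 1.0)
    zcol = {s: xz[:, i] for i, s in enumerate(samples)}
    bg_sorted = sorted(background)

    rows = []
    for factor, mut_samples in mutations.items():
        if factor not in sf_expr.index:
            raise KeyError(f"mutated factor {factor!r} not in the factor expression matrix")
        muts = sorted(s for s in mut_samples if s in set(samples))
        if not muts:
            rows.append((factor, 0, np.nan, np.nan, np.nan, "untestable"))
            continue
        pooled: list[str] = []
        for s in muts:
            dists = np.array([np.linalg.norm(zcol[s] - zcol[b]) for b in bg_sorted])
            order = np.lexsort((np.array(bg_sorted), dists))
            pooled.extend(bg_sorted[i] for i in order[:k])
        bg_vals = median_ep[pooled].to_numpy()
        bg_median = float(np.median(bg_vals))
        bg_sd = float(np.std(bg_vals, ddof=1)) if len(bg_vals) > 1 else 0.0
        mut_median = float(np.median(median_ep[muts]))
        if delta_mode == "relative":
            change = (mut_median - bg_median) / bg_median if bg_median != 0 else np.nan
        else:
            change = mut_median - bg_median
        if bg_sd > sd_max:
            cls = "discarded"
        elif not np.isfinite(change) or abs(change) < delta:
            cls = "untestable"
        else:
            cls = "increased" if change > 0 else "decreased"
        rows.append((factor, len(muts), mut_median, bg_median, change, cls))
    return pd.DataFrame(
        rows,
        columns=["factor", "n_mutant", "mutant_median_ep", "background_median_ep", "delta", "class"],
    ).set_index("factor")


def filter_nonsense(mutations: pd.DataFrame, whitelist=NONSENSE_CLASSES) -> dict[str, set[str]]:
    """MAF-like table -> {factor: mutated sample ids}, truncating classes only."""
    kept = mutations[mutations["variant_class"].isin(whitelist)]
    return {g: set(grp["sample_id"]) for g, grp in kept.groupby("gene")}


def compare_effect_coefficients(effects: pd.DataFrame, model: PlsrModel) -> dict:
    """Rank-sum comparison of coefficients: decreased vs increased factors."""
    dec = [f for f in effects.index[effects["class"] == "decreased"] if f in model.coef_std.index]
    inc = [f for f in effects.index[effects["class"] == "increased"] if f in model.coef_std.index]
    if not dec or not inc:
        log.warning("one of the effect groups is empty; comparison skipped")
        return {"n_decreased": len(dec), "n_increased": len(inc), "p": np.nan, "statistic": np.nan}
    a = model.coef_std[dec].to_numpy()
    b = model.coef_std[inc].to_numpy()
    stat, p = sps.ranksums(a, b)
    return {
        "n_decreased": len(dec),
        "n_increased": len(inc),
        "median_coef_decreased": float(np.median(a)),
        "median_coef_increased": float(np.median(b)),
        "statistic": float(stat),
        "p": float(p),
        "low_power": len(a) < 3 or len(b) < 3,
    }


# ----------------------------------------------------------------------
# knockdown analysis


def knockdown_response(
    control_psi: pd.DataFrame,
    kd_psi: dict[str, pd.DataFrame],
    kd_expr: pd.DataFrame,
    ep: set[str],
    min_kd: float = 0.5,
    dpsi_cut: float = -0.1,
) -> pd.DataFrame:
    """Per-factor fraction of EP events decreased in both replicates.

    Factors are kept only when their own expression dropped by at least
    ``min_kd`` (fraction of the control mean) in both replicates; an EP
    event counts as decreased when PSI(replicate) - mean control PSI is
    below ``dpsi_cut`` in both replicates.
    """
    ctrl = control_psi.mean(axis=1, skipna=True)
    ep_events = [e for e in control_psi.index if e in ep]
    rows = []
    for factor, reps in kd_psi.items():
        if reps.shape[1] != 2:
            log.warning("factor %s: expected 2 replicates, skipped", factor)
            continue
        if factor not in kd_expr.index:
            log.warning("factor %s: no expression check available, skipped", factor)
            continue
        ctrl_level = kd_expr.loc[factor, "control_mean"]
        drops = 1.0 - kd_expr.loc[factor, ["kd_rep1", "kd_rep2"]].to_numpy() / ctrl_level
        if (drops < min_kd).any():
            continue  # knockdown failed the expression criterion
        d = reps.loc[ep_events].sub(ctrl[ep_events], axis=0)
        both_down = (d < dpsi_cut).all(axis=1) & d.notna().all(axis=1)
        tested = d.notna().all(axis=1).sum()
        frac = float(both_down.sum() / tested) if tested else np.nan
        rows.append((factor, int(tested), frac))
    return pd.DataFrame(rows, columns=["factor", "n_ep_tested", "fraction_decreased"]).set_index(
        "factor"
    )


def compare_knockdown_fractions(fractions: pd.DataFrame, csf: set[str]) -> dict:
    """One-sided rank-sum: CSF knockdowns shift more EP events than others."""
    a = fractions.loc[[f for f in fractions.index if f in csf], "fraction_decreased"].dropna()
    b = fractions.loc[[f for f in fractions.index if f not in csf], "fraction_decreased"].dropna()
    if a.empty or b.empty:
        return {"n_csf": len(a), "n_ncsf": len(b), "p": np.nan}
    stat, p = sps.mannwhitneyu(a, b, alternative="greater")
    return {"n_csf": len(a), "n_ncsf": len(b), "statistic": float(stat), "p": float(p)}


# ----------------------------------------------------------------------
# CNV analysis


def cnv_stratified_gain(
    expr: pd.DataFrame,
    cnv: pd.DataFrame,
    csf: set[str],
    n_strata: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Mean CNV of each CSF across expression strata of that CSF.

    Samples are split per CSF into ``n_strata`` equal-frequency groups by
    the CSF's own expression (stable order breaks ties); the distributions
    of per-CSF mean CNV in the extreme strata are compared by a two-sided
    rank-sum test.
    """
    bad = set(cnv.to_numpy().ravel()) - {-1, 0, 1}
    if bad:
        raise ValueError(f"CNV values must be in {{-1, 0, 1}}, found {sorted(bad)[:5]}")
    samples = [s for s in expr.columns if s in set(cnv.columns)]
    rows = []
    for factor in sorted(csf):
        if factor not in expr.index or factor not in cnv.index:
            continue
        vals = expr.loc[factor, samples].to_numpy(dtype=float)
        if np.unique(vals).size < n_strata:
            log.warning("factor %s: < %d distinct expression values, skipped", factor, n_strata)
            continue
        order = np.argsort(vals, kind="mergesort")
        stratum = np.empty(len(samples), dtype=int)
        stratum[order] = np.arange(len(samples)) * n_strata // len(samples)
        cn = cnv.loc[factor, samples].to_numpy(dtype=float)
        means = [cn[stratum == g].mean() for g in range(n_strata)]
        rows.append([factor] + means)
    cols = ["factor"] + [f"stratum_{g}" for g in range(n_strata)]
    table = pd.DataFrame(rows, columns=cols).set_index("factor")
    if table.empty:
        return table, {"p": np.nan}
    lo = table[f"stratum_0"].to_numpy()
    hi = table[f"stratum_{n_strata - 1}"].to_numpy()
    if np.all(lo == hi):
        result = {"p": 1.0, "statistic": 0.0}
    else:
        stat, p = sps.ranksums(hi, lo)
        result = {"statistic": float(stat), "p": float(p)}
    result["mean_low"] = float(lo.mean())
    result["mean_high"] = float(hi.mean())
    return table, result
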