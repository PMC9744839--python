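"""Protein-domain interval mapping and per-domain enrichment tests.

Coordinates are 0-based half-open throughout; strand is ignored (domain
tracks are genome-projected).  Book-ended intervals of the same domain
merge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_enrichment

__all__ = ["merge_domain_intervals", "map_domains_to_exons", "test_domain_enrichment"]


def merge_domain_intervals(track: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per (domain, chrom); overlapping or touching merge."""
    if (track["start"] < 0).any():
        raise ValueError("negative coordinates in domain track")
    if (track["start"] >= track["end"]).any():
        raise ValueError("empty or inverted interval in domain track")
    rows = []
    for (name, chrom), grp in track.groupby(["name", "chrom"], sort=True):
        ivs = grp[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, name))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def map_domains_to_exons(
    track: pd.DataFrame,
    exons: dict[str, tuple[str, int, int]],
    min_overlap_bp: int = 1,
) -> dict[str, set[str]]:
    """Assign domains to exons with >= ``min_overlap_bp`` bases of overlap.

    ``exons`` maps event id -> (chrom, start, end).  Every event appears
    in the result, unmapped ones with an empty set.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in track.groupby("chrom"):
        g = grp.sort_values("start")
        by_chrom[chrom] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["name"].to_numpy(),
        )
    mapping: dict[str, set[str]] = {}
    for event, (chrom, start, end) in exons.items():
        hits: set[str] = set()
        if chrom in by_chrom:
            starts, ends, names = by_chrom[chrom]
            ov = np.minimum(ends, end) - np.maximum(starts, start)
            hits = set(names[ov >= min_overlap_bp].tolist())
        mapping[event] = hits
    return mapping


def test_domain_enrichment(
    mapping: dict[str, set[str]],
    ep: set[str],
    en: set[str],
    background: set[str],
    or_threshold: float = 1.0,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-(domain, class) Fisher enrichment against the background exons.

    BH correction is applied separately within the EP and EN families.
    A domain is flagged enriched when OR > ``or_threshold`` and q < ``alpha``.
    Domains absent from every exon are skipped.
    """
    if ep & background or en & background:
        raise ValueError("EP/EN sets must be disjoint from the background set")
    domains = sorted(set().union(*mapping.values())) if mapping else []
    rows = []
    for cls, fg in (("EP", ep), ("EN", en)):
        fg = {e for e in fg if e in mapping}
        bg = {e for e in background if e in mapping}
        for dom in domains:
            a = sum(1 for e in fg if dom in mapping[e])
            b = len(fg) - a
            c = sum(1 for e in bg if dom in mapping[e])
            d = len(bg) - c
            if a + c == 0:
                continue
            res = fisher_enrichment(a, b, c, d)
            rows.append(
                {
                    "domain": dom,
                    "class": cls,
                    "n_class_with": a,
                    "n_class_without": b,
                    "n_bg_with": c,
                    "n_bg_without": d,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for cls in ("EP", "EN"):
        mask = out["class"] == cls
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"])
    out["enriched"] = (out["odds_ratio"] > or_threshold) & (out["q"] < alpha)
    return out
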