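"""Exon-skip PSI quantification from transcript-level TPM.

PSI(event, sample) = sum of TPM over the inclusion transcripts divided by
the sum over all transcripts of the event; samples where the denominator
falls below ``min_total_tpm`` are reported as missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EventAnnotation", "read_events", "write_events", "compute_psi", "delta_psi"]

DEFAULT_MIN_TOTAL_TPM = 1.0


@dataclass(frozen=True)
class EventAnnotation:
    """One exon-skipping event: skipped-exon locus plus transcript sets."""

    event_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.event_id}: start must be < end")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValueError(
                f"{self.event_id}: inclusion transcripts must be a proper "
                "subset of the total transcripts"
            )
        if len(self.total_transcripts) < 2:
            raise ValueError(f"{self.event_id}: need at least two transcripts")


def read_events(path) -> list[EventAnnotation]:
    """Parse the tab-separated event file.

    Columns: chrom, gene_id, event_id, inclusion_transcripts,
    total_transcripts (comma-joined lists); optional start, end, strand.
    A header line is required.
    """
    events: list[EventAnnotation] = []
    seen: set[str] = set()
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (expected a header)")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) not in (5, 8):
            raise ValueError(f"{path}:{lineno}: expected 5 or 8 fields, got {len(fields)}")
        chrom, gene_id, event_id, inc, tot = fields[:5]
        start, end, strand = (0, 1, "+")
        if len(fields) == 8:
            try:
                start, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = fields[7]
        if event_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate event id {event_id!r}")
        seen.add(event_id)
        try:
            ev = EventAnnotation(
                event_id=event_id,
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                inclusion_transcripts=frozenset(t for t in inc.split(",") if t),
                total_transcripts=frozenset(t for t in tot.split(",") if t),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        events.append(ev)
    return events


def write_events(events: list[EventAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tgene_id\tevent_id\tinclusion_transcripts\t"
            "total_transcripts\tstart\tend\tstrand\n"
        )
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t"
                f"{','.join(sorted(ev.inclusion_transcripts))}\t"
                f"{','.join(sorted(ev.total_transcripts))}\t"
                f"{ev.start}\t{ev.end}\t{ev.strand}\n"
            )


def compute_psi(
    tpm: pd.DataFrame,
    events: list[EventAnnotation],
    min_total_tpm: float = DEFAULT_MIN_TOTAL_TPM,
) -> pd.DataFrame:
    """Compute the event x sample PSI matrix from transcript TPMs."""
    needed = set().union(*(ev.total_transcripts for ev in events)) if events else set()
    missing = sorted(needed - set(tpm.index))
    if missing:
        raise KeyError(f"transcripts absent from the TPM matrix: {missing[:10]}")
    values = np.empty((len(events), tpm.shape[1]))
    for i, ev in enumerate(events):
        inc = tpm.loc[sorted(ev.inclusion_transcripts)].to_numpy().sum(axis=0)
        tot = tpm.loc[sorted(ev.total_transcripts)].to_numpy().sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = np.where(tot > 0, inc / np.where(tot > 0, tot, 1.0), np.nan)
        psi = np.where(tot < min_total_tpm, np.nan, psi)
        values[i] = psi
    return pd.DataFrame(values, index=[ev.event_id for ev in events], columns=tpm.columns)


def delta_psi(a: pd.DataFrame, b: pd.DataFrame, aggregate: str = "median") -> pd.Series:
    """Per-event aggregate(a) - aggregate(b), skipping missing values.

    Events where either side is entirely missing come back as NaN.
    """
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both column groups must be non-empty")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    b = b.reindex(a.index)
    agg_a = getattr(a, aggregate)(axis=1, skipna=True)
    agg_b = getattr(b, aggregate)(axis=1, skipna=True)
    return agg_a - agg_b
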