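"""Planted ground truth carried alongside the simulated data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroundTruth"]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    pathway_labels: dict[str, str]            # pathway -> prenatal | postnatal
    exon_labels: dict[str, str]               # event -> EP | EN | null
    csf_set: set[str]
    sf_ids: list[str]
    driver_weights: dict[str, float]          # CSF drivers of the PSI link
    neg_regulators: dict[str, float]          # negative-weight factors
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_tf: str | None = None
    mutated_samples: dict[str, set[str]] = field(default_factory=dict)
    domain_planted: dict[str, str] = field(default_factory=dict)
    sample_reactivation: "pd.Series | None" = None   # tumor sample -> strength

    def __post_init__(self) -> None:
        labels = set(self.exon_labels.values())
        if not labels <= {"EP", "EN", "null"}:
            raise ValueError(f"unexpected exon labels: {labels}")
        if not self.csf_set <= set(self.sf_ids):
            raise ValueError("csf_set must be a subset of the splicing factors")

    @property
    def ncsf_set(self) -> set[str]:
        return set(self.sf_ids) - self.csf_set

    def events_with_label(self, label: str) -> set[str]:
        return {e for e, lab in self.exon_labels.items() if lab == label}
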