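"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["SimConfig"]


@dataclass
class SimConfig:
    """Parameters of the synthetic two-program developmental model.

    The defaults are sized so that a full generate-and-analyse cycle runs
    in a few seconds while leaving every planted signal recoverable by the
    downstream modules at their documented thresholds.
    """

    # cohort / feature sizes
    n_genes: int = 1200
    n_pathways: int = 60
    genes_per_pathway: int = 15
    frac_prenatal_pathways: float = 0.5
    n_timepoints_pre: int = 12
    n_timepoints_post: int = 20
    n_events: int = 2000
    frac_ep: float = 0.15
    frac_en: float = 0.15
    n_sf: int = 442
    n_csf: int = 100
    n_tumor: int = 100
    n_normal: int = 50

    # signal and noise
    reactivation_strength: float = 0.5
    noise_sd: float = 0.3
    psi_noise_sd: float = 0.4
    seed: int = 0

    # latent-program shape
    switch_steepness: float = 2.0
    program_amplitude: float = 3.0
    base_log_expr: float = 3.0
    pathway_noise_sd: float = 1.2
    reactivation_cv: float = 0.3

    # PSI link
    psi_gain_low: float = 1.8
    psi_gain_high: float = 2.6
    psi_low: float = 0.2

    # causal structure within the CSF set
    n_driver_csf: int = 4
    n_neg_reg: int = 6

    # cancer-cohort extras
    n_mut_csf: int = 4
    n_mut_neg: int = 4
    mut_frac: float = 0.08
    cnv_base_rate: float = 0.05
    cnv_gain_slope: float = 0.6

    # annotation / domains
    domain_planted_frac: float = 0.5
    domain_background_rate: float = 0.05
    n_decoy_domains: int = 8

    # regulatory layer
    n_decoy_tfs: int = 20
    tf_csf_coverage: float = 0.85
    tf_ncsf_rate: float = 0.08
    n_kd_csf: int = 12
    n_kd_ncsf: int = 20
    kd_dpsi: float = 0.2
    kd_efficiency: float = 0.8
    n_kd_controls: int = 4

    def __post_init__(self) -> None:
        counts = (
            "n_genes n_pathways genes_per_pathway n_timepoints_pre "
            "n_timepoints_post n_events n_sf n_csf n_tumor n_normal"
        ).split()
        for name in counts:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.frac_prenatal_pathways < 1:
            raise ValueError("frac_prenatal_pathways must be in (0, 1)")
        if self.frac_ep < 0 or self.frac_en < 0 or self.frac_ep + self.frac_en > 1:
            raise ValueError("need frac_ep, frac_en >= 0 and frac_ep + frac_en <= 1")
        if self.n_csf > self.n_sf:
            raise ValueError("n_csf must not exceed n_sf")
        if self.n_timepoints_pre + self.n_timepoints_post < 8:
            raise ValueError(
                "need at least 8 developmental timepoints for the PC smoothing step"
            )
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("n_genes too small for n_pathways * genes_per_pathway")
        if self.noise_sd < 0 or self.psi_noise_sd < 0 or self.reactivation_strength < 0:
            raise ValueError("noise and reactivation parameters must be nonnegative")
        if self.n_driver_csf > self.n_csf:
            raise ValueError("n_driver_csf must not exceed n_csf")
        if self.n_neg_reg > self.n_sf - self.n_csf:
            raise ValueError("n_neg_reg must fit among the non-CSF factors")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)
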