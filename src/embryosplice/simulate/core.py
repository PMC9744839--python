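"""Two-program developmental simulator with planted ground truth.

The generative model:

* a prenatal latent program p(t) follows a decreasing logistic switch
  centered at the pre/post-natal boundary; the postnatal program is 1-p;
* genes in prenatal (postnatal) pathways load on p (1-p) in log2 space
  with additive Gaussian noise;
* critical splicing factors (CSFs) track p; a small subset of them
  ("drivers") carries the weights of the PSI link; negative regulators
  track 1-p;
* EP event logit-PSI is an affine function of the weighted driver signal
  A(s) = sum_j w_j * (log-expression of driver j, rescaled to program
  units); EN events are mirrored; null events are flat noise;
* tumors re-express p at a per-sample strength r ~ reactivation_strength,
  normals sit at the postnatal state (r = 0);
* nonsense mutations null the mutated driver's term of A in that sample
  (expression is untouched, as for a truncated protein); mutations in
  negative regulators lift a constant repression term instead.

All randomness is drawn from per-output substreams of the master seed, so
adding a new output never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ..psi import EventAnnotation
from .config import SimConfig
from .truth import GroundTruth

__all__ = [
    "Simulator",
    "DevData",
    "CancerData",
    "AnnotationData",
    "RegulatoryData",
    "generate_development",
    "generate_cancer_cohort",
    "generate_annotation",
    "generate_regulatory_layer",
    "transcript_tpm",
]

# fixed substream labels: adding one never reshuffles the others
_STREAMS = {
    "blueprint": 11,
    "development": 12,
    "cancer": 13,
    "annotation": 14,
    "regulatory": 15,
    "knockdown": 16,
}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[label], seed & 0xFFFFFFFF, seed >> 32 & 0xFFFFFFFF])


@dataclass
class DevData:
    expr: pd.DataFrame          # genes + splicing factors x timepoints (TPM)
    psi: pd.DataFrame           # events x timepoints
    pathways: dict[str, set[str]]
    meta: pd.DataFrame          # sample_id index; columns timepoint, stage
    truth: GroundTruth


@dataclass
class CancerData:
    expr: pd.DataFrame
    psi: pd.DataFrame
    mutations: pd.DataFrame     # sample_id, gene, variant_class
    cnv: pd.DataFrame           # splicing factors x samples in {-1, 0, 1}
    meta: pd.DataFrame          # cohort (tumor|normal), stage


@dataclass
class AnnotationData:
    events: list[EventAnnotation]
    exon_bed: pd.DataFrame
    domain_bed: pd.DataFrame
    tss: pd.DataFrame           # gene, chrom, tss, strand


@dataclass
class KnockdownAssay:
    control_psi: pd.DataFrame               # events x control replicates
    kd_psi: dict[str, pd.DataFrame]         # factor -> events x 2 replicates
    kd_expr: pd.DataFrame                   # factor x [control_mean, kd_rep1, kd_rep2]


@dataclass
class RegulatoryData:
    binding: dict[str, set[str]]            # TF -> promoter-bound factors
    knockdown_sets: dict[str, set[str]]     # "TF:cell" -> downregulated factors
    tf_expr: pd.DataFrame                   # TF x cancer-cohort samples (TPM)
    assay: KnockdownAssay


class Simulator:
    """Deterministic blueprint plus the four generator operations."""

    def __init__(self, config: SimConfig):
        self.config = config
        c = config
        bp = _rng(c.seed, "blueprint")

        self.gene_ids = [f"G{i:05d}" for i in range(c.n_genes)]
        self.sf_ids = [f"SF{i:04d}" for i in range(c.n_sf)]
        self.event_ids = [f"EV{i:05d}" for i in range(c.n_events)]

        # pathway membership: disjoint blocks of genes
        self.pathways: dict[str, set[str]] = {}
        self.pathway_ids = [f"PW{i:03d}" for i in range(c.n_pathways)]
        for i, pw in enumerate(self.pathway_ids):
            lo = i * c.genes_per_pathway
            self.pathways[pw] = set(self.gene_ids[lo : lo + c.genes_per_pathway])
        n_pre_pw = round(c.frac_prenatal_pathways * c.n_pathways)
        pre_idx = bp.choice(c.n_pathways, size=n_pre_pw, replace=False)
        self.pathway_labels = {
            pw: ("prenatal" if i in set(pre_idx.tolist()) else "postnatal")
            for i, pw in enumerate(self.pathway_ids)
        }
        # per-gene loading: +1 prenatal program, -1 postnatal, 0 background
        self.gene_loading = np.zeros(c.n_genes)
        self.gene_pathway = np.full(c.n_genes, -1)
        for i, pw in enumerate(self.pathway_ids):
            sign = 1.0 if self.pathway_labels[pw] == "prenatal" else -1.0
            lo = i * c.genes_per_pathway
            self.gene_loading[lo : lo + c.genes_per_pathway] = sign
            self.gene_pathway[lo : lo + c.genes_per_pathway] = i
        self.gene_offsets = bp.normal(0.0, 0.3, size=c.n_genes)
        self.sf_offsets = bp.normal(0.0, 0.3, size=c.n_sf)

        # CSFs, drivers, negative regulators
        csf_idx = bp.choice(c.n_sf, size=c.n_csf, replace=False)
        self.csf_ids = [self.sf_ids[i] for i in sorted(csf_idx.tolist())]
        driver_pick = bp.choice(len(self.csf_ids), size=c.n_driver_csf, replace=False)
        self.driver_ids = [self.csf_ids[i] for i in sorted(driver_pick.tolist())]
        non_csf = [s for s in self.sf_ids if s not in set(self.csf_ids)]
        neg_pick = bp.choice(len(non_csf), size=c.n_neg_reg, replace=False)
        self.neg_ids = [non_csf[i] for i in sorted(neg_pick.tolist())]
        self.driver_weights = {d: 1.0 / c.n_driver_csf for d in self.driver_ids}
        self.neg_boost = {k: 0.35 for k in self.neg_ids}

        # event labels and link parameters
        n_ep = round(c.frac_ep * c.n_events)
        n_en = round(c.frac_en * c.n_events)
        labels = np.array(["EP"] * n_ep + ["EN"] * n_en + ["null"] * (c.n_events - n_ep - n_en))
        bp.shuffle(labels)
        self.event_labels = dict(zip(self.event_ids, labels.tolist()))
        self.event_gain = bp.uniform(c.psi_gain_low, c.psi_gain_high, size=c.n_events)
        self.null_baseline = bp.uniform(logit(0.25), logit(0.75), size=c.n_events)
        self.event_host = [self.gene_ids[i % c.n_genes] for i in range(c.n_events)]

    # ------------------------------------------------------------------
    def _sf_log_expr(self, prog: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Log2 expression of all splicing factors for program levels ``prog``."""
        c = self.config
        x = np.empty((c.n_sf, prog.size))
        csf = np.isin(self.sf_ids, self.csf_ids)
        neg = np.isin(self.sf_ids, self.neg_ids)
        x[:] = c.base_log_expr + self.sf_offsets[:, None]
        x[csf] += c.program_amplitude * prog[None, :]
        x[neg] += c.program_amplitude * (1.0 - prog)[None, :]
        x += rng.normal(0.0, c.noise_sd, size=x.shape)
        return x

    def _gene_log_expr(self, prog: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        c = self.config
        load = self.gene_loading
        x = c.base_log_expr + self.gene_offsets[:, None] + np.where(
            load[:, None] > 0,
            c.program_amplitude * prog[None, :],
            np.where(load[:, None] < 0, c.program_amplitude * (1.0 - prog)[None, :], 0.0),
        )
        # shared per-pathway temporal wobble decorrelates same-class pathways
        if c.pathway_noise_sd > 0:
            eta = rng.normal(0.0, c.pathway_noise_sd, size=(c.n_pathways, prog.size))
            in_pw = self.gene_pathway >= 0
            x[in_pw] += eta[self.gene_pathway[in_pw]]
        x += rng.normal(0.0, c.noise_sd, size=x.shape)
        return x

    def _driver_signal(
        self, sf_log: np.ndarray, nulled: dict[str, np.ndarray] | None = None
    ) -> np.ndarray:
        """A(s) = weighted, program-rescaled driver expression; nulled terms drop."""
        c = self.config
        sf_index = {s: i for i, s in enumerate(self.sf_ids)}
        a = np.zeros(sf_log.shape[1])
        for d, w in self.driver_weights.items():
            i = sf_index[d]
            contrib = (sf_log[i] - c.base_log_expr - self.sf_offsets[i]) / c.program_amplitude
            if nulled is not None and d in nulled:
                contrib = np.where(nulled[d], 0.0, contrib)
            a += w * contrib
        return a

    def _psi_from_signal(
        self,
        signal: np.ndarray,
        rng: np.random.Generator,
        boost: np.ndarray | None = None,
    ) -> np.ndarray:
        """Event x sample PSI from the driver signal (plus mutation boosts)."""
        c = self.config
        n_s = signal.size
        lo = logit(c.psi_low)
        hi = logit(1.0 - c.psi_low)
        z = np.empty((c.n_events, n_s))
        eps = rng.normal(0.0, c.psi_noise_sd, size=z.shape)
        b = np.zeros(n_s) if boost is None else boost
        for i, ev in enumerate(self.event_ids):
            lab = self.event_labels[ev]
            if lab == "EP":
                z[i] = lo + self.event_gain[i] * signal + b
            elif lab == "EN":
                z[i] = hi - self.event_gain[i] * signal - b
            else:
                z[i] = self.null_baseline[i]
        return expit(z + eps)

    @staticmethod
    def _tpm(log_expr: np.ndarray) -> np.ndarray:
        return np.clip(np.exp2(log_expr) - 1.0, 0.0, None)

    # ------------------------------------------------------------------
    def development(self) -> DevData:
        c = self.config
        rng = _rng(c.seed, "development")
        n_t = c.n_timepoints_pre + c.n_timepoints_post
        t = np.arange(n_t, dtype=float)
        boundary = c.n_timepoints_pre - 0.5
        prog = expit(-c.switch_steepness * (t - boundary))

        samples = [
            f"dev_{'pre' if i < c.n_timepoints_pre else 'post'}_{i:02d}" for i in range(n_t)
        ]
        gene_log = self._gene_log_expr(prog, rng)
        sf_log = self._sf_log_expr(prog, rng)
        expr = pd.DataFrame(
            np.vstack([self._tpm(gene_log), self._tpm(sf_log)]),
            index=self.gene_ids + self.sf_ids,
            columns=samples,
        )
        signal = self._driver_signal(sf_log)
        psi = pd.DataFrame(
            self._psi_from_signal(signal, rng), index=self.event_ids, columns=samples
        )
        meta = pd.DataFrame(
            {
                "timepoint": np.arange(n_t),
                "stage": ["prenatal"] * c.n_timepoints_pre
                + ["postnatal"] * c.n_timepoints_post,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        truth = GroundTruth(
            pathway_labels=dict(self.pathway_labels),
            exon_labels=dict(self.event_labels),
            csf_set=set(self.csf_ids),
            sf_ids=list(self.sf_ids),
            driver_weights=dict(self.driver_weights),
            neg_regulators=dict(self.neg_boost),
        )
        return DevData(expr=expr, psi=psi, pathways=dict(self.pathways), meta=meta, truth=truth)

    # ------------------------------------------------------------------
    def cancer(self, truth: GroundTruth) -> CancerData:
        c = self.config
        rng = _rng(c.seed, "cancer")
        n = c.n_tumor + c.n_normal
        tumor_ids = [f"tumor_{i:03d}" for i in range(c.n_tumor)]
        normal_ids = [f"normal_{i:03d}" for i in range(c.n_normal)]
        samples = tumor_ids + normal_ids

        r_tumor = np.clip(
            c.reactivation_strength
            * (1.0 + c.reactivation_cv * rng.standard_normal(c.n_tumor)),
            0.0,
            1.0,
        )
        prog = np.concatenate([r_tumor, np.zeros(c.n_normal)])

        gene_log = self._gene_log_expr(prog, rng)
        sf_log = self._sf_log_expr(prog, rng)
        expr = pd.DataFrame(
            np.vstack([self._tpm(gene_log), self._tpm(sf_log)]),
            index=self.gene_ids + self.sf_ids,
            columns=samples,
        )

        # nonsense mutations: drivers (effect nulled) + negative regulators
        mut_targets = self.driver_ids[: c.n_mut_csf] + self.neg_ids[: c.n_mut_neg]
        n_mut = min(max(2, round(c.mut_frac * c.n_tumor)), c.n_tumor)
        # when they fit, assign disjoint blocks of a single permutation so
        # planted effects never cancel within a sample; fall back to
        # overlapping draws at high mutation fractions
        disjoint = bool(mut_targets) and n_mut * len(mut_targets) <= c.n_tumor
        perm = rng.permutation(c.n_tumor)
        nulled: dict[str, np.ndarray] = {}
        boost = np.zeros(n)
        mut_rows = []
        mutated_samples: dict[str, set[str]] = {}
        for fi, factor in enumerate(mut_targets):
            if disjoint:
                pick = perm[fi * n_mut : (fi + 1) * n_mut]
            else:
                pick = rng.choice(c.n_tumor, size=n_mut, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[pick] = True
            mutated_samples[factor] = {tumor_ids[i] for i in pick}
            for i in pick:
                mut_rows.append((tumor_ids[i], factor, "Nonsense_Mutation"))
            if factor in self.driver_weights:
                nulled[factor] = mask
            else:
                boost = boost + np.where(mask, self.neg_boost[factor], 0.0)
        # benign missense noise to exercise variant-class whitelists downstream
        for _ in range(c.n_tumor // 10):
            s = int(rng.integers(c.n_tumor))
            g = self.sf_ids[int(rng.integers(c.n_sf))]
            mut_rows.append((tumor_ids[s], g, "Missense_Mutation"))
        mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_class"])

        signal = self._driver_signal(sf_log, nulled=nulled)
        psi = pd.DataFrame(
            self._psi_from_signal(signal, rng, boost=boost),
            index=self.event_ids,
            columns=samples,
        )

        # CNV: gains preferentially in CSFs of high-reactivation tumors
        cnv = np.zeros((c.n_sf, n), dtype=int)
        csf_mask = np.isin(self.sf_ids, self.csf_ids)
        p_gain = np.full((c.n_sf, n), c.cnv_base_rate)
        p_gain[np.ix_(csf_mask, np.arange(c.n_tumor))] = np.clip(
            c.cnv_base_rate + c.cnv_gain_slope * r_tumor[None, :], 0.0, 0.9
        )
        u = rng.random((c.n_sf, n))
        cnv[u < p_gain] = 1
        cnv[(u >= p_gain) & (u < p_gain + 0.03)] = -1
        cnv[:, c.n_tumor :] = 0  # normals are copy-neutral
        cnv_df = pd.DataFrame(cnv, index=self.sf_ids, columns=samples)

        # stage increases with reactivation strength (rank-based tertiles)
        order = np.argsort(r_tumor, kind="mergesort")
        stage_num = np.empty(c.n_tumor, dtype=int)
        stage_num[order] = np.minimum(np.arange(c.n_tumor) * 3 // c.n_tumor + 1, 3)
        meta = pd.DataFrame(
            {
                "cohort": ["tumor"] * c.n_tumor + ["normal"] * c.n_normal,
                "stage": [f"stage{k}" for k in stage_num] + ["na"] * c.n_normal,
            },
            index=pd.Index(samples, name="sample_id"),
        )

        truth.mutated_samples = mutated_samples
        truth.sample_reactivation = pd.Series(r_tumor, index=tumor_ids)
        return CancerData(expr=expr, psi=psi, mutations=mutations, cnv=cnv_df, meta=meta)

    # ------------------------------------------------------------------
    def annotation(self, truth: GroundTruth | None = None) -> AnnotationData:
        c = self.config
        rng = _rng(c.seed, "annotation")
        gene_span = 10_000
        gene_len = 8_000
        all_genes = self.gene_ids + self.sf_ids
        gene_start = {g: i * gene_span for i, g in enumerate(all_genes)}

        events: list[EventAnnotation] = []
        exon_rows = []
        slot_used: dict[str, int] = {}
        for i, ev in enumerate(self.event_ids):
            host = self.event_host[i]
            k = slot_used.get(host, 0)
            slot_used[host] = k + 1
            start = gene_start[host] + 500 + 300 * k
            end = start + 150
            if end > gene_start[host] + gene_len:
                raise RuntimeError("too many events per gene for the toy locus size")
            events.append(
                EventAnnotation(
                    event_id=ev,
                    gene_id=host,
                    chrom="chr1",
                    start=start,
                    end=end,
                    strand="+",
                    inclusion_transcripts=frozenset({f"{ev}.inc"}),
                    total_transcripts=frozenset({f"{ev}.inc", f"{ev}.exc"}),
                )
            )
            exon_rows.append(("chr1", start, end, ev, 0, "+"))
        exon_bed = pd.DataFrame(
            exon_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

        # planted domain covers domain_planted_frac of EP exons + background
        ep_idx = [i for i, ev in enumerate(self.event_ids) if self.event_labels[ev] == "EP"]
        dom_rows = []
        n_plant = round(c.domain_planted_frac * len(ep_idx))
        planted_pick = rng.choice(len(ep_idx), size=n_plant, replace=False) if ep_idx else []
        covered = {ep_idx[j] for j in planted_pick}
        bg_mask = rng.random(c.n_events) < c.domain_background_rate
        for i in range(c.n_events):
            if i in covered or (bg_mask[i] and i not in covered):
                s, e = exon_rows[i][1], exon_rows[i][2]
                dom_rows.append(("chr1", max(0, s - 20), e + 20, "DOM_planted", 0, "+"))
        decoy_names = [f"DOM_decoy{j:02d}" for j in range(c.n_decoy_domains)]
        for name in decoy_names:
            hit = rng.random(c.n_events) < c.domain_background_rate
            for i in np.flatnonzero(hit):
                s, e = exon_rows[i][1], exon_rows[i][2]
                dom_rows.append(("chr1", max(0, s - 20), e + 20, name, 0, "+"))
        domain_bed = (
            pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
            .drop_duplicates(subset=["name", "chrom", "start", "end"])
            .reset_index(drop=True)
        )

        tss = pd.DataFrame(
            {
                "gene": all_genes,
                "chrom": "chr1",
                "tss": [gene_start[g] for g in all_genes],
                "strand": "+",
            }
        )
        if truth is not None:
            truth.domain_planted = {"DOM_planted": "EP"}
        return AnnotationData(events=events, exon_bed=exon_bed, domain_bed=domain_bed, tss=tss)

    # ------------------------------------------------------------------
    def regulatory(self, truth: GroundTruth) -> RegulatoryData:
        c = self.config
        rng = _rng(c.seed, "regulatory")
        if truth.sample_reactivation is None:
            raise ValueError(
                "regulatory layer needs tumor reactivation strengths: "
                "run generate_cancer_cohort first"
            )

        csfs = sorted(truth.csf_set)
        ncsfs = sorted(truth.ncsf_set)
        planted_tf = "TF_planted"
        n_cov = round(c.tf_csf_coverage * len(csfs))
        targets = set(
            np.array(csfs)[rng.choice(len(csfs), size=n_cov, replace=False)].tolist()
        )
        targets |= set(np.array(ncsfs)[rng.random(len(ncsfs)) < c.tf_ncsf_rate].tolist())
        binding: dict[str, set[str]] = {planted_tf: targets}
        decoys = [f"TF_decoy{j:02d}" for j in range(c.n_decoy_tfs)]
        size = len(targets)
        for tf in decoys:
            pick = rng.choice(c.n_sf, size=min(size, c.n_sf), replace=False)
            binding[tf] = {self.sf_ids[i] for i in pick}

        # KnockTF-style downregulated sets; half the decoys lack coverage
        knockdown_sets: dict[str, set[str]] = {}
        for cell in ("cellA", "cellB"):
            keep = np.array(sorted(targets))[rng.random(len(targets)) < 0.85]
            knockdown_sets[f"{planted_tf}:{cell}"] = set(keep.tolist())
        for tf in decoys[: c.n_decoy_tfs // 2]:
            pick = rng.choice(c.n_sf, size=min(size, c.n_sf), replace=False)
            knockdown_sets[f"{tf}:cellA"] = {self.sf_ids[i] for i in pick}

        # TF expression over the cancer cohort (planted TF drives CSFs via r)
        r = truth.sample_reactivation
        samples = list(r.index) + [f"normal_{i:03d}" for i in range(c.n_normal)]
        prog = np.concatenate([r.to_numpy(), np.zeros(c.n_normal)])
        tf_names = [planted_tf] + decoys
        x = np.full((len(tf_names), len(samples)), c.base_log_expr)
        x[0] += c.program_amplitude * prog
        x += rng.normal(0.0, c.noise_sd, size=x.shape)
        tf_expr = pd.DataFrame(self._tpm(x), index=tf_names, columns=samples)

        truth.tf_targets = {tf: set(members) for tf, members in binding.items()}
        truth.planted_tf = planted_tf
        return RegulatoryData(
            binding=binding,
            knockdown_sets=knockdown_sets,
            tf_expr=tf_expr,
            assay=self._knockdown_assay(truth),
        )

    def _knockdown_assay(self, truth: GroundTruth) -> KnockdownAssay:
        """shRNA-style assay: controls plus two replicates per knocked factor."""
        c = self.config
        rng = _rng(c.seed, "knockdown")
        csfs = sorted(truth.csf_set)
        ncsfs = sorted(set(truth.ncsf_set) - set(self.neg_ids))
        kd_factors = (
            [csfs[i] for i in rng.choice(len(csfs), size=min(c.n_kd_csf, len(csfs)), replace=False)]
            + [
                ncsfs[i]
                for i in rng.choice(len(ncsfs), size=min(c.n_kd_ncsf, len(ncsfs)), replace=False)
            ]
        )

        # cell-line baseline: mid reactivation
        base_signal = 0.5
        lo = logit(c.psi_low)
        hi = logit(1.0 - c.psi_low)
        base_logit = np.empty(c.n_events)
        for i, ev in enumerate(self.event_ids):
            lab = self.event_labels[ev]
            if lab == "EP":
                base_logit[i] = lo + self.event_gain[i] * base_signal
            elif lab == "EN":
                base_logit[i] = hi - self.event_gain[i] * base_signal
            else:
                base_logit[i] = self.null_baseline[i]

        ctrl_cols = [f"ctrl_{j}" for j in range(c.n_kd_controls)]
        ctrl = expit(
            base_logit[:, None]
            + rng.normal(0.0, c.psi_noise_sd, size=(c.n_events, c.n_kd_controls))
        )
        control_psi = pd.DataFrame(ctrl, index=self.event_ids, columns=ctrl_cols)
        ctrl_mean = control_psi.mean(axis=1).to_numpy()

        is_ep = np.array([self.event_labels[e] == "EP" for e in self.event_ids])
        is_en = np.array([self.event_labels[e] == "EN" for e in self.event_ids])
        kd_psi: dict[str, pd.DataFrame] = {}
        expr_rows = []
        ctrl_expr = 2.0**c.base_log_expr - 1.0
        for factor in kd_factors:
            shift = np.zeros(c.n_events)
            if factor in truth.csf_set:
                shift[is_ep] = -c.kd_dpsi
                shift[is_en] = c.kd_dpsi
            reps = np.clip(
                ctrl_mean[:, None]
                + shift[:, None]
                + rng.normal(0.0, 0.05 * c.psi_noise_sd, size=(c.n_events, 2)),
                0.0,
                1.0,
            )
            kd_psi[factor] = pd.DataFrame(
                reps, index=self.event_ids, columns=["kd_rep1", "kd_rep2"]
            )
            kd_level = ctrl_expr * (1.0 - c.kd_efficiency)
            expr_rows.append((factor, ctrl_expr, kd_level, kd_level))
        kd_expr = pd.DataFrame(
            expr_rows, columns=["factor", "control_mean", "kd_rep1", "kd_rep2"]
        ).set_index("factor")
        return KnockdownAssay(control_psi=control_psi, kd_psi=kd_psi, kd_expr=kd_expr)


# ----------------------------------------------------------------------
# module-level operations


def generate_development(config: SimConfig) -> DevData:
    return Simulator(config).development()


def generate_cancer_cohort(truth: GroundTruth, config: SimConfig) -> CancerData:
    return Simulator(config).cancer(truth)


def generate_annotation(config: SimConfig, truth: GroundTruth | None = None) -> AnnotationData:
    return Simulator(config).annotation(truth)


def generate_regulatory_layer(truth: GroundTruth, config: SimConfig) -> RegulatoryData:
    return Simulator(config).regulatory(truth)


def transcript_tpm(annotation: AnnotationData, psi: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Transcript-level TPMs consistent with the given PSI and host expression.

    Each event contributes an inclusion and an exclusion transcript whose
    abundances split the host gene's TPM (plus one, to keep the event
    expressed) according to PSI.
    """
    rows = []
    index = []
    for ev in annotation.events:
        total = expr.loc[ev.gene_id].to_numpy() + 1.0
        p = psi.loc[ev.event_id].to_numpy()
        rows.append(p * total)
        index.append(f"{ev.event_id}.inc")
        rows.append((1.0 - p) * total)
        index.append(f"{ev.event_id}.exc")
    return pd.DataFrame(np.vstack(rows), index=index, columns=psi.columns)
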