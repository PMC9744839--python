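# embryosplice

A tested, reusable pipeline for identifying developmental exon-skipping
programs and their reactivation in cancer:

1. **PSI quantification** — exon-skip percent-spliced-in from transcript
   TPMs and an inclusion/total transcript annotation (`psi`).
2. **Pathway activity** — median log2(TPM+1) pathway scores over a
   developmental time course, PCA-cosine smoothing, and Ward clustering
   into embryonic-positive / embryonic-negative pathways (`pathways`).
3. **EP/EN exon calling** — per-exon Pearson correlation against every
   pathway with per-exon BH correction; an exon is embryonic-positive
   (EP) when significantly positively correlated with ≥10% of the
   embryonic-positive pathways (and ≤5% in the opposite direction);
   embryonic-negative (EN) mirrors (`exons`).
4. **Cancer events** — tumors deviating ≥2 normal-cohort SDs in ≥15% of
   patients define frequently increased/decreased events; Fisher overlap
   enrichment with EP/EN sets, stage-stratified variants, signature and
   phenotype correlation analyses (`cancer`).
5. **Protein domains** — interval merge + overlap mapping of domain
   tracks onto exons; per-domain Fisher enrichment (OR > 1, q < 0.1)
   among EP and EN exons vs background alternative exons (`domains`).
6. **Splicing regulators** — PLS regression of median EP inclusion on
   splicing-factor expression (components by LOO-CV, significance by
   jackknife over the LOO refits); critical splicing factors (CSFs) =
   positive coefficient with q < 0.05; cross-cohort prediction;
   expression-matched mutation effects; shRNA knockdown response; CNV
   stratification (`regulators`).
7. **TF cascade** — promoter-binding, knockdown, network, and
   expression-correlation filters combined as
   `chip AND (knockdown OR (network AND correlation))` (`tf`).
8. **Synthetic data** — a deterministic two-program developmental
   simulator (`simulate`) that plants every signal above with known
   ground truth, so the whole pipeline is testable offline.

## Command line

Each stage is a subcommand of `embryosplice`; the whole flow runs from a
YAML config:

```bash
# generate a synthetic world with planted ground truth
embryosplice simulate --outdir inputs/ --seed 1

# individual stages
embryosplice psi --tpm tpm.tsv --events events.tsv -o psi.tsv
embryosplice pathways --expr expr.tsv --gmt pathways.gmt --meta samples.tsv -o out/
embryosplice classify-exons --psi psi.tsv --activity out/activity.tsv \
    --labels out/pathway_labels.tsv -o exon_labels.tsv
embryosplice cancer-events --tumor tumor_psi.tsv --normal normal_psi.tsv -o calls.tsv
embryosplice domains --track pfam.bed --exons exons.bed --labels exon_labels.tsv -o dom.tsv
embryosplice plsr fit --expr expr.tsv --psi psi.tsv --exon-labels exon_labels.tsv \
    --factors sf_list.txt -o model.json
embryosplice tf-filter --chip chip.gmt --knock knock.gmt --network net.gmt \
    --expr tf_expr.tsv --sf-expr sf_expr.tsv --csf csf.txt --ncsf ncsf.txt -o evidence.tsv

# everything at once (simulate + all stages + manifest with checksums)
embryosplice run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
outdir: run
seed: 1
simulate: true
sim: {}            # overrides for the simulation config
thresholds: {}     # e.g. {min_frac: 0.15, pos_frac: 0.10}
```

Exit codes: 0 success, 2 config error, 3 data error.

## Layout

```
src/embryosplice/
  _stats.py      shared Fisher/BH/Pearson primitives (single implementation)
  io.py          TSV / GMT / BED readers and writers
  psi.py         event annotation + PSI quantification
  pathways.py    activity scoring, PC-cosine smoothing, embryonic labels
  exons.py       exon-pathway correlation screen, EP/EN calling
  cancer.py      frequent-event caller + enrichment analyses
  domains.py     interval merge/map + domain enrichment
  regulators.py  PLSR model, CSF calls, mutation/knockdown/CNV statistics
  tf.py          four-filter TF regulator cascade
  simulate/      synthetic-data generator with planted ground truth
  evaluation.py  end-to-end recovery metrics (shared by tests + acceptance)
  pipeline.py    stage orchestration, manifest, checksums
  cli.py         click CLI
```
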