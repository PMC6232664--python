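# zebramet

Untargeted LC-MS metabolomics analysis for drug-induced renal injury (DIRI)
studies in zebrafish larvae: from an aligned feature-intensity table to a
Venn partition of common versus drug-specific toxicity markers.

Zebrafish larvae exposed to nephrotoxic drugs (gentamicin, paracetamol,
tenofovir disoproxil fumarate "TDF", tenofovir "TFV") at their LC10 and
half-LC10 concentrations show metabolic changes measurable by untargeted
LC-MS. Extracting the toxicity signal from such a feature table requires a
chain of corrections before any model sees the data, and a supervised
contrast afterwards. `zebramet` implements that chain as a tested,
reusable pipeline for analysts working with aligned feature tables
(features × samples, with per-feature *m/z* and retention time):

1. **QC-pool RSD filter** — keep features with relative standard deviation
   ≤ 0.3 across repeated pooled-QC injections.
2. **Normalization** — total-area scaling, then probabilistic quotient
   normalization (PQN): each sample is divided by the median of its
   feature-wise quotients against the median reference spectrum.
3. **Extraction-block correction** — for each feature and extraction batch,
   divide by the factor *block mean / overall mean*, computed over the
   biological samples; block means are equalized exactly.
4. **Exogenous-compound exclusion** — (i) match features against
   theoretical *m/z* of [M+H]⁺/[M+Na]⁺/[M+K]⁺ adducts and their isotopologues
   of listed contaminants (HEPES buffer, the administered drugs) at 5 ppm;
   (ii) drop every feature with Pearson *r* ≥ 0.9 against a matched feature,
   catching fragments and unlisted satellites.
5. **PCA** (SVD, from scratch) for quality control and structure checks.
6. **Paired PLS-DA** (NIPALS PLS1, from scratch) between LC10 and ½LC10
   per drug, with **VIP** scoring; features with VIP > 1.0 on the first
   component are selected:

   VIP_j = sqrt( J · Σ_a q_a²(t_aᵀt_a) w_ja² / Σ_a q_a²(t_aᵀt_a) ),

   so mean(VIP²) = 1 and VIP > 1 flags above-average contributors.
7. **Venn partition** — features selected for every drug are candidate
   *common* DIRI markers; features selected for exactly one drug are
   *drug-specific* markers.

Because studies of this kind rarely deposit raw data, the package ships a
first-class **simulator** (`zebramet.synthetic_data`) reproducing the study
design — 83 biological samples in 10 dose groups, 12 QC-pool injections
built as pooled means, 4 extraction blocks with per-feature multiplicative
effects, per-sample dilution, shared and drug-specific toxicity signatures,
QC-unstable features, and exogenous contaminants with mass-consistent,
highly correlated adduct/isotope/fragment satellites — with complete ground
truth, so every stage is testable end to end.

## Worked example

```python
from zebramet import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(out_dir="demo", simulation=SimulationConfig(), seed=1)
result = run_pipeline(config)
stages = result.manifest["stages"]
print("features kept after QC filter:", stages["qc_filter"]["n_kept"])
print("exogenous features excluded:", stages["exogenous_exclusion"]["n_excluded"])
for drug in ("paracetamol", "tdf", "tfv"):
    m = stages["plsda"][f"{drug}:lc10-vs-half_lc10"]
    print(f"{drug}: r2y(comp1)={m['r2y_comp1']:.3f}, selected={m['n_selected']}")
print("Venn:", stages["venn"])
```

prints

```
features kept after QC filter: 415
exogenous features excluded: 22
paracetamol: r2y(comp1)=0.988, selected=148
tdf: r2y(comp1)=0.989, selected=151
tfv: r2y(comp1)=0.994, selected=163
Venn: {'common': 108, 'specific:paracetamol': 25, 'specific:tdf': 28,
       'specific:tfv': 43, 'shared:tdf+tfv': 6, 'shared:paracetamol+tfv': 6,
       'shared:paracetamol+tdf': 9}
```

Of the 445 simulated features, the 30 QC-unstable ones fall to the RSD
filter and all 22 injected contaminant features (parents plus satellites)
are excluded; the paired models then recover most of the 119 injected
common-toxicity features in the Venn common region (here 107 of the 108
listed are true positives; the manifest's `recovery` block reports the
exact rates). Gentamicin is simulated with no effect and its models are
fitted only as diagnostics, mirroring its behaviour as a negative example.

The same run is available from the shell:

```sh
zebramet simulate --seed 1 --out sim/
zebramet run-all --config pipeline.yaml
```

with per-stage subcommands (`filter`, `normalize`, `correct-blocks`,
`exclude`, `pca`, `plsda`, `select-markers`) for stepwise use. Every stage
writes CSV artifacts plus a `manifest.json` with the seed, a config hash,
and per-stage summaries, so any stage can be re-run reproducibly from its
persisted inputs.

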