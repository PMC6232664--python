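# Methods

This note documents the statistical model behind `zebramet`'s synthetic
data generator, the numerical conventions of each pipeline stage, and the
design decisions taken where the analysis convention was genuinely open.

## The data-generating model

All structure is multiplicative (log-normal): LC-MS intensities are
positive and their noise scales with signal. The intensity of endogenous
feature *j* in biological sample *i* is

    x_ji = base_j · block_{j,b(i)} · dilution_i · effect_{ji} · bio_{ji} · eps_ji

with

- `base_j` — a per-feature baseline, log-normal with log-mean 11.5 and
  log-SD 1.0 (median ≈ 1×10⁵ counts, spanning roughly three decades, a
  typical spread for an aligned feature list above a noise floor of ~10⁴);
- `block_{j,b}` — per-(feature, block) extraction effect,
  exp(N(0, 0.25)): every feature responds differently to each extraction
  batch, which is exactly the situation the per-variable quotient
  correction addresses;
- `dilution_i` — per-sample factor exp(N(0, 0.2)), the target of
  total-area + PQN normalization;
- `effect_{ji}` — the toxicity signal: fold 2.0 at LC10 and 1.2 at ½LC10
  for common features in any effect drug's samples and for drug-specific
  features in their drug's samples, direction (up or down) drawn once per
  feature; gentamicin carries no effect (fold 1.0) so the pipeline
  exercises a realistic negative;
- `bio_{ji}` — biological replicate variation, CV 0.25. Each column is an
  independent pool of larvae, so metabolite levels scatter between samples
  beyond dilution and batch effects. This term matters: without it, a
  drug-specific marker and that drug's contaminant parent would deviate
  from baseline in the same single exposure group and nothing else, making
  them nearly collinear, and the correlation-propagation step would
  wrongly swallow genuine markers. A 25% between-replicate CV is a
  mid-range value for pooled-organism metabolomics;
- `eps_ji` — analytical (injection) noise, CV 0.05.

**QC pools.** Each of the 12 QC injections is the arithmetic mean of all
biological pre-noise columns (mirroring physical pooling of reconstituted
extracts) times analytical noise and an extra QC-injection CV of 0.05.
Thirty "unstable" features get QC replicate scatter drawn uniformly from
CV 0.35–0.8 instead; the drawn noise vector is rescaled so the *realized*
12-replicate RSD equals the drawn target exactly. This pins the
unstable/stable ground truth: a raw log-normal draw at CV 0.35 would land
below the 0.3 filter threshold in a non-trivial fraction of 12-replicate
samples, turning the truth label into a coin flip.

**Contaminants.** Five compound families (HEPES buffer plus the four
drugs) contribute 22 features: one parent each and 5 (HEPES) or 3 (drugs)
satellites. Parents of drug compounds are zero in unexposed samples and
dose-proportional in exposed ones (½LC10 = half the LC10 level); HEPES is
present in every biological sample. Satellite features are the parent
molecule's other ions (M+Na, M+K, M+1, M+2, and a water-loss in-source
fragment): they share the parent's biological draw and block factor — the
same molecule in the same extract — at a fixed response ratio drawn from
U(0.1, 0.6), so their correlation with the parent is near 1 by
construction. Satellite *m/z* values are placed at the exact theoretical
offsets (±2 ppm error), and endogenous *m/z* values are rejection-sampled
to stay > 20 ppm from every theoretical contaminant ion, so mass matching
has unambiguous ground truth. The water-loss fragment is deliberately
absent from the theoretical ion table: it exists to exercise the
correlation step.

**Design.** Group sizes follow the study design (10 per tier for
gentamicin/paracetamol/TDF, 5 for TFV, 6 + 7 unexposed controls, 83
total). The two control arms are both unexposed and are encoded as
drug `none`, tier `control`. Biological samples are assigned to the four
extraction blocks round-robin within each (drug, tier) condition after a
seeded shuffle, guaranteeing that every condition appears in every block —
the balance that prevents the block correction from absorbing the drug
effect.

### What the simulator does not emulate

Chromatographic reality (peak shapes, retention-time drift, co-elution
beyond shared satellite RT), injection-order sensitivity drift, missing
values (matrices are complete, matching a feature list required present in
all QC pools), heteroscedastic "vest-pocket" noise at the detection limit,
correlated endogenous pathways (background features are independent), and
nonlinear dose-response. Passing recovery tests therefore demonstrates
that the pipeline's logic is correct under the design's assumptions, not
that real data meet those assumptions.

## Stage conventions

- **RSD filter**: sample SD (ddof = 1) over QC columns divided by the QC
  mean; threshold 0.3, boundary inclusive (≤ kept). Features with zero QC
  mean are reported with RSD +∞ and removed. Only QC columns influence the
  keep set.
- **Total area**: each column divided by its own sum (target sum 1; any
  positive constant is equivalent, 1 is testable).
- **PQN**: reference = per-feature median over *all* samples (the usual
  convention; a QC-only reference is available as an option). Features
  with zero reference are omitted from the quotient median but still
  rescaled. Order is total-area first, then PQN.
- **Block correction**: factors = block mean / overall mean per feature,
  computed over biological samples only — QC pools are pooled across
  blocks and pass through unchanged. Correction divides by the factor,
  which equalizes block means exactly (machine precision) and is
  idempotent. It runs on normalized, *unscaled* intensities: centering to
  mean 0 would destroy the quotient's meaning.
- **Exogenous exclusion**: adduct shifts +1.007276 (H), +22.989218 (Na),
  +38.963158 (K) Da; isotopologue spacing 1.003355 Da; charge 1; ppm
  tolerance 5, inclusive. Step 2 uses Pearson correlation over biological
  samples only (QC pools are cross-sample averages and would inflate
  correlations), a *signed* threshold r ≥ 0.9 (anti-correlated features
  are never removed), and a single pass anchored on step-1 features — no
  transitive closure. Constant features correlate 0 with everything.
- **Autoscaling**: per feature, mean 0 and sample SD 1 (ddof = 1);
  constant features are centered, left at zero, and flagged. Scaling is
  recomputed fresh inside each statistical model on that model's own
  sample subset, never inherited from the global matrix.
- **PCA**: SVD of the autoscaled matrix; explained fraction
  σ_a²/Σσ²; deterministic sign (largest-|loading| entry positive);
  components beyond the rank carry zero variance and a warning.
- **PLS-DA**: PLS1-NIPALS on a +1/−1 coded, centered response (two-class
  problems are exactly encodable in one response; any affine recoding
  leaves component-1 weights parallel). Up to min(5, n−1, J) components
  are fitted; selection uses VIP on component 1 only — the component
  responsible for class separation — with a strict VIP > 1.0 cut. r2y per
  component = q_a²(t_aᵀt_a)/‖y₀‖²; component 1's r2y is the separation
  diagnostic. Degenerate deflation truncates the model with a flag.
- **Venn partition**: regions are exact membership combinations (common =
  all drugs, specific = exactly one, shared pairs = exactly two); they are
  mutually disjoint and cover the union by construction.
- **Pipeline order**: filter → total-area → PQN → block correction →
  exogenous exclusion → PCA → paired PLS-DA → Venn. The block correction
  is applied unconditionally, and the manifest reports the block-label
  silhouette in PC1–2 score space before and after so the user can see
  the batch effect's footprint disappear. LC10 vs ½LC10 is the
  marker-defining contrast (both groups are exposed, so the comparison
  isolates toxicity from exposure); control-vs-tier models are fitted and
  logged as diagnostics only.

## Problem sizes

Recovery properties (marker sensitivity, contaminant capture, PQN and
block-factor recovery, null-drug ordering) are evaluated over 20
independent simulations at the full study design (445 features, 95
columns), which gives rate estimates stable to a few percent while keeping
the whole suite fast; exact algebraic identities are checked at full scale
on single tables, and closed-form oracles on miniature hand-built
matrices.

## Known limitations

- Formula parsing and monoisotopic masses come from `pyteomics`; only
  singly charged positive adducts (H, Na, K) are enumerated, by design —
  other adducts and in-source fragments are the correlation step's job.
- Gentamicin is a mixture; the shipped screening list uses the C1
  congener's formula. Users with other instruments or buffers should
  extend the compound CSV.
- The exclusion step can remove a genuine endogenous feature that happens
  to correlate ≥ 0.9 with a contaminant; the simulator quantifies this
  false-exclusion rate (reported in the manifest) but on real data it is
  unobservable.
- PLS-DA r2y on component 1 is an in-sample diagnostic. With many more
  features than samples it is optimistic (a no-effect contrast still
  reaches high r2y by overfitting); the pipeline uses it only for
  *ranking* contrasts, and no cross-validated component selection or
  permutation testing is implemented.
- The VIP > 1 rule has no error control; selected features are candidates
  for annotation, not confirmed markers.
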