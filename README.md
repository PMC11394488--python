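# damil

Dual-attention multiple-instance learning (DAMIL) for predicting 5-year
cancer recurrence from whole-slide images, with survival-based risk
stratification. The package implements the full pipeline end-to-end and
ships a synthetic-data module so every stage is testable offline with
known ground truth.

## Pipeline

1. **Preprocessing** (`damil.preprocess`) — tissue foreground via
   HSV-saturation thresholding, non-overlapping 896-px patch grids at the
   base magnification, and patch encoding behind a pluggable
   `PatchEncoder` interface (a deterministic color-histogram `ToyEncoder`
   is bundled; any pretrained encoder honoring the contract plugs in).
2. **Tumor-bulk restriction** (`damil.tumor_bulk`) — a pluggable patch
   classifier scores patches, scores are rasterized to a patch-grid mask,
   refined by binary closing, small-object removal and per-component
   convex-hull filling, and bags are restricted to tumor-bulk rows.
3. **Key set** (`damil.keyset`) — per training slide, the bag rows with
   the highest statistical leverage (projection onto the top-r singular
   subspace, r chosen by a spectral-energy rule) are concatenated across
   both classes into one joint key set `K` (D x tau).
4. **Aggregator** (`damil.model`) — cross-attention of the embedded key
   set against the bag (softmax over instances, scaled by 1/sqrt(Dh)),
   a tanh/sigmoid gated attention over the tau outputs, and an affine
   two-class head. Implemented in NumPy with hand-derived gradients that
   are verified against finite differences; a pure-loop reference
   implementation cross-checks the vectorized path.
5. **Training / CV** (`damil.training`) — Adam (lr 8e-5, weight decay
   1e-5), batch size one, inverse-class-frequency weighted sampling,
   early stopping (5 initial epochs + 5 patience, 50 max), and
   patient-level stratified five-fold cross-validation with leakage
   guards (key-set provenance is checked against validation/test slides).
6. **Evaluation** (`damil.survival`) — AUROC/accuracy/specificity/
   sensitivity per fold, patient-level aggregation (max-slide rule),
   univariate Cox proportional hazards (Breslow ties, Newton iteration,
   Wald CI), Kaplan–Meier tables, and a Pearson chi-squared association
   utility.

## CLI

```bash
damil simulate  --config config.yaml --out sim/ --seed 1   # synthetic cohort: bags.h5 + cohort.csv
damil preprocess --slide slide.png --out emb.h5            # tissue -> patches -> embeddings
damil segment   --slide slide.png --out seg/               # tumor-bulk mask (PNG + JSON sidecar)
damil keyset    --bags sim/bags.h5 --out keyset.h5         # leverage key set
damil crossval  --bags sim/bags.h5 --cohort sim/cohort.csv --out run/
damil evaluate  --pred run/predictions.csv --cohort sim/cohort.csv --out report/
damil run       --config config.yaml --out run/ --seed 1   # end-to-end pipeline
```

Configuration is YAML validated against a strict schema (unknown keys
rejected); see `damil.config.PipelineConfig` for all sections and
defaults. Per-stage seeds are derived from the global seed by fixed
offsets, and `damil run` writes a manifest with stage digests so reruns
are reproducible.

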