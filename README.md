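# lsnquant

Semi-automated liver surface nodularity (LSN) quantification for 2-D
abdominal MR slices, plus the diagnostic-statistics layer used to relate
LSN scores to fibrosis stage.

The pipeline:

1. **Bias correction + segmentation** (`lsnquant.segmentation`) — the slice
   is modelled as `I = b·J + n` (multiplicative slowly-varying bias `b`,
   piecewise-constant true image `J`, Gaussian noise). A two-phase local
   intensity clustering level-set energy is minimised by alternating an
   explicit, backtracking gradient step in the level-set field with the
   closed-form updates of the two cluster levels and the bias field.
2. **Surface line** (`lsnquant.surface`) — sub-pixel marching-squares
   boundary of the liver mask, ordered, resampled to 1-px arc-length steps,
   lightly smoothed, and sliced into ≥ 3 ROIs (reader CSV or automatic
   equal spacing).
3. **Nodularity score** (`lsnquant.nodularity`) — each ROI is rotated into
   its principal-axis frame and fitted with an order-2/3/4 polynomial by
   ordinary least squares; the per-ROI score is the RMS of the residuals
   and the subject score is the arithmetic mean over ROIs.
4. **Statistics** (`lsnquant.diagstats`) — Kruskal–Wallis, Mann–Whitney
   (exact for small tie-free samples), Wilcoxon signed-rank, CV, ICC(2,1)
   with Shrout–Fleiss intervals, and ROC analysis with DeLong CIs and a
   Youden-optimal "greater than t" cutoff.
5. **Phantoms** (`lsnquant.phantom`) — seeded synthetic slices with a
   star-convex liver whose boundary nodularity amplitude, bias field and
   noise are all controllable ground truth, so the whole pipeline is
   testable without patient data.

## CLI

```sh
# generate a phantom with known nodularity amplitude
lsn phantom --out ph/ --seed 3 --amplitude 2 --noise-sd 3

# measure a slice end to end (here using the ground-truth mask override)
lsn measure ph/phantom.nii --out meas/ --override-mask ph/true_mask.png

# full run with level-set segmentation, 4th-order fits, mm units
lsn measure scan.nii --out meas/ --order 4 --units mm

# cohort statistics (group tests, fibrosis strata, ROC tables)
lsn stats cohort.csv --out report/

# standalone ROC analysis of a score,label CSV
lsn roc scores.csv --out roc.json
```

`measure` accepts a TOML config (`--config run.toml`, schema-validated,
unknown keys rejected), reader-style ROI CSVs (`--roi-file`, repeatable for
repeat-measurement averaging), and a PNG mask override replacing the
level-set stage. Every run writes deterministic result JSON plus a
separate provenance/run log.

## Notes on units

Scores default to pixels ("pixel-by-pixel" residuals); `--units mm`
multiplies by the pixel spacing. Phantom scores live on the discretisation
scale of the rasterised boundary (≈ 0.06 px floor) and are not claimed to
land on any particular clinical scale.
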