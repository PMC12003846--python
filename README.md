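# fmriscrub

Motion censoring and connectome-level motion QC for resting-state fMRI.

`fmriscrub` implements an evaluation pipeline for volume censoring in
rs-fMRI: motion metrics (framewise displacement, scaled DVARS, tSNR),
one-step simultaneous censoring + nuisance regression + bandpass
filtering, functional-connectivity profiles with autocorrelation-corrected
Fisher z-scores, connectome-based prediction of motion and biological
targets with permutation nulls, and voxel-level seed-map group contrasts
with cluster-extent thresholding. A synthetic-data generator with known
ground truth (motion spikes, spike-locked distance-dependent BOLD
artifacts, planted covariate effects) exercises every stage end to end.

## Package layout

| module | contents |
| --- | --- |
| `fmriscrub.types` | shared domain types (motion traces, censor masks, ROI series, ...) |
| `fmriscrub.io` | TSV/JSON/NIfTI readers and writers |
| `fmriscrub.metrics` | FD, scaled DVARS, tSNR, motion summaries, FD-vs-sDVARS concordance |
| `fmriscrub.censoring` | censor masks, motion/tissue/spectral nuisance designs, one-step cleaning |
| `fmriscrub.connectivity` | FC matrices and profiles, motion-association screens, BH-FDR, distance analysis |
| `fmriscrub.prediction` | connectome-based SVR/SVC prediction with fold-internal selection and permutation nulls |
| `fmriscrub.clusters` | seed maps, group t-tests, cluster-extent thresholding, motion subgroups |
| `fmriscrub.simulate` | synthetic multi-scan datasets with recoverable ground truth |
| `fmriscrub.pipeline` | end-to-end orchestration shared by the CLI and evaluation |
| `fmriscrub.evaluation` | calibration and direction-of-effect experiments |

## CLI

All subcommands are deterministic given their inputs and `--seed`:

```bash
# generate a synthetic dataset with known ground truth
fmriscrub simulate --seed 7 --n-scans 20 --n-roi 30 --out-dir data/

# framewise displacement from a 6-parameter motion file
fmriscrub fd --motion data/scan000_motion.par --tr 3 --radius 35 --out fd.tsv

# censor mask + motion summary at an FD threshold
fmriscrub censor --fd fd.tsv --threshold 1.5 --out-dir qc/

# one-step censoring + nuisance regression + 0.01-0.1 Hz bandpass
fmriscrub regress --bold data/scan000_bold.tsv --motion data/scan000_motion.par \
    --tissue data/scan000_tissue.tsv --regressors 12 --out-dir clean/

# FC matrix and profile
fmriscrub connect --clean clean/clean_bold.tsv --meta clean/clean_meta.json --out-dir fc/

# across-scan FD-FC association screen
fmriscrub associate --data-dir data/ --threshold 1.5 --out-dir assoc/

# connectome-based prediction with a permutation null
fmriscrub predict --data-dir data/ --target sex --threshold 1.5 --seed 1 --out pred.json

# seed-based correlation map from a 4-D NIfTI
fmriscrub seedmap --image img.nii --brain-mask brain.nii --seed-mask seed.nii --out-dir maps/

# scan-level QC report
fmriscrub qc-report --motion data/scan000_motion.par --out qc.json
```

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which runs the
Monte-Carlo calibration and direction-of-effect experiments (a few
minutes on one CPU); everything else finishes in seconds.

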