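# mgpipe

Analysis pipeline for odour-evoked microglomerular (MG) activity in the
*Drosophila* mushroom-body calyx, and for the reciprocal connectivity of
its inhibitory hub neuron (APL).

In the calyx, each MG couples one projection-neuron (PN) bouton to Kenyon
cell (KC) dendritic claws, and the single GABAergic APL neuron makes
reciprocal synapses with both sides. The scientific question this pipeline
serves: PN boutons respond to different odours with very different
strengths — are those differences *normalized* at the KC claws by
APL-driven inhibition, and is that inhibition local within the calyx?

`mgpipe` implements the full desk-scale workflow:

- **`synthetic_data`** — simulates two-photon calcium movies (planar
  ~9 Hz, or 5-slice volumetric ~16 Hz) of ~5 µm MG blobs in a calyx-shaped
  field, with 5 s odour puffs separated by 20 s clean air, layer- and
  odour-dependent log-normal response amplitudes, photon-scaling noise,
  bleaching and rigid drift — plus APL-hub synapse tables with a linear
  reciprocal-weight law. Every dataset ships with machine-readable ground
  truth, so each stage below is quantitatively testable without downloads.
- **`io_formats`** — multi-page TIFF movies with JSON calibration
  sidecars, stimulus-protocol JSON, delimited synapse tables.
- **`registration`** — integer-pixel translation correction against the
  baseline-window mean.
- **`roi_detection`** — the active-MG detector: minimum-image divisive
  normalization `N = (F − M)/(M + ε)`, a per-trial response image (temporal
  max of N), Otsu thresholding, and 8-connected components kept when their
  area matches the expected 5 µm ROI diameter.
- **`traces`** — per-ROI ΔF/F₀ % traces with F₀ = mean of the first 30
  frames, within-trial peaks (ΔF/F₀ %MAX) and per-trial summaries
  (mean peak over active ROIs).
- **`stats`** — normality-gated paired tests (D'Agostino–Pearson →
  paired t or Wilcoxon), two-sample Kolmogorov–Smirnov on pooled peak
  distributions, per-fly response distances, and the two-factor
  (APL ON/OFF × odour) ANOVA with Tukey contrasts.
- **`volumetric`** — per-z-slice ΔF/F₀ %MAX, across-animal ratio profiles
  between odour pairs (average first, then ratio) and slope comparison via
  the group × slice interaction of a pooled linear model.
- **`connectome`** — calyx-filtered APL synapse tables: per-neuron
  reciprocal weights, weight correlations (r² of APL→PN vs PN→APL counts),
  bouton/claw localization fractions and the KC-subtype comparison.
- **`pipeline` / `mgpipe` CLI** — four end-to-end recipes
  (`planar_contrast`, `apl_on_off`, `volumetric_locality`,
  `connectome_audit`) with a YAML config and a reproducibility manifest.

## Worked example

Simulate one fly's PN-bouton movie (two odours, Oct amplitudes 1.6× Mch),
motion-correct it, detect active MGs per odour trial, and summarize peaks:

```python
import math
from mgpipe import (SimulationConfig, LayerModel, simulate_calyx_movie,
                    register_movie, detect_active_rois, score_detections,
                    extract_traces, summarize_trial)

cfg = SimulationConfig(rng_seed=11, n_puffs_per_odour=1)
layer = LayerModel(layer="PN_BOUTON",
                   odour_log_mean={"Mch": math.log(50), "Oct": math.log(80)},
                   odour_log_sd={"Mch": 0.4, "Oct": 0.4},
                   active_fraction={"Mch": 0.5, "Oct": 0.5})
movie, protocol, truth = simulate_calyx_movie(cfg, layer, ["Mch", "Oct"])
movie, _ = register_movie(movie, protocol)
for i, trial in enumerate(protocol.trials):
    rois = detect_active_rois(movie, protocol, trial)
    traces = extract_traces(movie, rois, protocol)
    s = summarize_trial(traces, trial, fly_id="fly00", trial_index=i)
    sens, prec = score_detections(rois, truth, trial.odour, movie.pixel_size_um)
    print(f"{trial.odour}: {s.active_roi_count} active ROIs, "
          f"mean peak {s.mean_peak:.1f}% dF/F0, "
          f"sensitivity {sens:.2f}, precision {prec:.2f}")
```

Output:

```
Mch: 34 active ROIs, mean peak 36.4% dF/F0, sensitivity 0.79, precision 1.00
Oct: 26 active ROIs, mean peak 60.8% dF/F0, sensitivity 0.72, precision 1.00
```

The active-ROI counts are similar between odours while the mean peak is
clearly higher for Oct — the PN-layer signature that the downstream paired
test picks up across flies. Precision is 1.0 (every detection sits on a
true active MG); sensitivity is ~0.75 because the threshold detector
misses the weak tail of the log-normal amplitude distribution, as a
threshold-based macro does on real data.

The same end to end, from the shell, for the connectome audit:

```sh
mgpipe run connectome_audit --out audit --seed 7
python -c "import json; print(json.load(open('audit/stats.json'))['pn_correlation'])"
# {'r2': 0.6675..., 'slope': 0.788..., 'intercept': 48.79..., 'n': 126}
```

126 of the table's 136 PNs make *and* receive synapses with APL, and
their reciprocal weights correlate with r² ≈ 0.63–0.67 across seeds —
every number recomputed from the emitted synapse rows, never read from
the generator's bookkeeping.

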