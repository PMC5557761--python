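# arcomp — frequency–space–time decomposition of the EEG alpha rhythm

`arcomp` decomposes the resting-state EEG alpha rhythm into a small
number of *alpha-rhythm components* (ARCs), each described by a
frequency profile, a cortical source distribution, and a temporal
envelope. The classical posterior alpha peak is treated not as one
oscillation but as a superposition of components with distinct peak
frequencies and distinct posterior generators — typically a
higher-frequency occipito-parietal component (ARC1) and a
lower-frequency occipito-temporal component (ARC2).

## Method in one paragraph

A recording is converted into a non-negative three-way array
(space × frequency × time) of amplitude spectral densities using
Hann-tapered 5 s windows over the extended 5–15 Hz alpha band. This
tensor is decomposed by non-negative PARAFAC (canonical polyadic
decomposition fitted with hierarchical alternating least squares); the
number of components is chosen with the core consistency diagnostic
(CORCONDIA ≥ 90 %). Components with flat spectra or non-posterior
topographies are rejected as noise. Retained components are then
source-localized: the sensor tensor is mapped through a LORETA-style
distributed inverse on a three-shell spherical head model, and a second
PARAFAC is fitted in source space with the frequency and temporal
loadings held fixed, so only the cortical distributions are
re-estimated. Group-level spatial contrasts between components use a
paired cluster-based permutation test on the source lattice, and
replicability is quantified with Tucker congruence coefficients (TCC;
0.85 = highly similar, 0.95 = nearly identical). Because no public
recordings with known component structure exist, the package ships a
synthetic EEG generator with exact ground truth against which every
stage is validated. See `docs/methods.md` for details.

## Quick start

Simulate a recording with two known alpha components and recover them:

```python
import numpy as np
from arcomp import (
    HeadModel, RunConfig, build_leadfield, default_channel_positions,
    default_two_arc_scenario, simulate_recording, ArcDecomposition,
)

config = RunConfig()
head = HeadModel(config.shell_radii, config.conductivities)
positions, names = default_channel_positions(62, head.outer_radius)
leadfield = build_leadfield(positions, n_sources=config.n_sources,
                            head=head, channel_names=names)

scenario = default_two_arc_scenario(seed=0)       # 10.4 Hz + 9.4 Hz patches
recording, truth = simulate_recording(scenario, leadfield)

results = ArcDecomposition(recording, config, leadfield=leadfield).fit(seed=0)
print(results.summary())
print()
print(results.selection_table.round(3))
```

Output (exact, including the model-order table — about half a minute
on one CPU):

```
Alpha-component decomposition
========================================
selected components: 2 (core-consistency threshold 90.0%)
retained after noise rejection: 2
sensor fit: 0.8436  source fit: 0.8157

label  peak_frequency_hz  spectral_flatness  posterior_fraction  magnitude
 ARC1               10.4           0.491530            0.796540  41.739722
 ARC2                9.2           0.589252            0.783431  31.710124

     fit  corcondia  converged  degenerate
K                                         
1  0.673    100.000       True       False
2  0.844    100.000       True       False
3  0.866     89.512       True       False
4  0.887    -38.151       True       False
5  0.905   -152.399       True       False
6  0.921   -255.929       True       False
```

The core consistency collapses beyond K = 2, so two components are
selected; they are labeled ARC1/ARC2 by peak frequency (the 9.4 Hz
patch peaks at 9.2 Hz here because the spectral profile is a noisy
draw, not a delta). Each `ArcComponent` in `results.components` carries
`frequency_loading`, `sensor_loading`, `source_loading`, and
`temporal_loading`; comparing `source_loading` against
`truth.true_spatial_profiles` with `arcomp.tucker_congruence` gives
congruences above 0.85 for both components.

## Command line

```bash
arcomp simulate --scenario default2arc --seed 0 --out data/subj0
arcomp decompose data/subj0/recording.npy --seed 0 --out results/subj0
arcomp groupstats results/subj* --out results/contrast.txt
arcomp replicability results/sessA results/sessB
arcomp selftest
```

Every run writes `run_log.json` with the package version, a hash of the
full configuration, and the seed.

## Package layout

| module | contents |
| --- | --- |
| `arcomp.spectral` | recordings, STFT, cross-spectra, amplitude-spectrum tensors |
| `arcomp.headmodel` | three-shell sphere, source lattice, analytic lead fields |
| `arcomp.inverse` | LORETA / minimum-norm inverse operators, source spectra |
| `arcomp.parafac` | non-negative PARAFAC (HALS), CORCONDIA, model-order selection |
| `arcomp.simulate` | synthetic EEG scenarios with exact ground truth |
| `arcomp.pipeline` | the two-stage per-subject decomposition (`ArcDecomposition`) |
| `arcomp.stats` | TCC, component matching, cluster permutation test, RM-ANOVA |
| `arcomp.config` | `RunConfig` with validation, YAML round trip, content hash |
| `arcomp.io` | `.npy`+JSON recordings, HDF5 tensors/models, TSV tables |
| `arcomp.cli` | `arcomp` command-line entry point |
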