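# vrgaze

Eye- and head-movement analytics for 360° panoramic viewing: from raw
eye-in-head vectors and head-pose quaternions to spherical fixations,
latitude-aware heatmap statistics, and cross-recurrence quantification of
scanpath similarity between scene encoding and recognition.

The package is aimed at researchers analyzing VR free-viewing experiments in
which an observer sits at the center of a stimulus sphere, eye direction is
tracked in head coordinates (~250 Hz) and head orientation as quaternions
(~70 Hz). Because raw recordings of such studies are rarely shareable, the
package includes a fully seeded synthetic study generator that reproduces the
behavioural structure of the paradigm (horizon-biased regions of interest,
image-driven vs idiosyncratic fixation targets, a head that lags and
under-shoots the eye, narrowed exploration during recognition) so every
stage of the analysis is testable end to end.

## What it computes

* **Preprocessing** — head quaternions are slerp-interpolated to the eye
  timestamps; the world gaze direction is the head rotation applied to the
  eye-in-head vector, the head point is the head rotation applied to the
  forward axis. All positions are (longitude, latitude) on the sphere.
* **Fixations** — a dispersion-threshold (I-DT) detector adapted to spherical
  data: a fixation is a window whose maximum pairwise great-circle distance
  stays ≤ 3° for ≥ 80 ms; its centroid is the spherical mean. Head fixations
  are spherical means of the head point over each eye fixation. Derived
  measures: saccade amplitudes, head shifts, exploration tendency (mean
  great-circle distance from the first fixation).
* **Spatial statistics** — per-trial spreads (SD of longitudes after circular
  recentering, SD of latitudes) with across-trial medians; heatmaps built by
  depositing an angular Gaussian kernel exp(−d²/2σ²), σ = 4°, on a 1°
  equirectangular grid; heatmap correlations weighted by cos(latitude), the
  inverse of the projection's area distortion; same-scene vs different-scene
  contrasts.
* **Cross-recurrence analysis (CRA)** — two equal-length fixation sequences
  E and R define a binary matrix r_ij = 1 iff the great-circle distance
  between e_i and r_j is at or below a radius; the radius is calibrated by
  bisection so that mean recurrence hits a target (7% by default). Nine
  measures: REC, DET, hLAM, hTT, vLAM, vTT, CORM, CLUST, ENT.
* **Study orchestration** — the four pairing conditions crossing participant
  and image identity (Sp-Si, Sp-Di, Dp-Si, Dp-Di), per-condition CRA
  aggregation, a 2×2 repeated-measures ANOVA helper, and memory-performance
  tables (Hit/Miss, CR/FA) with exact Mann–Whitney U contrasts.

## Worked example

```python
from vrgaze import StudyConfig, run_pipeline

cfg = StudyConfig(n_participants=4, n_scenes_encoding=12, n_old=6, n_new=6,
                  trial_duration_ms=6000)
report = run_pipeline(cfg, seed=3)

print(report.radii)
print(report.spread_eye.round(2))
print(report.cra_summary["rec"]["mean"].round(2))
c = report.contrasts["eye_enc_rec"]
print(round(c.mean_same, 3), round(c.mean_different, 3), f"p={c.p_value:.2g}")
```

prints (seed 3):

```
{'eye': 11.714337507628505, 'head': 17.4277086610134}
             sd_lon  sd_lat
phase_grp
encoding      84.92   19.88
recognition   72.34   20.95
condition  target
Dp-Di      eye       1.87
           head      3.80
Dp-Si      eye       6.07
           head      5.28
Sp-Di      eye       2.43
           head      4.50
Sp-Si      eye       7.00
           head      7.01
0.643 0.125 p=3.1e-06
```

Reading the output: the recurrence radii are calibrated so the same-scene
pairs reach 7% mean recurrence; the eye spreads shrink from encoding to
recognition (longitude median 84.9° → 72.3°); mean recurrence is high for
same-image conditions (Sp-Si, Dp-Si) and low when the image changes, the
signature of image-driven scanpaths; and same-scene encoding/recognition
heatmaps correlate far better (0.64) than different-scene pairs (0.13).

A thin CLI mirrors the stages: `vrgaze simulate`, `vrgaze detect`,
`vrgaze report` (see `--help`).

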