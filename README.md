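# ambarpet

Simulation and analysis of FDG-PET brain metabolism and MRI volumetry in a
four-arm longitudinal plasma-exchange trial for Alzheimer's disease.

The package builds a digital brain phantom, simulates a randomised cohort
with arm-specific metabolic decline, and runs the full neuroimaging analysis
chain on it: intensity normalisation and smoothing, a voxel-wise normative
template, Z-score defect mapping with grey-matter correction, three regional
metabolic parameters, voxel-wise group statistics with cluster-extent
thresholding, an AD-progression mask (MaskAD), and subcortical volumetry
statistics. Because the cohort is simulated, every result can be checked
against the ground truth that was seeded into it.

## The model

Each patient scan is normalised to its cerebellar mean and smoothed with an
8 mm FWHM isotropic Gaussian. A normative template is the voxel-wise mean
μ(x) and sample SD σ(x) of 48 preprocessed control scans (SD floored at 1%
of the in-brain mean). The defect map of a scan `s` is

    z(x) = (s(x) − μ(x)) / σ(x),   defect(x) = [z(x) ≤ −2] ∧ [p_GM(x) ≥ 0.5]

with severity bins at −2, −3, −4 SD. Longitudinally a defect voxel is
*improved* if Δz > +0.5, *worsened* if Δz ≤ −0.5, *maintained* otherwise,
with status changes (defect appearing/disappearing) taking precedence.

Three parameters summarise each atlas region: mean normalised uptake
(*metabolism intensity*), percent of in-mask voxels that are defect
(*defect extension*), and mean Z over defect voxels (*defect intensity*).
Regional change is tested with paired t-tests (p < 0.05); tables report
counts and percentages of significant regions.

At the voxel level, a paired t contrast of baseline→final decline is
thresholded at one-sided p < 0.001 uncorrected with cluster extent k ≥ 50
(18-connectivity), restricted to the in-brain mask. The surviving clusters
of the placebo arm define MaskAD; each arm's outcome is its mean percent
change of in-mask uptake. Volumetry tests 15 subcortical structures and the
GM/WM/CSF tissue classes (TIV = GM + WM + CSF, derived on demand).

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 0      # 64 subjects × 5 visits + 48 controls
python analysis/02_run_pipeline.py --seed 0         # full chain → results/run/table{1..4}.csv
python analysis/03_report_tables.py                 # print the four tables
python analysis/04_calibration_experiments.py       # self-diagnostics
```

With seed 0 the run reproduces the qualitative pattern the chain is built
to detect — placebo declines most inside MaskAD, the high-albumin + IVIG
arm least, and moderate patients decline more than mild ones:

```
table3 (percent metabolic loss in MaskAD)
   group  placebo  low_albumin  low_albumin_ivig  high_albumin_ivig
     all     -6.7         -5.0              -5.6               -2.3
    mild     -5.2         -3.7              -4.3               -1.9
moderate     -8.2         -6.3              -6.9               -2.6
```

The calibration diagnostics on the same build report a voxel-wise type-I
rate of 0.0012 at nominal p < 0.001, an empty MaskAD on 50/50 null-arm
seeds, per-arm percent-loss recovery within ~0.7 pp of the seeded declines,
and 100% localisation power for the regional and volumetric tests with
false-positive rates at or below the nominal 5%.

The same stages are available as a CLI (`ambarpet simulate|run|report …`)
and as library functions in `ambarpet.pipeline`.

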