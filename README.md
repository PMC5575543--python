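# petbench

A benchmarking toolkit for **PET auto-segmentation (PET-AS)** methods:
standardized agreement metrics, a set of reference segmentation algorithms,
a synthetic PET study simulator with exactly known ground truth, contour
perturbations for specificity testing, and agreement-limit statistics with
structured reporting.

## Who this is for

Developers of PET tumor-delineation algorithms need to answer a deceptively
simple question: *is my new contouring method at least as good as the
established ones?* Answering it reproducibly requires (a) reference
contours whose truth status is known, (b) agreed-upon metrics, and (c) a
statistical yardstick derived from existing methods. `petbench` provides
all three as a library plus a thin `petbench` command-line tool.

## The metrics

For a reference contour *A* and a test contour *B* (voxel sets on the same
grid), the toolkit computes:

**Level I (volumetric / uptake):**

- error in volume: (|B| − |A|)/|A| × 100 %
- error in mean and maximum uptake: signed fractional differences × 100 %
- error in center of mass: ‖com(B) − com(A)‖ in mm

**Level II (geometric):**

- Dice similarity coefficient: DSC = 2|A∩B| / (|A|+|B|)
- sensitivity S = |A∩B|/|A| and positive predictive value PPV = |A∩B|/|B|
- modified Hausdorff distance (cm): max of the two *mean* directed minimum
  surface-to-surface distances (the average replaces the classic maximum,
  making the metric robust to single outlier points)
- delineation uncertainty volume DUV = |A∪B| − |A∩B| (voxels), and its
  average thickness DUV·v / area(∂A) in cm

Every metric is verified against an independent brute-force implementation
in the test suite, and the algebraic identity DUV = (|A|+|B|)(1−DSC) holds
exactly.

**Agreement limits (AL):** for each metric, the per-method mean values of a
panel of established methods are summarized as median ± 1 sample SD; the
side corresponding to better-than-typical performance is clamped to the
best achievable value (0 for errors and distances, 1 for DSC/S/PPV). A new
method is "within the ALs" if its mean (absolute, for signed errors) falls
inside the interval.

## Included segmentation methods

Fixed threshold (% of max and absolute), signal-to-background-ratio
thresholding with phantom-fitted calibration θ(SBR) = a + b/SBR, iterative
adaptive thresholding, descending-threshold region growing, k-means and
Gaussian-mixture clustering (with a BIC-selected variant), and
watershed-based clustering. Contours from external tools (e.g. FLAB)
are imported via NIfTI masks or DICOM-RT RTSTRUCT files.

## The simulator

Since clinical and physical-phantom datasets cannot be redistributed, the
package generates synthetic studies with *absolute* ground truth: phantoms
(spheres, ellipsoids, sphere unions; homogeneous or two-level heterogeneous
uptake) are blurred by a Gaussian PSF, forward-projected slice-wise
(parallel-beam sparse-matrix projector), contaminated with Poisson noise
plus uniform scatter/randoms, and reconstructed with FBP or OSEM (± PSF
modelling). The reference contour is the support of uptake above background
in the original activity map. Everything is bit-reproducible under a fixed
seed.

## Worked example

```python
import warnings
from petbench.simulator import PhantomSpec, TumorSpec, ReconConfig, simulate_study
from petbench.segmentation import SearchRegion, SegmentationSpec, segment
from petbench.core_io import StudyDatabase
from petbench.report import evaluate, agreement_limits, within_limits

phantom = PhantomSpec(
    grid_shape=(32, 32, 16), spacing=(4.0, 4.0, 4.0),
    tumors=[TumorSpec(center_mm=(62, 62, 30), size=12.0, uptake=5.0,
                      label="lesion")],
    background=1.0)
cfg = ReconConfig(algorithm="OSEM", counts_target=1e6, seed=11)
study = simulate_study(phantom, cfg, "DEMO", site="lung")

region = SearchRegion.from_mask(study.reference, margin_mm=16)
contours = {}
for spec in [SegmentationSpec("FT", {"fraction": 42}),
             SegmentationSpec("KM", {"k": 2}, seed=1),
             SegmentationSpec("WC", {}, seed=1)]:
    contours[spec.method_id] = segment(study.image, region, spec)

table = evaluate(StudyDatabase([study]), {study.study_id: contours},
                 ["volume_error", "dsc", "sensitivity", "ppv", "hd_mod"])
print(table.pivot_table(index="method_id", columns="metric",
                        values="value").round(3))

al = agreement_limits("dsc", median=0.69, sd=0.07)
mean_dsc = table.loc[table.metric == "dsc", "value"].mean()
print(f"DSC agreement limits: ({al.lower:.2f}, {al.upper:.0f}); "
      f"mean DSC {mean_dsc:.3f} within limits: {within_limits(mean_dsc, al)}")
```

prints

```
metric       dsc  hd_mod    ppv  sensitivity  volume_error
method_id
FT         0.939   0.065  0.976        0.904        -7.353
KM         0.952   0.056  0.949        0.956         0.735
WC         0.711   0.305  1.000        0.551       -44.853
DSC agreement limits: (0.62, 1); mean DSC 0.867 within limits: True
```

Reading the table: on this simulated lung lesion the 42 % fixed threshold
slightly under-segments (volume error −7 %, DSC 0.94), k-means is nearly
exact, and the watershed method cuts at the gradient ridge and misses the
blurred rim (sensitivity 0.55, but PPV 1.0 — everything it labels is
tumor). The mean DSC across the three methods lies inside the example
agreement limits, so this trio would pass the DSC yardstick.

The same workflow is available from the shell: `petbench simulate`,
`petbench segment`, `petbench perturb`, `petbench evaluate`,
`petbench report`, `petbench calibrate-sbr` (see `--help` on each).

## Documentation

`docs/methods.md` describes the models, algorithms, parameter choices and
known limitations in detail.
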