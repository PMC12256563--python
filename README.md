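# helixreg

Single-pose CBCT image-to-robot registration for robotic histotripsy guidance.

Histotripsy destroys tissue mechanically with focused ultrasound delivered by a
transducer on a robotic arm. To target a lesion visible in cone-beam CT (CBCT)
but not in ultrasound, the transform between the robot base and the CBCT volume
must be known. `helixreg` implements a registration method that needs only a
**single 3D CBCT** of a calibration phantom: a cylinder carrying 32 stainless
steel fiducials (22 × 1.5 mm, 10 × 3 mm) on a helix, attached to the robot in
place of the transducer. The asymmetric small/large pattern lets the software
identify every fiducial from inter-fiducial distances alone — no initial pose
estimate, and as few as 4 large fiducials suffice.

## Method

Frames: robot base `r`, tool attachment `e`, phantom `p`, transducer `h`,
CBCT `c`; `Ta2b` maps points from frame `a` to `b` in homogeneous coordinates.
Given the robot pose held during registration `Tr2e(Reg)` and the fixed
attachment calibration `Te2p`, the registration chain is

```
Tr2c = Tp2c · Te2p · Tr2e(Reg)
```

and `Tp2c` is estimated from the CBCT:

1. **Detection** — global threshold at the 99.99th percentile of the volume
   histogram (or a percentile derived from the expected fiducial volume),
   26-connected components, geometric centroids, equivalent diameters, and a
   2.25 mm small/large split.
2. **Correspondence** — each detected large fiducial `f_i(CBCT)` is assigned
   the model fiducial `f_j(model)` minimizing the distance-pattern cost
   `d_ij = Σ_k min_{j'≠j} | ‖f_i − f_{i+k mod m}‖ − ‖f_j − f_{j'}‖ |`
   by brute force; the assignment must be injective with a 0.5 mm ambiguity
   margin.
3. **Estimation** — affine least squares `Tp2c · [f(model)] = [f(CBCT)]` via
   complete orthogonal decomposition, projected to the nearest rigid
   transform (polar decomposition).
4. **Refinement** — derivative-free direct search over 6 rigid parameters
   minimizing the RMSE between every detected fiducial (small and large) and
   its nearest model fiducial; stops at 2000 iterations, ΔRMSE < 10⁻³ mm, or
   step < 10⁻³ mm. The final RMSE is the fiducial registration error (FRE).

Once registered, the robot pose that places the transducer focal point on a
CBCT target `x` with transducer orientation `Rh2c` is

```
Tr2e(Tx) = Te2h⁻¹ · [Rh2c | x]⁻¹ · Tr2c
```

The package also ships synthetic-volume generators (fiducial phantom renders
with partial-volume weighting and Gaussian noise; layered agar treatment
phantoms with a homogenized ellipsoidal "bubble cloud" zone), treatment-zone
segmentation with targeting-error (TRE) measurement, and the reproducibility
statistics used to analyze repeated trials (pooled-variance t-tests,
day-centered variance F-tests, Benjamini–Hochberg correction, pooled
mean ± SD summaries). See `docs/methods.md` for modelling details.

## Worked example

```bash
$ helixreg validate-pattern
minimum large fiducials for unique identification: 4
visible in centered 160 mm FOV: 28 (8 large, 20 small)

$ helixreg simulate phantom --seed 1 --out phantom.nrrd --truth truth.csv
wrote phantom.nrrd (320^3 voxels, 28 fiducials in FOV)

$ helixreg register phantom.nrrd --out result.json
FRE 0.0585 mm, 8 large + 20 small fiducials, cost-tolerance after 7 iterations -> result.json

$ helixreg target result.json --target 12,-8,30 --out pose.json
wrote Tr2e(Tx) -> pose.json
```

The first command checks the shipped phantom pattern: four large fiducials
are enough to identify the helix uniquely, and a centered (16 cm)³ FOV sees
28 of the 32 fiducials (8 large, 20 small — the outermost two positions at
each helix end are truncated). The simulated scan renders those fiducials at
0.5 mm voxels with noise; registration then detects all 28, identifies the 8
large ones from their distance pattern, and converges in 7 direct-search
iterations to an FRE of 0.0585 mm — the noise floor of centroid estimation on
this synthetic volume. The final file holds the robot pose that would place
the transducer focal point on CBCT coordinate (12, −8, 30) mm.

The same pipeline is available as a library:

```python
import helixreg as hx
from helixreg.transforms import identity

model = hx.generate_model()                       # digital phantom
vol, truth = hx.render_phantom_cbct(model)        # synthetic CBCT
result = hx.register(vol, model, identity("r", "e"), identity("e", "p"))
print(result.fre, result.n_large_used, result.termination_reason)
```

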