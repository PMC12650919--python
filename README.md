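# sinusvol

Deterministic, rule-based segmentation and interval volumetry of the
maxillary sinus from grayscale tomographic slice stacks (CBCT exports),
for clinicians and researchers who need reproducible pre/post-operative
sinus volume measurements — e.g. around zygomatic or pterygoid implant
surgery — without training data or a GPU.

## Method

The input is an ordered stack of slices, each an integer matrix `I` with
intensities in [0, 255], plus one seed voxel known to lie in the sinus
and a user-chosen threshold `k`.

1. **Binarization.** Each slice becomes `M_ij = 1` iff the threshold rule
   holds (`I_ij < k` by default, since the air-filled sinus is
   radiolucent; `I_ij ≥ k` is available).
2. **Surface separation.** Foreground pixels of a slice split into
   *surfaces*: equivalence classes under chains of neighbours at
   L1 distance 1, i.e. 4-connected components.
3. **Seeded identification across planes.** The seed's surface is
   retained; sweeping to adjacent planes, a surface joins the detected
   volume `V` when one of its pixels lies at in-plane L1 distance ≤ 1
   from an already-retained pixel of the neighbouring plane.
4. **Invisible-septum removal** (layer depth `l`, default 2). Per slice:
   erode `l` layers with the plus-shaped structuring element
   (disconnecting any channel of width ≤ `l`), keep only the eroded
   components contiguous with the reference pixels, then reconstruct
   exactly `l` layers by dilation constrained to the original mask.
   The sinus boundary is restored; the channel and the cavity on its far
   side are not.
5. **Iterative refinement.** Alternating forward/reverse passes add
   surfaces that become reachable late (e.g. the far arm of a U-shaped
   cavity) until a fixpoint.
6. **Interval volumetry.** Per slice, a lower-bound mask keeps pixels
   whose plus-neighbourhood sums to 5 (boundary stripped) and an
   upper-bound mask keeps pixels with neighbourhood sum ≥ 1 (one layer
   added). With cubic voxels of side `L`,
   `V = (V_upper + V_lower)/2 ± (V_upper − V_lower)/2`.

Validation metrics (Cohen's κ on voxel labels, consensus union, Dice)
and paired cohort statistics (`ΔV_rel = (V_pre − V_post)/V_pre`, mean,
sample SD, Student-t 95 % CI) are provided alongside, plus a phantom
generator producing ellipsoidal cavities with analytic ground truth.

## Worked example

Generate the default phantom (a dark spherical cavity of radius 12
voxels in a bright matrix), segment it from a seed at its centre, and
measure the volume at 0.3 mm voxels:

```
$ sinusvol phantom --out demo
$ sinusvol segment --input demo/stack --seed 20,32,32 --threshold 100 \
    --layers 0 --voxel-side 0.3 --out demo/run
{
  "n_lower": 5976,
  "n_detected": 7208,
  "n_upper": 8536,
  ...
  "v_mid": 195.91199999999998,
  "v_err": 34.56
}
```

The detected 7208 voxels equal the phantom's ground-truth count exactly;
the reported volume 195.9 ± 34.6 mm³ is the midpoint of the
lower/upper-bound masks (5976 and 8536 voxels × 0.027 mm³), and the
interval brackets both the true voxel volume (194.6 mm³) and the
analytic sphere volume (7238.2 voxels × L³ = 195.4 mm³).

Cohort statistics on the bundled six-sample pre/post example
(`sinusvol.example_cohort()`):

```python
>>> from sinusvol import cohort_summary, example_cohort
>>> df = example_cohort()
>>> cohort_summary(df["v_pre"], df["v_post"]).as_dict()
{'n': 6, 'df': 5,
 'rel_changes_pct': [1.1, 4.8, 8.8, 11.8, 23.2, 24.5],
 'mean_rel_pct': 12.4, 'sd_rel_pp': 9.6, 'ci95_pct': [2.3, 22.5],
 't_crit': 2.5705818356363146,
 'mean_pre': 16137.7, 'sd_pre': 4511.7,
 'mean_post': 14459.3, 'sd_post': 5167.6}
```

i.e. an average postoperative volume reduction of 12.4 % (SD 9.6
percentage points, 95 % CI 2.3–22.5 %).

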