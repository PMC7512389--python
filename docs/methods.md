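# Methods

## Problem and model

The package performs two-class thresholding segmentation of single-channel
gray-level images (levels 0..L−1, L = 256 by default). Pure histogram
thresholding ignores spatial correlation between pixels: two images with
identical gray-level histograms can demand different thresholds. The method
implemented here injects spatial information by pairing each pixel's
original gray level i with the gray level j of a *non-local means* (NLM)
filtered companion image, and thresholding the joint distribution of the
pairs.

### Non-local means companion image

The filter estimates each pixel as a weighted average of candidate pixels,

  Y(i) = Σ_j w(i, j) X(j),
  w(i, j) ∝ exp(−‖X(N_i) − X(N_j)‖² / (h² σ²)),

where N_k is the (2r+1)×(2r+1) patch centred on pixel k, ‖·‖² is the plain
sum of squared gray-level differences over the patch (no intra-patch
Gaussian weighting), h is the filtering degree and σ the Gaussian-kernel
standard deviation; the weights are normalized to sum to one per pixel, and
the self term j = i participates like any other candidate. Because the
average is taken over *similar patches* rather than a local neighbourhood,
edges and fine details survive better than under a local mean, which is the
point of using it as the companion coordinate: pixels interior to an object
or the background land near the diagonal of the joint histogram, while edge
and noise pixels land off-diagonal.

Defaults: `patch_radius=2` (5×5 patch), `search_radius=10`, `h=10`,
`sigma=1`, reflect border padding. None of these have canonical values in
the thresholding setting; the defaults follow common NLM practice and every
one is overridable per call and from the CLI. `search_radius="full"`
performs the literal whole-image average; it is quadratic in the pixel
count, so a windowed search is the practical default. Note h and σ enter
only through the product h²σ²; they are kept as two parameters because
users of NLM conventionally tune h against an estimated noise σ.

The filtered value is a convex combination of input levels; it is rounded
half-up and clipped to [0, L−1] so it can index a histogram bin.

### Joint histogram and threshold vector

p[i, j] is the fraction of pixels with original level i and companion
level j. A threshold vector (s, t) cuts the L×L matrix into four
quadrants; the closed low-low box (i ≤ s, j ≤ t) is class 0 (background)
and the open high-high box (i > s, j > t) class 1 (object). The two
off-diagonal quadrants collect edge and noise pixels.

### Selection criterion

With class masses P0, P1 and mean vectors μ0 = (μ0i, μ0j), μ1 the selected
vector minimizes the cross-entropy-style objective

  D(s, t) = C − P0 (μ0i ln μ0i + μ0j ln μ0j) − P1 (μ1i ln μ1i + μ1j ln μ1j),
  C = Σ_ij (i p_ij ln i + j p_ij ln j).

C is an image-wide constant; the minimizer maximizes the recovered
moment-entropy of the two diagonal classes. Because C counts *every* cell
but the class terms recover only diagonal-box mass, thresholds that push
mass off-diagonal pay for it in full — which is what makes the criterion
well-posed.

A second, "direct" form accumulates the Kullback–Leibler discrepancy of
the diagonal boxes only:

  D_direct(s, t) = Σ_{i≤s, j≤t} [i p ln(i/μ0i) + j p ln(j/μ0j)]
                 + Σ_{i>s, j>t} [i p ln(i/μ1i) + j p ln(j/μ1j)].

The two are **not** equal up to a threshold-independent constant: they
differ by Σ_{off-diagonal quadrants} (i p ln i + j p ln j), which moves
with (s, t). (The 1-D minimum-cross-entropy reduction, where the two
classes partition the whole histogram, does not carry over to quadrant
classes.) Minimizing the direct form is degenerate — it is driven to ~0 by
corner vectors that dump nearly the entire image into the off-diagonal
quadrants, leaving two near-point-mass classes. The reduced form above is
therefore the operative criterion throughout the package; the direct form
remains available via `relative_entropy_objective(..., form="direct")`,
and the test suite pins the exact pointwise relationship between the two.

Conventions, chosen where the formulation is silent:

- natural logarithms (the argmin is base-invariant);
- 0·ln 0 := 0, and any term multiplied by gray level 0 vanishes;
- (s, t) is infeasible when either class mass is below 10⁻¹² (counts are
  multiples of 1/(MN), so this separates true zeros from float dust in the
  prefix tables);
- ties in D break toward lexicographically smallest (s, t);
- class-1 moment sums are normalized by the class-1 mass P1 (anything else
  would make μ1 not a mean and break the reduction identity).

The search is a literal exhaustive scan of all L² vectors, evaluated in
O(1) each from 2-D prefix tables of p, i·p and j·p after O(L²)
precomputation; tests assert it agrees with a naive direct-summation scan.

### Binarization

Diagonal-box pixels take their box's class. The criterion itself does not
say how to label the off-diagonal (edge/noise) pixels; here each such pixel
joins the class whose mean vector is nearer in the (i, j) plane, ties to
background. This keeps edge pixels with the population they resemble in
both coordinates.

## Baselines and evaluation

- **Otsu**: maximizes between-class variance P0 P1 (μ0 − μ1)² on the 1-D
  histogram.
- **Kapur**: maximizes the sum of Shannon entropies of the two normalized
  class distributions.
- **MCE** (minimum cross-entropy): minimizes −m0 ln μ0 − m1 ln μ1 with m_k
  the class first moments.
- **2DMCE**: exactly the proposed criterion run on the joint histogram of
  the image and its local 3×3 mean. No authoritative reference formula
  exists for this baseline as used in comparisons; defining it as the
  local-mean ablation of the main method makes the comparison isolate the
  filter choice, which is the claim under test. The test suite pins the
  ablation identity (`2DMCE == proposed with local-mean companion`)
  bit for bit.

All 1-D criteria share the zero/feasibility/tie conventions above and are
checked against naive full scans, and Otsu additionally against
scikit-image on the same histogram grid.

**Misclassification error** ME = 1 − (|B_o∩B_T| + |F_o∩F_T|)/(|B_o|+|F_o|)
over ground-truth and predicted background/foreground sets; it equals the
fraction of disagreeing pixels and is symmetric. Since a threshold method
does not know which class the ground truth calls "foreground", reported
scores use polarity alignment (the better of the mask and its complement)
by default, with a strict mode available.

## Synthetic scenes

The generator rasterizes seed-placed disks and boxes (pixel-centre-in-disk
rule) at a foreground mean on a background mean, adds i.i.d. Gaussian
noise, and rounds/clips to integer levels; the noiseless class map is the
exact ground truth. Defaults model the regime the method targets: contrast
120 levels (background 60, foreground 180) with noise σ = 10 — class
separation of six noise standard deviations. Presets: `clean` (σ = 0),
`noisy` (the defaults, ten seeds), `small-objects` (radius ≈ 3 px disks,
σ = 5), `low-contrast` (contrast 40, σ = 5). Scenes are 64×64, which keeps
the default test run and the verification script fast while leaving tens
of boundary pixels per scene — the interesting population for the
off-diagonal labeling rule.

What the scenes do *not* model: textured objects, illumination gradients,
multi-modal backgrounds, and impulse (salt-and-pepper) noise — patch
averaging is known to handle impulse noise poorly, so Gaussian noise is
the generator's only noise model and passing results say nothing about
impulse-corrupted images. Passing the suite shows the pipeline recovers
well-separated two-population images through noise; it does not certify
performance on natural photographs.

## Numerical choices

- Patch distances for the whole image are computed offset-by-offset with
  summed-area tables — an exact reorganization of the per-pixel definition
  (verified against a literal quadruple loop to 1e−6 pre-rounding), not an
  approximation.
- Quantization everywhere is round-half-up (`floor(x + 0.5)`) then clip.
- All mass/moment accumulations are float64; histogram feasibility uses
  the 10⁻¹² guard described above.
- A constant image raises a degenerate-input error from the threshold
  search (no feasible vector) rather than returning an arbitrary vector.

## Known limitations

- Two classes only; no multi-level extension.
- Whole-image (`"full"`) search is O((MN)²) and intended for small images
  or verification.
- The reduced-vs-direct objective discrepancy documented above is
  intrinsic to quadrant-class cross entropy; the package resolves it by
  always optimizing the reduced form.
- Ground-truth masks are read as 0 = background, nonzero = foreground.
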