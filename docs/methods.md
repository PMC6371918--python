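# Methods

## Model

An image is a sample of N pixels in a 3D color space. chromadist reduces it
to a discrete distribution ("color profile") P = {(cᵢ, pᵢ)}: bin centers cᵢ
and proportions pᵢ ≥ 0, Σpᵢ = 1. Distances between profiles are computed on
this reduced representation; spatial pattern (where on the object a color
sits) is deliberately discarded — the method quantifies palettes, not
patterns.

### Masking

Background removal is chroma-key style: the user supplies one or more
inclusive RGB ranges `[lower, upper]`, and a pixel is background iff it falls
inside some range on all three channels simultaneously. Matching happens on
the 0–1 float scale after decoding (8-/16-bit integers divided by the type
maximum). Fully transparent PNG pixels are background regardless of color;
partially transparent pixels are composited over white before matching. An
image whose every pixel is background is an error — the profile of an empty
object is undefined. No de-speckling is applied, so JPEG chroma artifacts
around a mask edge will leak a few off-color pixels into small bins; lossless
PNG masks are recommended.

### Color spaces

RGB is the storage space; HSV (hexcone, all channels scaled to [0, 1]) and
CIE L\*a\*b\* are derived from it. The RGB → Lab chain is:

1. sRGB inverse companding (piecewise: linear below 0.04045, 2.4-power
   above) — chosen over a flat 2.2 gamma because sRGB is the de facto file
   standard; the choice shifts Lab values at the ±1 level and is therefore
   stated here explicitly;
2. linear RGB → XYZ with the IEC 61966-2-1 D65 matrix;
3. Bradford chromatic adaptation when the requested reference white is not
   D65 (whites A, B, C, E, D50–D75 are built in, 2° observer, Y = 1);
4. the CIE piecewise f(t) (cube root above (6/29)³) to L ∈ [0, 100], a, b.

All arithmetic is double precision with no lookup tables. The published
conversion matrices carry seven digits, which bounds self-consistency at
about 2·10⁻⁵ in Lab units (RGB white maps to |a|, |b| ≤ 2·10⁻⁵, not exactly
0); tests assert neutrality and cross-implementation agreement at 10⁻⁴–10⁻²
accordingly. The inverse map Lab → RGB clips out-of-gamut results to [0, 1]
and logs how many pixels were affected; it exists for rendering bin colors,
where nearest-gamut is the right semantics.

Because the Lab transform is the slowest stage, pixel sets larger than
100,000 may be subsampled uniformly without replacement
(`sample_for_conversion`), reproducibly for a fixed seed. 100,000 pixels
estimate bin proportions to ±0.3 % (binomial), far below binning resolution.

### Binning

**Histogram** (default): each channel's bound interval is divided into equal
widths; boxes are half-open [low, high) with the top box closed at the
channel maximum, so assignment is a partition (the only edge convention with
that property). Bins are emitted in lexicographic order of channel-index
triples (third channel fastest), making identical grids positionally
comparable across images. A nonempty bin's center is the mean of its member
pixels; an empty bin keeps size 0 with its box midpoint as placeholder.
Default bounds are [0, 1] per channel in RGB/HSV and L ∈ [0, 100],
a, b ∈ [−128, 127] in Lab (the practical range of RGB-derived colors).
Narrowing the a/b bounds concentrates bins where a drab image set actually
lives; pixels outside the bounds raise an error naming the channel and the
observed range, rather than being silently clamped — enclosure is the user's
contract.

**k-means**: Lloyd iterations with k-means++ seeding, best of 10 restarts by
within-cluster sum of squares, deterministic for a fixed seed (backed by
scikit-learn; empty clusters are re-seeded internally so exactly k bins are
always returned). Requires at least k distinct colors. k-means bins have no
cross-image identity, so before bin-wise metrics the sets are aligned by the
Hungarian algorithm: bins of every set are matched to the first set's bins by
the bijection minimizing summed Euclidean center distance (sizes excluded
from the cost — the size/color trade-off belongs to the weighted metric, not
the ordering). Assignment is exact (`linear_sum_assignment`); among exactly
tied optima the returned bijection is deterministic but not guaranteed to be
the lexicographically least.

`combine_cluster_sets` averages aligned profiles: sizes by plain mean (each
image weighs equally), centers by pixel-count-weighted mean by default
(switchable to equal weights); a bin empty in every input falls back to its
geometric box midpoint.

### Distances

* **EMD** — solved exactly as the balanced transportation LP over the
  nonzero bins (HiGHS; zero-size bins carry no mass and are excluded to keep
  the program nondegenerate). Tests verify the LP against an independent
  atom-splitting + assignment oracle to 10⁻⁶ and check the metric axioms.
  RGB/HSV EMDs can be normalized by √3 (the cube diagonal, the maximum
  possible score); Lab has no universal maximum, so the normalize flag is
  ignored there with a warning. Profiles must be normalized (Σp = 1);
  unbalanced inputs are rejected rather than partially matched.
* **χ²** — Σ(pᵢ−qᵢ)²/(pᵢ+qᵢ) with 0/0 terms contributing 0 and no ½
  prefactor (the convention is fixed here and by tests). Positional, blind
  to centers: an all-black and an all-dark-gray image can score as identical.
* **color** — mean Euclidean distance of matched centers, sizes ignored.
* **weighted** — per matched pair, color_weight·‖Δc‖ + size_weight·|Δp|,
  averaged over bins; weights must sum to 1.

Matrices are stored at double precision; display rounding happens only in
reports. CSV and square-TSV serializations use `repr` floats and reload
bit-exact.

### Pipeline and reports

`image_cluster_pipeline` validates the whole configuration before reading
any image, runs load → convert → bin → (align) → matrix, and writes the
matrix CSV, per-image cluster CSVs, a heatmap, and a metadata record
(parameters, seeds, version). Partial outputs are removed on failure. The
heatmap orders rows by hierarchical clustering (complete linkage by default,
configurable) with optimal leaf ordering, so similar images are adjacent;
the figure embeds the caveat that this clustering is a visual aid — the
matrix, not the tree, is the result.

## Synthetic benchmarks

The fixtures module regenerates the study conditions programmatically:

* **Quantity squares A–E**: 100×100 px, cyan (0,1,1) proportions 1, ¾, ½, ¼,
  0 against red (1,0,0) — opposite RGB-cube corners, so the normalized EMD
  between squares equals their proportion difference exactly. This is the
  mixture-linearity law EMD(A, {A:1−t, B:t}) = t·EMD(A,B), which the tests
  assert directly.
* **Similarity gradient**: solid squares from blue (0,0,1) to yellow (1,1,0).
  Only the endpoints are calibrated anchors (normalized EMD exactly 1);
  interior colors of the original printed gradient exist only as figure
  artwork and are not linear RGB interpolants, so interior distances are not
  comparison targets here.
* **Green-screen scenes**: planted patch colors/proportions on a chroma-key
  background with a JSON ground-truth sidecar; largest-remainder rounding
  makes patch pixel counts exact. Masking + k-means recovers proportions
  exactly and centers within 8-bit quantization (1/255).

Squares are written as lossless PNG with contiguous color blocks; every
profile metric here is layout-invariant, so block layout is free. What these
fixtures do **not** emulate: lighting gradients, texture, shot noise, JPEG
artifacts, or mask-edge mixing — passing them shows the measurement chain is
exact on known distributions, not that photographs of organisms are this
clean.

## Verification against published values

With the default RGB pipeline (3 bins/channel, EMD/√3) the quantity squares
reproduce the published benchmark matrix to 10⁻⁶. In CIE Lab (D65) the same
squares give 39.11 / 78.23 / 117.34 / 156.46 for the ¼/½/¾/full steps, within
±1 of the published 40 / 78 / 118 / 157; the residual is attributable to the
original tool's unspecified conversion constants and its JPEG sources (the
corner colors are invariant to the companding choice, so no transfer-function
setting can close it). Tests assert the ±1 band.

The published flower histogram, butterfly heatmaps, and flounder scores
depend on companion photographs that cannot be regenerated from printed
numbers; `chromadist.integration.flower_histogram_check` runs that check when
a user supplies the photo locally and raises `FileNotFoundError` otherwise.

## Known limitations

* No image calibration (white balance, radiance normalization) — images must
  be calibrated and background-masked upstream.
* RGB is not perceptually uniform and none of the spaces model non-human
  vision; Lab distances approximate *human* perceptual difference only.
* No automatic choice of k, and no spatial/pattern information.
* Exact LP transport scales to hundreds of bins, ample for the intended
  3–5 bins/channel grids; entropic approximations are deliberately omitted.
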