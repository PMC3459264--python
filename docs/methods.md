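# Methods

## Pipeline and assumptions

The codec assumes single-channel images (8-bit native; 12/16-bit inputs are
carried as 16-bit) of at least 64×64 pixels whose statistics resemble
tomographic slices: large smooth regions, sharp organ boundaries, and rough
texture. Sides not divisible by `2**levels` are edge-replicated on the
bottom/right before the transform and cropped after the inverse; the DWT uses
periodized boundaries so band shapes are exact dyadic fractions and the LL
band holds exactly `4**-levels` of the coefficients. The LL branch is coded
"losslessly" *in the quantized domain*: `bior4.4` LL coefficients are real,
so they are rounded (step 1.0 by default) before Huffman coding, and the
reconstruction error attributable to the LL branch is bounded by step/2 per
coefficient. This rounding is the only loss that remains when every
sub-codebook is given as many codewords as there are distinct blocks.

## Blanket-method local fractal dimension

For a surface patch, upper/lower envelopes grow per scale step ε:
u_ε = max(u_{ε−1}+1, 4-neighborhood max of u_{ε−1}) and symmetrically for
b_ε, from u_0 = b_0 = surface. Volume v_ε = Σ(u_ε − b_ε), area
A(ε) = (v_ε − v_{ε−1})/2, and D = 2 − slope of the least-squares fit of
log A(ε) on log ε, clamped to [2, 3]. Numerical notes:

* A(ε) ≥ N (the pixel count) always, since u − b grows by at least 2 per
  step, so the log fit never sees non-positive areas; a flat surface has
  constant A, slope 0, and D = 2 exactly. Non-finite fits degrade to D = 2.
* ε ranges over 1..5 by default: a 5×5 window cannot support larger
  blankets, and larger ε on small windows only flattens the fit.
* `lfd_map` estimates per pixel on a mirror-padded window (default 5×5),
  each window first mapped by magnitude to [0, 255] (constant windows to
  zero), so the map measures local roughness shape, not amplitude. Height
  units matter because ε steps are one gray level; all estimation therefore
  happens on the codec's 8-bit surface convention, and validation surfaces
  are likewise rescaled to [0, 255].
* The vectorized window stack iterates the same recursion as the scalar
  estimator; tests pin both to a literal per-pixel transcription.

The fBm validation surfaces are synthesized spectrally (amplitude
|f|^−(H+1)) on a 2× supersampled grid and decimated. The decimation restores
the aliased high-frequency power a point-sampled fBm field carries; without
it, lag-1 increments are too smooth at low H and the structure-function
slope overshoots H by ~0.16 at H = 0.2. With it, measured slope errors stay
within ±0.1 and blanket estimates land within ±0.06 of 3 − H for
H ∈ {0.2, 0.5, 0.8} at 256².

## Classification and quadtree

Thresholds maximize between-class variance over a 64-bin histogram by
exhaustive search (n_classes = 3 by default); values equal to a threshold
fall in the lower class. If an LFD map is constant (e.g. a zero band),
thresholding is degenerate and every pixel goes to class 0. Class→size
mapping is worst-label based: an 8×8 cell requires all labels 0, a 4×4
quarter all labels ≤ 1; 2×2 leaves are unconditional.

The root-grid shift search scores all 15 candidates (row shifts 0..7 at
column 0, then column shifts 1..7 at row 0) with SUM_i = N_i + 10⁵·SSIM_i,
where both SSIM operands are label images mapped to {0, 128, 255}
(labels × 127.5, rounded) and SSIM is the global single-window form. Ties
keep the earliest candidate, so the unshifted grid is the deterministic
default. Note the criterion as defined *rewards* more 2×2 leaves, which
raises bit cost; it is implemented as specified rather than as a
rate-distortion optimum. Replication padding for a row shift k adds k rows
on top and enough below to complete the cell grid (l0 − k when the side is
already a multiple of l0), copying the first/last line; the decoder crops
the same amount. The division image is an exact quadtree fixed point on the
unpadded interior; inside replicated margins the labels are re-derived from
the cropped map, which is why the fixed-point test uses the unpadded case.

## Vector quantization

Blocks are flattened row-major. Energy initialization sorts by Σx² with a
stable sort (ties by block order) and seeds codeword j with the block at
position ⌊(j + 0.5)·N/k⌋; the pathway contains no randomness, so encoding is
bit-reproducible. The Forgy baseline draws k distinct blocks under a seed
derived from the config seed, band index, and block size. Lloyd iterations
use squared Euclidean distance (ties to the lowest index), stop when the
relative distortion decrease falls below 1e-4 or after 50 iterations, and
reseed empty clusters with the assigned block farthest from its codeword
(preferring blocks whose cluster retains a member), which cannot increase
distortion; the recorded distortion sequence is non-increasing.

Default codebook sizes are K = 256 (2×2), 256 (4×4), 128 (8×8) — the
reference experiments leave them unstated — capped at the number of blocks
and additionally at the number of *distinct* blocks: extra duplicate
codewords cannot lower distortion and only bloat the container (a constant
image would otherwise ship dozens of identical zero codewords per band).
Indices are fixed-width ⌈log₂K⌉ bits (0 bits when K = 1).

## Container and ratio accounting

All integers are little-endian; codewords are serialized as float32 (the
only precision the decoder sees — sub-gray-level, irrelevant after pixel
rounding). The header stores only non-derivable facts; band shapes, per-size
block counts and index widths are recomputed from the geometry and the
depth-first quadtree bitstrings (1 = split, 0 = leaf, root cells in raster
order, smallest leaves implicit). Truncated, oversized, or inconsistent
containers raise rather than decode partially.

Raw bits split 1/16 : 15/16 between the LL and detail parts (levels = 2).
The overall ratio is computed from part totals, so
CR = 1/(f/CR_LL + (1−f)/CR_HF) holds as an exact identity; header and
quadtree bits are charged to the lossy part. Two accountings are reported:
codebooks charged to the lossy part (default, self-contained container) and
excluded (as if codebooks were trained once and shared across a corpus —
per-image embedded codebooks dominate the bit budget at these image sizes,
e.g. six 8×8 codewords alone cost 1.5 kB).

## Synthetic data: what it does and does not show

The phantom mimics the structure triad the codec exploits — smooth gradients
(Gaussian-filtered field), sharp rims (anti-aliased ellipses), rough texture
(masked fBm patch, H = 0.4 default) — spanning ≥ 90% of the dynamic range,
with additive Gaussian noise (σ = 2 gray levels by default, a realistic CT
noise floor). Defaults are 512×512 and 8-bit, matching the evaluation scale
the codec is intended for. The phantom is *not* radiologically realistic: it
has no scanner point-spread function, no streak or quantum-correlated noise,
no anatomy. Passing tests demonstrate algorithmic correctness and
end-to-end soundness on images with the right local-complexity statistics,
not clinical quality; compression ratios on the noisy phantom are lower than
what smooth clinical CT allows, because σ = 2 noise inflates the entropy of
every band including LL.

## Problem sizes used by the test suite and acceptance script

Unit tests run phantoms at 128²–256²; the initialization comparison and the
acceptance script encode the full 512² phantom twice (energy and random),
estimate fBm dimensions at 256² over three seeds, and verify the partition
optimizer against exhaustive search on 50 random 32×32 class maps. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* The LL branch is lossless only after the rounding step; with step 1.0 the
  LL compression ratio on noisy inputs can drop below 1 (the 2-level LL gain
  ~4 adds ~2 bits of symbol entropy over the 8-bit raw budget).
* Only 3 classes / block sizes {2, 4, 8} and 1–2+ level dyadic decompositions
  are supported; no entropy coding of VQ indices; no progressive bitstream.
* The shift-selection criterion follows its definition, not a
  rate-distortion objective (see above).
* DICOM metadata is not read; feed pixel arrays or PGM/PNG.
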