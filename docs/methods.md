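# Methods

This note documents the models and numerical choices behind `msiclust`, in
the order the pipeline applies them, followed by the phantom design and the
recovery experiments that stand in for validation against real data.

## Data model

A dataset is a rectangular pixel grid (0-based, x = column, y = row;
imzML's 1-based coordinates are converted at the file boundary) of
centroided spectra: strictly ascending *m/z* (Da) with non-negative
intensities (a.u.). The raster step (default 50 µm) is metadata only. Files
are exchanged as processed-mode imzML 1.1 (64-bit *m/z*, 32-bit intensity,
via pyimzML); pixels with empty spectra are omitted on write, the usual
convention for processed files. Ion images and ROIs are exported as plain
TSV / 0-1 text grids; *m/z* column labels carry 3 decimals, matching common
reporting precision, while internal values keep full precision.

## Peak picking

The average spectrum bins all pixel spectra at 0.001 Da and assigns each
bin the mean (over pixels) of the summed intensity falling in it; only
occupied bins are kept, located at bin centers.

S/N uses a robust noise level: 1.4826 × the median absolute deviation of
the spectrum's intensities after discarding the top 5 %. This is deliberate
for centroided/binned data, where most retained bins are background
(spurious single-pixel peaks averaged down by the pixel count) and real
peaks are sparse outliers. If the retained intensities are all equal the
MAD is zero and the estimate falls back to their mean, so a flat featureless
spectrum yields S/N 1 everywhere and no peaks. S/N is scale-free; picking is
invariant to uniform intensity scaling.

Candidates with S/N ≥ 10 are merged within a 0.2 Da radius keeping the most
intense member (ties go to lower *m/z* for determinism). The stated
parameters (S/N 10, width 0.2 Da) admit two readings — merge radius or
integration width; we implement the merge radius. A consequence worth
knowing: a genuine peak within 0.2 Da of a stronger one is suppressed.

Ion images use the ±0.004 Da window with "maximum" interval mode (the
per-pixel maximum peak intensity in the window; a "sum" mode is provided).
A requested center outside the dataset's *m/z* range produces an all-zero
image with a warning, not an error.

## Screening

The published workflow screens distributions manually (keep on-tissue
signal; discard slide-homogeneous and off-tissue-enriched artefacts). The
automated surrogate computes the mean intensity inside and outside the
tissue ROI (all pixels, zeros included, so sparse images are not inflated):
off-tissue artefact if outside > inside (with a 1e-9 relative tolerance so
exact homogeneity is not misclassified by rounding), homogeneous artefact
if inside/outside < 2, biomolecule otherwise. The enrichment threshold 2 is
a package choice — no quantitative criterion exists for the manual rule —
and is recorded in every screening report for audit.

## PCA

The stack is pixels × images: each ion image is one feature column, so
component scores are spatial maps. Columns are centered and scaled to unit
variance (ddof = 1), i.e. PCA of the correlation structure; the published
parameter set (5 components, unit-variance scaling, no normalisation, no
denoising) is the default. The eigensolver is the deterministic LAPACK SVD
(no randomized methods), eigenvalues λₖ = sₖ²/(n−1) so that Σλ equals the
image count, and contributions are λₖ/Σλ × 100. Each loading vector's sign
is fixed by making its largest-magnitude entry positive, giving bit-for-bit
reproducible results; a zero-variance image is reported by name rather than
silently dropped.

## Similarity clustering

Cosine similarity is computed between raw (unnormalised, non-negative) ion
image vectors over ROI pixels; it is invariant to per-image positive
scaling. Hierarchical clustering uses average linkage (UPGMA) on
d = 1 − s — linkage is configurable (single/complete/average) since the
original software's algorithm is proprietary and undocumented.

Groups are extracted by cutting the dendrogram at d = 1 − threshold
(threshold 0.5): under UPGMA every merge below the cut happened at mean
pairwise similarity above the threshold, and the resulting blocks are
contiguous in leaf order. We initially implemented a greedy contiguous-run
scan with a running mean-similarity test, but a large coherent block keeps
its mean above threshold while absorbing many unrelated neighbours (a
19-member block of similarity ~1 can swallow ~19 zero-similarity images
before its mean halves), which merged planted archetypes; the dendrogram
cut applies the same mean rule merge-by-merge and does not dilute. Blocks
must pass the block criterion (mean pairwise similarity > threshold by
default; an all-pairs variant is provided) and have ≥ 7 members — the
"more than seven" label convention is resolved as ≥ 7, since reported
groups of exactly 7 members exist — to be reported as diagonal groups.

Off-diagonal groups are pairs of distinct diagonal blocks with mean
cross-block similarity above the threshold. Under average linkage the cut
guarantees no such pair exists (monotone merge heights equal mean cross
distances), so off-diagonal groups can only arise with single or complete
linkage, where separation is driven by extreme rather than mean pairwise
distances; this is documented behaviour, not an omission.

Occupancy ratios are size/total × 100 rounded half away from zero to one
decimal, with a grouped-total row summing the diagonal groups.

## Annotation chemistry

Diacyl glycerophospholipid shorthand `CLASS(c:d)` (classes PA, PC, PE, PG,
PS, PI; c total acyl carbons, d double bonds) expands by head-group rule,
e.g. PS(c:d) = C₍c₊₆₎H₍₂c₊₁₀₋₂d₎NO₁₀P. Monoisotopic masses use standard
atomic masses (C 12 exactly, H 1.00782503, N 14.00307400, O 15.99491462,
P 30.97376163, Na 22.98976928, K 38.96370668).

Two adduct conventions are provided. The default ("neutral") adds the
neutral-atom masses with **no electron correction** — this is the
convention required to reproduce the published adduct *m/z* values
(834.6224 = 833.6146 + 1.00783, not +1.00728). The "standard" convention
subtracts one electron mass (0.00054858 Da) and is the physically correct
choice for new work.

Isotope envelopes likewise come in two modes. The default carbon-only
binomial treats the k-th isotopologue as carrying k ¹³C atoms with relative
abundance C(n_C, k)·rᵏ (r = 0.0107/0.9893), base peak normalised to 100 and
a fixed 1.0034 Da display spacing — the simplest model consistent with the
published relative intensities (100/49/12 for [PS(39:0)+H]⁺, 100/47/11 for
[PI(34:0)+NH₄]⁺ after rounding). The "full" mode convolves the natural
isotope distributions of all elements and aggregates to nominal-mass
centroids; it is verified against exhaustive enumeration for small
molecules.

Isotopologue *theoretical* masses in assignments use the exact ¹³C−¹²C
shift (1.0033548 Da), not the rounded 1.0034: the published isotopologue
rows (834.6179, 835.6213, 873.5816, 874.5850) are only reproducible with
the exact shift. The reproduction helper also rounds theoretical *m/z* to
the 4 printed decimals *before* computing ppm deltas, because the published
deltas were evidently computed from the rounded values (−10.06 requires
834.6224; the unrounded value gives −10.08). `ppm_error` itself is the
plain formula (obs − theo)/theo × 10⁶.

Candidate assignment enumerates (molecule, adduct, isotopologue) triples
within a 10 ppm window, sorted by |ppm|; the threshold is applied per
candidate, and isotopologues of an accepted monoisotopic hit may sit
slightly outside it, mirroring the published table where propagated
isotopologue rows reach −10.5 ppm. Series detection chains peaks at
1.0034 ± 0.01 Da greedily left to right; singletons are length-1 series.

The bundled formula library (six classes × carbons 30–44 × 0–6 double
bonds, 630 species) is a local stand-in for an online metabolome-database
query; live queries are out of scope.

## Phantom design

Geometry: the tissue is an ellipse with an off-tissue margin; inside sit a
cerebellar disc, a ventral brainstem band, an elliptical fibre-tract
annulus and grey matter as the remainder. The partition is deterministic
and fails explicitly below 16×16 pixels.

Twelve spatial archetypes: four grey-matter bands (I, II, VII, IX), three
fibre-tract bands (IV, V, VIII), the cerebellar cortex (III), the brainstem
(X), tissue-wide homogeneous (VI), plus two artefact classes — homogeneous
over the whole slide, and off-tissue-enriched. Templates are binary
supports modulated by a smooth 20 % left-to-right gradient. Real molecule
groups overlap spatially; the sub-zone archetypes here are deliberately
pairwise disjoint (and VI, which nests them, has raw cosine
√(zone/tissue fraction) < 0.5 against each) so that group-recovery
experiments have an unambiguous ground truth. This is the main respect in
which passing tests do *not* certify behaviour on real data: partially
overlapping distributions can legitimately merge or split at the 0.5
threshold.

Molecules draw a distinct lipid species (restricted to those with an adduct
ion inside *m/z* 700–900), an archetype, 1–2 adducts and a log-uniform base
intensity in 200–2000 a.u. Rendering plants, at every pixel, one peak per
isotopologue per adduct at intensity base × template × envelope fraction,
with exact-¹³C spacing. Noise is multiplicative log-normal (σ = 0.2
default) on true peaks plus Poisson-rate spurious peaks (5 per spectrum,
uniform *m/z*, exponential intensity of scale 5 a.u.) — the simplest model
that exercises S/N thresholding; there is no mass jitter, no baseline
drift, and no correlated (matrix-cluster) chemical noise. A fixed seed
makes the rendered dataset bit-identical across runs.

## Recovery experiments

All experiments run at a 64×48 grid with 100 molecules (a desk-scale stand
in for full-size acquisitions; one run takes seconds on one CPU).

- **PCA recovery** plants three mutually disjoint archetypes (grey band I,
  fibre band IV, brainstem X) at weights 0.55/0.30/0.15 under low
  multiplicative noise (σ = 0.05, spurious background retained as the noise
  floor) and matches the top-3 score maps to the templates by maximising
  total |Pearson r| over assignments. Disjoint supports and distinctly
  separated group sizes are what make this identifiable: a nested
  homogeneous pattern correlates with the others' standardized images
  (~0.25) and near-equal group sizes make the top eigenvalues degenerate —
  in both cases PCA returns rotated contrasts rather than the planted
  patterns, which is a property of PCA, not a defect of the pipeline.
- **Clustering recovery** plants all ten on-tissue archetypes uniformly at
  default noise, runs picking → screening → clustering, and scores the
  diagonal groups against the planted labels of truth-matched images by
  adjusted Rand index (ungrouped images count as singletons).
- **Screening recovery** plants all twelve archetypes and measures the
  artefact discard rate and biomolecule loss rate of the enrichment rule.

Typical values (seeds 0–123): PCA template correlation ≥ 0.92, ARI ≥ 0.95,
artefact discard 100 %, biomolecule loss ≤ 3.2 %. The acceptance script
recomputes all of these for any seed.

## Known limitations

- Profile-mode spectra, baseline subtraction and recalibration are out of
  scope; input is assumed centroided.
- The screening surrogate is a two-number summary; structured artefacts
  (e.g. matrix rings) that happen to be tissue-enriched pass it.
- The carbon-binomial isotope model ignores ²H/¹⁵N/¹⁸O contributions (<1 % for
  these lipids); use full mode where that matters.
- Ether lipids, odd head groups, sn-isomers and negative-ion mode are not
  modelled.
- Ion-image extraction windows can collide when two species lie within
  8 mDa; the resulting mixed images are a property of the data, not
  resolved by the pipeline.
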