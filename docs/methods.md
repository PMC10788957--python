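# Methods

`curvsense` quantifies membrane curvature sensing by peripheral peptides on
a buckled lipid bilayer.  This note records the model, the estimators, the
numerical choices, and what the synthetic verification does and does not
demonstrate.

## The measurement problem

A laterally compressed ("buckled") bilayer exposes a continuous range of
mean curvatures in one periodic box.  A peptide bound to one leaflet
diffuses laterally; the distribution of membrane curvature at its position,
accumulated over a trajectory, reveals its curvature preference.  Two
corrections are essential:

1. **Geometry bias.** The two leaflets are (approximately) parallel
   surfaces of the membrane midplane.  A leaflet is stretched where the
   membrane curves away from it, so even a non-sensing particle visits
   curved regions non-uniformly.  The *accessible-curvature distribution* —
   the area-weighted histogram of curvature present on the peptide's
   leaflet — is the null distribution of a non-sensing particle.  Dividing
   the sampled histogram bin-wise by it ("reweighting") removes the bias; a
   non-sensor reweights to a uniform histogram.
2. **Sign convention.** Curvature is reported per peptide as positive when
   the membrane is convex toward the aqueous phase on the peptide's side.
   Upper- and lower-leaflet peptides are then directly comparable, and a
   buckle crest is positive for the upper-leaflet peptide and negative for
   the lower one.

## Surface model and curvature estimator

Each leaflet's phosphate beads are fitted per frame by ordinary least
squares with a truncated doubly periodic real Fourier basis
{1, cos, sin}(2*pi*m*x/Lx) x {1, cos, sin}(2*pi*n*y/Ly), m <= M, n <= N.
Derivatives and the Monge-gauge mean curvature

    H = [(1+h_y^2) h_xx - 2 h_x h_y h_xy + (1+h_x^2) h_yy]
        / (2 (1+h_x^2+h_y^2)^{3/2})

are evaluated analytically from the coefficients.

The curvature a peptide samples is that of the membrane *midplane*, not of
its phosphate surface: the phosphate surface of a leaflet at offset t from
a midplane of (cylinder) curvature k has curvature k/(1 - s t k)
(s = +1 upper, -1 lower), so each leaflet fit yields a midplane estimate by
inverting this relation.  The inversion amplifies fit noise by
(1 + s t k)^{-2} where the leaflet is the outer, flatter surface; the two
leaflets' estimates are therefore combined with inverse-variance weights
(1 + s t k)^4, after shifting the opposite leaflet's query point laterally
by 2 t grad(h)/g — parallel surfaces share tangent directions, so both
estimates then refer to the same midplane foot point.  The offset t is a
known physical parameter (≈ 2 nm midplane-to-phosphate for a POPC-like
bilayer) or is estimated from the two fits as the box average of
(h_upper - h_lower)/(2 g).

Using the midplane curvature keeps the accessible curvature range symmetric
between crests and troughs.  The only crest/trough asymmetry a non-sensing
peptide then experiences is the leaflet-area excess over regions curving
away from it, which is exactly what reweighting removes: the raw sampled
mean of a non-sensor is biased positive, its reweighted histogram is
uniform, and its reweighted mean vanishes.

**Choice of fit modes.** The basis truncation is a configuration knob
(package default (M, N) = (6, 2)).  For the synthetic mode-1 buckle the
verification studies use (4, 1): the buckle's harmonic content decays
geometrically, so truncation error beyond m = 4 is negligible there, while
per-frame curvature noise grows as k^2 per mode — with ~300 beads per
leaflet and 0.1 nm bead noise, a (6, 2) fit carries ~0.04 1/nm per-frame
curvature noise against ~0.007 1/nm for (4, 1).  Fit modes, bin width and
sign convention are recorded in every output's metadata.

**Cylindrical-curvature assumption.** The parallel-surface inversion treats
the local curvature as cylindrical (one non-zero principal curvature),
exact for the 1D buckle generated here; for weakly 2D-curved membranes the
correction factors commute with averaging to first order in t*k.

## Distributions and statistics

- **Binning.** Uniform bins of width 0.04 1/nm, with edges on a global
  lattice whose bin centers are integer multiples of the width.  The width
  resolves the Boltzmann preference width (2 kappa)^{-1/2} ≈ 0.1 1/nm of a
  kappa = 50 nm^2 sensor: with 0.02-wide bins the adjacent-bin contrast of
  the reweighted histogram (≈ kappa w^2 ≈ 2%) falls below the multinomial
  noise of a few-thousand-frame run and the histogram mode becomes
  unstable; 0.04-wide bins give ≈ 8% contrast.  The lattice makes "the bin
  containing H0" well defined for round preferred curvatures and lets runs
  be pooled or averaged bin-by-bin.
- **Accessible distribution.** Evaluated per frame from the fitted
  surfaces (membrane-curvature values, leaflet-area weights) and averaged
  over all frames, so it carries the same per-frame measurement noise as
  the sampled values — otherwise the noise-smeared tails of the two
  histograms would disagree.  Per frame a stratified-jittered lateral
  quadrature grid (default 64 x 4 points, fixed jitter stream) makes the
  frame average an unbiased quadrature.  The standalone
  `accessible_distribution` operation uses a regular grid (default
  128 x 128).
- **Support floor.** Bins holding < 1e-4 of total accessible mass are
  masked out of the reweighting support; sampled mass falling in masked
  bins is reported (warning above 1%), never silently dropped.
- **Summaries.** Weighted mean = sum(center x mass); weighted median uses
  linear interpolation inside the crossing bin (reported alongside the
  mean because preferred curvatures are conventionally quoted as medians
  when distributions are skewed).  Replica studies report the arithmetic
  mean and standard error over (by default three) independent replicas;
  upper- vs lower-leaflet agreement within combined replica error is the
  convergence check.
- **Uniformity test.** The null "reweighted = uniform" is tested on the
  sampled counts against multinomial expectations from the accessible
  masses (z = (N_k - N a_k)/sqrt(N a_k (1-a_k))), which is equivalent and
  has exact standard errors.

## Insertion depth

Depth is the signed distance from the peptide's centre of mass to the
fitted phosphate surface of its leaflet along the local surface normal,
positive toward the membrane core.  The nearest surface point is found by
a damped (Levenberg-Marquardt) Newton minimization of the squared distance
seeded at the peptide's lateral position (tolerance 1e-6 nm).  The normal
definition, unlike a vertical distance, is rotation-consistent on curved
regions; for gentle buckles the two differ by O(slope^2).

Peptides whose nearest surface contradicts their recorded leaflet are
flagged and excluded from that frame, never silently re-assigned.

## Synthetic membrane generator

The generator emulates a buckled POPC-like bilayer with analytically known
geometry so every estimator can be verified against closed forms:

- midplane z = A sin(2 pi mode x / Lx), invariant along y; leaflet
  surfaces are exact normal-offset (parallel) surfaces at ±t, which is
  what produces the crest/trough area imbalance without modelling lipids;
- phosphate-like beads on a jittered lateral grid (default 1.5 beads/nm^2
  per leaflet, the areal headgroup density of a POPC leaflet) with
  Gaussian noise of sd 0.1 nm along the local normal (the scale of
  phosphate height fluctuations about a frame-wise fitted surface);
- defaults Lx = 20 nm, Ly = 10 nm, A = 2 nm, mode = 1, t = 2 nm.  The
  preferred-curvature recovery study uses A = 3 nm so that target
  curvatures of ±0.08 1/nm lie well inside the accessible range
  ±A q^2/2 = ±0.148 1/nm — at A = 2 the range is ±0.099 1/nm and ±0.08
  sits within half a bin of the support edge, where the reweighted profile
  is intrinsically flat;
- peptides are placed independently each frame from the explicit Boltzmann
  preference density p(x) ∝ exp(-kappa (H(x) - H0)^2) dA(x), with H the
  signed membrane curvature, dA the leaflet area element, by inverse CDF
  on a grid of 1e-3 Lx resolution (no Metropolis autocorrelation), then
  displaced depth d along the inward normal with isotropic Gaussian blur
  sigma_p (default 0.1 nm);
- the non-self-intersection constraint for the offset surfaces is
  t A (2 pi mode/Lx)^2 < 1 (offset below the minimal radius of curvature).

**What the generator does not emulate:** lipid resolution (tails,
headgroup chemistry), packing defects, peptide diffusion dynamics and its
autocorrelation, membrane undulation dynamics, thermal area fluctuations,
and 2D (non-cylindrical) buckles.  Passing the verification studies
demonstrates that the estimators recover known geometry, preferences and
depths under realistic bead noise — not that a particular force field or
real peptide behaves any particular way.  Frames are independent draws, so
convergence questions of slowly diffusing peptides are outside scope by
construction.

## Degenerate and edge cases

- Rank-deficient fits (e.g. all beads at one x) raise an error naming the
  unresolvable basis directions; too few beads for the basis raise an
  insufficient-sampling error at generation or fit time.
- A flat membrane validly concentrates all accessible mass in the bin
  containing zero; reweighting then reproduces the sampled histogram on
  that single bin.
- A peptide exactly equidistant from both leaflet surfaces (within
  1e-6 nm) is an ambiguity error, not an arbitrary assignment.
- A single replica reports its mean with an undefined (NaN) sem.
- The parallel-surface inversion clamps its denominator at 0.2 so an
  isolated pathological fit cannot produce unbounded curvature.

## Units and I/O conventions

Lengths nm, curvature 1/nm, hydropathy kcal/mol; angstrom inputs are
converted at the I/O boundary (`--angstrom`).  Frames are exchanged as GRO
(single or concatenated; residue names UMB/LMB/PEP) or GRO + XTC; x and y
are periodic and wrapped, z is the membrane normal and kept unwrapped with
the midplane near z = 0.  Every summary records fit modes, bin width, sign
and depth conventions, and seeds.

## Hydropathy

Mean hydrophobicity of a sequence is the arithmetic per-residue mean of
Wimley-White transfer free energies (interfacial scale by default, octanol
packaged as an alternative; both stored as versioned CSVs with citations).
Idealized LS peptides are 21-residue leucine/serine helices whose serines
occupy the wheel positions (100°/residue) nearest a 180° polar axis,
giving a single contiguous polar arc; they are labelled LS*n* by serine
count and are stand-ins, not experimentally characterized sequences —
users supply real sequences for non-idealized analyses.

## Known limitations

- The midplane estimate is exact only for parallel leaflet surfaces with
  cylindrical curvature; real bilayers deviate where thickness varies.
- Reweighting support edges inherit measurement-noise smearing; bins just
  outside the true accessible range carry noisy ratios (they are retained,
  with the support floor as the only mask, and dominate neither the mean
  nor the mode at the default settings).
- The LS-family sequences are idealized; hydropathy values depend on the
  scale variant chosen (recorded in output metadata).
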