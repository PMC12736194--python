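# Methods

## Geometric model

A docked pose is a rigid set of atoms in a receptor-fixed Cartesian frame
(Å). No recentering or realignment happens on load: spatial overlap *is*
the signal (co-location in a binding site), so coordinates are taken
verbatim from the SDF/PDB records. Hydrogens are kept when present and
never added or removed; `strip_hydrogens` exists because vendor volume
tools are not unanimous about counting them. Bonds are parsed from SDF
records but enter no volume computation — they only feed ring detection
for pharmacophore typing.

Van der Waals radii are assigned explicitly from a table (never read from
files, never silently defaulted): Bondi (1964) values for the main-group
elements (H 1.20, C 1.70, N 1.55, O 1.52, P 1.80, S 1.80, Cl 1.75,
I 1.98 Å), Fe 2.05 Å following Batsanov's extension for metals, and a
logged 2.0 Å fallback for anything else. Radius lookups are
case-insensitive; table entries outside (0.5, 3.5) Å are rejected as
typos.

## Volume estimation

The molecular volume is the volume of the union of atom spheres; the
co-location statistic is

    overlap(a, b) = 100 · V(a ∩ b) / min(V(a), V(b))  [percent].

Normalizing by the smaller molecule is the only simple convention that
makes the self-set matrix symmetric with an exactly-100 diagonal, both
properties the matrix semantics require. For cross matrices an alternative
row normalization (divide by the row molecule's volume) is available via
`norm="row"`.

**Grid estimator (default).** A cubic grid (default spacing h = 0.2 Å)
covers the padded bounding box. Cells are classified by their center
against every sphere, with a guard band of half the cell diagonal
(δ = √3·h/2): centers deeper than δ inside some sphere are fully occupied
cells; centers farther than δ from every sphere are empty; the remaining
cells straddle a surface and are refined by testing 3×3×3 subcell centers
(effective spacing h/3) against the atoms whose spheres reach them. Plain
single-center counting was measured at +0.5% systematic error on a
two-sphere lens even at 0.15 Å spacing (the lens has a sharp rim, so the
error decays slowly and one-sidedly); the boundary refinement brings both
the sphere and the lens below 0.25% at 0.15 Å while keeping the estimator
deterministic. Intersections use the same classification on the
intersection of the two bounding boxes, with cells required to be inside
*both* unions.

**Monte-Carlo estimator.** Uniform samples over the bounding box with a
fixed seed; it exists as an independent cross-check of the grid, never as
the default.

Numerical conventions:

- If two poses' bounding spheres are disjoint, the intersection is exactly
  0.0 with no grid evaluation — spatially separated sites can never pick
  up sub-cell noise.
- The diagonal of a similarity matrix is set to exactly 100 (the
  self-overlap identity) rather than re-estimated.
- Percent values are kept at full precision internally and rounded to one
  decimal only when a matrix is serialized to CSV.
- Padding defaults to (largest radius + one spacing) and may not be set
  below the largest radius.

## Shape and pharmacophore similarity

Alignment maximizes a *Gaussian* volume overlap: each atom is replaced by
a spherical Gaussian with fixed amplitude 2.7 and decay chosen so the
Gaussian integrates to the atom's hard-sphere volume (Grant–Pickup style);
only first-order (pairwise) overlaps are summed, a documented
approximation. The Gaussian surrogate is smooth in the pose parameters,
which is all it is used for — every *reported* Tanimoto uses hard-sphere
volumes, keeping one volume definition across the package:

    tc_shape = V∩ / (V_ref + V_probe − V∩).

The optimizer centers both molecules on their centroids, seeds four proper
rotations from the principal-axes sign ambiguity, refines each seed by
L-BFGS over (rotation-vector, translation) until the score improvement
falls below 1e-6 Å³ or 200 iterations, and keeps the best; the final score
is never below any seed's. Reflections are never searched — molecules are
chiral, so a mirror image must score strictly below self-similarity.
Degenerate probes (coincident/collinear atoms, where principal axes are
undefined) fall back to translation-only alignment with a warning.

Pharmacophore ("color") similarity uses minimal rule-based typing: donor =
N/O with a hydrogen within 1.2 Å; acceptor = any N/O; cation/anion from
SDF formal charges; ring = centroid of any 5–6-cycle of the bond graph;
hydrophobe = carbon with no N/O within 2.0 Å; all features carry a 1.0 Å
Gaussian width. The color Tanimoto sums same-type Gaussian pair overlaps
after applying the shape alignment; molecules sharing no feature type
score exactly 0. This is a declared simplification of vendor color force
fields, not a reproduction of any of them. The combo score weights shape
and color equally by default; both weights are exposed.

## Displacement classification

Raw propidium displacement is normalized to donepezil (≡ 100%); a compound
is *active* iff its normalized displacement strictly exceeds 50% (exactly
50 → inactive: the boundary breaks toward the conservative call). The
classifier is a Fisher discriminant on two features — percent overlap with
the docked propidium pose and binding energy — implemented directly:
pooled within-class covariance (rejected when its condition number exceeds
1e10), weights `w = Σ⁻¹Δμ`, equal priors with the threshold at the
midpoint of the projected class means (`priors="proportional"` shifts it
by the log prior-odds). No feature standardization is applied: the
discriminant is affine-equivariant, so it would change nothing (verified
by the scale/translation equivariance tests). Accuracy is reported to one
decimal. Leave-one-out jackknifing refits on every fold and errors out if
a fold would lose a class entirely.

The assembled 19-compound study cohort (ten displacing ferrocene
derivatives, seven with zero displacement, donepezil and tacrine) ships as
a labeled table; the individual normalized values of the ten actives were
published only as a group mean and are stored as missing.

## Correlation layer

Pearson *r* with the exact t-transform p-value (n − 2 df); inputs must
have n ≥ 3 and nonzero variance. Normality is checked with the
D'Agostino–Pearson omnibus K² (skewness + kurtosis z² against χ²₂),
refused below n = 20 where the z-approximations degrade. Two dependent
correlations sharing one variable are compared with Steiger's (1980)
modification of the Dunn–Clark z using the mean correlation in the
covariance term; the choice of test is this package's (the underlying
claim of non-significance names none). p-values are returned at full
precision; "p < 0.0001"-style truncation belongs in report text only.

## Synthetic studies

The generator emulates the statistical structure of a small docking
campaign, not its chemistry (no valence model — downstream stages consume
geometry and statistics only):

- **Sites.** Compounds are assigned uniformly to a small number of binding
  sites whose pairwise separation must exceed 25 Å and twice a conservative
  bound on the ligand extent, guaranteeing cross-site overlaps of exactly
  zero. Defaults: two sites 40 Å apart (gorge mouth vs catalytic site),
  site jitter sd 1.0 Å.
- **Molecules.** 10–40 atoms drawn from an isotropic Gaussian (sd 2.0 Å);
  disconnected fragments of the ≤ 2.5 Å contact graph are translated onto
  the main cluster, so every atom's sphere fuses with a neighbor's. Radii
  are sampled from {1.2, 1.52, 1.55, 1.7, 2.05} Å and mapped back to the
  elements that carry them, so poses survive an SDF round trip plus radius
  assignment. The propidium-analog reference is 1.5× the largest compound
  and pinned at the reference site, making it the group's largest volume
  (as the real PAS ligand is).
- **Endpoints.** Ground-truth class = docked at the reference site.
  Binding energies are class-conditional normals (8.5 vs 6.5 kcal/mol,
  sd 0.6 — active compounds bind stronger). Observed labels flip with
  probability 0.05 (label noise). Normalized displacement is drawn
  consistently with the observed label (actives: truncated normal around
  the 84.1% cohort mean; inactives: 0). The graded endpoint is
  `clamp(−30 + 12·Eb + N(0, 10.5²), 0, 100)`, whose intercept puts the
  class means near 72% and 48% (inside the observed 43–90% range) and
  whose default noise makes the population energy–response correlation

      ρ = b·σ_Eb / √(b²σ_Eb² + σ_noise²) ≈ 0.80,

  the strength reported for such campaigns; `expected_r` evaluates the
  closed form (σ_Eb includes the class-mixture variance) and
  `noise_sd_for_r` inverts it. The closed form ignores the [0, 100]
  clamping, which touches only a small tail at the defaults (the
  Monte-Carlo agreement test bounds the discrepancy at < 0.005).
- **Reproducibility.** One study seed drives per-compound
  `SeedSequence` substreams: identical parameters give byte-identical
  SDF/CSV/JSON outputs, and appending a compound never perturbs earlier
  ones.

What passing tests on these studies show — and what they do not: the
pipeline recovers planted site structure, class boundaries and correlation
strength under the stated noise model. Real docking poses add
conformational flexibility, partial site overlap, correlated errors
between energy and geometry, and non-Gaussian endpoint noise, none of
which the generator produces; results on synthetic studies bound
implementation correctness, not real-data performance.

## Problem sizes

Default test and reproduction runs use: 19–21-compound studies for matrix
and classifier checks, 50 alignment-recovery trials, 20–50 poses for
grid-vs-Monte-Carlo comparison (10⁶ samples each), 500 replicate studies
of 200 compounds for correlation recovery, and 500–2000 replicates for
normality-test calibration — sizes at which every recovery target's
sampling error is comfortably below its acceptance band while a full run
stays in the minutes range on one core.

## Known limitations

- Hard-sphere volumes only: no solvent-excluded (Connolly) surfaces, and
  the Gaussian volume is never the reported statistic.
- First-order Gaussian overlaps slightly overestimate dense clusters'
  self-overlap; this affects only the alignment objective, not reported
  volumes.
- The pharmacophore typing is geometric and minimal; it will not reproduce
  vendor color scores.
- The LDA is strictly two-class with a full pooled covariance; no
  shrinkage beyond an error message suggesting jitter when the covariance
  is singular.
- The normality test is refused below n = 20 rather than approximated.
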