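# Methods

## Model

CoMFA represents each aligned ligand by the interaction energies a probe
atom would feel on a rectangular lattice around the superposed set, and
correlates those grid energies with activity by partial least squares.
The core assumptions are (i) the alignment is meaningful — here it is
inherited from docking into a common receptor frame and enforced by the
salt-bridge filter, so no re-superposition is ever applied; (ii) activity
is (after censoring) approximately linear in the field columns; and
(iii) the probe fields capture the relevant physics (steric bulk and
electrostatics only; H-bond/hydrophobic similarity fields are out of
scope).

### Alignment

A pose passes the filter when any protonatable nitrogen (formal charge
+1, or, failing that, a neutral non-amide/non-aryl sp³ amine) is within
`max_dist` of either carboxylate oxygen of the anchor residue.
`max_dist` defaults to 4.0 Å — a conventional salt-bridge cutoff; the
criterion in the underlying protocol is stated only as "interacts".
Among passing poses the representative is chosen by the deterministic
key (anchor distance, −overlap with the family reference pose, pose
index).  The overlap score operationalises "superposition of chemically
equivalent moieties": the fraction of reference heavy atoms with a
same-class atom within 1.5 Å.  Compounds with no passing pose are dropped
and reported, never force-aligned.

### Charges

σ charges are Gasteiger–Marsili PEOE: χ(q) = a + bq + cq², all bond
transfers applied simultaneously from a per-sweep snapshot (this makes
the result exactly permutation-invariant), damped by `damping^k`
(default 0.5, 8 sweeps — converged to ~1e-3 e).  The parameter table is
the published one; hydrogen's cation electronegativity is the customary
20.02 eV.  The π term is simple Hückel per conjugated fragment with a
conventional heteroatom (h, k) set; increments are (core π charge −
π population), so they sum to each fragment's net π charge.  In combined
"gh" mode the formal charges of atoms inside a π system are booked to the
Hückel calculation and removed from the PEOE seed, keeping the total at
the molecular net charge.  Because the commercial Gasteiger–Hückel
parameterisation is not public, plain PEOE is the tested default and the
π term is opt-in; the two differ structurally only on conjugated systems.

### Fields

Steric: 6-12 Lennard-Jones with R* and ε per coarse atom class
(Tripos-5.2-style values shipped in `fields.TRIPOS_LJ_PARAMS`), combined
by R*ᵢⱼ = R*ᵢ + R*_probe and εᵢⱼ = √(εᵢ ε_probe); capped at +30 kcal/mol
(probe-on-atom contacts hit the cap, never a division error).
Electrostatic: 332.0636·q_probe·Σ qᵢ/rᵢ² kcal/mol — the 1/r
distance-dependent dielectric folded into the square — clamped to ±30;
at lattice points inside a molecule's steric envelope (within any atom's
LJ radius) the value is replaced by the column mean of the compounds that
actually see the probe there, the standard CoMFA convention for
meaningless in-core Coulomb values.  Grid: spacing 2.0 Å, margin 4.0 Å,
edges snapped outward to whole steps (this makes the field matrix exactly
invariant under lattice-vector translations of the whole system).
Columns with sd < 2.0 kcal/mol are dropped once, on the full dataset;
each field block is then scaled so its centered total variance is 1
(CoMFA standard scaling).  All of these are the conventional defaults of
the commercial implementation and are exposed in the configuration.

### PLS and validation

NIPALS PLS1 on column-centered data (no autoscaling beyond the block
scaling); regression vector b = W(PᵀW)⁻¹q.  Leave-one-out refits include
re-centering but not re-selection of retained columns (the Sybyl-like
convention); one LOO sweep harvests predictions at every component count
from the per-fold NIPALS decomposition, and unit tests pin it to naive
per-sample refitting at 1e-8.  Q² = 1 − PRESS/SS_tot;
SEP = √(PRESS/(n−c−1)) — the n−c−1 convention is the default, with the
plain-n variant selectable.  ONC maximises Q² with ties (within 1e-12)
broken by smaller SEP, then fewer components.  F = R²(n−c−1)/(c(1−R²)):
this convention reproduces the canonical printed (R² ≈ 0.92, F = 338.9)
pair at n = 160, c = 5, which is how it was identified.  External R² is
the squared Pearson correlation of observed versus predicted — the one
convention under which training and test statistics are the same
quantity.  Field contributions are Σⱼ|bⱼ|·sdⱼ per block, normalised
to 100 %.

Progressive scrambling sorts y, partitions it into n_bins contiguous
bins (2–10, 10 repetitions each) and permutes within bins; R²yy is the
squared correlation of perturbed to original y.  Per component count, a
quadratic of perturbed LOO Q² on R²yy (the unperturbed point included as
anchor) is evaluated at the critical point 0.85: Q²s (reported in the
table's Q² column), cSDEP = √((1−Q²s)·SS_tot/(n−c−1)), and the slope
dQ²/dR²yy.  The raw perturbation cloud is kept alongside the summary, so
both the critical-point-adjusted and the raw unperturbed Q² are
available.

### Contours

STDEV*COEFF = bⱼ·sdⱼ per retained column, mapped back to the lattice
(dropped columns are zero).  Default isolevels: 80th percentile of the
positive values (favoured) and 20th percentile of the negative values
(disfavoured) — absent signs are flagged rather than invented.  Export is
OpenDX text (z fastest), round-tripped in tests against an independent
parser.  Interpretation against receptor residues is left to the viewer.

## The synthetic benchmark

The generator fabricates what the pipeline would receive from a real
docking campaign: 176 pseudo-ligands alternating between a benzamide-like
and an arylpiperazine-like scaffold, each a geometrically plausible atom
cloud (valid elements, bonds, formal charges) with its cationic nitrogen
fixed 3 Å from a synthetic aspartate carboxylate, decorated at fixed
sites with random substituents (alkyl, halogen, polar, phenyl; occupancy
0.55) plus 0.05 Å coordinate jitter.  Charges, fields and filtering then
run through the production code, and activities are planted on the
resulting field columns: five latent directions, each a sparsified
principal direction of the field matrix (top 40 loadings, ~2:1
steric:electrostatic support), orthogonalised and weighted 0.55…0.35,
plus Gaussian noise of 0.3 pIC₅₀ units, affinely mapped onto 5–9.4 with
the weakest 8 % left-censored at exactly 5.0.

The latent directions are drawn from well-separated parts of the variance
spectrum (principal components 0, 3, 7, 12, 18 by default).  This is what
makes the planted component count the true model dimension: PLS is a
Krylov method and resolves roughly one component per distinct eigenvalue
cluster carrying signal, so directions packed into the top of the
spectrum would be absorbed in 2–3 components regardless of how many were
planted — the same reason real field matrices support models of several
components.  A multi-pose mode emits 20 poses per compound of which
exactly one is alignable, exercising the filter's bookkeeping.

What the benchmark does not emulate: real conformational/protomer
diversity, docking-pose noise correlated with activity, assay
heterogeneity, and activity cliffs.  Passing tests therefore demonstrate
that the machinery recovers a known field-linear model under realistic
shape, size, censoring and noise — not that any particular real dataset
would yield a good model.

Censoring interacts with validation exactly as in real data: pinned
records violate linearity, and because the split criteria force the
held-out set to span 5–9, censored compounds always sit in the test set;
on the default benchmark this holds external R² around 0.90 even though
LOO Q² is ≈ 0.88 (the squared-Pearson on the non-censored test subset is
higher).

## Numerical choices and degenerate inputs

* Steric cap +30 kcal/mol, electrostatic clamp ±30; probe-atom distances
  floored at 1e-6 Å so coincident points hit the cap deterministically.
* Zero-variance y, empty datasets, unparseable records, residues without
  carboxylate atoms, open-shell π fragments and degenerate quadratic
  scrambling fits all raise (or warn and skip) with the offending record
  named.
* Degenerate Hückel shells are filled as whole degenerate blocks so
  symmetric molecules get exactly symmetric π charges.
* R² = 1 reports F as +inf rather than raising.
* All randomness flows through `numpy.random.default_rng` seeds;
  re-running any stage with the same configuration is bit-identical on a
  fixed platform (BLAS determinism is assumed within one machine).

## Problem sizes

The default benchmark produces a (18, 12, 11) lattice → 4752 raw
columns, ~270 after the sigma filter.  Component selection scans 1–10
components by full LOO on 160 compounds; progressive scrambling runs
9 bin levels × 10 repetitions, each with a full LOO sweep — about 15 s
single-core for the whole pipeline, which is the scale the package
targets (hundreds of compounds, thousands of grid points).

## Known limitations

* Tripos force-field parameters are a published-values reconstruction by
  coarse atom class, not the full commercial atom-type table.
* The Hückel heteroatom parameters are the textbook set; the commercial
  Gasteiger–Hückel tables are proprietary and no claim of numerical
  equivalence is made.
* `read_poses` maps SYBYL/MOL2 atom types through RDKit's perception;
  exotic atom types may need manual classes.
* The split repairs (activity span, family coverage) assume such a split
  exists; tables with a single extreme-activity record are rejected
  rather than silently relaxed.
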