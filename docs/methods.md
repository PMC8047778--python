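# Methods

`permut` computes absolute solvation entropies and spatially resolved
entropy maps from atomistic trajectories of identical solvent molecules.
This note records the model, the estimators, the numerical choices and the
limitations; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Entropy model

The total solvent entropy is split as

    S_tot = S_trans + S_rot - I_trans-rot

The translational part separates further into an analytic kinetic term and
a configurational term,

    S_kin / R  = 3/2 - 3 ln(lambda / l),     lambda = h / sqrt(2 pi m k_B T)

with molecular mass `m`, temperature `T` and an arbitrary reference length
`l` (default 1 nm) that renders the configurational density dimensionless.
`l` shifts `S_kin` and `S_conf` by opposite amounts (+-3 R ln l); the total
is invariant, which the suite asserts. For a noninteracting gas the sum has
the closed Sackur-Tetrode form `S/R = ln(1/(rho lambda^3)) + 5/2` — the
analytic anchor for every ideal-gas check (argon, 300 K, 27 nm^-3:
96.6 J mol^-1 K^-1).

`S_conf` is sampled directly from the trajectory, which raises two
problems this package exists to solve:

1. **Permutation redundancy.** N identical molecules make the sampled
   configuration-space volume N! times larger than physically necessary.
   Every frame is therefore relabeled with the permutation minimizing the
   summed squared minimum-image distance to a fixed reference configuration
   (a simple-cubic lattice filling the box, or a chosen frame). The
   relabeling is an exact linear sum assignment on the dense N x N
   squared-distance matrix; an optional sparse mode restricts candidates to
   reference sites within a cutoff (default 1.5 nm) and falls back to the
   dense problem if infeasible. After reduction each molecule is localized
   near its reference site, so low-dimensional marginals are meaningful.

2. **Dimensionality.** The 3N-dimensional entropy is expanded in a
   mutual-information series truncated at third order:

       S ~= sum_i S_i - sum_{i<j} I2(i,j) + sum_{i<j<k} I3(i,j,k)

   with `I2 = S_i + S_j - S_ij` and the interaction information
   `I3 = sum S1 - sum S2 + S3`. The signs are fixed by requiring exactness
   for jointly Gaussian molecules, which the suite verifies against the
   9-D closed form. Pair terms are evaluated for molecules whose
   time-averaged minimum-image distance is below 1.0 nm; triple terms
   require all three legs below a smaller cutoff (0.45 nm for argon-like
   liquids, 0.33 nm for water). Beyond those distances the MI of localized
   molecules is indistinguishable from estimator noise (measured on the
   ideal gas: pair MI decays from ~0.06 nats at lattice contact to zero by
   ~0.65 nm).

## Entropy and mutual-information estimators

Marginal entropies use the Kozachenko-Leonenko k-nearest-neighbor
estimator (`k = 1` by default),

    H_hat = psi(n_f) - psi(k) + (1/n_f) sum_i ln V(r_ik)

where `V` is the metric-ball volume of the space: the Euclidean d-ball for
translational marginals, the SO(3) cap volume `pi (2a - sin 2a)`,
`a = 2 arcsin(r/2)`, under the chordal quaternion metric
`d_quat = min(|q1-q2|, |q1+q2|)` (total volume pi^2, so uniform
orientations have entropy ln pi^2), and a numerically integrated volume for
the composite translational-rotational metric
`d = sqrt((xi d_eucl)^2 + d_quat^2)`. The composite volume is cached on a
4096-point log-radius grid with monotone cubic interpolation (relative
interpolation error < 1e-6 against direct quadrature); the scaling factor
`xi` defaults to 10 nm^-1 and results are insensitive to 20-30 nm^-1, which
the suite asserts at three standard errors. Neighbor searches use k-d
trees; SO(3) and composite searches insert both quaternion hemispheres and
discard duplicate sample indices, which is exact for these chordal metrics.
Periodic Euclidean searches use the toroidal topology of the tree directly;
localized (permutation-reduced) molecules are searched unwrapped unless
their spread exceeds a quarter box edge.

**Mutual-information terms.** Forming `I2` as a difference of independent
entropy estimates converges poorly on permutation-reduced data: the
marginals inherit sharp assignment-cell boundaries, and the boundary bias
of the 6-D joint estimate does not cancel against the 3-D marginals. On
the 216-particle ideal gas the difference route gives a second-order sum
of -15.7 J mol^-1 K^-1 at n_f = 1e4 and -11.8 at n_f = 1e5 with no sign of
convergence, even though the true pseudocorrelations are small. The
package therefore defaults to the matched-radius
Kraskov-Stogbauer-Grassberger (KSG) estimator for `I2` and for the
three-block multi-information (from which `I3` follows by
`I3 = I2_ij + I2_ik + I2_jk - M3`): marginal neighbor counts are taken at
the Chebyshev radius fixed by each sample's k-th joint neighbor, so the
leading finite-sample biases cancel. With it the ideal-gas pair
pseudocorrelation is stable in n_f (~0.06 nats at lattice contact) and the
second-order sum settles near -2.6 J mol^-1 K^-1; the third-order total
lands within ~1% of the Sackur-Tetrode value, which is the accuracy the
method is designed to deliver. The difference route remains available as
`method="difference"` for comparison. Published second-order values for
this system are estimator- and sample-size-specific; the package reports
the better-converged matched-radius number.

Two computational reductions keep large sweeps affordable without
affecting expectations: the mean over query points of `ln V(r_ik)` (or of
the KSG count terms) may be taken over a seeded random subset of query
points while neighbors are searched among all samples (`query_subsample`;
pure variance, no bias, and the variance averages out over thousands of
pair terms), and marginal neighbor counting uses an exact cell-grid range
counter built once per molecule.

**Degenerate inputs.** Duplicate samples give zero neighbor distance; the
default policy raises, an opt-in policy applies a deterministic 1e-9 nm
jitter and logs it. Ties in assignment or neighbor order are broken
deterministically and are measure-zero for continuous data.

## Rotational degrees of freedom

Orientations are extracted per frame as unit quaternions via Horn's
quaternion eigenvector method: the proper rotation optimally superimposing
a fixed site template (default: the first molecule's centered sites of the
first frame) onto each molecule's sites. Collinear site sets and fits with
superposition RMSD above 0.02 nm (non-rigid molecules or
reflection-requiring matches) are rejected. First-order rotational
entropies use the SO(3) estimator; they are reported relative to the
uniform-orientation reference and no rotational kinetic constant is added,
so only rotational entropy *differences* are meaningful — a documented
limitation. The translation-rotation coupling `I_tr(j,k) = S(x_j) + S(q_k)
- S(x_j, q_k)` is estimated in the composite space; the pair set defaults
to all self-pairs plus cross pairs within the pair cutoff (self-coupling
dominates and cross terms decay with distance), with a self-only mode
available.

The scale factor xi presumes the position and orientation spreads are
comparable after scaling — the regime of liquid water, whose orientations
are broad on SO(3) while positions localize to ~0.1-0.3 nm. For
concentrated orientation distributions the composite kNN balls become
anisotropic relative to the density and the joint estimate degrades; the
suite therefore probes translation-rotation coupling on broad-orientation
fixtures. Within that regime the I_tr estimate is stable under xi = 10 ->
20 nm^-1 at three standard errors; at xi = 30 nm^-1 a residual
finite-sample shift of ~0.2 nats remains at 1.5x10^4 frames, decaying
roughly as n^(-1/3) — a documented limit of the composite-metric estimate
at desk-scale sampling.

## Spatial resolution

Pair MI is split half/half and triple MI a third each among the molecules
involved; translation-rotation terms split between their two molecules
(all to one molecule for self terms). The resulting per-molecule values
sum to the assembled total exactly (asserted at 1e-10 relative). Hydration
shells are the `n` molecules (paper-style usage: 100) whose time-averaged
position is closest to any solute site, with a per-frame-average
alternative behind a flag. Voxel maps (default 128^3) average the
per-molecule values weighted by the frames each molecule spends in each
voxel; voxels never visited are NaN (undefined, not zero), and an optional
bulk reference (mean over molecules farther than 1.2 nm from the solute)
turns the map into an entropy difference map. Maps are written as OpenDX
scalar fields.

## Synthetic data

All tests run on generated inputs; identical spec + seed reproduce
bit-identical trajectories.

* `ideal_gas` draws positions i.i.d. uniform per frame — the equilibrium
  distribution of a noninteracting gas, with the Sackur-Tetrode oracle.
  Real trajectories are time-correlated; i.i.d. frames model the paper's
  10-ps sampling interval as fully decorrelated, so passing tests bound
  estimator behavior on independent samples only.
* `correlated_gaussian` samples a specified joint Gaussian around lattice
  sites and attaches the closed-form entropy — the oracle for every MI
  sign and exactness check.
* `lj_argon` samples a Lennard-Jones fluid (sigma = 0.3405 nm,
  epsilon/k_B = 119.8 K, 1.2 nm cutoff — standard argon parameters, chosen
  because the tool is force-field-agnostic) by single-particle Metropolis
  Monte Carlo from a lattice start, with adjustable equilibration sweeps
  and sweeps between frames. MC targets the exact NVT distribution without
  an MD engine, but consecutive frames remain partially correlated, which
  lowers the effective sample count of MI terms.
* `rigid_rotor` builds three-site rigid molecules with ideal-gas positions
  and either Haar-uniform orientations (zero translation-rotation
  coupling) or orientations tied to the position octant with a small
  random wobble (tunable, strictly positive coupling).

## Default problem sizes

The validation studies run at sizes a single CPU handles in minutes, at
the same number density (27 nm^-3) and temperature (300 K) as the
full-scale system they downscale: the ideal-gas study uses 216 particles
(6^3 reference lattice in a (2 nm)^3 box) with 2x10^4 frames, MI terms
with 2000 query points per term; the LJ study uses 216 particles with a
0.9 nm potential cutoff (2.64 sigma; the box must exceed twice the
cutoff) and 800 frames spaced 450 MC sweeps apart after 2000
equilibration sweeps. The spacing matters: kNN estimators assume
independent samples, and frames closer than the positional decorrelation
time make each sample's nearest neighbor its own temporal neighbor,
collapsing every entropy estimate. At the default spacing the lag-one
autocorrelation of the permutation-localized coordinates is ~0.04. At
these sizes the first-order entropies are converged (ideal gas within
its tolerance of the full-scale value; third-order ideal-gas total ~1%
from the analytic reference), but the LJ pair-correlation term remains
sampling-limited: with 800 frames the strong pair MI of a dense fluid is
underestimated, so the reduced-scale LJ total overestimates the entropy
by of order ten J mol^-1 K^-1. Converged third-order results for the
interacting fluid need O(10^5) decorrelated frames — hours of compute —
and are out of scope for the default suite; the qualitative ordering
(interacting fluid well below the ideal gas at equal density and
temperature) is asserted instead.

## Known limitations

* Frames are treated as decorrelated samples; no autocorrelation
  correction is applied.
* Only orthorhombic boxes; triclinic inputs are rejected.
* No solute-solvent correlation terms, no conformational (internal)
  solvent entropy, no expansion beyond third order.
* The rotational kinetic constant is omitted (differences only).
* Ideal-gas triples: with mean positions on a cubic lattice at 27 nm^-3,
  the all-legs rule at 0.45 nm selects no triples (the face diagonal is
  0.471 nm), so the ideal-gas third-order term is exactly zero; triples
  appear as soon as interactions displace the mean positions.
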