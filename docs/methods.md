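# Methods

This note documents the models, numerical choices and known limitations of
`ensaxs`. It is the package's own account of its procedures; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Bead model

Proteins are represented as one bead per residue at the Cα/backbone-bead
position, 1-based residue numbering, chain IDs for subunits. Each bead
carries a forward scattering factor f(0) (default 1, dimensionless in
synthetic use) and a net charge used only by the synthetic generator's bias
term. Coordinates and cutoffs are in Å, momentum transfer q in Å⁻¹.

## Debye calculator and the (c1, c2) form-factor model

Profiles are computed with the Debye double sum
I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sinc(q rᵢⱼ). Atomic-level excluded-volume and
hydration-layer corrections cannot apply verbatim to a one-bead-per-residue
model, so the adjustable form factor is a documented simplified analogue
preserving the roles of the two conventional fit parameters:

    fᵢ(q) = fᵢ(0)·exp(−(q σ_b c1)²/2) + c2·hᵢ·exp(−(q σ_w)²/2)

* c1 ∈ [0.95, 1.05] — effective excluded volume via the bead width
  (σ_b = 3.0 Å default);
* c2 ∈ [−2, 4] — hydration-layer amplitude on exposed beads
  (σ_w = 3.0 Å default);
* hᵢ — a deterministic solvent-exposure proxy,
  hᵢ = 1 − (neighbours within 7 Å)/12, clipped to [0, 1]; a cheap stand-in
  for a SASA calculation.

Because f is affine in the two q-dependent envelopes, the Debye sum splits
into three conformer-specific structure factors (f·f, f·h, h·h) computed
once per conformer (`DebyeFactors`); scanning (c1, c2) afterwards is O(M)
per evaluation. (c1, c2) fitting uses a coarse grid over the parameter box
(the neutral point c1=1, c2=0 is always a grid node) followed by bounded
1-D refinement per axis, with the multiplicative scale refit in closed form
at every evaluation. A free scale is included in all profile fitting since
synthetic data carry no absolute calibration; a constant offset is off by
default. Calculated profiles are linearly interpolated onto a data q-grid;
extrapolation is an error.

## Maximum-entropy reweighting

The objective L(w) = χ²(w)/2 − θ·S(w) is minimized over the simplex through
its convex dual: w_j(μ) ∝ w⁰_j exp(−μ·x_j) with x_ji = I_ji/σ_i, and
Γ(μ) = log Z(μ) + μ·y + (θ/2)|μ|² minimized by a damped Newton iteration
(analytic gradient and Hessian = covariance of x under w plus θI) started
from μ = 0, i.e. w = w⁰, with an L-BFGS-B fallback. The design is
standardized by σ and centred on the prior average for conditioning;
log-sum-exp guards the Gibbs weights. The dual is cheap because the number
of data points M (≤ ~60 here) is far below the number of snapshots N.
Convergence demands a vanishing dual gradient (relative tolerance 1e-8) and
stable objective (1e-10); failure of both routes raises with diagnostics.
The solver is deterministic.

χ² uses the raw formula with no scale factor by default, matching the
objective's definition; an optional global multiplicative scale (applied to
the calculated profiles, refit in closed form alternately with the weights)
is available and is switched on inside the iterative protocol, where
per-snapshot profile fitting already implies scale freedom. Whether a
per-snapshot or global scale is intended in such protocols is genuinely
open; the global-scale-on-the-weighted-average choice is this package's
default and the switch is exposed.

The two-round iterative protocol: (1) fit (c1, c2) and scale per snapshot
against the target; (2) BME with those per-snapshot profiles; (3) average
(c1, c2) with the BME weights; (4) recompute all profiles at the fixed
averaged parameters; (5) BME again. Both rounds are logged on the result.

θ selection: the default automation picks the maximum-curvature elbow of
the (log χ², S) trade-off curve from a 12-point logarithmic θ scan
(0.1–10⁴); a φ_eff-threshold criterion (keep φ_eff above, e.g., 0.7) is
available as the alternative selector. θ does not transfer between data
sets — it must be rechosen per target.

## Synthetic ensembles

The generator emulates ensembles of an HP1α-like protein:

* **Monomer (ΔCSD-like)**: 120 residues, rigid CD-like globule at 19–74,
  flexible N-tail (1–18) and C-tail (75–120). Available as one- and
  two-molecule systems (two-molecule: initial centroid separation > 60 Å
  before relaxation).
* **Dimer (full-length-like)**: two 191-residue chains, a CD globule per
  chain and a shared rigid CSD-dimer core at 113–173 built from two adjacent
  copies of one globule.
* **Charges**: basic segments +1, acidic segments −1, phosphoserines (11–14
  when phosphorylated) −2. The b3/b4/b6/b7 anchors (≈40–44, 68–72, 89–92,
  102–105) follow the protein; the remaining segment ranges are a declared
  emulation of the alternating acidic/basic layout, not a sequence map.

Geometry: Cα virtual bond 3.8 Å (exact on flexible segments), hard-sphere
excluded volume 4.0 Å. Rigid-domain templates are compact self-avoiding
walks grown greedily around an attractor offset from the first bead (keeping
chain termini on the surface for tail attachment), accepted only if
Rg ≤ 0.9·3.8·n^0.33 and all non-bonded pairs ≥ 4.0 Å; templates are
deterministic in (n, seed) and identical across all samples, so rigid-domain
internal distances are invariant by construction.

Conformers are grown rigid-bodies-first, flexible runs outward from their
anchors as excluded-volume random walks, then refined by seeded Metropolis
Monte Carlo with energy E = −κ · (number of phosphoserine/basic-bead pairs
within 8 Å). Moves: tail regrowth (global, proposals built clash-free),
pivot and crankshaft (local, hinge bonds preserved exactly by the rigid
rotation), and rigid-body translations/rotations of whole molecules in
multi-molecule systems; 6 sweeps (moves per flexible bead) by default.
κ = 0 samples the unbiased chain; κ = 5 compacts the tails onto the basic
segments, emulating phosphorylation-driven compaction. Compaction is a
contact-count bias rather than full electrostatics: the analysis pipeline,
not the force field, is the package's subject. The regrowth acceptance
treats the unbiased-growth proposal density as symmetric, ignoring
dead-end (Rosenbluth) corrections — adequate for a generator whose role is
a controllable, reproducible ensemble, not an equilibrium force field.

Mixtures allocate members deterministically (⌊N·f⌋ plus remainder by
largest fractional part, ties to the largest fraction then lowest index);
per-member seeds spawn from the mixture seed. Target profiles are
I_true = Σ w*_j I_j plus Gaussian noise with
σ(q) = noise_frac·I_true·(1 + q/q_max); defaults: q ∈ [0.01, 0.30] Å⁻¹,
60 log-spaced points (a typical usable SEC-SAXS range), noise_frac 0.02
(1% in the recovery study). The study-scale default of N = 500 conformers
is a desk-scale stand-in for trajectory-scale ensembles (thousands of
snapshots); this scales the statistics, not the method.

What passing tests show — and don't: the generator provides rigid cores,
flexible linkers, controlled compaction and known mixing fractions, so
recovery tests demonstrate the estimator and pipeline are correct and
well-conditioned under realistic noise. Real data add features the
generator omits (inter-particle structure factor, buffer-subtraction
artifacts, atomic form factors, hydration asymmetry), so passing here does
not certify accuracy on measured profiles.

## Guinier, P(r), Dmax

Guinier: linear fit of ln I vs q² on the largest low-q window satisfying
q_max·Rg ≤ 1.3 (the standard criterion), found by iterative trimming
(fit, trim to the limit, refit); at least 5 points; non-positive
intensities or a rising low-q profile are errors. The explicit trim rule
replaces automated range finders whose criteria are not reproducible.

P(r) from coordinates is the f_i·f_j-weighted histogram of bead pair
distances (self-terms excluded; their constant contribution to I is O(1/N)
of I(0)); for ensembles, per-conformer histograms mix with the ensemble
weights, and Dmax is the largest pair distance — this route is exact for
bead models and serves as the oracle for the profile route.

P(r) from a profile: non-negative least squares on 101 nodes over
[0, Dmax], forward model I(q) = 4π Σ_r P(r) sinc(qr) Δr, second-difference
smoothness penalty α, endpoints pinned to zero. α defaults to a 10-point
logarithmic generalized-cross-validation scan (the degrees of freedom of
the unconstrained ridge smoother approximate the NNLS df). α = 0 is
refused when the system is ill-conditioned (M < unknowns), with a message
advising α > 0.

Dmax scan: P(r) inversion per candidate; score = fit χ² + M·(P(r) mass in
the last 5% of bins). χ² falls steeply while the candidate underestimates
the true Dmax and plateaus above it, so the estimate is the smallest
candidate whose score is within 5% of the minimum — a declared tie-break
on the plateau.

## Contact maps and clustering

A residue pair interacts in a conformer when their beads are within 11 Å;
the map is the weight-averaged indicator. Intra-chain maps average the two
subunits of a dimer; inter-chain maps combine both subunit pairings and are
symmetrized (which pairing convention a reported inter-subunit map uses is
ambiguous in general; symmetrization is this package's declared choice).

Clustering is the GROMOS leader algorithm with the weight-sum modification:
pairwise Cα RMSD over a stated residue selection after superposition on a
stated selection (e.g. RMSD over 11–14, 19–74, 89–91, 102–107 (+ CSD for
dimers) after superposing the folded core; cutoffs 20 Å for the dimer,
10 Å for the two-molecule system); iteratively, the unassigned conformer
whose unassigned neighbours (RMSD ≤ cutoff, self included — the standard
GROMOS convention) have the largest *summed weight* becomes a center, ties
broken by lowest index; clusters are reported by descending weight. With
uniform weights this reduces exactly to classic neighbour-count GROMOS
(verified against an independent reimplementation). For dimers and
two-molecule systems the subunit labelling is arbitrary, so the
chain-swapped RMSD minimum is taken before the cutoff comparison. RMSD is
unweighted over the selected beads (whether mass weighting is intended in
published protocols is typically unstated; unweighted is declared here).

## Genetic-algorithm sub-ensemble selection

Chromosomes are multisets of K pool indices (repetition allowed, matching
EOM practice); fitness is the χ² of the scale-fitted uniform average of the
K member profiles against the target. Tournament selection (size 3),
single-point crossover (rate 0.8), per-gene mutation to a random pool index
(rate 0.02), elitism 2; population 100, 200 generations by default —
declared desk-scale defaults, not inferred from any published internals.
Fixed seeds give bit-identical runs; pool-vs-selected Dmax/Rg histograms
("before"/"after") are normalized on a shared grid.

## Chemical-shift perturbation

Δδ = sqrt(Δδ_H² + (Δδ_N/5)²) per residue present in both peak lists;
residues missing from either condition are reported absent, never imputed
as zero (exchange-broadened peaks carry information). Per-segment summaries
flag residues with Δδ > mean + k·SD over all residues (k = 1 default — a
package default; no universal numeric criterion exists).

## Determinism and configuration

Every stochastic stage takes an explicit seed; the pipeline driver writes a
manifest (config, seeds, version, outputs) sufficient to reproduce any
artifact, and repeated runs with the same config are bit-identical. The
pipeline config is YAML with strict key validation.

## Known limitations

* The Debye form factor is residue-level; no parity with atomic-level
  calculators is intended.
* The P(r) inversion is a simplified regularized NNLS, not a reimplementation
  of perceptual-criteria packages.
* The generator's two-molecule relaxation explores association only through
  rigid-body moves plus tail moves; association/dissociation kinetics are
  out of scope.
* Bootstrap-style error bars on BME weights are not provided.
* chain-swap handling enumerates subunit permutations only for 2 chains.
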