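# Methods

This note documents the models and conventions the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Network proximity screen

**Model.** The interactome is an undirected, unweighted graph over gene
symbols; identifiers are matched exactly and case-sensitively, with no alias
resolution. Self-loops and duplicate edges are dropped at load time (counts
logged). The drug–disease distance is the mean, over a drug's targets
mapped to the network, of the shortest-path distance to the nearest disease
gene plus a degree-dependent weight, −ln(D+1), granted only when the target
is itself a disease gene. The weight is what makes the score sign-carrying:
without any weighted target the score is a plain non-negative
closest-distance average, and the selection rule (distance < 0) can only
fire through direct targeting of connected disease genes.

**Reported statistic.** The raw weighted distance is the ranked and
selected quantity. The size-matched reference distribution (uniform random
node sets of the drug's mapped-target count, scored by the same rule,
weights included when a sampled node happens to be a disease gene) is
supplementary: it yields a per-drug z-score, cached per target count so
results are independent of drug order. Random sets are size-matched only —
not degree-matched — because the null being asked is "a random protein set
of this size", not "a random set with this degree profile".

**Edge cases.** Targets absent from the network are dropped with a log
line; a drug with no mapped target is unscorable, never scored zero
(silent zeros would fabricate proximity). A target unreachable from every
disease gene has an undefined closest distance and is dropped; if all
targets drop, the drug is unscorable and reported separately. Disconnected
node pairs return an explicit sentinel rather than a large number so that
this policy lives in one place.

**Parameters.** `n_samples` (default 1000) trades null precision for time;
the per-count sub-seed is derived deterministically from the run seed, which
is recorded in the output manifest. Ties in the ranking are broken by drug
id so output is reproducible byte-for-byte.

## Trajectory metrics

**Superposition.** All metrics first remove rigid-body motion by Kabsch
superposition (SVD-based, reflection-corrected, via
`scipy.spatial.transform.Rotation.align_vectors`). RMSD uses frame 0 as
reference (the common simulation-tool convention); RMSF, DCCM, and PCA use
the mean structure, computed with one refinement pass (align to frame 0,
average, re-align to the average). A separate fit mask may be supplied to
fit on one atom group and measure another.

**Definitions.** RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩), aggregated within a
residue by root-mean-square over its masked atoms. The cross-correlation
matrix uses one representative point per residue — the unweighted centroid
of its masked atoms (with a Cα-only mask this reduces to the conventional
Cα correlation; the centroid degrades gracefully for ligands) — and is
C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), clipped to [−1,1],
symmetric, unit diagonal; zero-variance residues get zeroed off-diagonal
rows with a warning rather than NaNs. PCA is the SVD of the centered,
superposed coordinate matrix, equivalent to diagonalising the 3N×3N
covariance; rank deficiency is handled naturally and variance fractions sum
to one by construction.

**Free-energy landscape.** F(bin) = −k_B·T·ln(P/P_max) on a 2D histogram of
(PC1, PC2), with k_B = 0.0019872 kcal/mol/K, default T = 310 K and 50×50
bins. Computing the ratio against the maximal count keeps the occupied
minimum at exactly zero in floating point; empty bins are NaN-masked. The
trailing convergence window (default: final 20% of frames, count rounded
up) is exposed for use upstream of landscapes and energy averaging.

**A note on superposition attenuation.** Least-squares fitting absorbs
whatever part of the internal motion resembles a rigid displacement, so a
concerted segment's amplitude and inter-residue correlation are slightly
attenuated after superposition — the effect shrinks as the moving segment
becomes a smaller fraction of the fitted atoms. This is a property of the
analysis itself, not an implementation artifact, and it shapes how the
synthetic generator is built (below).

## Energy aggregation

ΔG_bind is the exact sum of the four components (van der Waals,
electrostatic, polar solvation, nonpolar solvation), kept at full precision
internally and rounded to two decimals only for display. Per-frame
component tables are averaged componentwise over the trailing convergence
window before summation. Affinity labels use the conventional bands
(Weak −1.36…−5.46, Medium −6.83…−8.19, Strong −9.56…−12.29, Very strong
−13.66…−16.39 kcal/mol). The bands are gapped and bounded, so a value in a
gap or beyond the strongest band takes the nearest boundary's label with an
"(extrapolated)" qualifier, and anything weaker than −1.36 is "negligible";
this makes classification total and monotone without inventing thresholds.

## Compound and expression filters

Rule-of-five violations count {MW > 500 Da, LogP > 5, donors > 5,
acceptors > 10}; a compound passes with at most one violation (the standard
usage — no stricter threshold is claimed). Descriptors are inputs, not
computed from structure, and a PAINS flag from an external substructure
screen is passed through untouched.

The expression screen runs a two-sided Welch (unequal-variance) t-test and
classic pooled-SD Cohen's d per gene, selecting p < 0.05 and |d| > 0.8, with
direction retained in the output. No multiple-testing correction is applied
by default — the thresholds are used exactly as stated — but a
Benjamini–Hochberg q-value column is available as information. Genes with
zero pooled SD are excluded with a warning. The vectorised screen is tested
against the scalar per-gene path.

## Synthetic generators

All generators are pure functions of (scenario, seed).

**Networks.** A preferential-attachment graph (default 600 nodes, m = 2)
mimics interactome degree heterogeneity — heavy-tailed degrees are what
make the −ln(D+1) term consequential; a configuration-model alternative is
provided. The disease module is a connected sample grown preferentially
through low-degree nodes, keeping it peripheral so that nodes three or more
hops away exist. Drug classes are planted by construction:
"proximal-weighted" drugs target disease genes of degree ≥ 1 (distance
negative, guaranteed), "proximal-unweighted" drugs target non-disease first
neighbours (distance exactly 1), "remote" drugs target nodes ≥ 3 hops out.
Scenarios that cannot realise a class raise rather than degrade.

**Trajectories.** One Cα point per residue fluctuates about a helical
reference with Gaussian displacements: per-axis amplitude σ_i/√3 and a
planted inter-residue correlation matrix (identity plus user blocks,
validated positive semi-definite before Cholesky sampling). Displacements
are projected onto the orthogonal complement of the six rigid-body modes
and then rescaled — using the projected covariance, not a sample estimate —
so each residue's marginal amplitude is exactly σ_i. Internal protein
motions carry no net translation or rotation, so this is the physically
sensible convention, and it makes the planted amplitudes identifiable after
superposition (without it, fitting absorbs 5–10% of the planted signal).
A low-dimensional variant plants motion modes with chosen variances along
random directions drawn orthogonal to the rigid subspace, for PCA tests.
An optional random global rotation/translation per frame exercises the
superposition path. Residual attenuation of planted block correlations
(≈0.02–0.03 at 150 residues with a 6-residue block) remains, as expected
from the analysis itself.

What the generator does **not** emulate: real protein topology, anharmonic
or multi-basin dynamics, solvent, or force-field physics. Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimators on their statistical model, not fidelity to any particular
simulated system.

**Expression.** Gene baselines ~ N(8, 2) with i.i.d. unit-SD log-scale
noise across samples (default 10 cases vs 10 controls, a small
patient/control cohort); planted genes have their case mean shifted by
d·SD. Real expression data's correlation structure, heteroscedasticity, and
library-size effects are not modelled, so calibration results speak to the
test statistics, not to cohort artifacts.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale instances chosen to keep
Monte-Carlo error comfortably inside the tolerances they check: 2000-frame
trajectories (40–150 residues), 600-node networks over 20 seeds, 1000-draw
reference distributions, 2000-gene null cohorts, and 500 replicate power
cohorts. Every stochastic step takes an explicit seed; the pipeline records
the seed and input digests in its manifest, and rerunning with the same
inputs and seed reproduces outputs byte-for-byte.

## Known limitations

* The proximity screen treats the interactome as given; edge confidence
  scores, direction, and identifier mapping are out of scope.
* Energy components are consumed, not computed — there is no
  Poisson–Boltzmann or surface-area solver here.
* Trajectory I/O is text-only (multi-model PDB, plain coordinate tables);
  binary simulation formats are not read.
* The published affinity bands stop at −16.39 kcal/mol; labels beyond it
  are explicit extrapolations, flagged as such.
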