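# Methods

This note records the models implemented in `featnet`, the parameter choices
that matter, the numerical conventions, and what the synthetic data do and
do not establish.

## Feature extraction

**Natural vector.** Per amino acid *k*: count `n_k`, mean position
`μ_k = T_k/n_k` with `T_k = Σ_i s[k][i]`, and second normalized central
moment `D²_k = Σ_i (s[k][i] − μ_k)²/(n_k·n)` (`n` = sequence length). The
position convention `s` is ambiguous in the natural-vector literature
between "distance from the first residue" (first residue at 0) and the
position index (first residue at 1). We default to
`position_offset = 1` — the convention under which the moments of `AACAC`
are `μ_A = 7/3`, `D²_A = 14/45` — and expose `position_offset = 0`. Absent
amino acids contribute `(0, 0, 0)`, keeping the vector a fixed 60
dimensions. Sequences are restricted to the 20 canonical amino acids and at
least 20 residues; records violating either rule are dropped (never
translated), because the feature definitions exist only on the canonical
alphabet.

**Averaged property factors.** Sequence means of ten physical property
factors per residue. The ten factors are not reprinted in the source
analyses; we ship the standard published ten-factor table (Kidera et al.
1985, Table V, as used by Rackovsky) as a versioned TSV
(`data/kidera_factors.tsv`) and make the table swappable so users can pin
alternative values.

**PseAAC.** Classic type-1 form: `θ_j` is the mean over residue pairs `j`
apart of `Θ(a, b)` = mean of squared differences of three standardized
properties (hydrophobicity, hydrophilicity, side-chain mass; Chou 2001,
shipped raw in `data/pseaac_properties.tsv` and standardized to mean 0 /
sample SD 1 over the 20 amino acids at load time). Frequencies and weighted
tiers share the denominator `Σf + w·Σθ`, so every output is a probability
vector. Defaults: `w = 0.05`; the pipeline runs λ = 0 and λ = 10.
λ-selection by covariant discriminant analysis is out of scope; λ is a
plain parameter. For λ = 0 the implementation returns the frequency vector
directly (the denominator is exactly 1).

## Connectivity

All information quantities use natural logarithms (the nMIR normalization
cancels the base; TE is reported in nats).

**CR** is `|Pearson r|`. A constant feature series makes `r` undefined; its
off-diagonal entries are set to 0 with a warning rather than propagating
NaN.

**nMIR** uses a plug-in estimator on discretized series: `B = 10`
equal-frequency bins by default (`equal_width` available). Binning is by
quantile edges and value-based `searchsorted`, so tied values always share
a state and the estimate is *exactly* invariant under any permutation of
the rows. This invariance (shared by CR) is the mechanism behind the
10⁻¹⁵-order robustness entries for undirected networks: the only variation
across permutations is floating-point summation order. Off-diagonal entries
are `I(X_i;X_j)/H_max`, diagonal entries `H(X_i)/H_max`, with
`H_max = max_i H(X_i)`.

**Transfer entropy** is the conditional mutual information
`I(target_{n+1}; source embedding | target embedding)` with `l = k = 5`
(the embedding lengths are required equal), estimated by the KSG
nearest-neighbor method in its conditional (Frenzel–Pompe) form: `knn = 4`
neighbors, Chebyshev norm, `cKDTree` searches. Feature series are often
discrete-valued (counts, shared frequencies), which produces exact distance
ties; a jitter of 10⁻¹⁰ of each series' scale breaks them. The jitter is a
deterministic function of the series' values and the seed, so an exact copy
of a series receives the identical jitter — which makes TE of a series
against its own copy cancel to zero by construction, the correct behavior
for deterministic relations. Raw estimates may be negative.

**Bias correction.** For each ordered pair, `q = 10` surrogates of the
*target* are generated, the maximum surrogate TE is subtracted, and
negative results are clipped to 0. The default surrogate is a full random
permutation of the target (`shuffle`); a circular time-shift (`shift`, by a
random offset in `[T/4, 3T/4]`) is available. Shuffling the target rather
than the source is unusual among surrogate schemes but is implemented as
specified; users should be aware the two choices differ for autocorrelated
targets. With shuffled surrogates and serially independent series the raw
statistic and the q surrogate statistics are fully exchangeable, so a true
null pair survives correction with probability exactly `1/(q+1)` — about 9%
of null entries remain nonzero at q = 10 by construction. Time-shifted
surrogates at different offsets are mutually correlated, which weakens
their maximum and measurably raises that false-positive rate; this is why
`shuffle` is the default.

The matrix convention is `entry (i, j) = TE_corrected(j → i)` — columns are
sources — matching the directed-network convention below.

## Networks and centralities

Relation matrices become weighted adjacencies with the diagonal zeroed
(self-relations are not edges); zero entries mean no edge. CR/nMIR networks
are undirected: degree (strength) and eigenvector centrality (power
iteration from the uniform vector, convergence tolerance 10⁻¹⁴,
non-negative Perron orientation). Eigenvector centrality is restricted to
undirected networks. TE networks are directed, `a(i,j)` = weight of the
link `j → i`: in-strength (row sums), out-strength (column sums), Katz
`y = (I − αA)⁻¹·1`, PageRank `y = D(D − αA)⁻¹·1` with
`d_ii = max(1, out_i)`.

The Katz attenuation must satisfy `α < 1/k₁` (leading eigenvalue
magnitude) for the resolvent to exist; "slightly smaller than the leading
eigenvalue" cannot do that when `k₁ > 1`, so we parameterize
`α = attenuation/k₁` with attenuation 0.9 by default (`α = 0` for an empty
network, giving the all-ones vector). PageRank damping defaults to 0.85.
A singular attenuated system is retried once with α halved, then raised.
Every centrality vector is divided by its maximum (all-zero vectors remain
all-zero).

## Permutations, robustness, significance

The ensemble applies P = 100 seeded joint row permutations (permutation 1
is the identity; one master seed spawns per-permutation substreams so any
single permutation is reproducible alone). Because CR and nMIR are exactly
permutation-invariant, the pipeline computes them once and replicates their
centralities across the ensemble by default; `strict_paper = True` runs the
literal recomputation, and the test suite asserts the two agree to
floating-point noise. TE is genuinely order-dependent (the k-NN estimator
sees a different row arrangement) and is always recomputed.

The robustness statistic is the per-feature SD over permutations, averaged
over features, then over classes, tabulated per (connectivity measure,
centrality measure) × feature scheme. Undirected entries sit at
10⁻¹⁵–10⁻¹⁶; directed entries at 10⁻¹–10⁻².

Treating the P normalized centralities of each feature as samples, a Levene
check (mean-centered, standard upper-tail F) documents variance
heterogeneity — the reason a pooled-variance test is inappropriate. The
printed form of the Levene statistic in the source analysis carries an
extra `n_i` factor and a two-sided acceptance region; we implement the
standard statistic (via `scipy.stats.levene`) since its only role is to
justify Welch. Feature ordering uses pairwise one-sided Welch T-tests with
Welch–Satterthwaite degrees of freedom; `T ≥ t_θ(v)` declares *i* higher,
`T ≤ −t_θ(v)` lower. A pair with zero variance on both sides is decided by
exact mean comparison. A feature's score is the number of features
significantly lower; features are ranked by descending score, ties sharing
a score. **No multiple-testing correction is applied** across the
`K(K−1)/2` pairs; instead θ is swept over
{0.25, 0.1, 0.05, 0.025, 0.01, 0.005}, whose rejection regions are nested,
so decision counts are non-increasing as θ shrinks (checked by the sweep's
monotonicity report).

## Synthetic data

The sequence generator plants structure at the composition level: each
class draws residues i.i.d. from its own profile (by default
Dirichlet-perturbed around uniform with concentration 50 — mild,
realistic-scale between-class shifts), with lengths `20 + NB(mean, size)`
and an optional first-order repeat bias for arrangement structure. This
emulates what the cross-protein feature statistics need — classes that
differ in composition and arrangement — but not protein evolution,
homology, domain architecture, or real length/composition distributions;
green tests therefore establish correctness of the machinery, not
biological conclusions about real structural classes. The feature-series
generator provides ground truth for the connectivity measures: planted
correlation matrices (PSD-checked), a squared-latent nonlinear pair (low
CR, high nMIR — the measure-independence signature), and VAR(1) directed
coupling (spectral radius < 1 enforced; 100-sample burn-in).

The deposited PDB-ID lists are MAT containers; the loader handles cell
arrays and char matrices for the variables `PID_A/PID_B/PID_M` and
`PID_1..PID_4`. Sequence retrieval from PDB/CATH/SCOP is out of scope, so
tests exercise the loader with synthetic stand-in MAT files generated at
test time that carry the published per-class cardinalities
(1673/1772/4876; 960/1030/1490/1356).

## Problem sizes and numerical conventions

The shipped tests and the acceptance script run at desk scale, chosen to
make each check statistically meaningful: permutation invariance on 3
classes × 100 proteins × 100 permutations for all six schemes; TE
directionality at n = 1000 over 20 seeds; the TE null-suppression rate over
1680 ordered pairs (the exchangeability argument above makes the expected
zero rate exactly 10/11 ≈ 0.909, so a large pooled count is needed for the
observed fraction to concentrate); Welch calibration over 2000 null pairs.
Full-database runs (thousands of proteins, P = 100 with TE) use the same
code paths and scale linearly in P and quadratically in K.

Other conventions: sample SDs use `ddof = 1`; P = 1 ensembles report SD 0;
the PseAAC triplet is standardized with the sample SD; equal-frequency bin
edges come from `np.quantile`; the Welch critical value uses
`scipy.stats.t.ppf`.

## Known limitations

* The KSG estimator's raw values are biased for short series; only the
  surrogate-corrected values are meaningful, and ~1/(q+1) of true-null
  pairs survive correction by construction.
* The surrogate scheme randomizes the target, as specified; for strongly
  autocorrelated targets a source-randomizing scheme would be the more
  conventional null.
* nMIR depends on the bin count B; B = 10 equal-frequency bins is a
  reasonable default for N ≥ 100 samples but is not adaptive.
* Pairwise Welch decisions are uncorrected for multiplicity by design;
  scores should be read as a descriptive tournament summary, not
  family-wise-error-controlled inferences.
* Eigenvector centrality on disconnected networks reflects the dominant
  component only; nodes outside it get (near-)zero centrality.
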