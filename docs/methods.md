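# Methods

This note documents the models implemented in `psifold`, the choices
made where the underlying methodology left room, and what the synthetic
data do and do not establish.

## Reactivity processing

Chemical probing read out by mutational profiling yields per-nucleotide
mutation rates for a reagent-treated sample and an untreated control.
The raw reactivity is the rate difference `R_i = mutr_S − mutr_U`, with
standard error propagated from the two binomial rate variances.
Negative values (control noise exceeding signal) are retained through
normalization — they only affect the rank ordering used to find the
normalization factor — and floored at zero only when reactivities enter
likelihood evaluations.

Normalization is per nucleotide type: within each base's non-sentinel
values, the most reactive 2% are removed (count rounded half up) and the
mean of the following top decile (also rounded half up, at least one
value) is the division factor. This fixes the top-decile mean at 1, an
identity the tests assert, and makes the operation idempotent. Bases
with fewer than 10 informative values are emitted as no-data (−999)
with a warning. A visualization mode additionally rescales G/U profiles
to a 0.1 maximum, since the probing reagent methylates A/C and the G/U
signal is background.

For folding, G/U positions are masked to −999, values are capped at 5
(higher values are set to 5; the empirical reactivity distributions are
long-tailed and the cap keeps single outliers from dominating the
pseudo-energy), and negatives are floored at 0.

### Context likelihoods

Against a reference structure, each A/C nucleotide is classified as
unpaired, paired at a helix end (a paired position whose helix neighbor
`i±1` is unpaired or out of range on either strand side), or stacked
between two pairs. Per-class reactivity densities are kernel density
estimates with reflection at 0, truncated and renormalized on [0, 5],
bandwidth by Silverman's rule — a KDE avoids histogram binning choices.
A class with fewer than 20 observations triggers a fall-back to a merged
paired class (flagged on the result); calibration is refused outright if
even the merged class is too small, which is why calibration fixtures
need many helices (a single hairpin has only four helix-end positions).
For simulation, parametric gamma densities with fixed shape 2 and
per-context means are used instead (below).

## The folding engine

A single-strand, pseudoknot-free nearest-neighbor model:

* 6×6 stacking table over the canonical pairs (CG, GC, AU, UA, GU, UG).
  The default table sets `stack(p, q) = −(s_p + s_q)` with pair
  strengths 1.6 / 0.9 / 0.45 kcal/mol for CG/AU/GU-type pairs, which
  reproduces the ordering of measured tables (CG-on-CG −3.2 … GU-on-GU
  −0.9). The full parameter set round-trips through a TSV file, so
  measured nearest-neighbor values can be dropped in without touching
  the engine.
* hairpin loops: `5.4 + 1.75·RT·ln(L/3)` kcal/mol for loop length
  L ≥ 3 (minimum hairpin 3, no lonely-pair prohibition);
* internal/bulge loops: `1.7 + 1.75·RT·ln(L)` for total unpaired L ≥ 1,
  capped at 30 unpaired nucleotides inside the dynamic programs (the
  fixed-structure evaluator scores any size);
* multibranch loops: affine `3.4 + 0.4·(branches, closing pair
  included) + 0.1·unpaired`;
* a +0.5 kcal/mol terminal penalty for each AU/GU pair that delimits a
  loop (hairpin closing, both internal-loop pairs, multiloop closing
  and branch pairs, exterior branches). Stacked continuations carry no
  terminal penalty;
* temperature 310.15 K, RT = 0.0019872 × T kcal/mol.

Probing restraints enter as per-nucleotide pseudo-energies: a paired
nucleotide with reactivity r pays `−RT·ln[P(r|paired)/P(r|unpaired)]`,
exactly 0 for no-data positions. The partition-function recursions use
the two-state form, with P(r|paired) the count-weighted mixture of the
helix-end and stacked densities; a three-context mode rescoring fixed
structures with the context-specific density is available. With gamma
likelihoods the log-ratio is linear in r, so raising one nucleotide's
reactivity strictly lowers its equilibrium paired probability (asserted
as a property test).

Inside/outside recursions are McCaskill-style O(n³) dynamic programs in
log-space (no rescaling needed at any length), jit-compiled with numba;
stochastic traceback uses a self-contained xorshift64* generator so
sampling is bit-reproducible for a fixed seed across platforms. The MFE
recursion optimizes `(energy, pair count)` lexicographically, so ties
break toward fewer pairs; remaining co-optima are resolved by a fixed
traceback order (hairpin, stack, internal by ascending (k,l),
multibranch by ascending split). Every structure's Boltzmann weight is
counted exactly once: on all sequences up to 14 nt, log Z, every pair
probability and the MFE energy agree with exhaustive enumeration to
1e−9 relative (200 random sequences in the acceptance suite), and
empirical sampling frequencies match enumeration probabilities to four
binomial standard errors. The enumeration oracle itself is cross-checked
against a structurally different counting recursion.

## Unfolding energetics

The unfolding cost of a region is `ΔG‡ = ΔG(region forced single-
stranded) − ΔG(folded)`: every pair with at least one endpoint in the
region is removed from the fixed structure (the CT-file operation of
zeroing the partner column) and both forms are scored with the same
model. The convention is chosen so the cost of disrupting structure is
non-negative in practice; pseudo-energies are included in both
evaluations and therefore cancel for positions whose pairing the
unfolding does not change. Over 10⁴ sampled structures of the planted-
hairpin fixture the minimum cost is ≈ +20 kcal/mol — far from the sign
boundary — because the junction hairpin is both thermodynamically and
probing-supported.

Ensemble statistics are population moments (SD with 1/N, skew and
excess kurtosis defined as 0 for zero-variance ensembles) over the
per-member ΔG‡ values, plus the ΔG‡ of the single MFE structure fitted
from the same restraints.

Spliceosome footprints — the stretch of pre-mRNA enclosed around the
donor site in cryo-EM structures of assembly intermediates — are built
in as (exonic, intronic) extents: Pre-B (2, 8), B (10, 17), Pre-B^act
(9, 20), B^act (12, 31); the donor site itself is (3, 6), the 9-mer
read by U1 snRNA. A footprint resolves to the 1-based interval
`[offset − exonic + 1, offset + intronic]`. The counting routine
re-derives extents from PDB/mmCIF files: any residue with at least one
atom record on the pre-mRNA chain counts, residues missing from the
model do not, and an atom-free file counts as (0, 0).

The exon-independence scan refolds successively longer 3' extensions of
an exon (restraining each prefix to the profile positions available)
and reports the fraction of base pairs fully inside the exon; a fold
with no pairs reports 1.0 by convention with `n_pairs == 0` as the
flag.

## Motif strength

PWMs are log2(frequency/0.25) matrices built from k-mer sets with a
pseudocount of 0.5 per base per position (avoids −∞ weights; a position
frequency of 0.5 maps to weight 1). Each PWM's detection threshold is
the 95th percentile (linear interpolation) of its scores over all 4^w
k-mers, enumerated exhaustively (w ≤ 10).

A mutation's Δstrength for one PWM sums `score(mutant window) −
score(WT window)` over the windows that cover a mutated position and
whose **better allele** clears the threshold — gating on
max(WT, mutant) captures both motif gain and motif loss. Windows
truncated by the sequence end are skipped; ESE/ESS PWMs scan only
windows fully inside the exon, ISE/ISS only fully inside the intron
(junction-straddling windows are skipped — enhancer/silencer
compartment definitions are exon- or intron-specific); RBP PWMs scan
everywhere. Category aggregates are means of the non-zero per-PWM
Δstrengths (0 when none), enhancer = ΔESE + ΔISE, silencer = ΔESS +
ΔISS, and RBP inclusion/exclusion aggregates are computed the same way
over the correspondingly labeled PWMs.

The donor site is scored by a pluggable 9-mer scorer. The default is a
first-order log-odds matrix over consensus base frequencies of
annotated human donor sites (near-invariant GU at +1/+2); a loader
accepts an external exhaustive 9-mer score table (e.g. from a
maximum-entropy model) for users who have one. ΔSS is non-zero only
when a mutated position falls inside the 9-mer.

## The PSI models

Seven formulas (see the README) are fit by maximum likelihood under
Beta(μφ, (1−μ)φ) with logit link and constant precision, through
`statsmodels`' Beta likelihood behind a scikit-learn estimator surface.
The interactive model multiplies the structure block by
(isSynonymous + isIntronic) and the motif block by isNonSynonymous, as
products only (no ungated main effects); compensatory double mutations
derive their flags from their component substitutions (non-synonymous
dominates; otherwise the structure gate applies). WT-like variants
(verified to preserve the wild-type isoform balance) carry PSI 0.5 and
no flags.

Numerical choices: responses of exactly 0 or 1 are moved to the
Smithson–Verkuilen boundary images 0.5/n and (n−0.5)/n; interior
responses are untouched, keeping the likelihood exact (an
all-observation squeeze measurably attenuates slopes when many
responses sit near the boundary). Identically-zero predictors (e.g. the
donor-site term on a panel with no donor-site mutation) are dropped with
a warning and reported with coefficient 0. The optimizer is statsmodels'
quasi-Newton fit with up to four Nelder-Mead restarts; for exactly
deterministic responses the likelihood is unbounded in φ, and the fit is
accepted with a warning once the mean coefficients have stabilized
across restarts. Predictions are the inverse-logit of the linear
predictor and always lie strictly inside (0, 1).

The bootstrap draws ⌈0.7·n⌉ rows without replacement, refits, and
computes squared Pearson correlations overall and per category, 10
replicates by default. Following the estimation procedure being
mirrored, R² is computed on the training subsample; a held-out mode
(evaluate on the 30% complement) is provided because in-sample R² of a
many-parameter model on a 47-row panel is substantially inflated (a
permutation-null panel shows median training R² ≈ p/n even with no
signal).

## Ensemble digitization and feature maps

Structures flatten to element strings — stem `s`, hairpin loop `h`, 5'
exterior `f`, 3' exterior `t`, and every other loop context (internal,
bulge, multibranch, exterior segments between helices) mapped to `m` —
digitized as f,t→0, s→1, h→2, m→3. For the open chain, positions before
the midpoint are `f` and after it `t`; both digitize to 0 so the split
cannot affect downstream numbers. Pooled digitized ensembles are
embedded with t-SNE (perplexity 30, reduced for tiny inputs; PCA
initialization; fixed seed) and clustered with k-means (k = 5 by
default, k-means++ with 10 restarts, fixed seed); per-variant cluster
occupancies always sum to 1. If every structure is identical the
embedding degenerates to co-located points at the origin rather than
calling t-SNE (whose gradient is undefined there). A cluster's
representative structure is the member with the smallest Hamming
distance to the per-position plurality consensus (consensus ties to the
lower digit, distance ties to the earliest member), and is always a
member of the input.

The feature heatmap treats all features as changes versus wild type:
motif deltas already are, and the ensemble mean ΔG‡ is centred by the
wild-type ensemble mean. Non-zero values are clipped at their 5th/95th
percentiles, scaled by the maximum absolute value, silencer and mean
ΔG‡ are inverted (so 1 always reads "promotes inclusion"), and mapped
onto [0, 1] around 0.5; all-zero features stay at 0.5. Rows are ordered
by average-linkage Euclidean hierarchical clustering, first on
changed/unchanged flags (six clusters), then within clusters on the
normalized values. A mutation's support category compares the side of
0.5 taken by each feature with the side taken by its PSI, using strict
inequality (exactly-0.5 never supports): structure and at least one
motif feature agreeing gives `both`, otherwise `SRE`, `structure` or
`neither`.

## The synthetic data

The generators define the study conditions the tests run under:

* **Junction fixture** — 234 nt with the boundary after nucleotide 93
  (the length of the study's junction amplicon), one planted GC-biased
  hairpin whose 5' arm ends on the last exonic nucleotide (10 pairs by
  default, 4-nt A-rich loop opening the intron). The rest of the
  sequence is uniform random, so incidental structure exists, as in
  real RNA.
* **Reactivities** — gamma draws with shape 2 and per-context means
  0.8 (unpaired), 0.2 (helix end), 0.05 (stacked). The means are
  stand-ins reproducing the qualitative ordering of calibrated probing
  histograms, not estimates of them; they give a reactivity-as-
  classifier AUC ≈ 0.93–0.99 against the planted structure.
* **Rate tables** — treated rate = background + reactivity (identity
  scale, clipped at 0.99), untreated = background (0.005), binomial
  noise at the given depth; depth 0 returns analytic rates so the
  raw-reactivity reduction recovers the input exactly.
* **Mutation panels** — categories drawn to the requested mix
  (defaults 0.3/0.3/0.3 synonymous/intronic/non-synonymous plus 0.1
  compensatory, emulating a curated 47-variant panel), positions and
  alleles rejected-sampled until the category is satisfied; features
  come from the real pipeline (ensemble of N samples per mutant, WT
  profile with mutated sites masked to −999). PSI is drawn
  Beta(μφ, (1−μ)φ) with φ = 50 around the inverse-logit of the
  interactive linear predictor.
* **Generating truth** — the interactive formula shares one intercept
  between an absolute-scale structure block (mean ΔG‡ ≈ 30 kcal/mol)
  and a delta-scale motif block, so a coherent truth must keep the
  structure block centred near zero on the rows it gates. Slopes for
  SD/skew/kurtosis are fixed standardized effects (0.8 / 0.5 / 0.35
  per unit of variation across the gated rows), the mean-ΔG‡ slope is
  solved from the constraint that the block's gated-row average
  vanishes, the intercept is 0, and motif slopes are +0.6 / −0.6 /
  +0.5 (enhancer / silencer / donor site). This keeps the linear
  predictor within a physiological range for every seed while anchoring
  a typical variant near PSI 0.5.
* **Coordinates** — single-chain PDB fixtures with one phosphorus atom
  per residue and the junction residue number declared, sufficient for
  the footprint counter.

Every generator takes an explicit seed and owns its RNG stream; nothing
uses global random state.

What passing tests show — and don't. Parameter recovery on these panels
demonstrates that the estimation machinery is unbiased and its standard
errors are calibrated *under the generating model*; the check allows the
binomially expected number of 3-SE outliers over 160 estimates (a hard
bound on all of them would fail ≈ 35% of the time for a perfect
implementation) and requires ≥ 85% empirical coverage of nominal 95%
intervals. The synthetic data do not emulate replicate correlation
between experiments, probing biases beyond the three-context model,
protein occupancy, or any coupling between motif content and structure
beyond what the planted sequence induces — so recovery here does not
certify predictive accuracy on real junctions, only correctness of the
computation.

## Problem sizes

Defaults used by the test and acceptance runs: ensembles of 200 samples
per variant for pipeline studies (1000 is the analysis default),
recovery panels of n = 200 mutations at φ = 50, oracle sweeps of 200
random sequences up to 14 nt, and a 10⁴-member ensemble for the
unfolding-cost sweep. The acceptance script runs its pipeline stage
with a 120-mutation panel at 150 samples per variant.

## Known limitations

* The energy model is a compact surrogate: no dangles, coaxial
  stacking, special hairpin tables or Turner-parameter fidelity.
  Absolute energies are not comparable to measured tables; the
  analyses rest on ensemble differences.
* The two-state pseudo-energy is the standard likelihood-ratio
  formulation; full three-state restrained recursions inside the
  partition function are not implemented (three-state scoring of fixed
  structures is).
* Only the 5' (donor) side is modeled; 3' splice-site structure and
  branch-point accessibility are out of scope.
* MFE tie-breaking is deterministic but the final lexicographic-pair
  ordering among exactly co-optimal, equal-pair-count structures is the
  traceback's fixed decomposition order, not a global sort.
* The exhaustive PWM threshold limits motif width to 10.
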