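# Methods

## The generative model

A labeled peptide is summarized by its *dye sequence*: one character per
residue giving the fluorophore color attached to it ('.' = unlabeled),
with trailing unlabeled residues trimmed because nothing the instrument
measures depends on them. Sequencing is modeled per molecule and per
cycle:

1. Before imaging begins, each dye is independently missing (a *dud*)
   with probability `m_c` for its color `c`.
2. At each timestep the surviving dye counts are logged, then three
   events occur in order: the peptide detaches with probability `d`
   (absorbing — all later counts are zero), Edman degradation removes the
   N-terminal residue (and any dye on it) with probability `1 - e`, and
   each surviving dye is destroyed with probability `p_c`.
3. A logged count `l` in channel `c` is observed as a Gaussian intensity
   with mean `l * mu_c` and variance `sigma_bg_c^2 + l * sigma_c^2`
   (independent noise per fluorophore plus background).

Defaults (`p=0.05, m=0.07, e=0.06, d=0.05, mu=1.0, sigma=0.16,
sigma_bg=0.00667`) follow published estimates for Atto647N; every rate
may be set per color. The number of imaging timesteps defaults to `T=10`
and is configurable. Event order within a cycle matters only for
detachment bookkeeping: Edman and dye loss commute in distribution, but
one fixed order keeps simulations bit-reproducible.

## Reduced HMM state space

The physical state of a molecule — which specific residues still carry a
dye — grows exponentially with the label count. Because duds and
bleaching act i.i.d. across positions, the surviving dyes of a color are
exchangeable over the remaining labeled positions of that color, so the
observation process depends only on (number of successful Edman removals
`e*`, surviving count per color `l_c`), plus one absorbing DETACHED
state. The Edman transition uses this exchangeability: if the residue
removed at level `e*` is labeled with color `c` and `n_c(e*)` labeled
positions of that color remain, the removed residue carries a surviving
dye with probability `l_c / n_c(e*)`. This reduction is exact; the test
suite enforces equality with a brute-force per-position model to 1e-9
relative over random small dye sequences, rather than assuming it.

`e*` is capped at `min(len(code), T-1)`: there are only `T-1` cycles
between observations, and counts cannot change once the trimmed code is
exhausted. The cap level is absorbing for the Edman factor; it is only
reachable at the final observation, so no observable probability mass is
distorted. The DETACHED state is kept distinct from all-dark attached
states even though their emissions coincide; likelihoods are unaffected,
only the state count differs from the merged convention.

## Factored transitions, forward pass, and pruning

The one-cycle transition matrix factors into column-stochastic sparse
operators, one per independent effect: detachment, Edman advance, and one
binomial dye-loss operator per color, composed in the simulator's event
order. `fluoroseq.states` builds these factors explicitly (and a
directly-enumerated dense matrix used as their cross-check); the
production forward pass in `fluoroseq.hmm` applies the same algebra in a
block form — one count tensor per Edman level, each factor a small dense
operator along one axis — vectorized over a batch of reads. The two
implementations are tested to agree to machine precision.

Timestep convention: `T` observations indexed `0..T-1` with `T-1`
transitions between them; the initial vector (independent
`Binomial(n_c(0), 1-m_c)` counts per color) is weighted by the `t=0`
emission. The forward vector is renormalized each step with the log scale
accumulated, so likelihoods are computed in log space without underflow;
a read whose mass reaches exactly zero (possible only in degenerate
parameter corners) reports `-inf`.

Pruning: at each timestep, each color keeps the contiguous range of
counts `l` with `|y_c - l*mu_c| <= cutoff * sqrt(sigma_bg_c^2 +
l*sigma_c^2)`; emission weights outside the range are zeroed, which is
equivalent to propagating contiguous active index blocks through the
factors (states outside the reachable set already hold zero mass). If no
count passes the test the nearest count is kept, so pruning alone never
produces a zero likelihood. The default cutoff of 5 changes per-read
log-likelihoods by less than 0.01 for >= 99% of default-parameter reads
and leaves PR curves visually unchanged; `cutoff=None` disables pruning.

No conditioning on read observability is applied: simulated test sets
discard molecules that are dark at every timestep (they would never be
detected), but the likelihood is not renormalized for that truncation.
The effect on posteriors is a shared constant per model at the default
rates and is ignored.

## kNN and hybrid classification

kNN trains on *dye tracks* (integer counts, scaled by `mu_c` to share the
intensity space of raw reads), not raw reads: tracks deduplicate heavily,
and each unique track entry stores its multiplicity and per-dye-seq
production counts. The KD-tree (`scipy.spatial.cKDTree`,
`balanced_tree=True`: median splits on the widest dimension) is exact,
immutable after build, and is tested against a linear scan. Votes are
Gaussian-kernel weighted, `exp(-delta^2 / 2 sigma_kNN^2)`, each entry
splitting its weight across producing dye seqs in proportion to
production counts; the winner's score is its weight over the total.
`k` counts unique merged entries, not pre-merge simulated reads. The
batched vote path shifts the kernel by the nearest neighbor's squared
distance per read before exponentiating — a positive per-read rescaling
that leaves scores, rankings and shortlists unchanged while avoiding
underflow.

The hybrid classifier shortlists up to `h` dye seqs per read by vote
weight (ties to the lower id), runs the forward algorithm only for the
shortlist, and normalizes the posterior over the shortlist (truncated
Bayes, uniform prior over the shortlist; kNN vote weights are *not*
reused as priors). Truncation can only shrink the denominator, so hybrid
scores weakly dominate the full-Bayes score of the same candidate. With
`k` >= index size and `h` >= reference size (and a kernel wide enough
that every entry votes) the hybrid equals the full Bayesian classifier
bit for bit; the default `k=10000, sigma=0.5, h=1000, cutoff=5` agrees
with it on >= 95% of reads on the benchmarks here.

## Evaluation and inference

PR sweeps process descending score thresholds with ties handled as a
block; recall at read level uses all retained reads as denominator. The
*predicted* PR curve replaces 0/1 correctness with each read's own score,
so it needs no truth labels; calibration tables sort by score into
equal-count buckets (remainder spread one-per-bucket over the leading
buckets). Peptide scores are the max over reads of score/n where the
read's winning dye seq maps to n peptides; protein scores are the max
over peptides of score/n over n parent proteins. At the peptide and
protein level, an entity counts as truly present when any dye seq
sampled into the test set lists it as a source, and recall is measured
against the number of present entities.

Parameter recovery uses designed simulations that isolate one parameter
each by zeroing the other error processes: dud rate from the dark
fraction at `t=0`; Edman failure from first-cycle dye survival with
`p=d=m=0`; detachment by censored geometric maximum likelihood with
Edman disabled (`e=1`); bleach rate from one-step survival; `mu` and
`sigma` by moment matching of `t=0` intensities with `m=0` (delta-method
standard errors).

## Synthetic data and benchmark sizes

Test proteomes are random i.i.d. sequences at Swiss-Prot average
amino-acid composition, with lengths Poisson-distributed around 300
residues. They reproduce realistic tryptic peptide lengths and label
counts but none of the homology, repeats, or shared peptides between
related real proteins — so benchmark accuracies here say that the
classifiers work as specified under the error model, not what accuracy
to expect on any particular organism, where peptide sharing and database
size drive the numbers.

The packaged benchmarks use a 20-protein reference (training: 1000 tracks
per dye seq; test: 10,000 reads) for pruning, hybrid-fidelity and
calibration checks, and a 100-protein reference with 3,000 reads for the
read/peptide/protein-level comparison; these sizes were chosen to make
the suite quick on a single CPU while keeping every check
well-powered. Parameter-recovery runs use 100,000 molecules, putting
3-standard-error bands at about +/-0.003 absolute on the rates.

## Known limitations

* Dye-dye interactions (FRET, quenching) are not modeled; fluorophores
  are assumed independent.
* No missed or nonspecific cleavages, no proline blocking for trypsin;
  digestion is purely by residue identity.
* Error rates are treated as known; there is no fitting of rates from
  unlabeled reads (the designed-simulation estimators require control
  over the conditions).
* No decoy-database FDR machinery; scores are posteriors, and the
  predicted-PR route is the supported truth-free summary.
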