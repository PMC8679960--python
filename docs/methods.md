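# Methods

## Model

An admixed genome is modeled as a hidden Markov chain over windows of L
consecutive biallelic SNPs. The hidden state of window *t* is the ancestral
population (1..K) that contributed that stretch of the genome; the
observation is the vector of the individual's genotypes in the window.

**Genotype likelihood.** The per-site likelihood given ancestry *k* uses the
panel allele frequency f_ik. Diploid dosages g ∈ {0,1,2} follow the
Hardy–Weinberg binomial P(g|f) = C(2,g) f^g (1−f)^(2−g); haploid alleles are
Bernoulli. The haploid model is the 1-trial special case of the diploid one,
which keeps the two modes consistent. Missing genotypes contribute log
probability 0, i.e. they are skipped; a fully missing window has a flat
likelihood and is labeled purely by its neighbors through the transitions.

**Window emission.** Sites within a window are treated as independent given
the ancestry, so window log-likelihoods are sums of per-site terms. The
emission used by the decoder is, by default, the Bayesian *posterior* over
populations with the individual's global admixture vector as prior. This
means an informative prior is applied once per window; across T windows the
prior's influence accumulates T-fold, which is a strong cumulative effect. We
keep it as the default because it defines the method being implemented, and
expose `likelihood_emission=True` (CLI `--likelihood-emission`) for the
textbook alternative in which the prior enters only through the initial
distribution. The measured consequence of the default on simulated mosaics is
small (an accuracy change of under half a percent, sometimes negative for
skewed priors); the acceptance script reports it as
`informative_prior_accuracy_delta_pct`.

**Transitions.** Off-diagonal transition probability a_ij = 1/(K+x) with
penalty x ≥ 0; the diagonal absorbs the rest so rows sum to 1 exactly. x = 0
gives uniform transitions (the decoder then labels each window
independently); the default x = 10,000 makes one ancestry switch cost
log(K+x) ≈ 9.2 nats, which suppresses single-window noise while leaving true
segment boundaries (hundreds of nats of emission support) intact. A
distance-based alternative sets a_ij ∝ 1/D_ij for a supplied K×K
between-population distance matrix; the self-transition mass is a free
parameter not determined by the distances, and defaults to
1 − (K−1)/(K+x) so that equal distances reproduce the penalty model exactly.

**Decoding.** Standard Viterbi in log-space: δ_j(1) = log π_j + e_1j,
δ_j(t+1) = max_i [δ_i(t) + log a_ij] + e_{t+1,j}, with back-pointers and ties
broken toward the lowest population index (fixed for determinism). π is the
(floored, renormalized) prior, uniform when no Q-vector is given. Each
chromosome is decoded independently, restarting from π, so no transition
spans a chromosome boundary.

As the penalty grows the decoded path eventually freezes at the single state
maximizing log π_j + Σ_t e_tj, but only once log(K+x) exceeds the *total*
emission preference for switching. For realistic emissions (segments of tens
of windows, ~5–10 nats per window) that threshold lies at x ≈ e^(hundreds to
thousands), beyond double-precision range — in practice large penalties
converge to the true segment structure, not to a constant path, which is the
desired behavior.

## Numerical choices

- Allele frequencies are smoothed with a Jeffreys-style pseudocount
  (α = 0.5 per allele class): freq = (count + α)/(n_hap + 2α), keeping every
  frequency strictly inside (0,1) so log-likelihoods stay finite.
- All window-level arithmetic is in log-space; posteriors are normalized
  with `logsumexp`. Rows normalize to 1 within 1e-9 even for 5,000-SNP
  windows whose linear-space likelihoods underflow to ~e^-5000.
- Prior entries of exactly 0 (common in supervised admixture output) are
  floored at 1e-9 and the prior renormalized, so no state is forbidden
  outright; `hard_prior=True` keeps the zeros and can make decoding fail
  with "no admissible path", which is reported rather than papered over.
- Multi-allelic records and indels are excluded at load time; the model is
  defined on biallelic SNP dosages. Duplicate (chrom, pos) records keep the
  first occurrence; sites whose REF/ALT disagree across inputs are dropped.
- LD pruning scans left to right: a site is dropped iff an earlier *kept*
  site within 50 consecutive SNPs (same chromosome) has squared dosage
  correlation above 0.8. Dropped sites never participate in later
  comparisons; constant sites are treated as r² = 0 and kept; missing
  genotypes are dropped pairwise. This greedy rule is idempotent.
- Segment coordinates are 0-based half-open: a window starts at (position of
  its first SNP − 1) and ends at the position of its last SNP, matching BED.

## Modes

Diploid mode consumes unphased dosages directly. Haploid mode splits each
phased genotype column-wise into two pseudo-homozygous "parents" (left
allele → haplotype A, right → haplotype B); an unphased heterozygote is a
fatal error naming the position. The informative prior for both parents is
the diploid individual's Q-vector. On a fully homozygous individual the two
parents are identical to each other and decode exactly like the diploid
sample (verified to exact path equality in the tests); when heterozygous
ancestry is present the modes legitimately differ, and only weak agreement
(averaged parental aggregate within 0.1 of the diploid aggregate) is
expected or checked.

## Simulator

`simulate_panel` draws an ancestral frequency p ~ Uniform(0.05, 0.95) per
site and population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) — the
Balding–Nichols model, whose differentiation parameter F is recovered by a
Hudson-type FST estimator on the simulated haplotypes (checked within 0.05).
Reference haplotypes are Bernoulli draws from the population frequencies;
the panel's frequency matrix is then *estimated* from those haplotypes with
the same smoothing applied to real data, so panel noise is included.
`simulate_admixed` makes each haplotype's ancestry a Markov mosaic: initial
state from the admixture proportions q_true, per-SNP switch probability
`switch_rate`, destination drawn from q_true (hence q_true is the stationary
distribution). Alleles are independent Bernoulli draws given local ancestry.

Default conditions: K = 3, 20,000 sites at 1 kb spacing on one synthetic
chromosome, FST = 0.2 (continental-scale differentiation), 40 reference
haplotypes per population, q_true = (0.5, 0.3, 0.2), switch_rate = 5e-4
(mean tract 2,000 SNPs ≈ 40 windows). These sizes keep the full validation
suite at a few seconds per replicate while leaving dozens of windows per
ancestry tract.

What the simulator deliberately omits: linkage disequilibrium within
populations (the method itself assumes within-window independence, so
LD-free data is the matched null; a copy-with-error mode is not included),
recombination-map structure, phasing errors, genotyping error, and reference
panel mis-specification. Passing tests therefore demonstrate correctness of
the algorithm under its own assumptions — they do not bound accuracy on real
data, where marker correlation and imperfect references will lower it.

A note on aggregates: a single simulated individual carries only ~10 ancestry
tracts per haplotype at switch_rate = 5e-4, so its *realized* genome-wide
composition scatters around q_true with deviations of ~0.1–0.3. Aggregate
recovery is therefore judged against the individual's realized truth-track
fractions (the simulation analogue of its own global admixture vector), not
against the process parameter q_true, which no decoder — however exact —
could match from one genome.

## Enrichment scores

For SNP counts nA_i, nB_i of pathway *i* in population groups A and B,
p = nA/(nA+nB) is the genome-wide group-A fraction and
p_i = nA_i/(nA_i+nB_i) the pathway's fraction. The score is

    z_i = ((p − p_i) ± 1/(2 n_i)) / sqrt(p(1−p)/n_i),   n_i = nA_i + nB_i,

with the continuity correction taken toward zero (|p − p_i| is shrunk by
1/(2 n_i), and z_i = 0 when the deviation is within the correction). The
per-pathway denominator is n_i = nA_i + nB_i throughout — the only reading
consistent with the definition of p_i. Two-sided normal p-values are
corrected by Bonferroni and Benjamini–Hochberg over the pathways of each SNP
class separately (synonymous and nonsynonymous are separate families). A
pathway is declared differentially enriched iff its BH-adjusted
nonsynonymous p-value is below α (default 0.005) *and* its raw
nonsynonymous p-value is below its raw synonymous p-value — the paired rule
that discounts pathways whose apparent signal merely reflects overall SNP
accumulation. Null simulation at n_i = 400 gives a raw p < 0.05 rate of
~0.042: the continuity correction makes the test slightly conservative at
moderate counts, which is the intended direction.

## Known limitations

- Viterbi returns one best path; no per-window posterior confidence from
  forward–backward smoothing is computed.
- Windows are SNP-count based; with very uneven marker spacing a window can
  span a long physical distance, and the constant per-window switch
  probability then mis-scales relative to genetic distance.
- Sub-window ancestry tracts (< L SNPs) cannot be represented and are
  absorbed into neighboring segments.
- Lexicographic chromosome ordering is used when sorting sites; input order
  within a chromosome must be positional.
- The enrichment module consumes precomputed count tables; variant
  annotation and pathway membership assignment are upstream of this package.
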