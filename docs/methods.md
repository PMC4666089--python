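# Methods

## Population model

The simulator tracks individual animals with true breeding values (TBV) for
a single aggregate merit trait (dollars of lifetime net merit), per-locus
genotypes at a configurable panel of independent biallelic recessive loci,
pedigree links, herd membership, and life status. Selection accuracy is
perfect by construction — schemes act on TBV, not estimates — so simulated
genetic gains overstate practice but compare schemes on equal footing.

The base population is founders: 35,000 cows with TBV ~ N($0, $200²) spread
round-robin over 200 herds, and 350 bulls with TBV ~ N($300, $200²) and no
herd (sire portfolios are formed per herd at mating time). Genotypes are
drawn allele-wise at each locus's initial minor-allele frequency, giving
Hardy–Weinberg proportions. Birth years are uniform on [−4, 0] (cows) and
[−9, 0] (bulls), so the first simulated year already has a full age
structure. Founders are unrelated and non-inbred; a founder that happens to
draw a lethal homozygous genotype is kept alive (lethality is applied to
calves at birth; at realistic frequencies the expected number of such
founders is ≪ 1).

Each simulated year: mates are allocated; every mated cow bears one calf
(sex Bernoulli(½), dam's herd, one uniformly sampled allele per parent per
locus); TBV_calf = parent average + a Mendelian-sampling deviate with
variance ½[1 − ½(f_S + f_D)]σ_a², σ_a² = $40,000; calves homozygous for any
lethal allele are recorded and marked dead at birth (they stay in the
pedigree but never enter frequency counts or matings). Culling then runs in
a fixed order — bulls for age, then lowest-TBV-first to the 500-bull cap;
cows for age, then involuntary (rate 0 by default), then uniformly at
random to the 100,000-cow cap. An animal is age-culled at the end of the
year in which it reaches the maximum age (10 for bulls, 5 for cows), so no
animal breeds beyond the maximum; carrier status never affects culling.
Cows breed from age 2, bulls from age 1 (both configurable); generations
overlap. There is no mutation, migration, or herd movement.

## Mate-allocation schemes

* **random**: each eligible cow draws a uniform bull among those under the
  5,000-matings-per-year cap.
* **truncation**: the top `max(1, floor(0.10 × live bulls))` bulls by TBV
  serve the whole cow population at random, uncapped.
* **pryce**: per herd, 20 % of live bulls are sampled without replacement
  and the best 50 of the sample by TBV become the herd's sire portfolio
  (each herd sees a slightly different portfolio). The pairing score is
  B_ij = ½(TBV_i + TBV_j) − λ·F_ij with λ = $25 per **percent** of calf
  inbreeding — F enters as 100·f(sire, dam). With fractional F the $25
  penalty would be economically negligible (~$1.6 at F = 0.0625), which
  would defeat the method's purpose. Cows are processed in ascending-id
  order and each receives the under-cap bull with the highest B in her
  column (ties to the lowest bull id); the 5,000-mating cap is tracked
  globally across herds within the year. The rule is deliberately greedy
  and order-dependent — that is the published method, not an optimizing
  assignment — and the processing order is fixed for reproducibility.
* **modified_pryce**: as pryce on B′_ij = B_ij − Σ_r P(aa)_r·v_r, with
  P(aa)_r = (g_sire/2)(g_dam/2) per locus. Negative v_r (desirable
  recessives, e.g. red coat color at −$20) raises B′.

## Kinship

F_ij is the pedigree coancestry of bull i and cow j, evaluated to founders
with the standard recursion (f(x,x) = ½(1+F_x); recurse through the younger
animal's parents). Two exact implementations exist: a memoized recursive
evaluator over an arbitrary sire–dam graph (`KinshipCache`, the reference
path, validated against Henderson's tabular method to 1e-12 on random
pedigrees), and an incremental dense matrix over live animals
(`LiveKinship`) that appends one row per calf using the same recurrence and
is what the simulator uses — per year the portfolio schemes evaluate ~10⁵
candidate pairs, which per-pair recursion over a 20-generation pedigree
cannot sustain. The matrix is float32 (kinship values are dyadic rationals;
24 mantissa bits are exact for any realistic depth) and is compacted to
live animals each year. Memory is the binding constraint at full scale:
~170k concurrently live animals would need tens of gigabytes, so full-scale
runs require a large-memory machine; all shipped analyses use desk scale.

## Expected trajectories and comparisons

For lethal loci the expectation iterates, exactly as printed in its source,

    p_t = (p² + pq)/(2p² + pq),   q_t = pq/(2p² + pq).

Two documented quirks are preserved deliberately: p_t + q_t ≠ 1 away from
q = ½, and rare alleles drop almost twofold in the first step (denominator
≈ 2), both unlike the textbook post-selection recursion q′ = q/(1+q). The
textbook form is provided separately (`expected_frequency_lethal_textbook`)
and is never silently substituted; the two agree only at q = ½. Neutral
loci follow Hardy–Weinberg proportions — the identity, a constant series.

Observed and expected frequencies are regressed on year index by OLS
(year ≈ generation in this design, as the lifecycle steps one year at a
time); slopes are compared with a Welch unequal-variance t test and
Satterthwaite degrees of freedom, Bonferroni-corrected over the explicit
comparison family (the family size is an argument, since no canonical
family exists). Identical zero-variance samples give t = 0, p = 1 by
convention. The load diagnostics report the Pearson correlation of F_ij
with ΣP(aa) over every evaluated candidate mating and separate OLS fits for
made versus not-made pairs; ΣP(aa) (a sum, not a probability) is used as
the "affected" measure by definition, with the complement form
1 − Π(1 − P(aa)) available under `prob_any_affected`. Degenerate strata
(zero variance, < 3 pairs) are reported as undefined rather than guessed.

## Desk scale, and what it shows

The shipped tests and the acceptance script run a proportionally shrunken
program: 2,000 base cows, 50 base bulls, 20 herds, caps of 5,714 cows /
71 bulls, and a 300-matings cap (all ≈ 1/17.5 of full scale on the cow
side, 1/7 on the bull side, preserving the cap-to-matings ratio); 20 years;
replicate counts of 3 (acceptance script) or 10 (dynamics tests, matching
the full study's replicate count). A replicate takes ~15 s on one CPU.

Shrinking is not neutral. Exact and distributional properties (Mendelian
ratios, sampling variances, kinship, Hardy–Weinberg at base) are
scale-free and verified tightly. Mean purging of lethal load and the year-1
affected-calf rate also reproduce at desk scale. But per-locus trajectories
of rare alleles are drift-dominated: with ~15–30 effective sires a year,
the 20-year frequency drift SD (~0.05) exceeds the selective signals on
individual low-frequency loci, so full-scale findings that hinge on small
systematic trends — the slow erosion of red coat color under the plain
Pryce scheme, horned staying above 99 % under the modified scheme, and the
excess of affected calves over truncation selection — do not reliably
reproduce and their checks are expected to fail at this scale. A neutral
single-locus martingale check (40 replicates) confirms the simulator itself
is drift-unbiased. Full-scale behavior is reachable via
`examples/full_scale.py` given the memory noted above.

## Other fixed choices

* Replicate seeds derive from the scenario seed via `SeedSequence`
  (bit-identical replays; child seeds < 2³¹).
* Truncation rounding `floor`, minimum 1 sire; portfolio sample size
  `ceil(0.2 × live bulls)`, portfolio `min(50, sample)`.
* One calf per mated cow per year; embryo-death proportions use matings as
  the denominator (conceptions and matings coincide in this model).
* Many-locus panels sample MAF ~ U[0.01, 0.10] and value magnitudes
  ~ U[$10, $50]; values default to positive (costs), with a switch for the
  literal negative-sign reading since negative values denote desirable
  recessives (`literal_negative_values=True`).
* Horned is stored with the polled (minor) allele at 0.0071 and reported as
  the horned-allele frequency 0.9929; the $40 value attaches to the horned
  homozygote.
* Involuntary cow culling defaults to rate 0 (a documented knob); cow age
  at first breeding defaults to 2.

## Known limitations

Pedigree (not genomic) inbreeding throughout; no estimated breeding values
or phenotypes; no linear-programming or look-ahead mate selection; no
semen logistics; no mutation. The greedy allocation inherits the published
method's order dependence by design.
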