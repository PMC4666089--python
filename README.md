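# herdmate

Stochastic simulation of dairy-cattle mate allocation when many recessive
disorders segregate in the population.

Genomic screening keeps finding recessive alleles in dairy cattle — the
Holstein fertility haplotypes HH1–HH5, BLAD, CVM, DUMPS, brachyspina,
mulefoot — alongside managed non-lethal recessives such as red coat color
(desirable) and horned (undesirable). Avoiding carrier×carrier matings by
hand stops scaling once more than a few loci are tracked. `herdmate` is for
quantitative geneticists and breeding-program designers who want to study,
in simulation, how mate-allocation rules trade genetic gain, inbreeding,
and recessive-allele management against each other.

## The model

An overlapping-generations population is simulated on true breeding values
(TBV, dollars of lifetime net merit). A calf's merit is

    TBV_calf = ½(TBV_sire + TBV_dam) + MS,   MS ~ N(0, ½[1 − ½(f_S + f_D)]·σ_a²)

with σ_a² = 40,000 and f_S, f_D the parents' pedigree inbreeding
coefficients. Each recessive locus is an independent biallelic marker;
calves draw one allele per parent, and lethal homozygotes die at birth.
Four mate-allocation schemes are compared:

* **random** — every bull eligible, cows assigned uniformly (per-bull cap);
* **truncation** — top 10 % of bulls by TBV, random assignment, no cap;
* **pryce** — per herd, a portfolio of sires (random 20 % sample of live
  bulls, best 50 by TBV) scored per cow as

      B_ij = ½(TBV_i + TBV_j) − λ·F_ij

  with λ = $25 per 1 % of calf inbreeding and F_ij the prospective calf's
  pedigree inbreeding coefficient (the sire–dam coancestry), then assigned
  cow by cow to the best remaining bull under a mating cap;
* **modified_pryce** — the same with each pairing further adjusted by the
  expected economics of recessive genotypes:

      B′_ij = B_ij − Σ_r P(aa)_r · v_r

  where P(aa) ∈ {0, ¼, ½, 1} follows from parental genotypes and v_r is the
  locus value in dollars (negative v rewards desirable recessives).

The analysis layer provides the deterministic allele-frequency expectations
(a purging recursion for lethals, Hardy–Weinberg constancy for neutral
loci), OLS trajectory slopes, Welch/Bonferroni slope comparisons, and
diagnostics relating F_ij to the summed recessive load ΣP(aa) over all
candidate matings.

## A worked example

`examples/02_mating_plan.py` builds a 2-bull × 5-cow herd where every animal
carries one $400 lethal recessive, except bull 2 who is genotype-clean but
$70 behind bull 1 on TBV:

```
          pryce: cow3→bull1, cow4→bull1, cow5→bull1, cow6→bull2, cow7→bull2
                 carrier×carrier matings: 3, expected affected calves: 0.75
 modified_pryce: cow3→bull2, cow4→bull2, cow5→bull2, cow6→bull1, cow7→bull1
                 carrier×carrier matings: 2, expected affected calves: 0.50
```

The inbreeding-only scheme gives the high-TBV carrier bull his full cap of
carrier cows (expected loss 3 × 0.25 = 0.75 affected calves); the modified
scheme prices the 0.25 × $400 = $100 expected loss into each pairing, which
outweighs the $35 parent-average edge, and routes carrier cows to the clean
bull first.

Other examples: expected purging trajectories (`01`), a desk-scale
12-locus Holstein program under two schemes (`03`), inbreeding-vs-load
diagnostics on a 100-locus panel (`04`), and the full-scale driver
(`full_scale.py`, hours per scheme).

There is also a thin CLI:

```sh
herdmate presets
herdmate run --scenario holstein --scheme modified_pryce --reduced --seed 1 --out out/
herdmate compare out_pryce/ out_modified/
```

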