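# Methods notes

## Model summary and assumptions

The simulator is an individual-based, age-structured, two-sex forward model
with overlapping generations. Sex determination is a liability-threshold
trait: the male signal is the sum of the two sex-chromosome contributions
and an exogenous developmental component, and an individual develops male
iff the signal strictly exceeds its genotype's threshold. Core assumptions:

* parallel reaction norms — all genotypes share the same response of signal
  to the environment; warming shifts every genotype's signal by the same
  amount;
* the phenotype is fixed at birth; adults never re-experience climate;
* no mutation at any locus (evolution proceeds from standing variation
  only); loci are unlinked and recombination is irrelevant (one locus per
  chromosome pair);
* sex-reversed males and WW females are fully viable and fertile (unless φ
  is reduced); survival and fecundity are independent of genotype and sex;
* masculinization only (the signal rises with warming). A feminizing
  climate can be emulated by a negative `b_sig`, but that regime is not
  validated here.

## Signal scale and threshold placement

Only the 1.5 ratio between the chromosome contributions is fixed by the
biology; the absolute scale is a choice. We set `sig_a = 1`, `sig_A = 1.5`,
pre-warming mean exogenous signal `m0 = 0`. Given that scale:

* `thr_high` (per allele) is half the midpoint of the mean signals of the
  initial system's normal female and male genotypes: 1.375 in ZW (homozygote
  threshold 2.75 against female-genotype mean 2.5), 1.125 in XY (2.25 vs
  2.0). Normal genotypes therefore essentially never reverse before warming
  (the gap is ≈4.9 total s.d.).
* `thr_low` (per allele) is half of (female-genotype mean + z·σ_total) with
  σ_total = √(0.01² + 0.05²) ≈ 0.051 and z = 2.4: above the female
  genotype's average signal but just below its realized maximum, so ≈0.2%
  of genetically female offspring (homozygote and heterozygote carriers
  combined, at allele frequency 0.5) masculinize per pre-warming year. z is
  a configuration knob.
* the ten-allele sensitivity variant spaces 10 allele values evenly on
  [thr_low, thr_high] with uniform initial frequencies.

With `b_sig = 0.003`/year these placements put the loss of all female
production at ≈(0.25 + 3σ)/0.003 ≈ 134 warming years (≈45 generations) for
an XY system and ≈300 years (≈100 generations) for a ZW system that has
completed its turnover — the closed-form sanity check behind the simulated
extinction times.

## Life history and density dependence

Maturation at 2 y, annual survival 0.5 for juveniles and adults, maximum
age 8 y, carrying capacity Nmax = 400 recruits per year, 200 starting
adults. The yearly offspring number is `min(Nmax, Nmother · fert_f)`. We
set `fert_f = 40` (mean recruits a mated female could place into the
density-regulated offspring pool absent density dependence — a clutch
surplus representative of amphibians). The surplus matters structurally: a
`fert_f` near `Nmax / (n_start_adults/2)` makes expected recruits equal
expected deaths at *every* population size, i.e. a critical branching
process that drifts to demographic extinction on a century timescale, and
it would also make the late-phase cohort size female-limited, cutting
population persistence short of the point where female production truly
fails. With the surplus, the population self-regulates at ≈200 adults
(recruits/year at capacity = Nmax · juvenile_survival² = 100; expected
adult tenure ≈2 y) and the realized generation time is ≈2.96 y.

Initialization draws adult ages from the stationary (truncated-geometric)
age distribution of the survival process, seeds only normal genotypes at a
50:50 phenotypic sex ratio, samples `thr` alleles at frequency 0.5 and
`C_R` copies at the scenario's initial frequency, and adds standing
juveniles at their stationary abundance. Pre-warming sex reversal is not
seeded; it emerges from the signal model within a few years of burn-in.

## Mating market

Females choose sequentially in uniformly random order. The two male colour
classes are defined by the *initial* system's sex-linked cue (XY origin:
normal = carries A; ZW origin: normal = AA), so the classes females can
distinguish stay meaningful through a turnover. A female's class choice
uses her expressed preference c (probability of choosing a normal male)
weighted by remaining-libido availability, renormalized:
P(normal) = c·W_N / (c·W_N + (1−c)·W_R). Renormalization makes every
female with any available libido mate, which is what the definition of
Nmother (mated females) requires; with one class absent she mates within
the other (preference is non-exclusive). Within a class, a male is drawn
with probability proportional to his remaining libido (maximum 3 matings
per season). Conceptions are assigned to pairs uniformly with replacement,
so per-pair offspring numbers are multinomial. φ is charged at conception:
a conceived WW offspring enters the cohort with probability φ (the cohort
can therefore fall short of N when φ < 1); φ is applied only in ZW-origin
scenarios, where `aa` means WW.

## Derived statistics

* **Period segmentation** — a yearly state is computed from adult males
  (ZW while <5% carry chromosome a; XY while ≥95% are Aa; otherwise
  mixed; male-free years inherit the previous state), and a period ends at
  the first year from which its state fails for 50 consecutive years (or
  through the end of the record). The 50-year clause absorbs the strong
  annual fluctuation in male genotype composition.
* **N_e** = 4·N_f·N_m/(N_f + N_m) over adults at breeding. The
  unequal-sex-number formula captures the intended behaviour (N_e collapse
  as the ASR skews); a variance-corrected variant would need individual
  reproductive-success variance and is out of scope.
* **Sex-ratio selection coefficient** — broods are valued by Fisherian
  reproductive values, V = PSR/ASR + (1−PSR)/(1−ASR); s = V(C_R-class
  mothers)/V(C_N-class mothers) − 1. s = 0 exactly at ASR = 0.5 and is
  undefined (missing) when a maternal class is absent or the ASR is
  degenerate.
* **LD** — the Burrows composite Δ/2 on unphased adult copy counts,
  D = (1/2n)·Σ(x_i − 2p)(y_i − 2q). The composite is the right estimator
  for a census in which phase is unobservable; under random union of
  gametes it estimates gametic D, while for maximally inbred constructed
  populations it equals twice the haplotype-table D (a property the tests
  pin down explicitly).
* **Choice window** — the longest contiguous run of years in which both
  male classes exceed 5% of adult males and |s| > 1/(2·N_e) (selection
  stronger than drift). Frequency changes over a window or period are
  differences of 5-year means anchored at its ends.
* **Decline year** — the last year N_e reaches its baseline (the mean over
  the final 10 burn-in years); missing if N_e never stays below baseline.
* **Generation time** — the mean over retained offspring of the parents'
  mean age at conception.

## Numerical and implementation choices

* Ties in sex development go to female (male requires strictly exceeding
  the threshold).
* `round()` (half-to-even) in the offspring cap.
* Populations are stored column-wise in numpy arrays; the per-individual
  operations (signal, threshold, gamete, preference expression) exist as
  scalar functions and the engine's vectorized paths are tested against
  them.
* Replicate seeds fan out from a base seed through `SeedSequence` spawn
  keys, so a batch is bit-reproducible and order-independent; every run is
  a pure function of (scenario, seed).
* Heterozygote preference under intermediate inheritance is the midpoint
  of the two allele values (0.5).
* Extinction is declared when no phenotypic female remains in any age
  class; records stop at the last breeding census.

## What the generator emulates, and what it does not

The synthetic populations reproduce the study conditions: 200 stable
adults, ≈0.2% pre-warming masculinization, linear warming at 0.003 signal
units/year, and the three preference scenarios in both initial systems.
They do not emulate spatial structure or dispersal, density dependence
beyond the recruitment cap, genotype-dependent survival, new mutations, or
temperature per se (only its effect on the signal). Passing tests
therefore validate the model's internal logic and its match to the
published simulation behaviour, not predictions for any specific natural
population.

## Problem sizes

Batches use 30 replicates for the no-preference extinction medians and 100
replicates for the preference and φ-sensitivity scenarios; the pre-warming
masculinization rate pools six 200-year no-warming runs. A single run
spans 100–650 simulated years with ≤1000 individuals alive at once and
takes ~0.1–0.3 s, so the full acceptance recomputation finishes in a few
minutes on one CPU.

## Known limitations

* The φ = 0.25 with rare C_R scenario sits near a demographic bifurcation:
  the fraction of runs that complete the turnover is the quantity most
  sensitive to the life-history constants (fert_f, survivals, max age),
  and our parameterization yields ≈40% rescue rather than the ≈56%
  reported for the original (unpublished) parameter table, while matching
  the 0% and 90% C_R anchors (≈26% and ≈100%) and both failure/success
  persistence times (≈120 vs ≈270 years).
* Long no-warming runs inflate the pooled masculinization rate slightly
  above its p = 0.5 calibration point because the threshold-allele
  frequency drifts (the rate scales with E[p²] = 1/4 + Var(p)).
* The N_e, s and LD estimators are standard formulations chosen here; the
  original study's exact formulas for these auxiliary statistics were not
  available and alternatives could shift the derived windows by a few
  years.
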