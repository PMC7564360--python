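# Methods

## Model overview

`spovsim` is a forward-in-time, individual-based model of a univoltine
spider population with non-overlapping generations.  Two female behavioral
strategies compete: an aggressive-spillover family (SPOV and variants),
whose members attack approaching males with a fixed probability regardless
of their mating or hunger state, and a plastic "mate first, cannibalize
later" strategy (MFCL), whose members attack only when hungry or once
mated.  The strategy is determined by a single X-linked locus (XX females,
X0 males) with two alleles, S and M; heterozygous females express the
dominant allele's strategy (configurable), and males are phenotypically
identical carriers.

The population is held at carrying capacity: every generation exactly
`n_females` + `n_males` (500 + 500) offspring are sampled into adulthood.
Juvenile life is not simulated; it is collapsed into the single parameter
`different`, the proportion of spillover-phenotype juveniles surviving to
maturation relative to MFCL juveniles.

### Core assumptions

- Closed population, no migration or density feedback; fixed 1:1 sex ratio
  at maturation.
- No space: individuals encounter each other uniformly at random.
- No mate choice; prior residency at a female's burrow excludes rival males.
- Females mate at most once and are never sperm-limited afterwards.
- Post-mating cannibalism of the departing mate is negligible; all
  cannibalism occurs when a female attacks an approaching or cohabiting
  male before she mates with *him* (a mated female can still kill later
  suitors).
- Foraging is state-dependent only through a satiation threshold: a female
  whose condition (abdomen width, mm) reaches
  maxCOND_f = −38.98 + 11.73·CW − 0.63·CW² stops feeding for good.
- Egg size is constant; fitness is not enhanced by early oviposition.

## Parameters

All rates and regressions are field-calibrated values for *Lycosa
hispanica*, held in `spovsim.config`:

| quantity | default | units |
|---|---|---|
| season length | 79 | days |
| female maturation day (MFCL, SPOV, BCD-SPOV) | N(56, 0.5) | day |
| female maturation day (EARLY variants) | N(39, 0.5) | day |
| male maturation day | N(36, 0.5) | day |
| adult size CW (EARLY) | N(3.21 + 0.047·fem_mat + 0.39·CL, 0.5066) | mm |
| adult size CW (others) | N(3.21 + 0.024·fem_mat + 0.39·CL, 0.4679) | mm |
| initial condition COND₀ | N(3.54 + 0.49·CW, 0.2671) | mm |
| daily intake | U(0,1)·0.1482 (rich) / 0.0741 (poor), ×1.5 spillover | mm/day |
| male meal | +2.39, capped at maxCOND_f | mm |
| background mortality: MFCL ♀ / spillover ♀ / ♂ | 0.0030 / 0.0030·mort / 0.0045 | day⁻¹ |
| mort multiplier | 1.2 (rich), 1.5 (poor) | — |
| maxenc (encounters per male per day) | 1 (poor), 3 (rich) | day⁻¹ |
| pspov (spillover attack probability) | 0.9 (poor), 0.5 (rich) | — |
| pescape | exp(−0.1·CW) | — |
| egg-sac volume (SPOV, EARLY-SPOV) | N(−1156.43 + 277.21·CW, 140.33) | mm³ |
| egg-sac volume (BCD variants) | N(−1156.43 + 277.21·CW + 123.44·COND, 132.97) | mm³ |
| egg-sac volume (MFCL) | N(−2297.64 + 217.88·CW + 123.44·COND, 129.59) | mm³ |
| offspring per sac | round(57.54 + 0.16·vol) | — |
| different (spillover juvenile survival) | {0.1, 0.3, 0.5, 0.7, 0.9} | — |
| pmate (daily mating probability in cohabitation) | 0.5 | day⁻¹ |
| CL (carapace length covariate) | 3.5, constant | mm |

`pmate` is not field-measured; 0.5 makes cohabitation last ~2 days on
average, matching the qualitative observation that males spend "a few days"
at a female's burrow.  `CL` appears only inside the size regressions with no
documented distribution; it is exposed as a constant whose default keeps CW
in the species-plausible 5.5–6.5 mm range.  Both are configuration fields.

## The daily loop

Each season day, in fixed order: (1) maturation entry; (2) background
mortality, females then males by index; (3) feeding of unsatiated females;
(4) male search — each free mature male approaches up to `maxenc` distinct
living mature females; (5) cohabitation — each resident pair takes the
attack decision and, failing an attack, a mating draw.  All within-step
processing is in index order, and every stochastic decision consumes scalar
draws from one `numpy.random.Generator` in a documented order, so the
compiled engine (`spovsim._core`, numba) and the pure-Python
per-individual reference implementation (`spovsim.micro`) produce
bit-identical event traces from the same seed — the test suite exploits
this as an engine-against-oracle check.

### Design choices where the biology is open

Several micro-rules are not pinned down by the verbal model.  We fixed them
by simulating candidate readings and retaining the one whose emergent,
population-level behavior matches the documented phenomenology of the
system (classic SPOV always eliminated quickly; early-maturing spillover
favored in rich environments and at high juvenile survival; long-lived
polymorphisms in poor environments; rare-spillover invasion possible only
in rich environments with mild juvenile penalty).  The alternatives remain
available as configuration switches:

- **Satiated attacks are non-lethal by default**
  (`satiated_attacks_lethal=False`).  A satiated female no longer feeds, so
  her attack expresses aggression — it drives the suitor away and blocks
  mating — without consuming him.  This is the single most consequential
  choice: it makes male survival depend on how quickly spillover females
  satiate, which is what differentiates rich from poor environments.  With
  lethal satiated attacks, males are exterminated before late-maturing MFCL
  females ever mate, in every environment, and no polymorphism of any kind
  survives.
- **Attack decisions fire at the approach and on every cohabitation day**
  (`approach_attack_virgins=True`, `cohab_order="attack_first"`).  The
  mate-first alternative neuters the hungry-MFCL attack clause and lets
  classic SPOV persist, contradicting its robust elimination.
- **Encounters**: exactly `maxenc` distinct targets per male per day
  (`encounter_model="fixed"`); `"poisson"` and `"thinned"` (binomially
  scaled by the fraction of females currently encounterable) are provided.
- **Withdrawal**: by default all mature females remain encounterable;
  `withdrawal="gravid"` retires mated-and-satiated females to brood,
  `"satiated"` retires any satiated female.
- **MFCL attack rule**: `"literal"` (attack iff mated or not satiated) or
  `"mated_only"`.
- **Juvenile survival**: `different` is applied as a relative sampling
  weight on spillover-phenotype daughters in an exact weighted draw without
  replacement (`juvenile_mode="weight"`); a pre-sampling Bernoulli cull is
  available.  Sons are unweighted by default (males are phenotypically
  identical); `apply_different_to_sons` adds the weight to S-carrying sons
  for sensitivity.

## Numerical choices

- Maturation days are rounded half-up to the integer daily grid and clamped
  to [1, season_length].
- Condition is capped at maxCOND_f (feeding and male meals); satiation is
  absorbing.
- Females drawn with COND₀ ≥ maxCOND_f (a far-tail event for the default
  CL, a few percent of MFCL females) are marked satiated at entry rather
  than redrawn, preserving cohort size; their condition is left at COND₀.
- Negative egg-sac-volume draws truncate to 0 (the allometries extrapolate
  below their fitted range); offspring counts floor at 0.
- Next-generation sampling uses Efraimidis–Spirakis keys (u^(1/w)) for the
  weighted draw; if a sex's pool is smaller than the cohort, sampling falls
  back to with-replacement and logs the event.
- A renewal failure (no offspring of a required sex) ends a run with an
  explicit `extinct` flag; fixation is otherwise declared when the allele
  frequency over all 1500 adult X copies hits 0 or 1 at the start of a
  generation.
- One root `SeedSequence` spawns independent per-replicate streams; the run
  manifest records them, and a fixed seed reproduces a trajectory
  bit-identically.

## Equilibrium diagnostics

`spovsim.equilibrium` splits a polymorphic trajectory at an allele-frequency
threshold (default 0.85) into TOP and BOTTOM generations and fits
generation-level GLMs: binomial (logit) for the fraction of MFCL females
mating, Gaussian for spillover relative fitness (spillover females at
maturation over the two-strategy mean, a quantity in [0, 2]).  Each model
includes the phase label, generation number (temporal trend control) and
the allele frequency itself; the phase effect is tested by a likelihood
ratio against χ²₁, and covariate-adjusted means are computed at the grand
mean of the covariates (on the link scale for the binomial model, then
back-transformed to percentages).  A phase with no data yields a degenerate
report rather than a silent answer.  Null simulations in the test suite
confirm the test's size is near nominal despite the threshold's partial
collinearity with the frequency covariate.

## What the simulations show — and what they cannot

With the defaults above, the simulator robustly produces: rapid elimination
of classic SPOV in most scenarios; fixation of EARLY-SPOV in the recessive
maintenance design in about 4 of 10 environment × `different` cells, all of
them rich and at the higher survival values; long-lived (thousands of
generations) polymorphism in poor environments at high `different`; and
invasion of rare EARLY-SPOV into a pure-MFCL world only in rich
environments.

Two documented regimes are *not* reproduced, and we believe they cannot be
under any reading of the daily rules we constructed.  Both failures trace
to the same arithmetic: at a polymorphic equilibrium only ~10–30 females
mate per generation, so the effective number of parents is tiny and the
per-generation standard deviation of the allele frequency is ~0.05–0.1.
(a) A 20,000-generation oscillation of a *dominant* common allele in a
narrow high band: when the rare allele is masked in heterozygotes,
selection cannot see it near fixation, there is no restoring force at the
top of the band, and drift absorbs the polymorphism within tens to hundreds
of generations.  The equivalently structured polymorphism does persist for
thousands of generations here, but with the rare allele *recessive*-masked
(band below 0.5).  (b) Re-invasion by a rare dominant-masked allele from
frequency 0.01: its ~15 copies are selectively invisible and are lost by
drift almost immediately.  These limits are properties of the model
economy (male scarcity caps the number of broods), not of the
implementation; raising `pmate`, `maxenc`, or `n_males` inflates the brood
count and softens both.

The synthetic populations emulate the demographic and behavioral structure
of the field system, not its full biology: no spatial structure, no male
variation, no sperm limitation, no egg-size variation, no eco-evolutionary
feedback on density.  Passing tests therefore validate the internal logic
and the documented emergent patterns, not quantitative predictions for wild
populations.

## Problem sizes used by the test and acceptance runs

The test suite runs the full 500 + 500 cohort but caps multi-generation
experiments at 2,000–3,000 generations (maintenance and invasion designs)
— enough to classify fixation-versus-trend outcomes, since the interesting
transitions happen within hundreds of generations at these parameter
values.  Engine-level property tests use 60–120 individuals per sex.
`scripts/acceptance.py` runs the classic-SPOV grid (60 runs) to its
terminal generation with a 3,000-generation safety cap.
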