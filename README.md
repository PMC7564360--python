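# spovsim

An individual-based simulator for the evolution of two sexually cannibalistic
female strategies in a wolf-spider-like life history, parameterized with
field data from the Iberian tarantula (*Lycosa hispanica*).

Pre-mating sexual cannibalism is puzzling: a female that kills her suitors
before mating risks dying without sperm.  The *aggressive spillover*
hypothesis explains it as a by-product of selection for general voracity — a
behavioral syndrome in which aggression toward prey "spills over" onto
males.  The alternative is a plastic, state-dependent strategy: *mate first,
cannibalize later* (MFCL), in which a female attacks approaching males only
when hungry or once she has already secured sperm.  `spovsim` asks when
either strategy — or a polymorphism of both — can persist, by simulating the
full mating-season ecology: daily encounters, cohabitation at female
burrows, attacks and escapes, feeding, satiation, and X-linked inheritance
of the behavioral allele.

The package is aimed at behavioral ecologists and evolutionary modelers who
want to re-run, perturb, or extend the maintenance / invasion experiments
for these strategies.

## The model

A closed population of N = 1000 adults (500 females, 500 males) per
non-overlapping generation.  Aggression is controlled by one X-linked locus
with two alleles (S = spillover family, M = MFCL) under an XX / X0 system:
females are diploid, males hemizygous pure carriers.  Female phenotype
follows configurable dominance.

Within a 79-day season, each day:

- background mortality (MFCL females 0.0030 d⁻¹; spillover females 0.0036,
  raised to 0.0045 in poor environments; males 0.0045);
- each unsatiated female gains condition C (abdomen width, mm) by
  U(0,1) · 0.1482 mm (halved in poor environments; ×1.5 for spillover
  females), until the satiation threshold
  maxCOND_f = −38.98 + 11.73·CW − 0.63·CW²;
- each free male approaches up to `maxenc` (1 poor / 3 rich) random mature
  females.  Spillover females attack with probability `pspov` regardless of
  state; MFCL females attack iff mated or not satiated.  An attacked male
  escapes with probability exp(−0.1·CW); a male killed by a hungry female
  adds 2.39 mm to her condition.  A non-attacking virgin takes the male as
  resident (prior residency excludes rivals), and each cohabitation day he
  mates with probability 0.5 or faces the attack rule again;
- at season end, each surviving mated female lays one egg sac with volume
  from her strategy's allometry (e.g. −1156.43 + 277.21·CW for spillover;
  −2297.64 + 217.88·CW + 123.44·COND for MFCL) and
  N = 57.54 + 0.16·vol offspring.  Spillover-phenotype daughters survive
  the (unsimulated) juvenile stage with relative probability `different`,
  and exactly 500 + 500 new adults are sampled.

Five strategies are built in: `MFCL`, `SPOV`, `BCD-SPOV`, `EARLY-SPOV`
(matures 17 days earlier, steeper size-maturation slope), and
`BCD-EM-SPOV` (the `BCD` variants feed adult foraging back into fecundity).
See `docs/methods.md` for assumptions, calibration choices (notably the
satiation model and the CL covariate), and known limitations.

## Worked example

Run the maintenance experiment (alleles at 50%, female genotypes in thirds)
for the early-maturing spillover variant against MFCL in a poor environment
with spillover juvenile survival 0.7, spillover allele recessive:

```bash
spovsim simulate --seed 42 --out demo --environment poor \
    --different 0.7 --dominance mfcl --max-generations 2000
```

which logs

```
INFO spovsim: replicate 0: mfcl_fixed at generation 1702 (p = 0.0000)
```

and writes `demo/trajectory_rep0.csv`:

```
generation,p,n_es_females,n_mfcl_females,survivors_es,survivors_mfcl,matings_es,matings_mfcl,males_cannibalized,mfcl_mating_pct,rel_fitness_es
0,0.500667,167,333,138,311,19,80,463,24.024,0.668
1,0.459333,93,407,74,386,26,174,452,42.7518,0.372
```

Reading generation 0: the spillover allele starts at frequency p = 0.5007
(1500 X copies); 167 of 500 females express the spillover phenotype (the SS
homozygotes plus rounding of the thirds split); 463 of 500 males die by
cannibalism during the season; 24.0% of MFCL females and 19/167 = 11.4% of
spillover females mate; spillover relative fitness (spillover survivors over
the two-strategy mean) is 0.67.  The spillover allele then persists as a
long-lived polymorphism below 0.5 — a quasi-equilibrium — before the MFCL
allele finally fixes at generation 1702 (`"quasi_equilibrium": true` in
`demo/summary.json`).

Other entry points: `spovsim sweep` (environments × `different` × dominance
grid) and `spovsim equilibrium-report` (TOP/BOTTOM frequency-dependence
diagnostics), or the library API:

```python
from spovsim import load_config, run_generations
cfg = load_config({"environment": "rich", "different": 0.9,
                   "dominance": "spillover", "initial_state": 0.01})
traj = run_generations(cfg, rng=1)          # invasion of a rare mutant
print(traj.outcome, traj.terminal_generation)
```

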