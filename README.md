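# csiatrace

Compound-specific stable isotope analysis of amino acids (CSIA-AA) for
nutritional ecology of host–symbiont systems, built around the model system
of a symbiotic coral (animal host + dinoflagellate symbionts) reared under
autotrophic, mixotrophic and heterotrophic feeding regimes with brine-shrimp
(*Artemia*) prey.

The package provides a complete, testable pipeline:

1. **Synthetic cohorts** (`csiatrace.synthetic`) — per-sample true δ¹⁵N /
   δ¹³C amino-acid values drawn from a treatment × compartment parameter
   table, pushed through a GC-C-IRMS instrument forward model
   (derivatization carbon addition, affine nitrogen response, linear
   sequence drift, analytical noise, bracketing certified-standard blocks).
2. **Calibration** (`csiatrace.calibration`) — inversion of the instrument
   layer: replicate averaging, drift correction from the standards, a
   per-sequence nitrogen regression calibration, and the per-amino-acid
   derivatization carbon correction via the isotope mass balance

       n_cd · δ¹³C_cd = n_c · δ¹³C_c + n_d · δ¹³C_dcorr

   where *n_c* carbons belong to the amino acid, *n_d* are added by
   chloroformate derivatization, and δ¹³C_dcorr is the empirically
   determined correction factor estimated from certified standards.
3. **Trophic position** (`csiatrace.trophic`) — from the trophic/source
   amino-acid pair glutamic acid (Glu) and phenylalanine (Phe):

       TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β) / TDF + 1

   with defaults β = −0.36 ‰ and TDF = 4.54 ‰ (a calibration suited to
   chloroformate derivatization). TP = 1 is a primary producer, TP = 2 a
   primary consumer; a mixotroph falls in between.
4. **Statistics** (`csiatrace.stats`) — Levene/Bartlett variance checks,
   Kruskal–Wallis with pairwise Wilcoxon rank-sum post hoc and
   Benjamini–Hochberg adjustment, additive two-way ANOVA (sequential SS)
   with Tukey HSD, an adonis-style Euclidean PERMANOVA (sequential
   partitioning, free permutations) implemented from first principles, and
   non-metric MDS ordination.

## Worked example

```python
import numpy as np
from csiatrace import (load_config, generate_cohort, forward_instrument,
                       calibrate_runs, compute_tp_records)

config = load_config("paper_defaults")          # packaged study conditions
cohort = generate_cohort(config.cohort, seed=1) # 36 tissue + 3 prey samples
runs = forward_instrument(cohort, config.instrument, config.standards, seed=2)
records, reports = calibrate_runs(runs, config.standards)
tp = compute_tp_records(records, config.constants)
print(tp.groupby(["treatment", "compartment"])["tp"].agg(["mean", "std", "count"]).round(2))
```

prints

```
                          mean   std  count
treatment    compartment
autotrophy   host         1.25  0.26      6
             symbiont     1.14  0.35      6
heterotrophy host         1.59  0.53      6
             symbiont     2.29  0.74      6
mixotrophy   host         1.25  0.31      6
             symbiont     1.05  0.40      6
prey         prey         2.45  0.02      3
```

Reading: autotrophic and mixotrophic fractions sit near TP ≈ 1 (primary
producer / mostly autotrophic), the *Artemia* prey near TP ≈ 2.4, and the
heterotrophically fed symbionts climb toward the prey value (TP ≈ 2.3) —
the per-group spread reflects the between-colony variability built into the
generator plus residual analytical noise after calibration.

The same pipeline is available from the shell:

```sh
csiatrace run --config paper_defaults --seed 1 --out out/
csiatrace simulate --seed 1 --out out/sim        # single stages
csiatrace stats --corrected out/calibrate/corrected.csv --seed 1 --out out/stats
```

`run` writes per-stage CSVs (raw peaks, corrected values, TP table, rank
tests, PERMANOVA table in the conventional Df / Sum Sqs / Mean Sqs /
F. Model / p layout, nMDS coordinates) plus a manifest and run log.

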