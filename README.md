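# ceemdboost

Automatic detection of epileptic seizures in EEG recordings, built
around complementary ensemble empirical mode decomposition (CEEMD) and
gradient-boosted trees. The package is for researchers who want a
reproducible, testable implementation of the decomposition → feature
extraction → importance-based selection → classification pipeline, with
readers for the two common EEG distribution formats (single-channel
plain-text segments at 173.61 Hz and multi-channel EDF recordings at
256 Hz with seizure annotations) and a synthetic generator so everything
runs without clinical data.

## The method

A segment x(n) is decomposed into M intrinsic mode functions and a
residue,

    x(n) = Σⱼ IMFⱼ(n) + R(n),    j = 1..M,

by CEEMD: EMD (iterated cubic-spline envelope-mean sifting) is run on
x ± wₖ for paired white-noise realizations wₖ and the modes averaged, so
the injected noise cancels while mode mixing is suppressed. The number
of modes follows the dyadic rule M = floor(log₂ n): 12 for a
4097-sample segment, 14 for a 17,664-sample one.

From the raw series and every component, the package extracts a
time/frequency/time-frequency catalogue plus six entropies (permutation,
Shannon, spectral, approximate, sample, SVD). An xgboost classifier
supplies normalized gain importances; features with importance ≥ 0.001
survive, re-selected inside each training fold. Performance is reported
as stratified 10-fold cross-validated sensitivity, specificity, and
accuracy:

    SEN = TP/(TP+FN)·100%,  SPE = TN/(TN+FP)·100%,  ACC = (TP+TN)/N·100%.

See `docs/methods.md` for assumptions, parameter defaults, and the
numerical conventions.

## Worked example

```python
import ceemdboost as cb

segments = cb.gen_dataset(cb.standard_benchmark(n_per_class=30))
table, labels = cb.extract_table(segments, cb.DecomposeConfig(n_pairs=5, seed=0))

report = cb.cross_validate(table, labels, cb.ClassifierConfig(seed=0), k=5, seed=0)
print(report.to_text())

ranking = cb.importance_ranking(cb.fit_classifier(table, labels))
print(cb.top_features(ranking, 3).to_string(index=False))
```

prints

```
             SEN              SPE              ACC     Time
    96.67 ± 6.67    100.00 ± 0.00     98.33 ± 3.33     0.7s
                          name  score component domain
          raw__absolute_energy    1.0       raw   time
        imf_1__absolute_energy    0.0     imf_1   time
imf_1__absolute_sum_of_changes    0.0     imf_1   time
```

Reading the output: over five folds of 60 synthetic segments the
detector recovers 96.67% of seizure segments (SEN), never mislabels a
background segment (SPE), and is 98.33% accurate overall. The ranking
shows *why* this benchmark is easy — synthetic seizures are generated at
4× the background amplitude, so a single energy feature carries all the
split gain; on real EEG the importance spreads across components and
domains.

The same pipeline is scriptable from the shell:

```sh
ceemdboost synth --out segs --n-per-class 30 --seed 7
ceemdboost extract segs/segments.csv --out features.csv --pairs 5
ceemdboost evaluate features.csv --out report.json --k 5
ceemdboost run config.yaml          # all stages from one YAML config
```

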