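# ms1class

Class-level annotation of specialized metabolites from MS1 data alone.

Untargeted metabolomics detects far more features in full-scan (MS1) mode
than MS/MS ever fragments, but an accurate mass by itself identifies
nothing. `ms1class` pushes MS1 features to a defensible *class-level*
annotation (MSI Level 3) using only descriptors computable from a
molecular formula:

- Van Krevelen atomic ratios **H/C** and **O/C**,
- the double bond equivalent **DBE = C − (H + X)/2 + N/2 + 1**,
- the modified aromaticity index **AI_mod** (Koch–Dittmar),
- the **carbon count**.

A built-in knowledge base holds characteristic windows on these axes for
20 natural-product classes — flavonoids, phenolic acids, tannins,
coumarins, stilbenes, lignans, anthraquinones; ten alkaloid subclasses;
triterpenes, steroids and saponins — and a range-membership classifier
ranks candidate classes with nitrogen gating, half-integer-DBE logic for
protonated alkaloids, and DBE/carbon tie-breaking. The package also
enumerates candidate formulas for accurate masses under a 2 ppm
tolerance (completeness proven against brute force in the tests),
generates class-consistent synthetic datasets, and draws the standard
diagnostics (Van Krevelen scatter, DBE distributions, range bars,
boxplots, 3D H/C–O/C–DBE).

It is aimed at natural-products and metabolomics researchers who have
centroided high-resolution MS1 peak lists (or formula tables from vendor
software) and want a fast, reproducible, fully scriptable class survey of
a crude extract.

## Worked example

```python
>>> from ms1class import classify_table, default_kb
>>> classify_table(["C15H10O7", "C30H50O", "C8H10N4O2"], default_kb())[
...     ["formula", "hc", "oc", "dbe", "c", "n", "top1_class", "top1_score"]]
     formula        hc        oc   dbe   c  n  top1_class  top1_score
0   C15H10O7  0.666667  0.466667  11.0  15  0   flavonoid         1.0
1    C30H50O  1.666667  0.033333   6.0  30  0  triterpene         1.0
2  C8H10N4O2  1.250000  0.250000   6.0   8  4      purine         1.0
```

Quercetin (C15H10O7: H/C 0.67, O/C 0.47, DBE 11, C15) sits inside every
flavonoid window; lupeol (C30H50O: DBE 6, exactly 30 carbons) is a
textbook triterpene; caffeine (C8H10N4O2: DBE 6 with four nitrogens)
lands in the purine alkaloid window. A score of 1.0 means the profile is
inside all of the class's windows; the `candidates` column keeps the
ranked runners-up, and `msi_level` is always "3" — these are class
calls, not identifications.

The same pipeline from a peak list, on the command line:

```bash
ms1class simulate --classes flavonoid,purine,triterpene --n 10 --seed 11 \
    --out-formulas formulas.csv --out-peaks peaks.csv
ms1class assign --input peaks.csv --adduct "[M+H]+" --ppm 2 \
    --bounds C0-70H0-120N0-6O0-35 --out assigned.csv
ms1class classify --input assigned.csv --out annotated.csv
ms1class plot vk  --input annotated.csv --out vk.png
ms1class plot dbe_hist --input annotated.csv --out dbe.png
```

`assign` converts each m/z to a neutral mass (adduct atoms and electron
mass accounted for), enumerates every formula within the element bounds
and 2 ppm, and keeps the best by |ppm error|; peaks without a candidate
are flagged, never dropped. Every command writes a `*.manifest.json`
recording the exact configuration, and identical runs produce
byte-identical CSVs.

The estimator API mirrors scikit-learn and composes with its pipelines:

```python
from ms1class import VanKrevelenClassifier
clf = VanKrevelenClassifier(top_k=3).fit([])
clf.predict(["C15H10O7", "CH4"])   # -> ['flavonoid', 'unclassified']
```

## Layout

- `src/ms1class/` — formula parsing and adducts, descriptors, knowledge
  base (+ `docs/kb.schema.json` for user KB files), classifier,
  formula enumeration, synthetic data, plotting, CLI.
- `docs/methods.md` — the model, its assumptions, parameter defaults and
  known limitations.
- `tests/` — unit, property (hypothesis) and end-to-end suites.
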