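# Methods

## The annotation model

`ms1class` annotates specialized plant metabolites at the *class* level
(MSI confidence Level 3) from nothing but molecular formulas — either
supplied directly or assigned from accurate MS1 masses. Four
formula-derived descriptors span the chemical space:

- **H/C and O/C atomic ratios** (the Van Krevelen coordinates), tracking
  saturation and oxidation state;
- **DBE**, the ring-plus-double-bond equivalent,
  `DBE = C − (H + halogens)/2 + N/2 + 1`, tracking rings and π-bonds;
- **AI_mod**, the modified aromaticity index of Koch & Dittmar,
  `AI_mod = (1 + C − O/2 − S − (N + P + H)/2) / (C − O/2 − S − N − P)`,
  clamped to [0, 1] and defined as 0 for non-positive denominators;
- **carbon count**, which separates otherwise convergent classes (e.g.
  C30 triterpenes vs ≤C28 steroids vs C35–60 saponins).

Each of 20 built-in classes (7 phenolic, 10 alkaloid, 3 isoprenoid)
carries inclusive [min, max] windows on some or all of these axes. A
profile's score for a class is the **mean per-axis membership over the
class's defined axes**: 1 inside the window, `exp(−d/σ)` outside it,
where `d` is the distance to the nearest bound. Softness defaults:
σ = 0.1 for ratios, 1.0 for DBE, 2.0 for carbons; setting all σ to 0
gives hard in-or-out membership. A profile inside every window of a class
scores exactly 1. The score is a heuristic ranking device, not a
probability.

Three gates encode chemistry that windows alone cannot:

1. **Nitrogen**: alkaloid classes require N ≥ 1. In strict mode (default)
   nitrogen-bearing profiles are also barred from phenolic/isoprenoid
   classes, whose curated windows describe CHO formulas; in non-strict
   mode they are demoted by a factor of 0.5 instead, which is the right
   setting when glyco-conjugated N-containing phenolics are plausible.
2. **Half-integer DBE**: computed on an intact even-electron ion with one
   nitrogen (the `ion` convention), DBE is a half-integer — diagnostic of
   protonated alkaloids — so eligibility collapses to the nitrogenous
   group.
3. **Tie-breaks** at equal score: smaller |DBE − window midpoint| first
   (DBE is the primary discriminator), then |C − carbon midpoint|, then
   class name. Ranking is therefore total and deterministic.

### DBE conventions

The alkaloid literature quotes half-integer DBE windows (e.g. protoalkaloids
5.5–6.5, pyrrolizidines 6.5–7.5) because single-nitrogen compounds are
observed as protonated even-electron ions. The built-in windows keep
those printed endpoints verbatim. Descriptor profiles default to the
**neutral** convention (integer DBE; a neutral integer inside a
half-integer-bounded window is a legitimate match); passing the intact
ion composition with `convention="ion"` reproduces the half-integer
behaviour. Every output records which convention was used.

## The knowledge base

Bounds carry per-bound provenance. Windows printed in the literature are
tagged `paper` and reproduced verbatim (these are what the acceptance
checks compare). Axes described only qualitatively are tagged `derived`:
they are the observed min/max over ≥10 canonical member compounds per
class, shipped as data (`CANONICAL_MEMBERS`) so the derivation is
reproducible and auditable. Deliberate choices:

- flavonoid DBE 7–20 and phenolic-acid DBE 5–11 are the unions of the two
  printed ranges for each class;
- tannin carbon is capped at 120 ("30 to over 100" in prose);
  steroid carbon floor is 10 (to exclude trivial small molecules);
- "quinones" and "anthraquinones" are one class, `anthraquinone`;
- AI_mod has no published threshold, so it gates nothing by default; it
  is exported as a column and available as a user filter.

User KBs are JSON (`docs/kb.schema.json`); loading validates min ≤ max,
group names, duplicate class names, and reports all violations at once.
`validate_kb` additionally reports same-group window overlaps (fraction
of the narrower window covered), which is where classification leans on
the remaining axes and the tie-breaks.

## Formula assignment

Candidate formulas for a neutral mass are enumerated exactly within
per-element count bounds (defaults C 0–70, H 0–120, N 0–6, O 0–35,
S 0–2, P 0–2) and a ppm tolerance (default 2 ppm, defined against the
neutral mass; m/z-relative is available). The search walks elements
heavy-first with residual-mass pruning and resolves hydrogen
arithmetically at the leaves; the test suite proves set-equality against
a brute-force oracle. Ion→neutral conversion subtracts the adduct atoms
and restores the electron mass, which matters below m/z 300 at 2 ppm.
Default chemical filters require integer, non-negative DBE; H/C and O/C
range filters are available but off by default. Ranking is by |ppm
error|, ties by fewer heteroatoms, then formula string.

**Known limitation — accurate mass is not unique.** Above ~450 Da a
2 ppm window can contain near-doublets such as `P + N + H3 ↔ C4`
(0.4 mDa) and `C13 + N2 ↔ H8 + O11` (0.5 mDa) that no MS1-only method
can resolve; vendor pipelines disambiguate with isotope patterns, which
are outside this package's scope. Consequently the guarantee is
*retention*: the true formula is always in the candidate set (measured
100%). Rank-1 assignment rates on the synthetic benchmark are ~96% with
CHNO bounds and ~80% with the full CHNOPS defaults. Workflows on plant
specialized metabolomes should use CHNO(+S) bounds, e.g.
`--bounds C0-70H0-120N0-6O0-35`.

## Synthetic data

The generator emulates a curated class dataset, not an instrument:

- `window_sampled` draws integer (C, N, H, O) compositions uniformly from
  a class's windows. H is solved from the DBE window (DBE is linear in
  H) with the parity that makes neutral DBE an integer, so records are
  valid neutral formulas inside all windows by construction (a
  verification pass re-checks; an empty integer lattice raises — the
  built-in `protoalkaloid` windows are such a case, because their printed
  ion-convention DBE window 5.5–6.5 is incompatible with the
  member-derived H/C and carbon windows on the neutral integer lattice).
- `scaffold_built` starts from a canonical core (coumarin C9H6O2, tropane
  C8H15N, lupeol C30H50O, …) and adds 0–3 substituents from the
  natural-product vocabulary (hydroxyl, methoxyl, methyl, prenyl,
  methylenedioxy, glycosyl). These mimic homologue series and may leave
  the windows.

Peak lists apply Gaussian mass error in ppm (default σ = 0.5 ppm,
typical of a well-calibrated Orbitrap) and log-uniform intensities over
1e4–1e7. Everything is reproducible from integer seeds.

What passing the synthetic benchmark does **not** show: real spectra
contain isotopologues, in-source fragments, adduct mixtures, primary
metabolites outside every window, and correlated (not Gaussian,
not centred) mass error. The benchmark validates the descriptor/window
machinery, not instrument robustness.

### Benchmark sizes

The end-to-end recovery check uses 200 records — 20 from each of 10
classes spanning all three groups (tannin is replaced by anthraquinone
because tannin carbon counts extend past the C ≤ 70 enumeration default;
protoalkaloid is unsatisfiable, see above) — ionized as [M+H]+ at
0.5 ppm noise and assigned at 2 ppm with CHNO bounds. The
enumerator-vs-oracle equivalence check runs 100 random instances on a
small lattice where exhaustive search is cheap; self-recovery draws 500
random compositions against the full default bounds.

## Numerical choices

- Isotope masses are an embedded constants table (most-abundant isotope,
  CODATA/IUPAC; electron 0.00054858 Da), unit-tested against pyteomics.
- Exact rational arithmetic is avoided; all window comparisons are plain
  float comparisons on inclusive bounds, with 1e-9 guards only where
  integer lattices are constructed.
- Histogram binning uses the floor rule `bin = floor(dbe/width)·width`;
  width 0.5 (default) gives half-integer DBE values their own bins.
- Boxplots use matplotlib's default quartile rule (linear interpolation).
- Negative DBE is computed as-is and handled by filters/validation, not
  by raising.

## Limitations

- Charge states |z| > 1, parenthesized/hydrate/isotope-labelled formula
  syntax, and isotopologue patterns are out of scope.
- Class windows were curated for ESI-detectable specialized metabolites of
  plants; applying them to microbial or synthetic chemical space will
  misannotate.
- Scores are rankings, not calibrated posteriors; MSI Level 3 means the
  annotation names a plausible class, never a compound.
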