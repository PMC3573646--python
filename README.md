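# fragtree

Fragmentation trees for metabolite structural characterisation from
multistage mass spectrometry (MS^n).

Identifying a metabolite from mass spectra is hard because an elemental
formula alone is not structure-specific, and single-stage MS/MS spectra
of structural isomers can be nearly identical. Ion-trap instruments can
fragment fragments (MS³, MS⁴, …), and the *observed* precursor–product
hierarchy across those stages is itself a strong structural fingerprint.
`fragtree` turns raw MS^n runs into **fragmentation trees**: rooted
trees of fragment ions, each annotated with an unambiguous elemental
formula, each identified by its **Elemental Formula Path** (EFP) — the
chain of formulas from the precursor down to the ion, e.g.

```
C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1
```

The package is for mass spectrometrists and metabolomics
bioinformaticians who want MS^n data reduced to comparable, database-
ready tree objects.

## The method

For a fragment peak at observed m/z *x* under a precursor with ion
formula *P*, candidate formulas *F* must satisfy

- **mass**: |(x − m(F))/m(F)| ≤ 6 ppm, with m(F) the theoretical ion
  m/z including the electron mass, (Σᵢ nᵢmᵢ − polarity·mₑ)/z;
- **hierarchy**: F ⊆ P element-wise, so the neutral loss L = P − F has
  non-negative counts and F + L = P exactly;
- **plausibility**: heuristic element-ratio/count rules over CHNOPS,
  and non-integer RDBE (= C + 1 − H/2 + (N+P)/2) as expected for
  even-electron singly charged ions.

Peaks with no surviving candidate are spectral artifacts and are
removed. Repeated acquisitions are merged into a consensus tree keeping
EFPs present in ≥ 40% of repetitions. Trees are compared as EFP sets
with the Tanimoto coefficient |A∩B|/(|A|+|B|−|A∩B|) and clustered
(complete linkage, Euclidean distance on presence vectors) — specific
enough to separate structural isomers such as prostaglandins D2/E2.

A built-in simulator reproduces the data-dependent acquisition scheme
(top-5 peaks fragmented at MS² and MS³, top-3 at MS⁴, down to MS⁵ —
107 scan events per repetition when saturated; 4500-count precursor
threshold) with ppm-scale mass noise, intensity noise and injected
artifact peaks, so the whole pipeline is testable without instrument
data. The glutathione tree (21 EFPs) ships as a packaged worked
example.

## Worked example

```python
from fragtree import (FormulaConstraints, assign_tree, efp_strings,
                      glutathione_fixture, parse_formula,
                      spectrum_tree_from_truth)

truth, expected, ppm = glutathione_fixture()
stree = spectrum_tree_from_truth(truth, ppm_by_efp=ppm)   # MS1..MS5 scans
tree = assign_tree(stree, root_formula=parse_formula("C10H18N3O6S"),
                   constraints=FormulaConstraints(tol_ppm=6.0))
print(len(efp_strings(tree)), efp_strings(tree) == expected)
```

prints

```
21 True
```

— the 15-scan glutathione hierarchy, rebuilt from the published masses
and ppm errors, is assigned back to exactly the 21 published EFPs.
Running `python examples/01_glutathione_tree.py` lists all 21 paths
with their MS stage, observed m/z and mass error (root
m/z 308.0909 at −0.5 ppm for the C10H18N3O6S⁺ cation). The other
examples simulate a noisy 5-repetition run into a 21-EFP consensus
tree and discriminate a synthetic isomer pair (Tanimoto 13/43 ≈ 0.30
between isomers vs ≈ 0.9 between replicates).

Or from the shell:

```sh
fragtree simulate --fixture glutathione --reps 5 --seed 42 -o run.mzXML
fragtree build --mzxml run.mzXML --root-formula C10H17N3O6S --polarity pos -o tree.json
fragtree compare tree.json tree.json      # -> 1.0000
```

(`--root-formula` takes the neutral molecule; the tool forms the
[M+H]⁺/[M−H]⁻ ion per polarity. `--root-ion` accepts the ion
composition directly.)

## Layout

- `src/fragtree/formula.py` — CHNOPS formula arithmetic, filters,
  candidate enumeration
- `src/fragtree/spectra.py` — mzXML and peak-tree JSON IO, precursor
  linking, intensities
- `src/fragtree/builder.py` — hierarchy-constrained assignment,
  consensus, JSON/CML export
- `src/fragtree/compare.py` — Tanimoto, occurrence matrices,
  clustering, dot product
- `src/fragtree/simulate.py` — DDA simulator, truth-tree generators,
  packaged fixtures
- `src/fragtree/cli.py` — the `fragtree` command
- `docs/methods.md` — model, assumptions, parameter choices,
  limitations; `docs/formats.md` — file formats
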