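# tubmap

Residue-level mapping of tubulinopathy missense variants onto the
microtubule lattice, with composition-proportional enrichment statistics.

Heterozygous missense mutations in α-tubulin (TUBA1A) cause cortical
malformations — lissencephaly, microlissencephaly, pachygyria,
polymicrogyria. A natural meta-analytic question is whether the variants of
one malformation concentrate in a particular part of the tubulin protein:
a secondary-structure class (helix / sheet / loop) or a functional domain
of the microtubule lattice (longitudinal interface, lateral interface,
MAP-binding outer surface, GTP pocket, lumen, intradimer interface, other).
`tubmap` implements that analysis as a reusable, tested pipeline:

1. **Structure model** — read an α/β-tubulin heterodimer (mmCIF/PDB via
   gemmi), attach a three-class secondary-structure annotation table, and
   compute per-category residue compositions.
2. **Lattice domains** — rebuild the five-dimer lattice neighborhood from
   rigid transforms (one longitudinal, two lateral), detect interface
   residues by heavy-atom contact (4.5 Å default), classify exposed
   residues as outer (MAP-binding) or luminal by their radial coordinate,
   and combine the rules into a mutually exclusive seven-domain partition.
   A residue in the GTP pocket is labeled *GTP binding* regardless of any
   other membership (the GTP-precedence rule).
3. **Variant classification** — parse substitutions ("R402C",
   "p.Arg402Cys"), validate against the structure's sequence, and flag each
   as loss of charge / charge swap, gain of charge, hydrophobicity change,
   or no change (Kyte–Doolittle hydrophobicity; D,E negative, K,R positive,
   histidine-neutral by default).
4. **Enrichment statistics** — under the composition-proportional null the
   expected count in category *i* is E\_i = f\_i·N with f\_i the residue
   fraction. A χ² goodness-of-fit test (statistic Σ(Oᵢ−Eᵢ)²/Eᵢ, df = k−1)
   covers the whole variant set; an exact two-sided Fisher test
   (point-probability rule) per (phenotype, category) cell scans for
   phenotype-specific enrichment.
5. **Synthetic data** — toy cylindrical lattices with planted domain labels
   and variant tables with controllable planted enrichment, so every rule
   and test can be checked against construction-time ground truth.

## Worked example

```bash
tubmap fixtures --out-dir fixtures --seed 7      # toy inputs with ground truth
tubmap enrich \
    --structure fixtures/structure.cif \
    --ss fixtures/ss.tsv \
    --lattice fixtures/lattice.json \
    --variants fixtures/variants.tsv \
    --out-dir results/
```

prints

```
secondary_structure: X^2(df=2, N=120) = 1.327; p = 0.52
functional_domain: X^2(df=6, N=120) = 14.498; p = 0.02
```

i.e. for this generated 120-variant table the observed spread over helix /
sheet / loop is fully compatible with the composition-proportional null
(p = 0.52), while the functional-domain counts happen to deviate at
p = 0.02 for this seed. `results/report_wide.tsv` holds the per-phenotype
Fisher p-values (two decimals, `<0.01` floor), `report_long.tsv` the
full-precision values and 2×2 tables, and `provenance.json` the effective
configuration, the analyzed/dropped record counts and the goodness-of-fit
results. Library use mirrors the CLI:

```python
from tubmap import (make_toy_lattice, ToyLatticeParams, assign_domains,
                    enrichment_scan)
toy = make_toy_lattice(ToyLatticeParams(seed=7))
partition = assign_domains(toy.model, toy.spec)   # 100% planted-label recovery
```

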