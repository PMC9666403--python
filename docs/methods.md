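# Methods

## The analysis

The pipeline asks two questions about a set of heterozygous missense
variants in α-tubulin, each tagged with one predominant cortical
malformation (lissencephaly, microlissencephaly, pachygyria,
polymicrogyria, or `not_available` when no clinical imaging is known):

1. **Global bias.** Do variants, as a whole, fall into secondary-structure
   classes or lattice functional domains more often than residue
   composition alone predicts? Under the composition-proportional null,
   E_i = f_i·N where f_i is the fraction of residues in category i and N
   the variant count. The test is the χ² goodness of fit
   Σ(O_i−E_i)²/E_i with df = k−1; expected counts are kept as reals and
   rounded only for display. A zero expected cell is a hard error (merge
   categories instead of testing them).
2. **Phenotype-specific enrichment.** For each (phenotype m, category s)
   cell, an exact two-sided Fisher test on the 2×2 table
   `[[x_ms, n_m−x_ms], [R_s, R_tot−R_s]]` (default `residues` background:
   the category's residue count against the rest of the chain). The
   goodness-of-fit uses every record; the Fisher scan uses only clinically
   labeled records, and the report states both counts plus the number of
   dropped `not_available` rows. Two alternative backgrounds (`expected`:
   rounded expected counts; `other_mutations`: the other phenotypes'
   variants) are provided for sensitivity analysis. Raw p-values are
   reported; a Benjamini–Hochberg column is opt-in and off by default,
   matching the convention of reporting each cell's unadjusted exact p.

The two-sided Fisher p is the point-probability sum: all tables with the
observed margins whose hypergeometric probability does not exceed the
observed table's, compared at 1e-12 relative tolerance; a degenerate
margin gives p = 1 by convention. A one-sided (`greater`) variant exists
for directional enrichment questions.

## Domain partition

Every residue receives exactly one of seven labels. Membership rules, each
recorded per residue in an evidence trace:

- **GTP binding** — any heavy atom within `ligand_cutoff` (default 4.0 Å)
  of a tagged nucleotide (N-site on α at the intradimer surface, E-site on
  β at the interdimer surface).
- **longitudinal / lateral / intradimer** — any heavy atom within
  `contact_cutoff` (default 4.5 Å, a conventional interface definition) of
  the stacked dimers, the side-protofilament dimers, or the partner chain
  of the central dimer. Neighbors are rebuilt from the lattice spec: one
  longitudinal rigid transform (applied forward and inverted) and two
  lateral transforms; a transform that leaves >10 % of atoms within 1 Å of
  the central dimer is rejected as a degenerate lattice. Seam geometry and
  protofilament curvature are not modeled.
- **MAP binding / lumen** — exposed residues (relative exposure ≥
  `burial_threshold`, default 0.15) facing outward / inward: the mean
  side-chain radial coordinate above / below the chain's median radial
  coordinate. Treating the whole exposed outer surface as the MAP-binding
  region is a deliberate operationalization — no curated per-MAP footprint
  is used.
- **other** — the fall-through for buried, non-interface, non-pocket
  residues; it is the only label that requires no evidence entry.

Precedence resolves multiple memberships: GTP binding > longitudinal >
lateral > intradimer > surface classes > other. The GTP-first rule is part
of the classification scheme itself; the rest of the order puts specific
binding pockets and interfaces above generic surface classes and is
configurable (`DomainRules.precedence`), with the evidence trace making any
alternative order auditable after the fact.

Relative exposure defaults to a contact-number approximation: heavy atoms
within 10 Å of the residue centroid, counted over the full five-dimer
assembly (so lattice neighbors occlude interface surfaces), normalized by
the 95th percentile of the counts and inverted. An alternative
rolling-probe route (`exposure_method="sasa"`, via biotite, normalized by
Tien et al. theoretical maxima) suits real side-chain geometry; the
contact-number method is scale-free and is the one exercised by the toy
tests. Because contact cutoffs, burial criterion and lateral transforms are
explicit modeling choices here, per-residue agreement with any particular
published hand classification is not claimed; the partition is validated
against planted ground truth instead (below).

Secondary structure is consumed as an annotation table (TSV: chain,
resnum, ss3), never computed; a DSSP-style reduction (H,G,I→helix;
E,B→sheet; rest→loop) adapts eight-state input. Author residue numbering,
1-based per chain, matches mutation nomenclature such as R402C. Altlocs
keep the highest-occupancy conformer; hydrogens are dropped; insertion
codes are a hard error (tubulin structures do not use them).

## Substitution classes

The four side-chain-change categories are not mutually exclusive (except
`no_change`, which excludes the rest):

- `charge_loss_or_swap`: wild type charged, mutant neutral or opposite;
- `charge_gain`: wild type neutral, mutant charged;
- `hydrophobicity_change`: exactly one of the two is hydrophobic;
- `no_change`: none of the above.

Conventions, all configurable and echoed in output headers: charged =
{D, E negative; K, R positive}; histidine neutral by default (side-chain
pKa ≈ 6) with a `histidine_positive` toggle; hydrophobic = positive
Kyte–Doolittle hydropathy, i.e. {A, C, F, I, L, M, V}. The classifier is
checked exhaustively against an independently written per-pair oracle over
all 380 ordered pairs.

## Synthetic data: what it emulates and what it does not

`make_toy_lattice` builds a pseudo-heterodimer whose residues are 5-atom
motifs (a centroid plus four tetrahedral satellites at 0.9 Å) on a
cylindrical grid: 3 radial shells (luminal / core / outer, 6 Å apart,
cylinder radius 50 Å), 6 angular columns per protofilament wedge
(twist 360/13°), 5 z-levels per monomer (rise 25 Å), two stacked monomers
per dimer, positions jittered uniformly by ±0.15 Å per coordinate. One
pseudo-nucleotide per chain sits at the midpoint of a planted core-shell
residue pair (N-site on α, E-site on β; the generated lattice spec carries
a 3.2 Å ligand cutoff matched to that pocket geometry). Every residue
carries a construction-time domain label assigned by the same precedence
the classifier uses, plus its distance to the nearest planted category
boundary. The spacings were chosen once so that every planted
contact/no-contact and buried/exposed decision clears its cutoff with
margin even at worst-case jitter; on 20 seeds the geometric partition
recovers 100 % of planted labels.

`make_variant_table` draws variant positions per phenotype with weight
`fold` on the target (phenotype, category) cell and weight 1 elsewhere, so
`fold = 1` is exactly the composition-proportional null; mutant residues
are uniform over the 19 alternatives. Default phenotype marginals are 30
per clinical label; the paper-scale design (119 records of which 53 carry
clinical labels) is one parameter choice away. `run_simulation_study`
chains generator and scan over replicates and reports per-cell rejection
rates and the fraction of replicates in which the planted cell attains the
scan's minimum p.

The toys make no claim of structural realism: no real side chains, no
sequence homology, no seam, no curvature, no B-factors or missing density.
Passing tests therefore demonstrate the correctness of the geometric rules
and the statistics on unambiguous input, not robustness to crystallographic
artifacts of real structures.

## Numerical and calibration notes

- χ² tail probabilities and quantiles come from the regularized
  incomplete-gamma implementation (scipy); they match the even-df closed
  series exp(−x/2)·Σ_{i<df/2}(x/2)^i/i! to ≤1e-12 and round to the
  familiar anchors (p = 0.55 at 1.202/df 2; p = 0.52 at 5.177/df 6;
  critical values 5.99 and 12.59 at α = 0.05).
- The exact Fisher test is conservative on discrete 2×2 tables: its
  achieved size is at most, and typically well below, the nominal α. With
  ~20–30 variants per phenotype and category fractions between 0.02 and
  0.27, measured per-cell type-I rates at α = 0.05 fall around 0.003–0.023
  rather than 0.05. This is a property of exact conditional tests at small
  expected counts, not an implementation artifact; power against planted
  10-fold enrichment (n = 20 per phenotype) remains high — the planted
  cell attains the scan's minimum p in >95 % of replicates and its
  rejection rate is monotone in fold.
- Simulation sizes used by the reproduction script (5 recovery seeds, 400
  null replicates, 200 power replicates) were chosen as the smallest runs
  whose Monte-Carlo error is negligible relative to the effects reported;
  the test suite runs the larger designs (20 seeds, 2000/500 replicates).
- Determinism: every generator takes an explicit seed and produces
  byte-identical files on repeated calls; derived per-replicate seeds stay
  below 2³¹.

## Known limitations

- The per-variant phenotype label is taken as given; no re-adjudication of
  clinical literature, no severity scoring, no pathogenicity prediction.
- Only single-residue missense variants on the α chain are analyzed.
- The lattice model ignores the seam, protofilament curvature and
  nucleotide-state-dependent compaction; lateral neighbors are the union of
  two transforms.
- Published per-category variant counts for TUBA1A exist only as figure
  bars, so the pipeline's outputs on real data are validated structurally
  (anchors, oracles, planted truth) rather than against a published
  per-residue table.
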