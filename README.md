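# pocketphylo

Sequence–structure–function analysis for protein domain families:
neighbor-joining phylogeny, probe-based catalytic-pocket geometry,
cavity-lining-residue (CLR) consensus calling, and positional conservation
grading — wired together into one reproducible pipeline with fully
synthetic, ground-truth-labelled test data.

The package is aimed at structural bioinformaticians studying enzyme
families in which the shape and size of a catalytic pocket track the
family's functional divergence. The motivating use case is the product
template (PT) domain family of fungal non-reducing polyketide synthases,
where phylogenetic groups differ in first-ring cyclization regioselectivity
(C2–C7, C4–C9, C6–C11), and those functional groups differ measurably in
cavity volume, pocket depth, and which residues line the pocket. The same
machinery applies to any domain family with per-protein structure-model
ensembles and a master alignment.

## What it computes

1. **Phylogeny** — pairwise p-distances under pairwise or complete gap
   deletion, the Poisson correction `d = −ln(1 − p)` (substitutions/site),
   Saitou–Nei neighbor joining with deterministic tie-breaking, bootstrap
   bipartition supports, and seed-anchored assignment of leaves to groups
   via maximal clades on the midpoint-rooted tree.
2. **Pocket geometry** — a grid-based two-probe method (LIGSITE/POCASA
   family): a voxel is blocked for a probe of radius *p* when its centre is
   within vdW + *p* of an atom; pockets are the regions a small probe
   (1.4 Å, water) can occupy but a large closure probe (default 4.0 Å)
   cannot reach by rolling in from outside. Each pocket carries a volume
   (voxel count × h³), a mouth, a geodesic depth, and its lining residues.
3. **CLR consensus** — per protein, residues lining the catalytic pocket in
   ≥ 2 of 3 structure models; per group, master-alignment columns hit by
   ≥ 2 of 3 member proteins; then columns common to all groups and columns
   specific to exactly one group.
4. **Conservation** — Henikoff-weighted entropy scores per column,
   `score = (1 − H_w/ln 20)(1 − gap_fraction)`, binned into nine
   equal-frequency grades (9 = most conserved); conserved fractions
   (grade ≥ 7) for the whole alignment, all CLR columns, and the common
   CLR columns.
5. **Statistics** — Pearson correlation between per-group CLR counts and
   mean cavity volumes (t-based two-sided p, optional permutation p), and a
   JSON/TSV report bundle.

The synthetic-data module generates every input with planted truth:
pseudo-atom shells with cavities of analytic volume and depth, jittered
three-model ensembles, sequence families evolved on known trees under a
20-state Poisson model with per-site rates, and a complete seven-group
study whose planted CLR architecture (27 common columns, 11 and 8
group-specific columns, per-group totals between 31 and 45) and monotone
cavity-volume ladder mirror the scale of a published PT-domain analysis.

## Worked example

Generate the default synthetic study and run the whole pipeline:

```sh
pocketphylo synth --out study --seed 1
pocketphylo run study/config.yaml --out study_out
```

which prints

```
study written; config at study/config.yaml
done: 7 groups, 27 common CLR columns, r=0.976 (p=0.00016)
```

`study_out/report.json` then contains, among other things: per-group CLR
counts of 31, 34, 36, 44, 45, 33 and 41 (groups I–VII); 27 CLR columns
common to all seven groups; 11 columns specific to group IV and 8 to group
V; a CLR-count/cavity-volume Pearson r of 0.976 (n = 7 groups, p < 0.01);
and conserved fractions (grade 7–9) of 33.3 % over the whole 240-column
alignment, 82.8 % over the 64 distinct CLR columns, and 92.6 % (25 of 27)
over the common CLR columns. Those numbers are exactly the planted design
of the generator, recovered by measurement: large-cavity groups carry more
CLRs, and pocket-lining columns are strongly enriched in conserved
positions relative to the ~1/3 background that equal-frequency grading
fixes by construction.

Individual stages are available as `pocketphylo phylo`, `pocket`,
`conserve`, `clr` and `report`; see `--help` for flags (probe radii, grid
spacing, bootstrap replicates, anchor residues such as `"A:1345,A:1543"`
for dyad-anchored pocket selection).

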