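# Methods

This note documents the models and procedures implemented in pocketphylo,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic generators do and do not emulate.

## Distances and trees

p-distances are computed over aligned columns; under the default
**pairwise deletion** policy a column is skipped for a pair when either row
has a gap there (complete deletion, which drops any column containing a
gap, is available as a config option). The **Poisson correction**
`d = −ln(1 − p)` converts a p-distance into an expected number of amino
acid substitutions per site under a Poisson substitution process with
equal rates across residues; it diverges as p → 1, so p ≥ 1 − ε
(ε = 1e−9 by default) raises a saturation error rather than returning an
arbitrary large value.

**Neighbor joining** follows Saitou–Nei: at each step the pair minimising
Q(i,j) = (m−2)·d(i,j) − r(i) − r(j) is joined. Two choices are fixed for
reproducibility: labels are sorted alphabetically on entry and Q-ties
(absolute tolerance 1e−12) are broken by the smallest (i,j) index pair, so
permuting the input rows yields an isomorphic tree; and negative
branch-length estimates are clamped to zero without redistributing the
deficit, a common convention in distance-tree software. The result is an
unrooted tree represented with a trifurcating seed node.

**Bootstrap supports** resample alignment columns with replacement; the
support of a bipartition is the fraction of replicate NJ trees containing
it, attached to the NJ tree of the original alignment. One integer seed
drives all replicates.

**Group assignment** anchors each group with one or more seed leaves. The
tree is midpoint-rooted first; the implementation places the root on an
edge of the longest leaf-to-leaf path even when the midpoint coincides
with an internal node (node-snapping implementations produce a
trifurcating root there, which silently destroys the clade the caller is
asking about). Each group then claims the largest clade that contains all
of its seeds and none of any other group's; leaves outside every claimed
clade are reported as `unassigned`, mirroring the common situation where a
family tree carries a few sequences that belong to no recognised group.

The **progressive aligner** (UPGMA guide tree on Needleman–Wunsch
identities; profile–profile NW merges with affine gaps, match +1 /
mismatch −1 / gap open and extend −2 by default) exists to align synthetic
families only. Real alignments should be produced with a dedicated MSA
tool and loaded via `read_alignment`.

## Pocket detection

The detector is a grid-based two-probe method in the LIGSITE/POCASA
family, not an alpha-shape method: **absolute volumes are not comparable
with alpha-shape tools (e.g. CASTp); only relative comparisons between
structures analysed with the same parameters are meaningful.** All
pipeline statistics are of that relative kind.

Given grid spacing h (default 0.6 Å), a voxel is *blocked* for probe
radius p when its centre lies within vdW(element) + p of any atom centre
(vdW: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, default 1.70 Å;
hydrogens are used when present). The small probe is 1.4 Å (water). The
**closure** works by rolling: the large-probe exterior (probe-centre
positions flood-connected to the grid boundary) is dilated by
`probe_large − probe_small`, giving the region the small probe can reach
when carried in by the large probe; pocket candidates are small-probe-free
voxels outside that region. This construction makes a solid convex body
yield no pockets (a naive "complement of the large-probe exterior" leaves
a spurious surface skin of thickness `probe_large − probe_small` over
every exposed face).

Two discretisation details matter in practice. The large-probe exterior is
flooded with 26-connectivity, because its narrow dips over pocket mouths
are often only diagonally voxel-connected; and the dilation radius carries
a half-voxel correction (+h·√3/2) compensating the centre-sampling of the
exterior. Without both, mouth voxels systematically sit ~1–2 Å above the
physical rim of a narrow channel. Pocket components themselves use
6-connectivity (avoiding diagonal leaks through thin walls), and
components below `min_volume` (25 ų) are discarded as grid noise.

`probe_large` (default 4.0 Å) sets the closure scale: it bounds the mouth
aperture a pocket may have. This is a physical property of probe-based
closure, not an implementation detail — a 4 Å probe rolls straight into a
wide hemispherical dimple, so wide shallow concavities require a larger
closure probe (the dimple oracle in the tests uses 8 Å). The parameter is
exposed everywhere.

**Depth** is geodesic within the pocket, in Å: for an open pocket, the
maximum over voxels of the 26-connected Euclidean-cost distance to the
nearest mouth voxel (mouth = pocket voxels adjacent to the accessible
exterior); for an enclosed cavity, half the maximum geodesic diameter,
estimated by iterated farthest-point sweeps (exact on convex regions,
a standard double-sweep approximation otherwise). A cylindrical bore of
length L reports depth ≈ L; a hemispherical dimple of radius r reports
depth ≈ r.

**Lining residues** are those with ≥ 1 atom centre within
vdW + probe_small + h of a pocket voxel centre. The catalytic pocket of a
model is selected either as the largest pocket or, when anchor residues
are configured (e.g. a known His/Asp catalytic dyad), as the largest
pocket whose lining contains all anchors — anchoring is strongly
recommended because surface clefts can outsize the catalytic cavity.

## CLR consensus and mapping

Structure→sequence mapping aligns the model's extracted one-letter
sequence to the protein sequence globally (match +1 / mismatch −1 /
gap −2) and maps only aligned positions; identity below 0.9 over aligned
positions is an error (the model does not correspond to the sequence).
This handles models numbered in full-protein coordinates (e.g. a domain
numbered 1345–1724) as a constant-offset mapping.

Both consensus rules are majority votes phrased for ensembles of three:
per protein, sites lining the pocket in ≥ 2 of 3 models; per group,
master-MSA columns contributed by ≥ 2 of 3 member proteins. The
exactly-three cardinality is enforced by default (`allow_any_n=True`
generalises to ceil(2n/3)). A consensus site whose alignment position is
gapped for some other protein simply contributes nothing for that protein.
Groups represented by a single sequence should be left out of group-level
CLR statistics (the pipeline computes statistics over the groups given in
its config, so such a group is excluded by not listing it).

## Conservation

The scorer is a deliberate simplification of tree-aware empirical-Bayes
rate inference (ConSurf/rate4site style): rows receive Henikoff–Henikoff
position-based weights (gap treated as a 21st symbol type), and each
column scores `(1 − H_w/ln 20)·(1 − gap_fraction)` with H_w the weighted
Shannon entropy of its amino-acid frequencies. It is a functional
analogue, not a reproduction; **grades, not raw scores, are the
interface**. Scored columns are rank-binned into nine equal-frequency
grades (grade = floor((rank−1)·9/n)+1, ascending by score; tied scores all
take the grade of the lowest rank in the tie). Equal-frequency binning
pins the whole-alignment background of grades 7–9 at ~1/3 of scored
columns by construction, which is the right yardstick for enrichment
statements of the form "CLR columns are conserved far above background".
Columns with (weighted) gap fraction > 0.5 are unscored and excluded from
all fractions.

## Statistics

The CLR-count/volume association is a plain Pearson correlation over
groups (x = CLR count, y = mean over member proteins of the three-model
mean volume), with the two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. With as few as seven
groups that p rests heavily on normality, so a permutation p-value is
available (`permutation=True`). Zero variance in either variable and
n < 3 are errors, not NaNs. The report bundle (pydantic model, JSON plus
TSVs) records the seed, package version and a config hash; reruns with the
same config and seed are identical except for the timestamp.

## Synthetic data: what it emulates, and what it does not

Structures are shells of pseudo-atoms (element C, one atom per shell
point) analysed with an inflated 2.5 Å van der Waals radius so that a
single-layer wall is probe-tight at the default spacing. Wall atoms sit at
cavity radius + vdW + probe_small, so the free cavity has the requested
analytic radius; an outer layer 2.2 Å further out carries the non-lining
residues, far enough that they can never appear in the cavity lining. Wall
points are assigned round-robin to the designated lining residue
positions (~5–15 atoms per residue), which makes lining recovery robust to
the coordinate jitter. Model ensembles add iid Gaussian noise
(σ = 0.3 Å per coordinate, RMSD ≈ σ√3) to emulate disagreement between
independent homology models.

Sequence families evolve along a known tree under a 20-state Poisson
model: over a branch b, a site of rate r differs from its parent with
probability (19/20)(1 − e^{−(20/19)·r·b}). Rate-0 sites are invariant —
the planted conserved columns. An optional deletion-only indel mode
(geometric lengths) exists solely to exercise the aligner; the default has
no indels so the true alignment is the identity and planted residue
positions equal master-alignment columns.

The default study (`make_study`) is the package's standing test bed:
7 groups × 3 proteins × 3 jittered models of 240-residue proteins;
enclosed spherical cavities with radii 4.0–5.7 Å giving a monotone volume
ladder (I < II < VI < III < VII < IV < V); a planted CLR architecture of
27 common columns, 11 columns specific to group IV, 8 to group V, and 18
columns shared by intermediate subsets, for 64 distinct CLR columns and
per-group totals of 31/34/36/44/45/33/41; 53 planted invariant columns
(25 of the 27 common ones plus 28 other CLR columns) on a 240-column
alignment, placing the invariant block inside the grade-8 rank band;
tree branch lengths 0.05 within groups, 0.2 stems, 0.15 internal, with
variable sites at rate 1.5 so that chance invariance of a variable column
is rare (~e^{−5} per column). These defaults are the study conditions for
the whole test suite and the acceptance script; the first two planted
lining positions of each protein serve as its anchor residues, playing the
role of a catalytic dyad.

What passing on these data does **not** show: the generators use isotropic
jitter and idealised shell geometry, so they say nothing about homology-
model error modes (register shifts, mis-threaded loops, missing side
chains), about alpha-shape-comparable absolute volumes, or about MSA
quality on real families; and the entropy scorer has no phylogenetic
correction beyond sequence weighting, so on real data its grades can
differ from rate-based methods at sites with strong clade structure.

## Problem sizes and determinism

The shipped tests and the acceptance script use: geometry oracles at
h = 0.5/0.3 Å (sphere) and 0.6 Å (channel, dimple); 100 additive-matrix
trees of 6–10 leaves; 100 simulated 10-leaf/500-site families; 500 random
instances per voting oracle; the full default study once; and one
200-sequence/300-site family for conservation recovery. Every stochastic
step draws from a single integer seed; reruns are bit-reproducible.
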