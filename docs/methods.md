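# Methods

This note documents the models, parameters and numerical choices behind
`mutexbind`, and what the synthetic studies do and do not establish.

## Problem and model

Given a PPI map and per-protein chain structures, the package asks, for
every hub protein with at least three structure-mapped interactors:
*which of those interactors bind the hub mutually exclusively?* The
working hypothesis is structural: interactors competing for one hub
region tend to present a similar local surface substructure — a set of
three or more solvent-exposed residues, not necessarily contiguous in
sequence, that superpose well and are biochemically similar. The
pipeline therefore searches for such shared substructures among the
hub's interactors, clusters the chains that share one, and ranks the
clusters.

## Surface definition

Solvent accessible surface area is computed with the Shrake–Rupley
method: each heavy atom carries a deterministic golden-spiral lattice of
960 points on its solvent-expanded sphere (probe 1.4 Å; van der Waals
radii C 1.70, N 1.55, O 1.52, S 1.80, Se 1.90 Å), and a point is
accessible when outside every other expanded sphere. Two numerical
choices matter:

* **Frame canonicalisation.** The lattice is oriented in the chain's
  principal-axes frame (eigenvectors of the coordinate covariance,
  eigenvalue-ordered, sign-fixed on the largest component). This makes
  the computed ASA exactly invariant under rigid motion of the chain —
  with a lab-fixed lattice, 960-point quantisation noise of order 1–2 Å²
  per residue would appear under rotation. The frame is always derived
  from the chain's own atoms, so occluders added for interface analysis
  do not perturb it. Exactly symmetric point sets (degenerate principal
  axes) would fall back to an arbitrary but deterministic frame; real
  and generated chains are never symmetric.
* **Accuracy contract.** Per-residue ASA agrees with a 10×-denser
  independent brute-force evaluation to 2 % (with a 0.5 Å² absolute
  floor where the reference area is near zero, since point quantisation
  makes relative error meaningless there). This is tested on 20
  generated peptides.

**Relative accessibility** divides a residue's ASA on the isolated chain
by the ASA of the same residue type as the central residue of an
extended Ala-X-Ala tripeptide, built with this package's own geometry
and SASA code and frozen into `data/axa_reference.json`. Residues with
relative accessibility strictly above 0.5 form the surface set. Because
the reference is generated from the same reduced residue representation
the toy chains use (see below), surface calls on toy chains are
internally consistent; for real full-atom PDB chains the reduced
reference makes relative accessibility approximate (typically inflated),
which shifts the effective surface cutoff but preserves its ordering.

## Pairwise surface matching

A match between chains A and B is a one-to-one set of ≥ 3 surface
residue pairs such that

* every pair has non-negative PAM250 score (candidate admission);
* every two pairs are spatial neighbours (Cα–Cα ≤ 10 Å on **both**
  chains — applying the cutoff to both sides keeps `match(A,B)` and
  `match(B,A)` exactly symmetric) with compatible internal distances:
  the Cα–Cα and side-chain-centroid distances may disagree by at most
  the **distance tolerance** (2.5 Å, below);
* the 2k pseudo-atoms (Cα and side-chain centroid of every paired
  residue) superpose with **RMSD < 2.1 Å** (Kabsch, joint over both
  pseudo-atom types);
* the mean PAM250 score over the pairs is **≥ 1.2**. The 1.2 threshold
  is fractional while PAM250 entries are integers; it is interpreted as
  a threshold on the match mean. A stricter per-pair alternative
  (every pair ≥ 2) is available as `MatchParams(per_pair_pam=True)`.

Search: candidate pairs form a product graph whose edges encode the
pairwise constraints; maximal cliques (networkx, capped at 12 vertices —
reported motifs are small) are evaluated largest-first, and a clique
failing RMSD or mean-PAM acceptance is explored by memoised subset
descent with accepted-superset pruning. Accepted matches that are
subsets of other accepted matches are discarded. Because every subset
of a clique is reachable by the descent, the accepted set equals an
exhaustive search over all pairwise-compatible pair sets; this
equivalence is asserted against an independent brute-force oracle on 100
seeded instances with ≤ 7 surface residues per chain.

**Distance tolerance (2.5 Å).** The distance-compatibility gate is a
pruning pre-filter, not the discriminative criterion — discrimination is
the 2.1 Å RMSD ceiling. The tolerance is therefore sized to pass true
correspondences under the noise the matcher is designed to absorb:
between two independently noised copies of a motif (iid coordinate noise
σ per atom), internal-distance differences are approximately normal with
sd 2σ, i.e. 0.6 Å at the design level σ = 0.3 Å. The tolerance is set
to ≈ 4 sd (2.5 Å) so that a planted clique survives with high
probability; a 1 Å gate (≈ 1.7 sd) would reject at least one true edge
in most replicates at that noise level. The measured consequence:
planted-correspondence recovery is 50/50 at σ ∈ {0, 0.1, 0.2, 0.3} Å and
0/50 at σ = 10 Å.

## Clustering and the group similarity

Matches are vertices of a cluster graph; two matches are linked when
they share a chain and overlap in ≥ 3 residues on that chain. Within
each connected component touching ≥ 3 chains, a consensus is built:

1. only the best match per chain pair (largest, then lowest RMSD)
   contributes residue correspondences;
2. residues linked transitively form equivalence classes; a class is
   kept only while it holds at most one residue per chain (conflicting
   classes are discarded, not guessed at);
3. every **maximal chain subset supported by ≥ 3 classes** becomes one
   cluster, with the classes restricted to it as the aligned motif
   positions (the *group similarity*).

Step 3 is the load-bearing design choice: chance 3-residue matches are
common between small surfaces at the published thresholds (the original
evaluation found clusters in the vast majority of sub-networks), so one
component can span chains that do not all share a motif. Requiring the
consensus to cover the whole component would then discard everything;
extracting maximal supported subsets instead yields one clean cluster
per actual motif. Subset enumeration is exhaustive over the component's
chains, which is cheap because components span few chains.

`score = n_residues × n_chains` is the cluster's significance score.
Ranking is by score descending, then conservation (sum over motif
positions of the mean pairwise BLOSUM30 score), then mean pairwise
GDT_TS of the motif pseudo-atoms, then cluster id; `rank_clusters(...,
key="conservation")` swaps conservation ahead of the score for users who
prefer the re-sorted view. The exact combination rule is a design
choice; the score-primary ordering is the default because the score is
the stated primary ranking key of the approach this re-implements.

## Superposition and GDT_TS

Kabsch superposition uses SVD with reflection correction (det = +1
always, chirality preserved, collinear degeneracies handled). GDT_TS is
the mean over 1/2/4/8 Å cutoffs of the best fraction of point pairs
within the cutoff under some superposition. The search is seeded and
iterative: superpose on a seed subset, keep pairs within the cutoff,
re-superpose on the kept set until a fixed point, recording the best
fraction at every stage. For k ≤ 6 points every ≥ 3-subset is a seed,
which makes the search provably exhaustive (every subset the brute-force
oracle can superpose on is visited); for larger k the seeds are all
contiguous triples plus the full set, a heuristic in the spirit of the
standard iterative-superposition implementations. Exactness is
guaranteed — and tested — only at k ≤ 6.

## Ground truth and confusion counting

Two interactors are truly mutually exclusive when their hub-side
interfaces overlap. Interface residues are defined by ΔASA: a residue is
interfacial when its ASA on the isolated chain exceeds its ASA in the
two-chain complex by > 0.1 Å² (the threshold is explicit and
configurable; any buried area counts). Nodes whose hub interfaces
overlap in ≥ 1 hub residue are linked, and connected components form the
exclusivity groups; nodes without a solved complex are flagged unknown
and excluded from counting by default.

A predicted cluster is scored against the group it overlaps most (ties:
larger group, then lexicographically smallest member): TP = cluster ∩
group, FP = cluster \ group, FN = group \ cluster, TN = remaining nodes,
so TP+FP+TN+FN always equals the sub-network size. Summary statistics
(specificity, sensitivity, PPV, NPV, accuracy) are computed either
pooled (sum counts, then apply formulas — the default, consistent with
the reference evaluation's printed table) or macro (per-cluster values
averaged, skipping records with zero denominators). Interface recovery
reports both the ≥ 1-residue and ≥ 3-residue correctness conventions,
since both appear in practice.

## Synthetic data: what it emulates, what it does not

Toy chains are reduced-representation: a Cα trace on an ideal scaffold
(helix: 1.5 Å rise, 100°/residue; strand: 3.3 Å rise zigzag; coil:
seeded self-avoiding walk with 3.8 Å steps) plus 0–3 side-chain
pseudo-atoms per residue graded by side-chain size (Gly 0 … Trp 3),
stacked outward from the chain body. This is sufficient for everything
the pipeline consumes — Cα, side-chain centroid, and heavy-atom spheres
for SASA — and keeps fixtures fast and fully deterministic (identical
seeds give byte-identical PDB output).

`plant_motif` grafts a rigid motif (rotated per chain, seeded) onto a
window of surface residues, pushing it outward until it clears the
scaffold **and** every planted residue is solvent-exposed at the 0.5
cutoff, then adds iid Gaussian coordinate noise. The planted positions
are returned as the matcher's ground truth. Default motifs are rings
with a rising z-spiral: the asymmetry makes the zero-noise
self-correspondence unique (a flat symmetric ring admits rotated
zero-RMSD alternatives that scramble cross-pair consensus).

`make_two_group_subnetwork` builds the zero-noise perfect-recovery
study: two groups of three chains, each sharing its own motif, designed
to be chemically orthogonal — scaffold compositions rotate through
{Trp, Cys, Pro} (mutually negative PAM250) and the motif alphabets
(hydrophobic ILVM vs polar DEQND) score negatively against each other
and against every scaffold. No residue pair outside a shared motif can
seed a match, so a correct detector reports exactly the two groups.

What passing these studies shows: the search is exhaustive at small
scale, the planted signal is recovered whenever it is geometrically
recoverable, and the confusion arithmetic is exact. What it does not
show: performance on real structures — real surfaces have full side
chains, flexible conformations, and homologous (not identical) motifs,
and real negatives are not chemically orthogonal. On random-sequence toy
fixtures the matcher does find chance 3-residue similarities at the
published thresholds; that mirrors the behaviour of the original method
(which detects candidate clusters in most real sub-networks and relies
on validation for specificity) and is why the zero-noise study controls
composition explicitly.

`make_toy_complex` docks a node chain rigidly against a chosen hub
surface patch (seeded orientation, minimum interatomic distance within
3.5–4.5 Å, so contact without clash is guaranteed by construction) and
records the intended contact patch as the interface oracle.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `rmsd_max` | 2.1 | Å | acceptance ceiling, joint pseudo-atom RMSD |
| `pam_min` | 1.2 | — | minimum mean PAM250 of a match |
| `min_residues` | 3 | — | smallest match / motif |
| `min_chains` | 3 | — | smallest cluster |
| `neighbor_cutoff` | 10.0 | Å | Cα spatial-neighbourhood radius |
| `distance_tolerance` | 2.5 | Å | product-graph pre-filter (≈ 4 sd at σ = 0.3) |
| `clique_cap` | 12 | — | largest clique explored |
| exposure cutoff | 0.5 | — | relative accessibility defining surface |
| probe radius | 1.4 | Å | solvent probe |
| sphere points | 960 | — | SASA lattice density |
| redundancy threshold | 30 | % identity | node de-duplication |
| `dasa_min` | 0.1 | Å² | buried area defining an interface residue |

Sequence identity uses Biopython global alignment (match +1, mismatch 0,
gap open −10, extend −0.5) with the identity percentage over the shorter
sequence; `X` never counts as identical. Redundancy filtering is greedy
by descending sequence length (ties: lexicographic id), keeping a node
iff its identity to every kept node is ≤ 30 %.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on generated fixtures:
chains of 6–24 residues, motifs of 3–5 residues, sub-networks of 3–6
chains, 50-replicate noise sweeps, 100-instance oracle equivalence, and
a 10⁵-draw random-rotation baseline for the superposition. These sizes
keep every oracle exhaustive (the point of the contract) while the full
suite completes in well under a minute of compute per module.

## Known limitations

* Real-structure relative accessibility is approximate against the
  reduced-representation reference table (see Surface definition).
* The GDT_TS heuristic is exact only for k ≤ 6 motif positions; larger
  motifs get a lower bound.
* The clique cap (12) truncates pathological self-similarity (e.g. a
  chain matched against an identical copy); configurable.
* No steric-hindrance reasoning: interactors flagged non-exclusive may
  still compete sterically.
* mmCIF input, hydrogen placement and B-factor filtering are out of
  scope; PDB format only.
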