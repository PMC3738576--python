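# Methods

This note records the models behind each `zfp` stage, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not establish about real data.

## Zinc-finger spacing grammars

A zinc finger is modelled as an ordered list of ligand residue classes with
per-adjacent-pair bounds on the number of residues strictly between them
(`ZnPattern`).  Coordinates are 1-based and inclusive, matching residue-
counting conventions in the domain literature.

* **RING-H2 (family form).**  Ligands C,C,C,H,H,C,C,C with gaps
  (2, g2, 1, 2, 2, g6, 2), g2 ∈ [14, 34] and g6 ∈ [10, 11].  g2 = 14 with
  g6 = 10 is canonical for the family; g2 = 15 is the ATL-like spacing (the
  family's hallmark is being one residue shorter there than the ATL
  consensus); anything else is an insertion variant.  The g2 upper bound 34
  admits the largest observed insertion (20 residues); g6 = 11 admits the
  single-residue insertion seen between the sixth and seventh ligands.
  Exact-gap variant rules are evaluated before range rules.
* **BZF (C2/C2).**  Ligands C,C,C,C with gaps (2, d, 2).  The inter-pair
  distance d is measured strictly between the second and third cysteines;
  with the family's flank blocks this equals the variable spacer plus 8,
  which maps the spacer range x(3,12) onto d ∈ [11, 19], the canonical band.
  Default scan bounds are d ∈ [6, 26], the full observed range (a lancelet
  ortholog at 6; serine-track eudicot members up to 26).  The family
  description also cites a 30–42 total length for this region, which is
  inconsistent with its printed flank arithmetic (14 + 13 + 3..12 = 30–39);
  the grammar follows the flanks+spacer arithmetic.

The scanner enumerates every ligand placement satisfying the grammar
(depth-first over candidate ligand positions; `X` is tolerated in gaps but
never matches a ligand class, so draft-genome translations degrade softly).
Overlapping placements are resolved greedily by (score desc, start asc, gap
sum asc, positions); without a rescoring hook all scores are 0, so the
leftmost, most compact placement wins deterministically.  The test suite
holds the scanner equal to an independent exhaustive-enumeration oracle on
1000 random sequences, including C/H-enriched ones where placements overlap
heavily.

Profile-HMM retrieval is intentionally out of scope: the spacing grammar
(plus optional PSPM rescoring) is the content this package defines.

## Region decomposition

Regions are pure interval arithmetic on the two finger spans: I = [1,
bzf.start−1], II = bzf span, III = [bzf.end+1, ring.start−1], IV = ring
span, V = [ring.end+1, length]; empty intervals are recorded as empty, and
the invariant that non-empty regions tile [1, length] exactly is asserted
in tests.  A protein without a RING-H2 is rejected as a non-member; without
a BZF the pre-RING segment is carried as region III ("upstream") so motif
mapping still works.  Motif occurrences are assigned to the region
containing their midpoint — with integer midpoints ties are impossible and
the rule is deterministic.

## Motif discovery (ZOOPS EM) and the PSPM catalog

Motifs are position-specific probability matrices (width 10–50 over the
20-letter alphabet) with uniform background by default.  Discovery fits the
ZOOPS site model by EM:

* E step: posterior over "no site" and every window offset, with prior site
  probability γ shared across sequences and a uniform prior over offsets.
* M step: matrix MAP update with symmetric pseudocount 0.01 per cell
  (a Dirichlet(1.01) prior), γ by maximum likelihood.

The tracked objective is the observed-data log-likelihood relative to the
all-background model plus the Dirichlet log-prior; MAP-EM makes it
monotonically non-decreasing, which the tests assert per iteration.
Convergence is |Δobjective| < 1e-4 or 200 iterations; 10 restarts per width
seeded from corpus substrings (0.6 on the observed letter).  After the best
restart, the alignment is probed with ±1..2 column-shift moves, iterated to
a fixed point — EM otherwise phase-locks a few columns off the planted
optimum in a substantial fraction of corpora.

Width search is a coarse grid (multiples of 5 within the requested range)
followed by ±2 refinement around the best width.  Widths and final
acceptance are ranked by a BIC-adjusted expected log-likelihood ratio,
E[LLR] − ½·19w·ln(n_sites) nats.  An accepted motif needs that quantity
positive, at least 3 sites, and mean per-column information content of at
least 0.5 bits (IC is log2(20) − column entropy).  The extra significance
test exists because EM overfits featureless sequence: on a 20×100-residue
uniform-random corpus the fitted E[LLR] is ≈185 nats at width 10 — enough
to push raw mean IC well above 0.5 bits — while the BIC price is ≈257 nats,
so null corpora yield no motifs; genuinely planted motifs clear the bar by
hundreds of nats.  Exact MEME E-value statistics are a non-goal; this is
the package's replacement significance filter.

Accepted motifs' sites are masked ('X') before the next motif is sought;
masked positions contribute background likelihood and are excluded from
counts.  Redundancy between two PSPMs is the best sliding-offset mean
per-column Pearson correlation with at least 50% column overlap (of the
shorter motif); above 0.85 the lower-total-IC member is dropped, survivors
keeping input order.  Scanning reports windows whose log-odds reaches 70%
(default) of the motif's maximum attainable score, best-first among
overlapping hits of the same motif.  The catalog is serialized as MEME
minimal motif text; no logo images are rendered — the matrices and their
IC profiles are the artifact.

## Anchored alignment, distances, NJ, bootstrap, groups

Because both fingers have fixed-spacing blocks interrupted by exactly three
variable gaps (the BZF spacer and RING gaps 2 and 6), alignment needs no
optimizer: variable gaps are right-padded with '-' to the corpus maximum,
fixed blocks are copied verbatim, and the BZF block is concatenated with
the RING block.  The 12 ligand columns are anchors and are validated to
hold their C/H in every row.  Columns with more than 50% gaps are dropped
before distance computation.

Distances are p = mismatches / shared non-gap columns, Poisson-corrected as
d = −ln(1−p) with p capped at 0.95; a pair with no shared columns is an
error (in bootstrap replicates it falls back to the capped maximum rather
than aborting the replicate).  The JTT+Γ model used with optimizer-based
alignments is deliberately not implemented; the Poisson correction is the
package's stated simplification.

Neighbor joining is the standard Saitou–Nei agglomeration with two fixed
conventions: ties on the Q criterion break to the smallest (i, j) index
pair, and negative branch lengths are clamped to zero with the deficit
transferred to the sister edge (Kuhner–Felsenstein style), conserving the
joined pair's path length.  On additive matrices the implementation is
exact (topology and path lengths to 1e-9 in tests, cross-checked against
scikit-bio's independent NJ); trees are unrooted with a trifurcating root.

Bootstrap supports resample alignment columns with replacement (default 200
replicates, configurable to 1000); an internal edge's support is the
fraction of replicate NJ trees containing its bipartition.  Grouping
contracts every internal edge with support strictly below the threshold
(default 0.80), then considers, for every surviving edge, the bipartition
projected onto the ingroup (outgroup leaves removed from both sides),
oriented as the smaller projected side.  Projection matters: orienting
"away from the outgroup" would let the outgroup's attachment edge define
"everything else" as a clade, and that near-full clade would swallow the
real groups whenever a single distant outgroup attaches stably.  A
candidate clade qualifies if it contains at least one monocot and one
eudicot; groups are the maximal qualifying clades, labelled A, B, … by
decreasing size (ties by smallest member id).  Outgroup leaves and leaves
outside every group are "unclassified".  Collapsing on a single support
measure (bootstrap proportion) stands in for multi-method local support;
reconciling several support notions is out of scope.

## Gene models

GFF3 parsing (gene/mRNA/exon/CDS) goes through `gffutils`; introns are
always derived from exon gaps, never read from the file.  For multi-isoform
genes the mRNA with the longest total CDS is canonical.  Classification is
strand-aware relative to the translated span [cds_start, cds_end]: entirely
on the 5' side → `five_prime_UTR`, entirely 3' → `three_prime_UTR`,
strictly inside → `CDS`, anything else → `junction`.  For well-formed
models (CDS inside the exon union) `junction` is unreachable and the tests
assert so; it is kept as the conservative fallback and counted with CDS in
censuses.  UTR-intron summaries count each gene once per category (any/5'/
3'/both/intronless).  Tandem arrays are maximal runs of family genes on one
scaffold with at most `max_gap` (default 1) intervening non-family genes
between consecutive members — a formalization of the by-eye locus-adjacency
criterion.  A packaged reference table (`zfp/data/table2.tsv`) transcribes
the A. thaliana / O. sativa family UTR-intron census used as a fixture; its
multi-valued length fields are encoded as multiple introns, which leaves
the presence/absence summary counts unaffected.

## Synthetic data generator

`SimConfig` defaults define the study conditions:

* 3 monocot + 3 eudicot species, 6 groups, one gene per species per group,
  plus one chlorophyte outgroup species (39 proteins in total with the two
  planted tandem duplicates).
* BZF spacer: 97% uniform on [11, 19], 3% spread over [6,10] ∪ [20,26].
* RING variants: 90% canonical (g2=14), 5% ATL-like (g2=15), 5% insertion
  (g2 ∈ [16, 34]).
* Two-level evolution: a family ancestor's domain-gap templates diverge
  into group templates (per-site substitution 0.5; outgroup 0.7), and group
  members then mutate at per-site probability 0.05.  Ligand positions are
  never touched.  Group radiation is a star: no planted signal links one
  group to another, which is what makes "six maximal mixed clades" the
  correct answer for the grouping stage.
* Region III carries one group-specific 15-mer motif and two universal
  12-mers adjacent to the RING; region V carries a group 15-mer.  Motif
  instances mutate at 0.05 per position.
* Gene plans: groups 1–2 carry a 5'UTR intron with probability 0.9, groups
  3 and 5 are intronless, group 4 mixes 5' (0.5) and 3' (0.4) UTR introns,
  group 6 favours 3'UTR introns (0.6); the outgroup gene keeps one CDS
  intron.  Family loci are separated by 2–4 non-family filler genes so only
  the planted duplicates are tandem-adjacent.

Backgrounds, motif consensuses, gap fillers and substitution proposals all
exclude C and H (sampled from a renormalized average proteome
composition).  This is stronger than strictly necessary but makes planted-
domain truth provably unique: the inter-finger region always exceeds 34
residues (the widest legal RING gap), so no alternative grammar-legal
ligand placement can exist, and scanner recall against the truth table is
exactly 100% by construction rather than approximately.

What passing tests therefore show: the pipeline's machinery — scanning,
decomposition, EM, NJ/bootstrap/collapse, intron logic — is correct on data
whose generative structure matches its assumptions.  What they do not show:
robustness to indels inside domains, ligand loss, codon-level evolutionary
models, alignment ambiguity, fragmented gene models, or motif architectures
richer than one occurrence per region — real proteomes contain all of
these.  The spacer histogram and group-recovery rates measured on synthetic
families are properties of these simulation settings, not estimates for any
real proteome.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (numpy Generator); reruns
are byte-identical, and the pipeline report checksum is stable.  Default
problem sizes are chosen for desk-scale runs: 200 bootstrap replicates,
20-seed recovery experiments, 1000-sequence oracle batteries, ~1000-protein
spacer histograms.  All are configurable upward (e.g. 1000 bootstrap
replicates) without code changes.
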