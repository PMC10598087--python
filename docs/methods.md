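# Methods

This note records the models, numerical choices, and deliberate
simplifications behind each stage of the pipeline, and what the synthetic
benchmark does and does not demonstrate about real data.

## Synthetic family generator

Real viral-family pangenomes are assembled from public proteome snapshots
that change over time and cannot be redistributed, so validation runs on
simulated families with planted ground truth.

**Model.** A family is a star phylogeny.  Each planted cluster draws one
ancestor sequence i.i.d. from the Robinson–Robinson amino-acid background
(length uniform over `seq_length_range`, default 100–200 residues, the
scale of typical viral protein domains).  Every genome in the cluster's
occupancy set receives an independently mutated copy.  Occupancy is
planted per compartment: core clusters draw occupancy uniformly from
`[⌈0.95 N⌉, N]`, shell from `[3, ⌈0.95 N⌉ − 1]`, cloud from `{1, 2}`.
For N = 3 the shell interval is empty (the core needs all three genomes
and the cloud covers one or two), so requesting shell clusters there is
an error rather than a silent adjustment — a three-genome family simply
has no shell.

**Mutation.** Substitutions are applied per position at a given rate; the
target residue is drawn with probability ∝ `p_b · exp(λ_u · s(a,b))`
(BLOSUM62 scores in half-bit units, background `p_b`), so mutated copies
remain detectable by the same matrix used in the search.  Indels are
single-residue, deletion and insertion each at `indel_rate / 2` per
position.  The family-level `divergence` parameter is the expected
*pairwise* substituted fraction between cluster members; on the star
phylogeny each branch uses `p = 1 − √(1 − divergence)` so that two
independent branches compose to ≈ the requested pairwise value.

**Paralogs and orphans.** With probability `paralog_rate` per
cluster-genome incidence, a second copy is mutated *from the genome's
ortholog copy* at rate `p/2`.  This makes in-paralogs score higher
within-genome than between genomes, which is exactly the signal the
in-paralog attachment rule keys on.  Orphans are fresh background
sequences, unrecoverable by design.

**What the simulation does not model:** tree-shaped (non-star)
divergence, domain shuffling and fusion, compositional biases, length
heterogeneity between orthologs, and annotation noise.  Recovery results
on these families therefore demonstrate the correctness of the machinery
under its own assumptions, not expected performance on divergent real
proteomes.

## Search stage

The search replaces a heuristic tool (BLASTP-style) with an *optimal*
affine-gap local aligner (Gotoh algorithm via biotite), BLOSUM62, gap
open 11, gap extend 1; a gap of length L costs `11 + (L−1)·1`.
Non-standard residues are mapped to X and scored 0 (neutral).  E-values
use the Karlin–Altschul form `E = K·m·n·e^(−λS)` with the standard gapped
BLOSUM62/11/1 constants λ = 0.267, K = 0.041 held fixed rather than
estimated per search: E is used only as a reproducible cutoff, and fixed
constants keep every threshold deterministic.  The subject search space
`n` is the summed length of the subject genome's proteome, mirroring
per-proteome searching.  Hits must satisfy E < 10⁻⁵ and query coverage
≥ 0.75 (coverage is filtered on the query only; subject coverage is
recorded).  A k-mer prefilter (≥ 1 shared 4-mer, disable with
`prefilter_k=0`) trims the all-vs-all quadratic cost; its completeness at
moderate divergence is asserted by test, not assumed.  Intra-genome pairs
are searched too — in-paralog handling needs them — and self-hits are
excluded.  Ties anywhere break on the lexicographically smallest subject
id.

## Clustering stage

Bidirectional best hits (best = highest bit score per query × foreign
genome) seed COG triangles: three proteins from three distinct genomes,
pairwise mutual.  Triangles sharing an edge merge transitively
(union–find over edges).  Design choices where the classical rule is
silent:

* **Pair rescue.** BBH components that contain no triangle (typically
  two-genome pairs) become clusters of their own; without this, clusters
  occupying exactly two genomes — the cloud's defining case — would be
  unrepresentable.
* **Attachment of leftovers.** Proteins in no triangle or pair join the
  cluster of their highest-scoring filtered hit, iterated to a fixpoint.
  This is what gathers within-genome paralog copies, whose cross-genome
  best hits are shadowed by the ortholog copy.
* **Same-genome duplicate groups.** Remaining proteins whose only
  filtered hits are to each other (in practice same-genome duplicate
  pairs) form occupancy-1 clusters; a duplicated protein in a single
  genome is one cloud cluster, not two orphans.
* **Orphans** become singleton clusters, so the cluster set partitions
  the protein set exactly.
* **In-paralogs.** Within each cluster and genome the ortholog is the
  member with the highest summed bit score to the cluster's *other*-genome
  members (a direct, one-pass criterion; defining it against ortholog
  members only would be circular), ties to the smallest protein id.  Other
  same-genome members are in-paralogs.  In-paralog tallies count
  sequences, not clusters-containing-paralogs.

Cluster ids are assigned in sorted order of each cluster's smallest
member, so outputs are byte-reproducible.

**Redundancy filter.** Greedy longest-first sweep; a sequence is dropped
when its *global* (end-to-end, edlib) identity to a retained
representative strictly exceeds 0.80.  "Strictly" matters: a pair at
exactly 80% identity is kept whole.  The filter is idempotent.

**PSSM rescue.** Profile-HMM search over distant homologs is replaced by
a position-specific scoring matrix: members are star-aligned to the
longest member, per-column residue counts get one background pseudocount,
and scores are natural-log odds against the Robinson–Robinson background —
by the standard scaling identity such a matrix has λ = 1, so
`E = K·m·n·e^(−S)` applies directly with K = 0.041.  Candidates are
scored by their best *ungapped* segment (per-diagonal maximum subarray)
and rescued at E < 10⁻³.  This is a deliberate simplification: no
forward/Viterbi scoring, no gap states in the profile.  Its operating
characteristics (false-positive rate ≤ 5% at the cutoff on random
sequences; recovery of planted members at 45% divergence) are asserted by
test.

## Partitioning

Core iff occupancy ≥ `⌈core_fraction · N⌉` (with integer genomes, "at
least 95%" and the ceiling rule coincide); otherwise cloud iff occupancy
≤ 2; otherwise shell.  The precedence order core → cloud → shell is
documented because at tiny hypothetical parameter settings the conditions
could overlap; for N ≥ 3 at the defaults they cannot.  Occupancy counts
distinct genomes, so paralogs never promote a cluster.  Families with
fewer than three proteomes are rejected.  Softcore is not split from core
(no separate threshold is defined for it anywhere in the workflow).

## Rarefaction and the decay fit

For each of `n_perm` uniformly random genome orders (default 200 — medians
are stable at that count on family sizes up to ~50 genomes), the core
size and first-sighting (novel-cluster) counts are computed at every
prefix.  Fits use the *median* curve over permutations, which follows the
cited protocol for this model and tames heteroscedasticity; the model is
`F(n) = κ·e^(−n/τ) + Ω`, least squares with six geometric multi-starts in
τ, τ bounded to `[10⁻⁶, 10·N]`, and the optimizer capped at 2000 residual
evaluations per start (well past convergence on curves of this length; the
cap only stops ill-conditioned flat-curve grinding).  A constant curve
short-circuits to κ = 0, τ = NaN, Ω = mean.  The novel-cluster fit skips
n = 1, where a whole proteome is trivially "new".  The pangenome is called
**open** when the fitted novel-cluster asymptote exceeds 1 new cluster per
added genome; families too small for a 3-parameter fit (< 4 usable points)
are reported "undetermined" rather than extrapolated.  Note the asymptote
of a rarefaction on a *fixed* matrix is a within-sample summary: it
describes the discovery rate still observed at the sampled family size,
not a property of unsampled genomes.

## Functional categories

Letters live in a closed vocabulary: information (A B J K L), cellular
(D M N O T U V W Y Z), metabolism (C E F G H I P Q), poorly characterized
(R S), plus X (miscellaneous) and Vc (capsid-related, no cellular
counterpart).  Rules, in order: no identifiers → S; all cellular flags
(A/B/E) false plus a capsid/virion annotation → Vc; identifiers that map
to nothing → R; letters spanning ≥ 2 general-function groups with no
majority group (> half of the mapped letters) → X; otherwise the mapped
letters stand.  The "no majority" clause operationalizes "many unrelated
functions" while letting a dominant group keep its specific letters.
Profile matrices use `log10(count + 1)` — the standard pseudo-count that
keeps zeros on the scale and the transform exactly invertible on integer
counts.  The Pfam→category map and the V/A/B/E flags are input tables;
the packaged copies are small synthetic examples and say so.

## Oxygen screen

The catalog of strictly O₂-dependent enzyme families is a packaged TSV of
15 Pfam ids (R2 ribonucleotide reductase PF00268; Erv1/Alr PF04777 and
the poxviral PF04805; 2OG-Fe(II) oxygenases PF13532/PF13640/PF13759;
Cu/Zn SOD PF00080; fatty-acid desaturase/hydroxylase PF00487/PF04116;
AABH PF05118; cysteine dioxygenase PF05995; phytanoyl-CoA dioxygenase
PF05721; LPMO PF03067; cytochrome b5 domain PF00173; pheophorbide A
oxygenase PF08417) with cofactors and clans.  The catalog is
authoritative — no oxygen dependence is inferred from sequence.  The
matrix view shows one cell per (enzyme, family) using the precedence
Core > Shell > Cloud (the most conserved placement); every placement is
retained in the long-format companion, and the matrix is derivable from
it.  Enzyme families lacking a Pfam id cannot be screened this way and
are not in the catalog.

## Determinism and sizes

All randomness flows from one top-level seed through named substreams
(`numpy.random.SeedSequence`), so partial re-runs reproduce byte-identical
outputs.  The benchmark family used by the validation suite is 8 genomes ×
~60 proteins (40 core, 8 shell, 12 cloud clusters, paralog rate 0.2, two
orphans per genome, 15% divergence, lengths 100–200): large enough that
every compartment and the paralog/orphan machinery are exercised, small
enough that the whole suite runs on a laptop in about a minute.  Oracle
sweeps use 200 alignment pairs (lengths ≤ 8, where exhaustive enumeration
is tractable) and 500 random BBH graphs (≤ 12 proteins, where brute-force
triangle merging is tractable).

## Known limitations

* The aligner is optimal, not heuristic: scores can differ from a
  seeded-extension tool on the same inputs, and runtime is quadratic per
  pair — fine for viral proteomes (hundreds of proteins), not for
  bacteria-scale inputs.
* PSSM rescue is weaker than profile HMMs on gappy, multi-domain
  homologies.
* The in-paralog rule is one reasonable operationalization; tools
  implementing their own internal rules will not match it sequence for
  sequence.
* The generator's star phylogeny means clustering difficulty is uniform
  across a cluster; real families mix fast and slow lineages.
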