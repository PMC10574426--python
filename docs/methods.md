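# Methods

This note documents the statistical and algorithmic choices behind
`herbnet`, what the synthetic-data generators do and do not emulate, and
the numerical conventions used throughout.

## Screening rules

The compound screens are pure threshold filters, all boundaries
inclusive: OB ≥ 30 %, DL ≥ 0.18, Caco-2 ≥ −0.4 (TCMSP route) and GI
absorption = "High" with ≥ 2 satisfied drug-likeness rules (SwissADME
route). Records lacking a required property raise by default; a
`drop-missing` policy excludes them with a logged warning instead, since
real exports routinely carry gaps. Deduplication treats two records as
the same compound when their PubChem CIDs match (both present) or,
failing that, when their case-/whitespace-normalized names match; the
CID is preferred because curated tables occasionally list a compound
without one. The first occurrence wins, and molecular weights differing
by more than 1 % under one identity are flagged as a likely curation
error.

Target filters follow the conventions of their sources: prediction hits
need probability strictly greater than 0, DisGeNet records score ≥ 0.3
(inclusive), GeneCards relevance strictly > 10; OMIM and TTD are curated
and taken as-is. Gene symbols are compared case-insensitively after
trimming; no alias or ortholog resolution is attempted.

## PPI centralities and the key-target rule

Edge confidences act only as a filter (strictly > 0.9 by default, on a
0–1 scale with STRING's 0–1000 integer scale auto-detected); all
centralities are computed on the resulting *unweighted* simple graph,
matching the default behavior of the Cytoscape-ecosystem tools this
reimplements.

Definitions, for a node *v* in graph *G*:

- **BC** — raw (unnormalized) shortest-path betweenness over unordered
  pairs. Computed by Brandes' algorithm with integer path counts and
  exact rational dependency accumulation, rounded to float once at the
  end; on small graphs this matches exhaustive path enumeration bit for
  bit.
- **CC** — closeness, (n_c − 1) / Σ d(v,u) over *v*'s connected
  component of size n_c; 0 for isolated nodes.
- **DC** — degree.
- **EC** — the nonnegative, Euclidean-unit-norm principal eigenvector of
  the *largest* connected component's adjacency matrix (ties between
  equal-sized components broken by smallest member label); nodes outside
  that component score 0. A single-node largest component scores 1 by
  the unit-norm convention.
- **LAC** — mean degree of *v*'s neighbors within the subgraph induced
  by those neighbors; 0 for degree-0 nodes.
- **NC** — Σ over edges (v,w) of the edge clustering coefficient
  triangles(v,w) / min(deg v − 1, deg w − 1), defined 0 when the
  denominator is 0; accumulated as exact rationals.

Key targets are the nodes at or above the per-metric median on all six
centralities. Medians are midpoint-interpolated so the rule is
deterministic for even node counts, and values within 1e-9 relative of
the median count as meeting it — eigen-solvers return near-equal (not
bit-equal) components for symmetric nodes, and the tolerance keeps the
rule from splitting them arbitrarily.

## Over-representation analysis

The test statistic is the upper-tail hypergeometric probability
P(X ≥ k) for k study genes falling in a K-gene term, drawn n from a
background of N (scipy's stable survival function). The background
defaults to all genes appearing in the annotation collection; this is
configurable because published analyses rarely state it. Zero-overlap
terms are excluded *before* adjustment, so m is the number of tested
terms. Benjamini–Hochberg step-up adjustment is applied within each
category (KEGG, BP, CC, MF) separately, mirroring how GO results are
conventionally sorted and plotted per category. Results are kept at
p.adjust strictly < α, sorted by (p.adjust, −count, term id), and
truncated to top-k per category. GeneRatio is kept as an exact rational
count / |study ∩ background|.

Note that BH-adjusted values are *not* p-values: re-applying the
adjustment to its own output can inflate them further (the step-up map
is not idempotent; e.g. p = (0.927, 0.331) adjusts to (0.927, 0.661),
which re-adjusts to (0.927, 0.927)). The test suite documents this
explicitly rather than pretending otherwise.

## Heterogeneous network and docking/MD post-processing

Degree in the compound–target–pathway–function network is type-blind —
it counts incident edges of every relation kind — because that is what a
generic network-analysis degree reports and what makes compound degrees
reflect their target links. Ties in the top-k ranking break by ascending
node id for determinism.

Docking affinities classify as none (> −5 kcal/mol), moderate
(−7 to −5) or strong (< −7); the exact boundary values −5 and −7 are
assigned to the *stronger* class, a conservative reading of the usual
strict-inequality phrasing. Best-complex ties break lexicographically by
ligand id. A two-sided Wilcoxon rank-sum utility compares one receptor
group's affinities against the rest; it is offered as one reasonable
formalization of "group X binds significantly better" claims, which are
often reported without naming a test.

MM/PBSA bookkeeping is plain addition — MM = VDW + COU,
ΔH = MM + PB + SA, ΔG = ΔH + (−TΔS) — with a validation mode that
checks supplied totals to 0.011 kcal/mol per summation step: printed
tables are rounded to two decimals, so each sum may legitimately be off
by one unit in the last place. Per-residue decomposition fractions are
unit-aware (kJ/mol converts at 4.184), making the reported percentages
unit-invariant.

Trajectory stability uses a sliding-window rule: a series is stable from
the earliest time t such that every window of length w (default 5 ns)
between t and the end has value range (max − min) strictly below the
threshold (default 0.2 nm). "Fluctuation range" is operationalized as
the window range; both parameters are exposed because published
equilibration calls are usually visual. Plateau statistics are the
arithmetic mean ± sample (n−1) standard deviation over samples at or
after the chosen time; the ± in summary tables is taken to be the
sample sd.

## Synthetic data: what it emulates, and what it does not

One master seed drives every generator through fixed per-generator
substreams (numpy `SeedSequence` spawn keys), so outputs are
bit-reproducible and adding a generator never perturbs another. Gene
symbols are synthetic tokens (`G000001`…); no real vocabulary is
mimicked.

- **Compound tables**: a configurable fraction passes each screen
  exactly (default 0.6), with failing records violating one randomly
  chosen criterion strictly; a planted number of exact duplicates
  (default 3 of 30, echoing the scale of a typical curated herb) checks
  deduplication by counting.
- **Target sets**: compound/disease universes of 665/593 genes with an
  exactly planted 119-gene intersection — the canonical shape of a
  two-source Venn analysis at this scale.
- **PPI graphs**: Erdős–Rényi (default n = 119, p = 0.08, giving mean
  degree ≈ 9.4, a realistic post-filter density), Barabási–Albert, or a
  fixed edge list; edge confidences drawn above the 0.9 cutoff.
- **Annotations**: a planted term with effect e and size s takes
  round(e · min(s, |study|)) members from the study set and fills the
  rest from the non-study background; effect 0 draws uniformly from the
  whole background (the null). With effect 1 and s ≥ |study| the term
  contains every study gene.
- **Trajectories**: linear ramp from 0 to the plateau (default 0.35 nm
  at 13 ns, within a 50 ns / 0.1 ns-step run — typical RMSD magnitudes)
  plus i.i.d. Gaussian noise after equilibration.
- **Energy tables**: base components drawn uniformly from ranges chosen
  to bracket typical flavonoid–kinase MM/PBSA magnitudes (VDW −46 to
  −33, COU −10.5 to −3, PB 14 to 36, SA −5.8 to −4.5, −TΔS 1.5 to 5.5
  kcal/mol).

What passing tests on these inputs shows is that the *bookkeeping and
statistics* are correct: planted quantities are recovered exactly or
within stated tolerance. What they do not show is anything about real
biology — the generators have no correlation structure between stages
(a compound's ADME values are independent of its targets), no GO DAG
topology (terms are flat sets), no autocorrelated MD noise, and no
database-version effects. Headline counts from real analyses (numbers
of compounds, key targets or significant pathways) depend on live
database versions and are deliberately out of reach.

## Numerical and design notes

- The null-calibration experiment for the ORA uses a background of
  20 000 genes, a 2 000-gene study set and terms of 750–1000 genes. At
  small sizes the hypergeometric test is visibly conservative because of
  discreteness (the attainable level below 0.05 can be ≈ 0.035); at the
  chosen sizes the attainable level is ≈ 0.049, computed analytically
  from the null distribution, so the empirical rejection rate can be
  meaningfully compared against binomial bounds around the nominal 0.05.
- Exact recovery of a planted equilibration time by the sliding-window
  rule requires the ramp to rise at least `threshold` per sampling
  interval; shallower ramps are detected earlier by about
  threshold/slope, a property of the window rule itself. The recovery
  tests therefore use a steep-ramp regime (plateau 3 nm over 10 ns at
  1 ns sampling); with realistic shallow RMSD ramps the rule's
  equilibration time should be read as "fluctuations below threshold
  from here on", not "ramp end".
- Oracle tests run 200+ random graphs of ≤ 8 nodes against exhaustive
  path/triangle enumeration and shifted power iteration (the A + I
  shift guarantees convergence on bipartite components); BC/DC/LAC/NC
  compare exactly, CC/EC at 1e-9.
- Problem sizes throughout the suite (220 oracle graphs, 200 calibration
  replicates × 10 terms, 119-node pipeline graphs) are desk-scale by
  design: large enough to exercise the statistics, small enough to keep
  the whole suite interactive.

## Known limitations

- No weighted-centrality variants; confidences filter edges but never
  weight paths.
- The GO categories are flat gene sets; parent–child term relationships
  are ignored, as in most web ORA tools.
- `run_pipeline` currently orchestrates synthetic inputs only; real
  exports are handled by the per-stage functions and CLI subcommands.
- The rank-sum receptor comparison is one reading of an ambiguous
  reporting convention and is labeled as such.
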