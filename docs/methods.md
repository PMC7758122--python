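# Methods

## Scope and data model

`netpharm` implements the inference chain used in network-pharmacology
studies of multi-component preparations: docking-score thresholding,
multi-source target integration, construction of compound–target (CTN),
target–pathway (TPN) and compound–target–pathway (CTPN) networks, and
centrality-based screening of key targets and important pathways.

Entities are identified the way the field identifies them: compounds by a
short abbreviation, proteins by UniProt accession (validated against the
canonical 6/10-character grammar), pathways by KEGG `hsaNNNNN` id. Networks
are undirected, unweighted, simple graphs whose nodes carry a class label;
class-pair constraints (compound↔target for the CTN, target↔pathway for the
TPN, both for the CTPN) are enforced at edge insertion, so an invalid layer
mix is a construction-time error rather than a silent analysis artifact.

## Thermodynamic threshold

The docking filter converts an inhibition-constant threshold into a binding
free energy via ΔG = R·T·ln(Ki) with R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and
default T = 298.15 K. At Ki = 1 µM this gives −8.1855 kcal/mol; the widely
quoted −8.18 corresponds to the same relation evaluated at 298.0 K, a
0.007 kcal/mol difference with no effect on any decision for the packaged
data (the closest record sits at −8.19). The comparison is strict
("lower than"), with an `inclusive` switch for ties, and
`ThresholdSpec.pinned_energy` lets a user force a literal published cut-off
when replicating older work. Thresholding is applied per compound–protein
pair, one (best-pose) energy per pair.

## Integration

Database-evidenced and docking-evidenced edges are unioned and deduplicated
on the (compound, target) pair; a pair supported both ways keeps a single
edge recorded as database evidence with concatenated source labels. The
integration report counts **unique target accessions** per evidence class
(not edges), and its inclusion–exclusion identity
`n_union = n_known + n_docking − n_overlap` is enforced by the report type
itself.

## Network construction

Builders materialise only nodes incident to at least one surviving edge:
a compound whose interactions were all filtered out, or a target with no
KEGG pathway, simply does not appear. This drop-isolates semantics matches
how such networks are drawn and counted in practice (a preparation with 13
collected compounds can yield an 11-compound CTN). The CTPN is induced from
a pathway selection: selected pathways → their TPN targets → those targets'
CTN compounds, keeping only the induced compound–target and target–pathway
edges. Selecting a pathway absent from the TPN is a hard error naming it.

## Centralities

All three measures are computed from scratch on the whole heterogeneous
network; class filtering happens only at screening time.

- **Degree**: raw incident-edge count (the ">6" pathway rule operates on
  this scale).
- **Betweenness**: Brandes' accumulation over BFS shortest-path DAGs.
  Raw values are in unordered-pair units with endpoints excluded, and pairs
  with no connecting path contribute nothing; the normalised variant
  divides by (n−1)(n−2)/2. Because the screening rules compare against
  class means, selections are invariant to this scaling (tested).
- **Closeness**: r/D, reachable-node count over summed distances, the
  mean-distance-reciprocal form used by Cytoscape's NetworkAnalyzer; it is
  1.0 for a node adjacent to everything it can reach and 0 for isolates.
  Harmonic centrality was deliberately not used, to stay on the convention
  the screening thresholds assume.

Exhaustive reference implementations ship alongside: betweenness by
explicit enumeration of all shortest paths per pair, closeness by
Floyd–Warshall distances. They share no code with the production routines
and the suite checks exact agreement (|Δ| ≤ 1e−9) on hundreds of random
graphs of 4–12 nodes, connected or not, plus an independent networkx
cross-check.

## Screening rules

**Key targets** (on the CTN): candidates are targets whose degree is in the
top ten by value with all ties at the boundary value included — tie
inclusion makes the selection independent of row order, which matters
because degree ties are pervasive in small bipartite networks. Candidates
must then have betweenness and closeness strictly above the target-class
means. Strictness follows the "larger than the average" wording; it also
gives the sensible degenerate behaviour that a single-target network
selects nothing (its only value cannot exceed its own mean).

**Important pathways** (on the TPN): a cascade of degree > 6, betweenness >
class mean, removal of blocklisted non-specific pathways, closeness > class
mean. The stages are conjunctive so the final set is order-independent, but
the audit records the first stage at which each candidate fell, preserving
the narrative "12 high-degree pathways → remove 4 non-specific → remove 2
low-closeness → 6 important". The shipped blocklist contains metabolic
pathways, pathways in cancer, neuroactive ligand-receptor interaction and
microRNAs in cancer — a curation judgment, editable per run. The further
reduction of important pathways/targets to a handful of "key" ones is a
literature judgment, not an algorithm, and is therefore an explicit
user-supplied selection (`selected_pathways`), never computed.

The cross-talk map between the seven inflammation-related signalling
pathways (estrogen, PI3K-AKT, cGMP-PKG, calcium, cAMP, MAPK, NF-κB) is a
curated fixture, not a computation: directed edges with the mediating
molecules as labels and feedback regulations flagged. Its loader enforces
the seven-name vocabulary, and a validator checks the map's structural
property that every other pathway regulates NF-κB signalling directly.

## Synthetic data generator

`GeneratorConfig` defaults mirror the scale of the packaged study: 13
compounds, 84 targets with 12 planted hubs at ×5 edge-probability boost,
201 pathways, background compound–target probability 0.084 (≈ 144 expected
edges) and ≈ 6.9 memberships per target (≈ 580 expected pathway links).
Pathway sizes are Dirichlet-multinomial with concentration 0.3, giving a
few large pathways (degree > 6) and many tiny ones. Docking energies are a
two-Gaussian mixture: true binders at −9.5 ± 0.8 kcal/mol, non-binders at
−6.8 ± 1.0, chosen to straddle the −8.18 threshold so that the filter's
operating point is non-trivial (predicted pass rates Φ((ΔG_thr − μ)/σ):
≈ 95% for binders, ≈ 8% for non-binders). All randomness flows from a
single `numpy` generator; the returned ledger records hub ids, per-pathway
sizes and exact edge counts so network summaries can be checked against
the planted truth exactly.

What the generator does **not** emulate: database coverage bias, correlated
binding across chemically similar compounds, pathway overlap structure, or
any structure-based realism. Passing tests on synthetic data therefore
demonstrate the pipeline's correctness and statistical behaviour, not the
biological validity of any particular screen.

For the planted-hub recovery property the test harness uses 10 compounds,
50 targets and 5 hubs at background probability 0.15: with hub edge
probability 0.75 the expected hub degree (7.5) sits far above background
(1.5), i.e. the planted hubs are detectable in principle, which is the
premise the ≥90% recovery bound rests on. At much sparser backgrounds a
"hub" touching only a third of the compounds is often topologically
indistinguishable from noise and no screening rule could recover it.

## Numerical and engineering choices

- Node orderings, edge listings, JSON serialisation (sorted keys) and
  selection orderings (degree desc, betweenness desc, id asc) are all
  deterministic, so identical inputs give byte-identical pipeline reports.
- Centrality comparisons in tests use absolute tolerance 1e−9; BFS path
  counts are exact in double precision at the graph sizes screened here.
- Readers treat `""` and `"NA"` as absent, preserve row order, and fail
  hard (with row numbers) on malformed numerics, bad accessions, duplicate
  keys and dangling metabolite references. The docking reader implements
  the printed-table dialect where the compound label is named once per
  block and carried down.
- GraphML and edge-CSV exports round-trip node ids, classes and edge sets
  exactly; SIF (one `source  class-pair  target` line per edge) is provided
  for Cytoscape import.
- Problem sizes in the test suite and acceptance script (random graphs of
  4–12 nodes for exhaustive oracles, 100 generator replicates, 10,000
  docking draws) were chosen so exhaustive enumeration stays exact and
  Monte-Carlo error stays well below the asserted margins.

## Known limitations

- No docking engine is included or wrapped; binding energies are inputs.
- No pathway-enrichment statistics: screening is purely topological, as in
  the workflow this package reproduces.
- Closeness and betweenness conventions target NetworkAnalyzer semantics;
  other tools' normalisations will differ (selections do not, for any
  positive rescaling, since thresholds are class means).
- The full-scale network statistics of the original study depend on
  supplementary edge lists that were never publicly archived; the package
  reproduces every quantity derivable from the printed tables and exercises
  the remaining code paths against synthetic ledgers.
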