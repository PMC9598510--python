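# Methods

## Model

The pipeline infers a bipartite putative interactome between a foreign
proteome and human cancer genes under one assumption: a protein–protein
interaction is plausible whenever the two proteins carry domain families
known (or predicted) to interact physically. Formally, with dom(p) the
domain-family set annotated on protein p, dom(g) the set attached to gene g,
and D an unordered domain-pair relation, the predicted edge set is
{(p, g) : dom(p) × dom(g) ∩ D ≠ ∅}. This is a recall-oriented surrogate —
domain co-occurrence does not imply binding in context — so edges are
"putative" and every supporting domain pair is carried in the output for
inspection.

Two interaction counts are first-class and reported side by side:
`n_interactions` (distinct protein–gene pairs) and `n_domain_links` (total
supporting-pair multiplicity). Published genome-scale totals in this problem
area do not always state which convention they use; emitting both avoids
committing to one.

## Cancer-role classification

The gene catalogue is the union of a TSG list and an OCG list; symbols in
both are dual-role. Matching is exact and case-sensitive — alias resolution
is explicitly out of scope, so a case-mismatched mapping row attaches
nothing (it is logged). Each domain family's role comes from the genes that
carry it: TSG-specific (only TSGs), OCG-specific (only OCGs), dual-role
(both), unknown (no associated cancer gene; the ratio is undefined and is
rendered "Not available", deliberately distinct from 0).

The dual-role ratio is #TSG / (#TSG + #OCG). A dual-role gene increments
both tallies of each of its domains. This policy (`dual_counts_both=True`)
is the default because the published three-way domain partition this
statistic comes from only closes when shared genes contribute to both
sides; the alternative (excluding dual genes from both tallies) is exposed
as a flag since the original denominator convention is not documented.
Ratios are kept at full precision; the table writer renders 6 decimals.

## Input formats and parsing decisions

* FASTA protein identifiers are the first whitespace-delimited header
  token; duplicates are an error, an empty file is an empty proteome.
* HMMER3 `domtblout` rows are filtered on the *independent* E-value with
  default `evalue_max = 1e-5`. The threshold is a package decision: tools
  in this space commonly use either a fixed cutoff or Pfam gathering
  thresholds, and pre-thresholded TSV input (the `tsv` dialect) is loaded
  verbatim for the latter case.
* Pfam accession version suffixes (`PF00069.25`) are stripped on load
  everywhere, because DDI catalogues use unversioned accessions and the
  join must be on bare accessions. Accessions are validated against
  `PF\d{5}` unless disabled for synthetic vocabularies.
* DDI pairs are canonicalised unordered (lexicographic) and de-duplicated;
  self-pairs are legal. The count of rows dropped by the confidence filter
  is kept for audit.
* Secretion evidence is an outer join of SignalP 5 short output (call =
  prediction column ≠ `OTHER`) and TMHMM 2 short output (`PredHel=`,
  `Topology=`): missing SignalP row ⇒ no signal peptide, missing TMHMM row
  ⇒ zero helices. All coordinates are 1-based inclusive.

## Secretome rule

Default is strict subtraction: secreted ⇔ signal peptide ∧ zero predicted
TM helices. Signal peptides are frequently mis-predicted as a first TM
helix, so an N-terminal exemption (`nterm_exempt_len`) discounts helices
ending within the first N residues; it is off (0) by default to match the
plain subtraction rule, and the secreted set is provably monotone
non-decreasing in the exemption length. Proteins without any evidence are
non-secreted, not errors.

## Hubs and cross-species comparison

A TSG hub has ≥ `min_tsg_partners` (default 100, inclusive — "100 or more")
distinct TSG partners; dual-role partners count only with `include_dual`.
Cross-species overlap matrices compare partner-gene sets and foreign
interacting-domain sets by plain set intersection, keyed on gene symbol and
bare accession.

## Enrichment statistics

The upper tail P(X ≥ k) of the hypergeometric distribution is computed
exactly via log-space binomial coefficients (`lgamma` + log-sum-exp); no
normal approximation. Benjamini–Hochberg is the standard step-up with
enforced monotonicity and cap at 1. Note that BH is *not* idempotent on its
own output (re-adjusting rescales by m/rank); only constant vectors are
fixed points, and the tests assert exactly that. Significance is adj. p ≤
alpha with alpha = 0.01 by default. The background universe is always an
explicit argument: published analyses differ on whether "background" means
all protein-coding genes or an expressed subset, so no default is built in.
Query genes outside the background are dropped with a warning; terms empty
after background intersection are excluded.

## Synthetic benchmark generator

The generator emulates the statistical shape of the real inputs: several
species with proteomes over a shared 150-domain vocabulary, gene lists of
120 TSG / 80 OCG with 15 dual-role symbols, a DDI table covering 2% of
possible pairs with a 60/25/15 HC/MC/LC confidence mix, 15% signal-peptide
and 25% TM fractions, and 5 planted secreted hubs wired to ≥ 100 distinct
TSG partners each. Each hub carries a dedicated domain (reserved out of the
general vocabulary so no other protein can acquire it) connected by
high-confidence edges to enough TSG gene domains to meet the target —
constructive wiring, so unsatisfiable configurations (e.g. target exceeding
the number of TSG-specific genes) fail validation before any file is
written. Accidental hubs arising from random edges are forced non-secreted
so that "planted secreted hubs" is an exact, recoverable set.

Ground truth is *recomputed* from the emitted structures by an independent
brute-force enumeration (triple loop), not taken from the planting
bookkeeping, and serialised next to the dataset. One integer seed derives
per-component substreams, so a seed maps to one byte stream; the default
configuration generates and verifies in well under a minute on one CPU.

What the generator does not emulate — and what passing tests therefore do
not show about real data: realistic domain architectures (domains are drawn
i.i.d., real proteins have correlated multi-domain layouts), sequence
content (random amino acids; only lengths are used), evolutionary
relatedness between species, biased DDI coverage toward well-studied
families, and prediction errors in the secretion tools (calls are taken at
face value). Recovery results certify the bookkeeping and the inference
logic, not biological accuracy of the DDI surrogate.

## Numerical and determinism choices

Ranking ties break by accession ascending; interactome output sorts by
(species, protein, gene); all writers emit sorted rows, so repeated runs
are byte-identical. Exact set/rational arithmetic is used in test oracles;
the hypergeometric tail is validated against full rational enumeration for
all populations ≤ 25 at 1e-12.

## Known limitations

Domain-level inference cannot distinguish paralogues sharing a domain, and
edge confidence is inherited wholesale from the DDI tier filter — no
per-edge scoring. Gene symbols are trusted as given. The enrichment module
tests flat term sets only (no term hierarchy or semantic clustering of
redundant terms).
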