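# Methods

## Problem and model

The toolkit operationalizes structural-alert (SA) analysis for binary
toxicity endpoints.  The underlying model is deliberately simple and
interpretable: toxicity for an endpoint is attributed to the presence
of specific substructures, and a compound is predicted positive iff it
contains at least one alert of that endpoint's alert set.  There is no
weighting, voting, or probability calibration — the value of the method
is that every positive prediction points at a concrete, highlightable
fragment.

Alerts are *mined* from a labeled training set by frequency analysis:
a substructure qualifies when it is common enough to trust its
statistics and markedly enriched among toxic compounds.

## Data standardization

All structures pass one standardization gate before any statistic is
computed:

- unparseable SMILES are rejected (`unparseable`);
- multi-component entries are rejected (`salt_or_multicomponent`) —
  salts and mixtures share this gate, because a counterion-stripped
  structure was never tested as such.  An opt-in `strip_salts` mode
  removes entries from a short monoatomic counterion list instead;
- carbon-free structures are rejected (`inorganic`);
- structures with any atom outside H, B, C, N, O, F, Si, P, S, Cl, As,
  Se, Br, Te, I are rejected (`organometallic`) — the common
  organic-subset convention;
- within a dataset, identical canonical SMILES with identical labels
  collapse to one compound (`duplicate`); canonical SMILES observed
  with both labels are removed entirely (`label_conflict`).

The canonical form is RDKit's canonical SMILES.  One run uses one
dialect; byte-identity of canonical strings across other toolkits is
not promised, and no tautomer or stereochemistry normalization is
attempted.  Every input record is accounted for exactly once across
the accepted set and the typed rejection report.  Datasets are ordered
lexicographically by canonical SMILES, which makes every downstream
artifact independent of input order.

## Substructure statistics

For a substructure with `N_fragment` carrier compounds of which
`N_fragment_positive` are toxic:

- positive rate `PR = N_fragment_positive / N_fragment`;
- Fisher feature score of the binary presence vector x against labels:

      F = ((m⁺ − m)² + (m⁻ − m)²) / (v⁺ + v⁻)

  with m⁺/m⁻/m the means of x over toxic/non-toxic/all compounds and
  v⁺/v⁻ the within-class sample variances (denominator n−1; a class of
  size one contributes zero variance).  This is the standard
  feature-selection F-score for a binary descriptor.  Degenerate cases:
  a feature constant over the dataset scores 0; a perfect separator
  with zero within-class variance scores a serializable sentinel of
  1e9, which out-ranks every finite score.  The implementation works in
  exact rational arithmetic internally and converts to float once.

Threshold comparisons on PR are performed with exact rationals
(`Fraction(n_pos, n) >= Fraction("0.65")`), so a pattern at exactly the
boundary (e.g. 13 of 20 carriers toxic) is retained and a one-count-
below pattern is excluded; float rounding can never decide a boundary.

## Mining branches

**Fingerprints filter** (`mine_fp_filter`): every key of a predefined
SMARTS catalog is scored against the dataset; keys with support ≥ 6,
F ≥ 0.005, and PR ≥ 0.65 (all inclusive) become alerts.  Defaults
reflect the regime the filter is designed for; all three are exposed.
The bundled default catalog is a curated set of ~30 toxicophore-like
SMARTS (nitro, nitroso, epoxide, aromatic amine, Michael acceptors,
alkyl halides, quinones, ...).  The method is catalog-agnostic: any
SMARTS-per-line file (e.g. a full substructure-key fingerprint
definition) plugs in, and fingerprints are only comparable within one
named catalog.

**SARpy-style enumeration** (`mine_sarpy`): every compound is cleaved
recursively at all acyclic, single, non-aromatic bonds; rings, double,
triple and aromatic bonds are never opened, so every fragment is an
honest substructure of its parent and its SMARTS necessarily matches
the parent.  Fragments of 2–18 heavy atoms (attachment positions carry
no substitution constraint; implicit hydrogens and attachment markers
are not counted) occurring in ≥ 3 compounds are scored by PR over the
whole dataset via SMARTS matching, and those with PR ≥ 0.65 are kept.

Because all cuttable bonds are acyclic, contracting the uncuttable
bonds turns the molecule into a forest whose connected node-subsets are
exactly the fragments; enumeration walks that forest with pruning at
the size bound instead of iterating the exponential set of bond-cut
subsets.  A per-molecule cap (default 10,000 fragments, warned when
hit) bounds pathological cases such as long acyclic chains.

*Dominance pruning* (on by default, recorded in provenance): candidates
are decided smallest-first, and a fragment is dropped when a kept
smaller fragment (i) occurs in a superset of its carriers, (ii) has PR
at least as high, and (iii) is structurally contained in it.  The
containment check re-parses the larger pattern as a molecule without
full sanitization (fragment valences are not always sanitizable); when
even that parse fails, the carrier-superset evidence decides.  The
pruning keeps rule sets minimal — a more general fragment that explains
everything a specialization explains makes the specialization
redundant.

**Merging**: alert sets for one endpoint merge by SMARTS; on
duplicates the entry with larger support wins, ties broken by origin
(fp_filter > sarpy > imported).  Alert sets are always ordered by
descending PR, then descending support, then lexicographic SMARTS, and
ids are assigned in that order (`<endpoint>_<origin>_<ordinal>`), so
identical inputs yield byte-identical JSON files.

## Screening and applicability domain

Matching is centralized: catalog fingerprint bits, mining statistics,
and alert screening all use the same substructure matcher, so bit
presence and alert hits cannot disagree.  Embeddings are deduplicated
by atom-index set (the automorphisms of a symmetric pattern collapse),
and hits are reported as 0-based atom indices over the canonicalized
query, which is what fragment highlighting and the optional SVG
depiction consume.

The applicability domain is similarity-based: a query is in-domain when
its Tanimoto coefficient on catalog fingerprints to at least one
training compound is ≥ 0.5 (inclusive).  Two conventions matter:

- empty-vs-empty similarity is defined as 0 — a query setting no
  catalog keys carries no evidence of domain membership and must not be
  declared in-domain by a 0/0 artifact;
- the flag is advisory: verdicts are always reported, and batch
  screening offers an `ad_gate` mode that rewrites out-of-domain rows
  to `no_prediction` for users who want a hard gate.

## Evaluation

Alert sets are evaluated as classifiers via exact confusion counts and
Q, SE, SP, PPV.  A statistic with a zero denominator is *undefined* and
rendered `NA` — never silently 0 — because the small datasets used in
testing regularly produce all-negative predictions.  Reports render
proportions as percentages to two decimals and can be stratified by
domain membership; the stratum counts partition the totals exactly.

## Synthetic benchmark datasets

The generator assembles compounds from a fixed library of 20 small
organic scaffolds and 15 benign substituents (no random SMILES string
synthesis, so every structure is valid), embeds each planted alert
fragment in ⌈support_fraction × n⌉ compounds, and assigns labels so the
realized PR matches the target at integer counts (tolerance ±0.05;
specs that cannot be realized raise an error rather than silently
drifting).  Decoy fragments are embedded at the background label prior
of 0.4, giving realized decoy PRs near 0.4 — clearly below the alert
threshold, so a correct miner must reject them.  Optional label noise
flips labels after assignment.  All randomness flows from one integer
seed through one generator; identical specs yield byte-identical
dataset and manifest files.  The manifest records both planned and
*realized* per-pattern support and PR (recomputed by brute-force
matching over the emitted compounds), and tests assert against realized
values.

What the synthetic regime does not emulate: the chemical diversity of
real endpoint collections, correlated co-occurrence of toxicophores,
activity cliffs, assay noise structure, or class imbalance beyond the
configured prior.  Passing the planted-recovery benchmarks therefore
demonstrates correctness of the mining machinery (counting, thresholds,
boundaries, determinism), not predictive performance on real chemistry.

## Numerical and design choices

- PR thresholds: exact rational comparison (see above).  The f-score
  threshold is compared in floating point; with the score computed from
  rationals, the only inexactness is the final float conversion.
- Problem sizes: tests and the acceptance pipeline use datasets of
  40–200 compounds and fragment windows up to 10–18 heavy atoms, sizes
  at which exhaustive oracles (VF2 subgraph embedding, bond-cut-subset
  enumeration, exact-rational statistics) can verify the
  implementation end-to-end.
- Tie-breaks are specified everywhere order matters (alert ordering,
  merge conflicts, nearest-neighbour reporting takes the first maximum
  in dataset order) so that all artifacts are reproducible byte-for-byte.
- Estimator layer: `StructuralAlertClassifier` and
  `TanimotoApplicabilityDomain` expose mining/screening as
  scikit-learn-style fit/predict models over SMILES sequences; they
  delegate to the functional core and add nothing statistical.

## Known limitations

- No salt-stripping chemistry beyond a short monoatomic counterion
  list; genuinely mixed salts are rejected, not repaired.
- Alert SMARTS mined by fragment enumeration inherit the aromaticity
  model of the parent structures; exotic tautomers of a query can
  evade a pattern mined from the canonical form.
- The SARpy branch scores fragments only by support and PR; it does not
  reimplement the original SARpy likelihood machinery, and the
  dominance pruning is a minimality heuristic, not an optimality
  guarantee.
- Continuous endpoints must be thresholded to binary labels upstream.
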