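# Methods

## Problem setting

Taxonomic assignment of prokaryotic 16S rRNA sequences depends on a
reference database pairing sequences with seven-rank lineages (kingdom
through species). The three classic public references — RDP, SILVA and
Greengenes — disagree in coverage and in taxonomy-string dialect, and a
large share of their records stop short of an exact species name
(placeholders such as `bacterium`, `metagenome`, `uncultured_...`, or
genus-only `..._sp.` labels). This package implements the machinery to
(i) curate such references to exact-species resolution, (ii) merge
several sources into one integrated database, (iii) build benchmark
datasets with controlled taxonomy overlap, (iv) profile hypervariable-
region coverage, and (v) score classifier output per rank with
synonym-aware name matching.

## Canonicalisation

All sequences are normalised to one alphabet: uppercase, RNA `U` → `T`,
gap characters (`.`, `-`, `~`) and whitespace removed, IUPAC degenerate
codes kept verbatim. All taxonomy strings are parsed into a seven-slot
lineage with dialect prefixes (`k__`, `d:`) stripped and internal
whitespace replaced by underscores; comparisons are case-sensitive after
canonicalisation. The species slot always holds the full underscored
binomial: dialects that write an epithet-only `s__` field (Greengenes
style) have the genus joined on at parse time. Cross-database taxonomy
comparison is meaningless on raw dialect strings, so every downstream
operation works in this canonical space.

## Curation

A record passes curation iff its species slot is non-empty, is not a
bare or trailing `sp.`, and contains no blocklist token as a case-folded
substring. The default blocklist is `{bacterium, metagenome,
candidate_division, human_gut, unidentified, uncultured, unclassified}`;
it is a parameter, not a constant, because the placeholder vocabulary in
public references is open-ended. Substring (not whole-word) matching is
deliberate: placeholders are routinely embedded in longer labels such as
`uncultured_bacterium`. After filtering, byte-identical sequences under
an identical lineage collapse to one record (first id kept). Every
removal is reported with its reason, so the effect of the blocklist is
auditable. Curation is idempotent.

## Integration

Two merge semantics over an ordered (basis, candidate) pair:

**Sequence-based.** For each candidate sequence in input order: if it
contains one or more sequences of the working set as exact substrings,
all of them are removed and the candidate inserted once (`replaced`,
carrying the candidate's own lineage); else if some working sequence
contains the candidate, it is `skipped`; otherwise `added`. Containment
is literal: same orientation, degenerate codes compared as characters,
equality counts, one nucleotide difference defeats it. The working set
is the evolving merged database, so a chain of containments resolves to
the longest sequence seen; consequently the result depends on candidate
order (fixed as file order) and full pairwise substring-freeness of the
output is not guaranteed, only the single-pass semantics. Taxonomy
quality is ignored in this mode by design — it exists to show what
collecting all sequences does and does not buy.

**Taxonomy-based.** Requires curated inputs. A candidate whose canonical
lineage is absent from the working set is added; one whose lineage
exists is added only if its sequence differs from every working sequence
under that identical lineage, else skipped. The basis never shrinks, the
output's taxonomy set is exactly the union of the inputs', and all
sequences under one lineage are pairwise distinct.

`build_itgdb` left-folds an ordered source list (classically RDP, SILVA,
Greengenes) through either mode, one log per round. Ids are always
prefixed `source|id` so identical ids across sources cannot collide;
"identity" statements about re-integration are therefore statements
about (sequence, lineage) content, not about ids.

The sequence mode is backed by a k-mer anchor index (default k = 12):
basis-in-candidate queries look up basis prefixes along candidate
windows, candidate-in-basis queries look up the candidate's leading
k-mer in an all-windows table; sequences shorter than k fall back to a
linear side list. The index is an optimisation only — the test suite
holds it to exact agreement (entry sets and decision logs) with a naive
all-pairs substring scan across seeded random databases rich in
substring/superstring/equality structure.

Open design points resolved here: a replacing candidate carries its own
lineage (wholesale record replacement; keeping the basis lineage would
create chimeric records), and the displaced basis ids are logged with
each decision so the displaced taxonomy is recoverable.

## Benchmark datasets

Species membership, not sequence identity, decides the three validation
sets: **Union** (species in any source), **Exclusion** (species in
exactly one source) and **Intersection** (species in every source).
Union keeps all sequence variants per species; byte-identical
(sequence, lineage) pairs that recur across sources are collapsed once,
with the collapse count logged. The species ledger reports per-source,
exclusive, common and union species sets; exclusive sets are pairwise
disjoint and the counts obey inclusion–exclusion by construction.

## Region profiling

A sequence covers a region span iff a forward-primer site and a
reverse-primer site (searched as its reverse complement) exist with the
forward start strictly before the reverse start and an implied amplicon
length within bounds. Primer matching is IUPAC-aware on both sides — a
position matches when the two codes' expansions intersect — with a
mismatch budget. Coordinates are 0-based half-open internally; reports
are 1-based inclusive. The shipped panel maps the conventional span
labels (V1-V2 … V1-V9) to the canonical broad-range primers (27F/338R,
341F/534R, 515F/806R, …, 27F/1492R) with `max_mismatch: 2` and amplicon
bounds 50–2000 nt; every one of these values lives in the YAML config,
not in code, because there is no single community standard to hard-code.
Counts under this panel characterise a database's primer-site coverage
under these stated parameters; they are not comparable to counts
produced under a different, unstated panel.

## Evaluation

A prediction at a rank is correct when it names the truth taxon after
canonicalisation (underscores/spaces unified, case-folded) or shares an
NCBI names-dump group with it. The synonym map groups every name by
taxon identifier, restricted to an allow-list of name classes (default:
scientific name, synonym, equivalent name, genbank synonym — the
accepted classes are configuration, since reasonable choices differ).
Accuracy is micro (correct/evaluated); precision, recall and F1 are
tallied per truth class on one-vs-rest confusions — after collapsing
synonyms onto one representative — and macro-averaged by default
(`weighted` and `micro` are available). True negatives are never
counted: with hundreds of classes per rank they dwarf the informative
counts and reduce accuracy to a near-constant. False positives are
tallied only for predicted classes that exist in the truth set, which
keeps the confusion table within the evaluation universe; predictions
for reads outside the truth set are ignored and logged. An empty
prediction is simply incorrect. F1 is defined as 0 when precision +
recall = 0.

Assignment depth counts a read as assigned at a rank when its prediction
there is non-empty and, under a threshold, its confidence at that rank
reaches it. With rank-monotone confidences (as classifiers in the SINTAX
family produce) depth is non-increasing from family to species.

## Synthetic data

The fixture generator emulates three source databases with controlled
species overlap (per-source exclusive counts, all-shared and pairwise-
shared counts), planted ambiguous species labels, planted containment
pairs (a candidate engulfing a basis sequence, reusing an existing
candidate-side species so the overlap arithmetic is untouched), planted
byte-identical duplicates, a toy names-dump with planted aliases,
classifier output with an exact planted species-mislabel count
(`floor(rate · n)` reads), and primer-planted sequences (single-amplicon
plants per span, plus synthetic full-length genes carrying every panel
site at spaced, ordered offsets). Every plant is recorded in a ground-
truth object, and the test suite's backbone is round-trip closure:
each module's output on a fixture must equal the fixture's ground truth.

Default fixture sizes are small (a few species per overlap class,
sequences of 150–300 nt); the acceptance script scales to 85 species /
~600 sequences, and the integration oracle checks run at 200+200
sequences of up to 500 nt over 20 seeds. Sequences are uniform random
DNA: passing tests demonstrate the correctness of the set/substring/
string-matching logic under controlled structure, not performance or
behaviour on real 16S composition (real references have biased base
composition, shared conserved blocks — hence far more near-containments
— and far larger scale). Orientation handling is likewise out of scope:
inputs are assumed same-orientation, as the containment rule is defined
without reverse-complement search.

## Numerical and degenerate-input choices

Percentages are computed in double precision and reported to two
decimals; no rounding occurs before comparison. Empty databases yield
empty outputs and zero counts rather than errors; a rank with no truth
names is omitted from evaluation with a warning; requesting thresholded
depth without confidences, uncurated input to taxonomy-dependent
operations, fewer than two integration sources, and duplicate ids are
hard errors. Determinism is a contract throughout: identical inputs and
configuration produce byte-identical outputs, and every stochastic
fixture is a pure function of its seed.

## Known limitations

- Sequence-mode output is order-dependent by specification; reordering
  candidates can change which member of a containment chain survives.
- The k-mer index holds all windows of the working set in memory;
  profiling beyond ~10^6 sequences would want a disk-backed or
  suffix-automaton variant (the semantics would be unchanged).
- No chimera detection, no similarity-threshold (97/99%) clustering, no
  reconciliation when two sources assign one sequence different species.
- Synonym matching is name-based only; it does not consult the taxonomy
  hierarchy (nodes.dmp) and cannot resolve rank mismatches.
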