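# Methods

This note documents the models implemented in `spip`, the choices made
where the design was genuinely open, what the synthetic benchmark does
and does not emulate, and the known limitations.

## Evidence channels

All pairwise channels are seeded with a reference set *R* of known
spindle proteins ("baits") and score candidate proteins ("targets");
each target keeps its **best** score over all baits (the bait–target
collapse, `core.collapse_pairs`). A channel reports a score only for
targets it actually detects; undetected targets are *missing*, not
zero — a protein invisible to the literature or to a domain database
is not thereby evidence against membership.

**Co-citation (d-COCITE / i-COCITE).** The literature network is first
restricted to edges whose relation was classified as physical. For a
protein *i*, the direct context is (`n_ri`, `N_r`, `N_i`): the number
of edges from *i* into *R*, the total degree of the reference members
touching *i* (only those touching *i*, not all of *R*), and the degree
of *i*. The indirect context counts distinct length-2 paths *i–c–r*
with connector degrees `N_c` and reached-reference degrees `N_r2`.
The published variable roles fix the qualitative behaviour of the
scores (zero without contact, increasing in contacts, penalising
"sticky" high-degree proteins) but not a unique algebraic form, so the
form is pluggable, registered by name and recorded in output metadata;
the defaults are

    S1 = n_ri^2 / (N_r * N_i)        S2 = n_rci^2 / (N_r2 * N_c * N_i)

which satisfy every stated property. An isolated protein is
*undefined* (distinct error), not zero. Multi-edges collapse to simple
edges before counting.

**Domain fusion (CODA).** For query-genome proteins *p, q*, the
candidate set `J_{p,q}` holds all cross pairs of superfamilies
(a ∈ D_p, b ∈ D_q, a ≠ b); proteins sharing any superfamily are
excluded entirely — fusion evidence is circular for homologous
proteins. A domain pair scores `s_{a,b} = max_{t∈T} form(|T|, f^g_a,
f^g_b, f^t_a, f^t_b)` over the genomes *T* containing a fusion
protein, and the pair score is the maximum over `J_{p,q}`. The default
form `|T| / (f^g_a f^g_b f^t_a f^t_b)` rewards corroboration across
genomes and rare (hence specific) families; it is pluggable like the
co-citation forms. The channel runs twice, on two independent
annotation vocabularies (the "cath" and "pfam" dialects), giving two
evidence channels. `|T|` counts genomes containing a fusion protein,
not all genomes scanned.

**Domain over-representation (DORA).** A family's score is the ratio
of its relative frequency among the reference set's domains to its
relative frequency in the whole genome, `C_ij = (Ft/Nt)/(Fb/Nb)`; a
protein takes the best score over its families. Frequencies count
occurrences (repeats included). `Fb = 0` is undefined; `Ft = 0` gives
0 and the protein is treated as undetected.

**Interolog inheritance (hiPPI).** Families are sub-clustered at 11
nested sequence-identity levels (S-levels 1–11 for thresholds 0–100%;
nesting is validated on load). A known interaction (A1, B1) supports a
candidate pair (A2, B2) from the same two families with base score =
mean of the two shared S-levels; extra experimental evidence types and
extra species add a halving series on top (base/2 for the first extra,
base/4 for the next, extras pooled evidence-types-first — the order
that reproduces the worked configuration: base 8, second source +4,
second species +2). Distinct supporting known pairs sum. The
identity↔level mapping is a property of the input clustering table,
not hard-coded, since published level numberings are not fully
consistent.

**Expression correlation (GECO).** Plain Pearson correlation over
conditions observed in both profiles, after discarding any profile
with more than 5 missing values (the published missingness budget,
configurable); pairs with < 3 common observations or zero variance are
undefined. Collapse keeps the signed maximum (most positive)
correlation — the platform's orientation is "higher = more
spindle-like" and no two-sided rule is published.

**Semantic similarity (GOSS).** Resnik similarity: `p(c)` is the
fraction of annotated proteins annotated to term *c* or a descendant;
`IC = −ln p` (natural log, the Resnik convention); term similarity is
the IC of the most informative common ancestor; protein similarity
aggregates across the two annotation sets with `max` by default
(consistent with the platform-wide best-score collapse;
best-match-average is available). One ontology namespace at a time.

**Feature-based prediction (MLNN).** The labelled set is
homology-reduced (greedy Hobohm-style removal of the most-neighboured
protein in the similarity threshold graph, ties by identifier, until
the retained set is independent; default threshold 0.4, configurable).
Single features are ranked by 3-fold cross-validated Matthews
correlation coefficient, pairs grow from the best singles, triplets
from the best pairs, and the search stops when the best new
combination fails to beat the incumbent. The top 4 subsets each train
3 feed-forward networks (scikit-learn `MLPClassifier`, one hidden
layer of `max(2, ceil(n_features/2))` units, lbfgs solver — the
smallest architecture consistent with a feed-forward net on this data
size; 12 networks total, restart-seeded, deterministic given the run
seed). The ensemble prediction is the mean member output in [0, 1].
After fitting, member weights are extracted into plain arrays so
models serialize to JSON and prediction does not depend on estimator
internals. Two independently trained ensembles combine by averaging.

## Integration

Scores become **add-one empirical right-tail p-values** computed over
each channel's own score distribution:

    p(s) = (1 + #{scores >= s}) / (n + 1)

This is distribution-free, monotone in the score and never 0, so
Fisher's statistic is always finite. Channels map to three approaches
(LM: both co-citation channels; NNI: the network ensemble; DGC: the
six domain/context channels) and combine in two stages — Fisher within
approach, then Fisher across approach-level p-values — following the
platform's published architecture; a flat single-stage mode exists for
sensitivity analysis. Targets missing a channel or approach are
combined over what is available with degrees of freedom reduced
accordingly (imputing p = 1 would systematically penalise proteins
invisible to a data source for reasons unrelated to function). Ties in
the final ranking break by protein identifier.

Channel independence, which Fisher's method assumes, is diagnosed with
the normalised mutual-information distance `D(X,Y) = 1 − I(X;Y)/H(X,Y)`
(plug-in estimates in nats over 10 equal-frequency bins of the
p-values; D = 0 when either series determines the other, 1 under exact
empirical independence; it is the normalised variation-of-information
metric and satisfies the triangle inequality). `calibration_check`
reports a KS statistic against Uniform(0,1) and a right-tailed Z-test
on the mean probit transform (under uniformity `sqrt(n)·mean(−Φ⁻¹(p))`
is standard normal; large positive values flag p-values piled near 0).

### Calibration behaviour and a known limitation

Under a fully null benchmark the continuous-score channels (expression
correlation, the network ensemble, indirect co-citation) produce
uniform empirical p-values. The count- and vocabulary-based channels
(domain enrichment, semantic similarity, and to a lesser degree direct
co-citation and interolog inheritance) take finitely many score
values; the add-one estimator assigns every tie block its block-top
p-value, which makes those channels mildly **conservative** (null
p-values stochastically larger than uniform), and the Fisher
combination inherits a conservative bias (mean null integrated p
≈ 0.54 instead of 0.50 at the default benchmark size). The bias is
strictly in the safe direction — significance is understated, never
overstated — but a two-sided KS uniformity test on the integrated null
p-values rejects in roughly a quarter of seeds. Removing it would
require smoothing the score distributions (e.g. fitting continuous
densities before inversion), which trades distribution-freeness for
calibration and is deliberately not done here.

## Evaluation and hidden hubs

A ranking is benchmarked against a truth label set: confusion metrics
at a depth (sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP)), ROC and PR curves swept over every rank threshold (the
ROC area equals the Mann–Whitney rank statistic; average ranks for
ties), windowed fold-enrichment (labelled count in ranks 1..w over
w+1..2w), the Wald–Wolfowitz runs test on the label sequence (normal
approximation; flagged weak when either class has < 10 members), and
an empirical permutation test on the prefix label count with add-one
correction, which converges to the hypergeometric upper tail.

Two interaction graphs are compared per candidate: the KG
(experimental edge sources, merged simple graph with source tags) and
the PG (union of pair-level predictions from the ab-initio channels —
expression, interologs, both fusion channels — passing the p ≤ 0.014
gate, a published precision-motivated operating point). Hidden hubs
among the top-2% candidates satisfy: KG degree ≤ 5 ("few known
interactions" is published but unquantified; 5 is this package's
default, reported in output headers), PG degree ≥ 5 × max(KG degree,
1) (the published five-fold rule; the max(·,1) floor avoids division
by zero for fully unknown proteins while preserving intent), and
spindle fraction ≥ 0.5 of PG edges into the known-spindle set (the
denominator is the PG degree — the predicted context — an assumption,
since the published percentage's denominator is not stated). Ranking:
PG degree desc, spindle fraction desc, identifier.

## The synthetic benchmark

`fixtures.generate(params, seed)` builds a complete input bundle with
a planted positive module. Defaults (the study conditions at desk
scale): a 500-protein proteome with a 40-member module (25 SEED-like
baits, 15 EXPERT-like held-out members; ≈ 0.5% positive rate,
mirroring the 149-seed / 32,145-proteome ratio of the full-scale
problem). Module members co-cite at edge probability 0.25 vs 0.02
background (80% of edges physical); carry module-specific
superfamilies whose pairs are fused in 1–2 of 4 target genomes (two
independent vocabularies of 150 background superfamilies with mild
power-law popularity, exponent 0.4, so frequency-based scores take
many distinct values the way real domain-usage statistics do); sit in
tight families (members within 0.008 of a common position on the
binary-refinement axis, hence sharing S-levels ≈ 8–10) with ~30 known
interactions among the baits; co-express through a single latent
factor at pairwise correlation ρ = 0.7 over 40 conditions with 2%
missingness (the simplest model with a target ρ); share leaves of a
dedicated ontology branch (12 × 6 × 8 term tree, power-law leaf
popularity); and carry a +1.5 SD shift in 4 of 20 features. Labels are
the 25 baits (positive) and 90 random background proteins (negative,
≈ 1:4 — the published class-ratio regime); the similarity matrix is
low (≤ 0.25) with six planted near-duplicate pairs so homology
reduction has work to do. The `null` preset removes every signal
(p_in = p_out, ρ = 0, zero feature shift, no planted structures) while
keeping all background processes, so every channel still scores
targets under exchangeable noise. `strong` sharpens the signal for
demos. Bundles are byte-identical given (params, seed) — protein
draws are converted to plain strings and serialization is sorted — and
carry a SHA-256 content hash plus a per-file manifest.

What the generator does **not** emulate: literature text (the
co-citation network is sampled directly, with no sentence-level
structure); realistic domain grammar or architecture length
distributions; ontology depth heterogeneity and evidence codes;
expression batch structure; or correlated noise between channels.
Passing tests therefore demonstrate that the machinery recovers a
multi-channel signal and stays calibrated-or-conservative under a
null — not that any particular biological discovery would replicate.

## Problem sizes and numerics

The default test/benchmark sizes (n = 500, 30 full platform runs in
the statistical suites: 20 null seeds, 10 signal seeds) keep the whole
suite in a few minutes on one CPU; they are the package's chosen desk
scale, and all thresholds in the acceptance checks (held-out recovery
AUC > 0.8; integrated ≥ best single channel − 0.02) are evaluated as
means over those seeds. Numerical conventions: Fisher uses
`scipy.stats.chi2.sf` (log-scale survival, no underflow for the sizes
here); empirical p-values never reach 0 by construction; MI uses
plug-in estimates with 0·log 0 = 0; probits are clipped at 1e-12 for
the boundary p = 1; ranking ties break lexicographically; the
homology-reduction tie rule (most neighbours, then smallest
identifier) makes the retained set deterministic.

## File formats

All inputs and outputs are UTF-8 TSV with a header row, `NA` for
missing values and `#` comment lines carrying the config hash:
edge lists (`p1 p2 relation_class`), architectures
(`genome protein superfamilies` with comma-joined families),
clusterings (`protein family levels` with 11 comma-joined cluster
IDs), known interactions (`p1 p2 evidence_types species`), expression
and feature matrices (row = gene/protein, header = condition/feature),
annotations (`protein term`), term DAGs (`child parent`, or OBO via
obonet), reference sets (one identifier per line) and rankings
(`rank target p_spip p_<approach>...`). Readers validate column
contracts and name duplicates; writers round-trip losslessly.
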