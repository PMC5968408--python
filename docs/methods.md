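# Methods

## The network model

A claim-specific citation network restricts attention to the papers
addressing one scientific claim: a small set of primary studies `P`
(here, randomised trials) and the reviews `S` that cite them. The
graph is directed (citer → cited), acyclic by publication time, and
binary: a review citing the same trial in several passages contributes
one edge. All utilisation and bias measures are defined on the
review→primary edge set only; if a supplied corpus carries other edges
(review→review citations, say), they are preserved in the graph and
its exports but never enter `D`, the bias flags, the utilisation
histograms or the contingency table, since each measure compares a set
of reviews against the set of primaries.

Sub-graphs for a stance class keep *all* primary studies — including
ones that class never cites — plus the reviews of that class. The
vertex count of a class sub-graph is therefore
`|P| + |S_class|`, and the three class sub-graphs partition the
review→primary edges exactly.

Temporal validation allows same-year citations by default: publication
lag makes a 1969 review citing a 1969 paper unremarkable. A strict
mode forbids them. Violations are reported, never silently repaired.

## Density, bias, utilisation

`D = E / (|S| × |P|)` is stored as an exact integer ratio and reported
rounded to two decimals. It is undefined (an error, not 0/0) when the
scope contains no review or no primary.

A review's bias flag depends only on the stances of the primaries it
cites, not on the review's own stance: a review of any persuasion that
cites only supportive trials is biased toward "supportive". Reviews
citing exactly one primary are therefore always biased — single-citers
are the floor of the bias count. A review citing no primary violates
the usual inclusion criterion (every review cited at least one trial);
it is reported per-review rather than raising, so descriptive analyses
still run on imperfect corpora.

## Chi-square inference

The stance–citation association test is Pearson's chi-square of
independence on the counts table (review classes × primaries), without
continuity correction (the table is larger than 2×2):
`Χ² = Σ (O−E)²/E`, `E_ij = R_i C_j / N`, `df = (r−1)(c−1)`. The
p-value is the upper tail `Q(df/2, Χ²/2)` of the regularized
incomplete gamma function, computed by a power series for
`x < a + 1` and a modified-Lentz continued fraction otherwise, to a
relative tolerance of 1e-12 (tests verify agreement with an
independent gamma implementation to 1e-10 and with numerical
integration of the chi-square density to 1e-8). The standard validity
conditions (expected count > 5 in ≥80% of cells, ≥1 everywhere) are
computed and attached to every result but do not block the test: the
caller sees `conditions_met` and decides.

A zero row or column marginal makes an expected count zero; such
tables raise a degenerate-table error rather than dividing by zero.

## Synthetic corpora

`generate_corpus` draws each review→primary citation independently
with probability `π[review class][primary class]` — a stochastic block
structure expressing homophily (reviews preferentially citing trials
that share their stance). Primaries are published at the start of the
configured year range and reviews strictly later, so generated corpora
always pass temporal validation. A minimum-citation floor (default 1)
mirrors the inclusion criterion: a review left below the floor draws
additional distinct primaries uniformly. Everything is reproducible
from the config seed.

What the generator deliberately does *not* model: citation accrual
over time, reference-copying cascades between reviews (the information
cascade mechanism by which bibliographies propagate), quotation
accuracy, or trial outcomes. Passing tests on generated corpora
therefore demonstrate the correctness of the graph construction and
measures under independent citation choices, not that real citation
networks arise from independent choices.

### Realising a corpus from printed marginals

Published analyses often print only marginals: per-class out-degree
histograms and per-trial citation counts. `build_fixture_from_marginals`
checks each class block with the Gale–Ryser condition (a 0/1 matrix
with row sums `d` and column sums `c` exists iff the totals agree and
`Σ_{i≤k} d_i ≤ Σ_j min(c_j, k)` for every `k`), realises one incidence
greedily (largest-degree review first, fullest columns first, seeded
random tie-breaks), then mixes by checkerboard swaps, which preserve
every row and column sum. The result matches the profile's
contingency table and histograms exactly; the seed selects which valid
completion is returned.

A profile may additionally pin where the single-citing reviews point
(`singleton_allocation`), for sources that state this explicitly. For
the bundled study profile this matters only for the unsupportive
class: its bias count decomposes into reviews not citing the
supportive trial (forced by the marginals: class size minus that
trial's column count) plus single-citers pointing at it (stated in the
source; pinned at three). With the allocation pinned, every aggregate
the study reports — densities, degree totals, histograms, bias counts,
the contingency table — is invariant across completions, which is why
the acceptance values do not depend on the seed.

The trials in the bundled profile are the four secondary-prevention
diet trials (published 1965–1968; one supportive, three unsupportive),
and reviews receive years uniform on 1969–1984; the realised corpus
has 66 papers and 121 citations.

### Calibration and power

`power_simulation` estimates the test's size and power by replicated
generation. One modelling caveat matters: the chi-square reference
distribution presumes (product-)multinomial or Poisson cell sampling,
whereas the generator produces independent `Binomial(n_class, π)`
cells. For dense citation probabilities (π around 0.5) these cells
are markedly underdispersed relative to Poisson and the test is
conservative — the measured type-I rate can be far below α. In the
sparse regime the binomial approaches Poisson and the nominal level is
recovered; the calibration test uses π = 0.02 with 400 reviews per
class (expected cell counts ≈ 8, floor disabled) and checks the
rejection rate at α = 0.05 within three Monte-Carlo standard errors
over 1000 replicates. This is a property of the sampling model, not of
the test implementation, and is worth remembering when interpreting
chi-square p-values on real dense citation networks.

Degenerate replicates (a zero marginal) are counted and excluded from
the rates.

## Problem sizes and numerical choices

The test suite runs the full study reproduction (66 papers), property
tests on small random corpora (≤ 24 edges), the enumeration oracle for
the floor-adjusted expected density (exact over the 2⁴ citation
patterns of one review, 300 replicate corpora), parameter recovery at
200–400 reviews per class, and the 1000-replicate calibration above —
about 20 seconds end to end on one CPU. Vertex order is fixed by
sorted id everywhere, report JSON uses stable key order and carries
input digests instead of timestamps, so repeated runs are
byte-identical.

## Known limitations

* Stance classifications are input data; the package neither performs
  nor checks the quotation analysis that produces them.
* Binary adjacency discards citation multiplicity and prominence; a
  passing mention and a detailed critique weigh the same.
* The chi-square treats citations as the unit of count while reviews
  make correlated choices; see the calibration caveat above.
* Alias collapsing handles exact id aliases only (merged multi-paper
  publications); no fuzzy deduplication.
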