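"""Named pipeline defaults, each a single constant used everywhere."""

#: rarefaction depth for diversity analyses (reads per sample)
RAREFACTION_DEPTH = 22_000

#: abundance clause of the network filter: taxon total / grand total must
#: strictly exceed this fraction (0.01%)
MIN_REL_TOTAL = 1e-4

#: prevalence clause: present in at least ceil(frac * n_samples) samples
MIN_PREV_FRAC = 0.05

#: SparCC outer (Dirichlet) iterations for the point estimate
SPARCC_OUTER_ITERATIONS = 20

#: resamples for edge significance
SPARCC_RESAMPLES = 100

#: edge significance level
EDGE_ALPHA = 0.05

#: correlation magnitude threshold for an edge
CORRELATION_THRESHOLD = 0.3

#: thresholds for the sensitivity analysis
SENSITIVITY_THRESHOLDS = (0.2, 0.3, 0.4)

#: keystone composite weights (degree, closeness, transitivity, betweenness)
KEYSTONE_WEIGHTS = (0.25, 0.25, 0.25, 0.25)

#: fraction of nodes flagged as keystones
KEYSTONE_TOP_FRACTION = 0.10

#: permutations for the between-group topology comparison (library default;
#: the orchestrated pipeline uses a faster default, see pipeline module)
COMPARISON_PERMUTATIONS = 1000

#: permutations for distance-based community tests
DIVERSITY_PERMUTATIONS = 999
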