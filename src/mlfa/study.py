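"""Published reference summaries from the L.A. FANS collective-efficacy study.

The raw survey data (2,594 randomly selected adults in 65 Los Angeles census
tracts answering 10 five-category collective-efficacy items) is restricted
access, but the published analysis reports per-item intraclass correlations,
the within- and between-level polychoric correlation matrices, and the
rotated two-within / one-between factor solution.  Those printed values are
collected here: they calibrate the synthetic generator
(:func:`mlfa.simulate.default_study_config`) and serve as worked-example
inputs.
"""

import numpy as np

__all__ = [
    "ITEM_LABELS",
    "ICC_TABLE",
    "CORR_WITHIN",
    "CORR_BETWEEN",
    "EFA_LOADINGS_WITHIN",
    "EFA_LOADINGS_BETWEEN",
    "EFA_FACTOR_CORR_WITHIN",
    "CFA_LOADINGS_WITHIN",
    "CFA_LOADINGS_BETWEEN",
]

ITEM_LABELS = [
    "CLOSEKNIT",   # this is a close-knit neighborhood
    "ADULTS",      # there are adults that kids look up to
    "HELP",        # people here are willing to help their neighbors
    "ALONG",       # people here don't get along with each other (reverse coded)
    "SAFE",        # adults watch out that kids are safe
    "VALUES",      # people here do not share the same values (reverse coded)
    "TRUST",       # people in this neighborhood can be trusted
    "SKIP",        # would intervene: children skipping school, on the corner
    "GRAFFITI",    # would intervene: children spray-painting graffiti
    "DISRESPECT",  # would intervene: children showing disrespect to an adult
]

# Per-item ICCs: columns = total sample (N=2594), split half one (n=1291),
# split half two (n=1303).
ICC_TABLE = np.array([
    [0.083, 0.112, 0.121],
    [0.198, 0.253, 0.216],
    [0.133, 0.142, 0.174],
    [0.149, 0.148, 0.178],
    [0.085, 0.112, 0.089],
    [0.120, 0.174, 0.114],
    [0.203, 0.198, 0.254],
    [0.104, 0.131, 0.125],
    [0.262, 0.299, 0.273],
    [0.062, 0.093, 0.090],
])


def _sym(lower_rows):
    m = len(lower_rows) + 1
    R = np.eye(m)
    for i, row in enumerate(lower_rows, start=1):
        R[i, : len(row)] = row
        R[: len(row), i] = row
    return R


# Within-level (individual) polychoric correlations, split half one.
CORR_WITHIN = _sym([
    [0.461],
    [0.483, 0.467],
    [0.210, 0.310, 0.368],
    [0.395, 0.377, 0.458, 0.240],
    [0.153, 0.093, 0.165, 0.321, 0.141],
    [0.408, 0.422, 0.528, 0.309, 0.487, 0.234],
    [0.256, 0.207, 0.296, 0.174, 0.333, 0.124, 0.358],
    [0.219, 0.239, 0.283, 0.212, 0.358, 0.163, 0.294, 0.557],
    [0.287, 0.202, 0.285, 0.194, 0.261, 0.125, 0.278, 0.470, 0.476],
])

# Between-level (neighborhood) polychoric correlations, split half one.
CORR_BETWEEN = _sym([
    [0.735],
    [0.773, 0.862],
    [0.593, 0.758, 0.855],
    [0.749, 0.853, 0.897, 0.902],
    [0.561, 0.620, 0.668, 0.754, 0.705],
    [0.742, 0.842, 0.870, 0.834, 0.934, 0.653],
    [0.826, 0.641, 0.731, 0.677, 0.765, 0.650, 0.697],
    [0.729, 0.858, 0.870, 0.857, 0.865, 0.725, 0.823, 0.757],
    [0.489, 0.205, 0.478, 0.316, 0.254, 0.257, 0.320, 0.480, 0.382],
])

# Rotated (oblique) standardized ML-EFA loadings: two within factors
# (social cohesion; informal social control) and one between factor
# (collective efficacy).
EFA_LOADINGS_WITHIN = np.array([
    [0.618, 0.030],
    [0.642, -0.034],
    [0.735, 0.038],
    [0.418, -0.008],
    [0.630, 0.035],
    [0.297, 0.015],
    [0.773, -0.046],
    [0.121, 0.662],
    [0.001, 0.711],
    [-0.010, 0.723],
])

EFA_LOADINGS_BETWEEN = np.array(
    [0.797, 0.833, 0.935, 0.931, 0.972, 0.668, 0.924, 0.823, 0.917, 0.462]
).reshape(-1, 1)

EFA_FACTOR_CORR_WITHIN = 0.521

# Standardized ML-CFA loadings fitted on split half two (items 1-7 on the
# cohesion factor, items 8-10 on the control factor, one between factor).
CFA_LOADINGS_WITHIN = np.array(
    [0.622, 0.631, 0.701, 0.474, 0.649, 0.266, 0.681, 0.724, 0.769, 0.613]
)

CFA_LOADINGS_BETWEEN = np.array(
    [0.774, 0.824, 0.857, 0.828, 0.819, 0.807, 0.897, 0.667, 0.928, 0.353]
)
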