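"""Synthetic reconstruction of the published posterior coefficient draws.

The study's full posterior samples are deposited in an external research
archive rather than shipped with this package. For
post-processing checks (threshold probabilities, mother-father contrasts)
this module builds a SYNTHETIC stand-in: independent normal draws per
regression coefficient, parameterised by the published posterior means and
standard deviations. The normal approximation is adequate here because the
published means and medians coincide to ~0.02 and the published SD of the
mother-father coefficient difference (0.40) matches the independence value
sqrt(0.23^2 + 0.33^2) = 0.402, so the joint posterior of the two
coefficients is close to an independent bivariate normal.

These draws are a reconstruction, not the deposited samples; quantities
computed from them agree with the published derived summaries only as well
as the normal approximation allows.
"""

from __future__ import annotations

import numpy as np

# published posterior mean and SD of the hopelessness regression
# coefficients (informant-discrepancy and adolescent-report models,
# per parent role)
PUBLISHED_COEFFICIENT_SUMMARIES = {
    ("discrepancy", "mother"): (-0.25, 0.23),
    ("discrepancy", "father"): (-0.42, 0.33),
    ("adolescent", "mother"): (0.08, 0.19),
    ("adolescent", "father"): (0.06, 0.19),
}


def reconstructed_coefficient_draws(seed: int = 0, n_draws: int = 20000) -> dict:
    """Synthetic normal draws per (variant, role) coefficient.

    Returns a dict keyed like :data:`PUBLISHED_COEFFICIENT_SUMMARIES` with
    ``n_draws`` posterior draws each; coefficients are drawn independently
    (see module docstring for why that is defensible).
    """
    rng = np.random.default_rng(seed)
    return {
        key: rng.normal(mean, sd, size=n_draws)
        for key, (mean, sd) in PUBLISHED_COEFFICIENT_SUMMARIES.items()
    }
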