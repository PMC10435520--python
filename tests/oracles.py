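"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the FDR oracle
literally scans candidate rejection counts per the two-stage definition,
and the labelling oracle is a set of hand-derived closed-form polynomials
in the flux fractions.
"""

from __future__ import annotations

import numpy as np


def stepup_count_brute(p_sorted, level, denom) -> int:
    """Largest k with p_(k) <= k * level / denom, by explicit scan."""
    for k in range(len(p_sorted), 0, -1):
        if p_sorted[k - 1] <= k * level / denom:
            return k
    return 0


def bky_reject_brute(pvals, q) -> np.ndarray:
    """Two-stage step-up rejection mask, straight from the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    qp = q / (1.0 + q)
    ps = np.sort(p)
    r1 = stepup_count_brute(ps, qp, m)
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    r2 = stepup_count_brute(ps, qp, m0)
    if r2 == 0:
        return np.zeros(m, bool)
    return p <= ps[r2 - 1]


def bh_reject_brute(pvals, q) -> np.ndarray:
    """Plain linear step-up rejection mask by explicit scan."""
    p = np.asarray(pvals, float)
    ps = np.sort(p)
    r = stepup_count_brute(ps, q, p.size)
    if r == 0:
        return np.zeros(p.size, bool)
    return p <= ps[r - 1]


def closed_form_glucose(f_pc: float, f_pdh: float, g: float) -> dict[str, float]:
    """Hand-derived first-turn labelling statistics under the glucose tracer.

    With a = f_pc*g (P(oxaloacetate is m+3)) and b = f_pdh*g
    (P(acetyl-CoA is m+2)), citrate's condensation MID is
    {m0: (1-a)(1-b), m2: b(1-a), m3: a(1-b), m5: ab}, so

      fraction_enrichment(citrate)      = a + b - ab
      pc_pdh_ratio(citrate)             = a(1-b) / (b(1-a))
      carbon_pool_contribution(citrate) = (3a + 2b) / 6

    One uniform carbon loss (6C -> 5C) gives AKG m3 = a(1-b)/2 and
    m4 = 5ab/6; a second loss (5C -> 4C) gives oxidative malate
    m3 = (2/5)*a(1-b)/2 + (4/5)*5ab/6 = a(1-b)/5 + 2ab/3, and the
    malate/aspartate pool mixes in fresh PC-derived oxaloacetate:

      pc_activity(aspartate) = f_pc*g + (1-f_pc)*(a(1-b)/5 + 2ab/3)
    """
    a = f_pc * g
    b = f_pdh * g
    return {
        "fraction_enrichment_citrate": a + b - a * b,
        "pc_pdh_ratio_citrate": a * (1 - b) / (b * (1 - a)),
        "carbon_pool_contribution_citrate": (3 * a + 2 * b) / 6.0,
        "pc_activity_aspartate": f_pc * g
        + (1 - f_pc) * (a * (1 - b) / 5.0 + 2.0 * a * b / 3.0),
    }
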