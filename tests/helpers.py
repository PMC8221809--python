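"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive results by brute force / direct enumeration and
must stay independent of the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up, plain loops."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return np.array(q)


def huang_oracle(image) -> float:
    """Exhaustive search over candidate thresholds of Huang's fuzzy criterion."""
    flat = np.asarray(image).ravel().astype(float)
    levels, counts = np.unique(flat, return_counts=True)
    assert levels.size >= 2
    c = levels[-1] - levels[0]
    best_s, best_k = np.inf, None
    for k in range(levels.size - 1):
        lower_levels, lower_counts = levels[: k + 1], counts[: k + 1]
        upper_levels, upper_counts = levels[k + 1 :], counts[k + 1 :]
        m0 = np.average(lower_levels, weights=lower_counts)
        m1 = np.average(upper_levels, weights=upper_counts)
        s = 0.0
        for g, w in zip(levels, counts):
            mclass = m0 if g <= levels[k] else m1
            mu = 1.0 / (1.0 + abs(g - mclass) / c)
            if 0.0 < mu < 1.0:
                s += w * (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu))
        if s < best_s:
            best_s, best_k = s, k
    return float(0.5 * (levels[best_k] + levels[best_k + 1]))


def species_fraction_oracle(binding_log10, ph, mg):
    """Direct summation of bound-species fractions for each reactant.

    Returns the binding polynomials {atp, adp, pi, pcr} by enumerating every
    complex explicitly, one term per species.
    """
    b = {k: 10.0**v for k, v in binding_log10.items()}
    h = 10.0**-ph
    species = {
        "atp": [("H", h * b["h_atp"]), ("Mg", mg * b["mg_atp"]),
                ("MgH", h * b["h_atp"] * mg * b["mg_hatp"])],
        "adp": [("H", h * b["h_adp"]), ("Mg", mg * b["mg_adp"]),
                ("MgH", h * b["h_adp"] * mg * b["mg_hadp"])],
        "pi": [("H", h * b["h_pi"]), ("Mg", mg * b["mg_pi"])],
        "pcr": [("H", h * b["h_pcr"]), ("Mg", mg * b["mg_pcr"])],
    }
    out = {}
    for name, terms in species.items():
        total = 1.0
        for _, weight in terms:
            total += weight
        out[name] = total
    return out
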