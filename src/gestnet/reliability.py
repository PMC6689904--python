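"""Inter-coder agreement on nominal sequence codes.

Unweighted Cohen's kappa, kappa = (p_o - p_e) / (1 - p_e), with observed
agreement p_o and chance agreement p_e from the product of the two coders'
marginals.  Per-response-type reliability follows the field convention of
binarizing each category to present/absent per sequence and computing one
kappa per category.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohens_kappa", "kappa_report"]


def cohens_kappa(pairs: pd.DataFrame) -> float:
    """Kappa for a two-coder table with columns ``coder1`` and ``coder2``.

    Degenerate marginals (p_e = 1, both coders constant) yield kappa = 1
    under perfect agreement and are an error under disagreement, where the
    chance-corrected statistic is undefined.
    """
    if pairs.empty:
        raise ValueError("no coding pairs supplied")
    c1 = pairs["coder1"].astype(str)
    c2 = pairs["coder2"].astype(str)
    n = len(pairs)
    p_o = float((c1.to_numpy() == c2.to_numpy()).mean())
    cats = sorted(set(c1) | set(c2))
    m1 = c1.value_counts(normalize=True)
    m2 = c2.value_counts(normalize=True)
    p_e = float(sum(m1.get(c, 0.0) * m2.get(c, 0.0) for c in cats))
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError(
            "degenerate marginals: chance agreement is 1 but coders disagree"
        )
    return (p_o - p_e) / (1.0 - p_e)


def kappa_report(
    pairs: pd.DataFrame, categories: list[str] | None = None
) -> pd.DataFrame:
    """One kappa per response type, on presence/absence binarizations.

    ``pairs`` holds each coder's category per sequence (with ``"absent"``
    for no response).  The report contains a row for overall response
    presence/absence and one per category (was *this* category judged
    present), mirroring per-response-type reliability reporting.  Groups
    where a category never occurs for either coder are flagged degenerate
    and get no kappa.
    """
    if pairs.empty:
        raise ValueError("no coding pairs supplied")
    c1 = pairs["coder1"].astype(str)
    c2 = pairs["coder2"].astype(str)
    if categories is None:
        categories = sorted((set(c1) | set(c2)) - {"absent"})

    rows = []
    binarizations = [("response_presence", c1 != "absent", c2 != "absent")]
    binarizations += [(cat, c1 == cat, c2 == cat) for cat in categories]
    for name, b1, b2 in binarizations:
        sub = pd.DataFrame({"coder1": b1, "coder2": b2})
        try:
            k = cohens_kappa(sub)
            degenerate = False
        except ValueError:
            k, degenerate = float("nan"), True
        rows.append({"code": name, "kappa": k, "degenerate": degenerate,
                     "n_items": len(sub)})
    return pd.DataFrame(rows)
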