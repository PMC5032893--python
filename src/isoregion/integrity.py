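"""Local correspondence: Distinctiveness, Dominance, chance adjustment, and
Regional Integrity.

For a contingency table n_kl (region k x genetic cluster l, margins n_k, n_l,
total n):

* Distinctiveness  DIS_k = sum_l n_kl^2 / (n_k * n_l) — a location-quotient
  style measure, rescaled to (0, 1], of how exclusively region k's clusters
  occur in region k.  Its chance expectation is the region's share of
  observations, n_k / n.
* Dominance  DOM_k = sum_l (n_kl / n_k)^2 — the Simpson dominance index: the
  probability that two individuals drawn from region k share a cluster.  Its
  chance expectation under random cluster assignment is 1/L, with L the number
  of clusters present in the full table.
* Both are chance-adjusted as (actual - expected) / (maximum - expected) with
  maximum 1, so 0 means randomness and 1 perfect departure from it.
* Regional Integrity  RI_k = DIS_k.adj * DOM_k.adj, with negative adjusted
  components clamped to 0 first so two negatives cannot fake positive
  integrity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .correspondence import Contingency
from .types import ValidationError

__all__ = [
    "distinctiveness",
    "dominance",
    "adjust_index",
    "regional_integrity",
    "integrity_table",
]


def _check_rows(c: Contingency) -> None:
    empty = c.row_margins[c.row_margins == 0]
    if len(empty):
        raise ValidationError(f"region(s) with no observations: {list(empty.index)[:5]}")


def distinctiveness(c: Contingency) -> pd.Series:
    """DIS_k per region (row) of the contingency table."""
    _check_rows(c)
    m = c.table.to_numpy(dtype=float)
    n_k = m.sum(axis=1)
    n_l = m.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(n_l > 0, m**2 / np.outer(n_k, np.where(n_l > 0, n_l, 1.0)), 0.0)
    return pd.Series(terms.sum(axis=1), index=c.table.index, name="DIS")


def dominance(c: Contingency) -> pd.Series:
    """Simpson Dominance DOM_k per region of the contingency table."""
    _check_rows(c)
    m = c.table.to_numpy(dtype=float)
    n_k = m.sum(axis=1)
    return pd.Series(((m / n_k[:, None]) ** 2).sum(axis=1), index=c.table.index, name="DOM")


def adjust_index(actual, expected, maximum: float = 1.0):
    """(actual - expected) / (maximum - expected); 0 when degenerate.

    Accepts scalars or aligned pandas/numpy vectors.  Where expected equals the
    maximum (e.g. a single region holding the whole sample) the adjusted value
    is defined as 0 with a warning.
    """
    actual = np.asarray(actual, dtype=float)
    expected = np.asarray(expected, dtype=float)
    denom = maximum - expected
    degenerate = denom <= 0
    if np.any(degenerate):
        warnings.warn("expected value equals the maximum; adjusted index set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(degenerate, 0.0, (actual - expected) / np.where(degenerate, 1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out


def regional_integrity(dis_adj, dom_adj):
    """RI = clamp(DIS_adj, 0) * clamp(DOM_adj, 0), elementwise."""
    dis = np.clip(np.asarray(dis_adj, dtype=float), 0.0, None)
    dom = np.clip(np.asarray(dom_adj, dtype=float), 0.0, None)
    out = dis * dom
    if out.ndim == 0:
        return float(out)
    return out


def integrity_table(c: Contingency) -> pd.DataFrame:
    """Per-region table of n_k, DIS, DOM, adjusted versions, and RI."""
    dis = distinctiveness(c)
    dom = dominance(c)
    n_k = c.row_margins.astype(float)
    n = float(c.n)
    n_clusters = int((c.col_margins > 0).sum())
    exp_dis = (n_k / n).to_numpy()
    exp_dom = 1.0 / n_clusters
    dis_adj = adjust_index(dis.to_numpy(), exp_dis)
    dom_adj = adjust_index(dom.to_numpy(), np.full(len(n_k), exp_dom))
    ri = regional_integrity(dis_adj, dom_adj)
    return pd.DataFrame(
        {
            "n_k": c.row_margins,
            "DIS": dis,
            "DOM": dom,
            "DIS_adj": dis_adj,
            "DOM_adj": dom_adj,
            "RI": ri,
        },
        index=c.table.index,
    )
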