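"""Thresholded co-expression networks over screened features.

Edges connect feature pairs whose Pearson correlation of normalized log2
expression exceeds a threshold (default R > 0.6, positive correlations only);
features co-expressing with no other feature are dropped from the graph.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd


def correlation_graph(
    expr: pd.DataFrame,
    features: list[str] | None = None,
    threshold: float = 0.6,
    use_abs: bool = False,
    inclusive: bool = False,
) -> nx.Graph:
    """Build the co-expression graph over ``features`` (default: all rows).

    Pearson R is computed on the normalized values across samples for every
    pair; an edge is added iff R > threshold (or |R| with ``use_abs``, or >=
    with ``inclusive``). Nodes of degree 0 are dropped; constant features are
    excluded with a warning. Edge attribute ``weight`` stores R.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation graph needs >= 3 samples")
    sub = expr if features is None else expr.loc[features]
    arr = sub.to_numpy(dtype=float)
    sds = arr.std(axis=1)
    if (sds == 0).any():
        dropped = sub.index[sds == 0].tolist()
        warnings.warn(f"excluding {len(dropped)} constant feature(s): {dropped[:5]}", stacklevel=2)
        sub = sub.loc[sds > 0]
        arr = arr[sds > 0]
    ids = list(sub.index)
    g: nx.Graph = nx.Graph()
    if len(ids) < 2:
        return g
    cor = np.corrcoef(arr)
    vals = np.abs(cor) if use_abs else cor
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = vals[iu, ju] >= threshold if inclusive else vals[iu, ju] > threshold
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(ids[i], ids[j], weight=float(cor[i, j]))
    return g


def graph_components(g: nx.Graph) -> tuple[list[set], dict]:
    """Connected components (largest first) and per-node degree."""
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    return comps, dict(g.degree())
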