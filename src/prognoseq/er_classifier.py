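"""Estrogen-receptor status calls from normalized ESR1/PGR expression.

ESR1 expression in breast tumors is strongly bimodal; patients are called
ER-positive when normalized ESR1 expression is at or above a cutoff. When no
explicit cutoff is given, each marker's cutoff defaults to the midpoint
between the two component means of a two-component Gaussian mixture fitted
with deterministic initialization (means at the 25th/75th percentiles, equal
weights, shared variance). PGR is used only for a consistency flag: tumors
that are PGR-positive but ER-negative (or vice versa) are rare, so discordant
calls are reported for review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture


class CutoffError(ValueError):
    """Mixture fit degenerate (unimodal/collapsed); pass explicit cutoffs."""


@dataclass(frozen=True)
class ERCall:
    sample_id: str
    esr1: float
    pgr: float
    status: str  # "positive" | "negative"
    esr1_cutoff: float
    pgr_cutoff: float
    pgr_discordant: bool


def mixture_midpoint_cutoff(values: np.ndarray, min_separation: float = 1.0) -> float:
    """Midpoint between the two component means of a 1-D Gaussian mixture.

    Deterministic: weights start at 0.5/0.5, means at the 25th/75th
    percentiles, both precisions at 1/var. Raises :class:`CutoffError` when
    the fitted components are separated by fewer than ``min_separation``
    pooled SDs (no usable bimodality).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 4:
        raise CutoffError("too few samples to fit a mixture; pass an explicit cutoff")
    var = float(x.var())
    if var == 0:
        raise CutoffError("constant marker values; pass an explicit cutoff")
    q25, q75 = np.percentile(x, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        weights_init=[0.5, 0.5],
        means_init=[[q25], [q75]],
        precisions_init=[[[1.0 / var]], [[1.0 / var]]],
        random_state=0,
        max_iter=500,
    )
    gm.fit(x)
    m1, m2 = sorted(gm.means_.ravel())
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    if pooled_sd == 0 or (m2 - m1) / pooled_sd < min_separation:
        raise CutoffError(
            f"mixture components too close (separation {(m2 - m1) / max(pooled_sd, 1e-300):.2f} "
            "pooled SDs); the marker looks unimodal — pass an explicit cutoff"
        )
    return float((m1 + m2) / 2.0)


def call_er_status(
    esr1: Sequence[float],
    pgr: Sequence[float],
    sample_ids: Sequence[str] | None = None,
    esr1_cutoff: float | None = None,
    pgr_cutoff: float | None = None,
) -> list[ERCall]:
    """Call ER status per sample: positive iff esr1 >= esr1_cutoff.

    Cutoffs default to the mixture midpoint of the corresponding marker.
    Monotone in ESR1 (raising a sample's ESR1 never flips positive to
    negative) and deterministic under the fixed initialization.
    """
    esr1 = np.asarray(esr1, dtype=float)
    pgr = np.asarray(pgr, dtype=float)
    if esr1.shape != pgr.shape:
        raise ValueError("esr1 and pgr vectors must align")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(len(esr1))]
    if esr1_cutoff is None:
        esr1_cutoff = mixture_midpoint_cutoff(esr1)
    if pgr_cutoff is None:
        pgr_cutoff = mixture_midpoint_cutoff(pgr)
    calls = []
    for sid, e, p in zip(sample_ids, esr1, pgr):
        positive = e >= esr1_cutoff
        pgr_positive = p >= pgr_cutoff
        calls.append(
            ERCall(
                sample_id=sid,
                esr1=float(e),
                pgr=float(p),
                status="positive" if positive else "negative",
                esr1_cutoff=float(esr1_cutoff),
                pgr_cutoff=float(pgr_cutoff),
                pgr_discordant=bool(positive != pgr_positive),
            )
        )
    return calls
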