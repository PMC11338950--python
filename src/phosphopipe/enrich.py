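"""Generic over-representation analysis against user-supplied gene sets.

Hypergeometric upper-tail test of a hit list against a background, with
Benjamini-Hochberg adjustment — the standard ORA used for GO/KEGG-style
annotation of differentially regulated proteins. Set membership is
intersected with the background before counting, and the background defaults
(at the pipeline level) to all proteins quantified in the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet


@dataclass
class ORAResult:
    set_name: str
    k: int  # hits in set
    K: int  # set size within background
    n: int  # hit-list size
    N: int  # background size
    p_value: float
    q_value: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_test(
    hits: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
) -> list[ORAResult]:
    """Upper-tail hypergeometric ORA of ``hits`` against each gene set.

    For a set with K members in the background of size N, and n hits of which
    k fall in the set, p = P(X >= k) for X ~ Hypergeometric(N, K, n). Sets
    with no members in the background are omitted.
    """
    hits = frozenset(hits)
    background = frozenset(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    N, n = len(background), len(hits)
    kept: list[tuple[str, int, int]] = []
    for s in sets:
        members = s.members & background
        if not members:
            continue
        kept.append((s.name, len(members & hits), len(members)))
    p = np.array(
        [stats.hypergeom.sf(k - 1, N, K, n) for _, k, K in kept], dtype=float
    )
    q = bh_adjust(np.clip(p, 0.0, 1.0)) if len(p) else np.array([])
    return [
        ORAResult(name, k, K, n, N, float(pv), float(qv))
        for (name, k, K), pv, qv in zip(kept, p, q)
    ]


def ora_frame(results: Sequence[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
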