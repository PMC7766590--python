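"""Connectivity-map-style signature-reversal scoring.

Scores how strongly each reference perturbagen's expression profile
reverses (or mimics) a query up/down gene signature:

* ``weighted_enrichment_score`` — weighted Kolmogorov-Smirnov running-sum
  statistic of a gene set along the perturbagen's score-ranked gene list
  (weight exponent 1 on |score|),
* ``combined_score`` — WTCS = (ES_up - ES_down)/2 when the two enrichment
  scores disagree in sign, else 0,
* ``normalize_scores`` — NCS: WTCS divided by the mean |WTCS| of same-sign
  members of the same perturbagen group,
* ``tau_percentile`` — signed percentile of |NCS| against a touchstone
  distribution, in [-100, 100].

Negative tau marks perturbagens expected to induce the opposite signature
to the query, i.e. candidate reversers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signature import GeneSignature

__all__ = [
    "ReferenceSignatureLibrary",
    "ConnectivityResult",
    "weighted_enrichment_score",
    "combined_score",
    "normalize_scores",
    "tau_percentile",
    "query_library",
]


@dataclass
class ReferenceSignatureLibrary:
    """Perturbagen x gene differential-expression score matrix."""

    perturbagens: list[str]
    genes: list[str]
    scores: np.ndarray  # shape (n_perturbagens, n_genes)
    groups: list[str] | None = None  # optional cell/context label per perturbagen

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.perturbagens)) != len(self.perturbagens):
            raise ValueError("duplicate perturbagen ids")
        if self.scores.shape != (len(self.perturbagens), len(self.genes)):
            raise ValueError("scores shape does not match perturbagens x genes")
        if not np.isfinite(self.scores).any(axis=1).all():
            raise ValueError("every perturbagen row needs >=1 finite score")
        if self.groups is not None and len(self.groups) != len(self.perturbagens):
            raise ValueError("groups length must match perturbagens")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: list[str] | None = None) -> "ReferenceSignatureLibrary":
        """Build from a perturbagen x gene DataFrame (e.g. a parsed GCT)."""
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.perturbagens, columns=self.genes)


@dataclass
class ConnectivityResult:
    perturbagen: str
    es_up: float
    es_down: float
    wtcs: float
    ncs: float
    tau: float


def _rank_order(scores: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    """Indices sorting genes by score descending, ties by gene id."""
    lex = np.argsort(np.asarray(genes, dtype=object))
    # pre-permute into lexicographic order, then a stable sort on -score
    order_within = np.argsort(-scores[lex], kind="stable")
    return lex[order_within]


def weighted_enrichment_score(
    ranked_scores: Mapping[str, float],
    query_set: set[str],
) -> float:
    """Weighted KS enrichment of ``query_set`` along the score-ranked gene list.

    Hits advance the running sum by |score| / sum(|score| over the set);
    misses retreat by 1/(N - N_hits).  The ES is the extremum of largest
    magnitude (positive on an exact tie).
    """
    genes = list(ranked_scores.keys())
    scores = np.array([ranked_scores[g] for g in genes], dtype=float)
    hit = np.array([g in query_set for g in genes])
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits != len(query_set):
        missing = sorted(query_set - set(genes))
        if missing:
            raise ValueError(f"query genes outside universe: {missing[:5]}")
    if n_hits == 0 or n_hits == len(genes):
        raise ValueError("query set must be a non-empty proper subset of the universe")
    order = _rank_order(scores, genes)
    return _es_from_ordered(scores[order], hit[order])


def _es_from_ordered(scores: np.ndarray, hit: np.ndarray) -> float:
    n = scores.size
    n_hits = int(hit.sum())
    weight = np.abs(scores[hit])
    total = weight.sum()
    steps = np.empty(n)
    if total > 0:
        steps[hit] = weight / total
    else:  # degenerate all-zero hit scores: fall back to equal weights
        steps[hit] = 1.0 / n_hits
    steps[~hit] = -1.0 / (n - n_hits)
    running = np.cumsum(steps)
    hi = float(running.max())
    lo = float(running.min())
    # positive extremum wins ties (to float precision)
    return hi if hi >= -lo - 1e-9 * max(hi, -lo, 1.0) else lo


def combined_score(es_up: float, es_down: float) -> float:
    """WTCS: (ES_up - ES_down)/2 if the signs differ or either is 0, else 0."""
    for v in (es_up, es_down):
        if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
            raise ValueError("enrichment scores must lie in [-1, 1]")
    es_up = float(np.clip(es_up, -1.0, 1.0))
    es_down = float(np.clip(es_down, -1.0, 1.0))
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def normalize_scores(
    wtcs: Sequence[float],
    grouping: Sequence[str] | None = None,
) -> np.ndarray:
    """NCS: divide each WTCS by the mean |WTCS| of same-sign members of its group."""
    w = np.asarray(wtcs, dtype=float)
    groups = np.asarray(grouping if grouping is not None else ["all"] * w.size, dtype=object)
    ncs = np.zeros_like(w)
    for grp in np.unique(groups):
        in_grp = groups == grp
        for sign in (1.0, -1.0):
            sel = in_grp & (np.sign(w) == sign)
            if sel.any():
                # sort before averaging so the result is invariant to
                # perturbagen order (float summation is not associative)
                ncs[sel] = w[sel] / np.sort(np.abs(w[sel])).mean()
    return ncs


def tau_percentile(ncs: float, touchstone_abs_ncs: Sequence[float]) -> float:
    """Signed percentile of |ncs| against the touchstone |NCS| distribution."""
    ts = np.asarray(touchstone_abs_ncs, dtype=float)
    if ts.size == 0:
        raise ValueError("touchstone distribution is empty")
    frac = float(np.mean(ts < abs(ncs)))
    return float(np.sign(ncs)) * 100.0 * frac


def query_library(
    sig: GeneSignature,
    lib: ReferenceSignatureLibrary,
    tau_threshold: float = 0.0,
) -> tuple[list[ConnectivityResult], list[str]]:
    """Score every perturbagen against the signature and select reversers.

    Signature genes absent from the library universe are dropped; an empty
    up or down set after filtering is an error.  Results come back sorted by
    tau ascending; the selection is the perturbagens with ``tau <
    tau_threshold`` (default 0, i.e. negative-tau chemicals).
    """
    universe = set(lib.genes)
    up = sig.up & universe
    down = sig.down & universe
    dropped = sorted(sig.genes - universe)
    if not up or not down:
        raise ValueError(f"signature empty after filtering to library universe; dropped: {dropped[:10]}")

    genes = np.asarray(lib.genes, dtype=object)
    lex = np.argsort(genes)
    up_mask = np.isin(genes, sorted(up))
    down_mask = np.isin(genes, sorted(down))

    es_up = np.empty(len(lib.perturbagens))
    es_down = np.empty(len(lib.perturbagens))
    for i in range(len(lib.perturbagens)):
        row = lib.scores[i]
        order = lex[np.argsort(-row[lex], kind="stable")]
        es_up[i] = _es_from_ordered(row[order], up_mask[order])
        es_down[i] = _es_from_ordered(row[order], down_mask[order])

    wtcs = np.array([combined_score(u, d) for u, d in zip(es_up, es_down)])
    ncs = normalize_scores(wtcs, lib.groups)
    touchstone = np.abs(ncs)
    tau = np.array([tau_percentile(v, touchstone) for v in ncs])

    results = [
        ConnectivityResult(p, float(es_up[i]), float(es_down[i]), float(wtcs[i]), float(ncs[i]), float(tau[i]))
        for i, p in enumerate(lib.perturbagens)
    ]
    results.sort(key=lambda r: (r.tau, r.perturbagen))
    selection = [r.perturbagen for r in results if r.tau < tau_threshold]
    return results, selection


def results_to_frame(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbagen": [r.perturbagen for r in results],
            "es_up": [r.es_up for r in results],
            "es_down": [r.es_down for r in results],
            "wtcs": [r.wtcs for r in results],
            "ncs": [r.ncs for r in results],
            "tau": [r.tau for r in results],
        }
    )
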