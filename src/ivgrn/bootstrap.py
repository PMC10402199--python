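"""Bootstrap aggregation of network fits into edge-confidence frequencies.

Observations (rows of Y and the instrument pool, jointly) are resampled
with replacement; the two-stage fit is repeated on each resample with the
instrument sets held fixed from the original data; the B binary
adjacency matrices are averaged componentwise into the frequency matrix,
which is thresholded into a confidence network.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import BootstrapSummary, ExpressionMatrix, RegulatoryNetwork, ThresholdedGraph
from .spls import TwoStagePLS, _derived_seed

__all__ = ["bootstrap_networks", "aggregate", "threshold", "BootstrapNetwork"]


def bootstrap_networks(Y: ExpressionMatrix, pool: np.ndarray,
                       pool_index: dict[str, list[int]], B: int, seed: int = 0,
                       indices: list[np.ndarray] | None = None,
                       **params) -> list[RegulatoryNetwork]:
    """Fit B networks on with-replacement resamples of the observations.

    Rows of Y and of the instrument pool are resampled jointly with the
    same indices. ``indices`` overrides the resampling (one index array
    per bootstrap) for degenerate/diagnostic runs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = Y.n_samples
    rng = np.random.default_rng(seed)
    nets = []
    for b in range(B):
        idx = rng.integers(0, n, size=n) if indices is None else np.asarray(indices[b])
        Yb = ExpressionMatrix(Y.values[idx], [f"s{i}" for i in range(n)], list(Y.gene_ids))
        pool_b = pool[idx]
        est = TwoStagePLS(**{**params, "seed": _derived_seed(params.get("seed", seed), 7, b)})
        nets.append(est.fit(Yb, pool_b, pool_index).network_)
    return nets


def aggregate(nets: list[RegulatoryNetwork]) -> BootstrapSummary:
    """Componentwise average of adjacency matrices: frequency = (1/B) sum A(b)."""
    if not nets:
        raise ValueError("no networks to aggregate")
    genes = nets[0].gene_ids
    for net in nets[1:]:
        if net.gene_ids != genes:
            raise ValueError("networks have mismatched gene sets")
    counts = np.zeros((len(genes), len(genes)), dtype=np.int64)
    for net in nets:
        counts += net.adjacency.toarray().astype(np.int64)
    return BootstrapSummary(counts, len(nets), genes)


def threshold(summary: BootstrapSummary, cutoff: float) -> ThresholdedGraph:
    """Edges kept where frequency >= cutoff (inclusive); cutoff in (0, 1]."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    # compare on integer counts so the boundary is exact
    need = cutoff * summary.n_bootstraps
    E = (summary.counts >= need - 1e-9).astype(np.int8)
    np.fill_diagonal(E, 0)
    return ThresholdedGraph(E, cutoff, list(summary.gene_ids))


class BootstrapNetwork(BaseEstimator):
    """Bootstrap-aggregated network estimator.

    ``fit(Y, pool, pool_index)`` fits ``n_bootstraps`` resampled networks
    (plus, optionally, the original-data network) and exposes
    ``summary_`` (edge frequencies), ``networks_`` and a
    ``threshold(cutoff)`` convenience.
    """

    def __init__(self, n_bootstraps: int = 1000, seed: int = 0,
                 keep_networks: bool = False, **spls_params):
        self.n_bootstraps = n_bootstraps
        self.seed = seed
        self.keep_networks = keep_networks
        self.spls_params = spls_params

    def get_params(self, deep: bool = True) -> dict:
        return {"n_bootstraps": self.n_bootstraps, "seed": self.seed,
                "keep_networks": self.keep_networks, **self.spls_params}

    def set_params(self, **params) -> "BootstrapNetwork":
        for key in ("n_bootstraps", "seed", "keep_networks"):
            if key in params:
                setattr(self, key, params.pop(key))
        self.spls_params.update(params)
        return self

    def fit(self, Y: ExpressionMatrix, pool: np.ndarray,
            pool_index: dict[str, list[int]], y=None) -> "BootstrapNetwork":
        nets = bootstrap_networks(Y, pool, pool_index, self.n_bootstraps,
                                  seed=self.seed, **self.spls_params)
        self.summary_ = aggregate(nets)
        if self.keep_networks:
            self.networks_ = nets
        return self

    def threshold(self, cutoff: float) -> ThresholdedGraph:
        return threshold(self.summary_, cutoff)
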