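"""Scoring, ROC/AUC, conditional densities, edge ranking and the
noise-robustness experiment driver.

Pairs are scored by their Euclidean distance in the embedding space —
lower means more likely to interact.  A pair is classified as interacting
when its distance falls below a threshold; sweeping the threshold from 0
to the maximum distance traces the ROC curve.  The AUC is computed
rank-based (the probability that a random interacting pair scores lower
than a random non-interacting pair, ties counted half), which is exact
and free of threshold-grid artifacts; the sweep is still emitted for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, rankdata

from .graph_io import Network, _non_edge_pool, sample_non_edge_indices
from .model import Embedding

__all__ = ["EvalReport", "score_pairs", "roc_and_auc", "auc_score",
           "conditional_densities", "rank_edges", "evaluate_embedding",
           "noise_experiment"]


@dataclass
class Densities:
    grid: np.ndarray
    pos: np.ndarray
    neg: np.ndarray


@dataclass
class EvalReport:
    """ROC sweep + exact AUC (+ optional conditional densities)."""

    thresholds: np.ndarray
    roc_points: np.ndarray  # (k, 2): (1 - specificity, sensitivity)
    counts: np.ndarray  # (k, 4): TP, TN, FP, FN
    auc: float
    densities: Densities | None = None


def score_pairs(emb: Embedding, pairs) -> np.ndarray:
    """Euclidean embedding distances for index pairs (lower = more likely
    interacting)."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return emb.distances(pairs)


def auc_score(pos_scores, neg_scores) -> float:
    """Rank-based AUC: P(pos < neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_neg = ranks[len(pos):].sum()
    u = r_neg - len(neg) * (len(neg) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_and_auc(pos_scores, neg_scores) -> EvalReport:
    """Threshold sweep over all distinct scores (plus 0 and the maximum)
    with sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP); the AUC
    is rank-based.  A leading -inf threshold anchors the (0, 0) corner."""
    pos = np.sort(np.asarray(pos_scores, dtype=float))
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be nonempty")
    hi = max(pos[-1], neg[-1])
    thr = np.unique(np.concatenate([[-np.inf, 0.0], pos, neg, [hi]]))
    tp = np.searchsorted(pos, thr, side="right").astype(float)
    fp = np.searchsorted(neg, thr, side="right").astype(float)
    fn = len(pos) - tp
    tn = len(neg) - fp
    sens = tp / len(pos)
    fpr = fp / len(neg)
    return EvalReport(
        thresholds=thr,
        roc_points=np.column_stack([fpr, sens]),
        counts=np.column_stack([tp, tn, fp, fn]),
        auc=auc_score(pos, neg),
    )


def conditional_densities(
    pos_scores, neg_scores, bw_method: str | float = "silverman",
    grid_size: int = 512,
) -> Densities:
    """Gaussian KDE estimates of p(Distance|Interaction) and
    p(Distance|Non-interaction) on a shared grid (each integrates to 1
    within quadrature tolerance)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 scores per class")

    def bw_of(x):
        if np.ptp(x) == 0.0:
            return 0.0
        return float(np.sqrt(gaussian_kde(x, bw_method=bw_method).covariance[0, 0]))

    bwp, bwn = bw_of(pos), bw_of(neg)
    span = max(np.ptp(np.concatenate([pos, neg])), 1e-6)
    pad = 6.0 * max(bwp, bwn, 0.01 * span)
    lo = min(pos.min(), neg.min()) - pad
    hi = max(pos.max(), neg.max()) + pad
    grid = np.linspace(lo, hi, grid_size)
    h = grid[1] - grid[0]

    def density(x, bw):
        if bw == 0.0:
            # degenerate class: a sharp Gaussian, at least 2 grid steps
            # wide so it is resolved and integrates to 1 on the grid
            bw = 2.0 * h
            return np.exp(-0.5 * ((grid - x[0]) / bw) ** 2) / (
                bw * np.sqrt(2 * np.pi)
            )
        return np.asarray(gaussian_kde(x, bw_method=bw_method)(grid))

    return Densities(grid=grid, pos=density(pos, bwp), neg=density(neg, bwn))


def evaluate_embedding(
    emb: Embedding,
    net: Network,
    with_densities: bool = False,
    neg_sample_seed: int = 0,
) -> EvalReport:
    """ROC/AUC of recovering ``net``'s edges from embedding distances.

    Positives are the edges, negatives all non-edges (graphs up to 2000
    nodes) or a seeded uniform sample of 10|E| of them.
    """
    pos_pairs = net.edge_array()
    if net.n_nodes <= 2000:
        neg_pairs = _non_edge_pool(net)
    else:
        rng = np.random.default_rng(neg_sample_seed)
        neg_pairs = sample_non_edge_indices(
            net, min(10 * net.n_edges, net.n_non_edges()), rng
        )
    idx = [emb.node_order.index(v) for v in net.nodes] \
        if emb.node_order != net.nodes else None
    if idx is not None:
        remap = np.asarray(idx)
        pos_pairs = remap[pos_pairs]
        neg_pairs = remap[neg_pairs]
    pos = score_pairs(emb, pos_pairs)
    neg = score_pairs(emb, neg_pairs)
    report = roc_and_auc(pos, neg)
    if with_densities:
        report.densities = conditional_densities(pos, neg)
    return report


def rank_edges(emb: Embedding, net: Network) -> pd.DataFrame:
    """Edges sorted by embedding distance, most reliable first; ties are
    broken by node labels.  Columns: node_a, node_b, distance, rank."""
    labels = net.edge_labels()
    if labels:
        dists = score_pairs(
            emb,
            np.asarray(
                [[emb.node_order.index(a), emb.node_order.index(b)]
                 for a, b in labels]
                if emb.node_order != net.nodes else net.edge_array(),
            ),
        )
    else:
        dists = np.empty(0)
    df = pd.DataFrame(
        {
            "node_a": [min(a, b) for a, b in labels],
            "node_b": [max(a, b) for a, b in labels],
            "distance": dists,
        }
    )
    df = df.sort_values(
        ["distance", "node_a", "node_b"], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_fraction(ranked: pd.DataFrame, q: float) -> pd.DataFrame:
    """Top q (0 < q <= 1) of a ranked edge table (coverage slicing)."""
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    k = int(np.ceil(q * len(ranked)))
    return ranked.iloc[:k]


def noise_experiment(
    net: Network,
    levels,
    replicates: int,
    cfg,
    methods=("tlse_t1.9", "tlse_t1.0", "mdsgeo"),
) -> pd.DataFrame:
    """Robustness protocol: perturb the network at each noise level,
    re-embed the perturbed graph, and score the ORIGINAL edge/non-edge
    labels by embedding distance.

    Returns a tidy frame with one row per (level, method, replicate) and
    the AUC against the unperturbed labels; deterministic given
    ``cfg.seed``.
    """
    from dataclasses import replace as _replace

    from .mdsgeo import fit_mdsgeo_components
    from .nullmodels import perturb
    from .optimizer import fit_tlse

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pos_pairs = net.edge_array()
    if net.n_nodes <= 2000:
        neg_pairs = _non_edge_pool(net)
    else:
        rng = np.random.default_rng(cfg.seed)
        neg_pairs = sample_non_edge_indices(
            net, min(10 * net.n_edges, net.n_non_edges()), rng
        )
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for level in levels:
        for rep in range(replicates):
            pert_seed, fit_seed = (
                int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(2)
            )
            noisy = perturb(net, level, pert_seed)
            for method in methods:
                if method.startswith("tlse"):
                    t = float(method.split("_t")[1])
                    emb, _ = fit_tlse(noisy, _replace(cfg, t=t, seed=fit_seed))
                elif method == "mdsgeo":
                    emb = fit_mdsgeo_components(noisy, cfg.dim)
                    if emb.node_order != net.nodes:  # pragma: no cover
                        raise RuntimeError("node order mismatch")
                else:
                    raise ValueError(f"unknown method {method!r}")
                auc = auc_score(
                    score_pairs(emb, pos_pairs), score_pairs(emb, neg_pairs)
                )
                rows.append(
                    {"level": level, "method": method, "replicate": rep,
                     "auc": auc}
                )
    return pd.DataFrame(rows)


def summarize_noise(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of the AUC per (level, method)."""
    return (
        table.groupby(["level", "method"], as_index=False)["auc"]
        .agg(mean_auc="mean", sd_auc="std")
        .fillna({"sd_auc": 0.0})
    )
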