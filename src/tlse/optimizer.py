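"""Alternating minimization of the t-LSE objective.

The loss is smooth but non-convex for t > 1, and plain gradient descent on
the coordinates takes many tiny steps.  Two ideas make the fit practical:

* parameters are optimized alternately — the scalar bias b by 1-D gradient
  descent with backtracking (cheap, to local optimality), then the
  coordinate matrix Z by a single preconditioned step per outer iteration;
* the coordinate step uses the descent direction D = -M^{-1} grad, where M
  is a symmetric positive-definite matrix built from the mixing
  coefficients, combined with a line search satisfying the Wolfe
  conditions.  Any SPD M yields <D, grad> < 0, and by Zoutendijk's theorem
  the iteration converges to a stationary point.

Two preconditioners are provided: ``diagonal`` (Jacobi on the absolute
mixing coefficients, the default — provably SPD even when repulsive
negative weights would make the naive fixed-point diagonal indefinite)
and ``sparse_system`` (the Laplacian of the attractive weights plus a
ridge, applied through a sparse LSQR solve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import lsqr

from .graph_io import Network
from .model import Embedding, PairWeights, build_pairset
from .tmath import check_t

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitTrace", "search_direction", "wolfe_line_search",
           "fit_tlse"]


@dataclass
class FitConfig:
    """Hyperparameters of a t-LSE fit."""

    dim: int = 2
    t: float = 1.9
    max_outer_iters: int = 500
    tol_rel_obj: float = 1e-6
    neg_ratio: float = 5.0
    exact_negatives: bool = False
    seed: int = 0
    init: str = "mdsgeo"  # "mdsgeo" | "random"
    c1: float = 1e-4
    c2: float = 0.9
    max_backtracks: int = 30
    precond: str = "diagonal"  # "diagonal" | "sparse_system"
    damping: float = 1e-8
    init_scale: float = 0.1
    restarts: int = 1
    # for t > 1, first solve the convex t = 1 problem and refine at the
    # target t (graduated non-convexity); see fit_tlse
    continuation: bool = True

    def __post_init__(self) -> None:
        check_t(self.t)
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not (0 < self.c1 < self.c2 < 1):
            raise ValueError("need 0 < c1 < c2 < 1")
        if self.tol_rel_obj <= 0:
            raise ValueError("tol_rel_obj must be > 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.init not in ("random", "mdsgeo"):
            raise ValueError("init must be 'random' or 'mdsgeo'")
        if self.precond not in ("diagonal", "sparse_system"):
            raise ValueError("precond must be 'diagonal' or 'sparse_system'")


@dataclass
class FitTrace:
    """Per-iteration record of the fit; accepted steps never increase the
    objective and always have a negative directional derivative."""

    objectives: list[float] = field(default_factory=list)
    dir_derivs: list[float] = field(default_factory=list)
    steps: list[float] = field(default_factory=list)
    weak_steps: int = 0
    converged: bool = False
    reason: str = ""
    seed: int | None = None

    @property
    def n_iters(self) -> int:
        return len(self.steps)


def search_direction(
    emb: Embedding,
    grad: np.ndarray,
    weights: PairWeights,
    cfg: FitConfig,
) -> np.ndarray:
    """Preconditioned descent direction D = -M^{-1} grad.

    ``diagonal``: M = diag(sum_j |W_ij| + lambda) — Jacobi scaling by the
    total (attractive + repulsive) coefficient mass at each node.
    ``sparse_system``: M = diag(sum_j W+_ij) - W+ + lambda I on the
    attractive support, solved column-wise with LSQR.  The descent
    contract <D, grad> < 0 is verified; on failure the direction falls
    back to the negative gradient.
    """
    lam = cfg.damping
    if cfg.precond == "diagonal":
        absrow = np.asarray(np.abs(weights.W).sum(axis=1)).ravel()
        m = absrow + lam
        zero = m <= 0
        if np.any(zero):
            m = np.where(zero, 1.0, m)
        direction = -grad / m[:, None]
    else:
        Wp = weights.W.maximum(csr_matrix(weights.W.shape))  # attractive part
        rowp = np.asarray(Wp.sum(axis=1)).ravel()
        lam_eff = lam if lam > 0 else 1e-6
        M = diags(rowp + lam_eff) - Wp
        direction = np.empty_like(grad)
        for k in range(grad.shape[1]):
            direction[:, k] = -lsqr(M, grad[:, k], atol=1e-10, btol=1e-10)[0]
    dd = float(np.vdot(direction, grad))
    if not np.isfinite(dd) or dd >= 0.0:
        if np.any(grad):
            logger.warning("preconditioned direction not descending; "
                           "falling back to -grad")
        direction = -grad
    return direction


@dataclass
class LineSearchResult:
    step: float
    f_new: float
    n_evals: int
    weak: bool
    stalled: bool


def wolfe_line_search(
    phi,
    dphi0: float,
    cfg: FitConfig,
    phi0: float | None = None,
    dphi=None,
    eta0: float = 1.0,
    max_eta: float = 1e6,
) -> LineSearchResult:
    """Scalar line search along a descent direction.

    ``phi(eta)`` is the objective as a function of the step, ``dphi0`` its
    (negative) derivative at 0, and ``dphi(eta)`` — if supplied — the
    derivative at eta, enabling the curvature condition.  Returns a step
    satisfying Armijo (c1) and weak-Wolfe curvature (c2) when possible;
    otherwise the best backtracked step achieving plain decrease (flagged
    ``weak``); otherwise step 0 with ``stalled`` set.
    """
    if dphi0 >= 0:
        raise ValueError("wolfe_line_search requires a descent direction")
    f0 = phi(0.0) if phi0 is None else phi0
    c1, c2 = cfg.c1, cfg.c2
    evals = 0

    def armijo(eta, f):
        return f <= f0 + c1 * eta * dphi0

    # bracketing phase (Nocedal-Wright): expand until Armijo fails or
    # curvature holds
    lo, f_lo, d_lo = 0.0, f0, dphi0
    eta = eta0
    hi = f_hi = None
    for _ in range(cfg.max_backtracks):
        f = phi(eta)
        evals += 1
        if not np.isfinite(f) or not armijo(eta, f) or f >= f_lo:
            hi, f_hi = eta, f
            break
        if dphi is None:
            return LineSearchResult(eta, f, evals, weak=False, stalled=False)
        d = dphi(eta)
        if d >= c2 * dphi0:  # weak Wolfe curvature
            return LineSearchResult(eta, f, evals, weak=False, stalled=False)
        lo, f_lo, d_lo = eta, f, d
        eta *= 2.0
        if eta > max_eta:
            return LineSearchResult(lo, f_lo, evals, weak=True, stalled=False)
    if hi is None:
        return LineSearchResult(lo, f_lo, evals, weak=True, stalled=False) \
            if lo > 0 else LineSearchResult(0.0, f0, evals, weak=False, stalled=True)

    # zoom phase on (lo, hi) by bisection
    for _ in range(cfg.max_backtracks):
        eta = 0.5 * (lo + hi)
        f = phi(eta)
        evals += 1
        if not np.isfinite(f) or not armijo(eta, f) or f >= f_lo:
            hi, f_hi = eta, f
            continue
        if dphi is None:
            return LineSearchResult(eta, f, evals, weak=False, stalled=False)
        d = dphi(eta)
        if d >= c2 * dphi0:
            return LineSearchResult(eta, f, evals, weak=False, stalled=False)
        lo, f_lo, d_lo = eta, f, d
    if lo > 0 and f_lo < f0:
        return LineSearchResult(lo, f_lo, evals, weak=True, stalled=False)
    return LineSearchResult(0.0, f0, evals, weak=False, stalled=True)


def _optimize_bias(
    ev,
    Z: np.ndarray,
    bias: float,
    max_iters: int = 10,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """1-D gradient descent with backtracking on b (coordinates fixed).

    Candidates are projected onto the identifiable interval — the range
    of squared pairwise distances among the training pairs.  Outside that
    window b classifies every pair identically, and for t near 2 the
    heavy-tailed loss makes b -> -inf a degenerate descent path (reject
    all pairs, freeze the coordinates); projecting keeps the cutoff
    meaningful while the embedding is still disordered.  Only decreasing
    steps are accepted, so the objective never increases.
    """
    d2 = ev.sq_dists(Z)
    lo, hi = float(d2.min()), float(d2.max())
    b = min(max(bias, lo), hi)
    f = ev.objective_from_d2(d2, b)
    step = 1.0
    for _ in range(max_iters):
        db = ev.db_from_d2(d2, b)
        if abs(db) < tol:
            break
        accepted = False
        s = step
        for _ in range(40):
            b_new = min(max(b - s * db, lo), hi)
            if b_new == b:
                break
            f_new = ev.objective_from_d2(d2, b_new)
            if f_new < f:
                b, f = b_new, f_new
                step = min(s * 2.0, 1e3)
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
    return b, f


def _initial_coords(net: Network, cfg: FitConfig,
                    rng: np.random.Generator) -> np.ndarray:
    if cfg.init == "mdsgeo":
        from .graph_io import connected_components
        from .mdsgeo import classical_mds, shortest_path_matrix

        coords = np.zeros((net.n_nodes, cfg.dim))
        for comp in connected_components(net):
            if comp.n_nodes == 1:
                continue
            D = shortest_path_matrix(comp)
            sub = classical_mds(D, cfg.dim)
            rows = [net.index_of(v) for v in comp.nodes]
            coords[rows] = sub.coords
        # break exact symmetry / overlap of components
        coords += 0.01 * cfg.init_scale * rng.standard_normal(coords.shape)
        return coords
    return cfg.init_scale * rng.standard_normal((net.n_nodes, cfg.dim))


def _fit_once(net: Network, cfg: FitConfig, seed: int) -> tuple[Embedding, FitTrace]:
    from .model import PairEvaluator

    ss = np.random.SeedSequence(seed)
    rng_init, rng_neg = (np.random.default_rng(s) for s in ss.spawn(2))
    pairs = build_pairset(net, neg_ratio=cfg.neg_ratio, seed=rng_neg,
                          exact=cfg.exact_negatives)
    Z = _initial_coords(net, cfg, rng_init)
    if len(pairs.pos_pairs):
        d0 = Z[pairs.pos_pairs[:, 0]] - Z[pairs.pos_pairs[:, 1]]
        b = float(np.median(np.einsum("ij,ij->i", d0, d0)))
    else:
        b = 0.0
    b = max(b, 1e-6)

    if cfg.continuation and cfg.t > 1.0:
        # convex stage: solve the logistic (t = 1) problem on the same
        # pair sample, then refine at the target t from its solution
        ev1 = PairEvaluator(pairs, 1.0, net.n_nodes)
        Z, b, _ = _alternating_descent(ev1, Z, b, cfg, net.nodes)
    ev = PairEvaluator(pairs, cfg.t, net.n_nodes)
    Z, b, trace = _alternating_descent(ev, Z, b, cfg, net.nodes)
    trace.seed = seed
    emb = Embedding(coords=Z, bias=b, t=cfg.t, node_order=list(net.nodes))
    return emb, trace


def _alternating_descent(
    ev, Z: np.ndarray, b: float, cfg: FitConfig, node_order
) -> tuple[np.ndarray, float, FitTrace]:
    emb = Embedding(coords=Z, bias=b, t=ev.t, node_order=list(node_order))
    trace = FitTrace()
    f = ev.objective(Z, b)
    trace.objectives.append(f)

    for _ in range(cfg.max_outer_iters):
        f_outer_start = f
        # (a) bias to local optimality, coordinates fixed
        b, f = _optimize_bias(ev, Z, b)

        # (b) one preconditioned coordinate step
        dZ, _, weights = ev.gradient(Z, b)
        gnorm = float(np.linalg.norm(dZ))
        if gnorm < 1e-10:
            trace.converged = True
            trace.reason = "gradient"
            trace.objectives.append(f)
            break
        emb = replace(emb, coords=Z, bias=b)
        D = search_direction(emb, dZ, weights, cfg)
        dd = float(np.vdot(D, dZ))

        def phi(eta, _D=D, _Z=Z, _b=b):
            return ev.objective(_Z + eta * _D, _b)

        def dphi(eta, _D=D, _Z=Z, _b=b):
            g, _, _ = ev.gradient(_Z + eta * _D, _b)
            return float(np.vdot(g, _D))

        ls = wolfe_line_search(phi, dd, cfg, phi0=f, dphi=dphi)
        if ls.stalled:
            trace.converged = False
            trace.reason = "stall"
            trace.objectives.append(f)
            break
        Z = Z + ls.step * D
        f_new = ls.f_new
        trace.dir_derivs.append(dd)
        trace.steps.append(ls.step)
        trace.weak_steps += int(ls.weak)
        trace.objectives.append(f_new)
        if f_outer_start - f_new <= cfg.tol_rel_obj * max(1.0, abs(f_outer_start)):
            f = f_new
            trace.converged = True
            trace.reason = "objective"
            break
        f = f_new
    else:
        trace.reason = "max_iters"
    return Z, b, trace


def fit_tlse(net: Network, cfg: FitConfig) -> tuple[Embedding, FitTrace]:
    """Fit a t-LSE embedding of ``net``.

    Alternates bias and coordinate updates until the relative objective
    change drops below ``tol_rel_obj`` or ``max_outer_iters`` is reached.
    Deterministic given ``cfg.seed``; with ``restarts > 1`` the fit with
    the lowest final objective wins.
    """
    if net.n_nodes < 2 or net.n_edges < 1:
        raise ValueError("fit_tlse needs >= 2 nodes and >= 1 edge")
    best: tuple[Embedding, FitTrace] | None = None
    seeds = np.random.SeedSequence(cfg.seed).generate_state(max(cfg.restarts, 1))
    for s in seeds:
        emb, trace = _fit_once(net, cfg, int(s) % (2**31))
        if best is None or trace.objectives[-1] < best[1].objectives[-1]:
            best = (emb, trace)
    return best
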