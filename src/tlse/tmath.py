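"""The t-exponential family and the t-logistic loss.

The t-exponential ``exp_t`` generalizes the exponential function with a
power-law (heavy) tail for ``1 < t < 2``; ``log_t`` is its inverse.  A
two-class probability link is built by normalizing a symmetric pair of
t-exponentials,

    F_t(u) = exp_t(u/2 - G_t(u)),

where the normalizer ``G_t(u)`` is the unique scalar making
``F_t(u) + F_t(-u) = 1``.  The t-logistic loss is the ordinary negative
logarithm of that probability, ``l_t(u) = -log F_t(u)``.  At ``t = 1`` the
family collapses to ``exp``/``log`` and the loss is exactly the logistic
loss ``log(1 + e^(-u))``; for ``t`` near 2 the loss has bounded influence:
its derivative tends to zero again for very negative margins, which is
what makes the embedding robust to false links.

All functions accept scalars or numpy arrays and are vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "check_t",
    "exp_t",
    "log_t",
    "solve_normalizer",
    "link_eval",
    "LinkEval",
]

#: default residual tolerance of the normalizer solver
NORMALIZER_TOL = 1e-12


def check_t(t: float) -> float:
    """Validate the loss parameter; must satisfy ``1 <= t < 2``."""
    t = float(t)
    if not (1.0 <= t < 2.0):
        raise ValueError(f"t must lie in [1, 2), got {t}")
    return t


def exp_t(x, t: float):
    """t-exponential: ``exp(x)`` at t=1, else ``[1 + (1-t)x]_+^(1/(1-t))``.

    For ``t > 1`` the function is only defined where ``1 + (1-t)x > 0``
    (i.e. ``x < 1/(t-1)``); arguments outside that region raise.
    """
    t = check_t(t)
    x = np.asarray(x, dtype=float)
    if t == 1.0:
        return np.exp(x)
    bracket = 1.0 + (1.0 - t) * x
    if np.any(bracket <= 0.0):
        raise ValueError("exp_t domain error: 1 + (1-t)x <= 0 for t > 1")
    return bracket ** (1.0 / (1.0 - t))


def log_t(x, t: float):
    """Inverse of :func:`exp_t`: ``log(x)`` at t=1, else ``(x^(1-t) - 1)/(1-t)``."""
    t = check_t(t)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("log_t domain error: x must be > 0")
    if t == 1.0:
        return np.log(x)
    return (x ** (1.0 - t) - 1.0) / (1.0 - t)


def _residual(u, g, t):
    """exp_t(u/2 - g) + exp_t(-u/2 - g) - 1 and the two summands."""
    p1 = exp_t(u / 2.0 - g, t)
    p2 = exp_t(-u / 2.0 - g, t)
    return p1 + p2 - 1.0, p1, p2


def solve_normalizer(u, t: float, tol: float = NORMALIZER_TOL, max_iter: int = 200):
    """Solve ``exp_t(u/2 - g) + exp_t(-u/2 - g) = 1`` for g.

    The left side is strictly decreasing in g, so the root is unique.  For
    ``g >= |u|/2`` both arguments are <= 0, keeping exp_t in its valid
    domain, and the residual at ``g = |u|/2`` is ``exp_t(-|u|) >= 0``; the
    root therefore lies in ``[|u|/2, inf)`` and is found by safeguarded
    Newton iteration inside an expanding bracket.  At ``t = 1`` the closed
    form ``G_1(u) = log(2 cosh(u/2))`` is returned.
    """
    t = check_t(t)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)

    if t == 1.0:
        au = np.abs(u)
        g = au / 2.0 + np.log1p(np.exp(-au))  # log(2 cosh(u/2)), overflow-safe
        return float(g[0]) if scalar else g

    # t > 1: Newton from the left endpoint g0 = |u|/2, where the residual
    # r(g0) = exp_t(-|u|) >= 0.  For g >= |u|/2 both exp_t arguments are
    # <= 0, so the brackets 1 + (1-t)x stay >= 1 and no domain checks are
    # needed.  r is convex and strictly decreasing in g, so Newton from
    # the left converges monotonically to the root without safeguarding.
    # The identities p^t = p/bracket and p^(t-1) = 1/bracket keep each
    # iteration free of extra pow evaluations.
    omt = 1.0 - t  # in (-1, 0]
    ex = 1.0 / omt

    g = np.abs(u) / 2.0
    eps = np.finfo(float).eps
    done = np.zeros(u.shape, dtype=bool)
    for _ in range(max_iter):
        br1 = 1.0 + omt * (u / 2.0 - g)
        br2 = 1.0 + omt * (-u / 2.0 - g)
        p1 = br1**ex
        p2 = br2**ex
        r = p1 + p2 - 1.0
        dr = p1 / br1 + p2 / br2  # -(residual slope); strictly positive
        step = r / dr
        # stop on residual, or when the step falls below a few ulps of g
        # (for very large |u| the residual floor exceeds any fixed tol)
        done |= (np.abs(r) <= tol) | (np.abs(step) <= 4 * eps *
                                      np.maximum(1.0, np.abs(g)))
        if done.all():
            break
        g = np.where(done, g, g + step)
    else:
        raise RuntimeError("normalizer solve did not converge")
    return float(g[0]) if scalar else g


@dataclass(frozen=True)
class LinkEval:
    """Evaluation of the t-probability link at margin(s) u.

    Attributes
    ----------
    u : margin(s)
    g : normalizer G_t(u)
    p_pos : F_t(u), probability of the positive class
    p_neg : F_t(-u) = 1 - p_pos
    loss : -log p_pos, the t-logistic loss
    dloss_du : derivative of the loss in u (always <= 0)
    """

    u: np.ndarray
    g: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    loss: np.ndarray
    dloss_du: np.ndarray


def link_eval(u, t: float, tol: float = NORMALIZER_TOL) -> LinkEval:
    """Evaluate probability, loss and loss derivative of the t-logistic link.

    The derivative follows from implicit differentiation of the normalizer:

        l'(u) = -p_pos^(t-1) * p_neg^t / (p_pos^t + p_neg^t),

    which at t = 1 reduces to the logistic gradient ``-sigmoid(-u)``.
    """
    t = check_t(t)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)

    if t == 1.0:
        g = solve_normalizer(u, 1.0)
        p_pos = expit(u)
        p_neg = expit(-u)
        loss = np.logaddexp(0.0, -u)  # log(1 + e^-u), stable
        dloss = -expit(-u)
    else:
        g = solve_normalizer(u, t, tol=tol)
        b_pos = 1.0 + (1.0 - t) * (u / 2.0 - g)
        b_neg = 1.0 + (1.0 - t) * (-u / 2.0 - g)
        p_pos = b_pos ** (1.0 / (1.0 - t))
        p_neg = b_neg ** (1.0 / (1.0 - t))
        loss = np.log(b_pos) / (t - 1.0)  # -log p_pos without underflow
        # p^t = p/bracket and p^(t-1) = 1/bracket avoid extra pows
        dloss = -(1.0 / b_pos) * (p_neg / b_neg) / (
            p_pos / b_pos + p_neg / b_neg
        )

    if scalar:
        (u, g, p_pos, p_neg, loss, dloss) = (
            arr.reshape(()) for arr in (u, g, p_pos, p_neg, loss, dloss)
        )
    return LinkEval(u=u, g=g, p_pos=p_pos, p_neg=p_neg, loss=loss, dloss_du=dloss)
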