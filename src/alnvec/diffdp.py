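"""Differentiable Needleman-Wunsch with exact custom derivatives.

The global-alignment recursion

    v[i,j] = mu[i,j] + max( v[i-1,j-1],                (match)
                            g[i,j] + v[i-1,j],         (insert, X)
                            g[i,j] + v[i,j-1] )        (delete, Y)

is smoothed by replacing max with temperature-scaled log-sum-exp and argmax
with softmax.  The gradient of the terminal value with respect to the match
scores is the *expected alignment* e: entry (i,j) is the probability, under
the Gibbs distribution over monotone lattice paths, that the path visits
cell (i,j).  A second forward/backward sweep propagates a perturbation
Z = [z_mu, z_g] through the recursion, yielding the directional derivative
of the value and the Hessian-vector product needed to backpropagate through
e itself.

Two boundary conventions are supported:

* ``as_printed`` -- v[0,0] = 1 and all other boundary cells 0 (all finite),
  so paths may effectively enter the grid anywhere along the top/left edge.
* ``path_strict`` -- v[0,0] = 0 and all other boundary cells -inf, so every
  path runs from cell (1,1) to (p,q); the terminal value is then exactly the
  temperature-scaled log-sum-exp over complete path scores, which is the
  semantics the enumeration oracle checks.

By default mu is added on all three branches, exactly as the recursion above
is written; ``mu_on_gaps=False`` gives the textbook variant where mu only
rewards the match branch.  All derivative bookkeeping follows the selected
mode.

Storage is 0-based; the math above is 1-based.  ``value`` matrices carry the
boundary row/column explicitly (shape (p+1) x (q+1)); per-cell arrays
(weights, e) are p x q with [i-1, j-1] holding cell (i,j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from numba import njit
from scipy.special import logsumexp as _scipy_lse

__all__ = [
    "SmoothingConfig",
    "ScoreMatrices",
    "ForwardResult",
    "ExpectedAlignment",
    "DirectionalDerivativeResult",
    "AlignmentPath",
    "OracleResult",
    "smooth_max",
    "nw_forward",
    "nw_expected_alignment",
    "nw_directional",
    "nw_alignment_grads",
    "nw_hard_decode",
    "nw_forward_padded",
    "enumerate_paths_oracle",
    "write_expected_tsv",
    "read_expected_tsv",
    "PROB_FLOOR",
]

# numerical floor applied to probabilities before any log
PROB_FLOOR = 1e-12

# branch channel order everywhere: 0 = match (M), 1 = insert (X), 2 = delete (Y)
_M, _X, _Y = 0, 1, 2


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothed-operator settings.

    temperature -- scale of the log-sum-exp / softmax smoothing; 1.0
        reproduces the operators exactly as the recursion is written, and
        the zero-temperature limit recovers the classical hard maximum.
    border_mode -- boundary initialization convention (see module docstring).
    mu_on_gaps -- whether mu is added on the insert/delete branches too.
    """

    temperature: float = 1.0
    border_mode: Literal["as_printed", "path_strict"] = "as_printed"
    mu_on_gaps: bool = True

    def __post_init__(self):
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        if self.border_mode not in ("as_printed", "path_strict"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")


@dataclass(frozen=True)
class ScoreMatrices:
    """Paired match (mu) and gap (g) score matrices, both p x q."""

    mu: np.ndarray
    gap: np.ndarray

    def __post_init__(self):
        mu = np.ascontiguousarray(np.asarray(self.mu, dtype=np.float64))
        gap = np.ascontiguousarray(np.asarray(self.gap, dtype=np.float64))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "gap", gap)
        if mu.ndim != 2 or mu.shape != gap.shape:
            raise ValueError("mu and gap must be 2-D with identical shapes")
        if mu.shape[0] < 1 or mu.shape[1] < 1:
            raise ValueError("score matrices must be at least 1x1")
        if not (np.isfinite(mu).all() and np.isfinite(gap).all()):
            raise ValueError("scores must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu.shape


@dataclass(frozen=True)
class ForwardResult:
    """Smoothed forward pass output: value matrix and softmax weights."""

    value: np.ndarray  # (p+1) x (q+1), boundary included
    weights: np.ndarray  # p x q x 3 softmax weights (m, x, y)
    config: SmoothingConfig

    @property
    def terminal(self) -> float:
        return float(self.value[-1, -1])


@dataclass(frozen=True)
class ExpectedAlignment:
    """Per-cell alignment probabilities e = d value[p,q] / d mu."""

    e: np.ndarray  # p x q
    config: SmoothingConfig


@dataclass(frozen=True)
class DirectionalDerivativeResult:
    """Directional derivative along a perturbation Z = [z_mu, z_g]."""

    vdot: float  # <grad value, Z>
    edot: np.ndarray  # p x q, directional derivative of e (Hessian-vector product)
    omega_dot: np.ndarray  # p x q x 3, directional derivative of the weights
    perturbation: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


class AlignmentPath:
    """A concrete monotone alignment path.

    states -- string over {M, X, Y}: M consumes one residue of each sequence
    (a match edge), X consumes a query residue against a gap, Y a target
    residue against a gap.
    """

    __slots__ = ("states", "p", "q", "edges")

    def __init__(self, states: str):
        if not states or any(c not in "MXY" for c in states):
            raise ValueError("states must be a non-empty string over {M, X, Y}")
        i = j = 0
        edges: list[tuple[int, int]] = []
        for c in states:
            if c == "M":
                i += 1
                j += 1
                edges.append((i, j))
            elif c == "X":
                i += 1
            else:
                j += 1
        self.states = states
        self.p, self.q = i, j
        self.edges = frozenset(edges)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], p: int, q: int) -> "AlignmentPath":
        """Build a path from strictly increasing 1-based match pairs.

        Unmatched residues between consecutive edges are emitted as X runs
        before Y runs (a fixed, documented convention)."""
        es = sorted(edges)
        for (a, b), (c, d) in zip(es, es[1:]):
            if not (a < c and b < d):
                raise ValueError("edges must be strictly increasing in both coordinates")
        if es and (es[-1][0] > p or es[-1][1] > q or es[0][0] < 1 or es[0][1] < 1):
            raise ValueError("edges out of range")
        out = []
        i = j = 0
        for a, b in es:
            out.append("X" * (a - 1 - i))
            out.append("Y" * (b - 1 - j))
            out.append("M")
            i, j = a, b
        out.append("X" * (p - i))
        out.append("Y" * (q - j))
        states = "".join(out)
        if not states:
            raise ValueError("empty path (p=q=0)")
        return cls(states)

    def replay_score(self, scores: ScoreMatrices, config: SmoothingConfig) -> float:
        """Exact score of this path under the recursion's per-cell scoring."""
        if (self.p, self.q) != scores.shape:
            raise ValueError("path does not span the score matrix")
        i = j = 0
        total = 0.0
        for c in self.states:
            if c == "M":
                i += 1
                j += 1
                total += scores.mu[i - 1, j - 1]
            else:
                if c == "X":
                    i += 1
                else:
                    j += 1
                total += scores.gap[i - 1, j - 1]
                if config.mu_on_gaps:
                    total += scores.mu[i - 1, j - 1]
        return total

    def __repr__(self):
        return f"AlignmentPath({self.states!r})"

    def __eq__(self, other):
        return isinstance(other, AlignmentPath) and self.states == other.states

    def __hash__(self):
        return hash(self.states)


# ---------------------------------------------------------------------------
# smoothed operators
# ---------------------------------------------------------------------------


def smooth_max(x, config: SmoothingConfig = SmoothingConfig()) -> tuple[float, np.ndarray]:
    """Temperature-scaled log-sum-exp and its softmax weights.

    value = tau * log sum_i exp(x_i / tau); weights = softmax(x / tau).
    -inf entries are admissible (zero weight); an all-(-inf) input signals
    that no transition is admissible.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("smooth_max of empty vector")
    tau = config.temperature
    m = np.max(x)
    if m == -np.inf:
        raise ValueError("no admissible transition (all scores -inf)")
    w = np.exp((x - m) / tau)
    s = w.sum()
    return float(m + tau * math.log(s)), w / s


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_kernel(mu, gap, tau, as_printed, mu_on_gaps):
    p, q = mu.shape
    v = np.empty((p + 1, q + 1))
    if as_printed:
        for i in range(p + 1):
            for j in range(q + 1):
                v[i, j] = 0.0
        v[0, 0] = 1.0
    else:
        for i in range(p + 1):
            for j in range(q + 1):
                v[i, j] = -np.inf
        v[0, 0] = 0.0
    omega = np.zeros((p, q, 3))
    a = np.empty(3)
    for i in range(1, p + 1):
        for j in range(1, q + 1):
            m = mu[i - 1, j - 1]
            g = gap[i - 1, j - 1]
            a[0] = m + v[i - 1, j - 1]
            if mu_on_gaps:
                a[1] = m + g + v[i - 1, j]
                a[2] = m + g + v[i, j - 1]
            else:
                a[1] = g + v[i - 1, j]
                a[2] = g + v[i, j - 1]
            amax = a[0]
            if a[1] > amax:
                amax = a[1]
            if a[2] > amax:
                amax = a[2]
            if amax == -np.inf:
                v[i, j] = -np.inf
                continue
            s = 0.0
            for k in range(3):
                e = np.exp((a[k] - amax) / tau)
                omega[i - 1, j - 1, k] = e
                s += e
            v[i, j] = amax + tau * np.log(s)
            for k in range(3):
                omega[i - 1, j - 1, k] /= s
    return v, omega


@njit(cache=True)
def _backward_kernel(omega, p, q):
    """Adjoint sweep: E[i,j] = d v[p,q] / d v[i,j], padded to (p+2)x(q+2)."""
    E = np.zeros((p + 2, q + 2))
    E[p + 1, q + 1] = 1.0
    for i in range(p, 0, -1):
        for j in range(q, 0, -1):
            acc = 0.0
            # child (i+1, j+1), match branch; the virtual cell (p+1, q+1)
            # carries weights (1, 0, 0)
            if i == p and j == q:
                acc += E[p + 1, q + 1]
            elif i < p and j < q:
                acc += omega[i, j, 0] * E[i + 1, j + 1]
            # child (i+1, j), insert branch
            if i < p:
                acc += omega[i, j - 1, 1] * E[i + 1, j]
            # child (i, j+1), delete branch
            if j < q:
                acc += omega[i - 1, j, 2] * E[i, j + 1]
            E[i, j] = acc
    return E


@njit(cache=True)
def _directional_kernel(zmu, zg, omega, E, tau, mu_on_gaps):
    """Propagate perturbation Z through both sweeps.

    Forward: vdot = omega . adot, omega_dot = J(omega) adot / tau with
    J = diag(omega) - omega omega^T, i.e. omega_dot_k = omega_k (adot_k -
    vdot) / tau.  (The printed recursion carries a stray leading minus and
    folds omega into the argument; the rule here is the derivative of
    softmax(a / tau) and is validated against finite differences.)
    Backward: product rule on the adjoint sweep.
    """
    p, q = zmu.shape
    vdot = np.zeros((p + 1, q + 1))
    wdot = np.zeros((p, q, 3))
    adot = np.empty(3)
    for i in range(1, p + 1):
        for j in range(1, q + 1):
            zm = zmu[i - 1, j - 1]
            zgg = zg[i - 1, j - 1]
            adot[0] = zm + vdot[i - 1, j - 1]
            if mu_on_gaps:
                adot[1] = zm + zgg + vdot[i - 1, j]
                adot[2] = zm + zgg + vdot[i, j - 1]
            else:
                adot[1] = zgg + vdot[i - 1, j]
                adot[2] = zgg + vdot[i, j - 1]
            vd = 0.0
            for k in range(3):
                vd += omega[i - 1, j - 1, k] * adot[k]
            vdot[i, j] = vd
            for k in range(3):
                wdot[i - 1, j - 1, k] = omega[i - 1, j - 1, k] * (adot[k] - vd) / tau
    Ed = np.zeros((p + 2, q + 2))
    for i in range(p, 0, -1):
        for j in range(q, 0, -1):
            acc = 0.0
            if i == p and j == q:
                acc += 0.0  # virtual terminal weights are constant
            elif i < p and j < q:
                acc += wdot[i, j, 0] * E[i + 1, j + 1] + omega[i, j, 0] * Ed[i + 1, j + 1]
            if i < p:
                acc += wdot[i, j - 1, 1] * E[i + 1, j] + omega[i, j - 1, 1] * Ed[i + 1, j]
            if j < q:
                acc += wdot[i - 1, j, 2] * E[i, j + 1] + omega[i - 1, j, 2] * Ed[i, j + 1]
            Ed[i, j] = acc
    return vdot, wdot, Ed


@njit(cache=True)
def _hard_kernel(mu, gap, mu_on_gaps):
    p, q = mu.shape
    v = np.empty((p + 1, q + 1))
    for i in range(p + 1):
        for j in range(q + 1):
            v[i, j] = -np.inf
    v[0, 0] = 0.0
    ptr = np.zeros((p, q), dtype=np.int8)
    a = np.empty(3)
    for i in range(1, p + 1):
        for j in range(1, q + 1):
            m = mu[i - 1, j - 1]
            g = gap[i - 1, j - 1]
            a[0] = m + v[i - 1, j - 1]
            if mu_on_gaps:
                a[1] = m + g + v[i - 1, j]
                a[2] = m + g + v[i, j - 1]
            else:
                a[1] = g + v[i - 1, j]
                a[2] = g + v[i, j - 1]
            best = 0  # tie precedence: match > insert (X) > delete (Y)
            if a[1] > a[best]:
                best = 1
            if a[2] > a[best]:
                best = 2
            v[i, j] = a[best]
            ptr[i - 1, j - 1] = best
    # traceback
    states = np.empty(p + q, dtype=np.int8)
    n = 0
    i, j = p, q
    while i > 0 and j > 0:
        k = ptr[i - 1, j - 1]
        states[n] = k
        n += 1
        if k == 0:
            i -= 1
            j -= 1
        elif k == 1:
            i -= 1
        else:
            j -= 1
    return v[p, q], states[:n][::-1].copy()


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def nw_forward(scores: ScoreMatrices, config: SmoothingConfig = SmoothingConfig()) -> ForwardResult:
    """Smoothed forward recursion: value matrix plus per-cell softmax weights."""
    v, omega = _forward_kernel(
        scores.mu, scores.gap, config.temperature,
        config.border_mode == "as_printed", config.mu_on_gaps,
    )
    return ForwardResult(value=v, weights=omega, config=config)


def _adjoint(forward: ForwardResult) -> np.ndarray:
    p, q, _ = forward.weights.shape
    return _backward_kernel(forward.weights, p, q)


def nw_expected_alignment(forward: ForwardResult) -> ExpectedAlignment:
    """Expected alignment e = d value[p,q] / d mu via the adjoint sweep.

    With mu on all branches, e[i,j] is the marginal probability that the
    Gibbs path visits cell (i,j); with ``mu_on_gaps=False`` it is the
    probability the path *matches* (i,j)."""
    E = _adjoint(forward)
    e = E[1:-1, 1:-1]
    if not forward.config.mu_on_gaps:
        e = e * forward.weights[:, :, _M]
    return ExpectedAlignment(e=np.ascontiguousarray(e), config=forward.config)


def nw_directional(
    scores: ScoreMatrices,
    perturbation: tuple[np.ndarray, np.ndarray],
    forward: ForwardResult,
) -> DirectionalDerivativeResult:
    """Directional derivative of (value, e) along Z = [z_mu, z_g]."""
    zmu = np.ascontiguousarray(np.asarray(perturbation[0], dtype=np.float64))
    zg = np.ascontiguousarray(np.asarray(perturbation[1], dtype=np.float64))
    if zmu.shape != scores.shape or zg.shape != scores.shape:
        raise ValueError("perturbation shape must match scores")
    E = _adjoint(forward)
    vdot, wdot, Ed = _directional_kernel(
        zmu, zg, forward.weights, E, forward.config.temperature, forward.config.mu_on_gaps
    )
    edot = Ed[1:-1, 1:-1]
    if not forward.config.mu_on_gaps:
        edot = edot * forward.weights[:, :, _M] + E[1:-1, 1:-1] * wdot[:, :, _M]
    return DirectionalDerivativeResult(
        vdot=float(vdot[-1, -1]),
        edot=np.ascontiguousarray(edot),
        omega_dot=wdot,
        perturbation=(zmu, zg),
    )


def nw_alignment_grads(
    scores: ScoreMatrices,
    config: SmoothingConfig,
    de: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse-mode pullback of the expected alignment.

    Given the adjoint dL/de, returns (dL/dmu, dL/dgap, e).  By symmetry of
    second derivatives, the vector-Jacobian product with the Hessian of the
    value equals the *forward*-mode sweep along Z = (dL/de, 0):

        dL/dmu  = edot(Z)
        dL/dgap = edot(Z) * (w_x + w_y) + e * (wdot_x(Z) + wdot_y(Z))

    where the gap formula differentiates d value / d gap = E * (w_x + w_y).
    Only the default mu_on_gaps=True mode is supported here (the mode the
    trainable aligner uses).
    """
    if not config.mu_on_gaps:
        raise NotImplementedError("reverse mode implemented for mu_on_gaps=True")
    fwd = nw_forward(scores, config)
    E = _adjoint(fwd)
    e = E[1:-1, 1:-1]
    de = np.ascontiguousarray(np.asarray(de, dtype=np.float64))
    zeros = np.zeros_like(de)
    vdot, wdot, Ed = _directional_kernel(
        de, zeros, fwd.weights, E, config.temperature, True
    )
    edot = Ed[1:-1, 1:-1]
    wx_wy = fwd.weights[:, :, _X] + fwd.weights[:, :, _Y]
    wdx_wdy = wdot[:, :, _X] + wdot[:, :, _Y]
    dmu = edot
    dgap = edot * wx_wy + e * wdx_wdy
    return np.ascontiguousarray(dmu), np.ascontiguousarray(dgap), np.ascontiguousarray(e)


def nw_hard_decode(
    scores: ScoreMatrices, mu_on_gaps: bool = True
) -> tuple[float, AlignmentPath]:
    """Classical max/argmax evaluation under path_strict borders.

    Ties break in fixed order match > insert (X) > delete (Y); the returned
    path's replayed score equals the returned score exactly."""
    score, states = _hard_kernel(scores.mu, scores.gap, mu_on_gaps)
    return float(score), AlignmentPath("".join("MXY"[k] for k in states))


def nw_forward_padded(
    mu_batch: np.ndarray,
    gap_batch: np.ndarray,
    lengths: Iterable[tuple[int, int]],
    config: SmoothingConfig = SmoothingConfig(),
) -> list[ForwardResult]:
    """Evaluate a padded batch instance-by-instance.

    Padded cells are never read: each instance is sliced to its true (p, q)
    before the kernel runs, so results are bitwise identical to evaluating
    each instance alone and padding content is irrelevant (it is treated as
    masked / -inf-equivalent)."""
    out = []
    for b, (p, q) in enumerate(lengths):
        sm = ScoreMatrices(mu_batch[b, :p, :q], gap_batch[b, :p, :q])
        out.append(nw_forward(sm, config))
    return out


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleResult:
    value: float
    marginals: np.ndarray  # p x q, d value / d mu by exhaustive enumeration
    best_score: float
    best_states: str


def enumerate_paths_oracle(
    scores: ScoreMatrices, config: SmoothingConfig = SmoothingConfig()
) -> OracleResult:
    """Exhaustive path enumeration (test oracle; exponential, grids <= 36 cells).

    Enumerates every monotone path admitted by the border mode, scores each
    path exactly as the recursion does, and aggregates by temperature-scaled
    log-sum-exp.  Marginals are the softmax-weighted mu-coefficients per
    cell, i.e. the exact gradient d value / d mu."""
    p, q = scores.shape
    if p * q > 36:
        raise ValueError("grid too large for exhaustive enumeration (> 36 cells)")
    mu, gap = scores.mu, scores.gap
    tau = config.temperature
    mu_on_gaps = config.mu_on_gaps

    def cell_score(i: int, j: int, b: int) -> float:
        if b == _M:
            return mu[i - 1, j - 1]
        s = gap[i - 1, j - 1]
        if mu_on_gaps:
            s += mu[i - 1, j - 1]
        return s

    path_scores: list[float] = []
    path_cells: list[list[tuple[int, int, int]]] = []

    def extend(i: int, j: int, score: float, cells: list):
        if i == p and j == q:
            path_scores.append(score)
            path_cells.append(list(cells))
            return
        if i < p and j < q:
            cells.append((i + 1, j + 1, _M))
            extend(i + 1, j + 1, score + cell_score(i + 1, j + 1, _M), cells)
            cells.pop()
        if i < p:
            cells.append((i + 1, j, _X))
            extend(i + 1, j, score + cell_score(i + 1, j, _X), cells)
            cells.pop()
        if j < q:
            cells.append((i, j + 1, _Y))
            extend(i, j + 1, score + cell_score(i, j + 1, _Y), cells)
            cells.pop()

    if config.border_mode == "path_strict":
        # every path starts by matching cell (1,1)
        extend(1, 1, cell_score(1, 1, _M), [(1, 1, _M)])
    else:
        # paths may start at any cell whose entry branch reads a boundary
        # value; (0,0) carries initialization 1, the rest of the border 0
        for i in range(1, p + 1):
            for j in range(1, q + 1):
                if i == 1 or j == 1:  # match entry from boundary (i-1, j-1)
                    start = 1.0 if (i == 1 and j == 1) else 0.0
                    extend(i, j, start + cell_score(i, j, _M), [(i, j, _M)])
                if i == 1:  # insert entry from boundary (0, j)
                    extend(i, j, cell_score(i, j, _X), [(i, j, _X)])
                if j == 1:  # delete entry from boundary (i, 0)
                    extend(i, j, cell_score(i, j, _Y), [(i, j, _Y)])

    arr = np.array(path_scores)
    value = float(tau * _scipy_lse(arr / tau))
    w = np.exp((arr - arr.max()) / tau)
    w /= w.sum()
    marg = np.zeros((p, q))
    for weight, cells in zip(w, path_cells):
        for (i, j, b) in cells:
            if mu_on_gaps or b == _M:
                marg[i - 1, j - 1] += weight
    best_idx = int(np.argmax(arr))
    best_states = "".join("MXY"[b] for (_, _, b) in path_cells[best_idx])
    return OracleResult(
        value=value,
        marginals=marg,
        best_score=float(arr[best_idx]),
        best_states=best_states,
    )


# ---------------------------------------------------------------------------
# debug serialization
# ---------------------------------------------------------------------------


def write_expected_tsv(path, expected: ExpectedAlignment) -> None:
    """Write (i, j, e_ij) rows, 1-based coordinates."""
    e = expected.e
    with open(path, "w") as fh:
        fh.write("i\tj\te\n")
        for i in range(e.shape[0]):
            for j in range(e.shape[1]):
                fh.write(f"{i + 1}\t{j + 1}\t{e[i, j]:.12g}\n")


def read_expected_tsv(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "i\tj\te":
            raise ValueError("not an expected-alignment TSV")
        for line in fh:
            i, j, v = line.split("\t")
            rows.append((int(i), int(j), float(v)))
    p = max(r[0] for r in rows)
    q = max(r[1] for r in rows)
    e = np.zeros((p, q))
    for i, j, v in rows:
        e[i - 1, j - 1] = v
    return e
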