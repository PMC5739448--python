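"""Power iteration, Hotelling deflation, and eigenvector-subspace collection.

Power iteration on the *left* eigenproblem,

    u_{i+1} = u_i . J / ||u_i . J||,

converges to the leading left eigenvector (the leading mode) when the
largest-magnitude eigenvalue is well separated, and the Euclidean norm
||u . J|| of the last iterate approximates its magnitude.  The value of the
algorithm here is not numerical efficiency but interpretability: watching
which Jacobian entries stretch the iterate exposes the mode-determining
elements of J.  Hotelling deflation,

    J_{t+1} = J_t - u_t^T (u_t . J_t) / (u_t . u_t^T),

removes a converged eigenpair so iteration finds the next one, allowing a
walk down the timescale hierarchy.  When several eigenvalues are close in
magnitude the iterates converge into the spanned eigenvector *subspace*
instead of a single direction; running many random starts and collecting
linearly independent ending vectors recovers that subspace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

#: the dot-product convergence band: successive unit iterates must satisfy
#: | |<u_{i+1}, u_i>| - 1 | <= DOT_BAND  (i.e. lie in [0.9999, 1.0001]).
DOT_BAND = 1e-4


@dataclass
class PowerIterationTrace:
    """Iterate history of one power-iteration run.

    ``vectors`` stacks the starting vector and every normalized iterate
    (all unit Euclidean norm); ``norms[i]`` is ||u_i . J||, the eigenvalue
    magnitude approximation at step i.
    """

    vectors: np.ndarray
    norms: np.ndarray
    converged: bool
    status: str  # "converged" | "max_iterations" | "null_vector" | "complex_pair"
    n_iterations: int
    eigenvalue_magnitude: float
    rayleigh: float
    final_dot: float
    final_rel_change: float
    complex_pair: tuple[complex, complex] | None = None
    subspace: np.ndarray | None = None

    @property
    def final_vector(self) -> np.ndarray:
        return self.vectors[-1]


def _unit_random(rng: np.random.Generator, m: int) -> np.ndarray:
    u = rng.standard_normal(m)
    return u / np.linalg.norm(u)


def power_iterate(
    J: np.ndarray,
    u0: np.ndarray | None = None,
    max_iters: int = 1000,
    tol: float = 1e-12,
    criterion: str = "both",
    dot_band: float = DOT_BAND,
    seed: int | None = None,
    n_iters: int | None = None,
) -> PowerIterationTrace:
    """Left power iteration with the two convergence criteria AND-combined.

    ``criterion`` selects stopping: "norm" (relative change of the
    eigenvalue magnitude approximation below ``tol``), "dot" (successive
    iterates' absolute inner product within ``dot_band`` of 1), or "both"
    (default: both must hold).  Passing ``n_iters`` runs exactly that many
    iterations with no early stop.  A run whose iterate lands in the null
    space, or that oscillates because the leading eigenpair is complex,
    is reported through ``status`` rather than silently returned: for a
    suspected complex pair the last two iterates are orthonormalized into a
    2-dimensional real invariant-subspace estimate with the projected
    eigenvalues attached.
    """
    J = np.asarray(J, dtype=float)
    m = J.shape[0]
    if u0 is None:
        u0 = _unit_random(np.random.default_rng(seed), m)
    u = np.asarray(u0, dtype=float)
    nrm0 = np.linalg.norm(u)
    if nrm0 == 0:
        raise ValueError("starting vector must be nonzero")
    u = u / nrm0
    vectors = [u.copy()]
    norms: list[float] = []
    scale = np.linalg.norm(J, ord=2)
    prev_norm = None
    dot = math.nan
    rel_change = math.nan
    status = "max_iterations"
    converged = False
    limit = n_iters if n_iters is not None else max_iters
    for _ in range(limit):
        w = u @ J
        nrm = float(np.linalg.norm(w))
        if nrm <= 1e-14 * max(scale, 1e-300):
            norms.append(nrm)
            status = "null_vector"
            break
        u_next = w / nrm
        dot = float(u_next @ u)
        rel_change = (
            abs(nrm - prev_norm) / nrm if prev_norm is not None else math.inf
        )
        norms.append(nrm)
        vectors.append(u_next.copy())
        u = u_next
        prev_norm = nrm
        if n_iters is None:
            norm_ok = rel_change < tol
            dot_ok = abs(abs(dot) - 1.0) <= dot_band
            if criterion == "norm":
                ok = norm_ok
            elif criterion == "dot":
                ok = dot_ok
            elif criterion == "both":
                ok = norm_ok and dot_ok
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            if ok:
                status = "converged"
                converged = True
                break
    if n_iters is not None:
        status = "fixed_iterations"
    rayleigh = float(u @ J @ u)
    complex_pair = None
    subspace = None
    if status == "max_iterations" and len(vectors) >= 3:
        # persistent |dot| < 1 with oscillating norms: complex leading pair
        if abs(abs(dot) - 1.0) > dot_band:
            Q = np.linalg.qr(np.stack([vectors[-1], vectors[-2]]).T)[0]
            C = Q.T @ J.T @ Q
            pair = np.linalg.eigvals(C)
            if abs(pair[0].imag) > 0:
                status = "complex_pair"
                complex_pair = (complex(pair[0]), complex(pair[1]))
                subspace = Q.T
    return PowerIterationTrace(
        vectors=np.stack(vectors),
        norms=np.array(norms),
        converged=converged,
        status=status,
        n_iterations=len(norms),
        eigenvalue_magnitude=float(norms[-1]) if len(norms) else 0.0,
        rayleigh=rayleigh,
        final_dot=dot,
        final_rel_change=rel_change,
        complex_pair=complex_pair,
        subspace=subspace,
    )


def hotelling_deflate(
    J: np.ndarray, u: np.ndarray, lambda_est: float | None = None
) -> np.ndarray:
    """Remove a left eigenpair: J' = J - u^T (u.J) / (u.u^T).

    For any u the projector form annihilates u exactly (u.J' = 0); when u is
    a left eigenvector of a diagonalizable J the remaining spectrum is
    preserved and lambda is replaced by 0.  Passing ``lambda_est`` uses the
    classical rank-one form J - lambda u^T u / (u.u^T) instead, which
    deflates by the estimate rather than the exact projection.
    """
    J = np.asarray(J, dtype=float)
    u = np.asarray(u, dtype=float)
    uu = float(u @ u)
    if uu == 0.0:
        raise ValueError("cannot deflate with a zero vector")
    if lambda_est is None:
        return J - np.outer(u, u @ J) / uu
    return J - lambda_est * np.outer(u, u) / uu


@dataclass
class DeflationStep:
    u: np.ndarray
    eigenvalue: float  # signed Rayleigh estimate
    magnitude: float
    timescale: float
    residual_vs_original: float
    annihilation_residual: float = math.nan  # ||u.J_{t+1}|| / ||J|| after deflation


@dataclass
class DeflationSequence:
    """Eigenpairs collected while deflating down the timescale hierarchy."""

    steps: list[DeflationStep]
    final_J: np.ndarray
    status: str  # "reached" | "exhausted" | "stalled"
    target_timescale: float

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.array([s.eigenvalue for s in self.steps])


def deflate_until_timescale(
    J: np.ndarray,
    target_timescale: float,
    seed: int = 0,
    max_deflations: int | None = None,
    **power_kwargs,
) -> DeflationSequence:
    """Alternate power iteration and deflation until a timescale is reached.

    Each round finds the current leading left eigenpair and records it; the
    walk stops (without deflating further) once the magnitude timescale
    1/|lambda| of the current leading estimate is at least
    ``target_timescale``.  If the spectrum is exhausted first (iterates fall
    into the null space) the sequence is flagged "exhausted"; a
    non-converging round flags "stalled" and returns the partial sequence.
    Deflation error is tracked as ||u . J_original - lambda u|| relative to
    ||J_original|| for every recorded pair.
    """
    J0 = np.asarray(J, dtype=float)
    Jt = J0.copy()
    rng = np.random.default_rng(seed)
    scale = np.linalg.norm(J0, ord=2)
    steps: list[DeflationStep] = []
    if max_deflations is None:
        max_deflations = J0.shape[0]
    # the walk is exhausted once it has recorded one eigenpair per nonzero
    # singular direction; a norm test cannot tell residual deflation error
    # (~sqrt(tol).||J||) from a genuinely small trailing eigenvalue.
    sv = np.linalg.svd(J0, compute_uv=False)
    n_nonzero = int(np.sum(sv > 1e-10 * sv[0])) if sv.size else 0
    status = "stalled"
    for _ in range(max_deflations + 1):
        if len(steps) >= n_nonzero:
            status = "exhausted"
            break
        trace = power_iterate(Jt, u0=_unit_random(rng, J0.shape[0]), **power_kwargs)
        if trace.status == "null_vector":
            status = "exhausted"
            break
        if not trace.converged:
            status = "stalled"
            break
        u = trace.final_vector
        mag = trace.eigenvalue_magnitude
        lam = trace.rayleigh
        res = float(np.linalg.norm(u @ J0 - lam * u) / (scale or 1.0))
        tau = math.inf if mag == 0 else 1.0 / mag
        steps.append(
            DeflationStep(
                u=u, eigenvalue=lam, magnitude=mag, timescale=tau,
                residual_vs_original=res,
            )
        )
        if tau >= target_timescale:
            status = "reached"
            break
        Jt = hotelling_deflate(Jt, u)
        steps[-1].annihilation_residual = float(
            np.linalg.norm(u @ Jt) / (scale or 1.0)
        )
    return DeflationSequence(
        steps=steps, final_J=Jt, status=status, target_timescale=target_timescale
    )


@dataclass
class ClusterCollection:
    """Linearly independent ending vectors from many random starts.

    ``basis`` stacks the kept ending vectors (the rank-increment sweep keeps
    a vector only if it raises the numerical rank of the collection at
    ``rank_tol``); ``eigenvalue_estimates`` are the final iterate norms of
    all runs, which settle in the range of the similarly dominant
    eigenvalue cluster.
    """

    basis: np.ndarray
    kept_indices: list[int]
    eigenvalue_estimates: np.ndarray
    ending_vectors: np.ndarray
    n_starts: int
    n_iters: int

    @property
    def dimension(self) -> int:
        return self.basis.shape[0]

    def principal_angles_to(self, other_basis: np.ndarray) -> np.ndarray:
        """Principal angles (radians) between the collected span and another."""
        return sla.subspace_angles(self.basis.T, np.asarray(other_basis).T)


def cluster_subspace(
    J: np.ndarray,
    n_starts: int = 100,
    n_iters: int = 100,
    seed: int = 0,
    rank_tol: float = 1e-10,
) -> ClusterCollection:
    """Probe a clustered leading eigenvalue group with many fixed-length runs.

    ``J`` should already be deflated down to the cluster of interest.  Each
    of ``n_starts`` random unit vectors is multiplied through exactly
    ``n_iters`` iterations; ending vectors are swept in order and kept when
    the singular-value rank (threshold ``rank_tol`` times the largest) of
    the running collection increases.
    """
    J = np.asarray(J, dtype=float)
    rng = np.random.default_rng(seed)
    m = J.shape[0]
    endings = []
    estimates = []
    for _ in range(n_starts):
        trace = power_iterate(J, u0=_unit_random(rng, m), n_iters=n_iters)
        endings.append(trace.final_vector)
        estimates.append(trace.eigenvalue_magnitude)
    endings = np.stack(endings)
    kept: list[int] = []
    for i in range(n_starts):
        candidate = endings[kept + [i]]
        sv = np.linalg.svd(candidate, compute_uv=False)
        rank = int(np.sum(sv > rank_tol * sv[0]))
        if rank > len(kept):
            kept.append(i)
    return ClusterCollection(
        basis=endings[kept],
        kept_indices=kept,
        eigenvalue_estimates=np.array(estimates),
        ending_vectors=endings,
        n_starts=n_starts,
        n_iters=n_iters,
    )


@dataclass
class PCAResult:
    """Uncentered principal components of a stack of iteration vectors.

    ``contributions`` are squared-singular-value fractions (summing to 1);
    the first component tracks the leading eigenvector direction.  The
    decomposition is uncentered because the iterates alternate sign under a
    negative leading eigenvalue, making the mean direction meaningless.
    """

    contributions: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray
    scores: np.ndarray

    def alignment(self, direction: np.ndarray) -> float:
        """|cos| between the first principal component and a direction."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return float(abs(self.components[0] @ d))


def pca_iteration_vectors(
    traces: list[PowerIterationTrace] | np.ndarray,
) -> PCAResult:
    """PCA over all iteration vectors (starting vectors included)."""
    if isinstance(traces, np.ndarray):
        X = np.asarray(traces, dtype=float)
    else:
        X = np.vstack([t.vectors for t in traces])
    if X.shape[0] < 2:
        raise ValueError("need at least two vectors for PCA")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    power = s**2
    total = power.sum()
    contributions = power / total if total > 0 else power
    return PCAResult(
        contributions=contributions,
        components=Vt,
        singular_values=s,
        scores=U * s,
    )


@dataclass
class SubmatrixPerturbation:
    """Leading left eigenvector before and after editing Jacobian entries."""

    original: np.ndarray
    edited: np.ndarray
    eigenvalue_before: complex
    eigenvalue_after: complex
    vector_before: np.ndarray
    vector_after: np.ndarray

    def element_ratio(self, i: int, j: int, which: str = "after") -> float:
        """|v_i| / |v_j| of the requested eigenvector (diagnostic)."""
        v = self.vector_after if which == "after" else self.vector_before
        return float(abs(v[i]) / abs(v[j]))


def _leading_left(M: np.ndarray) -> tuple[complex, np.ndarray]:
    w, V = sla.eig(M.T)
    i = int(np.argmax(np.abs(w)))
    v = V[:, i]
    pivot = v[int(np.argmax(np.abs(v)))]
    v = v * (abs(pivot) / pivot)
    if np.allclose(v.imag, 0, atol=1e-12):
        v = v.real
    return complex(w[i]), v


def perturb_submatrix(
    J_sub: np.ndarray, edits: list[tuple[int, int, float]]
) -> SubmatrixPerturbation:
    """Apply entry edits to a Jacobian submatrix and compare leading modes.

    ``edits`` is a list of (row, col, new_value) applied in order, e.g. the
    two structured experiments: copy the (2,2) diagonal into (4,4), then
    symmetrize the off-diagonal pair (2,4) = (4,2).  A fully symmetric key
    block yields equal-magnitude eigenvector entries on its two positions.
    """
    A = np.asarray(J_sub, dtype=float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("submatrix must be square")
    lam0, v0 = _leading_left(A)
    B = A.copy()
    for i, j, val in edits:
        B[i, j] = val
    lam1, v1 = _leading_left(B)
    return SubmatrixPerturbation(
        original=A,
        edited=B,
        eigenvalue_before=lam0,
        eigenvalue_after=lam1,
        vector_before=v0,
        vector_after=v1,
    )
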