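"""Eigendecomposition of the Jacobian into modes and timescales.

The modal matrix M^-1 stacks the left eigenvectors of J (rows u with
u.J = lambda.u); its rows are the *modes*, dynamically independent
combinations m_i = <u_i | x> that obey dm_i/dt = lambda_i m_i in the linear
regime.  Rows spanning the left null space of J (moiety conservation sums)
are appended with eigenvalue exactly zero so the modal matrix is full rank.

Each mode decays on the characteristic timescale -1/Re(lambda).  Truncating
coefficients below 5% of the mode's maximum gives its effective support,
and modes whose truncated support reduces to a diagonally dominant species
are classified as explained by diagonal dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla

from .dominance import diagonal_fraction

DEFAULT_TRUNCATION_CUTOFF = 0.05


@dataclass
class ModalDecomposition:
    """Eigenvalues and left eigenvectors of J, plus appended null-space rows.

    ``modal_matrix`` is m x m with rows ordered by \\|Re(lambda)\\| descending
    (conservation rows, lambda = 0, last).  Rows are unit Euclidean norm
    with the largest-magnitude entry rotated to be positive real.
    ``n_conservation`` counts the appended left-null-space rows.
    """

    eigenvalues: np.ndarray
    modal_matrix: np.ndarray
    species: list[str] | None
    n_conservation: int
    condition: float
    defective: bool
    J: np.ndarray = field(repr=False)

    @property
    def timescales(self) -> np.ndarray:
        return np.array([timescale(l) for l in self.eigenvalues])

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_coefficients(self, i: int) -> np.ndarray:
        return self.modal_matrix[i]

    def reconstruction_error(self) -> float:
        """Relative error of M . Lambda . M^-1 against J."""
        Minv = self.modal_matrix
        M = np.linalg.inv(Minv)
        recon = M @ np.diag(self.eigenvalues) @ Minv
        scale = np.linalg.norm(self.J) or 1.0
        return float(np.linalg.norm(recon.real - self.J) / scale)

    def residuals(self) -> np.ndarray:
        """Row-wise ||u.J - lambda.u|| for every mode."""
        UJ = self.modal_matrix @ self.J
        return np.linalg.norm(UJ - self.eigenvalues[:, None] * self.modal_matrix, axis=1)

    def propagate(self, x_dev0: Sequence[float], t: Sequence[float]) -> np.ndarray:
        """Linear-regime deviations x'(t) = M exp(Lambda t) M^-1 x'(0).

        Returns a (len(t), m) real array.  Conservation modes (lambda = 0)
        persist unchanged, exactly as in the nonlinear dynamics.
        """
        x_dev0 = np.asarray(x_dev0, dtype=complex)
        Minv = self.modal_matrix
        M = np.linalg.inv(Minv)
        m0 = Minv @ x_dev0
        t = np.asarray(t, dtype=float)
        out = np.empty((len(t), len(x_dev0)))
        for k, tk in enumerate(t):
            out[k] = (M @ (np.exp(self.eigenvalues * tk) * m0)).real
        return out


@dataclass
class Mode:
    """One row of the modal matrix after truncation and classification."""

    index: int
    eigenvalue: complex
    coefficients: np.ndarray
    support: list[int]
    classification: str  # "explained" | "complex" | "conservation"
    dominant_species: int | None = None
    diagonal_fraction: float | None = None
    cluster_id: int | None = None
    species: list[str] | None = None

    @property
    def timescale(self) -> float:
        return timescale(self.eigenvalue)

    def support_names(self) -> list[str]:
        if self.species is None:
            return [str(i) for i in self.support]
        return [self.species[i] for i in self.support]


def _fix_row(u: np.ndarray) -> np.ndarray:
    u = u / np.linalg.norm(u)
    k = int(np.argmax(np.abs(u)))
    pivot = u[k]
    if pivot != 0:
        u = u * (abs(pivot) / pivot)
    if np.allclose(u.imag, 0.0, atol=1e-13):
        u = u.real.astype(complex)
    return u


def eigendecompose(
    J: np.ndarray,
    species: list[str] | None = None,
    zero_rtol: float = 1e-10,
) -> ModalDecomposition:
    """Left-eigendecompose J and append orthonormal left-null-space rows.

    Eigenvalues with magnitude below ``zero_rtol * ||J||`` are identified
    with the left null space: their rows are replaced by an orthonormal
    basis of null(J^T) and their eigenvalues are set to exactly zero.  A
    defective (non-diagonalizable) input is reported through ``defective``
    and ``condition`` (condition number of the modal matrix) but a
    decomposition is still returned.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    m = J.shape[0]
    scale = np.linalg.norm(J, 2) if m else 0.0
    w, V = sla.eig(J.T)  # J^T v = w v  =>  v^T J = w v^T
    U = V.T.copy()

    null_basis = sla.null_space(J.T, rcond=zero_rtol)
    k_null = null_basis.shape[1]
    order_small = np.argsort(np.abs(w))
    null_idx = set(int(i) for i in order_small[:k_null])
    rows = []
    vals = []
    for i in range(m):
        if i in null_idx:
            continue
        rows.append(_fix_row(U[i]))
        vals.append(w[i])
    for j in range(k_null):
        rows.append(_fix_row(null_basis[:, j].astype(complex)))
        vals.append(0.0 + 0.0j)
    vals = np.array(vals)
    rows = np.array(rows)

    nonnull = np.argsort(-np.abs(vals[: m - k_null].real), kind="stable")
    order = np.concatenate([nonnull, np.arange(m - k_null, m)])
    vals, rows = vals[order], rows[order]

    cond = float(np.linalg.cond(rows)) if m else 1.0
    return ModalDecomposition(
        eigenvalues=vals,
        modal_matrix=rows,
        species=list(species) if species is not None else None,
        n_conservation=k_null,
        condition=cond,
        defective=not math.isfinite(cond) or cond > 1e12,
        J=J,
    )


def mode_value(u: Sequence[float], x: Sequence[float]) -> complex | float:
    """Inner product m = <u|x> of a mode row with a concentration vector."""
    u = np.asarray(u)
    x = np.asarray(x)
    if u.shape != x.shape:
        raise ValueError("mode and state vectors must have equal length")
    out = complex(np.dot(u, x))
    return out.real if out.imag == 0.0 else out


def timescale(eigenvalue: complex) -> float:
    """Characteristic relaxation time -1/Re(lambda).

    Returns ``inf`` for a conservation mode (Re = 0) and a *negative* value
    for an unstable mode (Re > 0), which callers should treat as a flag.
    """
    re = complex(eigenvalue).real
    if re == 0.0:
        return math.inf
    return -1.0 / re


def truncate_mode(
    coefficients: Sequence[float], cutoff: float = DEFAULT_TRUNCATION_CUTOFF
) -> list[int]:
    """Indices with |c_j| >= cutoff * max|c|; ties at the threshold kept."""
    c = np.abs(np.asarray(coefficients))
    cmax = c.max(initial=0.0)
    if cmax == 0.0:
        raise ValueError("cannot truncate an all-zero mode")
    return [int(i) for i in np.nonzero(c >= cutoff * cmax)[0]]


@dataclass
class ModeClassificationSummary:
    explained: int
    complex: int
    conservation: int

    @property
    def total_nonnull(self) -> int:
        return self.explained + self.complex

    @property
    def total(self) -> int:
        return self.total_nonnull + self.conservation

    @property
    def explained_percentage(self) -> float:
        if self.total_nonnull == 0:
            return float("nan")
        return 100.0 * self.explained / self.total_nonnull

    @property
    def explained_percentage_including_conservation(self) -> float:
        """Same tally with lambda = 0 rows in the denominator.

        Whether conservation rows belong in the mode count is a reporting
        convention; both tallies are exposed so summaries can state theirs.
        """
        if self.total == 0:
            return float("nan")
        return 100.0 * self.explained / self.total


def _cluster_ids(eigenvalues: np.ndarray, rel_gap: float = 1e-6) -> list[int | None]:
    """Group near-degenerate eigenvalues (relative gap below ``rel_gap``)."""
    ids: list[int | None] = [None] * len(eigenvalues)
    mags = np.abs(eigenvalues)
    next_id = 0
    for i in range(len(eigenvalues)):
        if mags[i] == 0:
            continue
        for j in range(i):
            if mags[j] == 0:
                continue
            if abs(eigenvalues[i] - eigenvalues[j]) <= rel_gap * max(mags[i], mags[j]):
                ids[i] = ids[j] if ids[j] is not None else next_id
                if ids[j] is None:
                    ids[j] = next_id
                    next_id += 1
                break
    return ids


def classify_dominance_modes(
    decomposition: ModalDecomposition,
    J: np.ndarray | None = None,
    cutoff: float = DEFAULT_TRUNCATION_CUTOFF,
    dominance_threshold: float = 1.0,
) -> tuple[list[Mode], ModeClassificationSummary]:
    """Label every mode explained-by-diagonal-dominance, complex, or conservation.

    A non-conservation mode is *explained* when, after truncating
    coefficients below ``cutoff`` of the maximum, either (a) a single
    species remains and its row of J is diagonally dominant (f below
    ``dominance_threshold``), or (b) several remain but the largest
    coefficient is at least twice the runner-up and belongs to the most
    diagonally dominant (smallest-f) species of the support, itself
    dominant.  Complex eigenvalues are handled through coefficient
    magnitudes.  Conservation modes are tallied separately.
    """
    if J is None:
        J = decomposition.J
    modes: list[Mode] = []
    n_exp = n_cpx = n_null = 0
    clusters = _cluster_ids(decomposition.eigenvalues)
    for i in range(decomposition.n_modes):
        lam = decomposition.eigenvalues[i]
        coeffs = decomposition.modal_matrix[i]
        if lam == 0:
            n_null += 1
            modes.append(
                Mode(
                    index=i,
                    eigenvalue=lam,
                    coefficients=coeffs,
                    support=truncate_mode(coeffs, cutoff),
                    classification="conservation",
                    cluster_id=clusters[i],
                    species=decomposition.species,
                )
            )
            continue
        support = truncate_mode(coeffs, cutoff)
        mags = np.abs(coeffs[support])
        order = np.argsort(-mags)
        top = support[int(order[0])]
        f_top = diagonal_fraction(J, top)
        explained = False
        if len(support) == 1:
            explained = f_top < dominance_threshold
        else:
            second = mags[order[1]]
            fs = [diagonal_fraction(J, s) for s in support]
            most_dominant = support[int(np.argmin(fs))]
            explained = (
                mags[order[0]] >= 2.0 * second
                and top == most_dominant
                and f_top < dominance_threshold
            )
        cls = "explained" if explained else "complex"
        n_exp += explained
        n_cpx += not explained
        modes.append(
            Mode(
                index=i,
                eigenvalue=lam,
                coefficients=coeffs,
                support=support,
                classification=cls,
                dominant_species=top,
                diagonal_fraction=f_top,
                cluster_id=clusters[i],
                species=decomposition.species,
            )
        )
    return modes, ModeClassificationSummary(
        explained=n_exp, complex=n_cpx, conservation=n_null
    )
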