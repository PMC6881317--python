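"""61-state codon substitution model and pruning likelihood.

The model is the standard reversible codon parameterisation: instantaneous
rate pi_j * kappa^{ts} * omega^{nonsyn} between codons one nucleotide
apart, zero otherwise.  kappa is the transition/transversion rate ratio,
omega = dN/dS.  Each branch carries its own omega (grouped into classes by
the branch models); the generator is rescaled per branch so that branch
lengths are expected substitutions per codon at that branch's omega.

Log likelihoods are computed by Felsenstein pruning over codon-site
patterns, with per-node rescaling to keep partials in range on deep trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .genetic_code import (
    CODON_INDEX,
    N_STATES,
    PAIR_I,
    PAIR_IS_SYN,
    PAIR_IS_TS,
    PAIR_J,
    SENSE_CODONS,
)
from .seq_tree_io import CodonAlignment, PhyloTree, pair_check

OMEGA_CAP = 999.0  # reporting convention for effectively infinite dN/dS
OMEGA_FLOOR = 1e-6
KAPPA_BOUNDS = (1e-3, 100.0)
FREQ_FLOOR = 1e-10


@dataclass
class CodonModelSpec:
    """Parameter bundle for the branch-specific codon model."""

    kappa: float
    omega_of_branch: dict[int, float]
    freqs: np.ndarray
    freq_mode: str = "observed"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_STATES,):
            raise ValueError(f"frequency vector must have {N_STATES} entries")
        if np.any(self.freqs < 0) or abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be non-negative and sum to 1")
        if not (KAPPA_BOUNDS[0] <= self.kappa <= KAPPA_BOUNDS[1]):
            raise ValueError(f"kappa {self.kappa} outside {KAPPA_BOUNDS}")
        for b, w in self.omega_of_branch.items():
            if not (OMEGA_FLOOR <= w <= OMEGA_CAP):
                raise ValueError(f"omega {w} on branch {b} outside bounds")


@dataclass
class BranchFit:
    """A fitted branch-specific model."""

    lnL: float
    np: int
    kappa_hat: float
    omega_hat: dict[int, float]  # class index -> omega
    branch_lengths_hat: np.ndarray
    counts: dict[int, tuple[float, float]]  # branch_id -> (nN, nS)
    converged: bool = True
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# equilibrium frequencies
# ---------------------------------------------------------------------------


def codon_frequencies(aln: CodonAlignment, mode: str = "observed") -> np.ndarray:
    """Equilibrium sense-codon frequencies from a gap-free alignment.

    Modes: ``uniform`` (1/61 each), ``F1x4`` / ``F3x4`` (products of
    overall / per-position nucleotide frequencies, stop mass renormalised
    away), ``observed`` (empirical codon proportions).  Zero-frequency
    sense codons are floored at a tiny positive value so downstream
    likelihoods stay finite.
    """
    if mode == "uniform":
        return np.full(N_STATES, 1.0 / N_STATES)

    cells = [c for c in aln.codons.flat if c in CODON_INDEX]
    if not cells:
        raise ValueError("alignment has no sense codons")

    if mode == "observed":
        freqs = np.zeros(N_STATES)
        for c in cells:
            freqs[CODON_INDEX[c]] += 1.0
    elif mode in ("F1x4", "F3x4"):
        nt_index = {n: k for k, n in enumerate("ACGT")}
        if mode == "F1x4":
            counts = np.zeros(4)
            for c in cells:
                for n in c:
                    counts[nt_index[n]] += 1.0
            pos = [counts / counts.sum()] * 3
        else:
            pos = []
            for p in range(3):
                counts = np.zeros(4)
                for c in cells:
                    counts[nt_index[c[p]]] += 1.0
                pos.append(counts / counts.sum())
        freqs = np.array(
            [pos[0][nt_index[c[0]]] * pos[1][nt_index[c[1]]] * pos[2][nt_index[c[2]]]
             for c in SENSE_CODONS]
        )
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")

    freqs = np.maximum(freqs, 0.0)
    freqs = freqs / freqs.sum()
    freqs = np.maximum(freqs, FREQ_FLOOR)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# rate and transition matrices
# ---------------------------------------------------------------------------


def _generator(freqs: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Unscaled generator; off-diagonal pi_j * kappa^{ts} * omega^{nonsyn}."""
    q = np.zeros((N_STATES, N_STATES))
    rates = freqs[PAIR_J] * np.where(PAIR_IS_TS, kappa, 1.0)
    rates = rates * np.where(PAIR_IS_SYN, 1.0, omega)
    q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def rate_matrix(spec: CodonModelSpec, omega: float) -> np.ndarray:
    """Scaled generator: expected substitutions per unit time equal 1."""
    q = _generator(spec.freqs, spec.kappa, omega)
    scale = -float(np.dot(spec.freqs, np.diag(q)))
    return q / scale


def substitution_rate(freqs: np.ndarray, kappa: float, omega: float) -> float:
    """Equilibrium substitution flux of the *unscaled* generator.

    Dividing a generator by this value normalises it to one expected
    substitution per codon per unit time; site-class mixtures share one
    scale so that relative rates between classes reflect omega.
    """
    rates = freqs[PAIR_I] * freqs[PAIR_J] * np.where(PAIR_IS_TS, kappa, 1.0)
    rates = rates * np.where(PAIR_IS_SYN, 1.0, omega)
    return float(rates.sum())


def flux_fractions(freqs: np.ndarray, kappa: float, omega: float) -> tuple[float, float]:
    """Equilibrium (non-synonymous, synonymous) fractions of total flow."""
    rates = freqs[PAIR_I] * freqs[PAIR_J] * np.where(PAIR_IS_TS, kappa, 1.0)
    rates = rates * np.where(PAIR_IS_SYN, 1.0, omega)
    total = rates.sum()
    rho_n = rates[~PAIR_IS_SYN].sum() / total
    return rho_n, 1.0 - rho_n


def expected_substitutions(
    spec: CodonModelSpec, branch_id: int, t: float, n_codons: int
) -> tuple[float, float]:
    """Expected (nN, nS) counts along a fitted branch.

    ``t`` is in substitutions per codon, so nN + nS = n_codons * t.
    """
    omega = spec.omega_of_branch[branch_id]
    rho_n, rho_s = flux_fractions(spec.freqs, spec.kappa, omega)
    total = n_codons * t
    return total * rho_n, total * rho_s


class _Eigen:
    """Eigendecomposition of a scaled reversible generator.

    ``scale`` defaults to the generator's own equilibrium flux (one
    substitution per unit time at this omega); mixture models pass a
    shared scale instead.
    """

    def __init__(
        self, freqs: np.ndarray, kappa: float, omega: float, scale: float | None = None
    ):
        q = _generator(freqs, kappa, omega)
        if scale is None:
            scale = -float(np.dot(freqs, np.diag(q)))
        q /= scale
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)  # symmetrise away rounding noise
        w, v = scipy.linalg.eigh(sym)
        self.eigvals = w
        self.left = v / sqrt_pi[:, None]  # D^{-1/2} V
        self.right = (v * sqrt_pi[:, None]).T  # V^T D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.maximum(p, 0.0, out=p)
        return p

    def transitions(self, ts) -> np.ndarray:
        """Batched P(t) for many branch lengths: one BLAS call."""
        ts = np.asarray(ts, dtype=float)
        expv = np.exp(self.eigvals[None, :] * ts[:, None])  # (n, 61)
        scaled = self.left[None, :, :] * expv[:, None, :]
        p = (scaled.reshape(-1, N_STATES) @ self.right).reshape(
            len(ts), N_STATES, N_STATES
        )
        np.maximum(p, 0.0, out=p)
        return p


def transition_matrix(q: np.ndarray, t: float, freqs: np.ndarray | None = None) -> np.ndarray:
    """P = exp(Qt).  Uses the symmetric transform when ``freqs`` is given."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if freqs is None:
        p = scipy.linalg.expm(q * t)
    else:
        sqrt_pi = np.sqrt(freqs)
        sym = 0.5 * ((sqrt_pi[:, None] * q) / sqrt_pi[None, :])
        sym = sym + sym.T
        w, v = scipy.linalg.eigh(sym)
        p = ((v / sqrt_pi[:, None]) * np.exp(w * t)) @ (v * sqrt_pi[:, None]).T
    np.maximum(p, 0.0, out=p)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise FloatingPointError("transition matrix rows failed to normalise")
    return p


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Felsenstein pruning over compressed codon-site patterns.

    Built once per (alignment, tree) pair; every likelihood evaluation
    supplies per-branch transition matrices.  Site patterns are collapsed
    to unique columns with multiplicities, which dominates the speedup on
    real-size alignments.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        pair_check(aln, tree)
        if not aln.is_gap_free():
            raise ValueError("pruning requires a gap-free alignment (complete_deletion)")
        self.tree = tree
        self.n_branches = tree.n_branches

        order = tree.postorder()
        leaves = [n for n in order if n.is_leaf]
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        codes = np.empty((aln.n_taxa, aln.site_count), dtype=np.int16)
        for i in range(aln.n_taxa):
            for j in range(aln.site_count):
                codes[i, j] = CODON_INDEX[aln.codons[i, j]]
        # reorder rows to leaf traversal order, then compress columns
        leaf_rows = np.array([row_of[n.name] for n in leaves])
        cols = codes[leaf_rows].T  # (n_sites, n_leaves)
        patterns, pattern_of_site, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_leaves, n_patterns)
        self.pattern_of_site = pattern_of_site
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.n_sites = aln.site_count

        self._order = order
        self._leaf_index = {id(n): k for k, n in enumerate(leaves)}
        # rescaling at every 4th internal node (and the root) keeps
        # partials in range for trees far larger than these analyses use,
        # at a fraction of the per-node cost
        internals = [n for n in order if not n.is_leaf]
        self._rescale_at = {
            id(n) for k, n in enumerate(internals) if k % 4 == 3
        }
        self._rescale_at.add(id(order[-1]))

    def site_pattern_logliks(
        self, p_of_branch: dict[int, np.ndarray], freqs: np.ndarray
    ) -> np.ndarray:
        """Per-pattern log likelihoods given per-branch transition matrices."""
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self._order:
            if node.is_leaf:
                continue
            acc = None
            logf = None
            for ch in node.children:
                p = p_of_branch[ch.branch_id]
                if ch.is_leaf:
                    states = self.patterns[self._leaf_index[id(ch)]]
                    contrib = p[:, states]
                    ch_log = None
                else:
                    contrib = p @ partial.pop(id(ch))
                    ch_log = scale.pop(id(ch), None)
                acc = contrib if acc is None else acc * contrib
                if ch_log is not None:
                    logf = ch_log if logf is None else logf + ch_log
            if id(node) in self._rescale_at:
                m = acc.max(axis=0)
                m[m == 0.0] = 1.0
                acc /= m
                add = np.log(m)
                logf = add if logf is None else logf + add
            partial[id(node)] = acc
            if logf is not None:
                scale[id(node)] = logf
        root = self._order[-1]
        site_lik = freqs @ partial[id(root)]
        return np.log(np.maximum(site_lik, 1e-300)) + scale.get(id(root), 0.0)

    def site_pattern_logliks_multi(
        self, p_of_branch: dict[int, np.ndarray], freqs: np.ndarray
    ) -> np.ndarray:
        """As :meth:`site_pattern_logliks`, for C models at once.

        ``p_of_branch`` maps each branch to a (C, 61, 61) stack of
        transition matrices (one per site class / model); returns a
        (C, n_patterns) array.  One traversal with batched matrix
        products replaces C separate prunings.
        """
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self._order:
            if node.is_leaf:
                continue
            acc = None
            logf = None
            for ch in node.children:
                p = p_of_branch[ch.branch_id]  # (C, 61, 61)
                if ch.is_leaf:
                    states = self.patterns[self._leaf_index[id(ch)]]
                    contrib = p[:, :, states]
                    ch_log = None
                else:
                    contrib = np.matmul(p, partial.pop(id(ch)))
                    ch_log = scale.pop(id(ch), None)
                acc = contrib if acc is None else acc * contrib
                if ch_log is not None:
                    logf = ch_log if logf is None else logf + ch_log
            if id(node) in self._rescale_at:
                m = acc.max(axis=1)  # (C, n_patterns)
                m[m == 0.0] = 1.0
                acc /= m[:, None, :]
                add = np.log(m)
                logf = add if logf is None else logf + add
            partial[id(node)] = acc
            if logf is not None:
                scale[id(node)] = logf
        root = self._order[-1]
        site_lik = np.einsum("s,csp->cp", freqs, partial[id(root)])
        out = np.log(np.maximum(site_lik, 1e-300))
        if id(root) in scale:
            out = out + scale[id(root)]
        return out

    def loglik(self, p_of_branch: dict[int, np.ndarray], freqs: np.ndarray) -> float:
        return float(self.counts @ self.site_pattern_logliks(p_of_branch, freqs))

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector back to per-site order."""
        return per_pattern[..., self.pattern_of_site]


def branch_p_matrices(
    freqs: np.ndarray,
    kappa: float,
    omega_of_branch: dict[int, float],
    lengths: np.ndarray,
) -> dict[int, np.ndarray]:
    """Transition matrices per branch: one eigendecomposition and one
    batched exponential per distinct omega."""
    by_omega: dict[float, list[int]] = {}
    for b, w in omega_of_branch.items():
        by_omega.setdefault(w, []).append(b)
    out = {}
    for w, branch_ids in by_omega.items():
        eig = _Eigen(freqs, kappa, w)
        mats = eig.transitions([float(lengths[b]) for b in branch_ids])
        out.update(zip(branch_ids, mats))
    return out


def log_likelihood(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec) -> float:
    """Pruning log likelihood of a codon alignment under a fitted spec.

    Branch lengths are taken from the tree; a single-taxon alignment
    reduces to the sum of log equilibrium frequencies.
    """
    if aln.n_taxa == 1:
        return float(
            sum(np.log(spec.freqs[CODON_INDEX[c]]) for c in aln.codons[0])
        )
    engine = PruningEngine(aln, tree)
    p = branch_p_matrices(
        spec.freqs, spec.kappa, spec.omega_of_branch, tree.branch_lengths
    )
    return engine.loglik(p, spec.freqs)
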