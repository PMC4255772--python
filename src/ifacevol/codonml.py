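"""Codon-substitution maximum likelihood on a fixed tree.

The model is the Goldman–Yang style codon process: instantaneous change is
restricted to single-nucleotide codon moves, with rate proportional to the
target codon's equilibrium frequency (F3×4), multiplied by κ for transitions
and by ω for nonsynonymous changes.  The generator is scaled so branch
lengths are expected nucleotide substitutions per codon.  Stop codons are
excluded from the state space (61 states for the universal code, 60 for the
vertebrate mitochondrial code).

Implemented model structures:

* M0 — one ω shared by all sites; used to estimate branch lengths.
* fixed-sites — one ω per predefined site partition, shared κ, branch
  lengths fixed (the study's partitioned analysis).
* M1a / M2a — nearly-neutral and positive-selection site mixtures, compared
  by a χ²(2) likelihood-ratio test.

Per-branch nonsynonymous divergence is apportioned by conditional expected
labelled Markov counts under the fitted model (not by refitting free-ratio
models), divided by the partition's κ/π-weighted nonsynonymous site count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._codes import get_code, single_change_pairs
from .codonsort import CodonAlignment
from .divergence import _f3x4, _yn00_site_table
from .trees import PhyloTree

__all__ = [
    "CodonModelSpec",
    "FitResult",
    "BranchDN",
    "f3x4_frequencies",
    "gy94_rate_matrix",
    "transition_matrix",
    "TreeLikelihood",
    "tree_loglik",
    "fit_m0",
    "fit_fixed_sites",
    "fit_site_models_lrt",
    "branch_dn",
]

_MIN_BL = 1e-8
# floor on equilibrium frequencies: keeps the symmetrized generator
# well-conditioned when small alignments leave codons unobserved
_PI_FLOOR = 1e-6


@dataclass
class CodonModelSpec:
    """Parameters of a GY94-style codon model."""

    code_table: int = 2
    pi: np.ndarray | None = None  # sense-codon frequencies, sums to 1
    kappa: float = 2.0
    omega: float = 0.4

    def __post_init__(self):
        code = get_code(self.code_table)
        if self.pi is None:
            self.pi = np.full(code.n_states, 1.0 / code.n_states)
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.pi) != code.n_states:
            raise ValueError("pi length does not match sense-codon count")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")


@dataclass
class FitResult:
    lnl: float
    params: dict
    converged: bool
    n_function_evals: int
    model: str


@dataclass
class BranchDN:
    """Per-branch dN per partition plus the between-partition difference."""

    branch_ids: list  # child-node ids, one per branch
    dn: dict  # partition name -> (n_branches,) array
    difference: np.ndarray | None = None  # dN[a] - dN[b] per branch
    diff_parts: tuple = ()


def f3x4_frequencies(aln: CodonAlignment, code_table=None) -> np.ndarray:
    """F3×4 sense-codon frequencies: per-position nucleotide frequencies
    multiplied and renormalised over the sense codons; gaps excluded."""
    code = get_code(code_table if code_table is not None else aln.code_table)
    return _f3x4(aln.codons, code)


def gy94_rate_matrix(spec: CodonModelSpec, omega: float | None = None) -> np.ndarray:
    """Scaled GY94 generator over sense codons.

    Rows sum to zero and the matrix is scaled so the expected number of
    nucleotide substitutions per codon per unit time, -Σ πᵢ qᵢᵢ, equals 1.
    """
    omega = spec.omega if omega is None else omega
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if spec.kappa <= 0:
        raise ValueError("kappa must be positive")
    code = get_code(spec.code_table)
    pi = np.maximum(spec.pi, _PI_FLOOR)
    pi = pi / pi.sum()
    ii, jj, ts, ns = single_change_pairs(code.table_id)
    n = code.n_states
    Q = np.zeros((n, n))
    rate = pi[jj] * np.where(ts, spec.kappa, 1.0) * np.where(ns, omega, 1.0)
    Q[ii, jj] = rate
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def _eig_reversible(Q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a reversible generator.

    Returns (w, V, Vinv) with Q = V diag(w) Vinv.
    """
    sqrt_pi = np.sqrt(pi)
    # S = D^{1/2} Q D^{-1/2} with D = diag(pi): symmetric for reversible Q
    S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    w, E = np.linalg.eigh(S)
    w = np.minimum(w, 0.0)  # generator eigenvalues are nonpositive
    V = E / sqrt_pi[:, None]
    Vinv = E.T * sqrt_pi[None, :]
    return w, V, Vinv


def transition_matrix(spec: CodonModelSpec, omega: float, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length (clipped at 0 probability)."""
    Q = gy94_rate_matrix(spec, omega)
    pi = np.maximum(spec.pi, _PI_FLOOR)
    pi = pi / pi.sum()
    w, V, Vinv = _eig_reversible(Q, pi)
    P = (V * np.exp(w * t)[None, :]) @ Vinv
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------


class _Patterns:
    """Compressed site patterns for one partition."""

    def __init__(self, states: np.ndarray):
        # states: (T, L) sense-state indices, -1 ambiguous
        uniq, counts = np.unique(states, axis=1, return_counts=True)
        self.states = uniq  # (T, n_patterns)
        self.weights = counts.astype(float)
        self.n_columns = states.shape[1]


class TreeLikelihood:
    """Felsenstein pruning for a codon alignment on a fixed topology.

    Supports per-partition ω assignment (fixed-sites), scalar ω (M0) and
    ω mixtures (M1a/M2a).  π is F3×4 from the full alignment unless given.
    """

    def __init__(
        self,
        tree: PhyloTree,
        aln: CodonAlignment,
        code_table=None,
        pi: np.ndarray | None = None,
        partition: dict | None = None,
    ):
        self.code = get_code(code_table if code_table is not None else aln.code_table)
        self.tree = tree
        order = tree.tip_index()
        missing = [t for t in aln.taxa if t not in order]
        if missing or tree.n_tips != aln.n_taxa:
            raise ValueError(f"tree/alignment taxon mismatch: {missing[:5]}")
        # rows ordered by tree tip id
        idx = aln.codon_indices()
        states = np.full_like(idx, -1)
        for t in range(aln.n_taxa):
            for c in range(aln.n_columns):
                codon = aln.codons[t, c]
                s = self.code.sense_index.get(codon)
                if s is None and idx[t, c] >= 0:
                    raise ValueError(
                        f"stop codon {codon} at taxon {aln.taxa[t]!r}, "
                        f"codon site {c + 1}"
                    )
                states[t, c] = -1 if s is None else s
        row_of = [order[t] for t in aln.taxa]
        reordered = np.empty_like(states)
        for src, dst in enumerate(row_of):
            reordered[dst] = states[src]
        self.pi = _f3x4(aln.codons, self.code) if pi is None else np.asarray(pi)
        self.pi = np.maximum(self.pi, _PI_FLOOR)
        self.pi /= self.pi.sum()
        if partition is None:
            partition = {"all": list(range(aln.n_columns))}
        self.partition_names = list(partition)
        self.patterns = {
            name: _Patterns(reordered[:, np.asarray(cols, dtype=int)])
            for name, cols in partition.items()
        }
        self._postorder = tree.postorder()
        self._eig_cache: dict = {}

    # -- model pieces ----------------------------------------------------
    def _eig(self, kappa: float, omega: float):
        key = (round(float(kappa), 12), round(float(omega), 12))
        if key not in self._eig_cache:
            spec = CodonModelSpec(
                code_table=self.code.table_id, pi=self.pi, kappa=kappa, omega=1.0
            )
            spec.kappa = kappa
            Q = gy94_rate_matrix(spec, omega)
            self._eig_cache[key] = _eig_reversible(Q, self.pi)
            if len(self._eig_cache) > 64:
                self._eig_cache.pop(next(iter(self._eig_cache)))
        return self._eig_cache[key]

    def _branch_matrices(self, lengths: np.ndarray, kappa: float, omega: float):
        w, V, Vinv = self._eig(kappa, omega)
        mats = {}
        for bid, t in zip(self.tree.branch_ids(), lengths):
            t = max(float(t), _MIN_BL)
            P = (V * np.exp(w * t)[None, :]) @ Vinv
            mats[bid] = np.clip(P, 0.0, None)
        return mats

    # -- pruning ---------------------------------------------------------
    def _prune(self, pat: _Patterns, mats: dict):
        """Root partials with per-pattern log-scale; returns (partials, logscale)."""
        tree = self.tree
        n_pat = pat.states.shape[1]
        S = self.code.n_states
        partial = {}
        logscale = np.zeros(n_pat)
        for node in self._postorder:
            if node < tree.n_tips:
                continue
            acc = np.ones((n_pat, S))
            for child in tree.children[node]:
                P = mats[child]
                if child < tree.n_tips:
                    st = pat.states[child]
                    msg = np.where(
                        (st >= 0)[:, None], P.T[np.maximum(st, 0)], 1.0
                    )
                else:
                    msg = partial.pop(child) @ P.T
                acc *= msg
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[node] = acc
        return partial[tree.root], logscale

    def _site_lik(self, pat, lengths, kappa, omega):
        mats = self._branch_matrices(np.asarray(lengths, float), kappa, omega)
        root, logscale = self._prune(pat, mats)
        lik = root @ self.pi
        return lik, logscale

    def loglik(self, lengths, kappa: float, omegas) -> float:
        """lnL with one ω per partition (scalar ω broadcasts)."""
        omegas = np.broadcast_to(
            np.asarray(omegas, dtype=float).ravel(), (len(self.partition_names),)
        )
        total = 0.0
        for name, om in zip(self.partition_names, omegas):
            pat = self.patterns[name]
            lik, logscale = self._site_lik(pat, lengths, kappa, om)
            if (lik <= 0).any():
                return -np.inf
            total += float(pat.weights @ (np.log(lik) + logscale))
        return total

    def mixture_loglik(self, lengths, kappa, omegas, weights) -> float:
        """lnL of an ω mixture (site classes unknown, shared proportions)."""
        omegas = np.asarray(omegas, dtype=float)
        weights = np.asarray(weights, dtype=float)
        total = 0.0
        for name in self.partition_names:
            pat = self.patterns[name]
            liks, scales = [], []
            for om in omegas:
                lik, logscale = self._site_lik(pat, lengths, kappa, om)
                liks.append(lik)
                scales.append(logscale)
            scales = np.array(scales)
            liks = np.array(liks)
            ref = scales.max(axis=0)
            mix = (weights[:, None] * liks * np.exp(scales - ref[None, :])).sum(axis=0)
            if (mix <= 0).any():
                return -np.inf
            total += float(pat.weights @ (np.log(mix) + ref))
        return total

    # -- expected labelled counts ---------------------------------------
    def expected_nonsyn_counts(self, lengths, kappa: float, omega: float, name=None):
        """Expected nonsynonymous substitution count per branch.

        Conditional on the tip data, under the fitted model: for each branch
        the expectation of the number of nonsynonymous labelled transitions
        of the underlying Markov chain, summed over the partition's columns.
        Returns dict branch(child id) -> expected count.
        """
        if name is None:
            name = self.partition_names[0]
        pat = self.patterns[name]
        tree = self.tree
        S = self.code.n_states
        n_pat = pat.states.shape[1]
        w, V, Vinv = self._eig(kappa, omega)
        Q = (V * w[None, :]) @ Vinv
        ii, jj, _, ns = single_change_pairs(self.code.table_id)
        C = np.zeros((S, S))
        C[ii[ns], jj[ns]] = Q[ii[ns], jj[ns]]
        G = Vinv @ C @ V

        lengths = np.asarray(lengths, dtype=float)
        mats = self._branch_matrices(lengths, kappa, omega)
        bl = {bid: max(float(t), _MIN_BL) for bid, t in zip(tree.branch_ids(), lengths)}

        # below partials (unscaled ratios are all we need; rescale per node)
        below = {}
        for node in self._postorder:
            if node < tree.n_tips:
                st = pat.states[node]
                b = np.zeros((n_pat, S))
                known = st >= 0
                b[known, st[known]] = 1.0
                b[~known] = 1.0
            else:
                b = np.ones((n_pat, S))
                for child in tree.children[node]:
                    b *= below[child] @ mats[child].T
                mx = b.max(axis=1)
                b = b / np.where(mx > 0, mx, 1.0)[:, None]
            below[node] = b

        # above arrays: A[v][p, i] = lik of data outside subtree v given the
        # state i at v's parent (π folded in at the root); scaled per node.
        above = {}
        for node in tree.preorder():
            if node == tree.root:
                for child in tree.children[node]:
                    A = np.tile(self.pi[None, :], (n_pat, 1))
                    for sib in tree.children[node]:
                        if sib != child:
                            A = A * (below[sib] @ mats[sib].T)
                    mx = A.max(axis=1)
                    above[child] = A / np.where(mx > 0, mx, 1.0)[:, None]
                continue
            for child in tree.children[node]:
                A = above[node] @ mats[node]
                for sib in tree.children[node]:
                    if sib != child:
                        A = A * (below[sib] @ mats[sib].T)
                mx = A.max(axis=1)
                above[child] = A / np.where(mx > 0, mx, 1.0)[:, None]

        counts = {}
        for bid in tree.branch_ids():
            t = bl[bid]
            ew = np.exp(w * t)
            diff = w[:, None] - w[None, :]
            K = np.where(
                np.abs(diff) < 1e-10,
                t * ew[:, None],
                (ew[:, None] - ew[None, :]) / np.where(np.abs(diff) < 1e-10, 1.0, diff),
            )
            U = V @ (G * K) @ Vinv
            A, b = above[bid], below[bid]
            denom = np.einsum("pi,ij,pj->p", A, mats[bid], b)
            numer = np.einsum("pi,ij,pj->p", A, U, b)
            ok = denom > 0
            ratio = np.where(ok, numer / np.where(ok, denom, 1.0), 0.0)
            counts[bid] = float(pat.weights @ np.clip(ratio, 0.0, None))
        return counts


def tree_loglik(tree: PhyloTree, aln: CodonAlignment, spec: CodonModelSpec, column_omegas=None) -> float:
    """Log-likelihood of an alignment on a tree under a GY94 model.

    ``column_omegas`` optionally assigns an ω to every column (fixed-sites
    style); by default all columns share ``spec.omega``.
    """
    if column_omegas is None:
        tl = TreeLikelihood(tree, aln, spec.code_table, spec.pi)
        return tl.loglik(tree.branch_lengths(), spec.kappa, spec.omega)
    column_omegas = np.asarray(column_omegas, dtype=float)
    if len(column_omegas) != aln.n_columns:
        raise ValueError("one omega per column required")
    part = {}
    for col, om in enumerate(column_omegas):
        part.setdefault(float(om), []).append(col)
    tl = TreeLikelihood(tree, aln, spec.code_table, spec.pi, partition=part)
    return tl.loglik(
        tree.branch_lengths(), spec.kappa, np.array(list(part), dtype=float)
    )


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def _lbfgs(fun, x0, bounds):
    res = optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10},
    )
    return res


def fit_m0(
    tree: PhyloTree,
    aln: CodonAlignment,
    spec: CodonModelSpec | None = None,
    init_kappa: float = 2.0,
    init_omega: float = 0.4,
) -> FitResult:
    """M0 fit: maximise lnL over branch lengths, κ and a single ω.

    The fitted branch lengths (substitutions per codon) are the ones the
    partitioned and site-model fits keep fixed downstream.
    """
    if tree.n_tips < 3:
        raise ValueError("M0 fit needs at least 3 taxa")
    code_table = spec.code_table if spec else aln.code_table
    pi = spec.pi if spec else None
    tl = TreeLikelihood(tree, aln, code_table, pi)
    nb = tree.n_branches
    bl0 = np.clip(tree.branch_lengths(), 1e-3, 10.0)
    if not np.isfinite(tl.loglik(bl0, init_kappa, init_omega)):
        bl0 = np.full(nb, 0.1)
    x0 = np.concatenate([np.log(bl0), [np.log(init_kappa), np.log(init_omega)]])
    bounds = [(np.log(_MIN_BL), np.log(50.0))] * nb + [
        (np.log(0.01), np.log(100.0)),
        (np.log(1e-4), np.log(99.0)),
    ]
    evals = [0]

    def nll(x):
        evals[0] += 1
        val = tl.loglik(np.exp(x[:nb]), np.exp(x[nb]), np.exp(x[nb + 1]))
        return -val if np.isfinite(val) else 1e12

    res = _lbfgs(nll, x0, bounds)
    lengths = np.exp(res.x[:nb])
    return FitResult(
        lnl=-res.fun,
        params={
            "branch_lengths": lengths,
            "kappa": float(np.exp(res.x[nb])),
            "omega": float(np.exp(res.x[nb + 1])),
            "tree": tree.with_lengths(lengths),
            "pi": tl.pi,
        },
        converged=bool(res.success),
        n_function_evals=evals[0],
        model="M0",
    )


def fit_fixed_sites(
    tree: PhyloTree,
    aln: CodonAlignment,
    partition: dict,
    code_table=None,
    pi=None,
    init_kappa: float = 2.0,
    with_se: bool = True,
) -> FitResult:
    """Fixed-sites fit: shared κ, one ω per site partition, lengths fixed.

    ``partition`` maps partition name -> column indices.  Empty partitions
    are skipped with a warning entry in the result; an all-empty partition
    set is an error.  Standard errors come from the observed information
    (numeric curvature of the profile at the optimum).
    """
    names = [n for n, cols in partition.items() if len(cols) > 0]
    skipped = [n for n in partition if n not in names]
    if not names:
        raise ValueError("all partitions are empty")
    part = {n: partition[n] for n in names}
    tl = TreeLikelihood(tree, aln, code_table, pi, partition=part)
    K = len(names)
    lengths = tree.branch_lengths()
    x0 = np.concatenate([[np.log(init_kappa)], np.full(K, np.log(0.3))])
    bounds = [(np.log(0.01), np.log(100.0))] + [(np.log(1e-4), np.log(99.0))] * K
    evals = [0]

    def nll(x):
        evals[0] += 1
        val = tl.loglik(lengths, np.exp(x[0]), np.exp(x[1:]))
        return -val if np.isfinite(val) else 1e12

    res = _lbfgs(nll, x0, bounds)
    kappa = float(np.exp(res.x[0]))
    omegas = np.exp(res.x[1:])
    ses = {}
    if with_se:
        for k, name in enumerate(names):
            h = max(1e-4, 1e-3 * omegas[k])

            def prof(om):
                o = omegas.copy()
                o[k] = om
                return tl.loglik(lengths, kappa, o)

            f0 = prof(omegas[k])
            curv = (prof(omegas[k] + h) - 2 * f0 + prof(omegas[k] - h)) / h**2
            ses[name] = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan
    return FitResult(
        lnl=-res.fun,
        params={
            "kappa": kappa,
            "omega": {n: float(o) for n, o in zip(names, omegas)},
            "omega_se": ses,
            "skipped_partitions": skipped,
            "pi": tl.pi,
        },
        converged=bool(res.success),
        n_function_evals=evals[0],
        model="fixed-sites",
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _fit_m1a(tl: TreeLikelihood, lengths, starts):
    best = None
    total_evals = 0
    for kappa0, p0, om0 in starts:
        x0 = np.array(
            [np.log(kappa0), np.log(p0 / (1 - p0)), np.log(om0 / (1 - om0))]
        )

        def nll(x):
            kappa = np.exp(np.clip(x[0], -5, 5))
            p0_ = _sigmoid(np.clip(x[1], -12, 12))
            om0_ = 1e-4 + (1 - 2e-4) * _sigmoid(np.clip(x[2], -12, 12))
            val = tl.mixture_loglik(lengths, kappa, [om0_, 1.0], [p0_, 1 - p0_])
            return -val if np.isfinite(val) else 1e12

        res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 300})
        total_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(np.clip(best.x[0], -5, 5)))
    p0 = float(_sigmoid(np.clip(best.x[1], -12, 12)))
    om0 = float(1e-4 + (1 - 2e-4) * _sigmoid(np.clip(best.x[2], -12, 12)))
    return FitResult(
        lnl=-best.fun,
        params={"kappa": kappa, "p": [p0, 1 - p0], "omega": [om0, 1.0]},
        converged=bool(best.success),
        n_function_evals=total_evals,
        model="M1a",
    )


def _fit_m2a(tl: TreeLikelihood, lengths, starts):
    best = None
    total_evals = 0
    for kappa0, p0, p1, om0, om2 in starts:
        p2 = max(1e-3, 1 - p0 - p1)
        x0 = np.array(
            [
                np.log(kappa0),
                np.log(p0 / p2),
                np.log(p1 / p2),
                np.log(om0 / (1 - om0)),
                np.log(om2 - 1 + 1e-6),
            ]
        )

        def nll(x):
            kappa = np.exp(np.clip(x[0], -5, 5))
            a, b = np.clip(x[1], -12, 12), np.clip(x[2], -12, 12)
            z = np.exp([a, b, 0.0])
            p = z / z.sum()
            om0_ = 1e-4 + (1 - 2e-4) * _sigmoid(np.clip(x[3], -12, 12))
            om2_ = 1.0 + np.exp(np.clip(x[4], -14, 4))
            val = tl.mixture_loglik(lengths, kappa, [om0_, 1.0, om2_], p)
            return -val if np.isfinite(val) else 1e12

        res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 400})
        total_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(np.clip(best.x[0], -5, 5)))
    z = np.exp([np.clip(best.x[1], -12, 12), np.clip(best.x[2], -12, 12), 0.0])
    p = (z / z.sum()).tolist()
    om0 = float(1e-4 + (1 - 2e-4) * _sigmoid(np.clip(best.x[3], -12, 12)))
    om2 = float(1.0 + np.exp(np.clip(best.x[4], -14, 4)))
    return FitResult(
        lnl=-best.fun,
        params={"kappa": kappa, "p": p, "omega": [om0, 1.0, om2]},
        converged=bool(best.success),
        n_function_evals=total_evals,
        model="M2a",
    )


def fit_site_models_lrt(
    tree: PhyloTree,
    aln: CodonAlignment,
    code_table=None,
    pi=None,
    fit_lengths: bool = False,
) -> dict:
    """M1a-vs-M2a likelihood-ratio test for positive selection.

    Branch lengths are taken from the tree (typically an M0 fit); set
    ``fit_lengths=True`` to run the M0 fit here first.  The statistic
    2(lnL_M2a − lnL_M1a) is floored at zero and referred to χ² with 2 df.
    """
    if fit_lengths:
        m0 = fit_m0(tree, aln, CodonModelSpec(code_table=code_table or aln.code_table))
        tree = m0.params["tree"]
    tl = TreeLikelihood(tree, aln, code_table, pi)
    lengths = tree.branch_lengths()
    m1a = _fit_m1a(tl, lengths, [(2.0, 0.7, 0.2), (2.0, 0.4, 0.6), (4.0, 0.9, 0.05)])
    m2a = _fit_m2a(
        tl,
        lengths,
        [
            (2.0, 0.6, 0.3, 0.2, 2.0),
            (2.0, 0.4, 0.4, 0.5, 5.0),
            (4.0, 0.8, 0.15, 0.05, 1.5),
        ],
    )
    stat = 2.0 * (m2a.lnl - m1a.lnl)
    failed = stat < -1e-6
    stat = max(stat, 0.0)
    return {
        "lnL_M1a": m1a.lnl,
        "lnL_M2a": m2a.lnl,
        "stat": stat,
        "p": float(stats.chi2.sf(stat, df=2)),
        "m1a": m1a,
        "m2a": m2a,
        "optimizer_failure": bool(failed),
    }


def nonsyn_site_count(code, kappa: float, pi: np.ndarray, n_columns: int) -> float:
    """Mutational-opportunity nonsynonymous site count of a partition."""
    s64 = _yn00_site_table(code, kappa, pi)
    sense_idx = [i for i in range(64) if np.isfinite(s64[i])]
    s_sense = s64[sense_idx]
    return float(n_columns * (pi * (3.0 - s_sense)).sum())


def branch_dn(
    tree: PhyloTree,
    aln: CodonAlignment,
    partition: dict,
    omegas: dict,
    kappa: float,
    code_table=None,
    pi=None,
    diff: tuple | None = None,
) -> BranchDN:
    """Per-branch dN per partition and the per-branch difference statistic.

    For each branch and partition, the conditional expected nonsynonymous
    substitution count under the fitted model (ω per partition, shared κ,
    fixed lengths) is divided by the partition's nonsynonymous site count.
    ``diff=(a, b)`` names the two partitions whose per-branch difference
    dN_a − dN_b is reported (e.g. Mt–nu contact minus Mt–mt contact).
    """
    part = {n: cols for n, cols in partition.items() if len(cols) > 0}
    tl = TreeLikelihood(tree, aln, code_table, pi, partition=part)
    lengths = tree.branch_lengths()
    branch_ids = tree.branch_ids()
    dn = {}
    for name in part:
        counts = tl.expected_nonsyn_counts(lengths, kappa, omegas[name], name)
        nsites = nonsyn_site_count(tl.code, kappa, tl.pi, len(part[name]))
        dn[name] = np.array([counts[b] / nsites for b in branch_ids])
    difference = None
    if diff is not None:
        a, b = diff
        if a in dn and b in dn:
            difference = dn[a] - dn[b]
    return BranchDN(branch_ids=branch_ids, dn=dn, difference=difference, diff_parts=diff or ())
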