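"""Pairwise nonsynonymous divergence, ΣdN, and the interaction ratio.

dN (nonsynonymous substitutions per nonsynonymous site) is estimated per
unordered sequence pair by counting methods:

* ``ng86`` — Nei–Gojobori style: per-codon synonymous site fractions averaged
  over the two sequences, multi-hit codons averaged over minimal mutational
  pathways avoiding stop codons, Jukes–Cantor correction
  ``d = -(3/4) ln(1 - 4p/3)``.
* ``yn00`` (default) — adds transition/transversion (κ) and codon-frequency
  (F3×4) weighting to the site counts and pathway averaging, with κ estimated
  from fourfold-degenerate and nondegenerate positions (K80) and
  K80-style distance corrections applied separately to the transition and
  transversion components of pS and pN.

ΣdN is the sum of pairwise dN over all unordered pairs of a codon subset; the
interaction ratio is the quotient of two ΣdN values, read as "numerator class
evolves faster" when above 1.  Because the per-pair counts are additive over
columns, subset ΣdN values (resampling nulls, bootstrap standard errors) are
computed from a per-column cache rather than by re-running the estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._codes import (
    codon_index,
    get_code,
    is_transition,
    ng86_diff_tables,
    ng86_syn_sites,
    pathway_counts_detailed,
)
from .codonsort import CodonAlignment

__all__ = [
    "PairwiseDN",
    "DivergenceSummary",
    "PairStatsCache",
    "pairwise_dn",
    "sum_dn",
    "interaction_ratio",
]


@dataclass
class PairwiseDN:
    dn: float  # NaN when saturated/undefined
    ds: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    kappa_hat: float
    usable_codons: int
    method: str = "ng86"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.dn)


@dataclass
class DivergenceSummary:
    sum_dn: float
    n_pairs: int  # pairs contributing to the sum
    n_undefined_pairs: int  # excluded (saturated / no usable codons)
    se_sum_dn: float | None = None
    method: str = "yn00"


def _jc(p):
    """Jukes–Cantor correction; NaN at/beyond saturation (p >= 3/4)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - 4.0 * p / 3.0
        out = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
    return out


def _k80(P, Q):
    """Kimura two-parameter distance from transition/transversion proportions."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (a1 > 0) & (a2 > 0)
        d = np.where(
            ok,
            -0.5 * np.log(np.where(ok, a1, 1.0))
            - 0.25 * np.log(np.where(ok, a2, 1.0)),
            np.nan,
        )
    return d


# ---------------------------------------------------------------------------
# YN00-style helpers
# ---------------------------------------------------------------------------


def _degeneracy(codon: str, code) -> tuple:
    """Per-position degeneracy class: 4 (all syn), 0 (all nonsyn), else 2."""
    out = []
    aa0 = code.aa[codon_index(codon)]
    for pos in range(3):
        syn = tot = 0
        for n in "ACGT":
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            if code.is_stop(alt):
                continue
            tot += 1
            if code.aa[codon_index(alt)] == aa0:
                syn += 1
        if tot and syn == tot:
            out.append(4)
        elif syn == 0:
            out.append(0)
        else:
            out.append(2)
    return tuple(out)


def _estimate_kappa(c1_codons, c2_codons, code) -> float:
    """κ from K80 at fourfold-degenerate and nondegenerate positions.

    Falls back to 2.0 when the data are too sparse or too diverged for a
    stable estimate (e.g. identical sequences).
    """
    counts = {4: [0, 0, 0], 0: [0, 0, 0]}  # class -> [n, ts, tv]
    for a, b in zip(c1_codons, c2_codons):
        d1, d2 = _degeneracy(a, code), _degeneracy(b, code)
        for pos in range(3):
            cls = d1[pos]
            if cls != d2[pos] or cls == 2:
                continue
            counts[cls][0] += 1
            if a[pos] != b[pos]:
                if is_transition(a[pos], b[pos]):
                    counts[cls][1] += 1
                else:
                    counts[cls][2] += 1
    kappas, weights = [], []
    for cls, (n, ts, tv) in counts.items():
        if n == 0:
            continue
        P, Q = ts / n, tv / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            continue
        alpha = -0.5 * np.log(a1) + 0.25 * np.log(a2)
        beta = -0.25 * np.log(a2)
        if beta > 1e-9 and alpha > 0:
            kappas.append(alpha / beta)
            weights.append(n)
    if not kappas:
        return 2.0
    return float(np.average(kappas, weights=weights))


def _f3x4(codon_matrix, code) -> np.ndarray:
    """F3×4 sense-codon frequencies from a (T, L) codon-string matrix."""
    freqs = np.zeros((3, 4))
    nuc_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for codon in np.asarray(codon_matrix).ravel():
        if codon_index(codon) < 0:
            continue
        for pos, n in enumerate(codon):
            freqs[pos, nuc_idx[n]] += 1
    if (freqs.sum(axis=1) == 0).any():
        raise ValueError("a codon position has no observed nucleotides")
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.zeros(len(code.sense_codons))
    for s, codon in enumerate(code.sense_codons):
        pi[s] = (
            freqs[0, nuc_idx[codon[0]]]
            * freqs[1, nuc_idx[codon[1]]]
            * freqs[2, nuc_idx[codon[2]]]
        )
    return pi / pi.sum()


def _yn00_site_table(code, kappa: float, pi_sense: np.ndarray) -> np.ndarray:
    """Per-codon synonymous site counts with κ/frequency-weighted opportunities."""
    out = np.full(64, np.nan)
    for s, codon in enumerate(code.sense_codons):
        idx = codon_index(codon)
        wsyn = wtot = 0.0
        for pos in range(3):
            for n in "ACGT":
                if n == codon[pos]:
                    continue
                alt = codon[:pos] + n + codon[pos + 1 :]
                j = code.sense_index.get(alt)
                if j is None:
                    continue
                w = (kappa if is_transition(codon[pos], n) else 1.0) * pi_sense[j]
                wtot += w
                if code.aa[codon_index(alt)] == code.aa[idx]:
                    wsyn += w
        out[idx] = 3.0 * wsyn / wtot if wtot > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Additive per-column pair statistics
# ---------------------------------------------------------------------------


class PairStatsCache:
    """Per-(pair, column) counting statistics, additive over column subsets.

    For every unordered taxon pair and alignment column the cache holds the
    averaged synonymous site count, a usable-column flag, and the
    pathway-averaged substitution counts split by transition/transversion.
    ΣdN over any column subset then reduces to array sums followed by the
    method's distance correction, which makes resampling nulls and column
    bootstraps cheap and exactly consistent with :func:`pairwise_dn`.
    """

    def __init__(self, aln: CodonAlignment, method: str = "yn00", code_table=None):
        method = method.lower()
        if method not in ("ng86", "yn00"):
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.code = get_code(code_table if code_table is not None else aln.code_table)
        self.taxa = list(aln.taxa)
        self.pairs = list(itertools.combinations(range(len(self.taxa)), 2))
        codons = aln.codons
        T, L = codons.shape
        idx = aln.codon_indices()
        sense_ok = np.zeros((T, L), dtype=bool)
        for t in range(T):
            for c in range(L):
                sense_ok[t, c] = codons[t, c] in self.code.sense_index
        P = len(self.pairs)
        self.usable = np.zeros((P, L), dtype=bool)
        self.s_sites = np.zeros((P, L))  # averaged synonymous sites
        # substitution counts: syn-ts, syn-tv, nonsyn-ts, nonsyn-tv
        self.counts = np.zeros((P, L, 4))
        self.kappa = np.full(P, np.nan)

        if method == "ng86":
            s64 = ng86_syn_sites(self.code.table_id)
            sd64, nd64 = ng86_diff_tables(self.code.table_id)
            for p, (i, j) in enumerate(self.pairs):
                ok = sense_ok[i] & sense_ok[j]
                self.usable[p] = ok
                ci, cj = idx[i, ok], idx[j, ok]
                self.s_sites[p, ok] = 0.5 * (s64[ci] + s64[cj])
                # ts/tv split not needed for the JC correction: park totals
                self.counts[p, ok, 0] = sd64[ci, cj]
                self.counts[p, ok, 2] = nd64[ci, cj]
        else:
            pi = _f3x4(codons, self.code)
            for p, (i, j) in enumerate(self.pairs):
                ok = sense_ok[i] & sense_ok[j]
                self.usable[p] = ok
                kappa = _estimate_kappa(codons[i, ok], codons[j, ok], self.code)
                self.kappa[p] = kappa
                s64 = _yn00_site_table(self.code, kappa, pi)
                detail = {}
                cols = np.where(ok)[0]
                for c in cols:
                    a, b = codons[i, c], codons[j, c]
                    self.s_sites[p, c] = 0.5 * (s64[codon_index(a)] + s64[codon_index(b)])
                    key = (a, b) if a <= b else (b, a)
                    if key not in detail:
                        detail[key] = pathway_counts_detailed(
                            key[0], key[1], self.code, kappa
                        )
                    self.counts[p, c] = detail[key]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_stats(self, columns=None):
        """Aggregate (usable, S, N, counts) over a column subset, per pair."""
        if columns is None:
            usable = self.usable.sum(axis=1)
            S = self.s_sites.sum(axis=1)
            C = self.counts.sum(axis=1)
        else:
            cols = np.asarray(columns, dtype=int)
            usable = self.usable[:, cols].sum(axis=1)
            S = self.s_sites[:, cols].sum(axis=1)
            C = self.counts[:, cols].sum(axis=1)
        N = 3.0 * usable - S
        return usable, S, N, C

    def _distances(self, usable, S, N, C):
        """Per-pair (dn, ds) with the method's correction; NaN when undefined."""
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.method == "ng86":
                pn = np.where(N > 0, (C[..., 2] + C[..., 3]) / N, np.nan)
                ps = np.where(S > 0, (C[..., 0] + C[..., 1]) / S, np.nan)
                dn, ds = _jc(pn), _jc(ps)
            else:
                Pn = np.where(N > 0, C[..., 2] / N, np.nan)
                Qn = np.where(N > 0, C[..., 3] / N, np.nan)
                Ps = np.where(S > 0, C[..., 0] / S, np.nan)
                Qs = np.where(S > 0, C[..., 1] / S, np.nan)
                dn, ds = _k80(Pn, Qn), _k80(Ps, Qs)
        dn = np.where(usable > 0, dn, np.nan)
        ds = np.where(usable > 0, ds, np.nan)
        return dn, ds

    def pair_dn(self, columns=None):
        """(dn, ds) arrays over pairs for a column subset."""
        return self._distances(*self.pair_stats(columns))

    def sum_dn(self, columns=None) -> tuple:
        """(ΣdN over defined pairs, n defined, n undefined)."""
        dn, _ = self.pair_dn(columns)
        defined = np.isfinite(dn)
        return float(dn[defined].sum()), int(defined.sum()), int((~defined).sum())

    def subset_sums(self, draws: np.ndarray) -> np.ndarray:
        """ΣdN for many column subsets at once; ``draws`` is (B, m)."""
        draws = np.asarray(draws, dtype=int)
        usable = self.usable[:, draws].sum(axis=2).astype(float)  # (P, B)
        S = self.s_sites[:, draws].sum(axis=2)
        C = self.counts[:, draws, :].sum(axis=2)
        N = 3.0 * usable - S
        dn, _ = self._distances(usable, S, N, C)
        return np.nansum(dn, axis=0)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _pair_alignment(s1, s2, code_table):
    codons1 = [str(c) for c in s1]
    codons2 = [str(c) for c in s2]
    if len(codons1) != len(codons2):
        raise ValueError("sequences differ in codon length")
    return CodonAlignment(
        taxa=["seq1", "seq2"],
        codons=np.array([codons1, codons2], dtype="<U3"),
        code_table=get_code(code_table).table_id,
    )


def pairwise_dn(s1, s2, code_table=2, method: str = "yn00") -> PairwiseDN:
    """dN/dS between two equal-length codon sequences.

    ``s1``/``s2`` are sequences of codon strings (or nucleotide strings whose
    length is divisible by 3).  Codons with gaps or ambiguity in either
    sequence are skipped pairwise.
    """
    if isinstance(s1, str):
        s1 = [s1[i : i + 3] for i in range(0, len(s1), 3)]
    if isinstance(s2, str):
        s2 = [s2[i : i + 3] for i in range(0, len(s2), 3)]
    aln = _pair_alignment(s1, s2, code_table)
    cache = PairStatsCache(aln, method=method, code_table=code_table)
    usable, S, N, C = cache.pair_stats()
    dn, ds = cache._distances(usable, S, N, C)
    if usable[0] == 0:
        raise ValueError("no usable codons shared by the two sequences")
    return PairwiseDN(
        dn=float(dn[0]),
        ds=float(ds[0]),
        n_sites=float(N[0]),
        s_sites=float(S[0]),
        nd=float(C[0, 2] + C[0, 3]),
        sd=float(C[0, 0] + C[0, 1]),
        kappa_hat=float(cache.kappa[0]),
        usable_codons=int(usable[0]),
        method=method,
    )


def sum_dn(
    sub: CodonAlignment,
    code_table=None,
    method: str = "yn00",
    bootstrap_reps: int = 200,
    seed: int = 0,
    cache: PairStatsCache | None = None,
) -> DivergenceSummary:
    """ΣdN over all unordered taxon pairs of an alignment (or sub-alignment).

    Pairs with undefined dN (saturation, no usable codons) are excluded and
    counted.  The standard error is a codon-column bootstrap
    (``bootstrap_reps`` resamples of the columns with replacement).
    """
    if sub.n_taxa < 2:
        raise ValueError("ΣdN needs at least two taxa")
    if cache is None:
        cache = PairStatsCache(sub, method=method, code_table=code_table)
    total, n_def, n_undef = cache.sum_dn()
    se = None
    if bootstrap_reps and sub.n_columns > 1:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, sub.n_columns, size=(bootstrap_reps, sub.n_columns))
        sums = cache.subset_sums(draws)
        se = float(np.std(sums, ddof=1))
    return DivergenceSummary(
        sum_dn=total,
        n_pairs=n_def,
        n_undefined_pairs=n_undef,
        se_sum_dn=se,
        method=cache.method,
    )


def interaction_ratio(a: DivergenceSummary, b: DivergenceSummary) -> float:
    """ΣdN(a) / ΣdN(b); > 1 means the numerator class evolves faster.

    Returns NaN (with no exception) when the denominator ΣdN is zero, so the
    caller can flag the comparison as undefined.
    """
    if b.sum_dn == 0:
        return float("nan")
    return a.sum_dn / b.sum_dn
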