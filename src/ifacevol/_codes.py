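"""Genetic-code tables and codon bookkeeping shared across the package.

Codons are indexed lexicographically over (A, C, G, T), i.e. AAA=0 ... TTT=63.
The *sense* state space of a code excludes its stop codons: 61 states for the
universal code (NCBI table 1) and 60 for the vertebrate mitochondrial code
(table 2, stops TAA/TAG/AGA/AGG), which is the default for mtDNA-encoded genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

#: purine<->purine or pyrimidine<->pyrimidine single-nucleotide changes
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CODE_ALIASES = {
    "universal": 1,
    "standard": 1,
    "vertebrate-mito": 2,
    "vertebrate_mitochondrial": 2,
    "mito": 2,
}


def is_transition(n1: str, n2: str) -> bool:
    return (n1, n2) in _TRANSITIONS


def codon_str(index: int) -> str:
    return NUCS[index >> 4] + NUCS[(index >> 2) & 3] + NUCS[index & 3]


def codon_index(codon: str) -> int:
    """Index of a clean ACGT codon, or -1 for gaps/ambiguity."""
    try:
        return (
            (NUC_INDEX[codon[0]] << 4)
            | (NUC_INDEX[codon[1]] << 2)
            | NUC_INDEX[codon[2]]
        )
    except (KeyError, IndexError):
        return -1


ALL_CODONS = [codon_str(i) for i in range(64)]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code and its derived sense-codon state space."""

    table_id: int
    name: str
    aa: tuple  # length 64; '*' for stops
    stop_codons: frozenset
    sense_codons: tuple  # codon strings, lexicographic
    sense_index: dict = field(compare=False)  # codon string -> state 0..S-1

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        return self.aa[codon_index(codon)]


def resolve_table_id(code) -> int:
    if isinstance(code, GeneticCode):
        return code.table_id
    if isinstance(code, int):
        return code
    key = str(code).lower().replace(" ", "_")
    if key in CODE_ALIASES:
        return CODE_ALIASES[key]
    raise ValueError(f"unknown genetic code: {code!r}")


@lru_cache(maxsize=None)
def get_code(code="vertebrate-mito") -> GeneticCode:
    table_id = resolve_table_id(code)
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = []
    for codon in ALL_CODONS:
        aa.append("*" if codon in table.stop_codons else table.forward_table[codon])
    sense = tuple(c for c in ALL_CODONS if c not in table.stop_codons)
    return GeneticCode(
        table_id=table_id,
        name=table.names[0],
        aa=tuple(aa),
        stop_codons=frozenset(table.stop_codons),
        sense_codons=sense,
        sense_index={c: i for i, c in enumerate(sense)},
    )


# ---------------------------------------------------------------------------
# Single-nucleotide codon neighbourhoods (used by both NG86 and the GY94
# rate matrix): for every ordered sense-codon pair differing at one position.
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def single_change_pairs(table_id: int):
    """Ordered sense pairs (i, j) one nucleotide apart.

    Returns arrays (i, j, transition_flag, nonsyn_flag) over sense-state
    indices of the given code.
    """
    code = get_code(table_id)
    ii, jj, ts, ns = [], [], [], []
    for si, c1 in enumerate(code.sense_codons):
        for pos in range(3):
            for n in NUCS:
                if n == c1[pos]:
                    continue
                c2 = c1[:pos] + n + c1[pos + 1 :]
                sj = code.sense_index.get(c2)
                if sj is None:
                    continue
                ii.append(si)
                jj.append(sj)
                ts.append(is_transition(c1[pos], n))
                ns.append(code.aa[codon_index(c1)] != code.aa[codon_index(c2)])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


# ---------------------------------------------------------------------------
# NG86 per-codon site fractions and per-pair difference counts.
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def ng86_syn_sites(table_id: int) -> np.ndarray:
    """Synonymous site count s(c) per codon (64-vector, NaN for stops).

    Per position the synonymous fraction is (# synonymous changes) /
    (# changes not creating a stop); mutations to stop codons are excluded
    from both numerator and denominator so s + n = 3 for every sense codon.
    """
    code = get_code(table_id)
    out = np.full(64, np.nan)
    for idx, codon in enumerate(ALL_CODONS):
        if code.is_stop(codon):
            continue
        s = 0.0
        for pos in range(3):
            syn = 0
            valid = 0
            for n in NUCS:
                if n == codon[pos]:
                    continue
                alt = codon[:pos] + n + codon[pos + 1 :]
                if code.is_stop(alt):
                    continue
                valid += 1
                if code.aa[codon_index(alt)] == code.aa[idx]:
                    syn += 1
            if valid:
                s += syn / valid
        out[idx] = s
    return out


def pathway_counts_detailed(c1: str, c2: str, code: GeneticCode, kappa: float = 1.0):
    """Average substitution counts over minimal mutational pathways.

    Returns ``(sd_ts, sd_tv, nd_ts, nd_tv)``: synonymous/nonsynonymous
    substitutions split into transitions and transversions, averaged over
    the orderings of the differing positions.  Pathways passing through a
    stop codon are excluded; if every pathway is blocked, all are used.
    With ``kappa != 1`` pathways are weighted by the product of
    ``kappa**(number of transitions)`` over their steps (YN00-style).
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0
    results = []  # (weight, counts[4], blocked)
    for order in permutations(diff_pos):
        cur = c1
        counts = [0, 0, 0, 0]
        weight = 1.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
            ts = is_transition(cur[pos], c2[pos])
            if ts:
                weight *= kappa
            syn = code.aa[codon_index(cur)] == code.aa[codon_index(nxt)] and not (
                code.is_stop(cur) or code.is_stop(nxt)
            )
            counts[(0 if syn else 2) + (0 if ts else 1)] += 1
            cur = nxt
        results.append((weight, counts, blocked))
    usable = [r for r in results if not r[2]] or results
    wsum = sum(r[0] for r in usable)
    return tuple(
        sum(r[0] * r[1][k] for r in usable) / wsum for k in range(4)
    )


def _pathway_counts(c1: str, c2: str, code: GeneticCode, kappa: float = 1.0):
    """Pathway-averaged (synonymous, nonsynonymous) substitution counts."""
    sd_ts, sd_tv, nd_ts, nd_tv = pathway_counts_detailed(c1, c2, code, kappa)
    return sd_ts + sd_tv, nd_ts + nd_tv


@lru_cache(maxsize=None)
def ng86_diff_tables(table_id: int):
    """64x64 tables of pathway-averaged (Sd, Nd) between sense codons.

    Entries involving a stop codon are NaN.
    """
    code = get_code(table_id)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i, c1 in enumerate(ALL_CODONS):
        if code.is_stop(c1):
            continue
        for j, c2 in enumerate(ALL_CODONS):
            if code.is_stop(c2):
                continue
            if j < i:
                sd[i, j], nd[i, j] = sd[j, i], nd[j, i]
                continue
            sd[i, j], nd[i, j] = _pathway_counts(c1, c2, code)
    return sd, nd
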