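"""Synthetic inputs with planted ground truth.

Everything the analysis consumes can be generated here with known answers:

* toy multi-chain complexes whose residues have designed contact, interface
  and burial geometry (so the structural classifier can be checked exactly);
* random unrooted binary trees with exponential branch lengths;
* codon alignments simulated under the GY94 process with partition-specific
  ω (exact matrix-exponential sampling along the tree, per-column
  independence, no stop codons ever emitted);
* per-residue ΔΔG tables with class-dependent normal distributions.

Geometric realism of the toy complexes is irrelevant to the classifier
contracts: chains are straight backbones of glycine-like single-heavy-atom
residues, with designed inter-chain approaches at 3.5 Å (contact), 5.5 Å
(interface burial without contact) and solvent-excluding same-chain atom
cages around planted buried residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import get_code
from .codonml import CodonModelSpec, _eig_reversible, gy94_rate_matrix
from .structclass import ComplexStructure, Residue3D, SiteClass
from .trees import PhyloTree

__all__ = [
    "SyntheticTruth",
    "make_toy_complex",
    "simulate_tree",
    "simulate_codon_alignment",
    "simulate_ddg_table",
]

# layout constants (Å): chosen so designed relations are the only ones
_X_STEP = 6.0  # along-chain residue spacing
_Y_STEP = 14.0  # inter-chain spacing; > 2*(vdW+probe) + margin
_CONTACT_D = 3.5  # planted inter-chain contact distance (< 4 Å cutoff)
_IFACE_D = 5.5  # occludes ASA (< 6.2 Å) without contact (> 4 Å)
_CAGE_R = 3.9
_CAGE_N = 48


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic data set."""

    seed: int
    site_classes: dict = field(default_factory=dict)  # residue key -> SiteClass
    interface: dict = field(default_factory=dict)  # residue key -> bool | None
    omega_by_partition: dict = field(default_factory=dict)
    partition_columns: dict = field(default_factory=dict)
    kappa: float | None = None
    pi: np.ndarray | None = None
    tree_newick: str | None = None
    extras: dict = field(default_factory=dict)


def _golden_spiral(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def make_toy_complex(
    n_chains: int = 4,
    residues_per_chain: int = 60,
    contact_fraction: float = 0.10,
    buried_fraction: float = 0.05,
    seed: int = 0,
    n_mt_chains: int = 2,
    interface_fraction: float = 0.05,
):
    """Toy complex with planted residue classes.

    The first ``n_mt_chains`` chains are mtDNA-encoded (these get classified
    and carry the planted truth); the rest are nuclear-encoded partners.
    Returns ``(ComplexStructure, SyntheticTruth)``.
    """
    if not 0 <= contact_fraction <= 1 or not 0 <= buried_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if contact_fraction + buried_fraction + interface_fraction > 1:
        raise ValueError("planted fractions exceed the chain length")
    if not 1 <= n_mt_chains < n_chains:
        raise ValueError("need at least one mt and one nuclear chain")
    rng = np.random.default_rng(seed)
    R = residues_per_chain
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    mt_ids = chain_ids[:n_mt_chains]
    nu_ids = chain_ids[n_mt_chains:]
    encoding = {c: ("mt" if c in mt_ids else "nuclear") for c in chain_ids}
    y_of = {c: _Y_STEP * i for i, c in enumerate(chain_ids)}

    n_contact = round(contact_fraction * R)
    n_buried = round(buried_fraction * R)
    n_iface = round(interface_fraction * R)
    n_mm = n_contact // 2 if len(mt_ids) >= 2 else 0
    n_nu = n_contact - n_mm

    # events consume globally unique residue-index slots, 2 apart, so no two
    # special placements can interact (12 Å between event columns clears the
    # 6.2 Å ASA-occlusion radius and the ~4.2 Å cage extent)
    slots = list(range(1, R - 1, 2))
    rng.shuffle(slots)
    mm_events = -(-n_mm * len(mt_ids) // 2)  # each event serves two chains
    needed = mm_events + len(mt_ids) * (n_nu + n_iface + n_buried)
    if needed > len(slots):
        raise ValueError(
            f"infeasible geometry: {needed} planted events need "
            f"residues_per_chain >= {2 * needed + 2}"
        )

    # start from default backbone positions; events override
    coords = {c: {r: np.array([[_X_STEP * r, y_of[c], 0.0]]) for r in range(R)} for c in chain_ids}
    classes: dict = {}
    interface: dict = {}
    for c in mt_ids:
        for r in range(R):
            classes[(c, r + 1, "")] = SiteClass.EXPOSED_NONCONTACT
            interface[(c, r + 1, "")] = False

    def take_slot() -> int:
        return slots.pop()

    # mt-mt contact events (round-robin over adjacent mt pairs)
    mm_count = {c: 0 for c in mt_ids}
    if n_mm:
        i = 0
        while min(mm_count.values()) < n_mm:
            a = mt_ids[i % len(mt_ids)]
            b = mt_ids[(i + 1) % len(mt_ids)]
            i += 1
            if mm_count[a] >= n_mm and mm_count[b] >= n_mm:
                continue
            q = take_slot()
            coords[b][q] = coords[a][q] + np.array([[0.0, _CONTACT_D, 0.0]])
            for c in (a, b):
                classes[(c, q + 1, "")] = SiteClass.MT_MT_CONTACT
                interface[(c, q + 1, "")] = None
                mm_count[c] += 1

    for k, c in enumerate(mt_ids):
        # mt-nu contacts
        for j in range(n_nu):
            partner = nu_ids[(k + j) % len(nu_ids)]
            q = take_slot()
            coords[partner][q] = coords[c][q] + np.array([[0.0, _CONTACT_D, 0.0]])
            classes[(c, q + 1, "")] = SiteClass.MT_NU_CONTACT
            interface[(c, q + 1, "")] = None
        # exposed interface residues: foreign atom near enough to shave ASA,
        # too far for a contact
        for j in range(n_iface):
            partner = nu_ids[(k + j) % len(nu_ids)]
            q = take_slot()
            coords[partner][q] = coords[c][q] + np.array([[0.0, _IFACE_D, 0.0]])
            interface[(c, q + 1, "")] = True
        # buried residues: cage of same-chain atoms hosted by the flanking
        # residues blocks the solvent probe entirely
        cage = _golden_spiral(_CAGE_N) * _CAGE_R
        for _ in range(n_buried):
            q = take_slot()
            center = coords[c][q][0]
            half = _CAGE_N // 2
            coords[c][q - 1] = np.vstack([coords[c][q - 1], center + cage[:half]])
            coords[c][q + 1] = np.vstack([coords[c][q + 1], center + cage[half:]])
            classes[(c, q + 1, "")] = SiteClass.BURIED_NONCONTACT
            interface[(c, q + 1, "")] = None

    chains = {
        c: [
            Residue3D(
                chain_id=c,
                seq_number=r + 1,
                res_name="GLY",
                coords=coords[c][r],
                elements=("C",) * coords[c][r].shape[0],
            )
            for r in range(R)
        ]
        for c in chain_ids
    }
    heme_xyz = np.array([[0.0, -30.0, 0.0], [6.0, -30.0, 3.0], [12.0, -30.0, 0.0]])
    cx = ComplexStructure(
        chains=chains,
        hetero_groups={"HEM/Z/901": heme_xyz},
        encoding=encoding,
    )
    truth = SyntheticTruth(
        seed=seed,
        site_classes=classes,
        interface=interface,
        extras={"heme_xyz": heme_xyz, "mt_chains": mt_ids},
    )
    return cx, truth


def simulate_tree(n_tips: int, mean_branch_length: float = 0.1, seed: int = 0, prefix: str = "t") -> PhyloTree:
    """Random unrooted binary tree; lengths i.i.d. exponential(mean).

    Topology is grown by splitting a uniformly chosen branch for each added
    tip.  Branch count is 2n − 3.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 2
    parent = np.full(n_nodes, -1, dtype=int)
    root = n_tips
    parent[0] = parent[1] = parent[2] = root
    edges = [0, 1, 2]
    next_internal = n_tips + 1
    for tip in range(3, n_tips):
        e = edges[int(rng.integers(len(edges)))]
        new = next_internal
        next_internal += 1
        parent[new] = parent[e]
        parent[e] = new
        parent[tip] = new
        edges.extend([tip, new])
    lengths = np.zeros(n_nodes)
    branch_ids = [i for i in range(n_nodes) if i != root]
    lengths[branch_ids] = rng.exponential(mean_branch_length, size=len(branch_ids))
    taxa = [f"{prefix}{i + 1}" for i in range(n_tips)]
    return PhyloTree(taxa=taxa, parent=parent, edge_length=lengths)


def simulate_codon_alignment(
    tree: PhyloTree,
    omega_by_partition: dict,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    code_table=2,
    columns_per_partition: dict | None = None,
    seed: int = 0,
):
    """Simulate codons along a tree with partition-specific ω.

    Root codons are drawn from π; each branch applies exp(Qt) of its
    partition's GY94 process.  Columns of the partitions are laid out
    consecutively in the order of ``omega_by_partition``.  Returns
    ``(CodonAlignment, SyntheticTruth)`` with planted partition columns.
    """
    from .codonsort import CodonAlignment  # local to avoid cycles at import

    code = get_code(code_table)
    if pi is None:
        pi = np.full(code.n_states, 1.0 / code.n_states)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    if columns_per_partition is None:
        columns_per_partition = {k: 100 for k in omega_by_partition}
    rng = np.random.default_rng(seed)
    spec = CodonModelSpec(code_table=code.table_id, pi=pi, kappa=kappa)
    n_nodes = tree.n_nodes
    T = tree.n_tips

    cols_out = []
    partition_columns = {}
    offset = 0
    for name, omega in omega_by_partition.items():
        L = int(columns_per_partition[name])
        partition_columns[name] = list(range(offset, offset + L))
        offset += L
        if L == 0:
            continue
        Q = gy94_rate_matrix(spec, omega)
        w, V, Vinv = _eig_reversible(Q, np.maximum(pi, 1e-10) / np.maximum(pi, 1e-10).sum())
        states = np.empty((n_nodes, L), dtype=np.int64)
        states[tree.root] = rng.choice(code.n_states, size=L, p=pi)
        for node in tree.preorder():
            if node == tree.root:
                continue
            t = max(float(tree.edge_length[node]), 0.0)
            if t == 0.0:
                states[node] = states[tree.parent[node]]
                continue
            P = np.clip((V * np.exp(w * t)[None, :]) @ Vinv, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            cdf = np.cumsum(P, axis=1)
            u = rng.random(L)
            states[node] = np.minimum(
                (cdf[states[tree.parent[node]]] < u[:, None]).sum(axis=1),
                code.n_states - 1,
            )
        cols_out.append(states[:T])

    all_states = np.concatenate(cols_out, axis=1) if cols_out else np.empty((T, 0), int)
    sense = np.array(code.sense_codons, dtype="<U3")
    codons = sense[all_states]
    aln = CodonAlignment(taxa=list(tree.taxa), codons=codons, code_table=code.table_id)
    truth = SyntheticTruth(
        seed=seed,
        omega_by_partition=dict(omega_by_partition),
        partition_columns=partition_columns,
        kappa=kappa,
        pi=pi,
        tree_newick=tree.to_newick(),
    )
    return aln, truth


def simulate_ddg_table(labels, class_stats: dict, seed: int = 0) -> pd.DataFrame:
    """ΔΔG ~ Normal(class mean, class sd) per labelled residue (kJ/mol).

    ``class_stats`` maps each site class present in ``labels`` (class name or
    :class:`SiteClass`) to ``(mean, sd)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lab in labels:
        cls = getattr(lab.site_class, "value", lab.site_class)
        stats_key = cls if cls in class_stats else lab.site_class
        if stats_key not in class_stats:
            raise ValueError(f"no ΔΔG distribution for class {cls}")
        mean, sd = class_stats[stats_key]
        rows.append(
            {
                "chain": lab.chain_id,
                "resnum": lab.seq_number,
                "ddg_kj_mol": float(rng.normal(mean, sd)) if sd > 0 else float(mean),
            }
        )
    return pd.DataFrame(rows)
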