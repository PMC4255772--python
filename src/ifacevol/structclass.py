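"""Residue-level structural classification of a multi-subunit complex.

Every residue of a designated (typically mtDNA-encoded) chain is assigned to
exactly one of four classes, following the contact/exposure decision tree:

* ``MT_NU_CONTACT``   — within the contact cutoff (default 4 Å, minimal
  heavy-atom distance) of a chain encoded by the *other* genome;
* ``MT_MT_CONTACT``   — in contact, but only with chains from the same genome;
* ``BURIED_NONCONTACT`` — no inter-chain contact and relative solvent
  accessibility in the complex below the exposure threshold;
* ``EXPOSED_NONCONTACT`` — everything else.  Exposed noncontact residues are
  additionally flagged as *interface* when their accessible surface area
  shrinks upon complex formation (ΔASA = ASA_isolated − ASA_complex > 0).

Solvent accessible surface areas are computed with the Shrake–Rupley
algorithm.  Hetero groups (hemes, lipids, metals) never create contacts; heme
groups are used only for per-residue heme proximity profiles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from Bio.PDB import PDBParser

__all__ = [
    "SiteClass",
    "Residue3D",
    "ComplexStructure",
    "SiteStructuralLabel",
    "parse_structure",
    "write_pdb",
    "residue_min_distance",
    "build_contact_labels",
    "compute_residue_asa",
    "classify_sites",
    "heme_min_distances",
    "labels_to_dataframe",
    "read_labels_tsv",
]


class SiteClass(str, enum.Enum):
    MT_NU_CONTACT = "MT_NU_CONTACT"
    MT_MT_CONTACT = "MT_MT_CONTACT"
    EXPOSED_NONCONTACT = "EXPOSED_NONCONTACT"
    BURIED_NONCONTACT = "BURIED_NONCONTACT"


#: van der Waals radii (Å) for heavy elements; the fallback covers rare cases.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_RADIUS = 1.80

#: theoretical maximum ASA per residue (Å², Tien et al. 2013), used as the
#: denominator of relative solvent accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ASA = 200.0

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Residue3D:
    """One residue: heavy-atom coordinates plus identity within the file."""

    chain_id: str
    seq_number: int
    res_name: str
    coords: np.ndarray  # (n_atoms, 3) float64, heavy atoms only
    elements: tuple = ()  # element symbol per atom, for vdW radii
    icode: str = ""

    @property
    def key(self):
        return (self.chain_id, self.seq_number, self.icode)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValueError(f"residue {self.key} has no heavy atoms")
        if not self.elements:
            self.elements = ("C",) * self.coords.shape[0]

    def radii(self) -> np.ndarray:
        return np.array(
            [VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in self.elements]
        )


@dataclass
class ComplexStructure:
    """Chains of residues plus hetero groups and a chain→genome map."""

    chains: dict  # chain_id -> list[Residue3D], insertion order preserved
    hetero_groups: dict = field(default_factory=dict)  # id -> (n, 3) coords
    encoding: dict = field(default_factory=dict)  # chain_id -> "mt"|"nuclear"

    def __post_init__(self):
        for cid in self.encoding:
            if cid not in self.chains:
                raise ValueError(f"encoding names chain {cid!r} not in structure")

    def residues(self):
        for reslist in self.chains.values():
            yield from reslist

    def residue_index(self) -> dict:
        return {r.key: r for r in self.residues()}

    def mt_chains(self):
        return [c for c, g in self.encoding.items() if g == "mt"]

    def heme_groups(self, resnames=("HEM", "HEA", "HEC", "HAS")) -> dict:
        return {
            gid: xyz
            for gid, xyz in self.hetero_groups.items()
            if gid.split("/")[0] in resnames
        }


@dataclass
class SiteStructuralLabel:
    chain_id: str
    seq_number: int
    icode: str
    res_name: str
    partners: frozenset
    site_class: SiteClass
    interface: bool | None  # defined only for EXPOSED_NONCONTACT
    asa_isolated: float
    asa_complex: float
    delta_asa: float
    heme_min_dist: float | None = None

    @property
    def key(self):
        return (self.chain_id, self.seq_number, self.icode)


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------


def _pick_altloc(residue):
    """Atoms of a Bio.PDB residue with altlocs resolved to max occupancy."""
    atoms = []
    for atom in residue:
        if atom.is_disordered():
            children = sorted(
                atom.disordered_get_list(),
                key=lambda a: -(a.get_occupancy() or 0.0),
            )
            atoms.append(children[0])
        else:
            atoms.append(atom)
    return atoms


def parse_structure(path, encoding, chain_filter=None) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Hydrogens and waters are dropped, alternate locations resolved to the
    highest-occupancy conformer, and HETATM residues routed to
    ``hetero_groups`` (keyed ``resname/chain/number``).  Only the first model
    is used.

    Parameters
    ----------
    encoding : dict
        chain id → ``"mt"`` or ``"nuclear"`` for every chain to keep.
    chain_filter : iterable, optional
        Restrict parsing to these chains; defaults to the encoding's keys.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("cx", str(path)).get_models())
    keep = set(chain_filter) if chain_filter is not None else set(encoding)
    present = {c.id for c in model}
    missing = keep - present
    if missing:
        raise ValueError(f"chains {sorted(missing)} absent from {path}")
    for cid in keep:
        if cid not in encoding:
            raise ValueError(f"chain {cid!r} has no genome-of-origin encoding")

    chains: dict = {}
    hetero: dict = {}
    for chain in model:
        reslist = []
        for res in chain:
            hetflag, seqnum, icode = res.id
            atoms = [
                a
                for a in _pick_altloc(res)
                if (a.element or "").upper() not in ("H", "D")
            ]
            if not atoms:
                continue
            coords = np.array([a.get_coord() for a in atoms], dtype=float)
            if hetflag.strip():  # HETATM: kept regardless of the chain filter
                if res.get_resname().strip() in _WATER_NAMES:
                    continue
                gid = f"{res.get_resname().strip()}/{chain.id}/{seqnum}"
                hetero[gid] = coords
            elif chain.id not in keep:
                continue
            else:
                reslist.append(
                    Residue3D(
                        chain_id=chain.id,
                        seq_number=seqnum,
                        res_name=res.get_resname().strip(),
                        coords=coords,
                        elements=tuple((a.element or "C").upper() for a in atoms),
                        icode=icode.strip(),
                    )
                )
        if reslist:
            chains[chain.id] = reslist
    empty = keep - set(chains)
    if empty:
        raise ValueError(f"chains {sorted(empty)} contain no polymer residues")
    return ComplexStructure(
        chains=chains,
        hetero_groups=hetero,
        encoding={c: encoding[c] for c in chains},
    )


def write_pdb(cx: ComplexStructure, path) -> None:
    """Emit a minimal, deterministic PDB file (ATOM/HETATM/TER/END)."""
    lines = []
    serial = 1
    for cid, reslist in cx.chains.items():
        for res in reslist:
            for i, (xyz, elem) in enumerate(zip(res.coords, res.elements)):
                name = f"{elem[:1].upper()}{i + 1}"  # unique within the residue
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {res.res_name:>3s} "
                    f"{cid}{res.seq_number:4d}{res.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem[:2].upper():>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for gid, xyz_arr in cx.hetero_groups.items():
        resname, cid, num = gid.split("/")
        for i, xyz in enumerate(xyz_arr):
            lines.append(
                f"HETATM{serial:5d} FE{i + 1:<2d} {resname:>3s} {cid}{int(num):4d} "
                f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          FE"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def residue_min_distance(r1: Residue3D, r2: Residue3D) -> float:
    """Minimal Euclidean distance over all heavy-atom pairs (Å)."""
    return float(cdist(r1.coords, r2.coords).min())


def build_contact_labels(cx: ComplexStructure, cutoff: float = 4.0) -> dict:
    """Map every residue to the set of *other* chains within ``cutoff`` Å.

    A residue of chain X has partner chain Y != X iff some heavy atom of a
    residue of Y lies closer than ``cutoff`` to one of its heavy atoms.
    Hetero groups never count as partners.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keys, chain_of, res_of = [], [], []
    coords = []
    for r in cx.residues():
        keys.append(r.key)
        coords.append(r.coords)
        chain_of.append(r.chain_id)
        res_of.append(len(keys) - 1)
    atom_xyz = np.vstack(coords)
    atom_res = np.repeat(
        np.arange(len(keys)), [c.shape[0] for c in coords]
    )
    tree = cKDTree(atom_xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    partners: dict = {k: set() for k in keys}
    if pairs.size:
        ra, rb = atom_res[pairs[:, 0]], atom_res[pairs[:, 1]]
        for i, j in zip(ra, rb):
            ci, cj = chain_of[i], chain_of[j]
            if ci != cj:
                partners[keys[i]].add(cj)
                partners[keys[j]].add(ci)
    return partners


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def compute_residue_asa(unit, probe_radius: float = 1.4, sphere_points: int = 960):
    """Shrake–Rupley per-residue solvent accessible surface area (Å²).

    ``unit`` may be a :class:`ComplexStructure` (ASA in the complex) or an
    iterable of :class:`Residue3D` (e.g. one chain in isolation); only the
    atoms of ``unit`` occlude.  Returns residue key → ASA.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    residues = list(unit.residues()) if isinstance(unit, ComplexStructure) else list(unit)
    if not residues:
        raise ValueError("empty unit")
    xyz = np.vstack([r.coords for r in residues])
    radii = np.concatenate([r.radii() for r in residues])
    res_idx = np.repeat(np.arange(len(residues)), [r.coords.shape[0] for r in residues])
    points = _sphere_points(sphere_points)
    ext = radii + probe_radius
    tree = cKDTree(xyz)
    asa_atom = np.zeros(len(xyz))
    max_ext = ext.max()
    for a in range(len(xyz)):
        test = xyz[a] + ext[a] * points
        neigh = [b for b in tree.query_ball_point(xyz[a], ext[a] + max_ext) if b != a]
        accessible = np.ones(sphere_points, dtype=bool)
        for b in neigh:
            d2 = np.einsum("ij,ij->i", test - xyz[b], test - xyz[b])
            accessible &= d2 >= ext[b] ** 2
            if not accessible.any():
                break
        asa_atom[a] = 4.0 * math.pi * ext[a] ** 2 * accessible.mean()
    out = {}
    for i, r in enumerate(residues):
        out[r.key] = float(asa_atom[res_idx == i].sum())
    return out


def heme_min_distances(cx: ComplexStructure, chain_id: str, heme_resnames=("HEM", "HEA", "HEC", "HAS")) -> dict:
    """Per residue of ``chain_id``: distance (Å) to the closest heme group."""
    hemes = cx.heme_groups(heme_resnames)
    if not hemes:
        raise ValueError("structure has no heme hetero groups")
    heme_xyz = np.vstack(list(hemes.values()))
    out = {}
    for res in cx.chains[chain_id]:
        out[res.key] = float(cdist(res.coords, heme_xyz).min())
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_sites(
    cx: ComplexStructure,
    asa_isolated: dict,
    asa_complex: dict,
    partners: dict,
    exposure_threshold: float = 0.05,
    classify_chains=None,
    heme_dists: dict | None = None,
):
    """Assign each residue of the classified chains to one of the four classes.

    Contact residues split by partner genome: any nuclear-encoded partner
    takes precedence (``MT_NU_CONTACT``); otherwise ``MT_MT_CONTACT``.
    Noncontact residues are ``BURIED_NONCONTACT`` when relative accessibility
    in the complex (ASA₂ / residue-specific maximum ASA) falls below
    ``exposure_threshold``, else ``EXPOSED_NONCONTACT`` with
    ``interface = (ΔASA > 0)``.
    """
    if classify_chains is None:
        classify_chains = cx.mt_chains()
    labels = []
    for cid in classify_chains:
        for res in cx.chains[cid]:
            key = res.key
            if key not in asa_isolated or key not in asa_complex:
                raise ValueError(f"residue {key} missing an ASA value")
            a1, a2 = asa_isolated[key], asa_complex[key]
            delta = a1 - a2
            if delta < -1e-6:
                raise ValueError(
                    f"residue {key}: ASA in complex exceeds isolated ASA "
                    f"(ΔASA = {delta:.3g} Å²)"
                )
            delta = max(delta, 0.0)
            pset = frozenset(partners.get(key, ()))
            interface: bool | None = None
            if pset:
                genomes = {cx.encoding[p] for p in pset}
                cls = (
                    SiteClass.MT_NU_CONTACT
                    if "nuclear" in genomes
                    else SiteClass.MT_MT_CONTACT
                )
            else:
                rel = a2 / MAX_ASA.get(res.res_name, DEFAULT_MAX_ASA)
                if rel < exposure_threshold:
                    cls = SiteClass.BURIED_NONCONTACT
                else:
                    cls = SiteClass.EXPOSED_NONCONTACT
                    interface = delta > 1e-6
            labels.append(
                SiteStructuralLabel(
                    chain_id=cid,
                    seq_number=res.seq_number,
                    icode=res.icode,
                    res_name=res.res_name,
                    partners=pset,
                    site_class=cls,
                    interface=interface,
                    asa_isolated=a1,
                    asa_complex=a2,
                    delta_asa=delta,
                    heme_min_dist=None
                    if heme_dists is None
                    else heme_dists.get(key),
                )
            )
    return labels


def classify_complex(
    cx: ComplexStructure,
    cutoff: float = 4.0,
    exposure_threshold: float = 0.05,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    classify_chains=None,
    with_heme: bool = False,
):
    """Convenience wrapper: contacts + two-way ASA + classification."""
    if classify_chains is None:
        classify_chains = cx.mt_chains()
    partners = build_contact_labels(cx, cutoff=cutoff)
    asa2 = compute_residue_asa(cx, probe_radius, sphere_points)
    asa1 = {}
    for cid in classify_chains:
        asa1.update(compute_residue_asa(cx.chains[cid], probe_radius, sphere_points))
    heme = None
    if with_heme:
        heme = {}
        for cid in classify_chains:
            heme.update(heme_min_distances(cx, cid))
    return classify_sites(
        cx, asa1, asa2, partners, exposure_threshold, classify_chains, heme
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def labels_to_dataframe(labels) -> pd.DataFrame:
    rows = []
    for lab in labels:
        rows.append(
            {
                "chain": lab.chain_id,
                "resnum": lab.seq_number,
                "icode": lab.icode,
                "resname": lab.res_name,
                "site_class": lab.site_class.value,
                "interface": "" if lab.interface is None else str(lab.interface).lower(),
                "asa_isolated": round(lab.asa_isolated, 3),
                "asa_complex": round(lab.asa_complex, 3),
                "delta_asa": round(lab.delta_asa, 3),
                "heme_min_dist": ""
                if lab.heme_min_dist is None
                else round(lab.heme_min_dist, 3),
                "partners": ",".join(sorted(lab.partners)),
            }
        )
    return pd.DataFrame(rows)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str}, keep_default_na=False)
    df["resnum"] = df["resnum"].astype(int)
    return df
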