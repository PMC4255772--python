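"""Codon alignments and their projection onto structural residue classes.

An alignment column is tied to a residue of the reference structure through
the ungapped codons of a designated reference taxon (the structure's source
species): the k-th ungapped reference codon corresponds to residue
``first_residue_number + k - 1`` of the mapped chain.  Columns where the
reference is gapped cannot be structurally labelled and carry an explicit
``UNMAPPED`` tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._codes import codon_index, get_code

__all__ = [
    "CodonAlignment",
    "ReferenceMap",
    "SitePartition",
    "read_codon_alignment",
    "write_codon_alignment",
    "map_alignment_to_reference",
    "partition_alignment",
    "UNMAPPED",
]

UNMAPPED = "UNMAPPED"

_IUPAC = set("ACGTURYSWKMBDHVN-.")


@dataclass
class CodonAlignment:
    """Aligned codon matrix: ``codons[t, c]`` is the codon of taxon t at column c."""

    taxa: list
    codons: np.ndarray  # (T, L) of 3-character strings
    code_table: int = 2
    stop_positions: list = field(default_factory=list)  # (taxon, column) pairs

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon identifiers")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.codons.shape[1]

    def codon_indices(self) -> np.ndarray:
        """(T, L) array of 0..63 codon indices, -1 for gap/ambiguity."""
        flat = np.array([codon_index(c) for c in self.codons.ravel()])
        return flat.reshape(self.codons.shape).astype(np.int64)

    def sense_states(self) -> np.ndarray:
        """(T, L) sense-state indices under the code; -1 for gap/stop/ambiguous."""
        code = get_code(self.code_table)
        out = np.full(self.codons.shape, -1, dtype=np.int64)
        for t in range(self.n_taxa):
            for c in range(self.n_columns):
                out[t, c] = code.sense_index.get(self.codons[t, c], -1)
        return out

    def subset(self, columns) -> "CodonAlignment":
        cols = np.asarray(columns, dtype=int)
        return CodonAlignment(
            taxa=list(self.taxa),
            codons=self.codons[:, cols],
            code_table=self.code_table,
        )

    def sequence(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]


def _codons_of(seq: str):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def read_codon_alignment(path, code_table=2) -> CodonAlignment:
    """Read an aligned nucleotide FASTA as codons and validate it.

    Codons containing any gap character are normalised to fully gapped
    (``---``); internal stop codons under the code are recorded in
    ``stop_positions`` (the final column is exempt, as alignments may retain
    the termination codon).
    """
    names, seqs = [], []
    with open(path) as fh:
        for name, seq in SimpleFastaParser(fh):
            names.append(name.split()[0])
            seqs.append(seq.upper().replace("U", "T"))
    if not names:
        raise ValueError(f"no sequences in {path}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon identifiers")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"alignment length {length} not divisible by 3")
    bad = sorted({ch for s in seqs for ch in s} - _IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in alignment: {bad}")

    code = get_code(code_table)
    matrix = []
    stops = []
    for t, seq in enumerate(seqs):
        row = []
        for c, codon in enumerate(_codons_of(seq)):
            if "-" in codon or "." in codon:
                codon = "---"
            row.append(codon)
            if code.is_stop(codon) and c < length // 3 - 1:
                stops.append((names[t], c))
        matrix.append(row)
    return CodonAlignment(
        taxa=names,
        codons=np.array(matrix, dtype="<U3"),
        code_table=code.table_id,
        stop_positions=stops,
    )


def write_codon_alignment(aln: CodonAlignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for t, name in enumerate(aln.taxa):
            fh.write(f">{name}\n")
            seq = "".join(aln.codons[t])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class ReferenceMap:
    """Injective map alignment column → (chain_id, residue number)."""

    ref_taxon: str
    chain_id: str
    mapping: dict  # 0-based column -> (chain_id, seq_number)

    @property
    def n_mapped(self) -> int:
        return len(self.mapping)

    def mapped_columns(self):
        return sorted(self.mapping)


def map_alignment_to_reference(
    aln: CodonAlignment,
    ref_taxon: str,
    chain_id: str,
    first_residue_number: int = 1,
    chain_length: int | None = None,
) -> ReferenceMap:
    """Tie ungapped reference codons to consecutive structure residue numbers."""
    if ref_taxon not in aln.taxa:
        raise ValueError(f"reference taxon {ref_taxon!r} not in alignment")
    ref = aln.sequence(ref_taxon)
    mapping = {}
    k = 0
    for col in range(aln.n_columns):
        if ref[col] != "---":
            mapping[col] = (chain_id, first_residue_number + k)
            k += 1
    if chain_length is not None and k > chain_length:
        warnings.warn(
            f"{k - chain_length} mapped codons extend beyond chain "
            f"{chain_id} (length {chain_length})",
            stacklevel=2,
        )
    return ReferenceMap(ref_taxon=ref_taxon, chain_id=chain_id, mapping=mapping)


@dataclass
class SitePartition:
    """Structural class per alignment column, plus per-class column lists."""

    column_class: dict  # 0-based column -> class name (or UNMAPPED)
    column_interface: dict  # column -> bool (EXPOSED_NONCONTACT only)

    def class_columns(self, include_unmapped: bool = False) -> dict:
        out: dict = {}
        for col in sorted(self.column_class):
            cls = self.column_class[col]
            if cls == UNMAPPED and not include_unmapped:
                continue
            out.setdefault(cls, []).append(col)
        return out

    def interface_split(self, exposed_class: str = "EXPOSED_NONCONTACT"):
        """Columns of the exposed-noncontact class split by the interface flag."""
        iface, noniface = [], []
        for col, cls in sorted(self.column_class.items()):
            if cls != exposed_class:
                continue
            (iface if self.column_interface.get(col) else noniface).append(col)
        return {"INTERFACE": iface, "NONINTERFACE": noniface}


def partition_alignment(aln: CodonAlignment, refmap: ReferenceMap, labels):
    """Sort alignment columns into structural classes via the reference map.

    ``labels`` is an iterable of :class:`~ifacevol.structclass.SiteStructuralLabel`
    (or objects with ``chain_id``/``seq_number``/``site_class``/``interface``).
    Returns ``(partition, sub_alignments)`` where ``sub_alignments`` maps each
    nonempty class to the induced :class:`CodonAlignment` (taxon order kept).
    """
    by_residue = {}
    for lab in labels:
        cls = getattr(lab.site_class, "value", lab.site_class)
        by_residue[(lab.chain_id, lab.seq_number)] = (cls, lab.interface)

    column_class, column_interface = {}, {}
    missing = []
    for col in range(aln.n_columns):
        if col not in refmap.mapping:
            column_class[col] = UNMAPPED
            continue
        res = refmap.mapping[col]
        if res not in by_residue:
            missing.append(res)
            continue
        cls, iface = by_residue[res]
        column_class[col] = cls
        if iface is not None:
            column_interface[col] = bool(iface)
    if missing:
        raise ValueError(
            f"{len(missing)} mapped residues lack structural labels, e.g. "
            f"{missing[:5]}"
        )
    partition = SitePartition(column_class, column_interface)
    subs = {
        cls: aln.subset(cols)
        for cls, cols in partition.class_columns().items()
        if cols
    }
    return partition, subs
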