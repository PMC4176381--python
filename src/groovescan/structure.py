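"""Protein–DNA complex model and sequence threading.

The central object is a :class:`ProteinDNAComplex`: a protein (list of
residues with explicit atoms) bound to a double-stranded DNA duplex whose
backbone geometry is fixed.  Alternative DNA sequences are "threaded" onto
the duplex by replacing base atoms with idealized planar templates oriented
on per-position anchor frames, leaving every backbone and protein atom
untouched.  This is the substrate for exhaustive motif scanning: the
assumption (and documented limitation) is that the protein binds every
sequence variant in the same conformation as the crystal structure.

Groove chemistry is encoded per base: which major/minor-groove atoms can act
as hydrogen-bond donors, acceptors, or hydrophobic contacts.  The canonical
example is the minor-groove edge of guanine, which presents two functional
groups (the N2 amino donor and the aromatic N3 acceptor) where adenine
presents only one (N3) — the origin of bidentate versus monodentate
side-chain readout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_BASES",
    "Atom",
    "Residue",
    "GrooveSite",
    "BaseChemistry",
    "BASE_CHEMISTRY",
    "BASE_TEMPLATES",
    "BASE_ATOM_NAMES",
    "AnchorFrame",
    "DNADuplex",
    "DomainMap",
    "ProteinDNAComplex",
    "complement",
    "reverse_complement",
    "thread_sequence",
    "assign_domains",
    "transform_complex",
    "read_complex",
    "write_complex",
    "complex_summary",
]

CANONICAL_BASES = ("A", "C", "G", "T")
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_NUC_NAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
_SKIP_RESNAMES = {"HOH", "WAT"}


def complement(base: str) -> str:
    """Watson–Crick partner of a canonical base (an involution on {A,C,G,T})."""
    try:
        return _WC[base]
    except KeyError:
        raise ValueError(f"non-canonical base {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a 5'->3' sequence, returned 5'->3'."""
    return "".join(complement(b) for b in reversed(seq))


@dataclass
class Atom:
    """A named atom with element and Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")


@dataclass
class Residue:
    """A protein residue or nucleotide: 1-based file-order index, 3-letter or
    nucleotide code, chain id, and a non-empty atom list."""

    index: int
    name: str
    chain: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.index}: no atoms")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass(frozen=True)
class GrooveSite:
    """A base atom that can be read out in a groove: donor/acceptor/hydrophobic."""

    atom: str
    role: str

    _ROLES = ("donor", "acceptor", "hydrophobic")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"groove-site role must be one of {self._ROLES}")


@dataclass(frozen=True)
class BaseChemistry:
    identity: str
    major_groove_sites: tuple[GrooveSite, ...]
    minor_groove_sites: tuple[GrooveSite, ...]

    def __post_init__(self) -> None:
        if self.identity not in CANONICAL_BASES:
            raise ValueError(f"non-canonical base {self.identity!r}")

    def sites(self) -> tuple[GrooveSite, ...]:
        return self.major_groove_sites + self.minor_groove_sites


def _gs(*pairs: tuple[str, str]) -> tuple[GrooveSite, ...]:
    return tuple(GrooveSite(a, r) for a, r in pairs)


#: Groove functional groups per base.  Guanine's minor-groove edge offers two
#: H-bonding groups (N2 amino donor + aromatic N3 acceptor) whereas adenine
#: offers only the aromatic N3 acceptor — the bidentate/monodentate asymmetry
#: that side chains such as glutamine can discriminate.
BASE_CHEMISTRY: dict[str, BaseChemistry] = {
    "A": BaseChemistry("A", _gs(("N6", "donor"), ("N7", "acceptor")), _gs(("N3", "acceptor"))),
    "G": BaseChemistry("G", _gs(("O6", "acceptor"), ("N7", "acceptor")), _gs(("N2", "donor"), ("N3", "acceptor"))),
    "C": BaseChemistry("C", _gs(("N4", "donor")), _gs(("O2", "acceptor"))),
    "T": BaseChemistry("T", _gs(("O4", "acceptor"), ("C7", "hydrophobic")), _gs(("O2", "acceptor"))),
}

# Idealized planar base templates, coordinates (x, y) in Angstrom in the
# anchor frame: origin at C1', x toward the glycosidic nitrogen, +y toward
# the major-groove edge, -y toward the minor-groove edge.  The geometry is a
# deterministic caricature of real base geometry — ring bond lengths and
# groove-edge placements are approximate, which is sufficient because only
# relative energies of threaded variants are ever compared.
BASE_TEMPLATES: dict[str, list[tuple[str, float, float]]] = {
    "G": [
        ("N9", 1.47, 0.00), ("C4", 2.70, -0.50), ("N3", 2.95, -1.80),
        ("C2", 4.25, -2.10), ("N2", 4.60, -3.40), ("N1", 5.20, -1.15),
        ("C6", 5.00, 0.20), ("O6", 5.95, 1.05), ("C5", 3.70, 0.55),
        ("N7", 3.90, 1.90), ("C8", 2.60, 2.25),
    ],
    "A": [
        ("N9", 1.47, 0.00), ("C4", 2.70, -0.50), ("N3", 2.95, -1.80),
        ("C2", 4.25, -2.10), ("N1", 5.20, -1.15),
        ("C6", 5.00, 0.20), ("N6", 5.95, 1.05), ("C5", 3.70, 0.55),
        ("N7", 3.90, 1.90), ("C8", 2.60, 2.25),
    ],
    "C": [
        ("N1", 1.47, 0.00), ("C2", 2.75, -0.45), ("O2", 3.00, -1.70),
        ("N3", 3.75, 0.50), ("C4", 3.50, 1.80), ("N4", 4.45, 2.65),
        ("C5", 2.20, 2.25), ("C6", 1.25, 1.30),
    ],
    "T": [
        ("N1", 1.47, 0.00), ("C2", 2.75, -0.45), ("O2", 3.00, -1.70),
        ("N3", 3.75, 0.50), ("C4", 3.50, 1.80), ("O4", 4.45, 2.65),
        ("C5", 2.20, 2.25), ("C6", 1.25, 1.30), ("C7", 1.95, 3.55),
    ],
}

#: All atom names that belong to a base template (everything else in a
#: nucleotide residue is treated as fixed backbone).
BASE_ATOM_NAMES: frozenset[str] = frozenset(
    name for tmpl in BASE_TEMPLATES.values() for name, _, _ in tmpl
)

# glycosidic nitrogen and the in-plane reference atom used to recover frames
_GLYCOSIDIC = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}
_PLANE_REF = {"A": "C4", "G": "C4", "C": "C2", "T": "C2"}
_PLANE_REF_Y = {"A": -0.50, "G": -0.50, "C": -0.45, "T": -0.45}


def element_of(atom_name: str) -> str:
    """Chemical element inferred from a (PDB-style) atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class AnchorFrame:
    """Right-handed in-plane frame anchoring a base on its backbone: origin at
    C1', x toward the glycosidic bond, y toward the major groove."""

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x_hat = np.asarray(self.x_hat, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        for v in (self.x_hat, self.y_hat):
            n = np.linalg.norm(v)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError("anchor frame axes must be unit vectors")
        if abs(float(self.x_hat @ self.y_hat)) > 1e-6:
            raise ValueError("anchor frame axes must be orthogonal")

    def place(self, x: float, y: float) -> np.ndarray:
        return self.origin + x * self.x_hat + y * self.y_hat


def place_base(frame: AnchorFrame, base: str) -> list[Atom]:
    """Instantiate the idealized template for ``base`` on an anchor frame."""
    if base not in BASE_TEMPLATES:
        raise ValueError(f"non-canonical base {base!r}")
    return [
        Atom(name, element_of(name), frame.place(x, y))
        for name, x, y in BASE_TEMPLATES[base]
    ]


@dataclass
class DNADuplex:
    """A DNA duplex with fixed backbone anchors on both strands.

    ``ref_residues``/``comp_residues`` are aligned by pair position: entry
    ``i`` of each holds the two bases of base pair ``i+1`` (1-based motif
    position on the reference strand, 5'->3' as printed).  The complementary
    strand read 5'->3' is therefore the reverse of the per-position
    complements.
    """

    ref_residues: list[Residue]
    comp_residues: list[Residue]
    ref_frames: list[AnchorFrame]
    comp_frames: list[AnchorFrame]
    reference_chain: str = "D"
    complementary_chain: str = "E"

    def __post_init__(self) -> None:
        L = len(self.ref_residues)
        if not (len(self.comp_residues) == len(self.ref_frames) == len(self.comp_frames) == L):
            raise ValueError("duplex strand/frame lengths disagree")
        if L < 1:
            raise ValueError("empty duplex")
        for i, (r, c) in enumerate(zip(self.ref_residues, self.comp_residues), start=1):
            rb, cb = _base_of(r), _base_of(c)
            if complement(rb) != cb:
                raise ValueError(f"pairing error at position {i}: {rb} opposite {cb}")

    def __len__(self) -> int:
        return len(self.ref_residues)

    @property
    def reference_sequence(self) -> str:
        return "".join(_base_of(r) for r in self.ref_residues)

    @property
    def complementary_sequence(self) -> str:
        """Complementary strand 5'->3' (reverse complement of the reference)."""
        return "".join(_base_of(r) for r in self.comp_residues)[::-1]

    def residues(self) -> list[Residue]:
        return list(self.ref_residues) + list(self.comp_residues)


def _base_of(residue: Residue) -> str:
    name = residue.name
    if name in _NUC_NAMES:
        return _NUC_NAMES[name]
    if name in CANONICAL_BASES:
        return name
    raise ValueError(f"residue {residue.index}: unknown nucleotide code {name!r}")


@dataclass
class DomainMap:
    """Named, non-overlapping inclusive residue-index ranges (e.g. NTD/BTD/CTD)."""

    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: list[tuple[int, int, str]] = []
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"domain {name}: empty range ({lo}, {hi})")
            for plo, phi, pname in seen:
                if lo <= phi and plo <= hi:
                    raise ValueError(f"domains {pname} and {name} overlap")
            seen.append((lo, hi, name))

    def domain_of(self, index: int) -> str:
        for name, (lo, hi) in self.ranges.items():
            if lo <= index <= hi:
                return name
        return "linker"

    def names(self) -> list[str]:
        return list(self.ranges)


@dataclass
class ProteinDNAComplex:
    """A protein bound to a DNA duplex, plus an optional domain annotation and
    the numbering offset mapping file-order indices to author numbering."""

    protein: list[Residue]
    duplex: DNADuplex
    domain_map: DomainMap | None = None
    numbering_offset: int = 52

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("protein is empty")
        if self.duplex is None:
            raise ValueError("duplex is required")

    @property
    def L(self) -> int:
        return len(self.duplex)

    def author_residue_number(self, index: int) -> int:
        """Map a file-order protein index to the construct's author numbering."""
        return index + self.numbering_offset

    def protein_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(res, atom) for res in self.protein for atom in res.atoms]

    def dna_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(res, atom) for res in self.duplex.residues() for atom in res.atoms]


# ---------------------------------------------------------------------------
# operations


def thread_sequence(cplx: ProteinDNAComplex, motif: str) -> ProteinDNAComplex:
    """Thread ``motif`` onto the duplex, returning a variant complex.

    Base identities are replaced on both strands (complementarity
    maintained); base atoms are re-placed from idealized templates on the
    fixed anchor frames.  Backbone anchors and every protein atom are reused
    unchanged — threading never moves them.
    """
    motif = str(motif).upper()
    if len(motif) != cplx.L:
        raise ValueError(f"motif length {len(motif)} != duplex length {cplx.L}")
    for b in motif:
        if b not in CANONICAL_BASES:
            raise ValueError(f"non-canonical base {b!r} in motif {motif!r}")

    def rebuild(residues: list[Residue], frames: list[AnchorFrame], seq: str) -> list[Residue]:
        out = []
        for res, frame, base in zip(residues, frames, seq):
            backbone = [a for a in res.atoms if a.name not in BASE_ATOM_NAMES]
            out.append(Residue(res.index, "D" + base, res.chain, backbone + place_base(frame, base)))
        return out

    comp_seq = "".join(complement(b) for b in motif)
    duplex = DNADuplex(
        ref_residues=rebuild(cplx.duplex.ref_residues, cplx.duplex.ref_frames, motif),
        comp_residues=rebuild(cplx.duplex.comp_residues, cplx.duplex.comp_frames, comp_seq),
        ref_frames=cplx.duplex.ref_frames,
        comp_frames=cplx.duplex.comp_frames,
        reference_chain=cplx.duplex.reference_chain,
        complementary_chain=cplx.duplex.complementary_chain,
    )
    return ProteinDNAComplex(
        protein=cplx.protein,
        duplex=duplex,
        domain_map=cplx.domain_map,
        numbering_offset=cplx.numbering_offset,
    )


def assign_domains(cplx: ProteinDNAComplex, domain_map: DomainMap) -> ProteinDNAComplex:
    """Attach a domain map; residues outside every range are "linker"."""
    max_index = max(r.index for r in cplx.protein)
    for name, (lo, hi) in domain_map.ranges.items():
        if lo < 1 or hi > max_index:
            raise ValueError(f"domain {name}: range ({lo}, {hi}) outside residue span 1..{max_index}")
    return dataclasses.replace(cplx, domain_map=domain_map)


def transform_complex(
    cplx: ProteinDNAComplex,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> ProteinDNAComplex:
    """Apply a rigid-body transform to every atom and anchor frame."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)

    def tx_res(res: Residue) -> Residue:
        atoms = [Atom(a.name, a.element, R @ a.position + t) for a in res.atoms]
        return Residue(res.index, res.name, res.chain, atoms)

    def tx_frame(f: AnchorFrame) -> AnchorFrame:
        return AnchorFrame(R @ f.origin + t, R @ f.x_hat, R @ f.y_hat)

    duplex = DNADuplex(
        ref_residues=[tx_res(r) for r in cplx.duplex.ref_residues],
        comp_residues=[tx_res(r) for r in cplx.duplex.comp_residues],
        ref_frames=[tx_frame(f) for f in cplx.duplex.ref_frames],
        comp_frames=[tx_frame(f) for f in cplx.duplex.comp_frames],
        reference_chain=cplx.duplex.reference_chain,
        complementary_chain=cplx.duplex.complementary_chain,
    )
    return ProteinDNAComplex(
        protein=[tx_res(r) for r in cplx.protein],
        duplex=duplex,
        domain_map=cplx.domain_map,
        numbering_offset=cplx.numbering_offset,
    )


# ---------------------------------------------------------------------------
# PDB input / output (Biopython behind the scenes)


def read_complex(
    path: str | Path,
    reference_chain: str | None = None,
    numbering_offset: int = 52,
) -> ProteinDNAComplex:
    """Parse a protein–DNA complex from a PDB file.

    Protein and DNA chains are separated by residue code; the two DNA strands
    are paired by complementarity (antiparallel file order).  Only the first
    MODEL is used and alternate location 'A' is preferred.  The reference
    strand is ``reference_chain`` if given, otherwise the first DNA chain in
    file order; the choice is recorded on the duplex.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("cplx", str(path))))

    protein: list[Residue] = []
    dna_chains: dict[str, list[Residue]] = {}
    pindex = 0
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if resname in _SKIP_RESNAMES:
                continue
            atoms = []
            for atom in res:
                if atom.get_altloc() not in (" ", "A", ""):
                    continue
                el = (atom.element or "").strip() or element_of(atom.get_name())
                atoms.append(Atom(atom.get_name(), el, np.array(atom.get_coord(), dtype=float)))
            if not atoms:
                continue
            if resname in _AMINO3:
                pindex += 1
                protein.append(Residue(pindex, resname, chain.id, atoms))
            elif resname in _NUC_NAMES or resname in CANONICAL_BASES:
                lst = dna_chains.setdefault(chain.id, [])
                lst.append(Residue(len(lst) + 1, resname, chain.id, atoms))
            else:
                raise ValueError(
                    f"unknown residue code {resname!r} at {chain.id}:{res.get_id()[1]}"
                )

    if not dna_chains:
        raise ValueError("not a protein–DNA complex: no DNA chain found")
    if not protein:
        raise ValueError("no protein chain found")
    if len(dna_chains) != 2:
        raise ValueError(f"expected 2 DNA strands, found {len(dna_chains)}")

    chain_ids = list(dna_chains)
    if reference_chain is None:
        ref_id = chain_ids[0]
    elif reference_chain in dna_chains:
        ref_id = reference_chain
    else:
        raise ValueError(f"reference chain {reference_chain!r} is not a DNA chain")
    comp_id = next(c for c in chain_ids if c != ref_id)

    ref = dna_chains[ref_id]
    comp_53 = dna_chains[comp_id]
    if len(ref) != len(comp_53):
        raise ValueError(
            f"pairing error: strand lengths differ ({len(ref)} vs {len(comp_53)})"
        )
    comp = comp_53[::-1]  # align antiparallel partner to reference positions
    for i, (r, c) in enumerate(zip(ref, comp), start=1):
        if complement(_base_of(r)) != _base_of(c):
            raise ValueError(
                f"pairing error at position {i}: {_base_of(r)} opposite {_base_of(c)}"
            )

    duplex = DNADuplex(
        ref_residues=ref,
        comp_residues=comp,
        ref_frames=[_frame_from_residue(r) for r in ref],
        comp_frames=[_frame_from_residue(c) for c in comp],
        reference_chain=ref_id,
        complementary_chain=comp_id,
    )
    return ProteinDNAComplex(protein=protein, duplex=duplex, numbering_offset=numbering_offset)


def _frame_from_residue(res: Residue) -> AnchorFrame:
    """Recover the anchor frame from C1', the glycosidic N and an in-plane atom."""
    base = _base_of(res)
    c1 = res.atom("C1'")
    ng = res.atom(_GLYCOSIDIC[base])
    pref = res.atom(_PLANE_REF[base])
    if c1 is None or ng is None or pref is None:
        missing = [n for n, a in (("C1'", c1), (_GLYCOSIDIC[base], ng), (_PLANE_REF[base], pref)) if a is None]
        raise ValueError(f"residue {res.chain}:{res.index}: cannot build anchor frame, missing {missing}")
    x = ng.position - c1.position
    x_hat = x / np.linalg.norm(x)
    v = pref.position - c1.position
    perp = v - (v @ x_hat) * x_hat
    n = np.linalg.norm(perp)
    if n < 1e-9:
        raise ValueError(f"residue {res.chain}:{res.index}: degenerate base plane")
    y_hat = perp / n
    if _PLANE_REF_Y[base] < 0:
        y_hat = -y_hat
    return AnchorFrame(c1.position.copy(), x_hat, y_hat)


def write_complex(cplx: ProteinDNAComplex, path: str | Path) -> None:
    """Write the complex as a PDB file (protein chains, then the two strands)."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("cplx")
    sb.init_model(0)
    serial = 1

    def emit(chain_id: str, residues: list[Residue]) -> None:
        nonlocal serial
        sb.init_chain(chain_id)
        sb.init_seg("    ")
        for res in residues:
            sb.init_residue(res.name.rjust(3), " ", res.index, " ")
            for a in res.atoms:
                fullname = a.name if len(a.name) == 4 else f" {a.name}".ljust(4)
                sb.init_atom(a.name, a.position, 0.0, 1.0, " ", fullname,
                             serial, element=a.element)
                serial += 1

    by_chain: dict[str, list[Residue]] = {}
    for res in cplx.protein:
        by_chain.setdefault(res.chain, []).append(res)
    for chain_id, residues in by_chain.items():
        emit(chain_id, residues)
    emit(cplx.duplex.reference_chain, cplx.duplex.ref_residues)
    # complementary strand written back in its own 5'->3' file order
    comp = cplx.duplex.comp_residues[::-1]
    comp = [Residue(i + 1, r.name, r.chain, r.atoms) for i, r in enumerate(comp)]
    emit(cplx.duplex.complementary_chain, comp)

    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def complex_summary(cplx: ProteinDNAComplex) -> str:
    """Tab-separated one-stop summary of the complex."""
    lines = [
        "field\tvalue",
        f"protein_residues\t{len(cplx.protein)}",
        f"protein_atoms\t{sum(len(r.atoms) for r in cplx.protein)}",
        f"duplex_length\t{cplx.L}",
        f"reference_sequence\t{cplx.duplex.reference_sequence}",
        f"complementary_sequence\t{cplx.duplex.complementary_sequence}",
        f"reference_chain\t{cplx.duplex.reference_chain}",
        f"numbering_offset\t{cplx.numbering_offset}",
    ]
    if cplx.domain_map is not None:
        for name, (lo, hi) in cplx.domain_map.ranges.items():
            lines.append(f"domain_{name}\t{lo}-{hi}")
    return "\n".join(lines) + "\n"
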