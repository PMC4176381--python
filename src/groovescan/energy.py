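"""Empirical, term-decomposed protein–DNA binding energy function.

Scores a threaded complex with four additive terms, mirroring the
decomposition used in structure-based mutational scans of protein–DNA
interfaces:

* ``clash_dna`` — soft steric overlap internal to the DNA (>= 0),
* ``clash_protein`` — soft steric overlap between protein and DNA (>= 0),
* ``interaction_energy`` — distance-weighted favorable van-der-Waals-like
  contact term over protein–DNA atom pairs (<= 0),
* ``sidechain_hbond`` — geometric hydrogen bonds between protein side chains
  and base groove sites (<= 0); a single base may contribute two or more
  contacts (bidentate readout).

The total is defined as the exact sum of the four terms.  Absolute values
are on an arbitrary kcal/mol-like scale and are not calibrated against any
external force field: only relative binding energies (ΔΔG between threaded
sequence variants under identical parameters) are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import BASE_CHEMISTRY, ProteinDNAComplex, Residue, _base_of

__all__ = [
    "EnergyParameters",
    "HBondContact",
    "EnergyBreakdown",
    "VDW_RADII",
    "detect_hbonds",
    "clash_terms",
    "interaction_energy",
    "binding_energy",
    "relative_binding_energy",
    "clash_penalty",
]

#: van der Waals radii (Angstrom) by element; unknown elements default to C.
VDW_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
}
_DEFAULT_RADIUS = 1.70

# protein side-chain H-bonding atoms, keyed by (residue name, atom name)
PROTEIN_DONORS: frozenset[tuple[str, str]] = frozenset({
    ("GLN", "NE2"), ("ASN", "ND2"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2"),
})
PROTEIN_ACCEPTORS: frozenset[tuple[str, str]] = frozenset({
    ("GLN", "OE1"), ("ASN", "OD1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
})


@dataclass(frozen=True)
class EnergyParameters:
    """Tunable parameters of the energy function.

    Defaults follow conventional hydrogen-bond geometry (donor–acceptor
    2.5–3.5 A, donor angle >= 120 deg, -1 kcal/mol per ideal bond with
    linear distance/angle attenuation), a soft quadratic clash below 0.9x
    the summed van der Waals radii, and an attractive well truncated at 6 A.
    """

    hbond_distance_range: tuple[float, float] = (2.5, 3.5)
    hbond_angle_min: float = 120.0
    hbond_well_depth: float = 1.0
    clash_radius_scale: float = 0.9
    clash_penalty_scale: float = 10.0
    interaction_distance_cutoff: float = 6.0
    interaction_well_depth: float = 0.05
    term_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.hbond_distance_range
        if not lo < hi:
            raise ValueError("hbond distance range: min must be < max")
        for name in ("hbond_well_depth", "clash_radius_scale",
                     "clash_penalty_scale", "interaction_distance_cutoff",
                     "interaction_well_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def fingerprint(self) -> tuple:
        return (
            self.hbond_distance_range, self.hbond_angle_min,
            self.hbond_well_depth, self.clash_radius_scale,
            self.clash_penalty_scale, self.interaction_distance_cutoff,
            self.interaction_well_depth, self.term_weights,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyParameters":
        kwargs = dict(d)
        if "hbond_distance_range" in kwargs:
            kwargs["hbond_distance_range"] = tuple(kwargs["hbond_distance_range"])
        if "term_weights" in kwargs:
            kwargs["term_weights"] = tuple(kwargs["term_weights"])
        return cls(**kwargs)


DEFAULT_PARAMETERS = EnergyParameters()


@dataclass
class HBondContact:
    """One geometric hydrogen bond between a protein side chain and a base.

    ``donor``/``acceptor`` identify (residue index, atom name) on their
    respective sides; ``energy`` is <= 0.
    """

    donor: tuple[int, str]
    acceptor: tuple[int, str]
    distance: float
    angle: float
    energy: float


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-complex energy decomposition; ``total`` is the exact 4-term sum."""

    clash_dna: float
    clash_protein: float
    interaction_energy: float
    sidechain_hbond: float
    total: float
    params_fingerprint: tuple | None = None

    def __post_init__(self) -> None:
        if self.clash_dna < 0 or self.clash_protein < 0:
            raise ValueError("clash terms must be non-negative")
        if self.sidechain_hbond > 0:
            raise ValueError("side-chain H-bond term must be non-positive")

    @classmethod
    def from_terms(
        cls,
        clash_dna: float,
        clash_protein: float,
        interaction_energy: float,
        sidechain_hbond: float,
        params_fingerprint: tuple | None = None,
    ) -> "EnergyBreakdown":
        total = clash_dna + clash_protein + interaction_energy + sidechain_hbond
        return cls(clash_dna, clash_protein, interaction_energy,
                   sidechain_hbond, total, params_fingerprint)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _polar_protein_atoms(cplx: ProteinDNAComplex):
    """(residue, atom, is_donor, is_acceptor) for side-chain polar atoms."""
    out = []
    for res in cplx.protein:
        for atom in res.atoms:
            key = (res.name, atom.name)
            d, a = key in PROTEIN_DONORS, key in PROTEIN_ACCEPTORS
            if d or a:
                out.append((res, atom, d, a))
    return out


def _antecedent(res: Residue, atom) -> np.ndarray | None:
    """Nearest bonded heavy atom (< 1.8 A) used to define the donor angle."""
    best, best_d = None, 1.8
    for other in res.atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(other.position - atom.position))
        if d < best_d:
            best, best_d = other.position, d
    return best


def detect_hbonds(
    cplx: ProteinDNAComplex,
    params: EnergyParameters = DEFAULT_PARAMETERS,
) -> list[HBondContact]:
    """Geometric protein-side-chain-to-base hydrogen bonds.

    Donor and acceptor roles must be complementary (protein donor with base
    acceptor, or vice versa), the heavy-atom distance must lie inside the
    configured range, and the angle at the donor (antecedent–donor–acceptor)
    must exceed the minimum; when no antecedent atom is present the angle is
    assumed ideal.  Missing groove-site atoms are skipped with a warning.
    """
    lo, hi = params.hbond_distance_range
    d_ideal = 0.5 * (lo + hi)
    contacts: list[HBondContact] = []
    polar = _polar_protein_atoms(cplx)
    if not polar:
        return contacts

    for res in cplx.duplex.residues():
        chem = BASE_CHEMISTRY[_base_of(res)]
        for site in chem.sites():
            if site.role == "hydrophobic":
                continue
            satom = res.atom(site.atom)
            if satom is None:
                warnings.warn(
                    f"groove site {site.atom} missing on residue "
                    f"{res.chain}:{res.index}; contact skipped"
                )
                continue
            for pres, patom, p_don, p_acc in polar:
                if site.role == "acceptor" and p_don:
                    donor_res, donor_atom = pres, patom
                    acc_pos = satom.position
                    donor_key = (pres.index, patom.name)
                    acc_key = (res.index, site.atom)
                elif site.role == "donor" and p_acc:
                    donor_res, donor_atom = res, satom
                    acc_pos = patom.position
                    donor_key = (res.index, site.atom)
                    acc_key = (pres.index, patom.name)
                else:
                    continue
                dist = float(np.linalg.norm(acc_pos - donor_atom.position))
                if not (lo <= dist <= hi):
                    continue
                ante = _antecedent(donor_res, donor_atom)
                if ante is None:
                    angle = 180.0
                else:
                    # included angle antecedent-donor-acceptor: 180 deg when
                    # antecedent->donor and donor->acceptor are parallel
                    v1 = donor_atom.position - ante
                    v2 = acc_pos - donor_atom.position
                    cosang = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = 180.0 - float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < params.hbond_angle_min:
                    continue
                f_d = 1.0 if dist <= d_ideal else (hi - dist) / (hi - d_ideal)
                f_a = min(1.0, (angle - params.hbond_angle_min)
                          / (180.0 - params.hbond_angle_min))
                energy = -params.hbond_well_depth * f_d * max(0.0, f_a)
                contacts.append(HBondContact(donor_key, acc_key, dist, angle, energy))
    return contacts


# ---------------------------------------------------------------------------
# steric terms


def clash_penalty(distance: float, r1: float, r2: float,
                  params: EnergyParameters = DEFAULT_PARAMETERS) -> float:
    """Soft quadratic overlap penalty for one atom pair (0 beyond cutoff)."""
    rcut = params.clash_radius_scale * (r1 + r2)
    if distance >= rcut:
        return 0.0
    return params.clash_penalty_scale * (1.0 - distance / rcut) ** 2


def _atom_arrays(pairs):
    pos = np.array([a.position for _, a in pairs]) if pairs else np.zeros((0, 3))
    radii = np.array([VDW_RADII.get(a.element, _DEFAULT_RADIUS) for _, a in pairs])
    res_ids = np.array([id(r) for r, _ in pairs])
    return pos, radii, res_ids


def clash_terms(
    cplx: ProteinDNAComplex,
    params: EnergyParameters = DEFAULT_PARAMETERS,
) -> tuple[float, float]:
    """(clash_dna, clash_protein): DNA-internal and protein–DNA soft overlap.

    DNA-internal pairs are restricted to atoms of *different* nucleotide
    residues (bonded intra-residue geometry is fixed by construction).
    """
    dpos, drad, dres = _atom_arrays(cplx.dna_atoms())
    ppos, prad, _ = _atom_arrays(cplx.protein_atoms())

    clash_dna = 0.0
    if len(dpos) > 1:
        dist = cdist(dpos, dpos)
        rcut = params.clash_radius_scale * (drad[:, None] + drad[None, :])
        mask = (dist < rcut) & (dres[:, None] != dres[None, :])
        iu = np.triu(mask, k=1)
        if iu.any():
            terms = params.clash_penalty_scale * (1.0 - dist[iu] / rcut[iu]) ** 2
            clash_dna = float(terms.sum())

    clash_protein = 0.0
    if len(dpos) and len(ppos):
        dist = cdist(ppos, dpos)
        rcut = params.clash_radius_scale * (prad[:, None] + drad[None, :])
        mask = dist < rcut
        if mask.any():
            terms = params.clash_penalty_scale * (1.0 - dist[mask] / rcut[mask]) ** 2
            clash_protein = float(terms.sum())
    return clash_dna, clash_protein


def interaction_energy(
    cplx: ProteinDNAComplex,
    params: EnergyParameters = DEFAULT_PARAMETERS,
) -> float:
    """Favorable protein–DNA contact term: pairwise additive attractive well
    ``-eps * min(1, (r0/d)^6)`` truncated at the distance cutoff (<= 0).

    Electrostatics are folded into this term; there are no explicit charges.
    """
    dpos, drad, _ = _atom_arrays(cplx.dna_atoms())
    ppos, prad, _ = _atom_arrays(cplx.protein_atoms())
    if not len(dpos) or not len(ppos):
        return 0.0
    dist = cdist(ppos, dpos)
    r0 = prad[:, None] + drad[None, :]
    mask = dist <= params.interaction_distance_cutoff
    if not mask.any():
        return 0.0
    ratio = np.minimum(1.0, (r0[mask] / np.maximum(dist[mask], 1e-6)) ** 6)
    return float(-params.interaction_well_depth * ratio.sum())


# ---------------------------------------------------------------------------
# composition


def binding_energy(
    cplx: ProteinDNAComplex,
    params: EnergyParameters = DEFAULT_PARAMETERS,
) -> EnergyBreakdown:
    """All four energy terms for a threaded complex, plus their exact sum."""
    w_cd, w_cp, w_ie, w_hb = params.term_weights
    cd, cp = clash_terms(cplx, params)
    ie = interaction_energy(cplx, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hb = sum(c.energy for c in detect_hbonds(cplx, params))
    return EnergyBreakdown.from_terms(
        w_cd * cd, w_cp * cp, w_ie * ie, w_hb * hb,
        params_fingerprint=params.fingerprint(),
    )


def relative_binding_energy(reference: EnergyBreakdown, variant: EnergyBreakdown) -> float:
    """ΔΔG = variant total - reference total (both under identical parameters)."""
    if (
        reference.params_fingerprint is not None
        and variant.params_fingerprint is not None
        and reference.params_fingerprint != variant.params_fingerprint
    ):
        raise ValueError("breakdowns computed with different energy parameters")
    return variant.total - reference.total
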