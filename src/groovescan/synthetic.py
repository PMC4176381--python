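"""Seeded synthetic substrates for every analysis stage.

Nothing here is biophysically accurate — the generators exist so that the
scan, logo, calorimetry and dynamics machinery can be exercised end to end
on self-contained inputs with known ground truth:

* :func:`make_toy_complex` — a small idealized protein shell around an
  untwisted B-form-like duplex, with a glutamine-like probe posed against
  the minor-groove edge of the base complementary to position 1.  When that
  base is guanine the probe geometry realizes a bidentate hydrogen bond
  (amide O accepting from the guanine N2 amino group, amide N donating to
  the aromatic N3); adenine offers only N3, giving a single bond.  A
  "pocket" atom sits over the major groove of a chosen position so that the
  bulky methyl of thymine clashes where smaller bases do not.
* :func:`make_coupled_trajectory` — per-domain latent motions with a
  controllable inter-domain correlation, plus independent residue noise.
* :func:`make_itc_titration` — one-site thermograms with Gaussian noise.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .itc import Thermogram, TitrationProtocol, predict_heats
from .structure import (
    AnchorFrame,
    Atom,
    DNADuplex,
    DomainMap,
    ProteinDNAComplex,
    Residue,
    complement,
    place_base,
)

__all__ = [
    "make_toy_complex",
    "make_coupled_trajectory",
    "make_itc_titration",
    "ion_count",
    "load_fixture",
]

_DEFAULT_MOTIF = "CGTGGGAA"

# duplex layout constants (Angstrom): base-pair rise along z, C1'-C1' span
_RISE = 3.4
_C1_HALF_SPAN = 9.2


def make_toy_complex(
    L: int = 4,
    reference_sequence: str | None = None,
    probe_geometry: str = "bidentate",
    pocket_position: int | None = 2,
    shell_residues: int = 8,
    seed: int = 0,
) -> ProteinDNAComplex:
    """A toy protein–DNA complex for scanning and energy tests.

    The duplex is an untwisted ladder: base pair ``i`` lies in the plane
    z = (i-1) * 3.4 A with the two C1' anchors at x = -9.2 and +9.2 and the
    major-groove edge of every base facing +y.  The protein is a shell of
    glycine Cα atoms (jittered by the seed), one glutamine-like probe
    reading the base paired with position 1, and one alanine whose Cβ sits
    over the major groove of ``pocket_position``.

    ``probe_geometry`` is "bidentate" (hydrogen-bonding distance) or
    "displaced" (pushed 4 A away, out of range).
    """
    if not 2 <= L <= 8:
        raise ValueError(f"toy duplex length must be in 2..8, got {L}")
    if probe_geometry not in ("bidentate", "displaced"):
        raise ValueError(f"unknown probe geometry {probe_geometry!r}")
    seq = (reference_sequence or _DEFAULT_MOTIF[:L]).upper()
    if len(seq) != L:
        raise ValueError(f"reference sequence length {len(seq)} != L={L}")

    ref_frames, comp_frames = [], []
    ref_residues, comp_residues = [], []
    for i in range(L):
        z = i * _RISE
        rf = AnchorFrame(np.array([-_C1_HALF_SPAN, 0.0, z]),
                         np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        cf = AnchorFrame(np.array([+_C1_HALF_SPAN, 0.0, z]),
                         np.array([-1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        ref_frames.append(rf)
        comp_frames.append(cf)
        rb, cb = seq[i], complement(seq[i])
        ref_residues.append(Residue(i + 1, "D" + rb, "D",
                                    _backbone_atoms(rf) + place_base(rf, rb)))
        comp_residues.append(Residue(L - i, "D" + cb, "E",
                                     _backbone_atoms(cf) + place_base(cf, cb)))

    duplex = DNADuplex(ref_residues, comp_residues, ref_frames, comp_frames,
                       reference_chain="D", complementary_chain="E")

    rng = np.random.default_rng(seed)
    protein: list[Residue] = []
    zmax = (L - 1) * _RISE
    for k in range(shell_residues):
        theta = np.pi * (k + 0.5) / shell_residues  # upper half: away from probe
        z = zmax * k / max(1, shell_residues - 1)
        pos = np.array([13.0 * np.cos(theta), 13.0 * np.sin(theta), z])
        pos = pos + rng.normal(0.0, 0.05, 3)
        protein.append(Residue(k + 1, "GLY", "A",
                               [Atom("CA", "C", pos)]))

    protein.append(_probe_residue(len(protein) + 1, comp_frames[0],
                                  displaced=(probe_geometry == "displaced")))
    if pocket_position is not None:
        if not 1 <= pocket_position <= L:
            raise ValueError(f"pocket position {pocket_position} outside 1..{L}")
        protein.append(_pocket_residue(len(protein) + 1, ref_frames[pocket_position - 1]))

    return ProteinDNAComplex(protein=protein, duplex=duplex, numbering_offset=52)


def _backbone_atoms(frame: AnchorFrame) -> list[Atom]:
    """Fixed sugar/phosphate stand-ins: C1' at the anchor origin, P outboard."""
    p_pos = frame.origin - 1.5 * frame.x_hat + np.array([0.0, 0.0, -1.2])
    return [Atom("C1'", "C", frame.origin.copy()), Atom("P", "P", p_pos)]


def _probe_residue(index: int, frame: AnchorFrame, displaced: bool) -> Residue:
    """Glutamine-like side chain posed against the minor-groove edge of the
    base on ``frame``: OE1 opposite where guanine's N2 amino group sits,
    NE2 donating toward the aromatic N3 position."""
    n2 = frame.place(4.60, -3.40)
    c2 = frame.place(4.25, -2.10)
    n3 = frame.place(2.95, -1.80)
    c4 = frame.place(2.70, -0.50)

    u_n2 = n2 - c2
    u_n2 /= np.linalg.norm(u_n2)
    oe1 = n2 + 2.9 * u_n2

    mid = 0.5 * (c2 + c4)
    u_n3 = n3 - mid
    u_n3 /= np.linalg.norm(u_n3)
    ne2 = n3 + 2.9 * u_n3
    cd = ne2 + 1.5 * u_n3
    cg = cd + 1.5 * u_n3
    ca = cg + np.array([0.0, -1.5, 1.0])

    # the probe sits on the minor-groove (-y) side; "displaced" retreats it
    # a further 4 A out of the groove, beyond hydrogen-bonding range
    shift = -4.0 * frame.y_hat if displaced else np.zeros(3)
    atoms = [
        Atom("CA", "C", ca + shift),
        Atom("CG", "C", cg + shift),
        Atom("CD", "C", cd + shift),
        Atom("OE1", "O", oe1 + shift),
        Atom("NE2", "N", ne2 + shift),
    ]
    return Residue(index, "GLN", "A", atoms)


def _pocket_residue(index: int, frame: AnchorFrame) -> Residue:
    """Alanine whose Cβ hangs over the major groove where thymine's C7
    methyl would sit, so threading T there costs a steric clash."""
    c7 = frame.place(1.95, 3.55)
    cb = c7 + 2.65 * frame.y_hat
    ca = cb + 1.5 * frame.y_hat
    return Residue(index, "ALA", "A", [Atom("CA", "C", ca), Atom("CB", "C", cb)])


# ---------------------------------------------------------------------------
# trajectories


def make_coupled_trajectory(
    n_residues: int = 30,
    domains: DomainMap | None = None,
    coupling: float = 0.5,
    F: int = 400,
    noise: float = 0.3,
    amplitude: float = 1.0,
    seed: int = 0,
    return_latents: bool = False,
):
    """Synthetic Cα trajectory with controllable inter-domain coordination.

    Each domain d carries a latent scalar series z_d(t) built as
    sqrt(c) * s(t) + sqrt(1-c) * eta_d(t) from a shared series s and an
    independent one, so corr(z_d, z_e) = c = ``coupling`` for d != e.
    Residue i in domain d is displaced by amplitude * z_d(t) along a fixed
    axis with alternating sign per residue (so the net rigid-body motion
    cancels and superposition is near-neutral), plus isotropic Gaussian
    noise.  Domains are compact clusters 12 A apart, keeping all pairs
    inside a 30 A distance gate.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if domains is None:
        third = n_residues // 3
        domains = DomainMap({
            "NTD": (1, third),
            "BTD": (third + 1, 2 * third),
            "CTD": (2 * third + 1, n_residues),
        })
    rng = np.random.default_rng(seed)

    names = domains.names()
    centers = {name: np.array([12.0 * k, 0.0, 0.0]) for k, name in enumerate(names)}
    base = np.empty((n_residues, 3))
    domain_of = np.empty(n_residues, dtype=object)
    for i in range(n_residues):
        name = domains.domain_of(i + 1)
        if name == "linker":
            raise ValueError(f"residue {i+1} not covered by any domain")
        domain_of[i] = name
        base[i] = centers[name] + rng.uniform(-2.5, 2.5, 3)

    s = rng.standard_normal(F)
    latents = {
        name: np.sqrt(coupling) * s + np.sqrt(1.0 - coupling) * rng.standard_normal(F)
        for name in names
    }
    axis = np.array([1.0, 0.0, 0.0])
    signs = np.where(np.arange(n_residues) % 2 == 0, 1.0, -1.0)

    coords = np.empty((F, n_residues, 3))
    eps = rng.standard_normal((F, n_residues, 3))
    for i in range(n_residues):
        z = latents[domain_of[i]]
        coords[:, i, :] = base[i] + amplitude * signs[i] * np.outer(z, axis) \
            + noise * eps[:, i, :]

    traj = Trajectory(coords, [f"R{i+1}" for i in range(n_residues)], domains)
    if return_latents:
        return traj, latents
    return traj


# ---------------------------------------------------------------------------
# calorimetry


def make_itc_titration(
    n: float = 1.0,
    K: float = 2.0e6,
    dH: float = 8.8,
    protocol: TitrationProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """One-site thermogram with optional Gaussian noise (μcal, seeded).

    Defaults mimic a consensus-site titration: K = 2e6 M^-1, ΔH = 8.8
    kcal/mol, twenty 14 μl injections of 100 μM ligand into 10 μM
    macromolecule at 10 °C.
    """
    protocol = protocol or TitrationProtocol()
    tg = predict_heats(protocol, n, K, dH)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tg = Thermogram(protocol, tg.heats + rng.normal(0.0, noise_sd, len(tg.heats)))
    return tg


def ion_count(n_water: int) -> int:
    """Counter-ion count for a physiological 0.15 M salt box:
    N(ions) = N(water molecules) * 0.15 / 55.555, rounded."""
    if n_water < 0:
        raise ValueError("water count must be >= 0")
    return int(round(n_water * 0.15 / 55.555))


# ---------------------------------------------------------------------------
# packaged fixture tables


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged reference tables.

    ``"table1"`` — the four-term energy decomposition of the two consensus
    variants (C vs T at position 1).  ``"table2"`` — calorimetric constants
    for five ligand duplexes, including a weak binder (Kd > 50 μM) and a
    no-binding-detected (NBD) negative control.  Numeric cells are parsed to
    float; sentinel cells (">50", "NBD") are kept as strings.
    """
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown fixture {name!r}")
    path = resources.files("groovescan.data").joinpath(f"{name}.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)

    def parse(cell):
        if not isinstance(cell, str):
            return cell
        try:
            return float(cell)
        except ValueError:
            return cell

    for col in df.columns:
        if col not in ("sequence", "ligand", "flag"):
            df[col] = df[col].map(parse)
    return df
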