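"""Exhaustive motif-space enumeration and energy scanning.

Every sequence of length L over {A,C,G,T} is threaded onto the complex and
scored with the term-decomposed energy function; relative binding energies
(ΔΔG) are reported against the best-scoring motif, so the top record always
has ΔΔG = 0.  A threshold on ΔΔG (inclusive, measured from the top sequence)
partitions the 4^L motifs into a putative "bound" set and the residual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import DEFAULT_PARAMETERS, EnergyBreakdown, EnergyParameters, binding_energy
from .structure import CANONICAL_BASES, ProteinDNAComplex, thread_sequence

__all__ = [
    "Motif",
    "ScanRecord",
    "ScanTable",
    "BoundSet",
    "enumerate_motifs",
    "scan",
    "select_bound",
    "ddgs_from_totals",
]

MAX_SCAN_LENGTH = 12

Motif = str  # validated sequence over {A,C,G,T}


def _validate_motif(motif: str) -> str:
    motif = str(motif).upper()
    if len(motif) < 1:
        raise ValueError("motif must have length >= 1")
    for b in motif:
        if b not in CANONICAL_BASES:
            raise ValueError(f"non-canonical base {b!r} in motif {motif!r}")
    return motif


def enumerate_motifs(L: int) -> list[Motif]:
    """All 4^L motifs of length L, in lexicographic order (A < C < G < T)."""
    if not 1 <= L <= MAX_SCAN_LENGTH:
        raise ValueError(f"motif length must be in 1..{MAX_SCAN_LENGTH}, got {L}")
    return ["".join(p) for p in itertools.product(CANONICAL_BASES, repeat=L)]


def ddgs_from_totals(totals) -> np.ndarray:
    """ΔΔG values relative to the minimum total (invariant under a uniform shift)."""
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("empty totals")
    return totals - totals.min()


@dataclass(frozen=True)
class ScanRecord:
    motif: Motif
    ddG: float
    rank: int
    breakdown: EnergyBreakdown


@dataclass
class ScanTable:
    """Scan results sorted ascending by ΔΔG (ties broken lexicographically)."""

    records: list[ScanRecord]
    L: int
    params_fingerprint: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.records) != 4 ** self.L:
            raise ValueError(
                f"scan table must hold 4^{self.L} = {4 ** self.L} records, "
                f"got {len(self.records)}"
            )
        if abs(self.records[0].ddG) > 1e-12:
            raise ValueError("top record must have ddG = 0")

    @property
    def reference_motif(self) -> Motif:
        """The best-scoring motif (the ΔΔG origin)."""
        return self.records[0].motif

    def __len__(self) -> int:
        return len(self.records)

    def ddgs(self) -> np.ndarray:
        return np.array([r.ddG for r in self.records])

    def motifs(self) -> list[Motif]:
        return [r.motif for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": [r.motif for r in self.records],
                "ddG": [r.ddG for r in self.records],
                "rank": [r.rank for r in self.records],
                "clash_dna": [r.breakdown.clash_dna for r in self.records],
                "clash_protein": [r.breakdown.clash_protein for r in self.records],
                "interaction_energy": [r.breakdown.interaction_energy for r in self.records],
                "sidechain_hbond": [r.breakdown.sidechain_hbond for r in self.records],
                "total": [r.breakdown.total for r in self.records],
            }
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.6f")


def scan(
    cplx: ProteinDNAComplex,
    params: EnergyParameters = DEFAULT_PARAMETERS,
) -> ScanTable:
    """Thread and score every motif of the complex's duplex length.

    Deterministic: records are keyed by motif and sorted at the end by
    (ΔΔG, sequence), so the output is identical regardless of evaluation
    order.  Threading failures abort with the offending motif named.
    """
    L = cplx.L
    motifs = enumerate_motifs(L)
    breakdowns: dict[str, EnergyBreakdown] = {}
    for motif in motifs:
        try:
            variant = thread_sequence(cplx, motif)
            breakdowns[motif] = binding_energy(variant, params)
        except Exception as exc:  # identify the motif in scan-stage failures
            raise RuntimeError(f"scan failed at motif {motif}: {exc}") from exc

    totals = np.array([breakdowns[m].total for m in motifs])
    ddgs = ddgs_from_totals(totals)
    order = sorted(range(len(motifs)), key=lambda i: (ddgs[i], motifs[i]))
    records = [
        ScanRecord(motifs[i], float(ddgs[i]), rank, breakdowns[motifs[i]])
        for rank, i in enumerate(order, start=1)
    ]
    return ScanTable(records, L, params.fingerprint())


@dataclass
class BoundSet:
    """Threshold partition of a scan: records with ΔΔG <= threshold are bound."""

    threshold: float
    bound: list[ScanRecord]
    residual_count: int

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    @property
    def total(self) -> int:
        return len(self.bound) + self.residual_count

    def motifs(self) -> list[Motif]:
        return [r.motif for r in self.bound]

    def ddgs(self) -> np.ndarray:
        return np.array([r.ddG for r in self.bound])


def select_bound(table: ScanTable, threshold: float = 3.0) -> BoundSet:
    """Partition a scan table at an inclusive ΔΔG threshold from the top motif."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    bound = [r for r in table.records if r.ddG <= threshold]
    return BoundSet(threshold, bound, len(table) - len(bound))
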