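"""Cα trajectory statistics and distance-gated correlated-motion analysis.

Implements RMSD/RMSF with optimal (Kabsch) superposition, principal-motion
("porcupine") modes of the 3N x 3N displacement covariance, and the ICRM —
an internal coordination and rigidity matrix defined here as the absolute
normalized displacement covariance between residue pairs,

    ICRM_ij = |<d_i . d_j>| / sqrt(<|d_i|^2> <|d_j|^2>),

with entries gated to exactly 0 when the mean Cα–Cα distance exceeds a
threshold (default 30 A).  The largest eigenvalue of the gated matrix is a
one-number coordination score: it equals 1 for fully uncorrelated motion
and N for perfectly coherent motion, and increases with inter-domain
coupling.  Only relative orderings of this score across systems are
meaningful; its absolute scale depends on N and on the gating.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import DomainMap

__all__ = [
    "Trajectory",
    "CorrelationMatrix",
    "ModeProjection",
    "CoordinationScore",
    "read_trajectory",
    "write_trajectory",
    "discard_and_concatenate",
    "kabsch",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "covariance_modes",
    "icrm",
    "coordination_score",
    "domain_block_summary",
]


@dataclass
class Trajectory:
    """F x N x 3 Cα coordinates (Angstrom) with residue labels."""

    coords: np.ndarray
    labels: list[str] | None = None
    domains: DomainMap | None = None
    frame_spacing: float | None = None  # metadata only, no unit conversion

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        F, N, _ = self.coords.shape
        if F < 2:
            raise ValueError(f"need at least 2 frames, got {F}")
        if N < 2:
            raise ValueError(f"need at least 2 residues, got {N}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.labels is None:
            self.labels = [f"R{i+1}" for i in range(N)]
        elif len(self.labels) != N:
            raise ValueError("labels length must equal residue count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# I/O: multi-frame XYZ and long CSV dialects


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "xyz") -> None:
    path = Path(path)
    if format == "xyz":
        with path.open("w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_residues}\n")
                fh.write(f"frame {f}\n")
                for label, (x, y, z) in zip(traj.labels, traj.coords[f]):
                    fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")
    elif format == "csv":
        rows = []
        for f in range(traj.n_frames):
            for i, (x, y, z) in enumerate(traj.coords[f]):
                rows.append((f, traj.labels[i], x, y, z))
        pd.DataFrame(rows, columns=["frame", "residue", "x", "y", "z"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


def read_trajectory(path: str | Path, format: str = "xyz") -> Trajectory:
    """Read a multi-frame XYZ or long CSV trajectory; frames must be rectangular."""
    path = Path(path)
    if format == "xyz":
        lines = path.read_text().splitlines()
        frames: list[np.ndarray] = []
        labels: list[str] | None = None
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError:
                raise ValueError(f"line {i+1}: expected atom count") from None
            block = lines[i + 2: i + 2 + n]
            if len(block) < n:
                raise ValueError("truncated frame")
            frame_labels, xyz = [], []
            for line in block:
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"malformed coordinate line: {line!r}")
                frame_labels.append(parts[0])
                try:
                    xyz.append([float(v) for v in parts[1:]])
                except ValueError:
                    raise ValueError(f"non-numeric coordinate in line {line!r}") from None
            if labels is None:
                labels = frame_labels
            elif frame_labels != labels:
                raise ValueError("ragged frames: residue labels differ between frames")
            frames.append(np.array(xyz))
            i += 2 + n
        if not frames:
            raise ValueError("no frames found")
        return Trajectory(np.stack(frames), labels)
    if format == "csv":
        df = pd.read_csv(path)
        pivoted = []
        labels = None
        for f, grp in df.groupby("frame", sort=True):
            if labels is None:
                labels = grp["residue"].tolist()
            elif grp["residue"].tolist() != labels:
                raise ValueError("ragged frames: residue sets differ between frames")
            pivoted.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
        return Trajectory(np.stack(pivoted), labels)
    raise ValueError(f"unsupported trajectory format {format!r}")


def discard_and_concatenate(replicas: list[Trajectory], discard) -> Trajectory:
    """Drop an equilibration prefix from each replica and concatenate.

    ``discard`` is a leading frame count (int) or fraction (float < 1),
    applied per replica; replicas must share their residue count.
    """
    if not replicas:
        raise ValueError("no replicas")
    N = replicas[0].n_residues
    chunks = []
    for rep in replicas:
        if rep.n_residues != N:
            raise ValueError(
                f"residue-count mismatch: {rep.n_residues} vs {N}")
        k = int(round(discard * rep.n_frames)) if isinstance(discard, float) and discard < 1 else int(discard)
        if k < 0 or k >= rep.n_frames:
            raise ValueError(f"discard {k} not below replica length {rep.n_frames}")
        chunks.append(rep.coords[k:])
    first = replicas[0]
    return Trajectory(np.concatenate(chunks, axis=0), first.labels,
                      first.domains, first.frame_spacing)


# ---------------------------------------------------------------------------
# superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _fit_frame(frame: np.ndarray, ref: np.ndarray) -> np.ndarray:
    pc = frame - frame.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    R = kabsch(pc, rc)
    return pc @ R.T + ref.mean(axis=0)


def superpose(traj: Trajectory, reference: np.ndarray | None = None,
              iterations: int = 2) -> Trajectory:
    """Least-squares fit every frame to a reference structure.

    With ``reference=None`` the reference is the mean structure, refined
    iteratively (fit to mean, recompute mean) — stabilizes covariance for
    short trajectories.
    """
    coords = traj.coords.copy()
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        coords = np.stack([_fit_frame(f, ref) for f in coords])
    else:
        ref = coords.mean(axis=0)
        for _ in range(max(1, iterations)):
            coords = np.stack([_fit_frame(f, ref) for f in coords])
            ref = coords.mean(axis=0)
    return Trajectory(coords, traj.labels, traj.domains, traj.frame_spacing)


def rmsd_series(traj: Trajectory, reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame after optimal superposition."""
    ref = traj.coords[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fitted = _fit_frame(traj.coords[f], ref)
        out[f] = np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean())
    return out


def rmsf_profile(traj: Trajectory) -> np.ndarray:
    """Per-residue RMSF (A) about the mean structure after superposition."""
    sup = superpose(traj)
    mean = sup.coords.mean(axis=0)
    d2 = ((sup.coords - mean) ** 2).sum(axis=2)
    return np.sqrt(d2.mean(axis=0))


# ---------------------------------------------------------------------------
# covariance modes (porcupine projections)


@dataclass
class ModeProjection:
    """One principal motion: variance (A^2) and per-residue displacement vectors."""

    eigenvalue: float
    vectors: np.ndarray  # (N, 3), unit norm overall

    def __post_init__(self) -> None:
        if self.eigenvalue < -1e-9:
            raise ValueError("eigenvalue must be non-negative")
        self.eigenvalue = max(0.0, float(self.eigenvalue))


def covariance_modes(traj: Trajectory, k: int) -> list[ModeProjection]:
    """Top-k eigenpairs of the 3N x 3N displacement covariance, descending.

    The caller superposes first if rigid-body motion should be removed.
    Eigenvector sign is fixed so the largest-magnitude component is positive.
    """
    F, N, _ = traj.coords.shape
    if k > 3 * N:
        raise ValueError(f"k={k} exceeds 3N={3*N}")
    X = traj.coords.reshape(F, 3 * N)
    X = X - X.mean(axis=0)
    C = (X.T @ X) / F
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    modes = []
    for idx in order[:k]:
        v = evecs[:, idx]
        imax = np.argmax(np.abs(v))
        if v[imax] < 0:
            v = -v
        modes.append(ModeProjection(float(evals[idx]), v.reshape(N, 3)))
    return modes


def porcupine_pdb(traj: Trajectory, mode: ModeProjection, scale: float = 10.0) -> str:
    """Pseudo-atom PDB text pairing each mean Cα with its mode-displaced tip."""
    mean = traj.coords.mean(axis=0)
    tips = mean + scale * np.sqrt(max(mode.eigenvalue, 0.0)) * mode.vectors
    lines = []
    serial = 1
    for i in range(traj.n_residues):
        for pos, name in ((mean[i], "CA"), (tips[i], "TIP")):
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'GLY':>4s} A{i+1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    return "\n".join(lines) + "\nEND\n"


# ---------------------------------------------------------------------------
# ICRM


@dataclass
class CorrelationMatrix:
    """Symmetric residue-pair correlation matrix with distance gating applied."""

    values: np.ndarray
    gating_threshold: float
    gated: np.ndarray  # boolean mask of entries zeroed by the distance gate

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def icrm(traj: Trajectory, distance_threshold: float = 30.0) -> CorrelationMatrix:
    """Distance-gated absolute normalized displacement covariance.

    Entry (i, j) is |<d_i . d_j>| / sqrt(<|d_i|^2><|d_j|^2>) over frames,
    where d are mean-centered Cα displacement vectors; pairs whose *mean*
    Cα–Cα distance exceeds the threshold are set to exactly 0.  The input
    should already be superposed if rigid-body motion is to be excluded.
    Zero-variance residues yield zeroed rows with a warning.
    """
    coords = traj.coords
    disp = coords - coords.mean(axis=0)
    F, N, _ = disp.shape
    # <d_i . d_j> for all pairs: sum over frames and xyz
    cov = np.einsum("fix,fjx->ij", disp, disp) / F
    var = np.diag(cov).copy()
    dead = var < 1e-12
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance residue(s); entries zeroed")
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    values = np.abs(cov) / denom
    values[dead, :] = 0.0
    values[:, dead] = 0.0
    np.fill_diagonal(values, np.where(dead, 0.0, 1.0))

    mean_dist = cdist(coords.mean(axis=0), coords.mean(axis=0))
    gate = mean_dist > distance_threshold
    values = np.where(gate, 0.0, values)
    values = 0.5 * (values + values.T)  # exact symmetry against rounding
    values = np.clip(values, 0.0, 1.0)
    return CorrelationMatrix(values, distance_threshold, gate)


@dataclass(frozen=True)
class CoordinationScore:
    """First eigenvalue of a gated correlation matrix; higher = more coordinated."""

    first_eigenvalue: float
    system: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.first_eigenvalue):
            raise ValueError("coordination score must be finite")


def coordination_score(m: CorrelationMatrix, system: str = "") -> CoordinationScore:
    """Largest eigenvalue of the gated matrix (1 for identity, N for all-ones)."""
    evals = np.linalg.eigvalsh(m.values)
    return CoordinationScore(float(evals[-1]), system)


def domain_block_summary(m: CorrelationMatrix, domains: DomainMap) -> pd.DataFrame:
    """Mean absolute off-diagonal correlation per domain pair (and within).

    Domain ranges are 1-based residue indices into the matrix.
    """
    names = domains.names()
    idx: dict[str, np.ndarray] = {}
    for name in names:
        lo, hi = domains.ranges[name]
        if lo < 1 or hi > m.n:
            raise ValueError(f"domain {name}: indices ({lo}, {hi}) outside matrix 1..{m.n}")
        idx[name] = np.arange(lo - 1, hi)
    rows = []
    for a_i, a in enumerate(names):
        for b in names[a_i:]:
            ia, ib = idx[a], idx[b]
            block = m.values[np.ix_(ia, ib)]
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            rows.append({"domain_a": a, "domain_b": b,
                         "mean_abs_correlation": float(np.abs(vals).mean()) if vals.size else float("nan"),
                         "n_pairs": int(vals.size)})
    return pd.DataFrame(rows)
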