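"""Sequence-logo statistics for energy-ranked motif ensembles.

Converts a bound set of motifs (optionally Boltzmann-weighted by their
relative binding energies) into position frequency matrices, information
content profiles (bits), per-threshold frequency sweeps, and the positional
conditional-probability tensor P(base b at j | base a at i) used to flag
inter-position dependencies that a plain position weight matrix cannot see.

Base order is fixed A, C, G, T everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scan import BoundSet, ScanTable, select_bound
from .structure import CANONICAL_BASES

__all__ = [
    "KT_298K",
    "boltzmann_weights",
    "frequency_matrix",
    "information_profile",
    "frequency_vs_threshold",
    "conditional_probabilities",
    "tensor_to_long",
    "interaction_deviations",
    "render_logo",
]

#: kT in kcal/mol at 298 K — the default logo-weighting temperature.
KT_298K = 0.593

_BASE_INDEX = {b: i for i, b in enumerate(CANONICAL_BASES)}


def boltzmann_weights(ddgs, kT: float = KT_298K) -> np.ndarray:
    """Normalized weights w_i ∝ exp(-ΔΔG_i / kT).

    A uniform shift of all energies leaves the weights unchanged; kT -> inf
    converges to uniform weights.
    """
    if kT <= 0:
        raise ValueError("kT must be > 0")
    ddgs = np.asarray(ddgs, dtype=float)
    if ddgs.size == 0:
        raise ValueError("empty energy list")
    shifted = ddgs - ddgs.min()  # overflow guard; no effect on the result
    w = np.exp(-shifted / kT)
    return w / w.sum()


def _motif_array(motifs) -> np.ndarray:
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif list")
    L = len(motifs[0])
    arr = np.empty((len(motifs), L), dtype=np.int64)
    for i, m in enumerate(motifs):
        if len(m) != L:
            raise ValueError(f"motif length mismatch: {m!r} vs L={L}")
        for j, b in enumerate(m):
            try:
                arr[i, j] = _BASE_INDEX[b]
            except KeyError:
                raise ValueError(f"non-canonical base {b!r} in motif {m!r}") from None
    return arr


def _resolve_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights length {w.shape} does not match {n} motifs")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    return w


def frequency_matrix(motifs, weights=None) -> pd.DataFrame:
    """Position frequency matrix: rows are positions 1..L, columns A,C,G,T.

    Entry (j, b) is the summed weight of motifs carrying base b at position
    j; with ``weights=None`` all motifs count uniformly.  Every row sums to 1.
    """
    arr = _motif_array(motifs)
    w = _resolve_weights(arr.shape[0], weights)
    L = arr.shape[1]
    fm = np.zeros((L, 4))
    for j in range(L):
        np.add.at(fm[j], arr[:, j], w)
    return pd.DataFrame(fm, index=pd.RangeIndex(1, L + 1, name="position"),
                        columns=list(CANONICAL_BASES))


def information_profile(fm: pd.DataFrame) -> np.ndarray:
    """Per-position information content in bits: IC_j = 2 + Σ_b p log2 p."""
    p = np.asarray(fm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


def frequency_vs_threshold(table: ScanTable, thresholds) -> dict[float, pd.DataFrame]:
    """One uniform-weight frequency matrix per ΔΔG threshold (ascending)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    out: dict[float, pd.DataFrame] = {}
    for t in thresholds:
        bound = select_bound(table, t)
        out[t] = frequency_matrix(bound.motifs())
    return out


def conditional_probabilities(motifs, weights=None) -> np.ndarray:
    """P(base b at position j | base a at position i) as an (L,4,4L-shaped) tensor.

    Returns an array of shape (L, 4, L, 4): entry [i, a, j, b] is the
    conditional probability of base b at position j given base a at position
    i (0-based indices, base order A,C,G,T).  Slices with zero conditioning
    weight — and the diagonal i == j — are NaN ("undefined"), never 0, so
    absent conditions cannot masquerade as interactions.
    """
    arr = _motif_array(motifs)
    w = _resolve_weights(arr.shape[0], weights)
    n, L = arr.shape
    onehot = np.zeros((n, L, 4))
    rows = np.repeat(np.arange(n), L)
    cols = np.tile(np.arange(L), n)
    onehot[rows, cols, arr.ravel()] = 1.0

    marginal = np.einsum("n,nia->ia", w, onehot)            # W(a at i)
    joint = np.einsum("n,nia,njb->iajb", w, onehot, onehot)  # W(a at i ∧ b at j)

    tensor = np.full((L, 4, L, 4), np.nan)
    defined = marginal > 0
    tensor[defined, :, :] = joint[defined, :, :] / marginal[defined, None, None]
    for i in range(L):
        tensor[i, :, i, :] = np.nan
    return tensor


def tensor_to_long(tensor: np.ndarray) -> pd.DataFrame:
    """Long-format view of a conditional tensor: columns i, a, j, b, P.

    Positions are 1-based; undefined entries are omitted.
    """
    L = tensor.shape[0]
    rows = []
    for i in range(L):
        for a in range(4):
            for j in range(L):
                for b in range(4):
                    p = tensor[i, a, j, b]
                    if np.isfinite(p):
                        rows.append((i + 1, CANONICAL_BASES[a], j + 1,
                                     CANONICAL_BASES[b], p))
    return pd.DataFrame(rows, columns=["i", "a", "j", "b", "P"])


def interaction_deviations(
    motifs, weights=None, report_threshold: float = 0.1
) -> pd.DataFrame:
    """Inter-position dependencies: entries where |P(b at j | a at i) - P(b at j)|
    exceeds the report threshold, largest deviations first."""
    fm = frequency_matrix(motifs, weights).to_numpy()
    tensor = conditional_probabilities(motifs, weights)
    long = tensor_to_long(tensor)
    base_p = np.array([fm[j - 1, _BASE_INDEX[b]] for j, b in zip(long["j"], long["b"])])
    long = long.assign(P_marginal=base_p, deviation=(long["P"] - base_p).abs())
    flagged = long[long["deviation"] > report_threshold]
    return flagged.sort_values("deviation", ascending=False).reset_index(drop=True)


def render_logo(fm: pd.DataFrame, path, title: str | None = None) -> None:
    """Render an information-content logo (stacked scaled letters) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    p = np.asarray(fm, dtype=float)
    ic = information_profile(fm)
    fig, ax = plt.subplots(figsize=(max(3, 0.6 * len(p)), 2.6))
    for j in range(len(p)):
        order = np.argsort(p[j])  # smallest letters at the bottom
        y = 0.0
        for b_idx in order:
            h = p[j, b_idx] * ic[j]
            if h <= 0:
                continue
            base = CANONICAL_BASES[b_idx]
            ax.text(j + 1, y + h / 2, base, ha="center", va="center",
                    fontsize=24, fontweight="bold", color=colors[base],
                    fontstretch="expanded", clip_on=True,
                    transform=ax.transData,
                    bbox=None, zorder=3,
                    )
            ax.bar(j + 1, h, bottom=y, width=0.9, color=colors[base], alpha=0.15)
            y += h
    ax.set_xlim(0.4, len(p) + 0.6)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(range(1, len(p) + 1))
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
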