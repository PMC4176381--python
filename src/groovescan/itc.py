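"""One-site isothermal titration calorimetry: simulation, fitting, identities.

The forward model is the standard single-site (Wiseman) isotherm for a
perfusion-type cell: each injection displaces cell volume, diluting both the
macromolecule M in the cell and the previously injected ligand X, the bound
concentration follows from the binding quadratic with site concentration
n·[M], and the measured per-injection heat is the increment of cumulative
heat after accounting for the displaced (already-reacted) volume.

Fitted parameters are (n, K, ΔH).  The remaining thermodynamic quantities
follow from exact identities and are populated by construction:

    ΔG° = -R T ln K,   -TΔS° = ΔG° - ΔH°,   Kd [μM] = 10^6 / K [M^-1]

with R = 1.987e-3 kcal mol^-1 K^-1.  Heats are expressed in μcal
externally; energies in kcal/mol internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "R_KCAL",
    "TitrationProtocol",
    "Thermogram",
    "BindingFit",
    "NoBinding",
    "predict_heats",
    "fit_one_site",
    "thermo_derive",
    "write_thermogram",
    "read_thermogram",
    "fits_to_table",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

_KCAL_TO_UCAL = 1e9


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol: cell volume/concentrations in SI (L, mol/L), K.

    Defaults reflect a typical VP-ITC style experiment: 1.4 mL cell with
    10 μM macromolecule, 100 μM ligand in the syringe, twenty 14 μl
    injections, 10 °C.
    """

    cell_volume: float = 1.4e-3
    cell_concentration: float = 10e-6
    syringe_concentration: float = 100e-6
    injection_volumes: tuple[float, ...] = (14e-6,) * 20
    temperature: float = 283.15

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_concentration,
               self.syringe_concentration, self.temperature) <= 0:
            raise ValueError("protocol quantities must be positive")
        if len(self.injection_volumes) < 1:
            raise ValueError("at least one injection required")
        if min(self.injection_volumes) <= 0:
            raise ValueError("injection volumes must be positive")


@dataclass
class Thermogram:
    """Per-injection heats (μcal) under a protocol."""

    protocol: TitrationProtocol
    heats: np.ndarray

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (len(self.protocol.injection_volumes),):
            raise ValueError("heats length must equal the number of injections")


def _bound_concentration(m_tot: float, x_tot: float, n: float, K: float) -> float:
    """[MX] from the binding quadratic with site concentration n*m_tot.

    Uses the numerically stable smaller root of
    K x^2 - K (n m + x + 1/K) x + K n m x = 0.
    """
    s = n * m_tot
    b = s + x_tot + 1.0 / K
    disc = b * b - 4.0 * s * x_tot
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def predict_heats(protocol: TitrationProtocol, n: float, K: float, dH: float) -> Thermogram:
    """Noiseless one-site thermogram (μcal per injection).

    Perfusion dilution: injection i of volume v multiplies existing cell
    contents by (1 - v/V0) and adds ligand at the syringe concentration; the
    per-injection heat is Q_i - (1 - v/V0) Q_{i-1} where Q is the cumulative
    heat of complex in the cell.
    """
    if n <= 0 or K <= 0:
        raise ValueError("n and K must be positive")
    V0 = protocol.cell_volume
    m = protocol.cell_concentration
    x = 0.0
    q_prev = 0.0
    heats = np.empty(len(protocol.injection_volumes))
    for i, v in enumerate(protocol.injection_volumes):
        f = v / V0
        m *= 1.0 - f
        x = x * (1.0 - f) + protocol.syringe_concentration * f
        mx = _bound_concentration(m, x, n, K)
        q = dH * V0 * mx  # kcal
        heats[i] = (q - (1.0 - f) * q_prev) * _KCAL_TO_UCAL
        q_prev = q
    return Thermogram(protocol, heats)


def thermo_derive(K: float, dH: float, T: float) -> tuple[float, float, float]:
    """(ΔG°, -TΔS°, Kd in μM) from K [M^-1], ΔH° [kcal/mol], T [K]."""
    if K <= 0:
        raise ValueError("K must be > 0")
    if T <= 0:
        raise ValueError("T must be > 0")
    dG = -R_KCAL * T * np.log(K)
    return float(dG), float(dG - dH), float(1e6 / K)


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site parameters with exact derived thermodynamics."""

    n: float
    K: float
    dH: float
    Kd: float
    dG: float
    TdS_neg: float
    temperature: float
    residual_norm: float
    converged: bool

    @classmethod
    def from_parameters(
        cls, n: float, K: float, dH: float, temperature: float,
        residual_norm: float = 0.0, converged: bool = True,
    ) -> "BindingFit":
        dG, tds_neg, kd = thermo_derive(K, dH, temperature)
        return cls(n, K, dH, kd, dG, tds_neg, temperature, residual_norm, converged)


@dataclass(frozen=True)
class NoBinding:
    """Explicit no-fit outcome (no binding detected / non-convergent fit)."""

    reason: str
    residual_norm: float = float("nan")


def _model_heats(protocol: TitrationProtocol, params: np.ndarray) -> np.ndarray:
    n, log10K, dH = params
    return predict_heats(protocol, n, 10.0 ** log10K, dH).heats


def fit_one_site(thermogram: Thermogram) -> BindingFit | NoBinding:
    """Least-squares fit of (n, K, ΔH) to an integrated thermogram.

    Initialization: n0 = 1, ΔH0 from the first-injection heat assuming full
    binding, and a small multi-start over log10 K in 4..8 (bounds 2..12);
    the lowest-cost solution wins.  Degenerate thermograms (no measurable
    signal) and non-convergent fits return :class:`NoBinding` rather than
    silent numbers.
    """
    heats = thermogram.heats
    protocol = thermogram.protocol
    if len(heats) < 5:
        return NoBinding("fewer than 5 injections")
    scale = float(np.max(np.abs(heats)))
    if scale < 1e-6:
        return NoBinding("no measurable heat signal")

    v1 = protocol.injection_volumes[0]
    moles1 = protocol.syringe_concentration * v1
    dH0 = float(heats[0]) / _KCAL_TO_UCAL / moles1  # kcal/mol if first shot binds fully
    if abs(dH0) < 1e-3:
        dH0 = np.sign(dH0) or 1.0

    best = None
    for log10K0 in (4.0, 5.0, 6.0, 7.0, 8.0):
        try:
            res = least_squares(
                lambda p: _model_heats(protocol, p) - heats,
                x0=np.array([1.0, log10K0, dH0]),
                bounds=(np.array([0.05, 2.0, -200.0]), np.array([20.0, 12.0, 200.0])),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return NoBinding("optimizer failed to converge", residual_norm=float("nan"))

    residual_norm = float(np.linalg.norm(best.fun))
    # a "fit" that explains less than half of the signal is no fit at all
    if residual_norm > 0.5 * float(np.linalg.norm(heats)):
        return NoBinding("fit does not describe the data", residual_norm=residual_norm)
    n, log10K, dH = best.x
    return BindingFit.from_parameters(
        float(n), float(10.0 ** log10K), float(dH), protocol.temperature,
        residual_norm=residual_norm, converged=True,
    )


# ---------------------------------------------------------------------------
# text I/O


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    """Two-column TSV (injection index, heat μcal) with a protocol header."""
    p = tg.protocol
    lines = [
        f"# cell_volume_L\t{p.cell_volume:.6e}",
        f"# cell_concentration_M\t{p.cell_concentration:.6e}",
        f"# syringe_concentration_M\t{p.syringe_concentration:.6e}",
        f"# temperature_K\t{p.temperature:.4f}",
        "# injection_volumes_L\t" + ",".join(f"{v:.6e}" for v in p.injection_volumes),
        "injection\theat_ucal",
    ]
    for i, q in enumerate(tg.heats, start=1):
        lines.append(f"{i}\t{q:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_thermogram(path: str | Path) -> Thermogram:
    text = Path(path).read_text()
    header: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            header[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    protocol = TitrationProtocol(
        cell_volume=float(header["cell_volume_L"]),
        cell_concentration=float(header["cell_concentration_M"]),
        syringe_concentration=float(header["syringe_concentration_M"]),
        injection_volumes=tuple(
            float(v) for v in header["injection_volumes_L"].split(",")
        ),
        temperature=float(header["temperature_K"]),
    )
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    return Thermogram(protocol, df["heat_ucal"].to_numpy())


def fits_to_table(fits: dict[str, BindingFit | NoBinding]) -> pd.DataFrame:
    """Calorimetric report: one row per ligand, NBD rows flagged explicitly."""
    rows = []
    for label, fit in fits.items():
        if isinstance(fit, NoBinding):
            rows.append({"ligand": label, "K_Minv": "NBD", "Kd_uM": "NBD",
                         "dG_kcal_mol": "NBD", "dH_kcal_mol": "NBD",
                         "TdS_neg_kcal_mol": "NBD", "n": "NBD"})
        else:
            rows.append({
                "ligand": label,
                "K_Minv": f"{fit.K:.3e}",
                "Kd_uM": f"{fit.Kd:.3f}",
                "dG_kcal_mol": f"{fit.dG:.2f}",
                "dH_kcal_mol": f"{fit.dH:.2f}",
                "TdS_neg_kcal_mol": f"{fit.TdS_neg:.2f}",
                "n": f"{fit.n:.3f}",
            })
    return pd.DataFrame(rows)
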