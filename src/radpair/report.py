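"""Headline tables and figure-data generation.

:func:`run_table1` assembles the six summary quantities — the extremised
ELF and geomagnetic yield changes, their ratio Ω, and the three
temperature effects — for both bundled radical pairs under the reference
conditions (r = 1e6 s⁻¹, B0 = 50 μT, B1 = 1 μT, ΔB0 = −1 μT,
Δk = Δr = 1e3 s⁻¹).

:func:`run_figure_data` regenerates the sweep curves behind the
static-field and lifetime figures as CSV files with '#' metadata headers
plus a JSON sidecar.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .field_response import (
    FieldProtocol,
    SweepResult,
    lifetime_extremum,
    mfe_elf_quadrature,
    mfe_elf_taylor,
    mfe_gmf,
    phi_vs_field,
)
from .perturbations import RatePerturbation, temperature_effect
from .spin_core import ReactionKinetics, SpectralCache
from .systems import load_preset

__all__ = ["RunConfig", "run_table1", "run_figure_data", "round_sig"]

log = logging.getLogger(__name__)

FIGURE_IDS = ("fig2", "fig2s1", "fig4", "fig4s1", "fig4s2", "fig4s3")

#: Default lifetimes for the static-field sweep figure.
FIG2_TAUS = (30e-9, 100e-9, 300e-9, 1e-6, 3e-6, 10e-6, 100e-6)


@dataclass(frozen=True)
class RunConfig:
    """Reference run conditions for the summary table and figures."""

    r: float = 1e6
    B0_uT: float = 50.0
    B1_uT: float = 1.0
    dB0_uT: float = -1.0
    dk: float = 1e3
    dr: float = 1e3
    k: float = 1e6
    tau_range: tuple[float, float] = (1e-9, 1e-3)
    systems: tuple[str, ...] = ("FAD-TrpH", "FAD-Z")
    points_per_decade: int = 25
    field_grid_points: int = 121
    lifetime_grid_points: int = 61

    @property
    def protocol(self) -> FieldProtocol:
        return FieldProtocol(self.B0_uT, self.B1_uT, self.dB0_uT)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (printed-table precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def run_table1(config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Summary table of yield changes (ppm; Ω dimensionless).

    Rows: mfeELFmax, mfeGMFmax, Ω, and the three temperature effects.
    Raw values are in the ``<system>`` columns; ``<system>_2sf`` columns
    carry the 2-significant-figure printed form.
    """
    proto = config.protocol
    rows = {
        "mfeELFmax_ppm": {},
        "mfeGMFmax_ppm": {},
        "Omega": {},
        "Te_dk_ppm": {},
        "Te_dr_ppm": {},
        "Te_dk_dr_ppm": {},
    }
    for name in config.systems:
        system = load_preset(name)
        cache = SpectralCache()
        log.info(
            "table run: system=%s r=%.3g B0=%.3g B1=%.3g dB0=%.3g",
            name, config.r, config.B0_uT, config.B1_uT, config.dB0_uT,
        )
        _, elf = lifetime_extremum(
            system, config.r, proto, "elf", config.tau_range,
            points_per_decade=config.points_per_decade, cache=cache,
        )
        _, gmf = lifetime_extremum(
            system, config.r, proto, "gmf", config.tau_range,
            points_per_decade=config.points_per_decade, cache=cache,
        )
        kin = ReactionKinetics(k=config.k, r=config.r)
        te_k = temperature_effect(
            system, kin, RatePerturbation(dk=config.dk), config.B0_uT, cache=cache
        )
        te_r = temperature_effect(
            system, kin, RatePerturbation(dr=config.dr), config.B0_uT, cache=cache
        )
        te_kr = temperature_effect(
            system, kin, RatePerturbation(dk=config.dk, dr=config.dr),
            config.B0_uT, cache=cache,
        )
        rows["mfeELFmax_ppm"][name] = elf.ppm
        rows["mfeGMFmax_ppm"][name] = gmf.ppm
        rows["Omega"][name] = gmf.value / elf.value
        rows["Te_dk_ppm"][name] = te_k * 1e6
        rows["Te_dr_ppm"][name] = te_r * 1e6
        rows["Te_dk_dr_ppm"][name] = te_kr * 1e6

    df = pd.DataFrame(rows).T
    for name in config.systems:
        df[f"{name}_2sf"] = df[name].map(round_sig)
    return df


def _write(sweep: SweepResult, out_dir: Path, stem: str) -> None:
    sweep.to_csv(out_dir / f"{stem}.csv")
    sweep.to_json(out_dir / f"{stem}.json")


def _lifetime_sweep(
    system_name: str,
    mode: str,
    r: float,
    proto: FieldProtocol,
    config: RunConfig,
    method: str = "taylor",
) -> SweepResult:
    system = load_preset(system_name)
    cache = SpectralCache()
    taus = np.logspace(
        math.log10(config.tau_range[0]),
        math.log10(config.tau_range[1]),
        config.lifetime_grid_points,
    )
    vals = []
    for tau in taus:
        kin = ReactionKinetics.from_lifetime(tau, r)
        if mode == "elf":
            if method == "quadrature":
                res = mfe_elf_quadrature(system, kin, proto, cache=cache)
            else:
                res = mfe_elf_taylor(system, kin, proto, cache=cache)
        else:
            res = mfe_gmf(system, kin, proto, method="linear", cache=cache)
        vals.append(res.ppm)
    return SweepResult(
        axis_name="tau_s",
        axis_values=taus,
        values=np.array(vals),
        metadata={
            "system": system_name,
            "quantity": f"mfe_{mode}_ppm",
            "method": method,
            "r_per_s": r,
            "B0_uT": proto.B0_uT,
            "B1_uT": proto.B1_uT,
            "dB0_uT": proto.dB0_uT,
        },
    )


def run_figure_data(figure_id: str, config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write the CSV/JSON sweep data behind one figure; returns the paths.

    ``fig2``/``fig2s1``: ΦT vs B0 (0–5 mT) for a ladder of lifetimes at
    relaxation times 1 μs / 0.1 μs.  ``fig4``: mfeELF and mfeGMF vs τ for
    both presets.  ``fig4s1``: Taylor vs quadrature ELF curves.
    ``fig4s2``: the r = 1e7 s⁻¹ variant (sign flip).  ``fig4s3``: B0 ∈
    {25, 50, 65} μT variants.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(
            f"unknown figure id {figure_id!r}; expected one of {FIGURE_IDS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    proto = config.protocol

    def emit(sweep: SweepResult, stem: str) -> None:
        _write(sweep, out, stem)
        written.extend([out / f"{stem}.csv", out / f"{stem}.json"])

    if figure_id in ("fig2", "fig2s1"):
        r = config.r if figure_id == "fig2" else 1e7
        grid = np.linspace(0.0, 5000.0, config.field_grid_points)
        system = load_preset("FAD-TrpH")
        for tau in FIG2_TAUS:
            kin = ReactionKinetics.from_lifetime(tau, r)
            sweep = phi_vs_field(system, kin, grid)
            sweep.metadata["tau_s"] = tau
            emit(sweep, f"{figure_id}_phi_vs_B0_tau{tau:.0e}")
    elif figure_id == "fig4":
        for name in config.systems:
            for mode in ("elf", "gmf"):
                emit(
                    _lifetime_sweep(name, mode, config.r, proto, config),
                    f"fig4_mfe_{mode}_{name.lower()}",
                )
    elif figure_id == "fig4s1":
        for name in config.systems:
            for method in ("taylor", "quadrature"):
                emit(
                    _lifetime_sweep(name, "elf", config.r, proto, config, method),
                    f"fig4s1_mfe_elf_{method}_{name.lower()}",
                )
    elif figure_id == "fig4s2":
        for name in config.systems:
            for mode in ("elf", "gmf"):
                emit(
                    _lifetime_sweep(name, mode, 1e7, proto, config),
                    f"fig4s2_mfe_{mode}_{name.lower()}",
                )
    elif figure_id == "fig4s3":
        for b0 in (25.0, 50.0, 65.0):
            p = FieldProtocol(b0, config.B1_uT, config.dB0_uT)
            for mode in ("elf", "gmf"):
                emit(
                    _lifetime_sweep("FAD-TrpH", mode, config.r, p, config),
                    f"fig4s3_mfe_{mode}_B0_{b0:.0f}uT",
                )
    return written
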