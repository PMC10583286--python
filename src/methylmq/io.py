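"""Tabular and grid file formats, configuration and provenance helpers.

All tabular I/O is comma-separated with a mandatory header; units are
fixed by the column names (field_MHz, ppm, s⁻¹, ns). Spectrum grids are
plain-text matrices with ppm axes in comment headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import CONSTANTS, Constants, FieldSpec, parse_coherence
from .exchange import CPMGDataset, CPMGExperiment
from .he_analysis import DecayCurve, RateMeasurement
from .rates import MethylSystem

__all__ = [
    "read_rates", "write_rates", "read_decays", "write_decays",
    "read_cpmg", "write_cpmg", "read_clusters", "write_clusters",
    "read_csa_table", "write_csa_table", "read_grid", "write_grid",
    "load_config", "constants_from_config", "file_checksum",
]

_REQUIRED = {
    "rates": ["methyl_id", "coherence", "field_MHz", "rate", "err"],
    "decays": ["methyl_id", "coherence", "field_MHz", "sigma", "time_s",
               "amplitude"],
    "cpmg": ["methyl_id", "experiment", "field_MHz", "t_relax_s",
             "nu_cpmg_Hz", "Reff", "err"],
    "clusters": ["methyl_id", "cluster_id"],
    "csa": ["methyl_id", "dSigmaC_ppm", "dSigmaH_ppm", "s2tau_ns"],
}


def _read_table(path: Path | str, kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; header must "
            f"contain {_REQUIRED[kind]}")
    bad = df[df[_REQUIRED[kind]].isna().any(axis=1)]
    if len(bad):
        lineno = int(bad.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: line {lineno}: missing value")
    return df


def read_rates(path: Path | str) -> list[RateMeasurement]:
    df = _read_table(path, "rates")
    return [RateMeasurement(
        methyl_id=str(r.methyl_id), coherence=parse_coherence(r.coherence),
        fieldspec=FieldSpec(float(r.field_MHz)), rate=float(r.rate),
        err=float(r.err)) for r in df.itertuples()]


def write_rates(path: Path | str, rates: list[RateMeasurement]) -> None:
    pd.DataFrame([{
        "methyl_id": m.methyl_id, "coherence": m.coherence.name,
        "field_MHz": m.fieldspec.larmor_h, "rate": m.rate, "err": m.err}
        for m in rates]).to_csv(path, index=False)


def write_decays(path: Path | str, curves: list[DecayCurve]) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.amplitudes):
            rows.append({"methyl_id": c.methyl_id,
                         "coherence": c.coherence.name,
                         "field_MHz": c.fieldspec.larmor_h,
                         "sigma": c.sigma, "time_s": t, "amplitude": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decays(path: Path | str) -> list[DecayCurve]:
    df = _read_table(path, "decays")
    curves = []
    for (mid, coh, f, sig), grp in df.groupby(
            ["methyl_id", "coherence", "field_MHz", "sigma"], sort=False):
        grp = grp.sort_values("time_s")
        curves.append(DecayCurve(
            times=grp.time_s.to_numpy(), amplitudes=grp.amplitude.to_numpy(),
            sigma=float(sig), coherence=parse_coherence(coh),
            fieldspec=FieldSpec(float(f)), methyl_id=str(mid)))
    return curves


def write_cpmg(path: Path | str, datasets: list[CPMGDataset]) -> None:
    rows = []
    for ds in datasets:
        exp = ds.experiment
        for nu, r, e in zip(exp.nu_cpmg, ds.reff, ds.err):
            rows.append({"methyl_id": ds.methyl_id, "experiment": exp.kind,
                         "field_MHz": exp.fieldspec.larmor_h,
                         "t_relax_s": exp.t_relax, "nu_cpmg_Hz": nu,
                         "Reff": r, "err": e})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cpmg(path: Path | str) -> list[CPMGDataset]:
    df = _read_table(path, "cpmg")
    datasets = []
    for (mid, kind, f, t), grp in df.groupby(
            ["methyl_id", "experiment", "field_MHz", "t_relax_s"],
            sort=False):
        grp = grp.sort_values("nu_cpmg_Hz")
        exp = CPMGExperiment(kind=str(kind), t_relax=float(t),
                             nu_cpmg=tuple(grp.nu_cpmg_Hz),
                             fieldspec=FieldSpec(float(f)))
        datasets.append(CPMGDataset(methyl_id=str(mid), experiment=exp,
                                    reff=tuple(grp.Reff),
                                    err=tuple(grp.err)))
    return datasets


def write_clusters(path: Path | str, assignment: dict[str, str]) -> None:
    pd.DataFrame([{"methyl_id": m, "cluster_id": c}
                  for m, c in assignment.items()]).to_csv(path, index=False)


def read_clusters(path: Path | str) -> dict[str, str]:
    df = _read_table(path, "clusters")
    return {str(r.methyl_id): str(r.cluster_id) for r in df.itertuples()}


def write_csa_table(path: Path | str,
                    systems: dict[str, MethylSystem]) -> None:
    pd.DataFrame([{
        "methyl_id": mid, "dSigmaC_ppm": s.dsigma_c,
        "dSigmaH_ppm": s.dsigma_h, "s2tau_ns": s.s2tau * 1e9}
        for mid, s in systems.items()]).to_csv(path, index=False)


def read_csa_table(path: Path | str) -> dict[str, MethylSystem]:
    df = _read_table(path, "csa")
    return {str(r.methyl_id): MethylSystem(
        s2tau=float(r.s2tau_ns) * 1e-9, dsigma_c=float(r.dSigmaC_ppm),
        dsigma_h=float(r.dSigmaH_ppm)) for r in df.itertuples()}


def write_grid(path: Path | str, grid: np.ndarray, wh_ppm: np.ndarray,
               wc_ppm: np.ndarray, t_relax: float) -> None:
    """Plain-text 2D spectrum: ppm axes in '#' headers, C rows × H cols."""
    with open(path, "w") as fh:
        fh.write(f"# t_relax_s: {t_relax!r}\n")
        fh.write("# wH_ppm: " + " ".join(repr(float(x)) for x in wh_ppm)
                 + "\n")
        fh.write("# wC_ppm: " + " ".join(repr(float(x)) for x in wc_ppm)
                 + "\n")
        np.savetxt(fh, grid)


def read_grid(path: Path | str
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    t_relax, wh, wc = None, None, None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line[1:].partition(":")
        key = key.strip()
        if key == "t_relax_s":
            t_relax = float(val)
        elif key == "wH_ppm":
            wh = np.array([float(x) for x in val.split()])
        elif key == "wC_ppm":
            wc = np.array([float(x) for x in val.split()])
    if t_relax is None or wh is None or wc is None:
        raise ValueError(f"{path}: missing grid headers "
                         "(t_relax_s, wH_ppm, wC_ppm)")
    grid = np.loadtxt(lines[body_start:])
    if grid.shape != (wc.size, wh.size):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match "
                         f"axes ({wc.size}, {wh.size})")
    return grid, wh, wc, t_relax


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def constants_from_config(cfg: dict) -> Constants:
    overrides = cfg.get("constants", {})
    unknown = set(overrides) - set(Constants.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown constants overrides: {sorted(unknown)}")
    return CONSTANTS.with_overrides(**{k: float(v)
                                       for k, v in overrides.items()})


def file_checksum(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
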