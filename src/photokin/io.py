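"""Plain-text and HDF5 serialization of the pipeline's objects.

Surfaces travel as long-format delimited text (time_s, wavelength_nm,
delta_A) or a single HDF5 container for large grids; spectra as two-column
text; pH traces as two-column text with a YAML sidecar holding the
condition metadata; fit reports as JSON plus a delimited DAS table.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .assay import PHTrace
from .globalfit import GlobalFitResult
from .kinetics import TransientSurface
from .spectra import Spectrum

__all__ = [
    "write_surface_csv",
    "read_surface_csv",
    "write_surface_hdf5",
    "read_surface_hdf5",
    "write_spectrum",
    "read_spectrum",
    "write_ph_trace",
    "read_ph_trace",
    "write_fit_report",
    "write_scenario",
]


def write_surface_csv(surface: TransientSurface, path: str | Path) -> None:
    t, wl = np.meshgrid(surface.times, surface.wavelengths, indexing="ij")
    pd.DataFrame(
        {"time_s": t.ravel(), "wavelength_nm": wl.ravel(), "delta_A": surface.delta_a.ravel()}
    ).to_csv(path, sep="\t", index=False)


def read_surface_csv(path: str | Path) -> TransientSurface:
    df = pd.read_csv(path, sep="\t")
    times = np.unique(df["time_s"].to_numpy())
    wl = np.unique(df["wavelength_nm"].to_numpy())
    da = (
        df.pivot(index="time_s", columns="wavelength_nm", values="delta_A")
        .loc[times, wl]
        .to_numpy()
    )
    return TransientSurface(times=times, wavelengths=wl, delta_a=da)


def write_surface_hdf5(surface: TransientSurface, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=surface.times)
        f.create_dataset("wavelength_nm", data=surface.wavelengths)
        f.create_dataset("delta_A", data=surface.delta_a)
        if surface.noise_sd is not None:
            f.attrs["noise_sd"] = surface.noise_sd
        if surface.seed is not None:
            f.attrs["seed"] = surface.seed


def read_surface_hdf5(path: str | Path) -> TransientSurface:
    with h5py.File(path, "r") as f:
        return TransientSurface(
            times=f["time_s"][:],
            wavelengths=f["wavelength_nm"][:],
            delta_a=f["delta_A"][:],
            noise_sd=float(f.attrs["noise_sd"]) if "noise_sd" in f.attrs else None,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(), label=label)


def write_ph_trace(trace: PHTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "pH": trace.ph}).to_csv(path, sep="\t", index=False)
    meta = {
        "salt": trace.salt,
        "cccp": bool(trace.cccp),
        "light_on": float(trace.light_on),
        "light_off": float(trace.light_off),
        "sample": trace.sample,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_ph_trace(path: str | Path) -> PHTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    return PHTrace(
        times=df["time_s"].to_numpy(),
        ph=df["pH"].to_numpy(),
        light_on=meta["light_on"],
        light_off=meta["light_off"],
        salt=meta["salt"],
        cccp=meta["cccp"],
        sample=meta["sample"],
    )


def write_fit_report(fit: GlobalFitResult, json_path: str | Path, das_path: str | Path) -> None:
    """JSON summary (time constants, RSS, metadata) plus a DAS table."""
    report = {
        "time_constants_s": fit.taus.tolist(),
        "rss": fit.rss,
        "has_offset": fit.offset is not None,
        "meta": {k: v for k, v in fit.meta.items() if isinstance(v, (int, float, str, list))},
    }
    Path(json_path).write_text(json.dumps(report, indent=2))
    fit.to_frame().to_csv(das_path, sep="\t")


def write_scenario(cfg, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic scenario directory from one config.

    Produces the transient surface, dark-adaptation trace, dark/light
    absorption spectra, both chromatograms, the wildtype assay panel and a
    YAML record of the generating configuration.  Returns the path map.
    """
    from dataclasses import asdict

    from . import synth

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    surface = synth.make_transient_dataset(cfg)
    paths["surface"] = outdir / "transient_surface.tsv"
    write_surface_csv(surface, paths["surface"])

    t, a = synth.make_dark_adaptation_trace(cfg)
    paths["dark_adaptation"] = outdir / "dark_adaptation_585nm.tsv"
    pd.DataFrame({"time_s": t, "absorbance": a}).to_csv(
        paths["dark_adaptation"], sep="\t", index=False
    )

    s_dark, s_light = synth.make_absorption_pair(cfg)
    paths["spectrum_dark"] = outdir / "absorption_dark.tsv"
    paths["spectrum_light"] = outdir / "absorption_light.tsv"
    write_spectrum(s_dark, paths["spectrum_dark"])
    write_spectrum(s_light, paths["spectrum_light"])

    for condition in ("dark", "light"):
        chrom = synth.make_chromatogram(cfg, condition)
        key = f"chromatogram_{condition}"
        paths[key] = outdir / f"hplc_{condition}.tsv"
        pd.DataFrame({"time_min": chrom.times, "signal": chrom.signal}).to_csv(
            paths[key], sep="\t", index=False
        )

    panel = synth.make_assay_panel(cfg, "WT")
    for tr in panel.traces:
        key = f"ph_{tr.salt}_{'cccp' if tr.cccp else 'nocccp'}"
        paths[key] = outdir / f"{key}.tsv"
        write_ph_trace(tr, paths[key])
    paths["pigment"] = outdir / "pigment.tsv"
    paths["bleached"] = outdir / "bleached.tsv"
    write_spectrum(panel.pigment_spectrum, paths["pigment"])
    write_spectrum(panel.bleached_spectrum, paths["bleached"])

    cfg_dict = asdict(cfg)
    cfg_dict["time_constants"] = list(cfg_dict["time_constants"])
    paths["config"] = outdir / "scenario.yaml"
    paths["config"].write_text(yaml.safe_dump({"schema_version": 1, "config": cfg_dict}))
    return paths
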