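"""File-format adapters: scene YAML, 2-channel float TIFF with spacing
metadata, HDF5 A-line ensembles, and CSV instrument traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    AlineEnsemble,
    DualWavelengthImage,
    FluoroTrace,
    PhantomScene,
    RespiroTrace,
    VesselSpec,
)


# -- scenes ----------------------------------------------------------------

def scene_to_dict(scene: PhantomScene) -> dict:
    return dict(
        field_size_um=list(scene.field_size_um),
        pixel_spacing_um=list(scene.pixel_spacing_um),
        noise_snr_db=scene.noise_snr_db,
        psf_fwhm_um=scene.psf_fwhm_um,
        seed=scene.seed,
        vessels=[dict(
            id=v.id, centerline_um=v.centerline_um.tolist(),
            diameter_um=v.diameter_um, peak_speed_mm_s=v.peak_speed_mm_s,
            so2=v.so2, vessel_class=v.vessel_class, region=v.region,
            chb_g_per_L=v.chb_g_per_L) for v in scene.vessels],
    )


def scene_from_dict(d: dict) -> PhantomScene:
    vessels = [VesselSpec(
        id=v["id"], centerline_um=np.asarray(v["centerline_um"]),
        diameter_um=v["diameter_um"], peak_speed_mm_s=v["peak_speed_mm_s"],
        so2=v["so2"], vessel_class=v["vessel_class"], region=v["region"],
        chb_g_per_L=v["chb_g_per_L"]) for v in d["vessels"]]
    return PhantomScene(
        field_size_um=tuple(d["field_size_um"]),
        pixel_spacing_um=tuple(d["pixel_spacing_um"]),
        vessels=vessels, noise_snr_db=d.get("noise_snr_db"),
        psf_fwhm_um=d.get("psf_fwhm_um", 0.0), seed=d.get("seed", 0))


def write_scene(scene: PhantomScene, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scene_to_dict(scene), sort_keys=False))


def read_scene(path: str | Path) -> PhantomScene:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))


# -- images ----------------------------------------------------------------

def write_dual_tiff(img: DualWavelengthImage, path: str | Path) -> None:
    """2-channel 32-bit TIFF; spacing and wavelengths in the description."""
    stack = np.stack([img.a532, img.a558]).astype(np.float32)
    meta = json.dumps(dict(pixel_spacing_um=list(img.pixel_spacing_um),
                           wavelengths_nm=[532, 558]))
    tifffile.imwrite(str(path), stack, description=meta)


def read_dual_tiff(path: str | Path) -> DualWavelengthImage:
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return DualWavelengthImage(a532=stack[0], a558=stack[1],
                               pixel_spacing_um=tuple(meta["pixel_spacing_um"]))


# -- A-line ensembles ------------------------------------------------------

def write_ensemble(e: AlineEnsemble, path: str | Path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("lines", data=e.lines)
        f.attrs["dt_s"] = e.dt_s


def read_ensemble(path: str | Path) -> AlineEnsemble:
    with h5py.File(str(path), "r") as f:
        return AlineEnsemble(lines=f["lines"][()], dt_s=float(f.attrs["dt_s"]))


# -- traces ----------------------------------------------------------------

def _trace_frame(time_s, values, events) -> pd.DataFrame:
    df = pd.DataFrame({"time_s": time_s, "value": values, "event": ""})
    t = np.asarray(time_s)
    for et, label in events:
        idx = int(np.argmin(np.abs(t - et)))
        df.loc[idx, "event"] = label
    return df


def write_respiro_csv(trace: RespiroTrace, path: str | Path) -> None:
    df = _trace_frame(trace.time_s, trace.o2_nmol_per_ml, trace.events)
    df.attrs = {}
    header = f"# protein_mg={trace.protein_mg} chamber_ml={trace.chamber_ml}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_respiro_csv(path: str | Path) -> RespiroTrace:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    kv = dict(tok.split("=") for tok in header.lstrip("# ").split())
    events = [(float(r.time_s), str(r.event)) for r in df.itertuples()
              if isinstance(r.event, str) and r.event]
    return RespiroTrace(time_s=df["time_s"].to_numpy(),
                        o2_nmol_per_ml=df["value"].to_numpy(),
                        events=events, protein_mg=float(kv["protein_mg"]),
                        chamber_ml=float(kv["chamber_ml"]))


def write_fluoro_csv(trace: FluoroTrace, path: str | Path) -> None:
    df = _trace_frame(trace.time_s, trace.fluorescence_au, trace.events)
    with open(path, "w") as fh:
        fh.write(f"# kind={trace.kind}\n")
        df.to_csv(fh, index=False)


def read_fluoro_csv(path: str | Path) -> FluoroTrace:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    kv = dict(tok.split("=") for tok in header.lstrip("# ").split())
    events = [(float(r.time_s), str(r.event)) for r in df.itertuples()
              if isinstance(r.event, str) and r.event]
    return FluoroTrace(kind=kv["kind"], time_s=df["time_s"].to_numpy(),
                       fluorescence_au=df["value"].to_numpy(), events=events)


def vessels_to_csv(measures, path: str | Path) -> None:
    rows = [dict(id=m.id, region=m.region, vessel_class=m.vessel_class,
                 diameter_um=m.diameter_um, peak_speed_mm_s=m.peak_speed_mm_s,
                 so2=m.so2, chb_g_per_L=m.chb_g_per_L) for m in measures]
    pd.DataFrame(rows).to_csv(path, index=False)


def regions_to_json(regions: dict, path: str | Path) -> None:
    out = {name: dict(
        region=r.region, cbf_ml_100g_min=r.cbf_ml_100g_min, oef=r.oef,
        cmro2_ml_100g_min=r.cmro2_ml_100g_min, sa_o2=r.sa_o2, sv_o2=r.sv_o2,
        chb_g_per_L=r.chb_g_per_L, n_arteries=r.n_arteries, n_veins=r.n_veins,
        flags=list(r.flags)) for name, r in regions.items()}
    Path(path).write_text(json.dumps(out, indent=2))
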