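"""File I/O for the pipeline's typed objects.

Conventions recorded in sidecars: degrees of visual angle, x right-positive /
y up-positive, half-open eccentricity bands with a closed final band.
Volumes use NIfTI, streamlines TCK (TRK import supported), tables TSV,
configuration YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bands import BandProportions, EccBands
from .connectivity import Connectome, EndpointRecord
from .prf_fit import FitResult
from .prf_model import PRFParams
from .stimulus import ApertureSequence
from .synthetic import EccSurface

__all__ = ["save_aperture_nifti", "load_aperture_nifti",
           "save_connectome_tck", "load_connectome_tck", "load_connectome_trk",
           "save_surface_tsv", "load_surface_tsv",
           "save_endpoints_tsv", "load_endpoints_tsv",
           "save_fits_tsv", "load_params_tsv",
           "save_band_proportions_tsv", "load_band_proportions_tsv",
           "save_config", "load_config"]


# -- aperture ---------------------------------------------------------------

def save_aperture_nifti(aperture: ApertureSequence, path: str | Path) -> None:
    """Aperture movie as (H, W, 1, T) NIfTI plus a JSON sidecar with the grid."""
    path = Path(path)
    data = np.moveaxis(aperture.frames, 0, -1)[:, :, None, :].astype(np.uint8)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = aperture.frame_duration
    nib.save(img, path)
    extent = float(aperture.grid_x.max() - aperture.grid_x.min())
    spacing = float(aperture.grid_x[0, 1] - aperture.grid_x[0, 0])
    sidecar = {"frame_duration_s": aperture.frame_duration,
               "grid_resolution": aperture.frames.shape[1],
               "pixel_spacing_deg": spacing,
               "extent_deg": extent + spacing,
               "axes": "x right-positive, y up-positive, degrees"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_aperture_nifti(path: str | Path) -> ApertureSequence:
    path = Path(path)
    img = nib.load(path)
    frames = np.moveaxis(np.asarray(img.dataobj)[:, :, 0, :], -1, 0)
    meta = json.loads(Path(str(path) + ".json").read_text())
    res = meta["grid_resolution"]
    spacing = meta["pixel_spacing_deg"]
    coords = (np.arange(res) - (res - 1) / 2) * spacing
    gx, gy = np.meshgrid(coords, coords)
    return ApertureSequence(frames=frames.astype(np.uint8), grid_x=gx,
                            grid_y=gy[::-1], frame_duration=meta["frame_duration_s"])


# -- streamlines ------------------------------------------------------------

def save_connectome_tck(c: Connectome, path: str | Path) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in c.streamlines],
        affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def _from_tractogram(tg) -> Connectome:
    return Connectome(streamlines=[np.asarray(s, dtype=float) for s in tg.streamlines])


def load_connectome_tck(path: str | Path) -> Connectome:
    tf = nib.streamlines.load(str(path))
    if not isinstance(tf, nib.streamlines.TckFile):
        raise ValueError(f"{path}: not a TCK file")
    return _from_tractogram(tf.tractogram)


def load_connectome_trk(path: str | Path) -> Connectome:
    tf = nib.streamlines.load(str(path))
    if not isinstance(tf, nib.streamlines.TrkFile):
        raise ValueError(f"{path}: not a TRK file")
    return _from_tractogram(tf.tractogram)


# -- surfaces and endpoints -------------------------------------------------

def save_surface_tsv(surface: EccSurface, path: str | Path) -> None:
    pd.DataFrame({"x_mm": surface.vertices[:, 0], "y_mm": surface.vertices[:, 1],
                  "eccentricity_deg": surface.eccentricity}).to_csv(
        path, sep="\t", index=False)


def load_surface_tsv(path: str | Path) -> EccSurface:
    df = pd.read_csv(path, sep="\t")
    return EccSurface(vertices=df[["x_mm", "y_mm"]].to_numpy(),
                      eccentricity=df["eccentricity_deg"].to_numpy())


def save_endpoints_tsv(records: list[EndpointRecord], path: str | Path) -> None:
    pos = np.array([r.position for r in records], dtype=float)
    out = {f"pos{ax}_mm": pos[:, i] for i, ax in enumerate("xyz"[: pos.shape[1]])}
    out["eccentricity_deg"] = [r.eccentricity for r in records]
    out["tdi_weight"] = [r.tdi_weight for r in records]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def load_endpoints_tsv(path: str | Path) -> list[EndpointRecord]:
    df = pd.read_csv(path, sep="\t")
    pos_cols = [c for c in df.columns if c.startswith("pos")]
    return [EndpointRecord(position=row[pos_cols].to_numpy(dtype=float),
                           eccentricity=row["eccentricity_deg"],
                           tdi_weight=row["tdi_weight"])
            for _, row in df.iterrows()]


# -- fit tables -------------------------------------------------------------

def save_fits_tsv(fits: list[FitResult], path: str | Path,
                  extra: dict | None = None) -> None:
    """Per-voxel table: x, y, sigma, n, gain, ve, ecc, phase, size + flags."""
    rows = []
    for f in fits:
        p = f.params
        rows.append({"x": p.x, "y": p.y, "sigma": p.sigma, "n": p.n,
                     "gain": p.gain, "ve": f.variance_explained,
                     "ecc": p.eccentricity, "phase": p.phase, "size": p.size,
                     "converged": f.converged, "at_sigma_floor": f.at_sigma_floor,
                     **(extra or {})})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_params_tsv(path: str | Path) -> list[PRFParams]:
    df = pd.read_csv(path, sep="\t")
    return [PRFParams(x=r.x, y=r.y, sigma=r.sigma, n=r.n, gain=r.gain)
            for r in df.itertuples()]


# -- band proportions -------------------------------------------------------

def save_band_proportions_tsv(bp: BandProportions, path: str | Path) -> None:
    pd.DataFrame({"band": bp.bands.labels(), "fraction": bp.fractions,
                  "n_items": bp.n_items, "n_excluded": bp.n_excluded}).to_csv(
        path, sep="\t", index=False)


def load_band_proportions_tsv(path: str | Path) -> BandProportions:
    df = pd.read_csv(path, sep="\t")
    edges = [float(b.split("-")[0]) for b in df["band"]] + [float(df["band"].iloc[-1].split("-")[1])]
    return BandProportions(fractions=df["fraction"].to_numpy(),
                           n_items=int(df["n_items"].iloc[0]),
                           n_excluded=int(df["n_excluded"].iloc[0]),
                           bands=EccBands(tuple(edges)))


# -- config -----------------------------------------------------------------

def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
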