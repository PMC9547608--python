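"""HDF5 / image / checkpoint readers and writers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .acoustic import DetectorArray, Sinogram
from .optical import AbsorbedEnergyMap, FluenceMap
from .phantom import AbsorptionMap
from .recon import ReconImage


def save_absorption(path, amap: AbsorptionMap):
    with h5py.File(path, "w") as f:
        f.create_dataset("mu_a", data=amap.values)
        if amap.labels is not None:
            f.create_dataset("labels", data=amap.labels)
        f.attrs["spacing_mm"] = amap.spacing_mm
        f.attrs["wavelength_nm"] = amap.wavelength_nm
        f.attrs["seed"] = int(amap.meta.get("seed", -1))


def load_absorption(path) -> AbsorptionMap:
    with h5py.File(path, "r") as f:
        labels = f["labels"][:] if "labels" in f else None
        return AbsorptionMap(values=f["mu_a"][:], spacing_mm=float(f.attrs["spacing_mm"]),
                             wavelength_nm=float(f.attrs["wavelength_nm"]),
                             labels=labels, meta={"seed": int(f.attrs.get("seed", -1))})


def save_fluence(path, fl: FluenceMap, energy: AbsorbedEnergyMap | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=fl.phi)
        f.attrs["spacing_mm"] = fl.spacing_mm
        if energy is not None:
            f.create_dataset("H", data=energy.H)
            f.create_dataset("P0", data=energy.P0)
            f.attrs["gamma"] = energy.gamma
            f.attrs["wavelength_nm"] = energy.wavelength_nm


def load_p0(path) -> AbsorbedEnergyMap:
    with h5py.File(path, "r") as f:
        return AbsorbedEnergyMap(H=f["H"][:], gamma=float(f.attrs.get("gamma", 1.0)),
                                 spacing_mm=float(f.attrs["spacing_mm"]),
                                 wavelength_nm=float(f.attrs.get("wavelength_nm", 700.0)))


def save_sinogram(path, s: Sinogram):
    with h5py.File(path, "w") as f:
        f.create_dataset("sino", data=s.data)
        f.create_dataset("detector_positions_mm", data=s.detectors.positions_mm)
        f.attrs["dt"] = s.dt
        f.attrs["c"] = s.c
        f.attrs["geometry"] = s.detectors.geometry
        f.attrs["center_freq"] = s.detectors.center_freq
        f.attrs["frac_bandwidth"] = s.detectors.frac_bandwidth
        f.attrs["bandlimited"] = bool(s.bandlimited)
        if s.noise_snr_db is not None:
            f.attrs["noise_snr_db"] = s.noise_snr_db


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        det = DetectorArray(f["detector_positions_mm"][:],
                            geometry=str(f.attrs["geometry"]),
                            center_freq=float(f.attrs["center_freq"]),
                            frac_bandwidth=float(f.attrs["frac_bandwidth"]))
        return Sinogram(f["sino"][:], dt=float(f.attrs["dt"]), c=float(f.attrs["c"]),
                        detectors=det, bandlimited=bool(f.attrs.get("bandlimited", False)),
                        noise_snr_db=(float(f.attrs["noise_snr_db"])
                                      if "noise_snr_db" in f.attrs else None))


def save_recon(path, img: ReconImage):
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=img.values)
        f.attrs["spacing_mm"] = img.spacing_mm
        f.attrs["method"] = img.method


def save_preview_png(path, array: np.ndarray):
    """8-bit grayscale preview of a 2-D field."""
    import imageio.v3 as iio
    a = np.asarray(array, dtype=np.float64)
    rng = a.max() - a.min()
    a = (a - a.min()) / rng if rng > 0 else np.zeros_like(a)
    iio.imwrite(Path(path), (255 * a).astype(np.uint8))


def load_gray_image(path) -> np.ndarray:
    """User-supplied grayscale PNG/TIFF -> float image in [0, 1]."""
    import imageio.v3 as iio
    a = np.asarray(iio.imread(Path(path))).astype(np.float64)
    if a.ndim == 3:
        a = a.mean(axis=2)
    rng = a.max() - a.min()
    return (a - a.min()) / rng if rng > 0 else np.zeros_like(a)


def save_checkpoint(path, model):
    """Single-file archive of weights + config + normalization params."""
    from dataclasses import asdict
    arrays = model.net.state_arrays()
    disc = model.discriminator.state_arrays() if model.discriminator else []
    np.savez(path,
             config=json.dumps(asdict(model.config)),
             norm=json.dumps({k: list(v) for k, v in model.norm_params.items()}),
             history=json.dumps(model.history),
             n_net=len(arrays),
             **{f"a{i}": a for i, a in enumerate(arrays + disc)})


def load_checkpoint(path):
    from .models import NetConfig, build_network
    with np.load(path, allow_pickle=False) as z:
        cfg = NetConfig(**json.loads(str(z["config"])))
        model = build_network(cfg)
        n_net = int(z["n_net"])
        arrays = [z[f"a{i}"] for i in range(n_net)]
        model.net.load_state_arrays(arrays)
        if model.discriminator is not None:
            total = len([k for k in z.files if k.startswith("a")])
            model.discriminator.load_state_arrays(
                [z[f"a{i}"] for i in range(n_net, total)])
        model.norm_params = {k: tuple(v) for k, v in json.loads(str(z["norm"])).items()}
        model.history = json.loads(str(z["history"]))
    return model
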