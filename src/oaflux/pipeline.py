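"""End-to-end orchestration: dataset synthesis, training, evaluation tables.

The full chain per phantom seed is

    vessel phantom -> diffusion fluence (training wavelength)
    -> P0 = mu_a(lambda) * phi -> k-space forward propagation on the fine
    grid -> Gaussian bandwidth filter -> additive noise at the target SNR
    -> time-reversal reconstruction on the coarse grid

yielding (TR image, ground-truth mu_a, sinogram) triples.  Datasets are
split 80/10/10 by phantom, the training split is quadrupled by one flip and
two rotations, and everything is normalized to [0, 1] with per-dataset
(min, max) so intensities stay comparable across samples.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import metrics as _metrics
from .acoustic import AcquisitionPreset, add_noise, apply_bandwidth, forward_propagate, get_preset
from .errors import DegenerateInputError, OafluxError
from .models import (NetConfig, PairedSample, TrainedModel, build_network,
                     normalize, train)
from .optical import (DEFAULT_WAVELENGTH_LUT, OpticalMedium, SourceSet,
                      absorbed_energy, fluence_for_wavelength, solve_diffusion,
                      top_edge_sources)
from .phantom import PhantomConfig, generate_vessel_phantom
from .recon import time_reversal

log = logging.getLogger("oaflux")


@dataclass
class ExperimentConfig:
    """One-file description of a fluence-correction experiment."""

    preset: str = "desk2d"
    n_phantoms: int = 60
    snr_db_list: tuple = (30.0, 35.0, 40.0)
    wavelengths: tuple = (600.0, 700.0, 800.0)
    train_wavelength: float = 700.0
    train_snr_db: float = 40.0
    fractions: tuple = (0.8, 0.1, 0.1)
    archs: tuple = ("fd_unet",)
    seed: int = 0
    # desk-scale training protocol
    depth: int = 3
    base_channels: int = 8
    batch_size: int = 6
    lr: float = 1e-3
    max_epochs: int = 20
    patience: int = 12
    augment: bool = True
    diffusion_tol: float = 1e-8
    output_dir: str | None = None

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DegenerateInputError("split fractions must sum to 1")
        if self.train_wavelength not in DEFAULT_WAVELENGTH_LUT:
            raise DegenerateInputError("training wavelength missing from the LUT")

    def net_config(self, arch: str, seed_offset: int = 0) -> NetConfig:
        return NetConfig(arch=arch, depth=self.depth, base_channels=self.base_channels,
                         batch_size=self.batch_size, lr=self.lr,
                         max_epochs=self.max_epochs, patience=self.patience,
                         seed=self.seed + seed_offset)


def simulate_sample(phantom_seed: int, preset: AcquisitionPreset,
                    wavelength_nm: float = 700.0, snr_db: float = 40.0,
                    tol: float = 1e-8) -> dict:
    """Run the full simulation chain for one phantom seed.

    Returns raw (unnormalized) arrays: ``mu_a`` ground truth, ``recon`` TR
    image on the phantom grid, ``sino`` band-limited noisy sinogram.
    """
    t0 = time.perf_counter()
    pcfg = PhantomConfig(shape=preset.phantom_shape,
                         spacing_mm=preset.phantom_spacing_mm,
                         seed=int(phantom_seed), wavelength_nm=wavelength_nm)
    amap = generate_vessel_phantom(pcfg)
    fl = fluence_for_wavelength(amap, wavelength_nm, tol=tol)
    scale = fl.meta["mu_a_scale"]
    medium = OpticalMedium(mu_a=scale * amap.values,
                           mu_s_prime=fl.meta["mu_s_prime"],
                           spacing_mm=amap.spacing_mm)
    energy = absorbed_energy(medium, fl, gamma=1.0)
    sino = forward_propagate(energy, preset.c, preset.forward_grid, preset.detectors)
    sino = apply_bandwidth(sino)
    sino = add_noise(sino, snr_db, seed=phantom_seed)
    rec = time_reversal(sino, preset.recon_grid, preset.detectors,
                        crop=preset.phantom_shape)
    log.info("sample seed=%d lambda=%g snr=%g dB simulated in %.2f s",
             phantom_seed, wavelength_nm, snr_db, time.perf_counter() - t0)
    return {"mu_a": amap.values, "recon": rec.values, "sino": sino.data,
            "seed": int(phantom_seed), "wavelength_nm": wavelength_nm,
            "snr_db": snr_db}


def _resize_bilinear(a: np.ndarray, shape) -> np.ndarray:
    from scipy import ndimage
    factors = [t / s for t, s in zip(shape, a.shape)]
    return ndimage.zoom(a, factors, order=1, grid_mode=True, mode="nearest")


def augment_pair(x: np.ndarray, y: np.ndarray, s: np.ndarray | None):
    """Identity, horizontal flip, 90 and 270 degree rotations (x4).

    For the circular acquisition the sinogram of a rotated/flipped image is
    approximated by the corresponding permutation of the detector axis.
    """
    n_det = s.shape[0] if s is not None else 0
    out = [(x, y, s)]
    sf = np.roll(s[::-1], 1, axis=0) if s is not None else None
    out.append((np.fliplr(x), np.fliplr(y), sf))
    for k in (1, 3):
        sr = np.roll(s, k * n_det // 4, axis=0) if s is not None else None
        out.append((np.rot90(x, k), np.rot90(y, k), sr))
    return [(np.ascontiguousarray(a), np.ascontiguousarray(b),
             np.ascontiguousarray(c) if c is not None else None) for a, b, c in out]


@dataclass
class Dataset:
    """Normalized paired samples with their split and norm convention."""

    train: list
    val: list
    test: list
    norm: dict
    manifest: dict = field(default_factory=dict)


def build_dataset(cfg: ExperimentConfig, out_path=None, with_sino: bool = True) -> Dataset:
    """Simulate, split, augment and normalize a paired dataset.

    Per-sample failures are quarantined (logged, skipped); the dataset is
    produced as long as at least 90% of the phantoms succeed.
    """
    preset = get_preset(cfg.preset)
    raws, failures = [], []
    for i in range(cfg.n_phantoms):
        seed = cfg.seed * 100_000 + i
        try:
            raws.append(simulate_sample(seed, preset, cfg.train_wavelength,
                                        cfg.train_snr_db, tol=cfg.diffusion_tol))
        except OafluxError as exc:  # quarantine and continue
            log.warning("sample seed=%d quarantined: %s", seed, exc)
            failures.append({"seed": seed, "error": str(exc)})
    if len(raws) < 0.9 * cfg.n_phantoms:
        raise DegenerateInputError(
            f"only {len(raws)}/{cfg.n_phantoms} samples simulated successfully")

    n = len(raws)
    n_val = max(1, int(round(cfg.fractions[1] * n))) if n >= 3 else 0
    n_test = max(1, int(round(cfg.fractions[2] * n))) if n >= 3 else 0
    n_train = n - n_val - n_test
    splits = {"train": raws[:n_train], "val": raws[n_train:n_train + n_val],
              "test": raws[n_train + n_val:]}

    # per-dataset normalization from the training split
    tx = np.stack([r["recon"] for r in splits["train"]])
    ty = np.stack([r["mu_a"] for r in splits["train"]])
    norm = {"x": (float(tx.min()), float(tx.max())),
            "y": (float(ty.min()), float(ty.max()))}
    if with_sino:
        ts = np.stack([r["sino"] for r in splits["train"]])
        norm["s"] = (float(ts.min()), float(ts.max()))

    img_shape = splits["train"][0]["mu_a"].shape

    def to_sample(r, x=None, y=None, s=None):
        x = r["recon"] if x is None else x
        y = r["mu_a"] if y is None else y
        if with_sino:
            s = r["sino"] if s is None else s
            s = normalize(_resize_bilinear(s, img_shape), *norm["s"])
        return PairedSample(x=normalize(x, *norm["x"]),
                            y=normalize(y, *norm["y"]), s=s, norm_params=norm)

    sets = {}
    for name, rows in splits.items():
        samples = []
        for r in rows:
            if name == "train" and cfg.augment:
                for xa, ya, sa in augment_pair(r["recon"], r["mu_a"],
                                               r["sino"] if with_sino else None):
                    samples.append(to_sample(r, xa, ya, sa))
            else:
                samples.append(to_sample(r))
        sets[name] = samples

    manifest = {
        "preset": cfg.preset, "n_phantoms": cfg.n_phantoms,
        "n_train": len(sets["train"]), "n_val": len(sets["val"]),
        "n_test": len(sets["test"]), "augment": cfg.augment,
        "train_wavelength": cfg.train_wavelength, "train_snr_db": cfg.train_snr_db,
        "seed": cfg.seed, "failures": failures, "norm": {k: list(v) for k, v in norm.items()},
    }
    ds = Dataset(train=sets["train"], val=sets["val"], test=sets["test"],
                 norm=norm, manifest=manifest)
    if out_path is not None:
        _write_dataset_h5(out_path, ds, splits)
    return ds


def _write_dataset_h5(path, ds: Dataset, splits):
    import h5py
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, rows in splits.items():
            grp = f.create_group(name)
            for j, r in enumerate(rows):
                g = grp.create_group(f"sample_{j:04d}")
                g.create_dataset("mu_a", data=r["mu_a"])
                g.create_dataset("recon", data=r["recon"])
                g.create_dataset("sino", data=r["sino"])
                g.attrs["seed"] = r["seed"]
        f.attrs["manifest"] = json.dumps(ds.manifest)
    path.with_suffix(".manifest.json").write_text(json.dumps(ds.manifest, indent=2))


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def _mean_sd(values):
    a = np.asarray(values, dtype=np.float64)
    return float(a.mean()), float(a.std())


def _evaluate_rows(ds_test, model_outputs, rois):
    """Rows of (method, psnr m/sd, ssim m/sd, gcnr m/sd) for a test set."""
    rows = []
    for method, images in model_outputs.items():
        ps, ss, gc = [], [], []
        for sample, est in zip(ds_test, images):
            ps.append(_metrics.psnr(sample.y, est))
            ss.append(_metrics.ssim(sample.y, est))
            gc.append(_metrics.gcnr(est, rois))
        rows.append({"method": method,
                     "psnr_mean": _mean_sd(ps)[0], "psnr_sd": _mean_sd(ps)[1],
                     "ssim_mean": _mean_sd(ss)[0], "ssim_sd": _mean_sd(ss)[1],
                     "gcnr_mean": _mean_sd(gc)[0], "gcnr_sd": _mean_sd(gc)[1]})
    return rows


def _test_condition_samples(cfg, preset, wavelength, snr_db, norm, with_sino):
    """Re-simulate the test-split phantoms under a transfer condition."""
    n = cfg.n_phantoms
    n_val = max(1, int(round(cfg.fractions[1] * n))) if n >= 3 else 0
    n_test = max(1, int(round(cfg.fractions[2] * n))) if n >= 3 else 0
    first_test = n - n_test
    img_shape = preset.phantom_shape
    samples = []
    for i in range(first_test, n):
        seed = cfg.seed * 100_000 + i
        r = simulate_sample(seed, preset, wavelength, snr_db, tol=cfg.diffusion_tol)
        s = None
        if with_sino:
            s = normalize(_resize_bilinear(r["sino"], img_shape), *norm["s"])
        samples.append(PairedSample(x=normalize(r["recon"], *norm["x"]),
                                    y=normalize(r["mu_a"], *norm["y"]),
                                    s=s, norm_params=norm))
    return samples


def run_experiment(cfg: ExperimentConfig, outdir=None) -> dict:
    """Train every architecture once, evaluate across noise/wavelength
    transfer conditions, and write per-condition mean +/- sd tables.

    Returns {"models": {...}, "tables": {condition: rows}, "dataset": Dataset}.
    """
    import pandas as pd
    outdir = Path(outdir or cfg.output_dir or "oaflux_out")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=2))
    preset = get_preset(cfg.preset)
    with_sino = any(a in ("ynet", "fd_ynet") for a in cfg.archs)
    ds = build_dataset(cfg, with_sino=with_sino)
    rois = _metrics.deep_region_rois(preset.phantom_shape)

    models: dict[str, TrainedModel] = {}
    for arch in cfg.archs:
        t0 = time.perf_counter()
        model = build_network(cfg.net_config(arch))
        model.norm_params = ds.norm
        train(model, ds.train, ds.val)
        models[arch] = model
        log.info("trained %s in %.1f s (%d epochs)", arch,
                 time.perf_counter() - t0, len(model.history))
        pd.DataFrame(model.history).to_csv(outdir / f"loss_{arch}.csv", index=False)

    conditions = [(cfg.train_wavelength, snr) for snr in cfg.snr_db_list]
    conditions += [(wl, cfg.train_snr_db) for wl in cfg.wavelengths
                   if (wl, cfg.train_snr_db) not in conditions]
    tables = {}
    for wavelength, snr in conditions:
        test = _test_condition_samples(cfg, preset, wavelength, snr, ds.norm, with_sino)
        outputs = {"Input/TR": [s.x for s in test]}
        for arch, model in models.items():
            outputs[arch] = [model.predict(s.x.astype(np.float32),
                                           s.s.astype(np.float32) if s.s is not None else None)
                             for s in test]
        rows = _evaluate_rows(test, outputs, rois)
        key = f"{wavelength:g}nm_{snr:g}dB"
        tables[key] = rows
        df = pd.DataFrame(rows)
        df.to_csv(outdir / f"table_{key}.csv", index=False)
        md = df.to_markdown(index=False) if hasattr(df, "to_markdown") else df.to_string()
        (outdir / f"table_{key}.md").write_text(md)
    return {"models": models, "tables": tables, "dataset": ds}


def ablate(cfg: ExperimentConfig, batch_sizes=(2, 6, 12), depths=(2, 3, 4),
           outdir=None) -> dict:
    """Batch-size and depth ablation grids (final training loss per cell)."""
    import pandas as pd
    outdir = Path(outdir or cfg.output_dir or "oaflux_out")
    outdir.mkdir(parents=True, exist_ok=True)
    ds = build_dataset(cfg, with_sino=False)
    arch = cfg.archs[0]
    results = {"batch_size": [], "depth": []}
    for bs in batch_sizes:
        ncfg = cfg.net_config(arch)
        ncfg.batch_size = int(bs)
        model = train(build_network(ncfg), ds.train, ds.val)
        results["batch_size"].append({"batch_size": bs,
                                      "final_loss": model.history[-1]["val_loss"]})
    for d in depths:
        ncfg = cfg.net_config(arch)
        ncfg.depth = int(d)
        model = train(build_network(ncfg), ds.train, ds.val)
        results["depth"].append({"depth": d,
                                 "final_loss": model.history[-1]["val_loss"]})
    for key, rows in results.items():
        pd.DataFrame(rows).to_csv(outdir / f"ablation_{key}.csv", index=False)
    return results


def headline_improvement(seed: int = 0, n_phantoms: int = 60,
                         train_seeds=(0, 1, 2), arch: str = "fd_unet",
                         cfg: ExperimentConfig | None = None) -> dict:
    """Relative PSNR improvement of a trained network over its TR input.

    Builds a seeded vessel dataset end-to-end (fluence corruption,
    band-limited 40 dB detection, TR reconstruction), trains ``arch`` once
    per training seed, and reports the median over training seeds of

        100 * (mean test PSNR of corrected - mean test PSNR of TR input)
            / (mean test PSNR of TR input)

    on the held-out test split (normalized images, max intensity 1).
    """
    if cfg is None:
        cfg = ExperimentConfig(n_phantoms=n_phantoms, seed=seed)
    ds = build_dataset(cfg, with_sino=False)
    tr_psnr = float(np.mean([_metrics.psnr(s.y, s.x) for s in ds.test]))
    improvements, net_psnrs = [], []
    for ts in train_seeds:
        model = build_network(cfg.net_config(arch, seed_offset=int(ts)))
        model.norm_params = ds.norm
        train(model, ds.train, ds.val)
        net_psnr = float(np.mean([_metrics.psnr(s.y, model.predict(s.x.astype(np.float32)))
                                  for s in ds.test]))
        net_psnrs.append(net_psnr)
        improvements.append(100.0 * (net_psnr - tr_psnr) / tr_psnr)
    return {"improvement_pct": float(np.median(improvements)),
            "per_seed_pct": improvements, "tr_psnr": tr_psnr,
            "net_psnr": net_psnrs, "n_phantoms": cfg.n_phantoms,
            "n_test": len(ds.test)}


# ---------------------------------------------------------------------------
# 3-D slice-stack correction
# ---------------------------------------------------------------------------


def hemisphere_sources(shape, spacing_mm: float, n_sources: int = 10,
                       inset_cells: float = 3.0) -> SourceSet:
    """Sources spread over a dome surface (golden-angle spiral placement)."""
    nz, ny, nx = shape
    radius = min(nz - 2, ny // 2 - 2, nx // 2 - 2) - inset_cells
    golden = np.pi * (3 - np.sqrt(5))
    pos = []
    for i in range(n_sources):
        z = (i + 0.5) / n_sources  # cos(polar) in (0, 1): upper hemisphere
        r_xy = np.sqrt(1 - z ** 2)
        th = golden * i
        pos.append([z * radius, ny / 2 + radius * r_xy * np.sin(th),
                    nx / 2 + radius * r_xy * np.cos(th)])
    return SourceSet(np.asarray(pos), np.ones(n_sources))


def corrupt_volume_with_fluence(amap, tol: float = 1e-7,
                                mu_s_prime: float = 0.1) -> np.ndarray:
    """Fluence-corrupted 3-D volume H = mu_a * phi for a breast phantom."""
    medium = OpticalMedium(mu_a=amap.values, mu_s_prime=mu_s_prime,
                           spacing_mm=amap.spacing_mm)
    sources = hemisphere_sources(amap.values.shape, amap.spacing_mm)
    fl = solve_diffusion(medium, sources, tol=tol)
    return amap.values * fl.phi


def slice_stack_3d(volume_x: np.ndarray, volume_y: np.ndarray,
                   model: TrainedModel) -> dict:
    """Correct a 3-D volume slice-by-slice with a 2-D model trained on X-Y
    slices, then score each plane family.

    ``volume_x`` is the normalized corrupted volume (z, y, x), ``volume_y``
    the normalized truth.  Returns the stacked corrected volume and
    mean +/- sd PSNR/SSIM per plane family for input and corrected volumes.
    """
    if volume_x.shape != volume_y.shape:
        raise DegenerateInputError("volumes must share a shape")
    corrected = np.stack([model.predict(volume_x[z].astype(np.float32))
                          for z in range(volume_x.shape[0])])
    report = {}
    planes = {"xy": 0, "yz": 2, "xz": 1}
    for fam, axis in planes.items():
        for name, vol in (("input", volume_x), ("corrected", corrected)):
            ps, ss = [], []
            for i in range(vol.shape[axis]):
                sl = [slice(None)] * 3
                sl[axis] = i
                ref = volume_y[tuple(sl)]
                est = vol[tuple(sl)]
                if ref.max() == ref.min():
                    continue  # empty background slab
                ps.append(_metrics.psnr(ref, est))
                ss.append(_metrics.ssim(ref, est))
            report[f"{fam}_{name}_psnr"] = _mean_sd(ps)
            report[f"{fam}_{name}_ssim"] = _mean_sd(ss)
    return {"corrected": corrected, "report": report}
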