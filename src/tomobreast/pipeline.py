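"""Configurable end-to-end pipeline runner with a reproducibility manifest.

A pipeline config (YAML/JSON mapping) lists stages in order — any prefix
of phantom -> simulate -> recon -> artifact_reduction -> postproc -> sm ->
metrics — with per-stage parameters and seeds.  Identical config plus
seeds reproduce outputs digest-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .geometry import FocalSpotModel, make_geometry
from .phantoms import InsertSpec, add_insert, build_slab_phantom
from .projector import add_counting_noise, forward_project, to_line_integrals
from .postproc import FlavorConfig, NoiseModel, constrained_denoise, multiband_enhance, synthesize_sm
from .reconstruction import backproject_perspective, ramp_filter, resample_cartesian
from .artifact_reduction import masked_backproject, remove_objects, segment_objects
from .metrics import cnr_roi, emtf_from_wire
from .stackio import write_stack

log = logging.getLogger("tomobreast.pipeline")

STAGES = ("phantom", "simulate", "recon", "artifact_reduction", "postproc", "sm", "metrics")


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    stage_timings_s: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(config_path) -> dict:
    text = Path(config_path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "stages" not in cfg:
        raise ConfigurationError("pipeline config must be a mapping with a 'stages' list")
    return cfg


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute the configured stages in order; see module docstring."""
    if not isinstance(config, dict):
        config = load_config(config)
    stage_names = [next(iter(s)) if isinstance(s, dict) else s for s in config["stages"]]
    unknown = [s for s in stage_names if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown pipeline stages: {unknown}")
    order = [STAGES.index(s) for s in stage_names]
    if order != sorted(order):
        raise ConfigurationError("stages must appear in pipeline order")

    out_dir = Path(out_dir or config.get("out_dir", "tomobreast_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seeds={}, version=__version__)

    geom = make_geometry(_geom_config(config.get("geometry", {})))
    state: dict = {"geometry": geom}
    for entry in config["stages"]:
        name, params = (next(iter(entry.items())) if isinstance(entry, dict) else (entry, {}))
        params = params or {}
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            _run_stage(name, params, state, out_dir, manifest)
        except ConfigurationError as exc:
            raise ConfigurationError(f"stage {name!r} failed: {exc}") from exc
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.stage_timings_s[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, manifest.stage_timings_s[name])

    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.output_digests[p.name] = _digest(p)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _geom_config(gcfg: dict) -> dict:
    gcfg = dict(gcfg)
    fs = gcfg.pop("focal_spot", None)
    if fs is not None:
        gcfg["focal_spot"] = FocalSpotModel(**fs)
    return gcfg


def _run_stage(name, params, state, out_dir: Path, manifest: RunManifest) -> None:
    if name == "phantom":
        seed = int(params.get("seed", 0))
        manifest.seeds["phantom"] = seed
        ph = build_slab_phantom(
            thickness_mm=params.get("thickness_mm", 60.0),
            glandularity=params.get("glandularity", 0.3),
            shape=tuple(params.get("shape", (64, 64, 24))),
            voxel_size_mm=tuple(params.get("voxel_size_mm", (0.5, 0.5, 2.5))),
            texture_beta=params.get("texture_beta", 3.0),
            seed=seed,
        )
        for ins in params.get("inserts", []):
            ph = add_insert(ph, InsertSpec(**{**ins, "position_mm": tuple(ins["position_mm"])}))
        state["phantom"] = ph
    elif name == "simulate":
        seed = int(params.get("seed", 1))
        manifest.seeds["simulate"] = seed
        stack = forward_project(
            state["phantom"],
            state["geometry"],
            effective_energy_keV=params.get("effective_energy_keV", 20.0),
            n_spot_samples=params.get("n_spot_samples", 3),
            n_time_samples=params.get("n_time_samples", 3),
            step_mm=params.get("step_mm"),
        )
        gain = params.get("noise_gain")
        if gain:
            stack = add_counting_noise(stack, gain, seed)
        state["stack"] = stack
        write_stack(out_dir / "projections.tif", stack)
    elif name == "recon":
        stack = to_line_integrals(state["stack"])
        state["log_stack"] = stack
        fp = ramp_filter(stack, params.get("window", "hann"))
        z = params.get("z_planes_mm") or np.arange(
            params.get("zmin", 1.0), params.get("zmax", 59.0) + 1e-9, params.get("spacing", 1.0)
        ).tolist()
        vol = backproject_perspective(
            fp, stack.geometry, z, slice_thickness_mm=params.get("thickness", 2.0)
        )
        if params.get("coords", "perspective") == "cartesian":
            vol = resample_cartesian(vol)
        state["fp"] = fp
        state["z_planes"] = z
        state["volume"] = vol
        write_stack(out_dir / "recon.tif", vol)
    elif name == "artifact_reduction":
        stack = state["log_stack"]
        masks = segment_objects(
            stack,
            struct_radius_px=params.get("struct_radius_px", 15),
            k_threshold=params.get("k_threshold", 4.0),
            min_size_px=params.get("min_size_px", 5),
            dilation_px=params.get("dilation_px", 2),
        )
        removed = remove_objects(stack, masks)
        fp = ramp_filter(stack, params.get("window", "hann"), removed_stack=removed)
        vol = masked_backproject(fp, masks, stack.geometry, state["z_planes"])
        state["volume"] = vol
        import tifffile

        tifffile.imwrite(out_dir / "masks.tif", masks.masks.astype(np.uint8))
        write_stack(out_dir / "recon_ar.tif", vol)
    elif name == "postproc":
        cfg = FlavorConfig(
            n_bands=params.get("n_bands", 4),
            band_gains=tuple(params.get("band_gains", (1.0,) * params.get("n_bands", 4))),
            overshoot_clamp=params.get("overshoot_clamp"),
        )
        vol = multiband_enhance(state["volume"], cfg)
        state["volume"] = vol
        write_stack(out_dir / "recon_post.tif", vol)
    elif name == "sm":
        nm = NoiseModel(gain=params.get("gain", 1e4), clamp_k=params.get("clamp_k", 2.0))
        den = constrained_denoise(state["stack"], nm)
        sm = synthesize_sm(
            to_line_integrals(den), state["volume"],
            k_central=params.get("k_central", 2),
            detail_weight=params.get("detail_weight", 0.5),
        )
        state["sm"] = sm
        np.savetxt(out_dir / "sm.csv", sm, delimiter=",")
    elif name == "metrics":
        results = {}
        if "wire_height_mm" in params:
            curve = emtf_from_wire(
                state["stack"], state["geometry"],
                wire_height_mm=params["wire_height_mm"],
                wire_tilt_deg=params.get("wire_tilt_deg", 3.0),
            )
            results["emtf"] = {
                "frequencies_lpmm": curve.frequencies_lpmm.tolist(),
                "modulation": curve.modulation.tolist(),
            }
        if "cnr" in params:
            p = params["cnr"]
            img = state["sm"] if p.get("on", "sm") == "sm" else state["volume"].slices[p["slice"]]
            results["cnr"] = cnr_roi(
                img,
                (slice(*p["obj_rows"]), slice(*p["obj_cols"])),
                (slice(*p["bg_rows"]), slice(*p["bg_cols"])),
            )
        (out_dir / "metrics.json").write_text(json.dumps(results, indent=2))
        state["metrics"] = results
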