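"""End-to-end fitting pipeline driven by a YAML configuration.

A config names a protocol and either a synthetic-phantom specification or
measured input volumes, and the pipeline produces quantitative T1 and T2*
maps, a per-ROI median table, optional agreement statistics between two
sources, and a structured log of parameters and warnings.

Minimal phantom-driven config::

    protocol: mp2rageme
    output: out/
    phantom: {grid_shape: [48, 48, 48], snr: 30, seed: 1}

Measured-data config keys (all NIfTI paths)::

    inputs:
      uni: uni.nii.gz
      b1: b1map.nii.gz        # optional; omitted -> uncorrected (b1 = 1)
      echoes: [e1.nii.gz, e2.nii.gz, ...]
      tes: [3.0, 11.5, 20.0, 28.5]
      labels: rois.nii.gz     # optional
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .phantom import PhantomConfig, VolumeSet, generate_phantom
from .protocol import DEFAULT_TISSUES, TissueParams, load_protocol
from .quantification import (QuantMapSet, bland_altman, build_lookup,
                             resample_b1, roi_medians, t1_from_uni,
                             t2star_fit)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Configuration or stage failure; maps to a nonzero CLI exit status."""


def _load_config(config):
    if isinstance(config, dict):
        return dict(config), Path(".")
    path = Path(config)
    with open(path) as fh:
        return yaml.safe_load(fh), path.parent


def _phantom_cfg(spec: dict) -> PhantomConfig:
    spec = dict(spec)
    if "grid_shape" in spec:
        spec["grid_shape"] = tuple(spec["grid_shape"])
    if "tissue_table" in spec:
        spec["tissue_table"] = {
            int(k): TissueParams(**v) for k, v in spec["tissue_table"].items()}
    return PhantomConfig(**spec)


def _fit_volumes(p, lut, uni, b1, echoes, tes, noise_sd, affine) -> QuantMapSet:
    t1_map, valid = t1_from_uni(uni, b1, lut)
    t2s, s0, ok = t2star_fit(echoes, tes, noise_sd=noise_sd)
    return QuantMapSet(t1_map=t1_map, t2star_map=t2s, s0_map=s0,
                       validity_mask=valid & ok, affine=affine)


def _fit_phantom(p, lut, vs: VolumeSet) -> QuantMapSet:
    b1 = (vs.b1_map if vs.b1_map.shape == vs.uni.shape
          else resample_b1(vs.b1_map, vs.uni.shape))
    return _fit_volumes(p, lut, vs.uni, b1, vs.inv2_mag, vs.tes,
                        vs.noise_sd or None, vs.affine)


def run_pipeline(config, output_dir=None):
    """Execute all fit stages described by ``config`` (path or mapping).

    Returns a dict with the fitted :class:`QuantMapSet` (``maps``), the ROI
    table (``roi``), optional agreement statistics (``agreement``), and the
    structured ``report``.  Outputs are also written under the configured
    output directory.
    """
    t_start = time.time()
    cfg, base = _load_config(config)
    if "protocol" not in cfg:
        raise PipelineError("config is missing the required 'protocol' key")
    if ("phantom" not in cfg) and ("inputs" not in cfg):
        raise PipelineError("config needs either a 'phantom' or an 'inputs' section")

    outdir = Path(output_dir or cfg.get("output", "out"))
    if not outdir.is_absolute():
        outdir = base / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    proto_key = cfg["protocol"]
    p = load_protocol(proto_key)
    report = {"protocol": getattr(p, "name", "") or str(proto_key),
              "stages": [], "warnings": []}

    lut_cfg = cfg.get("lookup", {})
    t0 = time.time()
    lut = build_lookup(p,
                       t1_grid=lut_cfg.get("t1_grid"),
                       b1_grid=lut_cfg.get("b1_grid"))
    report["stages"].append({"stage": "lookup", "seconds": time.time() - t0,
                             "n_t1": len(lut.t1_grid), "n_b1": len(lut.b1_grid)})

    def fit_one(tag, source):
        t0 = time.time()
        if "phantom" in source:
            pc = _phantom_cfg(source["phantom"])
            vs = generate_phantom(pc, p)
            maps = _fit_phantom(p, lut, vs)
            labels, affine = vs.labels, vs.affine
            report["stages"].append({"stage": f"phantom:{tag}", "seed": pc.seed,
                                     "snr": pc.snr, "grid": list(pc.grid_shape),
                                     "seconds": time.time() - t0})
        else:
            inp = source["inputs"]
            uni, affine = nio.read_volume(base / inp["uni"])
            echoes = [nio.read_volume(base / e)[0] for e in inp["echoes"]]
            tes = inp["tes"]
            if "b1" in inp:
                b1, _ = nio.read_volume(base / inp["b1"])
                if b1.shape != uni.shape:
                    b1 = resample_b1(b1, uni.shape)
            else:
                msg = "no B1 map given: proceeding UNCORRECTED with b1 = 1"
                log.warning(msg)
                report["warnings"].append(msg)
                b1 = np.ones_like(uni)
            maps = _fit_volumes(p, lut, uni, b1, echoes, tes,
                                inp.get("noise_sd"), affine)
            labels = (nio.read_volume(base / inp["labels"])[0].astype(int)
                      if "labels" in inp else None)
            report["stages"].append({"stage": f"fit:{tag}",
                                     "seconds": time.time() - t0})
        return maps, labels, affine

    maps, labels, affine = fit_one("a", cfg)
    nio.write_volume(np.nan_to_num(maps.t1_map), affine, outdir / "t1_map.nii.gz")
    nio.write_volume(np.nan_to_num(maps.t2star_map), affine,
                     outdir / "t2star_map.nii.gz")
    nio.write_volume(maps.validity_mask.astype(np.uint8), affine,
                     outdir / "valid_mask.nii.gz")

    result = {"maps": maps, "report": report}
    if labels is not None:
        names = {k: t.label for k, t in DEFAULT_TISSUES.items()}
        roi_t1 = roi_medians(np.where(maps.validity_mask, maps.t1_map, np.nan),
                             labels, names)
        roi_t2 = roi_medians(np.where(maps.validity_mask, maps.t2star_map,
                                      np.nan), labels, names)
        roi = roi_t1.merge(roi_t2, on=["label", "name"],
                           suffixes=("_t1", "_t2star"))
        roi.to_csv(outdir / "roi_medians.csv", index=False)
        result["roi"] = roi

    # optional second source: per-ROI Bland-Altman agreement
    second = cfg.get("compare")
    if second is not None:
        maps_b, labels_b, _ = fit_one("b", second)
        lab = labels if labels is not None else labels_b
        if lab is None:
            raise PipelineError("agreement comparison requires ROI labels")
        names = {k: t.label for k, t in DEFAULT_TISSUES.items()}
        med_a = roi_medians(np.where(maps.validity_mask, maps.t1_map, np.nan),
                            lab, names)["median"].to_numpy()
        med_b = roi_medians(np.where(maps_b.validity_mask, maps_b.t1_map,
                                     np.nan), lab, names)["median"].to_numpy()
        stats = bland_altman(med_a, med_b)
        result["agreement"] = stats
        report["agreement_t1"] = stats.as_dict()

    report["total_seconds"] = time.time() - t_start
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return result
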