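"""Batch queue runner: per-ROI analysis jobs into per-ROI output folders.

A queue is a YAML or JSON file listing self-contained jobs.  Each job
names 1–3 channel position files, an optional ROI and seed, and the
analyses to run with their parameters; processing creates one output
folder per job holding the tables, curves and images generated for that
ROI plus a machine-readable run manifest.  Failures are isolated per job.

Example queue entry::

    jobs:
      - name: roi1
        channels: [a.tsv, b.tsv]
        roi: {type: rectangle, bounds: [0, 0, 5000, 5000]}
        seed: 1
        analyses:
          saa: {cutoff_multiplier: 1.65, i_reg: 0, n_randomizations: 20}
          ripley: {r_max: 1000, dr: 10}
          dbscan: {k: 10, eps: 100}
"""

from __future__ import annotations

import json
import os
import traceback
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ConversionSpec, read_positions
from .roi import RegionOfInterest, crop_to_roi, rasterize
from .saa import CdcSpec, saa_three_colour, saa_two_colour
from .spatial import cross_rdf, cross_ripley, default_radii, h_segment
from .clustering import (dbscan, extract_clusters_static_rd, hier_segment_rd,
                         optics_order)

__all__ = ["AnalysisJob", "load_queue_config", "run_queue"]

KNOWN_ANALYSES = ("saa", "rdf", "ripley", "dbscan", "optics", "hsegment",
                  "rasterize")


def _pkg_version() -> str:
    from . import __version__
    return __version__


@dataclass
class AnalysisJob:
    """One self-contained, re-runnable queue entry."""

    name: str
    channels: Sequence[str]
    analyses: dict
    roi: Optional[RegionOfInterest] = None
    seed: int = 0
    output_dir: Optional[str] = None
    conversion: ConversionSpec = field(default_factory=ConversionSpec)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 3:
            raise ValueError("a job needs 1-3 channel files")
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")


def load_queue_config(path) -> list[AnalysisJob]:
    """Parse a YAML/JSON queue file, validating before any job runs."""
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "jobs" not in cfg:
        raise ValueError("queue config must be a mapping with a 'jobs' list")
    jobs = []
    for i, spec in enumerate(cfg["jobs"]):
        roi = None
        if spec.get("roi"):
            roi = RegionOfInterest.from_dict(spec["roi"])
        conv = ConversionSpec(**spec.get("conversion", {}))
        jobs.append(AnalysisJob(
            name=spec.get("name", f"job{i}"),
            channels=spec["channels"],
            analyses=spec.get("analyses", {}),
            roi=roi,
            seed=int(spec.get("seed", 0)),
            output_dir=spec.get("output_dir"),
            conversion=conv,
        ))
    return jobs


def _write_curve(curve, path) -> None:
    pd.DataFrame({"r_nm": curve.radii, curve.kind: curve.values}).to_csv(
        path, index=False)


def _run_job(job: AnalysisJob, out_dir: str) -> dict:
    tables = [read_positions(p, job.conversion, channel_id=f"ch{i}")
              for i, p in enumerate(job.channels)]
    if job.roi is not None:
        tables = crop_to_roi(tables, job.roi)
    region = job.roi
    outputs: list[str] = []

    def save(name: str) -> str:
        path = os.path.join(out_dir, name)
        outputs.append(path)
        return path

    for analysis, params in job.analyses.items():
        params = dict(params or {})
        if analysis == "saa":
            spec = CdcSpec.from_tables(
                tables,
                i_reg=params.pop("i_reg", 0.0),
                cutoff_multiplier=params.pop("cutoff_multiplier", 1.65),
                sigma_override=params.pop("sigma", None))
            if len(tables) == 2:
                results = saa_two_colour(
                    tables[0], tables[1], spec, region=region,
                    seed=job.seed, **params)
                rows = []
                for r in results:
                    pd.DataFrame({"nn_nm": r.nn_distances}).to_csv(
                        save(f"saa_nn_{r.direction[0]}_to_"
                             f"{r.direction[1]}.csv"), index=False)
                    rows.append({
                        "direction": "->".join(r.direction),
                        "cdc_nm": r.cdc,
                        "fraction_below_cdc": r.fraction_below_cdc,
                        "srp_fraction_below_cdc": r.srp_fraction_below_cdc,
                        "mode_nm": r.mode_distance,
                        "n_randomizations": r.n_randomizations,
                    })
                pd.DataFrame(rows).to_csv(save("saa_summary.csv"),
                                          index=False)
            else:
                results = saa_three_colour(
                    tables[0], tables[1], tables[2], spec, region=region,
                    seed=job.seed, **params)
                rows = []
                for r in results:
                    for cls, frac in r.fractions.items():
                        rows.append({"reference": r.reference, "class": cls,
                                     "fraction": frac,
                                     "srp_fraction": r.srp_fractions[cls],
                                     "cdc_nm": r.cdc})
                pd.DataFrame(rows).to_csv(save("saa3_summary.csv"),
                                          index=False)
        elif analysis in ("rdf", "ripley"):
            radii = default_radii(params.pop("r_max", 1000.0),
                                  params.pop("dr", 10.0))
            src = tables[0]
            tgt = tables[1] if len(tables) > 1 else tables[0]
            if analysis == "rdf":
                curve = cross_rdf(src, tgt, region=region, radii=radii,
                                  **params)
                _write_curve(curve, save("rdf.csv"))
            else:
                k, h, hp = cross_ripley(src, tgt, region=region,
                                        radii=radii, **params)
                for c, nm in ((k, "ripley_k"), (h, "ripley_h"),
                              (hp, "ripley_h_prime")):
                    _write_curve(c, save(f"{nm}.csv"))
        elif analysis == "dbscan":
            lab = dbscan(tables[0], k=params.get("k", 10),
                         eps=params.get("eps", 100.0))
            pd.DataFrame({"label": lab.labels, "role": lab.roles}).to_csv(
                save("dbscan_labels.tsv"), sep="\t", index=False)
        elif analysis == "optics":
            mcs = params.get("min_cluster_size",
                             max(5, int(0.005 * tables[0].n)))
            profile = optics_order(tables[0], min_cluster_size=mcs)
            pd.DataFrame({
                "position": np.arange(profile.n),
                "molecule": profile.ordering,
                "reachability_nm": profile.reachability,
            }).to_csv(save("optics_rd.csv"), index=False)
            if "rd_threshold" in params:
                lab = extract_clusters_static_rd(
                    profile, params["rd_threshold"])
                pd.DataFrame({"label": lab.labels}).to_csv(
                    save("optics_static_labels.tsv"), sep="\t", index=False)
            else:
                tree = hier_segment_rd(
                    profile, min_cluster_size=mcs,
                    split_significance=params.get("split_significance",
                                                  0.75))
                lab = tree.leaf_labeling()
                pd.DataFrame({"label": lab.labels}).to_csv(
                    save("optics_hier_labels.tsv"), sep="\t", index=False)
        elif analysis == "hsegment":
            raster, labels, n_clusters = h_segment(
                tables[0], r0=params.get("r0", 50.0),
                threshold=params.get("threshold", 0.0),
                pixel_size=params.get("pixel_size", 20.0), region=region)
            raster.to_tiff(save("hsegment_mask.tif"))
        elif analysis == "rasterize":
            for t in tables:
                img = rasterize(t, pixel_size=params.get("pixel_size", 20.0),
                                roi=region)
                img.to_tiff(save(f"raster_{t.channel_id}.tif"))
    manifest = {
        "job": job.name,
        "channels": list(job.channels),
        "n_molecules": [t.n for t in tables],
        "roi": None if job.roi is None else job.roi.to_dict(),
        "seed": job.seed,
        "analyses": {a: dict(p or {}) for a, p in job.analyses.items()},
        "outputs": [os.path.basename(p) for p in outputs],
        "version": _pkg_version(),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_queue(jobs: Sequence[AnalysisJob], output_root: str) -> list[dict]:
    """Process a queue, one output folder per job, isolating failures.

    Returns one status record per job: ``{"job", "output_dir", "status",
    ["error"]}``.  A failing job is logged (``error.log`` in its folder)
    and does not stop the queue.
    """
    os.makedirs(output_root, exist_ok=True)
    statuses = []
    for job in jobs:
        out_dir = job.output_dir or os.path.join(output_root, job.name)
        os.makedirs(out_dir, exist_ok=True)
        try:
            _run_job(job, out_dir)
            statuses.append({"job": job.name, "output_dir": out_dir,
                             "status": "ok"})
        except Exception as exc:
            with open(os.path.join(out_dir, "error.log"), "w") as fh:
                fh.write(traceback.format_exc())
            statuses.append({"job": job.name, "output_dir": out_dir,
                             "status": "failed", "error": str(exc)})
    return statuses
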