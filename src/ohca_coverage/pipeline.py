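"""End-to-end orchestration of the five analysis steps.

simulate -> filter/describe -> isochrones -> spatial survival (PEP + diurnal
relative risk) -> AED siting (MCLP + coverage curve) -> paired comparison.
Stages communicate only via on-disk artifacts (CSV / GeoJSON / JSON), and a
manifest records inputs, seeds and output hashes so a run is reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import summarize_pair, wilcoxon_signed_rank
from .descriptives import filter_events, summarize
from .io import grid_to_geojson, read_config, write_city_geojson, write_events_csv
from .isochrone import band_areas, travel_time_field
from .mclp import aed_travel_times, aggregate_demand, build_coverage, coverage_curve, solve_greedy
from .spatial_survival import (
    McmcConfig,
    build_dataset,
    compute_pep,
    relative_risk_curve,
    run_mcmc,
)
from .synth_city import KMH, generate_city, simulate_events


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    n_calls: int = 476
    n_candidates: int = 624
    cell_size_m: float = 500.0
    threshold_s: float = 300.0
    preset: str = "test"          # {full, test} MCMC scale
    p_aeds: int = 100
    cutoff_s: float = 150.0
    pedestrian_speed: float = 10.0 * KMH
    curve_step: int = 20
    out_dir: str = "run_output"
    overwrite: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = read_config(path)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            elif f.type in ("bool",):
                kwargs[f.name] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = [
        "events.csv", "city.geojson", "summary.json", "isochrone.geojson",
        "pep.geojson", "rr_curve.csv", "mclp.json", "compare.json",
    ]
    if not config.overwrite:
        existing = [a for a in artifacts if (out / a).exists()]
        if existing:
            raise FileExistsError(
                f"outputs already exist in {out} (pass overwrite): {existing}"
            )

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3), **info}
        return done

    # 1. simulate
    done = stage("simulate")
    city = generate_city(n_candidates=config.n_candidates, seed=config.seed)
    events = simulate_events(city, config.n_calls, seed=config.seed)
    write_events_csv(events, out / "events.csv")
    write_city_geojson(city, out / "city.geojson")
    done(n_calls=len(events), n_candidates=len(city.candidates))

    # 2. describe
    done = stage("describe")
    cohort = filter_events(events)
    summary = summarize(cohort, n_total_calls=len(events))
    summary.write_json(out / "summary.json")
    done(n_cohort=len(cohort))

    # 3. isochrones
    done = stage("isochrone")
    full_grid = aggregate_demand(cohort, config.cell_size_m, bbox=city.bbox)
    field = travel_time_field(city, full_grid)
    iso_gj = grid_to_geojson(
        full_grid,
        {"minutes": [float(m) for m in field.minutes_to_nearest_base],
         "band": list(field.band)},
    )
    (out / "isochrone.geojson").write_text(json.dumps(iso_gj))
    done(band_areas_m2=band_areas(field))

    # 4. spatial survival
    done = stage("survival")
    data = build_dataset(cohort, full_grid, threshold_s=config.threshold_s,
                         prefiltered=True)
    cfg = (McmcConfig.full_scale(seed=config.seed)
           if config.preset == "full" else McmcConfig.test_scale(seed=config.seed))
    samples = run_mcmc(data, cfg)
    pep = compute_pep(samples, full_grid, config.threshold_s)
    pep_gj = grid_to_geojson(full_grid, {"pep": [float(v) for v in pep]})
    (out / "pep.geojson").write_text(json.dumps(pep_gj))
    rr = relative_risk_curve(samples)
    pd.DataFrame(
        {"hour": rr.hours, "median": rr.median, "lo95": rr.lo95, "hi95": rr.hi95}
    ).to_csv(out / "rr_curve.csv", index=False)
    done(n_samples=samples.n_samples, rr_peak_hour=rr.peak_hour,
         acceptance=samples.acceptance)

    # 5. MCLP
    done = stage("mclp")
    if not city.candidates:
        raise ValueError("mclp stage: city has no candidate sites")
    demand = aggregate_demand(cohort, config.cell_size_m)
    cov = build_coverage(demand, list(city.candidates), config.cutoff_s,
                         config.pedestrian_speed)
    weights = np.array([c.event_count for c in demand.active_cells], dtype=float)
    solution = solve_greedy(cov, weights, config.p_aeds)
    p_values = list(range(config.curve_step, config.p_aeds + 1, config.curve_step))
    curve, saturation = coverage_curve(cov, weights, p_values)
    mclp_report = {
        "p": solution.p,
        "selected": list(solution.selected),
        "n_active_cells": len(demand.active_cells),
        "n_covered": solution.n_covered,
        "coverage_fraction_cells": solution.coverage_fraction_cells,
        "covered_demand": solution.covered_demand,
        "curve": [
            {"p": p, "covered_cells": s.n_covered,
             "covered_demand": s.covered_demand}
            for p, s in zip(p_values, curve)
        ],
        "saturation_p": saturation,
    }
    (out / "mclp.json").write_text(json.dumps(mclp_report, indent=2))
    done(coverage_fraction=solution.coverage_fraction_cells)

    # 6. compare
    done = stage("compare")
    aed = aed_travel_times(solution, cohort, list(city.candidates),
                           config.pedestrian_speed)
    amb = np.array([e.response_time_s for e in cohort])
    test = wilcoxon_signed_rank(aed, amb)
    report = {
        "n_pairs": test.n_pairs,
        "wilcoxon_W": test.wilcoxon_W,
        "z": test.z,
        "p_value": test.p_value,
        "method": test.method,
        "summary": summarize_pair(aed, amb),
    }
    (out / "compare.json").write_text(json.dumps(report, indent=2))
    done(z=test.z)

    manifest["artifacts"] = {a: _sha256(out / a) for a in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
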