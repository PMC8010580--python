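"""End-to-end orchestration and deterministic fixture generation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ionarc.beam import BeamLibrary, BeamModelOptions, build_depth_profile
from ionarc.evaluation import (
    TCPParams,
    cumulative_histogram,
    delta_oer_vh,
    angular_fluence_map,
    evaluate_plan,
    summarize,
)
from ionarc.hypoxia import HypoxiaParams
from ionarc.ions import get_ion
from ionarc.mkm import MKMParams, PhotonLQParams
from ionarc.planning import PlanConfig, run_plan
from ionarc.scenario import build_po2_map, build_scenario
from ionarc import io

log = logging.getLogger("ionarc")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    case_id: str = "A"
    ion: str = "carbon"
    technique: str = "sharc"
    voxel_size: float = 2.0
    slab_thickness: float = 20.0
    hypoxia: bool = False
    n_fractions: int = 10
    seed: int = 0
    outdir: str = "ionarc_out"
    beam_options: BeamModelOptions = field(default_factory=BeamModelOptions)
    photon: PhotonLQParams = field(default_factory=PhotonLQParams)
    mkm: MKMParams = field(default_factory=MKMParams)
    hypoxia_params: HypoxiaParams = field(default_factory=HypoxiaParams)
    n_outer: int = 3
    n_inner: int = 120

    def plan_config(self) -> PlanConfig:
        return PlanConfig(
            ion=get_ion(self.ion),
            technique=self.technique,
            slab_thickness=self.slab_thickness,
            n_outer=self.n_outer,
            n_inner=self.n_inner,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return io._jsonable(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["beam_options"] = BeamModelOptions(**{
            **d.get("beam_options", {}),
            "nuclear_mfp": tuple(map(tuple, d.get("beam_options", {}).get(
                "nuclear_mfp", BeamModelOptions().nuclear_mfp))),
        }) if "beam_options" in d else BeamModelOptions()
        for key, typ in (("photon", PhotonLQParams), ("mkm", MKMParams),
                         ("hypoxia_params", HypoxiaParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def run_pipeline(config: RunConfig, write: bool = True):
    """beamlib -> scenario -> plan -> optimize -> evaluate (-> artifacts).

    Returns (MetricsReport, PlanEvaluation); when ``write`` is set, grids go
    to NRRD, curves/plans to CSV and metrics to JSON under ``config.outdir``,
    with a checksum manifest.
    """
    np.random.seed(config.seed % 2**31)
    stage = "scenario"
    try:
        scen = build_scenario(config.case_id, config.voxel_size)
        if config.hypoxia:
            build_po2_map(scen)
        stage = "beam library"
        lib = BeamLibrary(options=config.beam_options)
        stage = "planning/optimization"
        pcfg = config.plan_config()
        plan, infl = run_plan(scen, pcfg, lib, config.photon, config.mkm)
        stage = "evaluation"
        ev = evaluate_plan(plan, infl, scen,
                           hypoxia=config.hypoxia_params if config.hypoxia else None)
        report = summarize(ev, TCPParams(n_fractions=config.n_fractions)
                           if config.hypoxia else None)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc

    if not plan.converged:
        log.warning("optimizer returned best iterate without full convergence")
    if plan.n_pruned:
        log.info("pruned %d sub-threshold spot columns", plan.n_pruned)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []

        def _vol(name, rows):
            g = np.full(scen.shape, np.nan)
            g.ravel()[infl.slab_rows] = rows
            p = outdir / f"{name}.nrrd"
            io.write_nrrd(p, g, scen.voxel_size)
            paths.append(p)

        _vol("d_rbe", ev.d_rbe)
        _vol("letd", ev.letd)
        _vol("dose", ev.dose)
        if ev.d_oer is not None:
            _vol("d_oer_rbe", ev.d_oer)

        dvh = report.curves["dvh_target"]
        pd.DataFrame({"d_rbe_gy": dvh.edges, "volume_fraction": dvh.volume_fraction}) \
            .to_csv(outdir / "dvh_target.csv", index=False)
        paths.append(outdir / "dvh_target.csv")
        letd_t = ev.letd[ev.masks["target"]]
        lvh = cumulative_histogram(letd_t[np.isfinite(letd_t)])
        pd.DataFrame({"letd_kev_um": lvh.edges, "volume_fraction": lvh.volume_fraction}) \
            .to_csv(outdir / "letdvh_target.csv", index=False)
        paths.append(outdir / "letdvh_target.csv")
        if ev.d_oer is not None:
            dcurve = delta_oer_vh(ev, ev.masks["target"])
            pd.DataFrame({"delta_oer": dcurve.edges,
                          "volume_fraction": dcurve.volume_fraction}) \
                .to_csv(outdir / "delta_oer_vh_target.csv", index=False)
            paths.append(outdir / "delta_oer_vh_target.csv")

        ss = plan.spotset
        pd.DataFrame({
            "angle_deg": np.repeat(ss.angles, ss.n_v),
            "u_mm": np.repeat(ss.us, ss.n_v),
            "v_mm": np.tile(ss.v_positions, ss.n_groups),
            "energy_MeV_u": np.repeat(ss.energies, ss.n_v),
            "weight_particles": np.repeat(ss.weights, ss.n_v),
        }).to_csv(outdir / "plan_spots.csv", index=False)
        paths.append(outdir / "plan_spots.csv")

        fluence = angular_fluence_map(plan)
        io.write_json(outdir / "angular_fluence.json", fluence)
        paths.append(outdir / "angular_fluence.json")
        io.write_json(outdir / "metrics.json", report.metrics)
        paths.append(outdir / "metrics.json")
        io.write_json(outdir / "run_config.json", config.to_dict())
        paths.append(outdir / "run_config.json")
        io.write_manifest(outdir, paths)
    return report, ev


def make_fixtures(seed: int = 0) -> dict:
    """Miniature, fully deterministic test assets.

    Coarse-grid beam tables, a 4 mm-voxel scenario, a 5-spot toy plan layout
    and random mixed-field voxels with brute-force oracle answers.
    """
    rng = np.random.default_rng(seed)
    opts = BeamModelOptions(depth_step=0.5, tail_length=60.0)
    tables = {
        label: build_depth_profile(get_ion(label), e, opts)
        for label, e in (("proton", 120.0), ("helium", 120.0), ("carbon", 220.0))
    }
    scen = build_scenario("A", voxel_size=4.0)
    spots = [(float(a), float(u)) for a, u in
             zip((0.0, 72.0, 144.0, 216.0, 288.0), (-6.0, -3.0, 0.0, 3.0, 6.0))]

    n_comp = 10
    doses = rng.uniform(0.1, 2.0, n_comp)
    lets = rng.uniform(0.5, 120.0, n_comp)
    letd_oracle = float(np.sum(doses * lets) / np.sum(doses))
    return {
        "seed": seed,
        "beam_tables": tables,
        "scenario": scen,
        "toy_spots": spots,
        "mixed_field": {"doses": doses, "lets": lets, "letd_oracle": letd_oracle},
    }
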