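"""Shared fixtures: beam library and (lazily built) optimized study plans.

The full-study fixtures run the actual planning pipeline at the package's
desk-scale settings (2 mm voxels, 12 mm evaluation slab) and are session
scoped so the acceptance tests share one optimization per plan.
"""

from __future__ import annotations

import numpy as np
import pytest

from ionarc.beam import BeamLibrary
from ionarc.evaluation import TCPParams, evaluate_plan, summarize
from ionarc.hypoxia import HypoxiaParams
from ionarc.ions import get_ion
from ionarc.planning import (
    PlanConfig,
    compute_influence,
    optimize_weights,
    place_spots,
    prune_spots,
)
from ionarc.scenario import build_po2_map, build_scenario

SLAB_MM = 12.0


@pytest.fixture(scope="session")
def library() -> BeamLibrary:
    return BeamLibrary()


@pytest.fixture(scope="session")
def case_a() :
    return build_scenario("A", 2.0)


@pytest.fixture(scope="session")
def case_b():
    scen = build_scenario("B", 2.0)
    build_po2_map(scen)
    return scen


class StudyRun:
    """One optimized plan plus its evaluation and summary metrics."""

    def __init__(self, scen, library, ion_label, technique, hypoxia=False):
        cfg = PlanConfig(ion=get_ion(ion_label), technique=technique,
                         slab_thickness=SLAB_MM)
        ss = place_spots(scen, cfg)
        infl = compute_influence(scen, ss, library, cfg)
        plan = optimize_weights(infl, scen, cfg)
        self.pre_prune = plan
        plan = prune_spots(plan, infl, scen)
        self.scenario = scen
        self.config = cfg
        self.spotset = ss
        self.influence = infl
        self.plan = plan
        self.ev = evaluate_plan(plan, infl, scen,
                                hypoxia=HypoxiaParams() if hypoxia else None)
        self.report = summarize(self.ev, TCPParams() if hypoxia else None)
        infl.release()  # the suite keeps many runs alive; drop the matrices

    @property
    def metrics(self):
        return self.report.metrics


@pytest.fixture(scope="session")
def run_cache(library, case_a, case_b):
    cache = {}

    def get(case_id: str, ion: str, technique: str, hypoxia: bool = False) -> StudyRun:
        key = (case_id, ion, technique, hypoxia)
        if key not in cache:
            scen = case_a if case_id == "A" else case_b
            cache[key] = StudyRun(scen, library, ion, technique, hypoxia=hypoxia)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sharc_carbon_case_a(run_cache) -> StudyRun:
    return run_cache("A", "carbon", "sharc")
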