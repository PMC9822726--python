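import numpy as np
import pytest

from dropmet import synthgen as sg
from dropmet.pipeline import run_dataset
from dropmet.scenario import ScenarioConfig


@pytest.fixture(scope="session")
def mpr_config():
    return ScenarioConfig.preset("mpr_run")


@pytest.fixture(scope="session")
def cohort_config():
    return ScenarioConfig.preset("cohort")


@pytest.fixture(scope="session")
def panel(mpr_config):
    return sg.panel_for(mpr_config)


@pytest.fixture(scope="session")
def mpr_run(panel, mpr_config):
    """One rendered single-runner dataset (peak tables + metadata + truth)."""
    tables, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=11)
    return tables, meta, gt


@pytest.fixture(scope="session")
def mpr_pipeline(panel, mpr_config, mpr_run):
    """The rendered dataset pushed through the full preprocessing chain."""
    tables, meta, gt = mpr_run
    return run_dataset(panel, tables, meta, ground_truth=gt)


@pytest.fixture(scope="session")
def cohort_truth(cohort_config):
    """Cohort ground truth + metadata at the abundance level (no rendering)."""
    panel_c = sg.panel_for(cohort_config)
    _, meta, gt = sg.simulate_cohort(panel_c, cohort_config, seed=5, render=False)
    return panel_c, meta, gt


def random_peak(rng, peak_id="P", rt=100.0, sn=50.0, n_masses=4, n_scans=6):
    from dropmet.peakio import Peak

    masses = rng.choice(np.arange(70, 601), size=n_masses, replace=False)
    traces = {int(m): rng.uniform(1, 100, size=n_scans) for m in masses}
    return Peak(peak_id=peak_id, apex_rt_s=rt, sn=sn, traces=traces)
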