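"""Shared fixtures: one default synthetic cohort and its heavyweight
derived objects (resampling log, final clustering) are computed once per
session and reused by the unit and acceptance tests."""

import numpy as np
import pytest

import fcbiotype as fb

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """One default-design synthetic cohort (151 CHR + 88 HC, 246 ROIs)."""
    design = fb.SimulationDesign(seed=DEFAULT_SEED)
    cohort, stack, truth = fb.simulate_cohort(design)
    return design, cohort, stack, truth


@pytest.fixture(scope="session")
def chr_data(default_sim):
    """(edges, items) restricted to the patient group."""
    _, cohort, stack, _ = default_sim
    chr_idx = np.flatnonzero(cohort.group_mask("CHR"))
    edges = stack.edges[chr_idx]
    items = cohort.clinical_items(chr_idx).to_numpy(dtype=float)
    return edges, items


@pytest.fixture(scope="session")
def selection(chr_data):
    edges, items = chr_data
    return fb.screen_and_select(edges, items)


@pytest.fixture(scope="session")
def resample_log(chr_data):
    """100-iteration subsampling log on the default cohort."""
    edges, items = chr_data
    return fb.subsample_loop(edges, items, n_iter=100, seed=11)


@pytest.fixture(scope="session")
def final_solution(chr_data, selection, resample_log):
    """Final clustering at the modal cluster number."""
    edges, _ = chr_data
    modal_k, _ = resample_log.modal_k()
    sol, learned, _ = fb.simlr(
        edges[:, selection.selected_edges], k=modal_k, seed=13
    )
    return sol, learned


@pytest.fixture(scope="session")
def small_atlas():
    """60-ROI atlas with all eight networks, for scaled-down simulations."""
    return fb.make_atlas(
        {
            "visual": 8, "somatomotor": 9, "dorsal_attention": 7,
            "ventral_attention": 6, "limbic": 6, "frontoparietal": 7,
            "default": 9, "subcortical": 8,
        }
    )
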