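"""Simulator and renderer: forced outcomes, analytic laws, conservation."""

from __future__ import annotations

import dataclasses
import time

import numpy as np
import pytest
from scipy.stats import chisquare

import collapse_kinetics as ck
from conftest import one_frame_law


def test_certain_detachment_empties_region_in_one_step():
    params = ck.SimulationParams(pa=0.0, pd=1.0, p_nuc=0.0, n_frames=5,
                                 initial_regions=((64.0, 3),), seed=0)
    trace = ck.simulate_cluster_dynamics(params)
    detaches = [e for e in trace.events if e.kind == "detach"]
    assert len(detaches) == 3
    assert all(e.frame == 1 for e in detaches)
    occupancy = [sum(s.occupancy for s in fr) for fr in trace.frames]
    assert occupancy[0] == 3
    assert all(o == 0 for o in occupancy[1:])


def test_no_detachment_channel_gives_nondecreasing_occupancy():
    params = ck.SimulationParams(pa=0.3, pd=0.0, p_nuc=0.0, n_frames=80,
                                 initial_regions=((64.0, 1),), seed=1)
    trace = ck.simulate_cluster_dynamics(params)
    series = trace.count_series()
    assert len(series) == 1
    assert np.all(np.diff(series[0]) >= 0)


def test_same_seed_gives_bit_identical_trace():
    params = ck.SimulationParams(seed=42, n_frames=60)
    a = ck.simulate_cluster_dynamics(params)
    b = ck.simulate_cluster_dynamics(params)
    assert a.events == b.events
    assert a.frames == b.frames


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        ck.SimulationParams(pa=1.2)
    with pytest.raises(ValueError):
        ck.SimulationParams(pd=-0.1)
    with pytest.raises(ValueError):
        ck.SimulationParams(pc={3: 1.5})


def test_event_log_explains_every_occupancy_change():
    """Frame-to-frame occupancy differences must be fully accounted for by
    logged attach/detach/collapse/nucleate events."""
    pc = {n: 0.1 for n in range(2, 13)}
    params = ck.SimulationParams(pc=pc, n_frames=250, seed=7)
    trace = ck.simulate_cluster_dynamics(params)
    by_frame: dict[int, list] = {}
    for e in trace.events:
        by_frame.setdefault(e.frame, []).append(e)
    prev = {s.region_id: s.occupancy for s in trace.frames[0]}
    for f in range(1, trace.n_frames):
        now = {s.region_id: s.occupancy for s in trace.frames[f]}
        delta = {rid: now.get(rid, 0) - prev.get(rid, 0)
                 for rid in set(now) | set(prev)}
        expected = dict.fromkeys(delta, 0)
        for e in by_frame.get(f, []):
            if e.kind == "attach" or e.kind == "nucleate":
                expected[e.region_id] += 1
            elif e.kind == "detach":
                expected[e.region_id] -= 1
            elif e.kind == "collapse":
                expected[e.region_id] -= e.n_before
        assert delta == expected, f"frame {f}"
        prev = now


@pytest.mark.parametrize("start_size", [2, 4])
def test_one_frame_transitions_match_analytic_law(start_size):
    """Aggregated single-frame outcomes from many replicate simulations must
    follow the closed-form collapse/binomial-detachment/attachment law within
    3 standard errors per outcome, and pass a chi-square GOF test."""
    pa, pd = 0.15, 0.0554
    n_rep = 6000
    ss = np.random.SeedSequence(start_size).generate_state(n_rep)
    outcomes = np.zeros(start_size + 2, dtype=int)
    for s in ss:
        params = ck.SimulationParams(pa=pa, pd=pd, p_nuc=0.0, n_frames=2,
                                     initial_regions=((64.0, start_size),),
                                     seed=int(s) & 0x7FFFFFFF)
        trace = ck.simulate_cluster_dynamics(params)
        occ = sum(s_.occupancy for s_ in trace.frames[1])
        outcomes[occ] += 1
    law = one_frame_law(start_size, pa, pd)
    probs = np.array([law.get(j, 0.0) for j in range(start_size + 2)])
    freqs = outcomes / n_rep
    for j in range(start_size + 2):
        se = np.sqrt(max(probs[j] * (1 - probs[j]), 1e-12) / n_rep)
        assert abs(freqs[j] - probs[j]) <= 3 * se + 1e-9, f"{start_size}->{j}"
    # chi-square on outcomes with expected count >= 5; pool the sparse tail
    keep = probs * n_rep >= 5
    obs, exp = outcomes[keep], probs[keep] * n_rep
    if (~keep).any() and probs[~keep].sum() > 0:
        obs = np.append(obs, outcomes[~keep].sum())
        exp = np.append(exp, probs[~keep].sum() * n_rep)
    assert chisquare(obs, exp, sum_check=False).pvalue > 0.01


def test_collapse_channel_exceeds_binomial_complete_detachment():
    pc = {n: 0.15 for n in range(2, 13)}
    params = ck.SimulationParams(pc=pc, pd=0.0554, n_frames=3000, seed=3)
    trace = ck.simulate_cluster_dynamics(params)
    counts = ck.count_transitions(trace.count_series(), n_max=6)
    m = ck.to_matrix(counts, mode="per_frame")
    for i in range(2, 7):
        if counts.exposure[i] >= 30:
            assert m.p[i, 0] > 0.0554 ** i, f"size {i}"


def test_render_empty_trace_is_flat_background(noiseless_imaging):
    params = ck.SimulationParams(pa=0.0, pd=0.0, p_nuc=0.0, n_frames=5, seed=0)
    trace = ck.simulate_cluster_dynamics(params)
    imaging = dataclasses.replace(noiseless_imaging, background_offset=37.0)
    k = ck.render_kymograph(trace, imaging)
    assert np.allclose(k.intensity, 37.0)


@pytest.mark.parametrize("n_myosins", [1, 3])
def test_render_conserves_integrated_intensity(n_myosins, noiseless_imaging):
    params = ck.SimulationParams(pa=0.0, pd=0.0, p_nuc=0.0, n_frames=3,
                                 initial_regions=((64.0, n_myosins),), seed=0)
    trace = ck.simulate_cluster_dynamics(params)
    k = ck.render_kymograph(trace, noiseless_imaging)
    total = k.intensity[0].sum()
    expected = n_myosins * noiseless_imaging.unit_intensity
    assert abs(total - expected) <= 0.01 * expected


def test_generate_dataset_reproducible_and_replicates_differ():
    params = ck.SimulationParams(n_frames=40)
    imaging = ck.ImagingParams()
    a = ck.generate_dataset(params, imaging, 2, seed=5)
    b = ck.generate_dataset(params, imaging, 2, seed=5)
    for (ka, ta), (kb, tb) in zip(a, b):
        assert np.array_equal(ka.intensity, kb.intensity)
        assert ta.events == tb.events
    assert not np.array_equal(a[0][0].intensity, a[1][0].intensity)


def test_dataset_generation_speed_paper_scale():
    t0 = time.time()
    ck.generate_dataset(ck.SimulationParams(), ck.ImagingParams(), 20, seed=9)
    assert time.time() - t0 < 60.0
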