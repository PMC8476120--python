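"""Transition counting, matrices, the predicted model and rate inversion."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import collapse_kinetics as ck
from collapse_kinetics.transitions import (
    KineticParams,
    compare_collapse_to_prediction,
    count_transitions,
    detachment_probability,
    estimate_pa,
    invert_collapse_to_rate,
    pool_counts,
    predicted_matrix,
    read_transition_table_excel,
    to_matrix,
)


# ----------------------------------------------------------------- counting

def test_count_transitions_basic_series():
    c = count_transitions([np.array([2, 2, 1, 1, 0], float)])
    assert c.counts[2, 1] == 1
    assert c.counts[1, 0] == 1
    assert c.n_transitions == 2
    assert c.exposure[2] == 2 and c.exposure[1] == 2


def test_complete_collapse_pair_counted():
    c = count_transitions([np.array([3.0, 0.0])])
    assert c.counts[3, 0] == 1
    assert c.n_transitions == 1


def test_sizes_above_cap_discarded():
    c = count_transitions([np.array([7.0, 3.0])], n_max=6)
    assert c.n_transitions == 0
    assert c.exposure.sum() == 0


def test_missing_values_break_pairs():
    c = count_transitions([np.array([2, np.nan, 1, 0])])
    assert c.counts[1, 0] == 1
    assert c.n_transitions == 1


def test_single_transition_normalises_to_one():
    m = to_matrix(count_transitions([np.array([2.0, 1.0])]))
    assert m.p[2, 1] == 1.0
    assert m.p[2, [0, 2, 3, 4, 5, 6]].sum() == 0.0


def test_row_normalisation_matches_worked_example():
    # row 4 with counts {4->3: 20, 4->5: 5, 4->0: 75}: releasing one head has
    # probability 20%, one head binding 5%
    series = ([[4, 3]] * 20 + [[4, 5]] * 5 + [[4, 0]] * 75)
    c = count_transitions([np.array(s, float) for s in series])
    m = to_matrix(c)
    assert m.p[4, 3] == pytest.approx(0.20)
    assert m.p[4, 5] == pytest.approx(0.05)
    assert m.p[4, 0] == pytest.approx(0.75)


def test_observed_rows_sum_to_one_and_diagonal_zero():
    rng = np.random.default_rng(0)
    series = [rng.integers(0, 7, size=30).astype(float) for _ in range(20)]
    m = to_matrix(count_transitions(series))
    for i in range(1, 7):
        assert m.p[i, i] == 0.0
        if m.row_totals[i] > 0:
            assert m.p[i].sum() == pytest.approx(1.0, abs=1e-9)


def test_empty_counts_rejected():
    with pytest.raises(ValueError):
        to_matrix(count_transitions([np.array([1.0, 1.0])]))


def test_pooling_concatenates_counts():
    a = count_transitions([np.array([2.0, 1.0])])
    b = count_transitions([np.array([2.0, 1.0]), np.array([2.0, 3.0])])
    pooled = pool_counts([a, b])
    assert pooled.counts[2, 1] == 2
    assert pooled.counts[2, 3] == 1


# ---------------------------------------------------------------- kinetics

def test_detachment_probability_at_published_conditions():
    k = KineticParams(k_T=1.9, atp_uM=0.1, frame_s=0.30)
    pd = detachment_probability(k)
    assert pd == pytest.approx(1 - math.exp(-0.19 * 0.30), rel=1e-12)
    assert round(100 * pd, 1) == 5.5  # 0.0554, quoted as ~5.6% at 2 s.f.
    assert k.detachment_rate_s == pytest.approx(0.19)


def test_detachment_probability_vanishes_at_zero_time():
    with pytest.raises(ValueError):
        KineticParams(frame_s=0.0)
    k = KineticParams(frame_s=1e-12)
    assert detachment_probability(k) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------- predicted model

def test_predicted_matrix_superdiagonal_is_pa():
    m = predicted_matrix(pa=0.15, pd=0.0554)
    for i in range(1, 6):
        assert m.p[i, i + 1] == pytest.approx(0.15)


def test_predicted_detachment_coefficient_matches_subset_enumeration():
    """Brute-force oracle: the number of ways n of i heads detach is the
    number of n-subsets of i, so the unnormalised entry is C(i,n) pd^n."""
    pa, pd = 0.15, 0.0554
    m = predicted_matrix(pa, pd)
    mf = predicted_matrix(pa, pd, full_binomial=True)
    from scipy.stats import binom

    for i in range(1, 7):
        for j in range(0, i):
            n = i - j
            n_subsets = sum(1 for _ in itertools.combinations(range(i), n))
            assert m.p[i, j] == pytest.approx(n_subsets * pd**n, rel=1e-12)
            assert mf.p[i, j] == pytest.approx(binom.pmf(n, i, pd), rel=1e-9)


def test_predicted_complete_detachment_is_pd_to_the_i():
    m = predicted_matrix(0.15, 0.0554)
    for i in range(1, 7):
        assert m.p[i, 0] == pytest.approx(0.0554**i, rel=1e-12)
    curve = ck.collapse_curve(m)
    logs = [math.log(p) for _, p, _ in curve]
    diffs = np.diff(logs)
    assert np.allclose(diffs, diffs[0])  # log-linear in cluster size


def test_predicted_matrix_normalisation_flag():
    m = predicted_matrix(0.15, 0.0554, normalise=True)
    assert m.normalised
    for i in range(1, 7):
        assert m.p[i].sum() == pytest.approx(1.0)


def test_predicted_matrix_rejects_degenerate_probabilities():
    with pytest.raises(ValueError):
        predicted_matrix(0.0, 0.5)
    with pytest.raises(ValueError):
        predicted_matrix(0.5, 1.0)


# ------------------------------------------------------------- Pa estimate

def test_estimate_pa_is_superdiagonal_mean():
    p = np.zeros((7, 7))
    p[1, 2] = 0.1
    p[2, 3] = 0.2
    m = ck.TransitionMatrix(n_max=6, p=p, row_totals=np.array([0, 5, 5, 0, 0, 0, 0]),
                            sem=np.full_like(p, np.nan), normalised=True,
                            mode="conditional")
    assert estimate_pa(m) == pytest.approx(0.15)


def test_estimate_pa_single_row():
    p = np.zeros((7, 7))
    p[3, 4] = 0.4
    m = ck.TransitionMatrix(n_max=6, p=p, row_totals=np.array([0, 0, 0, 9, 0, 0, 0]),
                            sem=np.full_like(p, np.nan), normalised=True,
                            mode="conditional")
    assert estimate_pa(m) == pytest.approx(0.4)


def test_estimate_pa_requires_attachment_observations():
    p = np.zeros((7, 7))
    m = ck.TransitionMatrix(n_max=6, p=p, row_totals=np.zeros(7),
                            sem=np.full_like(p, np.nan), normalised=True,
                            mode="conditional")
    with pytest.raises(ValueError):
        estimate_pa(m)


def test_estimate_pa_survival_correction_unbiased_on_simulated_per_frame():
    """On a long pc = 0 simulation the per-frame superdiagonal is
    pa (1-pd)^i; dividing out the survival factor recovers pa."""
    params = ck.SimulationParams(pa=0.15, pd=0.056, n_frames=20000,
                                 filament_length_px=256, seed=11)
    trace = ck.simulate_cluster_dynamics(params)
    m = to_matrix(count_transitions(trace.count_series()), mode="per_frame")
    pa_hat = estimate_pa(m, pd=0.056)
    assert pa_hat == pytest.approx(0.15, abs=0.02)


# ---------------------------------------------------------- rate inversion

def test_rate_inversion_is_exact_algebraic_inverse():
    for k_rate in (0.19, 3.0, 6.0):
        pd = 1 - math.exp(-k_rate * 0.3)
        for i in range(1, 7):
            back = invert_collapse_to_rate(pd**i, i, 0.3)
            assert back == pytest.approx(k_rate, rel=1e-9)


def test_rate_inversion_published_values():
    assert invert_collapse_to_rate(0.0554, 1, 0.3) == pytest.approx(0.19, abs=0.002)
    assert invert_collapse_to_rate(0.35, 2, 0.3) == pytest.approx(3.0, abs=0.05)


def test_rate_inversion_domain_checks():
    with pytest.raises(ValueError):
        invert_collapse_to_rate(0.0, 2, 0.3)
    with pytest.raises(ValueError):
        invert_collapse_to_rate(1.0, 2, 0.3)
    with pytest.raises(ValueError):
        invert_collapse_to_rate(0.5, 0, 0.3)


# ------------------------------------------------------------ collapse curve

def test_collapse_curve_sem_missing_for_single_kymograph():
    c = count_transitions([np.array([2.0, 0.0, 0.0])])
    m = to_matrix(c)
    curve = ck.collapse_curve(m)
    assert all(np.isnan(sem) for _, _, sem in curve)


def test_collapse_excess_detected_with_collapse_channel():
    pc = {n: 0.2 for n in range(2, 13)}
    params = ck.SimulationParams(pc=pc, n_frames=4000, seed=13)
    trace = ck.simulate_cluster_dynamics(params)
    m = to_matrix(count_transitions(trace.count_series()), mode="per_frame")
    rows = compare_collapse_to_prediction(m, pd=0.0554)
    compared = [r for r in rows if r["compared"] and r["size"] >= 2]
    assert compared
    assert all(r["exceeds"] for r in compared)


# ------------------------------------------------------------ Excel reader

def test_transition_table_excel_roundtrip(tmp_path):
    """Reader finds the numeric block in a source-data style sheet built
    here synthetically (labels around a 6 x 7 probability table)."""
    import openpyxl

    m = predicted_matrix(0.15, 0.0554, normalise=True)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws["A1"] = "transition probabilities"
    ws.cell(row=2, column=1, value="start\\final")
    for j in range(7):
        ws.cell(row=2, column=2 + j, value=j)
    for i in range(1, 7):
        ws.cell(row=2 + i, column=1, value=i)
        for j in range(7):
            ws.cell(row=2 + i, column=2 + j, value=float(m.p[i, j]))
    path = tmp_path / "synthetic_source_data.xlsx"
    wb.save(path)
    loaded = read_transition_table_excel(path)
    assert np.allclose(loaded.p[1:, :], m.p[1:, :], atol=1e-12)
    assert estimate_pa(loaded) == pytest.approx(estimate_pa(m))
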