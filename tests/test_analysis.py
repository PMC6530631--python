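"""Spike-train analysis: PSTH conventions, excited/inhibited rules,
burst-pause detection, the center-surround formulas and correlograms."""

import numpy as np
import pytest

from cerescaffold import analysis as A
from cerescaffold.netsim import SpikeRecord


def record(pairs, T=1000.0):
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    order = np.argsort(pairs[:, 1], kind="stable")
    return SpikeRecord(pairs[order, 0].astype(np.int64), pairs[order, 1], T)


# -------------------------------------------------------------------- psth

def test_psth_conventions():
    spk = record([(0, 3.0), (0, 5.9), (1, 6.0), (0, 950.0)])
    counts, edges = A.psth(spk, [0, 1], bin_ms=3.0)
    assert counts.sum() == 4
    assert counts[1] == 2          # 3.0 and 5.9 fall in [3, 6)
    assert counts[2] == 1          # 6.0 opens the next bin
    assert edges[0] == 0.0 and np.allclose(np.diff(edges), 3.0)


def test_psth_empty_record():
    spk = record(np.empty((0, 2)))
    counts, _ = A.psth(spk, [0], bin_ms=3.0)
    assert (counts == 0).all()


def test_psth_requires_positive_bin():
    with pytest.raises(ValueError):
        A.psth(record([(0, 1.0)]), [0], bin_ms=0.0)


# ---------------------------------------------------------- classification

BEFORE, DURING = (0.0, 300.0), (300.0, 350.0)


def train(nid, rate_before, n_during):
    t_b = np.linspace(1, 299, int(round(rate_before * 0.3)))
    t_d = np.linspace(301, 349, n_during)
    return [(nid, t) for t in np.r_[t_b, t_d]]


def test_excited_granule_cell_reference_case():
    # baseline 2 Hz, three spikes during 50 ms (120 Hz): excited
    spk = record(train(0, 2.0, 3))
    assert A.classify_response(spk, 0, BEFORE, DURING, grc_rule=True) == "excited"


def test_granule_single_spike_rule():
    # silent baseline with exactly one during-spike stays unchanged
    spk = record(train(0, 0.0, 1))
    assert A.classify_response(spk, 0, BEFORE, DURING, grc_rule=True) == "unchanged"
    # a non-granule cell with the same pattern counts as excited
    assert A.classify_response(spk, 0, BEFORE, DURING) == "excited"


def test_unchanged_when_rates_equal():
    spk = record(train(0, 20.0, 1))  # 20 Hz both windows
    assert A.classify_response(spk, 0, BEFORE, DURING) == "unchanged"


def test_inhibited_on_rate_halving():
    spk = record(train(0, 40.0, 1))  # 40 Hz -> 20 Hz
    assert A.classify_response(spk, 0, BEFORE, DURING) == "inhibited"
    spk = record(train(0, 40.0, 0))
    assert A.classify_response(spk, 0, BEFORE, DURING) == "inhibited"


def test_silent_baseline_never_inhibited():
    spk = record(train(0, 0.0, 0))
    assert A.classify_response(spk, 0, BEFORE, DURING) == "unchanged"


def test_classification_scale_invariant():
    # rescaling both windows (with proportionally scaled spike trains)
    # leaves the label unchanged
    spk1 = record(train(0, 10.0, 4))
    lab1 = A.classify_response(spk1, 0, BEFORE, DURING)
    half = [(0, t / 2.0) for _, t in train(0, 10.0, 4)]
    spk2 = record(half)
    lab2 = A.classify_response(spk2, 0, (0, 150.0), (150.0, 175.0))
    assert lab1 == lab2 == "excited"


def test_classify_population_matches_scalar():
    rows = train(0, 2.0, 3) + train(1, 40.0, 1) + train(2, 20.0, 1)
    spk = record(rows)
    labels = A.classify_population(spk, np.array([0, 1, 2]), BEFORE, DURING)
    expected = [A.classify_response(spk, i, BEFORE, DURING) for i in range(3)]
    assert labels.tolist() == expected


# ------------------------------------------------------------- burst-pause

def regular_pc(nid=0, isi=20.0, stop=350.0, resume=None):
    t = list(np.arange(isi, stop, isi))
    if resume is not None:
        t += list(np.arange(resume, 990.0, isi))
    return record([(nid, x) for x in t])


def test_pause_on_long_first_interval():
    # perfectly regular pre-train (sd = 0); first post-stimulus interval is
    # three times the mean -> pause
    spk = regular_pc(isi=20.0, stop=300.0, resume=340.0 + 20.0)
    label = A.detect_burst_pause(spk, 0, 300.0, 350.0, (0.0, 300.0))
    assert label == "pause"


def test_no_pause_at_exact_mean_interval():
    spk = regular_pc(isi=20.0, stop=351.0, resume=360.0)
    label = A.detect_burst_pause(spk, 0, 300.0, 350.0, (0.0, 300.0))
    assert label == "none"


def test_burst_and_pause_combined():
    pre = [(0, t) for t in np.arange(20.0, 300.0, 20.0)]  # 50 Hz baseline
    burst = [(0, t) for t in np.arange(301.0, 349.0, 4.0)]  # 250 Hz burst
    post = [(0, t) for t in np.arange(450.0, 990.0, 20.0)]  # 100 ms pause
    spk = record(pre + burst + post)
    label = A.detect_burst_pause(spk, 0, 300.0, 350.0, (0.0, 300.0))
    assert label == "burst_and_pause"


def test_undetermined_with_few_pre_intervals():
    spk = record([(0, 100.0), (0, 200.0), (0, 400.0)])
    label = A.detect_burst_pause(spk, 0, 300.0, 350.0, (0.0, 300.0))
    assert label == "undetermined"


def test_pause_false_positive_rate_on_poisson_null():
    # Null model: a stationary Poisson train has no stimulus-locked pause.
    # The interval straddling the stimulus end is length-biased
    # (pdf lambda^2 x e^(-lambda x)) and the 2-sd threshold is estimated
    # from the finite pre-window, so the exact false-positive rate comes
    # from an independent Monte-Carlo of that statistic (it approaches
    # (1 + 3) e^-3 = 0.199 as the pre-window grows).
    rng = np.random.default_rng(5)
    rate = 0.05  # spikes per ms (50 Hz)

    # oracle: direct simulation of the decision rule's ingredients
    oracle_rng = np.random.default_rng(99)
    oracle_hits = 0
    n_oracle = 20000
    for _ in range(n_oracle):
        # pre-window ISIs of a 300 ms window at 50 Hz (~14 intervals)
        isi = oracle_rng.exponential(1.0 / rate, size=14)
        thr = isi.mean() + 2.0 * isi.std()
        straddle = (oracle_rng.exponential(1.0 / rate)
                    + oracle_rng.exponential(1.0 / rate))  # length-biased
        oracle_hits += straddle > thr
    oracle = oracle_hits / n_oracle

    hits, n = 0, 1500
    for _ in range(n):
        t = np.cumsum(rng.exponential(1.0 / rate, size=200))
        spk = record([(0, x) for x in t if x < 1000.0])
        if A.detect_burst_pause(spk, 0, 300.0, 350.0, (0.0, 300.0)) \
                in ("pause", "burst_and_pause"):
            hits += 1
    assert hits / n == pytest.approx(oracle, abs=0.05)
    assert 0.1 < hits / n < 0.4  # in the regime the asymptotic tail implies


# ------------------------------------------------------------------- EI/CS

def test_ei_cs_toy_map_hand_computed():
    t1 = np.array([[10.0, 4.0, 0.0]])
    t2 = np.array([[8.0, 6.0, 2.0]])
    inoff = np.array([[8.0, 10.0, 8.0]])
    m = A.compute_EI_CS(t1, t2, inoff, np.arange(4.0), np.arange(2.0))
    assert np.allclose(m.EI, [[0.0, -4.0, -6.0]])
    # raw CS = (10, 8, 6); normalized by max |CS| = 10
    assert np.allclose(m.CS, [[1.0, 0.8, 0.6]])
    assert m.normalized
    assert m.center_mask.sum() == 3 and m.surround_mask.sum() == 0
    assert m.center_area == pytest.approx(1.0)


def test_ei_zero_when_inhibition_off_equals_control():
    t1 = np.array([[5.0, 1.0]])
    t2 = np.array([[4.0, 2.0]])
    m = A.compute_EI_CS(t1, t2, t2, np.arange(3.0), np.arange(2.0))
    assert np.allclose(m.EI, 0.0)
    assert np.allclose(m.CS * np.abs(t1).max(), t1)


def test_cs_normalization_bounds_and_masks_disjoint(rng):
    t1 = rng.normal(size=(20, 20)) * 10
    t2 = rng.normal(size=(20, 20)) * 10
    ino = rng.normal(size=(20, 20)) * 10
    m = A.compute_EI_CS(t1, t2, ino, np.arange(21.0), np.arange(21.0))
    assert (np.abs(m.CS) <= 1.0 + 1e-12).all()
    assert not (m.center_mask & m.surround_mask).any()


def test_cs_permutation_equivariance(rng):
    t1, t2, ino = (rng.random((1, 6)) for _ in range(3))
    m = A.compute_EI_CS(t1, t2, ino, np.arange(7.0), np.arange(2.0))
    perm = rng.permutation(6)
    mp = A.compute_EI_CS(t1[:, perm], t2[:, perm], ino[:, perm],
                         np.arange(7.0), np.arange(2.0))
    assert np.allclose(mp.CS[0], m.CS[0, perm])


def test_cs_all_zero_flagged():
    z = np.zeros((2, 2))
    m = A.compute_EI_CS(z, z, z, np.arange(3.0), np.arange(3.0))
    assert not m.normalized


def test_cs_requires_shared_grid():
    with pytest.raises(ValueError):
        A.compute_EI_CS(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)),
                        np.arange(3.0), np.arange(3.0))


# ------------------------------------------------------------ correlogram

def test_autocorrelogram_symmetric_peak_at_zero(rng):
    a = rng.poisson(5.0, size=500).astype(float)
    c = A.correlogram(a, None, 10.0, 1000.0)
    mid = len(c.values) // 2
    assert np.allclose(c.values[:mid], c.values[:mid:-1])
    assert c.values[mid] == pytest.approx(1.0)
    assert c.values.max() == c.values[mid]


def test_correlogram_periodic_signal_frequency():
    # 2 Hz periodic bursts -> first autocorrelation peak at 500 ms
    t = np.arange(0, 10_000.0, 10.0)
    a = (np.sin(2 * np.pi * 2.0 * t / 1000.0) > 0.95).astype(float)
    c = A.correlogram(a, None, 10.0, 2000.0)
    assert c.dominant_frequency == pytest.approx(2.0, abs=0.1)


def test_coherence_formula_on_constructed_arrays():
    flat = np.ones(100)  # zero variance -> correlation defined as zeros
    c = A.correlogram(flat - flat.mean() + np.r_[1.0, np.zeros(99)],
                      None, 1.0, 50.0)
    assert 0.0 <= c.coherence <= 1.0
    # white noise: coherence is dominated by the lag-0 term
    rng = np.random.default_rng(0)
    w = rng.normal(size=5000)
    cw = A.correlogram(w, None, 1.0, 100.0)
    assert cw.coherence == pytest.approx(np.mean(np.abs(cw.values)))
    assert cw.coherence < 0.05


def test_correlogram_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        A.correlogram(np.empty(0), None, 1.0, 10.0)
    with pytest.raises(ValueError):
        A.correlogram(np.ones(10), np.ones(11), 1.0, 10.0)


# ------------------------------------------------------------- mean rates

def test_mean_rates_windows():
    spk = record([(0, 50.0), (0, 150.0), (1, 250.0)])
    rt = A.mean_rates(spk, [0, 1], {"w": (0.0, 200.0), "empty": (500.0, 600.0)})
    assert rt.per_neuron["w"][0] == pytest.approx(10.0)   # 2 spikes / 0.2 s
    assert rt.per_neuron["w"][1] == pytest.approx(0.0)
    assert rt.population["empty"] == (0.0, 0.0)
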