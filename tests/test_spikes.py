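import numpy as np
import pytest

from gazecells.config import NeuronSpec
from gazecells.spikes import (
    CLASS_TEMPLATES,
    contralateral_eye,
    default_population,
    generate_spike_population,
    sample_spikes_thinning,
    waveform_template,
    saccade_gaze_angles,
)


def test_contralateral_eye():
    assert contralateral_eye("left") == 1
    assert contralateral_eye("right") == 0
    with pytest.raises(ValueError):
        contralateral_eye("dorsal")


def test_thinning_homogeneous_poisson(rng):
    """Constant rate: count matches lambda*T and Fano factor is ~1."""
    lam, T, fs = 20.0, 50.0, 300.0
    counts = []
    for _ in range(60):
        times = sample_spikes_thinning(np.full(int(T * fs), lam), fs, rng)
        assert np.all((times >= 0) & (times <= T))
        counts.append(len(times))
    counts = np.asarray(counts, float)
    assert counts.mean() == pytest.approx(lam * T, rel=0.05)
    fano = counts.var() / counts.mean()
    assert 0.6 < fano < 1.5


def test_thinning_inhomogeneous_rate_recovery(rng):
    """A step-rate profile is recovered in the spike histogram."""
    fs = 300.0
    rate = np.concatenate([np.full(3000, 5.0), np.full(3000, 40.0)])
    times = np.concatenate(
        [sample_spikes_thinning(rate, fs, rng) for _ in range(30)]
    )
    edges = np.array([0.0, 10.0, 20.0])
    counts, _ = np.histogram(times, bins=edges)
    r1, r2 = counts / (30 * 10.0)
    assert r1 == pytest.approx(5.0, rel=0.1)
    assert r2 == pytest.approx(40.0, rel=0.1)


def test_thinning_zero_rate():
    assert len(sample_spikes_thinning(np.zeros(100), 300.0, np.random.default_rng(0))) == 0


def test_waveform_template_shape():
    wf = waveform_template(0.5, 0.3)
    assert len(wf) == 90
    itr = int(np.argmin(wf))
    assert wf[itr] < 0
    post = wf[itr:]
    assert post.max() > 0
    # asymmetry: post-trough peak larger than pre-trough peak for asym > 0
    pre_peak = wf[:itr].max() if itr > 0 else 0.0
    assert post.max() > pre_peak


def test_waveform_width_monotone():
    narrow = waveform_template(0.27, 0.5)
    wide = waveform_template(0.6, 0.5)
    fs = 30000.0

    def width(wf):
        itr = int(np.argmin(wf))
        return (itr + int(np.argmax(wf[itr:])) - itr) / fs * 1000.0

    def trough_to_peak(wf):
        itr = int(np.argmin(wf))
        return int(np.argmax(wf[itr:])) / fs * 1000.0

    assert trough_to_peak(wide) > trough_to_peak(narrow)


def test_population_metadata_consistent(arena, rng, short_session, calib):
    trace, events, truth = short_session
    specs = default_population(6, 2, 2, arena, rng)
    assert len(specs) == 10
    types = [s.cell_type for s in specs]
    assert types.count("excitatory") == 6
    spikes, waveforms, cells = generate_spike_population(
        specs, trace, truth.saccades, events.light_state, arena, calib, rng,
        trials=events.trials,
    )
    assert waveforms.shape == (10, 90)
    assert set(spikes["cell_id"]) <= set(cells["cell_id"])
    assert (spikes["t"] >= trace.t[0]).all() and (spikes["t"] <= trace.t[-1]).all()
    # higher baseline-rate templates for interneurons than excitatory cells
    exc = cells[cells["cell_type"] == "excitatory"]["mean_rate"].median()
    inh = cells[cells["cell_type"] != "excitatory"]["mean_rate"].median()
    assert inh > exc


def test_gaze_tuned_cell_fires_more_at_preferred_site(
    arena, calib, rng, short_session
):
    """Spike counts after saccades increase with gaze closeness."""
    trace, events, truth = short_session
    spec = NeuronSpec(
        cell_type="excitatory", baseline_rate=2.0, preferred_site=1,
        gaze_gain=25.0, place_gain=0.0,
    )
    spikes, _, _ = generate_spike_population(
        [spec], trace, truth.saccades, events.light_state, arena, calib, rng,
        trials=events.trials,
    )
    st = np.sort(spikes["t"].to_numpy())
    _, a_next = saccade_gaze_angles(trace, truth.saccades, arena, calib)
    contra = contralateral_eye("left")
    alpha = a_next[:, contra, 1]
    tp = truth.saccades["t_peak"].to_numpy()
    lo = np.searchsorted(st, tp)
    hi = np.searchsorted(st, tp + 0.3)
    counts = (hi - lo).astype(float)
    ok = np.isfinite(alpha)
    near = counts[ok & (alpha < 30)].mean()
    far = counts[ok & (alpha > 60)].mean()
    assert near > 1.5 * far


def test_generation_deterministic(arena, calib, short_session):
    trace, events, truth = short_session
    specs = default_population(3, 1, 1, arena, np.random.default_rng(11))
    out = []
    for _ in range(2):
        rng = np.random.default_rng(33)
        spikes, wf, cells = generate_spike_population(
            specs, trace, truth.saccades, events.light_state, arena, calib,
            rng, trials=events.trials,
        )
        out.append((spikes, wf))
    assert np.array_equal(out[0][0]["t"].to_numpy(), out[1][0]["t"].to_numpy())
    assert np.array_equal(out[0][1], out[1][1])


def test_class_templates_cover_three_types():
    assert set(CLASS_TEMPLATES) == {"excitatory", "inh_peak", "inh_trough"}
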