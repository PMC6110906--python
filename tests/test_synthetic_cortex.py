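import numpy as np
import pytest
from scipy import stats

from foldnet import synthetic_cortex as syn


def long_paradigm(n_volumes):
    """Block design with the standard timing stretched to n_volumes."""
    events, t = [], 0.0
    block = 0
    while t + 21.0 <= n_volumes * 0.72:
        cond = "face" if block % 2 == 0 else "shape"
        events.append((t, 3.0, "cue"))
        for k in range(6):
            events.append((t + 3.0 + 3.0 * k, 3.0, cond))
        t += 21.0
        block += 1
    return syn.TaskParadigm(tr=0.72, n_volumes=n_volumes, events=events)


class TestMakeSurface:
    def test_pcurv_at_crest_and_fundus(self):
        mesh = syn.make_surface(16, 4, fold_period=8.0, spacing=2.0)
        crest = np.flatnonzero(np.isclose(mesh.vertex_coords[:, 0], 2.0))
        fundus = np.flatnonzero(np.isclose(mesh.vertex_coords[:, 0], 6.0))
        assert np.allclose(mesh.pcurv[crest], 1.0)
        assert np.allclose(mesh.pcurv[fundus], -1.0)

    def test_gyral_fraction_matches_enumeration(self):
        mesh = syn.make_surface(64, 8, fold_period=8.0)  # spacing = 1 mm
        # oracle: enumerate x coordinates and count sine sign
        xs = mesh.vertex_coords[:, 0]
        expected = np.mean(np.sin(2 * np.pi * xs / 8.0) >= 0)
        assert np.mean(mesh.pcurv >= 0) == expected
        assert abs(expected - 0.5) < 0.1  # ~half plus the pcurv == 0 lines

    def test_alternating_stripes(self):
        mesh = syn.make_surface(32, 4, fold_period=8.0)
        assert np.any(mesh.pcurv >= 0) and np.any(mesh.pcurv < 0)

    def test_face_indices_valid(self):
        mesh = syn.make_surface(8, 5, fold_period=4.0)
        assert mesh.faces.min() >= 0
        assert mesh.faces.max() < mesh.n_vertices
        assert mesh.faces.shape == (2 * 7 * 4, 3)

    @pytest.mark.parametrize("nx,ny,period", [(3, 8, 4.0), (8, 3, 4.0), (8, 8, 0.0)])
    def test_invalid_parameters(self, nx, ny, period):
        with pytest.raises(ValueError):
            syn.make_surface(nx, ny, period)


class TestMakeParadigm:
    def test_volume_count_and_tr(self, paradigm):
        assert paradigm.n_volumes == 176
        assert paradigm.tr == 0.72

    def test_total_duration(self, paradigm):
        assert paradigm.duration == pytest.approx(176 * 0.72)

    def test_block_structure(self, paradigm):
        cues = [e for e in paradigm.events if e[2] == "cue"]
        assert len(cues) == 6
        # each block spans cue (3 s) + 6 trials x 3 s = 21 s
        starts = sorted(o for o, _, _ in cues)
        assert np.allclose(np.diff(starts), 21.0)
        faces = [e for e in paradigm.events if e[2] == "face"]
        shapes = [e for e in paradigm.events if e[2] == "shape"]
        assert len(faces) == 18 and len(shapes) == 18  # 3 blocks x 6 trials each

    def test_events_within_scan(self, paradigm):
        for onset, dur, _ in paradigm.events:
            assert onset + dur <= paradigm.duration + 1e-9


class TestHrf:
    def test_empty_condition_gives_zero_series(self):
        par = syn.TaskParadigm(tr=0.72, n_volumes=50,
                               events=[(0.0, 0.0, "face")])
        assert np.all(syn.hrf_convolve(par, "face") == 0)

    def test_unknown_condition_raises(self, paradigm):
        with pytest.raises(ValueError):
            syn.hrf_convolve(paradigm, "house")

    def test_impulse_equals_gamma_density(self):
        par = syn.TaskParadigm(tr=0.72, n_volumes=100,
                               events=[(0.0, 0.72, "face")])
        out = syn.hrf_convolve(par, "face", undershoot_ratio=0.0)
        t = np.arange(100) * 0.72
        expected = stats.gamma.pdf(t, a=7.0, scale=1.0)  # density peaking at 6 s
        assert np.allclose(out, expected, atol=1e-12)

    def test_impulse_argmax_at_volume_8(self):
        par = syn.TaskParadigm(tr=0.72, n_volumes=100,
                               events=[(0.0, 0.72, "face")])
        out = syn.hrf_convolve(par, "face")
        assert int(np.argmax(out)) == round(6 / 0.72) == 8


class TestTemplates:
    def test_tiny_radius_gives_singleton(self, mesh):
        nets = syn.make_network_templates(mesh, 1, 1, radius=0.4, seed=0)
        assert len(nets) == 1 and len(nets[0]) == 1

    def test_networks_pairwise_disjoint(self, mesh):
        nets = syn.make_network_templates(mesh, 2, 2, radius=4.0, seed=1)
        assert nets[0].isdisjoint(nets[1])

    def test_each_ball_spans_both_phases(self, mesh):
        # radius >= fold_period / 2 guarantees both stripes are hit
        rois = syn.make_network_rois(mesh, 2, 2, radius=4.0, seed=2)
        for net in rois:
            for ball in net:
                curv = np.array([mesh.pcurv[v] for v in ball])
                assert np.any(curv >= 0) and np.any(curv < 0)

    def test_ball_contents_match_brute_force(self, mesh):
        rois = syn.make_network_rois(mesh, 1, 1, radius=3.0, seed=3)
        ball = rois[0][0]
        xy = mesh.vertex_coords[:, :2]
        some = next(iter(ball))
        # oracle: the ball must be exactly the vertices within radius of
        # the center; recover the center as the vertex minimizing max dist
        dmat = np.linalg.norm(xy[:, None] - xy[sorted(ball)][None], axis=2)
        center = int(np.argmin(dmat.max(axis=1)))
        expected = set(np.flatnonzero(
            np.linalg.norm(xy - xy[center], axis=1) <= 3.0 + 1e-9).tolist())
        assert ball == expected

    def test_placement_failure_raises(self):
        mesh = syn.make_surface(4, 4, fold_period=2.0, spacing=0.5)
        with pytest.raises(RuntimeError):
            syn.make_network_templates(mesh, 9, 3, radius=1.5, seed=0,
                                       max_tries=200)

    def test_invalid_parameters(self, mesh):
        with pytest.raises(ValueError):
            syn.make_network_templates(mesh, 0, 1, radius=1.0, seed=0)
        with pytest.raises(ValueError):
            syn.make_network_templates(mesh, 1, 1, radius=-1.0, seed=0)


class TestSimulateSignals:
    def test_noise_free_columns_are_scalar_multiples(self, mesh, paradigm):
        nets = syn.make_network_templates(mesh, 1, 1, radius=4.0, seed=4)
        truth = syn.make_ground_truth(mesh, nets, paradigm, delta=0.0,
                                      sigma=0.0, seed=5)
        X = syn.simulate_signals(mesh, paradigm, truth)
        a = truth.atom_timecourses[0]
        for v in sorted(nets[0]):
            assert abs(abs(stats.pearsonr(X[:, v], a)[0]) - 1.0) < 1e-12

    def test_determinism(self, mesh, paradigm):
        nets = syn.make_network_templates(mesh, 2, 1, radius=4.0, seed=6)
        truth = syn.make_ground_truth(mesh, nets, paradigm, seed=7)
        X1 = syn.simulate_signals(mesh, paradigm, truth)
        X2 = syn.simulate_signals(mesh, paradigm, truth)
        assert np.array_equal(X1, X2)

    def test_invalid_parameters(self, mesh, paradigm):
        nets = syn.make_network_templates(mesh, 1, 1, radius=4.0, seed=8)
        with pytest.raises(ValueError):
            syn.make_ground_truth(mesh, nets, paradigm, delta=-0.1)
        with pytest.raises(ValueError):
            syn.make_ground_truth(mesh, nets, paradigm, sigma=-0.1)

    def test_monte_carlo_correlations_match_closed_form(self):
        # delta=1, sigma=0.5, w=1: sulcal r = 1/sqrt(2.25), gyral 1/sqrt(1.25)
        mesh = syn.make_surface(16, 4, 8.0)
        par = long_paradigm(12096)
        nets = syn.make_network_templates(mesh, 1, 1, radius=4.0, seed=0)
        truth = syn.make_ground_truth(mesh, nets, par, delta=1.0, sigma=0.5,
                                      seed=3)
        X = syn.simulate_signals(mesh, par, truth)
        a = truth.atom_timecourses[0]
        tset = sorted(nets[0])
        g = [v for v in tset if mesh.pcurv[v] >= 0]
        s = [v for v in tset if mesh.pcurv[v] < 0]
        rg = np.mean([stats.pearsonr(X[:, v], a)[0] for v in g])
        rs = np.mean([stats.pearsonr(X[:, v], a)[0] for v in s])
        assert rg == pytest.approx(1 / np.sqrt(1.25), abs=0.02)
        assert rs == pytest.approx(1 / np.sqrt(2.25), abs=0.02)

    def test_null_exchangeability_ignores_curvature(self, mesh, paradigm):
        # with delta = 0 the generator never consults pcurv
        nets = syn.make_network_templates(mesh, 1, 2, radius=4.0, seed=9)
        truth = syn.make_ground_truth(mesh, nets, paradigm, delta=0.0, seed=10)
        X1 = syn.simulate_signals(mesh, paradigm, truth)
        flipped = syn.SurfaceMesh(mesh.vertex_coords, mesh.faces, -mesh.pcurv)
        X2 = syn.simulate_signals(flipped, paradigm, truth)
        assert np.array_equal(X1, X2)

    def test_gap_monotone_in_delta(self):
        import dataclasses

        from foldnet import pipeline as pl
        cfg0 = pl.PipelineConfig(seed=0, nx=32, ny=16, k_networks=2,
                                 rois_per_network=2, m_atoms=20, n_perm=50)
        gaps = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            per_seed = []
            for s in (11, 12, 13):
                cfg = dataclasses.replace(cfg0, delta=delta, seed=s)
                rep = pl.run_pipeline(cfg)
                pooled = rep.accuracy_summary.iloc[-1]
                per_seed.append(pooled["mean_gyri"] - pooled["mean_sulci"])
            gaps.append(np.mean(per_seed))
        assert all(b > a - 0.01 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] > gaps[0]


class TestSimulateFa:
    def test_affine_no_noise_gives_r_1(self, mesh):
        rep = np.linspace(0.2, 0.9, mesh.n_vertices)
        fa = syn.simulate_fa(mesh, rep, b0=0.0, b1=0.5, sd=0.0, seed=0)
        assert stats.pearsonr(fa, rep)[0] == pytest.approx(1.0)

    def test_b1_zero_uncorrelated(self, mesh):
        rng = np.random.default_rng(0)
        rep = rng.uniform(0.2, 0.9, mesh.n_vertices)
        fa = syn.simulate_fa(mesh, rep, b0=0.5, b1=0.0, sd=0.05, seed=1)
        assert abs(stats.pearsonr(fa, rep)[0]) < 0.2

    def test_seeded_example_in_band(self, mesh):
        rng = np.random.default_rng(2)
        rep = rng.uniform(0.6, 1.0, mesh.n_vertices)
        fa = syn.simulate_fa(mesh, rep, b0=0.3, b1=0.3, sd=0.05, seed=3)
        r = stats.pearsonr(fa, rep)[0]
        assert 0.3 < r < 0.9

    def test_clamped_to_unit_interval(self, mesh):
        rep = np.linspace(0.0, 1.0, mesh.n_vertices)
        fa = syn.simulate_fa(mesh, rep, b0=0.8, b1=1.0, sd=0.5, seed=4)
        assert fa.min() >= 0.0 and fa.max() <= 1.0

    def test_determinism_and_errors(self, mesh):
        rep = np.full(mesh.n_vertices, 0.5)
        fa1 = syn.simulate_fa(mesh, rep, seed=5)
        fa2 = syn.simulate_fa(mesh, rep, seed=5)
        assert np.array_equal(fa1, fa2)
        with pytest.raises(ValueError):
            syn.simulate_fa(mesh, rep, sd=-1.0)
        with pytest.raises(ValueError):
            syn.simulate_fa(mesh, rep, b1=-0.1)
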