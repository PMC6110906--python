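"""Synthetic folded-cortex fMRI generator.

Produces a rectangular folded sheet with an analytic signed curvature
field, a block-design task paradigm, planted network templates spanning
gyral and sulcal stripes, signal matrices with a controllable
gyrus-sulcus representability gap, and a per-vertex FA-like scalar
coupled to representability.  The generator stands in for real
surface-mapped task fMRI so every downstream stage is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

__all__ = [
    "SurfaceMesh",
    "TaskParadigm",
    "GroundTruth",
    "make_surface",
    "make_paradigm",
    "hrf_samples",
    "hrf_convolve",
    "make_network_rois",
    "make_network_templates",
    "make_ground_truth",
    "simulate_signals",
    "representability",
    "simulate_fa",
]


@dataclass
class SurfaceMesh:
    """Triangulated sheet with per-vertex signed principal curvature.

    ``pcurv >= 0`` marks gyral (convex crest) vertices, ``pcurv < 0``
    sulcal (concave fundus) vertices.
    """

    vertex_coords: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (f, 3) int vertex indices
    pcurv: np.ndarray  # (n,) signed

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def validate(self) -> None:
        n = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face index out of range")
        if not np.all(np.isfinite(self.pcurv)):
            raise ValueError("non-finite curvature")


@dataclass
class TaskParadigm:
    """Block-design task timing: (onset s, duration s, condition) events."""

    tr: float
    n_volumes: int
    events: list  # of (onset, duration, condition)

    @property
    def duration(self) -> float:
        return self.tr * self.n_volumes

    @property
    def conditions(self) -> set:
        return {c for _, _, c in self.events}

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for onset, dur, _ in self.events:
            if onset + dur > self.duration + 1e-9:
                raise ValueError("event extends past scan end")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated signal matrix."""

    template_sets: list  # K vertex-index sets
    atom_timecourses: np.ndarray  # (K, n_volumes), unit variance each
    network_loadings: np.ndarray  # (n_vertices,) nonneg; 0 off-network
    sulcal_nuisance_amplitude: float
    noise_sd: float
    seed: int
    network_of_vertex: np.ndarray = field(default=None)  # (n,) int, -1 = background

    def validate(self) -> None:
        if self.sulcal_nuisance_amplitude < 0:
            raise ValueError("sulcal nuisance amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def make_surface(nx: int, ny: int, fold_period: float, spacing: float | None = None,
                 amplitude: float = 1.0) -> SurfaceMesh:
    """Build an ``nx`` x ``ny`` triangulated sheet folded along x.

    Height and curvature are ``sin(2*pi*x / fold_period)`` so gyral
    (pcurv >= 0) and sulcal (pcurv < 0) stripes alternate along x.  The
    curvature is the analytic sine value, not a mesh estimate.  Default
    spacing is ``fold_period / 8`` so both fold phases are well sampled.
    """
    if nx < 4 or ny < 4:
        raise ValueError("grid must be at least 4 x 4")
    if fold_period <= 0:
        raise ValueError("fold_period must be positive")
    if spacing is None:
        spacing = fold_period / 8.0
    if spacing <= 0:
        raise ValueError("spacing must be positive")

    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    phase = 2.0 * np.pi * gx / fold_period
    gz = amplitude * np.sin(phase)
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pcurv = np.sin(phase).ravel()

    # two triangles per grid cell; vertex index = i * ny + j
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    mesh = SurfaceMesh(coords, np.asarray(faces, dtype=np.intp), pcurv)
    mesh.validate()
    return mesh


def make_paradigm() -> TaskParadigm:
    """Emotion-task block design: TR 0.72 s, 176 volumes.

    Six alternating blocks (3 face, 3 shape), each a 3 s cue followed by
    six 3 s trials of the same condition.
    """
    tr = 0.72
    n_volumes = 176
    events = []
    t = 0.0
    for b in range(6):
        cond = "face" if b % 2 == 0 else "shape"
        events.append((t, 3.0, "cue"))
        for k in range(6):
            events.append((t + 3.0 + 3.0 * k, 3.0, cond))
        t += 21.0
    paradigm = TaskParadigm(tr=tr, n_volumes=n_volumes, events=events)
    paradigm.validate()
    return paradigm


def hrf_samples(tr: float, n_volumes: int, peak: float = 6.0,
                undershoot: float = 16.0, undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at volume times.

    Gamma densities with unit scale and modes at ``peak`` and
    ``undershoot`` seconds; the undershoot is subtracted with weight
    ``undershoot_ratio``.
    """
    t = np.arange(n_volumes) * tr
    main = sp_stats.gamma.pdf(t, a=peak + 1.0, scale=1.0)
    under = sp_stats.gamma.pdf(t, a=undershoot + 1.0, scale=1.0)
    return main - undershoot_ratio * under


def hrf_convolve(paradigm: TaskParadigm, condition: str, peak: float = 6.0,
                 undershoot: float = 16.0, undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Boxcar of one condition convolved with the double-gamma HRF.

    The boxcar is sampled at volume onsets; the result is truncated to
    ``n_volumes``.  Unknown conditions raise ``ValueError``.
    """
    if condition not in paradigm.conditions:
        raise ValueError(f"condition {condition!r} not in paradigm")
    times = np.arange(paradigm.n_volumes) * paradigm.tr
    boxcar = np.zeros(paradigm.n_volumes)
    for onset, dur, cond in paradigm.events:
        if cond == condition:
            boxcar[(times >= onset - 1e-9) & (times < onset + dur - 1e-9)] = 1.0
    h = hrf_samples(paradigm.tr, paradigm.n_volumes, peak, undershoot, undershoot_ratio)
    return np.convolve(boxcar, h)[: paradigm.n_volumes]


def _sheet_xy(mesh: SurfaceMesh) -> np.ndarray:
    return mesh.vertex_coords[:, :2]


def make_network_rois(mesh: SurfaceMesh, k: int, rois_per_network: int,
                      radius: float, seed: int, max_tries: int = 5000) -> list:
    """Plant ``k`` disjoint networks, each a list of disjoint ROI balls.

    ROI centers are drawn at mesh vertices; a ball is every vertex within
    ``radius`` (Euclidean in the flat sheet plane).  Each ball must hold
    at least one gyral and one sulcal vertex, and all balls across all
    networks are pairwise disjoint.  Raises ``RuntimeError`` when
    placement fails within ``max_tries`` draws.  Returns a nested list:
    ``rois[network][roi]`` is a vertex set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    xy = _sheet_xy(mesh)
    n = mesh.n_vertices
    taken = np.zeros(n, dtype=bool)
    networks = []
    tries = 0
    for _ in range(k):
        rois = []
        for _ in range(rois_per_network):
            while True:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        "could not place disjoint ROIs; enlarge the mesh or shrink radius")
                center = int(rng.integers(n))
                d = np.linalg.norm(xy - xy[center], axis=1)
                ball = np.flatnonzero(d <= radius + 1e-9)
                if taken[ball].any():
                    continue
                has_gyral = np.any(mesh.pcurv[ball] >= 0)
                has_sulcal = np.any(mesh.pcurv[ball] < 0)
                if ball.size > 1 and not (has_gyral and has_sulcal):
                    continue
                taken[ball] = True
                rois.append(set(int(v) for v in ball))
                break
        networks.append(rois)
    return networks


def make_network_templates(mesh: SurfaceMesh, k: int, rois_per_network: int,
                           radius: float, seed: int, max_tries: int = 5000) -> list:
    """Planted network vertex sets: the ROI unions of :func:`make_network_rois`."""
    rois = make_network_rois(mesh, k, rois_per_network, radius, seed, max_tries)
    return [set().union(*network) for network in rois]


def _lowpass(x: np.ndarray, tr: float, cutoff_hz: float = 0.1) -> np.ndarray:
    """Zero-phase low-pass filter used for intrinsic fluctuations."""
    nyq = 0.5 / tr
    b, a = sp_signal.butter(4, min(cutoff_hz / nyq, 0.99))
    return sp_signal.filtfilt(b, a, x)


def _unit_variance(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate time course")
    return (x - x.mean()) / sd


def make_ground_truth(mesh: SurfaceMesh, templates: list, paradigm: TaskParadigm,
                      delta: float = 0.5, sigma: float = 0.7, loading: float = 1.0,
                      task_weight: float = 0.6, seed: int = 0) -> GroundTruth:
    """Draw network time courses and loadings for :func:`simulate_signals`.

    Each network time course mixes HRF-convolved task regressors (random
    per-network condition weights) with low-pass-filtered intrinsic
    fluctuations, standardized to unit variance.  Loadings are ``loading``
    for every in-network vertex.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA51]))
    k = len(templates)
    regs = {c: hrf_convolve(paradigm, c) for c in ("face", "shape")}
    atom_tc = np.empty((k, paradigm.n_volumes))
    for i in range(k):
        wts = rng.normal(size=2)
        task = wts[0] * regs["face"] + wts[1] * regs["shape"]
        task_sd = task.std()
        task = task / task_sd if task_sd > 0 else task
        intrinsic = _unit_variance(_lowpass(rng.normal(size=paradigm.n_volumes), paradigm.tr))
        atom_tc[i] = _unit_variance(task_weight * task + (1.0 - task_weight) * intrinsic)

    network_of = np.full(mesh.n_vertices, -1, dtype=int)
    for i, tset in enumerate(templates):
        network_of[sorted(tset)] = i
    loadings = np.where(network_of >= 0, float(loading), 0.0)
    truth = GroundTruth(
        template_sets=[set(t) for t in templates],
        atom_timecourses=atom_tc,
        network_loadings=loadings,
        sulcal_nuisance_amplitude=float(delta),
        noise_sd=float(sigma),
        seed=int(seed),
        network_of_vertex=network_of,
    )
    truth.validate()
    return truth


def simulate_signals(mesh: SurfaceMesh, paradigm: TaskParadigm,
                     truth: GroundTruth) -> np.ndarray:
    """Simulate the raw t x n signal matrix from planted ground truth.

    In-network vertex v with network k:
    ``x_v = w_v * a_k + s_v * eta_v + eps_v`` where ``eta_v`` is a
    vertex-specific unit-variance nuisance series, ``s_v`` equals the
    sulcal nuisance amplitude for sulcal vertices (pcurv < 0) and zero
    for gyral ones, and ``eps_v`` is white noise with sd ``noise_sd``.
    Background vertices receive white noise only.  Deterministic given
    ``truth.seed``.
    """
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x516]))
    t = paradigm.n_volumes
    n = mesh.n_vertices
    delta = truth.sulcal_nuisance_amplitude
    sigma = truth.noise_sd

    X = np.empty((t, n))
    net = truth.network_of_vertex
    # vertex-order draws keep the matrix deterministic and seed-stable
    for v in range(n):
        k = net[v]
        if k < 0:
            X[:, v] = rng.normal(scale=sigma, size=t) if sigma > 0 else 0.0
            continue
        x = truth.network_loadings[v] * truth.atom_timecourses[k]
        s_v = delta if mesh.pcurv[v] < 0 else 0.0
        if s_v > 0:
            x = x + s_v * rng.normal(size=t)
        if sigma > 0:
            x = x + rng.normal(scale=sigma, size=t)
        X[:, v] = x
    return X


def representability(mesh: SurfaceMesh, truth: GroundTruth) -> np.ndarray:
    """Closed-form expected accuracy per vertex, ``w / sqrt(w^2 + s^2 + sigma^2)``.

    Background vertices get 0 (no shared component to represent).
    """
    w = truth.network_loadings
    s = np.where(mesh.pcurv < 0, truth.sulcal_nuisance_amplitude, 0.0)
    denom = np.sqrt(w ** 2 + s ** 2 + truth.noise_sd ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rep = np.where(denom > 0, w / denom, 0.0)
    return rep


def simulate_fa(mesh: SurfaceMesh, representability: np.ndarray, b0: float = 0.3,
                b1: float = 0.3, sd: float = 0.05, seed: int = 0) -> np.ndarray:
    """FA-like scalar affinely coupled to representability, clamped to [0, 1]."""
    if b1 < 0:
        raise ValueError("b1 must be >= 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rep = np.asarray(representability, dtype=float)
    if rep.shape[0] != mesh.n_vertices:
        raise ValueError("representability length must match vertex count")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA]))
    noise = rng.normal(scale=sd, size=rep.shape[0]) if sd > 0 else 0.0
    return np.clip(b0 + b1 * rep + noise, 0.0, 1.0)
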