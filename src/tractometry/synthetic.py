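"""Synthetic data generators with recorded ground truth.

Every pipeline input can be generated at toy scale with known truth —
bundle centerlines, tract-ridge scalar volumes, warped profile cohorts,
test-retest replicates with a target ICC, structurally driven FC matrices
and lifespan cohorts with inverted-U trajectories — so recovery tests can
compare estimates against what was actually simulated.

One global seed fans out to per-generator child seeds through
``numpy.random.SeedSequence.spawn`` keyed by a stable generator index, so
adding a generator never perturbs the fixtures of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .elastic import ProfileFunction
from .lifespan import LifespanSample
from .projection import ScalarVolume
from .streamlines import Streamline, Tractogram

__all__ = [
    "SyntheticTruth",
    "child_seed",
    "gen_bundle",
    "gen_ridge_volume",
    "gen_profile_cohort",
    "gen_test_retest",
    "gen_sc_fc_cohort",
    "gen_lifespan_cohort",
]

# stable fan-out indices; append-only so existing fixtures never shift
_GENERATOR_INDEX = {
    "bundle": 0,
    "ridge_volume": 1,
    "profile_cohort": 2,
    "test_retest": 3,
    "sc_fc_cohort": 4,
    "lifespan_cohort": 5,
}


def child_seed(seed: int, generator: str, stream: int = 0) -> np.random.SeedSequence:
    """Derive the per-generator child seed from one global seed."""
    idx = _GENERATOR_INDEX[generator]
    return np.random.SeedSequence(entropy=seed, spawn_key=(idx, stream))


@dataclass
class SyntheticTruth:
    """Ground-truth record for one generator call; JSON-serializable."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(
            {"generator": self.generator, "seed": self.seed, "params": self.params},
            default=default,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "SyntheticTruth":
        d = json.loads(s)
        return cls(generator=d["generator"], seed=d["seed"], params=d["params"])


def _smooth_offsets(rng, n_points: int, spread: float) -> np.ndarray:
    """Smooth random offset curve bounded by ~spread (low-order Fourier)."""
    t = np.linspace(0.0, 1.0, n_points)
    out = np.zeros(n_points)
    for k in range(1, 4):
        out += rng.normal(0, 1) * np.sin(np.pi * k * t) / k
    m = np.max(np.abs(out))
    if m > 0:
        out *= spread * rng.uniform(0.3, 1.0) / m
    return out


def gen_bundle(
    centerline: np.ndarray,
    n_fibers: int = 20,
    spread_mm: float = 1.0,
    seed: int = 0,
    stream: int = 0,
) -> tuple[Tractogram, SyntheticTruth]:
    """Fibers = centerline + smooth random offsets in the normal plane."""
    if spread_mm < 0:
        raise ValueError("spread must be nonnegative")
    center = np.asarray(centerline, dtype=float)
    rng = np.random.default_rng(child_seed(seed, "bundle", stream))
    # local frames along the centerline
    tangents = np.gradient(center, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    fibers = []
    for i in range(n_fibers):
        u = _smooth_offsets(rng, len(center), spread_mm)
        v = _smooth_offsets(rng, len(center), spread_mm)
        pts = np.empty_like(center)
        for j in range(len(center)):
            t = tangents[j]
            helper = np.zeros(3)
            helper[int(np.argmin(np.abs(t)))] = 1.0
            e1 = np.cross(t, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            pts[j] = center[j] + u[j] * e1 + v[j] * e2
        fibers.append(Streamline(points=pts, id=f"fiber_{stream}_{i:04d}"))
    truth = SyntheticTruth(
        generator="bundle",
        seed=seed,
        params={
            "centerline": center,
            "n_fibers": n_fibers,
            "spread_mm": spread_mm,
            "stream": stream,
        },
    )
    return Tractogram(streamlines=fibers, space="synthetic"), truth


def gen_ridge_volume(
    centerline: np.ndarray,
    peak_value: float = 0.8,
    sigma_mm: float = 6.0,
    shape: tuple = (64, 64, 64),
    affine: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    stream: int = 0,
) -> tuple[ScalarVolume, SyntheticTruth]:
    """Gaussian-ridge phantom: value = peak * exp(-d(x, line)^2 / 2 sigma^2)."""
    center = np.asarray(centerline, dtype=float)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    # distance to the polyline: nearest of densely resampled centerline points
    from scipy.spatial import cKDTree

    from .streamlines import Streamline as _S, resample_streamline

    dense = resample_streamline(_S(points=center), max(200, 4 * len(center))).points
    d, _ = cKDTree(dense).query(world)
    d2 = d**2
    data = peak_value * np.exp(-d2 / (2.0 * sigma_mm**2))
    if noise_sd > 0:
        rng = np.random.default_rng(child_seed(seed, "ridge_volume", stream))
        data = data + rng.normal(0, noise_sd, size=data.shape)
    vol = ScalarVolume(data=data.reshape(shape), affine=affine, space="synthetic")
    truth = SyntheticTruth(
        generator="ridge_volume",
        seed=seed,
        params={
            "centerline": center,
            "peak_value": peak_value,
            "sigma_mm": sigma_mm,
            "noise_sd": noise_sd,
            "stream": stream,
        },
    )
    return vol, truth


def _random_warp(rng, t: np.ndarray, warp_scale: float) -> np.ndarray:
    """Smooth monotone boundary-fixed warp; resampled if monotonicity fails."""
    for _ in range(100):
        g = t.copy()
        for k in (1, 2):
            g = g + rng.normal(0, warp_scale / k) * np.sin(np.pi * k * t) * 0.5
        if np.all(np.diff(g) > 0) and g[0] >= -1e-12 and g[-1] <= 1 + 1e-12:
            g = np.clip(g, 0, 1)
            g[0], g[-1] = 0.0, 1.0
            return g
    return t.copy()


def gen_profile_cohort(
    mother,
    n_subjects: int = 30,
    n_points: int = 50,
    warp_scale: float = 0.1,
    amplitude_sd: float = 0.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    stream: int = 0,
):
    """Cohort of profiles = mother o gamma_i + amplitude_i + noise.

    ``mother`` is a callable on [0,1].  The truth records each subject's
    warp (on the grid) and amplitude offset.
    """
    rng = np.random.default_rng(child_seed(seed, "profile_cohort", stream))
    t = np.linspace(0.0, 1.0, n_points)
    warps, amps, profiles = [], [], []
    for i in range(n_subjects):
        g = _random_warp(rng, t, warp_scale)
        a = rng.normal(0, amplitude_sd) if amplitude_sd > 0 else 0.0
        vals = np.asarray(mother(g), dtype=float) + a
        if noise_sd > 0:
            vals = vals + rng.normal(0, noise_sd, size=n_points)
        profiles.append(
            ProfileFunction(values=vals, subject_id=f"sub_{i:03d}", pathway_id=stream)
        )
        warps.append(g)
        amps.append(a)
    truth = SyntheticTruth(
        generator="profile_cohort",
        seed=seed,
        params={
            "warps": np.stack(warps),
            "amplitudes": np.array(amps),
            "mother_on_grid": np.asarray(mother(t), dtype=float),
            "warp_scale": warp_scale,
            "noise_sd": noise_sd,
            "stream": stream,
        },
    )
    return profiles, truth


def gen_test_retest(
    n_subjects: int = 500,
    icc_true: float = 0.8,
    mean: float = 100.0,
    total_sd: float = 10.0,
    seed: int = 0,
    stream: int = 0,
):
    """Two-visit table with a specified true ICC.

    Variance-components model: y_sv = mu + b_s + e_sv with
    icc_true = var(b) / (var(b) + var(e)).
    """
    if not 0.0 < icc_true < 1.0:
        raise ValueError("icc_true must be in (0, 1)")
    rng = np.random.default_rng(child_seed(seed, "test_retest", stream))
    sd_subj = total_sd * np.sqrt(icc_true)
    sd_noise = total_sd * np.sqrt(1.0 - icc_true)
    b = rng.normal(0, sd_subj, size=n_subjects)
    table = mean + b[:, None] + rng.normal(0, sd_noise, size=(n_subjects, 2))
    truth = SyntheticTruth(
        generator="test_retest",
        seed=seed,
        params={
            "icc_true": icc_true,
            "sd_subject": sd_subj,
            "sd_noise": sd_noise,
            "stream": stream,
        },
    )
    return table, truth


def gen_sc_fc_cohort(
    n_subjects: int = 500,
    n_pathways: int = 10,
    n_edges: int = 40,
    coupling_r2: float = 0.3,
    dominant_pathway: int = 0,
    seed: int = 0,
    stream: int = 0,
):
    """Structurally driven FC: edges are linear mixtures of pathway FA.

    Each FC edge is w_e . FA + noise, with the noise variance set so the
    structural part explains ``coupling_r2`` of each edge's variance.  One
    designated pathway dominates the mixing weights of the first edge, so
    contribution ranking has a known answer.  Returns (FA matrix, FC
    matrix, truth).
    """
    if not 0.0 <= coupling_r2 <= 1.0:
        raise ValueError("coupling_r2 must be in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, "sc_fc_cohort", stream))
    fa = 0.5 + 0.05 * rng.standard_normal((n_subjects, n_pathways))
    # dense mixtures: no pathway is the sole driver of any edge ...
    W = rng.normal(0, 1.0, size=(n_pathways, n_edges))
    # ... except the designated pathway, which exclusively drives edge 0,
    # so its best-match (max-over-edges) correlation is the largest by design
    W[:, 0] = 0.0
    W[dominant_pathway, 0] = 3.0
    signal = (fa - fa.mean(axis=0)) @ W
    fc = np.empty_like(signal)
    sig_var = signal.var(axis=0)
    noise_sd = np.sqrt(
        np.where(
            coupling_r2 > 0,
            sig_var * (1.0 - coupling_r2) / max(coupling_r2, 1e-12),
            1.0,
        )
    )
    if coupling_r2 == 0:
        signal = np.zeros_like(signal)
        noise_sd = np.ones(n_edges)
    fc = signal + rng.normal(0, 1.0, size=signal.shape) * noise_sd
    truth = SyntheticTruth(
        generator="sc_fc_cohort",
        seed=seed,
        params={
            "mixing": W,
            "coupling_r2": coupling_r2,
            "dominant_pathway": dominant_pathway,
            "noise_sd": noise_sd,
            "stream": stream,
        },
    )
    return fa, fc, truth


def inverted_u(t: np.ndarray, peak, scale: float = 0.15, width: float = 20.0) -> np.ndarray:
    """Smooth inverted-U lifespan curve peaking at ``peak`` years.

    A Gaussian developmental rise/decline around the peak plus a gentle
    quadratic late-life decline, on a baseline and amplitude matching
    network-mean FA values (~0.35-0.50 with a ~0.05 drop by age 90).
    """
    t = np.asarray(t, dtype=float)
    return (
        0.35
        + scale * np.exp(-((t - peak) ** 2) / (2.0 * width**2))
        - 0.10 * (np.maximum(t - peak, 0.0) / 65.0) ** 2
    )


def gen_lifespan_cohort(
    n: int = 3000,
    peak_male: float = 25.0,
    peak_female: float = 28.0,
    n_sites: int = 3,
    site_sd: float = 0.01,
    noise_sd: float = 0.025,
    seed: int = 0,
    stream: int = 0,
):
    """Lifespan samples with sex-specific inverted-U trajectories.

    Ages are uniform on [3, 90]; sex is balanced Bernoulli(0.5); sites get
    fixed offsets drawn once.  Truth records the peaks, site offsets and
    the noise scale.
    """
    rng = np.random.default_rng(child_seed(seed, "lifespan_cohort", stream))
    ages = rng.uniform(3.0, 90.0, size=n)
    sex = (rng.random(n) < 0.5).astype(int)
    site_ids = rng.integers(0, n_sites, size=n)
    offsets = rng.normal(0, site_sd, size=n_sites)
    peaks = np.where(sex == 1, peak_male, peak_female)
    y = inverted_u(ages, peaks) + offsets[site_ids] + rng.normal(0, noise_sd, size=n)
    samples = [
        LifespanSample(
            subject_id=f"sub_{i:05d}",
            age=float(ages[i]),
            sex=int(sex[i]),
            site=f"site_{site_ids[i]}",
            value=float(y[i]),
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(
        generator="lifespan_cohort",
        seed=seed,
        params={
            "peak_male": peak_male,
            "peak_female": peak_female,
            "site_offsets": offsets,
            "noise_sd": noise_sd,
            "stream": stream,
        },
    )
    return samples, truth
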