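"""Synthetic TCSPC data with known ground truth.

Generates photon-count cubes by evaluating a decay model per pixel (IRF
convolution, optional lens contamination, incomplete-decay wrap-around),
normalizing the decay part to a target photon number, adding a constant
background rate per channel and drawing independent Poisson counts — the
standard TCSPC photon-counting noise model.

Defaults mirror clinical fundus acquisitions: 1024 time channels of 12.2 ps
spanning a 12.5 ns repetition period, ~1,000 photons per raw pixel, an IRF
of 172 ps full width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FitResultMaps, IRFCurve, LensDecay, StudySet, SubjectRecord, TCSPCCube, TimeAxis
from .models import ModelSpec, ParamVector, evaluate_model
from .postprocess import mean_lifetime

__all__ = [
    "GroundTruth",
    "gaussian_irf",
    "biexponential_lens",
    "uniform_truth",
    "expected_curve",
    "sample_histogram",
    "simulate_cube",
    "simulate_group_study",
]


def gaussian_irf(
    time: TimeAxis, fwhm_ps: float = 172.0, t0_ps: float = 1000.0
) -> IRFCurve:
    """Gaussian IRF of a given full width at half maximum, centred at t0.

    172 ps matches the short-wavelength detection channel of the fundus
    instrument this package models; t0 leaves a pre-excitation interval
    before the pulse.
    """
    t = time.centers_ps()
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((t - t0_ps) / sigma) ** 2)
    return IRFCurve(values=vals, time=time)


def biexponential_lens(
    time: TimeAxis,
    tau_ps: tuple[float, float] = (400.0, 2200.0),
    weights: tuple[float, float] = (0.7, 0.3),
    t0_ps: float = 800.0,
) -> LensDecay:
    """Synthetic crystalline-lens decay (unit-sum, rises at t0).

    A single exponential does not describe lens fluorescence; two components
    are the minimal realistic stand-in for a measured lens curve.
    """
    t = time.centers_ps()
    vals = np.zeros_like(t)
    after = t >= t0_ps
    for w, tau in zip(weights, tau_ps):
        vals[after] += w * np.exp(-(t[after] - t0_ps) / tau)
    vals /= vals.sum()
    return LensDecay(values=vals, time=time)


@dataclass
class GroundTruth:
    """Per-pixel true decay parameters plus acquisition ingredients.

    ``alpha``/``tau``/``tc`` are (k, ny, nx) stacks of per-component maps,
    ``n_photons`` the target photon number of the decay part per pixel and
    ``background`` an additive per-channel count rate.
    """

    alpha: np.ndarray
    tau: np.ndarray
    n_photons: np.ndarray
    irf: IRFCurve
    time: TimeAxis
    tc: np.ndarray | None = None
    beta: float = 1.0
    alpha_lens: np.ndarray | None = None
    lens: LensDecay | None = None
    tc_lens: float = 0.0
    background: float = 0.0
    incomplete_j: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.n_photons = np.asarray(self.n_photons)
        if self.alpha.ndim != 3 or self.alpha.shape != self.tau.shape:
            raise ValueError("alpha and tau must be (k, ny, nx) stacks")
        if self.n_photons.shape != self.alpha.shape[1:]:
            raise ValueError("n_photons map shape mismatch")
        if np.any(self.alpha < 0) or np.any(self.alpha.sum(axis=0) <= 0):
            raise ValueError("weights must be >= 0 and not all zero per pixel")
        if np.any(self.tau <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.n_photons < 0) or np.any(np.mod(self.n_photons, 1) != 0):
            raise ValueError("n_photons must be non-negative integers")
        if (self.alpha_lens is not None) and self.lens is None:
            raise ValueError("alpha_lens requires a lens curve")

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha.shape[1:]

    @property
    def n_components(self) -> int:
        return self.alpha.shape[0]

    def model_spec(self) -> ModelSpec:
        if self.lens is not None:
            return ModelSpec(
                kind="lens_corrected",
                n_components=self.n_components,
                incomplete_j=self.incomplete_j,
                fix_beta=self.beta,
                lens=self.lens,
            )
        kind = "multiexp" if self.beta == 1.0 else "stretched"
        return ModelSpec(
            kind=kind,
            n_components=self.n_components,
            incomplete_j=self.incomplete_j,
        )


def uniform_truth(
    shape: tuple[int, int],
    time: TimeAxis,
    irf: IRFCurve,
    tau_ps: tuple[float, ...] = (500.0, 2500.0),
    alpha: tuple[float, ...] = (0.6, 0.4),
    n_photons: int = 1000,
    background: float = 0.0,
    lens: LensDecay | None = None,
    alpha_lens: float = 0.0,
    tc_lens: float = 0.0,
    incomplete_j: int = 0,
    seed: int = 0,
) -> GroundTruth:
    """Spatially constant ground truth — the simplest study condition."""
    ny, nx = shape
    k = len(tau_ps)
    return GroundTruth(
        alpha=np.broadcast_to(np.asarray(alpha, float)[:, None, None], (k, ny, nx)).copy(),
        tau=np.broadcast_to(np.asarray(tau_ps, float)[:, None, None], (k, ny, nx)).copy(),
        n_photons=np.full((ny, nx), n_photons, dtype=np.int64),
        irf=irf,
        time=time,
        alpha_lens=None if lens is None else np.full((ny, nx), alpha_lens),
        lens=lens,
        tc_lens=tc_lens,
        background=background,
        incomplete_j=incomplete_j,
        seed=seed,
    )


def expected_curve(truth: GroundTruth, row: int, col: int) -> np.ndarray:
    """Expected counts per channel for one pixel.

    The decay part (retinal components plus any lens contribution) is
    normalized to the pixel's target photon number; the background rate is
    then added per channel.
    """
    spec = truth.model_spec()
    params = ParamVector(
        alpha=truth.alpha[:, row, col],
        tau=truth.tau[:, row, col],
        tc=None if truth.tc is None else truth.tc[:, row, col],
        beta=truth.beta,
        alpha_lens=0.0 if truth.alpha_lens is None else float(truth.alpha_lens[row, col]),
        tc_lens=truth.tc_lens,
        background=0.0,
    )
    decay = evaluate_model(spec, params, truth.irf, truth.time)
    total = decay.sum()
    n = float(truth.n_photons[row, col])
    if total > 0 and n > 0:
        decay = decay * (n / total)
    else:
        decay = np.zeros_like(decay)
    return decay + truth.background


def sample_histogram(expected: np.ndarray, seed) -> np.ndarray:
    """Independent Poisson draw per time channel, reproducible given seed."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expectation must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(expected)


def simulate_cube(truth: GroundTruth) -> TCSPCCube:
    """Sample a full photon-count cube from the ground truth."""
    ny, nx = truth.shape
    rng = np.random.default_rng(truth.seed)
    counts = np.empty((ny, nx, truth.time.n_channels), dtype=np.int64)
    for y in range(ny):
        for x in range(nx):
            counts[y, x, :] = sample_histogram(expected_curve(truth, y, x), rng)
    return TCSPCCube(counts=counts, time=truth.time)


def simulate_group_study(
    n_per_group: int,
    effect_ps: float,
    seed: int,
    shape: tuple[int, int] = (16, 16),
    tau_ps: tuple[float, ...] = (500.0, 2500.0),
    alpha: tuple[float, ...] = (0.6, 0.4),
    target_component: int = 0,
    subject_sd_ps: float = 25.0,
    pixel_sd_ps: float = 50.0,
    group_names: tuple[str, str] = ("control", "patient"),
) -> StudySet:
    """Two-group study of lifetime parameter maps with a known group effect.

    Each subject's lifetime map is the population value plus a subject-level
    Gaussian offset (inter-individual variability) plus pixel-level Gaussian
    noise (residual fit scatter); group B's designated lifetime component is
    shifted by ``effect_ps``.  Per-subject seeds are spawned deterministically
    from the master seed, so the same seed reproduces the same study.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if not 0 <= target_component < len(tau_ps):
        raise ValueError("target_component out of range")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    subjects: list[SubjectRecord] = []
    ny, nx = shape
    idx = 0
    for g, gname in enumerate(group_names):
        for s in range(n_per_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            maps: dict[str, np.ndarray] = {}
            alpha_maps = []
            tau_maps = []
            for i, (a, tau) in enumerate(zip(alpha, tau_ps)):
                base = tau + (effect_ps if (g == 1 and i == target_component) else 0.0)
                subj = base + rng.normal(0.0, subject_sd_ps)
                m = subj + rng.normal(0.0, pixel_sd_ps, size=(ny, nx))
                m = np.maximum(m, 1.0)
                maps[f"tau{i + 1}"] = m
                maps[f"alpha{i + 1}"] = np.full((ny, nx), a)
                alpha_maps.append(maps[f"alpha{i + 1}"])
                tau_maps.append(m)
            maps["tau_m"] = mean_lifetime(np.stack(alpha_maps), np.stack(tau_maps))
            maps["chi2"] = np.ones((ny, nx))
            res = FitResultMaps(
                maps=maps,
                provenance={"seed": int(seed), "subject_index": idx - 1},
            )
            subjects.append(
                SubjectRecord(
                    subject_id=f"{gname}-{s + 1:02d}",
                    group=gname,
                    results=res,
                    roi_mask=np.ones((ny, nx), dtype=bool),
                )
            )
    return StudySet(subjects=subjects)
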