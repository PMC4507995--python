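"""Forward evaluation of fluorescence-decay models with IRF convolution.

Model zoo (all evaluated on the discrete TCSPC time axis, convolved with a
unit-sum instrument response function, plus a constant background b):

- ``multiexp``            I(t) = IRF * sum_i alpha_i exp(-t/tau_i) + b
- ``stretched``           Kohlrausch decay exp(-(t/tau)^beta)
- ``layered``             per-component time shifts tc_i for the layered eye
- ``layered_stretched``   shifts and a stretching exponent combined
- ``lens_corrected``      adds alpha_lens * I_lens(t - tc_lens), where I_lens
  is the separately measured crystalline-lens decay

Incomplete decay: when the lifetime is not much shorter than the laser
repetition period t_R, tails of preceding pulses overlap the current period.
The model is folded numerically, F(t) = I_C(t) + sum_{q=1..j} I_C(t + q*t_R),
with I_C evaluated on an extended time grid; the periodic excitation thereby
also fills the pre-excitation channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import IRFCurve, LensDecay, TimeAxis, SPEED_OF_LIGHT_M_PER_S

__all__ = [
    "ModelSpec",
    "ParamVector",
    "lens_time_shift",
    "shift_curve",
    "evaluate_model",
    "evaluate_decay_components",
    "evaluate_spectral_global",
    "apply_incomplete_decay",
]

_KINDS = (
    "multiexp",
    "stretched",
    "spectral_global",
    "layered",
    "layered_stretched",
    "lens_corrected",
)

_STRETCHED_KINDS = ("stretched", "layered_stretched", "lens_corrected")
_SHIFTED_KINDS = ("layered", "layered_stretched", "lens_corrected")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a decay model.

    Parameters
    ----------
    kind:
        One of ``multiexp``, ``stretched``, ``spectral_global``, ``layered``,
        ``layered_stretched``, ``lens_corrected``.
    n_components:
        Number of exponential components (1-3; more is not identifiable at
        realistic photon numbers).
    incomplete_j:
        Number of preceding repetition periods folded into the model (0 = no
        incomplete-decay correction; 1 suffices for lifetimes up to ~5 ns at
        t_R = 12.5 ns).
    tc_free:
        Per-component flags marking which time shifts are free parameters
        (shifted kinds only); fixed shifts stay at the value in ParamVector.
    fix_beta:
        Value to pin the stretching exponent to (e.g. 1.0 turns the
        lens-corrected model into plain exponentials), or None to fit it.
    lens:
        The measured crystalline-lens decay (required iff lens_corrected).
    """

    kind: str
    n_components: int = 2
    incomplete_j: int = 0
    tc_free: tuple[bool, ...] | None = None
    fix_beta: float | None = None
    lens: LensDecay | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 1 <= self.n_components <= 3:
            raise ValueError("n_components must be 1, 2 or 3")
        if self.incomplete_j < 0:
            raise ValueError("incomplete_j must be >= 0")
        if (self.lens is None) == (self.kind == "lens_corrected"):
            raise ValueError("a lens curve is required iff kind='lens_corrected'")
        if self.tc_free is not None and len(self.tc_free) != self.n_components:
            raise ValueError("tc_free must have one flag per component")

    @property
    def stretched(self) -> bool:
        return self.kind in _STRETCHED_KINDS

    @property
    def shifted(self) -> bool:
        return self.kind in _SHIFTED_KINDS


@dataclass
class ParamVector:
    """Concrete parameter values for a ModelSpec.

    Amplitudes and background are non-negative, lifetimes strictly positive
    (ps), the stretching exponent lies in (0, 1].  A single beta is shared
    by all components.
    """

    alpha: np.ndarray
    tau: np.ndarray
    tc: np.ndarray | None = None
    beta: float = 1.0
    alpha_lens: float = 0.0
    tc_lens: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.alpha.shape != self.tau.shape:
            raise ValueError("alpha and tau must have the same length")
        if np.any(self.alpha < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.tau <= 0):
            raise ValueError("lifetimes must be strictly positive")
        if self.tc is None:
            self.tc = np.zeros_like(self.tau)
        else:
            self.tc = np.atleast_1d(np.asarray(self.tc, dtype=float))
            if self.tc.shape != self.tau.shape:
                raise ValueError("tc must have one shift per component")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.alpha_lens < 0:
            raise ValueError("alpha_lens must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def n_components(self) -> int:
        return self.alpha.size


def lens_time_shift(d_mm: float, refractive_index: float) -> float:
    """Round-trip time shift tc = 2 d n / c between lens and retina, in ps.

    The excitation pulse excites the crystalline lens before travelling the
    vitreous distance d to the retina; the retinal fluorescence is therefore
    delayed by the two-way optical path.  For the Gullstrand schematic eye
    (d = 22.2 mm, n = 1.3668) this gives 202.3 ps.
    """
    if d_mm < 0:
        raise ValueError("distance must be non-negative")
    if refractive_index < 1:
        raise ValueError("refractive index must be >= 1")
    seconds = 2.0 * (d_mm * 1e-3) * refractive_index / SPEED_OF_LIGHT_M_PER_S
    return seconds * 1e12


def shift_curve(curve: np.ndarray, shift_ps: float, time: TimeAxis) -> np.ndarray:
    """Delay a sampled curve by `shift_ps` with linear interpolation.

    Positive shifts move the curve towards later channels; samples shifted in
    from before t = 0 are zero.  Negative shifts advance the curve and zero-
    fill the end.
    """
    if abs(shift_ps) >= time.rep_period_ps:
        raise ValueError("|shift| must be below the repetition period")
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    idx = np.arange(n) - shift_ps / time.channel_width_ps
    return np.interp(idx, np.arange(n), curve, left=0.0, right=0.0)


def _component_decay(
    t_ps: np.ndarray, tau: float, tc: float, beta: float
) -> np.ndarray:
    """Single (possibly stretched, shifted) exponential, zero before tc."""
    tt = t_ps - tc
    out = np.zeros_like(t_ps)
    pos = tt >= 0
    if beta == 1.0:
        out[pos] = np.exp(-tt[pos] / tau)
    else:
        out[pos] = np.exp(-((tt[pos] / tau) ** beta))
    return out


def _convolve_irf(decay: np.ndarray, irf_values: np.ndarray) -> np.ndarray:
    """Discrete linear convolution with the (unit-sum) IRF, same length."""
    kernel = irf_values / irf_values.sum()
    return np.convolve(decay, kernel)[: decay.size]


def _fold(extended: np.ndarray, time: TimeAxis, j: int) -> np.ndarray:
    """Sum shifted copies of an extended-grid curve over j repetition periods.

    extended has (j+1) * m channels; copy q is sampled at t + q * t_R with
    linear interpolation (t_R need not be an integer number of channels).
    """
    m = time.n_channels
    if j == 0:
        return extended[:m].copy()
    base = np.arange(m, dtype=float)
    grid = np.arange(extended.size, dtype=float)
    out = extended[:m].astype(float).copy()
    per_period = time.rep_period_ps / time.channel_width_ps
    for q in range(1, j + 1):
        out += np.interp(base + q * per_period, grid, extended, left=0.0, right=0.0)
    return out


def evaluate_decay_components(
    spec: ModelSpec,
    params: ParamVector,
    irf: IRFCurve,
    time: TimeAxis,
) -> np.ndarray:
    """Unit-amplitude convolved (and folded) component curves, shape (k, m).

    These are the basis curves of the variable-projection amplitude solve:
    the full model is ``alpha @ components + alpha_lens * lens_shifted + b``.
    """
    if spec.n_components != params.n_components:
        raise ValueError("spec and params disagree on the component count")
    j = spec.incomplete_j
    ext_time = time.extended(j + 1) if j > 0 else time
    t = ext_time.centers_ps()
    irf_vals = irf.normalized()
    if j > 0:
        irf_vals = np.concatenate(
            [irf_vals, np.zeros(ext_time.n_channels - irf_vals.size)]
        )
    beta = params.beta if spec.stretched else 1.0
    if spec.fix_beta is not None:
        beta = spec.fix_beta
    rows = []
    for i in range(spec.n_components):
        tc = params.tc[i] if spec.shifted else 0.0
        decay = _component_decay(t, params.tau[i], tc, beta)
        conv = _convolve_irf(decay, irf_vals)
        rows.append(_fold(conv, time, j))
    return np.vstack(rows)


def evaluate_model(
    spec: ModelSpec,
    params: ParamVector,
    irf: IRFCurve,
    time: TimeAxis,
) -> np.ndarray:
    """Expected counts per time channel for a model and parameter vector.

    The convolved multi-exponential part is folded for incomplete decay; the
    crystalline-lens term (an already IRF-broadened measured signal) and the
    constant background are added afterwards, each counted once.
    """
    comps = evaluate_decay_components(spec, params, irf, time)
    curve = params.alpha @ comps
    if spec.kind == "lens_corrected" and params.alpha_lens > 0:
        assert spec.lens is not None
        curve = curve + params.alpha_lens * shift_curve(
            spec.lens.values, params.tc_lens, time
        )
    return curve + params.background


def evaluate_spectral_global(
    specs: Sequence[ModelSpec],
    shared_lifetimes: Sequence[int],
    params: Sequence[ParamVector],
    irfs: Sequence[IRFCurve],
    time: TimeAxis,
) -> list[np.ndarray]:
    """Evaluate one model per spectral channel with tied lifetimes.

    Lifetimes with index in `shared_lifetimes` are forced to the value they
    take in the first channel's parameter vector (the fluorescence lifetime
    of a fluorophore does not depend on the detection band); every other
    parameter stays channel specific.
    """
    if not len(specs) == len(params) == len(irfs):
        raise ValueError("specs, params and irfs must align per channel")
    n_comp = {s.n_components for s in specs}
    for i in shared_lifetimes:
        if any(i >= s.n_components for s in specs):
            raise ValueError(f"shared lifetime index {i} missing in a channel")
    curves = []
    ref = params[0]
    for spec, p, irf in zip(specs, params, irfs):
        tau = p.tau.copy()
        for i in shared_lifetimes:
            tau[i] = ref.tau[i]
        curves.append(evaluate_model(spec, replace(p, tau=tau), irf, time))
    return curves


def apply_incomplete_decay(spec: ModelSpec, j: int) -> ModelSpec:
    """Return a spec whose evaluator folds j preceding repetition periods."""
    if j < 0:
        raise ValueError("j must be >= 0")
    return replace(spec, incomplete_j=j)
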