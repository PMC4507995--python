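"""Reduced-chi-square decay fitting with variable projection.

The figure of merit is the reduced chi-square over the fitted time channels,
with Neyman weighting (w_j = measured counts, floored at 1) or Pearson
weighting (w_j = model counts, recomputed per evaluation).  The model is
linear in the amplitudes, the lens amplitude and the background, so those
are solved by weighted non-negative least squares inside every evaluation of
the nonlinear objective (variable projection); only lifetimes, time shifts,
the stretching exponent and the lens shift are handled by the nonlinear
minimizers.

The image fit runs in two stages: differential evolution on the image-
integrated decay (best SNR, global search) supplies the starting point for
bound-constrained Nelder-Mead fits of every pixel.  Reflection artifacts are
detected once on the integrated decay and their time intervals excluded from
all figures of merit; an iterative sliding-window pass afterwards re-fits
outlier pixels from their best-fitting neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .binning import sum_all_pixels
from .core import DegenerateDofError, FitResultMaps, IRFCurve, TCSPCCube, TimeAxis
from .models import ModelSpec, ParamVector, evaluate_decay_components, shift_curve
from .postprocess import mean_lifetime

__all__ = [
    "FitConfig",
    "PixelFitResult",
    "compute_weights",
    "reduced_chi2",
    "neighborhood_chi2",
    "solve_amplitudes",
    "minimize_pixel",
    "global_init",
    "detect_reflection_artifacts",
    "fit_image",
    "treat_outliers",
    "estimate_background_preexcitation",
]

log = logging.getLogger(__name__)

_PEARSON_EPS = 1e-10

_DEFAULT_BOUNDS = {
    "tau": (10.0, 8000.0),
    "tc": (-600.0, 600.0),
    "beta": (0.05, 1.0),
    "tc_lens": (-600.0, 600.0),
}


@dataclass
class FitConfig:
    """Settings for the two-stage image fit.

    ``fit_interval`` 'auto' fits only the decay (from the histogram peak
    onward) for models without time shifts and the full signal including
    pre-excitation interval and rising edge for the layered and
    lens-corrected models.
    """

    weighting: str = "neyman"
    seed: int = 0
    de_popsize: int = 15
    de_maxiter: int = 100
    de_tol: float = 0.01
    nm_maxiter: int = 600
    nm_xatol: float = 0.05
    nm_fatol: float = 1e-8
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    neighborhood_fit: bool = False
    artifact_removal: bool = True
    outlier_window: int = 7
    outlier_threshold: float = 0.30
    outlier_iterations: int = 1
    fit_interval: str = "auto"
    background_from_preexcitation: bool = False

    def __post_init__(self) -> None:
        if self.weighting not in ("neyman", "pearson"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.outlier_window % 2 == 0 or self.outlier_window < 3:
            raise ValueError("outlier window must be odd and >= 3")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier threshold must be positive")
        if self.de_popsize < 5:
            raise ValueError("differential evolution population must be >= 5")
        if self.fit_interval not in ("auto", "decay_only", "full_signal"):
            raise ValueError(f"unknown fit_interval {self.fit_interval!r}")

    def resolved_interval(self, spec: ModelSpec) -> str:
        if self.fit_interval != "auto":
            return self.fit_interval
        return "full_signal" if spec.shifted else "decay_only"


@dataclass
class PixelFitResult:
    params: ParamVector
    chi2: float
    n_iter: int
    converged: bool
    channel_mask: np.ndarray


def compute_weights(measured: np.ndarray, method: str, model: np.ndarray | None = None) -> np.ndarray:
    """Per-channel chi-square weights.

    Neyman: the measured counts, floored at 1 so empty channels do not
    divide by zero.  Pearson: the model counts (floored at a tiny epsilon),
    which must be recomputed whenever the model changes.
    """
    if method == "neyman":
        return np.maximum(np.asarray(measured, dtype=float), 1.0)
    if method == "pearson":
        if model is None:
            raise ValueError("Pearson weighting needs the model curve")
        return np.maximum(np.asarray(model, dtype=float), _PEARSON_EPS)
    raise ValueError(f"unknown weighting method {method!r}")


def reduced_chi2(
    measured: np.ndarray,
    modeled: np.ndarray,
    weights: np.ndarray,
    p: int,
    channel_mask: np.ndarray | None = None,
) -> float:
    """chi^2_r = sum over fitted channels of (I_M - I_C)^2 / w / (m_used - p)."""
    measured = np.asarray(measured, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if channel_mask is None:
        channel_mask = np.ones(measured.size, dtype=bool)
    channel_mask = np.asarray(channel_mask, dtype=bool)
    m_used = int(channel_mask.sum())
    if m_used <= p:
        raise DegenerateDofError(
            f"{m_used} fitted channels but {p} free parameters"
        )
    resid = measured[channel_mask] - modeled[channel_mask]
    return float(np.sum(resid**2 / weights[channel_mask]) / (m_used - p))


def neighborhood_chi2(chi2_center: float, chi2_adjacent) -> float:
    """Spatially regularized figure of merit.

    The central pixel's reduced chi-square is squared and the mean of the
    adjacent pixels' values (computed with the central pixel's parameters)
    is added; as printed, the two terms are on different scales.
    """
    adj = np.asarray(chi2_adjacent, dtype=float)
    if adj.size == 0:
        raise ValueError("need at least one adjacent pixel")
    return float(chi2_center**2 + adj.mean())


def solve_amplitudes(
    bases: np.ndarray,
    lens_curve: np.ndarray | None,
    measured: np.ndarray,
    weights: np.ndarray,
    channel_mask: np.ndarray | None = None,
    fit_background: bool = True,
    fixed_background: float = 0.0,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Weighted non-negative least squares for the linear parameters.

    Solves min ||(A x - y) / sqrt(w)|| over x >= 0 where the columns of A
    are the component basis curves, the (shifted) lens curve and a constant
    column for the background.  Returns (alphas, alpha_lens, background,
    full-length model curve).
    """
    bases = np.atleast_2d(np.asarray(bases, dtype=float))
    if not np.any(bases > 0):
        raise ValueError("all-zero component basis")
    m = bases.shape[1]
    cols = [bases.T]
    if lens_curve is not None:
        cols.append(np.asarray(lens_curve, dtype=float)[:, None])
    if fit_background:
        cols.append(np.ones((m, 1)))
    A = np.hstack(cols)
    y = np.asarray(measured, dtype=float)
    if not fit_background:
        y = y - fixed_background
    if channel_mask is None:
        channel_mask = np.ones(m, dtype=bool)
    scale = 1.0 / np.sqrt(np.asarray(weights, dtype=float)[channel_mask])
    coef, _ = optimize.nnls(A[channel_mask] * scale[:, None], y[channel_mask] * scale)
    k = bases.shape[0]
    alphas = coef[:k]
    alpha_lens = float(coef[k]) if lens_curve is not None else 0.0
    b = float(coef[-1]) if fit_background else float(fixed_background)
    model = A @ coef + (0.0 if fit_background else fixed_background)
    return alphas, alpha_lens, b, model


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(np.asarray(x, dtype=float), kernel, mode="same")


def estimate_background_preexcitation(hist: np.ndarray, guard: int = 10) -> float:
    """Mean counts of the pre-excitation channels (before the rising edge)."""
    hist = np.asarray(hist, dtype=float)
    peak = int(np.argmax(_moving_average(hist, 5)))
    stop = max(1, peak - guard)
    return float(hist[:stop].mean())


class _Parameterization:
    """Packs the free nonlinear parameters of a spec into a flat vector."""

    def __init__(self, spec: ModelSpec, config: FitConfig):
        self.spec = spec
        names: list[str] = [f"tau{i + 1}" for i in range(spec.n_components)]
        if spec.shifted and spec.tc_free is not None:
            names += [f"tc{i + 1}" for i, free in enumerate(spec.tc_free) if free]
        if spec.stretched and spec.fix_beta is None:
            names.append("beta")
        if spec.kind == "lens_corrected":
            names.append("tc_lens")
        self.names = [n for n in names if n not in config.fixed]
        self.fixed = dict(config.fixed)
        self.bounds = []
        for n in self.names:
            key = "tau" if n.startswith("tau") else ("tc" if n.startswith("tc") and n != "tc_lens" else n)
            self.bounds.append(config.bounds.get(n, _DEFAULT_BOUNDS[key]))

    @property
    def n_free(self) -> int:
        return len(self.names)

    def to_params(self, theta: np.ndarray, template: ParamVector) -> ParamVector:
        vals = dict(zip(self.names, theta))
        vals.update(self.fixed)
        k = self.spec.n_components
        tau = np.array([vals.get(f"tau{i + 1}", template.tau[i]) for i in range(k)])
        tc = np.array([vals.get(f"tc{i + 1}", template.tc[i]) for i in range(k)])
        return replace(
            template,
            tau=tau,
            tc=tc,
            beta=float(vals.get("beta", self.spec.fix_beta or template.beta)),
            tc_lens=float(vals.get("tc_lens", template.tc_lens)),
        )

    def from_params(self, params: ParamVector) -> np.ndarray:
        out = []
        for n in self.names:
            if n.startswith("tau"):
                out.append(params.tau[int(n[3:]) - 1])
            elif n == "beta":
                out.append(params.beta)
            elif n == "tc_lens":
                out.append(params.tc_lens)
            else:
                out.append(params.tc[int(n[2:]) - 1])
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(np.asarray(out, dtype=float), lo, hi)


class _Objective:
    """Variable-projection reduced chi-square of one histogram."""

    def __init__(
        self,
        hist: np.ndarray,
        spec: ModelSpec,
        config: FitConfig,
        irf: IRFCurve,
        time: TimeAxis,
        channel_mask: np.ndarray,
        template: ParamVector,
    ):
        self.hist = np.asarray(hist, dtype=float)
        self.spec = spec
        self.config = config
        self.irf = irf
        self.time = time
        self.mask = channel_mask
        self.template = template
        self.packer = _Parameterization(spec, config)
        self.neyman = compute_weights(self.hist, "neyman")
        self.fit_background = not config.background_from_preexcitation
        self.fixed_b = (
            estimate_background_preexcitation(self.hist)
            if config.background_from_preexcitation
            else 0.0
        )
        # free parameters: nonlinear + amplitudes (+ lens amplitude) (+ b)
        self.p = (
            self.packer.n_free
            + spec.n_components
            + (1 if spec.kind == "lens_corrected" else 0)
            + (1 if self.fit_background else 0)
        )

    def _solve(self, theta: np.ndarray) -> tuple[ParamVector, np.ndarray, np.ndarray]:
        pv = self.packer.to_params(theta, self.template)
        bases = evaluate_decay_components(self.spec, pv, self.irf, self.time)
        lens_curve = None
        if self.spec.kind == "lens_corrected":
            lens_curve = shift_curve(self.spec.lens.values, pv.tc_lens, self.time)
        weights = self.neyman
        alphas, a_lens, b, model = solve_amplitudes(
            bases, lens_curve, self.hist, weights, self.mask,
            self.fit_background, self.fixed_b,
        )
        if self.config.weighting == "pearson":
            # one re-weighting pass: weights follow the current model
            weights = compute_weights(self.hist, "pearson", model)
            alphas, a_lens, b, model = solve_amplitudes(
                bases, lens_curve, self.hist, weights, self.mask,
                self.fit_background, self.fixed_b,
            )
        pv = replace(pv, alpha=alphas, alpha_lens=a_lens, background=b)
        return pv, model, weights

    def chi2(self, theta: np.ndarray) -> float:
        try:
            _, model, weights = self._solve(theta)
        except (ValueError, FloatingPointError):
            return np.inf
        return reduced_chi2(self.hist, model, weights, self.p, self.mask)

    def result(self, theta: np.ndarray) -> tuple[ParamVector, float]:
        pv, model, weights = self._solve(theta)
        return pv, reduced_chi2(self.hist, model, weights, self.p, self.mask)


def _channel_mask(
    hist: np.ndarray,
    spec: ModelSpec,
    config: FitConfig,
    artifact_intervals: list[tuple[int, int]],
) -> np.ndarray:
    m = np.asarray(hist).size
    mask = np.ones(m, dtype=bool)
    if config.resolved_interval(spec) == "decay_only":
        peak = int(np.argmax(_moving_average(hist, 5)))
        mask[:peak] = False
    for a, b in artifact_intervals:
        mask[a:b] = False
    return mask


def _sort_components(params: ParamVector, spec: ModelSpec) -> ParamVector:
    """Order components by ascending lifetime for stable map labels."""
    if spec.tc_free is not None:
        return params
    order = np.argsort(params.tau)
    return replace(
        params,
        alpha=params.alpha[order],
        tau=params.tau[order],
        tc=params.tc[order],
    )


def minimize_pixel(
    hist: np.ndarray,
    spec: ModelSpec,
    config: FitConfig,
    init: ParamVector,
    irf: IRFCurve,
    time: TimeAxis,
    artifact_intervals: list[tuple[int, int]] | None = None,
    neighbor_hists: list[np.ndarray] | None = None,
) -> PixelFitResult:
    """Bound-constrained Nelder-Mead fit of one pixel's histogram.

    Amplitudes and background are re-solved by non-negative least squares at
    every objective evaluation.  With ``neighbor_hists`` the objective is
    the neighborhood figure of merit (squared central chi-square plus the
    mean of the neighbours' chi-squares under the central parameters).
    """
    artifact_intervals = artifact_intervals or []
    mask = _channel_mask(hist, spec, config, artifact_intervals)
    obj = _Objective(hist, spec, config, irf, time, mask, init)
    use_neighbors = config.neighborhood_fit and neighbor_hists
    if use_neighbors:
        nbr_objs = [
            _Objective(h, spec, config, irf, time,
                       _channel_mask(h, spec, config, artifact_intervals), init)
            for h in neighbor_hists
        ]

        def fom(theta):
            center = obj.chi2(theta)
            if not np.isfinite(center):
                return np.inf
            return neighborhood_chi2(center, [o.chi2(theta) for o in nbr_objs])
    else:
        fom = obj.chi2

    theta0 = obj.packer.from_params(init)
    if theta0.size == 0:
        pv, chi2 = obj.result(theta0)
        return PixelFitResult(_sort_components(pv, spec), chi2, 0, True, mask)
    res = optimize.minimize(
        fom,
        theta0,
        method="Nelder-Mead",
        bounds=obj.packer.bounds,
        options={
            "maxiter": config.nm_maxiter,
            "xatol": config.nm_xatol,
            "fatol": config.nm_fatol,
        },
    )
    pv, chi2 = obj.result(res.x)
    return PixelFitResult(
        params=_sort_components(pv, spec),
        chi2=chi2,
        n_iter=int(res.nit),
        converged=bool(res.success),
        channel_mask=mask,
    )


def global_init(
    total_hist: np.ndarray,
    spec: ModelSpec,
    config: FitConfig,
    irf: IRFCurve,
    time: TimeAxis,
    seed: int | None = None,
    artifact_intervals: list[tuple[int, int]] | None = None,
) -> ParamVector:
    """Differential-evolution fit of the image-integrated decay.

    The stochastic stage runs once per image on the summed histogram (best
    SNR) and its solution initializes every pixel-wise deterministic fit.
    """
    artifact_intervals = artifact_intervals or []
    mask = _channel_mask(total_hist, spec, config, artifact_intervals)
    template = ParamVector(
        alpha=np.ones(spec.n_components),
        tau=np.linspace(200.0, 3000.0, spec.n_components),
        beta=spec.fix_beta if (spec.stretched and spec.fix_beta) else 1.0,
    )
    obj = _Objective(total_hist, spec, config, irf, time, mask, template)
    if obj.packer.n_free == 0:
        pv, _ = obj.result(np.empty(0))
        return pv
    res = optimize.differential_evolution(
        obj.chi2,
        bounds=obj.packer.bounds,
        seed=config.seed if seed is None else seed,
        popsize=config.de_popsize,
        maxiter=config.de_maxiter,
        tol=config.de_tol,
        polish=False,
    )
    pv, _ = obj.result(res.x)
    return _sort_components(pv, spec)


def detect_reflection_artifacts(
    total_hist: np.ndarray,
    smooth: int = 5,
    min_run: int = 2,
) -> list[tuple[int, int]]:
    """Detect reflection artifacts on the image-integrated decay.

    Reflections in the optical path re-inject delayed photons, producing a
    rising section in the otherwise monotone decay.  The gradient of the
    5-channel moving-average smoothed curve is scanned after the global
    peak for sustained rises (>= min_run consecutive positive gradients).
    Each candidate is refined on the raw curve: the artifact start is the
    preceding local minimum, its peak the local maximum ending the rise,
    and the masked interval is [start, start + 3 * (peak - start)) —
    the decay of the artifact is taken as three times its rise.  Overlapping
    intervals are merged.
    """
    hist = np.asarray(total_hist, dtype=float)
    m = hist.size
    s = _moving_average(hist, smooth)
    gp = int(np.argmax(s))
    g = np.diff(s)
    intervals: list[tuple[int, int]] = []
    k = gp + 1
    while k < m - 1:
        if g[k] > 0:
            run_start = k
            while k < m - 1 and g[k] > 0:
                k += 1
            run_len = k - run_start
            if run_len >= min_run:
                hi = min(m, k + smooth)
                peak_ch = run_start + int(np.argmax(hist[run_start:hi]))
                lo = max(gp + 1, run_start - smooth)
                start_ch = lo + int(np.argmin(hist[lo:peak_ch + 1]))
                if peak_ch > start_ch:
                    end = min(m, start_ch + 3 * (peak_ch - start_ch))
                    intervals.append((start_ch, end))
        else:
            k += 1
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return merged


def _result_param_names(spec: ModelSpec) -> list[str]:
    names = []
    for i in range(spec.n_components):
        names += [f"alpha{i + 1}", f"tau{i + 1}"]
    if spec.shifted:
        names += [f"tc{i + 1}" for i in range(spec.n_components)]
    if spec.stretched and spec.fix_beta is None:
        names.append("beta")
    if spec.kind == "lens_corrected":
        names += ["alpha_lens", "tc_lens"]
    names.append("background")
    return names


def _params_to_row(params: ParamVector, spec: ModelSpec) -> dict[str, float]:
    row = {}
    for i in range(spec.n_components):
        row[f"alpha{i + 1}"] = float(params.alpha[i])
        row[f"tau{i + 1}"] = float(params.tau[i])
        if spec.shifted:
            row[f"tc{i + 1}"] = float(params.tc[i])
    if spec.stretched and spec.fix_beta is None:
        row["beta"] = float(params.beta)
    if spec.kind == "lens_corrected":
        row["alpha_lens"] = float(params.alpha_lens)
        row["tc_lens"] = float(params.tc_lens)
    row["background"] = float(params.background)
    return row


def _row_to_params(maps: dict[str, np.ndarray], y: int, x: int, spec: ModelSpec) -> ParamVector:
    k = spec.n_components
    return ParamVector(
        alpha=np.array([maps[f"alpha{i + 1}"][y, x] for i in range(k)]),
        tau=np.array([max(maps[f"tau{i + 1}"][y, x], 1.0) for i in range(k)]),
        tc=(np.array([maps[f"tc{i + 1}"][y, x] for i in range(k)]) if spec.shifted else None),
        beta=float(maps.get("beta", np.ones((1, 1)))[y, x] if "beta" in maps else (spec.fix_beta or 1.0)),
        alpha_lens=float(maps["alpha_lens"][y, x]) if "alpha_lens" in maps else 0.0,
        tc_lens=float(maps["tc_lens"][y, x]) if "tc_lens" in maps else 0.0,
        background=float(maps["background"][y, x]),
    )


def fit_image(
    cube: TCSPCCube,
    spec: ModelSpec,
    config: FitConfig,
    irf: IRFCurve,
    radius_map: np.ndarray | None = None,
) -> FitResultMaps:
    """Two-stage fluorescence-lifetime fit of a (binned) cube.

    Pipeline: image-integrated decay -> reflection-artifact detection ->
    differential-evolution global initialization -> per-pixel Nelder-Mead
    fits -> iterative outlier treatment.  All stage settings and the seed
    are recorded in the result provenance.
    """
    time = cube.time
    total = sum_all_pixels(cube)
    artifacts = (
        detect_reflection_artifacts(total) if config.artifact_removal else []
    )
    init = global_init(
        total, spec, config, irf, time, artifact_intervals=artifacts
    )
    ny, nx, _ = cube.shape
    names = _result_param_names(spec)
    maps: dict[str, np.ndarray] = {n: np.zeros((ny, nx)) for n in names}
    maps["chi2"] = np.zeros((ny, nx))
    maps["converged"] = np.zeros((ny, nx))
    for y in range(ny):
        for x in range(nx):
            if config.neighborhood_fit:
                nbrs = [
                    cube.counts[yy, xx, :]
                    for yy in range(max(0, y - 1), min(ny, y + 2))
                    for xx in range(max(0, x - 1), min(nx, x + 2))
                    if (yy, xx) != (y, x)
                ]
            else:
                nbrs = None
            try:
                r = minimize_pixel(
                    cube.counts[y, x, :], spec, config, init, irf, time,
                    artifact_intervals=artifacts, neighbor_hists=nbrs,
                )
            except (ValueError, DegenerateDofError) as exc:
                log.warning("pixel (%d, %d) fit failed: %s", y, x, exc)
                continue
            for key, val in _params_to_row(r.params, spec).items():
                maps[key][y, x] = val
            maps["chi2"][y, x] = r.chi2
            maps["converged"][y, x] = float(r.converged)
    k = spec.n_components
    maps["tau_m"] = mean_lifetime(
        np.stack([np.maximum(maps[f"alpha{i + 1}"], 1e-12) for i in range(k)]),
        np.stack([np.maximum(maps[f"tau{i + 1}"], 1.0) for i in range(k)]),
    )
    if radius_map is not None:
        maps["radius"] = np.asarray(radius_map, dtype=float)
    results = FitResultMaps(
        maps=maps,
        artifact_intervals=artifacts,
        provenance={
            "model_kind": spec.kind,
            "n_components": spec.n_components,
            "incomplete_j": spec.incomplete_j,
            "weighting": config.weighting,
            "seed": int(config.seed),
            "fit_interval": config.resolved_interval(spec),
            "artifact_removal": config.artifact_removal,
            "outlier_window": config.outlier_window,
            "outlier_threshold": config.outlier_threshold,
        },
    )
    if config.outlier_iterations > 0:
        results, n_det, n_imp = treat_outliers(
            results, cube, spec, config, irf,
            window=config.outlier_window,
            threshold=config.outlier_threshold,
            iterations=config.outlier_iterations,
        )
        results.provenance["outliers_detected"] = n_det
        results.provenance["outliers_improved"] = n_imp
    return results


def _window_median_flags(img: np.ndarray, window: int, threshold: float) -> np.ndarray:
    ny, nx = img.shape
    half = window // 2
    flags = np.zeros((ny, nx), dtype=bool)
    for y in range(ny):
        y0, y1 = max(0, y - half), min(ny, y + half + 1)
        for x in range(nx):
            x0, x1 = max(0, x - half), min(nx, x + half + 1)
            med = np.median(img[y0:y1, x0:x1])
            if med != 0 and abs(img[y, x] - med) / abs(med) > threshold:
                flags[y, x] = True
    return flags


def treat_outliers(
    results: FitResultMaps,
    cube: TCSPCCube,
    spec: ModelSpec,
    config: FitConfig,
    irf: IRFCurve,
    window: int = 7,
    threshold: float = 0.30,
    iterations: int = 1,
) -> tuple[FitResultMaps, int, int]:
    """Detect and re-fit outlier pixels via a sliding median window.

    A pixel is flagged when, in any lifetime map or the chi-square map, its
    value deviates from the window median by more than the relative
    threshold.  Flagged pixels are re-fitted starting from the parameters of
    the window's best-chi-square pixel; the re-fit is kept only if its
    figure of merit strictly improves.
    """
    maps = {k: v.copy() for k, v in results.maps.items()}
    inspected = [k for k in maps if (k.startswith("tau") and k != "tau_m")] + ["chi2"]
    half = window // 2
    ny, nx = results.shape
    n_detected = 0
    n_improved = 0
    for _ in range(iterations):
        flags = np.zeros((ny, nx), dtype=bool)
        for name in inspected:
            flags |= _window_median_flags(maps[name], window, threshold)
        n_detected += int(flags.sum())
        for y, x in zip(*np.nonzero(flags)):
            y0, y1 = max(0, y - half), min(ny, y + half + 1)
            x0, x1 = max(0, x - half), min(nx, x + half + 1)
            chi_win = maps["chi2"][y0:y1, x0:x1]
            by, bx = np.unravel_index(int(np.argmin(chi_win)), chi_win.shape)
            init = _row_to_params(maps, y0 + by, x0 + bx, spec)
            try:
                r = minimize_pixel(
                    cube.counts[y, x, :], spec, config, init, irf, cube.time,
                    artifact_intervals=results.artifact_intervals,
                )
            except (ValueError, DegenerateDofError):
                continue
            if r.chi2 < maps["chi2"][y, x]:
                for key, val in _params_to_row(r.params, spec).items():
                    maps[key][y, x] = val
                maps["chi2"][y, x] = r.chi2
                n_improved += 1
        k = spec.n_components
        maps["tau_m"] = mean_lifetime(
            np.stack([np.maximum(maps[f"alpha{i + 1}"], 1e-12) for i in range(k)]),
            np.stack([np.maximum(maps[f"tau{i + 1}"], 1.0) for i in range(k)]),
        )
    out = FitResultMaps(
        maps=maps,
        artifact_intervals=list(results.artifact_intervals),
        provenance=dict(results.provenance),
    )
    return out, n_detected, n_improved
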