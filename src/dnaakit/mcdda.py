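"""Monte-Carlo diffusion distribution analysis (MC-DDA) of two-state motion.

A DnaA molecule switches between a freely diffusing state (D_free, default
2.7 um^2/s) and a DNA-bound, effectively immobile state, with first-order
rates k_fb (free -> bound) and k_bf (bound -> free).  The simulator
propagates particles inside a spherocylindrical cell with Brownian sub-steps
(t_step = 0.1 ms), records the (x, y) position every camera frame
(t_frame = 10 ms) with Gaussian localisation noise (sigma = 0.035 um), and
truncates tracks at 1-8 steps following the exponential track-length law of
the photoactivatable label (mean 3 steps).

Because bound molecules still jitter by the localisation noise, the apparent
diffusion coefficient of the immobile state has a floor of
sigma^2 / t_frame (~0.12 um^2/s at the defaults).

Fitting: :class:`DiffusionKineticsModel` wraps a measured 85-bin D*
histogram; :meth:`fit` adjusts (k_fb, k_bf) by Levenberg-Marquardt least
squares between the measured bin fractions and freshly simulated ones,
using common random numbers (a fixed simulation seed across objective
evaluations) so the objective is deterministic and smooth enough to
differentiate numerically.  Rates are optimised on a log scale to enforce
positivity; 95% confidence intervals come from the linearised covariance at
the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq, least_squares

from .tracking import DiffusionHistogram, apparent_D_batch, build_histogram

FREE, BOUND = 0, 1


def stationary_fractions(k_fb: float, k_bf: float) -> tuple[float, float]:
    """Stationary (p_free, p_bound) of the two-state switch.

    p_free = k_bf / (k_fb + k_bf); p_bound = k_fb / (k_fb + k_bf).
    With both rates zero there is no stationary law; the caller must fix the
    initial state explicitly.
    """
    if k_fb < 0 or k_bf < 0:
        raise ValueError("rates must be >= 0")
    tot = k_fb + k_bf
    if tot == 0:
        raise ValueError("both rates are 0: supply an explicit initial state")
    return k_bf / tot, k_fb / tot


def bound_fraction(k_fb: float, k_bf: float) -> float:
    """Stationary bound fraction k_fb / (k_fb + k_bf)."""
    return stationary_fractions(k_fb, k_bf)[1]


def mean_bound_time(k_bf: float) -> float:
    """Mean dwell time in the bound state, 1 / k_bf (seconds)."""
    if k_bf <= 0:
        raise ValueError("k_bf must be > 0")
    return 1.0 / k_bf


def track_length_probabilities(
    mean_steps: float = 3.0, min_steps: int = 1, max_steps: int = 8
) -> np.ndarray:
    """P(n) on {min..max} proportional to exp(-n/tau), truncated mean fixed.

    tau is solved numerically so that sum n P(n) equals ``mean_steps``.
    """
    n = np.arange(min_steps, max_steps + 1, dtype=float)
    if not min_steps < mean_steps < n.mean():
        raise ValueError(
            f"truncated mean {mean_steps} unreachable on {min_steps}..{max_steps}")

    def mean_at(tau):
        w = np.exp(-(n - min_steps) / tau)  # shifted for stability
        return (n * w).sum() / w.sum() - mean_steps

    tau = brentq(mean_at, 1e-3, 1e6)
    w = np.exp(-(n - min_steps) / tau)
    return w / w.sum()


def sample_track_length(
    rng: np.random.Generator, probs: np.ndarray | None = None, min_steps: int = 1
) -> int:
    """Draw a track length in steps from the truncated exponential law."""
    if probs is None:
        probs = track_length_probabilities()
    return int(rng.choice(np.arange(min_steps, min_steps + len(probs)), p=probs))


@dataclass(frozen=True)
class CellShape:
    """Spherocylinder: a cylinder along x capped by two hemispheres."""

    cylinder_length: float = 2.0  # um
    radius: float = 0.5  # um

    def __post_init__(self):
        if self.cylinder_length <= 0 or self.radius <= 0:
            raise ValueError("cell dimensions must be > 0")

    def contains(self, pos: np.ndarray) -> np.ndarray:
        """Vectorised membership test for (..., 3) positions."""
        pos = np.asarray(pos, dtype=float)
        x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
        h = self.cylinder_length / 2.0
        dx = np.maximum(np.abs(x) - h, 0.0)
        return dx**2 + y**2 + z**2 <= self.radius**2 + 1e-15


@dataclass(frozen=True)
class TwoStateModel:
    """Kinetic and optical parameter set of the MC-DDA forward simulator."""

    k_fb: float  # free -> bound rate, 1/s
    k_bf: float  # bound -> free rate, 1/s
    d_free: float = 2.7  # um^2/s
    sigma_loc: float = 0.035  # um, per-axis localisation noise
    t_frame: float = 0.010  # s
    t_step: float = 1e-4  # s
    mean_track_steps: float = 3.0
    min_track_steps: int = 1
    max_track_steps: int = 8

    def __post_init__(self):
        if self.k_fb < 0 or self.k_bf < 0:
            raise ValueError("rates must be >= 0")
        if self.d_free < 0 or self.sigma_loc < 0:
            raise ValueError("d_free and sigma_loc must be >= 0")
        n_sub = self.t_frame / self.t_step
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("t_frame must be an integer multiple of t_step")

    @property
    def n_substeps(self) -> int:
        return int(round(self.t_frame / self.t_step))

    @property
    def d_immobile(self) -> float:
        """Apparent D* floor of a strictly immobile molecule."""
        return self.sigma_loc**2 / self.t_frame

    @property
    def track_length_probs(self) -> np.ndarray:
        return track_length_probabilities(
            self.mean_track_steps, self.min_track_steps, self.max_track_steps
        )

    def bound_fraction(self) -> float:
        return bound_fraction(self.k_fb, self.k_bf)


@njit(cache=True)
def _sim_kernel(n_particles, k_fb, k_bf, d_free, sigma, n_sub, t_step,
                half_len, radius, tl_cum, min_steps, start_state, seed):
    np.random.seed(seed)
    max_locs = tl_cum.size + min_steps
    n_locs = np.empty(n_particles, np.int64)
    obs = np.zeros((n_particles, max_locs, 2))
    true_pos = np.zeros((n_particles, max_locs, 3))
    states = np.zeros((n_particles, max_locs), np.uint8)
    s = np.sqrt(2.0 * d_free * t_step)
    r2 = radius * radius
    tot = k_fb + k_bf
    p_bound = k_fb / tot if tot > 0.0 else 0.0
    for i in range(n_particles):
        u = np.random.random()
        steps = min_steps + tl_cum.size - 1
        for j in range(tl_cum.size):
            if u <= tl_cum[j]:
                steps = min_steps + j
                break
        # uniform initial position by rejection from the bounding box
        while True:
            x = (np.random.random() * 2.0 - 1.0) * (half_len + radius)
            y = (np.random.random() * 2.0 - 1.0) * radius
            z = (np.random.random() * 2.0 - 1.0) * radius
            dx = abs(x) - half_len
            if dx < 0.0:
                dx = 0.0
            if dx * dx + y * y + z * z <= r2:
                break
        if start_state >= 0:
            st = start_state
        else:
            st = 1 if np.random.random() < p_bound else 0
        k_cur = k_fb if st == FREE else k_bf
        t_change = 1e300 if k_cur <= 0.0 else -np.log(np.random.random()) / k_cur
        n_locs[i] = steps + 1
        true_pos[i, 0, 0] = x
        true_pos[i, 0, 1] = y
        true_pos[i, 0, 2] = z
        states[i, 0] = st
        obs[i, 0, 0] = x + np.random.normal() * sigma
        obs[i, 0, 1] = y + np.random.normal() * sigma
        for f in range(1, steps + 1):
            for _ in range(n_sub):
                if st == FREE:
                    for _attempt in range(100):
                        nx = x + np.random.normal() * s
                        ny = y + np.random.normal() * s
                        nz = z + np.random.normal() * s
                        dx = abs(nx) - half_len
                        if dx < 0.0:
                            dx = 0.0
                        if dx * dx + ny * ny + nz * nz <= r2:
                            x, y, z = nx, ny, nz
                            break
                t_change -= t_step
                if t_change <= 0.0:
                    st = 1 - st
                    k_cur = k_fb if st == FREE else k_bf
                    t_change = (1e300 if k_cur <= 0.0
                                else -np.log(np.random.random()) / k_cur)
            true_pos[i, f, 0] = x
            true_pos[i, f, 1] = y
            true_pos[i, f, 2] = z
            states[i, f] = st
            obs[i, f, 0] = x + np.random.normal() * sigma
            obs[i, f, 1] = y + np.random.normal() * sigma
    return n_locs, obs, true_pos, states


@dataclass
class SimulationResult:
    """Synthetic tracks from the forward simulator (padded arrays)."""

    model: TwoStateModel
    shape: CellShape
    seed: int
    n_locs: np.ndarray  # (n_particles,)
    observed_xy: np.ndarray  # (n_particles, max_locs, 2), noisy (x, y)
    true_positions: np.ndarray  # (n_particles, max_locs, 3)
    states: np.ndarray  # (n_particles, max_locs), state at each frame

    @property
    def n_particles(self) -> int:
        return len(self.n_locs)

    def frame_mask(self) -> np.ndarray:
        """(n_particles, max_locs) boolean validity mask."""
        return np.arange(self.observed_xy.shape[1])[None, :] < self.n_locs[:, None]

    def apparent_d(self) -> np.ndarray:
        """Per-track D* (NaN for tracks with < 3 localisations)."""
        return apparent_D_batch(self.observed_xy, self.n_locs, self.model.t_frame)


def simulate(
    model: TwoStateModel,
    shape: CellShape = CellShape(),
    n_particles: int = 50_000,
    seed: int = 0,
    start_state: int | None = None,
) -> SimulationResult:
    """Forward-simulate two-state confined Brownian tracks.

    Each particle starts uniformly inside the spherocylinder in a state drawn
    from the stationary law (or ``start_state`` when given — mandatory when
    both rates are zero), carries an exponential waiting time to its next
    switch, takes isotropic 3-D Gaussian sub-steps of per-axis sd
    sqrt(2*D_free*t_step) while free (redrawn up to 100 times if a step
    leaves the cell) and is immobile while bound.  Every t_frame the (x, y)
    position plus Gaussian localisation noise is recorded; track lengths
    follow the truncated exponential law.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if model.k_fb == 0 and model.k_bf == 0 and start_state is None:
        raise ValueError("both rates are 0: supply start_state")
    tl_cum = np.cumsum(model.track_length_probs)
    tl_cum[-1] = 1.0
    n_locs, obs, true_pos, states = _sim_kernel(
        n_particles, float(model.k_fb), float(model.k_bf), float(model.d_free),
        float(model.sigma_loc), model.n_substeps, float(model.t_step),
        shape.cylinder_length / 2.0, shape.radius, tl_cum,
        model.min_track_steps, -1 if start_state is None else int(start_state),
        int(seed) % (2**32),
    )
    return SimulationResult(model=model, shape=shape, seed=seed, n_locs=n_locs,
                            observed_xy=obs, true_positions=true_pos,
                            states=states)


def render_histogram(
    model: TwoStateModel,
    shape: CellShape = CellShape(),
    n_particles: int = 50_000,
    seed: int = 0,
    start_state: int | None = None,
    **hist_kwargs,
) -> DiffusionHistogram:
    """Simulate and bin: the forward map from rates to a D* histogram.

    Tracks with fewer than 3 localisations are excluded, exactly as in the
    measurement pipeline, and the same 85-bin log histogram is used.
    """
    sim = simulate(model, shape, n_particles, seed, start_state)
    d = sim.apparent_d()
    return build_histogram(d[np.isfinite(d)], **hist_kwargs)


@dataclass
class FitResult:
    """Fitted switching rates with linearised 95% confidence intervals."""

    k_fb_hat: float
    k_bf_hat: float
    k_fb_ci95: float  # halfwidth, natural scale
    k_bf_ci95: float
    bound_fraction: float
    bound_fraction_sd: float
    mean_bound_time: float  # s
    residual_norm: float
    n_particles_fit: int
    seed: int
    converged: bool
    n_fev: int
    cov_log: np.ndarray | None = field(default=None, repr=False)


class DiffusionKineticsModel:
    """MC-DDA kinetic model for a measured apparent-D* histogram.

    Parameters
    ----------
    data
        The measured 85-bin :class:`~dnaakit.tracking.DiffusionHistogram`.
    template
        A :class:`TwoStateModel` carrying the fixed optical/physical
        parameters (D_free, sigma, frame/step times, track-length law); its
        rates are overwritten during fitting.
    shape
        Confining cell geometry.
    n_particles_fit
        Particles per objective evaluation (the study used 50,000 for the
        fit and 250,000 for visualisation renders).
    seed
        Common-random-numbers seed: each objective evaluation re-simulates
        with this same seed, making the objective a deterministic function
        of the rates.
    """

    def __init__(self, data: DiffusionHistogram,
                 template: TwoStateModel | None = None,
                 shape: CellShape = CellShape(),
                 n_particles_fit: int = 50_000,
                 seed: int = 0):
        if data.n_tracks <= 0 or data.fractions.sum() == 0:
            raise ValueError("data histogram is empty")
        self.data = data
        self.template = template or TwoStateModel(k_fb=100.0, k_bf=100.0)
        self.shape = shape
        self.n_particles_fit = n_particles_fit
        self.seed = seed

    @classmethod
    def from_d_values(cls, d_values, **kwargs) -> "DiffusionKineticsModel":
        return cls(build_histogram(d_values), **kwargs)

    def _render(self, k_fb: float, k_bf: float) -> np.ndarray:
        m = replace(self.template, k_fb=k_fb, k_bf=k_bf)
        h = render_histogram(m, self.shape, self.n_particles_fit, self.seed,
                             d_min=self.data.edges[0], d_max=self.data.edges[-1],
                             n_bins=len(self.data.fractions))
        return h.fractions

    def fit(self, init: tuple[float, float] = (100.0, 100.0),
            xtol: float = 1e-4, ftol: float = 1e-6, max_nfev: int = 200
            ) -> "DiffusionKineticsResults":
        """Levenberg-Marquardt fit of (k_fb, k_bf) on a log scale."""
        if min(init) <= 0:
            raise ValueError("initial rates must be > 0")
        target = self.data.fractions

        def resid(logk):
            return self._render(np.exp(logk[0]), np.exp(logk[1])) - target

        res = least_squares(resid, np.log(np.asarray(init, dtype=float)),
                            method="lm", diff_step=0.05, xtol=xtol, ftol=ftol,
                            max_nfev=max_nfev)
        k_fb, k_bf = np.exp(res.x)
        m, p = len(target), 2
        s2 = 2.0 * res.cost / max(m - p, 1)
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
        sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        f = bound_fraction(k_fb, k_bf)
        # delta method: d f / d log k_fb = f(1-f), d f / d log k_bf = -f(1-f)
        var_f = (f * (1 - f)) ** 2 * (cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        fit = FitResult(
            k_fb_hat=float(k_fb), k_bf_hat=float(k_bf),
            k_fb_ci95=float(1.96 * k_fb * sd_log[0]),
            k_bf_ci95=float(1.96 * k_bf * sd_log[1]),
            bound_fraction=float(f),
            bound_fraction_sd=float(np.sqrt(max(var_f, 0.0))),
            mean_bound_time=float(1.0 / k_bf) if k_bf > 0 else float("inf"),
            residual_norm=float(np.sqrt(2.0 * res.cost)),
            n_particles_fit=self.n_particles_fit, seed=self.seed,
            converged=bool(res.success), n_fev=int(res.nfev),
            cov_log=cov,
        )
        return DiffusionKineticsResults(self, fit)


class DiffusionKineticsResults:
    """Results wrapper: estimates, uncertainties, rendering and summary."""

    def __init__(self, model: DiffusionKineticsModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> dict:
        return {"k_fb": self._fit.k_fb_hat, "k_bf": self._fit.k_bf_hat}

    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["_fit"], name)
        except AttributeError:
            raise AttributeError(name) from None

    def conf_int(self) -> dict:
        f = self._fit
        return {
            "k_fb": (f.k_fb_hat - f.k_fb_ci95, f.k_fb_hat + f.k_fb_ci95),
            "k_bf": (f.k_bf_hat - f.k_bf_ci95, f.k_bf_hat + f.k_bf_ci95),
        }

    def render(self, n_particles: int = 250_000, seed: int | None = None
               ) -> DiffusionHistogram:
        """High-particle-count render of the fitted model for display."""
        m = replace(self.model.template, k_fb=self._fit.k_fb_hat,
                    k_bf=self._fit.k_bf_hat)
        return render_histogram(m, self.model.shape, n_particles,
                                self.model.seed if seed is None else seed)

    def summary(self) -> str:
        f = self._fit
        t = self.model.template
        lines = [
            "MC-DDA two-state kinetic fit",
            "=" * 60,
            f"data: {self.model.data.n_tracks} tracks in "
            f"{len(self.model.data.fractions)} log bins "
            f"[{self.model.data.edges[0]:g}, {self.model.data.edges[-1]:g}] um^2/s",
            f"fixed: D_free = {t.d_free} um^2/s, sigma = {t.sigma_loc} um, "
            f"t_frame = {t.t_frame*1e3:g} ms, t_step = {t.t_step*1e3:g} ms",
            f"simulated particles per evaluation: {f.n_particles_fit}, "
            f"seed {f.seed}",
            "-" * 60,
            f"k_free->bound : {f.k_fb_hat:9.2f} +/- {f.k_fb_ci95:7.2f} 1/s (95% CI)",
            f"k_bound->free : {f.k_bf_hat:9.2f} +/- {f.k_bf_ci95:7.2f} 1/s (95% CI)",
            f"bound fraction: {100*f.bound_fraction:6.1f} +/- "
            f"{100*f.bound_fraction_sd:4.1f} %",
            f"mean bound time: {1e3*f.mean_bound_time:6.1f} ms",
            f"residual norm: {f.residual_norm:.3e}   "
            f"({'converged' if f.converged else 'NOT converged'}, "
            f"{f.n_fev} evaluations)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_particles_render: int = 250_000):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        ax.stairs(data.fractions, data.edges, fill=True, alpha=0.4, label="data")
        fit_h = self.render(n_particles_render)
        ax.stairs(fit_h.fractions, fit_h.edges, color="C3", label="MC-DDA fit")
        ax.set_xscale("log")
        ax.set_xlabel(r"apparent $D^*$ ($\mu m^2$/s)")
        ax.set_ylabel("fraction of tracks")
        ax.legend()
        return ax


def fit_rates(data: DiffusionHistogram, template: TwoStateModel | None = None,
              init: tuple[float, float] = (100.0, 100.0),
              shape: CellShape = CellShape(), n_fit: int = 50_000,
              seed: int = 0) -> FitResult:
    """Functional wrapper around :class:`DiffusionKineticsModel`."""
    model = DiffusionKineticsModel(data, template, shape, n_fit, seed)
    return model.fit(init=init)._fit
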