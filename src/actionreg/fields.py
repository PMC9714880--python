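"""Generic dynamic neural field (DNF) machinery.

A DNF describes the firing-rate activity ``u(x, t)`` of a population of
neurons over a continuous feature space (here: movement direction in degrees,
or an abstract index for context populations).  Activity evolves under leaky
integration toward the resting level ``h``, shaped by external input, a
difference-of-Gaussians lateral-interaction kernel (local excitation,
surround inhibition) applied to the sigmoided field output, and projections
from other fields:

    tau * du/dt = -u + h + S(x, t) + [w (*) f(u)](x, t) + sum_k [w_jk (*) f_k(u_k)]

Integration is forward Euler with additive Gaussian noise scaled by
``sqrt(dt)`` (Euler-Maruyama), so trial statistics are invariant to step-size
refinement.  The 0-180 degree direction space is treated as a bounded line,
not a ring, so convolutions are zero-padded (plain matrix products against a
distance-dependent weight matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, InvalidParameterError, WiringError

__all__ = [
    "KernelSpec",
    "FieldSpec",
    "FieldState",
    "NoiseSpec",
    "Projection",
    "kernel_weights",
    "sigmoid_output",
    "step_field",
    "project",
]


@dataclass(frozen=True)
class KernelSpec:
    """Difference-of-Gaussians lateral interaction kernel.

    Parameters
    ----------
    c_exc, c_inh : float
        Amplitudes of the excitatory and inhibitory Gaussian components.
    sigma_exc, sigma_inh : float
        Widths of the two components, in the same units as the field labels.
        Local excitation with broader surround inhibition (``sigma_inh >
        sigma_exc``) is the typical regime; the reverse is allowed with a
        warning.
    """

    c_exc: float
    c_inh: float
    sigma_exc: float
    sigma_inh: float

    def __post_init__(self):
        vals = (self.c_exc, self.c_inh, self.sigma_exc, self.sigma_inh)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"kernel parameters must be finite, got {vals}")
        if any(v < 0 for v in vals):
            raise InvalidParameterError(f"kernel parameters must be >= 0, got {vals}")
        if self.c_exc > 0 and self.sigma_exc <= 0:
            raise InvalidParameterError("sigma_exc must be > 0 when c_exc > 0")
        if self.c_inh > 0 and self.sigma_inh <= 0:
            raise InvalidParameterError("sigma_inh must be > 0 when c_inh > 0")
        if self.c_exc > 0 and self.c_inh > 0 and self.sigma_inh <= self.sigma_exc:
            warnings.warn(
                "kernel has sigma_inh <= sigma_exc (inhibition narrower than "
                "excitation); the usual regime is local excitation with "
                "broader surround inhibition",
                stacklevel=2,
            )


def kernel_weights(spec: KernelSpec, labels: np.ndarray) -> np.ndarray:
    """Build the square lateral-weight matrix for evenly spaced labels.

    Entry ``(i, j)`` is ``c_exc * exp(-(x_i - x_j)^2 / (2 sigma_exc^2))
    - c_inh * exp(-(x_i - x_j)^2 / (2 sigma_inh^2))``.  The matrix is
    symmetric because the kernel depends only on ``|x_i - x_j|``.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 1 or labels.size < 1:
        raise InvalidParameterError("labels must be a non-empty 1-D coordinate vector")
    if labels.size > 2:
        steps = np.diff(labels)
        if not np.allclose(steps, steps[0]):
            raise InvalidParameterError("labels must be evenly spaced")
    d2 = (labels[:, None] - labels[None, :]) ** 2
    w = np.zeros_like(d2)
    if spec.c_exc > 0:
        w += spec.c_exc * np.exp(-d2 / (2.0 * spec.sigma_exc**2))
    if spec.c_inh > 0:
        w -= spec.c_inh * np.exp(-d2 / (2.0 * spec.sigma_inh**2))
    return w


def sigmoid_output(u: np.ndarray, beta: float, u0: float = 0.0) -> np.ndarray:
    """Logistic output nonlinearity ``f(u) = 1 / (1 + exp(-beta (u - u0)))``.

    ``u0`` is the soft participation threshold; the default 0 reproduces the
    plain logistic.  Saturates gracefully for large ``|u|``.
    """
    if beta <= 0:
        raise InvalidParameterError(f"beta must be > 0, got {beta}")
    # expit equivalent, written explicitly to control clipping behavior
    z = np.clip(beta * (np.asarray(u, dtype=float) - u0), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FieldSpec:
    """Static description of one dynamic neural field.

    ``labels`` carries the per-neuron coordinate: degrees for direction-tuned
    fields (spanning [0, 180] inclusive, evenly spaced), an abstract index
    otherwise.
    """

    name: str
    n_neurons: int
    labels: np.ndarray
    tau: float
    h: float
    beta: float
    u0: float = 0.0
    kernel: KernelSpec | None = None
    ceiling: float = 50.0
    _kernel_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        if self.n_neurons < 1:
            raise InvalidParameterError("n_neurons must be >= 1")
        if self.labels.shape != (self.n_neurons,):
            raise WiringError(
                f"field '{self.name}': {self.labels.size} labels for "
                f"{self.n_neurons} neurons"
            )
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")

    @classmethod
    def directional(cls, name: str, n_neurons: int = 181, **kwargs) -> "FieldSpec":
        """A direction-tuned field with labels evenly spanning 0..180 degrees."""
        return cls(name=name, n_neurons=n_neurons,
                   labels=np.linspace(0.0, 180.0, n_neurons), **kwargs)

    @classmethod
    def indexed(cls, name: str, n_neurons: int, **kwargs) -> "FieldSpec":
        """A field over an abstract index coordinate (context, pause)."""
        return cls(name=name, n_neurons=n_neurons,
                   labels=np.arange(n_neurons, dtype=float), **kwargs)

    def kernel_matrix(self) -> np.ndarray | None:
        if self.kernel is None:
            return None
        if self._kernel_matrix is None:
            self._kernel_matrix = kernel_weights(self.kernel, self.labels)
        return self._kernel_matrix

    def rest_state(self) -> "FieldState":
        return FieldState(u=np.full(self.n_neurons, self.h, dtype=float), t=0.0)

    def output(self, u: np.ndarray) -> np.ndarray:
        return sigmoid_output(u, self.beta, self.u0)


@dataclass(frozen=True)
class FieldState:
    """Activity snapshot of one field: activation vector and simulated time (ms)."""

    u: np.ndarray
    t: float


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise for one field.

    ``sigma`` is the SD per neuron per sqrt(ms); the Euler step adds
    ``sigma * sqrt(dt) * xi``.  ``corr_len`` > 0 smooths the per-step noise
    vector with a Gaussian of that width (in label units) and rescales it to
    preserve unit per-neuron variance, so nearby neurons fluctuate together.
    ``sigma = 0`` makes the update deterministic.
    """

    sigma: float = 0.0
    corr_len: float = 0.0
    seed_stream: str = ""

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidParameterError(f"noise sigma must be >= 0, got {self.sigma}")

    def draw(self, rng: np.random.Generator, labels: np.ndarray, dt: float) -> np.ndarray | None:
        if self.sigma == 0.0:
            return None
        xi = rng.standard_normal(labels.size)
        if self.corr_len > 0 and labels.size > 1:
            from scipy.ndimage import convolve1d
            spacing = abs(labels[1] - labels[0])
            taps = _gaussian_taps(self.corr_len / spacing)
            xi = convolve1d(xi, taps, mode="constant")
        return self.sigma * np.sqrt(dt) * xi


def _gaussian_taps(sigma_samples: float) -> np.ndarray:
    """Unit-power Gaussian FIR taps (cached) for correlated-noise smoothing."""
    key = round(sigma_samples, 6)
    taps = _TAPS_CACHE.get(key)
    if taps is None:
        half = max(1, int(np.ceil(4 * sigma_samples)))
        x = np.arange(-half, half + 1, dtype=float)
        taps = np.exp(-x**2 / (2 * sigma_samples**2))
        taps /= np.sqrt(np.sum(taps**2))  # preserve per-neuron variance
        _TAPS_CACHE[key] = taps
    return taps


_TAPS_CACHE: dict = {}


@dataclass(frozen=True)
class Projection:
    """Directed inter-field connection.

    ``one_to_one`` maps neuron i to neuron i (requires equal sizes);
    ``one_to_all`` sends the summed source output to every target neuron.
    The effective contribution is ``weight * f(source)``, added or
    subtracted according to ``sign``.
    """

    source: str
    target: str
    topology: str
    weight: float
    sign: str = "excitatory"

    def __post_init__(self):
        if self.topology not in ("one_to_one", "one_to_all"):
            raise InvalidParameterError(f"unknown topology '{self.topology}'")
        if self.sign not in ("excitatory", "inhibitory"):
            raise InvalidParameterError(f"unknown sign '{self.sign}'")


def project(source_output: np.ndarray, projection: Projection, target_size: int) -> np.ndarray:
    """Apply a projection to a source rate vector, returning the target drive."""
    src = np.asarray(source_output, dtype=float)
    sgn = 1.0 if projection.sign == "excitatory" else -1.0
    if projection.topology == "one_to_one":
        if src.size != target_size:
            raise WiringError(
                f"one_to_one projection {projection.source}->{projection.target}: "
                f"source size {src.size} != target size {target_size}"
            )
        return sgn * projection.weight * src
    return np.full(target_size, sgn * projection.weight * float(src.sum()))


def step_field(
    state: FieldState,
    spec: FieldSpec,
    external_input: np.ndarray | float,
    projection_inputs: np.ndarray | float,
    dt: float,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> FieldState:
    """One forward-Euler step of the field equation.

    ``u <- u + (dt/tau) (-u + h + S + w (*) f(u) + projections) + noise``.
    Requires ``dt <= tau / 5`` so the explicit scheme stays well inside its
    stability region.  Raises :class:`DivergenceError` (naming the field) if
    the updated activity is non-finite or exceeds the configured ceiling.
    """
    if not (0 < dt <= spec.tau / 5.0):
        raise InvalidParameterError(
            f"dt must satisfy 0 < dt <= tau/5 = {spec.tau / 5.0}, got {dt}"
        )
    u = state.u
    for name, vec in (("external_input", external_input), ("projection_inputs", projection_inputs)):
        if np.ndim(vec) > 0 and np.shape(vec) != (spec.n_neurons,):
            raise WiringError(
                f"field '{spec.name}': {name} has shape {np.shape(vec)}, "
                f"expected ({spec.n_neurons},)"
            )
    drive = -u + spec.h + external_input + projection_inputs
    W = spec.kernel_matrix()
    if W is not None:
        drive = drive + W @ spec.output(u)
    u_new = u + (dt / spec.tau) * drive
    if noise is not None and noise.sigma > 0:
        if rng is None:
            raise InvalidParameterError("noise.sigma > 0 requires an rng")
        u_new = u_new + noise.draw(rng, spec.labels, dt)
    if not np.all(np.isfinite(u_new)) or np.max(np.abs(u_new)) > spec.ceiling:
        raise DivergenceError(spec.name)
    return FieldState(u=u_new, t=state.t + dt)
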