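"""Spectral preprocessing operators and composable strategies.

Operators (chemometrics shorthand in parentheses):

* mean centering (MC) — subtract the calibration-set mean of each variable;
* multiplicative scatter correction (MSC) — regress each spectrum on a
  reference (the calibration mean spectrum) and undo offset/slope;
* standard normal variate (SNV) — per-spectrum standardization to mean 0,
  sd 1 (sample sd, n-1 denominator);
* first/second derivative (FD/SD) — finite differences on the point index;
* Savitzky–Golay smoothing (SGS) — local polynomial least-squares filter;
* Norris derivative smoothing (NDS) — segment averaging + gap difference.

Strategies are written in the compact ``"SNV+NDS(5,5)+FD+MC"`` notation:
operators are applied left to right, each appears at most once, and MC (the
only operator with column-wise calibration state besides the MSC reference)
must come last.  Calibration state is fitted on the calibration matrix only
and re-applied verbatim to new data — never refitted (leakage guard).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .errors import (
    DegenerateFitError,
    DegenerateSpectrumError,
    ParameterError,
    ShapeError,
)
from .spectra_io import WavenumberGrid

OPERATOR_NAMES = ("MC", "MSC", "SNV", "FD", "SD", "SGS", "NDS")

#: Defaults used when a strategy string gives no parameters.
DEFAULT_SGS_WINDOW = 11
DEFAULT_SGS_POLYORDER = 3
DEFAULT_NDS_SEGMENT = 5
DEFAULT_NDS_GAP = 5


# ---------------------------------------------------------------------------
# elementary operators


def mean_center(
    X: np.ndarray, fitted_mean: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract per-variable (column) means.

    When ``fitted_mean`` is None, ``X`` is treated as the calibration set and
    its column means are both applied and returned; otherwise the stored
    calibration means are applied unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if fitted_mean is None:
        fitted_mean = X.mean(axis=0)
    else:
        fitted_mean = np.asarray(fitted_mean, dtype=float)
        if fitted_mean.shape != (X.shape[1],):
            raise ShapeError(
                f"fitted mean has length {fitted_mean.size}, expected {X.shape[1]}"
            )
    return X - fitted_mean, fitted_mean


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (row-wise) (x - mean) / sd, ddof=1."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return snv(x[np.newaxis, :])[0]
    if x.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs spectra of length >= 2")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def msc(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is fitted as ``x ~= a + b * reference`` by ordinary least
    squares and returned as ``(x - a) / b``, removing additive offset and
    multiplicative scatter relative to the reference (conventionally the
    calibration-set mean spectrum).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return msc(x[np.newaxis, :], reference)[0]
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (x.shape[1],):
        raise ShapeError(
            f"reference has length {reference.size}, expected {x.shape[1]}"
        )
    ref_centered = reference - reference.mean()
    denom = float(ref_centered @ ref_centered)
    if denom == 0.0:
        raise DegenerateFitError("MSC reference is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_centered / denom
    if np.any(np.abs(b) < 1e-12):
        raise DegenerateFitError("MSC slope numerically zero for some spectrum")
    a = x.mean(axis=1) - b * reference.mean()
    return (x - a[:, np.newaxis]) / b[:, np.newaxis]


def derivative(X: np.ndarray, order: int, grid: WavenumberGrid | None = None) -> np.ndarray:
    """First/second finite-difference derivative along the spectral axis.

    Differences are taken with respect to the point index (unit step): the
    first derivative uses central differences with one-sided endpoints, the
    second uses the three-point second difference with endpoint replication
    of the terminal one-sided value.  Output shape equals input shape.
    """
    if order not in (1, 2):
        raise ParameterError(f"derivative order must be 1 or 2, got {order}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 3:
        raise ShapeError("derivative needs at least 3 spectral points")
    if grid is not None:
        steps = -np.diff(grid.values)
        if steps.max() / steps.min() - 1.0 > 0.01:
            raise ParameterError(
                "derivative requires a uniformly spaced grid (within 1%)"
            )
    if order == 1:
        out = np.empty_like(X)
        out[:, 1:-1] = (X[:, 2:] - X[:, :-2]) / 2.0
        out[:, 0] = X[:, 1] - X[:, 0]
        out[:, -1] = X[:, -1] - X[:, -2]
        return out
    out = np.empty_like(X)
    out[:, 1:-1] = X[:, 2:] - 2.0 * X[:, 1:-1] + X[:, :-2]
    out[:, 0] = out[:, 1]
    out[:, -1] = out[:, -2]
    return out


def savitzky_golay(X: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay smoothing; edges by polynomial fit of the terminal windows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= polyorder or polyorder < 0:
        raise ParameterError(
            f"need odd window > polyorder >= 0, got window={window}, polyorder={polyorder}"
        )
    if window > X.shape[1]:
        raise ParameterError(f"window {window} exceeds {X.shape[1]} spectral points")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=-1, mode="interp")


def savgol_weights(window: int, polyorder: int) -> np.ndarray:
    """Central-point convolution weights of the Savitzky–Golay filter."""
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError("need odd window > polyorder")
    half = window // 2
    # value at the window center of the least-squares polynomial fit
    A = np.vander(np.arange(-half, half + 1), polyorder + 1, increasing=True)
    return (A @ np.linalg.pinv(A))[half]


def norris_derivative(X: np.ndarray, segment: int, gap: int, order: int) -> np.ndarray:
    """Norris derivative: segment-average smoothing then gap difference.

    Order 1 is the forward gap difference ``s[i+gap] - s[i]`` (so segment=1,
    gap=1 reduces to the plain first difference); order 2 is the symmetric
    ``s[i+gap] - 2 s[i] + s[i-gap]``.  Output length is preserved by
    replicating edge values.
    """
    if segment < 1 or segment % 2 == 0:
        raise ParameterError(f"segment must be odd >= 1, got {segment}")
    if gap < 1:
        raise ParameterError(f"gap must be >= 1, got {gap}")
    if order not in (1, 2):
        raise ParameterError(f"order must be 1 or 2, got {order}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if segment + gap > n:
        raise ParameterError(f"segment+gap={segment + gap} exceeds {n} spectral points")
    smoothed = uniform_filter1d(X, size=segment, axis=-1, mode="nearest") if segment > 1 else X
    out = np.empty_like(X)
    if order == 1:
        out[:, : n - gap] = smoothed[:, gap:] - smoothed[:, : n - gap]
        out[:, n - gap :] = out[:, n - gap - 1 : n - gap]
    else:
        out[:, gap : n - gap] = (
            smoothed[:, 2 * gap :] - 2.0 * smoothed[:, gap : n - gap] + smoothed[:, : n - 2 * gap]
        )
        out[:, :gap] = out[:, gap : gap + 1]
        out[:, n - gap :] = out[:, n - gap - 1 : n - gap]
    return out


# ---------------------------------------------------------------------------
# strategies

_STEP_RE = re.compile(r"^(?P<name>[A-Z]+)(?:\((?P<params>[^)]*)\))?$")


@dataclass(frozen=True)
class Step:
    name: str
    params: tuple[int, ...] = ()


@dataclass
class PreprocessStrategy:
    """Ordered operator composition with fit-on-calibration semantics.

    ``fitted_state`` holds the MSC reference spectrum and/or the MC column
    means after :meth:`fit`; these are the only pieces of calibration state.
    """

    steps: tuple[Step, ...]
    fitted_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        for name in names:
            if name not in OPERATOR_NAMES:
                raise ParameterError(f"unknown operator {name!r}")
        if len(set(names)) != len(names):
            raise ParameterError("operators may appear at most once in a strategy")
        if "MC" in names and names[-1] != "MC":
            raise ParameterError("MC, when present, must be the final step")

    # -- construction -------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "PreprocessStrategy":
        """Parse compact notation like ``"SNV+NDS(5,5)+FD+MC"``."""
        steps = []
        for token in text.replace(" ", "").split("+"):
            m = _STEP_RE.match(token)
            if not m:
                raise ParameterError(f"cannot parse strategy token {token!r}")
            params = ()
            if m.group("params"):
                params = tuple(int(p) for p in m.group("params").split(","))
            steps.append(Step(m.group("name"), params))
        return cls(tuple(steps))

    def __str__(self) -> str:
        return "+".join(
            s.name + (f"({','.join(map(str, s.params))})" if s.params else "")
            for s in self.steps
        )

    @property
    def is_fitted(self) -> bool:
        needs_state = any(s.name in ("MSC", "MC") for s in self.steps)
        return bool(self.fitted_state) or not needs_state

    # -- application --------------------------------------------------------

    def _step_params(self, step: Step) -> tuple[int, ...]:
        if step.params:
            return step.params
        if step.name == "SGS":
            return (DEFAULT_SGS_WINDOW, DEFAULT_SGS_POLYORDER)
        if step.name == "NDS":
            return (DEFAULT_NDS_SEGMENT, DEFAULT_NDS_GAP)
        return ()

    def _run(
        self,
        X: np.ndarray,
        grid: WavenumberGrid | None,
        state: dict,
        fitting: bool,
    ) -> np.ndarray:
        out = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            params = self._step_params(step)
            if step.name == "SNV":
                out = snv(out)
            elif step.name == "MSC":
                if fitting:
                    state["msc_reference"] = out.mean(axis=0)
                reference = state.get("msc_reference")
                if reference is None:
                    raise ParameterError("strategy with MSC applied before fitting")
                out = msc(out, reference)
            elif step.name == "FD":
                out = derivative(out, 1, grid)
            elif step.name == "SD":
                out = derivative(out, 2, grid)
            elif step.name == "SGS":
                out = savitzky_golay(out, *params)
            elif step.name == "NDS":
                segment, gap = params
                out = norris_derivative(out, segment, gap, 1)
            elif step.name == "MC":
                if fitting:
                    out, mean = mean_center(out)
                    state["mc_mean"] = mean
                else:
                    mean = state.get("mc_mean")
                    if mean is None:
                        raise ParameterError("strategy with MC applied before fitting")
                    out, _ = mean_center(out, mean)
        return out

    def fit(self, X_cal: np.ndarray, grid: WavenumberGrid | None = None) -> tuple[np.ndarray, "PreprocessStrategy"]:
        """Fit calibration state on ``X_cal``; return transformed matrix + fitted copy."""
        state: dict = {}
        out = self._run(X_cal, grid, state, fitting=True)
        return out, PreprocessStrategy(self.steps, state)

    def apply(self, X: np.ndarray, grid: WavenumberGrid | None = None) -> np.ndarray:
        """Apply the fitted strategy to new data without touching fitted state."""
        if not self.is_fitted:
            raise ParameterError("strategy must be fitted before applying to new data")
        return self._run(X, grid, dict(self.fitted_state), fitting=False)


def fit_apply_strategy(
    strategy: PreprocessStrategy | str,
    X_cal: np.ndarray,
    X_new: np.ndarray | None = None,
    grid: WavenumberGrid | None = None,
) -> tuple[np.ndarray, np.ndarray | None, PreprocessStrategy]:
    """Fit a strategy on the calibration matrix, apply it to both matrices.

    Returns ``(X_cal_transformed, X_new_transformed, fitted_strategy)``;
    the second element is None when ``X_new`` is None.
    """
    if isinstance(strategy, str):
        strategy = PreprocessStrategy.parse(strategy)
    cal_out, fitted = strategy.fit(X_cal, grid)
    new_out = fitted.apply(X_new, grid) if X_new is not None else None
    return cal_out, new_out, fitted
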