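"""Voxelwise T2 relaxometry of multi-echo spin-echo stacks.

The signal of a voxel across echoes follows the monoexponential decay
``S(TE) = S0 * exp(-TE / T2)``.  The default fit is a weighted log-linear
regression of ln S on TE with weights S^2 (the first-order noise
propagation weight for log-transformed Gaussian noise); an optional
nonlinear least-squares refinement (Levenberg-Marquardt, seeded by the
log-linear estimate) is available.  Voxels whose signal never rises above
the noise floor, or whose fitted T2 exceeds the ceiling ``t2_max``, are
marked invalid and excluded from every ROI summary.

The echo protocol defaults to 20 echoes equally spaced 20-400 ms at
TR 2500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "default_te_list",
    "EchoStack",
    "T2Map",
    "ROI",
    "fit_t2_voxel",
    "fit_t2_map",
    "roi_mean_t2",
    "render_t2_colormap",
    "classify_t2_bins",
    "T2_BIN_COLORS",
]

#: Default ceiling on fitted T2 (ms); voxels at the ceiling are invalid.
T2_MAX_MS = 1000.0


def default_te_list(first_ms: float = 20.0, last_ms: float = 400.0, n: int = 20) -> np.ndarray:
    """The 20-echo protocol: equally spaced echo times 20, 40, ... 400 ms."""
    return np.linspace(first_ms, last_ms, n)


@dataclass
class EchoStack:
    """Multi-echo signal volume; last axis indexes the echo."""

    signal: np.ndarray
    te_list_ms: np.ndarray = field(default_factory=default_te_list)
    tr_ms: float = 2500.0
    voxel_size_mm: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.te_list_ms = np.asarray(self.te_list_ms, dtype=float)
        if len(self.te_list_ms) < 3:
            raise ValueError("at least 3 echoes are required for fitting")
        if np.any(np.diff(self.te_list_ms) <= 0):
            raise ValueError("te_list must be strictly increasing")
        if self.signal.shape[-1] != len(self.te_list_ms):
            raise ValueError(
                f"echo-count mismatch: signal has {self.signal.shape[-1]} echoes, "
                f"te_list has {len(self.te_list_ms)}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")


@dataclass
class T2Map:
    """Fitted T2 (ms), S0 and validity mask on the stack's voxel grid."""

    t2_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    r_squared: np.ndarray

    def masked_t2(self) -> np.ndarray:
        out = np.where(self.valid, self.t2_ms, np.nan)
        return out


@dataclass
class ROI:
    """A voxel mask with a label, on the same grid as the map it summarises."""

    mask: np.ndarray
    label: str = "disc"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def _loglinear_fit(signal: np.ndarray, te: np.ndarray, floor: float = 0.0):
    """Vectorised weighted log-linear fit. ``signal``: (..., n_te).

    Solves the weighted least squares ln S = ln S0 - TE/T2 with weights
    S^2, echo-wise, in closed form, then refits once with weights taken
    from the *fitted* curve (one reweighting pass removes most of the bias
    that noisy measured-signal weights introduce at low SNR).  Returns
    (t2, s0, r2) arrays; sub-floor and non-positive echoes get zero weight
    (a voxel needs >= 3 usable echoes, enforced by the caller's validity
    mask).
    """
    s = np.asarray(signal, float)
    pos = s > max(floor, 0.0)
    y = np.where(pos, np.log(np.where(pos, s, 1.0)), 0.0)
    t2 = s0 = r2 = None
    w = np.where(pos, s * s, 0.0)
    for _ in range(2):  # initial fit + one model-weight refit
        t2, s0, r2, slope, my, mx = _wls_decay(w, y, te)
        with np.errstate(over="ignore", invalid="ignore"):
            model = s0[..., None] * np.exp(np.where(np.isfinite(slope), slope, 0.0)[..., None] * te)
        good = np.isfinite(model) & (model > 0)
        w = np.where(pos & good, model * model, np.where(pos, s * s, 0.0))
    return t2, s0, r2


def _wls_decay(w: np.ndarray, y: np.ndarray, te: np.ndarray):
    sw = w.sum(axis=-1)
    sw = np.where(sw > 0, sw, np.nan)
    mx = (w * te).sum(axis=-1) / sw
    my = (w * y).sum(axis=-1) / sw
    cxx = (w * (te - mx[..., None]) ** 2).sum(axis=-1)
    cxy = (w * (te - mx[..., None]) * (y - my[..., None])).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cxy / cxx
        t2 = -1.0 / slope
    s0 = np.exp(my - slope * mx)
    # weighted R^2 on the log scale
    yhat = my[..., None] + slope[..., None] * (te - mx[..., None])
    ss_res = (w * (y - yhat) ** 2).sum(axis=-1)
    ss_tot = (w * (y - my[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return t2, s0, r2, slope, my, mx


def _decay(te, s0, t2):
    return s0 * np.exp(-te / t2)


def fit_t2_voxel(
    signal_per_echo: np.ndarray,
    te_list_ms: np.ndarray,
    method: str = "loglinear_weighted",
    noise_floor: float = 0.0,
    t2_max: float = T2_MAX_MS,
) -> tuple[float, float, dict]:
    """Fit one voxel's decay; returns ``(t2_ms, s0, diagnostics)``.

    ``diagnostics['valid']`` is False for sub-floor signal, non-positive or
    ceiling-clipped T2.  ``method='nonlinear'`` refines the log-linear seed
    with Levenberg-Marquardt least squares on the raw signal.
    """
    s = np.asarray(signal_per_echo, float)
    te = np.asarray(te_list_ms, float)
    if np.count_nonzero(s > noise_floor) < 3:
        return float("nan"), float("nan"), {"valid": False, "reason": "sub-floor signal", "r_squared": float("nan")}
    t2, s0, r2 = _loglinear_fit(s[None, :], te, noise_floor)
    t2, s0, r2 = float(t2[0]), float(s0[0]), float(r2[0])
    if method == "nonlinear":
        if np.isfinite(t2) and 0 < t2 < t2_max:
            p0 = (s0, t2)
        else:
            p0 = (float(max(s.max(), 1e-12)), float(te[len(te) // 2]))
        try:
            (s0, t2), _ = curve_fit(_decay, te, s, p0=p0, maxfev=2000)
            resid = s - _decay(te, s0, t2)
            ss_tot = float(np.sum((s - s.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        except RuntimeError:
            pass  # keep the log-linear estimate
    elif method != "loglinear_weighted":
        raise ValueError(f"unknown fit method {method!r}")
    valid = bool(np.isfinite(t2) and 0 < t2 < t2_max)
    reason = None if valid else "non-positive, non-finite or ceiling-clipped T2"
    return t2, s0, {"valid": valid, "reason": reason, "r_squared": r2}


def fit_t2_map(
    stack: EchoStack,
    method: str = "loglinear_weighted",
    noise_floor: float | None = None,
    t2_max: float = T2_MAX_MS,
    exclude_first_echo: bool = False,
) -> T2Map:
    """Voxelwise fit over the whole stack.

    ``noise_floor=None`` estimates the floor as 3x the standard deviation of
    the last-echo signal over near-zero voxels (background); pass 0 to
    disable.  ``exclude_first_echo`` drops TE[0] (a common stimulated-echo
    mitigation), off by default since the protocol uses all 20 echoes.
    """
    te = stack.te_list_ms
    sig = stack.signal
    if exclude_first_echo:
        te, sig = te[1:], sig[..., 1:]
    if noise_floor is None:
        last = sig[..., -1]
        bg = last[last < 0.05 * max(float(sig.max()), 1e-300)]
        noise_floor = 3.0 * float(np.std(bg)) if bg.size else 0.0
    if method == "nonlinear":
        flat = sig.reshape(-1, sig.shape[-1])
        t2 = np.empty(flat.shape[0])
        s0 = np.empty(flat.shape[0])
        r2 = np.empty(flat.shape[0])
        valid = np.empty(flat.shape[0], dtype=bool)
        for i, row in enumerate(flat):
            t2[i], s0[i], diag = fit_t2_voxel(row, te, "nonlinear", noise_floor, t2_max)
            valid[i], r2[i] = diag["valid"], diag["r_squared"]
        shape = sig.shape[:-1]
        return T2Map(t2.reshape(shape), s0.reshape(shape), valid.reshape(shape), r2.reshape(shape))
    if method != "loglinear_weighted":
        raise ValueError(f"unknown fit method {method!r}")
    t2, s0, r2 = _loglinear_fit(sig, te, noise_floor)
    enough = (sig > noise_floor).sum(axis=-1) >= 3
    valid = enough & np.isfinite(t2) & (t2 > 0) & (t2 < t2_max)
    return T2Map(t2_ms=t2, s0=s0, valid=valid, r_squared=r2)


def roi_mean_t2(t2map: T2Map, roi: ROI) -> float:
    """Arithmetic mean T2 over the valid voxels of an ROI."""
    if roi.mask.shape != t2map.t2_ms.shape:
        raise ValueError("ROI mask is not on the map's grid")
    sel = roi.mask & t2map.valid
    if not sel.any():
        raise ValueError("ROI contains no valid voxels")
    return float(np.mean(t2map.t2_ms[sel]))


#: Deterministic palette, one RGB per bin, ordered low to high T2:
#: black -> blue -> cyan -> green -> yellow -> orange -> red (high T2 red,
#: low T2 blue/black).
T2_BIN_COLORS = np.array(
    [
        (0.00, 0.00, 0.00),
        (0.10, 0.10, 0.80),
        (0.00, 0.70, 0.90),
        (0.10, 0.75, 0.30),
        (0.95, 0.90, 0.10),
        (0.95, 0.55, 0.10),
        (0.90, 0.10, 0.10),
    ]
)


def classify_t2_bins(t2map: T2Map, bin_edges_ms: np.ndarray) -> np.ndarray:
    """Bin index per voxel (0 .. len(edges)); invalid voxels get -1."""
    edges = np.asarray(bin_edges_ms, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.searchsorted(edges, t2map.t2_ms, side="right")
    return np.where(t2map.valid, idx, -1)


def render_t2_colormap(t2map: T2Map, bin_edges_ms: np.ndarray) -> np.ndarray:
    """Colour-coded T2 map as an RGB array (invalid voxels black).

    ``bin_edges_ms`` must have at most ``len(T2_BIN_COLORS) - 1`` edges; the
    n+1 bins are painted with the low-to-high palette so that high T2
    renders red and low T2 blue/black.
    """
    edges = np.asarray(bin_edges_ms, float)
    n_bins = len(edges) + 1
    if n_bins > len(T2_BIN_COLORS):
        raise ValueError("too many bins for the fixed palette")
    # spread the available palette across the requested bins, keeping ends
    take = np.linspace(0, len(T2_BIN_COLORS) - 1, n_bins).round().astype(int)
    palette = T2_BIN_COLORS[take]
    idx = classify_t2_bins(t2map, edges)
    rgb = np.zeros(t2map.t2_ms.shape + (3,))
    for b in range(n_bins):
        rgb[idx == b] = palette[b]
    return rgb
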