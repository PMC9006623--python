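"""Per-pixel basal fluorescence (F0) estimation and ΔF/F0 normalisation.

The basal level of every pixel is modelled as a low-order polynomial in
time, which captures slow photobleaching and focus drift over recordings of
a few minutes.  Calcium transients are positive-going, so before the final
fit they are excluded by iterative *one-sided* sigma clipping: after each
least-squares fit, frames whose residual exceeds ``clip_k`` robust standard
deviations (1.4826 x median absolute deviation of the retained residuals)
above the fit are dropped, and the fit is repeated until the exclusion set
stabilises.

Fits use a time axis rescaled to [-1, 1] so the normal equations stay well
conditioned at high polynomial degree; the resulting baseline is identical
to a naive fit up to numerical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MovieStack, ParameterError

_EPS = 1e-12


@dataclass
class BaselineModel:
    """Per-pixel polynomial baseline.

    ``coefficients`` has shape ``(degree+1, H, W)`` in the rescaled-time
    power basis (lowest order first); ``f0`` is the evaluated baseline with
    the movie's shape; ``exclusion_mask[t, y, x]`` is True where frame ``t``
    was excluded from pixel ``(y, x)``'s fit; ``fallback_mask`` flags pixels
    where clipping removed too many samples and the no-exclusion fit was
    used instead.
    """

    coefficients: np.ndarray
    f0: np.ndarray
    exclusion_mask: np.ndarray
    fallback_mask: np.ndarray
    degree: int

    def evaluate(self, n_frames: int) -> np.ndarray:
        """Re-evaluate the fitted polynomials on the frame grid."""
        s = _scaled_time(n_frames)
        X = np.vander(s, self.degree + 1, increasing=True)
        return np.einsum("tk,kij->tij", X, self.coefficients)


@dataclass
class DffStack:
    """Normalised ΔF/F0 data with a validity mask.

    ``valid_mask[y, x]`` is False where the fitted baseline was not strictly
    positive at every frame; such pixels carry zeros and are excluded from
    all downstream analysis.
    """

    data: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _scaled_time(n_frames: int) -> np.ndarray:
    if n_frames == 1:
        return np.zeros(1)
    return -1.0 + 2.0 * np.arange(n_frames) / (n_frames - 1)


def _masked_polyfit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted least squares.

    X: (T, k) design; y: (T, P) traces; w: (T, P) 0/1 weights.
    Returns coefficients (k, P).
    """
    G = np.einsum("ti,tp,tj->pij", X, w, X, optimize=True)
    b = np.einsum("ti,tp->pi", X, w * y, optimize=True)
    k = X.shape[1]
    # Regularise singular systems (all-excluded pixels); callers overwrite those.
    G = G + np.eye(k) * _EPS
    beta = np.linalg.solve(G, b[..., None])[..., 0]  # (P, k)
    return beta.T


def estimate_f0(
    stack: MovieStack,
    degree: int,
    clip_k: float = 2.0,
    max_iter: int = 5,
) -> BaselineModel:
    """Fit the per-pixel polynomial baseline with transient exclusion.

    Parameters
    ----------
    stack
        (Pre-processed) movie.
    degree
        Polynomial degree ``d >= 0``; ``d + 1`` must be smaller than the
        number of retained frames per pixel.
    clip_k
        One-sided clip multiplier: frames with residual above
        ``clip_k * 1.4826 * MAD`` are excluded.  ``inf`` disables exclusion
        and reproduces the plain least-squares fit exactly.
    max_iter
        Maximum fit/exclude iterations (the loop also stops as soon as the
        exclusion set is stable).
    """
    T, H, W = stack.data.shape
    if degree < 0:
        raise ParameterError("degree must be >= 0")
    if degree + 1 >= T:
        raise ParameterError(
            f"degree {degree} leaves no residual degrees of freedom with {T} frames"
        )
    P = H * W
    y = stack.data.reshape(T, P).astype(float)
    s = _scaled_time(T)
    X = np.vander(s, degree + 1, increasing=True)

    include = np.ones((T, P), dtype=bool)
    beta = _masked_polyfit(X, y, include.astype(float))
    beta_full = beta.copy()  # no-exclusion fit, kept for fallbacks

    if np.isfinite(clip_k):
        # absolute floor on the clip level: numerically-zero residual scatter
        # (noise-free traces) must not trigger exclusions
        floor = 1e-8 * np.maximum(np.abs(y).max(axis=0), 1.0)
        import warnings

        for _ in range(max_iter):
            fit = X @ beta
            resid = y - fit
            r = np.where(include, resid, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(r, axis=0)
                mad = np.nanmedian(np.abs(r - med), axis=0)
            scale = 1.4826 * np.nan_to_num(mad)
            # threshold anchored at the median residual: if truncation pulls
            # the fit down, the residual median rises with it and the clip
            # level follows, so the one-sided bias does not compound
            thr = np.nan_to_num(med) + clip_k * scale + floor
            new_include = ~(resid > thr)  # one-sided: only positive residuals go
            if np.array_equal(new_include, include):
                break
            include = new_include
            beta = _masked_polyfit(X, y, include.astype(float))

    n_kept = include.sum(axis=0)
    fallback = n_kept < (degree + 1 + 1)
    if fallback.any():
        beta[:, fallback] = beta_full[:, fallback]
        include[:, fallback] = True

    f0 = (X @ beta).reshape(T, H, W)
    return BaselineModel(
        coefficients=beta.reshape(degree + 1, H, W),
        f0=f0,
        exclusion_mask=(~include).reshape(T, H, W),
        fallback_mask=fallback.reshape(H, W),
        degree=degree,
    )


def compute_dff(stack: MovieStack, baseline: BaselineModel) -> DffStack:
    """Normalise the movie: ΔF/F0 = (F - F0) / F0.

    Pixels whose baseline is not strictly positive at every frame are masked
    invalid (zeros in ``data``) rather than raising.
    """
    if stack.data.shape != baseline.f0.shape:
        raise ParameterError(
            f"shape mismatch: movie {stack.data.shape} vs baseline {baseline.f0.shape}"
        )
    f0 = baseline.f0
    valid = np.all(f0 > 0, axis=0)
    safe_f0 = np.where(f0 > 0, f0, 1.0)
    dff = (stack.data - f0) / safe_f0
    dff = np.where(valid[None, :, :], dff, 0.0)
    return DffStack(
        data=dff,
        valid_mask=valid,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )
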