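"""Advanced-MRI derived parametric maps.

From multi-b diffusion-weighted imaging: the apparent diffusion
coefficient (ADC) via a per-pixel log-linear least-squares fit of
``S(b) = S0 exp(-b * ADC)``.

From the dynamic contrast-enhanced (DCE) series: the subtraction
sequence (every frame minus the pre-contrast frame), three subtraction
snapshots at 0/50/100 s after contrast arrival, the steepest slope of
the time-intensity curve ``(SI_end - SI_prior) * 100 / (SI_base * T)``,
the area under the subtraction curve over the first 100 s, and the
standard two-compartment (Tofts) pharmacokinetic parameters
``K^trans`` (min^-1) and ``v_e`` obtained by bounded least squares of

    C_t(t) = K^trans \\int_0^t C_p(tau) e^{-(K^trans/v_e)(t - tau)} dtau

against tissue concentration, with signal <-> concentration conversion
through the spoiled-gradient-echo relation.  The convolution uses exact
piecewise-linear quadrature of the arterial input function, and the fit
exploits that the model is linear in ``K^trans`` once ``k_ep`` is fixed:
a dense logarithmic ``k_ep`` grid with closed-form amplitude and a local
parabolic refinement, evaluated for all pixels at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core_io import (ADC, DCE_AUC, DCE_KTRANS, DCE_SLOPE, DCE_SUB_0,
                      DCE_SUB_1, DCE_SUB_2, DCE_VE, AcquisitionParams,
                      DCESeries, ImageGrid, MaskGrid, MRICase)

# ---------------------------------------------------------------------------
# ADC
# ---------------------------------------------------------------------------

@dataclass
class ADCFitResult:
    adc: ImageGrid                 # mm^2/s
    s0: ImageGrid
    fit_residual: ImageGrid
    clamped: np.ndarray = field(default=None)  # pixels with clamped signals


def compute_adc(dwi) -> ADCFitResult:
    """Log-linear least-squares ADC from a multi-b DWI stack.

    ``dwi`` is a list of ``(b_value, ImageGrid)``.  Nonpositive signals
    are clamped to ``1e-6`` of the per-volume maximum (and flagged)
    before the logarithm.  Exact on noiseless mono-exponential input.
    """
    if len(dwi) < 2:
        raise ValueError("need at least two distinct b-values")
    bs = np.asarray([b for b, _ in dwi], dtype=np.float64)
    if np.any(bs < 0):
        raise ValueError("b-values must be nonnegative")
    if len(np.unique(bs)) < 2:
        raise ValueError("b-values must be distinct")
    ref = dwi[0][1]
    S = np.stack([np.asarray(g.values, dtype=np.float64) for _, g in dwi])
    clamped = S <= 0
    floor = 1e-6 * max(S.max(), 1e-30)
    S = np.where(clamped, floor, S)
    logS = np.log(S)

    bbar = bs.mean()
    denom = ((bs - bbar) ** 2).sum()
    slope = np.tensordot(bs - bbar, logS - logS.mean(axis=0), axes=(0, 0))
    slope /= denom
    intercept = logS.mean(axis=0) - slope * bbar
    pred = intercept[None] + slope[None] * bs.reshape(
        (-1,) + (1,) * slope.ndim)
    resid = np.sqrt(((logS - pred) ** 2).mean(axis=0))
    return ADCFitResult(adc=ref.with_values(-slope),
                        s0=ref.with_values(np.exp(intercept)),
                        fit_residual=ref.with_values(resid),
                        clamped=clamped.any(axis=0))


# ---------------------------------------------------------------------------
# Spoiled-gradient-echo signal <-> concentration
# ---------------------------------------------------------------------------

def spgr_signal_from_concentration(conc, s_base, t10: float,
                                   acq: AcquisitionParams):
    """Post-contrast SPGR signal given concentration (mM) and baseline."""
    conc = np.asarray(conc, dtype=np.float64)
    a = np.deg2rad(acq.flip_angle)
    e10 = np.exp(-acq.tr / t10)
    r1 = 1.0 / t10 + acq.r1_per_mm * conc
    e1 = np.exp(-acq.tr * r1)
    ratio = ((1.0 - e1) * (1.0 - np.cos(a) * e10)
             / ((1.0 - np.cos(a) * e1) * (1.0 - e10)))
    return np.asarray(s_base) * ratio


def concentration_from_spgr_signal(signal, s_base, t10: float,
                                   acq: AcquisitionParams):
    """Invert the SPGR relation; concentration in mM (clipped at 0)."""
    signal = np.asarray(signal, dtype=np.float64)
    s_base = np.asarray(s_base, dtype=np.float64)
    a = np.deg2rad(acq.flip_angle)
    e10 = np.exp(-acq.tr / t10)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_base > 0, signal / np.where(s_base > 0, s_base, 1.0),
                         1.0)
    B = ratio * (1.0 - e10) / (1.0 - np.cos(a) * e10)
    e1 = (1.0 - B) / (1.0 - B * np.cos(a))
    e1 = np.clip(e1, 1e-8, 1.0 - 1e-12)
    r1 = -np.log(e1) / acq.tr
    conc = (r1 - 1.0 / t10) / acq.r1_per_mm
    return np.clip(conc, 0.0, None)


# ---------------------------------------------------------------------------
# Subtraction, slope, AUC
# ---------------------------------------------------------------------------

def subtraction_sequence(dce: DCESeries) -> DCESeries:
    """Frame-wise subtraction of the pre-contrast frame (frame 0)."""
    if dce.n_frames < 2:
        raise ValueError("need at least two frames")
    base = dce.frames[0].values
    frames = [f.with_values(f.values - base) for f in dce.frames]
    return DCESeries(frames, dce.timestamps.copy(),
                     sampling_interval=dce.sampling_interval,
                     acquisition=dce.acquisition)


def steepest_slope_map(dce: DCESeries, use_absolute: bool = False,
                       base_floor_frac: float = 1e-3) -> ImageGrid:
    """Steepest wash-in slope of the time-intensity curve, in %/s.

    Per pixel, the consecutive-frame pair of the subtraction sequence
    with the maximum signed increase (maximum absolute difference when
    ``use_absolute``) defines ``SI_prior`` and ``SI_end``; the slope is
    ``(SI_end - SI_prior) * 100 / (SI_base * T)`` with ``SI_base`` the
    original pre-contrast signal floored at ``base_floor_frac`` of the
    volume maximum to avoid division blow-up.
    """
    sub = subtraction_sequence(dce)
    arr = sub.as_array()
    diffs = np.diff(arr, axis=0)
    if use_absolute:
        k = np.abs(diffs).argmax(axis=0)
    else:
        k = diffs.argmax(axis=0)
    best = np.take_along_axis(diffs, k[None], axis=0)[0]
    base = dce.frames[0].values
    floor = base_floor_frac * max(base.max(), 1e-30)
    base_f = np.maximum(base, floor)
    slope = best * 100.0 / (base_f * dce.sampling_interval)
    return dce.frames[0].with_values(slope)


def auc_map(dce_sub: DCESeries, horizon: float = 100.0) -> ImageGrid:
    """Trapezoidal area under the subtraction curve for ``t <= horizon``."""
    t = dce_sub.timestamps
    keep = t <= horizon + 1e-9
    if keep.sum() < 2:
        warnings.warn("fewer than two frames within the AUC horizon")
        return dce_sub.frames[0].with_values(
            np.zeros_like(dce_sub.frames[0].values))
    arr = dce_sub.as_array()[keep]
    auc = np.trapezoid(arr, x=t[keep], axis=0)
    return dce_sub.frames[0].with_values(auc)


# ---------------------------------------------------------------------------
# AIF and Tofts model
# ---------------------------------------------------------------------------

def extract_aif(dce: DCESeries, artery_mask: MaskGrid) -> np.ndarray:
    """Mean arterial concentration curve (mM) from a feeding-artery ROI."""
    mask = np.asarray(artery_mask.values, dtype=bool)
    if not mask.any():
        raise ValueError("empty artery mask")
    sig = np.array([f.values[mask].mean() for f in dce.frames])
    return concentration_from_spgr_signal(
        sig, sig[0], dce.acquisition.t1_blood, dce.acquisition)


def contrast_arrival_index(aif_conc: np.ndarray,
                           threshold_frac: float = 0.05) -> int:
    """First frame whose AIF concentration exceeds 5% of its peak."""
    aif_conc = np.asarray(aif_conc, dtype=np.float64)
    peak = aif_conc.max()
    if peak <= 0:
        return 0
    idx = np.nonzero(aif_conc > threshold_frac * peak)[0]
    return int(idx[0]) if idx.size else 0


def tofts_integral(t: np.ndarray, cp: np.ndarray,
                   kep_per_s) -> np.ndarray:
    """``I(t_j) = int_0^{t_j} Cp(tau) e^{-kep (t_j - tau)} dtau``.

    Exact for a piecewise-linear AIF.  ``kep_per_s`` may be a scalar or
    an array of rates (s^-1); the result has shape ``kep.shape + t.shape``.
    """
    t = np.asarray(t, dtype=np.float64)
    cp = np.asarray(cp, dtype=np.float64)
    kep = np.atleast_1d(np.asarray(kep_per_s, dtype=np.float64))
    out = np.zeros(kep.shape + t.shape)
    I = np.zeros(kep.shape)
    for j in range(1, t.size):
        dt = t[j] - t[j - 1]
        a = cp[j - 1]
        b = (cp[j] - cp[j - 1]) / dt
        kdt = kep * dt
        small = kdt < 1e-8
        with np.errstate(divide="ignore", invalid="ignore"):
            em = -np.expm1(-kdt)                       # 1 - exp(-k dt)
            term = np.where(small,
                            a * dt + 0.5 * b * dt ** 2,
                            a * em / np.where(small, 1.0, kep)
                            + b * (dt - em / np.where(small, 1.0, kep))
                            / np.where(small, 1.0, kep))
        I = I * np.exp(-kdt) + term
        out[..., j] = I
    return out


def tofts_concentration(t: np.ndarray, cp: np.ndarray, ktrans_per_min,
                        ve) -> np.ndarray:
    """Forward Tofts tissue concentration; K^trans in min^-1."""
    ktrans = np.atleast_1d(np.asarray(ktrans_per_min, dtype=np.float64))
    ve = np.atleast_1d(np.asarray(ve, dtype=np.float64))
    if np.any(ve <= 0) and np.any(ktrans[ve <= 0] > 0):
        raise ValueError("v_e = 0 with positive K^trans is not a model")
    ve_safe = np.where(ve > 0, ve, 1.0)
    kep = (ktrans / 60.0) / ve_safe                   # s^-1
    I = tofts_integral(t, cp, kep)
    ct = (ktrans / 60.0)[..., None] * I
    ct[ktrans <= 0] = 0.0
    return ct


@dataclass
class ToftsFitResult:
    ktrans: np.ndarray     # min^-1
    ve: np.ndarray
    rss: np.ndarray
    qc_flag: np.ndarray    # True where a bound was hit / fit unreliable


def fit_tofts_curves(t: np.ndarray, cp: np.ndarray, ct: np.ndarray,
                     ktrans_bounds=(0.0, 5.0),
                     kep_grid=None) -> ToftsFitResult:
    """Fit (K^trans, v_e) to tissue concentration curves.

    ``ct`` has shape ``(n_pixels, n_frames)``.  For each candidate
    ``k_ep`` the optimal ``K^trans`` is the closed-form least-squares
    amplitude; the best grid node is refined by parabolic interpolation
    of the residual in ``log k_ep``.
    """
    t = np.asarray(t, dtype=np.float64)
    cp = np.asarray(cp, dtype=np.float64)
    ct = np.atleast_2d(np.asarray(ct, dtype=np.float64))
    if kep_grid is None:
        kep_grid = np.geomspace(5e-3, 30.0, 160)      # min^-1
    kep_s = np.asarray(kep_grid) / 60.0
    Imat = tofts_integral(t, cp, kep_s)               # (K, T)
    den = (Imat ** 2).sum(axis=1)                     # (K,)
    den = np.where(den > 0, den, np.inf)
    num = ct @ Imat.T                                 # (N, K)
    amp = np.clip(num, 0.0, None) / den[None, :]      # K^trans / 60 per s
    rss = (ct ** 2).sum(axis=1)[:, None] - 2 * amp * num \
        + amp ** 2 * den[None, :]
    best = rss.argmin(axis=1)
    n = ct.shape[0]

    # Parabolic refinement in log kep around the best grid node.
    logk = np.log(np.asarray(kep_grid))
    b0 = np.clip(best, 1, len(kep_grid) - 2)
    f_m = rss[np.arange(n), b0 - 1]
    f_0 = rss[np.arange(n), b0]
    f_p = rss[np.arange(n), b0 + 1]
    denom = f_m - 2 * f_0 + f_p
    shift = np.where(np.abs(denom) > 1e-30,
                     0.5 * (f_m - f_p) / np.where(np.abs(denom) > 1e-30,
                                                  denom, 1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = np.gradient(logk)[b0]
    kep_ref = np.exp(logk[b0] + shift * step)         # min^-1

    Iref = tofts_integral(t, cp, kep_ref / 60.0)      # (N, T)
    den_r = (Iref ** 2).sum(axis=1)
    num_r = (ct * Iref).sum(axis=1)
    amp_r = np.where(den_r > 0, np.clip(num_r, 0.0, None)
                     / np.where(den_r > 0, den_r, 1.0), 0.0)
    rss_r = (ct ** 2).sum(axis=1) - 2 * amp_r * num_r + amp_r ** 2 * den_r

    # Keep whichever of grid node / refined node is better.
    use_ref = rss_r <= rss[np.arange(n), best]
    kep_fin = np.where(use_ref, kep_ref, np.asarray(kep_grid)[best])
    amp_fin = np.where(use_ref, amp_r,
                       amp[np.arange(n), best])
    rss_fin = np.where(use_ref, rss_r, rss[np.arange(n), best])

    ktrans = amp_fin * 60.0                           # min^-1
    qc = np.zeros(n, dtype=bool)
    hi = ktrans > ktrans_bounds[1]
    ktrans = np.clip(ktrans, ktrans_bounds[0], ktrans_bounds[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(kep_fin > 0, ktrans / kep_fin, 0.0)
    bad_ve = (ve > 1.0) | (ktrans <= 0)
    ve = np.clip(ve, 0.0, 1.0)
    qc |= hi | bad_ve
    return ToftsFitResult(ktrans=ktrans, ve=ve, rss=rss_fin, qc_flag=qc)


def fit_tofts(dce: DCESeries, aif_conc: np.ndarray, tumor_mask: MaskGrid):
    """Per-pixel Tofts maps over a mask; returns (ktrans, ve) ImageGrids."""
    mask = np.asarray(tumor_mask.values, dtype=bool)
    if not mask.any():
        raise ValueError("empty fit mask")
    arr = dce.as_array()
    base = arr[0]
    sig = arr[:, mask].T                              # (N, T)
    acq = dce.acquisition
    ct = concentration_from_spgr_signal(
        sig, base[mask][:, None], acq.t1_tissue, acq)
    fit = fit_tofts_curves(dce.timestamps, aif_conc, ct)
    kt = np.zeros(base.shape)
    ve = np.zeros(base.shape)
    kt[mask] = fit.ktrans
    ve[mask] = fit.ve
    g0 = dce.frames[0]
    return g0.with_values(kt), g0.with_values(ve), fit


# ---------------------------------------------------------------------------
# Case-level map derivation
# ---------------------------------------------------------------------------

@dataclass
class DCEMaps:
    sub_frames: tuple      # three ImageGrids at ~0/50/100 s post-arrival
    slope: ImageGrid
    auc: ImageGrid
    ktrans: ImageGrid
    ve: ImageGrid


def derive_parametric_maps(case: MRICase, inplane_dilation: int = 7,
                           aif_conc: Optional[np.ndarray] = None) -> MRICase:
    """Fill ``case.images`` with the eight advanced-MRI derived maps.

    The Tofts fit is evaluated on the VOI dilated in-plane by
    ``inplane_dilation`` pixels (the reach of the largest feature
    window); other maps are computed everywhere.  Cases without a DCE
    series simply receive no DCE-derived entries.
    """
    if case.dwi:
        case.images[ADC] = compute_adc(case.dwi).adc
    if case.dce is None:
        return case
    dce = case.dce
    sub = subtraction_sequence(dce)
    if aif_conc is None:
        if case.artery_mask is None:
            raise ValueError("need an artery mask or an explicit AIF")
        aif_conc = extract_aif(dce, case.artery_mask)
    arr_idx = contrast_arrival_index(aif_conc)
    t0 = dce.timestamps[arr_idx]
    for name, offset in ((DCE_SUB_0, 0.0), (DCE_SUB_1, 50.0),
                         (DCE_SUB_2, 100.0)):
        j = int(np.argmin(np.abs(dce.timestamps - (t0 + offset))))
        case.images[name] = sub.frames[j]
    case.images[DCE_SLOPE] = steepest_slope_map(dce)
    case.images[DCE_AUC] = auc_map(sub)
    if case.voi is None:
        raise ValueError("Tofts fitting needs a VOI")
    size = 2 * inplane_dilation + 1
    fit_mask = ndimage.binary_dilation(
        case.voi.values, structure=np.ones((size, size, 1), dtype=bool))
    kt, ve, _ = fit_tofts(dce, aif_conc,
                          MaskGrid(fit_mask, role="VOI",
                                   spacing=case.voi.spacing,
                                   origin=case.voi.origin))
    case.images[DCE_KTRANS] = kt
    case.images[DCE_VE] = ve
    return case
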