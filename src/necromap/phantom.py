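"""Synthetic paired multi-modal MR / histology phantoms.

Each phantom is one subject: an ellipsoidal tumor in a background
volume, split into necrotic and viable compartments with a target
necrosis fraction, imaged as

* three conventional sequences (PC, T1, STIR) whose class-conditional
  means, standard deviations and spatial correlation lengths differ
  (class textures are Gaussian random fields: white noise convolved
  with a Gaussian kernel of class-specific correlation length, added to
  the class mean);
* a multi-b DWI stack generated from a ground-truth ADC volume through
  the mono-exponential signal law (necrosis has the higher ADC);
* a DCE series generated from ground-truth ``K^trans`` / ``v_e``
  volumes through the Tofts forward model and the spoiled-gradient-echo
  signal relation (viable tumor enhances early and fast, necrosis
  barely), with a small feeding-artery region carrying the arterial
  input function;

plus a higher-resolution "histology" viability map related to the MR
plane of interest by a known smooth quadratic warp, with exact
control-point pairs (optionally jittered) and optional simulated tissue
loss.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (NECROTIC, NON_TUMOR, PC, STIR, T1, VIABLE,
                      AcquisitionParams, DCESeries, ImageGrid, MaskGrid,
                      MRICase, ViabilityMap)
from .param_maps import spgr_signal_from_concentration, tofts_concentration


@dataclass
class ClassSignal:
    """Class-conditional signal statistics for one image type.

    Liquefied necrosis is spatially homogeneous while viable tumor is
    heterogeneous, so the necrotic compartment gets a smaller standard
    deviation and a longer spatial correlation length by default.
    """

    background: float
    viable: float
    necrotic: float
    sd_background: float = 8.0
    sd_viable: float = 12.0
    sd_necrotic: float = 5.0
    #: Gaussian-kernel correlation length (pixels) per class
    corr_background: float = 1.5
    corr_viable: float = 1.0
    corr_necrotic: float = 2.5


@dataclass
class AIFParams:
    """Biexponential population arterial input function (per-kg dose)."""

    dose: float = 0.1        # mmol/kg
    a1: float = 3.99         # kg/L
    m1: float = 0.144        # min^-1
    a2: float = 4.78
    m2: float = 0.0111
    arrival_s: float = 10.0


def population_aif(t_seconds: np.ndarray, params: AIFParams) -> np.ndarray:
    """AIF plasma concentration (mM) at the given times."""
    t = np.asarray(t_seconds, dtype=np.float64)
    tau = (t - params.arrival_s) / 60.0
    # (mmol/kg) * (kg/L) = mmol/L = mM
    cp = params.dose * (params.a1 * np.exp(-params.m1 * tau)
                        + params.a2 * np.exp(-params.m2 * tau))
    cp = np.where(tau >= 0, cp, 0.0)
    return cp


@dataclass
class PhantomConfig:
    """Everything that determines one synthetic case."""

    shape: tuple = (96, 96, 12)
    spacing: tuple = (1.5, 1.5, 5.0)          # mm
    tumor_center: tuple = (48.0, 48.0, 6.0)   # lattice coords
    tumor_axes: tuple = (34.0, 28.0, 4.5)     # lattice units
    necrosis_fraction: float = 60.0           # target percent in [0, 100]
    n_necrosis_blobs: int = 0
    necrosis_blob_scale: float = 12.0         # field correlation length, px
    uniform_slice_fraction: bool = True
    conventional: dict = field(default_factory=lambda: {
        PC: ClassSignal(background=60.0, viable=180.0, necrotic=90.0,
                        sd_background=6.0, sd_viable=7.0, sd_necrotic=3.5),
        T1: ClassSignal(background=80.0, viable=128.0, necrotic=92.0,
                        sd_background=5.0, sd_viable=6.0, sd_necrotic=3.0),
        STIR: ClassSignal(background=70.0, viable=150.0, necrotic=215.0,
                          sd_background=7.0, sd_viable=8.0,
                          sd_necrotic=4.0),
    })
    b_values: tuple = (0.0, 400.0, 800.0)     # s/mm^2
    adc: dict = field(default_factory=lambda: {
        "background": 1.5e-3, "viable": 1.1e-3, "necrotic": 2.0e-3})
    adc_sd: dict = field(default_factory=lambda: {
        "background": 0.06e-3, "viable": 0.1e-3, "necrotic": 0.04e-3})
    #: texture correlation lengths of the scalar truth maps per class
    map_corr: dict = field(default_factory=lambda: {
        "background": 1.5, "viable": 1.0, "necrotic": 2.5})
    dwi_s0: float = 1000.0
    dwi_noise_sd: float = 2.0
    ktrans: dict = field(default_factory=lambda: {
        "background": 0.06, "viable": 0.25, "necrotic": 0.04})  # min^-1
    ktrans_sd: dict = field(default_factory=lambda: {
        "background": 0.006, "viable": 0.04, "necrotic": 0.006})
    ve: dict = field(default_factory=lambda: {
        "background": 0.15, "viable": 0.40, "necrotic": 0.12})
    ve_sd: dict = field(default_factory=lambda: {
        "background": 0.01, "viable": 0.04, "necrotic": 0.015})
    dce_duration: float = 180.0               # s
    dce_interval: float = 19.5                # s
    dce_base_signal: float = 200.0
    dce_noise_sd: float = 0.5
    aif: AIFParams = field(default_factory=AIFParams)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    histology_upsampling: int = 4
    tissue_loss_fraction: float = 0.0
    warp_amplitude: float = 2.0               # mm
    n_control_points: int = 12
    control_point_jitter: float = 0.0         # mm, in histology plane
    seed: int = 0

    def validate(self):
        f = self.necrosis_fraction
        if not 0.0 <= f <= 100.0:
            raise ValueError("necrosis fraction must lie in [0, 100]")
        if any(a <= 0 for a in self.tumor_axes):
            raise ValueError("tumor axes must be positive")
        c, a, s = self.tumor_center, self.tumor_axes, self.shape
        if any(c[i] - a[i] < 0 or c[i] + a[i] > s[i] - 1 for i in range(3)):
            raise ValueError("tumor exceeds the grid")
        if self.adc["necrotic"] <= self.adc["viable"]:
            raise ValueError("phantom requires ADC(necrotic) > ADC(viable)")
        if self.ktrans["necrotic"] >= self.ktrans["viable"]:
            raise ValueError(
                "phantom requires K^trans(necrotic) < K^trans(viable)")
        return self


@dataclass
class PhantomTruth:
    """Ground truth record accompanying a generated case."""

    labels: np.ndarray         # (nx, ny, nz) int, NON_TUMOR/VIABLE/NECROTIC
    aoi_fraction: float        # percent necrosis among AOI tumor pixels
    voi_fraction: float        # percent necrosis among VOI voxels
    adc: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray

    def aoi_labels(self, poi_index: int) -> np.ndarray:
        return self.labels[:, :, poi_index]


# ---------------------------------------------------------------------------
# Field helpers
# ---------------------------------------------------------------------------

def _grf(rng, shape, corr_len):
    """Unit-variance Gaussian random field with Gaussian correlation."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=(corr_len, corr_len, 1.0))
    sd = f.std()
    return f / (sd if sd > 0 else 1.0)


def _class_field(rng, labels, spec: ClassSignal):
    out = np.empty(labels.shape)
    for cls, mean, sd, corr in (
            (NON_TUMOR, spec.background, spec.sd_background,
             spec.corr_background),
            (VIABLE, spec.viable, spec.sd_viable, spec.corr_viable),
            (NECROTIC, spec.necrotic, spec.sd_necrotic,
             spec.corr_necrotic)):
        m = labels == cls
        if m.any():
            out[m] = mean + sd * _grf(rng, labels.shape, corr)[m]
    return out


def _scalar_field(rng, labels, means, sds, corrs=None, positive=True):
    if corrs is None:
        corrs = {"background": 1.5, "viable": 1.0, "necrotic": 2.5}
    out = np.empty(labels.shape)
    for cls, key in ((NON_TUMOR, "background"), (VIABLE, "viable"),
                     (NECROTIC, "necrotic")):
        m = labels == cls
        if m.any():
            out[m] = means[key] + sds[key] * _grf(rng, labels.shape,
                                                  corrs[key])[m]
    if positive:
        out = np.clip(out, 1e-6, None)
    return out


# ---------------------------------------------------------------------------
# Forward simulators
# ---------------------------------------------------------------------------

def simulate_dwi(adc_truth: ImageGrid, s0: ImageGrid, b_values,
                 noise_sd: float = 0.0, rng=None):
    """DWI stack ``S(b) = S0 exp(-b ADC)`` (+ Gaussian noise)."""
    bs = [float(b) for b in b_values]
    if any(b < 0 for b in bs):
        raise ValueError("b-values must be nonnegative")
    if len(set(bs)) != len(bs):
        raise ValueError("b-values must be distinct")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for b in bs:
        sig = s0.values * np.exp(-b * adc_truth.values)
        if noise_sd > 0:
            sig = sig + noise_sd * rng.standard_normal(sig.shape)
        out.append((b, adc_truth.with_values(sig)))
    return out


def simulate_dce(ktrans_truth: ImageGrid, ve_truth: ImageGrid,
                 aif_params: AIFParams, acquisition: AcquisitionParams,
                 noise_sd: float = 0.0, duration: float = 180.0,
                 interval: float = 19.5, base_signal=200.0,
                 artery_mask: Optional[np.ndarray] = None,
                 rng=None) -> DCESeries:
    """DCE series from the Tofts forward model and SPGR signal relation.

    Tissue concentration follows the Tofts convolution of the sampled
    (piecewise-linear) AIF; artery voxels, when a mask is given, carry
    the AIF itself converted with the blood T1.
    """
    kt = np.asarray(ktrans_truth.values, dtype=np.float64)
    ve = np.asarray(ve_truth.values, dtype=np.float64)
    if np.any((ve <= 0) & (kt > 0)):
        raise ValueError("v_e = 0 with positive K^trans")
    rng = np.random.default_rng() if rng is None else rng
    t = np.arange(0.0, duration, interval)
    cp = population_aif(t, aif_params)
    flat_kt = kt.ravel()
    flat_ve = ve.ravel()
    ct = tofts_concentration(t, cp, flat_kt, flat_ve)  # (N, T)
    base = np.broadcast_to(np.asarray(base_signal, dtype=np.float64),
                           kt.shape).ravel()
    sig = spgr_signal_from_concentration(
        ct, base[:, None], acquisition.t1_tissue, acquisition)
    if artery_mask is not None:
        am = np.asarray(artery_mask, dtype=bool).ravel()
        art_sig = spgr_signal_from_concentration(
            cp[None, :], base[am][:, None], acquisition.t1_blood,
            acquisition)
        sig[am] = art_sig
    if noise_sd > 0:
        sig = sig + noise_sd * rng.standard_normal(sig.shape)
    frames = [ktrans_truth.with_values(sig[:, j].reshape(kt.shape))
              for j in range(t.size)]
    return DCESeries(frames, t, sampling_interval=interval,
                     acquisition=acquisition)


def simulate_tissue_loss(vmap: ViabilityMap, loss_fraction: float,
                         seed=0) -> ViabilityMap:
    """Convert a connected ~``loss_fraction`` share of necrotic pixels
    to ``non_tumor`` (liquified necrosis lost during processing)."""
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss fraction must lie in [0, 1]")
    values = vmap.values.copy()
    nec = np.argwhere(values == NECROTIC)
    n_target = int(round(loss_fraction * len(nec)))
    if n_target == 0:
        return ViabilityMap(values, vmap.spacing, vmap.origin)
    rng = np.random.default_rng(seed)
    nec_set = {tuple(p) for p in nec}
    lost = set()
    frontier = []
    while len(lost) < n_target:
        if not frontier:
            remaining = sorted(nec_set - lost)
            frontier = [remaining[rng.integers(len(remaining))]]
        x, y = frontier.pop(rng.integers(len(frontier)))
        if (x, y) in lost:
            continue
        lost.add((x, y))
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            p = (x + dx, y + dy)
            if p in nec_set and p not in lost:
                frontier.append(p)
    for x, y in lost:
        values[x, y] = NON_TUMOR
    return ViabilityMap(values, vmap.spacing, vmap.origin)


# ---------------------------------------------------------------------------
# Warp between MR plane and histology plane
# ---------------------------------------------------------------------------

class QuadraticWarp:
    """Smooth random second-order displacement of the MR plane (mm)."""

    def __init__(self, rng, extent, amplitude):
        self.center = np.asarray(extent, dtype=np.float64) / 2.0
        self.scale = np.maximum(self.center, 1.0)
        coeffs = rng.standard_normal((2, 6))
        norm = np.abs(coeffs).sum(axis=1, keepdims=True)
        self.coeffs = amplitude * coeffs / np.where(norm > 0, norm, 1.0)

    def displacement(self, pts):
        u = (pts - self.center) / self.scale
        design = np.column_stack([
            np.ones(len(u)), u[:, 0], u[:, 1], u[:, 0] * u[:, 1],
            u[:, 0] ** 2, u[:, 1] ** 2])
        return design @ self.coeffs.T

    def forward(self, pts):
        """MR physical coords -> histology physical coords."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        return pts + self.displacement(pts)

    def inverse(self, pts, n_iter=12):
        """Fixed-point inversion (small smooth displacements)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        x = pts.copy()
        for _ in range(n_iter):
            x = pts - self.displacement(x)
        return x


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig):
    """Generate one synthetic case plus its ground-truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    spacing = tuple(config.spacing)

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cx, cy, cz = config.tumor_center
    ax, ay, az = config.tumor_axes
    tumor = (((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2
             + ((iz - cz) / az) ** 2) <= 1.0
    poi = int(round(cz))

    # Necrosis compartment: two-pole geometry.  Necrosis grows around an
    # interior pole while viable tumor remains a compact lens around the
    # opposite pole, so both compartments stay compact (short interface)
    # at any target fraction; a smooth random field wiggles the
    # interface.  Per-slice quantile thresholding keeps the slice-wise
    # fraction at the target (exact pixel counts).
    off = rng.uniform(0.35, 0.55)
    theta = rng.uniform(0, 2 * np.pi)
    pn = (cx + off * ax * np.cos(theta), cy + off * ay * np.sin(theta))
    pv = (cx - off * ax * np.cos(theta), cy - off * ay * np.sin(theta))
    d_n = np.sqrt(((ix - pn[0]) / ax) ** 2 + ((iy - pn[1]) / ay) ** 2)
    d_v = np.sqrt(((ix - pv[0]) / ax) ** 2 + ((iy - pv[1]) / ay) ** 2)
    fld = (d_v - d_n) + 0.35 * _grf(rng, config.shape,
                                    config.necrosis_blob_scale)
    for _ in range(config.n_necrosis_blobs):
        bx = cx + (rng.uniform(-0.6, 0.6)) * ax
        by = cy + (rng.uniform(-0.6, 0.6)) * ay
        bump = np.exp(-(((ix - bx) / (0.35 * ax)) ** 2
                        + ((iy - by) / (0.35 * ay)) ** 2))
        fld = fld + 1.5 * bump
    labels = np.full(config.shape, NON_TUMOR, dtype=np.int16)
    labels[tumor] = VIABLE
    f = config.necrosis_fraction / 100.0
    for z in range(nz):
        m = tumor[:, :, z]
        n = int(m.sum())
        if n == 0:
            continue
        k = int(round(f * n))
        if k <= 0:
            continue
        vals = fld[:, :, z][m]
        order = np.argsort(vals)[::-1]
        sel = np.zeros(n, dtype=bool)
        sel[order[:k]] = True
        plane = labels[:, :, z]
        mm = np.zeros((nx, ny), dtype=bool)
        mm[m] = sel
        plane[mm] = NECROTIC
        labels[:, :, z] = plane

    aoi_mask = tumor[:, :, poi]
    n_aoi = int(aoi_mask.sum())
    aoi_frac = 100.0 * (labels[:, :, poi] == NECROTIC).sum() / max(n_aoi, 1)
    voi_frac = 100.0 * (labels[tumor] == NECROTIC).sum() / max(tumor.sum(), 1)

    # Conventional images
    images = {}
    for name, spec in config.conventional.items():
        images[name] = ImageGrid(_class_field(rng, labels, spec), spacing)

    # DWI
    adc_vol = _scalar_field(rng, labels, config.adc, config.adc_sd,
                            corrs=config.map_corr)
    s0 = ImageGrid(np.full(config.shape, config.dwi_s0), spacing)
    dwi = simulate_dwi(ImageGrid(adc_vol, spacing), s0, config.b_values,
                       noise_sd=config.dwi_noise_sd, rng=rng)

    # DCE (+ feeding artery in a corner well away from the tumor)
    kt_vol = _scalar_field(rng, labels, config.ktrans, config.ktrans_sd,
                           corrs=config.map_corr)
    ve_vol = np.clip(
        _scalar_field(rng, labels, config.ve, config.ve_sd,
                      corrs=config.map_corr), 0.02, 1.0)
    artery = np.zeros(config.shape, dtype=bool)
    artery[2:4, 2:4, max(poi - 1, 0):poi + 1] = True
    kt_vol[artery] = 0.0
    dce = simulate_dce(ImageGrid(kt_vol, spacing), ImageGrid(ve_vol, spacing),
                       config.aif, config.acquisition,
                       noise_sd=config.dce_noise_sd,
                       duration=config.dce_duration,
                       interval=config.dce_interval,
                       base_signal=config.dce_base_signal,
                       artery_mask=artery, rng=rng)

    # Histology plane: known quadratic warp of the POI labels at higher res
    extent = (nx * spacing[0], ny * spacing[1])
    warp = QuadraticWarp(rng, extent, config.warp_amplitude)
    up = config.histology_upsampling
    hsp = (spacing[0] / up, spacing[1] / up)
    corners = np.array([[0.0, 0.0], [extent[0], 0.0], [0.0, extent[1]],
                        [extent[0], extent[1]]])
    wc = warp.forward(corners)
    h_origin = (wc[:, 0].min(), wc[:, 1].min())
    hnx = int(np.ceil((wc[:, 0].max() - h_origin[0]) / hsp[0])) + 1
    hny = int(np.ceil((wc[:, 1].max() - h_origin[1]) / hsp[1])) + 1
    hx, hy = np.meshgrid(np.arange(hnx), np.arange(hny), indexing="ij")
    hpts = np.column_stack([h_origin[0] + hx.ravel() * hsp[0],
                            h_origin[1] + hy.ravel() * hsp[1]])
    mr_pts = warp.inverse(hpts)
    gx = np.rint(mr_pts[:, 0] / spacing[0]).astype(np.int64)
    gy = np.rint(mr_pts[:, 1] / spacing[1]).astype(np.int64)
    inside = (gx >= 0) & (gx < nx) & (gy >= 0) & (gy < ny)
    hlab = np.full(hnx * hny, NON_TUMOR, dtype=np.int16)
    poi_labels = labels[:, :, poi]
    hlab[inside] = poi_labels[gx[inside], gy[inside]]
    histology = ViabilityMap(hlab.reshape(hnx, hny), spacing=hsp,
                             origin=h_origin)
    if config.tissue_loss_fraction > 0:
        histology = simulate_tissue_loss(
            histology, config.tissue_loss_fraction,
            seed=int(rng.integers(2 ** 31)))

    # Control points: a ring around the tumor boundary on the POI plane
    ncp = config.n_control_points
    ang = np.linspace(0, 2 * np.pi, ncp, endpoint=False)
    # alternate two radii so the landmarks do not all lie on one conic
    # (a single ellipse would make every local quadratic fit degenerate)
    radius = np.where(np.arange(ncp) % 2 == 0, 1.15, 1.45)
    ring = np.column_stack([
        (cx + radius * ax * np.cos(ang)) * spacing[0],
        (cy + radius * ay * np.sin(ang)) * spacing[1]])
    hist_cp = warp.forward(ring)
    if config.control_point_jitter > 0:
        hist_cp = hist_cp + config.control_point_jitter * rng.standard_normal(
            hist_cp.shape)
    cps = pd.DataFrame({
        "x_hist": hist_cp[:, 0], "y_hist": hist_cp[:, 1],
        "x_mr": ring[:, 0], "y_mr": ring[:, 1]})

    tumor_nec = histology.values[histology.values != NON_TUMOR]
    n_hist = (100.0 * (tumor_nec == NECROTIC).sum() / len(tumor_nec)
              if len(tumor_nec) else 0.0)

    case = MRICase(
        case_id=f"phantom-{config.seed}",
        images=images, dwi=dwi, dce=dce,
        voi=MaskGrid(tumor, role="VOI", spacing=spacing),
        poi_index=poi, histology=histology, control_points=cps,
        n_hist=float(n_hist),
        artery_mask=MaskGrid(artery, role="artery", spacing=spacing))
    truth = PhantomTruth(labels=labels, aoi_fraction=float(aoi_frac),
                         voi_fraction=float(voi_frac), adc=adc_vol,
                         ktrans=kt_vol, ve=ve_vol)
    return case, truth


#: Necrosis targets of the default phantom suite, skewed toward good
#: responders as in typical post-chemotherapy osteosarcoma cohorts.
DEFAULT_SUITE_FRACTIONS = (20.0, 35.0, 50.0, 65.0, 80.0, 88.0, 92.0, 95.0,
                           97.0, 99.0)


def make_default_suite(seed: int = 0, fractions=DEFAULT_SUITE_FRACTIONS,
                       **overrides):
    """The default 10-case suite; per-case seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child, frac in zip(ss.spawn(len(fractions)), fractions):
        cfg = PhantomConfig(necrosis_fraction=float(frac),
                            seed=int(child.generate_state(1)[0] % (2 ** 31)),
                            **overrides)
        out.append(generate_phantom(cfg))
    return out
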