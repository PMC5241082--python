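"""ADC map computation and gradient-nonlinearity correction.

ADC maps are computed from the log-trace (geometric-mean across directions)
diffusion-weighted images as

    ADC = [ln S_trace(0) - ln S_trace(b_high)] / b_high,

reported in 1e-3 mm^2/s, with values outside the physically plausible
0.5-3.3 range set to zero and masked.  Correction divides the map by the
direction-averaged corrector, ADC_c(r) = ADC(r) / C_av(r); the equivalent
intensity/b-value route rescales each direction's log-decay by 1/C_k before
recomputing the map and coincides with the direct division for noiseless
isotropic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corrector import CorrectorMap, DirectionSchema
from .grids import ImageGeometry

#: plausible ADC window in 1e-3 mm^2/s; values outside are zeroed and masked
ADC_CLIP_RANGE = (0.5, 3.3)

_DIR_TOL = 1e-6


@dataclass(frozen=True)
class DWISeries:
    """Multi-b-value DWI series.

    ``data`` is (ni, nj, nk, n_acq); acquisitions with equal (b, direction)
    are treated as repeated excitations and averaged arithmetically before
    any log-domain step.  ``bvecs`` holds unit direction columns per
    acquisition in (AP, RL, SI) components; rows for b = 0 are zero.
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    geometry: ImageGeometry
    schema: DirectionSchema | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, float)
        b = np.asarray(self.bvals, float)
        v = np.asarray(self.bvecs, float)
        if d.ndim != 4:
            raise ValueError("DWI data must be 4D (3 spatial axes + acquisition)")
        if d.shape[:3] != self.geometry.shape:
            raise ValueError("DWI data does not match its geometry")
        if b.shape != (d.shape[3],) or v.shape != (d.shape[3], 3):
            raise ValueError("bvals/bvecs must match the acquisition axis")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(d < 0):
            raise ValueError("DWI intensities must be non-negative")
        if 0.0 not in b or len(set(b.tolist())) < 2:
            raise ValueError("series needs b=0 plus at least one nonzero b-value")
        nz = b > 0
        norms = np.linalg.norm(v[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("diffusion directions must be unit vectors")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "bvals", b)
        object.__setattr__(self, "bvecs", v)

    @property
    def b_high(self) -> float:
        return float(self.bvals.max())

    def shells(self) -> dict[float, list[int]]:
        out: dict[float, list[int]] = {}
        for i, b in enumerate(self.bvals):
            out.setdefault(float(b), []).append(i)
        return out

    def _grouped(self, b: float) -> list[tuple[np.ndarray, np.ndarray]]:
        """(direction, excitation-averaged image) per distinct direction at b."""
        idx = [i for i, bb in enumerate(self.bvals) if abs(bb - b) < 1e-9]
        if not idx:
            raise ValueError(f"no acquisitions at b={b}")
        groups: list[tuple[np.ndarray, list[int]]] = []
        for i in idx:
            u = self.bvecs[i]
            for gu, gi in groups:
                if np.linalg.norm(u - gu) < _DIR_TOL:
                    gi.append(i)
                    break
            else:
                groups.append((u, [i]))
        return [(u, self.data[..., gi].mean(axis=-1)) for u, gi in groups]


@dataclass(frozen=True)
class ADCMap:
    """ADC in 1e-3 mm^2/s with a validity mask; invalid voxels store 0."""

    values: np.ndarray
    mask: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        m = np.asarray(self.mask, bool)
        if v.shape != self.geometry.shape or m.shape != v.shape:
            raise ValueError("ADC values/mask do not match the geometry")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


def clip_adc(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the plausibility window: out-of-range voxels -> 0, mask cleared.

    Idempotent: re-applying to an already clipped map changes nothing.
    """
    lo, hi = ADC_CLIP_RANGE
    ok = mask & np.isfinite(values) & (values >= lo) & (values <= hi)
    out = np.where(ok, values, 0.0)
    return out, ok


def trace_image(dwi: DWISeries, b: float) -> np.ndarray:
    """Geometric-mean (trace) image across the schema directions at shell b.

    Excitations are averaged arithmetically first; for b = 0 the plain mean
    is returned.  Raises if a schema direction has no acquisition at b.
    """
    groups = dwi._grouped(b)
    if b == 0:
        return np.mean([img for _, img in groups], axis=0)
    if dwi.schema is not None:
        for k, u in enumerate(dwi.schema.directions):
            if not any(
                min(np.linalg.norm(gu - u), np.linalg.norm(gu + u)) < _DIR_TOL
                for gu, _ in groups
            ):
                raise ValueError(
                    f"missing direction {np.round(u, 4).tolist()} "
                    f"(schema {dwi.schema.name}, index {k}) at b={b}"
                )
    imgs = np.stack([img for _, img in groups], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(imgs)
    return np.exp(np.mean(logs, axis=-1))


def compute_adc(dwi: DWISeries, b_high: float | None = None) -> ADCMap:
    """Two-point log-trace ADC map between b = 0 and the high shell.

    ``b_high`` defaults to the largest b-value present.  Voxels with a
    nonpositive intensity in either trace image are masked, not raised.
    """
    if b_high is None:
        b_high = dwi.b_high
    if b_high <= 0:
        raise ValueError("b_high must be positive")
    s0 = trace_image(dwi, 0.0)
    sb = trace_image(dwi, float(b_high))
    ok = (s0 > 0) & (sb > 0) & np.isfinite(s0) & np.isfinite(sb)
    adc = np.zeros_like(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[ok] = (np.log(s0[ok]) - np.log(sb[ok])) / b_high * 1e3
    values, mask = clip_adc(adc, ok)
    return ADCMap(values, mask, dwi.geometry)


def correct_adc(adc: ADCMap, c_av: CorrectorMap) -> ADCMap:
    """Pixel-wise GNL correction ADC_c = ADC / C_av, then re-clipped."""
    if c_av.geometry is None or not adc.geometry.matches(c_av.geometry):
        raise ValueError("corrector must be resampled to the ADC geometry")
    corrected = np.where(adc.mask, adc.values / c_av.values, 0.0)
    values, mask = clip_adc(corrected, adc.mask)
    return ADCMap(values, mask, adc.geometry)


def correct_intensities(
    dwi: DWISeries, correctors: list[tuple[np.ndarray, CorrectorMap]]
) -> DWISeries:
    """Equivalent intensity/b-value correction route.

    Each diffusion-weighted acquisition along direction u_k has its
    log-decay rescaled by 1/C_k(r) — i.e. its effective b-value b C_k(r)
    is mapped back to the nominal b — via S' = S0 (S/S0)^(1/C_k).  For
    noiseless isotropic input, recomputing the ADC map from the returned
    series reproduces ``correct_adc`` exactly.
    """
    cmap: list[tuple[np.ndarray, np.ndarray]] = []
    for u, c in correctors:
        if c.geometry is None or not dwi.geometry.matches(c.geometry):
            raise ValueError("per-direction correctors must match the DWI geometry")
        cmap.append((np.asarray(u, float), c.values))
    s0 = trace_image(dwi, 0.0)
    data = dwi.data.copy()
    for i in range(data.shape[-1]):
        if dwi.bvals[i] == 0:
            continue
        u = dwi.bvecs[i]
        for cu, cv in cmap:
            if min(np.linalg.norm(cu - u), np.linalg.norm(cu + u)) < _DIR_TOL:
                ck = cv
                break
        else:
            raise ValueError(
                f"no corrector supplied for direction {np.round(u, 4).tolist()}"
            )
        s = data[..., i]
        ok = (s > 0) & (s0 > 0)
        out = np.zeros_like(s)
        out[ok] = s0[ok] * (s[ok] / s0[ok]) ** (1.0 / ck[ok])
        data[..., i] = out
    return replace(dwi, data=data)


def zero_fill(dwi: DWISeries, shape2d: tuple[int, int]) -> DWISeries:
    """Frequency-domain zero-fill interpolation of the in-plane matrix.

    Pads the centered 2D spectrum of each slice/acquisition to ``shape2d``
    (e.g. low-resolution acquisitions interpolated to 256 x 256 before ADC
    computation); in-plane voxel spacing shrinks accordingly so physical
    coverage is preserved.
    """
    ni, nj, nk, na = dwi.data.shape
    mi, mj = shape2d
    if mi < ni or mj < nj:
        raise ValueError("zero-fill target must not be smaller than the matrix")
    spec = np.fft.fftshift(np.fft.fft2(dwi.data, axes=(0, 1)), axes=(0, 1))
    pad_i, pad_j = mi - ni, mj - nj
    pads = (
        (pad_i // 2, pad_i - pad_i // 2),
        (pad_j // 2, pad_j - pad_j // 2),
        (0, 0),
        (0, 0),
    )
    spec = np.pad(spec, pads)
    out = np.fft.ifft2(np.fft.ifftshift(spec, axes=(0, 1)), axes=(0, 1))
    out = np.abs(out) * (mi * mj) / (ni * nj)
    # DFT interpolation keeps the first sample position; spacing shrinks n/m
    aff = dwi.geometry.affine.copy()
    aff[:3, 0] *= ni / mi
    aff[:3, 1] *= nj / mj
    geom = ImageGeometry(aff, (mi, mj, nk))
    return replace(dwi, data=out, geometry=geom)
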