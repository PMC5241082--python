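"""Gradient-nonlinearity tensor fields: evaluation, rescaling, calibration.

The dimensionless nonlinearity tensor L(r) maps the nominal gradient vector
to the achieved gradient at location r; it is the identity at the magnet
isocenter.  A *generic* field L^M comes straight from a coil model's
harmonic expansion; a *system-specific* field is obtained by value-rescaling
the generic one with per-channel scale factors F_i fitted to empirical 1D
channel-characterization profiles (measured ADC along an axis divided by the
reference ice-water diffusivity 1.1e-3 mm^2/s):

    L_ii = F_i (L^M_ii - 1) + 1        (diagonal deviations scale)
    L_ij = F_i  L^M_ij                 (off-diagonal, row-channel scale)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import AXES, GridSpec
from .harmonics import HarmonicCoilModel

#: reference diffusivity of ice water, 1e-3 mm^2/s, used to normalize
#: empirical channel profiles to dimensionless L_ii samples
ICE_WATER_ADC = 1.1

_ISO_TOL = 1e-9


@dataclass(frozen=True)
class NonlinearityTensorField:
    """3x3 dimensionless tensor L sampled on a regular grid.

    ``tensor`` has shape ``grid.shape + (3, 3)``; component order follows
    the magnet axes (AP, RL, SI) for both rows and columns.
    """

    grid: GridSpec
    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, float)
        if t.shape != self.grid.shape + (3, 3):
            raise ValueError("tensor shape does not match grid")
        if not np.isfinite(t).all():
            raise ValueError("tensor field contains non-finite values")
        object.__setattr__(self, "tensor", t)

    @property
    def isocenter_tensor(self) -> np.ndarray:
        return self.tensor[self.grid.isocenter_index()]

    def check_isocenter_identity(self, tol: float = _ISO_TOL) -> None:
        dev = np.abs(self.isocenter_tensor - np.eye(3)).max()
        if dev > tol:
            raise ValueError(
                f"tensor at isocenter deviates from identity by {dev:.3g}"
            )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of all 9 components at (..., 3) mm points."""
        pts = np.asarray(points, float)
        if not self.grid.contains(pts.reshape(-1, 3)).all():
            raise ValueError("requested points fall outside the tensor grid")
        idx = self.grid.to_index(pts).reshape(-1, 3).T
        out = np.empty(pts.shape[:-1] + (3, 3), float)
        for i in range(3):
            for j in range(3):
                out[..., i, j] = ndimage.map_coordinates(
                    self.tensor[..., i, j], idx, order=1, mode="nearest"
                ).reshape(pts.shape[:-1])
        return out


def evaluate_generic_tensor(
    model: HarmonicCoilModel, grid: GridSpec
) -> NonlinearityTensorField:
    """Evaluate the generic tensor L^M(r) on a grid via analytic derivatives.

    The grid must contain a node at the magnet isocenter, where the
    normalized model's Jacobian is verified to be the identity.
    """
    grid.isocenter_index()  # raises if the isocenter is not a grid node
    pts = grid.meshgrid()
    tensor = model.jacobian(pts)
    field = NonlinearityTensorField(grid, tensor)
    field.check_isocenter_identity()
    return field


@dataclass(frozen=True)
class ChannelScaleFactors:
    """Per-channel value-scale factors F_i with fractional fit uncertainties."""

    F_AP: float
    F_RL: float
    F_SI: float
    fit_uncertainty: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.as_array()):
            raise ValueError("scale factors must be positive")
        if any(u < 0 for u in self.fit_uncertainty):
            raise ValueError("fit uncertainties must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.F_AP, self.F_RL, self.F_SI], float)


def rescale_tensor(
    generic: NonlinearityTensorField, F: ChannelScaleFactors
) -> NonlinearityTensorField:
    """System-specific field from the generic one by per-channel value scaling."""
    f = F.as_array()
    t = generic.tensor.copy()
    eye = np.eye(3, dtype=bool)
    t[..., eye] = f * (t[..., eye] - 1.0) + 1.0
    t[..., ~eye] *= np.repeat(f, 2)  # row-channel scale for the 6 off-diagonals
    out = NonlinearityTensorField(generic.grid, t)
    out.check_isocenter_identity()
    return out


@dataclass(frozen=True)
class Profile1D:
    """Empirical diagonal-term samples along one magnet axis.

    ``channel`` names the characterized gradient channel (the i of L_ii);
    ``axis`` names the axis along which the offsets run.  ``values`` are
    dimensionless L_ii samples, i.e. measured directional ADC divided by
    the reference diffusivity.
    """

    channel: str
    axis: str
    offsets_mm: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.channel not in AXES or self.axis not in AXES:
            raise ValueError(f"channel and axis must be one of {AXES}")
        off = np.asarray(self.offsets_mm, float)
        val = np.asarray(self.values, float)
        if off.ndim != 1 or off.shape != val.shape:
            raise ValueError("offsets and values must be matching 1D arrays")
        if not (np.all(np.diff(off) > 0) or np.all(np.diff(off) < 0)):
            raise ValueError("profile offsets must be strictly monotone")
        if np.any(val <= 0):
            raise ValueError("profile values must be positive")
        object.__setattr__(self, "offsets_mm", off)
        object.__setattr__(self, "values", val)
        if self.sd is not None:
            sd = np.asarray(self.sd, float)
            if sd.shape != off.shape or np.any(sd < 0):
                raise ValueError("sd must match offsets and be non-negative")
            object.__setattr__(self, "sd", sd)

    def points_mm(self) -> np.ndarray:
        pts = np.zeros((len(self.offsets_mm), 3))
        pts[:, AXES.index(self.axis)] = self.offsets_mm
        return pts

    @classmethod
    def from_adc(cls, channel, axis, offsets_mm, adc, sd=None,
                 reference_adc: float = ICE_WATER_ADC) -> "Profile1D":
        """Build from directional ADC measurements (1e-3 mm^2/s units)."""
        adc = np.asarray(adc, float)
        sdn = None if sd is None else np.asarray(sd, float) / reference_adc
        return cls(channel, axis, offsets_mm, adc / reference_adc, sdn)


def fit_scale_factors(
    profiles: list[Profile1D],
    generic: NonlinearityTensorField,
    min_signal: float = 1e-4,
) -> ChannelScaleFactors:
    """Weighted least-squares fit of F_i to channel-characterization profiles.

    For each channel, all of its profiles (typically the SI and the
    transverse cross-sections of L_ii) are fitted simultaneously to
    ``F (L^M_ii - 1) + 1`` with weights 1/sd^2 (uniform when sd is absent).
    The closed-form WLS estimate and its reduced-chi-square-scaled standard
    error are returned; a profile set with no off-center signal (all
    |L^M_ii - 1| below ``min_signal``) is a degenerate fit and raises.
    """
    by_channel: dict[str, list[Profile1D]] = {ch: [] for ch in AXES}
    for p in profiles:
        by_channel[p.channel].append(p)

    F = {}
    unc = {}
    for ch in AXES:
        plist = by_channel[ch]
        if not plist:
            raise ValueError(f"no profile provided for channel {ch}")
        i = AXES.index(ch)
        d_all, y_all, w_all = [], [], []
        for p in plist:
            lm = generic.sample(p.points_mm())[:, i, i]
            d_all.append(lm - 1.0)
            y_all.append(p.values - 1.0)
            w_all.append(
                np.ones_like(p.values) if p.sd is None else 1.0 / p.sd**2
            )
        d = np.concatenate(d_all)
        y = np.concatenate(y_all)
        w = np.concatenate(w_all)
        swd2 = float(np.sum(w * d * d))
        if np.max(np.abs(d)) < min_signal or swd2 == 0.0:
            raise ValueError(
                f"degenerate fit for channel {ch}: profiles carry no "
                "nonlinearity signal away from the isocenter"
            )
        fhat = float(np.sum(w * d * y) / swd2)
        if fhat <= 0:
            raise ValueError(f"fitted scale factor for channel {ch} is not positive")
        resid = y - fhat * d
        dof = max(len(y) - 1, 1)
        chi2nu = float(np.sum(w * resid**2) / dof)
        unc[ch] = float(np.sqrt(chi2nu / swd2) / fhat)
        F[ch] = fhat
    return ChannelScaleFactors(
        F["AP"], F["RL"], F["SI"], (unc["AP"], unc["RL"], unc["SI"])
    )


def write_profile(profile: Profile1D, path: str | Path) -> None:
    lines = [
        f"# channel\t{profile.channel}",
        f"# axis\t{profile.axis}",
        "offset_mm\tvalue\tsd",
    ]
    sd = profile.sd if profile.sd is not None else np.full_like(profile.values, np.nan)
    for o, v, s in zip(profile.offsets_mm, profile.values, sd):
        lines.append(f"{o:.6g}\t{v:.10g}\t{s:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> Profile1D:
    channel = axis = None
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("\t")
            if key == "channel":
                channel = val.strip()
            elif key == "axis":
                axis = val.strip()
            continue
        if line.startswith("offset_mm"):
            continue
        rows.append([float(v) for v in line.split("\t")])
    if channel is None or axis is None:
        raise ValueError(f"profile file {path} lacks channel/axis headers")
    arr = np.asarray(rows, float)
    sd = arr[:, 2] if arr.shape[1] > 2 and np.isfinite(arr[:, 2]).all() else None
    return Profile1D(channel, axis, arr[:, 0], arr[:, 1], sd)
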