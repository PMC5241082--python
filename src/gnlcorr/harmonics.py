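"""Spherical-harmonic gradient-coil models.

A gradient channel i in {AP, RL, SI} produces a longitudinal field whose
spatial profile is expanded in real solid harmonics

    f_i(r) = sum_{n,m} c_{nm} * R^(1-n) * {C_nm | S_nm}(x, y, z),

with C_nm = r^n P_n^m(cos th) cos(m ph) and S_nm the sin(m ph) partner,
P_n^m the unnormalized (Ferrers, no Condon-Shortley phase) associated
Legendre functions, R the reference radius in mm, and the polar axis along
SI.  Cartesian correspondence: x = AP, y = RL, z = SI.

Coefficients are stored relative to the channel's own linear (n = 1) term,
so every normalized channel has unit gradient at the isocenter and the
Jacobian of the three normalized fields — the gradient-nonlinearity tensor
L^M(r) — equals the identity at the origin.

Solid harmonics and their analytic gradients are generated symbolically
(sympy) once per model and evaluated as vectorized numpy closures; finite
differences are used only as a test oracle elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy as sp

from .grids import AXES, GridSpec

#: primary linear term (n, m, kind) per channel, fixing the normalization
PRIMARY_TERM = {"AP": (1, 1, "cos"), "RL": (1, 1, "sin"), "SI": (1, 0, "cos")}

_X, _Y, _Z = sp.symbols("x y z", real=True)


def solid_harmonic_expr(n: int, m: int, kind: str) -> sp.Expr:
    """Real solid harmonic r^n P_n^m(cos th) {cos|sin}(m ph) as a polynomial.

    Uses the Ferrers associated Legendre functions without the
    Condon-Shortley phase, so the n = 1 harmonics are exactly x, y and z.
    """
    if n < 1 or m < 0 or m > n:
        raise ValueError(f"invalid harmonic degree/order (n={n}, m={m})")
    if kind not in ("cos", "sin"):
        raise ValueError("kind must be 'cos' or 'sin'")
    if kind == "sin" and m == 0:
        raise ValueError("sin harmonic with m = 0 is identically zero")
    t = sp.Symbol("t")
    dpm = sp.diff(sp.legendre(n, t), t, m)  # d^m P_n / dt^m, polynomial in t
    r2 = _X**2 + _Y**2 + _Z**2
    radial = sp.S.Zero
    for k, a in sp.Poly(dpm, t).terms():
        j = (n - m - k[0]) // 2  # parity guarantees integrality
        radial += a * _Z ** k[0] * r2**j
    azim = sp.expand((_X + sp.I * _Y) ** m)
    azim = sp.re(azim) if kind == "cos" else sp.im(azim)
    return sp.expand(radial * azim)


@dataclass(frozen=True)
class HarmonicTerm:
    n: int
    m: int
    kind: str  # 'cos' | 'sin'
    coefficient: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.coefficient):
            raise ValueError("harmonic coefficient must be finite")
        if self.n < 1:
            raise ValueError("harmonic degree n must be >= 1")
        if not (0 <= self.m <= self.n):
            raise ValueError("harmonic order m must satisfy 0 <= m <= n")
        if self.kind not in ("cos", "sin"):
            raise ValueError("kind must be 'cos' or 'sin'")


class HarmonicCoilModel:
    """Three-channel (AP, RL, SI) solid-harmonic coil model.

    Parameters
    ----------
    channels : mapping channel -> list of HarmonicTerm
        Each channel must contain a nonzero primary linear term (see
        ``PRIMARY_TERM``).  Coefficients are renormalized on construction so
        the primary term is exactly 1.
    reference_radius_mm : float
        Radius R at which the dimensionless coefficients are referenced.
    normalization : str
        Free-form tag recording the coefficient convention.
    """

    def __init__(
        self,
        channels: dict[str, list[HarmonicTerm]],
        reference_radius_mm: float = 250.0,
        normalization: str = "relative-linear",
    ) -> None:
        if set(channels) != set(AXES):
            raise ValueError(f"model must define exactly the channels {AXES}")
        if reference_radius_mm <= 0:
            raise ValueError("reference radius must be positive")
        self.reference_radius_mm = float(reference_radius_mm)
        self.normalization = normalization
        self.channels: dict[str, tuple[HarmonicTerm, ...]] = {}
        for ch, terms in channels.items():
            prim = [t for t in terms if (t.n, t.m, t.kind) == PRIMARY_TERM[ch]]
            if not prim or prim[0].coefficient == 0:
                raise ValueError(
                    f"channel {ch} lacks a nonzero primary linear term "
                    f"{PRIMARY_TERM[ch]}"
                )
            c1 = prim[0].coefficient
            self.channels[ch] = tuple(
                HarmonicTerm(t.n, t.m, t.kind, t.coefficient / c1) for t in terms
            )
        self._jac_funcs: list[list] | None = None

    def _build(self) -> list[list]:
        """Lambdified d f_i / d x_j functions, rows ordered (AP, RL, SI)."""
        if self._jac_funcs is not None:
            return self._jac_funcs
        R = self.reference_radius_mm
        funcs: list[list] = []
        for ch in AXES:
            expr = sp.S.Zero
            for t in self.channels[ch]:
                expr += t.coefficient * R ** (1 - t.n) * solid_harmonic_expr(
                    t.n, t.m, t.kind
                )
            row = []
            for var in (_X, _Y, _Z):
                d = sp.expand(sp.diff(expr, var))
                row.append(sp.lambdify((_X, _Y, _Z), d, modules="numpy"))
            funcs.append(row)
        self._jac_funcs = funcs
        return funcs

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """L^M at physical points: (..., 3) mm -> (..., 3, 3) dimensionless.

        Row i is the gradient of channel i's normalized field, so
        ``jacobian(0) == I`` for a properly normalized model.
        """
        pts = np.asarray(points, float)
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
        funcs = self._build()
        out = np.empty(pts.shape[:-1] + (3, 3), float)
        for i in range(3):
            for j in range(3):
                out[..., i, j] = np.broadcast_to(funcs[i][j](x, y, z), x.shape)
        return out

    def max_degree(self) -> int:
        return max(t.n for terms in self.channels.values() for t in terms)


def default_generic_model() -> HarmonicCoilModel:
    """Synthetic generic horizontal-bore coil model.

    Vendor coil coefficients are proprietary; this stand-in carries the
    qualitative structure of a horizontal-bore whole-body gradient set:
    dominant degree-3 and small degree-5 terms per channel, with signs that
    make the achieved gradient roll off along the bore (SI) and pile up
    transversally (AP/RL) — the classic pattern of negative diffusion-
    weighting bias at superior offsets and positive bias in-plane.
    Amplitudes give roughly -20% direction-averaged b-value bias at a
    120 mm superior offset, a "substantial (>10%)" off-center bias.
    """
    return HarmonicCoilModel(
        {
            "AP": [
                HarmonicTerm(1, 1, "cos", 1.0),
                HarmonicTerm(3, 1, "cos", -0.08),
                HarmonicTerm(5, 1, "cos", 0.008),
            ],
            "RL": [
                HarmonicTerm(1, 1, "sin", 1.0),
                HarmonicTerm(3, 1, "sin", -0.08),
                HarmonicTerm(5, 1, "sin", 0.008),
            ],
            "SI": [
                HarmonicTerm(1, 0, "cos", 1.0),
                HarmonicTerm(3, 0, "cos", -0.2),
                HarmonicTerm(5, 0, "cos", 0.02),
            ],
        },
        reference_radius_mm=250.0,
    )


def write_coefficients(model: HarmonicCoilModel, path: str | Path) -> None:
    """Plain-text coefficient table: channel, n, m, cos|sin, coefficient."""
    lines = [
        f"# reference_radius_mm\t{model.reference_radius_mm:g}",
        f"# normalization\t{model.normalization}",
        "channel\tn\tm\tkind\tcoefficient",
    ]
    for ch in AXES:
        for t in model.channels[ch]:
            lines.append(f"{ch}\t{t.n}\t{t.m}\t{t.kind}\t{t.coefficient:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients(path: str | Path) -> HarmonicCoilModel:
    radius = 250.0
    normalization = "relative-linear"
    channels: dict[str, list[HarmonicTerm]] = {ch: [] for ch in AXES}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("\t")
            if key == "reference_radius_mm":
                radius = float(val)
            elif key == "normalization":
                normalization = val.strip()
            continue
        parts = line.split("\t")
        if parts[0] == "channel":  # header row
            continue
        ch, n, m, kind, coeff = parts[:5]
        if ch not in AXES:
            raise ValueError(f"unknown channel {ch!r} in {path}")
        channels[ch].append(HarmonicTerm(int(n), int(m), kind, float(coeff)))
    return HarmonicCoilModel(channels, radius, normalization)
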