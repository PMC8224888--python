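"""Analytic codon-model triplet potentials and boundary wall restraints.

These potentials are the synthetic stand-in for the all-atom energetics of
codon-anticodon base pairing: each base-pair distance d_i moves on a
one-dimensional profile with a "bound" well near 4.8 Å and an "unbound"
well near 8.0 Å on a soft quadratic background, and the three distances
are coupled through products of smooth "boundness" switch functions.

Per axis i (all energies in k_B*T, distances in Å):

    u_i(d) = k_bg/2 (d - c_bg)^2
             - A_b exp(-(d - m_b)^2 / 2 s_b^2)      bound well
             - A_u exp(-(d - m_u)^2 / 2 s_u^2)      unbound well
             - A_m exp(-(d - m_m)^2 / 2 s_m^2)      optional mid well

    U(d1,d2,d3) = sum_i u_i(d_i) + sum_{i<j} J_ij s(d_i) s(d_j)

with the logistic switch s(d) = 1 / (1 + exp((d - d_sw)/w_sw)), which is
~1 when a pair is bound and ~0 when unbound. Negative J_ij rewards joint
binding (cooperativity); positive J_ij penalizes it (anti-cooperativity).

Preset parameters were calibrated once against the dense-quadrature
free-energy oracle so that the binding-score ordering of the three codon
models is AUG_like < 0 < CUG_like <= GUG_like: the cognate codon binds,
the G:U first-position wobble codon is penalized, and the C:U codon sits
in between with extra shallow metastable minima. The presets target that
qualitative ordering only, not any all-atom magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .thermo import Thermo

__all__ = ["TripletPotential", "WallParams", "PRESET_NAMES"]


def _arr3(x) -> tuple[float, float, float]:
    a = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class TripletPotential:
    """Analytic potential U(d1, d2, d3) with exact gradient, in k_B*T."""

    name: str = "custom"
    k_bg: tuple = (0.0, 0.0, 0.0)
    c_bg: tuple = (6.5, 6.5, 6.5)
    a_bound: tuple = (0.0, 0.0, 0.0)
    m_bound: tuple = (4.8, 4.8, 4.8)
    s_bound: tuple = (0.5, 0.5, 0.5)
    a_unbound: tuple = (0.0, 0.0, 0.0)
    m_unbound: tuple = (8.0, 8.0, 8.0)
    s_unbound: tuple = (0.6, 0.6, 0.6)
    a_mid: tuple = (0.0, 0.0, 0.0)
    m_mid: tuple = (6.3, 6.3, 6.3)
    s_mid: tuple = (0.4, 0.4, 0.4)
    d_switch: float = 6.5
    w_switch: float = 0.4
    j12: float = 0.0
    j13: float = 0.0
    j23: float = 0.0

    def __post_init__(self) -> None:
        for f in ("k_bg", "c_bg", "a_bound", "m_bound", "s_bound",
                  "a_unbound", "m_unbound", "s_unbound",
                  "a_mid", "m_mid", "s_mid"):
            object.__setattr__(self, f, _arr3(getattr(self, f)))
        for f in ("s_bound", "s_unbound", "s_mid"):
            if any(s <= 0 for s in getattr(self, f)):
                raise ValueError(f"{f} must be positive")
        if self.w_switch <= 0:
            raise ValueError("w_switch must be positive")

    # -- evaluation ---------------------------------------------------

    def _axis_terms(self, d: np.ndarray):
        """Per-axis energy and derivative, vectorized over leading dims."""
        k = np.array(self.k_bg)
        c = np.array(self.c_bg)
        u = 0.5 * k * (d - c) ** 2
        du = k * (d - c)
        for amp, mu, sig in (
            (self.a_bound, self.m_bound, self.s_bound),
            (self.a_unbound, self.m_unbound, self.s_unbound),
            (self.a_mid, self.m_mid, self.s_mid),
        ):
            amp = np.array(amp)
            mu = np.array(mu)
            sig = np.array(sig)
            g = np.exp(-((d - mu) ** 2) / (2 * sig**2))
            u -= amp * g
            du += amp * g * (d - mu) / sig**2
        return u, du

    def _switch(self, d: np.ndarray):
        s = 1.0 / (1.0 + np.exp((d - self.d_switch) / self.w_switch))
        ds = -s * (1.0 - s) / self.w_switch
        return s, ds

    def energy(self, d) -> np.ndarray | float:
        """U at one point or an array of points with trailing dim 3."""
        d = np.asarray(d, dtype=float)
        scalar = d.ndim == 1
        u, _ = self._axis_terms(d)
        s, _ = self._switch(d)
        coup = (
            self.j12 * s[..., 0] * s[..., 1]
            + self.j13 * s[..., 0] * s[..., 2]
            + self.j23 * s[..., 1] * s[..., 2]
        )
        tot = u.sum(axis=-1) + coup
        return float(tot) if scalar else tot

    def gradient(self, d) -> np.ndarray:
        """Exact analytic dU/dd_i, same broadcasting as :meth:`energy`."""
        d = np.asarray(d, dtype=float)
        _, du = self._axis_terms(d)
        s, ds = self._switch(d)
        grad = du.copy()
        grad[..., 0] += ds[..., 0] * (self.j12 * s[..., 1] + self.j13 * s[..., 2])
        grad[..., 1] += ds[..., 1] * (self.j12 * s[..., 0] + self.j23 * s[..., 2])
        grad[..., 2] += ds[..., 2] * (self.j13 * s[..., 0] + self.j23 * s[..., 1])
        return grad

    def packed(self) -> np.ndarray:
        """Flat float64 parameter vector consumed by the numba kernels."""
        return np.concatenate(
            [
                self.k_bg, self.c_bg,
                self.a_bound, self.m_bound, self.s_bound,
                self.a_unbound, self.m_unbound, self.s_unbound,
                self.a_mid, self.m_mid, self.s_mid,
                [self.d_switch, self.w_switch, self.j12, self.j13, self.j23],
            ]
        ).astype(np.float64)

    # -- presets ------------------------------------------------------

    @classmethod
    def preset(cls, name: str, **overrides) -> "TripletPotential":
        try:
            pot = _PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
            ) from None
        return replace(pot, **overrides) if overrides else pot


def _build_presets() -> dict[str, TripletPotential]:
    base = dict(
        k_bg=0.6, c_bg=6.5,
        m_bound=4.8, s_bound=0.5,
        m_unbound=8.0, s_unbound=0.6,
    )
    presets = {
        "flat": TripletPotential(name="flat"),
        "harmonic": TripletPotential(name="harmonic", k_bg=2.0, c_bg=6.5),
        # 1-D double well (axis 1) with deep harmonic confinement of axes 2, 3;
        # barrier between the two wells is ~4 kT.
        "double_well_1d": TripletPotential(
            name="double_well_1d",
            k_bg=(0.1, 8.0, 8.0), c_bg=(6.4, 6.5, 6.5),
            a_bound=(4.5, 0.0, 0.0), m_bound=(4.8, 4.8, 4.8),
            s_bound=(0.55, 0.5, 0.5),
            a_unbound=(4.5, 0.0, 0.0), m_unbound=(8.0, 8.0, 8.0),
            s_unbound=(0.55, 0.6, 0.6),
        ),
        # Cognate codon: deep bound wells on all three pairs plus a mild
        # cooperative coupling; binding score strongly negative.
        "AUG_like": TripletPotential(
            name="AUG_like", **base,
            a_bound=3.5, a_unbound=2.0,
            j12=-0.3, j13=-0.3, j23=-0.3,
        ),
        # First-position G:U wobble: shallow bound well on d1 and an
        # anti-cooperative d1-d3 coupling (joint binding of the 1st and
        # 3rd pairs is rare); binding score positive.
        "GUG_like": TripletPotential(
            name="GUG_like", **base,
            a_bound=(0.8, 3.2, 3.2), a_unbound=(2.6, 2.1, 2.1),
            j12=-0.2, j13=2.6, j23=-0.2,
        ),
        # First-position C:U mismatch: intermediate bound well on d1 with
        # extra shallow mid-range minima (rugged, many metastable states);
        # binding score positive but below GUG_like.
        "CUG_like": TripletPotential(
            name="CUG_like", **base,
            a_bound=(1.3, 3.2, 3.2), a_unbound=(2.4, 2.1, 2.1),
            a_mid=(1.0, 0.0, 1.0), m_mid=6.3, s_mid=0.4,
            j12=-0.2, j13=1.8, j23=-0.2,
        ),
    }
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


@dataclass(frozen=True)
class WallParams:
    """Half-harmonic boundary restraints keeping each d_i in [low, high].

    The restraint engages only beyond the boundaries: inside [low, high]
    energy and force are exactly zero; beyond, U = spring/2 (d - edge)^2.
    The spring is stored in k_B*T/Å² (10 pN/Å at 310 K ≈ 0.2336 kT/Å²).
    """

    low: float = 3.0
    high: float = 10.0
    spring: float = 0.23364421019483617  # 10 pN/Å at 310 K

    def __post_init__(self) -> None:
        if self.spring <= 0:
            raise ValueError("spring must be positive")
        if not self.low < self.high:
            raise ValueError("low must be < high")

    @classmethod
    def from_pN_per_A(cls, spring_pN_per_A: float = 10.0,
                      thermo: Thermo | None = None,
                      low: float = 3.0, high: float = 10.0) -> "WallParams":
        thermo = thermo or Thermo()
        return cls(low=low, high=high,
                   spring=thermo.spring_pN_per_A_to_kT_per_A2(spring_pN_per_A))

    def energy_force(self, d):
        """Wall energy (kT) and restoring force (kT/Å) at one or many points."""
        d = np.asarray(d, dtype=float)
        below = np.minimum(d - self.low, 0.0)
        above = np.maximum(d - self.high, 0.0)
        x = below + above
        energy = 0.5 * self.spring * (x**2).sum(axis=-1)
        force = -self.spring * x
        if d.ndim == 1:
            return float(energy), force
        return energy, force
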