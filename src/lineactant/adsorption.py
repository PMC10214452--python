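"""Equilibrium line-adsorption model for interface-active tiles.

The model links the overall tile surface coverage ``sigma`` on a vesicle
to the occupied fraction ``phi`` of the L_d-L_o boundary and to the
line-partitioning coefficient ``K_p,int`` (interface-band density over
whole-surface average density).

Construction
------------
Tiles in the bulk membrane behave as a two-dimensional lattice gas with
coverage ``sigma_b`` and chemical potential ``mu_b = ln(sigma_b / (1 -
sigma_b))``.  Tiles adsorbed to the line form a one-dimensional Tonks gas
of hard rods of length ``ell`` (the long tile edge, which lies along the
boundary), confined to a band of width ``xi`` (the interface width), and
gain the line-binding free energy ``dG_line = n_dC * dG_dC`` -- moving
the dC anchor set from L_d into its preferred L_o phase, the sT set being
already optimal in bulk L_d.  Equating chemical potentials gives

    ln(phi/(1-phi)) + phi/(1-phi)
        = ln(sigma_b/(1-sigma_b)) - dG_line - ln(a_tile / (ell * xi))

where the last term is the standard-state mismatch between a 2D species
(one tile per area ``a_tile``) and a 1D species in the band; with
``dG_line = 0`` and no exclusion it makes the band density equal the bulk
density, i.e. K_p,int = 1 for inert tiles.  The overall coverage
constraint ``sigma = sigma_b * (1 - L*xi/A) + phi * L * a_tile / (ell * A)``
is solved self-consistently (line-bound tiles count toward the total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .calibration import AnchorThermo
from .tiles import AnchorLayout

__all__ = [
    "AdsorptionParams",
    "LineAdsorptionModel",
    "tile_line_binding_energy",
    "predict_phi",
    "predict_kpint",
    "fit_sigma",
]


@dataclass(frozen=True)
class AdsorptionParams:
    """Geometry of the vesicle and of the tile at the line.

    Defaults describe a Janus GUV of radius 10 um whose equator is the
    line-interface, decorated with ~90 x 60 nm rectangular tiles lying
    long-edge-on along the boundary.
    """

    xi_nm: float = 8.0            # interface width
    ell_nm: float = 90.0          # tile footprint length along the line
    tile_area_nm2: float = 90.0 * 60.0
    guv_radius_um: float = 10.0

    def __post_init__(self) -> None:
        if self.xi_nm <= 0 or self.ell_nm <= 0 or self.tile_area_nm2 <= 0:
            raise ValueError("xi, ell and tile area must be positive")
        if self.guv_radius_um <= 0:
            raise ValueError("GUV radius must be positive")

    @property
    def membrane_area_nm2(self) -> float:
        r = self.guv_radius_um * 1e3
        return 4.0 * math.pi * r * r

    @property
    def line_length_nm(self) -> float:
        return 2.0 * math.pi * self.guv_radius_um * 1e3

    @property
    def standard_state_shift(self) -> float:
        """ln(a_tile / (ell * xi)): 2D vs in-band 1D standard states (k_BT)."""
        return math.log(self.tile_area_nm2 / (self.ell_nm * self.xi_nm))


def tile_line_binding_energy(layout: AnchorLayout, thermo: AnchorThermo) -> float:
    """Line-binding free energy of one tile, k_BT.

    Relative to the tile's best bulk state (all anchors in L_d, where sT
    is already optimal and dC defines the zero of reference), straddling
    the line moves the dC set into L_o: ``dG_line = n_dC * dG_dC``.
    """
    n_dc = layout.n_anchors_per_set
    return n_dc * thermo.dg_dc


def _tonks_mu_excess(phi: float) -> float:
    """ln(phi/(1-phi)) + phi/(1-phi): 1D hard-rod chemical potential part."""
    return math.log(phi / (1.0 - phi)) + phi / (1.0 - phi)


class LineAdsorptionModel:
    """Predicts phi and K_p,int from coverage; inverts K_p,int to coverage."""

    def __init__(
        self,
        layout: AnchorLayout | str,
        params: AdsorptionParams | None = None,
        thermo: AnchorThermo | None = None,
    ):
        self.layout = (
            AnchorLayout.design(layout) if isinstance(layout, str) else layout
        )
        self.params = params or AdsorptionParams()
        self.thermo = thermo or AnchorThermo()
        self.dg_line = tile_line_binding_energy(self.layout, self.thermo)
        if self.dg_line > 0:
            raise ValueError(
                f"design {self.layout.name!r} has dG_line = {self.dg_line} > 0; "
                "not a line-actant"
            )

    # -- forward model ------------------------------------------------------

    def _phi_given_bulk(self, sigma_b: float) -> float:
        """Occupied line fraction in equilibrium with bulk coverage sigma_b."""
        if sigma_b <= 0.0:
            return 0.0
        rhs = (
            math.log(sigma_b / (1.0 - sigma_b))
            - self.dg_line
            - self.params.standard_state_shift
        )
        lo, hi = 1e-300, 1.0 - 1e-14
        if _tonks_mu_excess(hi) <= rhs:
            return hi
        return brentq(lambda p: _tonks_mu_excess(p) - rhs, lo, hi,
                      xtol=1e-15, rtol=8.9e-16, maxiter=200)

    def _bulk_from_total(self, sigma: float) -> float:
        """Bulk coverage consistent with overall coverage ``sigma``."""
        p = self.params
        band_frac = p.line_length_nm * p.xi_nm / p.membrane_area_nm2
        line_area = p.line_length_nm * p.tile_area_nm2 / (
            p.ell_nm * p.membrane_area_nm2
        )

        def total(sigma_b: float) -> float:
            return sigma_b * (1.0 - band_frac) + self._phi_given_bulk(sigma_b) * line_area

        if total(sigma) <= sigma:  # line term negligible
            return sigma
        return brentq(lambda sb: total(sb) - sigma, 0.0, sigma,
                      xtol=1e-16, rtol=8.9e-16, maxiter=200)

    def predict_phi(self, sigma: float) -> float:
        """Occupied line fraction phi at overall coverage sigma."""
        if not (0.0 <= sigma < 1.0):
            raise ValueError(f"sigma must be in [0, 1), got {sigma}")
        if sigma == 0.0:
            return 0.0
        return self._phi_given_bulk(self._bulk_from_total(sigma))

    def predict_kpint(self, sigma: float) -> float:
        """Line-partitioning coefficient at overall coverage sigma.

        K_p,int = (tile density in the xi-wide interface band) /
        (average tile density over the whole vesicle surface).
        """
        if sigma <= 0.0:
            raise ValueError("K_p,int is undefined at sigma = 0")
        if sigma >= 1.0:
            raise ValueError(f"sigma must be in (0, 1), got {sigma}")
        p = self.params
        sigma_b = self._bulk_from_total(sigma)
        phi = self._phi_given_bulk(sigma_b)
        rho_band = phi / (p.ell_nm * p.xi_nm)              # tiles / nm^2 in band
        rho_bulk = sigma_b / p.tile_area_nm2
        band_area = p.line_length_nm * p.xi_nm
        area = p.membrane_area_nm2
        rho_avg = (rho_bulk * (area - band_area) + rho_band * band_area) / area
        return rho_band / rho_avg

    # -- inverse ------------------------------------------------------------

    def attainable_kpint(self, sigma_max: float = 0.95) -> tuple[float, float]:
        """Range of K_p,int the model can produce (decreasing in sigma)."""
        hi = self.predict_kpint(1e-9)  # ~ exp(-dG_line), the sigma -> 0 limit
        lo = self.predict_kpint(sigma_max)
        return lo, hi

    def fit_sigma(
        self,
        kpint_measured: float,
        kpint_err: float | None = None,
        xi_rel_uncertainty: float = 0.0,
        sigma_max: float = 0.95,
    ) -> dict:
        """Coverage sigma reproducing a measured K_p,int.

        Returns a dict with the point estimate, the interval propagated
        from ``kpint_err`` (if given) and the sensitivity band from a
        relative uncertainty on the interface width xi (if given).
        """
        if kpint_measured <= 0:
            raise ValueError("measured K_p,int must be > 0")
        lo, hi = self.attainable_kpint(sigma_max)
        if not (lo < kpint_measured < hi):
            raise ValueError(
                f"K_p,int = {kpint_measured:.4g} outside the attainable interval "
                f"({lo:.4g}, {hi:.4g}) for design {self.layout.name!r}"
            )

        def invert(model: "LineAdsorptionModel", k: float) -> float:
            return brentq(
                lambda s: model.predict_kpint(s) - k, 1e-9, sigma_max,
                xtol=1e-14, rtol=8.9e-16, maxiter=200,
            )

        out = {"sigma": invert(self, kpint_measured)}
        if kpint_err is not None:
            bounds = []
            for k in (kpint_measured - kpint_err, kpint_measured + kpint_err):
                k = min(max(k, lo * (1 + 1e-9)), hi * (1 - 1e-9))
                bounds.append(invert(self, k))
            out["sigma_interval"] = (min(bounds), max(bounds))
        if xi_rel_uncertainty > 0:
            band = []
            for f in (1.0 - xi_rel_uncertainty, 1.0 + xi_rel_uncertainty):
                m = LineAdsorptionModel(
                    self.layout,
                    replace(self.params, xi_nm=self.params.xi_nm * f),
                    self.thermo,
                )
                lo_f, hi_f = m.attainable_kpint(sigma_max)
                k = min(max(kpint_measured, lo_f * (1 + 1e-9)), hi_f * (1 - 1e-9))
                band.append(invert(m, k))
            out["sigma_xi_band"] = (min(band), max(band))
        return out


# -- functional facade ------------------------------------------------------

def predict_phi(
    sigma: float,
    layout: AnchorLayout | str,
    params: AdsorptionParams | None = None,
    thermo: AnchorThermo | None = None,
) -> float:
    return LineAdsorptionModel(layout, params, thermo).predict_phi(sigma)


def predict_kpint(
    sigma: float,
    layout: AnchorLayout | str,
    params: AdsorptionParams | None = None,
    thermo: AnchorThermo | None = None,
) -> float:
    return LineAdsorptionModel(layout, params, thermo).predict_kpint(sigma)


def fit_sigma(
    kpint_measured: float,
    layout: AnchorLayout | str,
    params: AdsorptionParams | None = None,
    thermo: AnchorThermo | None = None,
    **kwargs,
) -> dict:
    return LineAdsorptionModel(layout, params, thermo).fit_sigma(
        kpint_measured, **kwargs
    )
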