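"""Gradient-wise genetic parameters from fitted variance components.

With first-order Legendre covariates phi(t) = (1, t), a 2x2 coefficient
(co)variance block yields the genetic variance at gradient t as the
quadratic form phi' B phi.  Heritabilities divide the direct (or
maternal) genetic variance at t by the total phenotypic variance at t,
with the direct-maternal covariance entering the denominator once.
Correlations between gradients, between traits, and between intercept
and slope follow as the usual normalised (co)variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TRAITS, VarianceComponents


class UndefinedParameter(ValueError):
    """A requested ratio has a non-positive denominator."""


def phi(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.stack([np.ones_like(t), t], axis=-1)


def variance_at_gradient(block: np.ndarray, t: float) -> float:
    """phi(t)' B phi(t) = b00 + 2 t b01 + t^2 b11."""
    b = np.asarray(block, dtype=float)
    return float(b[0, 0] + 2.0 * t * b[0, 1] + t * t * b[1, 1])


def covariance_between_gradients(block: np.ndarray, a: float, b: float) -> float:
    m = np.asarray(block, dtype=float)
    return float(phi(a) @ m @ phi(b))


def heritability_at_gradient(var_direct: float, var_maternal: float,
                             cov_dm: float, var_mpe: float, var_cg: float,
                             var_res: float) -> tuple[float, float]:
    """(h2_direct, h2_maternal) with the printed denominator
    sigma_u + sigma_v + sigma_uv + sigma_mpe + sigma_cg + sigma_e."""
    denom = var_direct + var_maternal + cov_dm + var_mpe + var_cg + var_res
    if denom <= 0:
        raise UndefinedParameter(
            f"non-positive phenotypic variance {denom:.4g} at this gradient")
    return var_direct / denom, var_maternal / denom


def genetic_correlation_between_gradients(block: np.ndarray, a: float, b: float) -> float:
    va = variance_at_gradient(block, a)
    vb = variance_at_gradient(block, b)
    if va <= 0 or vb <= 0:
        raise UndefinedParameter("zero genetic variance at a queried gradient")
    return covariance_between_gradients(block, a, b) / np.sqrt(va * vb)


def genetic_correlation_between_traits(cross_block: np.ndarray,
                                       block_bw: np.ndarray,
                                       block_ww: np.ndarray, t: float) -> float:
    v1 = variance_at_gradient(block_bw, t)
    v2 = variance_at_gradient(block_ww, t)
    if v1 <= 0 or v2 <= 0:
        raise UndefinedParameter("zero trait variance at the queried gradient")
    return float(phi(t) @ np.asarray(cross_block, dtype=float) @ phi(t)) / np.sqrt(v1 * v2)


def intercept_slope_stats(block: np.ndarray) -> tuple[float, float]:
    """(r between intercept and slope, slope-to-intercept variance ratio)."""
    b = np.asarray(block, dtype=float)
    if b[0, 0] <= 0 or b[1, 1] <= 0:
        raise UndefinedParameter("zero intercept or slope variance")
    return float(b[0, 1] / np.sqrt(b[0, 0] * b[1, 1])), float(b[1, 1] / b[0, 0])


@dataclass
class GradientGrid:
    """Scaled gradient points plus their raw-EC counterparts."""

    ec_name: str
    points: np.ndarray
    ec_scale: object = None  # ECScale, optional

    @classmethod
    def default(cls, ec_name: str, ec_scale=None, n: int = 11) -> "GradientGrid":
        return cls(ec_name, np.linspace(-1.0, 1.0, n), ec_scale)

    @property
    def raw(self) -> np.ndarray:
        if self.ec_scale is None:
            return self.points
        return self.ec_scale.unscale(self.points)


def gradient_parameter_table(vc: VarianceComponents, grid: GradientGrid) -> pd.DataFrame:
    """Per-gradient variances, heritabilities and trait correlations."""
    rows = []
    for t, raw in zip(grid.points, grid.raw):
        var_cg = {tr: vc.cg[i, i] for i, tr in enumerate(TRAITS)}
        var_mpe = {tr: vc.pm[i, i] for i, tr in enumerate(TRAITS)}
        var_res = {tr: vc.residual[i, i] for i, tr in enumerate(TRAITS)}
        for tr in TRAITS:
            vd = variance_at_gradient(vc.direct_block(tr), t)
            vm = variance_at_gradient(vc.maternal_block(tr), t)
            cdm = variance_at_gradient(vc.direct_maternal_block(tr), t)
            h2d, h2m = heritability_at_gradient(vd, vm, cdm, var_mpe[tr],
                                                var_cg[tr], var_res[tr])
            rows.append({"ec_name": grid.ec_name, "gradient": t, "ec_raw": raw,
                         "trait": tr, "var_direct": vd, "var_maternal": vm,
                         "cov_direct_maternal": cdm, "var_mpe": var_mpe[tr],
                         "var_cg": var_cg[tr], "var_residual": var_res[tr],
                         "h2_direct": h2d, "h2_maternal": h2m})
    out = pd.DataFrame(rows)
    r_bw_ww_d = [genetic_correlation_between_traits(
        vc.direct_cross_trait(), vc.direct_block("bw"), vc.direct_block("ww"), t)
        for t in grid.points]
    r_bw_ww_m = [genetic_correlation_between_traits(
        vc.maternal_cross_trait(), vc.maternal_block("bw"), vc.maternal_block("ww"), t)
        for t in grid.points]
    cross = pd.DataFrame({"gradient": grid.points,
                          "r_bw_ww_direct": r_bw_ww_d,
                          "r_bw_ww_maternal": r_bw_ww_m})
    return out.merge(cross, on="gradient")


def rec_matrix(block: np.ndarray, grid: GradientGrid) -> pd.DataFrame:
    """Correlation matrix of genetic effects between all gradient pairs."""
    pts = grid.points
    m = np.empty((len(pts), len(pts)))
    for i, a in enumerate(pts):
        for j, b in enumerate(pts):
            m[i, j] = genetic_correlation_between_gradients(block, a, b)
    return pd.DataFrame(m, index=np.round(pts, 3), columns=np.round(pts, 3))


def intercept_slope_table(vc: VarianceComponents, ec_name: str) -> pd.DataFrame:
    """Intercept-slope correlation and variance ratio per trait, for the
    direct and maternal genetic effects."""
    rows = []
    for tr in TRAITS:
        for effect, block in (("direct", vc.direct_block(tr)),
                              ("maternal", vc.maternal_block(tr))):
            r01, ratio = intercept_slope_stats(block)
            rows.append({"ec_name": ec_name, "trait": tr, "effect": effect,
                         "r_mu0_mu1": r01, "slope_to_intercept_ratio": ratio})
    return pd.DataFrame(rows)
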