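"""Sex-chromosome dosage arithmetic and component-fraction estimation.

A plasma sample mixing male and female genomes has sex-chromosome copy
numbers CN_X = 2 - m and CN_Y = m, where m is the fraction of DNA from male
genomes (each male genome trades one X for one Y against the two-X female
baseline). Normalizing so the shares sum to one gives
x_share = (2 - m)/2 and y_share = m/2, hence m = 2 * y_share. A sample with
X:Y share 0.59:0.41 therefore carries m = 0.82 male DNA.

With the placental fraction f known (e.g. from a read-distribution
predictor) and the fetal sex, the three component fractions follow by
subtraction: for a male fetus (w_A, w_B, w_C) = (m - f, 1 - m, f) where A is
the donor-hematopoietic, B the residual-maternal and C the placental
component. ``estimate_fractions_ls`` offers a self-contained alternative
that regresses plasma allele fractions on candidate component genotypes over
the SNP panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "XYDosage",
    "SexCall",
    "ComponentFractions",
    "FractionFit",
    "xy_dosage",
    "male_fraction_from_xy",
    "xy_shares_from_male_fraction",
    "infer_sex",
    "component_fractions",
    "estimate_fractions_ls",
]

_TOL = 1e-9


@dataclass(frozen=True)
class XYDosage:
    """Estimated X/Y copy numbers and their normalized shares."""

    cn_x: float
    cn_y: float
    x_share: float
    y_share: float

    def __post_init__(self) -> None:
        if self.cn_x < 0 or self.cn_y < 0:
            raise ValueError("copy numbers must be nonnegative")
        if abs(self.x_share + self.y_share - 1.0) > _TOL:
            raise ValueError("x_share + y_share must equal 1")

    @classmethod
    def from_shares(cls, x_share: float, y_share: float, total_cn: float = 2.0) -> "XYDosage":
        """Dosage from normalized shares under a fixed total copy number."""
        return cls(total_cn * x_share, total_cn * y_share, x_share, y_share)


@dataclass(frozen=True)
class SexCall:
    """Sex inferred from dosage: female, male, or a mixed-sex DNA sample."""

    label: str
    male_fraction: float


@dataclass(frozen=True)
class ComponentFractions:
    """Simplex weights of the three cfDNA sources with their karyotypes.

    A: donor-hematopoietic, B: residual-maternal, C: placental.
    """

    w_a: float
    w_b: float
    w_c: float
    sex_a: str = "46,XY"
    sex_b: str = "46,XX"
    sex_c: str = "46,XY"

    def __post_init__(self) -> None:
        w = (self.w_a, self.w_b, self.w_c)
        if any(x < -_TOL or x > 1 + _TOL for x in w):
            raise ValueError(f"component fractions must lie in [0,1], got {w}")
        if abs(sum(w) - 1.0) > _TOL:
            raise ValueError(f"component fractions must sum to 1, got {sum(w)}")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_a, self.w_b, self.w_c)

    @property
    def male_fraction(self) -> float:
        """Total weight of 46,XY components (forward map back to m)."""
        return sum(
            w for w, s in zip(self.weights, (self.sex_a, self.sex_b, self.sex_c)) if s == "46,XY"
        )


def xy_dosage(
    zfx_depths: pd.Series | np.ndarray,
    zfy_depths: pd.Series | np.ndarray,
    female_ref_depth: float,
) -> XYDosage:
    """Copy-number dosage from ZFX/ZFY region depths.

    ``female_ref_depth`` is the mean ZFX depth of a known 46,XX calibration
    sample, for which CN_X = 2; depths scale linearly with copy number, so
    cn = 2 * mean(depth) / female_ref_depth for each of X and Y.
    """
    zfx = np.asarray(zfx_depths, dtype=float)
    zfy = np.asarray(zfy_depths, dtype=float)
    if zfx.size == 0 or zfy.size == 0:
        raise ValueError("need at least one ZFX and one ZFY region depth")
    if female_ref_depth <= 0:
        raise ValueError("female_ref_depth must be positive")
    cn_x = 2.0 * zfx.mean() / female_ref_depth
    cn_y = 2.0 * zfy.mean() / female_ref_depth
    total = cn_x + cn_y
    if total == 0:
        raise ValueError("all ZFX and ZFY depths are zero")
    return XYDosage(cn_x, cn_y, cn_x / total, cn_y / total)


def male_fraction_from_xy(d: XYDosage) -> float:
    """Male-DNA fraction m = 2 * y_share under CN_X = 2 - m, CN_Y = m."""
    m = 2.0 * d.y_share
    if m < 0.0 or m > 1.0:
        logger.warning("male fraction %.4f outside [0,1]; clipping", m)
        m = min(max(m, 0.0), 1.0)
    return m


def xy_shares_from_male_fraction(m: float) -> tuple[float, float]:
    """Inverse model: normalized (x_share, y_share) of a sample with male fraction m."""
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"male fraction must lie in [0,1], got {m}")
    return ((2.0 - m) / 2.0, m / 2.0)


def infer_sex(d: XYDosage, t_low: float = 0.05, t_high: float = 0.95) -> SexCall:
    """Classify a sample as female (m < t_low), male (m > t_high), or mixed."""
    m = male_fraction_from_xy(d)
    if m < t_low:
        return SexCall("female", m)
    if m > t_high:
        return SexCall("male", m)
    return SexCall("mixed", m)


def component_fractions(m: float, f: float, fetal_sex: str) -> ComponentFractions:
    """Three-source fractions from total male fraction m and placental fraction f.

    Male fetus: the placenta contributes to the male pool, so
    (w_A, w_B, w_C) = (m - f, 1 - m, f). Female fetus: the placenta is part of
    the female pool, so (w_A, w_B, w_C) = (m, 1 - m - f, f). Raises when the
    stated fetal sex contradicts the dosage (f > m for a male fetus, or
    m + f > 1 for a female one).
    """
    if not (0.0 <= m <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError(f"m and f must lie in [0,1], got m={m}, f={f}")
    if fetal_sex in ("XY", "46,XY"):
        if f > m + _TOL:
            raise ValueError(
                f"placental fraction f={f} exceeds male-DNA fraction m={m}: "
                "inconsistent with a 46,XY fetus"
            )
        return ComponentFractions(m - f, 1.0 - m, f, sex_c="46,XY")
    if fetal_sex in ("XX", "46,XX"):
        if m + f > 1.0 + _TOL:
            raise ValueError(
                f"male fraction m={m} plus placental fraction f={f} exceeds 1: "
                "inconsistent with a 46,XX fetus"
            )
        return ComponentFractions(m, 1.0 - m - f, f, sex_c="46,XX")
    raise ValueError(f"fetal_sex must be 'XX' or 'XY', got {fetal_sex!r}")


@dataclass(frozen=True)
class FractionFit:
    """Result of least-squares fraction estimation on the simplex."""

    weights: np.ndarray
    objective: float
    degenerate: bool


def estimate_fractions_ls(
    plasma_af: pd.Series | np.ndarray,
    genotypes: pd.DataFrame | np.ndarray,
) -> FractionFit:
    """Estimate mixture weights by least squares on plasma allele fractions.

    Minimizes sum_l (af_l - sum_k w_k g_lk / 2)^2 over the k-simplex, where
    ``genotypes`` is a loci x k matrix of candidate component genotypes in
    {0,1,2}. Solved by non-negative least squares followed by normalization
    onto the simplex; a rank-deficient design (components indistinguishable
    on the panel) is flagged degenerate with a warning.
    """
    af = np.asarray(plasma_af, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != af.shape[0]:
        raise ValueError("plasma_af and genotypes must cover the same loci")
    if not np.isin(G[~np.isnan(G)], (0.0, 1.0, 2.0)).all():
        raise ValueError("candidate genotypes must be coded 0/1/2")
    keep = ~(np.isnan(af) | np.isnan(G).any(axis=1))
    af, G = af[keep], G[keep]
    k = G.shape[1]
    informative = (G != G[:, [0]]).any(axis=1).sum() if k > 1 else af.size
    if af.size < k or (k > 1 and informative < k):
        raise ValueError(
            f"need at least {k} informative loci to separate {k} components"
        )
    A = G / 2.0
    degenerate = np.linalg.matrix_rank(A) < k
    if degenerate:
        warnings.warn(
            "candidate components are indistinguishable on this panel "
            "(rank-deficient genotype matrix); weights are not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    w, _ = nnls(A, af)
    total = w.sum()
    if total == 0:
        raise ValueError("non-negative least squares returned the zero vector")
    w = w / total
    resid = af - A @ w
    return FractionFit(weights=w, objective=float(resid @ resid), degenerate=degenerate)
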