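"""Pairwise relatedness: the match-ratio statistic, classification, IBS/MDS.

The match-ratio statistic (mrs) of a sample pair is the number of identical
genotypes among shared loci divided by the number of common non-reference
loci — loci called in both samples where at least one genotype carries the
alt allele. Hom-ref/hom-ref agreements are excluded from both numerator and
denominator, so unrelated pairs do not inflate the ratio through the common
reference background. Duplicates score near 1, first-degree relatives in
between, unrelated pairs lowest; classification thresholds are calibrated on
simulated pairs rather than fixed a priori.

For visualization, pairwise genetic distance is 1 minus the mean
identity-by-state allele sharing (IBS = 2 - |g_a - g_b|, halved), embedded by
classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .panel import Panel
from .simulate import simulate_pedigree

__all__ = [
    "RelatednessRecord",
    "Thresholds",
    "mrs",
    "classify",
    "calibrate_thresholds",
    "ibs_distance",
    "classical_mds",
]

CLASSES = ("MZD", "1st", "NR")


@dataclass(frozen=True)
class RelatednessRecord:
    """mrs of one sample pair, with bookkeeping and (optional) class label."""

    sample_a: str
    sample_b: str
    mrs: float
    n_shared: int
    n_denominator: int
    relationship: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mrs <= 1.0):
            raise ValueError(f"mrs must lie in [0,1], got {self.mrs}")
        if self.n_denominator > self.n_shared:
            raise ValueError("denominator cannot exceed the shared-locus count")


def _as_float(gt) -> np.ndarray:
    """Genotype row to float array with NaN for missing."""
    if isinstance(gt, pd.Series):
        return gt.to_numpy(dtype="float64", na_value=np.nan)
    return np.asarray(gt, dtype=float)


def mrs(gt_a, gt_b, mode: str = "any_nonref") -> RelatednessRecord:
    """Match-ratio statistic between two genotype rows on the same panel.

    ``mode`` selects the denominator: ``"any_nonref"`` (default) counts
    shared loci where at least one genotype is non-reference;
    ``"both_nonref"`` requires both, for sensitivity analysis. Raises when
    the denominator is empty (degenerate pair).
    """
    name_a = gt_a.name if isinstance(gt_a, pd.Series) and gt_a.name else "a"
    name_b = gt_b.name if isinstance(gt_b, pd.Series) and gt_b.name else "b"
    if isinstance(gt_a, pd.Series) and isinstance(gt_b, pd.Series):
        if not gt_a.index.equals(gt_b.index):
            common = gt_a.index.intersection(gt_b.index)
            gt_a, gt_b = gt_a[common], gt_b[common]
    a, b = _as_float(gt_a), _as_float(gt_b)
    if a.shape != b.shape:
        raise ValueError("genotype rows must cover the same loci")
    called = ~(np.isnan(a) | np.isnan(b))
    if mode == "any_nonref":
        denom = called & ((a > 0) | (b > 0))
    elif mode == "both_nonref":
        denom = called & (a > 0) & (b > 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_den = int(denom.sum())
    if n_den == 0:
        raise ValueError(
            f"mrs undefined for pair ({name_a}, {name_b}): no common non-reference loci"
        )
    n_match = int((denom & (a == b)).sum())
    return RelatednessRecord(
        sample_a=str(name_a),
        sample_b=str(name_b),
        mrs=n_match / n_den,
        n_shared=int(called.sum()),
        n_denominator=n_den,
    )


@dataclass(frozen=True)
class Thresholds:
    """mrs classification thresholds with the calibration class statistics."""

    t_mzd: float
    t_first: float
    class_means: dict | None = None
    class_sds: dict | None = None

    def __post_init__(self) -> None:
        if self.t_mzd <= self.t_first:
            raise ValueError("t_mzd must exceed t_first")


def classify(
    record: RelatednessRecord,
    thresholds: Thresholds,
    margin: float = 0.0,
) -> RelatednessRecord:
    """Attach a relationship class: MZD / 1st / NR, by mrs thresholds.

    Boundaries are closed from below (mrs == t_first classifies as 1st).
    A record within ``margin`` of either threshold is labeled ambiguous.
    """
    t_mzd, t_first = thresholds.t_mzd, thresholds.t_first
    v = record.mrs
    if margin > 0 and (abs(v - t_mzd) < margin or abs(v - t_first) < margin):
        label = "ambiguous"
    elif v >= t_mzd:
        label = "MZD"
    elif v >= t_first:
        label = "1st"
    else:
        label = "NR"
    return replace(record, relationship=label)


def _apply_genotype_error(g: np.ndarray, error: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each genotype to one of the other two states with probability ``error``."""
    if error == 0:
        return g
    flip = rng.random(g.shape) < error
    shift = rng.integers(1, 3, size=g.shape)
    return np.where(flip, (g + shift) % 3, g)


def calibrate_thresholds(
    panel: Panel,
    n_reps: int = 100,
    seed: int = 0,
    genotype_error: float = 0.01,
    confusion_tol: float = 0.05,
) -> Thresholds:
    """Calibrate mrs thresholds on simulated duplicate/sibling/unrelated pairs.

    For each replicate, a pedigree over the panel provides a duplicate pair
    (the same genome observed twice with independent per-locus genotyping
    error), two first-degree pairs (full siblings and parent-child, pooled —
    both are first-degree but sit at different mrs levels) and an unrelated
    pair; each threshold is the midpoint between adjacent class means. Warns
    when the simulated classes overlap beyond ``confusion_tol`` at those
    thresholds.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {c: [] for c in CLASSES}
    for rep in range(n_reps):
        ped = simulate_pedigree(panel, seed=int(rng.integers(0, 2**31 - 1)))
        g = ped.genotypes
        mom = g.loc["mother"].to_numpy()
        pairs = [
            (
                "MZD",
                _apply_genotype_error(mom, genotype_error, rng),
                _apply_genotype_error(mom, genotype_error, rng),
            ),
            ("1st", mom, g.loc["bm_donor"].to_numpy()),
            ("1st", g.loc["father"].to_numpy(), g.loc["fetus"].to_numpy()),
            ("NR", mom, g.loc["father"].to_numpy()),
        ]
        for cls, a, b in pairs:
            try:
                values[cls].append(mrs(a, b).mrs)
            except ValueError:
                continue  # all-reference pair on a tiny panel: mrs undefined
    short = [c for c in CLASSES if len(values[c]) < 2]
    if short:
        warnings.warn(
            f"panel cannot separate relationship classes: too few defined mrs "
            f"values for {short}", RuntimeWarning, stacklevel=2,
        )
        raise ValueError(f"calibration failed: classes {short} have <2 usable pairs")
    arr = {c: np.asarray(v) for c, v in values.items()}
    means = {c: float(a.mean()) for c, a in arr.items()}
    sds = {c: float(a.std(ddof=1)) for c, a in arr.items()}
    if not (means["MZD"] > means["1st"] > means["NR"]):
        warnings.warn(
            f"calibration class means are not ordered: {means}", RuntimeWarning, stacklevel=2
        )
    t_mzd = (means["MZD"] + means["1st"]) / 2.0
    t_first = (means["1st"] + means["NR"]) / 2.0
    confusion = np.mean(
        np.concatenate(
            [
                arr["MZD"] < t_mzd,
                (arr["1st"] >= t_mzd) | (arr["1st"] < t_first),
                arr["NR"] >= t_first,
            ]
        )
    )
    if confusion > confusion_tol:
        warnings.warn(
            f"class distributions overlap: confusion {confusion:.3f} exceeds "
            f"tolerance {confusion_tol}; the panel may be too small to separate classes",
            RuntimeWarning,
            stacklevel=2,
        )
    return Thresholds(t_mzd=t_mzd, t_first=t_first, class_means=means, class_sds=sds)


def ibs_distance(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise genetic distance 1 - mean(IBS)/2 over shared called loci.

    ``genotypes`` is a samples x loci matrix with missing allowed; IBS at a
    locus is 2 - |g_a - g_b| (shared allele count). Returns a symmetric
    zero-diagonal DataFrame indexed by sample.
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = genotypes.to_numpy(dtype="float64", na_value=np.nan)
    samples = list(genotypes.index)
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if not ok.any():
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no called loci"
                )
            ibs = 2.0 - np.abs(X[i, ok] - X[j, ok])
            D[i, j] = D[j, i] = 1.0 - ibs.sum() / (2.0 * ok.sum())
    return pd.DataFrame(D, index=samples, columns=samples)


def classical_mds(distances: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-k coordinates scaled by sqrt(eigenvalue). Negative eigenvalues
    (non-Euclidean distances) are truncated with a warning.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals[:k] < -1e-10).any() or (vals < -1e-8 * max(vals.max(), 1.0)).any():
        warnings.warn(
            "distance matrix is non-Euclidean; negative eigenvalues truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    top = np.clip(vals[:k], 0.0, None)
    coords = vecs[:, :k] * np.sqrt(top)
    labels = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(n))
    return pd.DataFrame(coords, index=labels, columns=[f"dim{i + 1}" for i in range(k)])
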