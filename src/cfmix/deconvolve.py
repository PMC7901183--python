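"""Maximum-likelihood joint genotyping of cfDNA mixtures.

A plasma sample mixing k genomes at known fractions w_1..w_k has, at a
biallelic locus, expected alt-read fraction q = sum_k w_k g_k / 2 for the
component genotypes g_k in {0,1,2}. With a per-read substitution error eps
the observed alt fraction is p = q(1-eps) + (1-q)eps and the alt count is
Binomial(n, p). Enumerating all 3^k genotype configurations with a
Hardy-Weinberg prior per component yields a posterior over configurations;
the maximum a posteriori configuration is the joint call.

k=2 is the classical two-genome (pseudo-tetraploid) setting of fetal +
maternal plasma genotyping; k=3 extends it to a third genome (pseudo-
hexaploid), e.g. a bone-marrow-donor component. k=1 degenerates to plain
diploid genotyping and is exposed as :func:`call_diploid`.

Components are modeled as independent Hardy-Weinberg draws even when they
are in fact related — relatedness is exactly what the downstream match-ratio
analysis measures, so encoding it in the prior would be circular. A flat
prior is available for sensitivity checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureDeconvolution",
    "MAFSpectrum",
    "deconvolve",
    "call_diploid",
    "split_major_minor",
    "component_calls",
    "maf_spectrum",
]

_TIE_TOL = 1e-12
DEFAULT_POSTERIOR_FLOOR = 0.9


def _configs(k: int) -> np.ndarray:
    """All 3^k genotype configurations in lexicographic order, shape (3^k, k)."""
    return np.array(list(itertools.product((0, 1, 2), repeat=k)), dtype=np.int64)


@dataclass(frozen=True)
class MixtureDeconvolution:
    """Per-locus posterior over joint genotype configurations.

    Attributes
    ----------
    region_ids : list of locus identifiers, aligned with the row axis.
    weights : the k mixture fractions used.
    configs : (3^k, k) array of genotype configurations, lexicographic.
    posterior : (L, 3^k) posterior probabilities; rows sum to 1; NaN for
        loci with zero coverage.
    log_likelihood : (L, 3^k) binomial log-likelihood per configuration.
    map_index : (L,) index of the MAP configuration, -1 for missing loci.
    """

    region_ids: list[str]
    weights: np.ndarray
    configs: np.ndarray
    posterior: np.ndarray
    log_likelihood: np.ndarray
    map_index: np.ndarray

    @property
    def k(self) -> int:
        return self.configs.shape[1]

    @property
    def map_posterior(self) -> np.ndarray:
        """Posterior mass of the MAP configuration per locus (NaN if missing)."""
        out = np.full(len(self.region_ids), np.nan)
        ok = self.map_index >= 0
        out[ok] = self.posterior[np.flatnonzero(ok), self.map_index[ok]]
        return out

    @property
    def map_configs(self) -> np.ndarray:
        """(L, k) MAP genotype per component; -1 rows mark missing loci."""
        out = np.full((len(self.region_ids), self.k), -1, dtype=np.int64)
        ok = self.map_index >= 0
        out[ok] = self.configs[self.map_index[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per locus with MAP call and its posterior."""
        cfg = self.map_configs
        data = {"region_id": self.region_ids}
        for j in range(self.k):
            data[f"g{j + 1}"] = cfg[:, j]
        data["posterior"] = self.map_posterior
        q = cfg @ self.weights / 2.0
        q[cfg[:, 0] < 0] = np.nan
        data["expected_alt_fraction"] = q
        return pd.DataFrame(data).set_index("region_id")


def _hwe_log_priors(af: np.ndarray) -> np.ndarray:
    """(L, 3) log Hardy-Weinberg genotype probabilities per locus."""
    with np.errstate(divide="ignore"):
        return np.log(
            np.column_stack([(1 - af) ** 2, 2 * af * (1 - af), af**2])
        )


def deconvolve(
    depths: pd.DataFrame,
    weights,
    pop_af: pd.Series,
    eps: float = 0.005,
    flat_prior: bool = False,
) -> MixtureDeconvolution:
    """Joint ML genotyping of a k-component mixture at every panel locus.

    Parameters
    ----------
    depths : DataFrame indexed by region_id with ``ref_count``/``alt_count``.
    weights : k mixture fractions on the simplex, each strictly positive.
    pop_af : population alt-allele frequency per region_id (HWE prior).
    eps : per-read substitution error in [0, 0.5).
    flat_prior : use a uniform prior over configurations instead of HWE.

    Loci with zero coverage are emitted as missing (``map_index`` -1).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] not in (1, 2, 3):
        raise ValueError("deconvolve supports 1, 2 or 3 mixture components")
    if (w <= 0).any():
        zero = np.flatnonzero(w <= 0).tolist()
        raise ValueError(
            f"component(s) {zero} have non-positive weight; drop them from the "
            "model — a zero-weight genotype is unidentifiable"
        )
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    if not (0.0 <= eps < 0.5):
        raise ValueError(f"eps must lie in [0, 0.5), got {eps}")

    af = pop_af.reindex(depths.index)
    if af.isna().any():
        missing = af.index[af.isna()][:5].tolist()
        raise ValueError(f"no population allele frequency for loci {missing}")
    af = af.to_numpy(dtype=float)
    alt = depths["alt_count"].to_numpy(dtype=np.int64)
    ref = depths["ref_count"].to_numpy(dtype=np.int64)
    if (alt < 0).any() or (ref < 0).any():
        raise ValueError("read counts must be nonnegative")
    n = ref + alt

    cfg = _configs(w.shape[0])
    q = cfg @ w / 2.0
    p = q * (1.0 - eps) + (1.0 - q) * eps
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = binom.logpmf(alt[:, None], n[:, None], p[None, :])
    if flat_prior:
        lprior = np.zeros((af.shape[0], cfg.shape[0]))
    else:
        hwe = _hwe_log_priors(af)  # (L, 3)
        lprior = hwe[:, cfg].sum(axis=2)  # (L, 3^k)
    lpost = ll + lprior
    norm = logsumexp(lpost, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        post = np.exp(lpost - norm)

    # MAP with tie-breaks: among posterior ties, prefer the higher prior,
    # then the lexicographically smallest configuration (= first index).
    best = np.nanmax(lpost, axis=1, keepdims=True)
    tied = lpost >= best - _TIE_TOL
    n_tied = tied.sum(axis=1)
    score = np.where(tied, lprior, -np.inf)
    map_index = np.argmax(score, axis=1).astype(np.int64)
    if (n_tied > 1).any():
        logger.debug("MAP ties at %d loci; broken by prior then lexicographic order",
                     int((n_tied > 1).sum()))
    missing = n == 0
    map_index[missing] = -1
    post[missing] = np.nan
    return MixtureDeconvolution(
        region_ids=list(depths.index),
        weights=w,
        configs=cfg,
        posterior=post,
        log_likelihood=ll,
        map_index=map_index,
    )


def call_diploid(
    depths: pd.DataFrame,
    pop_af: pd.Series,
    eps: float = 0.005,
    posterior_floor: float = DEFAULT_POSTERIOR_FLOOR,
) -> pd.Series:
    """Diploid genotype calls (the k=1 degenerate mixture model).

    Returns an Int8 Series of 0/1/2 calls indexed by region_id, with loci
    whose MAP posterior falls below ``posterior_floor`` (or with zero
    coverage) set to missing.
    """
    res = deconvolve(depths, [1.0], pop_af, eps=eps)
    g = res.map_configs[:, 0].astype(object)
    conf = res.map_posterior
    g[(res.map_index < 0) | (conf < posterior_floor)] = pd.NA
    return pd.Series(g, index=res.region_ids, dtype="Int8", name="genotype")


def split_major_minor(
    result: MixtureDeconvolution,
    sample_id: str,
    posterior_floor: float = DEFAULT_POSTERIOR_FLOOR,
) -> pd.DataFrame:
    """Emit the two components of a k=2 deconvolution as genotype rows.

    The higher-weight component becomes ``<sample_id>major``, the other
    ``<sample_id>minor``. Loci whose MAP posterior falls below
    ``posterior_floor`` are set to missing in both rows.
    """
    if result.k != 2:
        raise ValueError("major/minor split requires a two-component deconvolution")
    w1, w2 = result.weights
    if w1 == w2:
        raise ValueError("components have equal weight; major/minor labels undefined")
    order = [0, 1] if w1 > w2 else [1, 0]
    cfg = result.map_configs
    conf = result.map_posterior
    bad = (result.map_index < 0) | ~(conf >= posterior_floor)
    rows = {}
    for label, j in zip(("major", "minor"), order):
        g = cfg[:, j].astype(object)
        g[bad] = pd.NA
        rows[f"{sample_id}{label}"] = g
    return pd.DataFrame(rows, index=result.region_ids).T.astype("Int8")


def component_calls(
    result: MixtureDeconvolution,
    sample_id: str,
    posterior_floor: float = DEFAULT_POSTERIOR_FLOOR,
) -> pd.DataFrame:
    """One genotype row per mixture component from the MAP configurations.

    Rows are labeled ``<sample_id>.c1`` .. ``<sample_id>.ck`` in component
    order; loci whose MAP posterior falls below ``posterior_floor`` are
    missing in every row.
    """
    cfg = result.map_configs
    conf = result.map_posterior
    bad = (result.map_index < 0) | ~(conf >= posterior_floor)
    rows = {}
    for j in range(result.k):
        g = cfg[:, j].astype(object)
        g[bad] = pd.NA
        rows[f"{sample_id}.c{j + 1}"] = g
    return pd.DataFrame(rows, index=result.region_ids).T.astype("Int8")


@dataclass(frozen=True)
class MAFSpectrum:
    """Distribution of per-locus alt fractions and its band-structure summary.

    A single diploid genome produces alt fractions concentrated in three
    bands at 0, 0.5 and 1; ``band_deviation`` is the fraction of
    well-covered loci falling outside delta-neighborhoods of those bands —
    a mixture of genomes pushes it up.
    """

    alt_fractions: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    band_deviation: float
    min_depth: int
    delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.hist_edges[:-1],
                "bin_right": self.hist_edges[1:],
                "count": self.hist_counts,
            }
        )


def maf_spectrum(depths: pd.DataFrame, min_depth: int = 100, delta: float = 0.1) -> MAFSpectrum:
    """Alt-fraction spectrum of loci with coverage >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not (0.0 < delta < 0.25):
        raise ValueError("delta must lie in (0, 0.25)")
    n = (depths["ref_count"] + depths["alt_count"]).to_numpy(dtype=float)
    ok = n >= min_depth
    if not ok.any():
        raise ValueError(f"no locus reaches min_depth={min_depth}")
    frac = depths["alt_count"].to_numpy(dtype=float)[ok] / n[ok]
    in_band = (frac <= delta) | (np.abs(frac - 0.5) <= delta) | (frac >= 1.0 - delta)
    counts, edges = np.histogram(frac, bins=50, range=(0.0, 1.0))
    return MAFSpectrum(
        alt_fractions=frac,
        hist_counts=counts,
        hist_edges=edges,
        band_deviation=float(1.0 - in_band.mean()),
        min_depth=min_depth,
        delta=delta,
    )
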