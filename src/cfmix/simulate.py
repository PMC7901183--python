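"""Synthetic pedigree and sequencing-read simulation for mixture deconvolution.

This module generates the data the analysis stages consume, with the
statistical structure they assume:

* a five-role pedigree — mother, her bone-marrow donor (a first-degree
  relative: full sibling by default, parent optionally), an egg donor and a
  father (both unrelated to the mother), and a fetus conceived from egg donor
  x father;
* per-locus allele depths for genomic DNA samples (Poisson depth, binomial
  allele sampling with a per-read substitution error);
* a plasma cell-free DNA sample mixing the bone-marrow-donor, maternal and
  placental genomes at fixed weights;
* ZFX/ZFY region depths driven by the sex-chromosome copy number of the mix.

Founder genotypes are Hardy-Weinberg draws from the panel's population allele
frequencies; children are formed by independent Mendelian transmission. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = [
    "ROLES",
    "KARYOTYPES",
    "Pedigree",
    "simulate_pedigree",
    "simulate_gdna_reads",
    "simulate_mixture_reads",
    "simulate_cfdna_mixture",
    "simulate_sex_dosage",
]

ROLES = ("mother", "bm_donor", "egg_donor", "father", "fetus")

#: (X copies, Y copies) per karyotype label
KARYOTYPES: dict[str, tuple[int, int]] = {"46,XX": (2, 0), "46,XY": (1, 1)}

#: default per-read substitution error of hybrid-capture sequencing
DEFAULT_ERROR_RATE = 0.005

SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class Pedigree:
    """True genotypes (0/1/2 alt-allele copies) for the five pedigree roles.

    ``genotypes`` is a roles x loci integer DataFrame over the panel's
    autosomal SNPs. ``donor_mode`` records whether the bone-marrow donor was
    simulated as the mother's full sibling or parent.
    """

    genotypes: pd.DataFrame
    donor_mode: str = "sibling"

    def __post_init__(self) -> None:
        missing = set(ROLES) - set(self.genotypes.index)
        if missing:
            raise ValueError(f"pedigree missing roles: {sorted(missing)}")

    def row(self, role: str) -> pd.Series:
        return self.genotypes.loc[role]


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per locus: allele 1 with probability g/2 (random segregation)."""
    return (rng.random(parent.shape[0]) < parent / 2.0).astype(np.int64)


def simulate_pedigree(panel: Panel, seed: int = 0, donor_mode: str = "sibling") -> Pedigree:
    """Draw pedigree genotypes over the panel's autosomal loci.

    Founders (the mother's two parents, the egg donor, the father) are
    Binomial(2, pop_af) draws per locus; mother and bone-marrow donor are
    formed by independent Mendelian transmission from the mother's parents
    (full siblings: IBD 0/1/2 with probability 1/4, 1/2, 1/4), or in
    ``donor_mode="parent"`` the donor is one of those parents; the fetus is a
    Mendelian child of egg donor x father.
    """
    if donor_mode not in ("sibling", "parent"):
        raise ValueError(f"donor_mode must be 'sibling' or 'parent', got {donor_mode!r}")
    af = panel.pop_af.to_numpy()
    if af.size == 0:
        raise ValueError("panel has no autosomal loci")
    rng = np.random.default_rng(seed)

    grandma = rng.binomial(2, af)
    grandpa = rng.binomial(2, af)
    mother = _transmit(grandma, rng) + _transmit(grandpa, rng)
    if donor_mode == "sibling":
        bm_donor = _transmit(grandma, rng) + _transmit(grandpa, rng)
    else:
        bm_donor = grandpa  # male first-degree relative: the mother's father
    egg_donor = rng.binomial(2, af)
    father = rng.binomial(2, af)
    fetus = _transmit(egg_donor, rng) + _transmit(father, rng)

    gt = pd.DataFrame(
        np.vstack([mother, bm_donor, egg_donor, father, fetus]),
        index=list(ROLES),
        columns=panel.snp_ids,
        dtype=np.int64,
    )
    return Pedigree(gt, donor_mode=donor_mode)


def _read_counts(
    q: np.ndarray,
    depth: float,
    eps: float,
    rng: np.random.Generator,
    fixed_n: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if not (0.0 <= eps < 0.5):
        raise ValueError(f"error rate must lie in [0, 0.5), got {eps}")
    if fixed_n:
        n = np.full(q.shape[0], int(round(depth)), dtype=np.int64)
    else:
        n = rng.poisson(depth, size=q.shape[0])
    p = q * (1.0 - eps) + (1.0 - q) * eps
    alt = rng.binomial(n, p)
    return n, alt


def _depth_frame(loci: Sequence[str], n: np.ndarray, alt: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"region_id": list(loci), "ref_count": n - alt, "alt_count": alt}
    ).set_index("region_id")


def simulate_gdna_reads(
    genotypes: pd.Series,
    depth: float = 2500.0,
    eps: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    fixed_n: bool = False,
) -> pd.DataFrame:
    """Allele depths for a single genome.

    Per locus, total reads n ~ Poisson(depth) (or exactly ``depth`` with
    ``fixed_n``) and alt reads ~ Binomial(n, p) with
    p = (g/2)(1-eps) + (1-g/2)·eps. Returns a DataFrame indexed by region_id
    with ``ref_count``/``alt_count`` columns.
    """
    g = genotypes.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n, alt = _read_counts(g / 2.0, depth, eps, rng, fixed_n)
    return _depth_frame(genotypes.index, n, alt)


def simulate_mixture_reads(
    component_genotypes: pd.DataFrame,
    weights: Sequence[float],
    depth: float = 2500.0,
    eps: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    fixed_n: bool = False,
) -> pd.DataFrame:
    """Allele depths for a weighted mixture of genomes.

    ``component_genotypes`` is a components x loci matrix; the expected alt
    fraction at each locus is q = sum_k w_k g_k / 2, read counts as in
    :func:`simulate_gdna_reads`.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != component_genotypes.shape[0]:
        raise ValueError("one weight per genotype row required")
    if (w < 0).any() or abs(w.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"weights must lie on the simplex, got {w.tolist()}")
    g = component_genotypes.to_numpy(dtype=float)
    q = (w @ g) / 2.0
    rng = np.random.default_rng(seed)
    n, alt = _read_counts(q, depth, eps, rng, fixed_n)
    return _depth_frame(component_genotypes.columns, n, alt)


def simulate_cfdna_mixture(
    pedigree: Pedigree,
    weights: Sequence[float],
    depth: float = 2500.0,
    eps: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    fixed_n: bool = False,
) -> pd.DataFrame:
    """Plasma cfDNA allele depths mixing three pedigree genomes.

    ``weights`` = (w_A, w_B, w_C) mapped to components A = bone-marrow donor
    (hematopoietic), B = mother (residual), C = fetus (placental).
    """
    if len(weights) != 3:
        raise ValueError("cfDNA mixture takes exactly three weights (donor, mother, fetus)")
    g = pedigree.genotypes.loc[["bm_donor", "mother", "fetus"]]
    return simulate_mixture_reads(g, weights, depth=depth, eps=eps, seed=seed, fixed_n=fixed_n)


def simulate_sex_dosage(
    panel: Panel,
    karyotypes: Sequence[str | tuple[int, int]],
    weights: Sequence[float],
    depth: float = 2500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ZFX/ZFY region depths for a mixture of components with known karyotype.

    Each component contributes its sex-chromosome copy number weighted by its
    mixture fraction: CN_mix = sum_k w_k CN_k. Every ZFX region draws depth
    ~ Poisson(depth * CN_X_mix / 2) and every ZFY region ~ Poisson(depth *
    CN_Y_mix / 2), i.e. a two-copy chromosome sequences at nominal depth.
    Returns a DataFrame indexed by region_id with a ``depth`` column.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(karyotypes):
        raise ValueError("one weight per component karyotype required")
    if (w < 0).any() or abs(w.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"weights must lie on the simplex, got {w.tolist()}")
    cn = np.array(
        [KARYOTYPES[k] if isinstance(k, str) else tuple(k) for k in karyotypes],
        dtype=float,
    )
    cn_x, cn_y = w @ cn[:, 0], w @ cn[:, 1]
    rng = np.random.default_rng(seed)
    rows = []
    for r in panel.zfx:
        rows.append((r.region_id, rng.poisson(depth * cn_x / 2.0)))
    for r in panel.zfy:
        rows.append((r.region_id, rng.poisson(depth * cn_y / 2.0)))
    return pd.DataFrame(rows, columns=["region_id", "depth"]).set_index("region_id")
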